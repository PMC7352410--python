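"""Gene-signature scoring and risk calls.

Implements the two per-sample prognostic scores for pseudomyxoma
peritonei expression profiles and their integration:

* **HRAC score** — mean log2 ratio of a "high-risk appendiceal cancer"
  gene signature versus a cohort-central reference sample (the sample
  most correlated with the averaged expression profile of the cohort).
* **CAF score** — mean linear-space signal of a cancer-associated
  fibroblast signature, by default centered on the cohort median so that
  a positive value carries the high-risk call.

Each continuous score is dichotomized at the cohort median (strictly
greater than the median → high risk), and the two binary calls are
combined by an OR rule: a unit is poor-prognosis if *either* score calls
it high.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .expression_io import LINEAR, LOG2, ExpressionMatrix

logger = logging.getLogger("pmprisk")

HIGH = "high"
LOW = "low"

#: Minimum fraction of signature genes that must be present in the matrix.
DEFAULT_MIN_COVERAGE = 0.5


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSignature:
    """A named, ordered, duplicate-free gene list."""

    name: str
    gene_symbols: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.gene_symbols) == 0:
            raise ValidationError(f"signature {self.name!r} is empty")
        folded = [g.casefold() for g in self.gene_symbols]
        if len(set(folded)) != len(folded):
            raise ValidationError(f"signature {self.name!r} has duplicate symbols")

    def __len__(self) -> int:
        return len(self.gene_symbols)


@dataclass
class ScoreTable:
    """Per-sample continuous scores with provenance.

    ``reference`` records the log2-ratio reference sample id (HRAC) or the
    centering constant (CAF); ``n_genes_used`` is the number of signature
    genes actually found in the matrix.
    """

    scores: pd.Series
    score_name: str
    reference: Optional[object] = None
    n_genes_used: int = 0

    def __post_init__(self) -> None:
        self.scores = self.scores.astype(float)
        self.scores.index = self.scores.index.astype(str)
        if self.scores.index.duplicated().any():
            raise ValidationError("duplicate unit ids in score table")
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValidationError("scores must be finite")


@dataclass
class RiskCall:
    """Binary high/low risk calls with threshold provenance."""

    calls: pd.Series
    threshold: Optional[float]
    source: str  # "HRAC" | "CAF" | "integrated"

    def __post_init__(self) -> None:
        self.calls.index = self.calls.index.astype(str)
        bad = set(self.calls.unique()) - {HIGH, LOW}
        if bad:
            raise ValidationError(f"invalid call labels: {sorted(bad)}")


# ---------------------------------------------------------------------------
# Signature loading and mapping
# ---------------------------------------------------------------------------

def load_signature(path, name: str) -> GeneSignature:
    """Load a plain-text gene list (one symbol per line, '#' comments)."""
    symbols: list[str] = []
    seen: set[str] = set()
    n_dup = 0
    for raw in Path(path).read_text().replace("\r\n", "\n").split("\n"):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key = line.casefold()
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        symbols.append(line)
    if n_dup:
        logger.warning("signature %s: removed %d duplicate symbols", name, n_dup)
    if not symbols:
        raise ValidationError(f"signature file {path} contains no gene symbols")
    return GeneSignature(name=name, gene_symbols=tuple(symbols), source=str(path))


def write_signature(sig: GeneSignature, path) -> None:
    Path(path).write_text("\n".join(sig.gene_symbols) + "\n")


def _matrix_gene_index(matrix: ExpressionMatrix) -> dict[str, str]:
    idx: dict[str, str] = {}
    for label in matrix.gene_ids:
        key = label.strip().casefold()
        if key not in idx:
            idx[key] = label
    return idx


def map_signature(sig: GeneSignature, matrix: ExpressionMatrix,
                  min_coverage: float = DEFAULT_MIN_COVERAGE,
                  ) -> tuple[list[str], list[str]]:
    """Partition a signature into (present, missing) w.r.t. the matrix rows.

    Matching is case-insensitive after whitespace stripping.  Raises when
    coverage is zero or falls below ``min_coverage``; logs a warning for
    any partial coverage.
    """
    idx = _matrix_gene_index(matrix)
    present = [g for g in sig.gene_symbols if g.strip().casefold() in idx]
    missing = [g for g in sig.gene_symbols if g.strip().casefold() not in idx]
    coverage = len(present) / len(sig)
    if coverage == 0:
        raise ValidationError(f"signature {sig.name!r}: no gene found in matrix")
    if coverage < min_coverage:
        raise ValidationError(
            f"signature {sig.name!r}: coverage {coverage:.2f} below minimum {min_coverage:.2f}"
        )
    if missing:
        logger.warning("signature %s: coverage %.2f (%d/%d genes present)",
                       sig.name, coverage, len(present), len(sig))
    else:
        logger.info("signature %s: all %d genes present", sig.name, len(sig))
    return present, missing


def _signature_rows(sig: GeneSignature, matrix: ExpressionMatrix,
                    min_coverage: float) -> list[str]:
    idx = _matrix_gene_index(matrix)
    present, _ = map_signature(sig, matrix, min_coverage=min_coverage)
    return [idx[g.strip().casefold()] for g in present]


# ---------------------------------------------------------------------------
# Central sample
# ---------------------------------------------------------------------------

def _central_of(values: pd.DataFrame) -> str:
    """Column most correlated (Pearson, over all genes) with the column mean.

    Zero-variance columns are excluded with a warning; exact ties break to
    the first column in order.
    """
    arr = values.to_numpy(dtype=float)
    mean_profile = arr.mean(axis=1)
    if np.std(mean_profile) == 0:
        raise ValidationError("mean profile has zero variance; correlation undefined")
    mp = mean_profile - mean_profile.mean()
    mp_norm = np.sqrt((mp ** 2).sum())
    best_r = -np.inf
    best_col = None
    for j, col in enumerate(values.columns):
        x = arr[:, j] - arr[:, j].mean()
        xn = np.sqrt((x ** 2).sum())
        if xn == 0:
            logger.warning("central sample: %r has constant expression; excluded", col)
            continue
        # round so that mathematically exact ties (e.g. constant shifts)
        # survive floating-point noise and resolve by sample order
        r = round(float((x @ mp) / (xn * mp_norm)), 12)
        if r > best_r:
            best_r = r
            best_col = col
    if best_col is None:
        raise ValidationError("all samples have constant expression; no central sample")
    return str(best_col)


def cohort_central_sample(matrix: ExpressionMatrix) -> str:
    """The cohort's central sample: maximal Pearson correlation with the
    per-gene mean profile across all samples (log2-space matrix required)."""
    if matrix.space != LOG2:
        raise ValidationError("cohort_central_sample expects a log2-space matrix")
    if matrix.shape[1] < 2:
        raise ValidationError("need at least 2 samples to select a central sample")
    return _central_of(matrix.values)


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

def hrac_score(matrix: ExpressionMatrix, sig: GeneSignature, reference: str,
               min_coverage: float = DEFAULT_MIN_COVERAGE) -> ScoreTable:
    """HRAC score: per-sample mean log2 ratio of signature genes versus the
    reference sample, computed from the linear-space matrix.

    ``score(reference) == 0`` by construction.
    """
    if matrix.space != LINEAR:
        raise ValidationError("hrac_score expects a linear-space matrix")
    if reference not in matrix.values.columns:
        raise ValidationError(f"reference sample {reference!r} not in matrix")
    rows = _signature_rows(sig, matrix, min_coverage)
    sub = matrix.values.loc[rows]
    arr = sub.to_numpy(dtype=float)
    if (arr <= 0).any():
        i, j = np.argwhere(arr <= 0)[0]
        raise ValidationError(
            f"non-positive linear value for signature gene {sub.index[i]!r} "
            f"in sample {sub.columns[j]!r}"
        )
    ratios = np.log2(arr / sub[reference].to_numpy(dtype=float)[:, None])
    scores = pd.Series(ratios.mean(axis=0), index=sub.columns)
    return ScoreTable(scores=scores, score_name="HRAC",
                      reference=str(reference), n_genes_used=len(rows))


def caf_score(matrix: ExpressionMatrix, sig: GeneSignature,
              centering: str = "cohort_median",
              cohort: Optional[Sequence[str]] = None,
              min_coverage: float = DEFAULT_MIN_COVERAGE) -> ScoreTable:
    """CAF score: per-sample mean *linear-space* signal of signature genes.

    With ``centering="cohort_median"`` (default) the median raw score of
    the threshold cohort (default: all samples) is subtracted so the sign
    of the score carries the high/low call; ``centering="none"`` returns
    the raw mean signal.
    """
    if matrix.space != LINEAR:
        raise ValidationError("caf_score expects a linear-space matrix")
    if centering not in ("cohort_median", "none"):
        raise ValidationError(f"unknown centering {centering!r}")
    rows = _signature_rows(sig, matrix, min_coverage)
    sub = matrix.values.loc[rows]
    raw = pd.Series(sub.to_numpy(dtype=float).mean(axis=0), index=sub.columns)
    if centering == "cohort_median":
        cohort_ids = list(raw.index) if cohort is None else list(cohort)
        missing = [c for c in cohort_ids if c not in raw.index]
        if missing:
            raise ValidationError(f"centering cohort samples not scored: {missing[:10]}")
        if not cohort_ids:
            raise ValidationError("empty centering cohort")
        center = float(np.median(raw.loc[cohort_ids]))
        return ScoreTable(scores=raw - center, score_name="CAF",
                          reference=center, n_genes_used=len(rows))
    return ScoreTable(scores=raw, score_name="CAF", reference=None, n_genes_used=len(rows))


# ---------------------------------------------------------------------------
# Risk calls
# ---------------------------------------------------------------------------

def median_threshold_call(scores: ScoreTable,
                          cohort: Optional[Sequence[str]] = None) -> RiskCall:
    """Dichotomize scores at the cohort median.

    The threshold is the median score over ``cohort`` (default: every
    scored unit); a unit is called high iff its score is strictly greater
    than the threshold, so the median unit itself is low.  For an even
    cohort the median is the midpoint of the two central order statistics.
    """
    s = scores.scores
    cohort_ids = list(s.index) if cohort is None else list(cohort)
    if len(cohort_ids) == 0:
        raise ValidationError("empty threshold cohort")
    missing = [c for c in cohort_ids if c not in s.index]
    if missing:
        raise ValidationError(f"threshold cohort units not scored: {missing[:10]}")
    threshold = float(np.median(s.loc[cohort_ids].to_numpy()))
    calls = pd.Series(np.where(s.to_numpy() > threshold, HIGH, LOW), index=s.index)
    return RiskCall(calls=calls, threshold=threshold, source=scores.score_name)


def integrate_calls(hrac: RiskCall, caf: RiskCall) -> RiskCall:
    """OR-rule integration: high iff the HRAC call OR the CAF call is high."""
    if set(hrac.calls.index) != set(caf.calls.index):
        raise ValidationError("integrate_calls: unit id mismatch between inputs")
    caf_aligned = caf.calls.loc[hrac.calls.index]
    merged = np.where((hrac.calls == HIGH) | (caf_aligned == HIGH), HIGH, LOW)
    return RiskCall(calls=pd.Series(merged, index=hrac.calls.index),
                    threshold=None, source="integrated")


def score_orthogonality(hrac: ScoreTable, caf: ScoreTable) -> float:
    """Squared Pearson correlation (R²) of the two scores on common units.

    Returns NaN (with a warning) when either vector is constant, in which
    case the correlation is undefined.
    """
    common = [u for u in hrac.scores.index if u in set(caf.scores.index)]
    if len(common) < 3:
        raise ValidationError("score_orthogonality needs >= 3 common units")
    x = hrac.scores.loc[common].to_numpy()
    y = caf.scores.loc[common].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("score_orthogonality: constant score vector; R^2 undefined")
        return float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r
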