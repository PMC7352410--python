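"""Expression-matrix I/O and preprocessing.

Reads gene-by-sample expression data (plain tab-delimited tables or the
table block of a GEO series-matrix file), applies the bead-array style
preprocessing contract — detection-p probe filtering, probe→gene collapse
by maximal signal variance, between-sample normalization (cyclic loess or
quantile) — and moves matrices between linear and log2 signal space.

All downstream scoring consumes the :class:`ExpressionMatrix` produced
here.  The matrix carries an explicit ``space`` flag because the two
signature scores of the pipeline are defined in different spaces: the
cancer-cell score in log2-ratio space, the stromal score in linear signal
space.
"""
from __future__ import annotations

import io
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .errors import ValidationError

logger = logging.getLogger("pmprisk")

LINEAR = "linear"
LOG2 = "log2"
SPACES = (LINEAR, LOG2)

#: Loess smoother span and number of cyclic passes used by cyclic-loess
#: between-sample normalization.
LOESS_SPAN = 0.7
LOESS_ITERATIONS = 2


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A validated genes × samples expression matrix.

    Parameters
    ----------
    values
        DataFrame with gene (or probe) ids on the index and sample ids on
        the columns.  All values must be finite; in linear space they must
        be strictly positive.
    space
        ``"linear"`` (raw signal intensities) or ``"log2"``.
    """

    values: pd.DataFrame
    space: str = LINEAR

    def __post_init__(self) -> None:
        if self.space not in SPACES:
            raise ValidationError(f"unknown space {self.space!r}; expected one of {SPACES}")
        if not isinstance(self.values, pd.DataFrame):
            raise ValidationError("values must be a pandas DataFrame")
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        dup_genes = self.values.index[self.values.index.duplicated()].unique().tolist()
        if dup_genes:
            raise ValidationError(f"duplicate gene/probe ids: {dup_genes[:10]}")
        dup_samples = self.values.columns[self.values.columns.duplicated()].unique().tolist()
        if dup_samples:
            raise ValidationError(f"duplicate sample ids: {dup_samples[:10]}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value at row {self.values.index[bad[0]]!r}, "
                f"column {self.values.columns[bad[1]]!r}"
            )
        if self.space == LINEAR and (arr <= 0).any():
            bad = np.argwhere(arr <= 0)[0]
            raise ValidationError(
                f"non-positive value {arr[bad[0], bad[1]]!r} in linear space at row "
                f"{self.values.index[bad[0]]!r}, column {self.values.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing[:10]}")
        return ExpressionMatrix(self.values[list(sample_ids)].copy(), self.space)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.space)


@dataclass
class DetectionTable:
    """Per-probe, per-sample detection p-values accompanying a raw matrix."""

    detection_p: pd.DataFrame

    def __post_init__(self) -> None:
        self.detection_p.index = self.detection_p.index.astype(str)
        self.detection_p.columns = self.detection_p.columns.astype(str)
        arr = self.detection_p.to_numpy()
        if not np.isfinite(arr).all():
            raise ValidationError("detection p-values must be finite")
        if ((arr < 0) | (arr > 1)).any():
            raise ValidationError("detection p-values must lie in [0, 1]")


@dataclass
class ProbeGeneMap:
    """Many-to-one probe → gene-symbol mapping.

    Symbols are stored whitespace-stripped; matching against expression
    rows is case-insensitive.
    """

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        clean = {}
        for probe, symbol in self.mapping.items():
            symbol = str(symbol).strip()
            if not symbol:
                raise ValidationError(f"empty gene symbol for probe {probe!r}")
            if probe in clean:
                raise ValidationError(f"probe {probe!r} mapped more than once")
            clean[str(probe)] = symbol
        self.mapping = clean


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_text(path) -> str:
    text = Path(path).read_text()
    # tolerate CRLF and trailing blank lines
    text = text.replace("\r\n", "\n").replace("\r", "\n")
    return text.rstrip("\n") + "\n"


def _parse_numeric_table(text: str, what: str) -> pd.DataFrame:
    lines = [ln for ln in text.split("\n") if ln.strip() != ""]
    if not lines:
        raise ValidationError(f"{what}: file is empty")
    header = [h.strip().strip('"') for h in lines[0].split("\t")]
    sample_ids = header[1:]
    seen: set[str] = set()
    dups = [s for s in sample_ids if s in seen or seen.add(s)]  # type: ignore[func-returns-value]
    if dups:
        raise ValidationError(f"{what}: duplicate sample ids in header: {sorted(set(dups))}")
    df = pd.read_csv(
        io.StringIO("\n".join(lines)), sep="\t", index_col=0, dtype=str,
        keep_default_na=False, quotechar='"',
    )
    df.index = [str(i).strip().strip('"') for i in df.index]
    df.columns = sample_ids
    out = {}
    for col in df.columns:
        cleaned = df[col].str.strip().str.strip('"')
        converted = pd.to_numeric(cleaned, errors="coerce")
        bad = converted.index[converted.isna()]
        if len(bad):
            raise ValidationError(
                f"{what}: non-numeric value {df.loc[bad[0], col]!r} at "
                f"row {bad[0]!r}, column {col!r}"
            )
        out[col] = converted.astype(float)
    return pd.DataFrame(out, index=df.index)


def _extract_series_matrix_table(text: str) -> str:
    lines = text.split("\n")
    start = end = None
    for i, ln in enumerate(lines):
        tag = ln.strip().lower()
        if tag == "!series_matrix_table_begin":
            start = i + 1
        elif tag == "!series_matrix_table_end":
            end = i
            break
    if start is None or end is None or end <= start:
        raise ValidationError(
            "series_matrix layout: missing !series_matrix_table_begin/_end block"
        )
    return "\n".join(lines[start:end]) + "\n"


def read_expression_matrix(path, layout: str = "tabular", space: str = LINEAR) -> ExpressionMatrix:
    """Read an expression matrix from disk.

    ``layout="tabular"`` expects a tab-delimited file whose header row
    holds sample ids and whose first column holds gene/probe ids.
    ``layout="series_matrix"`` extracts the table block of a GEO
    series-matrix style file (metadata lines starting with ``!`` are
    ignored).  ``space`` declares the signal space of the stored values
    (default linear, i.e. raw intensities).
    """
    if layout not in ("tabular", "series_matrix"):
        raise ValidationError(f"unknown layout {layout!r}")
    text = _read_text(path)
    if layout == "series_matrix":
        text = _extract_series_matrix_table(text)
    df = _parse_numeric_table(text, what=str(path))
    return ExpressionMatrix(df, space=space)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix in the tabular layout read back by
    :func:`read_expression_matrix` (lossless to full float precision)."""
    matrix.values.to_csv(path, sep="\t", index_label="id",
                         float_format="%.17g", lineterminator="\n")


def read_detection_table(path) -> DetectionTable:
    """Read a companion detection p-value table (same tabular layout)."""
    df = _parse_numeric_table(_read_text(path), what=str(path))
    return DetectionTable(df)


def read_probe_gene_map(path) -> ProbeGeneMap:
    """Read a two-column headerless TSV: probe_id <TAB> gene_symbol."""
    mapping: dict[str, str] = {}
    for lineno, ln in enumerate(_read_text(path).split("\n"), start=1):
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) < 2:
            raise ValidationError(f"{path}: line {lineno}: expected two tab-separated columns")
        probe, symbol = parts[0].strip(), parts[1].strip()
        if probe in mapping:
            raise ValidationError(f"{path}: probe {probe!r} appears more than once")
        mapping[probe] = symbol
    if not mapping:
        raise ValidationError(f"{path}: empty probe map")
    return ProbeGeneMap(mapping)


# ---------------------------------------------------------------------------
# Preprocessing operations
# ---------------------------------------------------------------------------

def filter_detected_probes(matrix: ExpressionMatrix, det: DetectionTable,
                           max_detection_p: float = 0.0) -> ExpressionMatrix:
    """Keep probes with a detectable signal in at least one sample.

    A probe is detectable in a sample when its detection p-value is
    ``<= max_detection_p``; the default 0.0 reproduces the strict
    "detection p value = 0" rule, while a small epsilon accommodates
    platforms that never emit exact zeros.  Row order is preserved.
    """
    missing = [p for p in matrix.gene_ids if p not in det.detection_p.index]
    if missing:
        raise ValidationError(f"probes missing from detection table: {missing[:10]}")
    missing_s = [s for s in matrix.sample_ids if s not in det.detection_p.columns]
    if missing_s:
        raise ValidationError(f"samples missing from detection table: {missing_s[:10]}")
    sub = det.detection_p.loc[matrix.gene_ids, matrix.sample_ids]
    keep = (sub.to_numpy() <= max_detection_p).any(axis=1)
    logger.info("detection filter: kept %d / %d probes (p <= %g in >=1 sample)",
                int(keep.sum()), len(keep), max_detection_p)
    if not keep.any():
        raise ValidationError("detection filter removed every probe")
    return ExpressionMatrix(matrix.values.loc[keep].copy(), matrix.space)


def collapse_probes_to_genes(matrix: ExpressionMatrix, probe_map: ProbeGeneMap,
                             variance_space: str = LOG2) -> ExpressionMatrix:
    """Collapse probe rows to one row per gene symbol.

    For genes targeted by several probes the probe with the highest
    signal variance across all samples is retained.  Variance is ranked
    in ``variance_space`` (default log2, where bead-array variances are
    usually compared); ties break to the lexicographically smallest probe
    id.  Unmapped probes are dropped with a logged count.  Gene symbols
    are matched case-insensitively; the retained probe's stripped symbol
    is used as the output row label.
    """
    if variance_space not in SPACES:
        raise ValidationError(f"unknown variance_space {variance_space!r}")
    mapped_probes = [p for p in matrix.gene_ids if p in probe_map.mapping]
    if not mapped_probes:
        raise ValidationError("no probes shared between matrix and probe map")
    n_unmapped = matrix.shape[0] - len(mapped_probes)
    if n_unmapped:
        logger.info("probe collapse: dropped %d unmapped probes", n_unmapped)

    vals = matrix.values.loc[mapped_probes]
    if variance_space == LOG2 and matrix.space == LINEAR:
        var_basis = np.log2(vals.to_numpy())
    elif variance_space == LINEAR and matrix.space == LOG2:
        var_basis = np.exp2(vals.to_numpy())
    else:
        var_basis = vals.to_numpy()
    variances = var_basis.var(axis=1)  # population variance; ranking only

    best: dict[str, tuple[float, str]] = {}
    display: dict[str, str] = {}
    order: list[str] = []
    for probe, var in zip(mapped_probes, variances):
        symbol = probe_map.mapping[probe]
        key = symbol.casefold()
        if key not in best:
            best[key] = (var, probe)
            display[key] = symbol
            order.append(key)
        else:
            cur_var, cur_probe = best[key]
            # higher variance wins; exact tie -> lexicographically smaller id
            if var > cur_var or (var == cur_var and probe < cur_probe):
                best[key] = (var, probe)
    rows = [best[k][1] for k in order]
    out = matrix.values.loc[rows].copy()
    out.index = [display[k] for k in order]
    logger.info("probe collapse: %d probes -> %d genes", len(mapped_probes), len(order))
    return ExpressionMatrix(out, matrix.space)


def _loess_fit(a: np.ndarray, m: np.ndarray, span: float) -> np.ndarray:
    spread = float(a.max() - a.min())
    return _sm_lowess(m, a, frac=span, it=1, delta=0.01 * spread, return_sorted=False)


def normalize_between_samples(matrix: ExpressionMatrix, method: str = "cyclic_loess",
                              span: float = LOESS_SPAN, iterations: int = LOESS_ITERATIONS,
                              variant: str = "fast") -> ExpressionMatrix:
    """Harmonize per-sample signal distributions (linear-space input).

    ``cyclic_loess`` fits a loess trend to each sample's M (log2 ratio)
    versus A (mean log2 signal) against a reference and subtracts it; the
    default ``"fast"`` variant uses the cohort mean log2 profile as the
    reference (one smoother fit per sample per iteration), while
    ``"pairs"`` performs the full pairwise cycle.  ``quantile`` forces all
    per-sample sorted value vectors to their cross-sample mean.  ``none``
    returns a copy.  Output stays in linear space.
    """
    if matrix.space != LINEAR:
        raise ValidationError("normalization requires a linear-space matrix")
    if method == "none":
        logger.info("normalization: method=none (matrix passed through)")
        return matrix.copy()
    v = matrix.values.to_numpy(dtype=float)
    if method == "quantile":
        order = np.argsort(v, axis=0, kind="stable")
        mean_sorted = np.sort(v, axis=0).mean(axis=1)
        out = np.empty_like(v)
        for j in range(v.shape[1]):
            out[order[:, j], j] = mean_sorted
    elif method == "cyclic_loess":
        if variant not in ("fast", "pairs"):
            raise ValidationError(f"unknown cyclic loess variant {variant!r}")
        x = np.log2(v)
        n = x.shape[1]
        for _ in range(iterations):
            if variant == "fast":
                ref = x.mean(axis=1)
                for j in range(n):
                    mm = x[:, j] - ref
                    aa = (x[:, j] + ref) / 2.0
                    x[:, j] -= _loess_fit(aa, mm, span)
            else:
                for j in range(n):
                    for k in range(j + 1, n):
                        mm = x[:, j] - x[:, k]
                        aa = (x[:, j] + x[:, k]) / 2.0
                        fit = _loess_fit(aa, mm, span)
                        x[:, j] -= fit / 2.0
                        x[:, k] += fit / 2.0
        out = np.exp2(x)
    else:
        raise ValidationError(f"unknown normalization method {method!r}")
    logger.info("normalization: method=%s variant=%s span=%g iterations=%d",
                method, variant if method == "cyclic_loess" else "-", span, iterations)
    return ExpressionMatrix(pd.DataFrame(out, index=matrix.values.index,
                                         columns=matrix.values.columns), LINEAR)


def change_space(matrix: ExpressionMatrix, target: str) -> ExpressionMatrix:
    """Move a matrix between linear and log2 space (round trip is identity)."""
    if target not in SPACES:
        raise ValidationError(f"unknown target space {target!r}")
    if target == matrix.space:
        return matrix.copy()
    arr = matrix.values.to_numpy(dtype=float)
    if matrix.space == LINEAR:
        if (arr <= 0).any():
            raise ValidationError("cannot log2-transform non-positive linear values")
        new = np.log2(arr)
    else:
        new = np.exp2(arr)
    return ExpressionMatrix(pd.DataFrame(new, index=matrix.values.index,
                                         columns=matrix.values.columns), target)
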