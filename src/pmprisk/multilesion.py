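"""Multi-lesion handling: cohort annotation, per-patient aggregation,
and intra-patient score heterogeneity.

Pseudomyxoma peritonei spreads locoregionally, so one patient may
contribute several lesion profiles with discordant risk scores.  This
module reduces lesion-level scores to one score per patient using the
strategies compared in the analysis (representative "central" sample,
gene-wise mean profile, mean / highest / middle / lowest score) and
quantifies discordance (lesion scores spanning both signs, i.e. lesions
of the same patient predicting opposite outcomes).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .expression_io import LINEAR, LOG2, ExpressionMatrix, change_space
from .signatures import ScoreTable, _central_of

logger = logging.getLogger("pmprisk")

HISTOLOGIES = ("DPAM", "PMCA", "CRC")
ANNOTATION_COLUMNS = ("patient_id", "lesion_label", "histology",
                      "dfs_months", "dfs_event", "os_months", "os_event")
AGGREGATION_STRATEGIES = ("central", "mean_profile", "mean_score",
                          "highest", "middle", "lowest")


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

@dataclass
class CohortAnnotation:
    """Per-sample clinical/structural metadata.

    ``table`` is indexed by sample_id and holds the columns
    ``patient_id, lesion_label, histology, dfs_months, dfs_event,
    os_months, os_event``.  Survival fields must agree across lesions of
    the same patient (they are patient-level endpoints).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in ANNOTATION_COLUMNS if c not in t.columns]
        if missing:
            raise ValidationError(f"annotation missing columns: {missing}")
        t.index = t.index.astype(str)
        if t.index.duplicated().any():
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids in annotation: {dups[:10]}")
        bad_hist = set(t["histology"].unique()) - set(HISTOLOGIES)
        if bad_hist:
            raise ValidationError(f"unknown histology labels: {sorted(bad_hist)}")
        for col in ("dfs_months", "os_months"):
            vals = t[col].to_numpy(dtype=float)
            if not np.isfinite(vals).all() or (vals < 0).any():
                raise ValidationError(f"{col} must be finite and non-negative")
            t[col] = vals
        for col in ("dfs_event", "os_event"):
            t[col] = _as_bool(t[col], col)
        t["patient_id"] = t["patient_id"].astype(str)
        # patient-level fields must be consistent across that patient's lesions
        for col in ("histology", "dfs_months", "dfs_event", "os_months", "os_event"):
            if t.groupby("patient_id")[col].nunique().gt(1).any():
                raise ValidationError(f"{col} differs between lesions of one patient")

    @property
    def sample_ids(self) -> list[str]:
        return self.table.index.tolist()

    @property
    def patient_ids(self) -> list[str]:
        return pd.unique(self.table["patient_id"]).tolist()

    def samples_of_patient(self, patient_id: str) -> list[str]:
        return self.table.index[self.table["patient_id"] == patient_id].tolist()

    def multi_lesion_patients(self) -> list[str]:
        counts = self.table.groupby("patient_id").size()
        order = {p: i for i, p in enumerate(self.patient_ids)}
        return sorted(counts.index[counts >= 2].tolist(), key=order.get)

    def patient_table(self) -> pd.DataFrame:
        """One row per patient (histology + survival endpoints)."""
        cols = ["histology", "dfs_months", "dfs_event", "os_months", "os_event"]
        return (self.table.reset_index(drop=True)
                .groupby("patient_id", sort=False)[cols].first())

    def subset(self, sample_ids: Sequence[str]) -> "CohortAnnotation":
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise ValidationError(f"samples not in annotation: {missing[:10]}")
        return CohortAnnotation(self.table.loc[list(sample_ids)].copy())


def _as_bool(series: pd.Series, name: str) -> pd.Series:
    mapping = {"true": True, "false": False, "1": True, "0": False,
               "t": True, "f": False, "yes": True, "no": False}
    out = []
    for v in series:
        if isinstance(v, (bool, np.bool_)):
            out.append(bool(v))
        elif isinstance(v, (int, np.integer, float, np.floating)) and v in (0, 1):
            out.append(bool(v))
        elif str(v).strip().lower() in mapping:
            out.append(mapping[str(v).strip().lower()])
        else:
            raise ValidationError(f"{name}: cannot interpret {v!r} as boolean")
    return pd.Series(out, index=series.index)


def read_annotation(path) -> CohortAnnotation:
    """Read the annotation CSV (columns: sample_id, patient_id, lesion_label,
    histology, dfs_months, dfs_event, os_months, os_event)."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: annotation must have a sample_id column")
    df = df.set_index("sample_id")
    return CohortAnnotation(df)


def write_annotation(ann: CohortAnnotation, path) -> None:
    out = ann.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, lineterminator="\n")


# ---------------------------------------------------------------------------
# Per-patient central sample
# ---------------------------------------------------------------------------

def patient_central_sample(matrix: ExpressionMatrix,
                           samples_of_patient: Sequence[str],
                           metric: str = "pearson") -> str:
    """The patient's representative lesion: the profile closest to the
    patient's averaged global expression profile.

    Closeness is maximal Pearson correlation with the per-gene mean over
    the patient's lesions (``metric="euclidean"`` minimizes distance to
    the mean instead).  Single-sample patients return their only sample;
    ties break to the first sample in input order.  Requires log2 space.
    """
    samples = [str(s) for s in samples_of_patient]
    if not samples:
        raise ValidationError("patient has no samples")
    if matrix.space != LOG2:
        raise ValidationError("patient_central_sample expects a log2-space matrix")
    missing = [s for s in samples if s not in matrix.values.columns]
    if missing:
        raise ValidationError(f"samples not in matrix: {missing}")
    if len(samples) == 1:
        return samples[0]
    sub = matrix.values[samples]
    if metric == "pearson":
        return _central_of(sub)
    if metric == "euclidean":
        arr = sub.to_numpy(dtype=float)
        mean_profile = arr.mean(axis=1)
        d = np.sqrt(((arr - mean_profile[:, None]) ** 2).sum(axis=0))
        return samples[int(np.argmin(d))]
    raise ValidationError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate_patient_scores(scores: ScoreTable, ann: CohortAnnotation,
                             strategy: str,
                             matrix: Optional[ExpressionMatrix] = None,
                             score_fn: Optional[Callable[[ExpressionMatrix], ScoreTable]] = None,
                             ) -> pd.DataFrame:
    """Reduce lesion-level scores to one score per patient.

    Strategies: ``central`` picks the score of the patient's central
    sample (needs ``matrix``); ``mean_profile`` averages lesion profiles
    gene-wise and scores the averaged profile (needs ``matrix`` and
    ``score_fn``); ``mean_score``/``highest``/``middle``/``lowest`` are
    arithmetic on the lesion scores (middle = median, midpoint convention
    for even lesion counts).

    Returns a DataFrame indexed by patient_id with columns ``score``,
    ``strategy``, ``representative_sample`` (set iff strategy=central) and
    ``discordant`` (lesion scores contain both a positive and a negative
    value).
    """
    if strategy not in AGGREGATION_STRATEGIES:
        raise ValidationError(f"unknown aggregation strategy {strategy!r}")
    scored = set(scores.scores.index)
    patients = [p for p in ann.patient_ids
                if any(s in scored for s in ann.samples_of_patient(p))]
    if not patients:
        raise ValidationError("no scored samples among annotated patients")

    mean_profile_scores: Optional[pd.Series] = None
    if strategy == "mean_profile":
        if matrix is None or score_fn is None:
            raise ValidationError("mean_profile aggregation needs matrix and score_fn")
        if matrix.space != LINEAR:
            raise ValidationError("mean_profile averages linear-space lesion profiles")
        profiles = {}
        for p in patients:
            lesions = [s for s in ann.samples_of_patient(p) if s in scored]
            profiles[p] = matrix.values[lesions].to_numpy(dtype=float).mean(axis=1)
        pm = ExpressionMatrix(pd.DataFrame(profiles, index=matrix.values.index), LINEAR)
        mean_profile_scores = score_fn(pm).scores

    log2m: Optional[ExpressionMatrix] = None
    if strategy == "central":
        if matrix is None:
            raise ValidationError("central aggregation needs the expression matrix")
        log2m = matrix if matrix.space == LOG2 else change_space(matrix, LOG2)

    rows = []
    for p in patients:
        lesions = [s for s in ann.samples_of_patient(p) if s in scored]
        lesion_scores = scores.scores.loc[lesions].to_numpy()
        discordant = bool((lesion_scores > 0).any() and (lesion_scores < 0).any())
        rep = None
        if strategy == "central":
            rep = patient_central_sample(log2m, lesions)
            value = float(scores.scores.loc[rep])
        elif strategy == "mean_profile":
            value = float(mean_profile_scores.loc[p])
        elif strategy == "mean_score":
            value = float(lesion_scores.mean())
        elif strategy == "highest":
            value = float(lesion_scores.max())
        elif strategy == "lowest":
            value = float(lesion_scores.min())
        else:  # middle
            value = float(np.median(lesion_scores))
        rows.append({"patient_id": p, "score": value, "strategy": strategy,
                     "representative_sample": rep, "discordant": discordant})
    return pd.DataFrame(rows).set_index("patient_id")


def patient_score_table(patient_scores: pd.DataFrame, score_name: str,
                        reference=None, n_genes_used: int = 0) -> ScoreTable:
    """View an aggregated per-patient score frame as a ScoreTable."""
    return ScoreTable(scores=patient_scores["score"].copy(), score_name=score_name,
                      reference=reference, n_genes_used=n_genes_used)


def count_discordant_patients(scores: ScoreTable, ann: CohortAnnotation) -> int:
    """Number of multi-lesion patients whose lesion scores include at least
    one strictly positive and one strictly negative value (exact zeros
    count as neither)."""
    scored = set(scores.scores.index)
    n = 0
    for p in ann.multi_lesion_patients():
        lesions = [s for s in ann.samples_of_patient(p) if s in scored]
        if len(lesions) < 2:
            continue
        vals = scores.scores.loc[lesions].to_numpy()
        if (vals > 0).any() and (vals < 0).any():
            n += 1
    return n
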