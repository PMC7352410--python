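"""Synthetic multifocal PMP-like cohorts with known latent structure.

The generator emulates the structure of the profiled cohort: 24 patients
(13 DPAM / 11 PMCA), ~9 of whom contribute multiple lesions, plus 11 CRC
peritoneal-carcinomatosis controls.  Two independent latent Bernoulli
risk factors live at the patient level:

* a **cancer-cell risk factor** expressed as a ± shift/2 log2 deviation
  of the HRAC signature genes (so latent-high and latent-low lesions
  differ by exactly ``hrac_log2_shift`` in mean log2 ratio),
* a **stromal-abundance factor** expressed as a Beta-distributed
  per-lesion CAF fraction that multiplicatively scales the CAF signature
  genes in linear space.

Occasional outlier lesions of multifocal patients flip the sign of their
patient's HRAC deviation, reproducing the intra-patient sign-discordance
phenomenon seen in multi-lesion profiling.  Disease-free survival is
exponential with a hazard multiplied by a ratio for each latent factor —
the OR-like risk structure the integrated classifier targets — with
independent exponential censoring and an administrative follow-up
horizon.  All randomness derives from one master seed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError
from .expression_io import LINEAR, ExpressionMatrix, write_expression_matrix
from .multilesion import CohortAnnotation, write_annotation
from .signatures import GeneSignature, HIGH, RiskCall, write_signature

logger = logging.getLogger("pmprisk")

OS_HAZARD_FACTOR = 0.5  # overall-survival hazard relative to DFS hazard


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the profiled study cohort: 24 patients, 13/24 DPAM,
    multi-lesion probability 9/24 (2-4 lesions when multifocal), a
    139-gene cancer-cell signature, 11 CRC controls; effect sizes
    ``hrac_log2_shift=1.0`` with lesion noise sd 0.2 give a strongly
    separable cohort.  Hazards are per month.
    """

    seed: int
    n_patients: int = 24
    frac_dpam: float = 13 / 24
    p_multi_lesion: float = 9 / 24
    lesion_min: int = 2
    lesion_max: int = 4
    n_genes: int = 2000
    n_hrac_genes: int = 139
    n_caf_genes: int = 50
    hrac_log2_shift: float = 1.0
    lesion_noise_sd: float = 0.2
    outlier_prob: float = 0.1
    outlier_flip_scale: float = 1.0
    prevalence_hrac: float = 0.5
    prevalence_caf: float = 0.5
    caf_high_mean: float = 0.7
    caf_low_mean: float = 0.3
    caf_concentration: float = 40.0
    caf_floor: float = 0.25
    caf_scale: float = 1.5
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.0
    baseline_hazard: float = 0.012
    hr_hrac: float = 5.0
    hr_caf: float = 5.0
    censor_rate: float = 0.004
    followup_months: float = 60.0
    n_crc: int = 11
    crc_caf_mean: float = 0.15

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        for name in ("frac_dpam", "p_multi_lesion", "outlier_prob",
                     "prevalence_hrac", "prevalence_caf"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        for name in ("caf_high_mean", "caf_low_mean", "crc_caf_mean"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must lie in (0, 1)")
        if self.n_patients < 1 or self.n_genes < 1 or self.n_crc < 0:
            raise ValidationError("counts must be positive")
        if self.n_hrac_genes + self.n_caf_genes > self.n_genes:
            raise ValidationError("signature genes exceed total gene count")
        if self.n_hrac_genes < 1 or self.n_caf_genes < 1:
            raise ValidationError("signatures need at least one gene")
        if not 1 <= self.lesion_min <= self.lesion_max:
            raise ValidationError("need 1 <= lesion_min <= lesion_max")
        for name in ("lesion_noise_sd", "hrac_log2_shift"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        for name in ("baseline_hazard", "censor_rate", "caf_concentration",
                     "followup_months", "caf_floor", "caf_scale",
                     "hr_hrac", "hr_caf"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


def strong_signal_config(seed: int, n_patients: int = 40, **overrides) -> SimulationConfig:
    """The strong-signal recovery configuration: study-condition defaults
    at 40 patients (hrac_log2_shift=1, lesion noise sd=0.2)."""
    return SimulationConfig(seed=seed, n_patients=n_patients, **overrides)


@dataclass
class SyntheticTruth:
    """Latent ground truth emitted with every generated cohort."""

    patients: pd.DataFrame  # index patient_id; latent_hrac_high, latent_caf_high
    samples: pd.DataFrame   # index sample_id; is_outlier_lesion, caf_fraction

    def high_risk_patients(self) -> pd.Series:
        """Latent poor-prognosis status: HRAC-high OR CAF-high."""
        return self.patients["latent_hrac_high"] | self.patients["latent_caf_high"]


# ---------------------------------------------------------------------------
# Gene layout
# ---------------------------------------------------------------------------

def _gene_ids(cfg: SimulationConfig) -> tuple[list[str], list[str], list[str]]:
    hrac = [f"HRAC{i + 1:03d}" for i in range(cfg.n_hrac_genes)]
    caf = [f"CAF{i + 1:03d}" for i in range(cfg.n_caf_genes)]
    n_bg = cfg.n_genes - cfg.n_hrac_genes - cfg.n_caf_genes
    bg = [f"BG{i + 1:05d}" for i in range(n_bg)]
    return hrac, caf, bg


def synthetic_signatures(cfg: SimulationConfig) -> tuple[GeneSignature, GeneSignature]:
    """Signature gene lists matching the generated gene ids."""
    hrac, caf, _ = _gene_ids(cfg)
    return (GeneSignature("HRAC-synthetic", tuple(hrac), source="synthetic generator"),
            GeneSignature("CAF-synthetic", tuple(caf), source="synthetic generator"))


def _rng_streams(cfg: SimulationConfig):
    """Shared gene baseline plus independent cohort/control streams."""
    ss = np.random.SeedSequence(cfg.seed)
    base_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    baseline = base_rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_genes)
    cohort_seq, crc_seq = ss.spawn(2)
    return baseline, np.random.default_rng(cohort_seq), np.random.default_rng(crc_seq)


def _draw_survival(rng, hazard: float, cfg: SimulationConfig) -> tuple[float, bool]:
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.exponential(1.0 / cfg.censor_rate)
    observed = min(t_event, t_cens, cfg.followup_months)
    event = t_event <= min(t_cens, cfg.followup_months)
    return float(observed), bool(event)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(cfg: SimulationConfig,
                    ) -> tuple[ExpressionMatrix, CohortAnnotation, SyntheticTruth]:
    """Generate the multifocal PMP cohort (linear-space expression matrix,
    per-sample annotation, latent truth).  Fully reproducible from the
    config seed."""
    baseline, rng, _ = _rng_streams(cfg)
    hrac_ids, caf_ids, bg_ids = _gene_ids(cfg)
    gene_ids = hrac_ids + caf_ids + bg_ids
    n_hrac = len(hrac_ids)
    n_caf = len(caf_ids)
    caf_slice = slice(n_hrac, n_hrac + n_caf)

    n = cfg.n_patients
    patient_ids = [f"P{i + 1:02d}" for i in range(n)]
    n_dpam = int(round(cfg.frac_dpam * n))
    histology = np.array(["PMCA"] * n, dtype=object)
    histology[rng.permutation(n)[:n_dpam]] = "DPAM"
    latent_h = rng.random(n) < cfg.prevalence_hrac
    latent_c = rng.random(n) < cfg.prevalence_caf
    multi = rng.random(n) < cfg.p_multi_lesion
    lesion_counts = np.where(
        multi, rng.integers(cfg.lesion_min, cfg.lesion_max + 1, size=n), 1)

    columns: dict[str, np.ndarray] = {}
    ann_rows = []
    truth_samples = []
    for i, pid in enumerate(patient_ids):
        hazard = (cfg.baseline_hazard
                  * (cfg.hr_hrac if latent_h[i] else 1.0)
                  * (cfg.hr_caf if latent_c[i] else 1.0))
        dfs_t, dfs_e = _draw_survival(rng, hazard, cfg)
        os_t, os_e = _draw_survival(rng, hazard * OS_HAZARD_FACTOR, cfg)
        caf_mu = cfg.caf_high_mean if latent_c[i] else cfg.caf_low_mean
        for lesion in range(1, int(lesion_counts[i]) + 1):
            sid = f"{pid}_L{lesion}"
            is_outlier = bool(lesion_counts[i] >= 2
                              and rng.random() < cfg.outlier_prob)
            dev = cfg.hrac_log2_shift / 2.0 * (1.0 if latent_h[i] else -1.0)
            if is_outlier:
                dev = -dev * cfg.outlier_flip_scale
            caf_frac = float(rng.beta(caf_mu * cfg.caf_concentration,
                                      (1.0 - caf_mu) * cfg.caf_concentration))
            log2v = baseline + rng.normal(0.0, cfg.lesion_noise_sd, cfg.n_genes) \
                if cfg.lesion_noise_sd > 0 else baseline.copy()
            log2v[:n_hrac] += dev
            log2v[caf_slice] += np.log2(cfg.caf_floor + cfg.caf_scale * caf_frac)
            columns[sid] = np.exp2(log2v)
            ann_rows.append({"sample_id": sid, "patient_id": pid,
                             "lesion_label": f"L{lesion}", "histology": histology[i],
                             "dfs_months": dfs_t, "dfs_event": dfs_e,
                             "os_months": os_t, "os_event": os_e})
            truth_samples.append({"sample_id": sid, "is_outlier_lesion": is_outlier,
                                  "caf_fraction": caf_frac})

    matrix = ExpressionMatrix(pd.DataFrame(columns, index=gene_ids), LINEAR)
    ann = CohortAnnotation(pd.DataFrame(ann_rows).set_index("sample_id"))
    truth = SyntheticTruth(
        patients=pd.DataFrame({"latent_hrac_high": latent_h,
                               "latent_caf_high": latent_c}, index=patient_ids),
        samples=pd.DataFrame(truth_samples).set_index("sample_id"),
    )
    logger.info("generated cohort: %d patients, %d samples, %d genes (seed=%d)",
                n, matrix.shape[1], cfg.n_genes, cfg.seed)
    return matrix, ann, truth


def generate_crc_controls(cfg: SimulationConfig,
                          ) -> tuple[ExpressionMatrix, CohortAnnotation]:
    """Generate the CRC peritoneal-carcinomatosis control samples.

    Controls share the cohort's gene baselines (so the matrices can be
    column-concatenated) but draw their per-sample CAF fraction from a
    lower-mean Beta distribution, giving PMP the systematically higher
    stromal score.  One lesion per control.
    """
    baseline, _, rng = _rng_streams(cfg)
    hrac_ids, caf_ids, bg_ids = _gene_ids(cfg)
    gene_ids = hrac_ids + caf_ids + bg_ids
    n_hrac, n_caf = len(hrac_ids), len(caf_ids)
    caf_slice = slice(n_hrac, n_hrac + n_caf)

    columns: dict[str, np.ndarray] = {}
    ann_rows = []
    for i in range(cfg.n_crc):
        pid = f"C{i + 1:02d}"
        sid = f"{pid}_L1"
        dfs_t, dfs_e = _draw_survival(rng, cfg.baseline_hazard, cfg)
        os_t, os_e = _draw_survival(rng, cfg.baseline_hazard * OS_HAZARD_FACTOR, cfg)
        caf_frac = float(rng.beta(cfg.crc_caf_mean * cfg.caf_concentration,
                                  (1.0 - cfg.crc_caf_mean) * cfg.caf_concentration))
        log2v = baseline + rng.normal(0.0, cfg.lesion_noise_sd, cfg.n_genes) \
            if cfg.lesion_noise_sd > 0 else baseline.copy()
        log2v[:n_hrac] -= cfg.hrac_log2_shift / 2.0  # controls carry no cancer-cell risk
        log2v[caf_slice] += np.log2(cfg.caf_floor + cfg.caf_scale * caf_frac)
        columns[sid] = np.exp2(log2v)
        ann_rows.append({"sample_id": sid, "patient_id": pid, "lesion_label": "L1",
                         "histology": "CRC", "dfs_months": dfs_t, "dfs_event": dfs_e,
                         "os_months": os_t, "os_event": os_e})
    matrix = ExpressionMatrix(pd.DataFrame(columns, index=gene_ids), LINEAR)
    ann = CohortAnnotation(pd.DataFrame(ann_rows).set_index("sample_id"))
    return matrix, ann


def merge_cohorts(matrix_a: ExpressionMatrix, ann_a: CohortAnnotation,
                  matrix_b: ExpressionMatrix, ann_b: CohortAnnotation,
                  ) -> tuple[ExpressionMatrix, CohortAnnotation]:
    """Column-concatenate two cohorts sharing the same gene space."""
    if matrix_a.gene_ids != matrix_b.gene_ids:
        raise ValidationError("cohorts do not share the same gene ids")
    if matrix_a.space != matrix_b.space:
        raise ValidationError("cohorts are in different signal spaces")
    values = pd.concat([matrix_a.values, matrix_b.values], axis=1)
    ann = CohortAnnotation(pd.concat([ann_a.table, ann_b.table], axis=0))
    return ExpressionMatrix(values, matrix_a.space), ann


# ---------------------------------------------------------------------------
# Recovery report
# ---------------------------------------------------------------------------

def recovery_report(truth: SyntheticTruth, calls: RiskCall) -> dict:
    """Compare patient-level integrated calls against the latent
    (HRAC-high OR CAF-high) status.  Returns accuracy / sensitivity /
    specificity."""
    truth_high = truth.high_risk_patients()
    if set(calls.calls.index) != set(truth_high.index):
        raise ValidationError("recovery_report: call/truth patient id mismatch")
    pred = (calls.calls.loc[truth_high.index] == HIGH).to_numpy()
    actual = truth_high.to_numpy(dtype=bool)
    tp = int((pred & actual).sum())
    tn = int((~pred & ~actual).sum())
    fp = int((pred & ~actual).sum())
    fn = int((~pred & actual).sum())
    total = tp + tn + fp + fn
    return {
        "accuracy": (tp + tn) / total if total else float("nan"),
        "sensitivity": tp / (tp + fn) if (tp + fn) else float("nan"),
        "specificity": tn / (tn + fp) if (tn + fp) else float("nan"),
        "n": total,
    }


# ---------------------------------------------------------------------------
# Disk round trip
# ---------------------------------------------------------------------------

def write_cohort(outdir, matrix: ExpressionMatrix, ann: CohortAnnotation,
                 truth: Optional[SyntheticTruth] = None,
                 cfg: Optional[SimulationConfig] = None) -> dict:
    """Write a cohort in the formats the readers consume; returns the paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"matrix": out / "matrix.tsv", "annotation": out / "annotation.csv"}
    write_expression_matrix(matrix, paths["matrix"])
    write_annotation(ann, paths["annotation"])
    if truth is not None:
        paths["truth_patients"] = out / "truth_patients.csv"
        paths["truth_samples"] = out / "truth_samples.csv"
        tp = truth.patients.copy()
        tp.index.name = "patient_id"
        tp.to_csv(paths["truth_patients"], lineterminator="\n")
        ts = truth.samples.copy()
        ts.index.name = "sample_id"
        ts.to_csv(paths["truth_samples"], lineterminator="\n")
    if cfg is not None:
        hrac_sig, caf_sig = synthetic_signatures(cfg)
        paths["hrac_signature"] = out / "hrac_signature.txt"
        paths["caf_signature"] = out / "caf_signature.txt"
        write_signature(hrac_sig, paths["hrac_signature"])
        write_signature(caf_sig, paths["caf_signature"])
    return {k: str(v) for k, v in paths.items()}
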