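"""End-to-end orchestration of the risk-classification pipeline.

``run_pipeline`` executes read → filter → collapse → normalize → score →
aggregate → call → integrate → evaluate on either real input files or a
synthetic cohort, and emits a reproducible :class:`RunReport`:
per-sample and per-patient scores/calls, ROC/AUC at the 24-month DFS
horizon for every subgroup (ALL, DPAM, PMCA) on both the all-samples and
the central-samples analysis sets, Kaplan-Meier/log-rank comparisons for
the HRAC-only and the integrated classifier, score orthogonality, the
intra-patient discordance count, and (when CRC controls are present) the
PMP-vs-CRC stromal-score contrast.

``validate_external_cohort`` is the single-lesion validation path: it
refuses multifocal input and skips the aggregation stage.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__ as _version
from .errors import StageError, ValidationError
from .expression_io import (LINEAR, LOG2, ExpressionMatrix, change_space,
                            collapse_probes_to_genes, filter_detected_probes,
                            normalize_between_samples, read_detection_table,
                            read_expression_matrix, read_probe_gene_map)
from .multilesion import (CohortAnnotation, aggregate_patient_scores,
                          count_discordant_patients, patient_central_sample,
                          patient_score_table, read_annotation)
from .signatures import (HIGH, LOW, GeneSignature, ScoreTable,
                         caf_score, cohort_central_sample, hrac_score,
                         integrate_calls, load_signature,
                         median_threshold_call, score_orthogonality)
from .survival import (BinaryOutcomeTable, binarize_dfs, delong_ci, km_fit,
                       logrank_test, roc_auc, two_sample_t)
from .synthetic import (SimulationConfig, SyntheticTruth, generate_cohort,
                        generate_crc_controls, merge_cohorts, recovery_report,
                        synthetic_signatures)

logger = logging.getLogger("pmprisk")

SUBGROUPS = ("ALL", "DPAM", "PMCA")
SAMPLE_SETS = ("all_samples", "central_samples")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input mode: either ``synthetic`` (a
    :class:`SimulationConfig`) or real input paths (``matrix_path`` +
    ``annotation_path`` + the two signature files, with optional
    detection table and probe map).
    """

    synthetic: Optional[SimulationConfig] = None
    matrix_path: Optional[str] = None
    matrix_layout: str = "tabular"
    detection_path: Optional[str] = None
    probe_map_path: Optional[str] = None
    annotation_path: Optional[str] = None
    hrac_signature_path: Optional[str] = None
    caf_signature_path: Optional[str] = None
    include_crc_controls: bool = True
    normalization: str = "cyclic_loess"
    loess_variant: str = "fast"
    centering: str = "cohort_median"
    analysis_set: str = "central_samples"
    aggregation: str = "central"
    horizon_months: float = 24.0
    min_coverage: float = 0.5
    km_subgroups: tuple = ("ALL",)
    outdir: Optional[str] = None
    seed: int = 0

    def validate(self) -> None:
        real = self.matrix_path is not None
        if real == (self.synthetic is not None):
            raise ValidationError("exactly one of synthetic config or matrix_path required")
        if real:
            required = {"matrix_path": self.matrix_path,
                        "annotation_path": self.annotation_path,
                        "hrac_signature_path": self.hrac_signature_path,
                        "caf_signature_path": self.caf_signature_path}
            for name, p in required.items():
                if p is None:
                    raise ValidationError(f"real-input run requires {name}")
            for name in ("matrix_path", "annotation_path", "hrac_signature_path",
                         "caf_signature_path", "detection_path", "probe_map_path"):
                p = getattr(self, name)
                if p is not None and not Path(p).exists():
                    raise ValidationError(f"{name}: no such file: {p}")
        if self.analysis_set not in SAMPLE_SETS:
            raise ValidationError(f"unknown analysis_set {self.analysis_set!r}")
        if self.horizon_months <= 0:
            raise ValidationError("horizon_months must be positive")
        unknown = set(self.km_subgroups) - set(SUBGROUPS)
        if unknown:
            raise ValidationError(f"unknown km_subgroups: {sorted(unknown)}")

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """All outputs of one run, traceable to the underlying operations."""

    sample_scores: pd.DataFrame
    patient_scores: pd.DataFrame
    roc_summary: pd.DataFrame
    km_summary: pd.DataFrame
    extras: dict
    provenance: dict


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except ValidationError:
                raise
            except StageError:
                raise
            except Exception as exc:  # pragma: no cover - defensive
                raise StageError(name, str(exc)) from exc
        return wrapper
    return deco


def _load_inputs(cfg: RunConfig):
    """Stage: load or generate matrix, annotation, signatures (and truth)."""
    truth: Optional[SyntheticTruth] = None
    if cfg.synthetic is not None:
        matrix, ann, truth = generate_cohort(cfg.synthetic)
        if cfg.include_crc_controls and cfg.synthetic.n_crc > 0:
            crc_m, crc_a = generate_crc_controls(cfg.synthetic)
            matrix, ann = merge_cohorts(matrix, ann, crc_m, crc_a)
        hsig, csig = synthetic_signatures(cfg.synthetic)
    else:
        matrix = read_expression_matrix(cfg.matrix_path, layout=cfg.matrix_layout)
        if cfg.detection_path is not None:
            det = read_detection_table(cfg.detection_path)
            matrix = filter_detected_probes(matrix, det)
        if cfg.probe_map_path is not None:
            pmap = read_probe_gene_map(cfg.probe_map_path)
            matrix = collapse_probes_to_genes(matrix, pmap)
        ann = read_annotation(cfg.annotation_path)
        hsig = load_signature(cfg.hrac_signature_path, "HRAC")
        csig = load_signature(cfg.caf_signature_path, "CAF")
    missing = [s for s in ann.sample_ids if s not in matrix.values.columns]
    if missing:
        raise ValidationError(f"annotated samples missing from matrix: {missing[:10]}")
    matrix = matrix.subset_samples(ann.sample_ids)
    return matrix, ann, hsig, csig, truth


def _score_set(matrix: ExpressionMatrix, hsig: GeneSignature, csig: GeneSignature,
               cohort: list[str], cfg: RunConfig):
    """Score one analysis set: central reference, HRAC/CAF scores, calls.

    The cohort-central reference and the median thresholds are computed on
    ``cohort`` (the PMP samples of this analysis set), then applied to all
    columns of ``matrix``.
    """
    log2m = change_space(matrix.subset_samples(cohort), LOG2)
    reference = cohort_central_sample(log2m)
    h = hrac_score(matrix, hsig, reference, min_coverage=cfg.min_coverage)
    c = caf_score(matrix, csig, centering=cfg.centering, cohort=cohort,
                  min_coverage=cfg.min_coverage)
    h_call = median_threshold_call(h, cohort=cohort)
    c_call = median_threshold_call(c, cohort=cohort)
    integrated = integrate_calls(h_call, c_call)
    return reference, h, c, h_call, c_call, integrated


def _roc_row(score_name: str, subgroup: str, sample_set: str, scores: pd.Series,
             outcomes: BinaryOutcomeTable) -> dict:
    row = {"score": score_name, "subgroup": subgroup, "sample_set": sample_set,
           "auc": np.nan, "ci_lower": np.nan, "ci_upper": np.nan,
           "n_pos": 0, "n_neg": 0, "n_indeterminate": 0, "note": ""}
    try:
        res = roc_auc(scores, outcomes)
        ci = delong_ci(scores, outcomes)
        row.update(auc=res.auc, ci_lower=ci["lower"], ci_upper=ci["upper"],
                   n_pos=res.n_pos, n_neg=res.n_neg,
                   n_indeterminate=res.n_indeterminate)
    except ValidationError as exc:
        row["note"] = str(exc)
        logger.warning("ROC %s/%s/%s skipped: %s", score_name, subgroup, sample_set, exc)
    return row


def _km_row(classifier: str, subgroup: str, times, events, calls: pd.Series) -> dict:
    row = {"classifier": classifier, "subgroup": subgroup,
           "statistic": np.nan, "p_value": np.nan,
           "n_low": int((calls == LOW).sum()), "n_high": int((calls == HIGH).sum()),
           "flagged": False, "note": ""}
    try:
        res = logrank_test(times, events, calls.to_numpy())
        row.update(statistic=res.statistic, p_value=res.p_value, flagged=res.flagged)
    except ValidationError as exc:
        row["note"] = str(exc)
        row["flagged"] = True
        logger.warning("KM %s/%s skipped: %s", classifier, subgroup, exc)
    return row


@_stage("evaluate")
def _evaluate(cfg: RunConfig, ann: CohortAnnotation, pmp_samples: list[str],
              sample_tables: dict, patient_tables: dict,
              central_map: dict) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    pmp_ann = ann.subset(pmp_samples)
    sample_out = binarize_dfs(pmp_ann, cfg.horizon_months, unit="sample")
    patient_out = binarize_dfs(pmp_ann, cfg.horizon_months, unit="patient")
    patient_hist = pmp_ann.patient_table()["histology"]
    sample_hist = pmp_ann.table["histology"]

    roc_rows = []
    for score_name in ("HRAC", "CAF"):
        for subgroup in SUBGROUPS:
            for sample_set in SAMPLE_SETS:
                if sample_set == "all_samples":
                    units = (sample_hist.index if subgroup == "ALL"
                             else sample_hist.index[sample_hist == subgroup])
                    scores = sample_tables[score_name].scores.loc[units]
                    out = BinaryOutcomeTable(sample_out.outcome.loc[units],
                                             sample_out.horizon_months)
                else:
                    units = (patient_hist.index if subgroup == "ALL"
                             else patient_hist.index[patient_hist == subgroup])
                    scores = patient_tables[score_name].scores.loc[units]
                    out = BinaryOutcomeTable(patient_out.outcome.loc[units],
                                             patient_out.horizon_months)
                roc_rows.append(_roc_row(score_name, subgroup, sample_set, scores, out))
    roc_summary = pd.DataFrame(roc_rows)

    km_rows = []
    pt = pmp_ann.patient_table()
    for classifier in ("HRAC", "integrated"):
        calls_all = patient_tables[f"{classifier}_call"].calls
        for subgroup in cfg.km_subgroups:
            pids = (pt.index if subgroup == "ALL"
                    else pt.index[pt["histology"] == subgroup])
            sub = pt.loc[pids]
            km_rows.append(_km_row(classifier, subgroup,
                                   sub["dfs_months"].to_numpy(),
                                   sub["dfs_event"].to_numpy(),
                                   calls_all.loc[pids]))
    km_summary = pd.DataFrame(km_rows)

    extras = {
        "orthogonality_r2": score_orthogonality(patient_tables["HRAC"],
                                                patient_tables["CAF"]),
        "discordant_patients_hrac": count_discordant_patients(
            sample_tables["HRAC"], pmp_ann),
        "discordant_patients_caf": count_discordant_patients(
            sample_tables["CAF"], pmp_ann),
        "n_multi_lesion_patients": len(pmp_ann.multi_lesion_patients()),
        "central_samples": dict(central_map),
    }

    # KM curve coordinates for the integrated classifier (export, no plotting)
    try:
        fits = km_fit(pt["dfs_months"].to_numpy(), pt["dfs_event"].to_numpy(),
                      patient_tables["integrated_call"].calls.loc[pt.index].to_numpy())
        extras["km_curves_integrated"] = {
            str(label): {"times": fit.times.tolist(),
                         "survival": fit.survival.tolist()}
            for label, fit in fits.items()}
    except ValidationError:
        pass
    return roc_summary, km_summary, extras


# ---------------------------------------------------------------------------
# Main entry points
# ---------------------------------------------------------------------------

def run_pipeline(cfg: RunConfig, _external: bool = False) -> RunReport:
    """Execute the full pipeline and return (and optionally write) a report."""
    cfg.validate()
    log_handler = _attach_log_handler(cfg.outdir)
    try:
        matrix, ann, hsig, csig, truth = _stage("load")(_load_inputs)(cfg)
        matrix = _stage("normalize")(normalize_between_samples)(
            matrix, method=cfg.normalization, variant=cfg.loess_variant)

        pmp_samples = [s for s in ann.sample_ids
                       if ann.table.loc[s, "histology"] != "CRC"]
        if not pmp_samples:
            raise ValidationError("no PMP samples in input")

        # --- per-sample scoring on the full sample set -------------------
        reference, h_s, c_s, h_call_s, c_call_s, int_call_s = _stage("score")(
            _score_set)(matrix, hsig, csig, pmp_samples, cfg)

        # --- per-patient reduction ---------------------------------------
        pmp_ann = ann.subset(pmp_samples)
        pmp_matrix = matrix.subset_samples(pmp_samples)
        log2_pmp = change_space(pmp_matrix, LOG2)
        central_map = {p: patient_central_sample(log2_pmp, pmp_ann.samples_of_patient(p))
                       for p in pmp_ann.patient_ids}

        if _external:
            multi = pmp_ann.multi_lesion_patients()
            if multi:
                raise ValidationError(
                    f"external validation expects single-lesion patients; "
                    f"{len(multi)} patients have multiple lesions — use run_pipeline")

        agg_h = aggregate_patient_scores(
            h_s, pmp_ann, cfg.aggregation, matrix=pmp_matrix,
            score_fn=_mean_profile_scorer(hsig, csig, cfg, reference, "HRAC",
                                          pmp_matrix))
        agg_c = aggregate_patient_scores(
            c_s, pmp_ann, cfg.aggregation, matrix=pmp_matrix,
            score_fn=_mean_profile_scorer(hsig, csig, cfg, reference, "CAF",
                                          pmp_matrix))

        if cfg.analysis_set == "central_samples" and cfg.aggregation == "central":
            # the paper's headline path: rebuild the analysis set from one
            # representative sample per patient and recompute reference,
            # centering and thresholds on that reduced set
            central_samples = [central_map[p] for p in pmp_ann.patient_ids]
            reduced = matrix.subset_samples(central_samples)
            ref_c, h_c, c_c, h_call_c, c_call_c, int_call_c = _stage("score")(
                _score_set)(reduced, hsig, csig, central_samples, cfg)
            to_patient = {central_map[p]: p for p in pmp_ann.patient_ids}
            h_p = ScoreTable(h_c.scores.rename(index=to_patient), "HRAC",
                             reference=ref_c, n_genes_used=h_c.n_genes_used)
            c_p = ScoreTable(c_c.scores.rename(index=to_patient), "CAF",
                             reference=c_c.reference, n_genes_used=c_c.n_genes_used)
            patient_reference = ref_c
        else:
            h_p = patient_score_table(agg_h, "HRAC", reference=reference,
                                      n_genes_used=h_s.n_genes_used)
            c_p = patient_score_table(agg_c, "CAF", reference=c_s.reference,
                                      n_genes_used=c_s.n_genes_used)
            patient_reference = reference
        h_call_p = median_threshold_call(h_p)
        c_call_p = median_threshold_call(c_p)
        int_call_p = integrate_calls(h_call_p, c_call_p)

        # --- evaluation ----------------------------------------------------
        sample_tables = {"HRAC": h_s, "CAF": c_s}
        patient_tables = {"HRAC": h_p, "CAF": c_p,
                          "HRAC_call": h_call_p, "CAF_call": c_call_p,
                          "integrated_call": int_call_p}
        roc_summary, km_summary, extras = _evaluate(
            cfg, ann, pmp_samples, sample_tables, patient_tables, central_map)

        # PMP-vs-CRC stromal contrast on raw (uncentered) CAF scores
        crc_samples = [s for s in ann.sample_ids
                       if ann.table.loc[s, "histology"] == "CRC"]
        if crc_samples:
            raw_caf = caf_score(matrix, csig, centering="none",
                                min_coverage=cfg.min_coverage)
            tt = two_sample_t(raw_caf.scores.loc[pmp_samples],
                              raw_caf.scores.loc[crc_samples])
            extras["caf_pmp_vs_crc"] = {"t": tt["t"], "p": tt["p"],
                                        "n_pmp": len(pmp_samples),
                                        "n_crc": len(crc_samples)}

        if truth is not None:
            extras["recovery"] = recovery_report(truth, int_call_p)

        # --- assemble tables -------------------------------------------------
        sample_scores = pd.DataFrame({
            "patient_id": ann.table["patient_id"],
            "histology": ann.table["histology"],
            "hrac_score": h_s.scores, "caf_score": c_s.scores,
            "hrac_call": h_call_s.calls, "caf_call": c_call_s.calls,
            "integrated_call": int_call_s.calls,
        })
        sample_scores.index.name = "sample_id"
        patient_hist = pmp_ann.patient_table()["histology"]
        patient_scores = pd.DataFrame({
            "histology": patient_hist,
            "representative_sample": pd.Series(central_map),
            "hrac_score": h_p.scores, "caf_score": c_p.scores,
            "hrac_call": h_call_p.calls, "caf_call": c_call_p.calls,
            "integrated_call": int_call_p.calls,
            "discordant_hrac": agg_h["discordant"],
            "discordant_caf": agg_c["discordant"],
        })
        patient_scores.index.name = "patient_id"

        extras.update({
            "cohort_central_reference": reference,
            "patient_level_reference": patient_reference,
            "hrac_threshold_samples": h_call_s.threshold,
            "caf_threshold_samples": c_call_s.threshold,
            "hrac_threshold_patients": h_call_p.threshold,
            "caf_threshold_patients": c_call_p.threshold,
        })
        provenance = {
            "config_hash": cfg.config_hash(),
            "version": _version,
            "seed": cfg.seed if cfg.synthetic is None else cfg.synthetic.seed,
            "normalization": cfg.normalization,
            "centering": cfg.centering,
            "analysis_set": cfg.analysis_set,
            "aggregation": cfg.aggregation,
            "aggregation_stage": "skipped" if _external else "run",
            "n_samples": int(matrix.shape[1]),
            "n_genes": int(matrix.shape[0]),
            "n_patients": len(pmp_ann.patient_ids),
        }
        report = RunReport(sample_scores=sample_scores, patient_scores=patient_scores,
                           roc_summary=roc_summary, km_summary=km_summary,
                           extras=extras, provenance=provenance)
        if cfg.outdir is not None:
            _write_report(report, cfg.outdir)
        return report
    finally:
        if log_handler is not None:
            logger.removeHandler(log_handler)
            log_handler.close()


def validate_external_cohort(cfg: RunConfig) -> RunReport:
    """Validation path for single-lesion cohorts (one sample per patient):
    skips the multilesion aggregation stage; multifocal input is an error
    directing the caller to :func:`run_pipeline`."""
    return run_pipeline(cfg, _external=True)


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _mean_profile_scorer(hsig, csig, cfg, reference, which, pmp_matrix):
    """Closure scoring a per-patient mean-profile matrix.

    For HRAC the cohort-central reference column is appended so log2
    ratios stay anchored to the same reference profile.
    """
    def scorer(pm: ExpressionMatrix) -> ScoreTable:
        if which == "HRAC":
            ref_col = pmp_matrix.values[[reference]]
            joined = ExpressionMatrix(pd.concat([pm.values, ref_col], axis=1), LINEAR)
            table = hrac_score(joined, hsig, reference, min_coverage=cfg.min_coverage)
            return ScoreTable(table.scores.drop(index=reference), "HRAC",
                              reference=reference, n_genes_used=table.n_genes_used)
        return caf_score(pm, csig, centering="none", min_coverage=cfg.min_coverage)
    return scorer


def _attach_log_handler(outdir):
    if outdir is None:
        return None
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    handler.setLevel(logging.INFO)
    logger.addHandler(handler)
    if logger.level == logging.NOTSET or logger.level > logging.INFO:
        logger.setLevel(logging.INFO)
    return handler


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _write_report(report: RunReport, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    score_cols = ["patient_id", "histology", "hrac_score", "caf_score"]
    report.sample_scores[score_cols].to_csv(out / "scores.tsv", sep="\t",
                                            lineterminator="\n")
    calls = pd.concat([
        report.sample_scores[["hrac_call", "caf_call", "integrated_call"]]
        .assign(level="sample"),
        report.patient_scores[["hrac_call", "caf_call", "integrated_call"]]
        .assign(level="patient")
        .rename_axis("sample_id"),
    ])
    calls.index.name = "unit_id"
    calls.to_csv(out / "calls.tsv", sep="\t", lineterminator="\n")
    report.patient_scores.to_csv(out / "patient_scores.tsv", sep="\t",
                                 lineterminator="\n")
    report.roc_summary.to_csv(out / "roc_summary.tsv", sep="\t", index=False,
                              lineterminator="\n")
    report.km_summary.to_csv(out / "km_summary.tsv", sep="\t", index=False,
                             lineterminator="\n")
    with open(out / "run.json", "w") as fh:
        json.dump({"provenance": _json_safe(report.provenance),
                   "extras": _json_safe(report.extras)}, fh, indent=2)
    logger.info("report written to %s", out)
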