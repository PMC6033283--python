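"""End-to-end pipeline: simulate -> QC/normalize -> train -> validate ->
score -> stratify -> report.

The discovery/validation split is a fixed input property of each sample
(cohort label), never re-randomized.  Single-sample predictors are trained
per ER x RT stratum on the discovery cohort, locked, and evaluated on the
validation cohort by ROC/AUC and Kaplan-Meier / log-rank on the IBTR
endpoint.  Strata with too few cases or controls are skipped with a warning
rather than failing the run.  Reruns with the same configuration are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import STRATA, annotate_strata
from .io_norm import QCThresholds, normalize, qc_filter
from .ktsp import KTSPConfig, predict, save_model, train_ssp
from .signatures import (
    correlate_scores,
    default_ten_gs,
    dichotomize_median,
    immune_score,
    load_signature,
    proliferation_score,
    rank_linear_score,
)
from .stratification import assign_groups, evaluate_rt_benefit
from .survival import logrank_test, roc_auc
from .synthetic import CohortConfig, generate_cohort, write_fixture

logger = logging.getLogger(__name__)

SCORE_COLUMNS = ("ten_gs", "proliferation", "immune", "ssp_vote_fraction")


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    ktsp: KTSPConfig = field(default_factory=KTSPConfig)
    signature_csv: str | None = None     # defaults to the bundled synthetic 10-GS
    run_stratification: bool = True
    out_dir: str = "radssp_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "cohort" in kwargs:
            kwargs["cohort"] = CohortConfig(**kwargs["cohort"])
        if "qc" in kwargs:
            kwargs["qc"] = QCThresholds(**kwargs["qc"])
        if "ktsp" in kwargs:
            kwargs["ktsp"] = KTSPConfig(**kwargs["ktsp"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _write_json(payload: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the report dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seeds": {"cohort": config.cohort.seed, "ktsp": config.ktsp.seed}}

    logger.info("stage simulate: generating synthetic cohort")
    counts, annot = generate_cohort(config.cohort)
    write_fixture(counts, annot, out / "raw")

    logger.info("stage qc: filtering probes and samples")
    filtered, qc_report = qc_filter(counts, config.qc)
    qc_report.to_json(out / "qc_report.json")
    report["qc"] = {
        "removed_probes": len(qc_report.removed_probes),
        "removed_samples": len(qc_report.removed_samples),
    }

    logger.info("stage normalize")
    expr_log = normalize(filtered, log=True)
    expr_lin = normalize(filtered, log=False)
    annot = annot[annot["sample_id"].isin(expr_log.samples)].reset_index(drop=True)
    annot = annot.assign(stratum=annotate_strata(annot))
    disc = annot[annot["cohort"] == "discovery"]
    valid = annot[annot["cohort"] == "validation"]
    report["n_discovery"] = int(len(disc))
    report["n_validation"] = int(len(valid))

    models: dict = {}
    model_paths: dict = {}
    report["strata"] = {}
    for stratum in STRATA:
        entry: dict = {}
        sub = disc[disc["stratum"] == stratum]
        n_cases = int(sub["ibtr_event"].sum())
        n_controls = int((~sub["ibtr_event"]).sum())
        entry["n_train"] = int(len(sub))
        entry["n_train_cases"] = n_cases
        if min(n_cases, n_controls) < config.ktsp.min_per_class:
            logger.warning(
                "stratum %s skipped: %d cases / %d controls (< %d per class)",
                stratum, n_cases, n_controls, config.ktsp.min_per_class,
            )
            entry["trained"] = False
            entry["skip_reason"] = f"{n_cases} cases / {n_controls} controls"
            report["strata"][stratum] = entry
            continue
        logger.info("stage train: stratum %s (%d samples)", stratum, len(sub))
        expr_sub = expr_log.subset_samples(sub["sample_id"])
        model = train_ssp(expr_sub, sub["ibtr_event"].to_numpy(), stratum, config.ktsp)
        path = out / f"ssp_{stratum.replace('+', 'pos').replace('-', 'neg')}.json"
        save_model(model, path)
        models[stratum] = model
        model_paths[stratum] = path.name
        entry.update(
            trained=True, k=model.k, n_genes=len(set(model.genes)), model_path=path.name
        )

        vsub = valid[valid["stratum"] == stratum]
        if len(vsub) and vsub["ibtr_event"].nunique() == 2:
            pred = predict(model, expr_log.subset_samples(vsub["sample_id"]))
            auc, _ = roc_auc(pred["vote_fraction"].to_numpy(), vsub["ibtr_event"].to_numpy())
            entry["validation"] = {"n": int(len(vsub)), "auc": auc}
            if pred["high_risk"].nunique() == 2 and vsub["ibtr_event"].sum() > 0:
                chi2, p = logrank_test(
                    vsub["time_years"].to_numpy(),
                    vsub["ibtr_event"].to_numpy(),
                    pred["high_risk"].to_numpy(),
                )
                entry["validation"]["logrank_chi2"] = chi2
                entry["validation"]["logrank_p"] = p
        else:
            entry["validation"] = {"n": int(len(vsub)), "auc": None}
        report["strata"][stratum] = entry

    logger.info("stage score: signature scores and correlations")
    sig = load_signature(config.signature_csv) if config.signature_csv else default_ten_gs()
    scores = pd.DataFrame(index=pd.Index(expr_log.samples, name="sample_id"))
    scores["ten_gs"] = rank_linear_score(expr_log, sig)
    scores["proliferation"] = proliferation_score(expr_lin)
    scores["immune"] = immune_score(expr_lin)
    vote = pd.Series(np.nan, index=scores.index)
    for stratum, model in models.items():
        ids = annot.loc[annot["stratum"] == stratum, "sample_id"]
        if len(ids):
            vote.loc[ids] = predict(model, expr_log.subset_samples(ids))["vote_fraction"]
    scores["ssp_vote_fraction"] = vote
    scores["ten_gs_high"] = dichotomize_median(scores["ten_gs"])
    scores.to_csv(out / "scores.tsv", sep="\t")

    correlations = {}
    cols = list(SCORE_COLUMNS)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            paired = scores[[a, b]].dropna()
            if len(paired) >= 3 and np.ptp(paired[a].to_numpy()) > 0:
                r, slope, p = correlate_scores(paired[a], paired[b])
                correlations[f"{a}~{b}"] = {"r": r, "slope": slope, "p": p, "n": int(len(paired))}
    report["score_correlations"] = correlations

    if config.run_stratification:
        logger.info("stage stratify: consecutive SSP treatment assignment")
        report["stratification"] = {}
        for er, label in (("pos", "ER+"), ("neg", "ER-")):
            rtminus, rtplus = models.get(f"{label}RT-"), models.get(f"{label}RT+")
            if rtminus is None or rtplus is None:
                logger.warning("stratification for %s skipped: missing SSP model(s)", label)
                report["stratification"][label] = {"skipped": True, "reason": "missing model"}
                continue
            vsub = valid[valid["er_status"] == er]
            if vsub.empty:
                report["stratification"][label] = {"skipped": True, "reason": "no samples"}
                continue
            assignments = assign_groups(
                expr_log.subset_samples(vsub["sample_id"]), rtminus, rtplus
            )
            assignments.to_csv(out / f"assignments_{label.replace('+', 'pos').replace('-', 'neg')}.csv", index=False)
            evaluation = evaluate_rt_benefit(assignments, vsub)
            report["stratification"][label] = {"skipped": False, "evaluation": evaluation}

    report["model_paths"] = model_paths
    _write_json(report, out / "report.json")
    logger.info("pipeline complete; report at %s", out / "report.json")
    return report
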