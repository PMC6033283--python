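"""Reading, quality filtering and normalization of nCounter-style counts.

Normalization follows the platform's two-step control scheme: each sample is
first scaled so that the geometric mean of its positive-control probes equals
the cohort average of those geometric means, then rescaled the same way on
the housekeeping genes, and finally log2(x + 1) transformed.  Control probes
are dropped from the analysis gene set afterwards.

QC removes samples whose positive-control scale factor is extreme or whose
housekeeping signal collapses, and endogenous probes that never rise above
the negative-control background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import RawCounts, ExpressionMatrix
from .panel import validate_manifest


def geometric_mean(values: np.ndarray) -> float:
    """Geometric mean; defined as 0 when any value is 0 (flags QC failures)."""
    values = np.asarray(values, dtype=float)
    if (values < 0).any():
        raise ValueError("geometric mean of negative values is undefined")
    if (values == 0).any():
        return 0.0
    return float(np.exp(np.mean(np.log(values))))


@dataclass
class QCThresholds:
    """Tunable QC cut-offs (common nCounter practice; fully configurable)."""

    pos_scale_lo: float = 1.0 / 3.0
    pos_scale_hi: float = 3.0
    housekeeping_floor: float = 32.0
    background_sd_mult: float = 2.0
    background_frac: float = 0.85


@dataclass
class QCReport:
    removed_probes: list = field(default_factory=list)    # (gene_id, reason)
    removed_samples: list = field(default_factory=list)   # (sample_id, reason)
    pos_scale_factor: dict = field(default_factory=dict)  # sample -> factor
    housekeeping_geomean: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def read_annotation(path) -> pd.DataFrame:
    from .containers import validate_annotation

    return validate_annotation(pd.read_csv(path))


def read_counts(counts_path, manifest_path) -> RawCounts:
    """Read a counts TSV (genes x samples, first column gene_id) + manifest CSV."""
    counts_path, manifest_path = Path(counts_path), Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    validate_manifest(manifest)
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    if counts.index.duplicated().any():
        raise ValueError("duplicate gene_ids in counts file")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("counts file contains non-numeric entries")
    if not np.allclose(values, np.round(values)):
        raise ValueError("counts must be integers")
    if (values < 0).any():
        raise ValueError("counts must be non-negative")
    missing = set(counts.index) - set(manifest["gene_id"])
    if missing:
        raise ValueError(f"counts contain genes absent from manifest: {sorted(missing)}")
    return RawCounts(counts=counts.astype(np.int64), manifest=manifest)


def _pos_scale_factors(counts: RawCounts) -> pd.Series:
    pos = counts.class_genes("positive_ctrl")
    if not pos:
        raise ValueError("no positive-control probes present")
    geo = counts.counts.loc[pos].apply(lambda col: geometric_mean(col.to_numpy()), axis=0)
    positive = geo[geo > 0]
    if positive.empty:
        raise ValueError("all samples have zero positive-control signal")
    target = float(np.exp(np.mean(np.log(positive))))
    with np.errstate(divide="ignore"):
        return target / geo


def qc_filter(counts: RawCounts, thresholds: QCThresholds | None = None):
    """Apply sample- then probe-level QC; returns (filtered RawCounts, QCReport).

    Samples are removed when their positive-control scale factor leaves
    [pos_scale_lo, pos_scale_hi] or their housekeeping geometric mean falls
    below the floor.  Endogenous probes are removed when they sit at or below
    the per-sample background (mean + k*SD of negative controls) in at least
    ``background_frac`` of the retained samples.
    """
    if thresholds is None:
        thresholds = QCThresholds()
    report = QCReport()

    scale = _pos_scale_factors(counts)
    hk = counts.class_genes("housekeeping")
    if not hk:
        raise ValueError("no housekeeping probes present")
    hk_geo = counts.counts.loc[hk].apply(lambda col: geometric_mean(col.to_numpy()), axis=0)
    report.pos_scale_factor = {s: float(scale[s]) for s in counts.samples}
    report.housekeeping_geomean = {s: float(hk_geo[s]) for s in counts.samples}

    keep_samples = []
    for s in counts.samples:
        f = scale[s]
        if not np.isfinite(f) or not (thresholds.pos_scale_lo <= f <= thresholds.pos_scale_hi):
            report.removed_samples.append((s, "positive_control_scale"))
        elif hk_geo[s] < thresholds.housekeeping_floor:
            report.removed_samples.append((s, "housekeeping_floor"))
        else:
            keep_samples.append(s)
    if not keep_samples:
        raise ValueError("QC removed every sample")

    retained = counts.counts[keep_samples]
    neg = counts.class_genes("negative_ctrl")
    if neg:
        neg_counts = retained.loc[neg].to_numpy(dtype=float)
        background = neg_counts.mean(axis=0) + thresholds.background_sd_mult * neg_counts.std(
            axis=0, ddof=1
        )
    else:
        background = np.zeros(len(keep_samples))

    endo = counts.class_genes("endogenous")
    flagged = retained.loc[endo].to_numpy(dtype=float) <= background[None, :]
    frac_flagged = flagged.mean(axis=1)
    removed_probes = [g for g, f in zip(endo, frac_flagged) if f >= thresholds.background_frac]
    for g in removed_probes:
        report.removed_probes.append((g, "background"))

    keep_genes = [g for g in counts.counts.index if g not in set(removed_probes)]
    filtered = RawCounts(
        counts=counts.counts.loc[keep_genes, keep_samples].copy(), manifest=counts.manifest
    )
    return filtered, report


def _scale_to_common_geomean(values: pd.DataFrame, ref_genes: list[str]) -> pd.DataFrame:
    geo = values.loc[ref_genes].apply(lambda col: geometric_mean(col.to_numpy()), axis=0)
    if (geo == 0).any():
        bad = geo.index[geo == 0].tolist()
        raise ValueError(
            f"zero geometric mean for reference probes in samples {bad}; run QC first"
        )
    # geometric across-sample target: makes the two-step scheme an exact
    # fixed point (re-normalizing normalized data changes nothing)
    target = float(np.exp(np.mean(np.log(geo))))
    return values * (target / geo)


def normalize_frame(values: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Positive-control then housekeeping scaling on a full linear matrix.

    Keeps all probes (controls included) on linear scale; idempotent.
    """
    present = manifest["gene_id"].isin(values.index)
    pos = manifest.loc[present & (manifest["probe_class"] == "positive_ctrl"), "gene_id"].tolist()
    hk = manifest.loc[present & (manifest["probe_class"] == "housekeeping"), "gene_id"].tolist()
    if not pos or not hk:
        raise ValueError("normalization needs positive-control and housekeeping probes")
    out = _scale_to_common_geomean(values.astype(float), pos)
    out = _scale_to_common_geomean(out, hk)
    return out


def normalize(counts: RawCounts, log: bool = True) -> ExpressionMatrix:
    """Normalize QC-passed counts; returns the endogenous analysis matrix.

    Steps, in fixed order: positive-control scaling, housekeeping scaling,
    then (by default) log2(x + 1).  Control and housekeeping probes are
    dropped from the output gene set.
    """
    full = normalize_frame(counts.counts, counts.manifest)
    endo = counts.class_genes("endogenous")
    out = full.loc[endo]
    if log:
        return ExpressionMatrix(values=np.log2(out + 1.0), scale="log2")
    # +1 offset keeps the linear output strictly positive, matching the
    # invertible log transform
    return ExpressionMatrix(values=out + 1.0, scale="linear")
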