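"""Core in-memory containers shared across modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import validate_manifest

STRATA = ("ER+RT+", "ER+RT-", "ER-RT+", "ER-RT-")

ANNOTATION_COLUMNS = [
    "sample_id",
    "cohort",
    "er_status",
    "rt",
    "ibtr_event",
    "time_years",
    "endocrine_therapy",
    "chemotherapy",
]


@dataclass
class RawCounts:
    """Probe-by-sample raw count matrix with its panel manifest.

    ``counts`` is a genes x samples DataFrame of non-negative integers whose
    index is ``gene_id``; every gene must appear in ``manifest``.
    """

    counts: pd.DataFrame
    manifest: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        validate_manifest(self.manifest)
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene_ids in counts: {dups}")
        unknown = set(self.counts.index) - set(self.manifest["gene_id"])
        if unknown:
            raise ValueError(f"genes in counts missing from manifest: {sorted(unknown)}")
        if self.counts.isna().any().any():
            raise ValueError("counts contain missing cells")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def class_genes(self, probe_class: str) -> list[str]:
        present = self.manifest["gene_id"].isin(self.counts.index)
        sel = self.manifest.loc[present & (self.manifest["probe_class"] == probe_class)]
        return sel["gene_id"].tolist()

    def subset(self, genes=None, samples=None) -> "RawCounts":
        counts = self.counts
        if genes is not None:
            counts = counts.loc[list(genes)]
        if samples is not None:
            counts = counts[list(samples)]
        return RawCounts(counts=counts.copy(), manifest=self.manifest)


@dataclass
class ExpressionMatrix:
    """Normalized gene x sample expression, on linear or log2 scale.

    The log2 representation stores log2(x + 1) of the normalized counts x;
    the linear representation stores the strictly positive pseudo-counted
    values x + 1.  ``to_log2``/``to_linear`` convert exactly between the two.
    """

    values: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.scale == "linear" and (arr <= 0).any():
            raise ValueError("linear-scale expression must be strictly positive")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def to_log2(self) -> "ExpressionMatrix":
        if self.scale == "log2":
            return self
        return ExpressionMatrix(values=np.log2(self.values), scale="log2")

    def to_linear(self) -> "ExpressionMatrix":
        if self.scale == "linear":
            return self
        return ExpressionMatrix(values=2.0 ** self.values, scale="linear")

    def sample(self, sample_id: str) -> pd.Series:
        return self.values[sample_id]

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(values=self.values[list(samples)].copy(), scale=self.scale)


def validate_annotation(annot: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort annotation table; returns it with canonical dtypes."""
    missing = set(ANNOTATION_COLUMNS) - set(annot.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    if annot["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_ids in annotation")
    if not set(annot["cohort"]) <= {"discovery", "validation"}:
        raise ValueError("cohort must be 'discovery' or 'validation'")
    if not set(annot["er_status"]) <= {"pos", "neg"}:
        raise ValueError("er_status must be 'pos' or 'neg'")
    if (annot["time_years"] <= 0).any():
        raise ValueError("time_years must be positive")
    out = annot.copy()
    for col in ("rt", "ibtr_event", "endocrine_therapy", "chemotherapy"):
        out[col] = out[col].astype(bool)
    out["time_years"] = out["time_years"].astype(float)
    return out


def stratum_of(er_status: str, rt: bool) -> str:
    """Map ER status and RT treatment to the stratum label."""
    return f"ER{'+' if er_status == 'pos' else '-'}RT{'+' if rt else '-'}"


def annotate_strata(annot: pd.DataFrame) -> pd.Series:
    return pd.Series(
        [stratum_of(e, r) for e, r in zip(annot["er_status"], annot["rt"])],
        index=annot.index,
        name="stratum",
    )
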