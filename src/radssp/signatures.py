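"""Gene-signature scoring and score-to-score correlation.

Three kinds of per-sample continuous scores are supported:

* a rank-linear signature (the 10-gene radiosensitivity-index surrogate):
  a linear combination of within-sample gene ranks,
* geometric-mean scores on linear expression (proliferation = MKI67 & AURKA,
  immune = ten immune-response genes),
* median dichotomization of any score into high/low, with "high" meaning
  strictly above the median of the provided set.

Correlation between raw scores uses Pearson r plus an OLS slope with a
two-sided zero-slope t test (n - 2 degrees of freedom).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import linregress, rankdata

from .containers import ExpressionMatrix
from .panel import IMMUNE_GENES, PROLIFERATION_GENES

RANK_SCOPES = ("signature_genes", "all_panel_genes")
RANK_DIRECTIONS = ("ascending", "descending")


@dataclass
class RankLinearSignature:
    genes: list
    coefficients: list
    rank_scope: str = "all_panel_genes"
    rank_direction: str = "ascending"
    name: str = "signature"

    def __post_init__(self):
        if len(self.genes) != len(self.coefficients):
            raise ValueError("genes and coefficients must have equal length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")
        if self.rank_scope not in RANK_SCOPES:
            raise ValueError(f"rank_scope must be one of {RANK_SCOPES}")
        if self.rank_direction not in RANK_DIRECTIONS:
            raise ValueError(f"rank_direction must be one of {RANK_DIRECTIONS}")


def load_signature(csv_path, meta_path=None) -> RankLinearSignature:
    """Load a signature from a gene_id,coefficient CSV (+ optional JSON meta)."""
    csv_path = Path(csv_path)
    table = pd.read_csv(csv_path)
    if not {"gene_id", "coefficient"} <= set(table.columns):
        raise ValueError("signature CSV needs columns gene_id, coefficient")
    meta = {}
    if meta_path is None:
        candidate = csv_path.with_suffix(".json")
        if candidate.exists():
            meta_path = candidate
    if meta_path is not None:
        with open(meta_path) as fh:
            meta = json.load(fh)
    return RankLinearSignature(
        genes=table["gene_id"].tolist(),
        coefficients=[float(c) for c in table["coefficient"]],
        rank_scope=meta.get("rank_scope", "all_panel_genes"),
        rank_direction=meta.get("rank_direction", "ascending"),
        name=meta.get("name", csv_path.stem),
    )


def default_ten_gs() -> RankLinearSignature:
    """The bundled synthetic placeholder for the 10-gene surrogate score."""
    here = Path(__file__).parent / "data"
    return load_signature(here / "ten_gs_synthetic.csv")


def rank_linear_score(expr, sig: RankLinearSignature) -> pd.Series:
    """Sum of coefficient x within-sample rank for each sample.

    Ranks are computed per sample over the configured scope with average
    ranks for ties; descending direction reverses the ordering.
    """
    M = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if isinstance(M, pd.Series):
        M = M.to_frame(name=M.name or "sample")
    missing = sorted(set(sig.genes) - set(M.index))
    if missing:
        raise ValueError(f"signature genes missing from expression matrix: {missing}")
    scope = M.loc[list(sig.genes)] if sig.rank_scope == "signature_genes" else M
    X = scope.to_numpy(dtype=float)
    if sig.rank_direction == "descending":
        X = -X
    ranks = rankdata(X, axis=0)
    idx = [list(scope.index).index(g) for g in sig.genes]
    coef = np.asarray(sig.coefficients, dtype=float)
    scores = coef @ ranks[idx, :]
    return pd.Series(scores, index=M.columns, name=sig.name)


def geometric_mean_score(expr, gene_set) -> pd.Series:
    """Geometric mean of linear-scale expression over ``gene_set``."""
    if isinstance(expr, ExpressionMatrix):
        if expr.scale != "linear":
            raise ValueError(
                "geometric_mean_score needs linear-scale expression; "
                "call .to_linear() first"
            )
        M = expr.values
    else:
        M = expr
    if isinstance(M, pd.Series):
        M = M.to_frame(name=M.name or "sample")
    gene_set = list(gene_set)
    missing = sorted(set(gene_set) - set(M.index))
    if missing:
        raise ValueError(f"score genes missing from expression matrix: {missing}")
    X = M.loc[gene_set].to_numpy(dtype=float)
    if (X <= 0).any():
        raise ValueError(
            "non-positive expression passed to geometric_mean_score; "
            "inputs must be strictly positive linear-scale values"
        )
    return pd.Series(np.exp(np.mean(np.log(X), axis=0)), index=M.columns)


def proliferation_score(expr) -> pd.Series:
    """Geometric mean of MKI67 and AURKA on linear expression."""
    return geometric_mean_score(expr, PROLIFERATION_GENES)


def immune_score(expr) -> pd.Series:
    """Geometric mean of the ten immune-response genes on linear expression."""
    return geometric_mean_score(expr, IMMUNE_GENES)


def dichotomize_median(scores) -> np.ndarray:
    """High iff score > median of the provided scores (exact median -> low)."""
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise ValueError("dichotomize_median needs at least 2 scores")
    if not np.isfinite(x).all():
        raise ValueError("scores must be finite")
    if np.ptp(x) == 0:
        warnings.warn("all scores identical; every sample assigned low", stacklevel=2)
    high = x > np.median(x)
    if isinstance(scores, pd.Series):
        return pd.Series(high, index=scores.index)
    return high


def correlate_scores(x, y):
    """Pearson r, OLS slope and the two-sided zero-slope p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("scores must be finite")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    fit = linregress(x, y)
    return float(fit.rvalue), float(fit.slope), float(fit.pvalue)
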