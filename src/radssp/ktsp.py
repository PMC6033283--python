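"""k-top-scoring-pairs (k-TSP) single-sample predictors.

A k-TSP model is an ordered list of k disjoint gene-pair rules of the form
"expression(gene_a) > expression(gene_b) votes high-risk", with the unweighted
majority vote as the decision cut point.  Because every rule only compares two
measurements within the same sample, predictions are invariant to any strictly
monotone per-sample transform — the property that makes the classifier a
single-sample predictor, portable across platforms and normalizations.

Pair ranking uses the classical two-key score: the primary score
delta = |P(X_a > X_b | class 1) - P(X_a > X_b | class 0)| (within-sample ties
count 1/2 toward each probability) and the secondary rank score gamma (the
absolute between-class difference of the mean within-sample rank difference),
with lexicographic gene order as the final deterministic tie-break.  The
number of pairs k is chosen by stratified cross-validation on balanced
accuracy, ties resolved toward smaller k.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class PairRule:
    """expression(gene_a) > expression(gene_b) votes high-risk."""

    gene_a: str
    gene_b: str

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise ValueError("a pair rule needs two distinct genes")


@dataclass(frozen=True)
class PairScore:
    delta: float
    gamma: float

    def __post_init__(self):
        if not (-1e-12 <= self.delta <= 1.0 + 1e-12):
            raise ValueError("delta must lie in [0, 1]")


@dataclass
class SSPModel:
    """A locked single-sample predictor for one ER x RT stratum."""

    stratum: str
    rules: list  # ordered list of PairRule
    decision: str = "majority_vote"
    metadata: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.rules)

    @property
    def genes(self) -> list[str]:
        out = []
        for r in self.rules:
            out.extend([r.gene_a, r.gene_b])
        return out

    def validate(self, require_odd: bool = True) -> None:
        genes = self.genes
        if len(genes) != len(set(genes)):
            raise ValueError("SSP rules must use pairwise distinct genes")
        if require_odd and self.k % 2 == 0:
            raise ValueError("SSP needs an odd number of rules for a decisive majority vote")


@dataclass
class KTSPConfig:
    """Training configuration.

    ``min_k`` honors the design choice of training with at least 100 pairs
    (so >= 200 genes enter each predictor), rounded up to odd so the
    majority vote cannot tie.
    """

    min_k: int = 101
    k_grid: list | None = None   # default: odd values from min_k to floor(n_genes/2)
    folds: int = 5
    seed: int = 0
    min_per_class: int = 10


def _as_frame(expr) -> pd.DataFrame:
    if isinstance(expr, ExpressionMatrix):
        return expr.values
    if isinstance(expr, pd.DataFrame):
        return expr
    raise TypeError("expected ExpressionMatrix or DataFrame")


def _check_labels(labels, columns) -> np.ndarray:
    y = np.asarray(labels).astype(bool)
    if y.shape[0] != len(columns):
        raise ValueError("labels must align with samples")
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError(f"need >=2 samples per class, got {n1} positive / {n0} negative")
    return y


def pair_score(expr, labels, gene_i: str, gene_j: str) -> PairScore:
    """Score one gene pair: (delta, gamma) as defined in the module docstring."""
    if gene_i == gene_j:
        raise ValueError("pair_score needs two distinct genes")
    M = _as_frame(expr)
    y = _check_labels(labels, M.columns)
    xi = M.loc[gene_i].to_numpy(dtype=float)
    xj = M.loc[gene_j].to_numpy(dtype=float)

    def p_gt(mask):
        gt = (xi[mask] > xj[mask]).mean()
        eq = (xi[mask] == xj[mask]).mean()
        return gt + 0.5 * eq

    ranks = rankdata(M.to_numpy(dtype=float), axis=0)
    ri = ranks[M.index.get_loc(gene_i)]
    rj = ranks[M.index.get_loc(gene_j)]
    diff = ri - rj
    delta = abs(p_gt(y) - p_gt(~y))
    gamma = abs(diff[y].mean() - diff[~y].mean())
    return PairScore(delta=float(delta), gamma=float(gamma))


def select_pairs(expr, labels, k_max: int) -> list[PairRule]:
    """Greedy disjoint pair selection.

    Pairs are sorted by delta (descending), gamma (descending), then
    lexicographic (gene_a, gene_b); the top k_max pairwise gene-disjoint
    pairs are returned, oriented so gene_a > gene_b is the class-1
    (high-risk) direction.
    """
    M = _as_frame(expr)
    y = _check_labels(labels, M.columns)
    genes = list(M.index)
    if k_max > len(genes) // 2:
        raise ValueError(f"k_max={k_max} exceeds floor(n_genes/2)={len(genes) // 2}")
    X = M.to_numpy(dtype=float)
    n1, n0 = int(y.sum()), int((~y).sum())

    # Exact integer sort keys (cross-multiplied counts), so that ties in
    # delta/gamma are real ties, never float-rounding artifacts:
    #   delta ~ |(2*gt1 + eq1)*n0 - (2*gt0 + eq0)*n1|
    #   gamma ~ |rank-diff-sum1 * n0 - rank-diff-sum0 * n1|  (doubled ranks)
    ranks2 = 2.0 * rankdata(X, axis=0)  # average ties -> doubled ranks are integers

    def class_counts(mask):
        Xc = X[:, mask]
        gt = (Xc[:, None, :] > Xc[None, :, :]).sum(axis=2, dtype=np.int64)
        eq = (Xc[:, None, :] == Xc[None, :, :]).sum(axis=2, dtype=np.int64)
        r = ranks2[:, mask].sum(axis=1)
        return gt, eq, np.rint(r[:, None] - r[None, :]).astype(np.int64)

    gt1, eq1, d1 = class_counts(y)
    gt0, eq0, d0 = class_counts(~y)
    signed_delta = (2 * gt1 + eq1) * n0 - (2 * gt0 + eq0) * n1
    gamma_key = np.abs(d1 * n0 - d0 * n1)

    candidates = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            s = signed_delta[i, j]
            if s > 0:
                a, b = genes[i], genes[j]
            elif s < 0:
                a, b = genes[j], genes[i]
            else:
                a, b = sorted((genes[i], genes[j]))
            candidates.append((abs(int(s)), int(gamma_key[i, j]), a, b))
    candidates.sort(key=lambda t: (-t[0], -t[1], t[2], t[3]))

    used: set[str] = set()
    rules: list[PairRule] = []
    for _, _, a, b in candidates:
        if a in used or b in used:
            continue
        rules.append(PairRule(gene_a=a, gene_b=b))
        used.update((a, b))
        if len(rules) == k_max:
            return rules
    raise ValueError(
        f"only {len(rules)} disjoint pairs available, {k_max} requested "
        f"(shortfall {k_max - len(rules)})"
    )


def rule_votes(rules: list[PairRule], expr) -> np.ndarray:
    """Vote matrix (rules x samples); tie within a sample counts 1/2."""
    M = _as_frame(expr)
    missing = sorted({g for r in rules for g in (r.gene_a, r.gene_b)} - set(M.index))
    if missing:
        raise ValueError(f"expression matrix is missing model genes: {missing}")
    Xa = M.loc[[r.gene_a for r in rules]].to_numpy(dtype=float)
    Xb = M.loc[[r.gene_b for r in rules]].to_numpy(dtype=float)
    return (Xa > Xb).astype(float) + 0.5 * (Xa == Xb)


def select_k_cv(expr, labels, k_grid, folds: int = 5, seed: int = 0) -> int:
    """Choose k from ``k_grid`` by stratified CV on balanced accuracy.

    Deterministic given ``seed``; ties favor the smaller k.  With a
    single-element grid no CV is run.
    """
    k_grid = sorted(set(int(k) for k in k_grid))
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    if any(k % 2 == 0 for k in k_grid):
        raise ValueError("all k in k_grid must be odd")
    if len(k_grid) == 1:
        return k_grid[0]
    if folds < 2:
        raise ValueError("folds must be >= 2")
    M = _as_frame(expr)
    y = _check_labels(labels, M.columns)
    class_min = min(int(y.sum()), int((~y).sum()))
    if class_min < folds:
        raise ValueError(
            f"smallest class has {class_min} samples; cannot build {folds} stratified folds"
        )
    k_max = max(k_grid)
    scores = {k: [] for k in k_grid}
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        rules = select_pairs(M.iloc[:, train_idx], y[train_idx], k_max)
        votes = rule_votes(rules, M.iloc[:, test_idx])
        cum = np.cumsum(votes, axis=0)
        for k in k_grid:
            pred = cum[k - 1] / k > 0.5
            scores[k].append(balanced_accuracy_score(y[test_idx], pred))
    means = {k: float(np.mean(v)) for k, v in scores.items()}
    best = max(k_grid, key=lambda k: (means[k], -k))
    logger.debug("select_k_cv: %s -> k=%d", means, best)
    return best


def default_k_grid(n_genes: int, min_k: int = 101) -> list[int]:
    """Odd k values from min_k up to floor(n_genes / 2)."""
    if min_k % 2 == 0:
        min_k += 1
    upper = n_genes // 2
    if upper < min_k:
        raise ValueError(
            f"panel of {n_genes} genes supports at most {upper} disjoint pairs; "
            f"minimum k is {min_k}"
        )
    return list(range(min_k, upper + 1, 2))


def train_ssp(expr, labels, stratum: str, config: KTSPConfig | None = None) -> SSPModel:
    """Train and lock a single-sample predictor for one stratum."""
    if config is None:
        config = KTSPConfig()
    M = _as_frame(expr)
    y = np.asarray(labels).astype(bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if min(n1, n0) < config.min_per_class:
        raise ValueError(
            f"stratum {stratum}: {n1} cases / {n0} controls; "
            f"need >= {config.min_per_class} per class to train"
        )
    k_grid = config.k_grid
    if k_grid is None:
        k_grid = default_k_grid(len(M.index), config.min_k)
    k = select_k_cv(M, y, k_grid, folds=config.folds, seed=config.seed)
    rules = select_pairs(M, y, k)
    model = SSPModel(
        stratum=stratum,
        rules=rules,
        metadata={
            "seed": config.seed,
            "folds": config.folds,
            "k_grid": list(k_grid),
            "n_cases": n1,
            "n_controls": n0,
        },
    )
    model.validate()
    return model


def predict(model: SSPModel, expr):
    """Majority-vote prediction.

    Returns a DataFrame (index = sample_id) with columns ``vote_fraction``
    and ``high_risk`` (vote_fraction > 0.5); for a single Series sample, a
    tuple (high_risk, vote_fraction).
    """
    single = isinstance(expr, pd.Series)
    if single:
        expr = expr.to_frame(name=expr.name or "sample")
    M = _as_frame(expr)
    votes = rule_votes(model.rules, M)
    frac = votes.mean(axis=0)
    out = pd.DataFrame({"vote_fraction": frac, "high_risk": frac > 0.5}, index=M.columns)
    if single:
        row = out.iloc[0]
        return bool(row["high_risk"]), float(row["vote_fraction"])
    return out


def subset_model(model: SSPModel, available_genes) -> SSPModel:
    """Drop rules whose genes are unavailable, keeping the vote decisive.

    If the remaining rule count is even, the lowest-ranked remaining rule is
    dropped too.  Dropped rules are recorded in the model metadata.
    """
    available = set(available_genes)
    kept = [r for r in model.rules if r.gene_a in available and r.gene_b in available]
    dropped = [r for r in model.rules if r not in kept]
    if len(kept) % 2 == 0 and kept:
        dropped.append(kept.pop())
    if not kept:
        raise ValueError("no rules remain after subsetting to the available genes")
    meta = dict(model.metadata)
    meta["dropped_rules"] = [[r.gene_a, r.gene_b] for r in dropped]
    out = SSPModel(stratum=model.stratum, rules=kept, decision=model.decision, metadata=meta)
    out.validate()
    return out


def save_model(model: SSPModel, path) -> None:
    model.validate(require_odd=False)
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "stratum": model.stratum,
        "k": model.k,
        "decision": model.decision,
        "rules": [{"gene_a": r.gene_a, "gene_b": r.gene_b} for r in model.rules],
        "metadata": model.metadata,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def load_model(path) -> SSPModel:
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as e:
            raise ValueError(f"corrupted model file {path}: {e}") from e
    for key in ("stratum", "k", "rules", "decision"):
        if key not in payload:
            raise ValueError(f"model file {path} missing field {key!r}")
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        warnings.warn(
            f"model file {path} has format_version {payload.get('format_version')}, "
            f"expected {MODEL_FORMAT_VERSION}",
            stacklevel=2,
        )
    rules = [PairRule(gene_a=r["gene_a"], gene_b=r["gene_b"]) for r in payload["rules"]]
    if payload["k"] != len(rules):
        raise ValueError(f"model file {path}: k={payload['k']} but {len(rules)} rules")
    model = SSPModel(
        stratum=payload["stratum"],
        rules=rules,
        decision=payload["decision"],
        metadata=payload.get("metadata", {}),
    )
    model.validate(require_odd=False)
    return model
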