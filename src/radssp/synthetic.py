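"""Synthetic nCounter-like cohort generator.

Emulates the structure of a two-cohort (discovery/validation) case-control
study of ipsilateral breast tumor recurrence (IBTR) profiled on a targeted
248-gene count panel: negative-binomial endogenous counts with lognormal
per-sample size factors, a positive-control spike ladder, negative-control
background probes, four ER x RT strata, and censored time-to-IBTR outcomes.

Class signal is planted purely in within-sample pair order: each gene of a
planted pair (A, B) is drawn uniformly from the same ladder of expression
levels in both classes (identical marginals, so no single gene separates
cases from controls), while the joint coupling of the two levels is shifted
cyclically upward in cases and downward in controls.  The result is that
P(A > B | case) - P(A > B | control) approximates a target difference -
exactly the quantity a top-scoring-pairs classifier detects - with no
marginal (single-gene) class signal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .containers import RawCounts, STRATA, ANNOTATION_COLUMNS, validate_annotation
from .panel import (
    default_manifest,
    IMMUNE_GENES,
    PROLIFERATION_GENES,
    RSI_GENES,
    LITERATURE_GENES,
)

#: Six positive-control concentrations in a 4-fold geometric series (counts).
POSITIVE_CONTROL_LADDER = (32768.0, 8192.0, 2048.0, 512.0, 128.0, 32.0)

#: Mean of the negative-control background probes (counts).
NEGATIVE_CONTROL_MEAN = 2.0

# Planted pairs use a cyclic-copula construction: each gene of a pair sits on
# one of _PAIR_LEVELS geometrically spaced expression levels, uniformly in
# BOTH classes (identical marginals, so no single gene carries class signal);
# in cases gene A is coupled one level above gene B (cyclically), in controls
# one level below.  The achievable order difference saturates at
# ~ (K-2)/K x P(adjacent levels resolve), about 0.63 at the defaults.
_PAIR_LEVELS = 8
_PAIR_SPACING = 3.0


@dataclass
class CohortConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the emulated study: 172 discovery + 164 validation
    samples, four ER x RT strata with a deliberately tiny ER-RT- stratum
    (N ~ 3), ~40% cases per stratum, median time to IBTR of 4.4 years and
    follow-up up to 25 years.  The default of 15 planted order-signal pairs
    per stratum at an order difference of 0.6 is sized so that a locked
    majority-vote predictor of >= 101 rules separates held-out cases from
    controls at AUC ~ 0.7-0.9 (the separation of the mean vote fraction
    scales as n_pairs * delta / k against a vote noise SD of ~ 0.5/sqrt(k)),
    emulating a cohort in which such predictors genuinely validate.
    """

    n_discovery: int = 172
    n_validation: int = 164
    stratum_fractions: dict = field(
        default_factory=lambda: {"ER+RT+": 0.52, "ER+RT-": 0.24, "ER-RT+": 0.22, "ER-RT-": 0.02}
    )
    case_fraction: float | dict = 0.40
    n_planted_pairs: int | dict = 15
    planted_delta: float = 0.6
    nb_dispersion: float = 10.0
    size_factor_sd: float = 0.25
    followup_max_years: float = 25.0
    median_time_to_ibtr: float = 4.4
    seed: int = 0

    def per_stratum(self, value) -> dict:
        if isinstance(value, dict):
            missing = set(STRATA) - set(value)
            if missing:
                raise ValueError(f"per-stratum value missing strata: {sorted(missing)}")
            return {s: value[s] for s in STRATA}
        return {s: value for s in STRATA}

    def validate(self) -> None:
        if self.n_discovery <= 0 or self.n_validation <= 0:
            raise ValueError("cohort sizes must be positive")
        fracs = self.stratum_fractions
        if set(fracs) != set(STRATA):
            raise ValueError(f"stratum_fractions must cover exactly {STRATA}")
        if any(not (0.0 <= f <= 1.0) for f in fracs.values()):
            raise ValueError("stratum fractions must lie in [0, 1]")
        if abs(sum(fracs.values()) - 1.0) > 1e-8:
            raise ValueError("stratum fractions must sum to 1")
        if not (0.0 <= self.planted_delta <= 1.0):
            raise ValueError("planted_delta must lie in [0, 1]")
        for name in ("nb_dispersion", "size_factor_sd", "followup_max_years", "median_time_to_ibtr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for s, cf in self.per_stratum(self.case_fraction).items():
            if not (0.0 <= cf <= 1.0):
                raise ValueError(f"case_fraction for {s} must lie in [0, 1]")
        for s, k in self.per_stratum(self.n_planted_pairs).items():
            if k < 0:
                raise ValueError("n_planted_pairs must be non-negative")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Ground truth of one generated cohort, for tests and diagnostics."""

    gene_means: pd.Series            # baseline mean per endogenous/housekeeping gene
    size_factors: pd.Series          # per-sample lognormal size factor
    planted_pairs: dict              # stratum -> list of (gene_a, gene_b); A>B marks cases
    coupling_rate: float             # probability a planted pair is class-coupled
    delta_ceiling: float             # max order difference the mechanism can plant


def _largest_remainder(n: int, fractions: dict) -> dict:
    """Apportion n into integer stratum counts by largest remainder."""
    raw = {s: n * fractions[s] for s in STRATA}
    counts = {s: int(np.floor(raw[s])) for s in STRATA}
    short = n - sum(counts.values())
    order = sorted(STRATA, key=lambda s: (-(raw[s] - counts[s]), STRATA.index(s)))
    for s in order[:short]:
        counts[s] += 1
    return counts


def _truncated_exponential(rng, rate: float, upper: float, size: int) -> np.ndarray:
    """Exponential event times conditioned on being <= upper."""
    u = rng.uniform(size=size)
    return -np.log1p(-u * (1.0 - np.exp(-rate * upper))) / rate


def generate_cohort(
    config: CohortConfig,
    manifest: pd.DataFrame | None = None,
    return_truth: bool = False,
):
    """Generate a synthetic cohort.

    Returns ``(RawCounts, annotation)`` or, with ``return_truth``,
    ``(RawCounts, annotation, SyntheticTruth)``.  Deterministic given
    ``config.seed``.
    """
    config.validate()
    if manifest is None:
        manifest = default_manifest()
    rng = np.random.default_rng(config.seed)

    endo = manifest.loc[manifest["probe_class"] == "endogenous", "gene_id"].tolist()
    hk = manifest.loc[manifest["probe_class"] == "housekeeping", "gene_id"].tolist()
    pos = manifest.loc[manifest["probe_class"] == "positive_ctrl", "gene_id"].tolist()
    neg = manifest.loc[manifest["probe_class"] == "negative_ctrl", "gene_id"].tolist()

    named = set(IMMUNE_GENES) | set(PROLIFERATION_GENES) | set(RSI_GENES) | set(LITERATURE_GENES)
    plantable = [g for g in endo if g not in named] or list(endo)
    planted_per_stratum = config.per_stratum(config.n_planted_pairs)
    n_pairs_total = sum(planted_per_stratum.values())
    if 2 * n_pairs_total > len(plantable):
        raise ValueError(
            f"{n_pairs_total} planted pairs need {2 * n_pairs_total} genes; "
            f"only {len(plantable)} available"
        )

    # --- samples and strata ---------------------------------------------
    cohorts = [("discovery", config.n_discovery, "D"), ("validation", config.n_validation, "V")]
    rows = []
    for cohort, n, prefix in cohorts:
        counts_by_stratum = _largest_remainder(n, config.stratum_fractions)
        i = 0
        for stratum in STRATA:
            for _ in range(counts_by_stratum[stratum]):
                i += 1
                rows.append((f"{prefix}{i:03d}", cohort, stratum))
    samples = pd.DataFrame(rows, columns=["sample_id", "cohort", "stratum"])
    samples["er_status"] = np.where(samples["stratum"].str.startswith("ER+"), "pos", "neg")
    samples["rt"] = samples["stratum"].str.endswith("RT+")

    # case/control labels per (cohort, stratum)
    case_frac = config.per_stratum(config.case_fraction)
    is_case = np.zeros(len(samples), dtype=bool)
    for (cohort, stratum), idx in samples.groupby(["cohort", "stratum"]).groups.items():
        idx = np.asarray(idx)
        n_cases = int(round(case_frac[stratum] * len(idx)))
        chosen = rng.choice(idx, size=n_cases, replace=False)
        is_case[chosen] = True
    samples["ibtr_event"] = is_case

    # --- expression means ------------------------------------------------
    n_s = len(samples)
    base_log2 = rng.normal(6.5, 1.2, size=len(endo)).clip(4.5, 12.0)
    mu_endo = pd.Series(2.0 ** base_log2, index=endo)
    mu_hk = pd.Series(2.0 ** rng.normal(9.0, 0.4, size=len(hk)), index=hk)

    pool = list(plantable)
    rng.shuffle(pool)
    planted: dict[str, list[tuple[str, str]]] = {}
    cursor = 0
    for stratum in STRATA:
        k = planted_per_stratum[stratum]
        pairs = []
        for _ in range(k):
            a, b = pool[cursor], pool[cursor + 1]
            cursor += 2
            pairs.append((a, b))
        planted[stratum] = pairs

    mean_mat = pd.DataFrame(
        np.tile(pd.concat([mu_endo, mu_hk]).to_numpy()[:, None], (1, n_s)),
        index=endo + hk,
        columns=samples["sample_id"],
    )
    pair_base = 2.0 ** 7.0
    K = _PAIR_LEVELS
    levels = pair_base * _PAIR_SPACING ** (np.arange(K) - (K - 1) / 2.0)

    # normal approximation of P(count at level i+1 > count at level i),
    # averaged over the cyclic steps -> the mechanism's delta ceiling
    d = config.nb_dispersion
    var = levels + levels**2 / d
    p_step = ndtr(
        (levels[(np.arange(K) + 1) % K] - levels) / np.sqrt(var[(np.arange(K) + 1) % K] + var)
    )
    delta_ceiling = float(2.0 * p_step.mean() - 1.0)
    coupling = config.planted_delta / delta_ceiling if config.planted_delta > 0 else 0.0
    if coupling > 1.0:
        warnings.warn(
            f"planted_delta={config.planted_delta} exceeds the mechanism ceiling "
            f"(~{delta_ceiling:.2f}); saturating at the ceiling",
            stacklevel=2,
        )
        coupling = 1.0

    for stratum, pairs in planted.items():
        if not pairs:
            continue
        in_stratum = (samples["stratum"] == stratum).to_numpy()
        n_st = int(in_stratum.sum())
        for a, b in pairs:
            # flat base outside the stratum: ordering is a coin flip there
            mean_mat.loc[a] = pair_base
            mean_mat.loc[b] = pair_base
            if n_st == 0:
                continue
            is_case = samples.loc[in_stratum, "ibtr_event"].to_numpy()
            j_b = rng.integers(0, K, size=n_st)
            coupled = rng.uniform(size=n_st) < coupling
            shift = np.where(is_case, 1, -1)
            j_a = np.where(coupled, (j_b + shift) % K, rng.integers(0, K, size=n_st))
            cols = samples.loc[in_stratum, "sample_id"].to_numpy()
            mean_mat.loc[a, cols] = levels[j_a]
            mean_mat.loc[b, cols] = levels[j_b]

    size_factors = pd.Series(
        rng.lognormal(0.0, config.size_factor_sd, size=n_s),
        index=samples["sample_id"].to_numpy(),
    )
    scaled = mean_mat.to_numpy() * size_factors.to_numpy()[None, :]
    d = config.nb_dispersion
    counts_main = rng.negative_binomial(d, d / (d + scaled))

    ladder = np.asarray(POSITIVE_CONTROL_LADDER[: len(pos)])
    counts_pos = rng.poisson(ladder[:, None] * size_factors.to_numpy()[None, :])
    counts_neg = rng.poisson(NEGATIVE_CONTROL_MEAN, size=(len(neg), n_s))

    counts = pd.DataFrame(
        np.vstack([counts_main, counts_pos, counts_neg]),
        index=endo + hk + pos + neg,
        columns=samples["sample_id"].to_numpy(),
    )
    # keep manifest row order
    counts = counts.loc[[g for g in manifest["gene_id"] if g in counts.index]]
    counts.index.name = "gene_id"

    # --- survival outcomes ----------------------------------------------
    rate = np.log(2.0) / config.median_time_to_ibtr
    time_years = np.zeros(n_s)
    for stratum in STRATA:
        in_stratum = (samples["stratum"] == stratum).to_numpy()
        cases = in_stratum & samples["ibtr_event"].to_numpy()
        ctrls = in_stratum & ~samples["ibtr_event"].to_numpy()
        case_times = _truncated_exponential(rng, rate, config.followup_max_years, cases.sum())
        time_years[cases] = case_times
        if ctrls.sum():
            if cases.sum():
                matched = rng.choice(case_times, size=ctrls.sum(), replace=True)
            else:
                matched = rng.uniform(0.5, config.followup_max_years / 2, size=ctrls.sum())
            time_years[ctrls] = rng.uniform(matched, config.followup_max_years)
    samples["time_years"] = np.round(time_years, 4)

    therapy_rates = {"discovery": (0.35, 0.20), "validation": (0.65, 0.23)}
    endocrine = np.zeros(n_s, dtype=bool)
    chemo = np.zeros(n_s, dtype=bool)
    for cohort, (p_endo, p_chemo) in therapy_rates.items():
        in_c = (samples["cohort"] == cohort).to_numpy()
        endocrine[in_c] = rng.uniform(size=in_c.sum()) < p_endo
        chemo[in_c] = rng.uniform(size=in_c.sum()) < p_chemo
    samples["endocrine_therapy"] = endocrine
    samples["chemotherapy"] = chemo

    annot = validate_annotation(samples[ANNOTATION_COLUMNS].copy())
    raw = RawCounts(counts=counts, manifest=manifest)

    if return_truth:
        truth = SyntheticTruth(
            gene_means=pd.concat([mu_endo, mu_hk]),
            size_factors=size_factors,
            planted_pairs=planted,
            coupling_rate=coupling,
            delta_ceiling=delta_ceiling,
        )
        return raw, annot, truth
    return raw, annot


def simulate_survival(
    hazard: np.ndarray,
    followup_max_years: float,
    rng: np.random.Generator,
    min_censor_years: float = 1e-3,
):
    """Draw (time, event) from exponential event times vs uniform censoring.

    Utility for treatment-effect simulations: ``hazard`` is the per-sample
    exponential event rate; censoring times are uniform on
    (min_censor_years, followup_max_years].
    """
    hazard = np.asarray(hazard, dtype=float)
    if (hazard <= 0).any():
        raise ValueError("hazards must be positive")
    t_event = rng.exponential(1.0 / hazard)
    t_censor = rng.uniform(min_censor_years, followup_max_years, size=hazard.shape)
    event = t_event <= t_censor
    return np.minimum(t_event, t_censor), event


def write_fixture(counts: RawCounts, annot: pd.DataFrame, dir_path) -> dict:
    """Write a cohort to disk as deterministic text files.

    Produces ``counts.tsv`` (genes as rows, first column gene_id),
    ``manifest.csv``, ``annotation.csv`` and ``fixture.json`` (file listing).
    Round-trips bit-exactly through :func:`radssp.io_norm.read_counts`.
    """
    if counts.counts.shape[1] == 0:
        raise ValueError("refusing to write an empty cohort (no samples)")
    missing = set(counts.samples) - set(annot["sample_id"])
    if missing:
        raise ValueError(f"samples without annotation rows: {sorted(missing)}")
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": dir_path / "counts.tsv",
        "manifest": dir_path / "manifest.csv",
        "annotation": dir_path / "annotation.csv",
    }
    counts.counts.to_csv(paths["counts"], sep="\t", index_label="gene_id")
    counts.manifest.to_csv(paths["manifest"], index=False)
    validate_annotation(annot).to_csv(paths["annotation"], index=False)
    listing = {name: p.name for name, p in paths.items()}
    with open(dir_path / "fixture.json", "w") as fh:
        json.dump(listing, fh, indent=2, sort_keys=True)
    paths["fixture"] = dir_path / "fixture.json"
    return {k: str(v) for k, v in paths.items()}
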