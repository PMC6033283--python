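import numpy as np
import pandas as pd
import pytest

from radssp import (
    CohortConfig,
    KTSPConfig,
    generate_cohort,
    normalize,
    qc_filter,
    stratum_of,
)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-sized synthetic cohort (with ground truth), QC'd + normalized."""
    counts, annot, truth = generate_cohort(CohortConfig(seed=7), return_truth=True)
    filtered, report = qc_filter(counts)
    expr = normalize(filtered)
    annot = annot[annot["sample_id"].isin(expr.samples)].reset_index(drop=True)
    annot = annot.assign(
        stratum=[stratum_of(e, r) for e, r in zip(annot["er_status"], annot["rt"])]
    )
    return {
        "counts": counts,
        "filtered": filtered,
        "qc": report,
        "expr": expr,
        "annot": annot,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def trained_ssp(default_cohort):
    """An SSP trained on the largest discovery stratum of the default cohort."""
    from radssp import train_ssp

    annot = default_cohort["annot"]
    sub = annot[(annot["cohort"] == "discovery") & (annot["stratum"] == "ER+RT+")]
    expr = default_cohort["expr"].subset_samples(sub["sample_id"])
    return train_ssp(expr, sub["ibtr_event"].to_numpy(), "ER+RT+", KTSPConfig(seed=0))


def single_stratum_config(seed, n_per_class=100, n_planted=5, delta=0.6, n_validation=20):
    """Cohort config with everything in ER+RT+ and a 50/50 case split."""
    return CohortConfig(
        n_discovery=2 * n_per_class,
        n_validation=n_validation,
        stratum_fractions={"ER+RT+": 1.0, "ER+RT-": 0.0, "ER-RT+": 0.0, "ER-RT-": 0.0},
        case_fraction=0.5,
        n_planted_pairs={"ER+RT+": n_planted, "ER+RT-": 0, "ER-RT+": 0, "ER-RT-": 0},
        planted_delta=delta,
        seed=seed,
    )


def empirical_pair_delta(counts, labels, gene_a, gene_b):
    """Counting estimate of P(a>b | case) - P(a>b | control) on raw counts."""
    xa = counts.counts.loc[gene_a].to_numpy(dtype=float)
    xb = counts.counts.loc[gene_b].to_numpy(dtype=float)
    y = np.asarray(labels).astype(bool)

    def p(mask):
        return ((xa[mask] > xb[mask]) + 0.5 * (xa[mask] == xb[mask])).mean()

    return p(y) - p(~y)
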