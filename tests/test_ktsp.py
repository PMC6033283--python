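"""k-TSP classifier tests: counting oracles, tie-breaks, CV determinism,
majority voting, model surgery and serialization."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata

from radssp import (
    KTSPConfig,
    PairRule,
    SSPModel,
    load_model,
    pair_score,
    predict,
    save_model,
    select_k_cv,
    select_pairs,
    subset_model,
    train_ssp,
)


# ---------------------------------------------------------------- oracles
def oracle_pair_score(M: pd.DataFrame, y: np.ndarray, gi: str, gj: str):
    """Direct per-sample counting of order probabilities and rank differences."""
    xi, xj = M.loc[gi], M.loc[gj]

    def p_gt(mask):
        total = 0.0
        for s in M.columns[mask]:
            if xi[s] > xj[s]:
                total += 1.0
            elif xi[s] == xj[s]:
                total += 0.5
        return total / mask.sum()

    ranks = pd.DataFrame(rankdata(M.to_numpy(), axis=0), index=M.index, columns=M.columns)
    diff = ranks.loc[gi] - ranks.loc[gj]
    delta = abs(p_gt(y) - p_gt(~y))
    gamma = abs(diff[y].mean() - diff[~y].mean())
    return delta, gamma


def oracle_select_pairs(M: pd.DataFrame, y: np.ndarray, k: int):
    """Exhaustive enumeration of ordered disjoint pair sequences.

    Every oriented candidate pair gets the key (delta, gamma, gene_a, gene_b)
    computed in exact rational arithmetic; among all length-k disjoint
    sequences the one with the lexicographically best key sequence (higher
    delta, then higher gamma, then smaller names) is returned.
    """
    from fractions import Fraction

    genes = list(M.index)
    ranks = pd.DataFrame(rankdata(M.to_numpy(), axis=0), index=M.index, columns=M.columns)

    def frac_p(gi, gj, mask):
        total = Fraction(0)
        for s in M.columns[mask]:
            if M.loc[gi, s] > M.loc[gj, s]:
                total += 1
            elif M.loc[gi, s] == M.loc[gj, s]:
                total += Fraction(1, 2)
        return total / int(mask.sum())

    def frac_rankdiff(gi, gj, mask):
        total = Fraction(0)
        for s in M.columns[mask]:
            total += Fraction(int(2 * (ranks.loc[gi, s] - ranks.loc[gj, s])), 2)
        return total / int(mask.sum())

    candidates = []
    for gi, gj in itertools.combinations(genes, 2):
        p1, p0 = frac_p(gi, gj, y), frac_p(gi, gj, ~y)
        gamma = abs(frac_rankdiff(gi, gj, y) - frac_rankdiff(gi, gj, ~y))
        if p1 > p0:
            a, b = gi, gj
        elif p1 < p0:
            a, b = gj, gi
        else:
            a, b = sorted((gi, gj))
        candidates.append((abs(p1 - p0), gamma, a, b))

    def better_key(p, q):
        # higher delta, then higher gamma, then smaller gene names
        kp = (-p[0], -p[1], p[2], p[3])
        kq = (-q[0], -q[1], q[2], q[3])
        return -1 if kp < kq else (1 if kp > kq else 0)

    def seq_cmp(sa, sb):
        for p, q in zip(sa, sb):
            c = better_key(p, q)
            if c:
                return c
        return 0

    best = None
    for seq in itertools.permutations(candidates, k):
        used = set()
        ok = True
        for _, _, a, b in seq:
            if a in used or b in used:
                ok = False
                break
            used.update((a, b))
        if not ok:
            continue
        if best is None or seq_cmp(seq, best) < 0:
            best = seq
    return [PairRule(gene_a=a, gene_b=b) for _, _, a, b in best]


def random_instance(rng, n_genes, n_samples, grid=6):
    """Random small matrix on an integer grid (plenty of ties), random labels."""
    M = pd.DataFrame(
        rng.integers(0, grid, size=(n_genes, n_samples)).astype(float),
        index=[f"G{i:02d}" for i in range(n_genes)],
        columns=[f"S{j:02d}" for j in range(n_samples)],
    )
    while True:
        y = rng.integers(0, 2, size=n_samples).astype(bool)
        if 2 <= y.sum() <= n_samples - 2:
            return M, y


# ---------------------------------------------------------------- pair_score
class TestPairScore:
    def test_perfect_separation(self):
        M = pd.DataFrame(
            {"s1": [2.0, 1.0], "s2": [3.0, 1.0], "s3": [1.0, 2.0], "s4": [0.0, 5.0]},
            index=["A", "B"],
        )
        y = np.array([True, True, False, False])
        score = pair_score(M, y, "A", "B")
        assert score.delta == 1.0

    def test_identical_class_frequencies_give_zero(self):
        M = pd.DataFrame(
            {"s1": [2.0, 1.0], "s2": [1.0, 2.0], "s3": [2.0, 1.0], "s4": [1.0, 2.0]},
            index=["A", "B"],
        )
        y = np.array([True, True, False, False])
        assert pair_score(M, y, "A", "B").delta == 0.0

    def test_half_delta_hand_example(self):
        # class 1 orderings {A>B, A<B}; class 0 {A<B, A<B}: delta = |0.5 - 0|
        M = pd.DataFrame(
            {"s1": [2.0, 1.0], "s2": [1.0, 2.0], "s3": [1.0, 2.0], "s4": [1.0, 2.0]},
            index=["A", "B"],
        )
        y = np.array([True, True, False, False])
        assert pair_score(M, y, "A", "B").delta == pytest.approx(0.5)

    def test_ties_count_half(self):
        M = pd.DataFrame(
            {"s1": [1.0, 1.0], "s2": [2.0, 1.0], "s3": [1.0, 2.0], "s4": [1.0, 2.0]},
            index=["A", "B"],
        )
        y = np.array([True, True, False, False])
        # P1 = (0.5 + 1)/2 = 0.75, P0 = 0
        assert pair_score(M, y, "A", "B").delta == pytest.approx(0.75)

    def test_empty_class_is_error(self):
        M = pd.DataFrame({"s1": [1.0, 2.0], "s2": [2.0, 1.0]}, index=["A", "B"])
        with pytest.raises(ValueError, match="per class"):
            pair_score(M, np.array([True, True]), "A", "B")

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        M, y = random_instance(rng, n_genes=int(rng.integers(3, 9)),
                               n_samples=int(rng.integers(5, 13)))
        gi, gj = rng.choice(M.index, size=2, replace=False)
        got = pair_score(M, y, gi, gj)
        delta, gamma = oracle_pair_score(M, y, gi, gj)
        assert got.delta == pytest.approx(delta, abs=1e-12)
        assert got.gamma == pytest.approx(gamma, abs=1e-12)


# ------------------------------------------------------------- select_pairs
class TestSelectPairs:
    def test_perfect_pair_ranked_first(self):
        rng = np.random.default_rng(0)
        M = pd.DataFrame(
            rng.normal(size=(6, 10)),
            index=[f"G{i}" for i in range(6)],
            columns=[f"S{j}" for j in range(10)],
        )
        y = np.array([True] * 5 + [False] * 5)
        M.loc["G0", y] = 5.0
        M.loc["G1", y] = 0.0
        M.loc["G0", ~y] = 0.0
        M.loc["G1", ~y] = 5.0
        rules = select_pairs(M, y, 3)
        assert (rules[0].gene_a, rules[0].gene_b) == ("G0", "G1")

    def test_deterministic_lexicographic_tie_break(self):
        # two pairs with identical delta and gamma by symmetry
        M = pd.DataFrame(
            {
                "s1": [2.0, 1.0, 2.0, 1.0],
                "s2": [1.0, 2.0, 1.0, 2.0],
                "s3": [1.0, 2.0, 1.0, 2.0],
                "s4": [1.0, 2.0, 1.0, 2.0],
            },
            index=["A", "B", "C", "D"],
        )
        y = np.array([True, True, False, False])
        rules = select_pairs(M, y, 2)
        first = (rules[0].gene_a, rules[0].gene_b)
        second = (rules[1].gene_a, rules[1].gene_b)
        assert first < second  # smaller oriented pair name chosen first

    def test_shortfall_is_error(self):
        M = pd.DataFrame(
            np.arange(8.0).reshape(2, 4), index=["A", "B"],
            columns=["s1", "s2", "s3", "s4"],
        )
        y = np.array([True, True, False, False])
        with pytest.raises(ValueError, match="exceeds"):
            select_pairs(M, y, 2)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        M, y = random_instance(rng, n_genes=6, n_samples=int(rng.integers(6, 13)))
        got = select_pairs(M, y, 2)
        want = oracle_select_pairs(M, y, 2)
        assert got == want


# -------------------------------------------------------------- select_k_cv
class TestSelectK:
    def _planted(self, seed, n_noise=14, n=40):
        rng = np.random.default_rng(seed)
        genes = [f"P{i}" for i in range(6)] + [f"N{i}" for i in range(n_noise)]
        M = pd.DataFrame(rng.normal(size=(len(genes), n)), index=genes,
                         columns=[f"S{j}" for j in range(n)])
        y = np.arange(n) % 2 == 0
        for i in range(3):  # 3 perfectly separating pairs
            M.loc[f"P{2*i}", y] = 10.0 + rng.normal(scale=0.1, size=y.sum())
            M.loc[f"P{2*i+1}", y] = 0.0 + rng.normal(scale=0.1, size=y.sum())
            M.loc[f"P{2*i}", ~y] = 0.0 + rng.normal(scale=0.1, size=(~y).sum())
            M.loc[f"P{2*i+1}", ~y] = 10.0 + rng.normal(scale=0.1, size=(~y).sum())
        return M, y

    def test_single_element_grid_short_circuits(self):
        M, y = self._planted(0)
        assert select_k_cv(M, y, [7]) == 7

    def test_three_informative_pairs_select_k3(self):
        hits = 0
        for seed in range(20):
            M, y = self._planted(seed)
            if select_k_cv(M, y, [3, 5, 7], folds=5, seed=seed) == 3:
                hits += 1
        assert hits >= 18

    def test_deterministic_given_seed(self):
        M, y = self._planted(1)
        ks = {select_k_cv(M, y, [3, 5, 7], seed=42) for _ in range(3)}
        assert len(ks) == 1

    def test_even_k_rejected(self):
        M, y = self._planted(0)
        with pytest.raises(ValueError, match="odd"):
            select_k_cv(M, y, [3, 4])

    def test_too_small_class_for_folds(self):
        M, y = self._planted(0, n=8)
        with pytest.raises(ValueError, match="stratified"):
            select_k_cv(M, y, [3, 5], folds=5)


# ------------------------------------------------------------------ predict
class TestPredict:
    def _model(self, rules):
        return SSPModel(stratum="ER+RT+", rules=[PairRule(*r) for r in rules])

    def test_unanimous_high_risk(self):
        model = self._model([("A", "B"), ("C", "D"), ("E", "F")])
        sample = pd.Series({"A": 5.0, "B": 1.0, "C": 4.0, "D": 2.0, "E": 9.0, "F": 0.0})
        high, frac = predict(model, sample)
        assert high and frac == 1.0

    def test_one_of_three_votes_is_low_risk(self):
        model = self._model([("A", "B"), ("C", "D"), ("E", "F")])
        sample = pd.Series({"A": 5.0, "B": 1.0, "C": 1.0, "D": 2.0, "E": 0.0, "F": 3.0})
        high, frac = predict(model, sample)
        assert not high and frac == pytest.approx(1 / 3)

    def test_odd_k_no_ties_is_decisive(self):
        rng = np.random.default_rng(0)
        model = self._model([("A", "B"), ("C", "D"), ("E", "F")])
        M = pd.DataFrame(rng.normal(size=(6, 50)), index=list("ABCDEF"))
        out = predict(model, M)
        assert (out["vote_fraction"] != 0.5).all()

    def test_missing_gene_error_lists_genes(self):
        model = self._model([("A", "B"), ("C", "D"), ("E", "F")])
        sample = pd.Series({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0, "E": 5.0})
        with pytest.raises(ValueError, match=r"\['F'\]"):
            predict(model, sample)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           coeffs=st.tuples(st.floats(0.1, 5.0), st.floats(-10.0, 10.0)))
    def test_rank_invariance_under_monotone_transforms(self, seed, coeffs):
        """predict(f(x)) == predict(x) for strictly increasing f."""
        a, b = coeffs
        rng = np.random.default_rng(seed)
        model = self._model([("A", "B"), ("C", "D"), ("E", "F")])
        M = pd.DataFrame(rng.normal(size=(6, 20)), index=list("ABCDEF"))
        base = predict(model, M)
        transformed = predict(model, np.exp(a * M + b))
        pd.testing.assert_series_equal(base["high_risk"], transformed["high_risk"])


# -------------------------------------------------- train / subset / io
class TestTrainAndSerialize:
    def test_small_stratum_refused(self):
        rng = np.random.default_rng(0)
        M = pd.DataFrame(rng.normal(size=(10, 3)), index=[f"G{i}" for i in range(10)],
                         columns=["s1", "s2", "s3"])
        with pytest.raises(ValueError, match="controls"):
            train_ssp(M, np.array([True, False, False]), "ER-RT-")

    def test_training_is_deterministic(self, default_cohort):
        annot = default_cohort["annot"]
        sub = annot[(annot["cohort"] == "discovery") & (annot["stratum"] == "ER-RT+")]
        expr = default_cohort["expr"].subset_samples(sub["sample_id"])
        y = sub["ibtr_event"].to_numpy()
        m1 = train_ssp(expr, y, "ER-RT+", KTSPConfig(seed=5))
        m2 = train_ssp(expr, y, "ER-RT+", KTSPConfig(seed=5))
        assert m1.rules == m2.rules

    def test_disjointness_invariant(self, trained_ssp):
        genes = trained_ssp.genes
        assert len(genes) == len(set(genes))
        assert trained_ssp.k % 2 == 1

    def test_subset_model_drops_pair_and_parity_rule(self):
        rules = [PairRule(f"A{i}", f"B{i}") for i in range(101)]
        model = SSPModel(stratum="ER+RT+", rules=rules)
        available = {g for r in rules for g in (r.gene_a, r.gene_b)} - {"A50"}
        out = subset_model(model, available)
        assert out.k == 99
        assert [list(r) for r in [("A50", "B50")]][0][0] not in out.genes
        dropped = out.metadata["dropped_rules"]
        assert ["A50", "B50"] in dropped and len(dropped) == 2

    def test_subset_model_identity_when_nothing_missing(self, trained_ssp):
        out = subset_model(trained_ssp, set(trained_ssp.genes))
        assert out.rules == trained_ssp.rules

    def test_subset_model_all_missing_is_error(self, trained_ssp):
        with pytest.raises(ValueError, match="no rules"):
            subset_model(trained_ssp, set())

    def test_save_load_round_trip(self, trained_ssp, tmp_path):
        path = tmp_path / "model.json"
        save_model(trained_ssp, path)
        back = load_model(path)
        assert back.rules == trained_ssp.rules
        assert back.stratum == trained_ssp.stratum
        assert back.k == trained_ssp.k
        assert back.metadata == trained_ssp.metadata

    def test_load_corrupted_file_is_error(self, tmp_path):
        path = tmp_path / "model.json"
        path.write_text("{not json")
        with pytest.raises(ValueError, match="corrupted"):
            load_model(path)

    def test_version_mismatch_warns(self, trained_ssp, tmp_path):
        import json

        path = tmp_path / "model.json"
        save_model(trained_ssp, path)
        payload = json.loads(path.read_text())
        payload["format_version"] = 99
        path.write_text(json.dumps(payload))
        with pytest.warns(UserWarning, match="format_version"):
            load_model(path)
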