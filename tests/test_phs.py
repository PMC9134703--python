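import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import cox_mle_newton, phs_loop
from phskit.hazards import GompertzHazard, hazard_curve
from phskit.phs import (
    PhsStratifier,
    PolygenicHazardScorer,
    SnpPanel,
    align_dosages,
    compute_phs,
    filter_candidate_snps,
    forward_stepwise_cox,
    stratify_phs,
)
from phskit.simulate import generate_onsets


def make_panel(ids, weights, forced=None, alleles=None):
    forced = forced or [False] * len(ids)
    return SnpPanel(
        pd.DataFrame(
            {
                "effect_allele": alleles or ["."] * len(ids),
                "weight": weights,
                "forced": forced,
            },
            index=pd.Index(ids, name="snp_id"),
        )
    )


class TestCandidateFilter:
    def test_no_variant_below_threshold(self):
        ss = pd.DataFrame({"snp_id": [f"rs{i}" for i in range(5)], "p": [0.5] * 5})
        assert filter_candidate_snps(ss, 1e-5) == []

    def test_strict_filter_preserves_order(self):
        ids = [f"rs{i}" for i in range(10)]
        p = [0.5] * 10
        for i in (7, 1, 4, 9):
            p[i] = 1e-6
        ss = pd.DataFrame({"snp_id": ids, "p": p})
        assert filter_candidate_snps(ss, 1e-5) == ["rs1", "rs4", "rs7", "rs9"]

    def test_boundary_p_excluded(self):
        ss = pd.DataFrame({"snp_id": ["a"], "p": [1e-5]})
        assert filter_candidate_snps(ss, 1e-5) == []

    def test_empty_table_and_malformed_p(self):
        assert filter_candidate_snps(pd.DataFrame(columns=["snp_id", "p"]), 1e-5) == []
        bad = pd.DataFrame({"snp_id": ["rsX"], "p": ["not-a-number"]})
        with pytest.raises(ValueError, match="rsX"):
            filter_candidate_snps(bad, 1e-5)


class TestComputePhs:
    def test_dot_product_example(self):
        dos = pd.DataFrame([[1.0, 2.0, 0.0]], columns=["a", "b", "c"], index=["P0"])
        panel = make_panel(["a", "b", "c"], [0.1, -0.2, 5.0])
        assert compute_phs(dos, panel).iloc[0] == pytest.approx(-0.3)

    def test_zero_dosages_zero_score(self):
        dos = pd.DataFrame(np.zeros((3, 2)), columns=["a", "b"])
        panel = make_panel(["a", "b"], [1.5, -2.0])
        assert (compute_phs(dos, panel) == 0).all()

    def test_matches_explicit_loop_oracle(self):
        rng = np.random.default_rng(0)
        dos = pd.DataFrame(rng.integers(0, 3, size=(40, 12)).astype(float),
                           columns=[f"s{j}" for j in range(12)])
        w = rng.normal(size=12)
        panel = make_panel(list(dos.columns), w)
        np.testing.assert_allclose(
            compute_phs(dos, panel).to_numpy(), phs_loop(dos.to_numpy(), w),
            rtol=1e-12, atol=1e-12,
        )

    def test_variant_order_irrelevant(self):
        rng = np.random.default_rng(1)
        dos = pd.DataFrame(rng.integers(0, 3, size=(10, 5)).astype(float),
                           columns=list("abcde"))
        panel = make_panel(list("abcde"), rng.normal(size=5))
        shuffled = dos[["d", "a", "e", "b", "c"]]
        pd.testing.assert_series_equal(compute_phs(dos, panel), compute_phs(shuffled, panel))

    def test_missing_variant_and_missing_value(self):
        dos = pd.DataFrame([[1.0]], columns=["a"])
        with pytest.raises(KeyError, match="b"):
            compute_phs(dos, make_panel(["a", "b"], [1.0, 1.0]))
        dos2 = pd.DataFrame([[np.nan]], columns=["a"])
        with pytest.raises(ValueError, match="a"):
            compute_phs(dos2, make_panel(["a"], [1.0]))


class TestAlleleAlignment:
    def test_flip_when_counted_allele_differs(self):
        dos = pd.DataFrame({"a": [0.0, 1.0, 2.0]})
        panel = make_panel(["a"], [1.0], alleles=["G"])
        flipped = align_dosages(dos, pd.Series({"a": "A"}), panel)
        np.testing.assert_array_equal(flipped["a"], [2.0, 1.0, 0.0])

    def test_palindromic_mismatch_raises(self):
        dos = pd.DataFrame({"a": [1.0]})
        panel = make_panel(["a"], [1.0], alleles=["T"])
        with pytest.raises(ValueError, match="ambiguous"):
            align_dosages(dos, pd.Series({"a": "A"}), panel)


class TestStratify:
    def test_fixed_thresholds_from_reported_analysis(self):
        s = pd.Series([1.2, -1.0, 0.0])
        out = stratify_phs(s, thresholds=(1.04, -0.67))
        assert list(out) == ["high", "low", "mid"]

    def test_gaussian_tail_fraction(self):
        rng = np.random.default_rng(0)
        s = pd.Series(rng.normal(size=100000))
        frac = (stratify_phs(s) == "high").mean() * 100
        assert abs(frac - 15.87) < 0.5

    def test_constant_scores(self):
        s = pd.Series([1.0, 1.0, 1.0])
        assert (stratify_phs(s, thresholds=(2.0, 0.0)) == "mid").all()
        with pytest.raises(ValueError):
            stratify_phs(s)

    def test_stratifier_estimator_roundtrip(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=500)
        st_ = PhsStratifier().fit(s)
        out = st_.transform(s)
        assert set(out.unique()) == {"low", "mid", "high"}
        assert st_.high_ == pytest.approx(s.mean() + s.std(ddof=1))


class TestHazardCurve:
    def test_zero_score_is_baseline(self):
        bh = GompertzHazard()
        h = hazard_curve(0.0, bh)
        t = np.linspace(0, 100, 11)
        np.testing.assert_allclose(h(t), bh.hazard(t))

    def test_log2_score_doubles_hazard_everywhere(self):
        bh = GompertzHazard()
        t = np.linspace(40, 100, 25)
        np.testing.assert_allclose(
            hazard_curve(np.log(2.0), bh)(t) / hazard_curve(0.0, bh)(t), 2.0
        )

    def test_cumulative_hazard_nondecreasing(self):
        h = hazard_curve(0.7, GompertzHazard())
        t = np.linspace(0, 110, 200)
        assert (np.diff(h.cumulative(t)) >= 0).all()


def _survival_from_scores(scores, seed, censor_age=None):
    onsets = generate_onsets(scores, GompertzHazard(), seed=seed)
    time = onsets if censor_age is None else np.minimum(onsets, censor_age)
    event = np.ones_like(time) if censor_age is None else (onsets <= censor_age).astype(int)
    return pd.DataFrame({"time": time, "event": event})


class TestForwardStepwise:
    def _dosages(self, n, m, seed, freqs=0.3):
        rng = np.random.default_rng(seed)
        cols = [f"c{j}" for j in range(m)] + ["APOE_e4", "APOE_e2"]
        return pd.DataFrame(
            rng.binomial(2, freqs, size=(n, m + 2)).astype(float), columns=cols
        )

    def test_cap_zero_returns_forced_only(self):
        dos = self._dosages(120, 3, seed=0)
        scores = 0.8 * dos["APOE_e4"].to_numpy()
        surv = _survival_from_scores(scores, seed=1)
        surv.index = dos.index
        panel = forward_stepwise_cox(["c0", "c1", "c2"], dos, surv, max_snps=0)
        assert panel.snp_ids == ["APOE_e4", "APOE_e2"]
        assert panel.table["forced"].all()

    def test_null_candidates_rarely_selected_at_strict_alpha(self):
        total = 0
        for seed in range(8):
            dos = self._dosages(200, 5, seed=seed)
            surv = _survival_from_scores(np.zeros(200), seed=seed + 100)
            surv.index = dos.index
            panel = forward_stepwise_cox(
                [f"c{j}" for j in range(5)], dos, surv, alpha_entry=1e-4
            )
            total += len(panel.snp_ids) - 2
        assert total <= 1

    def test_strong_candidate_selected_first(self):
        """A variant with log-hazard 1 is picked before five null variants."""
        hits = 0
        n_rep = 25
        for seed in range(n_rep):
            dos = self._dosages(300, 6, seed=seed)
            scores = 1.0 * dos["c0"].to_numpy() + 0.8 * dos["APOE_e4"].to_numpy()
            surv = _survival_from_scores(scores, seed=seed + 500)
            surv.index = dos.index
            panel = forward_stepwise_cox(
                [f"c{j}" for j in range(6)], dos, surv, max_snps=1
            )
            selected = [s for s in panel.snp_ids if not panel.table.loc[s, "forced"]]
            hits += selected == ["c0"]
        assert hits >= int(0.9 * n_rep)

    def test_greedy_step_matches_exhaustive_partial_likelihood(self):
        """On 8 subjects the first stepwise pick maximises the maximised
        partial likelihood over all single-candidate models (brute force)."""
        rng = np.random.default_rng(3)
        n = 8
        dos = pd.DataFrame(
            {
                "APOE_e4": [0, 1, 0, 1, 0, 0, 1, 2.0],
                "c0": [2, 1, 0, 1, 2, 0, 1, 1.0],
                "c1": [0, 0, 1, 1, 0, 1, 2, 0.0],
                "c2": [1, 2, 0, 0, 1, 1, 0, 2.0],
            }
        )
        time = np.array([3.1, 1.2, 7.4, 2.8, 5.5, 9.9, 0.7, 4.3])
        event = np.ones(8)
        surv = pd.DataFrame({"time": time, "event": event}, index=dos.index)

        from oracles import cox_neg_partial_loglik

        best, best_ll = None, -np.inf
        for cand in ["c0", "c1", "c2"]:
            X = dos[["APOE_e4", cand]].to_numpy()
            beta = cox_mle_newton(X, time, event)
            ll = -cox_neg_partial_loglik(beta, X, time, event)
            if ll > best_ll:
                best, best_ll = cand, ll
        panel = forward_stepwise_cox(
            ["c0", "c1", "c2"], dos, surv, forced_covariates=("APOE_e4",),
            alpha_entry=1.0, max_snps=1,
        )
        chosen = [s for s in panel.snp_ids if s != "APOE_e4"]
        assert chosen == [best]

    def test_requires_events(self):
        dos = self._dosages(10, 2, seed=0)
        surv = pd.DataFrame({"time": np.ones(10), "event": np.zeros(10)}, index=dos.index)
        with pytest.raises(ValueError, match="event"):
            forward_stepwise_cox(["c0"], dos, surv)


class TestScorerEstimator:
    def test_known_weights_recovered_by_cox_on_score(self):
        """Cox regression of simulated onsets on the derived score has
        coefficient compatible with 1 (the score is the linear predictor)."""
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(9)
        n = 2000
        dos = pd.DataFrame(
            rng.binomial(2, 0.3, size=(n, 3)).astype(float), columns=["a", "b", "APOE_e4"]
        )
        panel = make_panel(["a", "b", "APOE_e4"], [0.4, -0.3, 0.9])
        score = compute_phs(dos, panel)
        surv = _survival_from_scores(score.to_numpy(), seed=10)
        df = pd.DataFrame({"time": surv["time"], "event": surv["event"], "phs": score})
        cph = CoxPHFitter().fit(df, "time", "event")
        lo, hi = cph.confidence_intervals_.loc["phs"]
        assert lo < 1.0 < hi

    def test_fit_transform_with_summary_stats_filter(self):
        rng = np.random.default_rng(4)
        n = 300
        dos = pd.DataFrame(
            rng.binomial(2, 0.3, size=(n, 5)).astype(float),
            columns=["s0", "s1", "s2", "APOE_e4", "APOE_e2"],
        )
        ss = pd.DataFrame(
            {"snp_id": ["s0", "s1", "s2"], "p": [1e-7, 0.5, 1e-6]}
        )
        scores_true = 0.9 * dos["s0"] + 0.8 * dos["APOE_e4"]
        surv = _survival_from_scores(scores_true.to_numpy(), seed=5)
        surv.index = dos.index
        scorer = PolygenicHazardScorer(summary_stats=ss, alpha_entry=0.2).fit(dos, surv)
        assert "s1" not in scorer.panel_.snp_ids  # filtered out by the GWAS p threshold
        phs = scorer.transform(dos)
        assert len(phs) == n and np.isfinite(phs).all()


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 2), min_size=3, max_size=3))
def test_score_linear_in_dosages(dose_row):
    """Adding a copy of the effect allele changes the score by its weight."""
    w = [0.5, -1.25, 2.0]
    panel = make_panel(["a", "b", "c"], w)
    base = compute_phs(pd.DataFrame([dose_row], columns=["a", "b", "c"], dtype=float), panel)
    for j, col in enumerate(["a", "b", "c"]):
        if dose_row[j] < 2:
            bumped = list(dose_row)
            bumped[j] += 1
            new = compute_phs(
                pd.DataFrame([bumped], columns=["a", "b", "c"], dtype=float), panel
            )
            assert new.iloc[0] - base.iloc[0] == pytest.approx(w[j])
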