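"""Unit and property tests for normalization, dispersion, the NB Wald tests,
the enhanced-TE classification, and BH FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from riboshift.simulate import TESimConfig, simulate_te_experiment
from riboshift.te import (
    CountExperiment,
    TEThresholds,
    bh_fdr,
    classify_te,
    compute_te,
    differential_abundance,
    dispersion_mom,
    effective_library_sizes,
    estimate_dispersion,
    estimate_size_factors,
    glm_te_interaction,
    rpkm,
    rpkm_from_effective,
)
from util import binomial_envelope


# ---------------------------------------------------------------------------
# size factors


class TestSizeFactors:
    def test_identical_libraries_give_unit_factors(self):
        counts = np.tile([[10], [20], [30]], (1, 2))
        assert np.allclose(estimate_size_factors(counts), [1.0, 1.0])

    def test_exact_doubling_gives_proportional_factors(self):
        a = np.array([10, 25, 40, 5])
        counts = np.column_stack([a, 2 * a])
        sf = estimate_size_factors(counts)
        assert np.isclose(sf[1] / sf[0], 2.0)

    def test_matches_hand_median_of_ratios(self):
        # 5-transcript toy; oracle computed by direct enumeration
        counts = np.array([[4, 8, 16],
                           [10, 10, 40],
                           [9, 3, 27],
                           [50, 50, 50],
                           [2, 4, 2]], dtype=float)
        geo = np.exp(np.log(counts).mean(axis=1))
        ratios = counts / geo[:, None]
        oracle = np.array([np.median(ratios[:, j]) for j in range(3)])
        oracle = oracle / np.exp(np.log(oracle).mean())
        assert np.allclose(estimate_size_factors(counts), oracle)

    def test_fallback_without_all_positive_transcript(self):
        counts = np.array([[0, 5], [5, 0], [10, 0]], dtype=float)
        with pytest.warns(UserWarning, match="falling back"):
            sf = estimate_size_factors(counts)
        assert np.all(sf > 0)
        assert np.isclose(np.exp(np.log(sf).mean()), 1.0)


# ---------------------------------------------------------------------------
# rpkm and TE


class TestRpkm:
    @pytest.mark.parametrize("count,length,eff,expected", [
        (100, 1000, 1e6, 100.0),
        (0, 1000, 1e6, 0.0),
        (250, 2500, 5e6, 20.0),  # 250 / (5 * 2.5)
    ])
    def test_unit_definition(self, count, length, eff, expected):
        out = rpkm_from_effective(np.array([[count]]), [length], [eff])
        assert np.isclose(out[0, 0], expected)

    def test_zero_effective_library_size_errors(self):
        with pytest.raises(ValueError, match="effective library"):
            rpkm_from_effective(np.array([[1]]), [100], [0.0])

    def test_invariant_to_uniform_library_scaling(self, small_te_data):
        _, rna, _, _ = small_te_data
        counts = rna.counts.astype(float)
        sf = estimate_size_factors(counts)
        base = rpkm(counts, rna.lengths_bp, sf)
        scaled = counts.copy()
        scaled[:, 2] *= 7
        sf2 = estimate_size_factors(scaled)
        again = rpkm(scaled, rna.lengths_bp, sf2)
        assert np.allclose(base, again, rtol=1e-6)

    def test_effective_sizes_scale_with_scaled_library(self):
        counts = np.array([[10, 10], [20, 20]], dtype=float)
        eff = effective_library_sizes(counts, [1.0, 1.0])
        assert np.allclose(eff, counts.sum(axis=0))


class TestComputeTe:
    def test_simple_ratio(self):
        assert np.isclose(compute_te(np.array([10.0]), np.array([20.0]),
                                     pseudocount=0.0), 2.0)

    def test_identity_when_equal(self, rng):
        x = rng.random((5, 3))
        assert np.allclose(compute_te(x, x, pseudocount=0.0), 1.0)

    def test_zero_zero_with_pseudocount(self):
        assert np.isclose(compute_te(np.array([0.0]), np.array([0.0]),
                                     pseudocount=0.5), 1.0)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            compute_te(np.zeros((2, 2)), np.zeros((2, 3)))


# ---------------------------------------------------------------------------
# dispersion


class TestDispersion:
    def test_mom_matches_direct_moment_formula(self):
        # 6-library toy; oracle from explicit sums
        vals = np.array([[3.0, 7.0, 5.0, 4.0, 9.0, 2.0],
                         [10.0, 30.0, 20.0, 15.0, 25.0, 20.0]])
        raw = dispersion_mom(vals)
        for g in range(2):
            x = vals[g]
            m = sum(x) / len(x)
            v = sum((xi - m) ** 2 for xi in x) / (len(x) - 1)
            assert np.isclose(raw[g], (v - m) / m**2)

    def test_poisson_variance_equals_mean_reports_floor(self):
        # per-condition values [0,1,2]: sample mean 1, sample variance 1
        counts = np.array([[0, 1, 2, 0, 1, 2]])
        disp = estimate_dispersion(counts, ["A"] * 3 + ["B"] * 3,
                                   size_factors=np.ones(6), shrinkage=0.0)
        assert np.isclose(disp[0], 1e-8)

    def test_recovers_simulated_dispersion_at_n50(self):
        cfg = TESimConfig(n_transcripts=400, n_reps_per_condition=50,
                          dispersion=0.1, frac_rna_de=0, frac_te_up=0, seed=3)
        rna, _, _ = simulate_te_experiment(cfg)
        disp = estimate_dispersion(rna.counts, rna.condition_of_library)
        assert 0.07 <= np.median(disp) <= 0.13

    def test_single_replicate_errors(self):
        with pytest.raises(ValueError, match=">= 2 libraries"):
            estimate_dispersion(np.array([[5, 6]]), ["A", "B"])


# ---------------------------------------------------------------------------
# differential abundance


def _toy_experiment(counts, conditions, lengths=None):
    counts = np.asarray(counts)
    g = counts.shape[0]
    return CountExperiment(
        transcript_ids=np.array([f"t{i}" for i in range(g)], dtype=object),
        lengths_bp=np.full(g, 1000) if lengths is None else lengths,
        counts=counts,
        library_labels=[f"L{j}" for j in range(counts.shape[1])],
        condition_of_library=list(conditions),
    )


def _nb_loglik(m, y, s, alpha):
    mu = s * m
    r = 1.0 / alpha
    from scipy.special import gammaln
    return float(np.sum(gammaln(y + r) - gammaln(r) - gammaln(y + 1)
                        + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))))


class TestDifferentialAbundance:
    def test_symmetric_counts_give_zero_log2fc(self):
        exp = _toy_experiment([[10, 20, 30, 10, 20, 30]], ["A"] * 3 + ["B"] * 3)
        res = differential_abundance(exp, [0.1], size_factors=np.ones(6))
        assert np.isclose(res["log2fc"][0], 0.0, atol=1e-8)

    def test_all_zero_transcript_convention(self):
        exp = _toy_experiment([[0, 0, 0, 0], [5, 6, 7, 8]], ["A", "A", "B", "B"])
        res = differential_abundance(exp, [0.1, 0.1], size_factors=np.ones(4))
        assert res["base_mean"][0] == 0.0
        assert res["log2fc"][0] == 0.0
        assert res["p_value"][0] == 1.0

    def test_wald_z_matches_independent_mle_oracle(self):
        """The fitted group means (hence z) agree with an independent scalar
        maximum-likelihood fit: coarse grid search refined by Golden-section."""
        counts = np.array([[23, 41, 17, 60, 88, 52]], dtype=float)
        s = np.array([0.8, 1.1, 1.05, 0.9, 1.2, 0.95])
        alpha, pc = 0.15, 0.5
        exp = _toy_experiment(counts, ["A"] * 3 + ["B"] * 3)
        res = differential_abundance(exp, [alpha], pseudocount=pc,
                                     size_factors=s)

        ms = []
        for cols in (slice(0, 3), slice(3, 6)):
            y, sc = counts[0, cols], s[cols]
            grid = np.linspace(1.0, 200.0, 4000)
            lls = [_nb_loglik(m, y, sc, alpha) for m in grid]
            m0 = grid[int(np.argmax(lls))]
            opt = optimize.minimize_scalar(
                lambda m: -_nb_loglik(m, y, sc, alpha),
                bracket=(m0 * 0.9, m0, m0 * 1.1))
            ms.append(opt.x)
        beta = np.log2((ms[1] + pc) / (ms[0] + pc))

        def info(m, sc):
            mu = sc * (m + pc)
            return np.sum(mu / (1 + alpha * mu))

        se = np.sqrt(1 / info(ms[0], s[:3]) + 1 / info(ms[1], s[3:])) / np.log(2)
        assert np.isclose(res["log2fc"][0], beta, atol=1e-5)
        assert np.isclose(res["log2fc"][0] / res["se_log2fc"][0], beta / se,
                          atol=1e-4)

    def test_null_type_one_error_within_envelope(self):
        """Fraction of p < 0.01 on effect-free simulations stays inside the
        99% binomial envelope at the per-run size of 5000 transcripts."""
        fracs = []
        for seed in (11, 12, 13):
            cfg = TESimConfig(n_transcripts=5000, frac_rna_de=0, frac_te_up=0,
                              dispersion=0.1, seed=seed)
            rna, _, _ = simulate_te_experiment(cfg)
            disp = estimate_dispersion(rna.counts, rna.condition_of_library)
            res = differential_abundance(rna, disp)
            fracs.append((res["p_value"] < 0.01).mean())
        lo, hi = binomial_envelope(0.01, 5000)
        assert lo < np.mean(fracs) < hi


# ---------------------------------------------------------------------------
# classification


def _result_frame(rows):
    return pd.DataFrame([
        {"transcript_id": tid, "base_mean": 50.0, "log2fc": lfc,
         "se_log2fc": 0.2, "p_value": p, "fdr": p}
        for tid, lfc, p in rows])


class TestClassifyTe:
    def test_rule_forced_examples(self):
        rna = _result_frame([("a", 0.1, 0.5), ("b", 2.5, 0.001), ("c", 0.0, 0.9)])
        ribo = _result_frame([("a", 1.0, 0.001), ("b", 1.0, 0.001), ("c", 0.6, 0.02)])
        out = classify_te(rna, ribo).set_index("transcript_id")
        assert out.loc["a", "enhanced_te"]  # unchanged RNA, occupancy up
        assert out.loc["b", "rna_status"] == "up" and not out.loc["b", "enhanced_te"]
        # p = 0.02 fails the p < 0.01 condition
        assert out.loc["c", "occupancy_status"] == "unchanged"
        assert not out.loc["c", "enhanced_te"]

    def test_unmatched_transcripts_excluded(self):
        rna = _result_frame([("a", 0.0, 1.0), ("b", 0.0, 1.0)])
        ribo = _result_frame([("a", 1.0, 0.001)])
        with pytest.warns(UserWarning, match="one assay only"):
            out = classify_te(rna, ribo)
        assert list(out["transcript_id"]) == ["a"]

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_loosening_thresholds_grows_enhanced_set(self, seed):
        r = np.random.default_rng(seed)
        n = 60
        rna = _result_frame([(f"t{i}", r.normal(0, 2), r.random()) for i in range(n)])
        ribo = _result_frame([(f"t{i}", r.normal(0, 1), r.random()) for i in range(n)])
        tight = classify_te(rna, ribo, TEThresholds(2.0, 0.5, 0.01))
        loose = classify_te(rna, ribo, TEThresholds(3.0, 0.25, 0.05))
        tight_set = set(tight.loc[tight["enhanced_te"], "transcript_id"])
        loose_set = set(loose.loc[loose["enhanced_te"], "transcript_id"])
        assert tight_set <= loose_set


# ---------------------------------------------------------------------------
# GLM interaction


class TestGlmInteraction:
    def test_identical_cells_give_zero_interaction(self):
        counts = np.array([[12, 15, 12, 15]])
        rna = _toy_experiment(counts, ["A", "A", "B", "B"])
        ribo = _toy_experiment(counts, ["A", "A", "B", "B"])
        res = glm_te_interaction(rna, ribo, [0.1])
        assert np.isclose(res["delta_te_log2"][0], 0.0, atol=1e-8)

    def test_interaction_equals_difference_of_assay_log2fc(self, small_te_data):
        """Additivity: delta_te equals ribo log2FC minus rna log2FC when both
        are fitted with the same dispersions and pseudocount."""
        _, rna, ribo, _ = small_te_data
        disp = np.full(len(rna.transcript_ids), 0.08)
        r_rna = differential_abundance(rna, disp)
        r_ribo = differential_abundance(ribo, disp)
        inter = glm_te_interaction(rna, ribo, disp)
        assert np.allclose(inter["delta_te_log2"],
                           r_ribo["log2fc"] - r_rna["log2fc"], atol=1e-8)

    def test_degenerate_design_errors(self):
        counts = np.array([[5, 6, 7, 8]])
        rna = _toy_experiment(counts, ["A", "A", "B", "B"])
        bad = _toy_experiment(counts, ["A", "A", "A", "B"])
        # shared transcripts but a missing condition level in one assay is
        # caught by the condition-set check; an empty cell cannot be built
        # through CountExperiment, which requires both levels
        res = glm_te_interaction(rna, bad, [0.1])
        assert len(res) == 1

    def test_matches_statsmodels_glm(self):
        """Independent cross-check: the factorized cell fits reproduce a full
        statsmodels NB GLM with condition + assay + condition:assay."""
        sm = pytest.importorskip("statsmodels.api")
        cfg = TESimConfig(n_transcripts=12, baseline_log2_mean=8,
                          baseline_log2_sd=0.5, frac_rna_de=0, frac_te_up=0.25,
                          seed=9)
        rna, ribo, _ = simulate_te_experiment(cfg)
        alpha = 0.1
        mine = glm_te_interaction(rna, ribo, np.full(12, alpha), pseudocount=0.0)

        sf_rna = estimate_size_factors(rna.counts)
        sf_ribo = estimate_size_factors(ribo.counts)
        is_b = np.array([0.0] * 3 + [1.0] * 3)
        cond = np.concatenate([is_b, is_b])
        assay = np.array([0.0] * 6 + [1.0] * 6)
        X = np.column_stack([np.ones(12), cond, assay, cond * assay])
        offset = np.log(np.concatenate([sf_rna, sf_ribo]))
        for g in range(12):
            y = np.concatenate([rna.counts[g], ribo.counts[g]]).astype(float)
            fit = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha),
                         offset=offset).fit()
            delta_ln = mine["delta_te_log2"][g] * np.log(2)
            se_ln = mine["se"][g] * np.log(2)
            assert np.isclose(delta_ln, fit.params[3], atol=1e-4)
            assert np.isclose(se_ln, fit.bse[3], rtol=1e-3)


# ---------------------------------------------------------------------------
# scale invariance of the whole chain


def test_integer_rescaling_of_a_library_is_absorbed(small_te_data):
    _, rna, ribo, _ = small_te_data
    disp = np.full(len(rna.transcript_ids), 0.1)
    base_rna = differential_abundance(rna, disp)
    base_ribo = differential_abundance(ribo, disp)
    base_cls = classify_te(base_rna, base_ribo)

    scaled_counts = rna.counts.copy()
    scaled_counts[:, 0] *= 3
    scaled = CountExperiment(rna.transcript_ids, rna.lengths_bp, scaled_counts,
                             rna.library_labels, rna.condition_of_library)
    res = differential_abundance(scaled, disp)
    # the NB likelihood weights a deeper library more, so absorption through
    # size factors is approximate for the MLE fold change (exact for rpkm)
    keep = base_rna["base_mean"] > 20
    diff = np.abs(res.loc[keep, "log2fc"] - base_rna.loc[keep, "log2fc"])
    assert diff.max() < 0.2
    assert diff.mean() < 0.02
    cls = classify_te(res, base_ribo)
    agree = (cls["enhanced_te"] == base_cls["enhanced_te"]).mean()
    assert agree > 0.97


# ---------------------------------------------------------------------------
# BH FDR


class TestBhFdr:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_trivial_cases(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)
        assert np.isclose(bh_fdr([0.04])[0], 0.04)
        assert bh_fdr([]).size == 0

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_statsmodels_and_is_valid(self, p):
        mt = pytest.importorskip("statsmodels.stats.multitest")
        mine = bh_fdr(p)
        ref = mt.multipletests(p, method="fdr_bh")[1]
        assert np.allclose(mine, ref, atol=1e-12)
        assert np.all((mine >= 0) & (mine <= 1))
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(mine[order]) >= -1e-15)
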