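"""Constrained mixture estimator, the F-ratio test, and classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

from homoeoscan import alphamodel, pipeline, synthdata
from homoeoscan.alphamodel import (LABEL_AA, LABEL_AT, LABEL_NS, dose_factor,
                                   estimate_alpha, expression_call,
                                   permutation_test_alpha, x_statistic)


def brute_force_alpha(S, A, T):
    """Independent oracle: numeric minimizer of the constrained SSE."""
    S = np.atleast_2d(np.asarray(S, float).T).T

    def sse(alpha):
        pred = alpha * A + (1 - alpha) * T
        return float(np.sum((S - pred[:, None]) ** 2))

    res = optimize.minimize_scalar(sse, bounds=(-60, 60), method="bounded",
                                   options={"xatol": 1e-12})
    return res.x


def random_instance(rng, n=6, r=3):
    T = rng.lognormal(6, 0.5, n)
    A = T * rng.uniform(0.4, 1.0, n)
    alpha = rng.uniform(-0.2, 1.2)
    S = alpha * A + (1 - alpha) * T
    S = S[:, None] + rng.normal(0, 20.0, (n, r))
    return S, A, T


class TestEstimateAlpha:
    def test_pure_aa_signal_gives_one(self):
        A = np.array([50.0, 80.0, 120.0])
        T = np.array([100.0, 160.0, 240.0])
        S = np.tile(A[:, None], (1, 3))
        assert estimate_alpha(S, A, T) == pytest.approx(1.0)

    def test_pure_at_signal_gives_zero(self):
        A = np.array([50.0, 80.0, 120.0])
        T = np.array([100.0, 160.0, 240.0])
        S = np.tile(T[:, None], (1, 3))
        assert estimate_alpha(S, A, T) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_minimizer(self, rng):
        for _ in range(100):
            S, A, T = random_instance(rng)
            assert estimate_alpha(S, A, T) == pytest.approx(
                brute_force_alpha(S, A, T), abs=1e-8)

    def test_unidentifiable_rejected(self):
        A = T = np.array([10.0, 20.0, 30.0])
        with pytest.raises(ValueError, match="unidentifiable"):
            estimate_alpha(T, A, T)

    @settings(deadline=None, max_examples=40)
    @given(st.integers(0, 10_000), st.floats(0.1, 10.0))
    def test_joint_scale_invariance(self, seed, c):
        """Multiplying S, A, T jointly by c > 0 leaves alpha and X unchanged."""
        rng = np.random.default_rng(seed)
        S, A, T = random_instance(rng)
        F, _, _ = random_instance(rng)
        F = S + rng.normal(0, 5.0, S.shape)
        a1, a2 = estimate_alpha(S, A, T), estimate_alpha(F, A, T)
        X, _, _, _ = x_statistic(S, F, A, T, a1, a2)
        a1c = estimate_alpha(c * S, c * A, c * T)
        Xc, _, _, _ = x_statistic(c * S, c * F, c * A, c * T, a1c,
                                  estimate_alpha(c * F, c * A, c * T))
        assert a1c == pytest.approx(a1, rel=1e-9)
        assert Xc == pytest.approx(X, rel=1e-6)

    def test_swapping_parents_maps_alpha_to_one_minus(self, rng):
        S, A, T = random_instance(rng)
        assert estimate_alpha(S, T, A) == pytest.approx(
            1.0 - estimate_alpha(S, A, T), rel=1e-9)


class TestDoseFactor:
    def test_balanced_gene_unit_dose(self, rng):
        T = rng.lognormal(6, 0.5, 12)
        A = T * rng.uniform(0.5, 1.0, 12)
        S = np.tile(((A + T) / 2)[:, None], (1, 3))
        assert dose_factor(S, A, T) == pytest.approx(1.0)

    def test_deleted_gene_half_dose(self, rng):
        T = rng.lognormal(6, 0.5, 12)
        A = T * rng.uniform(0.5, 1.0, 12)
        S = np.tile((T / 2)[:, None], (1, 3))
        assert dose_factor(S, A, T) == pytest.approx(0.5)


class TestXStatistic:
    def test_equal_alphas_give_zero(self, rng):
        S, A, T = random_instance(rng)
        X, p, df2, _ = x_statistic(S, S, A, T, 0.5, 0.5)
        assert X == 0.0 and p == 1.0

    def test_printed_degrees_of_freedom(self, rng):
        S, A, T = random_instance(rng, n=5, r=3)
        _, _, df2, _ = x_statistic(S, S, A, T, 0.4, 0.5)
        assert df2 == 6 * 5 - 1

    def test_termwise_oracle(self, rng):
        """Re-derive numerator and denominator sums term by term."""
        S, A, T = random_instance(rng, n=3, r=3)
        F, _, _ = random_instance(rng, n=3, r=3)
        F = 0.5 * A[:, None] + 0.5 * T[:, None] + rng.normal(0, 10, (3, 3))
        a1, a2 = estimate_alpha(S, A, T), estimate_alpha(F, A, T)
        X, p, df2, _ = x_statistic(S, F, A, T, a1, a2)
        num = 0.0
        rss = 0.0
        for i in range(3):
            for j in range(3):
                num += (A[i] - T[i]) ** 2
                rss += (S[i, j] - T[i] - a1 * (A[i] - T[i])) ** 2
                rss += (F[i, j] - T[i] - a2 * (A[i] - T[i])) ** 2
        X_ref = 0.5 * (a1 - a2) ** 2 * num / (rss / (6 * 3 - 1))
        assert X == pytest.approx(X_ref, rel=1e-12)

    def test_exchanging_samples_leaves_x_invariant(self, rng):
        S, A, T = random_instance(rng)
        F = S + rng.normal(0, 5.0, S.shape)
        a1, a2 = estimate_alpha(S, A, T), estimate_alpha(F, A, T)
        X1 = x_statistic(S, F, A, T, a1, a2)[0]
        X2 = x_statistic(F, S, A, T, a2, a1)[0]
        assert X1 == pytest.approx(X2, rel=1e-12)

    def test_null_type_one_error_near_nominal(self):
        """Model-level null simulation: rejection at 0.05 stays near 0.05
        (slightly above, reflecting the printed 6n-1 denominator df)."""
        ps = []
        for S, F, A, T in synthdata.simulate_null_model_genes(
                2000, 5, 3, seed=77):
            a1, a2 = estimate_alpha(S, A, T), estimate_alpha(F, A, T)
            ps.append(x_statistic(S, F, A, T, a1, a2)[1])
        rate = np.mean(np.array(ps) < 0.05)
        assert 0.035 <= rate <= 0.07

    def test_permutation_cross_check_agrees(self, rng):
        S, A, T = random_instance(rng, n=8)
        F = 0.5 * A[:, None] + 0.5 * T[:, None] + rng.normal(0, 15, (8, 3))
        p_perm = permutation_test_alpha(S, F, A, T, n_perm=400, seed=5)
        a1, a2 = estimate_alpha(S, A, T), estimate_alpha(F, A, T)
        p_f = x_statistic(S, F, A, T, a1, a2)[1]
        # permutation of 3v3 replicate columns has coarse resolution; only
        # agreement in broad significance is expected
        assert (p_perm < 0.2) == (p_f < 0.05) or p_f > 0.01


class TestClassification:
    def test_identical_hybrid_draws_not_significant(self):
        rng = np.random.default_rng(0)
        T = rng.lognormal(8, 0.5, 10)
        A = T * rng.uniform(0.4, 0.9, 10)
        S = ((A + T) / 2)[:, None] + rng.normal(0, 10, (10, 3))
        per_gene = {"g": {"A_scaled": A, "T": T, "S": S, "F": S.copy(),
                          "df_mask": np.ones(10, dtype=bool)}}
        out, _ = alphamodel.classify_retention(per_gene)
        assert out["label"].iloc[0] == LABEL_NS
        assert out["delta_alpha"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_retention_recovery_against_truth(self, deletion_truth,
                                              retention_run):
        result, _ = retention_run
        m = result.merge(deletion_truth, left_on="gene_id", right_index=True)
        dele = m[m.retention_state != "both"]
        correct = (((dele.retention_state == "At_deleted")
                    & (dele.label == LABEL_AA))
                   | ((dele.retention_state == "Aa_deleted")
                      & (dele.label == LABEL_AT)))
        assert correct.mean() >= 0.8
        called = (m.label != LABEL_NS).sum()
        wrong = ((m.label != LABEL_NS)
                 & ~(((m.retention_state == "At_deleted") & (m.label == LABEL_AA))
                     | ((m.retention_state == "Aa_deleted")
                        & (m.label == LABEL_AT))))
        assert wrong.sum() / max(called, 1) <= 0.12  # small-cohort FDP bound

    def test_null_cohort_delta_alpha_unbiased(self, deletion_truth,
                                              retention_run):
        result, _ = retention_run
        m = result.merge(deletion_truth, left_on="gene_id", right_index=True)
        nulls = m[m.retention_state == "both"]["delta_alpha"]
        assert abs(nulls.mean()) < 3 * nulls.std() / np.sqrt(len(nulls))

    def test_expression_alpha_tracks_truth(self, deletion_truth,
                                           expression_run):
        result, _ = expression_run
        m = result.merge(deletion_truth, left_on="gene_id", right_index=True)
        m = m[m.retention_state == "both"]
        rho = stats.spearmanr(m["alpha1"], m["expression_alpha_true"]).statistic
        assert rho >= 0.9

    def test_deleted_gene_expression_follows_surviving_homoeolog(
            self, deletion_truth, expression_run):
        """A gene that lost its reference-parent copy can only transcribe
        the other homoeolog: RNA alpha and DNA alpha both approach 1."""
        result, _ = expression_run
        m = result.merge(deletion_truth, left_on="gene_id", right_index=True)
        at_del = m[m.retention_state == "At_deleted"]
        if len(at_del):
            assert at_del["alpha1"].median() > 0.7
            assert at_del["alpha2"].median() > 0.7


class TestExpressionCall:
    def test_gene_at_background_not_expressed(self, rng):
        import pandas as pd
        inter = rng.lognormal(4, 0.3, 500)
        med = pd.Series({"g": float(np.median(inter))})
        assert not expression_call(med, inter, percentile=95.0)["g"]

    def test_silent_fraction_recovered(self):
        cfg = synthdata.GeneratorConfig(n_genes=300, seed=17,
                                        expressed_fraction=0.5)
        bundle = synthdata.simulate(cfg)
        from homoeoscan import arrayio
        pre = arrayio.preprocess(arrayio.ProbeIntensityTable(bundle.probes),
                                 background="none",
                                 groups=arrayio.PER_GENOTYPE_GROUPS)
        bundles = pipeline.assemble_genes(pre)
        import pandas as pd
        med = pd.Series({g: float(np.median(d["rna"]))
                         for g, d in bundles.genes.items()})
        called = expression_call(med, bundles.intergenic_rna)
        assert abs(called.mean() - 0.5) < 0.05

    def test_raising_percentile_monotone(self, rng):
        import pandas as pd
        inter = rng.lognormal(4, 0.3, 500)
        med = pd.Series(rng.lognormal(4.5, 0.5, 100))
        counts = [expression_call(med, inter, percentile=q).sum()
                  for q in (80, 90, 95, 99)]
        assert counts == sorted(counts, reverse=True)

    def test_no_intergenic_needs_fallback(self, rng):
        import pandas as pd
        med = pd.Series({"g": 100.0})
        with pytest.raises(ValueError, match="fallback"):
            expression_call(med, np.empty(0))
        assert expression_call(med, np.empty(0), fallback_threshold=50.0)["g"]
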