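"""The four stability algorithms against hand computations and brute-force oracles."""
import numpy as np
import pandas as pd
import pytest

from refstab import (
    CorrectedCqMatrix,
    SimConfig,
    ValidationError,
    bestkeeper,
    delta_ct,
    genorm,
    normfinder,
    simulate_matrix,
)

from .oracles import oracle_delta_ct, oracle_genorm_m, oracle_normfinder_var


def as_corrected(df: pd.DataFrame) -> CorrectedCqMatrix:
    return CorrectedCqMatrix(df, df.min(axis=1))


def random_q(rng, k=6, n=10):
    genes = [f"g{i}" for i in range(k)]
    samples = [f"s{j}" for j in range(n)]
    return pd.DataFrame(
        np.exp2(rng.normal(0, 1, size=(k, n))), index=genes, columns=samples
    )


# ---------------------------------------------------------------------------
# geNorm
# ---------------------------------------------------------------------------

class TestGenorm:
    def test_toy_hand_computation(self, toy_quantities):
        res = genorm(toy_quantities)
        # log2(A/C) over samples = 0,-1,-2,-3 -> SD 1.29099; A-B ratio constant
        assert res.m_values["A"] == pytest.approx(0.5 * (0 + 1.29099), abs=1e-4)
        assert res.m_values["B"] == pytest.approx(res.m_values["A"])
        assert res.m_values["C"] == pytest.approx(1.29099, abs=1e-4)
        assert res.exclusion_order[0][0] == "C"
        assert res.final_pair == ("A", "B")
        # final pair reports its mutual pairwise SD (0 here)
        assert res.stepwise_m["A"] == pytest.approx(0.0, abs=1e-12)

    def test_duplicate_gene_zero_pairwise_sd(self):
        rng = np.random.default_rng(1)
        q = random_q(rng, k=4)
        q.loc["dup"] = q.loc["g0"]
        res = genorm(q)
        assert set(res.final_pair) == {"dup", "g0"}
        assert res.stepwise_m["dup"] == pytest.approx(0.0, abs=1e-12)

    def test_two_genes_share_single_pairwise_sd(self):
        rng = np.random.default_rng(2)
        q = random_q(rng, k=2)
        res = genorm(q)
        expected = np.std(np.log2(q.iloc[0] / q.iloc[1]), ddof=1)
        assert res.stepwise_m.tolist() == pytest.approx([expected, expected])
        assert res.warning is not None

    def test_full_panel_m_matches_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            q = random_q(rng)
            res = genorm(q)
            oracle = oracle_genorm_m(q)
            assert np.allclose(res.m_values.sort_index(), oracle.sort_index(), atol=1e-10)

    def test_exclusion_covers_all_genes(self):
        rng = np.random.default_rng(4)
        q = random_q(rng, k=7)
        res = genorm(q)
        assert len(res.exclusion_order) == 7
        assert len(res.final_pair) == 2
        assert set(res.stepwise_m.index) == set(q.index)

    def test_v_values_and_optimal_n(self):
        rng = np.random.default_rng(5)
        q = random_q(rng, k=6, n=30)
        res = genorm(q, v_cutoff=0.15)
        assert [n for n, _ in res.v_values] == [2, 3, 4, 5]
        if res.optimal_n is not None:
            assert dict(res.v_values)[res.optimal_n] < 0.15
            for n, v in res.v_values:
                if n < res.optimal_n:
                    assert v >= 0.15

    def test_nonpositive_quantity_rejected(self, toy_quantities):
        bad = toy_quantities.copy()
        bad.iloc[0, 0] = 0.0
        with pytest.raises(ValidationError):
            genorm(bad)


# ---------------------------------------------------------------------------
# NormFinder
# ---------------------------------------------------------------------------

class TestNormFinder:
    def test_additive_data_gives_zero_stability(self):
        alpha = np.array([1.0, -2.0, 0.5, 3.0])
        beta = np.array([0.3, -0.1, 0.0, 1.2, -0.7])
        y = pd.DataFrame(
            alpha[:, None] + beta[None, :],
            index=list("abcd"),
            columns=[f"s{j}" for j in range(5)],
        )
        model = normfinder(y)
        assert np.allclose(model.residuals.to_numpy(), 0.0, atol=1e-12)
        assert np.allclose(model.stability.to_numpy(), 0.0, atol=1e-12)

    def test_integer_toy_matches_closed_form(self):
        y = pd.DataFrame(
            [[1.0, 2.0, 6.0], [3.0, 5.0, 4.0], [2.0, 2.0, 2.0]],
            index=list("abc"),
            columns=["s1", "s2", "s3"],
        )
        model = normfinder(y)
        oracle = oracle_normfinder_var(y)
        assert np.allclose(model.variance, oracle, atol=1e-12)
        assert np.allclose(
            model.stability, np.sqrt(np.clip(oracle, 0, None)), atol=1e-12
        )

    def test_matches_oracle_on_random_matrices(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            y = pd.DataFrame(
                rng.normal(0, 1, size=(6, 10)),
                index=[f"g{i}" for i in range(6)],
                columns=[f"s{j}" for j in range(10)],
            )
            assert np.allclose(
                normfinder(y).variance, oracle_normfinder_var(y), atol=1e-10
            )

    def test_residuals_double_centered(self):
        rng = np.random.default_rng(7)
        y = pd.DataFrame(rng.normal(size=(5, 8)))
        model = normfinder(y)
        assert np.allclose(model.residuals.sum(axis=0), 0.0, atol=1e-10)
        assert np.allclose(model.residuals.sum(axis=1), 0.0, atol=1e-10)

    def test_estimator_unbiased(self):
        """Mean of the variance estimate matches truth to Monte-Carlo error.

        Model draws: y_ij = beta_j + eps_ij with per-gene sigma; over 500
        replicates each gene's mean estimate must sit within 3 standard
        errors of its true variance.
        """
        rng = np.random.default_rng(123)
        k, n = 6, 200
        sigma = np.linspace(0.1, 0.6, k)
        reps = 500
        estimates = np.empty((reps, k))
        for r in range(reps):
            beta = rng.normal(0, 1, size=n)
            y = beta[None, :] + rng.normal(0, 1, size=(k, n)) * sigma[:, None]
            estimates[r] = normfinder(pd.DataFrame(y)).variance.to_numpy()
        mean_est = estimates.mean(axis=0)
        se = estimates.std(axis=0, ddof=1) / np.sqrt(reps)
        assert (np.abs(mean_est - sigma**2) < 3 * se + 1e-12).all()

    def test_two_genes_rejected(self):
        y = pd.DataFrame(np.ones((2, 5)))
        with pytest.raises(ValidationError):
            normfinder(y)

    def test_constant_matrix_all_zero(self):
        y = pd.DataFrame(np.full((4, 6), 3.0))
        assert np.allclose(normfinder(y).stability, 0.0)


# ---------------------------------------------------------------------------
# BestKeeper
# ---------------------------------------------------------------------------

class TestBestKeeper:
    def test_hand_computed_sd_and_mad(self):
        cq = pd.DataFrame([[20.0, 21.0, 22.0]], index=["g"], columns=["a", "b", "c"])
        res = bestkeeper(as_corrected(cq))
        assert res.per_gene.loc["g", "sd"] == pytest.approx(1.0)
        assert res.per_gene.loc["g", "mad"] == pytest.approx(2.0 / 3.0)

    def test_constant_gene_zero_dispersion(self):
        cq = pd.DataFrame([[25.0] * 5], index=["g"], columns=list("abcde"))
        res = bestkeeper(as_corrected(cq))
        assert res.per_gene.loc["g", "sd"] == 0.0
        assert res.per_gene.loc["g", "mad"] == 0.0

    @pytest.mark.parametrize("sd, stable", [(0.783, True), (1.2, False)])
    def test_stable_flag_threshold(self, sd, stable):
        n = 201
        x = np.zeros(n)
        x[: n // 2] = 1.0
        x = 25.0 + (x - x.mean()) / x.std(ddof=1) * sd  # exact sample SD
        cq = pd.DataFrame([x], index=["g"])
        res = bestkeeper(as_corrected(cq))
        assert res.per_gene.loc["g", "sd"] == pytest.approx(sd)
        assert bool(res.per_gene.loc["g", "stable_flag"]) is stable

    def test_mad_dispersion_choice_changes_score(self):
        rng = np.random.default_rng(10)
        cq = pd.DataFrame(rng.normal(25, 1, size=(3, 12)))
        sd_scores = bestkeeper(as_corrected(cq), dispersion="sd").scores()
        mad_scores = bestkeeper(as_corrected(cq), dispersion="mad").scores()
        assert not np.allclose(sd_scores.scores, mad_scores.scores)

    def test_index_correlation_option(self):
        rng = np.random.default_rng(11)
        base = rng.normal(0, 1, size=20)
        cq = pd.DataFrame(
            25.0 + np.vstack([base + rng.normal(0, 0.05, 20) for _ in range(3)]),
            index=list("abc"),
        )
        res = bestkeeper(as_corrected(cq), with_index=True)
        assert res.index is not None
        assert (res.index_correlation["pearson_r"] > 0.9).all()


# ---------------------------------------------------------------------------
# comparative delta-Ct
# ---------------------------------------------------------------------------

class TestDeltaCt:
    def test_hand_computed_scores(self):
        cq = pd.DataFrame(
            [[20.0, 21.0, 22.0], [20.0, 21.0, 22.0], [20.0, 20.0, 20.0]],
            index=["X", "Y", "Z"],
        )
        scores = delta_ct(as_corrected(cq)).scores
        assert scores["X"] == pytest.approx(0.5)  # mean of SD 0 (vs Y) and SD 1 (vs Z)
        assert scores["Z"] == pytest.approx(1.0)

    def test_duplicated_pair_contributes_zero(self):
        rng = np.random.default_rng(12)
        cq = pd.DataFrame(rng.normal(25, 1, size=(3, 8)), index=["a", "b", "c"])
        cq.loc["b"] = cq.loc["a"]
        res = delta_ct(as_corrected(cq))
        assert res.diagnostics["pairwise_sd"].loc["a", "b"] == pytest.approx(0.0)

    def test_matches_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            cq = pd.DataFrame(
                rng.uniform(18, 32, size=(6, 10)),
                index=[f"g{i}" for i in range(6)],
            )
            assert np.allclose(
                delta_ct(as_corrected(cq)).scores, oracle_delta_ct(cq), atol=1e-10
            )


# ---------------------------------------------------------------------------
# cross-algorithm invariances
# ---------------------------------------------------------------------------

class TestSampleOffsetInvariance:
    def test_offsets_cancel_except_bestkeeper(self):
        """Per-sample constant shifts leave geNorm, delta-Ct and NormFinder
        scores unchanged but move BestKeeper's SD."""
        rng = np.random.default_rng(14)
        cq = pd.DataFrame(
            rng.uniform(20, 30, size=(5, 12)), index=[f"g{i}" for i in range(5)]
        )
        offsets = rng.normal(0, 2.0, size=12)
        shifted = cq + offsets[None, :]

        q, q_shift = np.exp2(-cq), np.exp2(-shifted)
        assert np.allclose(
            genorm(q).stepwise_m, genorm(q_shift).stepwise_m, atol=1e-9
        )
        assert np.allclose(
            delta_ct(as_corrected(cq)).scores,
            delta_ct(as_corrected(shifted)).scores,
            atol=1e-9,
        )
        assert np.allclose(
            normfinder(cq).stability, normfinder(shifted).stability, atol=1e-9
        )
        bk = bestkeeper(as_corrected(cq)).per_gene["sd"]
        bk_shift = bestkeeper(as_corrected(shifted)).per_gene["sd"]
        assert not np.allclose(bk, bk_shift, atol=1e-6)


class TestMonotoneDiscrimination:
    def test_more_noise_means_worse_scores_on_average(self):
        """Raising one gene's independent noise SD raises its expected
        delta-Ct score and NormFinder stability (200 seeds per level)."""
        levels = (0.2, 0.4, 0.6)
        dct_means, nf_means = [], []
        for sd in levels:
            noise = np.full(6, 0.2)
            noise[0] = sd
            dct_vals, nf_vals = [], []
            for seed in range(200):
                cfg = SimConfig(
                    n_genes=6,
                    n_samples=30,
                    n_animals=3,
                    gene_noise_sd=noise,
                    replicate_sd=0.0,
                    n_replicates=1,
                    seed=seed,
                )
                matrix, _ = simulate_matrix(cfg)
                corrected = as_corrected(matrix.values)
                dct_vals.append(delta_ct(corrected).scores.iloc[0])
                nf_vals.append(normfinder(matrix.values).stability.iloc[0])
            dct_means.append(np.mean(dct_vals))
            nf_means.append(np.mean(nf_vals))
        assert dct_means[0] < dct_means[1] < dct_means[2]
        assert nf_means[0] < nf_means[1] < nf_means[2]
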