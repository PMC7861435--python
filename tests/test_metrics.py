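"""Evaluation-suite metrics against brute-force oracles and exact identities."""

from itertools import combinations, product

import numpy as np
import pytest

from haplogen.haplotypes import HaplotypeMatrix
from haplogen.metrics import (
    FrequencyTables,
    adversarial_accuracy,
    allele_freq_comparison,
    evaluate_pair,
    fixed_site_report,
    joint_pca,
    ld_decay,
    ld_matrix,
    nearest_neighbor_profile,
    pairwise_distance_distributions,
    privacy_loss,
    spike_in_sensitivity,
    three_point_corr,
    wasserstein_2d,
)


def brute_force_r2(x: np.ndarray, y: np.ndarray) -> float:
    """r² from the 2x2 haplotype table: D² / (pA qA pB qB)."""
    pa, pb = x.mean(), y.mean()
    D = (x * y).mean() - pa * pb
    return D * D / (pa * (1 - pa) * pb * (1 - pb))


def brute_force_c3(X, i, j, k, a, b, c) -> float:
    """Direct evaluation of the connected 3-point moment by counting."""
    n = X.shape[0]
    fi = np.sum(X[:, i] == a) / n
    fj = np.sum(X[:, j] == b) / n
    fk = np.sum(X[:, k] == c) / n
    fij = np.sum((X[:, i] == a) & (X[:, j] == b)) / n
    fik = np.sum((X[:, i] == a) & (X[:, k] == c)) / n
    fjk = np.sum((X[:, j] == b) & (X[:, k] == c)) / n
    fijk = np.sum((X[:, i] == a) & (X[:, j] == b) & (X[:, k] == c)) / n
    return fijk - fij * fk - fik * fj - fjk * fi + 2 * fi * fj * fk


class TestAlleleFreq:
    def test_identical_datasets_correlate_perfectly(self, structured_data):
        _, r = allele_freq_comparison(structured_data, structured_data)
        assert r == pytest.approx(1.0)

    def test_toy_frequencies_match_hand_counts(self, toy_matrix):
        pairs, _ = allele_freq_comparison(toy_matrix, toy_matrix)
        assert np.allclose(pairs[:, 0], [0.5, 1.0, 0.5])

    def test_permuted_distinct_columns_below_one(self, rng):
        values = (rng.random((50, 6)) < np.linspace(0.1, 0.9, 6)).astype(np.int8)
        real = HaplotypeMatrix(values=values)
        art = HaplotypeMatrix(values=values[:, ::-1])
        _, r = allele_freq_comparison(real, art)
        assert r < 1.0

    def test_zero_variance_yields_nan_with_warning(self):
        flat = HaplotypeMatrix(values=np.ones((10, 3), dtype=np.int8))
        with pytest.warns(UserWarning, match="zero-variance"):
            _, r = allele_freq_comparison(flat, flat)
        assert np.isnan(r)


class TestLD:
    def test_duplicated_column_r2_is_one(self, rng):
        x = rng.integers(2, size=50)
        m = HaplotypeMatrix(values=np.column_stack([x, x, rng.integers(2, size=50)]))
        assert ld_matrix(m)[0, 1] == pytest.approx(1.0)

    def test_matches_brute_force_on_small_matrices(self, rng):
        values = rng.integers(2, size=(10, 6))
        # keep all sites segregating
        values[0] = 0
        values[1] = 1
        r2 = ld_matrix(HaplotypeMatrix(values=values))
        for i, j in combinations(range(6), 2):
            assert r2[i, j] == pytest.approx(
                brute_force_r2(values[:, i].astype(float), values[:, j].astype(float))
            )

    def test_independent_sites_near_null_expectation(self, rng):
        n = 10_000
        m = HaplotypeMatrix(values=(rng.random((n, 30)) < 0.5).astype(np.int8))
        r2 = ld_matrix(m)
        off = r2[np.triu_indices(30, k=1)]
        # E[r2] under independence ~ 1/(n-1)
        assert np.nanmean(off) < 5.0 / (n - 1)

    def test_fixed_sites_removed_from_decay_curve(self, rng):
        values = rng.integers(2, size=(40, 10))
        values[0], values[1] = 0, 1  # keep sites 0..9 segregating in real
        art = values.copy()
        art[:, 3] = 0  # fixed in artificial only
        real_m, art_m = HaplotypeMatrix(values=values), HaplotypeMatrix(values=art)
        decay = ld_decay(real_m, art_m, n_bins=5)
        assert decay["n_sites"] == 9  # joint filter removed the fixed site
        assert np.nansum(np.isfinite(decay["real"])) > 0

    def test_all_fixed_errors(self):
        flat = HaplotypeMatrix(values=np.ones((5, 4), dtype=np.int8))
        with pytest.raises(ValueError):
            ld_decay(flat, flat)

    def test_bp_distance_used_when_positions_present(self, rng):
        values = rng.integers(2, size=(40, 10))
        values[0], values[1] = 0, 1
        m = HaplotypeMatrix(values=values, positions=np.arange(10) * 1000 + 1)
        decay = ld_decay(m, m, n_bins=3)
        assert decay["bin_centers"].max() > 100  # bp scale, not index scale


class TestThreePoint:
    def test_fixed_site_gives_exact_zero(self):
        values = np.array([[1, 0, 1], [1, 1, 1], [1, 1, 0], [1, 0, 0]])
        ft = FrequencyTables(HaplotypeMatrix(values=values))
        for b, c in product((0, 1), repeat=2):
            assert ft.c3(0, 1, 2, 1, b, c) == pytest.approx(0.0, abs=1e-15)

    def test_toy_matches_brute_force_to_machine_precision(self, rng):
        values = rng.integers(2, size=(4, 3))
        ft = FrequencyTables(HaplotypeMatrix(values=values))
        for a, b, c in product((0, 1), repeat=3):
            assert ft.c3(0, 1, 2, a, b, c) == pytest.approx(
                brute_force_c3(values, 0, 1, 2, a, b, c), abs=1e-12
            )

    def test_allele_relabel_invariance(self, rng):
        """c is invariant under jointly flipping 0<->1 with flipped arguments."""
        values = rng.integers(2, size=(12, 3))
        ft = FrequencyTables(HaplotypeMatrix(values=values))
        ft_flip = FrequencyTables(HaplotypeMatrix(values=1 - values))
        for a, b, c in product((0, 1), repeat=3):
            assert ft.c3(0, 1, 2, a, b, c) == pytest.approx(
                ft_flip.c3(0, 1, 2, 1 - a, 1 - b, 1 - c), abs=1e-12
            )

    def test_independent_sites_mean_near_zero(self, rng):
        m = HaplotypeMatrix(values=(rng.random((4000, 40)) < 0.5).astype(np.int8))
        out = three_point_corr(m, separations=(1, 4), n_triplets=500, seed=0)
        for sep in (1, 4):
            assert abs(out[sep]["mean"]) < 0.002

    def test_vectorized_sampler_matches_frequency_tables(self, structured_data):
        out = three_point_corr(structured_data, separations=(2,), n_triplets=50,
                               seed=3)
        assert out[2]["values"].shape == (50,)
        # spot-check determinism
        again = three_point_corr(structured_data, separations=(2,), n_triplets=50,
                                 seed=3)
        assert np.array_equal(out[2]["values"], again[2]["values"])

    def test_oversized_separation_skipped_with_warning(self, toy_matrix):
        with pytest.warns(UserWarning, match="skipped"):
            out = three_point_corr(toy_matrix, separations=(64,), n_triplets=10)
        assert out == {}


class TestDistances:
    def test_between_distribution_counts_self_matches(self, structured_data):
        sub = structured_data.subset_rows(range(30))
        out = pairwise_distance_distributions(sub, sub)
        assert out["n_identical_pairs"] >= 30
        assert out["wasserstein_within"] == pytest.approx(0.0)

    def test_hamming_counts_differing_sites(self):
        real = HaplotypeMatrix(values=np.array([[0, 0, 0, 0], [1, 1, 1, 0]]))
        art = HaplotypeMatrix(values=np.array([[0, 0, 0, 0], [0, 1, 0, 0]]))
        out = pairwise_distance_distributions(real, art)
        assert list(out["within_real"]) == [3.0]
        assert list(out["within_art"]) == [1.0]
        assert out["n_identical_pairs"] == 1

    def test_nearest_neighbor_exact_copy_gives_zero_dts(self, structured_data):
        sub = structured_data.subset_rows(range(25))
        nd = nearest_neighbor_profile(sub, sub)
        assert np.all(nd.d_TS == 0)
        assert np.all(nd.d_ST == 0)

    def test_duplicated_real_row_has_zero_dtt(self, rng):
        values = rng.integers(2, size=(10, 20))
        values[7] = values[2]
        nd = nearest_neighbor_profile(
            HaplotypeMatrix(values=values),
            HaplotypeMatrix(values=rng.integers(2, size=(10, 20))),
        )
        assert nd.d_TT[2] == 0 and nd.d_TT[7] == 0

    def test_min_distance_concentrates_near_monte_carlo_expectation(self, rng):
        """d_TS for independent Bernoulli(p) sets matches a direct
        Monte-Carlo simulation of the same minimum-distance law."""
        p, L, n = 0.3, 60, 80
        real = HaplotypeMatrix(values=(rng.random((n, L)) < p).astype(np.int8))
        art = HaplotypeMatrix(values=(rng.random((n, L)) < p).astype(np.int8))
        observed = nearest_neighbor_profile(real, art).d_TS.mean()
        sims = []
        for _ in range(30):
            d = (rng.random((n, L)) < p).astype(int)
            e = (rng.random((n, L)) < p).astype(int)
            D = np.abs(d[:, None, :] - e[None, :, :]).sum(-1)
            sims.append(D.min(1).mean())
        assert abs(observed - np.mean(sims)) < 4 * np.std(sims)


class TestAdversarialAccuracy:
    def test_exact_copy_forces_all_zero(self, rng):
        values = rng.integers(2, size=(20, 30))
        m = HaplotypeMatrix(values=values)
        aa_truth, aa_syn, aa_ts = adversarial_accuracy(
            nearest_neighbor_profile(m, m)
        )
        assert (aa_truth, aa_syn, aa_ts) == (0.0, 0.0, 0.0)

    def test_displaced_set_forces_all_one(self, rng):
        real = HaplotypeMatrix(values=np.zeros((15, 40), dtype=np.int8))
        art = HaplotypeMatrix(values=np.ones((15, 40), dtype=np.int8))
        # tight real cluster, artificial far away
        real_v = real.values.copy()
        real_v[:, 0] = rng.integers(2, size=15)  # break exact ties within real
        aa = adversarial_accuracy(
            nearest_neighbor_profile(HaplotypeMatrix(values=real_v), art)
        )
        assert aa == (1.0, 1.0, 1.0)

    def test_aats_is_mean_of_components(self, structured_data, rng):
        art = HaplotypeMatrix(values=rng.integers(2, size=(100, 100)))
        sub = structured_data.subset_rows(range(100))
        aa_truth, aa_syn, aa_ts = adversarial_accuracy(
            nearest_neighbor_profile(sub, art)
        )
        assert aa_ts == pytest.approx(0.5 * (aa_truth + aa_syn))
        assert 0.0 <= aa_ts <= 1.0

    def test_null_calibration_mean_half_on_wide_panel(self):
        """Independent same-distribution samples score near the optimum 0.5
        on a wide panel, where integer-distance ties are rare.

        With strict inequalities a tie contributes 0, which biases the null
        mean down by half the tie rate; on an 805-SNP panel nearest-
        neighbour distance ties are rare enough for calibration to hold."""
        scores = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            f = r.uniform(0.05, 0.95, 805)
            a = HaplotypeMatrix(values=(r.random((100, 805)) < f).astype(np.int8))
            b = HaplotypeMatrix(values=(r.random((100, 805)) < f).astype(np.int8))
            scores.append(adversarial_accuracy(nearest_neighbor_profile(a, b))[2])
        assert abs(np.mean(scores) - 0.5) < 0.05

    def test_null_bias_equals_half_tie_rate(self):
        """On narrow panels the null AA_TS sits below 0.5 by exactly half
        the nearest-neighbour tie rate (the strict > counts ties as 0)."""
        gaps = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            f = r.uniform(0.05, 0.95, 100)
            a = HaplotypeMatrix(values=(r.random((200, 100)) < f).astype(np.int8))
            b = HaplotypeMatrix(values=(r.random((200, 100)) < f).astype(np.int8))
            nd = nearest_neighbor_profile(a, b)
            aa_ts = adversarial_accuracy(nd)[2]
            tie_rate = 0.5 * (np.mean(nd.d_TS == nd.d_TT)
                              + np.mean(nd.d_ST == nd.d_SS))
            gaps.append((0.5 - aa_ts) - 0.5 * tie_rate)
        assert abs(np.mean(gaps)) < 0.02

    def test_too_small_sets_rejected(self):
        one = HaplotypeMatrix(values=np.zeros((1, 5), dtype=np.int8))
        with pytest.raises(ValueError):
            adversarial_accuracy(nearest_neighbor_profile(one, one))


class TestPrivacy:
    def test_copy_of_train_leaks_half(self, rng):
        # wide panel keeps the test-side AA_TS near its tie-free null 0.5
        train = HaplotypeMatrix(values=rng.integers(2, size=(100, 805)))
        test = HaplotypeMatrix(values=rng.integers(2, size=(100, 805)))
        loss = privacy_loss(train, test, train)
        assert loss == pytest.approx(0.5, abs=0.06)

    def test_independent_art_near_zero(self):
        losses = []
        for seed in range(50):
            r = np.random.default_rng(1000 + seed)
            train = HaplotypeMatrix(values=r.integers(2, size=(80, 60)))
            test = HaplotypeMatrix(values=r.integers(2, size=(80, 60)))
            art = HaplotypeMatrix(values=r.integers(2, size=(80, 60)))
            losses.append(privacy_loss(train, test, art))
        assert abs(np.mean(losses)) < 0.05

    def test_antisymmetry(self, rng):
        train = HaplotypeMatrix(values=rng.integers(2, size=(40, 30)))
        test = HaplotypeMatrix(values=rng.integers(2, size=(40, 30)))
        art = HaplotypeMatrix(values=rng.integers(2, size=(40, 30)))
        assert privacy_loss(train, test, art) == pytest.approx(
            -privacy_loss(test, train, art)
        )

    def test_spike_in_zero_equals_unspiked_and_full_copy_case(self, rng):
        train = HaplotypeMatrix(values=rng.integers(2, size=(50, 40)))
        test = HaplotypeMatrix(values=rng.integers(2, size=(50, 40)))
        art = HaplotypeMatrix(values=rng.integers(2, size=(50, 40)))
        rows = spike_in_sensitivity(train, test, art, spike_counts=(0, 50), seed=1)
        unspiked_aats = adversarial_accuracy(
            nearest_neighbor_profile(train, art))[2]
        assert rows[0]["aats_train"] == pytest.approx(unspiked_aats)
        assert rows[1]["aats_train"] == 0.0  # all rows are training copies

    def test_spike_in_monotone_on_average(self):
        curves = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            train = HaplotypeMatrix(values=r.integers(2, size=(60, 50)))
            test = HaplotypeMatrix(values=r.integers(2, size=(60, 50)))
            art = HaplotypeMatrix(values=r.integers(2, size=(60, 50)))
            rows = spike_in_sensitivity(train, test, art,
                                        spike_counts=(0, 10, 30, 60), seed=seed)
            curves.append([row["aats_train"] for row in rows])
        mean_curve = np.mean(curves, axis=0)
        assert np.all(np.diff(mean_curve) <= 1e-12)


class TestEmbedding:
    def test_joint_pca_identical_datasets_overlap(self, structured_data):
        sub = structured_data.subset_rows(range(60))
        a, b = joint_pca([sub, sub], n_components=3)
        assert np.allclose(a, b)

    def test_score_variance_equals_retained_eigenvalues(self, structured_data):
        coords = joint_pca([structured_data], n_components=4, scale="raw")[0]
        total = coords.var(axis=0, ddof=1).sum()
        X = structured_data.values.astype(float)
        eigvals = np.linalg.eigvalsh(np.cov(X, rowvar=False))[::-1][:4]
        assert total == pytest.approx(eigvals.sum(), rel=1e-8)

    def test_wasserstein_point_pair_equals_squared_distance(self):
        for d in (1.0, 2.5):
            cost = wasserstein_2d(np.array([[0.0, 0.0]]), np.array([[d, 0.0]]),
                                  reg=1e-6)
            assert cost == pytest.approx(d * d, rel=1e-6)

    def test_wasserstein_symmetry_and_identity(self, rng):
        a = rng.standard_normal((30, 2))
        b = rng.standard_normal((25, 2)) + 1.0
        assert wasserstein_2d(a, b) == pytest.approx(wasserstein_2d(b, a), rel=1e-5)
        assert wasserstein_2d(a, a) < 0.05  # reg-scale entropic bias only

    def test_wasserstein_matches_exact_ot_on_small_clouds(self, rng):
        """Against the exact assignment solution (uniform weights, equal n)."""
        from scipy.optimize import linear_sum_assignment
        from scipy.spatial.distance import cdist

        a = rng.standard_normal((8, 2))
        b = rng.standard_normal((8, 2))
        C = cdist(a, b, "sqeuclidean")
        ri, ci = linear_sum_assignment(C)
        exact = C[ri, ci].mean()
        assert wasserstein_2d(a, b, reg=1e-5) == pytest.approx(exact, rel=1e-3)


class TestFixedSites:
    def test_identical_pair_reports_zero(self, structured_data):
        counts = fixed_site_report(structured_data, structured_data)
        assert all(v == 0 for v in counts.values())

    def test_all_zero_artificial_counts_polymorphic_sites(self, structured_data):
        art = HaplotypeMatrix(values=np.zeros_like(structured_data.values))
        f = structured_data.allele_frequencies()
        n_poly = int(np.sum((f > 0) & (f < 1)))
        counts = fixed_site_report(structured_data, art)
        assert counts["art_fixed_0_real_poly"] == n_poly
        assert counts["art_fixed_1_real_poly"] == 0

    def test_hand_built_toy(self):
        real = HaplotypeMatrix(values=np.array([[0, 1, 1], [1, 1, 0]]))
        art = HaplotypeMatrix(values=np.array([[0, 0, 1], [1, 0, 1]]))
        counts = fixed_site_report(real, art)
        assert counts["art_fixed_0_real_poly"] == 0  # site 1 fixed at 0 in art…
        assert counts["art_fixed_1_real_poly"] == 1  # …site 2 fixed at 1, real poly
        assert counts["real_fixed_0_art_poly"] == 0
        assert counts["real_fixed_1_art_poly"] == 0


class TestReport:
    def test_report_complete_and_reproducible(self, structured_data, rng):
        sub = structured_data.subset_rows(range(80))
        art = HaplotypeMatrix(values=rng.integers(2, size=(80, 100)))
        rep1 = evaluate_pair(sub, art, seed=5)
        rep2 = evaluate_pair(sub, art, seed=5)
        s1, s2 = rep1.summary(), rep2.summary()
        assert s1 == s2
        for key in ("allele_freq_corr", "ld_corr", "aa_ts", "pca_wasserstein_2d",
                    "wasserstein_pairwise", "n_identical_pairs"):
            assert key in s1

    def test_identical_pair_degenerate_values(self, structured_data):
        sub = structured_data.subset_rows(range(40))
        rep = evaluate_pair(sub, sub, seed=0)
        assert rep.allele_freq_corr == pytest.approx(1.0)
        assert rep.aa_ts == 0.0
        assert rep.pairwise["wasserstein_within"] == 0.0
        assert all(v == 0 for v in rep.fixed_sites.values())

    def test_row_shuffle_invariance(self, structured_data, rng):
        sub = structured_data.subset_rows(range(50))
        art = HaplotypeMatrix(values=rng.integers(2, size=(50, 100)))
        shuffled = art.subset_rows(rng.permutation(50))
        a = evaluate_pair(sub, art, seed=2, with_three_point=False).summary()
        b = evaluate_pair(sub, shuffled, seed=2, with_three_point=False).summary()
        for key in ("allele_freq_corr", "ld_corr", "aa_ts", "wasserstein_pairwise"):
            assert a[key] == pytest.approx(b[key], abs=1e-9)
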