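"""IBS/MDS/Procrustes, Li-Stephens painting and coancestry clustering."""

from __future__ import annotations

import numpy as np
import pytest

from finescale import coancestry, simdata
from finescale.exceptions import PhasingError, ValidationError

from .conftest import splits_gr_upb, structured_params


class TestIbsDistance:
    def test_identical_rows_have_zero_distance(self):
        g = np.tile([0, 1, 2, 1, 0], (2, 1))
        d = coancestry.ibs_distance(g)
        assert d.values[0, 1] == 0

    def test_opposite_homozygotes_have_distance_one(self):
        g = np.vstack([np.zeros(50), np.full(50, 2)])
        assert coancestry.ibs_distance(g).values[0, 1] == 1.0

    def test_hand_enumerated_example(self):
        g = np.array([[0, 1, 2, 2], [2, 1, 0, 2]])
        assert coancestry.ibs_distance(g).values[0, 1] == pytest.approx(0.5)

    def test_missing_sites_are_pairwise_complete(self):
        g = np.array([[0, -1, 2, 2], [2, 1, -1, 2]])
        # only sites 0 and 3 shared: (|0-2|/2 + 0)/2 = 0.5
        assert coancestry.ibs_distance(g).values[0, 1] == pytest.approx(0.5)

    def test_no_shared_sites_raises_naming_pair(self):
        g = np.array([[0, -1], [-1, 1], [0, 1]])
        with pytest.raises(ValidationError, match="s0.*s1"):
            coancestry.ibs_distance(g)

    def test_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(12, 80))
        d = coancestry.ibs_distance(g).values
        for _ in range(200):
            i, j, k = rng.choice(12, size=3, replace=False)
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestClassicalMds:
    @staticmethod
    def _euclid(points):
        diff = points[:, None, :] - points[None, :, :]
        return coancestry.DistanceMatrix(
            np.sqrt((diff**2).sum(-1)), [f"s{i}" for i in range(len(points))]
        )

    def test_recovers_planar_configuration(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(15, 2))
        res = coancestry.classical_mds(self._euclid(pts), k=2)
        corr = coancestry.procrustes_correlation(pts, res.coordinates)
        assert corr > 0.999

    def test_reproduces_euclidean_distances(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(10, 3))
        dist = self._euclid(pts)
        res = coancestry.classical_mds(dist, k=3)
        diff = res.coordinates[:, None, :] - res.coordinates[None, :, :]
        np.testing.assert_allclose(
            np.sqrt((diff**2).sum(-1)), dist.values, atol=1e-8
        )

    def test_agrees_with_reference_pcoa(self):
        # Independent route: scikit-bio's principal coordinate analysis.
        from skbio.stats.ordination import pcoa

        rng = np.random.default_rng(3)
        g = rng.integers(0, 3, size=(12, 200))
        dist = coancestry.ibs_distance(g)
        ours = coancestry.classical_mds(dist, k=2).coordinates
        ref = pcoa(dist.values, number_of_dimensions=2).samples.values
        assert coancestry.procrustes_correlation(ours, ref) > 0.9999

    def test_duplicated_samples_coincide(self):
        pts = np.array([[0.0, 0], [1, 0], [1, 0], [0, 1]])
        res = coancestry.classical_mds(self._euclid(pts), k=2)
        np.testing.assert_allclose(
            res.coordinates[1], res.coordinates[2], atol=1e-9
        )

    def test_equilateral_triangle_symmetry(self):
        d = coancestry.DistanceMatrix(
            np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float),
            ["a", "b", "c"],
        )
        res = coancestry.classical_mds(d, k=2)
        c = res.coordinates
        dists = [
            np.linalg.norm(c[0] - c[1]),
            np.linalg.norm(c[0] - c[2]),
            np.linalg.norm(c[1] - c[2]),
        ]
        np.testing.assert_allclose(dists, dists[0], rtol=1e-9)

    def test_eigenvalues_sorted_and_k_truncated(self, caplog):
        d = coancestry.DistanceMatrix(
            np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float),
            ["a", "b", "c"],
        )
        res = coancestry.classical_mds(d, k=5)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert res.coordinates.shape[1] == 2


class TestProcrustes:
    def test_exact_fit_has_correlation_one_and_minimal_p(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(10, 2))
        ang = 0.7
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        y = 3.0 * x @ rot + np.array([5.0, -2.0])
        corr, p = coancestry.procrustes_test(x, y, n_perm=999, seed=0)
        assert corr == pytest.approx(1.0, abs=1e-9)
        assert p == pytest.approx(1 / 1000)

    def test_collinear_self_match(self):
        x = np.column_stack([np.arange(5.0), np.arange(5.0)])
        corr, _ = coancestry.procrustes_test(x, x, n_perm=99, seed=0)
        assert corr == pytest.approx(1.0, abs=1e-9)

    def test_null_p_values_are_roughly_uniform(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(12, 2))
        ps = []
        for rep in range(40):
            y = rng.permutation(rng.normal(size=(12, 2)))
            _, p = coancestry.procrustes_test(x, y, n_perm=99, seed=rep)
            ps.append(p)
        assert 0.3 < np.mean(ps) < 0.7
        assert np.mean(np.array(ps) < 0.2) < 0.45

    def test_input_validation(self):
        x = np.zeros((5, 2))
        with pytest.raises(ValidationError):
            coancestry.procrustes_test(x, np.zeros((4, 2)), n_perm=99)
        with pytest.raises(ValidationError):
            coancestry.procrustes_test(x, x, n_perm=0)
        with pytest.raises(ValidationError):
            coancestry.procrustes_test(x[:2], x[:2], n_perm=99)


def _oracle_expected_lengths(rec, donors, positions, spans, rho, mu):
    """Matrix-form forward-backward, independent of the painting kernel."""
    L, K = len(positions), donors.shape[0]
    em = np.where(donors == rec[None, :], 1 - mu, mu)  # (K, L)
    alpha = np.zeros((L, K))
    c = np.zeros(L)
    alpha[0] = em[:, 0] / K
    c[0] = alpha[0].sum()
    alpha[0] /= c[0]
    for l in range(1, L):
        pj = 1 - np.exp(-rho * (positions[l] - positions[l - 1]))
        trans = (1 - pj) * np.eye(K) + pj / K
        a = em[:, l] * (trans.T @ alpha[l - 1])
        c[l] = a.sum()
        alpha[l] = a / c[l]
    beta = np.zeros((L, K))
    beta[L - 1] = 1.0
    for l in range(L - 2, -1, -1):
        pj = 1 - np.exp(-rho * (positions[l + 1] - positions[l]))
        trans = (1 - pj) * np.eye(K) + pj / K
        beta[l] = trans @ (em[:, l + 1] * beta[l + 1]) / c[l + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return (gamma * spans[:, None]).sum(axis=0)


class TestPainting:
    def _toy_panel(self, seed=0, n_ind=4, n_sites=120):
        rng = np.random.default_rng(seed)
        haps = rng.integers(0, 2, size=(2 * n_ind, n_sites)).astype(np.int8)
        # Recipient individual 0: both haplotypes copy donor individual 1.
        haps[0] = haps[2]
        haps[1] = haps[3]
        positions = np.sort(
            rng.choice(10**6, size=n_sites, replace=False)
        ).astype(np.int64)
        return simdata.HaplotypePanel(
            haplotypes=haps,
            positions=positions,
            sample_ids=[f"i{k}" for k in range(n_ind)],
            region_labels=["X"] * n_ind,
            coords=np.zeros((n_ind, 2)),
        )

    def test_matches_independent_forward_backward(self):
        from finescale._painting import paint_one

        rng = np.random.default_rng(7)
        L, K = 60, 5
        haps = rng.integers(0, 2, size=(K + 1, L)).astype(np.int8)
        positions = np.sort(rng.choice(10**5, size=L, replace=False)).astype(float)
        spans = np.gradient(positions)
        rec = haps[K]
        donors_idx = np.arange(K, dtype=np.int64)
        got, _, _ = paint_one(rec, haps, donors_idx, positions, spans, 1e-4, 1e-2)
        want = _oracle_expected_lengths(
            rec, haps[:K], positions, spans, 1e-4, 1e-2
        )
        np.testing.assert_allclose(got, want, rtol=1e-8)

    def test_identical_donor_dominates(self):
        panel = self._toy_panel()
        cm = coancestry.paint_panel(panel, switch_rate=1e-6, miscopy_rate=1e-3)
        frac = cm.lengths[:, 0] / cm.lengths[:, 0].sum()
        assert frac[1] > 0.9

    def test_identical_donors_get_equal_lengths(self):
        panel = self._toy_panel(seed=3)
        haps = panel.haplotypes.copy()
        haps[4:6] = haps[2:4]  # individual 2 duplicates individual 1
        panel = simdata.HaplotypePanel(
            haps, panel.positions, panel.sample_ids,
            panel.region_labels, panel.coords,
        )
        cm = coancestry.paint_panel(panel)
        # Recipient 3 sees donors 1 and 2 with identical haplotypes.
        assert cm.lengths[1, 3] == pytest.approx(cm.lengths[2, 3], abs=1e-9)

    def test_no_switch_no_miscopy_limit(self):
        panel = self._toy_panel(seed=5)
        cm = coancestry.paint_panel(panel, switch_rate=1e-15, miscopy_rate=1e-12)
        frac = cm.lengths[1, 0] / cm.lengths[:, 0].sum()
        assert frac > 1 - 1e-6

    def test_posterior_mass_conservation(self, small_panel):
        cm = coancestry.paint_panel(small_panel)
        np.testing.assert_allclose(
            cm.lengths.sum(axis=0),
            cm.painted_length,
            rtol=1e-6,
        )

    def test_unphased_input_rejected(self, small_panel):
        dos = simdata.DosagePanel(
            dosages=small_panel.dosages(),
            positions=small_panel.positions,
            sample_ids=small_panel.sample_ids,
        )
        with pytest.raises(PhasingError, match="dosage"):
            coancestry.paint_panel(dos)


class TestSwitchRateEm:
    def test_loglik_trace_is_nondecreasing(self, small_panel):
        sub = small_panel.subset_samples(range(8))
        fit = coancestry.estimate_switch_rate(sub, n_em_iters=5)
        assert np.all(np.diff(fit.loglik_trace) >= 0)

    def test_identical_haplotypes_drive_rate_to_floor(self):
        haps = np.tile(
            np.random.default_rng(0).integers(0, 2, size=60), (8, 1)
        ).astype(np.int8)
        panel = simdata.HaplotypePanel(
            haps,
            np.arange(60, dtype=np.int64) * 1000,
            [f"i{k}" for k in range(4)],
            ["X"] * 4,
            np.zeros((4, 2)),
        )
        fit = coancestry.estimate_switch_rate(
            panel, n_em_iters=40, init_rate=1e-5, min_rate=1e-12
        )
        # No switching is ever needed, so EM shrinks the rate toward the
        # floor (geometrically, via the donor-change expectation).
        assert fit.switch_rate < 1e-8

    def test_recombination_increases_estimated_switch_rate(self):
        rates = {}
        for label, recomb in [("low", 1e-9), ("high", 5e-8)]:
            vals = []
            for seed in range(3):
                panel = simdata.simulate_dataset(
                    simdata.panmictic_params(2000.0),
                    simdata.ModelConfig(
                        sequence_length=3e5,
                        recombination_rate=recomb,
                        seed=10 + seed,
                    ),
                )
                vals.append(
                    coancestry.estimate_switch_rate(panel, 4).switch_rate
                )
            rates[label] = np.mean(vals)
        assert rates["high"] > rates["low"]

    def test_single_site_panel_rejected(self):
        panel = simdata.HaplotypePanel(
            np.zeros((8, 1), dtype=np.int8) + np.array([[0],[1],[0],[1],[0],[1],[0],[1]], dtype=np.int8),
            np.array([100], dtype=np.int64),
            [f"i{k}" for k in range(4)],
            ["X"] * 4,
            np.zeros((4, 2)),
        )
        with pytest.raises(ValidationError):
            coancestry.estimate_switch_rate(panel, 3)


class TestClusterCoancestry:
    def test_recovers_planted_two_clusters(self):
        fx = simdata.make_fixture(
            "two_cluster_coancestry",
            dict(within_mean=2.0, between_mean=1.0, noise_sd=0.05),
            seed=1,
        )
        cm = coancestry.CoancestryMatrix(fx.matrix, fx.sample_ids)
        res = coancestry.cluster_coancestry(cm, k_max=5)
        assert res.best_k == 2
        labs = res.labels_by_k[2]
        assert len(set(labs[:10])) == 1
        assert len(set(labs[10:])) == 1
        assert labs[0] != labs[-1]

    def test_structureless_matrix_has_low_silhouette(self):
        rng = np.random.default_rng(2)
        n = 24
        mat = np.abs(1.0 + rng.normal(0, 1e-3, size=(n, n)))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0)
        cm = coancestry.CoancestryMatrix(mat, [f"s{i}" for i in range(n)])
        res = coancestry.cluster_coancestry(cm, k_max=6)
        assert max(res.silhouettes.values()) < 0.25

    def test_permutation_equivariance(self):
        fx = simdata.make_fixture(
            "two_cluster_coancestry", dict(noise_sd=0.05), seed=3
        )
        cm = coancestry.CoancestryMatrix(fx.matrix, fx.sample_ids)
        res = coancestry.cluster_coancestry(cm, k_max=4)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(fx.sample_ids))
        cm_p = coancestry.CoancestryMatrix(
            fx.matrix[np.ix_(perm, perm)],
            [fx.sample_ids[i] for i in perm],
        )
        res_p = coancestry.cluster_coancestry(cm_p, k_max=4)
        assert res_p.best_k == res.best_k
        # same co-membership structure modulo relabelling
        a = res.labels[perm]
        b = res_p.labels
        co_a = a[:, None] == a[None, :]
        co_b = b[:, None] == b[None, :]
        assert np.array_equal(co_a, co_b)

    def test_k_max_bounds_checked(self):
        fx = simdata.make_fixture("two_cluster_coancestry", dict(n_per_cluster=3), seed=0)
        cm = coancestry.CoancestryMatrix(fx.matrix, fx.sample_ids)
        with pytest.raises(ValidationError):
            coancestry.cluster_coancestry(cm, k_max=6)

    def test_separates_gr_from_upb_on_structured_panel(self):
        panel = simdata.simulate_dataset(
            structured_params(),
            simdata.ModelConfig(sequence_length=1e6, seed=99),
        )
        cm = coancestry.paint_panel(panel)
        res = coancestry.cluster_coancestry(cm, k_max=6)
        assert splits_gr_upb(
            res.labels_by_k[2], np.asarray(panel.region_labels)
        )


class TestMatrixTsv:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        m = rng.random((5, 5))
        ids = [f"s{i}" for i in range(5)]
        path = tmp_path / "m.tsv"
        coancestry.write_matrix_tsv(m, ids, path)
        back, back_ids = coancestry.read_matrix_tsv(path)
        assert back_ids == ids
        np.testing.assert_allclose(back, m, rtol=1e-9)
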