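import numpy as np
import pandas as pd
import pytest

from ordimap.correlation import AssociationMatrix, pairwise_matrix
from ordimap.matrix_io import SeedTable, TargetTable
from ordimap.ordination import classical_scaling_svd, to_distance
from ordimap.thematic import (
    ThematicError,
    complementarity_score,
    dispersion_ellipse,
    kernel_density_field,
    median_correlation_shift,
    mirsvr_distance_regression,
    seed_group_partition,
    sign_flip_association,
    target_pair_analysis,
)


def mixed_assoc(tau: np.ndarray, n_mir: int) -> AssociationMatrix:
    n = tau.shape[0]
    ids = [f"miR-{i}" for i in range(n_mir)] + [f"gene-{i}" for i in range(n - n_mir)]
    return AssociationMatrix(
        pd.DataFrame(tau, index=ids, columns=ids),
        species=pd.Series(["miRNA"] * n_mir + ["mRNA"] * (n - n_mir), index=ids),
        mode="simple",
    )


class TestDispersionEllipse:
    def test_isotropic_cloud_axes_near_scale(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(5000, 2))
        ell = dispersion_ellipse(pts, scale=1.6)
        np.testing.assert_allclose(ell.semi_axes(), [1.6, 1.6], rtol=0.10)

    def test_insufficient_points_rejected(self):
        with pytest.raises(ThematicError, match="at least 3"):
            dispersion_ellipse(np.array([[0.0, 0.0], [1.0, 1.0]]))

    def test_identical_points_rejected(self):
        with pytest.raises(ThematicError, match="degenerate"):
            dispersion_ellipse(np.ones((5, 2)))

    def test_affine_equivariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(300, 2))
        A = np.array([[2.0, 0.5], [-0.3, 1.5]])
        shift = np.array([4.0, -2.0])
        ell = dispersion_ellipse(pts)
        ell_t = dispersion_ellipse(pts @ A.T + shift)
        np.testing.assert_allclose(ell_t.center, ell.center @ A.T + shift, atol=1e-10)
        np.testing.assert_allclose(ell_t.covariance, A @ ell.covariance @ A.T, atol=1e-10)

    def test_contains_matches_mahalanobis_scale(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(2000, 2))
        ell = dispersion_ellipse(pts, scale=1.6)
        inside = ell.contains(pts).mean()
        # 2D Gaussian: P(inside 1.6 sd) = 1 - exp(-1.6^2/2) ~ 0.722
        assert inside == pytest.approx(0.722, abs=0.05)


class TestDensityField:
    def test_mode_at_cluster_center(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(0, 0.05, size=(200, 2)) + [2.0, -1.0]
        field = kernel_density_field(pts, grid_size=64, bandwidth=0.2)
        mx, my = field.mode_location()
        assert mx == pytest.approx(2.0, abs=0.15)
        assert my == pytest.approx(-1.0, abs=0.15)

    def test_normalized_over_grid(self):
        rng = np.random.default_rng(1)
        field = kernel_density_field(rng.normal(size=(50, 2)), 32, bandwidth=0.3)
        assert field.density.sum() * field.cell_area == pytest.approx(1.0)

    def test_two_separated_clusters_two_local_maxima(self):
        rng = np.random.default_rng(2)
        pts = np.vstack(
            [rng.normal(0, 0.1, size=(100, 2)), rng.normal(0, 0.1, size=(100, 2)) + 3.0]
        )
        field = kernel_density_field(pts, grid_size=80, bandwidth=0.2)
        d = field.density
        interior = d[1:-1, 1:-1]
        local_max = (
            (interior > d[:-2, 1:-1])
            & (interior > d[2:, 1:-1])
            & (interior > d[1:-1, :-2])
            & (interior > d[1:-1, 2:])
            & (interior > 0.05 * d.max())
        )
        assert local_max.sum() >= 2

    def test_zero_bandwidth_rejected(self):
        with pytest.raises(ThematicError, match="bandwidth"):
            kernel_density_field(np.zeros((3, 2)), 16, bandwidth=0.0)


class TestComplementarity:
    def _field(self, pts, extent):
        return kernel_density_field(pts, grid_size=48, bandwidth=0.3, extent=extent)

    def test_self_score_is_one(self):
        rng = np.random.default_rng(0)
        f = self._field(rng.normal(size=(100, 2)), (-4, 4, -4, 4))
        assert complementarity_score(f, f) == pytest.approx(1.0)

    def test_disjoint_clusters_strongly_negative(self):
        rng = np.random.default_rng(1)
        extent = (-1, 5, -1, 5)
        a = self._field(rng.normal(0, 0.3, size=(150, 2)), extent)
        b = self._field(rng.normal(0, 0.3, size=(150, 2)) + 4.0, extent)
        assert complementarity_score(a, b) < -0.3

    def test_grid_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        a = self._field(rng.normal(size=(50, 2)), (-3, 3, -3, 3))
        b = self._field(rng.normal(size=(50, 2)), (-2, 2, -2, 2))
        with pytest.raises(ThematicError, match="grid"):
            complementarity_score(a, b)

    def test_uniform_field_flagged_undefined(self):
        rng = np.random.default_rng(3)
        a = self._field(rng.normal(size=(50, 2)), (-3, 3, -3, 3))
        b = self._field(rng.normal(size=(50, 2)), (-3, 3, -3, 3))
        b.density = np.full_like(b.density, 1.0 / (b.cell_area * b.density.size))
        with pytest.warns(UserWarning, match="uniform"):
            assert np.isnan(complementarity_score(a, b))


class TestMedianShift:
    def _assoc_pair(self, delta_mirna: str | None = None, delta: float = -0.3):
        rng = np.random.default_rng(0)
        n_mir, n_mrna = 4, 20
        n = n_mir + n_mrna
        base = rng.uniform(-0.2, 0.2, size=(n, n))
        base = (base + base.T) / 2
        np.fill_diagonal(base, 1.0)
        a = base.copy()
        assoc_b = mixed_assoc(base, n_mir)
        if delta_mirna is not None:
            i = assoc_b.gene_ids.index(delta_mirna)
            a[i, n_mir:] += delta
            a[n_mir:, i] += delta
            a = np.clip(a, -1, 1)
            np.fill_diagonal(a, 1.0)
        return mixed_assoc(a, n_mir), assoc_b

    def test_identical_matrices_no_flags(self):
        a, b = self._assoc_pair()
        rep = median_correlation_shift(a, a)
        assert (rep.table["delta"] == 0).all()
        assert rep.decreased_ids == [] and rep.increased_ids == []

    def test_planted_decoupling_detected(self):
        a, b = self._assoc_pair("miR-2", delta=-0.3)
        rep = median_correlation_shift(a, b, threshold=0.15)
        assert rep.decreased_ids == ["miR-2"]
        assert rep.increased_ids == []

    def test_boundary_delta_not_flagged(self):
        a, b = self._assoc_pair("miR-1", delta=-0.15)
        rep = median_correlation_shift(a, b, threshold=0.15)
        assert "miR-1" not in rep.decreased_ids  # strict inequality

    def test_antisymmetry_under_condition_swap(self):
        a, b = self._assoc_pair("miR-0", delta=-0.4)
        fwd = median_correlation_shift(a, b, threshold=0.15)
        rev = median_correlation_shift(b, a, threshold=0.15)
        np.testing.assert_allclose(
            fwd.table["delta"].to_numpy(), -rev.table["delta"].to_numpy(), atol=1e-12
        )
        assert fwd.decreased_ids == rev.increased_ids
        assert fwd.increased_ids == rev.decreased_ids

    def test_no_mrnas_rejected(self):
        tau = np.eye(3)
        assoc = mixed_assoc(tau, 3)
        with pytest.raises(ThematicError, match="mRNA"):
            median_correlation_shift(assoc, assoc)


class TestTargetPairs:
    def _setup(self, bundle):
        assoc = pairwise_matrix(bundle.case_matrix, covariate=bundle.necrosis_covariate())
        ordn = classical_scaling_svd(to_distance(assoc), k=3)
        return assoc, ordn

    def test_single_pair_report(self, small_bundle):
        assoc, ordn = self._setup(small_bundle)
        one = TargetTable(small_bundle.targets.table.iloc[:1].reset_index(drop=True))
        rep = target_pair_analysis(ordn, assoc, one, n_dims=3)
        assert rep.n_pairs == 1
        assert rep.observed_mean >= 0

    def test_empty_targets_rejected(self, small_bundle):
        assoc, ordn = self._setup(small_bundle)
        empty = TargetTable(small_bundle.targets.table.iloc[:0])
        with pytest.raises(ThematicError, match="empty"):
            target_pair_analysis(ordn, assoc, empty)

    def test_distances_invariant_to_axis_signs_and_rotation(self, small_bundle):
        assoc, ordn = self._setup(small_bundle)
        rep = target_pair_analysis(ordn, assoc, small_bundle.targets, n_dims=3)
        rng = np.random.default_rng(0)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        rotated = ordn.coordinates.copy()
        rotated.iloc[:, :] = rotated.to_numpy() @ Q
        import dataclasses

        ordn_rot = dataclasses.replace(ordn, coordinates=rotated)
        rep_rot = target_pair_analysis(ordn_rot, assoc, small_bundle.targets, n_dims=3)
        assert rep_rot.observed_mean == pytest.approx(rep.observed_mean, rel=1e-9)
        assert rep_rot.background_mean == pytest.approx(rep.background_mean, rel=1e-9)

    def test_sign_flip_preserves_symmetry_and_flips_cross_block(self, small_bundle):
        assoc, _ = self._setup(small_bundle)
        flipped = sign_flip_association(assoc)
        a, f = assoc.tau, flipped.tau
        mir = assoc.species_ids("miRNA")
        mrna = assoc.species_ids("mRNA")
        np.testing.assert_allclose(
            f.loc[mir, mrna].to_numpy(), -a.loc[mir, mrna].to_numpy()
        )
        np.testing.assert_allclose(
            f.loc[mir, mir].to_numpy(), a.loc[mir, mir].to_numpy()
        )
        arr = f.to_numpy()
        np.testing.assert_allclose(arr, arr.T)


class TestMirsvrRegression:
    def _ordination(self, n_mir=30, n_mrna=170, k=10, seed=0):
        rng = np.random.default_rng(seed)
        coords = rng.normal(size=(n_mir + n_mrna, k))
        ids = [f"miR-{i}" for i in range(n_mir)] + [f"gene-{i}" for i in range(n_mrna)]
        from ordimap.ordination import OrdinationResult

        return OrdinationResult(
            coordinates=pd.DataFrame(coords, index=ids, columns=[f"dim{j+1}" for j in range(k)]),
            species=pd.Series(["miRNA"] * n_mir + ["mRNA"] * n_mrna, index=ids),
            singular_values=np.array([]),
            k_retained=k,
            method="classical_svd",
        )

    def _targets(self, ordn, n_pairs, seed=0, scores=None):
        rng = np.random.default_rng(seed)
        mir = [g for g in ordn.gene_ids if g.startswith("miR")]
        mrna = [g for g in ordn.gene_ids if g.startswith("gene")]
        pairs = [(rng.choice(mir), rng.choice(mrna)) for _ in range(n_pairs)]
        pairs = list(dict.fromkeys(pairs))
        if scores is None:
            scores = rng.uniform(-2, -0.1, size=len(pairs))
        return TargetTable(
            pd.DataFrame(
                {
                    "mirna_id": [p[0] for p in pairs],
                    "mrna_id": [p[1] for p in pairs],
                    "mirsvr_score": scores[: len(pairs)],
                    "conserved": True,
                }
            )
        )

    def test_perfect_linear_relation_r2_one(self):
        ordn = self._ordination(k=3)
        t = self._targets(ordn, 40)
        a = ordn.coordinates.loc[t.table["mirna_id"]].to_numpy()
        b = ordn.coordinates.loc[t.table["mrna_id"]].to_numpy()
        d1 = np.abs(a[:, 0] - b[:, 0])
        t.table["mirsvr_score"] = -0.1 - d1  # exact function of dim-1 distance
        reg = mirsvr_distance_regression(ordn, t, n_dims=3)
        assert reg.r_squared == pytest.approx(1.0, abs=1e-10)
        assert reg.coefficients["dim1"] == pytest.approx(-1.0, abs=1e-8)

    def test_too_few_pairs_rejected(self):
        ordn = self._ordination(k=10)
        t = self._targets(ordn, 9)
        with pytest.raises(ThematicError, match="pairs"):
            mirsvr_distance_regression(ordn, t, n_dims=10)

    def test_constant_scores_flagged(self):
        ordn = self._ordination(k=3)
        t = self._targets(ordn, 30)
        t.table["mirsvr_score"] = -0.5
        with pytest.warns(UserWarning, match="constant"):
            reg = mirsvr_distance_regression(ordn, t, n_dims=3)
        assert np.isnan(reg.r_squared)


class TestSeedGroups:
    def test_all_distinct_no_groups(self):
        t = SeedTable(
            pd.DataFrame(
                {"mirna_id": ["a", "b", "c"], "seed_sequence": ["GAGGUAG", "AAGGUAG", "CAGGUAG"]}
            )
        )
        groups = seed_group_partition(t)
        assert groups.n_groups == 0
        assert groups.n_singletons == 3

    def test_shared_seed_grouped(self):
        t = SeedTable(
            pd.DataFrame(
                {"mirna_id": ["a", "b", "c"], "seed_sequence": ["GAGGUAG", "GAGGUAG", "CAGGUAG"]}
            )
        )
        groups = seed_group_partition(t)
        assert groups.n_groups == 1
        assert groups.groups["GAGGUAG"] == ["a", "b"]

    def test_case_and_t_u_normalization(self):
        t = SeedTable(
            pd.DataFrame({"mirna_id": ["a", "b"], "seed_sequence": ["gagguag", "GAGGTAG"]})
        )
        groups = seed_group_partition(t)
        assert groups.n_groups == 1
        assert set(groups.groups["GAGGUAG"]) == {"a", "b"}

    def test_empty_table_rejected(self):
        t = SeedTable(pd.DataFrame({"mirna_id": [], "seed_sequence": []}))
        with pytest.raises(ThematicError, match="empty"):
            seed_group_partition(t)


def test_block_members_cluster_on_the_map(small_bundle):
    """Planted functional blocks occupy distinct map regions."""
    assoc = pairwise_matrix(
        small_bundle.case_matrix, covariate=small_bundle.necrosis_covariate()
    )
    ordn = classical_scaling_svd(to_distance(assoc), k=3)
    blocks = small_bundle.truth.block_membership
    coords = ordn.coordinates
    within, between = [], []
    mrnas = [g for g in ordn.gene_ids if blocks[g] >= 0]
    pts = coords.loc[mrnas].to_numpy()
    labs = blocks.loc[mrnas].to_numpy()
    from scipy.spatial.distance import pdist, squareform

    D = squareform(pdist(pts))
    same = labs[:, None] == labs[None, :]
    iu = np.triu_indices(len(mrnas), 1)
    within = D[iu][same[iu]]
    between = D[iu][~same[iu]]
    assert within.mean() < between.mean()
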