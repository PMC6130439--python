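import numpy as np
import pytest

from negconn import (
    ConnectivityMatrix,
    MaskRule,
    Parcellation,
    average_negative_connectivity,
    build_mask,
    candidate_edges,
    region_importance,
)
from negconn.mask import EmptyMaskError, edge_values


@pytest.fixture
def parc6():
    # 2 Default, 3 task-positive, 1 other
    return Parcellation(
        networks=("Default", "Default", "CinguloOperc", "DorsalAttn", "Salience", "Other")
    )


def _mat(z):
    z = np.asarray(z, float)
    np.fill_diagonal(z, np.nan)
    return ConnectivityMatrix(z=(z + z.T) / 2 if not np.allclose(z, z.T, equal_nan=True) else z)


def _ref_mats(parc, edge_z, fill=0.2):
    """Two reference matrices with given mean z planted on listed edges."""
    mats = []
    for shift in (-0.1, +0.1):
        z = np.full((parc.n_rois, parc.n_rois), fill)
        for (i, j), val in edge_z.items():
            z[i, j] = z[j, i] = val + shift
        np.fill_diagonal(z, np.nan)
        mats.append(ConnectivityMatrix(z=z))
    return mats


class TestCandidateEdges:
    def test_toy_taskpos_count(self, parc6):
        assert len(candidate_edges(parc6, "dmn_to_taskpos")) == 6

    def test_toy_all_count(self, parc6):
        assert len(candidate_edges(parc6, "dmn_to_all")) == 8

    def test_gordon_count(self, gordon):
        assert len(candidate_edges(gordon, "dmn_to_taskpos")) == 5043

    def test_every_pair_touches_default(self, parc6):
        pairs = candidate_edges(parc6, "dmn_to_all")
        dmn = set(parc6.default_indices)
        assert all(i in dmn or j in dmn for i, j in pairs)

    def test_empty_default_rejected(self):
        parc = Parcellation(networks=("Other", "DorsalAttn"))
        with pytest.raises(ValueError, match="non-empty"):
            candidate_edges(parc, "dmn_to_taskpos")


class TestBuildMask:
    def test_threshold_arithmetic_on_z_averaged_reference(self, parc6):
        # edge z values -0.5 and -0.3 across two references -> mean z -0.4
        # -> r = tanh(-0.4) = -0.3799...
        mats = _ref_mats(parc6, {(0, 2): -0.4})
        for cut, kept in ((-0.35, True), (-0.375, True), (-0.39, False)):
            if kept:
                m = build_mask(mats, parc6, rule=MaskRule("threshold", cut))
                assert m.edge_set() == {(0, 2)}
                assert m.ref_mean_r[0] == pytest.approx(np.tanh(-0.4))
            else:
                with pytest.raises(EmptyMaskError):
                    build_mask(mats, parc6, rule=MaskRule("threshold", cut))

    def test_density_ceiling_takes_most_negative(self, parc6):
        mats = _ref_mats(parc6, {(0, 2): -0.5, (1, 3): -0.3})
        m = build_mask(mats, parc6, rule=MaskRule("density", 0.05))
        # ceil(0.05 * 6) = 1 edge, the most negative
        assert m.n_edges == 1
        assert m.edge_set() == {(0, 2)}

    def test_all_positive_reference_is_empty_mask_error(self, parc6):
        mats = _ref_mats(parc6, {}, fill=0.3)
        with pytest.raises(EmptyMaskError, match="minimum"):
            build_mask(mats, parc6, rule=MaskRule("threshold", -0.35))

    def test_threshold_nesting_monotone(self, parc6, rng):
        z = rng.uniform(-0.8, 0.1, size=(6, 6))
        z = (z + z.T) / 2
        np.fill_diagonal(z, np.nan)
        mats = [ConnectivityMatrix(z=z.copy()) for _ in range(2)]
        masks = {}
        for cut in (-0.375, -0.35, -0.3):
            try:
                masks[cut] = build_mask(mats, parc6, rule=MaskRule("threshold", cut)).edge_set()
            except EmptyMaskError:
                masks[cut] = set()
        assert masks[-0.375] <= masks[-0.35] <= masks[-0.3]

    def test_taskpos_mask_nested_in_all_mask(self, parc6):
        mats = _ref_mats(parc6, {(0, 2): -0.6, (0, 5): -0.6})
        rule = MaskRule("threshold", -0.35)
        m_tp = build_mask(mats, parc6, scope="dmn_to_taskpos", rule=rule)
        m_all = build_mask(mats, parc6, scope="dmn_to_all", rule=rule)
        assert m_tp.edge_set() <= m_all.edge_set()
        assert (0, 5) in m_all.edge_set() and (0, 5) not in m_tp.edge_set()

    def test_retained_reference_r_below_cut(self, parc6, rng):
        z = -np.abs(rng.normal(0.4, 0.2, size=(6, 6)))
        z = (z + z.T) / 2
        np.fill_diagonal(z, np.nan)
        mats = [ConnectivityMatrix(z=z.copy()) for _ in range(3)]
        m = build_mask(mats, parc6, rule=MaskRule("threshold", -0.35))
        assert (m.ref_mean_r < -0.35).all()


class TestRegionImportance:
    def _mask_of(self, parc, edges):
        mats = _ref_mats(parc, {e: -0.6 for e in edges})
        return build_mask(mats, parc, rule=MaskRule("threshold", -0.35))

    def test_single_edge(self, parc6):
        counts = region_importance(self._mask_of(parc6, [(0, 2)]), 6)
        assert counts.tolist() == [1, 0, 1, 0, 0, 0]

    def test_star_hub(self, parc6):
        counts = region_importance(self._mask_of(parc6, [(0, 2), (0, 3), (0, 4)]), 6)
        assert counts[0] == 3
        assert counts[[2, 3, 4]].tolist() == [1, 1, 1]

    def test_handshake_sum(self, parc6, rng):
        m = self._mask_of(parc6, [(0, 2), (0, 4), (1, 3), (1, 2)])
        assert region_importance(m, 6).sum() == 2 * m.n_edges


class TestAverageNegativeConnectivity:
    def test_mean_of_two_edges(self, parc6):
        mask = build_mask(
            _ref_mats(parc6, {(0, 2): -0.6, (1, 3): -0.6}),
            parc6,
            rule=MaskRule("threshold", -0.35),
        )
        z = np.zeros((6, 6))
        z[0, 2] = z[2, 0] = -0.3
        z[1, 3] = z[3, 1] = -0.5
        np.fill_diagonal(z, np.nan)
        assert average_negative_connectivity(ConnectivityMatrix(z=z), mask) == pytest.approx(-0.4)

    def test_zero_matrix_gives_zero(self, parc6):
        mask = build_mask(
            _ref_mats(parc6, {(0, 2): -0.6}), parc6, rule=MaskRule("threshold", -0.35)
        )
        z = np.zeros((6, 6))
        np.fill_diagonal(z, np.nan)
        assert average_negative_connectivity(ConnectivityMatrix(z=z), mask) == 0.0

    def test_matches_brute_force_enumeration(self, parc6, rng):
        edges = [(0, 2), (0, 3), (1, 2), (1, 4)]
        mask = build_mask(
            _ref_mats(parc6, {e: -0.6 for e in edges}), parc6, rule=MaskRule("threshold", -0.35)
        )
        for _ in range(20):
            z = rng.normal(size=(6, 6))
            z = (z + z.T) / 2
            np.fill_diagonal(z, np.nan)
            mat = ConnectivityMatrix(z=z)
            brute = np.mean([z[i, j] for i, j in sorted(mask.edge_set())])
            assert average_negative_connectivity(mat, mask) == pytest.approx(brute, abs=1e-12)

    def test_undefined_masked_edge_is_error(self, parc6):
        mask = build_mask(
            _ref_mats(parc6, {(0, 2): -0.6}), parc6, rule=MaskRule("threshold", -0.35)
        )
        z = np.zeros((6, 6))
        z[0, 2] = z[2, 0] = np.nan
        np.fill_diagonal(z, np.nan)
        with pytest.raises(ValueError, match="undefined"):
            edge_values(ConnectivityMatrix(z=z), mask)
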