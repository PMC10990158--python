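"""Information-plane assembly, distinguishability and threshold detection."""

import numpy as np
import pytest

from dib.dib_objective import DIBModel, SweepConfig, TabularDataset, train_sweep
from dib.encoders import GaussianLatent
from dib.info_analysis import (
    AllocationHeatmap,
    DistinguishabilityMatrix,
    EvalConfig,
    InfoPlanePoint,
    allocation_heatmap,
    conditional_histograms,
    detect_threshold,
    distinguishability_matrix,
    info_plane,
    informative_subsets,
    quantile_grid,
)


def _point(bits, pred=0.5, beta=1.0, ids=None):
    bits = np.asarray(bits, float)
    ids = ids or [f"x{i+1}" for i in range(len(bits))]
    return InfoPlanePoint(
        beta=beta, step=1, channel_bits=bits, predictive_bits=pred, accuracy=0.9, feature_ids=ids
    )


class _StubChannel:
    """Channel with prescribed encodings over a grid (duck-typed encode)."""

    def __init__(self, fn):
        self.fn = fn

    def encode(self, values):
        mean, scale = self.fn(np.ravel(values))
        return GaussianLatent(mean, scale)


class TestInfoPlane:
    @pytest.fixture(scope="class")
    def tiny_run(self):
        from dib.boolean_circuit import BooleanCircuit, truth_table

        table = truth_table(BooleanCircuit(2, (("AND", (0, 1)),), 2))
        ds = TabularDataset.from_truth_table(table)
        cfg = SweepConfig(
            beta_start=1.0,
            beta_end=1e-4,
            n_steps=2500,
            n_checkpoints=8,
            latent_dim=4,
            encoder_hidden=(16,),
            decoder_hidden=(32,),
        )
        cks = train_sweep(ds, cfg, seed=0)
        model = DIBModel.build(ds, cfg, np.random.default_rng(0))
        points = info_plane(
            cks, ds, model, EvalConfig(n_mc_exact=4000, n_label_samples=8, seed=0)
        )
        return table, ds, cks, points

    def test_one_point_per_checkpoint_sorted(self, tiny_run):
        _, _, cks, points = tiny_run
        assert len(points) == len(cks)
        totals = [p.total_bits for p in points]
        assert totals == sorted(totals)

    def test_fresh_model_sits_at_the_origin(self, tiny_run):
        _, _, _, points = tiny_run
        first = points[0]  # earliest checkpoint: strong bottleneck
        assert abs(first.total_bits) < 0.05
        # the vertical axis is a lower bound on I(U;Y): near zero from below
        # at the start (exactly zero once the decoder matches the marginal)
        assert first.predictive_bits < 0.05
        assert all(p.predictive_bits > -0.2 for p in points)

    def test_final_point_reaches_output_entropy(self, tiny_run):
        table, _, _, points = tiny_run
        assert points[-1].predictive_bits == pytest.approx(table.output_entropy(), abs=0.05)

    def test_empty_checkpoint_list_rejected(self, tiny_run):
        _, ds, _, _ = tiny_run
        with pytest.raises(ValueError):
            info_plane([], ds, None)


class TestAllocationHeatmap:
    def test_single_point(self):
        hm = allocation_heatmap([_point([0.5, 0.1])])
        assert hm.matrix.shape == (2, 1)
        np.testing.assert_allclose(hm.matrix[:, 0], [0.5, 0.1])

    def test_column_sums_conserve_total_information(self):
        pts = [_point([0.5, 0.1]), _point([1.0, 0.7]), _point([0.0, 0.2])]
        hm = allocation_heatmap(pts)
        np.testing.assert_allclose(hm.matrix.sum(axis=0), hm.total_bits, atol=1e-9)
        assert np.all(np.diff(hm.total_bits) >= 0)

    def test_inconsistent_features_rejected(self):
        with pytest.raises(ValueError):
            allocation_heatmap([_point([0.5], ids=["a"]), _point([0.5], ids=["b"])])


class TestInformativeSubsets:
    def test_threshold_selects_expected_features(self):
        p = _point([0.5, 0.05, 0.2])
        assert informative_subsets(p, 0.1) == {"x1", "x3"}

    def test_all_zero_allocation(self):
        assert informative_subsets(_point([0.0, 0.0])) == set()

    def test_zero_threshold_takes_positives(self):
        p = _point([0.3, 0.0, 1e-4])
        assert informative_subsets(p, 0.0) == {"x1", "x3"}


class TestDistinguishabilityMatrix:
    def test_prior_channel_gives_zero_matrix(self):
        ch = _StubChannel(lambda v: (np.zeros((len(v), 2)), np.ones((len(v), 2))))
        dm = distinguishability_matrix(ch, np.linspace(0, 1, 8))
        np.testing.assert_allclose(dm.matrix, 0.0, atol=1e-12)

    def test_well_separated_values_fully_distinguishable(self):
        ch = _StubChannel(
            lambda v: (np.where(v[:, None] > 0.5, 10.0, -10.0), np.full((len(v), 1), 0.01))
        )
        dm = distinguishability_matrix(ch, np.array([0.0, 1.0]))
        assert dm.matrix[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_closed_form_equal_scales(self):
        """means 0 and 2, unit scales: 1 - exp(-4/8) = 0.3935 (quadrature-checked)."""
        ch = _StubChannel(lambda v: (v[:, None] * 2.0, np.ones((len(v), 1))))
        dm = distinguishability_matrix(ch, np.array([0.0, 1.0]))
        assert dm.matrix[0, 1] == pytest.approx(1.0 - np.exp(-0.5), abs=1e-9)
        # independent check: Bhattacharyya coefficient by numerical integration
        from scipy.integrate import quad
        from scipy.stats import norm

        bc, _ = quad(
            lambda u: np.sqrt(norm.pdf(u, 0.0, 1.0) * norm.pdf(u, 2.0, 1.0)), -20, 20
        )
        assert dm.matrix[0, 1] == pytest.approx(1.0 - bc, abs=1e-7)

    def test_symmetry_zero_diagonal_and_range(self):
        rng = np.random.default_rng(0)
        ch = _StubChannel(
            lambda v: (rng.normal(size=(len(v), 3)), np.exp(rng.normal(size=(len(v), 3))))
        )
        dm = distinguishability_matrix(ch, np.linspace(-1, 1, 6))
        np.testing.assert_allclose(dm.matrix, dm.matrix.T)
        np.testing.assert_array_equal(np.diag(dm.matrix), 0.0)
        assert np.all((dm.matrix >= 0) & (dm.matrix <= 1))

    def test_monotone_rows_for_threshold_channel(self):
        """A threshold-like channel yields distinguishability that grows away from the diagonal."""
        ch = _StubChannel(
            lambda v: (np.tanh(4 * (v[:, None] - 0.5)) * 3, np.full((len(v), 1), 0.3))
        )
        dm = distinguishability_matrix(ch, np.linspace(0, 1, 16))
        row = dm.matrix[0]
        assert np.all(np.diff(row[1:]) >= -1e-9)


class TestDetectThreshold:
    def _block_matrix(self, m, cut, within=0.0, between=1.0, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        mat = np.full((m, m), within)
        mat[:cut, cut:] = between
        mat[cut:, :cut] = between
        mat += noise * rng.random((m, m))
        mat = 0.5 * (mat + mat.T)
        np.fill_diagonal(mat, 0.0)
        return DistinguishabilityMatrix(grid=np.arange(m, dtype=float), matrix=np.clip(mat, 0, 1))

    def test_ideal_two_block(self):
        dm = self._block_matrix(6, 3)
        ts = detect_threshold(dm)
        assert ts.cut_index == 3
        assert ts.cutoff == pytest.approx(2.5)
        assert ts.error == pytest.approx(0.0, abs=1e-12)
        assert ts.within_mean == pytest.approx(0.0)
        assert ts.between_mean == pytest.approx(1.0)

    def test_all_zero_matrix_flagged_degenerate(self):
        dm = self._block_matrix(5, 2, within=0.0, between=0.0)
        ts = detect_threshold(dm)
        assert ts.degenerate
        assert ts.cutoff is None

    def test_noisy_matrix_matches_independent_scan(self):
        """The chosen cut equals a from-scratch exhaustive scan re-implementation."""
        dm = self._block_matrix(12, 7, within=0.1, between=0.8, noise=0.15, seed=3)
        ts = detect_threshold(dm)
        m = len(dm.grid)
        best_err, best_cut = np.inf, None
        for c in range(1, m):
            groups = (np.arange(m) >= c).astype(int)
            err = 0.0
            for gi in (0, 1):
                for gj in (0, 1):
                    vals = [
                        dm.matrix[i, j]
                        for i in range(m)
                        for j in range(m)
                        if i != j and groups[i] == gi and groups[j] == gj
                    ]
                    if vals:
                        err += np.sum((np.array(vals) - np.mean(vals)) ** 2)
            if err < best_err - 1e-12:
                best_err, best_cut = err, c
        assert ts.cut_index == best_cut

    def test_too_small_grid_rejected(self):
        dm = DistinguishabilityMatrix(grid=np.array([0.0, 1.0]), matrix=np.zeros((2, 2)))
        with pytest.raises(ValueError):
            detect_threshold(dm)


class TestConditionalHistograms:
    def _ds(self, x0, x1):
        x = np.concatenate([x0, x1])
        y = np.concatenate([np.zeros(len(x0), int), np.ones(len(x1), int)])
        return TabularDataset(features=x[:, None], labels=y, feature_ids=["f"])

    def test_identical_distributions_overlap_near_one(self, rng):
        vals = rng.normal(size=4000)
        ds = self._ds(vals[:2000], vals[2000:])
        *_, overlap = conditional_histograms(ds, "f")
        assert overlap > 0.9

    def test_disjoint_supports_overlap_zero(self, rng):
        ds = self._ds(rng.normal(-10, 0.5, 500), rng.normal(10, 0.5, 500))
        *_, overlap = conditional_histograms(ds, "f")
        assert overlap == pytest.approx(0.0, abs=1e-12)

    def test_single_class_rejected(self):
        ds = TabularDataset(
            features=np.zeros((4, 1)), labels=np.zeros(4, int), feature_ids=["f"]
        )
        with pytest.raises(ValueError):
            conditional_histograms(ds, "f")

    def test_unknown_feature_rejected(self, rng):
        ds = self._ds(rng.normal(size=10), rng.normal(size=10))
        with pytest.raises(ValueError):
            conditional_histograms(ds, "nope")


def test_quantile_grid_spans_sample(rng):
    s = rng.normal(size=1000)
    g = quantile_grid(s, 16)
    assert g[0] == s.min() and g[-1] == s.max()
    assert np.all(np.diff(g) >= 0)
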