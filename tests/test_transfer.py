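"""Clipped grid prediction and the four transferability metrics."""

import numpy as np
import pandas as pd
import pytest

from reeftransfer import (
    NegativeBinomialGLM,
    build_predictor_set,
    grid_abs_difference,
    high_low_agreement,
    pct_within_tolerance,
    predict_grid_clipped,
    rescale_minmax,
    transfer_report,
)


def _grid(predicted, clipped=None, node_ids=None):
    n = len(predicted)
    return pd.DataFrame({
        "node_id": node_ids if node_ids is not None else np.arange(n),
        "longitude": np.linspace(145, 146, n),
        "latitude": np.linspace(-18, -17, n),
        "predicted": np.asarray(predicted, dtype=float),
        "se": np.zeros(n),
        "clipped": np.zeros(n, bool) if clipped is None else np.asarray(clipped),
    })


@pytest.fixture(scope="module")
def reference_fit():
    rng = np.random.default_rng(0)
    raw = pd.DataFrame({"SST_av": rng.uniform(20, 30, 120)})
    pset = build_predictor_set(raw, ["SST_av"], quadratic=[])
    mu = np.exp(3.0 + 0.3 * pset.data["SST_av"])
    y = rng.negative_binomial(5.0, 5.0 / (5.0 + mu))
    fit = NegativeBinomialGLM().fit(pset.data, y)
    grid = pd.DataFrame({"node_id": np.arange(60),
                         "longitude": np.linspace(145, 146, 60),
                         "latitude": np.linspace(-18, -17, 60),
                         "SST_av": np.linspace(raw["SST_av"].min(),
                                               raw["SST_av"].max(), 60)})
    return fit, pset, grid, raw


class TestClippedPrediction:
    def test_identity_transfer_reproduces_in_sample_predictions(self, reference_fit):
        fit, pset, _, raw = reference_fit
        grid = raw.copy()
        grid["node_id"] = np.arange(len(raw))
        grid["longitude"] = 145.0
        grid["latitude"] = -18.0
        out = predict_grid_clipped(fit, pset, grid)
        assert not out["clipped"].any()
        assert np.allclose(out["predicted"], fit.predict(pset.data))

    def test_fully_shifted_predictor_clips_everything(self, reference_fit):
        fit, pset, grid, _ = reference_fit
        shifted = grid.copy()
        shifted["SST_av"] += 100.0
        out = predict_grid_clipped(fit, pset, shifted)
        assert out["clipped"].all()
        assert out["predicted"].isna().all()

    def test_hand_computed_exponential(self, reference_fit):
        fit, pset, _, _ = reference_fit
        toy = pd.DataFrame({"node_id": [0, 1, 2], "longitude": [145.0] * 3,
                            "latitude": [-18.0] * 3,
                            "SST_av": [pset.centres["SST_av"] + d for d in (-1.0, 0.0, 1.0)]})
        out = predict_grid_clipped(fit, pset, toy)
        b0, b1 = fit.coef_
        assert np.allclose(out["predicted"], np.exp(b0 + b1 * np.array([-1.0, 0.0, 1.0])))

    def test_provenance_columns(self, reference_fit):
        fit, pset, grid, _ = reference_fit
        out = predict_grid_clipped(fit, pset, grid,
                                   provenance={"scenario_id": "D", "model_id": "10"})
        assert (out["scenario_id"] == "D").all()


class TestGridDifference:
    def test_identical_grids(self):
        g = _grid([5.0, 10.0, 20.0])
        (m, s), (pm, ps) = grid_abs_difference(g, g)
        assert (m, s, pm, ps) == (0.0, 0.0, 0.0, 0.0)

    def test_hand_arithmetic(self):
        ref = _grid([100.0, 200.0])
        tra = _grid([110.0, 170.0])
        (m, s), (pm, ps) = grid_abs_difference(tra, ref)
        assert m == pytest.approx(20.0)
        assert s == pytest.approx(np.std([10.0, 30.0], ddof=1))  # ~14.1
        assert pm == pytest.approx(12.5)
        assert ps == pytest.approx(np.std([10.0, 15.0], ddof=1))  # ~3.5

    def test_restricted_to_jointly_unclipped(self):
        ref = _grid([1.0, 2.0, 3.0], clipped=[False, True, False])
        tra = _grid([1.0, 9.0, 3.0], clipped=[False, False, False])
        (m, _), _ = grid_abs_difference(tra, ref)
        assert m == 0.0

    def test_node_order_invariance(self):
        ref = _grid([1.0, 2.0, 3.0, 4.0])
        tra = _grid([2.0, 2.0, 4.0, 5.0])
        shuffled = tra.sample(frac=1, random_state=0)
        a = np.ravel(grid_abs_difference(tra, ref))
        b = np.ravel(grid_abs_difference(shuffled, ref))
        assert np.allclose(a, b)

    def test_disjoint_cells_rejected(self):
        ref = _grid([1.0, 2.0], clipped=[True, True])
        with pytest.raises(ValueError):
            grid_abs_difference(_grid([1.0, 2.0]), ref)


class TestWithinTolerance:
    def test_identical_grids_full_score(self):
        g = _grid([3.0, 6.0, 9.0])
        pct, excluded = pct_within_tolerance(g, g)
        assert pct == 100.0 and excluded == 0

    def test_boundary_inclusive(self):
        ref = _grid([100.0, 200.0])
        tra = _grid([110.0, 170.0])  # relative diffs exactly 0.10 and 0.15
        pct, _ = pct_within_tolerance(tra, ref, tolerance=0.15)
        assert pct == 100.0

    def test_zero_reference_cells_excluded(self):
        ref = _grid([0.0, 10.0])
        tra = _grid([5.0, 10.0])
        pct, excluded = pct_within_tolerance(tra, ref)
        assert excluded == 1 and pct == 100.0

    def test_monotone_in_tolerance(self):
        rng = np.random.default_rng(1)
        ref = _grid(rng.uniform(10, 100, 50))
        tra = _grid(rng.uniform(10, 100, 50))
        scores = [pct_within_tolerance(tra, ref, t)[0] for t in (0.05, 0.15, 0.5, 2.0)]
        assert scores == sorted(scores)


class TestRescale:
    def test_affine_example(self):
        assert rescale_minmax([0.0, 5.0, 10.0], 0.0, 100.0).tolist() == [0.0, 50.0, 100.0]

    def test_own_range_is_identity(self):
        v = np.array([2.0, 7.0, 4.0])
        assert np.allclose(rescale_minmax(v, 2.0, 7.0), v)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=30)
        out = rescale_minmax(v, -3.0, 11.0)
        manual = -3.0 + (v - v.min()) * 14.0 / (v.max() - v.min())
        assert np.allclose(out, manual)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            rescale_minmax([4.0, 4.0], 0.0, 1.0)


class TestHighLow:
    def test_affine_transform_agrees_fully(self):
        rng = np.random.default_rng(3)
        ref = _grid(rng.uniform(0, 50, 21))
        tra = _grid(2.0 + 3.0 * ref["predicted"])
        assert high_low_agreement(tra, ref) == 100.0

    def test_negated_pattern_agrees_nowhere(self):
        v = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0])
        ref = _grid(v)
        tra = _grid(v.max() + v.min() - v)
        # even cell count, all distinct: median classes flip exactly
        assert high_low_agreement(tra, ref) == 0.0

    def test_constant_grid_routed_as_error(self):
        with pytest.raises(ValueError):
            high_low_agreement(_grid([1.0, 1.0]), _grid([1.0, 2.0]))


class TestReport:
    def test_identity_transfer_suite(self, reference_fit):
        fit, pset, grid, _ = reference_fit
        ref_grid = predict_grid_clipped(fit, pset, grid)
        rep = transfer_report(ref_grid, ref_grid, scenario_id="D", response="TOTAL")
        assert rep.abs_diff == (0.0, 0.0)
        assert rep.pct_within == 100.0
        assert rep.high_low == 100.0
        assert rep.n_cells == len(grid)

    def test_degenerate_validation_routed_to_notes(self):
        g = _grid([1.0, 2.0, 3.0])
        rep = transfer_report(g, g, observed=[1.0, 2.0, 3.0],
                              predicted_at_sites=[4.0, 4.0, 4.0])
        assert rep.val_r2 is None
        assert any("validation" in n for n in rep.notes)
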