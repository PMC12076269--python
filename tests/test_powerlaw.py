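"""Power-law model, SSE objective and grid-search landscape."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemuq import (
    GridConfig,
    PowerLawParams,
    REFERENCE_PARAMS,
    ShearDataset,
    ShearRecord,
    min_sse_per_c,
    predict_hi,
    prediction_spread_within_margin,
    run_grid_search,
    sse,
)
from hemuq.powerlaw import PerCMin, SSELandscape


class TestPredictHI:
    @pytest.mark.parametrize(
        "params, tau, t, expected",
        [
            (PowerLawParams(1.0, 1.0, 1.0), 2.0, 3.0, 6.0),
            (PowerLawParams(0.5, 2.0, 1.0), 0.0, 1.0, 0.0),  # zero-stress limit
            # frozen from a 60-digit arbitrary-precision evaluation of
            # 1.228e-5 * 320**1.9918 * 1.48**0.6606
            (REFERENCE_PARAMS, 320.0, 1.48, 1.5539283240497112),
        ],
    )
    def test_point_values(self, params, tau, t, expected):
        assert predict_hi(params, tau, t) == pytest.approx(expected, rel=1e-12)

    def test_domain_errors(self):
        p = PowerLawParams(1.0, 0.5, 0.5)
        with pytest.raises(ValueError):
            predict_hi(p, -1.0, 1.0)
        with pytest.raises(ValueError):
            predict_hi(p, 1.0, -1.0)
        with pytest.raises(ValueError):
            predict_hi(PowerLawParams(1.0, 1.0, -1.0), 0.0, 1.0)
        with pytest.raises(ValueError):
            PowerLawParams(-1.0, 1.0, 1.0)

    @settings(deadline=None, derandomize=True)
    @given(
        k=st.floats(1e-3, 1e3),
        tau=st.floats(1e-2, 400.0),
        t=st.floats(1e-3, 2.0),
    )
    def test_scale_law_in_c(self, k, tau, t):
        """Scaling C by k scales the prediction by exactly k."""
        base = predict_hi(REFERENCE_PARAMS, tau, t)
        scaled = predict_hi(
            PowerLawParams(
                REFERENCE_PARAMS.c_coeff * k,
                REFERENCE_PARAMS.alpha,
                REFERENCE_PARAMS.beta,
            ),
            tau,
            t,
        )
        assert scaled == pytest.approx(k * base, rel=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(k=st.floats(0.2, 5.0), tau0=st.floats(10.0, 400.0))
    def test_c_beta_compensation_degeneracy(self, k, tau0):
        """At one operating point, C*k with beta - ln(k)/ln(tau0) is exact
        compensation — the root cause of the flat SSE minimum."""
        t0 = 0.5
        p = REFERENCE_PARAMS
        q = PowerLawParams(
            p.c_coeff * k, p.alpha, p.beta - np.log(k) / np.log(tau0)
        )
        assert predict_hi(q, tau0, t0) == pytest.approx(
            predict_hi(p, tau0, t0), rel=1e-10
        )

    def test_monotone_in_stress_and_time(self):
        taus = np.linspace(10, 300, 7)
        hi = predict_hi(REFERENCE_PARAMS, taus, 1.0)
        assert np.all(np.diff(hi) > 0)
        ts = np.linspace(0.05, 1.4, 7)
        hi = predict_hi(REFERENCE_PARAMS, 100.0, ts)
        assert np.all(np.diff(hi) > 0)


class TestSSE:
    def test_zero_on_self_generated_data(self, noisefree_dataset):
        assert sse(REFERENCE_PARAMS, noisefree_dataset) == 0.0

    def test_single_record_residual(self):
        ds = ShearDataset([ShearRecord(0.0, 1.0, 1.0)])
        assert sse(PowerLawParams(1.0, 1.0, 2.0), ds) == 1.0

    def test_matches_bruteforce_enumeration(self):
        """3-record toy set: SSE equals the hand-enumerated residual sum."""
        p = PowerLawParams(0.1, 0.5, 1.0)
        records = [(10.0, 0.25, 0.6), (50.0, 1.0, 4.5), (100.0, 0.04, 2.1)]
        expected = sum(
            (hi - 0.1 * tau**1.0 * t**0.5) ** 2 for tau, t, hi in records
        )
        ds = ShearDataset([ShearRecord(*r) for r in records])
        assert sse(p, ds) == pytest.approx(expected, rel=1e-14)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            ShearDataset([])


def _bruteforce_landscape(dataset, grid):
    """Independent scalar triple loop over all grid nodes."""
    out = np.empty(grid.shape)
    for i, c in enumerate(grid.c_values):
        for j, a in enumerate(grid.alpha_values):
            for k, b in enumerate(grid.beta_values):
                pred = c * dataset.tau**b * dataset.t_exp**a
                out[i, j, k] = np.sum((dataset.hi - pred) ** 2)
    return out


class TestGridSearch:
    def test_combination_count_and_shape(self, noisy_dataset):
        grid = GridConfig(
            c_values=np.geomspace(1e-6, 1e-4, 3),
            alpha_values=np.linspace(0.4, 0.9, 4),
            beta_values=np.linspace(1.5, 2.5, 5),
        )
        land = run_grid_search(noisy_dataset, grid)
        assert land.n_combinations == 3 * 4 * 5
        assert land.sse.shape == grid.shape

    def test_single_node_grid(self, noisy_dataset):
        grid = GridConfig(
            c_values=np.array([1.228e-5]),
            alpha_values=np.array([0.6606]),
            beta_values=np.array([1.9918]),
        )
        land = run_grid_search(noisy_dataset, grid)
        assert land.sse.shape == (1, 1, 1)
        assert land.sse[0, 0, 0] == sse(REFERENCE_PARAMS, noisy_dataset)
        assert land.global_min[1] == land.sse[0, 0, 0]

    def test_equals_bruteforce_triple_loop_exactly(self, noisy_dataset):
        grid = GridConfig(
            c_values=np.geomspace(5e-6, 5e-5, 4),
            alpha_values=np.linspace(0.3, 1.0, 5),
            beta_values=np.linspace(1.5, 2.4, 5),
        )
        land = run_grid_search(noisy_dataset, grid)
        brute = _bruteforce_landscape(noisy_dataset, grid)
        assert np.array_equal(land.sse, brute)

    def test_recovers_generating_node(self, noisefree_dataset):
        """On noise-free data whose truth lies on a grid node, the global
        argmin is the generating node."""
        grid = GridConfig(
            c_values=np.array([0.5e-5, 1.228e-5, 5e-5]),
            alpha_values=np.array([0.3, 0.6606, 0.9]),
            beta_values=np.array([1.5, 1.9918, 2.3]),
        )
        land = run_grid_search(noisefree_dataset, grid)
        params, val = land.global_min
        assert val == 0.0
        assert params == REFERENCE_PARAMS

    def test_invalid_axes_rejected(self):
        with pytest.raises(ValueError):
            GridConfig(
                c_values=np.array([2e-5, 1e-5]),  # not increasing
                alpha_values=np.array([0.5]),
                beta_values=np.array([2.0]),
            )
        with pytest.raises(ValueError):
            GridConfig(
                c_values=np.array([]),
                alpha_values=np.array([0.5]),
                beta_values=np.array([2.0]),
            )


class TestPerCMin:
    def test_partition_property(self, noisy_dataset):
        """Min over per-C entries equals the global minimum."""
        grid = GridConfig(
            c_values=np.geomspace(1e-6, 1e-4, 5),
            alpha_values=np.linspace(0.2, 1.0, 9),
            beta_values=np.linspace(1.2, 2.5, 9),
        )
        land = run_grid_search(noisy_dataset, grid)
        entries = min_sse_per_c(land)
        assert len(entries) == 5
        assert min(e.sse for e in entries) == land.global_min[1]
        assert all(e.sse >= land.global_min[1] for e in entries)

    def test_matches_exhaustive_scan(self, noisy_dataset):
        grid = GridConfig(
            c_values=np.array([1e-5, 1e-4]),
            alpha_values=np.linspace(0.4, 0.9, 2),
            beta_values=np.linspace(1.8, 2.2, 2),
        )
        land = run_grid_search(noisy_dataset, grid)
        brute = _bruteforce_landscape(noisy_dataset, grid)
        for k, entry in enumerate(min_sse_per_c(land)):
            assert entry.sse == brute[k].min()


class TestPredictionSpread:
    def _toy_landscape(self):
        grid = GridConfig(
            c_values=np.array([1.0, 2.0, 3.0]),
            alpha_values=np.array([1.0]),
            beta_values=np.array([1.0]),
        )
        sse_vals = np.array([1.0, 1.05, 2.0]).reshape(3, 1, 1)
        gm = (PowerLawParams(1.0, 1.0, 1.0), 1.0)
        per_c = [
            PerCMin(c, float(s), 1.0, 1.0)
            for c, s in zip(grid.c_values, sse_vals.ravel())
        ]
        return SSELandscape(axes=grid, sse=sse_vals, global_min=gm, per_c_min=per_c)

    def test_zero_margin_unique_minimum(self):
        land = self._toy_landscape()
        lo, hi, dev = prediction_spread_within_margin(
            land, lambda p: 10.0 * p.c_coeff, margin=0.0
        )
        assert (lo, hi, dev) == (10.0, 10.0, 0.0)

    def test_enumerated_extremes(self):
        """Hand-assigned sse/mih values: margin 10% admits nodes 1 and 2."""
        land = self._toy_landscape()
        lo, hi, dev = prediction_spread_within_margin(
            land, lambda p: 10.0 * p.c_coeff, margin=0.10
        )
        assert (lo, hi) == (10.0, 20.0)
        assert dev == pytest.approx(1.0)  # |20-10|/10

    def test_monotone_in_margin(self):
        land = self._toy_landscape()
        mih_fn = lambda p: 10.0 * p.c_coeff  # noqa: E731
        prev_lo, prev_hi, prev_dev = prediction_spread_within_margin(
            land, mih_fn, 0.0
        )
        for margin in (0.05, 0.10, 1.5):
            lo, hi, dev = prediction_spread_within_margin(land, mih_fn, margin)
            assert lo <= prev_lo and hi >= prev_hi and dev >= prev_dev
            prev_lo, prev_hi, prev_dev = lo, hi, dev

    def test_negative_margin_rejected(self):
        with pytest.raises(ValueError):
            prediction_spread_within_margin(
                self._toy_landscape(), lambda p: 1.0, -0.1
            )
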