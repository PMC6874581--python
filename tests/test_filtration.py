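"""OPP boundary fitting and virtual-core selection."""

import numpy as np
import pandas as pd
import pytest

from coreflow import filtration as flt


def make_bead_events(rng, n=500, anchor=(3.0, 2.5), slope_lo=0.6, slope_hi=1.2,
                     noise=0.0, spread=1.0):
    """Beads exactly on (or scattered around) a two-piece line through the anchor."""
    x0, y0 = anchor
    lx = x0 + rng.uniform(-spread, spread, n)
    ly = np.where(lx < x0, y0 + slope_lo * (lx - x0), y0 + slope_hi * (lx - x0))
    ly = ly + noise * rng.standard_normal(n)
    return pd.DataFrame({
        "d1": 10.0 ** ly, "d2": 10.0 ** ly, "fsc": 10.0 ** lx,
        "red": 1.0, "orange": 1.0,
    })


def pinball_loss(x, y, x0, y0, slope, tau):
    r = (y - y0) - slope * (x - x0)
    return np.sum(np.where(r >= 0, tau * r, (tau - 1) * r))


class TestAnchoredQuantileSlope:
    def test_exact_line_recovered(self, rng):
        ev = make_bead_events(rng, slope_lo=0.5, slope_hi=0.5)
        params = flt.fit_filtration_params(ev, np.ones(len(ev), bool))
        assert params.slopes[("d1", "below", 50.0)] == pytest.approx(0.5, abs=0.01)
        assert params.slopes[("d1", "above", 50.0)] == pytest.approx(0.5, abs=0.01)

    def test_two_piece_slopes_differ(self, rng):
        ev = make_bead_events(rng, slope_lo=0.6, slope_hi=1.2, noise=0.01)
        params = flt.fit_filtration_params(ev, np.ones(len(ev), bool))
        assert params.slopes[("d2", "below", 50.0)] == pytest.approx(0.6, abs=0.05)
        assert params.slopes[("d2", "above", 50.0)] == pytest.approx(1.2, abs=0.05)

    @pytest.mark.parametrize("tau", [0.025, 0.5, 0.975])
    @pytest.mark.parametrize("side", [-1, 1])
    def test_matches_pinball_grid_search(self, rng, tau, side):
        """The weighted-quantile solution must minimize the pinball loss.

        Oracle: brute-force minimization over a slope grid of step 1e-3.
        """
        n = 200
        x0, y0 = 1.0, 0.5
        x = x0 + side * rng.uniform(0.05, 1.0, n)
        y = y0 + 0.8 * (x - x0) + 0.2 * rng.standard_normal(n)
        fitted = flt.anchored_quantile_slope(x, y, x0, y0, tau)
        grid = np.arange(-2.0, 4.0, 1e-3)
        losses = np.array([pinball_loss(x, y, x0, y0, b, tau) for b in grid])
        best = grid[np.argmin(losses)]
        assert pinball_loss(x, y, x0, y0, fitted, tau) <= losses.min() + 1e-9
        assert fitted == pytest.approx(best, abs=1.1e-3)

    def test_quantile_subset(self, rng):
        ev = make_bead_events(rng)
        params = flt.fit_filtration_params(ev, np.ones(len(ev), bool),
                                           quantiles=(50.0,))
        assert params.quantiles == (50.0,)
        assert set(q for (_, _, q) in params.slopes) == {50.0}

    def test_too_few_beads_raises(self, rng):
        ev = make_bead_events(rng, n=40)
        with pytest.raises(ValueError, match="50 bead"):
            flt.fit_filtration_params(ev, np.ones(len(ev), bool))

    def test_degenerate_cloud_raises(self):
        ev = pd.DataFrame({"d1": np.full(100, 10.0), "d2": np.full(100, 10.0),
                           "fsc": np.full(100, 100.0), "red": 1.0, "orange": 1.0})
        with pytest.raises(ValueError, match="degenerate"):
            flt.fit_filtration_params(ev, np.ones(100, bool))


class TestBoundary:
    def test_segments_meet_exactly_at_anchor(self, rng):
        ev = make_bead_events(rng, slope_lo=0.6, slope_hi=1.3, noise=0.05)
        params = flt.fit_filtration_params(ev, np.ones(len(ev), bool))
        for det in ("d1", "d2"):
            for q in params.quantiles:
                below = params.boundary(det, q, params.bead_fsc - 1e-300)
                at = params.boundary(det, q, params.bead_fsc)
                assert below == at

    def test_quantile_boundaries_nested(self, rng):
        ev = make_bead_events(rng, noise=0.1)
        params = flt.fit_filtration_params(ev, np.ones(len(ev), bool))
        x = np.linspace(params.bead_fsc - 2, params.bead_fsc + 2, 101)
        for det in ("d1", "d2"):
            b_lo = params.boundary(det, 2.5, x)
            b_med = params.boundary(det, 50.0, x)
            b_hi = params.boundary(det, 97.5, x)
            assert np.all(b_lo <= b_med + 1e-12)
            assert np.all(b_med <= b_hi + 1e-12)


class TestSelectOpp:
    @pytest.fixture()
    def params(self, rng):
        ev = make_bead_events(rng, noise=0.08)
        return flt.fit_filtration_params(ev, np.ones(len(ev), bool))

    def test_anchor_particle_accepted_at_9750(self, params):
        ev = pd.DataFrame({"d1": [10.0 ** params.bead_d1],
                           "d2": [10.0 ** params.bead_d2],
                           "fsc": [10.0 ** params.bead_fsc],
                           "red": [1.0], "orange": [1.0]})
        assert len(flt.select_opp(ev, params, 97.5)) == 1

    def test_misaligned_particle_rejected_everywhere(self, params):
        ev = pd.DataFrame({"d1": [10.0 ** (params.bead_d1 + 3)],
                           "d2": [10.0 ** (params.bead_d2 - 3)],
                           "fsc": [10.0 ** params.bead_fsc],
                           "red": [1.0], "orange": [1.0]})
        for q in (2.5, 50.0, 97.5):
            assert len(flt.select_opp(ev, params, q)) == 0

    def test_vectorized_equals_scalar_reference(self, params, rng):
        """Brute-force oracle: per-row scalar re-evaluation of the predicates."""
        n = 10_000
        ev = pd.DataFrame({
            "d1": 10.0 ** rng.uniform(0, 5, n),
            "d2": 10.0 ** rng.uniform(0, 5, n),
            "fsc": 10.0 ** rng.uniform(1, 5, n),
            "red": np.ones(n), "orange": np.ones(n)})
        got = set(flt.select_opp(ev, params, 50.0).index)
        expected = set()
        for i in range(n):
            l1 = np.log10(ev.at[i, "d1"])
            l2 = np.log10(ev.at[i, "d2"])
            lx = np.log10(ev.at[i, "fsc"])
            seg = "below" if lx < params.bead_fsc else "above"
            b1 = params.bead_d1 + params.slopes[("d1", seg, 50.0)] * (lx - params.bead_fsc)
            b2 = params.bead_d2 + params.slopes[("d2", seg, 50.0)] * (lx - params.bead_fsc)
            if (abs(l1 - l2) <= params.alignment_tol and l1 <= b1 and l2 <= b2):
                expected.add(i)
        assert got == expected

    def test_quantile_nesting_on_random_tables(self, params, rng):
        for _ in range(5):
            n = 2000
            ev = pd.DataFrame({
                "d1": 10.0 ** rng.uniform(0, 5, n),
                "d2": 10.0 ** rng.uniform(0, 5, n),
                "fsc": 10.0 ** rng.uniform(1, 5, n),
                "red": np.ones(n), "orange": np.ones(n)})
            sets = {q: set(flt.select_opp(ev, params, q).index)
                    for q in (2.5, 50.0, 97.5)}
            assert sets[2.5] <= sets[50.0] <= sets[97.5]

    def test_scale_equivariance(self, params, rng):
        """A common channel rescaling plus matching anchor shift keeps membership."""
        from dataclasses import replace

        n = 3000
        ev = pd.DataFrame({
            "d1": 10.0 ** rng.uniform(0, 5, n),
            "d2": 10.0 ** rng.uniform(0, 5, n),
            "fsc": 10.0 ** rng.uniform(1, 5, n),
            "red": np.ones(n), "orange": np.ones(n)})
        k = 7.3
        scaled = ev.copy()
        for c in ("d1", "d2", "fsc"):
            scaled[c] = ev[c] * k
        shift = np.log10(k)
        shifted = replace(params, bead_fsc=params.bead_fsc + shift,
                          bead_d1=params.bead_d1 + shift,
                          bead_d2=params.bead_d2 + shift)
        a = flt.select_opp(ev, params, 50.0).index
        b = flt.select_opp(scaled, shifted, 50.0).index
        assert list(a) == list(b)

    def test_unknown_quantile_raises(self, params):
        ev = make_bead_events(np.random.default_rng(0))
        with pytest.raises(ValueError, match="quantile"):
            flt.select_opp(ev, params, 42.0)

    def test_nonpositive_rows_excluded(self, params):
        ev = pd.DataFrame({"d1": [0.0, 10 ** params.bead_d1],
                           "d2": [10.0, 10 ** params.bead_d2],
                           "fsc": [100.0, 10 ** params.bead_fsc],
                           "red": [1.0, 1.0], "orange": [1.0, 1.0]})
        out = flt.select_opp(ev, params, 97.5)
        assert 0 not in out.index


class TestOppRatio:
    def test_simple_fraction(self):
        events = pd.DataFrame({"d1": np.ones(1000)})
        opp = events.iloc[:100]
        assert flt.opp_ratio(opp, events) == 0.1
        assert flt.opp_ratio(events, events) == 1.0

    def test_empty_events_raises(self):
        with pytest.raises(ValueError):
            flt.opp_ratio(pd.DataFrame(), pd.DataFrame())

    def test_ratio_monotone_in_quantile(self, sim3, processed3):
        params = processed3.filtration
        for fid, ev in sim3.events.items():
            ratios = [flt.opp_ratio(flt.select_opp(ev, params, q), ev)
                      for q in (2.5, 50.0, 97.5)]
            assert ratios[0] <= ratios[1] <= ratios[2]


class TestVirtualCoreFilterEstimator:
    def test_fit_select_roundtrip(self, rng):
        ev = make_bead_events(rng, noise=0.05)
        est = flt.VirtualCoreFilter(quantile=50.0)
        est.fit(ev, bead_mask=np.ones(len(ev), bool))
        assert est.params_.filtration_id
        out = est.transform(ev)
        assert set(out.columns) >= {"d1", "d2", "fsc", "opp_quantile"}

    def test_requires_bead_mask(self, rng):
        with pytest.raises(ValueError, match="bead_mask"):
            flt.VirtualCoreFilter().fit(make_bead_events(rng))

    def test_filtration_id_deterministic(self, rng):
        ev = make_bead_events(rng, noise=0.05)
        mask = np.ones(len(ev), bool)
        p1 = flt.fit_filtration_params(ev, mask)
        p2 = flt.fit_filtration_params(ev, mask)
        assert p1.filtration_id == p2.filtration_id
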