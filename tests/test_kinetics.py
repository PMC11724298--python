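import numpy as np
import pandas as pd
import pytest

from overstretch.detect import Dwell
from overstretch.kinetics import (
    RateTable,
    attempt_rate,
    barrier_per_bp,
    fit_bell_evans,
    force_densities,
    hazard_rates,
    rates_from_survival,
    survival_curves,
    transition_counts,
)
from overstretch.model import DEFAULT_KBT, EQUILIBRIUM_TABLE, KINETICS_TABLE, bell_evans_rate


def _constant_hazard_dwells(k, r, f0=55.0, f_max=72.0, n=4000, seed=0, state="B"):
    """Dwells with a force-independent exit rate under a ramp of loading
    rate r: exit forces are f0 + Exp(scale = r/k), censored at f_max."""
    rng = np.random.default_rng(seed)
    exits = f0 + rng.exponential(r / k, n)
    observed = exits < f_max
    exits = np.minimum(exits, f_max)
    return [
        Dwell(i, state, f0, float(e), "transition" if o else "censored", 1)
        for i, (e, o) in enumerate(zip(exits, observed))
    ]


class TestForceDensities:
    def test_normalized_to_unit_area(self, noisy_detection):
        det, _, _ = noisy_detection
        dens = force_densities(det.events)
        for centers, rho in dens.values():
            assert np.trapezoid(rho, centers) == pytest.approx(1.0, abs=1e-6)

    def test_peaks_near_transition_force(self, noisy_detection):
        det, _, _ = noisy_detection
        dens = force_densities(det.events, bin_width=0.5)
        for centers, rho in dens.values():
            assert abs(centers[np.argmax(rho)] - 63.7) <= 0.75

    def test_too_few_events(self):
        ev = pd.DataFrame(
            {"cycle": [0], "time_s": [0.0], "direction": ["B->S"],
             "force_pN": [63.7], "delta_x_nm": [10.8]}
        )
        with pytest.raises(ValueError):
            force_densities(ev, min_events=2)


class TestSurvivalCurves:
    def test_hand_computed_product_limit(self):
        """Three uncensored B dwells entered at 55 pN exiting at 62, 63 and
        64 pN step the survival 1 -> 2/3 -> 1/3 -> 0."""
        dwells = [
            Dwell(0, "B", 55.0, 62.0, "transition", 1),
            Dwell(1, "B", 55.0, 63.0, "transition", 1),
            Dwell(2, "B", 55.0, 64.0, "transition", 1),
        ]
        s = survival_curves(dwells)["B"]
        assert np.allclose(s.forces, [62.0, 63.0, 64.0])
        assert np.allclose(s.survival, [2 / 3, 1 / 3, 0.0])
        assert s(61.9) == 1.0
        assert s(63.5) == pytest.approx(1 / 3)

    def test_left_truncation_shrinks_risk_set(self):
        dwells = [
            Dwell(0, "B", 55.0, 62.0, "transition", 1),
            Dwell(1, "B", 62.5, 63.0, "transition", 1),  # enters after first exit
        ]
        s = survival_curves(dwells)["B"]
        # each event sees a risk set of one
        assert np.allclose(s.at_risk, [1, 1])
        assert np.allclose(s.survival, [0.0, 0.0])

    def test_agrees_with_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(7)
        entries = 55 + rng.uniform(0, 3, 300)
        exits = entries + rng.exponential(2.0, 300)
        observed = exits < 68
        exits = np.minimum(exits, 68)
        dwells = [
            Dwell(i, "B", float(a), float(b), "transition" if o else "censored", 1)
            for i, (a, b, o) in enumerate(zip(entries, exits, observed))
        ]
        ours = survival_curves(dwells)["B"]
        kmf = lifelines.KaplanMeierFitter()
        kmf.fit(exits, observed, entry=entries)
        grid = np.linspace(56, 67.5, 40)
        theirs = kmf.survival_function_at_times(grid).to_numpy()
        assert np.allclose(ours(grid), theirs, atol=1e-10)

    def test_constant_hazard_matches_analytic(self):
        k, r = 3.0, 5.0
        s = survival_curves(_constant_hazard_dwells(k, r))["B"]
        grid = np.linspace(56, 66, 30)
        assert np.allclose(s(grid), np.exp(-k * (grid - 55.0) / r), atol=0.03)

    def test_all_censored_warns_and_stays_at_one(self):
        dwells = [Dwell(i, "B", 55.0, 72.0, "censored", 1) for i in range(5)]
        with pytest.warns(UserWarning, match="censored"):
            s = survival_curves(dwells)["B"]
        assert s(60.0) == 1.0


class TestRates:
    def test_constant_hazard_flat_rates(self):
        k, r = 3.0, 5.0
        dwells = _constant_hazard_dwells(k, r)
        rates = hazard_rates(dwells, r, bin_width=0.5)["B"]
        sel = rates.n_events >= 200  # counting error below ~7%
        assert sel.sum() >= 5
        assert np.all(np.abs(rates.rate[sel] / k - 1) < 0.10)

    def test_hazard_transform_from_density_and_survival(self):
        k, r = 3.0, 5.0
        dwells = _constant_hazard_dwells(k, r)
        curve = survival_curves(dwells)["B"]
        exits = np.array([d.exit_force for d in dwells if d.exit_kind == "transition"])
        bw = 0.5
        edges = np.arange(55, 70 + bw, bw)
        counts, _ = np.histogram(exits, bins=edges)
        centers = edges[:-1] + bw / 2
        rho = counts / counts.sum() / bw
        rt = rates_from_survival((centers, rho), curve, r, n_total_events=counts.sum())
        sel = rt.n_events >= 200
        assert sel.sum() >= 5
        assert np.all(np.abs(rt.rate[sel] / k - 1) < 0.10)

    def test_zero_density_bin_zero_rate(self):
        curve = survival_curves(_constant_hazard_dwells(3.0, 5.0))["B"]
        centers = np.array([56.0, 56.5])
        rho = np.array([1.0, 0.0])
        rt = rates_from_survival((centers, rho), curve, 5.0, n_total_events=100)
        assert 56.5 not in rt.centers  # empty bin dropped

    def test_survival_below_cut_everywhere(self):
        k, r = 50.0, 5.0  # survival collapses within the first bin
        dwells = _constant_hazard_dwells(k, r, n=500)
        curve = survival_curves(dwells)["B"]
        centers = np.array([60.0, 61.0])
        rho = np.array([0.5, 0.5])
        with pytest.raises(ValueError, match="below cut"):
            rates_from_survival((centers, rho), curve, r, n_total_events=200)


class TestBellEvansFit:
    def test_exact_rates_recovered(self):
        """Noise-free Bell-Evans rate tables invert to the exact
        transition-state distances."""
        f = np.arange(62.0, 65.5, 0.25)
        kf = bell_evans_rate(f, 12.0, 63.7, 6.5, "B->S")
        kr = bell_evans_rate(f, 12.0, 63.7, 4.3, "S->B")
        mk = lambda k: RateTable(f, k, k * 0.01, np.full(len(f), 100), np.ones(len(f)))
        be = fit_bell_evans(mk(kf), mk(kr), 63.7, window=2.0, unstable_margin=None)
        assert be.x_b_ts == pytest.approx(6.5, rel=1e-3)
        assert be.x_s_ts == pytest.approx(4.3, rel=1e-3)
        assert be.f_cross == pytest.approx(63.7, abs=1e-6)
        assert be.k_at_ftr == pytest.approx(12.0, rel=1e-3)
        assert be.ok

    def test_zero_force_intercepts(self):
        f = np.arange(62.0, 65.5, 0.25)
        kf = bell_evans_rate(f, 12.0, 63.7, 6.5, "B->S")
        kr = bell_evans_rate(f, 12.0, 63.7, 4.3, "S->B")
        mk = lambda k: RateTable(f, k, k * 0.01, np.full(len(f), 100), np.ones(len(f)))
        be = fit_bell_evans(mk(kf), mk(kr), 63.7, window=2.0, unstable_margin=None)
        assert be.log_k0_forward == pytest.approx(
            np.log(12.0) - 63.7 * 6.5 / DEFAULT_KBT, rel=1e-3
        )
        assert be.log_k0_reverse == pytest.approx(
            np.log(12.0) + 63.7 * 4.3 / DEFAULT_KBT, rel=1e-3
        )

    def test_wrong_sign_flagged(self):
        f = np.arange(62.0, 65.5, 0.25)
        k_down = bell_evans_rate(f, 12.0, 63.7, 4.3, "S->B")
        mk = lambda k: RateTable(f, k, k * 0.01, np.full(len(f), 100), np.ones(len(f)))
        be = fit_bell_evans(mk(k_down), mk(k_down), 63.7, window=2.0, unstable_margin=None)
        assert not be.ok

    def test_too_few_bins(self):
        f = np.array([63.5, 63.75])
        mk = RateTable(f, np.array([1.0, 2.0]), np.array([0.1, 0.1]),
                       np.array([10, 10]), np.ones(2))
        with pytest.raises(ValueError, match="rate bins"):
            fit_bell_evans(mk, mk, 63.7)


class TestTransitionCounts:
    def test_zero_event_cycles_counted(self):
        ev = pd.DataFrame(
            {"cycle": [0, 0, 2], "time_s": [0.1, 0.2, 0.3],
             "direction": ["B->S", "S->B", "B->S"],
             "force_pN": [63.0, 63.5, 64.0], "delta_x_nm": [10.8, 10.4, 10.5]}
        )
        out = transition_counts(ev, n_cycles=4)
        assert out["N"] == pytest.approx(3 / 4)
        assert len(out["per_cycle"]) == 4

    def test_empty_events(self):
        ev = pd.DataFrame(columns=["cycle", "time_s", "direction", "force_pN", "delta_x_nm"])
        assert transition_counts(ev, n_cycles=3)["N"] == 0.0


class TestBarrierScaling:
    def test_two_construct_ratio(self):
        """2.6-fold more transitions for 8.7 fewer transitioning bps gives
        the ~0.11 kBT/bp barrier."""
        g_ts, _ = barrier_per_bp([47.2, 38.5], [25, 65])
        assert g_ts == pytest.approx(np.log(65 / 25) / 8.7, rel=1e-9)
        assert round(g_ts, 2) == 0.11

    def test_five_construct_regression(self):
        names = ["Unmodified", "1tC", "2tC", "2tC-Stack", "3tC"]
        n = [EQUILIBRIUM_TABLE[x]["n"] for x in names]
        N = [KINETICS_TABLE[x]["N"] for x in names]
        g_ts, se = barrier_per_bp(n, N)
        assert round(g_ts, 2) == 0.11
        assert se > 0

    def test_equal_counts_zero_barrier(self):
        g_ts, _ = barrier_per_bp([47.0, 40.0, 35.0], [30, 30, 30])
        assert g_ts == pytest.approx(0.0, abs=1e-12)

    def test_equal_lengths_rejected(self):
        with pytest.raises(ValueError):
            barrier_per_bp([40.0, 40.0], [25, 65])


class TestAttemptRate:
    def test_barrier_undone(self):
        assert attempt_rate(1.0, 47.0, 0.1) == pytest.approx(np.exp(4.7), rel=1e-12)
        assert attempt_rate(10.0, 47.0, 0.1) == pytest.approx(10 * np.exp(4.7), rel=1e-12)

    def test_zero_barrier_identity(self):
        assert attempt_rate(3.0, 47.0, 0.0) == 3.0

    def test_log_space(self):
        assert attempt_rate(2.0, 50.0, 0.5, log_space=True) == pytest.approx(
            np.log(2.0) + 25.0
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            attempt_rate(-1.0, 47.0, 0.1)


def test_hazard_occupancy_consistency_within_counting_error(noisy_detection):
    """k_BS/(k_BS + k_SB) from the measured force-resolved rates tracks the
    equilibrium S occupancy near the transition force, within ~3x the
    binomial counting error of each bin (40-cycle fixture)."""
    from overstretch.model import two_state_ps

    det, _, protocol = noisy_detection
    rates = hazard_rates(det.dwells, protocol.loading_rate, 0.25)
    rb, rs = rates["B"], rates["S"]
    common = np.intersect1d(rb.centers, rs.centers)
    common = common[np.abs(common - 63.7) <= 1.0]
    mb = np.isin(rb.centers, common)
    ms = np.isin(rs.centers, common)
    kb, ks = rb.rate[mb], rs.rate[ms]
    tot = rb.n_events[mb] + rs.n_events[ms]
    occ = kb / (kb + ks)
    expect = two_state_ps(common, 63.7, 10.8)
    sigma = np.sqrt(np.clip(expect * (1 - expect), 0.05, None) / tot)
    assert len(occ) >= 4
    assert np.all(np.abs(occ - expect) < 3 * sigma + 0.02)
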