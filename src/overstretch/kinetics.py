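"""Force-resolved kinetics of the B-to-S transition.

The constant-velocity ramp converts residence times into residence force
intervals, so the transition kinetics can be read off the event and dwell
statistics:

* transition-force probability densities per direction;
* product-limit (Kaplan-Meier) survival curves of the B and S states in the
  force coordinate, with left truncation at each dwell's entry force and
  right censoring at the ramp ends;
* force-resolved rates ``k(F) = r * rho(F) / S(F)`` (hazard transform at
  loading rate ``r``), computed in practice as the occurrence/exposure
  estimator ``k = r * d_j / (Y_j * dF)`` pooled over stretch and release
  phases, which is the binned product-limit hazard increment;
* weighted log-linear (Bell-Evans) fits of the rates near the transition
  force, giving the transition-state distances ``X_B->TS`` and ``X_S->TS``,
  the crossing rate ``k(F_tr)`` and the zero-force extrapolations;
* transition counts per cycle, the per-bp barrier ``g_TS`` from the scaling
  of counts with duplex length, and the attempt rate
  ``k0_BS = k(F_tr) * exp(n * g_TS)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .detect import Dwell
from .model import DEFAULT_KBT

__all__ = [
    "KineticsResult",
    "BellEvansFit",
    "RateTable",
    "force_densities",
    "survival_curves",
    "rates_from_survival",
    "hazard_rates",
    "fit_bell_evans",
    "transition_counts",
    "barrier_per_bp",
    "attempt_rate",
    "analyze_kinetics",
]


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate in the force coordinate.

    ``forces`` are the distinct event coordinates (in traversal order),
    ``survival`` the Kaplan-Meier product after each, ``at_risk`` and
    ``n_events`` the risk set and event count at each step.  For
    release-phase strata the traversal coordinate is the *negated* force;
    ``forces`` are reported back on the physical axis.
    """

    forces: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def __call__(self, f):
        """Step-function evaluation S(f) (stretch-sense traversal)."""
        idx = np.searchsorted(self.forces, np.asarray(f, dtype=float), side="right")
        s = np.concatenate([[1.0], self.survival])
        out = s[idx]
        return out if out.ndim else float(out)


@dataclass
class RateTable:
    """Binned force-resolved transition rates for one direction."""

    centers: np.ndarray
    rate: np.ndarray
    rate_err: np.ndarray
    n_events: np.ndarray
    exposure_pN: np.ndarray


@dataclass
class BellEvansFit:
    """Log-linear force dependence of the two transition rates.

    Distances in nm (positive); ``f_cross``/``k_at_ftr`` locate the crossing
    of the two fitted lines; ``k0_forward``/``k0_reverse`` are the zero-force
    intercepts (extrapolation only — the ramp never probes low forces, so
    they carry no barrier-height information on their own).
    """

    x_b_ts: float
    x_b_ts_se: float
    x_s_ts: float
    x_s_ts_se: float
    f_cross: float
    k_at_ftr: float
    log_k0_forward: float
    log_k0_reverse: float
    ok: bool = True

    @property
    def x_bs(self) -> float:
        return self.x_b_ts + self.x_s_ts

    @property
    def ts_fraction(self) -> float:
        return 100.0 * self.x_b_ts / self.x_bs

    @property
    def k0_forward(self) -> float:
        return float(np.exp(self.log_k0_forward))

    @property
    def k0_reverse(self) -> float:
        return float(np.exp(self.log_k0_reverse))


@dataclass
class KineticsResult:
    """Per-construct kinetic summary (one report-table row)."""

    construct: str
    x_b_ts_hat: float
    x_b_ts_sem: float
    x_s_ts_hat: float
    x_s_ts_sem: float
    x_bs_hat: float
    n_hat: float
    xb_per_bp: float
    xs_per_bp: float
    ts_fraction: float
    k_at_ftr: float
    f_cross: float
    log_k0_forward: float
    log_k0_reverse: float
    n_per_cycle: float
    n_per_cycle_sem: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def force_densities(
    events: pd.DataFrame, bin_width: float = 0.25, min_events: int = 2
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Transition-force probability density per direction.

    Returns ``{direction: (bin_centers, density)}`` with each density
    normalized to unit trapezoid integral over its window.
    """
    out = {}
    for direction in ("B->S", "S->B"):
        f = events.loc[events["direction"] == direction, "force_pN"].to_numpy(float)
        if len(f) < min_events:
            raise ValueError(f"too few {direction} events ({len(f)})")
        lo = np.floor(f.min() / bin_width) * bin_width
        hi = np.ceil(f.max() / bin_width) * bin_width
        edges = np.arange(lo, hi + bin_width / 2, bin_width)
        counts, _ = np.histogram(f, bins=edges)
        centers = edges[:-1] + bin_width / 2
        dens = counts.astype(float)
        area = np.trapezoid(dens, centers) if len(centers) > 1 else dens.sum() * bin_width
        out[direction] = (centers, dens / area)
    return out


def _km(entries: np.ndarray, exits: np.ndarray, observed: np.ndarray) -> SurvivalCurve:
    """Left-truncated Kaplan-Meier estimator on an increasing coordinate."""
    order = np.argsort(exits, kind="stable")
    exits, entries, observed = exits[order], entries[order], observed[order]
    uniq = np.unique(exits[observed])
    surv = []
    at_risk = []
    d_list = []
    s = 1.0
    for u in uniq:
        y = int(np.sum((entries < u) & (exits >= u)))
        d = int(np.sum(observed & (exits == u)))
        s *= 1.0 - d / y
        surv.append(s)
        at_risk.append(y)
        d_list.append(d)
    return SurvivalCurve(
        forces=uniq,
        survival=np.asarray(surv),
        at_risk=np.asarray(at_risk, dtype=int),
        n_events=np.asarray(d_list, dtype=int),
    )


def survival_curves(
    dwells: Sequence[Dwell], ramp_sign: int = 1
) -> dict[str, SurvivalCurve]:
    """Kaplan-Meier survival of the B and S states versus force.

    Uses the dwells of the given ramp phase (+1 stretch, -1 release); the
    release phase is analyzed on the reversed force axis (its traversal
    coordinate is ``-F``) and reported back on the physical axis.  A dwell is
    at risk only between its entry and exit forces (left truncation);
    censored exits shrink the risk set without contributing an event.
    """
    out = {}
    for state in ("B", "S"):
        sel = [d for d in dwells if d.state == state and d.ramp_sign == ramp_sign]
        if not sel:
            continue
        sign = float(ramp_sign)
        entries = np.array([sign * d.entry_force for d in sel])
        exits = np.array([sign * d.exit_force for d in sel])
        observed = np.array([d.exit_kind == "transition" for d in sel])
        keep = exits > entries
        if not observed[keep].any():
            warnings.warn(
                f"all {state} dwells censored: survival stays at 1", stacklevel=2
            )
        curve = _km(entries[keep], exits[keep], observed[keep])
        curve.forces = sign * curve.forces
        out[state] = curve
    return out


def rates_from_survival(
    density: tuple[np.ndarray, np.ndarray],
    survival: SurvivalCurve,
    loading_rate: float,
    n_total_events: int | None = None,
    s_cut: float = 0.05,
    min_events: int = 5,
) -> RateTable:
    """Hazard transform ``k(F) = r * rho(F) / S(F)`` on the density's bins.

    Bins where the survival has decayed below ``s_cut`` or that hold fewer
    than ``min_events`` events are dropped.  Binomial counting errors are
    propagated (``dk/k = 1/sqrt(d)``).
    """
    centers, rho = density
    if len(centers) > 1:
        bw = float(np.median(np.diff(centers)))
    else:
        bw = 1.0
    n_tot = n_total_events if n_total_events is not None else int(survival.n_events.sum())
    s = np.asarray(survival(centers), dtype=float)
    ok = (s > s_cut) & (rho * n_tot * bw >= min_events - 0.5)
    if not np.any(ok) and np.any(rho > 0):
        raise ValueError("survival below cut everywhere the density has mass")
    k = np.zeros_like(rho)
    k[ok] = loading_rate * rho[ok] / s[ok]
    d = rho * n_tot * bw
    err = np.zeros_like(k)
    err[ok & (d > 0)] = k[ok & (d > 0)] / np.sqrt(d[ok & (d > 0)])
    return RateTable(
        centers=centers[ok],
        rate=k[ok],
        rate_err=err[ok],
        n_events=np.round(d[ok]).astype(int),
        exposure_pN=np.where(k[ok] > 0, loading_rate * d[ok] / np.maximum(k[ok], 1e-300), 0.0),
    )


def hazard_rates(
    dwells: Sequence[Dwell],
    loading_rate: float,
    bin_width: float = 0.25,
    f_range: tuple[float, float] | None = None,
    min_events: int = 5,
) -> dict[str, RateTable]:
    """Occurrence/exposure rates per state, pooled over stretch and release.

    Each dwell contributes ``|exit - entry|`` pN of exposure spread over the
    force bins it traverses (regardless of ramp direction, using the
    unsigned loading-rate magnitude); each observed exit adds one event to
    its bin.  ``k = r * d_j / (Y_j dF)`` is the binned product-limit hazard
    increment, so this pools the per-phase survival information correctly.
    """
    dwells = list(dwells)
    if f_range is None:
        f_all = [d.entry_force for d in dwells] + [d.exit_force for d in dwells]
        f_range = (min(f_all), max(f_all))
    edges = np.arange(f_range[0], f_range[1] + bin_width / 2, bin_width)
    centers = edges[:-1] + bin_width / 2
    out = {}
    for state, direction in (("B", "B->S"), ("S", "S->B")):
        sel = [d for d in dwells if d.state == state]
        if not sel:
            continue
        expo = np.zeros(len(centers))
        d_cnt = np.zeros(len(centers))
        for d in sel:
            a, b = sorted((d.entry_force, d.exit_force))
            overlap = np.minimum(edges[1:], b) - np.maximum(edges[:-1], a)
            expo += np.clip(overlap, 0.0, None)
            if d.exit_kind == "transition":
                j = np.searchsorted(edges, d.exit_force, side="right") - 1
                if 0 <= j < len(centers):
                    d_cnt[j] += 1
        ok = (d_cnt >= min_events) & (expo > 0)
        k = loading_rate * d_cnt[ok] / expo[ok]
        out[state] = RateTable(
            centers=centers[ok],
            rate=k,
            rate_err=k / np.sqrt(d_cnt[ok]),
            n_events=d_cnt[ok].astype(int),
            exposure_pN=expo[ok],
        )
    return out


def fit_bell_evans(
    rates_forward: RateTable,
    rates_reverse: RateTable,
    center: float,
    window: float = 1.2,
    unstable_margin: float | None = 0.5,
    kbt: float = DEFAULT_KBT,
) -> BellEvansFit:
    """Weighted log-linear fit of both rate branches near the crossing.

    ``ln k`` is regressed on ``F`` with weights from the binomial counting
    errors; the slopes times ``k_B T`` give the transition-state distances
    (forward positive, reverse negative slope), the line crossing gives
    ``(f_cross, k_at_ftr)`` and the intercepts the zero-force extrapolations.

    Each direction is fitted on ``center +/- window``, additionally trimmed
    to ``unstable_margin`` on the side where the *arrival* state is unstable
    (below ``center`` for B->S, above for S->B): there the arrival dwell is
    often shorter than the sampling dead time, events merge away, and the
    apparent rate is biased low.  Pass ``unstable_margin=None`` to disable
    the trim (e.g. for clean synthetic rate tables).
    """
    fits = []
    for rt, expect_sign in ((rates_forward, +1), (rates_reverse, -1)):
        sel = (np.abs(rt.centers - center) <= window) & (rt.rate > 0)
        if unstable_margin is not None:
            if expect_sign > 0:  # B->S arrives in S, unstable below center
                sel &= rt.centers >= center - unstable_margin
            else:  # S->B arrives in B, unstable above center
                sel &= rt.centers <= center + unstable_margin
        if sel.sum() < 4:
            raise ValueError(
                f"need >= 4 rate bins within {window} pN of {center}; got {int(sel.sum())}"
            )
        f = rt.centers[sel]
        y = np.log(rt.rate[sel])
        w = rt.n_events[sel].astype(float)  # var(ln k) ~ 1/d
        W = np.sum(w)
        fbar = np.sum(w * f) / W
        ybar = np.sum(w * y) / W
        sxx = np.sum(w * (f - fbar) ** 2)
        slope = np.sum(w * (f - fbar) * (y - ybar)) / sxx
        icpt = ybar - slope * fbar
        resid = y - (slope * f + icpt)
        dof = max(len(f) - 2, 1)
        s2 = np.sum(w * resid**2) / dof
        slope_se = np.sqrt(s2 / sxx)
        fits.append((slope, icpt, slope_se, expect_sign))
    (sf, if_, sef, _), (sr, ir, ser, _) = fits
    ok = sf > 0 and sr < 0
    f_cross = (ir - if_) / (sf - sr)
    log_k = sf * f_cross + if_
    return BellEvansFit(
        x_b_ts=sf * kbt,
        x_b_ts_se=sef * kbt,
        x_s_ts=-sr * kbt,
        x_s_ts_se=ser * kbt,
        f_cross=float(f_cross),
        k_at_ftr=float(np.exp(log_k)),
        log_k0_forward=float(if_),
        log_k0_reverse=float(ir),
        ok=bool(ok),
    )


def transition_counts(
    events: pd.DataFrame,
    n_cycles: int,
    force_bin: float = 0.5,
    ext_bin: float = 0.5,
) -> dict:
    """Transitions per stretch/release cycle and their force/extension histograms.

    ``N`` is the mean total event count (both directions) over all
    ``n_cycles`` cycles, including cycles with zero events; the SEM is over
    cycles.  The histograms locate where the hopping concentrates.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    counts = np.zeros(n_cycles)
    if len(events):
        grp = events.groupby("cycle").size()
        idx = np.asarray(grp.index, dtype=int)
        if idx.min() < 0 or idx.max() >= n_cycles:
            idx = idx - idx.min()
        counts[idx] = grp.to_numpy()
    n_mean = float(counts.mean())
    n_sem = float(counts.std(ddof=1) / np.sqrt(n_cycles)) if n_cycles > 1 else np.nan
    out = {"N": n_mean, "N_sem": n_sem, "per_cycle": counts}
    if len(events):
        f = events["force_pN"].to_numpy(float)
        x = events["delta_x_nm"].to_numpy(float)
        fc, fe = np.histogram(f, bins=np.arange(f.min(), f.max() + force_bin, force_bin))
        xc, xe = np.histogram(x, bins=np.arange(x.min(), x.max() + ext_bin, ext_bin))
        out["force_hist"] = (fe[:-1] + force_bin / 2, fc / n_cycles)
        out["ext_hist"] = (xe[:-1] + ext_bin / 2, xc / n_cycles)
        out["force_peak"] = float(out["force_hist"][0][np.argmax(fc)]) if len(fc) else np.nan
        out["ext_peak"] = float(out["ext_hist"][0][np.argmax(xc)]) if len(xc) else np.nan
    return out


def barrier_per_bp(
    n_bps: Sequence[float], n_counts: Sequence[float]
) -> tuple[float, float]:
    """Per-bp transition barrier ``g_TS`` at the transition force, k_B T/bp.

    The mean number of transitions per cycle is proportional to the hopping
    rate near ``F_tr``, which scales as ``exp(-n * g_TS)`` if the barrier is
    extensive in the number of transitioning bps ``n``.  ``ln N`` is
    regressed on ``n`` by ordinary least squares and the negated slope
    returned with its standard error; for exactly two constructs this
    reduces to ``ln(N_b/N_a) / (n_a - n_b)``.
    """
    n = np.asarray(n_bps, dtype=float)
    N = np.asarray(n_counts, dtype=float)
    if len(n) != len(N) or len(n) < 2:
        raise ValueError("need >= 2 (n, N) pairs")
    if np.ptp(n) == 0:
        raise ValueError("all n equal: slope undefined")
    if np.any(N <= 0):
        raise ValueError("counts must be positive")
    y = np.log(N)
    nbar, ybar = n.mean(), y.mean()
    sxx = np.sum((n - nbar) ** 2)
    slope = np.sum((n - nbar) * (y - ybar)) / sxx
    if len(n) > 2:
        resid = y - (ybar + slope * (n - nbar))
        se = np.sqrt(np.sum(resid**2) / (len(n) - 2) / sxx)
    else:
        se = np.nan
    return float(-slope), float(se)


def attempt_rate(
    k_at_ftr: float, n: float, g_ts: float, log_space: bool = False
) -> float:
    """Universal attempt rate ``k0_BS = k(F_tr) * exp(n * g_TS)``, 1/s.

    Undoes the extensive barrier to recover the force- and
    length-independent prefactor.  With ``log_space=True`` the natural log
    of the rate is returned instead (overflow guard for large barriers).
    """
    if k_at_ftr <= 0 or n <= 0 or g_ts < 0:
        raise ValueError("inputs must be positive (g_ts >= 0)")
    if log_space:
        return float(np.log(k_at_ftr) + n * g_ts)
    return float(k_at_ftr * np.exp(n * g_ts))


def analyze_kinetics(
    events: pd.DataFrame,
    dwells: Sequence[Dwell],
    loading_rate: float,
    f_tr_hat: float,
    n_cycles: int,
    n_hat: float,
    construct: str = "",
    kbt: float = DEFAULT_KBT,
    bin_width: float = 0.25,
    window: float = 1.2,
    unstable_margin: float | None = 0.5,
) -> KineticsResult:
    """Full per-construct kinetic summary (one report-table row)."""
    rates = hazard_rates(dwells, loading_rate, bin_width)
    be = fit_bell_evans(rates["B"], rates["S"], f_tr_hat, window, unstable_margin, kbt)
    counts = transition_counts(events, n_cycles)
    return KineticsResult(
        construct=construct,
        x_b_ts_hat=be.x_b_ts,
        x_b_ts_sem=be.x_b_ts_se,
        x_s_ts_hat=be.x_s_ts,
        x_s_ts_sem=be.x_s_ts_se,
        x_bs_hat=be.x_bs,
        n_hat=n_hat,
        xb_per_bp=be.x_b_ts / n_hat,
        xs_per_bp=be.x_s_ts / n_hat,
        ts_fraction=be.ts_fraction,
        k_at_ftr=be.k_at_ftr,
        f_cross=be.f_cross,
        log_k0_forward=be.log_k0_forward,
        log_k0_reverse=be.log_k0_reverse,
        n_per_cycle=counts["N"],
        n_per_cycle_sem=counts["N_sem"],
    )
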