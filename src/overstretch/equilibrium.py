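"""Equilibrium thermodynamics of the B-to-S transition.

From a detected event collection this module estimates the transition force
``F_tr`` (logistic fit of the S-state occupancy versus force), the mean
transition extension ``dX``, the transition free energy ``G_BS`` (mean jump
work ``F * dX / k_B T`` and the Bennett acceptance-ratio estimator over the
forward/reverse work samples), the number of transitioning base pairs
``n = dX / x_BS``, the per-bp free energy ``g = G_BS / n``, the net duplex
stabilization ``dG`` relative to a reference construct, and the fraying
slope ``d(dX)/dF``.  Standard errors come from a per-cycle bootstrap:
events within a cycle share the same tether and are correlated, so cycles
(not events) are the exchangeable unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit
from scipy.stats import linregress

from .model import DEFAULT_KBT, X_BS_PER_BP, two_state_ps

__all__ = [
    "EquilibriumResult",
    "estimate_ftr",
    "mean_transition_extension",
    "transition_free_energy",
    "bar_free_energy",
    "per_bp_quantities",
    "stabilization_dG",
    "extension_force_regression",
    "analyze_equilibrium",
]

N_BOOTSTRAP = 200


@dataclass
class EquilibriumResult:
    """Per-construct equilibrium summary (one table row).

    Energies in k_B T, forces in pN, lengths in nm; ``n_hat`` in base pairs
    (real-valued) and ``g_hat`` in k_B T per bp.  ``g_bs_bar`` is the Bennett
    acceptance-ratio estimate; ``dg`` the stabilization relative to the
    reference construct (0 for the reference itself).
    """

    construct: str
    m: int
    f_tr_hat: float
    f_tr_sem: float
    dx_hat: float
    dx_sem: float
    g_bs: float
    g_bs_sem: float
    g_bs_bar: float
    n_hat: float
    n_sem: float
    g_hat: float
    g_sem: float
    fray_slope_hat: float
    fray_slope_se: float
    dg: float = np.nan
    dg_sem: float = np.nan

    def to_dict(self) -> dict:
        return {k: (v if not isinstance(v, float) else float(v)) for k, v in self.__dict__.items()}


def _percycle_bootstrap(
    cycles: np.ndarray,
    stat: Callable[[np.ndarray], float],
    n_boot: int = N_BOOTSTRAP,
    seed: int = 0,
) -> float:
    """SEM of ``stat`` under resampling whole cycles with replacement.

    ``stat`` receives an index array selecting the rows that belong to the
    resampled cycles (with multiplicity).
    """
    uniq = np.unique(cycles)
    order = np.argsort(cycles, kind="stable")
    sorted_c = cycles[order]
    starts = np.searchsorted(sorted_c, uniq, side="left")
    stops = np.searchsorted(sorted_c, uniq, side="right")
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.integers(0, len(uniq), size=len(uniq))
        idx = np.concatenate([order[starts[j]:stops[j]] for j in pick])
        vals[b] = stat(idx)
    return float(np.std(vals, ddof=1))


def estimate_ftr(
    occupancy: pd.DataFrame,
    kbt: float = DEFAULT_KBT,
    bin_width: float = 0.25,
    n_boot: int = N_BOOTSTRAP,
    seed: int = 0,
) -> tuple[float, float]:
    """Transition force from the S-occupancy-versus-force curve.

    ``occupancy`` has one row per retained sample with columns ``cycle``,
    ``force`` and ``in_s`` (0/1 state assignment).  The time fraction spent
    in S per ``bin_width``-pN force bin is fitted with the two-state
    logistic with free midpoint and width; the midpoint is ``F_tr``.  The
    SEM comes from a per-cycle bootstrap of the binned fit.

    Raises
    ------
    ValueError
        If the occupancy never crosses 1/2 inside the force window
        (``"no midpoint"``).
    """
    force = occupancy["force"].to_numpy(dtype=float)
    in_s = occupancy["in_s"].to_numpy(dtype=float)
    cycles = occupancy["cycle"].to_numpy()
    lo = np.floor(force.min() / bin_width) * bin_width
    edges = np.arange(lo, force.max() + bin_width, bin_width)
    n_bins = len(edges) - 1
    which = np.clip(np.digitize(force, edges) - 1, 0, n_bins - 1)
    centers_all = edges[:-1] + bin_width / 2

    def _fit(idx: np.ndarray) -> float:
        cnt = np.bincount(which[idx], minlength=n_bins)[:n_bins]
        s_cnt = np.bincount(which[idx], weights=in_s[idx], minlength=n_bins)[:n_bins]
        f_sum = np.bincount(which[idx], weights=force[idx], minlength=n_bins)[:n_bins]
        ok = cnt >= 20
        p = s_cnt[ok] / cnt[ok]
        # mean force of the samples in the bin, not the nominal center:
        # avoids a half-bin bias when the force distribution is uneven
        centers = f_sum[ok] / cnt[ok]
        if p.max() < 0.5 or p.min() > 0.5:
            raise ValueError("no midpoint: occupancy never crosses 1/2")
        p0 = [centers[np.argmin(np.abs(p - 0.5))], 8.0]
        popt, _ = curve_fit(
            lambda f, ftr, dx: two_state_ps(f, ftr, dx, kbt),
            centers,
            p,
            p0=p0,
            maxfev=5000,
        )
        return float(popt[0])

    all_idx = np.arange(len(force))
    f_tr_hat = _fit(all_idx)

    def _safe(idx):
        try:
            return _fit(idx)
        except (ValueError, RuntimeError):
            return f_tr_hat

    sem = _percycle_bootstrap(cycles, _safe, n_boot, seed)
    return f_tr_hat, sem


def mean_transition_extension(
    events: pd.DataFrame, n_boot: int = N_BOOTSTRAP, seed: int = 0
) -> tuple[float, float]:
    """Mean per-event extension change over both jump directions, with SEM."""
    if len(events) < 1:
        raise ValueError("no events")
    dx = events["delta_x_nm"].to_numpy(dtype=float)
    cycles = events["cycle"].to_numpy()
    sem = _percycle_bootstrap(cycles, lambda idx: dx[idx].mean(), n_boot, seed)
    return float(dx.mean()), sem


def _event_extensions(
    events: pd.DataFrame, fray_slope: float = 0.0, f_ref: float | None = None
) -> np.ndarray:
    """Per-event extensions, optionally referred back to the force ``f_ref``.

    With a nonzero ``fray_slope`` (nm/pN, positive shortening rate) the
    measured extension ``dX_i`` of an event at force ``F_i`` is converted to
    the extension the same transition would have had at ``f_ref``:
    ``dX_i + fray_slope * (F_i - f_ref)``.  This removes the systematic
    force-fraying correlation: events do not occur exactly at the transition
    force, and at higher force fewer base pairs transition.
    """
    dx = events["delta_x_nm"].to_numpy(float)
    if fray_slope and f_ref is not None:
        dx = dx + fray_slope * (events["force_pN"].to_numpy(float) - f_ref)
    return dx


def transition_free_energy(
    events: pd.DataFrame,
    kbt: float = DEFAULT_KBT,
    directions: Sequence[str] = ("B->S", "S->B"),
    fray_slope: float = 0.0,
    f_ref: float | None = None,
    n_boot: int = N_BOOTSTRAP,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean jump work ``F * dX / k_B T`` over the selected directions.

    The work per event uses the pre-jump force; with near-equilibrium
    hopping the average over both directions estimates the transition free
    energy ``G_BS``.  When ``fray_slope``/``f_ref`` are given, each event's
    extension is referred back to ``f_ref`` first (see
    :func:`extension_force_regression`), so the estimate targets the free
    energy of the transition at the transition force rather than a mixture
    over fraying states.
    """
    ev = events[events["direction"].isin(directions)]
    if len(ev) < 1:
        raise ValueError("no events")
    dx = _event_extensions(ev, fray_slope, f_ref)
    w = ev["force_pN"].to_numpy(float) * dx / kbt
    cycles = ev["cycle"].to_numpy()
    sem = _percycle_bootstrap(cycles, lambda idx: w[idx].mean(), n_boot, seed)
    return float(w.mean()), sem


def event_works(
    events: pd.DataFrame,
    kbt: float = DEFAULT_KBT,
    fray_slope: float = 0.0,
    f_ref: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward (B->S) and reverse (S->B) work samples in k_B T."""
    dx = _event_extensions(events, fray_slope, f_ref)
    w = events["force_pN"].to_numpy(float) * dx / kbt
    fwd = w[events["direction"].to_numpy() == "B->S"]
    rev = w[events["direction"].to_numpy() == "S->B"]
    return fwd, rev


def bar_free_energy(
    forward_works: np.ndarray, reverse_works: np.ndarray, tol: float = 1e-6
) -> float:
    """Two-sided Bennett acceptance-ratio free-energy estimate, k_B T.

    Solves, by bracketing and bisection to ``tol``,

    ``sum_F 1/(1 + exp(w_F - dG + C)) = sum_R 1/(1 + exp(-w_R + dG - C))``

    with ``C = ln(n_F / n_R)``.  For two identical delta distributions this
    reduces to the common work value.
    """
    wf = np.asarray(forward_works, dtype=float)
    wr = np.asarray(reverse_works, dtype=float)
    if len(wf) == 0 or len(wr) == 0:
        raise ValueError("both work lists must be non-empty")
    c = np.log(len(wf) / len(wr))

    def h(dg: float) -> float:
        lhs = 1.0 / (1.0 + np.exp(np.clip(wf - dg + c, -700, 700)))
        rhs = 1.0 / (1.0 + np.exp(np.clip(-wr + dg - c, -700, 700)))
        return float(lhs.sum() - rhs.sum())

    lo = min(wf.min(), wr.min()) - 1.0
    hi = max(wf.max(), wr.max()) + 1.0
    for _ in range(60):
        if h(lo) * h(hi) <= 0:
            break
        span = hi - lo
        lo -= span
        hi += span
    else:
        raise ValueError("no sign change while bracketing the Bennett root")
    return float(brentq(h, lo, hi, xtol=tol))


def per_bp_quantities(
    dx_hat: float, g_bs: float, x_bs: float = X_BS_PER_BP
) -> tuple[float, float]:
    """Number of transitioning bps ``n = dX/x_BS`` and per-bp ``g = G_BS/n``.

    ``n`` is reported unrounded.
    """
    if x_bs <= 0:
        raise ValueError("x_bs must be positive")
    if dx_hat <= 0:
        raise ValueError("dx_hat must be positive (g undefined at n = 0)")
    n = dx_hat / x_bs
    return n, g_bs / n


def stabilization_dG(g_bs_mod: float, n_mod: float, g_ref: float) -> float:
    """Net duplex stabilization by a modification, k_B T.

    Compares the measured transition free energy of the modified duplex with
    that of an unmodified duplex over the same transitioning length:
    ``dG = G_BS,mod - n_mod * g_ref`` where ``g_ref`` is the per-bp free
    energy of the reference (unmodified) construct under the same salt and
    pulling-rate condition.  Zero when applied to the reference itself.
    """
    return g_bs_mod - n_mod * g_ref


def extension_force_regression(events: pd.DataFrame) -> tuple[float, float]:
    """Fraying slope: OLS of the per-event extension change on jump force.

    Returns the positive shortening rate ``-d(dX)/dF`` in nm/pN with its
    standard error.  Requires a force spread of at least ~1 pN among events.
    """
    if len(events) < 3:
        raise ValueError("too few events for the extension-force regression")
    f = events["force_pN"].to_numpy(float)
    dx = events["delta_x_nm"].to_numpy(float)
    if np.ptp(f) < 0.5:
        raise ValueError("insufficient force spread among events")
    res = linregress(f, dx)
    return float(-res.slope), float(res.stderr)


def analyze_equilibrium(
    events: pd.DataFrame,
    occupancy: pd.DataFrame,
    construct: str = "",
    m: int | None = None,
    kbt: float = DEFAULT_KBT,
    x_bs: float = X_BS_PER_BP,
    seed: int = 0,
) -> EquilibriumResult:
    """Full per-construct equilibrium summary (one report-table row)."""
    if m is None:
        m = int(occupancy["cycle"].nunique())
    f_tr_hat, f_tr_sem = estimate_ftr(occupancy, kbt, seed=seed)
    fray, fray_se = extension_force_regression(events)
    # refer every event's extension back to the transition force: individual
    # jumps happen over a ~2 pN band and lose ~fray nm of extension per pN,
    # so the raw per-event mean mixes fraying states and underestimates the
    # transition at F_tr whenever the event forces are not centred on it
    dx_ref = _event_extensions(events, fray, f_tr_hat)
    cycles = events["cycle"].to_numpy()
    dx_hat = float(dx_ref.mean())
    dx_sem = _percycle_bootstrap(cycles, lambda idx: dx_ref[idx].mean(), seed=seed)
    g_bs, g_bs_sem = transition_free_energy(
        events, kbt, fray_slope=fray, f_ref=f_tr_hat, seed=seed
    )
    fwd, rev = event_works(events, kbt, fray_slope=fray, f_ref=f_tr_hat)
    g_bs_bar = bar_free_energy(fwd, rev) if len(fwd) and len(rev) else np.nan
    n_hat, g_hat = per_bp_quantities(dx_hat, g_bs, x_bs)
    n_sem = dx_sem / x_bs
    # g = G/n: first-order error propagation with independent SEMs
    g_sem = g_hat * np.sqrt((g_bs_sem / g_bs) ** 2 + (n_sem / n_hat) ** 2)
    return EquilibriumResult(
        construct=construct,
        m=m,
        f_tr_hat=f_tr_hat,
        f_tr_sem=f_tr_sem,
        dx_hat=dx_hat,
        dx_sem=dx_sem,
        g_bs=g_bs,
        g_bs_sem=g_bs_sem,
        g_bs_bar=g_bs_bar,
        n_hat=n_hat,
        n_sem=n_sem,
        g_hat=g_hat,
        g_sem=g_sem,
        fray_slope_hat=fray,
        fray_slope_se=fray_se,
    )
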