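"""Jump detection: branch fitting, B<->S event calling and dwell extraction.

A half-cycle of the force-distance record shows two interleaved linear
branches ~1 pN apart in force (B above S at a given trap position).  The
detector (i) fits the two branch lines by alternating classification and
least squares, (ii) walks a hysteresis (Schmitt-trigger) state machine over
the median-filtered force to call the jump times, and (iii) converts the
state sequence into per-dwell survival records with entry/exit forces and
censoring flags.

Per event, the reported force is the last pre-jump sample's force and the
extension change is the horizontal distance between the fitted branch lines
at that force, so the force dependence of the jump extension (end fraying)
is observable event by event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .io import HalfCycle
from .simulate import EVENT_COLUMNS

__all__ = [
    "BranchFit",
    "Dwell",
    "DetectorConfig",
    "fit_branches",
    "detect_events",
    "extract_dwells",
    "analyze_half_cycle",
    "DWELL_COLUMNS",
]

DWELL_COLUMNS = [
    "cycle",
    "state",
    "entry_force",
    "exit_force",
    "exit_kind",
    "ramp_sign",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Tunable jump-detection parameters.

    ``median_window`` is the force median-filter width in samples;
    ``hysteresis`` the fraction of the branch gap the filtered force must
    cross toward the other branch before a flip is accepted; ``debounce``
    the number of consecutive filtered samples that must confirm the new
    branch; ``min_jump`` the minimum force step (pN) between the dwell
    levels around an accepted event.
    """

    median_window: int = 3
    hysteresis: float = 0.3
    debounce: int = 2
    min_jump: float = 0.5
    min_gap_nm: float = 2.0
    max_fit_iter: int = 5

    def __post_init__(self):
        if not 0 < self.hysteresis < 0.5:
            raise ValueError("hysteresis must be in (0, 0.5)")
        if self.median_window < 1 or self.median_window % 2 == 0:
            raise ValueError("median_window must be odd and >= 1")
        if self.debounce < 1:
            raise ValueError("debounce must be >= 1")


@dataclass
class BranchFit:
    """Linear fits ``F = slope * trap_position + intercept`` per branch.

    The S branch lies below B in force at fixed trap position.  ``usable``
    is False when only one branch could be resolved (slope_s/intercept_s
    then mirror the B fit and the gap is meaningless).
    """

    slope_b: float
    intercept_b: float
    slope_s: float
    intercept_s: float
    rms_b: float
    rms_s: float
    n_b: int
    n_s: int
    usable: bool = True

    def predict(self, lam: np.ndarray, state: str) -> np.ndarray:
        if state == "B":
            return self.slope_b * lam + self.intercept_b
        if state == "S":
            return self.slope_s * lam + self.intercept_s
        raise ValueError(f"unknown state {state!r}")

    def gap_nm(self, force) -> np.ndarray:
        """Horizontal branch separation x_S(F) - x_B(F) at the given force."""
        f = np.asarray(force, dtype=float)
        out = (f - self.intercept_s) / self.slope_s - (f - self.intercept_b) / self.slope_b
        return out if out.ndim else float(out)


@dataclass
class Dwell:
    """Residence interval in one state between consecutive jumps.

    ``exit_kind`` is ``"transition"`` for an observed jump and ``"censored"``
    when the ramp ended first.  ``ramp_sign`` is +1 (stretch) or -1
    (release); on a stretch the exit force is >= the entry force.
    """

    cycle: int
    state: str
    entry_force: float
    exit_force: float
    exit_kind: str
    ramp_sign: int


def _ls_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    A = np.polyfit(x, y, 1)
    return float(A[0]), float(A[1])


def fit_branches(half: HalfCycle, config: DetectorConfig = DetectorConfig()) -> BranchFit:
    """Fit the B and S force-distance lines of a half-cycle.

    The bistable hopping is confined to a narrow force window around the
    transition force, so the low-trap-position end of the ramp is pure B and
    the high end pure S.  Each branch line is seeded on its pure segment
    (lowest / highest 25% of trap positions), extrapolated across the ramp,
    and refined by alternating nearest-line classification and per-class
    least squares (at most ``max_fit_iter`` rounds, ties keep the previous
    class).  A half-cycle whose classes end up closer than ``min_gap_nm`` of
    extension, or with fewer than 50 samples on one branch, is returned as a
    flagged B-only fit (e.g. a ramp that never left B).
    """
    lam, F = half.trap_position, half.force
    if len(lam) < 100:
        raise ValueError("half-cycle too short to fit branches")
    if np.ptp(lam) < 1e-9:
        raise ValueError("no ramp")
    q25, q75 = np.quantile(lam, [0.25, 0.75])
    low, high = lam <= q25, lam >= q75
    sb, ib = _ls_line(lam[low], F[low])     # pure B end
    ss, is_ = _ls_line(lam[high], F[high])  # pure S end (if any hopping)
    upper = np.zeros(len(lam), dtype=bool)
    # classify on the median-filtered force (suppresses misclassification of
    # single noisy samples, which would bias both lines toward each other);
    # the per-class least squares still uses the raw force
    filt = _median_filter(F, config.median_window)

    def _single():
        s0, i0 = _ls_line(lam, F)
        rms = float(np.sqrt(np.mean((F - (s0 * lam + i0)) ** 2)))
        return BranchFit(s0, i0, s0, i0, rms, rms, len(lam), 0, usable=False)

    for _ in range(config.max_fit_iter):
        rb = filt - (sb * lam + ib)
        rs = filt - (ss * lam + is_)
        new = np.abs(rb) < np.abs(rs)
        tie = np.abs(np.abs(rb) - np.abs(rs)) < 1e-12
        new[tie] = upper[tie]  # hysteresis tie-break: keep previous class
        if new.sum() < 50 or (~new).sum() < 50:
            return _single()
        # fit each line only on samples well inside its own territory: a
        # single misclassified sample from the other branch would otherwise
        # lever the slope and make the extrapolated lines converge
        gap = np.maximum((sb * lam + ib) - (ss * lam + is_), 1e-6)
        fit_b = new & (np.abs(rb) < 0.4 * gap)
        fit_s = ~new & (np.abs(rs) < 0.4 * gap)
        if fit_b.sum() < 50 or fit_s.sum() < 50:
            return _single()
        if np.array_equal(new, upper):
            upper = new
            sb, ib = _ls_line(lam[fit_b], F[fit_b])
            ss, is_ = _ls_line(lam[fit_s], F[fit_s])
            break
        upper = new
        sb, ib = _ls_line(lam[fit_b], F[fit_b])
        ss, is_ = _ls_line(lam[fit_s], F[fit_s])
    fit = BranchFit(
        slope_b=sb,
        intercept_b=ib,
        slope_s=ss,
        intercept_s=is_,
        rms_b=float(np.sqrt(np.mean((F[upper] - (sb * lam[upper] + ib)) ** 2))),
        rms_s=float(np.sqrt(np.mean((F[~upper] - (ss * lam[~upper] + is_)) ** 2))),
        n_b=int(upper.sum()),
        n_s=int((~upper).sum()),
    )
    if fit.gap_nm(np.median(F)) < config.min_gap_nm:
        fit.usable = False
    return fit


def _median_filter(F: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return F
    return median_filter(F, size=window, mode="nearest")


def gap_floor(branches: BranchFit, config: DetectorConfig) -> float:
    """Minimum resolvable branch separation in force, pN.

    The flip threshold sits ``(1 - hysteresis) * gap`` from the occupied
    branch; that margin must clear the filtered noise by ~3 sigma, and never
    be below ``min_jump``.  End fraying makes the branches converge at high
    force, so each half-cycle has a maximum force beyond which states cannot
    be told apart; dwell exposure is clipped there.
    """
    sigma_filt = min(branches.rms_b, branches.rms_s) * (
        0.67 if config.median_window >= 3 else 1.0
    )
    return max(config.min_jump, 3.0 * sigma_filt / (1.0 - config.hysteresis))


def _state_sequence(
    filt: np.ndarray,
    pred_b: np.ndarray,
    pred_s: np.ndarray,
    hysteresis: float,
    debounce: int,
    gap_floor: float = 0.0,
) -> tuple[np.ndarray, list[int]]:
    """Schmitt-trigger walk; returns per-sample state (0=B,1=S) and flip indices.

    Samples where the branch separation is below ``gap_floor`` are frozen in
    the current state: end fraying makes the branches converge at high force,
    and where the gap is comparable to the noise no flip can be trusted.
    """
    gap = pred_b - pred_s
    ok = gap >= gap_floor
    if not np.any(ok):
        return np.zeros(len(filt), dtype=np.int8), [], 0
    i0 = int(np.argmax(ok))  # first sample where the branches are resolvable
    to_s = ok & (filt < pred_s + hysteresis * gap)  # deep in S territory
    to_b = ok & (filt > pred_b - hysteresis * gap)  # deep in B territory
    if debounce > 1:
        # require `debounce` consecutive confirming samples
        def runs(mask):
            out = mask.copy()
            for k in range(1, debounce):
                shifted = np.empty_like(mask)
                shifted[:-k] = mask[k:]
                shifted[-k:] = mask[-1]
                out &= shifted
            return out

        to_s, to_b = runs(to_s), runs(to_b)
    n = len(filt)
    state = np.zeros(n, dtype=np.int8)
    # classify the initial state at the first resolvable sample (a few-sample
    # median guards against a single outlier); before i0 the labels are
    # extrapolation and carry no exposure downstream
    j0 = np.median(filt[i0 : i0 + 5])
    cur = 1 if abs(j0 - pred_s[i0]) < abs(j0 - pred_b[i0]) else 0
    state[:i0] = cur
    idx_s = np.nonzero(to_s)[0]
    idx_b = np.nonzero(to_b)[0]
    flips: list[int] = []
    pos = i0
    while True:
        pool = idx_b if cur else idx_s
        j = np.searchsorted(pool, pos)
        if j >= len(pool):
            state[pos:] = cur
            break
        i = int(pool[j])
        state[pos:i] = cur
        cur = 1 - cur
        flips.append(i)
        pos = i
    return state, flips, i0


def detect_events(
    half: HalfCycle,
    branches: BranchFit,
    config: DetectorConfig = DetectorConfig(),
) -> tuple[pd.DataFrame, np.ndarray]:
    """Call B<->S jumps on a half-cycle.

    Returns the event table (columns as in the simulator's ground-truth log)
    and the per-sample state assignment (0 = B, 1 = S).  Events alternate in
    direction by construction of the state machine.  Flagged-unusable branch
    fits yield an empty event list and an all-B assignment.
    """
    n = len(half)
    if not branches.usable:
        return pd.DataFrame(columns=EVENT_COLUMNS), np.zeros(n, dtype=np.int8)
    lam, F = half.trap_position, half.force
    filt = _median_filter(F, config.median_window)
    pred_b = branches.predict(lam, "B")
    pred_s = branches.predict(lam, "S")
    state, flips, _ = _state_sequence(
        filt, pred_b, pred_s, config.hysteresis, config.debounce,
        gap_floor(branches, config),
    )
    # the gap floor already guarantees that any accepted flip happens where
    # the branch separation (= jump amplitude) exceeds min_jump, so no
    # per-event amplitude test is needed: one falsely rejected flip would
    # desynchronize the alternation downstream.  The pre-jump force is read
    # off the departing branch's fitted line at the last pre-jump sample:
    # the line pools hundreds of samples, so this removes the single-sample
    # noise that would otherwise smear every downstream force coordinate
    # (and, for dwells much shorter than noise/loading-rate, fake their
    # force span).
    rows = []
    for i in flips:
        if i == 0:
            continue
        departing = "B" if state[i] == 1 else "S"
        force = float(branches.predict(lam[i - 1 : i], departing)[0])
        rows.append(
            {
                "cycle": half.cycle_id,
                "time_s": float(half.time[i]),
                "direction": "B->S" if state[i] == 1 else "S->B",
                "force_pN": force,
                "delta_x_nm": float(branches.gap_nm(force)),
            }
        )
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return events, state


def extract_dwells(
    half: HalfCycle,
    events: pd.DataFrame,
    branches: BranchFit,
    resolve_floor: float = 0.0,
) -> list[Dwell]:
    """Turn a half-cycle's event list into survival records.

    The dwell count is one more than the event count; the first dwell enters
    at the ramp's starting force, the last is censored at the ramp end.
    Entry/exit forces are read off the fitted branch line of the occupied
    state, so the force intervals tile the ramp window of that branch.

    With ``resolve_floor`` > 0, dwell intervals are clipped to the force
    range where the branch separation is at least that floor: in the
    convergence zone near the ramp top no transition can be observed, so
    time spent there must not count as exposure at risk.
    """
    ev = events.sort_values("time_s", kind="stable")
    if len(ev) and not ev["time_s"].is_monotonic_increasing:
        raise ValueError("out-of-order events")
    lam0, lam1 = half.trap_position[0], half.trap_position[-1]
    sign = half.direction
    dirs = list(ev["direction"])
    for a, b in zip(dirs, dirs[1:]):
        if a == b:
            raise ValueError("events do not alternate in direction")
    first_state = ("B" if dirs[0] == "B->S" else "S") if dirs else None
    if first_state is None:
        first_state = "B"  # no events: assume the low-force state
    out: list[Dwell] = []
    cur = first_state
    entry = float(branches.predict(np.array([lam0]), cur)[0])
    for _, row in ev.iterrows():
        exit_f = float(row["force_pN"])
        out.append(
            Dwell(half.cycle_id, cur, entry, exit_f, "transition", sign)
        )
        cur = "S" if cur == "B" else "B"
        # entry force of the next dwell: its own branch line at the jump's
        # trap position (from the pre-jump force on the departing branch)
        lam_jump = (
            exit_f
            - (branches.intercept_s if cur == "B" else branches.intercept_b)
        ) / (branches.slope_s if cur == "B" else branches.slope_b)
        entry = float(branches.predict(np.array([lam_jump]), cur)[0])
    out.append(
        Dwell(
            half.cycle_id,
            cur,
            entry,
            float(branches.predict(np.array([lam1]), cur)[0]),
            "censored",
            sign,
        )
    )
    if resolve_floor > 0:
        out = _clip_to_resolvable(out, half, branches, resolve_floor)
    return out


def _clip_to_resolvable(
    dwells: list[Dwell], half: HalfCycle, branches: BranchFit, floor: float
) -> list[Dwell]:
    """Clip dwell force intervals to where the branches are separable."""
    lam = half.trap_position
    sep = branches.predict(lam, "B") - branches.predict(lam, "S")
    ok = sep >= floor
    if not np.any(ok):
        return []
    limits = {
        s: (float(branches.predict(lam[ok], s).min()), float(branches.predict(lam[ok], s).max()))
        for s in ("B", "S")
    }
    kept: list[Dwell] = []
    for d in dwells:
        lo, hi = limits[d.state]
        if d.exit_kind == "transition":
            # a detected jump always sits in the resolvable zone; clip the
            # entry side only
            entry = min(max(d.entry_force, lo), hi)
            if abs(d.exit_force - entry) <= 0:
                continue
            kept.append(Dwell(d.cycle, d.state, entry, d.exit_force, d.exit_kind, d.ramp_sign))
        else:
            a, b = sorted((d.entry_force, d.exit_force))
            a2, b2 = max(a, lo), min(b, hi)
            if b2 - a2 <= 0:
                continue
            entry, exit_ = (a2, b2) if d.entry_force <= d.exit_force else (b2, a2)
            kept.append(Dwell(d.cycle, d.state, entry, exit_, "censored", d.ramp_sign))
    return kept


def analyze_half_cycle(
    half: HalfCycle, config: DetectorConfig = DetectorConfig()
) -> tuple[BranchFit, pd.DataFrame, list[Dwell], np.ndarray]:
    """Branch fit + event detection + dwell extraction for one half-cycle."""
    branches = fit_branches(half, config)
    events, state = detect_events(half, branches, config)
    dwells = (
        extract_dwells(half, events, branches, gap_floor(branches, config))
        if branches.usable
        else []
    )
    return branches, events, dwells, state
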