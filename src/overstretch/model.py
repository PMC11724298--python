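"""Two-state physical model of the B-to-S DNA overstretching transition.

A torsionally unconstrained DNA duplex held between two beads in a stiff
optical trap hops, in a narrow force window around the equilibrium transition
force ``F_tr``, between canonical B-DNA and the overstretched, base-paired
S-form.  Within that window (roughly 55-72 pN) each elastic branch of the
force-distance curve is linear, the hopping rates follow the Bell-Evans
exponential force dependence, and the extension gained per jump shrinks
linearly with force as base pairs fray from the free duplex ends.

This module holds the unit conventions, the closed-form two-state and
Bell-Evans expressions, the linear branch geometry, and named parameter
presets for the duplex constructs used throughout the package.  Everything
here is pure: same inputs, bit-identical outputs.

Units: forces in pN, lengths in nm, energies in pN nm or thermal units
(k_B T), rates in 1/s.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Tuple

import numpy as np

__all__ = [
    "BOLTZMANN_PN_NM_PER_K",
    "KCAL_PER_KBT",
    "X_BS_PER_BP",
    "DEFAULT_KBT",
    "Constants",
    "ConstructModel",
    "RampProtocol",
    "boltzmann_energy",
    "two_state_ps",
    "bell_evans_rate",
    "branch_force",
    "branch_extension",
    "frayed_extension",
    "expected_events_per_cycle",
    "tune_rate_to_count",
    "construct_preset",
    "preset_names",
    "EQUILIBRIUM_TABLE",
    "KINETICS_TABLE",
]

#: Boltzmann constant in pN nm per kelvin.
BOLTZMANN_PN_NM_PER_K = 0.0138065

#: 1 k_B T expressed in kcal/mol (at ~room temperature).
KCAL_PER_KBT = 0.59

#: Per-bp elongation of the B-to-S transition, nm/bp, from polymeric dsDNA
#: overstretching.
X_BS_PER_BP = 0.23


def boltzmann_energy(temperature_C: float = 23.0) -> float:
    """Thermal energy k_B T in pN nm at the given temperature (Celsius).

    Raises
    ------
    ValueError
        If the temperature is at or below absolute zero.
    """
    if temperature_C <= -273.15:
        raise ValueError(
            f"nonphysical temperature {temperature_C} C (absolute zero is -273.15 C)"
        )
    return BOLTZMANN_PN_NM_PER_K * (temperature_C + 273.15)


#: k_B T at the 23 C working temperature of the experiments, pN nm.
DEFAULT_KBT = boltzmann_energy(23.0)


@dataclass(frozen=True)
class Constants:
    """Unit backbone shared by all thermodynamic formulas.

    ``boltzmann_energy`` is k_B T in pN nm at the stated temperature,
    ``x_bs`` the per-bp elongation of the B-to-S transition in nm/bp and
    ``kcal_per_kbt`` the conversion of one thermal unit to kcal/mol.
    """

    boltzmann_energy: float = DEFAULT_KBT
    x_bs: float = X_BS_PER_BP
    kcal_per_kbt: float = KCAL_PER_KBT

    def __post_init__(self):
        if self.boltzmann_energy <= 0 or self.x_bs <= 0:
            raise ValueError("boltzmann_energy and x_bs must be positive")


def two_state_ps(F, F_tr: float, dX: float, kbt: float = DEFAULT_KBT):
    """Equilibrium probability of the S state at force ``F``.

    ``P_S(F) = 1 / (1 + exp(-dX (F - F_tr) / kbt))``: the two-state
    partition of a transition that gains extension ``dX`` at its midpoint
    force ``F_tr``.  Monotone nondecreasing in ``F`` and exactly 1/2 at
    ``F = F_tr``.
    """
    if dX <= 0:
        raise ValueError("dX must be positive")
    if kbt <= 0:
        raise ValueError("kbt must be positive")
    arg = -np.asarray(F, dtype=float) + F_tr
    out = 1.0 / (1.0 + np.exp(np.clip(arg * dX / kbt, -700, 700)))
    return out if out.ndim else float(out)


def bell_evans_rate(
    F,
    k_tr: float,
    F_tr: float,
    x_ts: float,
    direction: str,
    kbt: float = DEFAULT_KBT,
):
    """Bell-Evans transition rate at force ``F``.

    The rates pivot on the equilibrium transition force where both equal
    ``k_tr``::

        k_B->S(F) = k_tr * exp(+(F - F_tr) * x_ts / kbt)
        k_S->B(F) = k_tr * exp(-(F - F_tr) * x_ts / kbt)

    ``x_ts`` is the distance to the transition state from the departing
    state (``X_B->TS`` for ``"B->S"``, ``X_S->TS`` for ``"S->B"``).
    """
    if k_tr <= 0:
        raise ValueError("k_tr must be positive")
    if x_ts <= 0:
        raise ValueError("x_ts must be positive")
    if direction == "B->S":
        sign = 1.0
    elif direction == "S->B":
        sign = -1.0
    else:
        raise ValueError(f"unknown direction {direction!r}; use 'B->S' or 'S->B'")
    arg = sign * (np.asarray(F, dtype=float) - F_tr) * x_ts / kbt
    out = k_tr * np.exp(np.clip(arg, -700, 700))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ConstructModel:
    """Ground-truth physical parameters of one duplex construct.

    Parameters
    ----------
    name : str
        Construct label (e.g. ``"Unmodified"``).
    f_tr : float
        Equilibrium transition force, pN.
    dx_tr : float
        Transition extension at ``f_tr``, nm.  Must equal
        ``x_b_ts + x_s_ts``.
    x_b_ts, x_s_ts : float
        Distances from the B (resp. S) state to the transition state, nm.
    k_tr : float
        Hopping rate at ``f_tr`` (both directions), 1/s.
    fray_slope : float
        d(dX)/dF magnitude, nm/pN; the transition extension shrinks by this
        much per pN of transition force as the duplex ends fray.
    b_branch : (float, float)
        (stiffness pN/nm, reference extension nm) of the B-state linear
        force-distance branch: ``F = stiffness * (extension - reference)``.
    s_offset : float
        Extra contour offset of the S branch beyond the frayed transition
        extension, nm (0 by default).
    """

    name: str
    f_tr: float
    dx_tr: float
    x_b_ts: float
    x_s_ts: float
    k_tr: float
    fray_slope: float = 1.0
    b_branch: Tuple[float, float] = (0.1, 0.0)
    s_offset: float = 0.0

    def __post_init__(self):
        if abs(self.x_b_ts + self.x_s_ts - self.dx_tr) > 1e-9:
            raise ValueError(
                f"x_b_ts + x_s_ts = {self.x_b_ts + self.x_s_ts} must equal "
                f"dx_tr = {self.dx_tr}"
            )
        for attr in ("f_tr", "dx_tr", "x_b_ts", "x_s_ts", "k_tr"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")
        if self.b_branch[0] <= 0:
            raise ValueError("branch stiffness must be positive")
        if self.fray_slope < 0:
            raise ValueError("fray_slope must be >= 0")

    @property
    def ts_fraction(self) -> float:
        """Position of the transition state as % of the B-to-S path."""
        return 100.0 * self.x_b_ts / self.dx_tr

    def rate(self, F, direction: str, kbt: float = DEFAULT_KBT):
        x = self.x_b_ts if direction == "B->S" else self.x_s_ts
        return bell_evans_rate(F, self.k_tr, self.f_tr, x, direction, kbt)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ConstructModel":
        d = json.loads(text)
        d["b_branch"] = tuple(d["b_branch"])
        return cls(**d)


@dataclass(frozen=True)
class RampProtocol:
    """Constant-velocity stretch/release protocol of the stiff trap.

    The trap of stiffness ``k_trap`` moves at ``velocity`` so the force ramps
    between ``f_min`` and ``f_max`` at the loading rate
    ``r = k_trap * velocity`` (derived, never stored).
    """

    f_min: float = 55.0
    f_max: float = 72.0
    velocity: float = 50.0
    k_trap: float = 0.1
    sample_rate: float = 1000.0
    n_cycles: int = 1
    seed: int | None = None
    noise_sigma_f: float = 0.2

    def __post_init__(self):
        if not self.f_min < self.f_max:
            raise ValueError("need f_min < f_max")
        for attr in ("velocity", "k_trap", "sample_rate"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")
        if self.noise_sigma_f < 0:
            raise ValueError("noise_sigma_f must be >= 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    @property
    def loading_rate(self) -> float:
        """Force loading rate k_trap * velocity, pN/s."""
        return self.k_trap * self.velocity

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def frayed_extension(F, construct: ConstructModel):
    """Force-dependent transition extension ``dX(F)``, nm (floored at 0).

    End fraying removes ~``fray_slope`` nm of transition extension per pN of
    force above ``f_tr``: ``dX(F) = dx_tr - fray_slope * (F - f_tr)``.
    """
    F = np.asarray(F, dtype=float)
    out = np.maximum(construct.dx_tr - construct.fray_slope * (F - construct.f_tr), 0.0)
    return out if out.ndim else float(out)


def branch_extension(F, state: str, construct: ConstructModel):
    """Trap-distance coordinate of a branch at force ``F``, nm.

    The S branch sits beyond the B branch by the frayed transition extension:
    ``x_S(F) = x_B(F) + s_offset + dX(F)``.
    """
    stiffness, ref = construct.b_branch
    if stiffness <= 0:
        raise ValueError("branch stiffness must be positive")
    F = np.asarray(F, dtype=float)
    x_b = ref + F / stiffness
    if state == "B":
        out = x_b
    elif state == "S":
        out = x_b + construct.s_offset + frayed_extension(F, construct)
    else:
        raise ValueError(f"unknown state {state!r}; use 'B' or 'S'")
    return out if out.ndim else float(out)


def branch_force(extension, state: str, construct: ConstructModel):
    """Force on the B or S elastic branch at the given trap distance, nm.

    Inverse of :func:`branch_extension`; linear in ``extension`` on both
    branches (the fraying term keeps the S branch linear too, with a
    slightly steeper slope ``k/(1 - k*fray_slope)``).
    """
    k, ref = construct.b_branch
    if k <= 0:
        raise ValueError("branch stiffness must be positive")
    x = np.asarray(extension, dtype=float)
    if state == "B":
        out = k * (x - ref)
    elif state == "S":
        m = construct.fray_slope
        denom = 1.0 - k * m
        if denom <= 0:
            raise ValueError("branch stiffness * fray_slope must be < 1")
        out = (
            k * (x - ref - construct.s_offset - construct.dx_tr) - k * m * construct.f_tr
        ) / denom
        # beyond the fraying floor the S branch coincides with the shifted B line
        floor = construct.f_tr + construct.dx_tr / m if m > 0 else np.inf
        hi = np.asarray(out) > floor
        if np.any(hi):
            out = np.where(hi, k * (x - ref - construct.s_offset), out)
    else:
        raise ValueError(f"unknown state {state!r}; use 'B' or 'S'")
    out = np.asarray(out)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Deterministic rate tuning
# ---------------------------------------------------------------------------

def expected_events_per_cycle(
    construct: ConstructModel,
    protocol: RampProtocol,
    kbt: float = DEFAULT_KBT,
    n_grid: int = 4000,
) -> float:
    """Expected number of hops per stretch-release cycle, by quadrature.

    In the quasi-equilibrium regime the event rate at trap position
    ``lambda`` is ``2 k_f k_r / (k_f + k_r)`` with the forward rate taken at
    the B-branch force and the reverse rate at the S-branch force.  One full
    cycle traverses the ramp twice.  The result is exactly linear in
    ``construct.k_tr``.
    """
    lam_lo = branch_extension(protocol.f_min, "B", construct)
    lam_hi = branch_extension(protocol.f_max, "B", construct)
    lam = np.linspace(lam_lo, lam_hi, n_grid)
    f_b = branch_force(lam, "B", construct)
    f_s = branch_force(lam, "S", construct)
    kf = construct.rate(f_b, "B->S", kbt)
    kr = construct.rate(f_s, "S->B", kbt)
    flux = 2.0 * kf * kr / (kf + kr)
    return 2.0 * np.trapezoid(flux, lam) / protocol.velocity


def tune_rate_to_count(
    construct: ConstructModel,
    protocol: RampProtocol,
    target_n: float,
    kbt: float = DEFAULT_KBT,
) -> ConstructModel:
    """Return a copy of ``construct`` with ``k_tr`` set so the expected
    number of transitions per cycle equals ``target_n``."""
    if target_n <= 0:
        raise ValueError("target_n must be positive")
    base = expected_events_per_cycle(construct, protocol, kbt) / construct.k_tr
    d = asdict(construct)
    d["b_branch"] = tuple(d["b_branch"])
    d["k_tr"] = target_n / base
    return ConstructModel(**d)


# ---------------------------------------------------------------------------
# Construct presets
# ---------------------------------------------------------------------------

#: Equilibrium properties per construct: number of cycles m, transition force
#: F_tr (pN), transition extension dX (nm), transition free energy G_BS
#: (k_B T), number of transitioning bps n, per-bp free energy g (k_B T/bp),
#: and net stabilization dG (k_B T) relative to the matching unmodified
#: reference.
EQUILIBRIUM_TABLE = {
    "Unmodified":          dict(m=176, f_tr=63.7, dx=10.8, g_bs=168.0, n=47.2, g=3.56, dg=0.0),
    "1tC":                 dict(m=117, f_tr=64.9, dx=10.0, g_bs=157.9, n=43.5, g=3.63, dg=3.04),
    "2tC":                 dict(m=82,  f_tr=65.2, dx=9.4,  g_bs=149.5, n=41.0, g=3.65, dg=3.69),
    "2tC-Stack":           dict(m=81,  f_tr=65.7, dx=9.2,  g_bs=147.2, n=40.1, g=3.67, dg=4.41),
    "3tC":                 dict(m=118, f_tr=66.2, dx=8.9,  g_bs=142.7, n=38.5, g=3.70, dg=5.39),
    "Unmodified-Int":      dict(m=237, f_tr=63.7, dx=10.6, g_bs=163.9, n=46.0, g=3.56, dg=-0.01),
    "Unmodified-Low":      dict(m=241, f_tr=62.2, dx=10.6, g_bs=160.1, n=46.1, g=3.48, dg=-3.69),
    "Unmodified-200nm/s":  dict(m=667, f_tr=62.9, dx=10.5, g_bs=160.1, n=45.5, g=3.52, dg=0.0),
    "3tC-200nm/s":         dict(m=124, f_tr=66.1, dx=8.4,  g_bs=134.4, n=36.4, g=3.69, dg=6.19),
    "Unmodified-150mM":    dict(m=55,  f_tr=62.7, dx=10.2, g_bs=154.8, n=44.2, g=3.50, dg=0.0),
}

#: Bell-Evans kinetic properties per construct: transition-state distances
#: X_B->TS and X_S->TS (nm), their sum X_BS (nm), bp count n from X_BS,
#: per-bp distances (nm/bp), TS position (% of path from B), and mean number
#: of transitions per stretch/release cycle N.
KINETICS_TABLE = {
    "Unmodified":          dict(x_b_ts=6.4, x_s_ts=4.2, x_bs=10.6, n=46.2, xb_per_bp=0.14, xs_per_bp=0.09, ts_pct=60.1, N=25),
    "1tC":                 dict(x_b_ts=6.1, x_s_ts=4.1, x_bs=10.2, n=44.2, xb_per_bp=0.14, xs_per_bp=0.09, ts_pct=60.0, N=28),
    "2tC":                 dict(x_b_ts=6.0, x_s_ts=3.6, x_bs=9.6,  n=41.8, xb_per_bp=0.14, xs_per_bp=0.09, ts_pct=62.3, N=42),
    "2tC-Stack":           dict(x_b_ts=5.3, x_s_ts=3.2, x_bs=8.6,  n=37.4, xb_per_bp=0.14, xs_per_bp=0.09, ts_pct=62.2, N=44),
    "3tC":                 dict(x_b_ts=5.6, x_s_ts=3.5, x_bs=9.2,  n=40.0, xb_per_bp=0.14, xs_per_bp=0.09, ts_pct=61.4, N=65),
    "Unmodified-Int":      dict(x_b_ts=6.5, x_s_ts=4.0, x_bs=10.5, n=45.8, xb_per_bp=0.14, xs_per_bp=0.09, ts_pct=61.8, N=23),
    "Unmodified-Low":      dict(x_b_ts=5.6, x_s_ts=4.2, x_bs=9.8,  n=42.7, xb_per_bp=0.13, xs_per_bp=0.10, ts_pct=57.3, N=31),
    "Unmodified-200nm/s":  dict(x_b_ts=6.4, x_s_ts=3.6, x_bs=10.0, n=43.5, xb_per_bp=0.15, xs_per_bp=0.08, ts_pct=64.5, N=7),
    "3tC-200nm/s":         dict(x_b_ts=4.5, x_s_ts=3.2, x_bs=7.7,  n=33.6, xb_per_bp=0.13, xs_per_bp=0.10, ts_pct=58.3, N=17),
    "Unmodified-150mM":    dict(x_b_ts=6.6, x_s_ts=3.4, x_bs=9.9,  n=43.2, xb_per_bp=0.15, xs_per_bp=0.08, ts_pct=66.2, N=36),
}

#: Reference pulling velocity (nm/s) at which each preset's N was measured.
_PRESET_VELOCITY = {name: (200.0 if name.endswith("200nm/s") else 50.0) for name in EQUILIBRIUM_TABLE}


def preset_names() -> list[str]:
    """Names of the available construct presets (Table-style labels)."""
    return list(EQUILIBRIUM_TABLE)


def construct_preset(
    name: str,
    kbt: float = DEFAULT_KBT,
    k_trap: float = 0.1,
    fray_slope: float = 1.0,
) -> ConstructModel:
    """Ground-truth :class:`ConstructModel` for a named preset.

    ``f_tr`` and ``dx_tr`` are the measured equilibrium values; the two
    transition-state distances are rescaled proportionally so that they sum
    exactly to ``dx_tr`` (the kinetic fit reports them with an independent
    error budget, so their printed sum differs from the equilibrium extension
    by ~2%); ``k_tr`` is tuned so the expected number of transitions per
    cycle at the preset's reference pulling velocity matches the measured
    mean N.
    """
    if name not in EQUILIBRIUM_TABLE:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(EQUILIBRIUM_TABLE)}")
    eq, kin = EQUILIBRIUM_TABLE[name], KINETICS_TABLE[name]
    scale = eq["dx"] / (kin["x_b_ts"] + kin["x_s_ts"])
    construct = ConstructModel(
        name=name,
        f_tr=eq["f_tr"],
        dx_tr=eq["dx"],
        x_b_ts=kin["x_b_ts"] * scale,
        x_s_ts=eq["dx"] - kin["x_b_ts"] * scale,
        k_tr=1.0,
        fray_slope=fray_slope,
        b_branch=(k_trap, 0.0),
    )
    protocol = RampProtocol(velocity=_PRESET_VELOCITY[name], k_trap=k_trap)
    return tune_rate_to_count(construct, protocol, kin["N"], kbt)
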