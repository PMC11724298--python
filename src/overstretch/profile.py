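"""Per-bp free-energy profile of the B-to-S transition and its zero-force tilt.

At the transition force the profile ``g(F_tr, x)`` over the per-bp extension
``x`` has two equally deep minima, at the B extension (``x = 0``) and at the
S extension (``x = x_BS = 0.23 nm/bp``), separated by a low barrier
``g_TS(F_tr) ~ 0.1 k_B T/bp`` at ``x_ts ~ 0.14 nm/bp`` (about 60% of the way
to S).  Outside the two minima the duplex is stiff: B-DNA stretches with an
elastic modulus of ~1000 pN and S-DNA of ~3000 pN, so the profile rises
steeply beyond the S extension (and below the B extension, off this grid).

Removing the force tilts the profile up by the mechanical work term:
``g(F=0, x) = g(F_tr, x) + F_tr * x / k_B T``.  For the measured barriers
this tilted profile increases monotonically beyond the barrier -- the S
state keeps no metastable minimum at zero force; it is an entirely
force-induced structure.

The interpolant between the anchored points (minima, barrier top, outer
walls) is illustrative geometry; the quantitative content of the profile is
the barrier height and position and the endpoint values, which is what the
tests pin down.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicHermiteSpline

from .model import DEFAULT_KBT, X_BS_PER_BP

__all__ = [
    "FreeEnergyProfile",
    "build_profile_at_ftr",
    "tilt",
    "tilt_to_zero_force",
    "classify_metastability",
    "B_STRETCH_MODULUS_PN",
    "S_STRETCH_MODULUS_PN",
    "B_RISE_NM",
    "S_RISE_NM",
]

#: Elastic stretch moduli of the two duplex forms, pN.
B_STRETCH_MODULUS_PN = 1000.0
S_STRETCH_MODULUS_PN = 3000.0
#: Per-bp rise of each form, nm (sets the per-bp spring constant
#: ``modulus / rise`` of the quadratic wells).
B_RISE_NM = 0.34
S_RISE_NM = 0.58

GRID_STEP = 0.001  # nm/bp


@dataclass
class FreeEnergyProfile:
    """Per-bp free-energy curves on the extension grid ``x`` (nm/bp).

    ``g_at_ftr`` is anchored at 0 in both minima (equal at the transition
    force); ``g_at_zero`` is filled in by :func:`tilt_to_zero_force`.
    Barrier bookkeeping: position ``x_ts`` and heights at ``F_tr`` and at
    zero force (k_B T/bp).
    """

    x: np.ndarray
    g_at_ftr: np.ndarray
    x_ts: float
    x_bs: float
    g_ts_at_ftr: float
    g_at_zero: np.ndarray | None = None
    g_ts_at_zero: float = np.nan
    f_tr: float = np.nan
    s_metastable_at_zero: bool | None = None


def build_profile_at_ftr(
    g_ts: float,
    x_ts: float = 0.14,
    x_bs: float = X_BS_PER_BP,
    stiff_b: float | None = None,
    stiff_s: float | None = None,
    kbt: float = DEFAULT_KBT,
    grid_step: float = GRID_STEP,
) -> FreeEnergyProfile:
    """Per-bp profile at the transition force on ``[0, 1.2 x_bs]``.

    Two minima pinned to zero at ``x = 0`` and ``x = x_bs``, joined by a
    smooth (C1) barrier of height ``g_ts`` peaking at ``x_ts`` (cubic
    Hermite bridge with zero slope at the three anchors); beyond ``x_bs``
    the quadratic S well wall rises with per-bp stiffness ``stiff_s``
    (``modulus / rise`` by default).  ``stiff_b`` shapes the B wall at
    ``x < 0``, outside this grid; it is kept for completeness.

    Raises
    ------
    ValueError
        If ``x_ts`` does not lie strictly between the minima, or
        ``g_ts < 0`` (``g_ts = 0`` degenerates to a flat bridge).
    """
    if not 0.0 < x_ts < x_bs:
        raise ValueError("x_ts must lie strictly between 0 and x_bs")
    if g_ts < 0:
        raise ValueError("g_ts must be >= 0")
    if stiff_s is None:
        stiff_s = S_STRETCH_MODULUS_PN / S_RISE_NM  # pN/nm per bp
    if stiff_b is None:
        stiff_b = B_STRETCH_MODULUS_PN / B_RISE_NM
    if stiff_b <= 0 or stiff_s <= 0:
        raise ValueError("well stiffnesses must be positive")
    x = np.arange(0.0, 1.2 * x_bs + grid_step / 2, grid_step)
    bridge = CubicHermiteSpline([0.0, x_ts, x_bs], [0.0, g_ts, 0.0], [0.0, 0.0, 0.0])
    g = np.where(x <= x_bs, bridge(np.minimum(x, x_bs)), 0.0)
    wall = x > x_bs
    g[wall] = 0.5 * stiff_s * (x[wall] - x_bs) ** 2 / kbt
    return FreeEnergyProfile(
        x=x, g_at_ftr=g, x_ts=x_ts, x_bs=x_bs, g_ts_at_ftr=float(g_ts)
    )


def tilt(g: np.ndarray, x: np.ndarray, force: float, kbt: float = DEFAULT_KBT) -> np.ndarray:
    """Add the mechanical work term ``force * x / k_B T`` to a profile.

    Tilting by ``+F`` and then by ``-F`` is the identity.
    """
    return g + force * np.asarray(x) / kbt


def tilt_to_zero_force(
    profile: FreeEnergyProfile, f_tr: float, kbt: float = DEFAULT_KBT
) -> FreeEnergyProfile:
    """Fill in the zero-force curve ``g(0, x) = g(F_tr, x) + F_tr x / kbt``.

    At ``x = x_bs`` the added work term is the equilibrium per-bp free
    energy ``F_tr * x_bs / k_B T``, consistent with ``g = G_BS / n``.
    """
    profile.g_at_zero = tilt(profile.g_at_ftr, profile.x, f_tr, kbt)
    profile.g_ts_at_zero = float(profile.g_ts_at_ftr + f_tr * profile.x_ts / kbt)
    profile.f_tr = float(f_tr)
    return profile


def classify_metastability(
    profile: FreeEnergyProfile,
    window_frac: float = 0.10,
    min_depth: float = 0.05,
) -> tuple[bool, float]:
    """Does the zero-force profile keep a metastable S minimum?

    Searches for an interior local minimum of ``g_at_zero`` within
    ``window_frac`` of ``x_bs``; its depth is the barrier against sliding
    back toward B (highest point between the barrier-top region and the
    minimum, minus the minimum).  Returns ``(metastable, depth)`` with
    ``depth = 0`` when no local minimum exists; metastable requires
    ``depth > min_depth`` (k_B T/bp).  The flag is stored on the profile.
    """
    if profile.g_at_zero is None:
        raise ValueError("tilt the profile to zero force first")
    g = profile.g_at_zero
    x = profile.x
    interior = slice(1, -1)
    local_min = (g[interior] < g[:-2]) & (g[interior] <= g[2:])
    idx = np.nonzero(local_min)[0] + 1
    near_s = idx[np.abs(x[idx] - profile.x_bs) <= window_frac * profile.x_bs]
    depth = 0.0
    for i in near_s:
        left = g[: i + 1]
        barrier = left.max()
        depth = max(depth, float(barrier - g[i]))
    metastable = depth > min_depth
    profile.s_metastable_at_zero = bool(metastable)
    return bool(metastable), float(depth)
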