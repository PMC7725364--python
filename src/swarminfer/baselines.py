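"""Closed-form pairwise interaction fields.

These are the expected instantaneous responses of a focal individual to a
*single* partner at relative position ``(x_rel, y_rel)`` (focal at the
origin, heading along +x), derived directly from each model's rules.  They
serve as comparison panels for, and independent oracles of, the surfaces the
averaging method infers from trajectories.

Zonal model (noise ignored): a visible partner inside the repulsion zone
drives a turn towards the opposite bearing, and a visible partner in the
attraction annulus a turn towards its bearing, both saturated at the maximum
turning rate.  Inside the orientation annulus the response depends on the
partner's heading, not its position, so the position-only field is zero
there by convention (see the module note).

ODE model: the Morse force ``(1/N) U'(d)`` on the focal resolves into a
tangential component ``(1/N) U'(d) cos(vartheta)`` that changes speed, and a
normal component whose induced turn rate is
``(180/pi) U'(d) sin(vartheta) / (N s)`` for focal speed ``s`` — so speed
changes are independent of the focal speed while turn rates scale as ``1/s``.
"""

from __future__ import annotations

import numpy as np

from .ode import ODEParams, morse_derivative
from .zonal import ZonalParams, _blind_applies

__all__ = [
    "zonal_pairwise_turn",
    "ode_pairwise_speed_change",
    "ode_pairwise_turn",
    "field_on_grid",
]

# Inside the orientation annulus the position-only response is taken as zero:
# an orientation turn depends on the partner's heading, which the relative
# position does not determine.
ZOO_CONVENTION = "zero"


def _wrap_deg(angle):
    """Wrap to (-180, 180]."""
    return -((-np.asarray(angle, dtype=float) + 180.0) % 360.0 - 180.0)


def zonal_pairwise_turn(x_rel, y_rel, params: ZonalParams):
    """Expected turn rate (deg/s) towards/away from a single partner.

    The turn over one step towards a target bearing ``b`` is
    ``sign(b) * min(|b| / dt, theta_max)`` with the model's anticlockwise
    resolution of the antipodal tie; repulsion targets the reversed partner
    bearing, attraction the partner bearing.  Partners hidden in the blind
    wedge (per the zone the distance falls in) and partners in the
    orientation annulus contribute zero.
    """
    x = np.asarray(x_rel, dtype=float)
    y = np.asarray(y_rel, dtype=float)
    d = np.hypot(x, y)
    if np.any(d == 0.0):
        raise ValueError("pairwise field undefined at the origin")
    bearing = np.degrees(np.arctan2(y, x))

    def turn_towards(target):
        delta = _wrap_deg(target)
        sign = np.where(delta == 0.0, 0.0, np.where(delta == 180.0, 1.0, np.sign(delta)))
        return sign * np.minimum(np.abs(delta) / params.dt, params.theta_max)

    out = np.zeros_like(d)
    for zone, lo, hi, target in (
        ("ZOR", 0.0, params.r_r, bearing + 180.0),
        ("ZOA", params.r_o, params.r_a, bearing),
    ):
        mask = (d > lo) & (d <= hi)
        if _blind_applies(zone, params):
            # hidden when |bearing| > 180 - omega/2
            mask &= np.abs(_wrap_deg(bearing)) <= 180.0 - params.omega_blind / 2.0
        out = np.where(mask, turn_towards(target), out)
    return out if out.ndim else float(out)


def ode_pairwise_speed_change(x_rel, y_rel, params: ODEParams):
    """Expected speed change (units/s^2): ``(1/N) U'(d) cos(vartheta)``.

    Positive dead ahead of an attracting partner, negative dead ahead of a
    repelling one; zero exactly abeam.  Independent of the focal speed.
    """
    x = np.asarray(x_rel, dtype=float)
    y = np.asarray(y_rel, dtype=float)
    d = np.hypot(x, y)
    if np.any(d == 0.0):
        raise ValueError("pairwise field undefined at the origin")
    out = morse_derivative(d, params) * (x / d) / params.N
    return out if np.ndim(out) else float(out)


def ode_pairwise_turn(x_rel, y_rel, focal_speed, params: ODEParams):
    """Expected turn rate (deg/s): ``(180/pi) U'(d) sin(vartheta) / (N s)``.

    Positive (anticlockwise, towards a left-side partner) when the partner
    attracts; scales inversely with the focal speed.
    """
    x = np.asarray(x_rel, dtype=float)
    y = np.asarray(y_rel, dtype=float)
    s = np.asarray(focal_speed, dtype=float)
    d = np.hypot(x, y)
    if np.any(d == 0.0):
        raise ValueError("pairwise field undefined at the origin")
    if np.any(s <= 0.0):
        raise ValueError("focal speed must be positive")
    out = np.degrees(morse_derivative(d, params) * (y / d) / (params.N * s))
    return out if np.ndim(out) else float(out)


def field_on_grid(func, grid) -> np.ndarray:
    """Evaluate a pairwise field at the bin centres of a grid.

    Returns an ``[ix, iy]`` array matching :class:`InteractionSurface`
    indexing; the origin bin (undefined) is set to ``NaN``.
    """
    cx, cy = np.meshgrid(grid.centres, grid.centres, indexing="ij")
    origin = (cx == 0) & (cy == 0)
    x = np.where(origin, 1.0, cx)  # placeholder, masked below
    out = np.asarray(func(x, cy), dtype=float)
    out[origin] = np.nan
    return out
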