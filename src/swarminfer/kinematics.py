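"""Finite-difference kinematics of tracked individuals.

From positions sampled every ``dt`` this module derives, per individual and
time, the forward-difference velocity, the unit heading, the speed, the
signed turn rate in degrees per second (positive = anticlockwise / left) and
the speed change.  Velocities exist for time indices ``0 .. T-2``; turn rate
and speed change need two consecutive velocities and exist for ``0 .. T-3``.
Quantities that are undefined (zero-speed frames) are encoded as ``NaN`` and
excluded from all downstream averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import Trajectory

__all__ = ["Kinematics", "compute_kinematics", "estimate_velocity", "signed_turn_rate", "speed_change"]

_COLLINEAR_TOL = 1e-12


@dataclass
class Kinematics:
    """Per-(agent, time) movement measures derived from a trajectory.

    Arrays are indexed ``[t, agent]``; ``headings`` is ``[t, agent, xy]``.
    ``u``/``v``/``speed``/``headings`` have ``T - 1`` rows, the differenced
    responses ``dtheta_dt`` (deg/s) and ``ds_dt`` (units/s^2) have ``T - 2``.
    """

    dt: float
    u: np.ndarray
    v: np.ndarray
    speed: np.ndarray
    headings: np.ndarray
    psi: np.ndarray
    lam: np.ndarray
    dtheta_dt: np.ndarray
    ds_dt: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Tidy table over the response-defined indices ``0 .. T-3``."""
        Tm2, N = self.dtheta_dt.shape
        t = np.repeat(np.arange(Tm2), N)
        a = np.tile(np.arange(N), Tm2)
        return pd.DataFrame(
            {
                "t_index": t,
                "agent_id": a,
                "u": self.u[:Tm2].ravel(),
                "v": self.v[:Tm2].ravel(),
                "speed": self.speed[:Tm2].ravel(),
                "dtheta_dt": self.dtheta_dt.ravel(),
                "ds_dt": self.ds_dt.ravel(),
            }
        )


def estimate_velocity(positions: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Forward-difference velocity components ``u, v`` with shape (T-1, N)."""
    positions = np.asarray(positions, dtype=float)
    if positions.shape[0] < 2:
        raise ValueError("need at least two time points")
    diff = np.diff(positions, axis=0) / dt
    return diff[..., 0], diff[..., 1]


def _unit_headings(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    speed = np.hypot(u, v)
    with np.errstate(invalid="ignore", divide="ignore"):
        hx = np.where(speed > 0, u / speed, np.nan)
        hy = np.where(speed > 0, v / speed, np.nan)
    return hx, hy


def signed_turn_rate(u: np.ndarray, v: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Signed turn rate in degrees/s from consecutive velocities.

    Returns ``(psi, lam, dtheta_dt)``: the unsigned heading change ``psi``
    (radians, arccos of the clamped heading dot product), the rotation sense
    ``lam`` (+1 anticlockwise, -1 clockwise, 0 collinear) and the signed rate
    ``(180/pi) * lam * psi / dt`` (with ``lam = 0`` treated as ``+1``).
    Zero-speed frames yield ``NaN``, never a silent zero.
    """
    hx, hy = _unit_headings(u, v)
    dot = hx[:-1] * hx[1:] + hy[:-1] * hy[1:]
    cross = hx[:-1] * hy[1:] - hx[1:] * hy[:-1]
    with np.errstate(invalid="ignore"):
        psi = np.arccos(np.clip(dot, -1.0, 1.0))
        lam = np.where(np.abs(cross) < _COLLINEAR_TOL, 0.0, np.sign(cross))
        lam = np.where(np.isnan(cross), np.nan, lam)
    sense = np.where(lam == 0.0, 1.0, lam)
    dtheta_dt = np.degrees(sense * psi) / dt
    return psi, lam, dtheta_dt


def speed_change(speed: np.ndarray, dt: float) -> np.ndarray:
    """Forward-difference speed change ``(s(t+dt) - s(t)) / dt``."""
    return np.diff(np.asarray(speed, dtype=float), axis=0) / dt


def compute_kinematics(traj: Trajectory) -> Kinematics:
    """All finite-difference movement measures of a trajectory."""
    u, v = estimate_velocity(traj.positions, traj.dt)
    speed = np.hypot(u, v)
    hx, hy = _unit_headings(u, v)
    psi, lam, dtheta_dt = signed_turn_rate(u, v, traj.dt)
    ds_dt = speed_change(speed, traj.dt)
    return Kinematics(
        dt=traj.dt,
        u=u,
        v=v,
        speed=speed,
        headings=np.stack([hx, hy], axis=-1),
        psi=psi,
        lam=lam,
        dtheta_dt=dtheta_dt,
        ds_dt=ds_dt,
    )
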