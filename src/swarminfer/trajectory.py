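"""Trajectory container and plain-text I/O.

A trajectory is the position record of ``N`` individuals over ``n_steps + 1``
uniformly spaced discrete times.  On disk it is a tidy delimited table with
columns ``replicate, t_index, agent_id, x, y`` — the same schema produced by
common 2-D tracking-software exports, so externally tracked data can be
imported directly.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "TrajectoryIOError",
    "MissingColumnError",
    "NonUniformTimeGridError",
    "DuplicateRecordError",
    "write_trajectory",
    "read_trajectory",
    "read_trajectories",
]

_COLUMNS = ["replicate", "t_index", "agent_id", "x", "y"]


class TrajectoryIOError(ValueError):
    """Base class for trajectory file-format errors."""


class MissingColumnError(TrajectoryIOError):
    """A required column is absent from the trajectory table."""


class NonUniformTimeGridError(TrajectoryIOError):
    """Time indices do not form a contiguous uniform grid for every agent."""


class DuplicateRecordError(TrajectoryIOError):
    """More than one record exists for the same (t_index, agent_id) key."""


@dataclass
class Trajectory:
    """Positions of a group over uniformly spaced times.

    Parameters
    ----------
    positions : ndarray of shape (T, N, 2)
        Coordinates of every agent at every saved time, ``T = n_steps + 1``.
    dt : float
        Time increment between consecutive rows, in seconds.
    replicate_id : int
        Identifier of the simulation replicate the record belongs to.
    params_fingerprint : str
        Opaque hash of the generating parameter set (empty for imported data).
    """

    positions: np.ndarray
    dt: float
    replicate_id: int = 0
    params_fingerprint: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError(
                f"positions must have shape (T, N, 2), got {self.positions.shape}"
            )
        if not np.isfinite(self.positions).all():
            raise ValueError("positions contain non-finite values")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_times(self) -> int:
        return self.positions.shape[0]

    @property
    def n_agents(self) -> int:
        return self.positions.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy (replicate, t_index, agent_id, x, y) table."""
        T, N, _ = self.positions.shape
        t = np.repeat(np.arange(T), N)
        a = np.tile(np.arange(N), T)
        flat = self.positions.reshape(T * N, 2)
        return pd.DataFrame(
            {
                "replicate": self.replicate_id,
                "t_index": t,
                "agent_id": a,
                "x": flat[:, 0],
                "y": flat[:, 1],
            }
        )


def params_fingerprint(obj) -> str:
    """Stable short hash of a parameter dataclass/dict, for manifests."""
    if hasattr(obj, "__dataclass_fields__"):
        items = sorted((k, getattr(obj, k)) for k in obj.__dataclass_fields__)
    elif isinstance(obj, dict):
        items = sorted(obj.items())
    else:
        items = [("value", obj)]
    payload = repr(items).encode()
    return hashlib.sha1(payload).hexdigest()[:12]


def write_trajectory(traj: Trajectory, path) -> None:
    """Write one trajectory as a delimited text table."""
    traj.to_frame().to_csv(path, index=False)


def write_trajectories(trajs: list[Trajectory], path) -> None:
    pd.concat([t.to_frame() for t in trajs], ignore_index=True).to_csv(
        path, index=False
    )


def _frame_to_trajectory(df: pd.DataFrame, dt: float, replicate_id: int) -> Trajectory:
    if df.duplicated(subset=["t_index", "agent_id"]).any():
        raise DuplicateRecordError(
            f"duplicate (t_index, agent_id) records in replicate {replicate_id}"
        )
    t_values = np.sort(df["t_index"].unique())
    expected = np.arange(t_values[0], t_values[0] + len(t_values))
    if not np.array_equal(t_values, expected):
        raise NonUniformTimeGridError(
            f"t_index values are not a contiguous grid in replicate {replicate_id}"
        )
    agents = np.sort(df["agent_id"].unique())
    pivot_x = df.pivot(index="t_index", columns="agent_id", values="x")
    pivot_y = df.pivot(index="t_index", columns="agent_id", values="y")
    pivot_x = pivot_x.reindex(index=t_values, columns=agents)
    pivot_y = pivot_y.reindex(index=t_values, columns=agents)
    if pivot_x.isna().any().any() or pivot_y.isna().any().any():
        raise NonUniformTimeGridError(
            f"missing (t_index, agent_id) records in replicate {replicate_id}"
        )
    positions = np.stack([pivot_x.to_numpy(), pivot_y.to_numpy()], axis=-1)
    return Trajectory(positions=positions, dt=dt, replicate_id=int(replicate_id))


def read_trajectories(path, dt: float) -> list[Trajectory]:
    """Read a delimited trajectory table, one :class:`Trajectory` per replicate.

    Extra columns (as produced by some tracking exports) are ignored with a
    warning.  ``dt`` must be supplied: the table stores integer time indices,
    the physical time increment lives in the run configuration.
    """
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"missing required columns: {missing}")
    extras = [c for c in df.columns if c not in _COLUMNS]
    if extras:
        warnings.warn(f"ignoring extra columns {extras}", stacklevel=2)
        df = df[_COLUMNS]
    return [
        _frame_to_trajectory(group, dt, rep)
        for rep, group in df.groupby("replicate", sort=True)
    ]


def read_trajectory(path, dt: float) -> Trajectory:
    """Read a trajectory file that must contain exactly one replicate."""
    trajs = read_trajectories(path, dt)
    if len(trajs) != 1:
        raise TrajectoryIOError(
            f"expected a single replicate, found {len(trajs)}"
        )
    return trajs[0]
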