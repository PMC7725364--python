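"""Deterministic analytic test tracks.

Closed-form trajectories with known kinematics — straight lines, uniform
circular motion (constant turn rate ``360 / period`` deg/s and zero speed
change), simple two-agent approach/recede tracks, and stationary agents —
for exercising the kinematics and averaging machinery against exact values.
"""

from __future__ import annotations

import numpy as np

from .trajectory import Trajectory

__all__ = ["make_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("straight_line", "circle", "approach", "two_stationary")


def make_fixture(
    kind: str,
    n_steps: int = 100,
    dt: float = 0.1,
    speed: float = 3.0,
    radius: float = 1.0,
    period: float = 12.0,
    anticlockwise: bool = True,
    seed: int = 0,
) -> Trajectory:
    """Build a closed-form trajectory of the requested ``kind``.

    * ``straight_line`` — one agent moving along +x at ``speed``.
    * ``circle`` — one agent on a circle of ``radius`` with the given
      ``period`` (s); signed turn rate is ``±360 / period`` deg/s.
    * ``approach`` — two agents on the x-axis moving towards each other at
      ``speed``, starting ``4 * radius`` apart.
    * ``two_stationary`` — two motionless agents (kinematics undefined).

    ``seed`` only randomises the straight line's direction, keeping fixture
    generation reproducible.
    """
    t = np.arange(n_steps + 1) * dt
    if kind == "straight_line":
        rng = np.random.default_rng(seed)
        angle = rng.uniform(0.0, 2.0 * np.pi)
        h = np.array([np.cos(angle), np.sin(angle)])
        pos = (speed * t)[:, None] * h
        return Trajectory(pos[:, None, :], dt)
    if kind == "circle":
        omega = 2.0 * np.pi / period * (1.0 if anticlockwise else -1.0)
        pos = radius * np.stack([np.cos(omega * t), np.sin(omega * t)], axis=-1)
        return Trajectory(pos[:, None, :], dt)
    if kind == "approach":
        x0 = 2.0 * radius
        a = np.stack([-x0 + speed * t, np.zeros_like(t)], axis=-1)
        b = np.stack([x0 - speed * t, np.zeros_like(t)], axis=-1)
        return Trajectory(np.stack([a, b], axis=1), dt)
    if kind == "two_stationary":
        pos = np.zeros((n_steps + 1, 2, 2))
        pos[:, 1, 0] = 1.0
        return Trajectory(pos, dt)
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
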