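"""Discrete-time zonal (repulsion / orientation / attraction) flocking model.

Self-propelled particles move at constant speed in an unbounded plane and
steer according to three concentric zones around each individual:

* **zone of repulsion (ZOR)**, radius ``r_r`` — move directly away from
  neighbours at collision range; this response overrides everything else;
* **zone of orientation (ZOO)**, annulus out to ``r_o = r_r + delta_r_o`` —
  align the heading with neighbours' headings;
* **zone of attraction (ZOA)**, annulus out to ``r_a = r_o + delta_r_a`` —
  move towards more distant neighbours to keep the group together.

A rear blind wedge of angular extent ``omega_blind`` hides neighbours from the
focal individual; turning per step is capped at ``theta_max * dt`` degrees and
the chosen direction is perturbed by Gaussian angular noise of standard
deviation ``eta`` radians.  All agents update synchronously from the same
time-``t`` snapshot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .trajectory import Trajectory, params_fingerprint

__all__ = ["ZonalParams", "visible_neighbours", "desired_direction", "step", "run_zonal"]

BLIND_SCOPES = ("all_zones", "orientation_and_attraction_only", "none")


@dataclass(frozen=True)
class ZonalParams:
    """Parameters of the zonal model.

    Defaults are the standard simulation values used throughout the package:
    maximum turning rate 40 deg/s, speed 3 units/s, time step 0.1 s, angular
    noise 0.1 rad, groups of 25 over 1000 steps, started in a 10-unit square.
    """

    N: int = 25
    r_r: float = 1.0
    delta_r_o: float = 2.0
    delta_r_a: float = 11.0
    omega_blind: float = 90.0
    blind_scope: str = "all_zones"
    theta_max: float = 40.0
    s: float = 3.0
    dt: float = 0.1
    eta: float = 0.1
    n_steps: int = 1000
    seed: int = 0
    init_box: float = 10.0
    # Whether the focal's own heading joins the orientation sum.  The classic
    # formulation uses partner headings only; kept switchable because the
    # choice is not observable from position data alone.
    include_self_heading: bool = False
    # How orientation and attraction terms combine when both zones are
    # populated: "sum" adds the raw partner sums (each partner carries equal
    # weight, as in the classic formulation), "normalised" averages the unit
    # orientation and attraction directions (each zone carries equal weight).
    combine_mode: str = "sum"

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.r_r <= 0 or self.delta_r_o < 0 or self.delta_r_a < 0:
            raise ValueError("zone sizes must satisfy r_r > 0 and widths >= 0")
        if not (self.r_r < self.r_o < self.r_a):
            raise ValueError("zone radii must satisfy r_r < r_o < r_a")
        if not (0 <= self.omega_blind < 360):
            raise ValueError("omega_blind must lie in [0, 360)")
        if self.blind_scope not in BLIND_SCOPES:
            raise ValueError(f"blind_scope must be one of {BLIND_SCOPES}")
        if self.theta_max <= 0 or self.s <= 0 or self.dt <= 0 or self.eta < 0:
            raise ValueError("theta_max, s, dt must be > 0 and eta >= 0")
        if self.combine_mode not in ("sum", "normalised"):
            raise ValueError("combine_mode must be 'sum' or 'normalised'")

    @property
    def r_o(self) -> float:
        return self.r_r + self.delta_r_o

    @property
    def r_a(self) -> float:
        return self.r_o + self.delta_r_a


def _blind_applies(zone: str, params: ZonalParams) -> bool:
    if params.omega_blind == 0 or params.blind_scope == "none":
        return False
    if params.blind_scope == "orientation_and_attraction_only":
        return zone in ("ZOO", "ZOA")
    return True  # all_zones


_ZONE_BOUNDS = {
    "ZOR": lambda p: (0.0, p.r_r),
    "ZOO": lambda p: (p.r_r, p.r_o),
    "ZOA": lambda p: (p.r_o, p.r_a),
}


def visible_neighbours(
    focal_position: np.ndarray,
    focal_heading: np.ndarray,
    positions: np.ndarray,
    zone: str,
    params: ZonalParams,
) -> np.ndarray:
    """Indices of ``positions`` that the focal individual perceives in ``zone``.

    A neighbour is perceived if its distance lies in the zone annulus
    (``ZOR``: (0, r_r], ``ZOO``: (r_r, r_o], ``ZOA``: (r_o, r_a]) and it is
    not hidden in the rear blind wedge of half-angle ``omega_blind / 2``
    centred on the reversed heading (when the blind zone applies to ``zone``).
    A neighbour exactly coincident with the focal position has no defined
    direction and is excluded with a warning.
    """
    if zone not in _ZONE_BOUNDS:
        raise ValueError(f"zone must be one of {tuple(_ZONE_BOUNDS)}")
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    diff = positions - np.asarray(focal_position, dtype=float)
    d = np.hypot(diff[:, 0], diff[:, 1])
    if np.any(d == 0.0):
        warnings.warn(
            "coincident neighbour position: direction undefined, excluded",
            stacklevel=2,
        )
    lo, hi = _ZONE_BOUNDS[zone](params)
    mask = (d > lo) & (d <= hi)
    if _blind_applies(zone, params):
        # hidden when the angle from the *reversed* heading is < omega/2,
        # i.e. the angle from the heading exceeds 180 - omega/2.
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = (diff @ np.asarray(focal_heading, dtype=float)) / np.where(
                d > 0, d, 1.0
            )
        mask &= cosang >= np.cos(np.radians(180.0 - params.omega_blind / 2.0))
    return np.flatnonzero(mask)


def _normalise(vec: np.ndarray) -> np.ndarray | None:
    norm = np.hypot(vec[0], vec[1])
    if norm < 1e-12:
        return None
    return vec / norm


def desired_direction(
    focal: int,
    positions: np.ndarray,
    headings: np.ndarray,
    params: ZonalParams,
) -> np.ndarray | None:
    """Preferred unit direction of agent ``focal``, or ``None`` (no preference).

    Repulsion from perceived ZOR neighbours overrides everything; otherwise
    the normalised orientation and attraction terms are averaged when both
    zones are populated.  A numerically zero resultant means no preference.
    """
    others = np.delete(np.arange(len(positions)), focal)
    fp, fh = positions[focal], headings[focal]

    diff = positions[others] - fp
    d = np.hypot(diff[:, 0], diff[:, 1])
    if np.any(d == 0.0):
        warnings.warn(
            "coincident neighbour position: direction undefined, excluded",
            stacklevel=2,
        )
    in_range = (d > 0.0) & (d <= params.r_a)
    if not in_range.any():
        return None
    unit = np.zeros_like(diff)
    unit[in_range] = diff[in_range] / d[in_range, None]
    cosang = unit @ fh
    blind_cos = np.cos(np.radians(180.0 - params.omega_blind / 2.0))

    def zone_visible(zone: str) -> np.ndarray:
        lo, hi = _ZONE_BOUNDS[zone](params)
        mask = in_range & (d > lo) & (d <= hi)
        if _blind_applies(zone, params):
            mask &= cosang >= blind_cos
        return mask

    zor = zone_visible("ZOR")
    if zor.any():
        return _normalise(-unit[zor].sum(axis=0))

    terms = []
    zoo = zone_visible("ZOO")
    if zoo.any():
        o_sum = headings[others][zoo].sum(axis=0)
        if params.include_self_heading:
            o_sum = o_sum + fh
        if params.combine_mode == "sum":
            terms.append(o_sum)
        else:
            o_hat = _normalise(o_sum)
            if o_hat is not None:
                terms.append(o_hat)
    zoa = zone_visible("ZOA")
    if zoa.any():
        a_sum = unit[zoa].sum(axis=0)
        if params.combine_mode == "sum":
            terms.append(a_sum)
        else:
            a_hat = _normalise(a_sum)
            if a_hat is not None:
                terms.append(a_hat)
    if not terms:
        return None
    return _normalise(np.sum(terms, axis=0))


def _rotate(vectors: np.ndarray, angles_rad: np.ndarray) -> np.ndarray:
    c, s = np.cos(angles_rad), np.sin(angles_rad)
    x, y = vectors[..., 0], vectors[..., 1]
    return np.stack([c * x - s * y, s * x + c * y], axis=-1)


def step(
    positions: np.ndarray,
    headings: np.ndarray,
    params: ZonalParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance all agents by one time step (synchronous update).

    Each agent's desired direction is computed from the time-``t`` snapshot,
    rotated by a Gaussian angle (sd ``eta`` rad), and the current heading is
    rotated towards the result by at most ``theta_max * dt`` degrees.  An
    agent with no preference steers towards its own (noise-perturbed)
    heading.  The position then advances by ``s * dt`` along the new heading,
    so speed is conserved exactly.  An exactly antipodal desired direction is
    resolved anticlockwise (``atan2`` returns +180 deg).
    """
    N = len(positions)
    desired = np.empty_like(headings)
    for i in range(N):
        d = desired_direction(i, positions, headings, params)
        desired[i] = headings[i] if d is None else d
    noise = rng.normal(0.0, params.eta, size=N) if params.eta > 0 else np.zeros(N)
    desired = _rotate(desired, noise)

    # signed angle from current heading to desired, clipped to the turn cap
    cross = headings[:, 0] * desired[:, 1] - headings[:, 1] * desired[:, 0]
    dot = np.einsum("ij,ij->i", headings, desired)
    turn = np.arctan2(cross, dot)
    cap = np.radians(params.theta_max * params.dt)
    turn = np.clip(turn, -cap, cap)
    new_headings = _rotate(headings, turn)
    new_headings /= np.hypot(new_headings[:, 0], new_headings[:, 1])[:, None]
    new_positions = positions + params.s * params.dt * new_headings
    return new_positions, new_headings


def initial_conditions(
    params: ZonalParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform positions in a centred square of side ``init_box``; uniform headings."""
    half = params.init_box / 2.0
    positions = rng.uniform(-half, half, size=(params.N, 2))
    angles = rng.uniform(0.0, 2.0 * np.pi, size=params.N)
    headings = np.stack([np.cos(angles), np.sin(angles)], axis=-1)
    return positions, headings


def run_zonal(params: ZonalParams, replicate_id: int = 0) -> Trajectory:
    """Run a seeded zonal simulation and return the position record.

    The same ``params`` (including ``seed``) always produce a bit-identical
    trajectory.
    """
    rng = np.random.default_rng(params.seed)
    positions, headings = initial_conditions(params, rng)
    out = np.empty((params.n_steps + 1, params.N, 2))
    out[0] = positions
    for t in range(params.n_steps):
        positions, headings = step(positions, headings, params, rng)
        out[t + 1] = positions
    return Trajectory(
        positions=out,
        dt=params.dt,
        replicate_id=replicate_id,
        params_fingerprint=params_fingerprint(params),
    )


def with_seed(params: ZonalParams, seed: int) -> ZonalParams:
    return replace(params, seed=seed)
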