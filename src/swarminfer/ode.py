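"""Continuous-time swarm model with self-propulsion, friction and a Morse potential.

Each of ``N`` individuals obeys

    dx_i/dt = v_i
    dv_i/dt = (alpha - beta |v_i|^2) v_i - (1/N) sum_{j != i} grad U(|x_i - x_j|)

with the Morse potential

    U(r) = -C_A exp(-r / l_A) + C_R exp(-r / l_R).

The self-propulsion/friction term drives individual speed towards the
equilibrium ``sqrt(alpha / beta)``; the pairwise force is attractive where
``U'(r) > 0`` and repulsive where ``U'(r) < 0``, with equilibrium spacing at
the zero crossing of ``U'``.  Time integration uses the classical
fourth-order Runge-Kutta scheme on an unbounded domain.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .trajectory import Trajectory, params_fingerprint

__all__ = [
    "ODEParams",
    "MORSE_PRESETS",
    "SingularConfigurationError",
    "morse_derivative",
    "morse_equilibrium_distance",
    "derivatives",
    "rk4_step",
    "run_ode",
]

_MIN_SEPARATION = 1e-9  # guard against overflow on near-coincident draws


class SingularConfigurationError(ValueError):
    """Two individuals occupy the same position; the force is undefined."""


@dataclass(frozen=True)
class ODEParams:
    """Parameters of the Morse-potential swarm model.

    ``init_speed_mode`` selects the initial speed: ``"sqrt_ratio"`` starts
    individuals at the self-propulsion equilibrium ``sqrt(alpha / beta)``
    (default), ``"ratio"`` at the literal quotient ``alpha / beta``.
    """

    N: int = 10
    alpha: float = 1.0
    beta: float = 1.0
    C_A: float = 100.0
    C_R: float = 50.0
    l_A: float = 50.0
    l_R: float = 5.0
    dt: float = 0.1
    n_steps: int = 10000
    seed: int = 0
    init_box: float = 100.0
    init_speed_mode: str = "sqrt_ratio"

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.alpha < 0 or self.beta <= 0:
            raise ValueError("require alpha >= 0 and beta > 0")
        if min(self.C_A, self.C_R, self.l_A, self.l_R) <= 0:
            raise ValueError("Morse amplitudes and length scales must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.init_speed_mode not in ("sqrt_ratio", "ratio"):
            raise ValueError("init_speed_mode must be 'sqrt_ratio' or 'ratio'")

    @property
    def equilibrium_speed(self) -> float:
        return float(np.sqrt(self.alpha / self.beta))


#: Named parameter sets spanning the model's emergent states: (a) double
#: mill, (b) mills / swarm, (c) parallel aligned / swarm, (d) swarm.
MORSE_PRESETS: dict[str, ODEParams] = {
    "a": ODEParams(alpha=0.15, beta=0.05, C_A=100, C_R=50, l_A=100, l_R=20),
    "b": ODEParams(alpha=0.04, beta=0.005, C_A=100, C_R=150, l_A=100, l_R=3),
    "c": ODEParams(alpha=1.0, beta=1.0, C_A=100, C_R=50, l_A=50, l_R=5),
    "d": ODEParams(alpha=1.0, beta=0.5, C_A=100, C_R=50, l_A=200, l_R=30),
}


def morse_derivative(r, params: ODEParams):
    """Radial derivative ``U'(r)`` of the Morse potential.

    ``U'(r) = (C_A / l_A) exp(-r / l_A) - (C_R / l_R) exp(-r / l_R)``;
    positive values mean net pairwise attraction, negative net repulsion.
    Raises for any ``r <= 0``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("morse_derivative requires r > 0")
    out = (params.C_A / params.l_A) * np.exp(-r / params.l_A) - (
        params.C_R / params.l_R
    ) * np.exp(-r / params.l_R)
    return out if out.ndim else float(out)


def morse_equilibrium_distance(params: ODEParams) -> float:
    """Zero crossing ``r*`` of ``U'``: the pairwise equilibrium spacing.

    Closed form: ``r* = ln(C_R l_A / (C_A l_R)) / (1/l_R - 1/l_A)``.
    Returns ``nan`` when repulsion never dominates (no sign change).
    """
    ratio = params.C_R * params.l_A / (params.C_A * params.l_R)
    denom = 1.0 / params.l_R - 1.0 / params.l_A
    if ratio <= 0 or denom == 0:
        return float("nan")
    r_star = np.log(ratio) / denom
    return float(r_star) if r_star > 0 else float("nan")


def derivatives(
    positions: np.ndarray, velocities: np.ndarray, params: ODEParams
) -> tuple[np.ndarray, np.ndarray]:
    """Phase-space rates (dx/dt, dv/dt) of the swarm ODE.

    ``dv_i/dt = (alpha - beta |v_i|^2) v_i + (1/N) sum_j U'(r_ij) rhat_ij``
    where ``rhat_ij`` points from ``i`` towards ``j`` (this is exactly
    ``-(1/N) sum grad U``).
    """
    positions = np.asarray(positions, dtype=float)
    velocities = np.asarray(velocities, dtype=float)
    N = len(positions)
    speed2 = np.einsum("ij,ij->i", velocities, velocities)
    dvel = (params.alpha - params.beta * speed2)[:, None] * velocities
    if N > 1:
        diff = positions[None, :, :] - positions[:, None, :]  # i -> j
        dist = np.hypot(diff[..., 0], diff[..., 1])
        off = ~np.eye(N, dtype=bool)
        if np.any(dist[off] == 0.0):
            i, j = np.argwhere(off & (dist == 0.0))[0]
            raise SingularConfigurationError(
                f"individuals {i} and {j} are coincident"
            )
        # clamp near-coincident separations to avoid overflow in exp(-r/l_R)
        dist_safe = np.maximum(dist, _MIN_SEPARATION)
        uprime = np.zeros_like(dist)
        uprime[off] = morse_derivative(dist_safe[off], params)
        coeff = np.where(off, uprime / dist_safe, 0.0)
        dvel = dvel + np.einsum("ij,ijk->ik", coeff, diff) / N
    return velocities.copy(), dvel


def rk4_step(
    positions: np.ndarray, velocities: np.ndarray, params: ODEParams
) -> tuple[np.ndarray, np.ndarray]:
    """One classical fourth-order Runge-Kutta step of length ``dt``."""
    h = params.dt
    k1x, k1v = derivatives(positions, velocities, params)
    k2x, k2v = derivatives(positions + 0.5 * h * k1x, velocities + 0.5 * h * k1v, params)
    k3x, k3v = derivatives(positions + 0.5 * h * k2x, velocities + 0.5 * h * k2v, params)
    k4x, k4v = derivatives(positions + h * k3x, velocities + h * k3v, params)
    new_pos = positions + (h / 6.0) * (k1x + 2 * k2x + 2 * k3x + k4x)
    new_vel = velocities + (h / 6.0) * (k1v + 2 * k2v + 2 * k3v + k4v)
    return new_pos, new_vel


def initial_conditions(
    params: ODEParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform positions in a square of side ``init_box``, random directions,
    initial speed per ``init_speed_mode``."""
    half = params.init_box / 2.0
    positions = rng.uniform(-half, half, size=(params.N, 2))
    angles = rng.uniform(0.0, 2.0 * np.pi, size=params.N)
    if params.init_speed_mode == "sqrt_ratio":
        s0 = params.equilibrium_speed
    else:
        s0 = params.alpha / params.beta
    velocities = s0 * np.stack([np.cos(angles), np.sin(angles)], axis=-1)
    return positions, velocities


def integrate(params: ODEParams) -> tuple[np.ndarray, np.ndarray]:
    """Full phase-space record: positions and velocities, shape (T, N, 2)."""
    rng = np.random.default_rng(params.seed)
    positions, velocities = initial_conditions(params, rng)
    pos_out = np.empty((params.n_steps + 1, params.N, 2))
    vel_out = np.empty_like(pos_out)
    pos_out[0], vel_out[0] = positions, velocities
    for t in range(params.n_steps):
        positions, velocities = rk4_step(positions, velocities, params)
        pos_out[t + 1], vel_out[t + 1] = positions, velocities
    return pos_out, vel_out


def run_ode(params: ODEParams, replicate_id: int = 0) -> Trajectory:
    """Run a seeded swarm-ODE simulation; positions are saved every ``dt``."""
    pos, _ = integrate(params)
    return Trajectory(
        positions=pos,
        dt=params.dt,
        replicate_id=replicate_id,
        params_fingerprint=params_fingerprint(params),
    )


def with_seed(params: ODEParams, seed: int) -> ODEParams:
    return replace(params, seed=seed)
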