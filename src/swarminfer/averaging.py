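"""Averaging (force-matching) inference of interaction surfaces.

The method expresses each individual's instantaneous responses — signed turn
rate and speed change — as a function of where its group mates are.  For
every ordered (focal, partner) pair at every time, the partner's position is
rewritten in the focal frame (focal at the origin, heading along +x) and the
focal's response is deposited into every overlapping square bin that contains
the partner's relative position.  The per-bin mean over all samples is the
inferred interaction surface; bins that never receive a sample are undefined
(rendered white in heat maps).

Binning may additionally be conditioned on the focal individual's speed,
producing one surface per speed class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import Kinematics, compute_kinematics
from .trajectory import Trajectory

__all__ = [
    "GridSpec",
    "FINE_GRID",
    "InteractionSurface",
    "relative_coordinates",
    "bin_responses",
    "pooled_surface",
    "surface_from_trajectories",
    "write_surface",
    "read_surface",
]

RESPONSES = {"turn_rate": "dtheta_dt", "speed_change": "ds_dt"}
WINDOWS = ("full", "first_half", "second_half")


@dataclass(frozen=True)
class GridSpec:
    """Overlapping square bins on a centred square domain.

    ``w`` is the bin side length, ``c`` the spacing between bin centres
    (``c < w`` gives overlap; the default is 50 %), ``L`` the half-extent of
    the domain: centres run from ``-L`` to ``+L`` in steps of ``c`` on each
    axis.  Membership is half-open per axis, ``[centre - w/2, centre + w/2)``,
    so a sample's set of containing bins is unambiguous.
    """

    w: float = 1.0
    c: float = 0.5
    L: float = 15.0

    def __post_init__(self) -> None:
        if self.w <= 0 or self.c <= 0 or self.L <= 0:
            raise ValueError("grid spec requires w > 0, c > 0, L > 0")

    @property
    def half_n(self) -> int:
        return int(round(self.L / self.c))

    @property
    def centres(self) -> np.ndarray:
        k = self.half_n
        return np.arange(-k, k + 1) * self.c


#: Finer, smaller-domain preset used to resolve sub-unit repulsion zones.
FINE_GRID = GridSpec(w=0.25, c=0.125, L=3.0)


@dataclass
class InteractionSurface:
    """Gridded mean response over relative partner coordinates.

    Arrays are indexed ``[ix, iy]`` following ``grid.centres`` on each axis.
    ``count``, ``value_sum`` and ``value_sqsum`` are the raw accumulators, so
    surfaces over the same grid can be pooled exactly; ``mean`` and ``var``
    are derived views with ``NaN`` in empty bins.
    """

    grid: GridSpec
    response: str
    count: np.ndarray
    value_sum: np.ndarray
    value_sqsum: np.ndarray
    speed_range: tuple[float, float] | None = None

    @classmethod
    def empty(cls, grid: GridSpec, response: str,
              speed_range: tuple[float, float] | None = None) -> "InteractionSurface":
        n = 2 * grid.half_n + 1
        z = np.zeros((n, n))
        return cls(grid, response, z.copy(), z.copy(), z.copy(), speed_range)

    @property
    def x_centres(self) -> np.ndarray:
        return self.grid.centres

    @property
    def y_centres(self) -> np.ndarray:
        return self.grid.centres

    @property
    def mean(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.count > 0, self.value_sum / self.count, np.nan)

    @property
    def var(self) -> np.ndarray:
        """Per-bin population variance (``NaN`` where the bin is empty)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            m = self.value_sum / self.count
            return np.where(self.count > 0, self.value_sqsum / self.count - m**2, np.nan)

    def to_frame(self) -> pd.DataFrame:
        cx, cy = np.meshgrid(self.x_centres, self.y_centres, indexing="ij")
        df = pd.DataFrame(
            {
                "x_centre": cx.ravel(),
                "y_centre": cy.ravel(),
                "count": self.count.ravel().astype(int),
                "mean": self.mean.ravel(),
                "var": self.var.ravel(),
            }
        )
        if self.speed_range is not None:
            df.insert(2, "speed_lo", self.speed_range[0])
            df.insert(3, "speed_hi", self.speed_range[1])
        return df


def relative_coordinates(
    traj: Trajectory, kin: Kinematics | None = None
) -> pd.DataFrame:
    """Focal-frame relative coordinates with paired focal responses.

    One row per ordered pair (focal ``i``, partner ``j != i``) per time at
    which both the focal heading and the focal responses are defined
    (``t = 0 .. T-3``).  Columns: ``focal, partner, t, d, phi, zeta,
    vartheta, x_rel, y_rel, dtheta_dt, ds_dt, s_focal``; ``phi`` and
    ``vartheta`` are in degrees, ``vartheta`` signed (+ = partner on the
    focal's left).  Rows with an undefined focal heading are omitted.
    """
    if kin is None:
        kin = compute_kinematics(traj)
    Tm2, N = kin.dtheta_dt.shape
    if N < 2:
        return pd.DataFrame(
            columns=["focal", "partner", "t", "d", "phi", "zeta", "vartheta",
                     "x_rel", "y_rel", "dtheta_dt", "ds_dt", "s_focal"]
        )
    pos = traj.positions[:Tm2]  # (T', N, 2)
    hx = kin.headings[:Tm2, :, 0]
    hy = kin.headings[:Tm2, :, 1]

    # (T', focal, partner)
    dx = pos[:, None, :, 0] - pos[:, :, None, 0]
    dy = pos[:, None, :, 1] - pos[:, :, None, 1]
    d = np.hypot(dx, dy)
    off = ~np.eye(N, dtype=bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        xhat = np.where(d > 0, dx / d, np.nan)
        yhat = np.where(d > 0, dy / d, np.nan)
        dot = hx[:, :, None] * xhat + hy[:, :, None] * yhat
        cross = hx[:, :, None] * yhat - hy[:, :, None] * xhat
        phi = np.degrees(np.arccos(np.clip(dot, -1.0, 1.0)))
    zeta = np.where(np.abs(cross) < 1e-12, 0.0, np.sign(cross))
    zeta = np.where(np.isnan(cross), np.nan, zeta)
    vartheta = np.where(zeta == 0.0, phi, zeta * phi)
    x_rel = d * np.cos(np.radians(vartheta))
    y_rel = d * np.sin(np.radians(vartheta))

    t_idx, f_idx, p_idx = np.broadcast_arrays(
        np.arange(Tm2)[:, None, None],
        np.arange(N)[None, :, None],
        np.arange(N)[None, None, :],
    )
    valid = off[None, :, :] & np.isfinite(vartheta)
    valid &= np.isfinite(kin.dtheta_dt)[:, :, None] & np.isfinite(kin.ds_dt)[:, :, None]
    m = valid.ravel()
    return pd.DataFrame(
        {
            "focal": f_idx.ravel()[m],
            "partner": p_idx.ravel()[m],
            "t": t_idx.ravel()[m],
            "d": d.ravel()[m],
            "phi": phi.ravel()[m],
            "zeta": zeta.ravel()[m],
            "vartheta": vartheta.ravel()[m],
            "x_rel": x_rel.ravel()[m],
            "y_rel": y_rel.ravel()[m],
            "dtheta_dt": np.broadcast_to(kin.dtheta_dt[:, :, None], d.shape).ravel()[m],
            "ds_dt": np.broadcast_to(kin.ds_dt[:, :, None], d.shape).ravel()[m],
            "s_focal": np.broadcast_to(kin.speed[:Tm2, :, None], d.shape).ravel()[m],
        }
    )


def _accumulate(surface: InteractionSurface, x, y, values) -> None:
    """Deposit each sample into every overlapping bin containing it."""
    g = surface.grid
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    values = np.asarray(values, dtype=float)
    K = g.half_n
    # bin centre c*k contains x iff c*k in (x - w/2, x + w/2]
    kx_min = np.floor((x - g.w / 2) / g.c).astype(int) + 1
    kx_max = np.floor((x + g.w / 2) / g.c).astype(int)
    ky_min = np.floor((y - g.w / 2) / g.c).astype(int) + 1
    ky_max = np.floor((y + g.w / 2) / g.c).astype(int)
    span = int(np.ceil(g.w / g.c)) + 1
    for ox in range(span):
        kx = kx_min + ox
        mx = (kx <= kx_max) & (np.abs(kx) <= K)
        if not mx.any():
            continue
        for oy in range(span):
            ky = ky_min + oy
            m = mx & (ky <= ky_max) & (np.abs(ky) <= K)
            if not m.any():
                continue
            ix, iy, val = kx[m] + K, ky[m] + K, values[m]
            np.add.at(surface.count, (ix, iy), 1.0)
            np.add.at(surface.value_sum, (ix, iy), val)
            np.add.at(surface.value_sqsum, (ix, iy), val**2)


def _speed_class_edges(speeds: np.ndarray, speed_classes) -> np.ndarray:
    if np.isscalar(speed_classes):
        q = np.linspace(0.0, 1.0, int(speed_classes) + 1)
        edges = np.quantile(speeds, q)
        edges[0], edges[-1] = -np.inf, np.inf
        return edges
    return np.asarray(speed_classes, dtype=float)


def bin_responses(
    pairs: pd.DataFrame,
    grid: GridSpec,
    response: str = "turn_rate",
    speed_classes=None,
) -> InteractionSurface | list[InteractionSurface]:
    """Bin pair samples into an interaction surface.

    ``response`` selects the deposited quantity (``"turn_rate"`` in deg/s or
    ``"speed_change"`` in units/s^2).  With ``speed_classes`` (an integer
    number of equal-count focal-speed quantile classes, or explicit edges) a
    list of surfaces is returned, one per class.  An all-empty surface is
    emitted with a warning rather than an error.
    """
    if response not in RESPONSES:
        raise ValueError(f"response must be one of {tuple(RESPONSES)}")
    col = RESPONSES[response]
    if speed_classes is not None:
        edges = _speed_class_edges(pairs["s_focal"].to_numpy(), speed_classes)
        out = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            sel = pairs[(pairs["s_focal"] >= lo) & (pairs["s_focal"] < hi)]
            surf = InteractionSurface.empty(grid, response, (float(lo), float(hi)))
            _accumulate(surf, sel["x_rel"], sel["y_rel"], sel[col])
            out.append(surf)
        return out
    surf = InteractionSurface.empty(grid, response)
    _accumulate(surf, pairs["x_rel"], pairs["y_rel"], pairs[col])
    if surf.count.sum() == 0:
        warnings.warn("no samples fell inside the binning domain", stacklevel=2)
    return surf


def pooled_surface(surfaces: list[InteractionSurface]) -> InteractionSurface:
    """Pool surfaces over replicates: counts and sums add, means recompute."""
    if not surfaces:
        raise ValueError("nothing to pool")
    first = surfaces[0]
    out = InteractionSurface.empty(first.grid, first.response, first.speed_range)
    for s in surfaces:
        if s.grid != first.grid or s.response != first.response:
            raise ValueError("cannot pool surfaces with mismatched grids or responses")
        out.count += s.count
        out.value_sum += s.value_sum
        out.value_sqsum += s.value_sqsum
    return out


def _window_mask(t: np.ndarray, n_response_times: int, window: str) -> np.ndarray:
    if window not in WINDOWS:
        raise ValueError(f"window must be one of {WINDOWS}")
    if window == "full":
        return np.ones(len(t), dtype=bool)
    split = n_response_times // 2
    return t < split if window == "first_half" else t >= split


def surface_from_trajectories(
    trajs: list[Trajectory],
    grid: GridSpec,
    response: str = "turn_rate",
    window: str = "full",
    speed_classes=None,
) -> InteractionSurface | list[InteractionSurface]:
    """Pooled surface over replicate trajectories, optionally time-windowed.

    The window restricts the response time index ``t`` (``first_half``:
    ``t < floor((T-2)/2)``; ``second_half``: the rest), so first- and
    second-half counts always partition the full-window counts.
    """
    per_rep = []
    for traj in trajs:
        pairs = relative_coordinates(traj)
        n_resp = traj.n_times - 2
        if len(pairs):
            pairs = pairs[_window_mask(pairs["t"].to_numpy(), n_resp, window)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            per_rep.append(bin_responses(pairs, grid, response, speed_classes))
    if speed_classes is None:
        surf = pooled_surface(per_rep)
        if surf.count.sum() == 0:
            warnings.warn("pooled surface is empty", stacklevel=2)
        return surf
    n_classes = len(per_rep[0])
    return [pooled_surface([r[k] for r in per_rep]) for k in range(n_classes)]


def antisymmetrise(surface: InteractionSurface) -> InteractionSurface:
    """Enforce left/right mirror antisymmetry on a turn-response surface.

    The turn response to a mirror-symmetric interaction rule obeys
    ``field(x, -y) = -field(x, y)``; emergent group rotation (milling
    replicates of one sense outnumbering the other) breaks this in finite
    ensembles by adding a common-mode offset to every bin.  Combining each
    bin with its negated mirror bin (count-weighted) cancels that rotation
    bias exactly while leaving an already antisymmetric surface unchanged.
    """
    out = InteractionSurface.empty(surface.grid, surface.response, surface.speed_range)
    out.count = surface.count + surface.count[:, ::-1]
    out.value_sum = surface.value_sum - surface.value_sum[:, ::-1]
    out.value_sqsum = surface.value_sqsum + surface.value_sqsum[:, ::-1]
    return out


def write_surface(surface: InteractionSurface, path) -> None:
    """Write a surface as a gridded delimited table."""
    surface.to_frame().to_csv(path, index=False)


def read_surface(path, grid: GridSpec | None = None,
                 response: str = "turn_rate") -> InteractionSurface:
    """Rebuild a surface written by :func:`write_surface`.

    The grid geometry is inferred from the centre columns when ``grid`` is
    not given (bin width then defaults to twice the centre spacing).
    """
    df = pd.read_csv(path)
    xs = np.sort(df["x_centre"].unique())
    c = float(xs[1] - xs[0])
    if grid is None:
        grid = GridSpec(w=2 * c, c=c, L=float(xs[-1]))
    surf = InteractionSurface.empty(grid, response)
    K = grid.half_n
    ix = np.rint(df["x_centre"].to_numpy() / grid.c).astype(int) + K
    iy = np.rint(df["y_centre"].to_numpy() / grid.c).astype(int) + K
    count = df["count"].to_numpy(dtype=float)
    mean = np.nan_to_num(df["mean"].to_numpy(), nan=0.0)
    var = np.nan_to_num(df["var"].to_numpy(), nan=0.0)
    surf.count[ix, iy] = count
    surf.value_sum[ix, iy] = mean * count
    surf.value_sqsum[ix, iy] = (var + mean**2) * count
    return surf
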