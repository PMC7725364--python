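"""Geometry of the apparent repulsion zone and blind angle.

On a mean turn-rate surface, turning-mediated repulsion appears as a
near-field region where the focal individual turns *away* from partners:
negative (clockwise) mean turn rate for partners on the left (``y > 0``),
positive for partners on the right.  The apparent zone-of-repulsion radius
is recovered by picking three points on the outer boundary of that
sign-consistent region along fixed rays and fitting the circle through them.
A rear blind zone appears as a wedge behind the focal individual, inside the
repulsion annulus, with no sign-consistent repulsion response; its angular
extent about bearing 180 deg is the apparent blind angle.

Point picking is fully algorithmic (deterministic ray scans with a relative
response threshold) so that estimates are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .averaging import InteractionSurface, antisymmetrise

__all__ = [
    "CircleFitResult",
    "BlindAngleEstimate",
    "EstimationError",
    "CollinearPointsError",
    "circumcircle",
    "repulsion_boundary_points",
    "fit_repulsion_zone",
    "estimate_blind_angle",
]

DEFAULT_RAY_BEARINGS = (90.0, 45.0, -45.0)
SIGN_THRESHOLD_FRAC = 0.05  # |mean| must exceed this fraction of max |mean|
MIN_EVIDENT_ANGLE = 30.0  # smaller rear gaps are reported as "no blind zone"


class EstimationError(RuntimeError):
    """The surface lacks the structure needed for a geometric estimate."""


class CollinearPointsError(ValueError):
    """Three collinear points do not define a circle."""


@dataclass
class CircleFitResult:
    """Circle through three boundary points of the repulsion region."""

    centre: np.ndarray
    radius: float
    points: np.ndarray  # (3, 2)


@dataclass
class BlindAngleEstimate:
    """Angular extent of the rear no-response wedge.

    ``evident`` is False when the wedge is narrower than
    ``MIN_EVIDENT_ANGLE`` — i.e. no blind zone is evident in the surface.
    """

    angle: float
    edge_points: np.ndarray  # (2, 2)
    evident: bool


def circumcircle(p1, p2, p3) -> CircleFitResult:
    """Unique circle through three distinct non-collinear points.

    Solves the perpendicular-bisector intersection as a 2x2 linear system.
    """
    pts = np.array([p1, p2, p3], dtype=float)
    a, b, c = pts
    A = 2.0 * np.array([b - a, c - a])
    rhs = np.array([b @ b - a @ a, c @ c - a @ a])
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    scale = max(np.abs(A).max(), 1.0)
    if abs(det) < 1e-12 * scale**2:
        raise CollinearPointsError(f"points {pts.tolist()} are (near-)collinear")
    centre = np.linalg.solve(A, rhs)
    radius = float(np.mean(np.hypot(*(pts - centre).T)))
    return CircleFitResult(centre=centre, radius=radius, points=pts)


def _sign_consistent(surface: InteractionSurface) -> np.ndarray:
    """Bins showing an away-from-partner turn above the response threshold."""
    mean = surface.mean
    with np.errstate(invalid="ignore"):
        threshold = SIGN_THRESHOLD_FRAC * np.nanmax(np.abs(mean))
    if not np.isfinite(threshold):
        raise EstimationError("surface has no defined bins")
    # bins exactly on the x-axis cannot testify to an away-from-partner sign
    # (left/right repulsion cancels there) and are never sign-consistent
    y = surface.y_centres[None, :]
    away = np.where(y > 0, -mean, np.where(y < 0, mean, -np.inf))
    with np.errstate(invalid="ignore"):
        mask = np.isfinite(mean) & (away > threshold)
    return _nearfield_component(surface, mask)


def _nearfield_component(surface: InteractionSurface, mask: np.ndarray) -> np.ndarray:
    """Restrict to the contiguous region closest to the focal individual.

    Group-level movement patterns can imprint spurious repulsion-signed
    patches at larger distances (e.g. behind individuals in rotating or
    polarised groups); only the connected component of sign-consistent bins
    nearest the origin is the near-field repulsion region.
    """
    if not mask.any():
        return mask
    labels, n = ndimage.label(mask)  # 4-connectivity
    if n <= 1:
        return mask
    cx, cy = np.meshgrid(surface.x_centres, surface.y_centres, indexing="ij")
    d = np.hypot(cx, cy)
    # the region is mirror-antisymmetric about the heading axis and the
    # excluded y = 0 row separates its halves: keep the component nearest
    # the origin on each side
    keep = np.zeros_like(mask)
    for half in (cy > 0, cy < 0):
        m = mask & half
        if m.any():
            keep |= labels == labels[m][np.argmin(d[m])]
    return keep


def _bin_index(surface: InteractionSurface, x: float, y: float) -> tuple[int, int] | None:
    K = surface.grid.half_n
    ix = int(round(x / surface.grid.c)) + K
    iy = int(round(y / surface.grid.c)) + K
    if 0 <= ix <= 2 * K and 0 <= iy <= 2 * K:
        return ix, iy
    return None


def repulsion_boundary_points(
    surface: InteractionSurface,
    ray_bearings: tuple[float, ...] = DEFAULT_RAY_BEARINGS,
    symmetrise: bool = True,
) -> np.ndarray:
    """Three points on the outer boundary of the near-field repulsion region.

    Each ray (bearing measured from the focal heading) is walked outward in
    bin-centre steps; the returned point is the outermost bin centre still
    inside the contiguous sign-consistent region.  By default the surface
    is first mirror-antisymmetrised, cancelling the rotation bias of pooled
    milling replicates (``symmetrise=False`` uses the raw surface).  Raises
    :class:`EstimationError` when a ray shows no repulsion-signed response.
    """
    if symmetrise:
        surface = antisymmetrise(surface)
    consistent = _sign_consistent(surface)
    defined = surface.count > 0
    g = surface.grid
    points = []
    for bearing in ray_bearings:
        ct, st = np.cos(np.radians(bearing)), np.sin(np.radians(bearing))
        last_good = None
        seen = False
        for r in np.arange(g.c, g.L + g.c / 2, g.c):
            idx = _bin_index(surface, r * ct, r * st)
            if idx is None:
                break
            if consistent[idx]:
                last_good = (
                    surface.x_centres[idx[0]],
                    surface.y_centres[idx[1]],
                )
                seen = True
            elif defined[idx] and seen:
                break  # contiguous region has ended
        if last_good is None:
            raise EstimationError(
                f"no sign-consistent repulsion response along bearing {bearing}"
            )
        points.append(last_good)
    return np.array(points)


def fit_repulsion_zone(
    surface: InteractionSurface,
    ray_bearings: tuple[float, ...] = DEFAULT_RAY_BEARINGS,
    symmetrise: bool = True,
) -> CircleFitResult:
    """Circumcircle of the three ray-scan boundary points."""
    pts = repulsion_boundary_points(surface, ray_bearings, symmetrise)
    return circumcircle(*pts)


def _has_repulsion_along(
    surface: InteractionSurface,
    consistent: np.ndarray,
    bearing: float,
    r_inner: float,
    r_outer: float,
) -> bool:
    ct, st = np.cos(np.radians(bearing)), np.sin(np.radians(bearing))
    for r in np.arange(r_inner, r_outer + surface.grid.c / 2, surface.grid.c):
        idx = _bin_index(surface, r * ct, r * st)
        if idx is not None and consistent[idx]:
            return True
    return False


def estimate_blind_angle(
    surface: InteractionSurface,
    radius: float | None = None,
    bearing_step: float = 1.0,
    inner_frac: float = 0.5,
    symmetrise: bool = True,
) -> BlindAngleEstimate:
    """Angular extent of the rear wedge lacking a repulsion response.

    Within the annulus ``[inner_frac * R, R]`` of the fitted repulsion radius
    ``R`` (or a supplied ``radius``) — the outer part of the repulsion disc,
    where turning-mediated repulsion is strongest and position correlations
    between partners distort the field least — bearings are scanned from
    dead-astern towards dead-ahead on each side; the first bearing showing a
    sign-consistent repulsion bin bounds the wedge.  For edges ``b1 > 0 >
    b2`` the blind angle is ``(180 - b1) + (180 + b2)``.  By default the
    surface is mirror-antisymmetrised first (see
    :func:`repulsion_boundary_points`).  A wedge narrower
    than ``MIN_EVIDENT_ANGLE`` yields ``evident=False`` ("no blind zone
    evident"); a wedge of zero width yields angle 0 with the same flag.
    """
    if radius is None:
        radius = fit_repulsion_zone(surface, symmetrise=symmetrise).radius
    if symmetrise:
        surface = antisymmetrise(surface)
    consistent = _sign_consistent(surface)
    r_inner = max(surface.grid.c, inner_frac * radius)

    def scan(side: int) -> float | None:
        # side=+1 scans 180 -> 0 (left), side=-1 scans -180 -> 0 (right)
        for b in np.arange(180.0, 0.0, -bearing_step):
            if _has_repulsion_along(surface, consistent, side * b, r_inner, radius):
                return side * b
        return None

    b1, b2 = scan(+1), scan(-1)
    if b1 is None or b2 is None:
        raise EstimationError("no repulsion response found on one side of the focal")
    if _has_repulsion_along(surface, consistent, 180.0, r_inner, radius):
        return BlindAngleEstimate(0.0, np.zeros((2, 2)), evident=False)
    angle = (180.0 - b1) + (180.0 + b2)
    edges = radius * np.array(
        [
            [np.cos(np.radians(b1)), np.sin(np.radians(b1))],
            [np.cos(np.radians(b2)), np.sin(np.radians(b2))],
        ]
    )
    return BlindAngleEstimate(angle, edges, evident=angle >= MIN_EVIDENT_ANGLE)
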