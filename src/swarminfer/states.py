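"""Order parameters and emergent-state classification.

Two scalar order parameters summarise a group's configuration at each time:
the polarisation ``p_group = |sum_i h_i| / N`` (1 = perfectly aligned
headings) and the angular momentum ``m_group = |sum_i rhat_ic x h_i| / N``
(1 = perfect mill), where ``rhat_ic`` is the unit vector from the group
centroid to individual ``i`` and the cross product is the scalar z-component.
Both are invariant under global rotation and translation.

Replicates are labelled from the window means (second half of the run by
default): groups that do not fragment are *parallel aligned* when
``p > 0.65`` and ``m < 0.35``, and exhibit *cohesion* when ``p < 0.35``
with ``m < 0.35`` (swarm) or ``m > 0.65`` (mill, whose sense comes from the
sign of the mean signed angular momentum).  Values falling in the threshold
gaps are left unclassified; fragmentation — more than one connected
component of the interaction-range neighbour graph persisting over the
window — overrides every other label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .kinematics import compute_kinematics
from .trajectory import Trajectory

__all__ = ["OrderSeries", "StateLabel", "order_parameters", "fragmentation", "classify", "classify_trajectory"]

P_ALIGNED, M_MILL, = 0.65, 0.65
P_LOW, M_LOW = 0.35, 0.35


@dataclass
class OrderSeries:
    """Per-time order parameters; ``m_signed`` keeps the rotation sense
    (positive = anticlockwise) that the unsigned ``m`` discards."""

    p: np.ndarray
    m: np.ndarray
    m_signed: np.ndarray

    def window_means(self, window: slice) -> tuple[float, float, float]:
        return (
            float(np.nanmean(self.p[window])),
            float(np.nanmean(self.m[window])),
            float(np.nanmean(self.m_signed[window])),
        )


@dataclass
class StateLabel:
    """Replicate-level emergent-state label with its order-parameter summary."""

    label: str  # parallel_aligned | cohesion | fragmented | unclassified
    sub_label: str  # swarm | mill_cw | mill_ccw | none
    p_mean: float
    m_mean: float
    n_components: float = 1.0


def order_parameters(traj: Trajectory) -> OrderSeries:
    """Polarisation and angular momentum per time.

    Headings come from the forward-difference unit velocities, so the series
    covers time indices ``0 .. T-2``.  An individual sitting exactly at the
    group centroid has no defined radial direction; its angular-momentum term
    is skipped with a warning.
    """
    kin = compute_kinematics(traj)
    h = kin.headings  # (T-1, N, 2)
    Tm1, N, _ = h.shape
    p = np.hypot(*np.nansum(h, axis=1).T) / N

    pos = traj.positions[:Tm1]
    centroid = pos.mean(axis=1, keepdims=True)
    r = pos - centroid
    rn = np.hypot(r[..., 0], r[..., 1])
    at_centre = rn == 0.0
    if at_centre.any():
        warnings.warn(
            "individual at the group centroid: angular-momentum term skipped",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        rx = np.where(~at_centre, r[..., 0] / rn, np.nan)
        ry = np.where(~at_centre, r[..., 1] / rn, np.nan)
    cross = rx * h[..., 1] - ry * h[..., 0]
    m_signed = np.nansum(np.where(at_centre, 0.0, cross), axis=1) / N
    m = np.abs(m_signed)
    # times where no heading is defined at all -> NaN
    all_nan = np.isnan(h[..., 0]).all(axis=1)
    p[all_nan] = np.nan
    m[all_nan] = np.nan
    m_signed[all_nan] = np.nan
    return OrderSeries(p=p, m=m, m_signed=m_signed)


def fragmentation(traj: Trajectory, link_radius: float, min_size: int = 1) -> np.ndarray:
    """Number of connected components of the neighbour graph at each time.

    Two individuals are linked when their distance is at most
    ``link_radius``; components are found on the resulting undirected graph.
    With ``min_size > 1`` only components of at least that many members are
    counted — e.g. ``min_size=2`` ignores lone stragglers, so a group only
    counts as split when it separates into multiple bona fide subgroups.
    """
    if link_radius <= 0:
        raise ValueError("link_radius must be positive")
    T = traj.n_times
    out = np.empty(T, dtype=int)
    for t in range(T):
        adj = squareform(pdist(traj.positions[t]) <= link_radius)
        n, labels = connected_components(adj, directed=False)
        if min_size <= 1:
            out[t] = n
        else:
            out[t] = int(np.sum(np.bincount(labels) >= min_size))
    return out


def _second_half(n: int) -> slice:
    return slice(n // 2, n)


def classify(
    p_mean: float,
    m_mean: float,
    m_signed_mean: float = 0.0,
    fragmented: bool = False,
) -> StateLabel:
    """Label a replicate from its window-mean order parameters."""
    if fragmented:
        return StateLabel("fragmented", "none", p_mean, m_mean)
    if p_mean > P_ALIGNED and m_mean < M_LOW:
        return StateLabel("parallel_aligned", "none", p_mean, m_mean)
    if p_mean < P_LOW and m_mean < M_LOW:
        return StateLabel("cohesion", "swarm", p_mean, m_mean)
    if p_mean < P_LOW and m_mean > M_MILL:
        sense = "mill_ccw" if m_signed_mean >= 0 else "mill_cw"
        return StateLabel("cohesion", sense, p_mean, m_mean)
    return StateLabel("unclassified", "none", p_mean, m_mean)


def classify_trajectory(
    traj: Trajectory,
    link_radius: float,
    window: slice | None = None,
) -> StateLabel:
    """Order parameters + fragmentation + thresholds for one replicate.

    ``window`` slices the order-parameter time series (default: its second
    half).  The group counts as fragmented when more than one multi-member
    subgroup (component with at least two individuals) is present in over
    half of the window frames; lone stragglers do not split a group.
    """
    series = order_parameters(traj)
    if window is None:
        window = _second_half(len(series.p))
    p_mean, m_mean, m_signed = series.window_means(window)
    n_comp = fragmentation(traj, link_radius, min_size=2)[: len(series.p)][window]
    fragmented = bool(np.mean(n_comp > 1) > 0.5)
    label = classify(p_mean, m_mean, m_signed, fragmented)
    label.n_components = float(np.mean(n_comp))
    return label
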