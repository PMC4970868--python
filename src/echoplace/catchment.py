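"""Template continuity: angular and linear catchment distances.

A template's catchment region is the neighbourhood of its reference pose over
which template dissimilarity (Mahalanobis distance) increases monotonically
with displacement — the region from which gradient descent on dissimilarity
would home onto the reference, in analogy with the catchment areas of
panoramic image differences in insect visual homing.

Two robustness rules guard against noise when scanning the dissimilarity
curve outward from zero separation: a decrease smaller than 1% of the median
pairwise dissimilarity M of the whole template set does not break the
monotone run, and the run only counts once dissimilarity has reached at least
10% of M (preventing trivial increases from registering as catchments).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .geometry import great_circle
from .scene import ConfigurationError
from .templates import TemplateSet

logger = logging.getLogger(__name__)

TOL_FRAC = 0.01  # tolerated dip, fraction of the median dissimilarity
MIN_FRAC = 0.10  # minimum rise required, fraction of the median dissimilarity


@dataclass
class CatchmentProfile:
    """Dissimilarity-vs-separation curve and its catchment distance."""

    separations: np.ndarray  # degrees (angular) or metres (linear)
    dissimilarities: np.ndarray  # mean Mahalanobis distance per separation
    catchment_distance: float
    reference: tuple[int, int]  # (position_index, direction_index); −1 = pooled


@dataclass
class CatchmentSummary:
    """Per-direction median linear catchments and the normalizing median M."""

    per_direction_median: np.ndarray
    median_pairwise_dissimilarity: float


def _distance_matrix(matrix: np.ndarray, sigma_n2: float) -> np.ndarray:
    return squareform(pdist(matrix) / np.sqrt(sigma_n2))


def median_pairwise_dissimilarity(tset: TemplateSet, sigma_n2: float) -> float:
    """Median Mahalanobis distance over all unordered template pairs (M)."""
    if len(tset) < 2:
        raise ConfigurationError("need at least two templates")
    return float(np.median(pdist(tset.matrix) / np.sqrt(sigma_n2)))


def monotone_run_length(
    dissimilarities: np.ndarray,
    M: float,
    tol_frac: float = TOL_FRAC,
    min_frac: float = MIN_FRAC,
) -> int:
    """Index of the catchment boundary in a dissimilarity-vs-separation curve.

    The curve starts at separation 0 with dissimilarity 0.  Scanning outward,
    the monotone run continues while every step's decrease (if any) is smaller
    than ``tol_frac * M``.  The catchment is the largest index within the run
    whose dissimilarity has reached at least ``min_frac * M``; 0 if that level
    is never reached inside the run.
    """
    d = np.asarray(dissimilarities, dtype=float)
    end = len(d) - 1
    for k in range(1, len(d)):
        if d[k] - d[k - 1] <= -tol_frac * M:
            end = k - 1
            break
    reached = np.flatnonzero(d[: end + 1] >= min_frac * M)
    return int(reached[-1]) if len(reached) else 0


def angular_catchment(
    tset: TemplateSet,
    position_index: int,
    sigma_n2: float,
    bin_width: float = 10.0,
    M: float | None = None,
    tol_frac: float = TOL_FRAC,
    min_frac: float = MIN_FRAC,
    strict: bool = False,
) -> CatchmentProfile:
    """Angular catchment of one position's full gaze panorama.

    All template pairs at the position are compared: their great-circle
    separation and Mahalanobis dissimilarity are computed, dissimilarities are
    averaged within ``bin_width``-degree separation bins, and the monotone-run
    rule is applied to the binned curve (prepended with the (0, 0) point).
    With ``strict=True`` the 1%/10% tolerances are disabled and any decrease
    ends the run.
    """
    sub = tset.subset(tset.position_indices == position_index)
    if len(sub) < 2:
        raise ConfigurationError("position has fewer than two templates")
    matrix = sub.matrix
    dirs = sub.directions()
    dist = _distance_matrix(matrix, sigma_n2)
    iu = np.triu_indices(len(sub), k=1)
    seps = great_circle(dirs[iu[0]], dirs[iu[1]])
    diss = dist[iu]
    if M is None:
        M = float(np.median(diss))
    nbins = int(np.ceil(seps.max() / bin_width))
    which = np.minimum((seps // bin_width).astype(int), nbins - 1)
    curve = np.full(nbins, np.nan)
    for b in range(nbins):
        sel = which == b
        if np.any(sel):
            curve[b] = diss[sel].mean()
    keep = ~np.isnan(curve)
    centres = (np.arange(nbins) + 0.5) * bin_width
    separations = np.concatenate([[0.0], centres[keep]])
    dissimilarities = np.concatenate([[0.0], curve[keep]])
    if strict:
        tol_frac = 0.0
        min_frac = 0.0
    k = monotone_run_length(dissimilarities, M, tol_frac, min_frac)
    return CatchmentProfile(
        separations=separations,
        dissimilarities=dissimilarities,
        catchment_distance=float(separations[k]),
        reference=(position_index, -1),
    )


def linear_catchment(
    tset: TemplateSet,
    direction_index: int,
    sigma_n2: float,
    M: float,
    tol_frac: float = TOL_FRAC,
    min_frac: float = MIN_FRAC,
) -> tuple[np.ndarray, float]:
    """Per-position linear catchment distances along a transect, one direction.

    For each transect position x, the dissimilarity between the template at x
    and the template at x ± Δx (same gaze direction; the two transect
    directions are averaged where both exist) is evaluated as a function of
    |Δx|, and the 1%/10% monotone-run rule applied.  Returns the per-position
    catchment distances and their median (the per-direction summary).
    """
    if tset.design is None or tset.design.design_name != "transect":
        raise ConfigurationError("linear catchment requires a transect TemplateSet")
    spacing = tset.design.spacing
    sub = tset.subset(tset.direction_indices == direction_index)
    if len(sub) < 3:
        raise ConfigurationError("transect must contain at least three positions")
    order = np.argsort(sub.position_indices)
    matrix = sub.matrix[order]
    n = len(matrix)
    dist = _distance_matrix(matrix, sigma_n2)
    catchments = np.zeros(n)
    for x in range(n):
        max_lag = max(x, n - 1 - x)
        curve = np.zeros(max_lag + 1)
        for lag in range(1, max_lag + 1):
            vals = []
            if x - lag >= 0:
                vals.append(dist[x, x - lag])
            if x + lag < n:
                vals.append(dist[x, x + lag])
            curve[lag] = np.mean(vals)
        k = monotone_run_length(curve, M, tol_frac, min_frac)
        catchments[x] = k * spacing
    return catchments, float(np.median(catchments))


def linear_catchment_summary(
    tset: TemplateSet,
    sigma_n2: float,
    M: float | None = None,
    tol_frac: float = TOL_FRAC,
    min_frac: float = MIN_FRAC,
) -> tuple[CatchmentSummary, np.ndarray]:
    """Median linear catchment for every gaze direction of a transect set.

    Returns the summary and the full (n_directions, n_positions) catchment
    matrix (position-sorted), for pairing with classification results.
    """
    if M is None:
        M = median_pairwise_dissimilarity(tset, sigma_n2)
    d_indices = np.unique(tset.direction_indices)
    n_pos = len(np.unique(tset.position_indices))
    medians = np.zeros(len(d_indices))
    per_pos = np.zeros((len(d_indices), n_pos))
    for j, d in enumerate(d_indices):
        per_pos[j], medians[j] = linear_catchment(
            tset, int(d), sigma_n2, M, tol_frac, min_frac
        )
    return CatchmentSummary(medians, float(M)), per_pos


@dataclass
class TradeoffReport:
    """Classifiability-vs-continuity trade-off statistics."""

    rho: float  # Spearman rank correlation between P_c and catchment
    rho_ci: tuple[float, float]  # 95% CI (Fisher z)
    rho_p: float
    ranksum_z: float  # two-site Wilcoxon rank-sum statistic (catchments)
    ranksum_p: float
    applicable: bool = True


def tradeoff_report(
    pc: np.ndarray,
    catchments: np.ndarray,
    site_labels: np.ndarray | None = None,
) -> TradeoffReport:
    """Rank correlation between P_c and linear catchment distance, plus an
    optional two-site Wilcoxon rank-sum comparison of the catchments.

    Degenerate inputs (constant P_c or catchment) yield a report flagged
    not-applicable rather than an error.
    """
    pc = np.asarray(pc, dtype=float)
    catchments = np.asarray(catchments, dtype=float)
    if np.ptp(pc) == 0 or np.ptp(catchments) == 0:
        z, p = _ranksum(catchments, site_labels)
        return TradeoffReport(np.nan, (np.nan, np.nan), np.nan, z, p, applicable=False)
    rho, pval = stats.spearmanr(pc, catchments)
    n = len(pc)
    if n > 3 and abs(rho) < 1:
        zr = np.arctanh(rho)
        se = 1.0 / np.sqrt(n - 3)
        ci = (float(np.tanh(zr - 1.959964 * se)), float(np.tanh(zr + 1.959964 * se)))
    else:
        ci = (np.nan, np.nan)
    z, p = _ranksum(catchments, site_labels)
    return TradeoffReport(float(rho), ci, float(pval), z, p)


def _ranksum(values: np.ndarray, labels: np.ndarray | None) -> tuple[float, float]:
    if labels is None:
        return np.nan, np.nan
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        return np.nan, np.nan
    a = values[labels == groups[0]]
    b = values[labels == groups[1]]
    res = stats.ranksums(a, b)
    return float(res.statistic), float(res.pvalue)
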