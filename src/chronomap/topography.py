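"""Quantification of the spatial progression of duration-preference maps.

Three indexes summarize whether labels progress systematically between the
two borders of a map:

* the weighted relative distance (wRD) of each duration-selective cluster,
  ``wRD = sum_i w_i * RD_i / Nvd`` with per-voxel weight ``w_i = Nnbrs_i /
  Nvd`` (same-label face-adjacent neighbors over cluster size) and
  ``RD_i = D1_i / TD`` (distance from the reference border over total
  border-to-border depth), plus the slope of wRD across duration rank and a
  one-sided signed-rank test of a negative slope across subjects;
* the preferred-duration profile: majority label in 1.5-mm planes along the
  progression axis, pooled over subjects and reduced by averaging every
  five consecutive values;
* weighted centroids: per-cluster centers of mass with integer weights
  equal to each voxel's same-label neighbor count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .maps import LabelMap

DEFAULT_BIN_WIDTH_MM = 1.5
DEFAULT_SPLIT_SECONDS = 1.0


@dataclass(frozen=True)
class BorderGeometry:
    """Planar borders of a map along its progression axis (mm).

    ``d1_border`` is the reference border (posterior by the package's
    convention); ``TD`` is the border-to-border depth.
    """

    axis: int
    d1_border: float
    d2_border: float
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        if self.d1_border == self.d2_border:
            raise ValueError("borders must be distinct")

    @property
    def td(self) -> float:
        return abs(self.d2_border - self.d1_border)


def neighbor_counts(mask: np.ndarray, connectivity: str = "face") -> np.ndarray:
    """Per-voxel count of same-label neighbors (self excluded).

    Face adjacency: 4 neighbors on a 2-D sheet, 6 on a 3-D lattice.
    """
    if connectivity != "face":
        raise ValueError("only face adjacency is implemented")
    mask = np.asarray(mask, bool)
    counts = np.zeros(mask.shape, dtype=int)
    for axis in range(mask.ndim):
        lo = [slice(None)] * mask.ndim
        hi = [slice(None)] * mask.ndim
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        both = mask[tuple(lo)] & mask[tuple(hi)]
        counts[tuple(lo)] += both
        counts[tuple(hi)] += both
    counts[~mask] = 0
    return counts


def vertex_weights(labels: LabelMap, label: float,
                   include_self: bool = False) -> np.ndarray:
    """Weights w = Nnbrs / Nvd over the full lattice (0 off the cluster)."""
    mask = labels.mask_of(label)
    nvd = int(mask.sum())
    if nvd == 0:
        raise ValueError(f"label {label} absent from map")
    nbrs = neighbor_counts(mask).astype(float)
    if include_self:
        nbrs[mask] += 1
    return np.where(mask, nbrs / nvd, 0.0)


def weighted_relative_distance(labels: LabelMap, geom: BorderGeometry,
                               label: float,
                               include_self: bool = False) -> float:
    """wRD of one duration-selective cluster from the reference border."""
    mask = labels.mask_of(label)
    w = vertex_weights(labels, label, include_self=include_self)
    coord = np.indices(labels.shape)[geom.axis] * labels.voxel_size
    lo, hi = sorted((geom.d1_border, geom.d2_border))
    outside = mask & ((coord < lo - 1e-9) | (coord > hi + 1e-9))
    if outside.any():
        raise ValueError(f"voxel {tuple(np.argwhere(outside)[0])} lies "
                         "outside the map borders")
    rd = np.abs(coord - geom.d1_border) / geom.td
    nvd = int(mask.sum())
    return float(np.sum(w[mask] * rd[mask]) / nvd)


def wrd_by_label(labels: LabelMap, geom: BorderGeometry,
                 include_self: bool = False) -> dict[float, float]:
    """wRD for every duration present in the map, keyed by duration."""
    return {float(d): weighted_relative_distance(labels, geom, d,
                                                 include_self=include_self)
            for d in labels.present_labels()}


@dataclass
class WRDSlopes:
    slope_rank: float | None          # wRD change per duration rank
    slope_per_second: float | None
    sub_slope: float | None = None    # durations <= split
    supra_slope: float | None = None  # durations > split
    n_points: int = 0


def _lsq_slope(x: np.ndarray, y: np.ndarray) -> float | None:
    if len(x) < 2:
        return None
    return float(np.polyfit(x, y, 1)[0])


def fit_wrd_slope(wrd_pairs, split_at: float | None = None) -> WRDSlopes:
    """Least-squares slope of wRD against duration rank (1..k).

    ``wrd_pairs`` is an iterable of (duration, wRD).  With ``split_at``,
    separate slopes are fitted for durations <= split and > split (the
    sub-/supra-second dissociation).  Segments with fewer than two points
    yield None.
    """
    pairs = sorted((float(d), float(v)) for d, v in wrd_pairs)
    durs = np.array([p[0] for p in pairs])
    vals = np.array([p[1] for p in pairs])
    ranks = np.arange(1, len(durs) + 1, dtype=float)
    out = WRDSlopes(slope_rank=_lsq_slope(ranks, vals),
                    slope_per_second=_lsq_slope(durs, vals),
                    n_points=len(durs))
    if split_at is not None:
        sub = durs <= split_at
        out.sub_slope = _lsq_slope(ranks[sub], vals[sub])
        out.supra_slope = _lsq_slope(ranks[~sub], vals[~sub])
    return out


@dataclass
class SlopeTest:
    p_value: float
    statistic: float
    n_used: int
    n_zeros_dropped: int
    alternative: str = "less"


def test_slopes(slopes, alternative: str = "less") -> SlopeTest:
    """One-sample Wilcoxon signed-rank test of the subject slopes against 0.

    ``alternative='less'`` tests for a negative slope (map progression).
    Exact null enumeration is used for n <= 15; zero slopes are dropped
    and reported.
    """
    slopes = np.asarray(list(slopes), float)
    if len(slopes) < 5:
        raise ValueError("need at least 5 subject slopes")
    nonzero = slopes[slopes != 0]
    n_zeros = len(slopes) - len(nonzero)
    method = "exact" if len(nonzero) <= 15 else "auto"
    try:
        res = stats.wilcoxon(nonzero, alternative=alternative, method=method)
    except ValueError:
        res = stats.wilcoxon(nonzero, alternative=alternative, method="auto")
    return SlopeTest(p_value=float(res.pvalue), statistic=float(res.statistic),
                     n_used=len(nonzero), n_zeros_dropped=n_zeros,
                     alternative=alternative)


def preferred_duration_profile(labelmaps, geoms,
                               bin_width: float = DEFAULT_BIN_WIDTH_MM,
                               reduce_every: int = 5
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Pooled preferred-duration profile along the progression axis.

    Per subject, voxels are binned into parallel planes of ``bin_width``
    mm; each plane's preferred duration is the majority label (ties toward
    the shorter duration) and its position the bin-center distance from
    the reference border divided by TD.  All subjects' (relative distance,
    preferred duration) pairs are pooled, sorted by distance, and reduced
    by averaging every ``reduce_every`` consecutive values.

    Returns ``(relative_distance, preferred_duration)`` arrays.
    """
    if isinstance(labelmaps, LabelMap):
        labelmaps, geoms = [labelmaps], [geoms]
    pooled: list[tuple[float, float]] = []
    for labels, geom in zip(labelmaps, geoms):
        coord = np.indices(labels.shape)[geom.axis] * labels.voxel_size
        lo, hi = sorted((geom.d1_border, geom.d2_border))
        edges = np.arange(lo, hi + bin_width, bin_width)
        for b0 in edges[:-1] if len(edges) > 1 else [lo]:
            b1 = b0 + bin_width
            sel = labels.labeled & (coord >= b0 - 1e-9) & (coord < b1 - 1e-9)
            if not sel.any():
                continue
            vals, counts = np.unique(labels.label[sel], return_counts=True)
            pd_bin = float(vals[counts == counts.max()].min())  # ties -> shorter
            center = min(b0 + bin_width / 2, hi)
            rd = abs(center - geom.d1_border) / geom.td
            pooled.append((min(rd, 1.0), pd_bin))
    if not pooled:
        raise ValueError("no labeled voxels fall inside the map borders")
    pooled.sort()
    rd = np.array([p[0] for p in pooled])
    pd_ = np.array([p[1] for p in pooled])
    n_groups = int(np.ceil(len(rd) / reduce_every))
    rd_out = np.array([rd[i * reduce_every:(i + 1) * reduce_every].mean()
                       for i in range(n_groups)])
    pd_out = np.array([pd_[i * reduce_every:(i + 1) * reduce_every].mean()
                       for i in range(n_groups)])
    return rd_out, pd_out


@dataclass
class Centroid:
    position_mm: np.ndarray
    fallback_unweighted: bool = False


def weighted_centroids(labels: LabelMap) -> dict[float, Centroid]:
    """Neighbor-count-weighted center of mass of every cluster (mm).

    Each voxel's position counts as many times as its same-label neighbor
    count; if every voxel of a label is isolated (all weights zero), the
    plain mean position is returned and flagged.
    """
    present = labels.present_labels()
    if len(present) == 0:
        raise ValueError("label map is empty")
    out: dict[float, Centroid] = {}
    for dur in present:
        mask = labels.mask_of(dur)
        coords = np.argwhere(mask).astype(float) * labels.voxel_size
        n = neighbor_counts(mask)[mask].astype(float)
        if n.sum() == 0:
            out[float(dur)] = Centroid(coords.mean(axis=0), True)
        else:
            out[float(dur)] = Centroid((coords * n[:, None]).sum(axis=0)
                                       / n.sum(), False)
    return out


@dataclass
class MapComparison:
    centroid_border_distance_a: dict[float, float]
    centroid_border_distance_b: dict[float, float]
    extent_a: float
    extent_b: float
    label_overlap: dict[float, float]
    cluster_proportions_a: dict[float, float]
    cluster_proportions_b: dict[float, float]
    overlap_defined: bool = True


def _cluster_proportions(labels: LabelMap) -> dict[float, float]:
    total = int(labels.labeled.sum())
    return {float(d): labels.count(d) / total for d in labels.present_labels()}


def compare_maps(map_a: LabelMap, geom_a: BorderGeometry,
                 map_b: LabelMap, geom_b: BorderGeometry) -> MapComparison:
    """Compare two duration-preference maps of the same region.

    Reports per-label centroid distances from each map's reference border
    (mm along the progression axis), the two map extents (TD), the
    per-label overlap proportion |same label in both| / |that label in
    either| (maps must share a lattice), and per-label cluster-size
    proportions.
    """
    cents_a = weighted_centroids(map_a)
    cents_b = weighted_centroids(map_b)
    dist_a = {d: abs(c.position_mm[geom_a.axis] - geom_a.d1_border)
              for d, c in cents_a.items()}
    dist_b = {d: abs(c.position_mm[geom_b.axis] - geom_b.d1_border)
              for d, c in cents_b.items()}
    shared = sorted(set(cents_a) & set(cents_b))
    overlap: dict[float, float] = {}
    defined = bool(shared)
    if shared and map_a.shape == map_b.shape:
        for d in shared:
            ma, mb = map_a.mask_of(d), map_b.mask_of(d)
            union = int((ma | mb).sum())
            overlap[float(d)] = float((ma & mb).sum() / union) if union else 0.0
    elif shared:
        raise ValueError("overlap requires maps on the same lattice")
    return MapComparison(
        centroid_border_distance_a=dist_a, centroid_border_distance_b=dist_b,
        extent_a=geom_a.td, extent_b=geom_b.td, label_overlap=overlap,
        cluster_proportions_a=_cluster_proportions(map_a),
        cluster_proportions_b=_cluster_proportions(map_b),
        overlap_defined=defined)


@dataclass
class BehaviorCorrelation:
    tau: float | None
    p_value: float | None
    flagged: str | None = None


def correlate_slope_behavior(slopes, accuracy, cv=None
                             ) -> dict[str, BehaviorCorrelation]:
    """Kendall tau-b between per-subject wRD slopes and behavioral indexes
    (accuracy, and optionally the coefficient of variation)."""
    slopes = np.asarray(list(slopes), float)
    if len(slopes) < 5:
        raise ValueError("need at least 5 paired observations")
    out: dict[str, BehaviorCorrelation] = {}
    for name, values in (("accuracy", accuracy), ("cv", cv)):
        if values is None:
            continue
        values = np.asarray(list(values), float)
        if len(values) != len(slopes):
            raise ValueError(f"{name} length does not match slopes")
        if np.all(values == values[0]) or np.all(slopes == slopes[0]):
            out[name] = BehaviorCorrelation(None, None, "constant input")
            continue
        tau, p = stats.kendalltau(slopes, values)
        out[name] = BehaviorCorrelation(float(tau), float(p))
    return out


@dataclass
class TopographyReport:
    """Serializable bundle of the three spatial indexes plus tests."""

    wrd: dict[float, float]
    slopes: WRDSlopes
    pd_profile_rd: list[float]
    pd_profile_pd: list[float]
    centroids: dict[float, list[float]]
    slope_test: SlopeTest | None = None
    behavior: dict[str, BehaviorCorrelation] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["wrd"] = {f"{k:g}": v for k, v in self.wrd.items()}
        d["centroids"] = {f"{k:g}": list(map(float, v))
                          for k, v in self.centroids.items()}
        return d


def quantify_topography(labels: LabelMap, geom: BorderGeometry,
                        split_at: float | None = None,
                        bin_width: float = DEFAULT_BIN_WIDTH_MM
                        ) -> TopographyReport:
    """All three spatial indexes for one subject's label map."""
    wrd = wrd_by_label(labels, geom)
    slopes = fit_wrd_slope(wrd.items(), split_at=split_at)
    rd, pd_ = preferred_duration_profile(labels, geom, bin_width=bin_width)
    cents = weighted_centroids(labels)
    return TopographyReport(
        wrd=wrd, slopes=slopes, pd_profile_rd=list(map(float, rd)),
        pd_profile_pd=list(map(float, pd_)),
        centroids={d: c.position_mm for d, c in cents.items()})
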