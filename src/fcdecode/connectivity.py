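"""Connectivity mapping and cluster-corrected group inference.

Global connectivity ("r score") at a voxel is the self-excluded mean of its
Pearson correlations with all other in-brain voxels, averaged in Fisher-z
space and back-transformed to an r. Seed-based connectivity correlates each
voxel with the mean time course of a seed region. Group comparisons use
voxelwise two-sample pooled-variance t statistics on Fisher-z maps, with
family-wise-error cluster correction by permutation of group labels against
the null distribution of the maximum suprathreshold cluster extent
(6-connectivity, positive and negative clusters formed separately).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from fcdecode.types import BoldSeries, ConnectivityMap, Parcellation, SeedSpec

logger = logging.getLogger(__name__)

_R_CLIP = 1.0 - 1e-7
#: faces-only neighbourhood for cluster formation
_STRUCTURE = ndimage.generate_binary_structure(3, 1)


@dataclass
class Cluster:
    """One suprathreshold cluster with its permutation-corrected p-value."""

    cluster_id: int
    voxels: np.ndarray  # boolean 3D mask
    extent: int
    peak_t: float
    sign: int
    corrected_p: float


@dataclass
class GroupComparisonResult:
    """Voxelwise t map plus the cluster table from permutation FWE correction."""

    t_map: np.ndarray
    df: int
    cluster_threshold_t: float
    clusters: list[Cluster]
    alpha_fwe: float
    n_permutations: int
    exhaustive: bool

    def surviving_mask(self) -> np.ndarray:
        """Union of voxels in clusters with corrected p <= alpha."""
        out = np.zeros(self.t_map.shape, dtype=bool)
        for c in self.clusters:
            if c.corrected_p <= self.alpha_fwe:
                out |= c.voxels
        return out

    def cluster_table(self) -> pd.DataFrame:
        rows = [
            {
                "cluster_id": c.cluster_id,
                "extent_voxels": c.extent,
                "peak_t": c.peak_t,
                "sign": c.sign,
                "corrected_p": c.corrected_p,
                "surviving": c.corrected_p <= self.alpha_fwe,
            }
            for c in self.clusters
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "cluster_id",
                "extent_voxels",
                "peak_t",
                "sign",
                "corrected_p",
                "surviving",
            ],
        )


def _standardize_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows z-scored by population SD; returns (z, valid) with valid = var > 0."""
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    valid = (sd > 0).ravel()
    z = np.zeros_like(x)
    z[valid] = (x[valid] - mean[valid]) / sd[valid]
    return z, valid


def global_connectivity_map(series: BoldSeries) -> ConnectivityMap:
    """Self-excluded mean correlation of each voxel with all other voxels.

    Correlations are averaged in Fisher-z space and back-transformed, so the
    map reports a variance-stabilized mean r. Zero-variance voxels are
    excluded from both the target and reference sets and logged.
    """
    mask = series.brain_mask
    vox = series.data[mask]  # V x t
    if vox.shape[0] < 2:
        raise ValueError("global connectivity needs at least 2 in-mask voxels")
    z, valid = _standardize_rows(vox)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.warning("excluding %d zero-variance voxels from connectivity", n_dropped)
    zv = z[valid]
    n_valid = zv.shape[0]
    if n_valid < 2:
        raise ValueError("fewer than 2 voxels with nonzero variance")
    t = vox.shape[1]
    corr = (zv @ zv.T) / t
    np.clip(corr, -_R_CLIP, _R_CLIP, out=corr)
    fz = np.arctanh(corr)
    np.fill_diagonal(fz, 0.0)
    mean_z = fz.sum(axis=1) / (n_valid - 1)
    r_score = np.tanh(mean_z)

    values = np.zeros(series.spatial_shape)
    inmask = np.zeros(vox.shape[0])
    inmask[valid] = r_score
    values[mask] = inmask
    return ConnectivityMap(values=values, metric="r", subject_id="", mask=mask)


def seed_connectivity_map(series: BoldSeries, seed: SeedSpec) -> ConnectivityMap:
    """Pearson correlation of every in-mask voxel with the seed-mean course."""
    seed_mask = seed.mask & series.brain_mask
    if not seed_mask.any():
        raise ValueError(f"seed {seed.name!r} does not intersect the brain mask")
    seed_course = series.data[seed_mask].mean(axis=0)
    if seed_course.std() == 0:
        raise ValueError(f"seed {seed.name!r} mean signal is constant")
    sc = (seed_course - seed_course.mean()) / seed_course.std()

    mask = series.brain_mask
    vox = series.data[mask]
    z, valid = _standardize_rows(vox)
    t = vox.shape[1]
    r = (z @ sc) / t
    r[~valid] = 0.0
    values = np.zeros(series.spatial_shape)
    values[mask] = r
    return ConnectivityMap(
        values=values, metric="r", subject_id="", seed_name=seed.name, mask=mask
    )


def fisher_z(cmap: ConnectivityMap) -> ConnectivityMap:
    """Variance-stabilizing transform z = atanh(r); clips |r| at 1 - 1e-7."""
    if cmap.metric != "r":
        raise ValueError("fisher_z expects a map with metric 'r'")
    vals = cmap.values
    if np.any(np.abs(vals) >= 1.0):
        warnings.warn("clipping |r| >= 1 before Fisher z-transform", stacklevel=2)
    z = np.arctanh(np.clip(vals, -_R_CLIP, _R_CLIP))
    return ConnectivityMap(
        values=z,
        metric="fisher_z",
        subject_id=cmap.subject_id,
        seed_name=cmap.seed_name,
        mask=cmap.mask,
    )


def _stack_maps(maps: list[ConnectivityMap]) -> np.ndarray:
    shapes = {m.values.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError(f"maps are on mismatched grids: {sorted(shapes)}")
    return np.stack([m.values for m in maps], axis=0)


def _pooled_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sample pooled-variance t, vectorized over trailing axes."""
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    ssa = ((a - ma) ** 2).sum(axis=0)
    ssb = ((b - mb) ** 2).sum(axis=0)
    sp2 = (ssa + ssb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (ma - mb) / denom, 0.0)
    return t


def group_ttest_map(
    maps_a: list[ConnectivityMap], maps_b: list[ConnectivityMap]
) -> tuple[np.ndarray, int]:
    """Voxelwise two-sample t map (positive where group A exceeds group B)."""
    if len(maps_a) < 2 or len(maps_b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    for m in maps_a + maps_b:
        if m.metric != "fisher_z":
            raise ValueError("group t-test expects Fisher-z maps")
    a = _stack_maps(maps_a)
    b = _stack_maps(maps_b)
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("groups are on mismatched grids")
    return _pooled_t(a, b), a.shape[0] + b.shape[0] - 2


def critical_t(df: int, alpha: float = 0.05) -> float:
    """Two-sided critical value of Student's t (cluster-defining threshold)."""
    return float(stats.t.ppf(1.0 - alpha / 2.0, df))


def _max_cluster_extent(t_map: np.ndarray, threshold: float, mask: np.ndarray) -> int:
    best = 0
    for supra in ((t_map > threshold) & mask, (t_map < -threshold) & mask):
        if supra.any():
            lab, n = ndimage.label(supra, structure=_STRUCTURE)
            if n:
                best = max(best, int(np.bincount(lab.ravel())[1:].max()))
    return best


def cluster_correct_fwe(
    t_map: np.ndarray,
    df: int,
    cluster_threshold_t: float,
    subject_maps: list[ConnectivityMap],
    group_labels: list[str],
    alpha: float = 0.05,
    n_perm: int = 1000,
    rng_seed: int = 0,
    mask: np.ndarray | None = None,
) -> GroupComparisonResult:
    """Permutation FWE correction of suprathreshold clusters.

    Suprathreshold voxels (|t| > threshold, positive and negative separately)
    are grouped under 6-connectivity; each observed cluster's corrected p is
    the proportion of group-label permutations whose maximum cluster extent
    reaches its extent (add-one correction in numerator and denominator).
    When the number of distinct relabelings does not exceed ``n_perm`` the
    null is enumerated exhaustively instead of sampled.
    """
    if cluster_threshold_t <= 0:
        raise ValueError("cluster threshold must be positive")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    labels = np.asarray(group_labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("exactly two group labels required")
    stacked = _stack_maps(subject_maps)
    n = stacked.shape[0]
    if n != len(labels):
        raise ValueError("one label per subject map required")
    if mask is None:
        mask = subject_maps[0].mask
        mask = np.ones(t_map.shape, dtype=bool) if mask is None else mask

    idx_a = np.flatnonzero(labels == uniq[0])
    n_a = idx_a.size

    # observed clusters
    clusters: list[Cluster] = []
    cid = 0
    observed: list[tuple[np.ndarray, int, float, int]] = []
    for sign, supra in (
        (1, (t_map > cluster_threshold_t) & mask),
        (-1, (t_map < -cluster_threshold_t) & mask),
    ):
        lab, n_clust = ndimage.label(supra, structure=_STRUCTURE)
        for k in range(1, n_clust + 1):
            vox = lab == k
            extent = int(vox.sum())
            peak = float(np.abs(t_map[vox]).max())
            observed.append((vox, extent, peak, sign))

    from math import comb

    n_distinct = comb(n, n_a)
    exhaustive = n_distinct <= n_perm
    if exhaustive:
        assignments = [np.array(c) for c in combinations(range(n), n_a)]
    else:
        rng = np.random.default_rng(rng_seed)
        assignments = [rng.permutation(n)[:n_a] for _ in range(n_perm)]

    null_max = np.empty(len(assignments), dtype=int)
    all_idx = np.arange(n)
    for i, a_idx in enumerate(assignments):
        b_idx = np.setdiff1d(all_idx, a_idx, assume_unique=True)
        t_perm = _pooled_t(stacked[a_idx], stacked[b_idx])
        null_max[i] = _max_cluster_extent(t_perm, cluster_threshold_t, mask)

    m = len(assignments)
    for vox, extent, peak, sign in sorted(observed, key=lambda o: -o[1]):
        cid += 1
        if exhaustive:
            p = float((null_max >= extent).sum()) / m
        else:
            p = (1.0 + float((null_max >= extent).sum())) / (1.0 + m)
        clusters.append(
            Cluster(
                cluster_id=cid,
                voxels=vox,
                extent=extent,
                peak_t=peak,
                sign=sign,
                corrected_p=p,
            )
        )

    return GroupComparisonResult(
        t_map=t_map,
        df=df,
        cluster_threshold_t=cluster_threshold_t,
        clusters=clusters,
        alpha_fwe=alpha,
        n_permutations=m,
        exhaustive=exhaustive,
    )


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def regional_connectivity_strength(
    cmap: ConnectivityMap, parcellation: Parcellation, regions: list[int]
) -> pd.DataFrame:
    """Mean map value per region, over the region's in-mask voxels."""
    mask = cmap.mask if cmap.mask is not None else np.ones(cmap.values.shape, dtype=bool)
    rows = []
    for lab in regions:
        region_mask = parcellation.mask_of(lab) & mask
        if not region_mask.any():
            raise ValueError(f"region {lab} has no in-mask voxels")
        rows.append({"region": lab, "mean_value": float(cmap.values[region_mask].mean())})
    return pd.DataFrame(rows, columns=["region", "mean_value"])
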