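"""Implicit shape statistics: signed distances, voxelwise permutation testing
and surface-of-interest (SOI) extraction.

The two-group comparison works on the signed-distance representation of the
aligned masks.  At every voxel of a narrow band around the template surface a
pooled two-sample t statistic is computed, and family-wise error is controlled
with the single-step max-statistic permutation scheme: each relabelling of the
group assignments yields the maximum |t| over the band, and the corrected
p-value of a voxel is the fraction of relabellings whose maximum reaches its
observed |t|.  When the number of distinct relabellings does not exceed the
requested permutation count the enumeration is exhaustive (permutation-exact
p-values); otherwise relabellings are sampled with a mandatory seed.

Significant voxels are then projected to a marching-cubes template surface:
a vertex belongs to the SOI iff some voxel within ``band_mm`` of it has a
corrected p-value below alpha.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from math import comb

import numpy as np
import trimesh
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure

from .volumes import BinaryMask, EmptyForegroundError, Vec3, VolumeError

logger = logging.getLogger("atriashape")


class StatsError(ValueError):
    """Invalid input to the statistical comparison."""


@dataclass
class SignedDistanceVolume:
    """Euclidean signed distance to the mask boundary, in mm; negative inside."""

    data: np.ndarray
    spacing: Vec3
    origin: Vec3 = (0.0, 0.0, 0.0)


@dataclass
class StatMap:
    """Voxelwise t field with FWER-corrected permutation p-values.

    Outside the analysis region t is 0 and p_corr is 1.
    """

    t: np.ndarray
    p_corr: np.ndarray
    region: np.ndarray
    spacing: Vec3
    origin: Vec3
    alpha: float
    n_perm: int
    exhaustive: bool
    max_t_null: np.ndarray = field(repr=False, default=None)


@dataclass
class SurfaceMesh:
    """Triangulated closed surface in template world coordinates (mm)."""

    vertices: np.ndarray
    faces: np.ndarray
    channels: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    @property
    def area(self) -> float:
        return float(self.to_trimesh().area)

    @property
    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)


@dataclass
class SOIMap:
    """Partition of template-mesh vertices into SOI and its complement cSOI."""

    soi_vertices: np.ndarray
    csoi_vertices: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        self.soi_vertices = np.asarray(self.soi_vertices, dtype=int)
        self.csoi_vertices = np.asarray(self.csoi_vertices, dtype=int)
        if np.intersect1d(self.soi_vertices, self.csoi_vertices).size:
            raise StatsError("SOI and cSOI overlap")


def signed_distance(mask: BinaryMask) -> SignedDistanceVolume:
    """Euclidean signed distance (mm) of a mask: negative inside, positive outside."""
    fg = mask.data.astype(bool)
    if not fg.any():
        raise EmptyForegroundError("cannot compute signed distance of an empty mask")
    outside = ndimage.distance_transform_edt(~fg, sampling=mask.spacing)
    inside = ndimage.distance_transform_edt(fg, sampling=mask.spacing)
    return SignedDistanceVolume(
        (outside - inside).astype(np.float64), mask.spacing, mask.origin
    )


def _stack_values(sdf_stack, region: np.ndarray | None):
    """Flatten a stack of SDVs (or arrays) to an (n_members, n_voxels) matrix."""
    arrays = [s.data if isinstance(s, SignedDistanceVolume) else np.asarray(s)
              for s in sdf_stack]
    shape = arrays[0].shape
    for a in arrays:
        if a.shape != shape:
            raise StatsError("all members must share a common grid")
    if region is None:
        region = np.ones(shape, dtype=bool)
    flat = region.ravel()
    X = np.stack([a.ravel()[flat] for a in arrays])
    return X, region


def _pooled_t(X: np.ndarray, g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """Two-sample pooled-variance t per column; zero pooled variance -> t = 0."""
    n1, n2 = len(g1), len(g2)
    m1 = X[g1].mean(axis=0)
    m2 = X[g2].mean(axis=0)
    v1 = X[g1].var(axis=0, ddof=1)
    v2 = X[g2].var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / se
    return np.where(se > 0, t, 0.0)


def voxel_tstat(sdf_stack, labels, region: np.ndarray | None = None) -> np.ndarray:
    """Voxelwise pooled two-sample t field (group 1 minus group 0).

    Returns a full-grid array; voxels outside ``region`` are 0.
    """
    labels = np.asarray(labels)
    X, region = _stack_values(sdf_stack, region)
    g1 = np.flatnonzero(labels == 1)
    g0 = np.flatnonzero(labels == 0)
    if len(g1) < 2 or len(g0) < 2:
        raise StatsError("need >= 2 members per group for a t-test")
    t = np.zeros(region.shape, dtype=np.float64)
    t.ravel()[region.ravel()] = _pooled_t(X, g1, g0)
    return t


def _max_abs_t_for_assignments(X, X2, assignments, n1, n2, chunk=128):
    """Max |t| over voxels for each row of a boolean assignment matrix.

    Uses sufficient statistics so each permutation costs two matrix products.
    """
    n = n1 + n2
    S = X.sum(axis=0)
    Q = X2.sum(axis=0)
    out = np.empty(len(assignments))
    for start in range(0, len(assignments), chunk):
        G = assignments[start : start + chunk].astype(np.float64)
        s1 = G @ X
        q1 = G @ X2
        s2 = S - s1
        q2 = Q - q1
        m1 = s1 / n1
        m2 = s2 / n2
        ss1 = q1 - s1 * m1
        ss2 = q2 - s2 * m2
        sp2 = (ss1 + ss2) / (n - 2)
        # rounding can push tiny variances negative
        np.clip(sp2, 0.0, None, out=sp2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.abs(m1 - m2) / se
        t[se == 0] = 0.0
        out[start : start + len(G)] = t.max(axis=1)
    return out


def permutation_maxT(
    sdf_stack,
    labels,
    n_perm: int = 5000,
    seed: int | None = None,
    alpha: float = 0.05,
    region: np.ndarray | None = None,
    spacing: Vec3 = (1.0, 1.0, 1.0),
    origin: Vec3 = (0.0, 0.0, 0.0),
) -> StatMap:
    """Voxelwise two-sided permutation test with maxT FWER correction.

    ``region`` restricts the analysis (and the max statistic) to a boolean
    voxel subset, typically a narrow band around the template surface.  When
    C(n, n1) <= n_perm all distinct relabellings are enumerated and p-values
    are permutation-exact (p = #{max|t| >= |t_obs|} / N); otherwise ``n_perm``
    relabellings are sampled with the mandatory ``seed`` and the +1 convention
    p = (1 + #{...}) / (n_perm + 1) keeps p > 0.
    """
    labels = np.asarray(labels)
    if n_perm < 1:
        raise StatsError(f"n_perm must be >= 1, got {n_perm}")
    if isinstance(sdf_stack[0], SignedDistanceVolume):
        spacing = sdf_stack[0].spacing
        origin = sdf_stack[0].origin
    X, region = _stack_values(sdf_stack, region)
    g1 = np.flatnonzero(labels == 1)
    g0 = np.flatnonzero(labels == 0)
    if len(g1) == 0 or len(g0) == 0:
        raise StatsError("both groups must be nonempty")
    if len(g1) < 2 or len(g0) < 2:
        raise StatsError("need >= 2 members per group")
    n, n1 = len(labels), len(g1)
    t_obs = _pooled_t(X, g1, g0)
    X2 = X * X

    n_distinct = comb(n, n1)
    exhaustive = n_distinct <= n_perm
    if exhaustive:
        assign = np.zeros((n_distinct, n), dtype=bool)
        for r, combo in enumerate(itertools.combinations(range(n), n1)):
            assign[r, list(combo)] = True
        denom = n_distinct
        extra = 0
    else:
        if seed is None:
            raise StatsError("seed is required for sampled permutations")
        rng = np.random.default_rng(seed)
        assign = np.zeros((n_perm, n), dtype=bool)
        for r in range(n_perm):
            assign[r, rng.permutation(n)[:n1]] = True
        denom = n_perm + 1
        extra = 1  # +1 convention: observed labelling counted in both sides

    max_null = _max_abs_t_for_assignments(X, X2, assign, n1, n - n1)
    max_sorted = np.sort(max_null)
    abs_t = np.abs(t_obs)
    n_ge = len(max_sorted) - np.searchsorted(max_sorted, abs_t, side="left")
    p_flat = (extra + n_ge) / denom

    shape = region.shape
    t_full = np.zeros(shape)
    p_full = np.ones(shape)
    flat = region.ravel()
    t_full.ravel()[flat] = t_obs
    p_full.ravel()[flat] = p_flat
    return StatMap(
        t=t_full,
        p_corr=p_full,
        region=region,
        spacing=spacing,
        origin=origin,
        alpha=alpha,
        n_perm=len(assign),
        exhaustive=exhaustive,
        max_t_null=max_null,
    )


def narrow_band(sdf: SignedDistanceVolume, band_mm: float = 5.0) -> np.ndarray:
    """Boolean analysis region: voxels within ``band_mm`` of the zero level set."""
    if band_mm <= 0:
        raise StatsError(f"band_mm must be > 0, got {band_mm}")
    return np.abs(sdf.data) <= band_mm


def extract_surface_mesh(template: BinaryMask) -> SurfaceMesh:
    """Marching-cubes isosurface of the mask at the 0.5 level, in world mm."""
    if not template.data.any():
        raise EmptyForegroundError("cannot mesh an empty mask")
    verts, faces, _, _ = measure.marching_cubes(
        template.data.astype(np.float32), level=0.5, spacing=template.spacing
    )
    verts = verts + np.asarray(template.origin)
    return SurfaceMesh(vertices=np.asarray(verts), faces=np.asarray(faces))


def identify_soi(
    stat: StatMap, mesh: SurfaceMesh, alpha: float = 0.05, band_mm: float = 3.0
) -> SOIMap:
    """Partition mesh vertices into SOI/cSOI from the corrected p map.

    A vertex is in the SOI iff the minimum corrected p among analysis voxels
    within ``band_mm`` of it is below ``alpha``.  ``alpha >= 1`` marks every
    vertex covered by the analysis region as significant (limit case).
    """
    if band_mm <= 0:
        raise StatsError(f"band_mm must be > 0, got {band_mm}")
    region_idx = np.argwhere(stat.region)
    in_region_p = stat.p_corr[stat.region]
    sig = in_region_p < alpha if alpha < 1 else np.ones(len(in_region_p), dtype=bool)
    all_idx = np.arange(mesh.n_vertices)
    if not sig.any():
        return SOIMap(np.empty(0, dtype=int), all_idx, alpha)
    sig_world = region_idx[sig] * np.asarray(stat.spacing) + np.asarray(stat.origin)
    tree = cKDTree(sig_world)
    dist, _ = tree.query(mesh.vertices, k=1, distance_upper_bound=band_mm)
    soi = np.flatnonzero(np.isfinite(dist) & (dist <= band_mm))
    csoi = np.setdiff1d(all_idx, soi)
    return SOIMap(soi, csoi, alpha)
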