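"""Synthetic atrium-like cohorts with a planted, localized group difference.

Patient data behind the method are not public, so every pipeline stage is
exercised on synthetic cohorts of smooth closed 3D shapes.  Each member is a
star-shaped radial perturbation of an ellipsoid,

    r(theta, phi) = s * r_ell(theta, phi) * (1 + f(theta, phi) / R)
                    + g * A * bump(theta, phi)

where ``r_ell`` is the ellipsoidal radius (base radius R with per-axis
ratios), ``s`` a per-member volume-jitter scale, ``f`` a smooth random field
on the sphere (random low-order spherical harmonics, RMS amplitude in mm),
``g`` the group indicator and ``A * bump`` an outward spherical-cap bump of
amplitude A (mm) applied to the positive group only.  Star-shapedness gives
an analytic ground-truth region for the planted cap, which acceptance checks
score SOI detection against.  Clinical covariates are drawn with the group
means/SDs and proportions of the study's published characteristics table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree
from scipy.special import sph_harm_y

from .outcome import CLINICAL_COLUMNS
from .shapestats import SOIMap, StatsError, SurfaceMesh
from .volumes import BinaryMask, VolumeError

logger = logging.getLogger("atriashape")


@dataclass(frozen=True)
class CohortSpec:
    """Generator parameters for a two-group shape cohort.

    Amplitudes are in mm.  The planted effect is an outward bump of
    ``effect_mm`` over a spherical cap of half-angle ``cap_deg`` around
    ``cap_center`` (a direction), applied to positive-group members only.
    """

    n_pos: int = 15
    n_neg: int = 15
    base_radius_mm: float = 30.0
    axis_ratios: tuple[float, float, float] = (1.0, 0.85, 0.7)
    variability_mm: float = 1.0
    smoothness_mm: float = 20.0
    cap_center: tuple[float, float, float] = (1.0, 0.0, 0.0)
    cap_deg: float = 30.0
    effect_mm: float = 3.0
    volume_jitter: float = 0.05
    spacing_mm: float = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_pos < 2 or self.n_neg < 2:
            raise VolumeError("need n_pos, n_neg >= 2")
        if self.variability_mm < 0 or self.effect_mm < 0 or self.volume_jitter < 0:
            raise VolumeError("amplitudes must be >= 0")
        if not 0 < self.cap_deg <= 90:
            raise VolumeError("cap angular radius must be in (0, 90] degrees")
        if self.spacing_mm <= 0 or self.base_radius_mm <= 0:
            raise VolumeError("spacing and base radius must be > 0")

    @property
    def cap_direction(self) -> np.ndarray:
        c = np.asarray(self.cap_center, dtype=float)
        return c / np.linalg.norm(c)


@dataclass
class GroundTruth:
    """Planted-effect record: cap geometry and per-member draw parameters."""

    cap_center: np.ndarray
    cap_deg: float
    effect_mm: float
    member_seeds: list[int] = field(default_factory=list)
    member_scales: list[float] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return self.effect_mm == 0

    def vertex_indicator(
        self, mesh: SurfaceMesh, center_world=(0.0, 0.0, 0.0)
    ) -> np.ndarray:
        """Boolean mask of mesh vertices inside the planted cap (by direction
        from the shape centre)."""
        if self.empty:
            return np.zeros(mesh.n_vertices, dtype=bool)
        d = mesh.vertices - np.asarray(center_world, dtype=float)
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        ang = np.degrees(np.arccos(np.clip(d @ self.cap_center, -1.0, 1.0)))
        return ang <= self.cap_deg


# ---------------------------------------------------------------------------
# Radial surface model
# ---------------------------------------------------------------------------

def _real_sph_harm(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Real orthonormal spherical harmonic (theta polar, phi azimuth)."""
    y = sph_harm_y(l, abs(m), theta, phi)
    if m == 0:
        return y.real
    if m > 0:
        return np.sqrt(2.0) * (-1) ** m * y.real
    return np.sqrt(2.0) * (-1) ** m * y.imag


def _smooth_sphere_field(
    rng: np.random.Generator, rms_mm: float, l_max: int, theta: np.ndarray, phi: np.ndarray
) -> np.ndarray:
    """Random smooth field on the sphere with pointwise RMS ``rms_mm``.

    Coefficients are i.i.d. Gaussian per (l, m), l = 1..l_max; by the addition
    theorem the pointwise variance is sum_l sigma_l^2 (2l+1) / (4 pi).
    """
    if rms_mm == 0 or l_max < 1:
        # keep the RNG stream aligned across effect-on/off cohorts
        return np.zeros_like(theta)
    n_terms = sum(2 * l + 1 for l in range(1, l_max + 1))
    sigma = rms_mm * np.sqrt(4 * np.pi / n_terms)
    out = np.zeros_like(theta)
    for l in range(1, l_max + 1):
        for m in range(-l, l + 1):
            out += rng.normal(0.0, sigma) * _real_sph_harm(l, m, theta, phi)
    return out


def _ellipsoid_radius(spec: CohortSpec, nx, ny, nz) -> np.ndarray:
    a, b, c = (spec.base_radius_mm * r for r in spec.axis_ratios)
    return 1.0 / np.sqrt((nx / a) ** 2 + (ny / b) ** 2 + (nz / c) ** 2)


#: Fraction of the cap radius carrying the full effect amplitude; the
#: remaining rim rolls off smoothly to zero at the cap edge.
_CAP_PLATEAU = 0.85


def _cap_bump(spec: CohortSpec, nx, ny, nz) -> np.ndarray:
    """Plateau cap profile: 1 out to ``_CAP_PLATEAU`` of the cap radius, then
    a raised-cosine roll-off to 0 at the edge (C1-smooth everywhere), so the
    mean planted radial difference inside the cap stays close to the nominal
    effect amplitude."""
    e = spec.cap_direction
    ang = np.degrees(np.arccos(np.clip(nx * e[0] + ny * e[1] + nz * e[2], -1.0, 1.0)))
    edge = spec.cap_deg
    plateau = _CAP_PLATEAU * edge
    bump = np.zeros_like(ang)
    bump[ang <= plateau] = 1.0
    rim = (ang > plateau) & (ang < edge)
    v = (ang[rim] - plateau) / (edge - plateau)
    bump[rim] = 0.5 * (1 + np.cos(np.pi * v))
    return bump


def _grid_geometry(spec: CohortSpec) -> tuple[int, float]:
    """Shared grid for all cohort members: side length (voxels) and origin."""
    r_max = (
        spec.base_radius_mm
        * max(spec.axis_ratios)
        * (1 + 3 * spec.volume_jitter)
        * (1 + 4 * spec.variability_mm / spec.base_radius_mm)
        + spec.effect_mm
    )
    half = r_max + 3 * spec.spacing_mm
    n_half = int(np.ceil(half / spec.spacing_mm))
    n_side = 2 * n_half + 1
    origin = -n_half * spec.spacing_mm
    return n_side, origin


def _radial_table(spec: CohortSpec, rng: np.random.Generator, group: int, scale: float):
    """Surface radius r(theta, phi) sampled on a lat-long table, plus an
    interpolator over it (phi wrapped periodically)."""
    n_theta, n_phi = 128, 256
    theta = np.linspace(0.0, np.pi, n_theta)
    phi = np.linspace(0.0, 2 * np.pi, n_phi, endpoint=False)
    T, P = np.meshgrid(theta, phi, indexing="ij")
    nx = np.sin(T) * np.cos(P)
    ny = np.sin(T) * np.sin(P)
    nz = np.cos(T)

    l_max = min(6, max(1, int(round(np.pi * spec.base_radius_mm / spec.smoothness_mm))))
    f = _smooth_sphere_field(rng, spec.variability_mm, l_max, T, P)
    r = scale * _ellipsoid_radius(spec, nx, ny, nz) * (1 + f / spec.base_radius_mm)
    if group == 1 and spec.effect_mm > 0:
        r = r + spec.effect_mm * _cap_bump(spec, nx, ny, nz)
    if (r <= 0.2 * spec.base_radius_mm).any():
        raise VolumeError("surface self-intersects: perturbation amplitude too large")

    # wrap phi for periodic interpolation
    phi_ext = np.concatenate([phi, [2 * np.pi]])
    r_ext = np.concatenate([r, r[:, :1]], axis=1)
    interp = RegularGridInterpolator((theta, phi_ext), r_ext, bounds_error=False,
                                     fill_value=None)
    return interp


def generate_member(spec: CohortSpec, group: int, member_seed: int) -> BinaryMask:
    """One cohort member: a rasterized star-shaped surface, deterministic in
    ``member_seed``.  ``group=1`` members carry the planted cap bump."""
    rng = np.random.default_rng(member_seed)
    scale = 1.0 + rng.normal(0.0, spec.volume_jitter / 3.0) if spec.volume_jitter else 1.0
    if scale <= 0.5:
        raise VolumeError("volume jitter drew a degenerate scale")
    interp = _radial_table(spec, rng, group, scale)

    n_side, origin = _grid_geometry(spec)
    coords = origin + spec.spacing_mm * np.arange(n_side)
    X, Y, Z = np.meshgrid(coords, coords, coords, indexing="ij")
    rho = np.sqrt(X**2 + Y**2 + Z**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(np.where(rho > 0, Z / np.where(rho > 0, rho, 1), 1), -1, 1))
    phi = np.mod(np.arctan2(Y, X), 2 * np.pi)
    r_surf = interp(np.stack([theta.ravel(), phi.ravel()], axis=1)).reshape(rho.shape)
    mask = BinaryMask(
        (rho <= r_surf).astype(np.uint8),
        (spec.spacing_mm,) * 3,
        (origin,) * 3,
    )
    mask.validate(margin=2)
    return mask


def generate_cohort(spec: CohortSpec):
    """Full two-group cohort.

    Returns (masks, labels, truth): ``n_pos`` positive members (label 1,
    carrying the planted effect) followed by ``n_neg`` negative members, and
    the ground-truth cap record.  Bit-for-bit reproducible from the spec.
    """
    if spec.seed is None:
        raise VolumeError("CohortSpec.seed is required for cohort generation")
    n = spec.n_pos + spec.n_neg
    member_seeds = [int(s) for s in np.random.SeedSequence(spec.seed).generate_state(n)]
    labels = np.array([1] * spec.n_pos + [0] * spec.n_neg)
    truth = GroundTruth(
        cap_center=spec.cap_direction,
        cap_deg=spec.cap_deg,
        effect_mm=spec.effect_mm,
        member_seeds=member_seeds,
    )
    masks = []
    for i, (g, ms) in enumerate(zip(labels, member_seeds)):
        masks.append(generate_member(spec, int(g), ms))
        rng = np.random.default_rng(ms)
        truth.member_scales.append(
            1.0 + rng.normal(0.0, spec.volume_jitter / 3.0) if spec.volume_jitter else 1.0
        )
    return masks, labels, truth


# ---------------------------------------------------------------------------
# Clinical covariates
# ---------------------------------------------------------------------------

#: Group moments of the published clinical characteristics table:
#: (mean, sd) per continuous variable and proportion per binary variable,
#: keyed by outcome (0 = no recurrence at 1 year, 1 = recurrence).
CLINICAL_MOMENTS: dict[int, dict[str, tuple[float, float]]] = {
    0: {"lvef": (54.5, 8.65), "bmi": (28.9, 5.2), "age": (62.6, 9.46),
        "la_volume": (153.5, 42.44)},
    1: {"lvef": (58.4, 5.94), "bmi": (31.4, 5.82), "age": (68.0, 8.24),
        "la_volume": (157.3, 45.14)},
}
CLINICAL_PROPORTIONS: dict[int, dict[str, float]] = {
    0: {"sex": 0.76, "sinus_rhythm": 0.76, "persistent_af": 0.24, "cryoablation": 0.27},
    1: {"sex": 0.61, "sinus_rhythm": 0.55, "persistent_af": 0.35, "cryoablation": 0.19},
}


def generate_clinical(n_pos: int, n_neg: int, seed: int) -> pd.DataFrame:
    """Clinical covariate table calibrated to the study's group statistics.

    Continuous covariates are normal draws with the group means/SDs; binary
    covariates are Bernoulli draws with the group proportions.  Rows are
    positives (recurrence = 1) first, matching :func:`generate_cohort`.
    """
    if n_pos < 2 or n_neg < 2:
        raise VolumeError("need >= 2 patients per group")
    rng = np.random.default_rng(seed)
    frames = []
    for label, count in ((1, n_pos), (0, n_neg)):
        cols = {}
        for var, (mean, sd) in CLINICAL_MOMENTS[label].items():
            cols[var] = rng.normal(mean, sd, size=count)
        for var, p in CLINICAL_PROPORTIONS[label].items():
            cols[var] = (rng.random(count) < p).astype(int)
        cols["recurrence"] = np.full(count, label, dtype=int)
        frames.append(pd.DataFrame(cols))
    table = pd.concat(frames, ignore_index=True)
    table.index.name = "patient_id"
    return table[list(CLINICAL_COLUMNS)]


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

def soi_recovery_score(
    detected: SOIMap,
    truth_vertices: np.ndarray,
    mesh: SurfaceMesh,
    dilate_mm: float = 5.0,
):
    """Score detected SOI vertices against the planted ground-truth region.

    sensitivity = |detected ∩ truth| / |truth|; precision = fraction of
    detected vertices within ``dilate_mm`` of a truth vertex.  With an empty
    truth and nonempty detection, sensitivity is undefined (None) and only
    precision (0) is meaningful; an empty detection scores precision 1
    vacuously.  Returns (sensitivity, precision).
    """
    truth_vertices = np.asarray(truth_vertices)
    if truth_vertices.dtype == bool:
        truth_idx = np.flatnonzero(truth_vertices)
    else:
        truth_idx = truth_vertices.astype(int)
    det = np.asarray(detected.soi_vertices, dtype=int)
    if len(truth_idx) == 0:
        if len(det) == 0:
            return None, 1.0
        logger.warning("empty truth region with nonempty detection")
        return None, 0.0
    sensitivity = len(np.intersect1d(det, truth_idx)) / len(truth_idx)
    if len(det) == 0:
        return 0.0, 1.0
    tree = cKDTree(mesh.vertices[truth_idx])
    dist, _ = tree.query(mesh.vertices[det], k=1)
    precision = float((dist <= dilate_mm).mean())
    return float(sensitivity), precision


def null_spec(spec: CohortSpec) -> CohortSpec:
    """The same cohort conditions with the planted effect switched off."""
    return replace(spec, effect_mm=0.0)
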