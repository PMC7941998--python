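"""Deformation-field radiomic descriptors on SOI / cSOI mesh regions.

The template mask is registered to each patient (affine + B-spline, the total
displacement field), the field and its curl are sampled at the template-mesh
vertices by trilinear interpolation, and per region (SOI and its complement
cSOI) 16 first-order statistics summarise the field:

* 4 norm statistics: min, mean, max, std of ||u|| (mm, sample std, n-1)
* 3 component means: mean u_x, u_y, u_z (mm)
* 9 curl statistics: min, mean, max of each curl component (dimensionless)

A full patient record is therefore 32 features (16 SOI + 16 cSOI).  "Curl
component k" in the outcome analysis refers to the z axis of the template
grid (i, j, k unit-vector convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .registration import (
    DeformationField,
    RegistrationError,
    _VectorFieldMixin,
    affine_displacement_field,
    register_affine,
    register_bspline,
)
from .shapestats import SOIMap, StatsError, SurfaceMesh
from .volumes import BinaryMask, Vec3, VolumeError

logger = logging.getLogger("atriashape")

#: Stable per-region feature order (16 names).
FEATURE_NAMES: tuple[str, ...] = (
    "norm_min",
    "norm_mean",
    "norm_max",
    "norm_std",
    "mean_ux",
    "mean_uy",
    "mean_uz",
    "curl_x_min",
    "curl_x_mean",
    "curl_x_max",
    "curl_y_min",
    "curl_y_mean",
    "curl_y_max",
    "curl_z_min",
    "curl_z_mean",
    "curl_z_max",
)

REGIONS: tuple[str, ...] = ("soi", "csoi")


def feature_schema() -> dict:
    """JSON-serialisable schema of the per-patient feature columns."""
    return {
        "regions": list(REGIONS),
        "per_region_features": list(FEATURE_NAMES),
        "columns": [f"{r}_{f}" for r in REGIONS for f in FEATURE_NAMES],
        "units": {
            "norm_*": "mm",
            "mean_u*": "mm",
            "curl_*": "dimensionless (mm/mm)",
        },
    }


@dataclass
class CurlField(_VectorFieldMixin):
    """Curl of a displacement field at grid points, shape (nx, ny, nz, 3)."""

    data: np.ndarray
    spacing: Vec3
    origin: Vec3 = (0.0, 0.0, 0.0)


def template_to_patient_field(
    template: BinaryMask,
    patient: BinaryMask,
    nonrigid_only: bool = False,
    affine_kwargs: dict | None = None,
    bspline_kwargs: dict | None = None,
) -> DeformationField:
    """Total (affine + B-spline) displacement field registering the template
    onto a patient mask, on the template grid.

    Registration runs template -> patient so that SOI vertex trajectories are
    tracked into the patient frame.  ``nonrigid_only`` subtracts the affine
    part, leaving the free-form component of the displacement.
    """
    affine = register_affine(template, patient, **(affine_kwargs or {}))
    fld = register_bspline(template, patient, affine, **(bspline_kwargs or {}))
    if nonrigid_only:
        aff_fld = affine_displacement_field(affine, template)
        fld = DeformationField(
            fld.data - aff_fld.data,
            fld.spacing,
            fld.origin,
            dice=fld.dice,
            gate_passed=fld.gate_passed,
        )
    return fld


def field_curl(field: DeformationField) -> CurlField:
    """Curl of the displacement field by central differences (per mm).

    c = (duz/dy - duy/dz, dux/dz - duz/dx, duy/dx - dux/dy); one-sided
    differences at grid borders.
    """
    if any(n < 3 for n in field.data.shape[:3]):
        raise VolumeError("curl needs >= 3 voxels per axis")
    ux, uy, uz = field.data[..., 0], field.data[..., 1], field.data[..., 2]
    sx, sy, sz = field.spacing
    duz_dy = np.gradient(uz, sy, axis=1)
    duy_dz = np.gradient(uy, sz, axis=2)
    dux_dz = np.gradient(ux, sz, axis=2)
    duz_dx = np.gradient(uz, sx, axis=0)
    duy_dx = np.gradient(uy, sx, axis=0)
    dux_dy = np.gradient(ux, sy, axis=1)
    c = np.stack((duz_dy - duy_dz, dux_dz - duz_dx, duy_dx - dux_dy), axis=-1)
    return CurlField(c, field.spacing, field.origin)


def magnitude_stats(vectors: np.ndarray) -> dict[str, float]:
    """Norm statistics (min/mean/max/std of ||u||) and component means.

    Sample std (n-1 divisor); a singleton set gets std 0.
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    if vectors.size == 0:
        raise StatsError("magnitude_stats on an empty vertex set")
    norms = np.linalg.norm(vectors, axis=1)
    std = float(norms.std(ddof=1)) if len(norms) > 1 else 0.0
    means = vectors.mean(axis=0)
    return {
        "norm_min": float(norms.min()),
        "norm_mean": float(norms.mean()),
        "norm_max": float(norms.max()),
        "norm_std": std,
        "mean_ux": float(means[0]),
        "mean_uy": float(means[1]),
        "mean_uz": float(means[2]),
    }


def curl_stats(curls: np.ndarray) -> dict[str, float]:
    """Min/mean/max of each curl component over a vertex set."""
    curls = np.atleast_2d(np.asarray(curls, dtype=float))
    if curls.size == 0:
        raise StatsError("curl_stats on an empty vertex set")
    out: dict[str, float] = {}
    for axis, name in enumerate("xyz"):
        comp = curls[:, axis]
        out[f"curl_{name}_min"] = float(comp.min())
        out[f"curl_{name}_mean"] = float(comp.mean())
        out[f"curl_{name}_max"] = float(comp.max())
    return out


def region_features(
    field: DeformationField, curl: CurlField, vertices: np.ndarray
) -> dict[str, float]:
    """The 16 statistics of one region, sampled at the given vertex positions."""
    u = field.sample(vertices)
    c = curl.sample(vertices)
    feats = magnitude_stats(u)
    feats.update(curl_stats(c))
    return {name: feats[name] for name in FEATURE_NAMES}


def compute_feature_table(
    template: BinaryMask,
    patients: list[BinaryMask],
    soimap: SOIMap,
    mesh: SurfaceMesh,
    patient_ids: list | None = None,
    nonrigid_only: bool = False,
    affine_kwargs: dict | None = None,
    bspline_kwargs: dict | None = None,
) -> tuple[pd.DataFrame, list[tuple[object, str]]]:
    """Per-patient 32-feature table (16 SOI + 16 cSOI).

    Registers the template to every patient, samples the displacement field
    and its curl at the SOI and cSOI mesh vertices, and returns a wide table
    (one row per patient) plus a list of (patient_id, reason) registration
    failures; failed patients are excluded from the table with a warning.
    """
    if len(soimap.soi_vertices) == 0:
        raise StatsError("empty SOI: no feature extraction possible for the SOI region")
    if len(soimap.csoi_vertices) == 0:
        raise StatsError("empty cSOI: the SOI covers the whole surface")
    if patient_ids is None:
        patient_ids = list(range(len(patients)))
    soi_xyz = mesh.vertices[soimap.soi_vertices]
    csoi_xyz = mesh.vertices[soimap.csoi_vertices]

    rows: list[dict] = []
    index: list = []
    failures: list[tuple[object, str]] = []
    for pid, patient in zip(patient_ids, patients):
        try:
            fld = template_to_patient_field(
                template,
                patient,
                nonrigid_only=nonrigid_only,
                affine_kwargs=affine_kwargs,
                bspline_kwargs=bspline_kwargs,
            )
        except RegistrationError as exc:
            logger.warning("patient %s excluded from feature table: %s", pid, exc)
            failures.append((pid, str(exc)))
            continue
        curl = field_curl(fld)
        row: dict[str, float] = {}
        for region, xyz in (("soi", soi_xyz), ("csoi", csoi_xyz)):
            for name, value in region_features(fld, curl, xyz).items():
                row[f"{region}_{name}"] = value
        rows.append(row)
        index.append(pid)
    table = pd.DataFrame(rows, index=pd.Index(index, name="patient_id"))
    return table[feature_schema()["columns"]] if len(table) else table, failures


def to_long_format(table: pd.DataFrame) -> pd.DataFrame:
    """Wide 32-column table -> long (patient_id, region, feature_name, value)."""
    long = table.reset_index().melt(
        id_vars="patient_id", var_name="column", value_name="value"
    )
    long["region"] = long["column"].str.split("_", n=1).str[0]
    long["feature_name"] = long["column"].str.split("_", n=1).str[1]
    return long[["patient_id", "region", "feature_name", "value"]]
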