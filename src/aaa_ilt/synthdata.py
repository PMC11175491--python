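"""Synthetic inputs with known ground truth.

Every generator here emulates one upstream data source of the study and
returns its ground truth alongside the data, so downstream estimators are
tested by parameter recovery:

* ``make_label_volume`` — an extruded slice geometry rasterized to a
  CT-segmentation-like label volume (classes by voxel-centre membership,
  no partial-volume model);
* ``make_density_field`` — HU-like densities per class, with the thrombus
  drawn from one of two cohort clusters (mean ratio 2 by default);
* ``make_paired_measurements`` — paired ultrasound/CT thrombus fractions
  with additive clipped Gaussian disagreement;
* ``make_boundary_tracks`` — wall and lining contours over a cardiac cycle,
  a solved displacement field scaled by a half-sine waveform, emulating
  speckle-tracked boundary motion.

All randomness flows from the per-call seed; there is no global state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InterpolationError, ResolutionError
from .geometry import POSITIONS, SliceGeometry, geometry_from_fraction
from .imaging import (
    CLASS_CALCIFICATION,
    CLASS_LUMEN,
    CLASS_THROMBUS,
    BoundaryTrack,
    LabelVolume,
    cluster_by_fraction,
)
from .mesh import Mesh, ring_interpolate

__all__ = [
    "CohortSpec",
    "make_label_volume",
    "make_density_field",
    "make_paired_measurements",
    "make_boundary_tracks",
    "write_cohort",
]

#: Fixed HU-like class means for non-thrombus classes.
CLASS_DENSITY = {0: 0.0, CLASS_LUMEN: 40.0, CLASS_CALCIFICATION: 300.0}


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic cohort description.

    ``fraction_range`` bounds a uniform thrombus-fraction distribution;
    ``density_clusters`` are two (mean, sd) pairs whose means differ by a
    factor of two by default, mirroring the bimodal density histogram of
    the cohort.
    """

    n_subjects: int = 21
    fraction_range: tuple[float, float] = (0.2, 0.99)
    positions: tuple = POSITIONS
    us_noise_sd: float = 0.05
    ct_noise_sd: float = 0.02
    density_clusters: tuple = ((60.0, 8.0), (120.0, 16.0))
    density_cluster_weights: tuple = (0.5, 0.5)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 0:
            raise ResolutionError("n_subjects must be >= 0")
        if self.us_noise_sd < 0 or self.ct_noise_sd < 0:
            raise ResolutionError("noise sds must be >= 0")
        lo, hi = self.fraction_range
        if not (0.0 <= lo < hi < 1.0):
            raise ResolutionError("fraction_range must be within [0, 1)")


def make_label_volume(
    geometry: SliceGeometry,
    n_slices: int = 8,
    spacing: tuple[float, float, float] = (0.5, 0.5, 2.0),
    seed: int = 0,
    jitter_sd: float = 0.0,
    calcification_count: int = 0,
) -> tuple[LabelVolume, dict]:
    """Rasterize an extruded slice geometry to a label volume.

    Voxel class is decided by its centre point: lumen circle -> lumen,
    cavity outside the lumen -> thrombus, elsewhere (wall and exterior) ->
    background.  ``jitter_sd`` (mm) shifts the lumen centre per transverse
    slice to emulate segmentation wobble; ``calcification_count`` sprinkles
    small calcified blobs into the thrombus.  Returns the volume and a
    ground-truth record (fraction, offset, radii).
    """
    rng = np.random.default_rng(seed)
    sx, sy, sz = spacing
    if geometry.has_thrombus and 2.0 * geometry.lumen_radius < 2.0 * max(sx, sy):
        raise ResolutionError(
            f"lumen (r={geometry.lumen_radius:.2f} mm) under 2 voxels across "
            f"at {max(sx, sy)} mm spacing"
        )
    b = geometry.wall_outer_radius
    half = b + 2.0
    nx = int(math.ceil(2 * half / sx))
    ny = int(math.ceil(2 * half / sy))
    xs = (np.arange(nx) + 0.5) * sx - half
    ys = (np.arange(ny) + 0.5) * sy - half
    gx, gy = np.meshgrid(xs, ys, indexing="ij")

    a = geometry.wall_inner_radius
    cavity = gx * gx + gy * gy < a * a
    vox = np.zeros((nx, ny, n_slices), dtype=np.int64)
    for k in range(n_slices):
        sl = np.zeros((nx, ny), dtype=np.int64)
        if geometry.has_thrombus:
            c = geometry.lumen_center + (
                rng.normal(0.0, jitter_sd, size=2) if jitter_sd > 0 else 0.0
            )
            lumen = (gx - c[0]) ** 2 + (gy - c[1]) ** 2 < geometry.lumen_radius**2
            sl[cavity] = CLASS_THROMBUS
            sl[lumen & cavity] = CLASS_LUMEN
        else:  # zero-thickness thrombus: the whole cavity is lumen
            sl[cavity] = CLASS_LUMEN
        vox[:, :, k] = sl

    for _ in range(calcification_count):
        thr = np.argwhere(vox == CLASS_THROMBUS)
        if thr.size == 0:
            break
        centre = thr[rng.integers(len(thr))]
        radius_vox = rng.integers(1, 3)
        lo = np.maximum(centre - radius_vox, 0)
        hi = np.minimum(centre + radius_vox + 1, vox.shape)
        block = vox[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        block[block == CLASS_THROMBUS] = CLASS_CALCIFICATION

    truth = {
        "fraction": geometry.thrombus_fraction,
        "lumen_offset": list(geometry.lumen_center),
        "lumen_radius": geometry.lumen_radius,
        "wall_inner_radius": a,
        "seed": seed,
    }
    return LabelVolume(vox, spacing), truth


def make_density_field(
    volume: LabelVolume,
    cluster_spec: tuple[float, float] = (60.0, 8.0),
    seed: int = 0,
) -> np.ndarray:
    """Attach an HU-like density channel; thrombus voxels from the subject's
    cluster component, other classes at fixed class means.  Returns the
    density grid (also stored on the volume)."""
    rng = np.random.default_rng(seed)
    mean, sd = cluster_spec
    density = np.zeros(volume.voxels.shape, dtype=float)
    for klass, value in CLASS_DENSITY.items():
        density[volume.voxels == klass] = value
    thr = volume.voxels == CLASS_THROMBUS
    n = int(np.count_nonzero(thr))
    density[thr] = mean if sd == 0 else rng.normal(mean, sd, size=n)
    volume.density = density
    return density


def make_paired_measurements(spec: CohortSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Paired US/CT thrombus fractions for a cohort.

    Both modalities observe the true fraction with additive Gaussian noise,
    clipped to [0, 1].  Returns the concordance table (subject, us_fraction,
    ct_fraction, cluster, position, density cluster index) and the true
    fractions.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.fraction_range
    true = rng.uniform(lo, hi, size=spec.n_subjects)
    us = np.clip(true + rng.normal(0.0, spec.us_noise_sd, size=spec.n_subjects), 0.0, 1.0)
    ct = np.clip(true + rng.normal(0.0, spec.ct_noise_sd, size=spec.n_subjects), 0.0, 1.0)
    positions = rng.choice(list(spec.positions), size=spec.n_subjects)
    weights = np.asarray(spec.density_cluster_weights, dtype=float)
    dens_cluster = rng.choice(len(spec.density_clusters), size=spec.n_subjects,
                              p=weights / weights.sum())
    table = pd.DataFrame(
        {
            "subject": [f"s{i:03d}" for i in range(spec.n_subjects)],
            "us_fraction": us,
            "ct_fraction": ct,
            "cluster": cluster_by_fraction(ct),
            "position": positions,
            "density_cluster": dens_cluster,
        }
    )
    return table, true


def _half_sine(t: np.ndarray) -> np.ndarray:
    return np.sin(math.pi * t)


def make_boundary_tracks(
    geometry: SliceGeometry,
    fld,
    waveform=None,
    n_points: int = 48,
    n_frames: int = 20,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> BoundaryTrack:
    """Contours of outer wall and lumen lining over one cardiac cycle.

    Rest contours are the geometric circles sampled at ``n_points``; the
    solved displacement field ``fld`` (on a mesh of the same geometry) is
    interpolated onto them and scaled by ``waveform(t)`` (default half-sine
    over the cycle).  ``noise_sd`` (mm) adds per-point Gaussian jitter.
    """
    if n_points < 12 or n_points % 6:
        raise InterpolationError("n_points must be >= 12 and divisible by 6")
    mesh: Mesh = fld.mesh
    waveform = _half_sine if waveform is None else waveform
    rng = np.random.default_rng(seed)
    theta = 2.0 * math.pi * np.arange(n_points) / n_points
    e = np.stack([np.cos(theta), np.sin(theta)], axis=1)

    rest_outer = geometry.wall_outer_radius * e
    rest_lining = geometry.lumen_center[None, :] + geometry.lumen_radius * e

    def interp_u(ring_nodes, rest, center):
        ring_xy = mesh.nodes[ring_nodes]
        return np.stack(
            [
                ring_interpolate(ring_xy, fld.u[ring_nodes, i], rest, center)
                for i in range(2)
            ],
            axis=1,
        )

    u_outer = interp_u(mesh.outer_nodes, rest_outer, np.zeros(2)) / 1.0e-3  # m -> mm
    u_lining = interp_u(mesh.lining_nodes, rest_lining, geometry.lumen_center) / 1.0e-3

    times = np.linspace(0.0, 1.0, n_frames)
    w = np.asarray([waveform(t) for t in times], dtype=float)
    outer = rest_outer[None] + w[:, None, None] * u_outer[None]
    lining = rest_lining[None] + w[:, None, None] * u_lining[None]
    if noise_sd > 0:
        outer = outer + rng.normal(0.0, noise_sd, size=outer.shape)
        lining = lining + rng.normal(0.0, noise_sd, size=lining.shape)
    return BoundaryTrack(outer=outer, lining=lining, times=times)


def write_cohort(spec: CohortSpec, outdir, volume_slices: int = 4,
                 spacing=(1.0, 1.0, 2.0), overwrite: bool = False) -> dict:
    """Write a complete synthetic cohort (volumes, tables, manifest).

    One label volume with density per subject (geometry from the subject's
    true fraction and position), the paired US/CT table, and a manifest JSON
    recording every seed and ground truth.  Returns the manifest.
    """
    out = Path(outdir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists (use overwrite/force)")
    (out / "volumes").mkdir(parents=True, exist_ok=True)
    table, true = make_paired_measurements(spec)
    subjects = []
    for i, row in table.iterrows():
        frac = float(true[i])
        position = str(row["position"])
        try:
            geo = geometry_from_fraction(frac, position)
        except Exception:
            geo = geometry_from_fraction(frac, "center")
            position = "center"
        vol, truth = make_label_volume(
            geo, n_slices=volume_slices, spacing=spacing, seed=spec.seed + 1000 + i
        )
        cluster = spec.density_clusters[int(row["density_cluster"])]
        make_density_field(vol, cluster, seed=spec.seed + 2000 + i)
        path = out / "volumes" / f"{row['subject']}.nii.gz"
        vol.to_nifti(path)
        truth.update(position=position, density_cluster=list(cluster),
                     volume=str(path.relative_to(out)))
        subjects.append({"subject": row["subject"], **truth})
    table.to_csv(out / "paired_fractions.csv", index=False)
    manifest = {
        "seed": spec.seed,
        "n_subjects": spec.n_subjects,
        "spacing": list(spacing),
        "true_fractions": [float(v) for v in true],
        "subjects": subjects,
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
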