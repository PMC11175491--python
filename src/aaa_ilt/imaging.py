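"""Imaging-side analyses: CT volumetry, concordance and strain traces.

The CT side works on segmentation label volumes (classes background / lumen
/ thrombus / calcification on a voxel grid with physical spacing): class
volumes by voxel counting, volumetric thrombus fraction
``V_thr / (V_thr + V_lumen)``, a 0-1 lumen eccentricity index, the
fraction clustering used to stratify subjects, and density summaries of the
thrombus voxels.  Concordance between paired ultrasound and CT fractions is
measured by a tie-corrected Spearman rank correlation with an exact
permutation p-value at small n.  The ultrasound side reduces tracked wall
and lumen contours over a cardiac cycle to 6-sector circumferential strain
curves (expansion positive) with their global peaks.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateContourError,
    DegenerateError,
    EmptyCavityError,
    LengthMismatchError,
    MissingDensityError,
    UnknownClassError,
)

__all__ = [
    "CLASS_BACKGROUND",
    "CLASS_LUMEN",
    "CLASS_THROMBUS",
    "CLASS_CALCIFICATION",
    "FRACTION_CLUSTERS",
    "LabelVolume",
    "BoundaryTrack",
    "class_volume",
    "thrombus_fraction_volume",
    "lumen_position_index",
    "cluster_by_fraction",
    "spearman_rank",
    "density_stats",
    "circumferential_strain",
]

CLASS_BACKGROUND = 0
CLASS_LUMEN = 1
CLASS_THROMBUS = 2
CLASS_CALCIFICATION = 3
_DECLARED_CLASSES = (CLASS_BACKGROUND, CLASS_LUMEN, CLASS_THROMBUS, CLASS_CALCIFICATION)

#: Cohort stratification bins for the thrombus fraction; all bins are
#: left-closed/right-open except the last, which is closed at 0.99.
FRACTION_CLUSTERS = ((0.2, 0.4), (0.4, 0.6), (0.6, 0.8), (0.8, 0.99))
OUT_OF_RANGE = "out-of-range"


@dataclass
class LabelVolume:
    """Segmentation label grid with voxel spacing and optional density.

    ``voxels`` is (nx, ny, nz) integer classes; ``spacing`` mm per axis;
    ``density`` an optional co-registered scalar grid (HU-like units) of the
    same shape.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    density: np.ndarray | None = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise UnknownClassError("voxels must be a 3D grid")
        if any(s <= 0 for s in self.spacing):
            raise UnknownClassError("spacing must be positive per axis")
        extra = set(np.unique(self.voxels)) - set(_DECLARED_CLASSES)
        if extra:
            raise UnknownClassError(f"undeclared classes {sorted(extra)}")
        if self.density is not None:
            self.density = np.asarray(self.density, dtype=float)
            if self.density.shape != self.voxels.shape:
                raise MissingDensityError("density grid shape mismatch")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def to_nifti(self, path) -> None:
        """Write as NIfTI-1 with spacing in the header; density, if present,
        goes to a sibling ``*_density`` image."""
        import nibabel as nib

        affine = np.diag([*self.spacing, 1.0])
        nib.save(nib.Nifti1Image(self.voxels.astype(np.int16), affine), str(path))
        if self.density is not None:
            p = str(path)
            for suffix in (".nii.gz", ".nii"):
                if p.endswith(suffix):
                    p = p[: -len(suffix)] + "_density" + suffix
                    break
            nib.save(nib.Nifti1Image(self.density.astype(np.float32), affine), p)

    @classmethod
    def from_nifti(cls, path, density_path=None) -> "LabelVolume":
        import nibabel as nib

        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        density = None
        if density_path is not None:
            density = np.asarray(nib.load(str(density_path)).dataobj, dtype=float)
        return cls(np.asarray(img.dataobj).astype(np.int64), spacing, density)

    def save_npz(self, path) -> None:
        """Compact array fixture format: compressed arrays + JSON sidecar."""
        np.savez_compressed(
            path,
            voxels=self.voxels.astype(np.int16),
            **({"density": self.density.astype(np.float32)} if self.density is not None else {}),
        )
        sidecar = str(path) + ".json" if not str(path).endswith(".npz") else str(path)[:-4] + ".json"
        with open(sidecar, "w") as fh:
            json.dump({"spacing": list(self.spacing)}, fh)

    @classmethod
    def load_npz(cls, path) -> "LabelVolume":
        data = np.load(path)
        sidecar = str(path)[:-4] + ".json" if str(path).endswith(".npz") else str(path) + ".json"
        with open(sidecar) as fh:
            meta = json.load(fh)
        density = data["density"] if "density" in data.files else None
        return cls(data["voxels"].astype(np.int64), tuple(meta["spacing"]), density)


def class_volume(volume: LabelVolume, klass: int) -> float:
    """Volume of one class in mm^3: voxel count times single-voxel volume."""
    if klass not in _DECLARED_CLASSES:
        raise UnknownClassError(f"class {klass} not in {_DECLARED_CLASSES}")
    return float(np.count_nonzero(volume.voxels == klass)) * volume.voxel_volume


def thrombus_fraction_volume(volume: LabelVolume) -> float:
    """Volumetric thrombus share of the cavity, V_thr / (V_thr + V_lumen)."""
    v_thr = class_volume(volume, CLASS_THROMBUS)
    v_lum = class_volume(volume, CLASS_LUMEN)
    if v_thr + v_lum == 0:
        raise EmptyCavityError("volume contains no lumen or thrombus voxels")
    return v_thr / (v_thr + v_lum)


def _slice_position_index(labels: np.ndarray, spacing_xy) -> float | None:
    """Eccentricity index of one transverse slice, or None if degenerate."""
    cavity = (labels == CLASS_LUMEN) | (labels == CLASS_THROMBUS)
    lumen = labels == CLASS_LUMEN
    n_cav, n_lum = np.count_nonzero(cavity), np.count_nonzero(lumen)
    if n_cav == 0 or n_lum == 0:
        return None
    sx, sy = spacing_xy
    ix, iy = np.nonzero(cavity)
    c_cav = np.array([ix.mean() * sx, iy.mean() * sy])
    ix, iy = np.nonzero(lumen)
    c_lum = np.array([ix.mean() * sx, iy.mean() * sy])
    # equivalent-circle radii from areas
    r_cav = math.sqrt(n_cav * sx * sy / math.pi)
    r_lum = math.sqrt(n_lum * sx * sy / math.pi)
    denom = r_cav - r_lum
    if denom <= 0:
        return 1.0
    return float(np.clip(np.linalg.norm(c_cav - c_lum) / denom, 0.0, 1.0))


def lumen_position_index(volume_or_slice, spacing=None) -> float:
    """Lumen eccentricity in [0, 1]: 0 concentric, 1 lumen touching the wall.

    Defined as |centroid(lumen) - centroid(cavity)| / (r_cavity - r_lumen)
    with equivalent-circle radii from the class areas, clipped to [0, 1].
    For a 3D volume the per-slice values (transverse slices along the last
    axis) are aggregated by their median.
    """
    if isinstance(volume_or_slice, LabelVolume):
        vol = volume_or_slice
        vals = [
            _slice_position_index(vol.voxels[:, :, k], vol.spacing[:2])
            for k in range(vol.voxels.shape[2])
        ]
        vals = [v for v in vals if v is not None]
        if not vals:
            raise EmptyCavityError("no slice contains both lumen and cavity")
        return float(np.median(vals))
    labels = np.asarray(volume_or_slice)
    sp = (1.0, 1.0) if spacing is None else tuple(spacing)
    val = _slice_position_index(labels, sp)
    if val is None:
        raise EmptyCavityError("slice contains no lumen or cavity voxels")
    return val


def cluster_by_fraction(fractions) -> list[str]:
    """Assign each fraction to its stratification bin.

    Bins are left-closed/right-open, the last closed at 0.99; values outside
    [0.2, 0.99] get the ``out-of-range`` flag.
    """
    labels = []
    for f in np.asarray(fractions, dtype=float):
        label = OUT_OF_RANGE
        for lo, hi in FRACTION_CLUSTERS:
            last = (lo, hi) == FRACTION_CLUSTERS[-1]
            if (lo <= f < hi) or (last and lo <= f <= hi):
                label = f"{lo:.1f}-{hi}"
                break
        labels.append(label)
    return labels


def _midranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    xs = x[order]
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and xs[j + 1] == xs[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    return float(a @ b) / denom


def spearman_rank(x, y, exact_max_n: int = 9) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation with two-sided p-value.

    rho is Pearson's correlation of mid-ranks.  The p-value is an exact
    permutation enumeration for n <= ``exact_max_n`` and the usual
    t-approximation with n-2 degrees of freedom otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise LengthMismatchError("x and y must be 1D of equal length")
    n = len(x)
    if n < 3:
        raise LengthMismatchError("need n >= 3")
    rx, ry = _midranks(x), _midranks(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        raise DegenerateError("constant variable: rank correlation undefined")
    rho = _pearson(rx, ry)
    if n <= exact_max_n:
        count = 0
        total = 0
        target = abs(rho) - 1e-12
        for perm in itertools.permutations(range(n)):
            r = _pearson(rx, ry[list(perm)])
            total += 1
            if abs(r) >= target:
                count += 1
        p = count / total
    else:
        rho_c = min(1.0 - 1e-15, abs(rho))
        t = rho_c * math.sqrt((n - 2) / (1.0 - rho_c * rho_c))
        from scipy.stats import t as t_dist

        p = 2.0 * float(t_dist.sf(t, n - 2))
    return rho, min(1.0, p)


@dataclass
class DensitySummary:
    n_voxels: int
    median: float = math.nan
    mean: float = math.nan
    std: float = math.nan
    histogram: tuple = ()
    bin_edges: tuple = ()

    @property
    def empty(self) -> bool:
        return self.n_voxels == 0


def density_stats(volume: LabelVolume, klass: int = CLASS_THROMBUS, bins: int = 32) -> DensitySummary:
    """Density summary (median, mean, std, histogram) over one class."""
    if volume.density is None:
        raise MissingDensityError("volume has no density channel")
    if klass not in _DECLARED_CLASSES:
        raise UnknownClassError(f"class {klass} not declared")
    vals = volume.density[volume.voxels == klass]
    if vals.size == 0:
        return DensitySummary(n_voxels=0)
    hist, edges = np.histogram(vals, bins=bins)
    return DensitySummary(
        n_voxels=int(vals.size),
        median=float(np.median(vals)),
        mean=float(vals.mean()),
        std=float(vals.std()),
        histogram=tuple(int(h) for h in hist),
        bin_edges=tuple(float(e) for e in edges),
    )


@dataclass
class BoundaryTrack:
    """Outer-wall and lumen-lining contours over one cardiac cycle.

    ``outer``/``lining``: (T, N, 2) closed simple contours (point i connects
    to i+1, last to first), N divisible by 6; ``times``: (T,) seconds.
    """

    outer: np.ndarray
    lining: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        self.outer = np.asarray(self.outer, dtype=float)
        self.lining = np.asarray(self.lining, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        for name, c in (("outer", self.outer), ("lining", self.lining)):
            if c.ndim != 3 or c.shape[2] != 2:
                raise DegenerateContourError(f"{name} must be (T, N, 2)")
            if c.shape[1] < 12 or c.shape[1] % 6:
                raise DegenerateContourError("need N >= 12 points divisible by 6")
        if self.outer.shape[0] != self.lining.shape[0] or self.outer.shape[0] < 2:
            raise DegenerateContourError("need T >= 2 frames on both contours")


def _sector_lengths(contour: np.ndarray, n_sectors: int) -> np.ndarray:
    """Arc length of each of ``n_sectors`` contiguous sectors per frame."""
    seg = np.linalg.norm(np.roll(contour, -1, axis=1) - contour, axis=2)  # (T, N)
    t, n = seg.shape
    per = n // n_sectors
    lengths = seg.reshape(t, n_sectors, per).sum(axis=2)
    if np.any(lengths <= 0):
        raise DegenerateContourError("collapsed sector (zero arc length)")
    return lengths


def circumferential_strain(track: BoundaryTrack, n_sectors: int = 6) -> dict:
    """Per-sector circumferential strain curves and global peaks.

    Sector strain is the relative arc-length change against frame 0,
    ``s_i(t) = (L_i(t) - L_i(0)) / L_i(0)``, expansion positive.  Returns
    inner (lumen lining) and outer (wall) curves, shape (T, n_sectors), and
    their peak absolute values.
    """
    if track.outer.shape[1] % n_sectors or track.lining.shape[1] % n_sectors:
        raise DegenerateContourError("contour points not divisible by sector count")
    out = {}
    for name, contour in (("outer", track.outer), ("inner", track.lining)):
        lengths = _sector_lengths(contour, n_sectors)
        strain = lengths / lengths[0][None, :] - 1.0
        peak_idx = np.unravel_index(np.argmax(np.abs(strain)), strain.shape)
        out[f"{name}_strain"] = strain
        out[f"{name}_peak"] = float(strain[peak_idx])
    out["times"] = track.times
    return out
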