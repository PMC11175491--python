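"""Parametric study over lumen position and thrombus fraction.

``run_sweep`` solves the slice problem on a (position, fraction) grid and
extracts the displacement metrics of the study: the 16 probe values, maximum
displacement of the outer wall and of the thrombus inner lining, the
arc-length-averaged outer-wall displacement, and the maximum equivalent
strain.  ``crossover_fraction`` and ``peak_fraction`` summarise the curves;
``critical_modulus`` and ``minimal_modulus`` perform the wall-stiffness
threshold searches in finite-strain mode, where a Newton collapse marks the
loss of an equilibrium solution.

Geometrically unbuildable records (an offset lumen too large for the cavity)
and solver failures are retained in the result table with ``converged=False``
rather than aborting the sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import elasticity as el
from .errors import (
    AaaIltError,
    BaselineDivergedError,
    InsufficientDataError,
    NonConvergence,
)
from .geometry import POSITIONS, SliceGeometry, geometry_from_fraction, probe_points
from .mesh import Mesh, build_mesh, ring_interpolate

__all__ = [
    "SweepConfig",
    "SweepResult",
    "run_sweep",
    "record_metrics",
    "crossover_fraction",
    "peak_fraction",
    "critical_modulus",
    "minimal_modulus",
]

DEFAULT_FRACTIONS = tuple(round(0.20 + 0.05 * i, 2) for i in range(16)) + (0.99,)


@dataclass(frozen=True)
class SweepConfig:
    """Grid, materials, loads and solver choices for one sweep."""

    positions: tuple = POSITIONS
    fractions: tuple = DEFAULT_FRACTIONS
    wall_material: el.Material = el.Material(1.0e6, 0.45)
    thrombus_material: el.Material = el.Material(1.0e5, 0.45)
    loads: el.LoadCase = el.LoadCase()
    solver_mode: str = "linear"  # "linear" | "finite"
    h_tissue: float = 0.4
    offset_magnitude: float = 2.5
    modulus_decrement: float = 0.01e6  # Pa
    modulus_floor: float = 0.1e6  # Pa
    strain_cap: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if list(self.fractions) != sorted(self.fractions):
            raise AaaIltError("fractions must be sorted ascending")
        if self.modulus_decrement <= 0 or self.modulus_floor <= 0:
            raise AaaIltError("modulus decrement and floor must be positive")
        if self.solver_mode not in ("linear", "finite"):
            raise AaaIltError(f"unknown solver mode {self.solver_mode!r}")

    @property
    def materials(self) -> dict:
        return {"wall": self.wall_material, "thrombus": self.thrombus_material}


@dataclass
class SweepResult:
    """One row per (position, fraction) with the displacement metrics."""

    table: pd.DataFrame
    config: SweepConfig

    def records(self, position: str) -> pd.DataFrame:
        return self.table[self.table["position"] == position]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.12g")


_PROBE_COLS = [f"probe_{kind}_{ang}_{pm}" for kind in ("wall", "lining")
               for ang in (0, 45, 90, 135) for pm in ("p", "m")]

_COLUMNS = (
    ["position", "fraction", "converged", "error", "max_wall_displacement",
     "max_lining_displacement", "mean_wall_displacement", "max_equivalent_strain",
     "contact_force", "n_nodes"]
    + _PROBE_COLS
)


def record_metrics(geometry: SliceGeometry, mesh: Mesh, fld: el.DisplacementField) -> dict:
    """Displacement metrics of one solved record (SI units, metres)."""
    mag = fld.magnitude()
    w = mesh.boundary_arc_weights(mesh.outer_nodes)
    out = {
        "max_wall_displacement": float(mag[mesh.outer_nodes].max()),
        "max_lining_displacement": float(mag[mesh.lining_nodes].max()),
        "mean_wall_displacement": float((mag[mesh.outer_nodes] * w).sum() / w.sum()),
        "max_equivalent_strain": float(el.equivalent_strain(fld).max()),
        "contact_force": float(fld.diagnostics.get("contact_force", 0.0)),
        "n_nodes": mesh.n_nodes,
    }
    probes = probe_points(geometry)
    wall_vals = ring_interpolate(
        mesh.nodes[mesh.outer_nodes], mag[mesh.outer_nodes], probes.wall_points,
        center=np.zeros(2),
    )
    lining_vals = ring_interpolate(
        mesh.nodes[mesh.lining_nodes], mag[mesh.lining_nodes], probes.lining_points,
        center=geometry.lumen_center,
    )
    for col, v in zip(_PROBE_COLS, np.concatenate([wall_vals, lining_vals])):
        out[col] = float(v)
    return out


def _solve_record(config: SweepConfig, position: str, fraction: float):
    geometry = geometry_from_fraction(
        fraction, position, config.offset_magnitude
    )
    mesh = build_mesh(geometry, h_tissue=config.h_tissue)
    if config.solver_mode == "finite":
        fld = el.solve_finite_strain(mesh, config.materials, config.loads, geometry=geometry)
    else:
        fld = el.solve_linear(mesh, config.materials, config.loads, geometry=geometry)
    return geometry, mesh, fld


def run_sweep(config: SweepConfig, progress=None) -> SweepResult:
    """Run the full grid; deterministic for a given config.

    Failed records (unbuildable geometry or solver collapse) are kept with
    ``converged=False`` and the error message in the ``error`` column.
    """
    rows = []
    for position in config.positions:
        for fraction in config.fractions:
            row = {c: np.nan for c in _COLUMNS}
            row.update(position=position, fraction=fraction, converged=False, error="")
            try:
                geometry, mesh, fld = _solve_record(config, position, fraction)
                row.update(record_metrics(geometry, mesh, fld))
                row["converged"] = bool(fld.converged)
            except AaaIltError as exc:
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
            if progress is not None:
                progress(position, fraction, row)
    table = pd.DataFrame(rows, columns=_COLUMNS)
    return SweepResult(table=table, config=config)


def crossover_fraction(result: SweepResult, position: str):
    """Smallest grid fraction where the sign of (max lining - max wall
    displacement) differs from its sign at the smallest converged fraction;
    ``None`` if the ordering never flips."""
    rec = result.records(position)
    rec = rec[rec["converged"]]
    if len(rec) < 2:
        raise InsufficientDataError(f"fewer than 2 converged records for {position!r}")
    diff = (rec["max_lining_displacement"] - rec["max_wall_displacement"]).to_numpy()
    fractions = rec["fraction"].to_numpy()
    ref = np.sign(diff[0])
    flipped = np.nonzero(np.sign(diff) != ref)[0]
    return float(fractions[flipped[0]]) if flipped.size else None


def peak_fraction(result: SweepResult, position: str) -> float:
    """Grid fraction maximising mean wall displacement (ties -> smaller)."""
    rec = result.records(position)
    rec = rec[rec["converged"]]
    if len(rec) < 3:
        raise InsufficientDataError(f"fewer than 3 converged records for {position!r}")
    vals = rec["mean_wall_displacement"].to_numpy()
    fractions = rec["fraction"].to_numpy()
    return float(fractions[int(np.argmax(vals))])  # argmax takes first of ties


def _modulus_grid(e0: float, decrement: float, floor: float) -> np.ndarray:
    n = int(math.floor((e0 - floor) / decrement + 1e-9))
    grid = e0 - decrement * np.arange(n + 1)
    if grid[-1] > floor + 1e-9:
        grid = np.append(grid, floor)
    return grid


def critical_modulus(
    config: SweepConfig,
    position: str,
    fraction: float,
    solver=None,
) -> float:
    """Lowest wall Young's modulus (Pa) on the decrement grid at which the
    finite-strain solve still converges.

    The search walks down from the baseline modulus in ``modulus_decrement``
    steps, warm-starting each solve from the previous equilibrium, and stops
    at the first collapse; the floor is returned if every modulus down to it
    converges.  ``solver`` can replace the FEM call (modulus -> bool) for
    testing the search logic.
    """
    grid = _modulus_grid(config.wall_material.young_modulus, config.modulus_decrement,
                         config.modulus_floor)
    if solver is not None:
        last = None
        for e in grid:
            if not solver(e):
                if last is None:
                    raise BaselineDivergedError(f"baseline modulus {e:g} Pa diverged")
                return last
            last = float(e)
        return last

    geometry = geometry_from_fraction(fraction, position, config.offset_magnitude)
    mesh = build_mesh(geometry, h_tissue=config.h_tissue)
    u0 = None
    last = None
    for e in grid:
        materials = {"wall": replace(config.wall_material, young_modulus=float(e)),
                     "thrombus": config.thrombus_material}
        try:
            fld = el.solve_finite_strain(mesh, materials, config.loads,
                                         geometry=geometry, u0=u0)
        except NonConvergence:
            if last is None:
                raise BaselineDivergedError(
                    f"baseline wall modulus {e:g} Pa diverged at "
                    f"{position!r}, fraction {fraction}"
                ) from None
            return last
        u0 = fld.u
        last = float(e)
    return last


def minimal_modulus(
    config: SweepConfig,
    position: str,
    fraction: float,
    strain_cap: float | None = None,
    solver=None,
) -> float:
    """Lowest wall modulus whose converged solution keeps the maximum
    equivalent strain at or below ``strain_cap``.

    The cap-bound set is a subset of the converged set, so the result is
    always >= :func:`critical_modulus`.  ``solver`` (modulus -> max strain or
    None on collapse) substitutes the FEM for search-logic tests.
    """
    cap = config.strain_cap if strain_cap is None else strain_cap
    if cap <= 0:
        raise AaaIltError("strain cap must be positive")
    grid = _modulus_grid(config.wall_material.young_modulus, config.modulus_decrement,
                         config.modulus_floor)

    if solver is not None:
        last = None
        for e in grid:
            strain = solver(e)
            if strain is None or strain > cap:
                if last is None:
                    raise BaselineDivergedError("baseline modulus exceeds the cap")
                return last
            last = float(e)
        return last

    geometry = geometry_from_fraction(fraction, position, config.offset_magnitude)
    mesh = build_mesh(geometry, h_tissue=config.h_tissue)
    u0 = None
    last = None
    for e in grid:
        materials = {"wall": replace(config.wall_material, young_modulus=float(e)),
                     "thrombus": config.thrombus_material}
        try:
            fld = el.solve_finite_strain(mesh, materials, config.loads,
                                         geometry=geometry, u0=u0)
        except NonConvergence:
            fld = None
        if fld is None or float(el.equivalent_strain(fld).max()) > cap:
            if last is None:
                raise BaselineDivergedError(
                    f"baseline wall modulus at {position!r}, fraction {fraction} "
                    "exceeds the strain cap or diverges"
                )
            return last
        u0 = fld.u
        last = float(e)
    return last
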