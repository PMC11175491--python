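"""The headline parametric study at the default (base-case) conditions.

Bundles the runs behind the study's summary figures so scripts and tests
execute exactly the same computation: the position x fraction displacement
sweep at the default materials (wall E = 1.0 MPa, thrombus E = 0.1 MPa,
nu = 0.45 both, 100/6 mmHg, h = 0.4 mm) and the wall-stiffness threshold
search at the smallest sweep fraction.
"""

from __future__ import annotations

from .sweep import (
    SweepConfig,
    SweepResult,
    critical_modulus,
    crossover_fraction,
    peak_fraction,
    run_sweep,
)

__all__ = ["STUDY_FRACTIONS", "study_config", "study_sweep", "study_summary",
           "critical_threshold"]

#: The sweep grid of the displacement study: 20%..95% in 5% steps.
STUDY_FRACTIONS = tuple(round(0.20 + 0.05 * i, 2) for i in range(16))


def study_config(h_tissue: float = 0.4, solver_mode: str = "linear",
                 seed: int = 0) -> SweepConfig:
    return SweepConfig(fractions=STUDY_FRACTIONS, h_tissue=h_tissue,
                       solver_mode=solver_mode, seed=seed)


def study_sweep(config: SweepConfig | None = None, progress=None) -> SweepResult:
    return run_sweep(config or study_config(), progress=progress)


def study_summary(result: SweepResult) -> dict:
    """Crossover, mean-displacement span and peak locations per position."""
    out = {}
    central = result.records("center")
    central = central[central["converged"]]
    mean_wall = central["mean_wall_displacement"].to_numpy()
    first = mean_wall[0]
    out["central_crossover_fraction"] = crossover_fraction(result, "center")
    out["central_mean_wall_decrease_pct"] = float(100.0 * (mean_wall.max() - mean_wall.min()) / first)
    out["central_mean_wall_ref_mm"] = float(first * 1e3)
    for pos in result.config.positions:
        if pos == "center":
            continue
        try:
            out[f"{pos}_peak_fraction"] = peak_fraction(result, pos)
            out[f"{pos}_crossover_fraction"] = crossover_fraction(result, pos)
        except Exception as exc:
            out[f"{pos}_error"] = str(exc)
    return out


def critical_threshold(position: str = "center", fraction: float = 0.20,
                       h_tissue: float = 0.4, seed: int = 0) -> float:
    """Critical wall modulus (Pa) at the stated configuration: 0.01 MPa
    decrements from 1.0 MPa with a 0.1 MPa floor, finite-strain solves."""
    return critical_modulus(study_config(h_tissue=h_tissue, seed=seed),
                            position, fraction)
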