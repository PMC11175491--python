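"""Run configuration: validated YAML blocks with materialized defaults.

The configuration mirrors the pipeline stages (geometry, materials, loads,
sweep, imaging, synthdata).  Unknown keys are rejected; the resolved
configuration (all defaults filled in) is persisted next to every output so
a run can be reproduced from its own artifacts.  The JSON schema is
published in-repo (``docs/run_config.schema.json``) and can be regenerated
with :func:`json_schema`.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from . import elasticity as el
from .errors import ConfigError
from .geometry import POSITIONS
from .sweep import DEFAULT_FRACTIONS, SweepConfig
from .synthdata import CohortSpec

__all__ = ["RunConfig", "json_schema"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class GeometryBlock(_Block):
    wall_outer_radius_mm: float = 25.0
    wall_thickness_mm: float = 2.0
    offset_magnitude_mm: float = 2.5
    spine_radius_mm: float = 15.0
    spine_gap_mm: float = 0.0


class MaterialsBlock(_Block):
    wall_young_modulus_pa: float = 1.0e6
    thrombus_young_modulus_pa: float = 1.0e5
    wall_poisson_ratio: float = 0.45
    thrombus_poisson_ratio: float = 0.45


class LoadsBlock(_Block):
    lumen_pressure_mmhg: float = 100.0
    external_pressure_mmhg: float = 6.0
    spine_contact: str = "penalty"
    penalty_stiffness_pa_per_m: float = 1.0e12
    load_steps: int = 5


class SweepBlock(_Block):
    positions: tuple = POSITIONS
    fractions: tuple = DEFAULT_FRACTIONS
    solver_mode: str = "linear"
    h_tissue_mm: float = 0.4
    modulus_decrement_mpa: float = 0.01
    modulus_floor_mpa: float = 0.1
    strain_cap: float = 0.2


class ImagingBlock(_Block):
    density_bins: int = 32
    exact_p_max_n: int = 9


class SynthdataBlock(_Block):
    n_subjects: int = 21
    fraction_low: float = 0.2
    fraction_high: float = 0.99
    us_noise_sd: float = 0.05
    ct_noise_sd: float = 0.02
    density_cluster_means: tuple[float, float] = (60.0, 120.0)
    density_cluster_sds: tuple[float, float] = (8.0, 16.0)
    volume_slices: int = 4
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 2.0)


class RunConfig(_Block):
    geometry: GeometryBlock = GeometryBlock()
    materials: MaterialsBlock = MaterialsBlock()
    loads: LoadsBlock = LoadsBlock()
    sweep: SweepBlock = SweepBlock()
    imaging: ImagingBlock = ImagingBlock()
    synthdata: SynthdataBlock = SynthdataBlock()
    output_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(**raw)
        except ValidationError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path) -> None:
        """Persist with every default materialized."""
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(self.model_dump_json()), fh, sort_keys=False)

    # -- builders -----------------------------------------------------------

    def load_case(self) -> el.LoadCase:
        lb = self.loads
        return el.LoadCase(
            lumen_pressure=lb.lumen_pressure_mmhg * el.MMHG_PA,
            external_pressure=lb.external_pressure_mmhg * el.MMHG_PA,
            spine_contact=lb.spine_contact,
            penalty_stiffness=lb.penalty_stiffness_pa_per_m,
            load_steps=lb.load_steps,
        )

    def material_dict(self) -> dict:
        mb = self.materials
        return {
            "wall": el.Material(mb.wall_young_modulus_pa, mb.wall_poisson_ratio),
            "thrombus": el.Material(mb.thrombus_young_modulus_pa, mb.thrombus_poisson_ratio),
        }

    def sweep_config(self) -> SweepConfig:
        sb, mats = self.sweep, self.material_dict()
        return SweepConfig(
            positions=tuple(sb.positions),
            fractions=tuple(sb.fractions),
            wall_material=mats["wall"],
            thrombus_material=mats["thrombus"],
            loads=self.load_case(),
            solver_mode=sb.solver_mode,
            h_tissue=sb.h_tissue_mm,
            offset_magnitude=self.geometry.offset_magnitude_mm,
            modulus_decrement=sb.modulus_decrement_mpa * 1.0e6,
            modulus_floor=sb.modulus_floor_mpa * 1.0e6,
            strain_cap=sb.strain_cap,
            seed=self.seed,
        )

    def cohort_spec(self) -> CohortSpec:
        nb = self.synthdata
        return CohortSpec(
            n_subjects=nb.n_subjects,
            fraction_range=(nb.fraction_low, nb.fraction_high),
            us_noise_sd=nb.us_noise_sd,
            ct_noise_sd=nb.ct_noise_sd,
            density_clusters=tuple(
                (m, s) for m, s in zip(nb.density_cluster_means, nb.density_cluster_sds)
            ),
            seed=self.seed,
        )


def json_schema() -> dict:
    return RunConfig.model_json_schema()


def write_schema(path) -> None:
    Path(path).write_text(json.dumps(json_schema(), indent=1) + "\n")
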