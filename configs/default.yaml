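# Default study configuration: the base-case slice and sweep conditions.
# Every key shown here is the built-in default; the resolved copy of this
# file is persisted next to every run's outputs.

geometry:
  wall_outer_radius_mm: 25.0     # outer wall radius (50 mm diameter)
  wall_thickness_mm: 2.0
  offset_magnitude_mm: 2.5       # lumen shift for the non-central positions
  spine_radius_mm: 15.0          # rigid circle tangent to the posterior wall
  spine_gap_mm: 0.0

materials:
  wall_young_modulus_pa: 1.0e6   # within published AAA-wall ranges
  thrombus_young_modulus_pa: 1.0e5
  wall_poisson_ratio: 0.45       # near-incompressible soft tissue
  thrombus_poisson_ratio: 0.45

loads:
  lumen_pressure_mmhg: 100.0     # on the thrombus inner lining
  external_pressure_mmhg: 6.0    # intra-abdominal, on the outer surface
  spine_contact: penalty         # none | penalty | clamp
  penalty_stiffness_pa_per_m: 1.0e12
  load_steps: 5                  # finite-strain ramp

sweep:
  positions: [center, anterior, posterior_spine, left, right]
  fractions: [0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50, 0.55,
              0.60, 0.65, 0.70, 0.75, 0.80, 0.85, 0.90, 0.95, 0.99]
  solver_mode: linear            # linear | finite
  h_tissue_mm: 0.4               # tissue cell size (spine needs no mesh)
  modulus_decrement_mpa: 0.01    # threshold-search step
  modulus_floor_mpa: 0.1         # below this the search stops
  strain_cap: 0.2                # minimal-modulus equivalent-strain cap

imaging:
  density_bins: 32
  exact_p_max_n: 9               # exact permutation p-value up to this n

synthdata:
  n_subjects: 21
  fraction_low: 0.2
  fraction_high: 0.99
  us_noise_sd: 0.05              # US fraction disagreement (fraction scale)
  ct_noise_sd: 0.02
  density_cluster_means: [60.0, 120.0]   # HU-like, 2x ratio cohort clusters
  density_cluster_sds: [8.0, 16.0]
  volume_slices: 4
  voxel_spacing_mm: [1.0, 1.0, 2.0]

output_dir: results
seed: 0
log_level: INFO
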