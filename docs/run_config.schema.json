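{
 "$defs": {
  "GeometryBlock": {
   "additionalProperties": false,
   "properties": {
    "wall_outer_radius_mm": {
     "default": 25.0,
     "title": "Wall Outer Radius Mm",
     "type": "number"
    },
    "wall_thickness_mm": {
     "default": 2.0,
     "title": "Wall Thickness Mm",
     "type": "number"
    },
    "offset_magnitude_mm": {
     "default": 2.5,
     "title": "Offset Magnitude Mm",
     "type": "number"
    },
    "spine_radius_mm": {
     "default": 15.0,
     "title": "Spine Radius Mm",
     "type": "number"
    },
    "spine_gap_mm": {
     "default": 0.0,
     "title": "Spine Gap Mm",
     "type": "number"
    }
   },
   "title": "GeometryBlock",
   "type": "object"
  },
  "ImagingBlock": {
   "additionalProperties": false,
   "properties": {
    "density_bins": {
     "default": 32,
     "title": "Density Bins",
     "type": "integer"
    },
    "exact_p_max_n": {
     "default": 9,
     "title": "Exact P Max N",
     "type": "integer"
    }
   },
   "title": "ImagingBlock",
   "type": "object"
  },
  "LoadsBlock": {
   "additionalProperties": false,
   "properties": {
    "lumen_pressure_mmhg": {
     "default": 100.0,
     "title": "Lumen Pressure Mmhg",
     "type": "number"
    },
    "external_pressure_mmhg": {
     "default": 6.0,
     "title": "External Pressure Mmhg",
     "type": "number"
    },
    "spine_contact": {
     "default": "penalty",
     "title": "Spine Contact",
     "type": "string"
    },
    "penalty_stiffness_pa_per_m": {
     "default": 1000000000000.0,
     "title": "Penalty Stiffness Pa Per M",
     "type": "number"
    },
    "load_steps": {
     "default": 5,
     "title": "Load Steps",
     "type": "integer"
    }
   },
   "title": "LoadsBlock",
   "type": "object"
  },
  "MaterialsBlock": {
   "additionalProperties": false,
   "properties": {
    "wall_young_modulus_pa": {
     "default": 1000000.0,
     "title": "Wall Young Modulus Pa",
     "type": "number"
    },
    "thrombus_young_modulus_pa": {
     "default": 100000.0,
     "title": "Thrombus Young Modulus Pa",
     "type": "number"
    },
    "wall_poisson_ratio": {
     "default": 0.45,
     "title": "Wall Poisson Ratio",
     "type": "number"
    },
    "thrombus_poisson_ratio": {
     "default": 0.45,
     "title": "Thrombus Poisson Ratio",
     "type": "number"
    }
   },
   "title": "MaterialsBlock",
   "type": "object"
  },
  "SweepBlock": {
   "additionalProperties": false,
   "properties": {
    "positions": {
     "default": [
      "center",
      "anterior",
      "posterior_spine",
      "left",
      "right"
     ],
     "items": {},
     "title": "Positions",
     "type": "array"
    },
    "fractions": {
     "default": [
      0.2,
      0.25,
      0.3,
      0.35,
      0.4,
      0.45,
      0.5,
      0.55,
      0.6,
      0.65,
      0.7,
      0.75,
      0.8,
      0.85,
      0.9,
      0.95,
      0.99
     ],
     "items": {},
     "title": "Fractions",
     "type": "array"
    },
    "solver_mode": {
     "default": "linear",
     "title": "Solver Mode",
     "type": "string"
    },
    "h_tissue_mm": {
     "default": 0.4,
     "title": "H Tissue Mm",
     "type": "number"
    },
    "modulus_decrement_mpa": {
     "default": 0.01,
     "title": "Modulus Decrement Mpa",
     "type": "number"
    },
    "modulus_floor_mpa": {
     "default": 0.1,
     "title": "Modulus Floor Mpa",
     "type": "number"
    },
    "strain_cap": {
     "default": 0.2,
     "title": "Strain Cap",
     "type": "number"
    }
   },
   "title": "SweepBlock",
   "type": "object"
  },
  "SynthdataBlock": {
   "additionalProperties": false,
   "properties": {
    "n_subjects": {
     "default": 21,
     "title": "N Subjects",
     "type": "integer"
    },
    "fraction_low": {
     "default": 0.2,
     "title": "Fraction Low",
     "type": "number"
    },
    "fraction_high": {
     "default": 0.99,
     "title": "Fraction High",
     "type": "number"
    },
    "us_noise_sd": {
     "default": 0.05,
     "title": "Us Noise Sd",
     "type": "number"
    },
    "ct_noise_sd": {
     "default": 0.02,
     "title": "Ct Noise Sd",
     "type": "number"
    },
    "density_cluster_means": {
     "default": [
      60.0,
      120.0
     ],
     "maxItems": 2,
     "minItems": 2,
     "prefixItems": [
      {
       "type": "number"
      },
      {
       "type": "number"
      }
     ],
     "title": "Density Cluster Means",
     "type": "array"
    },
    "density_cluster_sds": {
     "default": [
      8.0,
      16.0
     ],
     "maxItems": 2,
     "minItems": 2,
     "prefixItems": [
      {
       "type": "number"
      },
      {
       "type": "number"
      }
     ],
     "title": "Density Cluster Sds",
     "type": "array"
    },
    "volume_slices": {
     "default": 4,
     "title": "Volume Slices",
     "type": "integer"
    },
    "voxel_spacing_mm": {
     "default": [
      1.0,
      1.0,
      2.0
     ],
     "maxItems": 3,
     "minItems": 3,
     "prefixItems": [
      {
       "type": "number"
      },
      {
       "type": "number"
      },
      {
       "type": "number"
      }
     ],
     "title": "Voxel Spacing Mm",
     "type": "array"
    }
   },
   "title": "SynthdataBlock",
   "type": "object"
  }
 },
 "additionalProperties": false,
 "properties": {
  "geometry": {
   "$ref": "#/$defs/GeometryBlock",
   "default": {
    "wall_outer_radius_mm": 25.0,
    "wall_thickness_mm": 2.0,
    "offset_magnitude_mm": 2.5,
    "spine_radius_mm": 15.0,
    "spine_gap_mm": 0.0
   }
  },
  "materials": {
   "$ref": "#/$defs/MaterialsBlock",
   "default": {
    "wall_young_modulus_pa": 1000000.0,
    "thrombus_young_modulus_pa": 100000.0,
    "wall_poisson_ratio": 0.45,
    "thrombus_poisson_ratio": 0.45
   }
  },
  "loads": {
   "$ref": "#/$defs/LoadsBlock",
   "default": {
    "lumen_pressure_mmhg": 100.0,
    "external_pressure_mmhg": 6.0,
    "spine_contact": "penalty",
    "penalty_stiffness_pa_per_m": 1000000000000.0,
    "load_steps": 5
   }
  },
  "sweep": {
   "$ref": "#/$defs/SweepBlock",
   "default": {
    "positions": [
     "center",
     "anterior",
     "posterior_spine",
     "left",
     "right"
    ],
    "fractions": [
     0.2,
     0.25,
     0.3,
     0.35,
     0.4,
     0.45,
     0.5,
     0.55,
     0.6,
     0.65,
     0.7,
     0.75,
     0.8,
     0.85,
     0.9,
     0.95,
     0.99
    ],
    "solver_mode": "linear",
    "h_tissue_mm": 0.4,
    "modulus_decrement_mpa": 0.01,
    "modulus_floor_mpa": 0.1,
    "strain_cap": 0.2
   }
  },
  "imaging": {
   "$ref": "#/$defs/ImagingBlock",
   "default": {
    "density_bins": 32,
    "exact_p_max_n": 9
   }
  },
  "synthdata": {
   "$ref": "#/$defs/SynthdataBlock",
   "default": {
    "n_subjects": 21,
    "fraction_low": 0.2,
    "fraction_high": 0.99,
    "us_noise_sd": 0.05,
    "ct_noise_sd": 0.02,
    "density_cluster_means": [
     60.0,
     120.0
    ],
    "density_cluster_sds": [
     8.0,
     16.0
    ],
    "volume_slices": 4,
    "voxel_spacing_mm": [
     1.0,
     1.0,
     2.0
    ]
   }
  },
  "output_dir": {
   "default": "results",
   "title": "Output Dir",
   "type": "string"
  },
  "seed": {
   "default": 0,
   "title": "Seed",
   "type": "integer"
  },
  "log_level": {
   "default": "INFO",
   "title": "Log Level",
   "type": "string"
  }
 },
 "title": "RunConfig",
 "type": "object"
}
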