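{
  "distribution": {
    "area": [
      0.07,
      0.36,
      0.14,
      0.31,
      0.05,
      0.07
    ],
    "volume": [
      0.07,
      0.5,
      0.13,
      0.26,
      0.01,
      0.03
    ],
    "basal_met": [
      0.16,
      0.56,
      0.1,
      0.15,
      0.015,
      0.015
    ],
    "basal_skin_flow": [
      0.12,
      0.4,
      0.13,
      0.23,
      0.06,
      0.06
    ]
  },
  "geometry": {
    "skin_thickness_m": [
      0.002,
      0.002,
      0.0018,
      0.0018,
      0.0015,
      0.0015
    ],
    "muscle_interior_fraction": [
      0.15,
      0.45,
      0.6,
      0.6,
      0.3,
      0.3
    ],
    "min_shell_thickness_m": 0.0001
  },
  "tissue": {
    "conductivity": {
      "core": 0.54,
      "muscle": 0.42,
      "fat": 0.21,
      "skin": 0.34
    },
    "specific_heat": 3500.0,
    "fat_density": 900.0,
    "lean_density": 1100.0,
    "blood_specific_heat": 3850.0,
    "blood_density": 1060.0,
    "blood_volume_L_per_kg": 0.07,
    "latent_heat_vaporisation": 2426.0,
    "q10": 2.0
  },
  "basal": {
    "met_W_per_m2": 45.8,
    "skin_blood_flow_total_L_h": 11.0,
    "perfusion_W_per_K_per_W": 3.0,
    "met_node_split": {
      "core": 0.8,
      "muscle": 0.14,
      "fat": 0.01,
      "skin": 0.05
    }
  },
  "controller": {
    "setpoint_core": 37.0,
    "setpoint_skin": 33.0,
    "skin_weights": [
      0.07,
      0.36,
      0.14,
      0.31,
      0.05,
      0.07
    ],
    "core_weights": [
      0.15,
      0.85,
      0.0,
      0.0,
      0.0,
      0.0
    ],
    "shiver_gain_core": 0.0,
    "shiver_gain_skin": 41.5,
    "shiver_gain_product": 3.0,
    "shiver_cap_multiple_basal": 4.5,
    "constrict_gain_core": 1.5,
    "constrict_gain_skin": 0.25,
    "constrict_segment_factor": [
      0.3,
      0.5,
      1.0,
      1.0,
      2.5,
      2.5
    ],
    "interior_constrict_factor": [
      0.0,
      0.0,
      0.5,
      0.5,
      6.0,
      6.0
    ],
    "dilate_gain_L_h_per_K": 2.0,
    "dilate_core_weight": 3.0,
    "min_skin_flow_L_h": [
      0.5,
      1.0,
      0.3,
      0.4,
      0.02,
      0.02
    ],
    "max_skin_flow_L_h": [
      10.0,
      35.0,
      15.0,
      25.0,
      8.0,
      8.0
    ],
    "sweat_gain_skin": 0.0,
    "sweat_gain_product": 80.0,
    "max_sweat_g_min": 25.0,
    "wettedness_floor": 0.06,
    "shiver_skin_saturation_C": 6.0,
    "shiver_peak_core_C": 36.5,
    "shiver_fail_core_C": 32.0,
    "water_shiver_cap_multiple_basal": 1.2
  },
  "boundary": {
    "radiative_coeff": 4.7,
    "convective_coeff": 8.3,
    "convective_exponent": 0.6,
    "min_wind_speed": 0.15,
    "min_resistance": 0.012,
    "segment_film_factor": [
      1.1,
      1.0,
      1.0,
      1.0,
      1.2,
      1.2
    ],
    "lewis_ratio": 0.0165,
    "water_film_coeff": 100.0,
    "wet_insulation_factor": 0.8
  },
  "respiration": {
    "dry_coeff": 0.0014,
    "latent_coeff": 0.0173,
    "ref_temp": 34.0,
    "ref_vp_kPa": 5.87
  },
  "activity": {
    "rest": 105.0,
    "light": 250.0,
    "moderate": 400.0,
    "heavy": 600.0
  },
  "activity_muscle_split": [
    0.0,
    0.2,
    0.15,
    0.65,
    0.0,
    0.0
  ],
  "thresholds": {
    "hypothermia_core": 36.0,
    "extremity_frostbite_risk": 5.0,
    "comfort_wettedness": 0.5,
    "manual_performance_hand": 15.0,
    "survival_core": 28.0,
    "dehydration_fraction": 0.05
  },
  "initial_state": {
    "temperatures": [
      [
        37.0338,
        36.4192,
        35.4161,
        34.6119
      ],
      [
        36.999,
        36.6732,
        35.5138,
        34.9563
      ],
      [
        37.0034,
        36.4807,
        35.098,
        34.5376
      ],
      [
        36.9933,
        36.6312,
        35.2837,
        34.7291
      ],
      [
        35.6647,
        35.1286,
        34.7431,
        34.4027
      ],
      [
        35.4842,
        34.5705,
        33.9551,
        33.5323
      ]
    ],
    "blood": 36.7459
  },
  "wct_bands": {
    "none_above": -28.0,
    "thirty_above": -46.0,
    "ten_above": -55.0
  },
  "simulation": {
    "default_timestep_s": 30.0,
    "max_horizon_h": 72.0
  }
}
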