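# Default synthetic mediastinal study.
#
# Geometry is in mm with the isocenter at the grid centre; x = patient left,
# y = posterior (anterior body surface at negative y), z = superior.  The
# heart (with a left-atrium-like substructure and a deliberately sub-0.1 cc
# coronary-artery-like structure) sits posterior to the CTV, i.e. at the
# distal edge of the anterior fields.

seed: 0

grid:
  shape: [160, 120, 48]
  spacing_mm: [2.0, 2.0, 2.0]

phantom:
  body:         {center: [0, 0, 0],    semi_axes: [150, 95, 400]}
  ctv:          {center: [0, -30, 0],  semi_axes: [35, 25, 38]}
  heart:        {center: [15, 18, -4], semi_axes: [45, 40, 42]}
  left_atrium:  {center: [8, -2, 4],   semi_axes: [16, 12, 14]}
  lmca:         {center: [26, 6, 8],   semi_axes: [2.5, 2.5, 3.0]}
  lung_left:    {center: [88, 5, 0],   semi_axes: [48, 70, 400]}
  lung_right:   {center: [-88, 5, 0],  semi_axes: [48, 70, 400]}
  spinal_cord:  {center: [0, 78],      radius: 6}
  esophagus:    {center: [4, 52],      radius: 5}

beam_model:
  plateau_dose: 0.36          # entrance dose relative to the Bragg peak
  peak_width_mm: 6.0
  straggling_sigma_mm: 3.0
  let_plateau_kevum: 1.2
  let_scale_kevum_mm: 20.0
  let_softening_mm: 2.0
  let_cap_kevum: 15.0

planning:
  layer_spacing_mm: 3.0
  range_margin_mm: 3.0
  aperture_margin_mm: 12.0
  penumbra_sigma_mm: 5.0

prescription:
  total_dose_gy: 19.8
  n_fractions: 11

plans:
  - {name: 1F,      angles: [0]}
  - {name: 2F,      angles: [10, 350]}
  - {name: 2F-wide, angles: [30, 330]}
  - {name: 3F,      angles: [10, 350, 180]}

rbe:
  alpha_beta_gy: [2.0, 3.0, 10.0]
  fixed_rbe: 1.1
  # McNamara coefficients; overridable (c1/c2 for RBEmax, c3/c4 for RBEmin)
  coefficients: {c1: 0.99064, c2: 0.35605, c3: 1.1012, c4: 0.0038703}

metrics:
  dose_threshold_fraction: 0.05    # LET/vRBE evaluable where dose >= 5% of max
  overlap_dose_fraction: 0.8
  overlap_let_kevum: 6.0
  delta_dose_threshold_gy_rbe: 3.0
  v_dose_levels_gy: [5.0, 10.0]
  hot_volume_cc: 0.1
  dvh_bins: 200
  structures: [body, ctv, heart, left_atrium, lmca, lung_left, lung_right, spinal_cord, esophagus]

sensitivity:
  plan: 2F
  structure: left_atrium          # distal-edge OAR for the alpha/beta DVH spread

normalization:
  ctv_statistic: median           # composite CTV median dose = prescription
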