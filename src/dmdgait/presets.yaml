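# Group presets for the synthetic gait-signal generator, version 1.
#
# Per activity and group: mean/SD of cadence (steps/s), step length as a
# fraction of standing height, per-axis shares of total signal power
# (vertical, mediolateral, anteroposterior), and base acceleration
# amplitude (m/s^2).  Cadence, step length, and axial shares are anchored
# cell-by-cell to the published DMD/TD cohort summaries for these eight
# activities; amplitudes are plausible waist-level accelerations that
# grow with gait speed, with the between-group amplitude ratio anchored
# to the published total-power ratios.
#
# Course definitions: the five speed-calibration efforts are a 25 m
# course, the six-minute walk is duration-fixed at 360 s, the 100 m
# effort is distance-fixed, and the free walk is modeled as 60 s.
version: 1
noise_sd: 0.1           # m/s^2, within-subject additive sensor/soft-tissue noise
harmonics: 3
activities:
  SC-L1:
    course: {distance_m: 25.0}
    TD:
      cadence: [1.29, 0.19]
      sl_fraction: [0.27, 0.02]
      vp: [0.2845, 0.0407]
      mp: [0.3624, 0.0722]
      ap: [0.3531, 0.0545]
      amp: [1.0, 0.2]
    DMD:
      cadence: [1.12, 0.32]
      sl_fraction: [0.23, 0.04]
      vp: [0.2782, 0.0548]
      mp: [0.4210, 0.0617]
      ap: [0.3008, 0.0436]
      amp: [0.98, 0.25]
  SC-L2:
    course: {distance_m: 25.0}
    TD:
      cadence: [1.62, 0.16]
      sl_fraction: [0.34, 0.02]
      vp: [0.3148, 0.0778]
      mp: [0.3429, 0.0840]
      ap: [0.3423, 0.0563]
      amp: [1.5, 0.3]
    DMD:
      cadence: [1.58, 0.31]
      sl_fraction: [0.29, 0.03]
      vp: [0.2825, 0.0620]
      mp: [0.4016, 0.0680]
      ap: [0.3159, 0.0663]
      amp: [1.57, 0.35]
  SC-L3:
    course: {distance_m: 25.0}
    TD:
      cadence: [1.89, 0.23]
      sl_fraction: [0.40, 0.02]
      vp: [0.3693, 0.1022]
      mp: [0.3136, 0.0790]
      ap: [0.3170, 0.0572]
      amp: [2.0, 0.4]
    DMD:
      cadence: [1.89, 0.24]
      sl_fraction: [0.33, 0.03]
      vp: [0.3016, 0.0598]
      mp: [0.3932, 0.0748]
      ap: [0.3052, 0.0579]
      amp: [1.94, 0.45]
  SC-L4:
    course: {distance_m: 25.0}
    TD:
      cadence: [2.55, 0.32]
      sl_fraction: [0.50, 0.04]
      vp: [0.3892, 0.0875]
      mp: [0.3094, 0.0873]
      ap: [0.3014, 0.0584]
      amp: [3.0, 0.6]
    DMD:
      cadence: [2.40, 0.51]
      sl_fraction: [0.39, 0.06]
      vp: [0.2907, 0.1071]
      mp: [0.4011, 0.0929]
      ap: [0.3083, 0.0386]
      amp: [2.92, 0.7]
  SC-L5:
    course: {distance_m: 25.0}
    TD:
      cadence: [3.61, 0.52]
      sl_fraction: [0.67, 0.09]
      vp: [0.5013, 0.0893]
      mp: [0.2153, 0.1008]
      ap: [0.2834, 0.1009]
      amp: [5.0, 1.0]
    DMD:
      cadence: [2.82, 0.73]
      sl_fraction: [0.42, 0.07]
      vp: [0.3567, 0.1368]
      mp: [0.3501, 0.1086]
      ap: [0.2932, 0.0918]
      amp: [3.39, 0.9]
  6MWT:
    course: {duration_s: 360.0}
    TD:
      cadence: [2.36, 0.17]
      sl_fraction: [0.50, 0.03]
      vp: [0.4168, 0.1107]
      mp: [0.2951, 0.0901]
      ap: [0.2881, 0.0671]
      amp: [2.5, 0.5]
    DMD:
      cadence: [2.05, 0.39]
      sl_fraction: [0.38, 0.06]
      vp: [0.3161, 0.0602]
      mp: [0.3879, 0.0693]
      ap: [0.2960, 0.0546]
      amp: [2.02, 0.5]
  100MRW:
    course: {distance_m: 100.0}
    TD:
      cadence: [3.39, 0.47]
      sl_fraction: [0.67, 0.08]
      vp: [0.5289, 0.0886]
      mp: [0.1805, 0.0936]
      ap: [0.2906, 0.1053]
      amp: [4.5, 0.9]
    DMD:
      cadence: [2.57, 0.67]
      sl_fraction: [0.42, 0.07]
      vp: [0.3968, 0.1719]
      mp: [0.3482, 0.1228]
      ap: [0.2551, 0.0758]
      amp: [2.66, 0.7]
  FW:
    course: {duration_s: 60.0}
    TD:
      cadence: [1.96, 0.29]
      sl_fraction: [0.42, 0.04]
      vp: [0.4138, 0.0892]
      mp: [0.2846, 0.0749]
      ap: [0.3017, 0.0487]
      amp: [2.0, 0.4]
    DMD:
      cadence: [1.83, 0.42]
      sl_fraction: [0.33, 0.06]
      vp: [0.3287, 0.0851]
      mp: [0.3647, 0.0699]
      ap: [0.3066, 0.0719]
      amp: [1.85, 0.45]
# Anthropometrics drawn uniformly from the published cohort min-max ranges.
anthropometrics:
  TD:
    age: [4.0, 15.0]
    height_m: [1.085, 1.655]
    weight_kg: [18.6, 101.0]
    nsaa: [31, 34]
  DMD:
    age: [3.0, 16.0]
    height_m: [1.016, 1.533]
    weight_kg: [17.2, 67.7]
    nsaa: [8, 34]
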