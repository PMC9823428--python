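# Default synthetic-trial conditions: a two-arm web-based weight-loss RCT
# in German adults with overweight/obesity (BMI 27.5-34.9), four
# measurement occasions (baseline, 3 months, +6 months, +12 months),
# n = 153 with ~22.9% cumulative dropout.
#
# Component-score trajectories (means/SDs) follow the published per-arm
# descriptive statistics of the trial being emulated; anthropometric and
# cardiometabolic trajectories not printed there are realistic values for
# such a cohort, chosen once and documented in docs/methods.md.
#
# means: [t0, t1, t2, t3] per arm.  sd: baseline cross-sectional SD.
# icc: within-subject correlation share; change-score SD = sqrt(2*(1-icc))*sd.

design:
  n_total: 153
  block_sizes: [4, 6]
  dropout_cumulative: 0.229
  dropout_beta_control: 0.2     # log-odds shift for the control arm
  dropout_beta_bmi: 0.25        # log-odds shift per SD of baseline BMI

components:
  vegetables:
    max_points: 15
    intervention: [6.24, 7.71, 7.36, 7.60]
    control: [6.15, 6.67, 5.72, 6.57]
    sd: 3.41
    icc: 0.45
  fruits:
    max_points: 15
    intervention: [7.95, 7.89, 7.75, 7.34]
    control: [7.31, 7.20, 6.42, 6.77]
    sd: 4.37
    icc: 0.45
  grains:
    max_points: 10
    intervention: [6.67, 6.42, 6.98, 6.56]
    control: [6.71, 6.35, 7.00, 6.84]
    sd: 2.35
    icc: 0.45
  dairy:
    max_points: 10
    intervention: [7.08, 6.80, 7.14, 7.01]
    control: [7.15, 7.33, 7.27, 7.14]
    sd: 2.15
    icc: 0.45
  fish:
    max_points: 10
    intervention: [3.29, 3.87, 4.07, 4.15]
    control: [4.31, 3.18, 3.52, 3.13]
    sd: 3.90
    icc: 0.45
  beverages:
    max_points: 10
    intervention: [8.93, 8.97, 8.87, 8.75]
    control: [8.19, 8.10, 8.24, 8.22]
    sd: 2.08
    icc: 0.45
  eggs:
    max_points: 10
    intervention: [8.79, 8.91, 8.89, 8.84]
    control: [8.72, 8.31, 8.90, 8.62]
    sd: 1.92
    icc: 0.45
  spreadable_fats:
    max_points: 10
    intervention: [9.83, 9.92, 9.94, 9.95]
    control: [9.76, 9.91, 9.93, 9.90]
    sd: 0.82
    icc: 0.45
  alcohol:
    max_points: 10
    intervention: [9.23, 9.29, 9.57, 9.45]
    control: [9.04, 9.11, 9.30, 9.18]
    sd: 1.79
    icc: 0.45
  meat:
    max_points: 10
    intervention: [7.96, 8.52, 8.85, 8.15]
    control: [7.95, 8.13, 8.08, 7.83]
    sd: 2.43
    icc: 0.45

variables:
  energy_density:               # kcal/g, beverages excluded
    intervention: [1.65, 1.45, 1.48, 1.50]
    control: [1.63, 1.58, 1.57, 1.58]
    sd: 0.33
    icc: 0.50
    lower: 0.8
    upper: 3.2
  energy_intake:                # kcal/day
    intervention: [2100.0, 1850.0, 1900.0, 1950.0]
    control: [2080.0, 2000.0, 2010.0, 2020.0]
    sd: 420.0
    icc: 0.60
    lower: 1100.0
    upper: 4200.0
  body_weight:                  # kg
    intervention: [88.42, 86.30, 86.10, 86.60]
    control: [88.36, 87.40, 87.30, 87.70]
    sd: 10.65
    icc: 0.95
    lower: 50.0
  bmi:                          # kg/m^2
    intervention: [30.88, 30.10, 30.05, 30.20]
    control: [30.54, 30.20, 30.15, 30.30]
    sd: 2.13
    icc: 0.95
    lower: 18.0
  waist_circumference:          # cm
    intervention: [104.0, 102.0, 101.8, 102.2]
    control: [103.5, 102.8, 102.7, 103.0]
    sd: 8.0
    icc: 0.90
    lower: 60.0
  fat_mass:                     # kg
    intervention: [36.5, 34.8, 34.6, 35.0]
    control: [36.3, 35.6, 35.5, 35.8]
    sd: 7.0
    icc: 0.92
    lower: 10.0
  fat_free_mass:                # kg
    intervention: [51.9, 51.4, 51.4, 51.5]
    control: [52.0, 51.7, 51.7, 51.8]
    sd: 9.0
    icc: 0.96
    lower: 25.0
  total_cholesterol:            # mg/dL
    intervention: [205.0, 201.0, 201.0, 202.0]
    control: [205.0, 203.0, 203.0, 204.0]
    sd: 35.0
    icc: 0.80
    lower: 90.0
  hdl:                          # mg/dL
    intervention: [55.0, 55.5, 55.8, 55.8]
    control: [55.0, 55.2, 55.3, 55.3]
    sd: 14.0
    icc: 0.85
    lower: 20.0
  ldl:                          # mg/dL
    intervention: [130.0, 127.0, 126.5, 127.5]
    control: [130.0, 129.0, 128.5, 129.0]
    sd: 30.0
    icc: 0.85
    lower: 40.0
  fasting_glucose:              # mg/dL
    intervention: [95.0, 93.0, 93.0, 93.5]
    control: [95.0, 94.5, 94.3, 94.5]
    sd: 10.0
    icc: 0.70
    lower: 60.0
  hba1c:                        # %
    intervention: [5.50, 5.46, 5.45, 5.46]
    control: [5.50, 5.49, 5.49, 5.49]
    sd: 0.35
    icc: 0.85
    lower: 4.0
  systolic_bp:                  # mmHg
    intervention: [130.0, 127.0, 127.0, 127.5]
    control: [130.0, 129.0, 128.5, 129.0]
    sd: 12.0
    icc: 0.60
    lower: 85.0
  diastolic_bp:                 # mmHg
    intervention: [83.0, 81.0, 81.0, 81.3]
    control: [83.0, 82.3, 82.2, 82.3]
    sd: 8.0
    icc: 0.60
    lower: 50.0

# Correlations between the standardized change score of the total index
# and the change scores of panel variables (applied at every follow-up).
change_correlations:
  energy_density: -0.30
  fasting_glucose: 0.15
  fat_free_mass: -0.15
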