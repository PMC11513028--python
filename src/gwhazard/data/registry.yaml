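# Element toxicology / limit registry and cohort exposure profiles.
# Concentrations and limits in ug/L; doses in mg/kg/day; Kp in cm/h.
#
# mac_ci      : maximum admissible concentration (CF, CI, HEI denominator)
# standard_s  : highest permissible value (HPI / m-HPI denominator)
# ideal_i     : ideal (desirable) value for the HPI sub-index; standard_s/100
# who_limit, bis_limit : regulatory acceptable limits (drinking water)
# rfd_ing     : oral reference dose
# giabs       : gastrointestinal absorption factor (dermal RfD = rfd_ing * giabs)
# kp          : dermal permeability coefficient
# sf_ing      : oral carcinogenicity slope factor (null for non-carcinogens)
# detection_limit : instrument detection limit used for BDL substitution
version: "2024.1"
bdl_policy_default: half_dl
elements:
  Cr: {mac_ci: 50.0, standard_s: 50.0, ideal_i: 0.5, who_limit: 50.0, bis_limit: 50.0,
       rfd_ing: 0.003, giabs: 0.025, kp: 0.001, sf_ing: 1.5, detection_limit: 0.009}
  Ni: {mac_ci: 20.0, standard_s: 20.0, ideal_i: 0.2, who_limit: 70.0, bis_limit: 20.0,
       rfd_ing: 0.029, giabs: 0.2, kp: 0.0002, sf_ing: null, detection_limit: 0.011}
  As: {mac_ci: 50.0, standard_s: 50.0, ideal_i: 0.5, who_limit: 10.0, bis_limit: 10.0,
       rfd_ing: 0.003, giabs: 1.0, kp: 0.001, sf_ing: 0.5, detection_limit: 0.006}
  Mo: {mac_ci: 70.0, standard_s: 70.0, ideal_i: 0.7, who_limit: 70.0, bis_limit: 70.0,
       rfd_ing: 0.005, giabs: 1.0, kp: 0.001, sf_ing: null, detection_limit: 0.001}
  Cd: {mac_ci: 3.0, standard_s: 3.0, ideal_i: 0.03, who_limit: 3.0, bis_limit: 3.0,
       rfd_ing: 0.0005, giabs: 0.025, kp: 0.001, sf_ing: 0.0061, detection_limit: 0.002}
  Pb: {mac_ci: 10.0, standard_s: 10.0, ideal_i: 0.1, who_limit: 10.0, bis_limit: 10.0,
       rfd_ing: 0.0035, giabs: 1.0, kp: 0.001, sf_ing: 0.0085, detection_limit: 0.005}

# Cohort exposure constants: daily water intake (L/day), exposure frequency
# (day/year), exposure period (year), life expectancy (day), body weight (kg),
# exposed skin area (cm^2), exposure time (h/day), unit conversion (L/cm^3).
cohorts:
  adult: {dwi: 3.45, ef: 365.0, ep: 70.0, le: 25550.0, bw: 73.0, sa: 18000.0, et: 0.58, cf: 0.001}
  child: {dwi: 2.0, ef: 365.0, ep: 10.0, le: 3250.0, bw: 32.7, sa: 6600.0, et: 1.0, cf: 0.001}

# Classification schemes.  Bands are listed in increasing order; `upper` is the
# band's upper edge (null = unbounded) and `upper_inclusive` says whether the
# edge itself belongs to this band.  Where the source scale prints "< x" for a
# band, the edge x belongs to the next band (upper_inclusive: false);
# everywhere else a shared boundary is assigned to the lower band.
suitability:
  ec:
    - {upper: 750.0, upper_inclusive: false, label: "Desirable"}
    - {upper: 1500.0, upper_inclusive: true, label: "Permissible"}
    - {upper: 3000.0, upper_inclusive: true, label: "Not permissible"}
    - {upper: null, label: "Hazardous"}
  tds_drinking:
    - {upper: 500.0, upper_inclusive: false, label: "Desirable for drinking"}
    - {upper: 1000.0, upper_inclusive: true, label: "Permissible for drinking"}
    - {upper: 3000.0, upper_inclusive: true, label: "Useful for irrigation"}
    - {upper: null, label: "Not suitable for drinking and irrigation"}
  tds_salinity:
    - {upper: 1000.0, upper_inclusive: false, label: "Fresh water"}
    - {upper: 10000.0, upper_inclusive: true, label: "Brackish water"}
    - {upper: 100000.0, upper_inclusive: true, label: "Saline water"}
    - {upper: null, label: "Brine water"}

index_bands:
  hpi:
    critical: 100.0
    bands:
      - {upper: 25.0, upper_inclusive: false, label: "Excellent"}
      - {upper: 50.0, upper_inclusive: true, label: "Good"}
      - {upper: 75.0, upper_inclusive: true, label: "Poor"}
      - {upper: 100.0, upper_inclusive: true, label: "Very poor"}
      - {upper: null, label: "Unsuitable"}
  hei:
    critical: 20.0
    bands:
      - {upper: 10.0, upper_inclusive: false, label: "Low polluted"}
      - {upper: 20.0, upper_inclusive: true, label: "Medium polluted"}
      - {upper: null, label: "Highly polluted"}
  ci:
    critical: 3.0
    bands:
      - {upper: 1.0, upper_inclusive: false, label: "Low polluted"}
      - {upper: 3.0, upper_inclusive: true, label: "Moderate polluted"}
      - {upper: null, label: "Highly polluted"}
  cr:
    bands:
      - {upper: 1.0e-6, upper_inclusive: true, label: "very low"}
      - {upper: 1.0e-4, upper_inclusive: true, label: "lower"}
      - {upper: 1.0e-3, upper_inclusive: true, label: "moderate"}
      - {upper: 0.1, upper_inclusive: true, label: "higher"}
      - {upper: null, label: "very high"}
  mhpi:
    upper_limit: 100.0
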