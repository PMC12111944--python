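# Versioned default constants for the hepindex pipeline.
# Every clinically published threshold used by the package lives here;
# runtime configuration (RunConfig) starts from these values and logs
# any override.
version: 1

staging:
  # CAP (dB/m) lower bounds for steatosis grades S1, S2, S3
  steatosis_cap_thresholds: [294.0, 310.0, 331.0]
  # liver stiffness (kPa) lower bounds for fibrosis stages F2, F3, F4
  fibrosis_te_thresholds: [8.2, 9.7, 13.6]
  cap_device_range: [100.0, 400.0]
  te_device_range: [2.5, 75.0]
  # CAP screen for steatosis evidence (eligibility, not severity grading)
  cap_steatosis_screen: 248.0
  vcte_max_iqr_over_median: 0.30
  vcte_min_valid_readings: 10
  # upper normal limit (U/L) for the 5x transaminase exclusion
  ast_alt_uln: 40.0

cascade:
  # published NFS / FIB-4 grey-zone bounds
  nfs: {rule_out: -1.455, rule_in: 0.676}
  fib4: {rule_out: 1.3, rule_in: 2.67}
  # study-scale TyG / VAI cut-offs for the second stage
  tyg: {rule_out: 2.65, rule_in: 5.61, optimal: 4.80}
  vai: {rule_out: 1.67, rule_in: 6.21, optimal: 4.76}
  combination: both

diagnostics:
  # floors for constrained rule-out / rule-in threshold scans
  rule_out_se_floor: 0.80
  rule_in_sp_floor: 0.74

indices:
  tyg_log_base: natural
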