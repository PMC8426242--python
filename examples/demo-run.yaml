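# Demo end-to-end run: 6 synthetic whole-body scans, a simulated
# detector read, patient-level bootstrap metrics, and a 50-patient
# survival cohort.  Completes in about a minute on one CPU:
#
#     petmtv run-all --config examples/demo-run.yaml
seeds:
  phantom: 11
  detector: 22
  bootstrap: 33
  cohort: 44
n_patients_imaging: 6
bootstrap_replicates: 1000
output_dir: demo-run-output
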