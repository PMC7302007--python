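"""Type-I-error control of the summary-derived statistics.

Simulates a null model (no genetic effect, no interaction; the exposure
still affects the trait) and compares empirical rejection rates at
alpha = 0.05 for statistics computed from individual-level data with those
derived from the joint-model summaries — first with independent G and E
(both should sit at the nominal 5%), then with exposure-dependent
phenotypic variance (the derived stratified statistics lose calibration in
opposite directions while the individual-level ones do not).
"""

from jointstrat import null_scenario, run_null_study

for label, extra in [("independent G and E", 0.0),
                     ("heteroscedastic (extra noise among exposed)", 1.5)]:
    scn = null_scenario(n_individuals=4_000, n_replicates=1_000,
                        exposed_extra_noise_sd=extra, seed=44)
    report = run_null_study(scn, alpha=0.05)
    print(f"\n=== {label} ===")
    print(f"{'analysis':12s} {'true':>8s} {'estimated':>10s}")
    for name in ("unexposed", "exposed", "marginal"):
        print(f"{name:12s} {report.typeI_true[name]:8.3f} "
              f"{report.typeI_estimated[name]:10.3f}")

print("\nRates near 0.05 mean the nominal alpha is honoured. Under "
      "heteroscedasticity the estimated rate inflates in the noisier "
      "(exposed) stratum and deflates in the quieter one, because the "
      "joint fit's pooled residual variance misprices both stratum SEs.")
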