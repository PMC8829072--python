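"""Compare the two interventions on the variation compartment.

Sweeps the variation's immunization probability mu2 and its silencing
probability xi2 over the same grid with common random numbers (identical
graphs, initial spreaders and RNG streams across grid values), then
reports how much each intervention lowers the diffuser peak.
"""

from isvor import AbmConfig, NetworkSpec, intervention_comparison, run_sweep

spec = NetworkSpec("ws", n=2000, ws_k=10, ws_p=0.4)
cfg = AbmConfig(seed=3, t_max=100)

sweep = run_sweep(spec, cfg, "mu2", (0.1, 0.3, 0.5), reps=20)
print(sweep.summary[["param_value", "peak_diffuser", "peak_O", "final_R"]]
      .to_string(index=False))

report = intervention_comparison(spec, cfg, grid=(0.1, 0.5), reps=20)
print(f"\npeak reduction raising mu2 0.1 -> 0.5: {report.delta_mu2:.4f} "
      f"(95% CI {report.ci_mu2[0]:.4f}..{report.ci_mu2[1]:.4f})")
print(f"peak reduction raising xi2 0.1 -> 0.5: {report.delta_xi2:.4f} "
      f"(95% CI {report.ci_xi2[0]:.4f}..{report.ci_xi2[1]:.4f})")
print(f"stronger intervention on the peak: {report.better}")
print("\nInterpretation: both raising the variation's immunization rate and")
print("raising its silencing rate shave the diffuser peak; the deltas above")
print("quantify which lever moves the peak more under identical randomness.")
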