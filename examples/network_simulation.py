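"""Seeded agent-based ensembles on small-world and scale-free networks.

Runs the five-role chain from one random initial spreader on both network
families at the default rates and compares the headline statistic: the
diffuser peak max over t of S(t) + V(t).
"""

from isvor import AbmConfig, NetworkSpec, ensemble, peak_diffuser

cfg = AbmConfig(seed=7, t_max=100)
ws = NetworkSpec("ws", n=2000, ws_k=10, ws_p=0.4)  # small world
ba = NetworkSpec("ba", n=2000, ba_m=5)             # scale free

for name, spec in (("small-world (WS)", ws), ("scale-free (BA)", ba)):
    traj = ensemble(spec, cfg, reps=20)
    peak, when = peak_diffuser(traj)
    print(f"{name}: diffuser peak {peak:.4f} at step {when:.0f}; "
          f"V-peak {traj['V'].max():.4f}, O-peak {traj['O'].max():.4f}, "
          f"final R {traj['R'][-1]:.4f}")

print("\nInterpretation: the diffuser peak is the largest fraction of the")
print("population simultaneously circulating some version of the rumor.")
print("Hubs make the scale-free cascade peak a step or two earlier; the")
print("peak-height difference between the families is small (a few tenths")
print("of a percent) and needs larger ensembles to resolve. In both")
print("families the rumor dies out and most nodes end up immune.")
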