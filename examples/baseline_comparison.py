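"""The five-role model against SIR, SEIR and Twin-SIR on the same network.

All four models run with matched infection (alpha = 0.5) and recovery
(mu1 = 0.5) probabilities on 2000-node scale-free ensembles.
"""

import dataclasses

import numpy as np

from isvor import AbmConfig, BaselineParams, NetworkSpec, ensemble, peak_diffuser
from isvor.baselines import baseline_ensemble

ba = NetworkSpec("ba", n=2000, ba_m=5)
reps, seed = 20, 5
bp = BaselineParams(alpha=0.5, mu1=0.5)

isv = ensemble(ba, AbmConfig(seed=seed, t_max=100), reps)
sir = baseline_ensemble(ba, bp, 1, 100, reps, seed)
seir = baseline_ensemble(ba, dataclasses.replace(bp, model="seir"), 1, 100, reps, seed)
twin = baseline_ensemble(ba, dataclasses.replace(bp, model="twin_sir"), 1, 100, reps, seed)

pk, when = peak_diffuser(isv)
print(f"ISVOR    : diffuser peak {pk:.4f} at step {when:.0f}")
print(f"SIR      : I peak       {sir['I'].max():.4f} at step "
      f"{sir.times[np.argmax(sir['I'])]:.0f}")
print(f"SEIR     : E peak at step {seir.times[np.argmax(seir['E'])]:.0f}, "
      f"I peak {seir['I'].max():.4f} at step {seir.times[np.argmax(seir['I'])]:.0f}")
print(f"Twin-SIR : S1 peak      {twin['S1'].max():.4f} at step "
      f"{twin.times[np.argmax(twin['S1'])]:.0f}")

print("\nInterpretation: the five-role model's active pool (S+V) peaks lower")
print("than SIR's infected curve because silencing (oyster) and contact-driven")
print("immunization drain spreaders; SEIR's exposed wave precedes its infected")
print("wave; the Twin-SIR dispeller suppresses the rumor peak below SIR.")
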