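"""Pathway crosstalk and the calcium channel: PKA activation suppresses
ERK, and PKA sensitises the calcium indicator's response to an ionophore.
"""

import numpy as np

import ktrkit as k

pharm = k.PharmacologyTable()
t = np.arange(0.0, 45.0, 0.1)

fsk = [k.TreatmentEvent(time_min=5.0, agent="Fsk", dose=30.0, dose_unit="uM")]
acts = k.simulate_activities(fsk, pharm, t)
print(f"ERK activity before Fsk: {acts['ERK'].at(4.0):.2f}, "
      f"after Fsk: {acts['ERK'].at(25.0):.2f}  (PKA -> ERK suppression)")

egf = [k.TreatmentEvent(time_min=5.0, agent="EGF", dose=10.0, dose_unit="nM")]
acts = k.simulate_activities(egf, pharm, t)
print(f"PKA activity before EGF: {acts['PKA'].at(4.0):.2f}, "
      f"after EGF: {acts['PKA'].at(25.0):.2f}  (weak ERK -> PKA induction)")

iono = [k.TreatmentEvent(time_min=20.0, agent="A23187", dose=10.0, dose_unit="uM")]
fsk_iono = fsk + iono
pka = k.simulate_activities(fsk_iono, pharm, t)["PKA"]
alone = k.simulate_calcium(iono, pharm, t)
primed = k.simulate_calcium(fsk_iono, pharm, t, pka_activity=pka)
print(f"calcium-indicator plateau: ionophore alone {alone[-1]:.2f}, "
      f"with prior Fsk {primed[-1]:.2f} "
      f"(x{primed[-1] / alone[-1]:.2f} PKA-dependent gain)")
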