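"""Tuning bNLS strength: how the score of the import signal sets the
resting C/N ratio and the agonist response of a KTR.

Evaluates the closed-form steady-state C/N of a score series of PKA
sensors at rest (kinase off) and under saturating stimulation (kinase
fully active), plus the effect of blocking nuclear export.
"""

import ktrkit as k

params = k.TransportParams()
blocked = k.leptomycin(params)

print(f"{'score':>6} {'C/N rest':>9} {'C/N stim':>9} {'fold':>6} {'C/N +LMB':>9}")
for score in (8.0, 10.5, 11.5, 12.5, 15.5):
    s = k.SensorSpec(name=f"v{score}", nls_score=score, mw_kda=32.0, copies=2)
    rest = k.steady_state_cn(s, 0.0, params)
    stim = k.steady_state_cn(s, 1.0, params)
    lmb = k.steady_state_cn(s, 0.0, blocked)
    print(f"{score:6.1f} {rest:9.3f} {stim:9.3f} {stim / rest:6.2f} {lmb:9.3f}")

print(
    "\nWeak-import (8) and very-strong-import (15.5) sensors barely respond "
    "(fold < 1.5);\nmid-strength scores give the large, usable dynamic range. "
    "Export block (LMB)\nlowers resting C/N only where active import/export "
    "cycling matters."
)
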