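"""Full round trip: simulate a small imaging experiment to disk, then run
the measurement pipeline on it and compare recovered C/N to ground truth.

Writes TIFF stacks plus ground truth under example_output/sim and the
measurement tables under example_output/analysis.
"""

from pathlib import Path

import pandas as pd

import ktrkit as k

out = Path("example_output")
config = k.ExperimentConfig(
    seed=17, n_fields=2, n_cells=10, n_frames=20, field_px=(320, 320),
    schedule=[k.TreatmentEvent(time_min=3.0, agent="Fsk", dose=3.0, dose_unit="uM")],
)
manifest = k.run_simulate(config, out / "sim")
print(f"simulated {len(manifest['fields'])} fields, channels {manifest['channels']}")

measurements = k.run_analyze(out / "sim", out / "analysis")
gt = pd.read_csv(out / "sim" / "ground_truth.csv")

pka = measurements[(measurements["channel"] == "KTR_PKA") & measurements["valid"]]
rec = pka.groupby("t_min")["cn_ratio"].mean()
true = gt[gt["channel"] == "KTR_PKA"].groupby("frame")["cn_true"].mean()
print("\n t_min  measured C/N  true C/N")
for t in (0, 5, 10, 19):
    print(f"{t:6.0f} {rec.iloc[t]:13.3f} {true.iloc[t]:9.3f}")
print(
    "\nMean measured C/N tracks the generator's true ratio: low (nuclear) "
    "before the\nagonist at minute 3, rising toward the cytoplasmic plateau "
    "afterwards."
)
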