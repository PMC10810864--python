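"""Simulate the PI3K network under growth medium with and without BYL719.

Builds the builtin parental model, equilibrates it to its basal steady
state, and compares key phospho-readouts at 24 h of 1 uM BYL719 (a
PI3Kalpha inhibitor) against vehicle.  E below 1 means the drug suppresses
that readout relative to untreated cells.
"""

import numpy as np

from pi3knet import (
    StimulusInput,
    build_parental_model,
    byl719,
    equilibrate,
    extract_readouts,
    simulate_timecourse,
)

model = equilibrate(build_parental_model())
medium = StimulusInput("growth-medium", 1.0)
grid = np.linspace(0.0, 1440.0, 49)

vehicle = simulate_timecourse(model, medium, grid=grid)
treated = simulate_timecourse(model, medium, drugs=[byl719(1.0)], grid=grid)

print("readout        vehicle   BYL719    E (treated/vehicle)")
for readout in ("pAKT", "pAKT-S473", "pS6", "pERK", "cyclin D1", "pRb"):
    mapping = {readout: model.observable_map[readout]}
    v = extract_readouts(vehicle, mapping, times=[1440.0])[readout][0]
    d = extract_readouts(treated, mapping, times=[1440.0])[readout][0]
    print(f"{readout:12s}  {v:8.3f}  {d:8.3f}  {d / v:8.3f}")
print("\nPI3Kalpha inhibition collapses AKT-S473 phosphorylation while ERK "
      "is spared,\nthe classic signature of an isoform-selective PI3K "
      "inhibitor.")
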