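"""Viability screen on the cell-fate model: 25 co-targets at IC50 pairing.

Couples the phenomenological cell-cycle/DNA-damage model to the network
model's cyclin outputs, estimates each drug's IC50 on viability (V = R + M,
the repairing plus G2/M fraction), then scores each PI3Kalpha + co-target
pair with CDI on viability.  Co-targets whose single-drug response never
reaches 50% inhibition are reported as not evaluable (nan).

Takes ~20 s (one parameter set).
"""

import numpy as np

from pi3knet import build_parental_model, build_phenotypic_model, equilibrate
from pi3knet.phenotype import phenotypic_screen

model = equilibrate(build_parental_model())
phen = build_phenotypic_model(model)
result = phenotypic_screen(phen, None, pairing="ic50")

print("rank  co-target   mean CDI (viability)")
for ct, mean, se, l2, rank in result.table("viability"):
    label = f"{mean:8.4f}" if not np.isnan(mean) else "   (not evaluable)"
    print(f"{rank:4d}  {ct:10s}  {label}")

print("\nCHK1 at the top mirrors checkpoint-inhibitor sensitization: "
      "PI3Kalpha\ninhibition creates DNA damage that CHK1-driven repair "
      "shelters; removing\nCHK1 converts that damage into apoptosis.")
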