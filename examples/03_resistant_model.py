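"""Derive the drug-resistant model and compare its BYL719 response.

The resistant state carries 7x p21 and 3x cyclin D1 relative to parental
cells (with AKT and ERK unchanged).  After sustained-expression derivation
and re-equilibration, the resistant model retains more S6 phosphorylation
and Rb phosphorylation under 1 uM BYL719 -- the signaling signature of
resistance to PI3Kalpha inhibition.
"""

import numpy as np

from pi3knet import (
    build_parental_model,
    byl719,
    compare_states,
    derive_resistant_model,
    equilibrate,
)

parental = equilibrate(build_parental_model())
resistant = derive_resistant_model(parental)  # default folds: p21 x7, cycD1 x3

i = parental.species_names.index("p21")
print(f"p21 basal: parental {parental.species[i].initial:.3f}, "
      f"resistant {resistant.species[i].initial:.3f} "
      f"({resistant.species[i].initial / parental.species[i].initial:.1f}x)")

cmp = compare_states(parental, resistant, byl719(1.0),
                     readouts=("pAKT", "pS6", "cyclin D1", "pRb"),
                     grid=np.linspace(0, 2880, 49))
i24 = int(np.argmin(np.abs(cmp["times"] - 1440.0)))
print("\nreadout       parental@24h  resistant@24h")
for r in ("pAKT", "pS6", "cyclin D1", "pRb"):
    print(f"{r:12s}  {cmp['parental'][r][i24]:11.3f} "
          f"{cmp['resistant'][r][i24]:13.3f}")
print("\nHigher resistant pS6/pRb/cyclin D1 with matched pAKT reproduces "
      "the rewired,\np21-driven resistant signaling state.")
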