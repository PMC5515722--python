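"""Mean alpha energy per nuclear transition for therapy decay chains.

For a chain in secular equilibrium every daughter decays at the parent's
rate, so the energy released per parent decay is the yield-weighted sum of
all member alpha energies.  This constant (Delta) converts time-integrated
activity into absorbed dose.
"""

import alphadose as ad

for label in ad.nuclides.available_nuclides():
    chain = ad.get_chain(label)
    delta = ad.mean_alpha_energy_per_transition(chain)
    members = ", ".join(e.nuclide_label for e in chain.emissions)
    print(f"{label}: Delta = {delta:.3g} J/(Bq s)  [alphas from {members}]")

print()
print("Delta scales dose directly: the Ac-225 chain deposits "
      f"{ad.get_radionuclide('Ac-225').delta_alpha_j_per_bq_s / ad.get_radionuclide('Bi-213').delta_alpha_j_per_bq_s:.2f}x "
      "the energy per transition of a free Bi-213 decay.")
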