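"""Carbon/reductant conversion factors from molecular formulas.

Every compound's pair (C atoms, electron equivalents γ = 4C + H − 2O − 3N)
is derived from its formula alone. Multiplying a net concentration change
(μM) by the pair yields turnover in μM carbon and μM electron equivalents.
"""

from anoxmet import carbon_reductant_factors, default_registry

registry = default_registry()
print(f"{'compound':<12} {'formula':<10} {'C/molecule':>10} {'e-/molecule':>11}")
for name in ("NAG", "formate", "ethanol", "acetate", "propionate", "CH4", "CO2", "H2"):
    compound = registry[name]
    carbon, reductant = carbon_reductant_factors(compound)
    print(f"{name:<12} {str(compound.formula):<10} {carbon:>10} {reductant:>11}")

print()
print("Fully oxidized species (CO2, H2O, NH3) carry zero electron equivalents;")
print("methane, the most reduced one-carbon compound, carries eight.")
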