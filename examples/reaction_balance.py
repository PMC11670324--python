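"""Element and electron balance checking for anaerobic food-chain reactions.

A reaction is balanced iff every element residual (Σ coefficient × atom
count) and the electron residual (Σ coefficient × γ) are zero. The default
library — primary amino-sugar fermentation, methanogenesis from formate,
H2/CO2 and acetate, syntrophic ethanol oxidation, and acetogenesis — passes
by construction; a deliberately broken reaction shows what failure reports.
"""

from anoxmet import check_reaction_balance, default_reaction_library, default_registry, parse_reaction

for kinetic in default_reaction_library():
    report = check_reaction_balance(kinetic.reaction)
    status = "balanced" if report.balanced else "NOT balanced"
    print(f"{kinetic.name:<32} {status}   ({kinetic.reaction})")

print()
broken = parse_reaction("CH4 -> CO2", default_registry(), name="methane-to-co2 (broken)")
report = check_reaction_balance(broken)
print(f"{broken.name}: balanced={report.balanced}")
print(f"  element residuals: {dict(report.element_residuals)}")
print(f"  electron residual: {report.electron_residual}  (8 e- of CH4 have no sink)")
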