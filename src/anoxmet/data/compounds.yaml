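# Default compound registry for anaerobic food-chain accounting.
# Organic acids are registered as neutral (protonated) formulas; degree-of-
# reduction factors are computed from the formula, never stored here.
NAG: {formula: C8H15NO6, phase: dissolved}   # N-acetylglucosamine
glucose: {formula: C6H12O6, phase: dissolved}
acetate: {formula: C2H4O2, phase: dissolved}   # acetic acid
formate: {formula: CH2O2, phase: dissolved}    # formic acid
ethanol: {formula: C2H6O, phase: dissolved}
propionate: {formula: C3H6O2, phase: dissolved}  # propionic acid
butyrate: {formula: C4H8O2, phase: dissolved}    # butyric acid
methanol: {formula: CH4O, phase: dissolved}
CO2: {formula: CO2, phase: gaseous}
CH4: {formula: CH4, phase: gaseous}
H2: {formula: H2, phase: gaseous}
H2O: {formula: H2O, phase: dissolved}
NH3: {formula: NH3, phase: dissolved}
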