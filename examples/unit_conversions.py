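"""Headspace / slurry / dry-weight unit conversions for sealed microcosms.

A supplement given as a headspace volume percentage converts to mmol per
litre of slurry via the ideal gas law; slurry concentrations convert to
μmol per g dry weight of soil with the configured slurry divisor (default
10.5 for a standard 1:10 peat dilution).
"""

from anoxmet import GasConversionContext, headspace_to_slurry, umol_per_gdw

ctx = GasConversionContext(headspace_volume_l=0.3, slurry_volume_l=0.2)

for percent, gas in ((8.0, "H2"), (2.0, "CO2")):
    mmol = headspace_to_slurry(percent, ctx)
    print(f"{percent:4.1f} vol% {gas:<4} in {ctx.headspace_volume_l} L headspace "
          f"over {ctx.slurry_volume_l} L slurry = {mmol:.2f} mmol L⁻¹ slurry")

for conc in (1050.0, 500.0):
    print(f"{conc:7.1f} μM slurry = {umol_per_gdw(conc, ctx):6.1f} μmol per g dry weight")
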