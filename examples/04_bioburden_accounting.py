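"""Spore bioburden arithmetic and the SSB spore-to-viable conversion.

A wipe is eluted and concentrated to 5 mL; 100-uL aliquots of the
heat-shocked concentrate are pour-plated in quadruplicate. Pooled
colonies over pooled volume give the concentrate titre, scaled to the
whole concentrate and the wiped area. The Space Studies Board ratio
(50,000 viable cells per NSA spore) then bounds total viable bioburden,
which a direct viability measurement can be compared against.
"""

from sporeburden import (
    PlateCountRecord,
    cfu_per_area,
    cultivable_from_fraction,
    observed_ratio,
    ssb_viable_estimate,
)

rec = PlateCountRecord(colonies=[1, 2, 0, 1], volume_per_plate_ml=0.1,
                       concentrate_volume_ml=5.0, area_m2=1.0)
spores = cfu_per_area(rec)
print(f"quadruplicate plates (1,2,0,1 CFU in 0.1 mL each) -> "
      f"{spores:.0f} spores/m^2")

print(f"SSB-predicted viable bioburden: {ssb_viable_estimate(spores):,.0f} "
      f"cells/m^2 (50,000 viable per spore)")

# a facility-scale example: 36 spores/m^2 making up ~20% of cultivables
print(f"36 spores/m^2 at a 20% spore share -> "
      f"{cultivable_from_fraction(36.0, 0.20):.0f} cultivable cells/m^2")

# compare a measured viable density with the spore count of the same sample
est = observed_ratio(viable_measured_per_m2=8.8e5, spores_per_m2=35.0)
print(f"measured 8.8e5 viable/m^2 over 35 spores/m^2 -> observed ratio "
      f"{est.observed_ratio:,.0f} viable per spore "
      f"({est.fraction_of_ssb:.1%} of the SSB specification)")
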