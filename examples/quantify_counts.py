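"""Absolute quantification from droplet counts.

Converts positive/accepted droplet counts into copy-number
concentrations, including a gravimetric dilution factor.
"""
from dropval import GravimetricRecord, concentration_from_counts, gravimetric_dilution_factor

# a well with 3,000 positive of 17,000 accepted droplets of 0.834 nL
c_pcr, _ = concentration_from_counts(P=3000, A=17000)
print(f"P=3000, A=17000           -> c_PCR = {c_pcr:8.1f} cp/uL")

# the PCR mix was prepared by weighing 2 g of sample into 18.636 g of
# pre-sample mix (density 1.0353 g/mL): a 10x dilution into the mix
df_pcr = gravimetric_dilution_factor(GravimetricRecord(mass_sample_g=2.0, mass_premix_g=18.636))
c_pcr, c_sample = concentration_from_counts(P=3000, A=17000, df_pcr=df_pcr)
print(f"with gravimetric Df_PCR = {df_pcr:.3f} -> c_sample = {c_sample:8.1f} cp/uL")

print("\nc_PCR is the concentration inside the PCR mix; c_sample scales it")
print("back to the undiluted sample through the weighed dilution factors.")
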