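"""Stochastic limits of digital PCR: precision curve and minimum LOD.

Evaluates the closed-form relative SD caused by Poisson sampling and by
the binomial distribution of copies over droplets, and the smallest
concentration detectable with 95 % confidence for a given droplet count.
"""
from dropval import stochastic_curve, theoretical_min_lod

print("c_PCR (cp/uL)  s_sampling %  s_distribution %  combined %")
for pt in stochastic_curve([0.5, 2.5, 26, 255, 2575, 5400], a=17_000):
    print(f"{pt.c_pcr:12.1f} {100*pt.s_sampling_rel:12.2f} "
          f"{100*pt.s_distribution_rel:16.2f} {100*pt.s_stochastic_rel:10.2f}")

print("\nthe curve is U-shaped: counting noise dominates at low copy input,")
print("droplet saturation at high input; the method is most precise between.")

for a in (10_000, 15_000, 20_000):
    print(f"theoretical minimum LOD at {a:6d} droplets: "
          f"{theoretical_min_lod(a):.3f} cp/uL")
print("below this concentration >5 % of wells contain no target copy at all,")
print("so no classifier can guarantee detection.")
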