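"""Predict how far a curved membrane patch rolls up, and at what spacing.

Protein binding imposes a spontaneous curvature c_0 on a supported bilayer
patch; rolling starts when (k_c/2) c_0^2 beats the adhesion w_ad and stops
when the spiral's outer radius makes bending too costly.  The closed forms
give the final roll geometry; the inverse map turns a measured roll into a
layer spacing.
"""

from anxmorph.roll import ElasticParams, solve_roll, spacing_from_roll, sweep_rolled_length

NM, UM = 1e-9, 1e-6

# cholera-toxin-scale curvature, low adhesion, 13 nm layer repeat
params = ElasticParams.from_units(k_c_J=1e-19, ratio_per_um2=10.0, c0_per_nm=0.028, d_nm=13.0)
g = solve_roll(params)
print(f"maximum roll radius r_m = {g.r_m / UM:.2f} um")
print(f"inner radius        a   = {g.a / NM:.1f} nm")
print(f"rolled length       L   = {g.L / UM:.0f} um")
# L far exceeds any real patch (~tens of um): full roll-up is predicted.

# inverse: a roll measured at r_m = 350 nm, a = 15 nm after 30 um of rolling
b, d = spacing_from_roll(350 * NM, 15 * NM, 30 * UM)
print(f"implied inter-bilayer spacing d = {d / NM:.1f} nm")
# ~13 nm: bilayer + protein spacer between the turns.

# how the rolled length falls off with adhesion, for two curvatures
table = sweep_rolled_length([10, 30, 100, 300], [0.028, 0.033], b_nm=13 / 6.2832)
print(table[["ratio_per_um2", "c0_per_nm", "L_um", "rolls"]].to_string(index=False))
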