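# anxmorph

Modelling and measurement tools for annexin-induced membrane morphologies on
supported bilayer patches with free edges: membrane roll-up energetics,
inter-leaflet lens geometry, rolling kinetics from time-lapse imaging, and a
sequence-similarity dendrogram of the human annexin family.

Annexins are Ca²⁺-dependent proteins that bind anionic membranes. Bound
asymmetrically to one face of a bilayer patch they impose a spontaneous
curvature that can peel the patch off its support and roll it up from the
free edges — or, for other family members, produce blebs, folds, or bright
mobile "lenses" trapped between the leaflets. This package implements the
quantitative backbone of that phenomenology for people studying membrane
mechanics and remodelling in vitro.

## The models

**Roll-up energetics.** A patch adheres to the primary membrane with energy
`w_ad` (J/m²), has bending modulus `k_c` (J) and acquires spontaneous
curvature `c_0` (1/m). Rolling initiates when `(k_c/2)·c_0² > w_ad`. The roll
is an archimedean spiral `r(θ) = a + bθ` with layer spacing `d = 2πb`; the
elastic energy change is

    ΔE(θ, a) = (W·k_c/b) · [ ½ ln(1 + (b/a)θ) + ((w_ad/k_c)·a·b − c_0·b)·θ
                             + ½·(w_ad/k_c)·b²·θ² ]

whose minimization gives closed forms for the maximum roll radius
`r_m = (c_0 + √(c_0² − 2w_ad/k_c)) / (2w_ad/k_c)`, the inner radius
`a = [2(w_ad/k_c)·r_m]⁻¹`, the maximal angle `θ_m = (r_m − a)/b` and the
rolled length `L = a·θ_m + b·θ_m²/2`. Inverting `b = (r_m² − a²)/(2L)` turns
a measured roll into a layer spacing. A brute-force numeric minimizer of ΔE
is included as an independent cross-check.

**Lens geometry.** A lens of in-plane radius `w` and half-thickness `h`,
modelled as two spherical caps, has contact angle
`sin θ = 2hw/(h² + w²)`.

**Rolling kinetics.** The rolled area per frame transition is measured by
differencing consecutive frames and thresholding; the cumulative area is
fitted with `A(t) = A_inf / (1 + e^{−(t−t_0)/τ})`, whose time constant τ
characterizes the dynamics. The comparator `t* = σ²/4D` gives the lipid
diffusion timescale across a patch of size σ.

**Annexin dendrogram.** Progressive multiple alignment (BLOSUM matrices,
affine gaps), Jukes-Cantor amino-acid distances with pairwise deletion
(`d = −(19/20)·ln(1 − (20/19)·p)`), and UPGMA/WPGMA agglomeration into an
ultrametric tree with Newick output.

A seeded synthetic-imaging module renders cooperative rolling, fragmented
rolling, lens coarsening and static scenes with exact ground truth
(conserved integrated intensity, known τ), so the kinetics pipeline is
testable end to end without experimental data. The bundled annexin FASTA is
a clearly-labelled synthetic stand-in generated by the package's divergence
simulator (see `docs/methods.md`).

## Worked example

```sh
python examples/rolling_kinetics.py
```

```
synthetic stack: 82 frames, tau_true = 0.7 s
recovered tau = 0.78 s (midpoint t0 = 2.10 s)
plateau area  = 2014 um^2
lipid diffusion time across a 100 um patch: t* = 2500 s
separation of scales t*/tau = 3190x
```

A patch rolls up with a known time constant of 0.7 s; the analysis recovers
τ ≈ 0.78 s from the rendered images (the difference is measurement noise at
this seed). Rolling is ~1000× faster than lipid diffusion across the patch
(2500 s), which is the argument that rolling reflects mechanical
destabilization rather than transport. The other examples print the roll
geometry (`roll_energetics.py`: L ≈ 1870 µm at low adhesion, spacing
d ≈ 12.8 nm from a measured roll), the lens angle
(`lens_contact_angle.py`: θ = 15.7°), and the family dendrogram
(`annexin_dendrogram.py`: cherries ANXA1+ANXA2, ANXA4+ANXA5, ANXA7+ANXA11).

Everything is also reachable from the thin CLI:

```sh
anxmorph roll solve --ratio-per-um2 10 --c0-per-nm 0.028 --d-nm 13
anxmorph lens angle --h-nm 275 --w-nm 2000
anxmorph sim generate --mode cooperative_roll --tau 0.7 --seed 42 --out out/
anxmorph dyn analyze --stack out/cooperative_roll.tif --out out/analysis
anxmorph tree build --method upgma --out out/annexins
```

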