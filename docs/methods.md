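# Methods

## Roll-up model

The elastic model treats a planar bilayer patch on a primary supported
membrane as rolling up into an archimedean spiral `r(θ) = a + bθ` once the
spontaneous curvature `c_0` imposed by asymmetric protein binding overcomes
the adhesion `w_ad` to the support: `(k_c/2)·c_0² > w_ad`. The energy
functional ΔE(θ, a) combines the Helfrich bending energy of the spiral, the
adhesion paid for the lifted area, and the curvature energy gained; its
stationary point gives the closed forms for `r_m`, `a`, `θ_m` and `L`
implemented in `anxmorph.roll`. Assumptions worth keeping in mind:

- the membrane area is conserved during rolling (no stretching, no flow
  into or out of the roll);
- Gaussian-curvature and tilt terms are neglected, and no dynamical model
  (hydrodynamic drag) is attached — the model predicts final geometry, not
  speed;
- `W`, the roll width, is a pure prefactor of the energy and defaults to
  1 m, so energies are per unit roll width; geometry never depends on it;
- for the quadratic in `r_m` the larger root is always taken; the smaller
  root is an unstable equilibrium.

Parameters, units and defaults: `k_c` (J, typical 1e-19), `w_ad` (J/m²,
typical 1e-5, i.e. `w_ad/k_c` of 10–100 µm⁻²), `c_0` (1/m; 0.028–0.033 nm⁻¹
is the scale measured for curvature-generating toxins), `b` (m; a 13 nm
layer repeat gives `b = 13 nm/2π`). Internally everything is strict SI;
constructors take explicitly unit-tagged keywords (`c0_per_nm`, `d_nm`,
`ratio_per_um2`) and convert once at the boundary.

Below the rolling threshold `solve_roll` returns a flagged no-roll result
rather than raising, so parameter sweeps can traverse the threshold;
`max_roll_radius` alone raises. The independent check
(`minimize_energy_numeric`) minimizes ΔE by a 20 000 × 200 grid over
(θ, log a) bracketed at [0, 3θ_m] and two decades around the closed-form
core radius, followed by Nelder-Mead refinement on (θ/θ_grid-best, log a);
it shares no algebra with the closed forms beyond using them to bracket the
search.

## Lens geometry

Lenses are modelled as two back-to-back spherical caps; the contact angle
`θ = arcsin(2hw/(h²+w²))` is reported in degrees. The precondition `h ≤ w`
restricts the model to at-most-hemispherical caps, where the arcsine branch
is unambiguous; the observed lenses are far shallower. The cap radius
`R = (h²+w²)/(2h)` satisfies `R·sin θ = w` exactly.

## Kinetics measurement

`incremental_rolled_area` counts pixels whose intensity changes by more
than a cutoff between consecutive frames (absolute difference by default; a
signed decrease-only mode is available, as is an optional despeckle that
removes isolated changed pixels — both off by default). The default cutoff
is 5 × the robust noise scale (1.4826 × MAD) of the first difference image;
for strictly noiseless input it falls back to a tenth of the first frame's
robust contrast so only level transitions register. The cutoff actually
used is recorded on the trace.

The cumulative area is fitted with the standard three-parameter logistic
`A(t) = A_inf/(1+exp(−(t−t_0)/τ))` by least squares. Initialization is
deterministic (plateau at the trace maximum, midpoint at the half-max
crossing, τ from the 16–84 % rise span divided by 3.5) and the fit is done
with the area axis normalized to the trace maximum — SI areas are ~1e-9 m²
and would otherwise defeat scale-sensitive convergence tolerances. The
1–3 min delay while protein diffuses to the membrane is absorbed by the
free `t_0`, not by trimming the record. Degenerate traces (flat, all-zero,
< 5 points) raise an explicit error rather than returning garbage.

## Synthetic imaging

The generator (`anxmorph.simulate`) is kinematic: it renders what the
camera would see, with the energetics living elsewhere. Defaults emulate
the imaging conditions of the experiments the package is aimed at:
128 × 128 px at 0.4 µm/px, 10 frames/s, an irregular ~36 µm patch,
intensity levels background 10 < primary 30 < patch 100 (arbitrary units),
and additive Gaussian noise with sd = 0.5·√signal + 1 approximating shot
plus read noise (a Poisson-free stand-in that keeps exact moments).

In cooperative mode the swept area follows
`A_patch/(1+exp(−(t−t_0)/τ_true))` by construction, sweeping patch pixels
in order of distance from seeded edge nucleation points; the swept
intensity in excess of the primary level is re-deposited as a
Gaussian-profile ridge at the front, so the noiseless integrated intensity
is conserved to machine precision in every frame. The ridge width defaults
to 1.6 px ≈ 0.64 µm, the mid-range of AFM-measured roll diameters
(500–800 nm) at the default pixel size; a much wider ridge would make the
frame-difference measurement band-dominated in a way real rolls are not.
Records run to `t_0 + 9τ` (at least 60 frames) so the logistic genuinely
plateaus; `t_0` defaults to max(1 s, 2.5τ). Fragmented mode advances
thin fingers from edge points with ±30 % speed jitter and a 5 % per-step
branching probability; lens mode nucleates dots near the edge that
random-walk, merge on contact conserving summed intensity, and grow by
eroding the patch edge (default 30 % of the patch area over the record).

What the generator does *not* emulate: photobleaching, focus drift, a
realistic point-spread function, detector nonlinearity, patch translation,
or the blebbing/folding morphologies (which offer no scalar observable to
recover). Passing recovery tests therefore show that the measurement
pipeline is correct and well-conditioned under controlled imaging physics —
not that real data need no detrending.

End-to-end τ recovery under these defaults (fixed seeds, τ ∈ [0.5, 3] s)
shows a small positive bias of ~5 %: a pixel is counted once when the
bright front ridge arrives and again when it leaves, and the second count
lags the first by the ridge transit time, slightly widening the apparent
rise. The same double-counting affects any frame-difference measurement of
a moving bright front, so the recovered τ is an honest property of the
method, not a generator artefact.

## Sequence pipeline

Multiple alignment is progressive: k-mer (k = 3) pairwise distances build a
UPGMA guide tree, and blocks are merged by profile–profile global alignment
(Gotoh three-state DP, vectorized per row) scoring expected substitution
values between residue-frequency columns. Defaults are BLOSUM62 with gap
open −10 and extend −1 (charged as first-position/additional-position);
the dendrogram-level conclusions are checked to be stable across
BLOSUM50/62/80. Jukes-Cantor amino-acid distances use the 20-state
correction `d = −(19/20)ln(1−(20/19)p)` with pairwise deletion of gapped
sites (complete deletion behind a flag); saturated pairs (p ≥ 19/20) raise
an explicit error. UPGMA/WPGMA use merge height d/2 and break ties by the
lexicographically smallest pair of cluster labels, making the Newick output
bit-reproducible. Full sequences are aligned with no manual masking of the
ANXA6 double core; which core dominates the alignment is emergent.

### The bundled fixture is synthetic

The build environment has no access to sequence databases, so the 12
human annexin records could not be fetched. The bundled
`annexins_human_synthetic.fasta` is generated by
`synthesize_annexin_family`: a 320-residue core evolved down an ultrametric
family tree (uniform 20-state substitution process, seeded) whose structure
encodes the family's established relationships — tight pairs
(ANXA1, ANXA2), (ANXA4, ANXA5), (ANXA7, ANXA11), ANXA6 most distant with a
second, further-diverged core copy — plus variable N-terminal regions
(shared within pairs, taxon-specific elsewhere) sized so each synthetic
protein has the real protein's published length. Headers keep the real
accessions for bookkeeping and carry an explicit `synthetic` tag. Tree
tests on this fixture validate the pipeline's behaviour on a family with
annexin-like structure; they say nothing new about the real sequences.

`simulate_divergence` exposes the same evolution engine for recovery
experiments (e.g. cherry recovery rates over seeded replicates).

## Known limitations

- The energy functional is taken as given; it is not re-derived from a
  surface integral over the spiral.
- τ recovery statistics are computed at the generator's default noise and
  geometry; heavier noise, drift or bleaching would require detrending
  upstream of the fit.
- The dendrogram is a similarity summary, not phylogenetic inference: no
  bootstrap, no model selection, and topology-level claims only.
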