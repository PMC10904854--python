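# Methods

`tileswitch` screens intrinsically disordered protein (IDP) sequences for
*conformational switches*: contiguous peptides whose conformational ensemble
collapses from a broad, heterogeneous distribution to a narrow compact one
when the environment changes (a hydrophobic cosolvent probe, or a bound small
molecule).  The pipeline operates on conformational ensembles — multi-model
coordinate sets with per-atom parameters — wherever they come from; the
shipped synthetic generator provides seeded desk-scale stand-ins for
microsecond MD so that every stage is testable end to end.

## Tiling and sequence profiles

A protein is cut into fixed-length tiles (default 50 residues, non-overlapping),
named `<parent>_<start>–<end>` with 1-based inclusive coordinates; a
frame-shifted pass (offset 24) covers junction regions.  For the shipped
canonical 439-residue human c-MYC sequence this yields nine primary tiles
(the last one 39 residues) and eight shifted ones.  Hydropathy profiles use
the Miyazawa–Jernigan contact-energy-derived hydrophobicity scale by default
(Kyte–Doolittle selectable), smoothed by a centered mean over an odd window
(default 9; truncated at the termini).  The hydrophobic residue class is
{A, C, F, I, L, M, V, W}; under it the core epitope (residues 101–150) is
exactly half hydrophobic (25/50).  Disorder scores are read from external
per-residue CSVs when available; otherwise a FoldIndex-style proxy
(2.785·⟨H⟩ − |⟨q⟩| − 1.151, negated so larger means more disordered, with
Kyte–Doolittle hydropathy rescaled to [0, 1]) stands in.  Average peptide
masses (residue-mass sums + water, with N-acetyl/formyl and C-amide deltas)
and `m/z = (M + z·m_H)/z` support native-MS stoichiometry assignment.

## Ensemble comparison and the switch rule

Per-frame compactness is the mass-weighted radius of gyration; distributions
are normalized histograms (default 1 Å bins over 0–40 Å, the regime the
screen operates in).  Two conditions are compared by three statistics:

- **spread reduction** `1 − IQR(perturbed)/IQR(reference)`;
- **tail depletion** `P_ref(R_g > T) − P_pert(R_g > T)` with the
  compact/extended boundary `T = 15 Å`;
- **KS distance** between the two empirical R_g distributions.

A tile is flagged as a switch only if all three clear their thresholds
(defaults 0.5, 0.25, 0.3, all configurable).  The conjunction is deliberate:
KS distance alone is sensitive to any mean shift between independent finite
samples of a collapsed globule, but tail depletion requires genuine loss of
extended states, which is the phenomenon of interest.  The null calibration
(two independent draws of the same compact ensemble, 100 seeds, 120 frames
per series) holds false flags at ≤ 5%; percentiles use linear (type-7)
interpolation.  R_g–energy landscapes plot R_g against min–max-normalized
total energy; when two conditions are compared the normalization domain pools
both ensembles by default so the two clouds share a 0–1 energy axis.

## MM/GBSA energy model

The per-frame energy is `G = E_bon + E_vdw + E_ele + E_pol + E_npol`:

- `E_vdw`: 12-6 Lennard-Jones with Lorentz–Berthelot-style combining
  (`ε_ij = √(ε_i ε_j)`, `r_min,ij = r_i + r_j` from half-r_min parameters);
- `E_ele`: Coulomb with constant 332.0637 kcal·Å/mol/e² and the solute
  dielectric (default 1); with a bonded topology, 1-2/1-3 pairs are excluded
  and 1-4 pairs scaled by 1/2.0 (vdW) and 1/1.2 (electrostatics); without one
  (bead systems) all pairs interact and `E_bon = 0`;
- `E_bon`: harmonic bonds/angles and cosine dihedrals when a topology is
  supplied — it cancels identically in single-trajectory binding differences;
- `E_pol`: Generalized Born with Still's pair function
  `f_ij = √(r² + B_i B_j exp(−r²/4B_iB_j))`, effective radii from HCT
  pairwise descreening with offset 0.09 Å and screen factor 0.8, rescaled by
  the OBC-I coefficients (α = 0.8, β = 0, γ = 2.909125).  Salt (default
  150 mM) enters as Debye screening `exp(−0.73·κ·f)/ε_w` with
  κ = 0.329·√I Å⁻¹; note the screening factor makes single-ion solvation
  slightly *more* favorable with salt, as the published form dictates;
- `E_npol`: γ·SASA + b with γ = 0.0072 kcal/mol/Å², b = 0, probe 1.4 Å.
  SASA is Shrake–Rupley over a deterministic golden-spiral point set
  (default 960 points), so results are bit-reproducible; the fixed point set
  costs exact rotation invariance (a few per mille at 960 points) while
  translation invariance is exact.

Binding energies follow the single-trajectory convention
`ΔG = G(complex) − G(A) − G(B)` with parts cut from complex frames and their
Born radii and SASA recomputed in isolation, reported as mean ± SD over
frames (defaults mirror common practice: up to 5000 frames for single
peptides, 1000 for complexes, evenly subsampled).  Decomposition assigns
half of every pair term to each partner's residue and self/GB-diagonal and
SASA terms to the owning residue, so residue means sum to ΔG exactly; the
hotspot report lists residues at or below −2 kcal/mol.  No numeric parity
with any MD package is claimed: correctness is defined against the closed
forms and the scalar-transcription oracle shipped with the generators.

## Contacts and pose clustering

The contact score of a residue is the mean number of ligand heavy atoms
within the cutoff (default 4.5 Å, heavy atoms only) of any of its heavy
atoms; scores above 1 mean more than one ligand atom engaged on average.
Per-frame binary fingerprints (residue touched / not touched) feed
average-linkage hierarchical clustering under Jaccard distance, cut at 0.5;
representatives minimize the summed distance to co-members with lowest frame
index breaking ties.  Average linkage with ties is order-dependent, so
reproducibility guarantees hold for a fixed frame order.

## Projection-approximation CCS

CCS is estimated as the mean shadow area over quaternion-uniform random
orientations (default 300, early stop at 1 Å² standard error): each atom
projects to a disk of radius `r + probe` (probe default 1.0 Å) and the union
area is estimated by uniform Monte-Carlo sampling over the disks' bounding
box (default 4096 points).  The estimator is unbiased and seeded, but it is
a sampling estimator: monotonicity and bound guarantees hold up to
Monte-Carlo error, so checks use increments that dwarf that error.  Absolute
agreement with drift-gas experiments needs the linear calibration hook
(identity by default); uncalibrated values are for *ordering* ensembles by
compaction, which is how the pipeline uses them.

## Synthetic ensembles

One bead per residue on 3.8 Å virtual bonds; hard core 4.0 Å between beads
two or more apart; square-well attraction of depth ε_c (kT units) and range
7.0 Å between "sticky" beads at least three apart (all beads by default);
bending stiffness κ(1 + cos θ) with κ = 2 kT keeps the non-interacting chain
extended.  Sampling is Metropolis Monte Carlo mixing uniform pivots,
small-angle pivots (σ = 0.3 rad), and crankshaft rotations of ≤ 13-bead
internal segments about their chord (σ = 1.2 rad) — the crankshaft moves are
what keep collapsed globules ergodic.  Frames are recorded every 2N attempted
moves after a 60N burn-in from a straight start; all randomness is pre-drawn
from one seeded generator, so trajectories are exactly reproducible.  For
50-residue chains, ε_c = 0 gives a broad extended ensemble (mean R_g ≈ 22 Å,
excursions past 30 Å) and ε_c = 0.5 a collapsed one (≈ 9 Å, IQR ≈ 1 Å); the
collapse transition sits near ε_c ≈ 0.25–0.35, where bisection calibration
can pin intermediate targets such as a 12 Å mean.  The default compact model
(ε_c = 0.5) sits safely past the transition because ensembles *at* the
transition are bistable, which is the planted switch's job, not the null's.

Mixture ensembles draw each frame from the compact or extended sampler with
recorded ground-truth labels.  Planted ligands append pseudo-atoms near a
chosen residue with set occupancy (or far beyond the cutoff), with the truth
table stored.  The toy two-chain complex (6 + 5 beads with formal charges,
facing K/E pairs at 4.3 Å) ships with brute-force oracle energies computed by
an independent scalar transcription of the energy equations.

What the generator does *not* emulate: atomic detail and side-chain packing,
secondary-structure propensity, explicit probe/water molecules (probe effects
are emulated by raising ε_c), force-field realism, or kinetics (Monte-Carlo
"time" is not physical time).  Tests passing on these ensembles certify the
*analysis machinery* — not that any real sequence switches.

## Problem sizes and numerical choices

Default desk-scale study conditions: 150-frame ensembles for screens (120 for
the 100-seed null calibration), 10–20-frame toy complexes, 48–400 CCS
orientations depending on the precision needed, 960 SASA points.  Degenerate
inputs are handled explicitly: zero-IQR references report spread reduction 0
with a degeneracy flag rather than dividing by zero; all-identical energies
normalize to a flat 0 landscape with a warning; empty selections and
overlapping binding partners raise.  Tile names carry an en-dash
(`MYC_101–150`) to match field conventions; file outputs normalize it to an
ASCII hyphen.

## Known limitations

- The switch thresholds (0.5/0.25/0.3) are declared operating points
  validated by null calibration on the synthetic generator, not values fitted
  to any experimental dataset.
- The GB/SASA implementation targets bead and minimal heavy-atom systems; it
  has no parameter generation for arbitrary all-atom structures.
- PA CCS systematically underestimates experimental CCS for large ions
  (projection ignores multiple scattering); use the calibration hook before
  comparing to drift-tube numbers.
- VSL2-style disorder prediction is out of scope; external scores are read
  from CSV, and the fold-index proxy is a coarse fallback.
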