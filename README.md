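# tileswitch

Peptide-tiling conformational-switch screening for intrinsically disordered
proteins (IDPs).

Disordered transcription factors such as c-MYC cannot be targeted like folded
enzymes: they have no stable pocket.  One route around this is to find
*conformational switches* — short regions whose ensemble collapses from a
broad, heterogeneous distribution of shapes to a narrow compact one when a
hydrophobic probe or ligand is present — and to drug the switch rather than a
pocket.  `tileswitch` implements the computational arm of that strategy as a
reusable, tested pipeline for people who work with conformational ensembles
(from MD, from Monte-Carlo samplers, or from any multi-model PDB source):

- **tile** a sequence into fixed-length peptides and profile hydropathy,
  composition, and disorder;
- **compare** per-tile ensembles between conditions via normalized R_g
  distributions, order statistics, KS distance, and a three-part switch rule
  (spread reduction ≥ 0.5 ∧ tail depletion ≥ 0.25 ∧ KS ≥ 0.3);
- **score energetics** with an MM/GBSA model
  `G = E_bon + E_vdw + E_ele + E_pol + E_npol` (OBC-I Generalized Born,
  Shrake–Rupley surface term γ·SASA with γ = 0.0072 kcal/mol/Å²), binding
  energies `ΔG = G_complex − G_A − G_B` with per-residue decomposition and a
  ≤ −2 kcal/mol hotspot report;
- **map contacts** (mean ligand heavy atoms within 4.5 Å per residue) and
  cluster bound poses by Jaccard distance between contact fingerprints;
- **cross-check compaction** against ion mobility via projection-approximation
  collision cross sections (orientation-averaged shadow area);
- **generate synthetic ensembles**: seeded pivot/crankshaft Monte-Carlo bead
  chains with a hydrophobic-collapse knob, two-state mixtures, planted
  ligands, and a toy complex with stored brute-force oracle energies.

Everything is deterministic given a seed, and every non-trivial number the
pipeline produces is checked against an independent oracle (closed forms,
scalar transcriptions, dense grids, O(n³) reference algorithms) in the test
suite.

## Worked example

Run the analysis drivers in order (each is a thin script over the library):

```bash
python analysis/01_tile_and_profile.py
python analysis/02_simulate_ensembles.py
python analysis/03_switch_screen.py
python analysis/04_binding_energy.py
python analysis/05_contacts_and_ccs.py
```

The first driver tiles the shipped canonical 439-residue human c-MYC
sequence:

```
439-residue sequence -> 9 non-overlapping tiles (last: MYC_401-439, 39 aa) + 8 frame-shifted tiles
   MYC_101-150: 0.50  <- core epitope
hydropathy vs disorder-proxy correlation: r = -0.768
```

i.e. the 101–150 tile is exactly half hydrophobic-and-bulky — the highest of
all nine tiles — and hydropathy anti-correlates with predicted disorder along
the sequence, the signature of a hydrophobically collapsing region inside an
otherwise polar IDP.

The screen driver plants one switching tile in a nine-tile synthetic screen
(broad two-state reference that collapses under the emulated probe; all other
tiles get two independent compact draws) and recovers exactly it:

```
       tile  ref_mean  pert_mean  spread_reduction  tail_depletion  ks_d  flagged
MYC_101-150    14.868      9.318             0.795           0.447 0.500     True
MYC_151-200    13.398      9.439            -0.729           0.033 0.973    False
...
flagged tiles: MYC_101-150
```

Note the tile below it: a KS distance of 0.97 between two *same-condition*
draws — mean shifts between independent globule samples are cheap, which is
why flagging requires tail depletion and spread reduction too.

The binding driver scores the toy two-chain complex:

```
dG_bind = -9.23 ± 3.71 kcal/mol (n = 20 frames; oracle -9.23, |diff| = 1.8e-15)
residues with contribution <= -2 kcal/mol:
  A:LYS1: -2.67 ± 0.74   A:GLU3: -2.64 ± 0.77
  B:GLU101: -2.68 ± 0.84  B:LYS103: -2.56 ± 0.82
```

recovering the four planted interface charges, and the CCS driver orders the
ensembles by compaction (`compact 537 ± 9 Å², extended 989 ± 53 Å²`).

A `tileswitch` CLI wraps the same library
(`tile`, `profile`, `rg`, `screen`, `energy`, `contacts`, `ccs`, `simulate`,
`probe-count`, `manifest`); see `tileswitch --help`.

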