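# kinactive

Structural criteria for the **catalytically active, substrate-binding-competent
conformation of typical protein kinase domains**, packaged as a reusable
classifier with supporting tools for scoring predicted models, detecting
substrate/autophosphorylation poses in crystals, and benchmarking
activation-loop geometry.

## Who this is for

Structural biologists and computational chemists who need to know whether a
kinase structure — an experimental PDB chain or an AlphaFold-style model — is
in a conformation that could actually bind ATP, Mg²⁺ **and substrate**. The
widely used DFGin/BLAminus/salt-bridge tests cover the nucleotide site but
say nothing about the activation-loop segments that form the substrate
groove; many "active" structures in the literature would in fact occlude
substrate.

## The classifier

A chain is labeled **Active** only if all applicable criteria hold
(**Inactive** if any fails; **None** if undecidable from the resolved atoms):

1. **Spatial (DFGin)** — the DFG-Phe anchor atom (Cζ) is near the C-helix
   Glu4 Cα (≤ 11 Å) and far from the β3-Lys Cα (≥ 11 Å).
2. **Dihedral (BLAminus)** — Ramachandran regions of the X-D-F residues of
   the XDFG motif are B, L, A and the Phe χ1 is gauche-minus
   (χ1 ∈ (−120°, 0°)). Regions: A = φ∈(−180,0), ψ∈(−100,50];
   B = φ∈(−180,0), ψ∈(50,180]; L = φ∈(0,180], ψ∈(−50,100].
3. **Salt bridge** — min(Nζ–Oε1, Nζ–Oε2) between β3-Lys and C-helix-Glu
   < 3.6 Å (skipped for WNK1–4, MAP3K12/13).
4. **HRD** — HRD-His backbone in region A, HRD-Arg in region L (skipped for
   kinases lacking the αF-helix Asp: PIM1–3, HASPIN, PKDCC, AATK, LMTK2/3).
5. **ActLoopNT** — backbone–backbone hydrogen bond between activation-loop
   residue 6 (DFGxxX) and the residue before the HRD motif:
   min(N–O, O–N) < 3.6 Å.
6. **ActLoopCT** — the substrate-facing C-terminal segment of the loop,
   indexed backwards from the APE Glu (APE1): APE7/APE6 in regions (A,A) or
   the peptide-flipped (B,L); APE8 in region B; then per group —
   *non-TYR*: APE8 χ1 g⁻ when Ser/Thr, APE9-Cα to HRD-Arg-O < 6 Å, and
   Cβ–Cα distances to DFG4 of APE10 < 8 Å, APE11 ∈ (8,14) Å,
   APE12 ∈ (7,14) Å; *TYR*: APE9/APE10 also in region B and the APE9
   distance bound relaxed to < 8 Å. Kinases without an APE motif
   (HASPIN, TP53RK, PKDCC) skip this criterion.

The regulatory-spine distances (HRD-His/DFG-Phe, DFG-Phe/Glu4, Glu4/HPN7)
are measured and reported but never enter the verdict.

For predicted models, the activation-loop confidence is the intramolecular
ipSAE score

```
ipSAE_actloop = max over i ∉ loop, pLDDT_i > 60  of
                mean over j ∈ loop of 1 / (1 + (PAE_ij / d0)²),   d0 = 4 Å
```

and `select_best_model` picks the highest-scoring candidate that the
classifier labels Active.

## Worked example

Generate synthetic kinase fixtures and classify them:

```sh
$ kinactive fixture --out-dir demo --seed 0
$ kinactive classify -s demo/all_pass.pdb -s demo/violate_saltbr.pdb \
      -m demo/motif_map.csv
# kinactive 0.1.0 config 9241ede96c15
entry_id  kinase_id  chain_id  label     spatial  spatial_label  dihedral  dihedral_label  saltbr  saltbr_value ...
all_pass        CAMK_TOY1  A  Active    in  DFGin  in  BLAminus  in   3.000
violate_saltbr  CAMK_TOY1  A  Inactive  in  DFGin  in  BLAminus  out  4.500
```

The first fixture satisfies every criterion (salt bridge 3.00 Å < 3.6 Å)
and is Active; the second realizes a 4.50 Å Lys–Glu distance, fails only
the salt-bridge criterion, and is Inactive. Scoring a synthetic PAE matrix
whose entries all equal d0 = 4 Å returns the closed-form value 0.5:

```sh
$ kinactive score --pae demo/pae.json --model demo/all_pass.pdb --loop 12:32
{"argmax_residue": 0, "d0": 4.0, "ipsae_actloop": 0.5, "n_aligned": 12}
```

The same operations are available as a library
(`kinactive.classify`, `kinactive.ipsae_actloop`,
`kinactive.substrate_contacts.find_phosphoacceptors`,
`kinactive.superpose_benchmark.actloop_rmsd`, ...).

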