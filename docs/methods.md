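# Methods

## Model of kinase activity

The package treats "active" as a *structural* property: a typical protein
kinase domain is active when its conformation is compatible with
simultaneously binding ATP·Mg²⁺ and a protein substrate. Six joint
criteria operationalize this. Three concern the nucleotide site — the
DFGin spatial class of the DFG-Phe ring, the BLAminus backbone/rotamer
state of the XDFG motif, and the β3-Lys/C-helix-Glu salt bridge — and
three concern the substrate groove: the HRD backbone conformation that
keeps the catalytic loop poised, an anti-parallel β-bridge hydrogen bond
that pins the activation-loop N-terminus (residue 6 of the loop against
the residue preceding the HRD motif), and a set of dihedral and distance
bounds on the loop's C-terminal segment (indexed APE12…APE5 backwards
from the APE Glu) that must form the P+1 pocket and the floor of the
binding groove. TYR-family kinases bind substrate as a short β-strand
rather than in a groove, so their C-terminal criteria differ: APE8–APE10
must sit in the β region, the APE9-Cα/HRD-Arg-O bound is relaxed from
6 Å to 8 Å, and no Cβ–Cα distance bounds are imposed on APE10–APE12.

The verdict is tri-state with fail-beats-missing precedence: any violated
criterion ⇒ Inactive, even if other criteria could not be measured;
otherwise any unmeasurable criterion ⇒ None; otherwise Active. Criteria
skipped by per-kinase exceptions (WNK and MAP3K12/13 for the salt bridge;
kinases without the αF-helix Asp for HRD; kinases without an APE motif for
ActLoopCT) count neither way. Pseudokinases are not auto-detected — the
caller marks them and receives `Pseudo-skip`.

## Parameters and units

All cutoffs live in `conformational_labels.Thresholds` (Å and degrees) and
are config-overridable from the CLI; the defaults are the published
criteria and are listed in the README. Two choices deserve comment:

* **Spatial cutoffs.** The DFGin/DFGout distances (Phe anchor to Glu4-Cα
  and β3-Lys-Cα) separate into clear clusters empirically; we use
  ≤ 11 Å / ≥ 11 Å for DFGin and > 11 Å / ≤ 14 Å for DFGout, with
  anything else DFGinter. These are deliberately exposed as configuration
  because the separation, not the exact number, carries the information.
* **Interval closure.** The Ramachandran boxes are written with open
  bounds; a deterministic partition needs the boundaries assigned.
  A owns ψ = 50, L owns φ = 180 and ψ = 100, B owns ψ = 180 with
  ψ = −180 wrapped onto it. Distance criteria use strict `<` for upper
  and strict `>` for lower bounds. Boundary cases have measure zero in
  practice; the assignment only guarantees reproducibility.

Other conventions: torsions follow the IUPAC sign convention (verified
against Biopython); χ1 is N–Cα–Cβ–Xγ with γ-atom priority
OG/OG1/CG/CG1/SG; when the DFG-Phe position holds a non-aromatic residue
the anchor is the side-chain heavy atom most distal from Cα; Gly at
APE10–APE12 gets a virtual Cβ from the standard tetrahedral construction;
altlocs collapse to the highest-occupancy conformer (ties → altloc A);
only the first model of multi-model files is read; hydrogens are ignored
throughout. Author residue numbering is canonical because motif maps are
quoted in author numbering.

## Motif maps

Criteria are anchored on conserved motifs whose residue numbers vary by
kinase, so the classifier takes a per-chain motif map (CSV/TSV/JSON) as
input, mirroring how curated alignments are used in practice. Activation
loop residues are addressed two-endedly: DFGn counts from the DFG Asp
(DFG1), APEn counts backwards from the APE Glu (APE1); this tolerates the
highly variable loop middle. A regex scan
(`detect_motifs_from_sequence`) can propose motif positions from sequence
but reports ambiguities instead of guessing — the His of "HRD" can be
Tyr/Phe/Leu and the Phe of "DFG" can be Leu/Tyr/Trp/Met/Val, so curated
input is authoritative. Built-in exception tables cover the known
salt-bridge, noAPE and αF-Asp special cases, keyed on the gene part of
the family-prefixed kinase id; explicit columns override them.

## Model confidence (ipSAE)

For predicted structures the activation-loop confidence is an
intramolecular ipSAE: over aligned residues i outside the loop with
pLDDT > 60, the maximum of the mean over loop residues j of
1/(1 + (PAE_ij/d0)²). d0 is fixed at 4 Å so scores are comparable across
kinases with different loop lengths. The printed formula uses a strict
pLDDT gate; a `strict_gate=False` switch admits residues at exactly the
threshold. PAE is read in the AlphaFold orientation (row = aligned
residue). Among candidate models, selection restricts to Active labels
and takes the highest score, breaking exact ties by lexicographic model
name for determinism. Residues outside the motif map's domain span are
simply absent from the index map and never scored.

## Substrate and autophosphorylation detection

Candidate phosphoacceptor poses are Ser/Thr/Tyr hydroxyl oxygens within
4.5 Å (heavy atom) of the HRD-Asp carboxylate of a mapped kinase chain in
a different monomer. Crystal packing is handled by expanding all
space-group operator images of every chain over the 3×3×3 block of unit
cells (identity-at-origin excluded); symmetry images of the enzyme's own
chain count as distinct monomers, which is how autophosphorylation dimers
are found. Phospho-forms (SEP/TPO/PTR) count as their parent residue when
the hydroxyl oxygen is present. Activation-loop-swapped dimers are
excluded geometrically: a partner hydroxyl within 1.5 Å of the enzyme's
own APE8 γ-oxygen site (measured, or reconstructed from the ideal Cβ
direction when absent) occupies the intramolecular "from below" position
and is flagged as a swap, not a substrate. The 1.5 Å operationalization is
a declared heuristic and configurable. Contact maps count heavy-atom
pairs within 5 Å between substrate positions P−5…P+5 and loop residues
DFG1–DFG9 / APE15–APE1; averaging over structures reproduces the
per-loop-residue mean-contact convention with its ≥ 1 annotation level.

## Superposition and RMSD

Benchmark comparisons superpose on the Cα atoms of the 40 residues
C-terminal to the APE motif (requiring ≥ 20 shared pairs) using the SVD
superimposer, which always returns a proper rotation, then measure
backbone (N, Cα, C, O) RMSD of the activation loop without refitting.
Loop residues pair by their DFGn/APEn index, never by sequence alignment;
for loops of unequal length the `full` window truncates in the middle
(half the pairable residues from each end) and duplicated residues from
overlapping windows in short loops are counted once. Fixed windows:
`ntct` = first 9 + last 15 residues; `nt5ct15` = first 5 + last 15 (the
template-similarity screen).

## Synthetic study conditions

Every test runs on generated structures; nothing is downloaded. The toy
kinase favors geometric exactness over protein realism — the criteria are
local, so a main chain carrying the activation loop, a rigidly placed
catalytic-loop segment, and free-floating satellite residues for the
N-lobe motifs suffice. The main chain is grown from ideal internal
coordinates (NeRF), so every requested φ/ψ/χ1 is realized essentially
exactly; the dihedrals of the loop middle are then optimized by least
squares to hit the APE10/11/12-to-DFG4 Cβ–Cα distance targets. The
catalytic segment and satellites are placed by rigid-body least squares;
criteria defined as minima over atom pairs (salt bridge, the N–O/O–N
hydrogen bond, spine distances) get the minimum pinned to the requested
value with hinge terms that keep the competing pair at bay. The builder
re-measures everything afterwards and reports residuals; tests require
dihedrals within 1° and distances within 0.05 Å of the request, and
construction is deterministic for a given seed.

Default targets are the all-pass conformation: regions B/L/A with χ1 −60°
for X-D-F, salt bridge 3.0 Å, N-terminal hydrogen bond 2.9 Å, APE9
distance 4.0 Å (7.0 Å for the TYR preset), Cβ–Cα distances 7/10/11 Å —
each comfortably inside its bound, so a 0.05 Å coordinate-noise
robustness test cannot flip any criterion. Single-violation presets move
exactly one quantity across its cutoff (e.g. salt bridge to 4.5 Å,
APE10–DFG4 to 9 Å, Arg ψ into the β region). What passing these tests
shows is that the measurement and decision logic is correct; what it does
not show is performance on real structures, whose loops are continuous,
whose motifs are packed against a real C-lobe, and whose coordinates
carry experimental error. The exemplar acceptance test bridges that gap
by fetching real PDB entries and checking published salt-bridge distances
to ±0.02 Å, but it requires network access.

Synthetic prediction scores are uniform, two-block or seeded-random PAE
matrices with a pLDDT vector; the uniform profiles give closed-form ipSAE
values (PAE ≡ 0 → 1.0; PAE ≡ d0 → 0.5) used as anchors.

## Problem sizes and numerics

The default suite builds ~15 toy kinases (21-residue loops, optionally a
40-residue C-lobe tail), runs 1000-quadruple torsion-oracle comparisons
and a few hundred property-test examples; the acceptance script uses the
same sizes. Least-squares placements use multi-start (seeded) restarts
and accept residuals below 10⁻⁶ Å; superposition recovery is asserted to
10⁻⁶. Degenerate geometry (coincident or colinear points) raises a
typed `GeometryError` rather than returning NaN.

## Known limitations

* The classifier is only as good as its motif map; wrong residue
  addresses silently measure the wrong atoms. The sequence scanner
  mitigates but does not replace curation.
* "C-helix-in" as an independent concept is not implemented; the salt
  bridge distance is the only N-lobe closure measure (the underlying
  source defines no numeric C-helix criterion).
* The dihedral label is composed from region letters; the full cluster
  nomenclature beyond BLAminus/ABAminus-style strings is out of scope.
* Domain-swap exclusion is a geometric heuristic with a fixed 1.5 Å
  coincidence radius.
* noAPE kinases skip the entire C-terminal criterion; no substitute
  measure is attempted for their non-canonical loop ends.
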