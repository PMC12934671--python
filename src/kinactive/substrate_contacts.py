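"""Substrate and autophosphorylation pose detection, with crystal-symmetry expansion.

A candidate phosphoacceptor is a Ser/Thr/Tyr hydroxyl oxygen of one chain
within hydrogen-bonding distance (4.5 A, heavy atoms) of the HRD-Asp
carboxylate of a mapped kinase chain in a *different* monomer - either
another chain of the asymmetric unit or a symmetry image from the 3x3x3
block of unit cells.  Activation-loop-swapped dimers are excluded by a
geometric signature: the swapped hydroxyl occupies the enzyme's own
intramolecular APE8 gamma-oxygen site, approaching the Asp from below.

Contact maps count heavy-atom pairs within 5 A between substrate residues
P-5..P+5 and activation-loop residues addressed as DFG1..DFG9 and
APE15..APE1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from kinactive.geometry import virtual_cbeta, GeometryError
from kinactive.motif_map import KinaseMotifMap, actloop_index
from kinactive.structure_model import (
    StructureModel,
    Residue,
    SymmetryCopy,
    expand_crystal_neighbors,
    CapabilityError,
    MODIFIED_PARENT,
)

__all__ = [
    "PhosphoacceptorHit",
    "ContactMap",
    "find_phosphoacceptors",
    "flag_domain_swap",
    "contact_map",
    "average_contacts",
    "SEARCH_CUTOFF",
    "CONTACT_CUTOFF",
]

SEARCH_CUTOFF = 4.5  # hydroxyl-to-HRD-Asp heavy-atom search distance, A
CONTACT_CUTOFF = 5.0  # any-atom substrate/activation-loop contact distance, A
SWAP_SITE_CUTOFF = 1.5  # hydroxyl within this distance of the APE8 O-gamma site, A

_HYDROXYL_ATOMS = {"SER": "OG", "THR": "OG1", "TYR": "OH"}

SUBSTRATE_POSITIONS = list(range(-5, 6))  # P-5 .. P+5
LOOP_LABELS = [f"DFG{n}" for n in range(1, 10)] + [f"APE{n}" for n in range(15, 0, -1)]


@dataclass
class PhosphoacceptorHit:
    enzyme_chain: str
    substrate_chain: str
    substrate_seqnum: int
    substrate_type: str  # SER | THR | TYR
    d_oh_asp: float
    is_symmetry_mate: bool = False
    operator_index: int | None = None
    lattice_offset: tuple[int, int, int] | None = None
    swap_flag: bool | None = None


@dataclass
class ContactMap:
    counts: np.ndarray  # substrate position x loop label
    n_structures: int = 1

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        expected = (len(SUBSTRATE_POSITIONS), len(LOOP_LABELS))
        if self.counts.shape != expected:
            raise ValueError(f"contact matrix must have shape {expected}")


def _hydroxyl(res: Residue):
    """(parent_type, hydroxyl O position) for Ser/Thr/Tyr and their phospho-forms."""
    parent = MODIFIED_PARENT.get(res.name, res.name)
    name = _HYDROXYL_ATOMS.get(parent)
    if name is None:
        return None
    at = res.atom(name)
    if at is None:
        return None
    return parent, at.position


def _hrd_asp_oxygens(model: StructureModel, m: KinaseMotifMap):
    res = model.residue(m.chain_id, m.res_hrd_asp)
    if res is None:
        return []
    return [a.position for a in res.atoms if a.name in {"OD1", "OD2"}]


def find_phosphoacceptors(
    model: StructureModel,
    maps,
    use_symmetry: bool = True,
    cutoff: float = SEARCH_CUTOFF,
) -> list[PhosphoacceptorHit]:
    """Hydroxyl groups of one monomer near the HRD-Asp carboxylate of another.

    ``maps`` is one :class:`KinaseMotifMap` or a list (one per kinase
    chain).  With ``use_symmetry`` and crystal records present, the 3x3x3
    block of neighboring cells is searched; symmetry images of the enzyme
    chain itself count as distinct monomers.
    """
    if isinstance(maps, KinaseMotifMap):
        maps = [maps]
    hits: list[PhosphoacceptorHit] = []
    any_asp = False

    copies: list[SymmetryCopy] = []
    if use_symmetry:
        try:
            copies = expand_crystal_neighbors(model, shell=1)
        except CapabilityError:
            copies = []  # fall back to the deposited asymmetric unit

    for m in maps:
        asp_oxy = _hrd_asp_oxygens(model, m)
        if not asp_oxy:
            continue
        any_asp = True
        asp = np.asarray(asp_oxy)

        def scan(residues, chain_id, sym=False, op=None, off=None):
            for res in residues:
                if chain_id == m.chain_id and not sym:
                    continue  # same monomer: intramolecular contacts excluded
                hyd = _hydroxyl(res)
                if hyd is None:
                    continue
                parent, pos = hyd
                d = float(np.sqrt(((asp - pos) ** 2).sum(axis=1).min()))
                if d < cutoff:
                    hits.append(
                        PhosphoacceptorHit(
                            enzyme_chain=m.chain_id,
                            substrate_chain=chain_id,
                            substrate_seqnum=res.seqnum,
                            substrate_type=parent,
                            d_oh_asp=d,
                            is_symmetry_mate=sym,
                            operator_index=op,
                            lattice_offset=off,
                        )
                    )

        for cid, residues in model.chains.items():
            scan(residues, cid)
        for copy in copies:
            scan(copy.residues, copy.chain_id, sym=True, op=copy.op_index,
                 off=copy.lattice_offset)

    if not any_asp:
        raise ValueError("no mapped kinase chain with HRD-Asp side-chain oxygens")
    hits.sort(key=lambda h: (h.enzyme_chain, h.substrate_chain, h.substrate_seqnum, h.d_oh_asp))
    return hits


def _ape8_gamma_site(model: StructureModel, m: KinaseMotifMap) -> np.ndarray | None:
    """The enzyme's own APE8 gamma-oxygen position, measured or reconstructed.

    When APE8 is present but lacks a gamma oxygen (or the residue is
    missing its side chain) the site is approximated by the ideal C-beta
    direction extended to gamma-atom range, which is sufficient for the
    1.5 A coincidence test.
    """
    if m.group == "noAPE":
        return None
    try:
        seq = actloop_index(m, "APE8")
    except (IndexError, ValueError):
        return None
    res = model.residue(m.chain_id, seq)
    if res is None:
        return None
    for name in ("OG", "OG1"):
        at = res.atom(name)
        if at is not None:
            return at.position
    n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
    if None in (n, ca, c):
        return None
    try:
        cb = virtual_cbeta(n.position, ca.position, c.position)
    except GeometryError:
        return None
    # extend CA->CB by a C-O bond length to approximate the gamma position
    direction = cb - ca.position
    direction /= np.linalg.norm(direction)
    return cb + 1.42 * direction


def flag_domain_swap(
    hit: PhosphoacceptorHit,
    model: StructureModel,
    enzyme_map: KinaseMotifMap,
    substrate_position: np.ndarray,
    site_cutoff: float = SWAP_SITE_CUTOFF,
) -> bool | None:
    """True iff the candidate hydroxyl occupies the enzyme's own APE8 gamma-O site.

    In activation-loop-swapped dimers the partner's hydroxyl approaches the
    HRD-Asp from below, superposing on the position normally held by the
    enzyme's intramolecular APE8 hydroxyl; such hits are not substrates.
    Returns ``None`` (indeterminate) when the site cannot be located - the
    hit is then retained with a warning by callers.
    """
    site = _ape8_gamma_site(model, enzyme_map)
    if site is None:
        return None
    d = float(np.linalg.norm(np.asarray(substrate_position, dtype=float) - site))
    flagged = d < site_cutoff  # strict: exactly at the cutoff is not a swap
    hit.swap_flag = flagged
    return flagged


def contact_map(
    model: StructureModel,
    enzyme_map: KinaseMotifMap,
    substrate_chain: str,
    p0: int,
    substrate_residues: list[Residue] | None = None,
    cutoff: float = CONTACT_CUTOFF,
) -> ContactMap:
    """Heavy-atom contact counts between substrate P-5..P+5 and the activation loop.

    ``p0`` is the phosphoacceptor seqnum in the substrate chain; positions
    without a resolved residue contribute zero.  ``substrate_residues``
    allows counting against a placed symmetry copy instead of the deposited
    chain.
    """
    if substrate_residues is None:
        substrate_residues = model.chains.get(substrate_chain, [])
    sub_by_num = {r.seqnum: r for r in substrate_residues}
    enzyme_chain = {r.seqnum: r for r in model.chains.get(enzyme_map.chain_id, [])
                    if not r.hetero}

    counts = np.zeros((len(SUBSTRATE_POSITIONS), len(LOOP_LABELS)))
    for si, offset in enumerate(SUBSTRATE_POSITIONS):
        sres = sub_by_num.get(p0 + offset)
        if sres is None:
            continue
        s_pos = np.asarray([a.position for a in sres.atoms])
        for li, label in enumerate(LOOP_LABELS):
            try:
                seq = actloop_index(enzyme_map, label)
            except (IndexError, ValueError):
                continue
            lres = enzyme_chain.get(seq)
            if lres is None:
                continue
            l_pos = np.asarray([a.position for a in lres.atoms])
            d2 = ((s_pos[:, None, :] - l_pos[None, :, :]) ** 2).sum(axis=-1)
            counts[si, li] = int((d2 < cutoff**2).sum())
    return ContactMap(counts=counts, n_structures=1)


def average_contacts(maps: list[ContactMap]) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell and per-loop-residue mean contact counts over structures.

    Returns ``(cell_means, loop_residue_means)`` where the second array is
    the per-structure mean of contacts summed over substrate positions
    (the quantity whose >= 1 level marks the substrate-engaged loop
    residues).
    """
    if not maps:
        raise ValueError("no contact maps to average")
    shapes = {cm.counts.shape for cm in maps}
    if len(shapes) != 1:
        raise ValueError("contact maps have mismatched axes")
    stack = np.stack([cm.counts for cm in maps])
    cell_means = stack.mean(axis=0)
    loop_means = stack.sum(axis=1).mean(axis=0)
    return cell_means, loop_means
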