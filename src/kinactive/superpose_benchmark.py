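"""C-terminal-domain superposition and activation-loop backbone RMSD.

Benchmarking convention: two kinase chains are superposed on the C-alpha
atoms of the 40 residues C-terminal to the APE motif (the structurally
rigid C-lobe window), then the RMSD of the activation-loop backbone
(N, CA, C, O) is measured without refitting.  Loop residues are paired by
their two-ended index (DFGn with DFGn, APEn with APEn), which tolerates
length differences in the flexible loop middle.

Windows:

* ``full``    - the whole DFG..APE span (middle truncated for unequal loops)
* ``ntct``    - first 9 (DFG1-9) and last 15 (APE15-1) residues
* ``nt5ct15`` - first 5 and last 15 residues (template-similarity screen)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.SVDSuperimposer import SVDSuperimposer

from kinactive.motif_map import KinaseMotifMap, actloop_index
from kinactive.structure_model import StructureModel

__all__ = ["SuperpositionResult", "superpose_ctd", "actloop_rmsd", "InsufficientOverlap"]

BACKBONE_ATOMS = ("N", "CA", "C", "O")
CTD_WINDOW = 40
MIN_CTD_PAIRS = 20


class InsufficientOverlap(ValueError):
    """Too few shared atoms to fit or measure."""


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    fit_rmsd: float
    n_fit_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _ca_pairs_ctd(mobile, reference, map_mobile, map_reference):
    """Paired CA coordinates over the [APE1+1, APE1+40] window."""
    mob_chain = {r.seqnum: r for r in mobile.chains.get(map_mobile.chain_id, [])
                 if not r.hetero}
    ref_chain = {r.seqnum: r for r in reference.chains.get(map_reference.chain_id, [])
                 if not r.hetero}
    mob_pts, ref_pts = [], []
    for k in range(1, CTD_WINDOW + 1):
        rm = mob_chain.get(map_mobile.res_ape_glu + k)
        rr = ref_chain.get(map_reference.res_ape_glu + k)
        if rm is None or rr is None:
            continue
        am, ar = rm.atom("CA"), rr.atom("CA")
        if am is None or ar is None:
            continue
        mob_pts.append(am.position)
        ref_pts.append(ar.position)
    return np.asarray(mob_pts), np.asarray(ref_pts)


def superpose_ctd(
    mobile: StructureModel,
    reference: StructureModel,
    map_mobile: KinaseMotifMap,
    map_reference: KinaseMotifMap,
) -> SuperpositionResult:
    """Least-squares rigid fit of the mobile C-lobe window onto the reference.

    Uses the SVD superimposer, which always returns a proper rotation
    (determinant +1); mirror-related inputs therefore fit with a large
    residual instead of an improper transform.
    """
    mob, ref = _ca_pairs_ctd(mobile, reference, map_mobile, map_reference)
    if len(mob) < MIN_CTD_PAIRS:
        raise InsufficientOverlap(
            f"only {len(mob)} shared C-alpha pairs in the C-terminal-domain window "
            f"(need >= {MIN_CTD_PAIRS})"
        )
    sup = SVDSuperimposer()
    sup.set(ref, mob)  # superimpose mobile (second arg) onto reference
    sup.run()
    rot, tran = sup.get_rotran()
    # SVDSuperimposer applies y*rot + tran with row vectors; store as x -> R x + t
    rotation = np.asarray(rot).T
    translation = np.asarray(tran)
    return SuperpositionResult(
        rotation=rotation,
        translation=translation,
        fit_rmsd=float(sup.get_rms()),
        n_fit_atoms=len(mob),
    )


def _window_labels(mode: str, loop_len_a: int, loop_len_b: int) -> list[str]:
    if mode == "ntct":
        nt, ct = 9, 15
    elif mode == "nt5ct15":
        nt, ct = 5, 15
    elif mode == "full":
        n = min(loop_len_a, loop_len_b)
        nt = (n + 1) // 2
        ct = n - nt
    else:
        raise ValueError(f"unknown RMSD mode {mode!r}")
    return [f"DFG{i}" for i in range(1, nt + 1)] + [f"APE{i}" for i in range(ct, 0, -1)]


def actloop_rmsd(
    mobile: StructureModel,
    reference: StructureModel,
    map_mobile: KinaseMotifMap,
    map_reference: KinaseMotifMap,
    mode: str = "full",
    superposition: SuperpositionResult | None = None,
) -> tuple[float, int]:
    """Backbone RMSD of the activation loop after C-lobe superposition.

    Returns ``(rmsd, n_paired_atoms)``.  Atom pairs are assembled from the
    DFGn/APEn windows of ``mode``; duplicate residues arising from
    overlapping windows in short loops are counted once.
    """
    if superposition is None:
        superposition = superpose_ctd(mobile, reference, map_mobile, map_reference)

    labels = _window_labels(mode, map_mobile.loop_length, map_reference.loop_length)
    mob_chain = {r.seqnum: r for r in mobile.chains.get(map_mobile.chain_id, [])
                 if not r.hetero}
    ref_chain = {r.seqnum: r for r in reference.chains.get(map_reference.chain_id, [])
                 if not r.hetero}

    mob_pts, ref_pts = [], []
    seen: set[tuple[int, int]] = set()
    for label in labels:
        try:
            sm = actloop_index(map_mobile, label)
            sr = actloop_index(map_reference, label)
        except (IndexError, ValueError):
            continue
        if (sm, sr) in seen:
            continue
        seen.add((sm, sr))
        rm, rr = mob_chain.get(sm), ref_chain.get(sr)
        if rm is None or rr is None:
            continue
        for atom_name in BACKBONE_ATOMS:
            am, ar = rm.atom(atom_name), rr.atom(atom_name)
            if am is None or ar is None:
                continue
            mob_pts.append(am.position)
            ref_pts.append(ar.position)
    if not mob_pts:
        raise InsufficientOverlap("no paired activation-loop backbone atoms")
    mob_arr = superposition.apply(np.asarray(mob_pts))
    ref_arr = np.asarray(ref_pts)
    rmsd = float(np.sqrt(np.mean(np.sum((mob_arr - ref_arr) ** 2, axis=1))))
    return rmsd, len(mob_pts)
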