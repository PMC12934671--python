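"""The six activity criteria and the structural features behind them.

For one kinase chain, this module measures 26 structural features
(distances, backbone dihedral regions, side-chain rotamers) and turns them
into six criterion states:

1. ``spatial``   - DFGin/DFGout/DFGinter label of the DFG-Phe position
2. ``dihedral``  - XDF Ramachandran-region label plus Phe chi1 rotamer
                   (BLAminus is the catalytically competent state)
3. ``saltbr``    - beta3-Lys Nz to C-helix-Glu Oe distance < 3.6 A
4. ``hrd``       - HRD His/Arg backbone in the A and L regions
5. ``actloopNT`` - DFG6/XHRD backbone-backbone hydrogen bond < 3.6 A
6. ``actloopCT`` - APE5-helix dihedrals, APE8 region/rotamer, and the
                   APE9-APE12 distance bounds (group dependent)

All numeric cutoffs live in :class:`Thresholds` and can be overridden; the
defaults are the published criteria.  The regulatory-spine distances are
measured and reported but are never part of the Active decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from kinactive.geometry import (
    dihedral,
    rama_region,
    chi1_minus,
    rotamer_word,
    min_pair_distance,
    virtual_cbeta,
    GeometryError,
)
from kinactive.motif_map import KinaseMotifMap, actloop_index
from kinactive.structure_model import StructureModel, Residue

__all__ = [
    "Thresholds",
    "FeatureVector",
    "CriterionState",
    "compute_features",
    "spatial_dfg_label",
    "dihedral_xdf_label",
    "saltbridge_state",
    "actloopNT_state",
    "hrd_state",
    "actloopCT_state",
    "spine_distances",
    "evaluate_criteria",
]

BACKBONE = {"N", "CA", "C", "O", "OXT"}

# gamma-atom priority for chi1 (N-CA-CB-Xgamma)
_GAMMA_PRIORITY = ("OG", "OG1", "CG", "CG1", "SG")


@dataclass(frozen=True)
class Thresholds:
    """All numeric cutoffs of the classifier, defaulting to the published criteria."""

    saltbridge_max: float = 3.6
    nt_hbond_max: float = 3.6
    # spatial (DFGin/out/inter) cutoffs on the Phe anchor distances
    spatial_glu4_max: float = 11.0
    spatial_lys_min: float = 11.0
    spatial_out_lys_max: float = 14.0
    # ActLoopCT distance bounds
    ape9_hrdarg_max_nontyr: float = 6.0
    ape9_hrdarg_max_tyr: float = 8.0
    ape10_dfg4_max: float = 8.0
    ape11_dfg4_min: float = 8.0
    ape11_dfg4_max: float = 14.0
    ape12_dfg4_min: float = 7.0
    ape12_dfg4_max: float = 14.0
    spine_max: float = 5.0


DEFAULT_THRESHOLDS = Thresholds()


@dataclass
class FeatureVector:
    """All measured quantities behind the six criteria (None = unmeasurable)."""

    d_phe_glu4: float | None = None
    d_phe_lys: float | None = None
    xdf_regions: tuple[str, str, str] = ("none", "none", "none")
    phe_chi1: float | None = None
    d_saltbridge: float | None = None
    saltbridge_atypical: bool = False
    d_dfg6_xhrd: float | None = None
    hrd_his_region: str = "none"
    hrd_arg_region: str = "none"
    ape7_region: str = "none"
    ape6_region: str = "none"
    ape8_region: str = "none"
    ape9_region: str = "none"
    ape10_region: str = "none"
    ape8_chi1: float | None = None
    ape8_restype: str | None = None
    d_ape9ca_hrdargO: float | None = None
    d_ape10cb_dfg4ca: float | None = None
    d_ape11cb_dfg4ca: float | None = None
    d_ape12cb_dfg4ca: float | None = None
    spine1: float | None = None
    spine2: float | None = None
    spine3: float | None = None

    def as_row(self) -> dict:
        """Flat dict suitable for one TSV row."""
        d = asdict(self)
        x, dd, f = d.pop("xdf_regions")
        d["xdfg_x_region"] = x
        d["dfg_asp_region"] = dd
        d["dfg_phe_region"] = f
        return d


@dataclass
class CriterionState:
    name: str
    state: str  # in | out | none | skipped
    value: float | None = None
    detail: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# residue / dihedral plumbing


def _chain_by_seqnum(model: StructureModel, chain_id: str) -> dict[int, Residue]:
    return {r.seqnum: r for r in model.chains.get(chain_id, []) if not r.hetero}


def _phi_psi(chain: dict[int, Residue], seqnum: int) -> tuple[float | None, float | None]:
    res = chain.get(seqnum)
    prev = chain.get(seqnum - 1)
    nxt = chain.get(seqnum + 1)
    phi = psi = None
    if res is not None:
        n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
        if prev is not None and prev.atom("C") is not None and None not in (n, ca, c):
            try:
                phi = dihedral(prev.atom("C").position, n.position, ca.position, c.position)
            except GeometryError:
                phi = None
        if nxt is not None and nxt.atom("N") is not None and None not in (n, ca, c):
            try:
                psi = dihedral(n.position, ca.position, c.position, nxt.atom("N").position)
            except GeometryError:
                psi = None
    return phi, psi


def _chi1(res: Residue | None) -> float | None:
    if res is None or res.name in {"ALA", "GLY"}:
        return None
    n, ca, cb = res.atom("N"), res.atom("CA"), res.atom("CB")
    if None in (n, ca, cb):
        return None
    gamma = None
    for nm in _GAMMA_PRIORITY:
        gamma = res.atom(nm)
        if gamma is not None:
            break
    if gamma is None:
        return None
    try:
        return dihedral(n.position, ca.position, cb.position, gamma.position)
    except GeometryError:
        return None


def _sidechain_positions(res: Residue | None, include_ca_for_small: bool = False):
    if res is None:
        return []
    side = [a.position for a in res.atoms if a.name not in BACKBONE]
    if not side and include_ca_for_small and res.atom("CA") is not None:
        side = [res.atom("CA").position]
    return side


def _phe_anchor(res: Residue | None) -> np.ndarray | None:
    """Anchor atom of the DFG-Phe position: Cz for Phe/Tyr, else the side-chain
    heavy atom most distal from CA."""
    if res is None:
        return None
    if res.name in {"PHE", "TYR"}:
        cz = res.atom("CZ")
        if cz is not None:
            return cz.position
    ca = res.atom("CA")
    side = _sidechain_positions(res)
    if ca is None or not side:
        return None
    dists = [np.linalg.norm(p - ca.position) for p in side]
    return side[int(np.argmax(dists))]


def _cbeta_or_virtual(res: Residue | None) -> np.ndarray | None:
    if res is None:
        return None
    cb = res.atom("CB")
    if cb is not None:
        return cb.position
    n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
    if None in (n, ca, c):
        return None
    try:
        return virtual_cbeta(n.position, ca.position, c.position)
    except GeometryError:
        return None


def _loop_res(chain: dict[int, Residue], m: KinaseMotifMap, label: str) -> Residue | None:
    try:
        return chain.get(actloop_index(m, label))
    except IndexError:
        return None


# ---------------------------------------------------------------------------
# feature computation


def compute_features(
    model: StructureModel, m: KinaseMotifMap, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> FeatureVector:
    """Measure every structural feature used by the criteria for one chain."""
    chain = _chain_by_seqnum(model, m.chain_id)
    fv = FeatureVector()

    phe = _loop_res(chain, m, "DFG2")
    anchor = _phe_anchor(phe)
    glu4 = chain.get(m.res_glu4) if m.res_glu4 is not None else None
    lys = chain.get(m.res_saltbridge_lys) if m.res_saltbridge_lys is not None else None
    if anchor is not None and glu4 is not None and glu4.atom("CA") is not None:
        fv.d_phe_glu4 = float(np.linalg.norm(anchor - glu4.atom("CA").position))
    if anchor is not None and lys is not None and lys.atom("CA") is not None:
        fv.d_phe_lys = float(np.linalg.norm(anchor - lys.atom("CA").position))

    # XDF dihedral regions: residue before DFG, DFG-Asp, DFG-Phe
    x_seq = m.res_dfg_asp - 1
    fv.xdf_regions = (
        rama_region(*_phi_psi(chain, x_seq)),
        rama_region(*_phi_psi(chain, m.res_dfg_asp)),
        rama_region(*_phi_psi(chain, m.res_dfg_asp + 1)),
    )
    fv.phe_chi1 = _chi1(phe)

    # salt bridge
    if lys is not None:
        glu = chain.get(m.res_saltbridge_glu) if m.res_saltbridge_glu is not None else None
        if glu is not None:
            donors = [a.position for a in lys.atoms if a.name == "NZ"]
            acceptors = [a.position for a in glu.atoms if a.name in {"OE1", "OE2"}]
            if not donors:
                donors = [a.position for a in lys.atoms if a.element == "N" and a.name != "N"]
                fv.saltbridge_atypical = bool(donors)
            if not acceptors:
                acceptors = [
                    a.position
                    for a in glu.atoms
                    if a.element == "O" and a.name not in {"O", "OXT"}
                ]
                fv.saltbridge_atypical = fv.saltbridge_atypical or bool(acceptors)
            fv.d_saltbridge = min_pair_distance(donors, acceptors)

    # ActLoopNT: DFG6 <-> XHRD backbone hydrogen bond (min of N-O and O-N)
    dfg6 = _loop_res(chain, m, "DFG6")
    xhrd = chain.get(m.res_xhrd)
    if dfg6 is not None and xhrd is not None:
        pairs = []
        if dfg6.atom("N") is not None and xhrd.atom("O") is not None:
            pairs.append(np.linalg.norm(dfg6.atom("N").position - xhrd.atom("O").position))
        if dfg6.atom("O") is not None and xhrd.atom("N") is not None:
            pairs.append(np.linalg.norm(dfg6.atom("O").position - xhrd.atom("N").position))
        if pairs:
            fv.d_dfg6_xhrd = float(min(pairs))

    fv.hrd_his_region = rama_region(*_phi_psi(chain, m.res_hrd_his))
    fv.hrd_arg_region = rama_region(*_phi_psi(chain, m.res_hrd_arg))

    # ActLoopCT features (meaningless for noAPE maps but harmless to measure)
    if m.group != "noAPE":
        for n_ape in (6, 7, 8, 9, 10):
            res = _loop_res(chain, m, f"APE{n_ape}")
            if res is not None:
                region = rama_region(*_phi_psi(chain, res.seqnum))
            else:
                region = "none"
            setattr(fv, f"ape{n_ape}_region", region)
        ape8 = _loop_res(chain, m, "APE8")
        if ape8 is not None:
            fv.ape8_restype = ape8.name
            fv.ape8_chi1 = _chi1(ape8)

        hrd_arg = chain.get(m.res_hrd_arg)
        ape9 = _loop_res(chain, m, "APE9")
        if (
            ape9 is not None
            and ape9.atom("CA") is not None
            and hrd_arg is not None
            and hrd_arg.atom("O") is not None
        ):
            fv.d_ape9ca_hrdargO = float(
                np.linalg.norm(ape9.atom("CA").position - hrd_arg.atom("O").position)
            )

        dfg4 = _loop_res(chain, m, "DFG4")
        dfg4_ca = dfg4.atom("CA").position if dfg4 is not None and dfg4.atom("CA") else None
        if dfg4_ca is not None:
            for n_ape in (10, 11, 12):
                cb = _cbeta_or_virtual(_loop_res(chain, m, f"APE{n_ape}"))
                if cb is not None:
                    setattr(
                        fv,
                        f"d_ape{n_ape}cb_dfg4ca",
                        float(np.linalg.norm(cb - dfg4_ca)),
                    )

    # regulatory spine (reported only)
    his = chain.get(m.res_hrd_his)
    hpn7 = chain.get(m.res_hpn7) if m.res_hpn7 is not None else None
    s_his = _sidechain_positions(his, include_ca_for_small=True)
    s_phe = _sidechain_positions(phe, include_ca_for_small=True)
    s_glu4 = _sidechain_positions(glu4, include_ca_for_small=True)
    s_hpn7 = _sidechain_positions(hpn7, include_ca_for_small=True)
    fv.spine1 = min_pair_distance(s_his, s_phe)
    fv.spine2 = min_pair_distance(s_phe, s_glu4)
    fv.spine3 = min_pair_distance(s_glu4, s_hpn7)

    return fv


# ---------------------------------------------------------------------------
# criteria


def spatial_dfg_label(
    model: StructureModel,
    m: KinaseMotifMap,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    features: FeatureVector | None = None,
) -> str | None:
    """DFGin / DFGout / DFGinter from the DFG-Phe anchor distances; None if unmeasurable."""
    fv = features or compute_features(model, m, thresholds)
    d_glu4, d_lys = fv.d_phe_glu4, fv.d_phe_lys
    if d_glu4 is None or d_lys is None:
        return None
    t = thresholds
    if d_glu4 <= t.spatial_glu4_max and d_lys >= t.spatial_lys_min:
        return "DFGin"
    if d_glu4 > t.spatial_glu4_max and d_lys <= t.spatial_out_lys_max:
        return "DFGout"
    return "DFGinter"


def dihedral_xdf_label(
    model: StructureModel,
    m: KinaseMotifMap,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    features: FeatureVector | None = None,
) -> str | None:
    """Region letters of (X, Asp, Phe) plus the Phe chi1 rotamer word.

    e.g. ``BLAminus``; any region outside A/B/L gives ``other``; any missing
    dihedral gives ``None``.
    """
    fv = features or compute_features(model, m, thresholds)
    regions = fv.xdf_regions
    if any(r == "none" for r in regions):
        return None
    word = rotamer_word(fv.phe_chi1)
    if word is None:
        return None
    if any(r == "other" for r in regions):
        return "other"
    return "".join(regions) + word


def saltbridge_state(
    model: StructureModel,
    m: KinaseMotifMap,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    features: FeatureVector | None = None,
) -> CriterionState:
    if m.skip_saltbridge:
        return CriterionState("saltbr", "skipped")
    fv = features or compute_features(model, m, thresholds)
    if fv.d_saltbridge is None:
        return CriterionState("saltbr", "none")
    state = "in" if fv.d_saltbridge < thresholds.saltbridge_max else "out"
    detail = {"atypical_atoms": fv.saltbridge_atypical} if fv.saltbridge_atypical else {}
    return CriterionState("saltbr", state, fv.d_saltbridge, detail)


def actloopNT_state(
    model: StructureModel,
    m: KinaseMotifMap,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    features: FeatureVector | None = None,
) -> CriterionState:
    fv = features or compute_features(model, m, thresholds)
    if fv.d_dfg6_xhrd is None:
        return CriterionState("actloopNT", "none")
    state = "in" if fv.d_dfg6_xhrd < thresholds.nt_hbond_max else "out"
    return CriterionState("actloopNT", state, fv.d_dfg6_xhrd)


def hrd_state(
    model: StructureModel,
    m: KinaseMotifMap,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    features: FeatureVector | None = None,
) -> CriterionState:
    if m.skip_hrd:
        return CriterionState("hrd", "skipped")
    fv = features or compute_features(model, m, thresholds)
    if fv.hrd_his_region == "none" or fv.hrd_arg_region == "none":
        return CriterionState("hrd", "none")
    state = "in" if (fv.hrd_his_region == "A" and fv.hrd_arg_region == "L") else "out"
    return CriterionState(
        "hrd", state, detail={"his": fv.hrd_his_region, "arg": fv.hrd_arg_region}
    )


def _ct_subfeatures(fv: FeatureVector, group: str, t: Thresholds) -> dict[str, str]:
    """Per-subfeature pass/fail/none states of the ActLoopCT criterion."""
    sub: dict[str, str] = {}

    # APE5 helix: APE7/APE6 in (A,A), or the Type-II-turn peptide flip (B,L)
    r7, r6 = fv.ape7_region, fv.ape6_region
    if r7 == "none" or r6 == "none":
        sub["APE7/6"] = "none"
    else:
        sub["APE7/6"] = "pass" if (r7, r6) in {("A", "A"), ("B", "L")} else "fail"

    sub["APE8"] = (
        "none" if fv.ape8_region == "none" else ("pass" if fv.ape8_region == "B" else "fail")
    )

    if group == "TYR":
        for n_ape, region in (("APE9", fv.ape9_region), ("APE10", fv.ape10_region)):
            sub[n_ape + "-dihe"] = (
                "none" if region == "none" else ("pass" if region == "B" else "fail")
            )
        d9 = fv.d_ape9ca_hrdargO
        sub["APE9-dist"] = (
            "none" if d9 is None else ("pass" if d9 < t.ape9_hrdarg_max_tyr else "fail")
        )
    else:  # nonTYR
        if fv.ape8_restype in {"SER", "THR"}:
            g = chi1_minus(fv.ape8_chi1)
            sub["APE8-chi1"] = "none" if g is None else ("pass" if g else "fail")
        d9 = fv.d_ape9ca_hrdargO
        sub["APE9-dist"] = (
            "none" if d9 is None else ("pass" if d9 < t.ape9_hrdarg_max_nontyr else "fail")
        )
        d10 = fv.d_ape10cb_dfg4ca
        sub["APE10"] = "none" if d10 is None else ("pass" if d10 < t.ape10_dfg4_max else "fail")
        d11 = fv.d_ape11cb_dfg4ca
        sub["APE11"] = (
            "none"
            if d11 is None
            else ("pass" if t.ape11_dfg4_min < d11 < t.ape11_dfg4_max else "fail")
        )
        d12 = fv.d_ape12cb_dfg4ca
        sub["APE12"] = (
            "none"
            if d12 is None
            else ("pass" if t.ape12_dfg4_min < d12 < t.ape12_dfg4_max else "fail")
        )
    return sub


def actloopCT_state(
    model: StructureModel,
    m: KinaseMotifMap,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    features: FeatureVector | None = None,
) -> CriterionState:
    if m.group == "noAPE":
        return CriterionState("actloopCT", "skipped")
    fv = features or compute_features(model, m, thresholds)
    sub = _ct_subfeatures(fv, m.group, thresholds)
    if any(v == "fail" for v in sub.values()):
        state = "out"
    elif any(v == "none" for v in sub.values()):
        state = "none"
    else:
        state = "in"
    return CriterionState("actloopCT", state, detail=sub)


def spine_distances(
    model: StructureModel,
    m: KinaseMotifMap,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    features: FeatureVector | None = None,
) -> tuple[float | None, float | None, float | None, bool | None]:
    """Regulatory-spine minimum side-chain distances (reported, never a criterion)."""
    fv = features or compute_features(model, m, thresholds)
    vals = (fv.spine1, fv.spine2, fv.spine3)
    if any(v is None for v in vals):
        return (*vals, None)
    return (*vals, all(v < thresholds.spine_max for v in vals))


def evaluate_criteria(
    model: StructureModel, m: KinaseMotifMap, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> tuple[list[CriterionState], FeatureVector]:
    """All six criterion states for one chain, sharing a single feature pass."""
    fv = compute_features(model, m, thresholds)

    spatial = spatial_dfg_label(model, m, thresholds, features=fv)
    if spatial is None:
        c_spatial = CriterionState("spatial", "none")
    else:
        c_spatial = CriterionState("spatial", "in" if spatial == "DFGin" else "out",
                                   detail={"label": spatial})

    dihe = dihedral_xdf_label(model, m, thresholds, features=fv)
    if dihe is None:
        c_dihe = CriterionState("dihedral", "none")
    else:
        c_dihe = CriterionState("dihedral", "in" if dihe == "BLAminus" else "out",
                                detail={"label": dihe})

    return (
        [
            c_spatial,
            c_dihe,
            saltbridge_state(model, m, thresholds, features=fv),
            hrd_state(model, m, thresholds, features=fv),
            actloopNT_state(model, m, thresholds, features=fv),
            actloopCT_state(model, m, thresholds, features=fv),
        ],
        fv,
    )
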