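"""Synthetic kinase-like structures and synthetic prediction scores.

These generators make every criterion testable without downloading any
structure.  A toy kinase is *not* a protein model: it favors geometric
exactness over global realism.  It consists of

* a main chain carrying the activation loop (residue before DFG through
  APE1, optionally extended by a C-lobe tail), built residue-by-residue
  from ideal internal coordinates so every requested phi/psi/chi1 is
  realized exactly; the dihedrals of the loop middle are optimized so the
  APE10/11/12-to-DFG4 distances hit their targets;
* a rigid catalytic-loop segment (XHRD-His-Arg-Asp with flanking pads)
  placed by rigid-body least squares to realize the DFG6/XHRD hydrogen
  bond and the APE9-Ca/HRD-Arg-O distance;
* free-floating satellite residues for the beta3 Lys, C-helix Glu, Glu4
  and HPN7 positions, each placed to realize its pairwise distance
  targets.

The builder re-measures every requested quantity afterwards and reports
the residuals; construction is fully deterministic for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

import gemmi

from kinactive.actloop_confidence import PredictionScores
from kinactive.geometry import dihedral
from kinactive.motif_map import KinaseMotifMap
from kinactive.structure_model import Atom, Residue, StructureModel

__all__ = [
    "ToyKinaseSpec",
    "BuildError",
    "build_toy_kinase",
    "synth_prediction_scores",
    "all_pass_spec",
    "violation_specs",
    "write_pdb",
    "make_crystal_model",
]


class BuildError(RuntimeError):
    """Requested geometry could not be realized."""


# ---------------------------------------------------------------------------
# internal-coordinate (NeRF) atom placement

_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_CA_C_O = 120.8


def _place(a, b, c, r, theta_deg, chi_deg) -> np.ndarray:
    """Position of atom D bonded to C, with angle(B,C,D) and torsion(A,B,C,D)."""
    theta = math.radians(theta_deg)
    chi = math.radians(chi_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    # out-of-plane sign chosen so torsion(A,B,C,D) = +chi under the IUPAC
    # convention used by kinactive.geometry.dihedral
    d_local = np.array(
        [
            -r * math.cos(theta),
            r * math.sin(theta) * math.cos(chi),
            r * math.sin(theta) * math.sin(chi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


_SIDECHAIN_RECIPES: dict[str, list[tuple[str, tuple[str, str, str], float, float, str]]] = {
    # atom, (A, B, C) frame atoms, bond length, bond angle, torsion spec
    # torsion spec: 'chi1' or a float offset applied to chi1, or absolute value
    "SER": [("OG", ("N", "CA", "CB"), 1.417, 110.8, "chi1")],
    "THR": [
        ("OG1", ("N", "CA", "CB"), 1.433, 109.5, "chi1"),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.5, "chi1-120"),
    ],
    "CYS": [("SG", ("N", "CA", "CB"), 1.808, 113.8, "chi1")],
    "VAL": [
        ("CG1", ("N", "CA", "CB"), 1.527, 110.5, "chi1"),
        ("CG2", ("N", "CA", "CB"), 1.527, 110.5, "chi1+120"),
    ],
    "ASP": [
        ("CG", ("N", "CA", "CB"), 1.516, 112.6, "chi1"),
        ("OD1", ("CA", "CB", "CG"), 1.249, 118.4, "=0"),
        ("OD2", ("CA", "CB", "CG"), 1.249, 118.4, "=180"),
    ],
    "GLU": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, "chi1"),
        ("CD", ("CA", "CB", "CG"), 1.516, 112.6, "=180"),
        ("OE1", ("CB", "CG", "CD"), 1.249, 118.4, "=0"),
        ("OE2", ("CB", "CG", "CD"), 1.249, 118.4, "=180"),
    ],
    "LYS": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, "chi1"),
        ("CD", ("CA", "CB", "CG"), 1.520, 111.3, "=180"),
        ("CE", ("CB", "CG", "CD"), 1.508, 111.3, "=180"),
        ("NZ", ("CG", "CD", "CE"), 1.489, 111.9, "=180"),
    ],
    "LEU": [
        ("CG", ("N", "CA", "CB"), 1.530, 116.3, "chi1"),
        ("CD1", ("CA", "CB", "CG"), 1.521, 110.7, "=65"),
        ("CD2", ("CA", "CB", "CG"), 1.521, 110.7, "=185"),
    ],
    "PHE": [
        ("CG", ("N", "CA", "CB"), 1.502, 113.8, "chi1"),
        ("CD1", ("CA", "CB", "CG"), 1.384, 120.8, "=-90"),
        ("CD2", ("CA", "CB", "CG"), 1.384, 120.8, "=90"),
        ("CE1", ("CB", "CG", "CD1"), 1.382, 121.0, "=180"),
        ("CE2", ("CB", "CG", "CD2"), 1.382, 121.0, "=180"),
        ("CZ", ("CG", "CD1", "CE1"), 1.382, 120.0, "=0"),
    ],
    "TYR": [
        ("CG", ("N", "CA", "CB"), 1.512, 113.9, "chi1"),
        ("CD1", ("CA", "CB", "CG"), 1.389, 120.8, "=-90"),
        ("CD2", ("CA", "CB", "CG"), 1.389, 120.8, "=90"),
        ("CE1", ("CB", "CG", "CD1"), 1.382, 121.1, "=180"),
        ("CE2", ("CB", "CG", "CD2"), 1.382, 121.1, "=180"),
        ("CZ", ("CG", "CD1", "CE1"), 1.378, 119.6, "=0"),
        ("OH", ("CD1", "CE1", "CZ"), 1.376, 119.9, "=180"),
    ],
    "HIS": [
        ("CG", ("N", "CA", "CB"), 1.497, 113.8, "chi1"),
        ("ND1", ("CA", "CB", "CG"), 1.371, 122.7, "=-75"),
        ("CD2", ("CA", "CB", "CG"), 1.356, 131.0, "=105"),
    ],
    "ARG": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, "chi1"),
        ("CD", ("CA", "CB", "CG"), 1.520, 111.3, "=180"),
    ],
    "ASN": [
        ("CG", ("N", "CA", "CB"), 1.516, 112.6, "chi1"),
        ("OD1", ("CA", "CB", "CG"), 1.231, 120.8, "=0"),
        ("ND2", ("CA", "CB", "CG"), 1.328, 116.4, "=180"),
    ],
    "PRO": [
        ("CG", ("N", "CA", "CB"), 1.492, 104.5, "chi1"),
        ("CD", ("CA", "CB", "CG"), 1.503, 106.1, "=30"),
    ],
    "ALA": [],
    "GLY": [],
}

_ELEMENT = {"C": "C", "N": "N", "O": "O", "S": "S"}


def _element_of(atom_name: str) -> str:
    return _ELEMENT.get(atom_name[0], atom_name[0])


def _build_sidechain(name: str, atoms: dict[str, np.ndarray], chi1: float | None):
    recipe = _SIDECHAIN_RECIPES.get(name, [])
    if not recipe:
        return
    chi = -60.0 if chi1 is None else float(chi1)
    if name == "PRO":
        chi = 30.0 if chi1 is None else float(chi1)  # C-gamma-endo pucker
    for atom_name, (a, b, c), r, theta, tors in recipe:
        if tors == "chi1":
            t = chi
        elif tors.startswith("chi1"):
            t = chi + float(tors[4:])
        else:
            t = float(tors[1:])
        atoms[atom_name] = _place(atoms[a], atoms[b], atoms[c], r, theta, t)


def _build_chain(
    names: list[str],
    phis: list[float],
    psis: list[float],
    chi1s: list[float | None],
) -> list[dict[str, np.ndarray]]:
    """Backbone + side chains for a contiguous peptide from internal coordinates.

    ``phis[0]`` is unused (no preceding residue); the returned list holds
    one {atom_name: position} dict per residue, with CB placed from the
    standard L-chirality improper torsion.
    """
    n_res = len(names)
    residues: list[dict[str, np.ndarray]] = []
    for i in range(n_res):
        atoms: dict[str, np.ndarray] = {}
        if i == 0:
            atoms["N"] = np.zeros(3)
            atoms["CA"] = np.array([_B_N_CA, 0.0, 0.0])
            ang = math.radians(180.0 - _A_N_CA_C)
            atoms["C"] = atoms["CA"] + _B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
        else:
            prev = residues[i - 1]
            atoms["N"] = _place(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psis[i - 1])
            atoms["CA"] = _place(prev["CA"], prev["C"], atoms["N"], _B_N_CA, _A_C_N_CA, 180.0)
            atoms["C"] = _place(prev["C"], atoms["N"], atoms["CA"], _B_CA_C, _A_N_CA_C, phis[i])
        residues.append(atoms)
    # carbonyl O (anti to the next N) and side chains
    for i, atoms in enumerate(residues):
        psi = psis[i]
        atoms["O"] = _place(atoms["N"], atoms["CA"], atoms["C"], _B_C_O, _A_CA_C_O, psi + 180.0)
        if names[i] not in ("GLY",):
            atoms["CB"] = _place(atoms["C"], atoms["N"], atoms["CA"], 1.53, 110.4, -122.6)
            _build_sidechain(names[i], atoms, chi1s[i])
    return residues


# ---------------------------------------------------------------------------
# toy kinase specification


def _default_dihedrals(group: str) -> dict[str, tuple]:
    """Per-position (phi, psi[, chi1]) targets for the all-pass conformation."""
    d = {
        "XDFG": (-120.0, 130.0),        # B region
        "DFG1": (60.0, 40.0),           # L region (the Asp)
        "DFG2": (-90.0, -10.0, -60.0),  # A region, chi1 g- (the Phe)
        "DFG3": (-75.0, -25.0),
        "DFG4": (-120.0, 130.0),
        "APE10": (-120.0, 130.0),       # B region
        "APE9": (-120.0, 130.0),        # B region
        "APE8": (-120.0, 130.0, -60.0),  # B region, chi1 g-
        "APE7": (-75.0, -25.0),         # A region
        "APE6": (-75.0, -25.0),         # A region
        "APE5": (-60.0, -45.0),
        "APE4": (-60.0, -45.0),
        "APE3": (-75.0, -30.0),
        "APE2": (-65.0, 145.0),
        "APE1": (-75.0, 140.0),
        "XHRD": (-120.0, 130.0),
        "HRD1": (-70.0, -35.0),         # A region (His)
        "HRD2": (60.0, 40.0),           # L region (Arg)
        "HRD3": (-70.0, -35.0),
    }
    if group == "TYR":
        # APE8 is a proline: beta-region backbone, C-gamma-endo pucker
        d["APE8"] = (-75.0, 140.0, 30.0)
    return d


def _default_distances(group: str) -> dict[str, float]:
    d = {
        "phe_glu4": 8.0,
        "phe_lys": 14.0,
        "saltbridge": 3.0,
        "dfg6_xhrd": 2.9,
        "ape9_hrdargO": 4.0,
    }
    if group == "nonTYR":
        d.update({"ape10_dfg4": 7.0, "ape11_dfg4": 10.0, "ape12_dfg4": 11.0})
    if group == "TYR":
        d["ape9_hrdargO"] = 7.0
    return d


@dataclass
class ToyKinaseSpec:
    group: str = "nonTYR"
    loop_length: int = 21
    dihedrals: dict[str, tuple] = field(default_factory=dict)   # overrides
    distances: dict[str, float] = field(default_factory=dict)   # overrides
    ctd_residues: int = 0  # C-lobe tail length after APE1 (40 for RMSD work)
    kinase_id: str = "CAMK_TOY1"
    seed: int = 0

    def resolved_dihedrals(self) -> dict[str, tuple]:
        d = _default_dihedrals(self.group)
        d.update(self.dihedrals)
        return d

    def resolved_distances(self) -> dict[str, float]:
        d = _default_distances(self.group)
        d.update(self.distances)
        return d


def all_pass_spec(group: str = "nonTYR", **kwargs) -> ToyKinaseSpec:
    """Spec whose toy kinase satisfies every criterion (label Active)."""
    kid = {"nonTYR": "CAMK_TOY1", "TYR": "TYR_TOY1", "noAPE": "OTHER_HASPIN"}[group]
    kwargs.setdefault("kinase_id", kid)
    return ToyKinaseSpec(group=group, **kwargs)


def violation_specs(group: str = "nonTYR") -> dict[str, ToyKinaseSpec]:
    """One spec per criterion, each violating exactly that criterion."""
    base = all_pass_spec(group)
    out = {
        "spatial": replace(base, distances={"phe_glu4": 14.0, "phe_lys": 9.0}),
        "dihedral": replace(base, dihedrals={"DFG2": (-90.0, -10.0, 60.0)}),  # chi1 g+
        "saltbr": replace(base, distances={"saltbridge": 4.5}),
        "hrd": replace(base, dihedrals={"HRD2": (-120.0, 140.0)}),  # Arg flips to B
        "actloopNT": replace(base, distances={"dfg6_xhrd": 5.0}),
    }
    if group == "nonTYR":
        out["actloopCT"] = replace(base, distances={"ape10_dfg4": 9.0})
    elif group == "TYR":
        out["actloopCT"] = replace(base, dihedrals={"APE9": (-75.0, -25.0)})  # A, not B
    return out


# residue numbering of the toy chain
_SEQ_LYS, _SEQ_GLU, _SEQ_GLU4, _SEQ_HPN7 = 30, 50, 54, 60
_SEQ_CAT_START = 94  # pad, XHRD, His, Arg, Asp, pad -> 94..99
_SEQ_X = 119  # residue before DFG; DFG1 = 120


def _main_chain_names(spec: ToyKinaseSpec) -> list[str]:
    L = spec.loop_length
    names = ["GLY", "THR"]  # pad (for phi of X) + X[XDFG]
    loop = ["GLY"] * L
    loop[0], loop[1], loop[2], loop[3] = "ASP", "PHE", "GLY", "LEU"
    # C-terminal positions indexed from the end (APEn = loop[L-n])
    def set_ape(n, nm):
        loop[L - n] = nm

    if spec.group != "noAPE":
        set_ape(1, "GLU")
        set_ape(2, "PRO")
        set_ape(3, "ALA")
        set_ape(4, "ALA")
        set_ape(5, "ALA")
        set_ape(6, "ALA")
        set_ape(7, "PRO")
        set_ape(8, "PRO" if spec.group == "TYR" else "THR")
        set_ape(9, "GLY")
        set_ape(10, "VAL")
        set_ape(11, "ALA")
        set_ape(12, "ALA")
    return names + loop


def _label_to_chain_index(label: str, L: int) -> int:
    """Index into the main-chain list (pad=0, X=1, DFG1=2, ...)."""
    if label == "XDFG":
        return 1
    if label.startswith("DFG"):
        return 1 + int(label[3:])
    if label.startswith("APE"):
        return 1 + L - int(label[3:]) + 1
    raise KeyError(label)


def _main_chain_dihedrals(spec: ToyKinaseSpec):
    """(phis, psis, chi1s) arrays for the main chain, NaN where free."""
    L = spec.loop_length
    n = L + 2 + spec.ctd_residues
    phis = np.full(n, -120.0)
    psis = np.full(n, 130.0)
    chi1s: list[float | None] = [None] * n
    targets = spec.resolved_dihedrals()
    for label, tup in targets.items():
        if label.startswith(("HRD", "XHRD")):
            continue
        try:
            idx = _label_to_chain_index(label, L)
        except KeyError:
            continue
        if idx >= L + 2:
            continue
        phis[idx], psis[idx] = tup[0], tup[1]
        if len(tup) > 2:
            chi1s[idx] = tup[2]
    return phis, psis, chi1s


_FREE_SLOTS = ("DFG5", "DFG6", "DFG7", "DFG8", "DFG9")


def _free_indices(spec: ToyKinaseSpec) -> list[int]:
    """Chain indices of loop-middle residues whose phi/psi the optimizer may vary."""
    L = spec.loop_length
    lo = _label_to_chain_index("DFG5", L)
    hi = _label_to_chain_index("APE11", L) if spec.group != "noAPE" else L + 1
    fixed = set()
    for label in spec.resolved_dihedrals():
        try:
            fixed.add(_label_to_chain_index(label, L))
        except KeyError:
            pass
    return [i for i in range(lo, hi + 1) if i not in fixed]


def _measure_cb(res_atoms: dict[str, np.ndarray]) -> np.ndarray | None:
    return res_atoms.get("CB")


def _chain_distance_residuals(chain, spec: ToyKinaseSpec, dist):
    L = spec.loop_length
    res = []
    dfg4 = chain[_label_to_chain_index("DFG4", L)]["CA"]
    if spec.group == "nonTYR":
        for n_ape, key in ((10, "ape10_dfg4"), (11, "ape11_dfg4"), (12, "ape12_dfg4")):
            if key in dist:
                cb = _measure_cb(chain[_label_to_chain_index(f"APE{n_ape}", L)])
                res.append(float(np.linalg.norm(cb - dfg4)) - dist[key])
    # keep DFG6 and APE9 at a workable separation so the catalytic-loop
    # segment can satisfy both of its distance constraints
    n6 = chain[_label_to_chain_index("DFG6", L)]["N"]
    if spec.group != "noAPE":
        a9 = chain[_label_to_chain_index("APE9", L)]["CA"]
    else:
        a9 = chain[_label_to_chain_index(f"DFG{L - 8}", L)]["CA"]
    res.append(0.3 * (float(np.linalg.norm(n6 - a9)) - 8.0))
    return res


def _optimize_main_chain(spec: ToyKinaseSpec, rng):
    names = _main_chain_names(spec)
    if spec.ctd_residues:
        names = names + ["ALA"] * spec.ctd_residues
    phis, psis, chi1s = _main_chain_dihedrals(spec)
    free = _free_indices(spec)
    dist = spec.resolved_distances()

    def build(x):
        p = phis.copy()
        s = psis.copy()
        p[free] = x[: len(free)]
        s[free] = x[len(free):]
        return _build_chain(names, list(p), list(s), chi1s)

    def objective(x):
        return _chain_distance_residuals(build(x), spec, dist)

    best = None
    for attempt in range(8):
        if attempt == 0:
            x0 = np.concatenate([np.full(len(free), -70.0), np.full(len(free), -40.0)])
        else:
            x0 = rng.uniform(-170, 170, size=2 * len(free))
        sol = least_squares(objective, x0, bounds=(-175, 175), xtol=1e-14, ftol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < 1e-14:
            break
    chain = build(best.x)
    return names, chain, float(np.sqrt(2 * best.cost))


# ---------------------------------------------------------------------------
# rigid placement of the catalytic segment and satellites


def _rigid_apply(params, coords):
    rot = Rotation.from_rotvec(params[:3]).as_matrix()
    return coords @ rot.T + params[3:]


def _solve_rigid(constraints, coords, anchor_guess, rng, tol=1e-6):
    """Place a rigid atom group subject to distance constraints.

    Each constraint is ``(local_points, target_points, distance, kind)``:
    ``eq`` equates the single-pair distance, ``eqmin`` equates the minimum
    distance across the two point sets, and ``min`` is a hinge that only
    penalizes coming closer than the stated distance."""

    def residuals(params):
        out = []
        for local, target, d, kind in constraints:
            pts = _rigid_apply(params, np.atleast_2d(np.asarray(local)))
            tgt = np.atleast_2d(np.asarray(target))
            d2 = ((pts[:, None, :] - tgt[None, :, :]) ** 2).sum(axis=-1)
            r = float(np.sqrt(d2.min())) - d
            if kind == "min":
                r = min(r, 0.0) * 3.0
            out.append(r)
        return out

    best = None
    for attempt in range(12):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        t0 = anchor_guess + direction * rng.uniform(2.0, 8.0)
        x0 = np.concatenate([rng.uniform(-math.pi, math.pi, 3), t0])
        sol = least_squares(residuals, x0, xtol=1e-15, ftol=1e-15)
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < tol**2:
            break
    return _rigid_apply(best.x, coords), float(np.sqrt(2 * best.cost))


def _segment_to_dict(names, chain):
    return [dict(atoms) for atoms in chain], names


def build_toy_kinase(spec: ToyKinaseSpec):
    """Build a toy kinase realizing the requested geometry.

    Returns ``(StructureModel, KinaseMotifMap, residual_report)`` where the
    report maps each requested quantity to |achieved - requested| (degrees
    for dihedrals, Angstroms for distances).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.loop_length < 18:
        raise BuildError("activation loop must have at least 18 residues")
    dist = spec.resolved_distances()
    dihe = spec.resolved_dihedrals()
    L = spec.loop_length

    names, chain, chain_resid = _optimize_main_chain(spec, rng)

    def chain_atom(label, atom):
        return chain[_label_to_chain_index(label, L)][atom]

    # ---- catalytic-loop segment: pad, XHRD, His, Arg, Asp, pad
    cat_names = ["GLY", "VAL", "HIS", "ARG", "ASP", "GLY"]
    cat_phis = [-120.0, dihe["XHRD"][0], dihe["HRD1"][0], dihe["HRD2"][0], dihe["HRD3"][0], -120.0]
    cat_psis = [130.0, dihe["XHRD"][1], dihe["HRD1"][1], dihe["HRD2"][1], dihe["HRD3"][1], 130.0]
    cat_chain = _build_chain(cat_names, cat_phis, cat_psis, [None] * 6)

    n6 = chain_atom("DFG6", "N")
    o6 = chain_atom("DFG6", "O")
    cat_constraints = [
        (cat_chain[1]["O"], n6, dist["dfg6_xhrd"], "eq"),
        (cat_chain[1]["N"], o6, dist["dfg6_xhrd"] + 0.4, "min"),
    ]
    if spec.group != "noAPE":
        cat_constraints.append(
            (cat_chain[3]["O"], chain_atom("APE9", "CA"), dist["ape9_hrdargO"], "eq")
        )
    _bb = {"N", "CA", "C", "O"}
    phe_side = np.array(
        [p for nm, p in chain[_label_to_chain_index("DFG2", L)].items() if nm not in _bb]
    )
    if "spine1" in dist:
        his_side = np.array([p for nm, p in cat_chain[2].items() if nm not in _bb])
        cat_constraints.append((his_side, phe_side, dist["spine1"], "eqmin"))
    cat_coords = np.vstack([list(atoms.values()) for atoms in cat_chain])
    placed, cat_resid = _solve_rigid(
        cat_constraints, cat_coords, anchor_guess=n6, rng=rng
    )
    k = 0
    for atoms in cat_chain:
        for name in atoms:
            atoms[name] = placed[k]
            k += 1

    # ---- satellites
    cz = chain_atom("DFG2", "CZ")
    sat_resid = {}

    def place_satellite(name, chi1, constraints, guess):
        seg = _build_chain(["GLY", name, "GLY"], [-120.0] * 3, [130.0] * 3, [None, chi1, None])
        atom_names = list(seg[1].keys())
        coords = np.vstack([list(seg[1].values())])

        def local_points(sel):
            if sel == "sidechain":
                return np.array([p for nm, p in seg[1].items() if nm not in _bb])
            return seg[1][sel]

        cons = [(local_points(sel), target, d, kind)
                for sel, target, d, kind in constraints]
        placed_coords, resid = _solve_rigid(cons, coords, anchor_guess=guess, rng=rng)
        return dict(zip(atom_names, placed_coords)), resid

    lys_atoms, r = place_satellite(
        "LYS", -60.0, [("CA", cz, dist["phe_lys"], "eq")], guess=cz
    )
    sat_resid["phe_lys"] = r
    glu4_atoms, r = place_satellite(
        "LEU",
        -60.0,
        [("CA", cz, dist["phe_glu4"], "eq")]
        + ([("sidechain", phe_side, dist["spine2"], "eqmin")] if "spine2" in dist else []),
        guess=cz,
    )
    sat_resid["phe_glu4"] = r
    nz = lys_atoms["NZ"]
    glu_atoms, r = place_satellite(
        "GLU",
        -60.0,
        [("OE1", nz, dist["saltbridge"], "eq"), ("OE2", nz, dist["saltbridge"] + 0.4, "min")],
        guess=nz,
    )
    sat_resid["saltbridge"] = r
    glu4_side = np.array([p for nm, p in glu4_atoms.items() if nm not in _bb])
    hpn7_cons = [("sidechain", glu4_side, dist.get("spine3", 4.5), "eqmin")]
    hpn7_atoms, r = place_satellite("LEU", -60.0, hpn7_cons, guess=glu4_atoms["CA"])
    if "spine3" in dist:
        sat_resid["spine3"] = r

    # ---- assemble the StructureModel
    def mk_res(seqnum, name, atom_dict):
        # B-factors double as pLDDT when the toy stands in for a predicted model
        atoms = [
            Atom(an, _element_of(an), pos, occupancy=1.0, bfactor=90.0)
            for an, pos in atom_dict.items()
        ]
        return Residue("A", seqnum, "", name, atoms)

    residues = [
        mk_res(_SEQ_LYS, "LYS", lys_atoms),
        mk_res(_SEQ_GLU, "GLU", glu_atoms),
        mk_res(_SEQ_GLU4, "LEU", glu4_atoms),
        mk_res(_SEQ_HPN7, "LEU", hpn7_atoms),
    ]
    for i, (nm, atoms) in enumerate(zip(cat_names, cat_chain)):
        residues.append(mk_res(_SEQ_CAT_START + i, nm, atoms))
    for i, (nm, atoms) in enumerate(zip(names, chain)):
        residues.append(mk_res(_SEQ_X - 1 + i, nm, atoms))

    model = StructureModel(entry_id=f"TOY_{spec.kinase_id}", chains={"A": residues})

    m = KinaseMotifMap(
        kinase_id=spec.kinase_id,
        chain_id="A",
        res_saltbridge_lys=_SEQ_LYS,
        res_saltbridge_glu=_SEQ_GLU,
        res_glu4=_SEQ_GLU4,
        res_hpn7=_SEQ_HPN7,
        res_hrd_his=_SEQ_CAT_START + 2,
        res_hrd_arg=_SEQ_CAT_START + 3,
        res_hrd_asp=_SEQ_CAT_START + 4,
        res_dfg_asp=_SEQ_X + 1,
        res_ape_glu=_SEQ_X + L,
        group=spec.group,
    )

    report = _residual_report(model, m, spec, chain_resid, cat_resid, sat_resid)
    return model, m, report


def _label_seqnum(label: str, L: int) -> int | None:
    if label == "XDFG":
        return _SEQ_X
    if label == "XHRD":
        return _SEQ_CAT_START + 1
    if label.startswith("HRD"):
        return _SEQ_CAT_START + 1 + int(label[3:])
    if label.startswith("DFG"):
        return _SEQ_X + int(label[3:])
    if label.startswith("APE"):
        return _SEQ_X + L - int(label[3:]) + 1
    return None


def _angle_diff(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def _residual_report(model, m, spec, chain_resid, cat_resid, sat_resid):
    """Re-measure every requested quantity against its target."""
    from kinactive.conformational_labels import compute_features, _phi_psi, _chi1

    fv = compute_features(model, m)
    dist = spec.resolved_distances()
    report: dict[str, float] = {}
    measured = {
        "phe_glu4": fv.d_phe_glu4,
        "phe_lys": fv.d_phe_lys,
        "saltbridge": fv.d_saltbridge,
        "dfg6_xhrd": fv.d_dfg6_xhrd,
        "ape9_hrdargO": fv.d_ape9ca_hrdargO,
        "ape10_dfg4": fv.d_ape10cb_dfg4ca,
        "ape11_dfg4": fv.d_ape11cb_dfg4ca,
        "ape12_dfg4": fv.d_ape12cb_dfg4ca,
        "spine1": fv.spine1,
        "spine2": fv.spine2,
        "spine3": fv.spine3,
    }
    for key, target in dist.items():
        got = measured.get(key)
        if key == "dfg6_xhrd" and got is not None and got < target:
            # the non-requested backbone pair may come closer than the
            # requested one; for an "in" target a shorter bond still passes
            report[key] = 0.0 if got < 3.6 and target < 3.6 else abs(got - target)
        elif got is not None:
            report[key] = abs(got - target)
        else:
            report[key] = float("nan")
    chain = {r.seqnum: r for r in model.chains[m.chain_id]}
    for label, tup in spec.resolved_dihedrals().items():
        seq = _label_seqnum(label, spec.loop_length)
        if seq is None or seq not in chain:
            continue
        phi, psi = _phi_psi(chain, seq)
        if phi is not None:
            report[f"{label}_phi"] = _angle_diff(phi, tup[0])
        if psi is not None:
            report[f"{label}_psi"] = _angle_diff(psi, tup[1])
        if len(tup) > 2:
            chi = _chi1(chain[seq])
            if chi is not None:
                report[f"{label}_chi1"] = _angle_diff(chi, tup[2])

    report["_chain_lsq"] = chain_resid
    report["_catalytic_lsq"] = cat_resid
    for key, val in sat_resid.items():
        report[f"_{key}_lsq"] = val
    return report


# ---------------------------------------------------------------------------
# synthetic prediction scores


def synth_prediction_scores(
    n_residues: int,
    loop,
    pae_profile=("uniform", 0.0),
    plddt_profile=90.0,
    seed: int = 0,
) -> PredictionScores:
    """Synthetic PAE matrix and pLDDT vector.

    ``pae_profile`` is ``("uniform", c)``, ``("two_block", c_in, c_out)``
    (loop columns get c_in for non-loop rows, everything else c_out) or
    ``("random", scale)``; ``plddt_profile`` is a scalar or a vector.
    """
    loop_idx = np.asarray(sorted(set(int(i) for i in loop)), dtype=int)
    if loop_idx.size and (loop_idx.min() < 0 or loop_idx.max() >= n_residues):
        raise ValueError("loop indices outside the residue range")
    kind = pae_profile[0]
    if kind == "uniform":
        pae = np.full((n_residues, n_residues), float(pae_profile[1]))
    elif kind == "two_block":
        c_in, c_out = float(pae_profile[1]), float(pae_profile[2])
        pae = np.full((n_residues, n_residues), c_out)
        pae[:, loop_idx] = c_in
    elif kind == "random":
        scale = float(pae_profile[1]) if len(pae_profile) > 1 else 15.0
        rng = np.random.default_rng(seed)
        pae = rng.uniform(0.0, scale, size=(n_residues, n_residues))
    else:
        raise ValueError(f"unknown PAE profile {kind!r}")
    np.fill_diagonal(pae, 0.0)
    if np.isscalar(plddt_profile):
        plddt = np.full(n_residues, float(plddt_profile))
    else:
        plddt = np.asarray(plddt_profile, dtype=float)
    return PredictionScores(pae=pae, plddt=plddt)


# ---------------------------------------------------------------------------
# writers and crystal fixtures


def model_to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.entry_id
    if model.cell is not None:
        st.cell = gemmi.UnitCell(*model.cell)
    if model.spacegroup is not None:
        st.spacegroup_hm = model.spacegroup
    gm = gemmi.Model("1")
    for cid, residues in model.chains.items():
        ch = gemmi.Chain(cid)
        for r in residues:
            gr = gemmi.Residue()
            gr.name = r.name
            gr.seqid = gemmi.SeqId(r.seqnum, r.icode or " ")
            gr.het_flag = "H" if r.hetero else "A"
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.position)
                ga.occ = a.occupancy
                ga.b_iso = a.bfactor
                gr.add_atom(ga)
            ch.add_residue(gr)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_pdb(model: StructureModel, path) -> None:
    model_to_gemmi(model).write_pdb(str(path))


def write_mmcif(model: StructureModel, path) -> None:
    st = model_to_gemmi(model)
    st.make_mmcif_document().write_file(str(path))


def make_crystal_model(
    model: StructureModel,
    cell=(40.0, 40.0, 40.0, 90.0, 90.0, 90.0),
    spacegroup: str = "P 1",
) -> StructureModel:
    """Copy of a model with crystal records attached (for symmetry expansion)."""
    sg = gemmi.find_spacegroup_by_name(spacegroup)
    if sg is None:
        raise ValueError(f"unknown space group {spacegroup!r}")
    ops = list(sg.operations())
    ident = gemmi.Op("x,y,z")
    ops.sort(key=lambda op: 0 if op == ident else 1)
    return StructureModel(
        entry_id=model.entry_id,
        chains=model.chains,
        cell=tuple(float(x) for x in cell),
        spacegroup=sg.hm,
        symmetry_ops=ops,
    )
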