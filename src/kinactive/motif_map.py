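"""Residue addresses of the conserved kinase motifs needed by the activity criteria.

A :class:`KinaseMotifMap` locates, in author numbering, the beta3 Lys and
C-helix Glu of the N-terminal domain salt bridge, the Glu4 and HPN7 spine
residues, the HRD motif (plus the residue before it), and the activation
loop endpoints (DFG Asp through APE Glu).  Maps are normally supplied by
the user as CSV/TSV or JSON, mirroring a curated alignment; a regex-based
sequence scan is provided as a convenience with explicit ambiguity
reporting.

Activation-loop residues are addressed by the two-ended convention used
throughout: DFGn is the n-th residue from the loop start (DFG1 = Asp) and
APEn the n-th residue counting backwards from the loop end (APE1 = Glu).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "KinaseMotifMap",
    "MotifMapError",
    "MotifCandidates",
    "load_motif_map",
    "actloop_index",
    "detect_motifs_from_sequence",
    "SKIP_SALTBRIDGE_GENES",
    "NO_APE_GENES",
    "NO_AF_ASP_GENES",
]


class MotifMapError(ValueError):
    """A motif map row violates an invariant."""


# Built-in per-kinase exceptions (gene names without the family prefix).
# WNK kinases lack the beta3 Lys; MAP3K12/13 have Asp in place of the
# C-helix Glu with a broken C-helix, so the salt bridge is not required.
SKIP_SALTBRIDGE_GENES = frozenset(
    {"WNK1", "WNK2", "WNK3", "WNK4", "MAP3K12", "MAP3K13"}
)
# Kinases without an APE motif (no ActLoopCT requirement).
NO_APE_GENES = frozenset({"HASPIN", "TP53RK", "PKDCC"})
# Kinases without the conserved alphaF-helix Asp (HRD dihedral criteria skipped).
NO_AF_ASP_GENES = frozenset(
    {"PIM1", "PIM2", "PIM3", "HASPIN", "PKDCC", "AATK", "LMTK2", "LMTK3"}
)

_GROUPS = {"TYR", "nonTYR", "noAPE"}


def _gene_of(kinase_id: str) -> str:
    """Gene name from a family-prefixed id like 'TYR_BTK' or 'OTHER_WNK1'."""
    return kinase_id.split("_", 1)[1] if "_" in kinase_id else kinase_id


def _family_of(kinase_id: str) -> str | None:
    return kinase_id.split("_", 1)[0] if "_" in kinase_id else None


@dataclass
class KinaseMotifMap:
    kinase_id: str
    chain_id: str
    res_saltbridge_lys: int | None
    res_saltbridge_glu: int | None
    res_glu4: int | None
    res_hrd_his: int
    res_hrd_arg: int
    res_hrd_asp: int
    res_dfg_asp: int
    res_ape_glu: int
    res_hpn7: int | None = None
    res_xhrd: int | None = None
    group: str | None = None
    has_aF_asp: bool | None = None
    skip_saltbridge: bool | None = None
    skip_hrd: bool = field(init=False, default=False)

    def __post_init__(self):
        gene = _gene_of(self.kinase_id)
        fam = _family_of(self.kinase_id)
        if self.group is None:
            if gene in NO_APE_GENES:
                self.group = "noAPE"
            elif fam == "TYR":
                self.group = "TYR"
            else:
                # WEE/PKMYT1 kinases phosphorylate Tyr but bind substrate like
                # Ser/Thr kinases; they are classified nonTYR by family prefix.
                self.group = "nonTYR"
        if self.group not in _GROUPS:
            raise MotifMapError(
                f"{self.kinase_id}: group must be one of {sorted(_GROUPS)}, got {self.group!r}"
            )
        if self.skip_saltbridge is None:
            self.skip_saltbridge = gene in SKIP_SALTBRIDGE_GENES
        if self.has_aF_asp is None:
            self.has_aF_asp = gene not in NO_AF_ASP_GENES
        self.skip_hrd = not self.has_aF_asp
        if self.res_xhrd is None:
            self.res_xhrd = self.res_hrd_his - 1
        self._validate()

    def _validate(self):
        kid = self.kinase_id
        if self.res_dfg_asp >= self.res_ape_glu:
            raise MotifMapError(f"{kid}: dfg_asp must precede ape_glu")
        if self.loop_length < 18:
            raise MotifMapError(
                f"{kid}: activation loop has {self.loop_length} residues; "
                "at least 18 required so the DFG and APE windows do not overlap"
            )
        if self.res_xhrd != self.res_hrd_his - 1:
            raise MotifMapError(f"{kid}: xhrd must immediately precede hrd_his")
        if not (self.res_hrd_his < self.res_hrd_arg < self.res_hrd_asp):
            raise MotifMapError(f"{kid}: HRD residues must be consecutive ascending")
        if (
            self.res_saltbridge_glu is not None
            and self.res_glu4 is not None
            and self.res_glu4 != self.res_saltbridge_glu + 4
        ):
            raise MotifMapError(f"{kid}: glu4 must be saltbridge_glu + 4")

    @property
    def loop_length(self) -> int:
        return self.res_ape_glu - self.res_dfg_asp + 1

    def actloop_seqnums(self) -> list[int]:
        return list(range(self.res_dfg_asp, self.res_ape_glu + 1))


_LABEL_RE = re.compile(r"^(DFG|APE)(\d+)$")


def actloop_index(m: KinaseMotifMap, label: str) -> int:
    """Author seqnum of an activation-loop residue addressed as DFGn or APEn.

    DFGn counts forward from the loop start (DFG1 = the DFG Asp); APEn
    counts backward from the loop end (APE1 = the APE Glu).
    """
    match = _LABEL_RE.match(label.upper())
    if not match:
        raise ValueError(f"bad activation-loop label {label!r}; expected DFGn or APEn")
    anchor, n = match.group(1), int(match.group(2))
    if n < 1:
        raise IndexError(f"{label}: index must be >= 1")
    seq = m.res_dfg_asp + (n - 1) if anchor == "DFG" else m.res_ape_glu - (n - 1)
    if not (m.res_dfg_asp <= seq <= m.res_ape_glu):
        raise IndexError(f"{label} falls outside the activation loop of {m.kinase_id}")
    return seq


_REQUIRED_COLUMNS = [
    "kinase_id",
    "chain_id",
    "hrd_his",
    "hrd_arg",
    "hrd_asp",
    "dfg_asp",
    "ape_glu",
]
_OPTIONAL_INT = ["saltbridge_lys", "saltbridge_glu", "glu4", "hpn7", "xhrd"]
_OPTIONAL_BOOL = ["has_af_asp", "skip_saltbridge"]


def _row_to_map(row: dict, where: str) -> KinaseMotifMap:
    def geti(key):
        v = row.get(key)
        if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
            return None
        return int(v)

    def getb(key):
        v = row.get(key)
        if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
            return None
        if isinstance(v, str):
            return v.strip().lower() in {"1", "true", "yes", "y"}
        return bool(v)

    for col in _REQUIRED_COLUMNS:
        if row.get(col) is None or (isinstance(row.get(col), float) and pd.isna(row.get(col))):
            raise MotifMapError(f"{where}: missing required column {col!r}")
    group = row.get("group")
    if isinstance(group, float) and pd.isna(group):
        group = None
    try:
        return KinaseMotifMap(
            kinase_id=str(row["kinase_id"]),
            chain_id=str(row["chain_id"]),
            res_saltbridge_lys=geti("saltbridge_lys"),
            res_saltbridge_glu=geti("saltbridge_glu"),
            res_glu4=geti("glu4"),
            res_hrd_his=int(row["hrd_his"]),
            res_hrd_arg=int(row["hrd_arg"]),
            res_hrd_asp=int(row["hrd_asp"]),
            res_dfg_asp=int(row["dfg_asp"]),
            res_ape_glu=int(row["ape_glu"]),
            res_hpn7=geti("hpn7"),
            res_xhrd=geti("xhrd"),
            group=group or None,
            has_aF_asp=getb("has_af_asp"),
            skip_saltbridge=getb("skip_saltbridge"),
        )
    except MotifMapError as exc:
        raise MotifMapError(f"{where}: {exc}") from exc


def load_motif_map(path) -> list[KinaseMotifMap]:
    """Load motif maps from a CSV/TSV file (one row per structure chain) or JSON list."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        if isinstance(records, dict):
            records = [records]
        return [_row_to_map(rec, f"{path.name}[{i}]") for i, rec in enumerate(records)]
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MotifMapError(f"{path.name}: missing required columns {missing}")
    return [
        _row_to_map(row, f"{path.name} row {i + 2}")
        for i, row in enumerate(df.to_dict(orient="records"))
    ]


@dataclass
class MotifCandidates:
    """Result of a sequence scan: motif positions (0-based) or ambiguity lists."""

    hrd: int | None = None
    dfg: int | None = None
    ape: int | None = None
    hpn: int | None = None
    ambiguous: dict[str, list[int]] = field(default_factory=dict)
    note: str = ""


_HRD_RE = re.compile(r"[HYFL]RD")
_DFG_RE = re.compile(r"D[FLYWMV]G")
_APE_RE = re.compile(r"[ASP]PE")
_HPN_RE = re.compile(r"HPN")


def detect_motifs_from_sequence(seq: str) -> MotifCandidates:
    """Locate HRD / DFG / APE / HPN motif candidates in a one-letter sequence.

    This is a fallback aid, not a replacement for a curated map: the motif
    residues are degenerate (HRD-His can be Tyr/Phe/Leu; DFG-Phe can be
    Leu/Tyr/Trp/Met/Val) so any placement that is not unique is reported as
    an ambiguity instead of a guess.  Exception flags are never inferred.
    """
    seq = seq.upper()
    if len(seq) < 100:
        raise ValueError("sequence too short to be a kinase domain (< 100 residues)")
    out = MotifCandidates()

    hrd_hits = [m.start() for m in _HRD_RE.finditer(seq)]
    if len(hrd_hits) == 1:
        out.hrd = hrd_hits[0]
    elif hrd_hits:
        out.ambiguous["hrd"] = hrd_hits

    # DFG must come after HRD (catalytic loop precedes activation loop)
    dfg_lo = (out.hrd + 3) if out.hrd is not None else 0
    dfg_hits = [m.start() for m in _DFG_RE.finditer(seq) if m.start() >= dfg_lo]
    if len(dfg_hits) == 1:
        out.dfg = dfg_hits[0]
    elif dfg_hits:
        out.ambiguous["dfg"] = dfg_hits

    if out.dfg is not None:
        # APE lies 17-40 residues downstream of the DFG Asp in typical loops
        ape_hits = [
            m.start()
            for m in _APE_RE.finditer(seq)
            if out.dfg + 15 <= m.start() + 2 <= out.dfg + 45
        ]
        if len(ape_hits) == 1:
            out.ape = ape_hits[0]
        elif ape_hits:
            out.ambiguous["ape"] = ape_hits

    hpn_hits = [m.start() for m in _HPN_RE.finditer(seq)]
    if out.hrd is not None:
        hpn_hits = [h for h in hpn_hits if h < out.hrd]
    if len(hpn_hits) == 1:
        out.hpn = hpn_hits[0]
    elif hpn_hits:
        out.ambiguous["hpn"] = hpn_hits

    found = [k for k in ("hrd", "dfg", "ape", "hpn") if getattr(out, k) is not None]
    out.note = f"located: {', '.join(found) if found else 'none'}"
    if out.ambiguous:
        out.note += f"; ambiguous: {', '.join(sorted(out.ambiguous))}"
    return out
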