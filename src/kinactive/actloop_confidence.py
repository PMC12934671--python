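"""Activation-loop confidence of predicted models from PAE matrices.

The score is an intramolecular variant of ipSAE: for each aligned residue i
outside the activation loop whose pLDDT exceeds a gate (default 60), take
the mean over loop residues j of ``1 / (1 + (PAE_ij / d0)^2)`` and report
the maximum over i.  PAE follows the AlphaFold convention: ``PAE[i, j]`` is
the expected error at residue j when the prediction is aligned on residue
i.  ``d0`` is fixed at 4 A so scores are comparable across kinases with
different loop lengths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "PredictionScores",
    "LoopScore",
    "ScoringError",
    "ipsae_actloop",
    "select_best_model",
    "load_pae_json",
]


class ScoringError(ValueError):
    """No eligible aligned residue (distinct from a low score)."""


@dataclass
class PredictionScores:
    """PAE matrix (A) and per-residue pLDDT for one predicted model."""

    pae: np.ndarray
    plddt: np.ndarray
    index_map: list[tuple[str, int]] | None = None  # residue order -> (chain, seqnum)

    def __post_init__(self):
        self.pae = np.asarray(self.pae, dtype=float)
        self.plddt = np.asarray(self.plddt, dtype=float)
        n = self.pae.shape[0]
        if self.pae.ndim != 2 or self.pae.shape != (n, n):
            raise ValueError("PAE must be a square matrix")
        if np.any(self.pae < 0):
            raise ValueError("PAE entries must be non-negative")
        if self.plddt.shape != (n,):
            raise ValueError("pLDDT length must equal the PAE side")

    @property
    def n_residues(self) -> int:
        return self.pae.shape[0]

    def indices_for(self, chain_id: str, seqnums) -> list[int]:
        """Matrix indices of the given (chain, author seqnum) residues."""
        if self.index_map is None:
            raise ValueError("PredictionScores has no index_map")
        lookup = {key: i for i, key in enumerate(self.index_map)}
        return [lookup[(chain_id, s)] for s in seqnums if (chain_id, s) in lookup]


@dataclass
class LoopScore:
    value: float
    d0: float
    n_aligned: int
    argmax_residue: int


def ipsae_actloop(
    scores: PredictionScores,
    loop,
    d0: float = 4.0,
    plddt_min: float = 60.0,
    strict_gate: bool = True,
) -> LoopScore:
    """Maximum over eligible non-loop residues of the mean PAE similarity to the loop.

    ``loop`` is a set of residue indices (0-based positions in the PAE
    matrix).  Eligibility requires pLDDT > plddt_min (``>=`` when
    ``strict_gate`` is False).
    """
    loop_idx = np.asarray(sorted(set(int(i) for i in loop)), dtype=int)
    n = scores.n_residues
    if loop_idx.size == 0:
        raise ValueError("activation-loop index set is empty")
    if loop_idx.min() < 0 or loop_idx.max() >= n:
        raise ValueError("loop indices outside the PAE matrix")
    if loop_idx.size >= n:
        raise ValueError("loop must be a strict subset of the residues")

    outside = np.setdiff1d(np.arange(n), loop_idx)
    gate = scores.plddt[outside] > plddt_min if strict_gate else scores.plddt[outside] >= plddt_min
    eligible = outside[gate]
    if eligible.size == 0:
        raise ScoringError(
            f"no residue outside the loop has pLDDT {'>' if strict_gate else '>='} {plddt_min}"
        )
    sub = scores.pae[np.ix_(eligible, loop_idx)]
    row_means = np.mean(1.0 / (1.0 + (sub / d0) ** 2), axis=1)
    best = int(np.argmax(row_means))
    return LoopScore(
        value=float(row_means[best]),
        d0=d0,
        n_aligned=int(eligible.size),
        argmax_residue=int(eligible[best]),
    )


def select_best_model(candidates):
    """Highest-scoring Active model among ``(name, ActivityReport, LoopScore)`` triples.

    Returns ``(chosen_name_or_None, ranking)`` where the ranking lists all
    candidates ordered by score (descending), with exact score ties broken
    by lexicographically smaller name for determinism.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate models")
    ranking = sorted(
        (
            {
                "name": name,
                "label": report.label,
                "ipsae": score.value,
            }
            for name, report, score in candidates
        ),
        key=lambda r: (-r["ipsae"], r["name"]),
    )
    active = [r for r in ranking if r["label"] == "Active"]
    chosen = active[0]["name"] if active else None
    return chosen, ranking


def scores_from_files(pae_path, model=None, chain_id=None, plddt=None) -> PredictionScores:
    """Assemble PredictionScores from a PAE JSON plus a pLDDT source.

    pLDDT comes either from an explicit vector or from the B-factor column
    of a predicted model (per-residue CA value), the AlphaFold convention.
    """
    pae = load_pae_json(pae_path)
    index_map = None
    if plddt is None:
        if model is None:
            raise ValueError("need either a plddt vector or a model with pLDDT B-factors")
        chains = [chain_id] if chain_id else list(model.chains)
        values, index_map = [], []
        for cid in chains:
            for res in model.polymer_residues(cid):
                ca = res.atom("CA") or (res.atoms[0] if res.atoms else None)
                if ca is None:
                    continue
                values.append(ca.bfactor)
                index_map.append((cid, res.seqnum))
        plddt = values
    return PredictionScores(pae=pae, plddt=np.asarray(plddt, dtype=float),
                            index_map=index_map)


def load_pae_json(path) -> np.ndarray:
    """PAE matrix from an AlphaFold/ColabFold JSON file.

    Accepts ``{"pae": ...}``, ``{"predicted_aligned_error": ...}`` and the
    list-wrapped variants produced by the EBI AlphaFold database.
    """
    data = json.loads(Path(path).read_text())
    if isinstance(data, list):
        if not data:
            raise ValueError(f"{path}: empty PAE JSON")
        data = data[0]
    for key in ("pae", "predicted_aligned_error"):
        if key in data:
            return np.asarray(data[key], dtype=float)
    raise ValueError(f"{path}: no 'pae' or 'predicted_aligned_error' field")
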