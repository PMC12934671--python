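"""Combine the six criterion states into the tri-state Active / Inactive / None verdict.

Precedence follows the fail-beats-missing rule: any criterion labeled
``out`` makes the chain Inactive even when other criteria could not be
measured; otherwise any unmeasurable criterion gives None; otherwise the
chain is Active.  Criteria skipped by per-kinase exceptions count as
neither required passes nor failures.  Pseudokinases are not auto-detected:
callers mark them and receive a ``Pseudo-skip`` label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from kinactive.conformational_labels import (
    CriterionState,
    FeatureVector,
    Thresholds,
    DEFAULT_THRESHOLDS,
    evaluate_criteria,
    spine_distances,
)
from kinactive.motif_map import KinaseMotifMap
from kinactive.structure_model import StructureModel

__all__ = ["ActivityReport", "classify", "classify_batch"]

# criteria that make the verdict None when unmeasurable, in report order
_CORE = ("spatial", "dihedral", "saltbr", "hrd")
_LOOP = ("actloopNT", "actloopCT")


@dataclass
class ActivityReport:
    kinase_id: str
    chain_id: str
    label: str  # Active | Inactive | None | Pseudo-skip
    criteria: list[CriterionState] = field(default_factory=list)
    features: FeatureVector | None = None
    notes: str = ""

    def criterion(self, name: str) -> CriterionState | None:
        for c in self.criteria:
            if c.name == name:
                return c
        return None

    def failing(self) -> list[str]:
        return [c.name for c in self.criteria if c.state == "out"]

    def as_row(self) -> dict:
        row = {
            "kinase_id": self.kinase_id,
            "chain_id": self.chain_id,
            "label": self.label,
        }
        for c in self.criteria:
            row[c.name] = c.state
            if c.value is not None:
                row[f"{c.name}_value"] = round(c.value, 3)
            if "label" in c.detail:
                row[f"{c.name}_label"] = c.detail["label"]
        if self.features is not None:
            row.update({k: v for k, v in self.features.as_row().items() if k not in row})
        if self.notes:
            row["notes"] = self.notes
        return row


def classify(
    model: StructureModel,
    m: KinaseMotifMap,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    pseudokinase: bool = False,
) -> ActivityReport:
    """Tri-state activity verdict for one kinase chain."""
    if m.chain_id not in model.chains:
        raise KeyError(f"chain {m.chain_id!r} not present in {model.entry_id}")
    notes = []
    if m.skip_saltbridge:
        notes.append("salt-bridge criterion skipped (kinase exception)")
    if m.skip_hrd:
        notes.append("HRD criterion skipped (no alphaF-helix Asp)")
    if m.group == "noAPE":
        notes.append("ActLoopCT criterion skipped (no APE motif)")

    criteria, fv = evaluate_criteria(model, m, thresholds)
    if pseudokinase:
        return ActivityReport(
            m.kinase_id, m.chain_id, "Pseudo-skip", criteria, fv,
            "; ".join(["marked pseudokinase by caller"] + notes),
        )

    states = {c.name: c.state for c in criteria}
    if any(s == "out" for s in states.values()):
        label = "Inactive"
    elif any(states[n] == "none" for n in _CORE):
        label = "None"
    elif any(states[n] == "none" for n in _LOOP):
        label = "None"
    else:
        label = "Active"
    return ActivityReport(m.kinase_id, m.chain_id, label, criteria, fv, "; ".join(notes))


def classify_batch(
    items,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    with_spine: bool = False,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify many (model, map) pairs; returns a table plus per-label counts.

    ``items`` is an iterable of ``(StructureModel, KinaseMotifMap)`` or
    ``(StructureModel, KinaseMotifMap, is_pseudokinase)``.  Per-chain
    failures are recorded as ``error`` rows and the batch continues.  Rows
    are ordered deterministically by (entry, chain).
    """
    rows = []
    for item in items:
        model, m = item[0], item[1]
        pseudo = bool(item[2]) if len(item) > 2 else False
        try:
            report = classify(model, m, thresholds, pseudokinase=pseudo)
            row = report.as_row()
            row["entry_id"] = model.entry_id
            if with_spine:
                s1, s2, s3, intact = spine_distances(model, m, thresholds,
                                                     features=report.features)
                row["spine_intact"] = intact
            rows.append(row)
        except Exception as exc:  # noqa: BLE001 - batch must continue
            rows.append(
                {
                    "entry_id": model.entry_id,
                    "kinase_id": m.kinase_id,
                    "chain_id": m.chain_id,
                    "label": "error",
                    "notes": str(exc),
                }
            )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["entry_id", "chain_id"], kind="stable").reset_index(drop=True)
        lead = [c for c in ("entry_id", "kinase_id", "chain_id", "label") if c in df.columns]
        df = df[lead + [c for c in df.columns if c not in lead]]
    counts = df["label"].value_counts().to_dict() if not df.empty else {}
    return df, counts
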