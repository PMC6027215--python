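"""Autonomous / nonautonomous classification and dataset summaries.

An element is called autonomous when it both possesses a detectable TIR pair
and encodes an active-signature transposase; every failed criterion is kept
as a reason. N-suffixed derivative names are linked back to their autonomous
parent when the parent is present in the dataset (Ac/Ds-style pairing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .io import ConsensusElement, ElementName
from .tir import TIRPair
from .transposase import ResidueCheck

REASONS = ("no_tir", "truncated_transposase", "no_transposase")


@dataclass
class AutonomyCall:
    element_id: str
    status: str  # "autonomous" | "nonautonomous"
    reasons: frozenset
    parent_id: Optional[str] = None


def classify(
    element_id: str,
    best_tir: Optional[TIRPair],
    residue_check: ResidueCheck,
) -> AutonomyCall:
    """Autonomous iff a TIR pair exists and the transposase signature is
    active; reasons enumerate every failed criterion."""
    reasons = set()
    if best_tir is None:
        reasons.add("no_tir")
    if residue_check.status == "truncated":
        reasons.add("truncated_transposase")
    elif residue_check.status == "absent":
        reasons.add("no_transposase")
    status = "autonomous" if not reasons else "nonautonomous"
    return AutonomyCall(element_id=element_id, status=status, reasons=frozenset(reasons))


def link_derivatives(
    calls: Sequence[AutonomyCall], names: Sequence[ElementName]
) -> list[AutonomyCall]:
    """Fill parent_id for nonautonomous N-suffix derivatives whose stem names
    an element present in the dataset."""
    by_raw = {n.render(): n for n in names}
    present = set(by_raw)
    out = []
    for call in calls:
        parent = None
        name = by_raw.get(call.element_id)
        if (
            call.status == "nonautonomous"
            and name is not None
            and name.n_suffix_index is not None
            and name.stem in present
        ):
            parent = name.stem
        out.append(
            AutonomyCall(
                element_id=call.element_id,
                status=call.status,
                reasons=call.reasons,
                parent_id=parent,
            )
        )
    return out


@dataclass
class DatasetSummary:
    per_species: dict
    n_total: int
    n_autonomous: int
    autonomous_percent: float  # truncated to one decimal
    tir_consensus: str


def autonomous_percent(n_autonomous: int, n_total: int) -> float:
    """Percentage truncated (floored) to one decimal: 35/276 -> 12.6."""
    return math.floor(1000 * n_autonomous / n_total) / 10


def summarize(
    elements: Sequence[ConsensusElement],
    calls: Sequence[AutonomyCall],
    tir_consensus: str = "",
) -> DatasetSummary:
    if not elements:
        raise ValueError("empty dataset")
    if len(elements) != len(calls):
        raise ValueError("need exactly one call per element")
    per_species: dict = {}
    for e in elements:
        per_species[e.species_code] = per_species.get(e.species_code, 0) + 1
    n_auto = sum(1 for c in calls if c.status == "autonomous")
    return DatasetSummary(
        per_species=per_species,
        n_total=len(elements),
        n_autonomous=n_auto,
        autonomous_percent=autonomous_percent(n_auto, len(elements)),
        tir_consensus=tir_consensus,
    )
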