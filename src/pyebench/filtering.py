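"""Identification and quantification-eligibility filters.

The filtering cascade applied before any metric: decoy (reversed-sequence)
hits and potential contaminants are removed, proteins must be identified by
at least two peptides, and — when q-value gates are present (the DIA path) —
every configured gate must be <= its threshold.  For ratio-based metrics a
protein must additionally be quantified in at least three replicate runs of
each condition of the compared pair, and species-ambiguous ("mixed") or
unassigned groups are excluded (they still count toward ID totals upstream).

Removal reasons are attributed in a fixed order (decoy -> contaminant ->
peptides -> q-gates), each record to its first failing rule, so audits are
deterministic and conserve record counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from pyebench.quant_io import Q_GATE_COLUMNS, QuantIOError, QuantTable

__all__ = [
    "FilterPolicy",
    "apply_identification_filters",
    "quantification_eligibility",
    "restrict_for_ratio_metrics",
]

logger = logging.getLogger(__name__)

DEFAULT_Q_GATES: dict[str, float] = {gate: 0.01 for gate in Q_GATE_COLUMNS}


@dataclass(frozen=True)
class FilterPolicy:
    """Thresholds of the identification / quantification filter cascade."""

    min_peptides: int = 2
    q_gates: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_Q_GATES))
    min_reps_per_condition: int = 3
    drop_decoys: bool = True
    drop_contaminants: bool = True
    drop_mixed_species: bool = True  # ratio metrics only

    def __post_init__(self) -> None:
        object.__setattr__(self, "q_gates", dict(self.q_gates))
        if self.min_peptides < 1 or self.min_reps_per_condition < 1:
            raise ValueError("count thresholds must be >= 1")
        for gate, thr in self.q_gates.items():
            if gate not in Q_GATE_COLUMNS:
                raise ValueError(f"unknown q-value gate {gate!r}")
            if not 0 < thr <= 1:
                raise ValueError(f"gate threshold for {gate!r} must be in (0, 1]")


def apply_identification_filters(
    table: QuantTable, policy: FilterPolicy | None = None
) -> tuple[QuantTable, dict[str, int]]:
    """Remove decoys, contaminants, <min-peptide and q-gate-failing records.

    Absent q-values skip the gate checks (the DDA path carries none).
    Returns the filtered table and audit counts per removal reason; the
    audit attributes each removed record to its first failing rule in the
    order decoy -> contaminant -> peptides -> q-gates.
    """
    policy = policy or FilterPolicy()
    df = table.data
    removed = pd.Series("", index=df.index, dtype=object)

    def mark(mask: pd.Series, reason: str) -> None:
        fresh = mask & (removed == "")
        removed[fresh] = reason

    if policy.drop_decoys:
        mark(df["is_decoy"], "decoy")
    if policy.drop_contaminants:
        mark(df["is_contaminant"], "contaminant")
    mark(df["n_peptides"] < policy.min_peptides, "peptides")
    gate_fail = pd.Series(False, index=df.index)
    for gate, thr in policy.q_gates.items():
        gate_fail |= df[gate].notna() & (df[gate] > thr)
    mark(gate_fail, "q_gates")

    audit = {
        reason: int((removed == reason).sum())
        for reason in ("decoy", "contaminant", "peptides", "q_gates")
    }
    kept = df[removed == ""]
    return table.with_data(kept), audit


def quantification_eligibility(
    table: QuantTable,
    policy: FilterPolicy | None = None,
    pair: tuple[str, str] | None = None,
) -> pd.Series:
    """Per-protein eligibility for ratio metrics at one A/B pair.

    A protein is eligible iff it is quantified in at least
    `min_reps_per_condition` replicate runs of sample A AND of sample B.
    Ineligible proteins are excluded from ratio/violin computations but
    remain in ID counts upstream.  Returns a boolean Series indexed by
    protein group.
    """
    policy = policy or FilterPolicy()
    if pair is None:
        raise QuantIOError("pair=(sample_A, sample_B) is required")
    sample_a, sample_b = pair
    df = table.data
    present = set(df["sample_id"].unique())
    missing = {sample_a, sample_b} - present
    if missing:
        raise QuantIOError(f"pair samples absent from table: {sorted(missing)}")
    detected = df[df["intensity"].notna()]
    counts = (
        detected[detected["sample_id"].isin([sample_a, sample_b])]
        .groupby(["protein_group", "sample_id"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=[sample_a, sample_b], fill_value=0)
    )
    all_proteins = pd.Index(df["protein_group"].unique(), name="protein_group")
    counts = counts.reindex(all_proteins, fill_value=0)
    return (counts[sample_a] >= policy.min_reps_per_condition) & (
        counts[sample_b] >= policy.min_reps_per_condition
    )


def restrict_for_ratio_metrics(
    table: QuantTable, policy: FilterPolicy | None = None
) -> QuantTable:
    """Drop species-ambiguous ("mixed") and unassigned groups for ratio metrics."""
    policy = policy or FilterPolicy()
    if not policy.drop_mixed_species:
        return table
    df = table.data
    kept = df[~df["species"].isin(["mixed", "unknown"])]
    if kept.empty and not df.empty:
        warnings.warn("all protein groups are species-ambiguous; ratio table is empty")
        logger.warning("restrict_for_ratio_metrics produced an empty table")
    return QuantTable(kept, dict(table.metadata))
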