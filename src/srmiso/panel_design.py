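"""Proteotypic-peptide filtering and assay-panel assembly.

Candidate peptides are retained when they (a) classify to exactly one
detection group, (b) fall within length bounds, (c) carry at most the
configured number of missed cleavages, and (d) — because the target
family is glycosylated — contain no N-X-[S/T] glycosylation sequon.
Survivors are ranked: peptides free of oxidation-prone residues (M, W by
default) first, then shorter peptides, ties broken lexicographically so
panel assembly is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .isoform_db import (
    Classification,
    DetectionGroup,
    DigestPeptide,
    IsoformRecord,
    PeptideIndex,
    classify_peptide,
)


@dataclass(frozen=True)
class CandidateFilterRules:
    """Composition/size filters for proteotypic candidates.

    Defaults: 7–25 residues (community-standard PTP practice), sequon
    exclusion on, penalized residues {M, W} (oxidation-prone; C is fine
    because it is carbamidomethylated), fully cleaved peptides only for
    quantification.
    """

    min_length: int = 7
    max_length: int = 25
    forbid_sequon: bool = True
    penalized_residues: frozenset = frozenset("MW")
    max_missed_for_quant: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.min_length <= self.max_length):
            raise ValueError("need 1 <= min_length <= max_length")
        object.__setattr__(
            self, "penalized_residues", frozenset(self.penalized_residues)
        )


@dataclass
class AssayPanel:
    """Validated-style assay panel: ranked peptides per detection group."""

    entries: list  # list of (group_label, list[DigestPeptide])
    min_ptps: int = 2

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for _, peps in self.entries:
            for p in peps:
                if p.sequence in seen:
                    raise ValueError(
                        f"peptide {p.sequence} appears under two groups"
                    )
                seen.add(p.sequence)

    @property
    def species_count(self) -> int:
        return sum(1 for _, peps in self.entries if peps)

    @property
    def n_assays(self) -> int:
        return sum(len(peps) for _, peps in self.entries)

    def peptides_for(self, label: str) -> list:
        for lab, peps in self.entries:
            if lab == label:
                return list(peps)
        raise KeyError(label)

    def group_labels(self) -> list:
        return [lab for lab, _ in self.entries]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, peps in self.entries:
            for rank, p in enumerate(peps, start=1):
                rows.append(
                    {
                        "group_label": label,
                        "peptide": p.sequence,
                        "parent_id": p.parent_id,
                        "start": p.start,
                        "end": p.end,
                        "rank": rank,
                        "flags": "below_min_ptps" if len(peps) < self.min_ptps else "",
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["group_label", "peptide", "parent_id", "start", "end", "rank", "flags"],
        )


def has_glyco_sequon(peptide: DigestPeptide, parent_sequence: str) -> bool:
    """True iff an N-X-[S/T] sequon (X != P) *begins* at an N inside the
    peptide, evaluated in full parent context — the sequon may extend
    past the peptide's C-terminus."""
    if not (1 <= peptide.start <= peptide.end <= len(parent_sequence)):
        raise ValueError("peptide coordinates outside parent")
    for pos in range(peptide.start - 1, peptide.end):  # 0-based N positions
        if parent_sequence[pos] != "N":
            continue
        if pos + 2 < len(parent_sequence):
            x, third = parent_sequence[pos + 1], parent_sequence[pos + 2]
            if x != "P" and third in "ST":
                return True
    return False


def _rank_key(rules: CandidateFilterRules):
    def key(pep: DigestPeptide):
        penalized = any(r in rules.penalized_residues for r in pep.sequence)
        return (penalized, len(pep.sequence), pep.sequence)

    return key


def select_proteotypic(
    digest: Sequence[DigestPeptide],
    database: Iterable[IsoformRecord] | PeptideIndex,
    groups: Iterable[DetectionGroup],
    rules: CandidateFilterRules | None = None,
    il_equivalent: bool = True,
    max_missed: int = 2,
) -> tuple[dict, list]:
    """Filter and rank digest peptides per detection group.

    Returns ``(candidates, coverage_gaps)``: candidates maps group label
    -> ranked list of :class:`DigestPeptide`; coverage_gaps lists group
    labels with zero surviving candidates (reported, never raised).
    """
    rules = rules or CandidateFilterRules()
    groups = list(groups)
    if isinstance(database, PeptideIndex):
        index = database
    else:
        index = PeptideIndex(database, max_missed=max_missed, il_equivalent=il_equivalent)
    parents = {r.isoform_id: r.sequence for r in index.records}

    by_group: dict[str, dict[str, DigestPeptide]] = {g.label: {} for g in groups}
    for pep in digest:
        if pep.missed_cleavages > rules.max_missed_for_quant:
            continue
        if not (rules.min_length <= len(pep.sequence) <= rules.max_length):
            continue
        if rules.forbid_sequon and has_glyco_sequon(pep, parents[pep.parent_id]):
            continue
        cls = classify_peptide(index.membership(pep.sequence), groups)
        if not cls.is_proteotypic:
            continue
        # dedupe by sequence within a group (same peptide from many parents)
        by_group[cls.label].setdefault(pep.sequence, pep)

    key = _rank_key(rules)
    candidates = {
        g.label: sorted(by_group[g.label].values(), key=key) for g in groups
    }
    coverage_gaps = [lab for lab, peps in candidates.items() if not peps]
    return candidates, coverage_gaps


def build_panel(candidates: Mapping[str, Sequence[DigestPeptide]],
                min_ptps: int = 2, max_ptps: int = 3) -> AssayPanel:
    """Take up to ``max_ptps`` top-ranked candidates per group.

    ``species_count`` (on the returned panel) is the number of groups
    with at least one peptide; groups below ``min_ptps`` are flagged in
    the TSV export, not dropped.
    """
    entries = []
    assigned: set[str] = set()
    for label in sorted(candidates):
        peps = []
        for pep in candidates[label]:
            if pep.sequence in assigned:
                continue
            peps.append(pep)
            assigned.add(pep.sequence)
            if len(peps) >= max_ptps:
                break
        entries.append((label, peps))
    return AssayPanel(entries=entries, min_ptps=min_ptps)
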