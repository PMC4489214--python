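"""Isoform databases, in-silico tryptic digestion, and peptide classification.

A highly diversified protein family (the motivating case is the neurexin
family: 3 genes x {alpha, beta} promoters x binary insertions at named
alternatively spliced segments) is represented as a set of
:class:`IsoformRecord` objects.  Peptide-level evidence is interpreted
against this set: a peptide's *membership* is the exact set of isoforms
whose tryptic digest produces it, and its *classification* is the
detection group (pan / promoter-specific / splice-insertion-specific)
whose member set it matches.

Trypsin cleaves C-terminal to K or R unless the next residue is P.
Coordinates are 1-based inclusive throughout (protein convention).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids.  B, J, O, U, X, Z are rejected at parse
#: time because their monoisotopic mass is undefined or ambiguous.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

ALPHA = "alpha"
BETA = "beta"

GENE_PAN = "gene_pan"
PROMOTER = "promoter"
SPLICE_INSERTION = "splice_insertion"

#: classification sentinels
NON_PROTEOTYPIC = "non_proteotypic"
ABSENT = "absent"


class IsoformDatabaseError(ValueError):
    """Malformed isoform database input (header grammar, duplicate ids,
    invalid residues)."""


@dataclass(frozen=True)
class IsoformRecord:
    """One annotated protein isoform.

    Parameters
    ----------
    isoform_id : str
        Unique identifier within a database.
    gene : str
        Gene symbol (e.g. ``Nrxn1``).
    promoter_class : str
        ``"alpha"`` (long form) or ``"beta"`` (short form; in the
        neurexin architecture the beta sequence is a C-terminal suffix of
        alpha preceded by a short beta-unique N-terminus).
    insertions : mapping
        Segment name (e.g. ``AS4``) -> bool presence flag.  Segments that
        do not apply to this promoter class are simply absent.
    sequence : str
        Uppercase amino-acid sequence over the 20-letter alphabet.
    """

    isoform_id: str
    gene: str
    promoter_class: str
    insertions: Mapping[str, bool]
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise IsoformDatabaseError(f"{self.isoform_id}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise IsoformDatabaseError(
                f"{self.isoform_id}: invalid residue(s) {sorted(bad)}"
            )
        if self.promoter_class not in (ALPHA, BETA):
            raise IsoformDatabaseError(
                f"{self.isoform_id}: promoter_class must be 'alpha' or 'beta', "
                f"got {self.promoter_class!r}"
            )
        object.__setattr__(self, "insertions", dict(self.insertions))

    def __hash__(self) -> int:  # insertions dict is effectively frozen
        return hash((self.isoform_id, self.sequence))


@dataclass(frozen=True)
class DigestPeptide:
    """A fully tryptic peptide located in its parent sequence.

    ``start``/``end`` are 1-based inclusive; the parent slice
    ``parent[start-1:end]`` equals :attr:`sequence`.
    """

    sequence: str
    start: int
    end: int
    missed_cleavages: int
    parent_id: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DetectionGroup:
    """A named set of isoforms a proteotypic peptide can report on.

    ``level`` is one of ``gene_pan`` (all isoforms of one gene),
    ``promoter`` (all alpha or all beta isoforms of one gene) or
    ``splice_insertion`` (all isoforms of one gene carrying a given
    segment insertion).
    """

    label: str
    member_isoform_ids: frozenset
    level: str

    def __post_init__(self) -> None:
        if not self.member_isoform_ids:
            raise IsoformDatabaseError(f"group {self.label}: empty member set")
        object.__setattr__(
            self, "member_isoform_ids", frozenset(self.member_isoform_ids)
        )


# ---------------------------------------------------------------------------
# FASTA parsing
# ---------------------------------------------------------------------------

DEFAULT_HEADER_GRAMMAR = {"gene_key": "gene", "promoter_key": "promoter"}


def parse_isoform_fasta(path, header_grammar: Mapping | None = None) -> list[IsoformRecord]:
    """Read an isoform database from FASTA with annotated headers.

    Headers carry ``key=value`` tokens after the record id, e.g.::

        >N1_a_AS3+AS4- gene=Nrxn1 promoter=alpha AS3=1 AS4=0

    Keys other than the gene/promoter keys whose values are ``0``/``1``
    are interpreted as splice-segment flags.  ``header_grammar`` can
    remap ``gene_key`` / ``promoter_key`` for foreign databases.
    """
    grammar = dict(DEFAULT_HEADER_GRAMMAR)
    if header_grammar:
        grammar.update(header_grammar)
    gene_key = grammar["gene_key"]
    promoter_key = grammar["promoter_key"]

    records: list[IsoformRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        tokens = entry.description.split()[1:]
        kv: dict[str, str] = {}
        for tok in tokens:
            if "=" not in tok:
                raise IsoformDatabaseError(
                    f"entry {entry.id!r}: malformed header token {tok!r} "
                    "(expected key=value)"
                )
            key, _, value = tok.partition("=")
            kv[key] = value
        if gene_key not in kv or promoter_key not in kv:
            raise IsoformDatabaseError(
                f"entry {entry.id!r}: header missing {gene_key!r} or "
                f"{promoter_key!r}"
            )
        insertions = {
            k: v == "1"
            for k, v in kv.items()
            if k not in (gene_key, promoter_key)
        }
        for k, v in kv.items():
            if k in (gene_key, promoter_key):
                continue
            if v not in ("0", "1"):
                raise IsoformDatabaseError(
                    f"entry {entry.id!r}: segment flag {k}={v!r} must be 0 or 1"
                )
        if entry.id in seen:
            raise IsoformDatabaseError(f"duplicate isoform_id {entry.id!r}")
        seen.add(entry.id)
        seq = str(entry.seq).upper().rstrip("*")
        records.append(
            IsoformRecord(
                isoform_id=entry.id,
                gene=kv[gene_key],
                promoter_class=kv[promoter_key],
                insertions=insertions,
                sequence=seq,
            )
        )
    if not records:
        warnings.warn(f"no records parsed from {path}", stacklevel=2)
    return records


def write_isoform_fasta(records: Iterable[IsoformRecord], path, comment: str | None = None) -> None:
    """Write records with the key=value header grammar (60-column wrap)."""
    path = Path(path)
    with path.open("w") as fh:
        if comment:
            fh.write(f";{comment}\n")
        for rec in records:
            flags = " ".join(
                f"{seg}={int(flag)}" for seg, flag in sorted(rec.insertions.items())
            )
            header = f">{rec.isoform_id} gene={rec.gene} promoter={rec.promoter_class}"
            if flags:
                header += f" {flags}"
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Digestion
# ---------------------------------------------------------------------------

def cleavage_sites(sequence: str) -> list[int]:
    """Tryptic cleavage sites as 0-based indices *after* which the bond is
    cut: ``i`` is a site iff ``sequence[i] in 'KR'`` and the following
    residue (if any) is not P.  The C-terminus is not included."""
    n = len(sequence)
    return [
        i
        for i in range(n - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def tryptic_digest(record: IsoformRecord | str, max_missed: int = 0,
                   parent_id: str | None = None) -> list[DigestPeptide]:
    """All fully tryptic peptides with 0..``max_missed`` missed cleavages.

    Peptides are returned in coordinate order (by start, then by missed
    cleavages).  The zero-missed peptides concatenate to the parent
    sequence.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    if isinstance(record, IsoformRecord):
        seq, pid = record.sequence, record.isoform_id
    else:
        seq, pid = record, (parent_id or "")
    # segment boundaries: 0, site+1 ..., len
    bounds = [0] + [s + 1 for s in cleavage_sites(seq)] + [len(seq)]
    peptides: list[DigestPeptide] = []
    nseg = len(bounds) - 1
    for i in range(nseg):
        for m in range(max_missed + 1):
            j = i + m + 1
            if j > nseg:
                break
            peptides.append(
                DigestPeptide(
                    sequence=seq[bounds[i] : bounds[j]],
                    start=bounds[i] + 1,
                    end=bounds[j],
                    missed_cleavages=m,
                    parent_id=pid,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.missed_cleavages))
    return peptides


def _fold_il(seq: str) -> str:
    return seq.replace("I", "L")


class PeptideIndex:
    """Peptide -> isoform membership index over a database digest.

    Built once per database; membership queries then run in O(1).  With
    ``il_equivalent`` (the default) isobaric I and L are folded together
    before indexing, since SRM cannot distinguish them.
    """

    def __init__(self, database: Iterable[IsoformRecord], max_missed: int = 2,
                 il_equivalent: bool = True):
        self.records = list(database)
        ids = [r.isoform_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise IsoformDatabaseError("duplicate isoform_id in database")
        self.max_missed = max_missed
        self.il_equivalent = il_equivalent
        self._index: dict[str, set[str]] = {}
        for rec in self.records:
            for pep in tryptic_digest(rec, max_missed):
                key = _fold_il(pep.sequence) if il_equivalent else pep.sequence
                self._index.setdefault(key, set()).add(rec.isoform_id)

    def membership(self, peptide_sequence: str) -> frozenset:
        key = _fold_il(peptide_sequence) if self.il_equivalent else peptide_sequence
        return frozenset(self._index.get(key, ()))


def peptide_membership(peptide_sequence: str,
                       database: Iterable[IsoformRecord] | PeptideIndex,
                       il_equivalent: bool = True,
                       max_missed: int = 2) -> frozenset:
    """Exactly the isoforms whose tryptic digest (at ``max_missed``)
    contains ``peptide_sequence``.

    A peptide only "occurs" in an isoform where the digest would produce
    it, i.e. at tryptic boundaries — SRM observes digest products, not
    arbitrary substrings.
    """
    if not peptide_sequence:
        raise ValueError("peptide_sequence must be non-empty")
    if isinstance(database, PeptideIndex):
        return database.membership(peptide_sequence)
    index = PeptideIndex(database, max_missed=max_missed, il_equivalent=il_equivalent)
    return index.membership(peptide_sequence)


# ---------------------------------------------------------------------------
# Detection groups & classification
# ---------------------------------------------------------------------------

_LEVEL_SPECIFICITY = {SPLICE_INSERTION: 0, PROMOTER: 1, GENE_PAN: 2}


def build_detection_groups(database: Iterable[IsoformRecord]) -> list[DetectionGroup]:
    """Derive the standard detection-group taxonomy from a database.

    Per gene: a pan group (all isoforms), one promoter group per promoter
    class present, and one insertion group per declared segment (members
    = isoforms carrying the insertion).  Yields 17 groups for the
    neurexin-like architecture (3 genes; pan+alpha+beta each; AS3/AS4/AS6
    insertion groups for two genes and AS3/AS4 for the third).
    """
    records = list(database)
    genes = sorted({r.gene for r in records})
    groups: list[DetectionGroup] = []
    for gene in genes:
        members = [r for r in records if r.gene == gene]
        groups.append(
            DetectionGroup(
                label=f"{gene}-pan",
                member_isoform_ids=frozenset(r.isoform_id for r in members),
                level=GENE_PAN,
            )
        )
        for promoter in (ALPHA, BETA):
            sub = [r for r in members if r.promoter_class == promoter]
            if sub:
                groups.append(
                    DetectionGroup(
                        label=f"{gene}-{promoter}",
                        member_isoform_ids=frozenset(r.isoform_id for r in sub),
                        level=PROMOTER,
                    )
                )
        segments = sorted({s for r in members for s in r.insertions})
        for seg in segments:
            carriers = [r for r in members if r.insertions.get(seg, False)]
            if carriers:
                groups.append(
                    DetectionGroup(
                        label=f"{gene}-{seg}+",
                        member_isoform_ids=frozenset(r.isoform_id for r in carriers),
                        level=SPLICE_INSERTION,
                    )
                )
    return groups


@dataclass(frozen=True)
class Classification:
    """Outcome of matching a membership set against detection groups."""

    label: str
    group: DetectionGroup | None = None

    @property
    def is_proteotypic(self) -> bool:
        return self.group is not None


def classify_peptide(membership: frozenset | set,
                     groups: Iterable[DetectionGroup]) -> Classification:
    """Classify a membership set against a group taxonomy.

    Returns the most specific group whose member set equals the
    membership *exactly*; ``non_proteotypic`` when the membership spans
    several genes or matches no group; ``absent`` for an empty
    membership.  Deterministic and independent of group/database order.
    """
    membership = frozenset(membership)
    if not membership:
        return Classification(ABSENT)
    matches = [g for g in groups if g.member_isoform_ids == membership]
    if not matches:
        return Classification(NON_PROTEOTYPIC)
    matches.sort(key=lambda g: (_LEVEL_SPECIFICITY.get(g.level, 99), g.label))
    return Classification(matches[0].label, matches[0])
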