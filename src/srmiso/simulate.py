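"""Synthetic isoform families and SRM/shotgun data with known ground truth.

The family generator emulates the neurexin architecture: each gene has a
long alpha form and a short beta form transcribed from alternative
promoters, where the beta sequence is a C-terminal suffix of alpha
preceded by a short beta-unique N-terminus; binary insertions at named
alternatively spliced segments (AS3/AS6 in the alpha-specific region,
AS4 in the shared region) generate all 2^k combinations.  Sequences are
assembled from unique tryptic blocks (each ending in K or R, interior
residues avoiding K/R/P) so that every declared detection group is
covered by at least one proteotypic peptide *by construction*: shared
blocks yield pan peptides, alpha-region blocks yield alpha-specific
peptides, beta-prefix blocks yield beta-specific peptides, and each
insert is itself a tryptic block reporting its segment.

The SRM simulator produces transition-level peak areas under the
isotope-dilution model: light and heavy areas share a per-transition
base response (the co-elution/co-fragmentation assumption) scaled by the
respective analyte amounts, with multiplicative log-normal noise of
configurable CV applied independently per transition, replicate and
label.  At zero noise the quantification chain recovers the ground
truth exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .isoform_db import (
    ALPHA,
    BETA,
    IsoformRecord,
    PeptideIndex,
    build_detection_groups,
    tryptic_digest,
)
from .masscalc import HEAVY, LIGHT, PeptideSpecies, select_transitions
from .panel_design import AssayPanel, CandidateFilterRules, build_panel, select_proteotypic
from .quantify import PEAK_AREA_COLUMNS, StandardChain
from .profiling import SpectralCountTable

#: interior residues for generated tryptic blocks: no K/R (cleavage), no P
#: (would suppress cleavage), no I (keeps I/L-folded uniqueness trivial),
#: no N (keeps generated backbones sequon-free so composition filters
#: never empty a detection group)
_BLOCK_ALPHABET = "ACDEFGHLMQSTVWY"

NEUREXIN_SEGMENTS = {
    "NRX1": ("AS3", "AS4", "AS6"),
    "NRX2": ("AS3", "AS4"),
    "NRX3": ("AS3", "AS4", "AS6"),
}

#: whole-brain fmol/µg study conditions for the promoter variants
DEFAULT_ALPHA_AMOUNTS = {"NRX1": 3.86, "NRX2": 2.19, "NRX3": 4.18}
DEFAULT_BETA_AMOUNTS = {"NRX1": 0.87, "NRX2": 1.39, "NRX3": 1.97}
#: insertion-bearing fraction of the parent pool (AS3/AS6 of alpha, AS4 of pan)
DEFAULT_INSERTION_FRACTIONS = {"AS3": 0.5, "AS4": 0.4, "AS6": 0.25}


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class FamilyConfig:
    """Parameters of a generated isoform family.

    ``shared_segments`` lists the segments located in the region shared
    by alpha and beta (hence present in both promoter classes); all
    other segments live in the alpha-specific region.
    """

    seed: int
    n_genes: int = 3
    segments_per_gene: Mapping[str, tuple] = field(
        default_factory=lambda: dict(NEUREXIN_SEGMENTS)
    )
    insert_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"AS3": 12, "AS4": 12, "AS6": 12}
    )
    backbone_length: int = 120
    beta_unique_prefix_length: int = 24
    shared_segments: tuple = ("AS4",)

    def __post_init__(self) -> None:
        for seg, ln in self.insert_lengths.items():
            if ln < 4:
                raise SimulationError(f"insert length for {seg} must be >= 4")
        if self.n_genes != len(self.segments_per_gene):
            raise SimulationError("n_genes must match segments_per_gene")


def neurexin_like_config(seed: int) -> FamilyConfig:
    """The default study-condition family: 3 genes, pan+alpha+beta each,
    insertion groups AS3/AS4/AS6 for two genes and AS3/AS4 for one —
    26 isoforms and 17 detection groups."""
    return FamilyConfig(seed=seed)


def _random_block(rng: np.random.Generator, length: int) -> str:
    interior = rng.choice(list(_BLOCK_ALPHABET), size=length - 1)
    last = rng.choice(["K", "R"])
    return "".join(interior) + last


def _unique_block(rng, length, taken: set, max_tries: int = 200) -> str:
    for _ in range(max_tries):
        block = _random_block(rng, length)
        if block not in taken:
            taken.add(block)
            return block
    raise SimulationError("could not generate a unique tryptic block")


def generate_family(config: FamilyConfig,
                    rules: CandidateFilterRules | None = None) -> list[IsoformRecord]:
    """Generate all isoforms of a family; deterministic under the seed.

    Raises when the configuration cannot guarantee a proteotypic peptide
    per detection group (e.g. an insert shorter than the minimum peptide
    length), and verifies coverage on the finished family.
    """
    rules = rules or CandidateFilterRules()
    for seg, ln in config.insert_lengths.items():
        if not (rules.min_length <= ln <= rules.max_length):
            raise SimulationError(
                f"insert {seg} length {ln} cannot yield a proteotypic peptide "
                f"within length bounds [{rules.min_length}, {rules.max_length}]"
            )
    rng = np.random.default_rng(config.seed)
    taken: set[str] = set()
    records: list[IsoformRecord] = []

    def block_length() -> int:
        lo = rules.min_length + 1
        hi = min(rules.max_length, 16)
        return int(rng.integers(lo, hi + 1))

    n_blocks = max(5, round(config.backbone_length / 11))
    for gene in config.segments_per_gene:
        segments = tuple(config.segments_per_gene[gene])
        alpha_segs = [s for s in segments if s not in config.shared_segments]
        shared_segs = [s for s in segments if s in config.shared_segments]

        n_alpha_blocks = max(len(alpha_segs) + 1, (n_blocks * 3) // 5)
        n_shared_blocks = max(len(shared_segs) + 1, n_blocks - n_alpha_blocks)
        alpha_blocks = [_unique_block(rng, block_length(), taken)
                        for _ in range(n_alpha_blocks)]
        shared_blocks = [_unique_block(rng, block_length(), taken)
                         for _ in range(n_shared_blocks)]
        beta_prefix: list[str] = []
        while sum(map(len, beta_prefix)) < config.beta_unique_prefix_length:
            beta_prefix.append(_unique_block(rng, block_length(), taken))
        inserts = {
            seg: _unique_block(rng, config.insert_lengths[seg], taken)
            for seg in segments
        }
        # insertion slots: segment i sits after block i+1 of its region
        alpha_slots = {seg: i + 1 for i, seg in enumerate(alpha_segs)}
        shared_slots = {seg: i + 1 for i, seg in enumerate(shared_segs)}

        def assemble(region_blocks, slots, flags) -> str:
            parts = []
            for i, block in enumerate(region_blocks):
                parts.append(block)
                for seg, pos in slots.items():
                    if pos == i + 1 and flags.get(seg, False):
                        parts.append(inserts[seg])
            return "".join(parts)

        def combos(segs):
            if not segs:
                yield {}
                return
            for bits in range(2 ** len(segs)):
                yield {s: bool(bits >> i & 1) for i, s in enumerate(segs)}

        def iso_id(promoter, flags):
            tag = "".join(
                f"{s}{'+' if flags[s] else '-'}" for s in sorted(flags)
            )
            return f"{gene}_{promoter[0]}_{tag}" if tag else f"{gene}_{promoter[0]}"

        for flags_shared in combos(shared_segs):
            shared_seq = assemble(shared_blocks, shared_slots, flags_shared)
            for flags_alpha in combos(alpha_segs):
                flags = {**flags_alpha, **flags_shared}
                seq = assemble(alpha_blocks, alpha_slots, flags_alpha) + shared_seq
                records.append(
                    IsoformRecord(
                        isoform_id=iso_id(ALPHA, flags),
                        gene=gene,
                        promoter_class=ALPHA,
                        insertions=flags,
                        sequence=seq,
                    )
                )
            records.append(
                IsoformRecord(
                    isoform_id=iso_id(BETA, dict(flags_shared)),
                    gene=gene,
                    promoter_class=BETA,
                    insertions=dict(flags_shared),
                    sequence="".join(beta_prefix) + shared_seq,
                )
            )

    _check_group_coverage(records, rules)
    return records


def _check_group_coverage(records: Sequence[IsoformRecord],
                          rules: CandidateFilterRules) -> None:
    groups = build_detection_groups(records)
    index = PeptideIndex(records, max_missed=rules.max_missed_for_quant)
    digest = [p for r in records for p in tryptic_digest(r, rules.max_missed_for_quant)]
    _, gaps = select_proteotypic(digest, index, groups, rules)
    if gaps:
        raise SimulationError(
            f"generated family leaves detection group(s) without a "
            f"proteotypic peptide: {gaps}"
        )


def design_default_panel(records: Sequence[IsoformRecord],
                         rules: CandidateFilterRules | None = None,
                         min_ptps: int = 2, max_ptps: int = 2) -> AssayPanel:
    """Digest -> filter -> panel with default rules (convenience driver)."""
    rules = rules or CandidateFilterRules()
    groups = build_detection_groups(records)
    index = PeptideIndex(records, max_missed=max(2, rules.max_missed_for_quant))
    digest = [
        p for r in records for p in tryptic_digest(r, rules.max_missed_for_quant)
    ]
    candidates, _ = select_proteotypic(digest, index, groups, rules)
    return build_panel(candidates, min_ptps=min_ptps, max_ptps=max_ptps)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth amounts and acquisition parameters for a simulation.

    ``amounts`` maps species (detection-group) label -> fmol/µg;
    ``spike_levels`` maps label -> heavy standard amount in fmol (the
    heavy peptide spike in relative mode, the heavy fusion-standard
    amount in PSAQ mode).
    """

    amounts: Mapping[str, float]
    spike_levels: Mapping[str, float]
    noise_cv: float
    n_replicates: int
    seed: int
    protein_mass_ug: float = 5.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.amounts.values()):
            raise SimulationError("amounts must be >= 0")
        if self.noise_cv < 0:
            raise SimulationError("noise_cv must be >= 0")


def default_truth(labels: Iterable[str], seed: int, noise_cv: float = 0.0,
                  n_replicates: int = 1,
                  protein_mass_ug: float = 5.0) -> SimulationTruth:
    """Study-condition ground truth for the neurexin-like label set.

    Promoter-variant amounts follow the whole-brain scale (alpha 2.2–4.2
    fmol/µg, beta 0.9–2.0 fmol/µg); pan is their sum; insertion-bearing
    pools are fixed fractions of their parent.  Heavy spikes are
    titrated to the endogenous level (standard/endogenous ratio 1).
    """
    amounts: dict[str, float] = {}
    for label in labels:
        gene, _, variant = label.rpartition("-")
        alpha = DEFAULT_ALPHA_AMOUNTS.get(gene, 3.0)
        beta = DEFAULT_BETA_AMOUNTS.get(gene, 1.0)
        if variant == "pan":
            amounts[label] = alpha + beta
        elif variant == ALPHA:
            amounts[label] = alpha
        elif variant == BETA:
            amounts[label] = beta
        else:
            seg = variant.rstrip("+")
            frac = DEFAULT_INSERTION_FRACTIONS.get(seg, 0.3)
            parent = alpha if seg in ("AS3", "AS6") else alpha + beta
            amounts[label] = frac * parent
    spikes = {lab: amt * protein_mass_ug for lab, amt in amounts.items()}
    return SimulationTruth(
        amounts=amounts,
        spike_levels=spikes,
        noise_cv=noise_cv,
        n_replicates=n_replicates,
        seed=seed,
        protein_mass_ug=protein_mass_ug,
    )


def make_standard_chains(panel: AssayPanel, truth: SimulationTruth,
                         gfp_light_amount: float = 100.0) -> dict:
    """One PSAQ standard chain per panel species, each with two anchor
    (GFP) peptides and the species' panel peptides as target peptides."""
    chains = {}
    for label, peps in panel.entries:
        if not peps or label not in truth.amounts:
            continue
        chains[label] = StandardChain(
            gfp_light_amount=gfp_light_amount,
            gfp_peptides=(f"GFP.{label}.1", f"GFP.{label}.2"),
            target_peptides=tuple(p.sequence for p in peps),
            sample_protein_mass=truth.protein_mass_ug,
        )
    return chains


# ---------------------------------------------------------------------------
# SRM simulation
# ---------------------------------------------------------------------------

def _noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=size)


def simulate_srm_run(panel: AssayPanel, truth: SimulationTruth,
                     chains: Mapping[str, StandardChain] | StandardChain | None = None,
                     seed: int | None = None,
                     precursor_charge: int = 2,
                     max_transitions: int = 4) -> pd.DataFrame:
    """Transition-level peak areas for a panel under known truth.

    Per peptide × transition a base response is drawn once and shared by
    the light and heavy species (co-elution assumption); the light area
    scales with the endogenous amount × digested protein mass, the heavy
    area with the standard spike.  With ``chains``, anchor (GFP) peptide
    rows are added per chain: light at the known anchor spike, heavy at
    the fusion-standard amount (= the species' spike level).
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    panel_labels = {lab for lab, peps in panel.entries if peps}
    missing = sorted(set(truth.amounts) - panel_labels)
    if missing:
        raise SimulationError(f"species in truth missing from panel: {missing}")
    if isinstance(chains, StandardChain):
        chains = {lab: chains for lab in panel_labels}

    rows = []
    for label, peps in sorted(panel.entries):
        if not peps:
            continue
        amount = truth.amounts[label]
        spike = truth.spike_levels.get(label, 0.0)
        light_fmol = amount * truth.protein_mass_ug
        chain = (chains or {}).get(label)
        heavy_fmol = spike
        targets = [
            (p.sequence, [t.fragment_name for t in select_transitions(
                PeptideSpecies(p.sequence), precursor_charge, max_transitions)])
            for p in peps
        ]
        if chain is not None:
            targets += [(pep, ["t1", "t2", "t3"]) for pep in chain.gfp_peptides]
        for pep_seq, transition_ids in targets:
            is_anchor = chain is not None and pep_seq in chain.gfp_peptides
            l_amt = chain.gfp_light_amount if is_anchor else light_fmol
            h_amt = heavy_fmol
            base = rng.lognormal(mean=np.log(1e4), sigma=0.6,
                                 size=len(transition_ids))
            for rep in range(truth.n_replicates):
                run_id = f"rep{rep + 1}"
                for lab_ms, amt in ((LIGHT, l_amt), (HEAVY, h_amt)):
                    noise = _noise(rng, truth.noise_cv, len(transition_ids))
                    for t_id, b, nz in zip(transition_ids, base, noise):
                        rows.append(
                            (run_id, "S1", pep_seq, lab_ms, t_id, b * amt * nz)
                        )
    return pd.DataFrame(rows, columns=PEAK_AREA_COLUMNS)


# ---------------------------------------------------------------------------
# shotgun simulation
# ---------------------------------------------------------------------------

def simulate_shotgun_counts(amounts: Mapping[str, float] | pd.DataFrame,
                            lengths: Mapping[str, int],
                            depth: int, seed: int) -> SpectralCountTable:
    """Multinomial spectral counts with sampling probability proportional
    to amount × length (longer proteins yield more peptides)."""
    if depth <= 0:
        raise SimulationError("depth must be > 0")
    if isinstance(amounts, pd.DataFrame):
        table = amounts
    else:
        table = pd.DataFrame({"S1": pd.Series(dict(amounts), dtype=float)})
    rng = np.random.default_rng(seed)
    lens = pd.Series({r: float(lengths[r]) for r in table.index})
    counts = {}
    for col in table.columns:
        weights = table[col].to_numpy(dtype=float) * lens.to_numpy()
        total = weights.sum()
        if total <= 0:
            raise SimulationError(f"all-zero amounts in sample {col!r}")
        counts[col] = rng.multinomial(depth, weights / total)
    df = pd.DataFrame(counts, index=table.index)
    return SpectralCountTable(counts=df, lengths=dict(lens.astype(int)))
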