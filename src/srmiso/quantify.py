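"""Isotope-dilution quantification from transition-level peak areas.

The quantification chain mirrors standard stable-isotope-dilution SRM
practice:

* per peptide and run, transition areas are summed per label and the
  light/heavy ratio is formed over the transition set shared by both
  labels (robust to single-transition dropouts);
* peptide-level amounts are averaged over peptides and replicates into a
  species estimate (mean ± sample SD);
* absolute amounts use the two-step protein-standard (PSAQ) chain: a
  known light anchor-protein spike quantifies the heavy in-vitro-made
  fusion standard via anchor peptides, and the heavy standard in turn
  quantifies the endogenous target via target peptides;
* short promoter variants that lack enough unique sequence for a direct
  standard are obtained by subtraction (pan − alpha), with quadrature
  error propagation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

LIGHT = "light"
HEAVY = "heavy"

PEAK_AREA_COLUMNS = ["run_id", "sample_id", "peptide", "label", "transition_id", "area"]

#: which parent species a splice-insertion measurement is normalized to
DEFAULT_SEGMENT_PARENT_RULES = {"AS3": "alpha", "AS6": "alpha", "AS4": "pan"}

FLAG_TITRATION = "titration_out_of_range"
FLAG_BELOW_LOQ = "below_loq"
FLAG_NEGATIVE = "negative_subtraction"
FLAG_RATIO_GT_1 = "ratio_above_parent"


class QuantError(ValueError):
    pass


class UndefinedRatioError(QuantError):
    """All heavy areas zero (or no shared transitions) for a peptide."""


@dataclass
class QuantEstimate:
    """An amount with dispersion and provenance.

    ``amount`` is in fmol per µg protein for absolute mode, or a
    unitless ratio in relative/normalized modes.  ``dispersion`` is the
    sample SD across peptides × replicates.
    """

    target_label: str
    amount: float
    dispersion: float = 0.0
    n_peptides: int = 1
    n_replicates: int = 1
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise QuantError("dispersion must be >= 0")
        if self.n_peptides < 1:
            raise QuantError("n_peptides must be >= 1")


@dataclass(frozen=True)
class StandardChain:
    """PSAQ standard-chain definition for one target species.

    ``gfp_light_amount`` is the known amount (fmol) of the unlabeled
    anchor protein (GFP) spiked into the sample; ``gfp_peptides`` are
    the anchor peptides shared by the light anchor and the heavy fusion
    standard; ``target_peptides`` report the endogenous protein.
    """

    gfp_light_amount: float
    gfp_peptides: tuple
    target_peptides: tuple
    sample_protein_mass: float  # µg

    def __post_init__(self) -> None:
        if self.gfp_light_amount <= 0 or self.sample_protein_mass <= 0:
            raise QuantError("spike amount and protein mass must be positive")
        object.__setattr__(self, "gfp_peptides", tuple(self.gfp_peptides))
        object.__setattr__(self, "target_peptides", tuple(self.target_peptides))


# ---------------------------------------------------------------------------
# peak-area I/O
# ---------------------------------------------------------------------------

def read_peak_areas(path, sep: str = "\t") -> pd.DataFrame:
    """Read and validate a long-format peak-area table.

    Required columns: run_id, sample_id, peptide, label, transition_id,
    area.  Schema violations raise with the offending line number.
    """
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = [c for c in PEAK_AREA_COLUMNS if c not in df.columns]
    if missing:
        raise QuantError(f"{path}: missing column(s) {missing}")
    df = df[PEAK_AREA_COLUMNS]
    return validate_peak_areas(df, source=str(path))


def validate_peak_areas(df: pd.DataFrame, source: str = "<table>") -> pd.DataFrame:
    bad_label = ~df["label"].isin([LIGHT, HEAVY])
    if bad_label.any():
        line = int(df.index[bad_label][0]) + 2  # 1 header line, 1-based
        raise QuantError(f"{source}: line {line}: label must be light/heavy")
    area = pd.to_numeric(df["area"], errors="coerce")
    bad_area = area.isna() | (area < 0)
    if bad_area.any():
        line = int(df.index[bad_area][0]) + 2
        raise QuantError(f"{source}: line {line}: area must be a non-negative number")
    dup = df.duplicated(subset=["run_id", "peptide", "label", "transition_id"])
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise QuantError(
            f"{source}: line {line}: duplicate (run, peptide, label, transition)"
        )
    out = df.copy()
    out["area"] = area.astype(float)
    return out


# ---------------------------------------------------------------------------
# ratio arithmetic
# ---------------------------------------------------------------------------

def peptide_ratio(measurements: pd.DataFrame, peptide: str | None = None) -> float:
    """Light/heavy area ratio for one run × peptide.

    Areas are summed per label over the transition set observed in both
    labels (pairwise drop of one-sided transitions), then ratioed.
    """
    df = measurements
    if peptide is not None:
        df = df[df["peptide"] == peptide]
    if df.empty:
        raise UndefinedRatioError(f"no measurements for peptide {peptide!r}")
    name = peptide if peptide is not None else str(df["peptide"].iloc[0])
    light = df[df["label"] == LIGHT].set_index("transition_id")["area"]
    heavy = df[df["label"] == HEAVY].set_index("transition_id")["area"]
    shared = light.index.intersection(heavy.index)
    if len(shared) == 0:
        raise UndefinedRatioError(f"peptide {name}: no transition shared by both labels")
    h = float(heavy.loc[shared].sum())
    if h <= 0:
        raise UndefinedRatioError(f"peptide {name}: heavy areas sum to zero")
    return float(light.loc[shared].sum()) / h


def relative_amount(ratio: float, heavy_spike_fmol: float) -> float:
    """fmol of endogenous peptide from a light/heavy ratio and the known
    heavy spike."""
    if heavy_spike_fmol <= 0:
        raise QuantError("heavy spike must be positive")
    return ratio * heavy_spike_fmol


def aggregate_species(target_label: str,
                      peptide_amounts: Mapping[str, Sequence[float]] | Sequence[float],
                      center: str = "mean") -> QuantEstimate:
    """Combine peptide × replicate amounts into one species estimate.

    ``peptide_amounts`` is either a mapping peptide -> per-replicate
    amounts, or a flat sequence (treated as one peptide).  Mean ± sample
    SD by default (``center="median"`` available).  Order-invariant.
    """
    if isinstance(peptide_amounts, Mapping):
        values = [float(v) for seq in peptide_amounts.values() for v in seq]
        n_peptides = len(peptide_amounts)
        n_replicates = max(len(seq) for seq in peptide_amounts.values())
    else:
        values = [float(v) for v in peptide_amounts]
        n_peptides = 1
        n_replicates = len(values)
    if not values:
        raise QuantError(f"{target_label}: no amounts to aggregate")
    arr = np.asarray(values, dtype=float)
    amount = float(np.median(arr) if center == "median" else arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return QuantEstimate(
        target_label=target_label,
        amount=amount,
        dispersion=sd,
        n_peptides=n_peptides,
        n_replicates=n_replicates,
    )


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def _amount(x) -> float:
    return x.amount if isinstance(x, QuantEstimate) else float(x)


def normalize_profile(estimates: Mapping[str, object], reference_region: str) -> dict:
    """Divide a per-region profile by its reference region (maps to 1.0)."""
    if reference_region not in estimates:
        raise QuantError(f"reference region {reference_region!r} missing")
    ref = _amount(estimates[reference_region])
    if ref <= 0:
        raise QuantError(f"reference region {reference_region!r} amount must be > 0")
    return {region: _amount(v) / ref for region, v in estimates.items()}


def normalize_splice_to_parent(splice_estimate, parent_estimates: Mapping[str, object],
                               segment: str,
                               segment_rules: Mapping[str, str] | None = None):
    """Splice-insertion amount over its parent species amount.

    The parent is chosen per segment rule: insertions found exclusively
    in alpha variants (AS3, AS6 by default) are normalized to the alpha
    amount; insertions shared by both promoter classes (AS4) to the pan
    amount.  Ratios above 1 are allowed but flagged as implausible.
    """
    rules = segment_rules or DEFAULT_SEGMENT_PARENT_RULES
    if segment not in rules:
        raise QuantError(f"no parent rule for segment {segment!r}")
    parent_kind = rules[segment]
    if parent_kind not in parent_estimates:
        raise QuantError(f"parent estimate {parent_kind!r} not supplied")
    parent = _amount(parent_estimates[parent_kind])
    if parent <= 0:
        raise QuantError(f"parent amount for {segment} must be > 0")
    ratio = _amount(splice_estimate) / parent
    flags = {FLAG_RATIO_GT_1} if ratio > 1 else set()
    return QuantEstimate(
        target_label=f"{segment}/{parent_kind}", amount=ratio, flags=flags
    )


# ---------------------------------------------------------------------------
# absolute quantification (PSAQ)
# ---------------------------------------------------------------------------

def psaq_absolute(chain: StandardChain, areas: pd.DataFrame,
                  target_label: str = "target") -> QuantEstimate:
    """Two-step protein-standard absolute quantification.

    Step 1: the heavy fusion-standard amount is the known light anchor
    spike times the mean heavy/light ratio over anchor (GFP) peptides.
    Step 2: the endogenous amount is the heavy standard amount times the
    mean light/heavy ratio over target peptides, divided by the sample
    protein mass — yielding fmol/µg.  Ratios are averaged per step
    (configurable provenance is recorded on the estimate).  Replicates
    (distinct run_ids) are quantified independently and combined as
    mean ± sample SD.
    """
    runs = sorted(areas["run_id"].unique())
    if not runs:
        raise QuantError("no runs in peak-area table")
    per_run_peptide: list[float] = []
    n_rep = 0
    for run in runs:
        sub = areas[areas["run_id"] == run]
        gfp_ratios = []
        for pep in chain.gfp_peptides:
            rows = sub[sub["peptide"] == pep]
            if rows.empty:
                raise QuantError(f"run {run}: anchor peptide {pep} missing")
            gfp_ratios.append(1.0 / peptide_ratio(rows, pep))  # heavy/light
        heavy_fusion_fmol = chain.gfp_light_amount * float(np.mean(gfp_ratios))
        got_target = False
        for pep in chain.target_peptides:
            rows = sub[sub["peptide"] == pep]
            if rows.empty:
                raise QuantError(f"run {run}: target peptide {pep} missing")
            lh = peptide_ratio(rows, pep)  # light/heavy
            per_run_peptide.append(
                heavy_fusion_fmol * lh / chain.sample_protein_mass
            )
            got_target = True
        if got_target:
            n_rep += 1
    arr = np.asarray(per_run_peptide, dtype=float)
    return QuantEstimate(
        target_label=target_label,
        amount=float(arr.mean()),
        dispersion=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        n_peptides=len(chain.target_peptides),
        n_replicates=n_rep,
    )


def beta_by_subtraction(pan_estimate: QuantEstimate,
                        alpha_estimate: QuantEstimate) -> QuantEstimate:
    """Short-variant (beta) amount as pan − alpha for one gene.

    Dispersion is propagated in quadrature (independence assumption).
    Negative results are reported as-is with ``negative_subtraction``
    set — clamping would bias low-abundance estimates.
    """
    gene_pan = pan_estimate.target_label.split("-")[0]
    gene_alpha = alpha_estimate.target_label.split("-")[0]
    if gene_pan != gene_alpha:
        raise QuantError(
            f"gene mismatch: {pan_estimate.target_label} vs {alpha_estimate.target_label}"
        )
    amount = pan_estimate.amount - alpha_estimate.amount
    flags = {FLAG_NEGATIVE} if amount < 0 else set()
    return QuantEstimate(
        target_label=f"{gene_pan}-beta(by-subtraction)",
        amount=amount,
        dispersion=math.hypot(pan_estimate.dispersion, alpha_estimate.dispersion),
        n_peptides=pan_estimate.n_peptides + alpha_estimate.n_peptides,
        n_replicates=min(pan_estimate.n_replicates, alpha_estimate.n_replicates),
        flags=flags,
    )


def copies_per_synapse(target_fmol_per_ug: float, anchor_fmol_per_ug: float,
                       anchor_copies: float) -> float:
    """Scale a target amount to copies per synapse via an anchor protein
    of known copy number measured in the same units."""
    if anchor_fmol_per_ug <= 0 or anchor_copies <= 0:
        raise QuantError("anchor amount and copy number must be positive")
    return target_fmol_per_ug * anchor_copies / anchor_fmol_per_ug


def titration_check(standard_to_endogenous_ratio: float,
                    low: float = 0.5, high: float = 2.0) -> bool:
    """True iff the standard/endogenous signal ratio lies in the closed
    interval [low, high] where isotope-dilution ratios are reliable."""
    if standard_to_endogenous_ratio <= 0:
        raise QuantError("ratio must be > 0")
    return low <= standard_to_endogenous_ratio <= high


def apply_titration_flag(estimate: QuantEstimate, ratio: float) -> QuantEstimate:
    if not titration_check(ratio):
        estimate.flags.add(FLAG_TITRATION)
    return estimate


# ---------------------------------------------------------------------------
# panel-level driver
# ---------------------------------------------------------------------------

def quantify_panel_relative(areas: pd.DataFrame, panel,
                            heavy_spike_fmol: float | Mapping[str, float],
                            protein_mass_ug: float) -> dict:
    """Relative quantification of every panel species.

    For each species: per peptide and run, light/heavy ratio × spike
    gives endogenous fmol; dividing by the digested protein mass puts
    all species on a common fmol/µg scale.  ``heavy_spike_fmol`` is a
    single spike amount or a mapping species label -> spike (titrated
    standards).  Returns label -> :class:`QuantEstimate`.
    """
    out: dict[str, QuantEstimate] = {}
    runs = sorted(areas["run_id"].unique())
    for label, peps in panel.entries:
        if not peps:
            continue
        spike = (
            heavy_spike_fmol[label]
            if isinstance(heavy_spike_fmol, Mapping)
            else heavy_spike_fmol
        )
        per_pep: dict[str, list[float]] = {}
        for pep in peps:
            seq = pep.sequence
            vals = []
            for run in runs:
                rows = areas[(areas["run_id"] == run) & (areas["peptide"] == seq)]
                if rows.empty:
                    continue
                fmol = relative_amount(peptide_ratio(rows, seq), spike)
                vals.append(fmol / protein_mass_ug)
            if vals:
                per_pep[seq] = vals
        if per_pep:
            out[label] = aggregate_species(label, per_pep)
    return out


def quantify_panel_absolute(areas: pd.DataFrame,
                            chains: Mapping[str, StandardChain]) -> dict:
    """PSAQ quantification for every species with a standard chain.

    Returns label -> :class:`QuantEstimate` in fmol/µg.
    """
    return {
        label: psaq_absolute(chain, areas, target_label=label)
        for label, chain in chains.items()
    }
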