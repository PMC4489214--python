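"""Peptide/fragment monoisotopic masses, heavy-label shifts, transitions.

Mass conventions are standard triple-quadrupole practice: monoisotopic
residue masses (from pyteomics), water 18.010565 Da, proton 1.007276 Da,
fixed carbamidomethylation on every cysteine (+57.021464 Da).  Heavy
peptides carry 13C/15N-labeled lysine (+8.014199 Da) and arginine
(+10.008269 Da) at every K/R.

Transition selection follows the targeted-assay rule for tryptic
peptides: monitor singly charged y-ions whose m/z exceeds the precursor
m/z; fall back to b-ions (flagged) only when fewer than two y-ions
qualify.  Because tryptic y-ions contain the C-terminal K/R, light and
heavy species always yield the same fragment index set.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from pyteomics import mass as _ptmass

WATER = 18.010565
PROTON = 1.007276
CARBAMIDOMETHYL = 57.021464
K_HEAVY_SHIFT = 8.014199   # 13C6,15N2-Lys
R_HEAVY_SHIFT = 10.008269  # 13C6,15N4-Arg

LIGHT = "light"
HEAVY = "heavy"

_RESIDUE_MASS = dict(_ptmass.std_aa_mass)

DEFAULT_HEAVY_SHIFTS = {"K": K_HEAVY_SHIFT, "R": R_HEAVY_SHIFT}

#: vendor-style linear collision-energy parameters per precursor charge
DEFAULT_CE_PARAMS = {2: (0.034, 3.314), 3: (0.044, 3.314)}


class MassError(ValueError):
    pass


@dataclass(frozen=True)
class PeptideSpecies:
    """A peptide in a defined modification/label state.

    Carbamidomethylation of C is always applied (fixed modification);
    ``label`` switches the heavy K/R shifts on.
    """

    sequence: str
    label: str = LIGHT
    heavy_shift_per_residue: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HEAVY_SHIFTS)
    )

    def __post_init__(self) -> None:
        if not self.sequence:
            raise MassError("empty peptide sequence")
        if self.label not in (LIGHT, HEAVY):
            raise MassError(f"label must be 'light' or 'heavy', got {self.label!r}")
        bad = [r for r in self.sequence if r not in _RESIDUE_MASS]
        if bad:
            raise MassError(f"unknown residue(s) {sorted(set(bad))} in {self.sequence}")

    def residue_masses(self) -> list[float]:
        """Per-residue masses including fixed mods and label shifts."""
        out = []
        for r in self.sequence:
            m = _RESIDUE_MASS[r]
            if r == "C":
                m += CARBAMIDOMETHYL
            if self.label == HEAVY:
                m += self.heavy_shift_per_residue.get(r, 0.0)
            out.append(m)
        return out


@dataclass(frozen=True)
class AssayTransition:
    """One monitored precursor/product pair."""

    peptide: PeptideSpecies
    precursor_charge: int
    product_series: str  # 'y' or 'b'
    product_index: int
    product_charge: int
    precursor_mz: float
    product_mz: float
    collision_energy: float
    fallback: bool = False

    @property
    def fragment_name(self) -> str:
        return f"{self.product_series}{self.product_index}"


def monoisotopic_mass(peptide: PeptideSpecies | str) -> float:
    """Neutral monoisotopic peptide mass in Da (residues + water + mods)."""
    if isinstance(peptide, str):
        peptide = PeptideSpecies(peptide)
    return sum(peptide.residue_masses()) + WATER


def heavy_shift(peptide_sequence: str,
                shifts: Mapping[str, float] | None = None) -> float:
    """Total heavy-label mass shift: 8.014199·nK + 10.008269·nR."""
    shifts = shifts or DEFAULT_HEAVY_SHIFTS
    return sum(shifts.get(r, 0.0) for r in peptide_sequence)


def ion_mz(peptide: PeptideSpecies | str, kind: str,
           index: int | None = None, charge: int = 1) -> float:
    """m/z of the precursor or a y_i / b_i fragment.

    precursor: (M + z·p)/z; y_i: (sum of last i residues + water + z·p)/z;
    b_i: (sum of first i residues + z·p)/z — with heavy shifts included
    for labeled residues inside the fragment.
    """
    if isinstance(peptide, str):
        peptide = PeptideSpecies(peptide)
    if charge < 1:
        raise MassError("charge must be >= 1")
    if kind == "precursor":
        return (monoisotopic_mass(peptide) + charge * PROTON) / charge
    if kind not in ("y", "b"):
        raise MassError(f"unknown ion kind {kind!r}")
    n = len(peptide.sequence)
    if index is None or not (1 <= index < n):
        raise MassError(f"fragment index must be in [1, {n - 1}], got {index}")
    masses = peptide.residue_masses()
    if kind == "y":
        frag = sum(masses[n - index:]) + WATER
    else:
        frag = sum(masses[:index])
    return (frag + charge * PROTON) / charge


def collision_energy(precursor_mz: float, precursor_charge: int,
                     params: Mapping[int, tuple] | None = None) -> float:
    """Linear CE = slope(z)·m/z + intercept(z) in volts.

    The empirically optimal per-peptide CE is instrument-specific; the
    linear vendor-style defaults are explicit and configurable.
    """
    params = params or DEFAULT_CE_PARAMS
    if precursor_charge not in params:
        raise MassError(f"no CE parameters for charge {precursor_charge}")
    slope, intercept = params[precursor_charge]
    return slope * precursor_mz + intercept


def select_transitions(peptide: PeptideSpecies | str, precursor_charge: int = 2,
                       max_transitions: int = 4,
                       ce_params: Mapping[int, tuple] | None = None) -> list[AssayTransition]:
    """Transitions for one peptide under the y-ion selection rule.

    All singly charged y-ions with m/z above the precursor m/z, ordered
    by increasing index, truncated to the ``max_transitions``
    highest-index ions.  If fewer than two y-ions qualify, b-ions above
    the precursor m/z are appended (flagged ``fallback``).
    """
    if isinstance(peptide, str):
        peptide = PeptideSpecies(peptide)
    if precursor_charge not in (2, 3):
        raise MassError("precursor_charge must be 2 or 3")
    if max_transitions < 1:
        raise MassError("max_transitions must be >= 1")
    n = len(peptide.sequence)
    if n < 2:
        raise MassError(f"peptide {peptide.sequence!r} too short to fragment")
    pre_mz = ion_mz(peptide, "precursor", charge=precursor_charge)
    ce = collision_energy(pre_mz, precursor_charge, ce_params)

    def make(series: str, idx: int, fallback: bool) -> AssayTransition:
        return AssayTransition(
            peptide=peptide,
            precursor_charge=precursor_charge,
            product_series=series,
            product_index=idx,
            product_charge=1,
            precursor_mz=pre_mz,
            product_mz=ion_mz(peptide, series, idx, 1),
            collision_energy=ce,
            fallback=fallback,
        )

    y_ok = [i for i in range(1, n) if ion_mz(peptide, "y", i, 1) > pre_mz]
    kept = sorted(y_ok[-max_transitions:]) if y_ok else []
    transitions = [make("y", i, False) for i in kept]
    if len(y_ok) < 2:
        b_ok = [i for i in range(1, n) if ion_mz(peptide, "b", i, 1) > pre_mz]
        for i in sorted(b_ok, reverse=True):
            if len(transitions) >= 2:
                break
            transitions.append(make("b", i, True))
        transitions.sort(key=lambda t: (t.product_series, t.product_index))
    if not transitions:
        raise MassError(
            f"peptide {peptide.sequence!r} yields no usable fragment ions"
        )
    return transitions


def export_transition_list(panel, path=None, precursor_charge: int = 2,
                           max_transitions: int = 4,
                           ce_params: Mapping[int, tuple] | None = None,
                           sep: str = "\t") -> str:
    """Render a panel as a transition list (TSV by default).

    One row per peptide x label x transition; light rows precede heavy;
    m/z printed to 5 decimals, CE to 2.  Row order (group, peptide,
    label, fragment index) is stable so re-exports are byte-identical.
    Every exported y-ion product m/z is checked to exceed its precursor
    m/z before writing.
    """
    header = sep.join(
        [
            "group_label", "peptide", "label", "precursor_mz",
            "precursor_charge", "fragment", "product_mz", "product_charge",
            "collision_energy",
        ]
    )
    lines = [header]
    for label_g, peps in panel.entries:
        for pep in sorted(peps, key=lambda p: p.sequence):
            for lab in (LIGHT, HEAVY):
                species = PeptideSpecies(pep.sequence, label=lab)
                for tr in select_transitions(
                    species, precursor_charge, max_transitions, ce_params
                ):
                    if tr.product_series == "y" and not tr.product_mz > tr.precursor_mz:
                        raise MassError(
                            f"y-ion below precursor m/z for {pep.sequence} ({lab})"
                        )
                    lines.append(
                        sep.join(
                            [
                                label_g,
                                pep.sequence,
                                lab,
                                f"{tr.precursor_mz:.5f}",
                                str(tr.precursor_charge),
                                tr.fragment_name,
                                f"{tr.product_mz:.5f}",
                                str(tr.product_charge),
                                f"{tr.collision_energy:.2f}",
                            ]
                        )
                    )
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
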