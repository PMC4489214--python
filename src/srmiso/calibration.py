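"""Standard curves and LoB/LoD/LoQ by the blank / low-concentration method.

For each peptide a standard curve (ordinary least squares of peak area on
spiked concentration) is fitted over a dilution series.  Detection limits
follow the classical blank and low-concentration-sample method:

    LoB = mean(blank) + 1.645 · SD(blank)
    LoD = LoB + 1.645 · SD(low-concentration sample)

with one-sided 95% multipliers and sample (n−1) standard deviations.
LoQ is operationalized as the lowest calibration level whose replicate
CV is at or below a threshold (default 20%) and whose mean area reaches
the LoD; if no level qualifies, LoQ is reported as not determined
(``None``), never silently extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

Z_ONE_SIDED_95 = 1.645


class CalibrationError(ValueError):
    pass


@dataclass
class CalibrationCurve:
    """Dilution-series data and fitted linear response for one peptide."""

    peptide: str
    points: list  # (concentration fmol/µl, area, replicate id)
    blank_areas: list
    low_conc_areas: list
    slope: float = field(default=float("nan"))
    intercept: float = field(default=float("nan"))
    r_squared: float = field(default=float("nan"))

    def fit(self) -> "CalibrationCurve":
        conc = [p[0] for p in self.points]
        area = [p[1] for p in self.points]
        self.slope, self.intercept, self.r_squared = fit_standard_curve(
            list(zip(conc, area))
        )
        return self

    def back_calculate(self, area: float) -> float:
        """Concentration corresponding to an area, via the fitted line."""
        if not np.isfinite(self.slope) or self.slope == 0:
            raise CalibrationError(f"{self.peptide}: curve not fitted or flat")
        return (area - self.intercept) / self.slope


@dataclass
class LimitEstimates:
    """LoB/LoD/LoQ in area units and back-calculated concentration.

    ``loq_concentration`` is ``None`` when no calibration level meets
    the precision criterion.
    """

    peptide: str
    lob_area: float
    lod_area: float
    lob_concentration: float
    lod_concentration: float
    loq_concentration: float | None


def fit_standard_curve(points: Sequence) -> tuple[float, float, float]:
    """OLS of area on concentration: (slope, intercept, r_squared)."""
    conc = np.asarray([p[0] for p in points], dtype=float)
    area = np.asarray([p[1] for p in points], dtype=float)
    if len(np.unique(conc)) < 2:
        raise CalibrationError("need >= 2 distinct concentrations to fit")
    res = stats.linregress(conc, area)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def _sample_sd(values) -> float:
    arr = np.asarray(values, dtype=float)
    return float(arr.std(ddof=1)) if arr.size > 1 else 0.0


def lob_lod_loq(curve: CalibrationCurve, cv_threshold: float = 0.20) -> LimitEstimates:
    """Blank and low-concentration-sample limits for one fitted curve."""
    if len(curve.blank_areas) < 2:
        raise CalibrationError(f"{curve.peptide}: need >= 2 blank areas")
    if len(curve.low_conc_areas) < 2:
        raise CalibrationError(f"{curve.peptide}: need >= 2 low-concentration areas")
    if not np.isfinite(curve.slope):
        curve.fit()
    blanks = np.asarray(curve.blank_areas, dtype=float)
    lob = float(blanks.mean()) + Z_ONE_SIDED_95 * _sample_sd(blanks)
    lod = lob + Z_ONE_SIDED_95 * _sample_sd(curve.low_conc_areas)

    # LoQ: lowest level with replicate CV <= threshold and mean area >= LoD
    df = pd.DataFrame(curve.points, columns=["concentration", "area", "replicate"])
    loq = None
    for conc, grp in sorted(df.groupby("concentration"), key=lambda kv: kv[0]):
        areas = grp["area"].to_numpy(dtype=float)
        mean = areas.mean()
        if mean <= 0:
            continue
        cv = _sample_sd(areas) / mean if len(areas) > 1 else 0.0
        if cv <= cv_threshold and mean >= lod:
            loq = float(conc)
            break
    return LimitEstimates(
        peptide=curve.peptide,
        lob_area=lob,
        lod_area=lod,
        lob_concentration=curve.back_calculate(lob),
        lod_concentration=curve.back_calculate(lod),
        loq_concentration=loq,
    )


def read_calibration_table(path, sep: str = "\t") -> list[CalibrationCurve]:
    """Read a calibration TSV (peptide, concentration, area, replicate).

    Rows with concentration 0 are treated as blanks; the lowest nonzero
    concentration supplies the low-concentration replicate set.
    """
    df = pd.read_csv(path, sep=sep, comment="#")
    required = ["peptide", "concentration", "area", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CalibrationError(f"{path}: missing column(s) {missing}")
    curves = []
    for pep, grp in df.groupby("peptide", sort=True):
        blanks = grp[grp["concentration"] == 0]["area"].tolist()
        nonzero = grp[grp["concentration"] > 0]
        if nonzero.empty:
            raise CalibrationError(f"{pep}: no nonzero calibration points")
        low = nonzero["concentration"].min()
        low_areas = nonzero[nonzero["concentration"] == low]["area"].tolist()
        points = list(
            nonzero[["concentration", "area", "replicate"]].itertuples(index=False, name=None)
        )
        curves.append(
            CalibrationCurve(
                peptide=str(pep),
                points=points,
                blank_areas=blanks,
                low_conc_areas=low_areas,
            ).fit()
        )
    return curves
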