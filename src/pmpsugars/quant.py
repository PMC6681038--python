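"""Calibration, sensitivity limits and validation statistics.

Quantification follows standard external-calibration practice: peak area is
linear in derivative concentration (unweighted ordinary least squares),
detection and quantification limits are the concentrations giving
signal-to-noise 3 and 10 through the calibration slope (hence
LOQ = (10/3) LOD), and measured concentrations convert to polysaccharide
content (nmol per mg) through the sample-preparation constants: a known
sample mass is hydrolyzed, taken up in a dissolution volume, an aliquot of
which is derivatized to a final volume.  With the default constants
(20 mg sample, 5 mL dissolution, 0.1 mL aliquot, 1 mL final) the factor is

    content [nmol/mg] = concentration [umol/L] x (1 x 5 / 0.1) / 20
                      = 2.5 x concentration.

Method validation uses spike recovery, recovery% = (found - original) /
spiked x 100, and relative standard deviation with the sample (n-1)
standard deviation.  Reported percentages and limits are rounded half-up to
two decimals.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats as _st

from .chem import round_half_up

__all__ = [
    "CalibrationCurve",
    "SensitivityLimits",
    "ConversionConstants",
    "QuantRecord",
    "RecoveryRecord",
    "SampleSummary",
    "DEFAULT_CONSTANTS",
    "fit_calibration",
    "lod_loq",
    "back_calculate",
    "to_content",
    "from_content",
    "recovery",
    "rsd",
    "summarize_samples",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """area = slope * concentration + intercept over a validated linear range."""

    analyte: str
    slope: float           # area units per umol/L
    intercept: float       # area units
    r_squared: float
    linear_range: tuple[float, float]  # umol/L

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"{self.analyte}: slope must be positive")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError(f"{self.analyte}: r_squared must lie in [0, 1]")
        lo, hi = self.linear_range
        if not lo < hi:
            raise ValueError(f"{self.analyte}: linear range must satisfy low < high")

    def area(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept


@dataclass(frozen=True)
class SensitivityLimits:
    lod: float  # umol/L, S/N = 3
    loq: float  # umol/L, S/N = 10

    def __post_init__(self) -> None:
        if not 0 < self.lod < self.loq:
            raise ValueError("require 0 < LOD < LOQ")


@dataclass(frozen=True)
class ConversionConstants:
    """Sample-preparation volumes/mass linking solution concentration to content."""

    final_volume_ml: float = 1.0
    dissolution_volume_ml: float = 5.0
    aliquot_volume_ml: float = 0.1
    sample_mass_mg: float = 20.0

    def __post_init__(self) -> None:
        for name in ("final_volume_ml", "dissolution_volume_ml",
                     "aliquot_volume_ml", "sample_mass_mg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def factor(self) -> float:
        """nmol/mg per umol/L (= per nmol/mL)."""
        return (self.final_volume_ml * self.dissolution_volume_ml
                / self.aliquot_volume_ml / self.sample_mass_mg)


DEFAULT_CONSTANTS = ConversionConstants()


@dataclass
class QuantRecord:
    analyte: str
    concentration: float              # umol/L
    content: float                    # nmol/mg
    in_linear_range: bool
    constants: ConversionConstants = field(default=DEFAULT_CONSTANTS)


@dataclass(frozen=True)
class RecoveryRecord:
    analyte: str
    original: float   # nmol/mg
    spiked: float     # nmol/mg
    found: float      # nmol/mg
    recovery_pct: float
    rsd_pct: float | None = None


def fit_calibration(points: list[tuple[float, float]], analyte: str = "",
                    linear_range: tuple[float, float] | None = None) -> CalibrationCurve:
    """Unweighted least-squares line through (concentration, area) points.

    r_squared is the squared Pearson correlation between areas and fitted
    areas, which for a simple OLS line equals the squared correlation of
    areas with concentrations.
    """
    if len(points) < 3:
        raise ValueError("calibration requires at least 3 points")
    conc = [c for c, _ in points]
    area = [a for _, a in points]
    if len(set(conc)) < 2:
        raise ValueError("calibration concentrations have zero variance")
    res = _st.linregress(conc, area)
    if linear_range is None:
        linear_range = (min(conc), max(conc))
    return CalibrationCurve(analyte, res.slope, res.intercept,
                            res.rvalue ** 2, linear_range)


def lod_loq(noise_sd: float, curve: CalibrationCurve) -> SensitivityLimits:
    """Detection/quantification limits from baseline noise through the slope.

    S/N is signal height over the baseline-noise standard deviation, so the
    concentrations at S/N 3 and 10 are 3*sigma/slope and 10*sigma/slope.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    return SensitivityLimits(lod=3.0 * noise_sd / curve.slope,
                             loq=10.0 * noise_sd / curve.slope)


def back_calculate(area: float, curve: CalibrationCurve) -> tuple[float, bool]:
    """Invert the calibration line; flags whether the result is in range."""
    conc = (area - curve.intercept) / curve.slope
    lo, hi = curve.linear_range
    return conc, lo <= conc <= hi


def to_content(concentration: float,
               constants: ConversionConstants = DEFAULT_CONSTANTS) -> float:
    """Solution concentration (umol/L) -> polysaccharide content (nmol/mg)."""
    return concentration * constants.factor


def from_content(content: float,
                 constants: ConversionConstants = DEFAULT_CONSTANTS) -> float:
    """Inverse of :func:`to_content`."""
    return content / constants.factor


def recovery(found: float, original: float, spiked: float) -> float:
    """Spike recovery percentage, rounded half-up to 2 decimals.

    Invariant under a common rescaling of all three amounts.
    """
    if spiked <= 0:
        raise ValueError("spiked amount must be positive")
    return round_half_up((found - original) / spiked * 100.0, 2)


def rsd(values: list[float]) -> float:
    """Relative standard deviation (%) with the n-1 sample deviation."""
    if len(values) < 2:
        raise ValueError("RSD requires at least 2 replicates")
    mean = statistics.fmean(values)
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return round_half_up(statistics.stdev(values) / mean * 100.0, 2)


@dataclass
class SampleSummary:
    """Min/max and ranking summary of a samples x analytes content matrix."""

    global_min: float
    global_max: float
    min_location: tuple[str, str]          # (sample, analyte)
    max_location: tuple[str, str]
    analyte_ranges: dict[str, tuple[float, float]]
    rankings: dict[str, list[str]]         # sample -> analytes, descending content

    def top_analyte_in_every_sample(self) -> str | None:
        tops = {ranks[0] for ranks in self.rankings.values()}
        return tops.pop() if len(tops) == 1 else None


def summarize_samples(table: pd.DataFrame) -> SampleSummary:
    """Summarize a content matrix (rows = samples, columns = analytes)."""
    if table.empty:
        raise ValueError("content table is empty")
    stacked = table.stack()
    min_loc = stacked.idxmin()
    max_loc = stacked.idxmax()
    analyte_ranges = {
        a: (float(table[a].min()), float(table[a].max())) for a in table.columns
    }
    rankings = {
        str(sample): [str(a) for a in row.sort_values(ascending=False).index]
        for sample, row in table.iterrows()
    }
    return SampleSummary(
        global_min=float(stacked.min()),
        global_max=float(stacked.max()),
        min_location=(str(min_loc[0]), str(min_loc[1])),
        max_location=(str(max_loc[0]), str(max_loc[1])),
        analyte_ranges=analyte_ranges,
        rankings=rankings,
    )


def quantify_peak_table(peaks: pd.DataFrame, curves: dict[str, CalibrationCurve],
                        library, *, constants: ConversionConstants = DEFAULT_CONSTANTS,
                        rt_window: float = 1.0) -> pd.DataFrame:
    """Assign peaks to library species by retention time and quantify them.

    ``peaks`` needs columns ``rt`` and ``area``; ``library`` is a sequence of
    records with ``name`` and ``reference_rt`` attributes.  Each peak is
    assigned to the nearest reference retention time within ``rt_window``
    (unassignable peaks are reported with a null species), the area is
    back-calculated through that species' curve, and the concentration is
    converted to content.  Species without a curve yield null quantities.
    """
    if rt_window <= 0:
        raise ValueError("rt_window must be positive")
    rows = []
    for _, peak in peaks.iterrows():
        rt = float(peak["rt"])
        area = float(peak["area"])
        best = min(library, key=lambda rec: abs(rec.reference_rt - rt), default=None)
        species = None
        if best is not None and abs(best.reference_rt - rt) <= rt_window:
            species = best.name
        row = {"rt": rt, "area": area, "species": species,
               "concentration": None, "content": None, "in_linear_range": None}
        if species is not None and species in curves:
            conc, ok = back_calculate(area, curves[species])
            row.update(concentration=conc, content=to_content(conc, constants),
                       in_linear_range=ok)
        rows.append(row)
    return pd.DataFrame(rows, columns=["rt", "area", "species", "concentration",
                                       "content", "in_linear_range"])
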