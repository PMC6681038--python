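"""Synthetic LC-MS data with known ground truth.

Stands in for the instrument so every pipeline stage is testable end to
end: monosaccharide contents are converted to solution concentrations
(inverse of the content conversion), concentrations to peak areas through
the calibration lines, and areas to Gaussian chromatographic peaks centred
at the library retention times; one MS2 spectrum per species is drawn from
the fragment rules (expected high-abundance ions at relative intensity 1.0,
low at 0.1) with bounded m/z jitter and uniform decoy peaks over the
acquisition range m/z 100-700.

Noise model: multiplicative Gaussian noise on areas, additive Gaussian
baseline noise on the sampled trace, Gaussian RT jitter, and Gaussian m/z
jitter at MS1 (ppm) and MS2 (Da).  All jitters are clipped at ~3 sigma (RT)
or 2 sigma (m/z) so a noisy spectrum stays inside the matching tolerances
by construction rather than with high probability; defaults are set so that
replicate quantification reproduces relative standard deviations of the
order seen in practice (about 1%).  Every generator takes a mandatory seed:
the same seed reproduces the dataset byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import derivative_mz
from .fragments import ObservedSpectrum, SpeciesRecord, theoretical_spectrum
from .quant import CalibrationCurve, ConversionConstants, DEFAULT_CONSTANTS, from_content
from .doe import L9Design, build_l9

__all__ = [
    "SyntheticSampleConfig",
    "SyntheticChromatogram",
    "simulate_sample",
    "simulate_calibration",
    "simulate_l9",
]

_ABUNDANCE_INTENSITY = {"high": 1.0, "low": 0.1}
MZ_SCAN_RANGE = (100.0, 700.0)


@dataclass
class SyntheticSampleConfig:
    """Ground-truth contents plus all noise parameters for one sample."""

    contents: dict[str, float]                 # species -> nmol/mg
    constants: ConversionConstants = field(default=DEFAULT_CONSTANTS)
    peak_width_sd: float = 0.2                 # min
    area_rel_noise: float = 0.01
    baseline_noise_sd: float = 50.0            # area units per min
    ms1_jitter_ppm: float = 2.0                # sd
    ms2_jitter_da: float = 0.01                # sd, clipped at 2 sd
    rt_jitter_sd: float = 0.1                  # min, clipped at 3 sd
    n_decoy_peaks: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        for name in ("peak_width_sd", "area_rel_noise", "baseline_noise_sd",
                     "ms1_jitter_ppm", "ms2_jitter_da", "rt_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(v < 0 for v in self.contents.values()):
            raise ValueError("contents must be non-negative")


@dataclass
class SyntheticChromatogram:
    """Peak list plus a sampled trace with additive baseline noise."""

    peaks: pd.DataFrame        # columns: species, rt, height, area
    time: np.ndarray           # min
    intensity: np.ndarray      # area units per min

    def peak_table(self) -> pd.DataFrame:
        """The (rt, area, precursor_mz) table a peak picker would emit."""
        return self.peaks[["rt", "area", "precursor_mz"]].reset_index(drop=True)


def _clipped_normal(rng: np.random.Generator, sd: float, clip_sd: float,
                    size: int | None = None):
    if sd == 0:
        return 0.0 if size is None else np.zeros(size)
    x = rng.normal(0.0, sd, size)
    return np.clip(x, -clip_sd * sd, clip_sd * sd)


def simulate_sample(
    config: SyntheticSampleConfig,
    curves: dict[str, CalibrationCurve],
    library: list[SpeciesRecord],
) -> tuple[SyntheticChromatogram, list[ObservedSpectrum], dict[str, float]]:
    """Simulate one derivatized hydrolysate: chromatogram, MS2 spectra, truth.

    Every species with nonzero content must have both a calibration curve
    and a library record.  Returns the ground-truth contents alongside the
    data.
    """
    rng = np.random.default_rng(config.seed)
    records = {rec.name: rec for rec in library}
    active = {sp: c for sp, c in config.contents.items() if c > 0}
    for sp in active:
        if sp not in curves:
            raise ValueError(f"no calibration curve for {sp!r}")
        if sp not in records:
            raise ValueError(f"no library record for {sp!r}")

    rows = []
    spectra: list[ObservedSpectrum] = []
    for sp in sorted(active):
        rec = records[sp]
        conc = from_content(active[sp], config.constants)
        area = curves[sp].area(conc)
        area *= 1.0 + float(_clipped_normal(rng, config.area_rel_noise, 3.0))
        rt = rec.reference_rt + float(_clipped_normal(rng, config.rt_jitter_sd, 3.0))
        height = area / (config.peak_width_sd * math.sqrt(2.0 * math.pi))
        theo_prec = derivative_mz(rec.class_spec)
        prec = theo_prec * (1.0 + float(_clipped_normal(rng, config.ms1_jitter_ppm, 2.0)) * 1e-6)
        rows.append({"species": sp, "rt": rt, "height": height,
                     "area": area, "precursor_mz": prec})

        theo = theoretical_spectrum(rec.class_spec, species=sp)
        peaks = []
        for mz, _rule, abundance in theo.entries:
            jmz = mz + float(_clipped_normal(rng, config.ms2_jitter_da, 2.0))
            peaks.append((jmz, _ABUNDANCE_INTENSITY[abundance]))
        lo, hi = MZ_SCAN_RANGE
        for _ in range(config.n_decoy_peaks):
            peaks.append((float(rng.uniform(lo, hi)), float(rng.uniform(0.01, 0.1))))
        spectra.append(ObservedSpectrum(retention_time=rt, precursor_mz=prec,
                                        peaks=peaks))

    peaks_df = pd.DataFrame(
        rows, columns=["species", "rt", "height", "area", "precursor_mz"]
    )
    time = np.arange(0.0, 180.0, 0.05)
    intensity = np.zeros_like(time)
    for row in rows:
        intensity += row["height"] * np.exp(
            -0.5 * ((time - row["rt"]) / config.peak_width_sd) ** 2
        )
    if config.baseline_noise_sd > 0:
        intensity = intensity + rng.normal(0.0, config.baseline_noise_sd, time.shape)
    chrom = SyntheticChromatogram(peaks_df, time, intensity)
    return chrom, spectra, dict(active)


def simulate_calibration(curve: CalibrationCurve, levels: int,
                         relative_noise: float, seed: int) -> list[tuple[float, float]]:
    """Calibration points: log-spaced concentrations across the linear range,
    areas from the line with multiplicative Gaussian noise."""
    if levels < 3:
        raise ValueError("need at least 3 calibration levels")
    rng = np.random.default_rng(seed)
    lo, hi = curve.linear_range
    conc = np.geomspace(lo, hi, levels)
    eps = rng.normal(0.0, relative_noise, levels) if relative_noise > 0 else np.zeros(levels)
    return [(float(c), float(curve.area(c) * (1.0 + e))) for c, e in zip(conc, eps)]


def simulate_l9(effects: dict[str, tuple[float, float, float]],
                noise_sd: float, seed: int,
                grand_mean: float = 100.0,
                response_name: str = "yield") -> L9Design:
    """L9 response table with planted additive factor effects.

    response_i = grand_mean + sum_f effect[f][level_i(f)] + N(0, noise_sd).
    The empty column D carries no effect, only noise.
    """
    for f in effects:
        if f not in ("A", "B", "C"):
            raise ValueError("effects may be specified for factors A, B, C only")
    rng = np.random.default_rng(seed)
    design = build_l9()
    y = np.full(9, grand_mean, dtype=float)
    for f, levels in effects.items():
        col = {"A": 0, "B": 1, "C": 2}[f]
        y += np.asarray(levels, dtype=float)[design.array[:, col] - 1]
    if noise_sd > 0:
        y += rng.normal(0.0, noise_sd, 9)
    design.responses[response_name] = y
    return design
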