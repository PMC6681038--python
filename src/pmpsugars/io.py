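"""Readers and writers for the table and spectrum dialects the pipeline uses.

Tables are comma-separated UTF-8 text with a header row and "." decimals;
typographic minus/en-dash characters (common in published tables) are
normalized to ASCII on ingest.  MS2 spectra travel as MGF (BEGIN IONS /
PEPMASS / RTINSECONDS / peak pairs, via pyteomics) or as a two-column
delimited peak list.

The packaged reference fixtures hold the published method values: the
12-species reference-ion table (retention times, measured [M+H]+ with ppm
errors, MS2 fragment lists), the 10 calibration curves with linear ranges
and LOD/LOQ, the 10 spike-recovery rows, and the 12-sample content matrix.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .doe import L9Design
from .fragments import ObservedSpectrum, TheoreticalSpectrum
from .quant import CalibrationCurve, ConversionConstants, DEFAULT_CONSTANTS

__all__ = [
    "FRAGMENT_COLUMN_RULES",
    "PipelineConfig",
    "load_reference_ions",
    "reference_spectra",
    "load_calibration_table",
    "calibration_curves",
    "load_recovery_table",
    "load_sample_contents",
    "sample_content_matrix",
    "read_peak_table",
    "read_l9_table",
    "read_mgf",
    "write_mgf",
    "read_peaklist",
    "write_theoretical_spectrum",
    "write_manifest",
]

#: fixture fragment column -> rule ids that may populate it (plain, hexosamine)
FRAGMENT_COLUMN_RULES: dict[str, tuple[str, ...]] = {
    "mh_h2o": ("dehydration",),
    "c3c4_h2o": ("bispmp_c3c4", "bispmp_c3c4_amine"),
    "c2c3_h2o": ("bispmp_c2c3", "bispmp_c2c3_amine"),
    "mh_pmp": ("pmp_loss",),
    "mh_pmp_h2o": ("pmp_h2o_loss", "pmp_nh3_loss"),
    "mh_pmp_2h2o": ("pmp_2h2o_loss", "pmp_nh3_h2o_loss"),
    "mh_pmp_3h2o": ("pmp_3h2o_loss", "pmp_nh3_2h2o_loss"),
    "c5c6_2h2o": ("c5c6_cleavage",),
    "c4c5_2h2o": ("c4c5_cleavage",),
    "c2c3": ("c2c3_cleavage", "c2c3_cleavage_amine"),
    "c1c2": ("c1c2_cleavage",),
    "pmp_h": ("pmp_reporter",),
}

FRAGMENT_COLUMNS = tuple(FRAGMENT_COLUMN_RULES)

_DASH_CHARS = {0x2212: "-", 0x2013: "-", 0x2014: "-"}  # minus, en-dash, em-dash


def _read_csv_text(source) -> pd.DataFrame:
    """Read CSV with unicode-dash normalization and line-numbered errors."""
    path = Path(source)
    text = path.read_text(encoding="utf-8").translate(_DASH_CHARS)
    if not text.strip():
        raise ValueError(f"{path}: file is empty")
    try:
        return pd.read_csv(_io.StringIO(text))
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed table ({exc})") from exc


def _require_numeric(df: pd.DataFrame, columns, where: str,
                     allow_missing: bool = False) -> pd.DataFrame:
    for col in columns:
        if col not in df.columns:
            raise ValueError(f"{where}: missing column {col!r}")
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            # +2: header line plus 1-based counting
            line = int(bad.idxmax()) + 2
            raise ValueError(f"{where}: malformed value in column {col!r} at line {line}")
        if not allow_missing and coerced.isna().any():
            line = int(coerced.isna().idxmax()) + 2
            raise ValueError(f"{where}: missing value in column {col!r} at line {line}")
        df[col] = coerced
    return df


def _fixture(name: str) -> Path:
    return Path(str(resources.files("pmpsugars").joinpath("data", name)))


def load_reference_ions() -> pd.DataFrame:
    """The 12-species reference table; dash cells are NaN."""
    df = _read_csv_text(_fixture("reference_ions.csv"))
    df = _require_numeric(df, ("rt_min", "precursor_mz", "ppm_error"), "reference_ions")
    df = _require_numeric(df, FRAGMENT_COLUMNS, "reference_ions", allow_missing=True)
    if len(df) != 12:
        raise ValueError(f"reference_ions: expected 12 species, got {len(df)}")
    return df


def reference_spectra() -> list[tuple[str, ObservedSpectrum]]:
    """One observed spectrum per reference species, built from the printed
    retention time, measured precursor and all non-dash fragment m/z values
    at unit intensity."""
    out = []
    for _, row in load_reference_ions().iterrows():
        peaks = [(float(row[c]), 1.0) for c in FRAGMENT_COLUMNS if pd.notna(row[c])]
        out.append((row["species"],
                    ObservedSpectrum(retention_time=float(row["rt_min"]),
                                     precursor_mz=float(row["precursor_mz"]),
                                     peaks=peaks)))
    return out


def load_calibration_table() -> pd.DataFrame:
    df = _read_csv_text(_fixture("calibration_curves.csv"))
    df = _require_numeric(
        df, ("slope", "intercept", "r_squared", "range_low", "range_high", "lod", "loq"),
        "calibration_curves")
    if len(df) != 10:
        raise ValueError(f"calibration_curves: expected 10 analytes, got {len(df)}")
    return df


def calibration_curves() -> dict[str, CalibrationCurve]:
    return {
        row["analyte"]: CalibrationCurve(
            row["analyte"], float(row["slope"]), float(row["intercept"]),
            float(row["r_squared"]), (float(row["range_low"]), float(row["range_high"])),
        )
        for _, row in load_calibration_table().iterrows()
    }


def load_recovery_table() -> pd.DataFrame:
    df = _read_csv_text(_fixture("recovery.csv"))
    df = _require_numeric(
        df, ("original", "spiked", "found", "recovery_pct", "rsd_pct"), "recovery")
    if len(df) != 10:
        raise ValueError(f"recovery: expected 10 analytes, got {len(df)}")
    return df


def load_sample_contents() -> pd.DataFrame:
    """12 samples x 10 analytes, indexed by sample id, with an origin column."""
    df = _read_csv_text(_fixture("sample_contents.csv")).set_index("sample")
    value_cols = [c for c in df.columns if c != "origin"]
    df = _require_numeric(df.reset_index(), value_cols, "sample_contents").set_index("sample")
    if df.shape != (12, 11):
        raise ValueError(f"sample_contents: expected 12 x (origin + 10), got {df.shape}")
    return df


def sample_content_matrix() -> pd.DataFrame:
    """The numeric content matrix (nmol/mg) without the origin column."""
    return load_sample_contents().drop(columns="origin")


def read_peak_table(path) -> pd.DataFrame:
    """User peak table: columns rt (min), area, and optionally precursor_mz."""
    df = _read_csv_text(path)
    cols = ["rt", "area"] + (["precursor_mz"] if "precursor_mz" in df.columns else [])
    return _require_numeric(df, cols, str(path))


def read_l9_table(path) -> L9Design:
    """Design+response table: 9 rows of levels A,B,C,D plus response columns.

    Orthogonality is enforced by the design container.
    """
    df = _read_csv_text(path)
    for col in ("A", "B", "C", "D"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing design column {col!r}")
    df = _require_numeric(df, ("A", "B", "C", "D"), str(path))
    if len(df) != 9:
        raise ValueError(f"{path}: an L9 design needs exactly 9 rows, got {len(df)}")
    responses = {c: df[c].to_numpy(float)
                 for c in df.columns if c not in ("A", "B", "C", "D")}
    responses = {c: v for c, v in responses.items()}
    array = df[["A", "B", "C", "D"]].to_numpy(int)
    return L9Design(array, responses)


def read_mgf(path) -> list[ObservedSpectrum]:
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            rt = float(params.get("rtinseconds", 0.0)) / 60.0
            prec = float(params["pepmass"][0])
            peaks = list(zip(entry["m/z array"].tolist(),
                             entry["intensity array"].tolist()))
            spectra.append(ObservedSpectrum(rt, prec, peaks))
    return spectra


def write_mgf(spectra: list[ObservedSpectrum], path,
              titles: list[str] | None = None) -> None:
    entries = []
    for i, s in enumerate(spectra):
        mzs, intens = zip(*s.peaks) if s.peaks else ((), ())
        entries.append({
            "m/z array": np.asarray(mzs, float),
            "intensity array": np.asarray(intens, float),
            "params": {
                "title": titles[i] if titles else f"spectrum_{i}",
                "pepmass": (s.precursor_mz,),
                "rtinseconds": s.retention_time * 60.0,
            },
        })
    _mgf.write(entries, str(path), file_mode="w")


def read_peaklist(path, retention_time: float = 0.0,
                  precursor_mz: float | None = None) -> ObservedSpectrum:
    """Two-column delimited MS2 peak list (m/z, intensity); '#' comments allowed."""
    peaks = []
    for ln, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.translate(_DASH_CHARS).strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise ValueError(f"{path}: malformed peak at line {ln}")
        try:
            peaks.append((float(parts[0]), float(parts[1])))
        except ValueError:
            raise ValueError(f"{path}: malformed peak at line {ln}") from None
    if precursor_mz is None:
        raise ValueError("precursor_mz is required for a bare peak list")
    return ObservedSpectrum(retention_time, precursor_mz, peaks)


def write_theoretical_spectrum(spec: TheoreticalSpectrum, path) -> None:
    pd.DataFrame(
        [{"mz": mz, "rule_id": rid, "abundance": ab} for mz, rid, ab in spec.entries]
    ).to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """Tolerances, conversion constants and rounding used across the pipeline."""

    ms1_ppm: float = 10.0
    ms2_da: float = 0.05
    rt_window: float = 1.0
    report_decimals: int = 2
    seed: int | None = None
    constants: ConversionConstants = field(default=DEFAULT_CONSTANTS)

    def __post_init__(self) -> None:
        if min(self.ms1_ppm, self.ms2_da, self.rt_window) <= 0:
            raise ValueError("tolerances must be positive")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        const = raw.pop("constants", None)
        known = {"ms1_ppm", "ms2_da", "rt_window", "report_decimals", "seed"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if const is not None:
            kwargs["constants"] = ConversionConstants(**const)
        return cls(**kwargs)

    def to_json(self, path) -> None:
        data = asdict(self)
        Path(path).write_text(json.dumps(data, indent=2), encoding="utf-8")


def write_manifest(path, config, seed: int) -> None:
    """Record a synthetic dataset's generating config and seed."""
    data = {"seed": seed, "config": asdict(config)}
    Path(path).write_text(json.dumps(data, indent=2, default=str), encoding="utf-8")
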