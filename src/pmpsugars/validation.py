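"""Golden-value self-checks against the packaged reference fixtures.

Recomputes, from the package's own engines, every quantity the reference
tables print and compares: theoretical masses vs measured precursors (ppm),
fragment-rule coverage of the MS2 table (0.05 Da, including the absence
pattern), identification of spectra rebuilt from the table, spike-recovery
arithmetic, the LOQ = (10/3) LOD relation (to within one unit in the last
printed decimal, since the stored LODs are themselves rounded to 2 dp), and
the sample-content summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import io as pio
from .chem import SUGAR_CLASSES, derivative_mz, ppm_error, round_half_up
from .fragments import (
    SPECIES_LIBRARY,
    build_rule_set,
    identify,
    match_spectrum,
    sugar_class,
    theoretical_spectrum,
)
from .quant import recovery, summarize_samples

__all__ = ["Check", "golden_checks", "run_validation"]

NOMINAL_IONS = {"hexose": 511, "hexosamine": 510, "pentose": 481,
                "tetrose": 451, "methylpentose": 495, "hexuronic_acid": 525}


@dataclass
class Check:
    name: str
    passed: bool
    detail: str


def _check_nominal_masses() -> Check:
    got = {name: round(derivative_mz(spec)) for name, spec in SUGAR_CLASSES.items()}
    ok = got == NOMINAL_IONS and round_half_up(derivative_mz(sugar_class("hexose")), 4) == 511.2187
    return Check("nominal and exact quasimolecular ions", ok, f"{got}")


def _check_ppm_errors() -> Check:
    df = pio.load_reference_ions()
    worst = 0.0
    for _, row in df.iterrows():
        theo = derivative_mz(sugar_class(row["class"]))
        recomputed = ppm_error(float(row["precursor_mz"]), theo)
        worst = max(worst, abs(recomputed - float(row["ppm_error"])))
    return Check("precursor ppm errors within 0.1 ppm of printed", worst <= 0.1,
                 f"worst deviation {worst:.3f} ppm")


def _check_fragment_coverage() -> Check:
    df = pio.load_reference_ions()
    rules = {r.rule_id: r for r in build_rule_set()}
    bad: list[str] = []
    for _, row in df.iterrows():
        spec = sugar_class(row["class"])
        theo = theoretical_spectrum(spec, species=row["species"])
        theo_by_rule = {rid: mz for mz, rid, _ in theo.entries}
        for col, rule_ids in pio.FRAGMENT_COLUMN_RULES.items():
            applicable = [rid for rid in rule_ids
                          if rules[rid].applies_to(spec, row["species"])]
            cell = row[col]
            if pd.isna(cell):
                if applicable:
                    bad.append(f"{row['species']}/{col}: rule emitted for dash cell")
            else:
                if not applicable:
                    bad.append(f"{row['species']}/{col}: printed ion has no rule")
                elif min(abs(theo_by_rule[rid] - float(cell)) for rid in applicable) > 0.05:
                    bad.append(f"{row['species']}/{col}: deviation > 0.05 Da")
    return Check("MS2 fragment table coverage (0.05 Da, dashes included)",
                 not bad, "; ".join(bad) or "all 144 cells consistent")


def _check_identification() -> Check:
    correct = 0
    gluN_flag = False
    for species, obs in pio.reference_spectra():
        hits = identify(obs)
        if hits and hits[0].species.name == species:
            correct += 1
        if species == "glucosamine":
            m = match_spectrum(obs, sugar_class("hexosamine"), species="glucosamine")
            gluN_flag = m.hexosamine_diagnostics_present
    ok = correct == 12 and gluN_flag
    return Check("identification of reference spectra",
                 ok, f"{correct}/12 correct, glucosamine diagnostics={gluN_flag}")


def _check_recoveries() -> Check:
    df = pio.load_recovery_table()
    bad = [
        row["analyte"]
        for _, row in df.iterrows()
        if recovery(row["found"], row["original"], row["spiked"]) != row["recovery_pct"]
    ]
    return Check("spike recoveries reproduced exactly (2 dp)", not bad,
                 "; ".join(bad) or "all 10 reproduced")


def _check_loq_ratio() -> Check:
    df = pio.load_calibration_table()
    worst = 0.0
    for _, row in df.iterrows():
        worst = max(worst, abs(round_half_up(row["lod"] * 10.0 / 3.0, 2) - row["loq"]))
    # one unit in the last printed decimal: the stored LODs are rounded to 2 dp
    return Check("LOQ = (10/3) LOD within printed precision", worst <= 0.01 + 1e-9,
                 f"worst |(10/3)LOD - LOQ| = {worst:.2f}")


def _check_sample_summary() -> Check:
    matrix = pio.sample_content_matrix()
    summary = summarize_samples(matrix)
    values = [v for _, row in matrix.iterrows() for v in row]
    brute_min, brute_max = min(values), max(values)
    ok = (summary.global_min == brute_min and summary.global_max == brute_max
          and summary.top_analyte_in_every_sample() == "glucose")
    return Check("sample content summary (extremes + glucose predominance)", ok,
                 f"min {summary.global_min} at {summary.min_location}, "
                 f"max {summary.global_max} at {summary.max_location}")


def golden_checks() -> list[Check]:
    return [
        _check_nominal_masses(),
        _check_ppm_errors(),
        _check_fragment_coverage(),
        _check_identification(),
        _check_recoveries(),
        _check_loq_ratio(),
        _check_sample_summary(),
    ]


def run_validation() -> tuple[list[Check], bool]:
    checks = golden_checks()
    return checks, all(c.passed for c in checks)
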