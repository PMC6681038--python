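"""Fragment rule set, spectrum matching and species identification."""

import numpy as np
import pandas as pd
import pytest

from pmpsugars import io as pio
from pmpsugars.chem import derivative_mz, sugar_class
from pmpsugars.fragments import (
    SPECIES_LIBRARY,
    ObservedSpectrum,
    build_rule_set,
    identify,
    match_spectrum,
    theoretical_spectrum,
)

RULES = {r.rule_id: r for r in build_rule_set()}


def _observed_from_row(row):
    peaks = [(float(row[c]), 1.0) for c in pio.FRAGMENT_COLUMNS if pd.notna(row[c])]
    return ObservedSpectrum(float(row["rt_min"]), float(row["precursor_mz"]), peaks)


@pytest.mark.parametrize("row_idx", range(12))
def test_rule_set_reproduces_reference_fragment_table(reference_ions, row_idx):
    """Every printed ion within 0.05 Da of a rule ion; no rule fires on a dash."""
    row = reference_ions.iloc[row_idx]
    spec = sugar_class(row["class"])
    theo = {rid: mz for mz, rid, _ in
            theoretical_spectrum(spec, species=row["species"]).entries}
    for col, rule_ids in pio.FRAGMENT_COLUMN_RULES.items():
        applicable = [rid for rid in rule_ids
                      if RULES[rid].applies_to(spec, row["species"])]
        if pd.isna(row[col]):
            assert not applicable, f"{row['species']}/{col}: rule fires on a dash cell"
        else:
            assert applicable, f"{row['species']}/{col}: printed ion not covered"
            dev = min(abs(theo[rid] - float(row[col])) for rid in applicable)
            assert dev <= 0.05, f"{row['species']}/{col}: {dev:.4f} Da"


def test_rules_are_exclusively_loss_or_fixed():
    for r in RULES.values():
        assert (r.loss is None) != (r.fixed_fragment is None)


@pytest.mark.parametrize("class_name", sorted(
    {"hexose", "hexosamine", "pentose", "tetrose", "methylpentose", "hexuronic_acid"}))
def test_universal_reporter_ions(class_name):
    mzs = theoretical_spectrum(sugar_class(class_name)).mz_values()
    assert any(abs(m - 175.09) < 0.05 for m in mzs)
    assert any(abs(m - 187.09) < 0.05 for m in mzs)


def test_theoretical_spectrum_sorted_and_traceable():
    theo = theoretical_spectrum(sugar_class("hexose"), species="glucose")
    mzs = theo.mz_values()
    assert all(m > 0 for m in mzs) and mzs == sorted(mzs)
    rule_ids = [rid for _, rid, _ in theo.entries]
    assert len(set(rule_ids)) == len(rule_ids)


def test_hexuronic_acid_series():
    """Uronic acids dehydrate and reach -PMP-3H2O but skip the earlier losses."""
    theo = theoretical_spectrum(sugar_class("hexuronic_acid"))
    mzs = theo.mz_values()
    assert any(abs(m - 507.19) < 0.05 for m in mzs)
    assert any(abs(m - 297.09) < 0.05 for m in mzs)
    suppressed = {"pmp_loss", "pmp_h2o_loss", "pmp_2h2o_loss"}
    assert suppressed.isdisjoint(rid for _, rid, _ in theo.entries)


def test_tetrose_lacks_long_chain_cleavages():
    rule_ids = {rid for _, rid, _ in theoretical_spectrum(sugar_class("tetrose")).entries}
    assert "c5c6_cleavage" not in rule_ids
    assert "c4c5_cleavage" not in rule_ids


def test_pentose_precursor_and_backbone_ion():
    spec = sugar_class("pentose")
    assert derivative_mz(spec) == pytest.approx(481.208, abs=0.001)
    assert any(abs(m - 373.17) < 0.05 for m in theoretical_spectrum(spec).mz_values())


def test_hexosamine_diagnostic_ions_present():
    mzs = theoretical_spectrum(sugar_class("hexosamine")).mz_values()
    assert any(abs(m - 372.18) < 0.05 for m in mzs)
    assert any(abs(m - 402.19) < 0.05 for m in mzs)


def test_self_match_scores_one():
    spec = sugar_class("hexose")
    theo = theoretical_spectrum(spec, species="glucose")
    obs = ObservedSpectrum(115.3, derivative_mz(spec),
                           [(mz, 1.0) for mz in theo.mz_values()])
    assert match_spectrum(obs, spec, species="glucose").score == pytest.approx(1.0)


def test_reporter_only_spectrum_scores_low():
    spec = sugar_class("hexose")
    obs = ObservedSpectrum(115.3, derivative_mz(spec), [(175.0866, 1.0)])
    m = match_spectrum(obs, spec, species="glucose")
    assert m.matched_rule_ids == ["pmp_reporter"]
    # weight 2 of 18 total applicable weight for a hexose
    assert m.score == pytest.approx(2.0 / 18.0)
    assert m.score < 0.2


def test_score_monotone_under_peak_removal():
    spec = sugar_class("hexose")
    theo = theoretical_spectrum(spec, species="glucose")
    full = [(mz, 1.0) for mz in theo.mz_values()]
    base = match_spectrum(
        ObservedSpectrum(115.3, derivative_mz(spec), list(full)), spec, species="glucose"
    ).score
    for drop in range(len(full)):
        reduced = [p for i, p in enumerate(full) if i != drop]
        score = match_spectrum(
            ObservedSpectrum(115.3, derivative_mz(spec), reduced), spec, species="glucose"
        ).score
        assert score <= base


def test_empty_and_mismatched_precursor_give_no_match():
    spec = sugar_class("hexose")
    assert match_spectrum(
        ObservedSpectrum(10.0, derivative_mz(spec), []), spec).score == 0.0
    off = ObservedSpectrum(10.0, derivative_mz(spec) + 1.0, [(175.0866, 1.0)])
    assert match_spectrum(off, spec).score == 0.0


def test_glucosamine_diagnostics_flag(reference_ions):
    row = reference_ions[reference_ions["species"] == "glucosamine"].iloc[0]
    obs = _observed_from_row(row)
    m = match_spectrum(obs, sugar_class("hexosamine"), species="glucosamine")
    assert m.hexosamine_diagnostics_present
    # same ions but 372/402 below the intensity threshold -> no flag
    weak = [(mz, 0.05 if abs(mz - 372.19) < 0.5 or abs(mz - 402.17) < 0.5 else 1.0)
            for mz, _ in obs.peaks]
    m2 = match_spectrum(ObservedSpectrum(obs.retention_time, obs.precursor_mz, weak),
                        sugar_class("hexosamine"), species="glucosamine")
    assert not m2.hexosamine_diagnostics_present


def test_identify_all_reference_spectra():
    for species, obs in pio.reference_spectra():
        hits = identify(obs)
        assert hits and hits[0].species.name == species


def test_isobaric_hexoses_disambiguated_by_retention_time(reference_ions):
    row = reference_ions[reference_ions["species"] == "galactose"].iloc[0]
    obs = _observed_from_row(row)
    obs.retention_time = 130.1
    hits = identify(obs)
    assert hits[0].species.name == "galactose"
    names = {h.species.name for h in hits}
    assert "glucose" not in names and "mannose" not in names


def test_unknown_precursor_mass_yields_empty_result():
    obs = ObservedSpectrum(50.0, 999.0, [(175.0866, 1.0)])
    assert identify(obs) == []


def test_empty_library_rejected():
    obs = ObservedSpectrum(50.0, 511.2187, [(175.0866, 1.0)])
    with pytest.raises(ValueError):
        identify(obs, library=[])


def test_library_retention_times_strictly_increasing():
    rts = [rec.reference_rt for rec in SPECIES_LIBRARY]
    assert rts == sorted(rts) and len(set(rts)) == 12
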