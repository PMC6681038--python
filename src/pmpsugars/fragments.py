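"""Rule-based MS2 annotation and identification of PMP-labelled monosaccharides.

Collision-induced dissociation of bis-PMP sugar derivatives produces four
groups of fragments:

1. dehydration of the quasimolecular ion, [M+H-H2O]+ (low abundance);
2. loss of one PMP label followed by successive dehydration,
   [M+H-PMP-k.H2O]+ for k = 0..3 -- for hexosamines deamination takes the
   place of one dehydration ([M+H-PMP-NH3-k.H2O]+) (low abundance);
3. loss of one PMP label plus C-C cleavage of the sugar backbone, giving
   ions near m/z 271 (C5-C6), 241 (C4-C5), 217/216 (C2-C3; 216 for
   hexosamines) and the strong m/z 187 (C1-C2) (high abundance);
4. ions retaining both PMP labels: the reporter [PMP+H]+ at m/z 175, the
   C2-C3 cleavage/dehydration ion at m/z 373 (372 for hexosamines) and the
   weaker C3-C4 ion at m/z 403 (402 for hexosamines) (reporter and 373/372
   high; 403 low; the hexosamine 372/402 pair is a glucosamine diagnostic).

Which fragments appear depends on the sugar class -- a tetrose has no C5-C6
or C4-C5 bond to cleave, pentoses and methylpentoses lack the C5-C6 series,
and hexuronic acids suppress the early [M+H-PMP-k.H2O] series -- plus a few
species-level absences observed for rhamnose, xylose and fucose.

Cleavage-series ions are stored as fixed reference compositions (the same
backbone fragment regardless of precursor class); loss-series ions are
computed as neutral losses from the class [M+H]+.  Matching uses a Dalton
tolerance at MS2 (ion-trap accuracy) and a ppm tolerance at MS1 (TOF
accuracy), and identification combines precursor mass class, retention time
against a reference library, and the fragment score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chem import (
    AMMONIA,
    MASS_PROTON,
    PMP,
    SUGAR_CLASSES,
    WATER,
    ElementalComposition,
    SugarClassSpec,
    derivative_mz,
    monoisotopic_mass,
    ppm_error,
    sugar_class,
)

__all__ = [
    "FragmentRule",
    "TheoreticalSpectrum",
    "ObservedSpectrum",
    "SpeciesRecord",
    "MatchResult",
    "Assignment",
    "SPECIES_LIBRARY",
    "HEXOSAMINE_DIAGNOSTIC_RULES",
    "build_rule_set",
    "theoretical_spectrum",
    "match_spectrum",
    "identify",
]

ALL_CLASSES = frozenset(SUGAR_CLASSES)

# Default tolerances: TOF precursor accuracy comfortably covers the <5 ppm
# errors seen for these derivatives; ion-trap MS2 deviations reach tens of mDa.
DEFAULT_MS1_PPM = 10.0
DEFAULT_MS2_TOL = 0.05
DEFAULT_RT_WINDOW = 1.0
DEFAULT_DIAGNOSTIC_INTENSITY = 0.2

_WEIGHTS = {"high": 2.0, "low": 1.0}


@dataclass(frozen=True)
class FragmentRule:
    """A single MS2 fragment rule.

    Exactly one of ``loss`` (neutral loss from [M+H]+) or ``fixed_fragment``
    (elemental composition of a neutral backbone fragment whose protonated
    form is the ion) is set.  ``classes`` is the class-level applicability;
    ``excluded_species`` holds the few species within an applicable class
    for which the ion is nonetheless not observed.
    """

    rule_id: str
    group: int
    abundance: str  # "high" | "low"
    classes: frozenset[str]
    loss: ElementalComposition | None = None
    fixed_fragment: ElementalComposition | None = None
    excluded_species: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if (self.loss is None) == (self.fixed_fragment is None):
            raise ValueError(f"rule {self.rule_id}: exactly one of loss/fixed_fragment")
        if self.group not in (1, 2, 3, 4):
            raise ValueError(f"rule {self.rule_id}: group must be 1..4")
        if self.abundance not in _WEIGHTS:
            raise ValueError(f"rule {self.rule_id}: abundance must be high/low")

    def applies_to(self, spec: SugarClassSpec, species: str | None = None) -> bool:
        if spec.class_name not in self.classes:
            return False
        if species is not None and species in self.excluded_species:
            return False
        return True

    def ion_mz(self, spec: SugarClassSpec) -> float:
        if self.fixed_fragment is not None:
            return monoisotopic_mass(self.fixed_fragment) + MASS_PROTON
        return derivative_mz(spec) - monoisotopic_mass(self.loss)

    @property
    def weight(self) -> float:
        return _WEIGHTS[self.abundance]


def _ec(c: int = 0, h: int = 0, n: int = 0, o: int = 0) -> ElementalComposition:
    return ElementalComposition(c, h, n, o)


def build_rule_set() -> list[FragmentRule]:
    """The complete fragment rule set for the six sugar classes.

    Fixed backbone fragments are derived once from the hexose (or
    hexosamine) derivative minus the documented losses, e.g. the m/z 271
    C5-C6 ion is the protonated C15H14N2O3 fragment
    (hexose derivative - PMP - CH2O - 2 H2O).
    """
    non_amine = ALL_CLASSES - {"hexosamine"}
    loss_series = ALL_CLASSES - {"hexosamine", "hexuronic_acid"}
    rules = [
        # group 1 -- dehydration of [M+H]+
        FragmentRule("dehydration", 1, "low", ALL_CLASSES, loss=WATER,
                     excluded_species=frozenset({"rhamnose"})),
        # group 2 -- loss of one PMP, then dehydration / deamination
        FragmentRule("pmp_loss", 2, "low", ALL_CLASSES - {"hexuronic_acid"},
                     loss=PMP, excluded_species=frozenset({"xylose"})),
        FragmentRule("pmp_h2o_loss", 2, "low", loss_series, loss=PMP + WATER,
                     excluded_species=frozenset({"fucose"})),
        FragmentRule("pmp_2h2o_loss", 2, "low", loss_series, loss=PMP + 2 * WATER),
        FragmentRule("pmp_3h2o_loss", 2, "low",
                     frozenset({"hexose", "pentose", "methylpentose", "hexuronic_acid"}),
                     loss=PMP + 3 * WATER),
        FragmentRule("pmp_nh3_loss", 2, "low", frozenset({"hexosamine"}),
                     loss=PMP + AMMONIA),
        FragmentRule("pmp_nh3_h2o_loss", 2, "low", frozenset({"hexosamine"}),
                     loss=PMP + AMMONIA + WATER),
        FragmentRule("pmp_nh3_2h2o_loss", 2, "low", frozenset({"hexosamine"}),
                     loss=PMP + AMMONIA + 2 * WATER),
        # group 3 -- one PMP lost, C-C backbone cleavage (fixed fragments)
        FragmentRule("c5c6_cleavage", 3, "high",
                     frozenset({"hexose", "hexosamine", "hexuronic_acid"}),
                     fixed_fragment=_ec(15, 14, 2, 3)),           # m/z 271.11
        FragmentRule("c4c5_cleavage", 3, "high", ALL_CLASSES - {"tetrose"},
                     fixed_fragment=_ec(14, 12, 2, 2)),           # m/z 241.10
        FragmentRule("c2c3_cleavage", 3, "high", non_amine,
                     fixed_fragment=_ec(12, 12, 2, 2)),           # m/z 217.10
        FragmentRule("c2c3_cleavage_amine", 3, "high", frozenset({"hexosamine"}),
                     fixed_fragment=_ec(12, 13, 3, 1)),           # m/z 216.11
        FragmentRule("c1c2_cleavage", 3, "high", ALL_CLASSES,
                     fixed_fragment=_ec(11, 10, 2, 1)),           # m/z 187.09
        # group 4 -- both PMP labels retained
        FragmentRule("pmp_reporter", 4, "high", ALL_CLASSES,
                     fixed_fragment=PMP),                          # m/z 175.09
        FragmentRule("bispmp_c2c3", 4, "high", non_amine,
                     fixed_fragment=_ec(22, 20, 4, 2)),           # m/z 373.17
        FragmentRule("bispmp_c2c3_amine", 4, "high", frozenset({"hexosamine"}),
                     fixed_fragment=_ec(22, 21, 5, 1)),           # m/z 372.18
        FragmentRule("bispmp_c3c4", 4, "low",
                     frozenset({"hexose", "methylpentose"}),
                     fixed_fragment=_ec(23, 22, 4, 3),            # m/z 403.18
                     excluded_species=frozenset({"rhamnose"})),
        FragmentRule("bispmp_c3c4_amine", 4, "high", frozenset({"hexosamine"}),
                     fixed_fragment=_ec(23, 23, 5, 2)),           # m/z 402.19
    ]
    return rules


#: Both must match with high relative intensity to flag a hexosamine.
HEXOSAMINE_DIAGNOSTIC_RULES = frozenset({"bispmp_c2c3_amine", "bispmp_c3c4_amine"})

_RULES: list[FragmentRule] = build_rule_set()


@dataclass(frozen=True)
class SpeciesRecord:
    """A named monosaccharide with its mass class and reference retention time."""

    name: str
    class_name: str
    reference_rt: float  # minutes

    @property
    def class_spec(self) -> SugarClassSpec:
        return sugar_class(self.class_name)


#: The 12 reference species in elution order.
SPECIES_LIBRARY: list[SpeciesRecord] = [
    SpeciesRecord("mannose", "hexose", 33.830),
    SpeciesRecord("glucosamine", "hexosamine", 36.548),
    SpeciesRecord("lyxose", "pentose", 40.298),
    SpeciesRecord("rhamnose", "methylpentose", 47.701),
    SpeciesRecord("ribose", "pentose", 48.832),
    SpeciesRecord("erythrose", "tetrose", 64.678),
    SpeciesRecord("glucuronic acid", "hexuronic_acid", 94.865),
    SpeciesRecord("galacturonic acid", "hexuronic_acid", 107.503),
    SpeciesRecord("glucose", "hexose", 115.318),
    SpeciesRecord("galactose", "hexose", 130.080),
    SpeciesRecord("xylose", "pentose", 145.282),
    SpeciesRecord("fucose", "methylpentose", 166.837),
]


@dataclass(frozen=True)
class TheoreticalSpectrum:
    """Reference MS2 ions for a class (optionally species-refined)."""

    class_name: str
    species: str | None
    precursor_mz: float
    entries: tuple[tuple[float, str, str], ...]  # (m/z, rule_id, abundance), sorted

    def mz_values(self) -> list[float]:
        return [e[0] for e in self.entries]


def theoretical_spectrum(spec: SugarClassSpec, species: str | None = None,
                         rules: list[FragmentRule] | None = None) -> TheoreticalSpectrum:
    """Every applicable rule contributes exactly one ion."""
    rules = _RULES if rules is None else rules
    entries = sorted(
        (r.ion_mz(spec), r.rule_id, r.abundance)
        for r in rules if r.applies_to(spec, species)
    )
    return TheoreticalSpectrum(spec.class_name, species, derivative_mz(spec),
                               tuple(entries))


@dataclass
class ObservedSpectrum:
    """An acquired MS2 spectrum: RT, precursor m/z and a centroided peak list.

    Intensities are normalized so the base peak is 1; peaks are kept sorted
    by m/z.
    """

    retention_time: float
    precursor_mz: float
    peaks: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(mz <= 0 or inten < 0 for mz, inten in self.peaks):
            raise ValueError("peak m/z must be positive and intensities non-negative")
        peaks = sorted(self.peaks)
        top = max((i for _, i in peaks), default=0.0)
        if top > 0:
            peaks = [(mz, i / top) for mz, i in peaks]
        self.peaks = peaks


@dataclass
class MatchResult:
    """Outcome of matching one observed spectrum against one sugar class."""

    class_name: str
    species: str | None
    score: float
    matched_rule_ids: list[str]
    deviations: dict[str, float]  # rule_id -> observed - theoretical (Da)
    precursor_ppm: float | None
    hexosamine_diagnostics_present: bool

    @classmethod
    def no_match(cls, class_name: str, species: str | None = None,
                 precursor_ppm: float | None = None) -> "MatchResult":
        return cls(class_name, species, 0.0, [], {}, precursor_ppm, False)


def match_spectrum(obs: ObservedSpectrum, spec: SugarClassSpec, *,
                   species: str | None = None,
                   ms2_tol: float = DEFAULT_MS2_TOL,
                   ms1_ppm: float = DEFAULT_MS1_PPM,
                   diagnostic_intensity: float = DEFAULT_DIAGNOSTIC_INTENSITY,
                   rules: list[FragmentRule] | None = None) -> MatchResult:
    """Score an observed spectrum against a class's theoretical fragments.

    The precursor must agree with the class [M+H]+ within ``ms1_ppm``.  The
    score is the matched fraction of rule weights (weight 2 for expected
    high-abundance ions, 1 for low), so it is monotone in the matched set
    and reaches 1 only when every applicable ion is found.
    """
    if ms2_tol <= 0 or ms1_ppm <= 0:
        raise ValueError("tolerances must be positive")
    prec_ppm = ppm_error(obs.precursor_mz, derivative_mz(spec))
    if abs(prec_ppm) > ms1_ppm or not obs.peaks:
        return MatchResult.no_match(spec.class_name, species, prec_ppm)

    rules = _RULES if rules is None else rules
    applicable = [r for r in rules if r.applies_to(spec, species)]
    total = sum(r.weight for r in applicable)
    matched: list[str] = []
    deviations: dict[str, float] = {}
    matched_intensity: dict[str, float] = {}
    for r in applicable:
        target = r.ion_mz(spec)
        best = None
        for mz, inten in obs.peaks:
            d = abs(mz - target)
            if d <= ms2_tol and (best is None or d < abs(best[0] - target)):
                best = (mz, inten)
        if best is not None:
            matched.append(r.rule_id)
            deviations[r.rule_id] = best[0] - target
            matched_intensity[r.rule_id] = best[1]
    score = sum(_WEIGHTS[r.abundance] for r in applicable if r.rule_id in matched) / total
    diagnostics = all(
        matched_intensity.get(rid, 0.0) >= diagnostic_intensity
        for rid in HEXOSAMINE_DIAGNOSTIC_RULES
    ) and spec.class_name == "hexosamine"
    return MatchResult(spec.class_name, species, score, matched, deviations,
                       prec_ppm, diagnostics)


@dataclass(frozen=True)
class Assignment:
    species: SpeciesRecord
    score: float
    rt_deviation: float
    match: MatchResult


def identify(obs: ObservedSpectrum,
             library: list[SpeciesRecord] | None = None, *,
             rt_window: float = DEFAULT_RT_WINDOW,
             ms1_ppm: float = DEFAULT_MS1_PPM,
             ms2_tol: float = DEFAULT_MS2_TOL) -> list[Assignment]:
    """Rank candidate species for one spectrum.

    Candidates are filtered by precursor mass class (ppm) and retention time
    against the reference library; isobaric species (e.g. the three hexoses)
    are disambiguated by RT.  Ties break on higher fragment score, then
    smaller RT deviation, then name.  No candidate -> empty list.
    """
    library = SPECIES_LIBRARY if library is None else library
    if not library:
        raise ValueError("species library is empty")
    out: list[Assignment] = []
    for rec in library:
        if abs(ppm_error(obs.precursor_mz, derivative_mz(rec.class_spec))) > ms1_ppm:
            continue
        rt_dev = abs(obs.retention_time - rec.reference_rt)
        if rt_dev > rt_window:
            continue
        m = match_spectrum(obs, rec.class_spec, species=rec.name,
                           ms2_tol=ms2_tol, ms1_ppm=ms1_ppm)
        out.append(Assignment(rec, m.score, rt_dev, m))
    out.sort(key=lambda a: (-a.score, a.rt_deviation, a.species.name))
    return out
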