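# Methods

## Mass model

All masses are monoisotopic, computed from CODATA/IUPAC atomic masses
(H 1.00782503207, C 12 exactly, N 14.0030740048, O 15.9949146196 Da) with
the proton at 1.007276466879 Da. Using the proton mass rather than the
hydrogen-atom mass for [M+H]⁺ matters at the fourth decimal: the bis-PMP
hexose ion is 511.2187 with the proton, 511.2193 with an H atom. Elemental
compositions are integer vectors over (C, H, N, O); subtraction that would
go negative raises, which catches chemically impossible neutral losses at
construction time.

The derivative model is fixed at two PMP labels condensing with loss of one
water (bis-PMP). Mono-PMP derivatives, charge states above 1, adducts other
than protonation, and isotope envelopes are out of scope: the detected
species in this workflow are singly protonated bis-PMP derivatives, and the
annotation layer operates on centroided peak lists.

Display rounding is half-up (m/z to 4 decimals, ppm and percentages to 2);
all internal computation is full precision.

## Fragment rules

MS² fragments fall into four groups (see the package docstring of
`pmpsugars.fragments`). Two representations are used:

- **Loss rules** compute the ion as [M+H]⁺ of the class minus an explicit
  neutral-loss composition (H₂O; PMP + k·H₂O for k = 0..3; for hexosamines
  PMP + NH₃ + k·H₂O, deamination replacing one dehydration).
- **Fixed-fragment rules** store the elemental composition of the backbone
  fragment itself, derived once from the hexose (or hexosamine) derivative
  minus the documented losses — e.g. the *m/z* 271 C5–C6 ion is protonated
  C₁₅H₁₄N₂O₃ (hexose derivative − PMP − CH₂O − 2 H₂O). These ions are the
  same backbone fragment regardless of precursor class, which is why a
  single reference mass per ion suffices; at the ±0.05 Da matching
  tolerance, small composition ambiguities in the published nominal
  assignments are immaterial (worst observed deviation in the reference
  table is 45 mDa).

Applicability is class-level — tetroses lack the C5–C6 and C4–C5 series,
pentoses and methylpentoses lack C5–C6, hexuronic acids suppress
[M+H−PMP−k·H₂O] for k ≤ 2 — plus a per-species exclusion set for three
absences observed within otherwise applicable classes (rhamnose:
dehydration and the 403 ion; xylose: bare PMP loss; fucose: PMP + H₂O
loss). The packaged reference table is reproduced cell-for-cell, including
its absence pattern.

Expected abundance is two-level: cleavage/reporter ions high (weight 2),
loss-series and the non-amine 403 ion low (weight 1). The match score is
the matched fraction of applicable rule weight, so it is monotone under
adding matched peaks and equals 1 only for a complete match. The
glucosamine flag requires both the 372 and 402 ions matched at relative
intensity ≥ 0.2 ("high abundance" made operational; the threshold sits well
below the 1.0 used for high-abundance synthetic ions and well above the
≤ 0.1 decoy/low band).

## Identification

Candidates must satisfy the precursor tolerance (default 10 ppm — TOF
accuracy; the reference table's worst error is 4.76 ppm) and the retention
window (default ±1.0 min — under half the closest library gap,
rhamnose/ribose at 1.13 min). Ranking is by fragment score, then RT
deviation, then name; the ordering is total and deterministic. A spectrum
with no candidate yields an empty result rather than an error. The library
follows the reference-table elution order (lyxose < rhamnose < ribose).

## Quantification

Calibration is unweighted ordinary least squares of area on concentration
(no 1/x weighting — the shipped curves are plain linear fits with r²), via
`scipy.stats.linregress`. LOD and LOQ derive from baseline noise through
the slope (3σ/slope and 10σ/slope), making LOQ/LOD exactly 10/3. RSD uses
the n−1 sample standard deviation (replicate counts of 3–6). The
content conversion factor is configuration with defaults
(1 mL final × 5 mL dissolution / 0.1 mL aliquot) / 20 mg = 2.5
(nmol/mg per µmol/L).

Two internal inconsistencies exist in the shipped reference tables and are
deliberately left as printed. First, the glucosamine LOD/LOQ pair
(0.83, 2.76): (10/3) × 0.83 rounds to 2.77, so the pair is consistent with
the S/N derivation only through an unrounded LOD near 0.828; the `validate`
self-check therefore allows one unit in the last printed decimal. Second,
the 12-sample content matrix contains 15.67 (S9 galacturonic acid) and
3474.96 (S12 glucose), so summary extremes computed from the full matrix
are wider than the 20.88–3329.49 range sometimes quoted alongside it;
`summarize_samples` reports the true matrix extremes.

## Orthogonal design

The canonical L9(3⁴) array is used; row order is immaterial to every
statistic (only the level balance and pairwise orthogonality, which the
container enforces). The unassigned fourth column supplies the ANOVA error
term — the classical choice when runs are not replicated. Sums of squares
are SS_j = 3 Σᵢ (k_ij − ȳ)² with 2 df per column and decompose the total
exactly; F = MS_j/MS_error on (2, 2) df with significance at α = 0.05. With
only 2 error df the test has low power, which the planted-effect
simulations make explicit: a factor must move the response by many noise
standard deviations before it is reliably declared significant. A zero
error mean square (noise-free synthetic responses) flags the table as
degenerate and reports F = ∞, p = 0 for non-null factors instead of
dividing by zero. Optimum selection maximizes the per-factor level means
(hydrolysis yield); ties take the lowest level and are flagged.

## Synthetic data

The generator emulates the measurement chain in reverse: content →
concentration (inverse conversion) → area (calibration line) → Gaussian
peak (constant width, default σ = 0.2 min) at the library RT, sampled on a
0.05-min grid over the 0–180 min run with additive baseline noise; one MS²
spectrum per species from the rule set (high rules at relative intensity
1.0, low at 0.1) with m/z jitter and five uniform decoy peaks over the
acquisition range *m/z* 100–700. Calibration sets use log-spaced levels
because the shipped linear ranges span up to 18-fold. L9 responses are
grand mean + additive level effects + Gaussian noise.

Defaults: 1% multiplicative area noise (chosen to reproduce validation
RSDs of order 1%), RT jitter σ = 0.1 min clipped at 3σ, MS1 jitter σ = 2 ppm
and MS2 jitter σ = 0.01 Da each clipped at 2σ. Clipping keeps every jittered
quantity strictly inside the matching tolerances, so noise-free and default-
noise identification round trips are exact by construction, not merely with
high probability. Every generator requires a seed; one seed gives
byte-identical output.

What the generator does not emulate — and therefore what passing round-trip
tests do not demonstrate about real data: peak asymmetry/tailing and
width variation along the gradient, co-elution and shared fragment ions
between real isomers, intensity structure beyond the two-level abundance
labels, detector saturation, profile-mode signals and isotope envelopes.
The round trips validate the arithmetic and the decision logic, not
chromatographic robustness.

## Problem sizes

The test suite and the reproduction script run the planted-effect ANOVA
power study at 500 replicates, the quantification-bias study at 100 seeds ×
10 analytes, and calibration Monte-Carlo checks at 200 replicates; each
completes in seconds on one CPU, and the sizes give binomial/mean
uncertainties comfortably below the asserted margins.
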