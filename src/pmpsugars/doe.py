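"""Taguchi L9(3^4) orthogonal-array analysis for hydrolysis optimization.

Polysaccharide hydrolysis is optimized over three 3-level factors --
A: hydrolysis time (3/6/9 h), B: hydrolysis temperature (100/110/120 degC),
C: TFA concentration (2/3/4 mol/L) -- using the 9-run L9(3^4) array.  The
fourth column is left unassigned and serves as the error term for ANOVA
(classical Taguchi practice when runs are not replicated).

Range (extreme-difference) analysis computes, per factor j, the level sums
K_ij, level means k_ij and the range R_j = max_i k_ij - min_i k_ij; factors
are ranked by R.  ANOVA uses SS_j = 3 * sum_i (k_ij - grand mean)^2 with
2 degrees of freedom per column; F_j = MS_j / MS_error against the empty
column with (2, 2) df.  The optimum condition takes, per factor, the level
with the largest mean response (hydrolysis yield is maximized).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _st

__all__ = [
    "L9_ARRAY",
    "FACTORS",
    "L9Design",
    "RangeAnalysis",
    "AnovaTable",
    "build_l9",
    "range_analysis",
    "anova_l9",
    "select_optimum",
]

# Canonical L9(3^4) array, levels 1..3.
L9_ARRAY = np.array(
    [
        [1, 1, 1, 1],
        [1, 2, 2, 2],
        [1, 3, 3, 3],
        [2, 1, 2, 3],
        [2, 2, 3, 1],
        [2, 3, 1, 2],
        [3, 1, 3, 2],
        [3, 2, 1, 3],
        [3, 3, 2, 1],
    ],
    dtype=int,
)

#: factor label -> (description, unit, physical level values)
FACTORS: dict[str, tuple[str, str, tuple[float, ...]]] = {
    "A": ("hydrolysis time", "h", (3.0, 6.0, 9.0)),
    "B": ("hydrolysis temperature", "degC", (100.0, 110.0, 120.0)),
    "C": ("TFA concentration", "mol/L", (2.0, 3.0, 4.0)),
    "D": ("empty (error term)", "", ()),
}

ASSIGNED_FACTORS = ("A", "B", "C")
COLUMN_INDEX = {"A": 0, "B": 1, "C": 2, "D": 3}


@dataclass
class L9Design:
    """The L9(3^4) array with one or more named response vectors (length 9)."""

    array: np.ndarray
    responses: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array, dtype=int)
        if self.array.shape != (9, 4):
            raise ValueError("L9 array must be 9 x 4")
        for col in range(4):
            counts = np.bincount(self.array[:, col], minlength=4)[1:]
            if not np.all(counts == 3):
                raise ValueError(f"column {col}: each level must appear exactly 3 times")
        for i in range(4):
            for j in range(i + 1, 4):
                pairs = {(a, b) for a, b in self.array[:, [i, j]]}
                if len(pairs) != 9:
                    raise ValueError(f"columns {i},{j} are not orthogonal")
        self.responses = {k: np.asarray(v, dtype=float) for k, v in self.responses.items()}
        for name, v in self.responses.items():
            if v.shape != (9,):
                raise ValueError(f"response {name!r} must have 9 values")

    def physical_value(self, factor: str, level: int) -> float:
        return FACTORS[factor][2][level - 1]


def build_l9(responses: dict[str, np.ndarray] | None = None) -> L9Design:
    """The standard L9(3^4) design, optionally with responses attached."""
    return L9Design(L9_ARRAY.copy(), dict(responses or {}))


@dataclass
class RangeAnalysis:
    """K/k/R statistics per column and the factor ranking by R."""

    response: str
    level_sums: dict[str, np.ndarray]     # K_ij, 3 per column
    level_means: dict[str, np.ndarray]    # k_ij
    ranges: dict[str, float]              # R_j
    ranking: list[str]                    # assigned factors, R descending


def _resolve_response(design: L9Design, response: str | np.ndarray) -> tuple[str, np.ndarray]:
    if isinstance(response, str):
        if response not in design.responses:
            raise ValueError(f"design has no response {response!r}")
        return response, design.responses[response]
    y = np.asarray(response, dtype=float)
    if y.shape != (9,):
        raise ValueError("response must have 9 values")
    return "response", y


def range_analysis(design: L9Design, response: str | np.ndarray) -> RangeAnalysis:
    """Level sums/means and ranges per column; ranking over assigned factors.

    Ties in R break alphabetically by factor label.
    """
    name, y = _resolve_response(design, response)
    sums: dict[str, np.ndarray] = {}
    means: dict[str, np.ndarray] = {}
    ranges: dict[str, float] = {}
    for label, col in COLUMN_INDEX.items():
        K = np.array([y[design.array[:, col] == lev].sum() for lev in (1, 2, 3)])
        sums[label] = K
        means[label] = K / 3.0
        ranges[label] = float(means[label].max() - means[label].min())
    ranking = sorted(ASSIGNED_FACTORS, key=lambda f: (-ranges[f], f))
    return RangeAnalysis(name, sums, means, ranges, ranking)


@dataclass
class AnovaRow:
    factor: str
    sum_sq: float
    df: int
    mean_sq: float
    f_value: float | None
    p_value: float | None
    significant: bool | None  # at alpha = 0.05; None for the error row


@dataclass
class AnovaTable:
    response: str
    rows: dict[str, AnovaRow]   # A, B, C and "error"
    total_ss: float
    degenerate: bool            # True when the error SS is (numerically) zero

    def significant_factors(self) -> list[str]:
        return [f for f in ASSIGNED_FACTORS if self.rows[f].significant]


def anova_l9(design: L9Design, response: str | np.ndarray,
             alpha: float = 0.05) -> AnovaTable:
    """Per-factor ANOVA with the empty column as error term.

    SS_j = 3 sum_i (k_ij - grand)^2 with 2 df; F = MS_j / MS_error on
    (2, 2) df.  The column sums of squares decompose the total exactly.
    A zero error SS (noise-free synthetic data) gives infinite F, p = 0,
    and the table is flagged degenerate.
    """
    name, y = _resolve_response(design, response)
    ra = range_analysis(design, y)
    grand = float(y.mean())
    ss = {lab: float(3.0 * np.sum((ra.level_means[lab] - grand) ** 2))
          for lab in COLUMN_INDEX}
    total_ss = float(np.sum((y - grand) ** 2))
    err_ss = ss["D"]
    err_ms = err_ss / 2.0
    degenerate = err_ms <= max(1e-12 * max(total_ss, 1.0), 0.0)
    rows: dict[str, AnovaRow] = {}
    for lab in ASSIGNED_FACTORS:
        ms = ss[lab] / 2.0
        if degenerate:
            f = float("inf") if ms > 0 else None
            p = 0.0 if ms > 0 else None
        else:
            f = ms / err_ms
            p = float(_st.f.sf(f, 2, 2))
        rows[lab] = AnovaRow(lab, ss[lab], 2, ms, f, p,
                             None if p is None else p < alpha)
    rows["error"] = AnovaRow("error", err_ss, 2, err_ms, None, None, None)
    return AnovaTable(name, rows, total_ss, degenerate)


@dataclass
class OptimumCondition:
    """Best level per factor: (level index, physical value); tied flags per factor."""

    response: str
    levels: dict[str, int]
    values: dict[str, float]
    tied: dict[str, bool]

    def describe(self) -> str:
        parts = [
            f"{FACTORS[f][0]} = {self.values[f]:g} {FACTORS[f][1]}".rstrip()
            for f in ASSIGNED_FACTORS
        ]
        return ", ".join(parts)


def select_optimum(analysis: RangeAnalysis, direction: str = "maximize") -> OptimumCondition:
    """Pick, per assigned factor, the level with the best mean response.

    Ties take the lowest level index and are flagged.
    """
    if direction not in ("maximize", "minimize"):
        raise ValueError("direction must be 'maximize' or 'minimize'")
    sign = 1.0 if direction == "maximize" else -1.0
    levels: dict[str, int] = {}
    values: dict[str, float] = {}
    tied: dict[str, bool] = {}
    for f in ASSIGNED_FACTORS:
        k = sign * analysis.level_means[f]
        best = int(np.argmax(k)) + 1          # argmax -> first (lowest) index on ties
        levels[f] = best
        values[f] = FACTORS[f][2][best - 1]
        tied[f] = bool(np.sum(k == k.max()) > 1)
    return OptimumCondition(analysis.response, levels, values, tied)
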