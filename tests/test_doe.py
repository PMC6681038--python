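"""L9 orthogonal array, range analysis, ANOVA and optimum selection."""

import numpy as np
import pytest

from pmpsugars.doe import (
    FACTORS,
    L9Design,
    anova_l9,
    build_l9,
    range_analysis,
    select_optimum,
)
from pmpsugars.synthetic import simulate_l9


def brute_force_level_means(array, y):
    """Independent oracle: plain-python per-level group means and ranges."""
    out = {}
    for label, col in zip("ABCD", range(4)):
        means = []
        for lev in (1, 2, 3):
            vals = [y[i] for i in range(9) if array[i][col] == lev]
            means.append(sum(vals) / len(vals))
        out[label] = (means, max(means) - min(means))
    return out


def test_l9_level_balance_and_orthogonality():
    design = build_l9()
    for col in range(4):
        levels = list(design.array[:, col])
        assert all(levels.count(lev) == 3 for lev in (1, 2, 3))
    for i in range(4):
        for j in range(i + 1, 4):
            pairs = {(a, b) for a, b in design.array[:, [i, j]]}
            assert len(pairs) == 9


def test_factor_levels_map_to_physical_settings():
    design = build_l9()
    assert design.physical_value("C", 3) == 4.0     # mol/L TFA
    assert design.physical_value("A", 2) == 6.0     # hours
    assert design.physical_value("B", 1) == 100.0   # degC
    assert FACTORS["D"][2] == ()


def test_malformed_array_rejected():
    bad = build_l9().array.copy()
    bad[0, 0] = 2  # breaks level balance
    with pytest.raises(ValueError):
        L9Design(bad, {})
    with pytest.raises(ValueError):
        L9Design(build_l9().array[:8], {})


def test_constant_response_gives_zero_ranges_and_ss():
    design = build_l9({"y": np.full(9, 7.0)})
    ra = range_analysis(design, "y")
    assert all(r == pytest.approx(0.0) for r in ra.ranges.values())
    table = anova_l9(design, "y")
    assert table.total_ss == pytest.approx(0.0)
    assert table.degenerate


def test_range_analysis_matches_brute_force_oracle():
    rng = np.random.default_rng(123)
    design = build_l9()
    for _ in range(20):
        y = rng.normal(50.0, 10.0, 9)
        ra = range_analysis(design, y)
        oracle = brute_force_level_means(design.array.tolist(), y.tolist())
        for label in "ABCD":
            assert np.allclose(ra.level_means[label], oracle[label][0])
            assert ra.ranges[label] == pytest.approx(oracle[label][1])
        oracle_ranking = sorted("ABC", key=lambda f: (-oracle[f][1], f))
        assert ra.ranking == oracle_ranking


def test_planted_effect_ranking():
    # effect spreads C:10 > A:5 > B:1, no noise
    design = simulate_l9({"A": (0, 0, 5), "B": (0, 0, 1), "C": (0, 0, 10)},
                         noise_sd=0.0, seed=0)
    assert range_analysis(design, "yield").ranking == ["C", "A", "B"]


def test_dominant_factor_with_noise_ranks_first():
    design = simulate_l9({"C": (10.0, 20.0, 30.0)}, noise_sd=0.1, seed=5)
    assert range_analysis(design, "yield").ranking[0] == "C"


def test_anova_sum_of_squares_decomposition():
    rng = np.random.default_rng(7)
    design = build_l9()
    y = rng.normal(100.0, 5.0, 9)
    table = anova_l9(design, y)
    parts = sum(table.rows[f].sum_sq for f in ("A", "B", "C", "error"))
    assert parts == pytest.approx(table.total_ss, rel=1e-12)


def test_anova_detects_planted_effect():
    design = simulate_l9({"B": (0.0, 10.0, 20.0)}, noise_sd=1.0, seed=0)
    table = anova_l9(design, "yield")
    assert table.rows["B"].significant
    assert table.rows["B"].f_value > table.rows["A"].f_value
    assert table.rows["B"].f_value > table.rows["C"].f_value


def test_anova_degenerate_noise_free_effect():
    design = simulate_l9({"B": (0.0, 10.0, 20.0)}, noise_sd=0.0, seed=0)
    table = anova_l9(design, "yield")
    assert table.degenerate
    assert table.rows["B"].f_value == float("inf")
    assert table.rows["B"].p_value == 0.0


def test_anova_and_range_order_agree_on_planted_effects():
    design = simulate_l9({"A": (0, 0, 5), "B": (0, 0, 1), "C": (0, 0, 10)},
                         noise_sd=1e-3, seed=11)
    ra = range_analysis(design, "yield")
    table = anova_l9(design, "yield")
    f_order = sorted("ABC", key=lambda f: -table.rows[f].f_value)
    assert f_order == ra.ranking


def test_optimum_simple_level_response():
    design = simulate_l9({"A": (1.0, 2.0, 3.0)}, noise_sd=0.0, seed=0)
    opt = select_optimum(range_analysis(design, "yield"))
    assert opt.levels["A"] == 3
    assert opt.values["A"] == 9.0  # hours


def test_optimum_matches_planted_neutral_sugar_conditions():
    # response peaks at 6 h, 120 degC, 4 mol/L TFA
    design = simulate_l9(
        {"A": (0.0, 5.0, 2.0), "B": (0.0, 1.0, 3.0), "C": (0.0, 2.0, 6.0)},
        noise_sd=0.0, seed=0)
    opt = select_optimum(range_analysis(design, "yield"))
    assert (opt.values["A"], opt.values["B"], opt.values["C"]) == (6.0, 120.0, 4.0)
    assert not any(opt.tied.values())


def test_optimum_tie_takes_lowest_level_and_flags():
    design = build_l9({"y": np.full(9, 1.0)})
    opt = select_optimum(range_analysis(design, "y"))
    assert all(lv == 1 for lv in opt.levels.values())
    assert all(opt.tied.values())


def test_minimize_direction():
    design = simulate_l9({"A": (1.0, 2.0, 3.0)}, noise_sd=0.0, seed=0)
    opt = select_optimum(range_analysis(design, "yield"), direction="minimize")
    assert opt.levels["A"] == 1
    with pytest.raises(ValueError):
        select_optimum(range_analysis(design, "yield"), direction="sideways")
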