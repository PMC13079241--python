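import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mapsetrend.errors import ConfigurationError, ContractError, UndefinedRateError, UndefinedStatisticError
from mapsetrend.synthdata import generate_paired_changes
from mapsetrend.trending import (
    AnalysisConfig,
    ConcordanceResult,
    PairedChange,
    apply_exclusion_zone,
    build_pairs,
    concordance_by_wall,
    concordance_rate,
    four_quadrant_plot,
    global_mapse,
    paired_delta_comparison,
    round_half_up,
)
from mapsetrend.vocab import TIMEPOINTS, WALLS


def make_pairs(deltas, wall="anterior"):
    return [PairedChange(f"P{i}", wall, a, r) for i, (a, r) in enumerate(deltas)]


def cohort_frame(rows):
    return pd.DataFrame(rows, columns=["patient_id", "timepoint", "wall", "method", "mapse_mm", "n_cycles"])


def full_patient(pid, auto, manual):
    """Rows for one patient: auto per wall and manual per wall, both timepoints."""
    rows = []
    for tp in TIMEPOINTS:
        for w in WALLS:
            if (tp, w) in auto or w in {k[1] for k in auto if k[0] == tp}:
                pass
            rows.append((pid, tp, w, "auto", auto[(tp, w)], 3))
            rows.append((pid, tp, w, "manual", manual[(tp, w)], 3))
    return rows


class TestGlobalMapse:
    def test_four_walls_mean(self):
        assert global_mapse([8, 10, 12, 10]) == 10.0

    def test_three_walls_mean(self):
        assert global_mapse([9, 12, 12]) == 11.0

    def test_single_wall_infeasible(self):
        assert global_mapse([9], AnalysisConfig(min_walls_global=2)) is None

    def test_nan_values_dropped(self):
        assert global_mapse([9.0, float("nan"), 12.0]) == pytest.approx(10.5)


class TestBuildPairs:
    def test_worked_single_patient_pair(self):
        auto = {}
        manual = {}
        for tp in TIMEPOINTS:
            for w in WALLS:
                auto[(tp, w)] = 8.7 if tp == "pre_cpb" else 6.7
                manual[(tp, w)] = 11.1 if tp == "pre_cpb" else 7.6
        df = cohort_frame(full_patient("P1", auto, manual))
        pairs = build_pairs(df)
        assert len(pairs) == 4
        anterior = next(p for p in pairs if p.wall == "anterior")
        assert anterior.delta_auto_mm == pytest.approx(-2.0)
        assert anterior.delta_ref_mm == pytest.approx(-3.5)

    def test_infeasible_wall_omitted(self):
        auto = {(tp, w): 8.0 for tp in TIMEPOINTS for w in WALLS}
        manual = {(tp, w): 10.0 for tp in TIMEPOINTS for w in WALLS}
        rows = full_patient("P1", auto, manual)
        rows = [r for r in rows if not (r[1] == "icu" and r[2] == "septal" and r[3] == "auto")]
        pairs = build_pairs(cohort_frame(rows))
        assert {p.wall for p in pairs} == set(WALLS) - {"septal"}

    def test_complete_case_count(self):
        rows = []
        for i in range(49):
            auto = {(tp, w): 8.0 - (tp == "icu") for tp in TIMEPOINTS for w in WALLS}
            manual = {(tp, w): 10.0 - (tp == "icu") for tp in TIMEPOINTS for w in WALLS}
            rows += full_patient(f"P{i:03d}", auto, manual)
        assert len(build_pairs(cohort_frame(rows))) == 49 * 4

    def test_delta_ref_identical_across_walls(self):
        auto = {(tp, w): 8.0 + hash((tp, w)) % 3 for tp in TIMEPOINTS for w in WALLS}
        manual = {(tp, w): 10.0 + hash((w, tp)) % 2 - 2 * (tp == "icu") for tp in TIMEPOINTS for w in WALLS}
        pairs = build_pairs(cohort_frame(full_patient("P1", auto, manual)))
        refs = {p.delta_ref_mm for p in pairs}
        assert len(refs) == 1

    def test_empty_table_warns(self, caplog):
        df = cohort_frame([("P1", "pre_cpb", "anterior", "auto", 8.0, 3)])
        import logging
        with caplog.at_level(logging.WARNING):
            assert build_pairs(df) == []
        assert "no complete" in caplog.text

    def test_strict_mode_restricts_walls(self):
        auto = {(tp, w): 8.0 - (tp == "icu") * 2 for tp in TIMEPOINTS for w in WALLS}
        manual = {(tp, w): 10.0 for tp in TIMEPOINTS for w in WALLS}
        rows = full_patient("P1", auto, manual)
        # manual septal only at pre-CPB, with an outlying value
        rows = [r for r in rows if not (r[1] == "icu" and r[2] == "septal" and r[3] == "manual")]
        rows = [(p, tp, w, m, 30.0 if (w == "septal" and m == "manual") else v, n)
                for (p, tp, w, m, v, n) in rows]
        loose = build_pairs(cohort_frame(rows), AnalysisConfig(strict_global_walls=False))
        strict = build_pairs(cohort_frame(rows), AnalysisConfig(strict_global_walls=True))
        # default mode sees the septal manual value at pre-CPB only -> different delta_ref
        assert loose[0].delta_ref_mm != pytest.approx(strict[0].delta_ref_mm)


class TestExclusionZone:
    def test_both_inside_excluded(self):
        (p,) = apply_exclusion_zone(make_pairs([(0.5, -0.5)]))
        assert p.excluded is True and p.concordant is None

    def test_same_direction_concordant(self):
        (p,) = apply_exclusion_zone(make_pairs([(-2.0, -3.5)]))
        assert p.excluded is False and p.concordant is True

    def test_square_box_one_coordinate_outside_retained(self):
        (p,) = apply_exclusion_zone(make_pairs([(1.0, 3.0)]))
        assert p.excluded is False and p.concordant is True

    def test_opposite_signs_discordant(self):
        (p,) = apply_exclusion_zone(make_pairs([(2.0, -2.5)]))
        assert p.excluded is False and p.concordant is False

    def test_either_geometry_excludes_more(self):
        pairs = make_pairs([(1.0, 3.0)])
        (p,) = apply_exclusion_zone(pairs, AnalysisConfig(exclusion_geometry="either"))
        assert p.excluded is True

    def test_zero_delta_discordant_against_nonzero(self):
        (p,) = apply_exclusion_zone(make_pairs([(0.0, 2.5)]), AnalysisConfig(lsc_mm=0.0))
        assert p.excluded is False and p.concordant is False

    def test_zero_zero_concordant_when_lsc_zero(self):
        (p,) = apply_exclusion_zone(make_pairs([(0.0, 0.0)]), AnalysisConfig(lsc_mm=0.0))
        assert p.concordant is True

    @given(st.lists(st.tuples(st.floats(-10, 10), st.floats(-10, 10)), min_size=1, max_size=60),
           st.floats(0.0, 5.0), st.floats(1.001, 4.0))
    @settings(max_examples=100, deadline=None)
    def test_partition_monotonicity_scale_invariance(self, deltas, lsc, scale):
        pairs = make_pairs(deltas)
        flagged = apply_exclusion_zone(pairs, AnalysisConfig(lsc_mm=lsc))
        n_excl = sum(p.excluded for p in flagged)
        n_ret = sum(not p.excluded for p in flagged)
        assert n_excl + n_ret == len(pairs)
        # monotonicity: larger box never retains more
        wider = apply_exclusion_zone(pairs, AnalysisConfig(lsc_mm=lsc * scale))
        assert sum(not p.excluded for p in wider) <= n_ret
        # scale invariance of the flags
        scaled = apply_exclusion_zone(
            make_pairs([(a * scale, r * scale) for a, r in deltas]),
            AnalysisConfig(lsc_mm=lsc * scale),
        )
        assert [p.excluded for p in scaled] == [p.excluded for p in flagged]
        assert [p.concordant for p in scaled] == [p.concordant for p in flagged]


class TestConcordanceRate:
    def test_reported_counts_91_percent(self):
        pairs = make_pairs([(2.0, 2.0)] * 126 + [(2.0, -2.0)] * 12)
        res = concordance_rate(apply_exclusion_zone(pairs))
        assert res.n_retained == 138 and res.n_concordant == 126
        assert res.rate_int_pct == 91
        assert res.adequate is True

    def test_all_concordant_100(self):
        res = concordance_rate(apply_exclusion_zone(make_pairs([(-2, -3)] * 7)))
        assert res.rate_pct == 100.0 and res.adequate

    def test_random_signs_near_fifty(self):
        rng = np.random.default_rng(0)
        deltas = [(2.0 * s1, 2.0 * s2) for s1, s2 in rng.choice([-1, 1], size=(10_000, 2))]
        res = concordance_rate(apply_exclusion_zone(make_pairs(deltas)))
        lo = 100 * stats.binom.ppf(0.005, 10_000, 0.5) / 10_000
        hi = 100 * stats.binom.ppf(0.995, 10_000, 0.5) / 10_000
        assert lo <= res.rate_pct <= hi

    def test_requires_exclusion_flags(self):
        with pytest.raises(ContractError):
            concordance_rate(make_pairs([(1, 1)]))

    def test_zero_retained_raises(self):
        with pytest.raises(UndefinedRateError):
            concordance_rate(apply_exclusion_zone(make_pairs([(0.1, 0.1)])))

    def test_result_invariant_enforced(self):
        with pytest.raises(ContractError):
            ConcordanceResult(5, 6, 3, 50.0, False)

    def test_per_wall_and_pooled_partition(self):
        rng = np.random.default_rng(3)
        pairs = []
        for i in range(200):
            wall = WALLS[i % 4]
            pairs.append(PairedChange(f"P{i}", wall, float(rng.normal(0, 3)), float(rng.normal(0, 3))))
        flagged = apply_exclusion_zone(pairs)
        pooled = concordance_rate(flagged)
        per_wall = concordance_by_wall(flagged)
        assert pooled.n_retained == sum(r.n_retained for r in per_wall.values() if r)
        assert pooled.n_concordant == sum(r.n_concordant for r in per_wall.values() if r)

    def test_oracle_equivalence_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(1, 40))
            deltas = [(float(rng.normal(0, 3)), float(rng.normal(0, 3))) for _ in range(n)]
            flagged = apply_exclusion_zone(make_pairs(deltas))
            # independent brute-force loop
            ret = conc = 0
            for a, r in deltas:
                if abs(a) < 1.8 and abs(r) < 1.8:
                    continue
                ret += 1
                conc += (a > 0) == (r > 0) and a != 0 and r != 0 or (a == 0 and r == 0)
            if ret == 0:
                with pytest.raises(UndefinedRateError):
                    concordance_rate(flagged)
                continue
            res = concordance_rate(flagged)
            assert res.n_retained == ret and res.n_concordant == conc
            assert res.rate_pct == pytest.approx(round(100 * conc / ret, 1))


class TestPairedDeltaComparison:
    def test_identical_vectors(self):
        pairs = make_pairs([(-2.0, -2.0), (-3.0, -3.0), (1.0, 1.0)])
        res = paired_delta_comparison(pairs)
        assert res.mean_difference_mm == 0.0 and res.t_statistic == 0.0 and res.p_value == 1.0

    def test_hand_computed_oracle(self):
        # pairs {(-1,-2),(-3,-2),(-2,-3),(0,-1)}: differences (1,-1,1,1)
        # oracle by direct formula: mean=0.5, sd=1.0, t = 0.5/(1.0/2) = 1.0, df=3
        pairs = make_pairs([(-1, -2), (-3, -2), (-2, -3), (0, -1)])
        res = paired_delta_comparison(pairs)
        assert res.n == 4
        assert res.mean_difference_mm == pytest.approx(0.5)
        assert res.sd_difference_mm == pytest.approx(1.0)
        assert res.t_statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(2 * stats.t.sf(1.0, 3))

    def test_zero_noise_cohort_difference(self, zero_noise_cohort):
        cfg, m, _r, _t = zero_noise_cohort
        pairs = [p for p in build_pairs(m) if p.wall == "anterior"]
        res = paired_delta_comparison(pairs, "anterior")
        assert res.mean_difference_mm == pytest.approx(-2.0 - (-3.5), abs=1e-9)

    def test_single_pair_raises(self):
        with pytest.raises(UndefinedStatisticError):
            paired_delta_comparison(make_pairs([(1, 2)]))


class TestFourQuadrantPlot:
    def test_pooled_and_per_wall_files(self, tmp_path):
        pairs = apply_exclusion_zone(
            [PairedChange(f"P{i}", WALLS[i % 4], float(np.sin(i) * 4), float(np.cos(i) * 4)) for i in range(40)]
        )
        pooled = four_quadrant_plot(pairs, path=str(tmp_path / "pooled.png"))
        walls = four_quadrant_plot(pairs, path=str(tmp_path / "walls.png"), per_wall=True)
        assert (tmp_path / "pooled.png").stat().st_size > 0
        assert (tmp_path / "walls.png").stat().st_size > 0

    def test_empty_retained_annotates_undefined(self, tmp_path):
        pairs = apply_exclusion_zone(make_pairs([(0.1, 0.2), (0.3, -0.1)]))
        four_quadrant_plot(pairs, path=str(tmp_path / "empty.png"))
        assert (tmp_path / "empty.png").stat().st_size > 0

    def test_deterministic_bytes(self, tmp_path):
        pairs = apply_exclusion_zone(make_pairs([(2.0, 3.0), (-2.5, -1.9), (2.2, -2.2)]))
        a = tmp_path / "a.png"
        b = tmp_path / "b.png"
        four_quadrant_plot(pairs, path=str(a))
        four_quadrant_plot(pairs, path=str(b))
        assert a.read_bytes() == b.read_bytes()

    def test_no_pairs_raises(self):
        with pytest.raises(ContractError):
            four_quadrant_plot([])


class TestStatisticalRecovery:
    @pytest.mark.parametrize("p_target", [0.7, 0.9])
    def test_concordance_probability_recovered(self, p_target):
        rates = []
        for seed in range(200):
            df = generate_paired_changes(196, p_target, seed=seed)
            pairs = [PairedChange(r.patient_id, r.wall, r.delta_auto_mm, r.delta_ref_mm)
                     for r in df.itertuples()]
            rates.append(concordance_rate(apply_exclusion_zone(pairs)).rate_pct / 100)
        mean = np.mean(rates)
        mc_se = np.std(rates, ddof=1) / np.sqrt(len(rates))
        assert abs(mean - p_target) <= 2 * mc_se


class TestConfigAndRounding:
    def test_round_half_up(self):
        assert round_half_up(90.5) == 91
        assert round_half_up(91.304) == 91
        assert round_half_up(89.5) == 90
        assert round_half_up(-2.5) == -3

    @pytest.mark.parametrize("kwargs", [
        {"lsc_mm": -1}, {"adequacy_threshold_pct": 0}, {"adequacy_threshold_pct": 101},
        {"min_walls_global": 0}, {"min_walls_global": 5}, {"exclusion_geometry": "round"},
    ])
    def test_invalid_analysis_config(self, kwargs):
        with pytest.raises(ConfigurationError):
            AnalysisConfig(**kwargs)
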