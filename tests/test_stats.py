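"""Kinetics statistics: mean length, average rate, pause half-life,
relative tables, replicate summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tecelong import (
    PauseKinetics,
    average_elongation_rate,
    condition_results,
    full_length_fraction,
    mean_transcript_length,
    pause_half_life,
    relative_half_life,
    relative_rate,
    summarize_replicates,
    transient_distribution,
)
from tecelong.simulate import SimulationParams
from tecelong.stats import BIN_COLS


def rows_from_lbar(lbar_fn, times=(15, 30, 60, 120, 240), scheme=None):
    """Build bin rows whose midpoint-mean equals a prescribed Lbar(t) by
    mixing bin 1 (58) and bin 7 (216.5)."""
    from tecelong.binning import default_bin_scheme

    scheme = scheme or default_bin_scheme()
    m1, m7 = scheme.midpoints[0], scheme.midpoints[6]
    rows = []
    for t in times:
        lbar = lbar_fn(t)
        f7 = (lbar - m1) / (m7 - m1)
        f = {c: 0.0 for c in BIN_COLS}
        f["bin1"], f["bin7"] = 1.0 - f7, f7
        rows.append({"time_s": float(t), **f})
    return pd.DataFrame(rows)


class TestMeanLength:
    def test_all_stalled(self, scheme):
        f = np.zeros(7); f[0] = 1.0
        assert mean_transcript_length(f, scheme) == 58.0

    def test_all_full_length(self, scheme):
        f = np.zeros(7); f[6] = 1.0
        assert mean_transcript_length(f, scheme) == 216.5

    def test_uniform_is_mean_of_midpoints(self, scheme):
        f = np.full(7, 1.0 / 7.0)
        assert mean_transcript_length(f, scheme) == pytest.approx(
            scheme.midpoints.mean()
        )

    def test_bad_sum_rejected(self, scheme):
        with pytest.raises(ValueError):
            mean_transcript_length(np.full(7, 0.2), scheme)


class TestAverageRate:
    def test_exact_linear_elongation(self):
        rows = rows_from_lbar(lambda t: 58 + 0.5 * t)
        assert average_elongation_rate(rows) == pytest.approx(0.5)

    def test_no_elongation_is_zero(self):
        rows = rows_from_lbar(lambda t: 58.0)
        assert average_elongation_rate(rows) == pytest.approx(0.0)

    def test_zero_timepoint_rejected(self):
        rows = rows_from_lbar(lambda t: 58.0, times=(0, 15))
        with pytest.raises(ValueError):
            average_elongation_rate(rows)

    def test_matches_oracle_statistic(self, template, free_landscape,
                                      fast_params, scheme):
        """Simulated rate statistic agrees with the same formula applied to
        the exact transient distributions."""
        from tecelong import simulate_ensemble

        dists = simulate_ensemble(fast_params, free_landscape, template)
        rows = pd.DataFrame([
            {"time_s": d.time_s,
             **{f"bin{b+1}": f for b, f in enumerate(d.bin_fractions(scheme))}}
            for d in dists
        ])
        r_sim = average_elongation_rate(rows, scheme)
        oracle_rows = []
        for t in fast_params.obs_times:
            d = transient_distribution(fast_params, free_landscape, template, t)
            oracle_rows.append(
                {"time_s": t,
                 **{f"bin{b+1}": f for b, f in enumerate(d.bin_fractions(scheme))}}
            )
        r_oracle = average_elongation_rate(pd.DataFrame(oracle_rows), scheme)
        assert r_sim == pytest.approx(r_oracle, rel=0.05)


class TestRelativeRate:
    def test_ratio(self):
        assert relative_rate(0.4, 0.5) == pytest.approx(0.8)

    def test_identity(self):
        assert relative_rate(0.37, 0.37) == 1.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_rate(0.4, 0.0)

    def test_strictly_decreasing_in_barrier_strength(self, template, scheme):
        """Oracle-evaluated rate statistic falls monotonically as the first
        barrier strengthens."""
        from tecelong import make_landscape

        p = SimulationParams(k_step=2.0, k_release=0.05)
        rates = []
        for beta in [1.0, 5.0, 25.0, 125.0, 625.0]:
            ls = make_landscape(template, "custom", barrier_factors=beta)
            rows = []
            for t in p.obs_times:
                d = transient_distribution(p, ls, template, t)
                rows.append(
                    {"time_s": t,
                     **{f"bin{b+1}": f
                        for b, f in enumerate(d.bin_fractions(scheme))}}
                )
            rates.append(average_elongation_rate(pd.DataFrame(rows), scheme))
        rel = [r / rates[0] for r in rates]
        assert all(b < a for a, b in zip(rel, rel[1:]))


class TestPauseHalfLife:
    def test_halving_over_interval(self):
        pk = pause_half_life(0.5, 0.25, t1=15, t2=240)
        assert pk.t_half == pytest.approx(225.0)

    def test_no_decay_flagged_undefined(self):
        pk = pause_half_life(0.3, 0.3)
        assert pk.k == 0.0
        assert not pk.defined

    def test_growth_flagged_undefined(self):
        pk = pause_half_life(0.2, 0.3)
        assert pk.k < 0
        assert not pk.defined

    def test_exact_inversion_of_oracle_fractions(self):
        """Fed fractions from a true exponential, the estimator returns the
        generating half-life to machine precision."""
        k = 0.01
        pk = pause_half_life(math.exp(-k * 15), math.exp(-k * 240))
        assert pk.t_half == pytest.approx(math.log(2) / k, rel=1e-9)

    @pytest.mark.parametrize("bad", [(0.0, 0.5), (0.5, 0.0), (-0.1, 0.5)])
    def test_nonpositive_fractions_rejected(self, bad):
        with pytest.raises(ValueError):
            pause_half_life(*bad)

    def test_bad_interval_rejected(self):
        with pytest.raises(ValueError):
            pause_half_life(0.5, 0.25, t1=240, t2=15)

    @given(
        k=st.floats(1e-4, 0.1),
        t1=st.floats(1.0, 100.0),
        dt=st.floats(10.0, 1000.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_inversion_identity_grid(self, k, t1, dt):
        pk = pause_half_life(math.exp(-k * t1), math.exp(-k * (t1 + dt)),
                             t1=t1, t2=t1 + dt)
        assert pk.k == pytest.approx(k, rel=1e-9)
        assert pk.t_half == pytest.approx(math.log(2) / k, rel=1e-9)


class TestRelativeHalfLife:
    def _kin(self, t_half):
        k = math.log(2) / t_half
        return PauseKinetics(C1=0.5, C2=0.25, t1=15, t2=240, k=k, t_half=t_half)

    def test_reference_is_exactly_one(self):
        kin = {("WT", False): self._kin(100.0), ("G17D", False): self._kin(65.0)}
        table = relative_half_life(kin)
        ref = table[(table["condition"] == "WT") & (table["tfs"] == 0)]
        assert float(ref["relative_t_half"].iloc[0]) == 1.0

    def test_half_reference_gives_half(self):
        kin = {("WT", False): self._kin(100.0), ("X", False): self._kin(50.0)}
        table = relative_half_life(kin)
        x = table[table["condition"] == "X"]
        assert float(x["relative_t_half"].iloc[0]) == pytest.approx(0.5)

    def test_tfs_release_boost_shortens_half_life(self):
        """A TFS release multiplier > 1 strictly reduces the half-life:
        t_half = ln2 / (mult * k_release) in the exponential model."""
        k = 0.005
        for mult in [1.5, 2.0, 3.0]:
            minus = pause_half_life(math.exp(-k * 15), math.exp(-k * 240))
            plus = pause_half_life(
                math.exp(-mult * k * 15), math.exp(-mult * k * 240)
            )
            assert plus.t_half < minus.t_half

    def test_missing_reference_rejected(self):
        with pytest.raises(KeyError):
            relative_half_life({("X", False): self._kin(50.0)})


class TestSummaries:
    def test_full_length_fraction(self):
        row = pd.Series({c: 0.0 for c in BIN_COLS} | {"bin7": 0.42})
        assert full_length_fraction(row) == pytest.approx(0.42)

    def test_identical_replicates_zero_se(self):
        mean, se = summarize_replicates([0.5, 0.5, 0.5])
        assert mean == 0.5
        assert se == 0.0

    def test_two_replicates_closed_form(self):
        mean, se = summarize_replicates([0.4, 0.6])
        assert mean == pytest.approx(0.5)
        assert se == pytest.approx(0.1)

    def test_single_replicate_se_undefined(self):
        mean, se = summarize_replicates([0.4])
        assert mean == 0.4
        assert math.isnan(se)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_replicates([])


class TestConditionResults:
    def test_study_summary_structure(self):
        from tecelong import generate_study

        table = generate_study(master_seed=4, n_molecules=200)
        res = condition_results(table)
        assert len(res) == 20  # 10 variants x (-TFS, +TFS)
        ref = res[(res["condition"] == "WT") & (res["tfs"] == 0)]
        assert float(ref["relative_t_half"].iloc[0]) == 1.0
        free = res[(res["condition"] == "HTkA-free") & (res["tfs"] == 0)]
        assert float(free["relative_rate"].iloc[0]) == pytest.approx(1.0)
        assert (res["rate_nt_s"] >= 0).all()

    def test_mean_percentage_mode_agrees_closely(self):
        """Averaging fractions before computing the rate gives nearly the
        same answer as averaging per-replicate rates (the statistic is
        linear in the fractions for a fixed time grid)."""
        from tecelong import generate_study

        table = generate_study(master_seed=4, n_molecules=200)
        per_rep = condition_results(table)
        pooled = condition_results(table, averaging="mean_percentage")
        merged = per_rep.merge(
            pooled, on=["condition", "tfs"], suffixes=("_rep", "_pool")
        )
        assert np.allclose(
            merged["rate_nt_s_rep"], merged["rate_nt_s_pool"], rtol=1e-9
        )
        assert pooled["rate_se"].isna().all()

    def test_unknown_averaging_rejected(self):
        from tecelong import generate_study

        table = generate_study(master_seed=4, n_molecules=50)
        with pytest.raises(ValueError):
            condition_results(table, averaging="median")

    def test_missing_free_condition_rejected(self):
        from tecelong import generate_study
        from tecelong.simulate import StudyCondition

        table = generate_study(
            master_seed=4, n_molecules=50,
            conditions=[StudyCondition("WT", False, 2)],
        )
        with pytest.raises(ValueError):
            condition_results(table)
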