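import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import coralstress as cs
from coralstress.datatypes import CpTable, DilutionSeries
from coralstress.errors import (
    ConfigurationError,
    InsufficientDataError,
    InvalidArgumentError,
    NonAmplifyingSeriesError,
)


def series_from_slope(slope, n=7, intercept=15.0, gene="g"):
    """Exact dilution series with the given CP-vs-log2(amount) slope."""
    amounts = [2.0 ** (-i) for i in range(n)]
    pts = tuple((a, intercept + slope * math.log2(a)) for a in amounts)
    return DilutionSeries(gene_id=gene, points=pts)


class TestEstimateEfficiency:
    def test_perfect_doubling_series(self):
        est = cs.estimate_efficiency(series_from_slope(-1.0))
        assert est.slope == pytest.approx(-1.0)
        assert est.efficiency == pytest.approx(2.0)
        assert est.r_squared == pytest.approx(1.0)
        assert est.qc_pass

    def test_slope_minus_1_1(self):
        est = cs.estimate_efficiency(series_from_slope(-1.1))
        assert est.efficiency == pytest.approx(2.0 ** (1.0 / 1.1), abs=1e-9)
        assert est.efficiency == pytest.approx(1.878, abs=1e-3)
        assert est.qc_pass

    def test_increasing_cp_with_input_is_non_amplifying(self):
        with pytest.raises(NonAmplifyingSeriesError):
            cs.estimate_efficiency(series_from_slope(+1.0))

    def test_fewer_than_three_distinct_amounts(self):
        s = DilutionSeries("g", ((1.0, 20.0), (1.0, 20.1), (0.5, 21.0)))
        with pytest.raises(InvalidArgumentError):
            cs.estimate_efficiency(s)

    def test_qc_flag_outside_range(self):
        est = cs.estimate_efficiency(series_from_slope(-1.4))  # E ~ 1.64
        assert not est.qc_pass
        assert est.efficiency < 1.85

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_amount_rescaling_invariance(self, scale):
        base = series_from_slope(-1.05)
        scaled = DilutionSeries(
            "g", tuple((a * scale, cp) for a, cp in base.points)
        )
        e1 = cs.estimate_efficiency(base)
        e2 = cs.estimate_efficiency(scaled)
        assert e2.slope == pytest.approx(e1.slope, abs=1e-9)
        assert e2.efficiency == pytest.approx(e1.efficiency, abs=1e-9)


class TestCpToCa:
    def test_known_values(self):
        assert cs.cp_to_ca(20.0, 2.0) == pytest.approx(-20.0)
        assert cs.cp_to_ca(20.0, 1.9) == pytest.approx(-18.520, abs=1e-3)
        assert cs.cp_to_ca(0.0, 1.9) == 0.0

    def test_invalid_efficiency(self):
        for bad in (1.0, 0.5, -2.0):
            with pytest.raises(InvalidArgumentError):
                cs.cp_to_ca(20.0, bad)

    @given(st.floats(min_value=1.0, max_value=40.0),
           st.floats(min_value=1.05, max_value=2.5))
    def test_strictly_decreasing_in_cp_and_e(self, cp, eff):
        assert cs.cp_to_ca(cp + 0.5, eff) < cs.cp_to_ca(cp, eff)
        assert cs.cp_to_ca(cp, eff + 0.05) < cs.cp_to_ca(cp, eff)


def make_cp_table(rows):
    return CpTable(pd.DataFrame(rows, columns=["sample_id", "gene_id", "run_id", "cp"]))


class TestAggregateDuplicates:
    def test_mean_on_ca_scale(self):
        table = make_cp_table([("s1", "g", "r1", 20.0), ("s1", "g", "r2", 21.0)])
        ca = cs.aggregate_duplicates(table, {"g": 2.0})
        assert ca.values.loc["s1", "g"] == pytest.approx(-20.5)
        assert not ca.discordant.loc["s1", "g"]

    def test_single_run_no_flag(self):
        table = make_cp_table([("s1", "g", "r1", 18.0)])
        ca = cs.aggregate_duplicates(table, {"g": 2.0})
        assert ca.values.loc["s1", "g"] == pytest.approx(-18.0)
        assert not ca.discordant.loc["s1", "g"]

    def test_discordant_duplicates_kept_and_flagged(self):
        table = make_cp_table([("s1", "g", "r1", 20.0), ("s1", "g", "r2", 22.0)])
        ca = cs.aggregate_duplicates(table, {"g": 2.0}, discordance_limit=1.5)
        assert ca.values.loc["s1", "g"] == pytest.approx(-21.0)
        assert bool(ca.discordant.loc["s1", "g"])

    def test_missing_efficiency_is_config_error(self):
        table = make_cp_table([("s1", "g", "r1", 20.0)])
        with pytest.raises(ConfigurationError):
            cs.aggregate_duplicates(table, {"other": 2.0})

    def test_unmeasured_cell_is_explicit_missing(self):
        table = make_cp_table([
            ("s1", "a", "r1", 20.0), ("s1", "b", "r1", 21.0),
            ("s2", "a", "r1", 19.0),
        ])
        ca = cs.aggregate_duplicates(table, {"a": 2.0, "b": 2.0})
        assert np.isnan(ca.values.loc["s2", "b"])


class TestNormalizeCa:
    def test_subtracts_control_mean(self):
        values = pd.DataFrame(
            {"t": [-5.0], "c1": [-10.0], "c2": [-12.0], "c3": [-14.0]},
            index=["s1"],
        )
        norm = cs.normalize_ca(cs.CaMatrix(values=values), ["c1", "c2", "c3"])
        assert norm.values.loc["s1", "t"] == pytest.approx(7.0)
        assert norm.normalized
        assert norm.control_genes == ("c1", "c2", "c3")

    def test_loading_invariance(self, rng):
        values = pd.DataFrame(rng.normal(-15, 3, size=(4, 5)),
                              index=list("abcd"),
                              columns=["t1", "t2", "c1", "c2", "c3"])
        norm = cs.normalize_ca(cs.CaMatrix(values=values), ["c1", "c2", "c3"])
        shifted = values.copy()
        shifted.loc["b"] += 3.0
        norm2 = cs.normalize_ca(cs.CaMatrix(values=shifted), ["c1", "c2", "c3"])
        pd.testing.assert_frame_equal(norm.values, norm2.values)

    def test_normalized_controls_mean_zero_idempotence(self, rng):
        values = pd.DataFrame(rng.normal(-15, 3, size=(5, 4)),
                              index=list("abcde"),
                              columns=["t1", "c1", "c2", "c3"])
        controls = ["c1", "c2", "c3"]
        norm = cs.normalize_ca(cs.CaMatrix(values=values), controls,
                               include_controls=True)
        # per sample the normalized controls average to exactly 0, so a
        # second normalization subtracts ~0
        assert np.allclose(norm.values[controls].mean(axis=1), 0.0, atol=1e-12)
        renorm = cs.normalize_ca(norm, controls, include_controls=True)
        pd.testing.assert_frame_equal(renorm.values, norm.values)

    def test_geometric_mean_oracle(self, rng):
        """Arithmetic-mean subtraction on the log2 scale equals dividing the
        linear-scale amounts by the control genes' geometric mean."""
        values = pd.DataFrame(rng.normal(-18, 2, size=(6, 5)),
                              index=[f"s{i}" for i in range(6)],
                              columns=["t1", "t2", "c1", "c2", "c3"])
        controls = ["c1", "c2", "c3"]
        norm = cs.normalize_ca(cs.CaMatrix(values=values), controls)
        amounts = 2.0 ** values
        geo = np.exp(np.log(amounts[controls]).mean(axis=1))
        oracle = np.log2(amounts[["t1", "t2"]].div(geo, axis=0))
        assert np.allclose(norm.values, oracle, atol=1e-10)

    def test_sample_missing_all_controls_errors(self):
        values = pd.DataFrame(
            {"t": [-5.0, -6.0], "c1": [-10.0, np.nan], "c2": [-12.0, np.nan]},
            index=["s1", "s2"],
        )
        with pytest.raises(InsufficientDataError):
            cs.normalize_ca(cs.CaMatrix(values=values), ["c1", "c2"])

    def test_partial_controls_uses_available_mean(self):
        values = pd.DataFrame(
            {"t": [-5.0], "c1": [-10.0], "c2": [np.nan]}, index=["s1"]
        )
        norm = cs.normalize_ca(cs.CaMatrix(values=values), ["c1", "c2"])
        assert norm.values.loc["s1", "t"] == pytest.approx(-5.0 - (-10.0))

    def test_zero_noise_exp1_recovers_effects_exactly(self):
        from dataclasses import replace

        config = replace(cs.preset_scenario("exp1", seed=5),
                         colony_sd=0.0, residual_sd=0.0, loading_sd=0.0,
                         technical_sd=0.0)
        cp, truth = cs.simulate_experiment(config)
        ca = cs.aggregate_duplicates(cp, config.efficiency_map())
        norm = cs.normalize_ca(ca, list(cs.DEFAULT_NORMALIZATION_CONTROLS))
        meta = truth.metadata
        for gene in ("Hsp16", "Actin", "Chrom", "ADK"):
            stress = norm.values.loc[meta["treatment"] == "heat", gene]
            control = norm.values.loc[meta["treatment"] == "control", gene]
            diff = stress.to_numpy() - control.to_numpy()  # colonies align
            assert np.allclose(diff, config.effect_for(gene, ("heat",)),
                               atol=1e-10)
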