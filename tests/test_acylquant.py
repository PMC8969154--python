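import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import student_t_p
from acylpipe import acylquant, synthio
from acylpipe.errors import (
    CoordinateError,
    InvalidConfigError,
    NormalizationError,
    UnimputableSampleError,
)


def _table(rows):
    return pd.DataFrame(rows, columns=acylquant.TABLE_COLUMNS)


def _row(pep, site, mod, cond, rep, inten):
    return (pep, site, mod, cond, rep, inten)


class TestProteinAbundance:
    def test_single_unmodified_peptide(self):
        t = _table([_row("u1", None, "none", "a", 1, 10.0)])
        assert acylquant.protein_abundance(t, ("a", 1)) == 10.0

    def test_mean_of_two(self):
        t = _table([
            _row("u1", None, "none", "a", 1, 10.0),
            _row("u2", None, "none", "a", 1, 30.0),
        ])
        assert acylquant.protein_abundance(t, ("a", 1)) == 20.0

    def test_median_and_sum_options(self):
        t = _table([
            _row("u1", None, "none", "a", 1, 10.0),
            _row("u2", None, "none", "a", 1, 30.0),
            _row("u3", None, "none", "a", 1, 110.0),
        ])
        assert acylquant.protein_abundance(t, ("a", 1), agg="median") == 30.0
        assert acylquant.protein_abundance(t, ("a", 1), agg="sum") == 150.0

    def test_no_unmodified_raises(self):
        t = _table([_row("m1", 5, "glutaryl", "a", 1, 10.0)])
        with pytest.raises(NormalizationError):
            acylquant.protein_abundance(t, ("a", 1))

    def test_tracks_injected_scale_factor(self):
        # estimate regressed on the per-sample factor: R^2 > 0.99 at zero noise
        tab, _ = synthio.gen_acyl_table(5, 6, ["a"], 12, {}, seed=0,
                                        rep_noise_sd=1e-9, sample_scale_sd=0.5)
        est = np.log2([
            acylquant.protein_abundance(tab, ("a", rep)) for rep in range(1, 13)
        ])
        # recover the factor from the same table's unmodified rows
        truth_scale = (
            tab[tab.mod_type == "none"].groupby("replicate")["intensity"]
            .apply(lambda v: np.log2(v).mean())
            .sort_index()
            .to_numpy()
        )
        r = np.corrcoef(est, truth_scale)[0, 1]
        assert r**2 > 0.99


class TestNormalize:
    def test_scale_invariance_exact(self, acyl_table):
        table, _ = acyl_table
        table = table.dropna(subset=["intensity"]).reset_index(drop=True)
        scaled = table.copy()
        mask = (scaled.condition == "glut") & (scaled.replicate == 2)
        scaled.loc[mask, "intensity"] *= 7.0
        a = acylquant.normalize(table)
        b = acylquant.normalize(scaled)
        acyl = a.mod_type != "none"
        np.testing.assert_allclose(
            a.loc[acyl, "intensity"].to_numpy(float),
            b.loc[acyl, "intensity"].to_numpy(float),
            rtol=1e-12,
        )

    def test_uniform_table_all_equal(self):
        rows = []
        for cond in ("a", "b"):
            for rep in (1, 2):
                rows.append(_row("u1", None, "none", cond, rep, 5.0))
                rows.append(_row("m1", 13, "glutaryl", cond, rep, 5.0))
        out = acylquant.normalize(_table(rows))
        acyl = out.mod_type != "none"
        assert (out.loc[acyl, "intensity"] == 1.0).all()

    def test_null_generator_no_between_condition_shift(self):
        diffs = []
        for seed in range(20):
            tab, _ = synthio.gen_acyl_table(8, 4, ["a", "b"], 3, {}, seed=seed)
            norm = acylquant.normalize(tab)
            acyl = norm[norm.mod_type != "none"]
            m = acyl.groupby("condition")["intensity"].apply(
                lambda v: np.log2(v).mean()
            )
            diffs.append(m["b"] - m["a"])
        assert abs(np.mean(diffs)) < 0.05


class TestImputeLow:
    def test_identity_when_complete(self):
        t, _ = synthio.gen_acyl_table(5, 2, ["a"], 3, {}, missing_rate=0.0, seed=1)
        out = acylquant.impute_low(t, seed=0)
        pd.testing.assert_frame_equal(out, t)

    def test_seed_determinism(self, acyl_table):
        table, _ = acyl_table
        a = acylquant.impute_low(table, seed=42)
        b = acylquant.impute_low(table, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_imputed_below_quantile_ceiling(self):
        # property over 100 seeds: imputed values never exceed the sample's
        # 5th-percentile observed intensity
        for seed in range(100):
            t, _ = synthio.gen_acyl_table(10, 4, ["a", "b"], 3, {},
                                          missing_rate=0.25, seed=seed)
            out = acylquant.impute_low(t, quantile=0.05, seed=seed)
            was_missing = t["intensity"].isna()
            for (cond, rep), sub in t.groupby(["condition", "replicate"]):
                obs = sub["intensity"].dropna()
                if obs.empty:
                    continue
                ceiling = obs.quantile(0.05)
                m = was_missing & (t.condition == cond) & (t.replicate == rep)
                if m.any():
                    assert (out.loc[m, "intensity"] <= ceiling + 1e-12).all()

    def test_too_much_missing_rejected(self):
        t, _ = synthio.gen_acyl_table(5, 2, ["a"], 3, {}, seed=1)
        t.loc[: len(t) // 2 + 1, "intensity"] = np.nan
        with pytest.raises(InvalidConfigError):
            acylquant.impute_low(t)

    def test_fully_missing_sample_rejected(self):
        t, _ = synthio.gen_acyl_table(5, 2, ["a", "b"], 2, {}, seed=1)
        m = (t.condition == "a") & (t.replicate == 1)
        t.loc[m, "intensity"] = np.nan
        with pytest.raises(UnimputableSampleError):
            acylquant.impute_low(t)


class TestSiteDifferential:
    @staticmethod
    def _paired_table(a_vals, b_vals, site=17):
        rows = []
        for rep, (av, bv) in enumerate(zip(a_vals, b_vals), start=1):
            for cond, v in (("a", av), ("b", bv)):
                rows.append(_row("u1", None, "none", cond, rep, 1.0))
                rows.append(_row("m1", site, "glutaryl", cond, rep, float(v)))
        return _table(rows)

    def test_identical_groups_zero_fc(self):
        t = self._paired_table([4, 5, 6], [4, 5, 6])
        res = acylquant.site_differential(t, ("a", "b"))
        assert res[0].log2fc == pytest.approx(0.0, abs=1e-12)
        assert not res[0].significant

    def test_matches_t_oracle(self):
        a = [2.0, 2.0, 2.0]
        b = [2.0**4, 2.0**4.2, 2.0**3.9]
        t = self._paired_table(a, b)
        res = acylquant.site_differential(t, ("a", "b"))
        _, p_expected = student_t_p(np.log2(a), np.log2(b))
        assert res[0].p == pytest.approx(p_expected, abs=1e-9)
        assert res[0].log2fc == pytest.approx(np.mean([4, 4.2, 3.9]) - 1.0, abs=1e-12)

    def test_zero_variance_both_groups_not_testable(self):
        t = self._paired_table([4, 4, 4], [8, 8, 8])
        res = acylquant.site_differential(t, ("a", "b"))
        assert not res[0].testable
        assert np.isnan(res[0].p)

    def test_deglutarylation_no_fc_gate(self):
        # small but significant decrease: flagged only under deglutarylation rule
        a = [8.0, 8.1, 7.9]
        b = [6.0, 6.1, 5.9]
        t = self._paired_table(a, b)
        glut = acylquant.site_differential(t, ("a", "b"), ratio_kind="glutarylation")
        deglut = acylquant.site_differential(t, ("a", "b"), ratio_kind="deglutarylation")
        assert not glut[0].significant
        assert deglut[0].significant

    def test_recovery_simulation(self):
        effects = {i: 3.0 for i in range(1, 7)}
        exact = 0
        for seed in range(100):
            tab, truth = synthio.gen_acyl_table(
                10, 4, ["unmod", "glut"], 3, effects, missing_rate=0.02, seed=seed
            )
            comp = acylquant.impute_low(acylquant.normalize(tab), seed=seed)
            res = acylquant.site_differential(comp, ("unmod", "glut"))
            flagged = {r.site_residue for r in res if r.significant}
            true = {s for s, e in truth.true_site_log2fc.items() if e > 0}
            exact += flagged == true
        assert exact >= 95

    def test_full_null_false_flag_rate(self):
        # joint (fc>1.8 AND p<=0.05) gate is far below 0.05 under the null
        flags = total = 0
        for seed in range(50):
            tab, _ = synthio.gen_acyl_table(10, 4, ["a", "b"], 3, {}, seed=seed)
            res = acylquant.site_differential(acylquant.normalize(tab), ("a", "b"))
            flags += sum(r.significant for r in res)
            total += len(res)
        assert flags / total < 0.01


class TestMapResidue:
    def test_offset_zero_identity(self):
        assert acylquant.map_residue(7, 0, 1) == 7

    def test_configured_offset(self):
        assert acylquant.map_residue(209, 44, 1) == 253

    def test_negative_offset_rejected(self):
        with pytest.raises(CoordinateError):
            acylquant.map_residue(5, -1, 1)

    @settings(max_examples=200, deadline=None)
    @given(pos=st.integers(1, 5000), offset=st.integers(0, 200))
    def test_round_trip(self, pos, offset):
        full = acylquant.map_residue(pos, offset, 1)
        assert acylquant.unmap_residue(full, offset) == pos


class TestModMass:
    def test_empty_formula_zero(self):
        assert acylquant.mod_mass({}) == 0.0

    def test_glutaryl_mass(self):
        assert acylquant.mod_mass({"C": 5, "H": 6, "O": 3}) == pytest.approx(
            114.0316941, abs=1e-5
        )

    def test_water_mass(self):
        # 2*1.00782503207 + 15.99491461956
        assert acylquant.mod_mass({"H": 2, "O": 1}) == pytest.approx(
            18.0105646, abs=1e-5
        )

    def test_unknown_element(self):
        with pytest.raises(InvalidConfigError):
            acylquant.mod_mass({"Xe": 1})

    def test_composition_object(self):
        assert acylquant.GLUTARYL.monoisotopic_mass == pytest.approx(
            114.0316941, abs=1e-6
        )
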