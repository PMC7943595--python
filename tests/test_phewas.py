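"""Case/control derivation, eligibility, logistic association, IVW, burdens."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from uorfsel.phewas import (
    AssociationResult,
    bh_fdr,
    burden_collapse,
    derive_case_control,
    eligibility_filters,
    ivw_meta,
    logistic_assoc,
    phewas_thresholds,
    run_phewas,
)


def events_frame(rows):
    return pd.DataFrame(rows, columns=["individual", "code", "date"])


class TestCaseControl:
    IND = ["a", "b", "c", "d"]

    def test_two_dates_is_case_one_date_excluded(self):
        ev = events_frame(
            [
                ("a", "P1", "2015-01-01"),
                ("a", "P1", "2016-01-01"),
                ("b", "P1", "2015-01-01"),
            ]
        )
        status = derive_case_control(ev, "P1", self.IND)
        assert status["a"] == "case"
        assert status["b"] == "excluded"  # single dated diagnosis: ambiguous
        assert status["c"] == "control"

    def test_duplicate_date_counts_once(self):
        ev = events_frame(
            [("a", "P1", "2015-01-01"), ("a", "P1", "2015-01-01")]
        )
        status = derive_case_control(ev, "P1", self.IND)
        assert status["a"] == "excluded"

    def test_single_encounter_mode(self):
        """min_case_dates=1: one encounter suffices for case status."""
        ev = events_frame([("a", "P1", "2015-01-01")])
        status = derive_case_control(ev, "P1", self.IND, min_case_dates=1)
        assert status["a"] == "case"

    def test_control_exclusion_codes(self):
        ev = events_frame(
            [
                ("a", "P1", "2015-01-01"),
                ("a", "P1", "2016-01-01"),
                ("b", "P2", "2015-01-01"),
            ]
        )
        status = derive_case_control(
            ev, "P1", self.IND, control_exclusion_codes={"P2"}
        )
        assert status["b"] == "excluded"  # related code bars control status
        assert status["c"] == "control"


class TestEligibility:
    def _inputs(self, dosage_vals, n_cases=25):
        idx = [f"i{k}" for k in range(len(dosage_vals))]
        d = pd.Series(dosage_vals, index=idx, dtype=float)
        status = pd.Series("control", index=idx)
        status.iloc[:n_cases] = "case"
        return d, status

    def test_too_few_alt_alleles(self):
        d, s = self._inputs([1, 1, 1, 1] + [0] * 96)
        ok, reasons = eligibility_filters(d, s)
        assert not ok and reasons == ["min_alt_alleles"]

    def test_too_few_cases(self):
        d, s = self._inputs([1] * 10 + [0] * 90, n_cases=19)
        ok, reasons = eligibility_filters(d, s)
        assert not ok and "min_cases" in reasons

    def test_excess_missingness(self):
        vals = [1] * 10 + [np.nan] * 51 + [0] * 39
        d, s = self._inputs(vals)
        ok, reasons = eligibility_filters(d, s)
        assert not ok and "max_missing_frac" in reasons

    def test_eligible_variant_passes(self):
        d, s = self._inputs([1] * 6 + [0] * 94)
        ok, reasons = eligibility_filters(d, s)
        assert ok and reasons == []


class TestLogisticAssociation:
    def test_no_covariate_or_equals_cross_product(self):
        """With a binary exposure the ML OR is the 2x2 cross-product ratio."""
        a, b, c, d = 30, 70, 10, 90  # exposed cases/controls, unexposed ...
        dosage, status = [], []
        dosage += [1] * a + [1] * b + [0] * c + [0] * d
        status += ["case"] * a + ["control"] * b + ["case"] * c + ["control"] * d
        idx = [f"i{k}" for k in range(len(dosage))]
        res = logistic_assoc(
            pd.Series(dosage, index=idx, dtype=float),
            pd.Series(status, index=idx),
        )
        assert res.odds_ratio == pytest.approx((a * d) / (b * c), abs=1e-6)
        assert res.n_cases == a + c
        assert res.reliable

    def test_null_variant_or_near_one(self):
        rng = np.random.default_rng(0)
        n = 5000
        idx = [f"i{k}" for k in range(n)]
        dosage = pd.Series(rng.binomial(2, 0.3, size=n), index=idx, dtype=float)
        status = pd.Series(
            np.where(rng.random(n) < 0.2, "case", "control"), index=idx
        )
        cov = pd.DataFrame({"age": rng.uniform(20, 80, n)}, index=idx)
        res = logistic_assoc(dosage, status, cov)
        assert res.odds_ratio == pytest.approx(1.0, abs=0.15)
        assert res.p_value > 0.001

    def test_complete_separation_flagged_not_silent(self):
        idx = [f"i{k}" for k in range(40)]
        dosage = pd.Series([1] * 20 + [0] * 20, index=idx, dtype=float)
        status = pd.Series(["case"] * 20 + ["control"] * 20, index=idx)
        res = logistic_assoc(dosage, status)
        assert not res.reliable

    def test_firth_fit_finite_under_separation(self):
        idx = [f"i{k}" for k in range(40)]
        dosage = pd.Series([1] * 20 + [0] * 20, index=idx, dtype=float)
        status = pd.Series(["case"] * 20 + ["control"] * 20, index=idx)
        res = logistic_assoc(dosage, status, firth=True)
        assert np.isfinite(res.beta) and np.isfinite(res.se)
        assert res.reliable

    def test_missing_dosages_excluded(self):
        idx = [f"i{k}" for k in range(6)]
        dosage = pd.Series([1, 0, np.nan, 1, 0, 0], index=idx)
        status = pd.Series(
            ["case", "case", "case", "control", "control", "excluded"], index=idx
        )
        res = logistic_assoc(dosage, status)
        assert res.n_cases + res.n_controls == 4


class TestIvwMeta:
    def _r(self, beta, se, stratum="s"):
        return AssociationResult("v", "P1", beta, se, 0.5, 30, 70, stratum)

    def test_single_stratum_unchanged(self):
        r = self._r(0.4, 0.1)
        assert ivw_meta([r]) is r

    def test_equal_strata_closed_form(self):
        """Two strata, same beta and se s -> same beta, se = s/sqrt(2)."""
        meta = ivw_meta([self._r(0.4, 0.2, "EUR"), self._r(0.4, 0.2, "AFR")])
        assert meta.beta == pytest.approx(0.4)
        assert meta.se == pytest.approx(0.2 / np.sqrt(2))

    def test_three_unequal_strata_match_hand_computation(self):
        rs = [self._r(0.2, 0.1), self._r(0.5, 0.3), self._r(-0.1, 0.2)]
        w = np.array([100.0, 1 / 0.09, 25.0])
        b = np.array([0.2, 0.5, -0.1])
        meta = ivw_meta(rs)
        assert meta.beta == pytest.approx(float((w * b).sum() / w.sum()))
        assert meta.se == pytest.approx(float(w.sum() ** -0.5))
        expected_p = 2 * stats.norm.sf(abs(meta.beta / meta.se))
        assert meta.p_value == pytest.approx(expected_p)

    def test_variance_never_exceeds_best_stratum(self):
        rs = [self._r(0.1, 0.15), self._r(0.3, 0.4)]
        assert ivw_meta(rs).se <= 0.15

    def test_zero_se_rejected(self):
        with pytest.raises(ValueError):
            ivw_meta([self._r(0.1, 0.0)])

    def test_unreliable_strata_dropped(self):
        bad = AssociationResult("v", "P1", 9.0, 60.0, 0.5, 5, 95, "x",
                                separation=True)
        meta = ivw_meta([self._r(0.4, 0.2), bad])
        assert meta.beta == pytest.approx(0.4)


class TestBurden:
    ANN = pd.DataFrame(
        {
            "gene": ["G1", "G1", "G1", "G1", "G2"],
            "cds_labels": ["pLOF", "missense", "missense", "pLOF", "missense"],
            "revel": [np.nan, 0.5, 0.49, np.nan, 0.9],
            "maf": [1e-4, 1e-4, 1e-4, 2e-3, 1e-4],
        },
        index=["v1", "v2", "v3", "v4", "v5"],
    )

    def _dosages(self):
        return pd.DataFrame(
            {v: [1.0, 0.0] for v in self.ANN.index}, index=["a", "b"]
        )

    def test_qualifying_rules(self):
        """pLOF and REVEL >= 0.5 missense qualify; rare-frequency gate applies."""
        burden = burden_collapse("G1", self.ANN, self._dosages())
        # v1 (pLOF) + v2 (REVEL == 0.5 boundary included); v3 below REVEL,
        # v4 pLOF but MAF 0.2% > 0.1%
        assert burden["a"] == 2.0
        assert burden["b"] == 0.0

    def test_gene_without_qualifying_variants(self):
        ann = self.ANN.copy()
        ann["maf"] = 0.01
        burden = burden_collapse("G1", ann, self._dosages())
        assert (burden == 0).all()

    def test_other_gene_not_collapsed(self):
        burden = burden_collapse("G2", self.ANN, self._dosages())
        assert burden["a"] == 1.0  # only v5


class TestThresholds:
    def test_panel_arithmetic(self):
        bonf, fdr = phewas_thresholds(10, 800)
        assert bonf == pytest.approx(6.25e-6)
        assert fdr == pytest.approx(1.25e-4)

    def test_degenerate_panel(self):
        assert phewas_thresholds(1, 1) == (0.05, 0.1)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            phewas_thresholds(0, 10)

    def test_bh_stepup_is_monotone_in_alpha(self):
        p = [1e-6, 0.01, 0.2, 0.8]
        assert bh_fdr(p, 0.1).sum() >= bh_fdr(p, 0.01).sum()


def test_run_phewas_null_type_i_error():
    """With no true association, sub-Bonferroni hits are (almost surely) absent."""
    rng = np.random.default_rng(3)
    n = 2000
    idx = pd.Index([f"i{k}" for k in range(n)], name="individual")
    dosages = pd.DataFrame(
        {f"v{j}": rng.binomial(2, 0.05, n).astype(float) for j in range(3)},
        index=idx,
    )
    cov = pd.DataFrame({"age": rng.uniform(20, 80, n), "sex": rng.integers(0, 2, n)},
                       index=idx)
    rows = []
    for code in ("P1", "P2"):
        cases = rng.choice(n, size=200, replace=False)
        for i in cases:
            rows += [(idx[i], code, "2015-01-01"), (idx[i], code, "2016-01-01")]
    events = pd.DataFrame(rows, columns=["individual", "code", "date"])
    res = run_phewas(dosages, cov, events, ["P1", "P2"],
                     covariate_names=["age", "sex"])
    tested = res[res["tested"]]
    assert len(tested) == 6
    # expected sub-Bonferroni hits = alpha = 0.05; two would be a >3-sigma event
    assert (tested["p_value"] < phewas_thresholds(3, 2)[0]).sum() <= 1
    # and plainly null p-values are not clustered at zero
    assert tested["p_value"].median() > 0.05
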