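"""Reproducibility statistics: group CV, CV/ICC arithmetic against the
published summary cells, and REML variance components against a
balanced-ANOVA method-of-moments oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dwirepro import reference
from dwirepro.repro import (
    StatsError,
    analyse_metric_region,
    cv_from_components,
    fit_variance_components,
    group_cv,
    icc_pair,
    subgroup_analysis,
    summarize_report,
)
from dwirepro.study import generate_multicentre_study
from tests.test_study import balanced_design


def anova_components(table, metric="ADC", region="GM"):
    """Method-of-moments oracle for a balanced crossed design with
    additive scanner (fixed) and volunteer (random) effects."""
    sub = table[(table["metric"] == metric) & (table["region"] == region)]
    s = sub["scanner"].nunique()
    v = sub["volunteer"].nunique()
    n = len(sub)
    r = n // (s * v)
    grand = sub["value"].mean()
    smeans = sub.groupby("scanner")["value"].mean()
    vmeans = sub.groupby("volunteer")["value"].mean()
    ms_vol = s * r * ((vmeans - grand) ** 2).sum() / (v - 1)
    fitted = (grand
              + (sub["scanner"].map(smeans) - grand)
              + (sub["volunteer"].map(vmeans) - grand))
    ms_err = ((sub["value"] - fitted) ** 2).sum() / (n - s - v + 1)
    return {
        "mu": smeans.mean(),
        "sigma_inter": smeans.std(ddof=1),
        "sigma_volunteer": np.sqrt(max((ms_vol - ms_err) / (s * r), 0.0)),
        "sigma_intra": np.sqrt(ms_err),
    }


class TestGroupCV:
    def test_identical_values_zero_cv(self):
        assert group_cv([2.0, 2.0, 2.0]).cv == 0.0

    def test_phantom_overall_row(self):
        """The eight per-scanner phantom ADC means reproduce the published
        overall mean 1.1150, SD 0.0167, CV 1.5%."""
        g = group_cv(reference.phantom_means("ADC"))
        assert g.mean == pytest.approx(1.1150, abs=5e-5)
        assert g.sd == pytest.approx(0.0167, abs=5e-5)
        assert round(g.cv, 1) == 1.5

    def test_leave_one_scanner_out(self):
        """Excluding the scanner whose phantom was not at thermal
        equilibrium drops the ADC CV to 0.7%."""
        g = group_cv(reference.phantom_means("ADC", exclude=("F",)))
        assert round(g.cv, 1) == 0.7

    def test_zero_mean_flagged(self):
        g = group_cv([-1.0, 1.0])
        assert not g.defined

    def test_needs_two_values(self):
        with pytest.raises(StatsError):
            group_cv([1.0])

    @given(st.lists(st.floats(0.5, 2.0), min_size=3, max_size=10),
           st.floats(0.1, 100.0))
    @settings(deadline=None)
    def test_scale_invariance(self, values, c):
        a, b = group_cv(values), group_cv([c * v for v in values])
        if a.sd == 0:
            assert b.cv == pytest.approx(0.0, abs=1e-9)
        else:
            assert a.cv == pytest.approx(b.cv, rel=1e-9)


class TestCVICCArithmetic:
    def test_cv_worked_examples(self):
        # grey-matter ADC inter-scanner spread and grey-matter FA residual
        assert round(cv_from_components(0.8327, 0.0203), 1) == 2.4
        assert round(cv_from_components(0.1726, 0.0128), 1) == 7.4
        assert cv_from_components(5.0, 0.0) == 0.0

    def test_icc_worked_examples(self):
        # grey-matter ADC: near-even split of inter vs intra variance
        icc = icc_pair(0.0203, 0.0242)
        assert round(icc[0], 2) == 0.41 and round(icc[1], 2) == 0.59
        # white-matter ADC: scanner-dominated; the printed SDs give
        # 0.8948, within one print-rounding unit of the published 0.90
        icc = icc_pair(0.0210, 0.0072)
        assert icc[0] == pytest.approx(0.8948, abs=5e-5)
        assert abs(round(icc[0], 2) - 0.90) <= 0.01 + 1e-9

    def test_equal_variances_split_evenly(self):
        assert icc_pair(0.3, 0.3) == (0.5, 0.5)

    def test_both_zero_undefined(self):
        with pytest.raises(StatsError):
            icc_pair(0.0, 0.0)

    @given(st.floats(1e-6, 1.0), st.floats(1e-6, 1.0))
    @settings(deadline=None)
    def test_icc_sums_to_one(self, si, se):
        a, b = icc_pair(si, se)
        assert a + b == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= a <= 1.0


class TestPublishedTableRegression:
    """Every derived cell of the published volunteer tables is recomputed
    from its printed (mean, SD) inputs.

    CV cells must agree within 0.1 percentage point (the print rounding of
    the inputs); ICC cells within 0.01. A small documented set of cells is
    internally inconsistent in the source tables (SD typos and a partly
    misaligned ICC column) and is excluded.
    """

    @pytest.mark.parametrize(
        "row", reference.VOLUNTEER_CELLS,
        ids=[f"{m}-{r}" for m, r, *_ in reference.VOLUNTEER_CELLS],
    )
    def test_cv_cells(self, row):
        metric, region, mean, si, sv, se, ci, cv, ce, *_ = row
        for sd, printed, tag in [(si, ci, "inter"), (sv, cv, "volunteer"),
                                 (se, ce, "intra")]:
            if sd is None:
                assert printed is None
                continue
            if (metric, region, tag) in reference.CV_CELL_EXCLUSIONS:
                continue
            assert round(cv_from_components(mean, sd), 1) == pytest.approx(
                printed, abs=0.1 + 1e-9
            )

    @pytest.mark.parametrize(
        "row", reference.VOLUNTEER_CELLS,
        ids=[f"{m}-{r}" for m, r, *_ in reference.VOLUNTEER_CELLS],
    )
    def test_icc_cells(self, row):
        metric, region, _, si, _, se, *_, icc_i, icc_e = row
        if (metric, region) in reference.ICC_CELL_EXCLUSIONS:
            return
        a, b = icc_pair(si, se)
        assert abs(round(a, 2) - icc_i) <= 0.01 + 1e-9
        assert abs(round(b, 2) - icc_e) <= 0.01 + 1e-9


class TestVarianceComponents:
    def test_noiseless_deterministic_limit(self):
        """Single session per cell, zero noise: the residual SD is zero and
        the inter-scanner SD equals the sample SD of the offsets exactly."""
        design = balanced_design(n_sessions=1, offset_sd=0.03,
                                 volunteer_sd=0.0, residual_sd=0.0, seed=4)
        table, truth = generate_multicentre_study(design, seed=4)
        vc = fit_variance_components(table, "ADC", "GM")
        offs = [truth["scanner_offsets"][s]["ADC"]
                for s in sorted(truth["scanner_offsets"])]
        assert vc.sigma_intra == 0.0
        assert vc.sigma_inter == pytest.approx(np.std(offs, ddof=1), rel=1e-12)
        assert not vc.volunteer_estimable

    def test_reml_matches_balanced_anova(self):
        """On a balanced design the REML components coincide with the
        closed-form ANOVA method-of-moments estimates."""
        design = balanced_design(n_vol=6, volunteer_sd=0.015, seed=7)
        table, _ = generate_multicentre_study(design, seed=7)
        vc = fit_variance_components(table, "ADC", "GM")
        oracle = anova_components(table)
        assert vc.mu == pytest.approx(oracle["mu"], rel=1e-6)
        assert vc.sigma_inter == pytest.approx(oracle["sigma_inter"], rel=1e-6)
        assert vc.sigma_volunteer == pytest.approx(
            oracle["sigma_volunteer"], rel=1e-6)
        assert vc.sigma_intra == pytest.approx(oracle["sigma_intra"], rel=1e-6)

    def test_zero_volunteer_effect_hits_boundary_and_reported_ne(self):
        """With no true volunteer effect the REML estimate collapses to the
        boundary (and is reported NE) in about half of the replicates --
        the expected boundary mass for a variance component whose truth is
        zero. A two-sided band excludes both 'never NE' and 'always NE'."""
        ne = 0
        n_rep = 20
        for seed in range(n_rep):
            design = balanced_design(n_vol=6, volunteer_sd=0.0, seed=seed)
            table, _ = generate_multicentre_study(design, seed=seed)
            vc = fit_variance_components(table, "ADC", "GM")
            ne += not vc.volunteer_estimable
        assert 5 <= ne <= 15

    def test_single_scanner_rejected(self):
        table = pd.DataFrame({
            "scanner": ["A"] * 4, "volunteer": ["V1", "V2"] * 2,
            "session": list("abcd"), "region": ["GM"] * 4,
            "metric": ["ADC"] * 4, "value": [1.0, 1.1, 0.9, 1.0],
        })
        with pytest.raises(StatsError, match="2 scanners"):
            fit_variance_components(table, "ADC", "GM")


class TestSubgroupsAndReport:
    def test_single_scanner_subgroup_flagged_others_computed(self):
        design = balanced_design(n_scanners=3, n_vol=4, seed=2)
        table, _ = generate_multicentre_study(design, seed=2)
        fs = {"S0": 1.5, "S1": 3.0, "S2": 3.0}  # only one 1.5T scanner
        res = subgroup_analysis(table, fs, "ADC", "GM")
        assert not res["1.5T"].valid
        assert res["3T"].valid and res["all"].valid

    def test_symmetric_field_strengths_similar_cv(self):
        """Identical effect sizes at both field strengths give subgroup
        CVs that agree within Monte-Carlo error (averaged over seeds)."""
        diffs = []
        for seed in range(10):
            design = balanced_design(n_scanners=8, n_vol=6, seed=seed)
            table, _ = generate_multicentre_study(design, seed=seed)
            fs = {s.scanner_id: s.field_strength for s in design.scanners}
            res = subgroup_analysis(table, fs, "ADC", "GM")
            diffs.append(res["1.5T"].cv_intra - res["3T"].cv_intra)
        # intra-scanner CV is the best-estimated component; its subgroup
        # difference averages to zero
        assert abs(np.mean(diffs)) < 3 * np.std(diffs, ddof=1) / np.sqrt(len(diffs)) + 0.3

    def test_report_layout_and_mdc(self):
        design = balanced_design(seed=3)
        table, _ = generate_multicentre_study(design, seed=3)
        res = analyse_metric_region(table, "ADC", "GM")
        report = summarize_report([res])
        row = report.iloc[0]
        assert list(report.columns[:7]) == [
            "metric", "region", "subgroup", "mean", "sd_inter",
            "sd_volunteer", "sd_intra",
        ]
        # minimum detectable change is twice the inter-scanner CV
        assert row["mdc_pct"] == pytest.approx(2 * round(res.cv_inter, 1), abs=0.11)

    def test_empty_report(self):
        assert len(summarize_report([])) == 0

    def test_ne_rendered(self):
        design = balanced_design(volunteer_sd=0.0, seed=11)
        table, _ = generate_multicentre_study(design, seed=11)
        res = analyse_metric_region(table, "ADC", "GM")
        if not res.volunteer_estimable:
            report = summarize_report([res])
            assert report.iloc[0]["cv_volunteer_pct"] == "NE"
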