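"""Heterogeneity, pleiotropy, outlier, directionality and influence checks."""
import numpy as np
import pytest

from mrkit.estimators import egger, ivw
from mrkit.sensitivity import (
    cochran_q,
    egger_intercept_test,
    full_report,
    i_squared,
    leave_one_out,
    mr_presso,
    steiger_filter,
)
from mrkit.simulate import SimConfig, generate
from mrkit.summary_io import harmonize

from .conftest import make_variant, random_variants


def sim_variants(**kw):
    exposure, outcome, _ = generate(SimConfig(**kw))
    return harmonize(exposure, outcome)


class TestCochranQ:
    def test_identical_ratios_give_zero(self):
        vs = [
            make_variant(f"rs{i}", beta_exp=bx, beta_out=0.5 * bx, se_out=0.02)
            for i, bx in enumerate([0.1, 0.2, 0.3])
        ]
        q, df, p = cochran_q(vs)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert df == 2
        assert p == 1.0

    def test_equals_weighted_rss_of_origin_fit(self, rng):
        """Ratio-form Q must equal the weighted residual sum of squares of
        the origin-constrained IVW fit."""
        vs = random_variants(rng, n=12)
        q, df, _ = cochran_q(vs)
        beta = ivw(vs, "fixed").beta
        w = 1.0 / np.array([v.se_out for v in vs]) ** 2
        bx = np.array([v.beta_exp for v in vs])
        by = np.array([v.beta_out for v in vs])
        rss = float(np.sum(w * (by - beta * bx) ** 2))
        assert q == pytest.approx(rss, rel=1e-10)
        assert df == len(vs) - 1

    def test_requires_two_variants(self):
        with pytest.raises(ValueError):
            cochran_q([make_variant()])


class TestISquared:
    @pytest.mark.parametrize("q,df,expected", [(13.13, 8, 39), (16.28, 9, 45)])
    def test_published_worked_values(self, q, df, expected):
        assert round(i_squared(q, df)) == expected

    def test_truncated_at_zero(self):
        assert i_squared(5.0, 9) == 0.0
        assert i_squared(0.0, 3) == 0.0

    def test_scale_invariance(self, rng):
        """Rescaling the outcome-effect units (beta_out and se_out together
        by c) leaves Q, and hence I^2, unchanged."""
        vs = random_variants(rng, n=8)
        scaled = [
            make_variant(v.rsid, v.beta_exp, v.se_exp, 3.0 * v.beta_out,
                         3.0 * v.se_out)
            for v in vs
        ]
        q1, df1, _ = cochran_q(vs)
        q2, df2, _ = cochran_q(scaled)
        assert q2 == pytest.approx(q1, rel=1e-10)
        assert i_squared(q2, df2) == pytest.approx(i_squared(q1, df1), rel=1e-10)


class TestEggerIntercept:
    def test_no_intercept_exact_fit_p_one(self):
        vs = [
            make_variant(f"rs{i}", beta_exp=bx, beta_out=0.5 * bx, se_out=0.02)
            for i, bx in enumerate([0.1, 0.2, 0.3, 0.4])
        ]
        assert egger_intercept_test(egger(vs)) == 1.0

    def test_order_invariance(self, rng):
        vs = random_variants(rng, n=10)
        shuffled = list(vs)
        rng.shuffle(shuffled)
        assert egger(shuffled).intercept == pytest.approx(
            egger(vs).intercept, rel=1e-10
        )

    def test_detects_directional_pleiotropy_majority(self):
        """Mean pleiotropic effect 0.05 at L = 30: intercept flagged in a
        majority of seeded replicates."""
        hits = sum(
            egger(sim_variants(n_snps=30, theta=0.25, pleiotropy_mode="directional",
                               pleiotropy_mean=0.05, seed=40_000 + s)).intercept_p
            < 0.05
            for s in range(200)
        )
        assert hits / 200 > 0.5

    def test_balanced_pleiotropy_interval_covers_zero(self):
        """Under balanced pleiotropy the intercept should lie within 2 SE of
        zero at roughly its nominal rate."""
        ok = sum(
            abs(e.intercept) <= 2.0 * e.intercept_se
            for e in (
                egger(sim_variants(n_snps=30, theta=0.25,
                                   pleiotropy_mode="balanced", seed=30_000 + s))
                for s in range(500)
            )
        )
        assert ok / 500 >= 0.92


class TestMrPresso:
    def null_variants(self, seed=1):
        return sim_variants(n_snps=20, theta=0.3, seed=seed)

    def test_null_global_p_not_significant(self):
        res = mr_presso(self.null_variants(seed=1), n_sim=2000, seed=1)
        assert res.global_p > 0.05
        assert res.outlier_indices == ()
        assert res.estimate_outliers_removed is None

    def test_planted_outlier_flagged(self):
        vs = sim_variants(n_snps=20, theta=0.3, outlier_indices=(7,),
                          outlier_shift=10.0, seed=5)
        res = mr_presso(vs, n_sim=2000, seed=5)
        assert 7 in res.outlier_indices
        assert res.global_p < 0.05
        assert res.estimate_outliers_removed is not None
        assert res.estimate_outliers_removed.nsnp == 20 - len(res.outlier_indices)

    def test_empirical_p_floor(self):
        vs = sim_variants(n_snps=10, theta=0.3, outlier_indices=(0, 5),
                          outlier_shift=30.0, seed=9)
        res = mr_presso(vs, n_sim=500, seed=9)
        assert res.global_p == pytest.approx(1 / 501)

    def test_null_global_p_calibration(self):
        """Fraction of global p < 0.05 over seeds 1..200 under the null."""
        low = sum(
            mr_presso(self.null_variants(seed=s), n_sim=1000, seed=s).global_p < 0.05
            for s in range(1, 201)
        )
        assert 0.01 <= low / 200 <= 0.10

    def test_requires_four_variants(self):
        with pytest.raises(ValueError, match="4"):
            mr_presso([make_variant(str(i)) for i in range(3)], n_sim=100, seed=0)


class TestSteiger:
    def test_dominant_exposure_signal(self):
        v = make_variant(beta_exp=0.2, se_exp=0.01, beta_out=0.002, se_out=0.01)
        table = steiger_filter([v], n_exp=20_000, n_out=30_000)
        assert bool(table.direction_ok[0])
        assert table.steiger_p[0] < 1e-10

    def test_tie_gives_p_one(self):
        v = make_variant(beta_exp=0.1, se_exp=0.02, beta_out=0.1, se_out=0.02)
        table = steiger_filter([v], n_exp=10_000, n_out=10_000)
        assert table.r2_exp[0] == pytest.approx(table.r2_out[0])
        assert table.steiger_p[0] == pytest.approx(1.0)
        assert not bool(table.direction_ok[0])

    def test_reverse_causation_scenario_flagged(self):
        """When variants act primarily on the outcome, the majority should
        fail the directionality check."""
        n_bad = n_tot = 0
        for s in range(20):
            vs = sim_variants(n_snps=20, theta=0.3, reverse_causation=True,
                              seed=60_000 + s)
            t = steiger_filter(vs, n_exp=18_340, n_out=33_970, case_fraction=0.197)
            n_bad += int((~t.direction_ok).sum())
            n_tot += len(t)
        assert n_bad / n_tot > 0.5

    def test_small_samples_fatal(self):
        with pytest.raises(ValueError):
            steiger_filter([make_variant()], n_exp=3, n_out=100)


class TestLeaveOneOut:
    def test_identical_variants_all_equal_full(self):
        vs = [make_variant(f"rs{i}") for i in range(5)]
        results = leave_one_out(vs)
        full = results[-1]
        assert full.label == "all"
        for r in results[:-1]:
            assert r.beta == pytest.approx(full.beta, rel=1e-12)

    def test_outlier_omission_moves_estimate_most(self, rng):
        vs = random_variants(rng, n=8)
        outlier = make_variant("rs_out", beta_exp=0.2, beta_out=0.5, se_out=0.02)
        vs = vs + [outlier]
        results = leave_one_out(vs)
        full_beta = results[-1].beta
        deltas = {r.label: abs(r.beta - full_beta) for r in results[:-1]}
        assert max(deltas, key=deltas.get) == "rs_out"

    def test_output_length(self):
        vs = [make_variant(f"rs{i}") for i in range(6)]
        assert len(leave_one_out(vs)) == 7


def test_full_report_bundles_everything():
    vs = sim_variants(n_snps=12, theta=0.2, seed=42)
    report = full_report(vs, n_exp=18_340, n_out=33_970, case_fraction=0.197,
                         n_sim=500, seed=42)
    assert report.df == 11
    assert 0 <= report.i2 < 100
    assert report.presso is not None
    assert len(report.loo) == 13
    assert len(report.steiger) == 12
    text = report.summary()
    assert "Cochran's Q" in text and "MR-PRESSO" in text
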