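"""Stratification, score-survival correlation and the Cox fit."""

import numpy as np
import pandas as pd
import pytest

from p53netval import (
    CoxResult,
    PatientRecord,
    correlate_scores_with_survival,
    cox_table,
    interpret_hr,
    stratify_patients,
    univariate_cox,
)


def _record(i, status="wt", chemo=False, days=100.0, event=True, stage=None):
    return PatientRecord(id=f"P{i:03d}", p53_status=status, chemo=chemo,
                         survival_days=days, event=event, stage=stage)


def grid_search_beta(x, time, event, lo=-12.0, hi=12.0, n=240001):
    """Brute-force maximizer of the Breslow partial likelihood on a grid."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    betas = np.linspace(lo, hi, n)
    w = np.exp(np.outer(betas, x))  # n_betas x n_subjects
    ll = np.zeros(n)
    for t in np.unique(time[event]):
        at_risk = time >= t
        d = event & (time == t)
        ll += betas * x[d].sum() - d.sum() * np.log(w[:, at_risk].sum(axis=1))
    return float(betas[np.argmax(ll)])


class TestStratifyPatients:
    def test_partition_by_status_and_chemo(self):
        records = [_record(1, "wt", True), _record(2, "wt", False),
                   _record(3, "mut", False)]
        groups = stratify_patients(records)
        sizes = {g: len(m) for g, m in groups.items()}
        assert sizes == {("wt", True): 1, ("wt", False): 1,
                         ("mut", True): 0, ("mut", False): 1}

    def test_empty_input_gives_four_empty_groups(self, caplog):
        groups = stratify_patients([])
        assert len(groups) == 4
        assert all(len(m) == 0 for m in groups.values())

    def test_emulated_cohort_composition(self):
        # 71 patients split 27 / 26 / 1 / 17 over (wt,T) (wt,UT) (mut,T) (mut,UT)
        records = []
        i = 0
        for (status, chemo), n in [(("wt", True), 27), (("wt", False), 26),
                                   (("mut", True), 1), (("mut", False), 17)]:
            for _ in range(n):
                records.append(_record(i, status, chemo))
                i += 1
        groups = stratify_patients(records)
        assert [len(groups[g]) for g in
                [("wt", True), ("wt", False), ("mut", True), ("mut", False)]] \
            == [27, 26, 1, 17]

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            stratify_patients([_record(1), _record(1)])


class TestPearsonCorrelation:
    def test_perfect_anticorrelation(self):
        records = [_record(i, days=d) for i, d in enumerate([3.0, 2.0, 1.0])]
        scores = pd.DataFrame({"g": [1.0, 2.0, 3.0]},
                              index=[r.id for r in records])
        out = correlate_scores_with_survival(scores, records)
        assert out.loc[0, "r"] == pytest.approx(-1.0)

    def test_independent_scores_have_small_r(self, rng):
        n = 1000
        records = [_record(i, days=float(t))
                   for i, t in enumerate(rng.exponential(300, n) + 1)]
        scores = pd.DataFrame({"g": rng.normal(size=n)},
                              index=[r.id for r in records])
        out = correlate_scores_with_survival(scores, records)
        assert abs(out.loc[0, "r"]) < 0.1

    def test_zero_variance_gene_skipped(self):
        records = [_record(i, days=d) for i, d in enumerate([10.0, 20.0, 30.0])]
        scores = pd.DataFrame({"flat": [5.0, 5.0, 5.0], "g": [1.0, 2.0, 3.0]},
                              index=[r.id for r in records])
        out = correlate_scores_with_survival(scores, records)
        assert list(out["gene"]) == ["g"]

    def test_invariant_to_positive_affine_rescaling(self, rng):
        n = 30
        records = [_record(i, days=float(t))
                   for i, t in enumerate(rng.exponential(300, n) + 1)]
        x = rng.normal(size=n)
        ids = [r.id for r in records]
        r1 = correlate_scores_with_survival(
            pd.DataFrame({"g": x}, index=ids), records).loc[0, "r"]
        r2 = correlate_scores_with_survival(
            pd.DataFrame({"g": 3.5 * x + 100}, index=ids), records).loc[0, "r"]
        assert r1 == pytest.approx(r2)

    def test_sorted_most_negative_first(self, rng):
        n = 40
        t = rng.exponential(300, n) + 1
        records = [_record(i, days=float(ti)) for i, ti in enumerate(t)]
        scores = pd.DataFrame(
            {"neg": -t + rng.normal(0, 10, n), "pos": t + rng.normal(0, 10, n)},
            index=[r.id for r in records],
        )
        out = correlate_scores_with_survival(scores, records)
        assert list(out["gene"]) == ["neg", "pos"]


class TestUnivariateCox:
    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            univariate_cox([1.0] * 6, [1, 2, 3, 4, 5, 6], [True] * 6)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            univariate_cox([1, 2, 3], [1, 2, 3], [False, False, False])

    def test_matches_grid_search_oracle_on_toy_cohorts(self, rng):
        for _ in range(5):
            n = 8
            x = rng.normal(size=n)
            time = rng.exponential(100, n) + 1  # continuous: no ties
            event = np.ones(n, bool)
            res = univariate_cox(x, time, event)
            oracle = grid_search_beta(x, time, event)
            assert res.beta == pytest.approx(oracle, abs=1e-3)

    def test_breslow_tied_events_match_grid_oracle(self):
        x = np.array([0.5, -1.0, 1.5, 0.0, -0.5, 1.0])
        time = np.array([5.0, 5.0, 8.0, 8.0, 12.0, 15.0])
        event = np.array([True, True, True, False, True, True])
        res = univariate_cox(x, time, event)
        assert res.beta == pytest.approx(grid_search_beta(x, time, event), abs=1e-3)

    def test_recovers_known_beta_with_censoring(self, rng):
        n, beta_true = 500, 0.5
        x = rng.normal(size=n)
        event_time = rng.exponential(1.0 / (0.01 * np.exp(beta_true * x)))
        censor_time = rng.exponential(1.0 / 0.0025, size=n)  # ~20% censoring
        time = np.minimum(event_time, censor_time)
        event = event_time <= censor_time
        res = univariate_cox(x, time, event)
        assert res.beta == pytest.approx(beta_true, abs=0.15)
        assert res.ci_low < res.hr < res.ci_high

    def test_agrees_with_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        n = 80
        x = rng.normal(size=n)
        time = rng.exponential(1.0 / (0.01 * np.exp(0.4 * x)))
        event = rng.random(n) > 0.2
        if event.sum() < 2:
            event[:] = True
        res = univariate_cox(x, time, event)
        cph = lifelines.CoxPHFitter()
        cph.fit(pd.DataFrame({"x": x, "T": time, "E": event.astype(int)}),
                duration_col="T", event_col="E")
        assert res.beta == pytest.approx(cph.params_["x"], abs=1e-4)
        assert res.wald_p == pytest.approx(cph.summary.loc["x", "p"], abs=1e-4)

    def test_mean_bias_small_over_replicate_cohorts(self, rng):
        betas = []
        for _ in range(100):
            n, beta_true = 200, 0.4
            x = rng.normal(size=n)
            t = rng.exponential(1.0 / (0.01 * np.exp(beta_true * x)))
            betas.append(univariate_cox(x, t, np.ones(n, bool)).beta)
        assert abs(np.mean(betas) - 0.4) < 0.05

    def test_survival_decreasing_covariate_has_positive_beta(self, rng):
        # higher score -> higher hazard -> shorter survival: HR > 1,
        # pairing with a negative Pearson correlation against time
        n = 300
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.01 * np.exp(0.8 * x)))
        res = univariate_cox(x, t, np.ones(n, bool))
        assert res.beta > 0 and res.hr > 1
        assert np.corrcoef(x, t)[0, 1] < 0

    def test_separation_raises_named_error(self):
        x = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        time = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        with pytest.raises(RuntimeError, match="monotone|separation"):
            univariate_cox(-x, time, np.ones(6, bool))


class TestInterpretation:
    @pytest.mark.parametrize("hr, label", [
        (0.97, "good prognostic factor"),
        (1.0, "no effect"),
        (1.59, "bad prognostic factor"),
    ])
    def test_hazard_ratio_reading(self, hr, label):
        res = CoxResult(gene="g", beta=np.log(hr), hr=hr,
                        ci_low=hr * 0.8, ci_high=hr * 1.2, wald_p=0.05)
        assert interpret_hr(res) == label


def test_cox_table_skips_failing_genes(rng):
    n = 50
    records = [_record(i, days=float(t), event=True)
               for i, t in enumerate(rng.exponential(300, n) + 1)]
    scores = pd.DataFrame(
        {"ok": rng.normal(size=n), "flat": np.full(n, 2.0)},
        index=[r.id for r in records],
    )
    out = cox_table(scores, records)
    assert list(out["gene"]) == ["ok"]
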