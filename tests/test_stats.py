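"""Partial correlations, Fisher-z intervals, FDR, and mediation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from morphoconn import (
    fdr_bh,
    fisher_ci,
    mediate,
    partial_correlation,
    run_association_scan,
    spearman_partial,
)
from morphoconn.mc import MCProfile


def _precision_matrix_partial_r(x, y, cov):
    """Oracle: partial correlation from the inverse correlation matrix."""
    data = np.column_stack([x, y, cov])
    prec = np.linalg.inv(np.corrcoef(data.T))
    return -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])


class TestPartialCorrelation:
    def test_reduces_to_pearson_without_covariates(self, rng):
        x, y = rng.standard_normal((2, 30))
        r, p, n = partial_correlation(x, y)
        ref = sps.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)
        assert n == 30

    def test_perfect_correlation(self, rng):
        x = rng.standard_normal(24)
        r, p, _ = partial_correlation(x, x)
        assert r == 1.0 and p == 0.0

    def test_matches_precision_matrix_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            x, y = rng.standard_normal((2, 24))
            cov = rng.standard_normal((24, 2))
            r, _, _ = partial_correlation(x, y, cov)
            assert r == pytest.approx(_precision_matrix_partial_r(x, y, cov), abs=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x, y = rng.standard_normal((2, 24))
        cov = rng.standard_normal((24, 2))
        df = pd.DataFrame({"x": x, "y": y, "c1": cov[:, 0], "c2": cov[:, 1]})
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        r, p, _ = partial_correlation(x, y, cov)
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_rank_deficient_covariates_rejected(self, rng):
        x, y = rng.standard_normal((2, 24))
        c = rng.standard_normal(24)
        with pytest.raises(ValueError, match="rank"):
            partial_correlation(x, y, np.column_stack([c, 2 * c]))

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match="few"):
            partial_correlation(
                rng.standard_normal(5), rng.standard_normal(5), rng.standard_normal((5, 2))
            )

    def test_covariate_coding_invariance(self, rng):
        # recoding a binary covariate (0/1 -> 1/2) cannot move partial r
        x, y = rng.standard_normal((2, 24))
        sex = rng.integers(0, 2, 24).astype(float)
        r0, _, _ = partial_correlation(x, y, sex)
        r1, _, _ = partial_correlation(x, y, sex + 1.0)
        assert r0 == pytest.approx(r1, abs=1e-12)


class TestFisherCi:
    @pytest.mark.parametrize(
        "r, lo, hi",
        [
            (0.64, 0.32, 0.83),
            (-0.59, -0.80, -0.24),
            (0.53, 0.16, 0.77),
            (-0.49, -0.75, -0.11),
            (0.34, -0.07, 0.65),
        ],
    )
    def test_n24_intervals_at_two_decimals(self, r, lo, hi):
        lo_hat, hi_hat, se_z = fisher_ci(r, 24)
        assert round(lo_hat, 2) == lo
        assert round(hi_hat, 2) == hi
        assert se_z == pytest.approx(1 / np.sqrt(21), rel=1e-12)

    def test_symmetric_about_zero(self):
        lo, hi, _ = fisher_ci(0.0, 24)
        assert lo == pytest.approx(-hi, abs=1e-12)

    def test_boundary_r_rejected(self):
        with pytest.raises(ValueError):
            fisher_ci(1.0, 24)


class TestSpearmanPartial:
    def test_monotone_transform_invariance(self, rng):
        x = rng.random(30)
        y = rng.random(30)
        rho1, _ = spearman_partial(x, y)
        rho2, _ = spearman_partial(np.exp(5 * x), y)
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_identity(self, rng):
        x = rng.random(24)
        rho, _ = spearman_partial(x, x.copy())
        assert rho == pytest.approx(1.0)

    def test_matches_ranked_residual_brute_force(self, rng):
        x, y = rng.standard_normal((2, 24))
        cov = rng.standard_normal((24, 2))
        rho, _ = spearman_partial(x, y, cov)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        X = np.column_stack([np.ones(24), cov])
        res_x = rx - X @ np.linalg.lstsq(X, rx, rcond=None)[0]
        res_y = ry - X @ np.linalg.lstsq(X, ry, rcond=None)[0]
        assert rho == pytest.approx(
            float(res_x @ res_y) / np.sqrt((res_x @ res_x) * (res_y @ res_y)), abs=1e-10
        )


def _bh_oracle(pvals, alpha):
    """Textbook step-up definition, enumerated directly."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, bool)
    k_max = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= alpha * k / m:
            k_max = k
    reject[order[:k_max]] = True
    q = np.empty(m)
    running = 1.0
    for k in range(m, 0, -1):
        running = min(running, m * p[order[k - 1]] / k)
        q[order[k - 1]] = running
    return q, reject


class TestFdrBh:
    def test_two_small_p_among_22_rejected(self):
        pvals = np.array([0.001, 0.004] + [0.5] * 20)
        q_oracle, rej_oracle = _bh_oracle(pvals, 0.05)
        q, rej = fdr_bh(pvals)
        assert rej[0] and rej[1] and rej.sum() == 2
        np.testing.assert_array_equal(rej, rej_oracle)
        np.testing.assert_allclose(q, q_oracle, atol=1e-12)

    def test_all_ones_no_rejections(self):
        _, rej = fdr_bh(np.ones(10))
        assert not rej.any()

    def test_single_p_reduction(self):
        q, rej = fdr_bh(np.array([0.04]))
        assert q[0] == pytest.approx(0.04) and rej[0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([0.1, 1.3]))

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8))
    def test_matches_brute_force_enumeration(self, pvals):
        q, rej = fdr_bh(np.array(pvals))
        q_oracle, rej_oracle = _bh_oracle(pvals, 0.05)
        np.testing.assert_allclose(q, q_oracle, atol=1e-12)
        np.testing.assert_array_equal(rej, rej_oracle)


class TestMediate:
    def test_ols_identity_with_covariates(self, rng):
        x, m, y = rng.standard_normal((3, 24))
        cov = rng.standard_normal((24, 2))
        res = mediate(x, m, y, cov, n_boot=1000, rng_seed=1)
        assert res.c == pytest.approx(res.c_prime + res.indirect, abs=1e-10)

    def test_degenerate_identity_case(self):
        x = np.arange(24.0)
        res = mediate(x, x.copy(), x.copy(), n_boot=1000, rng_seed=0)
        assert res.c == pytest.approx(1.0, abs=1e-9)
        assert res.c == pytest.approx(res.c_prime + res.indirect, abs=1e-10)

    def test_null_mediator_gives_null_indirect(self, rng):
        x = rng.standard_normal(40)
        y = 0.5 * x + 0.5 * rng.standard_normal(40)
        m = rng.standard_normal(40)  # unrelated to both
        res = mediate(x, m, y, n_boot=2000, rng_seed=2)
        lo, hi = res.boot_ci95
        assert lo < 0 < hi
        assert abs(res.indirect) < 0.3

    def test_full_mediation_recovered(self):
        # planted chain x -> m -> y with no direct path, n = 24: the direct
        # estimate stays small and the indirect CI excludes zero in >= 80%
        # of replications (pre-calibrated by simulation)
        ok = 0
        for seed in range(25):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(24)
            m = 0.8 * x + 0.4 * rng.standard_normal(24)
            y = 0.8 * m + 0.4 * rng.standard_normal(24)
            res = mediate(x, m, y, n_boot=1000, rng_seed=seed)
            lo, hi = res.boot_ci95
            if abs(res.c_prime) < 0.35 and (lo > 0 or hi < 0):
                ok += 1
        assert ok >= 20

    def test_bootstrap_seeded_and_reproducible(self, rng):
        x, m, y = rng.standard_normal((3, 24))
        r1 = mediate(x, m, y, n_boot=1000, rng_seed=5)
        r2 = mediate(x, m, y, n_boot=1000, rng_seed=5)
        assert r1.boot_ci95 == r2.boot_ci95

    def test_small_n_boot_rejected(self, rng):
        x, m, y = rng.standard_normal((3, 24))
        with pytest.raises(ValueError, match="n_boot"):
            mediate(x, m, y, n_boot=100, rng_seed=0)


def _toy_profiles(rng, n_subj, targets=(2, 3), hemi="L"):
    profs = []
    for i in range(n_subj):
        entries = {t: float(rng.uniform(0.2, 0.9)) for t in targets}
        profs.append(MCProfile(f"s{i:02d}", hemi, 1, entries))
    return profs


def _behavior(rng, ids):
    n = len(ids)
    return pd.DataFrame(
        {
            "subject_id": ids,
            "bis_total": rng.integers(45, 90, n),
            "bis_attentional": rng.integers(10, 30, n),
            "bis_motor": rng.integers(10, 30, n),
            "bis_nonplanning": rng.integers(10, 30, n),
            "age": rng.integers(18, 34, n),
            "sex": rng.integers(0, 2, n),
        }
    )


class TestAssociationScan:
    def test_subject_order_irrelevant(self, rng):
        profs = _toy_profiles(rng, 12)
        beh = _behavior(rng, [p.subject_id for p in profs])
        res1 = run_association_scan(profs, beh)
        res2 = run_association_scan(profs[::-1], beh.sample(frac=1, random_state=0))
        for a, b in zip(res1, res2):
            assert (a.target_roi, a.r, a.p, a.q) == (b.target_roi, b.r, b.p, b.q)

    def test_id_mismatch_lists_offenders(self, rng):
        profs = _toy_profiles(rng, 10)
        beh = _behavior(rng, [p.subject_id for p in profs[:-1]] + ["ghost"])
        with pytest.raises(ValueError, match="s09"):
            run_association_scan(profs, beh)

    def test_q_at_least_p(self, rng):
        profs = _toy_profiles(rng, 14, targets=(2, 3, 4, 5))
        beh = _behavior(rng, [p.subject_id for p in profs])
        for res in run_association_scan(profs, beh):
            assert res.q >= res.p - 1e-15
            assert res.ci95[0] < res.r < res.ci95[1]

    def test_pooled_fdr_scope(self, rng):
        profs = _toy_profiles(rng, 14) + _toy_profiles(rng, 14, hemi="R")
        beh = _behavior(rng, sorted({p.subject_id for p in profs}))
        pooled = run_association_scan(profs, beh, fdr_scope="pooled")
        assert len(pooled) == 4

    def test_planted_coupling_attains_extreme_r(self):
        # strong planted coupling puts the coupled pair at the scan's extreme
        # |r| in the right hemisphere in >= 9/10 cohorts
        from morphoconn import CohortSpec, compute_mc_profile, generate_cohort

        hits = 0
        for seed in range(10):
            spec = CohortSpec(
                n_subjects=24, grid_shape=(16, 16, 16), n_rois=5, coupled_roi=3,
                coupling_strength=0.9, noise_sd=0.2, rng_seed=seed,
            )
            volumes, parc, behavior, truth = generate_cohort(spec)
            profs = []
            for vol in volumes:
                profs.extend(compute_mc_profile(vol, parc))
            scan = [r for r in run_association_scan(profs, behavior) if r.hemisphere == "R"]
            best = max(scan, key=lambda r: abs(r.r))
            hits += best.target_roi == truth.coupled_pair[1]
        assert hits >= 9
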