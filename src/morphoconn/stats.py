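"""Brain-behavior association statistics.

Partial Pearson/Spearman correlations with covariate adjustment, Fisher-z
standard errors and confidence intervals, Benjamini-Hochberg FDR across a
family of connections, and single-mediator mediation analysis with a
percentile bootstrap for the indirect effect.

Conventions
-----------
* Partial correlation residualizes both variables on an intercept plus the
  covariates by least squares and correlates the residuals; the t statistic
  uses ``n - 2 - k`` degrees of freedom, k = number of covariates.
* Confidence intervals for r are built on the Fisher z scale with
  ``se_z = 1 / sqrt(n - 3)`` where n is the total number of subjects (the
  convention of the classic CIr-style interval), then back-transformed.
* FDR is Benjamini-Hochberg step-up, by default applied within hemisphere.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .mc import MCProfile

logger = logging.getLogger(__name__)

REQUIRED_BEHAVIOR_COLUMNS = (
    "subject_id",
    "bis_total",
    "bis_attentional",
    "bis_motor",
    "bis_nonplanning",
    "age",
    "sex",
)
SUBSCALE_COLUMNS = ("bis_attentional", "bis_motor", "bis_nonplanning")


@dataclass
class AssociationResult:
    """Partial-correlation statistics for one seed-target connection."""

    target_roi: int
    hemisphere: str
    r: float
    p: float
    se_z: float
    ci95: tuple[float, float]
    rho: float
    rho_p: float
    q: float = float("nan")
    n: int = 0
    covariates: tuple[str, ...] = ()
    target_name: str = ""


@dataclass
class MediationResult:
    """Single-mediator OLS mediation with percentile-bootstrap indirect CI.

    Paths are standardized regression coefficients after covariate
    residualization: a (X->M), b (M->Y given X), c (total X->Y), c_prime
    (direct X->Y given M); indirect = a*b.  In linear OLS with identical
    covariate sets, c = c_prime + a*b holds to numerical precision.
    """

    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    boot_ci95: tuple[float, float]
    n_boot: int
    rng_seed: int
    p_c: float
    p_c_prime: float
    sobel_p: float
    full_mediation: bool
    n_redrawn: int = 0
    mediator: str = ""
    covariates: tuple[str, ...] = field(default_factory=tuple)


def _design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None or covariates.size == 0:
        return np.ones((n, 1))
    cov = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
    if cov.shape[0] != n:
        cov = cov.T
    if cov.shape[0] != n:
        raise ValueError("covariate matrix does not match sample size")
    X = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariate matrix (with intercept)")
    return X


def _residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float, int]:
    """Partial Pearson correlation of x and y given covariates.

    Residualizes x and y on [intercept | covariates], correlates the
    residuals, and tests with ``t = r * sqrt((n - 2 - k) / (1 - r**2))``
    (two-sided).  With no covariates this reduces to the plain Pearson
    correlation and test.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    X = _design(covariates, n)
    k = X.shape[1] - 1
    if n <= k + 3:
        raise ValueError(f"too few subjects (n={n}) for {k} covariates")
    rx = _residualize(x, X)
    ry = _residualize(y, X)
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0.0:
        raise ValueError("zero-variance residuals; correlation undefined")
    r = float(rx @ ry) / denom
    r = max(min(r, 1.0), -1.0)
    df = n - 2 - k
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * math.sqrt(df / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), df)
    return r, float(p), n


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float, float]:
    """Fisher-z confidence interval for a correlation coefficient.

    ``z = atanh(r)``, ``se_z = 1/sqrt(n - 3)``; bounds are
    ``tanh(z +/- z_crit * se_z)``.  Returns (lo, hi, se_z).  n is the total
    number of subjects regardless of how many covariates were partialled out.
    """
    if not -1.0 < r < 1.0:
        raise ValueError("|r| must be strictly less than 1 for a Fisher-z CI")
    if n <= 3:
        raise ValueError("need n > 3 for a Fisher-z interval")
    z = math.atanh(r)
    se_z = 1.0 / math.sqrt(n - 3)
    z_crit = float(sps.norm.ppf(0.5 + level / 2.0))
    lo = math.tanh(z - z_crit * se_z)
    hi = math.tanh(z + z_crit * se_z)
    return lo, hi, se_z


def spearman_partial(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Partial Spearman correlation: rank x and y (average ranks for ties),
    then run the partial Pearson machinery on the ranks."""
    rx = sps.rankdata(np.asarray(x, dtype=np.float64).ravel())
    ry = sps.rankdata(np.asarray(y, dtype=np.float64).ravel())
    rho, p, _ = partial_correlation(rx, ry, covariates)
    return rho, p


def fdr_bh(pvals: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR: returns (q-values, reject flags)."""
    p = np.asarray(pvals, dtype=np.float64).ravel()
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def mediate(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    n_boot: int = 5000,
    rng_seed: int = 0,
    alpha: float = 0.05,
) -> MediationResult:
    """Single-mediator mediation analysis with percentile bootstrap.

    All variables are residualized on [intercept | covariates] and z-scored;
    then a is the OLS slope of M~X, b and c' come from Y~X+M, c from Y~X, and
    the indirect effect is a*b.  The bootstrap resamples subjects (rows of
    the raw data, covariates included) and repeats the whole procedure;
    resamples with a constant column are redrawn and counted.  "Full
    mediation" = c significant, c' not, and the bootstrap CI for a*b
    excluding zero.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    m = np.asarray(m, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    n = x.size
    if not (m.size == n and y.size == n):
        raise ValueError("x, m, y must have equal length")
    if n_boot < 1000:
        raise ValueError("n_boot must be at least 1000 for a stable CI")
    cov = None
    if covariates is not None and np.asarray(covariates).size:
        cov = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
        if cov.shape[0] != n:
            cov = cov.T

    def paths(xi, mi, yi, ci):
        X = _design(ci, xi.size)
        zs = []
        for v in (xi, mi, yi):
            res = _residualize(v, X)
            sd = res.std(ddof=1)
            if sd <= 1e-12:
                raise ValueError("constant column")
            zs.append(res / sd)
        zx, zm, zy = zs
        a = float(np.linalg.lstsq(np.column_stack([np.ones(n_i := xi.size), zx]), zm, rcond=None)[0][1])
        bm = np.linalg.lstsq(np.column_stack([np.ones(n_i), zx, zm]), zy, rcond=None)[0]
        c_prime, b = float(bm[1]), float(bm[2])
        c = float(np.linalg.lstsq(np.column_stack([np.ones(n_i), zx]), zy, rcond=None)[0][1])
        return a, b, c, c_prime

    a, b, c, c_prime = paths(x, m, y, cov)
    indirect = a * b

    zx, zm, zy = _standard(x, cov), _standard(m, cov), _standard(y, cov)
    _, p_c, _ = partial_correlation(x, y, cov)
    # direct-path p from the multiple regression t test (mediator included)
    p_c_prime = _ols_slope_p(zy, np.column_stack([np.ones(n), zx, zm]), 1)

    # Sobel normal-theory test (secondary to the bootstrap)
    se_a = _ols_slope_se(zm, np.column_stack([np.ones(n), zx]), 1)
    se_b = _ols_slope_se(zy, np.column_stack([np.ones(n), zx, zm]), 2)
    sobel_se = math.sqrt(a * a * se_b * se_b + b * b * se_a * se_a)
    sobel_p = 2.0 * sps.norm.sf(abs(indirect) / sobel_se) if sobel_se > 0 else 1.0

    rng = np.random.default_rng(rng_seed)
    boots = np.empty(n_boot)
    n_redrawn = 0
    i = 0
    while i < n_boot:
        idx = rng.integers(0, n, size=n)
        try:
            ab, bb, _, _ = paths(x[idx], m[idx], y[idx], None if cov is None else cov[idx])
        except (ValueError, np.linalg.LinAlgError):
            n_redrawn += 1
            if n_redrawn > 100 * n_boot:
                raise RuntimeError("bootstrap cannot find non-degenerate resamples")
            continue
        boots[i] = ab * bb
        i += 1
    if n_redrawn:
        logger.info("mediation bootstrap redrew %d degenerate resamples", n_redrawn)
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    ci_excludes_zero = (lo > 0) or (hi < 0)
    full = (p_c < alpha) and (p_c_prime >= alpha) and ci_excludes_zero
    return MediationResult(
        a=a, b=b, c=c, c_prime=c_prime, indirect=indirect,
        boot_ci95=(float(lo), float(hi)), n_boot=n_boot, rng_seed=rng_seed,
        p_c=p_c, p_c_prime=p_c_prime, sobel_p=float(sobel_p),
        full_mediation=bool(full), n_redrawn=n_redrawn,
    )


def _standard(v: np.ndarray, cov: np.ndarray | None) -> np.ndarray:
    X = _design(cov, v.size)
    res = _residualize(np.asarray(v, dtype=np.float64).ravel(), X)
    return res / res.std(ddof=1)


def _ols_fit(y: np.ndarray, X: np.ndarray):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = y.size - X.shape[1]
    sigma2 = float(resid @ resid) / max(df, 1)
    # pinv tolerates perfectly collinear designs (e.g. mediator == predictor)
    cov_beta = sigma2 * np.linalg.pinv(X.T @ X)
    return beta, cov_beta, df


def _ols_slope_se(y: np.ndarray, X: np.ndarray, j: int) -> float:
    _, cov_beta, _ = _ols_fit(y, X)
    return math.sqrt(max(cov_beta[j, j], 0.0))


def _ols_slope_p(y: np.ndarray, X: np.ndarray, j: int) -> float:
    beta, cov_beta, df = _ols_fit(y, X)
    se = math.sqrt(max(cov_beta[j, j], 0.0))
    if se == 0.0:
        return 1.0 if beta[j] == 0.0 else 0.0
    t = beta[j] / se
    return float(2.0 * sps.t.sf(abs(t), max(df, 1)))


def run_association_scan(
    profiles: list[MCProfile],
    behavior: pd.DataFrame,
    outcome: str = "bis_total",
    covariate_columns: tuple[str, ...] = ("age", "sex"),
    alpha: float = 0.05,
    fdr_scope: str = "hemisphere",
    roi_names: dict[int, str] | None = None,
) -> list[AssociationResult]:
    """Partial-correlation scan of every seed-target MC against a behavior.

    Subjects are matched to behavior rows by ``subject_id`` (order-free);
    missing or extra ids raise with the offenders listed.  One result per
    target ROI per hemisphere; FDR (Benjamini-Hochberg) is applied within
    each hemisphere's family of targets by default, or pooled across both
    with ``fdr_scope='pooled'``.  Results are sorted by (hemisphere, target).
    """
    if fdr_scope not in ("hemisphere", "pooled"):
        raise ValueError("fdr_scope must be 'hemisphere' or 'pooled'")
    for col in (outcome, *covariate_columns, "subject_id"):
        if col not in behavior.columns:
            raise ValueError(f"behavior table lacks column {col!r}")
    used = [outcome, *covariate_columns]
    if behavior[used].isna().any().any():
        raise ValueError(f"missing values in behavior columns {used}")

    beh = behavior.set_index(behavior["subject_id"].astype(str))
    profile_ids = sorted({p.subject_id for p in profiles})
    missing = [sid for sid in profile_ids if sid not in beh.index]
    extra = [sid for sid in beh.index if sid not in set(profile_ids)]
    if missing or extra:
        raise ValueError(
            f"subject id mismatch; profiles without behavior: {missing}; "
            f"behavior without profiles: {extra}"
        )

    by_hemi: dict[str, dict[str, MCProfile]] = {}
    for prof in profiles:
        by_hemi.setdefault(prof.hemisphere, {})[prof.subject_id] = prof

    y = beh.loc[profile_ids, outcome].to_numpy(dtype=float)
    cov = (
        beh.loc[profile_ids, list(covariate_columns)].to_numpy(dtype=float)
        if covariate_columns
        else None
    )

    results: list[AssociationResult] = []
    for hemi in sorted(by_hemi):
        subj_profiles = by_hemi[hemi]
        absent = [sid for sid in profile_ids if sid not in subj_profiles]
        if absent:
            raise ValueError(f"hemisphere {hemi!r}: profiles missing for {absent}")
        targets = sorted(next(iter(subj_profiles.values())).entries)
        hemi_results = []
        for target in targets:
            mc = np.array([subj_profiles[sid].entries[target] for sid in profile_ids])
            r, p, n = partial_correlation(mc, y, cov)
            lo, hi, se_z = fisher_ci(r, n)
            rho, rho_p = spearman_partial(mc, y, cov)
            hemi_results.append(
                AssociationResult(
                    target_roi=target,
                    hemisphere=hemi,
                    r=r, p=p, se_z=se_z, ci95=(lo, hi),
                    rho=rho, rho_p=rho_p, n=n,
                    covariates=tuple(covariate_columns),
                    target_name=(roi_names or {}).get(target, ""),
                )
            )
        if fdr_scope == "hemisphere":
            q, _ = fdr_bh(np.array([res.p for res in hemi_results]), alpha)
            for res, qv in zip(hemi_results, q):
                res.q = float(qv)
        results.extend(hemi_results)

    if fdr_scope == "pooled":
        q, _ = fdr_bh(np.array([res.p for res in results]), alpha)
        for res, qv in zip(results, q):
            res.q = float(qv)
    return results


def associations_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Association table with full-precision floats plus 2-dp display columns."""
    rows = []
    for res in results:
        rows.append(
            {
                "roi": res.target_roi,
                "roi_name": res.target_name,
                "hemisphere": res.hemisphere,
                "r": res.r,
                "p": res.p,
                "se_z": res.se_z,
                "ci_lo": res.ci95[0],
                "ci_hi": res.ci95[1],
                "rho": res.rho,
                "rho_p": res.rho_p,
                "q": res.q,
                "n": res.n,
                "r_2dp": round(res.r, 2),
                "ci_2dp": f"[{res.ci95[0]:.2f}, {res.ci95[1]:.2f}]",
            }
        )
    return pd.DataFrame(rows)
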