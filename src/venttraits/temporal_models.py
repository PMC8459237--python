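"""Quadratic-in-time trend models with randomization inference.

Modality and guild composition is modelled by multinomial logistic regression:
counts at each time point are multinomial, and the log ratio of each
category's relative abundance to a baseline category is quadratic in time,

    log(p_k(t) / p_b(t)) = b0_k + b1_k t + b2_k t^2 .

The model is fit by maximum likelihood (Newton iterations on a centered and
scaled time design, coefficients reported back on the month scale).
Significance is assessed by randomization rather than the multinomial
likelihood-ratio test, because counts on the same surface are not independent
individuals: the sample-to-time assignment is permuted (observation times held
fixed), counts are re-pooled and the model refit, and the strict P-value is
the proportion of randomizations whose deviance falls below the observed
deviance. Diversity indices are fit by OLS on time and time squared, with an
analogous randomization of R^2.

Two tie rules are provided: ``strict`` (the proportion rule above, which can
return 0 under degenerate ties) and the default ``smoothed`` add-one rule
p = (1 + #{null >= as extreme}) / (1 + n_rand).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .trait_data import AbundanceTable, DataError, TraitTable, TraitSpec, \
    per_sample_modality_counts

logger = logging.getLogger("venttraits")

#: default number of randomizations
N_RAND_DEFAULT = 1000

#: Newton convergence: infinity-norm of the score
GRAD_TOL = 1e-8
MAX_ITER = 80
RIDGE = 1e-8


# ---------------------------------------------------------------------------
# Multinomial logistic regression, quadratic in time
# ---------------------------------------------------------------------------


@dataclass
class MultinomialFit:
    """Maximum-likelihood multinomial logit fit with a quadratic time design."""

    categories: list
    baseline: object
    beta: pd.DataFrame  # index: categories, columns: b0, b1, b2 (month scale)
    loglik: float
    deviance: float  # 2 * (loglik_saturated - loglik)
    fitted: pd.DataFrame  # index: times, columns: categories, probabilities
    times: np.ndarray
    converged: bool
    n_iter: int
    grad_norm: float

    def predict(self, times) -> pd.DataFrame:
        """Fitted category probabilities at arbitrary times (month scale)."""
        t = np.asarray(times, dtype=float)
        X = np.column_stack([np.ones_like(t), t, t * t])
        eta = X @ self.beta.to_numpy().T  # len(t) x K
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        p /= p.sum(axis=1, keepdims=True)
        return pd.DataFrame(p, index=t, columns=self.categories)


def _saturated_loglik(counts: np.ndarray) -> float:
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = counts * np.log(np.where(counts > 0, counts / totals, 1.0))
    return float(term.sum())


def _newton_multinomial(counts: np.ndarray, X: np.ndarray, baseline: int):
    """Newton maximization of the multinomial log-likelihood.

    counts: T x K, X: T x 3 design (centered/scaled time), baseline: column
    index with coefficients pinned at zero. Returns (gamma (K x 3 with zero
    baseline row), loglik, converged, n_iter, grad_norm).
    """
    T, K = counts.shape
    nx = X.shape[1]
    free = [k for k in range(K) if k != baseline]
    nf = len(free)
    totals = counts.sum(axis=1)
    gamma = np.zeros((K, nx))
    tol = GRAD_TOL * max(1.0, totals.sum())  # score scales with total count

    def probs(g):
        eta = X @ g.T
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def loglik(g):
        p = probs(g)
        with np.errstate(divide="ignore"):
            lp = np.log(p)
        return float(np.where(counts > 0, counts * lp, 0.0).sum())

    ll = loglik(gamma)
    grad_norm = np.inf
    for it in range(1, MAX_ITER + 1):
        p = probs(gamma)
        resid = counts[:, free] - totals[:, None] * p[:, free]  # T x nf
        g_vec = (resid.T @ X).ravel()  # nf*3 score vector
        grad_norm = float(np.abs(g_vec).max())
        if grad_norm < tol:
            return gamma, ll, True, it - 1, grad_norm
        # observed information: block (a,b) = sum_t N_t (p_a d_ab - p_a p_b) x x'
        pf = p[:, free]
        W = totals[:, None, None] * (
            np.einsum("ta,ab->tab", pf, np.eye(nf))
            - np.einsum("ta,tb->tab", pf, pf))
        H = np.einsum("tab,ti,tj->aibj", W, X, X).reshape(nf * nx, nf * nx)
        step = None
        ridge = 0.0
        for _ in range(6):
            try:
                step = np.linalg.solve(H + ridge * np.eye(nf * nx), g_vec)
                break
            except np.linalg.LinAlgError:
                ridge = RIDGE if ridge == 0 else ridge * 100
        if step is None:
            break
        new = gamma.copy()
        scale = 1.0
        for _ in range(25):  # step halving
            new[free] = gamma[free] + scale * step.reshape(nf, nx)
            ll_new = loglik(new)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        if ll_new < ll - 1e-9:  # no improving step found
            break
        improved = ll_new - ll
        gamma, ll = new, ll_new
        if improved < 1e-13 * max(1.0, abs(ll)) and grad_norm < 1e-4:
            # flat likelihood with tiny residual score: quasi-separation
            break
    return gamma, ll, grad_norm < tol, it, grad_norm


def fit_multinomial(counts, times, baseline=None) -> MultinomialFit:
    """Fit the quadratic-in-time multinomial logit to (time x category) counts.

    ``baseline`` defaults to the most abundant category overall; fitted
    probabilities and the deviance do not depend on this choice. Times must
    include at least three distinct values, otherwise the quadratic is
    unidentifiable.
    """
    if isinstance(counts, pd.DataFrame):
        categories = list(counts.columns)
        C = counts.to_numpy(dtype=float)
    else:
        C = np.asarray(counts, dtype=float)
        categories = list(range(C.shape[1]))
    t = np.asarray(times, dtype=float)
    if C.ndim != 2 or len(t) != C.shape[0]:
        raise DataError("counts must be (time x category) aligned with times")
    if C.shape[1] < 2:
        raise DataError("need at least 2 categories")
    if len(np.unique(t)) < 3:
        raise DataError("need >=3 distinct times for a quadratic model")
    if (C < 0).any():
        raise DataError("negative counts")

    totals_by_cat = C.sum(axis=0)
    empty = [c for c, tot in zip(categories, totals_by_cat) if tot == 0]
    if empty:
        warnings.warn(f"dropping categories empty at all times: {empty}")
        keep = totals_by_cat > 0
        C = C[:, keep]
        categories = [c for c, k in zip(categories, keep) if k]
        if C.shape[1] < 2:
            raise DataError("fewer than 2 non-empty categories")

    if baseline is None:
        b = int(np.argmax(C.sum(axis=0)))
    else:
        b = categories.index(baseline)

    mu, sd = t.mean(), t.std()
    sd = sd if sd > 0 else 1.0
    z = (t - mu) / sd
    X = np.column_stack([np.ones_like(z), z, z * z])

    gamma, ll, converged, n_iter, grad_norm = _newton_multinomial(C, X, b)
    if not converged:
        one_time = [categories[k] for k in range(len(categories))
                    if (C[:, k] > 0).sum() == 1]
        msg = ("multinomial fit did not reach gradient tolerance "
               f"(|grad|={grad_norm:.2e} after {n_iter} iterations)")
        if one_time:
            msg += (f"; possible separation: categories non-zero at a single "
                    f"time: {one_time}")
        logger.warning(msg)

    # back-transform z-scale gamma to month-scale beta
    g0, g1, g2 = gamma[:, 0], gamma[:, 1], gamma[:, 2]
    beta = np.column_stack([
        g0 - g1 * mu / sd + g2 * mu * mu / (sd * sd),
        g1 / sd - 2 * g2 * mu / (sd * sd),
        g2 / (sd * sd),
    ])
    beta_df = pd.DataFrame(beta, index=categories, columns=["b0", "b1", "b2"])

    eta = X @ gamma.T
    eta -= eta.max(axis=1, keepdims=True)
    P = np.exp(eta)
    P /= P.sum(axis=1, keepdims=True)
    deviance = 2.0 * (_saturated_loglik(C) - ll)
    return MultinomialFit(
        categories=categories, baseline=categories[b], beta=beta_df,
        loglik=ll, deviance=max(deviance, 0.0),
        fitted=pd.DataFrame(P, index=t, columns=categories),
        times=t, converged=converged, n_iter=n_iter, grad_norm=grad_norm)


def _fast_deviance(C: np.ndarray, X: np.ndarray) -> float:
    """Deviance of the quadratic multinomial fit (internal, z-scale design)."""
    b = int(np.argmax(C.sum(axis=0)))
    gamma, ll, _, _, _ = _newton_multinomial(C, X, b)
    return max(2.0 * (_saturated_loglik(C) - ll), 0.0)


# ---------------------------------------------------------------------------
# OLS on diversity indices
# ---------------------------------------------------------------------------


@dataclass
class OLSFit:
    """OLS of a diversity index on time and time squared."""

    params: pd.Series  # const, time, time2
    r2: float
    residuals: np.ndarray
    times: np.ndarray
    values: np.ndarray

    def predict(self, times) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        c = self.params
        return c["const"] + c["time"] * t + c["time2"] * t * t


def fit_ols_quadratic(values, times) -> OLSFit:
    """Least-squares fit of value ~ 1 + t + t^2; R^2 = 1 - SSE/SST."""
    y = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if len(y) != len(t):
        raise DataError("values and times length mismatch")
    if len(np.unique(t)) < 3:
        raise DataError("need >=3 distinct times for a quadratic model")
    X = pd.DataFrame({"const": 1.0, "time": t, "time2": t * t})
    res = sm.OLS(y, X).fit()
    r2 = float(res.rsquared) if np.ptp(y) > 0 else 0.0
    return OLSFit(params=res.params, r2=r2, residuals=np.asarray(res.resid),
                  times=t, values=y)


# ---------------------------------------------------------------------------
# Randomization tests
# ---------------------------------------------------------------------------


@dataclass
class RandTest:
    """Observed statistic against a permutation null distribution."""

    statistic_name: str
    observed: float
    null: np.ndarray
    n_rand: int
    p_strict: float
    p_smoothed: float
    mode: str
    seed: int

    @property
    def p_value(self) -> float:
        return self.p_strict if self.mode == "strict" else self.p_smoothed


def _check_rand_args(n_rand: int) -> None:
    if n_rand < 1:
        raise DataError("n_rand must be >= 1")


def randomization_test_deviance(sample_counts, times, n_rand: int = N_RAND_DEFAULT,
                                seed: int = 0, mode: str = "smoothed") -> RandTest:
    """Permutation test for a quadratic time trend in category composition.

    ``sample_counts`` holds per-surface category counts (surface x category)
    and ``times`` the observation time of each surface. Each randomization
    permutes the surface-to-time assignment uniformly (times held fixed),
    re-pools counts by time and refits the quadratic multinomial; surfaces,
    not individuals, are the exchangeable unit because individuals on one
    surface are not independent. Strict rule: p = #{D_rand < D_obs} / n_rand.
    Smoothed rule (default): p = (1 + #{D_rand <= D_obs}) / (1 + n_rand).
    """
    _check_rand_args(n_rand)
    if mode not in ("strict", "smoothed"):
        raise DataError(f"unknown mode {mode!r}")
    if isinstance(sample_counts, pd.DataFrame):
        S = sample_counts.to_numpy(dtype=float)
    else:
        S = np.asarray(sample_counts, dtype=float)
    t = np.asarray(times, dtype=float)
    if len(t) != S.shape[0]:
        raise DataError("times must align with sample rows")
    ut, inv = np.unique(t, return_inverse=True)
    if len(ut) < 3:
        raise DataError("need >=3 distinct times")
    if len(t) < len(ut):
        raise DataError("fewer samples than time points")
    keep = S.sum(axis=0) > 0
    if not keep.all():
        warnings.warn("dropping categories empty in all samples")
        S = S[:, keep]
    if S.shape[1] < 2:
        raise DataError("fewer than 2 non-empty categories")

    T = len(ut)
    z = (ut - ut.mean()) / (ut.std() if ut.std() > 0 else 1.0)
    X = np.column_stack([np.ones_like(z), z, z * z])

    def pooled_deviance(inverse) -> float:
        C = np.zeros((T, S.shape[1]))
        np.add.at(C, inverse, S)
        return _fast_deviance(C, X)

    observed = pooled_deviance(inv)
    rng = np.random.default_rng(seed)
    null = np.empty(n_rand)
    for r in range(n_rand):
        null[r] = pooled_deviance(inv[rng.permutation(len(inv))])
    p_strict = float((null < observed).sum() / n_rand)
    p_smoothed = float((1 + (null <= observed).sum()) / (1 + n_rand))
    return RandTest("deviance", observed, null, n_rand, p_strict, p_smoothed,
                    mode, seed)


def randomization_test_r2(values, times, n_rand: int = N_RAND_DEFAULT,
                          seed: int = 0, mode: str = "smoothed") -> RandTest:
    """Permutation test for a quadratic time trend in a diversity index.

    Values are permuted against the fixed times. Strict rule:
    p = #{R2_rand > R2_obs} / n_rand; smoothed (default):
    p = (1 + #{R2_rand >= R2_obs}) / (1 + n_rand).
    """
    _check_rand_args(n_rand)
    if mode not in ("strict", "smoothed"):
        raise DataError(f"unknown mode {mode!r}")
    y = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    fit = fit_ols_quadratic(y, t)
    observed = fit.r2

    X = np.column_stack([np.ones_like(t), t, t * t])
    hat = X @ np.linalg.pinv(X)  # projection onto the quadratic design
    ybar = y.mean()
    sst = float(((y - ybar) ** 2).sum())
    rng = np.random.default_rng(seed)
    null = np.empty(n_rand)
    if sst == 0:
        null[:] = 0.0
    else:
        perms = np.stack([y[rng.permutation(len(y))] for _ in range(n_rand)])
        fitted = perms @ hat.T
        sse = ((perms - fitted) ** 2).sum(axis=1)
        null = 1.0 - sse / sst
    p_strict = float((null > observed).sum() / n_rand)
    p_smoothed = float((1 + (null >= observed).sum()) / (1 + n_rand))
    return RandTest("r2", observed, null, n_rand, p_strict, p_smoothed,
                    mode, seed)


# ---------------------------------------------------------------------------
# Trend report over traits, guilds and diversity indices
# ---------------------------------------------------------------------------


def trend_report(table: AbundanceTable, traits: TraitTable,
                 specs, guild_labels: pd.Series, diversity_table: pd.DataFrame,
                 n_rand: int = N_RAND_DEFAULT, seed: int = 0,
                 mode: str = "smoothed",
                 raoq_outlier_times=(9,)) -> pd.DataFrame:
    """Randomization trend tests for every trait, the guild set, and each index.

    One row per unit with the observed statistic and both tie-rule P-values.
    Only post-eruption surfaces enter the tests. The RaoQ regression is also
    run excluding the listed outlier times (sensitivity row).
    """
    post_ids = [s.sample_id for s in table.samples if s.epoch == "post_eruption"]
    post = table.subset_samples(post_ids)
    times = np.array([s.time_months for s in post.samples], dtype=float)

    ss = np.random.SeedSequence(seed)
    rows = []

    def dev_row(unit: str, counts: pd.DataFrame):
        sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
        nonzero = counts.loc[:, counts.sum(axis=0) > 0]
        if nonzero.shape[1] < 2:
            rows.append({"unit": unit, "statistic_name": "deviance",
                         "observed": np.nan, "p_strict": np.nan,
                         "p_smoothed": np.nan, "n_rand": n_rand,
                         "seed": sub_seed, "converged": True,
                         "note": "skipped: fewer than 2 non-empty categories"})
            return
        rt = randomization_test_deviance(nonzero, times, n_rand=n_rand,
                                         seed=sub_seed, mode=mode)
        rows.append({"unit": unit, "statistic_name": "deviance",
                     "observed": rt.observed, "p_strict": rt.p_strict,
                     "p_smoothed": rt.p_smoothed, "n_rand": n_rand,
                     "seed": sub_seed, "converged": True, "note": ""})

    for spec in specs:
        dev_row(spec.name, per_sample_modality_counts(post, traits, spec))

    guild_cols = {}
    for g in sorted(guild_labels.unique()):
        members = [t for t in post.taxa if guild_labels.get(t) == g]
        guild_cols[g] = post.counts[members].sum(axis=1) if members else 0
    dev_row("guilds", pd.DataFrame(guild_cols, index=post.counts.index))

    div_times = diversity_table.index.to_numpy(dtype=float)
    for metric in diversity_table.columns:
        sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
        rt = randomization_test_r2(diversity_table[metric].to_numpy(), div_times,
                                   n_rand=n_rand, seed=sub_seed, mode=mode)
        rows.append({"unit": metric, "statistic_name": "r2",
                     "observed": rt.observed, "p_strict": rt.p_strict,
                     "p_smoothed": rt.p_smoothed, "n_rand": n_rand,
                     "seed": sub_seed, "converged": True, "note": ""})
        if metric == "raoq" and raoq_outlier_times:
            keep = ~np.isin(div_times, np.asarray(raoq_outlier_times, dtype=float))
            if keep.sum() >= 4 and keep.sum() < len(div_times):
                sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
                rt = randomization_test_r2(diversity_table[metric].to_numpy()[keep],
                                           div_times[keep], n_rand=n_rand,
                                           seed=sub_seed, mode=mode)
                excl = ",".join(str(x) for x in raoq_outlier_times)
                rows.append({"unit": f"raoq_excl_{excl}mo",
                             "statistic_name": "r2", "observed": rt.observed,
                             "p_strict": rt.p_strict,
                             "p_smoothed": rt.p_smoothed, "n_rand": n_rand,
                             "seed": sub_seed, "converged": True,
                             "note": f"excluding months {excl}"})
    return pd.DataFrame(rows)
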