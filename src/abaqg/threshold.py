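"""Ordinal probit threshold sire-dam model fitted by Gibbs sampling.

An unobserved liability l = mu + gender + sire + dam + family + e with
e ~ N(0, 1) underlies the observed category: score c iff
tau_{c-1} < l <= tau_c (tau_0 = -inf, tau_K = +inf). Fixing Var(e) = 1
identifies the probit scale; the first cutpoint is anchored at 0 and the
overall mean stays free. Estimation uses latent-variable data
augmentation: liabilities are drawn from truncated normals given the
observed categories, then ALL location effects (mean, gender, sire, dam,
family) jointly from their multivariate-normal full conditional — the
joint update matters because sire, dam and family effects are strongly
confounded at the family level and single-site updates mix glacially —
then variances (flat priors, scaled inverse-chi-square updates) and
interior cutpoints. Binary traits (survival) are the two-category
special case with no free cutpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from sklearn.base import BaseEstimator

from .genpar import h2_latent, c2_latent


class ThresholdModelError(ValueError):
    pass


@dataclass
class ThresholdFit:
    """Posterior summaries of the latent-scale model."""

    response: str
    posterior_mean: dict               # parameter -> mean
    posterior_sd: dict
    h2_latent: tuple                   # (mean, sd)
    c2_latent: tuple
    cutpoints: np.ndarray              # posterior mean interior cutpoints
    rhat: dict
    ess: dict
    chain_length: int
    burn_in: int
    thin: int
    seed: int
    converged: bool
    n_records: int
    draws: pd.DataFrame | None = None
    collapsed_categories: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "posterior_mean": self.posterior_mean,
            "posterior_sd": self.posterior_sd,
            "h2_latent": list(self.h2_latent),
            "c2_latent": list(self.c2_latent),
            "cutpoints": self.cutpoints.tolist(),
            "rhat": self.rhat,
            "ess": self.ess,
            "chain": {
                "length": self.chain_length,
                "burn_in": self.burn_in,
                "thin": self.thin,
                "seed": self.seed,
            },
            "converged": self.converged,
            "n_records": self.n_records,
        }


def _split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction factor."""
    n = len(x) // 2
    if n < 4:
        return float("nan")
    halves = np.stack([x[:n], x[len(x) - n :]])
    within = halves.var(axis=1, ddof=1).mean()
    between = n * halves.mean(axis=1).var(ddof=1)
    if within == 0:
        return float("nan")
    var_plus = (n - 1) / n * within + between / n
    return float(np.sqrt(var_plus / within))


def _ess(x: np.ndarray) -> float:
    """Effective sample size via Geyer's initial positive sequence."""
    n = len(x)
    if n < 8 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acov = np.correlate(xc, xc, mode="full")[n - 1 :] / n
    rho = acov / acov[0]
    s = 0.0
    for k in range(1, n // 2):
        pair = rho[2 * k - 1] + rho[2 * k] if 2 * k < n else 0.0
        if pair < 0:
            break
        s += pair
    return float(n / (1.0 + 2.0 * s))


def _sample_variance(ss: float, n: int, rng) -> float:
    """Draw sigma^2 | effects under a flat prior: SS / chi2_{n-2}."""
    df = n - 2
    if df < 1:
        raise ThresholdModelError("too few levels to sample a variance")
    return ss / rng.chisquare(df)


class ThresholdSireDamModel(BaseEstimator):
    """Gibbs-sampled probit sire-dam model for ordinal records.

    Parameters: ``response`` score column (integer categories; binary 0/1
    accepted), ``include_family`` full-sib common-environment term,
    chain controls and ``seed``. Expects data columns ``response``,
    ``sire``, ``dam``, ``family`` and optionally ``sex``.

    Fitted attributes: ``fit_`` (:class:`ThresholdFit`), plus
    ``sigma_s2_``, ``sigma_d2_``, ``sigma_f2_``, ``h2_latent_``,
    ``cutpoints_``.
    """

    def __init__(
        self,
        response="Fc",
        include_family=False,
        chain_length=20000,
        burn_in=5000,
        thin=10,
        seed=0,
        keep_draws=False,
    ):
        self.response = response
        self.include_family = include_family
        self.chain_length = chain_length
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.keep_draws = keep_draws

    # ------------------------------------------------------------------
    def fit(self, data: pd.DataFrame):
        need = {self.response, "sire", "dam", "family"}
        missing = need - set(data.columns)
        if missing:
            raise ThresholdModelError(f"data lacks columns {sorted(missing)}")
        sub = data.loc[data[self.response].notna()].reset_index(drop=True)
        if not len(sub):
            raise ThresholdModelError("no observed records")
        for col in ("sire", "dam", "family"):
            if (sub[col].astype(str) == "").any():
                raise ThresholdModelError(f"records with unknown {col}")

        raw = sub[self.response].to_numpy(float)
        cats, counts = np.unique(raw, return_counts=True)
        # collapse empty categories: remap observed values to consecutive
        # ranks 1..K (a category can only be empty relative to a declared
        # scale; unobserved scores between observed ones are impossible
        # here, so remapping is equivalent to neighbor-collapse)
        full_range = np.arange(raw.min(), raw.max() + 1)
        collapsed = [c for c in full_range if c not in set(cats)]
        if collapsed:
            warnings.warn(
                f"{self.response}: categories {collapsed} unobserved; "
                "collapsed with their lower neighbor"
            )
        score = np.searchsorted(cats, raw) + 1  # 1..K
        K = len(cats)
        if K < 2:
            raise ThresholdModelError(
                f"{self.response} has a single observed category"
            )

        sire, _ = pd.factorize(sub["sire"].astype(str))
        dam, _ = pd.factorize(sub["dam"].astype(str))
        fam, _ = pd.factorize(sub["family"].astype(str))
        n_s, n_d, n_f = sire.max() + 1, dam.max() + 1, fam.max() + 1
        if "sex" in sub.columns:
            sex, sex_levels = pd.factorize(sub["sex"].astype(str))
            n_g = len(sex_levels)
        else:
            sex = np.zeros(len(sub), dtype=int)
            sex_levels = pd.Index(["all"])
            n_g = 1
        n = len(sub)

        rng = np.random.default_rng(self.seed)

        # initial cutpoints from observed frequencies, anchored tau_1 = 0
        freq = np.bincount(score, minlength=K + 1)[1:]
        cum = np.cumsum(freq) / n
        tau_init = stats.norm.ppf(np.clip(cum[:-1], 1e-6, 1 - 1e-6))
        tau = tau_init - tau_init[0]
        mu = -tau_init[0]

        sig_s = sig_d = sig_f = 0.1

        # blocked location update: beta = [mu, gender(2..), s, d, f?]
        off_g = 1
        off_s = off_g + (n_g - 1)
        off_d = off_s + n_s
        off_f = off_d + n_d
        p_loc = off_f + (n_f if self.include_family else 0)
        X_rows = np.arange(n)
        # build dense X'X once (incidence design, a few hundred columns)
        import scipy.sparse as sp

        rows, ccols, vals = [X_rows], [np.zeros(n, dtype=np.int64)], [np.ones(n)]
        for g in range(1, n_g):
            mask = np.flatnonzero(sex == g)
            rows.append(mask)
            ccols.append(np.full(len(mask), off_g + g - 1))
            vals.append(np.ones(len(mask)))
        rows.append(X_rows); ccols.append(off_s + sire); vals.append(np.ones(n))
        rows.append(X_rows); ccols.append(off_d + dam); vals.append(np.ones(n))
        if self.include_family:
            rows.append(X_rows); ccols.append(off_f + fam); vals.append(np.ones(n))
        X = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(ccols))),
            shape=(n, p_loc),
        )
        XtX = (X.T @ X).toarray()
        beta = np.zeros(p_loc)
        beta[0] = mu

        lo_ix = score - 1
        hi_ix = score
        n_kept = (self.chain_length - self.burn_in) // self.thin
        draws = np.empty((n_kept, 4 + (K - 2) + n_g))
        kcol = 0
        eps = 1e-12
        from scipy.linalg import cho_factor, cho_solve, solve_triangular

        for it in range(self.chain_length):
            bounds = np.concatenate(([-np.inf], tau, [np.inf]))
            eta = X @ beta
            a = stats.norm.cdf(bounds[lo_ix] - eta)
            b = stats.norm.cdf(bounds[hi_ix] - eta)
            u = rng.uniform(np.clip(a, eps, 1 - eps), np.clip(b, eps, 1 - eps))
            liab = eta + stats.norm.ppf(u)

            # joint Gaussian update of all location effects
            prior = np.zeros(p_loc)
            prior[off_s:off_d] = 1.0 / sig_s
            prior[off_d:off_f] = 1.0 / sig_d
            if self.include_family:
                prior[off_f:] = 1.0 / sig_f
            P = XtX + np.diag(prior)
            c, low = cho_factor(P, lower=True)
            mean = cho_solve((c, low), X.T @ liab)
            z = rng.standard_normal(p_loc)
            beta = mean + solve_triangular(c, z, lower=True, trans="T")

            mu = beta[0]
            g_eff = np.concatenate(([0.0], beta[off_g:off_s]))
            s_eff = beta[off_s:off_d]
            d_eff = beta[off_d:off_f]
            f_eff = beta[off_f:] if self.include_family else np.zeros(0)

            sig_s = _sample_variance(float(s_eff @ s_eff), n_s, rng)
            sig_d = _sample_variance(float(d_eff @ d_eff), n_d, rng)
            if self.include_family:
                sig_f = _sample_variance(float(f_eff @ f_eff), n_f, rng)

            # interior cutpoints (Albert-Chib uniform conditionals)
            for c in range(2, K):
                lo = liab[score == c].max() if np.any(score == c) else tau[c - 2]
                hi = liab[score == c + 1].min() if np.any(score == c + 1) else lo
                lo = max(lo, tau[c - 2])
                hi = min(hi, bounds[c + 1])
                tau[c - 1] = rng.uniform(lo, hi) if hi > lo else lo

            if it >= self.burn_in and (it - self.burn_in) % self.thin == 0 and kcol < n_kept:
                sf = sig_f if self.include_family else 0.0
                draws[kcol] = np.concatenate(
                    ([mu, sig_s, sig_d, sf], tau[1:], g_eff)
                )
                kcol += 1

        draws = draws[:kcol]
        cols = (
            ["mu", "sigma_s2", "sigma_d2", "sigma_f2"]
            + [f"tau_{c}" for c in range(2, K)]
            + [f"gender[{lv}]" for lv in sex_levels]
        )
        dd = pd.DataFrame(draws, columns=cols)
        dd["h2_latent"] = [
            h2_latent(a, b, c)
            for a, b, c in zip(dd.sigma_s2, dd.sigma_d2, dd.sigma_f2)
        ]
        dd["c2_latent"] = [
            c2_latent(c, a, b)
            for a, b, c in zip(dd.sigma_s2, dd.sigma_d2, dd.sigma_f2)
        ]

        rhat = {c: _split_rhat(dd[c].to_numpy()) for c in dd.columns}
        ess = {c: _ess(dd[c].to_numpy()) for c in dd.columns}
        bad = [c for c, v in rhat.items() if np.isfinite(v) and v > 1.1]
        if bad:
            warnings.warn(f"possible non-convergence (split-Rhat > 1.1): {bad}")

        pm = dd.mean().to_dict()
        ps = dd.std(ddof=1).to_dict()
        self.sigma_s2_ = pm["sigma_s2"]
        self.sigma_d2_ = pm["sigma_d2"]
        self.sigma_f2_ = pm["sigma_f2"]
        self.h2_latent_ = pm["h2_latent"]
        self.cutpoints_ = np.concatenate(
            ([0.0], [pm[f"tau_{c}"] for c in range(2, K)])
        )
        self.fit_ = ThresholdFit(
            response=self.response,
            posterior_mean=pm,
            posterior_sd=ps,
            h2_latent=(pm["h2_latent"], ps["h2_latent"]),
            c2_latent=(pm["c2_latent"], ps["c2_latent"]),
            cutpoints=self.cutpoints_,
            rhat=rhat,
            ess=ess,
            chain_length=self.chain_length,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=self.seed,
            converged=not bad,
            n_records=n,
            draws=dd if self.keep_draws else None,
            collapsed_categories=[float(c) for c in collapsed],
        )
        return self


def fit_threshold(
    data,
    response="Fc",
    include_family=False,
    chain_length=20000,
    burn_in=5000,
    thin=10,
    seed=0,
    **kw,
) -> ThresholdFit:
    """Fit the probit sire-dam model; see :class:`ThresholdSireDamModel`."""
    est = ThresholdSireDamModel(
        response=response,
        include_family=include_family,
        chain_length=chain_length,
        burn_in=burn_in,
        thin=thin,
        seed=seed,
        **kw,
    ).fit(data)
    return est.fit_


def linear_score_fit(data, ped, response="Fc", **kw):
    """Linear animal model treating the ordinal score as continuous.

    Exists to reproduce the linear-vs-threshold heritability contrast on
    the same records.
    """
    from .reml import fit_reml

    scores = data[response].dropna()
    if scores.nunique() < 2:
        raise ThresholdModelError(
            f"{response} has zero variance; linear fit undefined"
        )
    return fit_reml(data, ped, traits=[response], **kw)
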