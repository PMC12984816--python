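"""REML variance-component estimation for pedigree linear animal models.

Model per trait: y = mean + gender + a (+ family) + e with
Var(a) = A (x) G0, Var(f) = I (x) F0, and record-level residual
covariance E0 applied only to co-observed trait pairs. Estimation works
on Henderson's sparse mixed-model equations; the restricted likelihood
uses the classic identity

    -2 lR = (n - p) log 2pi + log|R| + log|Gbig| + log|C| + y'Py,

with y'Py = y'R^-1 y - sol' rhs. Optimization is average-information
Newton ascent: the AI matrix is exact (a handful of MME solves); the
gradient's trace terms are exact via dense inverses on small systems and
seeded Hutchinson probes on large ones. Univariate fits start from an
EM warm-up; multivariate fits warm-start from the univariate components
plus sample phenotypic correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from sklearn.base import BaseEstimator

from .pedigree import (
    Pedigree,
    build_A,
    build_A_inverse,
    family_structure,
    prune_pedigree,
    relationship_factor,
    A_matvec,
)

_TWO_PI = 2.0 * np.pi


class ModelError(ValueError):
    pass


@dataclass
class MixedModelFit:
    """REML variance components and their uncertainty."""

    traits: list
    gcov: np.ndarray                  # additive (co)variance matrix G0
    ecov: np.ndarray                  # residual (co)variance matrix E0
    fcov: np.ndarray | None           # family (co)variance matrix, if fitted
    loglik: float
    ai_matrix: np.ndarray
    ai_params: list                   # [(term, i, j), ...] matching ai rows
    fixed_effects: pd.DataFrame
    converged: bool
    n_iterations: int
    boundary: list = field(default_factory=list)
    n_records: dict = field(default_factory=dict)

    @property
    def h2(self) -> np.ndarray:
        d = np.diag(self.gcov) + np.diag(self.ecov)
        return np.diag(self.gcov) / d

    def to_dict(self) -> dict:
        return {
            "traits": list(self.traits),
            "gcov": self.gcov.tolist(),
            "ecov": self.ecov.tolist(),
            "fcov": None if self.fcov is None else self.fcov.tolist(),
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "boundary": self.boundary,
            "n_records": self.n_records,
        }


def _vech_indices(t):
    return [(i, j) for i in range(t) for j in range(i, t)]


def _sex_design(sex_values):
    """Intercept + treatment-coded sex dummies (reference = first level)."""
    levels = [lv for lv in ("F", "M", "U") if lv in set(sex_values)]
    cols = [np.ones(len(sex_values))]
    names = ["intercept"]
    for lv in levels[1:]:
        cols.append((np.asarray(sex_values) == lv).astype(float))
        names.append(f"sex[{lv}]")
    return np.column_stack(cols), names


class _MME:
    """Assembled once per dataset; refactored per parameter value."""

    def __init__(self, data, ped, traits, include_family):
        self.traits = list(traits)
        t = len(self.traits)
        for tr in self.traits:
            if tr not in data.columns:
                raise ModelError(f"trait column {tr!r} missing from data")
        obs_any = data[self.traits].notna().any(axis=1)
        data = data.loc[obs_any].reset_index(drop=True)
        if not len(data):
            raise ModelError("no records observed for requested traits")
        self.ped = prune_pedigree(ped, data["id"].unique())
        self.q = len(self.ped)
        self.pos = self.ped.positions(data["id"].tolist())
        self.include_family = include_family

        self.Ainv, self.logdetA = build_A_inverse(self.ped, return_logdet=True)
        self.I_minus_T, self.dvec = relationship_factor(self.ped)

        fam = family_structure(self.ped).family_of.iloc[self.pos]
        self.fam_codes, self.fam_levels = pd.factorize(fam)
        self.nf = len(self.fam_levels)
        if include_family and (self.fam_codes < 0).any():
            raise ModelError("family term requires known sire and dam")

        sex = (
            data["sex"].astype(str).to_numpy()
            if "sex" in data.columns
            else np.array(["F"] * len(data))
        )
        X_full, self.fixed_names = _sex_design(sex)
        self.p_t = X_full.shape[1]

        self.obs = [data[tr].notna().to_numpy() for tr in self.traits]
        self.rec_rows = [np.flatnonzero(m) for m in self.obs]
        self.n_t = [len(r) for r in self.rec_rows]
        self.off = np.concatenate([[0], np.cumsum(self.n_t)]).astype(int)
        self.n_obs = int(self.off[-1])
        self.y = np.concatenate(
            [data[tr].to_numpy(float)[r] for tr, r in zip(self.traits, self.rec_rows)]
        )
        # record index per (trait, data row); -1 when unobserved
        self.rec_index = np.full((t, len(data)), -1, dtype=np.int64)
        for k in range(t):
            self.rec_index[k, self.rec_rows[k]] = self.off[k] + np.arange(self.n_t[k])

        # missingness patterns over data rows
        pat = np.stack(self.obs, axis=1)
        self.patterns = {}
        keys, inv = np.unique(pat, axis=0, return_inverse=True)
        for ki, key in enumerate(keys):
            rows = np.flatnonzero(inv == ki)
            self.patterns[tuple(bool(b) for b in key)] = rows

        # design matrix W: [animal t*q | family t*nf | fixed t*p_t]
        self.ncol_a = t * self.q
        self.ncol_f = t * self.nf if include_family else 0
        self.ncol_x = t * self.p_t
        rows, cols, vals = [], [], []
        for k in range(t):
            rr = self.off[k] + np.arange(self.n_t[k])
            rows.append(rr)
            cols.append(k * self.q + self.pos[self.rec_rows[k]])
            vals.append(np.ones(self.n_t[k]))
            if include_family:
                rows.append(rr)
                cols.append(self.ncol_a + k * self.nf + self.fam_codes[self.rec_rows[k]])
                vals.append(np.ones(self.n_t[k]))
            for j in range(self.p_t):
                rows.append(rr)
                cols.append(
                    np.full(self.n_t[k], self.ncol_a + self.ncol_f + k * self.p_t + j)
                )
                vals.append(X_full[self.rec_rows[k], j])
        self.ncol = self.ncol_a + self.ncol_f + self.ncol_x
        self.W = sp.csr_matrix(
            (
                np.concatenate(vals),
                (np.concatenate(rows), np.concatenate(cols)),
            ),
            shape=(self.n_obs, self.ncol),
        )
        self.Wt = self.W.T.tocsr()
        self.n_fixed = self.ncol_x

    # -- residual structure ------------------------------------------------
    def rinv(self, E0):
        """Sparse R^-1 and log|R| under record-level missingness."""
        t = len(self.traits)
        rows, cols, vals = [], [], []
        logdet = 0.0
        for key, members in self.patterns.items():
            ix = [k for k in range(t) if key[k]]
            if not ix:
                continue
            sub = E0[np.ix_(ix, ix)]
            sign, ld = np.linalg.slogdet(sub)
            if sign <= 0:
                raise FloatingPointError("residual covariance not PD")
            logdet += ld * len(members)
            inv = np.linalg.inv(sub)
            for a, ta in enumerate(ix):
                ra = self.rec_index[ta, members]
                for b, tb in enumerate(ix):
                    rb = self.rec_index[tb, members]
                    rows.append(ra)
                    cols.append(rb)
                    vals.append(np.full(len(members), inv[a, b]))
        Rinv = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_obs, self.n_obs),
        )
        return Rinv, logdet

    # -- per-parameter factorization ---------------------------------------
    def factorize(self, G0, E0, F0=None):
        t = len(self.traits)
        Rinv, logdetR = self.rinv(E0)
        signG, ldG0 = np.linalg.slogdet(G0)
        if signG <= 0:
            raise FloatingPointError("genetic covariance not PD")
        Ginv_big = sp.kron(np.linalg.inv(G0), self.Ainv, format="csr")
        blocks = [Ginv_big]
        logdetG = self.q * ldG0 + t * self.logdetA
        if self.include_family:
            signF, ldF0 = np.linalg.slogdet(F0)
            if signF <= 0:
                raise FloatingPointError("family covariance not PD")
            blocks.append(sp.kron(np.linalg.inv(F0), sp.eye(self.nf), format="csr"))
            logdetG += self.nf * ldF0
        prior = sp.block_diag(
            blocks + [sp.csr_matrix((self.ncol_x, self.ncol_x))], format="csr"
        )
        WtR = self.Wt @ Rinv
        C = (WtR @ self.W + prior).tocsc()
        rhs = WtR @ self.y
        factor = splu(C, permc_spec="MMD_AT_PLUS_A")
        sol = factor.solve(rhs)
        yry = float(self.y @ (Rinv @ self.y))
        ypy = yry - float(sol @ rhs)
        logdetC = float(np.sum(np.log(np.abs(factor.U.diagonal()))))
        loglik = -0.5 * (
            (self.n_obs - self.n_fixed) * np.log(_TWO_PI)
            + logdetR
            + logdetG
            + logdetC
            + ypy
        )
        return _State(self, G0, E0, F0, Rinv, factor, sol, loglik, C)

    def apply_V_dot(self, term, i, j, x):
        """V-derivative times an observation-space vector.

        term 'G': Z (J_ij (x) A) Z' x; term 'F': family analogue with
        identity; term 'E': record-level dR/dE_ij x.
        """
        t = len(self.traits)
        out = np.zeros_like(x)
        if term in ("G", "F"):
            w = np.zeros((t, self.q if term == "G" else self.nf))
            # gather Z' x per trait
            for k in range(t):
                rr = self.rec_rows[k]
                seg = x[self.off[k] : self.off[k + 1]]
                if term == "G":
                    np.add.at(w[k], self.pos[rr], seg)
                else:
                    np.add.at(w[k], self.fam_codes[rr], seg)
            v = np.zeros_like(w)
            pairs = [(i, j)] if i == j else [(i, j), (j, i)]
            for a, b in pairs:
                if term == "G":
                    v[a] += A_matvec(self.I_minus_T, self.dvec, w[b])
                else:
                    v[a] += w[b]
            for k in range(t):
                rr = self.rec_rows[k]
                src = v[k][self.pos[rr]] if term == "G" else v[k][self.fam_codes[rr]]
                out[self.off[k] : self.off[k + 1]] = src
            return out
        if term == "E":
            pairs = [(i, j)] if i == j else [(i, j), (j, i)]
            for a, b in pairs:
                ra = self.rec_index[a]
                rb = self.rec_index[b]
                both = (ra >= 0) & (rb >= 0)
                out[ra[both]] += x[rb[both]]
            return out
        raise ValueError(term)


class _State:
    def __init__(self, mme, G0, E0, F0, Rinv, factor, sol, loglik, C):
        self.mme = mme
        self.G0, self.E0, self.F0 = G0, E0, F0
        self.Rinv, self.factor, self.sol, self.loglik = Rinv, factor, sol, loglik
        self.C = C

    def project(self, x):
        """P x = R^-1 x - R^-1 W C^-1 W' R^-1 x."""
        rx = self.Rinv @ x
        return rx - self.Rinv @ (self.mme.W @ self.factor.solve(self.mme.Wt @ rx))

    def py(self):
        return self.Rinv @ (self.mme.y - self.mme.W @ self.sol)


def _param_list(t, include_family):
    out = [("G", i, j) for i, j in _vech_indices(t)]
    if include_family:
        out += [("F", i, i) for i in range(t)]
    out += [("E", i, j) for i, j in _vech_indices(t)]
    return out


def _pack(G0, E0, F0, params):
    vals = []
    for term, i, j in params:
        M = {"G": G0, "E": E0, "F": F0}[term]
        vals.append(M[i, j])
    return np.array(vals)


def _unpack(theta, t, params):
    G0, E0 = np.zeros((t, t)), np.zeros((t, t))
    F0 = np.zeros((t, t))
    has_f = False
    for v, (term, i, j) in zip(theta, params):
        M = {"G": G0, "E": E0, "F": F0}[term]
        M[i, j] = M[j, i] = v
        has_f = has_f or term == "F"
    return G0, E0, (F0 if has_f else None)


def _is_pd(M, floor=0.0):
    if M is None:
        return True
    try:
        w = np.linalg.eigvalsh(M)
    except np.linalg.LinAlgError:
        return False
    return w.min() > floor


class AnimalModelREML(BaseEstimator):
    """Pedigree animal model fitted by AI-REML (scikit-learn style).

    Parameters
    ----------
    traits : list of str
        Phenotype columns to model jointly (1 = univariate).
    include_family : bool
        Add a full-sib common-environment random term.
    max_iter, tol : optimizer controls; `tol` is the relative restricted
        log-likelihood change declaring convergence (parameter changes
        must simultaneously fall below 1e-6 relative).
    em_warmup : EM-REML iterations before Newton steps (univariate only).
    n_probes : Hutchinson probe vectors for gradient traces on systems too
        large for exact dense traces.
    dense_cutoff : observation count up to which traces are exact.
    seed : seeds the probe vectors (fit remains deterministic).

    Fitted attributes: ``gcov_``, ``ecov_``, ``fcov_``, ``loglik_``,
    ``ai_matrix_``, ``ai_params_``, ``fixed_effects_``, ``converged_``,
    ``n_iter_``, ``boundary_``, ``fit_`` (a :class:`MixedModelFit`).
    """

    def __init__(
        self,
        traits,
        include_family=False,
        max_iter=200,
        tol=1e-8,
        em_warmup=5,
        n_probes=48,
        dense_cutoff=1200,
        seed=0,
        start=None,
        max_halvings=20,
        diagonal_covariances=False,
    ):
        self.traits = traits
        self.include_family = include_family
        self.max_iter = max_iter
        self.tol = tol
        self.em_warmup = em_warmup
        self.n_probes = n_probes
        self.dense_cutoff = dense_cutoff
        self.seed = seed
        self.start = start
        self.max_halvings = max_halvings
        self.diagonal_covariances = diagonal_covariances

    # ----------------------------------------------------------------------
    def fit(self, data: pd.DataFrame, pedigree: Pedigree):
        traits = [self.traits] if isinstance(self.traits, str) else list(self.traits)
        t = len(traits)
        mme = _MME(data, pedigree, traits, self.include_family)
        self._mme = mme
        exact = mme.n_obs <= self.dense_cutoff
        rng = np.random.default_rng(self.seed)
        params = _param_list(t, self.include_family)
        if self.diagonal_covariances:
            params = [p for p in params if p[1] == p[2]]

        G0, E0, F0 = self._starting_values(data, pedigree, traits, mme)
        if self.start is not None:
            G0 = np.array(self.start.get("G", G0), dtype=float)
            E0 = np.array(self.start.get("E", E0), dtype=float)
            if "F" in self.start:
                F0 = np.array(self.start["F"], dtype=float)

        vp = np.diag(G0) + np.diag(E0)
        floor = 1e-8 * vp

        state = mme.factorize(G0, E0, F0)
        if t == 1 and self.em_warmup:
            for _ in range(self.em_warmup):
                G0n, E0n, F0n = self._em_step(state, exact, rng)
                new = mme.factorize(G0n, E0n, F0n)
                if not np.isfinite(new.loglik):
                    break
                state, G0, E0, F0 = new, G0n, E0n, F0n

        converged = False
        boundary = []
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            grad, AI = self._derivatives(state, params, exact, rng)
            try:
                step = np.linalg.solve(
                    AI + 1e-8 * np.eye(len(AI)) * max(1.0, np.trace(AI)), grad
                )
            except np.linalg.LinAlgError:
                step = grad / max(1.0, np.abs(np.diag(AI)).max())
            theta = _pack(G0, E0, F0, params)
            improved = False
            for h in range(self.max_halvings + 1):
                cand = theta + step / (2.0**h)
                G0n, E0n, F0n = _unpack(cand, t, params)
                G0n, E0n, pinned = self._constrain(G0n, E0n, floor)
                if F0n is not None:
                    F0n = np.diag(np.maximum(np.diag(F0n), floor))
                if not (_is_pd(G0n) and _is_pd(E0n)):
                    continue
                try:
                    new = mme.factorize(G0n, E0n, F0n)
                except FloatingPointError:
                    continue
                if np.isfinite(new.loglik) and (
                    new.loglik >= state.loglik - 1e-10 * (1 + abs(state.loglik))
                ):
                    improved = True
                    break
            if not improved:
                break
            rel_dl = abs(new.loglik - state.loglik) / (1.0 + abs(state.loglik))
            rel_dp = np.max(
                np.abs(_pack(G0n, E0n, F0n, params) - theta)
                / (1.0 + np.abs(theta))
            )
            state, G0, E0, F0 = new, G0n, E0n, F0n
            boundary = pinned
            ltol = self.tol if exact else max(self.tol, 1e-7)
            ptol = 1e-6 if exact else 1e-4
            if rel_dl < ltol and rel_dp < ptol:
                converged = True
                break

        _, AI = self._derivatives(state, params, exact, rng, gradient=False)
        self.gcov_, self.ecov_, self.fcov_ = G0, E0, F0
        self.loglik_ = state.loglik
        self.ai_matrix_ = AI
        self.ai_params_ = params
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.boundary_ = boundary
        fx = state.sol[mme.ncol_a + mme.ncol_f :]
        self.fixed_effects_ = pd.DataFrame(
            {
                "trait": np.repeat(traits, mme.p_t),
                "effect": mme.fixed_names * t,
                "estimate": fx,
            }
        )
        self.fit_ = MixedModelFit(
            traits=traits,
            gcov=G0,
            ecov=E0,
            fcov=F0,
            loglik=state.loglik,
            ai_matrix=AI,
            ai_params=params,
            fixed_effects=self.fixed_effects_,
            converged=converged,
            n_iterations=n_iter,
            boundary=boundary,
            n_records={tr: n for tr, n in zip(traits, mme.n_t)},
        )
        self._state = state
        return self

    # ----------------------------------------------------------------------
    def _constrain(self, G0, E0, floor):
        pinned = []
        t = len(floor)
        for name, M in (("G", G0), ("E", E0)):
            for k in range(t):
                if M[k, k] < floor[k]:
                    M[k, k] = floor[k]
                    pinned.append((name, k))
            for i in range(t):
                for j in range(i + 1, t):
                    cap = 0.999 * np.sqrt(M[i, i] * M[j, j])
                    M[i, j] = M[j, i] = np.clip(M[i, j], -cap, cap)
        return G0, E0, pinned

    def _starting_values(self, data, pedigree, traits, mme):
        t = len(traits)
        if t == 1:
            v = np.nanvar(data[traits[0]].to_numpy(float))
            G0 = np.array([[0.5 * v]])
            E0 = np.array([[0.5 * v]])
        else:
            comps = []
            for tr in traits:
                sub = AnimalModelREML(
                    traits=[tr],
                    include_family=self.include_family,
                    max_iter=30,
                    tol=1e-6,
                    em_warmup=3,
                    n_probes=self.n_probes,
                    dense_cutoff=self.dense_cutoff,
                    seed=self.seed,
                ).fit(data, pedigree)
                comps.append(
                    (sub.gcov_[0, 0], sub.ecov_[0, 0],
                     None if sub.fcov_ is None else sub.fcov_[0, 0])
                )
            rp = (
                data[traits].corr().to_numpy()
                if len(data) > 2
                else np.eye(t)
            )
            rp = np.nan_to_num(rp, nan=0.0)
            r0 = (
                np.eye(t)
                if self.diagonal_covariances
                else np.clip(0.8 * rp, -0.9, 0.9)
            )
            np.fill_diagonal(r0, 1.0)
            sa = np.sqrt([c[0] for c in comps])
            se = np.sqrt([c[1] for c in comps])
            G0 = r0 * np.outer(sa, sa)
            E0 = r0 * np.outer(se, se)
        F0 = None
        if self.include_family:
            if t == 1:
                fv = [0.05 * (G0[0, 0] + E0[0, 0])]
            else:
                fv = [
                    c[2] if c[2] else 0.05 * (G0[k, k] + E0[k, k])
                    for k, c in enumerate(comps)
                ]
            F0 = np.diag(np.asarray(fv, dtype=float))
        return G0, E0, F0

    # ----------------------------------------------------------------------
    def _em_step(self, state, exact, rng):
        """Univariate EM-REML update (exact or MC trace)."""
        mme = state.mme
        q = mme.q
        sol = state.sol
        a_hat = sol[:q]
        sa2 = state.G0[0, 0]
        se2 = state.E0[0, 0]
        quad_a = float(a_hat @ (mme.Ainv @ a_hat))
        tr_a = self._trace_block(state, "A", exact, rng)
        sa2_new = (quad_a + tr_a) / q
        e_hat = mme.y - mme.W @ sol
        tr_w = self._trace_block(state, "W", exact, rng)
        se2_new = (float(e_hat @ e_hat) + tr_w) / mme.n_obs
        F0n = state.F0
        if mme.include_family and F0n is not None:
            f_hat = sol[q : q + mme.nf]
            tr_f = self._trace_block(state, "F", exact, rng)
            F0n = np.array([[(float(f_hat @ f_hat) + tr_f) / mme.nf]])
        return np.array([[sa2_new]]), np.array([[se2_new]]), F0n

    def _trace_block(self, state, which, exact, rng):
        """tr(A^-1 C^aa), tr(C^-1 W'W) or tr(C^ff) for univariate EM."""
        mme = state.mme
        q, nf = mme.q, mme.nf
        if exact:
            Cinv = state.factor.solve(np.eye(mme.ncol))
            if which == "A":
                return float(np.sum(mme.Ainv.toarray() * Cinv[:q, :q]))
            if which == "F":
                return float(np.trace(Cinv[q : q + nf, q : q + nf]))
            WtW = (mme.Wt @ mme.W).toarray()
            return float(np.sum(WtW * Cinv))
        total = 0.0
        n = self.n_probes
        for _ in range(n):
            if which == "A":
                u = rng.choice([-1.0, 1.0], size=q)
                rhs = np.zeros(mme.ncol)
                rhs[:q] = u
                # tr(A^-1 C^aa) = E[u' A^-1 C^aa u]
                z = state.factor.solve(rhs)[:q]
                total += float(u @ (mme.Ainv @ z))
            elif which == "F":
                u = rng.choice([-1.0, 1.0], size=nf)
                rhs = np.zeros(mme.ncol)
                rhs[q : q + nf] = u
                z = state.factor.solve(rhs)[q : q + nf]
                total += float(u @ z)
            else:
                u = rng.choice([-1.0, 1.0], size=mme.n_obs)
                wu = mme.Wt @ u
                z = state.factor.solve(wu)
                total += float(wu @ z)
        return total / n

    # ----------------------------------------------------------------------
    def _derivatives(self, state, params, exact, rng, gradient=True):
        """REML gradient and exact AI matrix at the current parameters."""
        mme = state.mme
        py = state.py()
        ydots = [mme.apply_V_dot(term, i, j, py) for term, i, j in params]
        p_ydots = [state.project(v) for v in ydots]
        npar = len(params)
        AI = np.empty((npar, npar))
        for a in range(npar):
            for b in range(a, npar):
                AI[a, b] = AI[b, a] = 0.5 * float(ydots[a] @ p_ydots[b])
        if not gradient:
            return None, AI
        quad = np.array([float(py @ v) for v in ydots])
        traces = np.empty(npar)
        if exact:
            P = self._dense_P(state)
            for k, (term, i, j) in enumerate(params):
                Vd = self._dense_Vdot(mme, term, i, j)
                traces[k] = float(np.sum(P * Vd))
        else:
            acc = np.zeros(npar)
            for _ in range(self.n_probes):
                u = rng.choice([-1.0, 1.0], size=mme.n_obs)
                pu = state.project(u)
                for k, (term, i, j) in enumerate(params):
                    acc[k] += float(pu @ mme.apply_V_dot(term, i, j, u))
            traces = acc / self.n_probes
        grad = -0.5 * (traces - quad)
        return grad, AI

    def _dense_P(self, state):
        mme = state.mme
        Rinv = state.Rinv.toarray()
        Wd = mme.W.toarray()
        Cinv = state.factor.solve(np.eye(mme.ncol))
        RW = Rinv @ Wd
        return Rinv - RW @ Cinv @ RW.T

    def _dense_Vdot(self, mme, term, i, j):
        n = mme.n_obs
        out = np.zeros((n, n))
        if term in ("G", "F"):
            if term == "G":
                if not hasattr(mme, "_A_dense"):
                    mme._A_dense = build_A(mme.ped).values
                K = mme._A_dense
                idx = [mme.pos[mme.rec_rows[k]] for k in range(len(mme.traits))]
            else:
                K = np.eye(mme.nf)
                idx = [mme.fam_codes[mme.rec_rows[k]] for k in range(len(mme.traits))]
            pairs = [(i, j)] if i == j else [(i, j), (j, i)]
            for a, b in pairs:
                ra = slice(mme.off[a], mme.off[a + 1])
                rb = slice(mme.off[b], mme.off[b + 1])
                out[ra, rb] += K[np.ix_(idx[a], idx[b])]
            return out
        pairs = [(i, j)] if i == j else [(i, j), (j, i)]
        for a, b in pairs:
            ra = mme.rec_index[a]
            rb = mme.rec_index[b]
            both = (ra >= 0) & (rb >= 0)
            out[ra[both], rb[both]] += 1.0
        return out


# ---------------------------------------------------------------------------
# Functional surface


def assemble_mme(data, ped, traits, variance_components, include_family=False):
    """Sparse MME coefficient matrix and right-hand side at given components.

    ``variance_components`` is a dict with 'G', 'E' (t x t arrays) and
    optionally 'F'. Returned as (C, rhs).
    """
    traits = [traits] if isinstance(traits, str) else list(traits)
    mme = _MME(data, ped, traits, include_family)
    G0 = np.atleast_2d(np.asarray(variance_components["G"], dtype=float))
    E0 = np.atleast_2d(np.asarray(variance_components["E"], dtype=float))
    F0 = variance_components.get("F")
    if F0 is not None:
        F0 = np.atleast_2d(np.asarray(F0, dtype=float))
    state = mme.factorize(G0, E0, F0)
    return state.C, mme.Wt @ (state.Rinv @ mme.y)


def fit_reml(
    data,
    ped,
    traits,
    include_family=False,
    max_iter=200,
    tol=1e-8,
    start=None,
    seed=0,
    **kw,
) -> MixedModelFit:
    """Fit an animal model by AI-REML; see :class:`AnimalModelREML`."""
    est = AnimalModelREML(
        traits=traits,
        include_family=include_family,
        max_iter=max_iter,
        tol=tol,
        start=start,
        seed=seed,
        **kw,
    ).fit(data, ped)
    return est.fit_


def profile_loglik(data, ped, trait, grid):
    """Dense restricted log-likelihood on a grid of (sigma_a2, sigma_e2).

    Deliberately independent of the sparse MME path: builds the dense
    phenotypic covariance V = A_obs * sigma_a2 + I * sigma_e2 from the
    tabular A and evaluates lR directly. Refuses more than 500 records
    (it is a test oracle, not a fitting method).
    """
    sub = data.loc[data[trait].notna()].reset_index(drop=True)
    n = len(sub)
    if n > 500:
        raise ModelError("profile_loglik is a dense oracle; use <= 500 records")
    ped_s = prune_pedigree(ped, sub["id"].unique())
    A = build_A(ped_s).values
    pos = ped_s.positions(sub["id"].tolist())
    A_obs = A[np.ix_(pos, pos)]
    y = sub[trait].to_numpy(float)
    X, _ = _sex_design(
        sub["sex"].astype(str).to_numpy() if "sex" in sub.columns else ["F"] * n
    )
    p = X.shape[1]
    out = []
    for sa2, se2 in grid:
        V = A_obs * sa2 + np.eye(n) * se2
        Vinv = np.linalg.inv(V)
        XtVX = X.T @ Vinv @ X
        beta = np.linalg.solve(XtVX, X.T @ (Vinv @ y))
        r = y - X @ beta
        ypy = float(r @ (Vinv @ y))
        _, ldV = np.linalg.slogdet(V)
        _, ldX = np.linalg.slogdet(XtVX)
        ll = -0.5 * ((n - p) * np.log(_TWO_PI) + ldV + ldX + ypy)
        out.append((sa2, se2, ll))
    return pd.DataFrame(out, columns=["sigma_a2", "sigma_e2", "loglik"])
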