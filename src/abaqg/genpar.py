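"""Genetic-parameter summaries: h2, latent h2, c2, correlations, SEs.

Linear-model heritability is sigma_a2 / (sigma_a2 + sigma_e2). For the
probit sire-dam threshold model (residual fixed at 1), the additive
variance is 2(sigma_s2 + sigma_d2) and the liability-scale phenotypic
variance is sigma_s2 + sigma_d2 + sigma_f2 + 1 — the unit residual
already contains the within-family Mendelian-sampling variance
sigma_s2 + sigma_d2 — giving

    h2_latent = 2 (sigma_s2 + sigma_d2) / (sigma_s2 + sigma_d2 + sigma_f2 + 1)
    c2        =            sigma_f2     / (sigma_s2 + sigma_d2 + sigma_f2 + 1)

and an environmental residual share (1 - sigma_s2 - sigma_d2) / (same
denominator); the three shares sum to one. Standard errors for ratios of
REML components come from the delta method on the inverse
average-information matrix; threshold-model summaries use posterior SDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def h2_linear(sigma_a2: float, sigma_e2: float) -> float:
    """Narrow-sense heritability sigma_a2 / (sigma_a2 + sigma_e2)."""
    if sigma_a2 < 0 or sigma_e2 < 0:
        raise ValueError("variance components must be non-negative")
    tot = sigma_a2 + sigma_e2
    if tot == 0:
        raise ValueError("undefined heritability: both components are zero")
    return sigma_a2 / tot


def h2_latent(sigma_s2: float, sigma_d2: float, sigma_f2: float = 0.0) -> float:
    """Liability-scale heritability of a probit sire-dam model."""
    if min(sigma_s2, sigma_d2, sigma_f2) < 0:
        raise ValueError("variance components must be non-negative")
    return 2.0 * (sigma_s2 + sigma_d2) / (sigma_s2 + sigma_d2 + sigma_f2 + 1.0)


def c2_latent(sigma_f2: float, sigma_s2: float, sigma_d2: float) -> float:
    """Full-sib common-environment share on the liability scale."""
    if min(sigma_s2, sigma_d2, sigma_f2) < 0:
        raise ValueError("variance components must be non-negative")
    return sigma_f2 / (sigma_s2 + sigma_d2 + sigma_f2 + 1.0)


def latent_shares(sigma_s2, sigma_d2, sigma_f2=0.0):
    """(h2, c2, residual environmental share); sums to exactly 1.

    The residual share is (1 - sigma_s2 - sigma_d2)/denominator: the unit
    probit residual minus the Mendelian-sampling half of the additive
    variance. Requires sigma_s2 + sigma_d2 <= 1 (always true when the
    data-generating liability has non-negative environmental variance).
    """
    denom = sigma_s2 + sigma_d2 + sigma_f2 + 1.0
    h2 = 2.0 * (sigma_s2 + sigma_d2) / denom
    c2 = sigma_f2 / denom
    resid = (1.0 - sigma_s2 - sigma_d2) / denom
    return h2, c2, resid


def correlations(G: np.ndarray, E: np.ndarray):
    """Genetic and phenotypic correlation matrices from (co)variances.

    r_g = G_ij / sqrt(G_ii G_jj); r_p uses P = G + E. Entries with a zero
    diagonal are returned as NaN (flagged, not fatal).
    """
    G = np.asarray(G, dtype=float)
    E = np.asarray(E, dtype=float)
    P = G + E
    with np.errstate(divide="ignore", invalid="ignore"):
        dg = np.sqrt(np.diag(G))
        rg = G / np.outer(dg, dg)
        dp = np.sqrt(np.diag(P))
        rp = P / np.outer(dp, dp)
    return rg, rp


def _grad_ratio(kind, comp, params, ij):
    """Gradient of a named ratio w.r.t. the AI parameter vector."""
    grad = np.zeros(len(params))
    if kind == "h2":
        k = ij
        ga = comp["G"][k, k]
        ea = comp["E"][k, k]
        tot = ga + ea
        for m, (term, i, j) in enumerate(params):
            if (i, j) != (k, k):
                continue
            if term == "G":
                grad[m] = ea / tot**2
            elif term == "E":
                grad[m] = -ga / tot**2
        return grad
    if kind in ("rg", "rp"):
        a, b = ij
        if kind == "rg":
            M = comp["G"]

            def sel(term):
                return term == "G"
        else:
            M = comp["G"] + comp["E"]

            def sel(term):
                return term in ("G", "E")
        vaa, vbb, vab = M[a, a], M[b, b], M[a, b]
        r = vab / np.sqrt(vaa * vbb)
        for m, (term, i, j) in enumerate(params):
            if not sel(term):
                continue
            if (i, j) in ((a, b), (b, a)):
                grad[m] = 1.0 / np.sqrt(vaa * vbb)
            elif (i, j) == (a, a):
                grad[m] = -0.5 * r / vaa
            elif (i, j) == (b, b):
                grad[m] = -0.5 * r / vbb
        return grad
    raise ValueError(kind)


def se_delta(fit, quantity: str, traits=None) -> float:
    """Delta-method SE of 'h2:<trait>', 'rg:<t1>,<t2>' or 'rp:<t1>,<t2>'.

    Uses the inverse of the fit's average-information matrix; returns NaN
    when the AI matrix is singular (SE unavailable).
    """
    names = list(fit.traits)
    kind, _, rest = quantity.partition(":")
    comp = {"G": fit.gcov, "E": fit.ecov} if hasattr(fit, "gcov") else None
    if comp is None:
        comp = {"G": fit.gcov_, "E": fit.ecov_}
    try:
        cov = np.linalg.inv(fit.ai_matrix)
    except np.linalg.LinAlgError:
        return float("nan")
    if kind == "h2":
        ij = names.index(rest)
    else:
        a, b = rest.split(",")
        ij = (names.index(a), names.index(b))
    grad = _grad_ratio(kind, comp, fit.ai_params, ij)
    var = float(grad @ cov @ grad)
    return float(np.sqrt(var)) if var >= 0 else float("nan")


@dataclass
class ParamReport:
    """Heritabilities on the diagonal, genetic correlations above it,
    phenotypic correlations below — the conventional compact layout."""

    traits: list
    h2: dict                           # trait -> (estimate, se)
    r_g: dict = field(default_factory=dict)   # (t1,t2) -> (estimate, se)
    r_p: dict = field(default_factory=dict)
    latent_h2: dict = field(default_factory=dict)
    c2: dict = field(default_factory=dict)
    model: str = ""
    n_records: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        k = len(self.traits)
        M = np.full((k, k), np.nan)
        for i, a in enumerate(self.traits):
            if a in self.h2:
                M[i, i] = self.h2[a][0]
            for j in range(i + 1, k):
                b = self.traits[j]
                if (a, b) in self.r_g:
                    M[i, j] = self.r_g[(a, b)][0]
                if (a, b) in self.r_p:
                    M[j, i] = self.r_p[(a, b)][0]
        return pd.DataFrame(M, index=self.traits, columns=self.traits)

    def to_dict(self) -> dict:
        return {
            "traits": list(self.traits),
            "model": self.model,
            "h2": {k: list(v) for k, v in self.h2.items()},
            "latent_h2": {k: list(v) for k, v in self.latent_h2.items()},
            "c2": {k: list(v) for k, v in self.c2.items()},
            "r_g": {f"{a},{b}": list(v) for (a, b), v in self.r_g.items()},
            "r_p": {f"{a},{b}": list(v) for (a, b), v in self.r_p.items()},
            "n_records": dict(self.n_records),
            "flags": list(self.flags),
        }

    @classmethod
    def from_dict(cls, d) -> "ParamReport":
        def unkey(s):
            a, _, b = s.partition(",")
            return (a, b)

        return cls(
            traits=list(d["traits"]),
            model=d.get("model", ""),
            h2={k: tuple(v) for k, v in d["h2"].items()},
            latent_h2={k: tuple(v) for k, v in d.get("latent_h2", {}).items()},
            c2={k: tuple(v) for k, v in d.get("c2", {}).items()},
            r_g={unkey(k): tuple(v) for k, v in d.get("r_g", {}).items()},
            r_p={unkey(k): tuple(v) for k, v in d.get("r_p", {}).items()},
            n_records=d.get("n_records", {}),
            flags=list(d.get("flags", [])),
        )


def report_from_fit(fit, model: str = "") -> ParamReport:
    """Build a ParamReport (with delta-method SEs) from a REML fit.

    Point estimates outside the admissible range (|r| > 1 from sampling
    noise) are clipped to the boundary and flagged.
    """
    names = list(fit.traits)
    rg, rp = correlations(fit.gcov, fit.ecov)
    rep = ParamReport(traits=names, h2={}, model=model, n_records=dict(fit.n_records))
    for i, a in enumerate(names):
        rep.h2[a] = (
            h2_linear(fit.gcov[i, i], fit.ecov[i, i]),
            se_delta(fit, f"h2:{a}"),
        )
        for j in range(i + 1, len(names)):
            b = names[j]
            for which, M in (("r_g", rg), ("r_p", rp)):
                val = M[i, j]
                if np.isfinite(val) and abs(val) > 1.0:
                    rep.flags.append(f"{which}({a},{b}) clipped from {val:.3f}")
                    val = float(np.clip(val, -1.0, 1.0))
                se = se_delta(fit, f"{'rg' if which == 'r_g' else 'rp'}:{a},{b}")
                getattr(rep, which)[(a, b)] = (float(val), se)
    return rep
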