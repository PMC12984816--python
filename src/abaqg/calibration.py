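"""Default generating parameters for the simulated abalone population.

Trait means/SDs and record counts follow the harvest descriptive
statistics of the emulated study; heritabilities and genetic/phenotypic
correlations follow its multivariate and bivariate REML estimates; the
foot-color liability follows its threshold-model latent heritability.
Residual correlations are derived from the phenotypic ones via
r_e = (r_p * sp_i * sp_j - r_g * sa_i * sa_j) / (se_i * se_j).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .simulate import (
    MissingnessSpec,
    OrdinalSpec,
    Trait,
    TraitParams,
)

TRAIT_ORDER = [
    "SL_6", "SL_18", "SL_24", "SL_30", "Tww", "Fc", "Mw", "My", "survival",
]

# name -> (mean, phenotypic SD, h2)
_MOMENTS = {
    "SL_6": (23.85, 2.68, 0.71),
    "SL_18": (46.53, 4.33, 0.62),
    "SL_24": (62.64, 4.46, 0.45),
    "SL_30": (76.68, 5.34, 0.48),
    "Tww": (63.36, 14.6, 0.48),
    "Mw": (30.64, 13.03, 0.31),
    "My": (0.51, 0.04, 0.14),
}

LATENT_H2 = {"Fc": 0.46, "survival": 0.15}

# Foot-color target moments on the 1-4 score scale
FC_MEAN, FC_SD = 1.42, 0.64

# genetic correlations (printed where available, chained through Tww
# elsewhere; survival uncorrelated)
_RG = {
    ("SL_6", "SL_18"): 0.51,
    ("SL_6", "SL_24"): 0.31,
    ("SL_6", "SL_30"): 0.34,
    ("SL_6", "Tww"): 0.31,
    ("SL_18", "SL_24"): 0.31,
    ("SL_18", "SL_30"): 0.46,
    ("SL_18", "Tww"): 0.38,
    ("SL_24", "SL_30"): 0.71,
    ("SL_24", "Tww"): 0.53,
    ("SL_30", "Tww"): 0.90,
    ("Tww", "Fc"): -0.04,
    ("Tww", "Mw"): 0.92,
    ("Tww", "My"): -0.60,
}

# phenotypic correlations (printed)
_RP = {
    ("SL_6", "SL_18"): 0.38,
    ("SL_6", "SL_24"): 0.30,
    ("SL_6", "SL_30"): 0.24,
    ("SL_6", "Tww"): 0.22,
    ("SL_18", "SL_24"): 0.49,
    ("SL_18", "SL_30"): 0.44,
    ("SL_18", "Tww"): 0.37,
    ("SL_24", "SL_30"): 0.63,
    ("SL_24", "Tww"): 0.50,
    ("SL_30", "Tww"): 0.82,
    ("Tww", "Fc"): -0.01,
    ("Tww", "Mw"): 0.89,
    ("Tww", "My"): -0.10,
}

# modest sexual dimorphism on size/weight traits, as a fraction of the
# phenotypic SD; the raw pattern (F, M, U) is re-centered to zero mean
# under the sex frequencies inside Trait.from_moments
_GENDER_PATTERN = np.array([1.0, -1.3, -0.4])
_GENDER_SCALE = 0.08
_GENDER_TRAITS = {"SL_6", "SL_18", "SL_24", "SL_30", "Tww", "Mw"}


def solve_category_probs(
    mean: float, sd: float, tail_ratio: float = 0.5
) -> np.ndarray:
    """Four-category probabilities with given mean/SD and mode at 1.

    Matching a mean and an SD leaves one degree of freedom; it is fixed by
    the tail convention p4 = tail_ratio * p3 (the two darkest foot-color
    classes are rare, with the darkest rarer still).
    """
    r = tail_ratio
    M = np.array(
        [
            [1.0, 1.0, 1.0 + r],
            [1.0, 2.0, 3.0 + 4.0 * r],
            [1.0, 4.0, 9.0 + 16.0 * r],
        ]
    )
    rhs = np.array([1.0, mean, sd**2 + mean**2])
    p1, p2, p3 = np.linalg.solve(M, rhs)
    p = np.array([p1, p2, p3, r * p3])
    if np.any(p <= 0) or np.argmax(p) != 0:
        raise ValueError(
            f"no valid 4-category distribution with mean={mean}, sd={sd}"
        )
    return p


def solve_cutpoints(
    mean: float, sd: float, sigma_latent: float, tail_ratio: float = 0.5
) -> np.ndarray:
    """Liability cutpoints reproducing the target score mean/SD."""
    p = solve_category_probs(mean, sd, tail_ratio)
    return stats.norm.ppf(np.cumsum(p)[:3]) * sigma_latent


def _psd_corr(R: np.ndarray) -> np.ndarray:
    """Eigen-clip a correlation matrix to PSD and restore the unit diagonal."""
    w, V = np.linalg.eigh(R)
    if w.min() >= 1e-10:
        return R
    w = np.maximum(w, 1e-6)
    R2 = (V * w) @ V.T
    d = np.sqrt(np.diag(R2))
    R2 = R2 / np.outer(d, d)
    np.fill_diagonal(R2, 1.0)
    return (R2 + R2.T) / 2.0


def default_calibration():
    """Packaged defaults: (TraitParams, OrdinalSpec, MissingnessSpec)."""
    traits = []
    for name in TRAIT_ORDER:
        if name in LATENT_H2:
            traits.append(Trait.latent(name, LATENT_H2[name]))
        else:
            mean, sd, h2 = _MOMENTS[name]
            gender = (
                _GENDER_PATTERN * _GENDER_SCALE * sd
                if name in _GENDER_TRAITS
                else (0.0, 0.0, 0.0)
            )
            traits.append(
                Trait.from_moments(name, mean, sd, h2, gender_effects=gender)
            )
    k = len(traits)
    by_name = {t.name: i for i, t in enumerate(traits)}

    rg = np.eye(k)

    def set_sym(M, a, b, v):
        i, j = by_name[a], by_name[b]
        M[i, j] = M[j, i] = v

    for (a, b), v in _RG.items():
        set_sym(rg, a, b, v)
    # unknown pairs: chain through Tww (r_ij := r_iT * r_jT); leaves
    # survival independent of everything
    for a in ("SL_6", "SL_18", "SL_24", "SL_30"):
        for b in ("Fc", "Mw", "My"):
            set_sym(rg, a, b, _RG[(a, "Tww")] * _RG[("Tww", b)])
    set_sym(rg, "Fc", "Mw", _RG[("Tww", "Fc")] * _RG[("Tww", "Mw")])
    set_sym(rg, "Fc", "My", _RG[("Tww", "Fc")] * _RG[("Tww", "My")])
    # meat weight tracks total weight genetically (0.92), so the negative
    # yield correlation with weight must carry over to meat weight too
    set_sym(rg, "Mw", "My", _RG[("Tww", "Mw")] * _RG[("Tww", "My")])
    rg = _psd_corr(rg)

    re = np.eye(k)
    for (a, b), rp in _RP.items():
        i, j = by_name[a], by_name[b]
        ti, tj = traits[i], traits[j]
        spi = np.sqrt(ti.sigma_a2 + ti.sigma_e2)
        spj = np.sqrt(tj.sigma_a2 + tj.sigma_e2)
        cov_g = rg[i, j] * np.sqrt(ti.sigma_a2 * tj.sigma_a2)
        r_e = (rp * spi * spj - cov_g) / np.sqrt(ti.sigma_e2 * tj.sigma_e2)
        set_sym(re, a, b, float(np.clip(r_e, -0.95, 0.95)))
    re = _psd_corr(re)

    params = TraitParams(traits=traits, r_g=rg, r_e=re)
    fc = traits[by_name["Fc"]]
    sigma_lat = np.sqrt(fc.sigma_a2 + fc.sigma_e2)
    ordinal = OrdinalSpec(
        n_categories=4, cutpoints=solve_cutpoints(FC_MEAN, FC_SD, sigma_lat)
    )
    return params, ordinal, MissingnessSpec()
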