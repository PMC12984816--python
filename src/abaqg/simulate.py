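"""Synthetic population generator for the nested abalone mating design.

Emulates a single-generation aquaculture breeding study: sires mated to
one or two dams each, full-sib families reared together, offspring tagged
and phenotyped at harvest for growth, an ordinal foot-color score, a
dissection subsample for meat traits, and heritable survival. Breeding
values follow the pedigree covariance A (x) G exactly via Mendelian
sampling; phenotypes follow y = mu + gender + a + f + e.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import (
    Pedigree,
    UNKNOWN,
    family_structure,
    mendelian_variance_scale,
)

# Sex class frequencies among identified survivors (female, male,
# unidentifiable); sex is assigned i.i.d., not balanced within family.
SEX_PROBS = np.array([4210.0, 2983.0, 898.0])
SEX_PROBS = SEX_PROBS / SEX_PROBS.sum()


class DesignError(ValueError):
    """Raised for infeasible mating-design specifications."""


@dataclass
class DesignSpec:
    """Nested mating design: each sire serves one or two dams."""

    n_sires: int = 81
    n_dams: int = 124
    n_families: int = 141
    offspring_per_family: int = 80
    seed: int = 0

    def validate(self) -> None:
        n_two = self.n_families - self.n_sires
        n_reuse = self.n_families - self.n_dams
        if min(self.n_sires, self.n_dams, self.n_families,
               self.offspring_per_family) < 1:
            raise DesignError("all design counts must be positive")
        if n_two < 0:
            raise DesignError("more sires than families")
        if self.n_families > 2 * self.n_sires:
            raise DesignError(
                f"{self.n_families} families infeasible with "
                f"{self.n_sires} sires at <=2 dams per sire"
            )
        if n_reuse < 0:
            raise DesignError("more dams than families: some dams unused")
        if n_reuse > self.n_dams:
            raise DesignError("dam reuse exceeds two families per dam")


@dataclass
class Trait:
    """A trait's generating parameters.

    ``sigma_a2``/``sigma_f2``/``sigma_e2`` are the additive, full-sib
    common environment and residual variances; ``gender_effects`` are the
    three fixed sex-class effects (F, M, U), conventionally weighted to
    zero mean under the sex frequencies so the population mean stays
    ``mean``. ``kind`` is 'continuous' or 'latent' (liability traits:
    foot color, survival).
    """

    name: str
    mean: float
    sigma_a2: float
    sigma_e2: float
    sigma_f2: float = 0.0
    gender_effects: tuple = (0.0, 0.0, 0.0)
    kind: str = "continuous"

    @property
    def phenotypic_var(self) -> float:
        g = np.asarray(self.gender_effects)
        var_g = float(np.sum(SEX_PROBS * g**2) - np.sum(SEX_PROBS * g) ** 2)
        return self.sigma_a2 + self.sigma_f2 + self.sigma_e2 + var_g

    @property
    def h2(self) -> float:
        return self.sigma_a2 / (self.sigma_a2 + self.sigma_e2)

    @classmethod
    def from_moments(
        cls, name, mean, sd, h2, c2=0.0, gender_effects=(0.0, 0.0, 0.0)
    ) -> "Trait":
        """Partition a phenotypic variance sd^2 into components.

        Gender variance is carved out first so the simulated phenotypic SD
        reproduces ``sd`` and h2 = sigma_a2/(sigma_a2+sigma_e2) holds
        exactly as the generating truth.
        """
        g = np.asarray(gender_effects, dtype=float)
        g = tuple(g - np.sum(SEX_PROBS * g))
        var_g = float(np.sum(SEX_PROBS * np.asarray(g) ** 2))
        rem = sd**2 - var_g
        if rem <= 0:
            raise ValueError(f"gender effects exceed phenotypic variance for {name}")
        sigma_f2 = c2 * rem
        core = rem - sigma_f2
        return cls(
            name=name,
            mean=mean,
            sigma_a2=h2 * core,
            sigma_e2=(1.0 - h2) * core,
            sigma_f2=sigma_f2,
            gender_effects=g,
        )

    @classmethod
    def latent(cls, name, h2_latent, sigma_f2=0.0) -> "Trait":
        """Liability trait normalized so a sire-dam fit has unit residual.

        With additive liability variance sigma_a2 and environmental
        residual sigma_e2 = 1 - sigma_a2/2, the sire-dam model's residual
        (environment + Mendelian sampling) is exactly 1, and the standard
        latent heritability 2(sigma_s2+sigma_d2)/(sigma_s2+sigma_d2+
        sigma_f2+1) equals ``h2_latent``.
        """
        denom = 1.0 - h2_latent / 2.0
        sigma_a2 = h2_latent * (1.0 + sigma_f2) / denom
        return cls(
            name=name,
            mean=0.0,
            sigma_a2=sigma_a2,
            sigma_e2=1.0 - sigma_a2 / 2.0,
            sigma_f2=sigma_f2,
            kind="latent",
        )


@dataclass
class TraitParams:
    """Joint generating parameters: traits plus cross-trait correlations."""

    traits: list              # of Trait, defines order
    r_g: np.ndarray           # genetic correlation matrix
    r_e: np.ndarray           # residual correlation matrix

    def __post_init__(self):
        self.r_g = np.asarray(self.r_g, dtype=float)
        self.r_e = np.asarray(self.r_e, dtype=float)
        k = len(self.traits)
        for name, m in (("r_g", self.r_g), ("r_e", self.r_e)):
            if m.shape != (k, k):
                raise ValueError(f"{name} must be {k}x{k}")
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")

    @property
    def names(self):
        return [t.name for t in self.traits]

    def index(self, name) -> int:
        return self.names.index(name)

    def G(self) -> np.ndarray:
        sa = np.sqrt([t.sigma_a2 for t in self.traits])
        return self.r_g * np.outer(sa, sa)

    def E(self) -> np.ndarray:
        se = np.sqrt([t.sigma_e2 for t in self.traits])
        return self.r_e * np.outer(se, se)

    def subset(self, names) -> "TraitParams":
        ix = [self.index(n) for n in names]
        return TraitParams(
            traits=[self.traits[i] for i in ix],
            r_g=self.r_g[np.ix_(ix, ix)],
            r_e=self.r_e[np.ix_(ix, ix)],
        )

    def to_dict(self) -> dict:
        return {
            "traits": [asdict(t) for t in self.traits],
            "r_g": self.r_g.tolist(),
            "r_e": self.r_e.tolist(),
        }


@dataclass
class OrdinalSpec:
    """Ordinal categorization of the foot-color liability."""

    n_categories: int = 4
    cutpoints: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 2.0]))

    def __post_init__(self):
        self.cutpoints = np.asarray(self.cutpoints, dtype=float)
        if len(self.cutpoints) != self.n_categories - 1:
            raise ValueError("need n_categories - 1 cutpoints")
        if np.any(np.diff(self.cutpoints) <= 0):
            raise ValueError("cutpoints must be strictly increasing")

    def categorize(self, liability: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.cutpoints, liability, side="right") + 1


@dataclass
class MeatSubsample:
    n_families_sampled: int = 30
    min_per_family: int = 20
    max_per_family: int = 25
    total: int = 680


@dataclass
class MissingnessSpec:
    """Observation process applied after simulation.

    Survival comes from the heritable liability trait; tag retention and
    per-trait recording are i.i.d. thinning. Defaults reproduce the
    harvest record counts of the emulated study (survival 79.84% of
    tagged, 88.84% tag retention, per-trait Ns of ~7900 for growth/color).
    """

    survival_rate: float = 9006.0 / 11280.0
    tag_retention: float = 8001.0 / 9006.0
    trait_retention: dict = field(
        default_factory=lambda: {
            "SL_6": 6259.0 / 8001.0,
            "SL_18": 5492.0 / 8001.0,
            "SL_24": 6843.0 / 8001.0,
            "SL_30": 7948.0 / 8001.0,
            "Tww": 7993.0 / 8001.0,
            "Fc": 7913.0 / 8001.0,
        }
    )
    meat_subsample: MeatSubsample | None = field(default_factory=MeatSubsample)


@dataclass
class SimulatedPopulation:
    pedigree: Pedigree
    breeding_values: pd.DataFrame      # individuals x traits (true values)
    phenotypes: pd.DataFrame           # observed table with missing entries
    params: TraitParams
    family_of: pd.Series
    sex: pd.Series

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.pedigree.write_csv(outdir / "pedigree.csv")
        self.phenotypes.to_csv(outdir / "phenotypes.csv", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.params.to_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
# Design generation


def generate_design(spec: DesignSpec, rng=None) -> Pedigree:
    """Pedigree realizing the nested design.

    ``n_families - n_sires`` sires serve two dams; ``n_families - n_dams``
    dams are shared between two sires (creating maternal half-sib links),
    the unique reconciliation of the default counts 81/124/141. Offspring
    sex is drawn i.i.d. at the observed class frequencies.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n_two = spec.n_families - spec.n_sires
    sire_ids = [f"S{k + 1:03d}" for k in range(spec.n_sires)]
    dam_ids = [f"D{k + 1:03d}" for k in range(spec.n_dams)]
    # dam slot sequence: every dam once, then the reused dams again; slots
    # are consumed two per double-mated sire, then one per single-mated
    # sire, which keeps each reused dam on two distinct sires.
    n_reuse = spec.n_families - spec.n_dams
    slots = list(range(spec.n_dams)) + list(range(n_reuse))
    pairs = []
    cursor = 0
    for s in range(spec.n_sires):
        take = 2 if s < n_two else 1
        for _ in range(take):
            pairs.append((s, slots[cursor]))
            cursor += 1
    if len(set(pairs)) != spec.n_families:
        raise DesignError("could not realize distinct sire x dam pairs")

    ids, sires, dams, sexes = [], [], [], []
    for s in sire_ids:
        ids.append(s); sires.append("0"); dams.append("0"); sexes.append("M")
    for d in dam_ids:
        ids.append(d); sires.append("0"); dams.append("0"); sexes.append("F")
    sex_draw = rng.choice(
        ["F", "M", "U"],
        size=spec.n_families * spec.offspring_per_family,
        p=SEX_PROBS,
    )
    k = 0
    for fam, (s, d) in enumerate(pairs):
        for j in range(spec.offspring_per_family):
            ids.append(f"I{fam + 1:03d}_{j + 1:03d}")
            sires.append(sire_ids[s])
            dams.append(dam_ids[d])
            sexes.append(sex_draw[k])
            k += 1
    df = pd.DataFrame({"id": ids, "sire": sires, "dam": dams, "sex": sexes})
    from .pedigree import pedigree_from_frame

    return pedigree_from_frame(df)


# ---------------------------------------------------------------------------
# Breeding values


def simulate_breeding_values(
    ped: Pedigree, params: TraitParams, rng
) -> np.ndarray:
    """Multitrait breeding values with covariance A (x) G.

    Founders are drawn N(0, G); descendants get the parent average plus a
    Mendelian-sampling deviation scaled by d_i = 0.5 - 0.25(F_s + F_d)
    (0.75/1 with one/both parents unknown), per generation, vectorized.
    """
    G = params.G()
    eig = np.linalg.eigvalsh(G)
    if eig.min() < -1e-8 * max(1.0, eig.max()):
        raise ValueError(f"genetic covariance not PSD; eigenvalues {eig}")
    L = np.linalg.cholesky(G + 1e-12 * np.eye(len(G)))
    L[np.diag(G) == 0, :] = 0.0  # zero-variance traits stay exactly zero
    n, t = len(ped), len(params.traits)
    dvec = mendelian_variance_scale(ped)
    a = np.zeros((n, t))
    z = rng.standard_normal((n, t)) @ L.T
    for depth in range(ped.generation.max() + 1):
        idx = np.flatnonzero(ped.generation == depth)
        pa = np.zeros((len(idx), t))
        s, d = ped.sire[idx], ped.dam[idx]
        has_s, has_d = s != UNKNOWN, d != UNKNOWN
        pa[has_s] += 0.5 * a[s[has_s]]
        pa[has_d] += 0.5 * a[d[has_d]]
        a[idx] = pa + z[idx] * np.sqrt(dvec[idx])[:, None]
    return a


# ---------------------------------------------------------------------------
# Phenotypes


def _draw_meat_subsample(alive_ids, family_of, sub: MeatSubsample, rng):
    """Stratified dissection subsample: fixed total from sampled families."""
    fam = family_of.loc[alive_ids]
    sizes = fam.value_counts()
    eligible = sizes[sizes >= sub.min_per_family].index.to_numpy()
    if len(eligible) == 0:
        return np.array([], dtype=object)
    # smaller designs than the default study scale the subsample down
    # proportionally instead of failing
    n_fams = min(sub.n_families_sampled, len(eligible))
    total = int(round(sub.total * n_fams / sub.n_families_sampled))
    eligible = np.sort(eligible)
    chosen = rng.choice(eligible, size=n_fams, replace=False)
    base = total // n_fams
    counts = np.full(n_fams, base)
    extra = total - base * n_fams
    bump = np.zeros(n_fams, dtype=int)
    # spread the remainder one-at-a-time up to the per-family cap
    room = sub.max_per_family - base
    order = rng.permutation(n_fams)
    k = 0
    while extra > 0:
        f = order[k % len(order)]
        if bump[f] < room:
            bump[f] += 1
            extra -= 1
        k += 1
    counts = counts + bump
    picked = []
    for f, c in zip(chosen, counts):
        members = np.sort(fam.index[(fam == f).to_numpy()].to_numpy())
        picked.append(rng.choice(members, size=min(c, len(members)), replace=False))
    return np.concatenate(picked)


def simulate_phenotypes(
    ped: Pedigree,
    breeding_values: np.ndarray,
    params: TraitParams,
    ordinal: OrdinalSpec,
    miss: MissingnessSpec,
    rng,
    meat_mode: str = "composite",
) -> pd.DataFrame:
    """Phenotype table for the tagged offspring.

    Continuous traits: y = mean + gender + a + f + e with residuals drawn
    jointly from E. Foot color is the ordinal category of its liability;
    survival is the binary threshold of its liability at the quantile
    matching the target survival rate. Missingness: death hides all traits
    but survival, tag loss hides everything but survival, growth/color
    traits are thinned to their target record counts, and meat traits are
    observed on the stratified dissection subsample of survivors only.
    In 'composite' mode Mw is derived as My * Tww (so My = Mw/Tww exactly);
    in 'direct' mode Mw is its own simulated Gaussian trait.
    """
    names = params.names
    fammap = family_structure(ped)
    offspring = np.flatnonzero((ped.sire != UNKNOWN) & (ped.dam != UNKNOWN))
    n, t = len(offspring), len(names)

    sex_code = pd.Categorical(
        ped.sex[offspring], categories=["F", "M", "U"]
    ).codes
    fam_label = fammap.family_of.iloc[offspring]
    fam_codes, fam_uniques = pd.factorize(fam_label)

    E = params.E()
    Le = np.linalg.cholesky(E + 1e-12 * np.eye(t))
    resid = rng.standard_normal((n, t)) @ Le.T
    f_eff = np.zeros((n, t))
    for j, tr in enumerate(params.traits):
        if tr.sigma_f2 > 0:
            per_fam = rng.standard_normal(len(fam_uniques)) * np.sqrt(tr.sigma_f2)
            f_eff[:, j] = per_fam[fam_codes]

    means = np.array([tr.mean for tr in params.traits])
    geff = np.array([tr.gender_effects for tr in params.traits])  # t x 3
    y = (
        means[None, :]
        + geff.T[sex_code]
        + breeding_values[offspring]
        + f_eff
        + resid
    )
    raw = pd.DataFrame(y.copy(), columns=names)  # pre-missingness snapshot
    table = pd.DataFrame(y, columns=names)
    table.insert(0, "id", ped.ids[offspring])
    table.insert(1, "family", fam_label.to_numpy())
    table.insert(2, "sex", ped.sex[offspring])

    # ordinal foot color from its liability column
    if "Fc" in names:
        table["Fc"] = ordinal.categorize(table["Fc"].to_numpy()).astype(float)

    # heritable survival: alive iff liability below the rate quantile
    if "survival" in names:
        tr = params.traits[params.index("survival")]
        tau = stats.norm.ppf(miss.survival_rate) * np.sqrt(tr.phenotypic_var)
        alive = table["survival"].to_numpy() < tau
        table["survival"] = alive.astype(float)
    else:
        alive = rng.random(n) < miss.survival_rate

    tagged = rng.random(n) < miss.tag_retention
    observable = alive & tagged

    if meat_mode == "composite" and "My" in names and "Tww" in names:
        table["Mw"] = table["My"] * table["Tww"]
    elif meat_mode != "direct" and "My" in names:
        raise ValueError(f"unknown meat_mode {meat_mode!r}")

    for name in names:
        if name == "survival":
            continue
        keep = observable.copy()
        if name in miss.trait_retention:
            keep &= rng.random(n) < miss.trait_retention[name]
        if name in ("Mw", "My") and miss.meat_subsample is not None:
            keep = np.zeros(n, dtype=bool)
        table.loc[~keep, name] = np.nan
    if ("Mw" in table.columns or "My" in names) and miss.meat_subsample is not None:
        ids_alive = table["id"].to_numpy()[observable]
        fam_series = pd.Series(
            table["family"].to_numpy(), index=table["id"].to_numpy()
        )
        picked = _draw_meat_subsample(
            ids_alive, fam_series, miss.meat_subsample, rng
        )
        sel = table["id"].isin(picked).to_numpy()
        for name in ("Mw", "My"):
            if name in table.columns:
                vals = (
                    raw["My"].to_numpy() * raw["Tww"].to_numpy()
                    if (name == "Mw" and meat_mode == "composite")
                    else raw[name].to_numpy()
                )
                col = np.full(n, np.nan)
                col[sel] = vals[sel]
                table[name] = col
    return table


def simulate_population(
    design: DesignSpec,
    params: TraitParams = None,
    ordinal: OrdinalSpec = None,
    miss: MissingnessSpec = None,
    seed=None,
    traits=None,
    meat_mode: str = "composite",
) -> SimulatedPopulation:
    """One full simulated study: design, breeding values, phenotypes."""
    from .calibration import default_calibration

    cal_params, cal_ordinal, cal_miss = default_calibration()
    params = params if params is not None else cal_params
    ordinal = ordinal if ordinal is not None else cal_ordinal
    miss = miss if miss is not None else cal_miss
    if traits is not None:
        params = params.subset(traits)
    seed = design.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    ped = generate_design(design, rng)
    a = simulate_breeding_values(ped, params, rng)
    phen = simulate_phenotypes(
        ped, a, params, ordinal, miss, rng, meat_mode=meat_mode
    )
    fammap = family_structure(ped)
    return SimulatedPopulation(
        pedigree=ped,
        breeding_values=pd.DataFrame(a, index=ped.ids, columns=params.names),
        phenotypes=phen,
        params=params,
        family_of=fammap.family_of,
        sex=pd.Series(ped.sex, index=ped.ids),
    )
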