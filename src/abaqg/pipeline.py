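"""End-to-end orchestration: descriptives, the standard model set, and
replicate-based parameter-recovery scoring.

The standard analysis set mirrors the emulated study: one five-trait
multivariate REML model (shell lengths at 6/18/24/30 months + total wet
weight), three bivariates pairing total wet weight with foot color, meat
weight and meat yield, a univariate linear model and a threshold model
for foot color, and a binary threshold model for survival.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import default_calibration
from .genpar import ParamReport, report_from_fit, latent_shares
from .pedigree import Pedigree, family_structure, read_pedigree
from .reml import fit_reml
from .simulate import DesignSpec, SimulatedPopulation, simulate_population
from .threshold import fit_threshold, linear_score_fit

log = logging.getLogger("abaqg")

MODEL_SET = (
    "multi5", "biv_fc", "biv_mw", "biv_my",
    "lin_fc", "thresh_fc", "thresh_survival",
)

MULTI5_TRAITS = ["SL_6", "SL_18", "SL_24", "SL_30", "Tww"]


@dataclass
class RunConfig:
    mode: str = "simulate+fit"
    design: DesignSpec = field(default_factory=DesignSpec)
    models: tuple = MODEL_SET
    replicates: int = 1
    seed: int = 0
    meat_mode: str = "composite"
    chain_length: int = 20000
    burn_in: int = 5000
    thin: int = 10

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        design = DesignSpec(**raw.pop("design", {}))
        models = tuple(raw.pop("models", MODEL_SET))
        bad = set(models) - set(MODEL_SET)
        if bad:
            raise ValueError(f"unknown models {sorted(bad)}")
        cfg = cls(design=design, models=models, **raw)
        if cfg.replicates < 1:
            raise ValueError("replicates must be >= 1")
        return cfg


def descriptive_stats(data: pd.DataFrame, traits=None) -> pd.DataFrame:
    """Missing-aware N/mean/SD/min/max per trait column."""
    if traits is None:
        traits = [
            c for c in data.columns if c not in ("id", "family", "sex")
        ]
    rows = []
    for tr in traits:
        col = pd.to_numeric(data[tr], errors="coerce")
        n = int(col.notna().sum())
        if n == 0:
            rows.append((tr, 0, np.nan, np.nan, np.nan, np.nan))
        else:
            rows.append(
                (tr, n, col.mean(), col.std(ddof=1) if n > 1 else 0.0,
                 col.min(), col.max())
            )
    return pd.DataFrame(
        rows, columns=["trait", "N", "mean", "SD", "min", "max"]
    ).set_index("trait")


def attach_parentage(data: pd.DataFrame, ped: Pedigree) -> pd.DataFrame:
    """Add sire/dam (and family if absent) columns looked up from the pedigree."""
    fam = family_structure(ped)
    out = data.copy()
    ids = out["id"]
    out["sire"] = fam.sire_of.reindex(ids).to_numpy()
    out["dam"] = fam.dam_of.reindex(ids).to_numpy()
    if "family" not in out.columns:
        out["family"] = fam.family_of.reindex(ids).to_numpy()
    return out


def _reml_stage(data, ped, traits, model, seed):
    fit = fit_reml(data, ped, traits=traits, seed=seed)
    rep = report_from_fit(fit, model=model)
    return {"report": rep.to_dict(), "fit": fit.to_dict()}


def run_standard_suite(
    data: pd.DataFrame,
    ped: Pedigree,
    models=MODEL_SET,
    seed: int = 0,
    chain_length: int = 20000,
    burn_in: int = 5000,
    thin: int = 10,
    outdir=None,
) -> dict:
    """Run the standard analysis set on a phenotype table + pedigree.

    Returns a report bundle (plain dict, JSON-serializable). Any stage
    failure marks the bundle partial and records the error; completed
    stages are kept.
    """
    bundle = {"models": {}, "stages": [], "partial": False}
    t0 = time.time()
    bundle["descriptives"] = json.loads(
        descriptive_stats(data).to_json(orient="index")
    )
    full = attach_parentage(data, ped)

    def stage(name, fn):
        if name != "descriptives" and name not in models:
            return
        t = time.time()
        try:
            bundle["models"][name] = fn()
            status = "ok"
        except Exception as exc:  # noqa: BLE001 - stage log keeps going
            bundle["partial"] = True
            status = f"failed: {exc}"
            log.warning("stage %s failed: %s", name, exc)
        bundle["stages"].append(
            {"stage": name, "status": status, "seconds": round(time.time() - t, 2)}
        )

    stage("multi5", lambda: _reml_stage(data, ped, MULTI5_TRAITS, "multi5", seed))
    stage("biv_fc", lambda: _reml_stage(data, ped, ["Tww", "Fc"], "biv_fc", seed))
    stage("biv_mw", lambda: _reml_stage(data, ped, ["Tww", "Mw"], "biv_mw", seed))
    stage("biv_my", lambda: _reml_stage(data, ped, ["Tww", "My"], "biv_my", seed))

    def lin_fc():
        fit = linear_score_fit(data, ped, response="Fc", seed=seed)
        return {"report": report_from_fit(fit, model="lin_fc").to_dict()}

    stage("lin_fc", lin_fc)

    def _thresh(response):
        fit = fit_threshold(
            full,
            response=response,
            chain_length=chain_length,
            burn_in=burn_in,
            thin=thin,
            seed=seed,
        )
        return {"threshold": fit.to_dict()}

    stage("thresh_fc", lambda: _thresh("Fc"))
    stage("thresh_survival", lambda: _thresh("survival"))

    bundle["seconds_total"] = round(time.time() - t0, 2)
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def write_bundle(bundle: dict, outdir) -> None:
    outdir = Path(outdir)
    (outdir / "tables").mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=1, sort_keys=True)
    pd.DataFrame(bundle["descriptives"]).T.to_csv(outdir / "tables" / "descriptives.csv")
    for name, res in bundle["models"].items():
        if "report" in res:
            rep = ParamReport.from_dict(res["report"])
            rep.table().to_csv(outdir / "tables" / f"{name}.csv")


# ---------------------------------------------------------------------------
# Replicate-based parameter recovery


def _truth_for(pop: SimulatedPopulation, trait):
    tr = pop.params.traits[pop.params.index(trait)]
    return tr.h2


def recovery_study(
    config: RunConfig,
    targets=("h2:SL_30", "rg:Tww,Mw", "h2_latent:Fc"),
    chain_kwargs=None,
) -> pd.DataFrame:
    """Replicate simulate->fit->score loop.

    Each target is 'h2:<trait>', 'rg:<t1>,<t2>' (bivariate REML) or
    'h2_latent:<trait>' (threshold model). Returns per-target truth, the
    replicate mean/SD of the estimates, bias, and the coverage of
    estimate +/- 2 SE(delta/posterior) intervals.
    """
    chain_kwargs = chain_kwargs or {}
    rows = {t: [] for t in targets}
    ss = np.random.SeedSequence(config.seed)
    for rep, child in enumerate(ss.spawn(config.replicates)):
        seed = int(child.generate_state(1)[0] % (2**31))
        for target in targets:
            kind, _, rest = target.partition(":")
            if kind == "h2":
                pop = simulate_population(
                    config.design, traits=[rest], seed=seed,
                    meat_mode="direct",
                )
                fit = fit_reml(pop.phenotypes, pop.pedigree, traits=[rest], seed=seed)
                est = fit.h2[0]
                from .genpar import se_delta

                se = se_delta(fit, f"h2:{rest}")
                truth = _truth_for(pop, rest)
            elif kind == "rg":
                a, b = rest.split(",")
                pop = simulate_population(
                    config.design, traits=[a, b], seed=seed, meat_mode="direct"
                )
                fit = fit_reml(pop.phenotypes, pop.pedigree, traits=[a, b], seed=seed)
                from .genpar import correlations, se_delta

                rg, _ = correlations(fit.gcov, fit.ecov)
                est = float(rg[0, 1])
                se = se_delta(fit, f"rg:{a},{b}")
                i, j = pop.params.index(a), pop.params.index(b)
                truth = float(pop.params.r_g[i, j])
            elif kind == "h2_latent":
                pop = simulate_population(
                    config.design, traits=[rest, "survival"], seed=seed
                )
                data = attach_parentage(pop.phenotypes, pop.pedigree)
                tfit = fit_threshold(
                    data, response=rest, seed=seed,
                    chain_length=chain_kwargs.get("chain_length", config.chain_length),
                    burn_in=chain_kwargs.get("burn_in", config.burn_in),
                    thin=chain_kwargs.get("thin", config.thin),
                )
                est, se = tfit.h2_latent
                tr = pop.params.traits[pop.params.index(rest)]
                truth = latent_shares(tr.sigma_a2 / 4, tr.sigma_a2 / 4, tr.sigma_f2)[0]
            else:
                raise ValueError(f"unknown target kind {kind!r}")
            rows[target].append((truth, est, se))
    out = []
    for target, triples in rows.items():
        truth = triples[0][0]
        ests = np.array([t[1] for t in triples])
        ses = np.array([t[2] for t in triples])
        cover = np.mean(
            [(truth >= e - 2 * s) and (truth <= e + 2 * s)
             for e, s in zip(ests, ses) if np.isfinite(s)]
        ) if np.isfinite(ses).any() else np.nan
        out.append(
            {
                "target": target,
                "truth": truth,
                "mean_estimate": ests.mean(),
                "empirical_sd": ests.std(ddof=1) if len(ests) > 1 else np.nan,
                "bias": ests.mean() - truth,
                "coverage_2se": cover,
                "replicates": len(ests),
            }
        )
    return pd.DataFrame(out).set_index("target")


def simulate_to_dir(config: RunConfig, outdir) -> SimulatedPopulation:
    pop = simulate_population(
        config.design, seed=config.seed, meat_mode=config.meat_mode
    )
    pop.write(outdir)
    with open(Path(outdir) / "config.yaml", "w") as fh:
        yaml.safe_dump(
            {"design": asdict(config.design), "seed": config.seed,
             "meat_mode": config.meat_mode},
            fh,
        )
    return pop


def load_user_data(pedigree_path, phenotypes_path):
    ped = read_pedigree(pedigree_path)
    data = pd.read_csv(phenotypes_path)
    data["id"] = data["id"].astype(str)
    return data, ped
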