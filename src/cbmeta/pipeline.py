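"""Orchestration of the full analysis menu over real or synthetic inputs.

The neuroimaging side runs a main-effect ALE per declared subgroup, then
conjunctions and label-exchange contrasts for each declared pair, and a
contribution table for every significant cluster. The behavioral side runs
the intercept-only model, the two moderator meta-regressions (task-variant
moderators within color-word experiments; stimulus material across task
families), the small-study bias regression, case-deletion influence
diagnostics with an automatic refit excluding flagged cases, and the r- and
rho-sensitivity grids, under all three r-assignment strategies.

Subgroup membership is declarative — filters over moderator columns in the
config — so exclusion rules (e.g., mixed-within-blocks designs dropped from
the design comparison) are data, not code. Desk-scale defaults keep the
permutation and simulation counts modest (n_sim=1000, n_perm=2000);
``paper_scale=True`` restores 10,000 simulated datasets and 25,000
permutations.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cbmeta import io as cio
from cbmeta.ale import ALEResult, cluster_fwe, conjunction, contrast, contribution
from cbmeta.effect_size import (build_es_table, es_table_to_frame,
                                observed_correlations, impute_r,
                                records_from_frame)
from cbmeta.rve import (design_from_moderators, egger_rve, fit_rve,
                        influence_diagnostics, sensitivity_grid, wald_omnibus)
from cbmeta.synthetic import (BehavSimConfig, FociSimConfig, TruthCenter,
                              gen_behavioral_dataset, gen_foci_dataset)

logger = logging.getLogger(__name__)

NEUTRAL_LEVELS = ("neutral", "neutral_word", "neutral_symbol")

#: the standard subgroup menu: name -> moderator filters
DEFAULT_SUBGROUPS: dict[str, dict] = {
    "congruent_control": {"material": "color_word", "demand": "no",
                          "control_condition": "congruent"},
    "neutral_control": {"material": "color_word", "demand": "no",
                        "control_condition": list(NEUTRAL_LEVELS)},
    "neutral_word": {"material": "color_word", "demand": "no",
                     "control_condition": "neutral_word"},
    "neutral_symbol": {"material": "color_word", "demand": "no",
                       "control_condition": "neutral_symbol"},
    "blocked": {"material": "color_word", "demand": "no", "design": "blocked"},
    "mixed": {"material": "color_word", "demand": "no", "design": "mixed"},
    "demand": {"material": "color_word", "demand": "yes"},
    "no_demand": {"material": "color_word", "demand": "no"},
    "color_word": {"material": "color_word", "demand": "no",
                   "control_condition": "congruent"},
    "emotional": {"material": "emotional", "demand": "no",
                  "control_condition": "congruent"},
    "other": {"material": "other", "demand": "no",
              "control_condition": "congruent"},
}

DEFAULT_CONTRAST_PAIRS = [
    ("congruent_control", "neutral_control"),
    ("blocked", "mixed"),
    ("demand", "no_demand"),
    ("color_word", "emotional"),
    ("color_word", "other"),
    ("emotional", "other"),
]

DEFAULT_CONJUNCTIONS = [
    ("congruent_control", "neutral_control"),
    ("blocked", "mixed"),
    ("demand", "no_demand"),
    ("color_word", "emotional", "other"),
    ("color_word", "emotional"),
    ("color_word", "other"),
    ("emotional", "other"),
]


@dataclass
class ALESettings:
    cluster_forming_p: float = 0.001
    alpha: float = 0.05
    n_sim: int = 1000
    n_perm: int = 2000
    extent: int = 25
    connectivity: int = 26
    min_experiments: int = 17
    paper_scale: bool = False

    def __post_init__(self) -> None:
        if self.paper_scale:
            self.n_sim = 10000
            self.n_perm = 25000


@dataclass
class ESSettings:
    strategy: str = "observed_plus_imputed"
    rho: float = 0.8
    floor: float = 0.6
    imputed_r: float | None = None
    r_grid: list = field(default_factory=lambda: [round(0.1 * i, 1) for i in range(10)])
    rho_grid: list = field(default_factory=lambda: [0.2, 0.4, 0.6, 0.8, 0.9])


@dataclass
class AnalysisConfig:
    seed: int = 0
    output_dir: str | None = None
    coordinate_table: str | None = None
    behavioral_table: str | None = None
    mask: str | None = None
    synthetic_foci: FociSimConfig | None = None
    synthetic_behavioral: BehavSimConfig | None = None
    subgroups: dict = field(default_factory=lambda: dict(DEFAULT_SUBGROUPS))
    contrast_pairs: list = field(default_factory=lambda: list(DEFAULT_CONTRAST_PAIRS))
    conjunctions: list = field(default_factory=lambda: list(DEFAULT_CONJUNCTIONS))
    ale: ALESettings = field(default_factory=ALESettings)
    es: ESSettings = field(default_factory=ESSettings)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        cfg = cls.from_dict(raw)
        cfg._config_hash = hashlib.sha256(text.encode()).hexdigest()[:16]
        return cfg

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        kwargs = {k: raw[k] for k in ("seed", "output_dir", "coordinate_table",
                                      "behavioral_table", "mask") if k in raw}
        if "synthetic" in raw:
            syn = raw["synthetic"]
            if "foci" in syn:
                foci = dict(syn["foci"])
                foci["truth_centers"] = [TruthCenter(**c)
                                         for c in foci.get("truth_centers", [])]
                for key in ("n_range",):
                    if key in foci:
                        foci[key] = tuple(foci[key])
                kwargs["synthetic_foci"] = FociSimConfig(**foci)
            if "behavioral" in syn:
                beh = dict(syn["behavioral"])
                for key in ("es_per_study", "n_range"):
                    if key in beh:
                        beh[key] = tuple(beh[key])
                kwargs["synthetic_behavioral"] = BehavSimConfig(**beh)
        if "subgroups" in raw:
            kwargs["subgroups"] = raw["subgroups"]
        if "contrast_pairs" in raw:
            kwargs["contrast_pairs"] = [tuple(p) for p in raw["contrast_pairs"]]
        if "conjunctions" in raw:
            kwargs["conjunctions"] = [tuple(p) for p in raw["conjunctions"]]
        if "ale" in raw:
            kwargs["ale"] = ALESettings(**raw["ale"])
        if "es" in raw:
            kwargs["es"] = ESSettings(**raw["es"])
        return cls(**kwargs)


@dataclass
class AnalysisReport:
    """Everything the pipeline produced, with a manifest for reproduction."""

    neuro: dict = field(default_factory=dict)
    behavior: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _resolve_grid(cfg: AnalysisConfig) -> cio.BrainGrid:
    if cfg.mask:
        return cio.make_grid(cfg.mask)
    if cfg.coordinate_table:
        return cio.default_brain_grid(resolution=2)
    return cio.ellipsoid_grid()


def load_experiments(cfg: AnalysisConfig) -> tuple[cio.ExperimentSet, dict]:
    grid = _resolve_grid(cfg)
    if cfg.coordinate_table:
        return cio.read_experiment_table(cfg.coordinate_table, grid=grid), {}
    if cfg.synthetic_foci is None:
        raise ValueError("no coordinate table and no synthetic foci config")
    es, truth = gen_foci_dataset(cfg.synthetic_foci, grid)
    return es, {"ground_truth": truth}


def load_behavioral(cfg: AnalysisConfig) -> tuple[pd.DataFrame, dict]:
    if cfg.behavioral_table:
        return cio.read_behavioral_table(cfg.behavioral_table), {}
    if cfg.synthetic_behavioral is None:
        raise ValueError("no behavioral table and no synthetic behavioral config")
    table, truth = gen_behavioral_dataset(cfg.synthetic_behavioral)
    return table, {"ground_truth": truth}


def run_neuro_suite(cfg: AnalysisConfig,
                    experiment_set: cio.ExperimentSet | None = None) -> dict:
    """Main-effect ALE per subgroup plus conjunctions, contrasts, contributions."""
    extras = {}
    if experiment_set is None:
        experiment_set, extras = load_experiments(cfg)
    grid = experiment_set.grid
    rng = np.random.default_rng(cfg.seed)
    s = cfg.ale

    results: dict[str, ALEResult] = {}
    for name, filters in cfg.subgroups.items():
        subset = experiment_set.subset(**filters)
        if len(subset) < 2:
            logger.warning("subgroup %r has %d experiment(s); skipped",
                           name, len(subset))
            continue
        if len(subset) < s.min_experiments:
            logger.warning("subgroup %r below the %d-experiment guideline "
                           "(%d experiments)", name, s.min_experiments, len(subset))
        results[name] = cluster_fwe(
            subset, grid, cluster_forming_p=s.cluster_forming_p, alpha=s.alpha,
            n_sim=s.n_sim, seed=rng, connectivity=s.connectivity,
            min_experiments=s.min_experiments,
        )

    conjunctions = {}
    for names in cfg.conjunctions:
        if all(n in results for n in names):
            conjunctions[" & ".join(names)] = conjunction(
                [results[n].thresholded for n in names],
                extent=s.extent, connectivity=s.connectivity,
            )

    contrasts = {}
    for a, b in cfg.contrast_pairs:
        if a in results and b in results:
            map_ab, map_ba = contrast(
                results[a].experiments, results[b].experiments, grid,
                results[a].thresholded, results[b].thresholded,
                n_perm=s.n_perm, extent=s.extent, seed=rng,
                connectivity=s.connectivity,
            )
            contrasts[f"{a} > {b}"] = map_ab
            contrasts[f"{b} > {a}"] = map_ba

    contributions = {}
    for name, res in results.items():
        for cid in res.significant_cluster_ids:
            contributions[f"{name}#{cid}"] = contribution(
                res.labels == cid, res.experiments, grid,
            )
    return {"main_effects": results, "conjunctions": conjunctions,
            "contrasts": contrasts, "contributions": contributions, **extras}


def _collapse_control(levels: pd.Series) -> pd.Series:
    return levels.replace({lev: "neutral" for lev in NEUTRAL_LEVELS})


def run_behavior_suite(cfg: AnalysisConfig,
                       table: pd.DataFrame | None = None) -> dict:
    """Intercept model, both meta-regressions, bias, influence, sensitivity."""
    extras = {}
    if table is None:
        table, extras = load_behavioral(cfg)
    records = records_from_frame(table)
    s = cfg.es

    obs = observed_correlations(records)
    imputed_r = s.imputed_r
    if imputed_r is None and len(obs) >= 2:
        imputed_r = impute_r(obs, rho=s.rho)

    strategies = {}
    for strategy in ("observed_plus_imputed", "observed_plus_floor", "all_imputed"):
        es_records = build_es_table(records, strategy=strategy,
                                    imputed_r=imputed_r, floor=s.floor, rho=s.rho)
        frame = es_table_to_frame(es_records)
        fit = fit_rve(frame["g"].to_numpy(), frame["var_g"].to_numpy(),
                      frame["study_id"].to_numpy(), rho=s.rho)
        strategies[strategy] = {"frame": frame, "intercept_fit": fit}

    main = strategies[s.strategy]
    frame = main["frame"]
    out = {"imputed_r": imputed_r, "strategies": strategies,
           "intercept": main["intercept_fit"], **extras}

    def _fit_with(frame_sub, moderators, ref_levels=None):
        X, names = design_from_moderators(frame_sub, moderators, ref_levels)
        return fit_rve(frame_sub["g"].to_numpy(), frame_sub["var_g"].to_numpy(),
                       frame_sub["study_id"].to_numpy(), X=X, labels=names,
                       rho=s.rho), names

    # model 1: task-variant moderators within color-word experiments
    if "material" in frame.columns:
        cw = frame[frame["material"] == "color_word"].copy()
    else:
        cw = frame.copy()
    model1 = None
    mods1 = [m for m in ("control_condition", "design", "demand") if m in cw.columns]
    if mods1 and len(cw) >= 4:
        if "control_condition" in cw.columns:
            cw["control_condition"] = _collapse_control(cw["control_condition"])
        if "design" in cw.columns:
            cw = cw[cw["design"].isin(["blocked", "mixed"])]
        keep = cw.dropna(subset=mods1)
        if keep["study_id"].nunique() >= 2:
            try:
                fit1, names1 = _fit_with(keep, mods1)
                model1 = {"fit": fit1, "n_es": len(keep),
                          "n_studies": keep["study_id"].nunique()}
            except ValueError as err:
                logger.warning("model 1 skipped: %s", err)
    out["model1"] = model1

    # model 2: stimulus material, congruent-control / no-demand subset
    model2 = None
    if "material" in frame.columns and frame["material"].nunique() > 1:
        sub = frame.copy()
        if "control_condition" in sub.columns:
            sub = sub[sub["control_condition"] == "congruent"]
        if "demand" in sub.columns:
            sub = sub[sub["demand"] == "no"]
        if sub["study_id"].nunique() >= 2 and sub["material"].nunique() > 1:
            levels = sorted(sub["material"].unique())
            fits = {}
            for ref in levels:
                fit2, names2 = _fit_with(sub, ["material"],
                                         ref_levels={"material": ref})
                omnibus = wald_omnibus(fit2, list(range(1, len(names2))))
                fits[ref] = {"fit": fit2, "omnibus": omnibus, "labels": names2}
            model2 = {"by_reference": fits, "n_es": len(sub),
                      "n_studies": sub["study_id"].nunique()}
    out["model2"] = model2

    # small-study bias
    try:
        out["bias"] = egger_rve(frame["g"].to_numpy(), frame["var_g"].to_numpy(),
                                frame["study_id"].to_numpy(), rho=s.rho)
    except ValueError as err:
        logger.warning("bias regression skipped: %s", err)
        out["bias"] = None

    # influence diagnostics (independence model) and refit without outliers
    infl = influence_diagnostics(frame["g"].to_numpy(), frame["var_g"].to_numpy())
    out["influence"] = infl
    flagged = infl.loc[infl["influential"], "index"].to_numpy()
    if len(flagged):
        keep = frame.drop(index=frame.index[flagged])
        out["intercept_without_outliers"] = fit_rve(
            keep["g"].to_numpy(), keep["var_g"].to_numpy(),
            keep["study_id"].to_numpy(), rho=s.rho)
    else:
        out["intercept_without_outliers"] = main["intercept_fit"]

    # sensitivity grids
    try:
        out["r_sensitivity"] = sensitivity_grid(records, "r", s.r_grid, rho=s.rho)
    except ValueError as err:
        logger.warning("r sensitivity skipped: %s", err)
        out["r_sensitivity"] = None
    out["rho_sensitivity"] = sensitivity_grid(frame, "rho", s.rho_grid)
    return out


def run_all(cfg: AnalysisConfig) -> AnalysisReport:
    report = AnalysisReport()
    report.neuro = run_neuro_suite(cfg)
    report.behavior = run_behavior_suite(cfg)
    report.manifest = build_manifest(cfg)
    return report


def build_manifest(cfg: AnalysisConfig) -> dict:
    from cbmeta import __version__

    payload = {
        "package_version": __version__,
        "seed": cfg.seed,
        "ale": asdict(cfg.ale),
        "es": asdict(cfg.es),
        "subgroups": cfg.subgroups,
        "contrast_pairs": [list(p) for p in cfg.contrast_pairs],
        "conjunctions": [list(p) for p in cfg.conjunctions],
        "config_hash": getattr(cfg, "_config_hash", None),
    }
    return payload


def write_report(report: AnalysisReport, cfg: AnalysisConfig, outdir) -> None:
    """Persist maps (NIfTI), tables (CSV), fits (text) and the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    neuro = report.neuro
    grid = None
    for name, res in neuro.get("main_effects", {}).items():
        grid = res.grid
        cio.write_stat_map(res.ale, grid, outdir / f"ale_{name}.nii.gz")
        with np.errstate(divide="ignore"):
            neglog = np.where(grid.mask, -np.log10(res.p), 0.0)
        cio.write_stat_map(neglog, grid, outdir / f"neglog10p_{name}.nii.gz")
        cio.write_stat_map(res.thresholded, grid, outdir / f"thresh_{name}.nii.gz")
        res.cluster_table.to_csv(outdir / f"clusters_{name}.csv", index=False)
    for label, cmap in {**neuro.get("conjunctions", {}),
                        **neuro.get("contrasts", {})}.items():
        safe = label.replace(" ", "").replace(">", "_gt_").replace("&", "_and_")
        cio.write_stat_map(cmap, grid, outdir / f"map_{safe}.nii.gz")
    for label, table in neuro.get("contributions", {}).items():
        safe = label.replace("#", "_cluster")
        table.to_csv(outdir / f"contribution_{safe}.csv", index=False)

    behavior = report.behavior
    lines = []
    if behavior:
        lines.append(f"imputed r = {behavior['imputed_r']}")
        lines.append("\n== intercept-only model ==")
        lines.append(behavior["intercept"].report())
        if behavior.get("model1"):
            lines.append("\n== model 1 (color-word moderators) ==")
            lines.append(behavior["model1"]["fit"].report())
        if behavior.get("model2"):
            lines.append("\n== model 2 (stimulus material) ==")
            for ref, item in behavior["model2"]["by_reference"].items():
                om = item["omnibus"]
                lines.append(f"-- reference level: {ref} --")
                lines.append(item["fit"].report())
                lines.append(f"omnibus F({om.df1:.0f}, {om.df2:.1f}) = "
                             f"{om.F:.2f}, p = {om.p:.4g}")
        if behavior.get("bias") is not None:
            lines.append("\n== small-study bias regression ==")
            lines.append(behavior["bias"].report())
        behavior["influence"].to_csv(outdir / "influence.csv", index=False)
        if behavior.get("r_sensitivity") is not None:
            behavior["r_sensitivity"].to_csv(outdir / "r_sensitivity.csv", index=False)
        behavior["rho_sensitivity"].to_csv(outdir / "rho_sensitivity.csv", index=False)
        for strategy, item in behavior["strategies"].items():
            item["frame"].to_csv(outdir / f"es_table_{strategy}.csv", index=False)
    (outdir / "behavior_report.txt").write_text("\n".join(lines) or "no behavioral run\n")
    (outdir / "manifest.json").write_text(json.dumps(report.manifest, indent=2))
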