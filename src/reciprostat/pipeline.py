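"""End-to-end seeded analysis pipeline and report serialisation.

One run chains: synthetic-data generation (or a user trait table) ->
organ-height summaries and the four-combination inaccuracy decomposition
(with bootstrap CIs) -> the registry of factorial trait models with type-II
Wald tests, back-transformed marginal means and morph-conditioned contrasts
-> percent effect sizes.  A single global seed deterministically spawns
per-stage substreams, so identical configuration + seed reproduces every
output file byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import PopulationConfig
from .effects import add_nectar_calories, effect_table
from .models import ModelSpec, TraitModel, default_registry
from .reciprocity import ReciprocityAnalysis
from .synth import generate_dataset, validate_trait_table

ALPHA = 0.05  # significance level used to decide post-hoc contrasts


def _package_version() -> str:
    from importlib.metadata import version

    try:
        return version("reciprostat")
    except Exception:
        return "unknown"


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage (and model) that failed."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    population: PopulationConfig = field(default_factory=PopulationConfig)
    registry: list[ModelSpec] = field(default_factory=default_registry)
    bootstrap_B: int = 1000
    seed: int = 0


@dataclass
class RunReport:
    """Consolidated pipeline output (every table traceable to one stage)."""

    provenance: dict
    trait_table: pd.DataFrame
    inaccuracy: pd.DataFrame
    inaccuracy_ci: pd.DataFrame
    tests: pd.DataFrame
    marginal_means: pd.DataFrame
    contrasts: pd.DataFrame
    effects: pd.DataFrame
    model_info: pd.DataFrame


def _stage_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(int(seed)).generate_state(4)
    names = ("synth", "bootstrap", "models", "spare")
    return {n: int(s % (2**31)) for n, s in zip(names, state)}


def registry_to_yaml(registry: list[ModelSpec], path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(
        [dataclasses.asdict(s) for s in registry], sort_keys=False))


def registry_from_yaml(path: str | Path) -> list[ModelSpec]:
    raw = yaml.safe_load(Path(path).read_text())
    return [ModelSpec(**d) for d in raw]


def run_pipeline(config: RunConfig, table: pd.DataFrame | None = None) -> RunReport:
    """Execute the full pipeline; supply ``table`` to skip the synth stage."""
    seeds = _stage_seeds(config.seed)

    # ---- stage: synth -------------------------------------------------
    if table is None:
        try:
            pop = dataclasses.replace(config.population, seed=seeds["synth"])
            table = generate_dataset(pop)
            pop_hash = pop.content_hash()
        except Exception as exc:
            raise PipelineError("synth", str(exc)) from exc
    else:
        validate_trait_table(table)
        pop_hash = None
    table = add_nectar_calories(table)
    if "pollen_deposited" not in set(table["trait"]) and \
            any(s.trait == "pollen_deposited" for s in config.registry):
        pollen = table[table["trait"] == "pollen_grains"].copy()
        pollen["trait"] = "pollen_deposited"
        pollen["value"] = (pollen["value"] > 0).astype(float)
        table = pd.concat([table, pollen], ignore_index=True)

    # ---- stage: reciprocity ------------------------------------------
    try:
        rec = ReciprocityAnalysis(bootstrap_B=config.bootstrap_B,
                                  seed=seeds["bootstrap"]).fit(table)
        inaccuracy = rec.table_
        ci_frames = []
        for label, ci in rec.ci_.items():
            ci = ci.copy()
            ci.insert(0, "combination", label)
            ci_frames.append(ci)
        inaccuracy_ci = (pd.concat(ci_frames, ignore_index=True)
                         if ci_frames else pd.DataFrame(
                             columns=["combination", "component", "estimate",
                                      "ci_lower", "ci_upper"]))
    except Exception as exc:
        raise PipelineError("reciprocity", str(exc)) from exc

    # ---- stage: trait models -----------------------------------------
    tests_rows, mm_rows, contrast_rows, info_rows = [], [], [], []
    for spec in config.registry:
        trait_for_fit = spec.trait
        fit_table = table
        if spec.family == "beta-logit" and spec.trait == "nectar_concentration":
            # beta regression works on the proportion scale
            fit_table = table.copy()
            sel = fit_table["trait"] == spec.trait
            fit_table.loc[sel, "value"] = fit_table.loc[sel, "value"] / 100.0
        try:
            model = TraitModel.from_spec(spec, seed=seeds["models"]).fit(fit_table)
        except Exception as exc:
            raise PipelineError(f"fit[{spec.label or spec.trait}]", str(exc)) from exc
        f = model.fit_
        info_rows.append({
            "model": spec.label or spec.trait, "trait": spec.trait,
            "family": spec.family, "backend": f.backend,
            "re_handling": f.re_handling, "converged": f.converged,
            "n_obs": f.n_obs, "alpha": f.alpha, "zi_prob": f.zi_prob,
            "warnings": "; ".join(f.warnings),
        })
        if not f.converged:
            continue
        try:
            tt = model.wald_type2()
            tt.insert(0, "model", spec.label or spec.trait)
            tt.insert(1, "trait", spec.trait)
            tests_rows.append(tt)
            mm = model.marginal_means()
            mm.insert(0, "model", spec.label or spec.trait)
            mm.insert(1, "trait", spec.trait)
            mm_rows.append(mm)
            inter_p = float(tt.loc[tt["term"] == "area:morph", "p_value"].iloc[0])
            if inter_p < ALPHA:
                cc = model.conditional_contrasts()
                cc.insert(0, "model", spec.label or spec.trait)
                cc.insert(1, "trait", spec.trait)
                contrast_rows.append(cc)
        except Exception as exc:
            raise PipelineError(f"tests[{spec.label or spec.trait}]", str(exc)) from exc

    tests = (pd.concat(tests_rows, ignore_index=True) if tests_rows
             else pd.DataFrame(columns=["model", "trait", "term", "chi2", "df",
                                        "p_value"]))
    mmeans = (pd.concat(mm_rows, ignore_index=True) if mm_rows
              else pd.DataFrame(columns=["model", "trait", "kind", "group",
                                         "area", "morph", "mean", "se"]))
    contrasts = (pd.concat(contrast_rows, ignore_index=True) if contrast_rows
                 else pd.DataFrame(columns=["model", "trait", "morph", "contrast",
                                            "estimate_link", "se", "z", "p_value",
                                            "back_transformed"]))

    # ---- stage: effects ----------------------------------------------
    try:
        effects = _pipeline_effects(mmeans, contrasts)
    except Exception as exc:
        raise PipelineError("effects", str(exc)) from exc

    provenance = {
        "package_version": _package_version(),
        "seed": int(config.seed),
        "stage_seeds": _stage_seeds(config.seed),
        "population_hash": pop_hash,
        "bootstrap_B": int(config.bootstrap_B),
        "n_models": len(config.registry),
    }
    return RunReport(
        provenance=provenance, trait_table=table, inaccuracy=inaccuracy,
        inaccuracy_ci=inaccuracy_ci, tests=tests, marginal_means=mmeans,
        contrasts=contrasts, effects=effects,
        model_info=pd.DataFrame(info_rows),
    )


def _pipeline_effects(mmeans: pd.DataFrame, contrasts: pd.DataFrame) -> pd.DataFrame:
    """Fire-vs-no-fire (area) and S-vs-L (morph) percent effects per trait.

    When a trait had a significant interaction, the within-morph cell
    comparison (fire vs no-fire inside each morph) is added as well.
    """
    rows = []
    for (model, trait), mm in mmeans.groupby(["model", "trait"], sort=False):
        lut = mm.set_index(["kind", "group"])["mean"]

        def pct(focal_key, ref_key, comparison):
            focal = float(lut.loc[focal_key])
            ref = float(lut.loc[ref_key])
            if ref == 0:
                return
            val = round(100.0 * (focal - ref) / ref, 2)
            rows.append({"model": model, "trait": trait,
                         "comparison": comparison,
                         "percent_effect": val,
                         "direction": "increase" if val > 0 else
                         ("decrease" if val < 0 else "none")})

        pct(("area", "fire"), ("area", "no_fire"), "fire vs no_fire")
        pct(("morph", "S"), ("morph", "L"), "S vs L")
        had_contrast = (not contrasts.empty
                        and (contrasts["trait"] == trait).any())
        if had_contrast:
            for morph in ("L", "S"):
                pct(("cell", f"fire:{morph}"), ("cell", f"no_fire:{morph}"),
                    f"fire vs no_fire | morph {morph}")
    return pd.DataFrame(rows,
                        columns=["model", "trait", "comparison",
                                 "percent_effect", "direction"])


# ----------------------------------------------------------------------
# report I/O
# ----------------------------------------------------------------------

_CSV_SECTIONS = ("trait_table", "inaccuracy", "inaccuracy_ci", "tests",
                 "marginal_means", "contrasts", "effects", "model_info")


def write_report(report: RunReport, outdir: str | Path) -> list[Path]:
    """Write the report as CSV tables + JSON summary + readable text.

    Returns the list of files written (the manifest, in stable order).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for section in _CSV_SECTIONS:
        path = outdir / f"{section}.csv"
        getattr(report, section).to_csv(path, index=False)
        written.append(path)

    summary = {
        "provenance": report.provenance,
        "inaccuracy": report.inaccuracy.to_dict(orient="records"),
        "significant_terms": report.tests[report.tests["p_value"] < ALPHA][
            ["model", "trait", "term", "chi2", "p_value"]].to_dict(orient="records"),
        "effects": report.effects.to_dict(orient="records"),
        "model_info": report.model_info.replace({np.nan: None})
        .to_dict(orient="records"),
    }
    jpath = outdir / "report.json"
    jpath.write_text(json.dumps(summary, indent=2, sort_keys=True))
    written.append(jpath)

    tpath = outdir / "report.txt"
    tpath.write_text(_text_summary(report))
    written.append(tpath)
    return written


def load_report(outdir: str | Path) -> dict[str, pd.DataFrame]:
    """Read the CSV sections of a written report back into DataFrames."""
    outdir = Path(outdir)
    return {s: pd.read_csv(outdir / f"{s}.csv") for s in _CSV_SECTIONS}


def _text_summary(report: RunReport) -> str:
    lines = ["reciprostat run report",
             "======================",
             f"seed: {report.provenance['seed']}",
             f"package: {report.provenance['package_version']}",
             "",
             "Total inaccuracy per combination (mm^2):"]
    for r in report.inaccuracy.itertuples(index=False):
        lines.append(f"  {r.combination:24s} bias_high={r.maladaptive_bias_high:8.3f}"
                     f" imprec_high={r.imprecision_high:8.3f}"
                     f" total={r.total_inaccuracy:8.3f}")
    lines.append("")
    sig = report.tests[report.tests["p_value"] < ALPHA]
    lines.append(f"Significant terms at alpha={ALPHA} "
                 f"({len(sig)}/{len(report.tests)} tests):")
    for r in sig.itertuples(index=False):
        lines.append(f"  {r.model:6s} {r.trait:22s} {r.term:10s} "
                     f"chi2={r.chi2:8.2f} p={r.p_value:.4g}")
    lines.append("")
    lines.append("Percent effects (focal vs reference):")
    for r in report.effects.itertuples(index=False):
        lines.append(f"  {r.model:6s} {r.trait:22s} {r.comparison:28s} "
                     f"{r.percent_effect:+8.2f}% ({r.direction})")
    return "\n".join(lines) + "\n"
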