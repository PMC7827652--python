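"""End-to-end orchestration: simulate (or load), analyse, summarise.

``run_full_pipeline`` chains the behavioural analysis (locomotion,
visits, A-F ranking, day-11 standardization) and the catFISH analysis
(classification, proportions, similarity, ANOVAs) on synthetic cohorts,
writing every table as TSV plus a run manifest and a plain-text summary
mirroring the result structure of the study: sensitization curve, zone
preference, per-region IEG contrasts and the similarity comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .behavior import (
    count_visits,
    path_length,
    pooled_zone_matrix,
    rank_zones,
    sensitization_summary,
    standardize_sessions,
    zone_dominance,
)
from .catfish import NucleusClassifier, region_proportions
from .io import RunManifest, write_nuclei
from .similarity import scores_by_animal_region
from .stats import compare_similarity, run_mixed_anova
from .synth import BehaviorSimConfig, CatfishSimConfig, iter_trajectories, simulate_catfish_population

__all__ = ["run_full_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


def _stage(name):
    def deco(fn):
        def wrapper(*a, **k):
            try:
                return fn(*a, **k)
            except Exception as e:  # annotate and re-raise
                raise PipelineError(f"stage '{name}' failed: {e}") from e

        return wrapper

    return deco


@_stage("behavior")
def _behavior_stage(config: BehaviorSimConfig, outdir: Path, manifest: RunManifest):
    visit_rows = []
    path_rows = []
    for traj in iter_trajectories(config):
        visit_rows.append(count_visits([traj]))
        if traj.session == "daily":
            path_rows.append(
                {
                    "animal_id": traj.animal_id,
                    "group": traj.group,
                    "day": traj.day,
                    "path_cm": path_length(traj),
                }
            )
    visits = pd.concat(visit_rows, ignore_index=True)
    paths = pd.DataFrame(path_rows)

    days = range(1, config.n_days + 1)
    rank_map = rank_zones(visits[visits["session"] == "daily"], days=days)
    pooled = pooled_zone_matrix(visits[visits["session"] == "daily"], rank_map)
    senses = sensitization_summary(paths)
    dom = pd.concat(
        [
            zone_dominance(visits[visits["session"] == "daily"], rank_map, g,
                           days=range(min(4, config.n_days), config.n_days + 1)).assign(group=g)
            for g in ("QNP", "control")
            if (visits["group"] == g).any()
        ],
        ignore_index=True,
    )

    rates = None
    if config.include_day11:
        day10 = visits[(visits["day"] == config.n_days) & (visits["session"] == "daily")]
        a1 = visits[visits["session"] == "A1"]
        a2 = visits[visits["session"] == "A2"]
        rates = standardize_sessions(
            day10, a1, a2,
            day10_length_min=config.session_length / 60.0,
            probe_length_min=config.probe_length / 60.0,
        )

    for name, df in (
        ("visits.tsv", visits),
        ("rank_map.tsv", rank_map),
        ("pooled_zones.tsv", pooled),
        ("path_lengths.tsv", paths),
        ("sensitization.tsv", senses),
        ("zone_dominance.tsv", dom),
    ):
        df.to_csv(outdir / name, sep="\t", index=False)
        manifest.row_counts[name] = len(df)
    if rates is not None:
        rates.to_csv(outdir / "session_rates.tsv", sep="\t", index=False)
        manifest.row_counts["session_rates.tsv"] = len(rates)
    return visits, rank_map, senses, dom


@_stage("catfish")
def _catfish_stage(config: CatfishSimConfig, outdir: Path, manifest: RunManifest):
    nuclei = simulate_catfish_population(config)
    clf = NucleusClassifier()
    classified = clf.fit_predict(nuclei)
    props = region_proportions(classified)
    write_nuclei(nuclei, outdir / "nuclei.tsv")
    clf.thresholds_.to_csv(outdir / "thresholds.tsv", sep="\t", index=False)
    classified.to_csv(outdir / "classified_nuclei.tsv", sep="\t", index=False)
    props.to_csv(outdir / "region_proportions.tsv", sep="\t", index=False)
    manifest.row_counts.update(
        {
            "nuclei.tsv": len(nuclei),
            "classified_nuclei.tsv": len(classified),
            "region_proportions.tsv": len(props),
        }
    )
    return classified, props


@_stage("statistics")
def _stats_stage(props: pd.DataFrame, outdir: Path, manifest: RunManifest):
    # Long format: one row per animal x region x session epoch.
    long = props.melt(
        id_vars=["animal_id", "treatment", "environment", "region"],
        value_vars=["p_e1", "p_e2"],
        var_name="session",
        value_name="p_active",
    )
    long["session"] = long["session"].map({"p_e1": "A1", "p_e2": "A2"})
    effect_frames = []
    for region, g in long.groupby("region"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab = run_mixed_anova(g, dv="p_active")
        tab.insert(0, "region", region)
        effect_frames.append(tab)
    effects = pd.concat(effect_frames, ignore_index=True)

    scores = scores_by_animal_region(props)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sim_tables = compare_similarity(scores)
    sim = pd.concat(
        [t.assign(region=r) for r, t in sim_tables.items()], ignore_index=True
    )
    effects.to_csv(outdir / "ieg_anova.tsv", sep="\t", index=False)
    scores.to_csv(outdir / "similarity_scores.tsv", sep="\t", index=False)
    sim.to_csv(outdir / "similarity_anova.tsv", sep="\t", index=False)
    manifest.row_counts.update(
        {"ieg_anova.tsv": len(effects), "similarity_scores.tsv": len(scores)}
    )
    return effects, scores, sim


def _summary_text(senses, dom, effects, sim) -> str:
    lines = ["checkfish pipeline summary", "=" * 28, ""]
    lines.append("Locomotor sensitization (mean path length, cm):")
    for grp, g in senses.groupby("group"):
        last = g[g["day"] == g["day"].max()].iloc[0]
        lines.append(
            f"  {grp}: day-{int(last['day'])}/day-1 ratio = {last['ratio_to_day1']:.2f}"
        )
    lines.append("")
    lines.append("Zone-A dominance (rank-A visits > every other rank, per day):")
    for grp, g in dom.groupby("group"):
        n_dom = int(g["dominant"].sum())
        lines.append(f"  {grp}: dominant on {n_dom}/{len(g)} tested days")
    lines.append("")
    lines.append("IEG proportion ANOVA (treatment effect per region):")
    trt = effects[(effects["source"] == "treatment") & (effects["stratum"] == "between")]
    for row in trt.itertuples(index=False):
        lines.append(f"  {row.region}: F({row.df1:.0f},{row.df2:.0f}) = {row.F:.2f}, p = {row.p:.4f}")
    lines.append("")
    lines.append("Similarity-score ANOVA (treatment effect per region):")
    st = sim[sim["source"] == "treatment"]
    for row in st.itertuples(index=False):
        lines.append(f"  {row.region}: p = {row.p:.4f}")
    lines.append("")
    return "\n".join(lines)


def run_full_pipeline(
    outdir,
    behavior_config: Optional[BehaviorSimConfig] = None,
    catfish_config: Optional[CatfishSimConfig] = None,
    seed: Optional[int] = None,
) -> dict:
    """Run simulate -> analyse -> summarise and write all artifacts.

    Configuration is validated before anything is written, so an invalid
    config (e.g. zero animals) produces a clean error and no partial
    output.  Returns a dict with the main result tables.
    """
    behavior_config = behavior_config or BehaviorSimConfig()
    catfish_config = catfish_config or CatfishSimConfig()
    if seed is not None:
        behavior_config = replace(behavior_config, seed=seed)
        catfish_config = replace(catfish_config, seed=seed + 1)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        command="run-all",
        seed=seed if seed is not None else behavior_config.seed,
        config={
            "behavior": {k: v for k, v in asdict(behavior_config).items() if k != "arena"},
            "catfish": {
                k: (v if np.isscalar(v) else str(v))
                for k, v in asdict(catfish_config).items()
            },
        },
    )

    visits, rank_map, senses, dom = _behavior_stage(behavior_config, outdir, manifest)
    classified, props = _catfish_stage(catfish_config, outdir, manifest)
    effects, scores, sim = _stats_stage(props, outdir, manifest)

    summary = _summary_text(senses, dom, effects, sim)
    (outdir / "summary.txt").write_text(summary)
    manifest.write(outdir / "manifest.json")
    return {
        "visits": visits,
        "rank_map": rank_map,
        "sensitization": senses,
        "dominance": dom,
        "proportions": props,
        "ieg_anova": effects,
        "similarity_scores": scores,
        "similarity_anova": sim,
        "summary": summary,
    }
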