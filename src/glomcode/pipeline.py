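"""End-to-end orchestration: simulate -> extract -> analyse -> report.

A run is fully determined by its configuration and seed; every output
table is written as CSV under the run directory and the machine-readable
``summary.json`` collects the headline results (significant contrasts,
PC explained variances, distance-test outcomes, cluster labels, volume
and behaviour statistics).  Re-running with the same configuration and
seed reproduces ``summary.json`` byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behaviour as bhv
from . import coding, extraction, morphometry, stats, synthetic
from .io import (AMPLITUDE_SCHEMA, TRAP_SCHEMA, VOLUME_SCHEMA, save_config,
                 write_table)

__all__ = ["RunConfig", "run"]

log = logging.getLogger("glomcode")

ALL_STAGES = ("simulate", "extract", "coding", "volumes", "behaviour")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    outdir: str = "glomcode-run"
    seed: int = 0
    sim: synthetic.SimConfig = field(default_factory=synthetic.SimConfig)
    stages: tuple[str, ...] = ALL_STAGES
    alpha: float = 0.05
    n_perm: int = 10_000
    distance_method: str = "permutation"
    cluster_threshold_frac: float = 0.70

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {ALL_STAGES}")
        if self.sim.seed != self.seed:
            self.sim = self.sim.with_(seed=self.seed)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim, dict):
            panel = sim.pop("odour_panel", None)
            if panel is not None:
                sim["odour_panel"] = tuple(
                    synthetic.Stimulus(s["name"], tuple(s["components"]))
                    for s in panel
                )
            if "sigma_fly" in sim:
                sim["sigma_fly"] = tuple(sim["sigma_fly"])
            if "species" in sim:
                sim["species"] = tuple(sim["species"])
            sim = synthetic.SimConfig(**sim)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(sim=sim, **d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["odour_panel"] = [
            {"name": s.name, "components": list(s.components)}
            for s in self.sim.odour_panel
        ]
        d["sim"]["sigma_fly"] = list(self.sim.sigma_fly)
        d["sim"]["species"] = list(self.sim.species)
        d["stages"] = list(self.stages)
        return d


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    return obj


def run(config: RunConfig) -> dict:
    """Execute the selected stages and return the summary dictionary."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(config.to_dict(), out / "run_config.json")
    summary: dict = {"seed": config.seed, "stages": list(config.stages)}
    sim = config.sim

    amps_norm = None

    if "simulate" in config.stages or "extract" in config.stages or "coding" in config.stages:
        log.info("simulating traces (seed=%d)", config.seed)
        tuning = synthetic.gen_tuning(sim)
        traces = synthetic.gen_traces(sim, tuning)

    if "extract" in config.stages or "coding" in config.stages:
        log.info("extracting amplitudes")
        amps = extraction.amplitude_table(traces)
        write_table(amps, out / "amplitudes_raw.csv", AMPLITUDE_SCHEMA)
        amps_norm = extraction.cross_species_normalize(amps)
        if sim.n_sides > 1:
            amps_norm = extraction.pool_sides(amps_norm, alpha=config.alpha)
        write_table(amps_norm, out / "amplitudes_normalized.csv")
        means = amps_norm.groupby("species", observed=True)["amplitude"].mean()
        summary["normalized_species_means"] = means.to_dict()

    if "coding" in config.stages:
        log.info("coding-space analysis")
        factors = ["species", "odour", "glomerulus"]
        if amps_norm["side"].nunique() > 1:
            factors.append("side")
        aov = stats.nway_anova(amps_norm, "amplitude", factors, max_order=2)
        aov.to_csv(out / "amplitude_anova.csv", index=False)
        summary["amplitude_anova"] = {
            r["term"]: {"F": r["F"], "p": r["p"], "df": r["df"]}
            for _, r in aov.iterrows()
            if r["term"] != "Residual"
        }

        contrasts = coding.compare_amplitudes(amps_norm, alpha=config.alpha)
        contrasts.per_glomerulus.to_csv(out / "contrasts_per_glomerulus.csv", index=False)
        contrasts.per_odour.to_csv(out / "contrasts_per_odour.csv", index=False)
        summary["significant_glomeruli"] = {
            r["glomerulus"]: r["direction"]
            for _, r in contrasts.per_glomerulus.iterrows() if r["significant"]
        }
        summary["significant_odours"] = {
            r["odour"]: r["direction"]
            for _, r in contrasts.per_odour.iterrows() if r["significant"]
        }

        codes_t = coding.time_resolved_codes(traces)
        pca, traj = coding.fit_shared_pca(codes_t, k=3)
        traj.to_csv(out / "trajectories.csv", index=False)
        evr = [float(v) for v in pca.explained_variance_ratio_]
        (out / "explained_variance.json").write_text(
            json.dumps({"explained_variance_ratio": evr}, indent=2)
        )
        summary["pc_explained_variance_pct"] = [100 * v for v in evr]

        vectors = coding.coding_vectors(amps_norm, list(sim.glomeruli))
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(7,))
        )
        summaries = coding.distance_summaries(
            vectors, method=config.distance_method, n_perm=config.n_perm, rng=rng
        )
        rows = []
        ed_summary = {}
        for s in summaries:
            for sp, test in s.tests.items():
                rows.append({
                    "odour": s.odour, "species": sp,
                    "n_within": s.within[sp].size, "n_between": s.between.size,
                    "mean_within": s.within[sp].mean(),
                    "mean_between": s.between.mean(),
                    "statistic": test.statistic, "p": test.pvalue,
                    "direction": test.direction,
                    "significant_below": test.significantly_below(config.alpha),
                })
            ed_summary[s.odour] = {
                sp: {"p": t.pvalue, "direction": t.direction}
                for sp, t in s.tests.items()
            }
        pd.DataFrame(rows).to_csv(out / "distance_summaries.csv", index=False)
        summary["within_between"] = ed_summary

        cluster_labels = {}
        for sp in sim.species:
            sp_codes = (
                amps_norm[amps_norm["species"] == sp]
                .pivot_table(index="odour", columns="glomerulus", values="amplitude")
            )
            result = coding.hca(sp_codes, config.cluster_threshold_frac)
            pd.DataFrame(
                result.linkage, columns=["merge_i", "merge_j", "height", "n"]
            ).to_csv(out / f"linkage_{sp}.csv", index=False)
            result.labels.reset_index().to_csv(
                out / f"clusters_{sp}.csv", index=False
            )
            cluster_labels[sp] = result.labels.to_dict()
        summary["cluster_labels"] = cluster_labels

    if "volumes" in config.stages:
        log.info("volume analysis")
        vols = synthetic.gen_volumes(sim, shifts=synthetic.default_volume_shifts())
        write_table(vols, out / "volumes.csv", VOLUME_SCHEMA)
        rel = morphometry.relative_volumes(vols)
        vt = morphometry.volume_species_test(rel, alpha=config.alpha)
        vt.anova.to_csv(out / "volume_anova.csv", index=False)
        vt.contrasts.to_csv(out / "volume_contrasts.csv", index=False)
        totals = vols.groupby("species", observed=True)["volume_um3"].sum()
        n_flies = vols.groupby("species", observed=True)["fly"].nunique()
        mean_totals = totals / n_flies
        summary["al_volume_ratio"] = float(
            mean_totals[sim.species[1]] / mean_totals[sim.species[0]]
        )
        summary["significant_volume_glomeruli"] = {
            r["glomerulus"]: r["direction"]
            for _, r in vt.contrasts.iterrows() if r["significant"]
        }

    if "behaviour" in config.stages:
        log.info("behaviour analysis")
        traps = synthetic.gen_trap_counts(sim)
        write_table(traps, out / "trap_counts.csv", TRAP_SCHEMA)
        prop = bhv.proportions(traps)
        prop.to_csv(out / "trap_proportions.csv", index=False)
        behaviour_summary = {}
        for bait1 in sorted(prop["bait1_odour"].unique()):
            res = bhv.behaviour_test(prop, bait1, alpha=config.alpha)
            res.anova.to_csv(
                out / f"behaviour_anova_{bait1.replace(' ', '_')}.csv", index=False
            )
            behaviour_summary[bait1] = {
                "anova": {
                    r["term"]: {"F": r["F"], "p": r["p"]}
                    for _, r in res.anova.iterrows() if r["term"] != "Residual"
                },
                "n_significant_posthoc": {
                    sp: int(tbl["significant"].sum())
                    for sp, tbl in res.posthoc.items()
                },
            }
        summary["behaviour"] = behaviour_summary

    summary = _round_floats(summary)
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    log.info("run complete: %s", out / "summary.json")
    return summary
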