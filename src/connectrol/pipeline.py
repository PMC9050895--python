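"""End-to-end orchestration: metrics -> cohort stats -> flags -> simulations
-> resection analysis, with YAML-configurable constants and seeded stages.

Every output bundle embeds the resolved configuration and the master seed;
a single seed determines all stochastic stages through named substreams.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (DEFAULT_LOW_WEIGHT_CUTOFF, DEFAULT_Z_THRESHOLD,
                     build_cohort_table, glm_group_compare,
                     mean_matrix_difference, node_level_flags,
                     subset_sensitivity, zscore_vs_controls)
from .controllability import node_metrics
from .core import Connectome, Parcellation, load_connectome, load_manifest
from .graph_metrics import graph_metric_set
from .resection import build_resection_summary, resection_group_tests
from .simulate import PerturbationConfig, run_fingerprint_experiment

log = logging.getLogger("connectrol")


class StageError(RuntimeError):
    """A named pipeline stage failed."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage:{stage}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Pipeline configuration; defaults reproduce the analysis constants
    (z threshold 3.1, low-weight cutoff 100, 1440 boosted edges, 10
    constrained + 200 null models, 1000 virtual resections)."""

    manifest: str = "manifest.csv"
    parcellation: str = "parcellation.tsv"
    out_dir: str = "results"
    stabilization: str = "spectral"
    ac_statistic: str = "trace"
    z_threshold: float = DEFAULT_Z_THRESHOLD
    low_weight_cutoff: float = DEFAULT_LOW_WEIGHT_CUTOFF
    n_virtual: int = 1000
    subset_min_age: float | None = None
    louvain_repeats: int = 20
    run_simulations: bool = True
    simulation: PerturbationConfig = field(default_factory=PerturbationConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", {})
        raw.update(overrides)
        cfg = cls(**raw)
        if sim:
            cfg.simulation = PerturbationConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _load_inputs(config: RunConfig):
    try:
        parc = Parcellation.from_tsv(config.parcellation)
    except Exception as exc:
        raise StageError("load", f"parcellation: {exc}") from exc
    try:
        records = load_manifest(config.manifest, parc)
    except Exception as exc:
        raise StageError("load", f"manifest: {exc}") from exc
    base = Path(config.manifest).parent
    connectomes: dict[str, Connectome] = {}
    for r in records:
        path = Path(r.connectome_path)
        if not path.is_absolute():
            path = base / path
        try:
            connectomes[r.subject_id] = load_connectome(path, parc,
                                                        r.subject_id)
        except Exception as exc:
            raise StageError("load",
                             f"subject {r.subject_id}: {exc}") from exc
    return parc, records, connectomes


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a summary dict and writes TSV/JSON
    outputs under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, stream=sys.stderr,
                        format="%(levelname)s %(name)s: %(message)s")
    rng_master = np.random.SeedSequence(config.seed)
    sub_seeds = {name: int(s.generate_state(1)[0] % (2**31))
                 for name, s in zip(["louvain", "simulation", "resection"],
                                    rng_master.spawn(3))}
    summary: dict = {"version": __version__, "seed": config.seed,
                     "config": config.to_dict(), "stages": {}}
    parc, records, connectomes = _load_inputs(config)
    log.info("loaded %d subjects (%d parcels)", len(records), len(parc))

    # --- stage: per-subject metrics ---------------------------------------
    try:
        node_tables = {}
        graph_metrics = {}
        for r in records:
            C = connectomes[r.subject_id]
            node_tables[r.subject_id] = node_metrics(
                C, config.stabilization, config.ac_statistic)
            graph_metrics[r.subject_id] = graph_metric_set(
                C, louvain_repeats=config.louvain_repeats,
                seed=sub_seeds["louvain"])
        cohort = build_cohort_table(records, node_tables, graph_metrics)
        cohort.to_csv(out / "cohort_table.tsv", sep="\t", index=False)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("metrics", str(exc)) from exc
    summary["stages"]["metrics"] = {"n_subjects": len(records)}

    # --- stage: cohort statistics ----------------------------------------
    try:
        control_ids = [r.subject_id for r in records if r.group == "control"]
        Z = zscore_vs_controls(node_tables, control_ids)
        Z.data.to_csv(out / "zscores.tsv", sep="\t", index=False)
        comparisons = []
        for response, family in [("mean_wd", "gaussian"),
                                 ("mean_ac", "gaussian"),
                                 ("mean_mc", "gamma"),
                                 ("wd_ac_corr", "gaussian"),
                                 ("wd_mc_corr", "gaussian"),
                                 ("ac_mc_corr", "gaussian"),
                                 ("density", "gaussian"),
                                 ("modularity", "gaussian"),
                                 ("global_eff", "gaussian"),
                                 ("diffusion_eff", "gaussian")]:
            covs = ["age", "sex", "fsiq_class"]
            if response != "mean_wd":
                covs.append("mean_wd")
            table = cohort
            if config.subset_min_age is not None:
                table = subset_sensitivity(cohort, config.subset_min_age)
            for res in glm_group_compare(table, response, covs, family):
                comparisons.append(dataclasses.asdict(res))
        pd.DataFrame(comparisons).to_csv(out / "comparisons.tsv", sep="\t",
                                         index=False)
        patient_ids = [r.subject_id for r in records if r.group != "control"]
        flags = node_level_flags(Z, patient_ids, config.z_threshold)
        flag_rows = [{"metric": m, "direction": d,
                      "parcels": ";".join(map(str, sorted(s)))}
                     for m, dirs in flags.items() for d, s in dirs.items()]
        pd.DataFrame(flag_rows).to_csv(out / "flags.tsv", sep="\t",
                                       index=False)
        controls = [connectomes[c] for c in control_ids]
        patients = [connectomes[p] for p in patient_ids]
        diff = mean_matrix_difference(controls, patients,
                                      config.low_weight_cutoff)
        summary["stages"]["cohort"] = {
            "n_controls": len(control_ids),
            "low_weight_increase_counts": diff.counts,
        }
    except StageError:
        raise
    except Exception as exc:
        raise StageError("cohort", str(exc)) from exc

    # --- stage: fingerprint simulations -----------------------------------
    if config.run_simulations:
        try:
            sim = run_fingerprint_experiment(controls, config.simulation,
                                             seed=sub_seeds["simulation"])
            sim.fingerprints.to_csv(out / "sim_fingerprints.tsv", sep="\t",
                                    index=False)
            sim.zscores.to_csv(out / "sim_zscores.tsv", sep="\t", index=False)
            sim.tests.to_csv(out / "sim_tests.tsv", sep="\t", index=False)
            summary["stages"]["simulation"] = {
                "n_constrained": config.simulation.n_constrained_models,
                "n_null": config.simulation.n_null_models,
            }
        except Exception as exc:
            raise StageError("simulation", str(exc)) from exc

    # --- stage: resection analysis ----------------------------------------
    resective = [r for r in records
                 if r.group == "resective" and r.resected_parcels]
    if resective:
        try:
            summ = build_resection_summary(
                records, Z, connectomes=connectomes,
                control_connectomes=controls, n_virtual=config.n_virtual,
                seed=sub_seeds["resection"],
                stabilization=config.stabilization)
            summ.to_csv(out / "resection_summary.tsv", sep="\t", index=False)
            tests = resection_group_tests(summ)
            tests.to_csv(out / "resection_tests.tsv", sep="\t", index=False)
            summary["stages"]["resection"] = {"n_resective": len(resective)}
        except Exception as exc:
            raise StageError("resection", str(exc)) from exc

    (out / "run_summary.json").write_text(json.dumps(summary, indent=2,
                                                     default=str))
    log.info("pipeline complete: %s", out)
    return summary
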