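"""End-to-end orchestration: data in, every analysis stage, artifacts out.

Sequences the full analysis: probe collapsing (if a probe map is given),
per-layer fold-changes vs pooled controls, DE flagging at the active FDR
cutoff, profile correlations, the DE-vs-non-DE shift tests, the simple
variance-model null, the profile-shuffling nulls (DE and non-DE groups),
genome-wide correlations at three aggregation scales, and the FDR-cutoff
sweep with its regressions. All randomness flows from independent named
substreams of one seed, so changing the repetition count of one stage does
not perturb another's draws.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import correlations as corr
from . import datamodel as dm
from . import diffexpr as de
from . import nullmodels as nm
from . import robustness as rb
from . import simulate as sim

logger = logging.getLogger(__name__)

#: Named seed substreams, in spawn order.
SEED_STREAMS = ("generator", "simple_model", "shuffle_de", "shuffle_nonde")


def stage_seeds(seed: int) -> dict[str, int]:
    """Derive one independent 31-bit seed per named stage from a master seed."""
    children = np.random.SeedSequence(seed).spawn(len(SEED_STREAMS))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(SEED_STREAMS, children)
    }


@dataclasses.dataclass
class PipelineConfig:
    """One full-analysis configuration.

    Exactly one input source: either the four file paths (mRNA matrix,
    protein matrix, shared metadata sheet, optional probe map) or a
    :class:`~profcorr.simulate.SimulationConfig` for synthetic data.
    """

    mrna_path: str | None = None
    protein_path: str | None = None
    meta_path: str | None = None
    probe_map_path: str | None = None
    simulation: sim.SimulationConfig | None = None
    de_config: de.DEConfig = dataclasses.field(default_factory=de.DEConfig)
    reps_simple: int = 100_000
    reps_shuffle: int = 1000
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        have_paths = self.mrna_path is not None or self.protein_path is not None
        if have_paths == (self.simulation is not None):
            raise ValueError("supply exactly one of: input file paths, a simulation config")
        if have_paths and not (self.mrna_path and self.protein_path and self.meta_path):
            raise ValueError("file input needs mrna_path, protein_path and meta_path")


def _jsonable(obj):
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if isinstance(obj, (np.floating, np.integer)):
        return _jsonable(obj.item())
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return (and optionally write) the summary bundle.

    With ``out_dir`` set, writes fold-change tables, the correlation set,
    the sweep table and a ``summary.json`` holding every test result and
    group size. The summary is byte-identical across runs with the same
    config and seed.
    """
    seeds = stage_seeds(config.seed)

    # ---- load or simulate ------------------------------------------------
    if config.simulation is not None:
        sim_cfg = dataclasses.replace(config.simulation, seed=seeds["generator"])
        mrna, protein, truth = sim.generate_experiment(sim_cfg)
        logger.info("simulated experiment: %d genes, %d conditions", sim_cfg.n_genes, len(sim_cfg.conditions))
    else:
        mrna = dm.read_expression_dataset(config.mrna_path, "mrna", config.meta_path)
        protein = dm.read_expression_dataset(config.protein_path, "protein", config.meta_path)
        truth = None
        if config.probe_map_path:
            mrna = dm.collapse_probes(mrna, dm.read_probe_map(config.probe_map_path))

    # ---- fold changes and DE flags --------------------------------------
    fc_mrna = de.compute_fold_changes(mrna, moderation=config.de_config.moderation)
    fc_prot = de.compute_fold_changes(protein, moderation=config.de_config.moderation)
    flags = de.flag_de_profiles(fc_mrna, config.de_config.fdr_cutoff)
    logger.info("%d DE profile(s) at FDR < %g", len(flags), config.de_config.fdr_cutoff)

    # ---- correlations and the main shift test ---------------------------
    cs = corr.build_correlation_set(fc_mrna, fc_prot, flags)
    profiles = corr.build_profile_pairs(fc_mrna, fc_prot, flags)
    shift = corr.compare_shift(cs)

    # ---- simple variance-model null -------------------------------------
    simple = None
    if shift.n_de > 0 and shift.n_nonde > 0:
        params = nm.estimate_simple_model_params(fc_mrna, fc_prot, flags)
        null_d, null_w = nm.simple_model_pvalues(
            params, shift.ks_D, shift.wilcoxon_W,
            n_reps=config.reps_simple, seed=seeds["simple_model"],
        )
        simple = {
            "params": params.to_dict(),
            "ks_D": null_d.to_dict(),
            "wilcoxon_W": null_w.to_dict(),
        }
    else:
        logger.warning("skipping simple variance model: a DE group is empty")

    # ---- profile-shuffling nulls ----------------------------------------
    shuffles = {}
    for group, key in (("de", "shuffle_de"), ("nonde", "shuffle_nonde")):
        n_in_group = sum(p.de_flag == (group == "de") for p in profiles)
        if n_in_group < 2:
            logger.warning("skipping %s shuffle null: %d profile(s)", group, n_in_group)
            continue
        shuffles[group] = nm.shuffle_null_test(
            profiles, group=group, n_reps=config.reps_shuffle, seed=seeds[key]
        ).to_dict()

    # ---- genome-wide correlations ---------------------------------------
    genome = {}
    for scale in ("all", "by_condition", "by_gene"):
        r, n, p = corr.genome_wide(fc_mrna, fc_prot, scale)
        genome[scale] = {"r": r, "n": n, "p": p}

    # ---- FDR sweep -------------------------------------------------------
    sweep = rb.fdr_sweep(fc_mrna, fc_prot)
    regressions = {
        which: rb.sweep_regression(sweep, which).to_dict() for which in ("ks", "wilcoxon")
    }

    summary = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "n_features": int(mrna.n_features),
        "n_profiles": int(len(cs)),
        "n_de": shift.n_de,
        "n_nonde": shift.n_nonde,
        "fdr_cutoff": config.de_config.fdr_cutoff,
        "shift_test": shift.to_dict(),
        "simple_model": simple,
        "shuffle_null": shuffles,
        "genome_wide": genome,
        "sweep_regression": regressions,
        "sweep_rows": int(len(sweep.table)),
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        dm.write_fold_change_table(fc_mrna, out / "fold_changes_mrna.tsv")
        dm.write_fold_change_table(fc_prot, out / "fold_changes_protein.tsv")
        cs.to_csv(out / "correlations.tsv", sep="\t", index=False)
        rb.write_sweep(sweep, out / "sweep.tsv")
        if truth is not None:
            sim.write_truth_table(truth, out / "truth.tsv")
        with open(out / "summary.json", "w") as fh:
            json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
            fh.write("\n")

    summary["_tables"] = {"fc_mrna": fc_mrna, "fc_prot": fc_prot, "correlations": cs, "sweep": sweep.table}
    if truth is not None:
        summary["_tables"]["truth"] = truth
    return summary
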