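"""Synthetic replicate-level mRNA / protein experiment generator.

Emulates the shape of a two-tumour-model xenograft time course: 29 genes,
4 treatment conditions (2 tumour models x 2 drug regimes), 5 treated
harvest days, a handful of biological replicates per group, and pooled
untreated controls per tumour model. A tunable fraction of genes is
"responsive" — their mRNA follows a smooth latent treatment trajectory —
and the coupling parameter sets the expected correlation between a
responsive gene's mRNA and protein trajectories, so downstream stages can
be tested against known ground truth.

The latent trajectories are smoothed random curves rather than parametric
pharmacodynamic forms: only their correlation structure matters to the
analyses built on top.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import CONTROL, ExpressionDataset

#: Default condition tokens: tumour model prefix, drug regime suffix
#: (C = platinum monotherapy, CP = platinum + taxane combination).
DEFAULT_CONDITIONS = ("OV1002-C", "OV1002-CP", "HOX424-C", "HOX424-CP")

#: Harvest days of the treated time course.
DEFAULT_TIME_POINTS = (1, 2, 4, 7, 14)

#: Days controls are harvested on (cycled over control replicates; controls
#: are pooled per tumour model downstream, so the day is descriptive only).
CONTROL_DAYS = (0, 1, 2, 7, 14)


def tumour_model_of(condition: str) -> str:
    """Tumour model token of a condition (prefix before the first dash)."""
    return condition.split("-")[0]


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Attributes
    ----------
    n_genes
        Number of genes (features) measured on both layers.
    conditions
        Treatment condition tokens; the tumour model is the prefix before
        the first dash, so controls can be pooled per model.
    time_points
        Ordered treated harvest days.
    n_replicates
        Biological replicates per treated (condition, day) group, mRNA layer.
    n_replicates_protein
        Protein-layer replicates; ``None`` means same as mRNA.
    n_controls
        Pooled control replicates per tumour model (per layer).
    frac_responsive
        Fraction of genes given a treatment-driven mRNA trajectory.
    coupling
        Expected Pearson correlation between a responsive gene's latent
        mRNA and protein trajectories, in [-1, 1].
    effect_sd
        Amplitude (sd over time points) of latent treatment trajectories,
        in log2 fold-change units. The default keeps realised fold-changes
        mostly within [-1, 1].
    decoupled_noise_sd
        Amplitude of the independent protein trajectory of non-responsive
        genes (slow protein drift uncoupled from transcription).
    replicate_sd
        Measurement noise sd added independently to every replicate value.
    seed
        Seed for all randomness; identical config + seed gives
        bit-identical datasets.
    """

    n_genes: int = 29
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    time_points: tuple[int, ...] = DEFAULT_TIME_POINTS
    n_replicates: int = 3
    n_replicates_protein: int | None = None
    n_controls: int = 4
    frac_responsive: float = 0.4
    coupling: float = 0.8
    effect_sd: float = 0.6
    decoupled_noise_sd: float = 0.3
    replicate_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_replicates < 2 or (self.n_replicates_protein or 2) < 2:
            raise ValueError("need >= 2 replicates per group for two-sample t-tests")
        if self.n_controls < 2:
            raise ValueError("need >= 2 pooled control replicates")
        if not -1.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [-1, 1]")
        if not 0.0 <= self.frac_responsive <= 1.0:
            raise ValueError("frac_responsive must lie in [0, 1]")
        for name in ("effect_sd", "decoupled_noise_sd", "replicate_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if len(self.time_points) < 3:
            raise ValueError("need >= 3 time points for profile correlations")

    @property
    def tumour_models(self) -> tuple[str, ...]:
        seen: list[str] = []
        for c in self.conditions:
            tm = tumour_model_of(c)
            if tm not in seen:
                seen.append(tm)
        return tuple(seen)


def _smooth_unit_curve(rng: np.random.Generator, size: tuple[int, ...], t: int) -> np.ndarray:
    """Smoothed standardized random curves over ``t`` points.

    Draws t+2 iid normals per curve, smooths with a [1,2,1]/4 kernel, then
    standardizes each curve to mean 0 and sd 1 over its time points.
    """
    raw = rng.normal(size=size + (t + 2,))
    sm = 0.25 * raw[..., :-2] + 0.5 * raw[..., 1:-1] + 0.25 * raw[..., 2:]
    sm = sm - sm.mean(axis=-1, keepdims=True)
    sd = sm.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0  # degenerate draw: leave the flat curve at zero
    return sm / sd


def generate_experiment(
    config: SimulationConfig,
) -> tuple[ExpressionDataset, ExpressionDataset, pd.DataFrame]:
    """Simulate one experiment on both layers plus a ground-truth table.

    Returns
    -------
    mrna, protein
        :class:`ExpressionDataset` per layer, with treated samples per
        (condition, day, replicate) and pooled control samples per tumour
        model.
    truth
        One row per (gene, condition): ``responsive`` flag and ``true_r``,
        the realised Pearson correlation between the latent mRNA and
        protein trajectories (NaN for non-responsive genes, whose mRNA
        trajectory is flat).
    """
    t = len(config.time_points)
    genes = [f"G{i + 1:03d}" for i in range(config.n_genes)]
    n_resp = int(round(config.frac_responsive * config.n_genes))

    ss = np.random.SeedSequence(config.seed)
    rng_assign, rng_base, rng_traj, rng_noise = [np.random.default_rng(s) for s in ss.spawn(4)]

    responsive = np.zeros(config.n_genes, dtype=bool)
    responsive[rng_assign.choice(config.n_genes, size=n_resp, replace=False)] = True

    # per-gene baselines per layer (log2 scale)
    base_m = rng_base.normal(7.0, 1.0, size=config.n_genes)
    base_p = rng_base.normal(5.0, 1.0, size=config.n_genes)

    n_cond = len(config.conditions)
    z_m = _smooth_unit_curve(rng_traj, (config.n_genes, n_cond), t)
    z_ind = _smooth_unit_curve(rng_traj, (config.n_genes, n_cond), t)

    rho = config.coupling
    latent_m = np.zeros_like(z_m)
    latent_p = np.zeros_like(z_m)
    latent_m[responsive] = config.effect_sd * z_m[responsive]
    coupled = rho * z_m[responsive] + np.sqrt(max(0.0, 1.0 - rho**2)) * z_ind[responsive]
    latent_p[responsive] = config.effect_sd * coupled
    latent_p[~responsive] = config.decoupled_noise_sd * z_ind[~responsive]

    # realised latent trajectory correlation per (gene, condition)
    def _rowcorr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        ac = a - a.mean(axis=-1, keepdims=True)
        bc = b - b.mean(axis=-1, keepdims=True)
        denom = np.sqrt((ac**2).sum(-1) * (bc**2).sum(-1))
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, (ac * bc).sum(-1) / denom, np.nan)

    true_r = _rowcorr(latent_m, latent_p)
    true_r[~responsive, :] = np.nan

    truth = pd.DataFrame(
        {
            "feature": np.repeat(genes, n_cond),
            "condition": list(config.conditions) * config.n_genes,
            "responsive": np.repeat(responsive, n_cond),
            "true_r": true_r.ravel(),
        }
    )

    def _build_layer(layer: str, base: np.ndarray, latent: np.ndarray, n_rep: int) -> ExpressionDataset:
        cols: dict[str, np.ndarray] = {}
        meta_rows: list[dict] = []
        prefix = "m" if layer == "mrna" else "p"
        for ci, cond in enumerate(config.conditions):
            for ti, day in enumerate(config.time_points):
                for rep in range(1, n_rep + 1):
                    sid = f"{prefix}-{cond}-d{day}-r{rep}"
                    cols[sid] = base + latent[:, ci, ti] + rng_noise.normal(
                        0, config.replicate_sd, size=config.n_genes
                    )
                    meta_rows.append(
                        {
                            "sample_id": sid,
                            "condition": cond,
                            "tumour_model": tumour_model_of(cond),
                            "time_point": day,
                            "replicate": rep,
                        }
                    )
        for tm in config.tumour_models:
            for rep in range(1, config.n_controls + 1):
                sid = f"{prefix}-{tm}-CTRL-r{rep}"
                cols[sid] = base + rng_noise.normal(0, config.replicate_sd, size=config.n_genes)
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "condition": CONTROL,
                        "tumour_model": tm,
                        "time_point": CONTROL_DAYS[(rep - 1) % len(CONTROL_DAYS)],
                        "replicate": rep,
                    }
                )
        values = pd.DataFrame(cols, index=pd.Index(genes, name="feature"))
        samples = pd.DataFrame(meta_rows).set_index("sample_id")
        return ExpressionDataset(layer=layer, values=values, samples=samples)

    n_rep_p = config.n_replicates_protein or config.n_replicates
    mrna = _build_layer("mrna", base_m, latent_m, config.n_replicates)
    protein = _build_layer("protein", base_p, latent_p, n_rep_p)
    return mrna, protein, truth


def generate_null_experiment(
    config: SimulationConfig,
) -> tuple[ExpressionDataset, ExpressionDataset, pd.DataFrame]:
    """Global-null variant: no responsive genes, layers fully independent.

    Forces ``frac_responsive = 0`` and ``coupling = 0``; used for
    calibration tests of the downstream significance machinery.
    """
    null_cfg = dataclasses.replace(config, frac_responsive=0.0, coupling=0.0)
    return generate_experiment(null_cfg)


def write_truth_table(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)
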