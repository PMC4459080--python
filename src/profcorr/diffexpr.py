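"""Per-time-point fold-changes vs pooled controls, moderated t-tests, BH-FDR.

Each treated (condition, time point) group is contrasted against the pooled
untreated controls of its tumour model: log_fc is the difference of group
means on the log2 scale, and the p-value comes from a pooled-variance
two-sample t-statistic. With ``moderation="empirical_bayes"`` the gene-wise
variances within a contrast are shrunk toward a common prior fitted across
genes (a moderated t in the style of empirical-Bayes linear-model DE
analysis), which stabilises small-replicate tests and gives zero-variance
genes a positive variance floor. ``moderation="none"`` reproduces the
textbook pooled t-test exactly and exists for oracle testing.

BH adjustment is applied across genes within each (condition, time)
contrast. A profile (gene, condition) is flagged differentially expressed
when any of its time points has an adjusted p-value below the cutoff.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datamodel import CONTROL, FC_COLUMNS, ExpressionDataset, validate_fold_change_table

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class DEConfig:
    """Differential-expression settings.

    fdr_cutoff: BH-adjusted p-value threshold for calling a profile DE.
    moderation: "empirical_bayes" (default) or "none".
    """

    fdr_cutoff: float = 0.05
    moderation: str = "empirical_bayes"

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_cutoff < 1.0:
            raise ValueError("fdr_cutoff must lie strictly between 0 and 1")
        if self.moderation not in ("none", "empirical_bayes"):
            raise ValueError(f"unknown moderation {self.moderation!r}")


# ---------------------------------------------------------------------------
# Empirical-Bayes variance squeezing
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    # trigamma(y) ~ 1/y for large y, ~ 1/y^2 for small y
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def squeeze_variances(s2: np.ndarray, df: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Shrink gene-wise sample variances toward a common prior.

    Fits a scaled inverse-chi-square prior (prior df ``d0``, location
    ``s0^2``) to the observed variances by matching the first two moments
    of ``log s^2`` (using digamma/trigamma corrections for the chi-square
    sampling distribution of each ``s^2``), then returns the posterior
    variances ``(d0 s0^2 + df s^2) / (d0 + df)``.

    Genes with zero or missing variance are excluded from the fit but
    still squeezed, which floors zero sample variances at a positive
    value whenever ``d0 > 0``.

    Returns (posterior variances, d0, s0_squared).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        # nothing to fit: fall back to the raw variances
        return s2.copy(), 0.0, float("nan")

    z = np.log(s2[ok])
    e = z - special.digamma(df[ok] / 2.0) + np.log(df[ok] / 2.0)
    e_mean = float(e.mean())
    e_var = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, df[ok] / 2.0)))

    if e_var <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    else:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))

    with np.errstate(invalid="ignore"):
        if np.isinf(d0):
            post = np.full_like(s2, s0_sq)
            post[~np.isfinite(s2)] = np.nan
        else:
            post = (d0 * s0_sq + df * np.where(np.isfinite(s2), s2, 0.0)) / (d0 + df)
            post[~np.isfinite(s2) & (df <= 0)] = np.nan
    return post, float(d0), s0_sq


# ---------------------------------------------------------------------------
# Fold changes and p-values
# ---------------------------------------------------------------------------

def compute_fold_changes(dataset: ExpressionDataset, moderation: str = "empirical_bayes") -> pd.DataFrame:
    """Per-gene log2 fold-changes of each treated group vs pooled controls.

    For every (condition, time point) contrast: log_fc is the difference in
    means between the treated replicates and the pooled controls of the
    condition's tumour model; p_raw comes from a pooled-variance t-statistic,
    moderated across genes when requested; p_adj is BH within the contrast.

    Contrasts where a gene has fewer than 2 usable replicates on either
    side keep their fold-change (means are defined from one replicate) but
    get missing p-values, with a logged warning.
    """
    if moderation not in ("none", "empirical_bayes"):
        raise ValueError(f"unknown moderation {moderation!r}")

    meta = dataset.samples
    treated = meta[meta["condition"] != CONTROL]
    rows: list[pd.DataFrame] = []
    for (cond, day), grp in treated.groupby(["condition", "time_point"], sort=True):
        tms = grp["tumour_model"].unique()
        if len(tms) != 1:
            raise ValueError(f"condition {cond!r} spans multiple tumour models: {tms}")
        ctrl_ids = dataset.control_samples(tms[0])
        if not ctrl_ids:
            raise ValueError(f"no pooled controls for tumour model {tms[0]!r}")
        tvals = dataset.values[list(grp.index)].to_numpy()
        cvals = dataset.values[ctrl_ids].to_numpy()

        n1 = np.sum(np.isfinite(tvals), axis=1)
        n0 = np.sum(np.isfinite(cvals), axis=1)
        m1 = np.where(n1 > 0, np.nanmean(np.where(np.isfinite(tvals), tvals, np.nan), axis=1), np.nan)
        m0 = np.where(n0 > 0, np.nanmean(np.where(np.isfinite(cvals), cvals, np.nan), axis=1), np.nan)
        log_fc = m1 - m0

        usable = (n1 >= 2) & (n0 >= 2)
        if not usable.all():
            bad = dataset.values.index[~usable].tolist()
            logger.warning(
                "contrast (%s, day %s): %d gene(s) with <2 replicates on a side; "
                "p-values set to missing: %s", cond, day, len(bad), bad[:5],
            )

        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="Degrees of freedom")
            v1 = np.nanvar(np.where(np.isfinite(tvals), tvals, np.nan), axis=1, ddof=1)
            v0 = np.nanvar(np.where(np.isfinite(cvals), cvals, np.nan), axis=1, ddof=1)
        df = np.where(usable, n1 + n0 - 2.0, np.nan)
        with np.errstate(invalid="ignore"):
            s2 = np.where(usable, ((n1 - 1) * v1 + (n0 - 1) * v0) / df, np.nan)

        if moderation == "empirical_bayes":
            s2_used, d0, _ = squeeze_variances(s2, df)
            df_used = df + (0.0 if not np.isfinite(d0) else d0)
            if np.isinf(d0):
                df_used = np.full_like(df, np.inf)
        else:
            s2_used, df_used = s2, df

        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(s2_used * (1.0 / n1 + 1.0 / n0))
            tstat = log_fc / se
        p_raw = np.full(len(log_fc), np.nan)
        # infinite t (zero residual variance, nonzero fold-change) gives p = 0
        fin = usable & ~np.isnan(tstat)
        p_raw[fin] = 2.0 * stats.t.sf(np.abs(tstat[fin]), df_used[fin])

        rows.append(
            pd.DataFrame(
                {
                    "feature": dataset.values.index,
                    "condition": cond,
                    "time": day,
                    "log_fc": log_fc,
                    "p_raw": p_raw,
                }
            )
        )

    fc = pd.concat(rows, ignore_index=True)
    # BH across genes within each (condition, time) contrast
    fc["p_adj"] = np.nan
    for _, idx in fc.groupby(["condition", "time"], sort=False).groups.items():
        fc.loc[idx, "p_adj"] = adjust_fdr(fc.loc[idx, "p_raw"].to_numpy())
    fc = fc.loc[:, list(FC_COLUMNS)]
    return validate_fold_change_table(fc)


def adjust_fdr(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Missing values pass through as missing; everything else must lie in
    [0, 1]. Output is capped at 1 and satisfies the step-up monotonicity.
    """
    p = np.asarray(list(p_values) if not isinstance(p_values, np.ndarray) else p_values, dtype=float)
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if ok.sum() > 0:
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def flag_de_profiles(fc: pd.DataFrame, cutoff: float = 0.05) -> set[tuple[str, str]]:
    """(feature, condition) pairs differentially expressed at the cutoff.

    A profile is flagged iff the minimum adjusted p-value over its time
    points is below ``cutoff``. Profiles with all p-values missing are
    excluded from flagging and logged.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie strictly between 0 and 1")
    minp = fc.groupby(["feature", "condition"], sort=False)["p_adj"].min()
    all_missing = minp.index[minp.isna()]
    if len(all_missing):
        logger.warning("%d profile(s) with no usable p-values excluded from DE flagging", len(all_missing))
    return {(f, c) for (f, c), v in minp.items() if np.isfinite(v) and v < cutoff}


def min_adjusted_p(fc: pd.DataFrame) -> pd.Series:
    """Minimum adjusted p-value per (feature, condition) profile."""
    return fc.groupby(["feature", "condition"], sort=False)["p_adj"].min()
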