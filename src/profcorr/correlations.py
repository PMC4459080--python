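"""Profile correlations, DE vs non-DE shift tests, genome-wide correlations.

An individual-gene "profile correlation" is the Pearson coefficient between
a gene's mRNA and protein log fold-change vectors over the treated time
points of one condition. The central comparison asks whether the
correlation distribution of differentially expressed profiles is shifted
above that of non-differentially expressed profiles (two-sample
Kolmogorov–Smirnov on the distributions, Wilcoxon rank-sum on the medians).

Genome-wide correlations pool fold-changes across genes at three
aggregation scales: every (gene, condition, time) measurement; means over
time within a condition; means over everything per gene.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ProfilePair

logger = logging.getLogger(__name__)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3).

    Raises ValueError on length mismatch, n < 3, non-finite entries, or a
    constant vector (the correlation is undefined there; callers drop such
    profiles with a warning rather than impute).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in correlation input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# Profile pairs and the correlation set
# ---------------------------------------------------------------------------

def build_profile_pairs(
    mrna_fc: pd.DataFrame,
    prot_fc: pd.DataFrame,
    de_flags: set[tuple[str, str]],
) -> list[ProfilePair]:
    """Align the two layers' fold-changes into time-ordered profile pairs.

    One :class:`ProfilePair` per (feature, condition) present with a
    complete time course in both layers; incomplete profiles are dropped
    and logged.
    """
    pairs: list[ProfilePair] = []
    m_piv = mrna_fc.pivot_table(index=["feature", "condition"], columns="time", values="log_fc")
    p_piv = prot_fc.pivot_table(index=["feature", "condition"], columns="time", values="log_fc")
    times = sorted(set(m_piv.columns) & set(p_piv.columns))
    if len(times) < 3:
        raise ValueError("fewer than 3 shared time points between layers")
    n_dropped = 0
    for key in m_piv.index.intersection(p_piv.index):
        mv = m_piv.loc[key, times].to_numpy(dtype=float)
        pv = p_piv.loc[key, times].to_numpy(dtype=float)
        if not (np.isfinite(mv).all() and np.isfinite(pv).all()):
            n_dropped += 1
            continue
        feature, condition = key
        pairs.append(ProfilePair(feature, condition, mv, pv, de_flag=key in de_flags))
    if n_dropped:
        logger.warning("%d incomplete profile(s) dropped", n_dropped)
    return pairs


def build_correlation_set(
    mrna_fc: pd.DataFrame,
    prot_fc: pd.DataFrame,
    de_flags: set[tuple[str, str]],
) -> pd.DataFrame:
    """Per-profile Pearson correlations with DE flags attached.

    Returns a frame with columns feature, condition, r, de_flag — one row
    per complete (feature, condition) profile. With a complete n-gene x
    k-condition design this holds n*k records. Constant profiles (zero
    variance over the time points) are dropped with a warning.
    """
    records = []
    n_constant = 0
    for pp in build_profile_pairs(mrna_fc, prot_fc, de_flags):
        try:
            r = pearson(pp.mrna_lfc, pp.protein_lfc)
        except ValueError:
            n_constant += 1
            continue
        records.append({"feature": pp.feature, "condition": pp.condition, "r": r, "de_flag": pp.de_flag})
    if n_constant:
        logger.warning("%d constant profile(s) dropped (correlation undefined)", n_constant)
    return pd.DataFrame(records, columns=["feature", "condition", "r", "de_flag"])


# ---------------------------------------------------------------------------
# Distribution-shift tests
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ShiftTestResult:
    """Two-sample comparison of DE vs non-DE profile correlations.

    ``wilcoxon_W`` is the Mann–Whitney U statistic of the DE (first) group;
    ``ks_D`` the two-sample Kolmogorov–Smirnov statistic. Empty groups give
    missing statistics and p-values.
    """

    ks_D: float
    ks_p: float
    wilcoxon_W: float
    wilcoxon_p: float
    n_de: int
    n_nonde: int
    median_de: float = float("nan")
    median_nonde: float = float("nan")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def two_sample_shift(
    first: np.ndarray,
    second: np.ndarray,
    ks_alternative: str = "two-sided",
    wilcoxon_alternative: str = "greater",
    method: str = "auto",
) -> tuple[float, float, float, float]:
    """KS and Wilcoxon rank-sum of ``first`` vs ``second``.

    Defaults: two-sided KS, one-sided Wilcoxon with alternative "first
    group stochastically greater" — the direction of interest is a shift
    of DE correlations toward higher values. ``method`` follows scipy
    (exact for small untied samples, asymptotic with continuity correction
    otherwise).
    """
    ks_method = {"asymptotic": "asymp"}.get(method, method)
    mw_method = {"asymp": "asymptotic"}.get(method, method)
    ks = stats.ks_2samp(first, second, alternative=ks_alternative, method=ks_method)
    mw = stats.mannwhitneyu(first, second, alternative=wilcoxon_alternative, method=mw_method)
    return float(ks.statistic), float(ks.pvalue), float(mw.statistic), float(mw.pvalue)


def compare_shift(
    cs: pd.DataFrame,
    ks_alternative: str = "two-sided",
    wilcoxon_alternative: str = "greater",
    method: str = "auto",
) -> ShiftTestResult:
    """Test whether DE profile correlations are shifted above non-DE ones."""
    de = cs.loc[cs["de_flag"], "r"].to_numpy(dtype=float)
    nonde = cs.loc[~cs["de_flag"], "r"].to_numpy(dtype=float)
    if len(de) == 0 or len(nonde) == 0:
        logger.warning(
            "empty group in shift test (n_de=%d, n_nonde=%d); p-values missing", len(de), len(nonde)
        )
        nan = float("nan")
        return ShiftTestResult(nan, nan, nan, nan, len(de), len(nonde))
    ks_D, ks_p, w, w_p = two_sample_shift(de, nonde, ks_alternative, wilcoxon_alternative, method)
    return ShiftTestResult(
        ks_D, ks_p, w, w_p, len(de), len(nonde),
        median_de=float(np.median(de)), median_nonde=float(np.median(nonde)),
    )


# ---------------------------------------------------------------------------
# Genome-wide correlations
# ---------------------------------------------------------------------------

def genome_wide(
    mrna_fc: pd.DataFrame,
    prot_fc: pd.DataFrame,
    scale: str = "all",
) -> tuple[float, int, float]:
    """Pooled mRNA–protein fold-change correlation at one aggregation scale.

    scale="all": every matched (feature, condition, time) pair.
    scale="by_condition": fold-changes averaged over time first, one point
    per (feature, condition).
    scale="by_gene": averaged over time and conditions, one point per gene.

    Returns (Pearson r, n pairs used, two-sided p).
    """
    merged = mrna_fc.merge(
        prot_fc, on=["feature", "condition", "time"], suffixes=("_mrna", "_prot")
    )[["feature", "condition", "time", "log_fc_mrna", "log_fc_prot"]].dropna(
        subset=["log_fc_mrna", "log_fc_prot"]
    )
    if scale == "all":
        pts = merged
    elif scale == "by_condition":
        pts = merged.groupby(["feature", "condition"], as_index=False)[["log_fc_mrna", "log_fc_prot"]].mean()
    elif scale == "by_gene":
        pts = merged.groupby("feature", as_index=False)[["log_fc_mrna", "log_fc_prot"]].mean()
    else:
        raise ValueError(f"unknown scale {scale!r}")
    n = len(pts)
    if n < 3:
        raise ValueError(f"genome-wide correlation needs >= 3 pairs, got {n}")
    res = stats.pearsonr(pts["log_fc_mrna"], pts["log_fc_prot"])
    return float(res.statistic), n, float(res.pvalue)
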