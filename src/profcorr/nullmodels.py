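"""Bespoke significance procedures for the profile-correlation comparison.

Two nulls guard the headline DE-vs-non-DE shift against artifacts:

1. A *simple variance model*: every gene shares one linear mRNA→protein
   relationship, y = m·x + b + e with e ~ N(0, sigma_e), but mRNA values
   are drawn from either a high-variance distribution (matched to DE
   profiles' fold-changes) or a low-variance one (matched to non-DE). If
   the observed KS/Wilcoxon statistics merely reflected the larger dynamic
   range of DE profiles, this model would reproduce them. Empirical
   p-values come from many repetitions of the simulated comparison.

2. *Profile-label shuffling*: permuting which mRNA profile is paired with
   which protein profile (time order within each profile preserved),
   recomputing correlations per shuffle, and comparing the actual
   correlation distribution of a group against the pooled shuffled one.

Empirical p-values are count(null >= observed) / n_reps by default; an
optional +1 smoothing is available since the plain ratio can return 0.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .correlations import ShiftTestResult, two_sample_shift
from .datamodel import ProfilePair

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class SimpleModelParams:
    """Parameters of the shared linear mRNA→protein null model.

    m, b: slope and intercept of the OLS fit of protein on mRNA
    fold-changes over all matched measurements; sigma_e: residual sd of
    that fit. (mu_high, sd_high) / (mu_low, sd_low): moments of the mRNA
    fold-changes belonging to DE / non-DE profiles. n_high / n_low: how
    many profiles of each kind to simulate; T: points per profile.
    """

    m: float
    b: float
    sigma_e: float
    mu_high: float
    sd_high: float
    mu_low: float
    sd_low: float
    n_high: int
    n_low: int
    T: int = 5

    def __post_init__(self) -> None:
        if self.sd_high <= 0 or self.sd_low <= 0:
            raise ValueError("mRNA fold-change sds must be positive")
        if self.sigma_e < 0:
            raise ValueError("sigma_e must be non-negative")
        if self.n_high < 1 or self.n_low < 1:
            raise ValueError("need at least one profile per group")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class NullResult:
    """Observed statistic vs an empirical null sample."""

    observed: float
    null_sample: np.ndarray
    p_empirical: float
    n_reps: int

    def to_dict(self, include_sample: bool = False) -> dict:
        d = {"observed": self.observed, "p_empirical": self.p_empirical, "n_reps": self.n_reps}
        if include_sample:
            d["null_sample"] = np.asarray(self.null_sample).tolist()
        return d


def empirical_pvalue(null_sample: np.ndarray, observed: float, plus_one: bool = False) -> float:
    """Fraction of null statistics >= the observed statistic.

    ``plus_one`` applies the (k+1)/(N+1) correction, bounding the p-value
    away from zero.
    """
    null_sample = np.asarray(null_sample, dtype=float)
    k = int(np.sum(null_sample >= observed))
    n = null_sample.size
    return (k + 1) / (n + 1) if plus_one else k / n


# ---------------------------------------------------------------------------
# Parameter estimation
# ---------------------------------------------------------------------------

def estimate_simple_model_params(
    mrna_fc: pd.DataFrame,
    prot_fc: pd.DataFrame,
    de_flags: set[tuple[str, str]],
) -> SimpleModelParams:
    """Fit the shared linear model and the two mRNA variance groups.

    (m, b) is the OLS fit of protein fold-change on mRNA fold-change over
    all matched (feature, condition, time) measurements; sigma_e is the
    residual standard error of that fit (ddof = 2). The high/low moments
    are the mean and sd (ddof = 1) of the mRNA fold-changes of DE and
    non-DE profiles respectively, and n_high/n_low count those profiles.
    """
    merged = mrna_fc.merge(
        prot_fc, on=["feature", "condition", "time"], suffixes=("_mrna", "_prot")
    ).dropna(subset=["log_fc_mrna", "log_fc_prot"])
    if len(merged) < 3:
        raise ValueError("need at least 3 matched fold-change pairs")
    x = merged["log_fc_mrna"].to_numpy()
    y = merged["log_fc_prot"].to_numpy()
    design = np.column_stack([x, np.ones_like(x)])
    (m, b), *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - (m * x + b)
    sigma_e = float(np.sqrt(np.sum(resid**2) / (len(resid) - 2)))

    is_de = merged.apply(lambda row: (row["feature"], row["condition"]) in de_flags, axis=1).to_numpy()
    x_high, x_low = x[is_de], x[~is_de]
    if x_high.size < 2 or x_low.size < 2:
        raise ValueError("each variance group needs >= 2 mRNA fold-changes")
    profiles = merged[["feature", "condition"]].drop_duplicates()
    prof_de = [
        (f, c) in de_flags for f, c in zip(profiles["feature"], profiles["condition"])
    ]
    n_high = int(np.sum(prof_de))
    n_low = int(len(prof_de) - n_high)
    times = merged["time"].nunique()
    return SimpleModelParams(
        m=float(m),
        b=float(b),
        sigma_e=sigma_e,
        mu_high=float(x_high.mean()),
        sd_high=float(x_high.std(ddof=1)),
        mu_low=float(x_low.mean()),
        sd_low=float(x_low.std(ddof=1)),
        n_high=max(n_high, 1),
        n_low=max(n_low, 1),
        T=int(times),
    )


# ---------------------------------------------------------------------------
# Simulation core (vectorised over repetitions)
# ---------------------------------------------------------------------------

def _rowwise_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r along the last axis; sign(m)-degenerate rows give ±1, 0/0 gives NaN."""
    xc = x - x.mean(axis=-1, keepdims=True)
    yc = y - y.mean(axis=-1, keepdims=True)
    num = (xc * yc).sum(axis=-1)
    denom = np.sqrt((xc**2).sum(axis=-1) * (yc**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / denom
    return np.clip(r, -1.0, 1.0)


def _simulate_correlation_groups(
    params: SimpleModelParams, rng: np.random.Generator, n_reps: int
) -> tuple[np.ndarray, np.ndarray]:
    """(n_reps, n_high) and (n_reps, n_low) simulated profile correlations."""

    def group(n: int, mu: float, sd: float) -> np.ndarray:
        x = rng.normal(mu, sd, size=(n_reps, n, params.T))
        if params.sigma_e == 0:
            # y is an exact affine image of x: r = sign(m) (undefined at m = 0)
            fill = np.sign(params.m) if params.m != 0 else np.nan
            return np.full((n_reps, n), fill)
        y = params.m * x + params.b + rng.normal(0.0, params.sigma_e, size=x.shape)
        return _rowwise_pearson(x, y)

    return group(params.n_high, params.mu_high, params.sd_high), group(
        params.n_low, params.mu_low, params.sd_low
    )


def _ks_and_u(high: np.ndarray, low: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sample KS D and Mann–Whitney U (of the high group).

    Tie-aware: the CDF difference is only evaluated once all copies of a
    tied value are counted, and U uses midranks, matching the standard
    definitions on degenerate samples.
    """
    n1, n2 = high.shape[1], low.shape[1]
    pooled = np.concatenate([high, low], axis=1)
    order = np.argsort(pooled, axis=1, kind="stable")
    from_high = order < n1
    cdf1 = np.cumsum(from_high, axis=1) / n1
    cdf2 = np.cumsum(~from_high, axis=1) / n2
    sorted_vals = np.take_along_axis(pooled, order, axis=1)
    at_step = np.ones_like(sorted_vals, dtype=bool)
    at_step[:, :-1] = sorted_vals[:, :-1] != sorted_vals[:, 1:]
    d = np.max(np.where(at_step, np.abs(cdf1 - cdf2), 0.0), axis=1)
    ranks = stats.rankdata(pooled, axis=1)
    u = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0
    return d, u


def simple_model_comparison(params: SimpleModelParams, rng_seed: int) -> tuple[float, float]:
    """One simulated high-vs-low comparison: (KS D, Mann–Whitney U).

    Generates n_high profiles of T draws from the high-variance mRNA
    distribution (protein via y = m·x + b + e), n_low from the low-variance
    one, correlates each profile, and compares the two correlation samples.
    """
    rng = np.random.default_rng(rng_seed)
    high, low = _simulate_correlation_groups(params, rng, 1)
    d, u = _ks_and_u(high, low)
    return float(d[0]), float(u[0])


def simple_model_pvalues(
    params: SimpleModelParams,
    observed_D: float,
    observed_W: float,
    n_reps: int = 100_000,
    seed: int = 0,
    plus_one: bool = False,
    chunk: int = 4096,
) -> tuple[NullResult, NullResult]:
    """Empirical p-values of the observed KS D and Wilcoxon/Mann–Whitney U.

    Repeats the simulated comparison ``n_reps`` times and counts, per
    statistic independently, how often the simulated value is >= the
    observed one. ``observed_W`` must use the same U convention
    (first-group U) as :func:`simple_model_comparison`.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    d_all = np.empty(n_reps)
    u_all = np.empty(n_reps)
    done = 0
    while done < n_reps:
        take = min(chunk, n_reps - done)
        high, low = _simulate_correlation_groups(params, rng, take)
        d, u = _ks_and_u(high, low)
        d_all[done : done + take] = d
        u_all[done : done + take] = u
        done += take
    p_d = empirical_pvalue(d_all, observed_D, plus_one)
    p_u = empirical_pvalue(u_all, observed_W, plus_one)
    return (
        NullResult(observed_D, d_all, p_d, n_reps),
        NullResult(observed_W, u_all, p_u, n_reps),
    )


# ---------------------------------------------------------------------------
# Profile-label shuffling
# ---------------------------------------------------------------------------

def shuffle_profiles(profiles: Sequence[ProfilePair], rng_seed: int | np.random.Generator) -> list[ProfilePair]:
    """Permute which mRNA profile is paired with which protein profile.

    The mRNA vectors are reassigned by a uniform random permutation (fixed
    points allowed) across the profile set; protein vectors stay put and
    every profile keeps its internal time order, so the multiset of mRNA
    vectors is conserved.
    """
    if len(profiles) < 2:
        raise ValueError("shuffling needs at least 2 profiles")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    perm = rng.permutation(len(profiles))
    return [
        ProfilePair(p.feature, p.condition, profiles[j].mrna_lfc.copy(), p.protein_lfc.copy(), p.de_flag)
        for p, j in zip(profiles, perm)
    ]


def shuffle_null_test(
    profiles: Sequence[ProfilePair],
    group: str = "de",
    n_reps: int = 1000,
    seed: int = 0,
    within_condition: bool = False,
    ks_alternative: str = "two-sided",
    wilcoxon_alternative: str = "greater",
) -> ShiftTestResult:
    """Compare a group's actual correlations against its shuffled null.

    Selects the DE (``group="de"``) or non-DE (``"nonde"``) profiles,
    shuffles the mRNA-protein pairing within that group ``n_reps`` times
    (optionally only among profiles of the same condition), recomputes the
    profile correlations per shuffle, pools them, and runs KS and Wilcoxon
    tests of the actual correlation sample against the pooled shuffled one
    (default alternative: actual greater for Wilcoxon, two-sided KS).
    """
    if group not in ("de", "nonde"):
        raise ValueError("group must be 'de' or 'nonde'")
    want = group == "de"
    sel = [p for p in profiles if p.de_flag == want]
    if len(sel) < 2:
        raise ValueError(f"group {group!r} has {len(sel)} profile(s); shuffling undefined")

    m = np.stack([p.mrna_lfc for p in sel])
    pmat = np.stack([p.protein_lfc for p in sel])
    actual = _rowwise_pearson(m, pmat)
    ok = np.isfinite(actual)
    if not ok.all():
        logger.warning("%d constant profile(s) dropped from actual correlations", int((~ok).sum()))
        actual = actual[ok]

    if within_condition:
        conds = np.array([p.condition for p in sel])
        blocks = [np.nonzero(conds == c)[0] for c in pd.unique(conds)]
    else:
        blocks = [np.arange(len(sel))]

    rng = np.random.default_rng(seed)
    pooled = np.empty((n_reps, len(sel)))
    idx = np.arange(len(sel))
    for i in range(n_reps):
        perm = idx.copy()
        for blk in blocks:
            perm[blk] = blk[rng.permutation(len(blk))]
        pooled[i] = _rowwise_pearson(m[perm], pmat)
    shuffled = pooled.ravel()
    shuffled = shuffled[np.isfinite(shuffled)]

    ks_D, ks_p, w, w_p = two_sample_shift(
        actual, shuffled, ks_alternative, wilcoxon_alternative, method="asymp"
    )
    return ShiftTestResult(
        ks_D, ks_p, w, w_p, n_de=len(actual), n_nonde=len(shuffled),
        median_de=float(np.median(actual)), median_nonde=float(np.median(shuffled)),
    )
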