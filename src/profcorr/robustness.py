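"""FDR-cutoff sensitivity sweep for the DE vs non-DE correlation comparison.

If the shift of DE profile correlations toward higher values is genuinely
tied to differential expression, making the DE definition stricter (lower
FDR cutoff) should sharpen the contrast: comparison p-values should grow
with the cutoff. The sweep re-flags DE profiles at every cutoff from 0.01
to 0.50 in steps of 0.01, reruns the KS and Wilcoxon comparisons, and
regresses each comparison p-value on the cutoff.

Cutoffs yielding fewer than ten DE profiles are retained but marked
(``small_de``): the tests there are underpowered, and a caller may exclude
them from the regression. All rows enter the default regression.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .correlations import build_correlation_set, compare_shift
from .diffexpr import min_adjusted_p

logger = logging.getLogger(__name__)

#: Default cutoffs 0.01 .. 0.50 in steps of 0.01.
DEFAULT_CUTOFFS = tuple(np.round(np.arange(1, 51) * 0.01, 2))

#: Below this many DE profiles the comparison is marked underpowered.
SMALL_DE_THRESHOLD = 10


@dataclasses.dataclass
class SweepRegression:
    slope: float
    t_stat: float
    df: int
    p: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class SweepResult:
    """Per-cutoff comparison results plus the cutoffs used.

    ``table`` columns: cutoff, n_de, n_nonde, ks_p, wilcoxon_p, small_de.
    """

    table: pd.DataFrame


def fdr_sweep(
    mrna_fc: pd.DataFrame,
    prot_fc: pd.DataFrame,
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS,
    ks_alternative: str = "two-sided",
    wilcoxon_alternative: str = "greater",
) -> SweepResult:
    """Re-run the DE-vs-non-DE shift comparison over a grid of FDR cutoffs.

    The profile correlations do not depend on the cutoff, so they are
    computed once; only the DE flags are re-derived per cutoff (the flagged
    set grows monotonically with the cutoff). Cutoffs at which either group
    is empty yield missing p-values with a warning.
    """
    cutoffs = tuple(cutoffs)
    if len(cutoffs) == 0:
        raise ValueError("empty cutoff vector")
    if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError("cutoffs must be strictly increasing")

    cs = build_correlation_set(mrna_fc, prot_fc, de_flags=set())
    minp = min_adjusted_p(mrna_fc)
    keys = pd.MultiIndex.from_frame(cs[["feature", "condition"]])
    prof_minp = minp.reindex(keys).to_numpy()

    rows = []
    for cut in cutoffs:
        flags = np.isfinite(prof_minp) & (prof_minp < cut)
        cs_cut = cs.assign(de_flag=flags)
        res = compare_shift(cs_cut, ks_alternative, wilcoxon_alternative)
        rows.append(
            {
                "cutoff": cut,
                "n_de": int(flags.sum()),
                "n_nonde": int((~flags).sum()),
                "ks_p": res.ks_p,
                "wilcoxon_p": res.wilcoxon_p,
                "small_de": int(flags.sum()) < SMALL_DE_THRESHOLD,
            }
        )
    return SweepResult(table=pd.DataFrame(rows))


def sweep_regression(sweep: SweepResult, which: str = "ks", exclude_small_de: bool = False) -> SweepRegression:
    """OLS of the comparison p-value on the FDR cutoff.

    Returns the slope, its t-statistic, the residual degrees of freedom
    (non-missing rows minus 2) and the two-sided p-value of the slope.
    """
    col = {"ks": "ks_p", "wilcoxon": "wilcoxon_p"}.get(which)
    if col is None:
        raise ValueError("which must be 'ks' or 'wilcoxon'")
    tab = sweep.table
    if exclude_small_de:
        tab = tab[~tab["small_de"]]
    tab = tab.dropna(subset=[col])
    if len(tab) < 3:
        raise ValueError(f"need >= 3 non-missing {col} values, got {len(tab)}")
    fit = stats.linregress(tab["cutoff"].to_numpy(), tab[col].to_numpy())
    df = len(tab) - 2
    if fit.stderr == 0:
        # exact fit: slope recovered with zero residual variance
        t_stat = np.inf if fit.slope != 0 else 0.0
        p = 0.0 if fit.slope != 0 else 1.0
    else:
        t_stat = fit.slope / fit.stderr
        p = float(fit.pvalue)
    return SweepRegression(slope=float(fit.slope), t_stat=float(t_stat), df=df, p=float(p))


def write_sweep(sweep: SweepResult, path) -> None:
    sweep.table.to_csv(path, sep="\t", index=False)
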