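"""Core data structures and delimited-text I/O shared by all pipeline stages.

The pipeline operates on two expression layers measured on the same genes:
log2-scale mRNA expression (normalized upstream) and log2-transformed
protein abundance scores from quantitative immunofluorescence. Samples are
either drug-treated (a condition token plus a harvest day) or untreated
controls, which are pooled per tumour model and serve as the common
baseline for all fold-changes in that model.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Condition token reserved for untreated control samples.
CONTROL = "CONTROL"

#: Recognised expression layers.
LAYERS = ("mrna", "protein")

#: Columns of a sample-metadata sheet, in canonical order.
META_COLUMNS = ("sample_id", "layer", "condition", "tumour_model", "time_point", "replicate")

#: Columns of a fold-change table, in canonical order.
FC_COLUMNS = ("feature", "condition", "time", "log_fc", "p_raw", "p_adj")


def _delim(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


@dataclasses.dataclass
class ExpressionDataset:
    """Replicate-level expression values for one layer plus sample metadata.

    Parameters
    ----------
    layer
        ``"mrna"`` or ``"protein"``.
    values
        Feature x sample matrix of real expression values. Missing
        measurements are encoded explicitly as NaN; infinities are invalid.
    samples
        Sample metadata indexed by sample id with columns ``condition``,
        ``tumour_model``, ``time_point`` and ``replicate``. Control samples
        carry ``condition == CONTROL`` and the tumour model they belong to.
    """

    layer: str
    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- structural invariants -------------------------------------------
    def validate(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids in {self.layer} layer: {dups}")
        if self.samples.index.has_duplicates:
            dups = self.samples.index[self.samples.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids in metadata: {dups}")
        matrix_ids = set(self.values.columns)
        meta_ids = set(self.samples.index)
        if matrix_ids != meta_ids:
            missing_meta = sorted(matrix_ids - meta_ids)
            missing_matrix = sorted(meta_ids - matrix_ids)
            raise ValueError(
                "sample ids do not match between matrix and metadata: "
                f"in matrix only {missing_meta}; in metadata only {missing_matrix}"
            )
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression matrix contains non-numeric values")
        if np.isinf(arr).any():
            rows, cols = np.nonzero(np.isinf(arr))
            coords = [(self.values.index[r], self.values.columns[c]) for r, c in zip(rows, cols)]
            raise ValueError(f"non-finite (infinite) expression values at {coords[:10]}")
        for col in ("condition", "tumour_model", "time_point", "replicate"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata missing column {col!r}")

    # -- convenience -----------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def control_samples(self, tumour_model: str) -> list[str]:
        """Sample ids of the pooled controls for one tumour model."""
        m = (self.samples["condition"] == CONTROL) & (self.samples["tumour_model"] == tumour_model)
        return list(self.samples.index[m])

    def treated_conditions(self) -> list[str]:
        conds = self.samples.loc[self.samples["condition"] != CONTROL, "condition"]
        return sorted(conds.unique())


@dataclasses.dataclass
class ProfilePair:
    """Aligned mRNA and protein fold-change vectors for one gene in one condition.

    Both vectors are time-ordered over the same T treated time points
    (T >= 3, default 5). ``de_flag`` is true iff the mRNA showed an
    FDR-adjusted p-value below the active cutoff at any time point.
    """

    feature: str
    condition: str
    mrna_lfc: np.ndarray
    protein_lfc: np.ndarray
    de_flag: bool

    def __post_init__(self) -> None:
        self.mrna_lfc = np.asarray(self.mrna_lfc, dtype=float)
        self.protein_lfc = np.asarray(self.protein_lfc, dtype=float)
        if self.mrna_lfc.shape != self.protein_lfc.shape:
            raise ValueError("mRNA and protein fold-change vectors differ in length")
        if self.mrna_lfc.size < 3:
            raise ValueError("profile needs at least 3 time points")


def validate_fold_change_table(fc: pd.DataFrame) -> pd.DataFrame:
    """Check a fold-change table against its invariants and return it.

    Required columns: feature, condition, time, log_fc, p_raw, p_adj.
    One row per (feature, condition, time); log_fc finite; BH guarantees
    p_adj >= p_raw wherever both are present.
    """
    missing = [c for c in FC_COLUMNS if c not in fc.columns]
    if missing:
        raise ValueError(f"fold-change table missing columns {missing}")
    if fc.duplicated(subset=["feature", "condition", "time"]).any():
        raise ValueError("duplicate (feature, condition, time) rows in fold-change table")
    if not np.isfinite(fc["log_fc"].to_numpy()).all():
        raise ValueError("non-finite log fold-changes")
    both = fc.dropna(subset=["p_raw", "p_adj"])
    if (both["p_adj"] < both["p_raw"] - 1e-12).any():
        raise ValueError("p_adj < p_raw violates BH adjustment invariant")
    return fc


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression_dataset(path: str | Path, layer: str, meta_path: str | Path) -> ExpressionDataset:
    """Read an expression matrix (features x samples) and its sample sheet.

    The matrix is delimited text with a header row of sample ids and the
    feature id in the first column. The metadata sheet maps sample ids to
    layer, condition, tumour model, time point and replicate; only rows for
    the requested layer are used.

    Raises
    ------
    ValueError
        On sample ids present in only one of the two files (the offending
        ids are listed) or on non-numeric matrix cells (coordinates given).
    """
    raw = pd.read_csv(path, sep=_delim(path), index_col=0)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        coords = [(raw.index[r], raw.columns[c], raw.iat[r, c]) for r, c in zip(rows, cols)]
        raise ValueError(f"non-numeric expression cells at (feature, sample, value): {coords[:10]}")

    meta = pd.read_csv(meta_path, sep=_delim(meta_path), dtype={"sample_id": str})
    if "layer" in meta.columns:
        meta = meta[meta["layer"] == layer]
    meta = meta.set_index("sample_id")
    return ExpressionDataset(layer=layer, values=numeric.astype(float), samples=meta)


def write_expression_dataset(ds: ExpressionDataset, path: str | Path, meta_path: str | Path) -> None:
    """Write the matrix and metadata of a dataset as delimited text."""
    ds.values.to_csv(path, sep=_delim(path), index_label="feature")
    out = ds.samples.copy()
    out.insert(0, "layer", ds.layer)
    out.to_csv(meta_path, sep=_delim(meta_path), index_label="sample_id")


def write_fold_change_table(fc: pd.DataFrame, path: str | Path) -> None:
    fc.loc[:, list(FC_COLUMNS)].to_csv(path, sep=_delim(path), index=False)


def read_fold_change_table(path: str | Path) -> pd.DataFrame:
    return validate_fold_change_table(pd.read_csv(path, sep=_delim(path)))


# ---------------------------------------------------------------------------
# Probe collapsing
# ---------------------------------------------------------------------------

def collapse_probes(dataset: ExpressionDataset, probe_map: Mapping[str, str]) -> ExpressionDataset:
    """Collapse multiple probes per gene to one row per gene.

    For genes measured by several array probes, the probe with the highest
    mean expression over all its measurements is retained; ties are broken
    by the lexicographically smallest probe id for determinism.

    Parameters
    ----------
    dataset
        mRNA-layer dataset whose features are probe ids.
    probe_map
        Mapping probe id -> gene (feature) id covering every probe.
    """
    probes = list(dataset.values.index)
    unmapped = [p for p in probes if p not in probe_map]
    if unmapped:
        raise ValueError(f"probes missing from probe map: {unmapped[:10]}")

    by_feature: dict[str, list[str]] = {}
    for p in probes:
        by_feature.setdefault(probe_map[p], []).append(p)
    empty = [f for f in set(probe_map.values()) if f not in by_feature]
    if empty:
        raise ValueError(f"features with zero probes in dataset: {sorted(empty)[:10]}")

    means = dataset.values.mean(axis=1, skipna=True)
    chosen: dict[str, str] = {}
    for feature, plist in by_feature.items():
        # highest mean wins; ties go to the smallest probe id
        best = min(plist, key=lambda p: (-means[p], p))
        chosen[feature] = best

    order = sorted(chosen)
    collapsed = dataset.values.loc[[chosen[f] for f in order]].copy()
    collapsed.index = pd.Index(order, name=dataset.values.index.name)
    return ExpressionDataset(layer=dataset.layer, values=collapsed, samples=dataset.samples.copy())


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (probe_id, feature_id) delimited file."""
    df = pd.read_csv(path, sep=_delim(path))
    if df.shape[1] < 2:
        raise ValueError("probe map needs two columns: probe_id, feature_id")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
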