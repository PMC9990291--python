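"""Abundance transformations and per-feature filtering.

RNA and DNA pathway tables are analysed as counts-per-million (CPM), either
raw or log2 after adding a pseudocount. Taxon tables are compositional, so
they are analysed as raw proportions, logits, or centered log-ratios (CLR);
the CLR for a sample uses only that sample's strictly positive taxa, and
zero taxa become missing entries.

Per feature (a pathway within one species), only samples where the
untransformed RNA, DNA and that species' taxon abundance are all strictly
positive are retained — zeros in sparse shotgun data are treated as
non-observations rather than measured absences.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import PairedDataset

__all__ = [
    "TransformSpec",
    "FeatureView",
    "to_cpm",
    "log2_pseudo",
    "taxa_transform",
    "transform_dataset",
    "build_feature_view",
    "passes_min_obs",
]

RNA_DNA_MODES = ("raw_cpm", "log2_cpm", "identity")
TAXA_MODES = ("raw_proportion", "logit", "clr", "identity")


@dataclass(frozen=True)
class TransformSpec:
    """Which transformation is applied to each of the three tables.

    ``identity`` passes a table through untouched; it is used when a dataset
    already carries analysis-scale values (e.g. injected log2-CPM matrices).
    """

    rna_mode: str = "log2_cpm"
    dna_mode: str = "log2_cpm"
    taxa_mode: str = "clr"
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.rna_mode not in RNA_DNA_MODES:
            raise ValueError(f"rna_mode must be one of {RNA_DNA_MODES}")
        if self.dna_mode not in RNA_DNA_MODES:
            raise ValueError(f"dna_mode must be one of {RNA_DNA_MODES}")
        if self.taxa_mode not in TAXA_MODES:
            raise ValueError(f"taxa_mode must be one of {TAXA_MODES}")
        if not self.pseudocount > 0:
            raise ValueError("pseudocount must be positive")


@dataclass
class FeatureView:
    """One feature's aligned, filtered, transformed vectors.

    All three vectors share length and sample order; ``meta`` is the
    metadata subset for the retained samples.
    """

    feature: str
    rna: np.ndarray
    dna: np.ndarray
    taxa: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        n = len(self.rna)
        if len(self.dna) != n or len(self.taxa) != n or len(self.meta) != n:
            raise ValueError("FeatureView vectors and metadata must share length")

    @property
    def n_samples(self) -> int:
        return len(self.rna)


def to_cpm(counts: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Rescale each sample column to sum to 1e6 (counts per million).

    Zeros are preserved; a column with zero total is an error.
    """
    values = np.asarray(counts, dtype=float)
    if (values < 0).any():
        raise ValueError("CPM requires non-negative abundances")
    totals = values.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("cannot compute CPM for a column with zero total")
    scaled = values * (1e6 / totals)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(scaled, index=counts.index, columns=counts.columns)
    return scaled


def log2_pseudo(cpm: pd.DataFrame | np.ndarray, pseudocount: float = 1.0) -> pd.DataFrame | np.ndarray:
    """Elementwise log2(x + pseudocount)."""
    if not pseudocount > 0:
        raise ValueError("pseudocount must be positive")
    values = np.asarray(cpm, dtype=float)
    if (values < 0).any():
        raise ValueError("log2 transform requires non-negative abundances")
    out = np.log2(values + pseudocount)
    if isinstance(cpm, pd.DataFrame):
        return pd.DataFrame(out, index=cpm.index, columns=cpm.columns)
    return out


def taxa_transform(taxa: pd.DataFrame | np.ndarray, mode: str = "clr") -> pd.DataFrame | np.ndarray:
    """Transform a taxon-by-sample table column-wise.

    raw_proportion
        Each column normalized to sum to 1.
    logit
        log(p / (1 - p)) on the per-column proportions; p in {0, 1} becomes
        a missing entry rather than ±inf.
    clr
        Per column, natural log of each strictly positive taxon minus the
        mean log over that column's positive taxa; zero taxa become missing
        entries. A column with no positive taxon is an error.
    """
    if mode == "identity":
        return taxa.copy() if isinstance(taxa, pd.DataFrame) else np.array(taxa, dtype=float)
    values = np.asarray(taxa, dtype=float)
    if (values < 0).any():
        raise ValueError("taxa table must be non-negative")
    if mode in ("raw_proportion", "logit"):
        totals = values.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("column with zero total taxa abundance")
        props = values / totals
        if mode == "raw_proportion":
            out = props
        else:
            out = np.full_like(props, np.nan)
            ok = (props > 0) & (props < 1)
            out[ok] = np.log(props[ok] / (1.0 - props[ok]))
    elif mode == "clr":
        out = np.full_like(values, np.nan)
        pos = values > 0
        if not pos.any(axis=0).all():
            raise ValueError("CLR undefined for a column with no positive taxon")
        logv = np.where(pos, np.log(values, where=pos, out=np.zeros_like(values)), 0.0)
        gmean_log = logv.sum(axis=0) / pos.sum(axis=0)
        out[pos] = (logv - gmean_log)[pos]
    else:
        raise ValueError(f"unknown taxa mode {mode!r}")
    if isinstance(taxa, pd.DataFrame):
        return pd.DataFrame(out, index=taxa.index, columns=taxa.columns)
    return out


def _rna_dna_transform(mat: pd.DataFrame, mode: str, pseudocount: float) -> pd.DataFrame:
    if mode == "identity":
        return mat.copy()
    cpm = to_cpm(mat)
    if mode == "raw_cpm":
        return cpm
    return log2_pseudo(cpm, pseudocount)


def transform_dataset(
    data: PairedDataset, spec: TransformSpec
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Apply ``spec`` to all three tables at once; returns (rna, dna, taxa)."""
    rna_t = _rna_dna_transform(data.rna, spec.rna_mode, spec.pseudocount)
    dna_t = _rna_dna_transform(data.dna, spec.dna_mode, spec.pseudocount)
    taxa_t = taxa_transform(data.taxa, spec.taxa_mode)
    return rna_t, dna_t, taxa_t


def build_feature_view(
    data: PairedDataset,
    spec: TransformSpec,
    feature: str,
    transformed: tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame] | None = None,
) -> FeatureView:
    """Transform, filter and align one feature's RNA/DNA/taxon vectors.

    Retains exactly the samples where the *untransformed* RNA, DNA and the
    feature's taxon abundance are all strictly positive. Pass ``transformed``
    (from :func:`transform_dataset`) to avoid re-transforming whole matrices
    when looping over features.
    """
    if feature not in data.rna.index:
        raise KeyError(f"unknown feature {feature!r}")
    taxon = data.feature_taxon[feature]
    mask = (
        (data.rna.loc[feature].to_numpy() > 0)
        & (data.dna.loc[feature].to_numpy() > 0)
        & (data.taxa.loc[taxon].to_numpy() > 0)
    )
    if transformed is None:
        transformed = transform_dataset(data, spec)
    rna_t, dna_t, taxa_t = transformed
    cols = data.samples[mask]
    return FeatureView(
        feature=feature,
        rna=rna_t.loc[feature, cols].to_numpy(dtype=float),
        dna=dna_t.loc[feature, cols].to_numpy(dtype=float),
        taxa=taxa_t.loc[taxon, cols].to_numpy(dtype=float),
        meta=data.meta.loc[cols],
    )


def passes_min_obs(
    view: FeatureView, group_column: str = "group", min_per_group: int = 10
) -> bool:
    """True iff each of the two groups has >= ``min_per_group`` retained samples."""
    if group_column not in view.meta.columns:
        raise ValueError(f"group column {group_column!r} missing from metadata")
    labels = view.meta[group_column]
    if labels.isna().any():
        raise ValueError("group labels missing for retained samples")
    counts = labels.value_counts()
    if len(counts) > 2:
        raise ValueError("group label must have at most two levels")
    if len(counts) < 2:
        return False
    return bool((counts >= min_per_group).all())
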