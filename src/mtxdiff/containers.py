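"""Core data containers for paired metatranscriptomic / metagenomic datasets.

A :class:`PairedDataset` holds three aligned abundance tables — RNA
(metatranscriptomic pathway-per-species), DNA (metagenomic pathway-per-species)
and taxa (species relative abundance) — together with per-sample metadata and
the feature→taxon map. Every analysis in this package consumes this container.

:class:`SimTruth` carries the per-feature gold standard of a simulation:
whether a feature is differentially expressed, at what signal level, and
which sample group received the signal.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PairedDataset", "SimTruth"]


@dataclass
class PairedDataset:
    """Aligned RNA/DNA/taxa abundance matrices plus sample metadata.

    Parameters
    ----------
    rna, dna
        Feature-by-sample abundance tables (same feature index, same ordered
        sample columns). Values are non-negative; zeros encode dropout.
    taxa
        Taxon-by-sample abundance table sharing the ordered sample columns.
    feature_taxon
        Series mapping each feature id to a taxon id present in ``taxa``.
    meta
        Per-sample records indexed by sample id in the shared column order.
        Expected columns include ``subject_id`` and, once assigned, a
        two-level ``group`` label; optional covariates (age, antibiotics)
        travel here too.
    """

    rna: pd.DataFrame
    dna: pd.DataFrame
    taxa: pd.DataFrame
    feature_taxon: pd.Series
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        samples = list(self.rna.columns)
        if list(self.dna.columns) != samples or list(self.taxa.columns) != samples:
            raise ValueError("rna, dna and taxa must share one ordered sample-id list")
        if list(self.meta.index) != samples:
            raise ValueError("meta must be indexed by the shared ordered sample ids")
        if not self.rna.index.equals(self.dna.index):
            raise ValueError("rna and dna must share the same feature index")
        missing = set(self.feature_taxon) - set(self.taxa.index)
        if missing:
            raise ValueError(f"feature_taxon targets absent from taxa table: {sorted(missing)[:5]}")
        extra = set(self.rna.index) - set(self.feature_taxon.index)
        if extra:
            raise ValueError(f"features without a taxon mapping: {sorted(extra)[:5]}")
        for name, mat in (("rna", self.rna), ("dna", self.dna), ("taxa", self.taxa)):
            vals = mat.to_numpy()
            if np.isnan(vals).any():
                raise ValueError(f"{name} contains missing values")
            if (vals < 0).any():
                raise ValueError(f"{name} contains negative abundances")

    # -- convenience --------------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.rna.shape[0]

    @property
    def n_samples(self) -> int:
        return self.rna.shape[1]

    @property
    def n_taxa(self) -> int:
        return self.taxa.shape[0]

    @property
    def features(self) -> pd.Index:
        return self.rna.index

    @property
    def samples(self) -> pd.Index:
        return self.rna.columns

    def copy(self) -> "PairedDataset":
        return PairedDataset(
            rna=self.rna.copy(),
            dna=self.dna.copy(),
            taxa=self.taxa.copy(),
            feature_taxon=self.feature_taxon.copy(),
            meta=self.meta.copy(),
        )

    def with_groups(self, groups: pd.Series, column: str = "group") -> "PairedDataset":
        """Return a copy whose metadata carries the given group labels."""
        out = self.copy()
        out.meta[column] = groups.reindex(out.meta.index)
        return out


@dataclass
class SimTruth:
    """Per-feature ground truth of a simulated differential-expression run.

    ``frame`` is indexed by feature id with columns:

    - ``is_de`` (bool): whether the feature carries an injected/spiked signal
    - ``strength`` (float, NaN for nulls): signal level (scenario strength j,
      or the bin index for binned injection)
    - ``bin`` (nullable int, NaN for nulls): signal bin for binned injection
    - ``target_group`` (object, None for nulls): group that received the signal
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"is_de", "strength", "bin", "target_group"}
        missing = req - set(self.frame.columns)
        if missing:
            raise ValueError(f"SimTruth frame missing columns: {sorted(missing)}")
        nulls = self.frame.loc[~self.frame["is_de"]]
        if nulls["strength"].notna().any() or nulls["bin"].notna().any():
            raise ValueError("non-DE features must not carry a signal level")
        if nulls["target_group"].notna().any():
            raise ValueError("non-DE features must not carry a target group")

    @classmethod
    def null(cls, features) -> "SimTruth":
        """All-null truth: no feature is differentially expressed."""
        frame = pd.DataFrame(
            {
                "is_de": False,
                "strength": np.nan,
                "bin": pd.array([pd.NA] * len(features), dtype="Int64"),
                "target_group": pd.array([None] * len(features), dtype=object),
            },
            index=pd.Index(features, name="feature"),
        )
        return cls(frame)

    @property
    def is_de(self) -> pd.Series:
        return self.frame["is_de"]

    @property
    def de_features(self) -> pd.Index:
        return self.frame.index[self.frame["is_de"]]

    @property
    def n_de(self) -> int:
        return int(self.frame["is_de"].sum())
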