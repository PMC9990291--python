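"""Binned additive signal injection into a null-assigned dataset.

The injection benchmark works on the analysis scale: RNA and DNA are
log2(CPM + pseudocount), taxa stay raw (the models CLR-transform them).
All positive RNA values across all samples and features are sorted and cut
into equal-count bins — bin k's minimum is no smaller than bin (k-1)'s
maximum — so the bins form a ladder of increasingly strong additive
signals. For each feature selected by the partial-correlation screen
(|r| > 0.3 under either controlling direction), one sample group is chosen
at random and values drawn from bin k are added to that group's retained
RNA entries. Library sizes are not recalibrated. The three differential
models are then run on the same injected dataset.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import PairedDataset, SimTruth
from .models import model_specs, run_de
from .pcorr import pcorr_screen
from .synthetic import make_null_assignment
from .transforms import TransformSpec, log2_pseudo, to_cpm

__all__ = [
    "SignalBins",
    "InjectionPlan",
    "bin_positive_values",
    "make_injection_plan",
    "inject_signals",
    "to_analysis_scale",
    "run_study1",
]

ANALYSIS_TRANSFORM = TransformSpec(rna_mode="identity", dna_mode="identity", taxa_mode="clr")


@dataclass
class SignalBins:
    """Ordered equal-count bins of positive analysis-scale RNA values."""

    bins: list[np.ndarray]
    boundaries: list[tuple[float, float]]

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def validate(self) -> None:
        for k in range(1, self.n_bins):
            if self.bins[k].min() < self.bins[k - 1].max():
                raise ValueError(f"bin {k + 1} minimum below bin {k} maximum")


@dataclass
class InjectionPlan:
    """Which features receive signals, into which group, from which bin."""

    features: list[str]
    target_group: dict[str, str]
    bin_index: int  # 1-based
    seed: int


def to_analysis_scale(data: PairedDataset, pseudocount: float = 1.0) -> PairedDataset:
    """Return a dataset whose RNA/DNA carry log2(CPM + pseudocount) values.

    Taxa stay raw. Because log2(x + 1) > 0 iff x > 0, per-feature positivity
    filtering on the analysis-scale matrices retains exactly the samples the
    raw matrices would.
    """
    out = data.copy()
    out.rna = log2_pseudo(to_cpm(data.rna), pseudocount)
    out.dna = log2_pseudo(to_cpm(data.dna), pseudocount)
    return out


def bin_positive_values(rna: pd.DataFrame | np.ndarray, n_bins: int = 10) -> SignalBins:
    """Sort all positive entries ascending and split into equal-count bins.

    The remainder of an uneven split goes to the lowest bins, so bin sizes
    differ by at most one.
    """
    values = np.asarray(rna, dtype=float).ravel()
    positive = np.sort(values[values > 0])
    if len(positive) < n_bins:
        raise ValueError(f"need at least {n_bins} positive values, got {len(positive)}")
    chunks = np.array_split(positive, n_bins)
    return SignalBins(
        bins=[c.copy() for c in chunks],
        boundaries=[(float(c[0]), float(c[-1])) for c in chunks],
    )


def make_injection_plan(
    data: PairedDataset,
    bin_index: int,
    seed: int,
    threshold: float = 0.3,
    group_column: str = "group",
) -> InjectionPlan:
    """Select features by partial correlation and assign target groups.

    A feature is selected when |partial corr| > ``threshold`` under either
    controlling direction (RNA vs taxa | DNA, or RNA vs DNA | taxa), on the
    analysis-scale data. Target groups are drawn from one seeded stream in
    feature-id order.
    """
    rec_dna, _ = pcorr_screen(data, ANALYSIS_TRANSFORM, controlling="dna")
    rec_taxa, _ = pcorr_screen(data, ANALYSIS_TRANSFORM, controlling="taxa")
    high = set(rec_dna.loc[rec_dna["r"].abs() > threshold, "feature"]) | set(
        rec_taxa.loc[rec_taxa["r"].abs() > threshold, "feature"]
    )
    selected = [f for f in data.features if f in high]
    levels = sorted(data.meta[group_column].astype(str).unique())
    if len(levels) != 2:
        raise ValueError("group labels must be two-level; run make_null_assignment first")
    rng = np.random.default_rng(seed)
    targets = {f: levels[rng.integers(0, 2)] for f in selected}
    return InjectionPlan(features=selected, target_group=targets, bin_index=bin_index, seed=seed)


def inject_signals(
    data: PairedDataset,
    plan: InjectionPlan,
    bins: SignalBins,
    group_column: str = "group",
    per_feature_value: bool = False,
) -> tuple[pd.DataFrame, SimTruth]:
    """Add bin-k values to the target group's retained RNA entries.

    Per selected feature, each retained sample (all-positive in RNA, DNA and
    the feature's taxon) in the chosen group gets an independent draw (with
    replacement) from bin k added to its RNA value; with
    ``per_feature_value`` a single draw is applied to all of the feature's
    target samples. Other groups, non-selected features, DNA and taxa are
    untouched, and library sizes are not recalibrated.

    Returns the modified RNA matrix and the truth (selected features DE at
    bin k).
    """
    k = plan.bin_index
    if not 1 <= k <= bins.n_bins:
        raise ValueError(f"bin index {k} outside [1, {bins.n_bins}]")
    pool = bins.bins[k - 1]
    if len(pool) == 0:
        raise ValueError(f"bin {k} is empty")
    groups = data.meta[group_column].astype(str)
    rna = data.rna.copy()
    rng = np.random.default_rng(plan.seed)
    truth = SimTruth.null(data.features).frame
    for f in plan.features:  # feature-id order: one seeded stream
        taxon = data.feature_taxon[f]
        retained = (
            (data.rna.loc[f].to_numpy() > 0)
            & (data.dna.loc[f].to_numpy() > 0)
            & (data.taxa.loc[taxon].to_numpy() > 0)
        )
        target_mask = retained & (groups == plan.target_group[f]).to_numpy()
        n_target = int(target_mask.sum())
        if n_target == 0:
            raise ValueError(f"feature {f} has no retained samples in its target group")
        if per_feature_value:
            draws = np.repeat(rng.choice(pool, size=1), n_target)
        else:
            draws = rng.choice(pool, size=n_target, replace=True)
        rna.loc[f, target_mask] = rna.loc[f, target_mask].to_numpy() + draws
    truth.loc[plan.features, "is_de"] = True
    truth.loc[plan.features, "bin"] = k
    truth.loc[plan.features, "strength"] = float(k)
    truth.loc[plan.features, "target_group"] = [plan.target_group[f] for f in plan.features]
    return rna, SimTruth(truth)


def run_study1(
    data: PairedDataset,
    k: int,
    seed: int,
    n_bins: int = 10,
    threshold: float = 0.3,
    min_per_group: int = 10,
    per_subject_groups: bool = False,
    random_intercept_by: str | None = "subject_id",
) -> tuple[dict[str, pd.DataFrame], SimTruth, PairedDataset]:
    """Full injection benchmark at signal bin ``k`` on a raw paired dataset.

    Assigns null groups, converts to the analysis scale, screens features by
    partial correlation, bins the positive RNA values, injects signals from
    bin k, then runs the three differential models (DNA+Taxa, DNA, Taxa) on
    the same injected dataset.

    Returns (per-model result DataFrames, truth, the injected dataset).
    """
    if not 1 <= k <= n_bins:
        raise ValueError(f"bin index {k} outside [1, {n_bins}]")
    groups = make_null_assignment(data.meta, seed, per_subject=per_subject_groups)
    analysis = to_analysis_scale(data.with_groups(groups))
    plan = make_injection_plan(analysis, k, seed, threshold=threshold)
    bins = bin_positive_values(analysis.rna, n_bins)
    rna_new, truth = inject_signals(analysis, plan, bins)
    injected = analysis.copy()
    injected.rna = rna_new

    specs = model_specs(random_intercept_by=random_intercept_by)
    results = {
        name: run_de(injected, spec, ANALYSIS_TRANSFORM, min_per_group=min_per_group)
        for name, spec in specs.items()
    }
    return results, truth, injected
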