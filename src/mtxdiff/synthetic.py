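"""Synthetic paired RNA/DNA/taxa data with realistic confounding structure.

The generator emulates the statistical structure of paired shotgun
metatranscriptomic/metagenomic cohorts: compositional taxon abundances,
per-feature DNA tracking its taxon's abundance through a copy factor, RNA
tracking DNA with an *additional* taxon-linked component (the partial
correlation this package diagnoses), longitudinal subjects via random
intercepts, independent dropout zeros, and counts-per-million-like column
totals.

Four spike scenarios add group-associated signals on top of a null group
assignment: expression-only spikes, taxon-abundance shifts that propagate
to the spiked taxa's DNA and RNA, sequencing-depth shifts, and spikes
assigned to whole feature groups.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import PairedDataset, SimTruth
from .transforms import taxa_transform

__all__ = [
    "GeneratorConfig",
    "ScenarioSpec",
    "SCENARIO_MODES",
    "EFFECT_SCALE",
    "generate_paired_dataset",
    "make_null_assignment",
    "apply_scenario_spikes",
]

GROUP_LABELS = ("A", "B")

# multiplicative spike factor is exp(EFFECT_SCALE * j): strength j = 1 gives
# a 4 log2-fold change, the upper end of a realistic differential ladder
EFFECT_SCALE = 4.0 * np.log(2.0)

# structural constants of the generative model (log-scale SDs)
SD_TAXON_BASELINE = 1.0   # per-taxon mean log abundance spread (natural log)
SD_TAXON_SAMPLE = 1.0     # per-sample taxon fluctuation (natural log)
SD_COPY_FACTOR = 0.5      # per-feature DNA copy factor (log2)
# DNA pathway quantification from sparse shotgun data is noisy; this
# measurement noise is what lets taxon abundance carry information about RNA
# beyond the observed DNA (the partial-correlation channel the package dials)
SD_DNA_NOISE = 0.8        # DNA measurement noise (log2)
# real pathway tables span several orders of magnitude; a wide intercept
# spread reproduces that skew (CPM from ~1e-2 to ~1e4), which in turn makes
# the lowest injection bins genuinely weak signals
SD_FEATURE_INTERCEPT = 3.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Sizes, effect coefficients and noise levels of the generator.

    ``beta_dna`` and ``beta_taxa`` are the log-scale coefficients of RNA on
    log2 DNA and on the CLR taxon abundance; ``beta_taxa`` dials the
    RNA–taxon partial correlation given DNA. ``sigma_subject`` is the
    random-intercept SD across subjects, ``sigma_noise`` the residual SD
    (both log2 units). ``timepoints_per_subject`` may be an int or a
    per-subject sequence.
    """

    n_subjects: int = 50
    timepoints_per_subject: int | tuple[int, ...] = 2
    n_taxa: int = 20
    n_features: int = 200
    beta_dna: float = 1.0
    beta_taxa: float = 0.5
    sigma_subject: float = 0.5
    sigma_noise: float = 0.5
    dropout_rate: float = 0.1
    library_size_mean: float = 1e6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1 or self.n_taxa < 1 or self.n_subjects < 1:
            raise ValueError("n_features, n_taxa and n_subjects must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if not self.sigma_noise > 0:
            raise ValueError("sigma_noise must be positive")
        if self.sigma_subject < 0:
            raise ValueError("sigma_subject must be non-negative")
        if not self.library_size_mean > 0:
            raise ValueError("library_size_mean must be positive")
        for name in ("beta_dna", "beta_taxa", "sigma_subject", "sigma_noise"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def timepoints(self) -> tuple[int, ...]:
        t = self.timepoints_per_subject
        if isinstance(t, int):
            return (t,) * self.n_subjects
        if len(t) != self.n_subjects:
            raise ValueError("timepoints_per_subject sequence must have n_subjects entries")
        return tuple(t)


SCENARIO_MODES = ("none", "true_exp", "true_combo_bug_exp", "true_combo_dep_exp", "group_true_exp")


@dataclass(frozen=True)
class ScenarioSpec:
    """One spike scenario: which confound accompanies the expression spikes.

    ``signal_strength`` is the ladder parameter j in (0, 1]; the spike
    multiplies RNA by ``exp(EFFECT_SCALE * j)``. Defaults reproduce the
    canonical settings: 10% of features spiked, 50% of taxa shifted in the
    taxon-confounded mode.
    """

    mode: str = "true_exp"
    spike_exp_fraction: float = 0.1
    spike_bug_fraction: float = 0.5
    signal_strength: float = 0.5
    n_feature_groups: int = 20
    seed: int = 0
    effect_scale: float = EFFECT_SCALE
    # generative coefficients used to propagate a taxon-abundance spike to
    # the RNA of *all* features (through the CLR channel) and of the spiked
    # taxa's features (through the DNA channel); defaults match the
    # GeneratorConfig defaults so spikes stay consistent with the data
    propagate_beta_dna: float = 1.0
    propagate_beta_taxa: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in SCENARIO_MODES:
            raise ValueError(f"mode must be one of {SCENARIO_MODES}")
        for name in ("spike_exp_fraction", "spike_bug_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.signal_strength <= 1.0:
            raise ValueError("signal_strength must lie in (0, 1]")


def _sample_frame(config: GeneratorConfig) -> pd.DataFrame:
    rows = []
    for s, n_t in enumerate(config.timepoints):
        subject = f"S{s + 1:03d}"
        for t in range(n_t):
            rows.append((f"{subject}T{t + 1}", subject))
    meta = pd.DataFrame(rows, columns=["sample_id", "subject_id"]).set_index("sample_id")
    return meta


def generate_paired_dataset(config: GeneratorConfig) -> tuple[PairedDataset, SimTruth]:
    """Generate one paired dataset; the returned truth is all-null.

    Generative model, per sample j of subject s and feature f mapped to
    taxon i(f):

    - taxon log abundance  ``b_i + e_ij`` (lognormal), columns closed to the
      configured total;
    - ``log2 DNA_fj = log2 taxa_{i(f),j} + copy_f + dna_noise``;
    - ``log2 RNA_fj = a_f + beta_dna * log2 DNA_fj + beta_taxa * CLR_{i(f),j}
      + u_s + noise``, with ``u_s ~ N(0, sigma_subject^2)``;
    - independent dropout zeros at ``dropout_rate`` in all three tables;
    - every column rescaled to total ``library_size_mean``.
    """
    rng = np.random.default_rng(config.seed)
    meta = _sample_frame(config)
    n = len(meta)
    S = config.n_subjects
    F, T = config.n_features, config.n_taxa

    subj_codes = pd.Categorical(meta["subject_id"]).codes
    u = rng.normal(0.0, config.sigma_subject, size=S)[subj_codes]

    # compositional taxa
    taxon_base = rng.normal(0.0, SD_TAXON_BASELINE, size=T)
    taxa_log = taxon_base[:, None] + rng.normal(0.0, SD_TAXON_SAMPLE, size=(T, n))
    taxa = np.exp(taxa_log)
    taxa *= config.library_size_mean / taxa.sum(axis=0)

    clr = np.log(taxa) - np.log(taxa).mean(axis=0)  # all-positive columns here

    feature_tax = np.arange(F) % T
    copy_f = rng.normal(0.0, SD_COPY_FACTOR, size=F)
    dna_log2 = (
        np.log2(taxa[feature_tax])
        + copy_f[:, None]
        + rng.normal(0.0, SD_DNA_NOISE, size=(F, n))
    )
    intercept_f = rng.normal(0.0, SD_FEATURE_INTERCEPT, size=F)
    rna_log2 = (
        intercept_f[:, None]
        + config.beta_dna * dna_log2
        + config.beta_taxa * clr[feature_tax]
        + u[None, :]
        + rng.normal(0.0, config.sigma_noise, size=(F, n))
    )
    dna = np.exp2(dna_log2)
    rna = np.exp2(rna_log2)

    if config.dropout_rate > 0:
        rna[rng.random((F, n)) < config.dropout_rate] = 0.0
        dna[rng.random((F, n)) < config.dropout_rate] = 0.0
        taxa[rng.random((T, n)) < config.dropout_rate] = 0.0

    for mat in (rna, dna, taxa):
        totals = mat.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("a sample lost all abundance to dropout; lower dropout_rate")
        mat *= config.library_size_mean / totals

    feature_ids = [
        f"PWY{f + 1:04d}|g__Genus.s__species_{feature_tax[f] + 1:03d}" for f in range(F)
    ]
    taxon_ids = [f"g__Genus.s__species_{i + 1:03d}" for i in range(T)]
    data = PairedDataset(
        rna=pd.DataFrame(rna, index=feature_ids, columns=meta.index),
        dna=pd.DataFrame(dna, index=feature_ids, columns=meta.index),
        taxa=pd.DataFrame(taxa, index=taxon_ids, columns=meta.index),
        feature_taxon=pd.Series([taxon_ids[i] for i in feature_tax], index=feature_ids),
        meta=meta,
    )
    return data, SimTruth.null(feature_ids)


def make_null_assignment(
    meta: pd.DataFrame, seed: int, per_subject: bool = False
) -> pd.Series:
    """Random two-group labels: independent Bernoulli(1/2) per sample.

    With ``per_subject`` all of a subject's longitudinal samples share one
    draw, keeping the phenotype constant within subject.
    """
    if len(meta) == 0:
        raise ValueError("empty sample metadata")
    rng = np.random.default_rng(seed)
    if per_subject:
        subjects = pd.unique(meta["subject_id"])
        draw = pd.Series(rng.integers(0, 2, size=len(subjects)), index=subjects)
        labels = meta["subject_id"].map(draw).to_numpy()
    else:
        labels = rng.integers(0, 2, size=len(meta))
    return pd.Series(
        np.where(labels == 1, GROUP_LABELS[1], GROUP_LABELS[0]),
        index=meta.index,
        name="group",
    )


def _choose_de_features(features: pd.Index, spec: ScenarioSpec, rng) -> list[str]:
    n_de = int(round(spec.spike_exp_fraction * len(features)))
    if spec.mode == "group_true_exp":
        blocks = np.array_split(np.arange(len(features)), spec.n_feature_groups)
        order = rng.permutation(len(blocks))
        chosen: list[int] = []
        for b in order:
            if len(chosen) >= n_de:
                break
            chosen.extend(blocks[b].tolist())
        return [features[i] for i in sorted(chosen)]
    idx = rng.choice(len(features), size=n_de, replace=False)
    return [features[i] for i in sorted(idx)]


def apply_scenario_spikes(
    data: PairedDataset, spec: ScenarioSpec, group_column: str = "group"
) -> tuple[PairedDataset, SimTruth]:
    """Add group-associated spikes to a null-assigned dataset.

    All modes multiply the RNA of ``round(spike_exp_fraction * n_features)``
    randomly chosen DE features by ``exp(effect_scale * signal_strength)``
    in each feature's target group. Additionally:

    - ``true_combo_bug_exp``: a ``spike_bug_fraction`` subset of taxa is
      shifted by the same factor in one group, propagating to the DNA *and*
      RNA of those taxa's features (a more abundant organism contributes
      proportionally more of both);
    - ``true_combo_dep_exp``: one group's RNA and DNA library sizes are
      multiplied by ``1 + signal_strength``;
    - ``group_true_exp``: DE status is assigned to whole blocks of features.
    """
    if group_column not in data.meta.columns:
        raise ValueError(f"assign groups first: {group_column!r} missing from metadata")
    groups = data.meta[group_column].astype(str)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"group label must have exactly two levels, got {levels}")

    out = data.copy()
    truth = SimTruth.null(data.features).frame
    if spec.mode == "none":
        return out, SimTruth(truth)

    rng = np.random.default_rng(spec.seed)
    factor = float(np.exp(spec.effect_scale * spec.signal_strength))
    de_features = _choose_de_features(data.features, spec, rng)
    # one seeded stream in feature-id order: targets drawn feature by feature
    targets = {f: levels[rng.integers(0, 2)] for f in de_features}
    scenario_target = levels[rng.integers(0, 2)]

    group_cols = {lv: (groups == lv).to_numpy() for lv in levels}

    for f in de_features:
        cols = group_cols[targets[f]]
        out.rna.loc[f, cols] = out.rna.loc[f, cols] * factor

    if spec.mode == "true_combo_bug_exp":
        n_bug = int(round(spec.spike_bug_fraction * data.n_taxa))
        bug_idx = sorted(rng.choice(data.n_taxa, size=n_bug, replace=False))
        bug_taxa = [data.taxa.index[i] for i in bug_idx]
        cols = group_cols[scenario_target]
        clr_before = taxa_transform(out.taxa, "clr")
        for taxon in bug_taxa:
            out.taxa.loc[taxon, cols] = out.taxa.loc[taxon, cols] * factor
        # propagate through the generative equation: the spiked taxa's
        # features gain DNA (and RNA via beta_dna); *every* feature's RNA
        # responds to the CLR shift of its taxon via beta_taxa (spiking half
        # the community shifts the centered log-ratios of the other half too)
        clr_after = taxa_transform(out.taxa, "clr")
        dclr = (clr_after - clr_before).fillna(0.0)
        rna_mult = np.exp(
            spec.propagate_beta_taxa * dclr.loc[data.feature_taxon].to_numpy()
        )
        out.rna.iloc[:, :] = out.rna.to_numpy() * rna_mult
        dna_factor = factor
        rna_dna_factor = float(factor**spec.propagate_beta_dna)
        for taxon in bug_taxa:
            feats = data.feature_taxon.index[data.feature_taxon == taxon]
            out.dna.loc[feats, cols] = out.dna.loc[feats, cols] * dna_factor
            out.rna.loc[feats, cols] = out.rna.loc[feats, cols] * rna_dna_factor
    elif spec.mode == "true_combo_dep_exp":
        cols = group_cols[scenario_target]
        depth = 1.0 + spec.signal_strength
        out.rna.loc[:, cols] = out.rna.loc[:, cols] * depth
        out.dna.loc[:, cols] = out.dna.loc[:, cols] * depth

    truth.loc[de_features, "is_de"] = True
    truth.loc[de_features, "strength"] = spec.signal_strength
    truth.loc[de_features, "target_group"] = [targets[f] for f in de_features]
    return out, SimTruth(truth)
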