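"""Benchmark metrics: power at nominal FDR, realized FDR, FDR-sensitivity
AUC, and split-half reproducibility.

The FDR-sensitivity curve ranks features by p-value, sweeps every cutoff
depth, and records the best sensitivity achievable at or below each
realized-FDR level; its exact staircase integral over [0, 1] is the AUC
(1 for a perfect ranking). Power counts truly differential features among
BH discoveries; realized FDR counts nulls among them (0 when there are no
discoveries).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import PairedDataset, SimTruth
from .models import ModelSpec, model_specs, run_de
from .study1 import run_study1
from .synthetic import (
    GeneratorConfig,
    ScenarioSpec,
    apply_scenario_spikes,
    generate_paired_dataset,
    make_null_assignment,
)
from .transforms import TransformSpec

__all__ = [
    "EvalMetrics",
    "ReproResult",
    "power_at_fdr",
    "fdr_sensitivity_auc",
    "reproducibility_overlap",
    "run_benchmark",
]


@dataclass
class EvalMetrics:
    model: str
    signal: float
    power: float
    realized_fdr: float
    auc: float
    n_true: int
    n_null: int
    n_discoveries: int


def _align(results: pd.DataFrame, truth: SimTruth) -> pd.Series:
    common = results.index.intersection(truth.frame.index)
    if len(common) == 0:
        raise ValueError("results and truth share no features")
    return truth.frame.loc[results.index.intersection(truth.frame.index), "is_de"]


def power_at_fdr(
    results: pd.DataFrame, truth: SimTruth, alpha: float = 0.05
) -> tuple[float, float]:
    """(power, realized FDR) of the BH discoveries at nominal level alpha.

    Power is the fraction of *all* truly DE features in the truth that are
    discovered (features filtered out before testing count as missed).
    """
    is_de = _align(results, truth)
    n_true_total = truth.n_de
    if n_true_total == 0:
        raise ValueError("truth contains no DE feature; power undefined")
    disc = results.loc[is_de.index, "fdr"] < alpha
    n_disc = int(disc.sum())
    tp = int((disc & is_de).sum())
    power = tp / n_true_total
    realized = (n_disc - tp) / n_disc if n_disc > 0 else 0.0
    return float(power), float(realized)


def _ranking_curve(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(realized FDR, sensitivity) at every cutoff depth of a ranked label vector."""
    tp = np.cumsum(labels)
    d = np.arange(1, len(labels) + 1)
    fdr = (d - tp) / d
    sens = tp / labels.sum()
    return fdr, sens


def fdr_sensitivity_auc(results: pd.DataFrame, truth: SimTruth) -> float:
    """Area under the best-sensitivity-vs-realized-FDR staircase.

    Features are ranked by p ascending (ties by feature id); for each cutoff
    depth the realized FDR and sensitivity are computed; the curve
    ``S(x) = max{sensitivity(d) : FDR(d) <= x}`` (0 where no depth
    qualifies) is integrated exactly over [0, 1].
    """
    is_de = _align(results, truth)
    if is_de.sum() == 0:
        raise ValueError("truth contains no DE feature among scored features")
    sub = results.loc[is_de.index].copy()
    sub["_truth"] = is_de.to_numpy()
    # stable sort by p after an index sort: ties broken by feature id
    sub = sub.sort_index(kind="mergesort").sort_values("p", kind="mergesort")
    labels = sub["_truth"].to_numpy(dtype=float)
    fdr, sens = _ranking_curve(labels)
    return _staircase_auc(fdr, sens)


def _staircase_auc(fdr: np.ndarray, sens: np.ndarray) -> float:
    order = np.argsort(fdr, kind="mergesort")
    xs = fdr[order]
    best = np.maximum.accumulate(sens[order])
    # collapse duplicate FDR levels to their best sensitivity
    uniq_x: list[float] = []
    uniq_m: list[float] = []
    for x, m in zip(xs, best):
        if uniq_x and x == uniq_x[-1]:
            uniq_m[-1] = m
        else:
            uniq_x.append(float(x))
            uniq_m.append(float(m))
    auc = 0.0
    for i, (x, m) in enumerate(zip(uniq_x, uniq_m)):
        x_next = uniq_x[i + 1] if i + 1 < len(uniq_x) else 1.0
        auc += m * max(x_next - x, 0.0)
    return float(auc)


@dataclass
class ReproResult:
    """Top-n overlap between the DE rankings of two random subject halves."""

    top_n: list[int]
    overlap: dict[int, int]
    ranking_a: list[str]
    ranking_b: list[str]


def _rank_features(results: pd.DataFrame) -> list[str]:
    ordered = results.sort_index(kind="mergesort").sort_values(
        ["p", "fdr"], kind="mergesort"
    )
    return list(ordered.index)


def reproducibility_overlap(
    data: PairedDataset,
    spec: ModelSpec,
    transform: TransformSpec | None = None,
    top_n: tuple[int, ...] = (10, 20, 50),
    seed: int = 0,
    min_per_group: int = 10,
    group_column: str = "group",
) -> ReproResult:
    """Split subjects in half, run the DE model in each half, count the
    features shared by both halves' top-n lists (ranked by p, ties by FDR
    then feature id)."""
    subjects = pd.unique(data.meta["subject_id"])
    if len(subjects) < 4:
        raise ValueError("need at least 4 subjects to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(subjects))
    half = len(subjects) // 2
    set_a = set(subjects[perm[:half]])
    rankings = []
    for chosen in (set_a, set(subjects) - set_a):
        mask = data.meta["subject_id"].isin(chosen).to_numpy()
        cols = data.samples[mask]
        sub = PairedDataset(
            rna=data.rna.loc[:, cols],
            dna=data.dna.loc[:, cols],
            taxa=data.taxa.loc[:, cols],
            feature_taxon=data.feature_taxon,
            meta=data.meta.loc[cols],
        )
        res = run_de(sub, spec, transform, min_per_group=min_per_group)
        if len(res) == 0:
            raise ValueError("one subject half has no eligible features")
        rankings.append(_rank_features(res))
    a, b = rankings
    overlap = {n: len(set(a[:n]) & set(b[:n])) for n in top_n}
    return ReproResult(top_n=list(top_n), overlap=overlap, ranking_a=a, ranking_b=b)


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def run_benchmark(
    config: GeneratorConfig,
    study: str = "spike",
    scenario_mode: str = "true_exp",
    signal_levels: tuple[float, ...] = (0.2, 0.5, 1.0),
    n_replicates: int = 5,
    seed: int = 0,
    alpha: float = 0.05,
    min_per_group: int = 10,
    random_intercept_by: str | None = None,
    per_subject_groups: bool = False,
) -> pd.DataFrame:
    """Power/FDR/AUC of the three models over signal levels and replicates.

    ``study='spike'`` applies a scenario (``scenario_mode``, strength =
    level) on freshly generated data; ``study='injection'`` runs the binned
    injection pipeline (level = bin index). Returns a long-format table with
    one row per (signal level, replicate, model).
    """
    if study not in ("spike", "injection"):
        raise ValueError("study must be 'spike' or 'injection'")
    rows = []
    for level in signal_levels:
        for rep in range(n_replicates):
            child = np.random.SeedSequence([seed, int(round(level * 1000)), rep])
            gen_seed = _child_seed(child)
            cfg = GeneratorConfig(**{**config.__dict__, "seed": gen_seed})
            data, _ = generate_paired_dataset(cfg)
            if study == "spike":
                groups = make_null_assignment(data.meta, gen_seed + 1, per_subject=per_subject_groups)
                spiked, truth = apply_scenario_spikes(
                    data.with_groups(groups),
                    ScenarioSpec(
                        mode=scenario_mode, signal_strength=level, seed=gen_seed + 2
                    ),
                )
                specs = model_specs(random_intercept_by=random_intercept_by)
                results = {
                    name: run_de(spiked, ms, min_per_group=min_per_group)
                    for name, ms in specs.items()
                }
            else:
                results, truth, _ = run_study1(
                    data,
                    int(level),
                    gen_seed + 1,
                    min_per_group=min_per_group,
                    per_subject_groups=per_subject_groups,
                    random_intercept_by=random_intercept_by,
                )
            for name, res in results.items():
                if truth.n_de == 0 or len(res) == 0:
                    continue
                power, realized = power_at_fdr(res, truth, alpha)
                auc = fdr_sensitivity_auc(res, truth)
                n_disc = int((res["fdr"] < alpha).sum())
                rows.append(
                    (study, scenario_mode if study == "spike" else "injection", level,
                     rep, name, power, realized, auc, truth.n_de,
                     len(truth.frame) - truth.n_de, n_disc)
                )
    return pd.DataFrame(
        rows,
        columns=[
            "study", "scenario", "signal", "replicate", "model",
            "power", "realized_fdr", "auc", "n_true", "n_null", "n_discoveries",
        ],
    )
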