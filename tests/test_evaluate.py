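"""Evaluation metrics: power/FDR, the FDR-sensitivity AUC, reproducibility."""
import itertools

import numpy as np
import pandas as pd
import pytest

from mtxdiff import (
    GeneratorConfig,
    ModelSpec,
    fdr_sensitivity_auc,
    generate_paired_dataset,
    make_null_assignment,
    power_at_fdr,
    reproducibility_overlap,
    run_benchmark,
)
from mtxdiff.containers import SimTruth


def make_results(p_values, features=None):
    features = features or [f"f{i}" for i in range(len(p_values))]
    from mtxdiff.models import bh_adjust

    p = np.asarray(p_values, float)
    return pd.DataFrame(
        {"p": p, "fdr": bh_adjust(p)}, index=pd.Index(features, name="feature")
    )


def make_truth(labels, features=None):
    features = features or [f"f{i}" for i in range(len(labels))]
    frame = SimTruth.null(features).frame
    frame.loc[[f for f, l in zip(features, labels) if l], "is_de"] = True
    frame.loc[frame["is_de"], "strength"] = 1.0
    frame.loc[frame["is_de"], "target_group"] = "A"
    return SimTruth(frame)


def auc_bruteforce(labels_in_p_order):
    """Exhaustive cutoff enumeration + exact staircase integration."""
    labels = np.asarray(labels_in_p_order, dtype=float)
    n_true = labels.sum()
    pts = []
    for d in range(1, len(labels) + 1):
        tp = labels[:d].sum()
        pts.append(((d - tp) / d, tp / n_true))
    xs = sorted({x for x, _ in pts} | {1.0})
    auc = 0.0
    for lo, hi in zip(xs, xs[1:]):
        best = max([s for x, s in pts if x <= lo], default=0.0)
        auc += best * (hi - lo)
    # segment from the largest breakpoint to 1 is included above; segment
    # below the smallest breakpoint has S(x)=best at that x already handled
    first = xs[0]
    if first > 0:
        auc += 0.0 * first
    return auc


class TestPowerAtFdr:
    def test_direct_count(self):
        res = make_results([0.001, 0.2, 0.001, 0.8])
        truth = make_truth([True, True, False, False])
        res["fdr"] = [0.01, 0.2, 0.01, 0.8]
        power, fdr = power_at_fdr(res, truth, alpha=0.05)
        assert power == 0.5 and fdr == 0.5

    def test_no_discoveries(self):
        res = make_results([0.9, 0.8, 0.7])
        truth = make_truth([True, False, False])
        assert power_at_fdr(res, truth) == (0.0, 0.0)

    def test_everything_discovered(self):
        res = make_results([1e-10, 1e-9, 1e-8, 1e-7])
        truth = make_truth([True, False, False, True])
        power, fdr = power_at_fdr(res, truth)
        assert power == 1.0 and fdr == pytest.approx(0.5)

    def test_filtered_features_count_as_missed(self):
        res = make_results([1e-10])  # only one of two DE features scored
        truth = make_truth([True, True], features=["f0", "f1"])
        power, _ = power_at_fdr(res, truth)
        assert power == 0.5

    def test_all_null_truth_rejected(self):
        with pytest.raises(ValueError):
            power_at_fdr(make_results([0.5]), make_truth([False]))


class TestAuc:
    def test_perfect_ranking_is_one(self):
        res = make_results([0.01, 0.02, 0.6, 0.7])
        truth = make_truth([True, True, False, False])
        assert fdr_sensitivity_auc(res, truth) == pytest.approx(1.0)

    def test_known_interleaved_value(self):
        # ranked truth sequence [T, F, T, F] integrates to 5/6
        res = make_results([0.01, 0.02, 0.03, 0.04])
        truth = make_truth([True, False, True, False])
        assert fdr_sensitivity_auc(res, truth) == pytest.approx(5 / 6)

    def test_matches_bruteforce_small_rankings(self):
        for n in range(2, 7):
            for labels in itertools.product([False, True], repeat=n):
                if not any(labels):
                    continue
                res = make_results(np.linspace(0.01, 0.5, n))
                truth = make_truth(list(labels))
                assert fdr_sensitivity_auc(res, truth) == pytest.approx(
                    auc_bruteforce(labels), abs=1e-12
                )

    def test_adjacent_swap_never_decreases(self):
        # promoting a true feature past a null feature can only help
        for labels in itertools.permutations([True] * 3 + [False] * 3):
            labels = list(labels)
            for i in range(len(labels) - 1):
                if not labels[i] and labels[i + 1]:
                    swapped = labels.copy()
                    swapped[i], swapped[i + 1] = swapped[i + 1], swapped[i]
                    assert auc_bruteforce(swapped) >= auc_bruteforce(labels) - 1e-12

    def test_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(3, 12)
            labels = rng.random(n) < 0.4
            if not labels.any():
                labels[0] = True
            res = make_results(rng.random(n))
            assert 0.0 <= fdr_sensitivity_auc(res, make_truth(list(labels))) <= 1.0


class TestReproducibility:
    def test_overlap_counts_intersection(self):
        # API sanity on real data handled below; here the ranking logic
        from mtxdiff.evaluate import _rank_features

        res = make_results([0.01, 0.2, 0.03, 0.5], ["a", "b", "c", "d"])
        assert _rank_features(res)[:3] == ["a", "c", "b"]

    def test_null_overlap_is_small(self):
        cfg = GeneratorConfig(
            n_subjects=40, timepoints_per_subject=2, n_taxa=10, n_features=80,
            seed=71,
        )
        data, _ = generate_paired_dataset(cfg)
        data = data.with_groups(make_null_assignment(data.meta, 72))
        overlaps = []
        for seed in range(3):
            res = reproducibility_overlap(
                data, ModelSpec(random_intercept_by=None), top_n=(10,), seed=seed,
                min_per_group=5,
            )
            assert res.overlap[10] <= 10
            overlaps.append(res.overlap[10])
        # under independent null rankings expected overlap ~ n^2/F ~ 1.3
        assert np.mean(overlaps) <= 5

    def test_monotone_in_n(self):
        cfg = GeneratorConfig(
            n_subjects=30, timepoints_per_subject=2, n_taxa=8, n_features=50, seed=73
        )
        data, _ = generate_paired_dataset(cfg)
        data = data.with_groups(make_null_assignment(data.meta, 74))
        res = reproducibility_overlap(
            data, ModelSpec(random_intercept_by=None), top_n=(5, 10, 20, 40),
            seed=0, min_per_group=5,
        )
        vals = [res.overlap[n] for n in (5, 10, 20, 40)]
        assert vals == sorted(vals)

    def test_too_few_subjects_rejected(self):
        cfg = GeneratorConfig(n_subjects=3, seed=0)
        data, _ = generate_paired_dataset(cfg)
        data = data.with_groups(make_null_assignment(data.meta, 1))
        with pytest.raises(ValueError):
            reproducibility_overlap(data, ModelSpec())


class TestBenchmark:
    def test_deterministic(self):
        cfg = GeneratorConfig(
            n_subjects=30, timepoints_per_subject=1, n_taxa=8, n_features=40,
            sigma_subject=0.0, seed=0,
        )
        kw = dict(
            study="spike", scenario_mode="true_exp", signal_levels=(0.5,),
            n_replicates=2, seed=5, min_per_group=5,
        )
        t1 = run_benchmark(cfg, **kw)
        t2 = run_benchmark(cfg, **kw)
        pd.testing.assert_frame_equal(t1, t2)
        assert set(t1["model"]) == {"DNA+Taxa", "DNA", "Taxa"}
        assert len(t1) == 6
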