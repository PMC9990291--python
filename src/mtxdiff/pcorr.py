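"""Feature-wise partial correlations between RNA and DNA or taxon abundance.

Even after one confounder (say DNA) is regressed out of both RNA and the
other factor, many features keep a strong residual (partial) correlation —
the diagnostic that motivates controlling for both DNA and taxon abundance
in differential models. The screen tallies per-feature partial correlations
into three ranges with cutpoint 0.3.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import PairedDataset
from .transforms import TransformSpec, build_feature_view, transform_dataset

__all__ = ["PcorrRecord", "RangeTally", "regress_out", "partial_corr", "pcorr_screen"]

MIN_SAMPLES = 4  # floor for computing a partial correlation on a feature


@dataclass(frozen=True)
class PcorrRecord:
    feature: str
    controlling: str
    r: float
    n_samples: int


@dataclass
class RangeTally:
    """Counts of features whose r falls in (-1,-c], (-c,c), [c,1) with c=0.3."""

    negative: int = 0
    middle: int = 0
    positive: int = 0
    skipped: int = 0
    cutpoint: float = 0.3

    @property
    def total(self) -> int:
        return self.negative + self.middle + self.positive

    def add(self, r: float) -> None:
        if r <= -self.cutpoint:
            self.negative += 1
        elif r >= self.cutpoint:
            self.positive += 1
        else:
            self.middle += 1

    def as_series(self) -> pd.Series:
        c = self.cutpoint
        return pd.Series(
            {
                f"r<=-{c}": self.negative,
                f"-{c}<r<{c}": self.middle,
                f"r>={c}": self.positive,
                "total": self.total,
                "skipped": self.skipped,
            }
        )


def regress_out(y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Residuals of the OLS fit of ``y`` on an intercept and ``z``.

    The residuals are mean-zero and orthogonal to ``z``.
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if y.shape != z.shape or y.ndim != 1:
        raise ValueError("y and z must be one-dimensional and equal length")
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(z) == 0:
        raise ValueError("z is constant; cannot regress it out")
    X = np.column_stack([np.ones_like(z), z])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def partial_corr(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """Partial Pearson correlation of ``x`` and ``y`` given ``z``.

    Computed as the Pearson correlation of the two residual vectors after
    regressing ``z`` out of each; for a single control variable this equals
    the classical closed form
    ``(r_xy - r_xz r_zy) / sqrt((1 - r_xz^2)(1 - r_zy^2))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < MIN_SAMPLES:
        raise ValueError(f"need at least {MIN_SAMPLES} observations")
    rx = regress_out(x, z)
    ry = regress_out(y, z)
    sx = float(rx @ rx)
    sy = float(ry @ ry)
    # collinearity with z leaves only rounding noise in the residuals
    tol_x = 1e-15 * float(np.square(x - x.mean()).sum())
    tol_y = 1e-15 * float(np.square(y - y.mean()).sum())
    if sx <= tol_x or sy <= tol_y:
        raise ValueError("zero residual variance: partial correlation undefined")
    return float((rx @ ry) / np.sqrt(sx * sy))


def pcorr_screen(
    data: PairedDataset,
    spec: TransformSpec | None = None,
    controlling: str = "dna",
    cutpoint: float = 0.3,
) -> tuple[pd.DataFrame, RangeTally]:
    """Partial correlation of RNA with one factor controlling for the other.

    For every feature whose filtered view keeps at least 4 samples, computes
    ``partial_corr(RNA, other | controlling)`` on the transformed vectors and
    tallies r into the three ranges. Features failing the preconditions
    (too few samples, constant vectors) are skipped and counted.

    Returns a per-feature DataFrame (feature, controlling, r, n_samples) and
    the :class:`RangeTally`.
    """
    if controlling not in ("dna", "taxa"):
        raise ValueError("controlling must be 'dna' or 'taxa'")
    spec = spec or TransformSpec()
    transformed = transform_dataset(data, spec)
    tally = RangeTally(cutpoint=cutpoint)
    rows = []
    for feature in data.features:
        view = build_feature_view(data, spec, feature, transformed=transformed)
        if view.n_samples < MIN_SAMPLES:
            tally.skipped += 1
            continue
        other = view.taxa if controlling == "dna" else view.dna
        control = view.dna if controlling == "dna" else view.taxa
        try:
            r = partial_corr(view.rna, other, control)
        except ValueError:
            tally.skipped += 1
            continue
        tally.add(r)
        rows.append((feature, controlling, r, view.n_samples))
    records = pd.DataFrame(rows, columns=["feature", "controlling", "r", "n_samples"])
    return records, tally
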