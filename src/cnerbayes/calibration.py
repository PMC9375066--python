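"""Calibration of B-statistics into class-membership probabilities.

During leave-one-out scoring of the training set, the distributions of the
B-statistic for the CNE and non-CNE classes are estimated separately and
turned into probability curves Pc(B) and Pnc(B).  The curves are built from
the two *class-conditional* distributions with equal class weight,

    Pc(bin) = (n+/N+) / (n+/N+ + n-/N-),

not from the pooled posterior: the corpora this classifier is trained on are
heavily imbalanced (background tokens outnumber chemical ones ~15:1), and a
prevalence-weighted frequency would cap Pc far below 1 even in regions of
the B axis populated exclusively by chemical fragments.  Constructing the
probabilities from the per-class distributions makes them prevalence-free:
Pc -> 1 where only the CNE distribution has mass, -> 0 where only the
background distribution does.  Because Pc and Pnc come from two independent
one-vs-rest fits on two different B statistics, they need not sum to 1, and
a token with conflicting evidence can have both near zero.

The default estimator bins the B axis (equal-frequency quantiles of the
pooled scores, refined by per-class quantiles so minority-class regions keep
resolution) and interpolates the per-bin balanced frequencies
piecewise-linearly, constant beyond the outer bin centres; a least-squares
polynomial fitted to the same binned frequencies is the alternative.  Both
are clipped to [0, 1] and defined on all of [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_BINS = 20
DEFAULT_DEGREE = 5


def _pava_nondecreasing(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted pool-adjacent-violators: nondecreasing least-squares fit."""
    levels: list[float] = []
    wsums: list[float] = []
    counts: list[int] = []
    for v, w in zip(values, weights):
        levels.append(float(v))
        wsums.append(float(w))
        counts.append(1)
        while len(levels) > 1 and levels[-2] >= levels[-1]:
            v2, w2, c2 = levels.pop(), wsums.pop(), counts.pop()
            v1, w1, c1 = levels.pop(), wsums.pop(), counts.pop()
            levels.append((v1 * w1 + v2 * w2) / (w1 + w2))
            wsums.append(w1 + w2)
            counts.append(c1 + c2)
    return np.concatenate([np.full(c, v) for v, c in zip(levels, counts)])


def _binned_frequencies(scores: np.ndarray, positive: np.ndarray, q: int,
                        monotone: bool = True
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Balanced-class binned frequencies -> (bin centres, per-bin value).

    Bin edges come from per-class quantiles so the minority class keeps
    resolution; with ``monotone`` the values are made nondecreasing by
    weighted PAVA before interpolation (the B-statistic orders evidence, so
    the membership curve must not invert between noisy bins).
    """
    n_pos = float(positive.sum())
    n_neg = float(positive.size - positive.sum())
    unique = np.unique(scores)
    if unique.size <= q:
        edges = unique
    else:
        grid = np.linspace(0.0, 1.0, q // 2 + 1)
        edges = np.unique(np.concatenate([
            np.quantile(scores[positive], grid),
            np.quantile(scores[~positive], grid),
        ]))
    bins = np.searchsorted(edges, scores, side="right")
    centers, values, weights = [], [], []
    for b in np.unique(bins):
        member = bins == b
        pos_rate = positive[member].sum() / n_pos
        neg_rate = (member.sum() - positive[member].sum()) / n_neg
        centers.append(scores[member].mean())
        values.append(pos_rate / (pos_rate + neg_rate)
                      if pos_rate + neg_rate > 0 else 0.5)
        weights.append(member.sum())
    centers = np.asarray(centers)
    values = np.asarray(values)
    if monotone and len(values) > 1:
        values = _pava_nondecreasing(values, np.asarray(weights, dtype=float))
    return centers, values


@dataclass(frozen=True)
class BinnedCalibration:
    """Piecewise-linear interpolation of binned empirical class frequencies."""

    centers: np.ndarray
    values: np.ndarray
    q: int = DEFAULT_BINS

    @classmethod
    def fit(cls, scores, positive, q: int = DEFAULT_BINS) -> "BinnedCalibration":
        scores = np.asarray(scores, dtype=float)
        positive = np.asarray(positive, dtype=bool)
        if scores.size != positive.size:
            raise ValueError("scores and labels differ in length")
        if not positive.any() or positive.all():
            raise ValueError("calibration requires both label groups nonempty")
        centers, values = _binned_frequencies(scores, positive, q)
        return cls(centers, values, q)

    def __call__(self, b):
        out = np.interp(np.asarray(b, dtype=float), self.centers, self.values)
        out = np.clip(out, 0.0, 1.0)
        return float(out) if np.ndim(b) == 0 else out


@dataclass(frozen=True)
class PolynomialCalibration:
    """Least-squares polynomial through the binned frequencies, clipped to [0,1]."""

    coefficients: np.ndarray
    degree: int
    lo: float
    hi: float

    @classmethod
    def fit(cls, scores, positive, q: int = DEFAULT_BINS,
            degree: int = DEFAULT_DEGREE) -> "PolynomialCalibration":
        scores = np.asarray(scores, dtype=float)
        positive = np.asarray(positive, dtype=bool)
        if not positive.any() or positive.all():
            raise ValueError("calibration requires both label groups nonempty")
        centers, values = _binned_frequencies(scores, positive, q)
        deg = min(degree, len(centers) - 1)
        coeffs = np.polyfit(centers, values, deg)
        return cls(coeffs, deg, float(centers[0]), float(centers[-1]))

    def __call__(self, b):
        x = np.clip(np.asarray(b, dtype=float), self.lo, self.hi)
        out = np.clip(np.polyval(self.coefficients, x), 0.0, 1.0)
        return float(out) if np.ndim(b) == 0 else out


def fit_calibration(scores, positive, method: str = "binned",
                    q: int = DEFAULT_BINS, degree: int = DEFAULT_DEGREE):
    if method == "binned":
        return BinnedCalibration.fit(scores, positive, q)
    if method == "poly":
        return PolynomialCalibration.fit(scores, positive, q, degree)
    raise ValueError(f"unknown calibration method {method!r}")


@dataclass(frozen=True)
class CalibrationPair:
    """Pc from the CNE-vs-rest curve, Pnc from the NON_CNE-vs-rest curve."""

    pc_curve: object
    pnc_curve: object

    def pc(self, b_cne: float) -> float:
        return self.pc_curve(b_cne)

    def pnc(self, b_non_cne: float) -> float:
        return self.pnc_curve(b_non_cne)
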