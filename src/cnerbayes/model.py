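"""The B-statistic naïve Bayes estimator.

The classifier is count-based: fitting computes the sufficient statistics

* ``N``    — number of training FoTs,
* ``Nk``   — FoTs per class k,
* ``Ni``   — FoTs whose descriptor set contains gram i,
* ``Nik``  — FoTs of class k containing gram i,

from which priors ``P(Ck) = Nk/N`` and conditionals ``P(Ck|gi) = Nik/Ni``
follow directly; no coefficients are optimised.  A query with descriptor set
{g1..gm} is scored per class with the bounded B-statistic

    S0k = 2 P(Ck) - 1
    Sk  = sin( arcsin(S0k) + A ),   A = mean_i [ arcsin(2 P(Ck|gi) - 1)
                                                 - arcsin(S0k) ]
    Bk  = (Sk - S0k) / (1 - Sk * S0k)

The arcsine transform bounds each descriptor's contribution by ±π/2, so
conditionals of exactly 0 or 1 cannot dominate; centring each term on the
prior makes an uninformative gram (P(Ck|gi) = P(Ck)) contribute exactly
zero, and an empty or fully uninformative descriptor set yields Bk = 0.
The aggregate A is the mean of the centred terms by default (``sum_mode=
"mean"``); ``sum_mode="sum"`` restores a raw sum for comparison.  Grams never
seen in training (Ni = 0) are skipped.  Bk is always in [-1, 1]: the Möbius
form maps Sk, S0k in [-1, 1] there, and it is strictly increasing in Sk.

The union class CNE (any of the five base chemical types) is counted
alongside the base classes, and the background class NON_CNE completes the
partition: sum of base-class Nk plus NON_CNE equals N.

Organisation follows the model/results convention: ``FragmentNaiveBayes``
holds the training configuration and data, ``fit()`` returns a
``FragmentNaiveBayesResults`` carrying the counts plus prediction,
leave-one-out, calibration, persistence and ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .calibration import (DEFAULT_BINS, DEFAULT_DEGREE, BinnedCalibration,
                          CalibrationPair, PolynomialCalibration,
                          fit_calibration)
from .corpus import BASE_CLASSES, ClassLabel
from .ngrams import DEFAULT_N_MAX, fot_descriptors, position_ngrams
from .tokens import FoT

#: Fixed class order of the count matrices.
CLASS_ORDER: tuple[ClassLabel, ...] = (*BASE_CLASSES, ClassLabel.CNE,
                                       ClassLabel.NON_CNE)
CLASS_INDEX = {label: i for i, label in enumerate(CLASS_ORDER)}
_CNE = CLASS_INDEX[ClassLabel.CNE]
_NON_CNE = CLASS_INDEX[ClassLabel.NON_CNE]
_N_CLASSES = len(CLASS_ORDER)


@dataclass
class ModelCounts:
    """Sufficient statistics of the classifier (N, Nk, Ni, Nik)."""

    n_max: int
    window: int
    n_total: int                       # N
    nk: np.ndarray                     # (K,)   Nk in CLASS_ORDER
    grams: list[str]                   # index -> gram
    gram_index: dict[str, int]         # gram -> index
    ni: np.ndarray                     # (G,)   Ni
    nik: np.ndarray                    # (G, K) Nik

    def check(self) -> None:
        base = [CLASS_INDEX[c] for c in BASE_CLASSES]
        assert self.nk[base].sum() + self.nk[_NON_CNE] == self.n_total
        assert self.nk[_CNE] == self.nk[base].sum()
        assert (self.ni >= 0).all() and (self.nik >= 0).all()
        assert (self.nik <= self.ni[:, None]).all()
        assert (self.nik <= self.nk[None, :]).all()


@dataclass(frozen=True)
class Prediction:
    """Per-class B-statistics plus calibrated CNE membership probabilities."""

    b: dict[ClassLabel, float]
    pc: float
    pnc: float

    @property
    def score(self) -> float:
        """The extraction score Pc - Pnc."""
        return self.pc - self.pnc


def _b_vector(n_total: int, nk: np.ndarray, ni_sel: np.ndarray,
              nik_sel: np.ndarray, sum_mode: str = "mean",
              alpha: float = 0.0) -> np.ndarray:
    """B-statistics for all classes given the informative-gram count slices.

    ``ni_sel``/``nik_sel`` must already be restricted to grams with Ni > 0.
    """
    nk = np.asarray(nk, dtype=float)
    s0 = 2.0 * nk / n_total - 1.0
    a0 = np.arcsin(np.clip(s0, -1.0, 1.0))
    if ni_sel.size:
        cond = (nik_sel + alpha) / (ni_sel[:, None] + 2.0 * alpha)
        terms = np.arcsin(np.clip(2.0 * cond - 1.0, -1.0, 1.0)) - a0[None, :]
        agg = terms.mean(axis=0) if sum_mode == "mean" else terms.sum(axis=0)
    else:
        agg = np.zeros_like(s0)
    s = np.sin(a0 + agg)
    denom = 1.0 - s * s0
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(denom != 0.0, (s - s0) / np.where(denom != 0.0, denom, 1.0),
                     0.0)
    # Degenerate one-class priors (|S0k| = 1) carry no ranking information.
    b[np.abs(s0) >= 1.0] = 0.0
    return np.clip(b, -1.0, 1.0)


class FragmentNaiveBayes:
    """Count-based naïve Bayes model over FoT descriptor sets.

    Parameters
    ----------
    fots : sequence of FoT
        Labelled training fragments (one per token of the training corpus).
    n_max : int
        Maximal gram length (default 5).
    sum_mode : {"mean", "sum"}
        Aggregate the centred arcsine terms by their mean (default) or by the
        raw sum.
    smoothing_alpha : float
        Optional Laplace smoothing of the conditionals,
        ``(Nik + a) / (Ni + 2a)``; 0 disables it.
    """

    def __init__(self, fots: Sequence[FoT], n_max: int = DEFAULT_N_MAX,
                 sum_mode: str = "mean", smoothing_alpha: float = 0.0):
        if not fots:
            raise ValueError("cannot fit a model on an empty FoT list")
        if sum_mode not in ("mean", "sum"):
            raise ValueError(f"sum_mode must be 'mean' or 'sum', got {sum_mode!r}")
        if n_max < 1:
            raise ValueError(f"n_max must be >= 1, got {n_max}")
        windows = {fot.window for fot in fots}
        if len(windows) > 1:
            raise ValueError(f"mixed context windows in training data: {windows}")
        self.fots = list(fots)
        self.n_max = n_max
        self.window = windows.pop()
        self.sum_mode = sum_mode
        self.smoothing_alpha = smoothing_alpha

    def fit(self) -> "FragmentNaiveBayesResults":
        gram_index: dict[str, int] = {}
        grams: list[str] = []
        fot_ids: list[np.ndarray] = []
        labels = np.empty(len(self.fots), dtype=np.int64)
        surface_stats: dict[str, list[int]] = {}
        for row, fot in enumerate(self.fots):
            ids = []
            for gram in fot_descriptors(fot, self.n_max):
                idx = gram_index.get(gram)
                if idx is None:
                    idx = len(grams)
                    gram_index[gram] = idx
                    grams.append(gram)
                ids.append(idx)
            ids_arr = np.asarray(sorted(ids), dtype=np.int64)
            fot_ids.append(ids_arr)
            labels[row] = CLASS_INDEX[fot.label]
            key = fot.target.surface.casefold()
            stat = surface_stats.setdefault(key, [0, 0])
            stat[0] += 1
            stat[1] += int(fot.is_cne)

        n_grams = len(grams)
        nk = np.zeros(_N_CLASSES, dtype=np.int64)
        ni = np.zeros(n_grams, dtype=np.int64)
        nik = np.zeros((n_grams, _N_CLASSES), dtype=np.int64)
        for ids_arr, lab in zip(fot_ids, labels):
            nk[lab] += 1
            ni[ids_arr] += 1
            nik[ids_arr, lab] += 1
            if lab != _NON_CNE and lab != _CNE:
                # base chemical types are also positives for the union class
                nk[_CNE] += 1
                nik[ids_arr, _CNE] += 1
        counts = ModelCounts(self.n_max, self.window, len(self.fots), nk,
                             grams, gram_index, ni, nik)
        return FragmentNaiveBayesResults(self, counts, fot_ids, labels,
                                         surface_stats)


class FragmentNaiveBayesResults:
    """Fitted counts plus prediction, LOO, calibration and persistence."""

    def __init__(self, model: FragmentNaiveBayes | None, counts: ModelCounts,
                 fot_gram_ids: list[np.ndarray] | None = None,
                 fot_labels: np.ndarray | None = None,
                 surface_stats: dict[str, list[int]] | None = None,
                 sum_mode: str = "mean", smoothing_alpha: float = 0.0):
        self.model = model
        self.counts = counts
        self._fot_gram_ids = fot_gram_ids
        self._fot_labels = fot_labels
        self.surface_stats = surface_stats or {}
        self.sum_mode = model.sum_mode if model is not None else sum_mode
        self.smoothing_alpha = (model.smoothing_alpha if model is not None
                                else smoothing_alpha)
        self._loo_cache: np.ndarray | None = None

    # -- basic quantities ---------------------------------------------------

    @property
    def n_max(self) -> int:
        return self.counts.n_max

    @property
    def window(self) -> int:
        return self.counts.window

    def prior(self, label: ClassLabel) -> float:
        """P(Ck) = Nk / N."""
        return float(self.counts.nk[CLASS_INDEX[label]]) / self.counts.n_total

    def conditional(self, gram: str, label: ClassLabel) -> float | None:
        """P(Ck|gi) = Nik / Ni, or None for an uninformative gram (Ni = 0)."""
        idx = self.counts.gram_index.get(gram)
        if idx is None or self.counts.ni[idx] == 0:
            return None
        return (float(self.counts.nik[idx, CLASS_INDEX[label]])
                / float(self.counts.ni[idx]))

    # -- scoring ------------------------------------------------------------

    def _known_ids(self, grams: Iterable[str]) -> np.ndarray:
        index = self.counts.gram_index
        ids = [index[g] for g in grams if g in index]
        return np.asarray(sorted(ids), dtype=np.int64)

    def b_all(self, grams: Iterable[str]) -> np.ndarray:
        """B-statistics for every class in CLASS_ORDER, given a gram set."""
        ids = self._known_ids(grams)
        ids = ids[self.counts.ni[ids] > 0] if ids.size else ids
        return _b_vector(self.counts.n_total, self.counts.nk,
                         self.counts.ni[ids], self.counts.nik[ids],
                         self.sum_mode, self.smoothing_alpha)

    def b_statistic(self, grams: Iterable[str], label: ClassLabel) -> float:
        """Bk of a descriptor set for one class."""
        return float(self.b_all(grams)[CLASS_INDEX[label]])

    # -- leave-one-out ------------------------------------------------------

    def _require_training_data(self):
        if self._fot_gram_ids is None or self._fot_labels is None:
            raise ValueError(
                "per-FoT training data unavailable (model loaded from disk); "
                "leave-one-out requires a freshly fitted model")

    def loo_b_all(self, index: int) -> np.ndarray:
        """B-statistics of training FoT ``index`` with its own counts removed.

        Equivalent to refitting without that FoT (N-1; Nk-1 for its label and,
        for base chemical types, also for CNE; Ni, Nik down by one for each of
        its grams) and scoring its descriptor set.
        """
        self._require_training_data()
        c = self.counts
        if c.n_total <= 1:
            raise ValueError("leave-one-out needs at least two training FoTs")
        lab = int(self._fot_labels[index])
        ids = self._fot_gram_ids[index]
        nk = c.nk.astype(np.int64).copy()
        nk[lab] -= 1
        if lab != _NON_CNE and lab != _CNE:
            nk[_CNE] -= 1
        ni_sel = c.ni[ids] - 1
        nik_sel = c.nik[ids].copy()
        nik_sel[:, lab] -= 1
        if lab != _NON_CNE and lab != _CNE:
            nik_sel[:, _CNE] -= 1
        if (nk < 0).any() or (ni_sel < 0).any() or (nik_sel < 0).any():
            raise ValueError("count decremented below zero: FoT was not in training")
        keep = ni_sel > 0
        return _b_vector(c.n_total - 1, nk, ni_sel[keep], nik_sel[keep],
                         self.sum_mode, self.smoothing_alpha)

    def loo_predict(self, fot: FoT, label: ClassLabel) -> float:
        """LOO Bk for a FoT given by value (must occur in the training set)."""
        self._require_training_data()
        grams = fot_descriptors(fot, self.n_max)
        ids = self._known_ids(grams)
        if len(ids) != len(grams):
            raise ValueError("FoT has grams unseen in training: not a training FoT")
        lab = CLASS_INDEX[fot.label]
        for row, row_ids in enumerate(self._fot_gram_ids):
            if (self._fot_labels[row] == lab and row_ids.size == ids.size
                    and np.array_equal(row_ids, ids)):
                return float(self.loo_b_all(row)[CLASS_INDEX[label]])
        raise ValueError("FoT not found in the training set")

    def loo_matrix(self) -> np.ndarray:
        """(n_fots, n_classes) LOO B-statistics over the training set (cached)."""
        self._require_training_data()
        if self._loo_cache is None:
            n = len(self._fot_gram_ids)
            out = np.empty((n, _N_CLASSES), dtype=float)
            for i in range(n):
                out[i] = self.loo_b_all(i)
            self._loo_cache = out
        return self._loo_cache

    # -- calibration & prediction -------------------------------------------

    def calibrate(self, method: str = "binned", q: int = DEFAULT_BINS,
                  degree: int = DEFAULT_DEGREE) -> CalibrationPair:
        """Fit Pc/Pnc curves from LOO B-statistics of the training set."""
        self._require_training_data()
        loo = self.loo_matrix()
        is_cne = self._fot_labels != _NON_CNE
        pc_curve = fit_calibration(loo[:, _CNE], is_cne, method, q, degree)
        pnc_curve = fit_calibration(loo[:, _NON_CNE], ~is_cne, method, q, degree)
        return CalibrationPair(pc_curve, pnc_curve)

    def predict_grams(self, grams: Iterable[str],
                      calibration: CalibrationPair) -> Prediction:
        b = self.b_all(grams)
        return Prediction({label: float(b[i]) for i, label in enumerate(CLASS_ORDER)},
                          pc=calibration.pc(b[_CNE]),
                          pnc=calibration.pnc(b[_NON_CNE]))

    def predict_fot(self, fot: FoT, calibration: CalibrationPair) -> Prediction:
        if fot.window != self.window:
            raise ValueError(f"FoT window {fot.window} != model window {self.window}")
        return self.predict_grams(fot_descriptors(fot, self.n_max), calibration)

    def predict_position(self, token: str, index: int,
                         calibration: CalibrationPair) -> tuple[float, float]:
        """(Pc, Pnc) for one character of a token, from the grams covering it."""
        pred = self.predict_grams(position_ngrams(token, index, self.n_max),
                                  calibration)
        return pred.pc, pred.pnc

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        c = self.counts
        lines = [
            "Fragment naive Bayes (B-statistic) results",
            "=" * 54,
            f"FoTs (N):            {c.n_total}",
            f"Descriptors (grams): {len(c.grams)}",
            f"n_max:               {c.n_max}",
            f"context window:      {c.window}",
            f"aggregation:         {self.sum_mode} of centred arcsine terms",
            f"smoothing alpha:     {self.smoothing_alpha}",
            "-" * 54,
            f"{'class':<14}{'Nk':>10}{'P(Ck)':>10}{'R=N/Nk':>12}",
        ]
        for i, label in enumerate(CLASS_ORDER):
            nk = int(c.nk[i])
            ratio = f"{c.n_total / nk:>12.1f}" if nk else f"{'--':>12}"
            lines.append(f"{label.value:<14}{nk:>10}{nk / c.n_total:>10.4f}{ratio}")
        lines.append("=" * 54)
        return "\n".join(lines)

    # -- persistence ---------------------------------------------------------

    def save(self, path, calibration: CalibrationPair | None = None) -> None:
        """Write the counts (and optionally a binned calibration) as text."""
        c = self.counts
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# cnerbayes model v1\n")
            fh.write(f"n_max={c.n_max}\n")
            fh.write(f"window={c.window}\n")
            fh.write(f"sum_mode={self.sum_mode}\n")
            fh.write(f"smoothing_alpha={self.smoothing_alpha!r}\n")
            fh.write(f"N={c.n_total}\n")
            fh.write("classes=" + ",".join(l.value for l in CLASS_ORDER) + "\n")
            fh.write("NK=" + ",".join(str(int(v)) for v in c.nk) + "\n")
            if calibration is not None:
                for name, curve in (("pc", calibration.pc_curve),
                                    ("pnc", calibration.pnc_curve)):
                    if not isinstance(curve, BinnedCalibration):
                        raise ValueError(
                            "only binned calibrations are persisted")
                    fh.write(f"{name}_centers="
                             + ",".join(repr(float(v)) for v in curve.centers)
                             + "\n")
                    fh.write(f"{name}_values="
                             + ",".join(repr(float(v)) for v in curve.values)
                             + "\n")
            fh.write("[surfaces]\n")
            for surface, (count, cne) in sorted(self.surface_stats.items()):
                if count >= 5:
                    fh.write(f"{surface}\t{count}\t{cne}\n")
            fh.write("[grams]\n")
            for idx, gram in enumerate(c.grams):
                row = ",".join(str(int(v)) for v in c.nik[idx])
                fh.write(f"{gram}\t{int(c.ni[idx])}\t{row}\n")


def load_results(path) -> tuple[FragmentNaiveBayesResults, CalibrationPair | None]:
    """Load a model file written by :meth:`FragmentNaiveBayesResults.save`.

    The returned results object predicts and extracts; leave-one-out and
    re-calibration are unavailable (per-FoT data is not persisted).
    """
    header: dict[str, str] = {}
    surfaces: dict[str, list[int]] = {}
    grams: list[str] = []
    ni_rows: list[int] = []
    nik_rows: list[list[int]] = []
    section = "header"
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line or line.startswith("#"):
            continue
        if line == "[surfaces]":
            section = "surfaces"
            continue
        if line == "[grams]":
            section = "grams"
            continue
        if section == "header":
            key, _, value = line.partition("=")
            header[key] = value
        elif section == "surfaces":
            surface, count, cne = line.split("\t")
            surfaces[surface] = [int(count), int(cne)]
        else:
            gram, ni_s, nik_s = line.split("\t")
            grams.append(gram)
            ni_rows.append(int(ni_s))
            nik_rows.append([int(v) for v in nik_s.split(",")])

    class_names = header["classes"].split(",")
    if class_names != [l.value for l in CLASS_ORDER]:
        raise ValueError(f"unexpected class order in model file: {class_names}")
    counts = ModelCounts(
        n_max=int(header["n_max"]), window=int(header["window"]),
        n_total=int(header["N"]),
        nk=np.asarray([int(v) for v in header["NK"].split(",")], dtype=np.int64),
        grams=grams, gram_index={g: i for i, g in enumerate(grams)},
        ni=np.asarray(ni_rows, dtype=np.int64),
        nik=np.asarray(nik_rows, dtype=np.int64).reshape(len(grams), _N_CLASSES),
    )
    results = FragmentNaiveBayesResults(
        None, counts, surface_stats=surfaces,
        sum_mode=header.get("sum_mode", "mean"),
        smoothing_alpha=float(header.get("smoothing_alpha", "0.0")))
    calibration = None
    if "pc_centers" in header:
        def _arr(key):
            return np.asarray([float(v) for v in header[key].split(",")])
        calibration = CalibrationPair(
            BinnedCalibration(_arr("pc_centers"), _arr("pc_values")),
            BinnedCalibration(_arr("pnc_centers"), _arr("pnc_values")))
    return results, calibration
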