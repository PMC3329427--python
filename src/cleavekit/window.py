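"""Axis-aligned window search maximizing the F-score of blastocyst prediction.

The classifier is deliberately simple: pick 1-3 timing features and one
closed interval [lo, hi] per feature; an embryo inside every interval is
predicted to form a blastocyst.  Fitting is an exhaustive, exact search over
the Cartesian product of candidate interval endpoints (midpoints between
consecutive sorted unique feature values, plus +/-inf), maximizing the
F-score F = 2*pr*sn/(pr+sn) (accuracy as an alternative objective).  Ties are
broken by higher accuracy, then smaller window volume, then the
lexicographically smallest lower-bound vector, so the optimum is
deterministic.

The model-style entry point is :class:`WindowPredictor`; the functional API
(:func:`best_window`, :func:`evaluate_feature_panel`) underlies it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ArgumentError

_TIE_TOL = 1e-12


@dataclass
class WindowClassifier:
    """Inside-all-intervals rule over 1-3 features."""

    features: tuple[str, ...]
    intervals: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if len(self.features) != len(self.intervals):
            raise ArgumentError("one interval per feature required")
        for lo, hi in self.intervals:
            if not lo <= hi:
                raise ArgumentError(f"interval endpoints out of order: [{lo}, {hi}]")

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Boolean predictions; rows with a missing feature predict False."""
        inside = np.ones(len(features), dtype=bool)
        for name, (lo, hi) in zip(self.features, self.intervals):
            vals = features[name].to_numpy(dtype=float)
            inside &= (vals >= lo) & (vals <= hi)
        return inside


@dataclass
class PredictionScore:
    """Confusion counts and the derived window-classifier scores."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / total if total else 0.0

    @property
    def f_score(self) -> float:
        pr, sn = self.precision, self.sensitivity
        return 2.0 * pr * sn / (pr + sn) if pr + sn else 0.0


def candidate_boundaries(values) -> np.ndarray:
    """Interval-endpoint grid for one feature.

    Midpoints between consecutive sorted unique finite values, with -inf
    prepended and +inf appended; missing values are ignored.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ArgumentError("candidate_boundaries: no finite values")
    uniq = np.unique(arr)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.concatenate([[-np.inf], mids, [np.inf]])


def _prepare(features: pd.DataFrame, outcomes, names) -> tuple[np.ndarray, np.ndarray, int]:
    names = tuple(names)
    if not 1 <= len(names) <= 3:
        raise ArgumentError("best_window supports 1-3 features")
    for name in names:
        if name not in features.columns:
            raise ArgumentError(f"feature {name!r} absent from the table")
    X = features.loc[:, list(names)].to_numpy(dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if y.shape[0] != X.shape[0]:
        raise ArgumentError("features and outcomes must align")
    keep = ~np.isnan(X).any(axis=1)
    n_excluded = int((~keep).sum())
    X, y = X[keep], y[keep]
    if X.shape[0] == 0:
        raise ArgumentError("no embryos with all panel features present")
    return X, y, n_excluded


def score_window(
    classifier: WindowClassifier, features: pd.DataFrame, outcomes
) -> PredictionScore:
    """Confusion counts of a window rule; embryos missing a feature excluded."""
    X, y, _ = _prepare(features, outcomes, classifier.features)
    inside = np.ones(X.shape[0], dtype=bool)
    for axis, (lo, hi) in enumerate(classifier.intervals):
        inside &= (X[:, axis] >= lo) & (X[:, axis] <= hi)
    tp = int(np.sum(inside & y))
    fp = int(np.sum(inside & ~y))
    fn = int(np.sum(~inside & y))
    tn = int(np.sum(~inside & ~y))
    return PredictionScore(tp, fp, tn, fn)


def _volume(intervals, X) -> float:
    """Tie-break volume: product of interval widths clipped to the data range."""
    vol = 1.0
    for axis, (lo, hi) in enumerate(intervals):
        vmin, vmax = float(np.min(X[:, axis])), float(np.max(X[:, axis]))
        width = max(0.0, min(hi, vmax) - max(lo, vmin))
        vol *= width
    return vol


def _best_1d(values, is_pos, n_pos_total, n_neg_total):
    """Exact 1D scan, vectorized over all boundary pairs.

    Returns (f, acc, lo, hi, tp, fp) of every window as flat arrays, for the
    subset of embryos given; tp/fp count within the subset, while sn/F use
    the cohort-level positive total n_pos_total.
    """
    bounds = candidate_boundaries(values)
    m = bounds.size
    order = np.argsort(values, kind="mergesort")
    sv = values[order]
    sp = is_pos[order]
    cpos = np.concatenate([[0], np.cumsum(sp)])
    call = np.arange(sv.size + 1)
    # number of values (and positives) strictly below each boundary
    idx = np.searchsorted(sv, bounds, side="left")
    pos_below = cpos[idx]
    all_below = call[idx]
    i, j = np.triu_indices(m, k=1)
    tp = pos_below[j] - pos_below[i]
    inside = all_below[j] - all_below[i]
    fp = inside - tp
    fn = n_pos_total - tp
    tn = n_neg_total - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        sn = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        pr = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        denom = pr + sn
        f = np.where(denom > 0, 2 * pr * sn / denom, 0.0)
    acc = (tp + tn) / (n_pos_total + n_neg_total)
    return f, acc, bounds[i], bounds[j], tp, fp


def _key_better(cand, best) -> bool:
    """cand/best = (f_or_obj, acc, -volume, lo_vector); lexicographic compare."""
    for a, b in zip(cand[:3], best[:3]):
        if a > b + _TIE_TOL:
            return True
        if a < b - _TIE_TOL:
            return False
    # lower lo vector wins
    for a, b in zip(cand[3], best[3]):
        if a < b - _TIE_TOL:
            return True
        if a > b + _TIE_TOL:
            return False
    return False


def best_window(
    features: pd.DataFrame,
    outcomes,
    feature_names,
    objective: str = "f_score",
) -> tuple[WindowClassifier, PredictionScore]:
    """Exhaustive exact search for the objective-maximizing window.

    Complexity O(prod(m_i^2) * n) over per-axis candidate boundary counts
    m_i; no pruning that could change the argmax.
    """
    if objective not in ("f_score", "accuracy"):
        raise ArgumentError(f"unknown objective {objective!r}")
    X, y, _ = _prepare(features, outcomes, feature_names)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ArgumentError("best_window requires outcomes of both classes")

    names = tuple(feature_names)
    d = X.shape[1]
    best = None  # (obj, acc, -vol, lo_vec, intervals)

    def consider(f, acc, lo_vec, intervals):
        nonlocal best
        obj = f if objective == "f_score" else acc
        vol = _volume(intervals, X)
        cand = (obj, acc, -vol, lo_vec, intervals)
        if best is None or _key_better(cand, best):
            best = cand

    def search(axis, mask, prefix):
        if axis == d - 1:
            vals = X[mask, axis]
            if vals.size == 0:
                return
            f, acc, lo, hi, _, _ = _best_1d(vals, y[mask], n_pos, n_neg)
            # only windows tied (within tolerance) for the best objective on
            # this slice can win globally; hand just those to the tie-break
            obj = f if objective == "f_score" else acc
            for k in np.nonzero(obj >= obj.max() - _TIE_TOL)[0]:
                intervals = prefix + ((float(lo[k]), float(hi[k])),)
                consider(
                    float(f[k]), float(acc[k]),
                    tuple(iv[0] for iv in intervals), intervals,
                )
            return
        bounds = candidate_boundaries(X[mask, axis])
        m = bounds.size
        for i in range(m - 1):
            for j in range(i + 1, m):
                lo, hi = float(bounds[i]), float(bounds[j])
                sub = mask & (X[:, axis] >= lo) & (X[:, axis] <= hi)
                if not sub.any():
                    continue
                search(axis + 1, sub, prefix + ((lo, hi),))

    search(0, np.ones(X.shape[0], dtype=bool), ())
    if best is None:
        raise ArgumentError("no scoreable window found")
    classifier = WindowClassifier(names, best[4])
    score = score_window(classifier, features, outcomes)
    return classifier, score


def evaluate_feature_panel(
    features: pd.DataFrame,
    outcomes,
    panel,
    dims: int = 1,
    objective: str = "f_score",
) -> pd.DataFrame:
    """Best window for every size-``dims`` combination of panel features.

    One row per combination, sorted by F descending; reports the interval(s),
    the confusion counts and the number of embryos excluded for missing
    features.
    """
    panel = list(panel)
    if not panel:
        raise ArgumentError("panel must be non-empty")
    if not 1 <= dims <= 3:
        raise ArgumentError("dims must be 1, 2 or 3")
    rows = []
    for combo in combinations(panel, dims):
        _, _, n_excluded = _prepare(features, outcomes, combo)
        clf, score = best_window(features, outcomes, combo, objective=objective)
        rows.append(
            {
                "features": "+".join(combo),
                "intervals": "; ".join(
                    f"[{lo:.4g}, {hi:.4g}]" for lo, hi in clf.intervals
                ),
                "f_score": score.f_score,
                "accuracy": score.accuracy,
                "sensitivity": score.sensitivity,
                "precision": score.precision,
                "tp": score.tp,
                "fp": score.fp,
                "tn": score.tn,
                "fn": score.fn,
                "n_excluded_missing": n_excluded,
            }
        )
    out = pd.DataFrame(rows).sort_values("f_score", ascending=False, kind="mergesort")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# model-style wrapper


class WindowPredictor:
    """Window-rule blastocyst predictor, statsmodels-style.

    Parameters
    ----------
    endog : array-like of bool
        Blastocyst outcome per embryo.
    exog : DataFrame
        Timing-feature table (dotted feature names as columns).
    feature_names : sequence of 1-3 column names to search over.
    objective : "f_score" (default) or "accuracy".
    """

    def __init__(self, endog, exog: pd.DataFrame, feature_names, objective="f_score"):
        self.endog = np.asarray(endog, dtype=bool)
        self.exog = exog
        self.feature_names = tuple(feature_names)
        self.objective = objective

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, outcome: str, feature_names, objective="f_score"
    ) -> "WindowPredictor":
        y = data[outcome].astype(float)
        keep = y.notna()
        return cls(
            y[keep].astype(bool).to_numpy(),
            data.loc[keep],
            feature_names,
            objective,
        )

    def fit(self) -> "WindowPredictorResults":
        clf, score = best_window(
            self.exog, self.endog, self.feature_names, objective=self.objective
        )
        return WindowPredictorResults(self, clf, score)


class WindowPredictorResults:
    """Fitted window rule plus its in-sample prediction scores."""

    def __init__(self, model: WindowPredictor, classifier: WindowClassifier,
                 score: PredictionScore):
        self.model = model
        self.classifier = classifier
        self.score = score

    def predict(self, exog: pd.DataFrame | None = None) -> np.ndarray:
        return self.classifier.predict(
            self.model.exog if exog is None else exog
        )

    def summary(self) -> str:
        s = self.score
        lines = [
            "Window-rule blastocyst predictor",
            "=" * 40,
            f"objective: {self.model.objective} (in-sample)",
            f"n: {s.tp + s.fp + s.tn + s.fn}   prevalence: "
            f"{(s.tp + s.fn) / max(s.tp + s.fp + s.tn + s.fn, 1):.3f}",
            "-" * 40,
        ]
        for name, (lo, hi) in zip(self.classifier.features, self.classifier.intervals):
            lines.append(f"  {name:>10s} in [{lo:.3f}, {hi:.3f}]")
        lines += [
            "-" * 40,
            f"F-score     {s.f_score:.4f}",
            f"accuracy    {s.accuracy:.4f}",
            f"sensitivity {s.sensitivity:.4f}",
            f"precision   {s.precision:.4f}",
            f"confusion   tp={s.tp} fp={s.fp} tn={s.tn} fn={s.fn}",
        ]
        return "\n".join(lines)
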