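"""Single-trial SWLDA treatment classification.

Pipeline: per-session "difference trials" at the frontocentral channel
(each deviant minus the mean standard response, and the mean deviant
response minus each standard), 64 Hz time-domain features restricted to the
N1 (80-105 ms) and P3 (200-500 ms) ranges (22 points), minority-class
oversampling, stepwise regression feature selection (partial-F entry
p < 0.05, removal p > 0.1, min-p fallback), Fisher linear discriminant,
per-trial classification, session-level majority vote, leave-one-animal-out
evaluation, and 2x2 contingency / chi-square reporting per treatment pair.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import DEVIANT, STANDARD, EpochSet


@dataclass(frozen=True)
class FeatureWindowSpec:
    """Feature windows (ms post-stimulus) and the sampling rate they index."""

    windows_ms: tuple[tuple[float, float], ...] = ((80.0, 105.0),
                                                   (200.0, 500.0))
    fs_hz: float = 64.0

    def __post_init__(self) -> None:
        for (a0, a1), (b0, b1) in zip(self.windows_ms, self.windows_ms[1:]):
            if b0 < a1:
                raise ValueError("feature windows must be ordered and "
                                 "non-overlapping")

    @property
    def n_features(self) -> int:
        return sum(window_to_indices(w, self.fs_hz)[1]
                   for w in self.windows_ms)


@dataclass
class DifferenceTrialSet:
    """Per-session difference trials: (n_trials, n_samples) µV waveforms."""

    data: np.ndarray
    time_ms: np.ndarray
    fs_hz: float
    source_kind: np.ndarray   # 'deviant_minus_meanstd' | 'meandev_minus_standard'
    animal: int
    treatment: str

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass
class SWLDAModel:
    selected: list[int]
    trace: list[dict]
    weights: np.ndarray
    bias: float
    class_labels: tuple[str, str]

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("duplicate selected features")
        if len(self.weights) != len(self.selected):
            raise ValueError("weights must match selected features")


@dataclass
class SessionPrediction:
    animal: int
    actual: str
    predicted: str
    votes: dict[str, int]
    tie_broken: bool = False
    n_features: int = 0


@dataclass
class ContingencyTable:
    counts: np.ndarray            # 2x2, rows actual, cols predicted
    class_labels: tuple[str, str]
    session_accuracy: float
    chi2: float
    p: float


def window_to_indices(window_ms: tuple[float, float], fs_hz: float
                      ) -> tuple[int, int]:
    """Map an ms window to (first sample index, count) on an onset-anchored
    grid: first = round(start*fs/1000), count = ceil((end-start)*fs/1000).

    This convention gives 2 N1 + 20 P3 = 22 points at 64 Hz.
    """
    start, end = window_ms
    if fs_hz <= 0:
        raise ValueError("fs_hz must be positive")
    if end <= start:
        raise ValueError("window end must exceed start")
    first = round(start * fs_hz / 1000.0)
    count = int(np.ceil((end - start) * fs_hz / 1000.0 - 1e-9))
    return first, count


def make_difference_trials(epochs: EpochSet, channel: str = "FC"
                           ) -> DifferenceTrialSet:
    """Build difference trials at one channel from retained trials only.

    Kind 1: each retained deviant minus the mean retained standard.
    Kind 2: the mean retained deviant minus each retained standard.
    Both have the same expectation (the session difference curve), and
    together give n_dev + n_std trials.
    """
    ci = epochs.channel_index(channel)
    keep = epochs.retained[:, ci]
    dev = epochs.data[(epochs.trial_class == DEVIANT) & keep, ci]
    std = epochs.data[(epochs.trial_class == STANDARD) & keep, ci]
    if dev.shape[0] == 0 or std.shape[0] == 0:
        raise ValueError(
            "session has no retained trials of one class; excluded from "
            "classification")
    kind1 = dev - std.mean(axis=0)
    kind2 = dev.mean(axis=0) - std
    data = np.concatenate([kind1, kind2], axis=0)
    kinds = np.array(["deviant_minus_meanstd"] * kind1.shape[0]
                     + ["meandev_minus_standard"] * kind2.shape[0])
    return DifferenceTrialSet(
        data=data, time_ms=epochs.time_ms.copy(), fs_hz=epochs.fs_hz,
        source_kind=kinds, animal=int(epochs.meta.get("animal", -1)),
        treatment=str(epochs.meta.get("treatment", "")))


def extract_features(trials, spec: FeatureWindowSpec = FeatureWindowSpec()
                     ) -> np.ndarray:
    """Concatenate windowed 64 Hz samples into the feature matrix.

    Accepts a DifferenceTrialSet or a (trials, samples) array with an
    onset-anchored time axis at ``spec.fs_hz``.
    """
    if isinstance(trials, DifferenceTrialSet):
        data, time_ms, fs = trials.data, trials.time_ms, trials.fs_hz
    else:
        raise TypeError("extract_features expects a DifferenceTrialSet; "
                        "use feature_columns for raw arrays")
    if abs(fs - spec.fs_hz) > 1e-9:
        raise ValueError(
            f"trials sampled at {fs} Hz but features are defined at "
            f"{spec.fs_hz} Hz; resample first")
    cols = feature_columns(time_ms, spec)
    return data[:, cols]


def feature_columns(time_ms: np.ndarray, spec: FeatureWindowSpec
                    ) -> np.ndarray:
    """Sample indices (into an onset-anchored time axis) of all feature
    points, in window order."""
    step = 1000.0 / spec.fs_hz
    onset = int(np.argmin(np.abs(time_ms)))
    if abs(time_ms[onset]) > step / 2:
        raise ValueError("time axis has no sample at stimulus onset")
    cols = []
    for w in spec.windows_ms:
        first, count = window_to_indices(w, spec.fs_hz)
        idx = onset + first + np.arange(count)
        if idx[-1] >= time_ms.size:
            raise ValueError(f"feature window {w} extends beyond the epoch")
        cols.append(idx)
    return np.concatenate(cols)


def feature_times_ms(spec: FeatureWindowSpec = FeatureWindowSpec()
                     ) -> np.ndarray:
    """Post-stimulus times (ms) of the feature points."""
    step = 1000.0 / spec.fs_hz
    times = []
    for w in spec.windows_ms:
        first, count = window_to_indices(w, spec.fs_hz)
        times.append((first + np.arange(count)) * step)
    return np.concatenate(times)


def oversample_minority(X: np.ndarray, y: np.ndarray, seed: int = 0
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Duplicate seeded random minority-class rows (with replacement) until
    both classes have equally many trials; all original rows are kept."""
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("oversampling expects exactly two classes")
    if counts[0] == counts[1]:
        return X, y
    rng = np.random.default_rng(seed)
    minority = classes[np.argmin(counts)]
    need = int(abs(counts[0] - counts[1]))
    pool = np.flatnonzero(y == minority)
    extra = rng.choice(pool, size=need, replace=True)
    return np.concatenate([X, X[extra]]), np.concatenate([y, y[extra]])


# ---------------------------------------------------------------------------
# stepwise regression feature selection
# ---------------------------------------------------------------------------

def _rss(G: np.ndarray, g: np.ndarray, yy: float, idx: list[int]) -> float:
    """Residual sum of squares of OLS on the Gram submatrix ``idx``
    (index 0 is the intercept)."""
    Gs = G[np.ix_(idx, idx)]
    gs = g[idx]
    try:
        beta = np.linalg.solve(Gs, gs)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(Gs, gs, rcond=None)[0]
    return float(max(yy - gs @ beta, 0.0))


def _partial_f_p(rss_reduced: float, rss_full: float, n: int, k_full: int
                 ) -> float:
    """p-value of the 1-df partial F-test comparing nested OLS models;
    k_full counts regressors excluding the intercept."""
    df_den = n - k_full - 1
    if df_den <= 0 or rss_full <= 0:
        return 1.0 if rss_reduced <= rss_full else 0.0
    f = (rss_reduced - rss_full) / (rss_full / df_den)
    return float(stats.f.sf(max(f, 0.0), 1, df_den))


def stepwise_select(X: np.ndarray, y, p_enter: float = 0.05,
                    p_remove: float = 0.1, max_steps: int = 200
                    ) -> tuple[list[int], list[dict]]:
    """Stepwise regression of the (numeric ±1 coded) class label on the
    feature columns.

    Each step: compute the partial-F p-value for adding every excluded
    feature to the current OLS model; if the smallest is below ``p_enter``,
    add that feature. Otherwise, if any included feature's removal p-value
    exceeds ``p_remove``, remove the largest. Stop when neither applies.
    If no feature was ever selected, fall back to the single feature with
    the smallest first-step p-value. Returns (selected order, trace).
    """
    if p_enter >= p_remove:
        raise ValueError("p_enter must be below p_remove")
    X = np.asarray(X, dtype=float)
    yv = np.asarray(y)
    classes = np.unique(yv)
    if classes.size == 2 and not np.issubdtype(yv.dtype, np.number):
        yv = np.where(yv == classes[0], -1.0, 1.0)
    yv = np.asarray(yv, dtype=float)
    n, m = X.shape
    Z = np.column_stack([np.ones(n), X])
    G = Z.T @ Z
    g = Z.T @ yv
    yy = float(yv @ yv)

    selected: list[int] = []
    trace: list[dict] = []
    first_step_p: np.ndarray | None = None
    for _ in range(max_steps):
        cur = [0] + [j + 1 for j in selected]
        rss_cur = _rss(G, g, yy, cur)
        excluded = [j for j in range(m) if j not in selected]
        entry_p = np.full(m, np.nan)
        for j in excluded:
            rss_j = _rss(G, g, yy, cur + [j + 1])
            entry_p[j] = _partial_f_p(rss_cur, rss_j, n, len(selected) + 1)
        if first_step_p is None:
            first_step_p = entry_p.copy()
        if excluded:
            best = min(excluded, key=lambda j: (entry_p[j], j))
            if entry_p[best] < p_enter:
                selected.append(best)
                trace.append({"action": "add", "feature": best,
                              "p": float(entry_p[best])})
                continue
        removal_p = {}
        for j in selected:
            rest = [0] + [k + 1 for k in selected if k != j]
            rss_rest = _rss(G, g, yy, rest)
            removal_p[j] = _partial_f_p(rss_rest, rss_cur, n, len(selected))
        if removal_p:
            worst = max(selected, key=lambda j: (removal_p[j], -j))
            if removal_p[worst] > p_remove:
                selected.remove(worst)
                trace.append({"action": "remove", "feature": worst,
                              "p": float(removal_p[worst])})
                continue
        break
    else:
        raise RuntimeError(
            f"stepwise selection did not converge in {max_steps} steps; "
            f"trace: {trace}")
    if not selected:
        best = int(np.nanargmin(first_step_p))
        selected = [best]
        trace.append({"action": "fallback", "feature": best,
                      "p": float(first_step_p[best])})
    return selected, trace


# ---------------------------------------------------------------------------
# linear discriminant
# ---------------------------------------------------------------------------

def fit_lda(X: np.ndarray, y, class_labels: tuple[str, str] | None = None
            ) -> tuple[np.ndarray, float, tuple[str, str]]:
    """Fisher linear discriminant: w = S_pooled^-1 (mu_A - mu_B), bias at
    the midpoint projection. Singular pooled covariance falls back to a
    scaled-identity ridge."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if class_labels is None:
        uniq = np.unique(y)
        if uniq.size != 2:
            raise ValueError("need exactly two classes")
        class_labels = (str(uniq[0]), str(uniq[1]))
    a_mask = y == class_labels[0]
    b_mask = y == class_labels[1]
    if not a_mask.any() or not b_mask.any():
        raise ValueError("both classes must be present")
    Xa, Xb = X[a_mask], X[b_mask]
    mu_a, mu_b = Xa.mean(axis=0), Xb.mean(axis=0)
    na, nb = Xa.shape[0], Xb.shape[0]
    S = ((Xa - mu_a).T @ (Xa - mu_a) + (Xb - mu_b).T @ (Xb - mu_b))
    S /= max(na + nb - 2, 1)
    try:
        w = np.linalg.solve(S, mu_a - mu_b)
    except np.linalg.LinAlgError:
        ridge = 1e-6 * np.trace(S) / S.shape[0] + 1e-12
        w = np.linalg.solve(S + ridge * np.eye(S.shape[0]), mu_a - mu_b)
    bias = float(w @ (mu_a + mu_b) / 2.0)
    return w, bias, class_labels


def classify_trials(model: SWLDAModel, X_test: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Signed scores w.x - bias and labels: positive side -> class A
    (exact zeros are assigned to class A)."""
    X_test = np.asarray(X_test, dtype=float)
    if X_test.shape[1] != len(model.selected):
        raise ValueError(
            f"expected {len(model.selected)} selected-feature columns, got "
            f"{X_test.shape[1]}")
    scores = X_test @ model.weights - model.bias
    labels = np.where(scores >= 0, model.class_labels[0],
                      model.class_labels[1])
    return labels, scores


def majority_vote(trial_labels, trial_scores, class_labels: tuple[str, str]
                  ) -> tuple[str, dict[str, int], bool]:
    """Session label by simple majority; exact ties go to the class with the
    larger mean absolute score margin."""
    labels = np.asarray(trial_labels)
    scores = np.asarray(trial_scores, dtype=float)
    if labels.size == 0:
        raise ValueError("majority vote needs at least one trial")
    votes = {c: int((labels == c).sum()) for c in class_labels}
    a, b = class_labels
    if votes[a] != votes[b]:
        return (a if votes[a] > votes[b] else b), votes, False
    margins = {c: (np.abs(scores[labels == c]).mean()
                   if (labels == c).any() else 0.0) for c in class_labels}
    winner = a if margins[a] >= margins[b] else b
    return winner, votes, True


def train_swlda(X_train: np.ndarray, y_train,
                class_labels: tuple[str, str], p_enter: float = 0.05,
                p_remove: float = 0.1, seed: int = 0,
                oversample: bool = True) -> SWLDAModel:
    """Oversample, select features stepwise, and fit the discriminant."""
    y_train = np.asarray(y_train)
    if oversample:
        X_train, y_train = oversample_minority(X_train, y_train, seed=seed)
    selected, trace = stepwise_select(X_train, y_train, p_enter=p_enter,
                                      p_remove=p_remove)
    w, bias, labels = fit_lda(X_train[:, selected], y_train,
                              class_labels=class_labels)
    return SWLDAModel(selected=selected, trace=trace, weights=w, bias=bias,
                      class_labels=labels)


def loo_session_classification(
        trialsets: dict[tuple[int, str], DifferenceTrialSet],
        treatment_a: str, treatment_b: str,
        spec: FeatureWindowSpec = FeatureWindowSpec(),
        p_enter: float = 0.05, p_remove: float = 0.1, seed: int = 0,
        ) -> list[SessionPrediction]:
    """Leave-one-animal-out session classification for one treatment pair.

    Every session of either treatment is tested; its training set pools the
    difference trials of all *other* animals' sessions of the two
    treatments. Animals missing one of the pair still have their available
    session tested.
    """
    pair = (treatment_a, treatment_b)
    sessions = {k: v for k, v in trialsets.items() if k[1] in pair}
    animals = sorted({k[0] for k in sessions})
    if len(animals) < 2:
        raise ValueError("leave-one-animal-out needs sessions from at "
                         "least 2 animals")
    feats = {k: extract_features(v, spec) for k, v in sessions.items()}
    predictions = []
    for animal in animals:
        train_keys = [k for k in sessions if k[0] != animal]
        X = np.concatenate([feats[k] for k in train_keys])
        y = np.concatenate([np.full(feats[k].shape[0], k[1])
                            for k in train_keys])
        model = train_swlda(X, y, class_labels=pair, p_enter=p_enter,
                            p_remove=p_remove,
                            seed=(seed + animal) % (2**31))
        for treatment in pair:
            key = (animal, treatment)
            if key not in sessions:
                continue
            labels, scores = classify_trials(model,
                                             feats[key][:, model.selected])
            winner, votes, tie = majority_vote(labels, scores, pair)
            predictions.append(SessionPrediction(
                animal=animal, actual=treatment, predicted=winner,
                votes=votes, tie_broken=tie,
                n_features=len(model.selected)))
    return predictions


def contingency_and_chi2(predicted, actual,
                         class_labels: tuple[str, str],
                         yates: bool = False) -> ContingencyTable:
    """2x2 actual x predicted counts, session accuracy, and the Pearson
    chi-square test (no continuity correction by default)."""
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    if predicted.size == 0:
        raise ValueError("no predictions to tabulate")
    counts = np.array([[int(((actual == ai) & (predicted == pj)).sum())
                        for pj in class_labels] for ai in class_labels])
    accuracy = float(np.trace(counts) / counts.sum())
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(counts, correction=yates)
    return ContingencyTable(counts=counts, class_labels=class_labels,
                            session_accuracy=accuracy, chi2=float(chi2),
                            p=float(p))


def pairwise_report(trialsets: dict[tuple[int, str], DifferenceTrialSet],
                    treatments: list[str] | None = None,
                    spec: FeatureWindowSpec = FeatureWindowSpec(),
                    seed: int = 0, **swlda_kwargs) -> pd.DataFrame:
    """One-vs-one session classification for every treatment pair.

    Returns one row per unordered pair: treatment_a, treatment_b, n (animals
    with both sessions), n_sessions, accuracy, chi2, p.
    """
    if treatments is None:
        treatments = sorted({k[1] for k in trialsets})
    if len(treatments) < 2:
        raise ValueError("need at least two treatments")
    rows = []
    for a, b in itertools.combinations(treatments, 2):
        preds = loo_session_classification(trialsets, a, b, spec=spec,
                                           seed=seed, **swlda_kwargs)
        table = contingency_and_chi2([p.predicted for p in preds],
                                     [p.actual for p in preds], (a, b))
        animals_a = {k[0] for k in trialsets if k[1] == a}
        animals_b = {k[0] for k in trialsets if k[1] == b}
        rows.append({
            "treatment_a": a, "treatment_b": b,
            "n": len(animals_a & animals_b), "n_sessions": len(preds),
            "accuracy": table.session_accuracy,
            "chi2": table.chi2, "p": table.p,
        })
    return pd.DataFrame(rows)
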