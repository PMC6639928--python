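"""Weather feature engineering and event-onset prediction.

Builds the engineered predictor matrix — eight base weather variables, each
expanded into six variants (instantaneous value, values lagged by 24/48/72 h,
and past-cumulative aggregates over 48/72 h; 48 features in total) — and
fits a bagged decision-tree ensemble to the binary onset response, reporting
out-of-bag (OOB) error rates and permutation importance (mean decrease
accuracy), the standard random-forest importance measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier
from sklearn.tree import DecisionTreeClassifier

from .events import BreedingEvent
from .exceptions import InvalidInputError

logger = logging.getLogger(__name__)

BASE_VARIABLES = ("rain", "temp", "temp_var", "rh", "atm", "atm_var", "solrad", "phper")
#: Flux-like variables aggregate by sum over a past window; state variables by mean.
FLUX_VARIABLES = frozenset({"rain", "solrad"})
VARIANTS = ("inst", "lag24", "lag48", "lag72", "cum48", "cum72")
LAG_HOURS = {"lag24": 24, "lag48": 48, "lag72": 72}
CUM_HOURS = {"cum48": 48, "cum72": 72}


# ---------------------------------------------------------------------------
# Feature and response construction
# ---------------------------------------------------------------------------


def build_features(
    weather: pd.DataFrame, obs_cadence: str | pd.Timedelta = "24h"
) -> pd.DataFrame:
    """Engineered predictor block sampled every ``obs_cadence``.

    For each base variable v and observation time t:

    * ``v_inst``  = value at t
    * ``v_lagH``  = value at t - H hours, H in {24, 48, 72}
    * ``v_cumH``  = sum (rain, solrad) or mean (others) over (t - H, t]

    Observations in the first 72 h (incomplete history) are dropped.
    """
    missing = [c for c in BASE_VARIABLES if c not in weather.columns]
    if missing:
        raise InvalidInputError(f"weather series lacks base variables: {missing}")
    index = pd.DatetimeIndex(weather.index)
    span = index[-1] - index[0]
    if span <= pd.Timedelta(hours=72):
        raise InvalidInputError("weather series must span more than 72 h")
    obs_cadence = pd.Timedelta(obs_cadence)
    step = index[1] - index[0]
    obs = pd.date_range(index[0] + pd.Timedelta(hours=72), index[-1], freq=obs_cadence)

    cols = {}
    for var in BASE_VARIABLES:
        s = weather[var]
        cols[f"{var}_inst"] = s.reindex(obs).to_numpy()
        for name, h in LAG_HOURS.items():
            cols[f"{var}_{name}"] = s.reindex(obs - pd.Timedelta(hours=h)).to_numpy()
        win = {
            name: int(pd.Timedelta(hours=h) / step) for name, h in CUM_HOURS.items()
        }
        roll = {
            name: (s.rolling(w).sum() if var in FLUX_VARIABLES else s.rolling(w).mean())
            for name, w in win.items()
        }
        for name, r in roll.items():
            cols[f"{var}_{name}"] = r.reindex(obs).to_numpy()

    out = pd.DataFrame(cols, index=obs)
    out = out[[f"{v}_{variant}" for v in BASE_VARIABLES for variant in VARIANTS]]
    if out.isna().any().any():
        raise InvalidInputError(
            "predictor matrix contains missing values; observation times must "
            "lie on the weather series' grid"
        )
    return out


def build_response(
    events: Iterable[BreedingEvent],
    obs_index: pd.DatetimeIndex,
    tolerance: str | pd.Timedelta = "3h",
) -> pd.Series:
    """Binary vector: 1 at the observation nearest each event onset.

    Onsets with no observation within ``tolerance`` are skipped with a
    warning; two onsets mapping to the same observation leave a single 1.
    """
    obs_index = pd.DatetimeIndex(obs_index)
    tolerance = pd.Timedelta(tolerance)
    y = pd.Series(0, index=obs_index, name="onset")
    for ev in events:
        pos = obs_index.get_indexer([ev.onset], method="nearest")[0]
        if abs(obs_index[pos] - ev.onset) > tolerance:
            logger.warning(
                "onset %s has no observation within %s; skipped", ev.onset, tolerance
            )
            continue
        if y.iloc[pos] == 1:
            logger.warning(
                "onset %s maps to an already-marked observation %s",
                ev.onset,
                obs_index[pos],
            )
        y.iloc[pos] = 1
    return y


def build_predictor_matrix(
    weather_by_site: dict[str, pd.DataFrame],
    events: Sequence[BreedingEvent],
    obs_cadence: str | pd.Timedelta = "24h",
    tolerance: str | pd.Timedelta | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Stack per-site feature blocks and responses into one design matrix.

    ``tolerance`` for onset-to-observation mapping defaults to half the
    observation cadence (every onset maps to its nearest observation).
    """
    if tolerance is None:
        tolerance = pd.Timedelta(obs_cadence) / 2
    xs, ys = [], []
    for site, w in weather_by_site.items():
        X = build_features(w, obs_cadence=obs_cadence)
        y = build_response(
            [ev for ev in events if ev.site_id == site], X.index, tolerance=tolerance
        )
        X = X.set_index(pd.MultiIndex.from_product([[site], X.index], names=["site", "timestamp"]))
        y.index = X.index
        xs.append(X)
        ys.append(y)
    return pd.concat(xs), pd.concat(ys)


# ---------------------------------------------------------------------------
# Out-of-bag machinery (shared with the spectral-profile classifier)
# ---------------------------------------------------------------------------


def _oob_masks(forest: BaggingClassifier, n: int) -> list[np.ndarray]:
    """Per-tree boolean masks of observations excluded from the bootstrap."""
    masks = []
    for samples in forest.estimators_samples_:
        m = np.ones(n, dtype=bool)
        m[samples] = False
        masks.append(m)
    return masks


def _oob_votes(
    forest: BaggingClassifier, X: np.ndarray, masks: list[np.ndarray]
) -> np.ndarray:
    """(n, n_classes) OOB vote counts."""
    n = X.shape[0]
    votes = np.zeros((n, len(forest.classes_)), dtype=np.int32)
    for tree, mask in zip(forest.estimators_, masks):
        if not mask.any():
            continue
        pred = tree.predict(X[mask])
        for k in range(len(forest.classes_)):
            votes[mask, k] += pred == k
    return votes


def _oob_accuracy(votes: np.ndarray, y_enc: np.ndarray) -> float:
    """Accuracy of majority-vote OOB predictions (ties to the lower class)."""
    covered = votes.sum(axis=1) > 0
    pred = votes.argmax(axis=1)
    return float(np.mean(pred[covered] == y_enc[covered]))


def oob_permutation_importance(
    forest: BaggingClassifier,
    X: np.ndarray,
    y_enc: np.ndarray,
    n_repeats: int = 5,
    rng: np.random.Generator | None = None,
    scale: bool = True,
) -> np.ndarray:
    """Mean decrease accuracy per feature (per-tree OOB permutation).

    For every tree, each feature is permuted within the tree's out-of-bag
    rows and the tree's OOB accuracy decrease is recorded; the importance
    is the decrease averaged over trees (and repeats).  With ``scale=True``
    the mean is divided by its standard error across trees, the
    conventional scaled mean-decrease-accuracy of random-forest practice.
    """
    rng = rng or np.random.default_rng()
    n, p = X.shape
    masks = _oob_masks(forest, n)
    drops: list[np.ndarray] = []
    for _ in range(max(1, n_repeats)):
        for tree, mask in zip(forest.estimators_, masks):
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                continue
            m = idx.size
            Xo, yo = X[idx], y_enc[idx]
            base = np.mean(tree.predict(Xo) == yo)
            # stack the p single-feature permutations: one predict per tree
            stacked = np.tile(Xo, (p, 1))
            for j in range(p):
                stacked[j * m : (j + 1) * m, j] = Xo[rng.permutation(m), j]
            acc = (tree.predict(stacked).reshape(p, m) == yo).mean(axis=1)
            drops.append(base - acc)
    D = np.asarray(drops)
    mean = D.mean(axis=0)
    if not scale:
        return mean
    se = D.std(axis=0, ddof=1) / np.sqrt(D.shape[0])
    return np.divide(mean, se, out=np.zeros_like(mean), where=se > 0)


# ---------------------------------------------------------------------------
# Model / results objects
# ---------------------------------------------------------------------------


class OnsetForest:
    """Bagged decision-tree classifier of event onsets from weather features.

    Parameters
    ----------
    X : pandas.DataFrame
        Predictor matrix (observations x features).
    y : array-like of {0, 1}
        Binary onset response, one value per observation.
    n_trees : int
        Ensemble size.
    class_weight : str or dict or None
        Passed to the base trees; onsets are rare (~10 positives per season),
        so "balanced" is the default.
    importance_repeats : int
        Permutation repeats for mean decrease accuracy.
    seed : int, optional
        Seed for bootstrap sampling, feature subsampling and permutation.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y,
        n_trees: int = 500,
        class_weight: str | dict | None = "balanced",
        importance_repeats: int = 5,
        max_features: str | int | float = "sqrt",
        min_samples_leaf: int = 1,
        seed: int | None = None,
    ) -> None:
        self.X = pd.DataFrame(X)
        self.y = np.asarray(y).astype(int).ravel()
        if len(self.X) != len(self.y):
            raise InvalidInputError("X and y must be aligned")
        if len(np.unique(self.y)) < 2:
            raise InvalidInputError("response must contain both classes")
        self.n_trees = int(n_trees)
        self.class_weight = class_weight
        self.importance_repeats = int(importance_repeats)
        self.max_features = max_features
        self.min_samples_leaf = int(min_samples_leaf)
        self.seed = seed

    @classmethod
    def from_weather(
        cls,
        weather_by_site: dict[str, pd.DataFrame],
        events: Sequence[BreedingEvent],
        obs_cadence: str | pd.Timedelta = "24h",
        tolerance: str | pd.Timedelta | None = None,
        **kwargs,
    ) -> "OnsetForest":
        # Onsets are rare: coarse leaves keep the balanced class weights
        # effective out-of-bag (fully grown trees isolate each positive).
        kwargs.setdefault("min_samples_leaf", 50)
        X, y = build_predictor_matrix(
            weather_by_site, events, obs_cadence=obs_cadence, tolerance=tolerance
        )
        return cls(X, y, **kwargs)

    def fit(self, compute_importance: bool = True) -> "OnsetForestResults":
        rng = np.random.default_rng(self.seed)
        forest = BaggingClassifier(
            estimator=DecisionTreeClassifier(
                max_features=self.max_features,
                class_weight=self.class_weight,
                min_samples_leaf=self.min_samples_leaf,
            ),
            n_estimators=self.n_trees,
            bootstrap=True,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        Xv = self.X.to_numpy(dtype=float)
        forest.fit(Xv, self.y)
        masks = _oob_masks(forest, len(self.y))
        votes = _oob_votes(forest, Xv, masks)
        covered = votes.sum(axis=1) > 0
        pred = votes.argmax(axis=1)
        y = self.y
        tp = int(np.sum((pred == 1) & (y == 1) & covered))
        fp = int(np.sum((pred == 1) & (y == 0) & covered))
        fn = int(np.sum((pred == 0) & (y == 1) & covered))
        tn = int(np.sum((pred == 0) & (y == 0) & covered))
        importances = None
        if compute_importance:
            drops = oob_permutation_importance(
                forest, Xv, y, n_repeats=self.importance_repeats, rng=rng
            )
            importances = pd.Series(drops, index=self.X.columns, name="mean_decrease_accuracy")
        return OnsetForestResults(
            model=self,
            forest=forest,
            oob_prediction=pd.Series(pred, index=self.X.index),
            oob_covered=covered,
            confusion=(tp, fp, fn, tn),
            importances=importances,
        )


@dataclass
class OnsetForestResults:
    """OOB error estimates and permutation importances of a fitted forest."""

    model: OnsetForest
    forest: BaggingClassifier
    oob_prediction: pd.Series
    oob_covered: np.ndarray
    confusion: tuple[int, int, int, int]  # tp, fp, fn, tn
    importances: pd.Series | None

    @property
    def oob_misclassification(self) -> float:
        tp, fp, fn, tn = self.confusion
        total = tp + fp + fn + tn
        return (fp + fn) / total if total else float("nan")

    @property
    def oob_accuracy(self) -> float:
        return 1.0 - self.oob_misclassification

    @property
    def oob_tpr(self) -> float:
        tp, _, fn, _ = self.confusion
        return tp / (tp + fn) if (tp + fn) else float("nan")

    @property
    def oob_fpr(self) -> float:
        _, fp, _, tn = self.confusion
        return fp / (fp + tn) if (fp + tn) else float("nan")

    def top_features(self, k: int = 10) -> pd.Series:
        if self.importances is None:
            raise InvalidInputError("importances were not computed")
        return self.importances.sort_values(ascending=False).head(k)

    def summary(self) -> str:
        tp, fp, fn, tn = self.confusion
        lines = [
            "Onset forest (bagged decision trees) — out-of-bag estimates",
            "=" * 60,
            f"observations: {len(self.model.y):>6d}    positives: {int(self.model.y.sum())}",
            f"trees:        {self.model.n_trees:>6d}",
            f"OOB misclassification: {self.oob_misclassification:.4f}",
            f"OOB true positive rate: {self.oob_tpr:.4f}",
            f"OOB false positive rate: {self.oob_fpr:.4f}",
            f"confusion (tp fp fn tn): {tp} {fp} {fn} {tn}",
        ]
        if self.importances is not None:
            lines.append("-" * 60)
            lines.append("top features (mean decrease accuracy):")
            for name, val in self.top_features(10).items():
                lines.append(f"  {str(name):<16s} {val:+.4f}")
        return "\n".join(lines)

    def plot_importance(self, k: int = 20, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.3 * k + 1))
        top = self.top_features(k)[::-1]
        ax.barh(top.index, top.to_numpy())
        ax.set_xlabel("mean decrease accuracy")
        return ax


def fit_predict_oob(
    X: pd.DataFrame,
    y,
    n_trees: int = 500,
    class_weight: str | dict | None = "balanced",
    importance_repeats: int = 5,
    seed: int | None = None,
) -> OnsetForestResults:
    """Fit the bagged ensemble and return OOB metrics + permutation importance."""
    return OnsetForest(
        X,
        y,
        n_trees=n_trees,
        class_weight=class_weight,
        importance_repeats=importance_repeats,
        seed=seed,
    ).fit()
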