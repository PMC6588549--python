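"""Random-forest prediction of A2 domain state, statsmodels-style.

:class:`A2StateModel` wraps a balanced :class:`~shearfold.dataset.Dataset`
at one contour resolution; :meth:`A2StateModel.fit` trains one
independent binary forest per contour segment (Gini splitting,
bootstrapped trees, majority vote — scikit-learn's
``RandomForestClassifier``) and returns :class:`A2StateResults`, which
carries per-class recalls on the held-out test split, Gini feature
importances, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from . import importance as _imp
from .dataset import Dataset, build_dataset

__all__ = [
    "ForestConfig",
    "A2StateModel",
    "A2StateResults",
    "gini_impurity",
    "per_class_recall",
]


def gini_impurity(frequencies) -> float:
    """Gini impurity sum_i f_i (1 - f_i) of class frequencies at a node.

    Frequencies must be nonnegative and sum to one (tolerance 1e-9);
    the value lies in [0, 1 - 1/C] for C classes.
    """
    f = np.asarray(frequencies, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequencies must be nonnegative")
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("frequencies must sum to 1")
    return float(np.sum(f * (1.0 - f)))


def per_class_recall(y_true, y_pred) -> tuple[float, float]:
    """(folded, unfolded) recall: per-class fraction correctly predicted.

    Folded is class 0, unfolded class 1.  A class absent from
    ``y_true`` yields ``nan`` for its entry; an empty test set is an
    error.
    """
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.size == 0:
        raise ValueError("empty test set")
    if yt.shape != yp.shape:
        raise ValueError("shape mismatch")
    out = []
    for cls in (0, 1):
        mask = yt == cls
        out.append(float(np.mean(yp[mask] == cls)) if mask.any() else float("nan"))
    return tuple(out)


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters (none are dictated by the problem; all exposed)."""

    n_trees: int = 100
    max_features: str | int | float = "sqrt"
    bootstrap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


class A2StateModel:
    """Per-segment binary classifiers of A2 state at one resolution.

    Parameters
    ----------
    dataset
        Balanced, split feature/response table.
    config
        Forest hyperparameters; defaults to 100 Gini trees with
        sqrt(n_features) candidate features per split and bootstrapping.
    targets
        Response columns to fit; defaults to the per-segment responses
        ``y_s1 .. y_s<resolution>`` (at chain-level resolution the single
        segment *is* the chain).
    """

    def __init__(
        self,
        dataset: Dataset,
        config: ForestConfig | None = None,
        targets: Sequence[str] | None = None,
    ) -> None:
        self.dataset = dataset
        self.config = config or ForestConfig()
        self.targets = list(targets) if targets is not None else [
            f"y_s{s + 1}" for s in range(dataset.resolution)
        ]
        missing = set(self.targets) - set(dataset.Y.columns)
        if missing:
            raise ValueError(f"unknown targets {sorted(missing)}")

    @classmethod
    def from_trajectories(
        cls,
        trajectories,
        resolution: int,
        n_total: int,
        config: ForestConfig | None = None,
        **dataset_kwargs,
    ) -> "A2StateModel":
        """Build the dataset from simulated trajectories and wrap it."""
        ds = build_dataset(trajectories, resolution, n_total, **dataset_kwargs)
        return cls(ds, config=config)

    def fit(self) -> "A2StateResults":
        """Train one forest per target; deterministic given the config seed."""
        ds = self.dataset
        X_train = ds.features("train")
        forests: dict[str, RandomForestClassifier] = {}
        for i, target in enumerate(self.targets):
            y = ds.response(target, "train")
            if len(np.unique(y)) < 2:
                raise ValueError(
                    f"training response {target!r} has a single class; "
                    "simulate longer or sample more densely so both A2 states occur"
                )
            clf = RandomForestClassifier(
                n_estimators=self.config.n_trees,
                criterion="gini",
                max_features=self.config.max_features,
                bootstrap=self.config.bootstrap,
                random_state=self.config.seed + i,
                n_jobs=1,
            )
            clf.fit(X_train, y)
            forests[target] = clf
        return A2StateResults(self, forests)


class A2StateResults:
    """Fitted forests plus evaluation and importance accessors."""

    def __init__(self, model: A2StateModel, forests: Mapping[str, RandomForestClassifier]):
        self.model = model
        self.forests = dict(forests)
        self._recalls: dict[str, tuple[float, float]] | None = None

    @property
    def dataset(self) -> Dataset:
        return self.model.dataset

    def predict(self, target: str, X: np.ndarray) -> np.ndarray:
        return self.forests[target].predict(np.asarray(X))

    def recall(self, target: str) -> tuple[float, float]:
        """(folded, unfolded) recall of ``target``'s forest on the test split."""
        return self.performance()[target]

    def performance(self) -> dict[str, tuple[float, float]]:
        if self._recalls is None:
            ds = self.dataset
            X_test = ds.features("test")
            self._recalls = {}
            for target, clf in self.forests.items():
                y_pred = clf.predict(X_test)
                self._recalls[target] = per_class_recall(
                    ds.response(target, "test"), y_pred
                )
        return self._recalls

    def performance_report(self) -> pd.DataFrame:
        """Per-segment folded/unfolded test recalls, one row per class."""
        perf = self.performance()
        return pd.DataFrame(
            {t: {"folded": perf[t][0], "unfolded": perf[t][1]} for t in self.forests}
        ).T.rename_axis("target")

    # -- importances --------------------------------------------------
    def raw_importances(self, target: str) -> np.ndarray:
        """Mean-decrease-in-impurity importance per model input (sums to 1)."""
        return self.forests[target].feature_importances_

    def importance_report(self, target: str) -> pd.Series:
        """Importance aggregated to reported feature indices."""
        return _imp.aggregate_reported_indices(
            self.raw_importances(target), self.dataset.reported_indices
        )

    def top_k_cumulative(self, target: str, k: int = 14) -> float:
        report = self.importance_report(target)
        return _imp.top_k_cumulative(report, min(k, len(report)))

    def position_profile(self, target: str, axis) -> np.ndarray:
        n_beads = (len(self.dataset.reported_indices)
                   - 17 * self.dataset.resolution) // 3
        return _imp.position_profile(self.raw_importances(target), axis, n_beads)

    def ranked_features(self, target: str, k: int = 14) -> pd.DataFrame:
        target_segment = int(target[3:]) if target.startswith("y_s") else None
        return _imp.rank_with_segment_origin(
            self.importance_report(target),
            self.dataset.resolution,
            target_segment=target_segment,
        ).head(k)

    def summary(self) -> str:
        """Human-readable per-segment performance and importance summary."""
        ds = self.dataset
        lines = [
            "A2 domain state prediction (random forest)",
            "=" * 58,
            f"resolution: {ds.resolution} segment(s)   observations: {len(ds)}"
            f" (train {int(ds.rows('train').sum())} / test {int(ds.rows('test').sum())})",
            f"trees per forest: {self.model.config.n_trees}   "
            f"model inputs: {ds.X.shape[1]}   reported indices: "
            f"{int(ds.reported_indices.max())}",
            "-" * 58,
            f"{'target':<10}{'folded recall':>15}{'unfolded recall':>17}"
            f"{'top-14 cum.':>14}",
        ]
        for t in self.forests:
            fr, ur = self.recall(t)
            lines.append(
                f"{t:<10}{fr:>15.3f}{ur:>17.3f}{self.top_k_cumulative(t):>14.3f}"
            )
        lines.append("-" * 58)
        return "\n".join(lines)
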