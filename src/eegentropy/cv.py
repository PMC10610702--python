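"""Two-stage repeated stratified K-fold evaluation of a support-vector classifier.

Stage 1 selects SVC hyperparameters by mean validation accuracy over
N_stage1 × K fits; stage 2 re-evaluates the chosen setting on N_stage2 fresh
partitions (disjoint seed stream) and reports the mean validation accuracy
A_RKF over those folds (E_RKF = 1 − A_RKF).  Features are z-scored inside each
fold with statistics fitted on the training folds only — the scaler lives in
the same sklearn Pipeline as the classifier, so no test-fold information can
leak into standardization.

``split_unit='segment'`` stratifies at the segment level (the reference
protocol, where segments of one subject may straddle train/validation — a
known optimism source); ``'subject'`` keeps all segments of a subject in one
fold via grouped stratification.

The model-object surface: build :class:`EntropyClassifier` from a
:class:`~eegentropy.features.FeatureMatrix` (or a tidy DataFrame) and call
``fit()`` for a :class:`ClassificationResults` with estimates, per-repeat
dispersion and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedGroupKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .exceptions import InvalidArgumentError, ProtocolError
from .features import FeatureMatrix

__all__ = [
    "CVProtocol",
    "ClassificationResults",
    "EntropyClassifier",
    "default_svc_grid",
    "stage1_select",
    "stage2_arkf",
    "iter_splits",
    "fold_train_statistics",
]


@dataclass(frozen=True)
class CVProtocol:
    """Partitioning scheme of the two-stage repeated K-fold protocol."""

    K: int = 10
    n_stage1: int = 10
    n_stage2: int = 30
    seed_stage1: int = 101
    seed_stage2: int = 202
    split_unit: str = "segment"

    def __post_init__(self) -> None:
        if self.K < 2:
            raise InvalidArgumentError("K must be at least 2")
        if self.n_stage1 < 1 or self.n_stage2 < 1:
            raise InvalidArgumentError("repeat counts must be positive")
        if self.seed_stage1 == self.seed_stage2:
            raise InvalidArgumentError(
                "stage-1 and stage-2 seeds must differ (disjoint repeat streams)"
            )
        if self.split_unit not in ("segment", "subject"):
            raise InvalidArgumentError("split_unit must be 'segment' or 'subject'")

    def reduced(self, n_stage2: int = 5) -> "CVProtocol":
        return replace(self, n_stage2=n_stage2)


def default_svc_grid() -> list[dict]:
    """Compact SVC grid, ordered simplest-first (linear before RBF, small C
    first) so ties in stage 1 resolve toward parsimony."""
    grid: list[dict] = []
    for c in (0.1, 1.0, 10.0, 100.0):
        grid.append({"kernel": "linear", "C": c})
    for c in (0.1, 1.0, 10.0, 100.0):
        for gamma in ("scale", 0.01, 0.1):
            grid.append({"kernel": "rbf", "C": c, "gamma": gamma})
    return grid


def _make_pipeline(params: dict) -> Pipeline:
    return Pipeline([
        ("scale", StandardScaler()),
        ("svc", SVC(**params)),
    ])


def _check_protocol(labels: np.ndarray, protocol: CVProtocol) -> None:
    _, counts = np.unique(labels, return_counts=True)
    if len(counts) < 2:
        raise ProtocolError("need at least two classes")
    if counts.min() < protocol.K:
        raise ProtocolError(
            f"smallest class has {counts.min()} samples, fewer than K={protocol.K}"
        )


def iter_splits(
    labels: np.ndarray,
    protocol: CVProtocol,
    stage: int,
    groups: np.ndarray | None = None,
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield (train_idx, val_idx) over all repeats of the given stage."""
    if stage == 1:
        seed, repeats = protocol.seed_stage1, protocol.n_stage1
    elif stage == 2:
        seed, repeats = protocol.seed_stage2, protocol.n_stage2
    else:
        raise InvalidArgumentError("stage must be 1 or 2")
    x_dummy = np.zeros((len(labels), 1))
    if protocol.split_unit == "segment":
        splitter = RepeatedStratifiedKFold(
            n_splits=protocol.K, n_repeats=repeats, random_state=seed
        )
        yield from splitter.split(x_dummy, labels)
    else:
        if groups is None:
            raise InvalidArgumentError("subject-level splitting needs groups")
        for rep in range(repeats):
            gkf = StratifiedGroupKFold(
                n_splits=protocol.K, shuffle=True, random_state=seed + rep
            )
            yield from gkf.split(x_dummy, labels, groups)


def _fold_accuracies(
    fm: FeatureMatrix,
    params: dict,
    protocol: CVProtocol,
    stage: int,
) -> np.ndarray:
    x, y = fm.values, fm.labels
    accs = []
    for train, val in iter_splits(y, protocol, stage, groups=fm.groups):
        if len(np.unique(y[train])) < 2:
            raise ProtocolError("a training fold contains a single class")
        pipe = _make_pipeline(params)
        pipe.fit(x[train], y[train])
        accs.append(float(pipe.score(x[val], y[val])))
    return np.asarray(accs)


def stage1_select(
    fm: FeatureMatrix,
    grid: Sequence[dict] | None = None,
    protocol: CVProtocol = CVProtocol(),
) -> tuple[dict, pd.DataFrame]:
    """Pick the grid point with maximal stage-1 mean validation accuracy.

    Returns (chosen params, per-candidate score table).  Ties resolve to the
    earliest candidate in the grid's simplest-first ordering.
    """
    grid = list(grid) if grid is not None else default_svc_grid()
    if not grid:
        raise InvalidArgumentError("hyperparameter grid must be non-empty")
    _check_protocol(fm.labels, protocol)
    rows = []
    best_params, best_score = None, -np.inf
    for params in grid:
        score = float(_fold_accuracies(fm, params, protocol, stage=1).mean())
        rows.append({**params, "stage1_accuracy": score})
        if score > best_score:
            best_params, best_score = params, score
    table = pd.DataFrame(rows)
    return dict(best_params), table


def stage2_arkf(
    fm: FeatureMatrix,
    hyperparams: dict,
    protocol: CVProtocol = CVProtocol(),
) -> "ClassificationResults":
    """Evaluate fixed hyperparameters on the stage-2 partitions → A_RKF."""
    _check_protocol(fm.labels, protocol)
    fold_acc = _fold_accuracies(fm, hyperparams, protocol, stage=2)
    per_repeat = fold_acc.reshape(-1, protocol.K).mean(axis=1)
    a_rkf = float(fold_acc.mean())
    return ClassificationResults(
        A_RKF=a_rkf,
        E_RKF=1.0 - a_rkf,
        per_repeat_acc=per_repeat,
        fold_acc=fold_acc,
        chosen_hyperparams=dict(hyperparams),
        protocol=protocol,
        n_obs=fm.n_obs,
        n_features=fm.n_features,
    )


def fold_train_statistics(
    fm: FeatureMatrix,
    protocol: CVProtocol,
    stage: int = 2,
    max_folds: int | None = None,
) -> list[dict]:
    """Per-fold standardization statistics as actually fitted by the pipeline.

    Exposed for leakage auditing: each entry carries the train/validation
    indices and the scaler mean/scale fitted on the training rows.
    """
    out = []
    for i, (train, val) in enumerate(
        iter_splits(fm.labels, protocol, stage, groups=fm.groups)
    ):
        if max_folds is not None and i >= max_folds:
            break
        pipe = _make_pipeline({"kernel": "linear", "C": 1.0})
        pipe.fit(fm.values[train], fm.labels[train])
        scaler: StandardScaler = pipe.named_steps["scale"]
        out.append({
            "train_idx": train,
            "val_idx": val,
            "mean": scaler.mean_.copy(),
            "scale": scaler.scale_.copy(),
        })
    return out


@dataclass
class ClassificationResults:
    """Outcome of a stage-2 evaluation (and optionally stage-1 selection)."""

    A_RKF: float
    E_RKF: float
    per_repeat_acc: np.ndarray
    fold_acc: np.ndarray
    chosen_hyperparams: dict
    protocol: CVProtocol
    n_obs: int
    n_features: int
    stage1_table: pd.DataFrame | None = field(default=None, repr=False)

    def summary(self) -> str:
        hp = ", ".join(f"{k}={v}" for k, v in sorted(self.chosen_hyperparams.items()))
        sd = float(self.per_repeat_acc.std(ddof=1)) if len(self.per_repeat_acc) > 1 else 0.0
        lines = [
            "Repeated stratified K-fold SVC evaluation",
            "=" * 57,
            f"observations:        {self.n_obs:>6d}    features: {self.n_features}",
            f"protocol:            K={self.protocol.K}, N1={self.protocol.n_stage1}, "
            f"N2={self.protocol.n_stage2}, split_unit={self.protocol.split_unit}",
            f"chosen SVC:          {hp}",
            f"A_RKF:               {self.A_RKF:.4f}  ({self.A_RKF * 100:.2f}%)",
            f"E_RKF:               {self.E_RKF:.4f}",
            f"per-repeat acc:      mean {self.per_repeat_acc.mean():.4f}, "
            f"sd {sd:.4f}, range [{self.per_repeat_acc.min():.4f}, "
            f"{self.per_repeat_acc.max():.4f}]",
            "=" * 57,
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "A_RKF": self.A_RKF,
            "E_RKF": self.E_RKF,
            "per_repeat_acc": [float(a) for a in self.per_repeat_acc],
            "chosen_hyperparams": {
                k: (v if isinstance(v, str) else float(v))
                for k, v in self.chosen_hyperparams.items()
            },
            "protocol": {
                "K": self.protocol.K,
                "n_stage1": self.protocol.n_stage1,
                "n_stage2": self.protocol.n_stage2,
                "seed_stage1": self.protocol.seed_stage1,
                "seed_stage2": self.protocol.seed_stage2,
                "split_unit": self.protocol.split_unit,
            },
            "n_obs": self.n_obs,
            "n_features": self.n_features,
        }

    def plot_repeats(self, ax=None):
        """Histogram of per-repeat accuracies."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.per_repeat_acc, bins="sturges", color="steelblue",
                edgecolor="black")
        ax.axvline(self.A_RKF, color="crimson", label=f"A_RKF={self.A_RKF:.3f}")
        ax.set_xlabel("validation accuracy per repeat")
        ax.set_ylabel("repeats")
        ax.legend()
        return ax


class EntropyClassifier:
    """SVC-based two-class model over an entropy feature matrix.

    Parameters
    ----------
    features
        The segments × features matrix with labels and subject groups.
    protocol
        The repeated K-fold protocol; defaults to K=10, N1=10, N2=30.
    svc_grid
        Stage-1 candidate hyperparameters (simplest-first ordering).
    """

    def __init__(
        self,
        features: FeatureMatrix,
        protocol: CVProtocol | None = None,
        svc_grid: Sequence[dict] | None = None,
    ) -> None:
        self.features = features
        self.protocol = protocol or CVProtocol()
        self.svc_grid = list(svc_grid) if svc_grid is not None else default_svc_grid()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        protocol: CVProtocol | None = None,
        svc_grid: Sequence[dict] | None = None,
    ) -> "EntropyClassifier":
        return cls(FeatureMatrix.from_frame(df), protocol=protocol, svc_grid=svc_grid)

    def fit(self) -> ClassificationResults:
        """Stage-1 hyperparameter selection followed by stage-2 A_RKF."""
        params, table = stage1_select(self.features, self.svc_grid, self.protocol)
        results = stage2_arkf(self.features, params, self.protocol)
        results.stage1_table = table
        return results

    def select_features(
        self,
        max_k: int,
        hyperparams: dict | None = None,
        search_n_stage2: int = 5,
    ):
        """Greedy forward selection (delegates to
        :func:`eegentropy.selection.greedy_forward`)."""
        from .selection import greedy_forward

        if hyperparams is None:
            hyperparams, _ = stage1_select(self.features, self.svc_grid, self.protocol)
        return greedy_forward(
            self.features, self.protocol, hyperparams, max_k,
            search_n_stage2=search_n_stage2,
        )
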