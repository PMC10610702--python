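"""Greedy forward feature selection on A_RKF.

Step 1 keeps the single feature with the highest A_RKF; each later step tries
every remaining feature appended to the current set and keeps the argmax.
Inside the search A_RKF is evaluated on a reduced protocol (fewer stage-2
repeats) for tractability — the search is O(F^2) cross-validation runs — and
the reported curve is then re-evaluated at the full protocol.  Ties break by
lexicographic feature name, making the trace deterministic and invariant to
column permutations on tie-free inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cv import CVProtocol, stage2_arkf
from .exceptions import InvalidArgumentError
from .features import FeatureMatrix

__all__ = ["SelectionTrace", "ReducedModel", "greedy_forward", "reduced_model_report"]


@dataclass
class SelectionTrace:
    """Ordered greedy steps: (feature added, A_RKF of the set so far)."""

    steps: list[tuple[str, float]]
    protocol: CVProtocol
    hyperparams: dict

    @property
    def feature_names(self) -> list[str]:
        return [name for name, _ in self.steps]

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([a for _, a in self.steps])

    def running_max(self) -> np.ndarray:
        return np.maximum.accumulate(self.accuracies)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": np.arange(1, len(self.steps) + 1),
                "feature": self.feature_names,
                "arkf": self.accuracies,
            }
        )

    def plot(self, ax=None):
        """Accuracy-vs-feature-count curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        k = np.arange(1, len(self.steps) + 1)
        ax.plot(k, self.accuracies, "o-", color="steelblue")
        ax.set_xlabel("number of features")
        ax.set_ylabel("A_RKF")
        return ax


@dataclass
class ReducedModel:
    best_k: int
    features: list[str]
    arkf: float
    reached: bool  # False when no k met the tolerance and max_k was returned


def greedy_forward(
    fm: FeatureMatrix,
    protocol: CVProtocol,
    hyperparams: dict,
    max_k: int,
    search_n_stage2: int = 5,
) -> SelectionTrace:
    """Greedy forward selection of up to ``max_k`` features."""
    if not 1 <= max_k <= fm.n_features:
        raise InvalidArgumentError(
            f"max_k must lie in [1, {fm.n_features}], got {max_k}"
        )
    search_protocol = protocol.reduced(search_n_stage2)
    selected: list[str] = []
    remaining = list(fm.feature_names)
    search_steps: list[str] = []
    for _ in range(max_k):
        best_name, best_score = None, -np.inf
        for name in remaining:
            sub = fm.select(selected + [name])
            score = stage2_arkf(sub, hyperparams, search_protocol).A_RKF
            if score > best_score or (score == best_score and name < best_name):
                best_name, best_score = name, score
        selected.append(best_name)
        remaining.remove(best_name)
        search_steps.append(best_name)
    # Re-evaluate the nested feature sets at the full protocol for reporting.
    steps = []
    for k in range(1, len(search_steps) + 1):
        sub = fm.select(search_steps[:k])
        steps.append((search_steps[k - 1],
                      stage2_arkf(sub, hyperparams, protocol).A_RKF))
    return SelectionTrace(steps=steps, protocol=protocol, hyperparams=dict(hyperparams))


def reduced_model_report(
    trace: SelectionTrace,
    full_arkf: float,
    tol: float = 0.001,
) -> ReducedModel:
    """Smallest k whose A_RKF is within ``tol`` of the full-feature A_RKF."""
    if not trace.steps:
        raise InvalidArgumentError("selection trace is empty")
    target = full_arkf - tol
    for k, (_, arkf) in enumerate(trace.steps, start=1):
        if arkf >= target:
            return ReducedModel(
                best_k=k,
                features=trace.feature_names[:k],
                arkf=arkf,
                reached=True,
            )
    k = len(trace.steps)
    return ReducedModel(
        best_k=k,
        features=trace.feature_names,
        arkf=trace.accuracies[-1],
        reached=False,
    )
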