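"""Ensemble out-of-bag permutation importance for feature components.

Each round draws a stratified 70% training subsample; the rest is the
out-of-bag (OOB) block.  Seven base classifiers are fitted on the training
block and the most accurate on the OOB block is kept (score_1).  Shuffling
one feature column within the OOB block — a permutation, so the column's
marginal distribution is untouched — and re-predicting with the already
fitted model gives score_2, and the component's importance that round is
imp = score_1 - score_2.  Importances are averaged over n rounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .seq_io import FeatureMatrix

#: Roster order; earlier wins accuracy ties in fit_best.
LEARNER_ROSTER = ("LDA", "DTC", "KNN", "SVM", "LR", "GNB", "MLP")

#: Learners whose geometry is scale-sensitive get a train-fitted
#: standardiser; trees and naive Bayes see raw values.
_SCALED = frozenset({"LDA", "KNN", "SVM", "LR", "MLP"})

_SEED_MOD = 2**31


@dataclass(frozen=True)
class EnsembleSpec:
    """The seven-learner roster and its (near-default) settings.

    All learners run at their library defaults except the MLP iteration cap
    of 1000.  ``scale=False`` disables standardisation everywhere,
    reproducing a literal default-parameter run.
    """

    roster: tuple[str, ...] = LEARNER_ROSTER
    mlp_max_iter: int = 1000
    scale: bool = True

    def __post_init__(self) -> None:
        if len(set(self.roster)) != len(self.roster):
            raise ValueError("duplicate learner kinds in roster")
        unknown = set(self.roster) - set(LEARNER_ROSTER)
        if unknown:
            raise ValueError(f"unknown learner kinds: {sorted(unknown)}")

    def settings(self) -> dict:
        return {
            "roster": list(self.roster),
            "mlp_max_iter": self.mlp_max_iter,
            "scale": self.scale,
        }


def build_learner(kind: str, spec: EnsembleSpec, random_state: int):
    """One fresh, unfitted classifier of the given kind."""
    if kind == "LDA":
        est = LinearDiscriminantAnalysis()
    elif kind == "DTC":
        est = DecisionTreeClassifier(random_state=random_state)
    elif kind == "KNN":
        est = KNeighborsClassifier()
    elif kind == "SVM":
        est = SVC(random_state=random_state)
    elif kind == "LR":
        est = LogisticRegression(random_state=random_state)
    elif kind == "GNB":
        est = GaussianNB()
    elif kind == "MLP":
        est = MLPClassifier(
            max_iter=spec.mlp_max_iter, random_state=random_state
        )
    else:
        raise ValueError(f"unknown learner kind {kind!r}")
    if spec.scale and kind in _SCALED:
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


def fit_best(
    train_X: np.ndarray,
    train_y: np.ndarray,
    holdout_X: np.ndarray,
    holdout_y: np.ndarray,
    spec: EnsembleSpec | None = None,
    random_state: int = 0,
):
    """Fit every roster learner on train and keep the holdout-accuracy winner.

    Returns ``(kind, fitted_model, holdout_accuracy)``; accuracy ties are
    broken by roster order.  Raises if the training block is single-class.
    """
    spec = spec or EnsembleSpec()
    if len(np.unique(train_y)) < 2:
        raise ValueError("training data contains a single class")
    best = None
    for kind in spec.roster:
        model = build_learner(kind, spec, random_state)
        model.fit(train_X, train_y)
        acc = accuracy_score(holdout_y, model.predict(holdout_X))
        if best is None or acc > best[2]:
            best = (kind, model, acc)
    assert best is not None
    return best


@dataclass
class ImportanceTable:
    """Per-component importance: mean over rounds plus the per-round scores."""

    names: list[str]
    per_round: np.ndarray  # (rounds, n_components)
    rounds: int
    seed: int
    chosen_learners: list[str] = field(default_factory=list)
    round_scores: list[float] = field(default_factory=list)  # score_1 per round

    def __post_init__(self) -> None:
        self.per_round = np.asarray(self.per_round, dtype=float)
        if self.per_round.shape != (self.rounds, len(self.names)):
            raise ValueError(
                f"per-round block {self.per_round.shape} does not match "
                f"({self.rounds}, {len(self.names)})"
            )

    @property
    def mean(self) -> np.ndarray:
        return self.per_round.mean(axis=0)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "component": self.names,
                "mean_importance": self.mean,
            }
        )
        for r in range(self.rounds):
            df[f"round_{r}"] = self.per_round[r]
        with Path(path).open("w") as fh:
            fh.write(f"# rounds={self.rounds} seed={self.seed}\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.17g")

    @staticmethod
    def from_tsv(path: str | Path) -> "ImportanceTable":
        text = Path(path).read_text().splitlines()
        meta = dict(
            kv.split("=") for kv in text[0].lstrip("# ").split()
        )
        df = pd.read_csv(Path(path), sep="\t", comment="#")
        rounds = int(meta["rounds"])
        per_round = df[[f"round_{r}" for r in range(rounds)]].to_numpy().T
        return ImportanceTable(
            names=[str(c) for c in df["component"]],
            per_round=per_round,
            rounds=rounds,
            seed=int(meta["seed"]),
        )


def _stratified_split(
    labels: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class random split without replacement; both parts non-empty."""
    train_idx: list[np.ndarray] = []
    oob_idx: list[np.ndarray] = []
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        n_train = int(round(fraction * members.size))
        n_train = min(max(n_train, 1), members.size - 1) if members.size > 1 else n_train
        perm = rng.permutation(members)
        train_idx.append(perm[:n_train])
        oob_idx.append(perm[n_train:])
    tr = np.sort(np.concatenate(train_idx))
    ob = np.sort(np.concatenate(oob_idx))
    if ob.size == 0:
        raise ValueError(
            f"subsample fraction {fraction} leaves an empty out-of-bag set"
        )
    return tr, ob


def permutation_importance(
    data: FeatureMatrix,
    spec: EnsembleSpec | None = None,
    rounds: int = 100,
    subsample: float = 0.7,
    seed: int = 0,
) -> ImportanceTable:
    """Mean OOB permutation importance of every component over n rounds.

    Per round the permutation is applied to one column of the OOB block at
    a time; the fitted model is never retrained, so a round costs one
    ensemble fit plus one prediction per component.  Per-round seeds are
    derived deterministically from the master seed (seed + round index),
    making the whole table reproducible.
    """
    spec = spec or EnsembleSpec()
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if not 0 < subsample < 1:
        raise ValueError("subsample fraction must lie in (0, 1)")
    labels = data.labels
    for cls in (0, 1):
        if np.sum(labels == cls) < 2:
            raise ValueError(f"need >= 2 samples of class {cls}")

    m = data.n_components
    per_round = np.empty((rounds, m))
    chosen: list[str] = []
    score1s: list[float] = []
    X = data.values
    for r in range(rounds):
        round_seed = (seed + r) % _SEED_MOD
        rng = np.random.default_rng(round_seed)
        tr, ob = _stratified_split(labels, subsample, rng)
        kind, model, score1 = fit_best(
            X[tr], labels[tr], X[ob], labels[ob], spec, random_state=round_seed
        )
        chosen.append(kind)
        score1s.append(score1)
        oob_X = X[ob].copy()
        oob_y = labels[ob]
        for j in range(m):
            original = oob_X[:, j].copy()
            oob_X[:, j] = original[rng.permutation(original.size)]
            score2 = accuracy_score(oob_y, model.predict(oob_X))
            per_round[r, j] = score1 - score2
            oob_X[:, j] = original
    return ImportanceTable(
        names=list(data.names),
        per_round=per_round,
        rounds=rounds,
        seed=seed,
        chosen_learners=chosen,
        round_scores=score1s,
    )
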