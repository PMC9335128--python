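"""Incremental feature-subset selection and the two-stage pipeline.

Components are ranked by mean permutation importance and added one at a
time; each prefix is scored by stratified k-fold cross-validated accuracy
(within each fold the seven-learner ensemble is fitted on the training
folds and the most accurate learner scored on the held-out fold).  The
chosen subset is the smallest prefix whose mean accuracy reaches the curve
maximum (optionally within a tolerance, trading a little accuracy for
fewer components).

The full pipeline runs this per encoder (stage 1), concatenates the chosen
per-encoder subsets, rescores importance and reselects on the concatenation
(stage 2), then fits a final classifier — chosen by inner cross-validated
accuracy on the training set — on the final subset and evaluates it on the
independent test set (stage 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score
from sklearn.model_selection import StratifiedKFold

from .encoders import GroupingTable, encode_dataset
from .importance import (
    EnsembleSpec,
    ImportanceTable,
    build_learner,
    fit_best,
    permutation_importance,
)
from .metrics import EvalReport, decision_scores, evaluate
from .seq_io import FeatureMatrix, LabeledDataset

_SEED_MOD = 2**31


@dataclass
class SelectionResult:
    """Importance-ranked names, the CV accuracy curve, and the chosen prefix."""

    ranked_names: list[str]
    mean_curve: np.ndarray  # mean CV accuracy at prefix sizes 1..M
    fold_curves: np.ndarray  # (folds, M) per-fold accuracies
    chosen_size: int
    folds: int
    seed: int
    tolerance: float = 0.0

    def __post_init__(self) -> None:
        self.mean_curve = np.asarray(self.mean_curve, dtype=float)
        if self.mean_curve.shape[0] != len(self.ranked_names):
            raise ValueError("curve length must equal number of ranked names")

    @property
    def chosen_names(self) -> list[str]:
        return self.ranked_names[: self.chosen_size]

    @property
    def chosen_accuracy(self) -> float:
        return float(self.mean_curve[self.chosen_size - 1])

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "prefix_size": np.arange(1, len(self.ranked_names) + 1),
                "component_added": self.ranked_names,
                "mean_accuracy": self.mean_curve,
            }
        )
        for f in range(self.folds):
            df[f"fold_{f}"] = self.fold_curves[f]
        with Path(path).open("w") as fh:
            fh.write(
                f"# folds={self.folds} seed={self.seed} "
                f"tolerance={self.tolerance} chosen_size={self.chosen_size}\n"
            )
            df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def rank_components(imp: ImportanceTable) -> list[str]:
    """Names sorted by mean importance, descending; ties keep column order."""
    if not imp.names:
        raise ValueError("empty importance table")
    order = np.argsort(-imp.mean, kind="stable")
    return [imp.names[i] for i in order]


def incremental_select(
    data: FeatureMatrix,
    ranked: Sequence[str],
    folds: int = 10,
    spec: EnsembleSpec | None = None,
    seed: int = 0,
    tolerance: float = 0.0,
    max_prefix: int | None = None,
) -> SelectionResult:
    """CV accuracy of each importance-ranked prefix; pick the smallest best.

    ``max_prefix`` caps the curve length (prefixes beyond it are not
    evaluated), useful when the ranked list is long and the accuracy
    plateau is known to come early.
    """
    spec = spec or EnsembleSpec()
    if folds < 2:
        raise ValueError("folds must be >= 2")
    for cls in (0, 1):
        n_cls = int(np.sum(data.labels == cls))
        if n_cls < folds:
            raise ValueError(
                f"class {cls} has only {n_cls} samples; "
                f"use a fold count <= {n_cls}"
            )
    ranked = list(ranked)
    if max_prefix is not None:
        ranked = ranked[:max_prefix]
    M = len(ranked)
    X_full = data.subset(ranked).values
    y = data.labels
    skf = StratifiedKFold(
        n_splits=folds, shuffle=True, random_state=seed % _SEED_MOD
    )
    splits = list(skf.split(X_full, y))
    fold_curves = np.empty((folds, M))
    for m in range(1, M + 1):
        X = X_full[:, :m]
        for f, (tr, te) in enumerate(splits):
            _, _, acc = fit_best(
                X[tr], y[tr], X[te], y[te], spec,
                random_state=(seed + f) % _SEED_MOD,
            )
            fold_curves[f, m - 1] = acc
    mean_curve = fold_curves.mean(axis=0)
    best = mean_curve.max()
    chosen = int(np.argmax(mean_curve >= best - tolerance)) + 1
    return SelectionResult(
        ranked_names=ranked,
        mean_curve=mean_curve,
        fold_curves=fold_curves,
        chosen_size=chosen,
        folds=folds,
        seed=seed,
        tolerance=tolerance,
    )


def select_final_classifier(
    data: FeatureMatrix,
    spec: EnsembleSpec | None = None,
    folds: int = 10,
    seed: int = 0,
):
    """Pick the roster learner with the best inner-CV accuracy; fit on all.

    Returns ``(kind, fitted_model, mean_cv_accuracy)``.  Ties are broken
    by roster order.
    """
    spec = spec or EnsembleSpec()
    y = data.labels
    X = data.values
    skf = StratifiedKFold(
        n_splits=folds, shuffle=True, random_state=seed % _SEED_MOD
    )
    splits = list(skf.split(X, y))
    best_kind, best_acc = None, -1.0
    for kind in spec.roster:
        accs = []
        for f, (tr, te) in enumerate(splits):
            model = build_learner(kind, spec, (seed + f) % _SEED_MOD)
            model.fit(X[tr], y[tr])
            accs.append(accuracy_score(y[te], model.predict(X[te])))
        mean_acc = float(np.mean(accs))
        if mean_acc > best_acc:
            best_kind, best_acc = kind, mean_acc
    assert best_kind is not None
    final = build_learner(best_kind, spec, seed % _SEED_MOD)
    final.fit(X, y)
    return best_kind, final, best_acc


@dataclass
class StageResult:
    importance: ImportanceTable
    selection: SelectionResult


@dataclass
class PipelineResult:
    """All artefacts of a two-stage select-and-predict run."""

    stage1: dict[str, StageResult]
    stage2: StageResult
    final_subset: list[str]
    final_classifier: str
    final_cv_accuracy: float
    report: EvalReport
    baseline_report: EvalReport | None = None
    settings: dict = field(default_factory=dict)


def run_pipeline(
    train: LabeledDataset,
    test: LabeledDataset,
    encoders: Sequence[str] = ("aac", "ctd", "cksaap", "rpssm"),
    *,
    k: int = 1,
    groups: GroupingTable | None = None,
    pssm_dir: str | Path | None = None,
    spec: EnsembleSpec | None = None,
    rounds: int = 100,
    subsample: float = 0.7,
    folds: int = 10,
    tolerance: float = 0.0,
    seed: int = 0,
    max_prefix: int | None = None,
    skip_selection: bool = False,
    baseline: bool = False,
) -> PipelineResult:
    """The full concatenate-and-reselect pipeline on a train/test split.

    With ``skip_selection=True`` the full encodings are concatenated with
    no per-encoder selection and stage 2 operates on that concatenation
    directly (the all-features route).  ``baseline=True`` additionally
    evaluates an inner-CV-chosen classifier on the full concatenated
    encodings, for comparison against the selected subset.
    """
    spec = spec or EnsembleSpec()
    enc_kwargs = dict(k=k, groups=groups, pssm_dir=pssm_dir)
    train_parts = {
        e: encode_dataset(train, e, **enc_kwargs) for e in encoders
    }
    test_parts = {e: encode_dataset(test, e, **enc_kwargs) for e in encoders}

    stage1: dict[str, StageResult] = {}
    chosen_parts: list[FeatureMatrix] = []
    for i, enc in enumerate(encoders):
        mat = train_parts[enc]
        stage_seed = (seed + 1000 * (i + 1)) % _SEED_MOD
        if skip_selection:
            chosen_parts.append(mat)
            continue
        try:
            imp = permutation_importance(
                mat, spec, rounds=rounds, subsample=subsample, seed=stage_seed
            )
            ranked = rank_components(imp)
            sel = incremental_select(
                mat, ranked, folds=folds, spec=spec, seed=stage_seed,
                tolerance=tolerance, max_prefix=max_prefix,
            )
        except ValueError as exc:
            raise ValueError(f"stage 1 ({enc}): {exc}") from exc
        stage1[enc] = StageResult(imp, sel)
        chosen_parts.append(mat.subset(sel.chosen_names))

    concat = FeatureMatrix.concat(chosen_parts)
    stage2_seed = (seed + 777_000) % _SEED_MOD
    try:
        imp2 = permutation_importance(
            concat, spec, rounds=rounds, subsample=subsample, seed=stage2_seed
        )
        ranked2 = rank_components(imp2)
        sel2 = incremental_select(
            concat, ranked2, folds=folds, spec=spec, seed=stage2_seed,
            tolerance=tolerance, max_prefix=max_prefix,
        )
    except ValueError as exc:
        raise ValueError(f"stage 2 (concatenation): {exc}") from exc
    final_subset = sel2.chosen_names

    train_final = concat.subset(final_subset)
    test_concat = FeatureMatrix.concat(
        [test_parts[e] for e in encoders]
    )
    test_final = test_concat.subset(final_subset)
    try:
        kind, model, cv_acc = select_final_classifier(
            train_final, spec, folds=folds, seed=seed
        )
    except ValueError as exc:
        raise ValueError(f"stage 3 (final fit): {exc}") from exc
    pred = model.predict(test_final.values)
    scores = decision_scores(model, test_final.values)
    report = evaluate(pred, test_final.labels, scores)

    baseline_report = None
    if baseline:
        train_all = FeatureMatrix.concat(list(train_parts.values()))
        _, base_model, _ = select_final_classifier(
            train_all, spec, folds=folds, seed=seed
        )
        base_pred = base_model.predict(test_concat.values)
        baseline_report = evaluate(
            base_pred, test_concat.labels,
            decision_scores(base_model, test_concat.values),
        )

    settings = {
        "encoders": list(encoders),
        "k": k,
        "rounds": rounds,
        "subsample": subsample,
        "folds": folds,
        "tolerance": tolerance,
        "seed": seed,
        "max_prefix": max_prefix,
        "skip_selection": skip_selection,
        **spec.settings(),
    }
    return PipelineResult(
        stage1=stage1,
        stage2=StageResult(imp2, sel2),
        final_subset=final_subset,
        final_classifier=kind,
        final_cv_accuracy=cv_acc,
        report=report,
        baseline_report=baseline_report,
        settings=settings,
    )
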