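import numpy as np
import pytest
from sklearn.metrics import accuracy_score

import phagefs as pf
from phagefs.importance import (
    LEARNER_ROSTER,
    build_learner,
    fit_best,
    permutation_importance,
)


def separable_matrix(n=20, noise_cols=3, seed=0):
    """One threshold-separable column plus label-independent noise."""
    rng = np.random.default_rng(seed)
    labels = np.repeat([0, 1], n // 2)
    signal = labels * 2.0 + rng.normal(scale=0.1, size=n)
    noise = rng.normal(size=(n, noise_cols))
    return pf.FeatureMatrix(
        names=["signal"] + [f"noise{i}" for i in range(noise_cols)],
        values=np.column_stack([signal, noise]),
        labels=labels,
    )


class TestEnsembleSpec:
    def test_duplicate_roster_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            pf.EnsembleSpec(roster=("LDA", "LDA"))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            pf.EnsembleSpec(roster=("LDA", "RF"))


class TestFitBest:
    def test_separable_data_reaches_perfect_accuracy(self):
        mat = separable_matrix()
        kind, model, acc = fit_best(
            mat.values, mat.labels, mat.values, mat.labels
        )
        assert acc == 1.0

    def test_tie_broken_by_roster_order(self):
        # recompute every learner's holdout accuracy independently and
        # check the returned kind is the first argmax in roster order
        mat = separable_matrix(n=16, seed=3)
        tr = np.arange(0, 16, 2)
        ho = np.arange(1, 16, 2)
        spec = pf.EnsembleSpec()
        accs = {}
        for kind in LEARNER_ROSTER:
            m = build_learner(kind, spec, 0)
            m.fit(mat.values[tr], mat.labels[tr])
            accs[kind] = accuracy_score(
                mat.labels[ho], m.predict(mat.values[ho])
            )
        expected = max(LEARNER_ROSTER, key=lambda k: (accs[k], ))
        first_argmax = next(
            k for k in LEARNER_ROSTER if accs[k] == accs[expected]
        )
        kind, _, acc = fit_best(
            mat.values[tr], mat.labels[tr],
            mat.values[ho], mat.labels[ho], spec, random_state=0,
        )
        assert kind == first_argmax
        assert acc == accs[first_argmax]

    def test_single_class_training_errors(self):
        mat = separable_matrix()
        with pytest.raises(ValueError, match="single class"):
            fit_best(
                mat.values[:5], np.zeros(5, int), mat.values, mat.labels
            )

    def test_single_class_holdout_is_fine(self):
        mat = separable_matrix()
        _, _, acc = fit_best(
            mat.values, mat.labels, mat.values[:5], mat.labels[:5]
        )
        assert 0.0 <= acc <= 1.0


class TestPermutationImportance:
    def test_reproducible_under_seed(self):
        mat = separable_matrix()
        a = permutation_importance(mat, rounds=3, seed=5)
        b = permutation_importance(mat, rounds=3, seed=5)
        np.testing.assert_array_equal(a.per_round, b.per_round)
        assert a.chosen_learners == b.chosen_learners

    def test_scores_bounded_and_mean_consistent(self):
        mat = separable_matrix()
        imp = permutation_importance(mat, rounds=4, seed=1)
        assert np.all(imp.per_round >= -1.0) and np.all(imp.per_round <= 1.0)
        np.testing.assert_allclose(
            imp.mean, imp.per_round.mean(axis=0), atol=1e-15
        )

    def test_constant_column_importance_exactly_zero(self):
        mat = separable_matrix()
        values = np.column_stack([mat.values, np.full(mat.n_samples, 3.0)])
        mat2 = pf.FeatureMatrix(
            names=mat.names + ["const"], values=values, labels=mat.labels
        )
        imp = permutation_importance(mat2, rounds=3, seed=2)
        const_idx = mat2.names.index("const")
        assert np.all(imp.per_round[:, const_idx] == 0.0)

    def test_separating_column_beats_noise(self):
        mat = separable_matrix(n=40, noise_cols=5, seed=4)
        imp = permutation_importance(mat, rounds=10, seed=3)
        means = dict(zip(imp.names, imp.mean))
        assert all(
            means["signal"] > means[f"noise{i}"] for i in range(5)
        )

    def test_planted_residues_rank_high(self, planted_aac):
        imp = permutation_importance(planted_aac, rounds=10, seed=0)
        top5 = [imp.names[i] for i in np.argsort(-imp.mean)[:5]]
        assert "AAC:K" in top5 and "AAC:V" in top5

    def test_planted_set_recovered_and_noise_stays_low(self, planted_aac):
        """With 2 planted components among 20, the top-2 by mean
        importance recover the planted set at 100 rounds, and every
        label-independent component's |mean| stays below 0.02."""
        imp = permutation_importance(planted_aac, rounds=100, seed=17)
        order = np.argsort(-imp.mean)
        assert {imp.names[i] for i in order[:2]} == {"AAC:K", "AAC:V"}
        noise = [
            m for n, m in zip(imp.names, imp.mean)
            if n not in ("AAC:K", "AAC:V")
        ]
        assert max(abs(m) for m in noise) < 0.02

    def test_bad_parameters_rejected(self):
        mat = separable_matrix()
        with pytest.raises(ValueError, match="rounds"):
            permutation_importance(mat, rounds=0)
        with pytest.raises(ValueError, match="fraction"):
            permutation_importance(mat, subsample=1.5)

    def test_tsv_round_trip(self, tmp_path):
        mat = separable_matrix()
        imp = permutation_importance(mat, rounds=3, seed=9)
        path = tmp_path / "imp.tsv"
        imp.to_tsv(path)
        back = pf.ImportanceTable.from_tsv(path)
        assert back.names == imp.names
        assert back.rounds == imp.rounds and back.seed == imp.seed
        np.testing.assert_allclose(back.per_round, imp.per_round, atol=1e-15)
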