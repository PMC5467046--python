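import itertools
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pssmbind.core_scoring import AMINO_ACIDS, Ic50Transform, build_pssm, score_to_ic50
from pssmbind.evaluation import (
    ConfusionCounts,
    auc,
    confusion_metrics,
    cross_validate,
    generate_nonbinders,
    kfold_split,
)
from pssmbind.exceptions import RejectionBudgetError, UndefinedMetricError
from pssmbind.synthetic_fixtures import make_motif_profile, sample_binders


def pair_counting_auc(scores, labels):
    """Exhaustive Mann-Whitney oracle: count pairs directly."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p, q in itertools.product(pos, neg):
        if p > q:
            total += 1.0
        elif p == q:
            total += 0.5
    return total / (len(pos) * len(neg))


class TestKfoldSplit:
    def test_divisible_case(self):
        folds = kfold_split(20, 10, seed=0)
        sizes = Counter(folds.assignment)
        assert sizes == {f: 2 for f in range(1, 11)}

    def test_remainder_distribution(self):
        folds = kfold_split(23, 10, seed=1)
        sizes = sorted(Counter(folds.assignment).values())
        assert sizes == [2] * 7 + [3] * 3

    def test_deterministic_per_seed(self):
        a = kfold_split(57, 10, seed=3).assignment
        b = kfold_split(57, 10, seed=3).assignment
        c = kfold_split(57, 10, seed=4).assignment
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_partitions_all_indices(self):
        folds = kfold_split(41, 7, seed=9)
        seen = np.concatenate([folds.indices(f) for f in range(1, 8)])
        assert sorted(seen) == list(range(41))

    def test_n_less_than_k_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(5, 10, seed=0)

    def test_k_equals_n_allowed(self):
        folds = kfold_split(12, 12, seed=0)
        assert sorted(Counter(folds.assignment).values()) == [1] * 12


class TestGenerateNonbinders:
    def test_basic_output(self, background):
        peps = generate_nonbinders(100, 9, background, seed=0)
        assert len(peps) == 100
        assert all(len(p) == 9 for p in peps)
        assert all(set(p) <= set(AMINO_ACIDS) for p in peps)

    def test_seeded_reproducible(self, background):
        assert generate_nonbinders(50, 9, background, seed=5) == \
            generate_nonbinders(50, 9, background, seed=5)

    def test_vacuous_screen_identical_to_no_screen(self, background):
        no_screen = generate_nonbinders(50, 9, background, seed=3)
        vacuous = generate_nonbinders(50, 9, background, seed=3,
                                      screen=lambda p: 50000.0)
        assert no_screen == vacuous

    def test_screen_rejects_predicted_binders(self, background):
        # screen flags peptides starting with A..I as binders
        screened = generate_nonbinders(
            50, 9, background, seed=3,
            screen=lambda p: 100.0 if p[0] in "ACDEFGHI" else 50000.0,
        )
        assert all(p[0] not in "ACDEFGHI" for p in screened)

    def test_budget_exhaustion_reports_rate(self, background):
        with pytest.raises(RejectionBudgetError, match="acceptance rate"):
            generate_nonbinders(10, 9, background, seed=0,
                                screen=lambda p: 1.0, max_attempts_factor=3)

    def test_empirical_frequencies_match_background(self, background):
        # law-of-large-numbers check at 50k 9-mers
        peps = generate_nonbinders(50000, 9, background, seed=11)
        counts = Counter("".join(peps))
        total = 50000 * 9
        for i, aa in enumerate(AMINO_ACIDS):
            assert counts[aa] / total == pytest.approx(
                background.as_array()[i], abs=0.01
            )


class TestAuc:
    def test_perfect_separation(self):
        assert auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_all_ties(self):
        assert auc([5.0] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_one_inversion_among_nine_pairs(self):
        # positives {4, 5, 6}, negatives {1, 2, 4.5}: the pair (4, 4.5)
        # inverts -> 8/9 wins + 0 ties
        scores = [4, 5, 6, 1, 2, 4.5]
        labels = [1, 1, 1, 0, 0, 0]
        assert auc(scores, labels) == pytest.approx(pair_counting_auc(scores, labels))
        assert auc(scores, labels) == pytest.approx(8.0 / 9.0)

    def test_half_tie_case(self):
        # positives {4, 5, 6}, negatives {1, 2, 4}: 8 wins + one tie at 4
        scores = [4, 5, 6, 1, 2, 4]
        labels = [1, 1, 1, 0, 0, 0]
        assert auc(scores, labels) == pytest.approx(8.5 / 9.0)
        assert auc(scores, labels) == pytest.approx(pair_counting_auc(scores, labels))

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auc([1, 2, 3], [1, 1, 1])

    @settings(max_examples=200, deadline=None)
    @given(st.lists(
        st.tuples(st.integers(min_value=-50, max_value=50),
                  st.integers(min_value=0, max_value=1)),
        min_size=2, max_size=200,
    ))
    def test_matches_pair_counting_oracle(self, pairs):
        scores = [float(s) for s, _ in pairs]
        labels = [l for _, l in pairs]
        if len(set(labels)) < 2:
            return
        assert auc(scores, labels) == pytest.approx(
            pair_counting_auc(scores, labels), abs=1e-12
        )


class TestConfusionMetrics:
    def test_formula_arithmetic(self):
        c = ConfusionCounts(tp=9, tn=8, fp=1, fn=2)
        assert c.acc == pytest.approx(17 / 20)
        assert c.sensitivity == pytest.approx(9 / 11)
        assert c.specificity == pytest.approx(8 / 9)
        assert c.precision == pytest.approx(9 / 10)

    def test_all_correct(self):
        preds = [100.0, 100.0, 900.0, 900.0]
        c = confusion_metrics(preds, [1, 1, 0, 0])
        assert (c.acc, c.sensitivity, c.specificity) == (1.0, 1.0, 1.0)

    def test_no_predicted_positives(self):
        c = confusion_metrics([900.0, 900.0, 900.0], [1, 1, 0])
        assert c.sensitivity == 0.0
        assert c.tp == 0 and c.fn == 2

    def test_cutoff_is_strict(self):
        c = confusion_metrics([500.0], [1])
        assert c.fn == 1  # exactly 500 nM is not a positive call

    def test_counts_conserve_total(self, rng):
        ic50s = rng.uniform(1, 50000, size=100)
        labels = rng.integers(0, 2, size=100)
        c = confusion_metrics(ic50s, labels)
        assert c.total == 100

    def test_accepts_prediction_objects(self):
        class P:
            ic50 = 100.0
        c = confusion_metrics([P()], [1])
        assert c.tp == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="2.*3|3.*2"):
            confusion_metrics([1.0, 2.0], [1, 0, 1])


@pytest.fixture(scope="module")
def planted_groups(background):
    bg = background
    profile = make_motif_profile(9, anchors=(2, 9), dominance=0.7,
                                 background=bg, seed=13)
    binders = sample_binders(profile, 500, seed=13)
    return bg, {("HLA-A*02:01", 9): binders}


class TestCrossValidate:
    def test_planted_motif_recovers_high_auc(self, planted_groups):
        bg, groups = planted_groups
        summary = cross_validate(groups, bg, k=10, seed=13)
        assert len(summary.rows) == 1
        assert summary.rows[0].auc >= 0.9
        assert summary.rows[0].n_binders == 500

    def test_reproducible_per_seed(self, planted_groups):
        bg, groups = planted_groups
        s1 = cross_validate(groups, bg, k=10, seed=2)
        s2 = cross_validate(groups, bg, k=10, seed=2)
        assert s1.rows == s2.rows

    def test_leave_one_out_boundary(self, background):
        profile = make_motif_profile(9, anchors=(2, 9), dominance=0.7,
                                     background=background, seed=20)
        groups = {("HLA-A*02:01", 9): sample_binders(profile, 12, seed=20)}
        summary = cross_validate(groups, background, k=12, seed=20)
        assert len(summary.rows) == 1  # runs without error

    def test_small_group_skipped_with_report(self, background):
        groups = {("HLA-A*02:01", 9): sample_binders(
            make_motif_profile(9, anchors=(2,), dominance=0.7,
                               background=background, seed=1),
            5, seed=1)}
        summary = cross_validate(groups, background, k=10, seed=0)
        assert summary.rows == []
        assert len(summary.skipped) == 1

    def test_shuffled_labels_give_null_auc(self, background):
        profile = make_motif_profile(9, anchors=(2, 9), dominance=0.7,
                                     background=background, seed=17)
        binders = sample_binders(profile, 1000, seed=17)
        nonbinders = generate_nonbinders(1000, 9, background, seed=17)
        pool = binders + nonbinders
        rng = np.random.default_rng(17)
        labels = np.array([1] * 1000 + [0] * 1000)
        rng.shuffle(labels)
        shuffled_binders = [p for p, l in zip(pool, labels) if l == 1]
        shuffled_nonbinders = [p for p, l in zip(pool, labels) if l == 0]
        summary = cross_validate(
            {("HLA-A*02:01", 9): shuffled_binders},
            background, k=10, seed=17,
            nonbinders={("HLA-A*02:01", 9): shuffled_nonbinders},
        )
        assert summary.rows[0].auc == pytest.approx(0.5, abs=0.05)

    def test_training_validation_disjoint(self, background):
        # trace disjointness through the fold assignment itself
        binders = sample_binders(
            make_motif_profile(9, anchors=(2, 9), dominance=0.7,
                               background=background, seed=5),
            60, seed=5)
        folds = kfold_split(60, 10, seed=5)
        for f in range(1, 11):
            held = set(folds.indices(f))
            train = set(range(60)) - held
            assert held.isdisjoint(train)

    def test_macro_average_over_groups(self, background):
        profile = make_motif_profile(9, anchors=(2, 9), dominance=0.7,
                                     background=background, seed=8)
        groups = {
            ("HLA-A*02:01", 9): sample_binders(profile, 60, seed=8),
            ("HLA-B*07:02", 9): sample_binders(profile, 60, seed=9),
        }
        summary = cross_validate(groups, background, k=10, seed=8)
        assert len(summary.rows) == 2
        assert summary.macro_auc == pytest.approx(
            np.mean([r.auc for r in summary.rows])
        )

    def test_per_fold_option_runs(self, planted_groups):
        bg, groups = planted_groups
        summary = cross_validate(groups, bg, k=10, seed=1, per_fold=True)
        pooled = cross_validate(groups, bg, k=10, seed=1)
        # per-fold averaging is a different estimator but lands close to pooled
        assert summary.rows[0].auc == pytest.approx(pooled.rows[0].auc, abs=0.05)

    def test_summary_tsv(self, tmp_path, planted_groups):
        bg, groups = planted_groups
        summary = cross_validate(groups, bg, k=10, seed=1)
        summary.write_tsv(tmp_path / "eval.tsv")
        lines = (tmp_path / "eval.tsv").read_text().splitlines()
        assert lines[0].startswith("allele\tlength")
        assert len(lines) == 2
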