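import random

import pytest

from phenonote import (
    FinalLabel,
    TruthSet,
    model_metrics,
    partition_outcomes,
    system_metrics,
    time_sensitive_sensitivity,
)
from phenonote.metrics import OutcomeSets

from conftest import annotation

Y, N, U, NNF = FinalLabel.YES, FinalLabel.NO, FinalLabel.UNDECIDED, FinalLabel.NNF


def random_cohort(rng, max_units=50):
    """Random truth + annotations over <= max_units units."""
    n = rng.randint(2, max_units)
    units = [f"u{i}" for i in range(n)]
    pos = {u for u in units if rng.random() < 0.5}
    truth = TruthSet(frozenset(pos), frozenset(set(units) - pos))
    labels = {}
    for u in units:
        r = rng.random()
        if r < 0.35:
            lab, counts = Y, dict(n_yes=1 + rng.randint(0, 2))
        elif r < 0.6:
            lab, counts = N, dict(n_no=1 + rng.randint(0, 2))
        elif r < 0.8:
            k = rng.randint(0, 2)
            lab, counts = U, dict(n_yes=k, n_no=k, n_unknown=1 if k == 0 else 0)
        else:
            lab, counts = NNF, {}
        labels[u] = annotation(u, lab, **counts)
    return truth, list(labels.values())


def brute_force_reports(annotations, truth):
    """Independent per-unit confusion tallies for both modes."""
    label = {a.unit_id: a.final_label for a in annotations}
    m_tp = sum(1 for u in truth.positives if label[u] is Y)
    pos_eval = [u for u in truth.positives if label[u] is not NNF]
    neg_eval = [u for u in truth.negatives if label[u] is not NNF]
    m_tn = sum(1 for u in neg_eval if label[u] in (N, U))
    n_yes_total = sum(1 for u in label if label[u] is Y)
    prec = None if n_yes_total == 0 else m_tp / n_yes_total

    def f1(s, p):
        return None if s is None or p is None or s + p == 0 else 2 * s * p / (s + p)

    model = dict(
        sens=None if not pos_eval else sum(1 for u in pos_eval if label[u] is Y) / len(pos_eval),
        spec=None if not neg_eval else m_tn / len(neg_eval),
        prec=prec,
    )
    model["f1"] = f1(model["sens"], prec)
    system = dict(
        sens=None if not truth.positives else m_tp / len(truth.positives),
        spec=None if not truth.negatives
        else sum(1 for u in truth.negatives if label[u] in (N, U, NNF)) / len(truth.negatives),
        prec=prec,
    )
    system["f1"] = f1(system["sens"], prec)
    return model, system


class TestPartition:
    def test_direct_rule(self):
        anns = [annotation("a", Y, n_yes=1), annotation("b", N, n_no=1),
                annotation("c", U, n_unknown=1), annotation("d", NNF)]
        truth = TruthSet(frozenset("ab"), frozenset("cd"))
        sets = partition_outcomes(anns, truth)
        assert sets.m_llm == {"a"}
        assert sets.n_llm == {"b", "c"}
        assert sets.n_nnf == {"d"}

    def test_all_nnf(self):
        anns = [annotation("a", NNF), annotation("b", NNF)]
        truth = TruthSet(frozenset("a"), frozenset("b"))
        sets = partition_outcomes(anns, truth)
        assert sets.m_llm == set() == sets.n_llm

    def test_unknown_unit_is_fatal(self):
        truth = TruthSet(frozenset("a"), frozenset())
        with pytest.raises(ValueError, match="absent"):
            partition_outcomes([annotation("zz", Y, n_yes=1)], truth)

    def test_duplicate_annotation_is_fatal(self):
        truth = TruthSet(frozenset("a"), frozenset())
        anns = [annotation("a", Y, n_yes=1), annotation("a", NNF)]
        with pytest.raises(ValueError, match="duplicate"):
            partition_outcomes(anns, truth)

    def test_partition_property_on_random_cohorts(self):
        rng = random.Random(7)
        for _ in range(200):
            truth, anns = random_cohort(rng)
            sets = partition_outcomes(anns, truth)
            groups = [sets.m_llm, sets.n_llm, sets.n_nnf]
            assert sum(len(g) for g in groups) == len(anns)
            assert frozenset().union(*groups) == {a.unit_id for a in anns}


class TestHandEnumeratedFixture:
    """Five units: M_ICD={a,b,c}, N_ICD={d,e}; c is NNF; only a annotated Yes."""

    truth = TruthSet(frozenset("abc"), frozenset("de"))
    sets = OutcomeSets(frozenset("a"), frozenset("bde"), frozenset("c"))

    def test_model_mode(self):
        r = model_metrics(self.sets, self.truth)
        assert r.sensitivity == pytest.approx(1 / 2)
        assert r.specificity == pytest.approx(1.0)
        assert r.precision == pytest.approx(1.0)
        assert r.f1 == pytest.approx(2 / 3)
        assert r.counts["n_icd_positive_eval"] == 2

    def test_system_mode(self):
        r = system_metrics(self.sets, self.truth)
        assert r.sensitivity == pytest.approx(1 / 3)
        assert r.specificity == pytest.approx(1.0)
        assert r.precision == pytest.approx(1.0)
        assert r.f1 == pytest.approx(2 * (1 / 3) / (1 / 3 + 1))


class TestMetricProperties:
    def test_perfect_classifier_scores_one_everywhere(self):
        truth = TruthSet(frozenset("ab"), frozenset("cd"))
        sets = OutcomeSets(frozenset("ab"), frozenset("cd"), frozenset())
        for fn in (model_metrics, system_metrics):
            r = fn(sets, truth)
            assert (r.sensitivity, r.specificity, r.precision, r.f1) == (1, 1, 1, 1)

    def test_no_nnf_collapses_system_to_model(self):
        rng = random.Random(3)
        for _ in range(100):
            truth, anns = random_cohort(rng)
            anns = [a for a in anns if a.final_label is not NNF]
            truth = TruthSet(
                frozenset(a.unit_id for a in anns if a.unit_id in truth.positives),
                frozenset(a.unit_id for a in anns if a.unit_id in truth.negatives),
            )
            if not anns:
                continue
            sets = partition_outcomes(anns, truth)
            m, s = model_metrics(sets, truth), system_metrics(sets, truth)
            assert m.sensitivity == s.sensitivity
            assert m.specificity == s.specificity

    def test_oracle_agreement_on_random_cohorts(self):
        rng = random.Random(11)
        for _ in range(300):
            truth, anns = random_cohort(rng)
            sets = partition_outcomes(anns, truth)
            m, s = model_metrics(sets, truth), system_metrics(sets, truth)
            em, es = brute_force_reports(anns, truth)
            for got, exp in ((m, em), (s, es)):
                for key, attr in (("sens", "sensitivity"), ("spec", "specificity"),
                                  ("prec", "precision"), ("f1", "f1")):
                    g, e = getattr(got, attr), exp[key]
                    if e is None:
                        assert g is None
                    else:
                        assert g == pytest.approx(e, abs=1e-12)

    def test_algebraic_identities(self):
        rng = random.Random(13)
        for _ in range(300):
            truth, anns = random_cohort(rng)
            sets = partition_outcomes(anns, truth)
            m, s = model_metrics(sets, truth), system_metrics(sets, truth)
            if m.sensitivity is not None and s.sensitivity is not None:
                ratio = m.counts["n_icd_positive_eval"] / len(truth.positives)
                assert s.sensitivity == pytest.approx(m.sensitivity * ratio, abs=1e-12)
            if m.specificity is not None and s.specificity is not None:
                assert s.specificity >= m.specificity - 1e-12

    def test_undefined_metrics_are_flagged_not_zero(self):
        truth = TruthSet(frozenset(), frozenset("ab"))
        sets = OutcomeSets(frozenset(), frozenset("ab"), frozenset())
        r = system_metrics(sets, truth)
        assert r.sensitivity is None
        assert "sensitivity" in r.undefined
        assert r.precision is None  # nothing annotated Yes


class TestTimeSensitive:
    def test_direct_formula(self):
        r = time_sensitive_sensitivity([Y, Y, N, NNF], window_days=20)
        assert (r.n_correct, r.n_wrong, r.n_no_notes) == (2, 1, 1)
        assert r.sens_model == pytest.approx(2 / 3)
        assert r.sens_system == pytest.approx(1 / 2)

    def test_all_yes(self):
        r = time_sensitive_sensitivity([Y, Y, Y], 20)
        assert r.sens_model == 1.0 and r.sens_system == 1.0

    def test_counts_match_brute_force_tally_and_ordering(self):
        rng = random.Random(5)
        for _ in range(300):
            outcomes = [rng.choice([Y, N, U, NNF]) for _ in range(rng.randint(1, 40))]
            r = time_sensitive_sensitivity(outcomes, 30)
            assert r.n_correct == sum(1 for o in outcomes if o is Y)
            assert r.n_wrong == sum(1 for o in outcomes if o in (N, U))
            assert r.n_no_notes == sum(1 for o in outcomes if o is NNF)
            assert r.n_correct + r.n_wrong + r.n_no_notes == len(outcomes)
            if r.sens_model is not None:
                assert r.sens_system <= r.sens_model + 1e-12

    def test_zero_events_undefined_flagged(self):
        r = time_sensitive_sensitivity([], 20)
        assert r.sens_model is None and r.sens_system is None
        assert "sens_model" in r.undefined

    def test_truthset_rejects_overlap(self):
        with pytest.raises(ValueError):
            TruthSet(frozenset("ab"), frozenset("bc"))
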