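"""Mamdani classifier: membership, normalization, induction, inference, export."""

import math
import re

import numpy as np
import pandas as pd
import pytest

import fuzzsig as fs
from fuzzsig.fuzzy import (DEFAULT_SIGMA, FuzzyRule, FuzzyRuleBase,
                           NormalizationBounds, Prediction, _winning_term)

from conftest import two_group_matrix

TERMS = fs.default_terms()


# --- membership -------------------------------------------------------------

def test_membership_peaks_and_symmetry():
    small, medium, large = TERMS
    assert fs.membership(0.0, small) == 1.0
    assert fs.membership(0.5, medium) == 1.0
    assert fs.membership(1.0, large) == 1.0
    assert fs.membership(0.5, small) == pytest.approx(fs.membership(0.5, large), abs=1e-15)
    # direct evaluation of exp(-0.25 / (2 * 0.175^2))
    assert fs.membership(0.5, small) == pytest.approx(0.016879884148789895, abs=1e-12)


def test_term_validation():
    with pytest.raises(ValueError, match="sigma"):
        fs.LinguisticTerm("small", 0.0, sigma=0.0)


# --- normalization ----------------------------------------------------------

def test_normalize_endpoints_clamping_and_constant():
    b = NormalizationBounds({"g1": (2.0, 6.0), "g2": (3.0, 3.0)})
    assert b.normalize_one("g1", 2.0) == 0.0
    assert b.normalize_one("g1", 6.0) == 1.0
    assert b.normalize_one("g1", 5.0) == 0.75
    assert b.normalize_one("g1", 99.0) == 1.0  # clamped beyond training max
    assert b.normalize_one("g1", -99.0) == 0.0
    assert b.normalize_one("g2", 3.0) == 0.5  # constant gene convention
    with pytest.raises(KeyError, match="gX"):
        b.normalize_one("gX", 1.0)


def test_normalize_frame_matches_scalar_path():
    vals = pd.DataFrame([[2.0, 4.0, 6.0]], index=["g1"], columns=["a", "b", "c"])
    b = NormalizationBounds.fit(vals)
    out = fs.normalize(vals, b)
    np.testing.assert_allclose(out.loc["g1"], [0.0, 0.5, 1.0])


# --- rule induction ---------------------------------------------------------

def _norm_frame(samples: dict[str, list[float]], genes: list[str]) -> pd.DataFrame:
    return pd.DataFrame(samples, index=genes)


def test_single_sample_induces_single_full_weight_rule():
    norm = _norm_frame({"s1": [1.0, 1.0]}, ["gA", "gB"])
    rb = fs.induce_rules(norm, pd.Series({"s1": "tumor"}))
    assert len(rb.rules) == 1
    rule = rb.rules[0]
    assert rule.antecedents == ("large", "large")
    assert rule.consequent == "tumor" and rule.weight == 1.0


def test_conflicting_identical_samples_merge_to_tie_rule():
    norm = _norm_frame({"s1": [1.0], "s2": [1.0]}, ["gA"])
    labels = pd.Series({"s1": "tumor", "s2": "normal"})
    rb = fs.induce_rules(norm, labels)
    assert len(rb.rules) == 1
    # tie resolved toward normal (conservative), weight = its share = 0.5
    assert rb.rules[0].consequent == "normal"
    assert rb.rules[0].weight == pytest.approx(0.5)


def test_clustered_two_gene_data_induces_expected_patterns():
    rng = np.random.default_rng(5)
    samples, labels = {}, {}
    for i in range(10):
        samples[f"t{i}"] = [0.9 + rng.normal(0, 0.02), 0.1 + rng.normal(0, 0.02)]
        labels[f"t{i}"] = "tumor"
        samples[f"n{i}"] = [0.1 + rng.normal(0, 0.02), 0.9 + rng.normal(0, 0.02)]
        labels[f"n{i}"] = "normal"
    rb = fs.induce_rules(_norm_frame(samples, ["gA", "gB"]), pd.Series(labels))
    patterns = {r.antecedents: r.consequent for r in rb.rules}
    assert patterns == {("large", "small"): "tumor", ("small", "large"): "normal"}


def test_induction_rejects_empty_training_set():
    with pytest.raises(ValueError, match="empty training"):
        fs.induce_rules(pd.DataFrame(index=["g"], columns=[]), pd.Series(dtype=object))


# --- inference vs brute-force oracle ---------------------------------------

def _oracle_classify(sample, rb):
    """Independent re-implementation: explicit loops, no shared helpers."""
    agg = {"tumor": 0.0, "normal": 0.0}
    for rule in rb.rules:
        strength = None
        for gene, term_name in zip(rb.gene_order, rule.antecedents):
            term = next(t for t in rb.terms if t.name == term_name)
            mu = math.exp(-((sample[gene] - term.center) ** 2) / (2 * term.sigma ** 2))
            strength = mu if strength is None else min(strength, mu)
        strength *= rule.weight
        if strength > agg[rule.consequent]:
            agg[rule.consequent] = strength
    score = agg["tumor"] - agg["normal"]
    if agg["tumor"] == agg["normal"]:
        return rb.majority_class, score
    return ("tumor" if score > 0 else "normal"), score


def _random_rulebase(rng, n_genes=3, n_rules=5):
    genes = tuple(f"g{i}" for i in range(n_genes))
    patterns = set()
    while len(patterns) < n_rules:
        patterns.add(tuple(rng.choice(["small", "medium", "large"], n_genes)))
    rules = [FuzzyRule(p, str(rng.choice(["tumor", "normal"])),
                       float(rng.uniform(0.1, 1.0))) for p in patterns]
    return FuzzyRuleBase(rules=rules,
                         bounds=NormalizationBounds({g: (0.0, 1.0) for g in genes}),
                         terms=fs.default_terms(), gene_order=genes,
                         majority_class=str(rng.choice(["tumor", "normal"])))


def test_classify_matches_brute_force_oracle_exactly():
    rng = np.random.default_rng(123)
    for _ in range(20):
        rb = _random_rulebase(rng)
        for _ in range(50):
            sample = {g: float(rng.uniform(0, 1)) for g in rb.gene_order}
            pred = fs.classify(sample, rb)
            label, score = _oracle_classify(sample, rb)
            assert pred.label == label
            assert pred.score == score  # exact: same arithmetic, no reordering


def test_single_rule_fires_at_its_weight_on_term_centers():
    rule = FuzzyRule(("small", "large"), "tumor", 0.7)
    rb = FuzzyRuleBase([rule], NormalizationBounds({"gA": (0, 1), "gB": (0, 1)}),
                       fs.default_terms(), ("gA", "gB"))
    pred = fs.classify({"gA": 0.0, "gB": 1.0}, rb)
    assert pred.firing == (0.7,)
    assert pred.label == "tumor" and pred.score == pytest.approx(0.7)


def test_training_samples_classified_as_their_own_label_when_separable():
    rng = np.random.default_rng(9)
    rows = [(0.5 + rng.normal(0, 0.05, 8), -0.5 + rng.normal(0, 0.05, 8)),
            (-0.5 + rng.normal(0, 0.05, 8), 0.5 + rng.normal(0, 0.05, 8))]
    mat = two_group_matrix(rows, 8, 8)
    clf = fs.MamdaniFuzzyClassifier().fit(mat, ["g0", "g1"])
    pred = clf.predict(mat)
    assert (pred["label"] == mat.labels.loc[pred.index]).all()


def test_predictions_invariant_to_rule_and_gene_permutation():
    rng = np.random.default_rng(77)
    rb = _random_rulebase(rng, n_genes=4, n_rules=6)
    perm = [2, 0, 3, 1]
    rb_perm = FuzzyRuleBase(
        rules=[FuzzyRule(tuple(r.antecedents[j] for j in perm), r.consequent, r.weight)
               for r in reversed(rb.rules)],
        bounds=rb.bounds, terms=rb.terms,
        gene_order=tuple(rb.gene_order[j] for j in perm),
        majority_class=rb.majority_class)
    for _ in range(25):
        sample = {g: float(rng.uniform(0, 1)) for g in rb.gene_order}
        a, b = fs.classify(sample, rb), fs.classify(sample, rb_perm)
        assert (a.label, a.score) == (b.label, b.score)


def test_score_antisymmetric_under_class_swap():
    rng = np.random.default_rng(31)
    rb = _random_rulebase(rng)
    swap = {"tumor": "normal", "normal": "tumor"}
    rb_sw = FuzzyRuleBase(
        rules=[FuzzyRule(r.antecedents, swap[r.consequent], r.weight) for r in rb.rules],
        bounds=rb.bounds, terms=rb.terms, gene_order=rb.gene_order,
        majority_class=swap[rb.majority_class])
    for _ in range(25):
        sample = {g: float(rng.uniform(0, 1)) for g in rb.gene_order}
        assert fs.classify(sample, rb).score == pytest.approx(
            -fs.classify(sample, rb_sw).score, abs=1e-15)


def test_conflicting_rulebase_construction_rejected():
    bounds = NormalizationBounds({"gA": (0, 1)})
    with pytest.raises(ValueError, match="conflicting"):
        FuzzyRuleBase([FuzzyRule(("small",), "tumor", 1.0),
                       FuzzyRule(("small",), "normal", 1.0)],
                      bounds, fs.default_terms(), ("gA",))


# --- export / parse / serialization -----------------------------------------

RULE_REGEX = (r"^IF \(.+ is (small|medium|large)\)( \^ \(.+\))* "
              r"THEN the sample is a (tumor|normal) sample")


def test_export_format_and_round_trip():
    rng = np.random.default_rng(4)
    rb = _random_rulebase(rng, n_genes=12, n_rules=3)
    text = fs.export_rules(rb)
    lines = text.splitlines()
    assert len(lines) == 3
    for line in lines:
        assert re.match(RULE_REGEX, line)
        assert line.count("(") == 12  # one clause per signature gene
    back = fs.parse_rules(text, rb.bounds, rb.terms, rb.majority_class)
    assert back.gene_order == rb.gene_order
    assert [(r.antecedents, r.consequent) for r in back.rules] == \
        [(r.antecedents, r.consequent) for r in rb.rules]
    np.testing.assert_allclose([r.weight for r in back.rules],
                               [r.weight for r in rb.rules], atol=1e-6)


def test_json_round_trip_preserves_rulebase():
    rng = np.random.default_rng(8)
    rb = _random_rulebase(rng)
    back = FuzzyRuleBase.from_json(rb.to_json())
    assert back.gene_order == rb.gene_order
    assert back.rules == rb.rules
    assert back.bounds.bounds == rb.bounds.bounds
    assert back.terms == rb.terms


def test_empty_signature_predicts_majority_class():
    rows = [(np.ones(5), np.zeros(3))]
    mat = two_group_matrix(rows, 5, 3)
    clf = fs.MamdaniFuzzyClassifier().fit(mat, [])
    pred = clf.predict(mat)
    assert (pred["label"] == "tumor").all()  # 5 tumor vs 3 normal
    assert pred["defaulted"].all() and (pred["score"] == 0.0).all()
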