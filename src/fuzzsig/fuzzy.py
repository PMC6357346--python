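"""Mamdani fuzzy-rule classification of tumor vs normal samples.

Each signature gene's expression is min-max normalized to [0, 1] (bounds fitted
on training data only) and covered by three Gaussian linguistic terms —
"small", "medium", "large" centered at 0, 0.5 and 1 with sigma 0.175. Rules
are induced by the Wang-Mendel construction: every training sample contributes
one candidate rule whose antecedent assigns each gene its maximum-membership
term, whose consequent is the sample's class, and whose degree is the product
of the winning memberships. Candidates with identical antecedents are merged;
a pattern claimed by both classes keeps the class with the larger summed
degree (ties go to "normal", conservative toward non-cancer), and the final
rule weight is the kept class's share of the pattern's total degree.

Inference is classical Mamdani: a rule fires with min over its antecedent
memberships times its weight (t-norm), each class aggregates its rules by max
(s-norm), and the predicted class is the argmax. The signed difference
aggregate(tumor) - aggregate(normal) in [-1, 1] serves as the continuous score
for ROC analysis.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import NORMAL, TUMOR, OmicsMatrix

DEFAULT_SIGMA = 0.175
TERM_NAMES = ("small", "medium", "large")


@dataclass(frozen=True)
class LinguisticTerm:
    """A named Gaussian fuzzy set on the normalized [0, 1] expression range."""

    name: str
    center: float
    sigma: float = DEFAULT_SIGMA

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def default_terms(sigma: float = DEFAULT_SIGMA) -> tuple[LinguisticTerm, ...]:
    return (LinguisticTerm("small", 0.0, sigma),
            LinguisticTerm("medium", 0.5, sigma),
            LinguisticTerm("large", 1.0, sigma))


def membership(x: float, term: LinguisticTerm) -> float:
    """Gaussian membership degree ``exp(-(x - center)^2 / (2 sigma^2))``."""
    return math.exp(-((x - term.center) ** 2) / (2.0 * term.sigma ** 2))


@dataclass
class NormalizationBounds:
    """Per-gene (min, max) fitted on training data; constant genes map to 0.5."""

    bounds: dict[str, tuple[float, float]]

    @classmethod
    def fit(cls, values: pd.DataFrame) -> "NormalizationBounds":
        return cls({g: (float(row.min()), float(row.max()))
                    for g, row in values.iterrows()})

    def normalize_one(self, gene: str, x: float) -> float:
        if gene not in self.bounds:
            raise KeyError(f"no normalization bounds for gene {gene!r}")
        lo, hi = self.bounds[gene]
        if hi == lo:
            return 0.5
        return min(1.0, max(0.0, (x - lo) / (hi - lo)))


def normalize(values: pd.DataFrame, bounds: NormalizationBounds) -> pd.DataFrame:
    """Min-max normalize a genes x samples frame, clamping to [0, 1]."""
    out = {}
    for g, row in values.iterrows():
        out[g] = [bounds.normalize_one(g, float(v)) for v in row]
    return pd.DataFrame.from_dict(out, orient="index", columns=values.columns)


@dataclass(frozen=True)
class FuzzyRule:
    """One IF-THEN rule: a complete conjunction over the signature genes."""

    antecedents: tuple[str, ...]  # term name per gene, in rulebase gene order
    consequent: str  # tumor | normal
    weight: float

    def __post_init__(self) -> None:
        if not 0.0 < self.weight <= 1.0:
            raise ValueError("rule weight must lie in (0, 1]")
        if self.consequent not in (TUMOR, NORMAL):
            raise ValueError(f"invalid consequent {self.consequent!r}")


@dataclass
class FuzzyRuleBase:
    """Induced rules plus the normalization bounds and term definitions."""

    rules: list[FuzzyRule]
    bounds: NormalizationBounds
    terms: tuple[LinguisticTerm, ...]
    gene_order: tuple[str, ...]
    majority_class: str = NORMAL

    def __post_init__(self) -> None:
        seen: dict[tuple[str, ...], str] = {}
        for r in self.rules:
            if len(r.antecedents) != len(self.gene_order):
                raise ValueError("rule antecedents must cover every signature gene")
            if seen.setdefault(r.antecedents, r.consequent) != r.consequent:
                raise ValueError("conflicting rules share identical antecedents")

    def term(self, name: str) -> LinguisticTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(f"unknown term {name!r}")

    # --- serialization (versioned JSON) -------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "format_version": 1,
            "gene_order": list(self.gene_order),
            "majority_class": self.majority_class,
            "terms": [{"name": t.name, "center": t.center, "sigma": t.sigma}
                      for t in self.terms],
            "bounds": {g: list(b) for g, b in self.bounds.bounds.items()},
            "rules": [{"antecedents": list(r.antecedents), "consequent": r.consequent,
                       "weight": r.weight} for r in self.rules],
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FuzzyRuleBase":
        d = json.loads(text)
        return cls(
            rules=[FuzzyRule(tuple(r["antecedents"]), r["consequent"], r["weight"])
                   for r in d["rules"]],
            bounds=NormalizationBounds({g: (b[0], b[1]) for g, b in d["bounds"].items()}),
            terms=tuple(LinguisticTerm(t["name"], t["center"], t["sigma"])
                        for t in d["terms"]),
            gene_order=tuple(d["gene_order"]),
            majority_class=d["majority_class"],
        )


def _winning_term(x: float, terms) -> tuple[str, float]:
    best, mu = None, -1.0
    for t in terms:
        m = membership(x, t)
        if m > mu:
            best, mu = t.name, m
    return best, mu


def induce_rules(normalized: pd.DataFrame, labels: pd.Series,
                 terms: tuple[LinguisticTerm, ...] | None = None,
                 bounds: NormalizationBounds | None = None,
                 conflict: str = "weight") -> FuzzyRuleBase:
    """Wang-Mendel rule induction from normalized training samples.

    ``normalized`` is genes x samples with values in [0, 1]; ``labels`` maps
    sample ids to tumor/normal. ``conflict="weight"`` resolves antecedent
    clashes by summed membership degree, ``"count"`` by sample count.
    """
    if normalized.shape[1] == 0:
        raise ValueError("cannot induce rules from an empty training set")
    if conflict not in ("weight", "count"):
        raise ValueError(f"conflict must be weight|count, got {conflict!r}")
    terms = terms if terms is not None else default_terms()
    gene_order = tuple(normalized.index)
    if bounds is None:
        bounds = NormalizationBounds({g: (0.0, 1.0) for g in gene_order})

    n_tumor = int((labels.loc[list(normalized.columns)] == TUMOR).sum())
    n_normal = normalized.shape[1] - n_tumor
    majority = TUMOR if n_tumor > n_normal else NORMAL

    # accumulate candidate degree (and count) per antecedent pattern and class
    acc: dict[tuple[str, ...], dict[str, list[float]]] = {}
    for s in normalized.columns:
        pattern, degree = [], 1.0
        for g in gene_order:
            name, mu = _winning_term(float(normalized.at[g, s]), terms)
            pattern.append(name)
            degree *= mu
        pattern = tuple(pattern)
        cls = labels[s]
        slot = acc.setdefault(pattern, {TUMOR: [0.0, 0.0], NORMAL: [0.0, 0.0]})
        slot[cls][0] += degree
        slot[cls][1] += 1.0

    rules = []
    for pattern, slot in acc.items():
        idx = 0 if conflict == "weight" else 1
        wt, wn = slot[TUMOR][idx], slot[NORMAL][idx]
        consequent = TUMOR if wt > wn else NORMAL  # tie -> normal
        kept, total = max(wt, wn), wt + wn
        if consequent == NORMAL and wt == wn:
            kept = wn if wn > 0 else total
        weight = kept / total if total > 0 else 1.0
        rules.append(FuzzyRule(pattern, consequent, weight))
    rules.sort(key=lambda r: r.antecedents)
    return FuzzyRuleBase(rules=rules, bounds=bounds, terms=terms,
                         gene_order=gene_order, majority_class=majority)


@dataclass(frozen=True)
class Prediction:
    label: str
    score: float  # aggregate(tumor) - aggregate(normal), in [-1, 1]
    firing: tuple[float, ...] = field(default_factory=tuple, compare=False)
    defaulted: bool = False  # no rule fired (or exact tie); majority class used


def classify(sample, rulebase: FuzzyRuleBase) -> Prediction:
    """Classify one normalized sample (mapping gene -> value in [0, 1])."""
    x = [float(sample[g]) for g in rulebase.gene_order]
    term_mu = {t.name: [membership(v, t) for v in x] for t in rulebase.terms}
    agg = {TUMOR: 0.0, NORMAL: 0.0}
    firing = []
    for r in rulebase.rules:
        strength = 1.0
        for j, name in enumerate(r.antecedents):
            strength = min(strength, term_mu[name][j])
        strength *= r.weight
        firing.append(strength)
        agg[r.consequent] = max(agg[r.consequent], strength)
    score = agg[TUMOR] - agg[NORMAL]
    if agg[TUMOR] == agg[NORMAL]:
        return Prediction(rulebase.majority_class, score, tuple(firing), defaulted=True)
    return Prediction(TUMOR if score > 0 else NORMAL, score, tuple(firing))


def export_rules(rulebase: FuzzyRuleBase) -> str:
    """Human-readable IF-THEN listing, one rule per line."""
    lines = []
    for r in rulebase.rules:
        clauses = " ^ ".join(f"({g} is {t})"
                             for g, t in zip(rulebase.gene_order, r.antecedents))
        lines.append(f"IF {clauses} THEN the sample is a {r.consequent} sample"
                     f"  [weight={r.weight:.6f}]")
    return "\n".join(lines)


_RULE_RE = re.compile(
    r"^IF (?P<body>.+) THEN the sample is a (?P<cls>tumor|normal) sample"
    r"\s+\[weight=(?P<w>[0-9.eE+-]+)\]$")
_CLAUSE_RE = re.compile(r"\((?P<g>\S+) is (?P<t>small|medium|large)\)")


def parse_rules(text: str, bounds: NormalizationBounds,
                terms: tuple[LinguisticTerm, ...] | None = None,
                majority_class: str = NORMAL) -> FuzzyRuleBase:
    """Inverse of :func:`export_rules` (gene order taken from the first rule)."""
    terms = terms if terms is not None else default_terms()
    rules, gene_order = [], None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        m = _RULE_RE.match(line)
        if m is None:
            raise ValueError(f"unparseable rule line: {line!r}")
        clauses = _CLAUSE_RE.findall(m.group("body"))
        genes = tuple(g for g, _ in clauses)
        if gene_order is None:
            gene_order = genes
        elif genes != gene_order:
            raise ValueError("rules disagree on gene order")
        rules.append(FuzzyRule(tuple(t for _, t in clauses), m.group("cls"),
                               float(m.group("w"))))
    if gene_order is None:
        raise ValueError("no rules found")
    return FuzzyRuleBase(rules=rules, bounds=bounds, terms=terms,
                         gene_order=gene_order, majority_class=majority_class)


class MamdaniFuzzyClassifier:
    """Convenience estimator wrapping normalization + induction + inference.

    fit() takes a log2 expression matrix and the signature genes; bounds come
    from the training matrix only, so cross-validation stays honest.
    """

    def __init__(self, sigma: float = DEFAULT_SIGMA, conflict: str = "weight"):
        self.sigma = sigma
        self.conflict = conflict
        self.rulebase_: FuzzyRuleBase | None = None

    def fit(self, train: OmicsMatrix, genes) -> "MamdaniFuzzyClassifier":
        genes = [g for g in genes if g in train.values.index]
        if not genes:
            # degenerate: empty signature; predict the majority training class
            n_t = train.n_tumor
            self.rulebase_ = FuzzyRuleBase(
                rules=[], bounds=NormalizationBounds({}), terms=default_terms(self.sigma),
                gene_order=(), majority_class=TUMOR if n_t > train.n_normal else NORMAL)
            return self
        sub = train.values.loc[genes]
        bounds = NormalizationBounds.fit(sub)
        norm = normalize(sub, bounds)
        self.rulebase_ = induce_rules(norm, train.labels, default_terms(self.sigma),
                                      bounds=bounds, conflict=self.conflict)
        return self

    def predict(self, test: OmicsMatrix) -> pd.DataFrame:
        """Per-sample predicted label and continuous score."""
        rb = self.rulebase_
        if rb is None:
            raise RuntimeError("classifier is not fitted")
        rows = []
        if not rb.gene_order:
            for s in test.sample_ids:
                rows.append((s, rb.majority_class, 0.0, True))
        else:
            norm = normalize(test.values.loc[list(rb.gene_order)], rb.bounds)
            for s in test.sample_ids:
                pred = classify(norm[s], rb)
                rows.append((s, pred.label, pred.score, pred.defaulted))
        return pd.DataFrame(rows, columns=["sample", "label", "score", "defaulted"]
                            ).set_index("sample")
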