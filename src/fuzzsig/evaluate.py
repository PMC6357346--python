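"""Cross-validated and external evaluation of the signature + fuzzy pipeline.

The central entry point, :func:`cross_validate`, runs the ENTIRE pipeline —
DEG/DML/DMG calling, candidate intersection, penalty-weighted elastic-net
selection and fuzzy-rule training — inside each training fold, so the reported
accuracy/AUC is free of selection leakage. (A ``global_selection`` switch
reproduces the optimistic alternative where features are chosen once on the
full dataset; it exists for comparison, not for reporting.)

External cohorts measured on a different platform are first quantile
normalized against the internal reference so that per-sample value
distributions match before prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from . import diff
from .fuzzy import MamdaniFuzzyClassifier
from .io_formats import NORMAL, TUMOR, BiomarkerPanel, OmicsMatrix
from .select import (VARIANTS, SelectionConfig, Signature, build_feature_set,
                     select_signature)


@dataclass
class EvalReport:
    """Per-fold and aggregate performance of one model variant."""

    variant: str
    per_fold: pd.DataFrame  # columns: fold, accuracy, auc, n_test
    seed: int

    @property
    def mean_accuracy(self) -> float:
        return float(self.per_fold["accuracy"].mean())

    @property
    def mean_auc(self) -> float:
        return float(self.per_fold["auc"].dropna().mean())

    def summary(self) -> str:
        return (f"{self.variant}: mean accuracy {self.mean_accuracy:.3f}, "
                f"mean AUC {self.mean_auc:.3f} over {len(self.per_fold)} folds "
                f"(seed {self.seed})")


def compute_auc(scores, labels) -> float:
    """Probability a random tumor outscores a random normal (ties count 1/2)."""
    scores = np.asarray(list(scores), float)
    labels = np.asarray(list(labels))
    pos = scores[labels == TUMOR]
    neg = scores[labels == NORMAL]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC requires both tumor and normal samples")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def quantile_normalize(external: OmicsMatrix, reference: OmicsMatrix) -> OmicsMatrix:
    """Force each external sample's value distribution onto the reference's.

    Genes are intersected first; the reference vector is the pooled empirical
    quantile function of the reference values over the shared genes, evaluated
    at as many points as there are shared genes. Each external sample's values
    are replaced rank-by-rank with that vector (average ranks for ties, i.e.
    tied values get the mean of the tied quantiles).
    """
    shared = [g for g in external.feature_ids if g in set(reference.feature_ids)]
    if len(shared) < 2:
        raise ValueError(f"need >= 2 shared genes, got {len(shared)}")
    g = len(shared)
    pool = reference.values.loc[shared].to_numpy(float).ravel()
    ref_vector = np.quantile(pool, np.linspace(0.0, 1.0, g))
    out = np.empty((g, len(external.sample_ids)))
    ext = external.values.loc[shared].to_numpy(float)
    for j in range(ext.shape[1]):
        ranks = rankdata(ext[:, j], method="average")
        out[:, j] = np.interp(ranks, np.arange(1, g + 1), ref_vector)
    return OmicsMatrix(pd.DataFrame(out, index=shared, columns=external.sample_ids),
                       external.labels.copy())


@dataclass
class FittedPipeline:
    signature: Signature
    classifier: MamdaniFuzzyClassifier


def fit_pipeline(train_expr: OmicsMatrix, train_meth: OmicsMatrix | None,
                 promoter_map: dict[str, list[str]] | None,
                 panel: BiomarkerPanel | None, variant: str = "BIO+EXP+EMETH",
                 selection: SelectionConfig = SelectionConfig()) -> FittedPipeline:
    """Run feature selection + fuzzy training on (training) data only.

    ``train_expr`` must already be on the log2 scale. Variants that use
    methylation require ``train_meth`` and ``promoter_map``.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    needs_meth = variant in ("EXP+METH", "BIO+EXP+METH", "BIO+EXP+EMETH")
    if needs_meth and (train_meth is None or promoter_map is None):
        raise ValueError(f"variant {variant} requires methylation data and a promoter map")
    degs = diff.call_deg(train_expr) if variant != "BIO" else None
    dmgs = None
    if needs_meth:
        dml = diff.call_dml(train_meth)
        dmgs = diff.call_dmg(dml, promoter_map)
    panel_genes = tuple(panel.genes) if panel is not None else ()
    features, weighted = build_feature_set(variant, degs, dmgs, panel_genes)
    present = features & set(train_expr.feature_ids)
    clf = MamdaniFuzzyClassifier()
    if len(present) < 2:
        warnings.warn(f"variant {variant}: <2 usable features; empty signature")
        sig = Signature(genes=(), coefficients=(), lambda_chosen=float("nan"),
                        provenance=variant, is_biomarker=())
        clf.fit(train_expr, [])
        return FittedPipeline(sig, clf)
    sig = select_signature(train_expr, features, panel if weighted else None,
                           selection, provenance=variant,
                           use_panel_weighting=weighted)
    clf.fit(train_expr, sig.genes)
    return FittedPipeline(sig, clf)


def _evaluate_predictions(pred: pd.DataFrame, labels: pd.Series):
    truth = labels.loc[pred.index]
    acc = float((pred["label"] == truth).mean())
    try:
        auc = compute_auc(pred["score"], truth)
    except ValueError:
        auc = float("nan")  # single-class test fold (e.g. leave-one-out)
    return acc, auc


def stratified_folds(labels: pd.Series, k: int, seed: int):
    """Seeded stratified k-fold split; shrinks k (with warning) when a class
    has fewer than k samples. Returns a list of (train_ids, test_ids)."""
    samples = np.asarray(labels.index)
    y = np.asarray([1 if labels[s] == TUMOR else 0 for s in samples])
    if k >= len(samples):  # leave-one-out; stratification is moot
        return [([s for s in samples if s != t], [t]) for t in samples]
    k_eff = int(min(k, np.bincount(y).min()))
    if k_eff < 2:
        raise ValueError("each class needs >= 2 samples for cross-validation")
    if k_eff < k:
        warnings.warn(f"shrinking k from {k} to {k_eff} (smallest class size)")
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    return [(list(samples[tr]), list(samples[te])) for tr, te in skf.split(samples, y)]


def cross_validate(expression: OmicsMatrix, methylation: OmicsMatrix | None,
                   annotation: pd.DataFrame | None, loci: pd.DataFrame | None,
                   panel: BiomarkerPanel | None, variant: str = "BIO+EXP+EMETH",
                   k: int = 10, seed: int = 0,
                   selection: SelectionConfig | None = None,
                   global_selection: bool = False) -> EvalReport:
    """Stratified k-fold CV with in-fold feature selection (the default).

    ``expression`` must be on the log2 scale. Returns an :class:`EvalReport`
    with per-fold accuracy and AUC.
    """
    promoter_map = None
    if methylation is not None and annotation is not None and loci is not None:
        promoter_map = diff.map_promoter_loci(annotation, loci)
    if selection is None:
        selection = SelectionConfig(seed=seed)
    folds = stratified_folds(expression.labels.loc[expression.sample_ids], k, seed)

    fitted_global = None
    if global_selection:
        fitted_global = fit_pipeline(expression, methylation, promoter_map,
                                     panel, variant, selection)
    rows = []
    for fold_i, (train_ids, test_ids) in enumerate(folds):
        tr_expr = expression.subset_samples(train_ids)
        te_expr = expression.subset_samples(test_ids)
        if global_selection:
            clf = MamdaniFuzzyClassifier().fit(tr_expr, fitted_global.signature.genes)
        else:
            tr_meth = methylation.subset_samples(train_ids) if methylation is not None else None
            clf = fit_pipeline(tr_expr, tr_meth, promoter_map, panel,
                               variant, selection).classifier
        pred = clf.predict(te_expr)
        acc, auc = _evaluate_predictions(pred, te_expr.labels)
        rows.append((fold_i, acc, auc, len(test_ids)))
    per_fold = pd.DataFrame(rows, columns=["fold", "accuracy", "auc", "n_test"])
    return EvalReport(variant=variant, per_fold=per_fold, seed=seed)


def external_evaluate(expression: OmicsMatrix, methylation: OmicsMatrix | None,
                      annotation: pd.DataFrame | None, loci: pd.DataFrame | None,
                      panel: BiomarkerPanel | None, external: OmicsMatrix,
                      variant: str = "BIO+EXP+EMETH", seed: int = 0,
                      selection: SelectionConfig | None = None,
                      normalize_external: bool = True):
    """Train on the full internal cohort, predict a quantile-normalized
    external cohort. Returns ``(accuracy, auc, fitted_pipeline)``."""
    promoter_map = None
    if methylation is not None and annotation is not None and loci is not None:
        promoter_map = diff.map_promoter_loci(annotation, loci)
    if selection is None:
        selection = SelectionConfig(seed=seed)
    fitted = fit_pipeline(expression, methylation, promoter_map, panel,
                          variant, selection)
    ext = quantile_normalize(external, expression) if normalize_external else external
    pred = fitted.classifier.predict(ext)
    acc, auc = _evaluate_predictions(pred, ext.labels)
    return acc, auc, fitted


@dataclass
class VariantComparison:
    reports: dict[str, EvalReport]
    external: pd.DataFrame  # variant, accuracy, auc, n_genes

    def ranking(self) -> pd.DataFrame:
        rows = []
        for v, rep in self.reports.items():
            ext = self.external.set_index("variant")
            rows.append((v, rep.mean_accuracy, rep.mean_auc,
                         ext.at[v, "accuracy"], ext.at[v, "auc"]))
        out = pd.DataFrame(rows, columns=["variant", "cv_accuracy", "cv_auc",
                                          "external_accuracy", "external_auc"])
        return out.sort_values("external_accuracy", ascending=False).reset_index(drop=True)


def compare_variants(expression: OmicsMatrix, meth_expanded: OmicsMatrix | None,
                     meth_original: OmicsMatrix | None,
                     annotation: pd.DataFrame | None, loci: pd.DataFrame | None,
                     panel: BiomarkerPanel | None, external: OmicsMatrix,
                     variants=VARIANTS, k: int = 10, seed: int = 0,
                     selection: SelectionConfig | None = None) -> VariantComparison:
    """Run CV and external evaluation for several variants on the same folds.

    METH variants use ``meth_original`` (sparse-array stand-in); the EMETH
    variant uses ``meth_expanded``.
    """
    reports, ext_rows = {}, []
    for v in variants:
        meth = meth_expanded if v == "BIO+EXP+EMETH" else (
            meth_original if v in ("EXP+METH", "BIO+EXP+METH") else None)
        reports[v] = cross_validate(expression, meth, annotation, loci, panel,
                                    variant=v, k=k, seed=seed, selection=selection)
        acc, auc, fitted = external_evaluate(expression, meth, annotation, loci,
                                             panel, external, variant=v, seed=seed,
                                             selection=selection)
        ext_rows.append((v, acc, auc, len(fitted.signature)))
    external_df = pd.DataFrame(ext_rows, columns=["variant", "accuracy", "auc", "n_genes"])
    return VariantComparison(reports=reports, external=external_df)
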