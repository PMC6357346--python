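"""Statsmodels-style model facade over the integrative pipeline.

:class:`IntegrativeFuzzyModel` is built from the data (expression,
methylation, annotations, biomarker panel); :meth:`~IntegrativeFuzzyModel.fit`
runs differential calling, candidate intersection, biomarker-weighted
elastic-net selection and Mamdani rule induction, and returns an
:class:`IntegrativeFuzzyResults` carrying the signature, the rulebase, the
intermediate tables and a printable summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import diff
from .evaluate import EvalReport, cross_validate, external_evaluate
from .fuzzy import MamdaniFuzzyClassifier, export_rules
from .io_formats import BiomarkerPanel, OmicsMatrix
from .select import (VARIANTS, SelectionConfig, Signature, build_feature_set,
                     select_signature)


class IntegrativeFuzzyModel:
    """Integrative tumor/normal signature model.

    Parameters
    ----------
    expression : OmicsMatrix
        Gene expression, log2 scale (use :func:`fuzzsig.diff.log2_transform`
        on raw counts first).
    methylation : OmicsMatrix, optional
        CpG beta values; required by the METH/EMETH variants.
    annotation, loci : pandas.DataFrame, optional
        Gene TSS table and CpG coordinates (for promoter mapping).
    panel : BiomarkerPanel, optional
        Reported biomarkers to weight preferentially.
    variant : str
        One of BIO, EXP, EXP+METH, BIO+EXP+METH, BIO+EXP+EMETH.
    """

    def __init__(self, expression: OmicsMatrix, methylation: OmicsMatrix | None = None,
                 annotation: pd.DataFrame | None = None, loci: pd.DataFrame | None = None,
                 panel: BiomarkerPanel | None = None, variant: str = "BIO+EXP+EMETH"):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
        self.expression = expression
        self.methylation = methylation
        self.annotation = annotation
        self.loci = loci
        self.panel = panel
        self.variant = variant

    @classmethod
    def from_dataframes(cls, expression: pd.DataFrame, labels: pd.Series,
                        methylation: pd.DataFrame | None = None, **kw):
        meth = OmicsMatrix(methylation, labels) if methylation is not None else None
        return cls(OmicsMatrix(expression, labels), methylation=meth, **kw)

    def fit(self, selection: SelectionConfig | None = None,
            seed: int = 0) -> "IntegrativeFuzzyResults":
        selection = selection if selection is not None else SelectionConfig(seed=seed)
        needs_meth = self.variant in ("EXP+METH", "BIO+EXP+METH", "BIO+EXP+EMETH")
        degs = diff.call_deg(self.expression) if self.variant != "BIO" else None
        dmgs = dml = promoter_map = None
        if needs_meth:
            if self.methylation is None or self.annotation is None or self.loci is None:
                raise ValueError(f"variant {self.variant} requires methylation, "
                                 "annotation and loci")
            promoter_map = diff.map_promoter_loci(self.annotation, self.loci)
            dml = diff.call_dml(self.methylation)
            dmgs = diff.call_dmg(dml, promoter_map)
        panel_genes = tuple(self.panel.genes) if self.panel is not None else ()
        features, weighted = build_feature_set(self.variant, degs, dmgs, panel_genes)
        signature = select_signature(self.expression, features,
                                     self.panel if weighted else None, selection,
                                     provenance=self.variant,
                                     use_panel_weighting=weighted)
        clf = MamdaniFuzzyClassifier().fit(self.expression, signature.genes)
        return IntegrativeFuzzyResults(model=self, signature=signature,
                                       classifier=clf, deg_table=degs,
                                       dml_table=dml, dmg_table=dmgs)

    def cross_validate(self, k: int = 10, seed: int = 0,
                       selection: SelectionConfig | None = None) -> EvalReport:
        return cross_validate(self.expression, self.methylation, self.annotation,
                              self.loci, self.panel, variant=self.variant,
                              k=k, seed=seed, selection=selection)


@dataclass
class IntegrativeFuzzyResults:
    """Fitted signature + rulebase with the intermediate differential tables."""

    model: IntegrativeFuzzyModel
    signature: Signature
    classifier: MamdaniFuzzyClassifier
    deg_table: pd.DataFrame | None
    dml_table: pd.DataFrame | None
    dmg_table: pd.DataFrame | None

    def predict(self, expression: OmicsMatrix) -> pd.DataFrame:
        return self.classifier.predict(expression)

    def evaluate_external(self, external: OmicsMatrix, seed: int = 0):
        acc, auc, _ = external_evaluate(
            self.model.expression, self.model.methylation, self.model.annotation,
            self.model.loci, self.model.panel, external,
            variant=self.model.variant, seed=seed)
        return acc, auc

    def rules_text(self) -> str:
        return export_rules(self.classifier.rulebase_)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Integrative fuzzy signature model",
            "=" * 48,
            f"variant:            {m.variant}",
            f"samples:            {m.expression.n_tumor} tumor / "
            f"{m.expression.n_normal} normal",
            f"genes in matrix:    {len(m.expression.feature_ids)}",
        ]
        if self.deg_table is not None:
            lines.append(f"DEGs called:        {int(self.deg_table['is_deg'].sum())}")
        if self.dmg_table is not None:
            lines.append(f"DMGs called:        {int(self.dmg_table['is_dmg'].sum())}")
        lines += [
            f"signature size:     {len(self.signature)}",
            f"lambda chosen:      {self.signature.lambda_chosen:.6g}",
            f"fuzzy rules:        {len(self.classifier.rulebase_.rules)}",
            "",
            "signature genes (coefficient, biomarker):",
        ]
        for g, c, b in zip(self.signature.genes, self.signature.coefficients,
                           self.signature.is_biomarker):
            lines.append(f"  {g:<12s} {c:+.4f}  {'*' if b else ''}")
        return "\n".join(lines)
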