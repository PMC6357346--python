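"""Candidate construction and biomarker-weighted elastic-net signature selection.

The candidate feature set is the intersection of the DEG and DMG calls — genes
that are simultaneously differentially expressed and differentially methylated.
The final signature is chosen by an elastic-net-penalized logistic regression
(tumor vs normal) over the candidates plus the reported biomarker panel, in
which panel genes receive a reduced per-feature penalty multiplier so prior
knowledge is preferentially retained.

Per-feature penalty multipliers are realized by the standard scaling device:
column j is divided by its multiplier w_j before the unweighted fit and the
coefficient multiplied back afterwards. This places w_j on the L1 term and
w_j^2 on the L2 term of the elastic net; with the default mixing alpha = 0.5
the practical effect is the intended one — panel genes are shrunk less, and a
multiplier near 0 leaves them essentially unpenalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .io_formats import TUMOR, BiomarkerPanel, OmicsMatrix

#: floor for penalty multipliers: keeps the 1/w column scaling well conditioned
#: for the solver while leaving floored features effectively unpenalized;
#: multiplier 0 ("force inclusion") is mapped here
MIN_PENALTY = 0.01

VARIANTS = ("BIO", "EXP", "EXP+METH", "BIO+EXP+METH", "BIO+EXP+EMETH")


@dataclass(frozen=True)
class SelectionConfig:
    """Settings of the elastic-net selection step.

    ``alpha`` is the L1/L2 mixing parameter; ``biomarker_penalty`` the penalty
    multiplier applied to panel genes (non-panel genes always get 1); the
    regularization strength is chosen on ``lambda_grid`` by seeded stratified
    ``n_cv_folds``-fold CV minimizing the binomial deviance.
    """

    alpha: float = 0.5
    biomarker_penalty: float = 0.1
    lambda_grid: tuple[float, ...] | None = None
    n_lambda: int = 25
    n_cv_folds: int = 5
    lambda_rule: str = "min"  # or "1se"
    max_iter: int = 10000
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if not 0.0 <= self.biomarker_penalty <= 1.0:
            raise ValueError("biomarker_penalty must lie in [0, 1] "
                             "(never larger than the default multiplier 1)")
        if self.lambda_rule not in ("min", "1se"):
            raise ValueError(f"lambda_rule must be min|1se, got {self.lambda_rule!r}")


@dataclass(frozen=True)
class Signature:
    """Genes with nonzero coefficients at the CV-chosen regularization."""

    genes: tuple[str, ...]
    coefficients: tuple[float, ...]
    lambda_chosen: float
    provenance: str = "BIO+EXP+EMETH"
    is_biomarker: tuple[bool, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.genes)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "coefficient": self.coefficients,
                             "is_biomarker": self.is_biomarker})


def candidate_features(degs: pd.DataFrame, dmgs: pd.DataFrame) -> set[str]:
    """Genes called both DEG and DMG (the integrative candidate set)."""
    d = set(degs.loc[degs["is_deg"], "gene"])
    m = set(dmgs.loc[dmgs["is_dmg"], "gene"])
    return d & m


def build_feature_set(variant: str, degs: pd.DataFrame | None,
                      dmgs: pd.DataFrame | None,
                      panel_genes: tuple[str, ...]) -> tuple[set[str], bool]:
    """Feature-set constructor for the five model variants.

    Returns ``(feature_genes, use_panel_weighting)``. BIO uses the panel only;
    EXP the DEGs only; EXP+METH the DEG-and-DMG intersection; the BIO+ variants
    add the panel and switch the biomarker penalty weighting on. EMETH vs METH
    differ only in which methylation matrix produced ``dmgs``.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    if variant == "BIO":
        return set(panel_genes), False
    if degs is None:
        raise ValueError(f"variant {variant} requires DEG results")
    if variant == "EXP":
        return set(degs.loc[degs["is_deg"], "gene"]), False
    if dmgs is None:
        raise ValueError(f"variant {variant} requires DMG results")
    cand = candidate_features(degs, dmgs)
    if variant == "EXP+METH":
        return cand, False
    return cand | set(panel_genes), True  # BIO+EXP+METH, BIO+EXP+EMETH


def _lambda_grid(X: np.ndarray, y: np.ndarray, alpha: float, n_lambda: int):
    # glmnet-style decreasing grid from the smallest lambda that zeroes all
    # coefficients down to 1e-4 of it
    n = X.shape[0]
    resid = y - y.mean()
    lam_max = np.abs(X.T @ resid).max() / (n * max(alpha, 1e-3))
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * 1e-4, n_lambda)


def select_signature(log_expression: OmicsMatrix, candidates: set[str],
                     panel: BiomarkerPanel | None,
                     config: SelectionConfig = SelectionConfig(),
                     provenance: str = "BIO+EXP+EMETH",
                     use_panel_weighting: bool = True) -> Signature:
    """Fit the biomarker-weighted elastic net and return the nonzero support.

    The feature set is ``candidates`` plus the panel genes present in the
    matrix. Features are standardized internally; coefficients are reported on
    the original scale. Regularization is chosen by seeded stratified CV
    minimizing deviance (``lambda_rule="min"``; ``"1se"`` picks the sparsest
    model within one standard error).
    """
    config.validate()
    panel_genes = tuple(panel.genes) if panel is not None else ()
    present = set(log_expression.feature_ids)
    if not candidates and panel_genes:
        warnings.warn("candidate set is empty; selecting among biomarker panel genes only")
    features = sorted((set(candidates) | set(panel_genes)) & present)
    if len(features) < 2:
        raise ValueError(f"need >= 2 features present in the matrix, got {len(features)}")

    X = log_expression.values.loc[features].to_numpy(float).T
    y = np.asarray([1.0 if log_expression.labels[s] == TUMOR else 0.0
                    for s in log_expression.sample_ids])
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for signature selection")

    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    is_bio = np.array([g in set(panel_genes) for g in features])
    w = np.ones(len(features))
    if use_panel_weighting:
        w[is_bio] = max(config.biomarker_penalty, MIN_PENALTY)
    Xw = Xs / w  # penalty multipliers via the 1/w column-scaling device

    if config.lambda_grid is not None:
        lambdas = np.asarray(sorted(config.lambda_grid, reverse=True), float)
    else:
        lambdas = _lambda_grid(Xw, y, config.alpha, config.n_lambda)
    n = X.shape[0]
    Cs = 1.0 / (n * lambdas)

    n_folds = int(min(config.n_cv_folds, np.bincount(y.astype(int)).min()))
    if n_folds < 2:
        raise ValueError("each class needs >= 2 samples for internal CV")
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=config.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # saga convergence chatter on coarse grid ends
        model = LogisticRegressionCV(
            Cs=Cs, cv=cv, penalty="elasticnet", solver="saga",
            l1_ratios=[config.alpha], scoring="neg_log_loss",
            max_iter=config.max_iter, tol=1e-7, random_state=config.seed,
            refit=True, n_jobs=1,
        ).fit(Xw, y)

    if config.lambda_rule == "1se":
        # scores_: fold x Cs (x l1_ratio); pick sparsest lambda within 1 SE
        sc = model.scores_[1.0].reshape(n_folds, len(Cs), -1)[:, :, 0]
        mean, se = sc.mean(axis=0), sc.std(axis=0, ddof=1) / np.sqrt(n_folds)
        best = int(np.argmax(mean))
        ok = np.where(mean >= mean[best] - se[best])[0]
        idx = int(ok.min())  # smallest C = largest lambda = sparsest
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from sklearn.linear_model import LogisticRegression
            refit = LogisticRegression(
                C=Cs[idx], penalty="elasticnet", solver="saga",
                l1_ratio=config.alpha, max_iter=config.max_iter, tol=1e-7,
                random_state=config.seed).fit(Xw, y)
        coef_scaled = refit.coef_.ravel()
        lam = float(lambdas[idx])
    else:
        coef_scaled = model.coef_.ravel()
        lam = float(1.0 / (n * model.C_[0]))

    coef = coef_scaled / w / sd  # back to the original scale
    keep = np.abs(coef) > 1e-10
    return Signature(
        genes=tuple(np.array(features)[keep]),
        coefficients=tuple(coef[keep]),
        lambda_chosen=lam,
        provenance=provenance,
        is_biomarker=tuple(bool(b) for b in is_bio[keep]),
    )
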