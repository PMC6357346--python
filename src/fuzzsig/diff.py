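"""Differential expression and methylation calling.

Implements the three feature-level tests the signature pipeline is built on:

* DEG — per-gene Welch t-test on log2 expression, gene flagged when the
  absolute mean log2 difference exceeds 1 (two-fold) and the BH-adjusted
  p-value is below 0.01;
* DML — per-CpG Welch t-test on beta values, locus flagged when adjusted
  p < 0.01 and the absolute tumor-normal beta difference exceeds 0.1;
* DMG — gene-level call obtained by Fisher's combined probability test over
  the raw p-values of all CpG loci in the gene's promoter (TSS-1500..TSS+500,
  reflected on the minus strand), gated on the promoter containing at least
  one DML, with BH q-values computed across the gated genes.

"Adjusted p-value" defaults to Benjamini-Hochberg throughout; the original
description never names the procedure, so Bonferroni is available as an
alternative. Welch's (unequal-variance) t-test is used rather than the pooled
test — the robust default for the unequal group sizes typical of tumor/normal
cohorts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import NORMAL, TUMOR, OmicsMatrix

#: smallest p-value allowed into the Fisher log-sum (keeps the statistic finite)
P_FLOOR = 1e-300

DEFAULT_LFC_THRESHOLD = 1.0
DEFAULT_DELTA_BETA = 0.1
DEFAULT_P_ADJ = 0.01
DEFAULT_Q_DMG = 0.01
PROMOTER_UPSTREAM = 1500
PROMOTER_DOWNSTREAM = 500


def log2_transform(expression: OmicsMatrix, pseudocount: float = 1.0,
                   already_logged: bool = False) -> OmicsMatrix:
    """Return ``log2(v + pseudocount)`` element-wise; identity if already logged."""
    if already_logged:
        return expression
    arr = expression.values.to_numpy()
    if (arr < 0).any():
        r, c = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"negative expression value at {expression.values.index[r]!r}, "
            f"{expression.values.columns[c]!r}; raw counts must be non-negative"
        )
    out = pd.DataFrame(np.log2(arr + pseudocount),
                       index=expression.values.index, columns=expression.values.columns)
    return OmicsMatrix(out, expression.labels.copy())


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    key = {"bh": "fdr_bh", "fdr_bh": "fdr_bh", "bonferroni": "bonferroni"}[method.lower()]
    return multipletests(p, method=key)[1]


def _welch_by_row(values: pd.DataFrame, tumor: list[str], normal: list[str]):
    """Row-wise Welch t-test; zero-variance-in-both rows get p = 1 by convention."""
    xt = values[tumor].to_numpy(float)
    xn = values[normal].to_numpy(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # 0/0 in degenerate rows handled below
        res = stats.ttest_ind(xt, xn, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, float)
    p[np.isnan(p)] = 1.0
    return xt.mean(axis=1), xn.mean(axis=1), p


def _check_groups(mat: OmicsMatrix):
    tumor, normal = mat.samples_of(TUMOR), mat.samples_of(NORMAL)
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError(
            f"need >= 2 samples per class, got {len(tumor)} tumor / {len(normal)} normal"
        )
    return tumor, normal


def call_deg(log_expression: OmicsMatrix, lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
             p_adj_threshold: float = DEFAULT_P_ADJ, p_adj_method: str = "bh") -> pd.DataFrame:
    """Call differentially expressed genes on a log2-scale matrix.

    Returns one row per gene with columns ``gene, mean_tumor, mean_normal,
    log2fc, p, p_adj, is_deg`` where
    ``is_deg == (|log2fc| > lfc_threshold) & (p_adj < p_adj_threshold)``.
    """
    tumor, normal = _check_groups(log_expression)
    mt, mn, p = _welch_by_row(log_expression.values, tumor, normal)
    p_adj = _adjust(p, p_adj_method)
    lfc = mt - mn
    return pd.DataFrame({
        "gene": log_expression.feature_ids,
        "mean_tumor": mt, "mean_normal": mn, "log2fc": lfc,
        "p": p, "p_adj": p_adj,
        "is_deg": (np.abs(lfc) > lfc_threshold) & (p_adj < p_adj_threshold),
    })


def call_dml(methylation: OmicsMatrix, delta_beta_threshold: float = DEFAULT_DELTA_BETA,
             p_adj_threshold: float = DEFAULT_P_ADJ, p_adj_method: str = "bh") -> pd.DataFrame:
    """Call differentially methylated CpG loci on a beta-value matrix.

    Returns one row per locus with columns ``locus, delta_beta, p, p_adj,
    is_dml`` where ``is_dml == (p_adj < p_adj_threshold) &
    (|delta_beta| > delta_beta_threshold)``.
    """
    methylation.validate_betas()
    tumor, normal = _check_groups(methylation)
    mt, mn, p = _welch_by_row(methylation.values, tumor, normal)
    p_adj = _adjust(p, p_adj_method)
    db = mt - mn
    return pd.DataFrame({
        "locus": methylation.feature_ids,
        "delta_beta": db, "p": p, "p_adj": p_adj,
        "is_dml": (p_adj < p_adj_threshold) & (np.abs(db) > delta_beta_threshold),
    })


def map_promoter_loci(annotation: pd.DataFrame, loci: pd.DataFrame,
                      upstream: int = PROMOTER_UPSTREAM,
                      downstream: int = PROMOTER_DOWNSTREAM,
                      stranded: bool = True) -> dict[str, list[str]]:
    """Assign CpG loci to gene promoters.

    A locus maps to gene *g* iff it lies in ``[tss-upstream, tss+downstream]``
    on the + strand, or the strand-reflected window ``[tss-downstream,
    tss+upstream]`` on the - strand, inclusive at both ends. One locus may map
    to several genes with overlapping promoters. With ``stranded=False`` every
    gene uses the + strand window.
    """
    out: dict[str, list[str]] = {}
    by_chrom = {c: sub for c, sub in loci.groupby("chrom")}
    for row in annotation.itertuples(index=False):
        sub = by_chrom.get(row.chrom)
        if sub is None:
            continue
        if stranded and row.strand == "-":
            lo, hi = row.tss - downstream, row.tss + upstream
        else:
            lo, hi = row.tss - upstream, row.tss + downstream
        pos = sub["pos"].to_numpy()
        hit = sub["locus"].to_numpy()[(pos >= lo) & (pos <= hi)]
        if hit.size:
            out[row.gene] = list(hit)
    return out


def fisher_combine(pvalues) -> tuple[float, float]:
    """Fisher's combined probability test.

    Returns ``(stat, p)`` with ``stat = -2 * sum(ln p_i)`` referred to a
    chi-square distribution with ``2k`` degrees of freedom. Zero p-values are
    clamped to 1e-300 with a warning so the statistic stays finite.
    """
    p = np.asarray(list(pvalues), float)
    if p.size == 0:
        raise ValueError("fisher_combine requires at least one p-value")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if (p == 0).any():
        warnings.warn("p-value of 0 clamped to 1e-300 in Fisher combination")
        p = np.maximum(p, P_FLOOR)
    stat = float(-2.0 * np.log(p).sum())
    return stat, float(stats.chi2.sf(stat, df=2 * p.size))


def call_dmg(dml: pd.DataFrame, promoter_map: dict[str, list[str]],
             q_threshold: float = DEFAULT_Q_DMG, combine: str = "all_loci",
             p_adj_method: str = "bh") -> pd.DataFrame:
    """Call differentially methylated genes from locus results and a promoter map.

    For each gene with >= 1 promoter locus the raw locus p-values are combined
    with Fisher's test (``combine="all_loci"`` uses every promoter locus — the
    default, matching the rationale that one inaccurate locus should not flip a
    promoter; ``"dml_only"`` restricts to flagged loci). q-values are BH values
    computed across the genes with at least one DML; a gene with no DML is never
    a DMG. ``is_dmg == (n_dml >= 1) & (q < q_threshold)``.
    """
    if not promoter_map:
        raise ValueError("promoter map is empty; no gene has promoter loci")
    if combine not in ("all_loci", "dml_only"):
        raise ValueError(f"combine must be all_loci|dml_only, got {combine!r}")
    pmap = dml.set_index("locus")
    rows = []
    for gene, loci in promoter_map.items():
        known = [l for l in loci if l in pmap.index]
        if not known:
            warnings.warn(f"gene {gene!r} has promoter loci but none with test results; excluded")
            continue
        sub = pmap.loc[known]
        n_dml = int(sub["is_dml"].sum())
        use = sub.loc[sub["is_dml"], "p"] if combine == "dml_only" and n_dml else sub["p"]
        stat, p_comb = fisher_combine(use.to_numpy())
        rows.append((gene, len(known), n_dml, stat, p_comb))
    res = pd.DataFrame(rows, columns=["gene", "n_promoter_loci", "n_dml", "fisher_stat", "fisher_p"])
    res["q"] = np.nan
    gated = res["n_dml"] >= 1
    if gated.any():
        res.loc[gated, "q"] = _adjust(res.loc[gated, "fisher_p"].to_numpy(), p_adj_method)
    res["is_dmg"] = gated & (res["q"] < q_threshold)
    return res
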