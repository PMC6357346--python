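"""Paired synthetic expression/methylation data with planted ground truth.

Generates the statistical structure the downstream pipeline assumes:

* log2 expression per gene: normals draw from Normal(baseline_g, sd); tumors
  of planted DEGs are shifted by ``expr_effect`` with a random sign per gene;
* beta-value methylation per promoter CpG: Beta-distributed around a
  locus-specific mean with precision ``meth_concentration``; planted DMG
  promoters shift a random (>= 1) subset of their CpGs by ``meth_effect``,
  direction random per gene, means clipped away from the [0, 1] boundary;
* gene annotations on synthetic chromosomes with widely spaced TSSs, CpGs
  placed inside each gene's promoter window plus a configurable fraction of
  decoy loci outside any promoter (these exercise the interval filter);
* planted biomarker genes, drawn from the joint DEG-and-DMG set so that the
  panel is genuine signal.

Each data type (design, expression, methylation, annotation) uses its own RNG
stream spawned from the master seed, so changing one component's parameters
leaves the others' draws untouched. Identical configs produce bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (NORMAL, TUMOR, OmicsMatrix, write_annotation,
                         write_labels, write_loci, write_matrix)


class SynthConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one simulated paired dataset.

    Fractions are of ``n_genes``; ``frac_joint`` genes are planted as both DEG
    and DMG (the candidate-set ground truth). ``expr_effect`` is a mean log2
    shift; ``meth_effect`` a beta shift in (0.1, 0.5] so planted DMGs exceed
    the delta-beta call threshold in expectation.
    """

    n_tumor: int = 30
    n_normal: int = 30
    n_genes: int = 400
    cpgs_per_promoter: float = 3.0  # Poisson mean; genes may draw 0 loci
    frac_deg: float = 0.10
    frac_dmg: float = 0.10
    frac_joint: float = 0.05
    expr_effect: float = 3.0
    meth_effect: float = 0.4
    expr_noise_sd: float = 0.5
    meth_concentration: float = 60.0
    frac_decoy_loci: float = 0.10
    n_biomarkers: int = 5
    baseline_range: tuple[float, float] = (2.0, 10.0)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_tumor", "n_normal", "n_genes"):
            if getattr(self, name) < 1:
                raise SynthConfigError(f"{name} must be >= 1")
        for name in ("frac_deg", "frac_dmg", "frac_joint", "frac_decoy_loci"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SynthConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.frac_joint > min(self.frac_deg, self.frac_dmg):
            raise SynthConfigError("frac_joint cannot exceed min(frac_deg, frac_dmg)")
        if self.frac_deg + self.frac_dmg - self.frac_joint > 1.0:
            raise SynthConfigError("frac_deg + frac_dmg - frac_joint must be <= 1")
        if self.expr_noise_sd <= 0:
            raise SynthConfigError("expr_noise_sd must be positive")
        if self.meth_concentration <= 0:
            raise SynthConfigError("meth_concentration must be positive")
        if self.cpgs_per_promoter <= 0:
            raise SynthConfigError("cpgs_per_promoter must be positive")
        if self.n_biomarkers < 0:
            raise SynthConfigError("n_biomarkers must be >= 0")


@dataclass(frozen=True)
class SynthTruth:
    """Ground truth of a simulated dataset."""

    deg_genes: frozenset[str]
    dmg_genes: frozenset[str]
    biomarker_genes: frozenset[str]
    locus_gene_map: dict[str, str] = field(default_factory=dict, compare=False)
    deg_sign: dict[str, int] = field(default_factory=dict, compare=False)

    @property
    def joint_genes(self) -> frozenset[str]:
        return self.deg_genes & self.dmg_genes


def _streams(seed: int):
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(4)]


def simulate_dataset(config: SynthConfig):
    """Simulate one paired dataset.

    Returns ``(expression, methylation, annotation, loci, truth)`` where
    expression/methylation are :class:`OmicsMatrix`, annotation is the gene
    TSS table, loci the CpG coordinate table and truth the planted signal.
    Expression values are already on the log2 scale.
    """
    config.validate()
    rng_design, rng_expr, rng_meth, rng_ann = _streams(config.seed)

    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    samples = ([f"T{i:03d}" for i in range(config.n_tumor)]
               + [f"N{i:03d}" for i in range(config.n_normal)])
    labels = pd.Series([TUMOR] * config.n_tumor + [NORMAL] * config.n_normal,
                       index=samples)

    # annotation: genes spaced 100 kb apart on synthetic chromosomes, so
    # promoter windows never overlap
    n_per_chrom = 100
    ann = pd.DataFrame({
        "gene": genes,
        "chrom": [f"chr{1 + i // n_per_chrom}" for i in range(config.n_genes)],
        "tss": [100_000 * (1 + i % n_per_chrom) for i in range(config.n_genes)],
        "strand": rng_ann.choice(["+", "-"], size=config.n_genes),
    })

    # promoter CpGs
    cpg_counts = rng_ann.poisson(config.cpgs_per_promoter, size=config.n_genes)
    locus_rows, locus_gene = [], {}
    k = 0
    for g, chrom, tss, strand, cnt in zip(ann["gene"], ann["chrom"], ann["tss"],
                                          ann["strand"], cpg_counts):
        lo, hi = (tss - 1500, tss + 500) if strand == "+" else (tss - 500, tss + 1500)
        for pos in np.sort(rng_ann.integers(lo, hi + 1, size=cnt)):
            lid = f"cg{k:06d}"
            locus_rows.append((chrom, int(pos), lid))
            locus_gene[lid] = g
            k += 1
    # decoy loci in intergenic space (at least 5 kb from any TSS window)
    n_decoy = int(round(config.frac_decoy_loci * max(1, len(locus_rows))))
    for _ in range(n_decoy):
        i = int(rng_ann.integers(0, config.n_genes))
        chrom = f"chr{1 + i // n_per_chrom}"
        pos = int(100_000 * (1 + i % n_per_chrom) + rng_ann.integers(10_000, 50_000))
        locus_rows.append((chrom, pos, f"cg{k:06d}"))
        k += 1
    loci = pd.DataFrame(locus_rows, columns=["chrom", "pos", "locus"])

    # planted gene sets: joint first, then disjoint DEG-only / DMG-only
    n_joint = int(round(config.frac_joint * config.n_genes))
    n_deg = int(round(config.frac_deg * config.n_genes))
    n_dmg = int(round(config.frac_dmg * config.n_genes))
    with_cpg = [g for g, c in zip(genes, cpg_counts) if c >= 1]
    if n_dmg > len(with_cpg):
        raise SynthConfigError("frac_dmg asks for more DMGs than genes with promoter CpGs")
    joint = list(rng_design.choice(with_cpg, size=n_joint, replace=False))
    rest_for_dmg = [g for g in with_cpg if g not in set(joint)]
    dmg_only = list(rng_design.choice(rest_for_dmg, size=n_dmg - n_joint, replace=False))
    rest_for_deg = [g for g in genes if g not in set(joint) | set(dmg_only)]
    deg_only = list(rng_design.choice(rest_for_deg, size=n_deg - n_joint, replace=False))
    deg_genes = frozenset(joint) | frozenset(deg_only)
    dmg_genes = frozenset(joint) | frozenset(dmg_only)
    n_bio = min(config.n_biomarkers, n_joint)
    biomarkers = frozenset(rng_design.choice(joint, size=n_bio, replace=False)) if n_bio else frozenset()
    deg_sign = {g: int(s) for g, s in
                zip(sorted(deg_genes), rng_design.choice([-1, 1], size=len(deg_genes)))}

    # expression (log2 scale)
    lo_b, hi_b = config.baseline_range
    baseline = rng_expr.uniform(lo_b, hi_b, size=config.n_genes)
    expr = baseline[:, None] + rng_expr.normal(0.0, config.expr_noise_sd,
                                               size=(config.n_genes, len(samples)))
    tumor_cols = np.arange(config.n_tumor)
    for gi, g in enumerate(genes):
        if g in deg_genes:
            expr[gi, tumor_cols] += config.expr_effect * deg_sign[g]
    expression = OmicsMatrix(pd.DataFrame(expr, index=genes, columns=samples), labels)

    # methylation betas
    prom_ids = [lid for lid in loci["locus"] if lid in locus_gene]
    base_mean = {lid: m for lid, m in
                 zip(loci["locus"], rng_meth.uniform(0.15, 0.85, size=len(loci)))}
    dmg_dir = {g: int(s) for g, s in
               zip(sorted(dmg_genes), rng_meth.choice([-1, 1], size=len(dmg_genes)))}
    # per DMG promoter: shift a random subset (>= 1) of its CpGs
    shifted: set[str] = set()
    by_gene: dict[str, list[str]] = {}
    for lid in prom_ids:
        by_gene.setdefault(locus_gene[lid], []).append(lid)
    for g in sorted(dmg_genes):
        ids = by_gene[g]
        n_shift = int(rng_meth.integers(1, len(ids) + 1))
        shifted.update(rng_meth.choice(ids, size=n_shift, replace=False))

    c = config.meth_concentration
    beta = np.empty((len(loci), len(samples)))
    for li, lid in enumerate(loci["locus"]):
        m = np.full(len(samples), base_mean[lid])
        if lid in shifted:
            m[tumor_cols] = np.clip(m[tumor_cols] + config.meth_effect
                                    * dmg_dir[locus_gene[lid]], 0.02, 0.98)
        beta[li] = rng_meth.beta(m * c, (1.0 - m) * c)
    methylation = OmicsMatrix(
        pd.DataFrame(beta, index=list(loci["locus"]), columns=samples), labels)
    methylation.validate_betas()

    truth = SynthTruth(deg_genes=deg_genes, dmg_genes=dmg_genes,
                       biomarker_genes=biomarkers, locus_gene_map=locus_gene,
                       deg_sign=deg_sign)
    return expression, methylation, ann, loci, truth


def subsample_loci(methylation: OmicsMatrix, loci: pd.DataFrame,
                   frac: float = 1.0 / 18.0, seed: int = 0):
    """Emulate a sparse-array methylation profile: keep a random locus subset.

    The default fraction mirrors the ~18x coverage difference between an
    expanded genome-wide profile and a 450K-style array.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 11)))
    n_keep = max(2, int(round(frac * len(methylation.feature_ids))))
    keep = sorted(rng.choice(methylation.feature_ids, size=n_keep, replace=False))
    return methylation.subset_features(keep), loci[loci["locus"].isin(keep)].copy()


def add_expansion_noise(methylation: OmicsMatrix, sd: float = 0.05,
                        seed: int = 0) -> OmicsMatrix:
    """Perturb betas with truncated Gaussian noise, emulating the ~90%
    per-locus accuracy of a computational methylation-expansion step."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 13)))
    vals = methylation.values.to_numpy()
    noisy = np.clip(vals + rng.normal(0.0, sd, size=vals.shape), 0.0, 1.0)
    return OmicsMatrix(pd.DataFrame(noisy, index=methylation.values.index,
                                    columns=methylation.values.columns),
                       methylation.labels.copy())


def simulate_external(config: SynthConfig, truth: SynthTruth,
                      unstable_genes=frozenset(), n_tumor: int | None = None,
                      n_normal: int | None = None, seed_offset: int = 1000,
                      batch_shift: float = 1.0) -> OmicsMatrix:
    """Simulate an independent expression cohort for external validation.

    Planted DEGs keep their internal effect except for ``unstable_genes``,
    whose effect is reversed — emulating expression-only hits that do not
    reproduce outside the discovery cohort. A constant ``batch_shift`` is
    added to every value to emulate a platform/batch offset (removed by
    quantile normalization downstream).
    """
    cfg = replace(config,
                  n_tumor=n_tumor if n_tumor is not None else config.n_tumor,
                  n_normal=n_normal if n_normal is not None else config.n_normal)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed + seed_offset, 7)))
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    samples = ([f"XT{i:03d}" for i in range(cfg.n_tumor)]
               + [f"XN{i:03d}" for i in range(cfg.n_normal)])
    labels = pd.Series([TUMOR] * cfg.n_tumor + [NORMAL] * cfg.n_normal, index=samples)
    # baseline redrawn from the same stream definition as the internal cohort,
    # so per-gene levels agree up to the batch shift
    _, rng_expr, _, _ = _streams(config.seed)
    lo_b, hi_b = cfg.baseline_range
    baseline = rng_expr.uniform(lo_b, hi_b, size=cfg.n_genes)
    expr = (baseline[:, None] + batch_shift
            + rng.normal(0.0, cfg.expr_noise_sd, size=(cfg.n_genes, len(samples))))
    tumor_cols = np.arange(cfg.n_tumor)
    for gi, g in enumerate(genes):
        if g in truth.deg_genes:
            sign = truth.deg_sign[g] * (-1 if g in unstable_genes else 1)
            expr[gi, tumor_cols] += cfg.expr_effect * sign
    return OmicsMatrix(pd.DataFrame(expr, index=genes, columns=samples), labels)


def write_dataset(outdir, expression: OmicsMatrix, methylation: OmicsMatrix,
                  annotation: pd.DataFrame, loci: pd.DataFrame,
                  truth: SynthTruth) -> None:
    """Write a simulated dataset in the formats the loaders read."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(expression, out / "expression.tsv")
    write_matrix(methylation, out / "methylation.tsv")
    write_labels(expression.labels, out / "labels.tsv")
    write_annotation(annotation, out / "annotation.tsv")
    write_loci(loci, out / "loci.tsv")
    for name, genes in (("deg", truth.deg_genes), ("dmg", truth.dmg_genes),
                        ("biomarkers", truth.biomarker_genes)):
        (out / f"truth_{name}.txt").write_text("\n".join(sorted(genes)) + "\n")
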