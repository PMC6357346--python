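"""Readers and writers for omics matrices, annotations, labels and biomarker panels.

The on-disk formats are deliberately plain:

* matrices — TSV/CSV (auto-detected by extension, gzip-transparent), header row of
  sample ids, first column feature ids;
* gene annotations — 4-column BED-like TSV ``chrom  tss  gene  strand``;
* CpG locus coordinates — 3-column TSV ``chrom  pos  locus``;
* sample labels — 2-column TSV ``sample_id  {tumor,normal}``;
* biomarker panels — one gene symbol per line.

The module also ships the published per-cancer biomarker panels, the published
DEG/DMG count table, and the published per-cancer signatures as package data.
Gene symbols are opaque case-sensitive strings; no alias resolution is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

TUMOR = "tumor"
NORMAL = "normal"
VALID_LABELS = (TUMOR, NORMAL)

#: cancers with packaged biomarker panels
PACKAGED_CANCERS = ("BRCA", "PRAD", "LIHC", "HNSC", "KIRP", "THCA")


class FormatError(ValueError):
    """Malformed input file (duplicate ids, bad line, missing values...)."""


@dataclass
class OmicsMatrix:
    """A features x samples numeric matrix with tumor/normal sample labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are features (genes or CpG loci), columns are samples.
    labels : pandas.Series
        Maps every sample id to ``"tumor"`` or ``"normal"``.
    """

    values: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels)
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate feature id: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        missing = [s for s in self.values.columns if s not in self.labels.index]
        if missing:
            raise FormatError(f"samples without labels: {missing[:5]}")
        bad = set(self.labels.loc[list(self.values.columns)]) - set(VALID_LABELS)
        if bad:
            raise FormatError(f"invalid sample labels: {sorted(bad)}")
        if self.values.isna().any().any():
            r, c = np.argwhere(self.values.isna().to_numpy())[0]
            raise FormatError(
                f"missing value at feature {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}; NA cells are not permitted"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, label: str) -> list[str]:
        return [s for s in self.values.columns if self.labels[s] == label]

    @property
    def n_tumor(self) -> int:
        return len(self.samples_of(TUMOR))

    @property
    def n_normal(self) -> int:
        return len(self.samples_of(NORMAL))

    def subset_samples(self, sample_ids) -> "OmicsMatrix":
        ids = list(sample_ids)
        return OmicsMatrix(self.values[ids].copy(), self.labels.loc[ids].copy())

    def subset_features(self, feature_ids) -> "OmicsMatrix":
        ids = [f for f in feature_ids if f in self.values.index]
        return OmicsMatrix(self.values.loc[ids].copy(), self.labels.copy())

    def validate_betas(self) -> None:
        """Check all values lie in [0, 1] (methylation beta-value contract)."""
        arr = self.values.to_numpy()
        bad = np.argwhere((arr < 0.0) | (arr > 1.0))
        if bad.size:
            r, c = bad[0]
            raise FormatError(
                f"beta value {arr[r, c]!r} outside [0, 1] at locus "
                f"{self.values.index[r]!r}, sample {self.values.columns[c]!r}"
            )


@dataclass(frozen=True)
class BiomarkerPanel:
    """An ordered list of reported biomarker genes for one cancer."""

    cancer: str
    genes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.genes:
            raise FormatError(f"biomarker panel {self.cancer!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise FormatError(f"duplicate symbols in panel {self.cancer!r}")

    def __len__(self) -> int:
        return len(self.genes)


def _sep_for(path) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    return "," if name.endswith(".csv") else "\t"


def read_matrix(path, declared_type: str = "expression",
                labels_path=None, labels: pd.Series | None = None) -> OmicsMatrix:
    """Load a features x samples matrix with its sample labels.

    ``declared_type="methylation"`` additionally validates that every value is a
    beta value in [0, 1]. Labels come either from a companion 2-column TSV
    (``labels_path``) or a preloaded mapping (``labels``).
    """
    if declared_type not in ("expression", "methylation"):
        raise ValueError(f"declared_type must be expression|methylation, got {declared_type!r}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if labels is None:
        if labels_path is None:
            raise ValueError("either labels_path or labels is required")
        labels = read_labels(labels_path)
    mat = OmicsMatrix(df, labels)
    if declared_type == "methylation":
        mat.validate_betas()
    return mat


def write_matrix(mat: OmicsMatrix, path) -> None:
    mat.values.to_csv(path, sep=_sep_for(path))


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "label"], dtype=str)
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise FormatError(f"duplicate sample id in labels: {dup!r}")
    bad = set(df["label"]) - set(VALID_LABELS)
    if bad:
        raise FormatError(f"invalid labels {sorted(bad)}; expected {VALID_LABELS}")
    return df.set_index("sample")["label"]


def write_labels(labels: pd.Series, path) -> None:
    labels.rename_axis("sample").rename("label").to_csv(path, sep="\t", header=False)


def read_annotation(path) -> pd.DataFrame:
    """Read a 4-column BED-like TSV ``chrom  tss  gene  strand``.

    Coordinates are 1-based. Returns a DataFrame with columns
    ``gene, chrom, tss, strand`` (one row per gene, symbols unique).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom, tss_s, gene, strand = parts
            try:
                tss = int(tss_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: TSS {tss_s!r} is not an integer") from None
            if tss < 1:
                raise FormatError(f"{path}:{lineno}: TSS must be >= 1 (1-based)")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: strand must be + or -, got {strand!r}")
            rows.append((gene, chrom, tss, strand))
    ann = pd.DataFrame(rows, columns=["gene", "chrom", "tss", "strand"])
    if ann["gene"].duplicated().any():
        dup = ann.loc[ann["gene"].duplicated(), "gene"].iloc[0]
        raise FormatError(f"duplicate gene symbol in annotation: {dup!r}")
    return ann


def write_annotation(ann: pd.DataFrame, path) -> None:
    ann[["chrom", "tss", "gene", "strand"]].to_csv(path, sep="\t", header=False, index=False)


def read_loci(path) -> pd.DataFrame:
    """Read a 3-column TSV ``chrom  pos  locus`` of CpG coordinates (1-based)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos", "locus"],
                     dtype={"chrom": str, "locus": str})
    if df["locus"].duplicated().any():
        dup = df.loc[df["locus"].duplicated(), "locus"].iloc[0]
        raise FormatError(f"duplicate locus id: {dup!r}")
    return df


def write_loci(loci: pd.DataFrame, path) -> None:
    loci[["chrom", "pos", "locus"]].to_csv(path, sep="\t", header=False, index=False)


def _data_text(*parts: str) -> str:
    return resources.files("fuzzsig").joinpath("data", *parts).read_text()


def read_gene_list(path) -> tuple[str, ...]:
    genes = tuple(g.strip() for g in Path(path).read_text().splitlines() if g.strip())
    return genes


def load_biomarker_panel(cancer: str, path=None) -> BiomarkerPanel:
    """Return the packaged biomarker panel for ``cancer``, or load a custom list.

    Packaged panels exist for BRCA, PRAD, LIHC, HNSC, KIRP and THCA.
    """
    if path is not None:
        return BiomarkerPanel(cancer, read_gene_list(path))
    if cancer not in PACKAGED_CANCERS:
        raise KeyError(
            f"no packaged biomarker panel for {cancer!r}; valid labels: "
            f"{', '.join(PACKAGED_CANCERS)} (or pass path= for a custom list)"
        )
    genes = tuple(g for g in _data_text("biomarkers", f"{cancer}.txt").splitlines() if g)
    return BiomarkerPanel(cancer, genes)


def load_published_signature(cancer: str) -> tuple[str, ...]:
    """The published final gene signature for one of the six cancers."""
    if cancer not in PACKAGED_CANCERS:
        raise KeyError(f"no packaged signature for {cancer!r}")
    return tuple(g for g in _data_text("signatures", f"{cancer}.txt").splitlines() if g)


def load_dmg_count_table() -> pd.DataFrame:
    """Published per-cancer DEG/DMG counts (expanded vs original methylation).

    Columns: ``cancer, n_deg, n_dmg_expanded, n_dmg_original``.
    """
    from io import StringIO

    return pd.read_csv(StringIO(_data_text("dmg_counts.tsv")), sep="\t")
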