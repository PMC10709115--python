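"""Expression matrices: normalization, log transform, replicate collapse.

The analysis starts from a gene × sample abundance table (raw counts or
already-normalized values), a sample→species map, and optionally gene
lengths.  Counts can be normalized to CPM, RPKM, or TPM; values are then
log-transformed and replicates collapsed to per-species means with
standard errors — the trait vectors the phylogenetic models consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_TAGS = ("raw_counts", "CPM", "TPM", "RPKM", "log")


@dataclass
class ExpressionMatrix:
    """Gene × sample expression values with sample metadata.

    Parameters
    ----------
    values : DataFrame
        Rows are genes (unique ids), columns are samples. Missing entries
        are NaN; negative values are rejected (except under tag ``log``).
    sample_map : DataFrame
        Indexed by sample id with columns ``species`` and (optionally)
        ``tissue``. Every column of ``values`` must appear here.
    tag : str
        One of ``raw_counts, CPM, TPM, RPKM, log``.
    """

    values: pd.DataFrame
    sample_map: pd.DataFrame
    tag: str = "raw_counts"

    def __post_init__(self):
        if self.tag not in VALID_TAGS:
            raise ValueError(f"unknown normalization tag {self.tag!r}")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dupes)[:5]}")
        missing = [s for s in self.values.columns if s not in self.sample_map.index]
        if missing:
            raise ValueError(f"samples absent from sample map: {missing[:5]}")
        if "species" not in self.sample_map.columns:
            raise ValueError("sample map needs a 'species' column")
        if self.tag != "log" and (self.values.to_numpy() < 0).any():
            raise ValueError("negative expression values are not allowed")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def species_of(self, sample: str) -> str:
        return self.sample_map.loc[sample, "species"]

    def tissues(self) -> list:
        if "tissue" in self.sample_map.columns:
            return sorted(self.sample_map["tissue"].dropna().unique())
        return [None]


@dataclass
class TraitVector:
    """Per-species mean log-expression with standard errors for one gene.

    ``values`` and ``se`` are aligned Series indexed by species name; the
    SE is the standard error of the species mean on the log scale (0 for a
    single replicate) and enters the phylogenetic model as a fixed additive
    variance on the tip.
    """

    values: pd.Series
    se: pd.Series
    gene: str = ""
    tissue: str | None = None

    def __post_init__(self):
        self.values = self.values.astype(float)
        if self.se is None:
            self.se = pd.Series(0.0, index=self.values.index)
        self.se = self.se.reindex(self.values.index).fillna(0.0).astype(float)
        if (self.se < 0).any() or not np.isfinite(self.se).all():
            raise ValueError("standard errors must be finite and >= 0")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate species in trait vector")

    @property
    def species(self) -> list[str]:
        return list(self.values.index)

    def __len__(self) -> int:
        return len(self.values)

    def reorder(self, species: list[str]) -> "TraitVector":
        missing = [s for s in species if s not in self.values.index]
        if missing:
            raise KeyError(f"species without trait data: {missing}")
        return TraitVector(self.values.reindex(species), self.se.reindex(species),
                           gene=self.gene, tissue=self.tissue)


def normalize_counts(counts: ExpressionMatrix,
                     gene_lengths: pd.Series | dict | None = None,
                     method: str = "TPM") -> ExpressionMatrix:
    """Normalize raw counts to CPM, RPKM, or TPM.

    CPM_gs  = count_gs / libsize_s × 1e6
    RPKM_gs = count_gs / (libsize_s × length_g) × 1e9
    TPM_gs  = rate_gs / Σ_g rate_gs × 1e6,  rate_gs = count_gs / length_g

    Library size is the per-sample column sum over non-missing counts.
    TPM columns each sum to 1e6 by construction.
    """
    if counts.tag != "raw_counts":
        raise ValueError(f"normalize_counts expects raw counts, got {counts.tag!r}")
    method = method.upper()
    if method not in ("CPM", "RPKM", "TPM"):
        raise ValueError(f"unknown normalization method {method!r}")
    X = counts.values
    libsize = X.sum(axis=0, skipna=True)
    zero = libsize[libsize <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")

    if method == "CPM":
        out = X.div(libsize, axis=1) * 1e6
        return ExpressionMatrix(out, counts.sample_map, "CPM")

    lengths = pd.Series(gene_lengths) if gene_lengths is not None else None
    if lengths is None:
        raise ValueError(f"{method} requires gene lengths")
    missing = [g for g in X.index if g not in lengths.index]
    if missing:
        raise ValueError(f"gene length missing for: {missing[:5]}")
    lengths = lengths.reindex(X.index).astype(float)
    if (lengths <= 0).any():
        bad = list(lengths.index[lengths <= 0])
        raise ValueError(f"non-positive gene length for: {bad[:5]}")

    if method == "RPKM":
        out = X.div(lengths, axis=0).div(libsize, axis=1) * 1e9
        return ExpressionMatrix(out, counts.sample_map, "RPKM")

    rate = X.div(lengths, axis=0)
    out = rate.div(rate.sum(axis=0, skipna=True), axis=1) * 1e6
    return ExpressionMatrix(out, counts.sample_map, "TPM")


def log_transform(m: ExpressionMatrix, offset: float = 1.0,
                  base: float = 2.0) -> ExpressionMatrix:
    """log_base(value + offset); the conventional transform is log2(x + 1).

    A zero anywhere requires ``offset > 0``.
    """
    if m.tag == "log":
        raise ValueError("matrix is already log-transformed")
    if offset < 0:
        raise ValueError("offset must be >= 0")
    X = m.values
    if offset == 0 and (X.to_numpy() == 0).any():
        raise ValueError("zero expression values require a positive offset")
    out = np.log(X + offset) / np.log(base)
    return ExpressionMatrix(out, m.sample_map, "log")


def summarize_replicates(m: ExpressionMatrix, gene: str,
                         tissue: str | None = None) -> TraitVector:
    """Collapse replicate samples to per-species mean ± SE for one gene.

    Samples with a missing value for the gene are dropped; species with no
    remaining data are omitted (to be pruned from the tree downstream).
    SE = sample sd (n−1 denominator) / √n_reps; 0 for a single replicate.
    """
    if m.tag != "log":
        raise ValueError("summarize_replicates expects log-transformed values")
    if gene not in m.values.index:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    row = m.values.loc[gene]
    smap = m.sample_map
    if tissue is not None:
        if "tissue" not in smap.columns:
            raise ValueError("no tissue column in sample map")
        keep = smap.index[smap["tissue"] == tissue]
        row = row[row.index.intersection(keep)]
    # canonical sample order: per-species means must not depend on the
    # column order of the input table (floating-point summation order)
    row = row.dropna().sort_index()
    species = smap.loc[row.index, "species"]
    grouped = row.groupby(species.values)
    means = grouped.mean()
    n = grouped.count()
    sd = grouped.std(ddof=1)
    se = (sd / np.sqrt(n)).where(n > 1, 0.0)
    means.index.name = None
    return TraitVector(means.sort_index(), se.sort_index(), gene=gene, tissue=tissue)


# -- file I/O -----------------------------------------------------------

def read_expression_tsv(path, tag: str, sample_map: pd.DataFrame) -> ExpressionMatrix:
    """Read a gene × sample TSV (first column gene id, header row required)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, sample_map, tag)


def read_sample_map(path) -> pd.DataFrame:
    """Read a sample map TSV with columns sample_id, species[, tissue]."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns or "species" not in df.columns:
        raise ValueError("sample map needs columns 'sample_id' and 'species'")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in sample map")
    return df.set_index("sample_id")


def read_gene_lengths(path) -> pd.Series:
    """Read a gene length TSV with columns gene_id, length_bp."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns or "length_bp" not in df.columns:
        raise ValueError("gene length table needs columns 'gene_id' and 'length_bp'")
    return df.set_index("gene_id")["length_bp"].astype(float)
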