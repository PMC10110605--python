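"""Reading, validation and normalisation of triad expression data.

The analysis starts from gene-level read counts (genes x samples, TSV),
per-sample metadata (genotype, ploidy class, tissue, replicate, library
size) and a triad table mapping each 1:1:1 homoeologue set to its A, B and
D gene models with gene lengths in bp.  Expression is normalised to RPKM
(reads per kilobase of gene model per million mapped reads):

    RPKM = 1e9 * x / (l * N)

with x the raw count, l the gene length in bp and N the sample's total
mapped reads.  N is the whole-transcriptome library size supplied in the
metadata; when absent it falls back to the column sum of the matrix at
hand (a triad-only sum under-normalises, so supplying N is preferred).
"""

from __future__ import annotations

import logging

from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PLOIDY_LEVELS = ("diploid_DD", "tetraploid_AABB", "hexaploid_AABBDD")

#: canonical tissue labels, in the fixed presentation order used for
#: cross-tissue trend patterns
TISSUES = (
    "boot_head",
    "shoot",
    "lemma_palea",
    "glume",
    "pistil_AI",
    "pistil_AM",
    "pistil_1DAA",
    "anther",
    "hypocotyl",
    "root",
)

META_COLUMNS = ("sample_id", "genotype_id", "ploidy", "tissue", "replicate")


@dataclass
class CountMatrix:
    """Integer read counts (genes x samples) plus sample metadata.

    ``meta`` is indexed by sample_id and carries genotype_id, ploidy,
    tissue, replicate and library_size.  ``gene_lengths`` (bp) may be
    attached later; RPKM computation requires it for every row.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    gene_lengths: pd.Series | None = None

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def with_lengths(self, lengths: pd.Series | dict) -> "CountMatrix":
        lengths = pd.Series(lengths, dtype=float)
        return CountMatrix(self.counts, self.meta, lengths)


@dataclass
class ExpressionMatrix:
    """RPKM values with the same shape/metadata as the source counts."""

    values: pd.DataFrame
    meta: pd.DataFrame


def _validate_counts_frame(df: pd.DataFrame) -> pd.DataFrame:
    if df.shape[0] == 0:
        raise ValueError("no genes: count matrix has zero rows")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicated gene ID in count matrix: {dup!r}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals % 1 != 0)
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"non-integer or negative count at gene {row!r}, sample {col!r}: "
                f"{df.loc[row, col]!r}"
            )
    return df.astype(np.int64)


def validate_meta(meta: pd.DataFrame, tissues: tuple | None = None) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicated sample_id in metadata: {dup!r}")
    bad_ploidy = set(meta["ploidy"]) - set(PLOIDY_LEVELS)
    if bad_ploidy:
        raise ValueError(f"unknown ploidy class(es): {sorted(bad_ploidy)}")
    if tissues is not None:
        bad = set(meta["tissue"]) - set(tissues)
        if bad:
            raise ValueError(f"unknown tissue label(s): {sorted(bad)}")
    if (pd.to_numeric(meta["replicate"]) <= 0).any():
        raise ValueError("replicate indices must be positive integers")
    return meta.set_index("sample_id", drop=False)


def read_counts(path, meta_path, tissues: tuple | None = None) -> CountMatrix:
    """Read a counts TSV (first column gene IDs, header sample IDs) and its
    metadata TSV (keyed by sample_id) into a validated :class:`CountMatrix`.

    library_size is auto-derived as the column sum when the metadata has no
    library_size column; a user-supplied library_size must be >= the column
    sum (it is the whole-transcriptome total, of which the matrix may be a
    subset).
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise ValueError(f"no genes: {path} is empty") from None
    df = _validate_counts_frame(df)

    meta = validate_meta(pd.read_csv(meta_path, sep="\t"), tissues=tissues)
    unknown = [s for s in df.columns if s not in meta.index]
    if unknown:
        raise ValueError(f"samples in count header missing from metadata: {unknown}")
    meta = meta.loc[df.columns].copy()

    colsums = df.sum(axis=0)
    if "library_size" in meta.columns and meta["library_size"].notna().all():
        lib = pd.to_numeric(meta["library_size"]).astype(np.int64)
        too_small = lib < colsums
        if (lib <= 0).any():
            raise ValueError("library_size must be positive")
        if too_small.any():
            s = too_small.idxmax()
            raise ValueError(
                f"library_size for sample {s!r} ({lib[s]}) is smaller than its "
                f"column sum ({colsums[s]})"
            )
        meta["library_size"] = lib
    else:
        meta["library_size"] = colsums.astype(np.int64)
        logger.info("library_size auto-derived as column sums")
    return CountMatrix(df, meta)


TRIAD_COLUMNS = ("triad_id", "gene_A", "gene_B", "gene_D", "len_A", "len_B", "len_D")


def read_triads(path) -> pd.DataFrame:
    """Read and validate a triad table (triad_id -> A/B/D gene IDs + lengths)."""
    tri = pd.read_csv(path, sep="\t")
    missing = [c for c in TRIAD_COLUMNS if c not in tri.columns]
    if missing:
        raise ValueError(f"triad table missing columns: {missing}")
    return validate_triads(tri)


def validate_triads(tri: pd.DataFrame) -> pd.DataFrame:
    if tri["triad_id"].duplicated().any():
        raise ValueError("duplicated triad_id in triad table")
    genes = pd.concat([tri["gene_A"], tri["gene_B"], tri["gene_D"]])
    if genes.duplicated().any():
        dup = genes[genes.duplicated()].iloc[0]
        raise ValueError(f"gene {dup!r} appears in more than one triad slot")
    for c in ("len_A", "len_B", "len_D"):
        if (pd.to_numeric(tri[c]) <= 0).any():
            bad = tri.loc[pd.to_numeric(tri[c]) <= 0, "triad_id"].iloc[0]
            raise ValueError(f"non-positive gene length ({c}) in triad {bad!r}")
    return tri.reset_index(drop=True)


def triad_gene_lengths(tri: pd.DataFrame) -> pd.Series:
    """Gene-length series (bp) covering every gene in the triad table."""
    pairs = {}
    for g, l in (("gene_A", "len_A"), ("gene_B", "len_B"), ("gene_D", "len_D")):
        pairs.update(dict(zip(tri[g], pd.to_numeric(tri[l], errors="raise"))))
    return pd.Series(pairs, dtype=float)


def compute_rpkm(cm: CountMatrix) -> ExpressionMatrix:
    """RPKM = 1e9 * x / (l * N) per cell; zero counts map to zero RPKM."""
    if cm.gene_lengths is None:
        raise ValueError("gene lengths are required for RPKM; attach with with_lengths()")
    missing = cm.genes.difference(cm.gene_lengths.index)
    if len(missing) > 0:
        raise ValueError(f"missing gene lengths for: {list(missing[:10])}")
    l = cm.gene_lengths.loc[cm.genes].to_numpy(dtype=float)
    n = cm.meta.loc[cm.samples, "library_size"].to_numpy(dtype=float)
    vals = 1e9 * cm.counts.to_numpy(dtype=float) / (l[:, None] * n[None, :])
    return ExpressionMatrix(pd.DataFrame(vals, index=cm.genes, columns=cm.samples), cm.meta)


def mean_expression(expr: ExpressionMatrix, group) -> pd.Series:
    """Arithmetic mean RPKM per gene across the given sample group."""
    group = list(group)
    if not group:
        raise ValueError("empty sample group")
    absent = [s for s in group if s not in expr.values.columns]
    if absent:
        raise ValueError(f"samples not in expression matrix: {absent}")
    return expr.values[group].mean(axis=1)


_SORT_KEYS = ("triad_id", "tissue")


def write_results(df: pd.DataFrame, path) -> None:
    """Write a result table as TSV with stable ordering and formatting.

    Rows are sorted by (triad_id, tissue) where those columns exist, columns
    keep their order, floats use 6 significant digits, and missing values
    are serialised as "NA".
    """
    out = df.copy()
    keys = [k for k in _SORT_KEYS if k in out.columns]
    if keys:
        out = out.sort_values(keys, kind="mergesort")
    out.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def gene_lengths_from_gff3(path, merge_overlaps: bool = True) -> pd.Series:
    """Sum of exon spans (bp, 1-based inclusive) per gene from a GFF3 file.

    Exons are assigned to their top-level gene feature; overlapping exon
    intervals from alternative transcripts are merged before summing so that
    shared exonic bases are counted once.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    intervals: dict[str, list[tuple[int, int]]] = {}
    for exon in db.features_of_type("exon"):
        genes = [g.id for g in db.parents(exon, featuretype="gene")]
        if not genes:  # exon parented directly to a gene-less transcript
            genes = exon.attributes.get("Parent", [exon.id])
        for gid in genes:
            intervals.setdefault(gid, []).append((exon.start, exon.end))
    lengths = {}
    for gid, ivs in intervals.items():
        ivs.sort()
        total, cur_s, cur_e = 0, *ivs[0]
        if merge_overlaps:
            for s, e in ivs[1:]:
                if s > cur_e:
                    total += cur_e - cur_s + 1
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            total += cur_e - cur_s + 1
        else:
            total = sum(e - s + 1 for s, e in ivs)
        lengths[gid] = total
    return pd.Series(lengths, dtype=float)
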