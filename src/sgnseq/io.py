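"""Readers and writers for the pipeline's plain-text interchange formats.

Counts arrive either as a plain gene x sample TSV or in the featureCounts
dialect (comment lines starting with '#', annotation columns Geneid, Chr,
Start, End, Strand, Length before the sample columns). Gene lengths come
from a two-column TSV, from the featureCounts Length column, or from a GTF
(union-exon length per gene). Gene sets are exchanged as GMT.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .design import StudyDesign, SGN_AGE_ORDER

FEATURECOUNTS_ANNOT = ["Chr", "Start", "End", "Strand", "Length"]


class CountMatrix:
    """Raw integer counts with gene/sample labels and the study design.

    ``counts`` is a genes x samples pandas DataFrame of non-negative
    integers; ``lengths`` (optional) is a per-gene Series in bases.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        design: StudyDesign,
        lengths: pd.Series | None = None,
    ) -> None:
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if (counts.to_numpy() < 0).any():
            raise ValueError("negative counts are not allowed")
        missing = [s for s in design.sample_ids if s not in counts.columns]
        if missing:
            raise ValueError(f"samples in design but not in counts: {missing}")
        # column order follows the design
        self.counts = counts.loc[:, list(design.sample_ids)].astype(np.int64)
        self.counts.index.name = "gene_id"
        self.design = design
        if lengths is not None:
            lengths = lengths.reindex(counts.index)
            if lengths.isna().any():
                bad = lengths.index[lengths.isna()].tolist()
                raise ValueError(f"missing gene lengths for: {bad[:5]}")
        self.lengths = lengths

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_genes(self, gene_ids) -> "CountMatrix":
        sub = self.counts.loc[list(gene_ids)]
        lens = self.lengths.loc[list(gene_ids)] if self.lengths is not None else None
        return CountMatrix(sub, self.design, lens)


def read_sample_sheet(path: str | Path) -> StudyDesign:
    """Read a sample sheet TSV with columns sample_id, group, replicate."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "replicate"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample sheet needs columns {sorted(required)}")
    groups: list[str] = []
    for g in df["group"]:
        if g not in groups:
            groups.append(g)
    samples = tuple(
        (row.sample_id, row.group, int(row.replicate)) for row in df.itertuples()
    )
    sgn_ages = tuple(a for a in SGN_AGE_ORDER if a in groups)
    return StudyDesign(tuple(groups), samples, sgn_ages)


def write_sample_sheet(design: StudyDesign, path: str | Path) -> None:
    pd.DataFrame(
        design.samples, columns=["sample_id", "group", "replicate"]
    ).to_csv(path, sep="\t", index=False)


def read_counts(
    path: str | Path,
    design: StudyDesign,
    dialect: str = "plain",
    lengths: pd.Series | None = None,
) -> CountMatrix:
    """Read a counts TSV in the plain or featureCounts dialect.

    In the featureCounts dialect the Length column is captured and used as
    the per-gene length unless an explicit ``lengths`` Series is supplied.
    """
    if dialect not in ("plain", "featurecounts"):
        raise ValueError(f"unknown counts dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.set_index(df.columns[0])
    if dialect == "featurecounts":
        fc_lengths = None
        if "Length" in df.columns:
            fc_lengths = df["Length"].astype(float)
        df = df.drop(columns=[c for c in FEATURECOUNTS_ANNOT if c in df.columns])
        if lengths is None:
            lengths = fc_lengths
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = numeric.columns[numeric.isna().any()].tolist()
        raise ValueError(f"non-numeric count cells in columns: {bad}")
    if not np.allclose(numeric.to_numpy() % 1, 0):
        raise ValueError("counts must be integers")
    return CountMatrix(numeric.astype(np.int64), design, lengths)


def write_counts(m: CountMatrix, path: str | Path) -> None:
    out = m.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_lengths(path: str | Path) -> pd.Series:
    """Read a two-column gene_id / length TSV."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("lengths TSV needs two columns: gene_id, length")
    s = pd.Series(df.iloc[:, 1].astype(float).to_numpy(), index=df.iloc[:, 0])
    if (s <= 0).any():
        raise ValueError("gene lengths must be positive")
    return s


def write_lengths(lengths: pd.Series, path: str | Path) -> None:
    df = pd.DataFrame({"gene_id": lengths.index, "length": lengths.to_numpy()})
    df.to_csv(path, sep="\t", index=False)


_GTF_GENE_ID = re.compile(r'gene_id "([^"]+)"')


def read_gtf_lengths(path: str | Path) -> pd.Series:
    """Union-exon length per gene from a GTF.

    Exon records are merged per gene (1-based inclusive intervals); genes
    with no exon records fall back to the span of their "gene" record.
    """
    exon_ivals: dict[str, list[tuple[int, int]]] = {}
    gene_span: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            feature, start, end, attrs = parts[2], int(parts[3]), int(parts[4]), parts[8]
            match = _GTF_GENE_ID.search(attrs)
            if match is None:
                continue
            gid = match.group(1)
            if feature == "exon":
                exon_ivals.setdefault(gid, []).append((start, end))
            elif feature == "gene":
                gene_span[gid] = end - start + 1
    lengths: dict[str, int] = {}
    for gid, ivals in exon_ivals.items():
        ivals.sort()
        total, cur_s, cur_e = 0, *ivals[0]
        for s, e in ivals[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s + 1
                cur_s, cur_e = s, e
        lengths[gid] = total + cur_e - cur_s + 1
    for gid, span in gene_span.items():
        lengths.setdefault(gid, span)
    if not lengths:
        raise ValueError(f"no gene or exon records found in {path}")
    return pd.Series(lengths, dtype=float)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: one set per line (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            if parts[0] in sets:
                raise ValueError(f"duplicate gene-set name {parts[0]!r}")
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")
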