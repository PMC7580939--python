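"""Readers and writers for the pipeline's tabular formats.

Counts and taxa matrices travel as TSV (first column = feature id, header
row = sample ids, integer cells); sample metadata with CBC counts as CSV;
gene sets as GMT.  Every reader validates its invariants and every
reader/writer pair is a lossless round trip on valid files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composition import CELL_TYPES, CBCRecord

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input file; the message names the offending row/column."""


@dataclass
class CountMatrix:
    """Genes (rows) x samples (columns) of non-negative integer counts."""

    counts: pd.DataFrame  # integer dtype, index = gene ids, columns = sample ids
    gene_lengths: pd.Series | None = None  # bases, aligned to counts.index

    def __post_init__(self):
        idx, cols = self.counts.index, self.counts.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise FormatError("counts must be integers")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at gene {idx[g]!r}, sample {cols[s]!r}"
            )
        if self.gene_lengths is not None:
            self.gene_lengths = self.gene_lengths.reindex(idx)
            if self.gene_lengths.isna().any():
                missing = self.gene_lengths.index[self.gene_lengths.isna()][0]
                raise FormatError(f"missing length for gene {missing!r}")
            if (self.gene_lengths <= 0).any():
                bad = self.gene_lengths.index[self.gene_lengths <= 0][0]
                raise FormatError(f"non-positive length for gene {bad!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self):
        return self.counts.shape


def read_counts(path, lengths_path=None) -> CountMatrix:
    """Read a gene x sample TSV of integer counts (plus optional lengths TSV)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    float_like = df.select_dtypes(include="float")
    if not float_like.empty:
        if not (float_like.to_numpy() % 1 == 0).all():
            col = float_like.columns[0]
            raise FormatError(f"non-integer cell in column {col!r} of {path}")
        df = df.astype(np.int64)
    non_num = df.select_dtypes(exclude="number")
    if not non_num.empty:
        raise FormatError(f"non-numeric column {non_num.columns[0]!r} in {path}")
    lengths = None
    if lengths_path is not None:
        lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    cm = CountMatrix(df.astype(np.int64), gene_lengths=lengths)
    log.info("read %d genes x %d samples from %s", *cm.shape, path)
    return cm


def write_counts(cm: CountMatrix, path, lengths_path=None) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")
    if lengths_path is not None and cm.gene_lengths is not None:
        cm.gene_lengths.rename("length").to_csv(
            lengths_path, sep="\t", index_label="gene_id"
        )


@dataclass
class GeneSetCollection:
    """Named gene sets: name -> (description, ordered unique member ids)."""

    sets: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, (_desc, members) in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise FormatError(f"duplicate members in gene set {name!r}")

    def __len__(self):
        return len(self.sets)

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name <TAB> description <TAB> member ids..."""
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(parts)}"
                )
            name, desc, *members = parts
            members = [m for m in members if m]
            deduped = list(dict.fromkeys(members))
            if len(deduped) != len(members):
                log.warning(
                    "%s:%d: deduplicated %d repeated members in set %r",
                    path, lineno, len(members) - len(deduped), name,
                )
            sets[name] = (desc, deduped)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_metadata(path) -> pd.DataFrame:
    """Read the sample metadata CSV: dog_id, group, and the 7 CBC columns.

    Missing CBC fields are rejected rather than imputed: the composition
    model needs all seven cell types.
    """
    df = pd.read_csv(path)
    required = ["dog_id", "group", *CELL_TYPES]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"metadata {path} missing column {col!r}")
    if df["dog_id"].duplicated().any():
        dup = df.loc[df["dog_id"].duplicated(), "dog_id"].iloc[0]
        raise FormatError(f"duplicate dog_id {dup!r} in {path}")
    for ct in CELL_TYPES:
        if df[ct].isna().any():
            dog = df.loc[df[ct].isna(), "dog_id"].iloc[0]
            raise FormatError(f"missing {ct} count for dog {dog!r} in {path}")
    return df.set_index("dog_id")


def metadata_to_cbcs(meta: pd.DataFrame) -> list[CBCRecord]:
    return [
        CBCRecord(
            dog_id=str(dog),
            group=str(row["group"]),
            counts={ct: float(row[ct]) for ct in CELL_TYPES},
        )
        for dog, row in meta.iterrows()
    ]


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index_label="dog_id")
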