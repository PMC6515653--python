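"""File-format readers and writers: FASTA, TSV tables, Newick trees.

Thin wrappers over Biopython, pandas and dendropy that normalise the
dialects used throughout the pipeline (FASTA with free-text headers, TSV
with a header row, Newick with branch lengths and bootstrap supports stored
as internal-node labels) and raise errors that name the offending record.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A malformed input file."""


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a FASTA file as a list of ``(id, sequence)`` pairs.

    The record id is the first whitespace-delimited token of the header.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not rec.id:
            raise FormatError(f"{path}: FASTA record with empty header")
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | os.PathLike,
                width: int = 60) -> None:
    seqrecs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def read_tsv_table(path: str | os.PathLike,
                   required: Sequence[str] = ()) -> pd.DataFrame:
    """Read a TSV with a header row; error names any missing column."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={c: str for c in required
                                                if not c.endswith("fpkm")})
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message
        raise FormatError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def write_tsv_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_newick(path: str | os.PathLike) -> dendropy.Tree:
    """Read a Newick tree; internal-node labels are kept (bootstrap dialect)."""
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True,
                             suppress_internal_node_taxa=True)
    return tree


def write_newick(tree: dendropy.Tree, path: str | os.PathLike,
                 supports_as_comments: bool = False) -> None:
    """Write Newick with branch lengths; supports as internal labels.

    With ``supports_as_comments`` the support values are emitted as
    ``[&support=..]`` comments instead of internal-node labels.
    """
    if supports_as_comments:
        tree = tree.clone(depth=1)
        for nd in tree.preorder_internal_node_iter():
            if nd.label is not None:
                nd.annotations.add_new("support", nd.label)
                nd.label = None
        s = tree.as_string(schema="newick", unquoted_underscores=True,
                           suppress_annotations=False, suppress_rooting=True)
    else:
        s = tree.as_string(schema="newick", unquoted_underscores=True,
                           suppress_rooting=True)
    with open(path, "w") as fh:
        fh.write(s)
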