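"""Reading sequence sets and writing graph outputs.

Input sets (FASTQ, FASTA or one-sequence-per-line text) are collapsed to
*unique* reads: each distinct sequence becomes one record carrying its
observed frequency, with integer node ids assigned in first-occurrence
order.  Sequences are uppercased and U is mapped to T on load, so DNA and
RNA inputs share one alphabet {A, C, G, T, N}.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

ALPHABET = frozenset("ACGTN")

_NORMALIZE = str.maketrans("acgtun", "ACGTTN", "")


class SequenceFormatError(ValueError):
    """Raised when an input file cannot be parsed or contains bad symbols."""


@dataclass(frozen=True)
class ReadRecord:
    """One unique sequence with its observed multiplicity.

    Attributes
    ----------
    id : int
        Node identifier; consecutive from 0 in first-occurrence order.
    sequence : str
        Normalized sequence over {A, C, G, T, N}.
    frequency : int
        Number of occurrences in the raw input (>= 1).
    """

    id: int
    sequence: str
    frequency: int


@dataclass
class UniqueReadSet:
    """Ordered collection of unique reads; the node table of the graph."""

    records: list[ReadRecord] = field(default_factory=list)

    @property
    def total_reads(self) -> int:
        return sum(r.frequency for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ReadRecord]:
        return iter(self.records)

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @classmethod
    def from_sequences(cls, sequences: Iterable[str]) -> "UniqueReadSet":
        """Collapse an iterable of raw sequences (already normalized) into
        unique records, first-occurrence ordered."""
        counts: dict[str, int] = {}
        for seq in sequences:
            counts[seq] = counts.get(seq, 0) + 1
        records = [
            ReadRecord(i, seq, freq) for i, (seq, freq) in enumerate(counts.items())
        ]
        return cls(records)


def normalize_sequence(raw: str, where: str = "record") -> str:
    """Uppercase, map U->T, and validate against the {A,C,G,T,N} alphabet."""
    seq = raw.strip().upper().replace("U", "T")
    if not seq:
        raise SequenceFormatError(f"empty sequence at {where}")
    bad = set(seq) - ALPHABET
    if bad:
        raise SequenceFormatError(
            f"symbol {sorted(bad)[0]!r} outside alphabet ACGTN at {where}"
        )
    return seq


def _iter_plain(path: Path) -> Iterator[str]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            yield normalize_sequence(line, where=f"line {lineno}")


def _iter_seqio(path: Path, fmt: str) -> Iterator[str]:
    try:
        for idx, rec in enumerate(SeqIO.parse(str(path), fmt)):
            yield normalize_sequence(str(rec.seq), where=f"{fmt} record {idx}")
    except ValueError as exc:  # Bio.SeqIO parse failure
        raise SequenceFormatError(f"unparseable {fmt} file {path}: {exc}") from exc


def load_reads(path: str | Path, format: str = "auto") -> UniqueReadSet:
    """Load a read/UMI set and collapse it into unique records.

    Parameters
    ----------
    path : file path
    format : {"fastq", "fasta", "plain", "auto"}
        "auto" guesses from the extension (.fq/.fastq -> fastq,
        .fa/.fasta/.fna -> fasta, anything else -> plain).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        suffix = path.suffix.lower()
        if suffix in {".fq", ".fastq"}:
            format = "fastq"
        elif suffix in {".fa", ".fasta", ".fna"}:
            format = "fasta"
        else:
            format = "plain"
    if format == "plain":
        seqs = _iter_plain(path)
    elif format in {"fastq", "fasta"}:
        seqs = _iter_seqio(path, format)
    else:
        raise ValueError(f"unknown format {format!r}")
    return UniqueReadSet.from_sequences(seqs)


def write_graph(graph, reads: UniqueReadSet, node_path, edge_path,
                format: str = "tsv") -> None:
    """Write the node and edge tables of an edit-distance graph.

    TSV node columns: id, sequence, frequency.  TSV edge columns: id_a,
    id_b, edit_distance with id_a < id_b, sorted by (id_a, id_b) — output
    is byte-identical across runs for the same graph.  GraphML carries the
    same attributes (edge_path is used; node_path is ignored for graphml).
    """
    edges = sorted(
        (min(a, b), max(a, b), int(d))
        for a, b, d in graph.edges_with_distances()
    )
    if format == "tsv":
        with open(node_path, "w") as fh:
            fh.write("id\tsequence\tfrequency\n")
            for rec in reads.records:
                fh.write(f"{rec.id}\t{rec.sequence}\t{rec.frequency}\n")
        with open(edge_path, "w") as fh:
            fh.write("id_a\tid_b\tedit_distance\n")
            for a, b, d in edges:
                fh.write(f"{a}\t{b}\t{d}\n")
    elif format == "graphml":
        import networkx as nx

        g = nx.Graph()
        for rec in reads.records:
            g.add_node(rec.id, sequence=rec.sequence, frequency=rec.frequency)
        for a, b, d in edges:
            g.add_edge(a, b, edit_distance=d)
        buf = _stdio.BytesIO()
        nx.write_graphml(g, buf)
        Path(edge_path).write_bytes(buf.getvalue())
    else:
        raise ValueError(f"unknown output format {format!r}")


def read_edge_tsv(edge_path) -> set[tuple[int, int, int]]:
    """Parse an edge table written by :func:`write_graph` (tsv)."""
    edges = set()
    with open(edge_path) as fh:
        header = fh.readline()
        if not header.startswith("id_a"):
            raise SequenceFormatError(f"not an edge table: {edge_path}")
        for line in fh:
            a, b, d = line.split()
            edges.add((int(a), int(b), int(d)))
    return edges


def read_node_tsv(node_path) -> UniqueReadSet:
    """Parse a node table written by :func:`write_graph` (tsv)."""
    records = []
    with open(node_path) as fh:
        header = fh.readline()
        if not header.startswith("id"):
            raise SequenceFormatError(f"not a node table: {node_path}")
        for line in fh:
            i, seq, freq = line.split()
            records.append(ReadRecord(int(i), seq, int(freq)))
    return UniqueReadSet(records)
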