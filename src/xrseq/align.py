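"""Exact full-length placement of inserts on small references.

The filtering chain only ever keeps reads that match the reference
perfectly (any mismatch or gap is discarded downstream of a conventional
aligner), so on plasmid-scale references exact matching is the whole
alignment problem.  The index is a per-length hash of every reference
substring on the plus strand; minus-strand placements are found by looking
up the reverse complement of the query.  Circular references are indexed
through a virtual extension by the first ``max_query - 1`` bases, so
origin-spanning occurrences are found and reported modulo the length.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import XrseqError
from .preprocess import ProcessedRead
from .reference_io import Reference, revcomp


@dataclass(frozen=True)
class AlignedExcision:
    """An excised oligonucleotide placed on the reference.

    ``start`` is the leftmost plus-strand coordinate of the footprint
    (BED convention) whatever the strand; re-extracting ``length`` bases
    5'->3' on ``strand`` reproduces the insert exactly.
    """

    read_id: str
    ref_name: str
    start: int
    strand: str
    length: int
    umi: str = ""


class ExactIndex:
    """All exact occurrences of short queries on both strands."""

    def __init__(self, ref: Reference, min_query: int = 4, max_query: int = 64):
        if min_query < 1:
            raise XrseqError("min_query must be >= 1")
        self.ref = ref
        self.min_query = min_query
        self.max_query = max_query
        n = len(ref)
        ext = ref.sequence
        if ref.is_circular:
            ext = ext + ext[: min(max_query - 1, n - 1)]
        self._ext = ext
        self._tables: dict[int, dict[str, list[int]]] = {}

    def _table(self, qlen: int) -> dict[str, list[int]]:
        table = self._tables.get(qlen)
        if table is None:
            n = len(self.ref)
            ext = self._ext
            n_starts = n if self.ref.is_circular else n - qlen + 1
            table = {}
            for start in range(max(n_starts, 0)):
                table.setdefault(ext[start : start + qlen], []).append(start)
            self._tables[qlen] = table
        return table

    def lookup(self, query: str) -> list[tuple[int, str]]:
        """All (start, strand) exact placements of ``query``.

        Queries containing N never match (N aborts exact matching).
        """
        qlen = len(query)
        if qlen < self.min_query:
            raise XrseqError(
                f"query shorter than indexed minimum ({self.min_query})"
            )
        if qlen > min(self.max_query, len(self.ref)):
            return []
        if "N" in query:
            return []
        table = self._table(qlen)
        hits = [(p, "+") for p in table.get(query, ())]
        rc = revcomp(query)
        hits += [(p, "-") for p in table.get(rc, ())]
        hits.sort()
        return hits


def build_index(ref: Reference, min_query: int = 4, max_query: int = 64) -> ExactIndex:
    return ExactIndex(ref, min_query=min_query, max_query=max_query)


def align_all(
    index: ExactIndex,
    reads: Sequence[ProcessedRead],
    multimapper: str = "discard",
    rng: np.random.Generator | None = None,
) -> tuple[list[AlignedExcision], dict]:
    """Place each insert by exact matching.

    ``multimapper`` is ``discard`` (default; ambiguous placements are
    dropped and counted) or ``random_one`` (one placement drawn at
    random, requires ``rng``).
    """
    if multimapper not in ("discard", "random_one"):
        raise XrseqError(f"unknown multimapper policy {multimapper!r}")
    if multimapper == "random_one" and rng is None:
        raise XrseqError("random_one policy requires an rng")
    aligned: list[AlignedExcision] = []
    stats = {"input": len(reads), "aligned": 0, "unaligned": 0, "multimapper": 0}
    ref_name = index.ref.name
    for read in reads:
        hits = index.lookup(read.insert)
        if len(hits) == 1:
            pos, strand = hits[0]
        elif not hits:
            stats["unaligned"] += 1
            continue
        else:
            stats["multimapper"] += 1
            if multimapper == "discard":
                continue
            pos, strand = hits[int(rng.integers(len(hits)))]
        aligned.append(
            AlignedExcision(
                read_id=read.read_id,
                ref_name=ref_name,
                start=pos % len(index.ref),
                strand=strand,
                length=len(read.insert),
                umi=read.umi,
            )
        )
        stats["aligned"] += 1
    return aligned, stats


def extract_insert(ref: Reference, aln: AlignedExcision) -> str:
    """Reference substring an alignment claims to match (round-trip check)."""
    return ref.fetch(aln.start, aln.length, aln.strand)


def dedup_aligned_umi(
    alignments: Iterable[AlignedExcision],
) -> tuple[list[AlignedExcision], int]:
    """Collapse records sharing (start, strand, length, UMI).

    Records at the same position with different UMIs are genuine repeated
    repair events and are all kept.
    """
    seen: set[tuple] = set()
    kept: list[AlignedExcision] = []
    removed = 0
    for aln in alignments:
        key = (aln.start, aln.strand, aln.length, aln.umi)
        if key in seen:
            removed += 1
        else:
            seen.add(key)
            kept.append(aln)
    return kept, removed


def write_alignments_bed(
    alignments: Iterable[AlignedExcision], path: str | Path
) -> None:
    """BED6 output: name column is ``read_id:umi`` (``:`` omitted if no UMI)."""
    with open(path, "w") as fh:
        for a in alignments:
            name = f"{a.read_id}:{a.umi}" if a.umi else a.read_id
            fh.write(
                f"{a.ref_name}\t{a.start}\t{a.start + a.length}\t{name}\t0\t{a.strand}\n"
            )


def read_alignments_bed(path: str | Path) -> list[AlignedExcision]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 6:
                raise XrseqError(f"{path}:{lineno}: expected 6 BED columns")
            chrom, start, end, name, _score, strand = fields[:6]
            rid, _, umi = name.partition(":")
            out.append(
                AlignedExcision(
                    read_id=rid,
                    ref_name=chrom,
                    start=int(start),
                    strand=strand,
                    length=int(end) - int(start),
                    umi=umi,
                )
            )
    return out
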