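"""Raw-read deduplication, UMI extraction, and 3' adapter trimming.

The library layout is ``UMI + insert + 3' adapter``: the first
``umi_length`` bases are the unique molecular identifier and the insert
runs up to the leftmost adapter occurrence.  Because the UMI is part of
the raw sequence, collapsing byte-identical raw reads removes PCR
duplicates while retaining genuine repeated repair events at one site
(same insert, different UMI).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import XrseqError
from .synthetic_data import DEFAULT_ADAPTER3

DISCARD_REASONS = ("duplicate", "no_adapter", "too_short", "too_long")


@dataclass(frozen=True)
class LibraryLayout:
    """Read layout shared between the simulator and the trimmer."""

    umi_length: int = 8
    adapter3: str = DEFAULT_ADAPTER3
    min_overlap: int = 5
    max_mismatch: int = 0
    min_len: int = 4
    max_insert: int = 40


@dataclass(frozen=True)
class ProcessedRead:
    read_id: str
    insert: str
    umi: str
    discarded_reason: str | None = None

    @property
    def kept(self) -> bool:
        return self.discarded_reason is None


def dedup_raw(
    reads: Iterable[tuple[str, str]]
) -> tuple[list[tuple[str, str]], int]:
    """Collapse byte-identical raw sequences to their first occurrence."""
    seen: set[str] = set()
    unique: list[tuple[str, str]] = []
    dups = 0
    for rid, seq in reads:
        if seq in seen:
            dups += 1
        else:
            seen.add(seq)
            unique.append((rid, seq))
    return unique, dups


def _find_adapter(rem: str, adapter: str, min_overlap: int, max_mismatch: int) -> int | None:
    """Leftmost start of an adapter match in ``rem``.

    A match is a prefix of ``adapter`` of length
    ``min(len(adapter), len(rem) - i)`` with at most ``max_mismatch``
    mismatches, requiring at least ``min_overlap`` bases (so the adapter
    may run off the 3' end of the read).
    """
    na, nr = len(adapter), len(rem)
    if na == 0 or nr < min_overlap:
        return None
    if max_mismatch == 0:
        i = rem.find(adapter)
        if i != -1:
            return i
        # partial overlap at the 3' end
        for i in range(max(0, nr - na + 1), nr - min_overlap + 1):
            if adapter.startswith(rem[i:]):
                return i
        return None
    for i in range(nr - min_overlap + 1):
        k = min(na, nr - i)
        mism = sum(a != b for a, b in zip(rem[i : i + k], adapter[:k]))
        if mism <= max_mismatch:
            return i
    return None


def trim_read(read_id: str, raw: str, layout: LibraryLayout) -> ProcessedRead:
    """Split one raw read into UMI and insert, or record why it fails."""
    u = layout.umi_length
    if len(raw) < u:
        return ProcessedRead(read_id, "", "", "too_short")
    umi, rem = raw[:u], raw[u:]
    i = _find_adapter(rem, layout.adapter3, layout.min_overlap, layout.max_mismatch)
    if i is None:
        if len(rem) > layout.max_insert:
            return ProcessedRead(read_id, "", umi, "no_adapter")
        insert = rem  # adapter ran off the read end
    else:
        insert = rem[:i]
    if len(insert) < layout.min_len:
        return ProcessedRead(read_id, insert, umi, "too_short")
    if len(insert) > layout.max_insert:
        return ProcessedRead(read_id, insert, umi, "too_long")
    return ProcessedRead(read_id, insert, umi)


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTQ file; malformed input is a hard error."""
    try:
        with open(path) as fh:
            return [
                (title.split()[0], seq)
                for title, seq, _qual in FastqGeneralIterator(fh)
            ]
    except ValueError as exc:
        raise XrseqError(f"{path}: malformed FASTQ ({exc})") from exc


def preprocess_all(
    fastq_in: str | Path,
    layout: LibraryLayout,
    dedup: bool = True,
    fastq_out: str | Path | None = None,
    tsv_out: str | Path | None = None,
) -> tuple[list[ProcessedRead], dict]:
    """Dedup then trim a FASTQ file.

    Returns the kept reads and a stats dict satisfying
    ``input == kept + sum(discarded.values())``.
    """
    raw = read_fastq(fastq_in)
    n_in = len(raw)
    discarded = dict.fromkeys(DISCARD_REASONS, 0)
    if dedup:
        raw, dups = dedup_raw(raw)
        discarded["duplicate"] = dups
    kept: list[ProcessedRead] = []
    for rid, seq in raw:
        pr = trim_read(rid, seq, layout)
        if pr.kept:
            kept.append(pr)
        else:
            discarded[pr.discarded_reason] += 1
    stats = {"input": n_in, "kept": len(kept), "discarded": discarded}
    assert stats["input"] == stats["kept"] + sum(discarded.values())
    if fastq_out is not None:
        with open(fastq_out, "w") as fh:
            fh.write(
                "".join(
                    f"@{p.read_id}\n{p.insert}\n+\n{'I' * len(p.insert)}\n"
                    for p in kept
                )
            )
    if tsv_out is not None:
        with open(tsv_out, "w") as fh:
            fh.write("read_id\tumi\tinsert\n")
            fh.writelines(f"{p.read_id}\t{p.umi}\t{p.insert}\n" for p in kept)
    return kept, stats


def read_processed_tsv(path: str | Path) -> list[ProcessedRead]:
    """Read back the per-read TSV written by :func:`preprocess_all`."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["read_id", "umi", "insert"]:
            raise XrseqError(f"{path}: unexpected processed-read TSV header")
        for line in fh:
            rid, umi, insert = line.rstrip("\n").split("\t")
            out.append(ProcessedRead(rid, insert, umi))
    return out
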