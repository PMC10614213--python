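"""Damage-position filtering and repair-map summaries.

After alignment, reads are restricted to the canonical excision-product
length carrying a dipyrimidine at the expected dimer position (13-mers
with the dimer at read positions 8-9 for E. coli, 26-mers at 19-20 for
mammalian products), optionally subsampled to a fixed depth, and then
summarized as length distributions, per-position nucleotide profiles,
5'-flank base preferences, and strand-resolved coverage tracks.

Coordinate conventions: read positions are 1-based 5'->3' on the read's
own strand; track coordinates are 0-based plus-strand positions.  The
damage-site coordinate of a read is the plus-strand position of the
dimer's 5' base: ``start + first_dipy_pos - 1`` for plus-strand reads and
``start + length - first_dipy_pos`` (mirrored) for minus-strand reads.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import AlignedExcision
from .errors import XrseqError
from .reference_io import DIPY_KINDS, NUCLEOTIDES, Reference


@dataclass(frozen=True)
class DamageFilterSpec:
    """Which reads count as canonical damage-containing products."""

    read_length: int = 13
    dipy_positions: tuple[int, int] = (8, 9)
    kinds: frozenset = frozenset(DIPY_KINDS)

    def __post_init__(self) -> None:
        p1, p2 = self.dipy_positions
        if p2 != p1 + 1:
            raise XrseqError("dipy_positions must be consecutive")
        if not 1 <= p1 < self.read_length:
            raise XrseqError(
                f"dipy position {p1} out of range for length {self.read_length}"
            )
        object.__setattr__(self, "kinds", frozenset(self.kinds))
        bad = self.kinds - frozenset(DIPY_KINDS)
        if bad:
            raise XrseqError(f"unknown dipyrimidine kinds: {sorted(bad)}")


@dataclass
class RepairMap:
    """Per-position, per-strand counts over a reference."""

    ref_name: str
    plus: np.ndarray
    minus: np.ndarray
    mode: str = "damage_site"

    def strand(self, strand: str) -> np.ndarray:
        return self.plus if strand == "+" else self.minus


def damage_filter(
    alignments: Sequence[AlignedExcision],
    inserts: Mapping[str, str],
    spec: DamageFilterSpec,
) -> tuple[list[AlignedExcision], dict]:
    """Keep reads of exactly ``spec.read_length`` with a qualifying
    dipyrimidine at ``spec.dipy_positions`` (on the read's own sequence)."""
    p1 = spec.dipy_positions[0]
    kept = []
    stats = {"input": len(alignments), "kept": 0, "removed_length": 0,
             "removed_no_dipy": 0}
    for aln in alignments:
        if aln.length != spec.read_length:
            stats["removed_length"] += 1
            continue
        seq = inserts[aln.read_id]
        if seq[p1 - 1 : p1 + 1] in spec.kinds:
            kept.append(aln)
            stats["kept"] += 1
        else:
            stats["removed_no_dipy"] += 1
    return kept, stats


def subsample(
    alignments: Sequence[AlignedExcision],
    n: int,
    seed: int | np.random.Generator = 0,
) -> list[AlignedExcision]:
    """Uniform subsample without replacement, preserving input order."""
    if n < 0:
        raise XrseqError("subsample size must be >= 0")
    if n >= len(alignments):
        if n > len(alignments):
            warnings.warn(
                f"requested subsample {n} exceeds input size "
                f"{len(alignments)}; returning all reads",
                stacklevel=2,
            )
        return list(alignments)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(alignments), size=n, replace=False))
    return [alignments[i] for i in idx]


def length_distribution(
    alignments: Sequence[AlignedExcision],
) -> tuple[dict[int, int], dict[int, float]]:
    """Read-length histogram as (counts, fractions)."""
    counts = Counter(a.length for a in alignments)
    total = sum(counts.values())
    fractions = {L: c / total for L, c in counts.items()} if total else {}
    return dict(sorted(counts.items())), dict(sorted(fractions.items()))


def nucleotide_profile(
    alignments: Sequence[AlignedExcision],
    inserts: Mapping[str, str],
    length: int,
) -> pd.DataFrame:
    """Base frequency at each read position (1-based, 5' end = position 1).

    Only reads of exactly ``length`` contribute; rows sum to 1.
    """
    counts = np.zeros((length, 4), dtype=np.int64)
    col = {b: j for j, b in enumerate(NUCLEOTIDES)}
    n = 0
    for aln in alignments:
        if aln.length != length:
            continue
        seq = inserts[aln.read_id]
        for i, b in enumerate(seq):
            if b in col:
                counts[i, col[b]] += 1
        n += 1
    if n == 0:
        raise XrseqError(f"no reads of length {length}")
    freq = counts / counts.sum(axis=1, keepdims=True)
    return pd.DataFrame(
        freq, index=pd.RangeIndex(1, length + 1, name="position"),
        columns=list(NUCLEOTIDES),
    )


def flank_base_frequency(
    alignments: Sequence[AlignedExcision],
    inserts: Mapping[str, str],
    spec: DamageFilterSpec,
) -> dict[str, float]:
    """Base composition immediately 5' of the dimer within the reads.

    The position interrogated is ``spec.dipy_positions[0] - 1`` (1-based),
    so the first dimer position must be >= 2.
    """
    p1 = spec.dipy_positions[0]
    if p1 < 2:
        raise XrseqError("first dipyrimidine position must be >= 2")
    counts = Counter()
    n = 0
    for aln in alignments:
        if aln.length != spec.read_length:
            continue
        counts[inserts[aln.read_id][p1 - 2]] += 1
        n += 1
    if n == 0:
        raise XrseqError("no reads")
    return {b: counts.get(b, 0) / n for b in NUCLEOTIDES}


def damage_position(aln: AlignedExcision, spec: DamageFilterSpec, ref_length: int) -> int:
    """Plus-strand coordinate of the dimer's 5' base for one read."""
    p1 = spec.dipy_positions[0]
    if aln.strand == "+":
        pos = aln.start + p1 - 1
    else:
        pos = aln.start + aln.length - p1
    return pos % ref_length


def coverage_tracks(
    alignments: Sequence[AlignedExcision],
    ref: Reference,
    spec: DamageFilterSpec | None = None,
    mode: str = "damage_site",
) -> RepairMap:
    """Strand-resolved coverage over the reference.

    ``damage_site`` mode increments one position per read (the dimer's 5'
    base; requires ``spec``); ``footprint`` mode increments every covered
    position.  Circular references wrap.
    """
    n = len(ref)
    plus = np.zeros(n, dtype=np.int64)
    minus = np.zeros(n, dtype=np.int64)
    if mode == "damage_site":
        if spec is None:
            raise XrseqError("damage_site mode requires a DamageFilterSpec")
        for aln in alignments:
            vec = plus if aln.strand == "+" else minus
            vec[damage_position(aln, spec, n)] += 1
    elif mode == "footprint":
        for aln in alignments:
            vec = plus if aln.strand == "+" else minus
            idx = np.arange(aln.start, aln.start + aln.length) % n
            np.add.at(vec, idx, 1)
    else:
        raise XrseqError(f"unknown coverage mode {mode!r}")
    return RepairMap(ref_name=ref.name, plus=plus, minus=minus, mode=mode)


def write_bedgraph(repair_map: RepairMap, path: str | Path, strand: str) -> None:
    """Write one strand as bedGraph (0-based half-open, zero runs omitted,
    adjacent equal values merged)."""
    vec = repair_map.strand(strand)
    with open(path, "w") as fh:
        run_start = None
        run_val = 0
        for i, v in enumerate(vec):
            if run_start is not None and v != run_val:
                if run_val != 0:
                    fh.write(f"{repair_map.ref_name}\t{run_start}\t{i}\t{run_val}\n")
                run_start = None
            if run_start is None and v != 0:
                run_start, run_val = i, v
        if run_start is not None and run_val != 0:
            fh.write(f"{repair_map.ref_name}\t{run_start}\t{len(vec)}\t{run_val}\n")


def read_bedgraph(path: str | Path, length: int) -> np.ndarray:
    """Read a bedGraph file back into a per-position vector."""
    vec = np.zeros(length, dtype=np.int64)
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if not fields or fields[0] in ("track", "#"):
                continue
            _chrom, start, end, val = fields[:4]
            vec[int(start) : int(end)] = int(val)
    return vec


def write_length_distribution_tsv(
    alignments: Sequence[AlignedExcision], path: str | Path
) -> None:
    counts, fractions = length_distribution(alignments)
    with open(path, "w") as fh:
        fh.write("length\tcount\tfraction\n")
        for L in counts:
            fh.write(f"{L}\t{counts[L]}\t{fractions[L]:.6f}\n")
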