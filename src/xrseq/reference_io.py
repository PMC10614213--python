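"""References, gene annotations, and dipyrimidine site enumeration.

Everything downstream is expressed in the coordinate frame defined here:
0-based, half-open intervals on the plus strand of a named reference
sequence.  A reference may be circular (plasmids), in which case reads and
dinucleotide windows are allowed to span the origin and all reported
coordinates are reduced modulo the sequence length.

The transcribed strand (TS) of a gene is the strand *opposite* its sense
(coding) strand: RNA polymerase reads the template, so an annotation with
``sense_strand == '+'`` is transcribed from the minus strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .errors import UndefinedRatioError, XrseqError

NUCLEOTIDES = "ACGT"
DIPY_KINDS = ("TT", "TC", "CT", "CC")
_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Reference:
    """A named nucleotide sequence with linear or circular topology."""

    name: str
    sequence: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        if not self.name:
            raise XrseqError("reference name must be nonempty")
        if len(self.sequence) < 1:
            raise XrseqError(f"reference {self.name!r}: empty sequence")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise XrseqError(
                f"reference {self.name!r}: non-nucleotide characters "
                f"{sorted(bad)} (alphabet is A/C/G/T/N)"
            )
        if self.topology not in ("linear", "circular"):
            raise XrseqError(
                f"reference {self.name!r}: topology must be linear or circular, "
                f"got {self.topology!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def fetch(self, start: int, length: int, strand: str = "+") -> str:
        """Extract ``length`` bases 5'->3' on ``strand``.

        ``start`` is always the leftmost plus-strand coordinate of the
        spanned interval (BED convention), regardless of strand.  Circular
        references wrap past the origin; linear references raise if the
        interval runs off either end.
        """
        n = len(self.sequence)
        if length < 0:
            raise XrseqError("negative length")
        if self.is_circular:
            start %= n
            if length > n:
                raise XrseqError("fetch longer than circular reference")
            stop = start + length
            plus = (
                self.sequence[start:stop]
                if stop <= n
                else self.sequence[start:] + self.sequence[: stop - n]
            )
        else:
            if start < 0 or start + length > n:
                raise XrseqError(
                    f"interval [{start}, {start + length}) outside linear "
                    f"reference {self.name!r} of length {n}"
                )
            plus = self.sequence[start : start + length]
        return plus if strand == "+" else revcomp(plus)


@dataclass(frozen=True)
class GeneAnnotation:
    """An interval with a sense strand; the TS is the opposite strand."""

    gene: str
    start: int
    end: int
    sense_strand: str
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise XrseqError(
                f"gene {self.gene!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.sense_strand not in ("+", "-"):
            raise XrseqError(f"gene {self.gene!r}: strand must be + or -")

    @property
    def ts_strand(self) -> str:
        """Transcribed (template) strand."""
        return "-" if self.sense_strand == "+" else "+"

    def validate_against(self, ref: Reference) -> None:
        if self.end > len(ref):
            raise XrseqError(
                f"gene {self.gene!r}: end {self.end} exceeds reference "
                f"{ref.name!r} length {len(ref)}"
            )


@dataclass(frozen=True, order=True)
class DipySite:
    """A dipyrimidine dinucleotide on one strand.

    ``pos5`` is the 0-based plus-strand coordinate of the base that is 5'
    when the dinucleotide is read on its own strand.  On the minus strand
    the dinucleotide therefore occupies plus-strand positions
    ``pos5 - 1`` and ``pos5`` (modulo length for circular references).
    """

    pos5: int
    strand: str
    kind: str


def read_fasta(path: str | Path, topology: str | dict = "linear") -> list[Reference]:
    """Read a FASTA file into validated :class:`Reference` objects.

    ``topology`` is either a single value applied to every record or a
    mapping from record name to topology.  Lowercase (soft-masked) bases
    are uppercased; masking is not preserved.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise XrseqError(f"{path}: no FASTA records found")
    refs = []
    for rec in records:
        topo = topology.get(rec.id, "linear") if isinstance(topology, dict) else topology
        seq = str(rec.seq).upper()
        bad = set(seq) - _ALPHABET
        if bad:
            raise XrseqError(
                f"{path}: record {rec.id!r} contains non-nucleotide "
                f"characters {sorted(bad)}"
            )
        refs.append(Reference(name=rec.id, sequence=seq, topology=topo))
    return refs


def read_gene_bed(path: str | Path, ref: Reference) -> list[GeneAnnotation]:
    """Read BED6 gene annotations and validate them against ``ref``.

    The BED strand column is the gene's sense strand; the transcribed
    strand is derived from it.
    """
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise XrseqError(f"{path}:{lineno}: expected 6 BED columns")
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            if chrom != ref.name:
                raise XrseqError(
                    f"{path}:{lineno}: chrom {chrom!r} does not match "
                    f"reference {ref.name!r}"
                )
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise XrseqError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise XrseqError(f"{path}:{lineno}: start {start} >= end {end}")
            if strand not in ("+", "-"):
                raise XrseqError(f"{path}:{lineno}: strand must be + or -")
            gene = GeneAnnotation(gene=name, start=start, end=end, sense_strand=strand)
            try:
                gene.validate_against(ref)
            except XrseqError as exc:
                raise XrseqError(f"{path}:{lineno}: {exc}") from exc
            genes.append(gene)
    return genes


def enumerate_dipyrimidines(
    ref: Reference, kinds: Iterable[str] = DIPY_KINDS
) -> list[DipySite]:
    """All dipyrimidine sites of the requested kinds on both strands.

    A minus-strand site of kind K appears on the plus strand as
    ``revcomp(K)`` (e.g. a minus-strand TT is a plus-strand AA).  For
    circular references the origin-spanning dinucleotide (last base + first
    base) is included.  N never forms a dipyrimidine.
    """
    kinds = frozenset(kinds)
    bad = kinds - frozenset(DIPY_KINDS)
    if bad:
        raise XrseqError(f"unknown dipyrimidine kinds: {sorted(bad)}")
    seq = ref.sequence
    n = len(seq)
    # plus-strand dinucleotide -> minus-strand kind it encodes
    minus_of = {revcomp(k): k for k in kinds}
    sites: list[DipySite] = []
    windows = n if (ref.is_circular and n >= 2) else n - 1
    for q in range(windows):
        pair = seq[q] + seq[(q + 1) % n]
        if pair in kinds:
            sites.append(DipySite(pos5=q, strand="+", kind=pair))
        mk = minus_of.get(pair)
        if mk is not None:
            sites.append(DipySite(pos5=(q + 1) % n, strand="-", kind=mk))
    sites.sort(key=lambda s: (s.pos5, s.strand))
    return sites


def _count_tt_in_interval(ref: Reference, start: int, end: int) -> tuple[int, int]:
    """(plus-strand, minus-strand) TT counts with pos5 inside [start, end)."""
    plus = minus = 0
    for site in enumerate_dipyrimidines(ref, kinds=("TT",)):
        if start <= site.pos5 < end:
            if site.strand == "+":
                plus += 1
            else:
                minus += 1
    return plus, minus


def tt_strand_ratio(ref: Reference, gene: GeneAnnotation) -> float:
    """TT dinucleotide count on the TS divided by the count on the NTS.

    TT runs are the dominant substrate of UV cyclobutane pyrimidine dimer
    formation, so this ratio is the sequence-composition baseline against
    which strand-asymmetric repair counts can be judged.  A site counts
    toward the interval iff its ``pos5`` base lies in ``[start, end)``.
    """
    gene.validate_against(ref)
    plus, minus = _count_tt_in_interval(ref, gene.start, gene.end)
    ts_count, nts_count = (minus, plus) if gene.ts_strand == "-" else (plus, minus)
    if nts_count == 0:
        raise UndefinedRatioError(
            f"gene {gene.gene!r}: no TT on the nontranscribed strand, "
            "undefined ratio"
        )
    return ts_count / nts_count


def flank_background(ref: Reference, kind: str, base: str) -> float:
    """Fraction of ``kind`` sites whose immediate 5' neighbor equals ``base``.

    The neighbor is read on the site's own strand.  On a linear reference,
    sites whose 5' neighbor would fall off the sequence are excluded from
    the denominator; on a circular reference the neighbor wraps.  This is
    the genomic background for the 5'-flank preference observed in
    excision products.
    """
    if base not in NUCLEOTIDES:
        raise XrseqError(f"base must be one of {NUCLEOTIDES}")
    if len(ref) < 3:
        raise XrseqError("reference too short for flank analysis")
    seq = ref.sequence
    n = len(seq)
    total = hits = 0
    for site in enumerate_dipyrimidines(ref, kinds=(kind,)):
        if site.strand == "+":
            q = site.pos5 - 1
            if q < 0:
                if not ref.is_circular:
                    continue
                q %= n
            neighbor = seq[q]
        else:
            q = site.pos5 + 1
            if q >= n:
                if not ref.is_circular:
                    continue
                q %= n
            neighbor = revcomp(seq[q])
        total += 1
        if neighbor == base:
            hits += 1
    if total == 0:
        raise XrseqError(f"no {kind} sites with a 5' neighbor in {ref.name!r}")
    return hits / total
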