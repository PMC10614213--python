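"""Ground-truth simulator for excision-product sequencing libraries.

The generative model mirrors the structure of an XR-seq library prepared
from a UV-irradiated plasmid or small genome: nucleotide excision repair
releases short damage-containing oligomers (12-14 nt in prokaryotes,
24-30 nt in eukaryotes) whose cyclobutane pyrimidine dimer (CPD) sits at a
characteristic position within the product.  Each simulated molecule is

* drawn from a weighted table of dipyrimidine sites — weights combine a
  per-kind damage propensity with a per-gene transcribed-strand (TS)
  multiplier that models transcription-coupled repair (TCR);
* given a product length from a configured length distribution, placed so
  the dimer's 5' base sits at that length's configured offset;
* optionally 5'-truncated below 12 nt to emulate nucleolytic degradation
  tails;
* wrapped into a raw read as ``UMI + insert + 3' adapter`` and amplified
  into a Poisson number of byte-identical PCR duplicate copies.

A truth table records, per read, the originating site, strand, length,
gene, dimer coordinate, and duplicate parentage, so downstream stages can
be scored exactly.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import XrseqError
from .reference_io import (
    DIPY_KINDS,
    DipySite,
    GeneAnnotation,
    Reference,
    enumerate_dipyrimidines,
)

# Illumina TruSeq small-RNA 3' adapter; the real library adapters are a
# configurable stand-in, shared between simulator and trimmer.
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"

PROKARYOTE_LENGTH_WEIGHTS = {12: 0.05, 13: 0.85, 14: 0.10}
PROKARYOTE_DAMAGE_OFFSET = {12: 8, 13: 8, 14: 9}

# 24-30 nt products peaking at 26-27, dimer offset keeping the dimer a
# fixed distance from the 3' end (26-mer: positions 19-20).
EUKARYOTE_LENGTH_WEIGHTS = {
    24: 0.06,
    25: 0.14,
    26: 0.30,
    27: 0.25,
    28: 0.13,
    29: 0.08,
    30: 0.04,
}
EUKARYOTE_DAMAGE_OFFSET = {L: L - 7 for L in EUKARYOTE_LENGTH_WEIGHTS}

# CPDs form almost exclusively at TT in these libraries.
DEFAULT_KIND_WEIGHTS = {"TT": 0.95, "TC": 0.03, "CT": 0.01, "CC": 0.01}


@dataclass
class SimulationConfig:
    """Parameters of one simulated library."""

    mode: str = "prokaryote"
    n_molecules: int = 10_000
    length_weights: dict[int, float] = field(
        default_factory=lambda: dict(PROKARYOTE_LENGTH_WEIGHTS)
    )
    damage_offset: dict[int, int] = field(
        default_factory=lambda: dict(PROKARYOTE_DAMAGE_OFFSET)
    )
    kind_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_KIND_WEIGHTS)
    )
    tcr_enrichment: dict[str, float] = field(default_factory=dict)
    degradation_fraction: float = 0.05
    pcr_dup_mean: float = 1.0
    umi_length: int = 8
    adapter3: str = DEFAULT_ADAPTER3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("prokaryote", "eukaryote"):
            raise XrseqError(f"unknown mode {self.mode!r}")
        if self.n_molecules < 0:
            raise XrseqError("n_molecules must be >= 0")
        if abs(sum(self.length_weights.values()) - 1.0) > 1e-9:
            raise XrseqError("length_weights must sum to 1")
        missing = set(self.length_weights) - set(self.damage_offset)
        if missing:
            raise XrseqError(f"lengths without a damage_offset: {sorted(missing)}")
        for L, off in self.damage_offset.items():
            if not 1 <= off < L:
                raise XrseqError(f"damage offset {off} invalid for length {L}")
        if abs(sum(self.kind_weights.values()) - 1.0) > 1e-9:
            raise XrseqError("kind_weights must sum to 1")
        bad = set(self.kind_weights) - set(DIPY_KINDS)
        if bad:
            raise XrseqError(f"unknown dipyrimidine kinds: {sorted(bad)}")
        if any(e < 0 for e in self.tcr_enrichment.values()):
            raise XrseqError("tcr_enrichment multipliers must be >= 0")
        if not 0.0 <= self.degradation_fraction <= 1.0:
            raise XrseqError("degradation_fraction must be in [0, 1]")
        if self.pcr_dup_mean < 0:
            raise XrseqError("pcr_dup_mean must be >= 0")
        if self.umi_length < 0:
            raise XrseqError("umi_length must be >= 0")

    @classmethod
    def prokaryote(cls, **overrides) -> "SimulationConfig":
        return cls(mode="prokaryote", **overrides)

    @classmethod
    def eukaryote(cls, **overrides) -> "SimulationConfig":
        defaults = dict(
            mode="eukaryote",
            length_weights=dict(EUKARYOTE_LENGTH_WEIGHTS),
            damage_offset=dict(EUKARYOTE_DAMAGE_OFFSET),
            umi_length=0,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class TruthRecord:
    """Ground truth for one emitted read."""

    read_id: str
    origin_pos5: int
    origin_strand: str
    length: int
    gene: str | None
    damage_pos: int
    is_pcr_duplicate: bool = False
    parent_id: str | None = None
    is_degraded: bool = False


def random_reference(
    length: int,
    seed: int | np.random.Generator,
    name: str = "synthetic_plasmid",
    topology: str = "circular",
) -> Reference:
    """Uniform-random synthetic reference, e.g. a stand-in plasmid."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = lut[rng.integers(0, 4, size=length)].tobytes().decode()
    return Reference(name=name, sequence=seq, topology=topology)


def site_weight_table(
    ref: Reference,
    genes: Sequence[GeneAnnotation],
    config: SimulationConfig,
) -> dict[DipySite, float]:
    """Normalized sampling weight for every eligible dipyrimidine site.

    Base weight is the kind's damage propensity; sites lying on a gene's
    transcribed strand within the gene interval are additionally multiplied
    by that gene's TCR enrichment factor.
    """
    for gene in genes:
        gene.validate_against(ref)
    kinds = [k for k, w in config.kind_weights.items() if w > 0]
    sites = enumerate_dipyrimidines(ref, kinds=kinds)
    weights: dict[DipySite, float] = {}
    for site in sites:
        w = config.kind_weights[site.kind]
        for gene in genes:
            e = config.tcr_enrichment.get(gene.gene, 1.0)
            if e != 1.0 and site.strand == gene.ts_strand and gene.start <= site.pos5 < gene.end:
                w *= e
        if w > 0:
            weights[site] = w
    total = sum(weights.values())
    if total <= 0:
        raise XrseqError(f"no eligible damage sites on {ref.name!r}")
    return {s: w / total for s, w in weights.items()}


def simulate_excision_products(
    ref: Reference,
    genes: Sequence[GeneAnnotation],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[str], list[TruthRecord], int]:
    """Draw ``n_molecules`` excision products.

    Returns (insert sequences, truth records, resample count).  On linear
    references, draws whose read would run off an end are resampled and
    counted; circular references never reject.
    """
    n = config.n_molecules
    if n == 0:
        return [], [], 0

    table = site_weight_table(ref, genes, config)
    sites = list(table)
    probs = np.fromiter(table.values(), dtype=float, count=len(sites))
    probs /= probs.sum()
    pos5 = np.array([s.pos5 for s in sites])
    strand_minus = np.array([s.strand == "-" for s in sites])

    lengths = sorted(config.length_weights)
    lprobs = np.array([config.length_weights[L] for L in lengths], dtype=float)
    lprobs /= lprobs.sum()
    offsets = np.array([config.damage_offset[L] for L in lengths])
    lengths_arr = np.array(lengths)

    site_idx = rng.choice(len(sites), size=n, p=probs)
    len_idx = rng.choice(len(lengths), size=n, p=lprobs)

    ref_len = len(ref)
    if not ref.is_circular:
        # rejection-resample draws whose footprint leaves the reference
        resampled = 0
        while True:
            L = lengths_arr[len_idx]
            off = offsets[len_idx]
            p5 = pos5[site_idx]
            start = np.where(strand_minus[site_idx], p5 + off - L, p5 - (off - 1))
            bad = (start < 0) | (start + L > ref_len)
            n_bad = int(bad.sum())
            if n_bad == 0:
                break
            resampled += n_bad
            site_idx[bad] = rng.choice(len(sites), size=n_bad, p=probs)
            len_idx[bad] = rng.choice(len(lengths), size=n_bad, p=lprobs)
    else:
        resampled = 0

    degraded = (
        rng.random(n) < config.degradation_fraction
        if config.degradation_fraction > 0
        else np.zeros(n, dtype=bool)
    )
    trunc_len = rng.integers(4, 12, size=n)

    # vectorized extraction, grouped by (length, strand)
    L_all = lengths_arr[len_idx]
    off_all = offsets[len_idx]
    p5_all = pos5[site_idx]
    minus_all = strand_minus[site_idx]
    start_all = np.where(minus_all, p5_all + off_all - L_all, p5_all - (off_all - 1))
    if ref.is_circular:
        start_all = start_all % ref_len
    seq_u8 = np.frombuffer(ref.sequence.encode(), dtype=np.uint8)
    comp = np.arange(256, dtype=np.uint8)
    for a, b in zip(b"ACGTN", b"TGCAN"):
        comp[a] = b
    inserts_arr = np.empty(n, dtype=object)
    for L in np.unique(L_all):
        for on_minus in (False, True):
            sel = (L_all == L) & (minus_all == on_minus)
            if not sel.any():
                continue
            idx = (start_all[sel][:, None] + np.arange(L)) % ref_len
            block = seq_u8[idx]
            if on_minus:
                block = comp[block[:, ::-1]]
            inserts_arr[sel] = (
                np.ascontiguousarray(block).view(f"S{L}").ravel().astype(str)
            )

    # first annotated gene covering each damage site, if any
    gene_at = np.full(ref_len, None, dtype=object)
    for gene in reversed(genes):
        gene_at[gene.start : gene.end] = gene.gene

    strand_char = np.where(minus_all, "-", "+")
    inserts: list[str] = []
    truth: list[TruthRecord] = []
    for i in range(n):
        seq = inserts_arr[i]
        is_deg = bool(degraded[i])
        if is_deg:
            seq = seq[len(seq) - int(trunc_len[i]) :]
        p5 = int(p5_all[i])
        inserts.append(seq)
        truth.append(
            TruthRecord(
                read_id=f"r{i:07d}",
                origin_pos5=p5,
                origin_strand=strand_char[i],
                length=len(seq),
                gene=gene_at[p5],
                damage_pos=p5,
                is_degraded=is_deg,
            )
        )
    return inserts, truth, resampled


def attach_adapters_and_umi(
    inserts: Sequence[str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[str]:
    """Raw read = UMI (uniform random bases) + insert + 3' adapter."""
    n = len(inserts)
    u = config.umi_length
    if u == 0:
        return [ins + config.adapter3 for ins in inserts]
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    codes = lut[rng.integers(0, 4, size=(n, u))].tobytes().decode()
    return [
        codes[i * u : (i + 1) * u] + ins + config.adapter3
        for i, ins in enumerate(inserts)
    ]


def apply_pcr_duplication(
    raw_reads: Sequence[str],
    truth: Sequence[TruthRecord],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[str], list[TruthRecord]]:
    """Append k ~ Poisson(pcr_dup_mean) byte-identical copies per molecule."""
    n = len(raw_reads)
    if config.pcr_dup_mean == 0 or n == 0:
        return list(raw_reads), list(truth)
    extra = rng.poisson(config.pcr_dup_mean, size=n)
    out_reads = list(raw_reads)
    out_truth = list(truth)
    next_id = n
    for i in range(n):
        t = truth[i]
        for _ in range(int(extra[i])):
            out_reads.append(raw_reads[i])
            out_truth.append(
                TruthRecord(
                    read_id=f"r{next_id:07d}",
                    origin_pos5=t.origin_pos5,
                    origin_strand=t.origin_strand,
                    length=t.length,
                    gene=t.gene,
                    damage_pos=t.damage_pos,
                    is_pcr_duplicate=True,
                    parent_id=t.read_id,
                    is_degraded=t.is_degraded,
                )
            )
            next_id += 1
    return out_reads, out_truth


def write_fastq(path: str | Path, ids: Sequence[str], seqs: Sequence[str]) -> None:
    """Write reads with a constant Q40 placeholder quality."""
    with open(path, "w") as fh:
        fh.write(
            "".join(
                f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n"
                for rid, seq in zip(ids, seqs)
            )
        )


_TRUTH_COLUMNS = [f.name for f in dataclasses.fields(TruthRecord)]


def write_truth_table(path: str | Path, truth: Sequence[TruthRecord]) -> None:
    pd.DataFrame(
        {col: [getattr(t, col) for t in truth] for col in _TRUTH_COLUMNS}
    ).to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        dtype={"gene": "string", "parent_id": "string"},
    )


def simulate_library(
    ref: Reference,
    genes: Sequence[GeneAnnotation],
    config: SimulationConfig,
    fastq_path: str | Path,
    truth_path: str | Path | None = None,
    rng: np.random.Generator | None = None,
) -> dict:
    """Run the full generator for one library and write FASTQ (+ truth)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    inserts, truth, resampled = simulate_excision_products(ref, genes, config, rng)
    raws = attach_adapters_and_umi(inserts, config, rng)
    raws, truth = apply_pcr_duplication(raws, truth, config, rng)
    write_fastq(fastq_path, [t.read_id for t in truth], raws)
    if truth_path is not None:
        write_truth_table(truth_path, truth)
    return {
        "n_molecules": config.n_molecules,
        "n_reads": len(raws),
        "n_resampled": resampled,
    }


def simulate_experiment_pair(
    ref: Reference,
    genes: Sequence[GeneAnnotation],
    config: SimulationConfig,
    e_plus: Mapping[str, float] | None = None,
    e_minus: Mapping[str, float] | None = None,
    outdir: str | Path = ".",
) -> dict:
    """Simulate a matched mfd+ / mfd- library pair.

    The mfd+ library carries the ``e_plus`` per-gene TS enrichment (TCR is
    Mfd dependent); the mfd- library defaults to no enrichment.  The two
    libraries use independent child seeds derived from ``config.seed``.
    Read ids carry no ground truth; the truth tables do.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    children = np.random.SeedSequence(config.seed).spawn(2)
    result = {}
    for tag, enrich, child in (
        ("mfd_plus", e_plus, children[0]),
        ("mfd_minus", e_minus, children[1]),
    ):
        cfg = dataclasses.replace(
            config, tcr_enrichment=dict(enrich) if enrich else {}
        )
        fastq = outdir / f"{tag}.fastq"
        truth = outdir / f"{tag}.truth.tsv"
        stats = simulate_library(
            ref, genes, cfg, fastq, truth, rng=np.random.default_rng(child)
        )
        result[tag] = {"fastq": str(fastq), "truth": str(truth), **stats}
    return result
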