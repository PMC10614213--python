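"""Transcription-coupled repair (TCR) statistics.

For each gene the damage-filtered reads are split between the transcribed
strand (TS, opposite the sense strand) and the nontranscribed strand
(NTS).  Preferential repair of the TS in cells with the
transcription-repair coupling factor Mfd is quantified as a
ratio-of-ratios:

    TCR = (TS/NTS in the mfd+ library) / (TS/NTS in the mfd- library)

TCR > 1 indicates Mfd-dependent transcription-coupled repair.  The mfd-
library serves as the composition control, so sequence effects (e.g. an
uneven TT distribution between strands) cancel; an explicit TT
normalization is nevertheless available, and leaves the TCR unchanged
because it cancels in the ratio-of-ratios.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .align import AlignedExcision
from .errors import UndefinedRatioError, XrseqError
from .reference_io import GeneAnnotation, Reference, tt_strand_ratio
from .repair_map import DamageFilterSpec, damage_position


@dataclass(frozen=True)
class StrandCounts:
    """Damage-site read counts for one gene, split by strand role."""

    gene: str
    ts_count: int
    nts_count: int

    def __post_init__(self) -> None:
        if self.ts_count < 0 or self.nts_count < 0:
            raise XrseqError("counts must be non-negative")


@dataclass(frozen=True)
class TcrResult:
    gene: str
    ratio_plus: float   # TS/NTS in the mfd+ library (NaN if undefined)
    ratio_minus: float  # TS/NTS in the mfd- library
    tcr: float          # ratio_plus / ratio_minus
    tt_norm_ratio: tuple[float, float] | None = None


def count_by_gene(
    alignments: Sequence[AlignedExcision],
    spec: DamageFilterSpec,
    genes: Sequence[GeneAnnotation],
    ref_length: int,
) -> list[StrandCounts]:
    """Assign reads to genes by damage-site coordinate.

    A read counts toward a gene iff the plus-strand coordinate of its
    dimer's 5' base lies in ``[start, end)``; a read overlapping several
    genes counts toward each.
    """
    positions = np.array(
        [damage_position(a, spec, ref_length) for a in alignments], dtype=np.int64
    )
    on_minus = np.array([a.strand == "-" for a in alignments], dtype=bool)
    out = []
    for gene in genes:
        inside = (positions >= gene.start) & (positions < gene.end)
        minus_hits = int((inside & on_minus).sum())
        plus_hits = int(inside.sum()) - minus_hits
        ts, nts = (
            (minus_hits, plus_hits)
            if gene.ts_strand == "-"
            else (plus_hits, minus_hits)
        )
        out.append(StrandCounts(gene=gene.gene, ts_count=ts, nts_count=nts))
    return out


def ts_nts_ratio(counts: StrandCounts) -> float:
    if counts.nts_count == 0:
        raise UndefinedRatioError(
            f"gene {counts.gene!r}: zero NTS reads, undefined ratio"
        )
    return counts.ts_count / counts.nts_count


def tcr(ratio_plus: float, ratio_minus: float) -> float:
    """Ratio-of-ratios: (mfd+ TS/NTS) / (mfd- TS/NTS)."""
    if not ratio_minus > 0:
        raise UndefinedRatioError("mfd- TS/NTS ratio must be > 0")
    return ratio_plus / ratio_minus


def tcr_from_counts(
    counts_plus: StrandCounts, counts_minus: StrandCounts
) -> TcrResult:
    """TCR from raw counts; undefined components propagate as NaN.

    Algebraically the cross-ratio (ts+ * nts-) / (nts+ * ts-).
    """
    if counts_plus.gene != counts_minus.gene:
        raise XrseqError(
            f"gene mismatch: {counts_plus.gene!r} vs {counts_minus.gene!r}"
        )
    try:
        rp = ts_nts_ratio(counts_plus)
    except UndefinedRatioError:
        rp = math.nan
    try:
        rm = ts_nts_ratio(counts_minus)
    except UndefinedRatioError:
        rm = math.nan
    try:
        t = tcr(rp, rm)
    except UndefinedRatioError:
        t = math.nan
    if math.isnan(rp) or math.isnan(rm):
        t = math.nan
    return TcrResult(gene=counts_plus.gene, ratio_plus=rp, ratio_minus=rm, tcr=t)


def normalize_by_tt(
    result: TcrResult, ref: Reference, gene: GeneAnnotation
) -> TcrResult:
    """Divide both TS/NTS ratios by the gene's TT strand ratio.

    The TCR itself is unchanged: the normalization cancels in the
    ratio-of-ratios.
    """
    if gene.gene != result.gene:
        raise XrseqError(f"gene mismatch: {gene.gene!r} vs {result.gene!r}")
    tt = tt_strand_ratio(ref, gene)
    return dataclasses.replace(
        result, tt_norm_ratio=(result.ratio_plus / tt, result.ratio_minus / tt)
    )


def bootstrap_tcr_ci(
    counts_plus: StrandCounts,
    counts_minus: StrandCounts,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the TCR, resampling reads per library."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ests = []
    for _ in range(n_boot):
        vals = []
        for c in (counts_plus, counts_minus):
            n = c.ts_count + c.nts_count
            ts = rng.binomial(n, c.ts_count / n) if n else 0
            vals.append((ts, n - ts))
        (tp, np_), (tm, nm) = vals
        if np_ and tm:
            ests.append((tp / np_) / (tm / nm))
    if not ests:
        return (math.nan, math.nan)
    lo, hi = np.quantile(ests, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def _fmt(x: float) -> str:
    return "NA" if (x is None or math.isnan(x)) else f"{x:.2f}"


def report_table(results: Sequence[TcrResult]) -> pd.DataFrame:
    """Display table: TS/NTS per library and TCR, 2 decimals, NA where
    undefined, rows in input order."""
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "ts_nts_mfd_plus": [_fmt(r.ratio_plus) for r in results],
            "ts_nts_mfd_minus": [_fmt(r.ratio_minus) for r in results],
            "tcr": [_fmt(r.tcr) for r in results],
        }
    )


def write_report(results: Sequence[TcrResult], path: str | Path) -> None:
    report_table(results).to_csv(path, sep="\t", index=False)
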