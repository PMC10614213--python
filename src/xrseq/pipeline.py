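"""End-to-end orchestration: simulate -> preprocess -> align -> map -> tcr.

A pipeline run is configured by a plain dict (usually loaded from YAML),
executed stage by stage with conservation counts collected into a
manifest.  Two presets mirror the two library types:

* ``prokaryote``: 13-nt products, dimer at read positions 8-9, 8-nt UMI;
* ``eukaryote``: 26-nt products, dimer at positions 19-20, no UMI.

All randomness is derived from the single configured seed, so a rerun
with the same config produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import __version__
from .align import (
    AlignedExcision,
    align_all,
    build_index,
    dedup_aligned_umi,
    extract_insert,
    write_alignments_bed,
)
from .errors import XrseqError
from .preprocess import LibraryLayout, preprocess_all
from .reference_io import GeneAnnotation, Reference, read_fasta, read_gene_bed
from .repair_map import (
    DamageFilterSpec,
    coverage_tracks,
    damage_filter,
    subsample,
    write_bedgraph,
    write_length_distribution_tsv,
)
from .synthetic_data import DEFAULT_ADAPTER3, SimulationConfig, simulate_experiment_pair
from .tcr_stats import count_by_gene, tcr_from_counts, write_report

log = logging.getLogger("xrseq")

PRESETS = {
    "prokaryote": {"read_length": 13, "dipy_positions": (8, 9), "umi_length": 8},
    "eukaryote": {"read_length": 26, "dipy_positions": (19, 20), "umi_length": 0},
}

DEFAULT_CONFIG = {
    "mode": "prokaryote",
    "topology": "circular",
    "n_molecules": 10_000,
    "e_plus": {},
    "e_minus": {},
    "subsample_n": 200_000,
    "seed": 0,
    "umi_length": None,       # None -> preset default
    "adapter3": DEFAULT_ADAPTER3,
    "multimapper": "discard",
    "dedup_mode": "raw",      # raw | umi_aligned | both | none
    "filter_kinds": ["TT", "TC", "CT", "CC"],
}


def load_config(path: str | Path) -> dict:
    """Load a YAML pipeline config.

    Relative input paths are resolved first against the current directory,
    then against the config file's parent, so a config can sit next to the
    files it names.
    """
    import yaml

    path = Path(path)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(user)
    for key in ("reference", "genes"):
        p = cfg.get(key)
        if p is not None and not Path(p).exists():
            candidate = path.parent / p
            alt = path.parent.parent / p
            if candidate.exists():
                cfg[key] = str(candidate)
            elif alt.exists():
                cfg[key] = str(alt)
    return cfg


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def filter_spec_from_config(cfg: Mapping) -> DamageFilterSpec:
    preset = PRESETS[cfg.get("mode", "prokaryote")]
    return DamageFilterSpec(
        read_length=int(cfg.get("read_length", preset["read_length"])),
        dipy_positions=tuple(cfg.get("dipy_positions", preset["dipy_positions"])),
        kinds=frozenset(cfg.get("filter_kinds", DEFAULT_CONFIG["filter_kinds"])),
    )


def layout_from_config(cfg: Mapping) -> LibraryLayout:
    preset = PRESETS[cfg.get("mode", "prokaryote")]
    umi = cfg.get("umi_length")
    return LibraryLayout(
        umi_length=preset["umi_length"] if umi is None else int(umi),
        adapter3=cfg.get("adapter3", DEFAULT_ADAPTER3),
    )


def run_library(
    fastq: str | Path,
    ref: Reference,
    genes: Sequence[GeneAnnotation],
    layout: LibraryLayout,
    spec: DamageFilterSpec,
    subsample_n: int,
    seed: int,
    outdir: str | Path | None = None,
    tag: str = "library",
    multimapper: str = "discard",
    dedup_mode: str = "raw",
) -> tuple[list[AlignedExcision], dict[str, str], dict]:
    """Process one FASTQ through preprocess/align/filter/subsample.

    Returns (final alignments, read_id -> insert map, per-stage stats).
    If ``outdir`` is given, BED, bedGraph and distribution TSVs are
    written there under ``tag``.
    """
    stats: dict = {}
    processed, pre_stats = preprocess_all(
        fastq, layout, dedup=dedup_mode in ("raw", "both")
    )
    stats["preprocess"] = pre_stats

    index = build_index(ref, max_query=max(layout.max_insert, spec.read_length) + 1)
    rng = np.random.default_rng(seed)
    aligned, aln_stats = align_all(index, processed, multimapper=multimapper, rng=rng)
    stats["align"] = aln_stats

    if dedup_mode in ("umi_aligned", "both"):
        aligned, removed = dedup_aligned_umi(aligned)
        stats["align"]["umi_dedup_removed"] = removed

    inserts = {a.read_id: extract_insert(ref, a) for a in aligned}
    filtered, filt_stats = damage_filter(aligned, inserts, spec)
    stats["damage_filter"] = filt_stats

    final = subsample(filtered, subsample_n, seed=np.random.default_rng(seed + 1))
    stats["subsample"] = {"input": len(filtered), "kept": len(final)}

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_alignments_bed(final, outdir / f"{tag}.bed")
        track = coverage_tracks(final, ref, spec, mode="damage_site")
        write_bedgraph(track, outdir / f"{tag}.plus.bedgraph", "+")
        write_bedgraph(track, outdir / f"{tag}.minus.bedgraph", "-")
        write_length_distribution_tsv(aligned, outdir / f"{tag}.lengths.tsv")
    return final, inserts, stats


def run_all(config: Mapping | str | Path, outdir: str | Path) -> Path:
    """Simulate an mfd+/mfd- pair and carry both through to the TCR table."""
    if isinstance(config, (str, Path)):
        config = load_config(config)
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "load_inputs"
    try:
        ref_path = cfg["reference"]
        genes_path = cfg["genes"]
        for p in (ref_path, genes_path):
            if not Path(p).exists():
                raise XrseqError(f"input file not found: {p}")
        ref = read_fasta(ref_path, topology=cfg["topology"])[0]
        genes = read_gene_bed(genes_path, ref)

        stage = "simulate"
        layout = layout_from_config(cfg)
        spec = filter_spec_from_config(cfg)
        sim_cfg_kwargs = dict(
            n_molecules=int(cfg["n_molecules"]),
            umi_length=layout.umi_length,
            adapter3=layout.adapter3,
            seed=int(cfg["seed"]),
        )
        sim = (
            SimulationConfig.eukaryote(**sim_cfg_kwargs)
            if cfg["mode"] == "eukaryote"
            else SimulationConfig.prokaryote(**sim_cfg_kwargs)
        )
        sim_dir = outdir / "simulated"
        sim_info = simulate_experiment_pair(
            ref, genes, sim, e_plus=cfg["e_plus"], e_minus=cfg["e_minus"],
            outdir=sim_dir,
        )
        log.info("simulate: %s", {k: v["n_reads"] for k, v in sim_info.items()})

        manifest = {
            "xrseq_version": __version__,
            "seed": int(cfg["seed"]),
            "config": {k: v for k, v in cfg.items()},
            "inputs": {
                "reference": {"path": str(ref_path), "sha256": _sha256(ref_path)},
                "genes": {"path": str(genes_path), "sha256": _sha256(genes_path)},
            },
            "stages": {},
        }

        counts = {}
        for i, tag in enumerate(("mfd_plus", "mfd_minus")):
            stage = f"process:{tag}"
            final, _inserts, stats = run_library(
                sim_info[tag]["fastq"], ref, genes, layout, spec,
                subsample_n=int(cfg["subsample_n"]),
                seed=int(cfg["seed"]) * 2 + i + 1,
                outdir=outdir, tag=tag,
                multimapper=cfg["multimapper"], dedup_mode=cfg["dedup_mode"],
            )
            stats["simulate"] = {
                k: v for k, v in sim_info[tag].items() if isinstance(v, int)
            }
            manifest["stages"][tag] = stats
            counts[tag] = count_by_gene(final, spec, genes, len(ref))
            log.info("%s: %d reads after filter+subsample", tag, len(final))

        stage = "tcr"
        results = [
            tcr_from_counts(cp, cm)
            for cp, cm in zip(counts["mfd_plus"], counts["mfd_minus"])
        ]
        write_report(results, outdir / "tcr_table.tsv")
        manifest["tcr"] = [dataclasses.asdict(r) for r in results]

        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    except XrseqError as exc:
        raise XrseqError(f"[{stage}] {exc}") from exc
    return outdir
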