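import filecmp
import math
from collections import Counter

import numpy as np
import pytest
from scipy import stats

from xrseq import SimulationConfig, XrseqError, tt_strand_ratio
from xrseq.synthetic_data import (
    apply_pcr_duplication,
    attach_adapters_and_umi,
    random_reference,
    read_truth_table,
    simulate_excision_products,
    simulate_experiment_pair,
    site_weight_table,
)


class TestSiteWeightTable:
    def test_weights_normalized_and_uniform_within_kind(self, plasmid):
        cfg = SimulationConfig.prokaryote()
        table = site_weight_table(plasmid, [], cfg)
        assert sum(table.values()) == pytest.approx(1.0)
        by_kind = {}
        for site, w in table.items():
            by_kind.setdefault(site.kind, set()).add(round(w, 15))
        for kind, values in by_kind.items():
            assert len(values) == 1, f"non-uniform weights within {kind}"

    def test_enrichment_multiplies_ts_sites(self, plasmid, gene_bla):
        """e=6 scales gene-TS site weights 6x relative to all other sites
        (up to the global renormalization)."""
        base = site_weight_table(plasmid, [gene_bla], SimulationConfig.prokaryote())
        enriched = site_weight_table(
            plasmid, [gene_bla],
            SimulationConfig.prokaryote(tcr_enrichment={"bla": 6.0}),
        )
        ts = gene_bla.ts_strand
        in_ts, outside = [], []
        for site in base:
            r = enriched[site] / base[site]
            if site.strand == ts and gene_bla.start <= site.pos5 < gene_bla.end:
                in_ts.append(r)
            else:
                outside.append(r)
        assert np.allclose(in_ts, in_ts[0]) and np.allclose(outside, outside[0])
        assert in_ts[0] / outside[0] == pytest.approx(6.0)

    def test_zero_enrichment_removes_ts_sites(self, plasmid, gene_bla):
        cfg = SimulationConfig.prokaryote(tcr_enrichment={"bla": 0.0})
        table = site_weight_table(plasmid, [gene_bla], cfg)
        ts = gene_bla.ts_strand
        assert not any(
            s.strand == ts and gene_bla.start <= s.pos5 < gene_bla.end for s in table
        )

    def test_no_eligible_sites_is_error(self):
        ref = random_reference(50, seed=1, topology="linear")
        cfg = SimulationConfig.prokaryote(
            kind_weights={"TT": 0.0, "TC": 0.0, "CT": 0.0, "CC": 1.0}
        )
        # a sequence without CC/GG dinucleotides
        from xrseq import Reference

        with pytest.raises(XrseqError):
            site_weight_table(Reference("p", "ACAT" * 10), [], cfg)


class TestSimulateExcisionProducts:
    def test_zero_molecules(self, plasmid, rng):
        cfg = SimulationConfig.prokaryote(n_molecules=0)
        inserts, truth, resampled = simulate_excision_products(plasmid, [], cfg, rng)
        assert inserts == [] and truth == [] and resampled == 0

    def test_length_mode_is_13(self, plasmid, rng):
        cfg = SimulationConfig.prokaryote(n_molecules=10_000)
        inserts, truth, _ = simulate_excision_products(plasmid, [], cfg, rng)
        lengths = Counter(t.length for t in truth if not t.is_degraded)
        frac13 = lengths[13] / sum(lengths.values())
        assert abs(frac13 - 0.85) < 0.02

    def test_length_histogram_goodness_of_fit(self, plasmid, rng):
        cfg = SimulationConfig.prokaryote(n_molecules=10_000)
        _, truth, _ = simulate_excision_products(plasmid, [], cfg, rng)
        obs = Counter(t.length for t in truth if not t.is_degraded)
        n = sum(obs.values())
        expected = [cfg.length_weights[L] * n for L in (12, 13, 14)]
        chi2 = stats.chisquare([obs[L] for L in (12, 13, 14)], expected)
        assert chi2.pvalue > 0.01

    def test_dimer_at_configured_offset_every_read(self, plasmid, rng):
        """Every non-degraded read carries a dipyrimidine of a sampled kind
        at its length's damage offset, on its own sequence and on the
        reference at the recorded damage coordinate."""
        cfg = SimulationConfig.prokaryote(n_molecules=2_000)
        inserts, truth, _ = simulate_excision_products(plasmid, [], cfg, rng)
        kinds = set(cfg.kind_weights)
        for seq, t in zip(inserts, truth):
            if t.is_degraded:
                assert 4 <= t.length <= 11
                continue
            off = cfg.damage_offset[t.length]
            assert seq[off - 1 : off + 1] in kinds
            # independent check on the reference
            p = t.damage_pos
            if t.origin_strand == "+":
                ref_dinuc = plasmid.fetch(p, 2, "+")
            else:
                ref_dinuc = plasmid.fetch((p - 1) % len(plasmid), 2, "-")
            assert ref_dinuc == seq[off - 1 : off + 1]

    def test_linear_reference_resamples_overhanging_reads(self, rng):
        ref = random_reference(60, seed=3, topology="linear")
        cfg = SimulationConfig.prokaryote(n_molecules=500)
        inserts, truth, resampled = simulate_excision_products(ref, [], cfg, rng)
        assert len(inserts) == 500
        # no read may extend outside the linear reference
        for seq, t in zip(inserts, truth):
            if t.is_degraded:
                continue
            off = cfg.damage_offset[t.length]
            if t.origin_strand == "+":
                start = t.origin_pos5 - (off - 1)
            else:
                start = t.origin_pos5 + off - t.length
            assert 0 <= start and start + t.length <= 60


class TestAdaptersAndUmi:
    def test_no_umi_no_adapter_is_identity(self, rng):
        cfg = SimulationConfig.prokaryote(umi_length=0, adapter3="")
        assert attach_adapters_and_umi(["ACGTACGT"], cfg, rng) == ["ACGTACGT"]

    def test_read_layout_lengths(self, rng):
        cfg = SimulationConfig.prokaryote()
        (raw,) = attach_adapters_and_umi(["A" * 13], cfg, rng)
        assert len(raw) == 13 + 8 + len(cfg.adapter3)
        assert raw[8:21] == "A" * 13
        assert raw.endswith(cfg.adapter3)

    def test_same_insert_distinct_umis(self, rng):
        cfg = SimulationConfig.prokaryote()
        raws = attach_adapters_and_umi(["ACGTACGTACGTA"] * 2, cfg, rng)
        assert raws[0][:8] != raws[1][:8]


class TestPcrDuplication:
    def test_mean_zero_is_identity(self, rng):
        cfg = SimulationConfig.prokaryote(pcr_dup_mean=0.0)
        reads, truth, _ = simulate_excision_products(
            random_reference(500, 5), [], SimulationConfig.prokaryote(n_molecules=10), rng
        )
        out_reads, out_truth = apply_pcr_duplication(reads, truth, cfg, rng)
        assert out_reads == reads and out_truth == truth

    def test_poisson_mean_total_over_unique(self, plasmid, rng):
        cfg = SimulationConfig.prokaryote(n_molecules=10_000, pcr_dup_mean=1.0)
        inserts, truth, _ = simulate_excision_products(plasmid, [], cfg, rng)
        raws = attach_adapters_and_umi(inserts, cfg, rng)
        out_reads, out_truth = apply_pcr_duplication(raws, truth, cfg, rng)
        assert abs(len(out_reads) / len(raws) - 2.0) < 0.05

    def test_duplicates_byte_identical_with_parent_link(self, plasmid, rng):
        cfg = SimulationConfig.prokaryote(n_molecules=200, pcr_dup_mean=2.0)
        inserts, truth, _ = simulate_excision_products(plasmid, [], cfg, rng)
        raws = attach_adapters_and_umi(inserts, cfg, rng)
        out_reads, out_truth = apply_pcr_duplication(raws, truth, cfg, rng)
        by_id = {t.read_id: r for t, r in zip(out_truth, out_reads)}
        dups = [t for t in out_truth if t.is_pcr_duplicate]
        assert dups, "expected some duplicates at mean 2"
        for d in dups:
            assert by_id[d.read_id] == by_id[d.parent_id]


class TestExperimentPair:
    def test_identical_seeds_byte_identical_fastq(self, plasmid, gene_bla, tmp_path):
        cfg = SimulationConfig.prokaryote(n_molecules=500, seed=99)
        a = simulate_experiment_pair(
            plasmid, [gene_bla], cfg, e_plus={"bla": 2.0}, outdir=tmp_path / "a"
        )
        b = simulate_experiment_pair(
            plasmid, [gene_bla], cfg, e_plus={"bla": 2.0}, outdir=tmp_path / "b"
        )
        for tag in ("mfd_plus", "mfd_minus"):
            assert filecmp.cmp(a[tag]["fastq"], b[tag]["fastq"], shallow=False)
            assert filecmp.cmp(a[tag]["truth"], b[tag]["truth"], shallow=False)

    def test_pair_libraries_differ_and_parse(self, prokaryote_pair):
        from xrseq.preprocess import read_fastq

        info = prokaryote_pair["info"]
        plus = read_fastq(info["mfd_plus"]["fastq"])
        minus = read_fastq(info["mfd_minus"]["fastq"])
        assert plus and minus
        assert plus[0][1] != minus[0][1]
        # ids are anonymous serial numbers: no coordinates leaked
        assert all(rid.startswith("r") and rid[1:].isdigit() for rid, _ in plus)

    def test_truth_table_round_trips(self, prokaryote_pair):
        df = read_truth_table(prokaryote_pair["info"]["mfd_plus"]["truth"])
        n = prokaryote_pair["config"].n_molecules
        assert (~df.is_pcr_duplicate).sum() == n
        assert set(df.columns) >= {
            "read_id", "origin_pos5", "origin_strand", "length",
            "gene", "damage_pos", "is_pcr_duplicate", "parent_id",
        }

    def test_unenriched_ts_nts_matches_tt_composition(self, plasmid, gene_bla, rng):
        """With no enrichment and TT-only damage, the expected TS/NTS read
        count ratio in a gene equals its TT strand ratio."""
        cfg = SimulationConfig.prokaryote(
            n_molecules=100_000,
            kind_weights={"TT": 1.0},
            degradation_fraction=0.0,
            seed=5,
        )
        _, truth, _ = simulate_excision_products(
            plasmid, [gene_bla], cfg, np.random.default_rng(5)
        )
        ts = gene_bla.ts_strand
        in_gene = [t for t in truth if t.gene == "bla"]
        ts_n = sum(t.origin_strand == ts for t in in_gene)
        nts_n = len(in_gene) - ts_n
        observed = ts_n / nts_n
        expected = tt_strand_ratio(plasmid, gene_bla)
        se = observed * math.sqrt(1 / ts_n + 1 / nts_n)
        assert abs(observed - expected) < 3 * se
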