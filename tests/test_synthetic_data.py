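"""Generator determinism, constraint satisfaction and calibration."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from startpipe.startseq_signal import count_five_prime_ends
from startpipe.synthetic_data import (SimConfig, place_sites, simulate_annotation,
                                      simulate_chip_track, simulate_event_table,
                                      simulate_junction_reads, simulate_startseq)


SMALL = dict(n_genes=20, chrom_length=150_000, n_nu_sites=10, n_events=50)


class TestSimulateAnnotation:
    def test_deterministic_under_seed(self):
        a = simulate_annotation(SimConfig(seed=1, **SMALL))
        b = simulate_annotation(SimConfig(seed=1, **SMALL))
        assert a == b

    def test_different_seed_differs(self):
        a = simulate_annotation(SimConfig(seed=1, **SMALL))
        b = simulate_annotation(SimConfig(seed=2, **SMALL))
        assert a != b

    def test_genes_separated_by_min_gap(self):
        ann = simulate_annotation(SimConfig(seed=4, **SMALL))
        for chrom in ("chr1", "chr2"):
            spans = sorted(g.span for g in ann.genes_on(chrom))
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert s2 - e1 >= 1000

    def test_strand_balance_within_binomial_99ci(self):
        """Across seeds, plus-strand gene counts stay inside the exact
        central 99% binomial(n, 0.5) interval."""
        n = 100
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.5)
        for seed in range(10):
            ann = simulate_annotation(SimConfig(seed=seed))
            k = sum(1 for g in ann.genes if g.strand == "+")
            assert lo <= k <= hi

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="increase chrom_length"):
            simulate_annotation(SimConfig(seed=0, n_genes=500, chrom_length=100_000))

    def test_every_gene_has_utr_inside_terminal_exon(self):
        ann = simulate_annotation(SimConfig(seed=5, **SMALL))
        for g in ann.genes:
            exons = g.transcripts[0][1]
            terminal = exons[-1] if g.strand == "+" else exons[0]
            us, ue = g.utr3
            assert terminal[0] <= us < ue <= terminal[1]


class TestSimulateStartseq:
    def _run(self, seed=7, **over):
        config = SimConfig(seed=seed, **{**SMALL, **over})
        ann = simulate_annotation(config)
        sites = place_sites(ann, config)
        return config, ann, sites, simulate_startseq(ann, sites, config)

    def test_spike_counts_emitted_exactly(self):
        config, ann, _, reads = self._run()
        for sample, spec in config.samples.items():
            n_spike = sum(1 for r in reads[sample] if r.category == "spike")
            assert n_spike == spec["spike"]

    def test_deterministic_under_seed(self):
        _, _, _, a = self._run(seed=9)
        _, _, _, b = self._run(seed=9)
        assert a == b

    def test_zero_strength_site_never_observed(self):
        config, ann, sites, _ = self._run()
        site = dataclasses.replace(sites[0])
        site.expected_count_by_sample = {s: 0.0 for s in config.samples}
        reads = simulate_startseq(ann, [site], config)
        for sample in config.samples:
            genomic = [r for r in reads[sample] if r.category == "genomic"
                       and r.read_id.startswith(f"{sample}:{site.site_id}")]
            assert genomic == []

    def test_nu_sites_clear_of_annotated_tss(self):
        _, ann, sites, _ = self._run()
        tss = {(g.chrom, t) for g in ann.genes for t in g.annotated_tss}
        for s in sites:
            if s.status == "nu":
                assert all(not (c == s.chrom and abs(p - s.pos) <= 50) for c, p in tss)

    def test_site_counts_unbiased_over_seeds(self):
        """Mean observed count at one site over 200 seeds is within 3
        standard errors of its Poisson expectation."""
        config = SimConfig(seed=0, **SMALL)
        ann = simulate_annotation(config)
        site = place_sites(ann, config)[0]
        lam = site.expected_count_by_sample["hwt"]
        counts = []
        for seed in range(200):
            cfg = dataclasses.replace(config, seed=seed)
            reads = simulate_startseq(ann, [site], cfg)
            counts.append(sum(1 for r in reads["hwt"]
                              if r.read_id.startswith(f"hwt:{site.site_id}")))
        se = np.sqrt(lam / 200)
        assert abs(np.mean(counts) - lam) <= 3 * se

    def test_doubling_depth_doubles_expectation_but_not_spikes(self):
        config = SimConfig(seed=0, **SMALL)
        deeper = dataclasses.replace(config, samples={
            "hwt": {"depth": 2.0, "spike": 1000, "condition": "ctrl"},
            "k36r": {"depth": 2.4, "spike": 1200, "condition": "mut"},
        })
        ann = simulate_annotation(config)
        base = place_sites(ann, config)
        scaled = place_sites(ann, deeper)
        for a, b in zip(base, scaled):
            assert b.expected_count_by_sample["hwt"] == \
                pytest.approx(2.0 * a.expected_count_by_sample["hwt"])
        reads = simulate_startseq(ann, scaled, deeper)
        assert sum(1 for r in reads["hwt"] if r.category == "spike") == 1000

    def test_five_prime_ends_sit_on_site_bases(self):
        config, ann, sites, reads = self._run()
        genomic_sizes = {c: L for c, L in ann.chrom_sizes.items() if c != config.spike_ref}
        sig = count_five_prime_ends(reads["hwt"], "hwt", genomic_sizes)
        for s in sites[:10]:
            n = sum(1 for r in reads["hwt"]
                    if r.read_id.startswith(f"hwt:{s.site_id}:"))
            assert sig.vector(s.chrom, s.strand)[s.pos] >= n  # background may add


class TestSimulateJunctionReads:
    def _one_junction_ann(self, config):
        ann = simulate_annotation(config)
        first = next(g for g in ann.genes if len(g.transcripts[0][1]) >= 2)
        ann.genes = [first]
        return ann

    def test_rho_zero_all_reads_gapped(self):
        config = SimConfig(seed=1, **SMALL)
        ann = self._one_junction_ann(config)
        from startpipe.splicing_fidelity import enumerate_junctions
        jid = enumerate_junctions(ann)[0].junction_id
        reads, truth = simulate_junction_reads(
            ann, config, rho_by_junction={jid: {s: 0.0 for s in config.samples}},
            depth=200)
        sample = sorted(config.samples)[0]
        target = [r for r in reads[sample] if f":{jid}:" in r.read_id]
        assert target and all(len(r.blocks) == 2 for r in target)

    def test_rho_one_all_reads_contiguous(self):
        config = SimConfig(seed=1, **SMALL)
        ann = self._one_junction_ann(config)
        from startpipe.splicing_fidelity import enumerate_junctions
        jid = enumerate_junctions(ann)[0].junction_id
        reads, _ = simulate_junction_reads(
            ann, config, rho_by_junction={jid: {s: 1.0 for s in config.samples}},
            depth=200)
        sample = sorted(config.samples)[0]
        target = [r for r in reads[sample] if f":{jid}:" in r.read_id]
        assert target and all(len(r.blocks) == 1 for r in target)

    def test_realized_fraction_near_rho_at_high_depth(self):
        config = SimConfig(seed=2, **SMALL)
        ann = self._one_junction_ann(config)
        from startpipe.splicing_fidelity import enumerate_junctions
        jid = enumerate_junctions(ann)[0].junction_id
        _, truth = simulate_junction_reads(
            ann, config, rho_by_junction={jid: {s: 0.3 for s in config.samples}},
            depth=10_000)
        t = next(t for t in truth if t.junction_id == jid)
        se = np.sqrt(0.3 * 0.7 / 10_000)
        for s in config.samples:
            assert abs(t.n_by_sample[s] / 10_000 - 0.3) <= 3 * se

    def test_reads_respect_min_overhang(self):
        config = SimConfig(seed=3, **SMALL)
        ann = self._one_junction_ann(config)
        reads, _ = simulate_junction_reads(ann, config, depth=100)
        from startpipe.splicing_fidelity import enumerate_junctions
        jx = enumerate_junctions(ann)[0]
        sample = sorted(config.samples)[0]
        target = [r for r in reads[sample] if f":{jx.junction_id}:" in r.read_id]
        assert target
        for r in target:
            if len(r.blocks) == 2:
                (s1, e1), (s2, e2) = r.blocks
                assert e1 - s1 >= config.min_overhang and e2 - s2 >= config.min_overhang
            else:
                (s, e) = r.blocks[0]
                assert jx.donor - s + 1 >= config.min_overhang
                assert e - jx.donor - 1 >= config.min_overhang


class TestSimulateChipTrack:
    def test_zero_skew_flat_over_gene_body(self):
        config = SimConfig(seed=1, **SMALL, chip_skew=0.0, chip_exon_weight=1.0)
        ann = simulate_annotation(config)
        track, _ = simulate_chip_track(ann, config)
        g = ann.genes[0]
        vec = track.vector(g.chrom, ".")[g.span[0]:g.span[1]]
        assert np.allclose(vec, config.chip_base)

    def test_exon_intron_weight_ratio(self):
        config = SimConfig(seed=1, **SMALL, chip_skew=0.0, chip_exon_weight=2.0)
        ann = simulate_annotation(config)
        track, _ = simulate_chip_track(ann, config)
        g = next(g for g in ann.genes if len(g.transcripts[0][1]) >= 2)
        vec = track.vector(g.chrom, ".")
        s, e = g.span
        exon_mask = np.zeros(e - s, dtype=bool)
        for es, ee in g.union_exons():
            exon_mask[es - s:ee - s] = True
        assert vec[s:e][exon_mask].mean() == pytest.approx(
            2.0 * vec[s:e][~exon_mask].mean())

    def test_zero_background_leaves_intergenic_zero(self):
        config = SimConfig(seed=1, **SMALL, chip_background=0.0)
        ann = simulate_annotation(config)
        track, _ = simulate_chip_track(ann, config)
        covered = np.zeros(config.chrom_length, dtype=bool)
        for g in ann.genes_on("chr1"):
            covered[g.span[0]:g.span[1]] = True
        assert track.vector("chr1", ".")[~covered].sum() == 0.0

    def test_truth_matches_track_mean_over_gene(self):
        config = SimConfig(seed=6, **SMALL)
        ann = simulate_annotation(config)
        track, density = simulate_chip_track(ann, config)
        g = ann.genes[0]
        assert density[g.gene_id] == pytest.approx(
            track.vector(g.chrom, ".")[g.span[0]:g.span[1]].mean())


class TestSimulateEventTable:
    def test_forced_significant_construction(self):
        events, truth = simulate_event_table(100, SimConfig(seed=1, sig_fraction=1.0))
        assert all(truth.values())
        assert all(e.bayes_factor_combined > 10 for e in events)
        for e in events:
            signs = {np.sign(d) for d in e.delta_psi_by_replicate}
            assert len(signs) == 1 and 0 not in signs

    def test_zero_fraction_all_nonsignificant(self):
        events, truth = simulate_event_table(100, SimConfig(seed=1, sig_fraction=0.0))
        assert not any(truth.values())

    def test_manifest_count_matches_filter(self):
        from startpipe.splicing_fidelity import filter_events
        events, truth = simulate_event_table(100, SimConfig(seed=2))
        filter_events(events)
        assert {e.event_id: e.significant for e in events} == truth
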