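"""Junction enumeration, j/n counting, retention ratios and event filters."""

import numpy as np
import pytest

from startpipe.io_formats import GeneRecord, GenomeAnnotation, ReadAlignment
from startpipe.splicing_fidelity import (JunctionRecord, SplicingEvent, count_junction_reads,
                                         enumerate_junctions, filter_events, retention_ratio,
                                         severity_summary)


def brute_force_counts(reads, junctions, min_overhang):
    """Independent oracle: literal per-read per-junction rule evaluation."""
    out = {j.junction_id: [0, 0] for j in junctions}
    for j in junctions:
        for r in reads:
            if r.chrom != j.chrom or r.strand != j.strand:
                continue
            hit = None
            for k in range(len(r.blocks) - 1):
                (s1, e1), (s2, e2) = r.blocks[k], r.blocks[k + 1]
                gap_first, gap_last = e1, s2 - 1          # gap covers [e1, s2)
                if gap_first == j.donor + 1 and gap_last == j.acceptor - 1:
                    if e1 - s1 >= min_overhang and e2 - s2 >= min_overhang:
                        hit = "j"
            if hit is None:
                for (s, e) in r.blocks:
                    left = j.donor - s + 1
                    right = e - j.donor - 1
                    if s <= j.donor and j.donor + 1 < e and \
                            left >= min_overhang and right >= min_overhang:
                        hit = "n"
            if hit == "j":
                out[j.junction_id][0] += 1
            elif hit == "n":
                out[j.junction_id][1] += 1
    return out


class TestEnumerateJunctions:
    def test_single_exon_gene_has_no_junctions(self, tiny_annotation):
        only_gc = GenomeAnnotation(chrom_sizes=tiny_annotation.chrom_sizes,
                                   genes=[tiny_annotation.genes[2]])
        assert enumerate_junctions(only_gc) == []

    def test_three_exon_transcript_yields_two_junctions(self):
        g = GeneRecord(gene_id="g", chrom="chr1", strand="+", span=(100, 1000),
                       transcripts=[("t", [(100, 200), (300, 400), (500, 1000)])])
        ann = GenomeAnnotation(chrom_sizes={"chr1": 10_000}, genes=[g])
        jx = enumerate_junctions(ann)
        assert [(j.donor, j.acceptor) for j in jx] == [(199, 300), (399, 500)]

    def test_shared_junction_emitted_once(self):
        exons = [(100, 200), (300, 400)]
        g = GeneRecord(gene_id="g", chrom="chr1", strand="+", span=(100, 400),
                       transcripts=[("t1", exons), ("t2", exons)])
        ann = GenomeAnnotation(chrom_sizes={"chr1": 10_000}, genes=[g])
        assert len(enumerate_junctions(ann)) == 1


class TestCountJunctionReads:
    def _jx(self, donor=199, acceptor=300):
        return JunctionRecord(junction_id="j1", chrom="chr1", strand="+",
                              donor=donor, acceptor=acceptor)

    def _count(self, blocks, donor=199, acceptor=300):
        jx = [self._jx(donor, acceptor)]
        reads = [ReadAlignment("r", "s", "chr1", "+", blocks)]
        count_junction_reads({"c": reads}, jx)
        return jx[0].j_by_condition["c"], jx[0].n_by_condition["c"]

    def test_exact_gap_with_overhang_counts_junction(self):
        assert self._count([(190, 200), (300, 310)]) == (1, 0)

    def test_contiguous_read_through_donor_counts_non_junction(self):
        assert self._count([(189, 210)]) == (0, 1)

    def test_imprecise_gap_counts_neither(self):
        """A gapped read whose gap ends 2 nt short of the acceptor matches
        neither j nor n."""
        assert self._count([(190, 200), (298, 310)]) == (0, 0)

    def test_insufficient_overhang_counts_neither(self):
        assert self._count([(197, 200), (300, 310)]) == (0, 0)
        assert self._count([(197, 202)]) == (0, 0)

    def test_wrong_strand_ignored(self):
        jx = [self._jx()]
        reads = [ReadAlignment("r", "s", "chr1", "-", [(190, 200), (300, 310)])]
        count_junction_reads({"c": reads}, jx)
        assert jx[0].j_by_condition["c"] == 0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            junctions = []
            for k in range(int(rng.integers(1, 4))):
                donor = int(rng.integers(150, 700))
                acceptor = donor + int(rng.integers(30, 120))
                junctions.append(JunctionRecord(
                    junction_id=f"jx{k}", chrom="chr1", strand="+",
                    donor=donor, acceptor=acceptor))
            reads = []
            for i in range(int(rng.integers(10, 400))):
                anchor = int(rng.integers(100, 800))
                if rng.random() < 0.5:
                    gap = int(rng.integers(20, 150))
                    o1, o2 = int(rng.integers(1, 30)), int(rng.integers(1, 30))
                    blocks = [(anchor - o1, anchor), (anchor + gap, anchor + gap + o2)]
                else:
                    blocks = [(anchor, anchor + int(rng.integers(10, 60)))]
                reads.append(ReadAlignment(f"r{i}", "s", "chr1", "+", blocks))
            expected = brute_force_counts(reads, junctions, 4)
            count_junction_reads({"c": reads}, junctions, 4)
            for j in junctions:
                assert (j.j_by_condition["c"], j.n_by_condition["c"]) == \
                    tuple(expected[j.junction_id])


class TestRetentionRatio:
    def _jr(self, j_ctrl, n_ctrl, j_mut=0, n_mut=0):
        jr = JunctionRecord(junction_id="j", chrom="chr1", strand="+", donor=10, acceptor=50,
                            j_by_condition={"ctrl": j_ctrl, "mut": j_mut},
                            n_by_condition={"ctrl": n_ctrl, "mut": n_mut})
        retention_ratio([jr], "ctrl", "mut")
        return jr

    def test_all_junction_reads_give_zero_retention(self):
        assert self._jr(10, 0).R_by_condition["ctrl"] == 0.0

    def test_quarter_retention(self):
        assert self._jr(15, 5).R_by_condition["ctrl"] == 0.25

    def test_exactly_twenty_reads_is_unpowered(self):
        """The power filter is strictly greater than 20 total reads."""
        jr = self._jr(15, 5, j_mut=30, n_mut=5)
        assert jr.powered_by_condition["ctrl"] is False
        assert jr.powered_by_condition["mut"] is True
        assert jr.delta_R is None

    def test_delta_r_when_both_powered(self):
        jr = self._jr(21, 0, j_mut=15, n_mut=10)
        assert jr.delta_R == pytest.approx(10 / 25 - 0.0)

    def test_delta_r_antisymmetric_under_condition_swap(self):
        jr = JunctionRecord(junction_id="j", chrom="chr1", strand="+", donor=10, acceptor=50,
                            j_by_condition={"a": 30, "b": 18},
                            n_by_condition={"a": 10, "b": 12})
        retention_ratio([jr], "a", "b")
        fwd = jr.delta_R
        retention_ratio([jr], "b", "a")
        assert fwd == -jr.delta_R

    def test_r_monotone_nondecreasing_in_n(self):
        rs = [self._jr(10, n).R_by_condition["ctrl"] for n in range(0, 40)]
        assert all(0.0 <= r <= 1.0 for r in rs)
        assert all(b >= a for a, b in zip(rs, rs[1:]))


class TestFilterEvents:
    def _ev(self, bf, dpsi):
        return SplicingEvent(event_id="e", type="retained_intron",
                             bayes_factor_combined=bf, delta_psi_by_replicate=list(dpsi))

    @pytest.mark.parametrize("bf,dpsi,expected", [
        (12.0, (0.3, 0.2, 0.4), True),     # both rules pass
        (9.0, (0.3, 0.2, 0.4), False),     # BF below threshold
        (50.0, (0.3, -0.1, 0.4), False),   # inconsistent sign
        (10.0, (0.3, 0.2, 0.4), False),    # BF exactly 10 fails the strict bound
        (15.0, (-0.3, -0.2, -0.4), True),  # all-negative is consistent
        (15.0, (0.3, 0.0, 0.4), False),    # a zero breaks consistency
    ])
    def test_significance_rule_branches(self, bf, dpsi, expected):
        (ev,) = filter_events([self._ev(bf, dpsi)])
        assert ev.significant is expected

    def test_replicate_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="replicate"):
            filter_events([self._ev(12.0, (0.3, 0.2))])

    def test_combined_dpsi_is_replicate_mean(self):
        (ev,) = filter_events([self._ev(12.0, (0.3, 0.2, 0.4))])
        assert ev.delta_psi_combined == pytest.approx(0.3)


class TestSeveritySummary:
    def _events(self, spec):
        out = []
        for i, (etype, sig, dpsi) in enumerate(spec):
            ev = SplicingEvent(event_id=f"e{i}", type=etype, bayes_factor_combined=50.0,
                               delta_psi_by_replicate=[dpsi] * 3,
                               delta_psi_combined=dpsi, significant=sig)
            out.append(ev)
        return out

    def test_no_significant_events_gives_zeros(self):
        table = severity_summary(self._events([("retained_intron", False, 0.5)]))
        row = table.loc["retained_intron"]
        assert (row["n_significant"], row["n_above_threshold"], row["fraction"]) == (0, 0, 0.0)

    def test_fraction_above_threshold(self):
        spec = [("skipped_exon", True, 0.3)] + [("skipped_exon", True, 0.1)] * 3
        row = severity_summary(self._events(spec)).loc["skipped_exon"]
        assert (row["n_significant"], row["n_above_threshold"]) == (4, 1)
        assert row["fraction"] == pytest.approx(0.25)

    def test_zero_threshold_counts_all_significant(self):
        spec = [("retained_intron", True, 0.05), ("retained_intron", True, 0.4)]
        row = severity_summary(self._events(spec), dpsi_threshold=0.0).loc["retained_intron"]
        assert row["n_above_threshold"] == row["n_significant"] == 2
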