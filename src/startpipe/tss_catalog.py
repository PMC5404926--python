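"""Call single-base TSSs and classify them against a gene model.

A called initiation base that falls within a match tolerance of an
annotated transcription start site is an observed TSS (obsTSS); everything
else is a novel unannotated TSS (nuTSS).  nuTSSs are classified by genomic
context (exonic / intronic / intergenic, union-exon rule) and orientation
(sense / antisense relative to the resident gene), and placed on a scaled
gene-relative axis for positional summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_formats import GeneRecord, GenomeAnnotation
from .startseq_signal import BaseSignal

__all__ = [
    "TssRecord",
    "call_tss",
    "split_obs_nu",
    "classify_nutss",
    "nearest_gene_and_scaled_position",
    "read_signal_at",
]

DEFAULT_MATCH_TOL = 50
DEFAULT_MIN_SIGNAL = 3.0
DEFAULT_MERGE_DIST = 5
DEFAULT_FLANK = 1000


@dataclass
class TssRecord:
    """A single-base initiation site with signal, status and genomic context."""

    chrom: str
    pos: int
    strand: str
    signal_by_sample: dict[str, float] = field(default_factory=dict)
    pooled_signal: float = 0.0
    status: str = "nu"                 # obs | nu
    context: str = "intergenic"        # exonic | intronic | intergenic
    orientation: str = "na"            # sense | antisense | na
    resident_gene: Optional[str] = None
    nearest_gene: Optional[str] = None
    scaled_position: Optional[float] = None
    out_of_range: bool = False

    @property
    def tss_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.strand}"


def call_tss(
    signal: BaseSignal,
    min_signal: float = DEFAULT_MIN_SIGNAL,
    merge_dist: int = DEFAULT_MERGE_DIST,
) -> list[tuple[str, int, str, float]]:
    """Call candidate initiation bases from (normalized, usually pooled) signal.

    Bases with signal >= ``min_signal`` are candidates; candidates within
    ``merge_dist`` on the same strand merge into one cluster, represented by
    the base of maximum signal (ties resolved to the 5'-most base relative
    to the strand) and carrying the summed cluster signal.
    """
    if min_signal <= 0:
        raise ValueError("min_signal must be > 0")
    if merge_dist < 0:
        raise ValueError("merge_dist must be >= 0")
    calls: list[tuple[str, int, str, float]] = []
    for (chrom, strand), vec in sorted(signal.data.items()):
        if strand not in "+-":
            continue
        cand = np.flatnonzero(vec >= min_signal)
        if cand.size == 0:
            continue
        # split candidate bases into clusters with gaps > merge_dist
        breaks = np.flatnonzero(np.diff(cand) > merge_dist)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks + 1, [cand.size]))
        for s, e in zip(starts, ends):
            bases = cand[s:e]
            values = vec[bases]
            best = values.max()
            top = bases[values == best]
            rep = int(top.min() if strand == "+" else top.max())
            calls.append((chrom, rep, strand, float(values.sum())))
    calls.sort(key=lambda c: (c[0], c[1], c[2]))
    return calls


def _annotated_tss_index(ann: GenomeAnnotation) -> dict[tuple[str, str], list[tuple[int, str]]]:
    """(chrom, strand) -> sorted [(tss_pos, gene_id)]."""
    idx: dict[tuple[str, str], list[tuple[int, str]]] = {}
    for g in ann.genes:
        for t in g.annotated_tss:
            idx.setdefault((g.chrom, g.strand), []).append((t, g.gene_id))
    for key in idx:
        idx[key].sort()
    return idx


def split_obs_nu(
    calls: Sequence[tuple[str, int, str, float]],
    annotation: GenomeAnnotation,
    match_tol: int = DEFAULT_MATCH_TOL,
) -> list[TssRecord]:
    """Split calls into obsTSS (within +/-match_tol of an annotated TSS on the
    same strand) and nuTSS (everything else).

    An obs call is assigned to the nearest matching annotated TSS; when two
    annotated TSSs are equidistant the 5'-most one (relative to the call's
    strand) wins.
    """
    idx = _annotated_tss_index(annotation)
    records: list[TssRecord] = []
    for chrom, pos, strand, sig in calls:
        best: Optional[tuple[int, int, str]] = None  # (distance, five_prime_key, gene)
        for t, gid in idx.get((chrom, strand), []):
            d = abs(t - pos)
            if d > match_tol:
                continue
            five_key = t if strand == "+" else -t  # smaller = more 5'
            cand = (d, five_key, gid)
            if best is None or cand < best:
                best = cand
        rec = TssRecord(chrom=chrom, pos=pos, strand=strand, pooled_signal=sig)
        if best is not None:
            rec.status = "obs"
            rec.nearest_gene = best[2]
        records.append(rec)
    return records


def _locate(pos: int, gene: GeneRecord) -> Optional[str]:
    """'exonic' / 'intronic' for a base inside the gene span, else None."""
    s, e = gene.span
    if not (s <= pos < e):
        return None
    for es, ee in gene.union_exons():
        if es <= pos < ee:
            return "exonic"
    return "intronic"


def _tss_distance(pos: int, gene: GeneRecord) -> int:
    return min(abs(pos - t) for t in gene.annotated_tss)


def classify_nutss(records: list[TssRecord], annotation: GenomeAnnotation) -> list[TssRecord]:
    """Fill context / orientation / resident_gene on nuTSS records (in place).

    A base in any transcript's exon of any gene is exonic; otherwise a base
    within any gene span is intronic; otherwise intergenic.  The resident
    gene is chosen with exonic priority over intronic, then by nearest
    annotated TSS (ties to the lexicographically first gene id).  Sense
    means the nuTSS strand equals the resident gene strand.
    """
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in annotation.genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for rec in records:
        if rec.status != "nu":
            continue
        hits: list[tuple[int, int, str, GeneRecord]] = []  # (ctx_rank, tss_dist, gid, gene)
        for g in by_chrom.get(rec.chrom, []):
            ctx = _locate(rec.pos, g)
            if ctx is None:
                continue
            hits.append((0 if ctx == "exonic" else 1, _tss_distance(rec.pos, g), g.gene_id, g))
        if not hits:
            rec.context = "intergenic"
            rec.orientation = "na"
            rec.resident_gene = None
            continue
        hits.sort(key=lambda h: (h[0], h[1], h[2]))
        rank, _, gid, gene = hits[0]
        rec.context = "exonic" if rank == 0 else "intronic"
        rec.resident_gene = gid
        rec.orientation = "sense" if rec.strand == gene.strand else "antisense"
    return records


def _scaled_position(pos: int, gene: GeneRecord, flank: int) -> tuple[float, bool]:
    s, e = gene.span
    L = e - s
    if s <= pos < e:
        frac = (pos - s) / L if gene.strand == "+" else (e - 1 - pos) / L
        return frac, False
    # outside the span: upstream/downstream along the transcription direction
    if gene.strand == "+":
        upstream_d = s - pos if pos < s else 0
        downstream_d = pos - (e - 1) if pos >= e else 0
    else:
        upstream_d = pos - (e - 1) if pos >= e else 0
        downstream_d = s - pos if pos < s else 0
    if upstream_d > 0:
        if upstream_d > flank:
            return -0.5, True
        return -0.5 * upstream_d / flank, False
    if downstream_d > flank:
        return 1.5, True
    return 1.0 + 0.5 * downstream_d / flank, False


def _span_distance(pos: int, span: tuple[int, int]) -> int:
    s, e = span
    if s <= pos < e:
        return 0
    return s - pos if pos < s else pos - (e - 1)


def nearest_gene_and_scaled_position(
    records: list[TssRecord],
    annotation: GenomeAnnotation,
    flank: int = DEFAULT_FLANK,
) -> list[TssRecord]:
    """Assign each record its nearest gene and a scaled gene-relative position.

    The gene body maps to [0, 1] in transcription orientation, the upstream
    flank linearly to [-0.5, 0) and the downstream flank to (1, 1.5]; bases
    beyond the flank clamp to the boundary and are flagged out-of-range.
    """
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in annotation.genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for rec in records:
        genes = by_chrom.get(rec.chrom, [])
        if not genes:
            rec.nearest_gene = None
            rec.scaled_position = None
            continue
        gene = min(genes, key=lambda g: (_span_distance(rec.pos, g.span), g.gene_id))
        rec.nearest_gene = gene.gene_id
        rec.scaled_position, rec.out_of_range = _scaled_position(rec.pos, gene, flank)
    return records


def read_signal_at(records: list[TssRecord], signals: dict[str, BaseSignal]) -> list[TssRecord]:
    """Fill per-sample normalized signal at each record's exact base (in place)."""
    for rec in records:
        rec.signal_by_sample = {
            name: float(sig.vector(rec.chrom, rec.strand)[rec.pos])
            for name, sig in sorted(signals.items())
        }
    return records
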