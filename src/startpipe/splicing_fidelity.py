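"""Splice-junction retention ratios and alternative-splicing event filtering.

At each exon-exon junction, reads either map across it as a gapped
("junction", j) alignment whose gap coincides exactly with the intron, or
read through the exon/intron boundary contiguously ("non-junction", n),
evidence of intron retention.  The retention ratio R = n / (j + n) is
computed per condition; junctions need more than 20 total reads in a
condition to be considered powered, and the difference ΔR (mutant minus
control) is defined only when both conditions are powered.

PSI estimation itself is not reimplemented: event tables (Bayes factor plus
per-replicate ΔPSI) are consumed as produced by an external tool or the
simulator, and filtered with the strict rule "Bayes factor > 10 and
consistent ΔPSI sign in every replicate".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomeAnnotation, ReadAlignment

__all__ = [
    "JunctionRecord",
    "SplicingEvent",
    "enumerate_junctions",
    "count_junction_reads",
    "retention_ratio",
    "filter_events",
    "severity_summary",
]

DEFAULT_MIN_OVERHANG = 4
POWER_MIN_READS = 20          # powered means strictly more than this
DEFAULT_BF_THRESHOLD = 10.0
DEFAULT_DPSI_THRESHOLD = 0.25


@dataclass
class JunctionRecord:
    """One exon-exon boundary with per-condition j/n counts and R statistics.

    ``donor`` is the last exonic base of the upstream exon (0-based) and
    ``acceptor`` the first base of the downstream exon, both in genomic
    coordinates regardless of strand.
    """

    junction_id: str
    chrom: str
    strand: str
    donor: int
    acceptor: int
    j_by_condition: dict[str, int] = field(default_factory=dict)
    n_by_condition: dict[str, int] = field(default_factory=dict)
    R_by_condition: dict[str, float] = field(default_factory=dict)
    delta_R: Optional[float] = None
    powered_by_condition: dict[str, bool] = field(default_factory=dict)


@dataclass
class SplicingEvent:
    """An alternative-splicing event with its evidence and significance flag."""

    event_id: str
    type: str                      # skipped_exon | retained_intron
    bayes_factor_combined: float
    delta_psi_by_replicate: list[float] = field(default_factory=list)
    delta_psi_combined: float = 0.0
    significant: bool = False


def enumerate_junctions(annotation: GenomeAnnotation) -> list[JunctionRecord]:
    """One skeleton record per distinct (chrom, strand, donor, acceptor).

    Junctions shared between transcripts are emitted once; ids are
    deterministic ("chrom:donor-acceptor:strand"), sorted genomically.
    """
    seen: set[tuple[str, str, int, int]] = set()
    out: list[JunctionRecord] = []
    for g in annotation.genes:
        for _tid, exons in g.transcripts:
            for (s1, e1), (s2, _e2) in zip(exons, exons[1:]):
                donor, acceptor = e1 - 1, s2
                key = (g.chrom, g.strand, donor, acceptor)
                if key in seen:
                    continue
                seen.add(key)
                out.append(JunctionRecord(
                    junction_id=f"{g.chrom}:{donor}-{acceptor}:{g.strand}",
                    chrom=g.chrom, strand=g.strand, donor=donor, acceptor=acceptor))
    out.sort(key=lambda j: (j.chrom, j.donor, j.acceptor, j.strand))
    return out


def _classify_read(read: ReadAlignment, donor: int, acceptor: int, min_overhang: int) -> Optional[str]:
    """'j', 'n', or None for one read against one junction."""
    # junction: two consecutive blocks whose gap is exactly the intron
    for (s1, e1), (s2, e2) in zip(read.blocks, read.blocks[1:]):
        if e1 == donor + 1 and s2 == acceptor:
            if (e1 - s1) >= min_overhang and (e2 - s2) >= min_overhang:
                return "j"
    # non-junction: one contiguous block reading through the donor boundary
    for (s, e) in read.blocks:
        if s <= donor and donor + 1 < e:
            if (donor - s + 1) >= min_overhang and (e - (donor + 1)) >= min_overhang:
                return "n"
    return None


def count_junction_reads(
    reads_by_condition: dict[str, list[ReadAlignment]],
    junctions: list[JunctionRecord],
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> list[JunctionRecord]:
    """Fill per-condition j and n counts (in place).

    A gapped read counts as j when one of its gaps spans exactly
    donor+1..acceptor-1 with at least ``min_overhang`` aligned bases on each
    side; a contiguous block covering both donor and donor+1 with the same
    overhang counts as n.  A read increments at most one of {j, n} per
    junction (the junction match wins).
    """
    for jr in junctions:
        for cond in sorted(reads_by_condition):
            jr.j_by_condition.setdefault(cond, 0)
            jr.n_by_condition.setdefault(cond, 0)
    for cond in sorted(reads_by_condition):
        reads = [r for r in reads_by_condition[cond]
                 if r.category == "genomic" and r.mate != "2"]
        by_chrom: dict[str, list[ReadAlignment]] = {}
        for r in reads:
            by_chrom.setdefault(r.chrom, []).append(r)
        for jr in junctions:
            for r in by_chrom.get(jr.chrom, []):
                if r.strand != jr.strand:
                    continue
                kind = _classify_read(r, jr.donor, jr.acceptor, min_overhang)
                if kind == "j":
                    jr.j_by_condition[cond] += 1
                elif kind == "n":
                    jr.n_by_condition[cond] += 1
    return junctions


def retention_ratio(
    junctions: list[JunctionRecord],
    ctrl: str,
    mut: str,
) -> list[JunctionRecord]:
    """Compute R per condition, the power flag, and ΔR = R_mut - R_ctrl.

    R = n / (j + n) where j + n > 0; a condition is powered iff it has
    strictly more than 20 total reads; ΔR is defined only when both
    conditions are powered.
    """
    for jr in junctions:
        for cond in sorted(set(jr.j_by_condition) | {ctrl, mut}):
            j = jr.j_by_condition.get(cond, 0)
            n = jr.n_by_condition.get(cond, 0)
            if j + n > 0:
                jr.R_by_condition[cond] = n / (j + n)
            jr.powered_by_condition[cond] = (j + n) > POWER_MIN_READS
        if jr.powered_by_condition.get(ctrl) and jr.powered_by_condition.get(mut):
            jr.delta_R = jr.R_by_condition[mut] - jr.R_by_condition[ctrl]
        else:
            jr.delta_R = None
    return junctions


def filter_events(
    events: Sequence[SplicingEvent],
    bf_threshold: float = DEFAULT_BF_THRESHOLD,
    n_replicates: int = 3,
) -> list[SplicingEvent]:
    """Flag events significant iff BF > threshold and all ΔPSI share one sign.

    A zero replicate ΔPSI breaks sign consistency.  The combined ΔPSI is the
    replicate mean.  Events must carry exactly ``n_replicates`` ΔPSI values.
    """
    out: list[SplicingEvent] = []
    for ev in events:
        if len(ev.delta_psi_by_replicate) != n_replicates:
            raise ValueError(
                f"event {ev.event_id}: expected {n_replicates} replicate ΔPSI values, "
                f"got {len(ev.delta_psi_by_replicate)}")
        dpsi = ev.delta_psi_by_replicate
        consistent = all(d > 0 for d in dpsi) or all(d < 0 for d in dpsi)
        ev.delta_psi_combined = float(np.mean(dpsi))
        ev.significant = (ev.bayes_factor_combined > bf_threshold) and consistent
        out.append(ev)
    return out


def severity_summary(
    events: Sequence[SplicingEvent],
    dpsi_threshold: float = DEFAULT_DPSI_THRESHOLD,
) -> pd.DataFrame:
    """Per-type counts of significant events and those with |ΔPSI| >= threshold.

    Returns a DataFrame indexed by event type with columns n_significant,
    n_above_threshold and fraction (0 when there are no significant events).
    """
    rows = []
    for etype in sorted({ev.type for ev in events}):
        sig = [ev for ev in events if ev.type == etype and ev.significant]
        above = [ev for ev in sig if abs(ev.delta_psi_combined) >= dpsi_threshold]
        rows.append({
            "type": etype,
            "n_significant": len(sig),
            "n_above_threshold": len(above),
            "fraction": len(above) / len(sig) if sig else 0.0,
        })
    return pd.DataFrame(rows).set_index("type")
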