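"""Between-genotype comparisons: per-TSS fold changes, antisense counts,
per-gene FPKM and MA-style summaries.

The differential statistic here is deliberately a simple normalized-ratio
(pseudocounted log2 fold change plus the raw mutant-minus-control
difference); dispersion-modelled testing is out of scope and its tabular
output can be substituted interchangeably.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .io_formats import GenomeAnnotation, PeakSet, ReadAlignment
from .tss_catalog import TssRecord

__all__ = [
    "DiffRecord",
    "AntisenseRecord",
    "tss_differential",
    "antisense_counts",
    "gene_fpkm",
    "ma_summary",
]

DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_PEAK_DIST = 1000


@dataclass
class DiffRecord:
    """Per-feature differential summary between control and mutant samples."""

    feature_id: str
    base_mean: float
    ctrl_mean: float
    mut_mean: float
    log2fc: float
    abs_change: float
    status: str = ""
    context: str = ""
    orientation: str = ""
    scaled_position: Optional[float] = None


@dataclass
class AntisenseRecord:
    """Normalized antisense read counts over one gene, with peak proximity."""

    gene_id: str
    antisense_count_by_sample: dict[str, float] = field(default_factory=dict)
    near_peak: bool = False


def tss_differential(
    records: Sequence[TssRecord],
    ctrl_samples: Sequence[str],
    mut_samples: Sequence[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[DiffRecord]:
    """log2fc and absolute change of per-TSS normalized signal.

    log2fc = log2((mean_mut + pc) / (mean_ctrl + pc));
    abs_change = mean_mut - mean_ctrl (normalized scale, exact).
    """
    out: list[DiffRecord] = []
    for rec in records:
        for s in list(ctrl_samples) + list(mut_samples):
            if s not in rec.signal_by_sample:
                raise KeyError(f"TSS {rec.tss_id}: no signal for sample {s!r}")
        ctrl = float(np.mean([rec.signal_by_sample[s] for s in ctrl_samples]))
        mut = float(np.mean([rec.signal_by_sample[s] for s in mut_samples]))
        out.append(
            DiffRecord(
                feature_id=rec.tss_id,
                base_mean=(ctrl + mut) / 2.0,
                ctrl_mean=ctrl,
                mut_mean=mut,
                log2fc=float(np.log2((mut + pseudocount) / (ctrl + pseudocount))),
                abs_change=mut - ctrl,
                status=rec.status,
                context=rec.context,
                orientation=rec.orientation,
                scaled_position=rec.scaled_position,
            )
        )
    return out


def _gap_to_peaks(span: tuple[int, int], peaks: list[tuple[int, int]]) -> Optional[int]:
    best: Optional[int] = None
    s, e = span
    for ps, pe in peaks:
        if s < pe and ps < e:
            gap = 0
        elif e <= ps:
            gap = ps - e
        else:
            gap = s - pe
        best = gap if best is None else min(best, gap)
    return best


def antisense_counts(
    reads_by_sample: dict[str, list[ReadAlignment]],
    annotation: GenomeAnnotation,
    norm_factors: dict[str, float],
    peaks: PeakSet,
    peak_dist: int = DEFAULT_PEAK_DIST,
) -> list[AntisenseRecord]:
    """Count reads mapping antisense to each gene, scaled by norm factors.

    A read counts for a gene when any aligned block overlaps the gene span
    and the read strand differs from the gene strand.  ``near_peak`` is true
    when the gene span overlaps or lies within ``peak_dist`` (gap length) of
    a peak interval.
    """
    out: list[AntisenseRecord] = []
    for g in annotation.genes:
        counts: dict[str, float] = {}
        gs, ge = g.span
        for sample in sorted(reads_by_sample):
            n = 0
            for r in reads_by_sample[sample]:
                if r.category != "genomic" or r.chrom != g.chrom or r.strand == g.strand:
                    continue
                if r.mate == "2":
                    continue
                if any(bs < ge and gs < be for bs, be in r.blocks):
                    n += 1
            counts[sample] = n * norm_factors[sample]
        gap = _gap_to_peaks(g.span, peaks.on(g.chrom))
        out.append(AntisenseRecord(gene_id=g.gene_id,
                                   antisense_count_by_sample=counts,
                                   near_peak=gap is not None and gap <= peak_dist))
    return out


def gene_fpkm(
    reads_by_sample: dict[str, list[ReadAlignment]],
    annotation: GenomeAnnotation,
) -> dict[str, dict[str, float]]:
    """Per-gene FPKM per sample under a union-exon gene model.

    A fragment assigns to the gene whose union exons contain the midpoint of
    its 5'-end block, with matching strand.  FPKM = (assigned fragments /
    union-exon kb) / (total assigned fragments in millions).
    """
    exon_model: list[tuple[str, str, str, list[tuple[int, int]], float]] = []
    for g in sorted(annotation.genes, key=lambda g: g.gene_id):
        ue = g.union_exons()
        exon_model.append((g.gene_id, g.chrom, g.strand, ue,
                           sum(e - s for s, e in ue) / 1000.0))
    table: dict[str, dict[str, float]] = {}
    for sample in sorted(reads_by_sample):
        counts = {gid: 0 for gid, *_ in exon_model}
        total = 0
        for r in reads_by_sample[sample]:
            if r.category != "genomic" or r.mate == "2":
                continue
            block = r.blocks[0] if r.strand == "+" else r.blocks[-1]
            mid = (block[0] + block[1]) // 2
            for gid, chrom, strand, exons, _kb in exon_model:
                if chrom == r.chrom and strand == r.strand and any(s <= mid < e for s, e in exons):
                    counts[gid] += 1
                    total += 1
                    break
        if total == 0:
            raise ValueError(f"sample {sample!r}: zero fragments assigned to genes")
        table[sample] = {
            gid: (counts[gid] / kb) / (total / 1e6)
            for gid, _c, _s, _e, kb in exon_model
        }
    return table


def _tie_safe_spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected Spearman; 0.0 when either side has zero variance."""
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def ma_summary(diff: Sequence[DiffRecord], n_bins: int):
    """Bin features by control level and summarize log2fc per bin.

    Features are ranked ascending by control-level (ties broken by feature
    id), split into ``n_bins`` contiguous rank blocks (sizes differ by at
    most one, larger blocks first); returns (per-bin mean log2fc array,
    tie-corrected Spearman correlation of control level vs log2fc).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if len(diff) < n_bins:
        raise ValueError(f"{len(diff)} features is fewer than {n_bins} bins")
    order = sorted(diff, key=lambda d: (d.ctrl_mean, d.feature_id))
    n = len(order)
    base, rem = divmod(n, n_bins)
    means = np.empty(n_bins, dtype=float)
    i = 0
    for b in range(n_bins):
        size = base + (1 if b < rem else 0)
        means[b] = float(np.mean([d.log2fc for d in order[i:i + size]]))
        i += size
    ctrl = np.array([d.ctrl_mean for d in diff], dtype=float)
    lfc = np.array([d.log2fc for d in diff], dtype=float)
    return means, _tie_safe_spearman(ctrl, lfc)
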