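"""Strand-specific base-resolution initiation signal and spike-in scaling.

Start-seq captures short, nascent, capped RNAs; the 5' end of each capped
fragment marks a transcription initiation base.  This module turns aligned
fragments into dense per-base signal vectors, rescales samples by their
spike-in read totals, and extracts anchored windows and window sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_formats import ReadAlignment, ValidationError

__all__ = [
    "BaseSignal",
    "count_five_prime_ends",
    "spike_normalize",
    "pool_signals",
    "window_signal",
    "window_sum",
]


@dataclass
class BaseSignal:
    """Per-base signal for one sample: dense vectors keyed by (chrom, strand).

    ``norm_factor`` is 1.0 for raw counts; after spike normalization the
    total signal equals the raw total times ``norm_factor``.  Strand "."
    holds strandless coverage (ChIP/ATAC-style tracks).
    """

    sample: str
    chrom_sizes: dict[str, int]
    data: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    norm_factor: float = 1.0
    spike_total: int = 0

    @classmethod
    def zeros(cls, sample: str, chrom_sizes: dict[str, int]) -> "BaseSignal":
        return cls(sample=sample, chrom_sizes=dict(chrom_sizes))

    def vector(self, chrom: str, strand: str) -> np.ndarray:
        """Dense value vector for one chromosome strand (created on demand)."""
        if chrom not in self.chrom_sizes:
            raise ValidationError(f"unknown chromosome {chrom!r}")
        key = (chrom, strand)
        if key not in self.data:
            self.data[key] = np.zeros(self.chrom_sizes[chrom], dtype=float)
        return self.data[key]

    def strand_sum(self, chrom: str, strands: Sequence[str]) -> np.ndarray:
        out = np.zeros(self.chrom_sizes[chrom], dtype=float)
        for s in strands:
            if (chrom, s) in self.data:
                out += self.data[(chrom, s)]
        return out

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def scaled(self, factor: float) -> "BaseSignal":
        out = BaseSignal(sample=self.sample, chrom_sizes=dict(self.chrom_sizes),
                         norm_factor=self.norm_factor * factor, spike_total=self.spike_total)
        out.data = {k: v * factor for k, v in self.data.items()}
        return out


def count_five_prime_ends(
    reads: list[ReadAlignment],
    sample: str,
    chrom_sizes: dict[str, int],
) -> BaseSignal:
    """Count fragment 5' ends at single-base resolution, one strand at a time.

    Each fragment contributes +1 at the 5'-most base of its mate-1 (or
    unpaired) read: the leftmost block start on the plus strand, the
    rightmost block end minus one on the minus strand.  Spike-category reads
    are excluded from genomic signal and tallied into ``spike_total``.
    """
    sig = BaseSignal.zeros(sample, chrom_sizes)
    spike = 0
    for r in reads:
        if r.mate == "2":
            continue  # the cap sits at mate 1's 5' end
        if r.category == "spike":
            spike += 1
            continue
        if r.chrom not in chrom_sizes:
            raise ValidationError(f"read {r.read_id}: unknown chromosome {r.chrom!r}")
        sig.vector(r.chrom, r.strand)[r.five_prime()] += 1
    sig.spike_total = spike
    return sig


def spike_normalize(signals: dict[str, BaseSignal]) -> dict[str, BaseSignal]:
    """Rescale each sample by its spike-in total under the median rule.

    norm_factor_s = median over samples of spike_total / spike_total_s, so a
    sample sequenced twice as deep (twice the spike reads) is scaled down by
    half, and values stay on a typical-library scale.
    """
    for name, sig in signals.items():
        if sig.spike_total <= 0:
            raise ValidationError(f"sample {name!r}: spike_total is 0, normalization undefined")
    med = float(np.median([sig.spike_total for sig in signals.values()]))
    return {name: sig.scaled(med / sig.spike_total) for name, sig in signals.items()}


def pool_signals(signals: Sequence[BaseSignal], sample: str = "pooled") -> BaseSignal:
    """Base-wise sum of normalized signals, giving one shared TSS universe."""
    if not signals:
        raise ValueError("pool_signals needs at least one signal")
    sizes = signals[0].chrom_sizes
    out = BaseSignal.zeros(sample, sizes)
    for sig in signals:
        if sig.chrom_sizes != sizes:
            raise ValidationError("pooled signals must share chromosome sizes")
        for (chrom, strand), vec in sig.data.items():
            out.vector(chrom, strand)[:] += vec
    out.spike_total = sum(s.spike_total for s in signals)
    return out


def window_signal(
    signal: BaseSignal,
    anchors: Sequence[tuple[str, int, str]],
    upstream: int,
    downstream: int,
    *,
    anchor_strand_only: bool = True,
) -> tuple[np.ndarray, list[bool]]:
    """Extract an (anchors x positions) matrix around single-base anchors.

    Rows run 5'->3' relative to the anchor strand: column j holds the base at
    signed offset j-upstream (offset 0 is the anchor base), with upstream on
    the left for minus-strand anchors too.  Windows truncated by a
    chromosome end are zero-padded and flagged.  ``anchor_strand_only``
    selects anchor-strand signal; otherwise +, - and strandless signal sum.
    """
    width = upstream + downstream
    mat = np.zeros((len(anchors), width), dtype=float)
    clipped: list[bool] = []
    for i, (chrom, pos, strand) in enumerate(anchors):
        if chrom not in signal.chrom_sizes:
            raise ValidationError(f"anchor on unknown chromosome {chrom!r}")
        L = signal.chrom_sizes[chrom]
        if anchor_strand_only:
            vec = signal.strand_sum(chrom, [strand])
        else:
            vec = signal.strand_sum(chrom, ["+", "-", "."])
        offsets = np.arange(-upstream, downstream)
        genomic = pos + offsets if strand == "+" else pos - offsets
        ok = (genomic >= 0) & (genomic < L)
        mat[i, ok] = vec[genomic[ok]]
        clipped.append(bool((~ok).any()))
    return mat, clipped


def window_sum(
    signal: BaseSignal,
    anchors: Sequence[tuple[str, int, str]],
    upstream: int,
    downstream: int,
    *,
    anchor_strand_only: bool = True,
) -> np.ndarray:
    """Per-anchor total signal over the window (row sums of window_signal)."""
    mat, _ = window_signal(signal, anchors, upstream, downstream,
                           anchor_strand_only=anchor_strand_only)
    return mat.sum(axis=1)
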