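"""ChIP-density quantification, decile stratification, and metagene profiles.

"Density" is mean signal per base pair throughout, so windows of different
effective width (chromosome-truncated windows, 3'UTRs of any length) remain
comparable.  Decile 1 holds the lowest densities and decile 10 the highest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomeAnnotation, ValidationError
from .startseq_signal import BaseSignal
from .differential import _tie_safe_spearman

__all__ = [
    "StratumTable",
    "feature_density",
    "utr3_density",
    "decile_stratify",
    "stratum_summary",
    "metagene_profile",
]

DEFAULT_WINDOW = 400
DEFAULT_BODY_BINS = 100
DEFAULT_FLANK = 1000
DEFAULT_FLANK_BINS = 20

_TRACK_STRANDS = ["+", "-", "."]


@dataclass
class StratumTable:
    """One feature's density, decile label and expression change."""

    feature_id: str
    density: float
    decile: int
    log2fc: float


def _track_vector(track: BaseSignal, chrom: str) -> np.ndarray:
    return track.strand_sum(chrom, _TRACK_STRANDS)


def feature_density(
    track: BaseSignal,
    anchors: Sequence[tuple[str, int, str]],
    window: int = DEFAULT_WINDOW,
) -> tuple[np.ndarray, list[bool]]:
    """Mean per-bp signal in a centered window around each single-base anchor.

    The window is [pos - window/2, pos + window/2); a window extending past
    a chromosome end is truncated (the mean uses the effective width) and
    flagged.  Returns (densities, truncated flags).
    """
    if window % 2 != 0:
        raise ValueError("window must be even")
    half = window // 2
    out = np.empty(len(anchors), dtype=float)
    truncated: list[bool] = []
    for i, (chrom, pos, _strand) in enumerate(anchors):
        if chrom not in track.chrom_sizes:
            raise ValidationError(f"anchor on unknown chromosome {chrom!r}")
        L = track.chrom_sizes[chrom]
        s, e = max(0, pos - half), min(L, pos + half)
        if e <= s:
            raise ValidationError(f"window around {chrom}:{pos} is empty")
        vec = _track_vector(track, chrom)
        out[i] = float(vec[s:e].mean())
        truncated.append((e - s) != window)
    return out, truncated


def utr3_density(
    track: BaseSignal,
    annotation: GenomeAnnotation,
) -> tuple[dict[str, float], list[str]]:
    """Mean per-bp signal over each gene's annotated 3'UTR.

    Genes without a 3'UTR are excluded and returned in a side list.
    """
    densities: dict[str, float] = {}
    skipped: list[str] = []
    for g in annotation.genes:
        if g.utr3 is None:
            skipped.append(g.gene_id)
            continue
        s, e = g.utr3
        vec = _track_vector(track, g.chrom)
        densities[g.gene_id] = float(vec[s:e].mean())
    return densities, skipped


def decile_stratify(values: dict[str, float]) -> dict[str, int]:
    """Label features 1..10 by ascending density rank.

    Features are ranked ascending (value ties broken by feature id) and cut
    into 10 contiguous rank blocks whose sizes differ by at most one, with
    the larger blocks at the lower deciles; decile 1 is the lowest-density
    block and decile 10 the highest.
    """
    n = len(values)
    if n < 10:
        raise ValueError(f"decile stratification needs >= 10 features, got {n}")
    order = sorted(values, key=lambda fid: (values[fid], fid))
    base, rem = divmod(n, 10)
    labels: dict[str, int] = {}
    i = 0
    for d in range(1, 11):
        size = base + (1 if d <= rem else 0)
        for fid in order[i:i + size]:
            labels[fid] = d
        i += size
    return labels


def stratum_summary(table: Sequence[StratumTable]) -> tuple[pd.DataFrame, float]:
    """Per-decile order statistics of log2fc plus density-vs-log2fc Spearman.

    Medians and quartiles use the midpoint rule on exact order statistics.
    Returns (DataFrame indexed by decile with n/median/q1/q3, rho).
    """
    rows = []
    for d in sorted({t.decile for t in table}):
        vals = np.sort([t.log2fc for t in table if t.decile == d])
        rows.append({
            "decile": d,
            "n": len(vals),
            "median": float(np.percentile(vals, 50, method="midpoint")),
            "q1": float(np.percentile(vals, 25, method="midpoint")),
            "q3": float(np.percentile(vals, 75, method="midpoint")),
        })
    dens = np.array([t.density for t in table], dtype=float)
    lfc = np.array([t.log2fc for t in table], dtype=float)
    return pd.DataFrame(rows).set_index("decile"), _tie_safe_spearman(dens, lfc)


def metagene_profile(
    track: BaseSignal,
    annotation: GenomeAnnotation,
    groups: Optional[dict[str, str]] = None,
    body_bins: int = DEFAULT_BODY_BINS,
    flank: int = DEFAULT_FLANK,
    flank_bins: int = DEFAULT_FLANK_BINS,
) -> tuple[pd.DataFrame, list[str]]:
    """Scaled metagene: mean per-bp signal, length-normalized gene bodies.

    Each gene body is cut into ``body_bins`` bins (mean per-bp signal per
    bin); the two flanks are binned at fixed width flank/flank_bins.  Minus
    strand genes are reversed so every profile runs 5'->3'.  Group means are
    unweighted over genes.  Genes not longer than ``body_bins`` bases are
    excluded and returned in a side list.

    Returns (DataFrame: rows = group labels, columns = -flank_bins..,
    body_0.., downstream bins), plus the skipped gene ids.
    """
    if flank % flank_bins != 0:
        raise ValueError("flank must be divisible by flank_bins")
    fw = flank // flank_bins
    ncol = flank_bins + body_bins + flank_bins
    profiles: dict[str, list[np.ndarray]] = {}
    skipped: list[str] = []
    for g in annotation.genes:
        s, e = g.span
        L = e - s
        if L <= body_bins:
            skipped.append(g.gene_id)
            continue
        vec = _track_vector(track, g.chrom)
        chrom_len = track.chrom_sizes[g.chrom]
        row = np.zeros(ncol, dtype=float)
        # upstream flank (genomic left for +, right for -), fixed-width bins
        for b in range(flank_bins):
            if g.strand == "+":
                ws = s - flank + b * fw
                we = ws + fw
            else:
                we = e + flank - b * fw
                ws = we - fw
            cs, ce = max(0, ws), min(chrom_len, we)
            row[b] = vec[cs:ce].mean() if ce > cs else 0.0
        # body, length-normalized
        bounds = (s + np.floor(np.arange(body_bins + 1) * L / body_bins)).astype(int)
        body = np.array([vec[bounds[i]:bounds[i + 1]].mean() for i in range(body_bins)])
        if g.strand == "-":
            body = body[::-1]
        row[flank_bins:flank_bins + body_bins] = body
        # downstream flank
        for b in range(flank_bins):
            if g.strand == "+":
                ws = e + b * fw
                we = ws + fw
            else:
                we = s - b * fw
                ws = we - fw
            cs, ce = max(0, ws), min(chrom_len, we)
            row[flank_bins + body_bins + b] = vec[cs:ce].mean() if ce > cs else 0.0
        label = (groups or {}).get(g.gene_id, "all")
        profiles.setdefault(label, []).append(row)
    cols = ([f"up_{b}" for b in range(flank_bins)]
            + [f"body_{b}" for b in range(body_bins)]
            + [f"down_{b}" for b in range(flank_bins)])
    data = {label: np.mean(rows, axis=0) for label, rows in sorted(profiles.items())}
    return pd.DataFrame.from_dict(data, orient="index", columns=cols), skipped
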