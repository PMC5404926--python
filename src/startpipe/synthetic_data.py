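"""Synthetic genomes, Start-seq-like reads, junction reads, ChIP tracks and
splicing-event tables, all with a ground-truth manifest.

The generator emulates the data shapes of a nascent-TSS study of a
*Drosophila* histone-mutant: strand-specific single-base initiation signal
at annotated and cryptic (nuTSS) sites, exact spike-in read counts, gapped
and ungapped reads over exon-exon junctions with a known retention
fraction, and deterministic ChIP-like density tracks enriched over 3' gene
ends.  Every non-background read traces to one ground-truth element, and
all randomness flows from the config seed through named integer substreams
(one per component and sample), so outputs are byte-identical under a
fixed seed and independent of condition labels.

Count noise at initiation sites is Poisson (mean-parameterized, recorded in
the manifest); spike-in reads are emitted at exact configured counts so
normalization tests are exact rather than statistical.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .io_formats import GeneRecord, GenomeAnnotation, ReadAlignment
from .splicing_fidelity import JunctionRecord, SplicingEvent, enumerate_junctions
from .startseq_signal import BaseSignal

__all__ = [
    "SimConfig",
    "TrueSite",
    "TrueJunction",
    "GroundTruth",
    "simulate_annotation",
    "simulate_startseq",
    "simulate_junction_reads",
    "simulate_chip_track",
    "simulate_event_table",
    "simulate_all",
]


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named integer substream: deterministic across platforms."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


@dataclass
class SimConfig:
    """All generator parameters; the defaults are the study conditions.

    ``samples`` maps sample name -> {"depth": multiplier, "spike": exact
    spike read count, "condition": "ctrl"|"mut"}.  Depth multiplies every
    genomic expected count but never the spike counts (which are emitted
    exactly); in the defaults the spike count tracks depth, as the same
    spike RNA pool sequenced deeper would.
    """

    seed: int = 0
    # genome
    n_chroms: int = 2
    chrom_length: int = 500_000
    n_genes: int = 100
    min_gap: int = 1000
    exons_per_gene: tuple[int, int] = (2, 5)
    exon_length: tuple[int, int] = (200, 600)
    intron_length: tuple[int, int] = (100, 400)
    utr3_length: tuple[int, int] = (100, 300)
    # samples
    samples: dict[str, dict] = field(default_factory=lambda: {
        "hwt": {"depth": 1.0, "spike": 1000, "condition": "ctrl"},
        "k36r": {"depth": 1.2, "spike": 1200, "condition": "mut"},
    })
    # initiation sites
    n_nu_sites: int = 50
    site_strength_mean: float = 50.0
    site_strength_rel_range: tuple[float, float] = (0.4, 1.6)
    obs_effect_log2fc: tuple[float, ...] = (-1.0, 0.0, 1.0)
    obs_effect_probs: tuple[float, ...] = (0.25, 0.5, 0.25)
    nu_effect_log2fc: tuple[float, ...] = (-1.0, 0.0, 1.0)
    nu_effect_probs: tuple[float, ...] = (0.3, 0.4, 0.3)
    noise_rate: float = 5e-5          # expected background reads per strand-base
    read_length: int = 26
    spike_ref: str = "spike_ctrl1"
    spike_length: int = 1000
    # junction reads
    junction_read_length: int = 50
    junction_depth: tuple[int, int] = (50, 150)
    retention_range: tuple[float, float] = (0.0, 0.15)
    min_overhang: int = 4
    # ChIP-like track (deterministic construction)
    chip_base: float = 1.0
    chip_skew: float = 2.0            # density ramps 5'->3' as base*(1+skew*f)
    chip_exon_weight: float = 2.0
    chip_background: float = 0.1
    # splicing events
    n_events: int = 200
    sig_fraction: float = 0.2

    def conditions(self) -> dict[str, list[str]]:
        """condition label -> sorted sample names."""
        out: dict[str, list[str]] = {}
        for name in sorted(self.samples):
            out.setdefault(self.samples[name]["condition"], []).append(name)
        return out

    def expected_norm_factors(self) -> dict[str, float]:
        spikes = {s: self.samples[s]["spike"] for s in self.samples}
        med = float(np.median(list(spikes.values())))
        return {s: med / spikes[s] for s in sorted(spikes)}


@dataclass
class TrueSite:
    """Ground truth for one initiation site."""

    site_id: str
    chrom: str
    pos: int
    strand: str
    status: str                       # obs | nu
    context: str                      # exonic | intronic | intergenic
    orientation: str                  # sense | antisense | na
    resident_gene: Optional[str]
    base_strength: float              # expected reads at depth 1 in a ctrl sample
    log2fc: float                     # mut-vs-ctrl effect on expected counts
    expected_count_by_sample: dict[str, float] = field(default_factory=dict)
    expected_normalized_by_sample: dict[str, float] = field(default_factory=dict)


@dataclass
class TrueJunction:
    """Ground truth for one junction: retention fraction and realized counts."""

    junction_id: str
    rho_by_sample: dict[str, float] = field(default_factory=dict)
    depth_by_sample: dict[str, int] = field(default_factory=dict)
    n_by_sample: dict[str, int] = field(default_factory=dict)
    j_by_sample: dict[str, int] = field(default_factory=dict)


@dataclass
class GroundTruth:
    """Manifest tying every simulated signal unit to its generating element."""

    count_model: str
    sites: list[TrueSite] = field(default_factory=list)
    junctions: list[TrueJunction] = field(default_factory=list)
    chip_density_by_gene: dict[str, float] = field(default_factory=dict)
    gene_log2fc: dict[str, float] = field(default_factory=dict)
    event_significant: dict[str, bool] = field(default_factory=dict)
    expected_norm_factors: dict[str, float] = field(default_factory=dict)

    def write(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def simulate_annotation(config: SimConfig) -> GenomeAnnotation:
    """Place non-overlapping multi-exon genes with >= min_gap flanks.

    Genes alternate strands at random (fair coin); each gene is an exon /
    intron chain with a 3'UTR occupying the strand-appropriate end of the
    terminal exon.  Raises when the requested genes cannot be packed.
    """
    rng = _rng(config.seed, "annotation")
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chrom_sizes = {c: config.chrom_length for c in chroms}
    chrom_sizes[config.spike_ref] = config.spike_length
    genes: list[GeneRecord] = []
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    gi = 0
    for chrom, n_here in zip(chroms, per_chrom):
        cursor = config.min_gap
        for _ in range(n_here):
            gi += 1
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
            exon_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1, size=n_ex)
            intron_lens = rng.integers(config.intron_length[0], config.intron_length[1] + 1,
                                       size=max(0, n_ex - 1))
            gene_len = int(exon_lens.sum() + intron_lens.sum())
            cursor += int(rng.integers(0, config.min_gap))
            if cursor + gene_len + config.min_gap > config.chrom_length:
                raise ValueError(
                    f"cannot pack {config.n_genes} genes into {config.n_chroms} x "
                    f"{config.chrom_length} bp; increase chrom_length")
            exons: list[tuple[int, int]] = []
            p = cursor
            for k in range(n_ex):
                exons.append((p, p + int(exon_lens[k])))
                p += int(exon_lens[k])
                if k < n_ex - 1:
                    p += int(intron_lens[k])
            span = (cursor, p)
            u = int(rng.integers(config.utr3_length[0], config.utr3_length[1] + 1))
            if strand == "+":
                le = exons[-1]
                utr3 = (max(le[0], le[1] - u), le[1])
            else:
                fe = exons[0]   # genomic left exon is the 3' end of a minus gene
                utr3 = (fe[0], min(fe[1], fe[0] + u))
            gid = f"g{gi:04d}"
            genes.append(GeneRecord(gene_id=gid, chrom=chrom, strand=strand, span=span,
                                    transcripts=[(f"{gid}.t1", exons)], utr3=utr3))
            cursor = p + config.min_gap
    ann = GenomeAnnotation(chrom_sizes=chrom_sizes, genes=genes)
    ann.validate()
    return ann


# ---------------------------------------------------------------------------
# Start-seq reads
# ---------------------------------------------------------------------------


def _truth_context(ann: GenomeAnnotation, chrom: str, pos: int, strand: str
                   ) -> tuple[str, str, Optional[str]]:
    """Context/orientation by direct lookup (genes are non-overlapping)."""
    for g in ann.genes_on(chrom):
        s, e = g.span
        if s <= pos < e:
            ctx = "intronic"
            for es, ee in g.union_exons():
                if es <= pos < ee:
                    ctx = "exonic"
                    break
            return ctx, ("sense" if strand == g.strand else "antisense"), g.gene_id
    return "intergenic", "na", None


def place_sites(annotation: GenomeAnnotation, config: SimConfig) -> list[TrueSite]:
    """Choose obs sites (one per annotated TSS) and nu sites with effects.

    nu sites are kept > 60 nt from every annotated TSS (so they can never
    be mistaken for obsTSSs at the default 50 nt match tolerance) and >= 50
    nt from each other on the same strand, clear of chromosome edges.
    """
    rng = _rng(config.seed, "sites")
    norm = config.expected_norm_factors()
    sites: list[TrueSite] = []

    def strength() -> float:
        lo, hi = config.site_strength_rel_range
        return config.site_strength_mean * float(rng.uniform(lo, hi))

    def fill_expected(site: TrueSite) -> None:
        for s in sorted(config.samples):
            spec = config.samples[s]
            eff = 2.0 ** site.log2fc if spec["condition"] == "mut" else 1.0
            exp = site.base_strength * spec["depth"] * eff
            site.expected_count_by_sample[s] = exp
            site.expected_normalized_by_sample[s] = exp * norm[s]

    tss_positions: dict[tuple[str, str], list[int]] = {}
    all_tss: dict[str, list[int]] = {}
    k = 0
    for g in sorted(annotation.genes, key=lambda g: g.gene_id):
        for t in g.annotated_tss:
            k += 1
            lfc = float(rng.choice(config.obs_effect_log2fc, p=config.obs_effect_probs))
            site = TrueSite(site_id=f"obs{k:04d}", chrom=g.chrom, pos=t, strand=g.strand,
                            status="obs", context="exonic", orientation="sense",
                            resident_gene=g.gene_id, base_strength=strength(), log2fc=lfc)
            fill_expected(site)
            sites.append(site)
            tss_positions.setdefault((g.chrom, g.strand), []).append(t)
            all_tss.setdefault(g.chrom, []).append(t)

    chroms = sorted(c for c in annotation.chrom_sizes if c != config.spike_ref)
    placed: dict[tuple[str, str], list[int]] = {}
    n_placed = 0
    attempts = 0
    while n_placed < config.n_nu_sites:
        attempts += 1
        if attempts > 100 * config.n_nu_sites:
            raise ValueError("cannot place nu sites; genome too crowded")
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        L = annotation.chrom_sizes[chrom]
        pos = int(rng.integers(config.read_length, L - config.read_length))
        strand = "+" if rng.random() < 0.5 else "-"
        if any(abs(pos - t) <= 60 for t in all_tss.get(chrom, [])):
            continue
        if any(abs(pos - p) < 50 for p in placed.get((chrom, strand), [])):
            continue
        n_placed += 1
        ctx, orient, resident = _truth_context(annotation, chrom, pos, strand)
        lfc = float(rng.choice(config.nu_effect_log2fc, p=config.nu_effect_probs))
        site = TrueSite(site_id=f"nu{n_placed:04d}", chrom=chrom, pos=pos, strand=strand,
                        status="nu", context=ctx, orientation=orient,
                        resident_gene=resident, base_strength=strength(), log2fc=lfc)
        fill_expected(site)
        sites.append(site)
        placed.setdefault((chrom, strand), []).append(pos)
    return sites


def _site_read(site_chrom: str, pos: int, strand: str, read_len: int,
               chrom_len: int) -> tuple[int, int]:
    if strand == "+":
        return (pos, min(pos + read_len, chrom_len))
    return (max(0, pos - read_len + 1), pos + 1)


def simulate_startseq(
    annotation: GenomeAnnotation,
    sites: list[TrueSite],
    config: SimConfig,
) -> dict[str, list[ReadAlignment]]:
    """Emit Start-seq-like reads per sample.

    Per site and sample the read count is Poisson(expected count); the 5'
    end of every site read sits exactly on the site base.  Uniform
    background reads arrive at ``noise_rate`` per strand-base, and spike
    reads are emitted exactly ``spike`` times per sample on the spike
    reference.  RNG substreams are keyed by sample name only.
    """
    reads_by_sample: dict[str, list[ReadAlignment]] = {}
    chroms = sorted(c for c in annotation.chrom_sizes if c != config.spike_ref)
    for sample in sorted(config.samples):
        rng = _rng(config.seed, f"startseq:{sample}")
        reads: list[ReadAlignment] = []
        for site in sites:
            count = int(rng.poisson(site.expected_count_by_sample[sample]))
            L = annotation.chrom_sizes[site.chrom]
            for i in range(count):
                blocks = [_site_read(site.chrom, site.pos, site.strand, config.read_length, L)]
                reads.append(ReadAlignment(
                    read_id=f"{sample}:{site.site_id}:{i}", sample=sample,
                    chrom=site.chrom, strand=site.strand, blocks=blocks))
        # uniform background
        for chrom in chroms:
            L = annotation.chrom_sizes[chrom]
            n_bg = int(rng.poisson(config.noise_rate * L * 2))
            pos = rng.integers(config.read_length, L - config.read_length, size=n_bg)
            strands = rng.random(n_bg) < 0.5
            for i in range(n_bg):
                strand = "+" if strands[i] else "-"
                blocks = [_site_read(chrom, int(pos[i]), strand, config.read_length, L)]
                reads.append(ReadAlignment(
                    read_id=f"{sample}:bg:{chrom}:{i}", sample=sample,
                    chrom=chrom, strand=strand, blocks=blocks))
        # exact spike emission
        n_spike = int(config.samples[sample]["spike"])
        spos = rng.integers(0, config.spike_length - config.read_length, size=n_spike)
        for i in range(n_spike):
            reads.append(ReadAlignment(
                read_id=f"{sample}:spike:{i}", sample=sample, chrom=config.spike_ref,
                strand="+", blocks=[(int(spos[i]), int(spos[i]) + config.read_length)],
                category="spike"))
        reads_by_sample[sample] = reads
    return reads_by_sample


# ---------------------------------------------------------------------------
# Junction reads
# ---------------------------------------------------------------------------


def simulate_junction_reads(
    annotation: GenomeAnnotation,
    config: SimConfig,
    *,
    rho_by_junction: Optional[dict[str, dict[str, float]]] = None,
    depth: Optional[int] = None,
    samples: Optional[list[str]] = None,
) -> tuple[dict[str, list[ReadAlignment]], list[TrueJunction]]:
    """Emit junction-spanning reads with a known retention fraction.

    For each junction and sample with total depth T, non-junction
    (contiguous, intron-retaining) reads are drawn Binomial(T, rho) and the
    remaining T - n reads are gapped exactly over the intron; every read
    carries >= min_overhang aligned bases on both sides of the boundary.
    rho defaults to one draw per junction from ``retention_range`` shared by
    all samples; pass ``rho_by_junction[jid][sample]`` to override.
    """
    junctions = enumerate_junctions(annotation)
    sample_names = sorted(samples if samples is not None else config.samples)
    jl, mo = config.junction_read_length, config.min_overhang
    rho_rng = _rng(config.seed, "junction-rho")
    rho_default = {j.junction_id: float(rho_rng.uniform(*config.retention_range))
                   for j in junctions}
    truth = {j.junction_id: TrueJunction(junction_id=j.junction_id) for j in junctions}
    reads_by_sample: dict[str, list[ReadAlignment]] = {}
    for sample in sample_names:
        rng = _rng(config.seed, f"junctions:{sample}")
        reads: list[ReadAlignment] = []
        for jr in junctions:
            rho = (rho_by_junction or {}).get(jr.junction_id, {}).get(sample,
                                                                      rho_default[jr.junction_id])
            T = depth if depth is not None else int(rng.integers(*config.junction_depth))
            n = int(rng.binomial(T, rho))
            j = T - n
            t = truth[jr.junction_id]
            t.rho_by_sample[sample] = rho
            t.depth_by_sample[sample] = T
            t.n_by_sample[sample] = n
            t.j_by_sample[sample] = j
            for i in range(j):
                o1 = int(rng.integers(mo, jl - mo + 1))
                o2 = jl - o1
                blocks = [(jr.donor + 1 - o1, jr.donor + 1), (jr.acceptor, jr.acceptor + o2)]
                reads.append(ReadAlignment(
                    read_id=f"{sample}:{jr.junction_id}:j{i}", sample=sample,
                    chrom=jr.chrom, strand=jr.strand, blocks=blocks))
            for i in range(n):
                s = int(rng.integers(jr.donor + mo + 1 - jl, jr.donor - mo + 2))
                reads.append(ReadAlignment(
                    read_id=f"{sample}:{jr.junction_id}:n{i}", sample=sample,
                    chrom=jr.chrom, strand=jr.strand, blocks=[(s, s + jl)]))
        reads_by_sample[sample] = reads
    return reads_by_sample, [truth[j.junction_id] for j in junctions]


# ---------------------------------------------------------------------------
# ChIP-like track
# ---------------------------------------------------------------------------


def simulate_chip_track(
    annotation: GenomeAnnotation,
    config: SimConfig,
) -> tuple[BaseSignal, dict[str, float]]:
    """Deterministic ChIP-like density: a 5'->3' ramp over gene bodies.

    Value at gene-body fraction f (transcription direction) is
    chip_base * (1 + chip_skew * f), multiplied by chip_exon_weight on
    union-exon bases; intergenic bases sit at chip_background.  Returns the
    strandless track and true per-gene mean density.
    """
    sizes = {c: L for c, L in annotation.chrom_sizes.items() if c != config.spike_ref}
    track = BaseSignal.zeros("chip", sizes)
    density: dict[str, float] = {}
    for chrom in sorted(sizes):
        vec = track.vector(chrom, ".")
        vec[:] = config.chip_background
    for g in annotation.genes:
        s, e = g.span
        L = e - s
        vec = track.vector(g.chrom, ".")
        f = (np.arange(L) + 0.5) / L
        if g.strand == "-":
            f = f[::-1]
        v = config.chip_base * (1.0 + config.chip_skew * f)
        w = np.ones(L)
        for es, ee in g.union_exons():
            w[es - s:ee - s] = config.chip_exon_weight
        vec[s:e] = v * w
        density[g.gene_id] = float((v * w).mean())
    return track, density


# ---------------------------------------------------------------------------
# Splicing-event tables
# ---------------------------------------------------------------------------


def simulate_event_table(
    n_events: int,
    config: SimConfig,
) -> tuple[list[SplicingEvent], dict[str, bool]]:
    """Alternative-splicing events with known Bayes factors and replicate ΔPSI.

    A ``sig_fraction`` of events satisfy BF > 10 with three same-sign
    replicate ΔPSI values; the rest fail either the BF bound or sign
    consistency.  Returns (events, truth significance by event id).
    """
    rng = _rng(config.seed, "events")
    events: list[SplicingEvent] = []
    truth: dict[str, bool] = {}
    for i in range(n_events):
        eid = f"ev{i + 1:04d}"
        etype = "skipped_exon" if rng.random() < 0.5 else "retained_intron"
        sig = bool(rng.random() < config.sig_fraction)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        mags = rng.uniform(0.05, 0.5, size=3)
        if sig:
            bf = float(rng.uniform(10.5, 100.0))
            dpsi = list(sign * mags)
        elif rng.random() < 0.5:
            bf = float(rng.uniform(0.0, 10.0))      # fails the BF bound
            dpsi = list(sign * mags)
        else:
            bf = float(rng.uniform(10.5, 100.0))    # fails sign consistency
            dpsi = list(sign * mags)
            flip = int(rng.integers(0, 3))
            dpsi[flip] = -dpsi[flip]
        events.append(SplicingEvent(event_id=eid, type=etype, bayes_factor_combined=bf,
                                    delta_psi_by_replicate=[float(d) for d in dpsi]))
        truth[eid] = sig
    return events, truth


# ---------------------------------------------------------------------------
# One-shot simulation
# ---------------------------------------------------------------------------


def simulate_all(config: SimConfig) -> tuple[GenomeAnnotation, dict[str, list[ReadAlignment]],
                                             dict[str, list[ReadAlignment]], BaseSignal,
                                             list[SplicingEvent], GroundTruth]:
    """Generate every input the pipeline consumes plus the ground truth.

    Returns (annotation, startseq reads per sample, junction reads per
    sample, chip track, event table, ground truth manifest).
    """
    ann = simulate_annotation(config)
    sites = place_sites(ann, config)
    ss_reads = simulate_startseq(ann, sites, config)
    jx_reads, jx_truth = simulate_junction_reads(ann, config)
    chip, chip_density = simulate_chip_track(ann, config)
    events, ev_truth = simulate_event_table(config.n_events, config)
    gene_lfc = {s.resident_gene: s.log2fc for s in sites
                if s.status == "obs" and s.resident_gene is not None}
    truth = GroundTruth(count_model="poisson",
                        sites=sites, junctions=jx_truth,
                        chip_density_by_gene=chip_density,
                        gene_log2fc=gene_lfc,
                        event_significant=ev_truth,
                        expected_norm_factors=config.expected_norm_factors())
    return ann, ss_reads, jx_reads, chip, events, truth
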