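"""Readers and writers for the genomic formats the pipeline touches.

All coordinates are 0-based half-open internally; conversion to and from
1-based closed GFF3 happens only at the file boundary.  Every reader
validates its input eagerly and raises :class:`FormatError` (with a line
number where available) or :class:`ValidationError` rather than letting a
malformed record propagate.
"""

from __future__ import annotations

import dataclasses
import json
import typing
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pysam

__all__ = [
    "FormatError",
    "ValidationError",
    "GeneRecord",
    "GenomeAnnotation",
    "ReadAlignment",
    "PeakSet",
    "read_gene_model",
    "write_gene_model",
    "read_signal_track",
    "write_signal_track",
    "read_alignments",
    "write_alignments",
    "write_table",
    "read_table",
]

DEFAULT_SPIKE_PREFIX = "spike_"


class FormatError(ValueError):
    """A file does not parse under the named standard."""


class ValidationError(ValueError):
    """A parsed record violates a structural invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GeneRecord:
    """One gene: span, transcripts with exon chains, derived TSSs, 3'UTR.

    ``annotated_tss`` is always computed from the transcripts (the
    strand-appropriate 5' end of each transcript), never taken from input.
    """

    gene_id: str
    chrom: str
    strand: str
    span: tuple[int, int]
    transcripts: list[tuple[str, list[tuple[int, int]]]]
    annotated_tss: list[int] = field(default_factory=list)
    utr3: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        self.annotated_tss = self._derive_tss()

    def _derive_tss(self) -> list[int]:
        out: set[int] = set()
        for _, exons in self.transcripts:
            if not exons:
                continue
            if self.strand == "+":
                out.add(exons[0][0])
            else:
                out.add(exons[-1][1] - 1)
        return sorted(out)

    def validate(self, chrom_len: int) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"{self.gene_id}: strand must be + or -")
        s, e = self.span
        if not (0 <= s < e <= chrom_len):
            raise ValidationError(f"{self.gene_id}: span {self.span} outside [0, {chrom_len})")
        if not self.transcripts:
            raise ValidationError(f"{self.gene_id}: gene has no transcripts")
        for tx_id, exons in self.transcripts:
            if not exons:
                raise ValidationError(f"{tx_id}: transcript has no exons")
            prev_end = None
            for (es, ee) in exons:
                if not (s <= es < ee <= e):
                    raise ValidationError(f"{tx_id}: exon [{es},{ee}) outside gene span {self.span}")
                if prev_end is not None and es < prev_end:
                    raise ValidationError(f"{tx_id}: exons overlap or are unsorted at [{es},{ee})")
                prev_end = ee
        if self.utr3 is not None:
            us, ue = self.utr3
            if not (s <= us < ue <= e):
                raise ValidationError(f"{self.gene_id}: 3'UTR {self.utr3} outside gene span")

    def length(self) -> int:
        return self.span[1] - self.span[0]

    def union_exons(self) -> list[tuple[int, int]]:
        """Merged (union) exon intervals over all transcripts."""
        ivs = sorted(iv for _, exons in self.transcripts for iv in exons)
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [(s, e) for s, e in merged]


@dataclass
class GenomeAnnotation:
    """Chromosome sizes plus the gene models living on them."""

    chrom_sizes: dict[str, int]
    genes: list[GeneRecord]

    def validate(self) -> None:
        for g in self.genes:
            if g.chrom not in self.chrom_sizes:
                raise ValidationError(f"{g.gene_id}: unknown chromosome {g.chrom!r}")
            g.validate(self.chrom_sizes[g.chrom])

    def genes_on(self, chrom: str) -> list[GeneRecord]:
        return [g for g in self.genes if g.chrom == chrom]


@dataclass
class ReadAlignment:
    """One aligned fragment as a chain of gapless blocks.

    Gaps between consecutive blocks are splice gaps (the SAM 'N' operation).
    ``category`` is "spike" when the reference name carries the spike prefix.
    """

    read_id: str
    sample: str
    chrom: str
    strand: str
    blocks: list[tuple[int, int]]
    category: str = "genomic"
    mate: str = "unpaired"

    def validate(self, chrom_len: Optional[int] = None) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"{self.read_id}: bad strand {self.strand!r}")
        if not self.blocks:
            raise ValidationError(f"{self.read_id}: no aligned blocks")
        prev = None
        for s, e in self.blocks:
            if s >= e:
                raise ValidationError(f"{self.read_id}: empty block [{s},{e})")
            if prev is not None and s < prev:
                raise ValidationError(f"{self.read_id}: blocks overlap or unsorted")
            prev = e
        if chrom_len is not None and self.category == "genomic":
            if self.blocks[0][0] < 0 or self.blocks[-1][1] > chrom_len:
                raise ValidationError(f"{self.read_id}: blocks outside chromosome of length {chrom_len}")

    def five_prime(self) -> int:
        """Genomic coordinate of the 5'-most aligned base."""
        return self.blocks[0][0] if self.strand == "+" else self.blocks[-1][1] - 1


@dataclass
class PeakSet:
    """A set of (chrom, half-open interval) peaks, e.g. ChIP-seq peak calls."""

    intervals: list[tuple[str, int, int]]

    def validate(self, chrom_sizes: dict[str, int]) -> None:
        for chrom, s, e in self.intervals:
            if chrom not in chrom_sizes:
                raise ValidationError(f"peak on unknown chromosome {chrom!r}")
            if not (0 <= s < e <= chrom_sizes[chrom]):
                raise ValidationError(f"peak [{s},{e}) outside {chrom} bounds")

    def on(self, chrom: str) -> list[tuple[int, int]]:
        return [(s, e) for c, s, e in self.intervals if c == chrom]


# ---------------------------------------------------------------------------
# Gene models: GFF3 and BED12
# ---------------------------------------------------------------------------


def _parse_gff3_attrs(text: str, lineno: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise FormatError(f"line {lineno}: malformed GFF3 attribute {part!r}")
        k, v = part.split("=", 1)
        out[k] = v
    return out


def _read_gff3(path: Path) -> GenomeAnnotation:
    chrom_sizes: dict[str, int] = {}
    genes: dict[str, dict] = {}
    tx_parent: dict[str, str] = {}
    tx_exons: dict[str, list[tuple[int, int]]] = {}
    utr_parts: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) != 4:
                    raise FormatError(f"line {lineno}: malformed ##sequence-region pragma")
                chrom_sizes[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"line {lineno}: expected 9 tab-separated columns, got {len(cols)}")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = cols
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer coordinate") from exc
            if start_i < 1 or end_i < start_i:
                raise FormatError(f"line {lineno}: invalid GFF3 interval {start}..{end}")
            # 1-based closed -> 0-based half-open
            iv = (start_i - 1, end_i)
            a = _parse_gff3_attrs(attrs, lineno)
            if ftype == "gene":
                gid = a.get("ID")
                if gid is None:
                    raise FormatError(f"line {lineno}: gene without ID attribute")
                genes[gid] = {"chrom": chrom, "strand": strand, "span": iv}
                order.append(gid)
            elif ftype in ("mRNA", "transcript"):
                tid, parent = a.get("ID"), a.get("Parent")
                if tid is None or parent is None:
                    raise FormatError(f"line {lineno}: transcript missing ID/Parent")
                tx_parent[tid] = parent
                tx_exons.setdefault(tid, [])
            elif ftype == "exon":
                parent = a.get("Parent")
                if parent is None:
                    raise FormatError(f"line {lineno}: exon missing Parent")
                tx_exons.setdefault(parent, []).append(iv)
            elif ftype == "three_prime_UTR":
                parent = a.get("Parent")
                if parent is None:
                    raise FormatError(f"line {lineno}: three_prime_UTR missing Parent")
                utr_parts.setdefault(parent, []).append(iv)
            # other feature types are ignored

    records: list[GeneRecord] = []
    for gid in order:
        info = genes[gid]
        txs = [(tid, sorted(tx_exons[tid])) for tid, parent in tx_parent.items() if parent == gid]
        txs.sort(key=lambda t: t[0])
        utr = None
        for tid, _ in txs:
            if tid in utr_parts:
                parts = sorted(utr_parts[tid])
                utr = (parts[0][0], parts[-1][1])
                break
        records.append(
            GeneRecord(gene_id=gid, chrom=info["chrom"], strand=info["strand"],
                       span=info["span"], transcripts=txs, utr3=utr)
        )
    if not chrom_sizes:
        for r in records:
            chrom_sizes[r.chrom] = max(chrom_sizes.get(r.chrom, 0), r.span[1])
    ann = GenomeAnnotation(chrom_sizes=chrom_sizes, genes=records)
    ann.validate()
    return ann


def _read_bed12(path: Path, chrom_sizes: Optional[dict[str, int]]) -> GenomeAnnotation:
    records: list[GeneRecord] = []
    sizes: dict[str, int] = dict(chrom_sizes or {})
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(f"line {lineno}: BED12 requires 12 columns, got {len(cols)}")
            chrom, start, end, name, _score, strand = cols[:6]
            try:
                start_i, end_i = int(start), int(end)
                n_blocks = int(cols[9])
                sizes_l = [int(x) for x in cols[10].rstrip(",").split(",")]
                starts_l = [int(x) for x in cols[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer BED12 field") from exc
            if len(sizes_l) != n_blocks or len(starts_l) != n_blocks:
                raise FormatError(f"line {lineno}: blockCount disagrees with block lists")
            exons = [(start_i + off, start_i + off + sz) for off, sz in zip(starts_l, sizes_l)]
            records.append(
                GeneRecord(gene_id=name, chrom=chrom, strand=strand,
                           span=(start_i, end_i), transcripts=[(name + ".t1", exons)])
            )
            if chrom_sizes is None:
                sizes[chrom] = max(sizes.get(chrom, 0), end_i)
    ann = GenomeAnnotation(chrom_sizes=sizes, genes=records)
    ann.validate()
    return ann


def read_gene_model(path: Union[str, Path], chrom_sizes: Optional[dict[str, int]] = None) -> GenomeAnnotation:
    """Read a gene model from GFF3 (``.gff``/``.gff3``) or BED12 (``.bed``).

    GFF3 coordinates (1-based closed) are converted to the internal 0-based
    half-open convention.  Annotated TSSs are derived per transcript strand.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_gff3(path)
    if path.suffix.lower() == ".bed":
        return _read_bed12(path, chrom_sizes)
    raise FormatError(f"unrecognized gene-model extension: {path.suffix!r}")


def write_gene_model(ann: GenomeAnnotation, path: Union[str, Path]) -> None:
    """Write a GenomeAnnotation as GFF3 with ##sequence-region pragmas."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(ann.chrom_sizes):
            fh.write(f"##sequence-region {chrom} 1 {ann.chrom_sizes[chrom]}\n")
        for g in ann.genes:
            s, e = g.span
            fh.write(f"{g.chrom}\tstartpipe\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            for tid, exons in g.transcripts:
                fh.write(
                    f"{g.chrom}\tstartpipe\tmRNA\t{exons[0][0] + 1}\t{exons[-1][1]}\t.\t{g.strand}\t.\t"
                    f"ID={tid};Parent={g.gene_id}\n"
                )
                for es, ee in exons:
                    fh.write(f"{g.chrom}\tstartpipe\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\tParent={tid}\n")
                if g.utr3 is not None:
                    us, ue = g.utr3
                    fh.write(
                        f"{g.chrom}\tstartpipe\tthree_prime_UTR\t{us + 1}\t{ue}\t.\t{g.strand}\t.\tParent={tid}\n"
                    )


# ---------------------------------------------------------------------------
# bedGraph signal tracks
# ---------------------------------------------------------------------------


def read_signal_track(
    plus_path: Union[str, Path],
    chrom_sizes: dict[str, int],
    minus_path: Optional[Union[str, Path]] = None,
    *,
    sample: str = "",
    allow_negative: bool = False,
):
    """Read bedGraph file(s) into a dense per-base :class:`BaseSignal`.

    Default dialect is two files (plus/minus strand); with ``minus_path``
    omitted the track is stored strandless (strand "."), appropriate for
    ChIP/ATAC coverage.  Overlapping records or records beyond the
    chromosome end are errors; uncovered bases are 0.
    """
    from .startseq_signal import BaseSignal  # local import: avoids module cycle

    sig = BaseSignal.zeros(sample, chrom_sizes)
    if minus_path is None:
        _fill_bedgraph(sig, Path(plus_path), ".", chrom_sizes, allow_negative)
    else:
        _fill_bedgraph(sig, Path(plus_path), "+", chrom_sizes, allow_negative)
        _fill_bedgraph(sig, Path(minus_path), "-", chrom_sizes, allow_negative)
    return sig


def _fill_bedgraph(sig, path: Path, strand: str, chrom_sizes: dict[str, int], allow_negative: bool) -> None:
    import numpy as np

    covered: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) != 4:
                raise FormatError(f"{path.name} line {lineno}: bedGraph needs 4 columns")
            chrom, start, end, value = cols
            try:
                s, e, v = int(start), int(end), float(value)
            except ValueError as exc:
                raise FormatError(f"{path.name} line {lineno}: bad bedGraph fields") from exc
            if chrom not in chrom_sizes:
                raise FormatError(f"{path.name} line {lineno}: unknown chromosome {chrom!r}")
            if not (0 <= s < e <= chrom_sizes[chrom]):
                raise FormatError(f"{path.name} line {lineno}: interval [{s},{e}) beyond chromosome end")
            if not np.isfinite(v) or (v < 0 and not allow_negative):
                raise FormatError(f"{path.name} line {lineno}: value {value} not finite/nonnegative")
            for ps, pe in covered.get(chrom, []):
                if s < pe and ps < e:
                    raise FormatError(f"{path.name} line {lineno}: overlapping bedGraph records")
            covered.setdefault(chrom, []).append((s, e))
            sig.vector(chrom, strand)[s:e] += v


def write_signal_track(sig, plus_path: Union[str, Path], minus_path: Optional[Union[str, Path]] = None) -> None:
    """Write a BaseSignal as bedGraph (run-length encoded, zeros skipped)."""
    if minus_path is None:
        _dump_bedgraph(sig, ".", Path(plus_path))
    else:
        _dump_bedgraph(sig, "+", Path(plus_path))
        _dump_bedgraph(sig, "-", Path(minus_path))


def _dump_bedgraph(sig, strand: str, path: Path) -> None:
    import numpy as np

    with open(path, "w") as fh:
        for chrom in sorted(sig.chrom_sizes):
            vec = sig.vector(chrom, strand)
            if vec is None:
                continue
            # run boundaries where the value changes
            change = np.flatnonzero(np.diff(vec)) + 1
            bounds = np.concatenate(([0], change, [len(vec)]))
            for s, e in zip(bounds[:-1], bounds[1:]):
                v = vec[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# Alignments: SAM and tabular blocks
# ---------------------------------------------------------------------------

_QUERY_OPS = set("MIS=X")
_REF_IN_BLOCK = set("MD=X")


def _blocks_from_cigar(pos: int, cigartuples: list[tuple[int, int]], read_id: str,
                       query_len: Optional[int]) -> list[tuple[int, int]]:
    """Build gapless blocks: M/=/X/D extend the current block, N splits it."""
    op_chars = "MIDNSHP=XB"
    blocks: list[tuple[int, int]] = []
    cur_start, cur = pos, pos
    consumed = 0
    for op, length in cigartuples:
        ch = op_chars[op]
        if ch in "M=X":
            cur += length
            consumed += length
        elif ch == "D":
            cur += length
        elif ch == "N":
            if cur > cur_start:
                blocks.append((cur_start, cur))
            cur += length
            cur_start = cur
        elif ch in "IS":
            consumed += length
        # H, P consume nothing relevant
    if cur > cur_start:
        blocks.append((cur_start, cur))
    if query_len is not None and consumed != query_len:
        raise FormatError(f"{read_id}: CIGAR consumes {consumed} query bases but sequence has {query_len}")
    return blocks


def read_alignments(
    path: Union[str, Path],
    chrom_sizes: Optional[dict[str, int]] = None,
    *,
    spike_prefix: str = DEFAULT_SPIKE_PREFIX,
    sample: Optional[str] = None,
) -> list[ReadAlignment]:
    """Read alignments from SAM (``.sam``) or the tabular block format (``.tsv``).

    SAM parsing skips unmapped and secondary/supplementary records; CIGAR
    M/=/X/D consume reference within a block and N splits blocks.  Reads on
    references starting with ``spike_prefix`` are categorised as spike.
    """
    path = Path(path)
    if path.suffix.lower() == ".sam":
        return _read_sam(path, chrom_sizes, spike_prefix, sample)
    if path.suffix.lower() in (".tsv", ".txt"):
        return _read_tabular_reads(path, chrom_sizes, spike_prefix, sample)
    raise FormatError(f"unrecognized alignment extension: {path.suffix!r}")


def _read_sam(path: Path, chrom_sizes, spike_prefix: str, sample: Optional[str]) -> list[ReadAlignment]:
    out: list[ReadAlignment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        header_sizes = {r: l for r, l in zip(fh.references, fh.lengths)}
        sizes = chrom_sizes or header_sizes
        records = _iter_sam(fh, path)
        for rec in records:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            chrom = rec.reference_name
            qlen = len(rec.query_sequence) if rec.query_sequence else None
            blocks = _blocks_from_cigar(rec.reference_start, rec.cigartuples or [], rec.query_name, qlen)
            category = "spike" if chrom.startswith(spike_prefix) else "genomic"
            mate = "unpaired" if not rec.is_paired else ("1" if rec.is_read1 else "2")
            samp = sample
            if samp is None:
                samp = rec.get_tag("RG") if rec.has_tag("RG") else ""
            read = ReadAlignment(
                read_id=rec.query_name,
                sample=samp,
                chrom=chrom,
                strand="-" if rec.is_reverse else "+",
                blocks=blocks,
                category=category,
                mate=mate,
            )
            read.validate(sizes.get(chrom) if category == "genomic" else None)
            out.append(read)
    return out


def _iter_sam(fh, path: Path):
    """Iterate pysam records, converting htslib parse errors to FormatError."""
    it = iter(fh)
    while True:
        try:
            yield next(it)
        except StopIteration:
            return
        except (OSError, ValueError) as exc:
            raise FormatError(f"{path.name}: malformed SAM record "
                              f"(CIGAR/sequence mismatch or truncated line): {exc}") from exc


def _read_tabular_reads(path: Path, chrom_sizes, spike_prefix: str, sample: Optional[str]) -> list[ReadAlignment]:
    out: list[ReadAlignment] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["read_id", "sample", "chrom", "strand", "blocks", "mate"]
        if header != expected:
            raise FormatError(f"{path.name}: tabular reads header must be {expected}")
        for lineno, raw in enumerate(fh, 2):
            line = raw.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 6:
                raise FormatError(f"{path.name} line {lineno}: expected 6 columns")
            read_id, samp, chrom, strand, blocks_s, mate = cols
            try:
                blocks = [tuple(int(x) for x in b.split("-")) for b in blocks_s.split(",")]
            except ValueError as exc:
                raise FormatError(f"{path.name} line {lineno}: malformed blocks field") from exc
            category = "spike" if chrom.startswith(spike_prefix) else "genomic"
            read = ReadAlignment(read_id=read_id, sample=sample or samp, chrom=chrom,
                                 strand=strand, blocks=blocks, category=category, mate=mate)
            if chrom_sizes is not None and category == "genomic":
                if chrom not in chrom_sizes:
                    raise FormatError(f"{path.name} line {lineno}: unknown chromosome {chrom!r}")
                read.validate(chrom_sizes[chrom])
            else:
                read.validate(None)
            out.append(read)
    return out


def write_alignments(
    reads: list[ReadAlignment],
    path: Union[str, Path],
    chrom_sizes: Optional[dict[str, int]] = None,
) -> None:
    """Write alignments as SAM (``.sam``, via pysam) or tabular blocks (``.tsv``)."""
    path = Path(path)
    if path.suffix.lower() == ".sam":
        if chrom_sizes is None:
            raise ValueError("chrom_sizes required to build the SAM header")
        _write_sam(reads, path, chrom_sizes)
    elif path.suffix.lower() in (".tsv", ".txt"):
        with open(path, "w") as fh:
            fh.write("read_id\tsample\tchrom\tstrand\tblocks\tmate\n")
            for r in reads:
                blocks_s = ",".join(f"{s}-{e}" for s, e in r.blocks)
                fh.write(f"{r.read_id}\t{r.sample}\t{r.chrom}\t{r.strand}\t{blocks_s}\t{r.mate}\n")
    else:
        raise FormatError(f"unrecognized alignment extension: {path.suffix!r}")


def _write_sam(reads: list[ReadAlignment], path: Path, chrom_sizes: dict[str, int]) -> None:
    refs = sorted(chrom_sizes)
    header = {"HD": {"VN": "1.6", "SO": "unknown"},
              "SQ": [{"SN": r, "LN": chrom_sizes[r]} for r in refs]}
    ref_idx = {r: i for i, r in enumerate(refs)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for r in reads:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = r.read_id
            seg.reference_id = ref_idx[r.chrom]
            seg.reference_start = r.blocks[0][0]
            seg.mapping_quality = 255
            flag = 16 if r.strand == "-" else 0
            if r.mate in ("1", "2"):
                flag |= 0x1 | (0x40 if r.mate == "1" else 0x80)
            seg.flag = flag
            cig: list[tuple[int, int]] = []
            prev_end = None
            for s, e in r.blocks:
                if prev_end is not None:
                    cig.append((3, s - prev_end))  # N
                cig.append((0, e - s))  # M
                prev_end = e
            seg.cigartuples = cig
            qlen = sum(e - s for s, e in r.blocks)
            seg.query_sequence = "N" * qlen
            seg.query_qualities = pysam.qualitystring_to_array("I" * qlen)
            seg.set_tag("RG", r.sample)
            fh.write(seg)


# ---------------------------------------------------------------------------
# Generic record tables (TSV, round-trip with the matching reader)
# ---------------------------------------------------------------------------

_NA = "NA"


def _serialize(value, float_fmt: str = "%.6g") -> str:
    if value is None:
        return _NA
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return float_fmt % value
    if isinstance(value, (list, tuple, dict)):
        return json.dumps(value, sort_keys=True, separators=(",", ":"))
    return str(value)


def _parse(text: str, tp):
    origin = typing.get_origin(tp)
    if origin is Union:
        args = [a for a in typing.get_args(tp) if a is not type(None)]
        if text == _NA:
            return None
        return _parse(text, args[0])
    if tp is float:
        return float(text)
    if tp is int:
        return int(text)
    if tp is bool:
        return text == "true"
    if tp is str:
        return text
    if origin in (list, tuple, dict):
        loaded = json.loads(text)
        if origin is tuple:
            return tuple(loaded)
        if origin is list:
            inner = typing.get_args(tp)
            if inner and typing.get_origin(inner[0]) is tuple:
                return [tuple(x) for x in loaded]
            return loaded
        return loaded
    raise TypeError(f"unsupported field type for table round-trip: {tp}")


def write_table(records: list, path: Union[str, Path], *, header_comment: Optional[str] = None) -> None:
    """Write homogeneous dataclass records as TSV (floats at 6 significant digits).

    Column order is the dataclass field order, so files diff stably and
    round-trip losslessly through :func:`read_table`.
    """
    path = Path(path)
    if records and not dataclasses.is_dataclass(records[0]):
        raise TypeError("write_table expects dataclass records")
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        if not records:
            fh.write("\n")
            return
        fields = [f.name for f in dataclasses.fields(records[0])]
        fh.write("\t".join(fields) + "\n")
        for rec in records:
            if type(rec) is not type(records[0]):
                raise TypeError("write_table records must be homogeneous")
            fh.write("\t".join(_serialize(getattr(rec, f)) for f in fields) + "\n")


def read_table(path: Union[str, Path], record_type) -> list:
    """Read a TSV written by :func:`write_table` back into dataclass records."""
    hints = typing.get_type_hints(record_type)
    out = []
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if not l.startswith("#")]
    if not lines or lines[0] == "":
        return out
    fields = lines[0].split("\t")
    for line in lines[1:]:
        if not line:
            continue
        values = line.split("\t")
        if len(values) != len(fields):
            raise FormatError(f"{path}: row width disagrees with header")
        kwargs = {f: _parse(v, hints[f]) for f, v in zip(fields, values)}
        out.append(record_type(**kwargs))
    return out
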