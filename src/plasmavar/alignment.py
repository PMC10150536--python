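"""Turn aligned reads into per-position observations with read-level features.

Reads UMI-consensus alignments (SAM/BAM with MD, cD, cE tags) plus a reference
FASTA and produces one :class:`ReadPositionObservation` per read alignment
mismatch (for error-model training) or per covered candidate site (for
calling).  Coordinates are 1-based genomic, 0-based query internally.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pysam

NUCLEOTIDES = ("A", "C", "G", "T")
WINDOW_SIZE = 11  # bp of reference context used for GC / entropy features
_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")

# SAM flag bits
_FLAG_PAIRED = 0x1
_FLAG_UNMAPPED = 0x4
_FLAG_REVERSE = 0x10
_FLAG_FIRST_IN_PAIR = 0x40
_FLAG_SECONDARY = 0x100
_FLAG_QCFAIL = 0x200
_FLAG_DUPLICATE = 0x400
_FLAG_SUPPLEMENTARY = 0x800

_CIGAR_OP = re.compile(r"(\d+)([MIDNSHP=X])")
_CONSUMES_QUERY = set("MIS=X")
_CONSUMES_REF = set("MDN=X")


class MDParseError(ValueError):
    """Malformed MD string, or MD inconsistent with the CIGAR."""


@dataclass
class AlignedReadRecord:
    """A mapped consensus read with the tags the error model consumes."""

    query_name: str
    flags: int
    chrom: str
    pos: int  # 1-based leftmost mapped reference coordinate
    cigar: str
    md: str
    isize: int
    seq: str
    umi_group_size: int = 1  # fgbio cD tag
    umi_errors: int | Sequence[int] = 0  # fgbio cE tag (per read or per base)
    mapq: int = 60

    @classmethod
    def from_pysam(cls, aln: pysam.AlignedSegment,
                   missing_umi: str = "default") -> "AlignedReadRecord":
        """Build a record from a pysam segment.

        ``missing_umi``: 'default' substitutes cD=1/cE=0 when the consensus
        tags are absent; 'error' raises instead.
        """
        try:
            cd = int(aln.get_tag("cD"))
        except KeyError:
            if missing_umi == "error":
                raise KeyError(f"read {aln.query_name}: missing cD tag")
            cd = 1
        try:
            ce = aln.get_tag("cE")
            ce = int(ce) if not isinstance(ce, (list, tuple)) else list(ce)
        except KeyError:
            if missing_umi == "error":
                raise KeyError(f"read {aln.query_name}: missing cE tag")
            ce = 0
        return cls(
            query_name=aln.query_name,
            flags=aln.flag,
            chrom=aln.reference_name,
            pos=aln.reference_start + 1,
            cigar=aln.cigarstring or "",
            md=str(aln.get_tag("MD")) if aln.has_tag("MD") else "",
            isize=aln.template_length,
            seq=aln.query_sequence or "",
            umi_group_size=cd,
            umi_errors=ce,
            mapq=aln.mapping_quality,
        )

    @property
    def is_reverse(self) -> bool:
        return bool(self.flags & _FLAG_REVERSE)

    @property
    def is_first_in_pair(self) -> bool:
        return bool(self.flags & _FLAG_FIRST_IN_PAIR)


@dataclass(frozen=True)
class GenomicContext:
    """Local reference context around a position of interest."""

    trinucleotide: str
    window: str
    gc_content: float
    entropy_1mer: float
    entropy_2mer: float


@dataclass
class ReadPositionObservation:
    """One read x genomic position, with the feature set used by the model."""

    chrom: str
    genomic_pos: int
    ref_allele: str
    obs_allele: str
    read_position: int  # 1-based sequencing-cycle index from the 5' end
    strand: str  # 'forward' | 'reverse'
    first_in_pair: bool
    fragment_size: int
    seq_length: int
    umi_group_size: int
    umi_errors: int
    n_other_errors: int
    n_insertions: int
    n_deletions: int
    context: GenomicContext
    query_name: str = ""
    sample: str = ""

    def as_row(self) -> dict:
        return {
            "chrom": self.chrom,
            "genomic_pos": self.genomic_pos,
            "ref_allele": self.ref_allele,
            "obs_allele": self.obs_allele,
            "read_position": self.read_position,
            "strand": self.strand,
            "first_in_pair": self.first_in_pair,
            "fragment_size": self.fragment_size,
            "seq_length": self.seq_length,
            "umi_group_size": self.umi_group_size,
            "umi_errors": self.umi_errors,
            "n_other_errors": self.n_other_errors,
            "n_insertions": self.n_insertions,
            "n_deletions": self.n_deletions,
            "trinucleotide": self.context.trinucleotide,
            "gc_content": self.context.gc_content,
            "entropy_1mer": self.context.entropy_1mer,
            "entropy_2mer": self.context.entropy_2mer,
            "query_name": self.query_name,
            "sample": self.sample,
        }


OBSERVATION_COLUMNS = [
    "chrom", "genomic_pos", "ref_allele", "obs_allele", "read_position",
    "strand", "first_in_pair", "fragment_size", "seq_length",
    "umi_group_size", "umi_errors", "n_other_errors", "n_insertions",
    "n_deletions", "trinucleotide", "gc_content", "entropy_1mer",
    "entropy_2mer", "query_name", "sample",
]


@dataclass
class ReadFilter:
    """Which alignments enter feature extraction."""

    min_mapq: int = 20
    require_paired: bool = True
    exclude_duplicates: bool = True
    exclude_secondary: bool = True
    trim_start: int = 0  # bases ignored at the read's 5' end (cycles 1..trim_start)
    trim_end: int = 0

    def passes(self, rec: AlignedReadRecord) -> bool:
        if rec.flags & (_FLAG_UNMAPPED | _FLAG_SUPPLEMENTARY):
            return False
        if self.exclude_secondary and rec.flags & _FLAG_SECONDARY:
            return False
        if self.exclude_duplicates and rec.flags & _FLAG_DUPLICATE:
            return False
        if self.require_paired and not rec.flags & _FLAG_PAIRED:
            return False
        if rec.mapq < self.min_mapq:
            return False
        if rec.isize == 0:
            return False  # unpaired / undefined fragment size
        return True


def expand_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_OP.findall(cigar)]
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"invalid CIGAR: {cigar!r}")
    return ops


def aligned_query_offsets(cigar: str) -> list[int]:
    """0-based query offsets of bases aligned to the reference (M/=/X), in order."""
    out: list[int] = []
    q = 0
    for n, op in expand_cigar(cigar):
        if op in "M=X":
            out.extend(range(q, q + n))
            q += n
        elif op in "IS":
            q += n
    return out


def parse_md_mismatches(record: AlignedReadRecord) -> list[tuple[int, str, str]]:
    """Extract substitutions from the MD tag.

    Returns ``(query_offset, ref_base, obs_base)`` for every mismatch, in
    query order.  Deletion runs (``^``-prefixed) consume reference only.
    Raises :class:`MDParseError` for malformed MD or an MD whose implied
    aligned length disagrees with the CIGAR.
    """
    md = record.md
    if md == "":
        raise MDParseError("empty MD tag")
    aligned = aligned_query_offsets(record.cigar)
    consumed = "".join(m.group(0) for m in _MD_TOKEN.finditer(md))
    if consumed != md:
        raise MDParseError(f"malformed MD string: {md!r}")
    out: list[tuple[int, str, str]] = []
    k = 0  # index into aligned query bases
    for m in _MD_TOKEN.finditer(md):
        num, deletion, sub = m.groups()
        if num is not None:
            k += int(num)
        elif deletion is not None:
            continue  # deleted reference bases: no query base consumed
        else:
            if k >= len(aligned):
                raise MDParseError(
                    f"MD {md!r} longer than CIGAR-aligned length at token {sub!r}")
            q = aligned[k]
            out.append((q, sub.upper(), record.seq[q].upper()))
            k += 1
    if k != len(aligned):
        raise MDParseError(
            f"MD {md!r} covers {k} aligned bases but CIGAR {record.cigar!r} "
            f"aligns {len(aligned)}")
    return out


def map_query_to_reference(cigar: str, pos: int, query_offset: int) -> int | None:
    """1-based reference coordinate of a 0-based query offset, or None.

    Soft-clipped and inserted bases have no reference coordinate.
    """
    q = 0
    r = pos
    for n, op in expand_cigar(cigar):
        cq = op in _CONSUMES_QUERY
        cr = op in _CONSUMES_REF
        if cq and query_offset < q + n:
            return r + (query_offset - q) if cr else None
        if cq:
            q += n
        if cr:
            r += n
    raise IndexError(f"query offset {query_offset} outside read (CIGAR {cigar})")


def _shannon_entropy(counts: Counter) -> float:
    total = sum(counts.values())
    ent = 0.0
    for c in counts.values():
        p = c / total
        ent -= p * math.log2(p)
    return ent


class ContextError(ValueError):
    """Window touches a contig edge or contains non-ACGT characters."""


def window_stats(reference: Mapping[str, str], chrom: str,
                 genomic_pos: int) -> GenomicContext:
    """GC content, 1-/2-mer Shannon entropy and trinucleotide of the 11-bp window.

    ``reference`` is any mapping from contig name to sequence (a dict or a
    ``pyfaidx.Fasta``); ``genomic_pos`` is 1-based and must sit at least 5 bp
    from either contig edge.
    """
    half = WINDOW_SIZE // 2
    seq = reference[chrom]
    start = genomic_pos - 1 - half
    if start < 0 or genomic_pos + half > len(seq):
        raise ContextError(
            f"{chrom}:{genomic_pos} window extends past contig edge")
    window = str(seq[start:start + WINDOW_SIZE]).upper()
    if any(b not in "ACGT" for b in window):
        raise ContextError(f"{chrom}:{genomic_pos} window has non-ACGT base")
    tnc = window[half - 1:half + 2]
    gc = (window.count("G") + window.count("C")) / WINDOW_SIZE
    e1 = _shannon_entropy(Counter(window))
    e2 = _shannon_entropy(Counter(window[i:i + 2] for i in range(WINDOW_SIZE - 1)))
    return GenomicContext(trinucleotide=tnc, window=window, gc_content=gc,
                          entropy_1mer=e1, entropy_2mer=e2)


def read_cycle(record: AlignedReadRecord, query_offset: int) -> int:
    """1-based sequencing-cycle index of a query offset.

    Reverse-strand alignments store the reverse complement, so the cycle is
    counted from the alignment's right end.
    """
    if record.is_reverse:
        return len(record.seq) - query_offset
    return query_offset + 1


def _umi_errors_at(record: AlignedReadRecord, query_offset: int) -> int:
    ce = record.umi_errors
    if isinstance(ce, (list, tuple)):
        return int(ce[query_offset])
    return int(ce)


def extract_read_features(record: AlignedReadRecord) -> dict:
    """Read-level features shared by every position of one read."""
    n_ins = n_del = 0
    for n, op in expand_cigar(record.cigar):
        if op == "I":
            n_ins += 1
        elif op == "D":
            n_del += 1
    return {
        "strand": "reverse" if record.is_reverse else "forward",
        "first_in_pair": record.is_first_in_pair,
        "fragment_size": abs(record.isize),
        "seq_length": len(record.seq),
        "umi_group_size": record.umi_group_size,
        "n_insertions": n_ins,
        "n_deletions": n_del,
    }


def build_observations(
    record: AlignedReadRecord,
    reference: Mapping[str, str],
    target_sites: Mapping[tuple[str, int], tuple[str, str]] | None = None,
    exclusions: frozenset | set | None = None,
    read_filter: ReadFilter | None = None,
    sample: str = "",
) -> list[ReadPositionObservation]:
    """Observations for one read.

    Without ``target_sites``: one observation per MD mismatch not in
    ``exclusions`` (a set of ``(chrom, pos)``).  With ``target_sites`` (a
    mapping ``(chrom, pos) -> (ref, alt)``): one observation per covered
    site, match or mismatch.  Observations with obs_allele N (or any
    non-ACGT base) and positions whose context window is unusable are
    dropped.
    """
    rf = read_filter or ReadFilter()
    if not rf.passes(record):
        return []
    exclusions = exclusions or set()
    mismatches = parse_md_mismatches(record)
    n_mismatch_total = len(mismatches)
    shared = extract_read_features(record)
    seq_len = len(record.seq)

    def in_trim(cycle: int) -> bool:
        return cycle <= rf.trim_start or cycle > seq_len - rf.trim_end

    out: list[ReadPositionObservation] = []

    def emit(q: int, gpos: int, ref_base: str, obs_base: str, is_mm: bool):
        if obs_base not in NUCLEOTIDES:
            return
        cycle = read_cycle(record, q)
        if in_trim(cycle):
            return
        try:
            ctx = window_stats(reference, record.chrom, gpos)
        except ContextError:
            return
        out.append(ReadPositionObservation(
            chrom=record.chrom, genomic_pos=gpos,
            ref_allele=ref_base, obs_allele=obs_base,
            read_position=cycle,
            umi_errors=_umi_errors_at(record, q),
            n_other_errors=n_mismatch_total - (1 if is_mm else 0),
            context=ctx, query_name=record.query_name, sample=sample,
            **shared,
        ))

    if target_sites is None:
        for q, ref_base, obs_base in mismatches:
            gpos = map_query_to_reference(record.cigar, record.pos, q)
            if gpos is None or (record.chrom, gpos) in exclusions:
                continue
            emit(q, gpos, ref_base, obs_base, True)
    else:
        mm_by_ref = {}
        for q, ref_base, obs_base in mismatches:
            gpos = map_query_to_reference(record.cigar, record.pos, q)
            if gpos is not None:
                mm_by_ref[gpos] = (q, ref_base, obs_base)
        offsets = aligned_query_offsets(record.cigar)
        for q in offsets:
            gpos = map_query_to_reference(record.cigar, record.pos, q)
            key = (record.chrom, gpos)
            if key not in target_sites or key in exclusions:
                continue
            site_ref = target_sites[key][0]
            if gpos in mm_by_ref:
                _, ref_base, obs_base = mm_by_ref[gpos]
                emit(q, gpos, ref_base, obs_base, True)
            else:
                emit(q, gpos, site_ref, record.seq[q].upper(), False)
    return out


def iter_alignments(path: str, missing_umi: str = "default"
                    ) -> Iterable[AlignedReadRecord]:
    """Yield AlignedReadRecords from a SAM/BAM file."""
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.cigarstring is None:
                continue
            yield AlignedReadRecord.from_pysam(aln, missing_umi=missing_umi)
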