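"""Per-read scoring and per-line genotype calling at microsatellite loci.

Genotypes are scored as *allele length*: the number of sequenced read bases
separating the two non-repetitive flanking boundary bases aligned to the
reference, irrespective of where the aligner placed gaps inside the tract.
Two reads of the same allelic variant whose internal indel was aligned at
different positions therefore yield identical calls (gap invariance), which
avoids the classic false-allele problem of ambiguously placed indels.

A read contributes to a genotype only when it is "scorable":

1. it spans the entire repeat, with aligned (non-gap) bases at both
   boundary anchors (the base just left of the tract and the base just
   right of it);
2. at least ``min_flank`` consecutive flanking positions adjacent to the
   repeat match the reference on *both* sides;
3. it is uniquely mapped (MapQ > 0 and no alternative-hit annotation).

Lines are assumed homozygous (inbred panels), so a single majority allele
is called per locus per line; internal concordance R_major / R_total over
the scorable reads measures call purity.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import RepeatLocus

__all__ = [
    "AlignedReadView",
    "ScoredRead",
    "LocusCall",
    "GenotypeMatrix",
    "read_spans_locus",
    "count_flank_matches",
    "allele_length_from_alignment",
    "score_read",
    "rescore_with_min_flank",
    "call_locus",
    "genotype_panel",
    "PanelResult",
]

MISSING = "."

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass
class AlignedReadView:
    """Alignment of one read, as (read offset, reference position) pairs.

    ``pairs`` follows the SAM aligned-pairs convention: gaps are ``None``
    on the missing side (insertions and soft clips have no reference
    position, deletions no read offset).  Both coordinates are monotone.
    """

    read_name: str
    chrom: str
    read_length: int
    mapq: int
    unique: bool
    pairs: list[tuple[int | None, int | None]]
    sequence: str

    _qpos_by_ref: dict[int, int] = field(default=None, repr=False, compare=False)
    _ref_span: tuple[int, int] = field(default=None, repr=False, compare=False)

    def _index(self) -> None:
        if self._qpos_by_ref is None:
            d = {}
            lo, hi = None, None
            for q, r in self.pairs:
                if r is not None:
                    if lo is None:
                        lo = r
                    hi = r
                    if q is not None:
                        d[r] = q
            self._qpos_by_ref = d
            self._ref_span = (lo, hi) if lo is not None else (0, -1)

    @property
    def reference_span(self) -> tuple[int, int]:
        """(first, last) reference positions consumed, inclusive."""
        self._index()
        return self._ref_span

    def query_offset(self, ref_pos: int) -> int | None:
        """Read offset aligned at ``ref_pos``; None when gapped or uncovered."""
        self._index()
        return self._qpos_by_ref.get(ref_pos)

    @classmethod
    def from_pysam(cls, seg) -> "AlignedReadView":
        unique = seg.mapping_quality > 0 and not seg.has_tag("XA")
        return cls(
            read_name=seg.query_name,
            chrom=seg.reference_name,
            read_length=seg.query_length,
            mapq=seg.mapping_quality,
            unique=unique,
            pairs=seg.get_aligned_pairs(),
            sequence=seg.query_sequence or "",
        )

    @classmethod
    def from_cigar(
        cls,
        read_name: str,
        chrom: str,
        pos: int,
        cigar: str,
        sequence: str,
        *,
        mapq: int = 60,
        unique: bool = True,
    ) -> "AlignedReadView":
        """Build a view from a CIGAR string and 0-based mapping position."""
        pairs: list[tuple[int | None, int | None]] = []
        q, r = 0, pos
        for num, op in _CIGAR_RE.findall(cigar):
            n = int(num)
            if op in "M=X":
                pairs.extend((q + i, r + i) for i in range(n))
                q += n
                r += n
            elif op in "IS":
                pairs.extend((q + i, None) for i in range(n))
                q += n
            elif op in "DN":
                pairs.extend((None, r + i) for i in range(n))
                r += n
            # H and P consume nothing we track
        if q != len(sequence):
            raise ValueError(
                f"{read_name}: CIGAR consumes {q} read bases, sequence has {len(sequence)}"
            )
        return cls(
            read_name=read_name,
            chrom=chrom,
            read_length=len(sequence),
            mapq=mapq,
            unique=unique,
            pairs=pairs,
            sequence=sequence,
        )


@dataclass
class ScoredRead:
    """One read's contribution at one locus.

    ``allele_length`` is populated whenever both boundary anchors are
    aligned, even for reads later rejected on flank or uniqueness grounds,
    so that filter sweeps can re-threshold without re-scoring.
    """

    locus_id: str
    read_name: str
    allele_length: int | None
    flank_match_left: int
    flank_match_right: int
    scorable: bool
    rejection_reason: str  # "", not_spanning, unanchored, not_unique, flank_mismatch
    mapq: int = 0


@dataclass
class LocusCall:
    """Per-line genotype at one locus."""

    locus_id: str
    line_id: str
    allele_counts: dict[int, int]
    n_scorable: int
    majority_allele: int | None
    concordance: float | None
    status: str  # called | insufficient_reads | ambiguous_tie | excluded_het


# ---------------------------------------------------------------------------
# Reference access
# ---------------------------------------------------------------------------

def _chrom_seq(reference, chrom: str) -> str:
    """Chromosome sequence as an upper-case string from a dict or FASTA object."""
    seq = reference[chrom]
    if not isinstance(seq, str):
        seq = str(seq[:])  # pyfaidx FastaRecord
    return seq.upper()


# ---------------------------------------------------------------------------
# Read-level operations
# ---------------------------------------------------------------------------

def read_spans_locus(read: AlignedReadView, locus: RepeatLocus) -> bool:
    """True iff both boundary anchors are covered by aligned read bases.

    The anchors are reference positions ``locus.start - 1`` and
    ``locus.end``.  A locus at the chromosome edge has no flank on one
    side and can never be spanned.
    """
    if locus.start == 0:
        return False
    return (
        read.query_offset(locus.start - 1) is not None
        and read.query_offset(locus.end) is not None
    )


def count_flank_matches(
    read: AlignedReadView, locus: RepeatLocus, side: str, reference
) -> int:
    """Consecutive matching flank positions scanning outward from the tract.

    A mismatch, an alignment gap (including inserted read bases between
    flank positions), or the end of the read terminates the run.
    """
    chrom_seq = _chrom_seq(reference, locus.chrom)
    if side == "left":
        pos, step = locus.start - 1, -1
    elif side == "right":
        pos, step = locus.end, 1
    else:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    count = 0
    prev_q: int | None = None
    while 0 <= pos < len(chrom_seq):
        q = read.query_offset(pos)
        if q is None:
            break
        if prev_q is not None and abs(q - prev_q) != 1:
            break  # inserted read bases between flank positions
        if q >= len(read.sequence) or read.sequence[q].upper() != chrom_seq[pos]:
            break
        count += 1
        prev_q = q
        pos += step
    return count


def allele_length_from_alignment(read: AlignedReadView, locus: RepeatLocus) -> int:
    """Read bases between the two boundary anchors (gap-invariant).

    Insertions between the anchors count toward the allele length and
    deletions shorten it; the value does not depend on where gaps were
    placed inside the tract.
    """
    q_left = read.query_offset(locus.start - 1) if locus.start > 0 else None
    q_right = read.query_offset(locus.end)
    if q_left is None or q_right is None:
        raise ValueError(f"{read.read_name}: boundary anchor not aligned at {locus.locus_id}")
    return q_right - q_left - 1


def score_read(
    read: AlignedReadView,
    locus: RepeatLocus,
    reference,
    *,
    min_flank: int = 3,
    require_unique: bool = True,
) -> ScoredRead:
    """Apply the three scorability criteria to one read at one locus.

    Rejections are data, not errors; the first failing criterion (in the
    order spanning, anchoring, uniqueness, flank matching) is recorded.
    """
    chrom_seq = _chrom_seq(reference, locus.chrom)
    allele = None
    fl = fr = 0
    reason = ""
    edge = locus.start == 0 or locus.end >= len(chrom_seq)
    q_left = read.query_offset(locus.start - 1) if locus.start > 0 else None
    q_right = read.query_offset(locus.end) if locus.end < len(chrom_seq) else None
    if q_left is None or q_right is None:
        lo, hi = read.reference_span
        covered = lo <= locus.start - 1 and hi >= locus.end and not edge
        reason = "unanchored" if covered or edge else "not_spanning"
    else:
        allele = q_right - q_left - 1
        fl = count_flank_matches(read, locus, "left", reference)
        fr = count_flank_matches(read, locus, "right", reference)
        if require_unique and not read.unique:
            reason = "not_unique"
        elif fl < min_flank or fr < min_flank:
            reason = "flank_mismatch"
    return ScoredRead(
        locus_id=locus.locus_id,
        read_name=read.read_name,
        allele_length=allele,
        flank_match_left=fl,
        flank_match_right=fr,
        scorable=(reason == ""),
        rejection_reason=reason,
        mapq=read.mapq,
    )


def rescore_with_min_flank(scored: Iterable[ScoredRead], min_flank: int) -> list[ScoredRead]:
    """Re-threshold already scored reads at a different flank requirement.

    Reads rejected for spanning/anchoring/uniqueness stay rejected; reads
    with recorded flank counts are re-evaluated against ``min_flank``.
    """
    out = []
    for s in scored:
        if s.rejection_reason in ("", "flank_mismatch"):
            ok = s.flank_match_left >= min_flank and s.flank_match_right >= min_flank
            out.append(
                ScoredRead(
                    locus_id=s.locus_id,
                    read_name=s.read_name,
                    allele_length=s.allele_length,
                    flank_match_left=s.flank_match_left,
                    flank_match_right=s.flank_match_right,
                    scorable=ok,
                    rejection_reason="" if ok else "flank_mismatch",
                    mapq=s.mapq,
                )
            )
        else:
            out.append(s)
    return out


# ---------------------------------------------------------------------------
# Locus- and panel-level calling
# ---------------------------------------------------------------------------

def call_locus(
    scored: Sequence[ScoredRead],
    min_reads: int = 2,
    *,
    locus_id: str | None = None,
    line_id: str = "",
) -> LocusCall:
    """Call the majority-allele genotype from one line's scorable reads.

    Concordance = R_major / R_total over scorable reads.  An exact tie for
    the modal allele yields no genotype (inbred lines should be homozygous;
    a tie signals error).
    """
    usable = [s for s in scored if s.scorable and s.allele_length is not None]
    if locus_id is None:
        locus_id = scored[0].locus_id if scored else ""
    counts = Counter(s.allele_length for s in usable)
    n = sum(counts.values())
    if n < min_reads:
        return LocusCall(locus_id, line_id, dict(counts), n, None, None, "insufficient_reads")
    top = max(counts.values())
    winners = [a for a, c in counts.items() if c == top]
    if len(winners) > 1:
        return LocusCall(locus_id, line_id, dict(counts), n, None, None, "ambiguous_tie")
    return LocusCall(locus_id, line_id, dict(counts), n, winners[0], top / n, "called")


@dataclass
class GenotypeMatrix:
    """Loci x lines table of allele-length calls (NaN = missing)."""

    alleles: pd.DataFrame
    status: pd.DataFrame

    def to_tsv(self, path) -> None:
        out = self.alleles.copy()
        out.index.name = "locus_id"
        out.to_csv(path, sep="\t", na_rep=MISSING, float_format="%.0f")

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="locus_id", na_values=[MISSING])
        status = df.notna().replace({True: "called", False: "insufficient_reads"})
        return cls(alleles=df.astype(float), status=status)


@dataclass
class PanelResult:
    """Genotyping results for a panel of lines against one catalog."""

    calls: dict[tuple[str, str], LocusCall]  # (locus_id, line_id) -> call
    matrix: GenotypeMatrix
    locus_ids: list[str]
    line_ids: list[str]
    scored_reads: dict[tuple[str, str], list[ScoredRead]] | None = None

    def calls_for_line(self, line_id: str) -> list[LocusCall]:
        return [self.calls[(l, line_id)] for l in self.locus_ids]

    def calls_frame(self) -> pd.DataFrame:
        rows = [
            (
                c.locus_id,
                c.line_id,
                c.n_scorable,
                ";".join(f"{a}:{n}" for a, n in sorted(c.allele_counts.items())),
                c.majority_allele if c.majority_allele is not None else MISSING,
                round(c.concordance, 6) if c.concordance is not None else MISSING,
                c.status,
            )
            for c in self.calls.values()
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "locus_id",
                "line_id",
                "n_scorable",
                "allele_counts",
                "majority_allele",
                "concordance",
                "status",
            ],
        )


def _reads_from_source(source) -> Iterable[AlignedReadView]:
    """Yield AlignedReadView from a SAM/BAM path, pysam iterable, or view list."""
    import pysam

    if isinstance(source, (str,)) or hasattr(source, "__fspath__"):
        with pysam.AlignmentFile(str(source), check_sq=False) as fh:
            for seg in fh:
                if seg.is_unmapped:
                    continue
                yield AlignedReadView.from_pysam(seg)
    else:
        for item in source:
            if isinstance(item, AlignedReadView):
                yield item
            else:
                if item.is_unmapped:
                    continue
                yield AlignedReadView.from_pysam(item)


def _interval_overlaps(intervals: list[tuple[int, int]], start: int, end: int) -> bool:
    return any(s < end and start < e for s, e in intervals)


def genotype_panel(
    catalog: Sequence[RepeatLocus],
    alignments_by_line: Mapping[str, object],
    reference,
    *,
    min_flank: int = 3,
    min_reads: int = 2,
    require_unique: bool = True,
    exclude_regions_by_line: Mapping[str, Sequence[tuple[str, int, int]]] | None = None,
    keep_reads: bool = False,
) -> PanelResult:
    """Genotype every unflagged catalog locus in every line.

    ``alignments_by_line`` maps line id -> SAM/BAM path or iterable of
    reads.  ``exclude_regions_by_line`` marks per-line regions of residual
    heterozygosity; loci overlapping them are reported as ``excluded_het``.
    Deterministic given identical inputs.
    """
    loci = [l for l in catalog if not l.flags]
    line_ids = list(alignments_by_line)
    if len(set(line_ids)) != len(line_ids):
        raise ValueError("duplicate line ids")
    by_chrom: dict[str, list[RepeatLocus]] = {}
    for l in loci:
        by_chrom.setdefault(l.chrom, []).append(l)
    starts_by_chrom = {}
    for chrom, ls in by_chrom.items():
        ls.sort(key=lambda l: l.start)
        starts_by_chrom[chrom] = [l.start for l in ls]

    excl = exclude_regions_by_line or {}
    calls: dict[tuple[str, str], LocusCall] = {}
    scored_store: dict[tuple[str, str], list[ScoredRead]] = {} if keep_reads else None

    for line_id in line_ids:
        excluded: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in excl.get(line_id, []):
            excluded.setdefault(chrom, []).append((s, e))
        per_locus: dict[str, list[ScoredRead]] = {l.locus_id: [] for l in loci}
        for read in _reads_from_source(alignments_by_line[line_id]):
            ls = by_chrom.get(read.chrom)
            if not ls:
                continue
            lo, hi = read.reference_span
            if hi < lo:
                continue
            starts = starts_by_chrom[read.chrom]
            j = bisect_right(starts, hi) - 1
            # walk left over loci starting within the read span; only
            # spanning candidates are worth scoring
            while j >= 0:
                locus = ls[j]
                if locus.start - 1 < lo:
                    break
                if hi >= locus.end:
                    sr = score_read(
                        read,
                        locus,
                        reference,
                        min_flank=min_flank,
                        require_unique=require_unique,
                    )
                    per_locus[locus.locus_id].append(sr)
                j -= 1
        for locus in loci:
            key = (locus.locus_id, line_id)
            if locus.chrom in excluded and _interval_overlaps(
                excluded[locus.chrom], locus.start, locus.end
            ):
                calls[key] = LocusCall(
                    locus.locus_id, line_id, {}, 0, None, None, "excluded_het"
                )
            else:
                calls[key] = call_locus(
                    per_locus[locus.locus_id],
                    min_reads,
                    locus_id=locus.locus_id,
                    line_id=line_id,
                )
            if keep_reads:
                scored_store[key] = per_locus[locus.locus_id]

    locus_ids = [l.locus_id for l in loci]
    allele = pd.DataFrame(index=locus_ids, columns=line_ids, dtype=float)
    status = pd.DataFrame(index=locus_ids, columns=line_ids, dtype=object)
    for (lid, line_id), call in calls.items():
        allele.loc[lid, line_id] = (
            call.majority_allele if call.majority_allele is not None else np.nan
        )
        status.loc[lid, line_id] = call.status
    matrix = GenotypeMatrix(alleles=allele, status=status)
    return PanelResult(
        calls=calls,
        matrix=matrix,
        locus_ids=locus_ids,
        line_ids=line_ids,
        scored_reads=scored_store,
    )
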