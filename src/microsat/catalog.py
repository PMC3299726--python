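"""Microsatellite catalog construction and filtering.

A microsatellite (short tandem repeat, STR) is a tandem repetition of a
1-5 base unit.  This module builds a catalog of such loci on a reference
genome, either by parsing Tandem Repeats Finder ``.dat`` output or with a
native scan-line detector, and applies the exclusion filters used before
genotyping: proximity to larger repetitive elements (which confound unique
short-read mapping), heterochromatic sequence, and a minimum tract purity.

Coordinates are 0-based half-open throughout; the 1-based inclusive
conventions of the TRF and RepeatMasker dialects are converted on ingest.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

__all__ = [
    "RepeatLocus",
    "AnnotationInterval",
    "canonical_rotation",
    "find_tandem_repeats",
    "deduplicate_hits",
    "parse_trf_dat",
    "parse_repeatmasker_out",
    "filter_near_repetitive_elements",
    "exclude_heterochromatin",
    "default_het_chroms",
    "apply_purity_floor",
    "write_catalog_tsv",
    "read_catalog_tsv",
    "write_catalog_bed",
]

#: Detector score convention: a perfect tract of length L scores 2*L
#: (the first `unit_length` bases count as matches, then each base is
#: compared to the base one unit earlier at +2/-5).  With the minimum
#: score of 14 the shortest reportable perfect repeat is 7 bases for
#: every unit size.
MATCH_WEIGHT = 2
MISMATCH_PENALTY = 5
MIN_SCORE = 14
MAX_UNIT = 5
MIN_TRACT = 7

FLAG_RE_PROXIMAL = "re_proximal"
FLAG_HETEROCHROMATIC = "heterochromatic"
FLAG_LOW_PURITY = "low_purity"

_EXCLUDED_RM_CLASSES = ("Simple_repeat", "Low_complexity")


def canonical_rotation(unit: str) -> str:
    """Lexicographically minimal rotation of a repeat unit.

    Reverse-complement units are *not* merged: calls are made on the
    reference strand, so AC and GT remain distinct units.
    """
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


@dataclass
class RepeatLocus:
    """One cataloged microsatellite locus.

    ``purity`` is the fraction of tract bases consistent with a perfect
    repetition of the unit (comparison matches / (ref_length - unit_length));
    it is 1.0 iff the tract is perfect.  ``flags`` holds exclusion reasons;
    a locus carrying any flag is excluded from all downstream analyses.
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    unit: str
    unit_length: int
    purity: float
    ref_length: int
    score: float = 0.0
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.end - self.start != self.ref_length:
            raise ValueError(
                f"{self.locus_id}: ref_length {self.ref_length} != end-start"
            )
        if not (0.0 < self.purity <= 1.0):
            raise ValueError(f"{self.locus_id}: purity {self.purity} out of (0,1]")

    @property
    def excluded(self) -> bool:
        return bool(self.flags)


@dataclass(frozen=True)
class AnnotationInterval:
    """A repetitive-element annotation (e.g. a transposon hit)."""

    chrom: str
    start: int
    end: int
    repeat_class: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")


def _make_locus_id(chrom: str, start: int, end: int, unit: str) -> str:
    return f"{chrom}:{start}-{end}:{unit}"


# ---------------------------------------------------------------------------
# Native detector
# ---------------------------------------------------------------------------

def _maximal_scoring_segments(scores: Sequence[float]) -> list[tuple[int, int]]:
    """All maximal scoring subsequences (Ruzzo & Tompa), as [start, end) pairs."""
    segs: list[list[float]] = []  # [start, end, L, R] cumulative bounds
    out: list[tuple[int, int]] = []
    cum = 0.0
    for i, s in enumerate(scores):
        if s > 0:
            cand = [i, i + 1, cum, cum + s]
            while True:
                j = len(segs) - 1
                while j >= 0 and segs[j][2] >= cand[2]:
                    j -= 1
                if j < 0 or segs[j][3] >= cand[3]:
                    segs.append(cand)
                    break
                cand = [segs[j][0], cand[1], segs[j][2], cand[3]]
                del segs[j:]
        cum += s
    return [(int(a), int(b)) for a, b, _, _ in segs]


def _modal_unit(seq: str, start: int, end: int, u: int) -> str:
    """Most common full u-mer at unit-stride phase positions within the tract."""
    kmers = [seq[i : i + u] for i in range(start, end - u + 1, u)]
    if not kmers:
        kmers = [seq[start : start + u]]
    counts = Counter(kmers)
    top = max(counts.values())
    # tie-break toward the lexicographically smallest k-mer
    best = min(k for k, v in counts.items() if v == top)
    return canonical_rotation(best)


def find_tandem_repeats(
    seq: str,
    chrom: str,
    *,
    min_score: int = MIN_SCORE,
    max_unit: int = MAX_UNIT,
    dedup: bool = True,
) -> list[RepeatLocus]:
    """Detect tandem repeats of unit size 1..max_unit on one sequence.

    For each unit size u every base is compared to the base u positions
    earlier (+2 match / -5 mismatch, N always mismatches); Ruzzo-Tompa
    maximal scoring segments plus the leading unit form candidate tracts,
    reported when the total score (2*u + segment score) reaches
    ``min_score``.  No indels are modeled inside the tract.
    """
    seq = seq.upper()
    n = len(seq)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = (
        (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))
    )
    hits: list[RepeatLocus] = []
    for u in range(1, max_unit + 1):
        if n <= u:
            continue
        match = (arr[u:] == arr[:-u]) & valid[u:] & valid[:-u]
        scores = np.where(match, MATCH_WEIGHT, -MISMATCH_PENALTY).astype(np.int64)
        match_cum = np.concatenate([[0], np.cumsum(match)])
        for a, b in _maximal_scoring_segments(scores):
            m = int(match_cum[b] - match_cum[a])
            mm = (b - a) - m
            total = MATCH_WEIGHT * (u + m) - MISMATCH_PENALTY * mm
            if total < min_score:
                continue
            start = a  # comparison index a is sequence position a+u; tract starts u earlier
            end = b + u
            ref_length = end - start
            purity = m / (ref_length - u)
            unit = _modal_unit(seq, start, end, u)
            hits.append(
                RepeatLocus(
                    locus_id=_make_locus_id(chrom, start, end, unit),
                    chrom=chrom,
                    start=start,
                    end=end,
                    unit=unit,
                    unit_length=u,
                    purity=purity,
                    ref_length=ref_length,
                    score=float(total),
                )
            )
    return deduplicate_hits(hits) if dedup else hits


def deduplicate_hits(hits: Iterable[RepeatLocus]) -> list[RepeatLocus]:
    """Reduce redundant detector hits on one chromosome.

    Two hits conflict when they overlap and share the same canonical unit,
    or when one interval contains the other (any units).  Hits are accepted
    greedily in priority order (score, then length, then leftmost start,
    then smaller unit, then unit string); a candidate conflicting with an
    already accepted hit is dropped.  Output sorted by (start, end).
    """
    ranked = sorted(
        hits,
        key=lambda h: (-h.score, -(h.end - h.start), h.start, h.unit_length, h.unit),
    )
    accepted: list[RepeatLocus] = []
    for cand in ranked:
        ok = True
        for keep in accepted:
            if cand.start >= keep.end or cand.end <= keep.start:
                continue
            contained = (keep.start <= cand.start and cand.end <= keep.end) or (
                cand.start <= keep.start and keep.end <= cand.end
            )
            if contained or cand.unit == keep.unit:
                ok = False
                break
        if ok:
            accepted.append(cand)
    return sorted(accepted, key=lambda h: (h.start, h.end))


# ---------------------------------------------------------------------------
# TRF .dat parsing
# ---------------------------------------------------------------------------

def parse_trf_dat(
    stream: TextIO | str,
    chrom_names: Mapping[str, str] | None = None,
    *,
    max_unit: int = MAX_UNIT,
) -> list[RepeatLocus]:
    """Parse Tandem Repeats Finder ``.dat`` output into catalog loci.

    TRF reports 1-based inclusive coordinates; these are converted to
    0-based half-open.  Purity is TRF's percent-matches column / 100.
    Records whose period or consensus size exceeds ``max_unit`` are dropped.

    ``chrom_names`` optionally maps ``Sequence:`` headers to catalog
    chromosome names; with a map supplied, an unlisted header is an error.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    loci: list[RepeatLocus] = []
    chrom: str | None = None
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("Sequence:"):
            name = line.split(None, 1)[1].split()[0]
            if chrom_names is not None:
                if name not in chrom_names:
                    raise ValueError(f"line {lineno}: unknown sequence header {name!r}")
                name = chrom_names[name]
            chrom = name
            continue
        fields = line.split()
        if not fields[0][0].isdigit():
            # TRF banner / Parameters / Version preamble
            continue
        if chrom is None:
            raise ValueError(f"line {lineno}: repeat record before any Sequence header")
        if len(fields) < 14:
            raise ValueError(
                f"line {lineno}: malformed TRF record ({len(fields)} fields, need >= 14)"
            )
        try:
            start1 = int(fields[0])
            end1 = int(fields[1])
            period = int(fields[2])
            cons_size = int(fields[4])
            pct_match = float(fields[5])
            score = float(fields[7])
            consensus = fields[13].upper()
        except ValueError as exc:
            raise ValueError(f"line {lineno}: malformed TRF record: {exc}") from None
        if period > max_unit or cons_size > max_unit:
            continue
        start, end = start1 - 1, end1
        unit = canonical_rotation(consensus)
        loci.append(
            RepeatLocus(
                locus_id=_make_locus_id(chrom, start, end, unit),
                chrom=chrom,
                start=start,
                end=end,
                unit=unit,
                unit_length=len(unit),
                purity=pct_match / 100.0,
                ref_length=end - start,
                score=score,
            )
        )
    return loci


# ---------------------------------------------------------------------------
# RepeatMasker / BED annotations
# ---------------------------------------------------------------------------

def parse_repeatmasker_out(
    stream: TextIO | str,
    *,
    drop_classes: Sequence[str] = _EXCLUDED_RM_CLASSES,
) -> list[AnnotationInterval]:
    """Parse repetitive-element annotations (RepeatMasker ``.out`` or BED3+class).

    ``Simple_repeat`` and ``Low_complexity`` hits are removed (those are
    microsatellites themselves, not mapping hazards).  RepeatMasker's
    1-based inclusive coordinates are converted to 0-based half-open; BED
    input is taken as already 0-based.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out: list[AnnotationInterval] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split()
        first = fields[0]
        if first in ("SW", "score") or first.startswith("There"):
            continue  # .out header lines
        if first.lstrip("+-").isdigit():
            # RepeatMasker row: score div del ins query begin end left strand name class ...
            if len(fields) < 11:
                raise ValueError(
                    f"line {lineno}: malformed RepeatMasker row "
                    f"({len(fields)} fields, need >= 11)"
                )
            chrom = fields[4]
            try:
                begin1, end1 = int(fields[5]), int(fields[6])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: malformed coordinates: {exc}") from None
            repeat_class = fields[10]
            start, end = begin1 - 1, end1
        else:
            # BED3 + class column
            if len(fields) < 4:
                raise ValueError(
                    f"line {lineno}: malformed BED row ({len(fields)} fields, need >= 4)"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: malformed coordinates: {exc}") from None
            repeat_class = fields[3]
        if any(repeat_class.startswith(c) for c in drop_classes):
            continue
        out.append(AnnotationInterval(chrom, start, end, repeat_class))
    return out


# ---------------------------------------------------------------------------
# Filters (each adds a flag; flagged loci are excluded downstream)
# ---------------------------------------------------------------------------

def filter_near_repetitive_elements(
    loci: list[RepeatLocus],
    res: Iterable[AnnotationInterval],
    distance: int = 20,
) -> list[RepeatLocus]:
    """Flag loci within ``distance`` bases of (or overlapping) an annotation.

    The gap is measured between closest interval edges; gap <= distance
    triggers the ``re_proximal`` flag (overlap counts as gap 0).
    """
    by_chrom: dict[str, list[AnnotationInterval]] = {}
    for iv in res:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for ivs in by_chrom.values():
        ivs.sort(key=lambda iv: iv.start)
    for locus in loci:
        ivs = by_chrom.get(locus.chrom)
        if not ivs:
            continue
        for iv in ivs:
            if iv.end <= locus.start:
                gap = locus.start - iv.end
            elif locus.end <= iv.start:
                gap = iv.start - locus.end
            else:
                gap = 0
            if gap <= distance:
                locus.flags.add(FLAG_RE_PROXIMAL)
                break
    return loci


def default_het_chroms(chrom_names: Iterable[str]) -> set[str]:
    """Heterochromatic sequence names under the fly r5 naming scheme.

    Arms ending in "Het" plus the unscaffolded bin "U"; unique read mapping
    is unreliable there.
    """
    return {c for c in chrom_names if c.endswith("Het") or c == "U"}


def exclude_heterochromatin(
    loci: list[RepeatLocus], het_chrom_names: Iterable[str]
) -> list[RepeatLocus]:
    """Flag loci on heterochromatic / unscaffolded chromosomes."""
    het = set(het_chrom_names)
    for locus in loci:
        if locus.chrom in het:
            locus.flags.add(FLAG_HETEROCHROMATIC)
    return loci


def apply_purity_floor(
    loci: list[RepeatLocus], min_purity: float = 0.80
) -> list[RepeatLocus]:
    """Flag loci whose tract purity falls below ``min_purity`` (inclusive keep)."""
    for locus in loci:
        if locus.purity < min_purity:
            locus.flags.add(FLAG_LOW_PURITY)
    return loci


# ---------------------------------------------------------------------------
# Catalog I/O
# ---------------------------------------------------------------------------

_CATALOG_COLUMNS = [
    "locus_id",
    "chrom",
    "start",
    "end",
    "unit",
    "unit_length",
    "purity",
    "ref_length",
    "score",
    "flags",
]


def catalog_to_frame(loci: Iterable[RepeatLocus]) -> pd.DataFrame:
    rows = [
        (
            l.locus_id,
            l.chrom,
            l.start,
            l.end,
            l.unit,
            l.unit_length,
            l.purity,
            l.ref_length,
            l.score,
            ",".join(sorted(l.flags)) if l.flags else ".",
        )
        for l in loci
    ]
    return pd.DataFrame(rows, columns=_CATALOG_COLUMNS)


def write_catalog_tsv(loci: Iterable[RepeatLocus], path) -> None:
    catalog_to_frame(loci).to_csv(path, sep="\t", index=False)


def read_catalog_tsv(path) -> list[RepeatLocus]:
    df = pd.read_csv(path, sep="\t", dtype={"flags": str, "unit": str, "chrom": str})
    loci = []
    for row in df.itertuples(index=False):
        flags = set() if row.flags in (".", "", None) else set(str(row.flags).split(","))
        loci.append(
            RepeatLocus(
                locus_id=str(row.locus_id),
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                unit=str(row.unit),
                unit_length=int(row.unit_length),
                purity=float(row.purity),
                ref_length=int(row.ref_length),
                score=float(row.score),
                flags=flags,
            )
        )
    return loci


def write_catalog_bed(loci: Iterable[RepeatLocus], path) -> None:
    """BED6: name carries locus id, score column carries the detector score."""
    with open(path, "w") as fh:
        for l in loci:
            fh.write(
                f"{l.chrom}\t{l.start}\t{l.end}\t{l.locus_id}\t{int(l.score)}\t+\n"
            )
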