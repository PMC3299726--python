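"""Ground-truthed synthetic data for every stage of the pipeline.

The generator emulates the study design the analyses assume: a
multi-chromosome reference with planted perfect and imperfect repeats of
unit size 1-5, a panel of fully homozygous inbred lines whose repeat
alleles evolved by (mostly) whole-unit stepwise mutation with intensity
increasing in tract length and purity and decreasing in unit size, and
short reads emitted *pre-aligned* to the reference coordinate system --
simulating the output of the mapping step, not the mapper itself, which
keeps tests hermetic and deterministic.

Reads carry CIGARs reflecting each line's allele-length difference, with
the indel placed at a random position inside the tract so that downstream
gap-invariance can be exercised.  Error processes available: i.i.d. or
position-ramped substitution errors, +/-1-unit slippage concentrated in
homopolymer tracts, and a controllable fraction of reads reassigned to a
similar locus with degraded MapQ (mismapping; flank mismatches arise
naturally).

Everything is a deterministic function of the config seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import RepeatLocus, canonical_rotation

__all__ = [
    "MutationModel",
    "ReadModel",
    "SimConfig",
    "ReferenceSim",
    "SimResult",
    "simulate_reference",
    "simulate_panel",
    "simulate_reads",
    "simulate_all",
    "sim_reads_to_views",
    "write_sam",
    "write_fixtures",
    "spannable",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_GUARD = 10  # repeat-breaking bases enforced on each side of a planted tract

# SAM CIGAR op codes
_OP_M, _OP_I, _OP_D, _OP_S = 0, 1, 2, 4


@dataclass
class MutationModel:
    """Stepwise mutation model for the inbred panel.

    Per (locus, line) the number of mutation steps is Poisson with rate
    ``intensity * ref_length * purity / unit_length`` (variability rising
    with tract length and purity, falling with unit size).  Each step is a
    whole-unit +/-1 insertion/deletion with probability
    ``whole_unit_fraction``, otherwise a 1-2 base non-unit event.  With
    ``phase_threshold_by_unit`` set, loci shorter than the threshold for
    their unit mutate only by non-unit events and loci at or above it only
    by whole units (a switch-on length for true slippage).
    """

    intensity: float = 0.01
    whole_unit_fraction: float = 0.9
    phase_threshold_by_unit: dict[int, int] | None = None


@dataclass
class ReadModel:
    read_lengths: tuple[int, ...] = (75,)
    coverage: float = 20.0
    substitution_rate: float = 0.002
    ramp_errors: bool = False  # error rate rising linearly along the read
    slippage_rate: float = 0.02  # per homopolymer traversal, +/-1 base
    mismap_fraction: float = 0.01
    nonunique_fraction: float = 0.0


@dataclass
class SimConfig:
    seed: int = 0
    n_chromosomes: int = 3
    n_loci_per_unit: int = 40
    n_lines: int = 20
    length_min: int = 7
    length_max: int = 60
    length_distribution: str = "geometric"  # or "uniform"
    length_geom_p: float = 0.16  # median ~11 bases, ~90% below 23
    perfect_fraction: float = 0.85
    mutation: MutationModel = field(default_factory=MutationModel)
    reads: ReadModel = field(default_factory=ReadModel)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ReferenceSim:
    """Reference sequences plus the planted-locus truth catalog."""

    sequences: dict[str, str]
    loci: list[RepeatLocus]
    config: SimConfig

    def loci_by_chrom(self) -> dict[str, list[RepeatLocus]]:
        out: dict[str, list[RepeatLocus]] = {}
        for l in self.loci:
            out.setdefault(l.chrom, []).append(l)
        for ls in out.values():
            ls.sort(key=lambda l: l.start)
        return out


@dataclass
class SimRead:
    name: str
    chrom: str
    pos: int
    cigar: list[tuple[int, int]]
    seq: str
    mapq: int
    unique: bool
    origin_locus: str | None
    mismapped: bool
    slipped: int  # signed base change injected by slippage (0 if none)

    def cigar_string(self) -> str:
        codes = {_OP_M: "M", _OP_I: "I", _OP_D: "D", _OP_S: "S"}
        return "".join(f"{n}{codes[op]}" for op, n in self.cigar)


@dataclass
class SimResult:
    reference: ReferenceSim
    panel: pd.DataFrame  # locus_id x line_id true allele lengths (bases)
    reads_by_line: dict[str, list[SimRead]]
    read_truth: pd.DataFrame
    config: SimConfig


def spannable(locus: RepeatLocus, read_length: int) -> bool:
    """Can a read of this length cover the tract plus both anchor bases?"""
    return locus.ref_length + 2 <= read_length


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------

def _random_primitive_unit(rng: np.random.Generator, u: int) -> str:
    while True:
        unit = "".join(chr(b) for b in rng.choice(_BASES, size=u))
        if all(
            unit != unit[:d] * (u // d) for d in range(1, u) if u % d == 0
        ):
            return unit


def _has_shorter_full_period(tract: str, u: int) -> bool:
    """Does the tract as a whole also repeat at some period below u?

    Short tracts of a primitive unit can still carry a second full period
    (e.g. a 7-base penta tract that is also period 4); such plants would be
    ambiguous, so the generator rejects them.
    """
    return any(
        all(tract[i] == tract[i - d] for i in range(d, len(tract)))
        for d in range(1, u)
    )


def _guard_base(rng: np.random.Generator, forbidden_priority: list[str]) -> str:
    """A flank base avoiding repeat extension at nearby offsets.

    At most two bases are forbidden (the planted unit's offset and the
    adjacent base): excluding more would force a deterministic -- and
    itself periodic -- guard.  Residual matches at other offsets are
    handled by the verification pass.
    """
    forbidden: list[str] = []
    for b in forbidden_priority:
        if b not in forbidden:
            forbidden.append(b)
        if len(forbidden) == 2:
            break
    choices = [c for c in "ACGT" if c not in forbidden]
    return choices[int(rng.integers(0, len(choices)))]


def _sample_length(rng: np.random.Generator, cfg: SimConfig, u: int) -> int:
    lo = max(cfg.length_min, u + 2)
    if cfg.length_distribution == "uniform":
        return int(rng.integers(lo, cfg.length_max + 1))
    L = cfg.length_min + int(rng.geometric(cfg.length_geom_p)) - 1
    return int(min(max(L, lo), cfg.length_max))


def _tract_stats(tract: str, u: int) -> tuple[int, float, float]:
    m = sum(1 for i in range(u, len(tract)) if tract[i] == tract[i - u])
    mm = (len(tract) - u) - m
    purity = m / (len(tract) - u)
    score = 2.0 * (u + m) - 5.0 * mm
    return m, purity, score


def simulate_reference(
    config: SimConfig,
    *,
    rng: np.random.Generator | None = None,
    loci_spec: Sequence[tuple[int, int, int]] | None = None,
) -> ReferenceSim:
    """Build reference chromosomes with planted repeats and exact truth.

    Planted tracts are separated by at least twice the longest read length
    of unique flank, and a short guard zone of repeat-breaking bases is
    enforced at each boundary so the planted coordinates are exactly
    recoverable by the detector.

    ``loci_spec`` optionally fixes the planted loci as (unit_size, length,
    n_interruptions) triples, overriding the config's sampling.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    spacing = max(150, 2 * max(config.reads.read_lengths))

    if loci_spec is None:
        spec: list[tuple[int, int, int]] = []
        for u in range(1, 6):
            for _ in range(config.n_loci_per_unit):
                L = _sample_length(rng, config, u)
                n_int = 0
                if (
                    L >= 28
                    and u + 8 < L - u - 9
                    and rng.random() > config.perfect_fraction
                ):
                    n_int = int(rng.integers(1, 3))
                spec.append((u, L, n_int))
    else:
        spec = list(loci_spec)
    order = rng.permutation(len(spec))
    per_chrom: list[list[tuple[int, int, int]]] = [
        [] for _ in range(config.n_chromosomes)
    ]
    for k, idx in enumerate(order):
        per_chrom[k % config.n_chromosomes].append(spec[idx])

    sequences: dict[str, str] = {}
    loci: list[RepeatLocus] = []
    for ci, chrom_spec in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        chars: list[str] = []
        chrom_loci: list[tuple[int, int, str, int, float, float]] = []
        for u, L, n_int in chrom_spec:
            flank_len = spacing + int(rng.integers(0, 25))
            chars.extend(chr(b) for b in rng.choice(_BASES, size=flank_len))
            while True:
                unit = _random_primitive_unit(rng, u)
                tract = list((unit * (L // u + 2))[:L])
                if not _has_shorter_full_period("".join(tract), u):
                    break
            if n_int:
                cand = list(range(u + 8, L - u - 9))
                for ip in rng.choice(cand, size=min(n_int, len(cand)), replace=False):
                    alts = [b for b in "ACGT" if b != tract[ip]]
                    tract[ip] = alts[int(rng.integers(0, 3))]
            start = len(chars)
            chars.extend(tract)
            end = len(chars)
            _redraw_guards(chars, start, end, u, rng)
            # right guard bases become the head of the next flank
            for j in range(end, end + _GUARD):
                prio = [chars[j - d] for d in (u, 1) if j - d >= 0]
                chars.append(_guard_base(rng, prio))
            m, purity, score = _tract_stats("".join(tract), u)
            chrom_loci.append((start, end, unit, u, purity, score))
        tail_len = spacing + int(rng.integers(0, 25))
        chars.extend(chr(b) for b in rng.choice(_BASES, size=tail_len))
        # verification pass: perfect plants must be exactly recoverable by
        # the detector; redraw guard bases until they are
        for start, end, unit, u, purity, score in chrom_loci:
            if purity < 1.0:
                continue
            tries = 0
            while not _locus_recovered(chars, start, end) and tries < 40:
                _redraw_guards(chars, start, end, u, rng, redraw_right=True)
                tries += 1
            if tries >= 40:
                raise RuntimeError(
                    f"could not isolate planted repeat at {chrom}:{start}-{end}"
                )
        seq = "".join(chars)
        sequences[chrom] = seq
        for start, end, unit, u, purity, score in chrom_loci:
            unit_c = canonical_rotation(unit)
            loci.append(
                RepeatLocus(
                    locus_id=f"{chrom}:{start}-{end}:{unit_c}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    unit=unit_c,
                    unit_length=u,
                    purity=purity,
                    ref_length=end - start,
                    score=score,
                )
            )
    return ReferenceSim(sequences=sequences, loci=loci, config=config)


def _redraw_guards(
    chars: list[str],
    start: int,
    end: int,
    u: int,
    rng: np.random.Generator,
    *,
    redraw_right: bool = False,
) -> None:
    """(Re)draw the guard bases flanking a planted tract in place.

    Left guard bases are processed outward (each constrained against the
    final bases to its right); the right guard is only redrawn during
    verification, when its bases already exist.
    """
    for j in range(start - 1, max(start - _GUARD, 0) - 1, -1):
        prio = [chars[j + d] for d in (u, 1) if j + d < len(chars)]
        chars[j] = _guard_base(rng, prio)
    if redraw_right:
        for j in range(end, min(end + _GUARD, len(chars))):
            prio = [chars[j - d] for d in (u, 1) if j - d >= 0]
            chars[j] = _guard_base(rng, prio)


def _locus_recovered(chars: list[str], start: int, end: int, margin: int = 45) -> bool:
    """Does the detector report exactly [start, end) in a local window?"""
    from .catalog import find_tandem_repeats

    lo = max(0, start - margin)
    hi = min(len(chars), end + margin)
    window = "".join(chars[lo:hi])
    hits = find_tandem_repeats(window, "w")
    return any(h.start == start - lo and h.end == end - lo for h in hits)


# ---------------------------------------------------------------------------
# Panel evolution (stepwise mutation)
# ---------------------------------------------------------------------------

def _nonunit_step(rng: np.random.Generator, u: int) -> int:
    """A 1-2 base step that is not a whole-unit multiple."""
    if u <= 2:
        mag = 1
    else:
        mag = int(rng.integers(1, 3))
    return mag if rng.random() < 0.5 else -mag


def simulate_panel(
    reference: ReferenceSim,
    config: SimConfig | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Evolve per-line allele lengths from the reference by stepwise mutation.

    Returns a loci x lines table of true allele lengths in bases.
    """
    config = reference.config if config is None else config
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    mm = config.mutation
    line_ids = [f"line{i:02d}" for i in range(config.n_lines)]
    data = {}
    for locus in reference.loci:
        lam = mm.intensity * locus.ref_length * locus.purity / locus.unit_length
        n_steps = rng.poisson(lam, size=config.n_lines)
        alleles = np.full(config.n_lines, locus.ref_length, dtype=int)
        thr = None
        if mm.phase_threshold_by_unit is not None:
            thr = mm.phase_threshold_by_unit.get(locus.unit_length)
        for i in np.nonzero(n_steps)[0]:
            length = locus.ref_length
            for _ in range(int(n_steps[i])):
                if locus.unit_length == 1:
                    whole = True
                elif thr is not None:
                    whole = locus.ref_length >= thr
                else:
                    whole = rng.random() < mm.whole_unit_fraction
                if whole:
                    step = locus.unit_length if rng.random() < 0.5 else -locus.unit_length
                else:
                    step = _nonunit_step(rng, locus.unit_length)
                # a contraction below one unit would destroy the locus;
                # such steps do not occur
                if length + step >= locus.unit_length:
                    length += step
            alleles[i] = length
        data[locus.locus_id] = alleles
    panel = pd.DataFrame.from_dict(data, orient="index", columns=line_ids)
    panel.index.name = "locus_id"
    return panel


def _allele_sequence(ref_tract: str, u: int, allele_len: int) -> str:
    """Mutated tract sequence of the requested length.

    Whole units (copies of the leading unit) are inserted at a mid-tract
    phase boundary; deletions remove a mid-tract block.  Non-unit length
    differences insert/delete partial units the same way.
    """
    t = len(ref_tract)
    if allele_len == t:
        return ref_tract
    if allele_len > t:
        d = allele_len - t
        ip = (t // (2 * u)) * u
        motif = ref_tract[:u]
        ins = (motif * (d // u + 2))[:d]
        return ref_tract[:ip] + ins + ref_tract[ip:]
    d = t - allele_len
    dp = max(0, (t - d) // 2)
    return ref_tract[:dp] + ref_tract[dp + d :]


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass
class _Segment:
    line_start: int
    length: int  # length on the line's chromosome
    kind: str  # "flank" | "locus"
    ref_start: int
    ref_len: int
    locus: RepeatLocus | None = None
    allele_seq: str | None = None


def _line_layout(
    reference: ReferenceSim,
    chrom: str,
    chrom_loci: list[RepeatLocus],
    alleles: Mapping[str, int],
) -> list[_Segment]:
    seq = reference.sequences[chrom]
    segs: list[_Segment] = []
    pos_line = 0
    pos_ref = 0
    for locus in chrom_loci:
        if locus.start > pos_ref:
            flen = locus.start - pos_ref
            segs.append(_Segment(pos_line, flen, "flank", pos_ref, flen))
            pos_line += flen
        a = int(alleles[locus.locus_id])
        aseq = _allele_sequence(
            seq[locus.start : locus.end], locus.unit_length, a
        )
        segs.append(
            _Segment(pos_line, a, "locus", locus.start, locus.ref_length, locus, aseq)
        )
        pos_line += a
        pos_ref = locus.end
    if pos_ref < len(seq):
        flen = len(seq) - pos_ref
        segs.append(_Segment(pos_line, flen, "flank", pos_ref, flen))
        pos_line += flen
    return segs


def _walk_read(
    segments: list[_Segment],
    seg_idx: int,
    ref_seq: str,
    p: int,
    rl: int,
    rng: np.random.Generator,
    override: tuple[int, str] | None,
) -> tuple[int, list[tuple[int, int]], str]:
    """Extract one read's alignment starting at line coordinate ``p``.

    ``override`` = (segment index, replacement allele sequence) applies a
    per-read slippage to one locus segment.  Returns (reference start,
    cigar ops, sequence).
    """
    ops: list[tuple[int, int]] = []
    seq_parts: list[str] = []
    ref_start: int | None = None
    remaining = rl
    entered = False  # read began in an earlier segment

    def push(op: int, n: int) -> None:
        if n <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    i = seg_idx
    while remaining > 0 and i < len(segments):
        seg = segments[i]
        if seg.kind == "locus" and override is not None and override[0] == i:
            content = override[1]
        elif seg.kind == "locus":
            content = seg.allele_seq
        else:
            content = None
        eff_len = len(content) if content is not None else seg.length
        o = 0 if entered else p - seg.line_start
        take = min(remaining, eff_len - o)
        if take <= 0:
            i += 1
            entered = True
            continue
        if seg.kind == "flank":
            if ref_start is None:
                ref_start = seg.ref_start + o
            push(_OP_M, take)
            seq_parts.append(ref_seq[seg.ref_start + o : seg.ref_start + o + take])
        else:
            t = seg.ref_len
            a = eff_len
            full = entered and o == 0 and take == a and remaining > take
            if full:
                d = a - t
                if d == 0:
                    push(_OP_M, a)
                elif d > 0:
                    g = int(rng.integers(0, t + 1))
                    push(_OP_M, g)
                    push(_OP_I, d)
                    push(_OP_M, t - g)
                else:
                    g = int(rng.integers(0, a + 1))
                    push(_OP_M, g)
                    push(_OP_D, -d)
                    push(_OP_M, a - g)
            else:
                ro = min(o, t)
                m = min(take, t - ro)
                if ref_start is None and m > 0:
                    ref_start = seg.ref_start + ro
                if ref_start is None:
                    push(_OP_S, take - m)  # read starts inside inserted bases
                else:
                    if m > 0:
                        push(_OP_M, m)
                    over = take - m
                    if remaining > take:
                        # read continues: reconcile reference consumption
                        push(_OP_I, over)
                        push(_OP_D, (t - ro) - m)
                    else:
                        push(_OP_I, over)
            seq_parts.append(content[o : o + take])
        remaining -= take
        i += 1
        entered = True
    seq = "".join(seq_parts)
    if ref_start is None:
        ref_start = segments[seg_idx].ref_start
    return ref_start, ops, seq


def _apply_substitutions(
    seq: str, rate: float, ramp: bool, rng: np.random.Generator
) -> str:
    if rate <= 0:
        return seq
    n = len(seq)
    if ramp:
        w = 1.0 + 3.0 * np.arange(n) / max(n - 1, 1)
        probs = w / w.sum()
        k = rng.binomial(n, rate * 2.0)  # ramp mean ~2x base rate at read end
        if k == 0:
            return seq
        idx = rng.choice(n, size=min(k, n), replace=False, p=probs)
    else:
        k = rng.binomial(n, rate)
        if k == 0:
            return seq
        idx = rng.choice(n, size=k, replace=False)
    out = list(seq)
    for i in idx:
        alts = [b for b in "ACGT" if b != out[i]]
        out[i] = alts[int(rng.integers(0, 3))]
    return "".join(out)


def simulate_reads(
    reference: ReferenceSim,
    panel: pd.DataFrame,
    config: SimConfig | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[SimRead]], pd.DataFrame]:
    """Draw reads uniformly along each line's chromosomes, pre-aligned.

    Returns (reads by line, per-read truth table).
    """
    config = reference.config if config is None else config
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    rm = config.reads
    by_chrom = reference.loci_by_chrom()
    mean_rl = float(np.mean(rm.read_lengths))

    # partner loci for the mismap model: same unit size, different locus
    partners: dict[int, list[RepeatLocus]] = {}
    for l in reference.loci:
        partners.setdefault(l.unit_length, []).append(l)

    reads_by_line: dict[str, list[SimRead]] = {}
    truth_rows = []
    for line_id in panel.columns:
        alleles = panel[line_id]
        out: list[SimRead] = []
        ridx = 0
        for chrom, chrom_loci in sorted(by_chrom.items()):
            ref_seq = reference.sequences[chrom]
            segments = _line_layout(reference, chrom, chrom_loci, alleles)
            line_len = segments[-1].line_start + segments[-1].length
            seg_starts = [s.line_start for s in segments]
            n_reads = int(round(rm.coverage * line_len / mean_rl))
            for _ in range(n_reads):
                rl = int(rm.read_lengths[int(rng.integers(0, len(rm.read_lengths)))])
                if rl >= line_len:
                    continue
                p = int(rng.integers(0, line_len - rl + 1))
                # locate the first segment containing p
                si = bisect_right(seg_starts, p) - 1
                # which locus does this read touch (spacing allows at most one)?
                origin: RepeatLocus | None = None
                full_cover = False
                for j in (si, si + 1, si + 2):
                    if 0 <= j < len(segments) and segments[j].kind == "locus":
                        seg = segments[j]
                        if p < seg.line_start + seg.length and p + rl > seg.line_start:
                            origin = seg.locus
                            full_cover = (
                                p < seg.line_start
                                and p + rl > seg.line_start + seg.length
                            )
                            origin_idx = j
                            break
                override = None
                slipped = 0
                if (
                    origin is not None
                    and full_cover
                    and origin.unit_length == 1
                    and rm.slippage_rate > 0
                    and rng.random() < rm.slippage_rate
                ):
                    a = len(segments[origin_idx].allele_seq)
                    slipped = 1 if rng.random() < 0.5 else -1
                    a_eff = max(1, a + slipped)
                    slipped = a_eff - a
                    override = (
                        origin_idx,
                        _allele_sequence(
                            ref_seq[origin.start : origin.end], 1, a_eff
                        ),
                    )
                ref_start, ops, seq = _walk_read(
                    segments, si, ref_seq, p, rl, rng, override
                )
                chrom_out = chrom
                mapq = 60
                unique = True
                mismapped = False
                if (
                    origin is not None
                    and rm.mismap_fraction > 0
                    and rng.random() < rm.mismap_fraction
                ):
                    cands = [
                        x
                        for x in partners[origin.unit_length]
                        if x.locus_id != origin.locus_id
                    ]
                    if cands:
                        target = cands[int(rng.integers(0, len(cands)))]
                        new_pos = target.start + (ref_start - origin.start)
                        tlen = len(reference.sequences[target.chrom])
                        if 0 <= new_pos and new_pos + rl <= tlen:
                            chrom_out = target.chrom
                            ref_start = new_pos
                            ops = [(_OP_M, rl)]
                            mapq = int(rng.integers(10, 31))
                            mismapped = True
                if (
                    not mismapped
                    and rm.nonunique_fraction > 0
                    and rng.random() < rm.nonunique_fraction
                ):
                    unique = False
                seq = _apply_substitutions(
                    seq, rm.substitution_rate, rm.ramp_errors, rng
                )
                name = f"{line_id}_{chrom}_{ridx}"
                ridx += 1
                out.append(
                    SimRead(
                        name=name,
                        chrom=chrom_out,
                        pos=ref_start,
                        cigar=ops,
                        seq=seq,
                        mapq=mapq,
                        unique=unique,
                        origin_locus=origin.locus_id if origin else None,
                        mismapped=mismapped,
                        slipped=slipped,
                    )
                )
                truth_rows.append(
                    (
                        name,
                        line_id,
                        chrom,
                        origin.locus_id if origin else "",
                        mismapped,
                        slipped,
                    )
                )
        reads_by_line[line_id] = out
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_name", "line_id", "chrom", "origin_locus", "mismapped", "slipped"],
    )
    return reads_by_line, truth


def simulate_all(config: SimConfig) -> SimResult:
    """Reference -> panel -> reads, all from the config seed."""
    reference = simulate_reference(config)
    panel = simulate_panel(reference)
    reads_by_line, truth = simulate_reads(reference, panel)
    return SimResult(
        reference=reference,
        panel=panel,
        reads_by_line=reads_by_line,
        read_truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def sim_reads_to_views(reads: Iterable[SimRead]):
    """Convert simulated reads to alignment views without a SAM round-trip."""
    from .genotyper import AlignedReadView

    return [
        AlignedReadView.from_cigar(
            r.name,
            r.chrom,
            r.pos,
            r.cigar_string(),
            r.seq,
            mapq=r.mapq,
            unique=r.unique,
        )
        for r in reads
    ]


def _sam_header(reference: ReferenceSim):
    import pysam

    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": c, "LN": len(s)} for c, s in sorted(reference.sequences.items())
            ],
        }
    )


def write_sam(reads: Iterable[SimRead], reference: ReferenceSim, path) -> None:
    import pysam

    header = _sam_header(reference)
    names = list(header.references)
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for r in reads:
            a = pysam.AlignedSegment(header)
            a.query_name = r.name
            a.flag = 0
            a.reference_id = names.index(r.chrom)
            a.reference_start = r.pos
            a.mapping_quality = r.mapq
            a.cigartuples = r.cigar
            a.query_sequence = r.seq
            if not r.unique:
                a.set_tag("XA", "alt")
            fh.write(a)


def _write_fasta(sequences: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sequences):
            fh.write(f">{chrom}\n")
            s = sequences[chrom]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_fixtures(sim: SimResult, out_dir) -> dict:
    """Write FASTA, per-line SAM, catalog TSV/BED, truth tables and a manifest.

    The manifest records the config, seed and a content hash of every file,
    so identical configs produce identical manifests.
    """
    from .catalog import write_catalog_bed, write_catalog_tsv

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    fa = os.path.join(out_dir, "reference.fa")
    _write_fasta(sim.reference.sequences, fa)
    paths["reference"] = fa
    cat_tsv = os.path.join(out_dir, "catalog.tsv")
    write_catalog_tsv(sim.reference.loci, cat_tsv)
    paths["catalog_tsv"] = cat_tsv
    cat_bed = os.path.join(out_dir, "catalog.bed")
    write_catalog_bed(sim.reference.loci, cat_bed)
    paths["catalog_bed"] = cat_bed
    alleles = os.path.join(out_dir, "true_alleles.tsv")
    sim.panel.to_csv(alleles, sep="\t")
    paths["true_alleles"] = alleles
    truth = os.path.join(out_dir, "read_truth.tsv")
    sim.read_truth.to_csv(truth, sep="\t", index=False)
    paths["read_truth"] = truth
    for line_id, reads in sim.reads_by_line.items():
        sam = os.path.join(out_dir, f"{line_id}.sam")
        write_sam(reads, sim.reference, sam)
        paths[f"sam_{line_id}"] = sam
    hashes = {}
    for key, p in sorted(paths.items()):
        with open(p, "rb") as fh:
            hashes[key] = hashlib.sha256(fh.read()).hexdigest()
    manifest = {
        "config": sim.config.to_dict(),
        "seed": sim.config.seed,
        "files": {k: os.path.basename(v) for k, v in paths.items()},
        "sha256": hashes,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
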