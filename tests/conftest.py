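"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from microsat.catalog import RepeatLocus
from microsat.genotyper import AlignedReadView


def mk_locus(
    chrom="chr1",
    start=100,
    end=114,
    unit="AC",
    purity=1.0,
    score=None,
    flags=(),
) -> RepeatLocus:
    if score is None:
        score = 2.0 * (end - start)
    return RepeatLocus(
        locus_id=f"{chrom}:{start}-{end}:{unit}",
        chrom=chrom,
        start=start,
        end=end,
        unit=unit,
        unit_length=len(unit),
        purity=purity,
        ref_length=end - start,
        score=score,
        flags=set(flags),
    )


def mk_read(chrom, pos, cigar, seq, name="r1", mapq=60, unique=True) -> AlignedReadView:
    return AlignedReadView.from_cigar(
        name, chrom, pos, cigar, seq, mapq=mapq, unique=unique
    )


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def reference_with_tract(
    rng, unit="AC", tract_len=14, left=60, right=60, chrom="chr1"
):
    """A single-chromosome reference holding one perfect repeat.

    Flank bases adjacent to the tract are redrawn so that they cannot
    extend the repeat pattern; returns (reference dict, locus).
    """
    u = len(unit)
    lseq = list(random_seq(rng, left))
    tract = (unit * (tract_len // u + 2))[:tract_len]
    rseq = list(random_seq(rng, right))
    # break the unit period at both boundaries
    while lseq and lseq[-1] == tract[u - 1]:
        lseq[-1] = str(rng.choice([b for b in "ACGT" if b != tract[u - 1]]))
    while rseq and rseq[0] == tract[tract_len - u]:
        rseq[0] = str(rng.choice([b for b in "ACGT" if b != tract[tract_len - u]]))
    seq = "".join(lseq) + tract + "".join(rseq)
    locus = mk_locus(chrom, left, left + tract_len, unit)
    return {chrom: seq}, locus
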