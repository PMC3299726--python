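"""Population-scale summaries of microsatellite variation.

Given a loci x lines genotype matrix of allele lengths, this module
derives per-locus allele spectra (modal allele across lines, distinct
allele count, per-allele deviations from the mode), mean allele counts
binned by length / purity / unit size, the in-phase analysis -- the
percentage of non-modal alleles whose deviation from the modal allele is
an exact multiple of the unit length, the signature of whole-unit
stepwise mutation -- and per-unit histograms of deviations expressed in
repeat units.

Deviations are measured against the population's modal allele, not the
reference allele; mononucleotides are excluded from the comparative
analyses (unit sizes 2-5 only).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import RepeatLocus
from .genotyper import GenotypeMatrix

__all__ = [
    "AlleleSpectrum",
    "build_allele_spectra",
    "mean_alleles_by_bin",
    "in_phase_analysis",
    "unit_delta_histogram",
    "plateau_length",
    "PhaseStats",
]


@dataclass
class AlleleSpectrum:
    """Distribution of called allele lengths across lines at one locus."""

    locus_id: str
    modal_allele: int
    n_called: int
    n_distinct_alleles: int
    deltas: list[int]  # allele - modal, one entry per non-modal called line


@dataclass
class PhaseStats:
    unit_length: int
    length_bin: int
    n_variant_alleles: int
    n_in_phase: int

    @property
    def percent_in_phase(self) -> float:
        return 100.0 * self.n_in_phase / self.n_variant_alleles


def build_allele_spectra(
    matrix: GenotypeMatrix | pd.DataFrame, *, min_called: int = 2
) -> list[AlleleSpectrum]:
    """Per-locus allele spectra across lines.

    The modal allele is the most frequent allele length across lines (ties
    broken toward the smaller allele); loci called in fewer than
    ``min_called`` lines are skipped.
    """
    alleles = matrix.alleles if isinstance(matrix, GenotypeMatrix) else matrix
    out: list[AlleleSpectrum] = []
    for locus_id, row in alleles.iterrows():
        called = row.dropna().astype(int)
        if len(called) < min_called:
            continue
        counts = Counter(called)
        top = max(counts.values())
        modal = min(a for a, c in counts.items() if c == top)
        deltas = [int(a - modal) for a in called if a != modal]
        out.append(
            AlleleSpectrum(
                locus_id=str(locus_id),
                modal_allele=int(modal),
                n_called=len(called),
                n_distinct_alleles=len(counts),
                deltas=deltas,
            )
        )
    return out


def _catalog_index(catalog: Sequence[RepeatLocus]) -> dict[str, RepeatLocus]:
    return {l.locus_id: l for l in catalog}


def mean_alleles_by_bin(
    spectra: Sequence[AlleleSpectrum],
    catalog: Sequence[RepeatLocus],
    group_by: str = "unit_size",
    *,
    min_bin: int = 25,
    units: Sequence[int] = (2, 3, 4, 5),
    purity_classes: Sequence[tuple[float, float]] = (
        (0.8, 0.9),
        (0.9, 1.0),
        (1.0, 1.0),
    ),
) -> pd.DataFrame:
    """Mean distinct-allele count per modal-length bin and group.

    Groups are unit sizes or purity classes; bins holding fewer than
    ``min_bin`` loci are suppressed (thin bins are noise-dominated).
    """
    attrs = _catalog_index(catalog)
    rows = []
    for s in spectra:
        locus = attrs.get(s.locus_id)
        if locus is None or locus.unit_length not in units:
            continue
        if group_by == "unit_size":
            group = locus.unit_length
        elif group_by == "purity_class":
            group = None
            for lo, hi in purity_classes:
                if (lo <= locus.purity < hi) or (lo == hi == locus.purity):
                    group = f"{lo:.2f}-{hi:.2f}"
                    break
            if group is None:
                continue
        elif group_by == "length":
            group = "all"
        else:
            raise ValueError(f"unknown group_by {group_by!r}")
        rows.append((s.modal_allele, group, s.n_distinct_alleles))
    df = pd.DataFrame(rows, columns=["length", "group", "n_distinct"])
    if df.empty:
        return pd.DataFrame(columns=["length", "group", "n_loci", "mean_alleles"])
    agg = (
        df.groupby(["length", "group"])
        .agg(n_loci=("n_distinct", "size"), mean_alleles=("n_distinct", "mean"))
        .reset_index()
    )
    return agg[agg.n_loci >= min_bin].reset_index(drop=True)


def in_phase_analysis(
    spectra: Sequence[AlleleSpectrum],
    catalog: Sequence[RepeatLocus],
    *,
    pure_only: bool = True,
    units: Sequence[int] = (2, 3, 4, 5),
) -> pd.DataFrame:
    """Percent of non-modal alleles in whole-unit phase, by unit and length.

    The length bin is the modal allele length (the population's common
    allele).  With ``pure_only`` the analysis is restricted to
    uninterrupted (purity 1.0) repeats.
    """
    attrs = _catalog_index(catalog)
    acc: dict[tuple[int, int], list[int]] = {}
    for s in spectra:
        locus = attrs.get(s.locus_id)
        if locus is None or locus.unit_length not in units:
            continue
        if pure_only and locus.purity < 1.0:
            continue
        if not s.deltas:
            continue
        key = (locus.unit_length, s.modal_allele)
        acc.setdefault(key, []).extend(s.deltas)
    rows = []
    for (u, length), deltas in sorted(acc.items()):
        n_in = sum(1 for d in deltas if d % u == 0)
        rows.append(
            (u, length, len(deltas), n_in, 100.0 * n_in / len(deltas))
        )
    return pd.DataFrame(
        rows,
        columns=["unit_length", "length", "n_variant_alleles", "n_in_phase",
                 "percent_in_phase"],
    )


def unit_delta_histogram(
    spectra: Sequence[AlleleSpectrum],
    catalog: Sequence[RepeatLocus],
    *,
    min_purity: float = 0.90,
    min_length_by_unit: Mapping[int, int] = None,
    units: Sequence[int] = (2, 3, 4, 5),
) -> dict[int, pd.Series]:
    """Histogram of allele deviations in repeat units, per unit size.

    Only loci at least ``min_purity`` pure and at least the per-unit
    minimum modal length (defaults 13/20/23/27 bases for units 2-5, the
    lengths at which whole-unit mutation dominates) contribute.
    Non-integer ratios fall at fractional positions (resolution 1/unit);
    frequencies sum to 1 per unit size when any deltas exist.
    """
    if min_length_by_unit is None:
        min_length_by_unit = {2: 13, 3: 20, 4: 23, 5: 27}
    attrs = _catalog_index(catalog)
    acc: dict[int, list[float]] = {u: [] for u in units}
    for s in spectra:
        locus = attrs.get(s.locus_id)
        if locus is None or locus.unit_length not in units:
            continue
        if locus.purity < min_purity:
            continue
        if s.modal_allele < min_length_by_unit.get(locus.unit_length, 0):
            continue
        u = locus.unit_length
        acc[u].extend(d / u for d in s.deltas)
    out: dict[int, pd.Series] = {}
    for u, ratios in acc.items():
        if not ratios:
            out[u] = pd.Series(dtype=float)
            continue
        rounded = [round(r * u) / u for r in ratios]
        counts = pd.Series(Counter(rounded)).sort_index()
        out[u] = counts / counts.sum()
    return out


def plateau_length(
    series: pd.Series, criterion: float = 0.95, *, top_quartile: float = 0.25
) -> int | None:
    """Length at which a percent-in-phase series reaches its plateau.

    The asymptote is the mean over the top quartile of lengths; the
    plateau is the smallest length whose value first reaches
    ``criterion`` x asymptote.  Returns None for an empty series.
    """
    series = series.dropna().sort_index()
    if series.empty:
        return None
    n_top = max(1, int(np.ceil(len(series) * top_quartile)))
    asymptote = series.iloc[-n_top:].mean()
    target = criterion * asymptote
    hit = series[series >= target]
    return int(hit.index[0]) if len(hit) else None
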