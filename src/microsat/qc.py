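"""Accuracy metrics and diagnostics for microsatellite genotype calls.

Two headline metrics quantify call quality in homozygous inbred panels:

* completeness -- the fraction of catalog loci with at least two scorable
  reads (a genotype can be assigned);
* internal concordance -- R_major / R_total, the fraction of a locus's
  scorable reads supporting the majority allele.

Also here: per-line exclusion of chromosome arms showing residual
heterozygosity, smoothing of metric series by reference length, direct
comparison of genotypes derived from two read-length groups within one
line, a bootstrap test for allele-length bias at discordant loci, and
MapQ-based diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import RepeatLocus
from .genotyper import LocusCall, PanelResult, genotype_panel

__all__ = [
    "exclude_heterozygous_arms",
    "completeness",
    "mean_concordance",
    "bin_and_smooth",
    "binned_metrics",
    "compare_read_length_groups",
    "BiasTestResult",
    "bootstrap_bias_test",
    "mapq_diagnostics",
]


def exclude_heterozygous_arms(
    het_table: pd.DataFrame, threshold: float = 0.05
) -> dict[str, set[str]]:
    """Per-line chromosome arms to exclude for residual heterozygosity.

    ``het_table`` columns: line, arm, n_het, n_total.  An arm is excluded
    for a line iff n_het / n_total is strictly greater than ``threshold``
    (lines with zero SNP sites are retained).
    """
    out: dict[str, set[str]] = {}
    for row in het_table.itertuples(index=False):
        if row.n_total > 0 and row.n_het / row.n_total > threshold:
            out.setdefault(str(row.line), set()).add(str(row.arm))
    return out


def _eligible(calls: Iterable[LocusCall]) -> list[LocusCall]:
    return [c for c in calls if c.status != "excluded_het"]


def completeness(calls: Iterable[LocusCall], min_reads: int = 2) -> float:
    """Fraction of (non-excluded) loci with at least ``min_reads`` scorable reads."""
    cs = _eligible(calls)
    if not cs:
        return 0.0
    return sum(1 for c in cs if c.n_scorable >= min_reads) / len(cs)


def mean_concordance(calls: Iterable[LocusCall]) -> float:
    """Mean internal concordance over called loci (NaN when none called)."""
    vals = [c.concordance for c in calls if c.status == "called"]
    return float(np.mean(vals)) if vals else float("nan")


def bin_and_smooth(series: pd.Series, window: int = 2) -> pd.DataFrame:
    """Unweighted running mean over existing integer bins within +/-window.

    Endpoints use the truncated window.  Returns columns raw / smoothed,
    indexed like the input.
    """
    series = series.sort_index()
    idx = series.index.to_numpy()
    vals = series.to_numpy(dtype=float)
    smoothed = np.empty_like(vals)
    for i, x in enumerate(idx):
        mask = (idx >= x - window) & (idx <= x + window)
        smoothed[i] = vals[mask].mean()
    return pd.DataFrame({"raw": vals, "smoothed": smoothed}, index=series.index)


def binned_metrics(
    result: PanelResult,
    catalog: Sequence[RepeatLocus],
    by: str = "length",
    *,
    window: int = 2,
    min_reads: int = 2,
    aggregate: str = "lines",
) -> pd.DataFrame:
    """Completeness and concordance per bin of reference length, unit size
    or purity class, with smoothed variants.

    ``aggregate="lines"`` computes per-line bin means first and averages
    them across lines (each genome weighted equally); ``"pooled"`` pools
    all (locus, line) cells.
    """
    attrs = {l.locus_id: l for l in catalog}

    def bin_key(locus: RepeatLocus):
        if by == "length":
            return locus.ref_length
        if by == "unit":
            return locus.unit_length
        if by == "purity":
            return round(math.floor(locus.purity * 20) / 20, 2)
        raise ValueError(f"unknown binning {by!r}")

    rows = []
    for (locus_id, line_id), call in result.calls.items():
        locus = attrs.get(locus_id)
        if locus is None or call.status == "excluded_het":
            continue
        rows.append(
            (
                bin_key(locus),
                line_id,
                1.0 if call.n_scorable >= min_reads else 0.0,
                call.concordance if call.status == "called" else np.nan,
            )
        )
    df = pd.DataFrame(rows, columns=["bin", "line", "complete", "concordance"])
    if df.empty:
        return pd.DataFrame(
            columns=["n_loci", "completeness", "concordance",
                     "completeness_smoothed", "concordance_smoothed"]
        )
    if aggregate == "lines":
        per_line = df.groupby(["bin", "line"]).agg(
            complete=("complete", "mean"), concordance=("concordance", "mean")
        )
        agg = per_line.groupby(level="bin").mean()
    else:
        agg = df.groupby("bin").agg(
            complete=("complete", "mean"), concordance=("concordance", "mean")
        )
    n = df.groupby("bin")["complete"].size() / df["line"].nunique()
    out = pd.DataFrame(
        {
            "n_loci": n.round().astype(int),
            "completeness": agg["complete"],
            "concordance": agg["concordance"],
        }
    )
    out["completeness_smoothed"] = bin_and_smooth(out["completeness"], window)[
        "smoothed"
    ]
    conc = out["concordance"].dropna()
    sm = bin_and_smooth(conc, window)["smoothed"] if len(conc) else conc
    out["concordance_smoothed"] = sm.reindex(out.index)
    return out


def flank_sweep(
    result: PanelResult, ks: Sequence[int] = (0, 1, 2, 3, 4, 5), min_reads: int = 2
) -> pd.DataFrame:
    """Re-threshold the flank-match filter without re-scoring reads.

    Requires ``genotype_panel(..., keep_reads=True)`` run at the loosest
    setting (min_flank 0).  For each k the scorable-read total,
    completeness and mean concordance are recomputed; counts and
    completeness are exactly non-increasing in k by construction.
    """
    from .genotyper import call_locus, rescore_with_min_flank

    rows = []
    for k in ks:
        n_scorable = 0
        calls = []
        for (locus_id, line_id), reads in result.scored_reads.items():
            rs = rescore_with_min_flank(reads, k)
            n_scorable += sum(1 for s in rs if s.scorable)
            calls.append(
                call_locus(rs, min_reads, locus_id=locus_id, line_id=line_id)
            )
        rows.append(
            (k, n_scorable, completeness(calls, min_reads), mean_concordance(calls))
        )
    return pd.DataFrame(
        rows, columns=["min_flank", "n_scorable", "completeness", "concordance"]
    ).set_index("min_flank")


def compare_read_length_groups(
    reads,
    split,
    catalog: Sequence[RepeatLocus],
    reference,
    *,
    line_id: str = "line",
    min_flank: int = 3,
    min_reads: int = 2,
) -> tuple[pd.DataFrame, dict[str, PanelResult]]:
    """Genotype one line independently per read-length group and compare.

    ``split`` maps a read to a group label (e.g. by read length); loci
    called in both groups with different majority alleles are reported
    with both calls, the reference length, and the per-group deviations
    (call - reference length).  Loci called in only one group are not
    comparable and are excluded.
    """
    groups: dict[str, list] = {}
    for r in reads:
        groups.setdefault(str(split(r)), []).append(r)
    results = {
        g: genotype_panel(
            catalog,
            {line_id: rs},
            reference,
            min_flank=min_flank,
            min_reads=min_reads,
        )
        for g, rs in sorted(groups.items())
    }
    names = sorted(results)
    if len(names) != 2:
        raise ValueError(f"need exactly two read groups, got {names}")
    a, b = names
    attrs = {l.locus_id: l for l in catalog}
    rows = []
    for locus_id in results[a].locus_ids:
        ca = results[a].calls[(locus_id, line_id)]
        cb = results[b].calls[(locus_id, line_id)]
        if ca.status != "called" or cb.status != "called":
            continue
        if ca.majority_allele != cb.majority_allele:
            ref_len = attrs[locus_id].ref_length
            rows.append(
                (
                    locus_id,
                    ref_len,
                    ca.majority_allele,
                    cb.majority_allele,
                    ca.majority_allele - ref_len,
                    cb.majority_allele - ref_len,
                )
            )
    disc = pd.DataFrame(
        rows,
        columns=["locus_id", "ref_length", f"call_{a}", f"call_{b}",
                 f"delta_{a}", f"delta_{b}"],
    )
    return disc, results


@dataclass
class BiasTestResult:
    """Bootstrap bands for allele-length-difference spectra at discordant loci."""

    bins: np.ndarray  # sorted delta values (call - reference length)
    observed: dict[str, np.ndarray]  # per group, frequency per bin
    lo: dict[str, np.ndarray]  # 2.5th percentile per bin
    hi: dict[str, np.ndarray]  # 97.5th percentile per bin
    n_discordant: int
    n_trials: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        data = {"delta": self.bins}
        for g in self.observed:
            data[f"freq_{g}"] = self.observed[g]
            data[f"lo_{g}"] = self.lo[g]
            data[f"hi_{g}"] = self.hi[g]
        return pd.DataFrame(data)


def bootstrap_bias_test(
    records: pd.DataFrame,
    n_trials: int = 1000,
    seed: int | None = None,
    *,
    percentiles: tuple[float, float] = (2.5, 97.5),
) -> BiasTestResult:
    """Resample discordant loci with replacement and band the delta spectra.

    ``records`` must carry one ``delta_<group>`` column per read-length
    group (call minus reference length, in bases).  Loci are the sampling
    unit and are resampled jointly across groups; for each trial the
    per-bin frequencies are tabulated, and the 2.5th/97.5th percentiles
    across trials form the confidence band.  Deterministic under a seed.
    """
    delta_cols = [c for c in records.columns if c.startswith("delta_")]
    if not delta_cols:
        raise ValueError("records must contain delta_<group> columns")
    n = len(records)
    if n == 0:
        raise ValueError("no discordant records to resample")
    rng = np.random.default_rng(seed)
    deltas = {c[len("delta_"):]: records[c].to_numpy(dtype=int) for c in delta_cols}
    bins = np.unique(np.concatenate(list(deltas.values())))
    bin_index = {d: i for i, d in enumerate(bins)}
    idx = rng.integers(0, n, size=(n_trials, n))
    trial_rows = np.repeat(np.arange(n_trials), n)
    observed, lo, hi = {}, {}, {}
    p_lo, p_hi = percentiles
    for g, d in deltas.items():
        di = np.array([bin_index[v] for v in d])
        counts = np.zeros((n_trials, len(bins)), dtype=np.int64)
        np.add.at(counts, (trial_rows, di[idx].ravel()), 1)
        freqs = counts / n
        observed[g] = np.bincount(di, minlength=len(bins)) / n
        lo[g] = np.percentile(freqs, p_lo, axis=0)
        hi[g] = np.percentile(freqs, p_hi, axis=0)
    return BiasTestResult(
        bins=bins,
        observed=observed,
        lo=lo,
        hi=hi,
        n_discordant=n,
        n_trials=n_trials,
        seed=seed,
    )


def mapq_diagnostics(
    result: PanelResult,
    catalog: Sequence[RepeatLocus],
    *,
    length_strata: Sequence[tuple[int, int]] = ((10, 24), (25, 39), (40, 54)),
    min_majority: int = 4,
) -> dict:
    """MapQ-based diagnostics over scored reads.

    (a) Within each reference-length stratum, loci are binned by integer
    length; the Pearson correlation of per-bin mean MapQ with per-bin mean
    concordance is reported (NaN when fewer than two bins exist).
    (b) For loci with allele representation n:1 (n >= ``min_majority``),
    the MapQ of the discordant singleton is compared with the mean MapQ of
    the majority reads, as a mean relative difference.

    Requires ``genotype_panel(..., keep_reads=True)``.
    """
    if result.scored_reads is None:
        raise ValueError("mapq_diagnostics needs a PanelResult with keep_reads=True")
    attrs = {l.locus_id: l for l in catalog}
    rows = []
    rel_diffs = []
    for (locus_id, line_id), call in result.calls.items():
        reads = [s for s in result.scored_reads[(locus_id, line_id)] if s.scorable]
        if call.status != "called" or not reads:
            continue
        locus = attrs[locus_id]
        mean_mapq = float(np.mean([s.mapq for s in reads]))
        rows.append((locus.ref_length, mean_mapq, call.concordance))
        counts = call.allele_counts
        if len(counts) == 2:
            (a1, c1), (a2, c2) = sorted(counts.items(), key=lambda kv: -kv[1])
            if c2 == 1 and c1 >= min_majority:
                maj = [s.mapq for s in reads if s.allele_length == a1]
                single = [s.mapq for s in reads if s.allele_length == a2]
                if maj and single and np.mean(maj) > 0:
                    rel_diffs.append(
                        (np.mean(single) - np.mean(maj)) / np.mean(maj)
                    )
    df = pd.DataFrame(rows, columns=["ref_length", "mapq", "concordance"])
    correlations = {}
    for lo_s, hi_s in length_strata:
        sub = df[(df.ref_length >= lo_s) & (df.ref_length <= hi_s)]
        per_len = sub.groupby("ref_length").agg(
            mapq=("mapq", "mean"), concordance=("concordance", "mean")
        )
        if len(per_len) >= 2 and per_len["mapq"].std() > 0 and per_len[
            "concordance"
        ].std() > 0:
            r, p = stats.pearsonr(per_len["mapq"], per_len["concordance"])
        else:
            r, p = float("nan"), float("nan")
        correlations[f"{lo_s}-{hi_s}"] = {"r": r, "r2": r * r, "p": p,
                                          "n_bins": len(per_len)}
    singleton = float(np.mean(rel_diffs)) if rel_diffs else float("nan")
    return {
        "length_bin_correlation": correlations,
        "singleton_mapq_relative_difference": singleton,
        "n_singleton_loci": len(rel_diffs),
    }
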