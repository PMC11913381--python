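"""CPD-seq damage-map analytics.

A CPD (cyclobutane pyrimidine dimer) forms between two adjacent
pyrimidines on one strand. Each lesion count is assigned to BOTH positions
of the lesion-forming dipyrimidine, so per-position totals double the raw
lesion total; percentages across bins are unaffected by the doubling.

Lesion positions in input profiles are the 5' position of the dipyrimidine
on the lesion strand: the partner position is pos+1 on the plus strand and
pos-1 on the minus strand (whose dipyrimidine reads as a purine pair on
the reference).

The windowed scan and repeat-collapse score diagnose coverage artifacts
such as the rDNA locus, where reads from ~150-200 tandem repeat copies
collapse onto the 2 copies present in the reference assembly and inflate
apparent per-bp counts ~40-fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError
from .io_formats import CpdProfile, GenomeSequence, RegionMask
from .timing import (
    BIN_LABELS,
    BinCensus,
    ReplicationBins,
    TimingMap,
    interpolate_times,
)


@dataclass
class AssignedDamage:
    """Dense per-position assigned lesion counts per chromosome."""

    per_chrom: dict[str, np.ndarray]
    n_end_clipped: int = 0  # lesions whose partner position fell off-chromosome

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.per_chrom.values()))


def assign_lesion_positions(
    profile: CpdProfile, genome: GenomeSequence
) -> AssignedDamage:
    """Assign each lesion count to both positions of its dipyrimidine.

    When the partner position falls off the chromosome the count is
    assigned once and a warning counter incremented.
    """
    per_chrom = {c: np.zeros(genome.length(c)) for c in genome.chrom_names}
    clipped = 0
    for chrom, pos, strand, count in profile.items():
        if chrom not in per_chrom:
            raise DomainError(f"profile chromosome {chrom!r} not in genome")
        arr = per_chrom[chrom]
        if pos >= len(arr):
            raise DomainError(
                f"lesion at {chrom}:{pos} beyond chromosome end ({len(arr)} bp)"
            )
        arr[pos] += count
        partner = pos + 1 if strand == "+" else pos - 1
        if 0 <= partner < len(arr):
            arr[partner] += count
        else:
            clipped += 1
    return AssignedDamage(per_chrom, n_end_clipped=clipped)


@dataclass
class DamageBinSummary:
    """Per-bin assigned counts and percentages for one sample."""

    label: str
    table: pd.DataFrame  # index early/middle/late; assigned_count, percent_of_total, dipyrimidine_percent

    @property
    def counts(self) -> pd.Series:
        return self.table["assigned_count"]


def _bin_sums(
    assigned: AssignedDamage,
    tmap: TimingMap,
    bins: ReplicationBins,
    mask: RegionMask | None,
) -> np.ndarray:
    cuts = np.array([bins.cut_early_mid, bins.cut_mid_late])
    sums = np.zeros(3)
    for chrom, arr in assigned.per_chrom.items():
        if chrom not in tmap.chrom_names:
            continue
        nz = np.flatnonzero(arr)
        if len(nz) == 0:
            continue
        times = interpolate_times(tmap, chrom, nz)
        keep = ~np.isnan(times)
        if mask is not None:
            keep &= ~mask.bool_array(chrom, len(arr))[nz]
        if not keep.any():
            continue
        major = np.searchsorted(cuts, times[keep], side="right")
        sums += np.bincount(major, weights=arr[nz][keep], minlength=3)
    return sums


def damage_bin_summary(
    assigned: AssignedDamage,
    tmap: TimingMap,
    bins: ReplicationBins,
    census: BinCensus,
    mask: RegionMask | None = None,
    label: str = "sample",
) -> DamageBinSummary:
    """Sum assigned counts per bin over covered, unmasked positions and
    pair the percentages with the census dipyrimidine percentages."""
    sums = _bin_sums(assigned, tmap, bins, mask)
    total = sums.sum()
    if total == 0:
        raise DomainError("no assigned damage in covered, unmasked regions")
    table = pd.DataFrame(
        {
            "assigned_count": sums,
            "percent_of_total": 100 * sums / total,
            "dipyrimidine_percent": census.dipyrimidine_percent.to_numpy(),
        },
        index=list(BIN_LABELS),
    )
    return DamageBinSummary(label, table)


def repair_fraction(
    summary_t: DamageBinSummary,
    summary_0: DamageBinSummary,
    normalization: str = "none",
) -> pd.Series:
    """Fraction of lesions remaining per bin after repair.

    fraction[bin] = (count_t[bin]/s_t) / (count_0[bin]/s_0) with s the
    sample totals under ``library_size`` normalization, or 1 under
    ``none``. Bins with zero 0h counts yield NaN (flagged, not fatal).
    """
    if normalization not in ("none", "library_size"):
        raise DomainError(f"unknown normalization {normalization!r}")
    ct = summary_t.counts.astype(float)
    c0 = summary_0.counts.astype(float)
    if normalization == "library_size":
        ct = ct / ct.sum()
        c0 = c0 / c0.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = ct / c0
    frac[c0 == 0] = np.nan
    frac.name = "fraction_remaining"
    return frac


def window_scan(
    assigned: AssignedDamage,
    tmap: TimingMap,
    bins: ReplicationBins,
    width: int = 1000,
    chroms: list[str] | None = None,
) -> pd.DataFrame:
    """Tile chromosomes with fixed-width windows of summed assigned counts.

    Each window is labelled early/middle/late when every position is
    timing-covered and falls in that one bin; ``unavailable`` when no
    position is covered; ``mixed`` otherwise. Windows tile without overlap;
    only the last window of a chromosome may be short.
    """
    if width < 1:
        raise DomainError("window width must be >= 1")
    cuts = np.array([bins.cut_early_mid, bins.cut_mid_late])
    rows = []
    for chrom in chroms if chroms is not None else sorted(assigned.per_chrom):
        arr = assigned.per_chrom[chrom]
        L = len(arr)
        times = (
            interpolate_times(tmap, chrom, np.arange(L))
            if chrom in tmap.chrom_names
            else np.full(L, np.nan)
        )
        major = np.searchsorted(cuts, times, side="right")
        covered = ~np.isnan(times)
        for start in range(0, L, width):
            end = min(start + width, L)
            cov = covered[start:end]
            if not cov.any():
                label = "unavailable"
            else:
                labels = np.unique(major[start:end][cov])
                if cov.all() and len(labels) == 1:
                    label = BIN_LABELS[labels[0]]
                else:
                    label = "mixed"
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "count": float(arr[start:end].sum()),
                    "bin_label": label,
                }
            )
    return pd.DataFrame(rows)


def repeat_collapse_score(track: pd.DataFrame, candidate: RegionMask) -> float:
    """Fold enrichment of per-window counts inside a candidate region.

    mean per-window count over windows overlapping the candidate, divided
    by the mean over the remaining windows of the same chromosomes.
    A collapsed repeat with N true copies mapped onto r reference copies
    scores ~N/r.
    """
    chroms = {c for c, _, _ in candidate.intervals}
    sub = track[track["chrom"].isin(chroms)]
    inside = pd.Series(
        [
            candidate.overlaps(c, int(s), int(e))
            for c, s, e in zip(sub["chrom"], sub["start"], sub["end"])
        ],
        index=sub.index,
        dtype=bool,
    )
    if sub.empty or not inside.any():
        raise DomainError("candidate region overlaps no window")
    mean_in = sub.loc[inside, "count"].mean()
    outside = sub.loc[~inside, "count"]
    if len(outside) == 0 or outside.mean() == 0:
        raise DomainError("no nonzero windows outside the candidate region")
    return float(mean_in / outside.mean())
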