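"""Replication-timing map: interpolation, equal-sequence binning, census.

The timing map gives the minute in S-phase at which each anchor position
replicates, at a nominal 500-bp spacing. Times at arbitrary positions are
obtained by linear interpolation between the flanking anchors:

    time = time1 + (time2 - time1) * (pos - pos1) / (pos2 - pos1)

Positions outside the anchored range (e.g. the first ~250 bp of each
chromosome) are not covered and are excluded, never extrapolated.

The genome is partitioned into early/middle/late terciles — and nine
nested sub-bins — each covering an equal amount of mapped sequence. Each
anchor interval is weighted by its bp span and represented by its midpoint
time; cutpoints are the times at cumulative-bp fractions k/9 of the pooled
(all-chromosome) sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .contexts import TRINUC_32, TRINUC64_TO_CANON, dipyrimidine_sites, encode
from .errors import (
    DegenerateMapError,
    DomainError,
    FormatError,
    UnknownChromosomeError,
)
from .io_formats import GenomeSequence, MutationRecord, RegionMask

BIN_LABELS = ("early", "middle", "late")


class TimingMap:
    """Per-chromosome sorted (position, minutes) anchors."""

    def __init__(
        self,
        anchors: dict[str, Sequence[tuple[float, float]]],
        spacing: int = 500,
    ):
        self.spacing = spacing
        self._pos: dict[str, np.ndarray] = {}
        self._time: dict[str, np.ndarray] = {}
        for chrom, pairs in anchors.items():
            arr = np.asarray(sorted(pairs), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
                raise FormatError(f"{chrom}: need >=2 (pos, time) anchors")
            pos, time = arr[:, 0], arr[:, 1]
            if np.any(np.diff(pos) <= 0):
                raise FormatError(f"{chrom}: anchor positions must strictly increase")
            if not np.all(np.isfinite(time)) or np.any(time < 0):
                raise FormatError(f"{chrom}: times must be finite and >= 0")
            self._pos[chrom] = pos
            self._time[chrom] = time

    @property
    def chrom_names(self) -> list[str]:
        return list(self._pos)

    def anchors(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        try:
            return self._pos[chrom], self._time[chrom]
        except KeyError:
            raise UnknownChromosomeError(chrom) from None

    def coverage(self, chrom: str) -> tuple[int, int]:
        """Covered half-open position range [first_anchor, last_anchor + 1)."""
        pos, _ = self.anchors(chrom)
        return int(pos[0]), int(pos[-1]) + 1

    # -- serialisation: tab-separated chrom, pos (0-based), minutes --------
    @classmethod
    def from_tsv(cls, path: str | Path, spacing: int = 500) -> "TimingMap":
        anchors: dict[str, list[tuple[float, float]]] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: need chrom, pos, minutes")
            anchors.setdefault(fields[0], []).append(
                (float(fields[1]), float(fields[2]))
            )
        return cls(anchors, spacing=spacing)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in self.chrom_names:
                pos, time = self.anchors(chrom)
                for p, t in zip(pos, time):
                    fh.write(f"{chrom}\t{int(p)}\t{t:g}\n")


def interpolate_time(tmap: TimingMap, chrom: str, pos: float) -> float:
    """Replication time (minutes) at ``pos``, or NaN if not covered."""
    anchor_pos, anchor_time = tmap.anchors(chrom)
    if pos < anchor_pos[0] or pos > anchor_pos[-1]:
        return float("nan")
    i = int(np.searchsorted(anchor_pos, pos, side="right")) - 1
    if i == len(anchor_pos) - 1:  # exactly on the last anchor
        return float(anchor_time[-1])
    pos1, pos2 = anchor_pos[i], anchor_pos[i + 1]
    time1, time2 = anchor_time[i], anchor_time[i + 1]
    return float(time1 + (time2 - time1) * ((pos - pos1) / (pos2 - pos1)))


def interpolate_times(tmap: TimingMap, chrom: str, positions: np.ndarray) -> np.ndarray:
    """Vectorised :func:`interpolate_time`; NaN where not covered.

    Evaluates the same expression as the scalar version so results are
    bit-identical.
    """
    anchor_pos, anchor_time = tmap.anchors(chrom)
    positions = np.asarray(positions, dtype=float)
    out = np.full(positions.shape, np.nan)
    covered = (positions >= anchor_pos[0]) & (positions <= anchor_pos[-1])
    if not covered.any():
        return out
    p = positions[covered]
    i = np.searchsorted(anchor_pos, p, side="right") - 1
    i = np.minimum(i, len(anchor_pos) - 2)
    pos1, pos2 = anchor_pos[i], anchor_pos[i + 1]
    time1, time2 = anchor_time[i], anchor_time[i + 1]
    vals = time1 + (time2 - time1) * ((p - pos1) / (pos2 - pos1))
    # exact anchor hits must return the anchor time exactly
    on_last = p == anchor_pos[-1]
    vals[on_last] = anchor_time[-1]
    out[covered] = vals
    return out


@dataclass(frozen=True)
class ReplicationBins:
    """Tercile cutpoints (minutes) plus optional nested nine-bin cutpoints."""

    cut_early_mid: float
    cut_mid_late: float
    cuts9: tuple[float, ...] | None = None

    def __post_init__(self):
        if not self.cut_early_mid < self.cut_mid_late:
            raise DomainError("tercile cuts must be increasing")
        if self.cuts9 is not None:
            c = np.asarray(self.cuts9)
            if len(c) != 8 or np.any(np.diff(c) <= 0):
                raise DomainError("nine-bin cutpoints must be 8 increasing values")
            if c[2] != self.cut_early_mid or c[5] != self.cut_mid_late:
                raise DomainError("nine-bin cutpoints must nest in terciles")

    @property
    def labels(self) -> tuple[str, ...]:
        return BIN_LABELS


def classify(time: float, bins: ReplicationBins) -> str:
    """Major-bin label: [0, c1) early, [c1, c2) middle, [c2, inf) late."""
    if time < 0 or not np.isfinite(time):
        raise DomainError(f"invalid replication time {time}")
    if time < bins.cut_early_mid:
        return "early"
    if time < bins.cut_mid_late:
        return "middle"
    return "late"


def nine_bin_index(time: float, bins: ReplicationBins) -> int:
    """Nine-bin index in 1..9 (half-open boundaries, like :func:`classify`)."""
    if bins.cuts9 is None:
        raise DomainError("bins have no nine-bin cutpoints")
    if time < 0 or not np.isfinite(time):
        raise DomainError(f"invalid replication time {time}")
    return int(np.searchsorted(bins.cuts9, time, side="right")) + 1


def compute_bins(tmap: TimingMap, n_major: int = 3, n_sub: int = 3) -> ReplicationBins:
    """Partition the pooled genome into equal-sequence timing bins.

    Each anchor interval contributes its bp span at its midpoint time;
    intervals are sorted by time and cut at cumulative-bp fractions
    k/(n_major*n_sub). A time exactly at a cut belongs to the higher bin.
    """
    spans, mids = [], []
    for chrom in tmap.chrom_names:
        pos, time = tmap.anchors(chrom)
        spans.append(np.diff(pos))
        mids.append((time[:-1] + time[1:]) / 2)
    spans = np.concatenate(spans)
    mids = np.concatenate(mids)
    n = n_major * n_sub
    if len(spans) < n:
        raise DomainError(f"need >= {n} anchor intervals, have {len(spans)}")
    if np.all(mids == mids[0]):
        raise DegenerateMapError("all interval times identical")
    order = np.argsort(mids, kind="stable")
    mids_sorted = mids[order]
    cum = np.cumsum(spans[order])
    total = cum[-1]
    cuts = []
    for k in range(1, n):
        target = total * k / n
        j = int(np.searchsorted(cum, target, side="right"))
        j = min(j, len(mids_sorted) - 1)
        cuts.append(float(mids_sorted[j]))
    if np.any(np.diff(cuts) <= 0):
        raise DegenerateMapError("cutpoints not strictly increasing (tied times)")
    if n_major == 3 and n_sub == 3:
        return ReplicationBins(cuts[2], cuts[5], tuple(cuts))
    major = [cuts[k * n_sub - 1] for k in range(1, n_major)]
    nine = tuple(cuts) if n == 9 else None
    return ReplicationBins(major[0], major[-1], nine)


@dataclass(frozen=True)
class TimedSite:
    chrom: str
    pos: int
    time: float
    bin_label: str
    nine_bin_index: int


def assign_sites(
    records: Iterable[MutationRecord],
    tmap: TimingMap,
    bins: ReplicationBins,
) -> tuple[list[TimedSite], int]:
    """Interpolate a time and bin for each record; uncovered records are
    excluded and counted. Output order matches input."""
    sites: list[TimedSite] = []
    excluded = 0
    for rec in records:
        t = interpolate_time(tmap, rec.chrom, rec.pos)
        if np.isnan(t):
            excluded += 1
            continue
        sites.append(
            TimedSite(rec.chrom, rec.pos, t, classify(t, bins), nine_bin_index(t, bins))
        )
    return sites, excluded


@dataclass
class BinCensus:
    """Sequence-composition census of the covered, unmasked genome.

    ``trinuc`` counts pyrimidine-strand trinucleotides per major bin (the
    middle base's interpolated time decides the bin). ``dipyrimidine``
    counts positions starting a lesion-capable dinucleotide per major bin.
    ``nine_bp`` / ``nine_time_mean`` give covered bp and mean interpolated
    time per nine-bin, the abscissa of the nine-bin regression.
    """

    trinuc: pd.DataFrame  # 32 trinucleotides x 3 bins
    dipyrimidine: pd.Series  # per major bin
    covered_bp: pd.Series  # per major bin
    nine_bp: np.ndarray  # (9,)
    nine_time_mean: np.ndarray  # (9,)
    per_chrom: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def dipyrimidine_percent(self) -> pd.Series:
        return 100 * self.dipyrimidine / self.dipyrimidine.sum()


def trinucleotide_bin_census(
    genome: GenomeSequence,
    tmap: TimingMap,
    bins: ReplicationBins,
    mask: RegionMask | None = None,
    per_chrom: bool = False,
    chroms: Sequence[str] | None = None,
) -> BinCensus:
    """Census every covered, unmasked position of the genome by bin.

    Trinucleotide counts require a full A/C/G/T window centred on the
    position; windows containing N are excluded. Dipyrimidine counts
    require the position and its successor to be both pyrimidines or both
    purines (lesion-capable on either strand).
    """
    trinuc_counts = np.zeros((3, 32), dtype=np.int64)
    dipyr = np.zeros(3, dtype=np.int64)
    covered_bp = np.zeros(3, dtype=np.int64)
    nine_bp = np.zeros(9, dtype=np.int64)
    nine_time_sum = np.zeros(9)
    chrom_rows = []

    cuts9 = np.asarray(bins.cuts9) if bins.cuts9 is not None else None
    tercile_cuts = np.array([bins.cut_early_mid, bins.cut_mid_late])

    for chrom in chroms if chroms is not None else genome.chrom_names:
        if chrom not in tmap.chrom_names:
            continue
        codes = encode(genome.seq(chrom))
        L = len(codes)
        positions = np.arange(L)
        times = interpolate_times(tmap, chrom, positions)
        keep = ~np.isnan(times)
        if mask is not None:
            keep &= ~mask.bool_array(chrom, L)
        major = np.searchsorted(tercile_cuts, times, side="right")

        covered_bp += np.bincount(major[keep], minlength=3)
        if cuts9 is not None:
            nine = np.searchsorted(cuts9, times, side="right")
            nine_bp += np.bincount(nine[keep], minlength=9)
            nine_time_sum += np.bincount(nine[keep], weights=times[keep], minlength=9)

        # trinucleotide census over positions with a full non-N window
        if L >= 3:
            centre = np.arange(1, L - 1)
            window_ok = (codes[:-2] < 4) & (codes[1:-1] < 4) & (codes[2:] < 4)
            ok = keep[centre] & window_ok
            if ok.any():
                tri64 = (
                    codes[:-2][ok].astype(np.int64) * 16
                    + codes[1:-1][ok] * 4
                    + codes[2:][ok]
                )
                canon = TRINUC64_TO_CANON[tri64]
                b = major[centre][ok]
                trinuc_counts += np.bincount(
                    b * 32 + canon, minlength=96
                ).reshape(3, 32)

        # dipyrimidine census over positions starting a lesion-capable pair
        if L >= 2:
            start = np.arange(L - 1)
            dp = dipyrimidine_sites(codes) & keep[start]
            dipyr_chrom = np.bincount(major[start][dp], minlength=3)
            dipyr += dipyr_chrom
            if per_chrom:
                chrom_rows.append(
                    {
                        "chrom": chrom,
                        **{
                            f"dipyrimidine_{lbl}": int(dipyr_chrom[i])
                            for i, lbl in enumerate(BIN_LABELS)
                        },
                        **{
                            f"covered_bp_{lbl}": int(
                                np.bincount(major[keep], minlength=3)[i]
                            )
                            for i, lbl in enumerate(BIN_LABELS)
                        },
                    }
                )

    with np.errstate(invalid="ignore"):
        nine_mean = np.where(nine_bp > 0, nine_time_sum / np.maximum(nine_bp, 1), np.nan)
    return BinCensus(
        trinuc=pd.DataFrame(
            trinuc_counts.T, index=list(TRINUC_32), columns=list(BIN_LABELS)
        ),
        dipyrimidine=pd.Series(dipyr, index=list(BIN_LABELS)),
        covered_bp=pd.Series(covered_bp, index=list(BIN_LABELS)),
        nine_bp=nine_bp,
        nine_time_mean=nine_mean,
        per_chrom=pd.DataFrame(chrom_rows) if per_chrom else None,
    )
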