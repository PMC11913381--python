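"""Complex (clustered) mutation events — the translesion-synthesis signature.

A complex event is a run of >=2 mutations in the same sequenced isolate on
the same chromosome in which each member lies within ``max_gap`` base
pairs (default 10, inclusive) of its predecessor. Chaining is transitive:
positions 100, 110, 120 form one event of three. Members may be
substitutions, insertions, or deletions; indels are anchored at their
0-based start.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import DomainError
from .io_formats import MutationRecord
from .spectra import BinTable
from .timing import BIN_LABELS, ReplicationBins, TimingMap, assign_sites


def gap_distance(a: MutationRecord, b: MutationRecord) -> int:
    """Distance in bp between two records' anchor positions (symmetric)."""
    if a.chrom != b.chrom:
        raise DomainError(f"records on different chromosomes: {a.chrom}, {b.chrom}")
    return abs(b.pos - a.pos)


@dataclass(frozen=True)
class ComplexEvent:
    """One clustered multi-mutation event within a single isolate."""

    isolate: str
    members: tuple[MutationRecord, ...]

    def __post_init__(self):
        if len(self.members) < 2:
            raise DomainError("a complex event needs >= 2 members")
        chroms = {m.chrom for m in self.members}
        if len(chroms) != 1:
            raise DomainError("event members must share a chromosome")
        if any(m.isolate != self.isolate for m in self.members):
            raise DomainError("event members must share the isolate")

    @property
    def chrom(self) -> str:
        return self.members[0].chrom

    @property
    def span(self) -> int:
        return self.members[-1].pos - self.members[0].pos


def call_complex(
    records: Iterable[MutationRecord], max_gap: int = 10
) -> tuple[list[ComplexEvent], list[MutationRecord], list[MutationRecord]]:
    """Partition records into complex events, complex members, and simple
    records.

    Each isolate is considered separately; within each (isolate,
    chromosome) records are sorted by position and chained whenever the
    gap to the previous record is <= ``max_gap``. Maximal chains of size
    >= 2 become events. Every record lands in exactly one of the two
    output lists.
    """
    records = list(records)
    by_group: dict[tuple[str, str], list[MutationRecord]] = {}
    for rec in records:
        by_group.setdefault((rec.isolate, rec.chrom), []).append(rec)

    complex_ids: set[int] = set()
    events: list[ComplexEvent] = []
    for (isolate, _chrom), group in sorted(by_group.items()):
        group.sort(key=lambda r: (r.pos, r.ref, r.alt))
        chain: list[MutationRecord] = []
        for rec in group:
            if chain and rec.pos - chain[-1].pos <= max_gap:
                chain.append(rec)
            else:
                if len(chain) >= 2:
                    events.append(ComplexEvent(isolate, tuple(chain)))
                    complex_ids.update(id(m) for m in chain)
                chain = [rec]
        if len(chain) >= 2:
            events.append(ComplexEvent(isolate, tuple(chain)))
            complex_ids.update(id(m) for m in chain)

    complex_records = [r for r in records if id(r) in complex_ids]
    simple_records = [r for r in records if id(r) not in complex_ids]
    return events, complex_records, simple_records


def complex_bin_table(
    events: Sequence[ComplexEvent],
    tmap: TimingMap,
    bins: ReplicationBins,
    sbs_bin_counts: pd.Series,
) -> tuple[BinTable, int]:
    """Observed complex-member counts per bin against SBS-proportional
    expectations.

    Expected counts assume complex mutations distribute across
    early/middle/late in the same proportions as all single-base
    substitutions. Members not covered by the timing map are excluded and
    counted in the second return value.
    """
    sbs_total = float(sbs_bin_counts.sum())
    if sbs_total <= 0:
        raise DomainError("SBS bin counts must have positive total")
    members = [m for ev in events for m in ev.members]
    sites, excluded = assign_sites(members, tmap, bins)
    observed = pd.Series(0.0, index=list(BIN_LABELS))
    for s in sites:
        observed[s.bin_label] += 1
    expected = observed.sum() * sbs_bin_counts.astype(float) / sbs_total
    expected = expected.reindex(observed.index)
    return BinTable(observed, expected), excluded
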