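"""File formats and in-memory types for the analysis pipeline.

All internal coordinates are 0-based, half-open. BED-style inputs are read
as-is; prose-style 1-based inclusive coordinates (such as the published
rDNA locus boundaries) are converted once, when a :class:`RegionMask` is
constructed from them.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from .contexts import CHANNELS
from .errors import FormatError, UnknownChromosomeError

MClass = Literal["SBS", "insertion", "deletion"]

_ALLOWED = set("ACGTN")
# IUPAC ambiguity codes are accepted on input and normalised to N.
_AMBIGUITY = set("RYSWKMBDHV")


class GenomeSequence:
    """An ordered collection of chromosome sequences over {A,C,G,T,N}."""

    def __init__(self, seqs: dict[str, str] | Iterable[tuple[str, str]]):
        items = list(seqs.items() if isinstance(seqs, dict) else seqs)
        names = [n for n, _ in items]
        if len(set(names)) != len(names):
            raise FormatError("duplicate chromosome names")
        self._seqs: dict[str, str] = {}
        for name, seq in items:
            seq = self._normalise(name, seq)
            self._seqs[name] = seq

    @staticmethod
    def _normalise(name: str, seq: str) -> str:
        seq = seq.upper()
        bad = set(seq) - _ALLOWED
        if bad & _AMBIGUITY:
            table = str.maketrans({b: "N" for b in _AMBIGUITY})
            seq = seq.translate(table)
            bad = set(seq) - _ALLOWED
        if bad:
            raise FormatError(
                f"non-IUPAC characters {sorted(bad)} in sequence {name!r}"
            )
        if not seq:
            raise FormatError(f"empty sequence for chromosome {name!r}")
        return seq

    @property
    def chrom_names(self) -> list[str]:
        return list(self._seqs)

    def seq(self, chrom: str) -> str:
        try:
            return self._seqs[chrom]
        except KeyError:
            raise UnknownChromosomeError(chrom) from None

    def length(self, chrom: str) -> int:
        return len(self.seq(chrom))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Lowercase input is accepted and uppercased; record order is preserved.
    """
    text = Path(path).read_text()
    stripped = text.lstrip()
    if not stripped:
        raise FormatError(f"empty FASTA file: {path}")
    if not stripped.startswith(">"):
        raise FormatError(f"malformed FASTA header in {path}")
    records = [
        (rec.id, str(rec.seq)) for rec in SeqIO.parse(io.StringIO(text), "fasta")
    ]
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return GenomeSequence(records)


def infer_mclass(ref: str, alt: str) -> MClass:
    if len(ref) == 1 and len(alt) == 1:
        if ref == alt:
            raise FormatError(f"ref equals alt: {ref}>{alt}")
        return "SBS"
    if len(alt) > len(ref):
        return "insertion"
    if len(ref) > len(alt):
        return "deletion"
    raise FormatError(f"unsupported multi-base substitution: {ref}>{alt}")


@dataclass(frozen=True)
class MutationRecord:
    """One called mutation; ``pos`` is the 0-based position of the mutated
    base (for indels, the 0-based start)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    isolate: str
    mclass: MClass = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.pos < 0:
            raise FormatError(f"negative position {self.pos}")
        if not self.isolate:
            raise FormatError("empty isolate identifier")
        inferred = infer_mclass(self.ref, self.alt)
        if self.mclass is None:
            object.__setattr__(self, "mclass", inferred)
        elif self.mclass != inferred:
            raise FormatError(
                f"mclass {self.mclass} inconsistent with {self.ref}>{self.alt}"
            )

    @property
    def span(self) -> tuple[int, int]:
        """Reference footprint as a half-open interval. Insertions occupy
        their single anchor base."""
        if self.mclass == "insertion":
            return (self.pos, self.pos + 1)
        return (self.pos, self.pos + len(self.ref))


def read_mutation_bed(path: str | Path) -> list[MutationRecord]:
    """Read the 5+-column tab-separated mutation dialect.

    Columns: chrom, start (0-based), end, ``REF>ALT``, isolate; extra
    columns are ignored. Duplicate lines are kept (mutations in different
    isolates may coincide).
    """
    records: list[MutationRecord] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise FormatError(
                f"{path}:{lineno}: expected >=5 tab-separated columns "
                f"(chrom, start, end, REF>ALT, isolate), got {len(fields)}"
            )
        chrom, start_s, end_s, change, isolate = fields[:5]
        if ">" not in change:
            raise FormatError(f"{path}:{lineno}: malformed change {change!r}")
        ref, alt = change.split(">", 1)
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
        mclass = infer_mclass(ref, alt)
        if mclass == "SBS" and end != start + len(ref):
            raise FormatError(
                f"{path}:{lineno}: end {end} != start+len(ref) {start + len(ref)}"
            )
        records.append(MutationRecord(chrom, start, ref, alt, isolate, mclass))
    return records


def write_mutation_bed(records: Iterable[MutationRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            end = r.pos + len(r.ref)
            fh.write(f"{r.chrom}\t{r.pos}\t{end}\t{r.ref}>{r.alt}\t{r.isolate}\n")


class CpdProfile:
    """Per-position, strand-aware lesion counts.

    Positions are 0-based and refer to the 5' base of the lesion-forming
    dipyrimidine on the lesion strand.
    """

    def __init__(self):
        self._counts: dict[tuple[str, str], dict[int, int]] = {}

    def add(self, chrom: str, pos: int, strand: str, count: int) -> None:
        if count < 0:
            raise FormatError(f"negative lesion count {count}")
        if strand not in "+-":
            raise FormatError(f"invalid strand {strand!r}")
        if pos < 0:
            raise FormatError(f"negative position {pos}")
        if count == 0:
            return
        bucket = self._counts.setdefault((chrom, strand), {})
        bucket[pos] = bucket.get(pos, 0) + count

    def count(self, chrom: str, pos: int, strand: str) -> int:
        return self._counts.get((chrom, strand), {}).get(pos, 0)

    def items(self) -> Iterable[tuple[str, int, str, int]]:
        for (chrom, strand), bucket in self._counts.items():
            for pos in sorted(bucket):
                yield chrom, pos, strand, bucket[pos]

    def total(self) -> int:
        return sum(c for *_, c in self.items())

    @property
    def chrom_names(self) -> list[str]:
        return sorted({chrom for chrom, _ in self._counts})

    def __eq__(self, other) -> bool:
        if not isinstance(other, CpdProfile):
            return NotImplemented
        return dict(self._iter_nonzero()) == dict(other._iter_nonzero())

    def _iter_nonzero(self):
        for chrom, pos, strand, c in self.items():
            if c:
                yield (chrom, pos, strand), c


def read_wig_counts(
    path: str | Path,
    strand: str | None = None,
    into: CpdProfile | None = None,
) -> CpdProfile:
    """Read a UCSC text wiggle (fixedStep or variableStep) of lesion counts.

    Wiggle positions are 1-based and converted to internal 0-based; zero
    values are skipped. The strand comes from a ``strand=`` token on the
    track line, or the ``strand`` argument (which wins), defaulting to
    ``+``. Pass an existing profile as ``into`` to merge several files
    (e.g. a plus-strand and a minus-strand map).
    """
    profile = into if into is not None else CpdProfile()
    track_strand: str | None = None
    mode: str | None = None
    chrom: str | None = None
    step = span = 1
    nextpos = 0

    def current_strand() -> str:
        return strand or track_strand or "+"

    def parse_value(tok: str, lineno: int) -> int:
        try:
            v = float(tok)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric value {tok!r}") from None
        if v < 0:
            raise FormatError(f"{path}:{lineno}: negative value {v}")
        if v != int(v):
            raise FormatError(f"{path}:{lineno}: non-integer count {v}")
        return int(v)

    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("track"):
            for tok in line.split()[1:]:
                if tok.startswith("strand="):
                    track_strand = tok.split("=", 1)[1]
            continue
        first = line.split()[0]
        if first in ("fixedStep", "variableStep"):
            mode = first
            kv = dict(tok.split("=", 1) for tok in line.split()[1:])
            chrom = kv.get("chrom")
            if chrom is None:
                raise FormatError(f"{path}:{lineno}: declaration missing chrom=")
            span = int(kv.get("span", 1))
            if mode == "fixedStep":
                if "start" not in kv:
                    raise FormatError(f"{path}:{lineno}: fixedStep missing start=")
                nextpos = int(kv["start"])
                step = int(kv.get("step", 1))
            continue
        if mode is None:
            raise FormatError(
                f"{path}:{lineno}: data before a fixedStep/variableStep "
                f"declaration (unknown step type)"
            )
        toks = line.split()
        if mode == "variableStep":
            if len(toks) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'pos value'")
            pos1 = int(toks[0])
            value = parse_value(toks[1], lineno)
            start0 = pos1 - 1
        else:
            if len(toks) != 1:
                raise FormatError(f"{path}:{lineno}: expected a single value")
            value = parse_value(toks[0], lineno)
            start0 = nextpos - 1
            nextpos += step
        if value:
            for off in range(span):
                profile.add(chrom, start0 + off, current_strand(), value)
    if mode is None:
        raise FormatError(f"{path}: no wiggle declaration found")
    return profile


# Published rDNA locus boundaries on chromosome XII, given as 1-based
# inclusive prose coordinates and converted here to 0-based half-open.
RDNA_REGIONS_1BASED = (("chrXII", 451430, 468920), ("chrXII", 489928, 490455))


class RegionMask:
    """A set of half-open 0-based genomic intervals, merged per chromosome."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start >= end:
                raise FormatError(f"empty interval {chrom}:{start}-{end}")
            if start < 0:
                raise FormatError(f"negative interval start {start}")
            by_chrom.setdefault(chrom, []).append((start, end))
        self._by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged = [ivs[0]]
            for s, e in ivs[1:]:
                ls, le = merged[-1]
                if s <= le:
                    merged[-1] = (ls, max(le, e))
                else:
                    merged.append((s, e))
            self._by_chrom[chrom] = merged

    @classmethod
    def from_1based_inclusive(
        cls, intervals: Iterable[tuple[str, int, int]]
    ) -> "RegionMask":
        return cls((c, s - 1, e) for c, s, e in intervals)

    @classmethod
    def default_rdna(cls) -> "RegionMask":
        """The rDNA repeat regions excluded in the published analysis."""
        return cls.from_1based_inclusive(RDNA_REGIONS_1BASED)

    @classmethod
    def from_bed(cls, path: str | Path) -> "RegionMask":
        intervals = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: BED line needs >=3 columns")
            intervals.append((fields[0], int(fields[1]), int(fields[2])))
        return cls(intervals)

    @property
    def intervals(self) -> list[tuple[str, int, int]]:
        return [
            (chrom, s, e)
            for chrom, ivs in sorted(self._by_chrom.items())
            for s, e in ivs
        ]

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """Does [start, end) share any base with the mask?"""
        for s, e in self._by_chrom.get(chrom, ()):
            if s < end and start < e:
                return True
        return False

    def contains(self, chrom: str, pos: int) -> bool:
        return self.overlaps(chrom, pos, pos + 1)

    def bool_array(self, chrom: str, length: int) -> np.ndarray:
        """Boolean array over the chromosome: True where masked."""
        out = np.zeros(length, dtype=bool)
        for s, e in self._by_chrom.get(chrom, ()):
            out[max(s, 0) : min(e, length)] = True
        return out


Maskable = Union[Sequence[MutationRecord], CpdProfile]


def apply_mask(obj: Maskable, mask: RegionMask, invert: bool = False) -> Maskable:
    """Remove (or with ``invert=True``, keep only) items overlapping the mask.

    Works on mutation record lists (any shared reference base triggers
    overlap; insertions are tested at their single anchor position) and on
    CPD profiles (per lesion position).
    """
    if isinstance(obj, CpdProfile):
        out = CpdProfile()
        for chrom, pos, strand, count in obj.items():
            hit = mask.contains(chrom, pos)
            if hit == invert:
                out.add(chrom, pos, strand, count)
        return out
    kept = []
    for rec in obj:
        s, e = rec.span
        hit = mask.overlaps(rec.chrom, s, e)
        if hit == invert:
            kept.append(rec)
    return kept


@dataclass
class SignatureMatrix:
    """Mutational signatures over the 96 channels, columns summing to 1."""

    signature_names: list[str]
    values: np.ndarray  # shape (96, n_signatures)

    def __post_init__(self):
        if self.values.shape != (96, len(self.signature_names)):
            raise FormatError("signature matrix must be 96 x n_signatures")
        if (self.values < 0).any():
            raise FormatError("negative signature frequency")
        sums = self.values.sum(axis=0)
        if np.any(np.abs(sums - 1) > 1e-6):
            raise FormatError("signature columns must sum to 1")

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.signature_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(CHANNELS), columns=self.signature_names
        )


def read_signature_matrix(path: str | Path) -> SignatureMatrix:
    """Read a COSMIC v3-style tab-separated signature matrix.

    First column holds channel labels like ``A[C>A]A``; remaining columns
    are signatures. Channels are reordered to the canonical order and
    columns renormalised if within 1% of summing to 1.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = set(df.index)
    unknown = labels - set(CHANNELS)
    if unknown:
        raise FormatError(f"unknown channel labels: {sorted(unknown)[:3]}")
    if labels != set(CHANNELS):
        missing = sorted(set(CHANNELS) - labels)
        raise FormatError(f"missing channels (need 96): {missing[:3]}")
    if len(df.index) != 96:
        raise FormatError("duplicate channel labels")
    df = df.loc[list(CHANNELS)]
    values = df.to_numpy(dtype=float)
    sums = values.sum(axis=0)
    off = np.abs(sums - 1) > 0.01
    if off.any():
        bad = [df.columns[i] for i in np.flatnonzero(off)]
        raise FormatError(f"signature columns not normalised: {bad[:3]}")
    values = values / sums
    return SignatureMatrix(list(df.columns), values)
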