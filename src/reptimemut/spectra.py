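"""96-channel mutation spectra, composition-based expected counts, and
spectrum comparisons.

Expected counts per replication-timing bin answer the question "how many
mutations would each bin receive from sequence composition alone?": a
per-channel rate is estimated from the pooled covered genome
(observed_c / total census of the channel's trinucleotide) and applied to
each bin's trinucleotide census, so expected totals equal observed totals
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .contexts import CHANNELS, CHANNEL_TRINUC, channel_of
from .errors import DomainError, RefMismatchError, UndefinedSimilarityError
from .io_formats import GenomeSequence, MutationRecord
from .timing import BIN_LABELS


@dataclass
class SpectrumVector:
    """Counts over the 96 pyrimidine-strand trinucleotide channels."""

    counts: np.ndarray = field(default_factory=lambda: np.zeros(96))
    n_ref_mismatch: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise DomainError("spectrum must have exactly 96 channels")
        if (self.counts < 0).any():
            raise DomainError("negative channel count")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        if self.total == 0:
            raise UndefinedSimilarityError("empty spectrum has no frequencies")
        return self.counts / self.total

    def __add__(self, other: "SpectrumVector") -> "SpectrumVector":
        return SpectrumVector(
            self.counts + other.counts,
            self.n_ref_mismatch + other.n_ref_mismatch,
        )

    def to_frame(self) -> pd.DataFrame:
        freq = self.counts / self.total if self.total else np.zeros(96)
        return pd.DataFrame(
            {"channel": list(CHANNELS), "count": self.counts, "frequency": freq}
        )


def sbs_channel(genome: GenomeSequence, record: MutationRecord) -> int | None:
    """96-channel index of an SBS record, or None if undefined.

    Undefined when the record sits at a chromosome end (no flank) or any
    base of the trinucleotide is N. Raises :class:`RefMismatchError` when
    the genome base disagrees with the record's reference allele.
    """
    if record.mclass != "SBS":
        return None
    seq = genome.seq(record.chrom)
    if record.pos >= len(seq):
        raise DomainError(
            f"position {record.pos} beyond {record.chrom} ({len(seq)} bp)"
        )
    genome_ref = seq[record.pos]
    if genome_ref != record.ref:
        if genome_ref == "N" or record.ref == "N":
            return None
        raise RefMismatchError(
            f"{record.chrom}:{record.pos} genome has {genome_ref}, "
            f"record claims {record.ref}"
        )
    if record.pos == 0 or record.pos == len(seq) - 1:
        return None
    trinuc = seq[record.pos - 1 : record.pos + 2]
    return channel_of(trinuc, record.ref, record.alt)


def build_spectrum(
    records: Iterable[MutationRecord],
    genome: GenomeSequence,
    only: Callable[[MutationRecord], bool] | None = None,
) -> SpectrumVector:
    """Spectrum of the qualifying SBS records; indels never contribute.

    Records whose reference allele disagrees with the genome are skipped
    and tallied in ``n_ref_mismatch`` rather than aborting the run.
    """
    counts = np.zeros(96)
    mismatches = 0
    for rec in records:
        if rec.mclass != "SBS":
            continue
        if only is not None and not only(rec):
            continue
        try:
            ch = sbs_channel(genome, rec)
        except RefMismatchError:
            mismatches += 1
            continue
        if ch is not None:
            counts[ch] += 1
    return SpectrumVector(counts, n_ref_mismatch=mismatches)


@dataclass
class BinTable:
    """Observed vs expected counts per replication-timing bin."""

    observed: pd.Series
    expected: pd.Series

    def __post_init__(self):
        self.observed = self.observed.astype(float)
        self.expected = self.expected.reindex(self.observed.index).astype(float)
        tot_o, tot_e = self.observed.sum(), self.expected.sum()
        if tot_o > 0 and abs(tot_e - tot_o) > 1e-6 * tot_o:
            raise DomainError(
                f"expected total {tot_e} does not conserve observed total {tot_o}"
            )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"observed": self.observed, "expected": self.expected})
        df["observed_pct"] = 100 * df.observed / df.observed.sum()
        df["expected_pct"] = 100 * df.expected / df.expected.sum()
        return df


def channel_rates(
    observed: SpectrumVector, census_trinuc: pd.DataFrame
) -> np.ndarray:
    """Per-channel mutation rate over the pooled covered genome:
    observed_c / (total census of the channel's trinucleotide)."""
    census = census_trinuc.to_numpy(dtype=float)
    tot = census.sum(axis=1)
    obs = observed.counts
    per_channel_tot = tot[CHANNEL_TRINUC]
    bad = (obs > 0) & (per_channel_tot == 0)
    if bad.any():
        names = [CHANNELS[i] for i in np.flatnonzero(bad)]
        raise DomainError(
            f"census has zero sequence for contexts with observed mutations: "
            f"{names[:3]}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(
            per_channel_tot > 0, obs / np.maximum(per_channel_tot, 1e-300), 0.0
        )


def expected_from_rates(rates: np.ndarray, census_trinuc: pd.DataFrame) -> pd.Series:
    """Expected counts per bin given fixed per-channel rates."""
    census = census_trinuc.to_numpy(dtype=float)
    expected = rates @ census[CHANNEL_TRINUC]
    return pd.Series(expected, index=census_trinuc.columns)


def expected_counts(
    observed: SpectrumVector, census_trinuc: pd.DataFrame
) -> pd.Series:
    """Composition-based expected mutation counts per bin.

    ``census_trinuc`` is the 32-trinucleotide x bins table from
    :func:`reptimemut.timing.trinucleotide_bin_census`; it must cover the
    same region set that produced the observed spectrum. For each channel
    c with trinucleotide t(c): rate r_c = observed_c / sum_bins census[t(c)],
    expected[bin] = sum_c r_c * census[bin][t(c)].
    """
    return expected_from_rates(channel_rates(observed, census_trinuc), census_trinuc)


def bin_table(
    observed_counts: pd.Series, observed_spectrum: SpectrumVector,
    census_trinuc: pd.DataFrame,
) -> BinTable:
    """Convenience: observed per-bin counts paired with composition
    expectations from the same spectrum/census."""
    return BinTable(observed_counts, expected_counts(observed_spectrum, census_trinuc))


def spectrum_similarity(
    a: SpectrumVector | np.ndarray,
    b: SpectrumVector | np.ndarray,
    method: str = "cosine",
) -> float:
    """Similarity of two spectra on their frequency vectors.

    ``cosine``: a.b / (|a| |b|), in [0, 1] for nonnegative vectors.
    ``pearson_r2``: squared Pearson correlation of the 96 frequencies.
    """
    va = a.frequencies if isinstance(a, SpectrumVector) else np.asarray(a, float)
    vb = b.frequencies if isinstance(b, SpectrumVector) else np.asarray(b, float)
    if va.shape != vb.shape:
        raise DomainError("spectra must have the same number of channels")
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise UndefinedSimilarityError("zero vector has no direction")
    if method == "cosine":
        return float(va @ vb / (na * nb))
    if method == "pearson_r2":
        if np.all(va == va[0]) or np.all(vb == vb[0]):
            raise UndefinedSimilarityError("constant vector has no correlation")
        r = np.corrcoef(va, vb)[0, 1]
        return float(r * r)
    raise DomainError(f"unknown method {method!r}")


#: Reporting thresholds for COSMIC screens: cosine > 0.75 counts as high
#: similarity, > 0.59 as marginal.
COSINE_HIGH = 0.75
COSINE_MARGINAL = 0.59


def cosmic_screen(spectrum: SpectrumVector, matrix) -> pd.DataFrame:
    """Cosine similarity of a spectrum to every signature in a matrix.

    Returns one row per signature sorted by descending cosine, with a
    ``flag`` column marking high (>0.75) and marginal (>0.59) similarity.
    """
    freqs = spectrum.frequencies
    rows = []
    for name in matrix.signature_names:
        cos = spectrum_similarity(freqs, matrix.column(name), "cosine")
        flag = "high" if cos > COSINE_HIGH else (
            "marginal" if cos > COSINE_MARGINAL else ""
        )
        rows.append({"signature": name, "cosine": cos, "flag": flag})
    df = pd.DataFrame(rows).sort_values("cosine", ascending=False, kind="stable")
    return df.reset_index(drop=True)


def bin_counts_from_sites(sites, index=BIN_LABELS) -> pd.Series:
    """Count timed sites per major bin (helper shared by the pipelines)."""
    counts = pd.Series(0, index=list(index), dtype=int)
    for s in sites:
        counts[s.bin_label] += 1
    return counts
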