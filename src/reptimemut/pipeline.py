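"""End-to-end analyses mirroring the study's figure computations.

Each ``run_*`` function takes in-memory inputs, executes one analysis and
returns a result bundle of pandas tables plus test results; ``to_tsv``
writes every table with a stable header so outputs round-trip through the
readers. When a mask is supplied the analysis is run both without and
with it (the rDNA sensitivity-check pattern), and both bundles are
returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .complexmut import call_complex, complex_bin_table
from .cpd import (
    assign_lesion_positions,
    damage_bin_summary,
    repair_fraction,
    repeat_collapse_score,
    window_scan,
)
from .errors import DomainError, NoInformationError
from .io_formats import (
    CpdProfile,
    GenomeSequence,
    MutationRecord,
    RegionMask,
    SignatureMatrix,
    apply_mask,
)
from .spectra import (
    BinTable,
    SpectrumVector,
    bin_counts_from_sites,
    build_spectrum,
    channel_rates,
    cosmic_screen,
    expected_counts,
    expected_from_rates,
    spectrum_similarity,
)
from .stats import TestResult, chisq_gof, ninebin_regression, wilcoxon_matched_pairs
from .timing import (
    BIN_LABELS,
    ReplicationBins,
    TimingMap,
    assign_sites,
    compute_bins,
    trinucleotide_bin_census,
)

log = logging.getLogger("reptimemut")


@dataclass
class MutationAnalysis:
    """Per-bin observed/expected counts, chi-square, nine-bin regression,
    and per-bin spectra for one record set."""

    bin_table: BinTable
    chisq: TestResult
    nine_table: pd.DataFrame  # nine_bin, mean_time, count
    regression: TestResult
    spectra: dict[str, SpectrumVector]
    similarities: pd.DataFrame
    n_excluded_uncovered: int
    n_ref_mismatch: int

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "bin_table": self.bin_table.to_frame(),
            "nine_bin": self.nine_table,
            "similarities": self.similarities,
            "tests": _tests_frame(
                {"chisq_gof": self.chisq, "ninebin_regression": self.regression}
            ),
            **{
                f"spectrum_{name}": spec.to_frame()
                for name, spec in self.spectra.items()
            },
        }


def _tests_frame(tests: dict[str, TestResult]) -> pd.DataFrame:
    rows = []
    for name, t in tests.items():
        rows.append(
            {
                "test": name,
                "method": t.method,
                "statistic": t.statistic,
                "df": t.df if t.df is not None else "",
                "p_value": t.p_value,
                **t.estimates,
            }
        )
    return pd.DataFrame(rows)


def _covered_sbs(
    records: Sequence[MutationRecord], tmap: TimingMap, bins: ReplicationBins
):
    from .timing import interpolate_time

    sbs = [r for r in records if r.mclass == "SBS"]
    sites, excluded = assign_sites(sbs, tmap, bins)
    covered = [
        r for r in sbs if not np.isnan(interpolate_time(tmap, r.chrom, r.pos))
    ]
    return sbs, sites, covered, excluded


def run_mutation_analysis(
    genome: GenomeSequence,
    tmap: TimingMap,
    records: Sequence[MutationRecord],
    bins: ReplicationBins | None = None,
    mask: RegionMask | None = None,
) -> dict[str, MutationAnalysis]:
    """The core bin analysis: observed vs composition-expected SBS counts
    in early/middle/late bins with chi-square, plus the nine-bin
    regression of counts on mean replication time and per-bin spectra.

    Returns ``{"unmasked": ...}`` and additionally ``{"masked": ...}``
    when a mask is supplied.
    """
    if bins is None:
        bins = compute_bins(tmap)
    out: dict[str, MutationAnalysis] = {}
    for key, m in (("unmasked", None), ("masked", mask)):
        if key == "masked" and mask is None:
            continue
        recs = apply_mask(records, m) if m is not None else list(records)
        out[key] = _one_mutation_analysis(genome, tmap, bins, recs, m)
    return out


def _one_mutation_analysis(
    genome: GenomeSequence,
    tmap: TimingMap,
    bins: ReplicationBins,
    records: Sequence[MutationRecord],
    mask: RegionMask | None,
) -> MutationAnalysis:
    sbs, sites, covered, excluded = _covered_sbs(records, tmap, bins)
    if not sites:
        raise DomainError("no covered SBS records: empty analysis")
    log.info("mutation analysis: %d SBS, %d uncovered excluded", len(sbs), excluded)

    census = trinucleotide_bin_census(genome, tmap, bins, mask=mask)
    spectrum = build_spectrum(covered, genome)
    observed = bin_counts_from_sites(sites)
    if spectrum.total == 0:
        raise DomainError("no SBS with a defined trinucleotide channel")
    # expected totals conserve the spectrum total; rescale to the (possibly
    # slightly larger) site total, which also counts channel-undefined SBS
    expected = expected_counts(spectrum, census.trinuc)
    table = BinTable(
        observed.astype(float), expected * observed.sum() / spectrum.total
    )
    chisq = chisq_gof(table.observed.to_numpy(), table.expected.to_numpy())

    nine_counts = np.zeros(9)
    for s in sites:
        nine_counts[s.nine_bin_index - 1] += 1
    nine_table = pd.DataFrame(
        {
            "nine_bin": np.arange(1, 10),
            "mean_time": census.nine_time_mean,
            "count": nine_counts,
        }
    )
    regression = ninebin_regression(nine_counts, census.nine_time_mean)

    spectra = {"all": spectrum}
    for lbl in BIN_LABELS:
        keep = {
            (s.chrom, s.pos) for s in sites if s.bin_label == lbl
        }
        spectra[lbl] = build_spectrum(
            covered, genome, only=lambda r, k=keep: (r.chrom, r.pos) in k
        )
    sim_rows = []
    labels = list(BIN_LABELS)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            if spectra[a].total and spectra[b].total:
                sim_rows.append(
                    {
                        "pair": f"{a}-{b}",
                        "cosine": spectrum_similarity(spectra[a], spectra[b], "cosine"),
                        "pearson_r2": spectrum_similarity(
                            spectra[a], spectra[b], "pearson_r2"
                        ),
                    }
                )
    return MutationAnalysis(
        bin_table=table,
        chisq=chisq,
        nine_table=nine_table,
        regression=regression,
        spectra=spectra,
        similarities=pd.DataFrame(sim_rows),
        n_excluded_uncovered=excluded,
        n_ref_mismatch=spectrum.n_ref_mismatch,
    )


@dataclass
class PerChromosomeResult:
    table: pd.DataFrame  # chrom, observed/expected late percents, counts
    wilcoxon: TestResult | None
    n_chrom_skipped: int


def run_per_chromosome(
    genome: GenomeSequence,
    tmap: TimingMap,
    records: Sequence[MutationRecord],
    bins: ReplicationBins | None = None,
    mask: RegionMask | None = None,
    alternative: str = "two_sided",
) -> PerChromosomeResult:
    """Per-chromosome early/late mutation percentages vs composition
    expectations, with a Wilcoxon matched-pairs signed-rank test on the
    late percentages across chromosomes.

    Expected percentages use genome-wide per-channel rates applied to each
    chromosome's own trinucleotide census. Chromosomes with zero covered
    mutations are excluded and logged.
    """
    if bins is None:
        bins = compute_bins(tmap)
    recs = apply_mask(records, mask) if mask is not None else list(records)
    _, _, covered, _ = _covered_sbs(recs, tmap, bins)
    if not covered:
        raise DomainError("no covered SBS records: empty analysis")
    pooled_census = trinucleotide_bin_census(genome, tmap, bins, mask=mask)
    pooled_spectrum = build_spectrum(covered, genome)
    rates = channel_rates(pooled_spectrum, pooled_census.trinuc)

    rows = []
    skipped = 0
    for chrom in genome.chrom_names:
        if chrom not in tmap.chrom_names:
            skipped += 1
            continue
        chrom_recs = [r for r in covered if r.chrom == chrom]
        sites, _ = assign_sites(chrom_recs, tmap, bins)
        counts = bin_counts_from_sites(sites)
        if counts.sum() == 0:
            log.info("per-chromosome: %s has no covered mutations, skipped", chrom)
            skipped += 1
            continue
        census_c = trinucleotide_bin_census(
            genome, tmap, bins, mask=mask, chroms=[chrom]
        )
        expected = expected_from_rates(rates, census_c.trinuc)
        rows.append(
            {
                "chrom": chrom,
                "n_mutations": int(counts.sum()),
                "observed_early_pct": 100 * counts["early"] / counts.sum(),
                "observed_late_pct": 100 * counts["late"] / counts.sum(),
                "expected_early_pct": 100 * expected["early"] / expected.sum(),
                "expected_late_pct": 100 * expected["late"] / expected.sum(),
            }
        )
    table = pd.DataFrame(rows)
    wilcoxon = None
    if len(table) >= 5:
        try:
            wilcoxon = wilcoxon_matched_pairs(
                table["observed_late_pct"].to_numpy(),
                table["expected_late_pct"].to_numpy(),
                alternative=alternative,
            )
        except NoInformationError:
            log.warning("per-chromosome Wilcoxon: no informative pairs")
    return PerChromosomeResult(table, wilcoxon, skipped)


@dataclass
class ComplexAnalysis:
    n_events: int
    n_complex_records: int
    n_simple_records: int
    bin_table: BinTable
    chisq: TestResult | None
    events_table: pd.DataFrame
    nine_table: pd.DataFrame | None
    regression: TestResult | None
    complex_spectrum: SpectrumVector
    cosmic: pd.DataFrame | None
    n_excluded_uncovered: int

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {
            "complex_bin_table": self.bin_table.to_frame(),
            "events": self.events_table,
            "complex_spectrum": self.complex_spectrum.to_frame(),
        }
        if self.nine_table is not None:
            out["complex_nine_bin"] = self.nine_table
        tests = {}
        if self.chisq is not None:
            tests["chisq_gof"] = self.chisq
        if self.regression is not None:
            tests["ninebin_regression"] = self.regression
        if tests:
            out["tests"] = _tests_frame(tests)
        if self.cosmic is not None:
            out["cosmic_screen"] = self.cosmic
        return out


def run_complex_analysis(
    genome: GenomeSequence,
    tmap: TimingMap,
    records: Sequence[MutationRecord],
    bins: ReplicationBins | None = None,
    mask: RegionMask | None = None,
    max_gap: int = 10,
    signature_matrix: SignatureMatrix | None = None,
) -> ComplexAnalysis:
    """Call complex events and compare their timing distribution to
    SBS-proportional expectations; optionally screen the complex-SBS
    spectrum against a COSMIC signature matrix."""
    if bins is None:
        bins = compute_bins(tmap)
    recs = apply_mask(records, mask) if mask is not None else list(records)
    events, complex_records, simple_records = call_complex(recs, max_gap=max_gap)

    sbs = [r for r in recs if r.mclass == "SBS"]
    sbs_sites, _ = assign_sites(sbs, tmap, bins)
    sbs_counts = bin_counts_from_sites(sbs_sites)

    table, excluded = complex_bin_table(events, tmap, bins, sbs_counts)
    chisq = None
    if table.observed.sum() > 0 and (table.expected > 0).all():
        chisq = chisq_gof(table.observed.to_numpy(), table.expected.to_numpy())

    members = [m for ev in events for m in ev.members]
    member_sites, _ = assign_sites(members, tmap, bins)
    nine_table = regression = None
    if member_sites:
        census = trinucleotide_bin_census(genome, tmap, bins, mask=mask)
        nine_counts = np.zeros(9)
        for s in member_sites:
            nine_counts[s.nine_bin_index - 1] += 1
        nine_table = pd.DataFrame(
            {
                "nine_bin": np.arange(1, 10),
                "mean_time": census.nine_time_mean,
                "count": nine_counts,
            }
        )
        if not np.all(nine_counts == nine_counts[0]):
            regression = ninebin_regression(nine_counts, census.nine_time_mean)

    complex_spectrum = build_spectrum(members, genome)
    cosmic = None
    if signature_matrix is not None and complex_spectrum.total > 0:
        cosmic = cosmic_screen(complex_spectrum, signature_matrix)

    events_table = pd.DataFrame(
        [
            {
                "isolate": ev.isolate,
                "chrom": ev.chrom,
                "start": ev.members[0].pos,
                "end": ev.members[-1].pos + 1,
                "n_members": len(ev.members),
                "classes": ",".join(m.mclass for m in ev.members),
            }
            for ev in events
        ]
    )
    return ComplexAnalysis(
        n_events=len(events),
        n_complex_records=len(complex_records),
        n_simple_records=len(simple_records),
        bin_table=table,
        chisq=chisq,
        events_table=events_table,
        nine_table=nine_table,
        regression=regression,
        complex_spectrum=complex_spectrum,
        cosmic=cosmic,
        n_excluded_uncovered=excluded,
    )


@dataclass
class CpdAnalysis:
    summary: pd.DataFrame  # per-bin assigned counts and percents
    repair: pd.Series | None
    window_track: pd.DataFrame
    collapse_score: float | None
    n_end_clipped: int

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {"cpd_summary": self.summary, "window_track": self.window_track}
        if self.repair is not None:
            out["repair_fraction"] = self.repair.rename_axis("bin").reset_index()
        return out


def run_cpd_analysis(
    genome: GenomeSequence,
    tmap: TimingMap,
    profile_0h: CpdProfile,
    profile_repair: CpdProfile | None = None,
    bins: ReplicationBins | None = None,
    mask: RegionMask | None = None,
    window: int = 1000,
    normalization: str = "none",
    collapse_candidate: RegionMask | None = None,
) -> dict[str, CpdAnalysis]:
    """CPD damage-map analysis: both-position assignment, per-bin percents
    paired with dipyrimidine percents, optional repair fractions, a 1-kb
    window track, and a collapse score for a candidate repeat region.

    Returns ``{"unmasked": ...}`` plus ``{"masked": ...}`` when a mask is
    supplied.
    """
    if bins is None:
        bins = compute_bins(tmap)
    out: dict[str, CpdAnalysis] = {}
    for key, m in (("unmasked", None), ("masked", mask)):
        if key == "masked" and mask is None:
            continue
        census = trinucleotide_bin_census(genome, tmap, bins, mask=m)
        # masking is applied at the assigned-position level, so the masked
        # totals are exactly the unmasked totals minus the in-mask counts
        assigned0 = assign_lesion_positions(profile_0h, genome)
        s0 = damage_bin_summary(assigned0, tmap, bins, census, mask=m, label="0h")
        repair = None
        if profile_repair is not None:
            st = damage_bin_summary(
                assign_lesion_positions(profile_repair, genome),
                tmap,
                bins,
                census,
                mask=m,
                label="repair",
            )
            repair = repair_fraction(st, s0, normalization=normalization)
        track = window_scan(assigned0, tmap, bins, width=window)
        score = None
        if collapse_candidate is not None and m is None:
            score = repeat_collapse_score(track, collapse_candidate)
        out[key] = CpdAnalysis(
            summary=s0.table,
            repair=repair,
            window_track=track,
            collapse_score=score,
            n_end_clipped=assigned0.n_end_clipped,
        )
    return out


def write_tables(tables: dict[str, pd.DataFrame], outdir: str | Path) -> list[Path]:
    """Write every result table as TSV with a header line."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        path = outdir / f"{name}.tsv"
        frame = df.copy()
        if frame.index.name or not isinstance(frame.index, pd.RangeIndex):
            frame = frame.rename_axis(frame.index.name or "bin").reset_index()
        frame.to_csv(path, sep="\t", index=False)
        written.append(path)
    return written
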