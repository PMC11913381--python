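"""Synthetic genomes, timing maps, mutation call sets and CPD profiles.

Every generator is deterministic under the config seed and emulates the
statistical structure of the real study inputs at a reduced scale:

* a multi-chromosome genome of i.i.d. bases at a yeast-like GC fraction;
* a piecewise-linear replication-timing map produced by origins firing at
  sampled times with forks travelling at constant speed (V-shaped timing
  profiles sampled at 500-bp anchors, leaving chromosome ends uncovered);
* UV-like mutations placed per trinucleotide context (C>T at dipyrimidine
  contexts dominant) with a multiplicative log-linear replication-time
  effect exp(beta * time) on the per-site rate;
* explicitly seeded clustered events (2-4 mutations within 10 bp in one
  isolate) whose rate also scales with replication time, so caller truth
  is known exactly;
* Poisson CPD lesion counts proportional to dipyrimidine content, with
  one region whose counts are inflated by copy_number/reference_copies to
  emulate the rDNA repeat-collapse coverage artifact, and a repaired
  sample obtained by binomial thinning with per-bin survival fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .contexts import BASES, CHANNELS, channel_of, encode
from .errors import DomainError
from .io_formats import (
    CpdProfile,
    GenomeSequence,
    MutationRecord,
    RegionMask,
    write_mutation_bed,
)
from .timing import ReplicationBins, TimingMap, interpolate_times


def default_channel_weights() -> np.ndarray:
    """UV-like relative mutability of the 96 channels.

    C>T transitions dominate, especially with a pyrimidine 5' flank
    (the dipyrimidine context where CPDs form).
    """
    w = np.ones(96)
    for i, label in enumerate(CHANNELS):
        sub = label[2:5]
        five = label[0]
        if sub == "C>T":
            w[i] = 25.0 if five in "CT" else 5.0
    return w


@dataclass
class SimConfig:
    """Parameters of the synthetic study; defaults are the package's
    standing test-bed conditions (a ~1/20-scale yeast-like genome)."""

    n_chroms: int = 8
    chrom_length: int = 75_000
    gc_fraction: float = 0.38
    anchor_spacing: int = 500
    n_origins: int = 2
    fork_speed: float = 1500.0  # bp per minute
    origin_time_range: tuple[float, float] = (10.0, 30.0)
    timing_effect: float = 0.0  # beta: log-linear multiplier per minute
    n_mutations: float = 12_000.0  # expected background SBS count
    base_rate: float | None = None  # per-site scale; derived from n_mutations if None
    n_isolates: int = 48
    complex_rate: float = 0.0  # expected events per covered site
    complex_timing_effect: float = 0.0
    cpd_rate: float = 0.05  # expected lesions per dipyrimidine per strand
    repeat_region: tuple[str, int, int] | None = ("chr08", 40_000, 50_000)
    copy_number: int = 150
    reference_copies: int = 2
    survival: tuple[float, float, float] = (0.3, 0.3, 0.3)  # per bin, early/mid/late
    seed: int = 0

    def __post_init__(self):
        if self.chrom_length <= 0 or self.n_chroms <= 0:
            raise DomainError("genome dimensions must be positive")
        if not 0 <= self.gc_fraction <= 1:
            raise DomainError("gc_fraction must lie in [0, 1]")
        if self.copy_number < 1 or self.reference_copies < 1:
            raise DomainError("copy numbers must be >= 1")
        if min(self.cpd_rate, self.n_mutations, self.complex_rate) < 0:
            raise DomainError("rates must be >= 0")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1:02d}" for i in range(self.n_chroms)]


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    # independent, order-insensitive streams per generator
    return np.random.default_rng([cfg.seed, stream])


def gen_genome(cfg: SimConfig) -> GenomeSequence:
    """I.i.d. bases at the configured GC fraction."""
    rng = _rng(cfg, 1)
    gc = cfg.gc_fraction
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seqs = {}
    for name in cfg.chrom_names:
        codes = rng.choice(4, size=cfg.chrom_length, p=p)
        seqs[name] = "".join(BASES[c] for c in codes)
    return GenomeSequence(seqs)


def gen_timing_map(cfg: SimConfig, genome: GenomeSequence) -> TimingMap:
    """Origin-firing timing model sampled at the anchor spacing.

    time(pos) = min over origins of (firing_time + |pos - origin| / fork_speed),
    sampled every ``anchor_spacing`` bp from position 250 to ~250 bp short
    of the chromosome end (so chromosome extremities are uncovered, as in
    the real map).
    """
    rng = _rng(cfg, 2)
    anchors: dict[str, list[tuple[float, float]]] = {}
    lo, hi = cfg.origin_time_range
    for chrom in genome.chrom_names:
        L = genome.length(chrom)
        origins = rng.uniform(0, L, size=cfg.n_origins)
        fire = rng.uniform(lo, hi, size=cfg.n_origins)
        pos = np.arange(250, L - 250, cfg.anchor_spacing, dtype=float)
        if len(pos) < 2:
            raise DomainError(f"{chrom}: too short for a timing map")
        times = np.min(
            fire[:, None] + np.abs(pos[None, :] - origins[:, None]) / cfg.fork_speed,
            axis=0,
        )
        anchors[chrom] = list(zip(pos, times))
    return TimingMap(anchors, spacing=cfg.anchor_spacing)


def mean_bin_times(tmap: TimingMap, bins: ReplicationBins) -> pd.Series:
    """Span-weighted mean interval time per major bin."""
    spans, mids = [], []
    for chrom in tmap.chrom_names:
        pos, time = tmap.anchors(chrom)
        spans.append(np.diff(pos))
        mids.append((time[:-1] + time[1:]) / 2)
    spans = np.concatenate(spans)
    mids = np.concatenate(mids)
    cuts = np.array([bins.cut_early_mid, bins.cut_mid_late])
    idx = np.searchsorted(cuts, mids, side="right")
    out = {}
    for i, lbl in enumerate(("early", "middle", "late")):
        sel = idx == i
        out[lbl] = float(np.average(mids[sel], weights=spans[sel]))
    return pd.Series(out)


def beta_for_contrast(
    contrast: float, tmap: TimingMap, bins: ReplicationBins
) -> float:
    """Timing effect beta giving a target late-vs-early rate contrast.

    ``contrast`` is the fractional excess of the late-bin per-site rate
    over the early-bin rate (0.36 -> late 36% above early; negative values
    enrich early). beta = ln(1 + contrast) / (mean_late_time - mean_early_time).
    """
    if contrast <= -1:
        raise DomainError("contrast must exceed -1")
    mt = mean_bin_times(tmap, bins)
    return float(np.log1p(contrast) / (mt["late"] - mt["early"]))


def _site_weights(codes: np.ndarray) -> np.ndarray:
    """Per-site relative mutability: sum of its three channels' weights."""
    w = default_channel_weights()
    trinuc_weight = np.zeros(32)
    for i in range(96):
        label = CHANNELS[i]
        from .contexts import TRINUC_INDEX

        trinuc_weight[TRINUC_INDEX[label[0] + label[2] + label[6]]] += w[i]
    out = np.zeros(len(codes))
    if len(codes) < 3:
        return out
    ok = (codes[:-2] < 4) & (codes[1:-1] < 4) & (codes[2:] < 4)
    tri64 = codes[:-2].astype(np.int64) * 16 + codes[1:-1] * 4 + codes[2:]
    from .contexts import TRINUC64_TO_CANON

    centre = np.arange(1, len(codes) - 1)
    out[centre[ok]] = trinuc_weight[TRINUC64_TO_CANON[tri64[ok]]]
    return out


def _draw_alt(
    rng: np.random.Generator, trinuc: str, ref: str, weights: np.ndarray
) -> str:
    alts = [b for b in BASES if b != ref]
    w = []
    for alt in alts:
        ch = channel_of(trinuc, ref, alt)
        w.append(weights[ch] if ch is not None else 1.0)
    w = np.asarray(w)
    return alts[rng.choice(3, p=w / w.sum())]


_ALT_TABLES: tuple[np.ndarray, np.ndarray] | None = None


def _alt_tables() -> tuple[np.ndarray, np.ndarray]:
    """Per-trinucleotide alt-base lookup for vectorised drawing.

    Returns (alts, cum): for each of the 64 A/C/G/T trinucleotide ids,
    the three possible alternate bases and the cumulative channel-weight
    probabilities over them.
    """
    global _ALT_TABLES
    if _ALT_TABLES is None:
        weights = default_channel_weights()
        alts = np.empty((64, 3), dtype="<U1")
        cum = np.empty((64, 3))
        for a in range(4):
            for b in range(4):
                for c in range(4):
                    t64 = 16 * a + 4 * b + c
                    trinuc = BASES[a] + BASES[b] + BASES[c]
                    ref = BASES[b]
                    choices = [x for x in BASES if x != ref]
                    w = []
                    for alt in choices:
                        ch = channel_of(trinuc, ref, alt)
                        w.append(weights[ch] if ch is not None else 1.0)
                    w = np.asarray(w)
                    alts[t64] = choices
                    cum[t64] = np.cumsum(w / w.sum())
        _ALT_TABLES = (alts, cum)
    return _ALT_TABLES


def gen_mutations(
    cfg: SimConfig, genome: GenomeSequence, tmap: TimingMap
) -> tuple[list[MutationRecord], pd.DataFrame]:
    """Poisson mutation calls with a log-linear replication-time effect.

    Per covered site, the SBS rate is
    base_rate * site_weight(trinucleotide) * exp(timing_effect * time);
    ``base_rate`` is derived from ``n_mutations`` when unset so the
    expected background count matches the configured study size. Seeded
    clustered events (2-4 members within <= 10 bp, one isolate) are added
    at rate complex_rate * exp(complex_timing_effect * time) per site.

    Returns the records plus a truth table with each record's replication
    time and seeded event id (-1 for background mutations).
    """
    rng = _rng(cfg, 3)
    weights = default_channel_weights()
    records: list[MutationRecord] = []
    truth_rows: list[dict] = []

    # per-chromosome site rates
    site_lambda: dict[str, np.ndarray] = {}
    times_by_chrom: dict[str, np.ndarray] = {}
    for chrom in genome.chrom_names:
        codes = encode(genome.seq(chrom))
        times = interpolate_times(tmap, chrom, np.arange(len(codes)))
        covered = ~np.isnan(times)
        lam = _site_weights(codes)
        lam[~covered] = 0.0
        lam[covered] *= np.exp(cfg.timing_effect * times[covered])
        site_lambda[chrom] = lam
        times_by_chrom[chrom] = times

    total_weight = sum(lam.sum() for lam in site_lambda.values())
    if total_weight == 0:
        raise DomainError("no covered mutable sites")
    base_rate = (
        cfg.base_rate if cfg.base_rate is not None else cfg.n_mutations / total_weight
    )

    alt_lut, alt_cum = _alt_tables()
    event_id = 0
    for chrom in genome.chrom_names:
        seq = genome.seq(chrom)
        codes = encode(seq)
        lam = site_lambda[chrom] * base_rate
        times = times_by_chrom[chrom]
        counts = rng.poisson(lam)
        hit = np.flatnonzero(counts)
        positions = np.repeat(hit, counts[hit])
        if len(positions):
            t64 = (
                codes[positions - 1].astype(np.int64) * 16
                + codes[positions] * 4
                + codes[positions + 1]
            )
            u = rng.random(len(positions))
            alt_idx = (u[:, None] > alt_cum[t64]).sum(axis=1)
            alt_bases = alt_lut[t64, alt_idx]
            isolates = rng.integers(cfg.n_isolates, size=len(positions))
            for pos, alt, iso_i in zip(positions, alt_bases, isolates):
                pos = int(pos)
                iso = f"iso{iso_i:03d}"
                records.append(MutationRecord(chrom, pos, seq[pos], str(alt), iso))
                truth_rows.append(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "isolate": iso,
                        "time": float(times[pos]),
                        "event_id": -1,
                    }
                )

        # seeded clustered (complex) events
        if cfg.complex_rate > 0:
            covered = ~np.isnan(times)
            ev_lam = np.zeros(len(times))
            ev_lam[covered] = cfg.complex_rate * np.exp(
                cfg.complex_timing_effect * times[covered]
            )
            n_events = rng.poisson(ev_lam.sum())
            if n_events and ev_lam.sum() > 0:
                p = ev_lam / ev_lam.sum()
                starts = rng.choice(len(times), size=n_events, p=p)
                for start in np.sort(starts):
                    size = int(rng.integers(2, 5))
                    gaps = rng.integers(1, 11, size=size - 1)
                    positions = start + np.concatenate([[0], np.cumsum(gaps)])
                    positions = positions[positions < len(seq) - 1]
                    positions = positions[~np.isnan(times[positions])]
                    if len(positions) < 2:
                        continue
                    iso = f"iso{rng.integers(cfg.n_isolates):03d}"
                    for pos in positions:
                        pos = int(pos)
                        ref = seq[pos]
                        if ref == "N":
                            continue
                        alt = _draw_alt(rng, seq[pos - 1 : pos + 2], ref, weights)
                        records.append(MutationRecord(chrom, pos, ref, alt, iso))
                        truth_rows.append(
                            {
                                "chrom": chrom,
                                "pos": pos,
                                "isolate": iso,
                                "time": float(times[pos]),
                                "event_id": event_id,
                            }
                        )
                    event_id += 1

    truth = pd.DataFrame(
        truth_rows, columns=["chrom", "pos", "isolate", "time", "event_id"]
    )
    return records, truth


def gen_cpd(
    cfg: SimConfig,
    genome: GenomeSequence,
    tmap: TimingMap | None = None,
    bins: ReplicationBins | None = None,
) -> tuple[CpdProfile, CpdProfile]:
    """Poisson lesion counts at dipyrimidines, plus a repaired sample.

    Plus-strand lesions sit at reference pyrimidine pairs, minus-strand
    lesions at purine pairs (recorded at the 5' position on the lesion
    strand, i.e. the higher reference coordinate). Counts inside
    ``repeat_region`` are inflated by copy_number/reference_copies to
    emulate the collapsed-repeat mapping artifact. The repaired sample is
    a binomial thinning of the 0 h sample with per-bin survival fractions
    (genome-wide mean survival where no timing/bins are supplied).
    """
    rng = _rng(cfg, 4)
    t0 = CpdProfile()
    trep = CpdProfile()
    fold = cfg.copy_number / cfg.reference_copies
    surv = np.asarray(cfg.survival, dtype=float)
    cuts = (
        np.array([bins.cut_early_mid, bins.cut_mid_late])
        if bins is not None
        else None
    )
    for chrom in genome.chrom_names:
        codes = encode(genome.seq(chrom))
        L = len(codes)
        from .contexts import IS_PURINE, IS_PYRIMIDINE

        a, b = codes[:-1], codes[1:]
        plus_sites = np.flatnonzero(IS_PYRIMIDINE[a] & IS_PYRIMIDINE[b])
        minus_sites = np.flatnonzero(IS_PURINE[a] & IS_PURINE[b])

        inflate = np.ones(L)
        if cfg.repeat_region is not None and cfg.repeat_region[0] == chrom:
            _, rs, re = cfg.repeat_region
            inflate[rs:re] = fold

        if tmap is not None and cuts is not None and chrom in tmap.chrom_names:
            times = interpolate_times(tmap, chrom, np.arange(L))
            site_surv = np.full(L, surv.mean())
            cov = ~np.isnan(times)
            site_surv[cov] = surv[np.searchsorted(cuts, times[cov], side="right")]
        else:
            site_surv = np.full(L, surv.mean())

        for sites, strand in ((plus_sites, "+"), (minus_sites, "-")):
            lam = cfg.cpd_rate * inflate[sites]
            counts = rng.poisson(lam)
            hit = counts > 0
            # lesion coordinate: 5' position on the lesion strand
            lesion_pos = sites[hit] if strand == "+" else sites[hit] + 1
            for pos, c in zip(lesion_pos, counts[hit]):
                t0.add(chrom, int(pos), strand, int(c))
                remaining = rng.binomial(int(c), site_surv[pos])
                if remaining:
                    trep.add(chrom, int(pos), strand, int(remaining))
    return t0, trep


def repeat_region_mask(cfg: SimConfig) -> RegionMask | None:
    if cfg.repeat_region is None:
        return None
    chrom, s, e = cfg.repeat_region
    return RegionMask([(chrom, s, e)])


def write_bundle(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write a full input bundle (FASTA, timing TSV, mutation
    BED, per-strand wiggle pairs for both CPD samples, truth TSV)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = gen_genome(cfg)
    tmap = gen_timing_map(cfg, genome)
    records, truth = gen_mutations(cfg, genome, tmap)
    t0, trep = gen_cpd(cfg, genome, tmap)

    paths = {
        "genome": outdir / "genome.fa",
        "timing": outdir / "timing.tsv",
        "mutations": outdir / "mutations.bed",
        "truth": outdir / "mutations_truth.tsv",
    }
    genome.to_fasta(paths["genome"])
    tmap.to_tsv(paths["timing"])
    write_mutation_bed(records, paths["mutations"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    for sample, profile in (("0h", t0), ("repair", trep)):
        for strand, tag in (("+", "plus"), ("-", "minus")):
            p = outdir / f"cpd_{sample}_{tag}.wig"
            _write_wig(profile, strand, p)
            paths[f"cpd_{sample}_{tag}"] = p
    return paths


def _write_wig(profile: CpdProfile, strand: str, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"track type=wiggle_0 strand={strand}\n")
        last_chrom = None
        for chrom, pos, s, count in profile.items():
            if s != strand:
                continue
            if chrom != last_chrom:
                fh.write(f"variableStep chrom={chrom}\n")
                last_chrom = chrom
            fh.write(f"{pos + 1} {count}\n")
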