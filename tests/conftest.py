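import numpy as np
import pytest

import reptimemut as rm


@pytest.fixture(scope="session")
def toy_genome() -> rm.GenomeSequence:
    # 40 bp chromosomes with mixed composition, plus one with an N
    return rm.GenomeSequence(
        {
            "chrI": "ACGTTCCTAGGTTTCCAAGGACGTACGTTCCTAGGTACGT",
            "chrII": "TTCCGGAATTCCGGAATTCCGGAATTCCGGAATTCCGGAA",
            "chrN": "ACGTNACGTACGTACGTACGTACGTACGTACGTACGTACG",
        }
    )


@pytest.fixture(scope="session")
def toy_map() -> rm.TimingMap:
    # covers positions 2..38 of each toy chromosome
    return rm.TimingMap(
        {
            "chrI": [(2, 10.0), (14, 22.0), (26, 40.0), (38, 16.0)],
            "chrII": [(2, 30.0), (14, 12.0), (26, 24.0), (38, 36.0)],
            "chrN": [(2, 19.0), (14, 25.0), (26, 13.0), (38, 35.0)],
        },
        spacing=12,
    )


@pytest.fixture(scope="session")
def toy_bins(toy_map) -> rm.ReplicationBins:
    return rm.compute_bins(toy_map)


@pytest.fixture(scope="session")
def sim_small():
    """A small but non-trivial synthetic study used by several suites."""
    cfg = rm.SimConfig(
        seed=11,
        n_chroms=4,
        chrom_length=30_000,
        n_mutations=3_000,
        complex_rate=3e-5,
        repeat_region=("chr04", 20_000, 24_000),
        cpd_rate=0.05,
    )
    genome = rm.gen_genome(cfg)
    tmap = rm.gen_timing_map(cfg, genome)
    bins = rm.compute_bins(tmap)
    records, truth = rm.gen_mutations(cfg, genome, tmap)
    return cfg, genome, tmap, bins, records, truth


def brute_force_times(tmap: rm.TimingMap, chrom: str) -> np.ndarray:
    """Independent per-base oracle: walk every anchor interval and apply
    the interpolation formula directly at each base."""
    pos, time = tmap.anchors(chrom)
    first, last = int(pos[0]), int(pos[-1])
    out = np.full(last + 1, np.nan)
    for i in range(len(pos) - 1):
        pos1, pos2 = pos[i], pos[i + 1]
        time1, time2 = time[i], time[i + 1]
        for p in range(int(pos1), int(pos2) + 1):
            out[p] = time1 + (time2 - time1) * ((p - pos1) / (pos2 - pos1))
    out[last] = time[-1]
    out[:first] = np.nan
    return out
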