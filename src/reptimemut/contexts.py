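"""Trinucleotide-context machinery for 96-channel mutation spectra.

Substitutions are reported on the pyrimidine strand: a mutated purine is
reverse-complemented together with its flanks so every channel has a C or T
in the middle. Channel order follows the COSMIC convention — substitution
class major (C>A, C>G, C>T, T>A, T>C, T>G), then 5' flank, then 3' flank,
each in A, C, G, T order — giving labels like ``A[C>A]A`` ... ``T[T>G]T``.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")

#: The six pyrimidine-strand substitution classes, COSMIC order.
SUB_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: The 96 channel labels in canonical order.
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUB_CLASSES
    for five in BASES
    for three in BASES
)

CHANNEL_INDEX = {label: i for i, label in enumerate(CHANNELS)}

#: The 32 pyrimidine-centred trinucleotides, ordered consistently with
#: CHANNELS (channel i uses trinucleotide CHANNEL_TRINUC[i]).
TRINUC_32: tuple[str, ...] = tuple(
    f"{five}{centre}{three}"
    for centre in "CT"
    for five in BASES
    for three in BASES
)
TRINUC_INDEX = {t: i for i, t in enumerate(TRINUC_32)}

#: For each of the 96 channels, the index into TRINUC_32 of its underlying
#: trinucleotide (channels sharing a trinucleotide share its census).
CHANNEL_TRINUC = np.array(
    [TRINUC_INDEX[label[0] + label[2] + label[6]] for label in CHANNELS]
)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def canonical_trinuc(trinuc: str) -> str | None:
    """Map a trinucleotide to its pyrimidine-centred representative.

    Returns ``None`` if any base is not in {A,C,G,T}.
    """
    if len(trinuc) != 3 or any(b not in "ACGT" for b in trinuc):
        return None
    if trinuc[1] in PYRIMIDINES:
        return trinuc
    return revcomp(trinuc)


def channel_of(trinuc: str, ref: str, alt: str) -> int | None:
    """96-channel index for a substitution ``ref>alt`` at context ``trinuc``.

    ``trinuc[1]`` must equal ``ref``. Purine refs are folded onto the
    pyrimidine strand. Returns ``None`` when any base is ambiguous.
    """
    if any(b not in "ACGT" for b in trinuc + alt) or trinuc[1] != ref:
        return None
    if ref in PURINES:
        trinuc = revcomp(trinuc)
        ref = COMPLEMENT[ref]
        alt = COMPLEMENT[alt]
    label = f"{trinuc[0]}[{ref}>{alt}]{trinuc[2]}"
    return CHANNEL_INDEX.get(label)


# ---------------------------------------------------------------------------
# Vectorised sequence coding. Bases map A,C,G,T -> 0..3 and anything else
# (N and IUPAC ambiguity codes) -> 4.

_CODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i

#: 64-entry map: trinucleotide id (16*a + 4*b + c over base codes) ->
#: canonical index in TRINUC_32.
TRINUC64_TO_CANON = np.empty(64, dtype=np.int64)
for _a in range(4):
    for _b in range(4):
        for _c in range(4):
            _t = BASES[_a] + BASES[_b] + BASES[_c]
            TRINUC64_TO_CANON[16 * _a + 4 * _b + _c] = TRINUC_INDEX[
                canonical_trinuc(_t)
            ]

#: True where a base code is a pyrimidine (C=1, T=3).
IS_PYRIMIDINE = np.array([False, True, False, True, False])
IS_PURINE = np.array([True, False, True, False, False])


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A,C,G,T -> 0..3, else 4)."""
    return _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def dipyrimidine_sites(codes: np.ndarray) -> np.ndarray:
    """Boolean array over positions 0..L-2: position p starts a
    lesion-capable dinucleotide (both bases pyrimidines, or both purines —
    i.e. a dipyrimidine on the opposite strand)."""
    a, b = codes[:-1], codes[1:]
    both_pyr = IS_PYRIMIDINE[a] & IS_PYRIMIDINE[b]
    both_pur = IS_PURINE[a] & IS_PURINE[b]
    return both_pyr | both_pur
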