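"""Low-level nucleotide sequence helpers shared across modules.

Coordinates handled here are 0-based Python slices; 1-based closed genomic
coordinates live in :mod:`mobilnc.models`.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOP_CODONS = ("TAA", "TAG", "TGA")

#: the 61 sense codons (everything but the three stops)
SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


_BASES_U8 = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(rng: np.random.Generator, length: int) -> str:
    """Uniform i.i.d. ACGT sequence of the given length."""
    return _BASES_U8[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def translate(seq: str) -> str:
    """Translate a nucleotide sequence in frame 0; '*' marks stops, 'X' ambiguity."""
    out = []
    for i in range(0, len(seq) - 2, 3):
        out.append(_CODON_TABLE.get(seq[i : i + 3], "X"))
    return "".join(out)


def orf_lengths_forward(seq: str) -> list[int]:
    """Lengths (nt, stop codon included) of all complete ATG..stop ORFs in
    the three forward frames."""
    n = len(seq)
    lengths: list[int] = []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    # codon positions per frame, vectorised stop/start detection
    for frame in range(3):
        m = (n - frame) // 3
        if m < 2:
            continue
        c0 = arr[frame : frame + 3 * m : 3]
        c1 = arr[frame + 1 : frame + 1 + 3 * m : 3]
        c2 = arr[frame + 2 : frame + 2 + 3 * m : 3]
        A, C, G, T = 65, 67, 71, 84
        starts = np.flatnonzero((c0 == A) & (c1 == T) & (c2 == G))
        stops = np.flatnonzero(
            ((c0 == T) & (c1 == A) & (c2 == A))
            | ((c0 == T) & (c1 == A) & (c2 == G))
            | ((c0 == T) & (c1 == G) & (c2 == A))
        )
        if starts.size == 0 or stops.size == 0:
            continue
        idx = np.searchsorted(stops, starts)
        ok = idx < stops.size
        if not ok.any():
            continue
        lengths.extend(((stops[idx[ok]] - starts[ok] + 1) * 3).tolist())
    return lengths


def longest_orf(seq: str, six_frame: bool = False) -> int:
    """Length in nt of the longest complete ORF (ATG..stop, stop included).

    By default only the three forward frames are scanned, matching a
    strand-specific library; ``six_frame=True`` also scans the reverse
    complement.
    """
    lengths = orf_lengths_forward(seq)
    if six_frame:
        lengths += orf_lengths_forward(revcomp(seq))
    return max(lengths, default=0)


def longest_orf_interval(seq: str) -> tuple[int, int] | None:
    """1-based closed interval of the longest forward-frame ORF, or None."""
    best: tuple[int, int] | None = None
    best_len = 0
    for frame in range(3):
        i = frame
        while i + 3 <= len(seq):
            if seq[i : i + 3] == "ATG":
                j = i
                while j + 3 <= len(seq):
                    if seq[j : j + 3] in STOP_CODONS:
                        L = j + 3 - i
                        if L > best_len:
                            best_len = L
                            best = (i + 1, j + 3)
                        break
                    j += 3
            i += 3
    return best
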