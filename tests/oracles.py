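"""Independent brute-force oracles used to validate the implementation.

Every function here re-derives a quantity from first principles (exhaustive
scans, enumeration, closed forms) without touching the package's own code
paths, so agreement is meaningful.
"""

from __future__ import annotations

from functools import lru_cache
from math import comb

STOPS = {"TAA", "TAG", "TGA"}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def brute_longest_orf(seq: str, six_frame: bool = False) -> int:
    """Longest ATG..stop ORF (stop included) by scanning every ATG."""
    best = 0
    frames = [seq]
    if six_frame:
        frames.append(rc(seq))
    for s in frames:
        for i in range(len(s) - 2):
            if s[i : i + 3] != "ATG":
                continue
            j = i
            while j + 3 <= len(s):
                if s[j : j + 3] in STOPS:
                    best = max(best, j + 3 - i)
                    break
                j += 3
    return best


# ---------------------------------------------------------------------------
# class codes
# ---------------------------------------------------------------------------

def _exon_bases(t) -> set[int]:
    out: set[int] = set()
    for s, e in t.exons:
        out.update(range(s, e + 1))
    return out


def _intron_intervals(t) -> list[tuple[int, int]]:
    return [
        (t.exons[i][1] + 1, t.exons[i + 1][0] - 1) for i in range(len(t.exons) - 1)
    ]


def brute_class_code(cand, annotation) -> str:
    """Position-set reimplementation of the class-code logic: per-reference
    codes from explicit base sets, then the precedence = > i > x > o > e > u."""
    cand_bases = _exon_bases(cand)
    codes = set()
    span_overlap = False
    for ref in annotation:
        if ref.chrom != cand.chrom:
            continue
        if cand.start <= ref.end and ref.start <= cand.end:
            span_overlap = True
        if cand.exons == ref.exons and cand.strand == ref.strand:
            codes.add("=")
            continue
        in_intron = any(
            a <= cand.start and cand.end <= b for a, b in _intron_intervals(ref)
        )
        if in_intron:
            codes.add("i")
            continue
        if cand_bases & _exon_bases(ref):
            if cand.strand != ref.strand:
                codes.add("x")
            elif len(cand.exons) == 1 and any(
                cand_bases & set(range(a, b + 1)) for a, b in _intron_intervals(ref)
            ):
                codes.add("e")
            else:
                codes.add("o")
    for c in "=ixoe":
        if c in codes:
            return c
    return "other" if span_overlap else "u"


# ---------------------------------------------------------------------------
# cis pairs
# ---------------------------------------------------------------------------

def brute_cis_pairs(lncrnas, genes, window):
    """All-pairs distance scan over explicit base positions."""
    out = set()
    for l in lncrnas:
        for g in genes:
            if l.chrom != g.chrom:
                continue
            if l.start <= g.end and g.start <= l.end:
                d = 0
            else:
                d = max(g.start - l.end, l.start - g.end) - 1
            if d < window:
                out.add((l.transcript_id, g.gene_id, d))
    return out


# ---------------------------------------------------------------------------
# hybridisation: exhaustive local alignment by memoised recursion
# ---------------------------------------------------------------------------

PAIR = {
    ("G", "G"): 3, ("C", "C"): 3, ("A", "A"): 2, ("T", "T"): 2,
    ("G", "A"): 1, ("T", "C"): 1,
}
GAP = 4


def recursive_local_score(seq1: str, seq2: str) -> int:
    """Best local pairing score by enumerating alignments recursively:
    the best alignment starting at (i, j) either pairs the two bases, gaps
    one side, or stops. Independent of the matrix DP in the package."""
    a = seq1
    b = rc(seq2)

    @lru_cache(maxsize=None)
    def from_here(i: int, j: int) -> int:
        if i >= len(a) or j >= len(b):
            return 0
        s = PAIR.get((a[i], b[j]), -GAP)
        return max(
            0,
            s + from_here(i + 1, j + 1),
            -GAP + from_here(i + 1, j),
            -GAP + from_here(i, j + 1),
        )

    best = 0
    for i in range(len(a)):
        for j in range(len(b)):
            best = max(best, from_here(i, j))
    from_here.cache_clear()
    return best


# ---------------------------------------------------------------------------
# hypergeometric tail by direct enumeration
# ---------------------------------------------------------------------------

def enum_hypergeom_tail(k: int, M: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(M, K, n), summed from the pmf."""
    denom = comb(M, n)
    total = 0
    for x in range(k, min(K, n) + 1):
        total += comb(K, x) * comb(M - K, n - x)
    return total / denom


# ---------------------------------------------------------------------------
# closed-form OLS
# ---------------------------------------------------------------------------

def ols_closed_form(x, y):
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    sxy = sum(a * b for a, b in zip(x, y))
    syy = sum(v * v for v in y)
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    r = (n * sxy - sx * sy) / (
        ((n * sxx - sx * sx) * (n * syy - sy * sy)) ** 0.5
    )
    return slope, intercept, r
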