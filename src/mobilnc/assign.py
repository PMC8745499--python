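"""Dual-genome read classification: native, mobile, or filtered.

The classification rule is the heart of cross-species mobile-RNA detection:
a read that matches only the foreign genome is called *mobile*; a read
matching its own tissue's genome (alone or together with the foreign one)
is *native*; a read matching neither genome is *filtered* as a sequencing
artefact. The internal matcher is a canonical k-mer seed index with
splice-aware co-linear chaining and gapless extension — a transparent
stand-in for a spliced short-read aligner, adequate because the synthetic
genomes are cleanly divergent. A SAM ingestion path accepts externally
produced alignments for real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .models import (
    LNCRNA_TRUTH,
    MRNA,
    TISSUE_SPECIES,
    GenomeSet,
    ReadRecord,
    other_species,
)
from .overlap import ExonIndex
from .sequtils import revcomp

_ACGT = frozenset("ACGT")


class EmptyIndexError(ValueError):
    pass


@dataclass
class AssignmentParams:
    """Tuning knobs of the internal matcher and SAM ingestion."""

    k: int = 31
    min_seed_hits: int = 2
    max_mismatch_rate: float = 0.05
    mapq_floor: int = 1
    max_intron: int = 50_000
    #: mismatch-equivalent bonus for junction breakpoints whose skipped
    #: region carries a canonical splice motif (GT..AG or CT..AC)
    splice_motif_bonus: int = 2
    #: spacing of seed start positions along the read; must be small enough
    #: that any internal exon segment longer than k + stride - 1 bp seeds
    seed_stride: int = 16
    #: minimum fraction of the read that must remain aligned after end
    #: clipping for the read to count as matched
    min_aligned_fraction: float = 0.5

    def validate(self) -> None:
        if self.k < 15:
            raise ValueError("seed length k must be >= 15")
        if self.min_seed_hits < 1:
            raise ValueError("min_seed_hits must be >= 1")
        if not 0.0 <= self.max_mismatch_rate < 1.0:
            raise ValueError("max_mismatch_rate must be in [0,1)")


@dataclass
class Alignment:
    """A (possibly spliced) gapless-per-segment alignment of one read."""

    chrom: str
    strand: str
    segments: list[tuple[int, int]]  # 1-based closed, genome coordinate order
    n_mismatch: int
    read_len: int
    clip_head: int = 0  # soft-clipped bases at the 5' end of the oriented read
    clip_tail: int = 0

    @property
    def aligned_len(self) -> int:
        return self.read_len - self.clip_head - self.clip_tail

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.segments[i][1] + 1, self.segments[i + 1][0] - 1)
            for i in range(len(self.segments) - 1)
        ]

    @property
    def mismatch_rate(self) -> float:
        return self.n_mismatch / self.aligned_len


class SeedIndex:
    """Canonical k-mer index over one species' genome."""

    def __init__(self, sequences: dict[str, str], k: int, species: str = ""):
        # small k is allowed for the index itself (useful for enumerable
        # examples); the matcher's AssignmentParams enforces k >= 15
        if k < 2:
            raise ValueError("seed length k must be >= 2")
        if not sequences or k > max(len(s) for s in sequences.values()):
            raise EmptyIndexError(f"k={k} exceeds every chromosome length")
        self.k = k
        self.species = species
        self.sequences = {c: s.upper() for c, s in sequences.items()}
        self.index: dict[str, list[tuple[str, int, int]]] = {}
        for chrom, seq in self.sequences.items():
            L = len(seq)
            rc = revcomp(seq)
            valid = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            is_base = (
                (valid == 65) | (valid == 67) | (valid == 71) | (valid == 84)
            ).astype(np.int32)
            window_ok = np.convolve(is_base, np.ones(k, dtype=np.int32), "valid") == k
            for i in np.flatnonzero(window_ok):
                i = int(i)
                km = seq[i : i + k]
                rkm = rc[L - i - k : L - i]
                if km <= rkm:
                    self.index.setdefault(km, []).append((chrom, i, 1))
                else:
                    self.index.setdefault(rkm, []).append((chrom, i, -1))

    def query(self, kmer: str) -> list[tuple[str, int, int]]:
        """Locations of a k-mer; ``orient`` in each (chrom, offset, orient)
        is +1 when the indexed forward k-mer equals the canonical form."""
        rc = revcomp(kmer)
        return self.index.get(min(kmer, rc), [])


def _seed_positions(read_len: int, k: int, stride: int) -> list[int]:
    ps = list(range(0, read_len - k + 1, stride))
    if ps and ps[-1] != read_len - k:
        ps.append(read_len - k)
    return ps


def _mismatches(a: str, b: str) -> int:
    if a == b:
        return 0
    x = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    y = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    return int((x != y).sum())


def _extend_chain(
    r: str,
    genome: str,
    diag_seeds: dict[int, list[int]],
    params: AssignmentParams,
) -> Alignment | None:
    """Gapless extension of a co-linear seed chain; breakpoints between
    adjacent diagonals are chosen to minimise mismatches, with a bonus for
    canonical splice motifs. Returns None when the read hangs off the
    chromosome or the chain is inconsistent."""
    L = len(r)
    G = len(genome)
    diags = sorted(diag_seeds)
    # read-order consistency across diagonals
    for i in range(len(diags) - 1):
        if max(diag_seeds[diags[i]]) + params.k > min(diag_seeds[diags[i + 1]]):
            return None
        if diags[i + 1] - diags[i] > params.max_intron:
            return None
    if diags[0] < 0 or diags[-1] + L > G:
        return None

    n_mismatch = 0
    boundaries: list[int] = []  # breakpoint read positions between diagonals
    for i in range(len(diags) - 1):
        da, db = diags[i], diags[i + 1]
        a = max(diag_seeds[da])  # last seed start on left diagonal
        b = min(diag_seeds[db])  # first seed start on right diagonal
        lo, hi = a + params.k, b  # breakpoint x in [lo, hi]
        window = r[lo:hi]
        eq_left = np.frombuffer(window.encode(), dtype=np.uint8) == np.frombuffer(
            genome[da + lo : da + hi].encode(), dtype=np.uint8
        )
        eq_right = np.frombuffer(window.encode(), dtype=np.uint8) == np.frombuffer(
            genome[db + lo : db + hi].encode(), dtype=np.uint8
        )
        # cost(x) = mismatches left of x on da + mismatches right of x on db
        mis_left = np.concatenate(([0], np.cumsum(~eq_left)))
        mis_right_total = int((~eq_right).sum())
        mis_right = mis_right_total - np.concatenate(([0], np.cumsum(~eq_right)))
        cost = mis_left + mis_right
        bonus = np.zeros(hi - lo + 1)
        for xi, x in enumerate(range(lo, hi + 1)):
            donor = genome[da + x : da + x + 2]
            acceptor = genome[db + x - 2 : db + x]
            if (donor, acceptor) in {("GT", "AG"), ("CT", "AC")}:
                bonus[xi] = params.splice_motif_bonus
        x = lo + int(np.argmin(cost - bonus))
        boundaries.append(x)
        n_mismatch += int(cost[x - lo])

    # ends and seed-interior mismatches per diagonal segment
    cuts = [0] + boundaries + [L]
    segments: list[tuple[int, int]] = []
    clip_head = clip_tail = 0
    for d, rs, re_ in zip(diags, cuts[:-1], cuts[1:]):
        if re_ <= rs:
            return None
        # interior/end mismatches not yet counted: compare outside the
        # boundary windows handled above
        seeds = diag_seeds[d]
        left_known = min(seeds)
        right_known = max(seeds) + params.k
        if rs < left_known and d == diags[0]:
            mis, clip_head = _end_mismatches(
                r[rs:left_known], genome[d + rs : d + left_known], head=True
            )
            n_mismatch += mis
            rs += clip_head
        if right_known < re_ and d == diags[-1]:
            mis, clip_tail = _end_mismatches(
                r[right_known:re_], genome[d + right_known : d + re_], head=False
            )
            n_mismatch += mis
            re_ -= clip_tail
        # gaps between seeds on the same diagonal
        ordered = sorted(seeds)
        for s1, s2 in zip(ordered[:-1], ordered[1:]):
            if s1 + params.k < s2:
                n_mismatch += _mismatches(
                    r[s1 + params.k : s2], genome[d + s1 + params.k : d + s2]
                )
        segments.append((d + rs + 1, d + re_))
    aligned = L - clip_head - clip_tail
    if aligned < max(params.k, int(params.min_aligned_fraction * L)):
        return None
    if n_mismatch / aligned > params.max_mismatch_rate:
        return None
    return Alignment(
        chrom="", strand="", segments=segments, n_mismatch=n_mismatch,
        read_len=L, clip_head=clip_head, clip_tail=clip_tail,
    )


def _end_mismatches(r_part: str, g_part: str, head: bool) -> tuple[int, int]:
    """Greedy end extension: grow outward from the seeded core and stop at
    the first mismatching base; everything beyond is soft-clipped.

    This is deliberately stringent at the read ends (a junction or an error
    beyond the outermost seed truncates the alignment instead of dragging
    genomic — possibly intronic — bases into it); interior mismatches are
    still tolerated through the seed-gap comparisons.
    """
    if r_part == g_part:
        return 0, 0
    x = np.frombuffer(r_part.encode("ascii"), dtype=np.uint8)
    y = np.frombuffer(g_part.encode("ascii"), dtype=np.uint8)
    mismatch = x != y
    if head:
        mismatch = mismatch[::-1]
    first = int(np.argmax(mismatch))  # mismatch exists (checked above)
    return 0, len(mismatch) - first


def match_genome(seq: str, index: SeedIndex, params: AssignmentParams | None = None) -> Alignment | None:
    """Best alignment of a read against one genome, or None if unmatched.

    A read is matched when at least ``min_seed_hits`` co-linear seeds on one
    chromosome/strand extend to a full-length alignment with mismatch rate
    <= ``max_mismatch_rate``. Degenerate bases never seed or match.
    """
    params = params or AssignmentParams()
    params.validate()
    seq = seq.upper()
    L = len(seq)
    k = params.k
    if L < k:
        return None
    rc_read = revcomp(seq)

    # (chrom, strand) -> diag -> [oriented read positions]
    groups: dict[tuple[str, str], dict[int, list[int]]] = {}
    for p in _seed_positions(L, k, params.seed_stride):
        km = seq[p : p + k]
        if not _ACGT.issuperset(km):
            continue
        rkm = rc_read[L - p - k : L - p]
        orient_r = 1 if km <= rkm else -1
        for chrom, off, orient_g in index.query(km):
            if orient_g == orient_r:
                strand, rpos = "+", p
            else:
                strand, rpos = "-", L - k - p
            d = off - rpos
            groups.setdefault((chrom, strand), {}).setdefault(d, []).append(rpos)

    best: Alignment | None = None
    for (chrom, strand) in sorted(groups):
        diag_seeds = groups[(chrom, strand)]
        n_hits = sum(len(v) for v in diag_seeds.values())
        if n_hits < params.min_seed_hits:
            continue
        r = seq if strand == "+" else rc_read
        aln = _extend_chain(r, index.sequences[chrom], diag_seeds, params)
        if aln is None and len(diag_seeds) > 1:
            # inconsistent multi-diagonal chain: retry on the densest diagonal
            dbest = max(diag_seeds, key=lambda d: (len(diag_seeds[d]), -d))
            if len(diag_seeds[dbest]) >= params.min_seed_hits:
                aln = _extend_chain(r, index.sequences[chrom], {dbest: diag_seeds[dbest]}, params)
        if aln is not None:
            aln.chrom, aln.strand = chrom, strand
            if best is None or aln.n_mismatch < best.n_mismatch:
                best = aln
    return best


# ---------------------------------------------------------------------------
# read and library classification
# ---------------------------------------------------------------------------

LABELS = ("native", "mobile", "filtered")


def assign_read(
    seq: str,
    native_index: SeedIndex,
    foreign_index: SeedIndex,
    params: AssignmentParams | None = None,
) -> tuple[str, Alignment | None]:
    """Label one read: native (matches the native genome, alone or with the
    foreign one), mobile (foreign only), filtered (neither)."""
    an = match_genome(seq, native_index, params)
    if an is not None:
        return "native", an
    af = match_genome(seq, foreign_index, params)
    if af is not None:
        return "mobile", af
    return "filtered", None


@dataclass
class PairAssignment:
    read_id: str
    tissue: str
    label: str  # native | mobile | filtered (stems); parasite | host | ambiguous | filtered (interface)
    origin_species: str | None
    alignment: Alignment | None
    aligned_mate: int = 1  # which mate the stored alignment belongs to
    conflict: bool = False

    @property
    def fragment_strand(self) -> str | None:
        """Transcript-orientation strand of the fragment (mate 1 is forward)."""
        if self.alignment is None:
            return None
        s = self.alignment.strand
        if self.aligned_mate == 2:
            s = "-" if s == "+" else "+"
        return s


def _pair_matches(
    read: ReadRecord, index: SeedIndex, params: AssignmentParams
) -> tuple[Alignment | None, Alignment | None]:
    return match_genome(read.seq1, index, params), match_genome(read.seq2, index, params)


def assign_read_pair(
    read: ReadRecord,
    native_index: SeedIndex,
    foreign_index: SeedIndex,
    params: AssignmentParams | None = None,
    native_species: str | None = None,
) -> PairAssignment:
    """Classify one pair; a genome counts as matched when at least one mate
    matches it. Pairs whose mates match strictly opposite genomes are
    conflicting and are filtered (conservative: never inflates mobility)."""
    params = params or AssignmentParams()
    foreign_species = other_species(native_species) if native_species else None
    n1, n2 = _pair_matches(read, native_index, params)
    m1n, m2n = n1 is not None, n2 is not None
    if m1n and m2n:
        # both mates on the native genome: native regardless of the foreign
        # genome, and no mate-conflict is possible
        return PairAssignment(read.read_id, read.tissue, "native", native_species, n1, 1)
    f1, f2 = _pair_matches(read, foreign_index, params)
    m1f, m2f = f1 is not None, f2 is not None

    conflict = (m1n and not m1f and m2f and not m2n) or (
        m2n and not m2f and m1f and not m1n
    )
    if conflict:
        return PairAssignment(read.read_id, read.tissue, "filtered", None, None, conflict=True)
    if m1n or m2n:
        aln, mate = (n1, 1) if m1n else (n2, 2)
        return PairAssignment(read.read_id, read.tissue, "native", native_species, aln, mate)
    if m1f or m2f:
        aln, mate = (f1, 1) if m1f else (f2, 2)
        return PairAssignment(read.read_id, read.tissue, "mobile", foreign_species, aln, mate)
    return PairAssignment(read.read_id, read.tissue, "filtered", None, None)


def assign_interface_pair(
    read: ReadRecord,
    parasite_index: SeedIndex,
    host_index: SeedIndex,
    params: AssignmentParams | None = None,
) -> PairAssignment:
    """Interface tissue has no native species: pairs are labelled by origin
    (parasite / host); pairs matching both genomes are ambiguous."""
    params = params or AssignmentParams()
    p1, p2 = _pair_matches(read, parasite_index, params)
    h1, h2 = _pair_matches(read, host_index, params)
    mp, mh = (p1 or p2) is not None, (h1 or h2) is not None
    if mp and mh:
        return PairAssignment(read.read_id, read.tissue, "ambiguous", None, None)
    if mp:
        aln, mate = (p1, 1) if p1 else (p2, 2)
        return PairAssignment(read.read_id, read.tissue, "parasite", "parasite", aln, mate)
    if mh:
        aln, mate = (h1, 1) if h1 else (h2, 2)
        return PairAssignment(read.read_id, read.tissue, "host", "host", aln, mate)
    return PairAssignment(read.read_id, read.tissue, "filtered", None, None)


@dataclass
class AssignmentSummary:
    """Per-library label tallies and foreign-read proportion."""

    tissue: str
    counts: dict[str, int]
    n_conflict: int = 0
    foreign_proportion: float = math.nan
    by_biotype: dict[str, dict[str, float]] | None = None

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def assign_library(
    reads: list[ReadRecord],
    parasite_index: SeedIndex,
    host_index: SeedIndex,
    params: AssignmentParams | None = None,
    tissue: str | None = None,
    catalog: GenomeSet | None = None,
    exon_index: ExonIndex | None = None,
) -> tuple[AssignmentSummary, list[PairAssignment]]:
    """Label every pair of one tissue library and summarise.

    The foreign-read proportion is mobile/(mobile+native); with an empty
    library it is reported as NaN, never 0. When a transcript catalog is
    supplied, proportions are additionally split by biotype (lncRNA vs mRNA)
    of the transcript each fragment's alignment falls in.
    """
    params = params or AssignmentParams()
    if tissue is None:
        if not reads:
            raise ValueError("tissue must be given for an empty library")
        tissue = reads[0].tissue

    assignments: list[PairAssignment] = []
    if tissue == "interface":
        for r in reads:
            assignments.append(assign_interface_pair(r, parasite_index, host_index, params))
        counts = {"parasite": 0, "host": 0, "ambiguous": 0, "filtered": 0}
        for a in assignments:
            counts[a.label] += 1
        return AssignmentSummary(tissue, counts), assignments

    native_species = TISSUE_SPECIES[tissue]
    native_index = parasite_index if native_species == "parasite" else host_index
    foreign_index = host_index if native_species == "parasite" else parasite_index
    for r in reads:
        assignments.append(
            assign_read_pair(r, native_index, foreign_index, params, native_species)
        )
    counts = {"native": 0, "mobile": 0, "filtered": 0}
    n_conflict = 0
    for a in assignments:
        counts[a.label] += 1
        n_conflict += a.conflict
    denom = counts["native"] + counts["mobile"]
    proportion = counts["mobile"] / denom if denom else math.nan

    by_biotype = None
    if catalog is not None:
        if exon_index is None:
            exon_index = ExonIndex(catalog)
        tallies = {b: {"native": 0, "mobile": 0} for b in (LNCRNA_TRUTH, MRNA)}
        for a in assignments:
            if a.alignment is None or a.origin_species is None:
                continue
            tids = exon_index.overlapping(
                a.origin_species, a.alignment.chrom, a.fragment_strand, a.alignment.segments
            )
            biotypes = {exon_index.biotype[t] for t in tids}
            for b in biotypes:
                if b in tallies:
                    tallies[b][a.label] += 1
        by_biotype = {}
        for b, t in tallies.items():
            d = t["native"] + t["mobile"]
            by_biotype[b] = {
                "native": t["native"],
                "mobile": t["mobile"],
                "foreign_proportion": t["mobile"] / d if d else math.nan,
            }
    return AssignmentSummary(tissue, counts, n_conflict, proportion, by_biotype), assignments


# ---------------------------------------------------------------------------
# SAM ingestion (real-data path)
# ---------------------------------------------------------------------------

def ingest_alignments(
    native_sam: str,
    foreign_sam: str,
    mapq_floor: int = 1,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Label reads from two externally produced SAM/BAM files.

    A read is matched to a genome iff it has >= 1 primary alignment with
    mapping quality >= ``mapq_floor`` in that genome's file. Reads present
    in only one file are treated as unmatched in the other and logged.
    """

    def matched_names(path: str) -> tuple[set[str], set[str]]:
        seen: set[str] = set()
        matched: set[str] = set()
        try:
            with pysam.AlignmentFile(path, check_sq=False) as fh:
                for rec in fh:
                    seen.add(rec.query_name)
                    if (
                        not rec.is_unmapped
                        and not rec.is_secondary
                        and not rec.is_supplementary
                        and rec.mapping_quality >= mapq_floor
                    ):
                        matched.add(rec.query_name)
        except ValueError as exc:
            raise ValueError(f"malformed SAM file {path}: {exc}") from exc
        return seen, matched

    seen_n, matched_n = matched_names(native_sam)
    seen_f, matched_f = matched_names(foreign_sam)
    universe = sorted(seen_n | seen_f)
    rows = []
    for name in universe:
        mn, mf = name in matched_n, name in matched_f
        label = "native" if mn else ("mobile" if mf else "filtered")
        rows.append((name, mn, mf, label))
    log = {
        "only_in_native_file": len(seen_n - seen_f),
        "only_in_foreign_file": len(seen_f - seen_n),
    }
    df = pd.DataFrame(rows, columns=["read_id", "matched_native", "matched_foreign", "label"])
    return df.set_index("read_id"), log
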