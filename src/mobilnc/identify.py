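"""lncRNA identification: class codes, the five-filter cascade, a
transparent coding-potential rule, positional classification, and feature
summaries.

The identification cascade keeps a candidate transcript iff

1. its class code relative to the protein-coding annotation is one of
   i / x / u / o / e (novel, not an annotated isoform),
2. its spliced length is >= 200 nt,
3. it has >= 2 exons,
4. its maximum FPKM across tissues is >= 0.1, and
5. it shows no substantial protein-coding potential.

The coding-potential rule replaces the published three-tool vote and the
protein-domain scan with one transparent ORF-based criterion plus an
optional user-supplied amino-acid motif list; all thresholds are
configurable.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import TranscriptModel
from .sequtils import longest_orf, longest_orf_interval, orf_lengths_forward, translate

#: class-code precedence across reference transcripts (highest first)
CODE_PRECEDENCE = ("=", "i", "x", "o", "e", "u")

KEEP_CODES = frozenset("ixuoe")

LNCRNA_TYPE_BY_CODE = {
    "u": "lincRNA",
    "x": "antisense",
    "i": "intronic",
    "o": "sense",
    "e": "sense",
}


class ClassificationError(ValueError):
    pass


def _span_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _exonic_overlap(cand: TranscriptModel, ref: TranscriptModel) -> bool:
    for cs, ce in cand.exons:
        for rs, re_ in ref.exons:
            if cs <= re_ and rs <= ce:
                return True
    return False


def _code_vs_reference(cand: TranscriptModel, ref: TranscriptModel) -> str | None:
    """Relationship code of a candidate against one reference transcript.

    Cascade: identical exon chain (=); fully inside one reference intron,
    either strand (i); exonic overlap on the opposite strand (x); same
    strand: a single-exon candidate reaching from a reference exon into a
    flanking intron is pre-mRNA-like (e), any other partial exonic overlap
    is (o). None when the spans do not meet the above.
    """
    if cand.chrom != ref.chrom:
        return None
    if cand.exons == ref.exons and cand.strand == ref.strand:
        return "="
    for intron in ref.introns:
        if intron[0] <= cand.start and cand.end <= intron[1]:
            return "i"
    if _exonic_overlap(cand, ref):
        if cand.strand != ref.strand:
            return "x"
        if cand.n_exons == 1:
            for intron in ref.introns:
                if _span_overlap(cand.span, intron):
                    return "e"
        return "o"
    return None


def assign_class_code(
    candidate: TranscriptModel,
    annotation: list[TranscriptModel],
    chromosomes: dict[str, int] | None = None,
) -> str:
    """cuffcompare-style class code of a candidate against an annotation.

    When several references give different codes the highest-precedence one
    wins (= > i > x > o > e > u). A candidate overlapping a reference span
    without triggering any code (e.g. a spliced candidate lying entirely in
    introns but not within a single one) is reported as "other".
    """
    if chromosomes is not None and candidate.chrom not in chromosomes:
        raise ClassificationError(
            f"{candidate.transcript_id}: unknown chromosome {candidate.chrom}"
        )
    codes = set()
    any_span_overlap = False
    for ref in annotation:
        if ref.chrom != candidate.chrom:
            continue
        if _span_overlap(candidate.span, ref.span):
            any_span_overlap = True
        c = _code_vs_reference(candidate, ref)
        if c:
            codes.add(c)
    for c in CODE_PRECEDENCE[:-1]:
        if c in codes:
            return c
    return "other" if any_span_overlap else "u"


# ---------------------------------------------------------------------------
# coding potential
# ---------------------------------------------------------------------------

@dataclass
class CodingPotentialResult:
    longest_orf_length: int
    orf_coverage: float
    score: float
    is_coding: bool
    motif_hit: str | None = None


def coding_potential(
    spliced_sequence: str,
    orf_min: int = 300,
    coverage_min: float = 0.5,
    motifs: list[str] | None = None,
    six_frame: bool = False,
) -> CodingPotentialResult:
    """Transparent coding-potential call.

    The longest complete ORF (ATG..stop, stop included) is searched in the
    three forward frames — the library protocol is strand-specific, so the
    antisense frames are off by default (``six_frame=True`` enables them
    for non-stranded data). A transcript is coding when the longest ORF is
    >= ``orf_min`` nt, or covers >= ``coverage_min`` of the spliced length,
    or its translation matches a user-supplied amino-acid motif (regular
    expressions, stand-in for a protein-domain scan).
    """
    if not spliced_sequence:
        raise ValueError("empty sequence")
    seq = spliced_sequence.upper().replace("U", "T")
    if not set(seq) <= set("ACGTN"):
        raise ValueError("sequence must be over A/C/G/T/N")
    L = longest_orf(seq, six_frame=six_frame)
    coverage = L / len(seq)
    score = coverage * math.log(L) if L > 0 else 0.0
    motif_hit = None
    if motifs and L > 0:
        iv = longest_orf_interval(seq)
        if iv is not None:
            aa = translate(seq[iv[0] - 1 : iv[1]])
            for m in motifs:
                if re.search(m, aa):
                    motif_hit = m
                    break
    is_coding = (L >= orf_min) or (coverage >= coverage_min) or (motif_hit is not None)
    return CodingPotentialResult(L, coverage, score, is_coding, motif_hit)


# ---------------------------------------------------------------------------
# filter cascade
# ---------------------------------------------------------------------------

FILTER_NAMES = ("class_code", "length", "exon_count", "fpkm", "noncoding")


@dataclass
class LncRNARecord:
    model: TranscriptModel
    class_code: str
    filter_flags: dict[str, bool]
    passed_filters: bool
    lncrna_type: str | None = None
    coding: CodingPotentialResult | None = None


def classify_lncrna_type(class_code: str) -> str:
    """Positional lncRNA class from the class code:
    u -> lincRNA, x -> antisense, i -> intronic, o/e -> sense."""
    try:
        return LNCRNA_TYPE_BY_CODE[class_code]
    except KeyError:
        raise ClassificationError(
            f"class code {class_code!r} should have been filtered before typing"
        ) from None


def filter_candidates(
    candidates: list[TranscriptModel],
    class_codes: dict[str, str],
    fpkm: pd.DataFrame | pd.Series,
    sequences: dict[str, str] | None = None,
    min_length: int = 200,
    min_exons: int = 2,
    min_fpkm: float = 0.1,
    orf_min: int = 300,
    coverage_min: float = 0.5,
    motifs: list[str] | None = None,
) -> list[LncRNARecord]:
    """Apply the five-filter cascade; every rejection records which filters
    failed. Transcripts absent from the expression matrix count as FPKM 0.
    The FPKM filter uses the maximum over tissues (a transcript expressed
    anywhere remains a candidate). Without sequences the coding filter is
    vacuously passed (flagged True) — callers wanting the full cascade must
    supply spliced sequences.
    """
    if isinstance(fpkm, pd.DataFrame):
        max_fpkm = fpkm.max(axis=1)
    else:
        max_fpkm = fpkm
    out = []
    for t in candidates:
        code = class_codes[t.transcript_id]
        coding = None
        noncoding_ok = True
        if sequences is not None and t.transcript_id in sequences:
            coding = coding_potential(
                sequences[t.transcript_id], orf_min, coverage_min, motifs
            )
            noncoding_ok = not coding.is_coding
        flags = {
            "class_code": code in KEEP_CODES,
            "length": t.spliced_length >= min_length,
            "exon_count": t.n_exons >= min_exons,
            "fpkm": float(max_fpkm.get(t.transcript_id, 0.0)) >= min_fpkm,
            "noncoding": noncoding_ok,
        }
        passed = all(flags.values())
        out.append(
            LncRNARecord(
                model=t,
                class_code=code,
                filter_flags=flags,
                passed_filters=passed,
                lncrna_type=classify_lncrna_type(code) if passed else None,
                coding=coding,
            )
        )
    return out


def type_composition(records: list[LncRNARecord]) -> pd.Series:
    """Counts of the four positional classes among passing records."""
    passing = [r.lncrna_type for r in records if r.passed_filters]
    return pd.Series(passing).value_counts().reindex(
        ["lincRNA", "antisense", "sense", "intronic"], fill_value=0
    )


# ---------------------------------------------------------------------------
# feature summaries
# ---------------------------------------------------------------------------

@dataclass
class FeatureSummary:
    spliced_fraction: dict[str, float]
    mean_length: dict[str, float]
    exon_hist: pd.DataFrame
    length_hist: pd.DataFrame
    orf_hist: pd.DataFrame


def _hist(values: list[int], edges: np.ndarray) -> np.ndarray:
    counts, _ = np.histogram(values, bins=edges)
    return counts


def feature_summary(
    lncrnas: list[TranscriptModel],
    mrnas: list[TranscriptModel],
    sequences: dict[str, str] | None = None,
    max_exon_bin: int = 16,
) -> FeatureSummary:
    """Comparative distributions of lncRNA vs mRNA features.

    Length histogram bins are 200 bp wide starting at 200; ORF bins are
    100 nt wide; exon counts run 1..16 with a 16+ bucket.
    """
    if not lncrnas or not mrnas:
        raise ValueError("both transcript sets must be non-empty")
    groups = {"lncRNA": lncrnas, "mRNA": mrnas}
    lengths = {g: [t.spliced_length for t in ts] for g, ts in groups.items()}
    spliced_fraction = {
        g: sum(t.n_exons >= 2 for t in ts) / len(ts) for g, ts in groups.items()
    }
    mean_length = {g: float(np.mean(v)) for g, v in lengths.items()}

    top = max(max(v) for v in lengths.values())
    edges = np.arange(200, top + 401, 200)
    length_hist = pd.DataFrame(
        {g: _hist(v, edges) for g, v in lengths.items()},
        index=pd.Index(edges[:-1], name="length_bin_left"),
    )

    exon_edges = np.arange(1, max_exon_bin + 1)
    exon_rows = {}
    for g, ts in groups.items():
        n = np.array([min(t.n_exons, max_exon_bin) for t in ts])
        exon_rows[g] = [(n == e).sum() for e in exon_edges[:-1]] + [(n >= max_exon_bin).sum()]
    exon_hist = pd.DataFrame(
        exon_rows, index=pd.Index(list(exon_edges[:-1]) + [max_exon_bin], name="n_exons")
    )

    orf_hist = pd.DataFrame()
    if sequences is not None:
        orfs = {
            g: [
                max(orf_lengths_forward(sequences[t.transcript_id]), default=0)
                for t in ts
                if t.transcript_id in sequences
            ]
            for g, ts in groups.items()
        }
        top_orf = max(max(v, default=0) for v in orfs.values())
        orf_edges = np.arange(0, top_orf + 201, 100)
        orf_hist = pd.DataFrame(
            {g: _hist(v, orf_edges) for g, v in orfs.items()},
            index=pd.Index(orf_edges[:-1], name="orf_bin_left"),
        )
    return FeatureSummary(spliced_fraction, mean_length, exon_hist, length_hist, orf_hist)
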