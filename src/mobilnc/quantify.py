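"""Expression quantification, transcript-level mobility calls and statistics.

FPKM uses the standard definition
``fragments * 1e9 / (total_mapped_fragments * spliced_length_bp)``.
A transcript of species A is called mobile when at least
``min_mobile_fragments`` mobile-labelled fragments are assigned to it in
species B's stem library; detection in the interface tissue alone never
confers mobility, because the interface contains both species' RNA by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .models import LNCRNA_TRUTH, MRNA, SPECIES, GenomeSet, TranscriptModel
from .overlap import ExonIndex
from .assign import PairAssignment

#: pseudo-FPKM added before any log transform
LOG_EPSILON = 1e-3


class InsufficientDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# fragment counting
# ---------------------------------------------------------------------------

@dataclass
class CountResult:
    """Fractional fragment counts per transcript x tissue.

    ``mobile`` holds the subset of counts contributed by mobile-labelled
    fragments; ``intergenic`` counts mapped fragments overlapping no
    annotated exon; ``totals`` is the number of mapped fragments per tissue
    (assigned + intergenic), the FPKM denominator.
    """

    counts: pd.DataFrame
    mobile: pd.DataFrame
    intergenic: pd.Series
    totals: pd.Series


def count_fragments(
    assignments: dict[str, list[PairAssignment]],
    catalog: GenomeSet,
    exon_index: ExonIndex | None = None,
) -> CountResult:
    """Assign labelled fragments to transcripts.

    A fragment counts toward a transcript iff its alignment overlaps the
    transcript's exons on the correct strand; fragments overlapping several
    transcripts are split 1/n. Mobile-labelled fragments count toward the
    foreign species' transcripts in the tissue where they were observed.
    """
    if exon_index is None:
        exon_index = ExonIndex(catalog)
    tids = [t.transcript_id for s in SPECIES for t in catalog.transcripts[s]]
    tissues = list(assignments)
    counts_d: dict[str, dict[str, float]] = {t: {} for t in tissues}
    mobile_d: dict[str, dict[str, float]] = {t: {} for t in tissues}
    intergenic = pd.Series(0.0, index=tissues)
    totals = pd.Series(0, index=tissues, dtype=int)

    for tissue, pairs in assignments.items():
        cc = counts_d[tissue]
        mc = mobile_d[tissue]
        n_mapped = 0
        for a in pairs:
            if a.alignment is None or a.origin_species is None:
                continue
            n_mapped += 1
            hit = exon_index.overlapping(
                a.origin_species, a.alignment.chrom, a.fragment_strand, a.alignment.segments
            )
            if not hit:
                intergenic[tissue] += 1
                continue
            share = 1.0 / len(hit)
            for tid in hit:
                cc[tid] = cc.get(tid, 0.0) + share
                if a.label == "mobile":
                    mc[tid] = mc.get(tid, 0.0) + share
        totals[tissue] = n_mapped
    counts = pd.DataFrame(counts_d, columns=tissues).reindex(tids).fillna(0.0)
    mobile = pd.DataFrame(mobile_d, columns=tissues).reindex(tids).fillna(0.0)
    return CountResult(counts=counts, mobile=mobile, intergenic=intergenic, totals=totals)


# ---------------------------------------------------------------------------
# FPKM
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Transcript x tissue fragment counts and FPKM."""

    counts: pd.DataFrame
    fpkm: pd.DataFrame
    totals: pd.Series
    lengths: pd.Series


def compute_fpkm(
    counts: pd.DataFrame, lengths: pd.Series, totals: pd.Series
) -> ExpressionMatrix:
    """fpkm = fragment_count * 1e9 / (total_mapped_fragments * spliced_length_bp)."""
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise InsufficientDataError(f"total_mapped_fragments is 0 for tissues {bad}")
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every transcript needs a positive spliced length")
    fpkm = counts * 1e9
    fpkm = fpkm.div(lengths, axis=0).div(totals, axis=1)
    return ExpressionMatrix(counts=counts, fpkm=fpkm, totals=totals, lengths=lengths)


def catalog_lengths(catalog: GenomeSet) -> pd.Series:
    return pd.Series(
        {
            t.transcript_id: t.spliced_length
            for s in SPECIES
            for t in catalog.transcripts[s]
        }
    )


# ---------------------------------------------------------------------------
# mobility calls and the transfer table
# ---------------------------------------------------------------------------

def call_transcript_mobility(
    count_result: CountResult,
    catalog: GenomeSet,
    min_mobile_fragments: float = 1,
) -> pd.Series:
    """Boolean mobile flag per transcript.

    Species A transcripts are tested against mobile-labelled fragments in
    species B's stem library only.
    """
    foreign_stem = {"parasite": "host_stem", "host": "parasite_stem"}
    flags = {}
    for species in SPECIES:
        tissue = foreign_stem[species]
        for t in catalog.transcripts[species]:
            if tissue in count_result.mobile.columns:
                flags[t.transcript_id] = bool(
                    count_result.mobile.at[t.transcript_id, tissue] >= min_mobile_fragments
                )
            else:
                flags[t.transcript_id] = False
    return pd.Series(flags)


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float) -> float:
    """Percentage rounded half-up to printed precision: 1 decimal at >= 1%,
    2 decimals below 1% (matching how small percentages are reported)."""
    if denominator == 0:
        return math.nan
    p = 100.0 * numerator / denominator
    return _round_half_up(p, 1 if p >= 1 else 2)


@dataclass
class MobilityTable:
    """Counts of mobile and non-mobile transcripts per (species, biotype),
    with derived percentages always recomputed from the counts."""

    table: pd.DataFrame  # index (species, biotype); columns total, mobile, nonmobile

    @classmethod
    def from_counts(cls, counts: dict[tuple[str, str], tuple[int, int]]) -> "MobilityTable":
        """Build from {(species, biotype): (total, mobile)}."""
        rows = {}
        for key, (total, mob) in counts.items():
            if mob > total:
                raise ValueError(f"{key}: mobile {mob} exceeds total {total}")
            rows[key] = {"total": total, "mobile": mob, "nonmobile": total - mob}
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index = pd.MultiIndex.from_tuples(df.index, names=["species", "biotype"])
        return cls(df)

    def mobile_percent(self, species: str, biotype: str) -> float:
        row = self.table.loc[(species, biotype)]
        return percent(row["mobile"], row["total"])

    def cross_species_ratio(self, biotype: str) -> float:
        """host-mobile / parasite-mobile per biotype, as a percentage
        rounded half-up to 2 decimals."""
        h = self.table.loc[("host", biotype), "mobile"]
        p = self.table.loc[("parasite", biotype), "mobile"]
        if p == 0:
            return math.nan
        return _round_half_up(100.0 * h / p, 2)

    def catalog_total(self, biotype: str) -> int:
        return int(self.table.xs(biotype, level="biotype")["total"].sum())

    def to_frame(self) -> pd.DataFrame:
        df = self.table.copy()
        df["mobile_pct"] = [
            self.mobile_percent(s, b) for s, b in df.index
        ]
        return df


def build_mobility_table(flags: pd.Series, catalog: GenomeSet) -> MobilityTable:
    counts: dict[tuple[str, str], tuple[int, int]] = {}
    for species in SPECIES:
        for biotype in (LNCRNA_TRUTH, MRNA):
            ids = [
                t.transcript_id
                for t in catalog.transcripts[species]
                if t.biotype == biotype
            ]
            if not ids and not catalog.transcripts[species]:
                continue
            mob = int(flags.reindex(ids).fillna(False).sum())
            counts[(species, biotype)] = (len(ids), mob)
    if not counts:
        raise ValueError("empty catalog")
    return MobilityTable.from_counts(counts)


# ---------------------------------------------------------------------------
# abundance vs mobility and interface correlation
# ---------------------------------------------------------------------------

def abundance_mobility_summary(
    expression: ExpressionMatrix,
    flags: pd.Series,
    catalog: GenomeSet,
    tissue: str = "interface",
) -> pd.DataFrame:
    """Interface-tissue log2(FPKM+1) distributions of mobile vs non-mobile
    sets per (species, biotype), with a one-sided Mann-Whitney U test
    (mobile > non-mobile)."""
    rows = []
    logf = np.log2(expression.fpkm[tissue] + 1.0)
    for species in SPECIES:
        for biotype in (LNCRNA_TRUTH, MRNA):
            ids = [
                t.transcript_id
                for t in catalog.transcripts[species]
                if t.biotype == biotype
            ]
            f = flags.reindex(ids).fillna(False)
            mob = logf[f.index[f]]
            non = logf[f.index[~f]]
            row = {"species": species, "biotype": biotype,
                   "n_mobile": len(mob), "n_nonmobile": len(non)}
            for name, vals in (("mobile", mob), ("nonmobile", non)):
                if len(vals):
                    row[f"{name}_median"] = float(vals.median())
                    row[f"{name}_q1"] = float(vals.quantile(0.25))
                    row[f"{name}_q3"] = float(vals.quantile(0.75))
                else:
                    row[f"{name}_median"] = math.nan
                    row[f"{name}_q1"] = math.nan
                    row[f"{name}_q3"] = math.nan
            if len(mob) and len(non):
                u, p = stats.mannwhitneyu(mob, non, alternative="greater")
                row["u_stat"], row["p_value"] = float(u), float(p)
            else:
                row["u_stat"], row["p_value"] = math.nan, math.nan
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    n: int


def interface_correlation(
    expression: ExpressionMatrix,
    flags: pd.Series,
    foreign_stem: str = "host_stem",
    interface: str = "interface",
    eps: float = LOG_EPSILON,
) -> RegressionResult:
    """OLS of log10(FPKM_foreign_stem + eps) on log10(FPKM_interface + eps)
    over mobile transcripts with positive FPKM in both tissues."""
    ids = flags.index[flags]
    sub = expression.fpkm.loc[expression.fpkm.index.intersection(ids)]
    sub = sub[(sub[foreign_stem] > 0) & (sub[interface] > 0)]
    if len(sub) < 3:
        raise InsufficientDataError(
            f"need >= 3 mobile transcripts with positive FPKM in both tissues, have {len(sub)}"
        )
    x = np.log10(sub[interface] + eps)
    y = np.log10(sub[foreign_stem] + eps)
    res = stats.linregress(x, y)
    return RegressionResult(float(res.slope), float(res.intercept), float(res.rvalue), len(sub))


# ---------------------------------------------------------------------------
# coverage and junction evidence
# ---------------------------------------------------------------------------

@dataclass
class CoverageTrack:
    transcript_id: str
    tissue: str
    span: tuple[int, int]  # 1-based closed genomic span
    depth: np.ndarray  # per-base over the span
    junctions: dict[tuple[int, int], int]  # intron -> supporting read count

    def intronic_depth(self, transcript: TranscriptModel) -> int:
        s0 = self.span[0]
        total = 0
        for a, b in transcript.introns:
            total += int(self.depth[a - s0 : b - s0 + 1].sum())
        return total


def coverage_track(
    assignments: list[PairAssignment],
    transcript: TranscriptModel,
    tissue: str,
    mobile_only: bool = False,
) -> CoverageTrack:
    """Per-base depth over the transcript's genomic span and per-intron
    junction counts (reads whose alignment skips exactly that intron).

    For foreign-tissue evidence pass ``mobile_only=True`` so only
    mobile-labelled fragments contribute.
    """
    s0, e0 = transcript.span
    depth = np.zeros(e0 - s0 + 1, dtype=np.int64)
    junctions = {iv: 0 for iv in transcript.introns}
    for a in assignments:
        if a.tissue != tissue or a.alignment is None:
            continue
        if mobile_only and a.label != "mobile":
            continue
        aln = a.alignment
        if aln.chrom != transcript.chrom or a.fragment_strand != transcript.strand:
            continue
        if aln.segments[-1][1] < s0 or aln.segments[0][0] > e0:
            continue
        for gs, ge in aln.segments:
            lo = max(gs, s0) - s0
            hi = min(ge, e0) - s0
            if hi >= lo:
                depth[lo : hi + 1] += 1
        for intron in aln.introns:
            if intron in junctions:
                junctions[intron] += 1
    return CoverageTrack(transcript.transcript_id, tissue, (s0, e0), depth, junctions)


# ---------------------------------------------------------------------------
# z-scored expression matrices for heatmaps
# ---------------------------------------------------------------------------

def zscore_matrix(
    expression: ExpressionMatrix,
    ids: list[str],
    tissues: list[str] | None = None,
    log_base: int = 2,
    eps: float = LOG_EPSILON,
) -> tuple[pd.DataFrame, pd.Series]:
    """Row-wise z-scores of log_b(FPKM + eps); constant rows come back as
    all-zero and are flagged."""
    tissues = tissues or list(expression.fpkm.columns)
    if len(tissues) < 2:
        raise ValueError("z-scoring needs >= 2 tissues")
    m = np.log(expression.fpkm.loc[ids, tissues] + eps) / np.log(log_base)
    mu = m.mean(axis=1)
    sd = m.std(axis=1, ddof=0)
    constant = sd == 0
    sd_safe = sd.where(~constant, 1.0)
    z = m.sub(mu, axis=0).div(sd_safe, axis=0)
    z[constant] = 0.0
    return z, constant
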