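"""Synthetic two-species parasitic transcriptome and read-library generator.

The simulator emulates the study system: two divergent genomes (parasite and
host) with annotated protein-coding and lncRNA loci, three tissue libraries
(parasite stem, interface, host stem) in which a configurable fraction of
reads originates from the foreign species, foreign transcripts present only
as spliced mature isoforms, and mobility probability coupled to expression
abundance.

Because the two genomes are independent i.i.d. uniform sequences, exact
k-mer collisions between them are vanishingly rare for k >= 31, which gives
downstream read assignment a clean ground truth to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .models import (
    LNCRNA_TRUTH,
    MRNA,
    SPECIES,
    TISSUES,
    TISSUE_SPECIES,
    GenomeSet,
    ReadRecord,
    TranscriptModel,
    other_species,
)
from .sequtils import SENSE_CODONS, STOP_CODONS, longest_orf, random_seq, revcomp

#: ORF-length boundary (nt) separating simulated biotypes. lncRNA-truth
#: models are rejection-sampled until their longest six-frame ORF is below
#: this; every mRNA carries an embedded ORF of at least this length.
ORF_BOUNDARY_NT = 300

_MIN_GAP = 100  # minimum intergenic gap, bp


class SimulationError(ValueError):
    """Invalid simulator configuration."""


class PlacementError(SimulationError):
    """Loci cannot be placed on the configured genome."""


def _default_lncrna_exon_dist() -> dict[int, float]:
    # ~55% two-exon lncRNAs, decreasing beyond; the single-exon mass feeds
    # the spliced-fraction summaries.
    return {1: 0.25, 2: 0.55, 3: 0.12, 4: 0.05, 5: 0.03}


def _default_mrna_exon_dist() -> dict[int, float]:
    # broad distribution up to 20 exons with ~6% mass at >16
    d = {
        1: 0.04, 2: 0.07, 3: 0.09, 4: 0.10, 5: 0.10,
        6: 0.09, 7: 0.08, 8: 0.07, 9: 0.06, 10: 0.05,
        11: 0.045, 12: 0.04, 13: 0.035, 14: 0.03, 15: 0.025,
        16: 0.02, 17: 0.02, 18: 0.015, 19: 0.01, 20: 0.01,
    }
    assert abs(sum(d.values()) - 1.0) < 1e-9
    return d


@dataclass
class SimConfig:
    """Full specification of one synthetic experiment.

    An identical config (including ``seed``) always produces byte-identical
    FASTA/GFF3/FASTQ outputs.
    """

    seed: int = 0
    genome_length_per_species: int = 1_000_000
    n_genes_per_species: int = 70
    n_lncrnas_per_species: int = 50
    lncrna_exon_dist: dict[int, float] = field(default_factory=_default_lncrna_exon_dist)
    mrna_exon_dist: dict[int, float] = field(default_factory=_default_mrna_exon_dist)
    lncrna_len_mean: int = 1458
    mrna_len_mean: int = 2133
    read_length: int = 150
    n_read_pairs_per_tissue: int = 100_000
    #: fraction of host-stem pairs drawn from parasite transcripts (the
    #: dominant direction of movement in the study system)
    mobile_fraction_parasite_to_host: float = 0.015
    #: fraction of parasite-stem pairs drawn from host transcripts
    mobile_fraction_host_to_parasite: float = 0.0017
    #: fraction of interface reads drawn from the parasite
    interface_mix: float = 0.5
    #: exponent coupling transcript abundance to mobility propensity
    abundance_mobility_bias: float = 1.0
    #: fraction of each species' transcripts designated mobile-eligible
    mobile_transcript_fraction: float = 0.3
    abundance_sigma: float = 1.0
    #: probability that a native read of an intron-containing transcript is
    #: drawn from the unspliced pre-RNA
    unspliced_read_fraction: float = 0.15
    intron_len_mean: int = 300
    min_intron_len: int = 60
    min_exon_len: int = 50
    error_rate: float = 0.001

    def validate(self) -> None:
        for name in (
            "mobile_fraction_parasite_to_host",
            "mobile_fraction_host_to_parasite",
            "interface_mix",
            "mobile_transcript_fraction",
            "unspliced_read_fraction",
            "error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0,1], got {v}")
        for name in ("lncrna_exon_dist", "mrna_exon_dist"):
            d = getattr(self, name)
            if not d or abs(sum(d.values()) - 1.0) > 1e-6 or min(d.values()) < 0:
                raise SimulationError(f"{name} must be a distribution summing to 1")
            if min(d) < 1:
                raise SimulationError(f"{name}: exon counts must be >= 1")
        if self.read_length < 1:
            raise SimulationError("read_length must be positive")
        if self.abundance_mobility_bias < 0:
            raise SimulationError("abundance_mobility_bias must be >= 0")


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Deterministic per-stage RNG streams derived from one root seed."""
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def _draw_from_dist(rng: np.random.Generator, dist: dict[int, float]) -> int:
    keys = sorted(dist)
    p = np.array([dist[k] for k in keys], dtype=float)
    return int(rng.choice(keys, p=p / p.sum()))


def _draw_spliced_length(rng: np.random.Generator, mean: int, minimum: int) -> int:
    # gamma with shape 4 approximates the right-skewed transcript-length
    # distributions seen in plant annotation; redraw below the floor so the
    # exon-count distribution stays exact
    for _ in range(1000):
        L = int(rng.gamma(4.0, mean / 4.0))
        if L >= minimum:
            return L
    raise PlacementError(f"cannot draw spliced length >= {minimum} with mean {mean}")


def _split_exon_lengths(rng: np.random.Generator, total: int, n: int, min_exon: int) -> list[int]:
    extra = total - n * min_exon
    alloc = np.floor(rng.dirichlet(np.ones(n)) * extra).astype(int)
    alloc[0] += extra - alloc.sum()
    return (alloc + min_exon).tolist()


def _make_lncrna_seq(rng: np.random.Generator, length: int) -> str:
    """Random sequence that is non-coding by construction: the longest
    six-frame ORF stays below the biotype boundary and below half the
    transcript length (so no ORF-length or ORF-coverage rule can call it
    coding)."""
    for _ in range(10_000):
        s = random_seq(rng, length)
        if longest_orf(s, six_frame=True) < min(ORF_BOUNDARY_NT, length // 2):
            return s
    raise PlacementError(f"cannot sample ORF-free lncRNA sequence of length {length}")


def _make_mrna_seq(rng: np.random.Generator, length: int) -> tuple[str, tuple[int, int]]:
    """Random sequence with an embedded ATG..stop ORF of >= ORF_BOUNDARY_NT nt."""
    frac = rng.uniform(0.35, 0.6)
    orf_len = max(ORF_BOUNDARY_NT, 3 * int(frac * length / 3))
    orf_len = min(orf_len, 3 * ((length - 6) // 3))
    n_codons = orf_len // 3 - 2
    codons = ["ATG"]
    codons += [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=n_codons)]
    codons.append(STOP_CODONS[rng.integers(0, 3)])
    orf = "".join(codons)
    off = int(rng.integers(0, length - orf_len + 1))
    s = random_seq(rng, length)
    s = s[:off] + orf + s[off + orf_len:]
    return s, (off + 1, off + orf_len)


def _shifted_intron_has_motif(left: str, intron: str, right: str, max_shift: int = 20) -> bool:
    """True if some shifted placement of the intron both matches the exon
    sequence and carries a canonical splice motif (GT..AG or its reverse
    complement CT..AC), i.e. the junction would be ambiguous to a
    motif-aware aligner."""

    def motif(s: str) -> bool:
        if len(s) < 4:
            return False
        return (s.startswith("GT") and s.endswith("AG")) or (
            s.startswith("CT") and s.endswith("AC")
        )

    for s in range(1, max_shift + 1):
        if s <= len(right) and right[:s] == intron[:s]:
            shifted = intron[s:] + right[:s]
            if motif(shifted):
                return True
        if s <= len(left) and left[-s:] == intron[-s:]:
            shifted = left[-s:] + intron[:-s]
            if motif(shifted):
                return True
    return False


_MIN_EXON_PIECE = 47  # keeps every genomic exon piece long enough to seed


def _make_introns(
    rng: np.random.Generator,
    genomic_exons: list[str],
    mean: int,
    minimum: int,
    strand: str,
) -> tuple[list[str], list[str]]:
    """Genome-orientation intron sequences (coordinate order) with splice
    motifs, junctions free of shift ambiguity, and junction-adjacent bases
    distinct from the motif bases.

    Exon split points may be nudged by up to 3 bp (the spliced sequence is
    unchanged; only the genomic placement of the junction moves) so that the
    exon base flanking each junction differs from the adjacent motif base.
    Without this, an aligner extending a mature-RNA read past a junction
    could place chance-matching bases inside the intron, muddying the
    intron-free signature of mobile transcripts.
    """
    exons = list(genomic_exons)
    motifs: list[tuple[str, str]] = []
    default = ("GT", "AG") if strand == "+" else ("CT", "AC")
    alternate = ("CT", "AC") if strand == "+" else ("GT", "AG")
    for i in range(len(exons) - 1):
        combined = exons[i] + exons[i + 1]
        cut0 = len(exons[i])
        chosen = None
        for shift in (0, 1, -1, 2, -2, 3, -3):
            cut = cut0 + shift
            if min(cut, len(combined) - cut) < _MIN_EXON_PIECE:
                continue
            for motif in (default, alternate):
                bad = motif[0][0]  # G for GT..AG, C for CT..AC (both ends)
                if combined[cut - 1] != bad and combined[cut] != bad:
                    chosen = (cut, motif)
                    break
            if chosen:
                break
        if chosen is None:
            chosen = (cut0, default)
        cut, motif = chosen
        exons[i], exons[i + 1] = combined[:cut], combined[cut:]
        motifs.append(motif)

    introns: list[str] = []
    for i, (donor, acceptor) in enumerate(motifs):
        length = max(minimum, 4 + int(rng.exponential(max(1, mean - minimum))))
        left, right = exons[i], exons[i + 1]
        for _ in range(200):
            interior = random_seq(rng, length - 4)
            intron = donor + interior + acceptor
            if not _shifted_intron_has_motif(left, intron, right):
                break
        introns.append(intron)
    return exons, introns


def generate_genome_pair(config: SimConfig) -> GenomeSet:
    """Generate the two annotated genomes.

    Raises
    ------
    PlacementError
        If the configured loci cannot fit on ``genome_length_per_species``.
    """
    config.validate()
    rngs = _child_rngs(config.seed, 4)
    sequences: dict[str, dict[str, str]] = {}
    transcripts: dict[str, list[TranscriptModel]] = {}

    for si, species in enumerate(SPECIES):
        rng = rngs[si]
        chrom = f"{species}_chr1"
        glen = config.genome_length_per_species

        plans = []  # (biotype, n_exons, spliced_len, exon_lens)
        for kind, count, dist, mean in (
            (MRNA, config.n_genes_per_species, config.mrna_exon_dist, config.mrna_len_mean),
            (LNCRNA_TRUTH, config.n_lncrnas_per_species, config.lncrna_exon_dist, config.lncrna_len_mean),
        ):
            floor_len = 450 if kind == MRNA else 300
            for _ in range(count):
                n_exons = _draw_from_dist(rng, dist)
                L = _draw_spliced_length(rng, mean, max(floor_len, 2 * n_exons * config.min_exon_len))
                exon_lens = _split_exon_lengths(rng, L, n_exons, config.min_exon_len)
                plans.append((kind, n_exons, L, exon_lens))

        rng.shuffle(plans)

        # pre-draw intron lengths to size the spans
        regions = []
        for kind, n_exons, L, exon_lens in plans:
            strand = "+" if rng.random() < 0.5 else "-"
            if kind == MRNA:
                spliced, orf = _make_mrna_seq(rng, L)
            else:
                spliced, orf = _make_lncrna_seq(rng, L), None
            pieces, pos = [], 0
            for el in exon_lens:
                pieces.append(spliced[pos : pos + el])
                pos += el
            if strand == "+":
                genomic_exons = pieces
            else:
                genomic_exons = [revcomp(p) for p in reversed(pieces)]
            genomic_exons, introns = _make_introns(
                rng, genomic_exons, config.intron_len_mean,
                config.min_intron_len, strand,
            )
            region_parts = [genomic_exons[0]]
            for j, it in enumerate(introns):
                region_parts += [it, genomic_exons[j + 1]]
            region = "".join(region_parts)
            regions.append((kind, strand, genomic_exons, introns, region, orf))

        total_span = sum(len(r[4]) for r in regions)
        n_loci = len(regions)
        needed = total_span + (n_loci + 1) * _MIN_GAP
        if needed > glen:
            raise PlacementError(
                f"genome_length_per_species={glen} too short for "
                f"{n_loci} loci spanning {total_span} bp (needs >= {needed})"
            )

        extra = glen - needed
        gaps = np.floor(rng.dirichlet(np.ones(n_loci + 1)) * extra).astype(int) + _MIN_GAP

        genome = np.frombuffer(random_seq(rng, glen).encode("ascii"), dtype=np.uint8).copy()
        models: list[TranscriptModel] = []
        cursor = 0
        prefix = species[0].upper()
        for li, (kind, strand, genomic_exons, introns, region, orf) in enumerate(regions):
            cursor += int(gaps[li])
            start0 = cursor  # 0-based start of the region
            genome[start0 : start0 + len(region)] = np.frombuffer(region.encode("ascii"), dtype=np.uint8)
            exons = []
            p = start0
            for j, ex in enumerate(genomic_exons):
                exons.append((p + 1, p + len(ex)))
                p += len(ex)
                if j < len(introns):
                    p += len(introns[j])
            num = f"{li:04d}"
            models.append(
                TranscriptModel(
                    transcript_id=f"{prefix}T{num}",
                    gene_id=f"{prefix}G{num}",
                    species=species,
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    biotype=kind,
                    orf=orf,
                )
            )
            cursor += len(region)

        models.sort(key=lambda t: t.start)
        sequences[species] = {chrom: genome.tobytes().decode("ascii")}
        transcripts[species] = models

    return GenomeSet(sequences=sequences, transcripts=transcripts)


# ---------------------------------------------------------------------------
# expression and mobility propensity
# ---------------------------------------------------------------------------

@dataclass
class Abundances:
    """True per-transcript abundance weights and mobility designations.

    ``designated_mobile[s]`` is the set of species-``s`` transcripts eligible
    to emit foreign reads into the other species' stem library. The set is
    sampled without replacement with probability proportional to
    ``abundance ** abundance_mobility_bias``.
    """

    abundance: dict[str, pd.Series]
    propensity: dict[str, pd.Series]
    designated_mobile: dict[str, set[str]]

    def tissue_weights(self, species: str) -> pd.Series:
        """Sampling weights for native reads of a species (any tissue)."""
        a = self.abundance[species]
        return a / a.sum()


def simulate_expression(genomes: GenomeSet, config: SimConfig) -> Abundances:
    """Draw log-normal abundances and designate the mobile-eligible sets."""
    config.validate()
    rng = _child_rngs(config.seed, 4)[2]
    abundance, propensity, designated = {}, {}, {}
    outgoing_fraction = {
        "parasite": config.mobile_fraction_parasite_to_host,
        "host": config.mobile_fraction_host_to_parasite,
    }
    for species in SPECIES:
        ids = [t.transcript_id for t in genomes.transcripts[species]]
        a = pd.Series(rng.lognormal(0.0, config.abundance_sigma, size=len(ids)), index=ids)
        abundance[species] = a
        if len(ids):
            w = np.power(a.to_numpy(), config.abundance_mobility_bias)
            prop = pd.Series(w / w.sum(), index=ids)
        else:
            prop = pd.Series(dtype=float)
        propensity[species] = prop
        if outgoing_fraction[species] > 0 and len(ids):
            k = max(1, round(config.mobile_transcript_fraction * len(ids)))
            chosen = rng.choice(ids, size=min(k, len(ids)), replace=False, p=prop.to_numpy())
            designated[species] = set(chosen.tolist())
        else:
            designated[species] = set()
    return Abundances(abundance=abundance, propensity=propensity, designated_mobile=designated)


# ---------------------------------------------------------------------------
# read libraries
# ---------------------------------------------------------------------------

@dataclass
class LibrarySet:
    """Simulated read pairs per tissue plus skip log."""

    reads: dict[str, list[ReadRecord]]
    skipped: dict[str, int]
    config: SimConfig

    def truth_table(self) -> pd.DataFrame:
        rows = [
            (r.read_id, r.tissue, r.truth_species, r.truth_transcript_id,
             r.truth_spliced, r.truth_foreign)
            for tissue in TISSUES
            for r in self.reads.get(tissue, [])
        ]
        return pd.DataFrame(
            rows,
            columns=["read_id", "tissue", "truth_species", "truth_transcript_id",
                     "truth_spliced", "truth_foreign"],
        )

    def emitted_mobile_sets(self) -> dict[str, set[str]]:
        """Transcripts that actually emitted >= 1 foreign-origin pair into the
        other species' stem library (the recoverable ground truth)."""
        out: dict[str, set[str]] = {s: set() for s in SPECIES}
        for tissue, native in TISSUE_SPECIES.items():
            foreign = other_species(native)
            for r in self.reads.get(tissue, []):
                if r.truth_foreign:
                    out[foreign].add(r.truth_transcript_id)
        return out


def _mutate(seq: str, n_err: int, rng: np.random.Generator) -> str:
    if n_err == 0:
        return seq
    chars = list(seq)
    positions = rng.integers(0, len(chars), size=n_err)
    for p in positions:
        alternatives = [b for b in "ACGT" if b != chars[p]]
        chars[p] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def simulate_libraries(
    genomes: GenomeSet, abundances: Abundances, config: SimConfig
) -> LibrarySet:
    """Simulate the three tissue libraries.

    Native reads are drawn from both the spliced and (with probability
    ``unspliced_read_fraction``) unspliced templates of native transcripts;
    every foreign-origin read is drawn from the spliced mature sequence only.
    Reads start uniformly over the template; there is no fragment-size model
    because no downstream statistic here depends on one.
    """
    config.validate()
    rng_master = _child_rngs(config.seed, 4)[3]
    tissue_rngs = {t: r for t, r in zip(TISSUES, _child_rngs(int(rng_master.integers(2**31)), len(TISSUES)))}

    spliced: dict[str, dict[str, str]] = {}
    unspliced: dict[str, dict[str, str]] = {}
    for species in SPECIES:
        seqs = genomes.sequences[species]
        spliced[species] = {}
        unspliced[species] = {}
        for t in genomes.transcripts[species]:
            spliced[species][t.transcript_id] = t.spliced_sequence(seqs[t.chrom])
            if t.n_exons > 1:
                unspliced[species][t.transcript_id] = t.unspliced_sequence(seqs[t.chrom])

    rl = config.read_length
    qual = "I" * rl
    reads: dict[str, list[ReadRecord]] = {}
    skipped: dict[str, int] = {}

    for tissue in TISSUES:
        rng = tissue_rngs[tissue]
        n = config.n_read_pairs_per_tissue
        out: list[ReadRecord] = []
        n_skip = 0

        if tissue == "interface":
            species_is_parasite = rng.random(n) < config.interface_mix
            origin_species = np.where(species_is_parasite, "parasite", "host")
            foreign_mask = np.zeros(n, dtype=bool)
        else:
            native = TISSUE_SPECIES[tissue]
            foreign_sp = other_species(native)
            frac = (
                config.mobile_fraction_parasite_to_host
                if tissue == "host_stem"
                else config.mobile_fraction_host_to_parasite
            )
            foreign_mask = rng.random(n) < frac
            if foreign_mask.any() and not abundances.designated_mobile[foreign_sp]:
                raise SimulationError(
                    f"{tissue}: foreign reads requested but no {foreign_sp} "
                    "transcript is designated mobile (check mobile_transcript_fraction)"
                )
            origin_species = np.where(foreign_mask, foreign_sp, native)

        # per-species transcript choice
        chosen_ids = np.empty(n, dtype=object)
        for species in SPECIES:
            m = origin_species == species
            if not m.any():
                continue
            ids = abundances.abundance[species].index.to_numpy()
            w = abundances.tissue_weights(species).to_numpy()
            if tissue != "interface":
                fm = m & foreign_mask
                nm = m & ~foreign_mask
                if nm.any():
                    chosen_ids[nm] = rng.choice(ids, size=int(nm.sum()), p=w)
                if fm.any():
                    dlist = sorted(abundances.designated_mobile[species])
                    dw = abundances.abundance[species][dlist].to_numpy()
                    chosen_ids[fm] = rng.choice(np.array(dlist, dtype=object), size=int(fm.sum()), p=dw / dw.sum())
            else:
                chosen_ids[m] = rng.choice(ids, size=int(m.sum()), p=w)

        u_spliced = rng.random(n)
        u_start = rng.random(n)
        n_err1 = rng.binomial(rl, config.error_rate, size=n)
        n_err2 = rng.binomial(rl, config.error_rate, size=n)

        for i in range(n):
            tid = chosen_ids[i]
            species = str(origin_species[i])
            is_foreign = bool(foreign_mask[i])
            use_spliced = True
            if not is_foreign and tid in unspliced[species] and u_spliced[i] < config.unspliced_read_fraction:
                use_spliced = False
            template = spliced[species][tid] if use_spliced else unspliced[species][tid]
            if len(template) < rl:
                n_skip += 1
                continue
            s = int(u_start[i] * (len(template) - rl + 1))
            frag = template[s : s + rl]
            seq1 = _mutate(frag, int(n_err1[i]), rng)
            seq2 = _mutate(revcomp(frag), int(n_err2[i]), rng)
            out.append(
                ReadRecord(
                    read_id=f"{tissue}:{i:07d}",
                    seq1=seq1,
                    seq2=seq2,
                    qual=qual,
                    tissue=tissue,
                    truth_species=species,
                    truth_transcript_id=str(tid),
                    truth_spliced=use_spliced,
                    truth_foreign=is_foreign,
                )
            )
        reads[tissue] = out
        skipped[tissue] = n_skip

    return LibrarySet(reads=reads, skipped=skipped, config=config)


def simulate(config: SimConfig) -> tuple[GenomeSet, Abundances, LibrarySet]:
    """Convenience wrapper running the three simulation stages."""
    genomes = generate_genome_pair(config)
    ab = simulate_expression(genomes, config)
    libs = simulate_libraries(genomes, ab, config)
    return genomes, ab, libs
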