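"""Core domain objects: transcripts, genome pairs, and reads.

Conventions
-----------
* All annotation coordinates are 1-based closed intervals (GFF3 style).
  Conversion to 0-based half-open happens only inside BED/BedGraph writers.
* A genome pair always carries the two species labels ``"parasite"`` and
  ``"host"`` (the dodder and soybean of the study system, but nothing in the
  code depends on the organisms).
"""

from __future__ import annotations

from dataclasses import dataclass

from .sequtils import revcomp

SPECIES = ("parasite", "host")
TISSUES = ("parasite_stem", "interface", "host_stem")

#: native species of each pure stem tissue
TISSUE_SPECIES = {"parasite_stem": "parasite", "host_stem": "host"}

#: biotype labels used throughout
MRNA = "mRNA"
LNCRNA_TRUTH = "lncRNA-truth"
CANDIDATE = "candidate"


def other_species(species: str) -> str:
    if species == "parasite":
        return "host"
    if species == "host":
        return "parasite"
    raise ValueError(f"unknown species label: {species!r}")


@dataclass
class TranscriptModel:
    """One transcript: the unit of identification, quantification and targeting."""

    transcript_id: str
    gene_id: str
    species: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    biotype: str = CANDIDATE
    orf: tuple[int, int] | None = None  # 1-based closed, on the spliced sequence

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        prev_end = 0
        for s, e in self.exons:
            if s <= prev_end:
                raise ValueError(
                    f"{self.transcript_id}: exons must be sorted and non-overlapping"
                )
            if e < s:
                raise ValueError(f"{self.transcript_id}: empty exon ({s},{e})")
            prev_end = e
        if self.spliced_length < 1:
            raise ValueError(f"{self.transcript_id}: spliced length must be >= 1")
        if self.orf is not None:
            s, e = self.orf
            if not (1 <= s <= e <= self.spliced_length) or (e - s + 1) % 3:
                raise ValueError(f"{self.transcript_id}: invalid ORF interval {self.orf}")

    # -- geometry -----------------------------------------------------------
    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        """1-based closed intervals between consecutive exons."""
        return [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        ]

    # -- sequences ----------------------------------------------------------
    def spliced_sequence(self, chrom_seq: str) -> str:
        """Mature (spliced) transcript sequence in 5'->3' transcript orientation."""
        s = "".join(chrom_seq[a - 1 : b] for a, b in self.exons)
        return revcomp(s) if self.strand == "-" else s

    def unspliced_sequence(self, chrom_seq: str) -> str:
        """Pre-RNA sequence covering the full genomic span, transcript orientation."""
        s = chrom_seq[self.start - 1 : self.end]
        return revcomp(s) if self.strand == "-" else s


@dataclass
class GenomeSet:
    """The two species' genome sequences plus their transcript annotations."""

    sequences: dict[str, dict[str, str]]  # species -> chrom -> sequence
    transcripts: dict[str, list[TranscriptModel]]

    def __post_init__(self) -> None:
        for species, models in self.transcripts.items():
            chroms = self.sequences.get(species, {})
            for t in models:
                if t.chrom not in chroms:
                    raise ValueError(f"{t.transcript_id}: unknown chromosome {t.chrom}")
                if t.end > len(chroms[t.chrom]):
                    raise ValueError(f"{t.transcript_id}: exceeds chromosome length")

    def by_id(self, species: str) -> dict[str, TranscriptModel]:
        return {t.transcript_id: t for t in self.transcripts[species]}

    def spliced_sequences(self, species: str) -> dict[str, str]:
        seqs = self.sequences[species]
        return {
            t.transcript_id: t.spliced_sequence(seqs[t.chrom])
            for t in self.transcripts[species]
        }


@dataclass(slots=True)
class ReadRecord:
    """One simulated read pair with its ground-truth provenance."""

    read_id: str
    seq1: str
    seq2: str
    qual: str
    tissue: str
    truth_species: str | None = None
    truth_transcript_id: str | None = None
    truth_spliced: bool | None = None
    truth_foreign: bool = False  # True when the pair is a mobile (foreign-origin) pair
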