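"""Exon-overlap lookups shared by assignment summaries and fragment counting."""

from __future__ import annotations

from intervaltree import IntervalTree

from .models import GenomeSet


class ExonIndex:
    """Interval trees over exons, keyed by (species, chrom, strand).

    Coordinates stored 0-based half-open internally; queries take the
    package's 1-based closed intervals.
    """

    def __init__(self, genomes: GenomeSet):
        self._trees: dict[tuple[str, str, str], IntervalTree] = {}
        self.biotype: dict[str, str] = {}
        self.species_of: dict[str, str] = {}
        for species, models in genomes.transcripts.items():
            for t in models:
                key = (species, t.chrom, t.strand)
                tree = self._trees.setdefault(key, IntervalTree())
                for s, e in t.exons:
                    tree[s - 1 : e] = t.transcript_id
                self.biotype[t.transcript_id] = t.biotype
                self.species_of[t.transcript_id] = species

    def overlapping(
        self, species: str, chrom: str, strand: str, segments: list[tuple[int, int]]
    ) -> set[str]:
        """Transcript ids whose exons overlap any of the 1-based closed segments."""
        tree = self._trees.get((species, chrom, strand))
        if tree is None:
            return set()
        hits: set[str] = set()
        for s, e in segments:
            for iv in tree.overlap(s - 1, e):
                hits.add(iv.data)
        return hits
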