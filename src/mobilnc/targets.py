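"""Cis/trans target prediction for mobile lncRNAs, co-transfer detection,
term enrichment, TF-family tallies, and network export.

*Cis* targets are protein-coding genes whose genomic span lies strictly
closer than a window (default 100 kb) to the lncRNA's span. *Trans* targets
are ranked by a normalised hybridisation score ndG: a local
complementarity alignment between the two RNAs with per-pair energies
GC = -3, AU = -2, GU = -1 (arbitrary units) and a +4 gap/mismatch penalty;
dG is minus the best local score and ndG divides dG by the shorter
sequence length. The energy model is a transparent stand-in for a
published hybridisation predictor and is replaceable by an externally
computed pairs table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
from scipy import stats

from .models import TranscriptModel

DEFAULT_CIS_WINDOW = 100_000
DEFAULT_NDG_CUTOFF = -0.1

#: pairing scores in alignment space: sequence 2 is reverse-complemented, so
#: a Watson-Crick pair appears as an identity. GC pairs score 3, AU 2, and
#: the two G:U wobble configurations (G~A, T~C after the transform) 1.
_PAIR_SCORE = {
    ("G", "G"): 3, ("C", "C"): 3,
    ("A", "A"): 2, ("T", "T"): 2,
    ("G", "A"): 1, ("T", "C"): 1,
}
GAP_PENALTY = 4


class ReferentialIntegrityError(KeyError):
    pass


@dataclass
class TargetPair:
    """One lncRNA -> gene regulatory edge."""

    lncrna_id: str
    gene_id: str
    mode: str  # cis | trans
    distance_bp: int | None = None
    ndG: float | None = None
    lncrna_strand: str | None = None
    gene_strand: str | None = None
    lncrna_mobile: bool = False
    gene_mobile: bool = False

    def __post_init__(self) -> None:
        if self.mode == "cis" and (self.distance_bp is None or self.ndG is not None):
            raise ValueError("cis pairs carry distance_bp only")
        if self.mode == "trans" and (self.ndG is None or self.distance_bp is not None):
            raise ValueError("trans pairs carry ndG only")

    @property
    def cotransfer(self) -> bool:
        return self.lncrna_mobile and self.gene_mobile


# ---------------------------------------------------------------------------
# cis
# ---------------------------------------------------------------------------

def span_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Bases between the nearest ends of two 1-based closed spans; 0 when
    they overlap. Symmetric."""
    if a[0] <= b[1] and b[0] <= a[1]:
        return 0
    return b[0] - a[1] - 1 if b[0] > a[1] else a[0] - b[1] - 1


def predict_cis_targets(
    lncrnas: list[TranscriptModel],
    genes: list[TranscriptModel],
    window: int = DEFAULT_CIS_WINDOW,
) -> list[TargetPair]:
    """All (lncRNA, gene) pairs on one chromosome whose spans lie strictly
    less than ``window`` bp apart (overlap counts as distance 0). Strand is
    ignored for eligibility and recorded in the output."""
    pairs = []
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for l in lncrnas:
        for g in by_chrom.get(l.chrom, []):
            d = span_distance(l.span, g.span)
            if d < window:
                pairs.append(
                    TargetPair(
                        lncrna_id=l.transcript_id,
                        gene_id=g.gene_id,
                        mode="cis",
                        distance_bp=d,
                        lncrna_strand=l.strand,
                        gene_strand=g.strand,
                    )
                )
    return pairs


# ---------------------------------------------------------------------------
# trans
# ---------------------------------------------------------------------------

_RC = str.maketrans("ACGT", "TGCA")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _score_matrix() -> np.ndarray:
    m = np.full((256, 256), -GAP_PENALTY, dtype=np.int32)
    for (x, y), s in _PAIR_SCORE.items():
        m[ord(x), ord(y)] = s
    return m


_SCORES = _score_matrix()


def hybridization_score(seq1: str, seq2: str) -> int:
    """Best local complementarity alignment score between two RNAs.

    Implemented as Smith-Waterman of ``seq1`` against the reverse
    complement of ``seq2`` with the pair/gap scores above, swept along
    anti-diagonals so the inner loop is vectorised.
    """
    for name, s in (("seq1", seq1), ("seq2", seq2)):
        if not s:
            raise ValueError(f"{name} is empty")
        if not set(s) <= set("ACGTU"):
            raise ValueError(f"{name} must be over A/C/G/T/U")
    a = _encode(seq1.upper().replace("U", "T"))
    b = _encode(seq2.upper().replace("U", "T").translate(_RC)[::-1])
    n, m = len(a), len(b)
    sub = _SCORES[np.ix_(a, b)]
    prev2 = np.zeros(0, dtype=np.int64)
    prev1 = np.zeros(1, dtype=np.int64)
    best = 0
    # anti-diagonal d holds cells (i, j) with i + j = d
    for d in range(1, n + m):
        i_lo = max(1, d - m + 1) - 1  # 0-based row range on this diagonal
        i_hi = min(d, n)
        cur = np.zeros(i_hi - i_lo, dtype=np.int64)
        i = np.arange(i_lo, i_hi)
        j = d - 1 - i  # 0-based columns
        diag = np.zeros(len(i), dtype=np.int64)
        inner = (i > 0) & (j > 0)
        if inner.any():
            # cells (i-1, j-1) live on diagonal d-2
            off = (max(1, d - 2 - m + 1) - 1) if d >= 2 else 0
            diag[inner] = prev2[i[inner] - 1 - off]
        up = np.zeros(len(i), dtype=np.int64)
        left = np.zeros(len(i), dtype=np.int64)
        off1 = max(1, d - 1 - m + 1) - 1
        has_up = i > 0
        if has_up.any():
            up[has_up] = prev1[i[has_up] - 1 - off1]
        has_left = j > 0
        if has_left.any():
            left[has_left] = prev1[i[has_left] - off1]
        cur = np.maximum(0, diag + sub[i, j])
        cur = np.maximum(cur, up - GAP_PENALTY)
        cur = np.maximum(cur, left - GAP_PENALTY)
        m_ = int(cur.max()) if len(cur) else 0
        if m_ > best:
            best = m_
        prev2, prev1 = prev1, cur
    return best


def trans_pairing_score(lncrna_seq: str, mrna_seq: str) -> float:
    """ndG = -(best local hybridisation score) / min(len_lncrna, len_mrna)."""
    s = hybridization_score(lncrna_seq, mrna_seq)
    return -s / min(len(lncrna_seq), len(mrna_seq))


def predict_trans_targets(
    lncrna_seqs: dict[str, str],
    mrna_seqs: dict[str, str],
    gene_of: dict[str, str] | None = None,
    ndG_cutoff: float = DEFAULT_NDG_CUTOFF,
) -> list[TargetPair]:
    """Pairs with ndG <= cutoff, sorted by ndG ascending (strongest first).

    ``gene_of`` optionally maps mRNA transcript ids to gene ids for the
    emitted pairs (defaults to the transcript id itself).
    """
    pairs = []
    for lid, lseq in lncrna_seqs.items():
        for mid, mseq in mrna_seqs.items():
            ndg = trans_pairing_score(lseq, mseq)
            if ndg <= ndG_cutoff:
                pairs.append(
                    TargetPair(
                        lncrna_id=lid,
                        gene_id=(gene_of or {}).get(mid, mid),
                        mode="trans",
                        ndG=ndg,
                    )
                )
    pairs.sort(key=lambda p: (p.ndG, p.lncrna_id, p.gene_id))
    return pairs


# ---------------------------------------------------------------------------
# co-transfer
# ---------------------------------------------------------------------------

def identify_cotransfer_pairs(
    pairs: list[TargetPair],
    lncrna_mobility: dict[str, bool] | pd.Series,
    gene_mobility: dict[str, bool] | pd.Series,
) -> tuple[list[TargetPair], pd.DataFrame]:
    """Join mobility flags onto target pairs and return the co-transferred
    subset (mobile lncRNA AND mobile target gene) with counts by mode."""

    def look(table, key, what):
        try:
            return bool(table[key])
        except KeyError:
            raise ReferentialIntegrityError(f"{what} {key!r} has no mobility flag") from None

    co = []
    tallies: dict[str, dict[str, int]] = {}
    for p in pairs:
        p.lncrna_mobile = look(lncrna_mobility, p.lncrna_id, "lncRNA")
        p.gene_mobile = look(gene_mobility, p.gene_id, "gene")
        t = tallies.setdefault(p.mode, {"pairs": 0, "cotransfer": 0})
        t["pairs"] += 1
        if p.cotransfer:
            t["cotransfer"] += 1
            co.append(p)
    summary = pd.DataFrame(tallies).T.rename_axis("mode") if tallies else pd.DataFrame()
    return co, summary


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def enrich_terms(
    gene_set: set[str],
    term_map: dict[str, tuple[str, set[str]]],
    background: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per term.

    p = P(X >= overlap) with X ~ Hypergeom(N=|background|, K=|term|,
    n=|gene_set|). ``enriched`` applies the raw-p criterion (p < alpha);
    a Benjamini-Hochberg column is reported alongside for rigour.
    """
    if not background:
        raise ValueError("empty background")
    if not gene_set <= background:
        raise ValueError("gene_set must be a subset of background")
    M = len(background)
    N = len(gene_set)
    rows = []
    for term_id, (name, genes) in sorted(term_map.items()):
        genes = genes & background
        k = len(genes & gene_set)
        p = float(stats.hypergeom.sf(k - 1, M, len(genes), N))
        rows.append(
            {
                "term_id": term_id,
                "term_name": name,
                "set_count": k,
                "background_count": len(genes),
                "p_value": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_bh"] = stats.false_discovery_control(df["p_value"], method="bh")
        df["enriched"] = df["p_value"] < alpha
    return df


# ---------------------------------------------------------------------------
# TF families
# ---------------------------------------------------------------------------

def assign_tf_families(
    pairs: list[TargetPair],
    family_map: dict[str, str],
) -> pd.DataFrame:
    """Per TF family: number of targeted genes and number of distinct
    lncRNAs targeting them, sorted by lncRNA count (descending). Genes
    absent from the family map land in an "unassigned" bucket."""
    genes_by_family: dict[str, set[str]] = {}
    lncs_by_family: dict[str, set[str]] = {}
    for p in pairs:
        fam = family_map.get(p.gene_id, "unassigned")
        genes_by_family.setdefault(fam, set()).add(p.gene_id)
        lncs_by_family.setdefault(fam, set()).add(p.lncrna_id)
    rows = [
        {"family": fam, "n_genes": len(genes_by_family[fam]), "n_lncrnas": len(lncs_by_family[fam])}
        for fam in genes_by_family
    ]
    df = pd.DataFrame(rows, columns=["family", "n_genes", "n_lncrnas"])
    return df.sort_values(
        ["n_lncrnas", "n_genes", "family"], ascending=[False, False, True]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------

def export_network(
    pairs: list[TargetPair],
    outdir: str | Path,
    tf_families: dict[str, str] | None = None,
    basename: str = "network",
) -> tuple[Path, Path]:
    """Write a Cytoscape-ready SIF edge list plus a node-attribute TSV.

    Node roles: lncRNA (sources), TF (targets present in the family map),
    mRNA (other targets).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sif = outdir / f"{basename}.sif"
    nodes = outdir / f"{basename}.nodes.tsv"
    tf_families = tf_families or {}
    with open(sif, "w") as fh:
        for p in pairs:
            fh.write(f"{p.lncrna_id}\ttargets\t{p.gene_id}\n")
    rows = {}
    for p in pairs:
        rows[p.lncrna_id] = ("lncRNA", "", p.lncrna_mobile)
        role = "TF" if p.gene_id in tf_families else "mRNA"
        rows[p.gene_id] = (role, tf_families.get(p.gene_id, ""), p.gene_mobile)
    with open(nodes, "w") as fh:
        fh.write("node_id\trole\ttf_family\tmobile\n")
        for nid in sorted(rows):
            role, fam, mob = rows[nid]
            fh.write(f"{nid}\t{role}\t{fam}\t{str(mob).lower()}\n")
    return sif, nodes


def write_pairs_tsv(pairs: list[TargetPair], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "lncrna_id": p.lncrna_id,
                "gene_id": p.gene_id,
                "mode": p.mode,
                "distance_bp": p.distance_bp if p.distance_bp is not None else "",
                "ndG": p.ndG if p.ndG is not None else "",
                "lncrna_mobile": p.lncrna_mobile,
                "gene_mobile": p.gene_mobile,
                "cotransfer": p.cotransfer,
            }
            for p in pairs
        ]
    ).to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path: str | Path) -> list[TargetPair]:
    df = pd.read_csv(path, sep="\t")
    pairs = []
    for _, r in df.iterrows():
        mode = r["mode"]
        pairs.append(
            TargetPair(
                lncrna_id=r["lncrna_id"],
                gene_id=r["gene_id"],
                mode=mode,
                distance_bp=int(r["distance_bp"]) if mode == "cis" else None,
                ndG=float(r["ndG"]) if mode == "trans" else None,
                lncrna_mobile=bool(r["lncrna_mobile"]),
                gene_mobile=bool(r["gene_mobile"]),
            )
        )
    return pairs


def subnetwork_by_term(
    pairs: list[TargetPair],
    term_map: dict[str, tuple[str, set[str]]],
    term_id: str,
) -> list[TargetPair]:
    """Pairs whose target gene carries the given term."""
    try:
        _, genes = term_map[term_id]
    except KeyError:
        raise ReferentialIntegrityError(f"unknown term {term_id!r}") from None
    return [p for p in pairs if p.gene_id in genes]
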