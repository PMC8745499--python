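"""Quantification tests: fragment counting vs truth, the FPKM formula,
mobility calls and the transfer table, abundance/correlation statistics,
coverage tracks and z-scoring."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mobilnc.assign import Alignment, PairAssignment
from mobilnc.models import GenomeSet, TranscriptModel, SPECIES
from mobilnc.quantify import (
    CountResult,
    ExpressionMatrix,
    InsufficientDataError,
    MobilityTable,
    abundance_mobility_summary,
    build_mobility_table,
    call_transcript_mobility,
    compute_fpkm,
    count_fragments,
    coverage_track,
    interface_correlation,
    percent,
    zscore_matrix,
)

from oracles import ols_closed_form


def _mini_catalog():
    seqs = {"parasite": {"p1": "A" * 5_000}, "host": {"h1": "A" * 5_000}}
    tr = {
        "parasite": [
            TranscriptModel("tA", "gA", "parasite", "p1", "+", [(101, 400)], "mRNA"),
            TranscriptModel("tB", "gB", "parasite", "p1", "+", [(301, 700)], "mRNA"),
        ],
        "host": [TranscriptModel("tH", "gH", "host", "h1", "+", [(101, 400)], "lncRNA-truth")],
    }
    return GenomeSet(seqs, tr)


def _pa(read_id, tissue, label, species, chrom, segs, strand="+"):
    aln = Alignment(chrom, strand, segs, 0, sum(e - s + 1 for s, e in segs))
    return PairAssignment(read_id, tissue, label, species, aln)


def test_fragment_inside_one_exon_counts_once():
    cat = _mini_catalog()
    a = _pa("r1", "parasite_stem", "native", "parasite", "p1", [(150, 250)])
    res = count_fragments({"parasite_stem": [a]}, cat)
    assert res.counts.at["tA", "parasite_stem"] == 1.0
    assert res.counts.at["tB", "parasite_stem"] == 0.0
    assert res.totals["parasite_stem"] == 1


def test_fragment_over_two_transcripts_splits_half():
    cat = _mini_catalog()
    a = _pa("r1", "parasite_stem", "native", "parasite", "p1", [(350, 390)])
    res = count_fragments({"parasite_stem": [a]}, cat)
    assert res.counts.at["tA", "parasite_stem"] == 0.5
    assert res.counts.at["tB", "parasite_stem"] == 0.5


def test_unannotated_fragment_goes_intergenic():
    cat = _mini_catalog()
    a = _pa("r1", "parasite_stem", "native", "parasite", "p1", [(2_000, 2_100)])
    res = count_fragments({"parasite_stem": [a]}, cat)
    assert res.intergenic["parasite_stem"] == 1
    assert res.counts["parasite_stem"].sum() == 0


def test_wrong_strand_fragment_not_counted():
    cat = _mini_catalog()
    a = _pa("r1", "parasite_stem", "native", "parasite", "p1", [(150, 250)], strand="-")
    res = count_fragments({"parasite_stem": [a]}, cat)
    assert res.counts["parasite_stem"].sum() == 0


def test_counts_equal_truth_tallies(clean_run):
    """Error-free fully-spliced simulation: per-transcript fragment counts
    equal the truth-table tallies exactly in every tissue."""
    truth = clean_run.libraries.truth_table()
    got = clean_run.counts.counts
    for tissue in got.columns:
        expected = truth[truth.tissue == tissue].groupby("truth_transcript_id").size()
        for tid in got.index:
            assert got.at[tid, tissue] == expected.get(tid, 0), (tid, tissue)


# ---------------------------------------------------------------------------
# FPKM
# ---------------------------------------------------------------------------

def test_fpkm_direct_formula():
    counts = pd.DataFrame({"t1": [10.0, 0.0]}, index=["x", "y"])
    lengths = pd.Series({"x": 1_000, "y": 500})
    totals = pd.Series({"t1": 1_000_000})
    em = compute_fpkm(counts, lengths, totals)
    assert em.fpkm.at["x", "t1"] == pytest.approx(10.0)
    assert em.fpkm.at["y", "t1"] == 0.0


def test_fpkm_matches_independent_recompute():
    rng = np.random.default_rng(3)
    counts = pd.DataFrame(
        rng.integers(0, 500, size=(30, 3)).astype(float),
        index=[f"t{i}" for i in range(30)], columns=list("abc"),
    )
    lengths = pd.Series(rng.integers(200, 5_000, size=30), index=counts.index)
    totals = pd.Series(rng.integers(10_000, 100_000, size=3), index=counts.columns)
    em = compute_fpkm(counts, lengths, totals)
    for t in counts.index:
        for c in counts.columns:
            manual = counts.at[t, c] * 1e9 / (totals[c] * lengths[t])
            assert abs(em.fpkm.at[t, c] - manual) <= 1e-9 * max(manual, 1)


def test_fpkm_scale_invariance():
    counts = pd.DataFrame({"t1": [7.0, 3.0]}, index=["x", "y"])
    lengths = pd.Series({"x": 700, "y": 1_500})
    totals = pd.Series({"t1": 50_000})
    a = compute_fpkm(counts, lengths, totals).fpkm
    b = compute_fpkm(counts * 2, lengths, totals * 2).fpkm
    assert np.allclose(a, b)


def test_fpkm_zero_total_raises():
    with pytest.raises(InsufficientDataError):
        compute_fpkm(
            pd.DataFrame({"t1": [0.0]}, index=["x"]),
            pd.Series({"x": 100}),
            pd.Series({"t1": 0}),
        )


# ---------------------------------------------------------------------------
# mobility calls
# ---------------------------------------------------------------------------

def _count_result(mobile_host_stem: dict[str, float], cat) -> CountResult:
    tids = [t.transcript_id for s in SPECIES for t in cat.transcripts[s]]
    tissues = ["parasite_stem", "host_stem"]
    zero = pd.DataFrame(0.0, index=tids, columns=tissues)
    mob = zero.copy()
    for tid, v in mobile_host_stem.items():
        mob.at[tid, "host_stem"] = v
    return CountResult(zero.copy(), mob, pd.Series(0.0, index=tissues),
                       pd.Series(100, index=tissues))


def test_mobility_threshold_and_monotonicity():
    cat = _mini_catalog()
    res = _count_result({"tA": 2.0, "tB": 0.5}, cat)
    f1 = call_transcript_mobility(res, cat, min_mobile_fragments=0.5)
    f2 = call_transcript_mobility(res, cat, min_mobile_fragments=1)
    f3 = call_transcript_mobility(res, cat, min_mobile_fragments=3)
    assert f1["tA"] and f1["tB"]
    assert f2["tA"] and not f2["tB"]
    assert not f3["tA"]
    # raising the threshold never enlarges the mobile set
    assert set(f2[f2].index) <= set(f1[f1].index)
    assert set(f3[f3].index) <= set(f2[f2].index)


def test_mobility_calls_recover_truth(small_run):
    stats_ = small_run.recovery_stats()
    assert stats_["sensitivity"] == 1.0
    assert stats_["specificity"] == 1.0


def test_interface_detection_never_confers_mobility():
    cat = _mini_catalog()
    tids = [t.transcript_id for s in SPECIES for t in cat.transcripts[s]]
    tissues = ["parasite_stem", "interface", "host_stem"]
    zero = pd.DataFrame(0.0, index=tids, columns=tissues)
    mob = zero.copy()
    mob.at["tA", "interface"] = 50.0
    res = CountResult(zero.copy(), mob, pd.Series(0.0, index=tissues),
                      pd.Series(100, index=tissues))
    flags = call_transcript_mobility(res, cat)
    assert not flags.any()


# ---------------------------------------------------------------------------
# mobility table
# ---------------------------------------------------------------------------

def test_table_conservation_and_zero_case():
    mt = MobilityTable.from_counts({
        ("parasite", "lncRNA-truth"): (100, 0),
        ("host", "lncRNA-truth"): (50, 0),
    })
    df = mt.to_frame()
    assert (df["mobile"] + df["nonmobile"] == df["total"]).all()
    assert df["mobile_pct"].tolist() == [0.0, 0.0]


def test_table_rejects_impossible_counts():
    with pytest.raises(ValueError):
        MobilityTable.from_counts({("parasite", "mRNA"): (10, 11)})


def test_percent_rounding_is_half_up():
    assert percent(365, 4688) == 7.8
    assert percent(125, 1000) == 12.5
    assert percent(5, 1000) == 0.5
    assert percent(145, 10000) == 1.5   # 1.45 rounds half-up at 1 decimal
    assert percent(999, 100000) == 1.0  # 0.999% -> 1.0 (2dp rounds to 1.00)


def test_built_table_matches_flags(small_run):
    mt = small_run.mobility_table
    flags = small_run.mobility_flags
    byid = {s: small_run.genomes.by_id(s) for s in SPECIES}
    for (species, biotype), row in mt.table.iterrows():
        ids = [t for t, m in byid[species].items() if m.biotype == biotype]
        assert row["total"] == len(ids)
        assert row["mobile"] == int(flags[ids].sum())


# ---------------------------------------------------------------------------
# abundance vs mobility
# ---------------------------------------------------------------------------

def _expr_from_fpkm(fpkm: pd.DataFrame) -> ExpressionMatrix:
    lengths = pd.Series(1_000, index=fpkm.index)
    totals = pd.Series(1_000_000, index=fpkm.columns)
    counts = fpkm * 1.0
    return ExpressionMatrix(counts, fpkm, totals, lengths)


def test_single_transcript_sets_report_their_own_medians():
    cat = _mini_catalog()
    fpkm = pd.DataFrame({"interface": {"tA": 3.0, "tB": 7.0, "tH": 1.0}})
    expr = _expr_from_fpkm(fpkm)
    flags = pd.Series({"tA": True, "tB": False, "tH": False})
    df = abundance_mobility_summary(expr, flags, cat)
    row = df[(df.species == "parasite") & (df.biotype == "mRNA")].iloc[0]
    assert row["mobile_median"] == pytest.approx(math.log2(4.0))
    assert row["nonmobile_median"] == pytest.approx(math.log2(8.0))


def test_mannwhitney_null_calibration():
    """Identical mobile/non-mobile distributions: the one-sided test
    rejects at ~5% over 100 seeded replicates."""
    rng = np.random.default_rng(123)
    cat = GenomeSet(
        {"parasite": {"p1": "A" * 400_000}, "host": {"h1": "A" * 100}},
        {
            "parasite": [
                TranscriptModel(f"t{i}", f"g{i}", "parasite", "p1", "+",
                                [(1 + 400 * i, 300 + 400 * i)], "lncRNA-truth")
                for i in range(250)
            ],
            "host": [],
        },
    )
    tids = [f"t{i}" for i in range(250)]
    rejections = 0
    for rep in range(100):
        fpkm = pd.DataFrame({"interface": pd.Series(rng.lognormal(0, 1, 250), index=tids)})
        flags = pd.Series(False, index=tids)
        flags.iloc[rng.choice(250, size=50, replace=False)] = True
        df = abundance_mobility_summary(_expr_from_fpkm(fpkm), flags, cat)
        p = df[(df.species == "parasite") & (df.biotype == "lncRNA-truth")]["p_value"].iloc[0]
        rejections += p < 0.05
    rate = rejections / 100
    sigma = math.sqrt(0.05 * 0.95 / 100)
    assert abs(rate - 0.05) <= 3 * sigma


# ---------------------------------------------------------------------------
# interface correlation
# ---------------------------------------------------------------------------

def _fpkm_for_log_points(xs, ys, eps=1e-3):
    ids = [f"t{i}" for i in range(len(xs))]
    return pd.DataFrame(
        {
            "interface": pd.Series([10.0**x - eps for x in xs], index=ids),
            "host_stem": pd.Series([10.0**y - eps for y in ys], index=ids),
        }
    )


def test_regression_recovers_exact_line():
    xs = [0.1, 0.5, 1.0, 1.5, 2.0]
    ys = [2 * x + 1 for x in xs]
    expr = _expr_from_fpkm(_fpkm_for_log_points(xs, ys))
    flags = pd.Series(True, index=expr.fpkm.index)
    res = interface_correlation(expr, flags)
    assert res.slope == pytest.approx(2.0, abs=1e-9)
    assert res.intercept == pytest.approx(1.0, abs=1e-9)
    assert res.r == pytest.approx(1.0, abs=1e-12)


def test_regression_hand_ols():
    xs, ys = [1.0, 2.0, 3.0], [1.0, 3.0, 5.0]
    expr = _expr_from_fpkm(_fpkm_for_log_points(xs, ys))
    flags = pd.Series(True, index=expr.fpkm.index)
    res = interface_correlation(expr, flags)
    assert res.slope == pytest.approx(2.0, abs=1e-9)
    assert res.intercept == pytest.approx(-1.0, abs=1e-9)
    assert res.r == pytest.approx(1.0, abs=1e-12)


def test_regression_matches_closed_form():
    rng = np.random.default_rng(21)
    xs = rng.normal(1.0, 0.4, 500)
    ys = 0.8 * xs + rng.normal(0, 0.3, 500)
    expr = _expr_from_fpkm(_fpkm_for_log_points(xs, ys))
    flags = pd.Series(True, index=expr.fpkm.index)
    res = interface_correlation(expr, flags)
    # recompute on the exact points the implementation used
    x_used = np.log10(expr.fpkm["interface"] + 1e-3)
    y_used = np.log10(expr.fpkm["host_stem"] + 1e-3)
    slope, intercept, r = ols_closed_form(list(x_used), list(y_used))
    assert res.slope == pytest.approx(slope, abs=1e-9)
    assert res.intercept == pytest.approx(intercept, abs=1e-9)
    assert res.r == pytest.approx(r, abs=1e-9)


def test_regression_insufficient_data():
    expr = _expr_from_fpkm(_fpkm_for_log_points([1.0, 2.0], [1.0, 2.0]))
    flags = pd.Series(True, index=expr.fpkm.index)
    with pytest.raises(InsufficientDataError):
        interface_correlation(expr, flags)


# ---------------------------------------------------------------------------
# coverage tracks
# ---------------------------------------------------------------------------

def test_coverage_single_read():
    t = TranscriptModel("t", "g", "parasite", "c", "+", [(1, 100)], "mRNA")
    a = _pa("r", "parasite_stem", "native", "parasite", "c", [(10, 59)])
    tr = coverage_track([a], t, "parasite_stem")
    assert tr.depth[9:59].tolist() == [1] * 50
    assert tr.depth.sum() == 50


def test_coverage_depth_conserves_aligned_bases():
    t = TranscriptModel("t", "g", "parasite", "c", "+", [(1, 500)], "mRNA")
    pas = [
        _pa("r1", "parasite_stem", "native", "parasite", "c", [(10, 59)]),
        _pa("r2", "parasite_stem", "native", "parasite", "c", [(40, 139)]),
        _pa("r3", "parasite_stem", "native", "parasite", "c", [(400, 500)]),
    ]
    tr = coverage_track(pas, t, "parasite_stem")
    assert tr.depth.sum() == 50 + 100 + 101


def test_junction_counts():
    t = TranscriptModel("t", "g", "parasite", "c", "+", [(1, 100), (201, 300)], "mRNA")
    spanning = _pa("r1", "parasite_stem", "native", "parasite", "c", [(51, 100), (201, 250)])
    contained = _pa("r2", "parasite_stem", "native", "parasite", "c", [(1, 80)])
    tr = coverage_track([spanning, contained], t, "parasite_stem")
    assert tr.junctions == {(101, 200): 1}
    assert tr.intronic_depth(t) == 0


def test_foreign_tissue_tracks_have_zero_intronic_depth(small_run):
    g = small_run.genomes
    checked = 0
    for species, stem in (("parasite", "host_stem"), ("host", "parasite_stem")):
        emitted = small_run.libraries.emitted_mobile_sets()[species]
        for tid in emitted:
            t = g.by_id(species)[tid]
            tr = coverage_track(small_run.assignments[stem], t, stem, mobile_only=True)
            assert tr.intronic_depth(t) == 0
            assert tr.depth.sum() > 0
            checked += 1
    assert checked > 0


# ---------------------------------------------------------------------------
# z-scores
# ---------------------------------------------------------------------------

def test_zscore_constant_row_flagged():
    fpkm = pd.DataFrame({"a": {"t": 1.0}, "b": {"t": 1.0}, "c": {"t": 1.0}})
    z, const = zscore_matrix(_expr_from_fpkm(fpkm), ["t"])
    assert z.loc["t"].tolist() == [0.0, 0.0, 0.0]
    assert const["t"]


def test_zscore_rows_standardised():
    rng = np.random.default_rng(31)
    fpkm = pd.DataFrame(
        rng.lognormal(0, 1, size=(50, 3)),
        index=[f"t{i}" for i in range(50)], columns=list("abc"),
    )
    for base in (2, 10):
        z, const = zscore_matrix(_expr_from_fpkm(fpkm), list(fpkm.index), log_base=base)
        assert not const.any()
        assert np.allclose(z.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z.std(axis=1, ddof=0), 1, atol=1e-9)


def test_zscore_requires_two_tissues():
    fpkm = pd.DataFrame({"a": {"t": 1.0}})
    with pytest.raises(ValueError):
        zscore_matrix(_expr_from_fpkm(fpkm), ["t"], tissues=["a"])
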