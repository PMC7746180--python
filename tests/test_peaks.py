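"""Peak fold filtering, promoter assignment and region classification."""

import numpy as np
import pandas as pd
import pytest

from oxpattern import (
    GeneModel,
    assign_to_promoters,
    class_fractions,
    classify_peaks,
    classify_region,
    filter_peaks_fold,
    simulate_peaks,
)


def peak_frame(rows):
    return pd.DataFrame(rows, columns=["contig", "start", "end", "name",
                                       "sample_depth", "control_depth"])


def test_fold_arithmetic_and_strictness():
    peaks = peak_frame([
        ("c", 0, 100, "p1", 10.0, 2.0),   # (10+1)/(2+1) = 3.67 -> kept
        ("c", 0, 100, "p2", 4.0, 2.0),    # (4+1)/(2+1) = 1.67 -> dropped
    ])
    kept = filter_peaks_fold(peaks, 2.0, pseudocount=1.0)
    assert kept["name"].tolist() == ["p1"]
    assert kept["fold"].iloc[0] == pytest.approx(11 / 3)
    # pseudocount 0: fold exactly 2 is dropped (strict inequality)
    kept0 = filter_peaks_fold(peak_frame([("c", 0, 1, "p", 4.0, 2.0)]), 2.0, 0.0)
    assert len(kept0) == 0


def test_negative_depth_rejected():
    with pytest.raises(ValueError, match="depth"):
        filter_peaks_fold(peak_frame([("c", 0, 1, "p", -1.0, 2.0)]))


def test_threshold_monotonicity():
    table, _ = simulate_peaks(200, {"chr1": 1_000_000}, enriched_fraction=0.5,
                              enriched_fold=4.0, depth_noise=0.5, seed=6)
    sizes = [len(filter_peaks_fold(table, thr)) for thr in (1.5, 2.0, 3.0, 4.0)]
    assert sizes == sorted(sizes, reverse=True)


def test_planted_enrichment_recovered_exactly_without_noise():
    table, truth = simulate_peaks(100, {"chr1": 500_000}, enriched_fraction=0.3,
                                  enriched_fold=4.0, depth_noise=0.0, seed=2)
    kept = filter_peaks_fold(table, 2.0)
    assert set(kept["name"]) == {n for n, e in truth.enriched.items() if e}
    none_table, _ = simulate_peaks(50, {"chr1": 500_000}, enriched_fraction=0.0,
                                   enriched_fold=4.0, depth_noise=0.0, seed=2)
    assert len(filter_peaks_fold(none_table, 2.0)) == 0


def test_noise_sensitivity_matches_monte_carlo():
    """Sensitivity/specificity of the >2 filter vs a direct re-simulation."""
    kw = dict(contig_lengths={"chr1": 10_000_000}, enriched_fraction=0.5,
              enriched_fold=4.0, depth_noise=0.4)
    table, truth = simulate_peaks(2000, seed=10, **kw)
    kept = set(filter_peaks_fold(table, 2.0)["name"])
    enr = {n for n, e in truth.enriched.items() if e}
    sens = len(kept & enr) / len(enr)
    spec = 1 - len(kept - enr) / (2000 - len(enr))
    big, big_truth = simulate_peaks(10_000, seed=11, **kw)
    big_kept = set(filter_peaks_fold(big, 2.0)["name"])
    big_enr = {n for n, e in big_truth.enriched.items() if e}
    mc_sens = len(big_kept & big_enr) / len(big_enr)
    mc_spec = 1 - len(big_kept - big_enr) / (10_000 - len(big_enr))
    assert sens == pytest.approx(mc_sens, abs=0.05)
    assert spec == pytest.approx(mc_spec, abs=0.05)


# ---------------------------------------------------------------------------
# promoter assignment
# ---------------------------------------------------------------------------

def test_assignment_inside_and_outside_window(three_gene_models):
    peaks = peak_frame([
        ("chr1", 95_500, 95_600, "in_gA", 10, 1),     # within [95000, 100500)
        ("chr1", 94_000, 94_900, "before_gA", 10, 1), # ends before tss-5000
        ("chr1", 205_000, 205_100, "up_gB", 10, 1),   # minus strand upstream
        ("chr2", 95_500, 95_600, "wrong_contig", 10, 1),
    ])
    genes, table = assign_to_promoters(peaks, three_gene_models)
    assigned = table.set_index("name")["genes"].to_dict()
    assert assigned["in_gA"] == "gA"
    assert assigned["before_gA"] == ""
    assert assigned["up_gB"] == "gB"
    assert assigned["wrong_contig"] == ""
    assert genes == {"gA", "gB"}


def test_one_base_overlap_assigns(three_gene_models):
    # plus-strand window is [tss-5000, tss+500); a peak ending at 95001
    # overlaps by exactly one base, one ending at 95000 does not
    peaks = peak_frame([
        ("chr1", 94_900, 95_001, "one_base", 10, 1),
        ("chr1", 94_900, 95_000, "zero_base", 10, 1),
    ])
    genes, table = assign_to_promoters(peaks, three_gene_models)
    assigned = table.set_index("name")["genes"].to_dict()
    assert assigned["one_base"] == "gA" and assigned["zero_base"] == ""


def test_assignment_matches_quadratic_oracle():
    rng = np.random.default_rng(13)
    models = []
    for i in range(40):
        start = int(rng.integers(10_000, 2_000_000))
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(rng.integers(500, 5000))
        tss = start if strand == "+" else start + length - 1
        models.append(GeneModel(f"g{i}", "chr1", strand, tss, ((start, start + length),)))
    peaks = peak_frame([
        ("chr1", int(s), int(s) + 200, f"p{j}", 10, 1)
        for j, s in enumerate(rng.integers(0, 2_100_000, size=300))
    ])
    genes, table = assign_to_promoters(peaks, models)
    # brute-force all-pairs interval overlap
    expected = {}
    for row in peaks.itertuples(index=False):
        hit = []
        for gm in models:
            ws, we = gm.promoter_window(5000, 500)
            if row.start < we and ws < row.end:
                hit.append(gm.gene_id)
        expected[row.name] = ";".join(sorted(hit))
    assert table.set_index("name")["genes"].to_dict() == expected


def test_strand_mirror_symmetry():
    """Mirroring the whole annotation and peaks flips nothing."""
    L = 1_000_000
    models = [GeneModel("g", "chr1", "+", 600_000, ((600_000, 605_000),))]
    mirrored = [GeneModel("g", "chr1", "-", L - 600_000 - 1,
                          ((L - 605_000, L - 600_000),))]
    peaks = peak_frame([("chr1", 596_000, 596_200, "p", 10, 1)])
    m_peaks = peak_frame([("chr1", L - 596_200, L - 596_000, "p", 10, 1)])
    g1, _ = assign_to_promoters(peaks, models)
    g2, _ = assign_to_promoters(m_peaks, mirrored)
    assert g1 == g2 == {"g"}


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def test_classification_precedence_and_classes(three_gene_models):
    # gA: exons (100000,100500) + (101000,101400); promoter [95000, 100500)
    assert classify_region(("chr1", 100_100, 100_200), three_gene_models) == "promoter"
    assert classify_region(("chr1", 101_100, 101_200), three_gene_models) == "exon"
    assert classify_region(("chr1", 100_600, 100_900), three_gene_models) == "intron"
    assert classify_region(("chr1", 500_000, 500_100), three_gene_models) == "intergenic"
    assert classify_region(("chr2", 100_100, 100_200), three_gene_models) == "intergenic"


def test_class_fractions_match_constructed_truth(three_gene_models):
    peaks = peak_frame([
        ("chr1", 96_000, 96_100, "a", 10, 1),      # promoter of gA
        ("chr1", 101_100, 101_150, "b", 10, 1),    # exon 2 of gA
        ("chr1", 100_600, 100_700, "c", 10, 1),    # intron of gA
        ("chr1", 700_000, 700_100, "d", 10, 1),    # intergenic
    ])
    classified = classify_peaks(peaks, three_gene_models)
    assert classified["region_class"].tolist() == ["promoter", "exon", "intron", "intergenic"]
    fr = class_fractions(classified)
    assert fr == {"promoter": 0.25, "exon": 0.25, "intron": 0.25, "intergenic": 0.25}


def test_gene_model_validation():
    with pytest.raises(ValueError, match="exons"):
        GeneModel("g", "c", "+", 10, ((20, 10),))
    with pytest.raises(ValueError, match="tss"):
        GeneModel("g", "c", "+", 50, ((10, 20),))
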