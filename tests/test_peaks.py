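"""Peak IO, activity scoring/normalization, interval intersection against a
per-base oracle, and target-gene assignment against a quadratic oracle."""

import numpy as np
import pandas as pd
import pytest

from epidriver.exceptions import PeakFormatError, ValidationError
from epidriver.peaks import (
    GenomicInterval,
    PeakSet,
    activity_score,
    assign_target_genes,
    build_activity_matrix,
    covered_bases,
    intersect_peaks,
    read_peak_file,
    write_peak_file,
)
from epidriver.synthetic import GeneratorConfig, generate_cohort, generate_peak_files

from conftest import single_pair_config


def _write_lines(path, lines):
    path.write_text("".join(l + "\n" for l in lines))
    return path


NARROW_LINES = [
    "chr1\t100\t300\tp1\t0\t.\t3.0\t-1\t-1\t100",
    "chr1\t500\t900\tp2\t0\t.\t7.5\t-1\t-1\t200",
    "chr2\t10\t50\tp3\t0\t.\t0.0\t-1\t-1\t20",
]


def test_read_narrowpeak(tmp_path):
    ps = read_peak_file(_write_lines(tmp_path / "s__f.narrowPeak", NARROW_LINES), "narrowPeak")
    assert len(ps) == 3
    assert ps.sample_id == "s" and ps.factor_id == "f"
    assert ps.intervals[0] == GenomicInterval("chr1", 100, 300, 3.0)


def test_broadpeak_rejects_ten_columns(tmp_path):
    path = _write_lines(tmp_path / "x.broadPeak", NARROW_LINES)  # 10 cols
    with pytest.raises(PeakFormatError) as err:
        read_peak_file(path, "broadPeak")
    assert err.value.line_number == 1


def test_start_ge_end_rejected(tmp_path):
    path = _write_lines(tmp_path / "x.narrowPeak", ["chr1\t300\t300\tp\t0\t.\t1\t-1\t-1\t0"])
    with pytest.raises(ValidationError):
        read_peak_file(path, "narrowPeak")


def test_write_read_round_trip(tmp_path, rng):
    ivs = [
        GenomicInterval("chr%d" % rng.integers(1, 3), int(s), int(s) + int(rng.integers(1, 500)),
                        float(np.round(rng.random() * 50, 6)))
        for s in rng.integers(0, 10_000, size=40)
    ]
    ps = PeakSet("cl", "tf", "TF", ivs, "narrowPeak")
    write_peak_file(ps, tmp_path / "cl__tf.narrowPeak")
    back = read_peak_file(tmp_path / "cl__tf.narrowPeak", "narrowPeak")
    assert [(i.chrom, i.start, i.end, i.signal) for i in back.intervals] == [
        (i.chrom, i.start, i.end, i.signal) for i in ps.intervals
    ]


def test_activity_score_definition(rng):
    single = PeakSet("s", "f", "TF", [GenomicInterval("chr1", 0, 10, 3.0)])
    assert activity_score(single) == pytest.approx(2.0)
    const = PeakSet("s", "f", "TF", [GenomicInterval("chr1", i * 10, i * 10 + 5, 7.0) for i in range(5)])
    assert activity_score(const) == pytest.approx(np.log2(8.0))
    signals = rng.random(50) * 30
    random_set = PeakSet(
        "s", "f", "TF", [GenomicInterval("chr1", i * 10, i * 10 + 5, float(s)) for i, s in enumerate(signals)]
    )
    assert activity_score(random_set) == pytest.approx(np.mean(np.log2(1 + signals)), abs=1e-12)
    assert np.isnan(activity_score(PeakSet("s", "f", "TF", [])))


def _ps(sample, factor, scores):
    return [
        PeakSet(sample, factor, "TF", [GenomicInterval("chr1", 0, 10, float(2**s - 1))])
        for s in np.atleast_1d(scores)
    ][0]


def test_two_point_zscore_closed_form():
    mat = build_activity_matrix([_ps("a", "f", 1.0), _ps("b", "f", 3.0)])
    assert sorted(mat.values["f"]) == pytest.approx([-np.sqrt(0.5), np.sqrt(0.5)])


def test_constant_column_becomes_zero():
    mat = build_activity_matrix([_ps("a", "f", 2.0), _ps("b", "f", 2.0), _ps("c", "f", 2.0)])
    assert (mat.values["f"] == 0).all()


def test_single_observation_column_flagged():
    mat = build_activity_matrix([_ps("a", "f", 2.0), _ps("a", "g", 1.0), _ps("b", "g", 3.0)])
    assert "f" in mat.unnormalized
    assert mat.values.loc["a", "f"] == pytest.approx(2.0)  # left raw


def test_zscore_columns_standardized(rng):
    sets = [_ps(f"cl{i}", "f", float(rng.random() * 4)) for i in range(10)]
    col = build_activity_matrix(sets).values["f"]
    assert col.mean() == pytest.approx(0.0, abs=1e-9)
    assert col.std(ddof=1) == pytest.approx(1.0, abs=1e-9)


def test_round_trip_matches_cohort_activities(tmp_path):
    cfg = single_pair_config(n_cell_lines=8, n_background_peaks=6, n_loci_per_pair=4,
                             n_genes=20, n_target_genes=4)
    cohort = generate_cohort(cfg)
    manifest = generate_peak_files(cohort, tmp_path)
    sets = [read_peak_file(r.path, r.dialect, r.sample_id, r.factor_id, r.factor_class)
            for r in manifest.itertuples()]
    mat = build_activity_matrix(sets)
    expected = (cohort.tf_activity - cohort.tf_activity.mean()) / cohort.tf_activity.std(ddof=1)
    got = mat.by_class("TF").loc[expected.index, expected.columns]
    np.testing.assert_allclose(got.to_numpy(), expected.to_numpy(), atol=1e-9)


def test_emitted_files_have_dialect_column_counts(tmp_path):
    cfg = single_pair_config(n_cell_lines=3, n_background_peaks=4, n_loci_per_pair=2,
                             n_genes=10, n_target_genes=2)
    manifest = generate_peak_files(generate_cohort(cfg), tmp_path)
    from epidriver.peaks import DIALECT_COLUMNS

    for rec in manifest.itertuples():
        for line in open(rec.path):
            assert len(line.rstrip("\n").split("\t")) == DIALECT_COLUMNS[rec.dialect]


# ---------------------------------------------------------------------------
# intersection engine
# ---------------------------------------------------------------------------

def _random_set(rng, sample, factor, n, genome_len=50_000, max_w=120):
    ivs = []
    for _ in range(n):
        s = int(rng.integers(0, genome_len - max_w))
        ivs.append(GenomicInterval("chr1", s, s + int(rng.integers(1, max_w)), float(rng.random())))
    return PeakSet(sample, factor, "TF", ivs)


def _per_base_overlap(a: PeakSet, b: PeakSet, genome_len=50_000) -> int:
    cov_a = np.zeros(genome_len, dtype=bool)
    cov_b = np.zeros(genome_len, dtype=bool)
    for iv in a.intervals:
        cov_a[iv.start : iv.end] = True
    for iv in b.intervals:
        cov_b[iv.start : iv.end] = True
    return int(np.sum(cov_a & cov_b))


def test_disjoint_sets_no_loci():
    a = PeakSet("s", "t", "TF", [GenomicInterval("chr1", 0, 10, 1.0)])
    b = PeakSet("s", "h", "HM", [GenomicInterval("chr1", 10, 20, 1.0)])
    assert intersect_peaks(a, b) == []


def test_identical_interval_self_locus():
    iv = GenomicInterval("chr1", 5, 25, 2.0)
    a = PeakSet("s", "t", "TF", [iv])
    b = PeakSet("s", "h", "HM", [GenomicInterval("chr1", 5, 25, 4.0)])
    (locus,) = intersect_peaks(a, b)
    assert (locus.start, locus.end, locus.tf_signal, locus.hm_signal) == (5, 25, 2.0, 4.0)


def test_cell_line_mismatch_rejected():
    a = PeakSet("s1", "t", "TF", [])
    b = PeakSet("s2", "h", "HM", [])
    with pytest.raises(ValidationError):
        intersect_peaks(a, b)


def test_intersection_against_per_base_oracle(rng):
    for _ in range(10):
        a = _random_set(rng, "s", "t", 300)
        b = _random_set(rng, "s", "h", 300)
        loci = intersect_peaks(a, b)
        assert covered_bases(loci) == _per_base_overlap(a, b)
        # commutativity in coordinates
        rev = intersect_peaks(
            PeakSet("s", "h", "HM", b.intervals), PeakSet("s", "t", "TF", a.intervals)
        )
        assert covered_bases(rev) == covered_bases(loci)
        # covered overlap cannot exceed either side's footprint
        assert covered_bases(loci) <= min(covered_bases(a.intervals), covered_bases(b.intervals))


def test_planted_pairs_share_more_bases_than_unplanted(tmp_path):
    cfg = GeneratorConfig(
        n_cell_lines=4, n_tfs=2, n_hms=2, planted_pairs=((0, 0, 1.5),),
        n_background_peaks=10, n_loci_per_pair=10, n_genes=40, n_target_genes=10,
        n_drugs=2, n_patients=10, seed=3,
    )
    cohort = generate_cohort(cfg)
    manifest = generate_peak_files(cohort, tmp_path)
    sets = {
        (r.sample_id, r.factor_id): read_peak_file(r.path, r.dialect, r.sample_id, r.factor_id)
        for r in manifest.itertuples()
    }
    planted = covered_bases(intersect_peaks(sets[("CL000", "TF00")], sets[("CL000", "H3K4me3")]))
    unplanted = covered_bases(intersect_peaks(sets[("CL000", "TF01")], sets[("CL000", "H3K4me1")]))
    assert planted > unplanted


# ---------------------------------------------------------------------------
# target-gene assignment
# ---------------------------------------------------------------------------

def _loci(coords):
    from epidriver.peaks import CoboundLocus

    return [CoboundLocus("chr1", s, e, 1.0, 1.0, "cl") for s, e in coords]


def test_locus_on_tss_always_assigned():
    anno = pd.DataFrame({"gene_id": ["g1"], "chrom": ["chr1"], "tss": [500], "strand": ["+"]})
    assert assign_target_genes(_loci([(490, 510)]), anno, "H3K4me3", 1, 1) == {"g1"}
    assert assign_target_genes([], anno, "H3K4me3") == set()


def test_promoter_vs_enhancer_window():
    anno = pd.DataFrame({"gene_id": ["g1"], "chrom": ["chr1"], "tss": [5000], "strand": ["+"]})
    loci = _loci([(6500, 6600)])
    # promoter mark uses the (smaller) promoter window
    assert assign_target_genes(loci, anno, "H3K4me3", promoter_window=1000, enhancer_window=2000) == set()
    assert assign_target_genes(loci, anno, "H3K4me1", promoter_window=1000, enhancer_window=2000) == {"g1"}


def test_assignment_against_quadratic_oracle(rng):
    n_genes, n_loci = 60, 80
    anno = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n_genes)],
            "chrom": rng.choice(["chr1", "chr2"], n_genes),
            "tss": rng.integers(0, 30_000, n_genes),
            "strand": rng.choice(["+", "-"], n_genes),
        }
    )
    from epidriver.peaks import CoboundLocus

    loci = [
        CoboundLocus(str(c), int(s), int(s) + int(rng.integers(1, 400)), 1.0, 1.0, "cl")
        for c, s in zip(rng.choice(["chr1", "chr2"], n_loci), rng.integers(0, 30_000, n_loci))
    ]
    window = 700
    expected = {
        g.gene_id
        for g in anno.itertuples()
        for lc in loci
        if lc.chrom == g.chrom and lc.start < g.tss + window and lc.end > g.tss - window
    }
    got = assign_target_genes(loci, anno, "H3K4me1", promoter_window=1, enhancer_window=window)
    assert got == expected
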