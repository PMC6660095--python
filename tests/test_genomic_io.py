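"""Window grids, covariate tracks, and VCF round-tripping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mimland.genomic_io import (
    GenotypeMatrix,
    load_genotypes,
    make_windows,
    read_taxon_map,
    window_gene_count,
    window_recombination,
    write_vcf,
)


class TestMakeWindows:
    @pytest.mark.parametrize(
        "length,size,step,expected",
        [
            (1_000_000, 500_000, 500_000, 2),
            (1_000_000, 500_000, 50_000, 11),
            (120_000, 500_000, 500_000, 1),
        ],
    )
    def test_window_counts(self, length, size, step, expected):
        ws = make_windows({"c": length}, size, step)
        assert len(ws) == expected

    def test_sliding_starts_are_step_multiples(self):
        ws = make_windows({"c": 1_000_000}, 500_000, 50_000)
        assert [w.start for w in ws] == list(range(0, 500_001, 50_000))
        assert all(w.start % w.step == 0 for w in ws)

    def test_short_contig_truncated(self):
        (w,) = make_windows({"c": 120_000}, 500_000, 500_000)
        assert (w.start, w.end) == (0, 120_000)

    def test_nonoverlapping_tiles_contig(self):
        ws = make_windows({"c": 1_234_567}, 500_000, 500_000)
        assert ws[0].start == 0 and ws[-1].end == 1_234_567
        for a, b in zip(ws, ws[1:]):
            assert a.end == b.start

    def test_report_coords_one_based(self):
        (w,) = make_windows({"c": 100}, 500, 500)
        assert w.report_coords() == ("c", 1, 100)

    @given(
        length=st.integers(1, 3_000_000),
        size=st.sampled_from([100_000, 500_000]),
        step_frac=st.sampled_from([1, 5, 10]),
    )
    @settings(max_examples=50, deadline=None)
    def test_windows_within_contig_and_ordered(self, length, size, step_frac):
        ws = make_windows({"c": length}, size, size // step_frac)
        assert all(0 <= w.start < w.end <= length for w in ws)
        assert all(a.start < b.start for a, b in zip(ws, ws[1:]))

    def test_bad_arguments(self):
        with pytest.raises(ValueError):
            make_windows({"c": 100}, 0, 1)
        with pytest.raises(ValueError):
            make_windows({"c": 100}, 10, 20)


class TestRecombinationTrack:
    def test_single_interval_rate(self):
        gmap = pd.DataFrame(
            {"marker": ["a", "b"], "chrom": ["c", "c"], "bp": [1, 1_000_001], "cM": [0.0, 1.5]}
        )
        ws = make_windows({"c": 1_000_000}, 1_000_000, 1_000_000)
        out = window_recombination(gmap, ws, min_intervals=1)
        assert out["recomb_rate"].iloc[0] == pytest.approx(1.5)

    def test_min_three_intervals_required(self):
        # two intervals overlapping the window -> missing
        gmap = pd.DataFrame(
            {
                "marker": list("abc"),
                "chrom": ["c"] * 3,
                "bp": [1, 500_001, 1_000_001],
                "cM": [0.0, 0.5, 1.0],
            }
        )
        ws = make_windows({"c": 1_000_000}, 1_000_000, 1_000_000)
        out = window_recombination(gmap, ws)
        assert np.isnan(out["recomb_rate"].iloc[0])

    def test_top_five_percent_removed(self):
        # 100 equal-width intervals: 95 at 1 cM/Mbp, 5 at 100 cM/Mbp;
        # the inflated 5 are exactly the genome-wide top 5% and must go
        rates = np.ones(100)
        rates[10:15] = 100.0
        bp = np.arange(101) * 10_000 + 1
        cm = np.concatenate([[0.0], np.cumsum(rates * 0.01)])  # 10 kb = 0.01 Mbp
        gmap = pd.DataFrame(
            {"marker": [f"m{i}" for i in range(101)], "chrom": "c", "bp": bp, "cM": cm}
        )
        ws = make_windows({"c": 1_000_000}, 1_000_000, 1_000_000)
        out = window_recombination(gmap, ws)
        assert out["recomb_rate"].iloc[0] == pytest.approx(1.0, rel=1e-9)

    def test_zero_physical_distance_skipped_with_warning(self):
        gmap = pd.DataFrame(
            {"marker": list("abc"), "chrom": "c", "bp": [1, 1, 1_000_001], "cM": [0.0, 0.1, 1.0]}
        )
        ws = make_windows({"c": 1_000_000}, 1_000_000, 1_000_000)
        with pytest.warns(UserWarning, match="zero physical distance"):
            window_recombination(gmap, ws, min_intervals=1)


class TestGeneCount:
    def test_gene_spanning_two_windows_counted_in_both(self):
        ws = make_windows({"c": 1_000_000}, 500_000, 500_000)
        feats = pd.DataFrame({"chrom": ["c"], "start": [490_000], "end": [510_000]})
        out = window_gene_count(feats, ws, dialect="bed")
        assert out["gene_count"].tolist() == [1, 1]

    def test_empty_features(self):
        ws = make_windows({"c": 1_000_000}, 500_000, 500_000)
        out = window_gene_count(pd.DataFrame(columns=["chrom", "start", "end"]), ws)
        assert out["gene_count"].tolist() == [0, 0]

    def test_ten_genes_in_one_window(self):
        ws = make_windows({"c": 1_000_000}, 500_000, 500_000)
        feats = pd.DataFrame(
            {"chrom": "c", "start": np.arange(10) * 1000, "end": np.arange(10) * 1000 + 500}
        )
        out = window_gene_count(feats, ws)
        assert out["gene_count"].tolist() == [10, 0]

    def test_gff3_coordinates_inclusive(self):
        ws = make_windows({"c": 1000}, 500, 500)
        # GFF3 gene 500..500 is the last bp of window 1 (0-based 499)
        feats = pd.DataFrame({"chrom": ["c"], "start": [500], "end": [500]})
        out = window_gene_count(feats, ws, dialect="gff3")
        assert out["gene_count"].tolist() == [1, 0]

    def test_unknown_contig_warns(self):
        ws = make_windows({"c": 1000}, 500, 500)
        feats = pd.DataFrame({"chrom": ["zz"], "start": [0], "end": [10]})
        with pytest.warns(UserWarning, match="unknown contigs"):
            out = window_gene_count(feats, ws)
        assert out["gene_count"].sum() == 0


class TestVcfRoundTrip:
    def _write(self, tmp_path, lines, samples=("s1", "s2")):
        path = tmp_path / "t.vcf"
        header = (
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=c,length=1000>\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n"
        )
        path.write_text(header + "".join(line + "\n" for line in lines))
        return path

    def test_triallelic_dropped(self, tmp_path):
        path = self._write(
            tmp_path,
            [
                "c\t1\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t0/0",
                "c\t2\t.\tA\tT,G\t.\tPASS\t.\tGT\t0/1\t0/2",
                "c\t3\t.\tA\tT\t.\tPASS\t.\tGT\t1/1\t0/0",
            ],
        )
        m = load_genotypes(path, {"s1": "x", "s2": "y"})
        assert m.n_sites == 2
        assert m.positions.tolist() == [0, 2]

    def test_missing_and_half_calls(self, tmp_path):
        path = self._write(
            tmp_path,
            ["c\t1\t.\tA\tT\t.\tPASS\t.\tGT\t./.\t./1"],
        )
        m = load_genotypes(path, {"s1": "x", "s2": "y"})
        assert (m.calls[0] == -1).all()  # half-called treated as missing

    def test_invariant_site_retained(self, tmp_path):
        path = self._write(tmp_path, ["c\t5\t.\tG\t.\t.\tPASS\t.\tGT\t0/0\t0/0"])
        m = load_genotypes(path, {"s1": "x", "s2": "y"})
        assert m.n_sites == 1 and not m.is_variant[0]

    def test_sample_missing_from_map_errors(self, tmp_path):
        path = self._write(tmp_path, ["c\t1\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t0/0"])
        with pytest.raises(ValueError, match="absent from taxon map"):
            load_genotypes(path, {"s1": "x"})

    def test_synthetic_round_trip_identity(self, tmp_path):
        from mimland.synthetic_radiation import SyntheticConfig, generate_radiation

        cfg = SyntheticConfig(n_windows=10, n_chrom=2, window_bp=500, seed=5)
        data = generate_radiation(cfg)
        out = tmp_path / "rt.vcf"
        write_vcf(data.matrix, out)
        back = load_genotypes(out, data.matrix.taxon_map)
        assert back.n_sites == data.matrix.n_sites
        np.testing.assert_array_equal(back.calls, data.matrix.calls)
        np.testing.assert_array_equal(back.positions, data.matrix.positions)
        assert back.individuals == data.matrix.individuals


class TestGenotypeMatrix:
    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            GenotypeMatrix(
                chroms=np.array(["c", "c"], dtype=object),
                positions=np.array([5, 5]),
                ref=np.array(["A", "A"], dtype=object),
                alt=np.array(["T", "T"], dtype=object),
                calls=np.zeros((2, 1, 2), dtype=np.int8),
                individuals=["s"],
                taxon_map={"s": "x"},
            )

    def test_taxon_map_must_cover_individuals(self):
        with pytest.raises(ValueError, match="absent from taxon map"):
            GenotypeMatrix(
                chroms=np.array(["c"], dtype=object),
                positions=np.array([1]),
                ref=np.array(["A"], dtype=object),
                alt=np.array(["T"], dtype=object),
                calls=np.zeros((1, 2, 2), dtype=np.int8),
                individuals=["s", "u"],
                taxon_map={"s": "x"},
            )


def test_read_taxon_map_rejects_duplicates(tmp_path):
    p = tmp_path / "map.tsv"
    p.write_text("s1\tx\ns1\ty\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_taxon_map(p)
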