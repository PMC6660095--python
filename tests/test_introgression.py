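"""ABBA-BABA statistics: polarization, D, jackknife, f, and f_d."""

import numpy as np
import pandas as pd
import pytest

from mimland.genomic_io import WindowSpec
from mimland.introgression import (
    admixture_fraction_f,
    block_jackknife,
    fd_summary,
    fd_windows,
    patterson_d,
    polarize_sites,
    site_patterns,
)


def _freqs_obj(p1, p2, p3, positions=None, chroms=None, p3_dosage=None):
    from mimland.introgression import PolarizedFreqs

    p1, p2, p3 = (np.asarray(x, float) for x in (p1, p2, p3))
    n = len(p1)
    return PolarizedFreqs(
        labels=("P1", "P2", "P3", "O"),
        chroms=np.asarray(chroms) if chroms is not None else np.zeros(n, int),
        positions=np.asarray(positions) if positions is not None else np.arange(n),
        p1=p1,
        p2=p2,
        p3=p3,
        p3_dosage=p3_dosage if p3_dosage is not None else np.column_stack([p3] * 4),
    )


class TestPolarize:
    def test_outgroup_fixed_ref_retained(self, make_matrix):
        calls = np.zeros((1, 6, 2), dtype=np.int8)
        calls[0, 0] = [0, 1]  # P1 mixed
        calls[0, 2] = [1, 1]  # P2
        m = make_matrix(calls, ["p1", "p1", "p2", "p2", "og", "og"])
        fr = polarize_sites(m, ("p1", "p2", "p1", "og"), min_genotyped=2)
        assert fr.n_sites == 1
        assert fr.p1[0] == pytest.approx(0.25)

    def test_outgroup_polymorphic_dropped(self, make_matrix):
        calls = np.zeros((1, 6, 2), dtype=np.int8)
        calls[0, 4] = [0, 1]  # outgroup heterozygous
        calls[0, 0] = [1, 1]
        m = make_matrix(calls, ["p1", "p1", "p2", "p2", "og", "og"])
        fr = polarize_sites(m, ("p1", "p2", "p1", "og"), min_genotyped=2)
        assert fr.n_sites == 0

    def test_outgroup_fixed_alt_flips_derived(self, make_matrix):
        calls = np.zeros((1, 6, 2), dtype=np.int8)
        calls[0, 4] = [1, 1]
        calls[0, 5] = [1, 1]  # outgroup fixed for ALT -> REF is derived
        calls[0, 0] = [0, 0]  # P1 hom REF = derived freq 1
        calls[0, 1] = [1, 1]
        m = make_matrix(calls, ["p1", "p1", "p2", "p2", "og", "og"])
        fr = polarize_sites(m, ("p1", "p2", "p1", "og"), min_genotyped=2)
        assert fr.p1[0] == pytest.approx(0.5)

    def test_filter_count(self, make_matrix):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 2, (100, 9, 2)).astype(np.int8)
        calls[:80, 7:] = 0  # outgroup fixed at the first 80 sites
        calls[80:, 7] = [0, 1]  # polymorphic outgroup after that
        taxa = ["p1"] * 3 + ["p2"] * 2 + ["p3"] * 2 + ["og"] * 2
        m = make_matrix(calls, taxa)
        fr = polarize_sites(m, ("p1", "p2", "p3", "og"), min_genotyped=2)
        assert fr.n_sites == 80

    def test_unknown_taxon_errors(self, make_matrix):
        m = make_matrix(np.zeros((1, 2, 2), dtype=np.int8), ["a", "b"])
        with pytest.raises(KeyError):
            polarize_sites(m, ("a", "b", "zz", "a"), 1)


class TestPattersonD:
    def test_formula_examples(self):
        # 75% ABBA weight vs 25% BABA weight -> D = 0.5
        p1 = np.array([0.0] * 75 + [1.0] * 25)
        p2 = 1.0 - p1
        p3 = np.ones(100)
        d, abba, baba = patterson_d((p1, p2, p3))
        assert d == pytest.approx(0.5)
        assert abba.sum() == 75 and baba.sum() == 25

    def test_p1_equals_p2_gives_zero(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        d, _, _ = patterson_d((p, p, rng.random(50)))
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_single_pure_abba_site(self):
        d, _, _ = patterson_d((np.array([0.0]), np.array([1.0]), np.array([1.0])))
        assert d == 1.0

    def test_no_informative_sites_missing(self):
        d, _, _ = patterson_d((np.zeros(5), np.zeros(5), np.zeros(5)))
        assert np.isnan(d)

    def test_sign_flip_exact_under_p1_p2_exchange(self):
        rng = np.random.default_rng(1)
        p1, p2, p3 = rng.random((3, 200))
        d12, _, _ = patterson_d((p1, p2, p3))
        d21, _, _ = patterson_d((p2, p1, p3))
        assert d12 == -d21


class TestBlockJackknife:
    def _data(self, rng, g=20, per=50):
        abba = rng.random(g * per)
        baba = rng.random(g * per)
        pos = np.arange(g * per) * 10_000  # 500-kb blocks of 50 sites
        return abba, baba, pos

    def test_identical_blocks_flagged(self):
        abba = np.tile([1.0, 0.5], 500)
        baba = np.tile([0.5, 1.0], 500)
        pos = np.arange(1000) * 10_000
        se, z, p = block_jackknife(abba, baba, pos)
        assert se == 0.0 and np.isnan(p)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        abba, baba, pos = self._data(rng)
        r1 = block_jackknife(abba, baba, pos)
        r2 = block_jackknife(2 * abba, 2 * baba, pos)
        assert r1[1] == pytest.approx(r2[1], rel=1e-12)

    def test_too_few_blocks_errors(self):
        with pytest.raises(ValueError, match="blocks"):
            block_jackknife(np.ones(10), np.zeros(10), np.arange(10))

    def test_chromosomes_separate_blocks(self):
        rng = np.random.default_rng(3)
        abba, baba, pos = self._data(rng, g=12, per=40)
        chroms = np.repeat(np.arange(12), 40)
        # same positions on different chroms -> still 12 blocks
        se, z, p = block_jackknife(abba, baba, np.tile(pos[:40], 12), chroms)
        assert np.isfinite(z)

    def test_weighted_variant_runs(self):
        rng = np.random.default_rng(4)
        abba, baba, pos = self._data(rng)
        se_u, _, _ = block_jackknife(abba, baba, pos, weights="none")
        se_w, _, _ = block_jackknife(abba, baba, pos, weights="site_sum")
        assert se_u > 0 and se_w > 0

    def test_null_calibration_light(self):
        """~5% |Z|>1.96 under a no-migration coalescent null (small batch;
        the full 1,000-replicate calibration runs in the acceptance suite)."""
        from mimland.synthetic_radiation import simulate_quartet_loci

        rej = 0
        n = 60
        for i in range(n):
            p1, p2, p3, pos = simulate_quartet_loci(
                seed=7_000 + i, n_loci=25, locus_bp=5e4, mu=2e-8
            )
            d, abba, baba = patterson_d((p1, p2, p3))
            _, z, _ = block_jackknife(abba, baba, pos, block_bp=500_000)
            rej += abs(z) >= 1.96
        assert rej / n <= 0.18


class TestAdmixtureFraction:
    def test_complete_admixture_limit(self):
        # P2 is an independent sample of the same population as P3
        rng = np.random.default_rng(0)
        site_freq = rng.random(3000)
        dos3 = (rng.random((3000, 4)) < site_freq[:, None]).astype(float)
        dos2 = (rng.random((3000, 4)) < site_freq[:, None]).astype(float)
        fr = _freqs_obj(np.zeros(3000), dos2.mean(axis=1), dos3.mean(axis=1), p3_dosage=dos3)
        f = admixture_fraction_f(fr, seed=1)
        assert f == pytest.approx(1.0, abs=0.1)

    def test_no_admixture_gives_zero(self):
        rng = np.random.default_rng(1)
        dos = rng.integers(0, 3, (500, 4)) / 2.0
        p1 = rng.random(500)
        fr = _freqs_obj(p1, p1, dos.mean(axis=1), p3_dosage=dos)
        assert admixture_fraction_f(fr, seed=2) == pytest.approx(0.0, abs=1e-12)

    def test_single_p3_individual_errors(self):
        fr = _freqs_obj([0.0], [1.0], [1.0], p3_dosage=np.ones((1, 1)))
        with pytest.raises(ValueError, match="P3"):
            admixture_fraction_f(fr)


class TestFdWindows:
    def _windows(self, n, size=100):
        return [WindowSpec("0", i * size, (i + 1) * size, size, size) for i in range(n)]

    def test_donor_equals_recipient_gives_one(self):
        rng = np.random.default_rng(0)
        p3 = rng.random(100)
        p1 = np.zeros(100)
        fr = _freqs_obj(p1, p3, p3, chroms=np.array(["0"] * 100))
        track, swapped = fd_windows(fr, self._windows(1), genome_d=0.5)
        assert track["fd"].iloc[0] == pytest.approx(1.0)
        assert not swapped

    def test_p2_equals_p1_gives_zero(self):
        rng = np.random.default_rng(1)
        p1 = rng.random(100)
        fr = _freqs_obj(p1, p1, rng.random(100), chroms=np.array(["0"] * 100))
        track, _ = fd_windows(fr, self._windows(1), genome_d=0.1)
        assert track["fd"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_negative_d_swaps_p1_p2(self):
        rng = np.random.default_rng(2)
        p2 = rng.random(100)
        fr = _freqs_obj(p2 * 0.9, p2 * 0.1, p2, chroms=np.array(["0"] * 100))
        _, swapped = fd_windows(fr, self._windows(1), genome_d=-0.2)
        assert swapped

    def test_empty_window_missing(self):
        fr = _freqs_obj([0.0], [1.0], [1.0], positions=[5], chroms=np.array(["0"]))
        track, _ = fd_windows(fr, self._windows(2), genome_d=0.1)
        assert np.isnan(track["fd"].iloc[1])

    def test_negative_numerator_missing(self):
        # BABA-dominated window under positive genome D
        fr = _freqs_obj([1.0] * 10, [0.0] * 10, [1.0] * 10, chroms=np.array(["0"] * 10))
        track, _ = fd_windows(fr, self._windows(1), genome_d=0.3)
        assert np.isnan(track["fd"].iloc[0])


class TestFdSummary:
    def _track(self, fds):
        n = len(fds)
        return pd.DataFrame(
            {"chrom": "0", "start": np.arange(n) * 100, "end": np.arange(n) * 100 + 100,
             "fd": fds, "n_sites": 10}
        )

    def test_single_track_mean_equals_max(self):
        t = self._track([0.1, 0.5, np.nan])
        out = fd_summary([t])
        np.testing.assert_allclose(out["mean_fd"], out["max_fd"], equal_nan=True)

    def test_missing_skip_rule(self):
        out = fd_summary([self._track([0.1, np.nan]), self._track([np.nan, np.nan])])
        assert out["mean_fd"].iloc[0] == pytest.approx(0.1)
        assert out["n_tests"].tolist() == [1, 0]
        assert np.isnan(out["mean_fd"].iloc[1])

    def test_five_tracks_match_direct_reduction(self):
        rng = np.random.default_rng(0)
        vals = rng.random((5, 20))
        vals[rng.random((5, 20)) < 0.3] = np.nan
        tracks = [self._track(v) for v in vals]
        out = fd_summary(tracks)
        with np.errstate(invalid="ignore"):
            expected_mean = np.nanmean(vals, axis=0)
            expected_max = np.nanmax(vals, axis=0)
        np.testing.assert_allclose(out["mean_fd"], expected_mean, equal_nan=True)
        np.testing.assert_allclose(out["max_fd"], expected_max, equal_nan=True)

    def test_grid_mismatch_errors(self):
        t1 = self._track([0.1])
        t2 = self._track([0.1, 0.2])
        with pytest.raises(ValueError, match="grid"):
            fd_summary([t1, t2])


def test_site_patterns_formula():
    p1, p2, p3 = np.array([0.2]), np.array([0.8]), np.array([0.5])
    abba, baba = site_patterns(p1, p2, p3)
    assert abba[0] == pytest.approx(0.8 * 0.8 * 0.5)
    assert baba[0] == pytest.approx(0.2 * 0.2 * 0.5)
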