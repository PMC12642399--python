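"""Size-distribution processing: ingest, rebin, merge, KL, flatness."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import entropy as scipy_entropy

from phaselink import (
    DomainError,
    ParseError,
    ProbabilityMass,
    ReplicateSet,
    SizeDistribution,
    ValidationError,
    flatness_metric,
    kl_divergence,
    kl_profile,
    merge_cartridges,
    read_distribution_table,
    rebin_to_common_grid,
    to_probability,
)
from phaselink.sizedist import edges_from_centers, write_distribution_table


def constant_replicates(window, n_bins, value, n_rep, cartridge):
    edges = np.geomspace(window[0], window[1], n_bins + 1)
    reps = tuple(
        SizeDistribution(edges, np.full(n_bins, value), cartridge) for _ in range(n_rep)
    )
    return ReplicateSet(reps)


class TestIngest:
    def test_round_trip_three_column_table(self, tmp_path):
        text = "diameter_nm,rep1,rep2\n" + "\n".join(
            f"{d},{d * 2},{d * 3}" for d in range(100, 200)
        )
        path = tmp_path / "table.csv"
        path.write_text(text)
        rs = read_distribution_table(path, cartridge="C400")
        assert len(rs) == 2
        assert rs.replicates[0].density.size == 100
        # centers recovered from reconstructed edges
        assert np.allclose(rs.replicates[0].bin_centers, np.arange(100, 200))
        out = tmp_path / "out.csv"
        write_distribution_table(rs, out)
        rs2 = read_distribution_table(out)
        assert np.allclose(rs2.density_matrix, rs.density_matrix)

    def test_tab_delimited_autodetect(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("diameter_nm\trep1\n100\t1.0\n110\t2.0\n120\t3.0\n")
        assert read_distribution_table(path).replicates[0].density.size == 3

    def test_negative_density_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("diameter_nm,rep1\n100,1.0\n110,-2.0\n")
        with pytest.raises(ParseError, match="line 3"):
            read_distribution_table(path)

    def test_non_monotone_diameters_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("diameter_nm,rep1\n100,1\n90,1\n120,1\n")
        with pytest.raises(ParseError, match="increasing"):
            read_distribution_table(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(ParseError, match="empty"):
            read_distribution_table(path)

    def test_edges_from_centers_midpoints(self):
        edges = edges_from_centers(np.array([10.0, 20.0, 40.0]))
        assert np.allclose(edges, [5.0, 15.0, 30.0, 50.0])


class TestRebin:
    def test_identity_grid(self):
        d = SizeDistribution(np.array([0.0, 1, 2, 3]), np.array([4.0, 6, 2]))
        r = rebin_to_common_grid(d, d.bin_edges)
        assert np.allclose(r.density, d.density)

    def test_merge_two_equal_bins(self):
        d = SizeDistribution(np.array([0.0, 1, 2]), np.array([4.0, 6.0]))
        r = rebin_to_common_grid(d, np.array([0.0, 2.0]))
        assert np.allclose(r.density, [5.0])

    def test_split_bin_keeps_density(self):
        d = SizeDistribution(np.array([0.0, 2.0]), np.array([3.0]))
        r = rebin_to_common_grid(d, np.array([0.0, 1.0, 2.0]))
        assert np.allclose(r.density, [3.0, 3.0])

    def test_disjoint_support_rejected(self):
        d = SizeDistribution(np.array([0.0, 1.0]), np.array([1.0]))
        with pytest.raises(DomainError):
            rebin_to_common_grid(d, np.array([5.0, 6.0]))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_count_conservation_on_random_grids(self, seed):
        rng = np.random.default_rng(seed)
        src = np.sort(rng.uniform(0, 100, size=rng.integers(3, 20)))
        src = src[np.diff(np.concatenate([[-1], src])) > 1e-6]
        if src.size < 3:
            return
        dens = rng.uniform(0, 10, size=src.size - 1)
        d = SizeDistribution(src, dens)
        # target covering the full source support conserves every particle
        tgt = np.sort(np.concatenate([[src[0] - 1, src[-1] + 1], rng.uniform(src[0], src[-1], 5)]))
        tgt = tgt[np.diff(np.concatenate([[-10], tgt])) > 1e-6]
        r = rebin_to_common_grid(d, tgt)
        assert r.total_count() == pytest.approx(d.total_count(), rel=1e-9)


class TestMerge:
    def test_degenerate_constant_replicates(self):
        small = constant_replicates((70, 400), 32, 5.0, 3, "C400")
        large = constant_replicates((250, 2000), 32, 11.0, 3, "C2000")  # different calibration
        merged = merge_cartridges(small, large, n_boot=50, seed=1)
        # cross-scaling maps the C-2000 plateau onto the C-400 level
        assert np.allclose(merged.mean, 5.0)
        assert np.allclose(merged.spread, 0.0)
        assert merged.bin_edges[0] == pytest.approx(70.0)
        assert merged.bin_edges[-1] == pytest.approx(2000.0)

    def test_determinism(self):
        rng = np.random.default_rng(5)
        edges_s = np.geomspace(70, 400, 33)
        edges_l = np.geomspace(250, 2000, 33)
        small = ReplicateSet(
            tuple(SizeDistribution(edges_s, rng.uniform(1, 5, 32), "C400") for _ in range(3))
        )
        large = ReplicateSet(
            tuple(SizeDistribution(edges_l, rng.uniform(1, 5, 32), "C2000") for _ in range(3))
        )
        a = merge_cartridges(small, large, n_boot=20, seed=42)
        b = merge_cartridges(small, large, n_boot=20, seed=42)
        assert np.array_equal(a.mean, b.mean) and np.array_equal(a.spread, b.spread)
        c = merge_cartridges(small, large, n_boot=20, seed=43)
        assert not np.array_equal(a.mean, c.mean)

    def test_lognormal_recovery_within_three_standard_errors(self):
        # replicates are Poisson observations of a known lognormal density
        rng = np.random.default_rng(11)
        vol = 5e-3
        gen = lambda d: 3e5 * np.exp(-0.5 * ((np.log(d) - np.log(300)) / 0.6) ** 2)

        def replicate_set(window, cartridge):
            edges = np.geomspace(window[0], window[1], 33)
            centers = 0.5 * (edges[:-1] + edges[1:])
            widths = np.diff(edges)
            expected_counts = gen(centers) * widths * vol
            reps = tuple(
                SizeDistribution(edges, rng.poisson(expected_counts) / (vol * widths), cartridge)
                for _ in range(3)
            )
            return ReplicateSet(reps), centers, expected_counts, widths

        small, cs, ecs, ws = replicate_set((70, 400), "C400")
        large, cl, ecl, wl = replicate_set((250, 2000), "C2000")
        merged = merge_cartridges(small, large, n_boot=1000, seed=3)

        mc = 0.5 * (merged.bin_edges[:-1] + merged.bin_edges[1:])
        for centers, expected_counts, widths in ((cs, ecs, ws), (cl, ecl, wl)):
            # cartridge-exclusive ranges: below 250 nm and above 400 nm
            mask = (centers < 250) | (centers > 400)
            dens_expected = expected_counts / (vol * widths)
            se = np.sqrt(expected_counts) / (vol * widths) / np.sqrt(3)
            got = np.interp(centers[mask], mc, merged.mean)
            assert np.all(np.abs(got - dens_expected[mask]) <= 3 * se[mask])

    def test_spread_shrinks_with_replicate_agreement(self):
        small = constant_replicates((70, 400), 16, 2.0, 3, "C400")
        large = constant_replicates((250, 2000), 16, 2.0, 3, "C2000")
        assert merge_cartridges(small, large, n_boot=200, seed=0).spread.max() == 0.0

    def test_missing_overlap_rejected(self):
        small = constant_replicates((70, 200), 8, 1.0, 3, "C400")
        large = constant_replicates((250, 2000), 8, 1.0, 3, "C2000")
        with pytest.raises(DomainError):
            merge_cartridges(small, large, n_boot=10, seed=0)

    def test_bad_bootstrap_settings_rejected(self):
        small = constant_replicates((70, 400), 8, 1.0, 3, "C400")
        large = constant_replicates((250, 2000), 8, 1.0, 3, "C2000")
        with pytest.raises(ValidationError):
            merge_cartridges(small, large, n_boot=0, seed=0)
        with pytest.raises(ValidationError):
            merge_cartridges(small, large, n_boot=10, subsample_fraction=1.5, seed=0)


class TestProbability:
    def test_zero_floor_hand_normalization(self):
        d = SizeDistribution(np.array([0.0, 1, 2, 3]), np.array([0.0, 10, 30]))
        pm = to_probability(d, zero_floor=1e-5)
        assert np.allclose(pm.probabilities, [2.5e-7, 0.25, 0.75], atol=1e-6)

    def test_uniform_stays_uniform(self):
        d = SizeDistribution(np.linspace(0, 4, 5), np.full(4, 7.0))
        assert np.allclose(to_probability(d).probabilities, 0.25)

    def test_scale_invariance_for_positive_input(self):
        rng = np.random.default_rng(1)
        edges = np.geomspace(70, 400, 20)
        dens = rng.uniform(0.1, 5, 19)
        a = to_probability(SizeDistribution(edges, dens))
        b = to_probability(SizeDistribution(edges, 37.0 * dens))
        assert np.allclose(a.probabilities, b.probabilities)

    def test_all_zero_with_zero_floor_zero_rejected(self):
        d = SizeDistribution(np.array([0.0, 1.0]), np.array([0.0]))
        with pytest.raises(DomainError):
            to_probability(d, zero_floor=0.0)


class TestKL:
    def two_bin(self, p0):
        return ProbabilityMass(np.array([0.0, 1.0, 2.0]), np.array([p0, 1 - p0]))

    def test_identity_is_zero(self):
        p = self.two_bin(0.3)
        assert kl_divergence(p, p) == 0.0

    def test_worked_two_bin_values(self):
        # frozen by direct two-term summation: .5 ln 2 + .5 ln(2/3) etc.
        assert kl_divergence(self.two_bin(0.5), self.two_bin(0.25)) == pytest.approx(0.1438, abs=1e-4)
        assert kl_divergence(self.two_bin(0.25), self.two_bin(0.5)) == pytest.approx(0.1308, abs=1e-4)

    def test_mismatched_grids_rejected(self):
        p = self.two_bin(0.5)
        q = ProbabilityMass(np.array([0.0, 0.5, 2.0]), np.array([0.5, 0.5]))
        with pytest.raises(DomainError):
            kl_divergence(p, q)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_gibbs_inequality_and_scipy_agreement(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 40)
        edges = np.arange(n + 1, dtype=float)
        p = rng.dirichlet(np.ones(n))
        q = rng.dirichlet(np.ones(n))
        p = np.clip(p, 1e-12, None); p /= p.sum()
        q = np.clip(q, 1e-12, None); q /= q.sum()
        kl = kl_divergence(ProbabilityMass(edges, p), ProbabilityMass(edges, q))
        assert kl >= 0.0
        assert kl == pytest.approx(scipy_entropy(p, q), rel=1e-9, abs=1e-12)

    def test_profile_orientation_and_drift(self):
        edges = np.arange(11, dtype=float)
        base = np.exp(-0.3 * np.arange(10))
        ref = to_probability(SizeDistribution(edges, base))
        queries = [
            to_probability(SizeDistribution(edges, np.exp(-(0.3 + drift) * np.arange(10))))
            for drift in (0.0, 0.1, 0.2, 0.4)
        ]
        prof = kl_profile(ref, queries)
        assert prof[0] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(prof) > 0)


class TestFlatness:
    def edges(self):
        return np.geomspace(70, 2000, 65)

    def test_uniform_window_is_flat(self):
        e = self.edges()
        d = SizeDistribution(e, np.full(64, 3.0))
        res = flatness_metric(d)
        assert res.slope_per_nm == pytest.approx(0.0, abs=1e-12)
        assert res.is_flat

    def test_exponential_decay_slope(self):
        e = self.edges()
        centers = 0.5 * (e[:-1] + e[1:])
        d = SizeDistribution(e, np.exp(-centers / 100.0))
        res = flatness_metric(d)
        assert abs(res.slope_per_nm) == pytest.approx(0.01, rel=1e-6)
        assert not res.is_flat

    def test_too_few_bins_rejected(self):
        d = SizeDistribution(np.array([70.0, 400.0, 1500.0, 2000.0]), np.ones(3))
        with pytest.raises(DomainError):
            flatness_metric(d)
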