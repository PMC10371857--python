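import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from poolscan.differentiation import (FST_CAP, biallelic_reduce, branch_length,
                                      pbs_from_fst, pbs_scan, site_fst,
                                      window_fst)
from poolscan.io import SyncTable
from poolscan.simulate import simulate_frequency_landscape, simulate_pool_counts

from conftest import hudson_components_bruteforce, random_count_table


class TestBiallelicReduce:
    def test_fixed_difference(self):
        out = biallelic_reduce([(10, 0, 0, 0, 0, 0), (0, 10, 0, 0, 0, 0)])
        assert out is not None
        p, n = out
        assert sorted(p.tolist()) == [0.0, 1.0]
        assert n.tolist() == [10, 10]

    def test_triallelic_skipped(self):
        out = biallelic_reduce([(10, 8, 5, 0, 0, 0), (10, 8, 0, 0, 0, 0)])
        assert out is None

    def test_monomorphic_skipped(self):
        assert biallelic_reduce([(10, 0, 0, 0, 0, 0), (7, 0, 0, 0, 0, 0)]) is None

    def test_n_and_del_ignored(self):
        out = biallelic_reduce([(5, 5, 0, 0, 9, 9), (5, 5, 0, 0, 0, 0)])
        assert out is not None
        _, n = out
        assert n.tolist() == [10, 10]


class TestSiteFst:
    def test_identical_frequencies_slightly_negative(self):
        num, den = site_fst(0.5, 100, 0.5, 100)
        assert num == pytest.approx(-2 * 0.25 / 99)
        assert den == pytest.approx(0.5)
        assert num / den == pytest.approx(-0.010101, abs=1e-6)

    def test_fixed_difference_is_one(self):
        num, den = site_fst(1.0, 10, 0.0, 10)
        assert (num, den) == (1.0, 1.0)

    def test_hand_evaluated_example(self):
        num, den = site_fst(0.2, 100, 0.8, 100)
        assert num == pytest.approx(0.36 - 2 * 0.16 / 99)
        assert den == pytest.approx(0.68)
        assert num / den == pytest.approx(0.524659, abs=1e-6)

    def test_minimum_depth_enforced(self):
        with pytest.raises(ValueError):
            site_fst(0.5, 1, 0.5, 10)


class TestBranchLength:
    def test_zero(self):
        assert branch_length(0.0) == 0.0

    def test_half(self):
        assert branch_length(0.5) == pytest.approx(math.log(2), abs=1e-6)

    def test_cap(self):
        assert branch_length(FST_CAP) == pytest.approx(-math.log(1e-6), rel=1e-9)

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 0.9999999])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            branch_length(bad)

    def test_nan_propagates(self):
        assert math.isnan(float(branch_length(np.array([math.nan]))[0]))


class TestWindowFst:
    GENOME = [("chr1", 5000)]

    def test_matches_bruteforce_oracle(self):
        # ratio-of-averages window FST must equal an independent per-site
        # enumeration over 100-site instances to 1e-12 relative tolerance
        for seed in range(5):
            rng = np.random.default_rng(seed)
            table = random_count_table(rng, n_sites=100)
            track = window_fst(table, ("p0", "p1"), self.GENOME,
                               window=5000, step=5000, min_cov=4, max_cov=100)
            num = den = 0.0
            n_used = 0
            for s in range(table.n_sites):
                comp = hudson_components_bruteforce(table.counts[s], 0, 1,
                                                    min_cov=4, max_cov=100)
                if comp is None:
                    continue
                num += comp[0]
                den += comp[1]
                n_used += 1
            expected = min(max(num / den, 0.0), FST_CAP)
            assert track.n_snps[0] == n_used
            assert track.value[0] == pytest.approx(expected, rel=1e-12)

    def test_single_fixed_difference_clamped_to_cap(self):
        counts = np.zeros((1, 2, 6), dtype=np.int64)
        counts[0, 0, 0] = 10  # pool 1 all A
        counts[0, 1, 1] = 10  # pool 2 all T
        table = SyncTable(np.array(["chr1"], dtype=object), np.array([100]),
                          np.array(["A"], dtype=object), counts, pools=["p0", "p1"])
        track = window_fst(table, ("p0", "p1"), self.GENOME, window=5000, step=5000)
        assert track.value[0] == FST_CAP

    def test_negative_numerators_clamped_to_zero(self):
        # identical balanced pools: numerator negative, clamp to 0
        counts = np.zeros((3, 2, 6), dtype=np.int64)
        counts[:, :, 0] = 5
        counts[:, :, 1] = 5
        table = SyncTable(np.array(["chr1"] * 3, dtype=object),
                          np.array([10, 20, 30]),
                          np.array(["A"] * 3, dtype=object), counts,
                          pools=["p0", "p1"])
        track = window_fst(table, ("p0", "p1"), self.GENOME, window=5000, step=5000)
        assert track.value[0] == 0.0

    def test_min_sites_masks_thin_windows(self):
        rng = np.random.default_rng(0)
        table = random_count_table(rng, n_sites=3)
        track = window_fst(table, ("p0", "p1"), self.GENOME, window=5000,
                           step=5000, min_cov=4, max_cov=100, min_sites=10)
        assert math.isnan(track.value[0])


class TestPbs:
    def test_zero_fst_gives_zero_pbs(self):
        assert pbs_from_fst(0.0, 0.0, 0.0) == 0.0

    def test_equal_branches_give_half_t(self):
        t = branch_length(0.3)
        assert pbs_from_fst(0.3, 0.3, 0.3) == pytest.approx(t / 2)

    def test_asymmetric_example(self):
        assert pbs_from_fst(0.5, 0.5, 0.0) == pytest.approx(math.log(2), abs=1e-6)

    @settings(derandomize=True, max_examples=200)
    @given(st.tuples(*[st.floats(0, 0.99) for _ in range(3)]))
    def test_branch_sum_identity(self, fsts):
        # PBS_A + PBS_B + PBS_C = (T_AB + T_AC + T_BC) / 2 for any window
        f_ab, f_ac, f_bc = fsts
        pbs_a = pbs_from_fst(f_ab, f_ac, f_bc)
        pbs_b = pbs_from_fst(f_ab, f_bc, f_ac)
        pbs_c = pbs_from_fst(f_ac, f_bc, f_ab)
        total = (branch_length(f_ab) + branch_length(f_ac) + branch_length(f_bc)) / 2
        assert pbs_a + pbs_b + pbs_c == pytest.approx(total, rel=1e-9, abs=1e-12)

    def test_scan_identity_on_simulated_data(self, small_sim_config):
        cfg = small_sim_config
        panel = simulate_frequency_landscape(cfg)
        table = simulate_pool_counts(panel, cfg)
        kw = dict(window=5000, step=4000, min_cov=4, max_cov=40)
        t_focal = pbs_scan(table, ("focal", "east", "west"), cfg.genome, **kw)
        t_east = pbs_scan(table, ("east", "focal", "west"), cfg.genome, **kw)
        t_west = pbs_scan(table, ("west", "focal", "east"), cfg.genome, **kw)
        total = (t_focal.t_ab + t_focal.t_ac + t_focal.t_bc) / 2
        s = t_focal.pbs + t_east.pbs + t_west.pbs
        ok = np.isfinite(total)
        assert ok.any()
        np.testing.assert_allclose(s[ok], total[ok], rtol=1e-9, atol=1e-12)

    def test_unknown_population_rejected(self, small_sim_config):
        cfg = small_sim_config
        panel = simulate_frequency_landscape(cfg)
        table = simulate_pool_counts(panel, cfg)
        with pytest.raises(KeyError):
            pbs_scan(table, ("focal", "east", "nowhere"), cfg.genome)

    def test_missing_fst_propagates_to_pbs(self, small_sim_config):
        cfg = small_sim_config
        panel = simulate_frequency_landscape(cfg)
        table = simulate_pool_counts(panel, cfg)
        track = pbs_scan(table, ("focal", "east", "west"), cfg.genome,
                         min_sites=10_000)  # nothing passes
        assert np.isnan(track.pbs).all()

    def test_swept_windows_rank_above_background(self, small_sim_config):
        cfg = small_sim_config
        panel = simulate_frequency_landscape(cfg)
        table = simulate_pool_counts(panel, cfg)
        track = pbs_scan(table, ("focal", "east", "west"), cfg.genome,
                         window=5000, step=4000, min_cov=4, max_cov=40,
                         min_sites=5)
        sweep = cfg.sweeps[0]
        swept = (track.chroms == sweep.chrom) & (track.starts < sweep.end) \
            & (track.ends > sweep.start)
        assert np.nanmean(track.pbs[swept]) > np.nanmean(track.pbs[~swept])
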