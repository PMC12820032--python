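import numpy as np
import pytest

import methclock as mc
from methclock.regions import AgeCorrelations, build_regions, region_betas

from conftest import make_cohort


def brute_force_regions(chroms, r, tolerance, min_size=3, mode="both"):
    """Independent re-statement of the greedy membership rule.

    Walks the site list accumulating a run; a site extends the run only if
    it is on the run's chromosome, has defined r, and its correlation is
    within tolerance of the run's first member and of the previous member
    (per mode).  Runs shorter than min_size are discarded.
    """
    out = []
    run = []
    for i in range(len(r)):
        joins = False
        if run and not np.isnan(r[i]) and chroms[i] == chroms[run[0]]:
            ok_anchor = abs(r[i] - r[run[0]]) < tolerance
            ok_prev = abs(r[i] - r[run[-1]]) < tolerance
            joins = {
                "both": ok_anchor and ok_prev,
                "anchor_only": ok_anchor,
                "consecutive_only": ok_prev,
            }[mode]
        if joins:
            run.append(i)
        else:
            if len(run) >= min_size:
                out.append(tuple(run))
            run = [i] if not np.isnan(r[i]) else []
    if len(run) >= min_size:
        out.append(tuple(run))
    return out


def uniform_universe(n, chroms=("chr1",)):
    per = n // len(chroms)
    pairs = []
    for k, c in enumerate(chroms):
        cnt = per + (1 if k < n % len(chroms) else 0)
        pairs.extend((c, 100 + 50 * i) for i in range(cnt))
    return mc.SiteUniverse.from_pairs(pairs)


class TestAgeCorrelation:
    def test_perfect_linear_site(self):
        ages = np.linspace(20, 80, 20)
        beta = np.column_stack([ages / 100.0, np.full(20, 0.5)])
        cohort = make_cohort(beta, np.full((20, 2), 30, dtype=np.int64), ages)
        corr = mc.age_correlation(cohort, min_obs=5)
        assert corr.r[0] == pytest.approx(1.0)
        assert np.isnan(corr.r[1])  # zero variance -> undefined

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(4)
        ages = rng.uniform(20, 80, 20)
        beta = 0.3 + 0.002 * ages[:, None] + rng.normal(0, 0.02, (20, 5))
        cohort = make_cohort(beta, np.full((20, 5), 30, dtype=np.int64), ages)
        corr = mc.age_correlation(cohort, min_obs=5)
        for j in range(5):
            expected = np.corrcoef(beta[:, j], ages)[0, 1]
            assert corr.r[j] == pytest.approx(expected, abs=1e-12)

    def test_min_obs_and_pairwise_missingness(self):
        ages = np.linspace(20, 80, 12)
        beta = np.column_stack([ages / 100.0, ages / 100.0])
        beta[:4, 0] = np.nan  # 8 observations left
        beta[:10, 1] = np.nan  # 2 observations left
        cohort = make_cohort(beta, np.full((12, 2), 30, dtype=np.int64), ages)
        corr = mc.age_correlation(cohort, min_obs=5)
        assert corr.r[0] == pytest.approx(1.0)
        assert corr.n_obs[0] == 8
        assert np.isnan(corr.r[1])

    def test_too_few_samples_errors(self):
        cohort = make_cohort([[0.5]], [[30]], [40])
        with pytest.raises(ValueError):
            mc.age_correlation(cohort)


class TestBuildRegions:
    def test_two_plateaus_split_into_two_regions(self):
        r = np.array([0.50, 0.52, 0.55, 0.90, 0.91, 0.93])
        uni = uniform_universe(6)
        rs = build_regions(uni, AgeCorrelations(r, np.full(6, 20)), 0.075)
        assert [tuple(reg.ordinals) for reg in rs.regions] == [(0, 1, 2), (3, 4, 5)]
        assert rs.regions[0].anchor_r == pytest.approx(0.50)

    def test_arithmetic_ramp_yields_nothing(self):
        r = np.array([0.10, 0.20, 0.30, 0.40])
        uni = uniform_universe(4)
        rs = build_regions(uni, AgeCorrelations(r, np.full(4, 20)), 0.075)
        assert len(rs) == 0

    def test_constant_run_is_one_region(self):
        r = np.full(5, 0.3)
        uni = uniform_universe(5)
        rs = build_regions(uni, AgeCorrelations(r, np.full(5, 20)), 0.075)
        assert len(rs) == 1 and rs.regions[0].size == 5

    def test_chromosome_change_and_nan_break_regions(self):
        r = np.full(8, 0.5)
        r[3] = np.nan
        uni = uniform_universe(8, chroms=("chr1", "chr2"))  # 4 + 4 sites
        rs = build_regions(uni, AgeCorrelations(r, np.full(8, 20)), 0.075)
        assert [tuple(reg.ordinals) for reg in rs.regions] == [(0, 1, 2), (4, 5, 6, 7)]

    def test_tolerance_must_be_positive(self):
        uni = uniform_universe(3)
        with pytest.raises(ValueError):
            build_regions(uni, AgeCorrelations(np.zeros(3), np.full(3, 20)), 0.0)

    @pytest.mark.parametrize("mode", ["both", "anchor_only", "consecutive_only"])
    def test_oracle_equivalence_random_inputs(self, mode):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(1, 60))
            chroms = ("chr1",) if rng.random() < 0.5 else ("chr1", "chr2")
            uni = uniform_universe(n, chroms)
            r = rng.choice([np.nan, 0.0], p=[0.15, 0.85], size=n) + np.round(
                rng.normal(0, 0.3, n), 3
            )
            tol = float(rng.uniform(0.02, 0.3))
            got = build_regions(
                uni, AgeCorrelations(r, np.full(n, 20)), tol, mode=mode
            )
            expected = brute_force_regions(uni.chroms, r, tol, mode=mode)
            assert [tuple(reg.ordinals) for reg in got.regions] == expected

    def test_membership_constraints_hold_post_hoc(self):
        rng = np.random.default_rng(9)
        n = 200
        uni = uniform_universe(n, ("chr1", "chr2", "chr3"))
        r = rng.normal(0, 0.2, n)
        rs = build_regions(uni, AgeCorrelations(r, np.full(n, 20)), 0.1)
        assert len(rs) > 0
        prev_end = -1
        for reg in rs.regions:
            ords = reg.ordinals
            assert ords[0] > prev_end  # disjoint and sorted
            prev_end = ords[-1]
            anchor = r[ords[0]]
            for a, b in zip(ords[:-1], ords[1:]):
                assert abs(r[b] - anchor) < 0.1
                assert abs(r[b] - r[a]) < 0.1
                assert uni.chroms[a] == uni.chroms[b]

    def test_tolerance_limits(self):
        rng = np.random.default_rng(11)
        n = 150
        uni = uniform_universe(n)
        r = rng.normal(0.2, 0.15, n)
        corr = AgeCorrelations(r, np.full(n, 20))
        # tolerance -> 0 dissolves all regions (continuous r, no exact ties)
        assert len(build_regions(uni, corr, 1e-9)) == 0
        # |r| <= 1, so at tolerance >= 2 every defined-r same-chromosome run
        # merges maximally: one region covering all 150 sites
        rs = build_regions(uni, corr, 2.0)
        assert len(rs) == 1 and rs.regions[0].size == n

    def test_planted_blocks_recovered(self):
        """Blocks whose correlation jitter sits below the tolerance are
        recovered nearly exactly (mean per-block Jaccard >= 0.7).

        The premise requires the per-site r spread — slope jitter plus
        estimation noise — to stay under the 0.075 tolerance, so the
        fixture uses strong shared slopes, small jitter, deep coverage and
        enough samples; blocks whose baseline would clip the trend are
        excluded from scoring.
        """
        cfg = mc.SimConfig(
            n_samples=800,
            n_sites=1000,
            depth_lo=200,
            depth_hi=200,
            noise_sd=0.02,
            slope_low=0.003,
            slope_high=0.004,
            slope_jitter_sd=0.0002,
            baseline_weights=(0.0, 0.0, 1.0),
            seed=3,
        )
        cohort, truth = mc.simulate_cohort(cfg)
        corr = mc.age_correlation(cohort)
        rs = build_regions(cohort.universe, corr, 0.075)
        jaccards = []
        for b in np.unique(truth.block_id[truth.block_id >= 0]):
            idx = np.flatnonzero(truth.block_id == b)
            if len(idx) < 3:
                continue
            base = truth.baseline[idx]
            if not np.all((base > 0.15) & (base < 0.85)):
                continue  # clipped trend: premise not met
            members = set(idx.tolist())
            best = 0.0
            for reg in rs.regions:
                ords = set(reg.ordinals.tolist())
                best = max(best, len(ords & members) / len(ords | members))
            jaccards.append(best)
        assert len(jaccards) >= 5
        assert np.mean(jaccards) >= 0.7


class TestRegionBetas:
    def test_mean_of_available_members(self):
        uni = uniform_universe(3)
        rs = build_regions(
            uni, AgeCorrelations(np.full(3, 0.5), np.full(3, 20)), 0.075
        )
        beta = np.array([[0.2, 0.4, np.nan], [np.nan, np.nan, np.nan]])
        cohort = make_cohort(beta, np.full((2, 3), 10, dtype=np.int64), [30, 40], universe=uni)
        feats, counts = region_betas(cohort, rs)
        assert feats[0, 0] == pytest.approx(0.3)
        assert np.isnan(feats[1, 0])
        assert counts.tolist() == [[2], [0]]

    def test_empty_region_set(self, small_cohort):
        cohort, _ = small_cohort
        feats, counts = region_betas(cohort, mc.RegionSet([], 0.075))
        assert feats.shape == (cohort.n_samples, 0)

    def test_matches_loop_oracle(self, small_cohort):
        cohort, _ = small_cohort
        corr = mc.age_correlation(cohort)
        rs = build_regions(cohort.universe, corr, 0.075)
        assert len(rs) > 0
        feats, _ = region_betas(cohort, rs)
        for j, reg in enumerate(rs.regions):
            for i in range(cohort.n_samples):
                vals = [
                    cohort.beta[i, o]
                    for o in reg.ordinals
                    if not np.isnan(cohort.beta[i, o])
                ]
                if vals:
                    assert feats[i, j] == pytest.approx(np.mean(vals))
                else:
                    assert np.isnan(feats[i, j])
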