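"""Presence/absence calling, the stratified chi-square with max-T
permutations, coverage-ratio screening and the exact-match flank test."""

import math

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from homeocollapse import sexscreen
from homeocollapse.types import Interval, VariantSite


class TestPresence:
    def _sites(self):
        # 2 males called, 2 females missing on the target contig
        gts_list = [
            [(0, 0), (1, 1), None, None],
            [(1, 1), (0, 0), None, None],
            [(0, 0), (0, 0), None, (0, 0)],
        ]
        return [
            VariantSite("sdY", i, "A", ["T"], g, [30] * 4)
            for i, g in enumerate(gts_list)
        ]

    def test_calls(self):
        calls = sexscreen.call_presence_from_genotypes(
            self._sites(), ["M1", "M2", "F1", "F2"], "sdY"
        )
        by = {c.sample_id: c.call for c in calls}
        assert by == {"M1": "present", "M2": "present", "F1": "absent", "F2": "ambiguous"}

    def test_missing_contig_errors(self):
        with pytest.raises(ValueError):
            sexscreen.call_presence_from_genotypes(self._sites(), ["a"] * 4, "nope")

    def test_presence_from_depth(self):
        track = {"sdY": [(0, 50, 0.0), (50, 100, 0.0)]}
        call = sexscreen.call_presence_from_depth(track, "F1", "sdY")
        assert call.call == "absent"
        track2 = {"sdY": [(0, 100, 25.0)]}
        assert sexscreen.call_presence_from_depth(track2, "M1", "sdY").call == "present"


class TestAssociation:
    def test_perfect_single_stratum_equals_pearson_chi_square(self):
        """26 males all present, 26 females all absent: statistic = N = 52,
        agreeing with the direct N(ad-bc)^2 / row-col formula and scipy's
        uncorrected Pearson chi-square."""
        X = np.array([[1.0] * 26 + [0.0] * 26])
        sex = ["male"] * 26 + ["female"] * 26
        strata = ["s"] * 52
        res = sexscreen.association_test(X, ["m"], sex, strata, trials=1, n_perm=49, seed=0)
        assert res.statistic[0] == pytest.approx(52.0)
        table = np.array([[26, 0], [0, 26]])
        pearson, _, _, _ = chi2_contingency(table, correction=False)
        assert res.statistic[0] == pytest.approx(pearson)

    def test_general_single_stratum_matches_scipy(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 2, size=(1, 40)).astype(float)
        sex = ["male"] * 20 + ["female"] * 20
        res = sexscreen.association_test(X, ["m"], sex, ["s"] * 40, trials=1, n_perm=9, seed=0)
        a = int(X[0, :20].sum()); b = 20 - a
        c = int(X[0, 20:].sum()); d = 20 - c
        pearson, _, _, _ = chi2_contingency(np.array([[a, b], [c, d]]), correction=False)
        assert res.statistic[0] == pytest.approx(pearson)

    def test_single_sex_stratum_contributes_nothing(self):
        X = np.array([[1.0] * 5 + [0.0] * 5 + [1.0]])
        sex = ["male"] * 5 + ["female"] * 5 + ["female"]
        strata = ["a"] * 10 + ["lone"]
        res = sexscreen.association_test(X, ["m"], sex, strata, trials=1, n_perm=9, seed=0)
        assert res.statistic[0] == pytest.approx(10.0)  # N of the usable stratum

    def test_constant_marker_undefined(self):
        X = np.array([[1.0] * 10])
        sex = ["male"] * 5 + ["female"] * 5
        res = sexscreen.association_test(X, ["m"], sex, ["s"] * 10, trials=1, n_perm=9, seed=0)
        assert math.isnan(res.statistic[0]) and math.isnan(res.p_adjusted[0])

    def test_same_seed_bit_identical_and_monotone(self):
        rng = np.random.default_rng(7)
        X = rng.integers(0, 3, size=(8, 24)).astype(float)
        sex = (["male"] * 6 + ["female"] * 6) * 2
        strata = ["a"] * 12 + ["b"] * 12
        r1 = sexscreen.association_test(X, [f"m{i}" for i in range(8)], sex, strata,
                                        trials=2, n_perm=200, seed=11)
        r2 = sexscreen.association_test(X, [f"m{i}" for i in range(8)], sex, strata,
                                        trials=2, n_perm=200, seed=11)
        assert np.array_equal(r1.p_adjusted, r2.p_adjusted, equal_nan=True)
        # adjusted p monotone non-increasing in the statistic
        order = np.argsort(r1.statistic)
        adj = r1.p_adjusted[order]
        ok = ~np.isnan(adj)
        assert np.all(np.diff(adj[ok]) <= 1e-12)

    def test_null_family_wise_error_controlled(self):
        """Sex labels independent of every marker: the max-T adjusted
        family-wise error stays at or below nominal within Monte-Carlo
        tolerance (1000 permutations per replicate)."""
        rng = np.random.default_rng(99)
        n_reps = 60
        alpha = 0.05
        hits = 0
        sex = ["male"] * 10 + ["female"] * 10
        strata = ["a", "b"] * 10
        for rep in range(n_reps):
            X = rng.integers(0, 3, size=(15, 20)).astype(float)
            res = sexscreen.association_test(
                X, [f"m{i}" for i in range(15)], sex, strata,
                trials=2, n_perm=999, seed=1000 + rep,
            )
            if np.nanmin(res.p_adjusted) <= alpha:
                hits += 1
        rate = hits / n_reps
        se = math.sqrt(alpha * (1 - alpha) / n_reps)
        assert rate <= alpha + 3 * se

    def test_requires_both_sexes(self):
        X = np.zeros((1, 4))
        with pytest.raises(ValueError):
            sexscreen.association_test(X, ["m"], ["male"] * 4, ["s"] * 4)


class TestPeakScreen:
    def _tracks(self, male_peak, female_peak):
        male = {"chr1": [(0, 10_000, 30.0)] * 1, "chr2": [(0, 10_000, male_peak)]}
        male["chr1"] = [(i * 10_000, (i + 1) * 10_000, 30.0) for i in range(100)]
        female = {"chr1": [(i * 10_000, (i + 1) * 10_000, 30.0) for i in range(100)],
                  "chr2": [(0, 10_000, female_peak)]}
        return male, female

    def test_tenfold_male_ratio(self):
        male, female = self._tracks(300.0, 30.0)
        (p,) = sexscreen.screen_peak_coverage(male, female, [Interval("chr2", 0, 10_000)])
        assert p.normalized_ratio == pytest.approx(10.0, rel=0.1)
        assert p.flagged

    def test_equal_coverage_not_flagged(self):
        male, female = self._tracks(30.0, 30.0)
        (p,) = sexscreen.screen_peak_coverage(male, female, [Interval("chr2", 0, 10_000)])
        assert p.normalized_ratio == pytest.approx(1.0, rel=0.05)
        assert not p.flagged

    def test_zero_female_window_flagged_infinite(self):
        male, female = self._tracks(30.0, 0.0)
        (p,) = sexscreen.screen_peak_coverage(male, female, [Interval("chr2", 0, 10_000)])
        assert math.isinf(p.normalized_ratio) and p.flagged


class TestFlank:
    def test_unique_locus(self):
        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        res = sexscreen.flank_repeat_test({"c": seq}, ("c", 1000), flank_bp=50)
        assert res.n_exact_matches == 1 and not res.repetitive

    def test_three_planted_copies_repetitive(self):
        rng = np.random.default_rng(1)
        unit = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        filler = lambda n, s: "".join("ACGT"[i] for i in np.random.default_rng(s).integers(0, 4, n))
        seq = filler(500, 2) + unit + filler(500, 3) + unit + filler(500, 4)
        other = filler(300, 5) + unit + filler(300, 6)
        res = sexscreen.flank_repeat_test({"a": seq, "b": other}, ("a", 600), flank_bp=50)
        assert res.n_exact_matches == 3 and res.repetitive

    def test_two_copies_not_repetitive(self):
        rng = np.random.default_rng(2)
        unit = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        pad = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        seq = pad + unit + pad[::-1] + unit
        res = sexscreen.flank_repeat_test({"a": seq}, ("a", 500), flank_bp=50)
        assert res.n_exact_matches == 2 and not res.repetitive

    def test_reverse_complement_counted(self):
        rng = np.random.default_rng(3)
        unit = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        rc = unit.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        pad = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        seq = pad + unit + pad + rc + pad
        res = sexscreen.flank_repeat_test({"a": seq}, ("a", 400), flank_bp=50)
        assert res.n_exact_matches == 2

    def test_palindromic_flank_counted_once_per_position(self):
        # palindrome: equal to its own reverse complement
        half = "ACGTACGTACGT"
        rc = half.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        pal = half + "AT" + rc  # odd-ish construction; verify palindromicity
        probe = pal
        assert probe == probe.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        pad = "CCCCCCCCCCCCC"
        seq = pad + probe + pad
        center = len(pad) + len(probe) // 2
        res = sexscreen.flank_repeat_test({"a": seq}, ("a", center), flank_bp=len(probe) // 2)
        assert res.n_exact_matches == 1

    def test_case_insensitive_softmask(self):
        rng = np.random.default_rng(4)
        unit = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        pad = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        seq = pad + unit.lower() + pad + unit + pad
        res = sexscreen.flank_repeat_test({"a": seq}, ("a", 400), flank_bp=50)
        assert res.n_exact_matches == 2


class TestSyntheticRecovery:
    def test_sdy_presence_attains_maximal_statistic(self, sim_small, sample_ids):
        sim = sim_small
        sex = [s.sex for s in sim.samples]
        strata = [s.site for s in sim.samples]
        presence = sexscreen.call_presence_from_genotypes(
            sim.sites, sample_ids, sim.truth.sdy_contig
        )
        Xp = np.array([[1.0 if c.call == "present" else 0.0 for c in presence]])
        res_p = sexscreen.association_test(Xp, ["sdY"], sex, strata, trials=1,
                                           n_perm=199, seed=5)
        auto = [s for s in sim.sites if s.seq_id != sim.truth.sdy_contig]
        Xd = np.full((len(auto), len(sample_ids)), np.nan)
        for i, s in enumerate(auto):
            for j, gt in enumerate(s.genotypes):
                if gt is not None:
                    Xd[i, j] = gt[0] + gt[1]
        res_d = sexscreen.association_test(Xd, [str(i) for i in range(len(auto))],
                                           sex, strata, trials=2, n_perm=9, seed=5)
        assert res_p.statistic[0] > np.nanmax(res_d.statistic)
        assert res_p.p_adjusted[0] <= 0.05

    def test_planted_repeat_windows_flagged_and_clean_windows_not(self, sim_small):
        sim = sim_small
        males = [s.sample_id for s in sim.samples if s.sex == "male"]
        females = [s.sample_id for s in sim.samples if s.sex == "female"]
        from homeocollapse.pipeline import average_tracks
        male_track = average_tracks([sim.depth_tracks[s] for s in males])
        female_track = average_tracks([sim.depth_tracks[s] for s in females])
        planted = sim.truth.planted_repeat_windows
        exclude = {sim.truth.sdy_contig}
        screens = sexscreen.screen_peak_coverage(
            male_track, female_track, planted, ratio_flag=2.0,
            exclude_from_genome_mean=exclude,
        )
        assert all(p.flagged for p in screens)
        # clean control windows on another chromosome
        controls = [Interval("LG03", s, s + 10_000) for s in (100_000, 400_000, 800_000)]
        clean = sexscreen.screen_peak_coverage(
            male_track, female_track, controls, ratio_flag=2.0,
            exclude_from_genome_mean=exclude,
        )
        assert not any(p.flagged for p in clean)

    def test_repeat_snp_flanks_repetitive_sdy_markers_not(self, sim_small):
        sim = sim_small
        for snp in sim.truth.repeat_snps:
            res = sexscreen.flank_repeat_test(sim.assembly, snp, flank_bp=50)
            assert res.repetitive and res.n_exact_matches >= 3
        for snp in sim.truth.sdy_sites[:5]:
            res = sexscreen.flank_repeat_test(sim.assembly, snp, flank_bp=50)
            assert not res.repetitive
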