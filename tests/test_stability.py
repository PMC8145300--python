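import math

import numpy as np
import pytest

from acidstab.fg_registry import GroupAssignment, MatchResult
from acidstab.kinetics import Condition, RateGrid, RateLibrary
from acidstab.stability import (
    BAND_LABELS,
    StabilityResult,
    band_for,
    band_histogram,
    fraction_stable,
    load_results,
    mean_half_life,
    molecule_half_life,
    profile_stability,
    results_to_frame,
    save_results,
    summarize,
)


def flat_grid(gid, ln_k):
    return RateGrid(gid, np.array([70.0, 110.0]), np.array([200.0, 400.0]),
                    np.full((2, 2), ln_k))


def match_of(mol_id, *assignments):
    return MatchResult(
        molecule_id=mol_id,
        assignments=[
            GroupAssignment(gid, n, (frozenset(),), "solvolysis") for gid, n in assignments
        ],
        status="matched" if assignments else "no_reactive_groups",
    )


COND = Condition(85.0, 280.0)


class TestBandFor:
    @pytest.mark.parametrize(
        "t,label",
        [(0.5, "<1s"), (1.0, "1-1e3s"), (500.0, "1-1e3s"), (1e4, "1e3-1e6s"),
         (1e7, "1e6-1e8s"), (1e9, ">1e8s")],
    )
    def test_bands(self, t, label):
        assert band_for(t) == label

    def test_invalid(self):
        with pytest.raises(ValueError):
            band_for(0.0)


class TestMoleculeHalfLife:
    def test_fastest_group_wins(self):
        rates = RateLibrary([flat_grid("A", math.log(1e-3)), flat_grid("B", math.log(1e-6))])
        res = molecule_half_life(match_of("m", ("A", 1), ("B", 2)), rates, COND)
        assert res.half_life_s == pytest.approx(693.147, rel=1e-4)
        assert res.limiting_group == "A"
        assert res.limiting_n == 1

    def test_formic_acid_magnitude(self):
        rates = RateLibrary([flat_grid("A", math.log(6.93e-3))])
        res = molecule_half_life(match_of("m", ("A", 1)), rates, COND)
        assert res.half_life_s == pytest.approx(100.0, rel=1e-2)

    def test_no_reactive_groups_is_no_prediction(self):
        res = molecule_half_life(match_of("m"), RateLibrary(), COND)
        assert res.status == "no_prediction"
        assert res.half_life_s is None
        assert res.limiting_group is None

    def test_all_groups_without_grids_is_no_prediction(self):
        rates = RateLibrary([flat_grid("other", 0.0)])
        res = molecule_half_life(match_of("m", ("A", 1)), rates, COND)
        assert res.status == "no_prediction"

    def test_band_consistent_with_half_life(self):
        rates = RateLibrary([flat_grid("A", math.log(1e-3))])
        res = molecule_half_life(match_of("m", ("A", 1)), rates, COND)
        assert res.band == band_for(res.half_life_s)

    def test_copy_count_shortens_half_life(self):
        rates = RateLibrary([flat_grid("A", math.log(1e-3))])
        t1 = molecule_half_life(match_of("m", ("A", 1)), rates, COND).half_life_s
        t3 = molecule_half_life(match_of("m", ("A", 3)), rates, COND).half_life_s
        assert t3 < t1

    def test_brute_force_minimum_oracle(self):
        # fastest-group rule == independent min over per-group half-lives
        from scipy.interpolate import RegularGridInterpolator

        rng = np.random.default_rng(123)
        wt = np.array([70.0, 90.0, 110.0])
        T = np.array([220.0, 300.0, 380.0])
        for _ in range(100):
            n_groups = int(rng.integers(1, 5))
            grids = []
            interps = []
            for gi in range(n_groups):
                lnk = rng.uniform(-25, 2, size=(3, 3))
                lnk.sort(axis=1)
                grids.append(RateGrid(f"g{gi}", wt, T, lnk))
                interps.append(
                    RegularGridInterpolator((wt, 1.0 / T[::-1]), lnk[:, ::-1])
                )
            rates = RateLibrary(grids)
            copies = [int(rng.integers(1, 4)) for _ in range(n_groups)]
            cond = Condition(float(rng.uniform(70, 110)), float(rng.uniform(220, 380)))
            expected = min(
                -math.log1p(-0.5 ** n) / math.exp(float(f((cond.acid_wt_pct, 1.0 / cond.temperature))))
                for f, n in zip(interps, copies)
            )
            match = match_of("m", *[(f"g{i}", c) for i, c in enumerate(copies)])
            res = molecule_half_life(match, rates, cond)
            assert res.half_life_s == pytest.approx(expected, rel=1e-9)


class TestProfileStability:
    def test_result_count(self, dataset_matches, rate_library, venus_profile):
        results = profile_stability(dataset_matches[:10], rate_library, venus_profile)
        assert len(results) == 10 * len(venus_profile)

    def test_duplicates_get_identical_results(self, rate_library, venus_profile):
        m = match_of("dup", ("amine", 1))
        r1, r2 = profile_stability([m, m], rate_library, venus_profile)[:2]
        assert r1.half_life_s == r2.half_life_s

    def test_half_life_non_decreasing_on_monotone_profile(
        self, dataset_matches, rate_library, monotone_profile
    ):
        # positive acid slopes + temperature-monotone grids + cooling, weakening
        # profile => every molecule's half-life rises with altitude
        results = profile_stability(dataset_matches, rate_library, monotone_profile)
        by_mol = {}
        for r in results:
            if r.ok:
                by_mol.setdefault(r.molecule_id, []).append((r.altitude_km, r.half_life_s))
        assert by_mol
        for series in by_mol.values():
            ts = [t for _, t in sorted(series)]
            assert all(a <= b * (1 + 1e-12) for a, b in zip(ts, ts[1:]))


class TestFractionStable:
    def make(self, ts, alt=65.0):
        return [
            StabilityResult(
                molecule_id=f"m{i}", altitude_km=alt, half_life_s=t,
                limiting_group="A", limiting_n=1, band=band_for(t), status="ok",
            )
            for i, t in enumerate(ts)
        ]

    def test_single_level(self):
        results = self.make([10.0] * 3 + [0.1] * 7)
        assert fraction_stable(results, 1.0, 62.0) == pytest.approx(0.3)

    def test_threshold_zero_is_one(self):
        results = self.make([0.5, 2.0, 100.0])
        assert fraction_stable(results, 0.0, 62.0) == 1.0

    def test_non_increasing_in_threshold(self, dataset_results):
        fracs = [fraction_stable(dataset_results, thr, 62.0) for thr in (1.0, 1e3, 1e6, 1e8)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_no_qualifying_levels_errors(self):
        results = self.make([1.0], alt=50.0)
        with pytest.raises(ValueError):
            fraction_stable(results, 1.0, 62.0)

    def test_planted_fraction_recovered(self, dataset_results):
        assert fraction_stable(dataset_results, 1e8, 62.0) == 0.25


class TestMeanHalfLife:
    def make(self, ts):
        return TestFractionStable().make(ts)

    def test_geometric_mean(self):
        assert mean_half_life(self.make([10.0, 1000.0]), 65.0) == pytest.approx(100.0)

    def test_identical_values(self):
        assert mean_half_life(self.make([42.0] * 5), 65.0) == pytest.approx(42.0)

    def test_adding_mean_value_is_neutral(self):
        base = self.make([10.0, 1000.0])
        extended = self.make([10.0, 1000.0, 100.0])
        assert mean_half_life(extended, 65.0) == pytest.approx(mean_half_life(base, 65.0))

    def test_arithmetic_option(self):
        assert mean_half_life(self.make([10.0, 1000.0]), 65.0, kind="arithmetic") == pytest.approx(505.0)

    def test_empty_level_errors(self):
        with pytest.raises(ValueError):
            mean_half_life([], 65.0)


class TestBandHistogram:
    def test_single_band(self):
        results = TestFractionStable().make([0.1] * 5)
        hist = band_histogram(results)
        assert hist[(65.0, "<1s")] == (5, pytest.approx(math.log(5)))

    def test_counts_partition_matched(self, dataset_results):
        hist = band_histogram(dataset_results)
        by_alt = {}
        for (alt, _), (count, _) in hist.items():
            by_alt[alt] = by_alt.get(alt, 0) + count
        matched = {}
        for r in dataset_results:
            if r.ok:
                matched[r.altitude_km] = matched.get(r.altitude_km, 0) + 1
        assert by_alt == matched

    def test_zero_cells_absent(self):
        results = TestFractionStable().make([0.1])
        assert all(count > 0 for count, _ in band_histogram(results).values())


class TestSummarize:
    def test_summary_consistency(self, dataset_results):
        summary = summarize(dataset_results)
        frame = summary.per_altitude
        assert (frame["n_matched"] + frame["n_no_prediction"] > 0).all()
        for thr in summary.thresholds:
            col = frame[f"frac_ge_{thr:g}s"]
            assert ((0.0 <= col) & (col <= 1.0)).all()
        assert (summary.band_counts.sum(axis=1) == frame["n_matched"]).all()
        assert list(summary.band_counts.columns) == list(BAND_LABELS)


class TestResultsIO:
    def test_round_trip(self, tmp_path, dataset_results):
        p = tmp_path / "results.csv"
        subset = dataset_results[:60]
        save_results(subset, p)
        loaded = load_results(p)
        assert len(loaded) == len(subset)
        for a, b in zip(loaded, subset):
            assert a.molecule_id == b.molecule_id
            assert a.status == b.status
            if b.ok:
                assert a.half_life_s == pytest.approx(b.half_life_s, rel=1e-12)

    def test_frame_columns(self, dataset_results):
        frame = results_to_frame(dataset_results[:5])
        assert list(frame.columns) == [
            "molecule_id", "altitude_km", "half_life_s", "limiting_group",
            "limiting_N", "band", "status", "extrapolated",
        ]
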