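"""Peak caller, biweight normalization, permutation FDR, threshold calibration."""

import numpy as np
import pandas as pd
import pytest

from chipdyn import (
    SampleKey,
    biweight_location,
    calibrate_fdr_threshold,
    call_peaks,
    estimate_fdr,
    normalize_biweight,
)
from chipdyn.types import ChipdynError, ConfigError, ValidationError, WINDOW_ORIGIN

from conftest import noise_only_probes


# --------------------------------------------------------------------------
# independent oracles


def oracle_biweight(values, c=9.0):
    """Fixed-scale Tukey M-estimate by direct objective minimization on a grid."""
    x = np.asarray(values, float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return med

    def rho(t):
        u = (x - t) / (c * mad)
        inside = np.abs(u) < 1
        r = np.full_like(u, 1.0 / 6.0)
        r[inside] = (1 - (1 - u[inside] ** 2) ** 3) / 6.0
        return r.sum()

    grid = np.linspace(x.min(), x.max(), 20001)
    t0 = grid[np.argmin([rho(t) for t in grid])]
    fine = np.linspace(t0 - 0.01, t0 + 0.01, 2001)
    return fine[np.argmin([rho(t) for t in fine])]


def oracle_call_peaks(probes: pd.DataFrame, window_bp=500, min_probes=4, thr=0.4):
    """Enumerate every window start; dedupe to canonical (first-probe) starts;
    merge overlapping candidate windows; emit spans and member-probe means."""
    results = []
    for gene, sub in probes.groupby("gene_id", sort=True):
        sub = sub.sort_values("offset")
        offsets = sub["offset"].to_numpy()
        values = sub["log2_ratio"].to_numpy()
        candidates = {}
        for start in range(int(offsets.min()) - window_bp, int(offsets.max()) + 1):
            mask = (offsets >= start) & (offsets < start + window_bp)
            if mask.sum() < min_probes or values[mask].mean() < thr:
                continue
            first = int(offsets[mask][0])  # canonical representative
            candidates[first] = mask
        if not candidates:
            continue
        starts = sorted(candidates)
        run = [starts[0]]
        runs = []
        for s in starts[1:]:
            if s < run[-1] + window_bp:
                run.append(s)
            else:
                runs.append(run)
                run = [s]
        runs.append(run)
        for run in runs:
            member = np.zeros(len(offsets), bool)
            for s in run:
                member |= candidates[s]
            sel = np.flatnonzero(member)
            lo, hi = int(offsets[sel[0]]), int(offsets[sel[-1]]) + 1
            results.append((gene, lo - WINDOW_ORIGIN, hi - WINDOW_ORIGIN,
                            values[sel].mean()))
    return results


# --------------------------------------------------------------------------
# biweight


class TestBiweight:
    def test_constant_input_normalizes_to_zero(self):
        df = pd.DataFrame({"gene_id": ["g"] * 5, "offset": range(5),
                           "log2_ratio": [0.7] * 5})
        out = normalize_biweight(df)
        assert np.allclose(out["log2_ratio"], 0.0)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.5, 200)
        df = pd.DataFrame({"gene_id": "g", "offset": range(200), "log2_ratio": x})
        df2 = df.assign(log2_ratio=x + 1.7)
        np.testing.assert_allclose(
            normalize_biweight(df)["log2_ratio"],
            normalize_biweight(df2)["log2_ratio"],
            atol=1e-9,
        )

    def test_outlier_downweighted_matches_independent_oracle(self):
        x = [0.1, -0.1, 0.0, 0.2, 10.0]
        loc = biweight_location(x)
        assert -0.1 <= loc <= 0.2  # arithmetic mean 2.04 would fail
        assert abs(loc - oracle_biweight(x)) < 1e-3

    def test_random_samples_match_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            x = np.concatenate([rng.normal(0, 0.3, 50), rng.normal(3, 1, 5)])
            assert abs(biweight_location(x) - oracle_biweight(x)) < 1e-3

    def test_empty_input_raises(self):
        with pytest.raises(ValidationError):
            normalize_biweight(pd.DataFrame(columns=["gene_id", "offset", "log2_ratio"]))


# --------------------------------------------------------------------------
# caller


def bump_probes(site=0, height=2.0, spacing=100, gene="gA", width=500):
    grid = np.arange(-3250, 751, spacing)
    vals = height * np.clip(1 - np.abs(grid - site) / width, 0, None)
    return pd.DataFrame({"gene_id": gene, "offset": grid, "log2_ratio": vals})


class TestCallPeaks:
    def test_zero_signal_gives_no_peaks(self):
        df = bump_probes(height=0.0)
        assert call_peaks(df, score_threshold=0.5) == []

    def test_single_planted_bump_gives_one_peak_containing_site(self):
        df = bump_probes(site=-1000, height=2.0)
        peaks = call_peaks(df, score_threshold=0.5, min_probes=3)
        assert len(peaks) == 1
        (peak,) = peaks
        assert peak.start <= -1000 - WINDOW_ORIGIN < peak.end

    def test_two_bumps_2000bp_apart_give_two_peaks(self):
        df = bump_probes(site=-1800, height=2.0)
        df2 = bump_probes(site=200, height=2.0)
        df["log2_ratio"] += df2["log2_ratio"]
        peaks = call_peaks(df, score_threshold=0.5, min_probes=3)
        assert len(peaks) == 2

    def test_window_smaller_than_spacing_is_config_error(self):
        with pytest.raises(ConfigError):
            call_peaks(bump_probes(), window_bp=50)

    @pytest.mark.parametrize("seed", range(6))
    def test_caller_matches_exhaustive_window_start_oracle(self, seed):
        probes = noise_only_probes(8, seed, noise_sd=0.6)
        # add a couple of bumps so matches exercise merging
        rng = np.random.default_rng(seed)
        for gene in [f"g{i:05d}" for i in rng.choice(8, 3, replace=False)]:
            site = rng.integers(-2750, 251)
            mask = probes["gene_id"] == gene
            probes.loc[mask, "log2_ratio"] += 1.5 * np.clip(
                1 - np.abs(probes.loc[mask, "offset"] - site) / 500, 0, None
            )
        got = [(p.gene_id, p.start, p.end, p.score)
               for p in call_peaks(probes, score_threshold=0.4)]
        expected = oracle_call_peaks(probes, thr=0.4)
        assert len(got) == len(expected)
        for g, e in zip(sorted(got), sorted(expected)):
            assert g[:3] == e[:3]
            assert abs(g[3] - e[3]) < 1e-9

    def test_irregular_offsets_match_oracle(self):
        rng = np.random.default_rng(3)
        offsets = np.sort(rng.choice(np.arange(-3250, 751), 25, replace=False))
        probes = pd.DataFrame({
            "gene_id": "gX", "offset": offsets,
            "log2_ratio": rng.normal(0.3, 0.5, 25),
        })
        got = [(p.gene_id, p.start, p.end, round(p.score, 9))
               for p in call_peaks(probes, score_threshold=0.4, min_probes=3)]
        expected = [(g, s, e, round(sc, 9))
                    for g, s, e, sc in oracle_call_peaks(probes, min_probes=3, thr=0.4)]
        assert got == expected


# --------------------------------------------------------------------------
# permutation FDR


class TestEstimateFdr:
    def test_dominant_peak_gets_fdr_below_null_resolution(self):
        probes = noise_only_probes(20, 1, noise_sd=0.2)
        mask = probes["gene_id"] == "g00000"
        probes.loc[mask, "log2_ratio"] += 5.0 * np.clip(
            1 - np.abs(probes.loc[mask, "offset"] + 1000) / 500, 0, None
        )
        peaks = call_peaks(probes, score_threshold=0.4)
        n_perm = 25
        out = estimate_fdr(peaks, probes, n_permutations=n_perm, seed=2)
        top = max(out, key=lambda p: p.score)
        assert top.gene_id == "g00000"
        assert top.fdr < 1.0 / n_perm

    def test_fdr_monotone_non_increasing_in_score(self, small_signals):
        sample = SampleKey("chip", "Sirt6", "WT", 15)
        probes = normalize_biweight(small_signals[sample])
        peaks = estimate_fdr(call_peaks(probes), probes, 25, seed=3)
        by_score = sorted(peaks, key=lambda p: p.score)
        fdrs = [p.fdr for p in by_score]
        assert all(a >= b for a, b in zip(fdrs, fdrs[1:]))

    def test_equal_scores_get_equal_fdr(self):
        one = bump_probes(site=0, height=2.0, gene="gA")
        two = bump_probes(site=0, height=2.0, gene="gB")
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 0.2, len(one))
        one["log2_ratio"] += noise
        two["log2_ratio"] += noise  # identical windows -> identical scores
        probes = pd.concat([one, two], ignore_index=True)
        out = estimate_fdr(call_peaks(probes), probes, 20, seed=1)
        scores = {}
        for p in out:
            scores.setdefault(round(p.score, 12), set()).add(p.fdr)
        for fdrs in scores.values():
            assert len(fdrs) == 1

    def test_zero_permutations_rejected(self):
        with pytest.raises(ChipdynError):
            estimate_fdr([], bump_probes(), n_permutations=0)


# --------------------------------------------------------------------------
# calibration


class TestCalibration:
    def test_full_recovery_everywhere_chooses_smallest_threshold(self):
        sets = {0.05: {"a", "b"}, 0.1: {"a", "b", "c"}, 0.2: {"a", "b", "c", "d"}}
        report = calibrate_fdr_threshold(sets, {"a", "b"})
        assert report.chosen_threshold == 0.05

    def test_recovery_goal_rule_application(self):
        # recovery sequence (0.5, 0.95, 1.0) over thresholds (0.05, 0.1, 0.2)
        known = {f"k{i}" for i in range(20)}
        sets = {
            0.05: {f"k{i}" for i in range(10)},
            0.1: {f"k{i}" for i in range(19)},
            0.2: set(known),
        }
        assert calibrate_fdr_threshold(sets, known, recovery_goal=0.9).chosen_threshold == 0.1

    def test_report_counts_are_monotone(self):
        known = {"a", "b"}
        sets = {0.05: {"a"}, 0.1: {"a", "b"}, 0.2: {"a", "b", "c"}}
        report = calibrate_fdr_threshold(sets, known)
        assert report.table["n_targets"].is_monotonic_increasing
        assert report.table["n_known_recovered"].max() <= 2

    def test_empty_known_targets_raise(self):
        with pytest.raises(ChipdynError):
            calibrate_fdr_threshold({0.1: {"a"}}, set())
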