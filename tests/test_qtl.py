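"""Genome-scan machinery: conditional genotype probabilities, joint
imputation draws, LOD profiles, permutation thresholds and support
intervals, each checked against independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from fecmap.genmap import GeneticMap, GenotypeMatrix, recombination_fraction
from fecmap.qtl import (
    ImputationSet,
    LODProfile,
    PseudomarkerGrid,
    build_grid,
    conditional_genotype_probabilities,
    draw_imputations,
    lod_support_interval,
    permutation_threshold,
    scan,
    variance_explained,
)
from fecmap.simulate import simulate_ril_genotypes


def _gm(positions, calls):
    """One-chromosome map + genotype matrix from a dict line -> calls."""
    markers = [f"m{i}" for i in range(len(positions))]
    gmap = GeneticMap(
        pd.DataFrame({"marker": markers, "chrom": ["1"] * len(positions),
                      "cm": positions})
    )
    df = pd.DataFrame(calls, index=markers).T
    df.columns = markers
    return gmap, GenotypeMatrix(df, gmap)


def _manual_grid(gmap, extra_positions):
    rows = []
    pos_markers = dict(zip(gmap.table["cm"], gmap.table["marker"]))
    for p in sorted(set(gmap.table["cm"]).union(extra_positions)):
        rows.append(("1", float(p), pos_markers.get(p)))
    return PseudomarkerGrid(pd.DataFrame(rows, columns=["chrom", "cm", "marker"]),
                            step_cm=np.inf)


class TestGrid:
    def test_includes_all_markers_and_respects_step(self, ril_map):
        grid = build_grid(ril_map, 3.0)
        markers = set(grid.table["marker"].dropna())
        assert markers == set(ril_map.table["marker"])
        for _, idx in grid.chromosome_slices():
            gaps = np.diff(grid.table["cm"].to_numpy()[idx])
            assert (gaps <= 3.0 + 1e-9).all()

    def test_invalid_step_rejected(self, ril_map):
        with pytest.raises(ValueError):
            build_grid(ril_map, 0.0)


class TestConditionalProbabilities:
    def test_observed_markers_have_certain_probability(self):
        gmap, gm = _gm([0.0, 10.0], {"l1": ["A", "B"], "l2": ["B", "A"]})
        grid = build_grid(gmap, 5.0)
        probs = conditional_genotype_probabilities(gm, grid)
        at = {
            (line, mk): probs[i, j]
            for i, line in enumerate(gm.line_ids)
            for j, mk in enumerate(grid.table["marker"])
            if mk is not None
        }
        assert at[("l1", "m0")] == 1.0 and at[("l1", "m1")] == 0.0
        assert at[("l2", "m0")] == 0.0 and at[("l2", "m1")] == 1.0

    def test_midpoint_matches_two_state_enumeration(self):
        # flanking markers 20 cM apart, pseudomarker midway: enumerate the
        # two-state chain over the two 10 cM legs
        gmap, gm = _gm([0.0, 20.0], {"l1": ["A", "A"], "l2": ["A", "B"],
                                     "l3": ["B", "A"], "l4": ["B", "B"]})
        grid = _manual_grid(gmap, [10.0])
        probs = conditional_genotype_probabilities(gm, grid)
        r = recombination_fraction(10.0)
        p, q = 1 - r, r

        def enum(left, right):
            num = (p if left == "A" else q) * (p if right == "A" else q)
            den = num + (q if left == "A" else p) * (q if right == "A" else p)
            return num / den

        mid = 1  # grid column of the pseudomarker
        for i, (l, rgt) in enumerate([("A", "A"), ("A", "B"), ("B", "A"), ("B", "B")]):
            assert probs[i, mid] == pytest.approx(enum(l, rgt), abs=1e-12)

    def test_terminal_overhang_is_single_step_chain(self):
        gmap, gm = _gm([0.0], {"l1": ["B"]})
        grid = _manual_grid(gmap, [7.0])  # 7 cM beyond the only marker
        probs = conditional_genotype_probabilities(gm, grid)
        assert probs[0, 1] == pytest.approx(recombination_fraction(7.0), abs=1e-12)

    def test_missing_marker_between_identical_flanks(self):
        gmap, gm = _gm([0.0, 10.0, 20.0], {"l1": ["A", None, "A"]})
        grid = build_grid(gmap, 30.0)
        probs = conditional_genotype_probabilities(gm, grid)
        r = recombination_fraction(10.0)
        expect = (1 - r) ** 2 / ((1 - r) ** 2 + r**2)
        assert probs[0, 1] == pytest.approx(expect, abs=1e-12)


class TestImputations:
    def test_observed_markers_never_contradicted(self, typed_genotypes, ril_map):
        grid = build_grid(ril_map, 3.0)
        imps = draw_imputations(typed_genotypes, grid, 10, seed=0)
        codes = typed_genotypes.codes()
        marker_cols = {m: j for j, m in enumerate(ril_map.markers)}
        for t, mk in enumerate(grid.table["marker"]):
            if mk is None:
                continue
            obs = codes[:, marker_cols[mk]]
            typed = obs >= 0
            assert (imps.genotypes[:, typed, t] == obs[typed]).all()

    def test_seed_determinism(self, typed_genotypes, ril_map):
        grid = build_grid(ril_map, 3.0)
        a = draw_imputations(typed_genotypes, grid, 5, seed=9)
        b = draw_imputations(typed_genotypes, grid, 5, seed=9)
        assert (a.genotypes == b.genotypes).all()

    def test_midpoint_draw_frequency_matches_probability(self):
        # widely separated identical flanks: sampled mid-state frequency
        # must match the forward-backward probability
        gmap, gm = _gm([0.0, 200.0], {"l1": ["A", "A"]})
        grid = _manual_grid(gmap, [100.0])
        probs = conditional_genotype_probabilities(gm, grid)
        imps = draw_imputations(gm, grid, 10000, seed=3)
        frac_B = imps.genotypes[:, 0, 1].mean()
        pB = 1 - probs[0, 1]
        assert abs(frac_B - pB) < 3 * np.sqrt(pB * (1 - pB) / 10000)


def _brute_force_lod(y, env_idx, x):
    """Independent two-model least-squares LOD."""
    n = len(y)
    E = env_idx.max() + 1
    Xr = np.eye(E)[env_idx]
    Xf = np.column_stack([Xr, Xr * x[:, None]])
    rss = []
    for X in (Xr, Xf):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        rss.append(r @ r)
    return (n / 2.0) * np.log10(rss[0] / max(rss[1], 1e-300))


def _totals_frame(lines, envs, Y):
    rows = [(l, e, Y[i, j]) for i, l in enumerate(lines) for j, e in enumerate(envs)]
    return pd.DataFrame(rows, columns=["line", "environment", "total"])


class TestScan:
    def test_constant_phenotype_gives_zero_lod(self, typed_genotypes, ril_map):
        grid = build_grid(ril_map, 3.0)
        imps = draw_imputations(typed_genotypes, grid, 5, seed=0)
        totals = _totals_frame(list(typed_genotypes.line_ids), ["e1", "e2"],
                               np.full((12, 2), 100.0))
        prof = scan(totals, imps)
        assert np.nanmax(np.abs(prof.table["lod"].to_numpy())) < 1e-8

    def test_lod_at_typed_marker_matches_regression_oracle(self):
        # 8 lines, 2 environments, genotype at a typed marker perfectly
        # predicting a two-mean phenotype
        rng = np.random.default_rng(5)
        calls = {f"l{i}": ["A" if i < 4 else "B", "A" if i % 2 else "B"]
                 for i in range(8)}
        gmap, gm = _gm([0.0, 40.0], calls)
        grid = build_grid(gmap, 40.0)
        imps = draw_imputations(gm, grid, 7, seed=1)
        Y = np.where(np.array([i < 4 for i in range(8)])[:, None], 50.0, 30.0)
        Y = np.repeat(Y, 2, axis=1) + rng.normal(0, 1, (8, 2))
        totals = _totals_frame(list(gm.line_ids), ["e1", "e2"], Y)
        prof = scan(totals, imps)
        env_idx = np.tile([0, 1], 8)
        for t, mk in enumerate(grid.table["marker"]):
            if mk is None:
                continue
            x = np.repeat(np.where(gm.calls[mk] == "A", 0.5, -0.5), 2)
            oracle = _brute_force_lod(Y.ravel(), env_idx, x)
            assert prof.table["lod"].iloc[t] == pytest.approx(oracle, abs=1e-8)

    def test_typed_marker_lod_independent_of_imputation_count(
        self, typed_genotypes, ril_map
    ):
        rng = np.random.default_rng(2)
        grid = build_grid(ril_map, 3.0)
        totals = _totals_frame(list(typed_genotypes.line_ids), ["e1", "e2"],
                               rng.normal(300, 40, (12, 2)))
        typed = grid.table["marker"].notna().to_numpy()
        lods = []
        for n_imp in (1, 10):
            imps = draw_imputations(typed_genotypes, grid, n_imp, seed=4)
            lods.append(scan(totals, imps).table["lod"].to_numpy()[typed])
        np.testing.assert_allclose(lods[0], lods[1], atol=1e-10)

    def test_affine_invariance_of_profile(self, typed_genotypes, ril_map):
        rng = np.random.default_rng(3)
        grid = build_grid(ril_map, 6.0)
        Y = rng.normal(300, 40, (12, 2))
        imps = draw_imputations(typed_genotypes, grid, 10, seed=5)
        lines = list(typed_genotypes.line_ids)
        p1 = scan(_totals_frame(lines, ["e1", "e2"], Y), imps)
        p2 = scan(_totals_frame(lines, ["e1", "e2"], 3.0 * Y + 7.0), imps)
        np.testing.assert_allclose(p1.table["lod"], p2.table["lod"], atol=1e-8)
        assert (p1.table["lod"].to_numpy() >= -1e-12).all()

    def test_perfect_genotype_phenotype_gives_full_variance_explained(self):
        calls = {f"l{i}": ["A" if i < 4 else "B"] for i in range(8)}
        gmap, gm = _gm([0.0], calls)
        grid = build_grid(gmap, 5.0)
        imps = draw_imputations(gm, grid, 3, seed=0)
        Y = np.where(np.array([i < 4 for i in range(8)])[:, None], 50.0, 30.0)
        Y = np.broadcast_to(Y, (8, 2)).copy()
        totals = _totals_frame(list(gm.line_ids), ["e1", "e2"], Y)
        prof = scan(totals, imps)
        assert variance_explained(prof) == pytest.approx(100.0, abs=1e-6)


class TestPermutationThreshold:
    @pytest.fixture()
    def small_scan(self):
        gmap = GeneticMap(
            pd.DataFrame({"marker": [f"m{i}" for i in range(10)],
                          "chrom": ["1"] * 10,
                          "cm": np.arange(10) * 8.0})
        )
        gm = simulate_ril_genotypes(gmap, 10, seed=8)
        grid = build_grid(gmap, 4.0)
        imps = draw_imputations(gm, grid, 10, seed=9)
        rng = np.random.default_rng(10)
        totals = _totals_frame(list(gm.line_ids), ["e1", "e2"],
                               rng.normal(300, 40, (10, 2)))
        return totals, imps

    def test_threshold_monotone_in_alpha(self, small_scan):
        totals, imps = small_scan
        t05, null = permutation_threshold(totals, imps, 200, alpha=0.05, seed=1)
        t20, _ = permutation_threshold(totals, imps, 200, alpha=0.20, seed=1)
        t100, _ = permutation_threshold(totals, imps, 200, alpha=1.0, seed=1)
        assert t05 >= t20 >= t100
        assert t100 == pytest.approx(null.min())

    def test_invalid_alpha_and_nperm_rejected(self, small_scan):
        totals, imps = small_scan
        with pytest.raises(ValueError):
            permutation_threshold(totals, imps, 200, alpha=1.5, seed=0)
        with pytest.raises(ValueError):
            permutation_threshold(totals, imps, 50, alpha=0.05, seed=0)

    def test_seed_reproducibility(self, small_scan):
        totals, imps = small_scan
        a, _ = permutation_threshold(totals, imps, 150, seed=2)
        b, _ = permutation_threshold(totals, imps, 150, seed=2)
        assert a == b


class TestSupportInterval:
    def _profile(self, lods, cms=None):
        n = len(lods)
        cms = np.arange(n, dtype=float) if cms is None else cms
        tab = pd.DataFrame({
            "chrom": ["1"] * n, "cm": cms,
            "marker": [f"m{i}" for i in range(n)],
            "lod": lods, "ve": np.zeros(n),
        })
        return LODProfile(tab, ["e1"], 1, "mean_likelihood", n)

    def test_flat_profile_spans_chromosome(self):
        prof = self._profile(np.full(10, 2.0))
        iv = lod_support_interval(prof, drop=3.0)
        assert iv["cm_low"] == 0.0 and iv["cm_high"] == 9.0

    def test_zero_drop_contains_argmax(self):
        prof = self._profile(np.array([0.0, 1.0, 5.0, 1.0, 0.0]))
        iv = lod_support_interval(prof, drop=0.0)
        assert iv["cm_low"] == iv["cm_high"] == 2.0

    def test_matches_direct_thresholding_oracle(self):
        rng = np.random.default_rng(11)
        lods = np.abs(rng.normal(0, 1, 40))
        lods[25] = 8.0
        prof = self._profile(lods)
        iv = lod_support_interval(prof, drop=3.0)
        cutoff = 8.0 - 3.0
        # oracle: maximal contiguous run around the peak with lod >= cutoff
        lo = hi = 25
        while lo > 0 and lods[lo - 1] >= cutoff:
            lo -= 1
        while hi < 39 and lods[hi + 1] >= cutoff:
            hi += 1
        assert iv["cm_low"] == float(lo) and iv["cm_high"] == float(hi)
        assert iv["cm_low"] <= 25.0 <= iv["cm_high"]
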