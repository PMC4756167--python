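"""Window-cluster rule, correlation dendrogram, multiscale bootstrap, AU fitting."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lazpipe.clustering import (
    DEFAULT_SCALES,
    assign_window_clusters,
    au_from_bp,
    correlation_dendrogram,
    multiscale_bootstrap,
    supported_dendrogram,
    tree_bipartitions,
)

TIMES = (0, 12, 24, 48, 72)


def _diff(S, p, gene="g"):
    row = {}
    for t, s, pv in zip(TIMES, S, p):
        row[f"S_{t}"], row[f"p_S_{t}"] = s, pv
    df = pd.DataFrame([row], index=[gene])
    df.attrs["times"] = list(TIMES)
    return df


class TestWindowRule:
    def test_single_window_up(self):
        diff = _diff([3.1, 2.5, 0.4, -0.1, 0.2], [0.001] * 5)
        a = assign_window_clusters(diff)
        assert a.loc["g", "windows"] == ["up_W1"]
        assert a.loc["g", "primary_cluster"] == "C1"
        assert not a.loc["g", "multi_window"]

    def test_three_consecutive_passes(self):
        diff = _diff([3.1, 2.5, 2.2, 0.0, 0.0], [0.001] * 5)
        a = assign_window_clusters(diff)
        assert a.loc["g", "windows"] == ["up_W1", "up_W2"]
        assert a.loc["g", "primary_cluster"] == "C1"
        assert a.loc["g", "multi_window"] and a.loc["g", "run_length"] == 3

    def test_strict_threshold(self):
        diff = _diff([1.9, 1.9, 1.9, 1.9, 1.9], [0.001] * 5)
        assert assign_window_clusters(diff).loc["g", "primary_cluster"] is None

    def test_down_windows_map_to_c5_to_c8(self):
        diff = _diff([0, 0, -2.5, -2.7, 0], [0.001] * 5)
        a = assign_window_clusters(diff)
        assert a.loc["g", "windows"] == ["down_W3"]
        assert a.loc["g", "primary_cluster"] == "C7"

    def test_significance_required_at_both_timepoints(self):
        diff = _diff([3.0, 3.0, 0, 0, 0], [0.001, 0.5, 1, 1, 1])
        assert assign_window_clusters(diff).loc["g", "windows"] == []

    def test_missing_timepoint_errors(self):
        diff = _diff([1, 1, 1, 1, 1], [1] * 5).drop(columns=["S_24"])
        with pytest.raises(ValueError, match="24"):
            assign_window_clusters(diff, times=TIMES)

    def test_matches_bruteforce_over_all_patterns(self):
        """All 3^5 per-timepoint states (up-pass / down-pass / fail) agree with
        an independent brute-force reading of the rule."""
        state_to_sp = {"up": (3.0, 0.001), "down": (-3.0, 0.001), "fail": (0.0, 0.9)}
        rows, expected = [], []
        for pattern in itertools.product(["up", "down", "fail"], repeat=5):
            S = [state_to_sp[s][0] for s in pattern]
            p = [state_to_sp[s][1] for s in pattern]
            rows.append((S, p))
            # brute force: enumerate windows directly from the pattern
            wins = []
            for w in range(4):
                if pattern[w] == pattern[w + 1] == "up":
                    wins.append(("up", w + 1))
                if pattern[w] == pattern[w + 1] == "down":
                    wins.append(("down", w + 1))
            if wins:
                direction, k = min(wins, key=lambda dw: dw[1])
                expected.append(f"C{k}" if direction == "up" else f"C{4 + k}")
            else:
                expected.append(None)
        frames = []
        for i, (S, p) in enumerate(rows):
            frames.append(_diff(S, p, gene=f"g{i:03d}"))
        diff = pd.concat(frames)
        diff.attrs["times"] = list(TIMES)
        a = assign_window_clusters(diff)
        assert list(a["primary_cluster"]) == expected


class TestDendrogram:
    def test_identical_profiles_merge_at_zero(self):
        profiles = pd.DataFrame([[1, 2, 3, 4], [2, 4, 6, 8], [9, 1, 5, 2]],
                                index=["a", "b", "c"], dtype=float)
        Z, labels = correlation_dendrogram(profiles)
        assert Z[0, 2] == pytest.approx(0.0)  # a and b are perfectly correlated
        assert set(tree_bipartitions(Z, labels)[0]) == {"a", "b"}

    def test_anticorrelated_pair_merges_at_two(self):
        profiles = pd.DataFrame([[1, 2, 3], [3, 2, 1]], index=["a", "b"], dtype=float)
        Z, _ = correlation_dendrogram(profiles)
        assert Z[0, 2] == pytest.approx(2.0)

    def test_first_cut_separates_archetypes(self):
        # two planted archetype shapes, two genes each: the root split must
        # partition the leaves by archetype (checked against all pairings)
        up_w1 = [4.0, 4.0, 0.0, 0.0, 0.0]
        up_w3 = [0.0, 0.0, 4.0, 4.0, 0.0]
        profiles = pd.DataFrame(
            [up_w1, [v + 0.1 for v in up_w1], up_w3, [v - 0.1 for v in up_w3]],
            index=["a1", "a2", "b1", "b2"], dtype=float,
        )
        Z, labels = correlation_dendrogram(profiles)
        top = max(tree_bipartitions(Z, labels), key=len) if len(labels) > 2 else None
        parts = tree_bipartitions(Z, labels)
        assert frozenset({"a1", "a2"}) in parts and frozenset({"b1", "b2"}) in parts

    def test_zero_variance_profile_warns(self):
        profiles = pd.DataFrame([[1, 1, 1], [1, 2, 3]], index=["a", "b"], dtype=float)
        with pytest.warns(UserWarning, match="zero-variance"):
            correlation_dendrogram(profiles)


@pytest.fixture(scope="module")
def separated_profiles():
    # opposite ramps: the two groups stay perfectly separated under any
    # resampling of >= 2 distinct condition columns
    rng = np.random.default_rng(0)
    ramp = np.arange(10, dtype=float)
    base = np.vstack([np.outer([1.0, 2.0, 3.0], ramp), np.outer([-1.0, -2.0, -3.0], ramp)])
    return pd.DataFrame(base + rng.normal(0, 0.01, base.shape),
                        index=[f"g{i}" for i in range(6)])


class TestMultiscaleBootstrap:
    def test_determinism(self, separated_profiles):
        bp1 = multiscale_bootstrap(separated_profiles, nboot=20, seed=42)
        bp2 = multiscale_bootstrap(separated_profiles, nboot=20, seed=42)
        assert bp1 == bp2

    def test_strong_edge_has_bp_one_everywhere(self, separated_profiles):
        bp = multiscale_bootstrap(separated_profiles, nboot=50, seed=0)
        group = frozenset({"g0", "g1", "g2"})
        assert group in bp
        assert all(v == 1.0 for v in bp[group].values())

    def test_scale_and_nboot_validation(self, separated_profiles):
        with pytest.raises(ValueError, match="scales"):
            multiscale_bootstrap(separated_profiles, scales=[0.1], nboot=20)
        with pytest.raises(ValueError, match="nboot"):
            multiscale_bootstrap(separated_profiles, nboot=5)


class TestAuFit:
    def test_flat_half_curve_gives_au_half(self):
        sup = au_from_bp({r: 0.5 for r in DEFAULT_SCALES}, nboot=1000)
        assert sup.au == pytest.approx(0.5, abs=1e-12)
        assert sup.bp_fitted == pytest.approx(0.5, abs=1e-12)

    def test_closed_form_recovery(self):
        d, c = 1.0, 0.5
        curve = {
            r: float(1 - stats.norm.cdf(d * np.sqrt(r) + c / np.sqrt(r)))
            for r in DEFAULT_SCALES
        }
        sup = au_from_bp(curve, nboot=1000)
        assert sup.au == pytest.approx(1 - stats.norm.cdf(d - c), abs=1e-6)
        assert sup.d == pytest.approx(d, abs=1e-6) and sup.c == pytest.approx(c, abs=1e-6)

    def test_saturated_curves_are_degenerate(self):
        assert au_from_bp({r: 1.0 for r in DEFAULT_SCALES}, 100).au == 1.0
        assert au_from_bp({r: 0.0 for r in DEFAULT_SCALES}, 100).au == 0.0

    def test_au_bounds_and_ordering(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            d, c = rng.uniform(-1.5, 1.5), rng.uniform(0.01, 1.0)
            curve = {
                r: float(np.clip(1 - stats.norm.cdf(d * np.sqrt(r) + c / np.sqrt(r))
                                 + rng.normal(0, 0.01), 0.02, 0.98))
                for r in DEFAULT_SCALES
            }
            sup = au_from_bp(curve, nboot=1000)
            assert 0.0 <= sup.au <= 1.0 and 0.0 <= sup.bp_fitted <= 1.0
            if sup.c > 0:
                assert sup.au >= sup.bp_fitted


class TestSupportedDendrogram:
    def test_newick_and_support_table(self, separated_profiles=None):
        rng = np.random.default_rng(1)
        base = np.vstack([np.tile([8.0, 8.0, 0, 0, 0], (2, 1)),
                          np.tile([0, 0, 8.0, 8.0, 0], (2, 1))])
        profiles = pd.DataFrame(base + rng.normal(0, 0.1, base.shape),
                                index=["a1", "a2", "b1", "b2"])
        dendro = supported_dendrogram(profiles, nboot=20, seed=0)
        table = dendro.support_table()
        assert ((table["au"] >= 0) & (table["au"] <= 1)).all()
        nwk = dendro.to_newick()
        assert nwk.endswith(";") and "a1" in nwk and "|" in nwk
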