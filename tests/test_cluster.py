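"""Sign-flip and label-shuffle permutation tests with cluster correction.

Monte-Carlo z-maps are validated against exhaustive enumeration; the
connected-component labeling is validated against a brute-force flood fill.
"""

import itertools

import numpy as np
import pytest

from tmstheta.cluster import (
    DeviationStack,
    between_group_test,
    between_group_zmap_exact,
    center_by_subject,
    cluster_correct,
    label_clusters,
    max_cluster_size,
    signflip_zmap,
    signflip_zmap_exact,
    within_group_test,
)
from tmstheta.timefreq import TFMap


def roi_map(values, freqs=None, times=None, group="HC"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_f, n_t = values.shape
    return TFMap(
        power=values,
        freqs=np.arange(n_f) + 4.0 if freqs is None else freqs,
        times=np.arange(n_t) * 20.0 + 10.0 if times is None else times,
        scale="dB",
        baseline=(-400.0, -200.0),
        group=group,
    )


def stack_from(dev, site="lDLPFC"):
    dev = np.asarray(dev, dtype=float)
    if dev.ndim == 1:
        dev = dev[:, None, None]
    return DeviationStack(
        dev=dev,
        subjects=[f"s{i}" for i in range(dev.shape[0])],
        site=site,
        freqs=np.arange(dev.shape[1]) + 4.0,
        times=np.arange(dev.shape[2]) * 20.0 + 10.0,
    )


# ---------------------------------------------------------------------------
# subject centering
# ---------------------------------------------------------------------------

class TestCenterBySubject:
    def test_identical_maps_give_zero(self):
        maps = {"s1": {a: roi_map([[1.0, 2.0]]) for a in ("A", "B", "C")}}
        stacks = center_by_subject(maps)
        for st in stacks.values():
            np.testing.assert_allclose(st.dev, 0.0, atol=1e-12)

    def test_two_site_closed_form(self):
        maps = {"s1": {"A": roi_map([[3.0]]), "B": roi_map([[1.0]])}}
        stacks = center_by_subject(maps)
        assert stacks["A"].dev[0, 0, 0] == pytest.approx(1.0)   # (a-b)/2
        assert stacks["B"].dev[0, 0, 0] == pytest.approx(-1.0)  # (b-a)/2

    def test_three_site_closed_form(self):
        maps = {"s1": {"A": roi_map([[3.0]]), "B": roi_map([[1.0]]),
                       "C": roi_map([[-1.0]])}}
        stacks = center_by_subject(maps)
        assert stacks["A"].dev[0, 0, 0] == pytest.approx(2.0)
        assert stacks["B"].dev[0, 0, 0] == pytest.approx(0.0)
        assert stacks["C"].dev[0, 0, 0] == pytest.approx(-2.0)

    def test_missing_site_lists_subjects(self):
        maps = {
            "s1": {"A": roi_map([[1.0]]), "B": roi_map([[1.0]])},
            "s2": {"A": roi_map([[1.0]])},
        }
        with pytest.raises(ValueError, match="s2"):
            center_by_subject(maps)

    def test_across_site_sum_is_zero(self, rng):
        maps = {
            f"s{i}": {a: roi_map(rng.standard_normal((4, 6)))
                      for a in ("A", "B", "C")}
            for i in range(5)
        }
        stacks = center_by_subject(maps)
        total = sum(st.dev for st in stacks.values())
        np.testing.assert_allclose(total, 0.0, atol=1e-12)


# ---------------------------------------------------------------------------
# sign-flip z-maps
# ---------------------------------------------------------------------------

class TestSignflipZmap:
    def test_exact_enumeration_frozen_value(self):
        # n = 3, deviations (1, 2, 3): the 8 sign patterns give permutation
        # mean 0 and population std sqrt(sum d^2 / 9) = sqrt(14)/3, so
        # z = 2 / (sqrt(14)/3) = 6 / sqrt(14)
        z = signflip_zmap_exact(stack_from([1.0, 2.0, 3.0]))
        assert z[0, 0] == pytest.approx(6.0 / np.sqrt(14.0), abs=1e-12)

    def test_zero_deviations_warn_and_zero(self):
        with pytest.warns(RuntimeWarning):
            z = signflip_zmap(stack_from(np.zeros(4)), n_perm=50, seed=0)
        assert np.all(z == 0.0)

    def test_monte_carlo_matches_enumeration(self, rng):
        # oracle equivalence within 3 standard errors, n <= 12
        dev = rng.standard_normal((10, 4, 5)) + 0.4
        st = stack_from(dev)
        z_exact = signflip_zmap_exact(st)
        n_perm = 5000
        z_mc = signflip_zmap(st, n_perm=n_perm, seed=7)
        se = np.sqrt((1.0 + z_exact**2 / 2.0) / n_perm)
        assert np.all(np.abs(z_mc - z_exact) <= 3.0 * se)

    def test_scale_equivariance(self, rng):
        dev = rng.standard_normal((6, 3, 4))
        z1 = signflip_zmap(stack_from(dev), n_perm=200, seed=3)
        z2 = signflip_zmap(stack_from(dev * 7.3), n_perm=200, seed=3)
        np.testing.assert_allclose(z1, z2, rtol=1e-10)

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError):
            signflip_zmap(stack_from([1.0]), n_perm=10, seed=0)


# ---------------------------------------------------------------------------
# cluster labeling and correction
# ---------------------------------------------------------------------------

def flood_fill_label(mask):
    """Brute-force 8-connected labeling (test oracle)."""
    mask = np.asarray(mask, bool)
    labels = np.zeros(mask.shape, int)
    sizes = {}
    next_id = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        next_id += 1
        frontier = [start]
        labels[start] = next_id
        count = 0
        while frontier:
            i, j = frontier.pop()
            count += 1
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    ni, nj = i + di, j + dj
                    if (0 <= ni < mask.shape[0] and 0 <= nj < mask.shape[1]
                            and mask[ni, nj] and not labels[ni, nj]):
                        labels[ni, nj] = next_id
                        frontier.append((ni, nj))
        sizes[next_id] = count
    return labels, sizes


class TestClusterLabeling:
    def test_matches_flood_fill_on_random_masks(self, rng):
        for _ in range(100):
            mask = rng.random((12, 15)) < 0.35
            labels, sizes = label_clusters(mask)
            ref_labels, ref_sizes = flood_fill_label(mask)
            # same partition: identical size multisets and co-labeling
            assert sorted(sizes.values()) == sorted(ref_sizes.values())
            assert np.array_equal(labels > 0, ref_labels > 0)
            # bins sharing a label in one labeling share it in the other
            for cid in sizes:
                ref_ids = np.unique(ref_labels[labels == cid])
                assert len(ref_ids) == 1

    def test_max_size_empty_mask(self):
        assert max_cluster_size(np.zeros((5, 5)), 1.96) == 0


class TestClusterCorrect:
    def test_subthreshold_map_has_no_clusters(self, rng):
        z = rng.uniform(-1.5, 1.5, (10, 10))
        res = cluster_correct(z, np.arange(100, dtype=float))
        assert res.cluster_sizes == {}
        assert res.significant == ()
        assert res.cluster_forming_threshold == pytest.approx(1.959964, abs=1e-5)

    def test_planted_cluster_survives(self):
        # a 30-bin blob of |z| = 3 against a null whose 97.5th pct is 6
        z = np.zeros((12, 15))
        z[3:8, 4:10] = 3.0
        assert z[3:8, 4:10].size == 30
        null = np.full(1000, 6.0)
        res = cluster_correct(z, null, obs_map=z * 0.2,
                              freqs=np.arange(12) + 4.0,
                              times=np.arange(15) * 20.0)
        assert res.size_threshold == pytest.approx(6.0)
        assert len(res.significant) == 1
        peak = res.peaks[0]
        assert peak["sign"] == "positive"
        assert peak["z"] == pytest.approx(3.0)
        assert peak["value_db"] == pytest.approx(0.6)

    def test_requires_permutations(self):
        with pytest.raises(ValueError):
            cluster_correct(np.zeros((3, 3)), np.array([]))


# ---------------------------------------------------------------------------
# composed within- and between-group tests
# ---------------------------------------------------------------------------

def three_site_maps(rng, n_subj, effects=(0.0, 0.0, 0.0), noise=1.0,
                    shape=(6, 8), group="HC", prefix="s"):
    maps = {}
    for i in range(n_subj):
        maps[f"{prefix}{i}"] = {
            site: roi_map(eff + noise * rng.standard_normal(shape), group=group)
            for site, eff in zip(("A", "B", "C"), effects)
        }
    return maps


class TestWithinGroupTest:
    def test_deterministic_given_seed(self, rng):
        maps = three_site_maps(rng, 8, effects=(1.0, 0.0, -1.0), noise=0.5)
        r1 = within_group_test(maps, n_perm=300, seed=42)
        r2 = within_group_test(maps, n_perm=300, seed=42)
        for site in r1:
            np.testing.assert_array_equal(r1[site].zmap, r2[site].zmap)
            np.testing.assert_array_equal(r1[site].null_max_sizes,
                                          r2[site].null_max_sizes)
            assert r1[site].significant == r2[site].significant

    def test_detects_planted_site_effect(self, rng):
        maps = three_site_maps(rng, 16, effects=(2.0, -1.0, -1.0), noise=0.8)
        res = within_group_test(maps, n_perm=500, seed=0)
        assert res["A"].n_significant >= 1
        assert res["A"].peaks[0]["sign"] == "positive"


class TestBetweenGroupTest:
    def test_identical_groups_null(self, rng):
        maps_a = three_site_maps(rng, 6, noise=1.0)
        # same subjects duplicated under new ids
        maps_b = {f"t{i}": v for i, (k, v) in enumerate(maps_a.items())}
        res = between_group_test(maps_a, maps_b, n_perm=400, seed=1)
        for r in res.values():
            # observed difference is exactly zero; the tiny residual z is
            # Monte-Carlo noise of the permutation mean, O(1/sqrt(n_perm))
            assert np.abs(r.zmap).max() < 4.0 / np.sqrt(400)
            assert r.n_significant == 0

    def test_exhaustive_split_oracle(self, rng):
        # 3 + 3 subjects: 20 distinct splits enumerated exactly; the
        # Monte-Carlo z must converge to the enumeration z within 3 SE,
        # with the SE from the delta method using the exact null's moments
        # (the 20-atom null is far from Gaussian)
        dev_a = rng.standard_normal((3, 2, 3)) + 1.0
        dev_b = rng.standard_normal((3, 2, 3))
        z_exact = between_group_zmap_exact(dev_a, dev_b)
        from math import comb

        from tmstheta.cluster import _group_diff_perms, _zmap_from_perms

        # exact null distribution per cell, for its higher moments
        flat = np.concatenate([dev_a, dev_b]).reshape(6, -1)
        exact_means = []
        idx_all = frozenset(range(6))
        for combo in itertools.combinations(range(6), 3):
            b = sorted(idx_all - set(combo))
            exact_means.append(flat[list(combo)].mean(0) - flat[b].mean(0))
        exact_means = np.array(exact_means)
        assert len(exact_means) == comb(6, 3) == 20
        mu = exact_means.mean(0)
        sig = exact_means.std(0)
        g1 = (((exact_means - mu) / sig) ** 3).mean(0)
        kap = (((exact_means - mu) / sig) ** 4).mean(0)

        rng2 = np.random.default_rng(5)
        n_perm = 20000
        pooled, perm_means = _group_diff_perms(dev_a, dev_b, n_perm, rng2)
        obs = pooled[:3].mean(axis=0) - pooled[3:].mean(axis=0)
        z_mc, _ = _zmap_from_perms(obs, perm_means)
        z_flat = z_exact.reshape(-1)
        var_z = (1.0 + z_flat**2 * (kap - 1.0) / 4.0 + z_flat * g1) / n_perm
        se = np.sqrt(np.maximum(var_z, 1e-12))
        assert np.all(np.abs(z_mc - z_flat) <= 3.0 * se)

    def test_small_group_rejected(self, rng):
        maps_a = three_site_maps(rng, 1)
        maps_b = three_site_maps(rng, 4, prefix="t")
        with pytest.raises(ValueError):
            between_group_test(maps_a, maps_b, n_perm=10, seed=0)
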