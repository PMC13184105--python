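"""Cluster-based permutation tests on time-frequency maps.

Within-group test: each subject's site map is centered against their own
across-site mean, the per-site deviation stack is tested against zero with a
sign-flip permutation null, and pointwise z-scores

    z(f, t) = (observed mean - mean of permuted means) / std of permuted means

are corrected for multiplicity by comparing suprathreshold 8-connected
cluster sizes to the permutation distribution of maximum cluster sizes
(97.5th-percentile cutoff).  The between-group test applies the same
machinery to the difference of group-mean deviation maps under a
label-shuffle null.

Exact enumeration variants (all 2**n sign patterns; all label splits) are
exposed for small n so Monte-Carlo results can be validated against them.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import norm


__all__ = [
    "DeviationStack",
    "ClusterTestResult",
    "center_by_subject",
    "signflip_zmap",
    "signflip_zmap_exact",
    "label_clusters",
    "max_cluster_size",
    "cluster_correct",
    "within_group_test",
    "between_group_test",
    "between_group_zmap_exact",
]

EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass
class DeviationStack:
    """Per-subject deviations of one site's ROI map from the subject mean.

    ``dev`` has shape ``(n_subjects, n_freqs, n_bins)`` in dB.
    """

    dev: np.ndarray
    subjects: tuple
    site: str
    freqs: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        self.dev = np.asarray(self.dev, dtype=float)
        self.subjects = tuple(self.subjects)
        if self.dev.ndim != 3 or self.dev.shape[0] != len(self.subjects):
            raise ValueError("dev must be (n_subjects, n_freqs, n_bins)")


@dataclass
class ClusterTestResult:
    """Outcome of one cluster-corrected permutation test."""

    site: str
    zmap: np.ndarray
    obs_map: np.ndarray           # observed mean deviation / difference map, dB
    freqs: np.ndarray
    times: np.ndarray
    cluster_forming_threshold: float
    labels: np.ndarray            # 0 = background
    cluster_sizes: dict           # cluster id -> size in bins
    null_max_sizes: np.ndarray    # one per permutation
    size_threshold: float         # percentile of null_max_sizes
    percentile: float
    significant: tuple            # cluster ids with size > size_threshold
    peaks: tuple                  # per significant cluster: dict
    n_perm: int
    seed: object = None

    @property
    def n_significant(self) -> int:
        return len(self.significant)

    def to_dict(self) -> dict:
        """JSON-serializable summary (cluster table, no dense maps)."""
        return {
            "site": self.site,
            "cluster_forming_threshold": float(self.cluster_forming_threshold),
            "size_threshold": float(self.size_threshold),
            "percentile": float(self.percentile),
            "n_perm": int(self.n_perm),
            "seed": self.seed,
            "clusters": [
                {
                    "id": int(cid),
                    "size": int(self.cluster_sizes[cid]),
                    "sign": p["sign"],
                    "peak_db": p["value_db"],
                    "peak_freq_hz": p["freq_hz"],
                    "peak_time_ms": p["time_ms"],
                    "peak_z": p["z"],
                    "peak_p": p["p"],
                }
                for cid, p in zip(self.significant, self.peaks)
            ],
        }


# ---------------------------------------------------------------------------
# subject centering
# ---------------------------------------------------------------------------

def center_by_subject(roi_maps: dict) -> dict:
    """Mean-center ROI maps per subject across stimulation sites.

    Parameters
    ----------
    roi_maps : mapping ``subject -> {site -> TFMap}``
        ROI-averaged (no channel axis) maps on a common grid.

    Returns
    -------
    dict ``site -> DeviationStack`` where
    ``dev(subject, site) = map(subject, site) - mean_site map(subject, .)``.
    """
    subjects = list(roi_maps)
    if not subjects:
        raise ValueError("no subjects")
    sites = list(roi_maps[subjects[0]])
    missing = [s for s in subjects if set(roi_maps[s]) != set(sites)]
    if missing:
        raise ValueError(f"subjects missing sites: {', '.join(map(str, missing))}")
    ref = roi_maps[subjects[0]][sites[0]]
    stacks = {}
    arr = np.stack(
        [[roi_maps[s][site].power for site in sites] for s in subjects]
    )  # (subj, site, f, t)
    dev = arr - arr.mean(axis=1, keepdims=True)
    for j, site in enumerate(sites):
        stacks[site] = DeviationStack(
            dev=dev[:, j], subjects=subjects, site=site,
            freqs=ref.freqs.copy(), times=ref.times.copy(),
        )
    return stacks


# ---------------------------------------------------------------------------
# sign-flip permutation z-maps
# ---------------------------------------------------------------------------

def _zmap_from_perms(obs: np.ndarray, perm_means: np.ndarray, ddof: int = 1):
    """Normalize observed map by the permutation distribution.

    Returns the z-map and the z-scored permutation maps (same normalization).
    Cells with zero permutation std yield z = 0 with a warning.  Monte-Carlo
    callers use the n-1 variance estimator; exhaustive enumerations pass
    ``ddof=0`` because they hold the complete null population.
    """
    mu = perm_means.mean(axis=0)
    sd = perm_means.std(axis=0, ddof=ddof)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            "zero permutation std in some cells; their z is set to 0",
            RuntimeWarning,
            stacklevel=3,
        )
    sd_safe = np.where(zero, 1.0, sd)
    z = np.where(zero, 0.0, (obs - mu) / sd_safe)
    z_perm = np.where(zero, 0.0, (perm_means - mu) / sd_safe)
    return z, z_perm


def signflip_zmap(
    stack: DeviationStack,
    n_perm: int = 5000,
    seed=None,
    return_perms: bool = False,
):
    """Sign-flip permutation z-map for one site's deviation stack.

    Each permutation multiplies every subject's whole deviation map by an
    independent random sign and records the across-subject mean map.  The
    permutation std uses the n-1 denominator.
    """
    n = stack.dev.shape[0]
    if n < 2:
        raise ValueError("sign-flip test requires at least 2 subjects")
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    flat = stack.dev.reshape(n, -1)
    signs = rng.integers(0, 2, size=(n_perm, n)) * 2 - 1
    perm_means = (signs @ flat) / n
    obs = flat.mean(axis=0)
    z, z_perm = _zmap_from_perms(obs, perm_means)
    shape = stack.dev.shape[1:]
    if return_perms:
        return z.reshape(shape), z_perm.reshape((n_perm,) + shape)
    return z.reshape(shape)


def signflip_zmap_exact(stack: DeviationStack, return_perms: bool = False):
    """Exhaustive sign-flip z-map over all 2**n sign patterns (n <= 16)."""
    n = stack.dev.shape[0]
    if n < 2:
        raise ValueError("sign-flip test requires at least 2 subjects")
    if n > 16:
        raise ValueError("exact enumeration limited to n <= 16 subjects")
    flat = stack.dev.reshape(n, -1)
    signs = np.array(list(itertools.product((1, -1), repeat=n)), dtype=float)
    perm_means = (signs @ flat) / n
    obs = flat.mean(axis=0)
    z, z_perm = _zmap_from_perms(obs, perm_means, ddof=0)
    shape = stack.dev.shape[1:]
    if return_perms:
        return z.reshape(shape), z_perm.reshape((len(signs),) + shape)
    return z.reshape(shape)


# ---------------------------------------------------------------------------
# cluster identification and correction
# ---------------------------------------------------------------------------

def label_clusters(mask: np.ndarray):
    """8-connected components of a 2-D boolean mask.

    Returns ``(labels, sizes)`` with background labeled 0 and
    ``sizes[cid]`` the number of bins in cluster ``cid``.
    """
    labels, n = ndimage.label(mask, structure=EIGHT_CONN)
    sizes = {
        cid: int(cnt)
        for cid, cnt in zip(*np.unique(labels[labels > 0], return_counts=True))
    }
    return labels, sizes


def max_cluster_size(zmap: np.ndarray, threshold: float) -> int:
    """Largest 8-connected cluster with ``|z| >= threshold`` (0 if none)."""
    _, sizes = label_clusters(np.abs(zmap) >= threshold)
    return max(sizes.values(), default=0)


def cluster_correct(
    zmap: np.ndarray,
    null_builder,
    alpha_cf: float = 0.05,
    percentile: float = 97.5,
    obs_map: np.ndarray | None = None,
    freqs: np.ndarray | None = None,
    times: np.ndarray | None = None,
    site: str = "",
    n_perm: int | None = None,
    seed=None,
) -> ClusterTestResult:
    """Cluster-size correction against a max-cluster-size null.

    Parameters
    ----------
    zmap : ndarray (n_freqs, n_bins)
        Observed z-map.
    null_builder : callable or array
        Either the per-permutation maximum cluster sizes directly, or a
        callable ``f(threshold) -> array`` that computes one max cluster
        size per permutation by applying the identical thresholding and
        labeling to each permuted z-map.
    alpha_cf : float
        Two-sided cluster-forming level; the mask is
        ``|z| >= norm.ppf(1 - alpha_cf / 2)`` (1.96 at the default).
    percentile : float
        Percentile of the null max sizes; clusters at or below it are removed.
    """
    zmap = np.asarray(zmap, dtype=float)
    if not np.all(np.isfinite(zmap)):
        raise ValueError("z-map must be finite")
    thr = float(norm.ppf(1.0 - alpha_cf / 2.0))
    null_max = null_builder(thr) if callable(null_builder) else np.asarray(null_builder)
    null_max = np.asarray(null_max, dtype=float)
    if null_max.size == 0:
        raise ValueError("null distribution has no permutations")

    labels, sizes = label_clusters(np.abs(zmap) >= thr)
    size_thr = float(np.percentile(null_max, percentile))
    significant = tuple(cid for cid, sz in sizes.items() if sz > size_thr)

    if obs_map is None:
        obs_map = np.full_like(zmap, np.nan)
    if freqs is None:
        freqs = np.arange(zmap.shape[0], dtype=float)
    if times is None:
        times = np.arange(zmap.shape[1], dtype=float)

    peaks = []
    for cid in significant:
        inside = labels == cid
        masked = np.where(inside, np.abs(zmap), -np.inf)
        fi, ti = np.unravel_index(int(np.argmax(masked)), zmap.shape)
        zpk = float(zmap[fi, ti])
        peaks.append(
            {
                "sign": "positive" if zpk > 0 else "negative",
                "value_db": float(obs_map[fi, ti]),
                "freq_hz": float(freqs[fi]),
                "time_ms": float(times[ti]),
                "z": zpk,
                "p": float(2.0 * norm.sf(abs(zpk))),
            }
        )

    return ClusterTestResult(
        site=site,
        zmap=zmap,
        obs_map=np.asarray(obs_map, dtype=float),
        freqs=np.asarray(freqs, dtype=float),
        times=np.asarray(times, dtype=float),
        cluster_forming_threshold=thr,
        labels=labels,
        cluster_sizes=sizes,
        null_max_sizes=null_max,
        size_threshold=size_thr,
        percentile=percentile,
        significant=significant,
        peaks=tuple(peaks),
        n_perm=int(n_perm if n_perm is not None else len(null_max)),
        seed=seed,
    )


def _null_max_sizes(z_perm: np.ndarray, threshold: float) -> np.ndarray:
    """Max cluster size of each permuted z-map at the given threshold."""
    return np.array([max_cluster_size(zp, threshold) for zp in z_perm], dtype=float)


# ---------------------------------------------------------------------------
# composed tests
# ---------------------------------------------------------------------------

def within_group_test(
    roi_maps: dict,
    n_perm: int = 5000,
    seed=None,
    alpha_cf: float = 0.05,
    percentile: float = 97.5,
) -> dict:
    """Within-group site-differentiation test, per stimulation site.

    Composition of :func:`center_by_subject`, :func:`signflip_zmap` and
    :func:`cluster_correct`; the max-cluster-size null is built from the
    same sign-flip permutations that produce the z-map.  Sites are tested
    independently (independent RNG streams derived from ``seed``).
    """
    stacks = center_by_subject(roi_maps)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(stacks))
    results = {}
    for child, (site, stack) in zip(children, stacks.items()):
        z, z_perm = signflip_zmap(stack, n_perm=n_perm, seed=child, return_perms=True)
        results[site] = cluster_correct(
            z,
            lambda thr, zp=z_perm: _null_max_sizes(zp, thr),
            alpha_cf=alpha_cf,
            percentile=percentile,
            obs_map=stack.dev.mean(axis=0),
            freqs=stack.freqs,
            times=stack.times,
            site=site,
            n_perm=n_perm,
            seed=seed,
        )
    return results


def _group_diff_perms(dev_a, dev_b, n_perm, rng):
    """Label-shuffle null for the difference of group-mean deviation maps."""
    n_a = dev_a.shape[0]
    pooled = np.concatenate([dev_a, dev_b], axis=0).reshape(n_a + dev_b.shape[0], -1)
    n = pooled.shape[0]
    perm_means = np.empty((n_perm, pooled.shape[1]))
    for i in range(n_perm):
        idx = rng.permutation(n)
        perm_means[i] = pooled[idx[:n_a]].mean(axis=0) - pooled[idx[n_a:]].mean(axis=0)
    return pooled, perm_means


def between_group_test(
    roi_maps_a: dict,
    roi_maps_b: dict,
    n_perm: int = 5000,
    seed=None,
    alpha_cf: float = 0.05,
    percentile: float = 97.5,
) -> dict:
    """Between-group test on subject-centered deviation maps, per site.

    The observed statistic is the group-A minus group-B mean deviation map;
    the null reassigns subjects to groups uniformly at random preserving
    group sizes, with the identical z-scoring and cluster correction.
    """
    if len(roi_maps_a) < 2 or len(roi_maps_b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    stacks_a = center_by_subject(roi_maps_a)
    stacks_b = center_by_subject(roi_maps_b)
    if set(stacks_a) != set(stacks_b):
        raise ValueError("groups have different stimulation sites")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(stacks_a))
    results = {}
    for child, site in zip(children, stacks_a):
        sa, sb = stacks_a[site], stacks_b[site]
        rng = np.random.default_rng(child)
        pooled, perm_means = _group_diff_perms(sa.dev, sb.dev, n_perm, rng)
        n_a = sa.dev.shape[0]
        obs = pooled[:n_a].mean(axis=0) - pooled[n_a:].mean(axis=0)
        z, z_perm = _zmap_from_perms(obs, perm_means)
        shape = sa.dev.shape[1:]
        z = z.reshape(shape)
        z_perm = z_perm.reshape((n_perm,) + shape)
        results[site] = cluster_correct(
            z,
            lambda thr, zp=z_perm: _null_max_sizes(zp, thr),
            alpha_cf=alpha_cf,
            percentile=percentile,
            obs_map=obs.reshape(shape),
            freqs=sa.freqs,
            times=sa.times,
            site=site,
            n_perm=n_perm,
            seed=seed,
        )
    return results


def between_group_zmap_exact(dev_a: np.ndarray, dev_b: np.ndarray):
    """Exhaustive label-shuffle z-map over all group splits (small n only).

    Enumerates every assignment of the pooled subjects into groups of the
    original sizes and z-scores the observed mean difference against that
    full null.
    """
    n_a, n_b = dev_a.shape[0], dev_b.shape[0]
    pooled = np.concatenate([dev_a, dev_b], axis=0)
    n = n_a + n_b
    from math import comb

    if comb(n, n_a) > 200_000:
        raise ValueError("too many splits for exact enumeration")
    flat = pooled.reshape(n, -1)
    perm_means = []
    idx_all = frozenset(range(n))
    for combo in itertools.combinations(range(n), n_a):
        a = list(combo)
        b = sorted(idx_all - set(combo))
        perm_means.append(flat[a].mean(axis=0) - flat[b].mean(axis=0))
    perm_means = np.array(perm_means)
    obs = flat[:n_a].mean(axis=0) - flat[n_a:].mean(axis=0)
    z, _ = _zmap_from_perms(obs, perm_means, ddof=0)
    return z.reshape(dev_a.shape[1:])
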