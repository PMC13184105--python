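"""Desk-scale simulation experiments: calibration, power, and recovery.

These are the study conditions the package validates itself under: reduced
cohorts (500 Hz sampling, 20 epochs per site, the six fronto-central
electrodes, a 15-frequency grid, the 0-400 ms post-stimulus window in 20-ms
bins, 500 permutations) keep each experiment within minutes on one CPU while
preserving the full analysis chain end to end.
"""

from __future__ import annotations


import pandas as pd
from scipy import stats

from . import assoc, bands, cluster
from .cohort import CohortSpec, iter_epoch_sets, _draw_truth
from .timefreq import (
    bandpass,
    bin_time,
    db_normalize,
    interpolate_pulse_window,
    make_freq_grid,
    morlet_tfr,
)

__all__ = [
    "reduced_spec",
    "roi_theta_maps",
    "null_fwer",
    "pattern_recovery",
    "theta_recovery",
    "lmm_coverage",
]

REDUCED = {
    "sampling_rate": 500.0,
    "epochs_per_site": 20,
    "channels": bands.THETA_ELECTRODES,
}
REDUCED_N_FREQS = 15
REDUCED_WINDOW = (0.0, 400.0)


def reduced_spec(n_hc: int = 20, n_chr: int = 1, seed: int = 0,
                 **overrides) -> CohortSpec:
    """A cohort spec at the reduced desk-scale study conditions."""
    kwargs = dict(REDUCED)
    kwargs.update(n_hc=n_hc, n_chr=n_chr, seed=seed)
    kwargs.update(overrides)
    return CohortSpec(**kwargs)


def _zero_amps():
    from .cohort import DEFAULT_SITES, GROUPS

    return {g: {s: 0.0 for s in DEFAULT_SITES} for g in GROUPS}


def roi_theta_maps(
    spec: CohortSpec,
    subjects=None,
    n_freqs: int = REDUCED_N_FREQS,
    window=REDUCED_WINDOW,
    electrodes=None,
) -> dict:
    """Run the preprocessing/TFR/ROI chain, streaming one EpochSet at a time.

    Returns ``subject -> site -> TFMap`` of ROI-averaged, dB-scaled,
    20-ms-binned maps cropped to the test window.
    """
    grid = make_freq_grid(n=n_freqs)
    electrodes = bands.theta_electrodes() if electrodes is None else electrodes
    out: dict = {}
    for es in iter_epoch_sets(spec, subjects=subjects):
        es = interpolate_pulse_window(es)
        es = bandpass(es)
        tf = bin_time(db_normalize(morlet_tfr(es, grid)), 20.0)
        roi = bands.roi_average(tf, electrodes).crop(*window)
        out.setdefault(es.subject, {})[es.site] = roi
    return out


# ---------------------------------------------------------------------------
# family-wise error calibration under the exchangeable null
# ---------------------------------------------------------------------------

def null_fwer(
    n_cohorts: int = 200,
    n_subjects: int = 20,
    n_perm: int = 500,
    seed: int = 1,
    progress=None,
) -> dict:
    """Per-site false-positive rate of the within-group test on null cohorts.

    Each cohort contains noise-only epochs (all burst and ERP amplitudes
    zero), so the generative distribution is exchangeable across sites and
    the cluster-corrected test should report a significant cluster in at
    most ~5% of (cohort, site) analyses.  Cohort seeds are ``seed, seed+1,
    ..., seed+n_cohorts-1``.  Null cohorts use 10 epochs per site: the
    false-positive rate of the permutation test is pivotal in the epoch
    count, which only rescales the per-bin noise.
    """
    n_sig = 0
    n_tests = 0
    for i in range(n_cohorts):
        spec = reduced_spec(
            n_hc=n_subjects, n_chr=1, seed=int(seed) + i,
            theta_amp_db=_zero_amps(), gamma_amp_db=_zero_amps(), erp_amp=0.0,
            epochs_per_site=10,
        )
        hc = [s for s in spec.subjects if s.startswith("HC")]
        maps = roi_theta_maps(spec, subjects=hc)
        results = cluster.within_group_test(maps, n_perm=n_perm, seed=int(seed) + i)
        for site, res in results.items():
            n_tests += 1
            n_sig += int(res.n_significant > 0)
        if progress is not None:
            progress(i + 1, n_cohorts)
    return {"rate": n_sig / n_tests, "n_significant": n_sig, "n_tests": n_tests}


# ---------------------------------------------------------------------------
# qualitative pattern recovery at default effect sizes
# ---------------------------------------------------------------------------

def _sig_cluster_with_sign(res, sign: str, band=None) -> bool:
    """True if a significant cluster has the given peak sign and overlaps the band.

    A short Gaussian burst spreads spectrally well beyond its carrier, so
    clusters are scored by overlap with the band's frequency x time window
    rather than by peak location.
    """
    for cid, peak in zip(res.significant, res.peaks):
        if peak["sign"] != sign:
            continue
        if band is not None:
            fm = bands.freq_mask(res.freqs, band)
            tm = bands.time_mask(res.times, band)
            inside = (res.labels == cid) & fm[:, None] & tm[None, :]
            if not inside.any():
                continue
        return True
    return False


def pattern_recovery(
    n_reps: int = 25,
    n_per_group: int = 20,
    n_perm: int = 500,
    seed: int = 1,
    progress=None,
) -> dict:
    """Rates of recovering the expected group-level pattern.

    Per replicate: one cohort with the default effect maps (HC site-
    differentiated theta, CHR flattened).  Scores whether (a) the HC
    within-group test finds a theta-window cluster at every site with the
    injected sign (positive lDLPFC, negative lPPC and DMPFC), (b) the CHR
    test finds no cluster at any site, and (c) the between-group test flags
    lDLPFC.
    """
    theta = bands.default_bands()["theta"]
    ok_hc = ok_chr = ok_between = 0
    for i in range(n_reps):
        spec = reduced_spec(n_hc=n_per_group, n_chr=n_per_group, seed=int(seed) + i)
        maps = roi_theta_maps(spec)
        hc = {s: m for s, m in maps.items() if s.startswith("HC")}
        chr_ = {s: m for s, m in maps.items() if s.startswith("CHR")}

        res_hc = cluster.within_group_test(hc, n_perm=n_perm, seed=int(seed) + i)
        expected = {"lDLPFC": "positive", "lPPC": "negative", "DMPFC": "negative"}
        ok_hc += int(all(
            _sig_cluster_with_sign(res_hc[site], sign, theta)
            for site, sign in expected.items()
        ))

        res_chr = cluster.within_group_test(chr_, n_perm=n_perm, seed=int(seed) + i)
        ok_chr += int(all(r.n_significant == 0 for r in res_chr.values()))

        res_bw = cluster.between_group_test(hc, chr_, n_perm=n_perm,
                                            seed=int(seed) + i)
        ok_between += int(res_bw["lDLPFC"].n_significant > 0)
        if progress is not None:
            progress(i + 1, n_reps)
    return {
        "hc_all_sites_rate": ok_hc / n_reps,
        "chr_none_rate": ok_chr / n_reps,
        "between_ldlpfc_rate": ok_between / n_reps,
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# dB recovery against generator ground truth
# ---------------------------------------------------------------------------

def theta_recovery(n_subjects: int = 20, seed: int = 1,
                   theta_db: float = 3.0, epochs_per_site: int = 20) -> pd.DataFrame:
    """Pipeline-extracted theta ROI power vs the generator's stored targets.

    Injects ``theta_db`` at every cell so each subject x site estimate can
    be compared with its stored per-subject dB target.  ERP and gamma
    amplitudes are zeroed: the calibration defines the theta target as the
    burst's elevation over the noise floor, so phase-locked components
    would otherwise confound the comparison.
    """
    from .cohort import DEFAULT_SITES, GROUPS

    amps = {g: {s: theta_db for s in DEFAULT_SITES} for g in GROUPS}
    spec = reduced_spec(n_hc=n_subjects, n_chr=1, seed=seed, theta_amp_db=amps,
                        gamma_amp_db=_zero_amps(), erp_amp=0.0,
                        epochs_per_site=epochs_per_site)
    hc = [s for s in spec.subjects if s.startswith("HC")]
    truth, _ = _draw_truth(spec)
    maps = roi_theta_maps(spec, subjects=hc, window=(0.0, 420.0))
    theta = bands.default_bands()["theta"]
    rows = []
    t = truth.set_index(["subject", "site"])
    for subj, by_site in maps.items():
        for site, tf in by_site.items():
            est = bands.band_mean(tf, theta)
            rows.append({
                "subject": subj, "site": site,
                "estimated_db": est,
                "target_db": float(t.loc[(subj, site), "theta_db_target"]),
                "amp": float(t.loc[(subj, site), "theta_amp"]),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mixed-model parameter recovery
# ---------------------------------------------------------------------------

def lmm_coverage(
    n_reps: int = 100,
    n_per_group: int = 50,
    beta_site: float = -1.0,
    beta_interaction: float = 0.8,
    subject_sd: float = 0.5,
    resid_sd: float = 0.5,
    seed: int = 1,
) -> dict:
    """95%-CI coverage of known site and group x site effects.

    Tables are drawn directly from the generating mixed model (both
    non-reference sites get the same true effects) and refit; coverage is
    the fraction of replicates whose CI contains the truth, per term.
    """
    from .cohort import simulate_band_power_table

    hits = {"site": 0, "interaction": 0}
    for i in range(n_reps):
        tab = simulate_band_power_table(
            n_per_group=n_per_group,
            beta_site={"lPPC": beta_site, "DMPFC": beta_site},
            beta_interaction={"lPPC": beta_interaction, "DMPFC": beta_interaction},
            subject_sd=subject_sd,
            resid_sd=resid_sd,
            seed=int(seed) + i,
        )
        summ = assoc.fit_group_site_lmm(tab)
        crit = stats.t.ppf(0.975, summ.coefficients["df"].iloc[0])
        lppc = [t for t in summ.coefficients.index if "[T.lPPC]" in t]
        terms = {
            "site": next(t for t in lppc if ":" not in t),
            "interaction": next(t for t in lppc if ":" in t),
        }
        for kind, truth_val in (("site", beta_site),
                                ("interaction", beta_interaction)):
            est = summ.coefficients.loc[terms[kind], "estimate"]
            se = summ.coefficients.loc[terms[kind], "se"]
            if abs(est - truth_val) <= crit * se:
                hits[kind] += 1
    return {
        "site_coverage": hits["site"] / n_reps,
        "interaction_coverage": hits["interaction"] / n_reps,
        "n_reps": n_reps,
    }
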