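"""End-to-end orchestration: simulate -> TFR -> ROI -> tests -> statistics.

A :class:`PipelineConfig` (loadable from flat YAML) fully determines one
run; every random stage is seeded from the single config seed, so reruns
with the same config produce bit-identical machine-readable outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import assoc, bands, cluster, io
from .cohort import CohortSpec, simulate_cohort
from .timefreq import (
    bandpass,
    bin_time,
    db_normalize,
    interpolate_pulse_window,
    make_freq_grid,
    morlet_tfr,
)

logger = logging.getLogger("tmstheta")

__all__ = ["PipelineConfig", "run_pipeline", "report", "preprocess_and_tfr",
           "roi_maps_from_tfr"]


@dataclass
class PipelineConfig:
    """Flat, human-editable configuration of one pipeline run."""

    out_dir: str = "tmstheta_run"
    # cohort: kwargs forwarded to CohortSpec (seed comes from `seed` below)
    cohort: dict = field(default_factory=dict)
    input_epochs: str | None = None     # existing HDF5 container instead of simulating
    # preprocessing / decomposition
    interp_window_ms: tuple = (-1.0, 15.0)
    band_lo_hz: float = 3.0
    band_hi_hz: float = 100.0
    n_freqs: int = 30
    baseline_ms: tuple = (-400.0, -200.0)
    bin_ms: float = 20.0
    test_window_ms: tuple = (0.0, 500.0)
    # permutation settings
    n_perm: int = 5000
    alpha_cf: float = 0.05
    percentile: float = 97.5
    # statistics settings
    fdr_family: str = "band"
    seed: int = 0

    def __post_init__(self):
        if self.n_perm < 1:
            raise ValueError("n_perm must be positive")
        if not 0 < self.alpha_cf < 1:
            raise ValueError("alpha_cf must be in (0, 1)")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must be in (0, 100)")
        if self.fdr_family not in ("band", "band_site", "global"):
            raise ValueError("fdr_family must be 'band', 'band_site' or 'global'")
        if self.input_epochs is not None and not Path(self.input_epochs).exists():
            raise ValueError(f"input_epochs path does not exist: {self.input_epochs}")
        for name in ("interp_window_ms", "baseline_ms", "test_window_ms"):
            pair = tuple(float(x) for x in getattr(self, name))
            if len(pair) != 2 or pair[0] >= pair[1]:
                raise ValueError(f"{name} must be an increasing (lo, hi) pair")
            setattr(self, name, pair)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def cohort_spec(self) -> CohortSpec:
        kwargs = dict(self.cohort)
        kwargs.setdefault("seed", self.seed)
        return CohortSpec(**kwargs)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def preprocess_and_tfr(epoch_sets: dict, config: PipelineConfig) -> dict:
    """Interpolate, filter, decompose, dB-normalize, and bin every EpochSet.

    Returns channel-resolved, dB-scaled, time-binned maps per subject/site.
    """
    grid = make_freq_grid(n=config.n_freqs)
    out: dict = {}
    for subject, by_site in epoch_sets.items():
        for site, es in by_site.items():
            es = interpolate_pulse_window(es, *config.interp_window_ms)
            es = bandpass(es, config.band_lo_hz, config.band_hi_hz)
            tf = morlet_tfr(es, grid)
            tf = db_normalize(tf, config.baseline_ms)
            tf = bin_time(tf, config.bin_ms)
            out.setdefault(subject, {})[site] = tf
    return out


def roi_maps_from_tfr(tf_maps: dict, electrodes, window_ms: tuple) -> dict:
    """ROI-average and crop the binned maps for permutation testing."""
    out: dict = {}
    for subject, by_site in tf_maps.items():
        for site, tf in by_site.items():
            roi = bands.roi_average(tf, electrodes)
            out.setdefault(subject, {})[site] = roi.crop(*window_ms)
    return out


def _split_by_group(maps: dict) -> dict:
    groups: dict = {}
    for subject, by_site in maps.items():
        g = next(iter(by_site.values())).group
        groups.setdefault(g, {})[subject] = by_site
    return groups


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write machine-readable outputs.

    Writes the epoch container, TF maps, cluster-test JSON, the band-power
    table, mixed-model summaries, the correlation table, and a manifest
    with config hash, package version, and per-file checksums.  Any stage
    failure aborts with the stage name; outputs written so far remain on
    disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "stages": [],
        "outputs": {},
    }
    stage = "simulate"
    try:
        t0 = time.time()
        if config.input_epochs is not None:
            epoch_sets = io.load_epoch_sets(config.input_epochs)
            clinical = None
        else:
            cohort = simulate_cohort(config.cohort_spec())
            epoch_sets = cohort.epochs
            clinical = cohort.clinical
            io.save_epoch_sets(epoch_sets, out / "epochs.h5")
            io.write_table(cohort.clinical, out / "clinical.csv")
            io.write_table(cohort.truth, out / "truth.csv")
        manifest["stages"].append({"name": stage, "seconds": round(time.time() - t0, 2)})

        stage = "tfr"
        t0 = time.time()
        tf_maps = preprocess_and_tfr(epoch_sets, config)
        io.save_tf_maps(tf_maps, out / "tfr.h5")
        manifest["stages"].append({"name": stage, "seconds": round(time.time() - t0, 2)})

        stage = "cluster_tests"
        t0 = time.time()
        theta_roi = roi_maps_from_tfr(tf_maps, bands.theta_electrodes(),
                                      config.test_window_ms)
        by_group = _split_by_group(theta_roi)
        cluster_out: dict = {"within": {}, "between": {}}
        for g, maps in sorted(by_group.items()):
            res = cluster.within_group_test(
                maps, n_perm=config.n_perm, seed=config.seed,
                alpha_cf=config.alpha_cf, percentile=config.percentile,
            )
            cluster_out["within"][g] = {s: r.to_dict() for s, r in res.items()}
        if len(by_group) == 2:
            ga, gb = sorted(by_group)  # CHR, HC -> report HC minus CHR
            res = cluster.between_group_test(
                by_group[gb], by_group[ga], n_perm=config.n_perm,
                seed=config.seed, alpha_cf=config.alpha_cf,
                percentile=config.percentile,
            )
            cluster_out["between"][f"{gb}-{ga}"] = {
                s: r.to_dict() for s, r in res.items()
            }
        io.write_json(cluster_out, out / "clusters.json")
        manifest["stages"].append({"name": stage, "seconds": round(time.time() - t0, 2)})

        stage = "stats"
        t0 = time.time()
        band_defs = bands.default_bands()
        theta_tab = assoc.extract_band_power(
            tf_maps, band_defs["theta"], bands.theta_electrodes(), clinical
        )
        # per-site gamma electrode: peak of the site's grand-average map
        gamma_elec = {}
        sites = {s for by_site in tf_maps.values() for s in by_site}
        for site in sites:
            site_maps = [by_site[site] for by_site in tf_maps.values() if site in by_site]
            avg = dataclasses.replace(
                site_maps[0],
                power=np.mean([m.power for m in site_maps], axis=0),
            )
            gamma_elec[site] = bands.select_gamma_electrode(avg, band_defs["gamma"])
        gamma_tab = assoc.extract_band_power(
            tf_maps, band_defs["gamma"], gamma_elec, clinical
        )
        table = pd.concat([theta_tab, gamma_tab], ignore_index=True)
        io.write_table(table, out / "band_power.csv")

        stats_out: dict = {"gamma_electrodes": gamma_elec, "lmm": {}}
        if clinical is not None:
            for band in ("theta", "gamma"):
                try:
                    summ = assoc.fit_group_site_lmm(table, band=band)
                    stats_out["lmm"][band] = {
                        "coefficients": summ.coefficients.reset_index().to_dict("records"),
                        "conditional_r2": summ.conditional_r2,
                        "subject_var": summ.subject_var,
                        "resid_var": summ.resid_var,
                        "converged": summ.converged,
                        "singular": summ.singular,
                        "df_method": summ.df_method,
                    }
                except ValueError as e:
                    stats_out["lmm"][band] = {"error": str(e)}
            items = [c for c in ("P1", "P2", "P3", "P4", "P5", "N1", "N2", "N3",
                                 "N4", "N5", "N6", "COPER", "COGDIS", "SOFAS",
                                 "AVLT_first", "AVLT_total", "AVLT_delay", "DSST")
                     if c in table.columns]
            corr = assoc.spearman_fdr(table, items, family=config.fdr_family)
            io.write_table(corr, out / "correlations.csv")
        io.write_json(stats_out, out / "stats.json")
        manifest["stages"].append({"name": stage, "seconds": round(time.time() - t0, 2)})
    except Exception as e:
        (out / "error.log").write_text(f"stage {stage} failed: {e}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    io.write_json(manifest, out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def report(run_dir) -> list:
    """Render TF-map and z-map figures plus a cluster summary for one run.

    Returns the list of files written.  Images are PNG (lossless) with the
    package version embedded in their metadata.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run = Path(run_dir)
    manifest_path = run / "manifest.json"
    clusters_path = run / "clusters.json"
    tfr_path = run / "tfr.h5"
    missing = [p.name for p in (manifest_path, clusters_path, tfr_path) if not p.exists()]
    if missing:
        raise FileNotFoundError(f"run is missing artifact(s): {', '.join(missing)}")
    manifest = json.loads(manifest_path.read_text())
    clusters = json.loads(clusters_path.read_text())
    config = PipelineConfig.from_dict(manifest["config"])
    tf_maps = io.load_tf_maps(tfr_path)
    theta_roi = roi_maps_from_tfr(tf_maps, bands.theta_electrodes(),
                                  config.test_window_ms)
    by_group = _split_by_group(theta_roi)
    meta = {"Software": f"tmstheta {manifest['version']}"}
    written = []

    sites = sorted({s for by_site in theta_roi.values() for s in by_site})
    groups = sorted(by_group)
    fig, axes = plt.subplots(len(groups), len(sites),
                             figsize=(4 * len(sites), 3 * len(groups)),
                             squeeze=False)
    for gi, g in enumerate(groups):
        for si, site in enumerate(sites):
            maps = [by_site[site] for by_site in by_group[g].values()]
            mean_map = np.mean([m.power for m in maps], axis=0)
            ref = maps[0]
            ax = axes[gi][si]
            im = ax.pcolormesh(ref.times, ref.freqs, mean_map, shading="auto",
                               cmap="RdBu_r")
            ax.set_yscale("log")
            ax.set_title(f"{g} {site}")
            ax.set_xlabel("time (ms)")
            ax.set_ylabel("frequency (Hz)")
            fig.colorbar(im, ax=ax, label="dB")
    fig.tight_layout()
    p = run / "tf_maps.png"
    fig.savefig(p, dpi=120, metadata=meta)
    plt.close(fig)
    written.append(p)

    # z-maps with significant-cluster outlines
    for g, site_results in clusters.get("within", {}).items():
        fig, axes = plt.subplots(1, len(site_results),
                                 figsize=(4 * len(site_results), 3), squeeze=False)
        for si, (site, res) in enumerate(sorted(site_results.items())):
            ax = axes[0][si]
            maps = [by_site[site] for by_site in by_group[g].values()]
            stack = cluster.center_by_subject(by_group[g])[site]
            z = cluster.signflip_zmap(stack, n_perm=min(config.n_perm, 500),
                                      seed=config.seed)
            im = ax.pcolormesh(stack.times, stack.freqs, z, shading="auto",
                               cmap="RdBu_r", vmin=-5, vmax=5)
            for c in res["clusters"]:
                ax.plot(c["peak_time_ms"], c["peak_freq_hz"], "k*", markersize=10)
            ax.set_yscale("log")
            ax.set_title(f"{g} {site} ({len(res['clusters'])} sig. clusters)")
            fig.colorbar(im, ax=ax, label="z")
        fig.tight_layout()
        p = run / f"zmaps_{g}.png"
        fig.savefig(p, dpi=120, metadata=meta)
        plt.close(fig)
        written.append(p)

    lines = ["cluster summary", "==============="]
    for scope, groups_d in clusters.items():
        for g, site_results in groups_d.items():
            for site, res in sorted(site_results.items()):
                for c in res["clusters"]:
                    lines.append(
                        f"{scope} {g} {site}: {c['sign']} cluster, size {c['size']}, "
                        f"peak {c['peak_db']:.2f} dB at {c['peak_freq_hz']:.2f} Hz / "
                        f"{c['peak_time_ms']:.0f} ms (z = {c['peak_z']:.2f}, "
                        f"p = {c['peak_p']:.4g})"
                    )
                if not res["clusters"]:
                    lines.append(f"{scope} {g} {site}: no significant clusters")
    p = run / "summary.txt"
    p.write_text("\n".join(lines) + "\n")
    written.append(p)
    return written
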