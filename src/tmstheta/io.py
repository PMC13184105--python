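"""File formats: HDF5 epoch/TF containers, CSV tables, BrainVision reading.

Epoch container layout::

    /epochs/<subject>/<site>   dataset (epoch, channel, sample), float32
        attrs: sampling_rate, channels, tmin_ms, group

TF maps are stored analogously under ``/tfr`` with freqs/times/scale
attributes.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .timefreq import EpochSet, TFMap

__all__ = [
    "save_epoch_sets",
    "load_epoch_sets",
    "save_tf_maps",
    "load_tf_maps",
    "read_brainvision_epochs",
]


def save_epoch_sets(epoch_sets, path) -> None:
    """Write EpochSets (iterable or nested subject->site dict) to HDF5."""
    if isinstance(epoch_sets, dict):
        epoch_sets = [es for by_site in epoch_sets.values() for es in by_site.values()]
    with h5py.File(path, "w") as f:
        root = f.create_group("epochs")
        for es in epoch_sets:
            g = root.require_group(es.subject).create_group(es.site)
            d = g.create_dataset("data", data=es.data.astype(np.float32), track_times=False)
            d.attrs["sampling_rate"] = es.sfreq
            d.attrs["channels"] = list(es.channels)
            d.attrs["tmin_ms"] = float(es.times[0])
            d.attrs["group"] = es.group


def load_epoch_sets(path) -> dict:
    """Read the HDF5 epoch container into ``subject -> site -> EpochSet``."""
    out: dict = {}
    with h5py.File(path, "r") as f:
        for subject, subj_grp in f["epochs"].items():
            for site, g in subj_grp.items():
                d = g["data"]
                sfreq = float(d.attrs["sampling_rate"])
                n_s = d.shape[-1]
                tmin = float(d.attrs["tmin_ms"])
                times = tmin + np.arange(n_s) / sfreq * 1000.0
                out.setdefault(subject, {})[site] = EpochSet(
                    data=d[()],
                    channels=[c if isinstance(c, str) else c.decode() for c in d.attrs["channels"]],
                    sfreq=sfreq,
                    times=times,
                    subject=subject,
                    site=site,
                    group=str(d.attrs["group"]),
                )
    return out


def save_tf_maps(tf_maps: dict, path) -> None:
    """Write ``subject -> site -> TFMap`` to HDF5."""
    with h5py.File(path, "w") as f:
        root = f.create_group("tfr")
        for subject, by_site in tf_maps.items():
            for site, tf in by_site.items():
                g = root.require_group(subject).create_group(site)
                d = g.create_dataset("power", data=tf.power.astype(np.float32), track_times=False)
                g.create_dataset("freqs", data=tf.freqs, track_times=False)
                g.create_dataset("times", data=tf.times, track_times=False)
                d.attrs["scale"] = tf.scale
                d.attrs["group"] = tf.group
                if tf.baseline is not None:
                    d.attrs["baseline"] = list(tf.baseline)
                if tf.channels is not None:
                    d.attrs["channels"] = list(tf.channels)


def load_tf_maps(path) -> dict:
    out: dict = {}
    with h5py.File(path, "r") as f:
        for subject, subj_grp in f["tfr"].items():
            for site, g in subj_grp.items():
                d = g["power"]
                baseline = d.attrs.get("baseline")
                channels = d.attrs.get("channels")
                out.setdefault(subject, {})[site] = TFMap(
                    power=d[()].astype(float),
                    freqs=g["freqs"][()],
                    times=g["times"][()],
                    scale=str(d.attrs["scale"]),
                    baseline=None if baseline is None else tuple(float(b) for b in baseline),
                    channels=None if channels is None else
                    [c if isinstance(c, str) else c.decode() for c in channels],
                    subject=subject,
                    site=site,
                    group=str(d.attrs["group"]),
                )
    return out


def read_brainvision_epochs(
    vhdr_path,
    tmin_ms: float = -1000.0,
    tmax_ms: float = 1000.0,
    marker_prefix: str = "Stimulus",
    subject: str = "",
    site: str = "",
    group: str = "",
) -> EpochSet:
    """Epoch a BrainVision recording around its stimulus markers.

    Thin wrapper over mne's BrainVision reader: every marker whose
    description starts with ``marker_prefix`` becomes one epoch with t = 0
    at the marker.  Epochs extending past the recording are dropped.
    """
    import mne

    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    events, event_id = mne.events_from_annotations(raw, verbose="error")
    keep = [v for k, v in event_id.items() if k.startswith(marker_prefix)]
    events = events[np.isin(events[:, 2], keep)]
    if len(events) == 0:
        raise ValueError(f"no markers starting with {marker_prefix!r}")
    sfreq = raw.info["sfreq"]
    n_before = int(round(-tmin_ms / 1000.0 * sfreq))
    n_after = int(round(tmax_ms / 1000.0 * sfreq))
    sigs = raw.get_data() * 1e6  # volts -> microvolts
    epochs = []
    for sample in events[:, 0]:
        lo, hi = sample - n_before, sample + n_after
        if lo < 0 or hi > sigs.shape[1]:
            continue
        epochs.append(sigs[:, lo:hi])
    if not epochs:
        raise ValueError("no complete epochs inside the recording")
    times = (np.arange(-n_before, n_after) / sfreq) * 1000.0
    return EpochSet(
        data=np.stack(epochs),
        channels=raw.ch_names,
        sfreq=sfreq,
        times=times,
        subject=subject,
        site=site,
        group=group,
    )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
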