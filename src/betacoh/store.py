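"""HDF5 persistence for epochs and connectivity maps.

Layout for an :class:`~betacoh.containers.EpochSet` group:

    /data            float64 (trials, channels, samples)
    /rejected        bool (trials,)
    /meta/<column>   one dataset per trial-metadata column
    attrs: rate, t0_ms, ch_names, referenced

ImCoh maps are stored as ``/values`` with ``freqs`` and ``grid_ms`` axis
datasets plus estimator/baseline attributes.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .connectivity import ImCohMap
from .containers import EpochSet


def save_epochs(group: h5py.Group, epochs: EpochSet) -> None:
    group.create_dataset("data", data=epochs.data, compression="gzip", compression_opts=1)
    group.create_dataset("rejected", data=epochs.rejected)
    group.create_dataset(
        "rejection_reasons",
        data=np.array(epochs.rejection_reasons, dtype=h5py.string_dtype()),
    )
    meta = group.create_group("meta")
    for col in epochs.trial_meta.columns:
        vals = epochs.trial_meta[col].to_numpy()
        if vals.dtype == object:
            vals = vals.astype(h5py.string_dtype())
        meta.create_dataset(str(col), data=vals)
    group.attrs["columns"] = json.dumps(list(map(str, epochs.trial_meta.columns)))
    group.attrs["rate"] = epochs.rate
    group.attrs["t0_ms"] = epochs.t0_ms
    group.attrs["ch_names"] = json.dumps(epochs.ch_names)
    group.attrs["referenced"] = epochs.referenced


def load_epochs(group: h5py.Group) -> EpochSet:
    cols = json.loads(group.attrs["columns"])
    meta = {}
    for col in cols:
        v = group["meta"][col][()]
        if v.dtype.kind in ("S", "O"):
            v = np.array([x.decode() if isinstance(x, bytes) else x for x in v])
        meta[col] = v
    reasons = [
        x.decode() if isinstance(x, bytes) else x
        for x in group["rejection_reasons"][()]
    ]
    return EpochSet(
        data=group["data"][()],
        rate=float(group.attrs["rate"]),
        t0_ms=float(group.attrs["t0_ms"]),
        ch_names=json.loads(group.attrs["ch_names"]),
        trial_meta=pd.DataFrame(meta),
        rejected=group["rejected"][()],
        rejection_reasons=reasons,
        referenced=bool(group.attrs["referenced"]),
    )


def save_imcoh(group: h5py.Group, m: ImCohMap) -> None:
    group.create_dataset("values", data=m.values)
    group.create_dataset("freqs", data=m.freqs)
    group.create_dataset("grid_ms", data=m.grid_ms)
    group.attrs["estimator"] = m.estimator
    group.attrs["baseline_ms"] = json.dumps(m.baseline_ms)
    group.attrs["meta"] = json.dumps(m.meta, default=str)


def load_imcoh(group: h5py.Group) -> ImCohMap:
    baseline = json.loads(group.attrs["baseline_ms"])
    return ImCohMap(
        values=group["values"][()],
        freqs=group["freqs"][()],
        grid_ms=group["grid_ms"][()],
        estimator=str(group.attrs["estimator"]),
        baseline_ms=tuple(baseline) if baseline else None,
        meta=json.loads(group.attrs["meta"]),
    )
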