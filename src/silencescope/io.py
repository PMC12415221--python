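"""Reading and writing trace containers (HDF5/NPZ) and tidy CSV tables."""
from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .calcium import FluorescenceTrace
from .deconv import CurrentTrace
from .synth import GroundTruth

__all__ = [
    "write_traces_h5",
    "read_traces_h5",
    "write_trace_npz",
    "read_trace_npz",
    "read_trace_csv",
]


def _trace_attrs(trace) -> dict:
    attrs = {"fs": trace.sampling_rate}
    if isinstance(trace, CurrentTrace):
        attrs["kind"] = "vc"
        attrs["ctype"] = trace.ctype
        if trace.group is not None:
            attrs["group"] = trace.group
    else:
        attrs["kind"] = "ca"
    return attrs


def write_traces_h5(path, records: list[tuple[str, object, GroundTruth | None]]) -> None:
    """Write traces to HDF5, one group per neuron.

    Each record is (name, trace, truth-or-None); the layout is
    ``/<name>/raw`` plus optional ``/<name>/truth/times`` and
    ``/truth/amplitudes``, with sampling rate and labels as attributes.
    """
    with h5py.File(path, "w") as f:
        for name, trace, truth in records:
            g = f.create_group(name)
            g.create_dataset("raw", data=np.asarray(trace.samples, dtype=float))
            for k, v in _trace_attrs(trace).items():
                g.attrs[k] = v
            if truth is not None:
                tg = g.create_group("truth")
                tg.create_dataset("times", data=truth.event_times)
                tg.create_dataset("amplitudes", data=truth.event_amplitudes)
                if truth.ap_counts is not None:
                    tg.create_dataset("ap_counts", data=truth.ap_counts)
                if truth.label is not None:
                    tg.attrs["label"] = truth.label


def read_traces_h5(path) -> list[tuple[str, object, GroundTruth | None]]:
    """Read back records written by :func:`write_traces_h5`."""
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            g = f[name]
            samples = np.asarray(g["raw"])
            fs = float(g.attrs["fs"])
            kind = g.attrs.get("kind", "ca")
            if kind == "vc":
                trace = CurrentTrace(
                    samples, fs, str(g.attrs.get("ctype", "EPSC")),
                    None, g.attrs.get("group") and str(g.attrs["group"]),
                )
            else:
                trace = FluorescenceTrace(samples, fs)
            truth = None
            if "truth" in g:
                tg = g["truth"]
                truth = GroundTruth(
                    np.asarray(tg["times"]),
                    np.asarray(tg["amplitudes"]),
                    np.asarray(tg["ap_counts"]) if "ap_counts" in tg else None,
                    str(tg.attrs["label"]) if "label" in tg.attrs else None,
                )
            out.append((name, trace, truth))
    return out


def write_trace_npz(path, trace, truth: GroundTruth | None = None) -> None:
    """Single-trace NPZ container (samples + metadata + optional truth)."""
    payload = {"samples": np.asarray(trace.samples, dtype=float),
               "fs": np.array(trace.sampling_rate)}
    for k, v in _trace_attrs(trace).items():
        if k != "fs":
            payload[k] = np.array(str(v))
    if truth is not None:
        payload["truth_times"] = truth.event_times
        payload["truth_amplitudes"] = truth.event_amplitudes
    np.savez(path, **payload)


def read_trace_npz(path):
    """Read back a container written by :func:`write_trace_npz`."""
    z = np.load(path, allow_pickle=False)
    fs = float(z["fs"])
    kind = str(z["kind"]) if "kind" in z else "ca"
    if kind == "vc":
        group = str(z["group"]) if "group" in z else None
        trace = CurrentTrace(z["samples"], fs, str(z["ctype"]), None, group)
    else:
        trace = FluorescenceTrace(z["samples"], fs)
    truth = None
    if "truth_times" in z:
        truth = GroundTruth(z["truth_times"], z["truth_amplitudes"])
    return trace, truth


def read_trace_csv(path, ctype: str = "EPSC") -> CurrentTrace:
    """User-supplied current trace as CSV with `time_s` and `pA` columns."""
    df = pd.read_csv(path)
    for col in ("time_s", "pA"):
        if col not in df.columns:
            raise ValueError(f"trace CSV needs column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("trace CSV needs at least 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("trace CSV must be uniformly sampled")
    return CurrentTrace(df["pA"].to_numpy(dtype=float), 1.0 / dt[0], ctype)
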