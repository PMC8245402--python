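"""HDF5 dataset layout and CSV helpers.

Layout of a study container::

    /meta                  attrs: rho_cm, n_refractive, top_thickness_cm,
                           seed, wavelengths, config_hash, protocol_json
    /irf/<wavelength>      float array, attrs: bin_width_ps, t0_ns
    /subjects/<id>/<eye>/<hemisphere>/<wavelength>/dtof
                           integer counts (n_samples x n_bins),
                           attrs: bin_width_ps, t0_ns
    /truth/<table>         ground-truth tables, one dataset per column

Counts round-trip exactly; all tabular outputs elsewhere are CSV with a
``# config_hash=...`` comment line for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .forward import ReflectanceCurve, TimeGrid
from .simulate import SimulatedStudy, StimulationProtocol

__all__ = [
    "write_study",
    "read_study",
    "validate_dataset",
    "write_csv",
    "read_csv",
]


def _write_table(group: h5py.Group, df: pd.DataFrame) -> None:
    group.attrs["columns"] = json.dumps(list(df.columns))
    for col in df.columns:
        v = df[col].to_numpy()
        if v.dtype == object or v.dtype.kind in "U":
            v = v.astype("S")
        group.create_dataset(col, data=v)


def _read_table(group: h5py.Group) -> pd.DataFrame:
    cols = json.loads(group.attrs["columns"])
    data = {}
    for col in cols:
        v = group[col][()]
        if v.dtype.kind == "S":
            v = v.astype(str)
        data[col] = v
    return pd.DataFrame(data)


def write_study(path: str | Path, study: SimulatedStudy, config_hash: str = "") -> None:
    """Write a simulated study (DTOF stacks + ground truth) to HDF5."""
    grid = study.grid
    bin_ps = grid.bin_width * 1000.0
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["rho_cm"] = study.config.rho_cm
        meta.attrs["n_refractive"] = study.config.n_refractive
        meta.attrs["top_thickness_cm"] = study.config.top_thickness_cm
        meta.attrs["seed"] = study.config.seed
        meta.attrs["wavelengths"] = list(study.config.wavelengths)
        meta.attrs["config_hash"] = config_hash
        meta.attrs["protocol_json"] = json.dumps(
            {
                k: getattr(study.protocol, k)
                for k in (
                    "baseline_s",
                    "n_cycles",
                    "rest_s",
                    "stim_s",
                    "recovery_s",
                    "sampling_rate",
                )
            }
        )
        irf_g = f.create_group("irf")
        for wl, curve in study.irfs.items():
            d = irf_g.create_dataset(str(wl), data=curve.value)
            d.attrs["bin_width_ps"] = bin_ps
            d.attrs["t0_ns"] = float(grid.t[0])
        for (sid, eye, hemi, wl), stack in study.dtofs.items():
            g = f.require_group(f"subjects/{sid}/{eye}/{hemi}/{wl}")
            d = g.create_dataset(
                "dtof", data=np.asarray(stack, dtype=np.int64), compression="gzip"
            )
            d.attrs["bin_width_ps"] = bin_ps
            d.attrs["t0_ns"] = float(grid.t[0])
        truth = f.create_group("truth")
        _write_table(truth.create_group("design"), study.design)
        _write_table(truth.create_group("cycles"), study.truth_cycles)
        _write_table(truth.create_group("baseline"), study.truth_baseline)


def read_study(path: str | Path) -> dict:
    """Read a study container back into plain structures.

    Returns a dict with ``meta`` (dict), ``protocol``
    (StimulationProtocol), ``grid`` (TimeGrid), ``irfs``
    ({wavelength: ReflectanceCurve}), ``dtofs``
    ({(subject, eye, hemisphere, wavelength): int array}) and the truth
    tables ``design``, ``cycles``, ``baseline`` (DataFrames).
    """
    with h5py.File(path, "r") as f:
        meta = dict(f["meta"].attrs)
        proto = StimulationProtocol(**json.loads(meta["protocol_json"]))
        irfs = {}
        grid = None
        for name, d in f["irf"].items():
            bw = float(d.attrs["bin_width_ps"]) / 1000.0
            v = d[()]
            if grid is None:
                grid = TimeGrid(np.arange(v.size) * bw + float(d.attrs["t0_ns"]), bw)
            irfs[float(name)] = ReflectanceCurve(grid, v)
        dtofs = {}
        if "subjects" in f:
            for sid, s_g in f["subjects"].items():
                for eye, e_g in s_g.items():
                    for hemi, h_g in e_g.items():
                        for wl, w_g in h_g.items():
                            dtofs[(sid, eye, hemi, float(wl))] = w_g["dtof"][()]
        out = {
            "meta": meta,
            "protocol": proto,
            "grid": grid,
            "irfs": irfs,
            "dtofs": dtofs,
        }
        for name in ("design", "cycles", "baseline"):
            out[name] = _read_table(f[f"truth/{name}"])
    return out


def validate_dataset(path: str | Path) -> list[str]:
    """Structural checks of a study container; returns problem list."""
    problems = []
    try:
        with h5py.File(path, "r") as f:
            for req in ("meta", "irf", "truth"):
                if req not in f:
                    problems.append(f"missing group /{req}")
            if "meta" in f:
                for attr in ("rho_cm", "wavelengths", "seed", "protocol_json"):
                    if attr not in f["meta"].attrs:
                        problems.append(f"missing /meta attribute {attr}")
            if "subjects" in f:
                def check(name, obj):
                    if isinstance(obj, h5py.Dataset) and name.endswith("dtof"):
                        if obj.dtype.kind not in "iu":
                            problems.append(f"{name}: counts must be integer")
                        elif obj.ndim != 2:
                            problems.append(f"{name}: expected 2-d stack")
                        for attr in ("bin_width_ps", "t0_ns"):
                            if attr not in obj.attrs:
                                problems.append(f"{name}: missing attr {attr}")
                f["subjects"].visititems(check)
    except OSError as e:
        problems.append(f"cannot open file: {e}")
    return problems


def write_csv(df: pd.DataFrame, path: str | Path, config_hash: str) -> None:
    """CSV with a provenance comment line."""
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
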