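"""Cube and reference-spectrum I/O.

Two cube containers are supported:

* binary: a single HDF5 file (``.h5``/``.hdf5``) with datasets ``spectra``
  and ``axis_cm1`` and the grid/time attributes;
* text: a tab-delimited matrix (one pixel spectrum per row, row-major by
  depth then lateral position) plus a JSON sidecar ``<stem>.json`` holding
  ``n_depth, n_lateral, depth_step_um, lateral_step_um, time_h, axis_cm1``
  and free-form metadata.

Reference spectra are two-column delimited text (cm^-1, intensity) with a
JSON sidecar listing the characteristic peaks.
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .errors import FormatError
from .types import HyperMap, ReferenceSpectrum, Spectrum, WavenumberAxis

__all__ = [
    "write_hypermap",
    "read_hypermap",
    "write_reference",
    "read_reference",
]

_CUBE_FIELDS = ("n_depth", "n_lateral", "depth_step_um", "lateral_step_um", "time_h", "axis_cm1")
_H5_SUFFIXES = {".h5", ".hdf5"}


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_hypermap(cube: HyperMap, path: str | Path) -> Path:
    """Write a cube; container chosen by suffix (.h5/.hdf5 binary, else text)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in _H5_SUFFIXES:
        with h5py.File(path, "w") as f:
            f.create_dataset("spectra", data=cube.spectra)
            f.create_dataset("axis_cm1", data=cube.axis.values)
            for k in ("n_depth", "n_lateral", "depth_step_um", "lateral_step_um", "time_h"):
                f.attrs[k] = getattr(cube, k)
            f.attrs["metadata"] = json.dumps(cube.metadata)
    else:
        np.savetxt(path, cube.spectra, delimiter="\t", fmt="%.17g")
        sidecar = {
            "n_depth": cube.n_depth,
            "n_lateral": cube.n_lateral,
            "depth_step_um": cube.depth_step_um,
            "lateral_step_um": cube.lateral_step_um,
            "time_h": cube.time_h,
            "axis_cm1": cube.axis.values.tolist(),
            "metadata": cube.metadata,
        }
        _sidecar(path).write_text(json.dumps(sidecar))
    return path


def read_hypermap(path: str | Path) -> HyperMap:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such cube file: {path}")
    if path.suffix.lower() in _H5_SUFFIXES:
        with h5py.File(path, "r") as f:
            for k in ("spectra", "axis_cm1"):
                if k not in f:
                    raise FormatError(f"HDF5 cube missing dataset '{k}'")
            for k in ("n_depth", "n_lateral", "depth_step_um", "lateral_step_um", "time_h"):
                if k not in f.attrs:
                    raise FormatError(f"HDF5 cube missing attribute '{k}'")
            spectra = np.asarray(f["spectra"], dtype=float)
            axis = WavenumberAxis(np.asarray(f["axis_cm1"], dtype=float))
            meta = json.loads(f.attrs.get("metadata", "{}"))
            fields = {k: f.attrs[k] for k in ("n_depth", "n_lateral", "depth_step_um", "lateral_step_um", "time_h")}
    else:
        sc_path = _sidecar(path)
        if not sc_path.exists():
            raise FormatError(f"missing JSON sidecar for text cube: {sc_path}")
        sidecar = json.loads(sc_path.read_text())
        for k in _CUBE_FIELDS:
            if k not in sidecar:
                raise FormatError(f"cube sidecar missing field '{k}'")
        spectra = np.loadtxt(path, delimiter="\t", ndmin=2)
        axis = WavenumberAxis(np.asarray(sidecar["axis_cm1"], dtype=float))
        meta = sidecar.get("metadata", {})
        fields = {k: sidecar[k] for k in ("n_depth", "n_lateral", "depth_step_um", "lateral_step_um", "time_h")}
    n_rows = int(fields["n_depth"]) * int(fields["n_lateral"])
    if spectra.shape[0] != n_rows:
        raise FormatError(
            f"cube has {spectra.shape[0]} spectra but grid declares {n_rows} pixels"
        )
    if spectra.shape[1] != len(axis):
        raise FormatError(
            f"cube spectra have {spectra.shape[1]} channels but axis has {len(axis)}"
        )
    return HyperMap(
        axis=axis,
        n_depth=int(fields["n_depth"]),
        n_lateral=int(fields["n_lateral"]),
        depth_step_um=float(fields["depth_step_um"]),
        lateral_step_um=float(fields["lateral_step_um"]),
        time_h=float(fields["time_h"]),
        spectra=spectra,
        metadata=dict(meta),
    )


def write_reference(ref: ReferenceSpectrum, path: str | Path) -> Path:
    """Two-column (cm^-1, intensity) text file plus a JSON peak sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.column_stack([ref.spectrum.axis.values, ref.spectrum.intensities])
    np.savetxt(path, data, delimiter="\t", fmt="%.17g")
    _sidecar(path).write_text(
        json.dumps({"name": ref.name, "peaks": [list(p) for p in ref.peaks]})
    )
    return path


def read_reference(path: str | Path) -> ReferenceSpectrum:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such reference file: {path}")
    sc_path = _sidecar(path)
    if not sc_path.exists():
        raise FormatError(f"missing JSON sidecar for reference: {sc_path}")
    sidecar = json.loads(sc_path.read_text())
    for k in ("name", "peaks"):
        if k not in sidecar:
            raise FormatError(f"reference sidecar missing field '{k}'")
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    if data.shape[1] != 2:
        raise FormatError("reference file must have exactly two columns")
    axis = WavenumberAxis(data[:, 0])
    return ReferenceSpectrum(
        name=str(sidecar["name"]),
        spectrum=Spectrum(axis, data[:, 1]),
        peaks=[tuple(p) for p in sidecar["peaks"]],
    )
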