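"""HDF5 and CSV I/O for cubes, preprocessed cubes and manifests.

Cubes are stored with datasets ``absorbance`` (H x W x B float) and
``wavenumbers`` (B), metadata as root attributes — an HDF5 layout readable as
MATLAB v7.3.  Preprocessed cubes additionally carry the tissue mask and an
ordered provenance attribute.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .axis import WavenumberAxis
from .cube import HyperCube
from .errors import InvalidArgumentError

MANIFEST_COLUMNS = ("path", "class", "treatment", "animal_id")


def write_cube(path: str | Path, cube: HyperCube) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("absorbance", data=cube.absorbance)
        f.create_dataset("wavenumbers", data=cube.axis.values)
        f.attrs["meta"] = json.dumps(cube.meta)


def read_cube(path: str | Path) -> HyperCube:
    with h5py.File(path, "r") as f:
        arr = np.asarray(f["absorbance"])
        wn = np.asarray(f["wavenumbers"])
        meta = json.loads(f.attrs.get("meta", "{}"))
    return HyperCube(arr, WavenumberAxis(wn), meta)


def write_preprocessed(path: str | Path, pre) -> None:
    """Write a PreprocessedCube (spectra + mask + provenance)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("spectra", data=pre.spectra)
        f.create_dataset("wavenumbers", data=pre.axis.values)
        f.create_dataset("mask", data=pre.mask.keep)
        f.attrs["threshold"] = pre.mask.threshold
        f.attrs["peak_wavenumber"] = pre.mask.peak_wavenumber
        f.attrs["provenance"] = json.dumps(list(pre.provenance))
        f.attrs["meta"] = json.dumps(pre.meta)


def read_preprocessed(path: str | Path):
    from .preprocess import PreprocessedCube, TissueMask

    with h5py.File(path, "r") as f:
        spectra = np.asarray(f["spectra"])
        wn = np.asarray(f["wavenumbers"])
        keep = np.asarray(f["mask"]).astype(bool)
        mask = TissueMask(
            keep=keep,
            threshold=float(f.attrs["threshold"]),
            peak_wavenumber=float(f.attrs["peak_wavenumber"]),
        )
        provenance = tuple(json.loads(f.attrs.get("provenance", "[]")))
        meta = json.loads(f.attrs.get("meta", "{}"))
    return PreprocessedCube(
        spectra=spectra, axis=WavenumberAxis(wn), mask=mask, provenance=provenance, meta=meta
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise InvalidArgumentError(f"manifest missing columns {missing}")
    return manifest
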