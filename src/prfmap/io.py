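"""Reading and writing the standard on-disk formats.

Response matrices travel as:

* NIfTI-1 4-D volumes (one per split half): voxels are flattened in C order
  and a boolean mask may restrict them;
* CSV: one row per unit, one column per timepoint/position;
* HDF5: datasets ``data_odd`` and ``data_even`` plus a ``modality`` attribute
  (what :func:`save_dataset` writes).

Fit tables are plain CSV, one row per unit.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import ResponseDataset
from .stimulus import EffectiveStimulus


def read_response_matrix(path, mask: np.ndarray | None = None) -> np.ndarray:
    """Read one half's (n_units, T) response matrix from NIfTI, CSV or HDF5."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        vol = np.asanyarray(img.dataobj)
        if vol.ndim != 4:
            raise ValueError(f"{path}: expected a 4-D NIfTI volume")
        mat = vol.reshape(-1, vol.shape[-1])
        if mask is not None:
            mat = mat[np.asarray(mask).ravel().astype(bool)]
        return mat.astype(np.float64)
    if name.endswith(".csv"):
        return pd.read_csv(path, header=None).to_numpy(dtype=np.float64)
    if name.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as f:
            return f["responses"][...].astype(np.float64)
    raise ValueError(f"unrecognized response file format: {path}")


def save_dataset(dataset: ResponseDataset, path) -> None:
    """Write a split-half dataset (both halves + modality) to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data_odd", data=dataset.data_odd)
        f.create_dataset("data_even", data=dataset.data_even)
        f.attrs["modality"] = dataset.modality
        if dataset.tr is not None:
            f.attrs["tr"] = dataset.tr


def load_dataset(path, stim: EffectiveStimulus, hrf=None) -> ResponseDataset:
    """Load a split-half dataset written by :func:`save_dataset`."""
    import h5py

    with h5py.File(path, "r") as f:
        odd = f["data_odd"][...]
        even = f["data_even"][...]
        modality = f.attrs["modality"]
        tr = float(f.attrs["tr"]) if "tr" in f.attrs else None
    return ResponseDataset(
        data_odd=odd, data_even=even, modality=str(modality),
        stim=stim, hrf=hrf, tr=tr,
    )


def save_fits(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def load_fits(path) -> pd.DataFrame:
    return pd.read_csv(path)
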