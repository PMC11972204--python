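"""File I/O: BIDS-dialect events TSV, generic TSV tables, NIfTI-1 volumes.

Events tables round-trip losslessly through tab-separated text; volumetric
exports follow the NIfTI-1 standard with an RAS+ affine via nibabel.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from lamiquartet.events import validate_events


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    validate_events(events)
    events.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    validate_events(df)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_volume(data: np.ndarray, path: str | Path, affine: np.ndarray | None = None, tr_s: float | None = None) -> None:
    """Write a 3D/4D array as NIfTI-1 with an RAS+ affine (identity default)."""
    affine = np.eye(4) if affine is None else np.asarray(affine, dtype=float)
    img = nib.Nifti1Image(np.asarray(data), affine)
    if tr_s is not None and data.ndim == 4:
        img.header.set_zooms((*img.header.get_zooms()[:3], float(tr_s)))
    nib.save(img, str(path))


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns ``(data, affine)``."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), np.asarray(img.affine)


def timeseries_to_volume(data: np.ndarray) -> np.ndarray:
    """Pack a (volumes x voxels) matrix as a 4D (voxels x 1 x 1 x volumes) image."""
    return np.ascontiguousarray(data.T)[:, None, None, :]


def export_run(run, patch, out_dir: str | Path) -> None:
    """Export one simulated run as a 4D NIfTI-1 volume with sidecar events TSV,
    plus the patch ground truth as a TSV table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(timeseries_to_volume(run.data), out / f"{run.name}_bold.nii", tr_s=run.schedule.tr_s)
    write_events(run.events, out / f"{run.name}_events.tsv")
    write_table(patch.to_frame(), out / "patch_ground_truth.tsv")
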