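"""NIfTI-1 volume I/O.

Volumes are stored with the voxel spacing on the affine diagonal (mm) and
the acquisition time, when known, in the header's ``descrip`` field.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .types import CTVolume


def save_volume(volume: CTVolume, path) -> Path:
    path = Path(path)
    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.values.astype(np.float32), affine)
    img.header.set_zooms(volume.spacing)
    if volume.acquisition_time_s is not None:
        img.header["descrip"] = f"t={volume.acquisition_time_s:g}s".encode()
    nib.save(img, path)
    return path


def load_volume(path, acquisition_time_s: float | None = None) -> CTVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    if acquisition_time_s is None:
        descrip = bytes(img.header["descrip"]).split(b"\x00")[0].decode(errors="ignore")
        if descrip.startswith("t=") and descrip.endswith("s"):
            try:
                acquisition_time_s = float(descrip[2:-1])
            except ValueError:
                pass
    return CTVolume(np.asanyarray(img.dataobj, dtype=np.float64), spacing,
                    origin=origin, acquisition_time_s=acquisition_time_s)
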