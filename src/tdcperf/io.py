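"""On-disk artifacts for DSC-MRI perfusion analysis.

Conventions used throughout the package:

* 4D series are indexed ``(x, y, slice, time)``; time is always the last axis
  and the slice axis is the third spatial axis.
* TR and TE are in seconds.
* Parameter maps are float volumes; voxels outside the brain mask or excluded
  by an analysis rule carry a quiet-NaN sentinel.
* Files are NIfTI-1; fitted models and reports are JSON; tables are CSV.

No operation re-orients or resamples; a grid mismatch is always an error.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

#: Reserved value for voxels outside a mask or excluded by an analysis rule.
SENTINEL = np.nan

#: Allowed parameter-map names and their units.
MAP_UNITS = {
    "absTTP": "s",
    "stdTTP": "s",
    "z_f": "dimensionless",
    "stdZ": "dimensionless",
    "Tmax": "s",
}


@dataclass
class DscSeries:
    """A 4D dynamic susceptibility contrast acquisition (or derived curves).

    Parameters
    ----------
    signal : ndarray, shape (nx, ny, n_slices, n_frames)
        Signal (arbitrary units) or, after conversion, contrast-agent
        concentration.
    tr : float
        Repetition time (frame spacing) in seconds.
    te : float
        Echo time in seconds.
    voxel_size : tuple of float
        In-plane and through-plane voxel edge lengths in millimetres.
    """

    signal: np.ndarray
    tr: float
    te: float
    voxel_size: tuple = (1.8, 1.8, 5.0)

    def __post_init__(self):
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 4:
            raise ValueError(
                f"DSC series must be 4D (x, y, slice, time); got {self.signal.ndim} dimensions"
            )
        if not self.tr > 0:
            raise ValueError(f"tr must be positive (seconds); got {self.tr}")
        if not self.te > 0:
            raise ValueError(f"te must be positive (seconds); got {self.te}")

    @property
    def spatial_shape(self):
        return self.signal.shape[:3]

    @property
    def n_frames(self):
        return self.signal.shape[3]

    @property
    def n_slices(self):
        return self.signal.shape[2]

    @property
    def frame_times(self):
        """Acquisition time of each frame in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * self.tr

    def with_signal(self, signal):
        """Copy of this series with a replaced data array (same grid/timing)."""
        return DscSeries(signal=signal, tr=self.tr, te=self.te, voxel_size=self.voxel_size)


@dataclass
class VolumeMask:
    """Boolean 3D mask aligned to a series grid."""

    values: np.ndarray
    role: str = "brain"  # brain | lesion_truth | evaluation_region | predicted_lesion

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError(f"mask must be 3D; got {self.values.ndim} dimensions")

    @property
    def n_voxels(self):
        return int(self.values.sum())


@dataclass
class ParameterMap:
    """A per-voxel perfusion parameter volume.

    ``values`` holds seconds for absTTP/stdTTP/Tmax and dimensionless scores
    for z_f/stdZ; excluded voxels carry :data:`SENTINEL` (quiet NaN).
    """

    name: str
    values: np.ndarray
    units: str = ""

    def __post_init__(self):
        if self.name not in MAP_UNITS:
            raise ValueError(f"unknown map name {self.name!r}; expected one of {sorted(MAP_UNITS)}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"parameter map must be 3D; got {self.values.ndim} dimensions")
        if not self.units:
            self.units = MAP_UNITS[self.name]
        elif self.units != MAP_UNITS[self.name]:
            raise ValueError(
                f"units {self.units!r} inconsistent with map {self.name!r} ({MAP_UNITS[self.name]!r})"
            )

    @property
    def defined_mask(self):
        return np.isfinite(self.values)


def _affine(voxel_size):
    aff = np.diag(list(voxel_size) + [1.0])
    return aff


def save_series(series: DscSeries, path) -> None:
    """Write a 4D series as NIfTI-1, stashing TR/TE in the header.

    TR goes into the time zoom (pixdim[4]); TR and TE are additionally encoded
    in the ``descrip`` field so a round trip does not depend on time-unit
    handling of other software.
    """
    img = nib.Nifti1Image(np.asarray(series.signal), _affine(series.voxel_size))
    img.header.set_xyzt_units("mm", "sec")
    img.header.set_zooms(tuple(series.voxel_size) + (series.tr,))
    img.header["descrip"] = f"tr={series.tr:.6f}s;te={series.te:.6f}s".encode()
    nib.save(img, str(path))


_DESCRIP_RE = re.compile(r"tr=([0-9.eE+-]+)s;te=([0-9.eE+-]+)s")


def load_series(path, tr_override=None, te_override=None) -> DscSeries:
    """Load a 4D NIfTI series.

    TR/TE resolution order: explicit override > ``descrip`` field > header
    time zoom (TR only). Missing timing with no override is an error.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D NIfTI series (x, y, slice, time); got {data.ndim}D data")
    zooms = img.header.get_zooms()
    descrip = bytes(img.header["descrip"].tobytes()).decode(errors="replace")
    m = _DESCRIP_RE.search(descrip)
    tr = tr_override
    te = te_override
    if tr is None:
        if m:
            tr = float(m.group(1))
        elif len(zooms) > 3 and zooms[3] > 0:
            tr = float(zooms[3])
    if te is None and m:
        te = float(m.group(2))
    if tr is None or not tr > 0:
        raise ValueError("no repetition time in header and no tr_override given")
    if te is None or not te > 0:
        raise ValueError("no echo time in header and no te_override given")
    return DscSeries(signal=data, tr=tr, te=te, voxel_size=tuple(float(z) for z in zooms[:3]))


def save_mask(mask: VolumeMask, path, voxel_size=(1.8, 1.8, 5.0)) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), _affine(voxel_size))
    img.header["descrip"] = f"role={mask.role}".encode()
    nib.save(img, str(path))


def load_mask(path, role=None) -> VolumeMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D mask; got {data.ndim}D data")
    if role is None:
        descrip = bytes(img.header["descrip"].tobytes()).decode(errors="replace")
        descrip = descrip.rstrip("\x00").strip()
        role = descrip.split("role=", 1)[1] if "role=" in descrip else "brain"
    return VolumeMask(values=data > 0, role=role)


def save_map(pmap: ParameterMap, path, voxel_size=(1.8, 1.8, 5.0), reference_shape=None) -> None:
    """Write a parameter map as float32 NIfTI; sentinel voxels stay NaN."""
    if reference_shape is not None and tuple(pmap.values.shape) != tuple(reference_shape):
        raise ValueError(
            f"map shape {pmap.values.shape} does not match reference grid {tuple(reference_shape)}"
        )
    img = nib.Nifti1Image(pmap.values.astype(np.float32), _affine(voxel_size))
    img.header["descrip"] = f"name={pmap.name};units={pmap.units}".encode()
    nib.save(img, str(path))


def load_map(path, name=None) -> ParameterMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).astype(float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D parameter map; got {data.ndim}D data")
    descrip = bytes(img.header["descrip"].tobytes()).decode(errors="replace")
    if name is None:
        m = re.search(r"name=([^;]+);", descrip)
        if not m:
            raise ValueError("map name missing from header; pass name= explicitly")
        name = m.group(1)
    return ParameterMap(name=name, values=data)
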