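"""Per-VOI arrival-offset standardization: stdTTP and stdZ.

A VOI is by default one slice (the third spatial axis). For each VOI the
lower-tail quantile of the parameter values — the arrival offset — is
subtracted from every voxel and the result clamped at zero:

    stdTTP = max(0, ttp - Q_VOI(0.03))        (offset: lower 3% quantile)
    stdZ   = max(0, z_f - Q_VOI(0.02275))     (offset: lower 2.275% quantile,
                                               after excluding z_f < -3)

This simulates the simultaneous filling of all VOIs: constant per-slice
arrival delays cancel exactly. For TTP maps the subtraction is carried out in
the integer frame domain, ``(frames - x_l) - g * (x_{l+1} - x_l)`` with x_l
the anchor order statistic and g the interpolation fraction, which makes the
cancellation bit-exact, not merely exact in real arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import ParameterMap, VolumeMask, SENTINEL, MAP_UNITS
from .preprocessing import TtpMap
from .tdc import empirical_quantile

#: z_f values below this are excluded from the stdZ analysis entirely.
ZF_LOWER_INCLUSION = -3.0

#: Offset quantile probabilities.
P_STDTTP = 0.03
P_STDZ = 0.02275


@dataclass
class OffsetEntry:
    voi_id: int
    n_voxels: int
    offset: float
    fallback: bool = False
    # frame-domain anchors (TTP maps only) for the bit-exact path
    anchor_lo: int = None
    anchor_hi: int = None
    frac: float = None


@dataclass
class OffsetTable:
    """Per-VOI arrival offsets (seconds for TTP, dimensionless for z_f)."""

    entries: dict  # voi_id -> OffsetEntry
    p: float
    variable: str  # "ttp" | "z_f"

    def offset(self, voi_id):
        return self.entries[voi_id].offset

    def to_csv(self, path):
        import pandas as pd

        pd.DataFrame(
            [
                {
                    "voi_id": e.voi_id,
                    "n_voxels": e.n_voxels,
                    "offset": e.offset,
                    "p": self.p,
                    "fallback": e.fallback,
                }
                for e in self.entries.values()
            ]
        ).to_csv(path, index=False)


def voi_labels(shape, scheme="slice"):
    """Integer VOI label volume: per-slice (default) or whole-brain."""
    labels = np.zeros(shape, dtype=int)
    if scheme == "slice":
        labels[:] = np.arange(shape[2])[None, None, :]
    elif scheme == "whole_brain":
        labels[:] = 0
    else:
        raise ValueError(f"unknown VOI scheme {scheme!r}")
    return labels


def _quantile_anchors(sorted_frames, p):
    """Order-statistic anchors of the linear-interpolation p-quantile."""
    n = sorted_frames.size
    h = (n - 1) * p
    l = int(math.floor(h))
    g = h - l
    lo = int(sorted_frames[l])
    hi = int(sorted_frames[min(l + 1, n - 1)])
    return lo, hi, g


def voi_offsets(pmap, voi=None, p=P_STDTTP) -> OffsetTable:
    """Per-VOI lower p-quantile arrival offsets.

    ``pmap`` is a TtpMap (seconds; frame-exact path) or a z_f ParameterMap.
    VOIs with fewer than ceil(1/p) defined voxels inherit the whole-brain
    offset and are flagged as fallback. Raises if no VOI qualifies.
    """
    if not 0 < p < 1:
        raise ValueError(f"offset probability must be in (0, 1); got {p}")
    is_ttp = isinstance(pmap, TtpMap)
    if is_ttp:
        values = np.where(pmap.defined_mask, pmap.frames, np.nan).astype(float)
        shape, variable, scale = pmap.shape, "ttp", pmap.tr
    else:
        values = pmap.values
        shape, variable, scale = values.shape, "z_f", 1.0
    if voi is None:
        voi = voi_labels(shape, "slice")
    voi = np.asarray(voi)
    min_n = math.ceil(1.0 / p)

    defined = np.isfinite(values)
    if not defined.any():
        raise ValueError("no defined voxels for offset estimation")
    global_sample = np.sort(values[defined])

    entries = {}
    any_ok = False
    for vid in np.unique(voi):
        sample = values[(voi == vid) & defined]
        fallback = sample.size < min_n
        use = global_sample if fallback else np.sort(sample)
        if not fallback:
            any_ok = True
        if is_ttp:
            lo, hi, g = _quantile_anchors(use, p)
            offset = scale * (lo + g * (hi - lo))
            entries[int(vid)] = OffsetEntry(
                voi_id=int(vid),
                n_voxels=int(sample.size),
                offset=float(offset),
                fallback=fallback,
                anchor_lo=lo,
                anchor_hi=hi,
                frac=g,
            )
        else:
            offset = empirical_quantile(use, p)
            entries[int(vid)] = OffsetEntry(
                voi_id=int(vid), n_voxels=int(sample.size), offset=float(offset), fallback=fallback
            )
    if not any_ok:
        raise ValueError(
            f"no VOI has the >= {min_n} voxels needed to populate the {p:g} quantile"
        )
    return OffsetTable(entries=entries, p=p, variable=variable)


def standardize(pmap, offsets: OffsetTable, voi=None) -> ParameterMap:
    """Clamped per-VOI offset subtraction: value -> max(0, value - offset).

    TtpMap in: stdTTP map out (seconds, computed in the frame domain so that
    per-slice constant frame shifts cancel bit-exactly). z_f map in: stdZ map
    out, with z_f < -3 voxels excluded (sentinel) before subtraction.
    Excluded voxels keep the sentinel. Raises if a VOI present in the map has
    no offset entry.
    """
    is_ttp = isinstance(pmap, TtpMap)
    shape = pmap.shape if is_ttp else pmap.values.shape
    if voi is None:
        voi = voi_labels(shape, "slice")
    voi = np.asarray(voi)
    present = np.unique(voi)
    missing = [int(v) for v in present if int(v) not in offsets.entries]
    if missing:
        raise ValueError(f"offset table lacks entries for VOIs {missing}")

    out = np.full(shape, SENTINEL, dtype=float)
    if is_ttp:
        for vid in present:
            e = offsets.entries[int(vid)]
            sel = (voi == vid) & pmap.defined_mask
            std_frames = (pmap.frames[sel] - e.anchor_lo) - e.frac * (e.anchor_hi - e.anchor_lo)
            out[sel] = pmap.tr * np.maximum(0.0, std_frames)
        return ParameterMap(name="stdTTP", values=out)
    if pmap.name != "z_f":
        raise ValueError(f"standardize expects a TTP map or a z_f map; got {pmap.name!r}")
    vals = pmap.values
    for vid in present:
        e = offsets.entries[int(vid)]
        sel = (voi == vid) & np.isfinite(vals) & (vals >= ZF_LOWER_INCLUSION)
        out[sel] = np.maximum(0.0, vals[sel] - e.offset)
    return ParameterMap(name="stdZ", values=out)


def exclude_low_zf(zf_map: ParameterMap, bound=ZF_LOWER_INCLUSION) -> ParameterMap:
    """Sentinel-exclude voxels with z_f below the inclusion bound (default -3);
    the analysis includes z_f scores in [-3, +inf) only."""
    vals = zf_map.values.copy()
    vals[np.isfinite(vals) & (vals < bound)] = SENTINEL
    return ParameterMap(name=zf_map.name, values=vals)


class VoiStandardizer(BaseEstimator, TransformerMixin):
    """sklearn-style wrapper: fit learns per-VOI offsets, transform applies
    the clamped subtraction.

    Operates on a parameter map plus a VOI label volume; ``fit`` stores the
    :class:`OffsetTable` as ``offsets_``.
    """

    def __init__(self, p=P_STDTTP):
        self.p = p

    def fit(self, pmap, voi=None):
        self.offsets_ = voi_offsets(pmap, voi=voi, p=self.p)
        return self

    def transform(self, pmap, voi=None):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "offsets_")
        return standardize(pmap, self.offsets_, voi=voi)

    def fit_transform(self, pmap, voi=None):
        return self.fit(pmap, voi=voi).transform(pmap, voi=voi)


# --------------------------------------------------------------------------
# Thresholding
# --------------------------------------------------------------------------
@dataclass
class ThresholdSpec:
    """A critical-perfusion threshold with provenance.

    ``value`` may be a scalar or a per-voxel threshold volume (used for the
    per-VOI ipv-derived stdZ threshold).
    """

    parameter: str
    value: object
    units: str
    provenance: str  # "fixed" | "ipv_derived"

    def __post_init__(self):
        if self.parameter not in MAP_UNITS:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.units != MAP_UNITS[self.parameter]:
            raise ValueError(
                f"threshold units {self.units!r} do not match {self.parameter} "
                f"({MAP_UNITS[self.parameter]!r})"
            )


#: Fixed literature thresholds (seconds).
FIXED_THRESHOLDS = {
    "Tmax": ThresholdSpec("Tmax", 6.0, "s", "fixed"),
    "stdTTP": ThresholdSpec("stdTTP", 7.0, "s", "fixed"),
}


def threshold_map(pmap: ParameterMap, spec) -> VolumeMask:
    """Boolean predicted-lesion mask of voxels with value >= threshold.

    ``spec`` is a :class:`ThresholdSpec` or a bare scalar/volume; sentinel
    voxels are never positive. Unit mismatch is rejected.
    """
    if isinstance(spec, ThresholdSpec):
        if spec.parameter != pmap.name:
            raise ValueError(
                f"threshold is for {spec.parameter!r} but map is {pmap.name!r}"
            )
        thr = spec.value
    else:
        thr = spec
    thr = np.asarray(thr, dtype=float)
    if thr.ndim not in (0, 3):
        raise ValueError("threshold must be a scalar or a per-voxel volume")
    if thr.ndim == 3 and thr.shape != pmap.values.shape:
        raise ValueError("per-voxel threshold volume does not match map grid")
    with np.errstate(invalid="ignore"):
        pred = np.isfinite(pmap.values) & (pmap.values >= thr)
    return VolumeMask(values=pred, role="predicted_lesion")


def stdz_threshold_volume(zf_at_ipv: float, offsets: OffsetTable, shape, voi=None):
    """Per-voxel stdZ threshold: the standardized equivalent of the IPv score,
    max(0, zf_at_ipv - offset(VOI))."""
    if voi is None:
        voi = voi_labels(shape, "slice")
    voi = np.asarray(voi)
    thr = np.full(shape, np.nan)
    for vid in np.unique(voi):
        thr[voi == vid] = max(0.0, zf_at_ipv - offsets.offset(int(vid)))
    return thr
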