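"""Synthetic 4D DSC-MRI bolus-passage phantoms with known timing ground truth.

The phantom emulates a T2*-weighted first pass: each brain voxel carries a
gamma-variate concentration curve C(t) = K (t - t0)^a exp(-(t - t0)/b) (zero
for t <= t0), converted to signal via S(t) = S0 exp(-k C(t) TE), with

* per-slice bolus arrival delays (the vessel-tree run-time effect the
  standardization step is designed to cancel),
* an embedded spherical hypoperfused lesion with delayed, dispersed and
  attenuated bolus,
* a small set of "artery" voxels per slice with early, narrow, high-amplitude
  curves (targets for automatic AIF selection),
* additive zero-mean Gaussian noise at a stated baseline SNR.

Two protocol presets mirror common clinical settings: a 3T scanner with
TR = 1.390 s / TE = 29 ms / 80 frames and a 1.5T scanner with TR = 0.689 s /
TE = 17 ms / 81 frames (sampling rates 0.72 Hz and 1.45 Hz).

Not simulated: head motion, susceptibility artifacts, partial-volume large
vessels, contrast extravasation. Noise is Gaussian on signal, not Rician —
the magnitude bias is negligible at the baseline SNRs simulated (>= 20).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .io import DscSeries, VolumeMask, save_series, save_mask, save_map, ParameterMap

#: Effective contrast rate constant k (a.u.) in S = S0 exp(-k C TE). With the
#: concentration curves normalized to unit peak this gives a ~40% peak signal
#: drop at TE = 29 ms, typical for a tissue first pass.
CONTRAST_RATE = 18.0

#: Acquisition presets (seconds / frame counts).
PROTOCOLS = {
    "3T_longTR": {"tr": 1.390, "te": 0.029, "n_frames": 80},
    "15T_shortTR": {"tr": 0.689, "te": 0.017, "n_frames": 81},
}


def _default_slice_delays(n_slices):
    # bolus fills the slice stack over ~2 s
    return tuple(np.round(np.linspace(0.0, 2.1, n_slices), 3))


@dataclass
class PhantomSpec:
    """Full description of a synthetic acquisition; identical specs (including
    seed) produce bit-identical phantoms."""

    grid_shape: tuple = (32, 32, 8)
    n_frames: int = 80
    tr: float = 1.390
    te: float = 0.029
    baseline_frames: int = 8
    s0: float = 100.0
    slice_delays: tuple = None  # defaults to a linear 0..2.1 s ramp
    tissue_arrival: float = 12.0
    gamma_shape: float = 3.0
    gamma_scale: float = 1.5
    lesion_center: tuple = (10, 16, 4)
    lesion_radius: float = 3.0
    lesion_delay: float = 10.0
    lesion_dispersion: float = 1.3
    lesion_amplitude: float = 0.7
    snr: float = 20.0
    seed: int = 0
    # AIF targets: early, narrow, high-amplitude voxels near each slice centre
    artery_lead: float = 1.0
    artery_amplitude: float = 3.0
    artery_width_factor: float = 0.6
    n_artery_per_slice: int = 4

    def __post_init__(self):
        self.grid_shape = tuple(int(v) for v in self.grid_shape)
        self.lesion_center = tuple(int(v) for v in self.lesion_center)
        if self.slice_delays is None:
            self.slice_delays = _default_slice_delays(self.grid_shape[2])
        self.slice_delays = tuple(float(v) for v in self.slice_delays)
        self.validate()

    def validate(self):
        nx, ny, nz = self.grid_shape
        if len(self.slice_delays) != nz:
            raise ValueError(
                f"slice_delays has {len(self.slice_delays)} entries for {nz} slices"
            )
        if self.baseline_frames < 3:
            raise ValueError("baseline_frames must be >= 3")
        if not self.snr > 0:
            raise ValueError(f"snr must be > 0; got {self.snr}")
        if not (0 < self.lesion_amplitude <= 1):
            raise ValueError("lesion_amplitude must be in (0, 1]")
        if self.lesion_dispersion < 1:
            raise ValueError("lesion_dispersion must be >= 1")
        cx, cy, cz = self.lesion_center
        r = self.lesion_radius
        if self.lesion_radius > 0 and not (
            r <= cx < nx - r and r <= cy < ny - r and r <= cz < nz - r
        ):
            raise ValueError(
                f"lesion sphere (center {self.lesion_center}, radius {r}) "
                f"does not lie inside grid {self.grid_shape}"
            )
        needed = (
            self.tissue_arrival
            + max(self.slice_delays)
            + self.lesion_delay
            + 4 * self.gamma_shape * self.gamma_scale
        )
        if self.n_frames * self.tr < needed:
            raise ValueError(
                f"acquisition covers {self.n_frames * self.tr:.1f} s but the bolus "
                f"needs {needed:.1f} s; increase n_frames or shorten timing"
            )

    # ---- plain-text (YAML) round trip -------------------------------------
    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self):
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["slice_delays"] = list(self.slice_delays)
        d["lesion_center"] = list(self.lesion_center)
        return d

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**d)

    @classmethod
    def from_protocol(cls, name, **overrides):
        """Spec preset for a named protocol ('3T_longTR' or '15T_shortTR')."""
        if name not in PROTOCOLS:
            raise ValueError(f"unknown protocol {name!r}; expected one of {sorted(PROTOCOLS)}")
        params = dict(PROTOCOLS[name])
        params.update(overrides)
        return cls(**params)


@dataclass
class PhantomTruth:
    """Ground truth accompanying a phantom: the noiseless per-voxel peak time
    (seconds; NaN outside the brain) and the lesion/brain/artery masks."""

    true_ttp: np.ndarray
    lesion_mask: VolumeMask
    brain_mask: VolumeMask
    artery_mask: VolumeMask


def _gamma_variate(t, t0, shape, scale):
    """Unit-peak gamma variate; peak at t0 + shape*scale, zero for t <= t0."""
    out = np.zeros_like(t, dtype=float)
    u = t - t0
    pos = u > 0
    tp = shape * scale
    out[pos] = (u[pos] / tp) ** shape * np.exp(shape - u[pos] / scale)
    return out


def _brain_mask(grid_shape):
    nx, ny, nz = grid_shape
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    rx, ry = 0.45 * nx, 0.45 * ny
    ellipse = ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0
    return np.repeat(ellipse[:, :, None], nz, axis=2)


def _sphere_mask(grid_shape, center, radius):
    if radius <= 0:
        return np.zeros(grid_shape, dtype=bool)
    nx, ny, nz = grid_shape
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    cx, cy, cz = center
    return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= radius**2


def _artery_mask(spec, brain, lesion):
    nx, ny, nz = spec.grid_shape
    mask = np.zeros(spec.grid_shape, dtype=bool)
    cx, cy = nx // 2, ny // 2
    offsets = [(0, 0), (1, 0), (0, 1), (1, 1), (-1, 0), (0, -1), (-1, -1), (1, -1), (-1, 1)]
    for z in range(nz):
        placed = 0
        for dx, dy in offsets:
            if placed >= spec.n_artery_per_slice:
                break
            i, j = cx + dx, cy + dy
            if 0 <= i < nx and 0 <= j < ny and brain[i, j, z] and not lesion[i, j, z]:
                mask[i, j, z] = True
                placed += 1
    return mask


def generate_phantom(spec: PhantomSpec):
    """Generate a phantom and its ground truth.

    Returns
    -------
    series : DscSeries
        Noisy 4D signal; outside the brain the signal is zero plus noise.
    truth : PhantomTruth
        Noiseless peak times and the geometry masks.
    """
    spec.validate()
    nx, ny, nz = spec.grid_shape
    brain = _brain_mask(spec.grid_shape)
    lesion = _sphere_mask(spec.grid_shape, spec.lesion_center, spec.lesion_radius)
    if not np.all(brain[lesion]):
        raise ValueError("lesion sphere extends outside the brain mask")
    arteries = _artery_mask(spec, brain, lesion)

    t = np.arange(spec.n_frames) * spec.tr

    # per-voxel curve parameters
    t0 = np.full(spec.grid_shape, np.nan)
    scale = np.full(spec.grid_shape, spec.gamma_scale)
    amp = np.ones(spec.grid_shape)
    for z in range(nz):
        t0[:, :, z] = spec.tissue_arrival + spec.slice_delays[z]
    t0[lesion] += spec.lesion_delay
    scale[lesion] *= spec.lesion_dispersion
    amp[lesion] = spec.lesion_amplitude
    t0[arteries] -= spec.artery_lead
    scale[arteries] = spec.gamma_scale * spec.artery_width_factor
    amp[arteries] = spec.artery_amplitude

    signal = np.zeros(spec.grid_shape + (spec.n_frames,))
    # evaluate curves per unique (t0, scale, amp) group: a handful per slice
    flat_brain = brain.ravel()
    keys = np.stack([t0.ravel(), scale.ravel(), amp.ravel()], axis=1)
    sig_flat = signal.reshape(-1, spec.n_frames)
    uniq, inverse = np.unique(keys[flat_brain], axis=0, return_inverse=True)
    brain_idx = np.flatnonzero(flat_brain)
    for g, (g_t0, g_scale, g_amp) in enumerate(uniq):
        curve = g_amp * _gamma_variate(t, g_t0, spec.gamma_shape, g_scale)
        s = spec.s0 * np.exp(-CONTRAST_RATE * curve * spec.te)
        sig_flat[brain_idx[inverse == g]] = s

    if np.isfinite(spec.snr):
        rng = np.random.default_rng(spec.seed)
        signal = signal + rng.normal(0.0, spec.s0 / spec.snr, size=signal.shape)

    true_ttp = np.where(brain, t0 + spec.gamma_shape * scale, np.nan)

    series = DscSeries(signal=signal, tr=spec.tr, te=spec.te)
    truth = PhantomTruth(
        true_ttp=true_ttp,
        lesion_mask=VolumeMask(lesion, role="lesion_truth"),
        brain_mask=VolumeMask(brain, role="brain"),
        artery_mask=VolumeMask(arteries, role="evaluation_region"),
    )
    return series, truth


def write_phantom(spec: PhantomSpec, outdir):
    """Generate and write a phantom (series, masks, truth TTP, spec echo)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    series, truth = generate_phantom(spec)
    save_series(series, outdir / "series.nii.gz")
    save_mask(truth.brain_mask, outdir / "brain_mask.nii.gz")
    save_mask(truth.lesion_mask, outdir / "lesion_mask.nii.gz")
    save_mask(truth.artery_mask, outdir / "artery_mask.nii.gz")
    ttp_img = ParameterMap(name="absTTP", values=truth.true_ttp)
    save_map(ttp_img, outdir / "true_ttp.nii.gz")
    spec.to_yaml(outdir / "phantom_spec.yaml")
    return series, truth
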