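"""Reference Tmax pipeline: gamma-variate fitting, automatic AIF selection and
truncated-SVD deconvolution of tissue concentration curves.

The tissue curve is modelled as C_t(t) = CBF * (AIF (*) R)(t); discretizing the
convolution gives a linear system solved by truncated SVD:

* sSVD — lower-triangular Toeplitz convolution matrix, singular values below
  ``lambda_rel`` of the maximum truncated (delay sensitive);
* oSVD — block-circulant embedding after zero-padding to 2N, with per-voxel
  oscillation-index-adaptive truncation (delay insensitive by construction).

Tmax is the time of the maximum of the recovered (scaled) residue function,
reported on the TR grid without sub-TR interpolation. For oSVD, residue
indices in the upper half of the circulant grid represent negative lags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, TransformerMixin

from .io import DscSeries, VolumeMask, ParameterMap, SENTINEL
from .preprocessing import TtpMap

DEFAULT_LAMBDA_REL = 0.20
DEFAULT_OI_THRESHOLD = 0.095


# --------------------------------------------------------------------------
# Gamma-variate pre-fit
# --------------------------------------------------------------------------
@dataclass
class GammaFit:
    params: dict  # K, t0, alpha, beta
    curve: np.ndarray
    success: bool


def _gamma_model(t, K, t0, alpha, beta):
    u = np.maximum(t - t0, 0.0)
    with np.errstate(invalid="ignore"):
        out = K * u**alpha * np.exp(-u / beta)
    return np.where(u > 0, out, 0.0)


_SSE_PENALTY = 1e300


def _loglinear_sse(t0, t, c, w):
    """Weighted log-linear gamma-variate solve at fixed t0; returns
    (sse, (K, alpha, beta)) with sse in the linear (concentration) domain."""
    u = t - t0
    ok = (u > 0) & (c > 0) & np.isfinite(c)
    if ok.sum() < 4:
        return _SSE_PENALTY, None
    X = np.stack([np.ones(ok.sum()), np.log(u[ok]), -u[ok]], axis=1)
    y = np.log(c[ok])
    ww = w[ok]
    try:
        coef, *_ = np.linalg.lstsq(X * ww[:, None], y * ww, rcond=None)
    except np.linalg.LinAlgError:
        return _SSE_PENALTY, None
    logK, alpha, inv_beta = coef
    if alpha <= 0 or inv_beta <= 0:
        return _SSE_PENALTY, None
    params = (np.exp(logK), alpha, 1.0 / inv_beta)
    fit = _gamma_model(t, params[0], t0, params[1], params[2])
    return float(np.nansum((fit - c) ** 2)), params


def fit_gamma_variate(curve, t_grid) -> GammaFit:
    """Gamma-variate fit of a concentration curve by log-linearization.

    For a trial bolus-arrival time t0 the model is linear in
    (ln K, alpha, 1/beta) on the log scale; t0 itself is found by a bracketed
    scalar minimization of the linear-domain residual (weights proportional
    to concentration counteract the log-domain distortion). Failure (flat
    curve, no positive peak, degenerate solve) is never fatal: the raw curve
    is passed through with ``success=False``.
    """
    from scipy.optimize import minimize_scalar

    curve = np.asarray(curve, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    peak = np.nanmax(curve) if np.isfinite(curve).any() else 0.0
    if not peak > 0:
        return GammaFit(params={}, curve=curve.copy(), success=False)
    ip = int(np.nanargmax(curve))
    dt = t[1] - t[0]
    w = np.clip(np.nan_to_num(curve), 0.0, None) / peak  # down-weight the noisy tail/log blowup
    # fit only the first pass: stop where the curve first falls below 30% of
    # the peak after the peak (tail points carry noise, not bolus shape)
    post = np.nonzero(curve[ip:] < 0.3 * peak)[0]
    stop = ip + int(post[0]) if post.size else curve.size
    w[stop:] = 0.0
    above = np.nonzero(curve[: ip + 1] > 0.1 * peak)[0]
    rise = t[above[0]] if above.size else max(t[ip] - 5 * dt, t[0])
    lo = max(t[0], rise - 4 * dt)
    hi = max(t[ip] - dt / 2, lo + dt / 4)
    # coarse grid bracket, then golden refinement of t0
    cand = np.linspace(lo, hi, 9)
    sses = [_loglinear_sse(c0, t, curve, w)[0] for c0 in cand]
    ibest = int(np.argmin(sses))
    if not np.isfinite(sses[ibest]):
        return GammaFit(params={}, curve=curve.copy(), success=False)
    blo = cand[max(ibest - 1, 0)]
    bhi = cand[min(ibest + 1, len(cand) - 1)]
    if bhi > blo:
        res = minimize_scalar(
            lambda x: _loglinear_sse(x, t, curve, w)[0],
            bounds=(blo, bhi),
            method="bounded",
            options={"xatol": dt * 1e-4},
        )
        t0 = float(res.x)
    else:
        t0 = float(cand[ibest])
    sse, params = _loglinear_sse(t0, t, curve, w)
    if params is None:
        return GammaFit(params={}, curve=curve.copy(), success=False)
    K, alpha, beta = params
    fitted = _gamma_model(t, K, t0, alpha, beta)
    if not np.isfinite(fitted).all() or fitted.max() <= 0:
        return GammaFit(params={}, curve=curve.copy(), success=False)
    return GammaFit(params={"K": K, "t0": t0, "alpha": alpha, "beta": beta}, curve=fitted, success=True)


# --------------------------------------------------------------------------
# AIF selection
# --------------------------------------------------------------------------
@dataclass
class Aif:
    """Arterial input function with the voxels and quality metrics behind it."""

    concentration: np.ndarray
    source_voxels: list
    peak_amplitude: float
    first_moment: float
    fwhm: float


def _fwhm(curve, tr):
    peak = curve.max()
    if peak <= 0:
        return np.inf
    above = np.nonzero(curve >= peak / 2.0)[0]
    if above.size == 0:
        return np.inf
    return (above[-1] - above[0] + 1) * tr


def select_aif(conc: DscSeries, ttp: TtpMap, brain: VolumeMask, n_candidates: int = 5) -> Aif:
    """Automatic AIF selection.

    Candidates are brain voxels in the lowest 1% of TTP *and* the top 5% of
    peak concentration (early, strong enhancement — arteries); they are
    ranked by ascending FWHM (sharpest bolus first) and the best
    ``n_candidates`` curves are averaged. Deterministic given the inputs.
    """
    if not brain.values.any():
        raise ValueError("brain mask is empty")
    data = conc.signal
    ok = brain.values & ttp.defined_mask & np.all(np.isfinite(data), axis=-1)
    if not ok.any():
        raise ValueError("no usable voxels for AIF selection; supply a manual AIF")
    ttp_vals = ttp.frames[ok] * ttp.tr
    peaks = data[ok].max(axis=-1)
    ttp_cut = np.quantile(ttp_vals, 0.01)
    peak_cut = np.quantile(peaks, 0.95)
    cand = (ttp_vals <= ttp_cut) & (peaks >= peak_cut)
    if not cand.any():
        raise ValueError(
            "no AIF candidates (early-TTP, high-peak voxels absent); supply a manual AIF"
        )
    coords = np.argwhere(ok)[cand]
    curves = data[ok][cand]
    widths = np.array([_fwhm(c, conc.tr) for c in curves])
    order = np.argsort(widths, kind="stable")
    n_use = min(n_candidates, order.size)
    chosen = order[:n_use]
    aif_curve = curves[chosen].mean(axis=0)
    aif_curve = np.maximum(aif_curve, 0.0)
    t = conc.frame_times
    mass = aif_curve.sum()
    first_moment = float((t * aif_curve).sum() / mass) if mass > 0 else np.nan
    return Aif(
        concentration=aif_curve,
        source_voxels=[tuple(int(v) for v in c) for c in coords[chosen]],
        peak_amplitude=float(aif_curve.max()),
        first_moment=first_moment,
        fwhm=float(_fwhm(aif_curve, conc.tr)),
    )


# --------------------------------------------------------------------------
# SVD deconvolution
# --------------------------------------------------------------------------
@dataclass
class ResidueOutput:
    """Scaled residue function R(t)*CBF with its Tmax (seconds) and, for
    oSVD, the oscillation index of the accepted solution."""

    residue: np.ndarray
    tmax: float
    oscillation_index: float = np.nan


def _oscillation_index(residue):
    """Mean absolute second difference, normalized by 2 L max|R| (Wu-style)."""
    r = np.asarray(residue)
    L = r.size
    rmax = np.abs(r).max()
    if rmax <= 0:
        return np.inf
    d2 = np.abs(r[2:] - 2 * r[1:-1] + r[:-2])
    return float(d2.sum() / (2.0 * L * rmax))


class SvdDeconvolver(BaseEstimator, TransformerMixin):
    """Truncated-SVD deconvolution against a fixed AIF, sklearn-style.

    Parameters
    ----------
    tr : float
        Frame spacing in seconds.
    mode : {"ssvd", "osvd"}
        Toeplitz truncated SVD vs block-circulant OI-regularized SVD.
    lambda_rel : float
        sSVD relative singular-value cutoff (fraction of the largest).
    oi_threshold : float
        oSVD oscillation-index acceptance level.

    ``fit`` takes the AIF concentration curve and precomputes the SVD;
    ``transform`` maps an (n_voxels, n_frames) curve matrix to scaled residue
    functions; :meth:`tmax` reduces them to per-voxel Tmax in seconds.
    """

    # relative-threshold ladder scanned by the OI-adaptive truncation
    _OSVD_LADDER = np.concatenate([[0.0], np.geomspace(1e-4, 0.5, 40)])

    def __init__(self, tr=1.0, mode="osvd", lambda_rel=DEFAULT_LAMBDA_REL, oi_threshold=DEFAULT_OI_THRESHOLD):
        self.tr = tr
        self.mode = mode
        self.lambda_rel = lambda_rel
        self.oi_threshold = oi_threshold

    def fit(self, aif, y=None):
        a = aif.concentration if isinstance(aif, Aif) else np.asarray(aif, dtype=float)
        if not np.any(a > 0):
            raise ValueError("AIF is identically zero")
        if self.mode not in ("ssvd", "osvd"):
            raise ValueError(f"mode must be 'ssvd' or 'osvd'; got {self.mode!r}")
        n = a.size
        self.n_frames_ = n
        if self.mode == "ssvd":
            # lower-triangular Toeplitz convolution matrix
            A = np.zeros((n, n))
            for j in range(n):
                A[j:, j] = a[: n - j]
            A *= self.tr
        else:
            # block-circulant embedding, zero-padded to 2N
            m = 2 * n
            apad = np.concatenate([a, np.zeros(n)])
            idx = (np.arange(m)[:, None] - np.arange(m)[None, :]) % m
            A = self.tr * apad[idx]
        self.u_, self.s_, self.vt_ = np.linalg.svd(A, full_matrices=False)
        return self

    # ------------------------------------------------------------------
    def _inverse_operator(self, rel_cutoff):
        s = self.s_
        inv = np.where(s >= rel_cutoff * s[0], 1.0 / np.where(s > 0, s, 1.0), 0.0)
        inv[s <= 0] = 0.0
        return (self.vt_.T * inv) @ self.u_.T

    def transform(self, curves):
        """Scaled residue functions for an (n_voxels, n_frames) curve array
        (a single curve is also accepted)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "s_")
        C = np.atleast_2d(np.asarray(curves, dtype=float))
        if C.shape[1] != self.n_frames_:
            raise ValueError("tissue curves and AIF are not on the same grid")
        if self.mode == "ssvd":
            Ainv = self._inverse_operator(self.lambda_rel)
            R = C @ Ainv.T
            self.oscillation_index_ = np.full(C.shape[0], np.nan)
            return R
        # oSVD: zero-pad, then per-voxel OI-adaptive truncation (scan the
        # ladder from least to most regularized, keep the first acceptable)
        m = 2 * self.n_frames_
        Cpad = np.concatenate([C, np.zeros_like(C)], axis=1)
        nv = C.shape[0]
        R = np.zeros((nv, m))
        oi = np.full(nv, np.inf)
        pending = np.arange(nv)
        last = None
        for cutoff in self._OSVD_LADDER:
            if pending.size == 0:
                break
            Ainv = self._inverse_operator(cutoff)
            cand = Cpad[pending] @ Ainv.T
            last = (pending, cand)
            oi_c = np.array([_oscillation_index(r) for r in cand])
            ok = oi_c <= self.oi_threshold
            accepted = pending[ok]
            R[accepted] = cand[ok]
            oi[accepted] = oi_c[ok]
            pending = pending[~ok]
        if pending.size and last is not None:
            # never met the OI criterion: keep the most regularized solution
            sel = np.isin(last[0], pending)
            R[pending] = last[1][sel]
            oi[pending] = [_oscillation_index(r) for r in last[1][sel]]
        self.oscillation_index_ = oi
        return R

    def tmax(self, curves):
        """Per-voxel Tmax (seconds, TR grid, earliest-tie rule)."""
        R = self.transform(curves)
        idx = np.argmax(R, axis=1)
        if self.mode == "osvd":
            m = R.shape[1]
            idx = np.where(idx >= m // 2, idx - m, idx)
        return idx * self.tr


def deconvolve(
    conc_voxel,
    aif,
    tr,
    mode="osvd",
    lambda_rel=DEFAULT_LAMBDA_REL,
    oi_threshold=DEFAULT_OI_THRESHOLD,
) -> ResidueOutput:
    """Single-voxel deconvolution (thin wrapper over :class:`SvdDeconvolver`)."""
    dec = SvdDeconvolver(tr=tr, mode=mode, lambda_rel=lambda_rel, oi_threshold=oi_threshold)
    dec.fit(aif)
    R = dec.transform(conc_voxel)[0]
    idx = int(np.argmax(R))
    if mode == "osvd" and idx >= R.size // 2:
        idx -= R.size
    oi = dec.oscillation_index_[0]
    return ResidueOutput(residue=R, tmax=idx * tr, oscillation_index=oi)


def tmax_map(
    conc: DscSeries,
    aif: Aif,
    brain: VolumeMask,
    mode="osvd",
    lambda_rel=DEFAULT_LAMBDA_REL,
    oi_threshold=DEFAULT_OI_THRESHOLD,
    gamma_fit=True,
) -> ParameterMap:
    """Voxelwise Tmax over the brain mask; sentinel outside and for
    unusable (non-finite) voxels.

    With ``gamma_fit`` (default), each tissue curve is replaced by its
    gamma-variate fit before deconvolution (failed fits pass through raw) —
    the conventional pre-fit of Tmax pipelines, never used for the
    distribution-based parameters.
    """
    if brain.values.shape != conc.spatial_shape:
        raise ValueError("brain mask does not match series grid")
    data = conc.signal
    ok = brain.values & np.all(np.isfinite(data), axis=-1)
    out = np.full(conc.spatial_shape, SENTINEL)
    if not ok.any():
        return ParameterMap(name="Tmax", values=out)
    curves = data[ok]
    if gamma_fit:
        t = conc.frame_times
        curves = np.stack([fit_gamma_variate(c, t).curve for c in curves])
    dec = SvdDeconvolver(tr=conc.tr, mode=mode, lambda_rel=lambda_rel, oi_threshold=oi_threshold)
    dec.fit(aif)
    out[ok] = dec.tmax(curves)
    return ParameterMap(name="Tmax", values=out)
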