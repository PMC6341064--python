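"""The TTP distribution curve (TDC) and its generic double-Gaussian model.

The envelope of the main first-pass peak of the brain-wide TTP histogram — the
TDC — is modelled by a two-component Gaussian mixture fitted by
expectation-maximization,

    TDC_f(t) = k1 N(t; mu1, sigma1) + k2 N(t; mu2, sigma2),   k1 + k2 = 1,

with components reported in ascending-mean order (early arterial/capillary
enhancement first, late venous enhancement second). A voxel's absolute TTP is
mapped to the dimensionless score

    z_f = k1 (ttp - mu1)/sigma1 + k2 (ttp - mu2)/sigma2,

the probability-weighted sum of per-component z-scores; with k = (1, 0) this
is exactly the classical z-score. Because both terms increase in ttp, z_f is
a strictly increasing (affine) function of ttp, so thresholding in z_f is
equivalent to thresholding in ttp.

The venous inflection point IPv — the latest curvature change on the
descending (katacrotic, wash-out) limb of the fitted density — serves as the
critical-perfusion threshold for z_f and stdZ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import brentq
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocessing import FirstPassWindow, TtpMap

_LOG2PI = np.log(2.0 * np.pi)


# --------------------------------------------------------------------------
# TDC histogram
# --------------------------------------------------------------------------
@dataclass
class TdcHistogram:
    """TTP histogram over the first-pass window, bin width = TR."""

    bin_edges: np.ndarray  # seconds, len = n_bins + 1
    counts: np.ndarray
    density: np.ndarray
    source_voxels: int
    window: FirstPassWindow

    def to_csv(self, path):
        import pandas as pd

        pd.DataFrame(
            {
                "bin_left_s": self.bin_edges[:-1],
                "bin_right_s": self.bin_edges[1:],
                "count": self.counts,
                "density": self.density,
            }
        ).to_csv(path, index=False)


def build_tdc(ttp: TtpMap, window: FirstPassWindow, voi=None, min_voxels: int = 50) -> TdcHistogram:
    """Histogram of defined TTP values restricted to the first-pass window.

    ``voi`` optionally restricts to one VOI: either a slice index (int) or a
    boolean 3D selector. Bin width is one TR; bins span exactly the window.
    """
    sel = ttp.defined_mask.copy()
    if voi is not None:
        if np.isscalar(voi):
            keep = np.zeros_like(sel)
            keep[:, :, int(voi)] = True
            sel &= keep
        else:
            sel &= np.asarray(voi, dtype=bool)
    frames = ttp.frames[sel]
    frames = frames[(frames >= window.start_frame) & (frames < window.end_frame)]
    if frames.size < min_voxels:
        raise ValueError(
            f"too few TTP voxels in selection (VOI={voi!r}): {frames.size} < {min_voxels}"
        )
    n_bins = window.n_frames
    counts = np.bincount(frames - window.start_frame, minlength=n_bins).astype(float)
    edges = (np.arange(n_bins + 1) + window.start_frame - 0.5) * ttp.tr
    density = counts / counts.sum()
    return TdcHistogram(
        bin_edges=edges,
        counts=counts,
        density=density,
        source_voxels=int(frames.size),
        window=window,
    )


def empirical_quantile(values, p: float) -> float:
    """Lower-tail quantile by linear interpolation between order statistics.

    Accepts a raw value sample or a :class:`TdcHistogram` (expanded to the
    per-voxel sample it was built from, all values on the TR bin grid).
    """
    if not 0 < p < 1:
        raise ValueError(f"quantile probability must be in (0, 1); got {p}")
    if isinstance(values, TdcHistogram):
        lefts = (values.bin_edges[:-1] + values.bin_edges[1:]) / 2.0
        sample = np.repeat(lefts, values.counts.astype(int))
    else:
        sample = np.asarray(values, dtype=float)
        sample = sample[np.isfinite(sample)]
    if sample.size == 0:
        raise ValueError("empty sample")
    return float(np.quantile(sample, p, method="linear"))


# --------------------------------------------------------------------------
# Double-Gaussian mixture (EM)
# --------------------------------------------------------------------------
class DegenerateMixtureError(RuntimeError):
    """All EM restarts collapsed a component (sigma -> 0)."""


@dataclass
class TdcModel:
    """Fitted generic double-Gaussian TDC model (ascending-mean order)."""

    mu: tuple
    sigma: tuple
    k: tuple
    loglik: float = np.nan
    n_iter: int = 0
    converged: bool = True

    def __post_init__(self):
        self.mu = tuple(float(v) for v in self.mu)
        self.sigma = tuple(float(v) for v in self.sigma)
        self.k = tuple(float(v) for v in self.k)
        if len(self.mu) != 2 or len(self.sigma) != 2 or len(self.k) != 2:
            raise ValueError("TDC model has exactly two components")
        if any(s <= 0 for s in self.sigma):
            raise ValueError(f"component SDs must be positive; got {self.sigma}")
        if abs(sum(self.k) - 1.0) > 1e-9:
            raise ValueError(f"component weights must sum to 1; got {self.k}")

    # ---- density ----------------------------------------------------------
    def pdf(self, t):
        t = np.asarray(t, dtype=float)
        out = 0.0
        for m, s, w in zip(self.mu, self.sigma, self.k):
            out = out + w * np.exp(-0.5 * ((t - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))
        return out

    def cdf(self, t):
        from scipy.stats import norm

        t = np.asarray(t, dtype=float)
        out = 0.0
        for m, s, w in zip(self.mu, self.sigma, self.k):
            out = out + w * norm.cdf(t, loc=m, scale=s)
        return out

    def dpdf(self, t):
        t = np.asarray(t, dtype=float)
        out = 0.0
        for m, s, w in zip(self.mu, self.sigma, self.k):
            phi = np.exp(-0.5 * ((t - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))
            out = out - w * phi * (t - m) / s**2
        return out

    def d2pdf(self, t):
        t = np.asarray(t, dtype=float)
        out = 0.0
        for m, s, w in zip(self.mu, self.sigma, self.k):
            phi = np.exp(-0.5 * ((t - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))
            out = out + w * phi * ((t - m) ** 2 - s**2) / s**4
        return out

    # ---- z_f transform -----------------------------------------------------
    def zf(self, ttp):
        """z_f = sum_i k_i (ttp - mu_i) / sigma_i (strictly increasing in ttp)."""
        ttp = np.asarray(ttp, dtype=float)
        return sum(w * (ttp - m) / s for m, s, w in zip(self.mu, self.sigma, self.k))

    def zf_inverse(self, z):
        """ttp at a given z_f (the transform is affine in ttp)."""
        a = sum(w / s for s, w in zip(self.sigma, self.k))
        b = sum(-w * m / s for m, s, w in zip(self.mu, self.sigma, self.k))
        return (np.asarray(z, dtype=float) - b) / a

    # ---- JSON round trip ---------------------------------------------------
    def to_json(self, path=None, extra=None):
        d = asdict(self)
        d["loglik"] = None if not np.isfinite(self.loglik) else self.loglik
        if extra:
            d.update(extra)
        if path is None:
            return json.dumps(d, indent=2)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            mu=d["mu"],
            sigma=d["sigma"],
            k=d["k"],
            loglik=d.get("loglik") if d.get("loglik") is not None else np.nan,
            n_iter=d.get("n_iter", 0),
            converged=d.get("converged", True),
        )


class TdcMixtureModel(BaseEstimator, TransformerMixin):
    """Two-component 1-D Gaussian mixture fitted by EM, sklearn-style.

    Parameters
    ----------
    tol : float
        Convergence tolerance on the log-likelihood increase.
    max_iter : int
        Maximum EM iterations per restart.
    n_restarts : int
        Seeded restarts; the best log-likelihood wins. The first restart
        initializes means at the 40th/90th sample percentiles, SDs at half
        the sample SD, weights (0.8, 0.2); later restarts perturb the means.
    random_state : int or None
        Seed for the restart perturbations.

    Attributes (after fit)
    ----------------------
    means_, sigmas_, weights_ : ndarray, shape (2,), ascending-mean order
    loglik_ : float, final log-likelihood
    loglik_path_ : ndarray, per-iteration log-likelihood of the winning restart
    n_iter_ : int
    converged_ : bool
    model_ : TdcModel
    """

    def __init__(self, tol=1e-6, max_iter=500, n_restarts=5, random_state=None):
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _em_run(self, x, mu, sigma, k):
        n = x.size
        floor = 1e-8 * max(x.std(), 1e-12)
        path = []
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            # E-step (log domain)
            logp = np.empty((n, 2))
            for i in range(2):
                logp[:, i] = (
                    np.log(k[i])
                    - np.log(sigma[i])
                    - 0.5 * _LOG2PI
                    - 0.5 * ((x - mu[i]) / sigma[i]) ** 2
                )
            m = logp.max(axis=1)
            lse = m + np.log(np.exp(logp - m[:, None]).sum(axis=1))
            ll = float(lse.sum())
            path.append(ll)
            if len(path) > 1 and path[-1] - path[-2] < self.tol:
                converged = True
                break
            resp = np.exp(logp - lse[:, None])
            # M-step
            nk = resp.sum(axis=0)
            if np.any(nk < 1e-10):
                raise DegenerateMixtureError("a component lost all responsibility")
            k = nk / n
            mu = resp.T @ x / nk
            var = np.einsum("ni,n->i", resp, x**2) / nk - mu**2
            sigma = np.sqrt(np.maximum(var, 0.0))
            if np.any(sigma < floor):
                raise DegenerateMixtureError("a component SD collapsed toward zero")
        return mu, sigma, k, np.asarray(path), converged, it

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        x = x[np.isfinite(x)]
        if x.size < 100:
            raise ValueError(f"mixture fit needs >= 100 finite values; got {x.size}")
        rng = np.random.default_rng(self.random_state)
        sd = x.std()
        base_mu = np.percentile(x, [40.0, 90.0])
        best = None
        for r in range(self.n_restarts):
            mu0 = base_mu.copy()
            if r > 0:
                mu0 = mu0 + rng.normal(0.0, sd / 4.0, size=2)
            sigma0 = np.array([sd / 2.0, sd / 2.0])
            k0 = np.array([0.8, 0.2])
            try:
                res = self._em_run(x, mu0, sigma0, k0)
            except DegenerateMixtureError:
                continue
            if best is None or res[3][-1] > best[3][-1]:
                best = res
        if best is None:
            raise DegenerateMixtureError("all EM restarts degenerated")
        mu, sigma, k, path, converged, n_iter = best
        order = np.argsort(mu)
        self.means_ = mu[order]
        self.sigmas_ = sigma[order]
        self.weights_ = k[order] / k.sum()
        self.loglik_ = float(path[-1])
        self.loglik_path_ = path
        self.n_iter_ = int(n_iter)
        self.converged_ = bool(converged)
        self.model_ = TdcModel(
            mu=tuple(self.means_),
            sigma=tuple(self.sigmas_),
            k=tuple(self.weights_),
            loglik=self.loglik_,
            n_iter=self.n_iter_,
            converged=self.converged_,
        )
        return self

    def transform(self, X):
        """Map TTP values to z_f scores (shape preserved)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        return self.model_.zf(X)


def fit_tdc_model(values, n_components: int = 2, seed=None, tol=1e-6, max_iter=500, n_restarts=5) -> TdcModel:
    """EM fit of the double-Gaussian TDC model (thin wrapper over
    :class:`TdcMixtureModel`)."""
    if n_components != 2:
        raise ValueError("the TDC model has a fixed two components")
    est = TdcMixtureModel(tol=tol, max_iter=max_iter, n_restarts=n_restarts, random_state=seed)
    est.fit(values)
    return est.model_


# --------------------------------------------------------------------------
# z_f transform (map-level wrapper)
# --------------------------------------------------------------------------
def zf_transform(ttp, model: TdcModel):
    """z_f score of a TTP value/array, or the z_f ParameterMap of a TtpMap."""
    if isinstance(ttp, TtpMap):
        from .io import ParameterMap, SENTINEL

        vals = np.where(ttp.defined_mask, model.zf(np.where(ttp.defined_mask, ttp.frames * ttp.tr, 0.0)), SENTINEL)
        return ParameterMap(name="z_f", values=vals)
    return model.zf(ttp)


# --------------------------------------------------------------------------
# Venous inflection point
# --------------------------------------------------------------------------
@dataclass
class IpvThreshold:
    """Critical-perfusion threshold at the venous inflection point."""

    ttp_at_ipv: float
    zf_at_ipv: float
    method: str


def ipv_threshold(model: TdcModel, grid_step: float = 0.1) -> IpvThreshold:
    """Locate the venous inflection point IPv of the fitted TDC_f.

    Sign changes of the analytic second derivative of the mixture density are
    bracketed on a dense grid (spacing ``grid_step``, typically TR/10) over
    [mu1, mu2 + 4 sigma2]; among brackets lying on the descending (wash-out)
    limb (density slope < 0) the latest is kept and polished by Brent root
    finding. Fallback when no root is bracketed: mu2 + sigma2.
    """
    mu1, mu2 = model.mu
    sig2 = model.sigma[1]
    lo, hi = mu1, mu2 + 4.0 * sig2
    if hi <= lo:
        hi = lo + 4.0 * sig2
    t = np.arange(lo, hi + grid_step, grid_step)
    f2 = model.d2pdf(t)
    f1 = model.dpdf(t)
    sign = np.sign(f2)
    idx = np.nonzero((sign[:-1] * sign[1:] < 0) & (f1[:-1] < 0))[0]
    if idx.size == 0:
        ttp = mu2 + sig2
        method = "fallback_mu2_plus_sigma2"
    else:
        i = idx[-1]
        ttp = float(brentq(model.d2pdf, t[i], t[i + 1], xtol=1e-12))
        method = "descending_limb_second_derivative_root"
    return IpvThreshold(ttp_at_ipv=float(ttp), zf_at_ipv=float(model.zf(ttp)), method=method)
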