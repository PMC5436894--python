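"""Vector-autoregressive model fitting and frequency-resolved (conditional)
Granger causality.

A VAR(p) model U_t = sum_k A_k U_{t-k} + e_t with residual covariance Sigma
yields the spectral transfer function H(lambda) = (I - sum_k A_k
e^{-i k lambda})^{-1} and the cross power spectral density S = H Sigma H*.
The spectral Granger causality from Y to X is

    f_{Y->X}(lambda) = ln |S_xx| / |S_xx - H'_xy Sigma'_yy H'_xy*|

after rotating the residuals so that the X and Y innovations are
uncorrelated (the rotation leaves the causality invariant).  The
denominator is the "intrinsic" part of S_xx, the numerator the total, so
the measure quantifies how much of X's spectral power at each frequency is
inherited from Y's innovations.

The conditional variant f_{Y->X|Z} discounts a common driver Z (here: the
shared alpha modulation current).  It follows the classical two-model
construction: a reduced VAR on (X, Z) whitens X against its own history
and Z's, and the full (X, Y, Z) model is expressed in that whitened frame;
what Y's innovations still explain there is the conditional causality.

Model order is chosen by AIC; multi-trial data are pooled by stacking the
per-trial regression blocks (each trial loses its first p samples).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VarModel",
    "GcSpectrum",
    "fit_var",
    "spectral_gc",
    "conditional_spectral_gc",
    "pairwise_spectral_gc",
    "time_domain_gc",
    "sliding_gc",
]


class UnstableModelError(ValueError):
    """Raised when the fitted VAR has a companion spectral radius >= 1."""


@dataclass
class VarModel:
    """Fitted VAR(p): coefficient matrices and residual covariance."""

    coeffs: np.ndarray  # shape (p, n_channels, n_channels)
    sigma: np.ndarray  # residual covariance, (n_channels, n_channels)

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    def spectral_radius(self) -> float:
        p, n, _ = self.coeffs.shape
        comp = np.zeros((n * p, n * p))
        comp[:n, :] = self.coeffs.transpose(1, 0, 2).reshape(n, n * p)
        if p > 1:
            comp[n:, :-n] = np.eye(n * (p - 1))
        return float(np.max(np.abs(np.linalg.eigvals(comp))))

    def transfer_function(self, freqs: np.ndarray, fs: float = 1000.0) -> np.ndarray:
        """H(lambda) for each frequency in Hz; shape (n_freqs, n, n)."""
        lam = 2 * np.pi * np.asarray(freqs, dtype=float) / fs
        p, n, _ = self.coeffs.shape
        k = np.arange(1, p + 1)
        phase = np.exp(-1j * lam[:, None] * k[None, :])  # (n_freqs, p)
        A_f = np.tensordot(phase, self.coeffs, axes=(1, 0))  # (n_freqs, n, n)
        return np.linalg.inv(np.eye(n)[None] - A_f)


@dataclass
class GcSpectrum:
    freqs: np.ndarray
    values: np.ndarray  # f_{source->target}(lambda), >= 0
    source: int
    target: int
    conditioning: str = "none"


def _stack_trials(trials) -> np.ndarray:
    x = np.asarray(trials, dtype=float)
    if x.ndim == 2:
        x = x[None]
    if x.ndim != 3:
        raise ValueError("expected (channels, time) or (trials, channels, time)")
    return x


def _fit_fixed_order(data: np.ndarray, p: int):
    """Least-squares VAR(p) fit pooled over trials.

    data: (trials, channels, time).  Returns (coeffs, sigma, n_obs, logdet).
    """
    n_trials, n_ch, T = data.shape
    if T <= p:
        raise ValueError("trials shorter than model order")
    if np.var(data, axis=-1).min() <= 0:
        raise ValueError("constant channel: singular covariance")
    Y_blocks, X_blocks = [], []
    for m in range(n_trials):
        x = data[m]
        Y_blocks.append(x[:, p:].T)  # (T-p, n_ch)
        lagged = [x[:, p - k : T - k].T for k in range(1, p + 1)]
        X_blocks.append(np.hstack(lagged))  # (T-p, n_ch*p)
    Y = np.vstack(Y_blocks)
    X = np.vstack(X_blocks)
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ B
    n_obs = Y.shape[0]
    sigma = resid.T @ resid / (n_obs - n_ch * p)
    coeffs = B.reshape(p, n_ch, n_ch).transpose(0, 2, 1)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise ValueError("singular residual covariance (degenerate input)")
    return coeffs, sigma, n_obs, logdet


def fit_var(trials, max_order: int = 20, order: int | None = None) -> VarModel:
    """Fit a VAR by least squares, selecting the order by AIC up to
    ``max_order`` (or at a fixed ``order`` if given).

    Raises ``UnstableModelError`` if the selected model is not stable and
    ``ValueError`` on degenerate (e.g. constant) input.
    """
    data = _stack_trials(trials)
    n_trials, n_ch, T = data.shape
    if order is not None:
        candidates = [order]
    else:
        max_order = min(max_order, (T - 1) // max(2, n_ch))
        candidates = range(1, max_order + 1)
        best, best_aic = None, np.inf
        for p in candidates:
            coeffs, sigma, n_obs, logdet = _fit_fixed_order(data, p)
            aic = logdet + 2.0 * p * n_ch * n_ch / n_obs
            if aic < best_aic:
                best_aic, best = aic, p
        candidates = [best]
    coeffs, sigma, _, _ = _fit_fixed_order(data, candidates[0])
    model = VarModel(coeffs=coeffs, sigma=sigma)
    if model.spectral_radius() >= 1.0:
        raise UnstableModelError(
            f"unstable VAR fit (spectral radius {model.spectral_radius():.3f})"
        )
    return model


def _rotate_out(sigma: np.ndarray, keep: np.ndarray, against: np.ndarray):
    """Return the transform P that decorrelates ``keep`` rows of the
    residuals from ``against`` rows: e_keep <- e_keep - C e_against."""
    n = sigma.shape[0]
    P = np.eye(n)
    S_ka = sigma[np.ix_(keep, against)]
    S_aa = sigma[np.ix_(against, against)]
    P[np.ix_(keep, against)] = -S_ka @ np.linalg.inv(S_aa)
    return P


def spectral_gc(
    model: VarModel,
    freqs,
    source: int = 1,
    target: int = 0,
    fs: float = 1000.0,
) -> GcSpectrum:
    """Unconditional spectral Granger causality source -> target.

    Valid for a bivariate model or for a pair of channels of a larger model
    (the remaining channels are marginalized implicitly, which is exact only
    for the bivariate case; use ``conditional_spectral_gc`` to condition).
    """
    freqs = np.asarray(freqs, dtype=float)
    sigma = model.sigma
    # Rotate residuals so the source innovation is uncorrelated with the
    # target innovation (leaves the causality invariant).
    P = _rotate_out(sigma, keep=np.array([source]), against=np.array([target]))
    sigma_r = P @ sigma @ P.T
    H = model.transfer_function(freqs, fs) @ np.linalg.inv(P)
    s_xx = np.einsum("fij,jk,fik->f", H[:, [target], :], sigma, H[:, [target], :].conj()).real
    h_xy = H[:, target, source]
    causal = (np.abs(h_xy) ** 2) * sigma_r[source, source]
    intrinsic = np.maximum(s_xx - causal, np.finfo(float).tiny)
    vals = np.log(s_xx / intrinsic)
    return GcSpectrum(freqs=freqs, values=np.maximum(vals, 0.0), source=source, target=target)


def pairwise_spectral_gc(trials, freqs, max_order: int = 20, order: int | None = None):
    """Convenience: fit a bivariate VAR on (x, y) trials and return both
    directed spectra (x->y, y->x)."""
    model = fit_var(trials, max_order=max_order, order=order)
    return (
        spectral_gc(model, freqs, source=0, target=1),
        spectral_gc(model, freqs, source=1, target=0),
        model,
    )


def time_domain_gc(trials, source: int = 1, target: int = 0, order: int | None = None,
                   max_order: int = 20) -> float:
    """Time-domain Granger causality ln(var_reduced / var_full) from two
    nested regressions; the frequency average of the spectral measure."""
    data = _stack_trials(trials)
    full = fit_var(data, max_order=max_order, order=order)
    p = full.order
    reduced_data = data[:, [target], :]
    _, sigma_red, _, _ = _fit_fixed_order(reduced_data, p)
    return float(np.log(sigma_red[0, 0] / full.sigma[target, target]))


def conditional_spectral_gc(
    x_trials,
    y_trials,
    z_trials,
    freqs,
    max_order: int = 20,
    order: int | None = None,
    fs: float = 1000.0,
) -> GcSpectrum:
    """Spectral Granger causality y -> x conditioned on z.

    Fits a reduced VAR on (x, z) and a full VAR on (x, y, z) at the same
    order, expresses the full model in the frame where the reduced model's
    x-innovations are white, and measures what y's innovations explain
    there.  When z is independent of both signals this reduces to the
    unconditional value; when z commonly drives both, the conditional
    causality collapses toward zero.
    """
    freqs = np.asarray(freqs, dtype=float)
    x = np.atleast_2d(np.asarray(x_trials, dtype=float))
    y = np.atleast_2d(np.asarray(y_trials, dtype=float))
    z = np.atleast_2d(np.asarray(z_trials, dtype=float))
    if not (x.shape == y.shape == z.shape):
        raise ValueError("x, y, z trials must share shape")
    full_data = np.stack([x, y, z], axis=1)  # (trials, 3, T)
    red_data = np.stack([x, z], axis=1)
    # Guard against collinearity of z with x or y.
    for other, name in ((x, "x"), (y, "y")):
        r = np.corrcoef(z.ravel(), other.ravel())[0, 1]
        if np.abs(r) > 0.999:
            raise ValueError(f"z is collinear with {name}")
    full = fit_var(full_data, max_order=max_order, order=order)
    p = full.order
    red_coeffs, red_sigma, _, _ = _fit_fixed_order(red_data, p)
    reduced = VarModel(coeffs=red_coeffs, sigma=red_sigma)

    H = full.transfer_function(freqs, fs)  # (f, 3, 3), order (x, y, z)
    G = reduced.transfer_function(freqs, fs)  # (f, 2, 2), order (x, z)
    nf = freqs.size
    G_emb = np.zeros((nf, 3, 3), dtype=complex)
    G_emb[:, 0, 0] = G[:, 0, 0]
    G_emb[:, 0, 2] = G[:, 0, 1]
    G_emb[:, 2, 0] = G[:, 1, 0]
    G_emb[:, 2, 2] = G[:, 1, 1]
    G_emb[:, 1, 1] = 1.0
    Q = np.linalg.solve(G_emb, H)  # G_emb^{-1} H, per frequency

    # Decorrelate y's innovations from (x, z) so its contribution is pure.
    P = _rotate_out(full.sigma, keep=np.array([1]), against=np.array([0, 2]))
    Pinv = np.linalg.inv(P)
    Qt = Q @ Pinv
    sigma_t = P @ full.sigma @ P.T
    causal = (np.abs(Qt[:, 0, 1]) ** 2) * sigma_t[1, 1]
    total = red_sigma[0, 0]
    intrinsic = np.maximum(total - causal, np.finfo(float).tiny)
    vals = np.maximum(np.log(total / intrinsic), 0.0)
    return GcSpectrum(freqs=freqs, values=vals, source=1, target=0, conditioning="z")


def sliding_gc(
    x,
    y,
    window: float = 500.0,
    step: float = 100.0,
    band: tuple[float, float] = (30.0, 50.0),
    fs: float = 1000.0,
    order: int | None = 8,
):
    """Directed gamma-band GC in sliding windows over a single long pair.

    Returns a list of dicts with window start (ms), both band-mean GC
    values, and the dominant direction label ('x->y' or 'y->x').
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if window < 200:
        raise ValueError("window must be at least 200 ms")
    n_win = int(round(window * fs / 1000.0))
    n_step = int(round(step * fs / 1000.0))
    if n_win > x.size:
        raise ValueError("window longer than the data")
    freqs = np.linspace(band[0], band[1], 11)
    out = []
    for start in range(0, x.size - n_win + 1, n_step):
        seg = np.stack([x[start : start + n_win], y[start : start + n_win]])
        seg = seg - seg.mean(axis=1, keepdims=True)
        try:
            gc_xy, gc_yx, _ = pairwise_spectral_gc(seg, freqs, order=order)
        except (ValueError, UnstableModelError):
            continue
        fxy = float(gc_xy.values.mean())
        fyx = float(gc_yx.values.mean())
        out.append(
            {
                "start_ms": start / fs * 1000.0,
                "gc_xy": fxy,
                "gc_yx": fyx,
                "dominant": "x->y" if fxy >= fyx else "y->x",
            }
        )
    return out
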