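"""Low-pass smoothing of window signals via the discrete wavelet transform.

Each channel of a window is decomposed one or more levels with an
orthogonal filter pair (h, g); the high-frequency detail coefficients are
discarded and the low-frequency approximation coefficients are kept as a
decimated, smoothed signal. Under the defaults (Daubechies-4, one level,
symmetric padding) a length-50 window becomes length 28:
``floor((50 + 8 - 1) / 2) = 28``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .data import WindowedDataset


@dataclass(frozen=True)
class WaveletConfig:
    """Choice of wavelet family, decomposition depth and boundary handling.

    Parameters
    ----------
    family : str
        PyWavelets name of an orthogonal wavelet with a finite filter pair
        (e.g. ``"db4"``: Daubechies with 4 vanishing moments, 8 taps).
    level : int
        Decomposition depth; the level-``level`` approximation is returned.
    padding : str
        Boundary extension mode. ``"symmetric"`` (default) mirrors the
        signal; ``"periodization"`` yields a non-redundant orthonormal
        transform (exact energy conservation).
    """

    family: str = "db4"
    level: int = 1
    padding: str = "symmetric"

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError("level must be >= 1")
        try:
            w = pywt.Wavelet(self.family)
        except ValueError as e:
            raise ValueError(f"unknown wavelet family {self.family!r}") from e
        if not w.orthogonal:
            raise ValueError(f"wavelet family {self.family!r} is not orthogonal")

    @property
    def filter_length(self) -> int:
        return pywt.Wavelet(self.family).dec_len


def approx_length(n: int, cfg: WaveletConfig) -> int:
    """Output length of :func:`smooth_window` on a length-``n`` signal."""
    for _ in range(cfg.level):
        n = pywt.dwt_coeff_len(n, cfg.filter_length, mode=cfg.padding)
    return n


def smooth_window(x: np.ndarray, cfg: WaveletConfig = WaveletConfig()) -> np.ndarray:
    """Level-``cfg.level`` approximation coefficients of a 1-D signal.

    Convolves with the scaling (low-pass) filter and downsamples by two at
    each level, discarding the detail branch. For level 1 with symmetric
    padding the output length is ``floor((N + L - 1) / 2)`` for filter
    length ``L``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("smooth_window expects a 1-D signal")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    if len(x) < cfg.filter_length:
        raise ValueError(
            f"signal length {len(x)} is shorter than the {cfg.family} "
            f"filter length {cfg.filter_length}"
        )
    a = x
    for _ in range(cfg.level):
        a, _ = pywt.dwt(a, cfg.family, mode=cfg.padding)
    return a


def dwt_single(
    x: np.ndarray, cfg: WaveletConfig = WaveletConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """One-level (approximation, detail) pair; used for energy checks."""
    x = np.asarray(x, dtype=float)
    return pywt.dwt(x, cfg.family, mode=cfg.padding)


def smooth_array(X: np.ndarray, cfg: WaveletConfig = WaveletConfig()) -> np.ndarray:
    """Apply :func:`smooth_window` along axis 1 of a (N, T, S, C) stack."""
    N, T, S, C = X.shape
    T_out = approx_length(T, cfg)
    if N == 0:
        return np.empty((0, T_out, S, C), dtype=X.dtype)
    # pywt.dwt vectorizes along an axis; fold all non-time axes into one batch
    flat = np.moveaxis(X.astype(float), 1, -1).reshape(-1, T)  # (N*S*C, T)
    try:
        a = flat
        for _ in range(cfg.level):
            a, _ = pywt.dwt(a, cfg.family, mode=cfg.padding, axis=-1)
    except ValueError as e:
        raise ValueError(f"wavelet smoothing failed: {e}") from e
    return np.moveaxis(a.reshape(N, S, C, T_out), -1, 1)


def smooth_dataset(
    ds: WindowedDataset, cfg: WaveletConfig = WaveletConfig()
) -> WindowedDataset:
    """Replace every channel of every window by its approximation.

    Window length shrinks accordingly (50 -> 28 under the defaults);
    labels and class names are unchanged.
    """
    T_out = approx_length(ds.X.shape[1], cfg)
    out = smooth_array(ds.X, cfg)
    meta = dict(ds.metadata)
    meta["wavelet"] = {
        "family": cfg.family,
        "level": cfg.level,
        "padding": cfg.padding,
    }
    return WindowedDataset(
        out, ds.y, list(ds.class_names), T_out, ds.step, meta
    )
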