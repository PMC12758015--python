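"""Depth-gated spectral transfer function between two ultrasound machines.

The received spectrum factors as I(f, x) = S(f, x) P(f, x). Imaging one
calibration phantom with both machines cancels the tissue term, so the ratio
of the two machines' depth-gated spectra isolates the system-response ratio

    Gamma(f, x) = S_victim(f, x) / S_perpetrator(f, x),

estimated here as the square root of the ratio of view- and line-averaged
tapered periodograms per depth window. Because raw spectral division amplifies
out-of-band noise, the applied form is the Wiener-regularized magnitude

    Gamma_W = |Gamma|^-1 / (|Gamma|^-2 + SNR^-1),

with per-depth SNR measured against the noise floor outside the analysis
bandwidth. Multiplying perpetrator spectra by Gamma_W maps them into the
victim machine's domain (X_perp -> X_perp->victim); phase is preserved from
the input, since speckle phase carries the tissue term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import get_window

from .preprocess import PatchSet
from .rf_sim import RFFrame

__all__ = [
    "DepthGrid",
    "DepthSpectrum",
    "TransferFunction",
    "depth_gated_spectrum",
    "estimate_snr",
    "compute_gamma",
    "wiener_gamma",
    "apply_gamma",
    "apply_gamma_patches",
    "log_spectral_distance",
    "WienerTransferFunction",
]

SNR_CAP = 1e6


@dataclass(frozen=True)
class DepthGrid:
    """Depth-gating grid: tapered analysis windows along the axial axis."""

    window_length: int = 200
    window_overlap: float = 0.5
    start_offset: int = 0
    window_taper: str = "hann"

    def __post_init__(self) -> None:
        if not 0 <= self.window_overlap < 1:
            raise ValueError("window_overlap must lie in [0, 1)")
        if self.window_length < 4 or self.start_offset < 0:
            raise ValueError("invalid depth grid")

    @property
    def hop(self) -> int:
        return max(1, int(round(self.window_length * (1 - self.window_overlap))))

    def window_starts(self, n_axial: int) -> np.ndarray:
        if self.start_offset + self.window_length > n_axial:
            raise ValueError("depth window exceeds frame depth")
        return np.arange(self.start_offset, n_axial - self.window_length + 1, self.hop)

    def taper(self) -> np.ndarray:
        return get_window(self.window_taper, self.window_length, fftbins=True)


@dataclass
class DepthSpectrum:
    """View- and line-averaged power spectra per depth window."""

    power: np.ndarray  # (n_windows, n_freq)
    freq_grid: np.ndarray  # MHz
    depth_centers: np.ndarray  # mm
    n_views_averaged: int


@dataclass
class TransferFunction:
    """Per-depth magnitude transfer function with its Wiener regularization."""

    gamma_raw: np.ndarray  # (n_windows, n_freq)
    gamma_wiener: np.ndarray
    snr: np.ndarray  # (n_windows,) linear
    band_mask: np.ndarray  # (n_freq,) bool
    freq_grid: np.ndarray  # MHz
    depth_centers: np.ndarray  # mm
    grid: DepthGrid = field(default_factory=DepthGrid)
    sampling_rate: float = 0.0  # MHz (victim rate)
    axial_spacing: float = 0.0  # mm / sample


def depth_gated_spectrum(views: list[RFFrame], grid: DepthGrid = DepthGrid()) -> DepthSpectrum:
    """Average tapered periodogram over views and lateral lines per depth window."""
    if not views:
        raise ValueError("need at least one view")
    fs = views[0].sampling_rate
    shape = views[0].samples.shape
    for v in views:
        if v.samples.shape != shape or v.sampling_rate != fs:
            raise ValueError("views must share geometry and sampling rate")
    starts = grid.window_starts(shape[0])
    win = grid.taper()
    L = grid.window_length
    freq = np.fft.rfftfreq(L, d=1.0 / fs)
    power = np.zeros((len(starts), len(freq)))
    for v in views:
        for w, s in enumerate(starts):
            seg = v.samples[s : s + L] * win[:, None]
            spec = np.fft.rfft(seg, axis=0)
            power[w] += np.mean(np.abs(spec) ** 2, axis=1)
    power /= len(views)
    centers = (starts + L / 2.0) * views[0].axial_spacing
    return DepthSpectrum(power, freq, centers, n_views_averaged=len(views))


def noise_floor_power(
    spec: DepthSpectrum, band_mask: np.ndarray, guard_factor: float = 1.2
) -> np.ndarray:
    """Per-window noise-floor power: mean of bins above ``guard_factor``
    times the upper edge of the analysis band."""
    band_mask = np.asarray(band_mask, dtype=bool)
    if not band_mask.any():
        raise ValueError("band mask is empty")
    f_hi = spec.freq_grid[band_mask].max()
    out_mask = spec.freq_grid > guard_factor * f_hi
    if not out_mask.any():
        raise ValueError("no out-of-band bins available for the noise floor")
    return spec.power[:, out_mask].mean(axis=1)


def estimate_snr(spec: DepthSpectrum, band_mask: np.ndarray, guard_factor: float = 1.2) -> np.ndarray:
    """Per-window linear SNR: mean in-band power over the noise-floor power
    measured outside the analysis bandwidth; capped at 1e6 so noiseless data
    stays finite."""
    band_mask = np.asarray(band_mask, dtype=bool)
    floor = noise_floor_power(spec, band_mask, guard_factor)
    inband = spec.power[:, band_mask].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(floor > 0, inband / np.maximum(floor, 1e-300), np.inf)
    return np.minimum(np.where(np.isfinite(snr), snr, SNR_CAP), SNR_CAP)


def _band_mask_from_spectra(power: np.ndarray, threshold_db: float) -> np.ndarray:
    """Bins whose depth-averaged power is within ``threshold_db`` of the peak."""
    mean = power.mean(axis=0)
    mask = mean >= mean.max() * 10.0 ** (threshold_db / 10.0)
    # keep the contiguous run containing the peak (stray noise bins excluded)
    peak = int(np.argmax(mean))
    lo = peak
    while lo > 0 and mask[lo - 1]:
        lo -= 1
    hi = peak
    while hi < len(mask) - 1 and mask[hi + 1]:
        hi += 1
    out = np.zeros_like(mask)
    out[lo : hi + 1] = True
    return out


def _clamp_outside_band(gamma: np.ndarray, band_mask: np.ndarray) -> np.ndarray:
    """Hold gamma at its band-edge value outside the analysis band."""
    idx = np.flatnonzero(band_mask)
    lo, hi = idx[0], idx[-1]
    out = gamma.copy()
    out[:, :lo] = gamma[:, lo : lo + 1]
    out[:, hi + 1 :] = gamma[:, hi : hi + 1]
    return out


def _band_rolloff(band_mask: np.ndarray, roll_bins: int = 8) -> np.ndarray:
    """Unity inside the analysis band, raised-cosine ramp to zero over
    ``roll_bins`` bins beyond each edge."""
    idx = np.flatnonzero(band_mask)
    lo, hi = idx[0], idx[-1]
    n = len(band_mask)
    env = np.zeros(n)
    env[lo : hi + 1] = 1.0
    ramp = 0.5 * (1 + np.cos(np.pi * np.arange(1, roll_bins + 1) / roll_bins))
    left = np.arange(lo - 1, max(lo - roll_bins - 1, -1), -1)
    env[left] = ramp[: len(left)]
    right = np.arange(hi + 1, min(hi + roll_bins + 1, n))
    env[right] = ramp[: len(right)]
    return env


def wiener_gamma(gamma_raw: np.ndarray, snr: np.ndarray) -> np.ndarray:
    """Wiener-regularized magnitude response.

    Gamma_W = |Gamma|^-1 / (|Gamma|^-2 + SNR^-1); per-window SNR broadcasts
    over frequency. Equals |Gamma| in the infinite-SNR limit and shrinks
    strictly below it for finite SNR.
    """
    g = np.asarray(gamma_raw, dtype=np.float64)
    s = np.asarray(snr, dtype=np.float64)
    if np.any(g <= 0) or np.any(s <= 0):
        raise ValueError("gamma_raw and snr must be positive")
    if s.ndim == 1 and g.ndim == 2:
        s = s[:, None]
    return (1.0 / g) / (g ** -2.0 + 1.0 / s)


def compute_gamma(
    victim_views: list[RFFrame],
    perp_views: list[RFFrame],
    grid: DepthGrid = DepthGrid(),
    band_threshold_db: float = -20.0,
) -> TransferFunction:
    """Estimate the transfer function from paired calibration views.

    Perpetrator views must already be resampled to the victim sampling rate so
    both spectra live on one frequency grid. The analysis band keeps bins
    where both machines' calibration spectra exceed ``band_threshold_db``
    relative to their in-band peak; outside it the ratio is clamped to its
    band-edge value before Wiener shrinkage.
    """
    spec_v = depth_gated_spectrum(victim_views, grid)
    spec_p = depth_gated_spectrum(perp_views, grid)
    if spec_v.power.shape != spec_p.power.shape or not np.allclose(
        spec_v.freq_grid, spec_p.freq_grid
    ):
        raise ValueError("victim and perpetrator views must share the frequency grid "
                         "(resample the perpetrator views first)")
    band = _band_mask_from_spectra(spec_v.power, band_threshold_db) & _band_mask_from_spectra(
        spec_p.power, band_threshold_db
    )
    if not band.any():
        raise ValueError("machines share no analysis band above the threshold")
    if np.any(spec_p.power[:, band] <= 0):
        raise ValueError("zero perpetrator power inside the analysis band")
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma_raw = np.sqrt(spec_v.power / np.maximum(spec_p.power, 1e-300))
    gamma_raw = np.where(np.isfinite(gamma_raw) & (gamma_raw > 0), gamma_raw, np.nan)
    # out-of-band bins may be 0/0 on noiseless data; clamping overwrites them
    gamma_raw = _fill_nan_with_band_edge(gamma_raw, band)
    snr = estimate_snr(spec_p, band)
    gamma_clamped = _clamp_outside_band(gamma_raw, band)
    gw = wiener_gamma(gamma_clamped, snr)
    # Outside the analysis band the perpetrator carries only noise, which the
    # band-edge ratio would amplify into the calibrated output; roll the
    # applied response smoothly to zero there instead.
    gw = gw * _band_rolloff(band, roll_bins=8)[None, :]
    return TransferFunction(
        gamma_raw=gamma_raw,
        gamma_wiener=gw,
        snr=snr,
        band_mask=band,
        freq_grid=spec_v.freq_grid,
        depth_centers=spec_v.depth_centers,
        grid=grid,
        sampling_rate=victim_views[0].sampling_rate,
        axial_spacing=victim_views[0].axial_spacing,
    )


def _fill_nan_with_band_edge(gamma: np.ndarray, band_mask: np.ndarray) -> np.ndarray:
    idx = np.flatnonzero(band_mask)
    lo, hi = idx[0], idx[-1]
    out = gamma.copy()
    cols_nan = np.isnan(out)
    for w in range(out.shape[0]):
        row = out[w]
        bad = np.flatnonzero(cols_nan[w])
        if bad.size:
            row[bad[bad < lo]] = row[lo]
            row[bad[bad > hi]] = row[hi]
            interior = bad[(bad >= lo) & (bad <= hi)]
            if interior.size:  # isolated zero-power bins: nearest finite
                good = np.flatnonzero(~cols_nan[w])
                row[interior] = np.interp(interior, good, row[good])
    return out


def _gamma_at_depth(tf: TransferFunction, depth_mm: np.ndarray) -> np.ndarray:
    """Linear interpolation of Gamma_W rows between depth-window centers,
    clamped at the edges. Returns (len(depth_mm), n_freq)."""
    centers = tf.depth_centers
    d = np.clip(np.asarray(depth_mm, dtype=np.float64), centers[0], centers[-1])
    hi = np.searchsorted(centers, d, side="right").clip(1, len(centers) - 1)
    lo = hi - 1
    span = centers[hi] - centers[lo]
    t = np.where(span > 0, (d - centers[lo]) / np.where(span > 0, span, 1.0), 0.0)
    return (1 - t)[:, None] * tf.gamma_wiener[lo] + t[:, None] * tf.gamma_wiener[hi]


def apply_gamma(
    data: np.ndarray | RFFrame, tf: TransferFunction, axial_start: int = 0
) -> np.ndarray | RFFrame:
    """Zero-phase magnitude filtering of RF data by Gamma_W.

    Frames (taller than one depth window) are processed by Hann overlap-add
    with reflection padding, each window's spectrum magnitude scaled by the
    depth-interpolated Gamma_W; data no taller than one window (e.g. a patch)
    are filtered as a single rectangular window at their center depth.
    ``axial_start`` gives the absolute frame row of the input's first sample
    so patches keep their true depth. Phase is preserved; the operation is
    linear in the input.
    """
    frame_in = isinstance(data, RFFrame)
    x = data.samples if frame_in else np.asarray(data, dtype=np.float64)
    fs_in = data.sampling_rate if frame_in else tf.sampling_rate
    if frame_in and not np.isclose(fs_in, tf.sampling_rate):
        raise ValueError("input sampling rate must equal the victim rate")
    L = tf.grid.window_length
    n = x.shape[0]
    dz = tf.axial_spacing

    if n <= L:
        depth = (axial_start + n / 2.0) * dz
        _check_depth_cover(tf, depth)
        g = _gamma_at_depth(tf, np.array([depth]))[0]
        spec = np.fft.rfft(x, n=L, axis=0)
        gi = np.interp(np.fft.rfftfreq(L, 1.0 / tf.sampling_rate), tf.freq_grid, g)
        y = np.fft.irfft(spec * gi[:, None], n=L, axis=0)[:n]
    else:
        _check_depth_cover(tf, (axial_start + n - 1) * dz, (axial_start) * dz)
        hop = L // 2
        win = get_window("hann", L, fftbins=True)
        pad = hop
        xp = np.pad(x, ((pad, pad + L), (0, 0)), mode="reflect")
        out = np.zeros_like(xp)
        wsum = np.zeros(xp.shape[0])
        for s in range(0, xp.shape[0] - L + 1, hop):
            center_row = axial_start + (s - pad) + L / 2.0
            g = _gamma_at_depth(tf, np.array([center_row * dz]))[0]
            seg = xp[s : s + L] * win[:, None]
            spec = np.fft.rfft(seg, axis=0)
            out[s : s + L] += np.fft.irfft(spec * g[:, None], axis=0, n=L)
            wsum[s : s + L] += win
        y = (out / np.maximum(wsum, 1e-3)[:, None])[pad : pad + n]

    if frame_in:
        res = RFFrame(
            samples=y,
            sampling_rate=data.sampling_rate,
            axial_spacing=data.axial_spacing,
            lateral_pitch=data.lateral_pitch,
            machine_id=data.machine_id,
            phantom_id=data.phantom_id,
            frame_index=data.frame_index,
        )
        return res
    return y


def _check_depth_cover(tf: TransferFunction, *depths_mm: float) -> None:
    half = tf.grid.window_length * tf.axial_spacing / 2.0
    lo = tf.depth_centers[0] - half
    hi = tf.depth_centers[-1] + half
    for d in depths_mm:
        if d < lo - half or d > hi + half:
            raise ValueError("transfer function does not cover the input depth span")


def apply_gamma_patches(patchset: PatchSet, tf: TransferFunction) -> PatchSet:
    """Vectorized Gamma_W application to a PatchSet using each patch's frame
    depth (coords); returns a new PatchSet flagged 'calibrated'."""
    x = np.asarray(patchset.patches, dtype=np.float64)
    n, h, w = x.shape
    L = tf.grid.window_length
    if h > L:
        raise ValueError("patch height exceeds the transfer-function window")
    depths = (patchset.coords[:, 1] + h / 2.0) * tf.axial_spacing
    g = _gamma_at_depth(tf, depths)  # (n, n_freq_tf)
    freqs = np.fft.rfftfreq(L, 1.0 / tf.sampling_rate)
    if len(freqs) != len(tf.freq_grid) or not np.allclose(freqs, tf.freq_grid):
        g = np.vstack([np.interp(freqs, tf.freq_grid, gi) for gi in g])
    spec = np.fft.rfft(x, n=L, axis=1)
    y = np.fft.irfft(spec * g[:, :, None], n=L, axis=1)[:, :h, :]
    return PatchSet(
        y, patchset.coords.copy(),
        None if patchset.labels is None else patchset.labels.copy(),
        provenance="calibrated",
        sampling_rate=patchset.sampling_rate,
        axial_spacing=patchset.axial_spacing,
    )


def log_spectral_distance(
    spec_a: DepthSpectrum, spec_b: DepthSpectrum, band_mask: np.ndarray
) -> float:
    """Mean absolute in-band difference of the two log power spectra (dB)."""
    pa = np.maximum(spec_a.power[:, band_mask], 1e-300)
    pb = np.maximum(spec_b.power[:, band_mask], 1e-300)
    return float(np.mean(np.abs(10 * np.log10(pa) - 10 * np.log10(pb))))


class WienerTransferFunction:
    """sklearn-style transformer around compute_gamma / apply_gamma.

    fit(victim_views, perp_views) estimates Gamma; transform maps RFFrames,
    arrays, or PatchSets from the perpetrator domain into the victim domain.
    """

    def __init__(self, grid: DepthGrid = DepthGrid(), band_threshold_db: float = -20.0):
        self.grid = grid
        self.band_threshold_db = band_threshold_db

    def get_params(self, deep: bool = True) -> dict:
        return {"grid": self.grid, "band_threshold_db": self.band_threshold_db}

    def set_params(self, **params) -> "WienerTransferFunction":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, victim_views: list[RFFrame], perp_views: list[RFFrame]) -> "WienerTransferFunction":
        self.tf_ = compute_gamma(victim_views, perp_views, self.grid, self.band_threshold_db)
        return self

    def transform(self, X):
        if not hasattr(self, "tf_"):
            raise RuntimeError("WienerTransferFunction is not fitted")
        if isinstance(X, PatchSet):
            return apply_gamma_patches(X, self.tf_)
        if isinstance(X, list):
            return [apply_gamma(f, self.tf_) for f in X]
        return apply_gamma(X, self.tf_)
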