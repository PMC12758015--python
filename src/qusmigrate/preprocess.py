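"""Sampling-rate harmonization, patch extraction, standardization, splits.

Coordinates are 0-based with half-open index intervals throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np
from scipy.signal import firwin, resample_poly

from .rf_sim import RFFrame

__all__ = [
    "PatchConfig",
    "PatchSet",
    "resample_rate",
    "extract_patches",
    "extract_patches_dataset",
    "zscore",
    "augment_flip",
    "split_frames",
    "SPLIT_SCHEMES",
]


@dataclass(frozen=True)
class PatchConfig:
    """Patch-extraction grid. Defaults give a 9 x 9 grid of 81 patches on a
    full-scale 2080 x 256 frame (200 x 26-sample patches, 4 mm x 4 mm)."""

    axial_skip: int = 540
    patch_height: int = 200
    patch_width: int = 26
    axial_step: int = 100
    lateral_step: int = 26
    equalize_counts: bool = True

    def __post_init__(self) -> None:
        for name in ("patch_height", "patch_width", "axial_step", "lateral_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.axial_skip < 0:
            raise ValueError("axial_skip must be nonnegative")


@dataclass
class PatchSet:
    """Stack of extracted patches with grid provenance.

    patches: (n, height, width); coords: (n, 3) rows of
    (frame_index, axial_start, lateral_start); labels: optional (n,) in {0,1};
    provenance: 'raw' or 'calibrated'.
    """

    patches: np.ndarray
    coords: np.ndarray
    labels: np.ndarray | None = None
    provenance: str = "raw"
    sampling_rate: float = 0.0
    axial_spacing: float = 0.0

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches)
        self.coords = np.asarray(self.coords, dtype=np.int64)
        if self.patches.ndim != 3:
            raise ValueError("patches must be (n, height, width)")
        if self.coords.shape != (len(self.patches), 3):
            raise ValueError("coords must be (n, 3)")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (len(self.patches),):
                raise ValueError("labels must be (n,)")

    def __len__(self) -> int:
        return len(self.patches)

    def subset(self, idx: np.ndarray) -> "PatchSet":
        return PatchSet(
            self.patches[idx],
            self.coords[idx],
            None if self.labels is None else self.labels[idx],
            self.provenance,
            self.sampling_rate,
            self.axial_spacing,
        )


def _multirate_fir(up: int, down: int, taps_per_phase: int = 24) -> np.ndarray:
    """Kaiser-windowed low-pass for polyphase resampling: cutoff at
    min(1/up, 1/down) of the upsampled Nyquist, ``taps_per_phase`` taps per
    polyphase phase."""
    m = max(up, down)
    numtaps = taps_per_phase * m + 1
    return firwin(numtaps, 1.0 / m, window=("kaiser", 8.0))


def resample_rate(frame: RFFrame, up: int, down: int) -> RFFrame:
    """Multirate FIR rate conversion along the axial axis (e.g. up 4 / down 5
    turns 50 MHz data into 40 MHz data, 1000 samples into 800)."""
    if int(up) != up or int(down) != down or up < 1 or down < 1:
        raise ValueError("up and down must be positive integers")
    up, down = int(up), int(down)
    if up == down:
        return replace(frame, samples=frame.samples.copy())
    # resample_poly scales the supplied coefficients by `up` internally
    h = _multirate_fir(up, down)
    samples = resample_poly(frame.samples, up, down, axis=0, window=h)
    return RFFrame(
        samples=samples,
        sampling_rate=frame.sampling_rate * up / down,
        axial_spacing=frame.axial_spacing * down / up,
        lateral_pitch=frame.lateral_pitch,
        machine_id=frame.machine_id,
        phantom_id=frame.phantom_id,
        frame_index=frame.frame_index,
    )


def patch_grid_starts(
    frame_height: int, frame_width: int, cfg: PatchConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Admissible (axial, lateral) start indices under the truncation rule."""
    if frame_height < cfg.axial_skip + cfg.patch_height or frame_width < cfg.patch_width:
        raise ValueError("frame too small for the patch configuration")
    lat = np.arange(0, frame_width - cfg.patch_width + 1, cfg.lateral_step)
    ax = np.arange(cfg.axial_skip, frame_height - cfg.patch_height + 1, cfg.axial_step)
    if cfg.equalize_counts and len(ax) > len(lat):
        ax = ax[: len(lat)]
    return ax, lat


def extract_patches(
    frame: RFFrame, cfg: PatchConfig = PatchConfig(), frame_index: int | None = None
) -> PatchSet:
    """Row-major patch grid (axial outer, lateral inner); when
    ``equalize_counts`` the axial count is truncated to the lateral count, so
    the default configuration yields 81 patches on a full-scale frame."""
    ax, lat = patch_grid_starts(frame.axial_samples, frame.lateral_lines, cfg)
    fi = frame.frame_index if frame_index is None else frame_index
    patches = np.empty((len(ax) * len(lat), cfg.patch_height, cfg.patch_width))
    coords = np.empty((len(ax) * len(lat), 3), dtype=np.int64)
    k = 0
    for a in ax:
        for l in lat:
            patches[k] = frame.samples[a : a + cfg.patch_height, l : l + cfg.patch_width]
            coords[k] = (fi, a, l)
            k += 1
    return PatchSet(
        patches, coords, provenance="raw",
        sampling_rate=frame.sampling_rate, axial_spacing=frame.axial_spacing,
    )


def extract_patches_dataset(
    frames: list[RFFrame],
    labels: np.ndarray | None = None,
    cfg: PatchConfig = PatchConfig(),
) -> PatchSet:
    """Patchify a frame list; frame labels broadcast to their patches."""
    sets = [extract_patches(f, cfg, frame_index=i) for i, f in enumerate(frames)]
    patches = np.concatenate([s.patches for s in sets])
    coords = np.concatenate([s.coords for s in sets])
    lab = None
    if labels is not None:
        lab = np.concatenate([np.full(len(s), labels[i]) for i, s in enumerate(sets)])
    return PatchSet(
        patches, coords, lab, provenance="raw",
        sampling_rate=frames[0].sampling_rate, axial_spacing=frames[0].axial_spacing,
    )


def zscore(patch: np.ndarray) -> np.ndarray:
    """Patch-wise standardization to zero mean, unit population std.

    Accepts a single patch or a stack (n, h, w); statistics are per patch.
    """
    x = np.asarray(patch, dtype=np.float64)
    if x.ndim == 2:
        if x.size < 2:
            raise ValueError("patch must have at least 2 samples")
        sd = x.std()
        if sd == 0:
            raise ValueError("zero-variance patch cannot be standardized")
        return (x - x.mean()) / sd
    if x.ndim == 3:
        mu = x.mean(axis=(1, 2), keepdims=True)
        sd = x.std(axis=(1, 2), keepdims=True)
        if np.any(sd == 0):
            raise ValueError("zero-variance patch cannot be standardized")
        return (x - mu) / sd
    raise ValueError("patch must be 2-D or a 3-D stack")


def augment_flip(
    patch: np.ndarray, probability: float, rng: np.random.Generator
) -> np.ndarray:
    """Horizontal (lateral-axis) flip with the given probability.

    For a stack (n, h, w) the Bernoulli draw is per patch.
    """
    if not 0 <= probability <= 1:
        raise ValueError("probability must lie in [0, 1]")
    x = np.asarray(patch)
    if x.ndim == 2:
        return x[:, ::-1].copy() if rng.random() < probability else x.copy()
    flips = rng.random(len(x)) < probability
    out = x.copy()
    out[flips] = out[flips, :, ::-1]
    return out


#: Frame-level split schemes. 'victim': 80/20 train/validation. 'perpetrator':
#: 50% held-out test, then 45/5 (i.e. 900/100 of 2000) train/validation.
SPLIT_SCHEMES: dict[str, dict[str, float]] = {
    "victim": {"train": 0.8, "val": 0.2},
    "perpetrator": {"test": 0.5, "train": 0.45, "val": 0.05},
}


def split_frames(
    labels: np.ndarray, scheme: str | dict[str, float], seed: int
) -> dict[str, np.ndarray]:
    """Class-stratified frame-level split into named index subsets.

    All patches of a frame travel together (splits happen before patch
    extraction), preventing within-frame leakage.
    """
    fractions = SPLIT_SCHEMES[scheme] if isinstance(scheme, str) else dict(scheme)
    fr = np.asarray(list(fractions.values()), dtype=float)
    if not np.isclose(fr.sum(), 1.0):
        raise ValueError("split fractions must sum to 1")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    subsets: dict[str, list[np.ndarray]] = {k: [] for k in fractions}
    credit = np.zeros(len(fr))  # fractional rounding debt carried across classes
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        raw = fr * len(idx) + credit
        counts = np.floor(raw).astype(int)
        for i in np.argsort(-(raw - counts))[: len(idx) - counts.sum()]:
            counts[i] += 1
        credit = raw - counts
        pos = 0
        for name, c in zip(fractions, counts):
            subsets[name].append(idx[pos : pos + c])
            pos += c
    out = {k: np.sort(np.concatenate(v)) for k, v in subsets.items()}
    if any(len(v) == 0 for v in out.values()):
        raise ValueError("split fractions yield an empty subset")
    return out
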