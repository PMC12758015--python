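"""Synthetic beamformed-RF ultrasound simulator.

Implements the multiplicative spectral model I(f, x) = S(f, x) P(f, x): the
received spectrum factors into a machine-dependent system response S (pulse
spectrum, gain, electronic noise floor) and a tissue term P (random scatterer
field, frequency power-law backscatter, depth-dependent attenuation). Frames
are emitted as beamformed RF sample grids (axial x lateral); beamforming of
raw channel data is not simulated.

Two virtual machines and three phantoms parameterize the default study: a
9 MHz victim scanner sampling at 40 MHz, a 5 MHz perpetrator scanner sampling
at 50 MHz, two classification phantoms differing in attenuation slope
(0.4 vs 0.1 dB/cm/MHz) and scatterer size, and a 0.74 dB/cm/MHz calibration
phantom imaged by both machines.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, asdict
from fractions import Fraction
from math import ceil, log, sqrt

import numpy as np
from scipy.signal import fftconvolve, resample_poly
from scipy.signal.windows import hann

__all__ = [
    "MachineProfile",
    "PhantomProfile",
    "RFFrame",
    "make_pulse_spectrum",
    "simulate_frame",
    "simulate_dataset",
    "simulate_calibration_views",
    "victim_machine",
    "perpetrator_machine",
    "phantom_liver_like",
    "phantom_low_attenuation",
    "phantom_calibration",
    "CAL_LABEL",
]

CAL_LABEL = "calibration"

# -6 dB amplitude points sit at half the peak amplitude.
_HALF_AMP_SIGMAS = sqrt(2.0 * log(2.0))  # bw half-width in units of sigma_f


def _crc(text: str) -> int:
    return zlib.crc32(text.encode("utf-8"))


def _rng(*entropy: int) -> np.random.Generator:
    """Deterministic child generator from a tuple of integer entropy words."""
    return np.random.default_rng(np.random.SeedSequence([int(e) & 0x7FFFFFFF for e in entropy]))


@dataclass(frozen=True)
class MachineProfile:
    """Parametric system response of one virtual scanner.

    center_frequency and sampling_rate are in MHz; fractional_bandwidth is the
    -6 dB spectral width divided by the center frequency; gain is a linear
    amplitude factor; noise_floor is the white electronic-noise level in dB
    relative to the in-band peak of the shallow-depth signal spectrum
    (``-inf`` disables noise).
    """

    machine_id: str
    center_frequency: float
    fractional_bandwidth: float
    sampling_rate: float
    gain: float = 1.0
    noise_floor: float = -40.0
    transducer_id: str = "generic"

    def __post_init__(self) -> None:
        if not self.center_frequency < self.sampling_rate / 2:
            raise ValueError("center_frequency must be below Nyquist (sampling_rate/2)")
        if not 0 < self.fractional_bandwidth <= 1:
            raise ValueError("fractional_bandwidth must lie in (0, 1]")
        if not self.gain > 0:
            raise ValueError("gain must be positive")

    @property
    def sigma_f(self) -> float:
        """Gaussian spectral std-dev (MHz) implied by the -6 dB bandwidth."""
        return self.fractional_bandwidth * self.center_frequency / 2.0 / _HALF_AMP_SIGMAS


@dataclass(frozen=True)
class PhantomProfile:
    """Tissue-mimicking phantom: attenuation, sound speed, scatterer field.

    acs is the attenuation coefficient slope in dB/cm/MHz (two-way attenuation
    is 2*acs*depth_cm*f_MHz); sos the speed of sound in m/s; scatterer_density
    in scatterers per mm^2 (>= ~4/mm^2 for fully developed speckle);
    backscatter_exponent the amplitude power-law exponent of the scatterer
    spectrum, abstracting scatterer size.
    """

    phantom_id: str
    acs: float
    sos: float
    scatterer_density: float
    backscatter_exponent: float = 1.0
    class_label: object = CAL_LABEL

    def __post_init__(self) -> None:
        if self.acs < 0:
            raise ValueError("acs must be nonnegative")
        if self.scatterer_density < 0:
            raise ValueError("scatterer_density must be nonnegative")
        if self.sos <= 0:
            raise ValueError("sos must be positive")


@dataclass
class RFFrame:
    """One beamformed RF frame: samples[axial, lateral] plus acquisition metadata.

    axial_spacing follows the pulse-echo convention sos / (2 fs), in mm per
    sample. lateral_pitch is mm per scan line.
    """

    samples: np.ndarray
    sampling_rate: float  # MHz
    axial_spacing: float  # mm / sample
    lateral_pitch: float  # mm / line
    machine_id: str = ""
    phantom_id: str = ""
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (axial x lateral) array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def axial_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def lateral_lines(self) -> int:
        return self.samples.shape[1]

    def depth_mm(self, sample_index: np.ndarray | float) -> np.ndarray | float:
        return np.asarray(sample_index) * self.axial_spacing


# ---------------------------------------------------------------------------
# default study profiles


def victim_machine(**overrides) -> MachineProfile:
    """9 MHz pulse, 40 MHz sampling: the scanner hosting the original model."""
    kw = dict(
        machine_id="victim-9mhz",
        center_frequency=9.0,
        fractional_bandwidth=0.7,
        sampling_rate=40.0,
        gain=1.0,
        noise_floor=-40.0,
        transducer_id="L9-4",
    )
    kw.update(overrides)
    return MachineProfile(**kw)


def perpetrator_machine(**overrides) -> MachineProfile:
    """5 MHz pulse, 50 MHz sampling: the scanner the model migrates to."""
    kw = dict(
        machine_id="perpetrator-5mhz",
        center_frequency=5.0,
        fractional_bandwidth=0.8,
        sampling_rate=50.0,
        gain=1.0,
        noise_floor=-40.0,
        transducer_id="L9-4",
    )
    kw.update(overrides)
    return MachineProfile(**kw)


def phantom_liver_like(**overrides) -> PhantomProfile:
    kw = dict(
        phantom_id="class-0-liver-like",
        acs=0.4,
        sos=1540.0,
        scatterer_density=30.0,
        backscatter_exponent=0.5,
        class_label=0,
    )
    kw.update(overrides)
    return PhantomProfile(**kw)


def phantom_low_attenuation(**overrides) -> PhantomProfile:
    kw = dict(
        phantom_id="class-1-low-attenuation",
        acs=0.1,
        sos=1539.0,
        scatterer_density=30.0,
        backscatter_exponent=1.5,
        class_label=1,
    )
    kw.update(overrides)
    return PhantomProfile(**kw)


def phantom_calibration(**overrides) -> PhantomProfile:
    kw = dict(
        phantom_id="calibration",
        acs=0.74,
        sos=1545.0,
        scatterer_density=30.0,
        backscatter_exponent=1.0,
        class_label=CAL_LABEL,
    )
    kw.update(overrides)
    return PhantomProfile(**kw)


# ---------------------------------------------------------------------------
# spectra


def make_pulse_spectrum(machine: MachineProfile, freq_grid: np.ndarray) -> np.ndarray:
    """Gaussian amplitude spectrum of the machine's pulse on ``freq_grid`` (MHz).

    Peak amplitude equals ``gain`` at the center frequency; the -6 dB points
    (amplitude 1/2 of peak) sit at center +/- fractional_bandwidth*center/2.
    """
    f = np.asarray(freq_grid, dtype=np.float64)
    if np.any(f < 0) or np.any(f > machine.sampling_rate / 2 + 1e-9):
        raise ValueError("freq_grid must lie within [0, sampling_rate/2]")
    if machine.center_frequency < f.min() or machine.center_frequency > f.max():
        raise ValueError("center frequency lies outside the frequency grid")
    s = machine.sigma_f
    return machine.gain * np.exp(-((f - machine.center_frequency) ** 2) / (2.0 * s * s))


def _backscatter_amplitude(phantom: PhantomProfile, freq_grid: np.ndarray, f_ref: float = 5.0) -> np.ndarray:
    """Amplitude power-law (f/f_ref)^exponent of the scatterer spectrum."""
    f = np.abs(np.asarray(freq_grid, dtype=np.float64))
    return (f / f_ref) ** phantom.backscatter_exponent


def _segment_response(
    machine: MachineProfile,
    phantom: PhantomProfile,
    freq_grid: np.ndarray,
    depth_cm: float,
) -> np.ndarray:
    """|H(f)| for one depth segment: pulse x two-way attenuation x backscatter."""
    pulse = make_pulse_spectrum(machine, freq_grid)
    atten_db = 2.0 * phantom.acs * depth_cm * freq_grid
    return pulse * _backscatter_amplitude(phantom, freq_grid) * 10.0 ** (-atten_db / 20.0)


# ---------------------------------------------------------------------------
# synthesis core


def _axial_spacing_mm(phantom: PhantomProfile, sampling_rate_mhz: float) -> float:
    # pulse-echo convention: one sample spans sos / (2 fs)
    return phantom.sos * 1e3 / (2.0 * sampling_rate_mhz * 1e6)  # mm per sample


def _reflectivity(
    rng: np.random.Generator, n_axial: int, n_lateral: int, density_per_sample: float
) -> np.ndarray:
    """Bernoulli-Gaussian scatterer grid with per-sample variance = density."""
    amp = rng.standard_normal((n_axial, n_lateral))
    occ = rng.random((n_axial, n_lateral)) < density_per_sample
    return amp * occ


def _synthesize(
    reflectivity: np.ndarray,
    machine: MachineProfile,
    phantom: PhantomProfile,
    axial_spacing_mm: float,
    noise_rng: np.random.Generator | None,
    density_per_sample: float,
    segment_len: int = 64,
) -> np.ndarray:
    """Piecewise-stationary synthesis: Hann overlap-add depth segments, each
    convolved with a zero-phase pulse carrying the segment-center two-way
    attenuation, plus white electronic noise at the configured floor."""
    n_ax, n_lat = reflectivity.shape
    fs = machine.sampling_rate
    hop = segment_len // 2
    win = hann(segment_len, sym=False)

    # zero-phase impulse-response length: cover +/- 5 temporal sigmas
    sigma_t_samples = fs / (2.0 * np.pi * machine.sigma_f)
    half = max(16, int(ceil(5.0 * sigma_t_samples)))
    nfft = 2 * half + 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)  # MHz

    out = np.zeros((n_ax, n_lat))
    weight = np.zeros(n_ax)
    starts = range(0, max(n_ax - hop, 1), hop)
    for start in starts:
        stop = min(start + segment_len, n_ax)
        w = win[: stop - start]
        depth_cm = (start + (stop - start) / 2.0) * axial_spacing_mm / 10.0
        h_spec = _segment_response(machine, phantom, freqs, depth_cm)
        h = np.fft.fftshift(np.fft.irfft(h_spec, n=nfft))  # symmetric, zero-phase
        chunk = reflectivity[start:stop] * w[:, None]
        conv = fftconvolve(chunk, h[:, None], axes=0)  # length stop-start+nfft-1
        o0 = start - nfft // 2
        lo = max(0, -o0)
        hi = min(conv.shape[0], n_ax - o0)
        out[o0 + lo : o0 + hi] += conv[lo:hi]
        weight[start:stop] += w

    # COLA weight is 1 in the interior for a periodic Hann at 50% hop; fix the
    # half-window edges so the speckle field is stationary over the full depth.
    out /= np.maximum(weight, 0.05)[:, None]

    if noise_rng is not None and np.isfinite(machine.noise_floor):
        shallow = _segment_response(machine, phantom, freqs, depth_cm=0.0)
        peak = float(np.max(shallow))
        p = density_per_sample if density_per_sample > 0 else 1.0
        sigma_n = 10.0 ** (machine.noise_floor / 20.0) * sqrt(p) * peak
        out = out + noise_rng.standard_normal(out.shape) * sigma_n
    return out


DEFAULT_AXIAL = 1040
DEFAULT_LATERAL = 128
FULL_SCALE_AXIAL = 2080
FULL_SCALE_LATERAL = 256
DEFAULT_LATERAL_PITCH_MM = 38.0 / 256.0


def simulate_frame(
    machine: MachineProfile,
    phantom: PhantomProfile,
    seed: int,
    axial_samples: int = DEFAULT_AXIAL,
    lateral_lines: int = DEFAULT_LATERAL,
    lateral_pitch_mm: float = DEFAULT_LATERAL_PITCH_MM,
    frame_index: int = 0,
) -> RFFrame:
    """Simulate one beamformed RF frame; identical (machine, phantom, seed)
    tuples yield bit-identical frames."""
    dz = _axial_spacing_mm(phantom, machine.sampling_rate)
    p = phantom.scatterer_density * dz * lateral_pitch_mm
    scat_rng = _rng(seed, _crc(phantom.phantom_id), 0)
    noise_rng = _rng(seed, _crc(machine.machine_id), 1)
    refl = _reflectivity(scat_rng, axial_samples, lateral_lines, p)
    samples = _synthesize(refl, machine, phantom, dz, noise_rng, p)
    return RFFrame(
        samples=samples,
        sampling_rate=machine.sampling_rate,
        axial_spacing=dz,
        lateral_pitch=lateral_pitch_mm,
        machine_id=machine.machine_id,
        phantom_id=phantom.phantom_id,
        frame_index=frame_index,
    )


def simulate_dataset(
    machine: MachineProfile,
    phantoms: list[PhantomProfile],
    n_frames_per_phantom: int,
    seed: int,
    **frame_kwargs,
) -> tuple[list[RFFrame], np.ndarray]:
    """Balanced labeled frame dataset; per-frame seeds derive from the master
    seed, so the whole dataset is a pure function of (profiles, seed)."""
    if not phantoms:
        raise ValueError("phantom list must be non-empty")
    if n_frames_per_phantom < 1:
        raise ValueError("n_frames_per_phantom must be >= 1")
    frames: list[RFFrame] = []
    labels: list[int] = []
    idx = 0
    for pi, phantom in enumerate(phantoms):
        for k in range(n_frames_per_phantom):
            child = int(_rng(seed, pi, k, 7).integers(0, 2**31 - 1))
            frames.append(
                simulate_frame(machine, phantom, seed=child, frame_index=idx, **frame_kwargs)
            )
            labels.append(phantom.class_label)
            idx += 1
    return frames, np.asarray(labels)


def _common_fine_rate(fs_a: float, fs_b: float) -> tuple[int, int, float]:
    """Least common sampling rate of two machines and the integer decimation
    factor of each, via exact rational arithmetic on the MHz values."""
    fa, fb = Fraction(str(fs_a)), Fraction(str(fs_b))
    lcm_num = np.lcm(fa.numerator * fb.denominator, fb.numerator * fa.denominator)
    fine = Fraction(int(lcm_num), fa.denominator * fb.denominator)
    da, db = fine / fa, fine / fb
    if da.denominator != 1 or db.denominator != 1:
        raise ValueError("sampling rates have no small common multiple")
    return int(da), int(db), float(fine)


def simulate_calibration_views(
    victim: MachineProfile,
    perp: MachineProfile,
    cal: PhantomProfile,
    n_views: int,
    mode: str = "stable",
    seed: int = 0,
    axial_samples: int = DEFAULT_AXIAL,
    lateral_lines: int = DEFAULT_LATERAL,
    lateral_pitch_mm: float = DEFAULT_LATERAL_PITCH_MM,
    freehand_jitter_mm: float = 2.0,
) -> tuple[list[RFFrame], list[RFFrame]]:
    """Paired calibration-phantom views from both machines.

    The scatterer field is drawn once on a fine common axial grid and
    band-limited-decimated to each machine's own grid, so the tissue term is
    physically shared between the two machines. ``stable`` mode reuses one
    realization for all views (views differ only in electronic noise),
    emulating a clamped transducer; ``freehand`` mode laterally translates the
    field by a uniform [0, jitter] mm offset per view index, shared between
    machines, emulating probe motion during a video sweep.

    ``axial_samples`` is the victim-grid frame height; the perpetrator frame
    height covers the same physical depth at its own rate.
    """
    if cal.class_label != CAL_LABEL:
        raise ValueError("calibration phantom must carry the calibration class label")
    if n_views < 1:
        raise ValueError("n_views must be >= 1")
    if mode not in ("stable", "freehand"):
        raise ValueError("mode must be 'stable' or 'freehand'")

    d_v, d_p, fs_fine = _common_fine_rate(victim.sampling_rate, perp.sampling_rate)
    n_fine = axial_samples * d_v
    n_perp = n_fine // d_p
    dz_fine = _axial_spacing_mm(cal, fs_fine)
    p_fine = cal.scatterer_density * dz_fine * lateral_pitch_mm

    margin = int(ceil(freehand_jitter_mm / lateral_pitch_mm)) + 1 if mode == "freehand" else 0
    field_rng = _rng(seed, _crc(cal.phantom_id), 2)
    base_field = _reflectivity(field_rng, n_fine, lateral_lines + margin, p_fine)
    jitter_rng = _rng(seed, 3)
    offsets = (
        np.floor(jitter_rng.random(n_views) * freehand_jitter_mm / lateral_pitch_mm).astype(int)
        if mode == "freehand"
        else np.zeros(n_views, dtype=int)
    )

    views_v: list[RFFrame] = []
    views_p: list[RFFrame] = []
    for v in range(n_views):
        fld = base_field[:, offsets[v] : offsets[v] + lateral_lines]
        for machine, dec, n_ax, sink in (
            (victim, d_v, axial_samples, views_v),
            (perp, d_p, n_perp, views_p),
        ):
            refl = fld if dec == 1 else resample_poly(fld, 1, dec, axis=0)
            refl = refl[:n_ax]
            dz = _axial_spacing_mm(cal, machine.sampling_rate)
            # per-sample variance on the machine grid after anti-aliased
            # decimation: fine-grid PSD is preserved in band
            p_machine = p_fine / dec
            noise_rng = _rng(seed, v, _crc(machine.machine_id), 4)
            samples = _synthesize(refl, machine, cal, dz, noise_rng, p_machine)
            sink.append(
                RFFrame(
                    samples=samples,
                    sampling_rate=machine.sampling_rate,
                    axial_spacing=dz,
                    lateral_pitch=lateral_pitch_mm,
                    machine_id=machine.machine_id,
                    phantom_id=cal.phantom_id,
                    frame_index=v,
                )
            )
    return views_v, views_p


def profile_to_json(profile) -> str:
    d = asdict(profile)
    d["__type__"] = type(profile).__name__
    return json.dumps(d)


def profile_from_json(text: str):
    d = json.loads(text)
    kind = d.pop("__type__")
    cls = {"MachineProfile": MachineProfile, "PhantomProfile": PhantomProfile}[kind]
    return cls(**d)
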