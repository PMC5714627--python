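"""Synthetic moving phantom, breathing programs and dual-surrogate synthesis.

This module generates everything the analysis pipeline needs to be exercised
end to end without scanner hardware:

* breathing programs -- superior-inferior (S-I) target displacement with a
  coupled anterior-posterior (A-P) chest-wall channel.  The regular kind is
  a raised-cosine-power cycle (``A * sin(pi*t/T)**(2n)``, trough-to-trough);
  the irregular kind draws per-cycle period and amplitude from lognormal
  jitter and adds a linear baseline drift, emulating the erratic patient
  curves (7-22 breaths/min, amplitude %CV roughly 60-155%) that a motion
  platform replays in a controlled comparison study;
* dual surrogate channels -- each samples ``gain * AP(t - lag) + noise`` at
  its own rate (30 Hz for the marker-block channel, ~38 Hz for the pressure
  belt), with an optional low-amplitude plateau floor reproducing the
  belt's truncation of extreme exhale positions, and an X-RAY ON window
  whose rising edge is identical in wall-clock time for both channels;
* a digital lung-mimicking phantom -- a low-HU slab (default -800 HU,
  within the -900..-600 HU lung window) carrying high-contrast inserts;
* a helical oversampled acquisition -- the couch advances at
  ``detector_width * pitch / rotation_period`` and every rotation images all
  slice positions under the detector, each shifted in z by the program's
  S-I displacement at that instant (pure geometric resampling; no
  projection physics);
* the ground-truth internal target volume -- the union of the object mask
  at end-inhale (max S-I), end-exhale (min S-I) and the midpoint
  displacement, the artifact-free reference an experimental ITV is
  compared against.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .image_metrics import Mask, Volume3D
from .waveform_io import SurrogateLabel, SurrogateTrace

__all__ = [
    "MotionProgram",
    "SurrogateModel",
    "InsertSpec",
    "PhantomSpec",
    "DigitalPhantom",
    "AcquisitionConfig",
    "SliceRecord",
    "GeometryError",
    "CoverageError",
    "make_breathing_curve",
    "synthesize_surrogates",
    "build_phantom",
    "object_mask",
    "shift_volume_z",
    "simulate_acquisition",
    "ground_truth_itv",
]


class GeometryError(ValueError):
    """Phantom geometry is invalid (insert outside grid, bad spacing)."""


class CoverageError(ValueError):
    """The motion program does not span the simulated scan."""


@dataclass
class MotionProgram:
    """Time-stamped target and chest-wall displacement, in cm."""

    times: np.ndarray
    si_displacement: np.ndarray
    ap_displacement: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.si_displacement = np.asarray(self.si_displacement, dtype=float)
        self.ap_displacement = np.asarray(self.ap_displacement, dtype=float)
        if not (len(self.times) == len(self.si_displacement) == len(self.ap_displacement)):
            raise ValueError("times and displacement channels must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def si_at(self, t) -> np.ndarray:
        return np.interp(t, self.times, self.si_displacement)

    def ap_at(self, t) -> np.ndarray:
        return np.interp(t, self.times, self.ap_displacement)

    @property
    def span(self) -> Tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])


@dataclass
class SurrogateModel:
    """How one external surrogate transduces chest-wall motion.

    gain converts cm of A-P platform motion into the channel's signal
    units (mm for a marker block, arbitrary pressure units for a belt);
    lag_ms delays the channel; noise_sd adds white Gaussian noise;
    plateau_floor clamps the output from below, reproducing a belt that is
    not taut enough to follow the lowest displacements.
    """

    label: SurrogateLabel = SurrogateLabel.OTHER
    gain: float = 10.0
    lag_ms: float = 0.0
    noise_sd: float = 0.0
    plateau_floor: Optional[float] = None
    sampling_rate: float = 30.0

    def __post_init__(self) -> None:
        self.label = SurrogateLabel(self.label)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


# Amplitude range a motion platform typically replays for lung targets.
SI_AMPLITUDE_RANGE_CM = (0.5, 3.0)
MAX_CYCLE_AMPLITUDE_CM = 2.5  # jittered cycles stay inside the platform's excursion range
DEFAULT_AP_RATIO = 0.3  # chest-wall A-P motion per unit of target S-I motion
DEFAULT_SHAPE_POWER = 2  # sin**(2n) cycle shape; n=2 gives a realistic exhale dwell

# Envelope of clinical breathing patterns a batch of cases emulates:
# breathing rates of roughly 7-22 breaths/min, widely varying cycle
# amplitude/period irregularity, and slow baseline drift.
CLINICAL_ENVELOPE = {
    "mean_period_s": (60.0 / 22.0, 60.0 / 7.2),
    "mean_amplitude_cm": (0.5, 1.0),
    "amplitude_jitter_pct": (10.0, 60.0),
    "period_jitter_pct": (5.0, 25.0),
    "drift_cm_per_min": (-0.1, 0.1),
}


def sample_case_parameters(seed: int) -> dict:
    """Draw one simulated case's breathing parameters from the clinical envelope.

    A latent irregularity factor couples a slower breathing rate with
    stronger cycle-amplitude jitter, reproducing the negative association
    between breathing rate and amplitude %CV observed across replayed
    patient curves; the remaining parameters are drawn independently.
    Deterministic in the seed, so a batch of seeds reproduces a diverse set
    of breathing patterns the way a set of distinct patient curves does.
    """
    rng = np.random.default_rng(seed + 2**20)  # offset: independent of the curve's own stream
    u = rng.uniform()  # 0 = fast and steady, 1 = slow and erratic
    jitter = 0.3 * rng.uniform(-1.0, 1.0)

    def lerp(key: str, frac: float) -> float:
        lo, hi = CLINICAL_ENVELOPE[key]
        return float(lo + (hi - lo) * min(max(frac, 0.0), 1.0))

    return {
        "mean_period_s": lerp("mean_period_s", u + jitter),
        "mean_amplitude_cm": float(rng.uniform(*CLINICAL_ENVELOPE["mean_amplitude_cm"])),
        "amplitude_jitter_pct": lerp("amplitude_jitter_pct", u - jitter),
        "period_jitter_pct": lerp("period_jitter_pct", u),
        "drift_cm_per_min": float(rng.uniform(*CLINICAL_ENVELOPE["drift_cm_per_min"])),
    }


def _cycle_shape(u: np.ndarray, n: int) -> np.ndarray:
    """Trough-to-trough breathing cycle on u in [0, 1]: sin(pi*u)**(2n)."""
    return np.sin(np.pi * u) ** (2 * n)


def make_breathing_curve(
    kind: str = "irregular",
    mean_period_s: float = 4.0,
    mean_amplitude_cm: float = 1.0,
    duration_s: float = 120.0,
    period_jitter_pct: float = 15.0,
    amplitude_jitter_pct: float = 30.0,
    drift_cm_per_min: float = 0.0,
    ap_ratio: float = DEFAULT_AP_RATIO,
    shape_power: int = DEFAULT_SHAPE_POWER,
    sample_rate_hz: float = 100.0,
    seed: int = 0,
) -> MotionProgram:
    """Generate a regular or irregular breathing program.

    regular: identical cycles ``A * sin(pi*(t - t_i)/T)**(2n)`` concatenated
    trough to trough, so maxima equal A at mid-cycle and the signal is zero
    at cycle boundaries.  irregular: each cycle's period and amplitude are
    multiplied by lognormal factors with the given percent coefficients of
    variation, and a linear baseline drift is added.  The A-P channel is
    the S-I channel scaled by ``ap_ratio``.
    """
    if kind not in ("regular", "irregular"):
        raise ValueError(f"unknown curve kind {kind!r}")
    if not (SI_AMPLITUDE_RANGE_CM[0] <= mean_amplitude_cm <= SI_AMPLITUDE_RANGE_CM[1]):
        warnings.warn(
            f"mean amplitude {mean_amplitude_cm} cm outside the typical "
            f"{SI_AMPLITUDE_RANGE_CM} cm platform range",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s, 1.0 / sample_rate_hz)
    si = np.zeros_like(t)
    cycle_records: List[Tuple[float, float, float]] = []  # (start, period, amplitude)
    t0 = 0.0
    while t0 < duration_s:
        if kind == "regular":
            period, amp = mean_period_s, mean_amplitude_cm
        else:
            period = mean_period_s * _lognormal_factor(rng, period_jitter_pct)
            amp = mean_amplitude_cm * _lognormal_factor(rng, amplitude_jitter_pct)
            amp = min(amp, MAX_CYCLE_AMPLITUDE_CM)  # platform excursion limit
        period = max(period, 1.2)  # keep cycles physically plausible
        cycle_records.append((t0, period, amp))
        in_cycle = (t >= t0) & (t < t0 + period)
        u = (t[in_cycle] - t0) / period
        si[in_cycle] = amp * _cycle_shape(u, shape_power)
        t0 += period
    si = si + drift_cm_per_min * t / 60.0
    meta = {
        "kind": kind,
        "mean_period_s": mean_period_s,
        "mean_amplitude_cm": mean_amplitude_cm,
        "period_jitter_pct": period_jitter_pct if kind == "irregular" else 0.0,
        "amplitude_jitter_pct": amplitude_jitter_pct if kind == "irregular" else 0.0,
        "drift_cm_per_min": drift_cm_per_min,
        "ap_ratio": ap_ratio,
        "shape_power": shape_power,
        "seed": seed,
        "cycles": cycle_records,
    }
    return MotionProgram(t, si, ap_ratio * si, metadata=meta)


def _lognormal_factor(rng: np.random.Generator, cv_pct: float) -> float:
    """Unit-median lognormal multiplier with the given percent CV."""
    if cv_pct <= 0:
        return 1.0
    sigma = np.sqrt(np.log1p((cv_pct / 100.0) ** 2))
    return float(rng.lognormal(mean=0.0, sigma=sigma))


def synthesize_surrogates(
    program: MotionProgram,
    rpm_model: Optional[SurrogateModel] = None,
    bellows_model: Optional[SurrogateModel] = None,
    beam_window: Tuple[float, float] = (0.0, 60.0),
    seed: int = 0,
) -> Tuple[SurrogateTrace, SurrogateTrace]:
    """Sample two surrogate channels from one chest-wall motion program.

    Each channel samples ``gain * AP(t - lag) + noise`` on its own time
    grid spanning the program; ``beam_on`` is true exactly inside
    ``beam_window`` (the same wall-clock window for both channels, as the
    scanner's X-RAY ON signal is distributed to both systems).  A bellows
    plateau floor, when set, clamps that channel from below.
    """
    rpm_model = rpm_model or SurrogateModel(
        label=SurrogateLabel.RPM, gain=10.0, sampling_rate=30.0
    )
    bellows_model = bellows_model or SurrogateModel(
        label=SurrogateLabel.BELLOWS, gain=1.0, sampling_rate=38.0
    )
    t_start, t_end = program.span
    w0, w1 = beam_window
    if not (t_start <= w0 < w1 <= t_end):
        raise ValueError("beam_window must lie within the program span")
    rng = np.random.default_rng(seed)
    traces = []
    for model in (rpm_model, bellows_model):
        lag_s = model.lag_ms / 1000.0
        if abs(lag_s) >= (t_end - t_start):
            raise ValueError("surrogate lag exceeds the program span")
        times = np.arange(t_start, t_end, 1.0 / model.sampling_rate)
        amp = model.gain * program.ap_at(times - lag_s)
        if model.noise_sd > 0:
            amp = amp + rng.normal(0.0, model.noise_sd, size=times.shape)
        if model.plateau_floor is not None:
            amp = np.maximum(amp, model.plateau_floor)
        beam_on = (times >= w0) & (times <= w1)
        traces.append(
            SurrogateTrace(
                label=model.label,
                times=times,
                amplitudes=amp,
                beam_on=beam_on,
                nominal_rate=model.sampling_rate,
                meta={"lag_ms": model.lag_ms, "gain": model.gain, "seed": seed},
            )
        )
    return traces[0], traces[1]


@dataclass
class InsertSpec:
    """A high-contrast insert: sphere or box, physical units in mm."""

    shape: str = "sphere"  # "sphere" | "box"
    center_mm: Tuple[float, float, float] = (32.0, 32.0, 60.0)  # centre of the default grid
    size_mm: float | Tuple[float, float, float] = 30.0  # diameter or box edge lengths
    hu: float = 50.0


@dataclass
class PhantomSpec:
    """Grid geometry and insert list for the digital phantom."""

    shape: Tuple[int, int, int] = (32, 32, 60)
    spacing_mm: Tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    background_hu: float = -800.0
    inserts: List[InsertSpec] = field(default_factory=lambda: [InsertSpec()])


@dataclass
class DigitalPhantom:
    """A lung-mimicking HU slab with high-contrast inserts."""

    volume: Volume3D
    spec: PhantomSpec

    @property
    def insert_mask(self) -> Mask:
        """Voxels belonging to any insert (HU above the background)."""
        return Mask(
            self.volume.data != self.spec.background_hu,
            self.volume.spacing,
            self.volume.origin,
            label="insert",
        )


@dataclass
class AcquisitionConfig:
    """Helical oversampled acquisition geometry and timing."""

    slice_thickness_mm: float = 2.0
    rotation_period_s: float = 0.5
    couch_pitch: float = 0.08  # fraction of detector width advanced per rotation; 0.06-0.08 is typical for 4D CT
    detector_width_mm: float = 16.0
    scan_start_s: float = 0.0
    scan_stop_s: Optional[float] = None  # None: run until the couch clears the grid

    def __post_init__(self) -> None:
        if not (0.0 < self.couch_pitch <= 1.5):
            raise ValueError("couch_pitch must be in (0, 1.5]")
        if self.rotation_period_s <= 0:
            raise ValueError("rotation_period must be positive")

    @property
    def couch_speed_mm_s(self) -> float:
        return self.detector_width_mm * self.couch_pitch / self.rotation_period_s

    @property
    def dwell_s(self) -> float:
        """Time a fixed slice position stays under the detector."""
        return self.detector_width_mm / self.couch_speed_mm_s


@dataclass
class SliceRecord:
    """One simulated axial slice: where, when, and the pixel data."""

    couch_z: float
    acquisition_time: float
    pixels: np.ndarray
    pixel_spacing: Tuple[float, float]


def _voxel_centers(n: int, spacing: float, origin: float) -> np.ndarray:
    return origin + (np.arange(n) + 0.5) * spacing


def build_phantom(spec: Optional[PhantomSpec] = None) -> DigitalPhantom:
    """Voxelise the phantom: background slab plus centre-of-voxel inserts."""
    spec = spec or PhantomSpec()
    if any(s <= 0 for s in spec.spacing_mm):
        raise GeometryError("voxel spacing must be positive")
    nx, ny, nz = spec.shape
    data = np.full(spec.shape, spec.background_hu, dtype=np.float32)
    xs = _voxel_centers(nx, spec.spacing_mm[0], spec.origin_mm[0])
    ys = _voxel_centers(ny, spec.spacing_mm[1], spec.origin_mm[1])
    zs = _voxel_centers(nz, spec.spacing_mm[2], spec.origin_mm[2])
    extent_lo = [spec.origin_mm[d] for d in range(3)]
    extent_hi = [spec.origin_mm[d] + spec.shape[d] * spec.spacing_mm[d] for d in range(3)]
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    for ins in spec.inserts:
        cx, cy, cz = ins.center_mm
        if ins.shape == "sphere":
            r = float(ins.size_mm) / 2.0
            lo = [cx - r, cy - r, cz - r]
            hi = [cx + r, cy + r, cz + r]
            inside = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= r**2
        elif ins.shape == "box":
            sz = ins.size_mm if isinstance(ins.size_mm, (tuple, list)) else (ins.size_mm,) * 3
            lo = [c - s / 2 for c, s in zip(ins.center_mm, sz)]
            hi = [c + s / 2 for c, s in zip(ins.center_mm, sz)]
            inside = (
                (np.abs(X - cx) <= sz[0] / 2)
                & (np.abs(Y - cy) <= sz[1] / 2)
                & (np.abs(Z - cz) <= sz[2] / 2)
            )
        else:
            raise GeometryError(f"unknown insert shape {ins.shape!r}")
        if any(l < el for l, el in zip(lo, extent_lo)) or any(
            h > eh for h, eh in zip(hi, extent_hi)
        ):
            raise GeometryError(f"insert {ins} extends outside the phantom grid")
        data[inside] = ins.hu
    return DigitalPhantom(Volume3D(data, spec.spacing_mm, spec.origin_mm), spec)


def shift_volume_z(volume: Volume3D, shift_mm: float, fill: float) -> np.ndarray:
    """Return the volume's data translated along z by the nearest voxel count.

    Voxels shifted in from outside the grid take the *fill* value (the
    phantom slab continues beyond the field of view).
    """
    k = int(round(shift_mm / volume.spacing[2]))
    out = np.full_like(volume.data, fill)
    if k == 0:
        return volume.data.copy()
    if k > 0:
        out[:, :, k:] = volume.data[:, :, :-k]
    else:
        out[:, :, :k] = volume.data[:, :, -k:]
    return out


def object_mask(phantom: DigitalPhantom, displacement_cm: float) -> Mask:
    """Insert mask with the object translated by *displacement_cm* along S-I."""
    shifted = shift_volume_z(
        phantom.volume, displacement_cm * 10.0, phantom.spec.background_hu
    )
    return Mask(
        shifted != phantom.spec.background_hu,
        phantom.volume.spacing,
        phantom.volume.origin,
        label=f"object@{displacement_cm:+.3f}cm",
    )


def simulate_acquisition(
    phantom: DigitalPhantom,
    program: MotionProgram,
    config: Optional[AcquisitionConfig] = None,
) -> List[SliceRecord]:
    """Simulate a low-pitch helical scan of the moving phantom.

    The couch advances at ``detector_width * pitch / rotation_period``.
    Once per rotation, every slice position currently under the detector is
    imaged; the slice pixels are read from the phantom translated in z by
    the S-I displacement at that rotation's time (nearest-voxel shift).
    With pitch low enough that the dwell time per position exceeds one
    breathing period, every position is imaged across a full cycle.
    """
    config = config or AcquisitionConfig()
    vol = phantom.volume
    zs = _voxel_centers(vol.shape[2], vol.spacing[2], vol.origin[2])
    speed = config.couch_speed_mm_s
    half_w = config.detector_width_mm / 2.0
    # detector centre sweeps from below the first slice to above the last
    z_first = zs[0] - half_w
    z_last = zs[-1] + half_w
    total_time = (z_last - z_first) / speed
    t_stop = (
        config.scan_stop_s
        if config.scan_stop_s is not None
        else config.scan_start_s + total_time
    )
    if program.span[1] < t_stop or program.span[0] > config.scan_start_s:
        raise CoverageError(
            f"motion program [{program.span[0]}, {program.span[1]}] s does not cover "
            f"the scan [{config.scan_start_s}, {t_stop}] s"
        )
    records: List[SliceRecord] = []
    n_rot = int(np.floor((t_stop - config.scan_start_s) / config.rotation_period_s))
    bg = phantom.spec.background_hu
    for k in range(n_rot + 1):
        t = config.scan_start_s + k * config.rotation_period_s
        if t > t_stop:
            break
        z_center = z_first + speed * (t - config.scan_start_s)
        active = np.flatnonzero(np.abs(zs - z_center) <= half_w)
        if active.size == 0:
            continue
        shifted = shift_volume_z(vol, float(program.si_at(t)) * 10.0, bg)
        for iz in active:
            records.append(
                SliceRecord(
                    couch_z=float(zs[iz]),
                    acquisition_time=t,
                    pixels=shifted[:, :, iz].copy(),
                    pixel_spacing=(vol.spacing[0], vol.spacing[1]),
                )
            )
    return records


def ground_truth_itv(phantom: DigitalPhantom, program: MotionProgram) -> Mask:
    """Union of object masks at end-inhale, end-exhale and mid displacement.

    End-inhale is the program's global maximum S-I displacement, end-exhale
    the global minimum, and mid their midpoint -- the three platform pause
    positions whose union defines the artifact-free reference ITV.
    """
    si = program.si_displacement
    ei = float(si.max())
    ee = float(si.min())
    mid = 0.5 * (ei + ee)
    union = np.zeros(phantom.volume.shape, dtype=bool)
    for d in (ei, ee, mid):
        union |= object_mask(phantom, d).data
    return Mask(union, phantom.volume.spacing, phantom.volume.origin, label="itv_true")
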