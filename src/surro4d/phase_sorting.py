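"""Retrospective phase assignment and slice sorting.

Each breathing cycle is delimited by two consecutive end-inhale (0%) tags.
Between tags the respiratory phase grows linearly with time from 0 to 1
(time-based, not amplitude-based sorting), so 50% falls at mid-cycle, which
coincides with end-exhale for symmetric breathing.  Phases are then binned
into ``n_bins`` equally spaced bins (10 by default: 0%, 10%, ..., 90%) by
circular nearest-centre assignment, and for every couch position the slice
whose continuous phase is circularly closest to each bin centre is selected
to assemble the per-phase volumes.

Tags normally come straight from the end-inhale peak detector
(:func:`auto_tag`); :func:`edit_tags` supports the manual add/remove
corrections that clinical practice applies when a breathing cycle is missed
or mis-tagged, keeping an audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np

from .image_metrics import Volume3D
from .waveform_analysis import InsufficientDataError, PeakList

__all__ = [
    "TagList",
    "PhaseMap",
    "PhaseStudy",
    "TagEditError",
    "auto_tag",
    "edit_tags",
    "assign_phase",
    "circular_phase_distance",
    "sort_slices",
    "save_phase_study",
]

MIN_TAG_SEPARATION_S = 1.0


class TagEditError(ValueError):
    """A tag edit would violate the tag-list invariants."""


@dataclass
class TagList:
    """End-inhale (0% phase) tags with edit provenance."""

    tag_times: np.ndarray
    provenance: List[str]  # "auto" or "manual_add", per tag
    removed_times: List[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.tag_times = np.asarray(self.tag_times, dtype=float)
        if len(self.tag_times) != len(self.provenance):
            raise ValueError("tag_times and provenance must have equal length")
        if len(self.tag_times) > 1:
            gaps = np.diff(self.tag_times)
            if not np.all(gaps > 0):
                raise ValueError("tag_times must be strictly increasing")
            if np.any(gaps <= MIN_TAG_SEPARATION_S):
                raise ValueError(
                    f"consecutive tags must be more than {MIN_TAG_SEPARATION_S} s apart"
                )

    def __len__(self) -> int:
        return len(self.tag_times)


@dataclass
class PhaseMap:
    """Continuous phase and phase bin for a set of time points.

    phase_fraction is in [0, 1) with 0 at end-inhale; valid is false for
    times before the first or after the last tag (no cycle context).
    """

    times: np.ndarray
    phase_fraction: np.ndarray
    phase_bin: np.ndarray  # bin centre in percent: 0, 10, ..., 90
    valid: np.ndarray


@dataclass
class PhaseStudy:
    """Per-phase sorted volumes plus provenance and artifact bookkeeping."""

    bin_percents: List[int]
    volumes: Dict[int, Volume3D]
    provenance: List[dict]  # one record per selected slice
    artifact_flags: List[Tuple[float, int]]  # (couch_z_mm, bin_percent) without admissible slice
    n_excluded_slices: int = 0
    selection_rule: str = "closest-phase"


def auto_tag(peaks: PeakList) -> TagList:
    """Tag every detected end-inhale peak as a 0% phase marker."""
    if len(peaks) < 2:
        raise InsufficientDataError(
            "phase sorting requires at least two end-inhale tags (one full cycle)"
        )
    return TagList(peaks.peak_times.copy(), ["auto"] * len(peaks))


def edit_tags(
    tags: TagList,
    add: Sequence[float] = (),
    remove: Sequence[float] = (),
    tol_s: float = 1e-6,
) -> TagList:
    """Apply manual tag corrections (missed or spurious breathing cycles).

    Removals are matched to existing tags within ``tol_s`` and logged in
    ``removed_times``; additions must respect the minimum 1 s separation
    from surviving tags or the edit is rejected.
    """
    times = list(tags.tag_times)
    prov = list(tags.provenance)
    removed = list(tags.removed_times)
    for r in remove:
        matches = [i for i, t in enumerate(times) if abs(t - r) <= tol_s]
        if not matches:
            raise TagEditError(f"no tag within {tol_s} s of removal time {r}")
        i = matches[0]
        removed.append(times.pop(i))
        prov.pop(i)
    for a in add:
        if any(abs(t - a) <= MIN_TAG_SEPARATION_S for t in times):
            raise TagEditError(
                f"added tag at {a} s violates the {MIN_TAG_SEPARATION_S} s separation rule"
            )
        times.append(float(a))
        prov.append("manual_add")
    order = np.argsort(times)
    return TagList(
        np.asarray(times)[order],
        [prov[i] for i in order],
        removed_times=removed,
    )


def _bin_from_fraction(frac: np.ndarray, n_bins: int) -> np.ndarray:
    """Nearest bin centre with wraparound; exact midpoints round down.

    Bin centres sit at k/n_bins.  A fraction exactly halfway between two
    interior centres is assigned to the lower one; a fraction within half a
    bin of 1.0 wraps around to bin 0.
    """
    scaled = frac * n_bins
    idx = np.ceil(scaled - 0.5).astype(int)  # round-half-down
    idx[scaled >= n_bins - 0.5] = n_bins  # wrap ties at the top toward 0
    return (idx % n_bins).astype(int)


def assign_phase(times: Sequence[float], tags: TagList, n_bins: int = 10) -> PhaseMap:
    """Linearly interpolate respiratory phase between consecutive tags.

    For t between tags T_i and T_{i+1}: fraction = (t - T_i)/(T_{i+1} - T_i).
    Times outside [first tag, last tag] are marked invalid.  Bins are the
    centres {0, 1/n, ..., (n-1)/n} assigned by circular nearest distance.
    """
    if len(tags) < 2:
        raise InsufficientDataError("phase assignment requires at least two tags")
    t = np.asarray(times, dtype=float)
    tag_t = tags.tag_times
    valid = (t >= tag_t[0]) & (t <= tag_t[-1])
    # index of the cycle each time falls in
    seg = np.clip(np.searchsorted(tag_t, t, side="right") - 1, 0, len(tag_t) - 2)
    t0 = tag_t[seg]
    t1 = tag_t[seg + 1]
    frac = np.where(valid, (t - t0) / (t1 - t0), 0.0)
    frac = np.clip(frac, 0.0, None)
    frac = np.where(frac >= 1.0, 0.0, frac)  # the last tag itself is phase 0
    bins = _bin_from_fraction(frac, n_bins) * (100 // n_bins)
    return PhaseMap(times=t, phase_fraction=frac, phase_bin=bins, valid=valid)


def circular_phase_distance(a: np.ndarray, b: float) -> np.ndarray:
    """Distance between phase fractions on the unit circle (max 0.5)."""
    d = np.abs(np.asarray(a) - b) % 1.0
    return np.minimum(d, 1.0 - d)


@dataclass
class _SliceLike:
    couch_z: float
    acquisition_time: float
    pixels: np.ndarray
    pixel_spacing: Tuple[float, float]


def sort_slices(
    slices: Sequence,
    phase_map: PhaseMap,
    n_bins: int = 10,
    fill_missing: bool = True,
) -> PhaseStudy:
    """Sort oversampled slices into per-phase volumes, one per bin.

    ``phase_map`` must be evaluated at the slices' acquisition times (same
    order).  For each couch position and bin, the admissible slices are
    those whose (tie-broken) nearest bin is that bin -- i.e. whose
    continuous phase falls inside the bin's interval; among them the
    circularly closest to the bin centre is selected.  A (position, bin) pair with no
    admissible slice is recorded in ``artifact_flags`` and -- when
    ``fill_missing`` -- filled with the globally closest-phase slice at
    that position, mimicking the duplication artifact a scanner produces
    when a phase was never sampled at a couch position.  Slices at invalid
    (untagged) times are excluded and counted.
    """
    slices = list(slices)
    if len(phase_map.times) != len(slices):
        raise ValueError("phase_map must be evaluated at the slice acquisition times")
    centers = [k / n_bins for k in range(n_bins)]
    bin_percents = [int(round(c * 100)) for c in centers]

    by_couch: Dict[float, List[int]] = {}
    n_excluded = 0
    for i, s in enumerate(slices):
        if not phase_map.valid[i]:
            n_excluded += 1
            continue
        by_couch.setdefault(round(float(s.couch_z), 6), []).append(i)
    if not by_couch:
        raise InsufficientDataError("no slices at valid (tagged) times")
    couch_zs = sorted(by_couch)

    provenance: List[dict] = []
    artifact_flags: List[Tuple[float, int]] = []
    # (bin -> list of 2D arrays ordered by couch position)
    stacks: Dict[int, List[np.ndarray]] = {bp: [] for bp in bin_percents}
    for z in couch_zs:
        idxs = by_couch[z]
        fracs = phase_map.phase_fraction[idxs]
        assigned = _bin_from_fraction(fracs, n_bins) * (100 // n_bins)
        for c, bp in zip(centers, bin_percents):
            dist = circular_phase_distance(fracs, c)
            in_bin = assigned == bp
            if in_bin.any():
                cand = np.flatnonzero(in_bin)
                best = int(cand[np.argmin(dist[cand])])
            else:
                best = int(np.argmin(dist))
            admissible = bool(in_bin.any())
            if not admissible:
                artifact_flags.append((z, bp))
                if not fill_missing:
                    stacks[bp].append(np.full(slices[idxs[0]].pixels.shape, np.nan))
                    continue
            chosen = idxs[best]
            stacks[bp].append(slices[chosen].pixels)
            provenance.append(
                {
                    "couch_z_mm": z,
                    "bin_percent": bp,
                    "acquisition_time_s": float(slices[chosen].acquisition_time),
                    "phase_fraction": float(phase_map.phase_fraction[chosen]),
                    "admissible": bool(admissible),
                }
            )

    first = slices[by_couch[couch_zs[0]][0]]
    dz = (
        float(np.median(np.diff(couch_zs)))
        if len(couch_zs) > 1
        else 1.0
    )
    spacing = (first.pixel_spacing[0], first.pixel_spacing[1], dz)
    origin = (0.0, 0.0, couch_zs[0] - 0.5 * dz)
    volumes = {
        bp: Volume3D(np.stack(stacks[bp], axis=-1), spacing, origin)
        for bp in bin_percents
    }
    return PhaseStudy(
        bin_percents=bin_percents,
        volumes=volumes,
        provenance=provenance,
        artifact_flags=artifact_flags,
        n_excluded_slices=n_excluded,
    )


def save_phase_study(study: PhaseStudy, out_dir: Union[str, Path]) -> None:
    """Write one NIfTI per phase bin plus the artifact-flag CSV."""
    from .image_metrics import save_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for bp in study.bin_percents:
        save_volume(study.volumes[bp], out / f"phase_{bp:02d}.nii.gz")
    with (out / "artifact_flags.csv").open("w", encoding="utf-8") as fh:
        fh.write("couch_z_mm,bin_percent\n")
        for z, bp in study.artifact_flags:
            fh.write(f"{z:.3f},{bp}\n")
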