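# Methods

This note documents the models, numerical choices and limitations behind
`surro4d`. It covers the waveform-comparison chain, the phase-sorting
model, the synthetic study (breathing programs, surrogate transduction,
phantom and acquisition), the similarity metrics, and what the synthetic
validation does and does not demonstrate about real data.

## Surrogate traces and synchronisation

A surrogate trace is a time series of (time, amplitude, beam-on) samples.
The two supported file dialects differ only superficially: the VXP-style
export carries amplitude (mm), a vendor phase column, millisecond
timestamps, a validity flag, the TTL beam indicator and a mark column; the
bellows-style CSV carries seconds, displacement in arbitrary pressure
units, and the beam flag. Both are reduced to seconds internally. The
vendor phase column is carried through file round trips but never used for
sorting — clinical practice retags end-inhale manually when the automatic
tags miss a cycle, so the file phase is treated as advisory.

All analysis is restricted to the first contiguous beam-on (X-RAY ON)
interval and the first retained sample defines t = 0 for each channel.
Because both systems receive the same scanner beam signal, this gives the
two channels a mutual origin up to one sample period; the residual
misalignment (< 33 ms for a 30 Hz channel) is the irreducible
synchronisation error of the method and is why latency-recovery accuracy
is quoted in units of one rpm sample interval (33.4 ms).

The faster channel is downsampled onto the slower channel's timestamps by
linear interpolation (the error for breathing-band signals is O(h²f″),
~2·10⁻⁴ of amplitude for a 4 s sine at 38 Hz, negligible against the
quantities of interest). Beam flags are taken from the nearest original
sample.

## End-inhale peak detection

Peaks are local maxima with prominence of at least 10% of the trace's
amplitude range and at least 1.5 s separation (supporting breathing up to
40 breaths/min, comfortably above the 7–22 BPM envelope the generator
emulates). Around each maximum, the maximal run of consecutive samples
within 2% of the range below the peak value is examined: if the run lasts
longer than 0.3 s the peak is reported at the run's temporal midpoint
("plateau_midpoint"), which handles truncated or flat-topped cycles — a
pressure belt that is not taut enough clamps the extreme positions, and
the midpoint is then a better estimate of the true extremum time than any
single sample. Monotone traces simply yield no peaks.

Amplitudes are normalised by the largest amplitude attained at a detected
peak, so the tallest end-inhale peak sits at exactly 1 in both channels;
this is what makes a mm-scale channel comparable with an arbitrary-unit
channel. Normalisation is idempotent and cannot move peak times. The
alternative convention — dividing by the global maximum sample — differs
only when noise spikes exceed every true peak; the detected-peak
convention was chosen because it is robust to exactly that case.

## Latency

Peaks of the two channels are paired greedily by increasing absolute time
difference, each peak used at most once, with pairs farther apart than
half the median breathing period discarded (this prevents cross-cycle
mismatches on irregular traces). For a pair (t_rpm, t_bellows) the latency
is Δt = (t_bellows − t_rpm) in ms, so a positive value means the rpm
end-inhale occurred first (rpm leads). Summaries report mean, sample SD
(n − 1), min/max and a histogram over half-open (left, right] bins aligned
to multiples of the bin width (default 20 ms); a 10⁻⁹ ms epsilon keeps
deltas that land exactly on an edge in the lower bin regardless of float
representation.

Statistical comparisons use the Pearson product-moment correlation between
the normalised, co-sampled amplitude series, and a two-sided Mann–Whitney
U test (exact by enumeration when the pooled sample has ≤ 20 observations
and no ties, otherwise the normal approximation with tie and continuity
corrections). %CV = sample SD / mean × 100 over beam-on samples quantifies
amplitude irregularity; breathing rate is the detected peak count divided
by the analysed duration.

## Phase sorting

Phase is linear in time between consecutive end-inhale tags: for t between
tags T_i and T_{i+1}, fraction = (t − T_i)/(T_{i+1} − T_i), with 0% at
end-inhale; 50% coincides with end-exhale for time-symmetric cycles. Times
before the first or after the last tag have no cycle context and are
marked invalid rather than extrapolated. Fractions are binned to the
nearest of the n = 10 centres {0, 0.1, …, 0.9} with circular wraparound
(fraction ≥ 0.95 belongs to bin 0); an exact midpoint between two interior
centres goes to the lower bin, for determinism. n is configurable —
published comparisons report similar target volumes with as few as 4–6
phases — but 10 is the clinical default.

Slices are grouped by couch position. For each (position, bin), slices
whose tie-broken nearest bin is that bin are admissible and the one
circularly closest to the bin centre is selected; a pair with no
admissible slice is recorded as an artifact flag and, by default, filled
with the globally closest-phase slice at that position — the duplication
artifact a scanner produces when a phase was never sampled during the
dwell. The closest-phase selection rule (rather than first-acquired) is
recorded in the study's `selection_rule` metadata. Each output volume
notes per-slice provenance: couch position, acquisition time, continuous
phase at selection, and whether the selection was admissible.

## The synthetic study

**Breathing programs.** A cycle is a raised-cosine power,
s(u) = A·sin(πu)^(2n) for u ∈ [0, 1] (trough to trough; n = 2 by default,
giving the long exhale dwell real traces show and a per-sample amplitude
%CV near 100%). Cycles are concatenated trough-to-trough so that per-cycle
amplitude changes never introduce discontinuities. The irregular kind
multiplies each cycle's period and amplitude by unit-median lognormal
factors with configurable percent CVs and adds a linear baseline drift;
per-cycle amplitude is capped at 2.5 cm so jittered cycles stay inside the
0.5–3 cm excursion range a motion platform replays. The chest-wall (A-P)
channel — what the surrogates actually see — is the target (S-I) channel
scaled by 0.3 by default; the exact coupling ratio of a platform is not
critical because both surrogates see the same A-P signal.

**Case envelope.** A batch of simulated cases emulates a set of *distinct*
replayed patient curves, not replicates of one statistical pattern: per
case, the mean period spans 7–22 breaths/min, amplitude jitter 10–60%,
period jitter 5–25% and baseline drift ±0.1 cm/min, with a latent
irregularity factor coupling slower breathing to stronger jitter, the
association observed across published replayed-curve statistics. All draws
are deterministic in the case seed.

**Surrogate transduction.** Each channel samples
gain · AP(t − lag) + ε, ε ~ N(0, σ²), on its own grid (30 Hz rpm, 38 Hz
bellows), with an optional plateau floor clamping the bellows from below
(the belt-truncation effect). The beam window is identical in wall-clock
time for both channels.

**Phantom and acquisition.** The phantom is a −800 HU slab (inside the
−900…−600 HU lung window) with high-contrast inserts, default one 3 cm
sphere at +50 HU, on a 32×32×60 grid at 2 mm isotropic spacing. Voxels
are assigned by centre-of-voxel inclusion. The helical acquisition moves
the couch at detector_width × pitch / rotation_period (defaults 16 mm ×
0.08 / 0.5 s = 2.56 mm/s, dwell 6.25 s per position — longer than the 4 s
mean breathing period, as oversampled 4D CT requires); once per rotation
every slice position under the detector images the phantom translated
along z by the program's S-I displacement at that instant, as a
nearest-voxel shift. No projection or reconstruction physics is modelled:
the comparisons of interest concern sorting and delineation, not
reconstruction fidelity.

**Ground truth.** The reference ITV is the union of the object mask at the
program's global maximum displacement (end-inhale), global minimum
(end-exhale) and their midpoint — the three positions at which a physical
platform is paused for static reference scans. It represents the
artifact-free envelope; a sorted, MIP-derived ITV can only reach
displacements actually sampled during each position's dwell, which is why
irregular breathing produces systematic underestimation, stronger for
higher amplitude variability and slower breathing.

## Image metrics

Arrays are indexed [ix, iy, iz] with x lateral, y anterior–posterior, z
superior–inferior; the physical centre of voxel (i, j, k) is
origin + (index + 0.5) × spacing, in mm. The MIP is the voxelwise maximum
over phase volumes. Threshold segmentation selects an HU window inside an
ROI and keeps the largest 26-connected component; the simplified lung
segmentation discards air connected to the grid border, seeds from the
axial slice with the two largest enclosed air areas, and grows a
6-connected 3D flood fill (26-connectivity for component analysis,
6-connectivity for filling — the conservative choice that cannot leak
through voxel corners). DSC and OI are voxel-count ratios; DSC is
symmetric, OI deliberately is not (it measures inclusion of the accepted
volume in the test volume). Percent volume change is signed so that a
larger test volume gives a negative value. Centroids are unweighted means
of voxel-centre coordinates. Masks and volumes are exchanged as NIfTI.

Unlike the clinical workflow, no manual contour adjustment is applied
after thresholding — the segmentations here are exactly reproducible,
which removes observer variability but also means small manual-edit
effects present in published per-case numbers are not modelled.

## Validation scale and determinism

The default study sizes keep every computation small: 90–120 s breathing
programs, a 32×32×60 phantom, ~680 slice records per scan, batches of 8
cases, 20 seeds per injected-lag condition. The full test suite runs in a
few seconds; the acceptance script in a few. All generators take explicit
seeds and are bit-reproducible; batch tables ship a trailing mean/SD pair
and every report file embeds the configuration hash and seed.

## What the synthetic results do and do not show

Passing tests demonstrate that the pipeline is internally consistent and
recovers known injected effects: latency to within one rpm sample at zero
noise (50 ms at 5% noise), near-exact dual-surrogate sorting concordance
when both channels see the same motion without noise or lag, systematic
positive MIP underestimation of the ground-truth ITV under irregular
breathing, and a positive rank association between amplitude %CV and that
underestimation. They do not establish hardware-specific quantities —
real inter-system latencies, absolute target volumes, or per-patient
waveform correlations depend on the physical systems and patients and can
only be measured, not simulated; the bundled published summary tables are
included precisely so the derivable statistics of such a measurement can
be recomputed and cross-checked offline.

## Known limitations

* Slice imaging is geometric resampling with nearest-voxel z-shifts: no
  partial volume blur, scatter, cone-beam geometry or cardiac motion.
* The bellows plateau floor is a hard clamp; real belts saturate softly.
* Surrogate noise is white Gaussian; real channels show drift and
  quantisation structure.
* The missing-phase fill rule duplicates the closest-phase slice, which is
  one plausible vendor behaviour among several.
* Phase is assigned linearly in time between tags; amplitude-based binning
  is out of scope.
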