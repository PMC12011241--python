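# Methods

## Signal model and preprocessing

Marker trajectories are treated as uniformly sampled 3D tracks (default
120 Hz) with an explicit axis convention (default X = mediolateral,
Y = anteroposterior, Z = vertical; configurable, because lab frames vary
and a silent ML/VT swap is the most damaging mistake this kind of pipeline
can make). All internal lengths are millimetres, times seconds.

Invalid samples are never zero-filled: gaps of at most 10 frames are
linearly interpolated per coordinate; anything longer rejects the trial
with a diagnostic, since both range statistics and minimum detection are
untrustworthy across long occlusions.

Filtering is a 4th-order Butterworth low-pass at 6 Hz, applied
forward–backward (zero phase) to every coordinate independently, with odd
reflection padding of 3·(order+1) samples per edge. Zero-phase filtering is
the norm in gait kinematics because event timing must not be lagged;
"4th order" names the single-pass design order (the two-pass magnitude is
effectively 8th order), and `order_interpretation="effective"` halves the
prototype order for readers who use the other convention. Because the
filter is linear, filtering all coordinates before extracting ML components
is equivalent to the reverse order.

## Events and cycles

Heel contact is the frame at which the heel marker's vertical coordinate is
lowest within a stride. On a treadmill this is implemented as local minima
of the filtered vertical heel series with two guards: a prominence floor
(default 2 mm, well below any physiological heel lift but above filtered
noise) and a minimum separation (default 0.4 × the expected stride time for
the speed preset — Normal 1.05 s, Slow 1.63 s). Flat minima resolve to the
earliest frame of the plateau. A global minimum would find one contact per
trial; the local-minimum form finds one per stride, which is what cycle
segmentation needs.

A gait cycle runs from one left heel contact to the next and must contain
exactly one right contact; trials violating left/right alternation are
rejected, not repaired. Seven consecutive cycles are extracted starting at
the first left contact after a 2 s settling interval (recordings are ~30 s;
which seven cycles are used is a free choice, and skipping treadmill
spin-up is the conservative one). Both the cycle count and the start policy
are configurable.

## Parameters

Per cycle: stride time = (end − start)/fs; the two step widths are the
absolute ML separation of the heels at each lead contact (L→R at the right
contact, R→L at the closing left contact), step lengths the same on the AP
axis. The per-cycle step width that normalises %DIS is the mean of the two
step widths inside the cycle (options: first, min) — the cycle contains two
steps and using both is the least arbitrary reduction.

DIS is max − min of a segment's ML series over the half-open cycle slice
[start, end), so contiguous cycles never double-count their shared contact
frame. The pelvis ML series is the midpoint of the left and right PSIS
markers (a single-PSIS option exists); head and T4 use their markers
directly. %DIS is stored as the exact mm/mm ratio and rendered ×100.
CV-%DIS uses the sample SD (n−1) over the 7 per-cycle values — seven cycles
are a sample, not a population — with a population-SD flag for
compatibility.

## Repeated-measures ANOVA and the decomposition ladder

Designs are balanced and fully within-subject: step width (NB/WB) × speed
(Normal/Slow), plus body segment (head/T4/pelvis) for segment parameters.
The engine computes every effect's SS from cell/marginal means via
orthogonal projections (inclusion–exclusion over factor subsets), and tests
each within effect against its own participant × effect interaction mean
square — the standard univariate convention, giving error df N−1 per df of
a 2-level effect and 2(N−1) for the segment factor.

For effects with ≥ 2 numerator df, Mauchly's W is computed on the
covariance of orthonormally contrast-transformed subject scores
(Kronecker-product contrasts for interaction effects), with the usual
chi-square approximation; Greenhouse–Geisser ε = tr(S)²/(k·tr(S²)) on the
same matrix, bounded in [1/k, 1]. Both are always reported; the
GG-corrected p replaces the uncorrected one for significance decisions only
when Mauchly rejects at α. The engine agrees with pingouin to machine
precision on shared functionality and with a brute-force cell-means oracle
on small fixtures; sums of squares close the total to 1e−8 relative.

After a significant highest-order interaction, all simple two-way
interactions (one per level of the third factor, seven in total) are
tested; each significant simple interaction spawns simple–simple main
effects of its constituent factors at fixed levels of the other two
(deduplicated). Every simple or simple–simple effect of a factor set E is
the effect computed on the sliced cell means, tested against the **omnibus
error term of E** — the same MSE and error df for every stratum, which is
the convention of the repeated-measures packages this field uses and the
reason a single MSE value repeats down a simple-effects table.
Benjamini–Hochberg adjustment is applied within each tier's family (the
seven simple interactions; all spawned simple–simple tests). A
simple–simple segment effect whose adjusted p falls below 0.10 — trends
included, matching common reporting practice — triggers paired t-tests
among the three segments at that condition cell, BH-adjusted within the
cell's three pairs, with Cohen's d_av (mean difference over the average of
the two level SDs, sign preserving; d_z selectable).

Observed power uses the SPSS/G*Power convention λ = F·df₁ on the
noncentral F (noncentral t for pairwise tests). Published power values
computed from raw data effect sizes are generally not recoverable from an
F-ratio alone — power is not even monotone in F across table rows at
identical df — so reported powers here are exactly this convention and
nothing else. Degenerate inputs are explicit: a constant response reports
SS = 0, F = 0, p = 1; zero-variance differences with zero mean give p = 1,
d = 0; η²ₚ with both SS zero is NaN, not 0.

## Synthetic cohorts and what they do (not) show

The generator emulates the study conditions: 2 × 2 condition grid, 17
participants by default, ~30 s trials at 120 Hz, six markers. Stride times
are Gaussian per cycle (Normal 1.05 s, Slow 1.63 s, SD 0.02 s); heel
vertical motion is a raised cosine with exactly one minimum per stride at
the scheduled contacts; heel ML placements alternate at ±width/2 (NB 80 mm,
WB 280 mm — straddling the ≈240 mm pelvic width that motivates the wide
condition) with 10 mm placement noise, settling mid-swing so filtered
placements are stable at contact instants; heel AP follows a belt-speed
sawtooth so step length is physical. Segment sway is a per-cycle sinusoid
whose amplitude is the commanded DIS/2 times a lognormal per-cycle jitter
(CV 0.10 — lognormal keeps amplitudes positive and maps the CV parameter
directly onto CV-%DIS), times per-participant lognormal multipliers (a
common whole-body factor, CV 0.15, and a segment-specific factor, CV 0.05,
so segments are correlated within a person), plus AR(1) measurement noise
(φ = 0.9, σ = 1 mm) that stresses the filter more realistically than white
noise. Segment phase offsets (head 0, T4 0.2, pelvis 0.4 rad) break perfect
synchrony. The per-condition DIS presets follow the orderings reported for
this paradigm (T4 largest; narrow < wide; normal < slow) and are plain
config values, set once.

Every drawn quantity is recorded as ground truth, and `truth_compare`
scores pipeline estimates against registered tolerances. A parameter-level
fast path draws the same per-cycle quantities without frame synthesis for
thousand-replicate calibration studies; its null configuration (identical
conditions and segments) gives omnibus type-I error at the nominal 5 %
within Monte-Carlo tolerance.

What passing these simulations does **not** show: the generator has no
double-support timing, no pelvic drop, no drift or marker swaps, sinusoidal
rather than skewed sway waveforms, and exchangeable segment covariance —
real data can violate sphericity and stationarity in ways the synthetic
cohorts do not, which is precisely why Mauchly/GG handling is always on.

## Problem sizes and numerical choices

Default analyses use 17 participants × 4 conditions × 7 cycles (the study
design); calibration runs use 1000–2000 replicates at the parameter level
and 200 virtual participants for marker-level CV recovery. Tolerances used
by the recovery report: stride time 2 %, step width 5 %, DIS 5 %, %DIS 7 %,
CV-%DIS 15 % relative. Sums of squares below 1e−12 of the response energy
are clamped to zero to keep degenerate cases exact; scipy's noncentral F at
zero noncentrality is bypassed (power = α by definition). Events are
integers (frames); ±1 frame is the accepted discretisation for all
schedule-recovery checks.
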