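# Methods

## The measurement problem

Eco-HAB is an automated home-cage assay for mouse social behavior: four
housing compartments at the corners of a square, joined into a ring by four
tube corridors, each corridor carrying an RFID antenna at either end.
Subcutaneous transponders emit a unique 14-digit code when a mouse passes
under an antenna; the acquisition software writes every read-out to hourly
tab-separated text files.  All behavioral quantities are derived from this
event stream — the animals are never handled during testing.

This package reimplements the complete processing chain (raw-file IO →
session reconstruction → phase masking → behavioral measures) and couples
it to a ground-truth movement simulator so that every stage can be
validated quantitatively without animal data.

## Session reconstruction

A mouse is credited with residence in a compartment only between an entry
and an exit event.  Per mouse, the chronological event list e1…eN is
scanned in overlapping consecutive pairs, each classified by gap and
geometry:

1. gap < threshold (default **2 s**) → skipped (antenna re-read bursts, or
   a dash straight through a compartment);
2. same antenna, gap ≥ threshold → a visit to that antenna's nearest
   compartment;
3. two antennas of one corridor → skipped (corridor transit);
4. antennas of two corridors sharing a nearest compartment → a visit to
   that compartment;
5. anything else ("opposite") → skipped; such a pair requires at least one
   missed detection and is counted as an ambiguous position.

Rule 4 is applied at *antenna* granularity: a session is assigned only when
both antennas' nearest compartments coincide.  Two antennas in different
corridors whose nearest compartments differ are evidence of missed reads,
and assigning a compartment there would rest on provably incomplete data.
The fraction of above-threshold pairs falling into rule 5 is reported by
the diagnostics as the log's unidentified-position rate; on healthy
hardware it is well below 1%.

The `antennas_consecutive` flag is True for two-antenna visits (rule 4) and
False for single-antenna visits (rule 2).  Because pairs overlap, one event
may close a visit and open the next — exactly what happens when a mouse
walks from one compartment to an adjacent one.  No synthetic sessions are
invented at the edges of a recording: the first and last dwells of a mouse
lack a bounding event and are unobservable by construction.  Analysis
windows should therefore sit inside the recorded span; the recovery
experiments inset them by a few minutes.

Ties (two events at the same millisecond) are processed in log order and
fall to rule 1 (gap 0 < threshold), so they are harmless.

## Time, masking and formats

Timestamps are integer milliseconds since the Unix epoch; wall-clock text
in raw files is interpreted as UTC, making parsing independent of host
locale and timezone.  All intervals are half-open `[t1, t2)` so adjacent
phases never double-count an instant.

Two masking modes exist.  `start_based` reproduces the original scripts:
keep, whole, every session *starting* inside the window.  `clip` keeps
sessions overlapping the window and truncates them to it.  Duration-bearing
measures use `clip` internally, because start-based masking either drops or
over-counts time at window boundaries; `start_based` remains available for
comparability.  Clip mode conserves time exactly under any partition of a
span into consecutive windows (a tested invariant).

The on-disk dialect (date `DD.MM.YYYY`, time `HH:MM:SS.mmm`, tab-separated,
one file per wall-clock hour, event numbers restarting per file) is
configurable, since real installations may export other conventions.  Event
identity across overlapping hourly files is `(timestamp, antenna, code)`;
exact duplicates are dropped at load, while near-duplicate read bursts are
deliberately kept for the sessionizer's threshold rule to handle.
Corrupted recording segments are handled as user-declared exclusion
intervals subtracted from analysis windows (`subtract_exclusions`); no
automatic detector is attempted.

## Behavioral measures

With `t_ai` the fraction of the analysis interval mouse *a* spent in
compartment *i* (times normalized by interval length, so every quantity is
in [0, 1] and corridor/undetected time is the deficit from 1):

* **In-cohort sociability** of pair (a, b):
  `t_ab − (t_a1·t_b1 + t_a2·t_b2 + t_a3·t_b3 + t_a4·t_b4)`, where
  `t_ab = Σ_i t_abi` is the fraction of the interval the pair spent in the
  same compartment simultaneously.  The subtracted term is the expected
  co-residence under independent exploration, so the score is
  chance-corrected: 0 for independent animals, positive for affiliation,
  negative for avoidance.  Closed forms used as exactness checks: both
  animals in one compartment all the time → 0; perfectly synchronized
  50/50 split over two compartments → +0.5; perfectly anti-synchronized
  split → −0.5.  The attainable ceiling is
  `Σ_i min(t_ai, t_bi) − Σ_i t_ai·t_bi`.
* **Approach to social odor**: `(T_S/T_nS) / (t_S/t_nS)` with `T` times
  from a stimulus-phase bin and `t` times from a pre-stimulus baseline bin
  in the last dark phase before presentation.  Any zero denominator makes
  the ratio *undefined* (not infinite); undefined results feed the
  exclusion path, mirroring the treatment of extremely inactive animals.
  The default baseline bin has the same duration and the same offset from
  phase onset as the stimulus bin, controlling for circadian phase; it is
  fully overridable.  Statistics are always computed on raw ratios;
  log-scale display is presentation only.
* **Activity**: the number of visits (sessions starting) in a window.
* **QC exclusion**: an animal is excluded when it failed to visit every
  stimulus compartment at least once in the adaptation phase or in the
  testing phase; an animal with no sessions at all is excluded as
  "no visits".
* **Dominance score**: percent of tube-test confrontations won.

Group comparisons (Mann-Whitney U) and correlations (Pearson) are thin
wrappers over `scipy.stats`, with the conventional α = 0.05.

## The simulator

Mice perform a continuous-time walk on the ring: exponential dwell in a
compartment (mean **60 s** by default), then transit through one of the two
adjacent corridors (equal probability) taking a fixed **2.5 s** — above the
2-s threshold by design, so genuine corridor transits are classified by
geometry (rule 3) rather than discarded as short gaps.  Defaults emulate
free exploration during an adaptation phase, compressed to desk scale;
durations of one to eight simulated hours are used throughout the tests.

Couplings, both acting on the leaving rate because dwell time is exactly
what the downstream measures integrate:

* **Affinity**: while co-resident with affiliated partners, a mouse's
  leaving rate is divided by `1 + α*`, with `α*` the strongest affinity
  among its co-residents.  A per-partner multiplicative slowdown was
  considered and rejected: in an 8-mouse cohort with uniform strong
  affinity it compounds to a ~16000-fold slowdown, the cohort clumps into
  one compartment and stops crossing antennas, so the event stream (and
  every measure computed from it) collapses.  The strongest-partner rule is
  identical for a pair of mice, bounded for cohorts, and preserves
  monotonicity of measured sociability in α.
* **Odor effect**: from a configurable onset, dwell in a designated
  compartment is multiplied by `k` (rate divided by `k`).  By ring
  symmetry, visit frequencies to all compartments are equal, so the
  stationary occupancy ratio between the odor compartment and a control
  compartment approaches `k` — which is what the approach-ratio measure
  recovers.

Exponential dwells make rate changes (a partner arriving or leaving, the
odor switching on) exact to handle: the residual dwell is resampled at the
change point (memorylessness).  Each mouse draws from its own stream
spawned from the master seed, so runs are reproducible and mice are
independent unless coupled.

**Detection model**: each corridor-end passage yields, with probability
`1 − p_miss`, a burst of `1 + Poisson(λ)` reads; within-burst reads are
spaced 0.3 s apart, above the acquisition hardware's 210 ms
read-out-termination window (closer repeats would have been merged into a
single read-out) and below the 2-s threshold (so the sessionizer absorbs
them).  The default is perfect detection (`p_miss = 0`, single reads),
matching the measured hardware efficiency of at least one read per
crossing; imperfect settings are used to validate the diagnostics.

What the simulator deliberately does not model: circadian rhythm,
dominance, aggression, scent-mark diffusion, thigmotaxis, or any spatial
structure within a compartment.  Passing recovery tests therefore
demonstrates correctness of the *processing chain*, not realism of mouse
behavior: conclusions about real data still depend on the hardware
detection efficiency and on biological variability the simulator does not
emulate.

## Validation design

Every stage is checked against an independent oracle rather than against
itself: the sessionizer against a brute-force restatement of the pair rules
with its own hard-coded antenna table; duration sums against a 1-ms
discretized timeline (exact, since all timestamps are integer
milliseconds); end-to-end occupancy against the simulator's ground-truth
paths; the sociability score against closed-form scenarios and a
Monte-Carlo null; the odor ratio against the planted multiplier.  Problem
sizes (1000 random logs, 8-mouse 1–2 h cohorts, 50 mice with 4 h bins, 20
null pairs, 10+10 cohorts for the rank-sum comparison) were chosen so the
whole validation runs in seconds while keeping Monte-Carlo error small
relative to the tolerances tested.

Known numerical notes: the mean-of-ratios estimator for odor approach is
slightly biased upward at short bins (Jensen's inequality applied to the
baseline ratio in the denominator); 4-h bins keep this within a few
percent.  Sociability scores are exact rational arithmetic on millisecond
integers divided by interval length, hence the 1e-12 closed-form
tolerances.

## Known limitations

* The first and last visits of every recording are unobservable (no
  bounding event); analysis windows should be interior to the span.
* The exact on-disk date/time format of the original acquisition software
  is not published; the default dialect follows the only date format the
  system's configuration files use, and is configurable.
* Physical antenna numbering of real installations may differ from the
  canonical ring; a topology file maps antennas to corridors and nearest
  compartments.
* Sub-threshold visits (< 2 s) are invisible by design; they are part of
  the small residual in the occupancy-recovery experiments.
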