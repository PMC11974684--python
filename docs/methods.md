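# Methods

## The six-pool cleavage model

The model describes cis cleavage of a supercoiled plasmid target as two
sequential first-order steps with unproductive side branches. Pools (percent
of total plasmid): productive supercoiled `SC`, unproductive supercoiled
`ucSC`, productive nicked `NICK`, pre-nicked background `NICK1`,
unproductive nicked `ucNICK`, linear product `LIN`. Rates (all s⁻¹, all
bounded to [0, 100] during fitting):

| rate  | meaning | default / starting guess |
|-------|---------|---------------------------|
| `ka`  | NTS cleavage, SC → NICK (k_NTS) | 0.50 (fit guess) |
| `kb`  | TS cleavage, NICK → LIN (k_TS)  | 0.50 (fit guess) |
| `kini`  | SC (and NICK1) → unproductive | 0.01 (fit guess) |
| `kini2` | NICK → unproductive           | 0.01 (fit guess) |

Rates are in s⁻¹ because all assay time points are in seconds. The
observables are `TotSC = SC + ucSC`, `TotNICK = NICK + NICK1 + ucNICK`, and
`LIN`; the unproductive pools are what let the observable sums plateau below
complete conversion.

### The two variants

The transcribed equations contain `-ka·NICK1` inside d/dt NICK: the
pre-nicked pool decays at `ka + kini` *and* the same `ka·NICK1` flux is
subtracted from `NICK`, feeding no pool, so total mass decays at
`2·ka·NICK1(t)`. Whether this is the intended behaviour of the upstream
model or a transcription slip cannot be decided from the source text, so
both readings are implemented:

* `as_printed` (default) — the literal equations. Total mass follows
  `total(0) − 2·ka·initNICK1·(1−e^{−(ka+kini)t})/(ka+kini)`, which
  `printed_total_mass()` provides in closed form and the tests verify to
  1e−6.
* `mass_conserving` — the term flipped to `+ka·NICK1` (re-cleaved pre-nicked
  plasmid joins the productive nicked pool); total mass is exactly constant.

With no pre-nicked material the variants coincide and mass is conserved in
both. A consequence of the printed term worth knowing: if
`initNICK1 > initSC`, `NICK` can go transiently negative in `as_printed`
mode. Because `SC` and `NICK1` decay at the identical rate `ka + kini`,
non-negativity of every pool is guaranteed whenever `initSC ≥ initNICK1` —
true of any real plasmid prep and of all generator presets — and that is the
regime in which the non-negativity and monotonicity properties are tested.

### Numerics

The system is linear, `x' = A x` with constant `A`, so the implementation
builds `A` once and hands the solver its exact Jacobian. Integration uses
LSODA (stiff-capable, adaptive) with rtol 1e−10 / atol 1e−12; at these
settings the solution agrees with the closed-form sequential scheme (the
`kini = kini2 = 0`, pure SC start limit) to better than 1e−7 percentage
points over [0, 300] s grids, and halving tolerances moves no value by more
than 1e−6. The closed form switches to its `ka = kb` branch when
`|kb − ka| < 1e−12·max(ka, kb, 1)` to avoid catastrophic cancellation.

A convention worth stating: `integrate` applies the initial condition at
`times[0]`, i.e. the first observed sample defines the time origin. This
matches how fitting reads its initial pools (below) and makes the
generator → fit round trip exact.

## Fitting

Per replicate: residuals of the three observable series at the replicate's
time points, pooled unweighted (the source analysis states no weighting),
minimised by bounded trust-region-reflective least squares
(`scipy.optimize.least_squares`, ftol/xtol/gtol 1e−12). Initial pools are
read from the earliest observed time point
(`initSC, initNICK1, initLIN ← totSC, totNICK, lin`), not fitted — the
observed nicked fraction at t₀ is attributed entirely to the pre-nicked
pool. Data are renormalised per time point to sum to exactly 100 before
fitting (gel quantification drifts; the CSV reader accepts sums in
[95, 105]).

Ten restarts guard against local minima: the first from the standard guess,
the rest from seeded multiplicative jitters (factors log-uniform in
[0.1, 10] per parameter); the best final cost wins. Fits are
bit-reproducible under a fixed seed. All four rates are free by default;
`freeze_kini=True` holds the unproductive rates at the guess. Fitting the
`Tot` observables is the default — the plateaus are only explicable through
the unproductive pools feeding the `Tot` sums — with `fit_observables="raw"`
available to fit bare `SC`/`NICK`/`LIN` instead.

Aggregation is the arithmetic mean and sample s.d. (n−1) of `ka` and `kb`
across replicate fits (exact zeros when all replicates agree); nuclease
comparisons are ratios of means.

## Synthetic data: what it emulates, what it does not

`generate_timecourse` integrates the model, adds independent Gaussian noise
per fraction (default s.d. 2 percentage points, the scale of replicate
scatter in gel densitometry), clips at zero and renormalises each time point
to 100; a Dirichlet noise model is available behind a flag. Presets pair a
rate truth with a sampling grid of 12 log-spaced points:
fn-like (ka = kb = 0.5 s⁻¹; grid 1–30 s), lb-like (0.18 / 0.1; 1–300 s),
as-like (0.12 / 0.012; 1–2700 s), each with kini = kini2 = 0.01 and a
95% SC / 5% pre-nicked prep. The spans match the plateau windows of the
three orthologues' observed cis-cleavage; the log spacing resolves both the
fast NTS drop and the slow TS tail.

What this does not emulate: correlated densitometry errors within a gel,
band-overlap misquantification, time-zero quench artefacts, or any
Cas12a-binding kinetics upstream of the first-order scheme. Passing recovery
tests therefore shows the estimator is correct and well-conditioned under
the stated noise model — not that real gels carry 2% independent Gaussian
errors.

`generate_ensemble` builds two rigid random atom clouds (default 50 heavy
atoms cycling C/N/O/S plus 10 hydrogens each, radius 5 Å) with residue
numbers tiling the requested REC2/NUC ranges; per frame the separation
vector has a seeded Normal(mean, sd) length and random direction, and the
whole frame receives a random rigid rotation + translation. It produces
controlled distance distributions for validating the geometry code; it is
not molecular dynamics — domains neither deform nor interact, and contact
*patterns* (which residues touch) reshuffle every frame, so persistent-pair
analyses on it are only smoke tests.

## Geometry

Centre of mass is mass-weighted by default (standard atomic masses; the
common trajectory-analysis convention), with a geometric option since either
reading of "centre of mass" is defensible. Contacts use strict `< cutoff`
(default 3.5 Å) between heavy atoms; candidate pairs come from a k-d tree
queried at the cutoff radius (inclusive) and are re-filtered with the strict
inequality, so the tree path is exactly equivalent to O(N²) enumeration —
the tests assert equality on 100 random frames including exact-boundary
pairs. Element resolution: the PDB element column when present, else the
leading letter of the atom name after digit stripping; unresolvable names
raise rather than guess (so a calcium/Cα confusion is at least
deterministic and documented: bare atom-name inference maps "CA" to
carbon). Residue selection is by author residue number only; insertion
codes are rejected at parse time.

`contact_residue_pairs` reports pairs in contact in at least
`min_frame_fraction` of frames (default 0.1) — an explicit, reproducible
replacement for identifying contacting residues by eye; the threshold is a
free choice and is surfaced as a parameter.

KDE is an explicit 1-D Gaussian kernel sum with Scott's bandwidth
`h = sd·n^{−1/5}` (sample s.d.); implementing the sum directly (rather than
delegating) lets a zero-variance sample still be smoothed under an explicit
bandwidth override, while the zero-variance + no-override case raises with
that suggestion. The tests cross-check the estimate against
`scipy.stats.gaussian_kde` to 1e−10.

## Assay summaries

Tm is the temperature of the raw fluorescence maximum on the 25–99 °C /
1 °C grid — deliberately not a derivative-based call, to stay faithful to
the peak definition used with this assay. Ties resolve to the lowest
temperature with a warning; a maximum on a grid boundary sets `no_peak`
(the signature of a protein with no detectable transition). Tm is invariant
to positive affine rescaling of the signal. Trans-cleavage curves are
summarised by the OLS slope over the first 10% of the time span (window
configurable); no mechanistic (Michaelis–Menten) fit is attempted.

## Problem sizes and determinism

The shipped tests and the acceptance script use: a 5×5 (ka, kb) oracle grid
× 40 time points; one noise-free + three 2%-noise replicates of 12 points
for recovery; 3 presets × 3 replicates for the ordering/fold-change
comparison; 100 frames × 60 atoms/domain for the contact oracle; 2000
frames for distance/KDE calibration. These sizes make every check sharp
(recovery to 0.1% noise-free, ordering strict, contact equality exact)
while keeping a full run in tens of seconds. All randomness flows through
integer-seeded `numpy.random.default_rng`; identical seeds give
byte-identical generated CSVs and bit-identical fits.

## Known limitations

* The four-parameter fit from a single replicate can be weakly identified
  when `kini`/`kini2` trade off against early-time `ka` signal; the
  multi-start plus exact-zero lower bounds keep estimates stable in the
  tested regimes, but profile-likelihood confidence intervals are out of
  scope.
* `as_printed` mass loss means fitted fractions need not sum to 100 even
  noise-free; the per-point renormalisation makes the data side consistent,
  the model side is left as specified.
* The geometry code analyses whatever frames it is given; it does not
  attempt alignment, imaging, or periodic-boundary handling, and multi-chain
  PDBs are reduced to a single chain (first, or user-selected).
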