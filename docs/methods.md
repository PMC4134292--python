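# Methods

## The problem

Large multielectrode arrays record spiking from hundreds of neurons at
sub-millisecond resolution. Statistical dependencies between neuron pairs
(functional connectivity) live on very different time scales: a
monosynaptic coupling produces a sharp cross-correlogram peak a few
milliseconds wide and offset from zero, whereas shared oscillatory drive
(gamma, beta, theta) produces broad, zero-centered, often oscillatory
correlogram structure. `wavecon` separates these by frequency: it
wavelet-transforms each pairwise cross-correlogram, tests the resulting
time–frequency power plane against a Monte-Carlo Poisson null, and builds
one binary network per frequency band.

## Cross-correlogram

For a neuron pair (I, J) the cross-correlation histogram (CCH) is

    C_IJ(τ) = Σ_t i(t) · j(t + τ)

where `i(t)`, `j(t)` are binary bin states (1 when the neuron fired in the
bin of width δt centred at t, 0 otherwise). Two analysis scales are used:

| scale | δt | transformed window | peak window | frequencies |
|---|---|---|---|---|
| 1 | 50 µs | ±70 ms (2801 bins) | ±20 ms | 20–1000 Hz, 101 log-spaced |
| 2 | 500 µs | ±700 ms (2801 bins) | ±200 ms | 2–100 Hz, 101 log-spaced |

Counts are left unnormalized: the significance test is Monte-Carlo-based on
the same count statistic, so any normalization cancels. Positive lag means
J fires after I; this sign convention fixes the orientation of directed
edges everywhere.

Bins are half-open `[centre − δt/2, centre + δt/2)`; if two spikes of one
neuron share a bin, the bin state is still 1 (immaterial at 50 µs for
realistic rates, but it defines the statistic exactly).

**Near-electrode artifact.** When two sorted units sit within 180 µm (three
inter-electrode spacings) sorting cross-talk can fabricate an ultra-sharp
central peak or trough. For such pairs the segment |τ| ≤ 1 ms is replaced
by the straight line joining the flank averages over [−1.5, −1.0] ms and
[+1.0, +1.5] ms, anchored at the flank centres ∓1.25 ms (the unbiased
anchor choice; the operation is idempotent for flat flanks).

## Wavelet transform

The CCH is convolved with scaled, translated, normalized complex Morlet
wavelets, ψ₀(η) = π^(−1/4) e^(iω₀η) e^(−η²/2), with ω₀ = 4. The transform
follows the standard continuous-wavelet framework: daughter wavelets are
Gaussians in angular frequency restricted to ω > 0, with the
(2πs/δt)^(1/2) energy normalization, applied multiplicatively in the
frequency domain; power is |W|². A scale s corresponds to the Fourier
period T = 4πs/(ω₀ + √(2 + ω₀²)), so each analysis frequency f maps to the
scale with T = 1/f.

Before transforming, both ends of the 2801-bin series are padded with the
mean of the 100 edge bins up to the next power of two (4096), the pad split
as evenly as possible (647 left / 648 right). Only the original window is
returned, and peaks are only accepted well inside it, so pad effects never
reach the statistic.

**Worked example.** A zero-centred Gaussian correlogram peak with σ = 1 ms
produces a power maximum at lag 0 and ≈116 Hz on the scale-1 grid
(116.30 Hz on the 101-point log grid; the continuous optimum is at
u² = ω₀² + √(ω₀⁴+1), i.e. 115.9 Hz). Equivalently the best-matching
Fourier period is T ≈ 8.6σ. These two numbers anchor the
frequency-to-scale convention and are asserted in the tests.

## Significance: Monte-Carlo Poisson null

The null for a CCH with n total counts is white noise: n counts placed
uniformly at random over the window's 2801 bins (collisions allowed, so
each bin is Poisson). No closed form is available for the wavelet power of
Poisson white noise, so thresholds are calibrated by simulation: each
surrogate is transformed and the maximum power over the
peak-identification window is recorded per frequency; the threshold at
level p is the (p·n_reps)-th highest maximum at each frequency (the 100th
of 10⁵ at the defaults, p = 0.001).

Thresholds are tabulated at counts 10^k, k = 0.0, 0.1, …, 6.0 and
interpolated linearly in k = log₁₀(n) (the grid is uniform in k). Lookups
outside [1, 10⁶] raise rather than extrapolate. Each grid point uses an
independent seed stream, so the table does not depend on evaluation order;
a fixed seed reproduces the table bitwise. A running maximum across the
count grid guards the structural monotonicity of thresholds in n against
Monte-Carlo noise (at the default replication the grid spacing dwarfs that
noise).

The null maximum is taken over the peak window, not the full transformed
window, so the nominal p refers to exactly the region where peaks are
accepted. Validity is checked by a held-out experiment: thresholds built
from one ensemble are applied to a fresh ensemble and the per-frequency
exceedance must match p within 3 binomial standard errors. The default
test/verification replication is 10⁴ surrogates with order statistic 10
(same p = 0.001); the full-fidelity 10⁵/100 calibration is supported and
identical in structure. Monte-Carlo batches run in single precision (the
order statistics sit far above round-off); the per-correlogram transform is
double precision.

## Connections and networks

Peaks are points of the power plane strictly greater than their 8
neighbours, above threshold, inside the peak window. A correlogram may
yield several peaks; peaks in different bands are different connections.

Bands: HFC 100–1000 Hz (scale 1), GFC 30–80 Hz, BFC 12–30 Hz, TFC 4–12 Hz
(scale 2). Intervals are half-open [lo, hi) — avoiding double assignment at
the 12 and 30 Hz borders — except the HFC top, which closes the covered
range at 1000 Hz. Peaks in covered-but-unbanded gaps (80–100 Hz at scale 2,
20–100 Hz at scale 1) are dropped.

A connection is *directed* when |delay| strictly exceeds T/4 of the matched
wavelet — the offset at which the wavelet's primary lobe no longer overlaps
zero lag. For a Gaussian peak of width σ this boundary sits at
(8.6/4)σ ≈ 2.15σ. Orientation follows the delay sign.

Networks are built per band at a target connectivity density (fraction of
connected unordered pairs): connections are ranked by significance (peak
power / threshold power; ties broken on lexicographic pair id for
determinism), one edge per pair per band (most significant peak wins), and
pairs are kept until ⌊target·n(n−1)/2⌋. Bands that cannot supply the
target keep everything and report the lower achieved density — dropping
them would bias toward high-degree nodes. When several bands of one data
set are compared, all are re-truncated to the minimum achieved density.

**Temporal degradation.** `jitter` displaces every spike by independent
Gaussian noise (default σ = 50 ms, typical of population calcium imaging),
clipping to the recording interval. Clipping can tie spikes at the
boundaries; trains therefore tolerate ties, which collapse to one binary
bin state downstream. Millisecond-scale structure cannot survive 50 ms
jitter, so HFC/GFC detections vanish at unchanged thresholds — the
acceptance suite verifies ≥ 90 % loss on a synthetic population.

## Graph measures under subsampling

Comparing graphs with different node/edge counts biases every standard
measure, so statistics are computed on repeated random subsamples of fixed
size (100 nodes, 100 repeats at full fidelity) at matched densities
(0.5–2 %, step 0.5 %), reporting mean and RMS spread; repeats where a
measure is undefined are excluded and counted.

* **Disconnected nodes**: zero total degree.
* **Global clustering**: mean local clustering over nodes with ≥ 2
  neighbours (nodes below that have no defined local coefficient); NaN when
  no node qualifies.
* **Efficiency**: mean 1/d(i,j) over ordered pairs, 0 for unreachable
  pairs — finite on disconnected graphs, unlike mean path length.
* **Assortativity**: Pearson correlation of end-point degrees over edges,
  computed from the edge-list closed form; NaN for < 2 edges or zero
  end-degree variance (regular graphs).

Clustering, efficiency and assortativity use the undirected projection (a
pair is connected regardless of direction; density is pair-based). Degree
distributions use out-degree, where a non-directed edge contributes to both
end-points.

**Model degree laws** at size N and density p: binomial B(N−1, p)
(Erdős–Rényi); a discrete exponential P(k) ∝ e^(−αk) on k = 0…N−1 with α
fixed by matching the mean degree (N−1)p — the one parameterization fully
determined by N and p; and the empirical out-degree law of 100-node uniform
subsamples of 1000-node preferential-attachment graphs built at density p
(subsampling destroys the power-law tail, so the subsampled law is the
correct comparison). The preferential-attachment generator supports
fractional mean attachment via Bernoulli mixing of ⌊m⌋/⌈m⌉, since the
target density rarely maps to integer m. Observed laws are compared to the
models by reduced χ² over bins with defined SEM.

## Distance decay of connection probability

Pairs are binned by inter-neuron distance (50 µm bins), the connection
probability is computed per bin per network, averaged across networks, and
P(d) = A·e^(−d/λ) + C is fitted by ordinary least squares with 95 % normal
confidence intervals from the fit covariance. Two robustness choices: only
bins holding ≥ 50 pairs in every network enter the fit (sparse
extreme-distance bins otherwise contribute 0-or-1 probability outliers
that can drag λ anywhere), and each bin is evaluated at the mean distance
of its pairs rather than the bin centre (positions are lattice-like, so
within-bin distances are far from uniform). With few replicate networks
the cross-network SEM is too noisy to use as weights (chance near-zero
SEMs dominate a weighted fit); SEM is reported per bin but the fit is
unweighted. Parameter-recovery simulations at 6 networks × 300 nodes with
P(d) = 0.05·e^(−d/300 µm) + 0.002 recover λ within the interval at
approximately nominal coverage. A distance-independent wiring (A = 0)
leaves λ unidentifiable, surfacing as a vanishing amplitude and/or a very
wide interval.

## Synthetic populations

The generator emulates the statistical features the pipeline detects, with
known, exhaustive ground truth:

* **Rates**: lognormal, default 10^(−0.16 ± 0.64) Hz — the observed
  cortical-culture distribution; homogeneous Poisson trains.
* **Geometry**: hexagonal 60 µm lattice inside 0.9 × 1.9 mm with ≤ 30 µm
  uniform scatter (default ±10 µm per axis), so distance bins stay
  distinct.
* **Synaptic couplings**: each source spike elicits a target spike with
  probability `efficacy` at `delay + N(0, jitter)` (defaults 3 ms, 1 ms) —
  an offset HFC-band correlogram peak. The 1 ms width puts the peak's
  matched frequency (~116 Hz) inside the HFC band, and the 3 ms delay
  exceeds the ≈2.15 ms direction boundary.
* **Common drive**: member trains regenerated as inhomogeneous Poisson with
  shared sinusoidal rate modulation (thinning), a common random phase, and
  preserved rates — zero-centred correlograms oscillating at the drive
  frequency. Oscillatory correlograms are modelled phenomenologically;
  no field potential is simulated.

What the generator does **not** emulate: network bursts (population-wide
rate co-fluctuations; off by default — no downstream operation requires
burst statistics, and real bursty data will produce broader low-frequency
correlation than these surrogates), inhibition (correlogram troughs; the
network construction uses power peaks only, so troughs would surface as
peaks of oscillatory power, not as a separate class), refractoriness,
non-stationary rates, and spike-sorting errors other than the modelled
near-electrode artifact. Passing recovery tests therefore demonstrate the
pipeline's correctness on its own statistical model, not performance on
tissue recordings.

## Problem sizes used by the test and acceptance runs

Chosen so the whole suite runs on one CPU in minutes while keeping every
statistical check meaningful:

* calibration validity: 10⁴ + 10⁴ surrogates at spike count 10³, scale 1;
* pipeline recovery: 40 neurons at 2 Hz for one hour, 20 couplings at
  efficacy 0.5; thresholds from 2000 surrogates per grid point
  (p = 0.005, rank 10) on a 10^2.0–10^4.5 count grid covering the
  population's actual pair counts;
* decay fit: 6 networks × 300 nodes;
* scale-free model law: 30 parents × 20 subsamples (invariance to parent
  size 500 vs 1000 checked at that replication);
* oracle equivalence: all 1024 labeled 5-node graphs plus random 6-node
  graphs; 512-bin series for the O(N²) DFT oracle.

## Known limitations

* The significance test is per pair; no multiple-comparison correction is
  applied across pairs (by design — density control replaces it: networks
  are compared at matched edge counts, so a uniform false-positive floor
  affects all bands equally).
* Band borders and the count-grid interpolation variable are conventions
  (half-open intervals; linear in log₁₀ n); results change only marginally
  under the alternatives.
* The direction rule is a geometric criterion on one peak; it does not
  model conduction-delay distributions or distinguish common input with
  asymmetric delays from true directed influence.
* `read_spikes` assumes sorted, de-duplicated units; spike-sorting quality
  control is out of scope.
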