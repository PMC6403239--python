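# Methods

`lopnet` implements a graph-theoretical analysis of how levels of processing
(LOP) during incidental memory encoding reorganize a network of
encoding-relevant brain regions, together with a synthetic-cohort generator
that makes every stage of the analysis testable end to end. This note
describes the models, the parameters that matter, the numerical choices, and
what passing tests do and do not establish.

## The analysis chain

**Stimulus classification.** Each of the ~100 encoding events (an object
paired with a "can you eat it?" / "can you lift it?" question) is answered
yes/no by every participant. Events are ranked by their total number of
"yes" responses and split into four quartiles (cuts at rank positions
`floor(E/4)`, ties broken by rank, not by yes-count): the outer quartiles
(near-unanimous answers) are *low elaboration*, the middle two (high
disagreement) *high elaboration*. With 100 events this forces an exact
50/50 split. *Congruity* is idiosyncratic: for each participant, events they
answered "yes" to are high congruity.

**Memory scoring.** The delayed test asks three questions per item:
recognition (Q1), claimed memory for the encoding action (Q2), and the
action decision itself (Q3). Full source memory = correct chain through all
three. The corrected source score subtracts wrong Q3 decisions from source
hits (floored at 0), compensating in expectation for lucky guesses.
Recognition sensitivity is d' = Phi^-1(hit rate) - Phi^-1(false-alarm rate)
with rates clipped to [1/(2n), 1 - 1/(2n)] (the standard half-count
convention for extreme rates, a choice the analysis makes explicit
because reported d' values rarely state it). Participants
with fewer than 10 trials in any condition-by-memory cell used by a
contrast, or below 10% overall source memory, are excluded.

**Node definition.** A simplified surface-cluster algorithm on a generic
vertex mesh: connected suprathreshold components (extent strictly > 100
vertices), greedy local maxima at >= 25 mm Euclidean separation (the metric
on the real cortical surface is not specified; Euclidean in vertex
coordinates is used and documented), and descending-value flood-fill growth
from each peak up to 600 vertices, with earlier-grown nodes claiming
territory. Predefined nodes (e.g. subcortical regions delineated in volume
space) can be injected by id.

**Connectivity (correlational PPI).** Per node the observed signal (first
eigenvariate when several series contribute) is high-pass filtered
(polynomial up to order 2 plus discrete-cosine drifts below 0.01 Hz),
deconvolved against the canonical two-gamma HRF (6 s peak, 16 s undershoot,
unit dispersions, 6:1 ratio, 32 s support, peak-normalized) into a
neural-event estimate, multiplied by each condition's event boxcar at
microtime resolution (TR/16), reconvolved with the HRF and sampled at volume
times. Pairwise Pearson correlations between the resulting PPI terms,
clipped to +-(1 - 1e-7) and Fisher z-transformed, form one symmetric
node-by-node matrix per participant and condition, computed over the whole
scan (the correlational-PPI convention) with runs concatenated at the
term level.

**Graphs and centrality.** Each matrix is reduced to an undirected binary
graph by keeping exactly `floor(d * n(n-1)/2)` strongest edges (signed z,
ties broken lexicographically) at densities 20-30% in steps of 2. The 20%
floor is validated with the 85/85 rule: at least 85% of nodes must retain an
edge in at least 85% of participants. Four centralities are computed from
their definitions: closeness `CC(v) = 1 / sum_i d(v,i)` (unnormalized;
unreachable pairs enter at distance n so CC stays finite and isolated nodes
rank lowest), degree, betweenness (Brandes accumulation, fractional
shortest-path counting, unnormalized, per unordered pair), and eigenvector
(power iteration on A + I to tolerance 1e-10; on disconnected graphs the
component with the largest leading eigenvalue carries the vector, zeros
elsewhere).

**Inference.** Node-wise paired t-tests compare conditions at every density;
Benjamini-Hochberg FDR (q = 0.05) is applied within density; only nodes
significant with a consistent direction at *all six* densities survive the
conjunction. For the surviving (increased) set, per-participant mean
centrality change between subsequently remembered and forgotten events
(averaged over the set and all densities) is correlated with corrected
source memory. Specificity is assessed exhaustively: the same correlation is
recomputed for every possible same-size subset of the remaining nodes
(C(38,4) = 73815 subsets when 4 nodes are excluded and 4 chosen), and the
empirical p is the fraction of subsets with r at least as large (one-sided,
unsmoothed, matching the convention of counting "similar or higher" values;
a +1-smoothed p is reported alongside). The subset enumeration uses a
centered Gram-matrix identity, so each subset's r is exact and the full
73815-subset scan takes well under a second.

**Trial-count matching.** The two conditions of a contrast usually hold
different numbers of events (e.g. high-elaboration events are remembered
almost twice as often as low-elaboration ones). Unequal effective samples
bias the Fisher-z estimates of strong pairs by different amounts per
condition - a bias shared by every participant, which density thresholding
does not remove and which the paired tests would otherwise detect as
spurious, direction-consistent "effects" (we observed exactly this in null
simulations). The pipeline therefore subsamples the larger condition of
each contrast to equal trial counts per participant (seeded, reported in
the run log). This is standard practice in subsequent-memory designs and
can be disabled (`match_trial_counts=False`).

## The synthetic cohort generator

The generator emulates the study conditions: 113 participants, 100 events
(two runs of 50), TR 2.39 s, 131 volumes per run, 2 s events, ITIs drawn
from {1, 3, 5, 7} s with geometric weights fitted so the mean is 2.98 s
(the emulated design specifies the 1-7 s range, four discrete intervals and
the 2.98 s mean, but not the interval values themselves; its stated SD of
2.49 s cannot be matched simultaneously by any obvious support, so only the
mean is targeted).

**Behavior.** Population yes-rates follow a three-part mixture - near-0
(Beta(1.3,160)), near-1 (mirror), and an ambiguous band
(0.1 + 0.8 Beta(0.8,0.8)) with default weights (0.25, 0.25, 0.5) - matched
to the observed agreement spectrum (category means ~99% "no", ~98% "yes",
~50/50). Responses are independent Bernoulli draws; response times gain a
configurable shift (default 186 ms) on ambiguous events. Test-phase
outcomes follow a logistic model on elaboration level (+-1/2 coding,
effect 1.18 => ~64% vs ~36% source memory), congruity level (0.58 => ~57%
vs ~43%), and participant ability; items without true source memory can be
recognized and can guess the action at chance, which is what the corrected
score compensates for. One foil per encoded item (false-alarm rate 0.15)
supports d'. These are the simplest calibratable forms for a task that has
no canonical generative behavioral model.

**Baseline covariance.** Node signals share a unit-diagonal correlation
matrix built from a weak common term (0.2), a low-rank factor part
(6 factors, loading SD 0.15, row norms capped), and a deterministic
distance-decay component (0.55 for ring-adjacent nodes, halving per step).
The structured hierarchy matters: with an exchangeable (compound-symmetric)
baseline, density-thresholded graphs degenerate into near-random graphs
whose closeness values are dominated by fluctuating disconnection - which no
empirical connectome resembles - and the distance-decay part guarantees
every node a few reliably strong partners, keeping the 85/85 rule
comfortably satisfied. Eigenvalues are clipped at 1e-8 and the diagonal
renormalized if the sum ever leaves the PSD cone.

**Signal model.** Node activity is stationary multivariate noise with the
baseline covariance on a microtime grid, *plus one evoked amplitude vector
per event* - drawn with the same covariance and held constant over the
2 s event. This trial-wise evoked co-activation is the quantity
task-modulated connectivity actually measures: event-scale content survives
the HRF's low-pass and is recoverable by deconvolution, whereas
faster-than-TR fluctuations are not. Everything is convolved with the
canonical HRF, sampled at the TR, and corrupted with AR(1) observation
noise (rho 0.3, sigma 0.3).

**The planted effect.** Four hub nodes form the ground-truth "elaboration
network". During *successfully encoded deep (high-elaboration) events*, each
hub's evoked amplitude is mixed, variance-preservingly, toward the
network-wide common evoked signal of that event:
`a_hub <- sqrt(1-c^2) a_hub + c g`, with `c = coupling_gain` (per
participant, truncated normal, mean 0.65, SD 0.2). Synchronizing with the
common mode raises a hub's correlation with *every* other node in
proportion to that node's own common-mode loading - the operational meaning
of "becoming more central" - without inflating variances or starving
peripheral nodes of edges. Tying the coupling to successful deep trials
(rather than all deep trials) implements the subsequent-memory logic at the
trial level: deep processing that centralizes the hubs is what produces the
durable memory. The participant's ability in the behavioral model is
`memory_slope * (gain - mean gain) + noise` (slope 1.5, noise SD 0.3), so
participants who centralize more strongly also remember more, giving the
downstream centrality-change/memory correlation a true positive target.
An optional affiliate mechanism (nodes copying their hub's amplitude) is
available for experiments but off by default.

Earlier drafts planted the coupling as shared input in the fast noise
component; this is essentially invisible to the PPI chain (only ~25% of
within-window correlation survives deconvolution, while stationary baseline
correlations pass at full strength), and several variance-inflating
variants concentrated the fixed edge budget enough to disconnect weak nodes
and depress closeness globally. The evoked-amplitude common-mode model is
the configuration in which a moderate, physiologically sensible effect is
recoverable.

## Numerical choices

- **Deconvolution** minimizes `||Hn - y||^2 + lambda ||n||^2`. The kernel
  is sampled at t = TR, 2TR, ... : the two-gamma HRF is exactly zero at
  t = 0, and absorbing that leading zero keeps the Toeplitz operator
  lower-triangular with a nonzero diagonal, hence exactly invertible. The
  one-volume timing offset this introduces is compensated when interaction
  terms are built (`align_shift=1`); without the compensation, deconvolved
  event mass lands one volume late and event windows pick up negative
  ringing. The operator default is `lambda = 0.05 tr(H'H)/T`; the pipeline
  uses 0.01 (sharper deconvolution reduces cross-condition leakage of event
  content at the simulated SNR). The exact (lambda = 0) inverse is
  numerically stable only over short stretches - the inverse filter of a
  kernel whose first tap is not dominant amplifies rounding error
  geometrically - so exactness is asserted on ~20-sample series.
- **Band-limited upsampling** (polyphase resampling) interpolates the
  neural estimate to the microtime grid before the boxcar multiplication;
  zero-order hold would make adjacent events sharing one TR block carry
  identical values, an artifactual cross-condition leak.
- **Ties** are broken deterministically everywhere: event ranking by event
  id, density cuts by lexicographic node-pair order, peak selection and
  region growth by vertex index.
- **Seeds**: one master seed expands via `numpy.random.SeedSequence` into
  fixed-order substreams (event bank, responses, ground truth, outcomes,
  designs, time series, trial matching); every run is bit-reproducible.
- **Degenerate inputs**: zero-variance paired differences give t = 0/p = 1
  when the mean difference is zero (flagged), NaN/p = 1 otherwise; constant
  PPI terms get zeroed rows with a warning; edgeless graphs yield zero
  eigenvector centrality with a warning.

## What the tests show - and what they do not

Unit and property tests pin each operation to independent oracles
(matrix-power path counting, dense eigendecomposition, closed-form t and
d' values, naive permutation loops, networkx cross-checks). The acceptance
suite verifies, on synthetic cohorts at the study conditions: exact
recovery of the planted four-node network by the FDR conjunction in >= 90%
of replicate cohorts (n = 100; 12 planted and 12 null replicates are run,
a replicate count chosen to keep the suite fast; thresholds unchanged),
empty conjunctions under the null in >= 95%, BH false-discovery control
over 500 null simulations, uniformity of the exhaustive-permutation p under
null cohorts, and the forced 50/50 elaboration split.

The generator reproduces the *phenomenology* of the real study - agreement
spectrum, RT effects, source-memory and d' contrasts, a four-node network
with increased closeness under deep processing, a positive
centrality-change/memory correlation (r ~ 0.2-0.3) with a small exhaustive
permutation p - but it is a forward model with known ground truth, not real
fMRI: no motion or physiological noise, no spatial smoothing or
registration error, stationary baseline covariance shared across
participants, and a planted effect whose geometry (common-mode coupling)
is one of many that could underlie the real finding. Passing tests
establish that the analysis chain recovers what was planted under realistic
noise; they do not validate the neuroscientific claim itself.

Two deliberate divergences from the real study's report: in our synthetic
world the remembered-vs-forgotten contrast also detects the planted network
(the planted coupling is trial-linked to memory success by construction,
while the real study found no memory-contrast conjunction), and decreased-
direction conjunctions can appear at strong gains because relative density
thresholding makes centrality approximately zero-sum; both are properties
of the generator, documented rather than hidden.

## Known limitations

- Closeness on density-thresholded binary graphs is highly sensitive to
  disconnection; the d = n substitution keeps it finite but makes isolated
  nodes a dominant variance source at low densities.
- The exhaustive permutation is exact but limited to enumerable pools
  (a configurable cap, default 2 * 10^6 subsets, raises an instructive
  error rather than silently sampling).
- The vertex-mesh node extraction operates on synthetic meshes; real
  surface geometry, registration and smoothing are out of scope.
- Run-level artifacts (two runs are simulated and concatenated at the PPI
  term level) share one HRF and drift model; no between-run effects are
  modeled.
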