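# Methods

## Dynamics model and controllability statistics

The brain is modelled as a noise-free, discrete-time, linear
time-invariant system `x(t+1) = A x(t) + B_k u_k(t)` on the structural
connectivity matrix A (streamline counts, symmetric, zero diagonal, no
thresholding). `B_k` is the canonical selector of the control parcel; the
input `u` is never materialised because only infinite-horizon summary
statistics are computed.

**Normalisation.** Two conventions are implemented. `mean_edge_weight`
divides A by the mean of its nonzero upper-triangle weights — "edge
weight" is read as *existing* edges; averaging zeros into the denominator
would make the result density-dependent and even less stable. On dense
weighted connectomes this convention leaves the spectral radius far above
one (ρ ≈ mean degree), so the Gramian series diverges; `stabilize` then
warns and any infinite-horizon request raises `UnstableSystemError`
rather than returning garbage. The `spectral` convention divides by
(1 + |λ_max|), guaranteeing ρ < 1, and is the default used by
`node_metrics` and the pipeline. Because within-subject *ranks* drive all
cohort statistics, the choice of stabilisation convention is largely
immaterial downstream: weighted-degree and modal-controllability ranks are
identical under both (modal controllability is a monotone function of the
squared row norms), and average-controllability ranks agree closely.

**Average controllability** is reported as trace(W_k) of the
infinite-horizon single-node Gramian. For symmetric stable A this has the
closed form `trace(W_k) = [(I − A²)^{-1}]_{kk}`, which is what the fast
path computes; a `trace_inverse` variant (trace of the Gramian
pseudo-inverse) is available but numerically delicate, since single-node
Gramians of large networks are severely ill-conditioned. Every entry is
≥ 1 (the τ=0 term).

**Modal controllability** is `φ_i = Σ_j (1 − λ_j²) v_ij²`. Identities used
in tests: φ ≡ 1 for A = 0; for symmetric A, φ_i = 1 − (A²)_ii, so
1 − λ_max² ≤ φ_i ≤ 1 − λ_min².

Ranks are ascending (rank 1 = smallest value), ties averaged.

## Graph metrics

Conventions follow common connectivity-toolbox practice: shortest-path
lengths are reciprocal weights; global efficiency is the mean inverse
shortest-path distance over ordered pairs; modularity is weighted Newman Q
with a resolution parameter (default 1.0), maximised by Louvain over
seeded restarts (igraph backend; best-Q restart reported; default 100
restarts in the metric API, fewer in the high-throughput simulation loop
where only within-subject contrasts matter). Mean first passage times come
from the fundamental matrix `Z = (I − P + 1πᵀ)^{-1}` of the random walk
P = A/rowsum(A), via `h_ij = (Z_jj − Z_ij)/π_j`; diffusion efficiency is
the mean of 1/h_ij over ordered pairs (harmonic form — the per-pair
inverse, not the inverse of the mean, matching toolbox usage; the verbal
definition alone is ambiguous).

## Cohort statistics

Per-parcel metric ranks are normalised to the control cohort:
`z = (rank − mean_ctrl)/sd_ctrl` per parcel and metric (sd with ddof=1).
By construction the control cohort has per-parcel mean z = 0 and sd = 1;
a zero control sd (an exact rank tie across all controls) is an error
naming the parcel, because the z-score is undefined there.

Group comparisons use GLMs (`response ~ group + age + sex + fsiq_class
[+ mean weighted degree]`), Gaussian/identity by default and gamma/log for
positively skewed responses such as mean modal controllability. Estimated
marginal means are computed on a reference grid that holds covariates at
the observed cohort composition (each group's design row is the average
over all subjects' covariate rows with the group indicator switched);
pairwise contrasts are unadjusted Wald tests (Fisher's LSD), and Cohen's d
is the EMM difference over the response-scale residual SD (an EMM-based d
needs some pooled scale; the model residual SD is the natural one).
FSIQ class enters as an unordered factor.

Node-level flags mark parcels whose patient-group mean z crosses ±3.1,
treated as a given constant standing in for a 253-comparison correction.
The mean-matrix difference summary counts entries with 0 < Δ < 100
(streamlines) per anatomical edge class; *localisation* is judged by the
per-class rate (count over class pair count), since raw counts are
dominated by the sheer abundance of contralateral pairs.

## Perturbation simulations

For each control connectome the experiment draws, without replacement,
1440 existing edges (4.5% of all pairs; on non-253-parcel graphs the
operative count is min(1440, ⌊0.045 · #edges⌋)) and adds a positive
N(50, 15) increment to each, symmetrically (non-positive draws are
redrawn; the truncation is negligible, p ≈ 4×10⁻⁴). Constrained models
draw from ipsilateral thalamocortical edges; null models from all
ipsilateral edges. Each of the nine fingerprint metrics is z-scored
against the control's own null-model mean and sd, and group tests are
two-sample t-tests (constrained-model z's and null-model z's against the
baseline z's) with Benjamini–Hochberg FDR within each contrast family.
Random edge *addition* (density experiments) samples absent pairs
uniformly and draws weights from the same Weibull(0.717, 0.325) family as
the generator, on the same streamline scale with the same tail cap, so
simulation and synthetic data are mutually consistent.

## Resection analysis

The resected parcel set (the operationalised epileptogenic zone; any
partially resected parcel counts as resected) is summarised per subject by
its mean z per metric, compared against (i) the whole-brain mean (paired
t-tests within outcome strata), (ii) 1000 virtual resections — uniform
random cortical sets of the same size, not forced disjoint from the real
set and not contiguity- or hemisphere-constrained (hemisphere matching is
available as an option) — via `(real − mean_virtual)/sd_virtual`, and
(iii) a post-operative surrogate. The surrogate deletes the resected
rows/columns and re-references the reduced graph's metric ranks against
the controls reduced by the same set; it is flagged `surrogate=True`
because the original expected post-operative connectome re-ran
tractography, and streamline redistribution has no graph-level analogue.
Consequently the surrogate retains the group-level (thalamocortical)
z shift but not the re-tractography increase; it also removes the rank
inflation that a deflated zone induces in the non-resected parcels — the
tests assert exactly this contract. BH-FDR is applied across the
metric × contrast family per stratum; a Kruskal–Wallis test across
histology groups is available when histology labels are supplied.

## Synthetic cohort generator

The generator emulates the *structure* of the study data, not its exact
metric distributions. Design, and what it does and does not imitate:

* **Layout.** 253 parcels: 219 cortical (110 left / 109 right), 7 thalamic
  nuclei and 8 other subcortical structures per hemisphere, 4 midline
  brainstem parcels; tags for thalamic nuclei and posterior/isthmus
  cingulate. Smaller layouts scale these counts proportionally.
* **Topology.** A stochastic block model on connection probabilities only:
  hemispheres (within 1.15 / between 0.7), five contiguous "lobes" per
  hemisphere (×1.6), an elevated ipsilateral thalamocortical block (×3)
  and deep-grey block (×3), calibrated by bisection so the expected
  density hits the target (controls 0.63; patients are then densified to
  0.71 with uniformly random new edges). Degrees are therefore roughly
  block-uniform — deliberately, because the ipsilateral null model samples
  existing edges uniformly, and degree-carried hubness would make that
  null systematically strengthen the AC–MC correlation.
* **Weights.** Cortico-cortical weights are Weibull(scale 0.717, shape
  0.325) draws, capped at 80 raw units and scaled by 15 streamlines per
  unit, times per-node log-normal hub factors (σ = 0.4): hubness lives in
  the weighted, not the binary, degree. The cap keeps single freak edges
  from pinning the spectral radius, so the coherent thalamocortical
  eigenmode sits near the top of the spectrum and the boost can move it —
  this is what makes mean average and modal controllability *rise* under
  the constrained boost, as in the study's simulation. Ipsilateral
  thalamocortical edges instead carry moderate low-variance log-normal
  weights (mean 90, σ = 0.3, times a per-nucleus anatomical size factor,
  σ = 0.3), mirroring the many thin thalamocortical projections;
  ipsilateral deep-grey edges are uniform-ish (mean 250), binding the deep
  structures into their own community so that thalamocortical boosts are
  between-module weight and *decrease* modularity; within-lobe cortical
  weights are tripled so Louvain finds crisp lobe communities.
* **Cross-subject consistency.** The hub profile, per-pair base weights
  and nucleus sizes are *anatomical* — shared across subjects (drawn from
  a fixed anatomy seed) — with per-subject log-normal jitter on nodes
  (σ = 0.2) and edges (σ = 0.35) and per-subject edge presence. Real
  white-matter anatomy is highly consistent across people; without this
  consistency, per-parcel control rank SDs are so large that no parcel
  could ever cross the ±3.1 z threshold.
* **Patient effect.** Patients receive the 1440-edge thalamocortical
  boost (N(50, 15)) scaled by a mean-one log-normal subject severity
  (σ = 0.5) — severity varies widely across patients clinically, and the
  heterogeneity is also what keeps the (zero-sum-rank) cortical offset
  from producing spurious paired-test significance in the
  not-seizure-free stratum — plus random edge addition to density 0.71.
* **Resection effect.** Seizure-free resective subjects carry a planted
  zone of 3–24 within-hemisphere cortical parcels (size ≈ N(12, 4.5)
  clipped, median 12) whose incident edge weights are deflated ×0.45
  (within-zone edges doubly so); not-seizure-free subjects get a random
  resected set with *no* planted effect, modelling a resection that
  missed the epileptogenic zone.
* **Demographics.** Ages: controls ~ U(12, 19), patients ~ U(3, 18)
  (reproducing the imbalance direction); sex 1:1; four FSIQ classes with
  patients shifted low; outcomes 33/52 seizure-free and 11/27 VNS
  responders.

What passing tests on this generator do **not** show: geometry
(distance-dependent connectivity), realistic lobe anatomy, streamline
redistribution after resection, developmental age effects on
controllability, or the real data's exact metric scales. The generator
demonstrates that the *pipeline* detects planted effects of the stated
anatomy and recovers the stated directional results, not that the
biological findings are inevitable.

## Numerical choices and problem sizes

* Symmetry tolerance 1e-9 absolute on load; round-trip accuracy 1e-12.
* Lyapunov solves via `scipy.linalg.solve_discrete_lyapunov`; residual
  tolerance 1e-8 asserted in tests.
* Louvain: igraph multilevel, per-restart seeds from a master seed, ties
  broken by the first-found best Q.
* All stochastic stages derive named substreams from one master seed
  (`numpy.random.SeedSequence`); fixed seeds give byte-identical outputs.
* Test-suite problem sizes: the oracle checks use ≤ 10-node systems
  (partial-sum horizon 10⁴, 50 systems), ≤ 8-node graphs for exhaustive
  partition/path enumeration, and 10⁵-walk Monte-Carlo MFPT estimates;
  the fingerprint reproduction uses 20 synthetic controls with 10
  constrained + 50 null models each; the resection reproduction uses a
  10/14/8 cohort with 1000 virtual resections; the null calibration uses
  100 cohorts of 60 parcels with a compressed hub spectrum (small graphs
  tie ranks easily). These sizes were chosen to keep the full suite fast
  while leaving every statistical conclusion comfortably powered.

## Known limitations

* The mean-edge-weight normalisation is faithful to its verbal definition
  but cannot produce finite infinite-horizon Gramians on realistic dense
  connectomes; the spectral convention is the operative default.
* The ipsilateral null boosts in the synthetic generator slightly
  *strengthen* the AC–MC correlation instead of leaving it exactly
  unchanged; the dissociation is therefore stated directionally (a
  significant weakening occurs only in the constrained models).
* The post-operative surrogate is a node deletion, not a re-tractography;
  see above for what it can and cannot reproduce.
* `trace_inverse` average controllability is exposed for completeness but
  inherits the Gramian's conditioning; treat its absolute values with
  caution.
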