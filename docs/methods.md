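# Methods

`neoconn` analyzes resting-state functional connectivity (RSFC) in neonatal
hemodynamic recordings: 20-channel fNIRS (oxy- and deoxy-hemoglobin, HbO/Hbr)
and lobe-averaged BOLD fMRI. This note documents the models, the estimators,
the synthetic-cohort generator that stands in for clinical recordings, the
numerical conventions, and what the validation experiments do and do not
demonstrate.

## Signal model and preprocessing

**Montage.** The whole-head infant montage has 20 channels — per hemisphere
4 temporal, 2 parietal, 2 frontal, 2 occipital — mapping onto 8
(hemisphere, lobe) nodes. All 8×8 maps use one canonical node order (left
then right hemisphere; frontal, parietal, temporal, occipital within each),
shared between fNIRS and fMRI so cross-modal comparisons are entry-aligned.

**MBLL conversion.** Optical-density changes at 760 and 850 nm convert to
(ΔHbO, ΔHbr) by solving, per channel and sample, the modified Beer–Lambert
2×2 system ΔOD(λ) = [ε_HbO(λ)ΔHbO + ε_Hbr(λ)ΔHbr]·d·DPF(λ). Defaults are
conventions, not measurements: Prahl-type molar extinction coefficients
(ε in cm⁻¹M⁻¹: 586/1548.52 at 760 nm, 1058/691.32 at 850 nm for HbO/Hbr),
neonatal DPF (5.0, 4.4) and source–detector distance 2.5 cm; all
configurable. The inversion is the exact inverse of the stated forward
model (validated to 1e−10 relative error).

**Filtering.** Zero-phase (forward–backward) 4th-order Butterworth
band-pass: 0.01–0.1 Hz for fNIRS, 0.01–0.2 Hz for BOLD. The BOLD upper
edge exceeds the Nyquist frequency at TR = 3 s (0.167 Hz); it is clamped
to 0.95×Nyquist with a logged warning rather than treated as an error, the
closest physically realizable version of that setting. Because filtering
and lobe averaging are both linear, their order is immaterial; the
pipeline filters first.

## Connectivity maps and sparsification

Maps are Pearson correlations between channel (20×20) or lobe-node (8×8)
time series; raw r values are used as weights throughout (no Fisher
transform). Proportional sparsification removes negative and zero weights,
then keeps the top `floor(s·N(N−1)/2)` positive edges at sparsity level
`s`; `floor` guarantees the retained fraction never exceeds the stated
level, and threshold ties break lexicographically on the node pair so
results are platform-reproducible. Weighted maps keep the original r;
binarized maps set retained edges to 1. When fewer positive edges exist
than the budget allows, all positive edges are kept with a logged warning.
Total connectivity strength is the unfiltered signed sum of the weights
over unordered pairs.

## Cross-modal comparison

Euclidean and Jaccard distances act on the full sparsified adjacency
matrices, summed over all ordered off-diagonal entries (each unordered
connection counted twice, consistently for both metrics, so relative
comparisons are unaffected; absent edges contribute 0). The Jaccard ratio
uses Σmin/Σmax with the convention that two empty maps are identical
(distance 0). Distances are computed subject-by-subject over a sparsity
grid (default 0.20–0.46 in steps of 0.02) and aggregated to mean, SD and a
t-based 95% CI. Cohort-level similarity maps have the same dimensions as
the connectivity maps: the weighted mode stores the mean per-connection
absolute difference (a per-entry Euclidean distance), the binarized mode
the fraction of subjects retaining the connection in both modalities.

A caution discovered while validating: on *weighted* maps the Euclidean
distance is not monotone in signal quality — near-null maps carry tiny
weights and therefore tiny weighted distances — so the monotonicity
experiment (below) uses binarized maps, where shrinking distance genuinely
means better cross-modal agreement.

## Graph measures

All measures are applied literally to the sparsified adjacency supplied
(weighted or binarized; the pipeline default is binarized).

- **Clustering coefficient** C_p = (1/N)Σ_i [Σ_{j,k} a_ij a_ik a_jk /
  ((s_i−1)s_i)], s_i the node strength. The denominator degenerates for
  s_i ≤ 1 (binarized: degree < 2); such nodes contribute 0.
- **Local network efficiency** NE averages, over nodes, the mean inverse
  shortest-path distance among G_i = {i} ∪ neighbors(i), with distances
  measured *within the subgraph induced by G_i* (the standard local
  reading); hop counts for binarized maps, edge lengths 1/w for weighted.
  Nodes with |G_i| < 2 contribute 0.
- **Modularity** M = Σ_p [e_pp − (Σ_q e_pq)²], e_pq the fraction of edge
  weight between communities p and q with within-community weight fully on
  the diagonal; this equals Newman's Q. Partitions come from the seeded
  greedy Louvain optimizer (networkx); the node-visit order is controlled
  by the seed, and a result below the trivial single-community partition's
  M = 0 falls back to that partition.
- **Partition agreement** is the confusion-matrix normalized mutual
  information, MI = −2Σ c_wv ln(c_wv N/(c_w· c_·v)) / [Σ c_w· ln(c_w·/N) +
  Σ c_·v ln(c_·v/N)], with 0·ln 0 = 0; two trivial single-community
  partitions score 1. This equals arithmetic-mean-normalized NMI.
- **Nodal features** for classification: strength (sum of retained
  weights), degree centrality (degree/(N−1)), closeness centrality
  ((N−1)/Σd, 0 when some node is unreachable; a harmonic variant is
  selectable for disconnected graphs), and the per-node clustering and
  efficiency terms.

Shortest paths use a dense Floyd–Warshall — on ≤ 20-node graphs this is
faster than sparse-graph machinery by an order of magnitude and exact.

## Group statistics

Metric tables (subject × signal type × sparsity) are compared between
groups cell-wise with two-sided t-tests, Welch by default (pooled
available); no multiple-testing correction is applied by default, matching
the per-cell reporting convention, with Benjamini–Hochberg behind a flag.
Within-group consistency is the mean pairwise MI between subjects'
partitions; pairs sharing a subject are not independent, so beside the
simple pairs-as-observations test a subject-level jackknife mode is
provided (each subject summarized by its mean MI to the rest of its
group). Connectivity strength is regressed on grey- or white-matter volume
by OLS adjusted for gestational age at birth, postmenstrual age at scan
and sex (coded M=1/F=0); rank-deficient designs raise.

## Classification

Only feature columns significant in the group t-test (p < α, default 0.05)
enter the SVM — a deliberate reproduction of pre-selection outside the CV
loop; a leakage-safe per-fold selection is the better practice for new
studies and the selection function can simply be applied inside a custom
loop for that. The classifier is a linear SVM (C = 1, both configurable —
the smallest assumption set at n ≈ 40 subjects) under stratified fourfold
cross-validation with standardization fit on training folds only.
Out-of-fold decision scores pool into a single ROC; the trapezoidal AUC
equals the Mann–Whitney concordance probability exactly, ties credited ½.
Both the best single-fold accuracy ("maximal accuracy") and the fold mean
are reported.

## The synthetic cohort

No recordings are distributed with the package, so a generative model
provides ground-truth data with the statistical structure the analysis
assumes.

**Latents.** Each of the 8 lobe nodes carries a zero-mean, unit-variance
signal synthesized directly in the frequency domain with support exactly
inside the 0.01–0.1 Hz band (spectra are drawn at the next fast FFT length
and truncated; >99% of power stays in-band). Lobes load on a global
factor, a community factor and an idiosyncratic term, giving correlation
`rho_within` (default 0.3) inside a community and `rho_between` (default
0.1) across communities. The default communities split the lobes by
hemisphere. A per-subject jitter (SD 0.1) on the within-community
correlation makes subjects differ beyond correlation-estimator noise.

**Channels.** Each fNIRS channel is √f·latent + √(1−f)·noise with
`shared_fraction` f (default 0.6) and independent band-limited noise, so f
is the latent-driven variance fraction. Hbr = −0.5·HbO + noise models the
physiological anticorrelation. BOLD resamples the same latents at TR = 3 s
(35 volumes) with additive white noise — the two modalities share ground
truth, which is what makes cross-modal agreement measurable.

**Planted group effect.** Cases get (a) within-community coupling raised
by the effect magnitude (default +0.3, i.e. 0.6 vs 0.3) and (b) a
per-subject random re-draw of the 4+4 lobe-community assignment. Both
parts are needed to reproduce the study's qualitative pattern: stronger
coupling raises case C_p, NE and M, while the subject-specific community
layouts lower the cases' within-group partition consistency — stronger
coupling alone would make cases *more* consistent, the opposite of the
observed pattern. The nonzero baseline `rho_between` matters: with fully
segregated controls, the within-lobe channel cliques shared by both groups
dominate the retained edges at low sparsity and the planted contrast only
becomes visible from sparsity ≈ 0.3 upward; with the (more realistic)
weak global coupling, the case/control segregation difference expresses
across the whole 0.20–0.45 grid.

**Covariates and volumes.** GA ~ U(36, 42) wk, PMA = GA + U(0, 2) wk, sex
Bernoulli(½) — term-neonate inclusion ranges with invented distributional
forms. Grey/white-matter volumes (means 220/180 cm³, SDs 25/20 cm³ in mm³
units) are linked to each subject's overall lobe-wise HbO strength with a
configurable slope (default 10 000 mm³ per cohort z-score, ~r = 0.37;
0 disables the link), so the volume regression has recoverable ground
truth. One RNG stream per subject is spawned from the master seed; cohorts
are bit-reproducible.

**What the generator does not emulate:** optode geometry and photon
transport, cardiac/respiratory physiological noise, motion artifacts,
scanner drift, or spatially heterogeneous coupling. Passing validation
therefore shows the *estimators and inference machinery* behave correctly
on data satisfying the model's assumptions — not that the pipeline is
robust to the artifact structure of real neonatal recordings.

## Validation experiments and problem sizes

The `experiments` module (exercised by the acceptance tests and
`scripts/acceptance.py`) runs:

- **Null calibration** — 500 cohorts (20/group) with no planted effect;
  the pooled rejection rate of the group t-tests on C_p/NE/M at sparsity
  0.3 should sit near α = 0.05; plus 50 label permutations of one null
  cohort through the full CV-SVM, whose mean AUC should be ≈ 0.5.
- **Effect recovery** — 100 cohorts with the default planted effect; a
  replicate succeeds when all three metrics show case > control with
  p < 0.05 at ≥ 4 of the 6 grid points *and* case consistency is lower.
- **Cross-modal monotonicity** — mean binarized Jaccard and Euclidean
  profiles over 20 seeds at shared_fraction 0.2/0.5/0.9 must fall strictly
  as coupling rises.
- **Regression recovery** — 200 datasets at β = 0.5, n = 40: mean slope
  bias < 5%; matched null datasets: type-I error ≈ 5%.
- **Exact oracles** — the graph measures agree to 1e−12 with brute-force
  implementations on every non-isomorphic graph of ≤ 6 nodes; the AUC
  equals the concordance oracle; the MBLL round trip is exact to 1e−10.

These sizes keep the whole validation run in minutes on one CPU while
leaving binomial noise well inside the asserted bands.

## Known limitations

- The clustering-coefficient formula applied to weighted maps is not
  bounded by [0, 1] and its denominator is unstable for strengths just
  above 1; the pipeline default is binarized maps, where C_p, NE ∈ [0, 1].
- Pre-CV feature selection (the reproduced design) optimistically biases
  accuracy estimates; see Classification above.
- The pairs-as-observations consistency t-test ignores the dependence
  between pairs sharing a subject; the jackknife mode is the conservative
  alternative.
- With ~65 effective samples in a 6-minute 0.01–0.1 Hz recording,
  single-subject correlation estimates carry SD ≈ 0.12; analyses should
  not over-interpret individual edges at these durations.
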