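# Methods

## The decomposition

The package models a multiplex secretome table `X` (cytokines × samples,
pg/mL) on the natural-log scale as

    ln X_i(k) = ln X_i0(k) − Σ_{α≥1} G_iα λ_α(k)

and realises the decomposition by a singular value decomposition of the
completed ln matrix. Component 0 — the largest singular value — is the
steady-state term `ln X_i0(k) = G_i0 λ_0(k)`, stored per cytokine *and*
per sample (the steady state of a concentration matrix with heterogeneous
samples is itself sample-dependent). Components α ≥ 1 are candidate
unbalanced processes with weights `G_iα` (left singular vector entries)
and amplitudes `λ_α(k)` (singular value × right singular vector entries);
the model's minus sign is absorbed into the component sign. Because SVD
signs are arbitrary, each component is flipped so the cytokine with the
largest |G| has positive G, making outputs reproducible run to run;
comparisons against planted truth are sign-agnostic.

The full component sum reconstructs the input to numerical precision;
truncation at the significant processes leaves a residual at the noise
floor. G columns are orthonormal and λ rows mutually orthogonal by
construction.

Log transform: entries become `ln(max(value, detection_floor))`. The
detection floor is a pseudocount applied only inside the log; raw
concentrations are never modified, and missing entries stay missing.

## Number of significant processes

How many components are real processes rather than assay noise is decided
by a Monte-Carlo null. The statistic of component α is its peak
amplitude `max_k |λ_α(k)|`. The null distribution is the same statistic
— maximised over *all* components and samples — of `n_boot` (default
100) i.i.d. Gaussian matrices of the data's shape at the ln-scale noise
SD. A process is significant when its statistic exceeds the null's 95th
percentile. Using all components of the noise matrix makes the test
conservative: under the no-process hypothesis every non-steady-state
component of the data is itself noise, and the largest of them is what a
false positive would look like. This Monte-Carlo construction is a fully
specified stand-in for replicate-based error limits on λ and is flagged
as such in the JSON output (`null_method`).

Two numerical details:

- The null threshold is floored at `1e-8 ×` the largest observed
  statistic, so that an exactly low-rank input (noise SD 0) reports
  exactly its true rank instead of counting float-epsilon trailing
  components.
- The noise SD can be supplied, or estimated two ways. Preferred, when
  replicate fragments exist: the pooled SD of ln values across fragments
  of one animal × arm (replicates of one tumor under one treatment differ
  only by assay/sampling noise). Fallback, from the matrix alone: the
  median singular value (steady state excluded), calibrated against the
  same statistic of simulated unit-variance Gaussian matrices of the same
  shape — valid while fewer than half the components carry signal.

## Membership and activity

Membership of process α uses a fold cutoff against the uninvolved
background: the baseline is the mean |G| of the `floor(quantile · n)`
cytokines with smallest |G| (at least one; ties broken by cytokine-id
order, |·| because "low" weights are the uninvolved ones), and members
are cytokines with `|G| ≥ fold × baseline`. Defaults: fold 20, quantile
0.20. Members keep their signed weights; membership is monotone
non-increasing in the fold.

Activity of process α in sample k compares `λ_α(k)` against a positive
threshold: `active_positive` above it, `active_negative` below its
negative, `inactive` between. The `"auto"` threshold reuses the 95th-
percentile null amplitude from the significance test as a single global
threshold — amplitudes that pure noise could produce are not interpreted
as activity. (A per-sample rescaling of the threshold would require a
per-sample error model the data do not provide; the global null is the
design choice made here.)

## Missing values

Iterative truncated-SVD imputation: missing entries start at row means,
then are repeatedly replaced by a rank-r SVD reconstruction until the
largest relative change of any imputed entry drops below `tol`. Observed
entries are never altered; an all-missing row or column is an error;
hitting `max_iter` flags non-convergence with a warning rather than
raising. Defaults: rank `min(5, min(dims) − 1)`, `tol = 1e-9`,
`max_iter = 1000`. The tolerance is deliberately much tighter than the
target accuracy because the iteration converges linearly: the per-step
change understates the remaining error by the (unknown) contraction
factor, and 1e-9 on the step reliably delivers better than 1e-6 on the
completed values for low-rank matrices.

## Association statistics

Pearson matrices are pairwise-complete (cells with fewer than three
complete pairs, or a zero-variance feature, are reported missing, never
zero). Heatmap ordering uses agglomerative clustering of rows and columns
with Chebyshev ("maximum") distance and average linkage — the vocabulary
of the ClustVis-style tools this mirrors — with Euclidean and correlation
distance available; missing correlation cells are filled with 0 for
distance purposes only and the fill is flagged.

Infiltrates are measured once per tumor while secretion is measured per
explant fragment, so association runs at the tumor level: fragments map
to their tumor through the metadata's animal id, fragment values (or
amplitudes) are averaged per tumor (mean by default, median available),
and correlations are computed across tumors. Fragment-level pairing is
possible by passing an identity mapping.

PCA centers rows (features) by default, optionally scales them to unit
variance (the convention for treatment-response views), imputes missing
entries first, and reports per-sample scores with explained-variance
fractions.

Treatment comparisons are two-tailed unpaired equal-variance Student
t-tests on raw concentrations, baseline vs arm, restricted to one animal
(replicate fragments of one tumor) or one tumor model, with df = n1 + n2
− 2. Stars follow the raw-p tiers (* < 0.05, ** < 0.01, *** < 0.001, NS
otherwise) to match standard practice; because many cytokines are tested
a Benjamini–Hochberg adjusted column (`p_bh`) is additionally emitted and
clearly labelled. No correction is applied to the starred raw p values
themselves.

## The synthetic-data generator

The generator is first-class, tested code: it draws datasets from exactly
the generative reading of the model so every downstream stage is testable
by parameter recovery.

    values = exp(baseline + planted_G · planted_lambda [+ shifts] + noise)

- **Noise** is additive Gaussian on the ln scale (multiplicative
  log-normal on concentrations), matching how multiplex bead assays
  behave; default SD 0.1.
- **Baselines** are per-cytokine `N(ln 100, 1)` — concentrations around
  100 pg/mL spanning roughly an order of magnitude.
- **Planted weights** are orthonormal columns drawn by QR, orthogonal to
  both the baseline direction and the uniform cytokine direction. The
  first keeps the steady-state SVD component exactly separate from the
  processes (exact noiseless recovery); the second makes the
  decomposition scale-covariant (multiplying all concentrations by c adds
  a uniform ln c term that then folds entirely into the steady state).
- **Planted amplitudes** are drawn per replicate group (all fragments of
  one tumor × arm share the tumor state, so within-group spread is pure
  assay noise), centered, mutually orthogonalised, and broadcast to
  samples. `amplitude_sd` is the RMS ln-scale deviation the leading
  process induces across matrix entries — i.e. the per-entry
  signal-to-noise of that process — with default 1.0 (ten-fold the
  default noise). Successive processes shrink geometrically (factor
  0.85): real processes have decreasing importance, and distinct scales
  keep the singular values non-degenerate so planted process α is
  identifiable with component α (equal scales would let the SVD rotate
  freely inside the planted subspace).
- **Missingness** masks an exact rounded fraction of entries uniformly at
  random.
- **Infiltrates**: linked populations are `loc + scale·(r·z +
  √(1−r²)·ε)` with `z` the standardised (tumor-averaged) planted
  amplitude, calibrated so the expected sample Pearson correlation is the
  target r; `loc = 1000, scale = 150` keeps counts positive without
  clipping distortion. Unlinked populations are independent log-normal
  draws. The default study links process 3 to CD4/CD8/CD90.2 and process
  1 to TAM.
- **Treatment shifts** add fixed ln-scale offsets to chosen cytokines in
  chosen arms (default: IFNg/IP10 up under PD-1 blockade, IL17A/IL4 up
  under OX40 agonism — Th1- vs Th17/Th2-style responses).
- The default layout is 4 tumor models × 3 animals × 4 arms (48 explants,
  one fragment each; `replicates` multiplies fragments per arm), 30
  analytes with realistic murine panel names.

Everything is reproducible from one integer seed (separate deterministic
streams for noise, masking and infiltrates).

**What passing recovery tests does and does not show.** The generator
matches the model's own assumptions: log-normal noise, exactly orthogonal
planted structure, group-constant amplitudes, missingness completely at
random. Real multiplex data violate all of these to some degree —
detection-limit censoring (values clipped at an assay floor rather than
missing at random), correlated plate/batch noise, non-orthogonal
overlapping programs, and drifting baselines. Recovery under the
generator therefore validates the implementation and the statistical
design, not robustness to those real-world artefacts.

## Pipeline and determinism

`run_pipeline` executes read/simulate → log transform → imputation →
decomposition → significance → membership/activity → associations →
networks, writing every intermediate artifact plus `manifest.json` with
input checksums, the seed, package versions and all parameters — and no
timestamps, so two runs from one configuration are byte-identical in
every artifact (the log file records elapsed times and is the one
exception, written only to the logger). Floats are serialised with 12
significant digits, which also bounds the table round-trip error.

## Problem sizes

Tests and the acceptance script use the default study geometry (30 × 48,
four processes, 50 simulation seeds for rate estimates, 100-draw nulls;
the association calibration uses n = 200 samples where the target is a
correlation value). These are the study-scale defaults of the package;
the library itself has no size limits beyond memory and O(min(n,p)·n·p)
SVD cost.

## Known limitations

- Censored (below-detection) concentrations are floored, not modelled;
  there is no interval-censoring likelihood.
- The Monte-Carlo process-count test assumes i.i.d. Gaussian ln-scale
  noise; correlated noise (plates, batches) will inflate the count.
- The spectral noise estimator biases upward when half or more of the
  components carry signal; prefer the replicate-based estimator.
- Chebyshev/average-linkage leaf order matches the clustering tool the
  analysis mirrors but is not an optimal-leaf-ordering; ties resolve by
  input order.
- No multi-omics extension; one secretome matrix per run.
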