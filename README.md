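# secretoscope

Surprisal analysis of tumor-explant cytokine secretomes.

Fresh tumor fragments (explants) cultured *ex vivo* secrete a panel of
cytokines and chemokines into their supernatant, measured in pg/mL by a
multiplex bead assay. Those concentrations carry a readout of the tumor
immune environment: which co-secretion programs are running, how they
relate to the infiltrating immune cells measured per tumor by flow
cytometry, and how individual tumors respond to checkpoint or agonist
immunotherapy applied to replicate fragments. `secretoscope` implements
that analysis as a tested, reusable library for anyone working with
explant or similar multiplex secretion data: a latent-process
decomposition at its core, plus the association and treatment-comparison
statistics around it, and a synthetic-data generator with planted ground
truth so every stage can be validated by parameter recovery.

## The model

Surprisal analysis writes the log concentration of cytokine *i* in sample
*k* as a steady-state term plus deviations imposed by constraints:

```
ln X_i(k) = ln X_i0(k) − Σ_α G_iα λ_α(k)
```

Each constraint drives one **unbalanced process** α: a subnetwork of
cytokines whose log levels deviate coordinately from the steady state.
`G_iα` is the signed participation of cytokine *i* (opposite signs within
one process mean anti-correlated movement) and `λ_α(k)` is the amplitude
of the process in sample *k* (its sign marks the direction of deviation,
near-zero means the process is inactive there). Operationally the
decomposition is an SVD of the ln-concentration matrix: the leading
component is the steady state and subsequent components are candidate
processes, the equation's minus sign being absorbed into the arbitrary
SVD signs.

On top of the decomposition the package provides:

- **Number of significant processes** — a Monte-Carlo null: a process
  counts if its peak amplitude exceeds the 95th percentile of the same
  statistic from pure-noise matrices at the assay's ln-scale noise level
  (estimated from replicate fragments or from the singular spectrum).
- **Membership calls** — cytokines with `|G| ≥ 20×` the mean of the
  lowest-20% weights belong to the process.
- **Activity calls** — samples where `|λ|` clears the noise threshold are
  active (positive or negative).
- **Iterative-SVD imputation** of missing multiplex values.
- **Association** — pairwise-complete Pearson matrices clustered with
  Chebyshev ("maximum") distance and average linkage; process-amplitude
  vs immune-infiltrate correlations via explant-to-tumor alignment; PCA
  of secretion profiles.
- **Treatment response** — two-tailed unpaired Student t-tests per
  cytokine between treated and baseline replicate fragments, with the
  conventional star tiers and a clearly labelled Benjamini–Hochberg
  column.
- **Signed subnetworks** — STRING-style edge lists restricted to process
  members, nodes signed by G (GraphML + tidy CSV output, no live database
  calls).

## Worked example

`examples/01_decompose_synthetic.py` generates the default study layout —
30 cytokines × 48 explants (4 tumor models × 3 tumors × 4 treatment
arms) with four planted processes at ten-fold signal-to-noise — and runs
the full decomposition:

```
secretome: 30 cytokines × 48 explants, K_true = 4
significant unbalanced processes: K = 4 (noise SD estimated at 0.106 on the ln scale)
null amplitude threshold (95th pct of pure noise): 0.595

process 1 members (2 cytokines, signed G):
        IFNg  G = -0.441
        IP10  G = +0.467

process 1 activity over 48 explants: active_positive=23, active_negative=19, inactive=6

max principal angle to planted subspace: 1.25°  (< 5° means the planted processes were recovered)
```

The analysis found exactly the four planted processes; the opposite signs
of IFNg and IP10 in process 1 mean that process moves them in opposite
directions; 42 of 48 explants have the process running in one direction
or the other; and the recovered process subspace is within 1.25° of the
planted one. The other examples cover infiltrate associations
(`02_infiltrate_associations.py`), per-tumor treatment statistics
(`03_treatment_response.py`) and signed subnetworks
(`04_process_networks.py`).

A thin CLI mirrors the library for shell use:

```bash
secretoscope simulate --seed 1 --outdir data/
secretoscope decompose data/secretome.csv --detection-floor 1e-8 --outdir out/
secretoscope run --config run.yaml --outdir out/
```

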