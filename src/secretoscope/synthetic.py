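"""Synthetic explant datasets with known planted structure.

The generator realizes the generative reading of the surprisal model: on
the natural-log scale a secretome matrix is a per-cytokine steady-state
baseline plus a small number of planted unbalanced processes (rank-one
terms G_alpha · lambda_alpha) plus i.i.d. Gaussian noise, exponentiated to
pg/mL.  Multiplex bead assays are well described by log-normal
concentrations, so additive Gaussian noise on the ln scale is both the
realistic choice and the one that makes the planted model exactly the
decomposition the analysis fits.

Identifiability of the planted truth is enforced geometrically: planted
weight vectors (columns of G) are orthonormal and orthogonal to the
baseline direction, and planted amplitude rows are mutually orthogonal and
centered (orthogonal to the all-ones sample vector).  With zero noise the
SVD of the generated ln-matrix then recovers the planted column space
exactly, so every downstream stage is testable by parameter recovery.

The default scenario mirrors a four-model murine explant study: 30
analytes × 48 explants (4 tumor models × 3 animals × 4 treatment arms),
four planted processes, ln-scale noise SD 0.1 with per-entry amplitude SD
ten times larger.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import InfiltrateTable, SampleMetadata, SecretomeMatrix

__all__ = [
    "SyntheticTruth",
    "make_truth",
    "gen_secretome",
    "gen_infiltrates",
    "make_metadata",
    "simulate_study",
    "DEFAULT_CYTOKINES",
    "DEFAULT_POPULATIONS",
]

#: A realistic 30-analyte multiplex panel (murine cytokines/chemokines).
DEFAULT_CYTOKINES = (
    "IFNg", "IL1b", "IL2", "IL4", "IL5", "IL6", "IL9", "IL10", "IL12p70",
    "IL13", "IL15", "IL17A", "IL18", "IL22", "IL23", "IL27", "TNFa",
    "GM-CSF", "M-CSF", "RANTES", "MCP1", "MIP1a", "MIP1b", "IP10", "GROa",
    "Eotaxin", "KC", "MIG", "LIF", "VEGF",
)

#: Flow-cytometry populations reported per tumor.
DEFAULT_POPULATIONS = (
    "CD4", "CD8", "CD90.2", "TAM", "Monocyte", "Neutrophil", "DC1", "DC2",
    "Treg",
)


@dataclass
class SyntheticTruth:
    """Planted ground truth for one synthetic dataset.

    Attributes
    ----------
    baseline_log_levels
        Per-cytokine ln-concentration at steady state (length n_cytokines).
    planted_G
        (n_cytokines × K_true) signed participation weights; columns are
        orthonormal and orthogonal to the baseline direction.
    planted_lambda
        (K_true × n_samples) process amplitudes; rows are mutually
        orthogonal and centered.
    noise_sd
        SD of i.i.d. additive noise on the ln scale.
    missing_fraction
        Proportion of entries masked at random in the generated matrix.
    infiltrate_link
        process index (1-based) -> tuple of population ids whose synthetic
        abundances track that process's amplitude.
    """

    n_cytokines: int
    n_samples: int
    baseline_log_levels: np.ndarray
    planted_G: np.ndarray
    planted_lambda: np.ndarray
    noise_sd: float
    missing_fraction: float
    infiltrate_link: dict[int, tuple[str, ...]] = field(default_factory=dict)
    seed: int = 0
    cytokine_ids: tuple[str, ...] = ()
    sample_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")
        k = self.K_true
        if k:
            gtg = self.planted_G.T @ self.planted_G
            if not np.allclose(gtg - np.diag(np.diag(gtg)), 0, atol=1e-8):
                raise ValueError("planted_G columns must be orthogonal")
            llt = self.planted_lambda @ self.planted_lambda.T
            if not np.allclose(llt - np.diag(np.diag(llt)), 0, atol=1e-6):
                raise ValueError("planted_lambda rows must be orthogonal")
        for alpha in self.infiltrate_link:
            if not 1 <= alpha <= k:
                raise ValueError(
                    f"infiltrate_link references process {alpha}, but "
                    f"K_true = {k}"
                )

    @property
    def K_true(self) -> int:
        return int(self.planted_G.shape[1]) if self.planted_G.ndim == 2 else 0


def _default_ids(prefix: str, n: int) -> tuple[str, ...]:
    return tuple(f"{prefix}{i + 1:02d}" for i in range(n))


def make_truth(
    n_cytokines: int = 30,
    n_samples: int = 48,
    k_true: int = 4,
    noise_sd: float = 0.1,
    amplitude_sd: float = 1.0,
    amplitude_decay: float = 0.85,
    missing_fraction: float = 0.0,
    infiltrate_link: dict[int, tuple[str, ...]] | None = None,
    seed: int = 0,
    cytokine_ids=None,
    sample_ids=None,
    sample_groups=None,
    baseline_log_mean: float = np.log(100.0),
    baseline_log_sd: float = 1.0,
) -> SyntheticTruth:
    """Draw a random planted truth.

    ``amplitude_sd`` is the root-mean-square ln-scale deviation the
    leading planted process induces across the matrix entries (the
    Frobenius norm of its rank-one term G_alpha·lambda_alpha spread over
    n_cytokines × n_samples entries), so amplitude_sd / noise_sd is the
    per-entry signal-to-noise ratio of that process in the data.

    Successive processes shrink geometrically by ``amplitude_decay``:
    real unbalanced processes have decreasing importance, and distinct
    scales keep the singular values non-degenerate so planted process
    alpha is identifiable with SVD component alpha (equal scales would
    let the SVD rotate arbitrarily inside the planted subspace).

    ``sample_groups`` (one label per sample) plants amplitudes at the
    group level — replicate fragments of one tumor × arm share the tumor
    state, so within-group variation is pure assay noise.
    """
    rng = np.random.default_rng(seed)
    baseline = rng.normal(baseline_log_mean, baseline_log_sd, n_cytokines)

    if k_true > 0:
        if k_true >= min(n_cytokines, n_samples) - 2:
            raise ValueError("k_true too large for the matrix shape")
        # G: orthonormal columns orthogonal to the baseline direction and to
        # the uniform (all-ones) cytokine direction.  The first keeps the
        # steady-state SVD component exactly separate from the planted
        # processes; the second makes the decomposition scale-covariant
        # (multiplying concentrations by c adds ln c to every entry, a
        # rank-one term sharing the steady state's uniform sample vector).
        m = np.empty((n_cytokines, k_true + 2))
        m[:, 0] = baseline / np.linalg.norm(baseline)
        m[:, 1] = 1.0
        m[:, 2:] = rng.standard_normal((n_cytokines, k_true))
        q, _ = np.linalg.qr(m)
        planted_g = q[:, 2:]
        # lambda: drawn per replicate group (all fragments of one tumor ×
        # arm share the tumor state), centered rows (orthogonal to ones),
        # then row-orthonormalized and broadcast back to samples.
        if sample_groups is None:
            group_labels = list(range(n_samples))
        else:
            if len(sample_groups) != n_samples:
                raise ValueError("sample_groups must have one label per sample")
            group_labels = list(sample_groups)
        uniq = list(dict.fromkeys(group_labels))
        n_groups = len(uniq)
        if k_true >= n_groups - 1:
            raise ValueError("k_true too large for the number of groups")
        counts = np.array([group_labels.count(g) for g in uniq], dtype=float)
        raw = rng.standard_normal((k_true, n_groups))
        # orthogonality in the sample (broadcast) inner product, weighted
        # by group sizes, so the planted rows stay orthogonal and centered
        w = np.sqrt(counts)
        raw_w = raw * w
        raw_w -= (raw_w @ w)[:, None] * w / np.sum(counts)
        qr_q, _ = np.linalg.qr(raw_w.T)
        group_l = qr_q.T / w
        idx = np.array([uniq.index(g) for g in group_labels])
        base_l = group_l[:, idx]
        scales = amplitude_sd * amplitude_decay ** np.arange(k_true)
        planted_l = base_l * (scales[:, None] * np.sqrt(n_samples * n_cytokines))
    else:
        planted_g = np.zeros((n_cytokines, 0))
        planted_l = np.zeros((0, n_samples))

    if cytokine_ids is None:
        cytokine_ids = (
            DEFAULT_CYTOKINES
            if n_cytokines == len(DEFAULT_CYTOKINES)
            else _default_ids("CK", n_cytokines)
        )
    if sample_ids is None:
        sample_ids = _default_ids("S", n_samples)

    return SyntheticTruth(
        n_cytokines=n_cytokines,
        n_samples=n_samples,
        baseline_log_levels=baseline,
        planted_G=planted_g,
        planted_lambda=planted_l,
        noise_sd=noise_sd,
        missing_fraction=missing_fraction,
        infiltrate_link=dict(infiltrate_link or {}),
        seed=seed,
        cytokine_ids=tuple(cytokine_ids),
        sample_ids=tuple(sample_ids),
    )


def gen_secretome(
    truth: SyntheticTruth,
    detection_floor: float = 1e-8,
    treatment_shifts: dict[str, dict[str, float]] | None = None,
    metadata: SampleMetadata | None = None,
) -> tuple[SecretomeMatrix, SyntheticTruth]:
    """Generate a concentration matrix from a planted truth.

    values = exp(baseline + G·lambda [+ treatment shifts] + noise), then
    ``missing_fraction`` of entries are masked at random.  Fully
    reproducible from ``truth.seed``.

    ``treatment_shifts`` maps treatment arm -> {cytokine id: ln-scale
    additive shift}; it requires ``metadata`` to locate each arm's samples.

    The default ``detection_floor`` is a pure numerical guard: synthetic
    concentrations are exactly log-normal, so flooring must never truncate
    the planted model.  Real assay tables should carry their true
    detection limit instead.
    """
    rng = np.random.default_rng([truth.seed, 1])
    ln = truth.baseline_log_levels[:, None] + truth.planted_G @ truth.planted_lambda
    ln = ln + rng.normal(0.0, truth.noise_sd, ln.shape) if truth.noise_sd else ln.copy()

    cyt = list(truth.cytokine_ids)
    samples = list(truth.sample_ids)
    if treatment_shifts:
        if metadata is None:
            raise ValueError("treatment_shifts requires metadata")
        col_of = {s: j for j, s in enumerate(samples)}
        row_of = {c: i for i, c in enumerate(cyt)}
        for arm, shifts in treatment_shifts.items():
            for s in metadata.samples_for(treatment=arm):
                if s not in col_of:
                    continue
                for c, delta in shifts.items():
                    ln[row_of[c], col_of[s]] += delta

    x = np.exp(ln)
    if truth.missing_fraction > 0:
        mask_rng = np.random.default_rng([truth.seed, 2])
        total = x.size
        n_mask = int(round(truth.missing_fraction * total))
        flat = mask_rng.choice(total, size=n_mask, replace=False)
        x.flat[flat] = np.nan

    df = pd.DataFrame(x, index=cyt, columns=samples)
    return SecretomeMatrix(df, detection_floor), truth


def gen_infiltrates(
    truth: SyntheticTruth,
    populations=DEFAULT_POPULATIONS,
    target_r: float = 0.9,
    sample_ids=None,
    amplitudes: np.ndarray | None = None,
    loc: float = 1000.0,
    scale: float = 150.0,
) -> InfiltrateTable:
    """Generate per-sample immune-infiltrate abundances.

    Populations named in ``truth.infiltrate_link`` are affine transforms of
    the linked process's planted amplitude plus Gaussian noise calibrated
    so the expected sample Pearson correlation is ``target_r``; all other
    populations are independent log-normal draws.

    ``sample_ids``/``amplitudes`` override the default per-explant layout,
    e.g. to produce one animal-level record per tumor from
    animal-averaged amplitudes.
    """
    if not abs(target_r) < 1:
        raise ValueError(f"target_r must lie in (-1, 1), got {target_r}")
    rng = np.random.default_rng([truth.seed, 3])
    if sample_ids is None:
        sample_ids = list(truth.sample_ids)
    if amplitudes is None:
        col_idx = [list(truth.sample_ids).index(s) for s in sample_ids]
        amplitudes = truth.planted_lambda[:, col_idx] if truth.K_true else None
    n = len(sample_ids)

    linked_pop: dict[str, int] = {}
    for alpha, pops in truth.infiltrate_link.items():
        for p in pops:
            linked_pop[p] = alpha

    rows = np.empty((len(populations), n))
    for i, pop in enumerate(populations):
        if pop in linked_pop:
            lam = amplitudes[linked_pop[pop] - 1]
            z = (lam - lam.mean()) / (lam.std() or 1.0)
            eps = rng.standard_normal(n)
            y = target_r * z + np.sqrt(1.0 - target_r**2) * eps
            rows[i] = np.clip(loc + scale * y, 0.0, None)
        else:
            rows[i] = rng.lognormal(np.log(500.0), 0.5, n)
    df = pd.DataFrame(rows, index=list(populations), columns=list(sample_ids))
    return InfiltrateTable(df, unit="count")


def make_metadata(
    models=("Moc1", "Moc1-ova", "Moc2", "SCC-VII"),
    animals_per_model: int = 3,
    arms=("untreated", "anti-PD1", "anti-CTLA4", "anti-OX40"),
    replicates: int = 1,
) -> SampleMetadata:
    """Build a factorial sample sheet: model × animal × arm × replicate.

    Sample ids are "<model>_a<j>_<arm>[_r<i>]"; animal ids "<model>_a<j>".
    The defaults yield the 48-explant layout (4 models × 3 animals × 4
    arms, one fragment each).
    """
    records = []
    for model in models:
        for j in range(1, animals_per_model + 1):
            animal = f"{model}_a{j}"
            for arm in arms:
                for r in range(1, replicates + 1):
                    sid = f"{animal}_{arm}" + (f"_r{r}" if replicates > 1 else "")
                    records.append((sid, model, animal, arm))
    df = pd.DataFrame(
        records, columns=["sample_id", "tumor_model", "animal_id", "treatment"]
    ).set_index("sample_id")
    return SampleMetadata(df)


#: Default treatment-induced ln-scale shifts (Th1/Th17/Th2-style responses).
DEFAULT_TREATMENT_SHIFTS = {
    "anti-PD1": {"IFNg": 1.0, "IP10": 0.8},
    "anti-OX40": {"IL17A": 1.0, "IL4": 0.6},
}


def simulate_study(
    seed: int = 0,
    n_cytokines: int = 30,
    k_true: int = 4,
    noise_sd: float = 0.1,
    amplitude_sd: float = 1.0,
    missing_fraction: float = 0.0,
    replicates: int = 1,
    infiltrate_link: dict[int, tuple[str, ...]] | None = None,
    target_r: float = 0.8,
    treatment_shifts: dict[str, dict[str, float]] | None = None,
    detection_floor: float = 1e-8,
):
    """One call producing a full paper-like study.

    Returns (SecretomeMatrix, InfiltrateTable, SampleMetadata,
    SyntheticTruth).  Infiltrates are generated at the animal level (one
    record per tumor, linked populations tracking the animal-averaged
    planted amplitudes), matching how flow cytometry is measured once per
    tumor while secretion is measured per explant fragment.
    """
    if infiltrate_link is None:
        infiltrate_link = {3: ("CD4", "CD8", "CD90.2"), 1: ("TAM",)} if k_true >= 3 else {}
    if treatment_shifts is None:
        treatment_shifts = DEFAULT_TREATMENT_SHIFTS
    metadata = make_metadata(replicates=replicates)
    sample_ids = tuple(metadata.sample_ids)
    groups = [
        f"{metadata.animal_of(s)}|{metadata.table.loc[s, 'treatment']}"
        for s in sample_ids
    ]
    truth = make_truth(
        n_cytokines=n_cytokines,
        n_samples=len(sample_ids),
        k_true=k_true,
        noise_sd=noise_sd,
        amplitude_sd=amplitude_sd,
        missing_fraction=missing_fraction,
        infiltrate_link=infiltrate_link,
        seed=seed,
        sample_ids=sample_ids,
        sample_groups=groups,
    )
    secretome, truth = gen_secretome(
        truth,
        detection_floor=detection_floor,
        treatment_shifts=treatment_shifts,
        metadata=metadata,
    )
    # Animal-level infiltrates: average the planted amplitudes over each
    # animal's fragments, then apply the correlation calibration at n_animals.
    seen: dict[str, None] = {}
    for s in sample_ids:
        seen.setdefault(metadata.animal_of(s), None)
    animals = list(seen)
    if truth.K_true:
        agg_lambda = np.column_stack([
            truth.planted_lambda[
                :, [list(sample_ids).index(s) for s in metadata.samples_for(animal_id=a)]
            ].mean(axis=1)
            for a in animals
        ])
    else:
        agg_lambda = None
    infiltrates = gen_infiltrates(
        truth, target_r=target_r, sample_ids=animals, amplitudes=agg_lambda
    )
    return secretome, infiltrates, metadata, truth
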