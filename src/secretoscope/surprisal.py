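"""Surprisal-analysis decomposition of ln-scale secretome matrices.

Surprisal analysis writes the measured level of each secreted protein as a
deviation from a steady state imposed by constraints:

    ln X_i(k) = ln X_i0(k) - sum_alpha G_{i,alpha} lambda_alpha(k)

where X_i(k) is the measured concentration of cytokine i in sample k,
X_i0(k) its steady-state level, G_{i,alpha} the signed participation of
cytokine i in unbalanced process alpha, and lambda_alpha(k) the amplitude
of that process in sample k.  Operationally the decomposition is realized
by a singular value decomposition of the ln-concentration matrix: the
leading component is the steady state (alpha = 0) and each further
component is one candidate unbalanced process, the paper-form minus sign
being absorbed into the arbitrary SVD sign.

This module provides the log transform (with detection-floor pseudocount),
iterative-SVD imputation of missing values, the decomposition itself, a
Monte-Carlo test for the number of significant processes, the fold-based
membership cutoff, per-sample activity calls, and low-rank reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import SampleMetadata, SecretomeMatrix

__all__ = [
    "DecompositionResult",
    "UnbalancedProcess",
    "ImputedMatrix",
    "log_transform",
    "impute_missing_svd",
    "decompose",
    "count_significant_processes",
    "estimate_noise_sd_replicates",
    "process_membership",
    "process_activity",
    "reconstruct",
]

# Relative floor (vs the largest amplitude statistic) below which a
# component is numerically zero; keeps the noiseless case exact.
_STAT_RTOL = 1e-8


def log_transform(secretome: SecretomeMatrix) -> pd.DataFrame:
    """Natural log of concentrations, floored at the detection limit.

    Entries become ln(max(value, detection_floor)); missing entries stay
    missing.  Raw concentrations are never modified.
    """
    floored = secretome.values.clip(lower=secretome.detection_floor)
    return np.log(floored)


@dataclass
class ImputedMatrix:
    """Completed ln-matrix plus convergence diagnostics."""

    values: pd.DataFrame
    n_iter: int
    converged: bool
    rank: int


def impute_missing_svd(
    lnX: pd.DataFrame,
    rank: int | None = None,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> ImputedMatrix:
    """Iterative truncated-SVD imputation of missing ln values.

    Missing entries are initialized to row means, then repeatedly replaced
    by a rank-``rank`` SVD reconstruction until the largest relative change
    of any imputed entry falls below ``tol``.  Observed entries are never
    altered.  Non-convergence at ``max_iter`` sets ``converged=False`` and
    emits a warning rather than raising.

    Default rank is min(5, min(matrix dims) - 1).  The default ``tol`` is
    deliberately strict: the iteration converges linearly and can be slow
    on nearly-degenerate matrices, so the per-step change understates the
    remaining error by the (unknown) convergence factor.
    """
    a = lnX.to_numpy(dtype=float).copy()
    miss = np.isnan(a)
    if rank is None:
        rank = max(1, min(5, min(a.shape) - 1))
    if not miss.any():
        return ImputedMatrix(lnX.copy(), 0, True, rank)
    if miss.all(axis=1).any():
        bad = lnX.index[miss.all(axis=1)][0]
        raise ValueError(f"row {bad!r} has no observed entries")
    if miss.all(axis=0).any():
        bad = lnX.columns[miss.all(axis=0)][0]
        raise ValueError(f"column {bad!r} has no observed entries")

    row_means = np.nanmean(a, axis=1)
    a[miss] = np.broadcast_to(row_means[:, None], a.shape)[miss]

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        u, s, vt = np.linalg.svd(a, full_matrices=False)
        recon = (u[:, :rank] * s[:rank]) @ vt[:rank]
        old = a[miss]
        new = recon[miss]
        a[miss] = new
        denom = max(np.max(np.abs(old)), 1e-12)
        if np.max(np.abs(new - old)) / denom < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"SVD imputation did not converge in {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    return ImputedMatrix(
        pd.DataFrame(a, index=lnX.index, columns=lnX.columns), it, converged, rank
    )


@dataclass
class DecompositionResult:
    """Full surprisal decomposition of one ln-concentration matrix.

    ``G`` holds the weights G_{i,alpha} (cytokines × components, component
    0 = steady state, columns orthonormal); ``lam`` holds the amplitudes
    lambda_alpha(k) (components × samples, rows mutually orthogonal, each
    row = singular value × right singular vector).  The entrywise sum
    sum_alpha G_{i,alpha} lambda_alpha(k) reproduces the input exactly.
    """

    G: pd.DataFrame
    lam: pd.DataFrame
    singular_values: np.ndarray
    K_significant: int | None = None
    noise_sd_est: float | None = None
    null_threshold: float | None = None
    amplitude_stats: np.ndarray | None = None

    @property
    def cytokine_ids(self) -> list[str]:
        return list(self.G.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.lam.columns)

    @property
    def n_components(self) -> int:
        return self.G.shape[1]

    @property
    def steady_state_log(self) -> pd.DataFrame:
        """Per-cytokine-per-sample steady-state term G_{i0} lambda_0(k)."""
        return pd.DataFrame(
            np.outer(self.G.iloc[:, 0], self.lam.iloc[0]),
            index=self.G.index,
            columns=self.lam.columns,
        )


def decompose(lnX: pd.DataFrame) -> DecompositionResult:
    """SVD decomposition of a completed ln-matrix into surprisal terms.

    Component alpha contributes G_{i,alpha} = U[i, alpha] and
    lambda_alpha(k) = s_alpha · V[k, alpha]; alpha = 0 (largest singular
    value) is the steady state.  Each component's sign is fixed so the
    cytokine with the largest |G| has positive G, making outputs
    reproducible despite the inherent SVD sign ambiguity.
    """
    if lnX.shape[1] < 2:
        raise ValueError("decompose needs at least 2 samples")
    arr = lnX.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("lnX contains missing entries; impute first")
    u, s, vt = np.linalg.svd(arr, full_matrices=False)
    lam = s[:, None] * vt
    for alpha in range(u.shape[1]):
        i_star = int(np.argmax(np.abs(u[:, alpha])))
        if u[i_star, alpha] < 0:
            u[:, alpha] = -u[:, alpha]
            lam[alpha] = -lam[alpha]
    comps = [str(a) for a in range(u.shape[1])]
    return DecompositionResult(
        G=pd.DataFrame(u, index=lnX.index, columns=comps),
        lam=pd.DataFrame(lam, index=comps, columns=lnX.columns),
        singular_values=s,
    )


def reconstruct(result: DecompositionResult, n_processes: int) -> pd.DataFrame:
    """Steady state plus the first ``n_processes`` unbalanced processes."""
    if not 0 <= n_processes <= result.n_components - 1:
        raise ValueError(
            f"n_processes must be in [0, {result.n_components - 1}], "
            f"got {n_processes}"
        )
    m = n_processes + 1
    g = result.G.iloc[:, :m].to_numpy()
    l = result.lam.iloc[:m].to_numpy()
    return pd.DataFrame(g @ l, index=result.G.index, columns=result.lam.columns)


def _amplitude_stats(lam: np.ndarray) -> np.ndarray:
    """max over samples of |lambda_alpha(k)|, per component."""
    return np.max(np.abs(lam), axis=1)


def _spectral_noise_estimate(
    singular_values: np.ndarray, shape: tuple[int, int], rng: np.random.Generator,
    n_cal: int = 5,
) -> float:
    """Estimate ln-scale noise SD from the singular spectrum.

    The median singular value (steady state excluded) is compared against
    the same statistic of simulated unit-variance Gaussian matrices of the
    same shape; valid when fewer than half the components carry signal.
    """
    s_med = float(np.median(singular_values[1:]))
    cal = []
    for _ in range(n_cal):
        n = rng.standard_normal(shape)
        sv = np.linalg.svd(n, compute_uv=False)
        cal.append(np.median(sv[1:]))
    return s_med / float(np.mean(cal))


def count_significant_processes(
    result: DecompositionResult,
    noise_sd: float | str = "estimate",
    n_boot: int = 100,
    seed: int = 0,
) -> int:
    """Number of unbalanced processes distinguishable from assay noise.

    A process alpha >= 1 is significant when its amplitude statistic
    max_k |lambda_alpha(k)| exceeds the 95th percentile of the same
    statistic (max over all components and samples) computed from
    ``n_boot`` pure-noise matrices of the same shape, i.i.d. Gaussian with
    the given or spectrally estimated ln-scale ``noise_sd``.  Using all
    components of the noise matrix for the null makes the test
    conservative: under the no-process hypothesis every non-steady-state
    data component is itself noise.

    Stores ``K_significant``, ``noise_sd_est``, ``null_threshold`` and the
    per-process statistics on ``result`` and returns K.
    """
    if n_boot < 10:
        raise ValueError(f"n_boot must be >= 10, got {n_boot}")
    rng = np.random.default_rng(seed)
    shape = (len(result.cytokine_ids), len(result.sample_ids))
    if noise_sd == "estimate":
        sigma = _spectral_noise_estimate(result.singular_values, shape, rng)
    else:
        sigma = float(noise_sd)
        if sigma < 0:
            raise ValueError("noise_sd must be >= 0")

    stats = _amplitude_stats(result.lam.to_numpy())
    if sigma > 0:
        null = np.empty(n_boot)
        for b in range(n_boot):
            noise = rng.normal(0.0, sigma, shape)
            u, s, vt = np.linalg.svd(noise, full_matrices=False)
            null[b] = np.max(np.abs(s[:, None] * vt))
        thr = float(np.percentile(null, 95))
    else:
        thr = 0.0
    # numerical floor: trailing SVD components of an exactly low-rank
    # matrix carry float-eps amplitudes that must not count as processes
    thr = max(thr, _STAT_RTOL * float(stats.max(initial=0.0)))

    k = int(np.sum(stats[1:] > thr))
    result.K_significant = k
    result.noise_sd_est = sigma
    result.null_threshold = thr
    result.amplitude_stats = stats
    return k


def estimate_noise_sd_replicates(
    secretome: SecretomeMatrix, metadata: SampleMetadata
) -> float:
    """Pooled ln-scale SD across replicate fragments of one animal × arm.

    Replicate explants of the same tumor under the same treatment should
    differ only by assay/sampling noise; their pooled within-group SD of
    ln concentrations estimates the ln-scale noise level.  Requires at
    least one group with >= 2 fragments.
    """
    ln = log_transform(secretome)
    groups: dict[tuple[str, str], list[str]] = {}
    known = set(metadata.sample_ids)
    for s in secretome.sample_ids:
        if s not in known:
            continue
        key = (
            metadata.animal_of(s),
            str(metadata.table.loc[s, "treatment"]),
        )
        groups.setdefault(key, []).append(s)
    ss = 0.0
    df_total = 0
    for samples in groups.values():
        if len(samples) < 2:
            continue
        sub = ln.loc[:, samples].to_numpy()
        dev = sub - np.nanmean(sub, axis=1, keepdims=True)
        counts = (~np.isnan(dev)).sum(axis=1)
        ss += float(np.nansum(dev**2))
        df_total += int(np.maximum(counts - 1, 0).sum())
    if df_total == 0:
        raise ValueError("no animal × treatment group has >= 2 replicates")
    return float(np.sqrt(ss / df_total))


@dataclass
class UnbalancedProcess:
    """One unbalanced co-secretion process (alpha >= 1).

    ``member_weights`` carries the signed G of member cytokines: opposite
    signs mean the process moves those cytokines in opposite directions.
    ``activity_calls`` labels each sample active_positive / active_negative
    / inactive by comparing lambda_alpha(k) with the amplitude threshold.
    """

    alpha: int
    member_ids: list[str] = field(default_factory=list)
    member_weights: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    activity_threshold: float | None = None
    activity_calls: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))


def process_membership(
    result: DecompositionResult,
    alpha: int,
    fold: float = 20.0,
    quantile: float = 0.20,
    process: UnbalancedProcess | None = None,
) -> UnbalancedProcess:
    """Call member cytokines of process ``alpha`` by the fold cutoff.

    The baseline is the mean |G| of the floor(quantile · n_cytokines)
    cytokines with smallest |G| (at least one; ties broken by cytokine-id
    order); members are all cytokines with |G| >= fold × baseline, keeping
    their signed weights.  The default 20-fold / lowest-20% rule separates
    involved cytokines from the background of uninvolved ones.
    """
    if alpha == 0:
        raise ValueError("the steady state (alpha = 0) has no membership")
    if not 1 <= alpha <= result.n_components - 1:
        raise ValueError(f"alpha must be in [1, {result.n_components - 1}]")
    g = result.G.iloc[:, alpha]
    absg = g.abs()
    n_low = max(1, int(np.floor(quantile * len(g))))
    order = np.lexsort((np.arange(len(g)), absg.to_numpy()))
    baseline = float(absg.to_numpy()[order[:n_low]].mean())
    members = absg >= fold * baseline
    proc = process or UnbalancedProcess(alpha=alpha)
    proc.alpha = alpha
    proc.member_ids = list(g.index[members])
    proc.member_weights = g[members].copy()
    return proc


def process_activity(
    result: DecompositionResult,
    alpha: int,
    threshold: float | str = "auto",
    process: UnbalancedProcess | None = None,
) -> UnbalancedProcess:
    """Label samples where process ``alpha`` is active.

    Sample k is active_positive when lambda_alpha(k) > threshold,
    active_negative when lambda_alpha(k) < -threshold, else inactive.
    ``"auto"`` uses the 95th-percentile pure-noise amplitude from
    :func:`count_significant_processes` (run it first) as a single global
    threshold; amplitudes below what noise alone produces are not
    interpretable as activity.
    """
    if not 1 <= alpha <= result.n_components - 1:
        raise ValueError(f"alpha must be in [1, {result.n_components - 1}]")
    if threshold == "auto":
        if result.null_threshold is None:
            raise ValueError(
                "auto threshold requires count_significant_processes first"
            )
        thr = float(result.null_threshold)
    else:
        thr = float(threshold)
    if thr <= 0:
        raise ValueError(f"activity threshold must be > 0, got {thr}")
    lam = result.lam.iloc[alpha]
    calls = pd.Series("inactive", index=lam.index, dtype=object)
    calls[lam > thr] = "active_positive"
    calls[lam < -thr] = "active_negative"
    proc = process or UnbalancedProcess(alpha=alpha)
    proc.alpha = alpha
    proc.activity_threshold = thr
    proc.activity_calls = calls
    return proc
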