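"""Linking secretion to infiltration and treatment.

Four analyses connect the decomposition (and raw cytokines) to the rest of
the study design:

* pairwise Pearson correlation matrices between two feature tables, with
  agglomerative clustering of rows/columns (Chebyshev "maximum" distance,
  average linkage) for heatmap ordering;
* correlations between unbalanced-process amplitudes and immune-infiltrate
  populations, computed at the animal level via the explant-to-tumor
  sample alignment;
* PCA of cytokine profiles to separate tumor models / treatment arms;
* per-cytokine treatment-vs-baseline comparisons by the two-tailed
  unpaired equal-variance Student t-test, with the conventional star tiers
  and an additionally emitted Benjamini–Hochberg column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .datamodel import InfiltrateTable, SampleMetadata, SecretomeMatrix
from .io import AlignedSamples
from .surprisal import DecompositionResult, impute_missing_svd

__all__ = [
    "CorrelationReport",
    "TreatmentComparison",
    "pearson_matrix",
    "cluster_order",
    "amplitude_infiltrate_correlation",
    "pca_scores",
    "compare_treatments",
    "compare_all_treatments",
    "significance_stars",
]

_MIN_PAIRS = 3


@dataclass
class CorrelationReport:
    """Pearson correlation matrix with clustering metadata.

    ``r`` is rows × cols of product-moment coefficients (NaN where fewer
    than three complete pairs exist or a feature has zero variance);
    ``n_pairs`` counts the samples used per cell.  ``row_order`` /
    ``col_order`` are leaf permutations from hierarchical clustering.
    """

    r: pd.DataFrame
    n_pairs: pd.DataFrame
    row_order: list[int] | None = None
    col_order: list[int] | None = None
    linkage_params: dict = field(default_factory=dict)

    @property
    def row_ids(self) -> list[str]:
        return list(self.r.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.r.columns)

    def ordered(self) -> pd.DataFrame:
        """r with clustering permutations applied (identity if unclustered)."""
        ro = self.row_order or list(range(len(self.r)))
        co = self.col_order or list(range(self.r.shape[1]))
        return self.r.iloc[ro, co]


def _pearson_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < _MIN_PAIRS:
        return np.nan, n
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return np.nan, n
    return float(stats.pearsonr(xs, ys).statistic), n


def pearson_matrix(rows: pd.DataFrame, cols: pd.DataFrame) -> CorrelationReport:
    """Pairwise-complete Pearson correlations between two feature tables.

    Both tables are features × samples over a shared sample set (the
    intersection of their columns is used).  Cells with fewer than three
    complete pairs, or involving a zero-variance feature, are NaN.
    """
    shared = [s for s in rows.columns if s in set(cols.columns)]
    if len(shared) < _MIN_PAIRS:
        raise ValueError(
            f"need >= {_MIN_PAIRS} shared samples, got {len(shared)}"
        )
    rx = rows.loc[:, shared].to_numpy(dtype=float)
    cx = cols.loc[:, shared].to_numpy(dtype=float)
    r = np.empty((rx.shape[0], cx.shape[0]))
    n = np.empty_like(r, dtype=int)
    for i in range(rx.shape[0]):
        for j in range(cx.shape[0]):
            r[i, j], n[i, j] = _pearson_pair(rx[i], cx[j])
    return CorrelationReport(
        r=pd.DataFrame(r, index=rows.index, columns=cols.index),
        n_pairs=pd.DataFrame(n, index=rows.index, columns=cols.index),
    )


_DISTANCES = {"chebyshev": "chebyshev", "maximum": "chebyshev",
              "euclidean": "euclidean", "correlation": "correlation"}


def cluster_order(
    report: CorrelationReport,
    distance: str = "chebyshev",
    linkage_method: str = "average",
) -> tuple[list[int], list[int]]:
    """Leaf orders from agglomerative clustering of the correlation matrix.

    Missing r cells are filled with 0 for distance purposes (flagged in
    ``linkage_params``).  Default is Chebyshev ("maximum") distance with
    average linkage.  A single row or column yields the identity order.
    """
    if distance not in _DISTANCES:
        raise ValueError(f"unknown distance {distance!r}")
    metric = _DISTANCES[distance]
    filled = report.r.to_numpy(dtype=float)
    had_missing = bool(np.isnan(filled).any())
    filled = np.nan_to_num(filled, nan=0.0)

    def order_of(mat: np.ndarray) -> list[int]:
        if mat.shape[0] < 2:
            return list(range(mat.shape[0]))
        z = linkage(pdist(mat, metric=metric), method=linkage_method)
        return [int(i) for i in leaves_list(z)]

    report.row_order = order_of(filled)
    report.col_order = order_of(filled.T)
    report.linkage_params = {
        "distance": distance,
        "linkage": linkage_method,
        "missing_filled_with_zero": had_missing,
    }
    return report.row_order, report.col_order


def amplitude_infiltrate_correlation(
    result: DecompositionResult,
    infiltrates: InfiltrateTable,
    mapping: AlignedSamples | dict[str, str],
) -> CorrelationReport:
    """Correlate unbalanced-process amplitudes with infiltrate levels.

    Explant samples are grouped by their matched infiltrate record (one
    per tumor) and their amplitudes averaged, so each correlation is
    computed across tumors.  Rows are the significant processes (run
    :func:`count_significant_processes` first), columns the populations.
    """
    if not result.K_significant:
        raise ValueError("no significant processes; run the significance test")
    pairs = mapping.mapping if isinstance(mapping, AlignedSamples) else dict(mapping)
    groups: dict[str, list[str]] = {}
    lam_samples = set(result.sample_ids)
    for exp, inf in pairs.items():
        if exp in lam_samples and inf in set(infiltrates.sample_ids):
            groups.setdefault(inf, []).append(exp)
    if len(groups) < _MIN_PAIRS:
        raise ValueError("fewer than 3 matched tumors after alignment")
    inf_ids = [s for s in infiltrates.sample_ids if s in groups]
    alphas = [str(a) for a in range(1, result.K_significant + 1)]
    amp = pd.DataFrame(
        {inf: result.lam.loc[alphas, groups[inf]].mean(axis=1) for inf in inf_ids}
    )
    amp.index = [f"process {a}" for a in alphas]
    return pearson_matrix(amp, infiltrates.values.loc[:, inf_ids])


def pca_scores(
    profiles: pd.DataFrame,
    n_components: int = 2,
    center_rows: bool = True,
    scale_rows: bool = False,
    impute_rank: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of a features × samples table; returns per-sample scores.

    Missing entries are first completed by iterative-SVD imputation.  Rows
    (features) are centered by default; optional unit-variance row scaling
    matches the convention used for treatment-response heatmaps.  Returns
    (scores: samples × components, explained-variance fractions).
    """
    if n_components > min(profiles.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(dims)={min(profiles.shape)}"
        )
    x = profiles.to_numpy(dtype=float)
    if np.isnan(x).any():
        x = impute_missing_svd(profiles, rank=impute_rank).values.to_numpy()
    if center_rows:
        x = x - x.mean(axis=1, keepdims=True)
    if scale_rows:
        sd = x.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    frac = s**2 / max(float(np.sum(s**2)), 1e-300)
    scores = pd.DataFrame(
        (s[:n_components, None] * vt[:n_components]).T,
        index=profiles.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return scores, frac[:n_components]


def significance_stars(p: float) -> str:
    """Conventional star tiers: * <0.05, ** <0.01, *** <0.001, else NS."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


@dataclass
class TreatmentComparison:
    """One cytokine's treated-vs-baseline comparison (unpaired t-test)."""

    cytokine_id: str
    arm: str
    baseline_mean: float
    treated_mean: float
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    significance_stars: str


def compare_treatments(
    secretome: SecretomeMatrix,
    metadata: SampleMetadata,
    cytokine: str,
    arm: str,
    animal_id: str | None = None,
    tumor_model: str | None = None,
    baseline_arm: str = "untreated",
) -> TreatmentComparison:
    """Two-tailed unpaired equal-variance Student t-test for one cytokine.

    Compares raw concentrations between the ``arm``-treated and baseline
    explant fragments, optionally restricted to one animal (replicate
    fragments of one tumor) or one tumor model.  Both groups need at least
    two fragments with observed values.
    """
    base_samples = metadata.samples_for(
        treatment=baseline_arm, animal_id=animal_id, tumor_model=tumor_model
    )
    trt_samples = metadata.samples_for(
        treatment=arm, animal_id=animal_id, tumor_model=tumor_model
    )
    present = set(secretome.sample_ids)
    row = secretome.values.loc[cytokine]
    base = row[[s for s in base_samples if s in present]].dropna().to_numpy()
    trt = row[[s for s in trt_samples if s in present]].dropna().to_numpy()
    if len(base) < 2 or len(trt) < 2:
        raise ValueError(
            f"need >= 2 replicates per group for {cytokine!r} / {arm!r}; "
            f"got {len(base)} baseline, {len(trt)} treated"
        )
    res = stats.ttest_ind(base, trt, equal_var=True)
    df = len(base) + len(trt) - 2
    p = float(res.pvalue)
    return TreatmentComparison(
        cytokine_id=cytokine,
        arm=arm,
        baseline_mean=float(base.mean()),
        treated_mean=float(trt.mean()),
        t_statistic=float(res.statistic),
        degrees_of_freedom=df,
        p_value=p,
        significance_stars=significance_stars(p),
    )


def compare_all_treatments(
    secretome: SecretomeMatrix,
    metadata: SampleMetadata,
    arms=None,
    by: str | None = "tumor_model",
    baseline_arm: str = "untreated",
) -> pd.DataFrame:
    """Tidy table of t-tests for every cytokine × arm (× group).

    ``by`` splits comparisons per tumor_model or animal_id (None pools
    everything).  Raw p-values carry the star tiers; a Benjamini–Hochberg
    adjusted column (``p_bh``) is added because many cytokines are tested.
    Cells with too few replicates are skipped.
    """
    if arms is None:
        arms = [
            a for a in metadata.table["treatment"].unique() if a != baseline_arm
        ]
    if by is None:
        groups = [None]
    else:
        groups = list(dict.fromkeys(metadata.table[by]))
    rows = []
    for grp in groups:
        sel = {by: grp} if by else {}
        for arm in arms:
            for cyt in secretome.cytokine_ids:
                try:
                    cmp_ = compare_treatments(
                        secretome, metadata, cyt, arm,
                        baseline_arm=baseline_arm,
                        **{
                            "animal_id": grp if by == "animal_id" else None,
                            "tumor_model": grp if by == "tumor_model" else None,
                        },
                    )
                except ValueError:
                    continue
                rows.append({
                    "group": grp if grp is not None else "all",
                    "arm": arm,
                    "cytokine": cyt,
                    "baseline_mean": cmp_.baseline_mean,
                    "treated_mean": cmp_.treated_mean,
                    "t": cmp_.t_statistic,
                    "df": cmp_.degrees_of_freedom,
                    "p": cmp_.p_value,
                    "stars": cmp_.significance_stars,
                })
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
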