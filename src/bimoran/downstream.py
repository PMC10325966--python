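"""Downstream interpretation of selected interactions.

Covers: grouping selected pairs into spatial communication patterns,
pathway enrichment of a selection, cell-type attribution of local signal
(chord-diagram edge weights and a linear decoding of cell-type weights from
local p-values), and differential interaction testing across samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .io import LRDatabase
from .local_stats import LocalResult
from .weights import SpatialWeights

__all__ = [
    "PatternResult",
    "cluster_patterns",
    "pathway_enrichment",
    "chord_celltype",
    "chord_lr",
    "celltype_regression",
    "DifferentialResult",
    "differential_test",
]


# ---------------------------------------------------------------------------
# communication patterns
# ---------------------------------------------------------------------------


@dataclass
class PatternResult:
    """K spatial communication patterns over the selected pairs.

    ``labels`` maps each eligible pair to a pattern in [0, K);
    ``intensity`` is the K x spots matrix of per-pattern mean smoothed hit
    profiles (a soft picture of where each pattern communicates).
    """

    labels: pd.Series
    intensity: np.ndarray
    k: int

    def write_tsv(self, labels_path, intensity_path=None, spot_ids=None) -> None:
        self.labels.rename("pattern").to_frame().to_csv(labels_path, sep="\t")
        if intensity_path is not None:
            cols = spot_ids if spot_ids is not None else np.arange(self.intensity.shape[1])
            pd.DataFrame(self.intensity, columns=cols).to_csv(intensity_path, sep="\t")


def cluster_patterns(
    hits: pd.DataFrame,
    coords: np.ndarray,
    k: int,
    length_scale: float,
    seed: int = 0,
    min_hits: int = 10,
) -> PatternResult:
    """Cluster binary per-pair hit profiles into K spatial patterns.

    Each pair's 0/1 hit vector is smoothed over the tissue with a
    row-normalized RBF kernel at ``length_scale`` (turning sparse hits into
    a spatial intensity), then the smoothed profiles are grouped by k-means
    with a fixed seed. This is a deliberately light-weight stand-in for
    Gaussian-process "expression histology" mixtures: it preserves the
    behaviour that matters here (pairs hitting the same tissue region land
    in the same pattern) without the GP machinery. Pairs with fewer than
    ``min_hits`` hit spots are excluded as too sparse to place.
    """
    if not isinstance(hits, pd.DataFrame):
        hits = pd.DataFrame(np.asarray(hits))
    eligible = hits.index[hits.sum(axis=1) >= min_hits]
    if k > len(eligible):
        raise ValueError(
            f"K={k} exceeds the {len(eligible)} pairs with >= {min_hits} hit spots"
        )
    coords = np.asarray(coords, dtype=float)
    kern = np.exp(-cdist(coords, coords, "sqeuclidean") / (2 * length_scale**2))
    kern /= kern.sum(axis=1, keepdims=True)
    smoothed = hits.loc[eligible].to_numpy(dtype=float) @ kern.T

    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(smoothed)
    labels = pd.Series(km.labels_, index=eligible, name="pattern")
    intensity = np.vstack(
        [smoothed[km.labels_ == j].mean(axis=0) for j in range(k)]
    )
    return PatternResult(labels=labels, intensity=intensity, k=k)


# ---------------------------------------------------------------------------
# pathway enrichment
# ---------------------------------------------------------------------------


def pathway_enrichment(selected_pairs, db: LRDatabase) -> pd.DataFrame:
    """One-sided Fisher's exact enrichment of a selection per pathway.

    For each pathway the 2x2 table (selected vs not) x (in pathway vs not)
    over all database pairs is tested with alternative='greater'. Pathways
    with fewer than 2 selected pairs are flagged (too thin to visualise).
    """
    selected = {p.pair_id if hasattr(p, "pair_id") else str(p) for p in selected_pairs}
    unknown = selected - set(db.pair_ids)
    if unknown:
        raise ValueError(f"selected pairs not in database: {sorted(unknown)[:5]}")
    df = db.to_dataframe()
    df["selected"] = df["pair_id"].isin(selected)
    total = len(df)
    n_sel = int(df["selected"].sum())
    rows = []
    for pathway, grp in df.groupby("pathway", sort=True):
        in_path = len(grp)
        a = int(grp["selected"].sum())          # selected, in pathway
        b = n_sel - a                            # selected, outside
        c = in_path - a                          # unselected, in pathway
        d = total - in_path - b                  # unselected, outside
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(
            {
                "pathway": pathway,
                "n_selected": a,
                "pct_of_pathway": 100.0 * a / in_path,
                "fisher_p": p,
                "flagged": a < 2,
            }
        )
    return pd.DataFrame(rows).sort_values("fisher_p", ignore_index=True)


# ---------------------------------------------------------------------------
# chord-diagram edge weights
# ---------------------------------------------------------------------------


def _type_vector(celltype_weights: pd.DataFrame, name: str) -> np.ndarray:
    if name not in celltype_weights.columns:
        raise ValueError(f"unknown cell type {name!r}")
    return celltype_weights[name].to_numpy(dtype=float)


def chord_celltype(
    local: LocalResult,
    weights: SpatialWeights,
    celltype_weights: pd.DataFrame,
    type_a: str,
    type_b: str,
) -> float:
    """Edge weight from sender type A to receiver type B for one pair.

    n_AB = sum_ij w_ij * sender_R_i * A_i * receiver_R_j * B_j, i.e. the
    pair's sender signal deposited in A-rich spots flowing along W into its
    receiver signal in B-rich spots. Bilinear in the cell-type weights, so
    summing over all type combinations recovers the total directed flow.
    """
    a = _type_vector(celltype_weights, type_a)
    b = _type_vector(celltype_weights, type_b)
    return float((local.sender_R * a) @ weights.dot(local.receiver_R * b))


def chord_lr(
    locals_: dict[str, LocalResult],
    weights: SpatialWeights,
    celltype_weights: pd.DataFrame,
    type_a: str,
    type_b: str,
) -> pd.Series:
    """Per-pair edge weights for a fixed (sender type, receiver type)."""
    return pd.Series(
        {
            pid: chord_celltype(res, weights, celltype_weights, type_a, type_b)
            for pid, res in locals_.items()
        },
        name=f"{type_a}->{type_b}",
    )


# ---------------------------------------------------------------------------
# cell-type decoding from local statistics
# ---------------------------------------------------------------------------


@dataclass
class CelltypeRegressionResult:
    coef: np.ndarray
    predicted: pd.DataFrame
    pearson_r: float


def celltype_regression(
    local_p: pd.DataFrame, celltype_weights: pd.DataFrame
) -> CelltypeRegressionResult:
    """Linearly decode cell-type weights from local p-values.

    Ordinary least squares (with intercept) from the spots x pairs matrix of
    local p-values to the spots x types weight matrix, fitted and evaluated
    on all spots. A high Pearson correlation between flattened predicted and
    observed weights indicates that local interaction calls track the
    underlying cell-type architecture.
    """
    if local_p.shape[0] != celltype_weights.shape[0]:
        raise ValueError("local_p and celltype_weights must share spot ordering")
    X = np.column_stack([np.ones(len(local_p)), local_p.to_numpy(dtype=float)])
    Y = celltype_weights.to_numpy(dtype=float)
    coef, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn("rank-deficient predictors; least-norm solution used")
    pred = X @ coef
    r = float(np.corrcoef(pred.ravel(), Y.ravel())[0, 1])
    predicted = pd.DataFrame(
        pred, index=celltype_weights.index, columns=celltype_weights.columns
    )
    return CelltypeRegressionResult(coef=coef, predicted=predicted, pearson_r=r)


# ---------------------------------------------------------------------------
# differential interaction between conditions
# ---------------------------------------------------------------------------


@dataclass
class DifferentialResult:
    """Per-pair likelihood-ratio comparison of z-scores across samples."""

    table: pd.DataFrame
    condition: pd.Series
    fdr_threshold: float
    quantile_cut: float
    var_method: str
    p_method: str

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def differential_test(
    z_matrix: pd.DataFrame,
    condition,
    fdr_threshold: float = 0.1,
    quantile_cut: float = 0.3,
    var_method: str = "pooled",
    p_method: str | None = None,
) -> DifferentialResult:
    """Test each pair for differential interaction strength across samples.

    ``z_matrix`` is pairs x samples of global z-scores (NaN, i.e. a pair
    undetected in a sample, enters as 0). ``condition`` is either a
    two-level categorical label per sample or a continuous covariate. Per
    pair a Gaussian linear model of z on the condition (full) is compared
    with intercept-only (reduced) by a likelihood-ratio statistic.

    Variance handling (``var_method``):

    * ``'pooled'`` (default) — the Gaussian error variance is estimated
      once from the full-model residuals of *all* pairs. z-scores share a
      common null scale by construction (unit, under the global null), and
      with the handful of replicates typical here a per-pair estimate on
      n - 2 degrees of freedom is far too unstable; borrowing strength
      across pairs is the standard remedy. The LRT
      ``(RSS_reduced - RSS_full) / pooled_sigma2`` is then referred to
      chi-squared(1), which is essentially exact because the pooled
      error degrees of freedom are large.
    * ``'per_pair'`` — each pair estimates its own variance by ML;
      ``lrt = n log(RSS_reduced/RSS_full)``. ``p_method='fstat'``
      (default here) uses the exact finite-sample F(1, n-2) tail of the
      monotone-equivalent F statistic; ``'chi2'`` the asymptotic
      chi-squared(1) tail, which is anti-conservative for few samples.

    Direction labels: z_diff = mean(z | condition 1) - mean(z | condition 2)
    (the fitted slope for a continuous covariate); cutoffs at the
    ``quantile_cut`` and ``1 - quantile_cut`` quantiles of z_diff across all
    pairs; only FDR-significant pairs outside the cutoffs get a non-``ns``
    label.
    """
    if var_method not in {"pooled", "per_pair"}:
        raise ValueError(f"unknown var_method {var_method!r}")
    if p_method is None:
        p_method = "chi2" if var_method == "pooled" else "fstat"
    if p_method not in {"fstat", "chi2"}:
        raise ValueError(f"unknown p_method {p_method!r}")
    if var_method == "pooled" and p_method == "fstat":
        raise ValueError("p_method='fstat' applies only to var_method='per_pair'")
    condition = pd.Series(condition, index=z_matrix.columns)
    Z = z_matrix.fillna(0.0).to_numpy(dtype=float)
    m = Z.shape[1]

    levels = pd.unique(condition)
    if len(levels) == 2:
        covar = (condition == levels[1]).to_numpy(dtype=float)
        label_hi = f"{levels[0]}_specific"
        label_lo = f"{levels[1]}_specific"
    elif np.issubdtype(condition.dtype, np.number) and len(levels) > 2:
        covar = condition.to_numpy(dtype=float)
        label_hi, label_lo = "positive", "negative"
    else:
        raise ValueError(
            "condition must have exactly two levels or be a continuous covariate"
        )
    if len(levels) == 2 and (covar.sum() == 0 or covar.sum() == m):
        raise ValueError("each condition needs at least one sample")

    X = np.column_stack([np.ones(m), covar])
    H = X @ np.linalg.pinv(X)
    resid_full = Z - Z @ H.T
    rss_full = (resid_full**2).sum(axis=1)
    rss_red = ((Z - Z.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)

    df_full, df_diff = X.shape[1], 1
    if var_method == "pooled":
        pooled = rss_full.sum() / (len(rss_full) * (m - df_full))
        improvement = np.maximum(rss_red - rss_full, 0.0)
        # guard against all-residuals-zero degeneracy (and its fp residue)
        if pooled <= 1e-12 * max(float(rss_red.max()), 1.0):
            lrt = np.where(improvement > 0, np.inf, 0.0)
        else:
            lrt = improvement / pooled
        p = stats.chi2.sf(lrt, df_diff)
    elif p_method == "chi2":
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(rss_full > 0, rss_red / np.maximum(rss_full, 1e-300), 1.0)
            ratio = np.where((rss_full == 0) & (rss_red > 0), np.inf, ratio)
            lrt = m * np.log(ratio)
        lrt = np.where(rss_red == 0, 0.0, lrt)
        p = stats.chi2.sf(lrt, df_diff)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (rss_red - rss_full) / df_diff / np.where(
                rss_full > 0, rss_full / (m - df_full), np.nan
            )
        F = np.where(rss_red == 0, 0.0, F)
        F = np.where((rss_full == 0) & (rss_red > 0), np.inf, F)
        lrt = m * np.log1p(np.where(np.isfinite(F), F, 0.0) * df_diff / (m - df_full))
        lrt = np.where(np.isinf(F), np.inf, lrt)
        p = stats.f.sf(F, df_diff, m - df_full)
    p = np.nan_to_num(p, nan=1.0)

    fdr = multipletests(p, method="fdr_bh")[1]

    if len(levels) == 2:
        mask1 = (condition == levels[0]).to_numpy()
        z_diff = Z[:, mask1].mean(axis=1) - Z[:, ~mask1].mean(axis=1)
    else:
        beta = np.linalg.pinv(X) @ Z.T
        z_diff = beta[1]

    lo = np.quantile(z_diff, quantile_cut)
    hi = np.quantile(z_diff, 1.0 - quantile_cut)
    label = np.full(len(Z), "ns", dtype=object)
    sig = fdr < fdr_threshold
    label[sig & (z_diff >= hi)] = label_hi
    label[sig & (z_diff <= lo)] = label_lo

    table = pd.DataFrame(
        {
            "pair_id": z_matrix.index,
            **{f"z_{s}": z_matrix.fillna(0.0)[s].to_numpy() for s in z_matrix.columns},
            "lrt_stat": lrt,
            "p": p,
            "fdr": fdr,
            "z_diff": z_diff,
            "label": label,
        }
    ).reset_index(drop=True)
    return DifferentialResult(
        table=table,
        condition=condition,
        fdr_threshold=fdr_threshold,
        quantile_cut=quantile_cut,
        var_method=var_method,
        p_method=p_method,
    )
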