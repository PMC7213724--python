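"""Two-group differential expression for matched mRNA / miRNA matrices.

The mRNA branch consumes a raw count matrix (genes x samples), normalizes it
with median-of-ratios size factors, log2-transforms with a pseudocount and
tests each gene with an empirical-Bayes moderated t-statistic.  The miRNA
branch consumes already-normalized log2 intensities and runs the same
moderated test directly.  Selection rules differ by platform: genes are
called at BH-adjusted p < 0.05 with |log2FC| > 1; miRNAs at raw p < 0.01
with no fold-change cut-off.

The moderated test shrinks per-feature sample variances toward a pooled
prior estimated by method of moments on the log sample variances, using the
digamma/trigamma moment identities of the scaled inverse-chi-square model.
With prior degrees of freedom forced to zero the statistic reduces exactly
to the ordinary pooled two-sample t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ModeratedTestHyper",
    "QCReport",
    "median_ratio_size_factors",
    "log_normalize",
    "moderated_t_table",
    "bh_adjust",
    "select_de",
    "ddct_fold_change",
    "sample_qc",
]

_TRIGAMMA_EPS = 1e-8


@dataclass(frozen=True)
class ModeratedTestHyper:
    """Empirical-Bayes hyperparameters of the moderated variance prior.

    d0 is the prior degrees of freedom (``inf`` when the moment estimate
    collapses, i.e. the observed log-variances are underdispersed relative
    to pure chi-square sampling noise), s0_sq the prior variance and d the
    residual degrees of freedom n1 + n2 - 2 of each per-feature variance.
    """

    d0: float
    s0_sq: float
    d: int

    def __post_init__(self) -> None:
        if not (self.d0 > 0):  # inf allowed
            raise ValueError("prior degrees of freedom must be positive")
        if not (self.s0_sq > 0):
            raise ValueError("prior variance must be positive")
        if self.d < 1:
            raise ValueError("residual degrees of freedom must be >= 1")


@dataclass
class QCReport:
    """Per-sample quality metrics: PCA, distances, clustering, outliers."""

    pca_coordinates: pd.DataFrame  # samples x (PC1, PC2)
    variance_explained: np.ndarray  # fractions for PC1, PC2
    distance_matrix: pd.DataFrame  # samples x samples, Euclidean
    dendrogram_order: list[str]  # average-linkage leaf order
    outliers: list[str]
    top_features: pd.Series  # mean expression of the N most abundant features


def _as_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(matrix, pd.DataFrame):
        raise TypeError("expression matrix must be a pandas DataFrame")
    return matrix


def median_ratio_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    The reference sample is the per-gene geometric mean over genes with
    strictly positive counts in every sample; each sample's factor is the
    median ratio of its counts to that reference.
    """
    counts = _as_matrix(counts)
    values = counts.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("counts must be non-negative")
    all_positive = (values > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; consider a "
            "pseudo-reference fallback (add a pseudocount before calling)"
        )
    log_ref = np.log(values[all_positive]).mean(axis=1)
    ratios = np.log(values[all_positive]) - log_ref[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def log_normalize(
    counts: pd.DataFrame,
    size_factors: pd.Series | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """log2(count / size_factor + pseudocount), shape preserved."""
    counts = _as_matrix(counts)
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    values = counts.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("counts must be non-negative")
    if size_factors is None:
        size_factors = median_ratio_size_factors(counts)
    factors = np.asarray(size_factors.reindex(counts.columns), dtype=float)
    if np.any(~np.isfinite(factors)) or np.any(factors <= 0):
        raise ValueError("size factors must be positive and cover all samples")
    return pd.DataFrame(
        np.log2(values / factors[None, :] + pseudocount),
        index=counts.index,
        columns=counts.columns,
    )


def _trigamma_inverse(y: np.ndarray | float) -> np.ndarray | float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    trigamma is convex and decreasing on (0, inf); the iteration below (in
    1/x scale) converges monotonically from the asymptotic start x ~ 1/y.
    """
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y  # good start: trigamma(x) ~ 1/x + 1/(2x^2)
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x - dif
        if np.all(np.abs(dif) < 1e-10 * np.maximum(x, 1.0)):
            break
    return x


def _fit_variance_prior(s_sq: np.ndarray, d: int) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0_sq) from per-feature variances.

    Uses e = log(s^2): under the scaled model var(e) = trigamma(d/2) +
    trigamma(d0/2) and E[e] = log(s0^2) + digamma(d/2) - log(d/2) -
    digamma(d0/2) + log(d0/2).  Zero variances carry no information about
    the spread of true variances and are excluded from the fit.
    """
    e = np.log(s_sq[s_sq > 0])
    if e.size < 2:
        # degenerate: no spread information, fall back to a flat prior
        mean_e = float(e.mean()) if e.size else 0.0
        s0_sq = float(np.exp(mean_e - special.digamma(d / 2) + np.log(d / 2)))
        return np.inf, max(s0_sq, _TRIGAMMA_EPS)
    excess = e.var(ddof=1) - special.polygamma(1, d / 2)
    if excess <= _TRIGAMMA_EPS:
        d0 = np.inf
        log_s0 = e.mean() - special.digamma(d / 2) + np.log(d / 2)
    else:
        half_d0 = float(_trigamma_inverse(max(excess, _TRIGAMMA_EPS)))
        d0 = 2.0 * half_d0
        log_s0 = (
            e.mean()
            - special.digamma(d / 2)
            + np.log(d / 2)
            + special.digamma(half_d0)
            - np.log(half_d0)
        )
    return float(d0), float(np.exp(log_s0))


def moderated_t_table(
    matrix: pd.DataFrame,
    groups: pd.Series,
    *,
    case_label: str = "AF",
    control_label: str = "SR",
    prior_df: float | None = None,
) -> tuple[pd.DataFrame, ModeratedTestHyper]:
    """Moderated two-group t-test on a log-scale expression matrix.

    Returns a per-feature table (feature_id index; base_mean, log2FC,
    p_raw, p_adj columns; log2FC is case minus control) together with the
    fitted variance-prior hyperparameters.  ``prior_df`` overrides the
    estimated prior degrees of freedom; 0 gives the ordinary pooled t.
    """
    matrix = _as_matrix(matrix)
    groups = groups.reindex(matrix.columns)
    if groups.isna().any():
        raise ValueError("every sample column needs a group label")
    case = matrix.columns[groups == case_label]
    control = matrix.columns[groups == control_label]
    n1, n2 = len(case), len(control)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")

    x1 = matrix[case].to_numpy(dtype=float)
    x2 = matrix[control].to_numpy(dtype=float)
    lfc = x1.mean(axis=1) - x2.mean(axis=1)
    d = n1 + n2 - 2
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x2 - x2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s_sq = ss / d

    if prior_df is None:
        d0, s0_sq = _fit_variance_prior(s_sq, d)
    elif prior_df == 0:
        d0, s0_sq = 0.0, 1.0  # s0 unused at weight 0
    else:
        d0 = float(prior_df)
        _, s0_sq = _fit_variance_prior(s_sq, d)

    if np.isinf(d0):
        post_var = np.full_like(s_sq, s0_sq)
        df_total = np.inf
    else:
        post_var = (d0 * s0_sq + d * s_sq) / (d0 + d)
        df_total = d0 + d

    se = np.sqrt(post_var * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(se > 0, lfc / se, 0.0)
    if np.isinf(df_total):
        p_raw = 2.0 * stats.norm.sf(np.abs(t_stat))
    else:
        p_raw = 2.0 * stats.t.sf(np.abs(t_stat), df=df_total)
    p_raw = np.clip(p_raw, np.nextafter(0, 1), 1.0)

    table = pd.DataFrame(
        {
            "base_mean": matrix.to_numpy(dtype=float).mean(axis=1),
            "log2FC": lfc,
            "p_raw": p_raw,
            "p_adj": bh_adjust(p_raw),
        },
        index=matrix.index.rename("feature_id"),
    )
    hyper = ModeratedTestHyper(
        d0=d0 if d0 > 0 else _TRIGAMMA_EPS, s0_sq=float(s0_sq), d=d
    )
    return table, hyper


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D array of p-values")
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adjusted, 0.0, 1.0)
    return out


def annotate_directions(
    table: pd.DataFrame,
    mode: str,
    *,
    fdr: float = 0.05,
    lfc: float = 1.0,
    mirna_p: float = 0.01,
) -> pd.DataFrame:
    """Add a ``direction`` column (up/down/ns) under the platform rule."""
    table = table.copy()
    if mode == "gene":
        significant = (table["p_adj"] < fdr) & (table["log2FC"].abs() > lfc)
    elif mode == "mirna":
        significant = table["p_raw"] < mirna_p
    else:
        raise ValueError("mode must be 'gene' or 'mirna'")
    table["direction"] = np.where(
        significant & (table["log2FC"] > 0),
        "up",
        np.where(significant & (table["log2FC"] < 0), "down", "ns"),
    )
    return table


def select_de(
    table: pd.DataFrame,
    mode: str,
    *,
    fdr: float = 0.05,
    lfc: float = 1.0,
    mirna_p: float = 0.01,
) -> tuple[list[str], list[str]]:
    """Split significant features into (up, down) ID lists.

    Gene mode requires BH-adjusted p strictly below ``fdr`` and |log2FC|
    strictly above ``lfc``; miRNA mode requires raw p strictly below
    ``mirna_p`` with no fold-change cut-off.
    """
    annotated = annotate_directions(table, mode, fdr=fdr, lfc=lfc, mirna_p=mirna_p)
    up = annotated.index[annotated["direction"] == "up"].tolist()
    down = annotated.index[annotated["direction"] == "down"].tolist()
    return up, down


def ddct_fold_change(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative qPCR fold change by the 2^-ddCt method.

    Reference Ct values may be means over several normalizer assays.
    """
    delta_case = ct_target_case - ct_ref_case
    delta_control = ct_target_control - ct_ref_control
    return float(2.0 ** -(delta_case - delta_control))


def sample_qc(matrix: pd.DataFrame, top_n: int = 20) -> QCReport:
    """PCA, sample-to-sample distances, clustering order and outlier flags.

    Outliers are samples whose median Euclidean distance to the others
    strictly exceeds Q3 + 1.5 IQR of all samples' median distances.
    """
    matrix = _as_matrix(matrix)
    samples = list(matrix.columns)
    if len(samples) < 3:
        raise ValueError("sample QC needs at least 3 samples")
    values = matrix.to_numpy(dtype=float)
    centered = values - values.mean(axis=1, keepdims=True)

    # PCA of samples: right singular vectors of the feature-centered matrix
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    total = float((s**2).sum())
    n_pc = min(2, len(s))
    coords = np.zeros((len(samples), 2))
    var_exp = np.zeros(2)
    for i in range(n_pc):
        loading = u[:, i]
        sign = 1.0 if loading[np.argmax(np.abs(loading))] >= 0 else -1.0
        coords[:, i] = sign * s[i] * vt[i]
        var_exp[i] = (s[i] ** 2) / total if total > 0 else 0.0

    dist_condensed = pdist(values.T, metric="euclidean")
    dist = squareform(dist_condensed)
    dist_df = pd.DataFrame(dist, index=samples, columns=samples)

    if np.all(dist_condensed == 0):
        order = list(samples)
        outliers: list[str] = []
    else:
        order = [samples[i] for i in leaves_list(linkage(dist_condensed, "average"))]
        medians = np.array(
            [np.median(np.delete(dist[i], i)) for i in range(len(samples))]
        )
        q1, q3 = np.percentile(medians, [25, 75])
        cutoff = q3 + 1.5 * (q3 - q1)
        outliers = [samples[i] for i in np.flatnonzero(medians > cutoff)]

    top = (
        pd.Series(values.mean(axis=1), index=matrix.index, name="mean_expression")
        .sort_values(ascending=False)
        .head(top_n)
    )
    return QCReport(
        pca_coordinates=pd.DataFrame(coords, index=samples, columns=["PC1", "PC2"]),
        variance_explained=var_exp,
        distance_matrix=dist_df,
        dendrogram_order=order,
        outliers=outliers,
        top_features=top,
    )
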