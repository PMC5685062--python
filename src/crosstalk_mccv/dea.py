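"""Per-gene differential expression with an empirical-Bayes moderated t-test.

The statistic is the standard limma-style moderated t (Smyth 2004): per-gene
pooled variances s_g^2 with d = n1 + n2 - 2 residual degrees of freedom are
shrunk towards a common prior variance s0^2 estimated, together with its
prior degrees of freedom d0, by moment-matching the log pooled variances to
a scaled log-F distribution.  The posterior variance

    s~_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)

replaces s_g^2 in the two-sample t statistic, which is referred to a
Student t distribution with d0 + d degrees of freedom.  With d0 = 0 the
statistic reduces exactly to the ordinary pooled-variance t-test; with
d0 = inf every gene uses the common variance s0^2 and a normal reference.

Genes are called differentially expressed (DEGs) when |log2FC| exceeds a
fold-change cut-off and the Benjamini-Hochberg adjusted p-value falls below
an FDR cut-off (defaults 1 and 0.05).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io_data import ExpressionMatrix, SampleLabels


class DegenerateVarianceError(ValueError):
    """All pooled variances are zero; the moderated t is undefined."""


@dataclass(frozen=True)
class GeneStats:
    """Per-gene group means, log2 fold change and pooled variance.

    ``log2fc`` is case minus control on the already-log2 scale; ``s2`` is
    the pooled two-sample variance with ``df = n_case + n_control - 2``.
    """

    genes: pd.Index
    mean_case: np.ndarray
    mean_control: np.ndarray
    log2fc: np.ndarray
    s2: np.ndarray
    df: int
    n_case: int
    n_control: int


@dataclass(frozen=True)
class ModeratedTParams:
    """Estimated shrinkage hyperparameters: prior df d0 and prior variance s0^2."""

    prior_df: float  # may be math.inf
    prior_var: float


def group_stats(expr: ExpressionMatrix, labels: SampleLabels) -> GeneStats:
    """Compute per-gene means, log2FC and pooled variance between groups."""
    labels.validate_against(expr)
    case_ids = [s for s in expr.sample_ids if labels.groups.get(s) == "case"]
    control_ids = [s for s in expr.sample_ids if labels.groups.get(s) == "control"]
    n1, n2 = len(case_ids), len(control_ids)
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"need >=2 samples per group for a pooled variance, got {n1} case / "
            f"{n2} control"
        )
    case = expr.frame[case_ids].to_numpy()
    control = expr.frame[control_ids].to_numpy()
    mean_case = case.mean(axis=1)
    mean_control = control.mean(axis=1)
    var_case = case.var(axis=1, ddof=1)
    var_control = control.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    s2 = ((n1 - 1) * var_case + (n2 - 1) * var_control) / df
    return GeneStats(
        genes=expr.frame.index,
        mean_case=mean_case,
        mean_control=mean_control,
        log2fc=mean_case - mean_control,
        s2=s2,
        df=df,
        n_case=n1,
        n_control=n2,
    )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (monotone decreasing, bracketed root)."""
    if x <= 0:
        raise ValueError("trigamma inverse requires x > 0")
    trigamma = lambda y: float(special.polygamma(1, y))
    lo, hi = 1e-8, 1e8
    # widen the bracket if needed; trigamma(lo) is huge, trigamma(hi) ~ 1/hi
    while trigamma(hi) > x:
        hi *= 10
    while trigamma(lo) < x:
        lo /= 10
    from scipy.optimize import brentq

    return float(brentq(lambda y: trigamma(y) - x, lo, hi, xtol=1e-12, rtol=1e-14))


def estimate_prior(s2: np.ndarray, df: int) -> ModeratedTParams:
    """Moment-match log pooled variances to a scaled F to get (d0, s0^2).

    Under the hierarchical model s_g^2 ~ s0^2 F(d, d0), the log variance has
    mean log s0^2 + psi(d/2) - log(d/2) - psi(d0/2) + log(d0/2) and variance
    psi'(d/2) + psi'(d0/2).  An excess variance of log s_g^2 over psi'(d/2)
    identifies d0 through the trigamma inverse.  A non-positive excess means
    the variances scatter less than chi-square sampling alone would produce;
    the prior is then a point mass (d0 = inf) at the geometric mean of the
    variances, so a constant-variance ensemble is an exact fixed point of
    the shrinkage.  Non-positive variances are excluded from the moment fit.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise DegenerateVarianceError("all pooled variances are zero")
    if positive.size < 2:
        return ModeratedTParams(prior_df=math.inf, prior_var=float(positive.mean()))
    z = np.log(positive)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    n = e.size
    e_mean = float(e.mean())
    e_var = float(((e - e_mean) ** 2).sum() / (n - 1))
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0 or not math.isfinite(excess):
        return ModeratedTParams(prior_df=math.inf, prior_var=float(math.exp(z.mean())))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = math.exp(
        e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
    )
    return ModeratedTParams(prior_df=d0, prior_var=s0_sq)


def moderated_t_test(
    stats_: GeneStats, prior_df: float | None = None
) -> tuple[ModeratedTParams, np.ndarray]:
    """Moderated t-test for every gene; returns hyperparameters and raw p-values.

    Parameters
    ----------
    stats_
        Output of :func:`group_stats` over at least 10 genes.
    prior_df
        Override for d0.  ``0`` disables shrinkage (ordinary pooled t);
        ``math.inf`` forces the common-variance normal test; ``None``
        (default) estimates d0 from the variance ensemble.
    """
    s2 = np.asarray(stats_.s2, dtype=float)
    if s2.size < 10 and prior_df is None:
        raise ValueError("hyperparameter estimation needs >= 10 genes")
    if np.all(s2 == 0):
        raise DegenerateVarianceError("all pooled variances are zero")

    if prior_df is None:
        params = estimate_prior(s2, stats_.df)
    elif prior_df == 0:
        params = ModeratedTParams(prior_df=0.0, prior_var=float("nan"))
    elif math.isinf(prior_df):
        params = ModeratedTParams(
            prior_df=math.inf, prior_var=float(estimate_prior(s2, stats_.df).prior_var)
        )
    else:
        params = ModeratedTParams(
            prior_df=float(prior_df),
            prior_var=float(estimate_prior(s2, stats_.df).prior_var),
        )

    d = stats_.df
    if params.prior_df == 0:
        post_var = s2
        total_df = d
    elif math.isinf(params.prior_df):
        post_var = np.full_like(s2, params.prior_var)
        total_df = math.inf
    else:
        d0 = params.prior_df
        post_var = (d0 * params.prior_var + d * s2) / (d0 + d)
        total_df = d0 + d

    se = np.sqrt(post_var * (1.0 / stats_.n_case + 1.0 / stats_.n_control))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, stats_.log2fc / se, np.where(stats_.log2fc == 0, 0.0, np.inf))
    if math.isinf(total_df):
        raw_p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        raw_p = 2.0 * stats.t.sf(np.abs(t), total_df)
    return params, raw_p


def benjamini_hochberg(raw_p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(raw_p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def deg_table(
    stats_: GeneStats,
    raw_p: np.ndarray,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Assemble the per-gene DEG table and apply the DEG filter.

    A gene is a DEG iff |log2FC| > ``lfc_threshold`` and BH-FDR <
    ``fdr_threshold``.  Returns a DataFrame indexed by gene with columns
    ``log2fc``, ``raw_p``, ``fdr``, ``is_deg``, in input gene order.
    """
    if lfc_threshold <= 0 or fdr_threshold <= 0:
        raise ValueError("thresholds must be > 0")
    fdr = benjamini_hochberg(raw_p)
    df = pd.DataFrame(
        {
            "log2fc": stats_.log2fc,
            "raw_p": raw_p,
            "fdr": fdr,
            "is_deg": (np.abs(stats_.log2fc) > lfc_threshold) & (fdr < fdr_threshold),
        },
        index=stats_.genes,
    )
    df.index.name = "gene"
    return df


def deg_list(table: pd.DataFrame) -> list[str]:
    """DEG gene IDs sorted by FDR ascending, ties broken by gene ID."""
    hits = table[table["is_deg"]]
    hits = hits.sort_values(by="fdr", kind="mergesort")
    order = sorted(zip(hits["fdr"], hits.index))
    return [g for _, g in order]


def apply_deg_filter(
    log2fc: np.ndarray,
    fdr: np.ndarray,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> np.ndarray:
    """The bare DEG filter: |log2FC| > cut and FDR < cut (boolean vector)."""
    return (np.abs(np.asarray(log2fc)) > lfc_threshold) & (
        np.asarray(fdr) < fdr_threshold
    )


def run_dea(
    expr: ExpressionMatrix,
    labels: SampleLabels,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Full differential-expression stage: stats, moderated t, BH, filter."""
    stats_ = group_stats(expr, labels)
    _, raw_p = moderated_t_test(stats_, prior_df=prior_df)
    return deg_table(stats_, raw_p, lfc_threshold, fdr_threshold)
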