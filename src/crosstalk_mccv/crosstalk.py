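"""Pathway-pair activity features and the discriminating score (DS).

For every unordered pair of enriched pathways, each sample gets a pathway
"activity" — the mean log2 expression over the pathway's representative
genes (by default, its members that are DEGs; optionally all members
present in the matrix) — and a difference feature

    f_s = activity_A(s) - activity_B(s).

The pair-level discriminating score is the Orsetti-style signal-to-noise
statistic on f between the two groups::

    DS = |mean_case(f) - mean_control(f)| / (sd_case(f) + sd_control(f))

with sample standard deviations (n - 1 denominator).  A larger DS means
the joint activity pattern of the pair differs more between groups.  When
both group standard deviations vanish, DS is 0 for equal means and a large
sentinel otherwise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_data import ExpressionMatrix, GeneSetCollection, SampleLabels

logger = logging.getLogger(__name__)

#: DS reported when the means differ but both group SDs are exactly zero
DS_SENTINEL = 1e6


class EmptyPathwayError(ValueError):
    """A pathway has no representative genes in the expression matrix."""


def pathway_activity(
    expr: ExpressionMatrix, genes: Iterable[str], name: str = "<pathway>"
) -> pd.Series:
    """Per-sample mean log2 expression over the pathway's genes.

    Only genes present in the matrix contribute; an empty intersection
    raises :class:`EmptyPathwayError` naming the pathway.
    """
    present = [g for g in expr.gene_ids if g in set(genes)]
    if not present:
        raise EmptyPathwayError(
            f"pathway {name!r} has no representative genes in the matrix"
        )
    return expr.frame.loc[present].mean(axis=0)


@dataclass(frozen=True)
class PairFeatures:
    """Per-sample features for one canonical pathway pair (a < b)."""

    pathway_a: str
    pathway_b: str
    activity_a: pd.Series
    activity_b: pd.Series

    @property
    def pair(self) -> tuple[str, str]:
        return (self.pathway_a, self.pathway_b)

    @property
    def diff(self) -> pd.Series:
        """Difference feature f_s = activity_a - activity_b."""
        return self.activity_a - self.activity_b

    def feature_matrix(self, sample_ids: Sequence[str], mode: str = "both") -> np.ndarray:
        """Sample x feature matrix for the classifier.

        ``mode="both"`` gives two columns (activity_a, activity_b);
        ``mode="diff"`` gives the single difference column.
        """
        if mode == "both":
            return np.column_stack(
                [self.activity_a[list(sample_ids)], self.activity_b[list(sample_ids)]]
            )
        if mode == "diff":
            return self.diff[list(sample_ids)].to_numpy()[:, None]
        raise ValueError(f"unknown feature mode {mode!r}")


def representative_genes(
    pathway_members: Iterable[str],
    degs: Iterable[str] | None,
    matrix_genes: Iterable[str],
    restrict_to_degs: bool = True,
) -> set[str]:
    """Genes representing a pathway: members ∩ DEGs by default, or all
    members present in the matrix when ``restrict_to_degs`` is off."""
    members = set(pathway_members) & set(matrix_genes)
    if restrict_to_degs:
        if degs is None:
            raise ValueError("restrict_to_degs=True requires a DEG list")
        return members & set(degs)
    return members


def pair_feature_matrix(
    expr: ExpressionMatrix,
    selected_pathways: Sequence[str],
    sets: GeneSetCollection,
    degs: Iterable[str] | None = None,
    restrict_to_degs: bool = True,
) -> list[PairFeatures]:
    """Build features for every unordered pair of usable selected pathways.

    A pathway is usable when its representative gene set is non-empty.
    Pairs are canonicalised (a < b lexicographically); pairs whose two
    representative sets coincide are kept (their difference feature is
    identically zero) and logged.  Raises if fewer than two pathways are
    usable.
    """
    matrix_genes = set(expr.gene_ids)
    activities: dict[str, pd.Series] = {}
    for name in selected_pathways:
        reps = representative_genes(sets[name], degs, matrix_genes, restrict_to_degs)
        if not reps:
            logger.info("pathway %r has no representative genes; skipped", name)
            continue
        activities[name] = pathway_activity(expr, reps, name)
    if len(activities) < 2:
        raise EmptyPathwayError(
            f"need >= 2 usable pathways for pair features, got {len(activities)}"
        )
    reps_cache = {
        name: representative_genes(sets[name], degs, matrix_genes, restrict_to_degs)
        for name in activities
    }
    pairs = []
    for a, b in combinations(sorted(activities), 2):
        if reps_cache[a] == reps_cache[b]:
            logger.info("pair (%s, %s) has identical representative sets", a, b)
        pairs.append(
            PairFeatures(
                pathway_a=a,
                pathway_b=b,
                activity_a=activities[a],
                activity_b=activities[b],
            )
        )
    return pairs


def discriminating_score(
    f: pd.Series | np.ndarray,
    labels: SampleLabels,
    sample_ids: Sequence[str] | None = None,
    sentinel: float = DS_SENTINEL,
) -> float:
    """Orsetti-style signal-to-noise DS of the difference feature *f*.

    ``f`` is indexed by sample (a Series, or an array aligned with
    *sample_ids*).  Requires >= 2 samples per group.
    """
    if isinstance(f, pd.Series):
        series = f
    else:
        if sample_ids is None:
            raise ValueError("sample_ids required when f is a bare array")
        series = pd.Series(np.asarray(f, dtype=float), index=list(sample_ids))
    case = series[[s for s in series.index if labels.groups.get(s) == "case"]]
    control = series[[s for s in series.index if labels.groups.get(s) == "control"]]
    if len(case) < 2 or len(control) < 2:
        raise ValueError(
            f"need >= 2 samples per group, got {len(case)} case / "
            f"{len(control)} control"
        )
    delta = abs(case.mean() - control.mean())
    spread = case.std(ddof=1) + control.std(ddof=1)
    if spread == 0:
        if np.isclose(delta, 0.0):
            return 0.0
        warnings.warn(
            "zero within-group spread with unequal means; DS set to sentinel",
            RuntimeWarning,
            stacklevel=2,
        )
        return sentinel
    return float(delta / spread)


def pair_ds_table(
    pairs: Sequence[PairFeatures], labels: SampleLabels
) -> pd.DataFrame:
    """DS for every pair, as a DataFrame (pathway_a, pathway_b, ds)."""
    rows = [
        (p.pathway_a, p.pathway_b, discriminating_score(p.diff, labels))
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=["pathway_a", "pathway_b", "ds"])
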