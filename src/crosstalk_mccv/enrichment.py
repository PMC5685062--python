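"""Over-representation analysis of DEGs in pathway gene sets.

Each pathway is tested with the one-sided hypergeometric tail (Fisher exact
test for enrichment): with a background of N genes, a pathway covering K of
them, and n DEGs of which x fall in the pathway, the p-value is
P(X >= x) for X ~ Hypergeometric(N, K, n).  Pathways are retained when the
raw p-value is below ``p_threshold`` (default 0.01) and the BH-adjusted
p-value is below ``fdr_threshold`` (default 0.05).

The background is the set of genes present in the analysed expression
matrix; pathways with no background overlap are untestable and dropped.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .dea import benjamini_hochberg
from .io_data import GeneSetCollection

logger = logging.getLogger(__name__)


class EmptyDEGError(ValueError):
    """No DEGs supplied — relax the DEG thresholds or treat as degenerate."""


def hypergeom_tail(x: int, K: int, n: int, N: int) -> float:
    """Upper hypergeometric tail P(X >= x), X ~ Hypergeometric(N, K, n).

    ``N`` background genes of which ``K`` are in the pathway; ``n`` draws
    (DEGs) of which ``x`` land in the pathway.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not (0 <= x <= min(K, n)):
        raise ValueError(f"overlap x={x} outside [0, min(K={K}, n={n})]")
    if x == 0:
        return 1.0
    # survival function at x-1; scipy evaluates the tail in log-space internally
    return float(stats.hypergeom.sf(x - 1, N, K, n))


def enrich_pathways(
    degs: Iterable[str],
    sets: GeneSetCollection,
    background: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric enrichment of every pathway against the DEG list.

    Returns one row per testable pathway (background overlap K >= 1) with
    columns ``pathway_size`` (K), ``overlap`` (x), ``raw_p`` and ``fdr``
    (BH across tested pathways), indexed by pathway name in collection
    order.  Pathways with K = 0 are dropped and logged.
    """
    deg_set = set(degs)
    bg = set(background)
    if not deg_set:
        raise EmptyDEGError(
            "no DEGs to test for enrichment; relax the DEG thresholds"
        )
    stray = deg_set - bg
    if stray:
        raise ValueError(
            f"DEGs absent from background: {sorted(stray)[:5]}"
        )
    N, n = len(bg), len(deg_set)
    rows = []
    for name in sets.names:
        members = sets[name] & bg
        K = len(members)
        if K == 0:
            logger.info("pathway %r has no background overlap; dropped", name)
            continue
        x = len(members & deg_set)
        rows.append((name, K, x, hypergeom_tail(x, K, n, N)))
    if not rows:
        return pd.DataFrame(
            columns=["pathway_size", "overlap", "raw_p", "fdr"]
        ).rename_axis("pathway")
    df = pd.DataFrame(
        rows, columns=["pathway", "pathway_size", "overlap", "raw_p"]
    ).set_index("pathway")
    df["fdr"] = benjamini_hochberg(df["raw_p"].to_numpy())
    return df


def select_pathways(
    records: pd.DataFrame,
    p_threshold: float = 0.01,
    fdr_threshold: float = 0.05,
) -> list[str]:
    """Pathways with raw p < ``p_threshold`` and FDR < ``fdr_threshold``.

    Sorted by FDR ascending, ties broken by pathway name.
    """
    hits = records[
        (records["raw_p"] < p_threshold) & (records["fdr"] < fdr_threshold)
    ]
    order = sorted(zip(hits["fdr"], hits.index))
    return [name for _, name in order]
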