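"""Monte Carlo cross-validation driver and cross-iteration aggregation.

Each iteration draws a stratified 60/40 train/test split, reruns the whole
pipeline on the training portion — differential expression, pathway
enrichment, pair features and discriminating scores, per-pair random-forest
CV AUC — keeps the top-k pairs, and validates them on the held-out portion.
After ``n_iterations`` draws (default 50) the pairs appearing in at least
``min_occurrence`` top-k lists (default 3) form the final report, carrying
their occurrence counts and mean CV / validation AUCs.

Iterations that degenerate statistically (no DEGs, fewer than two usable
pathways, unbuildable folds) are recorded and skipped, keeping the
occurrence denominator honest; only I/O and configuration errors raise.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import crosstalk, dea, enrichment, pair_ranking
from .io_data import (
    AggregateReport,
    ExpressionMatrix,
    GeneSetCollection,
    SampleLabels,
)

logger = logging.getLogger(__name__)


class MCCVError(RuntimeError):
    """The Monte Carlo run cannot produce a report (no usable iterations)."""


@dataclass(frozen=True)
class MCCVConfig:
    """Settings of the Monte Carlo cross-validation loop.

    Defaults follow the study design the pipeline targets: 50 iterations of
    a stratified 60/40 split, top-10 pairs per iteration, pairs kept in the
    final report when they occur in >= 3 iterations; DEG thresholds
    |log2FC| > 1 and FDR < 0.05; pathway thresholds p < 0.01 and
    FDR < 0.05.
    """

    n_iterations: int = 50
    train_fraction: float = 0.6
    top_k: int = 10
    min_occurrence: int = 3
    master_seed: int = 0
    lfc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    pathway_p_threshold: float = 0.01
    pathway_fdr_threshold: float = 0.05
    restrict_to_degs: bool = True
    feature_mode: str = "both"  # "both" activities or single "diff" column
    rf: pair_ranking.RFConfig = field(default_factory=pair_ranking.RFConfig)

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not (1 <= self.min_occurrence <= self.n_iterations):
            raise ValueError("min_occurrence must lie in [1, n_iterations]")
        if self.feature_mode not in ("both", "diff"):
            raise ValueError("feature_mode must be 'both' or 'diff'")


@dataclass(frozen=True)
class IterationResult:
    """Outcome of one Monte Carlo iteration."""

    index: int
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    status: str  # "ok" or "degenerate"
    reason: str = ""
    deg_genes: tuple[str, ...] = ()
    selected_pathways: tuple[str, ...] = ()
    top_pairs: tuple[pair_ranking.PairScore, ...] = ()

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_split(
    labels: SampleLabels, train_fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Per-group random split: round(train_fraction * n_group) samples train.

    Rounding is half-up (60% of 16 gives 10 train / 6 test per group).
    Both portions must keep >= 2 samples per group.  Deterministic under
    *seed*.
    """
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for group_ids in (labels.case_ids, labels.control_ids):
        n = len(group_ids)
        n_train = _round_half_up(train_fraction * n)
        if n_train < 2 or n - n_train < 2:
            raise ValueError(
                f"split leaves a portion with < 2 samples in a group "
                f"(group size {n}, fraction {train_fraction})"
            )
        picked = rng.choice(n, size=n_train, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[picked] = True
        train.extend(g for g, m in zip(group_ids, mask) if m)
        test.extend(g for g, m in zip(group_ids, mask) if not m)
    return train, test


def run_iteration(
    expr: ExpressionMatrix,
    labels: SampleLabels,
    sets: GeneSetCollection,
    config: MCCVConfig,
    iteration_seed: int,
    index: int = 0,
) -> IterationResult:
    """One full pipeline pass on a fresh stratified split.

    The training portion alone drives DEG calling, enrichment and the
    choice of representative genes; pathway activities are then computed
    for all samples so the held-out portion can be scored without refit.
    Statistical degeneracies yield ``status="degenerate"`` with a reason.
    """
    seeds = np.random.SeedSequence(iteration_seed)
    split_seed, rf_root = [
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in seeds.spawn(2)
    ]
    train_ids, test_ids = stratified_split(labels, config.train_fraction, split_seed)
    base = dict(index=index, train_ids=tuple(train_ids), test_ids=tuple(test_ids))

    train_expr = expr.subset_samples(train_ids)
    train_labels = labels.subset(train_ids)

    table = dea.run_dea(
        train_expr, train_labels, config.lfc_threshold, config.fdr_threshold
    )
    degs = dea.deg_list(table)
    if not degs:
        return IterationResult(**base, status="degenerate", reason="no DEGs")

    records = enrichment.enrich_pathways(degs, sets, train_expr.gene_ids)
    selected = enrichment.select_pathways(
        records, config.pathway_p_threshold, config.pathway_fdr_threshold
    )
    if len(selected) < 2:
        return IterationResult(
            **base,
            status="degenerate",
            reason=f"only {len(selected)} enriched pathway(s)",
            deg_genes=tuple(degs),
        )

    try:
        pairs = crosstalk.pair_feature_matrix(
            expr, selected, sets, degs, restrict_to_degs=config.restrict_to_degs
        )
    except crosstalk.EmptyPathwayError as exc:
        return IterationResult(
            **base,
            status="degenerate",
            reason=str(exc),
            deg_genes=tuple(degs),
            selected_pathways=tuple(selected),
        )

    y_train = train_labels.is_case_vector(train_ids)
    test_labels = labels.subset(test_ids)
    y_test = test_labels.is_case_vector(test_ids)

    pair_seeds = np.random.SeedSequence(rf_root).spawn(len(pairs))
    scores: list[pair_ranking.PairScore] = []
    try:
        for feat, ps in zip(pairs, pair_seeds):
            seed = int(ps.generate_state(1)[0] % (2**31 - 1))
            rf = replace(config.rf, seed=seed)
            X_train = feat.feature_matrix(train_ids, config.feature_mode)
            auc = pair_ranking.cv_auc(X_train, y_train, rf)
            ds = crosstalk.discriminating_score(feat.diff, train_labels)
            scores.append(
                pair_ranking.PairScore(pair=feat.pair, cv_auc=auc, ds=ds)
            )
    except pair_ranking.FoldConstructionError as exc:
        return IterationResult(
            **base,
            status="degenerate",
            reason=str(exc),
            deg_genes=tuple(degs),
            selected_pathways=tuple(selected),
        )

    top = pair_ranking.rank_pairs(scores, config.top_k)
    by_pair = {feat.pair: feat for feat in pairs}
    validated: list[pair_ranking.PairScore] = []
    try:
        for s in top:
            feat = by_pair[s.pair]
            rf = replace(config.rf, seed=_pair_holdout_seed(rf_root, s.pair))
            v = pair_ranking.holdout_auc(
                feat.feature_matrix(train_ids, config.feature_mode),
                y_train,
                feat.feature_matrix(test_ids, config.feature_mode),
                y_test,
                rf,
            )
            validated.append(replace(s, validation_auc=v))
    except ValueError as exc:
        return IterationResult(
            **base,
            status="degenerate",
            reason=f"hold-out validation failed: {exc}",
            deg_genes=tuple(degs),
            selected_pathways=tuple(selected),
        )

    return IterationResult(
        **base,
        status="ok",
        deg_genes=tuple(degs),
        selected_pathways=tuple(selected),
        top_pairs=tuple(validated),
    )


def _pair_holdout_seed(rf_root: int, pair: tuple[str, str]) -> int:
    """Deterministic per-pair seed for the hold-out forest."""
    import zlib

    tag = zlib.crc32("|".join(pair).encode())
    return int((rf_root ^ tag) % (2**31 - 1))


def aggregate(
    results: list[IterationResult], min_occurrence: int
) -> AggregateReport:
    """Count top-k membership per pair across ok iterations and average AUCs.

    Pairs with occurrence >= ``min_occurrence`` are retained; mean AUCs are
    taken over the iterations that contributed the pair.
    """
    ok = [r for r in results if r.ok]
    if not ok:
        raise MCCVError("no successful Monte Carlo iterations to aggregate")
    cv: dict[tuple[str, str], list[float]] = defaultdict(list)
    val: dict[tuple[str, str], list[float]] = defaultdict(list)
    for r in ok:
        for s in r.top_pairs:
            cv[s.pair].append(s.cv_auc)
            if s.validation_auc is not None:
                val[s.pair].append(s.validation_auc)
    rows = [
        (
            a,
            b,
            len(cv[(a, b)]),
            float(np.mean(cv[(a, b)])),
            float(np.mean(val[(a, b)])) if val[(a, b)] else float("nan"),
        )
        for (a, b) in sorted(cv)
        if len(cv[(a, b)]) >= min_occurrence
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "pathway_a",
            "pathway_b",
            "occurrence_count",
            "mean_cv_auc",
            "mean_validation_auc",
        ],
    )
    return AggregateReport(df)


def count_partner_pathways(report: AggregateReport, pathway: str) -> int:
    """Number of distinct pathways paired with *pathway* in the report."""
    partners = set(
        report.rows.loc[report.rows["pathway_b"] == pathway, "pathway_a"]
    ) | set(report.rows.loc[report.rows["pathway_a"] == pathway, "pathway_b"])
    return len(partners)


@dataclass(frozen=True)
class MCCVRun:
    """Everything a full Monte Carlo run produced."""

    report: AggregateReport
    iterations: list[IterationResult]
    config: MCCVConfig

    @property
    def n_ok(self) -> int:
        return sum(r.ok for r in self.iterations)

    def best_pair(self) -> tuple[str, str] | None:
        """Retained pair with the highest mean CV AUC (None when empty)."""
        if not len(self.report):
            return None
        row = self.report.rows.sort_values(
            by=["mean_cv_auc", "pathway_a", "pathway_b"],
            ascending=[False, True, True],
            kind="mergesort",
        ).iloc[0]
        return (row["pathway_a"], row["pathway_b"])


def run_mccv(
    expr: ExpressionMatrix,
    labels: SampleLabels,
    sets: GeneSetCollection,
    config: MCCVConfig,
) -> MCCVRun:
    """Run the full Monte Carlo cross-validation loop.

    Iteration seeds are ``master_seed + index``; the whole run is
    bit-reproducible under a fixed master seed.
    """
    labels.validate_against(expr)
    results = []
    for i in range(config.n_iterations):
        result = run_iteration(
            expr, labels, sets, config, iteration_seed=config.master_seed + i, index=i
        )
        if not result.ok:
            logger.info("iteration %d degenerate: %s", i, result.reason)
        results.append(result)
    report = aggregate(results, config.min_occurrence)
    return MCCVRun(report=report, iterations=results, config=config)
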