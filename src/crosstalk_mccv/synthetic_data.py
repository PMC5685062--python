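"""Two-group expression simulator with planted differential pathways.

The generator emulates the statistical structure the downstream analysis
assumes: a balanced case/control cohort, gene-level log2-normal expression,
and a configurable subset of genes shifted between groups.  The shifted
(differentially expressed) genes are drawn from the members of designated
"planted" pathways, so that specific pathway pairs carry discriminative
signal and the whole pipeline — differential expression, enrichment,
pair features, classifier ranking, Monte Carlo aggregation — can be tested
end to end against a known ground truth.

Model for gene g in sample s (log2 scale)::

    value(g, s) = mu_g + delta * sign_g * 1[g planted and s is a case] + eps
    eps ~ Normal(0, sigma^2),  mu_g ~ Uniform(baseline_mean_range)

with sign_g drawn equiprobably from {-1, +1}, so half the planted genes go
up in cases and half go down — exercising the absolute-value side of the
|log2FC| filter.  All randomness flows from the single integer ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .io_data import (
    CASE,
    CONTROL,
    ExpressionMatrix,
    GeneSetCollection,
    SampleLabels,
)


class ConfigError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic two-group expression study.

    Defaults mirror a small blood-transcriptome case/control design:
    16 + 16 samples, 2,000 genes, 20 pathways of 15-40 members with two
    planted differential pathways, 20 shifted genes with a mean log2 shift
    of 4 against per-gene noise sigma = 0.5, and baselines uniform on
    log2-intensity range 6-12.
    """

    n_case: int = 16
    n_control: int = 16
    n_genes: int = 2000
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (15, 40)
    planted_pathways: tuple[str, ...] = ("PW001", "PW002")
    n_de_genes: int = 20
    effect_size: float = 4.0  # mean log2 shift delta
    gene_sd: float = 0.5  # per-gene noise sigma, log2 units
    baseline_mean_range: tuple[float, float] = (6.0, 12.0)
    gene_sd_jitter: float = 0.0  # optional per-gene sigma spread (lognormal scale)
    #: plant the first listed pathway up and the second down instead of random
    #: per-gene signs — an antagonistic pair whose activity *difference*
    #: (not just the joint pattern) separates the groups
    opposing_planted_signs: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ConfigError("need at least 2 samples per group")
        lo, hi = self.pathway_size_range
        if not (0 < lo <= hi <= self.n_genes):
            raise ConfigError(
                f"pathway_size_range {self.pathway_size_range} must satisfy "
                f"0 < min <= max <= n_genes ({self.n_genes})"
            )
        if self.n_pathways < 1:
            raise ConfigError("n_pathways must be >= 1")
        if self.n_de_genes < 0:
            raise ConfigError("n_de_genes must be >= 0")
        if self.gene_sd <= 0:
            raise ConfigError("gene_sd must be > 0")
        known = set(self.pathway_names())
        unknown = set(self.planted_pathways) - known
        if unknown:
            raise ConfigError(f"planted pathways not generated: {sorted(unknown)}")

    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def pathway_names(self) -> list[str]:
        width = max(3, len(str(self.n_pathways)))
        return [f"PW{i:0{width}d}" for i in range(1, self.n_pathways + 1)]


@dataclass(frozen=True)
class GroundTruth:
    """What the simulator planted: the shifted genes and the pathway pairs
    expected to discriminate (all unordered pairs of planted pathways)."""

    de_genes: frozenset[str]
    signal_pairs: frozenset[tuple[str, str]]
    de_signs: dict[str, int] = field(default_factory=dict)


def _rngs(config: SimulationConfig) -> tuple[np.random.Generator, np.random.Generator]:
    """Independent child streams (gene sets, expression) off the one seed."""
    children = np.random.SeedSequence(config.seed).spawn(2)
    return np.random.default_rng(children[0]), np.random.default_rng(children[1])


def generate_gene_sets(config: SimulationConfig) -> GeneSetCollection:
    """Draw ``n_pathways`` gene sets from the gene universe.

    Set sizes are uniform on ``pathway_size_range``; members are sampled
    without replacement within each set (overlap across sets is allowed).
    Deterministic under a fixed ``config.seed``.
    """
    rng, _ = _rngs(config)
    genes = np.array(config.gene_names())
    lo, hi = config.pathway_size_range
    sets: dict[str, frozenset[str]] = {}
    for name in config.pathway_names():
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        sets[name] = frozenset(members.tolist())
    return GeneSetCollection(sets, {name: "simulated pathway" for name in sets})


def simulate_expression(
    config: SimulationConfig, sets: GeneSetCollection
) -> tuple[ExpressionMatrix, SampleLabels, GroundTruth]:
    """Simulate the expression matrix, labels and ground truth.

    Differentially expressed genes are drawn without replacement from the
    union of the planted pathways' members; every unordered pair of planted
    pathways is recorded as a signal pair.
    """
    missing = [p for p in config.planted_pathways if p not in sets]
    if missing:
        raise ConfigError(f"planted pathways absent from collection: {missing}")
    planted_members = sorted(
        set().union(*(sets[p] for p in config.planted_pathways))
        if config.planted_pathways
        else set()
    )
    if config.n_de_genes > len(planted_members):
        raise ConfigError(
            f"n_de_genes={config.n_de_genes} exceeds planted-pathway membership "
            f"({len(planted_members)} genes)"
        )
    _, rng = _rngs(config)

    genes = config.gene_names()
    n_samples = config.n_case + config.n_control
    case_ids = [f"CASE{i:02d}" for i in range(1, config.n_case + 1)]
    control_ids = [f"CTRL{i:02d}" for i in range(1, config.n_control + 1)]
    sample_ids = case_ids + control_ids

    de_genes = [
        planted_members[i]
        for i in rng.choice(len(planted_members), config.n_de_genes, replace=False)
    ]
    if config.opposing_planted_signs and len(config.planted_pathways) >= 2:
        first = sets[config.planted_pathways[0]]
        signs = np.array([1 if g in first else -1 for g in de_genes])
        rng.choice([-1, 1], size=config.n_de_genes)  # keep stream position stable
    else:
        signs = rng.choice([-1, 1], size=config.n_de_genes)

    mu = rng.uniform(*config.baseline_mean_range, size=config.n_genes)
    sd = np.full(config.n_genes, config.gene_sd)
    if config.gene_sd_jitter > 0:
        sd = sd * rng.lognormal(0.0, config.gene_sd_jitter, size=config.n_genes)
    values = mu[:, None] + rng.normal(0.0, 1.0, (config.n_genes, n_samples)) * sd[:, None]

    gene_pos = {g: i for i, g in enumerate(genes)}
    for g, sign in zip(de_genes, signs):
        values[gene_pos[g], : config.n_case] += config.effect_size * sign

    frame = pd.DataFrame(values, index=genes, columns=sample_ids)
    labels = SampleLabels(
        {**{s: CASE for s in case_ids}, **{s: CONTROL for s in control_ids}}
    )
    truth = GroundTruth(
        de_genes=frozenset(de_genes),
        signal_pairs=frozenset(
            tuple(sorted(pair)) for pair in combinations(config.planted_pathways, 2)
        ),
        de_signs={g: int(s) for g, s in zip(de_genes, signs)},
    )
    return ExpressionMatrix(frame), labels, truth


def simulate_study(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleLabels, GeneSetCollection, GroundTruth]:
    """Convenience wrapper: gene sets plus expression in one call."""
    sets = generate_gene_sets(config)
    expr, labels, truth = simulate_expression(config, sets)
    return expr, labels, sets, truth


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Write the planted genes and signal pairs as a two-section TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("kind\tvalue\n")
        for g in sorted(truth.de_genes):
            sign = truth.de_signs.get(g, "")
            fh.write(f"de_gene\t{g}:{sign:+d}\n" if sign != "" else f"de_gene\t{g}\n")
        for a, b in sorted(truth.signal_pairs):
            fh.write(f"signal_pair\t{a}|{b}\n")


def write_study(
    config: SimulationConfig,
    out_dir,
    *,
    expression_name: str = "expression.tsv",
    labels_name: str = "labels.tsv",
    gmt_name: str = "pathways.gmt",
    truth_name: str = "ground_truth.tsv",
) -> dict[str, str]:
    """Simulate a study and write the four files to *out_dir*."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    expr, labels, sets, truth = simulate_study(config)
    paths = {
        "expression": os.path.join(out_dir, expression_name),
        "labels": os.path.join(out_dir, labels_name),
        "gmt": os.path.join(out_dir, gmt_name),
        "ground_truth": os.path.join(out_dir, truth_name),
    }
    expr.frame.to_csv(paths["expression"], sep="\t", index_label="gene")
    with open(paths["labels"], "w", encoding="utf-8") as fh:
        for s, g in labels.groups.items():
            fh.write(f"{s}\t{g}\n")
    with open(paths["gmt"], "w", encoding="utf-8") as fh:
        for name in sets.names:
            desc = sets.descriptions.get(name, "")
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")
    write_ground_truth(truth, paths["ground_truth"])
    return paths
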