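"""Readers, writers and validated containers for the pipeline's on-disk formats.

Four formats are touched: a genes x samples expression matrix (TSV, log2
scale), a two-column sample-label table (TSV), gene sets (GMT) and the
aggregated cross-talk report (TSV).  Everything is tab-delimited UTF-8;
trailing blank lines are ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"

#: default mapping of label-file tokens onto the canonical group names
DEFAULT_GROUP_ALIASES: dict[str, str] = {CASE: CASE, CONTROL: CONTROL}


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(ValueError):
    """Parsed content violates a container invariant."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x sample matrix of log2 expression intensities.

    Parameters
    ----------
    frame
        DataFrame indexed by gene symbol with one column per sample ID.
        Gene and sample IDs must be unique, all values finite, and the
        matrix at least 2 x 2.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        if f.shape[0] < 2 or f.shape[1] < 2:
            raise ValidationError(
                f"expression matrix must be at least 2x2, got {f.shape}"
            )
        if f.index.has_duplicates:
            dup = f.index[f.index.duplicated()][0]
            raise ValidationError(f"duplicate gene ID {dup!r}")
        if f.columns.has_duplicates:
            dup = f.columns[f.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample ID {dup!r}")
        values = f.to_numpy()
        if not np.issubdtype(values.dtype, np.number) or not np.all(
            np.isfinite(values)
        ):
            raise ValidationError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.frame.shape[0]

    @property
    def n_samples(self) -> int:
        return self.frame.shape[1]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        """Restrict to the given samples, preserving the given order."""
        ids = list(sample_ids)
        missing = set(ids) - set(self.frame.columns)
        if missing:
            raise ValidationError(f"unknown sample IDs: {sorted(missing)}")
        return ExpressionMatrix(self.frame[ids])


@dataclass(frozen=True)
class SampleLabels:
    """Mapping of sample ID to group, canonically ``case`` or ``control``."""

    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {g for g in self.groups.values() if g not in (CASE, CONTROL)}
        if bad:
            raise ValidationError(f"unknown group tokens: {sorted(bad)}")
        if not self.case_ids or not self.control_ids:
            raise ValidationError("both case and control groups must be non-empty")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.groups)

    @property
    def case_ids(self) -> list[str]:
        return [s for s, g in self.groups.items() if g == CASE]

    @property
    def control_ids(self) -> list[str]:
        return [s for s, g in self.groups.items() if g == CONTROL]

    def subset(self, sample_ids: Iterable[str]) -> "SampleLabels":
        ids = list(sample_ids)
        missing = set(ids) - set(self.groups)
        if missing:
            raise ValidationError(f"unlabelled sample IDs: {sorted(missing)}")
        return SampleLabels({s: self.groups[s] for s in ids})

    def is_case_vector(self, sample_ids: Iterable[str]) -> np.ndarray:
        """Boolean vector (True = case) in the order of *sample_ids*."""
        return np.array([self.groups[s] == CASE for s in sample_ids], dtype=bool)

    def validate_against(self, expr: ExpressionMatrix) -> None:
        """Check every labelled sample exists in the matrix."""
        missing = set(self.groups) - set(expr.sample_ids)
        if missing:
            raise ValidationError(
                f"labelled samples absent from expression matrix: {sorted(missing)}"
            )


@dataclass(frozen=True)
class GeneSetCollection:
    """Named pathway gene sets with optional per-set descriptions."""

    sets: Mapping[str, frozenset[str]]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets


REPORT_COLUMNS = [
    "pathway_a",
    "pathway_b",
    "occurrence_count",
    "mean_cv_auc",
    "mean_validation_auc",
]


@dataclass(frozen=True)
class AggregateReport:
    """Final cross-iteration report: one row per retained pathway pair.

    Rows carry the canonical pair (``pathway_a < pathway_b``), the number
    of Monte Carlo iterations whose top-k list contained the pair, and the
    mean cross-validated / held-out validation AUCs over those iterations.
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.rows
        missing = [c for c in REPORT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"report missing columns: {missing}")
        if len(df) and not (df["pathway_a"] < df["pathway_b"]).all():
            raise ValidationError("pairs must be canonical (pathway_a < pathway_b)")
        if len(df) and (df["occurrence_count"] < 1).any():
            raise ValidationError("occurrence_count must be >= 1")
        for col in ("mean_cv_auc", "mean_validation_auc"):
            if len(df) and not df[col].between(0.0, 1.0).all():
                raise ValidationError(f"{col} must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.rows)

    def sorted_rows(self) -> pd.DataFrame:
        """Rows in report order: occurrence desc, CV AUC desc, pair name asc."""
        return self.rows.sort_values(
            by=["occurrence_count", "mean_cv_auc", "pathway_a", "pathway_b"],
            ascending=[False, False, True, True],
            kind="mergesort",
        ).reset_index(drop=True)


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first row sample IDs, first column gene IDs).

    Duplicate gene rows are collapsed by per-sample mean (logged); a
    malformed numeric cell raises :class:`FormatError` naming the offending
    gene and sample.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").rstrip("\r").split("\t")
    samples = header[1:]
    seen: set[str] = set()
    for s in samples:
        if s in seen:
            raise ValidationError(f"duplicate sample ID {s!r} in {path}")
        seen.add(s)
    raw = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False, na_values=[]
    )
    raw.index = raw.index.astype(str)
    raw.columns = samples
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & (raw != "")
    if bad.to_numpy().any():
        gene = bad.index[bad.any(axis=1)][0]
        sample = bad.columns[bad.loc[gene]][0]
        raise FormatError(
            f"non-numeric cell {raw.loc[gene, sample]!r} at gene {gene!r}, "
            f"sample {sample!r} in {path}"
        )
    if numeric.isna().to_numpy().any():
        raise FormatError(f"empty cell in {path}")
    if numeric.index.has_duplicates:
        n_dup = int(numeric.index.duplicated().sum())
        logger.info("collapsing %d duplicate gene rows by mean", n_dup)
        order = numeric.index.drop_duplicates()
        numeric = numeric.groupby(level=0, sort=False).mean().loc[order]
    return ExpressionMatrix(numeric)


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets in GMT format: name TAB description TAB gene TAB gene ..."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate pathway {name!r}")
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def read_labels(path, aliases: Mapping[str, str] | None = None) -> SampleLabels:
    """Read a two-column sample_id TAB group TSV.

    Group tokens are normalised to ``case``/``control`` through *aliases*
    (e.g. ``{"AS": "case", "normal": "control"}``); matching falls back to
    the lower-cased token.
    """
    alias_map = dict(DEFAULT_GROUP_ALIASES)
    if aliases:
        for token, target in aliases.items():
            if target not in (CASE, CONTROL):
                raise ValidationError(
                    f"alias target must be 'case' or 'control', got {target!r}"
                )
            alias_map[token] = target
    groups: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, "
                    f"got {len(fields)}"
                )
            sample, token = fields
            if sample in groups:
                raise ValidationError(f"{path}:{lineno}: duplicate sample {sample!r}")
            group = alias_map.get(token, alias_map.get(token.lower()))
            if group is None:
                raise ValidationError(
                    f"{path}:{lineno}: unknown group token {token!r}"
                )
            groups[sample] = group
    return SampleLabels(groups)


def write_report(report: AggregateReport, path) -> None:
    """Write the aggregate report as TSV (header + one row per pair).

    Rows are sorted by occurrence count descending, then mean CV AUC
    descending, then pair name; ``read_report`` round-trips exactly.
    """
    report.sorted_rows().to_csv(path, sep="\t", index=False)


def read_report(path) -> AggregateReport:
    """Read a report written by :func:`write_report`."""
    df = pd.read_csv(path, sep="\t", dtype={"pathway_a": str, "pathway_b": str})
    return AggregateReport(df)
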