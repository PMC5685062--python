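"""Published reference tables bundled for bookkeeping checks.

Two small tables from a published ankylosing-spondylitis blood
transcriptome study (16 active patients vs 16 matched controls, Illumina
HT-12 v3 arrays, GEO accession GSE25101) ship with the package:

* ``as_deg_stats.tsv`` — the study's reported differentially expressed
  genes with their log2 fold changes and BH-adjusted p-values;
* ``as_top_pairs.tsv`` — the study's final pathway-pair list with the
  number of Monte Carlo iterations each pair occurred in.

They serve as fixed inputs for the DEG-filter and partner-count
bookkeeping operations; the pipeline itself runs on user or simulated
data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io_data import AggregateReport


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath("data", name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_published_deg_stats() -> pd.DataFrame:
    """Reported DEG statistics: columns ``gene``, ``log2fc``, ``fdr``."""
    return _read("as_deg_stats.tsv")


def load_published_pair_occurrences() -> AggregateReport:
    """Reported pathway-pair occurrence table as an :class:`AggregateReport`.

    The published table carries no AUC columns; means are filled with 1.0
    placeholders so the container validates — only the pair identities and
    occurrence counts are meaningful.
    """
    df = _read("as_top_pairs.tsv")
    df = df.assign(
        pathway_a=df[["pathway_a", "pathway_b"]].min(axis=1),
        pathway_b=df[["pathway_a", "pathway_b"]].max(axis=1),
        mean_cv_auc=1.0,
        mean_validation_auc=1.0,
    )
    return AggregateReport(df)
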