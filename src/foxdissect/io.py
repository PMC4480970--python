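"""Count-matrix container and tab-separated readers/writers.

The pipeline starts from a gene-by-sample matrix of integer read counts
(e.g. the output of a feature-counting step), a per-gene transcript length
(sum of non-overlapping exonic bases) and per-sample metadata giving the
biological condition and replicate of each library.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CountMatrix:
    """Integer read counts per gene per sample with lengths and metadata.

    Attributes
    ----------
    counts
        DataFrame, rows indexed by gene id, columns by sample id; integer,
        non-negative.
    gene_lengths
        Series indexed by gene id; positive transcript length in bases.
    metadata
        DataFrame indexed by sample id with columns ``condition`` and
        ``replicate``.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    metadata: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        counts = self.counts
        if (counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = counts.index.difference(self.gene_lengths.index)
        if len(missing):
            raise ValueError(f"{len(missing)} genes lack a transcript length")
        if (self.gene_lengths.loc[counts.index] <= 0).any():
            raise ValueError("gene lengths must be positive")
        self.gene_lengths = self.gene_lengths.loc[counts.index].astype(float)
        if self.metadata is not None:
            missing = counts.columns.difference(self.metadata.index)
            if len(missing):
                raise ValueError(f"samples without metadata: {list(missing)}")
            if "condition" not in self.metadata.columns:
                raise ValueError("metadata must have a 'condition' column")
            self.metadata = self.metadata.loc[counts.columns]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_of(self, condition: str) -> list[str]:
        """Sample ids belonging to one condition."""
        if self.metadata is None:
            raise ValueError("no metadata attached")
        sel = self.metadata["condition"] == condition
        if not sel.any():
            raise KeyError(f"unknown condition: {condition!r}")
        return list(self.metadata.index[sel])

    @property
    def conditions(self) -> list[str]:
        if self.metadata is None:
            return []
        return list(dict.fromkeys(self.metadata["condition"]))


def read_counts(counts_tsv: str, lengths_tsv: str, meta_tsv: str | None = None) -> CountMatrix:
    """Read a count matrix from TSV files.

    ``counts_tsv``: first column gene id, remaining columns one per sample.
    ``lengths_tsv``: two columns, gene id and length in bases.
    ``meta_tsv``: columns sample, condition, replicate.
    """
    counts = pd.read_csv(counts_tsv, sep="\t", index_col=0, comment="#")
    lengths = pd.read_csv(lengths_tsv, sep="\t", index_col=0, comment="#").iloc[:, 0]
    meta = None
    if meta_tsv is not None:
        meta = pd.read_csv(meta_tsv, sep="\t", index_col=0, comment="#")
    return CountMatrix(counts=counts.astype(np.int64), gene_lengths=lengths, metadata=meta)


def write_counts(cm: CountMatrix, counts_tsv: str, lengths_tsv: str, meta_tsv: str | None = None) -> None:
    """Write a :class:`CountMatrix` back to TSV (round-trips with :func:`read_counts`)."""
    cm.counts.to_csv(counts_tsv, sep="\t", index_label="gene")
    cm.gene_lengths.rename("length").to_csv(lengths_tsv, sep="\t", index_label="gene")
    if meta_tsv is not None and cm.metadata is not None:
        cm.metadata.to_csv(meta_tsv, sep="\t", index_label="sample")
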