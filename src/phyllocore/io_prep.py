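"""Tables, metadata and tree I/O plus deterministic preprocessing.

The exchange object for the whole pipeline is :class:`AbundanceTable`, a
samples x taxa matrix in either ``counts`` or ``relative`` mode.  Preprocessing
follows common amplicon practice: drop rare ASVs by dataset-wide total read
count, then rarefy every sample to a common depth by subsampling reads without
replacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

HABITATS = ("litter", "sphagnum", "soil")

__all__ = [
    "HABITATS",
    "AbundanceTable",
    "SampleMetadata",
    "read_abundance_table",
    "write_abundance_table",
    "read_sample_metadata",
    "read_tree",
    "filter_rare_asvs",
    "rarefy",
    "to_relative",
]


@dataclass
class AbundanceTable:
    """Samples x taxa abundance matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are samples, columns are taxa (ASVs). Non-negative.
    mode : {"counts", "relative"}
        In relative mode every non-empty row sums to 1 (tol 1e-9).
    """

    data: pd.DataFrame
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "relative"):
            raise ValueError(f"mode must be 'counts' or 'relative', got {self.mode!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon ids: {dups}")
        vals = self.data.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("abundance values must be numeric")
        if (vals < 0).any():
            raise ValueError("abundance table contains negative entries")
        if self.mode == "relative":
            sums = vals.sum(axis=1)
            bad = ~(np.isclose(sums, 1.0, atol=1e-9) | (sums == 0.0))
            if bad.any():
                raise ValueError(
                    "relative-mode rows must sum to 1 or 0; offending samples: "
                    f"{self.data.index[bad].tolist()}"
                )

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        return AbundanceTable(self.data.loc[list(sample_ids)].copy(), mode=self.mode)

    def subset_taxa(self, taxon_ids) -> "AbundanceTable":
        # a relative-mode slice no longer sums to 1, so renormalisation or a
        # counts-mode source is the caller's responsibility
        if self.mode == "relative":
            raise ValueError("subset taxa on the counts table, then renormalise")
        return AbundanceTable(self.data[list(taxon_ids)].copy(), mode=self.mode)


@dataclass
class SampleMetadata:
    """Per-sample habitat/site/plot labels and field covariates (pH, elevation)."""

    data: pd.DataFrame

    REQUIRED = ("habitat", "site", "plot", "pH", "elevation")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if self.data.index.has_duplicates:
            raise ValueError("metadata has duplicate sample ids")
        bad_hab = set(self.data["habitat"]) - set(HABITATS)
        if bad_hab:
            raise ValueError(f"unknown habitats {sorted(bad_hab)}; expected {HABITATS}")
        ph = self.data["pH"].to_numpy(dtype=float)
        if ((ph <= 0) | (ph >= 14)).any():
            raise ValueError("pH values must lie in (0, 14)")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    def habitat_of(self, sample_id) -> str:
        return self.data.at[sample_id, "habitat"]

    def samples_in(self, habitat: str) -> list:
        return list(self.data.index[self.data["habitat"] == habitat])

    def aligned_to(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.data.loc[list(sample_ids)].copy())


def read_abundance_table(path, orientation: str = "samples_rows") -> AbundanceTable:
    """Read a TSV abundance table into counts mode (always samples x taxa).

    ``orientation="taxa_rows"`` transposes input whose rows are taxa.
    """
    if orientation not in ("samples_rows", "taxa_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = pd.read_csv(path, sep="\t", index_col=0)
    for col in raw.columns:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        if coerced.isna().any() and not raw[col].isna().any():
            row = raw.index[coerced.isna().argmax()]
            raise ValueError(f"non-numeric value at row {row!r}, column {col!r}")
        raw[col] = coerced
    if raw.isna().to_numpy().any():
        raise ValueError("abundance table contains missing values")
    if orientation == "taxa_rows":
        raw = raw.T
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    return AbundanceTable(raw, mode="counts")


def write_abundance_table(tab: AbundanceTable, path, orientation: str = "samples_rows") -> None:
    data = tab.data if orientation == "samples_rows" else tab.data.T
    data.to_csv(path, sep="\t", float_format="%.10g")


def read_sample_metadata(path) -> SampleMetadata:
    return SampleMetadata(pd.read_csv(path, sep="\t", index_col=0))


def read_tree(path) -> TreeNode:
    """Read a rooted Newick tree; missing branch lengths become 0."""
    tree = TreeNode.read(str(path), format="newick")
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        raise ValueError("tree tip labels are not unique")
    for node in tree.traverse():
        if node.length is None:
            node.length = 0.0
        if node.length < 0:
            raise ValueError(f"negative branch length at node {node.name!r}")
    return tree


def filter_rare_asvs(tab: AbundanceTable, min_total: int = 10) -> AbundanceTable:
    """Drop every taxon whose total count across all samples is < ``min_total``.

    Subsumes singleton/doubleton removal for the default threshold of 10 reads.
    """
    if tab.mode != "counts":
        raise ValueError("rare-ASV filter is defined on counts, not relative abundances")
    totals = tab.data.sum(axis=0)
    keep = totals[totals >= min_total].index
    return AbundanceTable(tab.data[keep].copy(), mode="counts")


def rarefy(tab: AbundanceTable, depth: int, seed: int) -> AbundanceTable:
    """Subsample each sample to exactly ``depth`` reads without replacement."""
    if tab.mode != "counts":
        raise ValueError("rarefaction is defined on counts")
    counts = np.rint(tab.values).astype(np.int64)
    totals = counts.sum(axis=1)
    low = totals < depth
    if low.any():
        bad = [f"{sid} ({tot})" for sid, tot in zip(np.asarray(tab.sample_ids)[low], totals[low])]
        raise ValueError(f"samples below rarefaction depth {depth}: {bad}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(counts)
    for i in range(counts.shape[0]):
        out[i] = rng.multivariate_hypergeometric(counts[i], depth)
    return AbundanceTable(
        pd.DataFrame(out, index=tab.data.index, columns=tab.data.columns), mode="counts"
    )


def to_relative(tab: AbundanceTable) -> AbundanceTable:
    """Convert counts to within-sample relative abundances (rows sum to 1)."""
    if tab.mode != "counts":
        raise ValueError("input must be in counts mode")
    vals = tab.values.astype(float)
    totals = vals.sum(axis=1)
    empty = totals == 0
    if empty.any():
        warnings.warn(
            f"all-zero samples left as zeros: {list(np.asarray(tab.sample_ids)[empty])}",
            stacklevel=2,
        )
    safe = np.where(empty, 1.0, totals)
    rel = vals / safe[:, None]
    return AbundanceTable(
        pd.DataFrame(rel, index=tab.data.index, columns=tab.data.columns), mode="relative"
    )
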