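"""ASV feature tables, sample metadata, and tree input/output.

The central container is :class:`FeatureTable`: an ASV-by-sample matrix of
non-negative integer read counts with a per-ASV kingdom label (``bacteria``
or ``fungi``).  Tables are stored dense as :class:`pandas.DataFrame`; the
amplicon tables this package targets are a few hundred to a few thousand
taxa, for which dense storage is the simpler and faster choice.

File formats
------------
* Feature table: TSV, first header cell ``#ASV_ID``, one column per sample.
* Taxonomy: TSV with columns ``#ASV_ID``, ``kingdom``, ``genus``.
* Metadata: TSV with columns ``sample_id``, ``site``, ``genotype``,
  ``replicate``.
* Tree: Newick with named tips and branch lengths.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import ValidationError

KINGDOMS = ("bacteria", "fungi")
GENOTYPES = ("wild", "cultivated")

ID_COL = "#ASV_ID"


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} ID: {i!r}")
        seen.add(i)


@dataclass
class FeatureTable:
    """ASV x sample count matrix with per-taxon kingdom labels.

    Parameters
    ----------
    counts : pandas.DataFrame
        Rows are ASVs, columns are samples, values are non-negative integers.
    kingdom : pandas.Series, optional
        Per-ASV label in ``{"bacteria", "fungi"}`` indexed like ``counts``.
        Defaults to ``"bacteria"`` for every taxon.
    """

    counts: pd.DataFrame
    kingdom: pd.Series = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.kingdom is None:
            self.kingdom = pd.Series("bacteria", index=self.counts.index)
        _check_unique(self.counts.index, "ASV")
        _check_unique(self.counts.columns, "sample")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(np.isfinite(vals)) or np.any(vals != np.round(vals)):
                raise ValidationError("counts must be finite integers")
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if np.any(vals < 0):
            bad = self.counts.index[np.any(vals < 0, axis=1)][0]
            raise ValidationError(f"negative count for ASV {bad!r}")
        if not self.kingdom.index.equals(self.counts.index):
            self.kingdom = self.kingdom.reindex(self.counts.index)
        if self.kingdom.isna().any():
            bad = self.kingdom.index[self.kingdom.isna()][0]
            raise ValidationError(f"missing kingdom label for ASV {bad!r}")
        bad_k = set(self.kingdom.unique()) - set(KINGDOMS)
        if bad_k:
            raise ValidationError(f"unknown kingdom label(s): {sorted(bad_k)}")

    # -- basic accessors -------------------------------------------------

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return self.counts.equals(other.counts) and self.kingdom.equals(other.kingdom)

    # -- transforms ------------------------------------------------------

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances; every column sums to 1.

        Raises
        ------
        ValidationError
            If any sample has zero total reads (named in the message).
        """
        totals = self.counts.sum(axis=0)
        zero = totals.index[totals == 0]
        if len(zero):
            raise ValidationError(f"sample {zero[0]!r} has zero total count")
        return self.counts / totals

    def filter_rare(self, min_mean_relabund: float) -> "FeatureTable":
        """Drop taxa whose mean per-sample relative abundance is below a floor.

        The published rule removes ASVs below 0.01 % mean relative abundance
        before network inference; the threshold is a fraction (0.0001), must
        lie in ``[0, 1)``, and row order is preserved.
        """
        if not 0 <= min_mean_relabund < 1:
            raise ValidationError(
                f"min_mean_relabund must be in [0, 1), got {min_mean_relabund}"
            )
        if min_mean_relabund == 0:
            return FeatureTable(self.counts.copy(), self.kingdom.copy())
        mean_rel = self.relative_abundance().mean(axis=1)
        keep = mean_rel >= min_mean_relabund
        return FeatureTable(self.counts.loc[keep].copy(), self.kingdom.loc[keep].copy())

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise ValidationError(f"unknown sample ID: {missing[0]!r}")
        return FeatureTable(self.counts[list(sample_ids)].copy(), self.kingdom.copy())

    def subset_kingdom(self, kingdom: str) -> "FeatureTable":
        if kingdom not in KINGDOMS:
            raise ValidationError(f"unknown kingdom {kingdom!r}")
        keep = self.kingdom == kingdom
        return FeatureTable(self.counts.loc[keep].copy(), self.kingdom.loc[keep].copy())

    def drop_absent_taxa(self) -> "FeatureTable":
        keep = self.counts.sum(axis=1) > 0
        return FeatureTable(self.counts.loc[keep].copy(), self.kingdom.loc[keep].copy())

    def rarefy(self, depth: int, seed: int = 0) -> "FeatureTable":
        """Seeded subsampling without replacement to a common depth.

        Provided for sensitivity checks only; the default pipeline works on
        relative abundances without rarefaction.
        """
        rng = np.random.default_rng(seed)
        totals = self.counts.sum(axis=0)
        if (totals < depth).any():
            bad = totals.index[totals < depth][0]
            raise ValidationError(
                f"sample {bad!r} has fewer than {depth} reads; cannot rarefy"
            )
        out = np.zeros(self.counts.shape, dtype=np.int64)
        vals = self.counts.to_numpy()
        for j in range(vals.shape[1]):
            reads = np.repeat(np.arange(vals.shape[0]), vals[:, j])
            pick = rng.choice(reads, size=depth, replace=False)
            out[:, j] = np.bincount(pick, minlength=vals.shape[0])
        return FeatureTable(
            pd.DataFrame(out, index=self.counts.index, columns=self.counts.columns),
            self.kingdom.copy(),
        )


@dataclass
class SampleMetadata:
    """Per-sample factors: site, genotype (wild/cultivated), replicate."""

    frame: pd.DataFrame  # index sample_id; columns site, genotype, replicate

    def __post_init__(self) -> None:
        _check_unique(self.frame.index, "sample")
        for col in ("site", "genotype", "replicate"):
            if col not in self.frame.columns:
                raise ValidationError(f"metadata missing column {col!r}")
        bad_g = set(self.frame["genotype"].unique()) - set(GENOTYPES)
        if bad_g:
            raise ValidationError(f"unknown genotype label(s): {sorted(bad_g)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def align_to(self, table: FeatureTable) -> "SampleMetadata":
        """Reorder to the table's sample order; error on any mismatch."""
        missing = [s for s in table.sample_ids if s not in self.frame.index]
        if missing:
            raise ValidationError(f"metadata missing sample {missing[0]!r}")
        extra = [s for s in self.frame.index if s not in table.sample_ids]
        if extra:
            raise ValidationError(f"metadata has unknown sample {extra[0]!r}")
        return SampleMetadata(self.frame.loc[table.sample_ids].copy())

    def samples_for(self, factor: str, level: str) -> list[str]:
        return list(self.frame.index[self.frame[factor] == level])


# -- readers / writers ---------------------------------------------------


def read_feature_table(path: str | Path, taxonomy_path: str | Path | None = None) -> FeatureTable:
    """Read a TSV count table (rows ASVs, first column ``#ASV_ID``).

    If ``taxonomy_path`` is given, kingdom labels are taken from its
    ``kingdom`` column; otherwise all taxa default to ``bacteria``.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != ID_COL:
        raise ValidationError(
            f"feature table must start with {ID_COL!r}, got {df.columns[0]!r}"
        )
    df = df.set_index(ID_COL)
    try:
        counts = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-numeric counts in {path}: {exc}") from None
    kingdom = None
    if taxonomy_path is not None:
        tax = read_taxonomy(taxonomy_path)
        kingdom = tax["kingdom"]
    return FeatureTable(counts, kingdom)


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    tax = pd.read_csv(path, sep="\t", dtype=str)
    if tax.columns[0] != ID_COL:
        raise ValidationError(
            f"taxonomy must start with {ID_COL!r}, got {tax.columns[0]!r}"
        )
    tax = tax.set_index(ID_COL)
    _check_unique(tax.index, "ASV")
    return tax


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "site": str, "genotype": str})
    if "sample_id" not in df.columns:
        raise ValidationError("metadata must have a 'sample_id' column")
    return SampleMetadata(df.set_index("sample_id"))


def read_tree(path: str | Path) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and edge.length is None:
            raise ValidationError("tree has edges without branch lengths")
    return tree


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    out = table.counts.copy()
    out.index.name = ID_COL
    out.to_csv(path, sep="\t")


def write_taxonomy(table: FeatureTable, path: str | Path, genus: pd.Series | None = None) -> None:
    df = pd.DataFrame({"kingdom": table.kingdom})
    df["genus"] = genus if genus is not None else "unclassified"
    df.index.name = ID_COL
    df.to_csv(path, sep="\t")


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    out = meta.frame.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(tree.as_string(schema="newick"))


def tree_distance_matrix(tree: dendropy.Tree, taxon_ids: Sequence[str]) -> np.ndarray:
    """Patristic (tip-to-tip) distance matrix ordered like ``taxon_ids``.

    Raises
    ------
    ValidationError
        Listing the taxa missing from the tree, if any.
    """
    pdm = tree.phylogenetic_distance_matrix()
    by_label = {t.label: t for t in tree.taxon_namespace}
    missing = [t for t in taxon_ids if t not in by_label]
    if missing:
        raise ValidationError(f"taxa missing from tree: {missing}")
    n = len(taxon_ids)
    dist = np.zeros((n, n))
    taxa = [by_label[t] for t in taxon_ids]
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            dist[i, j] = dist[j, i] = d
    return dist
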