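"""Ortholog-map validation, cross-species count joining and the minimum-read
filter.

Two per-species gene-level count matrices are joined row-wise through a
one-to-one ortholog map into a single combined matrix (rows = ortholog
pairs, columns = all samples of both species), which is then filtered to
pairs with a minimum total read count across all samples.  Joint treatment
of both species in one matrix is what makes the downstream joint
normalization and cross-species fold-change comparison possible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("crossheart")

__all__ = [
    "CountMatrix",
    "OrthologMap",
    "CombinedMatrix",
    "read_counts",
    "read_metadata",
    "read_ortholog_map",
    "join_counts",
    "filter_min_sum",
]

VALID_CONDITIONS = {"untouched", "sham", "cryoinjured"}


@dataclass
class CountMatrix:
    """Raw gene-level counts (genes x samples) with per-sample metadata.

    ``samples`` is indexed by sample_id with columns ``species``,
    ``condition`` (untouched / sham / cryoinjured) and ``time_hours``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing metadata: {sorted(missing)[:5]}")
        self.samples = self.samples.loc[list(self.counts.columns)]
        bad = set(self.samples["condition"]) - VALID_CONDITIONS
        if bad:
            raise ValueError(f"unknown conditions {sorted(bad)}")
        if (self.samples["time_hours"] < 0).any():
            raise ValueError("negative time_hours")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integral")

    @property
    def species(self) -> str:
        sp = self.samples["species"].unique()
        if len(sp) != 1:
            raise ValueError(f"matrix mixes species {list(sp)}")
        return sp[0]


@dataclass
class OrthologMap:
    """Validated one-to-one gene pairing between two species."""

    pairs: list

    def __post_init__(self):
        self.pairs = [(str(a), str(b)) for a, b in self.pairs]
        a_ids = [a for a, _ in self.pairs]
        b_ids = [b for _, b in self.pairs]
        if len(set(a_ids)) != len(a_ids) or len(set(b_ids)) != len(b_ids):
            raise ValueError("ortholog map is not one-to-one")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class CombinedMatrix:
    """Ortholog-pair x sample count matrix spanning both species.

    Row index is ``"geneA|geneB"``; ``pairs`` keeps the split ids.  Columns
    are all species-A samples then all species-B samples, each block sorted
    by (condition, time).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    pairs: pd.DataFrame  # columns gene_A, gene_B, indexed like counts

    def species_columns(self, species: str) -> list:
        return list(self.samples.index[self.samples["species"] == species])


def read_counts(path: str) -> pd.DataFrame:
    """Genes x samples TSV, first column gene id, header = sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    return df


def read_metadata(path: str) -> pd.DataFrame:
    """Sample metadata TSV: sample_id, species, condition, time_hours."""
    meta = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    meta.index = meta.index.astype(str)
    return meta


def _looks_like_header(rows: list) -> bool:
    # Header iff first-row tokens are non-repeating, appear nowhere else in
    # the id columns, and look like column labels rather than gene ids
    # (no digits, while the data ids do carry digits).  The last clause keeps
    # a short headerless file of unique ids intact.
    first = rows[0]
    if len(rows) < 2 or len(set(first)) != len(first):
        return False
    rest = [tok for row in rows[1:] for tok in row]
    if set(first) & set(rest):
        return False
    first_has_digits = any(ch.isdigit() for tok in first for ch in tok)
    data_have_digits = sum(
        any(ch.isdigit() for ch in tok) for tok in rest
    ) > len(rest) / 2
    return not first_has_digits and data_have_digits


def read_ortholog_map(path: str) -> OrthologMap:
    """Read a two-column TSV of (gene_A, gene_B) pairs; header auto-detected.

    Any gene participating in a one-to-many or many-to-one relation is
    dropped entirely, together with all of its rows — no representative is
    chosen.  The number of dropped rows is logged.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: expected >=2 tab-separated columns")
            rows.append((fields[0].strip(), fields[1].strip()))
    if not rows:
        raise ValueError(f"{path}: empty ortholog map file")
    if _looks_like_header(rows):
        rows = rows[1:]
    if not rows:
        raise ValueError(f"{path}: ortholog map has a header but no data rows")
    rows = list(dict.fromkeys(rows))  # exact duplicate pairs collapse to one
    a_counts = pd.Series([a for a, _ in rows]).value_counts()
    b_counts = pd.Series([b for _, b in rows]).value_counts()
    kept = [
        (a, b) for a, b in rows if a_counts[a] == 1 and b_counts[b] == 1
    ]
    dropped = len(rows) - len(kept)
    if dropped:
        logger.info("ortholog map: dropped %d rows in one-to-many relations", dropped)
    if not kept:
        raise ValueError(
            f"{path}: zero surviving pairs after removing one-to-many relations"
        )
    return OrthologMap(kept)


def _sorted_sample_ids(samples: pd.DataFrame) -> list:
    order = samples.sort_values(
        ["condition", "time_hours"], kind="stable"
    )
    return list(order.index)


def join_counts(
    counts_A: CountMatrix, counts_B: CountMatrix, omap: OrthologMap
) -> CombinedMatrix:
    """Join raw counts of both species into one ortholog-pair matrix.

    Pairs with a gene missing from either matrix are dropped (logged);
    surviving rows carry the untouched raw counts of both genes.
    """
    if counts_A.species == counts_B.species:
        raise ValueError(
            f"both matrices declare species {counts_A.species!r}; "
            "expected two different species"
        )
    present_A = set(counts_A.counts.index)
    present_B = set(counts_B.counts.index)
    kept = [(a, b) for a, b in omap.pairs if a in present_A and b in present_B]
    dropped = len(omap.pairs) - len(kept)
    if dropped:
        logger.info("join_counts: dropped %d pairs missing from a matrix", dropped)
    if not kept:
        raise ValueError("no ortholog pairs with data in both species")

    cols_A = _sorted_sample_ids(counts_A.samples)
    cols_B = _sorted_sample_ids(counts_B.samples)
    genes_A = [a for a, _ in kept]
    genes_B = [b for _, b in kept]
    block_A = counts_A.counts.loc[genes_A, cols_A].to_numpy()
    block_B = counts_B.counts.loc[genes_B, cols_B].to_numpy()
    pair_ids = [f"{a}|{b}" for a, b in kept]
    combined = pd.DataFrame(
        np.hstack([block_A, block_B]), index=pair_ids, columns=cols_A + cols_B
    )
    samples = pd.concat(
        [counts_A.samples.loc[cols_A], counts_B.samples.loc[cols_B]]
    )
    pairs = pd.DataFrame({"gene_A": genes_A, "gene_B": genes_B}, index=pair_ids)
    return CombinedMatrix(combined, samples, pairs)


def filter_min_sum(
    combined: CombinedMatrix, min_total: int = 5, per_species: bool = False
) -> CombinedMatrix:
    """Keep ortholog pairs with a minimum total raw count.

    Default reading: the sum over ALL samples of the combined matrix (both
    species, all conditions) must be >= ``min_total`` (boundary inclusive).
    ``per_species=True`` instead requires the threshold within each species'
    sample block separately — the stricter per-species interpretation.
    Row order is preserved; an empty result is allowed (logged).
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    if per_species:
        keep = np.ones(len(combined.counts), dtype=bool)
        for sp in combined.samples["species"].unique():
            cols = combined.species_columns(sp)
            keep &= combined.counts[cols].sum(axis=1).to_numpy() >= min_total
    else:
        keep = combined.counts.sum(axis=1).to_numpy() >= min_total
    dropped = int((~keep).sum())
    if dropped:
        logger.info(
            "filter_min_sum: dropped %d/%d pairs below total %d",
            dropped, len(keep), min_total,
        )
    if not keep.any():
        logger.warning("filter_min_sum: no pairs survive the filter")
    return CombinedMatrix(
        combined.counts.loc[keep],
        combined.samples,
        combined.pairs.loc[keep],
    )
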