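"""Joint median-of-ratios normalization and log2 fold-change matrices.

Size factors are estimated once on the combined cross-species matrix (the
median-of-ratios estimator popularized by DESeq), so both species share one
scale.  Because the design has one pooled library per condition/time and no
replicates, fold changes are simple per-sample ratios of normalized counts
against the species' untouched 0 h baseline, stabilized with a pseudocount.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ortholog import CombinedMatrix

logger = logging.getLogger("crossheart")

__all__ = [
    "SizeFactors",
    "FoldChangeMatrix",
    "size_factors",
    "normalize",
    "log2_fc",
    "default_contrasts",
    "build_fc_matrix",
    "contrast_label",
]


SizeFactors = pd.Series  # per-sample positive reals keyed by sample_id


def size_factors(
    combined: CombinedMatrix, per_species: bool = False
) -> SizeFactors:
    """Median-of-ratios size factors.

    For sample j: factor_j = median over reference genes g of
    count[g, j] / geomean(count[g, :]), where the reference genes are those
    with a strictly positive count in every sample (geometric mean > 0).
    With an even number of reference genes the median is the mean of the two
    central ratios (numpy convention).

    ``per_species=True`` estimates factors within each species' sample block
    independently (sensitivity-analysis mode); the default is the joint
    estimate on the full combined matrix.
    """
    if per_species:
        parts = []
        for sp in combined.samples["species"].unique():
            cols = combined.species_columns(sp)
            sub = CombinedMatrix(
                combined.counts[cols],
                combined.samples.loc[cols],
                combined.pairs,
            )
            parts.append(size_factors(sub))
        return pd.concat(parts).loc[combined.counts.columns]

    mat = combined.counts.to_numpy(dtype=float)
    ref = (mat > 0).all(axis=1)
    if not ref.any():
        raise ValueError(
            "no reference genes: every gene has a zero count in some sample; "
            "cannot compute median-of-ratios size factors"
        )
    logmat = np.log(mat[ref])
    loggeomean = logmat.mean(axis=1)
    factors = np.exp(np.median(logmat - loggeomean[:, None], axis=0))
    return pd.Series(factors, index=combined.counts.columns, name="size_factor")


def normalize(combined: CombinedMatrix, sf: SizeFactors) -> pd.DataFrame:
    """Raw counts divided by their sample's size factor."""
    missing = set(combined.counts.columns) - set(sf.index)
    if missing:
        raise ValueError(f"size factors missing for samples: {sorted(missing)[:5]}")
    if not np.all(np.isfinite(sf.loc[combined.counts.columns])) or (
        sf.loc[combined.counts.columns] <= 0
    ).any():
        raise ValueError("size factors must be finite and > 0")
    return combined.counts / sf.loc[combined.counts.columns]


def _baseline_sample(samples: pd.DataFrame, species: str) -> str:
    mask = (
        (samples["species"] == species)
        & (samples["condition"] == "untouched")
        & (samples["time_hours"] == 0)
    )
    ids = list(samples.index[mask])
    if not ids:
        raise ValueError(f"species {species!r} lacks an untouched 0 h sample")
    return ids[0]


def contrast_label(species: str, condition: str, time_hours: float) -> str:
    return f"{species}:{condition}:{time_hours:g}h"


def log2_fc(
    normalized: pd.DataFrame,
    samples: pd.DataFrame,
    contrast: tuple,
    pseudocount: float = 1.0,
) -> pd.Series:
    """log2((x_sample + pc) / (x_untouched + pc)) for one contrast.

    ``contrast`` is (species, condition, time_hours), compared against the
    same species' untouched 0 h sample.  No replicates are assumed or used.
    """
    species, condition, t = contrast
    if condition == "untouched" and float(t) == 0.0:
        raise ValueError("contrast against itself (untouched 0 h vs itself)")
    base_id = _baseline_sample(samples, species)
    mask = (
        (samples["species"] == species)
        & (samples["condition"] == condition)
        & (samples["time_hours"] == float(t))
    )
    ids = list(samples.index[mask])
    if not ids:
        raise ValueError(f"no sample for contrast {contrast}")
    x = normalized[ids[0]]
    base = normalized[base_id]
    out = np.log2((x + pseudocount) / (base + pseudocount))
    out.name = contrast_label(species, condition, float(t))
    return out


def default_contrasts(samples: pd.DataFrame, conditions=("cryoinjured", "sham")):
    """All (species, condition, time) slots present in the metadata, vs the
    untouched baseline — cryoinjury contrasts first, species A then B."""
    out = []
    for cond in conditions:
        for sp in sorted(samples["species"].unique()):
            sub = samples[
                (samples["species"] == sp) & (samples["condition"] == cond)
            ]
            for t in sorted(sub["time_hours"].unique()):
                out.append((sp, cond, float(t)))
    return out


@dataclass
class FoldChangeMatrix:
    """Ortholog pairs x contrasts log2 fold changes vs untouched baselines.

    ``contrasts`` lists (species, condition, time_hours) in column order;
    ``values`` columns carry the matching ``species:condition:<t>h`` labels.
    """

    values: pd.DataFrame
    contrasts: list
    pseudocount: float = 1.0

    def __post_init__(self):
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("fold-change matrix contains non-finite values")
        labels = [contrast_label(*c) for c in self.contrasts]
        if labels != list(self.values.columns):
            raise ValueError("contrast list does not match value columns")

    def species_columns(self, species: str) -> list:
        return [
            contrast_label(*c) for c in self.contrasts if c[0] == species
        ]


def build_fc_matrix(
    normalized: pd.DataFrame,
    samples: pd.DataFrame,
    contrasts: Sequence[tuple],
    min_norm_per_timepoint: float = 5.0,
    pseudocount: float = 1.0,
) -> FoldChangeMatrix:
    """Fold-change matrix over the declared contrasts.

    Rows are restricted to pairs with at least ``min_norm_per_timepoint``
    normalized counts (boundary inclusive) in EVERY sample entering any
    contrast, baselines included.
    """
    contrasts = [(sp, cond, float(t)) for sp, cond, t in contrasts]
    if not contrasts:
        raise ValueError("empty contrast list")

    involved: list = []
    for sp, cond, t in contrasts:
        mask = (
            (samples["species"] == sp)
            & (samples["condition"] == cond)
            & (samples["time_hours"] == t)
        )
        ids = list(samples.index[mask])
        if not ids:
            raise ValueError(f"no sample for contrast {(sp, cond, t)}")
        involved.extend(ids)
        involved.append(_baseline_sample(samples, sp))
    involved = list(dict.fromkeys(involved))

    keep = (normalized[involved] >= min_norm_per_timepoint).all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info(
            "build_fc_matrix: dropped %d/%d pairs below %g normalized counts",
            dropped, len(keep), min_norm_per_timepoint,
        )
    sub = normalized.loc[keep]
    cols = [
        log2_fc(sub, samples, c, pseudocount=pseudocount) for c in contrasts
    ]
    values = pd.concat(cols, axis=1)
    return FoldChangeMatrix(values, contrasts, pseudocount)
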