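"""Sample-Level Enrichment Analysis (SLEA).

Each contrast's fold changes are linearly rescaled to [-10, +10] and
column-mean centered, then every module's per-contrast mean is compared to
the distribution of means of many (default 10,000) random gene sets of the
same size drawn without replacement from the same column.  The resulting
Z-score — (observed mean - null mean) / null sd — is significant above
|Z| = 4 (strict).  Because the null is re-sampled from the very column
being scored, the score is self-calibrating per sample and needs no
replicates, which is what makes it usable on a pooled one-library-per-
time-point design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Set, Union

import numpy as np
import pandas as pd

from .enrichment import ModuleCollection
from .normalize import FoldChangeMatrix, contrast_label

logger = logging.getLogger("crossheart")

__all__ = [
    "ScaledMatrix",
    "SLEAResult",
    "scale_center",
    "resolve_members",
    "slea_z",
    "call_significant",
    "differential_response",
    "upstream_input_prep",
]


@dataclass
class ScaledMatrix:
    """Per-column rescaled and centered fold changes, with the scaling
    metadata (min, max, subtracted mean) needed to invert the map."""

    values: pd.DataFrame
    column_meta: pd.DataFrame  # per column: min, max, subtracted_mean, degenerate
    contrasts: list = field(default_factory=list)
    mode: str = "minmax"


def scale_center(fc: Union[FoldChangeMatrix, pd.DataFrame],
                 mode: str = "minmax") -> ScaledMatrix:
    """Scale each contrast column into [-10, +10], then subtract its mean.

    ``mode='minmax'``: x -> 20*(x - min)/(max - min) - 10 (default).
    ``mode='maxabs'``: x -> 10*x/max|x| — the symmetric, zero-preserving
    alternative reading of "linearly scaled between -10 and +10".
    A constant column cannot be scaled and is mapped to all zeros with a
    degenerate-column warning.
    """
    df = fc.values if isinstance(fc, FoldChangeMatrix) else fc
    contrasts = fc.contrasts if isinstance(fc, FoldChangeMatrix) else []
    out = {}
    meta = []
    for col in df.columns:
        x = df[col].to_numpy(dtype=float)
        lo, hi = float(x.min()), float(x.max())
        degenerate = False
        if mode == "minmax":
            span = hi - lo
            if span == 0:
                degenerate = True
                scaled = np.zeros_like(x)
            else:
                scaled = 20.0 * (x - lo) / span - 10.0
        elif mode == "maxabs":
            m = max(abs(lo), abs(hi))
            if m == 0:
                degenerate = True
                scaled = np.zeros_like(x)
            else:
                scaled = 10.0 * x / m
        else:
            raise ValueError(f"unknown scaling mode {mode!r}")
        if degenerate:
            logger.warning("scale_center: constant column %r mapped to zeros", col)
            sub_mean = 0.0
        else:
            sub_mean = float(scaled.mean())
            scaled = scaled - sub_mean
        out[col] = scaled
        meta.append(
            {"column": col, "min": lo, "max": hi,
             "subtracted_mean": sub_mean, "degenerate": degenerate}
        )
    values = pd.DataFrame(out, index=df.index)[list(df.columns)]
    return ScaledMatrix(
        values, pd.DataFrame(meta).set_index("column"), list(contrasts), mode
    )


def resolve_members(members: Set[str], index: pd.Index) -> np.ndarray:
    """Row positions of a module in a matrix indexed by gene ids or by
    ortholog-pair ids of the form ``geneA|geneB`` (a member matches a pair
    row if it equals either side)."""
    members = set(members)
    pos = []
    for i, rid in enumerate(index):
        if rid in members:
            pos.append(i)
        elif "|" in rid:
            a, _, b = rid.partition("|")
            if a in members or b in members:
                pos.append(i)
    return np.asarray(pos, dtype=int)


@dataclass
class SLEAResult:
    """Modules x contrasts Z-scores with their resampling-null metadata."""

    z: pd.DataFrame
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame
    degenerate: pd.DataFrame  # True where null sd was 0 (Z forced to 0)
    n_rand: int
    seed: int
    z_cut: float = 4.0
    contrasts: list = field(default_factory=list)

    @property
    def significant(self) -> pd.DataFrame:
        return (self.z.abs() > self.z_cut) & ~self.degenerate


def _null_moments(column: np.ndarray, size: int, n_rand: int,
                  rng: np.random.Generator) -> tuple:
    """Mean and sample sd (n-1) of the means of ``n_rand`` random
    without-replacement gene sets of ``size`` drawn from ``column``."""
    n_rows = column.shape[0]
    # vectorized sampling w/o replacement: top-`size` of a random key per draw
    keys = rng.random((n_rand, n_rows))
    idx = np.argpartition(keys, size - 1, axis=1)[:, :size]
    means = column[idx].mean(axis=1)
    return float(means.mean()), float(means.std(ddof=1))


def slea_z(
    scaled: Union[ScaledMatrix, pd.DataFrame],
    modules: ModuleCollection,
    n_rand: int = 10000,
    seed: int = 0,
    min_size: int = 5,
    z_cut: float = 4.0,
) -> SLEAResult:
    """Score every module in every contrast against its same-column null.

    For each (module, column): observed = mean of the member values in that
    column; the null is the set of means of ``n_rand`` uniform
    without-replacement samples of identical size from the same column;
    Z = (observed - null mean) / null sd, with the sample sd (n-1
    denominator).  Null draws are deterministic given ``seed`` and cached
    per (column, module size).  A degenerate null (sd = 0, e.g. a constant
    column) yields Z = 0 with a flag rather than +-inf.

    Modules with fewer than ``min_size`` members present in the matrix are
    skipped (logged); a module covering every row has no null and is
    rejected.
    """
    df = scaled.values if isinstance(scaled, ScaledMatrix) else scaled
    contrasts = scaled.contrasts if isinstance(scaled, ScaledMatrix) else []
    n_rows = len(df)

    memberships: Dict[str, np.ndarray] = {}
    for name, members in modules.modules.items():
        pos = resolve_members(members, df.index)
        if len(pos) < min_size:
            logger.info(
                "slea_z: skipping module %r (%d < %d members present)",
                name, len(pos), min_size,
            )
            continue
        if len(pos) >= n_rows:
            raise ValueError(
                f"module {name!r} covers all {n_rows} rows; no null exists"
            )
        memberships[name] = pos
    if not memberships:
        raise ValueError("no module has enough members present in the matrix")

    names = list(memberships)
    sizes = sorted({len(p) for p in memberships.values()})
    rng = np.random.default_rng(seed)

    z = np.zeros((len(names), df.shape[1]))
    nmean = np.zeros_like(z)
    nsd = np.zeros_like(z)
    degen = np.zeros(z.shape, dtype=bool)

    # deterministic order: columns outer, sizes inner, so the cache key
    # sequence (and hence the RNG stream) is a pure function of the input
    for j, col in enumerate(df.columns):
        column = df[col].to_numpy(dtype=float)
        moments = {
            s: _null_moments(column, s, n_rand, rng) for s in sizes
        }
        for i, name in enumerate(names):
            pos = memberships[name]
            mu, sd = moments[len(pos)]
            obs = float(column[pos].mean())
            nmean[i, j], nsd[i, j] = mu, sd
            if sd == 0.0:
                degen[i, j] = True
            else:
                z[i, j] = (obs - mu) / sd

    mk = lambda arr: pd.DataFrame(arr, index=names, columns=df.columns)
    return SLEAResult(
        z=mk(z), null_mean=mk(nmean), null_sd=mk(nsd),
        degenerate=pd.DataFrame(degen, index=names, columns=df.columns),
        n_rand=n_rand, seed=seed, z_cut=z_cut, contrasts=list(contrasts),
    )


def call_significant(result: SLEAResult, z_cut: float = 4.0) -> pd.DataFrame:
    """Long table of (module, contrast, Z, direction) with |Z| strictly
    above ``z_cut``; direction + marks activation, - inactivation."""
    if z_cut <= 0:
        raise ValueError("z_cut must be > 0")
    rows = []
    for name in result.z.index:
        for col in result.z.columns:
            zval = result.z.loc[name, col]
            if abs(zval) > z_cut and not result.degenerate.loc[name, col]:
                rows.append(
                    {"module": name, "contrast": col, "z": float(zval),
                     "direction": "+" if zval > 0 else "-"}
                )
    return pd.DataFrame(rows, columns=["module", "contrast", "z", "direction"])


def differential_response(
    result: SLEAResult,
    matched_times: Sequence[float] = (6.0, 48.0, 72.0),
    condition: str = "cryoinjured",
    species: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Rank modules by cross-species divergence of their SLEA Z profiles.

    score = max over matched times of |Z_A - Z_B| for the given condition;
    descending, ties broken by module name.  Both species must have a
    contrast at every matched time.
    """
    if not result.contrasts:
        raise ValueError("SLEAResult carries no contrast metadata")
    if species is None:
        species = sorted({c[0] for c in result.contrasts})
    if len(species) != 2:
        raise ValueError(f"expected two species, got {species}")
    sa, sb = species
    matched = [float(t) for t in matched_times]
    if not matched:
        raise ValueError("no matched times given")
    pairs = []
    for t in matched:
        ca, cb = contrast_label(sa, condition, t), contrast_label(sb, condition, t)
        if ca not in result.z.columns or cb not in result.z.columns:
            raise ValueError(
                f"missing contrast at matched time {t:g} h "
                f"({ca!r} or {cb!r} absent)"
            )
        pairs.append((ca, cb))
    scores = {}
    for name in result.z.index:
        scores[name] = max(
            abs(result.z.loc[name, ca] - result.z.loc[name, cb])
            for ca, cb in pairs
        )
    table = (
        pd.Series(scores, name="score")
        .rename_axis("module")
        .reset_index()
        .sort_values(["score", "module"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def upstream_input_prep(
    fc: FoldChangeMatrix, abs_log2fc_threshold: float = 1.0
) -> pd.DataFrame:
    """Export genes with |log2 FC| strictly above the threshold in >=1
    contrast, with their signed per-contrast fold changes, ranked by peak
    |FC| — the input list expected by external pathway/upstream-regulator
    tools.  No pathway scoring is performed here."""
    if abs_log2fc_threshold < 0:
        raise ValueError("threshold must be >= 0")
    absfc = fc.values.abs()
    keep = (absfc > abs_log2fc_threshold).any(axis=1)
    out = fc.values.loc[keep].copy()
    out.insert(0, "max_abs_fc", absfc.loc[keep].max(axis=1))
    out = out.sort_values("max_abs_fc", ascending=False, kind="stable")
    return out.rename_axis("gene")
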