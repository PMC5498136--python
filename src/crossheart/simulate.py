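"""Two-species cardiac-injury time-course count simulator.

Emulates the pooled-library design of the zebrafish/medaka cryoinjury
comparison: per species one RNA-seq library per (condition, time point) —
untouched baseline at 0 h, then sham-operated and cryoinjured hearts sampled
along a time course — with a known module-structured injury response so that
every downstream pipeline stage (ortholog join, joint normalization,
fold changes, DEG selection, GO enrichment, SLEA) can be tested against
ground truth.

The injury response of a responsive gene is a pulse in log2-fold-change
space: zero at 0 h, linear rise to the module amplitude at the species'
peak time, then exponential decay with a fixed half-life.  The comparator
species ("B", medaka-like) defaults to an attenuated (0.4x) and delayed
(2x peak time) response.  Counts are negative-binomial around
baseline * size_factor * 2**fc(t).
"""

from __future__ import annotations

import dataclasses
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ortholog import CountMatrix, OrthologMap
from .enrichment import ModuleCollection

__all__ = [
    "ModuleSpec",
    "SimConfig",
    "GroundTruth",
    "SimulatedExperiment",
    "pulse_fc",
    "sample_nb",
    "simulate_experiment",
    "write_experiment",
]

CONDITIONS = ("untouched", "sham", "cryoinjured")


@dataclass(frozen=True)
class ModuleSpec:
    """A planted gene module: ``size`` consecutive orthologs responding to
    injury in the species listed in ``responsive_in`` (subset of {"A","B"})."""

    name: str
    size: int
    responsive_in: frozenset = frozenset()

    def __post_init__(self):
        if self.size < 1:
            raise ValueError(f"module {self.name!r}: size must be positive")
        object.__setattr__(self, "responsive_in", frozenset(self.responsive_in))
        bad = self.responsive_in - {"A", "B"}
        if bad:
            raise ValueError(f"module {self.name!r}: unknown species {sorted(bad)}")


def _default_modules() -> tuple:
    responsive = tuple(
        ModuleSpec(f"module_{i:02d}", 50, frozenset({"A"})) for i in range(1, 6)
    )
    silent = tuple(ModuleSpec(f"module_{i:02d}", 50) for i in range(6, 11))
    return responsive + silent


@dataclass
class SimConfig:
    """Study-design parameters of the simulated two-species experiment.

    Defaults encode the reference design: 2000 one-to-one orthologs, ten
    disjoint modules of 50 genes of which five respond to cryoinjury only in
    species A with a 3 log2-unit pulse peaking at 48 h; species B responses
    (for modules responsive in B) are attenuated to 0.4x the species-A
    amplitude and delayed to 2x the peak time.  One library per
    (condition, time), no replicates, matching a pooled-hearts design.

    Library depth and count overdispersion are free parameters (not fixed by
    the emulated design); defaults are a lognormal baseline with ln-mean 4.0
    (~55 counts median) and sd 1.5, NB dispersion 0.05 and lognormal size
    factors with sd 0.3 on the log scale.
    """

    n_orthologs: int = 2000
    modules: Sequence[ModuleSpec] = field(default_factory=_default_modules)
    amplitude_A: float = 3.0
    amplitude_B: float = 1.2
    peak_time_A: float = 48.0
    peak_time_B: float = 96.0
    decay_halflife: float = 48.0
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.5
    dispersion: float = 0.05
    size_factor_sd: float = 0.3
    timepoints_A: Sequence[float] = (0.0, 6.0, 24.0, 48.0, 72.0, 120.0)
    timepoints_B: Sequence[float] = (0.0, 6.0, 48.0, 72.0, 144.0)
    conditions: Sequence[str] = CONDITIONS
    sham_fraction_of_amplitude: float = 0.3
    replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_orthologs < 1:
            raise ValueError("n_orthologs must be positive")
        names = [m.name for m in self.modules]
        if len(set(names)) != len(names):
            raise ValueError("module names must be unique")
        total = sum(m.size for m in self.modules)
        if total > self.n_orthologs:
            raise ValueError(
                f"sum of module sizes ({total}) exceeds n_orthologs "
                f"({self.n_orthologs})"
            )
        for m in self.modules:
            if m.size > self.n_orthologs:
                raise ValueError(f"module {m.name!r} larger than n_orthologs")
        bad = set(self.conditions) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions {sorted(bad)}")
        if "untouched" not in self.conditions:
            raise ValueError("conditions must include 'untouched'")
        for label, tps in (("A", self.timepoints_A), ("B", self.timepoints_B)):
            if 0.0 not in [float(t) for t in tps]:
                raise ValueError(f"timepoints_{label} must contain 0 (baseline)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.size_factor_sd <= 0:
            raise ValueError("size_factor_sd must be > 0")
        if not (0.0 <= self.sham_fraction_of_amplitude <= 1.0):
            raise ValueError("sham_fraction_of_amplitude must lie in [0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def pulse_fc(t: float, amplitude: float, peak_time: float, halflife: float) -> float:
    """Injury-response pulse in log2 units: 0 at t=0, linear rise to
    ``amplitude`` at ``peak_time``, exponential decay with ``halflife``."""
    if t <= 0 or amplitude == 0:
        return 0.0
    if t <= peak_time:
        return amplitude * t / peak_time
    return amplitude * 2.0 ** (-(t - peak_time) / halflife)


def sample_nb(mean, dispersion: float, rng: np.random.Generator):
    """Negative-binomial counts with E = mean, Var = mean + dispersion*mean^2.

    ``mean`` may be a scalar or array of positive reals; tiny means (<1e-8)
    are floored and return 0 (the NB parametrization degenerates there).
    A vanishing ``dispersion`` is treated as the Poisson limit.
    """
    mean = np.asarray(mean, dtype=float)
    if np.any(mean <= 0):
        raise ValueError("sample_nb requires strictly positive mean")
    if dispersion <= 0:
        raise ValueError("sample_nb requires positive dispersion")
    tiny = mean < 1e-8
    safe_mean = np.where(tiny, 1.0, mean)
    if dispersion < 1e-12:
        draws = rng.poisson(safe_mean)
    else:
        n = 1.0 / dispersion  # NB number of failures
        p = n / (n + safe_mean)
        draws = rng.negative_binomial(n, p)
    draws = np.where(tiny, 0, draws)
    if draws.shape == ():
        return int(draws)
    return draws.astype(np.int64)


@dataclass
class GroundTruth:
    """Noise-free truth for recovery tests.

    ``true_mean_A``/``true_mean_B``: per-gene per-sample NB means (genes x
    samples).  ``true_fc``: per-module per-contrast mean log2 fold change
    (modules x contrast labels); non-member and non-responsive entries are 0.
    ``membership``: module name -> species-A gene-id set.  ``size_factors``:
    true per-sample depth multipliers for both species.
    """

    true_mean_A: pd.DataFrame
    true_mean_B: pd.DataFrame
    true_fc: pd.DataFrame
    membership: dict
    size_factors: pd.Series


@dataclass
class SimulatedExperiment:
    counts_A: CountMatrix
    counts_B: CountMatrix
    ortholog_map: OrthologMap
    modules: ModuleCollection
    truth: GroundTruth


def _sample_plan(config: SimConfig, species: str) -> list:
    """One (condition, time, replicate) slot per library, baseline first.

    Untouched exists only at 0 h; sham/cryoinjured at every positive time.
    """
    tps = config.timepoints_A if species == "A" else config.timepoints_B
    tps = sorted(float(t) for t in tps)
    plan = []
    for rep in range(config.replicates):
        plan.append(("untouched", 0.0, rep))
    for cond in ("sham", "cryoinjured"):
        if cond not in config.conditions:
            continue
        for t in tps:
            if t <= 0:
                continue
            for rep in range(config.replicates):
                plan.append((cond, t, rep))
    return plan


def _sample_id(species: str, cond: str, t: float, rep: int, replicates: int) -> str:
    base = f"{species}_{cond}_{t:g}h"
    return base if replicates == 1 else f"{base}_r{rep + 1}"


def _true_fc_value(config: SimConfig, module: ModuleSpec, species: str,
                   cond: str, t: float) -> float:
    if species not in module.responsive_in or cond == "untouched":
        return 0.0
    amp = config.amplitude_A if species == "A" else config.amplitude_B
    peak = config.peak_time_A if species == "A" else config.peak_time_B
    fc = pulse_fc(t, amp, peak, config.decay_halflife)
    if cond == "sham":
        fc *= config.sham_fraction_of_amplitude
    return fc


def true_fc_matrix(config: SimConfig) -> pd.DataFrame:
    """Module x contrast matrix of planted log2 fold changes.

    Pure function of the config — no sampling — so it is exactly
    reproducible.  Contrast labels follow the pipeline convention
    ``species:condition:<t>h``.
    """
    cols, vals = [], []
    for species in ("A", "B"):
        for cond, t, rep in _sample_plan(config, species):
            if cond == "untouched" or rep > 0:
                continue
            cols.append(f"{species}:{cond}:{t:g}h")
            vals.append(
                [_true_fc_value(config, m, species, cond, t) for m in config.modules]
            )
    return pd.DataFrame(
        np.array(vals).T if vals else np.empty((len(config.modules), 0)),
        index=[m.name for m in config.modules],
        columns=cols,
    )


def simulate_experiment(config: SimConfig) -> SimulatedExperiment:
    """Draw a full two-species experiment from ``config``.

    Deterministic given ``config.seed``: all stochastic draws flow from a
    single ``numpy`` generator.  Species baselines are drawn independently,
    so the dominant expression axis separates the species (as a
    between-species PCA of real data does).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_orthologs

    genes_A = [f"gA{i:05d}" for i in range(1, n + 1)]
    genes_B = [f"gB{i:05d}" for i in range(1, n + 1)]

    # consecutive index blocks -> disjoint modules by construction
    membership_idx: dict[str, np.ndarray] = {}
    start = 0
    for m in config.modules:
        membership_idx[m.name] = np.arange(start, start + m.size)
        start += m.size

    baseline = {
        sp: np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, n))
        for sp in ("A", "B")
    }

    plans = {sp: _sample_plan(config, sp) for sp in ("A", "B")}
    n_samples = {sp: len(plans[sp]) for sp in ("A", "B")}
    sf = {
        sp: np.exp(rng.normal(0.0, config.size_factor_sd, n_samples[sp]))
        for sp in ("A", "B")
    }

    counts, means, metas = {}, {}, {}
    for sp, genes in (("A", genes_A), ("B", genes_B)):
        fc = np.zeros((n, n_samples[sp]))
        for j, (cond, t, _rep) in enumerate(plans[sp]):
            for m in config.modules:
                v = _true_fc_value(config, m, sp, cond, t)
                if v:
                    fc[membership_idx[m.name], j] = v
        mean = baseline[sp][:, None] * sf[sp][None, :] * 2.0 ** fc
        draws = sample_nb(mean, config.dispersion, rng)
        ids = [
            _sample_id(sp, cond, t, rep, config.replicates)
            for cond, t, rep in plans[sp]
        ]
        counts[sp] = pd.DataFrame(draws, index=genes, columns=ids)
        means[sp] = pd.DataFrame(mean, index=genes, columns=ids)
        metas[sp] = pd.DataFrame(
            {
                "species": sp,
                "condition": [c for c, _, _ in plans[sp]],
                "time_hours": [t for _, t, _ in plans[sp]],
            },
            index=pd.Index(ids, name="sample_id"),
        )

    cm_A = CountMatrix(counts["A"], metas["A"])
    cm_B = CountMatrix(counts["B"], metas["B"])
    omap = OrthologMap(list(zip(genes_A, genes_B)))

    modules = ModuleCollection(
        modules={
            m.name: {genes_A[i] for i in membership_idx[m.name]}
            for m in config.modules
        },
        descriptions={
            m.name: (
                "responsive in " + "/".join(sorted(m.responsive_in))
                if m.responsive_in
                else "non-responsive"
            )
            for m in config.modules
        },
    )

    truth = GroundTruth(
        true_mean_A=means["A"],
        true_mean_B=means["B"],
        true_fc=true_fc_matrix(config),
        membership={
            m.name: {genes_A[i] for i in membership_idx[m.name]}
            for m in config.modules
        },
        size_factors=pd.concat(
            [
                pd.Series(sf["A"], index=metas["A"].index),
                pd.Series(sf["B"], index=metas["B"].index),
            ]
        ),
    )
    return SimulatedExperiment(cm_A, cm_B, omap, modules, truth)


# ---------------------------------------------------------------- file output

def write_experiment(exp: SimulatedExperiment, outdir: str) -> dict:
    """Write counts/metadata TSVs, ortholog-map TSV, GMT modules and ground
    truth under ``outdir``; returns the path map."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "counts_A": os.path.join(outdir, "counts_A.tsv"),
        "counts_B": os.path.join(outdir, "counts_B.tsv"),
        "metadata": os.path.join(outdir, "metadata.tsv"),
        "orthologs": os.path.join(outdir, "orthologs.tsv"),
        "modules": os.path.join(outdir, "modules.gmt"),
        "true_fc": os.path.join(outdir, "true_module_fc.tsv"),
        "true_size_factors": os.path.join(outdir, "true_size_factors.tsv"),
    }
    exp.counts_A.counts.to_csv(paths["counts_A"], sep="\t", index_label="gene_id")
    exp.counts_B.counts.to_csv(paths["counts_B"], sep="\t", index_label="gene_id")
    meta = pd.concat([exp.counts_A.samples, exp.counts_B.samples])
    meta.to_csv(paths["metadata"], sep="\t")
    pd.DataFrame(exp.ortholog_map.pairs, columns=["gene_A", "gene_B"]).to_csv(
        paths["orthologs"], sep="\t", index=False
    )
    exp.modules.write_gmt(paths["modules"])
    exp.truth.true_fc.to_csv(paths["true_fc"], sep="\t", index_label="module")
    exp.truth.size_factors.rename("size_factor").to_csv(
        paths["true_size_factors"], sep="\t", index_label="sample_id"
    )
    return paths
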