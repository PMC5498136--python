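"""Pipeline configuration, orchestration and reporting.

A single configuration document drives the whole analysis chain:

    simulate -> join -> normalize -> fc -> deg -> cluster -> pca -> go -> slea -> report

Every stage reads its inputs from, and writes its outputs to, the run's
output directory, so stages can be re-run in isolation; a run manifest
records the resolved configuration, package versions, input checksums and
the row-count funnel after each filter.  One top-level seed
deterministically derives per-stage seeds.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import logging
import os
import platform
from dataclasses import dataclass, field, fields as dc_fields
from typing import Optional

import numpy as np
import pandas as pd

from . import enrichment, multivariate, ortholog
from . import slea as slea_mod
from .normalize import (
    FoldChangeMatrix, build_fc_matrix, default_contrasts,
    normalize as normalize_counts, size_factors,
)
from .ortholog import CountMatrix, CombinedMatrix

logger = logging.getLogger("crossheart")

__all__ = ["PipelineConfig", "PipelineError", "validate_config", "run_pipeline",
            "STAGES"]

STAGES = ("simulate", "join", "normalize", "fc", "deg", "cluster", "pca",
          "go", "slea", "report")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run.

    The threshold defaults are the reference analysis parameters: minimum
    total of 5 raw reads per ortholog pair, at least 5 normalized counts in
    every contrasted sample, DEGs at |log2 FC| >= 2, pathway-export genes at
    |log2 FC| > 1, SLEA significance above |Z| = 4 with 10,000 random
    modules, and enrichment FDR 0.05.
    """

    outdir: str = "crossheart_run"
    seed: int = 0
    simulate: bool = True
    # input files (ignored when simulate=True; then written under outdir/inputs)
    counts_a: Optional[str] = None
    counts_b: Optional[str] = None
    metadata: Optional[str] = None
    ortholog_map: Optional[str] = None
    gmt: Optional[str] = None
    obo: Optional[str] = None
    # thresholds
    min_total: int = 5
    min_norm: float = 5.0
    deg_fc: float = 2.0
    ipa_fc: float = 1.0
    z_cut: float = 4.0
    n_rand: int = 10000
    alpha: float = 0.05
    min_module_size: int = 5
    pseudocount: float = 1.0
    # mode switches
    scaling_mode: str = "minmax"
    pca_transform: str = "log2p1"
    strict_deg: bool = False
    per_species_min_sum: bool = False
    per_species_size_factors: bool = False
    go_background: str = "annotated"   # or "all"
    heatmap_clusters: int = 4
    matched_times: tuple = (6.0, 48.0, 72.0)

    def inputs_dir(self) -> str:
        return os.path.join(self.outdir, "inputs")

    def input_path(self, key: str) -> str:
        if self.simulate:
            names = {
                "counts_a": "counts_A.tsv", "counts_b": "counts_B.tsv",
                "metadata": "metadata.tsv", "ortholog_map": "orthologs.tsv",
                "gmt": "modules.gmt",
            }
            return os.path.join(self.inputs_dir(), names[key])
        return getattr(self, key)

    def config_hash(self) -> str:
        """Hash of the scientific parameters (output location excluded, so
        identical analyses in different directories hash identically)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir")
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        """Per-stage seed derived from the top-level seed (stable, < 2^31)."""
        ss = np.random.SeedSequence([int(self.seed), STAGES.index(stage)])
        return int(ss.generate_state(1)[0] % (2 ** 31))


def validate_config(config) -> PipelineConfig:
    """Build a PipelineConfig from a dict (or pass one through), injecting
    defaults and checking cross-field constraints.  Unknown keys are
    rejected with a closest-match suggestion."""
    if isinstance(config, PipelineConfig):
        cfg = config
    else:
        known = {f.name for f in dc_fields(PipelineConfig)}
        unknown = set(config) - known
        if unknown:
            key = sorted(unknown)[0]
            hint = difflib.get_close_matches(key, known, n=1)
            suggestion = f" (did you mean {hint[0]!r}?)" if hint else ""
            raise ValueError(f"unknown config key {key!r}{suggestion}")
        cfg = PipelineConfig(**config)

    for name in ("min_total", "min_norm", "deg_fc", "ipa_fc", "z_cut",
                 "n_rand", "alpha", "min_module_size", "pseudocount"):
        if getattr(cfg, name) < 0:
            raise ValueError(f"config key {name!r} must be non-negative")
    if cfg.n_rand < 2:
        raise ValueError("config key 'n_rand' must be >= 2")
    if cfg.scaling_mode not in ("minmax", "maxabs"):
        raise ValueError(f"unknown scaling_mode {cfg.scaling_mode!r}")
    if cfg.pca_transform not in ("log2p1", "raw"):
        raise ValueError(f"unknown pca_transform {cfg.pca_transform!r}")
    if cfg.go_background not in ("annotated", "all"):
        raise ValueError(f"unknown go_background {cfg.go_background!r}")
    if not cfg.simulate:
        for key in ("counts_a", "counts_b", "metadata", "ortholog_map", "gmt"):
            path = getattr(cfg, key)
            if path is None:
                raise ValueError(f"config key {key!r} required when simulate=false")
            if not os.path.exists(path):
                raise ValueError(f"config key {key!r}: file not found: {path}")
    logger.info("resolved config: %s", json.dumps(dataclasses.asdict(cfg),
                                                  sort_keys=True, default=str))
    return cfg


# ------------------------------------------------------------------ output IO

def _write_tsv(df: pd.DataFrame, path: str, stage: str, cfg: PipelineConfig,
               float_format: Optional[str] = None, index_label=None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# stage={stage} config={cfg.config_hash()}\n")
        df.to_csv(fh, sep="\t", float_format=float_format,
                  index_label=index_label)


def _read_tsv(path: str, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0, **kw)


def _out(cfg: PipelineConfig, name: str) -> str:
    return os.path.join(cfg.outdir, name)


def _load_combined(cfg: PipelineConfig) -> CombinedMatrix:
    counts = _read_tsv(_out(cfg, "combined_counts.tsv"))
    meta = ortholog.read_metadata(cfg.input_path("metadata"))
    meta = meta.loc[list(counts.columns)]
    split = [rid.partition("|") for rid in counts.index]
    pairs = pd.DataFrame(
        {"gene_A": [a for a, _, _ in split], "gene_B": [b for _, _, b in split]},
        index=counts.index,
    )
    return CombinedMatrix(counts, meta, pairs)


def _load_fc(cfg: PipelineConfig) -> FoldChangeMatrix:
    values = _read_tsv(_out(cfg, "fc_matrix.tsv"))
    contrasts = []
    for col in values.columns:
        sp, cond, t = col.split(":")
        contrasts.append((sp, cond, float(t.rstrip("h"))))
    return FoldChangeMatrix(values, contrasts, cfg.pseudocount)


# --------------------------------------------------------------------- stages

def stage_simulate(cfg: PipelineConfig) -> None:
    from .simulate import SimConfig, simulate_experiment, write_experiment

    if not cfg.simulate:
        logger.info("simulate: skipped (using provided input files)")
        return
    sim = SimConfig(seed=cfg.stage_seed("simulate"))
    exp = simulate_experiment(sim)
    write_experiment(exp, cfg.inputs_dir())
    logger.info("simulate: %d orthologs, %d+%d samples, %d modules",
                sim.n_orthologs, exp.counts_A.counts.shape[1],
                exp.counts_B.counts.shape[1], len(exp.modules))


def stage_join(cfg: PipelineConfig) -> None:
    counts_a = ortholog.read_counts(cfg.input_path("counts_a"))
    counts_b = ortholog.read_counts(cfg.input_path("counts_b"))
    meta = ortholog.read_metadata(cfg.input_path("metadata"))
    cm_a = CountMatrix(counts_a, meta.loc[list(counts_a.columns)])
    cm_b = CountMatrix(counts_b, meta.loc[list(counts_b.columns)])
    omap = ortholog.read_ortholog_map(cfg.input_path("ortholog_map"))
    combined = ortholog.join_counts(cm_a, cm_b, omap)
    n_joined = len(combined.counts)
    combined = ortholog.filter_min_sum(
        combined, cfg.min_total, per_species=cfg.per_species_min_sum
    )
    logger.info("join: %d pairs joined, %d pass min_total=%d",
                n_joined, len(combined.counts), cfg.min_total)
    _write_tsv(combined.counts, _out(cfg, "combined_counts.tsv"), "join", cfg,
               index_label="pair_id")


def stage_normalize(cfg: PipelineConfig) -> None:
    combined = _load_combined(cfg)
    sf = size_factors(
        combined, per_species=cfg.per_species_size_factors
    )
    normalized = normalize_counts(combined, sf)
    _write_tsv(sf.to_frame(), _out(cfg, "size_factors.tsv"), "normalize", cfg,
               float_format="%.6f", index_label="sample_id")
    _write_tsv(normalized, _out(cfg, "normalized_counts.tsv"), "normalize",
               cfg, float_format="%.6f", index_label="pair_id")


def stage_fc(cfg: PipelineConfig) -> None:
    combined = _load_combined(cfg)
    normalized = _read_tsv(_out(cfg, "normalized_counts.tsv"))
    contrasts = default_contrasts(combined.samples)
    fc = build_fc_matrix(
        normalized, combined.samples, contrasts,
        min_norm_per_timepoint=cfg.min_norm, pseudocount=cfg.pseudocount,
    )
    logger.info("fc: %d pairs x %d contrasts", *fc.values.shape)
    _write_tsv(fc.values, _out(cfg, "fc_matrix.tsv"), "fc", cfg,
               float_format="%.6f", index_label="pair_id")


def stage_deg(cfg: PipelineConfig) -> None:
    fc = _load_fc(cfg)
    degs = multivariate.select_degs(
        fc, cfg.deg_fc, strict=cfg.strict_deg
    )
    _write_tsv(pd.DataFrame(index=pd.Index(degs, name="pair_id")),
               _out(cfg, "deg_list.tsv"), "deg", cfg)
    upstream = slea_mod.upstream_input_prep(fc, cfg.ipa_fc)
    _write_tsv(upstream, _out(cfg, "upstream_input.tsv"), "deg", cfg,
               float_format="%.6f")


def stage_cluster(cfg: PipelineConfig) -> None:
    fc = _load_fc(cfg)
    degs = list(_read_tsv(_out(cfg, "deg_list.tsv")).index)
    if len(degs) < 2:
        logger.warning("cluster: <2 DEGs, skipping clustering outputs")
        return
    dendro = multivariate.cluster_heatmap(
        fc.values.loc[degs], render_to=_out(cfg, "heatmap.png")
    )
    with open(_out(cfg, "dendrogram.newick"), "w") as fh:
        fh.write(dendro.to_newick() + "\n")
    k = min(cfg.heatmap_clusters, len(degs))
    clusters = multivariate.discordant_clusters(
        FoldChangeMatrix(fc.values.loc[degs], fc.contrasts,
                              cfg.pseudocount),
        dendro, k=k, matched_times=cfg.matched_times,
    )
    _write_tsv(clusters.set_index("cluster"), _out(cfg, "clusters.tsv"),
               "cluster", cfg, float_format="%.6f")


def stage_pca(cfg: PipelineConfig) -> None:
    combined = _load_combined(cfg)
    normalized = _read_tsv(_out(cfg, "normalized_counts.tsv"))
    pca = multivariate.run_pca(
        normalized, combined.samples, transform=cfg.pca_transform
    )
    _write_tsv(pca.scores, _out(cfg, "pca_scores.tsv"), "pca", cfg,
               float_format="%.6f", index_label="sample_id")
    _write_tsv(pca.loadings, _out(cfg, "pca_loadings.tsv"), "pca", cfg,
               float_format="%.6f", index_label="pair_id")
    var = pd.DataFrame(
        {"variance_fraction": pca.variance_explained},
        index=pd.Index(pca.scores.columns, name="component"),
    )
    _write_tsv(var, _out(cfg, "pca_variance.tsv"), "pca", cfg,
               float_format="%.6f")
    logger.info("pca: PC1+PC2 capture %.1f%% of the variance",
                100 * pca.variance_explained[:2].sum())
    _render_pca(pca, combined.samples, _out(cfg, "pca.png"))


def _render_pca(pca, samples, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for sp, marker in zip(sorted(samples["species"].unique()), "os^v"):
        ids = [s for s in pca.scores.index
               if samples.loc[s, "species"] == sp]
        ax.scatter(pca.scores.loc[ids, "PC1"], pca.scores.loc[ids, "PC2"],
                   marker=marker, label=f"species {sp}")
    ax.set_xlabel(f"PC1 ({100 * pca.variance_explained[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * pca.variance_explained[1]:.1f}%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def stage_go(cfg: PipelineConfig) -> None:
    fc = _load_fc(cfg)
    degs = list(_read_tsv(_out(cfg, "deg_list.tsv")).index)
    modules = enrichment.read_gmt(cfg.input_path("gmt"))
    if cfg.obo:
        parents = enrichment.read_obo_parents(cfg.obo)
        modules = enrichment.propagate_annotations(modules, parents)
    # FC rows are pair ids; enrichment runs in the species-A id space
    measured = {rid.partition("|")[0] for rid in fc.values.index}
    deg_genes = {rid.partition("|")[0] for rid in degs}
    if cfg.go_background == "annotated":
        annotated = set().union(*modules.modules.values())
        universe = measured & annotated
        selected = deg_genes & universe
    else:
        universe = measured
        selected = deg_genes
    if not universe:
        raise ValueError("empty enrichment universe (no annotated measured genes)")
    table = enrichment.enrich(
        selected, universe, modules, alpha=cfg.alpha,
        min_module_size=cfg.min_module_size,
    )
    _write_tsv(table.set_index("module"), _out(cfg, "go_enrichment.tsv"),
               "go", cfg, float_format="%.6g")


def stage_slea(cfg: PipelineConfig) -> None:
    fc = _load_fc(cfg)
    modules = enrichment.read_gmt(cfg.input_path("gmt"))
    scaled = slea_mod.scale_center(fc, mode=cfg.scaling_mode)
    result = slea_mod.slea_z(
        scaled, modules, n_rand=cfg.n_rand, seed=cfg.stage_seed("slea"),
        min_size=cfg.min_module_size, z_cut=cfg.z_cut,
    )
    _write_tsv(result.z, _out(cfg, "slea_z.tsv"), "slea", cfg,
               float_format="%.6f", index_label="module")
    sig = slea_mod.call_significant(result, cfg.z_cut)
    _write_tsv(sig.set_index("module"), _out(cfg, "slea_significant.tsv"),
               "slea", cfg, float_format="%.6f")
    try:
        ranking = slea_mod.differential_response(
            result, matched_times=cfg.matched_times
        )
        _write_tsv(ranking.set_index("module"),
                   _out(cfg, "differential_response.tsv"), "slea", cfg,
                   float_format="%.6f")
    except ValueError as exc:
        logger.warning("slea: differential response skipped (%s)", exc)
    _render_slea(result, _out(cfg, "slea_heatmap.png"))


def _render_slea(result, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    clipped = result.z.clip(-10, 10)  # display clip only; raw Z is stored
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * clipped.shape[1]), max(3, 0.3 * len(clipped)))
    )
    im = ax.imshow(clipped.to_numpy(), cmap="RdBu_r", vmin=-10, vmax=10,
                   aspect="auto", interpolation="nearest")
    ax.set_xticks(range(clipped.shape[1]))
    ax.set_xticklabels(clipped.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(clipped)))
    ax.set_yticklabels(clipped.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="SLEA Z (clipped at ±10)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def stage_report(cfg: PipelineConfig) -> None:
    import crossheart

    def _sha(path):
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            h.update(fh.read())
        return h.hexdigest()[:16]

    funnel = {}
    for name, fname in (("joined_pairs", "combined_counts.tsv"),
                        ("fc_pairs", "fc_matrix.tsv"),
                        ("degs", "deg_list.tsv")):
        path = _out(cfg, fname)
        if os.path.exists(path):
            funnel[name] = len(_read_tsv(path))
    manifest = {
        "package": "crossheart",
        "version": crossheart.__version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "thresholds": {
            "min_total": cfg.min_total, "min_norm": cfg.min_norm,
            "deg_fc": cfg.deg_fc, "ipa_fc": cfg.ipa_fc, "z_cut": cfg.z_cut,
            "n_rand": cfg.n_rand, "alpha": cfg.alpha,
        },
        "config": dataclasses.asdict(cfg),
        "input_checksums": {
            key: _sha(cfg.input_path(key))
            for key in ("counts_a", "counts_b", "metadata", "ortholog_map", "gmt")
            if cfg.input_path(key) and os.path.exists(cfg.input_path(key))
        },
        "funnel": funnel,
    }
    with open(_out(cfg, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


_STAGE_FUNCS = {
    "simulate": stage_simulate, "join": stage_join,
    "normalize": stage_normalize, "fc": stage_fc, "deg": stage_deg,
    "cluster": stage_cluster, "pca": stage_pca, "go": stage_go,
    "slea": stage_slea, "report": stage_report,
}


def run_stage(cfg: PipelineConfig, stage: str) -> None:
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}")
    os.makedirs(cfg.outdir, exist_ok=True)
    try:
        _STAGE_FUNCS[stage](cfg)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc


def run_pipeline(config) -> str:
    """Run every stage in order; returns the output directory."""
    cfg = validate_config(config)
    os.makedirs(cfg.outdir, exist_ok=True)
    for stage in STAGES:
        logger.info("=== stage %s ===", stage)
        run_stage(cfg, stage)
    return cfg.outdir
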