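"""End-to-end pipeline: network + per-gene statistics -> ranked genes,
resampling profile, and extracted module.

Two branches mirror the two kinds of input statistics:

* descriptive — two per-group vectors (e.g. per-group mutation
  frequencies f1, f2) are each smoothed and subtracted (dS);
* inferential — one vector (e.g. lfcp) is optionally binarised to its
  top-N genes, smoothed, and permutation-adjusted (Sp).

Either ranking then feeds the network-resampling profile and the module
cut.  Genes absent from the network are carried through the output with
dS = Sp = 0.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .estimators import ModuleDetector, NetworkSmoother, SpScorer
from .indices import binarize_top, delta_smoothing_index, smoothing_index
from .interactome import align_scores, read_edge_list
from .io import read_scores, write_rnk, write_sif

logger = logging.getLogger("diffmod")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    network: str
    mode: str  # "descriptive" | "inferential"
    outdir: str
    scores_cases: str | None = None  # descriptive: u2 / f2
    scores_controls: str | None = None  # descriptive: u1 / f1
    scores: str | None = None  # inferential: u
    score_column: int | None = None
    min_score: float | None = None
    alpha: float = 0.7
    epsilon: float | None = None  # default depends on mode
    tol: float = 1e-6
    n_perm: int = 1000
    k: int = 100
    n_max: int | None = None
    threshold: float = 0.05
    top_n: int | None = None  # inferential binarisation; None = raw vector
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("descriptive", "inferential"):
            raise ValueError(f"mode must be descriptive or inferential, got {self.mode!r}")
        if self.mode == "descriptive" and not (self.scores_cases and self.scores_controls):
            raise ValueError("descriptive mode requires scores_cases and scores_controls")
        if self.mode == "inferential" and not self.scores:
            raise ValueError("inferential mode requires scores")
        if self.epsilon is None:
            # 0.25 suits descriptive (frequency-like) inputs, 1 inferential
            self.epsilon = 0.25 if self.mode == "descriptive" else 1.0
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


_CONFIG_TYPES = {
    "score_column": int, "n_perm": int, "k": int, "n_max": int, "top_n": int,
    "seed": int, "alpha": float, "epsilon": float, "tol": float,
    "min_score": float, "threshold": float,
}


def load_config(path) -> PipelineConfig:
    """Read a flat key=value (or key<TAB>value) config file."""
    kv = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" in line:
                key, _, val = line.partition("=")
            else:
                key, _, val = line.partition("\t")
            key, val = key.strip(), val.strip()
            kv[key] = _CONFIG_TYPES[key](val) if key in _CONFIG_TYPES else val
    return PipelineConfig(**kv)


def _stage(name):
    logger.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured branch and write all outputs.

    Returns a dict of output paths.  On failure the partially written
    output files are removed and the stage error is re-raised with the
    stage name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        stage = "read network"
        t0 = _stage(stage)
        net = read_edge_list(config.network, config.score_column, config.min_score)
        logger.info("network: %d genes, %d links (%.2fs)", net.n_nodes, net.n_edges, time.perf_counter() - t0)

        genes = list(net.nodes)
        unmapped_all: set[str] = set()
        if config.mode == "descriptive":
            stage = "smooth descriptive statistics"
            _stage(stage)
            smoother = NetworkSmoother(alpha=config.alpha, epsilon=config.epsilon, tol=config.tol).fit(net)
            u1 = read_scores(config.scores_controls)
            u2 = read_scores(config.scores_cases)
            x1, un1 = align_scores(u1, net)
            x2, un2 = align_scores(u2, net)
            unmapped_all = set(un1) | set(un2)
            S1 = smoothing_index(smoother.propagate(x1), x1, config.epsilon, config.alpha, "u1", tuple(genes))
            S2 = smoothing_index(smoother.propagate(x2), x2, config.epsilon, config.alpha, "u2", tuple(genes))
            delta = delta_smoothing_index(S2, S1)
            score_vec = delta.delta_S
            table = pd.DataFrame({
                "gene": genes, "u1": x1, "u2": x2,
                "S1": S1.S, "S2": S2.S, "delta_S": score_vec,
            })
            score_name = "delta_S"
        else:
            stage = "smooth inferential statistic"
            _stage(stage)
            u = read_scores(config.scores)
            x, un = align_scores(u, net)
            unmapped_all = set(un)
            if config.top_n:
                x = binarize_top(x, genes, config.top_n)
            scorer = SpScorer(
                alpha=config.alpha, epsilon=config.epsilon,
                n_perm=config.n_perm, random_state=config.seed,
            ).fit(net)
            sp = scorer.transform(x)
            table = pd.DataFrame({
                "gene": genes, "u": x, "S": scorer.S_, "p": scorer.p_values_, "Sp": sp,
            })
            score_vec = sp
            score_name = "Sp"

        if unmapped_all:
            frac = len(unmapped_all) / (len(unmapped_all) + net.n_nodes)
            log = logger.warning if frac > 0.5 else logger.info
            log("%d input genes not in the network (%.0f%%)", len(unmapped_all), 100 * frac)
            extra = pd.DataFrame({"gene": sorted(unmapped_all)})
            for col in table.columns[1:]:
                extra[col] = 0.0
            table = pd.concat([table, extra], ignore_index=True)

        stage = "rank genes"
        table = table.sort_values("gene", ignore_index=True)
        ranked_path = outdir / "ranked_genes.tsv"
        table.to_csv(ranked_path, sep="\t", index=False, float_format="%.10g")
        written.append(ranked_path)
        rnk_path = outdir / f"{score_name}.rnk"
        write_rnk(rnk_path, table["gene"], table[score_name])
        written.append(rnk_path)

        stage = "network resampling"
        _stage(stage)
        scores_map = dict(zip(genes, score_vec))
        detector = ModuleDetector(
            k=config.k, n_max=config.n_max, threshold=config.threshold,
            random_state=config.seed,
        )
        empty_module = not any(v > 0 for v in scores_map.values())
        if empty_module:
            logger.warning("no positive %s: module is empty", score_name)
            profile = pd.DataFrame(columns=["n", "omega", "p_nr"])
            module_genes: tuple = ()
            module_edges: tuple = ()
            n_star = first_sig = 0
        else:
            detector.fit(net, scores_map)
            profile = detector.profile_
            module_genes = detector.module_genes_
            module_edges = detector.module_edges_
            n_star = detector.n_star_
            first_sig = detector.first_significant_rank_

        profile_path = outdir / "resampling_profile.tsv"
        profile.to_csv(profile_path, sep="\t", index=False, float_format="%.10g")
        written.append(profile_path)
        module_path = outdir / "module_genes.tsv"
        pd.DataFrame({"gene": list(module_genes)}).to_csv(module_path, sep="\t", index=False)
        written.append(module_path)
        sif_path = outdir / "module_edges.sif"
        write_sif(sif_path, module_edges)
        written.append(sif_path)

        stage = "metadata"
        meta = {
            "diffmod_version": __version__,
            "parameters": {k: v for k, v in asdict(config).items()},
            "n_network_genes": net.n_nodes,
            "n_network_edges": net.n_edges,
            "n_unmapped_genes": len(unmapped_all),
            "unmapped_genes": sorted(unmapped_all),
            "score_name": score_name,
            "n_star": int(n_star),
            "first_significant_rank": int(first_sig),
            "module_size": len(module_genes),
        }
        meta_path = outdir / "run_metadata.json"
        meta_path.write_text(json.dumps(meta, indent=2))
        written.append(meta_path)
        return {p.name: p for p in written}
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
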