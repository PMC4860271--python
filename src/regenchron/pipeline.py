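"""End-to-end orchestration: simulate/load -> contrasts -> episodes -> clustering -> ORA.

A run is described by a :class:`RunConfig` (typically parsed from YAML):
either paths to a normalized log2 matrix plus sample metadata, or an
inline simulation block, never both.  Outputs land in a fixed layout
under the chosen directory together with ``manifest.json`` recording the
configuration, the seed, per-stage row counts and a content hash of
every file, so identical config + seed reruns are byte-identical.

The run seed is expanded through ``numpy.random.SeedSequence`` into
independent substreams (simulation, jackknife, bootstrap), so stages can
be rerun in isolation with the same draws.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from regenchron._version import __version__
from regenchron.clustering import bootstrap_support, jackknife_consensus
from regenchron.differential import (
    DEConfig,
    run_adjacent_contrasts,
    run_baseline_contrasts,
)
from regenchron.enrichment import annotated_universe, enrich, probes_to_genes
from regenchron.episodes import (
    baseline_divergence_counts,
    cumulative_first_detection,
    detect_episodes,
    episodes_table,
    times_significant_histogram,
)
from regenchron.io import (
    read_expression_matrix,
    read_gene_sets,
    read_probe_annotation,
    read_sample_table,
    validate_expression_matrix,
    write_expression_matrix,
    write_results_table,
    write_sample_table,
)
from regenchron.simulate import SimConfig, simulate_timecourse

logger = logging.getLogger(__name__)

_SIM_KEYS = {f.name for f in dataclasses.fields(SimConfig)}
_KNOWN_KEYS = {
    "matrix",
    "samples",
    "annotation",
    "gene_sets",
    "simulation",
    "p_threshold",
    "fc",
    "episode_mode",
    "family_alpha",
    "n_jackknife",
    "n_bootstrap",
    "seed",
    "out_dir",
}


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    matrix: str | None = None
    samples: str | None = None
    annotation: str | None = None
    gene_sets: str | None = None
    simulation: SimConfig | None = None
    de: DEConfig = field(default_factory=DEConfig)
    episode_mode: str = "increase"
    family_alpha: float = 0.05
    n_jackknife: int = 1000
    n_bootstrap: int = 1000
    seed: int = 0
    out_dir: str = "regenchron_out"


def validate_config(raw: dict[str, Any]) -> RunConfig:
    """Normalize a raw (YAML/flag) mapping into a :class:`RunConfig`.

    Defaults: p 0.01, fold change 1.5, family alpha 0.05, 1000
    resampling iterations.  Exactly one of (matrix+samples paths |
    simulation block) must be present; ``fc`` is given on the fold
    scale and converted to log2.
    """
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    has_paths = raw.get("matrix") is not None or raw.get("samples") is not None
    has_sim = raw.get("simulation") is not None
    if has_paths and has_sim:
        raise ValueError("config must give either input paths or a simulation block, not both")
    if has_paths and (raw.get("matrix") is None or raw.get("samples") is None):
        raise ValueError("matrix and samples paths must be given together")
    if not has_paths and not has_sim:
        raise ValueError("config needs input paths or a simulation block")

    sim = None
    if has_sim:
        sim_raw = dict(raw["simulation"] or {})
        unknown_sim = set(sim_raw) - _SIM_KEYS
        if unknown_sim:
            raise ValueError(f"unknown simulation key(s): {sorted(unknown_sim)}")
        if "schedule" in sim_raw:
            sim_raw["schedule"] = tuple(sim_raw["schedule"])
        if "scale_choices" in sim_raw:
            sim_raw["scale_choices"] = tuple(sim_raw["scale_choices"])
        sim = SimConfig(**sim_raw)

    fc = float(raw.get("fc", 1.5))
    if fc < 1:
        raise ValueError("fold-change cutoff must be >= 1")
    de = DEConfig(
        p_threshold=float(raw.get("p_threshold", 0.01)),
        fc_threshold_log2=float(np.log2(fc)),
    )
    mode = raw.get("episode_mode", "increase")
    if mode not in ("increase", "decrease"):
        raise ValueError(f"episode_mode must be increase or decrease, got {mode!r}")
    cfg = RunConfig(
        matrix=raw.get("matrix"),
        samples=raw.get("samples"),
        annotation=raw.get("annotation"),
        gene_sets=raw.get("gene_sets"),
        simulation=sim,
        de=de,
        episode_mode=mode,
        family_alpha=float(raw.get("family_alpha", 0.05)),
        n_jackknife=int(raw.get("n_jackknife", 1000)),
        n_bootstrap=int(raw.get("n_bootstrap", 1000)),
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", "regenchron_out")),
    )
    if not 0 < cfg.family_alpha < 1:
        raise ValueError("family_alpha must lie in (0, 1)")
    return cfg


def _substream_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(3)
    names = ("simulation", "jackknife", "bootstrap")
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and write artifacts plus ``manifest.json``.

    Returns the output directory.  On a stage failure the manifest is
    persisted with the stages completed so far and the error re-raised
    with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _substream_seeds(config.seed)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "substream_seeds": seeds,
        "config": _config_dict(config),
        "stages": {},
        "files": {},
    }
    stage = "setup"
    try:
        stage = "input"
        t0 = time.perf_counter()
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation, seed=seeds["simulation"])
            matrix, samples, truth = simulate_timecourse(sim)
            write_expression_matrix(matrix, out / "matrix.tsv")
            write_sample_table(samples, out / "samples.tsv")
            write_results_table(truth.probes, out / "sim_truth_probes.tsv")
            annotation = None
        else:
            matrix = read_expression_matrix(config.matrix)
            samples = read_sample_table(config.samples)
            validate_expression_matrix(matrix, samples)
            annotation = (
                read_probe_annotation(config.annotation) if config.annotation else None
            )
        manifest["stages"][stage] = {
            "n_probes": int(matrix.shape[0]),
            "n_samples": int(matrix.shape[1]),
            "seconds": round(time.perf_counter() - t0, 3),
        }

        stage = "differential"
        t0 = time.perf_counter()
        baseline = run_baseline_contrasts(matrix, samples, config.de)
        adjacent = run_adjacent_contrasts(matrix, samples, config.de)
        write_results_table(baseline.summaries, out / "baseline_summary.tsv")
        write_results_table(adjacent.summaries, out / "adjacent_summary.tsv")
        baseline.calls.reset_index().to_csv(out / "baseline_calls.tsv", sep="\t", index=False)
        adjacent.calls.reset_index().to_csv(out / "adjacent_calls.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "n_baseline_contrasts": len(baseline.specs),
            "n_adjacent_contrasts": len(adjacent.specs),
            "seconds": round(time.perf_counter() - t0, 3),
        }

        stage = "episodes"
        t0 = time.perf_counter()
        episode_calls = detect_episodes(
            adjacent.calls, mode=config.episode_mode, family_alpha=config.family_alpha
        )
        write_results_table(episodes_table(episode_calls), out / "episodes.tsv")
        divergence = baseline_divergence_counts(baseline.calls)
        write_results_table(divergence.per_day, out / "divergence_counts.tsv")
        records, curve = cumulative_first_detection(baseline.calls)
        write_results_table(records, out / "first_detection.tsv")
        write_results_table(curve, out / "first_detection_curve.tsv")
        hist = times_significant_histogram(baseline.calls)
        write_results_table(hist.reset_index(), out / "times_significant_histogram.tsv")
        manifest["stages"][stage] = {
            "n_comparisons": episode_calls[0].n_comparisons if episode_calls else 0,
            "n_flagged": sum(c.flagged for c in episode_calls),
            "flagged_intervals": [c.contrast_later for c in episode_calls if c.flagged],
            "n_unique_significant": divergence.n_unique,
            "grand_total_significant": divergence.grand_total,
            "seconds": round(time.perf_counter() - t0, 3),
        }

        stage = "clustering"
        t0 = time.perf_counter()
        jack = jackknife_consensus(
            matrix, samples, n_iter=config.n_jackknife, seed=seeds["jackknife"]
        )
        boot = bootstrap_support(
            matrix, samples, n_iter=config.n_bootstrap, seed=seeds["bootstrap"]
        )
        (out / "jackknife_consensus.nwk").write_text(jack.tree.to_newick(jack.support) + "\n")
        (out / "bootstrap_tree.nwk").write_text(boot.tree.to_newick(boot.support) + "\n")
        manifest["stages"][stage] = {
            "n_jackknife": jack.n_iterations,
            "n_bootstrap": boot.n_iterations,
            "seconds": round(time.perf_counter() - t0, 3),
        }

        stage = "enrichment"
        t0 = time.perf_counter()
        if annotation is not None and config.gene_sets:
            gene_sets = read_gene_sets(config.gene_sets)
            universe = annotated_universe(annotation)
            n_rows = 0
            for call in episode_calls:
                if not call.flagged:
                    continue
                col = adjacent.calls[call.contrast_later]
                probe_hits = col.index[col.isin(("up", "down"))]
                hits = probes_to_genes(probe_hits, annotation)
                table = enrich(hits, gene_sets, universe)
                write_results_table(
                    table, out / f"enrichment_{call.contrast_later.replace('.', '_')}.tsv"
                )
                n_rows += len(table)
            manifest["stages"][stage] = {
                "n_tables": sum(c.flagged for c in episode_calls),
                "n_rows": n_rows,
                "seconds": round(time.perf_counter() - t0, 3),
            }
        else:
            manifest["stages"][stage] = {"skipped": "no annotation/gene sets supplied"}
    except Exception as exc:
        manifest["error"] = {"stage": stage, "message": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for path in sorted(out.iterdir()):
        if path.name != "manifest.json" and path.is_file():
            manifest["files"][path.name] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _config_dict(config: RunConfig) -> dict[str, Any]:
    d = dataclasses.asdict(config)
    if d.get("simulation") is not None:
        d["simulation"]["schedule"] = list(d["simulation"]["schedule"])
        d["simulation"]["scale_choices"] = list(d["simulation"]["scale_choices"])
        d["simulation"]["archetype_mix"] = dict(d["simulation"]["archetype_mix"])
    return d
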