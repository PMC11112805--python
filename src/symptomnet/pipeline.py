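"""End-to-end analysis pipeline and report bundle.

Runs simulate/load -> per-wave network estimation -> centrality ->
stability -> longitudinal comparisons -> responder classification,
matching and the matched-group comparison, writing every table, figure
and a machine-readable manifest to an output directory.  All randomness
descends from one master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .centrality import centrality_long, centrality_table
from .comparison import nct, paired_complete_cases
from .network import connectivity, estimate_network, export_network
from .outcomes import NON_RESPONDER, RESPONDER, classify_responders, match_on_total
from .scale import (
    TimepointMatrix,
    complete_cases,
    cronbach_alpha,
    load_cohort,
    summarize_cohort,
)
from .simulate import GeneratorConfig, default_config, generate
from .stability import DEFAULT_GRID, bootstrap_edges, case_drop_bootstrap, cs_coefficient
from .viz import fr_layout, render_network

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """What to run and at what problem sizes."""

    out_dir: str | Path = "results/run"
    cohort_csv: str | Path | None = None  # load this file, or simulate when None
    generator: GeneratorConfig | None = None
    seed: int = 0
    edge_bootstraps: int = 500
    cs_bootstraps: int = 100
    cs_grid: tuple[float, ...] = DEFAULT_GRID
    permutations: int = 1000
    display_min: float = 0.1
    scale_max: float | None = None
    make_figures: bool = True


class StageError(RuntimeError):
    """A pipeline stage failed; earlier outputs are preserved."""


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(
        {k: str(v) for k, v in vars(config).items()}, sort_keys=True
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "version": __version__,
        "outputs": [],
    }

    def record(path: Path) -> None:
        manifest["outputs"].append(str(path.relative_to(out)))

    def stage(name: str):
        logger.info("pipeline stage: %s", name)
        return name

    current = stage("cohort")
    try:
        if config.cohort_csv is not None:
            cohort = load_cohort(config.cohort_csv)
        else:
            gen = config.generator or default_config(seed=config.seed)
            cohort = generate(gen)
            path = out / "cohort.csv"
            cohort.data.to_csv(path, index=False)
            record(path)

        current = stage("summary")
        summary = summarize_cohort(cohort)
        path = out / "summary.csv"
        summary.to_csv(path, index=False)
        record(path)

        waves = cohort.present_timepoints()
        matrices: dict[str, TimepointMatrix] = {}
        networks = {}
        current = stage("estimation")
        for tp in waves:
            matrices[tp] = complete_cases(cohort, tp)
            networks[tp] = estimate_network(matrices[tp])
            for p in export_network(networks[tp], out / f"network_{tp}", config.display_min):
                record(p)
        manifest["connectivity"] = {
            tp: connectivity(networks[tp]) for tp in waves
        }
        manifest["cronbach_alpha"] = {waves[0]: cronbach_alpha(matrices[waves[0]])}

        current = stage("centrality")
        for tp in waves:
            table = centrality_table(networks[tp])
            path = out / f"centrality_{tp}.csv"
            centrality_long(table).to_csv(path, index=False)
            record(path)

        if config.make_figures:
            current = stage("figures")
            layout = fr_layout(networks[waves[0]], seed=config.seed)
            observed_max = max(
                float(np.abs(networks[tp].weights).max()) for tp in waves
            )
            scale_max = config.scale_max or observed_max
            for tp in waves:
                path = render_network(
                    networks[tp], layout, out / f"network_{tp}.png",
                    display_min=config.display_min, scale_max=scale_max, title=tp,
                )
                record(path)

        current = stage("stability")
        base_tp = waves[0]
        ebr = bootstrap_edges(
            matrices[base_tp], B=config.edge_bootstraps, seed=config.seed
        )
        path = out / "edge_bootstrap.csv"
        ebr.table.to_csv(path, index=False)
        record(path)
        csr = case_drop_bootstrap(
            matrices[base_tp], grid=config.cs_grid, B_per=config.cs_bootstraps,
            seed=config.seed,
        )
        path = out / "cs_quantiles.csv"
        csr.quantiles.to_csv(path, index=False)
        record(path)
        cs = cs_coefficient(csr)
        path = out / "cs_coefficients.csv"
        cs.to_csv(path, index=False)
        record(path)
        manifest["cs_coefficients"] = dict(zip(cs["index"], cs["cs"]))

        current = stage("longitudinal_nct")
        targets = [t for t in ("end", "followup12m") if t in waves[1:]]
        if not targets and len(waves) > 1:
            targets = [waves[-1]]
        manifest["longitudinal_nct"] = {}
        for tp in targets:
            a, b = paired_complete_cases(cohort, waves[0], tp)
            res = nct(a, b, design="paired", B=config.permutations, seed=config.seed)
            payload = {
                "s1": res.s1, "s2": res.s2,
                "global_strength_stat": res.global_strength_stat,
                "global_strength_p": res.global_strength_p,
                "structure_stat": res.structure_stat,
                "structure_p": res.structure_p,
                "design": res.design, "B": res.B,
                "edges_gated": res.edges_gated,
            }
            path = out / f"nct_{waves[0]}_vs_{tp}.json"
            path.write_text(json.dumps(payload, indent=2))
            record(path)
            path = out / f"nct_{waves[0]}_vs_{tp}_edges.csv"
            res.edge_table.to_csv(path, index=False)
            record(path)
            manifest["longitudinal_nct"][f"{waves[0]}_vs_{tp}"] = payload

        current = stage("responders")
        if "followup12m" in waves:
            labels = classify_responders(cohort, baseline=waves[0])
            path = out / "responder_labels.csv"
            labels.to_csv(path, index=False)
            record(path)
            match = match_on_total(labels, seed=config.seed)
            path = out / "match.csv"
            match.matched.assign(kept=True).to_csv(path, index=False)
            record(path)
            manifest["responders"] = {
                "n_responder": int((labels["label"] == RESPONDER).sum()),
                "n_non_responder": int((labels["label"] == NON_RESPONDER).sum()),
                "n_unclassified": int((labels["label"] == "unclassified").sum()),
                "n_matched_per_group": match.n_per_group,
                "n_excluded": len(match.excluded),
            }

            current = stage("matched_nct")
            base = matrices[waves[0]]
            idx = {sid: i for i, sid in enumerate(base.subject_ids)}
            groups = {}
            for grp in (RESPONDER, NON_RESPONDER):
                rows = [idx[s] for s in match.ids(grp) if s in idx]
                groups[grp] = TimepointMatrix(
                    values=np.asarray(base.values)[rows],
                    subject_ids=np.asarray([s for s in match.ids(grp) if s in idx]),
                    timepoint=base.timepoint,
                    scale=base.scale,
                )
            res = nct(
                groups[RESPONDER], groups[NON_RESPONDER], design="independent",
                B=config.permutations, seed=config.seed,
            )
            payload = {
                "s_responder": res.s1, "s_non_responder": res.s2,
                "global_strength_stat": res.global_strength_stat,
                "global_strength_p": res.global_strength_p,
                "structure_stat": res.structure_stat,
                "structure_p": res.structure_p,
                "design": res.design, "B": res.B,
            }
            path = out / "nct_matched_groups.json"
            path.write_text(json.dumps(payload, indent=2))
            record(path)
            manifest["matched_nct"] = payload
    except Exception as exc:
        raise StageError(f"pipeline stage {current!r} failed: {exc}") from exc

    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return manifest
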