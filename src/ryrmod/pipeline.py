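"""End-to-end orchestration: simulate -> screen -> enrich -> interact -> calcium.

A run is described by a :class:`RunConfig` (usually loaded from YAML).  One
integer seed in the config is expanded deterministically into per-stage seeds
via ``numpy.random.SeedSequence``, so re-running an identical config
reproduces byte-identical outputs; the emitted manifest records every
parameter, row counts and output checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import calcium as ca
from . import chem, interaction, io, synthetic, worm

__all__ = ["RunConfig", "run_pipeline", "load_config", "report"]

logger = logging.getLogger(__name__)

STAGES = ["simulate", "worm", "chem", "interact", "calcium", "qpcr"]


@dataclass
class RunConfig:
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    out_dir: str = "results"
    seed: int = 0
    params: dict = field(default_factory=dict)  # per-stage parameter maps

    def __post_init__(self):
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid stages: {STAGES}")


def load_config(path: str | Path) -> RunConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(
        stages=raw.get("stages", list(STAGES)),
        out_dir=raw.get("out_dir", "results"),
        seed=int(raw.get("seed", 0)),
        params=raw.get("params", {}),
    )


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {s: int(c.generate_state(1)[0] % (2**31)) for s, c in zip(STAGES, children)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages on synthetic data and write TSV outputs
    plus a JSON manifest to ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    p = config.params
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages": {},
        "params": p,
        "warnings": [],
    }

    wells = None
    if "simulate" in config.stages or "worm" in config.stages:
        sp = p.get("worm", {})
        rescue = {
            str(k): tuple(v) for k, v in sp.get("rescue_effect", {"chem0000": (0.05, 0.45, 0.5)}).items()
        }
        spec = synthetic.WormScreenSpec(
            n_conditions=int(sp.get("n_conditions", 50)),
            wells_per_condition=int(sp.get("wells_per_condition", 2)),
            per_worm_escape_prob=float(
                sp.get(
                    "per_worm_escape_prob",
                    synthetic.per_worm_escape_prob_for_well_rate(0.08),
                )
            ),
            rescue_effect=rescue,
            n_control_wells=int(sp.get("n_control_wells", 100)),
            seed=seeds["simulate"],
        )
        wells = synthetic.gen_worm_screen(spec)
        io.write_worm_wells(wells, out / "worm_wells.tsv")
        manifest["stages"]["simulate"] = {"rows_out": len(wells)}

    if "worm" in config.stages:
        sp = p.get("worm", {})
        calls, rate_pct = worm.call_hits(
            wells,
            min_escaped=int(sp.get("min_escaped", 1)),
            require_all_replicates=bool(sp.get("require_all_replicates", True)),
        )
        hits_df = pd.DataFrame(
            {
                "condition_id": [c.condition_id for c in calls],
                "escaped_per_replicate": [
                    ",".join(map(str, c.escaped_per_replicate)) for c in calls
                ],
                "is_primary_hit": [c.is_primary_hit for c in calls],
            }
        )
        hits_df.to_csv(out / "worm_hits.tsv", sep="\t", index=False)
        frac, n_esc, n_tot = worm.escapee_rate(wells[wells["is_control"]])
        manifest["stages"]["worm"] = {
            "rows_in": len(wells),
            "rows_out": len(hits_df),
            "hit_rate_pct": rate_pct,
            "control_escapee_pct": round(100 * frac, 1),
        }

    if "chem" in config.stages:
        sp = p.get("chem", {})
        lib_spec = synthetic.LibrarySpec(
            n_compounds=int(sp.get("n_compounds", 200)),
            n_clusters=int(sp.get("n_clusters", 3)),
            cluster_sizes=tuple(sp.get("cluster_sizes", (8, 8, 8))),
            hit_rate_per_cluster={0: 0.8, 1: 0.8, 2: 0.8},
            seed=seeds["chem"],
        )
        library = synthetic.gen_chemical_library(lib_spec)
        io.write_fingerprints(library, out / "library.tsv")
        dend, clusters = chem.clusters_from_records(
            library,
            tanimoto_threshold=float(sp.get("tanimoto_threshold", 0.55)),
            cut=sp.get("cut", "auto"),
        )
        groups = {f"cluster{c.cluster_id}": c.member_ids for c in clusters if len(c.member_ids) > 1}
        enr = chem.enrichment_report(groups, library)
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        _heatmap(chem.pairwise_tanimoto(library), dend, out / "tanimoto_heatmap.png")
        manifest["stages"]["chem"] = {
            "rows_in": len(library),
            "rows_out": len(enr),
            "n_clusters": len(clusters),
        }

    if "interact" in config.stages:
        sp = p.get("interact", {})
        spec = synthetic.SpeedSpec(
            n_per_group=int(sp.get("n_per_group", 20)),
            genotype_effect=float(sp.get("genotype_effect", 0.5)),
            chemical_effect=float(sp.get("chemical_effect", 0.8)),
            interaction_model=sp.get("interaction_model", "custom"),
            epsilon=float(sp.get("epsilon", 0.3)),
            noise_sd=float(sp.get("noise_sd", 0.1)),
            seed=seeds["interact"],
        )
        speeds = synthetic.gen_speed_dataset(spec)
        io.write_speeds(speeds, out / "speeds.tsv")
        res = interaction.interaction_test(
            speeds, alpha=float(sp.get("alpha", 0.05)), model=sp.get("model", "multiplicative")
        )
        pd.DataFrame(
            [
                {
                    "W": res.W, "G": res.G, "C": res.C, "GC_obs": res.GC_obs,
                    "E_add": res.E_add, "E_mult": res.E_mult,
                    "eps_add": res.eps_add, "eps_mult": res.eps_mult,
                    "p_interaction": res.p_interaction,
                    "classification": res.classification,
                }
            ]
        ).to_csv(out / "interaction.tsv", sep="\t", index=False)
        _interaction_bars(res, out / "interaction_means.png")
        manifest["stages"]["interact"] = {
            "rows_in": len(speeds),
            "classification": res.classification,
        }

    if "calcium" in config.stages:
        sp = p.get("calcium", {})
        traces = []
        for gid, amp in dict(sp.get("group_amplitudes", {"WT-DMSO": 1.0, "KO-DMSO": 0.05})).items():
            traces += synthetic.gen_calcium_traces(
                synthetic.TraceSpec(
                    peak_delta=float(amp),
                    noise_sd=float(sp.get("noise_sd", 0.02)),
                    n_cells_per_group=int(sp.get("n_cells_per_group", 20)),
                    group_id=gid,
                    seed=seeds["calcium"],
                )
            )
        io.write_traces(traces, out / "traces.tsv")
        responses = [ca.caffeine_response(t) for t in traces]
        summary = ca.group_summary(responses)
        summary.to_csv(out / "calcium_summary.tsv", sep="\t", index=False)
        manifest["stages"]["calcium"] = {"rows_in": len(traces), "rows_out": len(summary)}

    if "qpcr" in config.stages:
        sp = p.get("qpcr", {})
        knock = float(sp.get("knockdown_ddct", 1.0))  # ddCt of 1 = 50% knockdown
        ct = pd.DataFrame(
            [
                ("s1", "neg-siRNA", "Mapk11", 20.0),
                ("s1", "neg-siRNA", "Tbp", 20.0),
                ("s2", "siRNA", "Mapk11", 20.0 + knock),
                ("s2", "siRNA", "Tbp", 20.0),
            ],
            columns=["sample_id", "condition", "gene", "ct"],
        )
        folds = ca.ddct_fold_change(ct, target="Mapk11")
        folds.to_csv(out / "qpcr_folds.tsv", sep="\t", index=False)
        manifest["stages"]["qpcr"] = {"rows_out": len(folds)}

    manifest["checksums"] = {
        f.name: _checksum(f) for f in sorted(out.glob("*.tsv"))
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _heatmap(matrix, dend, path: Path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = [matrix.row_ids.index(i) for i in dend.leaf_order]
    vals = matrix.values[np.ix_(order, order)]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(vals, cmap="viridis", vmin=0, vmax=1, interpolation="nearest")
    fig.colorbar(im, label="Tanimoto score")
    ax.set_xlabel("library compounds (leaf order)")
    ax.set_ylabel("library compounds (leaf order)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _interaction_bars(res, path: Path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    labels = ["WT+veh", "mut+veh", "WT+chem", "mut+chem obs", "E additive", "E mult"]
    vals = [res.W, res.G, res.C, res.GC_obs, res.E_add, res.E_mult]
    colors = ["0.4"] * 4 + ["tab:orange", "tab:blue"]
    ax.bar(labels, vals, color=colors)
    ax.set_ylabel("normalized movement speed")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def report(manifest: dict) -> str:
    """Human-readable run summary generated from the manifest alone."""
    lines = [f"ryrmod v{manifest['version']} run (seed={manifest['seed']})", ""]
    stages = manifest.get("stages", {})
    if not stages:
        lines.append("no stages were run")
    for name, info in stages.items():
        lines.append(f"[{name}]")
        for k, v in info.items():
            lines.append(f"  {k}: {v}")
        if name == "worm" and info.get("hit_rate_pct", 1) == 0:
            lines.append("  0 hits called; enrichment downstream will be empty")
    if manifest.get("warnings"):
        lines.append("")
        lines.append("warnings:")
        lines += [f"  - {w}" for w in manifest["warnings"]]
    return "\n".join(lines)
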