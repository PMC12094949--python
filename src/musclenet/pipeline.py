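"""End-to-end pipeline: simulate -> preprocess -> synergies -> networks ->
centrality -> bootstrap -> similarity, with a manifest of every artifact."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as mio
from .config import PipelineConfig, SynthEmgConfig, derive_seed
from .metrics import centrality_table
from .network import select_network
from .preprocess import preprocess_trials
from .similarity import deltacon_similarity
from .stability import bootstrap_summary
from .synergy import build_weight_observations, select_synergy_count, vaf_curve
from .synthetic import generate_dataset
from .types import EmgTrial, PcorNetwork


@dataclass
class PipelineResult:
    """In-memory bundle of every stage output."""

    vaf_tables: dict[str, pd.DataFrame]
    k_selected: dict[str, int]
    selection_reports: dict[str, object]
    networks: dict[str, PcorNetwork]
    centrality: dict[str, pd.DataFrame]
    bootstrap: dict[str, object]
    similarity: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: PipelineConfig,
    trials: list[EmgTrial] | None = None,
    out_dir: str | Path | None = None,
    run_bootstrap: bool = True,
) -> PipelineResult:
    """Run every stage on supplied trials (or freshly simulated ones).

    One network is estimated per condition x synergy index; similarity is
    reported for every pair of those networks.  When ``out_dir`` is given,
    all artifacts are written and a manifest JSON records their hashes and
    the per-stage seeds.
    """
    conditions = list(config.k_true_by_condition)
    if trials is None:
        # each condition is simulated with its own planted synergy count
        trials = []
        for cond, k_true in config.k_true_by_condition.items():
            synth = SynthEmgConfig(**{**config.synth.__dict__, "k_true": k_true})
            trials.extend(generate_dataset(synth, conditions=(cond,))[0])
    processed = preprocess_trials(trials, config.preprocess)

    vaf_tables: dict[str, pd.DataFrame] = {}
    k_selected: dict[str, int] = {}
    reports: dict[str, object] = {}
    networks: dict[str, PcorNetwork] = {}
    centrality: dict[str, pd.DataFrame] = {}
    boots: dict[str, object] = {}

    for cond in conditions:
        cond_trials = [t for t in processed if t.condition == cond]
        table = vaf_curve(
            cond_trials,
            k_range=config.k_range,
            seed=derive_seed(config.seed, "vaf", cond),
            n_restarts=config.vaf_restarts,
            max_iter=config.nmf_max_iter,
            tol=config.nmf_tol,
        )
        vaf_tables[cond] = table
        k, report = select_synergy_count(table, alpha=config.alpha)
        k_selected[cond] = k
        reports[cond] = report
        obs_list = build_weight_observations(
            cond_trials, cond, k, seed=derive_seed(config.seed, "weights", cond),
            n_restarts=config.nmf_restarts,
        )
        for obs in obs_list:
            key = f"{cond}_synergy{obs.synergy_index}"
            net = select_network(
                obs,
                gamma=config.gamma,
                n_points=config.path_points,
                ratio=config.path_ratio,
            )
            networks[key] = net
            centrality[key] = centrality_table(net)
            if run_bootstrap:
                boots[key] = bootstrap_summary(
                    obs,
                    sample_net=net,
                    n_boot=config.n_boot,
                    gamma=config.gamma,
                    seed=derive_seed(config.seed, "boot", key),
                    n_points=config.path_points,
                    ratio=config.path_ratio,
                )

    sim_rows = []
    keys = sorted(networks)
    for i, a in enumerate(keys):
        for b in keys[i + 1 :]:
            res = deltacon_similarity(networks[a], networks[b])
            sim_rows.append(
                {
                    "net_a": a,
                    "net_b": b,
                    "distance": res.distance,
                    "similarity": res.similarity,
                    "epsilon": res.epsilon,
                }
            )
    similarity = pd.DataFrame(sim_rows)

    result = PipelineResult(
        vaf_tables=vaf_tables,
        k_selected=k_selected,
        selection_reports=reports,
        networks=networks,
        centrality=centrality,
        bootstrap=boots,
        similarity=similarity,
    )
    if out_dir is not None:
        result.manifest = _write_artifacts(result, config, Path(out_dir))
    return result


def _write_artifacts(
    result: PipelineResult, config: PipelineConfig, out_dir: Path
) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def register(path: Path) -> None:
        artifacts[str(path.relative_to(out_dir))] = _sha256(path)

    for cond, table in result.vaf_tables.items():
        p = out_dir / f"vaf_{cond}.csv"
        table.to_csv(p)
        register(p)
    for key, net in result.networks.items():
        paths = mio.write_network(net, out_dir / "networks", name=key)
        for p in paths.values():
            register(p)
        p = out_dir / f"centrality_{key}.csv"
        result.centrality[key].to_csv(p)
        register(p)
    for key, summ in result.bootstrap.items():
        p = out_dir / f"bootstrap_edges_{key}.csv"
        summ.edge_table.to_csv(p, index=False)
        register(p)
    p = out_dir / "similarity.csv"
    result.similarity.to_csv(p, index=False)
    register(p)

    manifest = {
        "seed": config.seed,
        "k_selected": result.k_selected,
        "warnings": {
            cond: rep.notes
            for cond, rep in result.selection_reports.items()
            if getattr(rep, "fallback", False)
        },
        "config": config.to_dict(),
        "artifacts": artifacts,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
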