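"""End-to-end orchestration and the command-line interface.

Two stages: ``discover-targets`` runs network assembly -> clique filtration ->
sheaf spectra -> perturbation ranking; ``repurpose`` runs activity
preparation -> ensemble training -> consensus prediction -> binder calling ->
CNS screen.  ``simulate`` writes seeded synthetic fixtures.  Every run emits
a JSON manifest (config, seed, input checksums, package version) sufficient
to reproduce it, and all randomness flows from the single config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import click
import pandas as pd

from sheafscreen import __version__
from sheafscreen.clique_filtration import (
    DEFAULT_THRESHOLDS,
    FiltrationSpec,
    build_confidence_filtration,
)
from sheafscreen.cns_screen import (
    ScreenPolicy,
    apply_cns_screen,
    read_admet_table,
    screen_report,
)
from sheafscreen.network_io import (
    build_labeled_network,
    read_deg_table,
    read_interaction_edges,
    select_top_upregulated,
)
from sheafscreen.perturbation_ranking import (
    RankingResult,
    rank_and_intersect,
    score_all_genes,
)
from sheafscreen.repurposing_ml import (
    ActivityRecord,
    CompoundRecord,
    call_binders,
    predict_consensus,
    prepare_compound_set,
    train_affinity_ensemble,
)
from sheafscreen.sheaf_spectra import SHEAF_STRATEGIES
from sheafscreen.synthetic_fixtures import (
    generate_admet_table,
    generate_affinity_dataset,
    generate_planted_network,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """Pipeline failure tagged with the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    deg_path: str = ""
    edge_path: str = ""
    activity_path: str = ""
    candidate_path: str = ""
    admet_path: str = ""
    out_dir: str = "results"
    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS
    top_n_degs: int = 200
    p_max: float = 0.05
    top_k: int = 25
    max_dim: int = 2
    sheaf_strategy: str = "default"
    delta_g_max: float = -9.2
    bbb_min: float = 0.70
    pgp_max: float = 0.50
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.sheaf_strategy not in SHEAF_STRATEGIES:
            raise ValueError(
                f"unknown sheaf strategy {self.sheaf_strategy!r}; "
                f"options: {sorted(SHEAF_STRATEGIES)}"
            )
        FiltrationSpec(thresholds=self.thresholds, max_dim=self.max_dim)
        if self.top_k < 1 or self.top_n_degs < 2:
            raise ValueError("top_k >= 1 and top_n_degs >= 2 required")


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(config: RunConfig, out_dir: Path, inputs: list[str]) -> None:
    manifest = {
        "tool_version": __version__,
        "config": asdict(config),
        "input_checksums": {p: _checksum(p) for p in inputs if p and Path(p).exists()},
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(name, exc) from exc
        logger.info("stage %s: %.2fs", name, time.perf_counter() - t0)
        return result

    return wrap


def run_target_discovery(config: RunConfig) -> RankingResult:
    """DEG selection, network assembly, filtration, scoring, ranking."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    degs = _stage("read_deg_table")(read_deg_table, config.deg_path)
    top = _stage("select_top_upregulated")(
        select_top_upregulated, degs, config.top_n_degs, config.p_max
    )
    edges = _stage("read_interaction_edges")(read_interaction_edges, config.edge_path)
    network = _stage("build_labeled_network")(build_labeled_network, top, edges)

    spec = FiltrationSpec(thresholds=config.thresholds, max_dim=config.max_dim)
    complexes = _stage("build_confidence_filtration")(
        build_confidence_filtration, network, spec
    )
    sheaf_factory = SHEAF_STRATEGIES[config.sheaf_strategy]
    scores = _stage("score_all_genes")(
        score_all_genes, network, complexes, spec.thresholds, sheaf_factory
    )
    result = _stage("rank_and_intersect")(rank_and_intersect, scores, config.top_k)

    rank_lookup = {
        (scale, gene): rank + 1
        for scale, ordered in result.per_scale.items()
        for rank, gene in enumerate(ordered)
    }
    pd.DataFrame(
        {
            "gene": [s.gene for s in scores],
            "scale": [s.scale for s in scores],
            "distance": [s.distance for s in scores],
            "rank_in_scale": [rank_lookup[(s.scale, s.gene)] for s in scores],
            "in_final_set": [s.gene in result.intersected for s in scores],
        }
    ).to_csv(out_dir / "perturbation_scores.csv", index=False)
    (out_dir / "final_gene_set.txt").write_text(
        "\n".join(sorted(result.intersected)) + "\n" if result.intersected else ""
    )
    (out_dir / "gene_frequencies.json").write_text(
        json.dumps(result.frequencies, indent=2)
    )
    _write_manifest(config, out_dir, [config.deg_path, config.edge_path])
    return result


def run_repurposing(config: RunConfig) -> list[CompoundRecord]:
    """Train the consensus ensemble, predict, call binders, screen."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    raw = pd.read_csv(config.activity_path)
    activities = [
        ActivityRecord(
            compound_id=str(r["compound_id"]),
            smiles=str(r["smiles"]),
            activity_nM=float(r["activity_nM"]),
            activity_type=str(r.get("activity_type", "IC50")),
        )
        for r in raw.to_dict("records")
    ]
    prepared = _stage("prepare_compound_set")(prepare_compound_set, activities)
    train_kwargs = config.extra.get("train_kwargs", {})
    model = _stage("train_affinity_ensemble")(
        train_affinity_ensemble, prepared, config.seed, **train_kwargs
    )
    (out_dir / "model_manifest.json").write_text(json.dumps(model.manifest, indent=2))

    cand = pd.read_csv(config.candidate_path)
    compounds = [
        CompoundRecord(
            compound_id=str(r["compound_id"]),
            smiles=str(r["smiles"]),
            name=str(r.get("name", "") or ""),
        )
        for r in cand.to_dict("records")
    ]
    compounds = _stage("predict_consensus")(predict_consensus, model, compounds)
    pd.DataFrame(
        {
            "compound_id": [c.compound_id for c in compounds],
            "name": [c.name for c in compounds],
            "smiles": [c.smiles for c in compounds],
            "delta_g_member1": [c.delta_g_member1 for c in compounds],
            "delta_g_member2": [c.delta_g_member2 for c in compounds],
            "delta_g_pred": [c.delta_g_pred for c in compounds],
            "binder_flag": [
                (not c.failed and c.delta_g_pred is not None
                 and c.delta_g_pred < config.delta_g_max)
                for c in compounds
            ],
            "failed": [c.failed for c in compounds],
        }
    ).to_csv(out_dir / "predictions.csv", index=False)

    binders = _stage("call_binders")(call_binders, compounds, config.delta_g_max)
    admet = _stage("read_admet_table")(read_admet_table, config.admet_path)
    policy = ScreenPolicy(
        delta_g_max=config.delta_g_max, bbb_min=config.bbb_min, pgp_max=config.pgp_max
    )
    screened = _stage("apply_cns_screen")(apply_cns_screen, binders, admet, policy)
    screen_report(screened, admet).to_csv(out_dir / "screened_candidates.csv", index=False)
    _write_manifest(
        config, out_dir,
        [config.activity_path, config.candidate_path, config.admet_path],
    )
    return screened


# ---------------------------------------------------------------------------
# CLI


@click.group()
@click.option("-v", "--verbose", is_flag=True)
def cli(verbose: bool) -> None:
    """Sheaf-Laplacian gene ranking and drug repurposing screen."""
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        stream=sys.stderr,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def _config_from_file(path: str | None) -> dict:
    if path is None:
        return {}
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out


@cli.command("discover-targets")
@click.option("--deg", "deg_path", required=True, type=click.Path(exists=True))
@click.option("--edges", "edge_path", required=True, type=click.Path(exists=True))
@click.option("--out", "out_dir", default="results", show_default=True)
@click.option("--thresholds", default=",".join(map(str, DEFAULT_THRESHOLDS)), show_default=True)
@click.option("--top-n-degs", default=200, show_default=True)
@click.option("--p-max", default=0.05, show_default=True)
@click.option("--top-k", default=25, show_default=True)
@click.option("--max-dim", default=2, show_default=True)
@click.option("--sheaf-strategy", default="default", show_default=True)
@click.option("--seed", default=0, show_default=True)
def discover_targets_cmd(deg_path, edge_path, out_dir, thresholds, top_n_degs,
                         p_max, top_k, max_dim, sheaf_strategy, seed) -> None:
    """Rank genes by topological perturbation and intersect top-k per scale."""
    config = RunConfig(
        deg_path=deg_path, edge_path=edge_path, out_dir=out_dir,
        thresholds=tuple(int(t) for t in thresholds.split(",")),
        top_n_degs=top_n_degs, p_max=p_max, top_k=top_k, max_dim=max_dim,
        sheaf_strategy=sheaf_strategy, seed=seed,
    )
    try:
        result = run_target_discovery(config)
    except StageError as exc:
        raise click.ClickException(str(exc)) from exc
    click.echo(f"final gene set ({len(result.intersected)}): "
               + ", ".join(sorted(result.intersected)))


@cli.command("repurpose")
@click.option("--activities", "activity_path", required=True, type=click.Path(exists=True))
@click.option("--candidates", "candidate_path", required=True, type=click.Path(exists=True))
@click.option("--admet", "admet_path", required=True, type=click.Path(exists=True))
@click.option("--out", "out_dir", default="results", show_default=True)
@click.option("--delta-g-max", default=-9.2, show_default=True)
@click.option("--bbb-min", default=0.70, show_default=True)
@click.option("--pgp-max", default=0.50, show_default=True)
@click.option("--seed", default=0, show_default=True)
def repurpose_cmd(activity_path, candidate_path, admet_path, out_dir,
                  delta_g_max, bbb_min, pgp_max, seed) -> None:
    """Train the consensus affinity ensemble and screen candidates."""
    config = RunConfig(
        activity_path=activity_path, candidate_path=candidate_path,
        admet_path=admet_path, out_dir=out_dir, delta_g_max=delta_g_max,
        bbb_min=bbb_min, pgp_max=pgp_max, seed=seed,
    )
    try:
        screened = run_repurposing(config)
    except StageError as exc:
        raise click.ClickException(str(exc)) from exc
    click.echo(f"{len(screened)} candidates pass the CNS screen")


@cli.command("simulate")
@click.option("--kind", type=click.Choice(["network", "affinity", "admet"]), required=True)
@click.option("--out", "out_dir", default="fixtures", show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--n", default=30, show_default=True, help="genes or compounds")
@click.option("--pass-fraction", default=0.5, show_default=True)
@click.option("--sigma", default=0.0, show_default=True)
def simulate_cmd(kind, out_dir, seed, n, pass_fraction, sigma) -> None:
    """Write seeded synthetic fixtures with recorded ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if kind == "network":
        truth = generate_planted_network(n_genes=n, seed=seed)
        truth.write(out / "degs.csv", out / "edges.tsv")
        (out / "network_truth.json").write_text(
            json.dumps({"hubs": truth.hubs, "seed": seed}, indent=2)
        )
    elif kind == "affinity":
        truth = generate_affinity_dataset(n_compounds=max(n, 50), sigma=sigma, seed=seed)
        truth.write(out / "activities.csv")
        (out / "affinity_truth.json").write_text(
            json.dumps({"true_delta_g": truth.true_delta_g, "seed": seed}, indent=2)
        )
    else:
        ids = [f"CPD{i:04d}" for i in range(n)]
        truth = generate_admet_table(ids, pass_fraction, seed=seed)
        truth.write(out / "admet.csv", out / "admet_truth.json")
    click.echo(f"wrote {kind} fixture to {out}")


if __name__ == "__main__":
    cli()
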