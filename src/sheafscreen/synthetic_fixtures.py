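"""Seeded synthetic inputs with recorded ground truth.

Every generator is a pure function of its parameters and seed, writes the
same CSV/TSV dialects the readers consume, and records its own bookkeeping
(hub identities, true binding energies, which ADMET rows pass) so tests can
check the pipeline against construction-time truth without external data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from sheafscreen.network_io import DEGRecord, InteractionEdge
from sheafscreen.repurposing_ml import (
    ActivityRecord,
    activity_from_delta_g,
    ecfp_fingerprint,
)

# Appendable SMILES units: each begins and ends with an atom that accepts an
# extra single bond, so any concatenation is a valid molecule.
_FRAGMENTS = (
    "C", "CC", "CO", "CN", "c1ccccc1", "C(=O)N", "C1CCCCC1", "CS",
    "CCO", "c1ccncc1",
)

_SCORE_IN_MODULE = (700, 990)
_SCORE_BACKGROUND = (150, 450)
_HUB_LOG2FC = (1.5, 3.0)
_NONHUB_LOG2FC = (0.1, 0.8)


@dataclass
class PlantedNetworkTruth:
    """Generated network plus construction-time bookkeeping."""

    hubs: list[str]
    modules: dict[str, int]
    degs: list[DEGRecord]
    edges: list[InteractionEdge]
    seed: int

    def write(self, deg_path: str | Path, edge_path: str | Path) -> None:
        pd.DataFrame(
            {
                "gene": [r.gene for r in self.degs],
                "log2fc": [r.log2fc for r in self.degs],
                "pvalue": [r.pvalue for r in self.degs],
            }
        ).to_csv(deg_path, index=False)
        pd.DataFrame(
            {
                "gene_a": [e.gene_a for e in self.edges],
                "gene_b": [e.gene_b for e in self.edges],
                "score": [e.score for e in self.edges],
            }
        ).to_csv(edge_path, sep="\t", index=False)


@dataclass
class SyntheticAffinityTruth:
    """Compound set with an additive structure-activity ground truth."""

    records: list[ActivityRecord]
    true_delta_g: dict[str, float]
    bit_weights: dict[int, float]
    base_delta_g: float
    sigma: float
    seed: int

    def write(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "compound_id": [r.compound_id for r in self.records],
                "smiles": [r.smiles for r in self.records],
                "activity_nM": [r.activity_nM for r in self.records],
                "activity_type": [r.activity_type for r in self.records],
            }
        ).to_csv(path, index=False)


def generate_planted_network(
    n_genes: int = 30,
    n_modules: int = 2,
    hub_per_module: int = 1,
    seed: int = 0,
    in_module_p: float = 0.5,
    background_p: float = 0.08,
) -> PlantedNetworkTruth:
    """Dense near-clique modules with one or more planted hubs each.

    Hubs connect to every member of their module with high-confidence scores
    and carry top-decile |log2fc|; non-hub in-module pairs connect with
    probability ``in_module_p``; cross-module background edges are sparse and
    low-confidence.  Hubs therefore have top-decile degree by construction.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if n_modules * (hub_per_module + 2) > n_genes:
        raise ValueError("too many modules/hubs for the gene count")
    rng = np.random.default_rng(seed)

    width = len(str(n_genes - 1))
    genes = [f"G{i:0{width}d}" for i in range(n_genes)]
    modules = {g: i % n_modules for i, g in enumerate(genes)}
    hubs: list[str] = []
    for m in range(n_modules):
        members = [g for g in genes if modules[g] == m]
        hubs.extend(members[:hub_per_module])

    degs = []
    for g in genes:
        lo, hi = _HUB_LOG2FC if g in hubs else _NONHUB_LOG2FC
        degs.append(
            DEGRecord(
                gene=g,
                log2fc=float(np.round(rng.uniform(lo, hi), 6)),
                pvalue=float(np.round(rng.uniform(1e-8, 0.01), 10)),
            )
        )

    edges: dict[tuple[str, str], InteractionEdge] = {}

    def add(a: str, b: str, lo: int, hi: int) -> None:
        e = InteractionEdge(a, b, int(rng.integers(lo, hi + 1)))
        edges.setdefault(e.pair, e)

    hub_set = set(hubs)
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            if modules[a] == modules[b]:
                if a in hub_set or b in hub_set:
                    add(a, b, *_SCORE_IN_MODULE)
                elif rng.random() < in_module_p:
                    add(a, b, *_SCORE_IN_MODULE)
            elif rng.random() < background_p:
                add(a, b, *_SCORE_BACKGROUND)

    return PlantedNetworkTruth(
        hubs=hubs,
        modules=modules,
        degs=degs,
        edges=sorted(edges.values()),
        seed=seed,
    )


def generate_affinity_dataset(
    n_compounds: int = 500,
    sigma: float = 0.0,
    seed: int = 0,
    base_delta_g: float = -8.0,
    n_weighted_bits: int = 12,
    weight_scale: float = 0.6,
) -> SyntheticAffinityTruth:
    """Compound set whose true binding energy is additive over fingerprint bits.

    Compounds are concatenations of 2-3 appendable SMILES fragments.  Weights
    go to fingerprint bits with balanced prevalence in the generated set (so
    the signal is identifiable from a few hundred examples); true
    dG = base + sum of weights over set bits + N(0, sigma), and the recorded
    activity is the exact inverse of the dG conversion.
    """
    if n_compounds < 50:
        raise ValueError("n_compounds must be >= 50")
    rng = np.random.default_rng(seed)

    smiles_list: list[str] = []
    seen: set[str] = set()
    while len(smiles_list) < n_compounds:
        k = int(rng.integers(2, 4))
        smi = "".join(rng.choice(_FRAGMENTS) for _ in range(k))
        if smi not in seen:
            seen.add(smi)
            smiles_list.append(smi)

    fps = [ecfp_fingerprint(s) for s in smiles_list]
    prevalence = np.mean(fps, axis=0)
    balanced = np.flatnonzero((prevalence > 0.25) & (prevalence < 0.75))
    if balanced.size == 0:
        balanced = np.flatnonzero(prevalence > 0)
    chosen = rng.choice(
        balanced, size=min(n_weighted_bits, balanced.size), replace=False
    )
    bit_weights = {
        int(b): float(rng.normal(0.0, weight_scale)) for b in sorted(chosen)
    }

    records, true_dg = [], {}
    for i, (smi, fp) in enumerate(zip(smiles_list, fps)):
        cid = f"CPD{i:04d}"
        dg = base_delta_g + sum(w for b, w in bit_weights.items() if fp[b] > 0)
        dg += float(rng.normal(0.0, sigma)) if sigma > 0 else 0.0
        true_dg[cid] = dg
        records.append(
            ActivityRecord(
                compound_id=cid,
                smiles=smi,
                activity_nM=activity_from_delta_g(dg),
                activity_type="IC50",
            )
        )
    return SyntheticAffinityTruth(
        records=records,
        true_delta_g=true_dg,
        bit_weights=bit_weights,
        base_delta_g=base_delta_g,
        sigma=sigma,
        seed=seed,
    )


@dataclass
class ADMETTableTruth:
    table: pd.DataFrame
    passing_ids: list[str]
    seed: int

    def write(self, path: str | Path, manifest_path: str | Path | None = None) -> None:
        self.table.to_csv(path, index=False)
        if manifest_path is not None:
            Path(manifest_path).write_text(
                json.dumps({"seed": self.seed, "passing_ids": self.passing_ids}, indent=2)
            )


def generate_admet_table(
    compound_ids: list[str],
    pass_fraction: float,
    seed: int = 0,
    bbb_min: float = 0.70,
    pgp_max: float = 0.50,
) -> ADMETTableTruth:
    """ADMET table where exactly round(pass_fraction * n) rows satisfy the
    probability rules; the rest violate at least one."""
    if not 0.0 <= pass_fraction <= 1.0:
        raise ValueError("pass_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(compound_ids)
    n_pass = round(pass_fraction * n)
    pass_idx = set(rng.choice(n, size=n_pass, replace=False).tolist())

    rows, passing = [], []
    for i, cid in enumerate(compound_ids):
        if i in pass_idx:
            bbb = rng.uniform(bbb_min + 0.05, 1.0)
            sub = rng.uniform(0.0, pgp_max - 0.05)
            inh = rng.uniform(0.0, pgp_max - 0.05)
            passing.append(cid)
        else:
            # violate at least one rule, chosen at random
            mode = rng.integers(0, 3)
            bbb = rng.uniform(0.0, bbb_min - 0.05) if mode == 0 else rng.uniform(bbb_min + 0.05, 1.0)
            sub = rng.uniform(pgp_max + 0.05, 1.0) if mode == 1 else rng.uniform(0.0, pgp_max - 0.05)
            inh = rng.uniform(pgp_max + 0.05, 1.0) if mode == 2 else rng.uniform(0.0, pgp_max - 0.05)
        rows.append(
            {"id": cid, "bbb": round(float(bbb), 4), "pgp_sub": round(float(sub), 4),
             "pgp_inh": round(float(inh), 4)}
        )
    return ADMETTableTruth(table=pd.DataFrame(rows), passing_ids=passing, seed=seed)
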