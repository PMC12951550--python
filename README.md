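# sheafscreen

Sheaf-Laplacian perturbation ranking of dysregulated gene-interaction
networks, with a consensus machine-learning binding-affinity stage and a
CNS-oriented ADMET screen for drug repurposing.

## What it does

**Target discovery.** A table of differentially expressed genes (symbol,
log2 fold-change, p-value) and a confidence-weighted interaction edge list
(STRING dialect, scores in 0–1000) are assembled into a labeled network: the
top up-regulated genes become vertices, each carrying its dysregulation
magnitude |log2FC|. Raising the minimum edge confidence over the thresholds
[250, 400, 550, 700] induces a nested family of clique complexes. On each
complex a cellular sheaf is placed (one-dimensional stalks; restriction maps
built from the vertex quantities and a confidence-derived edge length), and
the L0/L1 sheaf-Laplacian spectra are summarized by six statistics each
(min, mean, max, std, sum, number of zeros). A gene's significance at a
scale is the order-1 Wasserstein distance between this 12-entry feature
vector and the one obtained after deleting the gene's vertex star. Genes are
ranked per scale and the final set is the intersection of the per-scale
top-k lists.

**Repurposing.** Compound activities (IC50/EC50 in nM) are converted to
binding free energies (ΔG = RT·ln C), two gradient-boosted regressors are
trained — one on 2048-bit radius-2 circular fingerprints, one on a
deterministic hashed character-n-gram embedding of the SMILES (a pluggable
provider; a pretrained encoder drops in) — with 10-fold CV on a 70/30 split
before refitting on all data, and their predictions are averaged. Binders
(ΔG below a per-target threshold, strictly) are then screened against an
externally produced ADMET table: single-fragment molecules with BBB
probability > 0.70 and both P-gp probabilities < 0.50.

All synthetic fixtures (planted-hub networks, additive structure–activity
compound sets, ADMET tables with an exact pass count) are first-class,
seeded generators in `sheafscreen.synthetic_fixtures`.

## CLI

```sh
# seeded synthetic inputs
sheafscreen simulate --kind network  --out fixtures --seed 7
sheafscreen simulate --kind affinity --out fixtures --seed 7 --n 200
sheafscreen simulate --kind admet    --out fixtures --seed 7 --n 40

# rank genes by topological perturbation
sheafscreen discover-targets --deg fixtures/degs.csv --edges fixtures/edges.tsv \
    --out results --top-n-degs 200 --top-k 25 --seed 7

# train, predict, and screen candidates
sheafscreen repurpose --activities fixtures/activities.csv \
    --candidates candidates.csv --admet fixtures/admet.csv \
    --out results --delta-g-max -9.2 --seed 7
```

Outputs are CSV/JSON: per-gene per-scale scores with ranks, the final gene
set, per-compound predictions with member and consensus ΔG, the screened
candidate table, and a run manifest (config, seed, input checksums,
version).

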