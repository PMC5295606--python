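# netgi — predicting genetic interactions from functional gene networks

Genetic interactions (synthetic lethality, phenotypic enhancement and
suppression, dosage effects, ...) are pairs of genes whose joint
perturbation produces a phenotype not expected from the individual
perturbations. Mapping them exhaustively by experiment is infeasible —
the pair space is quadratic in the genome — so computational
prioritization matters, for example when nominating synthetic-lethal
partners of cancer mutations as drug targets.

`netgi` implements a guilt-by-association method built on one hypothesis:
**functionally related genes tend to share genetic interaction partners.**
It works from two inputs: a weighted functional gene network (an
integrated network whose edge weights are log likelihood scores, LLS,
quantifying confidence that two genes act in the same biological
process), and a catalog of known genetic interactions of a given class
(BioGRID-style tables are read natively).

## The method

For a query gene *X*, collect its known interaction partners of one class —
the **seed set**. Score every gene *g* in the network by summed edge
weight to the partners *P*:

```
S(g) = Σ_{p ∈ P} LLS(g, p)
```

Because the network has no self-edges, each partner's own score counts
only the *other* partners — an implicit leave-one-out cross-validation.
Ranking scores against the binary is-a-partner label vector yields an ROC
curve; its area is computed in the rank-based (Mann–Whitney) form with
midrank tie handling:

```
AUC = (R₊ − n₊(n₊+1)/2) / (n₊ n₋)
```

Seed sets with AUC ≥ 0.9 are called highly predictive, and their
top-scoring unlabelled genes are ranked as novel candidate partners.

Two companion analyses complete the toolkit:

* **Complex enrichment.** With background rate *p* (the fraction of all
  gene pairs in a stated universe that interact), a protein complex with
  *m* member genes contributes *n = C(m, 2)* pair trials; observing *k*
  interacting pairs gives the exact binomial tail p-value *P(X ≥ k)*,
  with Benjamini–Hochberg control of the FDR at 5%.
* **Withholding simulations.** Known interactions are progressively
  removed — at random, or by the interaction degree of their genes — and
  the enrichment pipeline is re-run at each level to find how sparse the
  known-interaction map can be before the signal disappears.

A fully synthetic world generator (modular network + planted coherent
seed sets + interaction-dense complexes, all with ground truth) makes
every stage testable without any database download.

## Worked example

```bash
python examples/01_score_seed_sets.py
```

```
coherent  n=20  mean AUC=0.982  frac >= 0.9: 1.00
control   n=20  mean AUC=0.479  frac >= 0.9: 0.00
```

Twenty seed sets whose partners were planted inside one functional module
are all recovered as highly predictive (AUC ≥ 0.9), while twenty random
control sets hover at chance (AUC ≈ 0.5) — the separation the method
relies on. The other examples rank candidates for a textbook
five-gene-module instance (`02`), separate planted from null complexes by
binomial enrichment (`03`, planted p-values ≤ 1e-44 vs. null ≥ 0.19), and
trace withholding curves (`04`), where removing pairs of genes with
degree > 5 wipes out enrichment but random removal degrades it only
gradually.

The same workflow is scriptable from a shell:

```bash
netgi simulate --seed 42 --out-dir world/
netgi score   --network world/network.tsv --interactions world/interactions.tsv \
              --type "Phenotypic Enhancement" --out results.tsv
netgi predict --network world/network.tsv --interactions world/interactions.tsv \
              --type "Phenotypic Enhancement" --min-auc 0.9 --top-k 20 --out candidates.tsv
netgi enrich  --interactions world/interactions.tsv --type "Negative Genetic" \
              --complexes world/complexes.tsv --out enrich.tsv
netgi run     --out-dir run/ --seed 7   # composite pipeline with manifest
```

Real inputs (a HumanNet/YeastNet-style edge list, a BioGRID TAB 2.0
interaction table, a complex membership table) drop into the same
commands; `--year-cutoff` reproduces the circularity guard used when a
network was built from pre-cutoff data.

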