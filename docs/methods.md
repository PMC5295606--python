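# Methods

## Seed-set scoring and leave-one-out ROC

A seed set is a query gene together with its known genetic interaction
partners of one interaction class. Every gene in the functional network
receives the score `S(g) = Σ_p LLS(g, p)` over the partners `p`; missing
edges contribute zero. The network contains no self-edges, so a partner's
own score sums only its edges to the *other* partners: each partner is
thereby scored exactly as if it had been withheld and predicted back from
the rest, which is why no explicit cross-validation loop exists — the
leave-one-out structure is a property of the scoring rule.

The AUC is computed in the rank-based Mann–Whitney form with midrank tie
handling: `AUC = (R₊ − n₊(n₊+1)/2)/(n₊ n₋)`, equivalently the probability
that a random partner outscores a random non-partner with ties counting
½. Midranks make the all-tied (zero-signal) case exactly 0.5, matching
the interpretation of uninformative seed sets as "no better than random";
a trapezoidal ROC over the same rankings gives the identical value, which
the tests confirm against scikit-learn. Genes with score zero are kept as
negatives — dropping them would shrink the negative set and inflate the
AUC of sparse seed sets.

The seed gene itself, when it happens to be a network gene, is excluded
from both vectors rather than scored as a negative (configurable): it is
the query, not a candidate. Seed sets need at least two usable partners;
with fewer, the leave-one-out logic is vacuous.

### Assembly filters

Seed sets are assembled per (gene, interaction class) from an interaction
table, in a fixed order: class/organism restriction (labels matched
case-insensitively after trimming, unknown labels pass through), the
publication-year cutoff, intersection of partners with network genes, and
optional exclusion of seed–partner pairs that are themselves network
edges. The last two are circularity guards: out-of-network partners
cannot be scored at all, and a genetic interaction that also contributed
an edge to the network would let the network predict its own training
data. When a year cutoff is set, records without a year are dropped —
their discovery date cannot be certified. Duplicate records of the same
pair and class keep the earliest year seen, since the cutoff asks when
the pair was *first* reported.

## Candidate ranking and display clusters

A seed set whose AUC clears `min_auc` (default 0.9) is predictive; its
label-0 genes with positive score, ordered by score descending with ties
broken by gene id (deterministic output), are the ranked novel
candidates. Scores are reported raw (summed LLS, no normalization is
defined for them); a midrank percentile of the candidate's score within
the seed set's full score vector is added as a derived column so
candidates of different seeds can be compared. Zero-score genes are never
candidates: no functional evidence links them to the partners.

Display clusters follow the conventions used for drawing such
predictions: only edges with LLS strictly above 3.0 are kept, and a
non-partner gene is retained only if, after that edge filter, it still
links to at least two distinct partners (the membership rule is evaluated
jointly with the edge cutoff, since only supra-cutoff edges are drawn).
Raising either threshold can only shrink the cluster.

## Binomial enrichment of protein complexes

Model: each of the `n = C(m, 2)` gene pairs of a complex with `m`
universe members interacts independently with probability `p`, the
fraction of all `C(|U|, 2)` pairs of the universe `U` that are known to
interact. The p-value of observing `k` interacting pairs is the exact
binomial upper tail `P(X ≥ k)` (no normal approximation — complexes are
small, and approximations fail exactly where the decision is made).
Benjamini–Hochberg step-up at FDR 5% flags significant complexes;
ineligible complexes (fewer than two members in the universe) are
reported with `n = 0`, `p-value = 1` and excluded from the BH family.

The universe is a required, surfaced parameter. Whether `U` is the union
of catalog and interaction genes (the default), the network's genes, or
an explicit list changes `p` — and thus every p-value — so it is recorded
in all outputs. Interacting pairs are counted without direction or
multiplicity; pairs shared by overlapping complexes count once per
complex, so per-complex counts may double-count across the catalog.

## Withholding simulations

Each plan point reduces the known-interaction set and re-runs the whole
enrichment pipeline. Degree-based modes compute interaction degrees once
on the full original set — withholding "genes with degree > 5" refers to
a property of the data as it exists, not of the partially removed set.
`degree_above` removes every pair touching a gene above the cutoff;
`degree_below` removes pairs whose both endpoints fall under it; random
mode removes `⌊proportion × N⌋` pairs uniformly without replacement,
averaged over 20 seeded replicates by default (mean, min and max of the
significant count are reported; replicate draws are independent per
point, each seeded from the plan seed, the point index and the replicate
index).

The background rate `p` is recomputed on each reduced set, because the
simulation's premise is that withheld pairs were never observed; a flag
switches to the fixed original `p`, and its state is part of the output,
since the two conventions answer different questions. Recomputing `p`
also guarantees the degenerate endpoint: at full withholding every `k`
and `p` are zero, all tails equal 1, and nothing is significant. The gene
universe stays fixed across points — the hypothetical is fewer known
interactions, not fewer genes. Both the number and the fraction of
significant complexes are emitted.

## The synthetic world generator

The generator encodes the method's working hypothesis as a generative
model, with ground truth for every seed set and complex.

* **Network.** `n_modules` disjoint modules of `module_size` genes, wired
  as cliques (each within-module pair present with
  `within_module_edge_prob`, default 1.0) at `within_module_lls` = 4.0;
  background edges between the remaining pairs with probability
  `background_edge_prob` = 0.01 at `background_lls` = 0.5. The two-point
  weight distribution deliberately straddles the 3.0 display cutoff and
  exercises tie handling; matching the degree distribution or edge-weight
  spectrum of real integrated networks is out of scope.
* **Seed sets.** Coherent seeds draw `partners_per_seed` = 6 partners
  from a single module, with `⌊partner_noise × partners_per_seed⌋`
  partners relocated outside it (floor, so noise below 1/partners leaves
  sets fully coherent); control seeds draw partners uniformly. Seed genes
  carry dedicated identifiers outside the network gene pool — only
  partners are scored, and a query gene need not be in the network.
* **Complexes and growth-score interactions.** Enriched complexes sample
  `complex_size` = 8 members from one module and plant internal
  interactions at `within_complex_interaction_prob` = 0.9; null complexes
  are uniform gene sets. A uniform interaction background at
  `background_interaction_prob` = 0.005 keeps the estimated `p`
  realistic and non-zero. Seed-set interactions use a phenotypic class
  label and complex/background interactions a growth-score class label,
  so per-class analyses stay separable, mirroring how interaction classes
  are analysed independently on real data.

Default world size (500 genes, 10 modules of 15, 20 coherent + 20 control
seeds, 10 enriched + 10 null complexes) is chosen so a full generate-and-
evaluate cycle takes tens of milliseconds while leaving hundreds of
negatives per seed set; complexes of 8 give 28 pair trials, enough for
binomial tails far below any BH threshold when dense and near 1 when
null. Everything derives from a single `rng_seed`; equal seeds give
byte-identical serialized worlds.

What passing on synthetic worlds does *not* show: robustness to
overlapping modules (disjointness keeps truth labels unambiguous),
ascertainment bias in which pairs get screened, continuous LLS spectra,
or gene-identifier noise. Results on real networks additionally depend on
network coverage and interaction-catalog sparsity.

## Numerical and design notes

* AUC: `scipy.stats.rankdata` midranks; validated to 1e−12 against the
  exhaustive pairwise comparison and scikit-learn on randomized instances
  with forced ties. Degenerate label vectors (no positives or no
  negatives) are a hard error, not a default value.
* Binomial tail: `scipy.stats.binom.sf(k−1, n, p)`, validated to 1e−12
  against exact rational (Fraction) enumeration for n ≤ 25; `P(X ≥ 0) = 1`
  by construction.
* BH: stable argsort, largest rank `i` with `p(i) ≤ i·q/m`; ties share
  the decision of their rank block. Validated against a literal step-up
  scan and statsmodels.
* Duplicate network edges with conflicting weights keep the maximum and
  warn; self-edges are dropped at parse time (they would silently break
  the leave-one-out property). Malformed rows fail hard with their line
  number — silent row-skipping in genomics tables is a classic source of
  unreproducible results.
* Isolated genes survive edge-list round trips via `#node` directive
  lines: zero-degree genes must stay in the score vector as
  zero-evidence negatives.
* Pipeline artifacts contain no timestamps; identical config and seed
  reproduce byte-identical outputs, and each run writes a manifest of
  parameters, inputs and row counts.
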