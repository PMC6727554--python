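# Methods

## Scoring model

Each gene `g` has homology hits `h = (ec_h, lineage_h)`; lineages are
ordered root → leaf. For a candidate EC `e` among the hits of `g`:

* `freq(e) = |{h : ec_h = e}| / |{h : ec_h defined}|` — the cardinality of
  the EC among the gene's EC-bearing hits;
* `tax(e) = mean over {h : ec_h = e} of d(q, lineage_h) / |q|`, where `q`
  is the query organism's lineage and `d` the length of the shared
  root-anchored prefix;
* `score(e) = α · freq(e) + (1 − α) · tax(e)`, α ∈ (0, 1).

The gene is annotated with the arg-max EC (ties to the lexicographically
smallest EC string, for determinism). Genes with no EC-bearing hit are
"potentially non-metabolic": annotated `none` with score 0, excluded from
the potentially-metabolic count but kept in the tables so sampling can
expose them. Published descriptions of frequency/taxonomy scorers state
the contract (both components in [0, 1], cardinality-based frequency,
proximity-based taxonomy) but not a unique formula; the definitions above
— a ratio over EC-bearing hits and a mean normalised shared-prefix depth —
are this package's own concrete choice, and the mean (rather than a max or
a weighted scheme) over carrier hits is a documented design decision. EC
strings are compared for exact equality, including partial ECs with `-`
fields: no partial-match credit is defined anywhere, so none is invented.

The default α grid is 0.1–0.9 in steps of 0.1. The extremes 0.0 and 1.0
silence one component entirely and are refused unless explicitly allowed
(`allow_extreme_alpha`).

## Stratified sampling

The curation sample contains `round(fraction · n)` of the `n` potentially
metabolic genes (default fraction 0.05, the low end of the conventional
5–10% band). Genes are binned by their score at a reference α into
intervals of width 0.1 (`[0, 0.1), …, [0.9, 1.0]`, top bin closed); the
target is split as evenly as possible over the occupied bins (even base
quota, remainder round-robin in bin order), quotas are capped at bin
occupancy, and any deficit goes to the bins with the most remaining
capacity, largest first, so the sample size stays exact. Within a bin,
selection is uniform without replacement under a numpy `default_rng`
seed. If the target is smaller than the number of occupied bins, the
sampler warns and takes one gene from each of the fullest bins up to the
budget. The reference α defaults to 0.5 — the neutral initial value a
project would start from; which scores the original tool stratifies on is
not documented, so the initial-α score is used.

## Assessment grid

For thresholds `t ∈ {0.0, 0.1, …, 1.0}` (the score range; step
configurable) and every α column, each sample gene is classified by
comparing the curated label (an EC set, or "not an enzyme") with the
proposed EC and its score:

| curated | proposal | score ≥ t | score < t |
|---|---|---|---|
| EC set | member EC | CA | IR |
| EC set | other EC | IA | IR (default) / CR (variant) |
| not an enzyme | any EC | IA | CR |

Acceptance is at score ≥ t — equality accepted. A curated EC *set*
matches if the proposal is any member (isozymes and complexes make
multi-EC curations routine). The `wrong_below` switch exists because the
published rule for a wrong EC proposal below the threshold is stated both
ways in its source (flow-chart: IR; worked example's phrasing: CR); the
default is the flow-chart reading, and both are implemented rather than
silently picking one. A proposal of `none` is treated as correct exactly
for "not an enzyme" genes and then follows the same accept/reject split,
which preserves the invariant that nothing is rejected at t = 0.

Every cell of the grid sums to the sample size, and the accepted count
CA+IA is non-increasing in t — both enforced as tests.

## Metrics, thresholds and the recommendation

Per cell: `accuracy = (CA+CR)/x1`, `precision = CA/(CA+IA)`,
`NPV = CR/(CR+IR)`. A zero denominator makes the metric *vacuous*
(nothing accepted / nothing rejected); a vacuous metric satisfies any
target, since no error has been committed. Per α column the mean accuracy
averages over all configured threshold rows.

At precision target `p` and NPV target `q` (both in [0.75, 1.0]; the
relaxation ladder 1.00/0.95/0.85/0.75 is conventional):

* `t_U` = lowest t with precision ≥ p (unreachable → max t + step:
  accept nothing, flagged);
* `t_L` = highest t with NPV ≥ q (unreachable → 0: reject nothing,
  flagged).

On the **full genome** annotation at each α (not the sample), genes score
≥ t_U are auto-accepted, < t_L auto-rejected, and the band
`t_L ≤ score < t_U` is the curation set — counting the band on the whole
genome is what makes the curation fraction an effort estimate. If
`t_L > t_U` the pair is flagged as crossed, never reordered; operationally
acceptance takes precedence in the overlap, so the curation band is empty
and accepted + rejected + to-curate still partitions the potentially
metabolic genes. The recommended α maximises
`curation_ratio = mean_accuracy / (n_curate / n_potentially_metabolic)`;
an empty band scores +inf (nothing left to curate). Ties break to higher
mean accuracy, then to the lower α.

## Synthetic benchmark generator

The generator emulates the inputs of a homology-annotation project:
`n_genes` genes (default 500), of which `frac_enzymatic` (0.55) carry a
true EC from a pool of 40; each gene has `hits_per_gene` hits (uniform in
a range); a hit of an enzymatic gene carries a wrong EC with probability
`misannotation_rate`, no EC with `no_ec_rate`, and the true EC otherwise.
Lineages share a root-anchored prefix with the 7-level query lineage whose
depth is drawn from `proximity_profile`; `taxonomy_informativeness`
re-draws correct hits from a close-relative profile and wrong hits from a
distant one, and `frequency_informativeness` scatters wrong ECs over the
pool (1.0) instead of piling them on a per-gene confounder (0.0). A
fraction `nonenzyme_decoy_rate` (0.35) of non-enzymatic genes receives
only misannotated hits, giving the realistic population of
potentially-metabolic non-enzymes the lower threshold must reject; the
rest have unlabelled hits only.

`make_taxa_scenarios()` freezes two archetypes. *Taxa-rich* (many close,
well-annotated relatives): 5–25 hits per gene, 20% misannotation scattered
over the pool, proximity mass at deep prefixes, weak correctness–proximity
coupling (0.15) — frequency is diagnostic, taxonomy nearly flat.
*Taxa-poor* (few close relatives, and those reliable): 3–10 hits, 45%
misannotation concentrated on a confounder, shallow proximity mass, strong
coupling (0.9) — frequency is close to a coin flip on short hit lists
while taxonomy separates true from false. Run end to end (8% sample,
stratified at α = 0.5, 100% targets), the taxa-poor genomes should be
recommended a lower α than the taxa-rich ones; the test suite requires the
direction in at least 8 of 10 seeded replicates, and the medians sit below
and at-or-above 0.5 respectively.

What the generator does **not** emulate: sequence-level effects (hit
identity, alignment coverage, e-values), database redundancy across
sources, correlated misannotation between related database entries,
multi-EC truth, and hit-list sizes in the hundreds. Passing tests
therefore demonstrate that the selection machinery recovers the designed
signal structure, not that any particular α is right for a real organism.

## Reconstructed demonstration data

`samplertune.worked_example` is a synthetic stand-in for the original
50-gene demonstration sample and its ~1000-gene genome, rebuilt from the
published summary statistics (see its docstring for the full list: the
29/12/4/5 confusion matrix at (0.5, 0.2), α = 0.1 as the top-accuracy
column with precision 1 only above t = 0.9 and NPV 1 below t = 0.2, and a
301-gene / 30% curation band). Score placements inside those constraints
are invented; the below-threshold incorrect proposals are all non-enzyme
cases so the pinned matrix is identical under both `wrong_below` readings.

## Numerical and degenerate-input choices

* Thresholds and α values are compared after rounding to 9 decimals, so
  0.1-step grids built by repeated addition hash consistently.
* Empty hit tables annotate to an empty table with a warning; empty truth,
  empty grids and empty threshold lists are errors.
* All TSV readers reject malformed rows (bad EC syntax, scores outside
  [0, 1], duplicate keys) with row numbers rather than coercing.
* Problem sizes in tests and in `scripts/acceptance.py` (500-gene genomes,
  10 replicates) are the package's chosen defaults for a convincing yet
  quick demonstration; the generator scales to larger genomes unchanged.

## Known limitations

* The scorer is a clean-room stand-in: it honours the published contract
  but will not reproduce another implementation's scores bit for bit.
* Only the single weight α is swept; the grid data model keys columns by
  the parameter value and would need a composite label for
  multi-parameter sweeps.
* Mean column accuracy averages over the full configured threshold grid;
  restricting rows to the observed score range would change the ranking
  only when score supports differ strongly between α columns.
* Transporter (TC-number) annotation and the curation workflow itself are
  out of scope.
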