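# Methods

## The screening model

`netpharm` formalizes the target-screening procedure used in network
pharmacology to nominate the proteins through which a multi-compound
herbal formula may act on a disease.  The underlying assumptions are the
field's usual ones: (i) a compound is a plausible oral drug constituent
if its predicted oral bioavailability and drug-likeness clear standard
cut-offs; (ii) a formula's pharmacology is captured by the union of its
compounds' protein targets; (iii) disease genes are those consistently
differentially expressed between diseased and normal tissue across
independent cohorts; (iv) the proteins that matter are those that are
*topologically central* in the subnetwork where drug targets and disease
genes meet on a background interactome.  None of these assumptions is
validated here — the package reproduces the inference procedure, not its
biological claims.

### Ingredient screen

A compound record (herb, compound, OB, DL, whitelist flag) is retained
iff `OB >= ob_min and DL >= dl_min`, or its whitelist flag is set.  Both
thresholds are **inclusive** (the conventional "≥ 30 %" / "≥ 0.18"
notation), with defaults `ob_min = 30.0` (percent) and `dl_min = 0.18`
(dimensionless).  Provenance is tracked per record: a whitelisted record
that also clears the thresholds is tagged `threshold`, so the whitelist
count reflects only records the thresholds alone would have lost.  The
bundled 66-ingredient formula table lists names only (the published
source prints no per-compound OB/DL), so it is loaded as an already
screened candidate set and never re-screened; consequently the 43
threshold / 23 whitelist split reported for it is not reproducible from
the shipped data and is not asserted anywhere.

### Differential expression and cohort intersection

Per cohort, each gene is tested tumor vs normal with a Welch two-sample
*t*-test on log2 expression, BH-adjusted across the cohort's genes; a
gene is called at `q < alpha` (default 0.05) and `|log2FC| >= lfc_min`
(default 1.0).  The published workflows this mirrors rarely state their
DE method; Welch + BH + fold-change gate is the common GEO two-group
convention, and both knobs are exposed.  Degenerate genes are kept:
when both group variances are zero the statistic is undefined, so p is
set to 1 for equal means and 0 for unequal means (forced separation)
rather than dropping the gene.  Cohort intersection ignores the sign of
the fold change by default (the workflow being emulated intersects bare
gene sets); `require_concordant_sign=True` applies the stricter rule.

### Networks

Node identity is upper-cased symbol equality; no identifier-mapping
service is consulted.  Seed expansion returns the subgraph induced on
seeds plus neighbors within `depth` hops (default 1, the "add nodes and
edges" behavior of interactome plug-ins); seeds missing from the
interactome stay as isolated nodes so the caller can see them.  Network
intersection keeps only nodes *and edges* present in both inputs
(Cytoscape merge-intersection): this is why the merged network is far
sparser than either parent, and it guarantees validity by construction.

### Two-stage median screen and hubs

Stage 1 keeps nodes with `DC >= factor × median(DC)` over all nodes of
the merged network (default factor 2, inclusive `>=`); an even node
count uses the mean of the two middle values.  Stage 2 recomputes DC,
BC, CC **on the stage-1 subnetwork** — medians are never inherited from
the parent graph — and keeps nodes strictly (`>`) above all three
medians.  The inclusive/strict comparators are flags (`stage1_cmp`,
`stage2_cmp`) because the published wording ("two times higher than",
"higher than") supports either reading.  Hub selection ranks the
core subnetwork by each metric, takes the top-k (default 10) *including
all ties at the k-th value* — deterministic and order-independent — and
intersects the three sets.

Centralities are computed on the largest connected component, because
closeness is undefined across components; excluded nodes are logged.
BC is Brandes' unnormalized geodesic count; since the screen only ever
compares medians and ranks, any positive rescaling of BC provably
changes nothing (covered by a test).  CC is `(n_c − 1) / Σ d(v, u)`
within the component of size `n_c`.

### Enrichment

Over-representation is the hypergeometric upper tail `P(X ≥ k)` for the
overlap `k` between query and term within the background universe,
computed via the survival function in log space, BH-adjusted across the
tested terms (those with `k ≥ 1`).  The default background is the union
of all collection members (DAVID-like) and can be overridden.  The
default significance gate is `q < 0.05`; `adjust=False` flags on raw
`p < 0.05` to mirror DAVID/ClueGO defaults.  Term grouping à la ClueGO
(kappa networks) is out of scope.

### Docking aggregation

The docking module only *consumes* AutoDock-style outputs: a complete
ligand × receptor matrix of binding energies in kcal/mol.  "Stronger
binding" means more negative energy.  Pairs are ranked ascending with
lexicographic tie-breaks; the total is the plain sum of all cells.  In
the bundled 7 × 6 matrix, the published narrative and the published
table disagree on which of the two strongest MCM2 binders scored
−7.44 kcal/mol (senkyunolide G vs ferulic acid); the table is taken as
authoritative, so the best pair is (Ferulic acid, MCM2, −7.44).

## Synthetic data: what it emulates, what it does not

The generators replace five online resources with seeded simulations:

- **Interactome** — Barabási–Albert preferential attachment
  (`n_nodes = 500`, `edges_per_new_node = 3` by default): connected,
  simple, heavy-tailed like real PPI networks, which is the property the
  median filters exploit.  No attempt is made to match any real
  interactome's size or clustering, and multi-database evidence merging
  is not modeled.
- **Planted module** (`n_module > 0`) — the last `n_module` symbols form
  a clique, each member additionally wired to its own staggered window
  of the `2 × module_hub_links + n_module` highest-degree backbone
  nodes.  The staggering matters: members attached to an *identical*
  hub set are topologically interchangeable, their shared centrality
  value tends to sit exactly at the screened network's median, and the
  strict stage-2 rule then excludes the whole block — a degenerate
  symmetry real disease modules do not have.  Distinct windows give
  each member its own bridging role.
- **Compound table** — OB ~ U(0, 100), DL ~ U(0, 1), whitelist flags
  i.i.d. Bernoulli(`whitelist_rate`), herbs cycling through `n_herbs`
  names: both sides of both thresholds are always exercised.
- **Expression cohorts** — `n_cohorts` (default 3) series over a shared
  namespace; one shared planted set of `n_de` genes shifted by
  ±`effect_log2fc` in tumor samples (sign fixed per gene across
  cohorts), additive Gaussian noise (sd `noise_sd`) on log2 scale,
  per-cohort baselines.  Defaults (2000 genes, 50 planted, |log2FC| = 2,
  sd = 1, 20 vs 20) represent a strong, clean microarray signal.  No
  normalization artifacts, probe effects, batch effects or missing
  values are simulated — passing recovery tests therefore demonstrates
  correctness of the procedure, not robustness to real microarray
  pathology.
- **Gene sets** — `n_terms` random draws without replacement, sizes
  uniform over `term_size_range`, plus an optional spiked term equal to
  a caller-supplied list (a known enrichment positive).

Determinism: each generator call derives its own sub-seed as
`(seed × 1000003 + crc32(call_name)) mod (2³¹ − 1)`, so calls are
independent of each other and reproducible byte-for-byte.  Planted
truths (module members, DE genes, spiked term) are always returned or
stored explicitly, never re-inferred.

## End-to-end study condition

The pipeline-level recovery experiment uses a 300-node interactome with
an 8-gene planted module, 80 planted DE genes among 800 (the module
included), 3 cohorts of 12 vs 12, and 8 targets per compound with the
module distributed among the compounds' targets — i.e. a disease with a
broad expression signature whose core module the formula actually hits.
The breadth is deliberate: it keeps the merged drug ∩ disease network
large enough (~90 nodes) that stage medians are set by background
topology rather than by the module itself.  Under these conditions the
module is recovered into the core-target set essentially completely
across seeds.

## Numerical and edge-case choices

- Median of an even-length list: mean of the two middle values.
- Empty results are legal everywhere downstream of validation: a
  regular graph annihilates under the degree filter; vertex-transitive
  graphs yield empty core sets; queries disjoint from every term yield
  empty enrichment tables.
- Hypergeometric inputs are bounds-checked; `k = 0` returns exactly 1.
- BH is delegated to `statsmodels`; its output is property-tested
  against a literal step-up implementation to 1e-12.
- Welch p-values of NaN (zero variance in both groups) are replaced by
  the forced-separation convention above; one-group-zero-variance cases
  are left to Welch, which handles them.
- Docking rank tie-break: (energy, ligand, receptor) lexicographic.

## Calibration caveat

Under null queries the hypergeometric test's positive rate at
`p < 0.05` is systematically *below* 0.05 (observed ≈ 0.02–0.03 at the
default synthetic sizes): the statistic is discrete, so
`P(p ≤ α) ≤ α` with a strict deficit for small contingency tables.
Tests and the acceptance script therefore check the enrichment null
rate as a one-sided bound, while the (continuous) Welch null rate is
checked two-sided against the nominal 5 %.

## Known limitations

- The published pipeline's headline counts (243 putative targets, 189
  common disease genes, the 4,961/110,021 → 1,762/39,450 → 460/17,748 →
  123/2,808 network cascade, 6 hub targets) depend on 2020 versions of
  commercial/curated databases and are not reproducible from shipped
  data; they serve as qualitative references only and are asserted
  nowhere.
- No microarray preprocessing, probe-to-gene collapsing, or GEO
  retrieval; no live TCMSP/SwissTargetPrediction/DAVID/ClueGO queries;
  no docking engine; no visualization layouts.
- Enrichment treats terms independently; term-term redundancy (shared
  genes between GO terms) is not modeled or corrected for.
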