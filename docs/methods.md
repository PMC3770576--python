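# Methods

## Data model

Genotypes are haploid calls at a panel of biallelic mtDNA SNPs mapped to
1-based rCRS (NC_012920) coordinates; internally sites are 0-based column
indices and calls are `REF=0 / ALT=1 / MISSING=-1`. Heteroplasmy is out of
model: heterozygous diploid-style VCF genotypes become MISSING with a
warning. Multiallelic records are rejected rather than split, because the
single-mutation edge model of the network assumes binary sites.

Missingness policy (upstream array data are typically near-complete, and
collapsing requires complete vectors): individuals with more than
`max_missing_rate` (default 0.05) missing calls are dropped, remaining
holes are imputed to the panel-wide major allele at the site (ties to
REF), and a site missing in every retained individual is an error. Drops
and imputations are itemized in a report, never silent.

Collapsing maps each distinct allele vector to one haplotype; haplotypes
are ordered and numbered lexicographically by allele vector so output is
deterministic. The member sets partition the retained individuals.

## Phenotypes

* `HOC = [hipp_L/(hipp_L+ilv_L) + hipp_R/(hipp_R+ilv_R)] / 2`, in [0, 1];
  low values indicate degenerative atrophy. Zero hemisphere denominators
  raise.
* Percent change over two years: `100*(followup-baseline)/baseline`
  (loss negative); change scores are plain differences. Atrophy phenotypes
  are total two-year percent change, not annualized.
* Volume normalization defaults to the ICV proportion rescaled by the
  sample-mean ICV, keeping values on the mm^3 scale; plain proportion and
  passthrough are configurable.
* APOE enters the clade scan as a binary e4-carrier flag and the
  single-variant screen as the allele count (0/1/2).
* The correlation screen is pairwise-complete Pearson with a minimum of 3
  complete pairs per cell; sparser cells are reported absent.

Missing measures propagate as NaN through every derivation.

## Network estimation

Components are connected at increasing Hamming distance d = 1, 2, ...
(Kruskal order, default limit 10 steps): a d-step connection inserts d-1
unobserved intermediate nodes, flipping sites in ascending rCRS position.
Because the connection order is a minimum-spanning construction, the total
number of single-mutation edges is minimal over all spanning topologies
(verified against brute-force Prufer enumeration in the tests). A
configurable step limit is used instead of a parsimony-probability
connection limit; an mtDNA SNP panel essentially never reaches it, and a
probabilistic limit could be added behind the same interface. If the limit
is reached the partitioned graph is returned with an explicit flag, never
silently truncated.

Two ambiguity kinds are tracked:

* **Connection loops** — a pair of haplotypes becomes connectable at the
  same distance at which their components were already joined in the same
  round (the signature of homoplasy). The alternative connection is
  materialized, creating a cycle, so with k unresolved loops the graph has
  |nodes| - 1 + k edges.
* **Path-order loops** — multi-step connections admit several orderings of
  the intermediate mutations. The ascending-rCRS order is materialized and
  the alternatives recorded as metadata only: every ordering induces the
  same bipartitions of observed haplotypes, so they cannot affect any
  test.

Resolution applies two criteria in order: (1) *age* — the child keeps the
edge to the candidate parent with the higher ancestry score, a 50/50 blend
of relative haplotype frequency and closeness centrality rescaled to
[0, 1] (interior, frequent nodes are plausibly older); (2) *frequency* —
on a score tie, the higher-count parent. Double ties stay unresolved and
are carried into scanning by enumerating each alternative resolution and
tagging the resulting contrasts with a resolution id, so the ambiguity is
reported side by side rather than guessed away. Resolving a loop removes
the rejected connection's edges plus any inferred nodes it strands; for
single-step loops (the homoplasy case) node count is preserved exactly and
edge count drops by one per resolved loop. The root is the ancestry-score
argmax with a lexicographic allele-vector tie-break.

Contrasts: every bridge edge of the (resolved) tree is cut and induces a
bipartition of observed haplotypes, hence of individuals. Cuts flanking
the same inferred chain induce identical bipartitions; they are merged
into one contrast retaining all contributing branch ids, because they are
statistically the same test and counting them twice would distort the
multiplicity correction. The clade side (`side_a`) is the smaller group.

## Association scan

Statistic: partial F (1 numerator df) for the group indicator in OLS of
the phenotype on intercept + covariates + group. With a binary group this
equals the squared covariate-adjusted two-sample t, so "difference in
average phenotype" and ANCOVA formulations coincide. Rank-deficient
designs (group collinear with a covariate) raise with the offending
columns named. Contrasts with fewer than `min_group` (default 5)
analyzable individuals on either side — assessed per phenotype, since
missingness differs across phenotypes — are reported as skipped.

Permutation null: Freedman–Lane. The phenotype is regressed on the
covariates only; the residuals are permuted with a seeded generator
(`numpy` PCG64), fitted values added back, and all contrast statistics
recomputed per permutation. One shared permutation stream serves every
contrast in a family and both covariate models, because the minP
correction needs the joint distribution. Plain phenotype shuffling is
available as a configured fallback. The whole scan is vectorized: with QR
residualization the per-permutation statistics for all contrasts reduce to
one matrix product.

Nominal p defaults to the analytic F tail probability — permutation
estimates are quantized at 1/(B+1) and cannot produce values such as
8e-4 at B = 10,000 unless the analytic route is taken — with the
+1/+1-corrected permutation estimate `(1 + #{F_perm >= F_obs})/(1 + B)`
available by configuration (the +1 avoids zero p-values).

Corrected p: Westfall–Young free step-down minP over the shared
permutation matrix. Contrasts are ordered by ascending nominal p;
per-permutation pseudo-p values (analytic transforms of the permuted F in
analytic mode, within-row ranks in permutation mode) are suffix-minimized
down the ordering; the corrected p is the +1/+1 exceedance rate of those
minima, made monotone along the ordering and floored at the nominal p.
In analytic mode the ordering by p coincides with descending F; in
permutation mode each contrast has its own discrete null, so monotonicity
is guaranteed along the step-down (nominal-p) ordering.

Second round: for a significant branch, each side is subdivided by the
network cuts interior to it (a three-allele system with the opposite side
held fixed). The statistic is the covariate-adjusted F between the two
sub-alleles computed on the focal side's individuals only, and the
permutations shuffle residuals only within that side — the conditional
null. Step-down correction applies within this conditional family. Sides
that cannot be split under `min_group` are reported unsplittable.

Single-variant screen: per-site ANCOVA partial F with covariates age, sex
and APOE allele count; monomorphic sites yield an absent p with a reason.
The per-test Bonferroni threshold is family alpha / number of sites
truncated to one significant figure, matching the convention in which
0.05/138 is printed as 0.0003.

## Haplogroup naming

Clades are named by a three-step shared-variant procedure: intersect the
ALT variants common to every haplotype in the clade, look each up in a
user-supplied phylotree-style rule table (variant -> carrier haplogroups,
minus haplogroups flagged back-mutated for that variant), and keep the
haplogroups consistent with all shared variants. One candidate is a
plausible assignment; an empty or larger-than-threshold set (default 10)
is reported indistinguishable — sparse SNP panels often cannot separate
major haplogroups. Unknown variants are listed and block the
single-candidate status. The rule table is a TSV snapshot supplied by the
user; the bundled `synthetic_haplogroup_rules.tsv` is a small constructed
fixture covering the K and U5 lineages plus decoys, not a phylotree
export, and conflicting literature for a variant must be resolved by the
table's author, not the code.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, at
desk scale: default 500 individuals on 40 haplotypes at 138 sites
(downscaled from a cohort-scale 821 individuals / 196 haplotypes on the
same panel width). A genealogy grows by sequential uniform attachment;
each edge carries one distinct site (infinite sites), so each haplotype is
the XOR of the mutations on its root path and the true network is a
unique single-SNP-per-edge tree — which is what makes exact
network-recovery oracle tests possible. Optional homoplasy reuses the site
of a grandparent edge on a descendant edge two steps below, producing
exactly one equally parsimonious alternative connection (one ambiguity
loop) in the estimated network. Individuals are drawn onto haplotypes with
power-law-skewed weights (every haplotype gets at least one carrier, so
collapsing inverts the assignment exactly); the planted branch is the
genealogy edge whose subtree tally is closest to the configured clade
size.

Covariates loosely match an elderly neuroimaging cohort — age ~ N(75, 7),
55% male, APOE e4 allele counts (0.5/0.4/0.1, ~50% carriers), CN/MCI/AD
mix — with no claim of demographic realism. The phenotype is

```
y = b0 + b_age*age + b_sex*male + b_apoe*carrier + delta*sigma*clade + N(0, sigma^2)
```

with defaults b_age = 0.05, b_sex = 0.5, b_apoe = -0.5, sigma = 1; the
published region-class panel composition is reproduced for 138-site runs
(its printed counts sum to 128, so the remaining 10 sites are filled as
protein-coding). Missingness is completely at random only, applied
separately to phenotypes and (optionally) genotypes. What passing tests on
these data do **not** show: robustness to recurrent mutation beyond a
single event, informative missingness, population stratification,
non-Gaussian phenotype noise, or genotyping error.

## Numerical and design notes

* Determinism: a single global seed fans out to per-stage seeds by stable
  SHA-256 hashing of stage names; identical seed + inputs give
  byte-identical reports.
* Degenerate fits: a phenotype perfectly explained by covariates gives
  F = 0, p = 1; a group term absorbing all residual variance gives
  F = inf, p = 0; collinearity thresholds are relative (1e-10, 1e-12).
* Ties in ancestry scores are compared at 1e-12; root and haplotype-id
  tie-breaks are lexicographic on allele vectors.
* Problem sizes in the test and acceptance suites (e.g. 300 null datasets
  of 150 individuals at 200 permutations; 200 planted datasets of 500
  individuals at 300 permutations; exhaustive network checks on up to 6
  haplotypes over 8 sites) were chosen as the smallest scales at which the
  targeted properties are statistically decisive; all complete in tens of
  seconds on one CPU.
* The per-case tolerance for Monte-Carlo vs exhaustive permutation
  agreement is statistical: a 2-SE band is a 95% interval, so the suite
  requires 2-SE coverage consistent with the binomial expectation and a
  4-SE hard cap, rather than demanding every case fall inside 2 SE.

## Known limitations

Recombination is assumed absent (appropriate for mtDNA). The TCS-style
95% parsimony connection limit is replaced by a fixed step limit. The
ancestry score is a heuristic stand-in for outgroup-weighted rooting.
Second-round families inherit the first round's resolution choice.
Haplogroup calls are only as good as the supplied rule table and the
panel's marker density.
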