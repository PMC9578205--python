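# Methods

## Data model

Genotypes are biallelic SNPs over diploid samples (`genomatrix`). All
internal coordinates are 0-based half-open; VCF positions are converted
on ingest and restored on output. A half-called diploid ("./1") is
treated as fully missing — the simplest consistent contract for
frequency- and window-based statistics. Strand is ignored everywhere
except fourfold-degenerate site calling. Matrices are flagged phased
only when every call in the source VCF used the `|` separator;
haplotype-level operations (haplotype extraction, tract implanting)
refuse unphased input rather than guessing phase.

## Neutral-site selection

Fourfold-degenerate sites (`sitefilter.fourfold_sites`) are third codon
positions whose codon family encodes one amino acid under the standard
genetic code, called strand-aware from a reference FASTA and CDS GFF3
with phase adjustment. Only the reference annotation determines
degeneracy; no check is made that an observed SNP preserves it (site-
class masking semantics). CDS groups whose phase-adjusted length is not
a multiple of 3 are skipped with a warning; overlapping-frame positions
are implicitly excluded by per-transcript scanning.

LD pruning (`sitefilter.ld_prune`) is a greedy left-to-right scan on
diploid dosages: a variant is dropped when its squared Pearson
correlation with any of the last 49 (window 50) retained variants
strictly exceeds the threshold (0.5 for structure-style filtering, 0.1
before demographic inference). r² on dosages is phase-free and differs
from EM haplotype r²; the window is defined over retained sites, which
makes pruning idempotent. Monomorphic sites are retained untested
(correlation undefined).

## Joint SFS

The observed spectrum (`sfs`) is polarized by the Middle Eastern
domestic outgroup: the ancestral allele is the allele fixed among called
outgroup alleles; sites with a polymorphic or missing outgroup are
dropped with logged reasons. Projection to fixed haploid sizes is the
expected (fractional) hypergeometric downsampling used by easySFS/dadi:
each site contributes to cell (k₁…k_g) the product over groups of the
probability of drawing k derived alleles without replacement from the
group's called alleles. Fractional projection is deterministic;
total cell mass equals the number of retained sites, and projecting to n
then to m < n equals projecting directly to m (hypergeometric
consistency, tested to 1e-9). Only the unfolded spectrum is supported —
an outgroup exists by design. Spectra serialize to a small plain-text
format and a dadi-style reader is provided for interoperability.

## Coalescent engine

`coalsim` wraps msprime behind a compact `DemographicModel`: demes with
piecewise-constant diploid Ne, clean splits (backwards in time all child
lineages join the parent deme, which persists as the ancestral deme),
and one-way admixture pulses (backwards, each recipient lineage moves to
the donor with probability α). Models validate structurally before
simulation: positive event times, α ∈ [0,1), exactly one root deme, and
no event referencing a deme after its merge.

SFS replicates do not drop mutations site by site: conditional on a
genealogy, infinite-sites mutation counts per derived-count cell are
independent Poisson variables with mean μ × (branch length subtending
the cell), so each locus contributes its branch-mode allele-frequency
spectrum and Poisson noise is added once over the locus aggregate. This
is exact under the infinite-sites model and an order of magnitude faster
than sequence simulation. Window mode (for the FST null and genotype
scenarios) simulates one genealogy per window with no intra-window
recombination — matching the block structure of SFS-based simulators —
and pairs consecutive haplotypes into diploids (exchangeability makes
the pairing arbitrary). Mutation model: μ = 1 × 10⁻⁸ per bp per
generation, generation time 2 years; both are fixed constants of the
study system, not estimated.

## Demographic model choice (rejection ABC)

`abcdemog.builtin_models` encodes the four competing histories on the
topology ((Ws,Cs),(Ec,MEc)) with Ec branching from MEc:

* **M1** early Ws/Cs split + differential introgression (independent
  pulses Ec→Ws and Ec→Cs);
* **M2** early split + one late pulse (into Ws, the deme flagged by the
  D-statistic analyses as the introgressed one — the schematic leaves
  the single-pulse target open);
* **M3** late split + early pulse (necessarily into the ancestral
  wildcat deme);
* **M4** late split + late pulse, landing in the ancestral wildcat deme
  whenever the drawn pulse time predates the split (in the merge
  representation this is automatic: the parent deme carries the
  ancestral lineages).

Default priors (overridable; the study's own prior table is not public,
so these are declared stand-ins anchored to reported values): late split
U(50, 500) generations, early split U(2000, 5000), late pulse
U(250, 1100), early pulse U(900, 1500), α U(0.01, 0.5), all Ne
log-uniform(10², 10⁵). Domestication split U(3000, 8000) and root
log-uniform(2×10⁴, 10⁵) generations reflect domestication ≈ 10 ky and a
silvestris/lybica divergence of order 10⁵ y at 2 y/generation.

The reference table stores, per prior draw, the flattened joint SFS with
the two monomorphic corner cells removed. Rejection: each summary
coordinate is standardized by its median absolute deviation over the
pooled table (zero-MAD coordinates dropped with a warning), Euclidean
distances to the observed spectrum are ranked, and the closest
`tolerance` fraction is accepted; model posteriors are acceptance
shares. No regression adjustment is applied — the study reports raw
acceptance percentages. A posterior-predictive check re-simulates
spectra at accepted draws and reports the fraction of observed cells
inside the 2.5–97.5% envelope.

**Desk-scale configuration and a known limitation.** The packaged
experiments use 4 haploid samples per deme (spectrum shape 5×5×5×5) and
100 loci × 25 kb per spectrum, chosen so that summary cells are dense
enough to survive MAD standardization; the full-scale 17×17×17×11
spectrum is almost entirely zero-MAD at feasible table sizes (and an
8000-row table of it would not fit memory). At this scale the model
*selection* problem is only partially identified: with wide Ne priors an
early-split model can mimic a late split (large Ne makes post-split
drift negligible) and near-equal differential pulses mimic a single
ancestral pulse, so an M4-generated spectrum is typically assigned M4
only as the modal model, not with a decisive posterior. The
corresponding acceptance test states the decisive-posterior requirement
and is expected to fail at desk scale; parameter posteriors for the
split and pulse times remain informative. Full-data analyses with
narrow, externally calibrated priors do not face this degeneracy in the
same way.

## Introgression statistics

Site patterns use derived-allele frequencies with the ancestral allele
taken as the outgroup majority (a 50/50 outgroup tie is uninformative
and skipped; unlike SFS polarization, outgroup-polymorphic sites are
retained with p₄ the outgroup derived frequency — the frequency
formulation uses it directly). D sums weights over sites; the block
jackknife deletes one of 20 contiguous equal-site-count blocks at a
time, SE² = (B−1)/B × Σ(θ₋ᵢ − θ̄₋)², Z = θ/SE, two-sided normal p.
Blocks without informative sites are merged into a neighbor. The
working significance threshold |Z| > 3 is exposed as configuration.
Windowed D defaults to 100-kb non-overlapping windows; wider display
windows are a parameter, not a different method.

f̂ splits the donor panel into random halves (seeded), substitutes one
half for the recipient and the other for the donor in the S-sum, and
reports num/den with a jackknife CI of the ratio. An odd donor panel
leaves one sample out with a warning.

## Known-truth calibration scenario

`synthdata.calibration_model` fixes the demography used for D/f̂
validation: wildcat demes at Ne 20,000 with a 100-generation split (the
recipient side of the tree stays symmetric, minimizing baseline
ABBA/BABA asymmetry), a European domestic deme bottlenecked at Ne 1,000
since its 2,000-generation split (domestication-style drift — the
drifted donor frequencies are precisely the signal both D and the f̂
denominator measure), root at 10,000 generations with ancestral
Ne 30,000 (retaining cross-species shared polymorphism). Scenarios are
simulated as four recombining 4-Mb contigs (r = 10⁻⁸), giving ~90k SNPs
whose between-site independence makes the 20-block jackknife well
calibrated; the donor pool doubles the Ec sample so implant donors stay
outside the analysed P3 panel (otherwise f̂ is inflated by
panel-sampling covariance). Implanted tracts are 50-kb slots drawn
without replacement over (haplotype, slot) pairs, so the implanted
fraction is exact up to slot granularity and truth intervals are
recorded. Under this design the no-gene-flow scenario gives |Z| < 3 and
an f_true = 0.10 implant gives Z ≈ 10–15 with f̂ within ±0.01 of truth
per replicate.

What the generator does *not* emulate: sequencing/genotyping error,
missing data patterns, variable recombination and mutation rate,
reference bias, and continuous (as opposed to pulse) gene flow. Passing
tests therefore demonstrate correctness of the statistics under the
stated models, not robustness to real-data artifacts.

## FST scan and enrichment

Per-site Weir–Cockerham components a, b, c for two populations are
computed from called-diploid counts, allele frequencies and observed
heterozygosity; windows report Σa/Σ(a+b+c) (the VCFtools "weighted"
convention) over polymorphic, usable (≥2 diploids per group) sites, and
negative estimates are kept — the estimator is not clamped. The null is
the same 10-kb window statistic on sequences simulated under the
best-fit neutral demography sampling the two wildcat demes; the
empirical 0.99 quantile (linear interpolation) is the outlier threshold,
computed over polymorphic simulated windows only, mirroring the
empirical emission rule. Note that with one genealogy per 10-kb window
the panmictic null quantile is far from zero (~0.19 at 16+16 haploids) —
all window sites share one tree, so the estimator has heavy tails under
panmixia; calibration is therefore checked as "≈1% of same-model windows
exceed the threshold", which holds.

"Falls within a gene" is interpreted as any window/gene interval
overlap (half-open), not containment — containment would drop genes
shorter than a window. Enrichment is a one-sided hypergeometric
(classic Fisher) test per GO term with BH q-values over all tested
terms; the topGO "weight01" GO-graph decorrelation is deliberately not
implemented and outputs are labelled "classic-Fisher".

## Runs of homozygosity

The scanning-window algorithm: a window of `window_snp` consecutive
sites is homozygous-compatible iff it has ≤ `window_het` heterozygous
and ≤ `window_missing` missing calls; a site is eligible iff its hit
rate (compatible windows containing it / windows containing it) is
≥ `window_threshold` — the boundary is inclusive here, a declared
divergence from PLINK's strict inequality, covered by a test at exactly
0.05. Maximal eligible runs are split at inter-site gaps >
`max_gap_kb`, then broken at heterozygous calls so that no segment
carries more than `max_het_in_segment` of them (the violating call
starts the next piece), then filtered by `min_snp`, `min_kb` and
`max_density`. Segment endpoints are the first/last eligible site
positions. Sites are pre-filtered to ≥90% genotyping rate. The
per-site denominator ("windows containing it") near chromosome ends is
a declared choice, not asserted PLINK-identical. F_ROH divides summed
segment length by the genome length, taken from configuration as the
summed analysed contig lengths ("genome length" is ambiguous between
assembly and callable length; the choice is declared). Group
comparisons use Welch t-tests with Bonferroni correction.

## Haplotype networks

Haplotypes are allele strings over a region's phased variant sites (not
reference-spliced sequences); samples with missing calls in the region
are excluded and listed. The network is a minimum-spanning network:
Kruskal over Hamming distances where, within each weight class, every
edge joining components that were separate when the class was reached is
kept (ties not broken). TCS statistical parsimony is approximated by a
connection limit: the automatic limit is the largest step count j whose
no-homoplasy probability — approximated as ∏_{i<j}(1 − i/L) for L
variable sites, the probability that each successive mutation hits a
previously unhit site — stays ≥ 0.95. The exact Templeton–Crandall–Sing
recursion is not implemented; outputs are labelled as the approximation.

## Problem sizes and numerical choices

Test and reproduction runs use: 16-Mb genomes (4 × 4 Mb) for
introgression calibration; 2,000 simulated windows each for the FST
null and its calibration check; 2,000 draws per model (tolerance 1%)
for the ABC experiment at 100 × 25-kb loci per spectrum; 5,000 loci for
the diversity calibration and 50,000 for the neutral-SFS shape check;
and ≤ 800-site inputs for the 100-fold ROH oracle comparison. Quantile
interpolation is linear (type 7); random seeds below 2³¹ are derived
from a single generator per run; simulation results are bit-reproducible
given (model, seed).

## Interfaces

The package is a library: the functions and `scripts/acceptance.py` are
the interface, and every external format is plain text (VCF 4.2, BED,
GFF3, TSV population maps and tables, FASTA, dadi-style SFS, nexus-style
network export). No separate command-line tool is shipped — the
analysis surface is too composite for a useful flag set, and the worked
examples cover the common paths.
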