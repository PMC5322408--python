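# Methods

This note records the statistical models behind `depthcline`, the defaults
that matter, and the choices made where more than one defensible
convention exists.

## The problem setting

A mixed-species gill-net survey of a lake samples fish at several depths,
dates and mesh sizes. If several closely related species spawn along the
depth gradient, every catch is a mixture: the survey must first undo the
gear's length selectivity, then decide how many growth clusters the
length-at-age data support, and only then ask whether those clusters are
genetically differentiated (reproductively isolated species) and whether
genetic distance tracks adaptive phenotypes (isolation-by-adaptation)
rather than geography (isolation-by-distance).

## Gill-net selectivity

Retention of a mesh is modelled as a skew-normal function of standard
length, `f(SL; ξ, ω, α)` with location ξ (mm), scale ω (mm) and shape
α ≥ 0 (right skew). Because the mesh panels are fished in series with
equal effort, the catch-at-length of one mesh is treated as a sample from
its retention curve, and (ξ, ω, α) are estimated by direct maximum
likelihood (L-BFGS-B on the negative log-likelihood; method-of-moments
start, α started at 1 with extra fixed starts at 0.1 and 3; ω bounded to
[0.05, 10]× the sample sd). No contact-versus-retention decomposition and
no effort standardization are attempted.

Two caveats are deliberate:

* α is weakly identified near 0 (the Fisher information is singular
  there), so individual fits on symmetric data can return α up to ~1
  while the fitted density is essentially normal. The fitted *mode* is the
  stable quantity and is what the class boundaries use.
* Curves are rescaled to unit maximum before anything else is done with
  them; class boundaries are the crossings of adjacent unit-scaled curves,
  bracketed between the two modes and refined by bisection (tolerance
  1e-6 mm). The evaluation grid is 1 mm over the observed SL range ± 20 mm.
  k meshes give k − 1 boundaries; intervals are half-open, so a fish
  exactly on a boundary joins the lower class, and fish outside the fitted
  range join the nearest extreme class with a warning. Meshes with fewer
  than 10 measured fish are fitted but flagged unreliable.

## Growth-cluster delineation

All delineation operates on standard length of a single age class
(three-year-olds by default), since SL-at-age proxies growth rate.

**Mixtures.** Univariate Gaussian mixtures with k = 1..3 components are
fitted by EM and compared by AICc with p = 3k − 1 free parameters:
`AICc = −2 ln L + 2p + 2p(p+1)/(n−p−1)`. EM is initialized from a
Lloyd-refined k-means partition (means, within-cluster sds, proportions),
run with 10 restarts per k, a component-sd floor of 1 mm, and stopped when
the mean per-observation log-likelihood gain falls below 1e-6. The
k-means initialization matters: seeding EM with raw k-means++ draws and a
very strict tolerance finds the spurious narrow-component optima that
plague heteroscedastic mixtures and inflates AICc overselection on
unimodal data. The selected k is the AICc argmin; fits within ΔAICc < 2
are additionally reported as equally likely.

**Tree cut.** The dynamic tree-cut idea — detect preliminary clusters from
the dendrogram, then attach stragglers — is implemented as recursive
splitting of the average-linkage tree on |ΔSL| distances. A split is
accepted only when the two branches are separated by a genuine density
valley: a Gaussian KDE of the parent's values (bandwidth `n^(-1/5)` times
the smaller within-branch sd, since the parent's pooled sd is inflated by
the separation being tested) must dip, between the branch medians, below
half the lower of the two branch peak densities. Branches smaller than
`ceil(0.10 n)` are left unassigned in stage 1 and attached to the nearest
cluster medoid in stage 2; clusters are labelled 1..k by ascending medoid.
This reproduces the published algorithm's contract (no prespecified k,
minimum cluster size 10% of N, detect-then-attach) without its many
internal constants; recovery is validated behaviourally (trimodal
simulations with ≥ 3 sd separation recover k = 3; unimodal controls stay
at k = 1). Fish from other sites or ages are assigned to the nearest
medoid, ties to the lower-SL cluster.

Age differences between SL classes use two-sided Mann–Whitney U tests
(exact null enumeration when both classes have ≤ 20 aged fish).

## Population genetics

Missing genotypes are handled by per-locus pairwise deletion everywhere;
gene counts are locus-specific. All permutation p-values use
(b + 1)/(m + 1).

* **Diversity.** H_O is the heterozygote fraction; H_E uses the
  small-sample correction `2n/(2n−1) · (1 − Σp²)`. F_IS per locus is
  `1 − H_O/H_E` (undefined at monomorphic loci); the multilocus value is
  the ratio of sums over loci.
* **θ (F_ST).** Weir–Cockerham variance components a, b, c per allele and
  locus, combined as a ratio of sums. Negative estimates are reported as
  computed. Pairwise significance permutes individuals between the two
  groups; flags are BH-FDR corrected across pairs.
* **AMOVA.** Variance components among groups / among individuals within
  groups / within individuals from allele-indicator sums of squares; these
  equal the Weir–Cockerham components, so Φ_ST coincides with θ (the test
  suite checks the two code paths agree to 1e-6). Negative components are
  retained, not zeroed. Significance permutes individuals among groups.
* **Hardy–Weinberg.** Exact conditional test on the Levene distribution.
  Loci with ≤ 3 alleles and ≤ 12 typed individuals are enumerated
  completely; otherwise a Metropolis chain over genotype lists is run with
  allele-swap proposals. The chain's target on lists is 2^het with a
  Hastings correction for gene choice (a homozygote offers its allele at
  both positions); this makes the table marginal exactly the Levene
  distribution, which the tests verify against enumeration. Desk defaults
  are 100,000 steps after 1,000 dememorization steps; `--full` restores
  10,000,000 / 10,000.
* **Linkage disequilibrium.** G-statistic on the two-locus genotype
  contingency table, null by shuffling one locus within the group.
* **Rarefaction.** ADZE-style hypergeometric formulas: expected distinct
  alleles at g genes, private richness for one group, and generalized
  private richness for any group subset (allele present in every member's
  subsample and absent from every other group's). Standardized g defaults
  to the smallest per-group gene count. Exact agreement with exhaustive
  subsample enumeration is part of the acceptance suite.
* **Distances and trees.** Smouse–Peakall individual distance: half the
  squared Euclidean distance between allele-count vectors per shared
  locus, summed. Cavalli-Sforza chord distance per locus is
  `sqrt(2(1 − Σ√(p q)))`, averaged over loci typed in both populations —
  dialects differ between programs, and this per-locus-average convention
  is the one fixed here. Neighbour-joining uses scikit-bio's Saitou–Nei
  implementation; bootstrap replicates resample loci with replacement and
  supports are bipartition percentages on the reference topology.

## Association tests

Mantel r is the Pearson correlation of off-diagonal elements; the null
permutes rows and columns of the first matrix simultaneously; p-values are
one-sided (observed or larger), matching the common vegan default. The
partial Mantel test residualizes both matrices on the control matrix and
permutes the residualized first matrix (the residual-permutation variant;
several variants exist and the choice is documented here, validated by
type-I-error simulation). Phenotype distance matrices use raw absolute
differences; whether to standardize first is an open convention, and raw
differences leave Mantel r unchanged under any affine rescaling of one
trait. Geographic distances are straight-line haversine (km), not
over-water least-cost paths. DAPC assignment column-centers the
individual allele-count matrix (missing calls imputed at column means),
retains the PC count minimizing cross-validated RMS of (1 − P(correct
group)) over a 1..min(rank, 50, n − folds) grid, and fits a linear
discriminant on the retained PCs.

## The synthetic survey generator

The generator produces exactly the statistical structure the analysis
assumes, which is what makes the test suite informative:

* **Genetics.** Balding–Nichols divergence: per locus, each species'
  frequency vector is Dirichlet-drawn around the ancestral vector with
  concentration (1 − F)/F, so expected pairwise θ tracks F (calibration
  checked to ±0.02 for F ≤ 0.15). Ancestral loci carry 5–12 alleles with
  broken-stick frequencies, matching microsatellite-like allelic richness
  (rarefied A_R ≈ 3–3.6 at survey sample sizes). Genotypes are drawn in
  Hardy–Weinberg proportions within species with unlinked loci — by
  construction, so HWE/LD tests on simulated data probe calibration, not
  biology. F = 0 returns the ancestral frequencies for every species.
* **Phenotypes.** SL is normal around an age-adjusted mean (+40 mm/year
  off age 3 by default); gill-raker counts are rounded normals ≥ 1;
  spawning depth is a truncated normal ≥ 0. Ages 2–6 follow a fixed
  distribution peaked at age 3.
* **Survey.** Each fish snaps to the net depth nearest its spawning depth,
  runs one Bernoulli retention lottery per mesh (unit-maximum skew-normal
  truth curves), and keeps one of the successful meshes uniformly; fish
  failing all lotteries drop out. Capture dates are uniform over the five
  survey dates and carry no genetic structure, mirroring the
  nonsignificant date effect in the field data.
* **The `lucerne3` preset** encodes the reference study conditions: three
  species with SL-at-age-3 means 200/275/350 mm (sd 15), gill-raker means
  37.8/33.3/27.7 (sd 2.63/3.79/2.83), survey design 5 depths (2–40 m) ×
  5 dates × 3 meshes (25/35/45 mm), true selectivity modes near
  203/278/353 mm, and cohort sizes 220/160/140. Two quantities the field
  study does not report were fixed once as the preset's free parameters:
  the within-species spawning-depth sd (12 m, means 32/20/8 m), set so a
  capture-depth grouping explains roughly half the genetic variance a
  length-class grouping does, as the field AMOVAs show; and the divergence
  parameter F = 0.08, inside the reported 0.019–0.124 pairwise F_ST range.

What the generator does **not** emulate: admixture or hybridization,
null alleles and genotyping error, within-species isolation-by-distance,
age-dependent selectivity beyond SL, temporal (eutrophication) dynamics,
and linkage. Passing tests therefore show the machinery is correct and
well calibrated under the model's assumptions, not that real surveys meet
those assumptions.

## Numerical conventions and degenerate inputs

Permutation counts: F_ST 10,000 and Mantel 1,000 by default, scaled to
desk sizes (≤ 1,000 / ≤ 199) inside the bundled pipeline's heavier loops;
the `--full` flag restores survey-scale settings. One integer seed drives
every stream, split deterministically per stage. Monomorphic loci give
H_E = 0 with F_IS undefined and HWE p = 1. Empty retained surveys return
empty tables with a warning. A mesh pair whose curves do not cross between
their modes raises an error naming the pair. EM components that collapse
are held at the 1 mm sd floor. Allelic codes are raw fragment sizes used
verbatim (3-digit Genepop encoding by default; 2-digit accepted).

## Problem sizes

The bundled simulations are sized for a single CPU: surveys of ~400–650
retained fish and 10 loci, 20-seed calibration studies, permutation tests
at 199–999 permutations, and HWE chains of 10⁵ steps. All reported
behaviour (estimator recovery, type-I error, cluster recovery, the
end-to-end ordering of Mantel correlations) is computed at these sizes by
the test suite and `scripts/acceptance.py`.
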