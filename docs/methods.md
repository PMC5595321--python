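# Methods

## Thermodynamic activation model

The probability that the basal transcriptional machinery (BTM) occupies a
gene's promoter is computed from an equilibrium ensemble over all
configurations of its regulatory region.  A configuration assigns each
binding site one of: free; bound; or, for repressor sites, bound-effective.
Legality rules: bound sites may not overlap; an effective repressor
forbids **all** other binding (activator or repressor) within its
repression range `d` on both sides.  "Within range" means the gap between
the two site intervals is at most the range; overlapping or touching
intervals have gap 0.  Configuration weights multiply `q_s` per bound
site, β per effective repressor, and ω per cooperating bound neighbour of
the same TF within the cooperativity range — so a cooperating bound pair
carries ω² in total.  The alternative one-ω-per-pair convention common in
the literature is available via `ThermoParams.omega_per_pair`.  With
`Z_OFF` the total weight and `Z_ON` the total weight with a factor α per
bound activator site, `E = Z_ON/(Z_ON + Z_OFF)`; with nothing bound both
sums are 1 and `E = 1/2`.  The basal promoter weight
(`btm_basal_weight`, default 1) is exposed because a fitted promoter
strength would rescale `Z_ON`.

Site weights are `q_s = K · v · exp(P_s − P_max)`.  Normalizing by the
TF's best possible score `P_max` makes `K` literally the association
constant of the strongest site; the unnormalized `exp(P_s)` convention is
available via `normalize_by_max=False` (it only rescales `K`).

Two evaluation routes exist and must agree exactly: explicit enumeration
of all legal configurations (`brute_force_partition`, the oracle, up to 16
sites) and a memoized frontier dynamic program (`partition_functions`)
that scales to hundreds of sites by discarding bound sites that can no
longer interact with undecided ones.  Interaction reach is the maximum of
all cooperativity and repression ranges; a site leaves the frontier only
when its end plus the reach is strictly left of the next site's start.
The DP accepts weight *vectors* (one entry per nucleus × time point) and
broadcasts, which is what makes whole activation fields cheap.
Equivalence is enforced by a 1000-instance randomized test at 1e-10
relative tolerance.

### Perturbation algebra

A point mutation at column `j` of a site changes the weight linearly:
`q(S̃) = q(S) + q(S̄)·δ` with `q(S̄)` computed from the score with the
`j`-th column's contribution removed and `δ = exp(L_new) − exp(L_old)` on
that column's log-odds.  This realization is forced by requiring the
identity to hold exactly (it is verified to 1e-12 relative on random
PWM/site/mutation triples); any alternative constant scaling of δ would
rescale `q(S̄)` correspondingly.  Because every configuration contains a
site at most once, `Z_ON` and `Z_OFF` are multilinear in the site weights,
hence affine in each δ at fixed others — checked by vanishing second
finite differences.  Sensitivities ∂E/∂q_s use central differences with
one step of Richardson extrapolation (step `1e-6·q_s`, floored at 1e-8),
accurate to ~1e-5 relative against plain central differences.

Whether cooperativity applies across an intervening effective repressor
is not constrained by the model statement; the implemented rule is that
cooperativity factors apply whenever both sites are bound and within
range, regardless of what sits between them.

## Binding-site annotation

PWMs are natural-log odds against a supplied background; count matrices
are converted with pseudocount 0.5.  Thresholds are `mean + 3 s.d.` of the
exact score distribution over all 4^k k-mers, computed from per-column
moments (columns are independent, so the column-moment sums equal full
enumeration; the uniform k-mer distribution is the default, a
background-weighted variant is a flag).  Both strands are scanned; a
same-TF hit on both strands at one interval keeps the higher-scoring
strand; windows containing N are skipped and counted.  A site is a *model*
site iff its interval is fully contained in one accessible interval
(midpoint containment available as an option).  Region positions partition
into model sites, non-model sites (minus the model class), and
non-functional sequence (remainder minus CDS) split by accessibility; the
classes are disjoint and exhaustive by construction and tested as such.
Mutations never create sites: the inventory is fixed at reference-scan
time and mutated genotypes only re-score existing sites.

## Expression dynamics

mRNA and protein obey linear reaction–diffusion–delay equations driven by
the activation field `E(i, t)` (data-driven TF profiles; no feedback).
Parameters per gene: synthesis rates `R_u, R_v` (a.u./min), decay rates
`λ_u, λ_v` (1/min), per-cycle diffusion `D(n)` (1/min), and the
transcription-to-protein delay τ (min).  Boundary nuclei drop the missing
neighbour term (zero flux).  At the cycle 13 → 14A boundary each nucleus
divides, daughters `2i, 2i+1` copying the mother's concentrations.

The solver is fixed-step classical Runge–Kutta (default step 0.01 min)
with a stored mRNA history for the delay; `u(t−τ)` is linearly
interpolated on the step grid (τ must be 0 or ≥ one step), and the history
before t = 0 equals the initial condition (zero by default).  The
activation field is precomputed on the half-step stage grid by linear
interpolation in time from the per-cycle field arrays.  Verified limits:
the single-nucleus closed form `u = (R_u E/λ_u)(1 − e^{−λ_u t})` to 1e-6
relative, total-mRNA conservation at `R = λ = 0` to 1e-8, and
step-halving changes below 1e-6 relative at the default step scale.

Output is sampled at 9 times — mid-cycle-13 and the midpoints of the
eight ~6.25-min time classes of cycle 14A — giving
`4 genes × (50 + 8×100) = 3400` grid points at full scale.  Nuclei are
abstract A–P bins at positions `(i + ½)/n`.

## Scores

RMS is the root of the mean squared protein difference over all grid
points (root-of-mean, the standard RMS reading).  wPGP components per
(gene, time) are `f = 0.5 − 0.5(reward − penalty)` with

    reward  = Σ V·min(V, v) / Σ V²
    penalty = Σ min(max(0, v − V), Vmax − V)·(Vmax − V) / Σ (Vmax − V)²

summed over the nuclei present at that time.  Saturating the
overexpression excess at `Vmax − V` is this package's choice: it keeps
reward and penalty in [0, 1] and hence every `f` in [0, 1] for arbitrary
nonnegative patterns — the unsaturated numerator is unbounded for extreme
overexpression, contradicting the bound the score is supposed to satisfy —
and it leaves moderate-overexpression values (all worked examples)
unchanged.  A flat-at-maximum reference pattern with any overexpression
makes the penalty undefined and raises.  Sign classification of Δv uses a
tolerance of `1e-9 × max|V|` to guard float noise; the same tolerance
defines "non-vanishing influence" in the additivity preselection.

## Population machinery

SNP tables are haploid 0/1/missing matrices.  Raw nucleotide tables are
filtered by: dropping >2-allele rows, dropping configured bad genotypes,
relabeling heterozygous calls as missing; for density analyses rows below
the coverage floor (default 170) are dropped and the rest down-sampled to
exactly that depth (rows monomorphic afterwards are flagged
non-polymorphic); for effect scoring all polymorphic rows are kept at full
coverage.  The major allele is the most frequent non-missing call, ties
broken toward the reference.

Families of randomly mutated genotypes: neutral mode draws the configured
total of distinct positions uniformly from the model-site union,
alternative alleles uniform over the three non-reference nucleotides, and
carrier counts from the supplied SFS with a drawn frequency `f` mapping to
`min(max(1, round(f·n)), n−1)` carriers — the clamping preserves
polymorphism and spectrum shape (the mapping is otherwise unconstrained).
Population mode gives each simulated genotype exactly as many SNPs as its
template genotype, at uniform union positions.  The built-in neutral
spectrum is Watterson's `P(i) ∝ 1/i`.

## Selection statistics

All Monte-Carlo p-values use `(1 + k)/(1 + n)` (never zero with finite
resamples); two-sided is twice the smaller tail, capped at 1.  The
SNP-density comparison pairs each model-TFBS nucleotide with the
other-class nucleotides sharing its major allele (controlling GC content),
then bootstraps pairs with replacement to the focal length inside each
genotype-down-sampling fold (defaults 20 folds × 500 bootstraps),
reporting the polymorphic fraction of each pair member.  The associated
hypothesis test is a sign-flip permutation over one canonical
matched-pair sample per fold — mates assigned distinct where the partner
pool allows — which is exact under within-pair exchangeability and is
calibration-tested against a null synthetic population; the bootstrap
density distributions themselves are what the density comparison reports.
Additivity pairs `(Σ_SNP Δv^k, Δv_gen^k)` at components where ≥2 SNPs act,
labels a point "competing" when the largest single-SNP magnitude minus the
sum of the rest is below 70% of the largest, and summarizes deviation as
the mean perpendicular distance `|y − x|/√2` to the additivity line
(perpendicular rather than vertical: the two axes carry the same units).
The two-sample bootstrap tests (KS, chi-square on pooled-decile bins
merged to expected counts ≥ 5) resample both samples from the pooled data.
Permutation correlation tests (Spearman/Pearson) enumerate all
permutations exactly when `n! ≤ n_perm`.

## Synthetic data

The generator emulates the study conditions at full scale by default:
4 genes, 8 TFs (2–3 activators, the rest repressors), 800-bp regions with
an accessible core and a CDS tail, 12 planted sites per gene in two
affinity tiers (consensus, and one-substitution sites kept above
threshold) plus one deliberately overlapping pair, smooth
gaussian/exponential/logistic TF gradients over 50 → 100 nuclei with a
mild temporal ramp, thermodynamic and kinetic constants drawn once from
documented ranges, 213 genotypes and 90 SNPs under a Watterson spectrum.
Planted motifs are written into a GC-matched random background; every
planted window still scoring above threshold after all planting is
guaranteed to be re-discovered by scanning, and the mandatory ground-truth
ledger records each plant's role, tier, realized score and recovery.
Reduced presets (`SynthConfig.small`, `SynthConfig.tiny`) shrink genes,
nuclei and solver resolution for test- and calibration-scale runs; the
problem sizes used by the test suite (e.g. 1 gene × 8 nuclei for
calibration batteries, 2 genes × 16 nuclei for end-to-end checks) are
stated in the fixtures.

What the generator does **not** emulate: real fly gradient calibration,
linkage between SNPs, indels or multi-allelic variation, heterozygosity
(the model is haploid by construction), Zelda-like pioneer factors, and
site turnover (mutations never create sites).  Passing tests therefore
demonstrate internal correctness and calibration of the machinery on data
matching the model's assumptions, not fidelity to any particular real
dataset.

## Known limitations

- The quasi-equilibrium ensemble ignores binding kinetics and
  facilitated diffusion; the dynamics are deterministic and linear in `E`.
- TF concentrations are fixed across genotypes; variation in trans is out
  of scope.
- The frontier DP's cost grows with local site density and interaction
  reach; pathological inputs (hundreds of mutually-in-range sites) would
  be slow, though realistic densities are fast.
- The sign-flip density test treats matched pairs as independent;
  residual dependence from shared partners at small pool sizes makes it
  mildly liberal, which the calibration test bounds.
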