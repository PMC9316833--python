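# Methods

## Scope and data model

The package models equilibrium binding affinity (Ki, converted to the molar
negative log, pKi = −log₁₀(Ki·10⁻⁹) for Ki in nM) of small-molecule ligands
at the serotonin 5-HT6 receptor as a multilinear regression on six bespoke
molecular descriptors, and re-implements the surrounding workflow: data
curation, descriptor computation, descriptor-set search and model
validation.

All computation happens on `MoleculeRecord`, a plain snapshot of a molecule:
explicit-hydrogen graph, 3D coordinates (Å), per-atom partial charges
(elementary-charge units), element/mass, ring membership, hybridization and
attached-H counts, plus the optional activity.  Records come either from
RDKit parsing (SMILES, SDF V2000, MOL2) or from hand construction.  When an
input has no conformer, one is embedded with ETKDG at a fixed seed (42) so
descriptor values are reproducible; embedded geometries are MMFF-relaxed.

**Partial charges are consumed, never computed ab initio.**  The original
descriptors were defined over semi-empirical (PM3) charges.  Such charges
can be supplied per atom (MOL2 charge column, or an SDF `PARTIAL_CHARGES`
data field with one value per atom).  When absent, Gasteiger charges are
assigned and the record is marked `charge_origin="gasteiger"`; the pipeline
logs that descriptor values computed this way are **not comparable** to
externally charged runs.  Literature per-molecule descriptor values that
depend on the original charges/geometries are therefore treated as
reference annotations, not as assertable test values.

## Descriptor definitions

Distances "within n bonds" are shortest-path bond counts d with 1 ≤ d ≤ n —
an atom never qualifies at distance 0 from itself; "exactly n" means d = n.
The geometric gate "within 3 Å" is inclusive Euclidean distance from the
mass-weighted centre of mass (hydrogens included) to the hydrogen nucleus.

Atom classes:

* *non-polar hydrogen*: H with |q| ≤ 0.200 e (boundary inclusive);
* *lipophilic atom*: Cl, Br, I, S, or a carbon all of whose heavy
  neighbours are carbons.  The source material uses the term without
  defining it; this rule is the package's own definition, chosen so that an
  added ring methyl is lipophilic while ring carbons adjacent to nitrogen
  are not — the behaviour the published interpretation examples require;
* *H-bond donor*: N or O bearing at least one hydrogen (the classical
  donor definition);
* *sp³ N / sp² O*: by assigned hybridization; aromatic atoms form their own
  class, so an aromatic (furan-type) oxygen is not sp² for this purpose.
  Atoms with unknown hybridization are excluded from hybridization-
  dependent classes with a logged warning.

The six descriptors: `com_Hhyd_3A` (count of non-polar H within 3 Å of the
centre of mass), `ringC_S_4Bc` (charge sum over the *set* of ring carbons
within four bonds of any sulfur — a carbon near several sulfurs counts
once), `flipo&S_ringN3B` (ring nitrogens whose minimum distance to the
lipophilic∪sulfur class is exactly 3; a class member at ≤ 2 bonds
disqualifies the nitrogen), `KRFPC620` (nitrogens bearing exactly three
heavy substituents, each an ethyl CH₂–CH₃; counted per unique central N —
the Klekota–Roth fragment-620 pattern, taking the plain "three ethyls"
reading rather than the "planar nitrogen" gloss, which contradicts the
pyramidal nitrogen of triethylamine), `sp3N_sp2O_8B` (sp³ N within eight
bonds of any sp² O, per nitrogen), and `fsp3Cdon1B` (donors directly bonded
to at least one sp³ carbon, per donor).

## Curation

Removal order fixes each molecule's single primary reason: invalid
structure → metal derivative (any element outside
{H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I} anywhere in the record) →
undefined Ki → rule-of-five violator → duplicate.  Counter-ions are
stripped by keeping the largest carbon-containing fragment.  A rule-of-five
violator breaks ≥ 2 of the four criteria (MW > 500, logP > 5, donors > 5,
acceptors > 10) by default — the classical one-violation allowance — with a
strict ≥ 1 option; the source procedure does not say which it used.
Duplicates share the canonical desalted parent structure; the survivor
carries the median pKi of the group with Ki back-transformed, keeping the
Ki/pKi invariant and making curation idempotent.  Which duplicate's
activity the original study kept is unknown; the median is this package's
choice.

## Feature selection

*Objective* selection drops any column whose modal value covers ≥ 90% of
molecules, then greedily breaks pairs with |Pearson R| > 0.90 (largest |R|
first), dropping the member with the smaller |correlation with y| (ties
keep the first by position) — deterministic, and retaining the more
informative column.

*Subjective* selection is a genetic algorithm over fixed-size descriptor
subsets with leave-one-out Q² as fitness.  Defaults (the original search
tool's schedule is unpublished; these are conventional GA values):
population 100, up to 300 generations, tournament size 3, uniform crossover
with repair to size k (probability 0.8), single-swap mutation (0.1),
elitism 1, early stop after 50 stagnant generations.  Fitness uses the
exact hat-matrix LOO identity (below); rank-deficient subsets score −∞.
Best fitness is monotone across generations by elitism.  Subset size is
chosen from a Q²LOO-vs-k scan: the optimum is the size just before the
first increment whose gain falls below 0.01 (configurable); search spaces
up to 2000 subsets are enumerated exactly instead of searched.

## Validation battery

With e the training residuals and h the diagonal of the hat matrix of the
intercept-augmented design:

* R²tr = 1 − RSS/TSS; R²adj = 1 − (1 − R²)(n − 1)/(n − p − 1); RMSE uses
  denominator n (common QSAR reporting convention), MAE the mean absolute
  residual.
* Lin's CCC = 2 S_xy / (S_xx + S_yy + n(x̄ − ȳ)²) with raw sums of squared
  deviations — no degrees-of-freedom choice arises.
* Q²LOO = 1 − PRESS/TSS with the exact deleted residual e_i/(1 − h_ii); the
  test suite pins this to n explicit refits at 1e−10.  Folds with
  h_ii → 1 are flagged and excluded with a warning.
* Q²LMO pools PRESS and TSS over seeded random leave-out rounds (default
  20% out, 500 rounds), TSS referenced to the full training mean, so
  single-element folds reduce exactly to Q²LOO.
* Y-scrambling reports the mean R² over models refitted on permuted
  responses (500 permutations; the maximum is not used).
* External set: Q²F1 = 1 − Σ(ŷ−y)²/Σ(y−ȳtr)², Q²F2 uses the external mean,
  Q²F3 = 1 − (Σ(ŷ−y)²/n_ext)/(Σ(ytr−ȳtr)²/n_tr); R²ex is the squared
  Pearson correlation of predicted vs observed.
* Applicability domain: leverage h_i = x_iᵀ(XᵀX)⁻¹x_i over the training
  design, warning leverage h\* = 3(p+1)/n; standardized residuals e/s with
  s = √(RSS/(n−p−1)).  A molecule is outside the domain if h > h\* or
  |standardized residual| > 2.5 (the published plot leaves its residual
  band unlabeled; ±2.5 is the conventional choice).

Acceptance criteria: R²tr ≥ 0.6, Q²LOO ≥ 0.5, Q²LMO ≥ 0.6, R²tr > Q²LOO,
R²ex ≥ 0.6, CCC_ex ≥ 0.80, Q²F1/F2/F3 ≥ 0.60, RMSE_tr < RMSE_cv, and
R²Yscr ≤ 0.2 (the source states only "low"; 0.2 is the conventional
chance-correlation guard, and the printed 0.006 passes it comfortably).

The 80:20 split is seeded and reproducible; sizes are round(0.8·n) with the
remainder external.  The original study reports 1024/254 of 1278 (which
rounding cannot produce), so an explicit size override reproduces that
split shape when wanted.

## Synthetic data

The toy-molecule panel (19 molecules: methane through sulfonyl-piperazine)
uses idealized geometry — regular polygons for rings, zig-zag chains,
tetrahedral methane — and assigned charges.  Hydrogens irrelevant to a
fixture carry +0.25 e (outside the non-polar window) so its
centre-of-mass count is zero by construction; fixtures probing that count
use symmetric geometries where the answer is unambiguous.  Every fixture
is annotated with hand-derived values for all six descriptors; the
annotations were worked out on the drawn structures (path counting, charge
sums, symmetry) and double as an oracle for the engine.

Feature matrices plant a sparse linear signal: Poisson count-like columns
(λ ∈ [1, 3]) plus one Gaussian charge-like column that always belongs to
the true subset (mirroring the published model's single charge descriptor;
its coefficient is scaled ×4 so the term carries signal comparable to the
count terms).  Decoys include two near-constant columns (Bernoulli 0.02)
and two collinear pairs, planted among decoys only — pruning is exercised
without making recovery ill-posed.  Coefficients are drawn from
±U(0.3, 0.8), and the response is affinely mapped onto pKi 4.5–9.3, the
activity span of the modelled dataset; the truth record stores the
post-map effective coefficients, intercept and noise.  Default study
conditions: n = 300, p = 40, k = 6, σ = 0.3 pKi units — large enough to
make the criteria battery meaningful, small enough to run in seconds.

What passing on synthetic data does **not** show: the generator has no
chemistry — no descriptor intercorrelation structure from shared molecular
features, no activity cliffs, no assay noise heteroscedasticity — so
recovery there demonstrates the correctness of the machinery, not the
real-data performance of the modelling recipe.

## Known limitations

* Descriptor values depend on the charge scheme and conformer; without the
  original semi-empirical inputs, per-molecule literature values (and the
  printed validation table) cannot be reproduced bit-for-bit, only the
  machinery can be verified.
* The lipophilic-atom rule is an informed reconstruction (see above).
* Molecular docking, homology modelling, quantum-chemical charge
  computation and the many-thousand-descriptor universes of general
  descriptor packages are out of scope; only the six model descriptors and
  their generic counting kernels are provided.
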