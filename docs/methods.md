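# Methods

## The problem

Most QSPR models predict properties of single compounds. Binary liquid
mixtures add two complications. First, a mixture must be represented by one
feature vector built from two component structures and a composition. Second,
naive cross-validation leaks information: the same mixture measured at a
slightly different mole ratio, or a mixture of compounds seen elsewhere in
training, makes random splits look far better than prospective use would be.
This package implements the mixture data model, the mixture descriptor
schemes, the leakage-safe validation protocols, and the evaluation metrics
needed to build and honestly assess such models, together with a synthetic
data generator that makes every claim testable without proprietary data.

## Canonical storage of mixture records

A data point is `(component1, component2, x1, property, value, unit, source)`
with `x1` the molar fraction of `component1`. Canonical form requires
`x1 ∈ [0.5, 1]`: a row uploaded with fraction `f < 0.5` is stored as the
swapped pair with fraction `1 − f`. Since `x1 + x2 = 1`, the minority
fraction is derived, never stored. This collapses the two orientations of one
measurement onto a single key, which is what makes duplicate detection a
grouping problem rather than a matching problem. Equimolar rows (`f = 0.5`)
are ordered by lexicographic canonical structure — an arbitrary but
deterministic tie-break independent of the chemistry toolkit.

Pure compounds are stored as degenerate mixtures (`x1 = 1`, no second
component) rather than as self-pairs; self-pairing would create artificial
zero difference-blocks in the 2m-feature schemes and ambiguous duplicate
keys. Structure canonicalization is an injected contract
(`str -> str`, deterministic and idempotent); the default is RDKit canonical
SMILES, and synthetic studies use an identity canonicalizer over opaque
tokens.

Duplicate detection clusters records with the same unordered pair and
property whose fractions agree within 1e-6 (experimental fractions are
reported to at most 4 decimals) and values within a caller-chosen tolerance,
under transitive closure. Record-level clusters are additionally merged per
unordered pair into mixture-level groups, the unit in which duplicate audits
of composition series are usually counted (a duplicated 18-point series is
one duplicated mixture, not 18 findings). At value tolerance 0 the
record-level clusters coincide with exact grouping by
`(pair, x1, property, value)`, which the tests verify by brute force.

Pure-compound augmentation adds an `x1 = 1` record for every compound
appearing in any mixture. For classification with the `zeotrope` policy the
added records carry the zeotrope label — a pure compound cannot form an
azeotrope with itself. For regression, pure values must be supplied; missing
compounds are reported by name, never silently invented. The operation is
idempotent.

## Component descriptors

Descriptor backends map a canonical structure to a named float vector,
deterministically. The shipped default is a fixed 30-column RDKit 2D set
(size, lipophilicity, polarity, connectivity, kappa shape, VSA and charge
terms); it is 2D-only so results are bit-for-bit reproducible — conformer
generation would introduce a hidden degree of freedom. Any external engine's
output can be injected through a descriptor-cache CSV (first column =
canonical structure).

Matrix assembly drops constant columns (no information) and columns with any
non-finite value. Column-drop rather than imputation keeps the feature space
identical across cross-validation folds and is the common QSPR convention.
Scaling (`none`, `zscore`, `minmax`) is a separate fitted object whose
statistics come only from a caller-specified fit subset; during
cross-validation that subset is the training records' compounds, so no
test-fold information reaches the scaler. Degenerate (zero-spread) columns
scale to 0.

## Mixture descriptor schemes

With `D1`, `D2` the component vectors and `x2 = 1 − x1`:

* `AVERAGE` = (D1 + D2)/2 and `SUM_ABSDIFF` = [D1 + D2, |D1 − D2|] ignore
  composition and suit endpoints with one value per mixture;
* `WEIGHTED_SUM` = x1·D1 + x2·D2 and
  `WEIGHTED_SUM_ABSDIFF` = [x1·D1 + x2·D2, |x1·D1 − x2·D2|] encode
  composition and suit endpoints measured across compositions.

The weighted difference block is weight-then-difference, |x1·D1 − x2·D2|,
the direct generalization of mole-weighted fragment counting from which this
descriptor family descends; the alternative reading |x1 − x2|·|D1 − D2| is
rejected as a design choice. All four forms are symmetric under component
relabeling `(A, x1, B) → (B, x2, A)`, so canonicalization plus the functional
form guarantees one feature row per mixture; the tests check this by brute
force over random vectors and fractions.

Pure records: weighted schemes use `D2 = 0, x1 = 1`, which reduces exactly to
the compound's own vector; unweighted schemes use `D1 = D2`, reading a pure
compound as a degenerate mixture of itself (sum block doubles, difference
block vanishes). Scheme/endpoint pairing is advisory — a mismatch warns but
does not fail, since exploring a composition-blind model on composition data
is a legitimate ablation.

## Validation protocols

* **Points out** — records are dealt into k balanced folds at random. The
  same mixture typically spans folds, so this estimates interpolation to new
  compositions only; constructing such a plan emits a warning.
* **Mixtures out** — records are grouped by unordered component pair and
  groups are packed greedily (largest first into the lightest fold) to
  balance record counts. No pair straddles folds.
* **Compounds out** — compounds are randomly partitioned into k groups. Each
  mixture is *anchored* to one of its two compounds (chosen greedily for
  record-count balance) and all its records follow the anchor's group; pure
  records follow their compound. Each fold then receives a *training
  exclusion list*: records outside the fold that contain any of the fold's
  anchor compounds. Training for fold f uses the complement minus these
  exclusions.

The compounds-out guarantee — every external mixture contains at least one
compound absent from the training set used against it — cannot be satisfied
by a plain partition on a connected dataset: a pure record of compound c is
valid only if *every* record touching c shares its fold, and with pure
records for all compounds that forces folds to be unions of connected
components of the pair graph. Purging resolves this: the guarantee is
enforced against the effective training set, at the cost of a small amount of
discarded training data per fold (reported in the audit). Assigning whole
pairs rather than individual records keeps every compounds-out plan a valid
mixtures-out plan, preserving the strength ordering of the protocols.

`audit_plan` verifies each guarantee by brute force — pair/fold cross-tables
for mixtures out, per-record novel-compound checks against the effective
training set for compounds out — and `crossvalidate` re-audits the plan and
refuses to run on a failing one. Plans are fully determined by
`(dataset, k, seed)` via `numpy.random.default_rng`.

## Models and metrics

Estimators are pluggable `fit/predict` objects; the registry ships
regularized linear regression (`ridge`, `linear`), RBF support vectors
(`svr`/`svc`), random forests (`rf`/`rfc`) and k-nearest neighbours
(`knn`/`knnc`) as open stand-ins for the neural-network and LibSVM engines of
the original mixture-QSPR studies. Classification uses the estimator's native
decision rule; no threshold tuning.

Metrics: R² is the squared Pearson correlation (affine-invariant; undefined
and reported missing — never coerced to 0 — on constant input or n < 3);
RMSE; Q² = 1 − PRESS/TSS over pooled out-of-fold predictions with the pooled
truth mean; balanced accuracy = mean of the two per-class recalls. Per-fold
metrics are aggregated as mean ± standard deviation across folds. Because the
fold-averaged and pooled conventions for cross-validated R² genuinely differ,
reports carry both (`aggregate` vs `pooled`). The ± spread is the plain
across-fold standard deviation, documented here because published tables
often leave the definition implicit.

Held-out evaluation prints an overlap report (shared pairs, shared
compounds) and classifies the holdout as points-, mixtures-, or
compounds-out-like, so a test-set number is never quoted without its
difficulty class.

## Synthetic data generator

The generator emulates the shapes of three study types: a
deviation-from-ideal-density regression (many compositions per mixture,
deviation endpoint), a bubble-temperature-like regression (absolute values),
and a balanced azeotrope/zeotrope classification (one label per mixture).

Per compound: descriptors `d_i ~ N(0, I_m)` and latent pure value
`p_i = w·d_i + c_i`, `c_i ~ N(0, σ_c²)`. The compound effect `c_i` is
deliberately invisible to the descriptors — it is what separates the
protocols, since points-out and mixtures-out folds can absorb it through
shared compounds while compounds-out folds cannot.

Per realized pair (sampled without replacement; a repair step guarantees
every compound appears in at least one pair whenever the pair budget allows,
so augmentation counts are seed-independent) and composition `x1` on an even
grid strictly inside (0.5, 1):

```
observed = x1·p_i + x2·p_j + γ·x1·x2·g_ij + ε,   ε ~ N(0, σ_ε²)
g_ij = u·(d_i ⊙ d_j) + b·(v·|d_i − d_j|)
```

with `u`, `v`, `b` drawn once per seed. The `x1·x2` envelope makes the
non-additive term vanish at the pure limits, as excess properties do. The
deviation endpoint stores `observed − ideal`; the ideal part is the
mole-fraction-linear combination of the pure values (the literal
"combine pure values by their ratio" baseline — physically, ideal densities
mix via molar volumes, and a hook is left for a volume-based variant). The
azeotrope label is positive when `γ·g_ij` exceeds the empirical median of the
realized pairs' scores, giving exactly balanced classes per dataset; the
median is the fixed point a bisection to 50/50 balance would reach. The grid
excludes 0.5 and 1 so mixture records never collide with pure records or the
equimolar tie-break.

What the generator does **not** emulate: real descriptor correlation
structure (columns are independent Gaussians), irregular experimental
composition grids, heteroscedastic measurement error, unit heterogeneity, and
any actual thermodynamics (no activity coefficients, no Antoine equations).
Passing tests therefore demonstrate the correctness of the *methodology* —
featurization arithmetic, leakage-free splitting, metric definitions, and the
qualitative protocol-difficulty ordering — not predictive accuracy on real
chemistry.

## Problem sizes and numerical choices

The standing experiments use 60 compounds × 150 pairs × 9 compositions
(1,410 records with pures), k = 5 folds and 10 independent studies for the
protocol-ordering comparison; 10-fold compounds-out for parameter recovery;
and 65 compounds × 400 pairs for the azeotrope construction — sizes chosen to
match the regimes the methodology targets while keeping a full verification
run around a minute on one CPU. Scheme arithmetic is checked to 1e-12,
metric cross-checks to 1e-10, scaler round-trips to 1e-9; greedy packing ties
are broken by a seeded permutation so plans are reproducible across platforms.
Fractions of exactly 0, negatives, or > 1 are hard errors, never clipped.

## Known limitations

* Only binary mixtures; the descriptor schemes extend naturally to more
  components but the data model does not yet.
* No unit conversion: records in one dataset must share a unit, and
  mismatches during duplicate detection raise immediately.
* The compounds-out purge discards some training records per fold (typically
  a few percent; the audit reports the counts); fold training sets are
  therefore slightly smaller than (k−1)/k of the data.
* The RDKit backend is a pragmatic 2D set, not a reproduction of any
  commercial descriptor engine; models built on it are not comparable
  column-for-column with Dragon/Adriana-based ones.
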