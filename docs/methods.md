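# Methods

`spectraqsar` studies one question: how much chemical-structure information
does a unit-mass GC-EI-MS measurement — the binned full-scan spectrum plus
the Kovats retention index (RI) — carry, compared with structure-derived
molecular descriptors, when both are used as QSAR/QSPR inputs?  The package
implements the complete workflow on a synthetic corpus with known ground
truth, so every claim a test makes is checkable against the generating
model.

## The analytical descriptor

A spectrum is consolidated to nominal (integer) mass by round-half-up
binning over a global frame (default 35–600 u; the frame grows to the union
of all peaks when a library exceeds it).  Colliding peaks are summed.  With
base-peak normalization (the library convention) the vector is rescaled so
its maximum is 999; without it, total intensity is conserved.  The
*analytical descriptor* is this bin vector with the RI appended as the last
feature; a *without-RI* variant omits it.

Standardization is consumer-specific, and deliberately so:

* **Embedding input** — every column (bins and RI) is z-scored with the
  sample mean and standard deviation (ddof=1). Constant columns become
  all-zero and are flagged rather than dropped, so feature indices stay
  stable. Standardization is idempotent to 1e-9.
* **Boosted-model input** — raw, unstandardized intensities. Tree splits
  are invariant to monotone per-feature rescaling, so standardizing would
  change nothing while complicating the schema.

Molecular descriptors are computed from SMILES with RDKit: `ecfp6` (Morgan
radius 3, hashed to 1024 bits by default), `maccs` (the 166-bit key; RDKit
emits 167 bits with bit 0 unused, which is dropped), `topological` (a fixed
list of 20 continuous 2D descriptors, including the mass-derived `MolWt` /
`ExactMolWt`), and `pubchem`. No installed toolkit computes the true
881-bit PubChem key, so `pubchem` is an 881-bit pattern-fingerprint
substructure key of the same length; the matrix carries the provenance tag
`pubchem_fallback(rdkit-pattern-881)` and results for this kind should be
read as "a dense structure key", not the literal PubChem definition.

## t-SNE

The embedding is written from first principles (dense, no Barnes–Hut),
because its internals are the object under test:

* Conditional affinities p(j|i) are Gaussian with per-point bandwidths
  found by binary search so each row's perplexity `2^H` matches the target
  within 1e-4 (H in bits). If a row's entropy floor sits above the target —
  duplicated or perfectly equidistant neighbors — the beta→∞ limit is used:
  equal mass on the nearest neighbor(s).
* The joint is the symmetrized average p_ij = (p(j|i)+p(i|j))/(2n); the map
  affinity is the Student-t kernel (1+||y_i−y_j||²)^(−1) normalized over
  all ordered pairs and floored at 1e-12 for loss stability. Both are unit-
  mass joint distributions at every iteration (tested).
* The loss is KL(P‖Q); the gradient is the standard closed form
  4 Σ_j (p_ij−q_ij)(y_i−y_j)(1+||y_i−y_j||²)^(−1), validated against
  central finite differences (max deviation < 1e-4 at n=10). The update is
  momentum gradient *descent* — the sign convention follows the loss-
  minimization semantics.
* Inputs wider than `initial_dims` (default 30) are PCA-reduced first.
  Initialization is a seeded small-variance Gaussian by default; a
  deterministic PCA initialization (`init_mode="pca"`, scaled to small
  variance with the PC1/PC2 aspect preserved) is available and is the right
  choice when global ordering matters, e.g. homolog ladders. Early
  exaggeration (factor > 1 for a fixed number of iterations) is off by
  default so loss traces are monotone-comparable, and enabled for
  ladder-style analyses where cluster cohesion helps.
* Defaults where a canonical value exists: perplexity 30, out_dims 2,
  n_iter 1000, η=200, momentum 0.5 before iteration 250 and 0.8 after.

One notational point: the textbook map-affinity denominator is a sum over
all pairs k≠l; writing it as a sum over k≠i of the (i,j) term does not
yield a joint distribution and is treated here as a typesetting slip — the
loss requires Q to be a single distribution, and the package normalizes
accordingly.

## Cluster similarity and composition

Clusters come from a label file (hand-circled regions) or seeded k-means
(10 restarts, lowest inertia) on the 2D map. Similarity summaries use
cosine similarity of the *standardized spectrum columns only* — the RI
column is excluded — because the question is whether spectra inside a map
cluster resemble each other. Cosine of standardized vectors is naturally
negative for anti-correlated spectra, which is why between-cluster values
below zero are meaningful. Within-cluster similarity is the mean over
unordered member pairs (singletons are reported as missing, not 0);
between-cluster entries are means over cross pairs; per-class summaries are
computed identically over taxonomy labels. Everything is checked against a
brute-force double loop to 1e-12.

## QSAR benchmarking

Per property, one seeded uniform-random 70/15/15 split (largest-remainder
rounding) is shared across every descriptor kind, and performance is
reported on the pooled validation+test rows by default. Models are XGBoost
regressors (300 trees, depth 6, learning rate 0.1, subsample 0.8, `hist`,
single-thread, fixed seed). RMSE and MAE are reported with per-compound
absolute errors retained for map overlays. Split membership, determinism,
and report/per-compound consistency are tested; RMSE ≥ MAE is *not*
asserted (it is not an identity).

## Spectral indicators and OLS baselines

Six scalars summarize a binned spectrum: intensity-weighted center of m/z
and its weighted standard deviation (`center_mz`, `sd_mz`; unweighted
variants behind a flag), the m/z of the most intense bin (`maxint_mz`, ties
to the lowest m/z), the highest occupied bin (`max_mz`), the count of
nonzero bins (`bin_num`, no intensity threshold), and the RI. All six are
invariant to uniform intensity rescaling. OLS models (single-variable and
all-six) are fit by QR least squares on the same splits as the boosted
models; coefficients are verified against the normal equations to 1e-8,
and a rank-deficient design raises an error naming the collinear columns.

## The synthetic corpus

The generator emulates the statistical structure the analysis depends on,
with four scaffold families:

| scaffold | base (u) | step (u) | substituents | superclass |
|---|---|---|---|---|
| `pcb_like` | 154 (biphenyl) | +34 per Cl | 0–10 | Benzenoids |
| `alkane_like` | 72 (C5) | +14 per CH2 | 0–20 | Lipids and lipid-like molecules |
| `alkylbenzene` | 92 (toluene) | +14 | 0–16 | Benzenoids |
| `methyl_ester` | 74 | +14 | 0–18 | Organic oxygen compounds |

A spectrum contains the molecular ion (largest deterministic weight, hence
base peak up to noise), one or more sequential neutral-loss ions,
scaffold-specific fixed fragments whose relative weights drift slowly with
substitution degree, a homolog-shared *core fragment series* on the common
mass grid (dechlorinated biphenylene ions at 152+34j for the PCB family;
C_nH_{2n+1}+, acylium, and methyltropylium series for the aliphatic
families), and a Poisson(6) number of weak incidental ions at random
masses. Intensities carry multiplicative log-normal noise (CV 0.10 by
default) and are rescaled to base peak 999.

Two intentional deviations from textbook EI behavior: the molecular ion is
always the strongest deterministic peak (for real long-chain alkanes a C3/C4
fragment usually wins), and the PCB family keeps a single distinct [M−Cl]+
ion while deeper dechlorination mass collapses onto the shared 152+34j
grid. Both choices serve the regimes under study — `maxint_mz` as a
mass-bearing indicator, and homolog similarity that decays gradually with
the substitution gap (real congener spectra share exactly such fragment
families at unit mass; without them, all homolog pairs would look equally
dissimilar after standardization and a map could not order the ladder).

RI follows a Kovats-like model: 7.0 per u (≈100 per CH2), +120 for
aromatic scaffolds on the semi-polar column, Gaussian noise (sd 10), plus a
per-compound latent "shape" factor (scale 15) that also enters the boiling
point (scale 8). The shared factor encodes a real phenomenon — isomers
that elute late for their mass also tend to boil high — and is what makes
the measured RI informative for BP *beyond* what the spectrum already
determines; without it, with-RI and without-RI models would differ only by
noise on this corpus.

Properties are linear in (nominal mass, substituent count, aromatic flag)
with Gaussian noise, except `log_mw = log10(nominal mass)` exactly.
Because each family has its own base mass and mass step, the property
surface is *piecewise*-linear in mass across families over a wide shared
mass range: a single linear model in any indicator set cannot fit all
families at once, while the full spectrum identifies the family and
resolves it. This is the synthetic analogue of the regime where the
full-spectrum boosted model overwhelms every indicator-based linear model.

What the corpus does **not** emulate: isotope clusters (so no ³⁷Cl
envelopes), rearrangement chemistry, condition-dependent fragmentation,
instrument-specific intensity response, retention-index calibration error
structure, or any property nonlinearity beyond the piecewise-family
structure. Passing tests therefore demonstrate that the pipeline's
machinery is correct and that it reproduces the expected qualitative
contrasts *under these assumptions*; they do not certify performance
numbers on real libraries.

## Problem sizes and numerical choices

Benchmark tests use n=1000 compounds (seeded); embedding and cluster
checks use n=60–300 with 100–1000 iterations; the homolog ladder is
k=1..10 with 5 replicates at CV 0.05. The ladder embedding uses perplexity
10, PCA initialization, and early exaggeration ×4 for 100 of 1000
iterations — with ten tight replicate blobs, random initialization can
leave a boundary blob on the wrong side of the 2-means cut, and "separates
low from high k" is scored as ≥90% agreement with the best threshold
partition on chlorine count. Binary searches run to 1e-4 on perplexity;
standardization tolerances are 1e-9; brute-force similarity oracles agree
to 1e-12. Degenerate inputs have defined behavior throughout: empty
datasets, all-zero spectra, zero-norm vectors, and rank-deficient designs
raise informative errors; singleton clusters yield missing values.

## Known limitations

* The PubChem descriptor is a stand-in key (see above).
* The `topological` set is an RDKit selection, not the CDK list; its
  dominance on molecular-weight prediction (it contains MolWt) is by
  construction and mirrors the expected mechanism, not a discovery.
* Applicability-domain estimation, hyperparameter search, isotope-resolved
  binning, and Silhouette/ARI cluster indices are out of scope.
* Dense t-SNE is O(n²) per iteration; it is intended for library subsets
  up to a few thousand spectra, not full-library embeddings.
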