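# Methods

## Shape, size and superimposition

A specimen is a configuration of p labelled 2D landmarks (the data model
allows d = 3, but all analyses here are 2D). Size is measured by centroid
size, CS = √Σᵢ‖xᵢ − x̄‖². Generalised Procrustes Analysis centres every
configuration, scales it to unit centroid size, and iteratively rotates
it onto the running consensus (the normalised mean), until the
root-mean-square change of the consensus falls below a tolerance
(default 1e-10 for plain GPA, 1e-12 inside the symmetry decomposition;
iteration cap 100/200, with a warning and `converged=False` on failure).

Two choices matter for symmetry analysis:

* **Rotations only.** The orthogonal alignment step is constrained to
  det +1. If the fit could absorb a reflection, the asymmetric component
  of variation — which is the object of study — would be silently
  destroyed. Reflections enter only as explicit data operations.
* **Tangent projection.** Aligned configurations are projected
  orthogonally to the consensus direction (the consensus has unit
  centroid size, so its flattened vector is the unit normal of the
  tangent hyperplane). At the variance levels used here the difference
  from other tangent conventions is far below every tolerance asserted.

Optimality of the per-configuration rotation makes four directions of the
flattened coordinate space exactly variance-free (two translations, the
scale direction, and the rotation generator at the consensus), so a
full-rank 2D sample has exactly 2p − 4 principal components with non-null
eigenvalue. The null cut-off is eigenvalue < 1e-10 × largest.

After convergence the consensus is rotated to its principal axes
(conventional display orientation); ties are broken by requiring the
first landmark's x coordinate to be non-negative.

## Object symmetry: expanded datasets

The symmetry group Cn or Cnv is represented by elements (reflect, k):
an optional reflection about the y axis followed by a rotation by
k·360°/n. A relabelling map gives, for the reflection and for each
successive rotation, the permutation of landmark labels that makes
corresponding landmarks match across copies; maps are plain-text files of
1-based integer columns (one column for C1v, n−1 for Cn, 1 + (n−1) for
Cnv) and are validated for bijectivity, the reflection involution, and
cyclic consistency (column k must be the k-th power of column 1).

Expansion produces |G| copies per specimen with the
`_ori_Cn00 / _ref_Cn00 / _ori_Cn01 …` id grammar. Reflection copies have
x negated and labels swapped; rotation copies are **relabelled only** —
the rotation that superimposes them is supplied by the GPA, so an exactly
symmetric configuration has Procrustes distance 0 to each of its copies.
Applying bilateral expansion twice with the two mirror maps of a
disymmetric flower is equivalent to one C2v expansion up to a rotation
absorbed by the fit (tested property).

### Exact symmetrisation of the consensus

GPA converges the consensus to within its tolerance of the symmetric
fixed point, which is not quite enough when downstream assertions sit at
1e-8. After convergence the consensus is therefore replaced by its group
average (each transformed relabelled image optimally rotated back and
averaged, iterated a few times — a contraction onto the invariant set),
and all copies are realigned once to this exactly symmetric consensus.
The group then acts on the aligned sample by fixed orthogonal operators
to machine precision, which is what pins within-pair eigenvalue equality
near 1e-15 rather than near the GPA tolerance.

## Symmetry PCA

The PCA is an eigendecomposition of the sample covariance (divisor
N − 1) of the tangent coordinates of **all** configurations, originals
and copies alike; scores are centred on the grand mean. Eigenvector signs
follow the largest-magnitude-loading-positive convention.

**Classification.** For an unpaired PC and each non-identity element g,
the scores of the g-copies are compared with the originals' scores
specimen by specimen: equal (within a relative tolerance of 1e-6, scaled
by the root-mean-square score) means symmetric under g, negated means
antisymmetric, anything else is recorded as neither. The per-element
signature determines the category: all-symmetric ("fully symmetric"),
symmetric under all rotations but antisymmetric under the reflections
("rotation-only symmetric"), symmetric under one reflection
("bilaterally symmetric", with the mirror element named), otherwise
"fully asymmetric". A signature that fits none of these is reported as
"unclassified" with a warning, never guessed. Categories are counted by
full signature, so e.g. the two single-mirror classes of a disymmetric
flower stay distinct.

**Equal-eigenvalue pairs.** Consecutive non-null eigenvalues agreeing to
a relative tolerance of 1e-6 form a pair (the default is generous:
thanks to the exact symmetrisation the structural equality holds to
~1e-15, while distinct eigenvalues of the sampled covariance differ at
the percent level). A near-coincidence of three eigenvalues raises an
error instead of guessing. Each pair is then rotated in its plane so that
the mean score of all **unrotated** copies (rotation index 0 — the
originals and, for groups with a reflection, their mirrored copies) lies
on the pair's first axis. Including the mirrored copies is what places
that axis on a reflection axis of the pair plane, so that for dihedral
groups the rotated pair splits into one bilaterally symmetric and one
fully asymmetric PC; for pure rotation groups the two readings of
"unrotated" coincide and both members remain fully asymmetric. A pair
whose mean unrotated score sits at the origin is left unrotated and
flagged. Pair members are labelled "paired/unresolved" until rotated.

**Components.** The symmetric component of a specimen is the average of
its aligned copies over the group orbit (exactly invariant by
construction); the asymmetry component for operator g is the aligned
original minus the aligned g-copy.

## Measurement-error ANOVA and allometry

The measurement-error design is balanced and nested: individuals, images
per individual, digitisings per image. Sums of squares come from nested
means; for shape they are summed over all p·d tangent variables and the
design degrees of freedom are multiplied by the shape dimensionality
s = p·d − 4 (so the 30 × 2 × 2, p = 21 design gives df 1102/1140/2280;
centroid size gives 29/30/60). F at a level is its MS over the MS of the
level nested within it, with parametric P from the F distribution at
those df; this is the conventional Goodall-style treatment, and the df
and MS-ratio surface is what the package asserts. The ANOVA runs on
original (non-expanded) configurations; dissecting error within an
expanded dataset's reduced subspaces is out of scope. Unbalanced designs
are rejected rather than approximated.

Allometry is an ordinary multivariate least-squares regression of the
tangent coordinates on log centroid size (log optional); the effect size
is predicted SS / total SS × 100 and the permutation test permutes sizes
with p = (b + 1)/(n_perm + 1). Seeds are mandatory wherever randomness
enters; there is no global random state.

## Synthetic data

Templates are assembled from group orbits — full orbits in general
position (size |G|), mirror-fixed orbits on a reflection axis (size n),
and the centre — so the matching relabelling map is known by
construction and the template is exactly invariant (< 1e-12). Built-in
layouts encode four floral case studies: bilateral p=21 (8 mirror pairs
+ 5 on-axis), disymmetric p=32 (8 orbits of 4), 5-fold p=11 (centre +
two 5-orbits) and C3v p=10 (6-orbit + mirror-fixed 3-orbit + centre).
Orbit radii and angles are generic values chosen to avoid accidental
extra symmetry or collinearity; their specific values are irrelevant to
every asserted property.

Samples add i.i.d. isotropic Gaussian noise per landmark coordinate in
template space, before any Procrustes treatment — the standard
digitising-noise model. The default noise sd is 2% of template centroid
size: small enough for tangent-space linearity, large enough for
full-rank covariances at the default sample sizes. Defaults are n = 30
specimens per layout, except n = 61 for the disymmetric layout so that
the original sample alone spans its 60-dimensional shape space (the
usual rule that landmark count should stay below half the specimen
count). Optional directional asymmetry (a fixed displacement field),
fluctuating asymmetry (per-specimen displacement, antisymmetrised when a
reflection map is supplied) and nested imaging/digitising replicates
(shared image-level displacement plus independent digitising
displacement, ids `Ind001a1b1…`) complete the generator.

What the generator does **not** emulate: real digitising error is not
isotropic or homoscedastic across landmarks, petals deform in correlated
ways, and real corollas have allometry and biological covariance
structure. Passing tests therefore demonstrate the machinery — counts,
subspace structure, invariances, error propagation — not biological
effect sizes; variance percentages printed by the examples are
realisation-dependent and are never asserted.

## Known limitations

* 2D acceptance surface; 3D configurations are stored but the symmetry
  operations assume planar groups.
* No semilandmark sliding, no partial (non-scaling) Procrustes, no
  resistant fit.
* The two-way mixed-model ANOVA separating directional from fluctuating
  asymmetry in complex-symmetry designs is not implemented.
* For non-prime rotation orders (e.g. 6) the classification reports
  per-element signatures but does not factor the symmetric subspace by
  prime factor; finer decomposition is left to the user.
* Infinite symmetry families (translational, helical) are out of scope.
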