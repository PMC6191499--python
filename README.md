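# symmorph

Landmark-based geometric morphometrics of symmetric biological structures
— flower corollas above all — decomposing 2D shape variation into its
symmetric and asymmetric components for any finite planar symmetry group:
bilateral symmetry (zygomorphy, C1v), two perpendicular mirror axes
(disymmetry, C2v), pure rotational symmetry (Cn) and combined reflection +
rotational symmetry (actinomorphy, Cnv).

It is written for evolutionary and developmental biologists quantifying
corolla shape, floral symmetry transitions, directional and fluctuating
asymmetry, and measurement error in landmark data.

## The method

For a structure with **object symmetry** (the symmetry axes pass through
the structure itself), each specimen's landmark configuration is augmented
with one transformed, relabelled copy per symmetry-group element: a
reflection copy negates one coordinate (x) and swaps the labels of
mirror-paired landmarks; a rotation copy permutes labels only, the
compensating rotation being supplied by the superimposition. A single
Generalised Procrustes Analysis (GPA) of this expanded dataset removes
location, scale (unit centroid size, CS = √Σᵢ‖xᵢ − x̄‖²) and orientation
(rotations only, never reflections), and yields an exactly symmetric
consensus. A PCA of the covariance matrix of the Procrustes tangent
coordinates then splits shape space into orthogonal, complementary
subspaces, one per symmetry category of the group; each PC is classified
by its **score signature** — for each group element, the scores of the
element's copies equal the originals' scores (symmetric under that
element), their negation (antisymmetric), or neither.

For rotation orders above 2 the group-invariant covariance forces **pairs
of PCs with equal eigenvalues**, whose eigenvector plane is rotationally
indeterminate. Each pair is fixed by rotating it so that the mean score of
all unrotated copies lies on its first axis, after which the two members
show definite symmetry types (e.g. one bilaterally symmetric, one fully
asymmetric for C3v).

The package also provides matching-symmetry utilities for repeated,
physically disconnected parts, a balanced one-way nested Procrustes ANOVA
for measurement error (individuals / imaging / digitising, with
Goodall-style shape degrees of freedom s = p·d − 4 and F as the MS ratio
of adjacent nested levels), and multivariate regression of shape on log
centroid size (allometry) with a permutation test.

## Worked example

```python
from symmorph import SymmetryPCA, layout_sample

# simulate 30 flowers with reflection + 3-fold rotational symmetry
# (10 landmarks: a full 6-orbit, a mirror-fixed 3-orbit and the centre)
spec, template, rmap, flowers = layout_sample("trillium", seed=42)
model = SymmetryPCA(spec.group, rmap).fit(flowers)

print("non-null PCs:", model.n_components_)
print("equal-eigenvalue pairs:", model.pairs_)
for cat, pct in sorted(model.category_variance_.items()):
    print(f"  {cat}: {model.categories_.count(cat)} PCs, {pct:.1f}% of variance")
```

prints

```
non-null PCs: 16
equal-eigenvalue pairs: [(0, 1), (2, 3), (7, 8), (9, 10), (11, 12), (14, 15)]
  bilaterally symmetric (ref_Cn00): 6 PCs, 37.8% of variance
  fully asymmetric: 6 PCs, 37.8% of variance
  fully symmetric: 2 PCs, 10.9% of variance
  rotation-only symmetric: 2 PCs, 13.6% of variance
```

16 = 2p − 4 non-null PCs survive the Procrustes fit; six equal-eigenvalue
pairs carry 12 of them, and after the pair rotation each pair splits into
one bilaterally symmetric and one fully asymmetric direction; the
singletons are the two fully symmetric and two rotation-only-symmetric
PCs. The variance shares depend on the noise realisation; the counts do
not.

The same pipeline is scriptable from the shell:

```
symmorph simulate vinca --seed 1 --out sim/
symmorph analyze sim/vinca.tps --map sim/co_vinca.txt --group C5 --out results/
symmorph simulate fedia --seed 2 --replicates 2 2 --out err/
symmorph error-anova err/fedia.tps --individual 1 6 --imaging 7 8 \
    --digitising 9 10 --out err/anova/
```

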