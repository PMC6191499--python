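"""PCA of tangent coordinates and symmetry decomposition of shape variation.

A PCA of an expanded dataset (originals plus all transformed relabelled
copies) separates shape variation into orthogonal subspaces, one per
symmetry category of the group.  Each principal component is classified
by its score signature: for every group element, the scores of the
element's copies either equal the scores of the originals (the PC is
symmetric under that element), equal their negation (antisymmetric), or
neither.

For rotation orders above 2 the group-invariant covariance forces pairs
of PCs with exactly equal eigenvalues; the eigenvector plane of such a
pair is rotationally indeterminate.  The pair is fixed by rotating it so
that the mean score of all unrotated copies (identity and, when present,
the reflected-unrotated copies) lies on the first axis of the pair, after
which each member exhibits a definite symmetry type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .groups import (
    ExpandedDataset,
    RelabellingMap,
    SymmetryGroup,
    apply_element,
    expand_dataset,
)
from .io import Dataset, LandmarkConfiguration
from .procrustes import (
    _principal_axes_align,
    centroid_size,
    gpa,
    optimal_rotation,
    tangent_project,
)

__all__ = [
    "PCADecomposition",
    "pca",
    "detect_pairs",
    "classify_pcs",
    "rotate_pc_pair",
    "category_variance",
    "symmetric_component",
    "asymmetry_component",
    "SymmetryPCA",
]

PAIRED_UNRESOLVED = "paired/unresolved"


@dataclass
class PCADecomposition:
    """Eigenstructure of the tangent-space covariance with symmetry metadata.

    ``eigenvectors`` holds one unit eigenvector per column, eigenvalues in
    descending order; ``scores`` are mean-centred projections of every
    configuration (originals and copies alike).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    scores: np.ndarray
    mean: np.ndarray
    null_tol: float
    n_nonnull: int
    pairs: list[tuple[int, int]] = field(default_factory=list)
    rotated_pairs: list[tuple[int, int]] = field(default_factory=list)
    unrotatable_pairs: list[tuple[int, int]] = field(default_factory=list)
    signatures: list[tuple[str, ...] | None] = field(default_factory=list)
    categories: list[str | None] = field(default_factory=list)
    category_variance: dict[str, float] = field(default_factory=dict)

    def pair_of(self, j: int) -> tuple[int, int] | None:
        for pair in self.pairs:
            if j in pair:
                return pair
        return None


def _sign_fix(vectors: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude loading positive."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def pca(tangent: np.ndarray, null_tol: float = 1e-10) -> PCADecomposition:
    """Eigendecomposition of the sample covariance (divisor N-1) of tangent
    coordinates; every configuration of the expanded dataset counts once."""
    tangent = np.asarray(tangent, dtype=float)
    if tangent.ndim != 2 or tangent.shape[0] < 2:
        raise ValueError("PCA needs at least two configurations of tangent coordinates")
    mean = tangent.mean(axis=0)
    centred = tangent - mean
    cov = centred.T @ centred / (tangent.shape[0] - 1)
    values, vectors = np.linalg.eigh(cov)
    order = np.argsort(values)[::-1]
    values = np.clip(values[order], 0.0, None)
    vectors = _sign_fix(vectors[:, order])
    scores = centred @ vectors
    n_nonnull = int(np.sum(values > null_tol * values[0])) if values[0] > 0 else 0
    m = tangent.shape[1]
    return PCADecomposition(
        eigenvalues=values,
        eigenvectors=vectors,
        scores=scores,
        mean=mean,
        null_tol=null_tol,
        n_nonnull=n_nonnull,
        signatures=[None] * m,
        categories=[None] * m,
    )


def detect_pairs(decomp: PCADecomposition, rel_tol: float = 1e-6) -> PCADecomposition:
    """Group consecutive non-null eigenvalues that agree to ``rel_tol``
    (relative) into equal-eigenvalue pairs."""
    values = decomp.eigenvalues
    pairs: list[tuple[int, int]] = []
    i = 0
    while i < decomp.n_nonnull - 1:
        rel = (values[i] - values[i + 1]) / values[i]
        if rel < rel_tol:
            if i + 2 < decomp.n_nonnull:
                nxt = (values[i + 1] - values[i + 2]) / values[i + 1]
                if nxt < rel_tol:
                    raise ValueError(
                        f"eigenvalues {i + 1}..{i + 3} coincide to rel_tol={rel_tol};"
                        " reduce rel_tol or inspect the fixture for degeneracy"
                    )
            pairs.append((i, i + 1))
            i += 2
        else:
            i += 1
    decomp.pairs = pairs
    return decomp


def _element_signature(
    decomp: PCADecomposition,
    expanded: ExpandedDataset,
    group: SymmetryGroup,
    j: int,
    tol: float,
) -> tuple[str, ...]:
    rows_id = expanded.rows_for(False, 0)
    s_id = decomp.scores[rows_id, j]
    scale = np.sqrt(np.mean(s_id**2))
    statuses = []
    for reflect, k in group.elements[1:]:
        s_g = decomp.scores[expanded.rows_for(reflect, k), j]
        if scale == 0:
            statuses.append("n")
            continue
        d_sym = np.sqrt(np.mean((s_g - s_id) ** 2))
        d_anti = np.sqrt(np.mean((s_g + s_id) ** 2))
        if d_sym < tol * scale:
            statuses.append("s")
        elif d_anti < tol * scale:
            statuses.append("a")
        else:
            statuses.append("n")
    return tuple(statuses)


def _label(signature: tuple[str, ...], group: SymmetryGroup, paired: bool) -> str:
    elements = group.elements[1:]
    rot = [s for s, (r, _) in zip(signature, elements) if not r]
    refl = [(s, k) for s, (r, k) in zip(signature, elements) if r]
    if all(s == "s" for s in signature):
        return "fully symmetric"
    sym_refl = [k for s, k in refl if s == "s"]
    if sym_refl:
        return f"bilaterally symmetric (ref_Cn{sym_refl[0]:02d})"
    if rot and all(s == "s" for s in rot):
        return "rotation-only symmetric"
    if not paired and "n" in signature:
        return "unclassified"
    return "fully asymmetric"


def classify_pcs(
    decomp: PCADecomposition,
    expanded: ExpandedDataset,
    group: SymmetryGroup,
    rmap: RelabellingMap | None = None,
    tol: float = 1e-6,
) -> PCADecomposition:
    """Assign a symmetry category to every non-null PC via its score signature.

    Members of unrotated equal-eigenvalue pairs are labelled
    ``paired/unresolved``; rotated pair members get a definite category
    (score patterns of pair members mix under rotations, so a blank entry
    in their signature is expected, not an error).
    """
    for j in range(decomp.n_nonnull):
        pair = decomp.pair_of(j)
        if pair is not None and pair not in decomp.rotated_pairs:
            decomp.signatures[j] = None
            decomp.categories[j] = PAIRED_UNRESOLVED
            continue
        sig = _element_signature(decomp, expanded, group, j, tol)
        decomp.signatures[j] = sig
        label = _label(sig, group, paired=pair is not None)
        if label == "unclassified":
            warnings.warn(
                f"PC{j + 1} has score signature {sig} matching no symmetry"
                " category; reported as unclassified",
                RuntimeWarning,
            )
        decomp.categories[j] = label
    return decomp


def rotate_pc_pair(
    decomp: PCADecomposition,
    pair: tuple[int, int],
    expanded: ExpandedDataset,
    min_norm: float = 1e-12,
) -> PCADecomposition:
    """Fix the orientation of an equal-eigenvalue pair.

    The two eigenvectors are rotated in their plane so that the mean score
    of all unrotated copies (rotation index 0: originals and, for groups
    with reflection, their reflected-unrotated copies) lies on the first
    axis of the pair.  Eigenvalues and orthonormality are unchanged.
    """
    if pair not in decomp.pairs:
        raise ValueError(f"{pair} is not a detected equal-eigenvalue pair")
    i, j = pair
    rows = np.nonzero(expanded.copy_index[:, 2] == 0)[0]
    m = decomp.scores[rows][:, [i, j]].mean(axis=0)
    norm = np.linalg.norm(m)
    if norm < min_norm * np.sqrt(decomp.eigenvalues[i]):
        warnings.warn(
            f"mean unrotated-copy score of pair {pair} is at the origin;"
            " pair left unrotated",
            RuntimeWarning,
        )
        decomp.unrotatable_pairs.append(pair)
        return decomp
    c, s = m / norm
    rot = np.array([[c, -s], [s, c]])
    decomp.eigenvectors[:, [i, j]] = decomp.eigenvectors[:, [i, j]] @ rot
    decomp.scores[:, [i, j]] = decomp.scores[:, [i, j]] @ rot
    decomp.rotated_pairs.append(pair)
    return decomp


def category_variance(decomp: PCADecomposition) -> PCADecomposition:
    """Percentage of total (non-null) variance captured by each category."""
    total = decomp.eigenvalues[: decomp.n_nonnull].sum()
    shares: dict[str, float] = {}
    for j in range(decomp.n_nonnull):
        cat = decomp.categories[j] or "unclassified"
        shares[cat] = shares.get(cat, 0.0) + decomp.eigenvalues[j]
    decomp.category_variance = {k: 100.0 * v / total for k, v in shares.items()}
    return decomp


def symmetric_component(expanded: ExpandedDataset, aligned: np.ndarray) -> Dataset:
    """Per-specimen average of all aligned copies over the group orbit;
    the result is an exactly group-symmetric shape for every specimen."""
    n_src = expanded.source_count()
    order = expanded.group.order if expanded.group else len(expanded) // n_src
    out = []
    for i in range(n_src):
        rows = np.nonzero(expanded.copy_index[:, 0] == i)[0]
        if len(rows) != order:
            raise ValueError(f"specimen {i} has {len(rows)} copies, expected {order}")
        mean = aligned[rows].mean(axis=0)
        base = expanded.configurations[rows[0]].specimen_id.rsplit("_ori_", 1)[0]
        out.append(LandmarkConfiguration(base + "_sym", mean))
    return Dataset(out)


def asymmetry_component(
    expanded: ExpandedDataset, aligned: np.ndarray, element: tuple[bool, int]
) -> Dataset:
    """Aligned original minus the aligned copy for one symmetry operator,
    per specimen (e.g. the left-right asymmetry for a reflection)."""
    reflect, k = element
    rows_id = expanded.rows_for(False, 0)
    rows_g = expanded.rows_for(reflect, k)
    if len(rows_id) != len(rows_g):
        raise ValueError(f"element {element} is missing copies for some specimens")
    out = []
    for ri, rg in zip(rows_id, rows_g):
        diff = aligned[ri] - aligned[rg]
        base = expanded.configurations[ri].specimen_id.rsplit("_ori_", 1)[0]
        out.append(LandmarkConfiguration(base + f"_asym_Cn{k:02d}", diff))
    return Dataset(out)


def _symmetrize_consensus(
    consensus: np.ndarray,
    group: SymmetryGroup,
    rmap: RelabellingMap,
    iters: int = 4,
) -> np.ndarray:
    """Average the consensus over its group orbit (with optimal re-alignment)
    until it is exactly group-invariant to machine precision."""
    c = consensus
    for _ in range(iters):
        acc = np.zeros_like(c)
        for element in group.elements:
            y = apply_element(LandmarkConfiguration("c", c), element, rmap).coords
            y = y - y.mean(axis=0)
            y = y / centroid_size(y)
            acc += y @ optimal_rotation(y, c)
        c = acc / group.order
        c = c - c.mean(axis=0)
        c = c / centroid_size(c)
    return c


class SymmetryPCA:
    """Symmetry decomposition of landmark shape variation, scikit-learn style.

    ``fit`` takes raw 2D configurations of one structure with object
    symmetry, generates the transformed relabelled copy for every group
    element, superimposes the expanded sample with a single GPA, and runs a
    PCA of the tangent coordinates.  Principal components are classified
    into the group's symmetry categories; equal-eigenvalue pairs (rotation
    order > 2) are detected and rotationally fixed.

    Parameters
    ----------
    group : SymmetryGroup or str
        The structure's symmetry group (e.g. ``"C1v"``, ``"C5"``, ``"C3v"``).
    relabelling : RelabellingMap
        Landmark permutations for the reflection and/or successive rotations.
    align_principal_axes : bool, default True
        Orient the consensus along its principal axes.
    gpa_tol, gpa_max_iter : GPA convergence controls.
    null_tol : float, default 1e-10
        Eigenvalues below ``null_tol * largest`` count as null; GPA removes
        exactly 4 degrees of freedom in 2D, so a full-rank sample has
        2p - 4 non-null PCs.
    pair_rel_tol : float, default 1e-6
        Relative tolerance for equal-eigenvalue pair detection.
    classify_tol : float, default 1e-6
        Relative tolerance for score-signature classification.
    rotate_pairs : bool, default True
        Fix the orientation of every detected pair after classification.

    Attributes
    ----------
    expanded_ : ExpandedDataset
    consensus_ : (p, d) ndarray, exactly group-symmetric mean shape
    aligned_ : (N, p, d) ndarray of superimposed copies
    tangent_ : (N, p*d) ndarray
    centroid_sizes_ : (N,) ndarray
    decomposition_ : PCADecomposition
    eigenvalues_, components_, scores_ : non-null part of the decomposition
        (``components_`` has one PC per row, sklearn convention)
    n_components_ : int, number of non-null PCs
    categories_ : list of per-PC category labels
    pairs_ : list of equal-eigenvalue index pairs
    category_variance_ : dict mapping category label to percent of variance
    """

    def __init__(
        self,
        group,
        relabelling: RelabellingMap,
        *,
        align_principal_axes: bool = True,
        gpa_tol: float = 1e-12,
        gpa_max_iter: int = 200,
        null_tol: float = 1e-10,
        pair_rel_tol: float = 1e-6,
        classify_tol: float = 1e-6,
        rotate_pairs: bool = True,
    ):
        self.group = group
        self.relabelling = relabelling
        self.align_principal_axes = align_principal_axes
        self.gpa_tol = gpa_tol
        self.gpa_max_iter = gpa_max_iter
        self.null_tol = null_tol
        self.pair_rel_tol = pair_rel_tol
        self.classify_tol = classify_tol
        self.rotate_pairs = rotate_pairs

    def get_params(self, deep: bool = True) -> dict:
        return {
            "group": self.group,
            "relabelling": self.relabelling,
            "align_principal_axes": self.align_principal_axes,
            "gpa_tol": self.gpa_tol,
            "gpa_max_iter": self.gpa_max_iter,
            "null_tol": self.null_tol,
            "pair_rel_tol": self.pair_rel_tol,
            "classify_tol": self.classify_tol,
            "rotate_pairs": self.rotate_pairs,
        }

    def set_params(self, **params) -> "SymmetryPCA":
        valid = self.get_params()
        for key, value in params.items():
            if key not in valid:
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def _group(self) -> SymmetryGroup:
        if isinstance(self.group, SymmetryGroup):
            return self.group
        return SymmetryGroup.from_schoenflies(self.group)

    def fit(self, X, y=None) -> "SymmetryPCA":
        group = self._group()
        if isinstance(X, ExpandedDataset):
            expanded = X
        else:
            if isinstance(X, Dataset):
                dataset = X
            else:
                arr = np.asarray(X, dtype=float)
                if arr.ndim == 2:  # (n, p*d) flat rows, x1 y1 x2 y2 ...
                    arr = arr.reshape(arr.shape[0], -1, 2)
                dataset = Dataset(
                    [LandmarkConfiguration(str(i + 1), c) for i, c in enumerate(arr)]
                )
            expanded = expand_dataset(dataset, group, self.relabelling)

        result = gpa(
            expanded,
            align_principal_axes=False,
            tol=self.gpa_tol,
            max_iter=self.gpa_max_iter,
        )
        # make the consensus exactly group-invariant, then realign once, so
        # that the group action on the aligned sample is exact to machine
        # precision (this is what pins within-pair eigenvalue equality)
        consensus = _symmetrize_consensus(result.consensus, group, self.relabelling)
        aligned = result.aligned
        for i in range(aligned.shape[0]):
            aligned[i] = aligned[i] @ optimal_rotation(aligned[i], consensus)
        if self.align_principal_axes:
            consensus, aligned, _ = _principal_axes_align(consensus, aligned)
        result.consensus = consensus
        result.aligned = aligned
        tangent_project(result)

        decomp = pca(result.tangent, null_tol=self.null_tol)
        detect_pairs(decomp, rel_tol=self.pair_rel_tol)
        if self.rotate_pairs:
            for pair in list(decomp.pairs):
                rotate_pc_pair(decomp, pair, expanded)
        classify_pcs(decomp, expanded, group, self.relabelling, tol=self.classify_tol)
        category_variance(decomp)

        self.expanded_ = expanded
        self.procrustes_ = result
        self.consensus_ = consensus
        self.aligned_ = aligned
        self.tangent_ = result.tangent
        self.centroid_sizes_ = result.centroid_sizes
        self.decomposition_ = decomp
        k = decomp.n_nonnull
        self.n_components_ = k
        self.eigenvalues_ = decomp.eigenvalues[:k]
        self.components_ = decomp.eigenvectors[:, :k].T
        self.scores_ = decomp.scores[:, :k]
        self.categories_ = list(decomp.categories[:k])
        self.pairs_ = list(decomp.pairs)
        self.category_variance_ = dict(decomp.category_variance)
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).scores_

    def symmetric_component(self) -> Dataset:
        return symmetric_component(self.expanded_, self.aligned_)

    def asymmetry_component(self, element: tuple[bool, int]) -> Dataset:
        return asymmetry_component(self.expanded_, self.aligned_, element)
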