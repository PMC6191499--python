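"""Symmetry PCA: subspace counts, classification, pairs, components."""

import numpy as np
import pytest

from symmorph import (
    SymmetryPCA,
    asymmetry_component,
    centroid_size,
    detect_pairs,
    pca,
    procrustes_distance,
    rotate_pc_pair,
    symmetric_component,
)
from symmorph.pca import PAIRED_UNRESOLVED
from symmorph.simulate import layout_spec, make_template, simulate_sample

STRUCTURE = {
    # layout -> (non-null PCs, number of PC pairs)
    "fedia": (38, 0),
    "erysimum": (60, 0),
    "vinca": (18, 8),
    "trillium": (16, 6),
}


@pytest.mark.parametrize("layout", list(STRUCTURE))
def test_nonnull_pc_counts(layout, fitted_layout):
    """2p - 4 non-null PCs for a full-rank 2D expanded sample: 38 for the
    bilateral 21-landmark layout, 60 for the disymmetric 32-landmark one,
    18 and 16 for the rotational layouts."""
    *_, model = fitted_layout(layout)
    expected, _ = STRUCTURE[layout]
    assert model.n_components_ == expected
    assert expected == 2 * model.expanded_.p - 4


@pytest.mark.parametrize("layout", list(STRUCTURE))
def test_pair_counts(layout, fitted_layout):
    *_, model = fitted_layout(layout)
    _, expected_pairs = STRUCTURE[layout]
    assert len(model.pairs_) == expected_pairs
    # no PC belongs to two pairs
    members = [j for pair in model.pairs_ for j in pair]
    assert len(members) == len(set(members))


@pytest.mark.parametrize("layout", ["vinca", "trillium"])
def test_within_pair_eigenvalue_equality(layout, fitted_layout):
    """The group-invariant covariance forces exactly equal eigenvalues
    within each pair (rotation order > 2)."""
    *_, model = fitted_layout(layout)
    for i, j in model.pairs_:
        rel = (model.eigenvalues_[i] - model.eigenvalues_[j]) / model.eigenvalues_[i]
        assert abs(rel) < 1e-8


def test_fedia_two_categories_of_19(fitted_layout):
    *_, model = fitted_layout("fedia")
    counts = {c: model.categories_.count(c) for c in set(model.categories_)}
    assert counts == {"fully symmetric": 19, "fully asymmetric": 19}


def test_erysimum_four_categories_of_15(fitted_layout):
    *_, model = fitted_layout("erysimum")
    counts = {c: model.categories_.count(c) for c in set(model.categories_)}
    assert sorted(counts.values()) == [15, 15, 15, 15]
    assert "fully symmetric" in counts
    assert "rotation-only symmetric" in counts  # symmetric under 180deg only
    assert sum(1 for c in counts if c.startswith("bilaterally")) == 2


def test_vinca_two_fully_symmetric_singletons(fitted_layout):
    *_, model = fitted_layout("vinca")
    paired = {j for pair in model.pairs_ for j in pair}
    singles = [j for j in range(model.n_components_) if j not in paired]
    assert len(singles) == 2
    assert all(model.categories_[j] == "fully symmetric" for j in singles)
    assert all(model.categories_[j] == "fully asymmetric" for j in paired)


def test_trillium_categories_and_pair_split(fitted_layout):
    """2 fully symmetric, 2 rotation-only symmetric singletons; each rotated
    pair splits into one bilaterally symmetric and one fully asymmetric PC."""
    *_, model = fitted_layout("trillium")
    paired = {j for pair in model.pairs_ for j in pair}
    singles = [j for j in range(model.n_components_) if j not in paired]
    single_counts = {c: [model.categories_[j] for j in singles].count(c)
                     for c in set(model.categories_[j] for j in singles)}
    assert single_counts == {"fully symmetric": 2, "rotation-only symmetric": 2}
    for i, j in model.pairs_:
        cats = {model.categories_[i], model.categories_[j]}
        assert "fully asymmetric" in cats
        assert any(c.startswith("bilaterally symmetric") for c in cats)


def test_unrotated_pairs_are_flagged_unresolved():
    spec = layout_spec("vinca")
    template, rmap = make_template(spec)
    ds = simulate_sample(template, 20, 0.02, seed=21)
    model = SymmetryPCA(spec.group, rmap, rotate_pairs=False).fit(ds)
    paired = {j for pair in model.pairs_ for j in pair}
    assert all(model.categories_[j] == PAIRED_UNRESOLVED for j in paired)


def test_rotate_pc_pair_defining_conditions(fitted_layout):
    """After rotation the mean unrotated-copy score lies on the first axis
    of the pair, eigenvectors stay orthonormal and eigenvalues untouched."""
    *_, model = fitted_layout("trillium")
    decomp = model.decomposition_
    expanded = model.expanded_
    rows = np.nonzero(expanded.copy_index[:, 2] == 0)[0]
    for i, j in model.pairs_:
        mean = decomp.scores[rows][:, [i, j]].mean(axis=0)
        assert abs(mean[1]) < 1e-10
    gram = decomp.eigenvectors.T @ decomp.eigenvectors
    np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-10)


def test_eigendecomposition_agrees_with_svd_oracle(fitted_layout):
    """Independent route: singular values of the centred data matrix."""
    *_, model = fitted_layout("vinca")
    tangent = model.tangent_
    centred = tangent - tangent.mean(axis=0)
    svals = np.linalg.svd(centred, compute_uv=False)
    lam = svals**2 / (tangent.shape[0] - 1)
    k = model.n_components_
    np.testing.assert_allclose(model.eigenvalues_, lam[:k], rtol=1e-8)


def test_scores_of_copies_are_orthogonal_images(fitted_layout):
    """The score vector of a transformed copy has the same norm as the
    original's: the group acts orthogonally on the score space, so paired
    scatterplots are group-invariant point sets."""
    spec, _, rmap, _, model = fitted_layout("vinca")
    k = model.n_components_
    expanded = model.expanded_
    s_id = model.scores_[expanded.rows_for(False, 0)]
    for element in spec.group.elements[1:]:
        s_g = model.scores_[expanded.rows_for(*element)]
        np.testing.assert_allclose(
            np.linalg.norm(s_g, axis=1), np.linalg.norm(s_id, axis=1), rtol=1e-8
        )
        # singleton symmetric PCs have identical scores on copies
        paired = {j for pair in model.pairs_ for j in pair}
        singles = [j for j in range(k) if j not in paired]
        np.testing.assert_allclose(s_g[:, singles], s_id[:, singles], atol=1e-8)


def test_category_variance_sums_to_100(fitted_layout):
    for layout in STRUCTURE:
        *_, model = fitted_layout(layout)
        assert sum(model.category_variance_.values()) == pytest.approx(100.0, abs=1e-9)


def test_symmetric_only_noise_has_no_asymmetric_variance():
    """Noise applied as an exactly symmetrised perturbation leaves the
    asymmetric category empty."""
    spec = layout_spec("fedia")
    template, rmap = make_template(spec)
    rng = np.random.default_rng(31)
    from symmorph import Dataset, LandmarkConfiguration

    configs = []
    for i in range(25):
        noise = rng.normal(0, 0.03, size=template.coords.shape)
        mirrored = noise * [-1, 1]
        sym_noise = (noise + mirrored[rmap.reflection_perm]) / 2.0
        configs.append(
            LandmarkConfiguration(f"s{i}", template.coords + sym_noise)
        )
    model = SymmetryPCA(spec.group, rmap).fit(Dataset(configs))
    asym_pct = model.category_variance_.get("fully asymmetric", 0.0)
    assert asym_pct < 1e-8


def test_symmetric_component_is_group_invariant(fitted_layout):
    spec, _, rmap, _, model = fitted_layout("trillium")
    sym = model.symmetric_component()
    from symmorph import apply_element

    for config in sym.configurations[:5]:
        for element in spec.group.elements[1:]:
            moved = apply_element(config, element, rmap)
            assert procrustes_distance(moved.coords, config.coords) < 1e-8


def test_perfectly_symmetric_input_has_zero_asymmetry():
    spec = layout_spec("fedia")
    template, rmap = make_template(spec)
    rng = np.random.default_rng(17)
    from symmorph import Dataset, LandmarkConfiguration

    # distinct specimens, each exactly symmetric (symmetrised noise)
    configs = []
    for i in range(6):
        noise = rng.normal(0, 0.05, size=template.coords.shape)
        mirrored = noise * [-1, 1]
        sym_noise = (noise + mirrored[rmap.reflection_perm]) / 2.0
        configs.append(LandmarkConfiguration(f"p{i}", template.coords + sym_noise))
    model = SymmetryPCA(spec.group, rmap).fit(Dataset(configs))
    asym = model.asymmetry_component((True, 0))
    assert np.max(np.abs(asym.coords_array())) < 1e-8


def test_directional_asymmetry_recovery():
    """A known left-right offset injected into a bilateral template is
    recovered by the mean asymmetry component within 2 Monte-Carlo SEs."""
    spec = layout_spec("fedia")
    template, rmap = make_template(spec)
    cs = centroid_size(template.coords)
    rng = np.random.default_rng(99)
    da = np.zeros_like(template.coords)
    da[0] = [0.03 * cs, -0.01 * cs]  # push one paired landmark off-axis
    da[2] = [-0.015 * cs, 0.02 * cs]
    n, sd = 200, 0.02 * cs
    noisy = simulate_sample(template, n, sd, seed=101, da_offset=da)
    model = SymmetryPCA(spec.group, rmap).fit(noisy)
    asym = model.asymmetry_component((True, 0)).coords_array()

    # reference: the noise-free asymmetry of the offset template, aligned in
    # the fitted model's own consensus frame (avoids comparing across frames)
    from symmorph import expand_dataset
    from symmorph.pca import asymmetry_component
    from symmorph.procrustes import optimal_rotation

    clean = simulate_sample(template, 2, 0.0, seed=1, da_offset=da)
    clean_exp = expand_dataset(clean, spec.group, rmap)
    aligned = clean_exp.coords_array()
    aligned -= aligned.mean(axis=1, keepdims=True)
    for i in range(aligned.shape[0]):
        aligned[i] /= centroid_size(aligned[i])
        aligned[i] = aligned[i] @ optimal_rotation(aligned[i], model.consensus_)
    ref = asymmetry_component(clean_exp, aligned, (True, 0)).coords_array()[0]

    mean_asym = asym.mean(axis=0)
    se = asym.std(axis=0, ddof=1) / np.sqrt(n)
    # aggregate agreement within 2 Monte-Carlo standard errors: an
    # elementwise bound over all p*d coordinates would reject even an
    # unbiased estimate most of the time
    assert np.linalg.norm(mean_asym - ref) < 2 * np.sqrt(np.sum(se**2))
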