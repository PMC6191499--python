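"""Synthetic landmark data with exact symmetry and controlled noise.

Templates are built from orbit specifications: each orbit is the set of
images of one representative landmark under the symmetry group (a full
orbit in general position), a mirror-fixed orbit whose representatives
sit on a reflection axis, or the fixed centre point.  Because landmarks
are generated by group elements acting on representatives, the matching
relabelling map is known by construction and emitted with the template.

Samples add independent isotropic Gaussian noise per landmark coordinate
(the usual digitising-noise model), optionally a deterministic
directional-asymmetry displacement and per-specimen fluctuating
asymmetry.  Nested imaging/digitising replicates reproduce the classic
measurement-error design with ids of the form ``Ind001_a1b1``.

Built-in layouts mirror four floral case studies:

========= ====== ==== ==========================================
layout    group  p    orbit structure
========= ====== ==== ==========================================
fedia     C1v    21   8 mirror pairs + 5 landmarks on the axis
erysimum  C2v    32   8 full orbits of 4
vinca     C5     11   centre + two full orbits of 5
trillium  C3v    10   one full 6-orbit + one mirror-fixed 3-orbit
                      + centre
========= ====== ==== ==========================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .groups import RelabellingMap, SymmetryGroup
from .io import Dataset, LandmarkConfiguration
from .procrustes import centroid_size

__all__ = [
    "Orbit",
    "OrbitSpec",
    "make_template",
    "simulate_sample",
    "make_replicates",
    "LAYOUTS",
    "layout_spec",
]


@dataclass(frozen=True)
class Orbit:
    """One orbit of the group action: ``kind`` is "full", "mirror_fixed"
    or "centre"; ``radius`` and ``angle`` place the representative."""

    kind: str
    radius: float = 0.0
    angle: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("full", "mirror_fixed", "centre"):
            raise ValueError(f"unknown orbit kind {self.kind!r}")
        if self.kind != "centre" and self.radius <= 0:
            raise ValueError(f"{self.kind} orbit needs a positive radius")


@dataclass(frozen=True)
class OrbitSpec:
    group: SymmetryGroup
    orbits: tuple[Orbit, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "orbits", tuple(self.orbits))


def _rotation(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def _element_matrix(reflect: bool, k: int, n: int) -> np.ndarray:
    mat = np.eye(2)
    if reflect:
        mat = np.diag([-1.0, 1.0]) @ mat
    return _rotation(2 * np.pi * k / n) @ mat


def make_template(spec: OrbitSpec) -> tuple[LandmarkConfiguration, RelabellingMap]:
    """Build an exactly symmetric template and its relabelling map.

    The map is correct by construction: orbit members are indexed by the
    group elements that generate them, so reflection and rotation
    permutations follow from the group's multiplication rule.
    """
    group = spec.group
    n = group.rotation_order
    points: list[np.ndarray] = []
    # per-landmark bookkeeping for permutation construction
    refl_targets: list[int] = []
    rot_targets: list[int] = []  # target under one rotation step

    for orbit in spec.orbits:
        base = len(points)
        if orbit.kind == "centre":
            points.append(np.zeros(2))
            refl_targets.append(base)
            rot_targets.append(base)
            continue
        rep = orbit.radius * np.array([np.cos(orbit.angle), np.sin(orbit.angle)])
        if orbit.kind == "mirror_fixed":
            if not group.has_reflection:
                raise ValueError("mirror_fixed orbits need a group with reflection")
            if abs(rep[0]) > 1e-12 * orbit.radius:
                raise ValueError(
                    "mirror_fixed representative must lie on the y axis"
                    " (angle +pi/2 or -pi/2)"
                )
            members = [_rotation(2 * np.pi * k / n) @ rep for k in range(n)]
            points.extend(members)
            for k in range(n):
                # one rotation step: member k -> position of member k+1, so
                # the copy at slot i takes its coordinates from slot i-1... the
                # permutation convention new[i] = old[perm[i]] makes the
                # relabelled copy equal the rotated template
                rot_targets.append(base + (k + 1) % n)
                refl_targets.append(base + (-k) % n)
        else:  # full orbit, one member per group element in element order
            elements = group.elements
            members = {
                e: _element_matrix(*e, n) @ rep for e in elements
            }
            index_of = {e: base + i for i, e in enumerate(elements)}
            pts = [members[e] for e in elements]
            arr = np.array(pts)
            dists = np.linalg.norm(arr[:, None] - arr[None, :], axis=-1)
            np.fill_diagonal(dists, np.inf)
            if dists.min() < 1e-9 * orbit.radius:
                raise ValueError(
                    f"full orbit at angle {orbit.angle:.3f} is degenerate"
                    " (representative on a symmetry axis?)"
                )
            points.extend(pts)
            for reflect, k in elements:
                # rotating the template by one step sends element (r, k) to
                # (r, k+1); reflecting sends it to (not r, -k)
                rot_targets.append(index_of[(reflect, (k + 1) % n)])
                if group.has_reflection:
                    refl_targets.append(index_of[(not reflect, (-k) % n)])
                else:
                    refl_targets.append(index_of[(reflect, k)])

    coords = np.array(points)
    p = len(points)

    rotation_perms: list[np.ndarray] = []
    if n > 1:
        gen = np.array(rot_targets, dtype=int)
        acc = gen.copy()
        for _ in range(n - 1):
            rotation_perms.append(acc.copy())
            acc = acc[gen]
    reflection = np.array(refl_targets, dtype=int) if group.has_reflection else None
    rmap = RelabellingMap(p, reflection_perm=reflection, rotation_perms=rotation_perms)
    template = LandmarkConfiguration("template", coords)
    return template, rmap


def simulate_sample(
    template: LandmarkConfiguration,
    n: int,
    noise_sd: float,
    seed: int,
    da_offset: np.ndarray | None = None,
    fa_sd: float | None = None,
    relabelling: RelabellingMap | None = None,
    id_prefix: str = "Ind",
) -> Dataset:
    """Draw ``n`` specimens around a template.

    Each specimen is template + optional directional-asymmetry offset
    (a fixed (p, d) displacement) + optional per-specimen fluctuating
    asymmetry (Gaussian displacement of sd ``fa_sd``, antisymmetrised when
    a relabelling map with a reflection column is supplied) + i.i.d.
    isotropic Gaussian noise of sd ``noise_sd`` per coordinate.
    """
    if n < 2:
        raise ValueError("need at least 2 specimens")
    if noise_sd < 0 or (fa_sd is not None and fa_sd < 0):
        raise ValueError("noise standard deviations must be non-negative")
    rng = np.random.default_rng(seed)
    base = template.coords.copy()
    if da_offset is not None:
        da = np.asarray(da_offset, dtype=float)
        if da.shape != base.shape:
            raise ValueError(f"da_offset shape {da.shape} != template {base.shape}")
        base = base + da
    configs = []
    for i in range(n):
        coords = base.copy()
        if fa_sd:
            disp = rng.normal(0.0, fa_sd, size=base.shape)
            if relabelling is not None and relabelling.reflection_perm is not None:
                mirrored = disp.copy()
                mirrored[:, 0] = -mirrored[:, 0]
                disp = (disp - mirrored[relabelling.reflection_perm]) / 2.0
            coords = coords + disp
        coords = coords + rng.normal(0.0, noise_sd, size=base.shape)
        configs.append(LandmarkConfiguration(f"{id_prefix}{i + 1:03d}", coords))
    return Dataset(configs)


def make_replicates(
    dataset: Dataset,
    n_imaging: int,
    n_digitising: int,
    imaging_sd: float,
    digitising_sd: float,
    seed: int,
) -> Dataset:
    """Expand each specimen into imaging x digitising replicates.

    The imaging-level displacement is shared by all digitisings of one
    image; the digitising-level displacement is independent per
    observation.  Ids follow the ``<specimen>a<i>b<j>`` grammar and the
    individual/imaging/digitising classifiers are populated.
    """
    if imaging_sd < 0 or digitising_sd < 0:
        raise ValueError("replicate noise sds must be non-negative")
    rng = np.random.default_rng(seed)
    configs = []
    ind, img, dig = [], [], []
    for c in dataset.configurations:
        for a in range(1, n_imaging + 1):
            img_disp = rng.normal(0.0, imaging_sd, size=c.coords.shape) if imaging_sd else 0.0
            for b in range(1, n_digitising + 1):
                dig_disp = (
                    rng.normal(0.0, digitising_sd, size=c.coords.shape)
                    if digitising_sd
                    else 0.0
                )
                configs.append(
                    LandmarkConfiguration(
                        f"{c.specimen_id}a{a}b{b}",
                        c.coords + img_disp + dig_disp,
                        scale_factor=c.scale_factor,
                    )
                )
                ind.append(c.specimen_id)
                img.append(f"a{a}")
                dig.append(f"b{b}")
    return Dataset(
        configs, {"individual": ind, "imaging": img, "digitising": dig}
    )


def _fedia_spec() -> OrbitSpec:
    group = SymmetryGroup(1, True)
    orbits = [
        Orbit("full", 1.00, 0.55),
        Orbit("full", 1.35, 0.95),
        Orbit("full", 0.90, -0.40),
        Orbit("full", 1.60, 0.20),
        Orbit("full", 1.10, -1.05),
        Orbit("full", 0.70, 1.25),
        Orbit("full", 1.45, -0.75),
        Orbit("full", 0.85, 0.05),
        Orbit("mirror_fixed", 0.50, np.pi / 2),
        Orbit("mirror_fixed", 1.20, np.pi / 2),
        Orbit("mirror_fixed", 0.30, -np.pi / 2),
        Orbit("mirror_fixed", 0.95, -np.pi / 2),
        Orbit("mirror_fixed", 1.55, -np.pi / 2),
    ]
    return OrbitSpec(group, tuple(orbits))


def _erysimum_spec() -> OrbitSpec:
    group = SymmetryGroup(2, True)
    radii = [1.00, 1.30, 0.85, 1.55, 1.10, 0.70, 1.40, 0.95]
    angles = [0.30, 0.75, 1.10, 0.15, 0.95, 0.50, 1.30, 0.60]
    return OrbitSpec(group, tuple(Orbit("full", r, a) for r, a in zip(radii, angles)))


def _vinca_spec() -> OrbitSpec:
    group = SymmetryGroup(5, False)
    return OrbitSpec(
        group,
        (Orbit("centre"), Orbit("full", 1.00, 0.20), Orbit("full", 1.60, 0.55)),
    )


def _trillium_spec() -> OrbitSpec:
    group = SymmetryGroup(3, True)
    return OrbitSpec(
        group,
        (
            Orbit("full", 1.50, 0.35),
            Orbit("mirror_fixed", 0.80, np.pi / 2),
            Orbit("centre"),
        ),
    )


LAYOUTS = {
    "fedia": _fedia_spec,
    "erysimum": _erysimum_spec,
    "vinca": _vinca_spec,
    "trillium": _trillium_spec,
}

#: default sample sizes per layout; the disymmetric layout needs the
#: original sample alone to span its 60-dimensional shape space
DEFAULT_N = {"fedia": 30, "erysimum": 61, "vinca": 30, "trillium": 30}

#: default landmark noise, as a fraction of template centroid size: small
#: enough for tangent-space linearity, large enough for full-rank covariances
DEFAULT_NOISE_FRACTION = 0.02


def layout_spec(name: str) -> OrbitSpec:
    try:
        return LAYOUTS[name]()
    except KeyError:
        raise ValueError(
            f"unknown layout {name!r}; known layouts: {sorted(LAYOUTS)}"
        ) from None


def layout_sample(
    name: str,
    n: int | None = None,
    noise_sd: float | None = None,
    seed: int = 0,
    **kwargs,
):
    """Convenience: template, map and simulated sample for a named layout."""
    spec = layout_spec(name)
    template, rmap = make_template(spec)
    if n is None:
        n = DEFAULT_N[name]
    if noise_sd is None:
        noise_sd = DEFAULT_NOISE_FRACTION * centroid_size(template.coords)
    dataset = simulate_sample(
        template, n, noise_sd, seed, relabelling=rmap, **kwargs
    )
    return spec, template, rmap, dataset
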