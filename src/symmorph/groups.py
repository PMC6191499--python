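"""Finite symmetry groups and landmark relabelling.

A planar structure with object symmetry (the symmetry axis passes through
the structure itself) is analysed by adding to each original configuration
one transformed, relabelled copy per symmetry-group element.  The group is
described in Schoenflies notation: ``Cn`` for an n-fold rotation axis,
``Cnv`` when a mirror line is present as well (``C1v`` is plain bilateral
symmetry, ``C2v`` disymmetry).

Reflection copies are produced by negating the x coordinate and swapping
the labels of landmarks that are mirror images of each other.  Rotation
copies keep their coordinates unchanged and only permute labels: the
rotation that brings a copy back onto the original is supplied later by
the Procrustes superimposition, so relabelling alone is sufficient.

Relabelling maps live in plain-text files of whitespace-separated 1-based
integer columns, one row per landmark: one column for a reflection
(``C1v``), n-1 columns for successive rotations (``Cn``), and 1 + (n-1)
columns for ``Cnv``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Dataset, LandmarkConfiguration

__all__ = [
    "SymmetryGroup",
    "RelabellingMap",
    "ExpandedDataset",
    "load_relabelling",
    "save_relabelling",
    "reflect_relabel",
    "rotation_relabel",
    "apply_element",
    "expand_dataset",
    "match_units",
]


@dataclass(frozen=True)
class SymmetryGroup:
    """A finite planar symmetry group Cn or Cnv.

    Elements are (reflect, k) pairs meaning: reflect about the y axis
    (optional), then rotate by k * 360/n degrees.  The identity
    (False, 0) is always first; within each rotation index the unreflected
    element precedes the reflected one, matching the ori/ref copy listing
    order.
    """

    rotation_order: int
    has_reflection: bool

    def __post_init__(self) -> None:
        if self.rotation_order < 1:
            raise ValueError("rotation_order must be >= 1")

    @classmethod
    def from_schoenflies(cls, name: str) -> "SymmetryGroup":
        m = name.strip().upper()
        if not m.startswith("C"):
            raise ValueError(f"unsupported Schoenflies symbol {name!r}")
        body = m[1:]
        has_reflection = body.endswith("V")
        if has_reflection:
            body = body[:-1]
        try:
            n = int(body)
        except ValueError:
            raise ValueError(f"unsupported Schoenflies symbol {name!r}")
        return cls(n, has_reflection)

    @property
    def order(self) -> int:
        return self.rotation_order * (2 if self.has_reflection else 1)

    @property
    def elements(self) -> list[tuple[bool, int]]:
        out = []
        for k in range(self.rotation_order):
            out.append((False, k))
            if self.has_reflection:
                out.append((True, k))
        return out

    @property
    def schoenflies(self) -> str:
        return f"C{self.rotation_order}" + ("v" if self.has_reflection else "")

    def suffix(self, reflect: bool, k: int) -> str:
        return f"{'ref' if reflect else 'ori'}_Cn{k:02d}"


def _check_permutation(col: np.ndarray, p: int, what: str) -> np.ndarray:
    col = np.asarray(col, dtype=int)
    if col.shape != (p,):
        raise ValueError(f"{what}: expected {p} entries, got {col.shape}")
    if sorted(col) != list(range(p)):
        raise ValueError(f"{what}: not a bijection on 1..{p}")
    return col


@dataclass
class RelabellingMap:
    """Landmark-label permutations accompanying each symmetry transformation.

    Permutations are stored 0-based with the convention
    ``new_coords[i] = old_coords[perm[i]]``. ``rotation_perms[k-1]`` is the
    permutation for a rotation by k steps of 360/n degrees.
    """

    p: int
    reflection_perm: np.ndarray | None = None
    rotation_perms: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.reflection_perm is not None:
            self.reflection_perm = _check_permutation(
                self.reflection_perm, self.p, "reflection column"
            )
            if not np.array_equal(
                self.reflection_perm[self.reflection_perm], np.arange(self.p)
            ):
                raise ValueError("reflection column is not an involution")
        perms = [
            _check_permutation(c, self.p, f"rotation column {i + 1}")
            for i, c in enumerate(self.rotation_perms)
        ]
        # successive columns must be powers of the first (cyclic consistency)
        if perms:
            acc = perms[0]
            for i, perm in enumerate(perms[1:], start=2):
                acc = acc[perms[0]]
                if not np.array_equal(perm, acc):
                    raise ValueError(
                        f"rotation column {i} is not the {i}-th power of column 1"
                    )
        self.rotation_perms = perms

    @property
    def rotation_order(self) -> int:
        return len(self.rotation_perms) + 1


def load_relabelling(path, p: int, group: SymmetryGroup) -> RelabellingMap:
    """Read a relabelling file (1-based integer columns, one row per landmark)."""
    table = np.loadtxt(path, dtype=int, ndmin=2)
    if table.shape[0] != p:
        raise ValueError(f"relabelling file has {table.shape[0]} rows, expected p={p}")
    expected = (1 if group.has_reflection else 0) + (group.rotation_order - 1)
    if table.shape[1] != expected:
        raise ValueError(
            f"relabelling file has {table.shape[1]} columns; {group.schoenflies}"
            f" needs {expected}"
        )
    table = table - 1  # to 0-based
    refl = None
    cols = list(table.T)
    if group.has_reflection:
        refl = cols.pop(0)
    return RelabellingMap(p, reflection_perm=refl, rotation_perms=cols)


def save_relabelling(rmap: RelabellingMap, path) -> None:
    cols = []
    if rmap.reflection_perm is not None:
        cols.append(rmap.reflection_perm)
    cols.extend(rmap.rotation_perms)
    if not cols:
        raise ValueError("map has no columns to write")
    table = np.column_stack(cols) + 1  # back to 1-based
    np.savetxt(path, table, fmt="%d")


def reflect_relabel(
    config: LandmarkConfiguration, rmap: RelabellingMap, suffix: str = "_ref"
) -> LandmarkConfiguration:
    """Mirror a configuration (negate x) and swap paired landmark labels."""
    if rmap.reflection_perm is None:
        raise ValueError("relabelling map has no reflection column")
    mirrored = config.coords.copy()
    mirrored[:, 0] = -mirrored[:, 0]
    out = mirrored[rmap.reflection_perm]
    return LandmarkConfiguration(
        config.specimen_id + suffix, out, scale_factor=config.scale_factor
    )


def rotation_relabel(
    config: LandmarkConfiguration, rmap: RelabellingMap, k: int, suffix: str | None = None
) -> LandmarkConfiguration:
    """Relabel landmarks for a rotation by k steps; coordinates are untouched.

    The compensating rotation is supplied downstream by the Procrustes fit,
    so an exactly symmetric configuration superimposes on its relabelled
    copy with zero Procrustes distance.
    """
    n = rmap.rotation_order
    if not (1 <= k <= n - 1):
        raise ValueError(f"rotation index must be in 1..{n - 1}, got {k}")
    out = config.coords[rmap.rotation_perms[k - 1]]
    if suffix is None:
        suffix = f"_Cn{k:02d}"
    return LandmarkConfiguration(
        config.specimen_id + suffix, out, scale_factor=config.scale_factor
    )


def apply_element(
    config: LandmarkConfiguration,
    element: tuple[bool, int],
    rmap: RelabellingMap,
    group: SymmetryGroup | None = None,
) -> LandmarkConfiguration:
    """Apply one group element: optional reflection, then rotation relabelling."""
    reflect, k = element
    out = config
    if reflect:
        out = reflect_relabel(out, rmap, suffix="")
    if k > 0:
        out = rotation_relabel(out, rmap, k, suffix="")
    suffix = f"_{'ref' if reflect else 'ori'}_Cn{k:02d}"
    return LandmarkConfiguration(
        config.specimen_id + suffix, out.coords, scale_factor=config.scale_factor
    )


@dataclass
class ExpandedDataset(Dataset):
    """Originals plus transformed relabelled copies.

    ``copy_index`` has one row per configuration: (source specimen index,
    reflect flag, rotation index). The identity copies carry the
    ``_ori_Cn00`` suffix.
    """

    copy_index: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=int))
    group: SymmetryGroup | None = None
    relabelling: RelabellingMap | None = None

    def source_count(self) -> int:
        return int(self.copy_index[:, 0].max()) + 1 if len(self) else 0

    def rows_for(self, reflect: bool, k: int) -> np.ndarray:
        """Row indices of the copies produced by group element (reflect, k),
        ordered by source specimen."""
        mask = (self.copy_index[:, 1] == int(reflect)) & (self.copy_index[:, 2] == k)
        rows = np.nonzero(mask)[0]
        return rows[np.argsort(self.copy_index[rows, 0])]


def expand_dataset(
    dataset: Dataset, group: SymmetryGroup, rmap: RelabellingMap
) -> ExpandedDataset:
    """Generate all transformed relabelled copies for every specimen.

    A C1v group doubles the dataset; Cn multiplies it by n and Cnv by 2n.
    """
    if dataset.p != rmap.p:
        raise ValueError(f"dataset has p={dataset.p} but map has p={rmap.p}")
    if group.has_reflection and rmap.reflection_perm is None:
        raise ValueError(f"{group.schoenflies} needs a reflection column in the map")
    if group.rotation_order - 1 > len(rmap.rotation_perms):
        raise ValueError(
            f"{group.schoenflies} needs {group.rotation_order - 1} rotation columns,"
            f" map has {len(rmap.rotation_perms)}"
        )
    configs: list[LandmarkConfiguration] = []
    index: list[tuple[int, int, int]] = []
    for i, config in enumerate(dataset.configurations):
        for reflect, k in group.elements:
            configs.append(apply_element(config, (reflect, k), rmap))
            index.append((i, int(reflect), k))
    return ExpandedDataset(
        configs,
        copy_index=np.array(index, dtype=int),
        group=group,
        relabelling=rmap,
    )


def match_units(
    dataset: Dataset,
    side_classifier: str,
    reference_level: str,
    relabelling: RelabellingMap | None = None,
) -> Dataset:
    """Mirror non-reference units onto the reference orientation
    (matching symmetry for repeated, physically disconnected parts).

    Units whose side differs from ``reference_level`` are reflected
    (x negated) and, when a map with a reflection column is given,
    relabelled; the result is ready for one joint Procrustes fit.
    """
    if side_classifier not in dataset.classifiers:
        raise ValueError(f"no classifier named {side_classifier!r}")
    sides = dataset.classifiers[side_classifier]
    if reference_level not in sides:
        raise ValueError(
            f"reference level {reference_level!r} absent from classifier"
            f" {side_classifier!r}"
        )
    out = []
    for config, side in zip(dataset.configurations, sides):
        if side == reference_level:
            out.append(config)
        else:
            mirrored = config.coords.copy()
            mirrored[:, 0] = -mirrored[:, 0]
            if relabelling is not None and relabelling.reflection_perm is not None:
                mirrored = mirrored[relabelling.reflection_perm]
            out.append(
                LandmarkConfiguration(
                    config.specimen_id, mirrored, scale_factor=config.scale_factor
                )
            )
    return Dataset(out, dict(dataset.classifiers))
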