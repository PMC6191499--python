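"""Reading and writing landmark data (TPS and NTS text dialects).

TPS files are the native output of the tpsDig family of digitising tools:
each record starts with an ``LM=<count>`` line, followed by that many
coordinate lines, and optional ``IMAGE=``, ``ID=`` and ``SCALE=`` key lines.
NTS files are the rectangular-matrix format used by NTSYSpc and accepted by
most morphometric software: a header declaring the number of objects and
variables, then one labelled row of ``x1 y1 x2 y2 ...`` per specimen.

Scale factors are stored on read but never applied implicitly; conversion
from pixels to physical units happens only when explicitly requested on
NTS export.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkConfiguration",
    "Dataset",
    "ParseError",
    "read_tps",
    "write_tps",
    "read_nts",
    "write_nts",
    "extract_classifier",
]


class ParseError(ValueError):
    """A landmark file violated the expected dialect."""


@dataclass
class LandmarkConfiguration:
    """One specimen's labelled landmark set.

    Parameters
    ----------
    specimen_id : str
        Identifier, typically the image file name from digitising.
    coords : (p, d) ndarray
        Cartesian landmark coordinates in digitising order, d = 2 or 3.
    scale_factor : float, optional
        Pixels-to-units conversion factor recorded at digitising time.
    """

    specimen_id: str
    coords: np.ndarray
    scale_factor: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise ValueError(
                f"coords must be a (p, 2) or (p, 3) array, got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates in {self.specimen_id!r}")
        if self.scale_factor is not None and self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")

    @property
    def p(self) -> int:
        return self.coords.shape[0]

    @property
    def d(self) -> int:
        return self.coords.shape[1]


@dataclass
class Dataset:
    """An ordered collection of configurations sharing landmark scheme.

    ``classifiers`` holds named categorical variables (one value per
    configuration), e.g. individual / imaging / digitising factors for
    measurement-error designs.
    """

    configurations: list[LandmarkConfiguration]
    classifiers: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.configurations:
            p, d = self.configurations[0].p, self.configurations[0].d
            for c in self.configurations:
                if (c.p, c.d) != (p, d):
                    raise ValueError(
                        f"configuration {c.specimen_id!r} has (p, d)=({c.p}, {c.d}),"
                        f" expected ({p}, {d})"
                    )
        for name, values in self.classifiers.items():
            if len(values) != len(self.configurations):
                raise ValueError(
                    f"classifier {name!r} has {len(values)} values for"
                    f" {len(self.configurations)} configurations"
                )

    def __len__(self) -> int:
        return len(self.configurations)

    def __getitem__(self, i: int) -> LandmarkConfiguration:
        return self.configurations[i]

    @property
    def p(self) -> int:
        return self.configurations[0].p

    @property
    def d(self) -> int:
        return self.configurations[0].d

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    def coords_array(self) -> np.ndarray:
        """Stack coordinates into an (n, p, d) array."""
        return np.stack([c.coords for c in self.configurations])

    def flat(self) -> np.ndarray:
        """Coordinates as an (n, p*d) matrix in x1, y1, x2, y2, ... order."""
        n = len(self)
        return self.coords_array().reshape(n, -1)

    def classifier_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(self.classifiers), index=pd.Index(self.specimen_ids, name="specimen")
        )


_TPS_KEY = re.compile(r"^\s*(LM|IMAGE|ID|SCALE|CURVES|POINTS)\s*=\s*(.*?)\s*$", re.I)


def read_tps(path) -> Dataset:
    """Read a TPS file into a :class:`Dataset`.

    Accepts CRLF or LF endings and case-insensitive keys. CURVES/POINTS
    blocks (semilandmark outlines) are skipped. ``SCALE=`` is stored on the
    configuration but not applied to the coordinates.
    """
    configs: list[LandmarkConfiguration] = []
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()

    i = 0
    record = 0
    while i < len(lines):
        line = lines[i]
        if not line.strip():
            i += 1
            continue
        m = _TPS_KEY.match(line)
        if not m or m.group(1).upper() != "LM":
            raise ParseError(f"line {i + 1}: expected an LM= record header, got {line!r}")
        record += 1
        try:
            p = int(m.group(2))
        except ValueError:
            raise ParseError(f"record {record}, line {i + 1}: malformed count {line!r}")
        i += 1
        coords = []
        while len(coords) < p:
            if i >= len(lines):
                raise ParseError(
                    f"record {record}: expected {p} coordinate lines, got {len(coords)}"
                )
            parts = lines[i].split()
            if not parts:
                i += 1
                continue
            if _TPS_KEY.match(lines[i]):
                raise ParseError(
                    f"record {record}: expected {p} coordinate lines, got {len(coords)}"
                )
            try:
                coords.append([float(v) for v in parts])
            except ValueError:
                raise ParseError(
                    f"record {record}, line {i + 1}: non-numeric coordinate {lines[i]!r}"
                )
            i += 1
        image = ident = None
        scale = None
        # trailing key lines until the next LM=
        while i < len(lines):
            m = _TPS_KEY.match(lines[i])
            if m is None:
                if lines[i].strip():
                    raise ParseError(f"record {record}, line {i + 1}: unexpected {lines[i]!r}")
                i += 1
                continue
            key = m.group(1).upper()
            if key == "LM":
                break
            if key == "IMAGE":
                image = m.group(2)
            elif key == "ID":
                ident = m.group(2)
            elif key == "SCALE":
                try:
                    scale = float(m.group(2))
                except ValueError:
                    raise ParseError(f"record {record}: malformed SCALE= line")
            elif key in ("CURVES", "POINTS"):
                # semilandmark outline block: skip its coordinate lines
                pass
            i += 1
        arr = np.array(coords, dtype=float)
        if arr.ndim != 2:
            raise ParseError(f"record {record}: ragged coordinate lines")
        specimen_id = image or ident or str(record)
        configs.append(LandmarkConfiguration(specimen_id, arr, scale_factor=scale))
    return Dataset(configs)


def write_tps(dataset: Dataset, path) -> None:
    """Write a dataset as a TPS file (LM=, coordinates, IMAGE=, SCALE=)."""
    if not len(dataset):
        raise ValueError("cannot write an empty dataset")
    with open(path, "w", encoding="utf-8") as fh:
        for c in dataset.configurations:
            fh.write(f"LM={c.p}\n")
            for row in c.coords:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write(f"IMAGE={c.specimen_id}\n")
            if c.scale_factor is not None:
                fh.write(f"SCALE={c.scale_factor:.6f}\n")


def read_nts(path) -> Dataset:
    """Read a rectangular NTS matrix: header, then one labelled row per specimen."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip() and not ln.lstrip().startswith(("'", '"'))]
    if not lines:
        raise ParseError("empty NTS file")
    header = lines[0].split()
    if len(header) < 4:
        raise ParseError(f"malformed NTS header {lines[0]!r}")
    nobj_tok = header[1]
    labelled = nobj_tok.upper().endswith("L")
    nobj = int(nobj_tok[:-1] if labelled else nobj_tok)
    nvar = int(header[2].rstrip("Ll"))
    rows = lines[1:]
    if len(rows) != nobj:
        raise ParseError(f"header declares {nobj} objects but file has {len(rows)} rows")
    configs = []
    # 2D is the only layout the writer produces; d=2 recovered from nvar parity
    d = 2
    if nvar % d != 0:
        raise ParseError(f"variable count {nvar} is not a multiple of {d}")
    for r, row in enumerate(rows, start=1):
        parts = row.split()
        label = parts[0] if labelled else str(r)
        vals = parts[1:] if labelled else parts
        if len(vals) != nvar:
            raise ParseError(f"row {r} ({label!r}): {len(vals)} values, expected {nvar}")
        try:
            flat = np.array([float(v) for v in vals])
        except ValueError:
            raise ParseError(f"row {r} ({label!r}): non-numeric value")
        configs.append(LandmarkConfiguration(label, flat.reshape(-1, d)))
    return Dataset(configs)


def write_nts(dataset: Dataset, path, apply_scale: bool = False) -> None:
    """Write an NTS matrix; ``apply_scale`` multiplies coordinates by each
    configuration's scale factor (pixel -> physical units)."""
    if not len(dataset):
        raise ValueError("cannot write an empty dataset")
    n, nvar = len(dataset), dataset.p * dataset.d
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"1 {n}L {nvar} 0\n")
        for c in dataset.configurations:
            coords = c.coords
            if apply_scale and c.scale_factor is not None:
                coords = coords * c.scale_factor
            flat = coords.reshape(-1)
            fh.write(c.specimen_id + " " + " ".join(f"{v:.6f}" for v in flat) + "\n")


def extract_classifier(dataset: Dataset, name: str, first: int, last: int) -> Dataset:
    """Define a classifier from a 1-based inclusive substring of each specimen id.

    E.g. ids of the form ``Fedia01a1b1.jpg`` yield individual (chars 1-7),
    imaging (8-9) and digitising (10-11) factors.
    """
    if not (1 <= first <= last):
        raise ValueError(f"need 1 <= first <= last, got first={first}, last={last}")
    values = []
    for c in dataset.configurations:
        if last > len(c.specimen_id):
            raise ValueError(
                f"specimen {c.specimen_id!r} is shorter than character range"
                f" [{first}, {last}]"
            )
        values.append(c.specimen_id[first - 1 : last])
    classifiers = dict(dataset.classifiers)
    classifiers[name] = values
    return Dataset(list(dataset.configurations), classifiers)
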