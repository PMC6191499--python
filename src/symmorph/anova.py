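"""Procrustes ANOVA for measurement error and allometry regression.

The measurement-error design is a balanced one-way nested hierarchy:
specimens ("individuals"), images taken per specimen ("imaging"), and
digitising repeats per image ("digitising").  The ANOVA dissects the
variance of centroid size (univariate) and of shape (Procrustes tangent
coordinates, summed over all landmark variables) across these levels.

For shape, degrees of freedom at each level are multiplied by the
dimensionality of the shape space, s = p*d - 4 for 2D configurations
after a Procrustes fit (Goodall-style ANOVA); F at a level is its MS over
the MS of the level nested within it.

Allometry is the multivariate regression of shape on (log) centroid
size; significance comes from a permutation test of the predicted sum of
squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaTable",
    "nested_ss",
    "anova_size",
    "procrustes_anova_shape",
    "allometry_regression",
]


@dataclass
class AnovaTable:
    """Effect rows (SS, MS, df, F, P) for the nested design, in the order
    individual, imaging, digitising."""

    effects: list[str]
    ss: np.ndarray
    ms: np.ndarray
    df: np.ndarray
    f: np.ndarray  # NaN for the innermost level
    p: np.ndarray  # NaN for the innermost level

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"SS": self.ss, "MS": self.ms, "df": self.df, "F": self.f, "P": self.p},
            index=pd.Index(self.effects, name="Effect"),
        )

    def __str__(self) -> str:
        return self.to_frame().to_string(float_format=lambda v: f"{v:.10g}")


def _check_balanced(individual, imaging, digitising):
    ind = np.asarray(individual)
    img = np.asarray(imaging)
    dig = np.asarray(digitising)
    if not (len(ind) == len(img) == len(dig)):
        raise ValueError("classifier lengths differ")
    frame = pd.DataFrame({"ind": ind, "img": img, "dig": dig})
    per_ind = frame.groupby("ind")["img"].nunique()
    per_img = frame.groupby(["ind", "img"])["dig"].nunique()
    counts = frame.groupby(["ind", "img", "dig"]).size()
    if per_ind.nunique() != 1 or per_img.nunique() != 1 or not (counts == 1).all():
        raise ValueError("unbalanced nested design: equal replicate counts required")
    return frame, len(per_ind), int(per_ind.iloc[0]), int(per_img.iloc[0])


def nested_ss(y: np.ndarray, frame: pd.DataFrame) -> tuple[float, float, float]:
    """Sums of squares for the three nested levels, summed over all columns
    of ``y``; SS_ind + SS_img + SS_dig equals the total SS about the grand
    mean (conservation)."""
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    grand = y.mean(axis=0)
    ind_means = pd.DataFrame(y).groupby(frame["ind"].values).transform("mean").values
    img_means = (
        pd.DataFrame(y)
        .groupby([frame["ind"].values, frame["img"].values])
        .transform("mean")
        .values
    )
    ss_ind = float(np.sum((ind_means - grand) ** 2))
    ss_img = float(np.sum((img_means - ind_means) ** 2))
    ss_dig = float(np.sum((y - img_means) ** 2))
    return ss_ind, ss_img, ss_dig


def _table(ss, df) -> AnovaTable:
    ss = np.asarray(ss, dtype=float)
    df = np.asarray(df, dtype=int)
    with np.errstate(invalid="ignore", divide="ignore"):
        ms = ss / df
        f = np.full(3, np.nan)
        p = np.full(3, np.nan)
        for lvl in range(2):
            if ms[lvl + 1] > 0:
                f[lvl] = ms[lvl] / ms[lvl + 1]
                p[lvl] = stats.f.sf(f[lvl], df[lvl], df[lvl + 1])
    return AnovaTable(
        effects=["individual", "imaging", "digitising"], ss=ss, ms=ms, df=df, f=f, p=p
    )


def anova_size(centroid_sizes, individual, imaging, digitising) -> AnovaTable:
    """Univariate nested ANOVA on centroid size.

    df: individual n_ind-1; imaging n_ind*(n_img-1); digitising
    n_ind*n_img*(n_dig-1).
    """
    frame, n_ind, n_img, n_dig = _check_balanced(individual, imaging, digitising)
    y = np.asarray(centroid_sizes, dtype=float)
    if len(y) != len(frame):
        raise ValueError("one centroid size per observation required")
    ss = nested_ss(y, frame)
    df = [n_ind - 1, n_ind * (n_img - 1), n_ind * n_img * (n_dig - 1)]
    return _table(ss, df)


def procrustes_anova_shape(
    tangent: np.ndarray,
    individual,
    imaging,
    digitising,
    n_shape_dims: int | None = None,
) -> AnovaTable:
    """Nested Procrustes ANOVA on shape (tangent coordinates).

    SS are summed over all p*d coordinate variables; df are the nested
    design formulas multiplied by the shape dimensionality
    s = p*d - 4 (2D Procrustes fit).  The classic balanced 30 x 2 x 2
    design with p = 21 gives df = 1102, 1140, 2280.
    """
    frame, n_ind, n_img, n_dig = _check_balanced(individual, imaging, digitising)
    y = np.asarray(tangent, dtype=float)
    if y.ndim != 2 or y.shape[0] != len(frame):
        raise ValueError("tangent must be (n_obs, p*d) with one row per observation")
    s = n_shape_dims if n_shape_dims is not None else y.shape[1] - 4
    if s < 1:
        raise ValueError(f"shape dimensionality {s} is not positive")
    ss = nested_ss(y, frame)
    df = [s * (n_ind - 1), s * n_ind * (n_img - 1), s * n_ind * n_img * (n_dig - 1)]
    return _table(ss, df)


def allometry_regression(
    shape: np.ndarray,
    sizes,
    use_log: bool = True,
    n_perm: int = 999,
    seed: int | None = None,
) -> dict:
    """Multivariate regression of shape on (log) centroid size.

    Returns the percentage of total shape variation predicted by size and
    a permutation p-value for the predicted sum of squares, computed as
    (b + 1) / (n_perm + 1) where b counts permutations with predicted SS
    at least the observed one.
    """
    y = np.asarray(shape, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    x = np.asarray(sizes, dtype=float)
    if len(x) != y.shape[0]:
        raise ValueError("one size value per specimen required")
    if np.ptp(x) == 0:
        raise ValueError("size vector is constant; regression undefined")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if seed is None:
        raise ValueError("a seed is required for the permutation test")
    if use_log:
        if np.any(x <= 0):
            raise ValueError("log size requires positive sizes")
        x = np.log(x)

    yc = y - y.mean(axis=0)
    total_ss = float(np.sum(yc**2))

    def predicted_ss(xv: np.ndarray) -> float:
        xc = xv - xv.mean()
        beta = (xc @ yc) / (xc @ xc)
        return float((xc @ xc) * np.sum(beta**2))

    observed = predicted_ss(x)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if predicted_ss(rng.permutation(x)) >= observed:
            exceed += 1
    return {
        "percent_predicted": 100.0 * observed / total_ss,
        "p_value": (exceed + 1) / (n_perm + 1),
        "predicted_ss": observed,
        "total_ss": total_ss,
    }
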