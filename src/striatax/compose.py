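"""Compositional comparison of class abundances between regions.

Per-sample class fractions are mapped to centered log-ratio (CLR)
coordinates, ``CLR_x = log(r_x / g)`` with ``g`` the geometric mean of the
class fractions, and compared across regions with a two-sided Wilcoxon
rank-sum test per class.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .stats import rank_sum_test

logger = logging.getLogger(__name__)

__all__ = ["clr", "composition_per_sample", "region_wilcoxon"]


def clr(fractions: np.ndarray) -> np.ndarray:
    """Centered log-ratio (natural log) of a strictly positive composition.

    The output sums to zero by construction.
    """
    r = np.asarray(fractions, dtype=float)
    if np.any(r <= 0):
        raise ValueError(
            "CLR requires strictly positive fractions; apply the zero-handling "
            "pseudocount upstream"
        )
    log_r = np.log(r)
    return log_r - log_r.mean()


def composition_per_sample(
    labels: pd.DataFrame,
    pseudocount: float = 0.5,
    class_column: str = "class",
) -> pd.DataFrame:
    """Per-sample class fractions, geometric mean and CLR values.

    ``labels`` needs one row per cell with columns ``sample``, ``region`` and
    the class label.  Samples with zero cells are impossible by construction;
    classes absent from a sample are handled by adding ``pseudocount`` to
    every class count of that sample before forming fractions, keeping the
    CLR defined.  Returns a tidy frame with columns sample, region, class,
    count, fraction, geometric_mean, clr.
    """
    required = {"sample", "region", class_column}
    if not required.issubset(labels.columns):
        raise ValueError(f"labels must have columns {sorted(required)}")
    classes = sorted(labels[class_column].unique())
    rows = []
    for (sample, region), grp in labels.groupby(["sample", "region"], sort=True):
        counts = grp[class_column].value_counts().reindex(classes, fill_value=0)
        counts = counts.astype(float)
        if (counts == 0).any():
            counts += pseudocount
        frac = counts / counts.sum()
        values = clr(frac.to_numpy())
        g = float(np.exp(np.log(frac.to_numpy()).mean()))
        for cls, c, f, v in zip(classes, counts, frac, values):
            rows.append((sample, region, cls, c, f, g, v))
    return pd.DataFrame(
        rows,
        columns=["sample", "region", "class", "count", "fraction", "geometric_mean", "clr"],
    )


def region_wilcoxon(
    table: pd.DataFrame,
    cls: str,
    regions: tuple[str, str] = ("CN", "Pu"),
    exact_max: int = 8,
) -> tuple[float, float]:
    """Two-sided rank-sum test on per-sample CLR values between two regions.

    Unpaired by design (donor pairing available upstream by subsetting).
    Exact permutation null when both regions have at most ``exact_max``
    samples, normal approximation with tie correction otherwise.  Returns
    ``(rank_sum_statistic, p)``.
    """
    sub = table[table["class"] == cls]
    groups = []
    for region in regions:
        vals = sub.loc[sub["region"] == region, "clr"].to_numpy()
        if len(vals) < 2:
            raise ValueError(f"region {region!r} has fewer than 2 samples for class {cls!r}")
        groups.append(vals)
    return rank_sum_test(groups[0], groups[1], exact_max=exact_max)
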