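"""Mid-parent heterosis (MPH) statistics for features and biomass.

MPH = 100 x (F1 - A) / A, where F1 is the hybrid group mean and A the
mid-parent mean (average of the two parental group means).  MPH is computed
on group means, is scale-invariant, and is only defined for a positive
mid-parent mean.  Class-level summaries test the MPH distribution of a
metabolite class against zero with a one-sample t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import TriomicsError, DEFAULT_CROSSES


def mph(f1_mean: float, female_mean: float, male_mean: float) -> float:
    """Percent mid-parent heterosis: 100 x (F1 - A) / A with A the parental average."""
    a = (float(female_mean) + float(male_mean)) / 2.0
    if not a > 0:
        raise TriomicsError(f"mid-parent mean must be positive, got {a}")
    return 100.0 * (float(f1_mean) - a) / a


@dataclass
class ClassMPHSummary:
    class_label: str
    n: int
    mean_mph: float
    median_mph: float
    t: float
    p: float
    flag: str          # "" | "n<2" | "zero-variance"

    @property
    def significance(self) -> str:
        if self.p < 0.01:
            return "**"
        if self.p < 0.05:
            return "*"
        return ""


def class_mph_distribution(
    records: pd.DataFrame, classes: Mapping[str, str]
) -> list[ClassMPHSummary]:
    """Per-class MPH summaries with a one-sample t-test against 0.

    ``records`` needs columns ``item`` and ``mph``; ``classes`` maps item id
    to class label (unmapped items fall into "not annotated").  Classes of
    size < 2 are emitted without a test; a zero-variance class reports p = 1
    with a flag rather than claiming significance from constant data.
    """
    labels = [classes.get(i, "not annotated") for i in records["item"]]
    df = pd.DataFrame({"class": labels, "mph": records["mph"].astype(float)})
    out: list[ClassMPHSummary] = []
    for label, grp in df.groupby("class", sort=True):
        v = grp["mph"].to_numpy()
        if v.size < 2:
            out.append(ClassMPHSummary(label, int(v.size), float(v.mean()),
                                       float(np.median(v)), float("nan"), float("nan"), "n<2"))
            continue
        if v.std(ddof=1) == 0:
            out.append(ClassMPHSummary(label, int(v.size), float(v.mean()),
                                       float(np.median(v)), 0.0, 1.0, "zero-variance"))
            continue
        t, p = stats.ttest_1samp(v, 0.0)
        out.append(ClassMPHSummary(label, int(v.size), float(v.mean()),
                                   float(np.median(v)), float(t), float(p), ""))
    return out


def feature_mph(
    norm_means: pd.DataFrame, female: str, hybrid: str, male: str
) -> pd.DataFrame:
    """Per-feature MPH from a feature x group mean table (columns = group names)."""
    F = norm_means[female].to_numpy(dtype=float)
    H = norm_means[hybrid].to_numpy(dtype=float)
    M = norm_means[male].to_numpy(dtype=float)
    a = (F + M) / 2.0
    ok = a > 0
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} features with nonpositive mid-parent mean skipped",
                      stacklevel=2)
    vals = np.full(a.shape, np.nan)
    vals[ok] = 100.0 * (H[ok] - a[ok]) / a[ok]
    return pd.DataFrame({"item": norm_means.index, "mph": vals}).loc[ok].reset_index(drop=True)


def biomass_mph(
    weights: pd.DataFrame,
    crosses: Mapping[str, tuple[str, str]] = DEFAULT_CROSSES,
    traits: Sequence[str] = ("fresh_weight_g", "dry_weight_g"),
) -> pd.DataFrame:
    """MPH of biomass traits per condition x cross from a replicate weight table.

    ``weights`` needs columns genotype, condition, replicate plus the trait
    columns.  Group means are taken per genotype x condition; a missing
    genotype skips that record with a warning.
    """
    for col in ("genotype", "condition", "replicate"):
        if col not in weights.columns:
            raise TriomicsError(f"biomass table missing column {col!r}")
    means = weights.groupby(["genotype", "condition"])[list(traits)].mean()
    rows = []
    for cross, (fem, male) in crosses.items():
        for cond in dict.fromkeys(weights["condition"]):
            for trait in traits:
                try:
                    f1 = means.loc[(cross, cond), trait]
                    fm = means.loc[(fem, cond), trait]
                    mm = means.loc[(male, cond), trait]
                except KeyError as e:
                    warnings.warn(
                        f"missing genotype for {cross}/{cond}/{trait}: {e}; skipped",
                        stacklevel=2,
                    )
                    continue
                rows.append((cross, cond, trait, float(f1), float((fm + mm) / 2),
                             mph(f1, fm, mm)))
    return pd.DataFrame(
        rows, columns=["cross", "condition", "trait", "f1_mean", "midparent_mean", "mph"]
    )
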