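"""Relative quantification (2^-ddCt) and ANOVA + Duncan's multiple range test.

Ct tables carry one row per (sample, gene, biological replicate,
technical replicate).  Technical replicates are averaged to one Ct per
biological replicate before dCt = Ct_target - Ct_reference is formed;
ddCt subtracts the calibrator sample's mean dCt and the fold change is
RQ = 2^-ddCt, so the calibrator's own mean ddCt is zero by construction.

Group differences in RQ are tested with one-way ANOVA, and Duncan's
multiple range test assigns the familiar letter groupings using
studentized-range critical values at the protection level
alpha_p = 1 - (1 - alpha)^(p-1) for a span of p ordered means.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from statistics import harmonic_mean

import numpy as np
import pandas as pd
from scipy.stats import f_oneway, studentized_range


@lru_cache(maxsize=4096)
def _q_crit(prob: float, p: int, df: int) -> float:
    """Memoized studentized-range quantile (scipy's ppf is expensive)."""
    return float(studentized_range.ppf(prob, p, df))

__all__ = [
    "RQResult",
    "DuncanGrouping",
    "read_ct_tsv",
    "relative_expression",
    "anova_duncan",
]

_CT_COLUMNS = ("sample", "gene", "bio_rep", "tech_rep", "ct")


@dataclass(frozen=True)
class RQResult:
    """Per-sample fold change relative to the calibrator sample."""

    sample: str
    gene: str
    rq: tuple[float, ...]  # one value per biological replicate
    mean: float
    sd: float


@dataclass(frozen=True)
class DuncanGrouping:
    """Groups ordered by descending mean with their significance letters."""

    groups: tuple[str, ...]
    means: tuple[float, ...]
    letters: tuple[str, ...]


def read_ct_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    return df


def relative_expression(ct: pd.DataFrame, target: str, reference: str,
                        calibrator_sample: str) -> list[RQResult]:
    """2^-ddCt fold changes per sample, relative to the calibrator.

    Biological replicates missing the reference gene are dropped with a
    warning; a sample losing all replicates is an error, as is a missing
    calibrator.
    """
    sub = ct[ct["gene"].isin([target, reference])]
    mean_ct = (sub.groupby(["sample", "bio_rep", "gene"])["ct"]
               .mean().unstack("gene"))
    if target not in mean_ct.columns:
        raise ValueError(f"no Ct values for target gene {target!r}")
    if reference not in mean_ct.columns:
        raise ValueError(f"no Ct values for reference gene {reference!r}")
    bad = mean_ct[mean_ct[reference].isna() & mean_ct[target].notna()]
    for sample, rep in bad.index:
        warnings.warn(f"dropping {sample} bio_rep {rep}: reference Ct missing")
    mean_ct = mean_ct.dropna(subset=[target, reference])
    if mean_ct.empty:
        raise ValueError("all biological replicates dropped")
    dct = mean_ct[target] - mean_ct[reference]
    if calibrator_sample not in dct.index.get_level_values("sample"):
        raise ValueError(f"calibrator sample {calibrator_sample!r} absent")
    cal_mean = dct.xs(calibrator_sample, level="sample").mean()
    results: list[RQResult] = []
    for sample in mean_ct.index.get_level_values("sample").unique():
        ddct = dct.xs(sample, level="sample") - cal_mean
        rq = np.power(2.0, -ddct.to_numpy())
        results.append(RQResult(
            sample=str(sample), gene=target, rq=tuple(float(x) for x in rq),
            mean=float(rq.mean()),
            sd=float(rq.std(ddof=1)) if len(rq) > 1 else 0.0))
    return results


def _duncan_letters(names: list[str], means: np.ndarray, mse: float,
                    df_error: int, n_per_group: float, alpha: float,
                    ) -> tuple[str, ...]:
    """Letter assignment from the maximal non-significant spans."""
    k = len(names)
    # critical range for a span of p ordered means
    ranges = {p: (0.0 if mse == 0.0 else
                  _q_crit((1 - alpha) ** (p - 1), p, df_error)
                  * math.sqrt(mse / n_per_group))
              for p in range(2, k + 1)}
    # non-significant intervals of the descending mean order
    intervals: list[tuple[int, int]] = []
    for i in range(k):
        j_max = i
        for j in range(i + 1, k):
            if means[i] - means[j] <= ranges[j - i + 1] + 1e-12:
                j_max = j
        intervals.append((i, j_max))
    # keep maximal intervals only (not contained in another)
    maximal = [iv for iv in intervals
               if not any(o != iv and o[0] <= iv[0] and iv[1] <= o[1]
                          for o in intervals)]
    maximal.sort()
    letters = [""] * k
    for letter_idx, (i, j) in enumerate(maximal):
        letter = chr(ord("a") + letter_idx)
        for g in range(i, j + 1):
            letters[g] += letter
    return tuple(letters)


def anova_duncan(groups: dict[str, list[float]], alpha: float = 0.05,
                 ) -> tuple[float, float, DuncanGrouping]:
    """One-way ANOVA F and p plus Duncan letter groupings.

    Requires >= 2 groups with >= 2 values each; unequal group sizes use
    the harmonic-mean n in the critical ranges (with a warning).  Zero
    error variance with unequal means yields all-distinct letters.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    arrays = {name: np.asarray(vals, dtype=float) for name, vals in groups.items()}
    sizes = [len(v) for v in arrays.values()]
    if len(set(sizes)) > 1:
        warnings.warn("unequal group sizes: using harmonic-mean n for Duncan")
        n_per_group = harmonic_mean(sizes)
    else:
        n_per_group = sizes[0]
    N = sum(sizes)
    k = len(arrays)
    df_error = N - k
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in arrays.values())
    mse = ss_within / df_error
    if mse == 0.0:
        # degenerate: identical replicates; F is infinite unless means tie
        means_set = {v.mean() for v in arrays.values()}
        F = math.inf if len(means_set) > 1 else 0.0
        p = 0.0 if len(means_set) > 1 else 1.0
    else:
        F, p = f_oneway(*arrays.values())
        F, p = float(F), float(p)
    order = sorted(arrays, key=lambda g: -arrays[g].mean())
    means = np.array([arrays[g].mean() for g in order])
    letters = _duncan_letters(order, means, mse, max(df_error, 1),
                              n_per_group, alpha)
    grouping = DuncanGrouping(groups=tuple(order),
                              means=tuple(float(m) for m in means),
                              letters=letters)
    return F, p, grouping
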