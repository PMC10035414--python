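"""Relative expression by 2^-ddCt, one-way ANOVA and Duncan's multiple
range test with a compact letter display."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, InputError

CT_COLUMNS = ("gene", "treatment", "bio_rep", "tech_rep", "ct")


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    ms_error: float


def relative_expression_ddct(
    table: pd.DataFrame,
    reference_gene: str,
    calibrator: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Livak 2^-ddCt relative quantification.

    Technical replicates are averaged first; dCt = Ct_target - Ct_reference
    per biological replicate; ddCt subtracts each gene's mean calibrator
    dCt.  Returns (per-replicate values, per-treatment mean +/- SD summary).
    """
    missing_cols = set(CT_COLUMNS) - set(table.columns)
    if missing_cols:
        raise DataError(f"Ct table lacks columns: {sorted(missing_cols)}")
    if not np.isfinite(table["ct"]).all():
        raise DataError("Ct values must be finite")
    tech_avg = (
        table.groupby(["gene", "treatment", "bio_rep"], sort=True)["ct"]
        .mean()
        .reset_index()
    )
    ref = tech_avg[tech_avg["gene"] == reference_gene].set_index(
        ["treatment", "bio_rep"]
    )["ct"]
    targets = tech_avg[tech_avg["gene"] != reference_gene].copy()
    if targets.empty:
        raise DataError("no target genes in Ct table")
    samples = list(zip(targets["treatment"], targets["bio_rep"]))
    absent = sorted({s for s in samples if s not in ref.index})
    if absent:
        raise DataError(
            f"missing reference gene rows for samples: {absent}"
        )
    targets["dct"] = targets["ct"].values - ref.loc[samples].values
    out = []
    for gene, grp in targets.groupby("gene", sort=True):
        cal = grp[grp["treatment"] == calibrator]
        if cal.empty:
            raise DataError(f"gene {gene!r}: no calibrator ({calibrator!r}) rows")
        base = cal["dct"].mean()
        g = grp.copy()
        g["ddct"] = g["dct"] - base
        g["rel_expr"] = np.power(2.0, -g["ddct"])
        out.append(g)
    detail = pd.concat(out, ignore_index=True)[
        ["gene", "treatment", "bio_rep", "dct", "ddct", "rel_expr"]
    ]
    summary = (
        detail.groupby(["gene", "treatment"], sort=True)["rel_expr"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_rel_expr", "std": "sd_rel_expr", "count": "n"})
    )
    return detail, summary


def anova_oneway(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Standard between/within decomposition with an F-distribution p-value."""
    if len(groups) < 2:
        raise InputError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(len(a) < 2 for a in arrays.values()):
        raise InputError("each group needs at least 2 values")
    all_values = np.concatenate(list(arrays.values()))
    grand = all_values.mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays.values())
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_b = len(arrays) - 1
    df_w = len(all_values) - len(arrays)
    msb = ssb / df_b
    mse = ssw / df_w
    if mse == 0.0:
        if ssb > 0:
            return AnovaResult(np.inf, df_b, df_w, 0.0, 0.0)
        return AnovaResult(0.0, df_b, df_w, 1.0, 0.0)
    f = msb / mse
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), df_b, df_w, p, float(mse))


@lru_cache(maxsize=4096)
def _studentized_range_quantile(level: float, p: int, df: int) -> float:
    return float(stats.studentized_range.ppf(level, p, df))


def duncan_critical_range(p: int, df: int, mse: float, n: float, alpha: float) -> float:
    """Duncan's critical range for a span of p ordered means.

    Uses the studentized-range quantile at protection level
    (1 - alpha)^(p - 1).
    """
    q = _studentized_range_quantile((1.0 - alpha) ** (p - 1), p, df)
    return float(q * np.sqrt(mse / n))


def _maximal_homogeneous_spans(means_sorted, ranges):
    """Indices (i, j) of maximal spans whose range does not exceed the
    Duncan critical range for their width."""
    m = len(means_sorted)
    acceptable = []
    for i in range(m):
        for j in range(i + 1, m):
            span = means_sorted[i] - means_sorted[j]
            if span <= ranges[j - i + 1] + 1e-12:
                acceptable.append((i, j))
    maximal = [
        (i, j)
        for (i, j) in acceptable
        if not any((a <= i and j <= b and (a, b) != (i, j)) for a, b in acceptable)
    ]
    return maximal


def duncan_letters(
    means: Mapping[str, float],
    n: int | Mapping[str, int],
    mse: float,
    df: int,
    alpha: float = 0.05,
) -> dict[str, str]:
    """Compact letter display for Duncan's multiple range test.

    Treatments sharing a letter are not significantly different; the
    highest mean receives 'a'.  Unequal group sizes are handled via the
    harmonic mean (with a warning).
    """
    if df < 1:
        raise InputError("df must be >= 1")
    if mse < 0:
        raise InputError("MSE must be >= 0")
    if isinstance(n, Mapping):
        sizes = [n[t] for t in means]
        if len(set(sizes)) > 1:
            warnings.warn("unequal group sizes: using the harmonic mean")
        n_h = len(sizes) / sum(1.0 / s for s in sizes)
    else:
        n_h = float(n)
    order = sorted(means, key=lambda t: (-means[t], t))
    values = [means[t] for t in order]
    m = len(order)
    ranges = {p: duncan_critical_range(p, df, mse, n_h, alpha) for p in range(2, m + 1)}
    spans = _maximal_homogeneous_spans(values, ranges)
    # singletons not inside any homogeneous span get their own letter
    covered = set()
    for i, j in spans:
        covered.update(range(i, j + 1))
    for i in range(m):
        if i not in covered:
            spans.append((i, i))
    spans.sort()
    letters = {t: "" for t in order}
    for letter_idx, (i, j) in enumerate(spans):
        letter = chr(ord("a") + letter_idx)
        for k in range(i, j + 1):
            letters[order[k]] += letter
    return letters
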