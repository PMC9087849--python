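"""Evaluation of predicted counts and genotype yield statistics.

Per-plot predictions are regressed on ground truth (ordinary least squares);
accuracy is summarized with R-squared, NRMSE (RMSE normalized by the range of
the ground-truth counts), and MAPE.  Per-genotype means are compared with a
one-way ANOVA and Fisher's LSD letter grouping at alpha = 0.05, the standard
presentation of agricultural trial results.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import GroundTruthRecord, ValidationError


@dataclass
class RegressionReport:
    """OLS fit of predicted counts on ground truth plus Eq-style error metrics.

    ``nrmse`` is RMSE of (truth - predicted) divided by (max - min) of truth;
    ``mape_pct`` is the mean absolute percentage error.  Residuals are OLS
    residuals (predicted minus fitted line); plots whose residual lies more
    than 3 standard deviations from the mean residual are flagged as
    outliers but kept in the reported fit.
    """

    n: int
    slope: float
    intercept: float
    r_squared: float
    nrmse: float
    mape_pct: float
    mean_gt: float
    plot_ids: list[str]
    residuals: np.ndarray
    outlier_ids: list[str]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        blob = {
            "n": self.n,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "nrmse": self.nrmse,
            "mape_pct": self.mape_pct,
            "mean_gt": self.mean_gt,
            "outlier_ids": self.outlier_ids,
        }
        path.write_text(json.dumps(blob, indent=2))
        return path


def regress_counts(
    predicted: Mapping[str, float],
    truth: Sequence[GroundTruthRecord],
    refit_without_outliers: bool = False,
) -> RegressionReport:
    """Regress predicted per-plot counts against ground truth.

    ``predicted`` maps plot_id to the pipeline's boll count.  Every ground
    truth plot must have a prediction.  With ``refit_without_outliers`` the
    OLS fit and R-squared are recomputed after dropping flagged plots
    (error metrics still cover all plots).
    """
    ids = [r.plot_id for r in truth]
    missing = [pid for pid in ids if pid not in predicted]
    if missing:
        raise ValidationError(f"no prediction for plot_id(s): {missing}")
    if len(ids) < 3:
        raise ValidationError("need at least 3 plots for regression")
    y = np.array([float(r.boll_count) for r in truth])
    yhat = np.array([float(predicted[pid]) for pid in ids])

    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    y_range = float(y.max() - y.min())
    nrmse = rmse / y_range if y_range > 0 else float("nan")
    mape = (
        float(np.mean(np.abs((y - yhat) / y)) * 100.0)
        if np.all(y > 0)
        else float("nan")
    )

    if y_range == 0:
        # degenerate design: slope undefined; residuals about the mean
        class _Flat:
            slope = float("nan")
            intercept = float("nan")
            rvalue = float("nan")

        fit = _Flat()
        residuals = yhat - yhat.mean()
    else:
        fit = stats.linregress(y, yhat)
        residuals = yhat - (fit.intercept + fit.slope * y)
    sd = residuals.std(ddof=1) if len(residuals) > 1 else 0.0
    centered = np.abs(residuals - residuals.mean())
    outliers = [pid for pid, c in zip(ids, centered) if sd > 0 and c > 3 * sd]

    if refit_without_outliers and outliers:
        keep = [i for i, pid in enumerate(ids) if pid not in outliers]
        fit = stats.linregress(y[keep], yhat[keep])
        residuals = yhat - (fit.intercept + fit.slope * y)

    return RegressionReport(
        n=len(ids),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        nrmse=nrmse,
        mape_pct=mape,
        mean_gt=float(y.mean()),
        plot_ids=ids,
        residuals=residuals,
        outlier_ids=outliers,
    )


def anova_oneway(
    groups: Mapping[str, Sequence[float]],
) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA: returns (F, df_between, df_within, p).

    All values identical across the board yields F = 0, p = 1 by convention.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValidationError("ANOVA needs at least 2 groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if any(a.size == 0 for a in arrays):
        raise ValidationError("every group needs at least 1 value")
    n_total = sum(a.size for a in arrays)
    k = len(arrays)
    if n_total <= k:
        raise ValidationError("total n must exceed the number of groups")
    grand = np.concatenate(arrays).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n_total - k
    if ssw == 0:
        if ssb == 0:
            return 0.0, df_b, df_w, 1.0
        return float("inf"), df_b, df_w, 0.0
    F = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return float(F), df_b, df_w, p


def _pairwise_nonsignificant(
    means: Sequence[float],
    ns: Sequence[int],
    msw: float,
    df_w: int,
    alpha: float,
) -> np.ndarray:
    """Boolean matrix: True where a pair is NOT significantly different."""
    t_crit = stats.t.ppf(1 - alpha / 2, df_w)
    k = len(means)
    ns_mat = np.ones((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            lsd = t_crit * math.sqrt(msw * (1.0 / ns[i] + 1.0 / ns[j]))
            same = abs(means[i] - means[j]) <= lsd
            ns_mat[i, j] = ns_mat[j, i] = same
    return ns_mat


def lsd_letters(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> dict[str, str]:
    """Fisher's LSD letter grouping.

    Pairwise t-tests use the pooled ANOVA error mean square and its degrees
    of freedom: LSD(i,j) = t(1-alpha/2, df_w) * sqrt(MSW * (1/n_i + 1/n_j)).
    Means are sorted descending and maximal runs of mutually non-different
    groups become letters 'a', 'b', ...; groups sharing any letter are not
    significantly different at ``alpha``.
    """
    names = list(groups)
    if len(names) == 1:
        return {names[0]: "a"}
    _F, _dfb, df_w, _p = anova_oneway(groups)
    arrays = {g: np.asarray(groups[g], dtype=float) for g in names}
    msw = sum(((a - a.mean()) ** 2).sum() for a in arrays.values()) / df_w
    order = sorted(names, key=lambda g: -arrays[g].mean())
    means = [arrays[g].mean() for g in order]
    ns = [arrays[g].size for g in order]
    nonsig = _pairwise_nonsignificant(means, ns, msw, df_w, alpha)

    k = len(order)
    runs: list[tuple[int, int]] = []  # inclusive index ranges on sorted means
    for i in range(k):
        j = i
        while j + 1 < k and nonsig[i : j + 2, i : j + 2].all():
            j += 1
        runs.append((i, j))
    # drop runs contained in an earlier maximal run
    maximal = [r for r in runs if not any(o != r and o[0] <= r[0] and r[1] <= o[1] for o in runs)]
    letters: dict[str, str] = {g: "" for g in order}
    for letter_idx, (lo, hi) in enumerate(sorted(set(maximal))):
        ch = chr(ord("a") + letter_idx)
        for g in order[lo : hi + 1]:
            letters[g] += ch
    return letters


@dataclass
class GenotypeSummary:
    """Per-genotype yield summary with ANOVA and LSD letters."""

    table: pd.DataFrame  # genotype, sample_size, mean, se, letters
    anova_F: float
    df_between: int
    df_within: int
    p_value: float
    alpha: float

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path


def genotype_summary(
    counts: Mapping[str, float],
    truth: Sequence[GroundTruthRecord],
    alpha: float = 0.05,
) -> GenotypeSummary:
    """Summarize predicted counts by genotype: n, mean, SE, ANOVA, LSD letters.

    Genotypes with a single plot get an undefined (NaN) SE and are excluded
    from the LSD letter assignment.
    """
    groups: dict[str, list[float]] = {}
    for rec in truth:
        if rec.plot_id not in counts:
            raise ValidationError(f"no predicted count for plot {rec.plot_id}")
        groups.setdefault(rec.genotype, []).append(float(counts[rec.plot_id]))
    F, df_b, df_w, p = anova_oneway(groups)
    multi = {g: v for g, v in groups.items() if len(v) > 1}
    letters = lsd_letters(multi, alpha=alpha) if len(multi) > 1 else {
        g: "a" for g in multi
    }
    rows = []
    for g, vals in groups.items():
        arr = np.asarray(vals)
        se = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else float("nan")
        rows.append(
            {
                "genotype": g,
                "sample_size": arr.size,
                "mean": float(arr.mean()),
                "se": se,
                "letters": letters.get(g, ""),
            }
        )
    table = pd.DataFrame(rows).sort_values("mean", ascending=False, ignore_index=True)
    return GenotypeSummary(
        table=table, anova_F=F, df_between=df_b, df_within=df_w, p_value=p, alpha=alpha
    )
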