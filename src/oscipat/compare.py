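"""Two-group comparison of band summaries (Mann-Whitney U).

Subject-level band summaries (one value per subject per channel x band
cell, avoiding pseudo-replication of epochs) are compared between two
groups with the two-sided Mann-Whitney U test.  The exact null
distribution is used for combined samples up to 30 without ties; a normal
approximation with tie and continuity corrections otherwise.  Cells with
p <= alpha (default 0.001) are flagged significant; no multiple-testing
adjustment is applied by default (a Benjamini-Hochberg option exists).

Percent difference is reported relative to group A (the reference/healthy
group): 100 * (mean_A - mean_B) / mean_A, so a positive value is a
reduction in group B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm as _norm

__all__ = [
    "MannWhitneyResult",
    "mann_whitney",
    "GroupComparison",
    "compare_groups",
    "plot_band_boxes",
]


class MannWhitneyResult(NamedTuple):
    U: float
    p_value: float
    method: str


@lru_cache(maxsize=256)
def _exact_u_cdf(n: int, m: int) -> np.ndarray:
    """CDF of the null Mann-Whitney U distribution for group sizes (n, m).

    Counts via the recurrence  c(n, m, u) = c(n-1, m, u-m) + c(n, m-1, u)
    (number of rank arrangements with statistic u); exact in float64 for
    n + m <= 30.
    """
    nm = n * m
    # c[a][b] -> array over u of arrangement counts
    prev = [np.zeros(nm + 1) for _ in range(m + 1)]
    for b in range(m + 1):
        prev[b][0] = 1.0  # a = 0
    for a in range(1, n + 1):
        cur = [np.zeros(nm + 1) for _ in range(m + 1)]
        cur[0][0] = 1.0
        for b in range(1, m + 1):
            cur[b][b:] += prev[b][: nm + 1 - b]
            cur[b] += cur[b - 1]
        prev = cur
    pmf = prev[m] / prev[m].sum()
    return np.cumsum(pmf)


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float]
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Returns the U statistic of group A (number of (a, b) pairs with
    a > b, counting ties as 1/2) and the two-sided p value:
    ``2 * min(P(U <= u), P(U >= u))`` capped at 1 under the exact null
    (combined n <= 30, no ties), or the tie-corrected,
    continuity-corrected normal approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values in input")
    n, m = a.size, b.size
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both groups; p = 1",
                      RuntimeWarning, stacklevel=2)
        return MannWhitneyResult(U=n * m / 2.0, p_value=1.0,
                                 method="degenerate")

    # midranks
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(pooled.size)
    sv = pooled[order]
    i = 0
    tie_sizes = []
    while i < sv.size:
        j = i
        while j + 1 < sv.size and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i: j + 1]] = 0.5 * (i + j) + 1.0
        tie_sizes.append(j - i + 1)
        i = j + 1
    r_a = ranks[:n].sum()
    u = r_a - n * (n + 1) / 2.0
    has_ties = any(t > 1 for t in tie_sizes)

    if not has_ties and n + m <= 30:
        cdf = _exact_u_cdf(n, m)
        ui = int(round(u))
        p_le = cdf[ui]
        p_ge = 1.0 - (cdf[ui - 1] if ui > 0 else 0.0)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return MannWhitneyResult(U=float(u), p_value=float(p), method="exact")

    nn = n + m
    mu = n * m / 2.0
    tie_term = sum(t ** 3 - t for t in tie_sizes) / (nn * (nn - 1.0))
    var = n * m / 12.0 * (nn + 1.0 - tie_term)
    if var <= 0:
        return MannWhitneyResult(U=float(u), p_value=1.0, method="asymptotic")
    z = (abs(u - mu) - 0.5) / np.sqrt(var)
    p = min(1.0, 2.0 * _norm.sf(z))
    return MannWhitneyResult(U=float(u), p_value=float(p),
                             method="asymptotic")


# ---------------------------------------------------------------------------
# Grid comparison
# ---------------------------------------------------------------------------

def _describe(x: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    return {
        "mean": float(np.mean(x)),
        "median": float(med),
        "sd": float(np.std(x, ddof=1)) if x.size > 1 else np.nan,
        "q1": float(q1),
        "q3": float(q3),
        "whisker_lo": float(inside.min()) if inside.size else float(np.min(x)),
        "whisker_hi": float(inside.max()) if inside.size else float(np.max(x)),
        "n_outliers": int(((x < lo_fence) | (x > hi_fence)).sum()),
        "n": int(x.size),
    }


@dataclass
class GroupComparison:
    """Result of a two-group band comparison.

    ``table`` holds one row per channel x band x metric with group
    descriptive statistics, the U statistic, p value, percent difference
    (relative to group A) and the significance flag.
    """

    table: pd.DataFrame
    alpha: float
    adjust: Optional[str] = None

    def flagged(self, metric: str = "N") -> set:
        """Set of (channel, band) cells flagged significant for a metric."""
        t = self.table
        sel = t[(t["metric"] == metric) & t["significant"]]
        return set(zip(sel["channel"], sel["band"]))

    def flagged_bands(self, metric: str = "N") -> set:
        """Bands flagged significant in at least one channel."""
        return {band for (_, band) in self.flagged(metric)}

    def summary(self, metric: Optional[str] = None) -> str:
        t = self.table if metric is None else self.table[
            self.table["metric"] == metric
        ]
        lines = [
            f"Two-group band comparison (Mann-Whitney, alpha={self.alpha})",
            f"{'chan':<5}{'band':>4}{'metric':>8}{'mean_A':>10}"
            f"{'mean_B':>10}{'diff_%':>8}{'U':>7}{'p':>11}  sig",
        ]
        for _, r in t.iterrows():
            lines.append(
                f"{r['channel']:<5}{r['band']:>4}{r['metric']:>8}"
                f"{r['mean_a']:>10.4g}{r['mean_b']:>10.4g}"
                f"{r['percent_difference']:>8.1f}{r['U']:>7.1f}"
                f"{r['p_value']:>11.3e}  {'*' if r['significant'] else ''}"
            )
        return "\n".join(lines)


def compare_groups(
    summaries_a: pd.DataFrame,
    summaries_b: pd.DataFrame,
    alpha: float = 0.001,
    metrics: Tuple[str, ...] = ("N", "T_mean"),
    adjust: Optional[str] = None,
) -> GroupComparison:
    """Compare two groups of subject band summaries per channel x band.

    Inputs are long tables (from :func:`oscipat.bands.summarize_subject`,
    concatenated over subjects) and must cover the same channel x band
    grid.  For duration metrics, subjects with no patterns in a cell
    (missing duration) are dropped from that cell's test.

    ``adjust="bh"`` applies Benjamini-Hochberg across all cells of each
    metric and flags on the adjusted p values (off by default).
    """
    grid_a = set(zip(summaries_a["channel"], summaries_a["band"]))
    grid_b = set(zip(summaries_b["channel"], summaries_b["band"]))
    if grid_a != grid_b:
        missing = sorted(grid_a.symmetric_difference(grid_b))
        raise ValueError(f"mismatched channel x band grids; unmatched cells: "
                         f"{missing[:20]}")

    rows = []
    cells = sorted(grid_a)
    ga = summaries_a.groupby(["channel", "band"])
    gb = summaries_b.groupby(["channel", "band"])
    for (channel, band) in cells:
        sub_a = ga.get_group((channel, band))
        sub_b = gb.get_group((channel, band))
        for metric in metrics:
            va = sub_a[metric].to_numpy(dtype=float)
            vb = sub_b[metric].to_numpy(dtype=float)
            va = va[np.isfinite(va)]
            vb = vb[np.isfinite(vb)]
            row = {"channel": channel, "band": band, "metric": metric}
            if va.size >= 2 and vb.size >= 2:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    res = mann_whitney(va, vb)
                row.update(U=res.U, p_value=res.p_value, method=res.method)
            else:
                row.update(U=np.nan, p_value=np.nan, method="insufficient")
            for key, val in (("a", va), ("b", vb)):
                if val.size:
                    for stat, v in _describe(val).items():
                        row[f"{stat}_{key}"] = v
                else:
                    for stat in ("mean", "median", "sd", "q1", "q3",
                                 "whisker_lo", "whisker_hi", "n_outliers",
                                 "n"):
                        row[f"{stat}_{key}"] = np.nan
            ma = row["mean_a"]
            mb = row["mean_b"]
            row["percent_difference"] = (
                100.0 * (ma - mb) / ma if (np.isfinite(ma) and ma != 0)
                else np.nan
            )
            rows.append(row)
    table = pd.DataFrame(rows)

    if adjust is None:
        pcol = table["p_value"]
    elif adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        padj = np.full(len(table), np.nan)
        for metric in metrics:
            sel = (table["metric"] == metric) & np.isfinite(table["p_value"])
            if sel.any():
                padj[sel.to_numpy()] = multipletests(
                    table.loc[sel, "p_value"], method="fdr_bh"
                )[1]
        table["p_adjusted"] = padj
        pcol = table["p_adjusted"]
    else:
        raise ValueError("adjust must be None or 'bh'")
    table["significant"] = np.isfinite(pcol) & (pcol <= alpha)
    return GroupComparison(table=table, alpha=alpha, adjust=adjust)


# ---------------------------------------------------------------------------
# Plotting
# ---------------------------------------------------------------------------

def plot_band_boxes(
    group_tables: List[pd.DataFrame],
    group_labels: List[str],
    channel: str,
    metric: str = "N",
    significant_bands: Optional[set] = None,
    ax=None,
):
    """Box plots per band mirroring the study's conventions: quartile box,
    median line, mean point, 1.5 IQR whiskers, asterisk outliers;
    significant bands shaded."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(12, 4))
    n_groups = len(group_tables)
    width = 0.8 / n_groups
    colors = plt.cm.tab10(np.linspace(0, 1, max(n_groups, 3)))
    bands = sorted(group_tables[0]["band"].unique())
    for gi, (tab, lab) in enumerate(zip(group_tables, group_labels)):
        data, positions = [], []
        for band in bands:
            vals = tab[(tab["channel"] == channel) & (tab["band"] == band)][
                metric
            ].dropna()
            if len(vals):
                data.append(vals.to_numpy())
                positions.append(band + (gi - (n_groups - 1) / 2) * width)
        bp = ax.boxplot(
            data, positions=positions, widths=width * 0.9, whis=1.5,
            showmeans=True, sym="*", patch_artist=True,
            meanprops={"marker": "o", "markersize": 3},
        )
        for patch in bp["boxes"]:
            patch.set_facecolor(colors[gi])
            patch.set_alpha(0.5)
            patch.set_label(None)
        bp["boxes"][0].set_label(lab)
    if significant_bands:
        for band in significant_bands:
            ax.axvspan(band - 0.5, band + 0.5, color="0.85", zorder=0)
    ax.set_xticks(bands)
    ax.set_xticklabels([f"Df{b}" for b in bands], rotation=45)
    ax.set_xlabel("frequency band")
    ax.set_ylabel(metric)
    ax.set_title(f"channel {channel}")
    ax.legend(loc="upper right")
    return ax
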