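"""Multiplicity control and plot tables: q-values, QQ bands, Manhattan data.

q-values follow the Storey-Tibshirani recipe: the null proportion pi0 is
estimated from the flat right tail of the p-value histogram via a lambda
grid and a cubic smoother, and the q-value of the i-th smallest p is the
step-down minimum of ``pi0 * m * p_(j) / j`` over ``j >= i``. A q-value of
0.1 means calling that test (and everything more significant) positive
yields an expected false discovery rate of 10%. With pi0 = 1 the procedure
reduces exactly to Benjamini-Hochberg adjusted p-values.

QQ bands are pointwise: the i-th smallest of m uniform p-values follows a
Beta(i, m - i + 1) distribution, whose 2.5%/97.5% quantiles bound the
expected spread of the observed order statistics under the global null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.951, 0.05), 2)
MIN_M_FOR_PI0 = 100


@dataclass
class QValueResult:
    qvalues: np.ndarray          # original input order
    pi0: float
    lambda_grid: np.ndarray
    pi0_lambda: np.ndarray       # raw pi0 estimates along the grid (may be empty)


def storey_qvalues(p, lambda_grid=None) -> QValueResult:
    """q-values with a smoothed pi0 estimate.

    For short vectors (m < 100) the lambda smoother is unreliable, so pi0 is
    forced to 1 (a logged warning), which makes the result identical to
    Benjamini-Hochberg.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("p must be a non-empty 1-d vector")
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, float)

    if m < MIN_M_FOR_PI0:
        logger.warning("m=%d < %d: pi0 smoother unreliable, forcing pi0=1 "
                       "(Benjamini-Hochberg)", m, MIN_M_FOR_PI0)
        pi0, raw = 1.0, np.empty(0)
    else:
        raw = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in grid])
        # cubic least-squares smoother evaluated at the right end of the grid
        coef = np.polyfit(grid, raw, deg=3)
        pi0 = float(np.polyval(coef, grid.max()))
        pi0 = min(max(pi0, 1.0 / m), 1.0)  # clamp to (0, 1]

    order = np.argsort(p, kind="mergesort")
    ps = p[order]
    ranks = np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate((pi0 * m * ps / ranks)[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return QValueResult(qvalues=q, pi0=pi0, lambda_grid=grid, pi0_lambda=raw)


def qq_points(p, band: float = 0.95) -> pd.DataFrame:
    """Observed vs expected -log10 p with a pointwise confidence band.

    Row i (ascending p) has expected quantile ``-log10(i / (m + 1))`` and
    band endpoints from the Beta(i, m - i + 1) distribution of the i-th
    uniform order statistic. ``band_lo <= band_hi`` on the -log10 scale.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    i = np.arange(1, m + 1)
    alpha = (1.0 - band) / 2.0
    lo_p = beta.ppf(alpha, i, m - i + 1)        # small p quantile
    hi_p = beta.ppf(1 - alpha, i, m - i + 1)    # large p quantile
    return pd.DataFrame({
        "expected": -np.log10(i / (m + 1)),
        "observed": -np.log10(np.sort(p)),
        "band_lo": -np.log10(hi_p),
        "band_hi": -np.log10(lo_p),
    })


def manhattan_table(scan: pd.DataFrame, highlight_p: float = 1e-6) -> pd.DataFrame:
    """Plot-ready Manhattan table from a scan: cumulative x-coordinate,
    -log10 p, and a highlight flag for p below ``highlight_p``."""
    cols = ["chrom", "pos", "neglog10_p", "x", "highlight"]
    if len(scan) == 0:
        return pd.DataFrame(columns=cols)
    df = scan[["chrom", "pos", "p"]].copy()
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    offset, offsets = 0, {}
    for chrom, grp in df.groupby("chrom", sort=True):
        offsets[chrom] = offset - int(grp["pos"].min()) + 1
        offset = offsets[chrom] + int(grp["pos"].max()) + 1
    df["x"] = df["pos"] + df["chrom"].map(offsets)
    df["neglog10_p"] = -np.log10(df["p"])
    df["highlight"] = df["p"] < highlight_p
    return df[cols]


def render_qq(qq: pd.DataFrame, path) -> None:
    """Optional PNG rendering of a QQ table (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.fill_between(qq["expected"], qq["band_lo"], qq["band_hi"],
                    color="0.85", label="95% band")
    lim = max(qq["expected"].max(), qq["observed"].max()) * 1.05
    ax.plot([0, lim], [0, lim], color="0.4", lw=1)
    ax.plot(qq["expected"], qq["observed"], "o", ms=3, color="C0")
    ax.set_xlabel(r"expected $-\log_{10} p$")
    ax.set_ylabel(r"observed $-\log_{10} p$")
    ax.legend(frameon=False)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def render_manhattan(mh: pd.DataFrame, path) -> None:
    """Optional PNG rendering of a Manhattan table (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3.5))
    for chrom, grp in mh.groupby("chrom"):
        ax.plot(grp["x"], grp["neglog10_p"], ".", ms=3,
                color="C0" if chrom % 2 else "C7")
    hl = mh[mh["highlight"]]
    if len(hl):
        ax.plot(hl["x"], hl["neglog10_p"], "o", ms=4, color="blue")
    ax.set_xlabel("genomic position")
    ax.set_ylabel(r"$-\log_{10} p$")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
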