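"""Gene-environment interaction: exposure-stratified fits and the Wald RRR test.

A gene-environment effect is present when the child relative risk of a
haplotype differs between offspring of exposed and unexposed mothers. It is
measured by the relative risk ratio ``RRR = RR(exposed) / RR(unexposed)``
and tested on the log scale with a Wald statistic whose variance is the sum
of the two independent stratum variances::

    z = (log rr1 - log rr0) / sqrt(se1^2 + se0^2)

Strata are fitted independently (their haplotype frequencies may genuinely
differ under ascertainment), but the reference haplotype is fixed from the
pooled fit so the stratum RRs are comparable. Families with unknown exposure
contribute to the pooled (child-effect) fit only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .ped_io import EXPOSED, UNEXPOSED, UNKNOWN, ExposureTable, GenotypeDataset
from .triad_model import (
    ModelOptions,
    TriadFit,
    Window,
    fit_patterns,
    resolve_window,
    window_pattern_counts,
)

logger = logging.getLogger(__name__)

Z95 = float(norm.ppf(0.975))


class EmptyStratumError(ValueError):
    """An exposure stratum has no informative families."""


class ResultSuppressed(ValueError):
    """The RRR is not estimable for this haplotype (rare/absent in a stratum)."""


@dataclass
class GxEResult:
    """RRR with CI and Wald p for one haplotype at one window."""

    window: str
    haplotype: str
    rr_exposed: float
    rr_exposed_ci: tuple[float, float]
    rr_unexposed: float
    rr_unexposed_ci: tuple[float, float]
    rrr: float
    rrr_ci: tuple[float, float]
    p_value: float
    freq_exposed: float
    freq_unexposed: float
    n_exposed: int
    n_unexposed: int


# ---------------------------------------------------------------------------


def sliding_windows(markers: pd.DataFrame, k: int) -> list[Window]:
    """All runs of k consecutive markers on one chromosome, stepping by 1."""
    if k < 1:
        raise ValueError("window size must be >= 1")
    wins: list[Window] = []
    for chrom, grp in markers.groupby("chrom", sort=False):
        snps = list(grp["snp"])
        for i in range(len(snps) - k + 1):
            wins.append(Window(snps=tuple(snps[i:i + k]), chrom=int(chrom)))
    if not wins:
        logger.warning("window size %d exceeds every chromosome's marker count", k)
    return wins


def fit_strata(
    ds: GenotypeDataset,
    exposure: ExposureTable,
    window,
    options: ModelOptions | None = None,
    exposure_name: str | None = None,
) -> tuple[TriadFit, TriadFit, TriadFit]:
    """Fit the window in the exposed stratum, the unexposed stratum, and the
    full sample (returned in that order).

    Unknown-exposure families enter only the pooled fit. The pooled fit's
    reference haplotype is imposed on both stratum fits.
    """
    options = options or ModelOptions()
    if exposure_name is None:
        if len(exposure.exposures) != 1:
            raise ValueError("exposure_name required when the table has several exposures")
        exposure_name = exposure.exposures[0]
    win, idx = resolve_window(ds, window)
    status = exposure.strata(ds, exposure_name)

    fit_all = fit_patterns(window_pattern_counts(ds, idx), win, options)
    stratum_options = replace(options, reference=fit_all.reference)

    fits = {}
    for label in (EXPOSED, UNEXPOSED):
        mask = status == label
        if not mask.any():
            raise EmptyStratumError(f"empty stratum {label!r} for {exposure_name!r}")
        pats = window_pattern_counts(ds, idx, family_mask=mask)
        try:
            fits[label] = fit_patterns(pats, win, stratum_options)
        except ValueError as e:
            # informative families exist for the exposure but not at this
            # window: a window-level condition, so the scan can skip it
            raise ValueError(
                f"stratum {label!r} uninformative at {win.label}: {e}"
            ) from e
    return fits[EXPOSED], fits[UNEXPOSED], fit_all


def rrr_wald(fit1: TriadFit, fit0: TriadFit, haplotype: int) -> GxEResult:
    """Wald test of RRR = RR(exposed)/RR(unexposed) for one haplotype.

    ``fit1`` is the exposed-stratum fit, ``fit0`` the unexposed one. Raises
    :class:`ResultSuppressed` when the haplotype has no free RR (rare or
    absent) or no usable standard error in either stratum.
    """
    for f, name in ((fit1, "exposed"), (fit0, "unexposed")):
        if haplotype not in f.estimated_haps:
            raise ResultSuppressed(
                f"haplotype {haplotype} not estimated in {name} stratum "
                f"(rare, absent, or reference)"
            )
    rr1, se1 = fit1.rr_of(haplotype), fit1.se_of(haplotype)
    rr0, se0 = fit0.rr_of(haplotype), fit0.se_of(haplotype)
    if not (np.isfinite(se1) and np.isfinite(se0) and se1 > 0 and se0 > 0):
        raise ResultSuppressed(f"haplotype {haplotype}: unusable standard error")
    log_rrr = np.log(rr1) - np.log(rr0)
    se = float(np.hypot(se1, se0))
    z = log_rrr / se
    p = float(2 * norm.sf(abs(z)))
    p = max(p, np.finfo(float).tiny)
    return GxEResult(
        window=fit1.window.label,
        haplotype=str(haplotype),
        rr_exposed=rr1, rr_exposed_ci=fit1.rr_ci(haplotype),
        rr_unexposed=rr0, rr_unexposed_ci=fit0.rr_ci(haplotype),
        rrr=float(np.exp(log_rrr)),
        rrr_ci=(float(np.exp(log_rrr - Z95 * se)), float(np.exp(log_rrr + Z95 * se))),
        p_value=p,
        freq_exposed=fit1.freq_of(haplotype),
        freq_unexposed=fit0.freq_of(haplotype),
        n_exposed=fit1.n_families,
        n_unexposed=fit0.n_families,
    )


def _hap_string(ds: GenotypeDataset, win: Window, hap: int) -> str:
    """Human-readable allele string of a haplotype code, e.g. ``2-1-2``."""
    snp_to_idx = {s: i for i, s in enumerate(ds.markers["snp"])}
    parts = []
    for j, s in enumerate(win.snps):
        a1, a2 = ds.alleles[snp_to_idx[s]]
        bit = (hap >> j) & 1
        lab = (a2 if bit else a1)
        parts.append(lab if lab is not None else str(bit))
    return "-".join(parts)


def scan(
    ds: GenotypeDataset,
    exposure: ExposureTable,
    windows: list[Window] | int,
    options: ModelOptions | None = None,
    exposure_name: str | None = None,
) -> pd.DataFrame:
    """GxE scan over windows; one row per (window, non-reference haplotype).

    ``windows`` may be a prepared list or a window size k (sliding windows
    are then generated). Returns a DataFrame with columns chrom, pos, window,
    snps, haplotype, freq_all, freq_unexp, freq_exp, rr_all, rr_unexp,
    rr_exp, rrr, rrr_lo, rrr_hi, p, q, top — sorted by p, the ``top`` flag
    marking each window's lowest-p haplotype; ``q`` is left NaN for the
    multiplicity stage to fill. Deterministic given dataset and options.
    """
    options = options or ModelOptions()
    if isinstance(windows, int):
        windows = sliding_windows(ds.markers, windows)
    pos_of = dict(zip(ds.markers["snp"], ds.markers["pos"]))

    rows = []
    for win in windows:
        try:
            f1, f0, fall = fit_strata(ds, exposure, win, options, exposure_name)
        except EmptyStratumError as e:
            raise
        except ValueError as e:
            logger.warning("window %s skipped: %s", win.label, e)
            continue
        for hap in fall.estimated_haps:
            try:
                res = rrr_wald(f1, f0, hap)
            except ResultSuppressed as e:
                logger.info("window %s: %s", win.label, e)
                continue
            rows.append({
                "chrom": win.chrom,
                "pos": int(pos_of[win.snps[0]]),
                "window": win.label,
                "snps": ",".join(win.snps),
                "haplotype": _hap_string(ds, win, hap),
                "freq_all": fall.freq_of(hap),
                "freq_unexp": res.freq_unexposed,
                "freq_exp": res.freq_exposed,
                "rr_all": fall.rr_of(hap),
                "rr_unexp": res.rr_unexposed,
                "rr_exp": res.rr_exposed,
                "rrr": res.rrr,
                "rrr_lo": res.rrr_ci[0],
                "rrr_hi": res.rrr_ci[1],
                "p": res.p_value,
                "q": np.nan,
            })
    table = pd.DataFrame(rows, columns=[
        "chrom", "pos", "window", "snps", "haplotype", "freq_all", "freq_unexp",
        "freq_exp", "rr_all", "rr_unexp", "rr_exp", "rrr", "rrr_lo", "rrr_hi",
        "p", "q",
    ])
    if len(table):
        table["top"] = table.groupby("window")["p"].transform("min") == table["p"]
        table = table.sort_values("p", kind="mergesort").reset_index(drop=True)
    else:
        table["top"] = pd.Series(dtype=bool)
    return table


# ---------------------------------------------------------------------------


def ld_pairwise(two_snp_freqs) -> tuple[float, float]:
    """Pairwise linkage disequilibrium (D', r^2) from a 2-SNP haplotype
    frequency vector in haplotype-code order: index bit 0 = variant allele
    at the first SNP, bit 1 = variant allele at the second.

    Returns (nan, nan) when either locus is monomorphic.
    """
    p = np.asarray(two_snp_freqs, dtype=float)
    if p.shape != (4,):
        raise ValueError("expected a 4-haplotype frequency vector")
    pA = p[0] + p[2]          # reference allele, SNP 1
    pB = p[0] + p[1]          # reference allele, SNP 2
    pa, pb = 1 - pA, 1 - pB
    if min(pA, pa, pB, pb) <= 0:
        logger.warning("monomorphic locus: LD undefined")
        return float("nan"), float("nan")
    D = p[0] - pA * pB
    if D >= 0:
        dmax = min(pA * pb, pa * pB)
    else:
        dmax = min(pA * pB, pa * pb)
    d_prime = 0.0 if dmax == 0 else D / dmax
    r2 = D ** 2 / (pA * pa * pB * pb)
    return float(d_prime), float(r2)
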