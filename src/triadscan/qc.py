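"""Marker and individual quality control for triad genotype data.

The pruning cascade mirrors GWAS-era family QC: drop individuals with very
low call rates, then drop SNPs deviating from Hardy-Weinberg equilibrium
among founders, with excess missingness, low minor allele frequency, or an
excess Mendelian-error rate; finally mask (set missing) the residual
Mendelian-inconsistent family genotypes at retained SNPs. A SNP may fail
several criteria but is removed once, so the remaining count reflects the
union of the failing sets, and each criterion's tally is reported separately.

HWE is tested on founders (parents) only: affected children are ascertained
cases and deviate from HWE by design whenever the marker affects risk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .ped_io import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)


@dataclass
class QCThresholds:
    """Cutoffs for the pruning cascade (all fractions/probabilities in [0,1]).

    hwe_p_min : remove SNPs with founder-HWE p below this.
    snp_missing_max : remove SNPs with missing-call fraction above this.
    maf_min : remove SNPs with founder MAF <= this (strictly greater is kept).
    mendel_rate_max : remove SNPs with Mendelian-error family fraction >= this.
    indiv_callrate_min : remove individuals with call rate below this.
    """

    hwe_p_min: float = 0.001
    snp_missing_max: float = 0.05
    maf_min: float = 0.05
    mendel_rate_max: float = 0.01
    indiv_callrate_min: float = 0.10

    def __post_init__(self):
        for name, v in vars(self).items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QCReport:
    """Per-criterion accounting. Criteria overlap: ``remaining_snps`` equals
    the total minus the union of failing sets, not the sum of the tallies."""

    total_snps: int
    failed_hwe: int
    failed_missing: int
    failed_maf: int
    failed_mendel: int
    removed_snps: int
    remaining_snps: int
    individuals_removed: int
    families_removed: int
    genotypes_masked: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("Total no. of SNPs before pruning", self.total_snps),
            ("Failed HWE test", self.failed_hwe),
            ("Failed missingness test", self.failed_missing),
            ("Failed SNP frequency test", self.failed_maf),
            ("Mendelian errors detected", self.failed_mendel),
            ("Remaining SNPs after pruning", self.remaining_snps),
            ("Individuals removed (low call rate)", self.individuals_removed),
            ("Families removed (child lost)", self.families_removed),
            ("Family genotypes masked (residual Mendelian)", self.genotypes_masked),
        ]
        return pd.DataFrame(rows, columns=["criterion", "count"])


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------


def hwe_chi2(n_AA: int, n_Aa: int, n_aa: int) -> tuple[float, float]:
    """1-df chi-square goodness-of-fit of founder genotype counts against
    Hardy-Weinberg proportions at the observed allele frequency.

    Returns (statistic, p). A monomorphic marker fits HWE trivially:
    (0.0, 1.0).
    """
    counts = np.asarray([n_AA, n_Aa, n_aa], dtype=float)
    if (counts < 0).any():
        raise ValueError("negative genotype counts")
    n = counts.sum()
    if n <= 0:
        raise ValueError("no founder genotypes")
    pA = (2 * counts[0] + counts[1]) / (2 * n)
    if pA in (0.0, 1.0):
        return 0.0, 1.0
    expected = n * np.array([pA ** 2, 2 * pA * (1 - pA), (1 - pA) ** 2])
    stat = float(((counts - expected) ** 2 / expected).sum())
    return stat, float(chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# Mendelian consistency (single SNP, dosage codes; missing = unconstrained)
# ---------------------------------------------------------------------------


def _build_mendel_table() -> np.ndarray:
    """consistent[gm, gf, gc] over dosage codes 0/1/2 and 3 = missing,
    by enumerating every parental transmission."""
    pairs = {0: [(0, 0)], 1: [(0, 1)], 2: [(1, 1)], 3: [(0, 0), (0, 1), (1, 1)]}
    ok = np.zeros((4, 4, 4), dtype=bool)
    for gm, gf, gc in product(range(4), repeat=3):
        for am in pairs[gm]:
            for af in pairs[gf]:
                for x in set(am):
                    for y in set(af):
                        if gc == 3 or x + y == gc:
                            ok[gm, gf, gc] = True
    return ok


_MENDEL_OK = _build_mendel_table()


def mendel_inconsistent(ds: GenotypeDataset) -> np.ndarray:
    """Boolean (families x markers): family genotypes impossible under
    Mendelian transmission (missing members/calls are unconstrained)."""
    m_idx, f_idx, c_idx = ds.family_role_matrix()

    def codes(idx: np.ndarray) -> np.ndarray:
        g = np.full((len(idx), ds.n_markers), 3, dtype=np.int8)
        has = idx >= 0
        sub = ds.calls[idx[has], :]
        g[has] = np.where(sub == MISSING, 3, sub)
        return g

    gm, gf, gc = codes(m_idx), codes(f_idx), codes(c_idx)
    return ~_MENDEL_OK[gm, gf, gc]


# ---------------------------------------------------------------------------
# Per-SNP statistics
# ---------------------------------------------------------------------------


def founder_genotype_counts(ds: GenotypeDataset) -> np.ndarray:
    """(markers x 3) dosage counts 0/1/2 among genotyped founders."""
    rows = ds.founder_rows()
    calls = ds.calls[rows, :] if rows.size else np.empty((0, ds.n_markers), dtype=np.int8)
    out = np.zeros((ds.n_markers, 3), dtype=int)
    for d in (0, 1, 2):
        out[:, d] = (calls == d).sum(axis=0)
    return out


def snp_stats(ds: GenotypeDataset) -> pd.DataFrame:
    """Per-SNP missing fraction (all typed persons), founder MAF, and the
    fraction of families Mendelian-inconsistent at the SNP."""
    n_persons = max(ds.n_persons, 1)
    missing_fraction = (ds.calls == MISSING).sum(axis=0) / n_persons

    fc = founder_genotype_counts(ds)
    n_alleles = 2 * fc.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_var = np.where(n_alleles > 0, (2 * fc[:, 2] + fc[:, 1]) / np.maximum(n_alleles, 1), 0.0)
    maf = np.minimum(p_var, 1 - p_var)
    maf = np.where(n_alleles > 0, maf, 0.0)

    n_fam = max(ds.n_families, 1)
    mendel_rate = mendel_inconsistent(ds).sum(axis=0) / n_fam

    return pd.DataFrame({
        "snp": ds.markers["snp"],
        "missing_fraction": missing_fraction,
        "maf": maf,
        "mendel_rate": mendel_rate,
    })


def founder_hwe(ds: GenotypeDataset) -> pd.DataFrame:
    """Per-SNP founder HWE chi-square statistic and p-value."""
    fc = founder_genotype_counts(ds)
    stats, ps, mono = [], [], []
    for j in range(ds.n_markers):
        n0, n1, n2 = int(fc[j, 0]), int(fc[j, 1]), int(fc[j, 2])
        if n0 + n1 + n2 == 0:
            stats.append(0.0); ps.append(1.0); mono.append(True)
            continue
        s, p = hwe_chi2(n0, n1, n2)
        stats.append(s); ps.append(p)
        pA = (2 * n0 + n1) / (2 * (n0 + n1 + n2))
        mono.append(pA in (0.0, 1.0))
    return pd.DataFrame({
        "snp": ds.markers["snp"],
        "hwe_stat": np.asarray(stats, dtype=float),
        "hwe_p": np.asarray(ps, dtype=float),
        "monomorphic": np.asarray(mono, dtype=bool),
    })


# ---------------------------------------------------------------------------
# The cascade
# ---------------------------------------------------------------------------


def apply_qc(
    ds: GenotypeDataset, th: QCThresholds | None = None
) -> tuple[GenotypeDataset, QCReport]:
    """Run the pruning cascade and return the cleaned dataset plus a report.

    Order: (1) drop low-call-rate individuals; (2) recompute per-SNP stats;
    (3) drop SNPs failing any criterion (union semantics); (4) mask residual
    Mendelian-inconsistent family genotypes at retained SNPs.
    """
    th = th or QCThresholds()
    total_snps = ds.n_markers
    n_fam_before = ds.n_families

    # (1) individual call rate
    if ds.n_markers > 0 and ds.n_persons > 0:
        callrate = (ds.calls != MISSING).sum(axis=1) / ds.n_markers
        drop_persons = np.flatnonzero(callrate < th.indiv_callrate_min)
    else:
        drop_persons = np.empty(0, dtype=int)
    ds1 = ds.drop_persons(drop_persons) if drop_persons.size else ds

    # (2) per-SNP statistics on the surviving sample
    stats = snp_stats(ds1)
    hwe = founder_hwe(ds1)

    # (3) SNP filters, union semantics
    fail_hwe = (hwe["hwe_p"].to_numpy() < th.hwe_p_min) & ~hwe["monomorphic"].to_numpy()
    fail_missing = stats["missing_fraction"].to_numpy() > th.snp_missing_max
    fail_maf = stats["maf"].to_numpy() <= th.maf_min
    fail_mendel = stats["mendel_rate"].to_numpy() >= th.mendel_rate_max
    failing = fail_hwe | fail_missing | fail_maf | fail_mendel
    ds2 = ds1.subset_markers(~failing) if failing.any() else ds1

    # (4) mask residual Mendelian inconsistencies at retained SNPs; skipped
    # when the Mendelian criterion is disabled (vacuous bound), so that
    # fully relaxed thresholds return the dataset unchanged
    masked = 0
    if th.mendel_rate_max < 1.0 and ds2.n_markers and ds2.n_families:
        bad = mendel_inconsistent(ds2)
        if bad.any():
            m_idx, f_idx, c_idx = ds2.family_role_matrix()
            calls = ds2.calls.copy()
            fam_i, snp_j = np.nonzero(bad)
            for fi, j in zip(fam_i, snp_j):
                for row in (m_idx[fi], f_idx[fi], c_idx[fi]):
                    if row >= 0:
                        calls[row, j] = MISSING
            ds2 = GenotypeDataset(
                markers=ds2.markers, alleles=ds2.alleles, persons=ds2.persons,
                calls=calls, families=ds2.families,
            )
            masked = int(bad.sum())

    report = QCReport(
        total_snps=total_snps,
        failed_hwe=int(fail_hwe.sum()),
        failed_missing=int(fail_missing.sum()),
        failed_maf=int(fail_maf.sum()),
        failed_mendel=int(fail_mendel.sum()),
        removed_snps=int(failing.sum()),
        remaining_snps=int((~failing).sum()),
        individuals_removed=int(drop_persons.size),
        families_removed=n_fam_before - ds2.n_families,
        genotypes_masked=masked,
    )
    if report.remaining_snps == 0:
        logger.warning("QC removed every SNP; downstream scans will refuse to run")
    logger.info("QC: %s", report)
    return ds2, report
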