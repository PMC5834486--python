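"""Asymptotic power of the single-SNP Wald RRR test, with Monte-Carlo checks.

Under case ascertainment the (mother, father, child) genotype trio at a
biallelic SNP falls into 15 possible dosage categories whose probabilities
are Hardy-Weinberg mating probabilities times Mendelian transmission, tilted
by the child's multiplicative risk ``rr^c`` and renormalised by
``mu = ((1-p) + p*rr)^2``. The expected per-family Fisher information for
log RR follows directly; inverting the joint (allele frequency, log RR)
information accounts for the frequency being estimated rather than known.

The Wald RRR test then has asymptotic variance
``var(log RRR) = 1/(n1 I1) + 1/(n0 I0)`` over the two independent exposure
strata, and two-sided power

    Phi(z - z_{1-a/2}) + Phi(-z - z_{1-a/2}),   z = |log RRR| / sd.

At RRR = 1 this is exactly the nominal level alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.stats import norm

from . import triad_model
from .gxe import ResultSuppressed, rrr_wald
from .sim import _simulate_stratum_rng

logger = logging.getLogger(__name__)

def _transmission_prob(gm: int, gf: int, gc: int) -> float:
    qm, qf = gm / 2.0, gf / 2.0
    if gc == 0:
        return (1 - qm) * (1 - qf)
    if gc == 1:
        return qm * (1 - qf) + (1 - qm) * qf
    return qm * qf


#: the 15 (mother, father, child) dosage trios possible under Mendelian
#: transmission at a biallelic locus
TRIAD_CATEGORIES: tuple[tuple[int, int, int], ...] = tuple(
    (gm, gf, gc)
    for gm, gf, gc in product(range(3), repeat=3)
    if _transmission_prob(gm, gf, gc) > 0
)
assert len(TRIAD_CATEGORIES) == 15


@dataclass
class PowerScenario:
    """Design parameters for a single-SNP GxE power calculation.

    The variant (minor) allele is the risk allele; ``rr_exposed`` and
    ``rr_unexposed`` are its per-copy relative risks in the two maternal
    exposure strata, so the effect under test is
    ``rrr = rr_exposed / rr_unexposed``.
    """

    n_total: int
    maf: float
    rr_exposed: float
    rr_unexposed: float = 1.0
    exposed_fraction: float = 0.5
    alpha: float = 0.05

    def __post_init__(self):
        if not 0 < self.exposed_fraction < 1:
            raise ValueError("exposed_fraction must be in (0, 1)")
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must be in (0, 0.5]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if min(self.rr_exposed, self.rr_unexposed) <= 0:
            raise ValueError("relative risks must be positive")

    @property
    def rrr(self) -> float:
        return self.rr_exposed / self.rr_unexposed

    @property
    def n_exposed(self) -> int:
        return int(round(self.exposed_fraction * self.n_total))

    @property
    def n_unexposed(self) -> int:
        return self.n_total - self.n_exposed


def triad_category_probs(p: float, rr: float) -> np.ndarray:
    """Probabilities of the 15 triad dosage categories given ascertainment,
    in :data:`TRIAD_CATEGORIES` order; sums to 1."""
    if not 0 < p < 1:
        raise ValueError("allele frequency must be in (0, 1)")
    hwe = np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
    mu = ((1 - p) + p * rr) ** 2
    out = np.array([
        hwe[gm] * hwe[gf] * _transmission_prob(gm, gf, gc) * rr ** gc / mu
        for gm, gf, gc in TRIAD_CATEGORIES
    ])
    return out


def _log_category_probs(eta: float, beta: float) -> np.ndarray:
    """log category probabilities at logit allele frequency eta, log RR beta."""
    p = 1.0 / (1.0 + np.exp(-eta))
    return np.log(triad_category_probs(p, float(np.exp(beta))))


def info_log_rr(p: float, rr: float, joint: bool = True, step: float = 1e-5) -> float:
    """Expected per-family Fisher information for log RR at (p, rr).

    With ``joint=True`` (default) the 2x2 expected information in
    (logit p, log RR) is inverted and the log-RR block returned as
    ``1 / [I^{-1}]_bb`` — the effective information when the allele frequency
    is estimated alongside the risk. ``joint=False`` treats p as known.
    """
    if not 0 < p < 1:
        raise ValueError("allele frequency on the boundary")
    eta = float(np.log(p / (1 - p)))
    beta = float(np.log(rr))
    probs = triad_category_probs(p, rr)

    g_eta = (_log_category_probs(eta + step, beta)
             - _log_category_probs(eta - step, beta)) / (2 * step)
    g_beta = (_log_category_probs(eta, beta + step)
              - _log_category_probs(eta, beta - step)) / (2 * step)
    I_bb = float(probs @ (g_beta * g_beta))
    if not joint:
        return I_bb
    I_ee = float(probs @ (g_eta * g_eta))
    I_eb = float(probs @ (g_eta * g_beta))
    det = I_ee * I_bb - I_eb ** 2
    if det <= 0 or I_ee <= 0:
        raise ValueError(f"degenerate information matrix at p={p}, rr={rr}")
    return det / I_ee  # = 1 / [I^{-1}]_{beta,beta}


def asymptotic_power(sc: PowerScenario) -> float:
    """Two-sided asymptotic power of the Wald RRR test for one SNP."""
    n1, n0 = sc.n_exposed, sc.n_unexposed
    if n1 == 0 or n0 == 0:
        raise ValueError("degenerate stratum size 0")
    i1 = info_log_rr(sc.maf, sc.rr_exposed)
    i0 = info_log_rr(sc.maf, sc.rr_unexposed)
    sd = np.sqrt(1.0 / (n1 * i1) + 1.0 / (n0 * i0))
    z = abs(np.log(sc.rrr)) / sd
    zc = norm.ppf(1 - sc.alpha / 2)
    return float(norm.cdf(z - zc) + norm.cdf(-z - zc))


def monte_carlo_power(
    sc: PowerScenario, n_reps: int, seed: int,
    options: triad_model.ModelOptions | None = None,
) -> float:
    """Empirical power from repeated simulated single-SNP GxE scans.

    Each replicate draws the two exposure strata by exact case-ascertained
    rejection sampling, fits the triad likelihood per stratum (reference =
    the major allele so the variant allele carries the free RR), and applies
    the Wald RRR test at ``sc.alpha``.
    """
    rng = np.random.default_rng(seed)
    freqs = np.array([1 - sc.maf, sc.maf])
    win = triad_model.Window(snps=("snp",), chrom=1)
    base = options or triad_model.ModelOptions()
    opts = triad_model.ModelOptions(
        rare_haplotype_min=base.rare_haplotype_min, tol=base.tol,
        max_iter=base.max_iter, rr_cap=base.rr_cap, reference=0,
        n_starts=1, seed=base.seed,
    )
    rejections = suppressed = 0
    for _ in range(n_reps):
        fits = {}
        for label, n, rr in (("exp", sc.n_exposed, sc.rr_exposed),
                             ("unexp", sc.n_unexposed, sc.rr_unexposed)):
            d = _simulate_stratum_rng(n, freqs, np.array([1.0, rr]), rng)
            rows = np.stack([d.m1 + d.m2, d.f1 + d.f2, d.tm + d.tf], axis=1)
            pats, counts = np.unique(rows, axis=0, return_counts=True)
            pattern_counts = {
                ((int(r[0]),), (int(r[1]),), (int(r[2]),)): int(c)
                for r, c in zip(pats, counts)
            }
            fits[label] = triad_model.fit_patterns(pattern_counts, win, opts)
        try:
            res = rrr_wald(fits["exp"], fits["unexp"], 1)
        except ResultSuppressed:
            suppressed += 1
            continue
        if res.p_value < sc.alpha:
            rejections += 1
    if suppressed:
        logger.warning("%d/%d replicates suppressed (variant too rare)",
                       suppressed, n_reps)
    return rejections / n_reps
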