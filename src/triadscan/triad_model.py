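"""Retrospective log-linear likelihood for case-parent triads and dyads.

Model
-----
For a window of k tightly linked SNPs, let ``p_h`` be the population
frequency of haplotype ``h`` (2^k possible allele strings) and ``rr_h`` the
multiplicative relative risk conferred on the child by one copy of ``h``
(two copies confer ``rr_h * rr_h``; one copy each of h and h' confers
``rr_h * rr_h'``). Parents mate at random with haplotypes drawn independently
from ``p`` (Hardy-Weinberg), each parent transmits one of their two
haplotypes with probability 1/2, and the family is ascertained through the
affected child. The probability of a fully phased configuration
(ordered maternal pair, ordered paternal pair, transmitted pair) given
ascertainment is then::

    p_m1 p_m2 p_f1 p_f2 * 1/4 * rr_tm rr_tf / mu,   mu = (sum_h p_h rr_h)^2

Phase, untransmitted haplotypes, missing genotypes and missing parents
(dyads) are never observed: a family's likelihood contribution sums this
probability over every configuration compatible with its observed unordered
genotypes. Only risk ratios relative to a reference haplotype are
identifiable (the configuration probability is invariant under a common
rescaling of ``rr``), so the most frequent haplotype is pinned at RR = 1.

Haplotypes are encoded as integers in ``0 .. 2^k - 1``: bit j set means the
haplotype carries the variant (dosage-counted) allele at the j-th SNP of the
window. A person's observed data at the window is the per-SNP dosage tuple
with -1 for missing.

Estimation maximises the observed-data log-likelihood over the frequency
simplex (softmax parameterisation) and the free log-RRs with a bounded
quasi-Newton optimizer; standard errors come from the observed information
(numerical Hessian), with the log-RR block extracted from the full inverse so
that haplotype-frequency estimation is accounted for.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations_with_replacement

import numpy as np
from scipy.optimize import minimize

from .ped_io import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)

Genotype = tuple[int, ...]  # per-SNP dosages, -1 missing
FamilyCalls = tuple[Genotype, Genotype, Genotype]  # (mother, father, child)

# Each canonical configuration (unordered parent pairs + transmitted pair)
# corresponds to 2 (ordered mother pair x transmitted slot) x 2 (father)
# realisations of the spec probability formula.
CONFIG_MULTIPLICITY = 4


@dataclass(frozen=True)
class Window:
    """A run of contiguous SNPs on one chromosome (k = 1, 2 or 3 typical)."""

    snps: tuple[str, ...]
    chrom: int

    @property
    def k(self) -> int:
        return len(self.snps)

    @property
    def label(self) -> str:
        return "-".join(self.snps)


@dataclass
class ModelOptions:
    """Tuning knobs for the triad-likelihood fit.

    rare_haplotype_min : haplotypes with fitted frequency below this are not
        assigned a free RR (pinned at 1, no standard error).
    tol : relative log-likelihood convergence tolerance.
    rr_cap : |log RR| is bounded by log(rr_cap); a fit pinned at the bound is
        flagged as separated.
    reference : force this haplotype code as the RR reference (used to keep
        stratum fits comparable); default None = most frequent haplotype.
    n_starts : optimizer restarts (perturbed initial values) for k >= 3
        windows; None = 1 for k <= 2, 3 otherwise.
    """

    rare_haplotype_min: float = 0.01
    tol: float = 1e-8
    max_iter: int = 500
    rr_cap: float = 1e3
    reference: int | None = None
    n_starts: int | None = None
    seed: int = 0

    def __post_init__(self):
        if not self.tol > 0:
            raise ValueError("tol must be > 0")
        if not 0 <= self.rare_haplotype_min < 0.5:
            raise ValueError("rare_haplotype_min must be in [0, 0.5)")


@dataclass
class TriadFit:
    """Maximum-likelihood fit of one window in one (sub)sample."""

    window: Window
    haplotypes: list[int]           # haplotype codes with nonzero support
    freqs: np.ndarray               # aligned with haplotypes, sums to 1
    rr: np.ndarray                  # RR per haplotype; reference exactly 1
    se_log_rr: np.ndarray           # nan where RR is pinned
    vcov_log: np.ndarray            # over estimated haplotypes, order of `estimated_haps`
    estimated_haps: list[int]       # haplotype codes with a free RR
    loglik: float
    n_families: int
    n_excluded: int
    converged: bool
    reference: int                  # haplotype code
    flags: list[str] = field(default_factory=list)

    def hap_index(self, hap: int) -> int:
        return self.haplotypes.index(hap)

    def rr_of(self, hap: int) -> float:
        return float(self.rr[self.hap_index(hap)])

    def se_of(self, hap: int) -> float:
        return float(self.se_log_rr[self.hap_index(hap)])

    def freq_of(self, hap: int) -> float:
        return float(self.freqs[self.hap_index(hap)])

    def rr_ci(self, hap: int, z: float = 1.959963984540054) -> tuple[float, float]:
        lr, se = np.log(self.rr_of(hap)), self.se_of(hap)
        return float(np.exp(lr - z * se)), float(np.exp(lr + z * se))


# ---------------------------------------------------------------------------
# Elementary pieces
# ---------------------------------------------------------------------------


def child_risk(copies, rr) -> float:
    """Multiplicative child risk ``prod_h rr_h^copies_h`` (copies sum to 2)."""
    copies = np.asarray(copies)
    rr = np.asarray(rr, dtype=float)
    if copies.sum() != 2:
        raise ValueError("a child carries exactly 2 haplotype copies")
    return float(np.prod(rr ** copies))


def hap_bits(h: int, k: int) -> tuple[int, ...]:
    """Variant-allele indicator of haplotype ``h`` at each of the k SNPs."""
    return tuple((h >> j) & 1 for j in range(k))


def _pair_compatible(h1: int, h2: int, g: Genotype) -> bool:
    for j, gj in enumerate(g):
        if gj != MISSING and ((h1 >> j) & 1) + ((h2 >> j) & 1) != gj:
            return False
    return True


@lru_cache(maxsize=100_000)
def _compatible_pairs(g: Genotype, k: int) -> tuple[tuple[int, int], ...]:
    """All unordered haplotype pairs consistent with a dosage tuple."""
    return tuple(
        (h1, h2)
        for h1, h2 in combinations_with_replacement(range(2 ** k), 2)
        if _pair_compatible(h1, h2, g)
    )


@lru_cache(maxsize=100_000)
def _configs_cached(family_calls: FamilyCalls, k: int):
    gm, gf, gc = family_calls
    out = []
    for m1, m2 in _compatible_pairs(gm, k):
        tms = (m1,) if m1 == m2 else (m1, m2)
        for f1, f2 in _compatible_pairs(gf, k):
            tfs = (f1,) if f1 == f2 else (f1, f2)
            for tm in tms:
                for tf in tfs:
                    if _pair_compatible(tm, tf, gc):
                        out.append((m1, m2, f1, f2, tm, tf))
    if not out:
        return None
    a = np.asarray(out, dtype=np.int64)
    return a[:, 0], a[:, 1], a[:, 2], a[:, 3], a[:, 4], a[:, 5]


def enumerate_compatible(family_calls: FamilyCalls, window: Window | int):
    """List the phased configurations compatible with a family's genotypes.

    Parameters
    ----------
    family_calls : (mother, father, child) per-SNP dosage tuples (-1 missing;
        an absent parent is an all-missing tuple).
    window : a :class:`Window` or the window size k.

    Returns
    -------
    list of ``(config, multiplicity)`` where config is
    ``((m1, m2), (f1, f2), (tm, tf))`` — unordered parental haplotype pairs
    and the transmitted (maternal, paternal) pair — and multiplicity is the
    number of ordered realisations collapsed into the canonical entry.
    An empty list signals Mendelian inconsistency at this window.
    """
    k = window.k if isinstance(window, Window) else int(window)
    gm, gf, gc = (tuple(g) for g in family_calls)
    if all(x == MISSING for x in gc):
        raise ValueError("child must be genotyped at >= 1 window SNP")
    cfg = _configs_cached((gm, gf, gc), k)
    if cfg is None:
        return []
    m1, m2, f1, f2, tm, tf = cfg
    return [
        (((int(a), int(b)), (int(c), int(d)), (int(e), int(g))), CONFIG_MULTIPLICITY)
        for a, b, c, d, e, g in zip(m1, m2, f1, f2, tm, tf)
    ]


def config_probability(config, freqs, rr) -> float:
    """Probability of one ordered phased configuration given ascertainment:
    ``p_m1 p_m2 p_f1 p_f2 / 4 * rr_tm rr_tf / (sum_h p_h rr_h)^2``."""
    (m1, m2), (f1, f2), (tm, tf) = config
    p = np.asarray(freqs, dtype=float)
    r = np.asarray(rr, dtype=float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(r))):
        raise ValueError("non-finite parameters")
    mu = float(p @ r) ** 2
    return float(p[m1] * p[m2] * p[f1] * p[f2] * 0.25 * r[tm] * r[tf] / mu)


# ---------------------------------------------------------------------------
# Pattern aggregation (families collapsed by observed genotype pattern)
# ---------------------------------------------------------------------------


@dataclass
class _PatternTable:
    """Configs of all distinct genotype patterns, concatenated for vector math."""

    k: int
    counts: np.ndarray        # families per pattern
    offsets: np.ndarray       # start index of each pattern's config block
    m1: np.ndarray
    m2: np.ndarray
    f1: np.ndarray
    f2: np.ndarray
    tm: np.ndarray
    tf: np.ndarray
    n_excluded: int           # Mendelian-inconsistent at this window
    n_dropped: int            # uninformative (child fully missing)
    present: np.ndarray       # haplotype codes occurring in any config

    @property
    def n_families(self) -> int:
        return int(self.counts.sum())

    def logliks(self, p: np.ndarray, rr: np.ndarray) -> np.ndarray:
        """Per-pattern log-likelihood (log sum of configuration probabilities)."""
        w = p[self.m1] * p[self.m2] * p[self.f1] * p[self.f2] * rr[self.tm] * rr[self.tf]
        s = np.add.reduceat(w, self.offsets)
        mu = (p @ rr) ** 2
        with np.errstate(divide="ignore"):
            return np.log(s) - np.log(mu)

    def loglik(self, p: np.ndarray, rr: np.ndarray) -> float:
        return float(self.counts @ self.logliks(p, rr))


def window_pattern_counts(
    ds: GenotypeDataset,
    marker_idx: np.ndarray,
    family_mask: np.ndarray | None = None,
) -> dict[FamilyCalls, int]:
    """Collapse families into distinct (mother, father, child) dosage patterns."""
    m_idx, f_idx, c_idx = ds.family_role_matrix()
    if family_mask is not None:
        m_idx, f_idx, c_idx = m_idx[family_mask], f_idx[family_mask], c_idx[family_mask]
    k = len(marker_idx)
    n = len(c_idx)
    G = np.full((n, 3 * k), MISSING, dtype=np.int8)
    calls = ds.calls[:, np.asarray(marker_idx, dtype=int)]
    for col, idx in ((0, m_idx), (1, f_idx), (2, c_idx)):
        has = idx >= 0
        G[has, col * k:(col + 1) * k] = calls[idx[has], :]
    rows, counts = np.unique(G, axis=0, return_counts=True)
    out: dict[FamilyCalls, int] = {}
    for r, c in zip(rows, counts):
        pat = (tuple(int(x) for x in r[:k]),
               tuple(int(x) for x in r[k:2 * k]),
               tuple(int(x) for x in r[2 * k:]))
        out[pat] = int(c)
    return out


def _build_table(patterns: dict[FamilyCalls, int], k: int) -> _PatternTable:
    counts, offs, cols = [], [], [[] for _ in range(6)]
    n_excluded = n_dropped = 0
    pos = 0
    for pat, cnt in patterns.items():
        gm, gf, gc = pat
        if all(x == MISSING for x in gc):
            n_dropped += cnt
            continue
        cfg = _configs_cached(pat, k)
        if cfg is None:
            n_excluded += cnt
            continue
        counts.append(cnt)
        offs.append(pos)
        pos += len(cfg[0])
        for c, arr in zip(cols, cfg):
            c.append(arr)
    if not counts:
        arrs = [np.empty(0, dtype=np.int64)] * 6
    else:
        arrs = [np.concatenate(c) for c in cols]
    present = np.unique(np.concatenate(arrs)) if arrs[0].size else np.empty(0, dtype=np.int64)
    return _PatternTable(
        k=k,
        counts=np.asarray(counts, dtype=float),
        offsets=np.asarray(offs, dtype=np.int64),
        m1=arrs[0], m2=arrs[1], f1=arrs[2], f2=arrs[3], tm=arrs[4], tf=arrs[5],
        n_excluded=n_excluded,
        n_dropped=n_dropped,
        present=present,
    )


def resolve_window(ds: GenotypeDataset, window) -> tuple[Window, np.ndarray]:
    """Accept a Window, a SNP-id sequence or marker indices; return both forms."""
    if isinstance(window, Window):
        snp_to_idx = {s: i for i, s in enumerate(ds.markers["snp"])}
        idx = np.asarray([snp_to_idx[s] for s in window.snps], dtype=int)
        return window, idx
    window = list(window)
    if all(isinstance(w, (int, np.integer)) for w in window):
        idx = np.asarray(window, dtype=int)
    else:
        snp_to_idx = {s: i for i, s in enumerate(ds.markers["snp"])}
        idx = np.asarray([snp_to_idx[s] for s in window], dtype=int)
    chroms = set(int(c) for c in ds.markers["chrom"].iloc[idx])
    if len(chroms) != 1:
        raise ValueError("window spans multiple chromosomes")
    win = Window(snps=tuple(ds.markers["snp"].iloc[idx]), chrom=chroms.pop())
    return win, idx


# ---------------------------------------------------------------------------
# Observed-data log-likelihood and fitting
# ---------------------------------------------------------------------------


def observed_loglik(ds: GenotypeDataset, window, freqs, rr) -> float:
    """Sum over families of log sum over compatible configurations.

    Families that are Mendelian-inconsistent at the window, or whose child is
    entirely missing there, contribute nothing (they are excluded/dropped).
    """
    win, idx = resolve_window(ds, window)
    table = _build_table(window_pattern_counts(ds, idx), win.k)
    p = np.asarray(freqs, dtype=float)
    r = np.asarray(rr, dtype=float)
    return table.loglik(p, r)


def _softmax(alpha: np.ndarray) -> np.ndarray:
    z = np.concatenate(([0.0], alpha))
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def _fit_table(table: _PatternTable, win: Window, options: ModelOptions) -> TriadFit:
    k = table.k
    H = 2 ** k
    present = [int(h) for h in table.present]
    nh = len(present)
    if table.n_families == 0:
        raise ValueError("no informative families in window " + win.label)

    flags: list[str] = []
    code_to_local = {h: i for i, h in enumerate(present)}

    def expand(p_local: np.ndarray, rr_local: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p = np.zeros(H)
        r = np.ones(H)
        p[present] = p_local
        r[present] = rr_local
        return p, r

    if nh == 1:
        # monomorphic window: frequency 1, nothing to estimate
        p, r = expand(np.ones(1), np.ones(1))
        ll = table.loglik(p, r)
        return TriadFit(
            window=win, haplotypes=present, freqs=np.ones(1), rr=np.ones(1),
            se_log_rr=np.full(1, np.nan), vcov_log=np.empty((0, 0)),
            estimated_haps=[], loglik=ll, n_families=table.n_families,
            n_excluded=table.n_excluded, converged=True, reference=present[0],
            flags=["monomorphic"],
        )

    # --- stage 1: frequencies under the null (all RR = 1) ----------------
    ones = np.ones(H)

    def null_nll(alpha: np.ndarray) -> float:
        p, _ = expand(_softmax(alpha), np.ones(nh))
        return -table.loglik(p, ones)

    # linkage-equilibrium style start from marginal config usage
    alpha0 = np.zeros(nh - 1)
    res0 = minimize(null_nll, alpha0, method="L-BFGS-B",
                    bounds=[(-30, 30)] * (nh - 1),
                    options={"maxiter": options.max_iter, "ftol": options.tol * 1e-2})
    p0_local = _softmax(res0.x)

    if options.reference is not None:
        if options.reference not in code_to_local:
            raise ValueError(
                f"forced reference haplotype {options.reference} absent from window"
            )
        ref = options.reference
    else:
        ref = present[int(np.argmax(p0_local))]
    rare = {
        h for h, pl in zip(present, p0_local)
        if pl < options.rare_haplotype_min and h != ref
    }
    est_haps = [h for h in present if h != ref and h not in rare]
    ne = len(est_haps)
    lcap = np.log(options.rr_cap)

    # --- stage 2: joint (frequencies, free log-RRs) ----------------------
    def unpack(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p_local = _softmax(theta[:nh - 1])
        rr_local = np.ones(nh)
        for i, h in enumerate(est_haps):
            rr_local[code_to_local[h]] = np.exp(theta[nh - 1 + i])
        return expand(p_local, rr_local)

    def nll(theta: np.ndarray) -> float:
        p, r = unpack(theta)
        return -table.loglik(p, r)

    with np.errstate(divide="ignore"):
        base0 = np.log(np.maximum(p0_local, 1e-12))
    alpha_start = base0[1:] - base0[0]
    bounds = [(-30, 30)] * (nh - 1) + [(-lcap, lcap)] * ne

    n_starts = options.n_starts if options.n_starts is not None else (3 if k >= 3 else 1)
    rng = np.random.default_rng(options.seed)
    best = None
    for s in range(n_starts):
        theta0 = np.concatenate([alpha_start, np.zeros(ne)])
        if s > 0:
            theta0 = theta0 + rng.normal(scale=0.5, size=theta0.size)
        res = minimize(nll, theta0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": options.max_iter, "ftol": options.tol * 1e-4})
        if best is None or res.fun < best.fun:
            best = res
    res = best
    converged = bool(res.success)

    theta = res.x
    p_full, rr_full = unpack(theta)
    loglik = -res.fun

    at_bound = [h for i, h in enumerate(est_haps)
                if abs(theta[nh - 1 + i]) >= lcap - 1e-6]
    if at_bound:
        flags.append("separation: RR capped for haplotypes " + str(at_bound))

    # --- observed information: numerical Hessian on the full parameter ----
    vcov_rr = np.full((ne, ne), np.nan)
    se_local = np.full(nh, np.nan)
    if ne:
        Hmat = _num_hessian(nll, theta)
        try:
            cov = np.linalg.pinv(Hmat)
            vcov_rr = cov[nh - 1:, nh - 1:]
            d = np.diag(vcov_rr).copy()
            bad = d <= 0
            if bad.any():
                flags.append("non-positive curvature for some log-RRs")
                d[bad] = np.nan
            se = np.sqrt(d)
            for i, h in enumerate(est_haps):
                se_local[code_to_local[h]] = se[i]
        except np.linalg.LinAlgError:
            flags.append("singular information matrix")

    p_out = p_full[present]
    rr_out = rr_full[present]
    return TriadFit(
        window=win, haplotypes=present, freqs=p_out, rr=rr_out,
        se_log_rr=se_local, vcov_log=vcov_rr, estimated_haps=est_haps,
        loglik=loglik, n_families=table.n_families, n_excluded=table.n_excluded,
        converged=converged, reference=ref, flags=flags,
    )


def _num_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian (small dimension; f smooth)."""
    n = x.size
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n); ei[i] = h
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n); ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h ** 2)
    return H


def fit(ds: GenotypeDataset, window, options: ModelOptions | None = None) -> TriadFit:
    """Maximum-likelihood fit of haplotype frequencies and child relative
    risks for one window.

    The reference haplotype (most frequent, or ``options.reference``) is
    pinned at RR = 1, as are haplotypes rarer than
    ``options.rare_haplotype_min``; all other haplotypes get a free log-RR
    with a standard error from the observed information.
    """
    options = options or ModelOptions()
    win, idx = resolve_window(ds, window)
    table = _build_table(window_pattern_counts(ds, idx), win.k)
    if table.n_excluded:
        logger.warning("window %s: %d Mendelian-inconsistent families excluded",
                       win.label, table.n_excluded)
    if table.n_dropped:
        logger.warning("window %s: %d uninformative families dropped",
                       win.label, table.n_dropped)
    return _fit_table(table, win, options)


def fit_patterns(
    patterns: dict[FamilyCalls, int], window: Window, options: ModelOptions | None = None
) -> TriadFit:
    """Fit directly from aggregated genotype-pattern counts (fast path used
    by the scan and the simulation-based power validation)."""
    options = options or ModelOptions()
    return _fit_table(_build_table(patterns, window.k), window, options)
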