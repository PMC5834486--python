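"""Triad likelihood: enumeration, probabilities, and ML fitting vs oracles."""

import numpy as np
import pytest

from triadscan import child_risk, config_probability, enumerate_compatible, fit
from triadscan.ped_io import MISSING
from triadscan.sim import simulate_stratum
from triadscan.triad_model import (
    ModelOptions,
    Window,
    _build_table,
    fit_patterns,
    observed_loglik,
    window_pattern_counts,
)

from conftest import dataset_from_dosages

WIN1 = Window(snps=("s0",), chrom=1)


# --- independent full-enumeration oracle -----------------------------------


def _match(h1: int, h2: int, g) -> bool:
    return all(
        gj == MISSING or ((h1 >> j) & 1) + ((h2 >> j) & 1) == gj
        for j, gj in enumerate(g)
    )


def bruteforce_family_prob(gm, gf, gc, p, rr) -> float:
    """Family likelihood by looping every ordered parental 4-tuple and every
    transmission choice — no sharing with the package's enumeration."""
    k = len(gc)
    H = range(2 ** k)
    mu = sum(p[h] * rr[h] for h in H) ** 2
    tot = 0.0
    for m1 in H:
        for m2 in H:
            if not _match(m1, m2, gm):
                continue
            for f1 in H:
                for f2 in H:
                    if not _match(f1, f2, gf):
                        continue
                    for tm in (m1, m2):
                        for tf in (f1, f2):
                            if _match(tm, tf, gc):
                                tot += (p[m1] * p[m2] * p[f1] * p[f2]
                                        * 0.25 * rr[tm] * rr[tf] / mu)
    return tot


def patterns_from_draw(d) -> dict:
    rows = np.stack([d.m1 + d.m2, d.f1 + d.f2, d.tm + d.tf], axis=1)
    pats, counts = np.unique(rows, axis=0, return_counts=True)
    return {((int(r[0]),), (int(r[1]),), (int(r[2]),)): int(c)
            for r, c in zip(pats, counts)}


# --- child_risk ------------------------------------------------------------


@pytest.mark.parametrize("copies, rr, want", [
    ((2, 0), (1.0, 1.5), 1.0),        # two reference copies
    ((0, 2), (1.0, 1.5), 2.25),       # homozygous risk: RR x RR
    ((1, 1), (1.2, 0.5), 0.6),        # product across haplotypes
])
def test_child_risk(copies, rr, want):
    assert child_risk(copies, rr) == pytest.approx(want)


def test_child_risk_requires_two_copies():
    with pytest.raises(ValueError):
        child_risk((1, 0), (1.0, 1.0))


# --- enumeration -----------------------------------------------------------


def test_all_homozygous_single_config():
    cfgs = enumerate_compatible(((0,), (0,), (0,)), 1)
    assert len(cfgs) == 1
    ((m, f, t), mult) = cfgs[0]
    assert m == (0, 0) and f == (0, 0) and t == (0, 0)


def test_all_heterozygous_two_transmissions():
    cfgs = enumerate_compatible(((1,), (1,), (1,)), 1)
    transmitted = sorted(c[0][2] for c in cfgs)
    assert transmitted == [(0, 1), (1, 0)]


def test_missing_parents_count_matches_bruteforce():
    gm = (MISSING, MISSING)
    gf = (MISSING, MISSING)
    gc = (1, 1)  # double heterozygote, 2 SNPs
    cfgs = enumerate_compatible((gm, gf, gc), 2)
    # brute force over ordered assignments, collapsed the same way
    seen = set()
    for m1 in range(4):
        for m2 in range(4):
            for f1 in range(4):
                for f2 in range(4):
                    for tm in (m1, m2):
                        for tf in (f1, f2):
                            if _match(tm, tf, gc):
                                seen.add((tuple(sorted((m1, m2))),
                                          tuple(sorted((f1, f2))), (tm, tf)))
    assert len(cfgs) == len(seen)


def test_mendelian_inconsistency_yields_no_configs():
    assert enumerate_compatible(((0,), (0,), (2,)), 1) == []


def test_child_fully_missing_rejected():
    with pytest.raises(ValueError):
        enumerate_compatible(((0,), (0,), (MISSING,)), 1)


# --- configuration probabilities -------------------------------------------


def test_null_model_normalizes_over_complete_categories():
    p, rr = [0.6, 0.4], [1.0, 1.0]
    total = 0.0
    for gm in range(3):
        for gf in range(3):
            for gc in range(3):
                try:
                    cfgs = enumerate_compatible(((gm,), (gf,), (gc,)), 1)
                except ValueError:
                    continue
                total += sum(mult * config_probability(c, p, rr) for c, mult in cfgs)
    assert total == pytest.approx(1.0, abs=1e-12)


def test_mu_closed_form():
    # p=(0.6, 0.4), rr=(1, 2): mu = (0.6 + 0.8)^2 = 1.96
    cfg = (((0, 0), (0, 0)), ((0, 0),))  # placeholder shape fixed below
    c = ((0, 0), (0, 0), (0, 0))
    got = config_probability(c, [0.6, 0.4], [1.0, 2.0])
    assert got == pytest.approx(0.6 ** 4 * 0.25 / 1.96, rel=1e-12)


def test_rr_scale_invariance():
    c = ((0, 1), (0, 0), (1, 0))
    p, rr = [0.7, 0.3], [1.0, 1.8]
    a = config_probability(c, p, rr)
    b = config_probability(c, p, [2.0, 3.6])
    assert a == pytest.approx(b, rel=1e-12)


# --- observed log-likelihood ----------------------------------------------


def test_single_homozygous_triad_closed_form():
    ds = dataset_from_dosages([([0], [0], [0])], n_snps=1)
    p, rr = [0.7, 0.3], [1.0, 1.5]
    mu = (0.7 + 0.3 * 1.5) ** 2
    want = np.log(0.7 ** 4 / mu)
    assert observed_loglik(ds, ["rs0"], p, rr) == pytest.approx(want, abs=1e-12)
    cfgs = enumerate_compatible(((0,), (0,), (0,)), 1)
    total = sum(m * config_probability(c, p, rr) for c, m in cfgs)
    assert np.log(total) == pytest.approx(want, abs=1e-12)


def test_loglik_matches_bruteforce_enumeration():
    rng = np.random.default_rng(42)
    # 20 families x 2 SNPs with missing calls and missing parents
    trios = []
    for i in range(20):
        t = rng.integers(0, 3, size=(3, 2)).tolist()
        if i % 5 == 0:
            t[1] = [MISSING, MISSING]       # dyad
        if i % 7 == 0:
            t[0][1] = MISSING               # missing call
        trios.append(tuple(t))
    ds = dataset_from_dosages(trios, n_snps=2)
    p = np.array([0.4, 0.3, 0.2, 0.1])
    rr = np.array([1.0, 1.7, 0.6, 1.2])
    want = 0.0
    n_incompatible = 0
    for gm, gf, gc in trios:
        lik = bruteforce_family_prob(gm, gf, gc, p, rr)
        if lik == 0.0:
            n_incompatible += 1
            continue
        want += np.log(lik)
    got = observed_loglik(ds, ["rs0", "rs1"], p, rr)
    assert got == pytest.approx(want, abs=1e-10)


def test_all_missing_family_contributes_nothing():
    base = [([1], [1], [1]), ([0], [1], [1])]
    ds1 = dataset_from_dosages(base, n_snps=1)
    ds2 = dataset_from_dosages(base + [([MISSING], [MISSING], [MISSING])], n_snps=1)
    p, rr = [0.5, 0.5], [1.0, 2.0]
    assert observed_loglik(ds1, ["rs0"], p, rr) == pytest.approx(
        observed_loglik(ds2, ["rs0"], p, rr), abs=1e-14
    )


# --- fitting ---------------------------------------------------------------


def test_null_simulation_recovery():
    d = simulate_stratum(2000, [0.7, 0.3], [1.0, 1.0], seed=123)
    f = fit_patterns(patterns_from_draw(d), WIN1, ModelOptions(reference=0))
    log_rr = np.log(f.rr_of(1))
    assert abs(log_rr) < 3 * f.se_of(1)
    assert f.freq_of(1) == pytest.approx(0.3, abs=0.02)
    assert f.converged


def test_fit_attains_grid_optimum():
    trios = [([0], [1], [1]), ([1], [1], [2]), ([1], [0], [0]),
             ([2], [1], [2]), ([1], [1], [1]), ([0], [0], [0]),
             ([MISSING], [1], [1]), ([1], [MISSING], [1])]
    ds = dataset_from_dosages(trios, n_snps=1)
    f = fit(ds, ["rs0"], ModelOptions(reference=0))
    table = _build_table(window_pattern_counts(ds, np.array([0])), 1)
    best_grid = -np.inf
    for p1 in np.linspace(0.05, 0.95, 91):
        p = np.array([1 - p1, p1])
        for rr1 in np.exp(np.linspace(np.log(0.1), np.log(10), 161)):
            ll = table.loglik(p, np.array([1.0, rr1]))
            best_grid = max(best_grid, ll)
    assert f.loglik >= best_grid - 1e-6


def test_allele_relabeling_symmetry():
    d = simulate_stratum(800, [0.65, 0.35], [1.0, 1.6], seed=9)
    pats = patterns_from_draw(d)
    flipped = {tuple(tuple(2 - x for x in g) for g in pat): c for pat, c in pats.items()}
    f1 = fit_patterns(pats, WIN1, ModelOptions(reference=0))
    # hap codes swap 0 <-> 1: same risk haplotype, same fit
    f2 = fit_patterns(flipped, WIN1, ModelOptions(reference=1))
    assert f2.loglik == pytest.approx(f1.loglik, abs=1e-6)
    assert f2.freq_of(0) == pytest.approx(f1.freq_of(1), abs=1e-5)
    assert np.log(f2.rr_of(0)) == pytest.approx(np.log(f1.rr_of(1)), abs=1e-4)
    # reading the flipped data against the opposite reference inverts the RR
    f3 = fit_patterns(flipped, WIN1, ModelOptions(reference=0))
    assert np.log(f3.rr_of(1)) == pytest.approx(-np.log(f1.rr_of(1)), abs=1e-4)
    assert f3.loglik == pytest.approx(f1.loglik, abs=1e-6)


def test_estimation_error_shrinks_with_n():
    rng = np.random.default_rng(77)
    meds = []
    for n in (500, 2000, 8000):
        errs = []
        for _ in range(40):
            d = _sim(n, rng)
            f = fit_patterns(patterns_from_draw(d), WIN1, ModelOptions(reference=0))
            errs.append(abs(np.log(f.rr_of(1)) - np.log(1.5)))
        meds.append(np.median(errs))
    assert meds[0] > meds[1] > meds[2]


def _sim(n, rng):
    return simulate_stratum(n, [0.7, 0.3], [1.0, 1.5],
                            seed=int(rng.integers(2 ** 31)))


def test_large_sample_approaches_transmission_ratio():
    d = simulate_stratum(20000, [0.7, 0.3], [1.0, 1.8], seed=2024)
    f = fit_patterns(patterns_from_draw(d), WIN1, ModelOptions(reference=0))
    # transmitted/untransmitted variant counts from heterozygous parents
    t = u = 0
    for h1, h2, tr in ((d.m1, d.m2, d.tm), (d.f1, d.f2, d.tf)):
        het = h1 != h2
        t += int((tr[het] == 1).sum())
        u += int((tr[het] == 0).sum())
    log_tu = np.log(t / u)
    log_rr = np.log(f.rr_of(1))
    assert abs(log_rr - log_tu) < 0.05
    assert abs(log_rr - np.log(1.8)) < 0.06


def test_dyad_only_recovery_with_wider_cis():
    d = simulate_stratum(3000, [0.7, 0.3], [1.0, 1.6], seed=55)
    pats = patterns_from_draw(d)
    dyads = {}
    for (gm, gf, gc), c in pats.items():
        key = (gm, (MISSING,), gc)  # drop every father
        dyads[key] = dyads.get(key, 0) + c
    f_full = fit_patterns(pats, WIN1, ModelOptions(reference=0))
    f_dyad = fit_patterns(dyads, WIN1, ModelOptions(reference=0))
    assert abs(np.log(f_dyad.rr_of(1)) - np.log(1.6)) < 3 * f_dyad.se_of(1)
    assert f_dyad.se_of(1) > f_full.se_of(1)


def test_monomorphic_window_flagged():
    ds = dataset_from_dosages([([0], [0], [0])] * 4, n_snps=1)
    f = fit(ds, ["rs0"], ModelOptions())
    assert "monomorphic" in f.flags and f.estimated_haps == []


def test_inconsistent_family_excluded_from_window():
    trios = [([1], [1], [1])] * 6 + [([0], [0], [2])]
    ds = dataset_from_dosages(trios, n_snps=1)
    f = fit(ds, ["rs0"], ModelOptions())
    assert f.n_excluded == 1 and f.n_families == 6
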