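"""Stratified fits, the Wald RRR test, scans, sliding windows, and LD."""

import numpy as np
import pandas as pd
import pytest

from triadscan import fit_strata, ld_pairwise, rrr_wald, scan, sliding_windows
from triadscan.gxe import EmptyStratumError, ResultSuppressed
from triadscan.ped_io import EXPOSED, UNEXPOSED, ExposureTable
from triadscan.sim import LocusSpec, SimConfig, simulate_study
from triadscan.triad_model import ModelOptions, TriadFit, Window


def make_fit(rr: float, se: float, freq: float = 0.4, n: int = 1000,
             label: str = "w") -> TriadFit:
    """Minimal single-SNP fit with a free RR for haplotype 1."""
    return TriadFit(
        window=Window(snps=(label,), chrom=1),
        haplotypes=[0, 1],
        freqs=np.array([1 - freq, freq]),
        rr=np.array([1.0, rr]),
        se_log_rr=np.array([np.nan, se]),
        vcov_log=np.array([[se ** 2]]),
        estimated_haps=[1],
        loglik=0.0, n_families=n, n_excluded=0, converged=True, reference=0,
    )


def exposure_from_truth(truth, name="vitamin") -> ExposureTable:
    fids = [f"F{i:05d}" for i in range(len(truth.stratum))]
    return ExposureTable(
        table=pd.DataFrame({name: list(truth.stratum)},
                           index=pd.Index(fids, name="family_id"))
    )


# --- sliding windows -------------------------------------------------------


def _markers(rows):
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos"])


def test_window_size_one_is_per_snp():
    m = _markers([("a", 1, 1), ("b", 1, 2), ("c", 2, 5)])
    wins = sliding_windows(m, 1)
    assert [w.snps for w in wins] == [("a",), ("b",), ("c",)]


def test_windows_step_by_one():
    m = _markers([("a", 1, 1), ("b", 1, 2), ("c", 1, 3)])
    assert [w.snps for w in sliding_windows(m, 2)] == [("a", "b"), ("b", "c")]


def test_windows_never_cross_chromosomes():
    m = _markers([("a", 1, 1), ("b", 1, 2), ("c", 1, 3),
                  ("d", 2, 1), ("e", 2, 2)])
    wins = sliding_windows(m, 3)
    assert [w.snps for w in wins] == [("a", "b", "c")]
    assert sliding_windows(m, 4) == []


# --- Wald RRR --------------------------------------------------------------


def test_equal_stratum_rrs_give_null_result():
    res = rrr_wald(make_fit(1.3, 0.08), make_fit(1.3, 0.05), 1)
    assert res.rrr == pytest.approx(1.0)
    assert res.p_value == pytest.approx(1.0)
    assert res.rrr_ci[0] < 1.0 < res.rrr_ci[1]


def test_printed_single_snp_rrr_and_ci():
    # stratum RRs and CIs as printed for the lead SNP: exposed 0.66
    # (0.56-0.78), unexposed 1.17 (1.03-1.33)
    se1 = np.log(0.78 / 0.56) / (2 * 1.959963984540054)
    se0 = np.log(1.33 / 1.03) / (2 * 1.959963984540054)
    res = rrr_wald(make_fit(0.66, se1), make_fit(1.17, se0), 1)
    assert res.rrr == pytest.approx(0.56, abs=0.005)
    assert res.rrr_ci[0] == pytest.approx(0.46, abs=0.01)
    assert res.rrr_ci[1] == pytest.approx(0.70, abs=0.01)
    assert res.p_value == pytest.approx(6e-8, rel=3)


def test_rrr_suppressed_when_not_estimated():
    f1 = make_fit(0.8, 0.1)
    f0 = make_fit(1.2, 0.1)
    f0.estimated_haps = []  # rare in the unexposed stratum
    with pytest.raises(ResultSuppressed):
        rrr_wald(f1, f0, 1)


def test_swapping_strata_inverts_rrr():
    f1, f0 = make_fit(0.7, 0.09), make_fit(1.25, 0.07)
    a = rrr_wald(f1, f0, 1)
    b = rrr_wald(f0, f1, 1)
    assert b.rrr == pytest.approx(1 / a.rrr, rel=1e-12)
    assert b.p_value == pytest.approx(a.p_value, rel=1e-12)


# --- stratified fits -------------------------------------------------------


@pytest.fixture(scope="module")
def gxe_study():
    """One GxE SNP (rr0=1.25, rr1=0.65) among two null SNPs; stratum pools
    differ (0.38 vs 0.43) at the GxE SNP."""
    f_unexp, f_exp = 0.38, 0.43
    gxe_locus = LocusSpec(
        snps=("rsGXE",), chrom=2, positions=(500,),
        freqs={UNEXPOSED: (1 - f_unexp, f_unexp), EXPOSED: (1 - f_exp, f_exp)},
        rr={UNEXPOSED: (1.0, 1.25), EXPOSED: (1.0, 0.65)},
    )
    loci = [
        LocusSpec.snp("rsN1", chrom=1, pos=100, maf=0.3),
        gxe_locus,
        LocusSpec.snp("rsN2", chrom=3, pos=900, maf=0.2),
    ]
    cfg = SimConfig(loci=loci, seed=101, n_families=2000, dyad_fraction=0.0,
                    genotype_missing_rate=0.0, genotype_error_rate=0.0,
                    exposure_missing_rate=0.0)
    return simulate_study(cfg)


def test_all_unknown_exposure_is_an_error(clean_study):
    ds, _, _ = clean_study
    empty = ExposureTable(table=pd.DataFrame(
        {"vitamin": []}, index=pd.Index([], name="family_id")))
    with pytest.raises(EmptyStratumError):
        fit_strata(ds, empty, ["rs0"], exposure_name="vitamin")


def test_null_strata_agree_within_sampling_error(clean_study):
    ds, exposures, _ = clean_study
    f1, f0, fall = fit_strata(ds, exposures, ["rs0"], exposure_name="vitamin")
    diff = abs(np.log(f1.rr_of(1)) - np.log(f0.rr_of(1)))
    assert diff < 3 * np.hypot(f1.se_of(1), f0.se_of(1))
    assert f1.reference == f0.reference == fall.reference


def test_stratum_frequencies_recover_truth(gxe_study):
    ds, _, truth = gxe_study
    exposures = exposure_from_truth(truth)
    f1, f0, _ = fit_strata(ds, exposures, ["rsGXE"], exposure_name="vitamin")
    assert f1.freq_of(1) == pytest.approx(0.43, abs=0.03)
    assert f0.freq_of(1) == pytest.approx(0.38, abs=0.03)


def test_qualitative_interaction_detected(gxe_study):
    ds, _, truth = gxe_study
    exposures = exposure_from_truth(truth)
    f1, f0, _ = fit_strata(ds, exposures, ["rsGXE"], exposure_name="vitamin")
    assert f1.rr_of(1) < 1.0 < f0.rr_of(1)
    res = rrr_wald(f1, f0, 1)
    assert res.rrr == pytest.approx(0.65 / 1.25, abs=0.12)
    assert res.p_value < 1e-4


# --- scan ------------------------------------------------------------------


def test_scan_equals_composition_on_single_window(gxe_study):
    ds, _, truth = gxe_study
    exposures = exposure_from_truth(truth)
    opts = ModelOptions()
    win = Window(snps=("rsGXE",), chrom=2)
    table = scan(ds, exposures, [win], opts, "vitamin")
    f1, f0, fall = fit_strata(ds, exposures, win, opts, "vitamin")
    res = rrr_wald(f1, f0, 1)
    assert len(table) == 1
    row = table.iloc[0]
    assert row["rrr"] == pytest.approx(res.rrr, rel=1e-9)
    assert row["p"] == pytest.approx(res.p_value, rel=1e-9)
    assert row["rr_all"] == pytest.approx(fall.rr_of(1), rel=1e-9)


def test_scan_ranks_planted_effect_first(gxe_study):
    ds, _, truth = gxe_study
    exposures = exposure_from_truth(truth)
    table = scan(ds, exposures, 1, exposure_name="vitamin")
    assert len(table) == 3
    assert table.iloc[0]["window"] == "rsGXE"
    assert table["p"].is_monotonic_increasing
    assert bool(table.iloc[0]["top"])


def test_scan_label_swap_inverts_rrr(gxe_study):
    ds, _, truth = gxe_study
    swapped = np.where(truth.stratum == EXPOSED, UNEXPOSED, EXPOSED)

    class T:  # tiny stand-in with the stratum array swapped
        stratum = swapped
    a = scan(ds, exposure_from_truth(truth), 1, exposure_name="vitamin")
    b = scan(ds, exposure_from_truth(T), 1, exposure_name="vitamin")
    a = a.sort_values("window").reset_index(drop=True)
    b = b.sort_values("window").reset_index(drop=True)
    np.testing.assert_allclose(b["rrr"], 1 / a["rrr"], rtol=1e-6)
    np.testing.assert_allclose(b["p"], a["p"], rtol=1e-6)


# --- LD --------------------------------------------------------------------


@pytest.mark.parametrize("freqs, want_dp, want_r2", [
    ([0.3, 0.2, 0.3, 0.2], 0.0, 0.0),          # independent: p_ab = pa*pb
    ([0.5, 0.0, 0.0, 0.5], 1.0, 1.0),          # complete LD
    ([0.4, 0.1, 0.2, 0.3], 0.5, 1.0 / 6.0),    # hand arithmetic
])
def test_ld_pairwise_values(freqs, want_dp, want_r2):
    dp, r2 = ld_pairwise(freqs)
    assert dp == pytest.approx(want_dp, abs=1e-12)
    assert r2 == pytest.approx(want_r2, abs=1e-12)


def test_ld_monomorphic_flagged_missing():
    dp, r2 = ld_pairwise([0.6, 0.4, 0.0, 0.0])
    assert np.isnan(dp) and np.isnan(r2)
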