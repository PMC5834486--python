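"""Shared fixtures: tiny hand-written pedigrees and simulated datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from triadscan import LocusSpec, SimConfig, simulate_study
from triadscan.ped_io import GenotypeDataset
from triadscan.sim import dataset_from_trios


@pytest.fixture()
def tiny_pedmap(tmp_path):
    """One complete triad, one SNP: parents 1/1 and 1/2, affected child 1/2."""
    ped = tmp_path / "tiny.ped"
    map_ = tmp_path / "tiny.map"
    ped.write_text(
        "F1 F1_M 0 0 2 1 1 1\n"
        "F1 F1_F 0 0 1 1 1 2\n"
        "F1 F1_C F1_F F1_M 0 2 1 2\n"
    )
    map_.write_text("1 rs1 0 1000\n")
    return ped, map_


def dataset_from_dosages(trios: list[tuple], n_snps: int) -> GenotypeDataset:
    """Complete-triad dataset from (gm, gf, gc) dosage rows (-1 = missing)."""
    return dataset_from_trios(trios, n_snps)


@pytest.fixture(scope="session")
def clean_study():
    """A small error-free study: 300 families, 6 null SNPs, no dyads."""
    loci = [LocusSpec.snp(f"rs{j}", chrom=j + 1, pos=1000, maf=0.3) for j in range(6)]
    cfg = SimConfig(
        loci=loci, seed=11, n_families=300, dyad_fraction=0.0,
        genotype_missing_rate=0.0, genotype_error_rate=0.0,
        exposure_missing_rate=0.0,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def messy_study():
    """Study-structured data with dyads, missingness, genotype errors, NA."""
    loci = [LocusSpec.snp(f"rs{j}", chrom=j + 1, pos=1000, maf=0.25) for j in range(5)]
    cfg = SimConfig(
        loci=loci, seed=23, n_families=200, dyad_fraction=0.165,
        genotype_missing_rate=0.02, genotype_error_rate=0.02,
        exposure_missing_rate=0.1,
    )
    return simulate_study(cfg)
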