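"""Synthetic case-parent triad generator.

Emulates the structure of a family-based orofacial-cleft GWAS: nuclear
families ascertained through an affected child, with 0-2 genotyped parents,
maternal exposure strata of unequal size with yes/no/NA coding, founder
haplotypes drawn from Hardy-Weinberg pools, multiplicative per-haplotype
child relative risks that may differ between exposure strata, and injected
genotype missingness and allele-flip errors (which deliberately create
Mendelian inconsistencies so the QC stage has something to find).

Ascertainment is exact rejection sampling: a candidate family (four founder
haplotypes drawn from the stratum's frequency pool, uniform transmission) is
accepted with probability ``child_risk / max_child_risk``, which conditions
the retained families on the child being a case under the multiplicative
risk model.

All randomness flows from a single master seed through
``numpy.random.SeedSequence.spawn``: stream 0 drives locus genotypes
(spawned once per locus), stream 1 the dyad parent deletions, stream 2
genotype missingness, stream 3 allele-flip errors, and stream 4 exposure
missingness. Identical configs therefore give byte-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ped_io import (
    EXPOSED,
    MISSING,
    UNEXPOSED,
    ExposureTable,
    Family,
    GenotypeDataset,
)

STRATA = (UNEXPOSED, EXPOSED)


@dataclass(frozen=True)
class LocusSpec:
    """One window of tightly linked SNPs with stratum-specific parameters.

    freqs/rr vectors are indexed by haplotype code (bit j = variant allele at
    the j-th SNP); ``freqs[s]`` must sum to 1 for each stratum ``s``.
    """

    snps: tuple[str, ...]
    chrom: int
    positions: tuple[int, ...]
    freqs: dict[str, tuple[float, ...]]   # stratum -> 2^k haplotype frequencies
    rr: dict[str, tuple[float, ...]]      # stratum -> 2^k relative risks

    @property
    def k(self) -> int:
        return len(self.snps)

    @property
    def label(self) -> str:
        return "-".join(self.snps)

    def __post_init__(self):
        H = 2 ** self.k
        if len(self.positions) != self.k:
            raise ValueError(f"{self.label}: positions/snps length mismatch")
        for s in STRATA:
            if s not in self.freqs or s not in self.rr:
                raise ValueError(f"{self.label}: missing stratum {s!r}")
            if len(self.freqs[s]) != H or len(self.rr[s]) != H:
                raise ValueError(f"{self.label}: parameter vectors must have length {H}")
            if abs(sum(self.freqs[s]) - 1.0) > 1e-9:
                raise ValueError(f"{self.label}: frequencies must sum to 1")

    @classmethod
    def snp(
        cls, snp_id: str, chrom: int, pos: int, maf: float,
        rr_unexposed: float = 1.0, rr_exposed: float = 1.0,
    ) -> "LocusSpec":
        """Single biallelic SNP; the minor (variant) allele carries the risk."""
        f = (1.0 - maf, maf)
        return cls(
            snps=(snp_id,), chrom=chrom, positions=(pos,),
            freqs={UNEXPOSED: f, EXPOSED: f},
            rr={UNEXPOSED: (1.0, rr_unexposed), EXPOSED: (1.0, rr_exposed)},
        )


@dataclass
class SimConfig:
    """Study-structure parameters. The defaults mirror the emulated design:
    1,908 families of which 314 are dyads, an even split of exposed and
    unexposed mothers, and small genotyping missingness/error rates."""

    loci: list[LocusSpec]
    seed: int
    n_families: int = 1908
    exposed_fraction: float = 0.5
    dyad_fraction: float = 314 / 1908
    genotype_missing_rate: float = 0.01
    genotype_error_rate: float = 0.001
    exposure_missing_rate: float = 0.05
    exposure_name: str = "vitamin"

    def __post_init__(self):
        for name in ("exposed_fraction", "dyad_fraction", "genotype_missing_rate",
                     "genotype_error_rate", "exposure_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        key = [(l.chrom, l.positions[0]) for l in self.loci]
        if key != sorted(key):
            raise ValueError("loci must be ordered by (chrom, position)")


@dataclass
class StratumDraw:
    """Latent phased haplotypes for one stratum at one locus.

    m1/m2, f1/f2 are the maternal and paternal haplotype codes; tm/tf the
    transmitted (maternal, paternal) pair; n_attempted counts rejection-
    sampling proposals."""

    m1: np.ndarray
    m2: np.ndarray
    f1: np.ndarray
    f2: np.ndarray
    tm: np.ndarray
    tf: np.ndarray
    n_attempted: int


@dataclass
class SimTruth:
    """Everything needed to recompute any summary of the generated data."""

    config: SimConfig
    stratum: np.ndarray                     # per family: "unexposed"/"exposed"
    loci: dict[str, dict[str, np.ndarray]]  # label -> family-aligned m1..tf
    deleted_parent: np.ndarray              # per family: ""/"mother"/"father"
    exposure_observed: np.ndarray           # bool per family

    def stratum_counts(self) -> dict[str, int]:
        return {s: int((self.stratum == s).sum()) for s in STRATA}

    def transmission_counts(self, locus_label: str, hap: int, k: int) -> tuple[int, int]:
        """(transmitted, untransmitted) counts of the variant allele... of a
        haplotype code across all parents (truth-level T/U record)."""
        L = self.loci[locus_label]
        t = int((L["tm"] == hap).sum() + (L["tf"] == hap).sum())
        um = np.where(L["tm"] == L["m1"], L["m2"], L["m1"])
        uf = np.where(L["tf"] == L["f1"], L["f2"], L["f1"])
        u = int((um == hap).sum() + (uf == hap).sum())
        return t, u


# ---------------------------------------------------------------------------


def _simulate_stratum_rng(
    n: int, freqs: np.ndarray, rr: np.ndarray, rng: np.random.Generator
) -> StratumDraw:
    freqs = np.asarray(freqs, dtype=float)
    rr = np.asarray(rr, dtype=float)
    if np.all(rr[freqs > 0] == 0):
        raise ValueError("every achievable child risk is 0: ascertainment impossible")
    max_risk = rr.max() ** 2
    H = len(freqs)
    out = {k: [] for k in ("m1", "m2", "f1", "f2", "tm", "tf")}
    accepted, attempted = 0, 0
    while accepted < n:
        batch = max(1024, int(1.5 * (n - accepted) * max_risk / max(freqs @ rr, 1e-12) ** 2))
        batch = min(batch, 2_000_000)
        haps = rng.choice(H, size=(batch, 4), p=freqs)
        coin = rng.integers(0, 2, size=(batch, 2))
        tm = haps[np.arange(batch), coin[:, 0]]
        tf = haps[np.arange(batch), 2 + coin[:, 1]]
        risk = rr[tm] * rr[tf]
        keep = rng.random(batch) * max_risk < risk
        attempted += batch
        idx = np.flatnonzero(keep)[: n - accepted]
        out["m1"].append(haps[idx, 0]); out["m2"].append(haps[idx, 1])
        out["f1"].append(haps[idx, 2]); out["f2"].append(haps[idx, 3])
        out["tm"].append(tm[idx]); out["tf"].append(tf[idx])
        accepted += idx.size
    return StratumDraw(
        **{k: np.concatenate(v) for k, v in out.items()}, n_attempted=attempted
    )


def simulate_stratum(n: int, freqs, rr, seed: int) -> StratumDraw:
    """Draw ``n`` case-ascertained families from one exposure stratum.

    Parents are two independent haplotypes each from ``freqs`` (random
    mating under HWE); each parent transmits uniformly; families are kept by
    rejection sampling with probability ``child_risk / max_child_risk``.
    Deterministic given ``seed``.
    """
    return _simulate_stratum_rng(n, freqs, rr, np.random.default_rng(seed))


def _dosage(h1: np.ndarray, h2: np.ndarray, k: int) -> np.ndarray:
    """(n, k) dosage matrix from two haplotype-code arrays."""
    j = np.arange(k)
    return (((h1[:, None] >> j) & 1) + ((h2[:, None] >> j) & 1)).astype(np.int8)


def simulate_study(cfg: SimConfig) -> tuple[GenotypeDataset, ExposureTable, SimTruth]:
    """Generate a full synthetic study: genotypes, exposures, and the truth
    record sufficient to recompute any summary exactly."""
    n = cfg.n_families
    n_exposed = int(round(cfg.exposed_fraction * n))
    n_unexposed = n - n_exposed
    if any(s == 0 for s in (n_exposed, n_unexposed)) and cfg.exposed_fraction not in (0, 1):
        raise ValueError("degenerate stratum size")
    stratum = np.array([UNEXPOSED] * n_unexposed + [EXPOSED] * n_exposed)

    ss = np.random.SeedSequence(cfg.seed)
    s_loci, s_dyad, s_miss, s_err, s_expna = ss.spawn(5)
    locus_seeds = s_loci.spawn(len(cfg.loci))

    # latent haplotypes per locus, family-aligned (unexposed block first)
    truth_loci: dict[str, dict[str, np.ndarray]] = {}
    markers_rows = []
    dose_blocks = {"m": [], "f": [], "c": []}
    for locus, lseed in zip(cfg.loci, locus_seeds):
        rng = np.random.default_rng(lseed)
        draws = {
            UNEXPOSED: _simulate_stratum_rng(
                n_unexposed, locus.freqs[UNEXPOSED], locus.rr[UNEXPOSED], rng),
            EXPOSED: _simulate_stratum_rng(
                n_exposed, locus.freqs[EXPOSED], locus.rr[EXPOSED], rng),
        }
        lat = {
            key: np.concatenate([getattr(draws[UNEXPOSED], key), getattr(draws[EXPOSED], key)])
            for key in ("m1", "m2", "f1", "f2", "tm", "tf")
        }
        truth_loci[locus.label] = lat
        for s_id, pos in zip(locus.snps, locus.positions):
            markers_rows.append((s_id, locus.chrom, pos))
        dose_blocks["m"].append(_dosage(lat["m1"], lat["m2"], locus.k))
        dose_blocks["f"].append(_dosage(lat["f1"], lat["f2"], locus.k))
        dose_blocks["c"].append(_dosage(lat["tm"], lat["tf"], locus.k))

    markers = pd.DataFrame(markers_rows, columns=["snp", "chrom", "pos"])
    m_dose = np.hstack(dose_blocks["m"])
    f_dose = np.hstack(dose_blocks["f"])
    c_dose = np.hstack(dose_blocks["c"])
    n_markers = m_dose.shape[1]

    # dyads: delete one random parent in a fixed-size random subset
    rng_dyad = np.random.default_rng(s_dyad)
    n_dyads = int(round(cfg.dyad_fraction * n))
    dyad_fams = rng_dyad.choice(n, size=n_dyads, replace=False)
    which = rng_dyad.integers(0, 2, size=n_dyads)  # 0 = mother, 1 = father
    deleted = np.full(n, "", dtype=object)
    deleted[dyad_fams] = np.where(which == 0, "mother", "father")

    # assemble person table and calls (mother, father, child per family)
    prow, crow = [], []
    fams: list[Family] = []
    for i in range(n):
        fid = f"F{i:05d}"
        mid, did, cid = f"{fid}_M", f"{fid}_F", f"{fid}_C"
        mother = father = -1
        if deleted[i] != "mother":
            mother = len(prow)
            prow.append((fid, mid, "0", "0", "2", "1"))
            crow.append(m_dose[i])
        if deleted[i] != "father":
            father = len(prow)
            prow.append((fid, did, "0", "0", "1", "1"))
            crow.append(f_dose[i])
        child = len(prow)
        prow.append((fid, cid, did, mid, "0", "2"))
        crow.append(c_dose[i])
        fams.append(Family(fid=fid, child=child, mother=mother, father=father))

    persons = pd.DataFrame(
        prow, columns=["fid", "pid", "father_id", "mother_id", "sex", "phenotype"]
    )
    calls = np.vstack(crow).astype(np.int8)

    # genotype errors: symmetric per-allele flips, applied post-ascertainment
    if cfg.genotype_error_rate > 0:
        rng_err = np.random.default_rng(s_err)
        a1 = (calls >= 1).astype(np.int8)
        a2 = (calls == 2).astype(np.int8)
        flip1 = rng_err.random(calls.shape) < cfg.genotype_error_rate
        flip2 = rng_err.random(calls.shape) < cfg.genotype_error_rate
        calls = ((a1 ^ flip1) + (a2 ^ flip2)).astype(np.int8)

    # genotype missingness
    if cfg.genotype_missing_rate > 0:
        rng_miss = np.random.default_rng(s_miss)
        calls[rng_miss.random(calls.shape) < cfg.genotype_missing_rate] = MISSING

    alleles = [("1", "2")] * n_markers
    ds = GenotypeDataset(
        markers=markers, alleles=alleles, persons=persons, calls=calls, families=fams
    )
    ds.validate()

    # exposures with injected NA
    rng_na = np.random.default_rng(s_expna)
    observed = rng_na.random(n) >= cfg.exposure_missing_rate
    codes = np.where(observed, np.where(stratum == EXPOSED, "yes", "no"), "NA")
    exp_df = pd.DataFrame(
        {cfg.exposure_name: [_decode(c) for c in codes]},
        index=pd.Index([f.fid for f in fams], name="family_id"),
    )
    exposures = ExposureTable(table=exp_df)

    truth = SimTruth(
        config=cfg, stratum=stratum, loci=truth_loci,
        deleted_parent=deleted, exposure_observed=observed,
    )
    return ds, exposures, truth


def _decode(code: str) -> str:
    return {"yes": EXPOSED, "no": UNEXPOSED, "NA": "unknown"}[code]


def write_exposure_tsv(exposures: ExposureTable, path) -> None:
    """Serialize an ExposureTable back to the yes/no/NA TSV dialect."""
    enc = {EXPOSED: "yes", UNEXPOSED: "no", "unknown": "NA"}
    df = exposures.table.replace(enc)
    df.to_csv(path, sep="\t")


def dataset_from_trios(trios, n_snps: int, chrom: int | None = None) -> GenotypeDataset:
    """Build a complete-triad dataset directly from (mother, father, child)
    dosage rows (-1 = missing call); handy for constructing exact fixtures."""
    markers = pd.DataFrame({
        "snp": [f"rs{j}" for j in range(n_snps)],
        "chrom": [chrom or 1] * n_snps,
        "pos": [1000 * (j + 1) for j in range(n_snps)],
    })
    prow, calls, fams = [], [], []
    for i, (gm, gf, gc) in enumerate(trios):
        fid = f"F{i:04d}"
        mother = len(prow)
        prow.append((fid, f"{fid}_M", "0", "0", "2", "1")); calls.append(gm)
        father = len(prow)
        prow.append((fid, f"{fid}_F", "0", "0", "1", "1")); calls.append(gf)
        child = len(prow)
        prow.append((fid, f"{fid}_C", f"{fid}_F", f"{fid}_M", "0", "2")); calls.append(gc)
        fams.append(Family(fid=fid, child=child, mother=mother, father=father))
    persons = pd.DataFrame(
        prow, columns=["fid", "pid", "father_id", "mother_id", "sex", "phenotype"]
    )
    ds = GenotypeDataset(
        markers=markers, alleles=[("1", "2")] * n_snps, persons=persons,
        calls=np.asarray(calls, dtype=np.int8), families=fams,
    )
    ds.validate()
    return ds
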