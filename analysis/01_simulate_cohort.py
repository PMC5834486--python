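"""Generate the synthetic study cohort.

Emulates the emulated study's structure — 1,908 case-parent families (314 of
them dyads), a 50/50 maternal vitamin-use split with 5% missing exposure —
with 60 null SNPs plus one planted gene-environment locus (variant frequency
0.40, per-copy child RR 1.0 among non-takers vs 0.6 among takers, the regime
of the reported protective interaction). Writes PED/MAP, the exposure TSV,
and a truth summary under results/.
"""

import json
from pathlib import Path

import numpy as np

import triadscan as ts
from triadscan.sim import write_exposure_tsv

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20_240_101


def build_config() -> ts.SimConfig:
    rng = np.random.default_rng(SEED)
    loci, pos = [], {}
    for j in range(60):
        c = j % 20 + 1
        pos[c] = pos.get(c, 0) + 50_000
        loci.append(ts.LocusSpec.snp(f"rs{j:04d}", chrom=c, pos=pos[c],
                                     maf=float(rng.uniform(0.1, 0.5))))
    planted = ts.LocusSpec(
        snps=("rsGXE",), chrom=21, positions=(1_000_000,),
        freqs={"unexposed": (0.6, 0.4), "exposed": (0.6, 0.4)},
        rr={"unexposed": (1.0, 1.0), "exposed": (1.0, 0.6)},
    )
    loci.append(planted)
    loci.sort(key=lambda l: (l.chrom, l.positions[0]))
    return ts.SimConfig(loci=loci, seed=SEED)


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = build_config()
    ds, exposures, truth = ts.simulate_study(cfg)
    ts.write_pedmap(ds, OUT / "cohort.ped", OUT / "cohort.map")
    write_exposure_tsv(exposures, OUT / "cohort.exposures.tsv")
    summary = {
        "seed": cfg.seed,
        "n_families": ds.n_families,
        "n_markers": ds.n_markers,
        "n_dyads": int((truth.deleted_parent != "").sum()),
        "stratum_counts": truth.stratum_counts(),
        "planted_snp": "rsGXE",
        "planted_rr": {"unexposed": 1.0, "exposed": 0.6},
    }
    (OUT / "cohort.truth.json").write_text(json.dumps(summary, indent=2))
    print(f"wrote {ds.n_families} families x {ds.n_markers} SNPs "
          f"({summary['n_dyads']} dyads) to {OUT}/cohort.*")


if __name__ == "__main__":
    main()
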