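"""Pedigree (PED/MAP) and maternal-exposure I/O.

The on-disk dialect is whitespace-delimited PLINK-style text without headers:

* ``.ped`` — one row per genotyped person: family id, person id, father id,
  mother id, sex, phenotype, then two allele columns per marker. Allele code
  ``0`` is missing; the affected child carries phenotype code ``2``. A missing
  parent (dyad) has no row of their own but is still referenced by id on the
  child's row.
* ``.map`` — one row per marker: chromosome, SNP id, genetic distance
  (ignored), base-pair position (1-based). Only autosomes 1-22 are accepted.

Genotypes are unordered: the allele pair is stored sorted and phase is never
taken from the input (the likelihood machinery reconstructs it). Internally a
marker's calls are kept as the dosage of the lexically larger allele
(0/1/2, -1 missing), which is lossless for biallelic markers.

Exposure tables are TSV with a ``family_id`` column and one yes/no/NA column
per exposure; exposures are maternal, so the join key is the family id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1  # dosage sentinel

EXPOSED = "exposed"
UNEXPOSED = "unexposed"
UNKNOWN = "unknown"

_EXPOSURE_CODES = {
    "yes": EXPOSED, "y": EXPOSED, "1": EXPOSED,
    "no": UNEXPOSED, "n": UNEXPOSED, "0": UNEXPOSED,
    "na": UNKNOWN, "nan": UNKNOWN, "": UNKNOWN, ".": UNKNOWN,
}


class PedigreeError(ValueError):
    """Malformed PED/MAP content (ragged line, bad family structure...)."""


@dataclass(frozen=True)
class Family:
    """One nuclear family: row indices into the person table (-1 = absent)."""

    fid: str
    child: int
    mother: int = -1
    father: int = -1

    @property
    def n_parents(self) -> int:
        return int(self.mother >= 0) + int(self.father >= 0)


@dataclass
class GenotypeDataset:
    """Case-parent families x biallelic autosomal SNPs.

    Attributes
    ----------
    markers : DataFrame with columns ``snp``, ``chrom``, ``pos``, ordered
        strictly by (chrom, pos).
    alleles : per-marker (a1, a2) observed allele labels, lexically sorted;
        ``None`` where an allele was never observed. Dosage counts copies
        of ``a2``.
    persons : DataFrame with columns ``fid``, ``pid``, ``father_id``,
        ``mother_id``, ``sex``, ``phenotype`` (all strings), in file order.
    calls : int8 array (n_persons, n_markers) of dosages, -1 = missing.
    families : one record per family; exactly one affected child each,
        0-2 parents present.
    """

    markers: pd.DataFrame
    alleles: list[tuple[str | None, str | None]]
    persons: pd.DataFrame
    calls: np.ndarray
    families: list[Family] = field(default_factory=list)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    @property
    def n_families(self) -> int:
        return len(self.families)

    def validate(self) -> None:
        if self.calls.shape != (self.n_persons, self.n_markers):
            raise PedigreeError(
                f"calls shape {self.calls.shape} != (persons, markers) "
                f"({self.n_persons}, {self.n_markers})"
            )
        if len(self.alleles) != self.n_markers:
            raise PedigreeError("alleles list does not match marker count")
        key = list(zip(self.markers["chrom"], self.markers["pos"]))
        if any(b <= a for a, b in zip(key, key[1:])):
            raise PedigreeError("markers not strictly increasing by (chrom, pos)")
        bad = set(self.markers["chrom"]) - set(range(1, 23))
        if bad:
            raise PedigreeError(f"non-autosomal chromosome codes: {sorted(bad)}")
        for fam in self.families:
            if not 0 <= fam.child < self.n_persons:
                raise PedigreeError(f"family {fam.fid}: bad child index")

    # --- indexing helpers -------------------------------------------------

    def founder_rows(self) -> np.ndarray:
        """Row indices of all genotyped parents (the founders)."""
        idx = [i for f in self.families for i in (f.mother, f.father) if i >= 0]
        return np.asarray(idx, dtype=int)

    def child_rows(self) -> np.ndarray:
        return np.asarray([f.child for f in self.families], dtype=int)

    def family_role_matrix(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(mother, father, child) row indices per family, -1 where absent."""
        m = np.asarray([f.mother for f in self.families], dtype=int)
        f_ = np.asarray([f.father for f in self.families], dtype=int)
        c = np.asarray([f.child for f in self.families], dtype=int)
        return m, f_, c

    def family_window_genotypes(
        self, fam: Family, marker_idx: list[int] | np.ndarray
    ) -> tuple[tuple[int, ...], tuple[int, ...], tuple[int, ...]]:
        """(mother, father, child) dosage tuples over a window; absent parent
        is all-missing."""
        idx = np.asarray(marker_idx, dtype=int)
        missing = tuple([MISSING] * len(idx))

        def row(i: int) -> tuple[int, ...]:
            return missing if i < 0 else tuple(int(x) for x in self.calls[i, idx])

        return row(fam.mother), row(fam.father), row(fam.child)

    # --- subsetting (used by QC) -----------------------------------------

    def subset_markers(self, keep: np.ndarray) -> "GenotypeDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeDataset(
            markers=self.markers.iloc[keep].reset_index(drop=True),
            alleles=[self.alleles[i] for i in keep],
            persons=self.persons.copy(),
            calls=self.calls[:, keep].copy(),
            families=list(self.families),
        )

    def drop_persons(self, drop_rows: np.ndarray) -> "GenotypeDataset":
        """Remove persons (e.g. low call rate). A dropped parent demotes the
        family to a dyad; a dropped child removes the family."""
        drop = set(int(i) for i in np.atleast_1d(drop_rows))
        keep = [i for i in range(self.n_persons) if i not in drop]
        remap = {old: new for new, old in enumerate(keep)}
        fams = []
        for f in self.families:
            if f.child in drop:
                continue
            fams.append(
                Family(
                    fid=f.fid,
                    child=remap[f.child],
                    mother=remap.get(f.mother, -1) if f.mother >= 0 else -1,
                    father=remap.get(f.father, -1) if f.father >= 0 else -1,
                )
            )
        return GenotypeDataset(
            markers=self.markers.copy(),
            alleles=list(self.alleles),
            persons=self.persons.iloc[keep].reset_index(drop=True),
            calls=self.calls[keep, :].copy(),
            families=fams,
        )


# ---------------------------------------------------------------------------
# PED/MAP reading
# ---------------------------------------------------------------------------


def _read_map(map_path) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise PedigreeError(
                    f"{map_path}:{lineno}: expected 4 MAP columns, got {len(parts)}"
                )
            chrom_s, snp, _gendist, pos_s = parts
            try:
                chrom, pos = int(chrom_s), int(pos_s)
            except ValueError as e:
                raise PedigreeError(f"{map_path}:{lineno}: bad chrom/pos") from e
            rows.append((snp, chrom, pos))
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos"])


def read_pedmap(ped_path, map_path, keep_first_affected: bool = False) -> GenotypeDataset:
    """Read a PED/MAP pair into a :class:`GenotypeDataset`.

    Parameters
    ----------
    keep_first_affected : if a family contains more than one offspring row,
        keep the first affected child and drop the other offspring instead of
        rejecting the family (strict mode, the default).
    """
    markers = _read_map(map_path)
    m = len(markers)

    prows: list[tuple[str, str, str, str, str, str]] = []
    geno_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise PedigreeError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} columns "
                    f"(6 + 2x{m} markers), got {len(parts)}"
                )
            prows.append(tuple(parts[:6]))
            geno_rows.append(parts[6:])

    persons = pd.DataFrame(
        prows, columns=["fid", "pid", "father_id", "mother_id", "sex", "phenotype"]
    )
    n = len(persons)

    # per-marker allele alphabet, then dosage encoding
    alleles: list[tuple[str | None, str | None]] = []
    calls = np.full((n, m), MISSING, dtype=np.int8)
    if n:
        raw = np.array(geno_rows, dtype=object).reshape(n, m, 2)
        for j in range(m):
            col = raw[:, j, :]
            labels = sorted({a for a in col.ravel() if a != "0"})
            if len(labels) > 2:
                raise PedigreeError(
                    f"marker {markers['snp'][j]}: >2 allele symbols {labels}"
                )
            a1 = labels[0] if labels else None
            a2 = labels[1] if len(labels) > 1 else None
            alleles.append((a1, a2))
            obs = (col[:, 0] != "0") & (col[:, 1] != "0")
            if ((col[:, 0] == "0") ^ (col[:, 1] == "0")).any():
                raise PedigreeError(
                    f"marker {markers['snp'][j]}: half-missing genotype (one allele 0)"
                )
            if a2 is not None:
                dose = (col[:, 0] == a2).astype(np.int8) + (col[:, 1] == a2).astype(np.int8)
            else:
                dose = np.zeros(n, dtype=np.int8)
            calls[obs, j] = dose[obs]
    else:
        alleles = [(None, None)] * m

    fams, drop_rows = _link_families(persons, keep_first_affected)
    ds = GenotypeDataset(
        markers=markers, alleles=alleles, persons=persons, calls=calls, families=fams
    )
    if drop_rows:
        ds = ds.drop_persons(np.asarray(sorted(drop_rows)))
    ds.validate()
    logger.info(
        "read %d persons, %d families, %d markers from %s",
        ds.n_persons, ds.n_families, ds.n_markers, ped_path,
    )
    return ds


def _link_families(
    persons: pd.DataFrame, keep_first_affected: bool
) -> tuple[list[Family], list[int]]:
    """Infer mother/father/child roles from the father-id/mother-id links."""
    families: list[Family] = []
    drop_rows: list[int] = []
    by_fid: dict[str, list[int]] = {}
    for i, fid in enumerate(persons["fid"]):
        by_fid.setdefault(fid, []).append(i)
    index = {(persons["fid"][i], persons["pid"][i]): i for i in range(len(persons))}

    for fid, rows in by_fid.items():
        offspring = [
            i for i in rows
            if persons["father_id"][i] != "0" or persons["mother_id"][i] != "0"
            or persons["phenotype"][i] == "2"
        ]
        affected = [i for i in offspring if persons["phenotype"][i] == "2"]
        if len(affected) == 0:
            raise PedigreeError(f"family {fid}: no affected child (phenotype 2)")
        if len(affected) > 1 or len(offspring) > 1:
            if not keep_first_affected:
                raise PedigreeError(
                    f"family {fid}: {len(offspring)} offspring rows "
                    f"({len(affected)} affected); strict mode keeps triads/dyads only"
                )
            child = affected[0]
            drop_rows.extend(i for i in offspring if i != child)
        else:
            child = affected[0]
        mother = index.get((fid, persons["mother_id"][child]), -1)
        father = index.get((fid, persons["father_id"][child]), -1)
        extras = set(rows) - {child, mother, father} - set(drop_rows)
        if extras:
            raise PedigreeError(
                f"family {fid}: rows not linked as parents of the affected child: "
                f"{sorted(persons['pid'][i] for i in extras)}"
            )
        families.append(Family(fid=fid, child=child, mother=mother, father=father))
    return families, drop_rows


# ---------------------------------------------------------------------------
# PED/MAP writing
# ---------------------------------------------------------------------------


def write_pedmap(ds: GenotypeDataset, ped_path, map_path) -> None:
    """Write a dataset back to PED/MAP; inverse of :func:`read_pedmap`.

    Output is single-space delimited; allele pairs are written sorted, so
    ``read_pedmap(write_pedmap(ds))`` reproduces ``ds`` exactly.
    """
    with open(map_path, "w") as fh:
        for _, r in ds.markers.iterrows():
            fh.write(f"{r['chrom']} {r['snp']} 0 {r['pos']}\n")

    with open(ped_path, "w") as fh:
        for i in range(ds.n_persons):
            p = ds.persons.iloc[i]
            fields = [p["fid"], p["pid"], p["father_id"], p["mother_id"],
                      p["sex"], p["phenotype"]]
            for j in range(ds.n_markers):
                d = ds.calls[i, j]
                a1, a2 = ds.alleles[j]
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [a1, a1]
                elif d == 1:
                    fields += [a1, a2]
                else:
                    fields += [a2, a2]
            fh.write(" ".join(fields) + "\n")
    logger.info("wrote %d persons x %d markers to %s", ds.n_persons, ds.n_markers, ped_path)


# ---------------------------------------------------------------------------
# Exposure tables
# ---------------------------------------------------------------------------


@dataclass
class ExposureTable:
    """Per-family maternal exposure status: exposed / unexposed / unknown."""

    table: pd.DataFrame  # index = family_id, one column per exposure

    @property
    def exposures(self) -> list[str]:
        return list(self.table.columns)

    def status(self, fid: str, exposure: str) -> str:
        if fid not in self.table.index:
            return UNKNOWN
        return self.table.loc[fid, exposure]

    def strata(self, ds: GenotypeDataset, exposure: str) -> np.ndarray:
        """Per-family status array aligned with ``ds.families``."""
        return np.asarray([self.status(f.fid, exposure) for f in ds.families])

    def reconcile(self, ds: GenotypeDataset, exposure: str) -> dict[str, int]:
        """Counts per stratum for a dataset, families absent from the table
        counted as unknown."""
        s = self.strata(ds, exposure)
        return {
            EXPOSED: int((s == EXPOSED).sum()),
            UNEXPOSED: int((s == UNEXPOSED).sum()),
            UNKNOWN: int((s == UNKNOWN).sum()),
            "absent_from_table": sum(f.fid not in self.table.index for f in ds.families),
        }


def read_exposures(path, exposure_names: list[str] | None = None) -> ExposureTable:
    """Read a TSV exposure table (header ``family_id<TAB><exposure>...``).

    Codes yes/no/NA (case-insensitive) map to exposed/unexposed/unknown;
    any other code or a duplicated family id is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "family_id" not in df.columns:
        raise ValueError(f"{path}: missing family_id column")
    if exposure_names is None:
        exposure_names = [c for c in df.columns if c != "family_id"]
    missing_cols = set(exposure_names) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing exposure columns {sorted(missing_cols)}")
    dup = df["family_id"][df["family_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate family_id {sorted(set(dup))}")

    out = df.set_index("family_id")[exposure_names].copy()
    n_rejected = 0
    for col in exposure_names:
        decoded = []
        for rowno, v in enumerate(out[col]):
            code = _EXPOSURE_CODES.get(str(v).strip().lower())
            if code is None:
                raise ValueError(
                    f"{path}: row {rowno + 2} exposure {col!r}: "
                    f"unrecognized code {v!r} (expected yes/no/NA)"
                )
            decoded.append(code)
        out[col] = decoded
    logger.info("read %d exposure rows from %s (%d rejected)", len(out), path, n_rejected)
    return ExposureTable(table=out)
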