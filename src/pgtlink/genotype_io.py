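"""Core containers and tabular I/O for the PGT-M pipeline.

Conventions
-----------
* Variant coordinates are 1-based inclusive (VCF convention).
* Coverage bins are 0-based half-open (BED convention).
* Diploid genotypes are coded internally as integers:
  ``0`` hom-ref, ``1`` het, ``2`` hom-alt, ``-1`` missing.
* The TSV genotype dialect spells calls ``AA`` (hom-ref), ``AB`` (het),
  ``BB`` (hom-alt), ``NC`` (no call); the VCF dialect honours only
  CHROM, POS, ID, REF, ALT and the GT field (chip exports carry no
  depth information), with missing spelled ``./.``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

_TSV_TO_CODE = {"AA": HOM_REF, "AB": HET, "BA": HET, "BB": HOM_ALT, "NC": MISSING}
_CODE_TO_TSV = {HOM_REF: "AA", HET: "AB", HOM_ALT: "BB", MISSING: "NC"}
_CODE_TO_VCF = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}

ROLES = ("father", "mother", "reference_embryo", "embryo", "fetus")
CARRIER_STATUSES = ("carrier", "non_carrier", "unknown")


class GenotypeIOError(ValueError):
    """Raised on malformed or internally inconsistent tabular input."""


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNP site, 1-based coordinates."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    site_id: str = ""

    def __post_init__(self):
        if self.pos < 1:
            raise GenotypeIOError(f"site position must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise GenotypeIOError(
                f"ref and alt alleles identical at {self.chrom}:{self.pos}"
            )


@dataclass(frozen=True)
class PedigreeSample:
    sample_id: str
    role: str
    carrier_status: str = "unknown"

    def __post_init__(self):
        if self.role not in ROLES:
            raise GenotypeIOError(f"unknown role {self.role!r}")
        if self.carrier_status not in CARRIER_STATUSES:
            raise GenotypeIOError(f"unknown carrier status {self.carrier_status!r}")


@dataclass
class Pedigree:
    """Named roles of a nuclear PGT family.

    Exactly one father and one mother are required; at most one
    reference embryo (the "waste embryo" proband anchoring parental
    phase) is allowed.
    """

    samples: list[PedigreeSample] = field(default_factory=list)

    def __post_init__(self):
        for role, lo, hi in (("father", 1, 1), ("mother", 1, 1),
                             ("reference_embryo", 0, 1)):
            n = sum(1 for s in self.samples if s.role == role)
            if not lo <= n <= hi:
                raise GenotypeIOError(f"pedigree needs {lo}..{hi} {role}, found {n}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise GenotypeIOError("duplicate sample_id in pedigree")

    def by_role(self, role: str) -> list[PedigreeSample]:
        return [s for s in self.samples if s.role == role]

    def one(self, role: str) -> PedigreeSample:
        found = self.by_role(role)
        if len(found) != 1:
            raise GenotypeIOError(f"expected exactly one {role}, found {len(found)}")
        return found[0]

    @property
    def father(self) -> PedigreeSample:
        return self.one("father")

    @property
    def mother(self) -> PedigreeSample:
        return self.one("mother")

    @property
    def reference_embryo(self) -> PedigreeSample | None:
        found = self.by_role("reference_embryo")
        return found[0] if found else None

    @property
    def embryos(self) -> list[PedigreeSample]:
        return self.by_role("embryo")


class GenotypeMatrix:
    """Sites x samples grid of diploid genotype calls.

    Sites are kept strictly sorted by (chrom, pos); calls are an int8
    array aligned with ``sites`` rows and ``sample_ids`` columns.
    """

    def __init__(self, sites: Sequence[VariantSite], sample_ids: Sequence[str],
                 calls: np.ndarray):
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(sites), len(sample_ids)):
            raise GenotypeIOError(
                f"calls shape {calls.shape} != ({len(sites)}, {len(sample_ids)})"
            )
        bad = ~np.isin(calls, (HOM_REF, HET, HOM_ALT, MISSING))
        if bad.any():
            raise GenotypeIOError("genotype codes must be in {-1, 0, 1, 2}")
        order = sorted(range(len(sites)), key=lambda i: (sites[i].chrom, sites[i].pos))
        self.sites: list[VariantSite] = [sites[i] for i in order]
        self.sample_ids: list[str] = list(sample_ids)
        self.calls: np.ndarray = calls[order]
        keys = [(s.chrom, s.pos) for s in self.sites]
        if len(set(keys)) != len(keys):
            raise GenotypeIOError("duplicate (chrom, pos) in sites")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise GenotypeIOError(f"sample {sample_id!r} not in matrix") from None

    def column(self, sample_id: str) -> np.ndarray:
        return self.calls[:, self.sample_index(sample_id)]

    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    def site_index(self, chrom: str, pos: int) -> int:
        for i, s in enumerate(self.sites):
            if s.chrom == chrom and s.pos == pos:
                return i
        raise GenotypeIOError(f"site {chrom}:{pos} not in matrix")

    def __eq__(self, other) -> bool:
        return (isinstance(other, GenotypeMatrix)
                and self.sites == other.sites
                and self.sample_ids == other.sample_ids
                and np.array_equal(self.calls, other.calls))


# ---------------------------------------------------------------------------
# genotype matrices
# ---------------------------------------------------------------------------

def write_genotypes(matrix: GenotypeMatrix, path: str | Path,
                    dialect: str = "tsv") -> None:
    """Write a genotype matrix as chip-export TSV or minimal GT-only VCF."""
    path = Path(path)
    if dialect == "tsv":
        rows = []
        for i, s in enumerate(matrix.sites):
            row = {"snp_id": s.site_id or f"{s.chrom}_{s.pos}", "chrom": s.chrom,
                   "pos": s.pos, "ref": s.ref_allele, "alt": s.alt_allele}
            for j, sid in enumerate(matrix.sample_ids):
                row[sid] = _CODE_TO_TSV[int(matrix.calls[i, j])]
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    elif dialect == "vcf":
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for chrom in dict.fromkeys(s.chrom for s in matrix.sites):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(matrix.sample_ids) + "\n")
            for i, s in enumerate(matrix.sites):
                gts = "\t".join(_CODE_TO_VCF[int(c)] for c in matrix.calls[i])
                fh.write(f"{s.chrom}\t{s.pos}\t{s.site_id or '.'}\t{s.ref_allele}"
                         f"\t{s.alt_allele}\t.\t.\t.\tGT\t{gts}\n")
    else:
        raise GenotypeIOError(f"unknown dialect {dialect!r}")


def read_genotypes(path: str | Path, dialect: str = "tsv",
                   pedigree: Pedigree | None = None) -> GenotypeMatrix:
    """Read a genotype matrix, normalizing calls to the internal coding.

    Unknown TSV codes become missing (a warning counts them); duplicate
    sites, non-biallelic VCF records and (if a pedigree is given)
    sample-set mismatches are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise GenotypeIOError(f"no such file: {path}")
    if dialect == "tsv":
        matrix = _read_tsv(path)
    elif dialect == "vcf":
        matrix = _read_vcf(path)
    else:
        raise GenotypeIOError(f"unknown dialect {dialect!r}")
    if pedigree is not None:
        missing = {s.sample_id for s in pedigree.samples
                   if s.role != "fetus"} - set(matrix.sample_ids)
        if missing:
            raise GenotypeIOError(f"pedigree samples absent from matrix: "
                                  f"{sorted(missing)}")
    return matrix


def _read_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    fixed = ["snp_id", "chrom", "pos", "ref", "alt"]
    if list(df.columns[:5]) != fixed:
        raise GenotypeIOError(f"TSV must start with columns {fixed}")
    sample_ids = list(df.columns[5:])
    sites = [VariantSite(r.chrom, int(r.pos), r.ref, r.alt, r.snp_id)
             for r in df.itertuples()]
    n_unknown = 0
    calls = np.full((len(sites), len(sample_ids)), MISSING, dtype=np.int8)
    for j, sid in enumerate(sample_ids):
        for i, raw in enumerate(df[sid]):
            code = _TSV_TO_CODE.get(str(raw).strip().upper())
            if code is None:
                n_unknown += 1
                code = MISSING
            calls[i, j] = code
    if n_unknown:
        warnings.warn(f"{n_unknown} unrecognized genotype codes set to missing")
        logger.warning("%d unrecognized genotype codes set to missing", n_unknown)
    return GenotypeMatrix(sites, sample_ids, calls)


def _read_vcf(path: Path) -> GenotypeMatrix:
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        sample_ids = list(vf.header.samples)
        sites, rows = [], []
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise GenotypeIOError(
                    f"non-biallelic record at {rec.chrom}:{rec.pos}")
            sites.append(VariantSite(rec.chrom, rec.pos, rec.ref, rec.alts[0],
                                     rec.id or ""))
            row = []
            for sid in sample_ids:
                gt = rec.samples[sid].get("GT")
                if gt is None or any(a is None for a in gt):
                    row.append(MISSING)
                else:
                    row.append(int(sum(gt)))  # 0/1 and 1/0 both -> het
            rows.append(row)
    return GenotypeMatrix(sites, sample_ids, np.array(rows, dtype=np.int8))


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\trole\tcarrier_status\n")
        for s in ped.samples:
            fh.write(f"{s.sample_id}\t{s.role}\t{s.carrier_status}\n")


def read_pedigree(path: str | Path) -> Pedigree:
    path = Path(path)
    if not path.exists():
        raise GenotypeIOError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"sample_id", "role", "carrier_status"}
    if not need <= set(df.columns):
        raise GenotypeIOError(f"pedigree file must have columns {sorted(need)}")
    return Pedigree([PedigreeSample(r.sample_id, r.role, r.carrier_status)
                     for r in df.itertuples()])


# ---------------------------------------------------------------------------
# binned coverage (BED-like, 0-based half-open)
# ---------------------------------------------------------------------------

def write_binned_coverage(bins: pd.DataFrame, path: str | Path) -> None:
    """``bins`` columns: chrom, start, end, count."""
    bins[["chrom", "start", "end", "count"]].to_csv(path, sep="\t", index=False)


def read_binned_coverage(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t",
                     dtype={"chrom": str, "start": np.int64,
                            "end": np.int64, "count": np.int64})
    if (df["count"] < 0).any():
        raise GenotypeIOError("negative bin counts")
    if (df["end"] <= df["start"]).any():
        raise GenotypeIOError("empty or inverted bins")
    return df


# ---------------------------------------------------------------------------
# cfDNA allele-depth table
# ---------------------------------------------------------------------------

CFDNA_COLUMNS = ["chrom", "pos", "ref", "alt", "ref_depth", "alt_depth"]


def write_cfdna_table(table: pd.DataFrame, path: str | Path) -> None:
    table[CFDNA_COLUMNS].to_csv(path, sep="\t", index=False)


def read_cfdna_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if not set(CFDNA_COLUMNS) <= set(df.columns):
        raise GenotypeIOError(f"cfDNA table needs columns {CFDNA_COLUMNS}")
    if (df[["ref_depth", "alt_depth"]] < 0).any().any():
        raise GenotypeIOError("negative cfDNA depths")
    return df


# ---------------------------------------------------------------------------
# diagnosis report
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "embryo_id", "n_M1_up", "n_M2_up", "n_M1_down", "n_M2_down",
    "haplotype_call", "recombination_breakpoints", "direct_test",
    "concordant", "final_status",
]


def write_report(diagnoses: Iterable, path: str | Path) -> None:
    """Write per-embryo diagnoses as TSV with a machine-readable JSON twin.

    Each diagnosis provides the fields in ``REPORT_COLUMNS`` (dataclass
    attributes or mapping keys). The JSON twin is written next to the
    TSV with a ``.json`` suffix.
    """
    path = Path(path)
    rows = []
    for d in diagnoses:
        get = d.get if isinstance(d, dict) else lambda k, _d=d: getattr(_d, k)
        rows.append({k: get(k) for k in REPORT_COLUMNS})
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for row in rows:
            out = dict(row)
            out["recombination_breakpoints"] = ",".join(
                f"{a}-{b}" for a, b in row["recombination_breakpoints"])
            fh.write("\t".join(str(out[k]) for k in REPORT_COLUMNS) + "\n")
    json_rows = [dict(row, recombination_breakpoints=[
        list(bp) for bp in row["recombination_breakpoints"]]) for row in rows]
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(json_rows, fh, indent=2, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def read_report_json(path: str | Path) -> list[dict]:
    with open(path) as fh:
        return json.load(fh)
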