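"""On-disk formats: PLINK bed/bim/fam, pedigree/phenotype CSVs, result TSVs,
and the YAML run configuration.

Coordinates are 1-based inclusive throughout (bim convention).  Allele
content counts the bim A1 allele by default; pass ``count_a1=False`` to
flip orientation.  Missing genotypes are ``NaN`` in the in-memory matrix —
no sentinel ever leaks into arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .pedigree import PedigreeTable

__all__ = [
    "FormatError",
    "SnpMap",
    "RunConfig",
    "read_genotypes",
    "write_genotypes",
    "read_genotypes_csv",
    "read_pedigree",
    "write_pedigree",
    "read_assoc",
    "write_assoc",
    "read_individual_phenotypes",
    "read_cage_feed",
    "read_body_weights",
]

log = logging.getLogger("cagewas")

ASSOC_COLUMNS = [
    "snp_id", "chromosome", "position_bp", "effect", "se",
    "lrt", "p", "q", "method", "trait",
]


class FormatError(ValueError):
    """Raised when an input file set is malformed or internally inconsistent."""


@dataclass(frozen=True)
class SnpMap:
    """Genomic coordinates of the SNP panel (1-based positions)."""

    snp_id: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray
    allele1: Optional[np.ndarray] = None
    allele2: Optional[np.ndarray] = None

    def __post_init__(self):
        object.__setattr__(self, "snp_id", np.asarray(self.snp_id, dtype=object))
        object.__setattr__(self, "chromosome", np.asarray(self.chromosome, dtype=object))
        object.__setattr__(self, "position_bp", np.asarray(self.position_bp, dtype=np.int64))
        if len(set(self.snp_id)) != len(self.snp_id):
            raise FormatError("snp ids are not unique")
        if np.any(self.position_bp <= 0):
            raise FormatError("positions must be strictly positive (1-based)")
        n = len(self.snp_id)
        if len(self.chromosome) != n or len(self.position_bp) != n:
            raise FormatError("snp map columns differ in length")

    def __len__(self) -> int:
        return len(self.snp_id)

    def to_dataframe(self) -> pd.DataFrame:
        d = {
            "snp_id": self.snp_id,
            "chromosome": self.chromosome,
            "position_bp": self.position_bp,
        }
        if self.allele1 is not None:
            d["allele1"] = self.allele1
            d["allele2"] = self.allele2
        return pd.DataFrame(d)

    def subset(self, mask_or_index) -> "SnpMap":
        i = np.asarray(mask_or_index)
        return SnpMap(
            snp_id=self.snp_id[i],
            chromosome=self.chromosome[i],
            position_bp=self.position_bp[i],
            allele1=None if self.allele1 is None else np.asarray(self.allele1, object)[i],
            allele2=None if self.allele2 is None else np.asarray(self.allele2, object)[i],
        )


@dataclass
class RunConfig:
    """Pipeline-level thresholds and knobs (serialised as YAML)."""

    sample_call_rate: float = 0.90     # keep samples with call rate >= this
    snp_missing_max: float = 0.05      # keep SNPs with missingness < this
    maf_min: float = 0.05              # keep SNPs with MAF > this (strict)
    correction_level: str = "chromosome"   # 'genome' | 'chromosome'
    pfdr: float = 0.05
    region_gap_bp: int = 1_000_000
    annotation_window_bp: int = 1_000_000
    em_tol: float = 1e-6
    em_max_iter: int = 500
    count_a1: bool = True
    freq_from_mu: bool = False         # SNP frequency from fitted mean/2 instead of observed
    mid_fattening_day: float = 43.0
    metabolic_exponent: float = 0.75
    rfi_common_slopes: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("sample_call_rate", "snp_missing_max", "maf_min", "pfdr"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.correction_level not in ("genome", "chromosome"):
            raise ValueError("correction_level must be 'genome' or 'chromosome'")
        if self.region_gap_bp <= 0 or self.annotation_window_bp <= 0:
            raise ValueError("region gap and annotation window must be > 0")
        if self.em_tol <= 0 or self.em_max_iter < 1:
            raise ValueError("bad EM tolerances")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# 2-bit code -> A1 allele count: 00 hom A1 (2), 01 missing, 10 het (1), 11 hom A2 (0)
_CODE_TO_COUNT = np.array([2.0, np.nan, 1.0, 0.0])


def _byte_lut() -> np.ndarray:
    """(256, 4) table mapping a packed byte to four A1 counts."""
    codes = np.arange(256, dtype=np.uint8)
    out = np.empty((256, 4))
    for k in range(4):
        out[:, k] = _CODE_TO_COUNT[(codes >> (2 * k)) & 0b11]
    return out


_LUT = _byte_lut()


def read_genotypes(path_prefix, *, count_a1: bool = True, dtype=np.float64):
    """Read a PLINK ``.bed/.bim/.fam`` file set.

    Returns ``(GenotypeMatrix, SnpMap)`` with allele content coded 0/1/2
    (count of the bim A1 allele unless ``count_a1=False``), missing as NaN,
    and sample rows in fam order.
    """
    from .genotype_qc import GenotypeMatrix  # deferred: avoids import cycle

    prefix = Path(path_prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"iid": str, "fid": str},
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chromosome", "snp_id", "cm", "position_bp", "allele1", "allele2"],
        dtype={"chromosome": str, "snp_id": str},
    )
    n, m = len(fam), len(bim)
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic bytes")
    if raw[2] != _SNP_MAJOR:
        raise FormatError(f"{prefix}.bed: only SNP-major layout is supported")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != m * bytes_per_snp:
        raise FormatError(
            f"{prefix}.bed: size {body.size} does not match "
            f"{n} samples x {m} SNPs from fam/bim"
        )
    lut = _LUT if dtype == np.float64 else _LUT.astype(dtype)
    decoded = lut[body.reshape(m, bytes_per_snp)].reshape(m, bytes_per_snp * 4)
    values = np.ascontiguousarray(decoded[:, :n].T)
    if not count_a1:
        values = 2.0 - values
    snp_map = SnpMap(
        snp_id=bim["snp_id"].to_numpy(object),
        chromosome=bim["chromosome"].to_numpy(object),
        position_bp=bim["position_bp"].to_numpy(),
        allele1=bim["allele1"].to_numpy(object),
        allele2=bim["allele2"].to_numpy(object),
    )
    G = GenotypeMatrix(sample_ids=tuple(fam["iid"]), snp_ids=tuple(bim["snp_id"]),
                       values=values)
    return G, snp_map


def write_genotypes(path_prefix, G, snp_map: SnpMap, *, count_a1: bool = True) -> None:
    """Write a ``GenotypeMatrix`` + ``SnpMap`` as a bed/bim/fam set."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = G.values.shape
    if m != len(snp_map):
        raise FormatError("genotype matrix and snp map disagree on SNP count")
    vals = G.values if count_a1 else 2.0 - G.values
    # A1-count -> 2-bit code (missing -> 01)
    code = np.full(vals.shape, 1, dtype=np.uint8)
    code[vals == 2] = 0b00
    code[vals == 1] = 0b10
    code[vals == 0] = 0b11
    bytes_per_snp = (n + 3) // 4
    padded = np.ones((m, bytes_per_snp * 4), dtype=np.uint8) * 0b11  # pad hom A2
    padded[:, :n] = code.T
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
        fh.write(packed.tobytes())
    fam = pd.DataFrame(
        {
            "fid": list(G.sample_ids),
            "iid": list(G.sample_ids),
            "father": 0,
            "mother": 0,
            "sex": 0,
            "phenotype": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep=" ", header=False, index=False)
    a1 = snp_map.allele1 if snp_map.allele1 is not None else np.full(m, "A", object)
    a2 = snp_map.allele2 if snp_map.allele2 is not None else np.full(m, "B", object)
    bim = pd.DataFrame(
        {
            "chromosome": snp_map.chromosome,
            "snp_id": snp_map.snp_id,
            "cm": 0,
            "position_bp": snp_map.position_bp,
            "allele1": a1,
            "allele2": a2,
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)


def read_genotypes_csv(path, map_path=None):
    """Fallback reader: plain 0/1/2 matrix CSV (rows = samples, cols = SNPs).

    Optional companion map CSV with snp_id/chromosome/position_bp columns.
    """
    from .genotype_qc import GenotypeMatrix

    df = pd.read_csv(path, index_col=0)
    G = GenotypeMatrix(
        sample_ids=tuple(df.index.astype(str)),
        snp_ids=tuple(df.columns.astype(str)),
        values=df.to_numpy(dtype=float),
    )
    snp_map = None
    if map_path is not None:
        m = pd.read_csv(map_path, dtype={"snp_id": str, "chromosome": str})
        snp_map = SnpMap(
            snp_id=m["snp_id"].to_numpy(object),
            chromosome=m["chromosome"].to_numpy(object),
            position_bp=m["position_bp"].to_numpy(),
        )
        if list(snp_map.snp_id) != list(G.snp_ids):
            raise FormatError("map and matrix SNP ids disagree")
    return G, snp_map


# ---------------------------------------------------------------------------
# Pedigree and phenotype CSVs
# ---------------------------------------------------------------------------

def read_pedigree(path) -> PedigreeTable:
    """3-column pedigree CSV (animal, sire, dam); 0/blank = unknown parent."""
    df = pd.read_csv(path, dtype=str).rename(columns=str.lower)
    missing = {"animal", "sire", "dam"} - set(df.columns)
    if missing:
        raise FormatError(f"pedigree file lacks columns: {sorted(missing)}")
    return PedigreeTable.from_records(df["animal"], df["sire"], df["dam"])


def write_pedigree(ped: PedigreeTable, path) -> None:
    pd.DataFrame(
        {
            "animal": list(ped.animal),
            "sire": ["0" if s is None else s for s in ped.sire],
            "dam": ["0" if d is None else d for d in ped.dam],
        }
    ).to_csv(path, index=False)


def read_individual_phenotypes(path) -> pd.DataFrame:
    """Individual records with fixed/random-effect labels.

    Required columns: animal, batch, parity, litter_size_class,
    cage_size_class, cage, litter, regime; plus trait columns (e.g. adg).
    """
    df = pd.read_csv(path, dtype={"animal": str, "cage": str, "litter": str})
    required = {
        "animal", "batch", "parity", "litter_size_class",
        "cage_size_class", "cage", "litter", "regime",
    }
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"phenotype file lacks columns: {sorted(missing)}")
    return df


def read_body_weights(path) -> pd.DataFrame:
    """Long-format weekly body weights: animal, age_days, bw_g."""
    df = pd.read_csv(path, dtype={"animal": str})
    missing = {"animal", "age_days", "bw_g"} - set(df.columns)
    if missing:
        raise FormatError(f"body-weight file lacks columns: {sorted(missing)}")
    return df


def read_cage_feed(path) -> pd.DataFrame:
    """Weekly cage feed: cage, week, feed_g, animal_days."""
    df = pd.read_csv(path, dtype={"cage": str})
    missing = {"cage", "week", "feed_g", "animal_days"} - set(df.columns)
    if missing:
        raise FormatError(f"cage-feed file lacks columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Association results
# ---------------------------------------------------------------------------

def write_assoc(records, path) -> None:
    """Write association records as a Manhattan-plot-ready TSV.

    ``records`` is a DataFrame (or a sequence of mappings) carrying at least
    snp_id/chromosome/position_bp/lrt/p; missing optional columns are
    emitted as empty fields in a stable column order.
    """
    df = pd.DataFrame(records)
    for col in ASSOC_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[ASSOC_COLUMNS]
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_assoc(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values="NA",
                     dtype={"snp_id": str, "chromosome": str})
    missing = set(ASSOC_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"association file lacks columns: {sorted(missing)}")
    return df
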