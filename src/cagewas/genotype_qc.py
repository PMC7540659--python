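"""Genotype quality control, allele frequencies, LD and distance pruning.

Filter semantics follow the conventions used for array data here: samples
are kept when their call rate is at least the threshold, SNPs when their
missingness is strictly below the threshold and their MAF strictly above
the threshold; non-autosomal SNPs are dropped last.  Missing calls are
excluded pairwise in LD computations (no imputation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import SnpMap

__all__ = [
    "GenotypeMatrix",
    "QcReport",
    "qc_filter",
    "ld_r2",
    "prune_by_distance",
    "ld_decay",
]

log = logging.getLogger("cagewas")


@dataclass(frozen=True)
class GenotypeMatrix:
    """Allele-content matrix, samples x SNPs, values in {0, 1, 2, NaN}."""

    sample_ids: tuple
    snp_ids: tuple
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError(
                f"genotype matrix shape {v.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        if v.size:
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", RuntimeWarning)
                lo, hi = np.nanmin(v), np.nanmax(v)
            if np.isfinite(lo) and (lo < 0 or hi > 2):
                raise ValueError("allele content must lie in [0, 2]")
        object.__setattr__(self, "values", v)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def freq(self) -> np.ndarray:
        """Per-SNP allele frequency over non-missing calls (NaN if all missing)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        f = self.freq
        return np.minimum(f, 1.0 - f)

    @property
    def snp_missingness(self) -> np.ndarray:
        return np.isnan(self.values).mean(axis=0)

    @property
    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.values).mean(axis=1)

    def subset(self, *, samples=None, snps=None) -> "GenotypeMatrix":
        """Subset by boolean masks or integer indices (samples and/or SNPs)."""
        si = np.arange(self.n_samples) if samples is None else np.asarray(samples)
        pi = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        if si.dtype == bool:
            si = np.flatnonzero(si)
        if pi.dtype == bool:
            pi = np.flatnonzero(pi)
        return GenotypeMatrix(
            sample_ids=tuple(self.sample_ids[i] for i in si),
            snp_ids=tuple(self.snp_ids[j] for j in pi),
            values=self.values[np.ix_(si, pi)],
        )

    def column(self, snp_id) -> np.ndarray:
        return self.values[:, self.snp_ids.index(snp_id)]


@dataclass(frozen=True)
class QcReport:
    n_samples_in: int
    n_samples_kept: int
    n_snps_in: int
    n_snps_after_missingness: int
    n_snps_after_maf: int
    n_snps_kept: int
    removed_samples: tuple
    steps: tuple  # human-readable log of filter order

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"step": self.steps})


def qc_filter(
    G: GenotypeMatrix,
    snp_map: Optional[SnpMap] = None,
    *,
    sample_call_rate: float = 0.90,
    snp_missing_max: float = 0.05,
    maf_min: float = 0.05,
    autosomes: Optional[Iterable] = None,
):
    """Apply sample, missingness, MAF and autosome filters, in that order.

    Returns ``(G_filtered, snp_map_filtered_or_None, QcReport)``.  Raises
    ``ValueError`` when nothing survives.
    """
    for name, v in (("sample_call_rate", sample_call_rate),
                    ("snp_missing_max", snp_missing_max), ("maf_min", maf_min)):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must lie in (0, 1)")
    steps = []

    keep_s = G.sample_call_rate >= sample_call_rate
    removed_samples = tuple(
        sid for sid, k in zip(G.sample_ids, keep_s) if not k
    )
    G1 = G.subset(samples=keep_s)
    steps.append(
        f"samples: call rate >= {sample_call_rate:g} kept "
        f"{G1.n_samples}/{G.n_samples}"
    )
    if G1.n_samples == 0:
        raise ValueError("QC removed every sample")

    keep_miss = G1.snp_missingness < snp_missing_max
    G2 = G1.subset(snps=keep_miss)
    steps.append(
        f"snps: missingness < {snp_missing_max:g} kept {G2.n_snps}/{G1.n_snps}"
    )
    n_after_missing = G2.n_snps

    with np.errstate(invalid="ignore"):
        keep_maf = G2.maf > maf_min
    keep_maf = np.where(np.isnan(G2.maf), False, keep_maf)
    G3 = G2.subset(snps=keep_maf)
    steps.append(f"snps: MAF > {maf_min:g} kept {G3.n_snps}/{G2.n_snps}")
    n_after_maf = G3.n_snps

    map_out = None
    G4 = G3
    if snp_map is not None:
        kept_ids = set(G2.snp_ids[j] for j in np.flatnonzero(keep_maf))
        mask = np.array([s in kept_ids for s in snp_map.snp_id])
        map_out = snp_map.subset(mask)
        if autosomes is not None:
            auto = set(str(c) for c in autosomes)
            amask = np.array([str(c) in auto for c in map_out.chromosome])
            map_out = map_out.subset(amask)
            keep_ids2 = set(map_out.snp_id)
            G4 = G3.subset(snps=np.array([s in keep_ids2 for s in G3.snp_ids]))
            steps.append(f"snps: autosomes kept {G4.n_snps}/{G3.n_snps}")
    elif autosomes is not None:
        raise ValueError("autosome filtering requires a snp_map")

    if G4.n_snps == 0:
        raise ValueError("QC removed every SNP")
    report = QcReport(
        n_samples_in=G.n_samples,
        n_samples_kept=G1.n_samples,
        n_snps_in=G.n_snps,
        n_snps_after_missingness=n_after_missing,
        n_snps_after_maf=n_after_maf,
        n_snps_kept=G4.n_snps,
        removed_samples=removed_samples,
        steps=tuple(steps),
    )
    for s in steps:
        log.info("qc: %s", s)
    return G4, map_out, report


def ld_r2(g1: Sequence[float], g2: Sequence[float]) -> float:
    """Squared Pearson correlation over pairwise-complete samples.

    Returns NaN when fewer than two complete pairs exist or either vector
    is constant among the complete pairs.
    """
    x = np.asarray(g1, dtype=float)
    y = np.asarray(g2, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 2:
        return float("nan")
    x, y = x[ok], y[ok]
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    r = np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy)
    return float(r * r)


def prune_by_distance(snp_map: SnpMap, window_bp: int) -> np.ndarray:
    """Greedy per-chromosome distance pruning: keep the first SNP, then the
    next SNP at least ``window_bp`` downstream of the last kept one.

    Returns a boolean mask in the original SNP order.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    keep = np.zeros(len(snp_map), dtype=bool)
    df = pd.DataFrame(
        {"chrom": snp_map.chromosome, "bp": snp_map.position_bp,
         "i": np.arange(len(snp_map))}
    )
    for _, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("bp", kind="mergesort")
        last = None
        for bp, i in zip(grp["bp"], grp["i"]):
            if last is None or bp - last >= window_bp:
                keep[i] = True
                last = bp
    return keep


def ld_decay(
    G: GenotypeMatrix,
    snp_map: SnpMap,
    *,
    max_dist_bp: int,
    bin_bp: int,
) -> pd.DataFrame:
    """Mean r^2 of intra-chromosome SNP pairs, binned by physical distance.

    Bins are ``[k*bin_bp, (k+1)*bin_bp)`` covering ``[0, max_dist_bp)``;
    empty bins are reported with ``n_pairs = 0`` and NaN mean.
    """
    if max_dist_bp <= 0 or bin_bp <= 0:
        raise ValueError("max_dist_bp and bin_bp must be > 0")
    n_bins = int(np.ceil(max_dist_bp / bin_bp))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    df = pd.DataFrame(
        {"chrom": snp_map.chromosome, "bp": snp_map.position_bp,
         "i": np.arange(len(snp_map))}
    )
    for _, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("bp", kind="mergesort")
        pos = grp["bp"].to_numpy()
        idx = grp["i"].to_numpy()
        for a in range(len(pos)):
            b = a + 1
            while b < len(pos) and pos[b] - pos[a] < max_dist_bp:
                r2 = ld_r2(G.values[:, idx[a]], G.values[:, idx[b]])
                if np.isfinite(r2):
                    k = (pos[b] - pos[a]) // bin_bp
                    sums[k] += r2
                    counts[k] += 1
                b += 1
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_start_bp": np.arange(n_bins) * bin_bp,
            "bin_end_bp": (np.arange(n_bins) + 1) * bin_bp,
            "mean_r2": means,
            "n_pairs": counts,
        }
    )
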