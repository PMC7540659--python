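"""Multiple-testing correction, QTL-region merging and annotation windows.

q-values follow Storey's positive false discovery rate: pi0 is estimated by
the natural-cubic-smoother recipe over a lambda grid and q_i is the minimum
of ``pi0 * m * p_j / rank(p_j)`` over all ``p_j >= p_i``.  Significant SNPs
closer than the gap threshold (default 1 Mb) are merged into one QTL
region; annotation windows expand each region by +/- 1 Mb, clipped at 1 bp.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssocRecord",
    "QtlRegion",
    "storey_pi0",
    "storey_q",
    "correct",
    "call_regions",
    "annotation_windows",
    "region_overlaps",
]

log = logging.getLogger("cagewas")

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.96, 0.05), 2)


@dataclass(frozen=True)
class AssocRecord:
    snp_id: str
    chromosome: str
    position_bp: int
    effect: float
    lrt: float
    p: float
    method: str
    trait: str
    se: float = float("nan")
    q: float = float("nan")

    def __post_init__(self):
        if np.isfinite(self.p) and not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p-value {self.p} outside [0, 1]")
        if np.isfinite(self.q) and not 0.0 <= self.q <= 1.0:
            raise ValueError(f"q-value {self.q} outside [0, 1]")


@dataclass(frozen=True)
class QtlRegion:
    chromosome: str
    start_bp: int
    end_bp: int
    snp_ids: tuple          # significant SNPs in the region
    n_snps_in_span: int     # tested SNPs within [start_bp, end_bp]
    top_snp: str            # min q, tie -> min p, tie -> smallest bp
    top_q: float
    top_p: float
    top_effect: float
    top_maf: float
    method: str = ""
    trait: str = ""

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValueError("region start after end")


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

def _natural_cubic_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Truncated-power natural cubic spline basis (intercept, x, then one
    column per interior knot) with linearity enforced beyond the boundary
    knots."""
    k = knots
    K = len(k)

    def d(j, xx):
        return ((np.maximum(xx - k[j], 0.0) ** 3
                 - np.maximum(xx - k[K - 1], 0.0) ** 3) / (k[K - 1] - k[j]))

    cols = [np.ones_like(x), x]
    for j in range(K - 2):
        cols.append(d(j, x) - d(K - 2, x))
    return np.column_stack(cols)


def _smoother_df(lam: float, B: np.ndarray, Omega: np.ndarray) -> float:
    H = B @ np.linalg.solve(B.T @ B + lam * Omega, B.T)
    return float(np.trace(H))


def storey_pi0(
    p: np.ndarray,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    *,
    df: float = 3.0,
) -> float:
    """Estimate the null proportion pi0 with the natural-cubic-smoother
    method: smooth ``pi0(lambda) = #{p > lambda} / (m (1 - lambda))`` with a
    spline of ~``df`` effective degrees of freedom and evaluate at the
    largest lambda.  Falls back to 1 with a warning for m < 20."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    if m < 20:
        warnings.warn(
            "fewer than 20 p-values: pi0 smoother unstable, using pi0 = 1",
            stacklevel=2,
        )
        return 1.0
    lam = np.asarray(lambda_grid, dtype=float)
    pi0_l = np.array([(p > l).mean() / (1.0 - l) for l in lam])
    knots = lam
    B = _natural_cubic_basis(lam, knots)
    # second-derivative penalty by finite differences on a fine grid
    grid = np.linspace(lam[0], lam[-1], 401)
    Bg = _natural_cubic_basis(grid, knots)
    h = grid[1] - grid[0]
    D2 = (Bg[2:] - 2 * Bg[1:-1] + Bg[:-2]) / h**2
    Omega = D2.T @ D2 * h
    # bisect the penalty to hit the requested effective df
    lo, hi = 1e-10, 1e10
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if _smoother_df(mid, B, Omega) > df:
            lo = mid
        else:
            hi = mid
    lam_pen = np.sqrt(lo * hi)
    coef = np.linalg.solve(B.T @ B + lam_pen * Omega, B.T @ pi0_l)
    pi0 = float((_natural_cubic_basis(np.array([lam[-1]]), knots) @ coef)[0])
    return float(min(max(pi0, 1e-8), 1.0))


def storey_q(
    p: Sequence[float],
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    *,
    pi0: Optional[float] = None,
):
    """Storey q-values.  Returns ``(q, pi0)``.

    ``q_i = min over {j : p_j >= p_i} of pi0 * m * p_j / rank(p_j)`` with
    maximum ranks for ties, clipped to [0, 1].  With ``pi0 = 1`` this
    reduces exactly to Benjamini-Hochberg adjusted p-values.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([]), 1.0
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    m = len(p)
    if pi0 is None:
        pi0 = storey_pi0(p, lambda_grid)
    order = np.argsort(p, kind="mergesort")
    ranks_max = np.searchsorted(p[order], p, side="right")  # max rank with ties
    raw = pi0 * m * p / ranks_max
    # running minimum of raw values from the largest p downwards
    q_sorted = np.minimum.accumulate(raw[order][::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, float(pi0)


def correct(
    records: pd.DataFrame,
    *,
    level: str = "chromosome",
    pfdr: float = 0.05,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
) -> pd.DataFrame:
    """Attach q-values and significance flags to association records.

    ``level='genome'`` corrects over every test at once;
    ``level='chromosome'`` corrects within each chromosome separately.
    Significance means ``q < pfdr``.
    """
    if level not in ("genome", "chromosome"):
        raise ValueError("level must be 'genome' or 'chromosome'")
    out = records.copy()
    if len(out) == 0:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        return out
    if level == "genome":
        q, pi0 = storey_q(out["p"].to_numpy(), lambda_grid)
        out["q"] = q
        log.info("correction: genome-wide pi0 = %.3f", pi0)
    else:
        out["q"] = np.nan
        for chrom, grp in out.groupby("chromosome", sort=False):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                q, pi0 = storey_q(grp["p"].to_numpy(), lambda_grid)
            out.loc[grp.index, "q"] = q
            log.info("correction: chromosome %s pi0 = %.3f", chrom, pi0)
    out["significant"] = out["q"] < pfdr
    return out


# ---------------------------------------------------------------------------
# Region calling
# ---------------------------------------------------------------------------

def call_regions(
    significant: pd.DataFrame,
    *,
    gap_bp: int = 1_000_000,
    snp_map=None,
    method: str = "",
    trait: str = "",
) -> list:
    """Merge significant SNPs into QTL regions by single-linkage clustering
    along each chromosome: consecutive significant SNPs less than ``gap_bp``
    apart share a region.  ``snp_map`` (optional) supplies the panel used to
    count tested SNPs within each span; without it the count falls back to
    the number of significant SNPs."""
    if gap_bp <= 0:
        raise ValueError("gap_bp must be > 0")
    regions = []
    if len(significant) == 0:
        return regions
    df = significant.sort_values(
        ["chromosome", "position_bp"], kind="mergesort"
    )
    for chrom, grp in df.groupby("chromosome", sort=False):
        pos = grp["position_bp"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) >= gap_bp)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for s, e in zip(starts, ends):
            cluster = grp.iloc[s : e + 1]
            start_bp = int(cluster["position_bp"].min())
            end_bp = int(cluster["position_bp"].max())
            ranked = cluster.sort_values(
                ["q", "p", "position_bp"], kind="mergesort"
            )
            top = ranked.iloc[0]
            if snp_map is not None:
                in_span = int(
                    np.sum(
                        (np.asarray(snp_map.chromosome, dtype=object) == chrom)
                        & (snp_map.position_bp >= start_bp)
                        & (snp_map.position_bp <= end_bp)
                    )
                )
            else:
                in_span = len(cluster)
            maf = float(top["maf"]) if "maf" in cluster.columns else float("nan")
            regions.append(
                QtlRegion(
                    chromosome=str(chrom),
                    start_bp=start_bp,
                    end_bp=end_bp,
                    snp_ids=tuple(cluster["snp_id"]),
                    n_snps_in_span=in_span,
                    top_snp=str(top["snp_id"]),
                    top_q=float(top["q"]),
                    top_p=float(top["p"]),
                    top_effect=float(top["effect"]),
                    top_maf=maf,
                    method=method or str(top.get("method", "")),
                    trait=trait or str(top.get("trait", "")),
                )
            )
    return regions


def regions_to_frame(regions: Sequence[QtlRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trait": r.trait,
                "method": r.method,
                "chromosome": r.chromosome,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "n_snps_in_span": r.n_snps_in_span,
                "n_significant": len(r.snp_ids),
                "top_snp": r.top_snp,
                "top_q": r.top_q,
                "top_effect": r.top_effect,
                "top_maf": r.top_maf,
            }
            for r in regions
        ]
    )


def annotation_windows(
    regions: Sequence[QtlRegion],
    *,
    window_bp: int = 1_000_000,
    gene_intervals: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Expand regions by +/- ``window_bp`` (start clipped at 1 bp).

    ``gene_intervals`` (optional) is a frame with chromosome/start_bp/end_bp
    and an id column; overlapping ids are joined comma-separated.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    rows = []
    for r in regions:
        win_start = max(1, r.start_bp - window_bp)
        win_end = r.end_bp + window_bp
        row = {
            "chromosome": r.chromosome,
            "start_bp": r.start_bp,
            "end_bp": r.end_bp,
            "window_start_bp": win_start,
            "window_end_bp": win_end,
            "trait": r.trait,
            "method": r.method,
        }
        if gene_intervals is not None:
            hit = gene_intervals[
                (gene_intervals["chromosome"].astype(str) == r.chromosome)
                & (gene_intervals["start_bp"] <= win_end)
                & (gene_intervals["end_bp"] >= win_start)
            ]
            id_col = "gene_id" if "gene_id" in hit.columns else hit.columns[-1]
            row["genes"] = ",".join(str(g) for g in hit[id_col])
        rows.append(row)
    return pd.DataFrame(rows)


def region_overlaps(
    regions_a: Sequence[QtlRegion], regions_b: Sequence[QtlRegion]
) -> pd.DataFrame:
    """Interval intersections across two (trait, method) strata — used to
    report cross-trait overlap without merging regions across strata."""
    rows = []
    for ra in regions_a:
        for rb in regions_b:
            if ra.chromosome != rb.chromosome:
                continue
            lo = max(ra.start_bp, rb.start_bp)
            hi = min(ra.end_bp, rb.end_bp)
            if lo <= hi:
                rows.append(
                    {
                        "chromosome": ra.chromosome,
                        "overlap_start_bp": lo,
                        "overlap_end_bp": hi,
                        "trait_a": ra.trait,
                        "trait_b": rb.trait,
                        "method_a": ra.method,
                        "method_b": rb.method,
                    }
                )
    return pd.DataFrame(rows)
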