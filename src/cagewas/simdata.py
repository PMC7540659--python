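"""Synthetic-data generator mirroring the experiment's statistical structure.

Produces a multi-batch pedigree with litters, cages of 6-8 animals split by
weaning-size class and feeding regime (littermates spread across both
regimes, at most two kits of a litter per cage), genotypes in approximate
HWE with distance-decaying LD gene-dropped through the pedigree, weekly
body weights and weekly cage feed records (ad-libitum cages eat freely;
restricted cages receive 0.75 x 1.10 x the previous week's ad-libitum
per-animal intake), plus a truth file with every simulated quantity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_qc import GenotypeMatrix
from .io_formats import SnpMap, write_genotypes, write_pedigree
from .pedigree import PedigreeTable, build_A

__all__ = [
    "SimConfig",
    "SimulationError",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_phenotypes",
    "draw_breeding_values",
    "simulate_trait_records",
    "cage_mean_records",
    "emit",
    "simulate_all",
]

WEIGH_DAYS = (30, 37, 44, 51)   # last fattening week already discarded
N_FEED_WEEKS = 3
LITTER_SIZES = (3, 4, 5, 6, 7, 8, 9)  # the seven litter-size classes


class SimulationError(ValueError):
    """Raised for infeasible simulation constraints."""


@dataclass
class SimConfig:
    n_batches: int = 5
    cages_per_batch: int = 12          # total, split across the two regimes
    animals_per_cage: int = 8          # 6 or 8
    fraction_genotyped: float = 0.3
    n_snps: int = 400
    n_chromosomes: int = 2
    chromosome_length_bp: int = 40_000_000
    ld_decay_bp: float = 2_000_000.0   # d0 of the founder-haplotype LD chain
    morgans_per_bp: float = 1e-8
    causal: tuple = ()                 # (snp_index, trait, effect) triples
    sigma2_a_adg: float = 16.0
    sigma2_a_rfi: float = 9.0
    genetic_corr_adg_rfi: float = 0.58
    sigma2_cage: float = 8.0
    sigma2_litter: float = 10.0
    sigma2_e_adg: float = 44.0
    adg_mean_f: float = 53.0
    adg_mean_r: float = 35.0
    bw30_mean: float = 700.0
    bw30_sd: float = 80.0
    bw_noise_sd: float = 10.0
    fcr_target: float = 2.8
    fi_noise_sd: float = 4.0           # g/day per-animal cage feed noise
    restriction: float = 0.75
    growth_allowance: float = 0.10
    fixed_effect_sd: float = 2.0       # spread of batch/parity/litter-size effects
    n_sires_per_batch: int = 6
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.fraction_genotyped <= 1.0:
            raise ValueError("fraction_genotyped must lie in (0, 1]")
        for name in ("sigma2_a_adg", "sigma2_a_rfi", "sigma2_cage",
                     "sigma2_litter", "sigma2_e_adg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not -1.0 <= self.genetic_corr_adg_rfi <= 1.0:
            raise ValueError("genetic correlation must lie in [-1, 1]")
        if self.animals_per_cage < 2:
            raise ValueError("animals_per_cage must be >= 2")


# ---------------------------------------------------------------------------
# Pedigree, litters and cage assignment
# ---------------------------------------------------------------------------

def _assign_cages(kits: pd.DataFrame, cage_prefix: str, capacity: int):
    """Fill cages greedily, taking at most two kits of a litter per cage.

    Each cage draws two kits at a time from the litter with most kits left,
    which keeps litters maximally spread.  Kits that do not fill a whole
    cage stay unassigned.  When the two-per-litter rule blocks completing a
    cage (too few litters for the cage count) the partial cage is unwound
    and filling stops — unless not even the first cage could be formed, in
    which case the stratum is infeasible and :class:`SimulationError` is
    raised.
    """
    remaining = {
        litter: list(grp["animal"])
        for litter, grp in kits.groupby("litter", sort=True)
    }
    assignment = {}
    cage_no = 0
    while sum(len(v) for v in remaining.values()) >= capacity:
        cage_no += 1
        cage = f"{cage_prefix}{cage_no}"
        taken_from = {}
        filled = 0
        in_cage = []
        while filled < capacity:
            candidates = [
                l for l, v in remaining.items()
                if v and taken_from.get(l, 0) < 2
            ]
            if not candidates:
                break
            litter = max(candidates, key=lambda l: len(remaining[l]))
            take = min(2 - taken_from.get(litter, 0), capacity - filled,
                       len(remaining[litter]))
            for _ in range(take):
                kit = remaining[litter].pop()
                assignment[kit] = cage
                in_cage.append(kit)
            taken_from[litter] = taken_from.get(litter, 0) + take
            filled += take
        if filled < capacity:
            for kit in in_cage:
                del assignment[kit]
            if cage_no == 1:
                raise SimulationError(
                    f"too few litters to fill cage {cage!r} with at most "
                    "two kits per litter"
                )
            break
    return assignment


def simulate_pedigree(config: SimConfig, rng: np.random.Generator):
    """Base population plus one offspring generation organised into batches,
    litters, regimes and cages.

    Returns ``(PedigreeTable, assignments)``; ``assignments`` has one row
    per kit (animal, batch, parity, litter, litter_size_class, regime,
    weaning_bw, cage_size_class, cage) — kits left over after cage filling
    carry a null cage and are excluded from phenotyping downstream.
    """
    animal_rows = []
    ped_animal, ped_sire, ped_dam = [], [], []
    capacity = config.animals_per_cage
    for b in range(1, config.n_batches + 1):
        sires = [f"S{b}_{i}" for i in range(1, config.n_sires_per_batch + 1)]
        for s in sires:
            ped_animal.append(s); ped_sire.append(None); ped_dam.append(None)
        needed = config.cages_per_batch * capacity
        litter_id = 0
        produced = 0
        while produced < int(needed * 1.3) + 4:
            litter_id += 1
            dam = f"D{b}_{litter_id}"
            ped_animal.append(dam); ped_sire.append(None); ped_dam.append(None)
            sire = sires[int(rng.integers(len(sires)))]
            size = int(rng.choice(LITTER_SIZES))
            parity = int(rng.integers(1, 5))
            for k in range(size):
                kit = f"A{b}_{litter_id}_{k + 1}"
                ped_animal.append(kit)
                ped_sire.append(sire)
                ped_dam.append(dam)
                animal_rows.append(
                    {
                        "animal": kit,
                        "batch": f"B{b}",
                        "parity": parity,
                        "litter": f"L{b}_{litter_id}",
                        "litter_size_class": LITTER_SIZES.index(size) + 1,
                        # alternate within litter so every litter with >= 2
                        # kits appears under both feeding regimes
                        "regime": "F" if k % 2 == 0 else "R",
                        "weaning_bw": float(
                            rng.normal(config.bw30_mean, config.bw30_sd)
                        ),
                    }
                )
                produced += 1
    ped = PedigreeTable.from_records(ped_animal, ped_sire, ped_dam)
    kits = pd.DataFrame(animal_rows)
    kits["cage_size_class"] = np.where(kits["weaning_bw"] > 700.0, "LS", "SS")
    kits["cage"] = None
    for (batch, regime, size_class), grp in kits.groupby(
        ["batch", "regime", "cage_size_class"], sort=True
    ):
        prefix = f"C{batch}_{regime}_{size_class}_"
        assignment = _assign_cages(grp, prefix, capacity)
        kits.loc[grp.index, "cage"] = grp["animal"].map(assignment)
    return ped, kits


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _snp_positions(config: SimConfig, rng: np.random.Generator):
    chroms, positions = [], []
    per = [config.n_snps // config.n_chromosomes] * config.n_chromosomes
    per[0] += config.n_snps - sum(per)
    for c, m in enumerate(per, start=1):
        spacing = config.chromosome_length_bp / (m + 1)
        base = spacing * (np.arange(m) + 1)
        jitter = rng.uniform(-0.3, 0.3, size=m) * spacing
        pos = np.maximum(np.sort(base + jitter).astype(np.int64), 1)
        pos = np.maximum.accumulate(pos + np.arange(m))  # enforce increasing
        chroms += [str(c)] * m
        positions.append(pos)
    return np.array(chroms, dtype=object), np.concatenate(positions)


def simulate_genotypes(
    ped: PedigreeTable, config: SimConfig, rng: np.random.Generator
):
    """Gene-drop genotypes for every pedigree member.

    Founder haplotypes come from a Gaussian-copula Markov chain whose
    neighbour correlation decays as ``exp(-distance / d0)``, giving HWE
    founders with distance-decaying LD; offspring haplotypes recombine the
    parental pair with Haldane crossovers.  Returns ``(GenotypeMatrix,
    SnpMap)`` with rows in pedigree order.
    """
    chroms, positions = _snp_positions(config, rng)
    m = len(positions)
    freqs = rng.uniform(0.1, 0.9, size=m)
    thresholds = stats.norm.ppf(freqs)
    new_chrom = np.ones(m, dtype=bool)
    new_chrom[1:] = chroms[1:] != chroms[:-1]
    gaps = np.empty(m)
    gaps[0] = np.inf
    gaps[1:] = np.where(
        new_chrom[1:], np.inf, np.diff(positions).astype(float)
    )
    rho = np.exp(-gaps / config.ld_decay_bp)
    rec = 0.5 * (1.0 - np.exp(-2.0 * config.morgans_per_bp * gaps))

    def founder_hap():
        eps = rng.standard_normal(m)
        z = np.empty(m)
        z[0] = eps[0]
        for j in range(1, m):
            z[j] = rho[j] * z[j - 1] + np.sqrt(1.0 - rho[j] ** 2) * eps[j]
        return (z < thresholds).astype(np.uint8)

    def child_hap(h0, h1):
        switch = rng.random(m) < rec  # rec is 0.5 at chromosome starts
        source = np.cumsum(switch) % 2
        return np.where(source == 0, h0, h1).astype(np.uint8)

    haplo = {}
    for i, a in enumerate(ped.animal):
        s, d = ped.sire[i], ped.dam[i]
        pat = founder_hap() if s is None else child_hap(*haplo[s])
        mat = founder_hap() if d is None else child_hap(*haplo[d])
        haplo[a] = (pat, mat)
    values = np.array(
        [haplo[a][0] + haplo[a][1] for a in ped.animal], dtype=float
    )
    snp_map = SnpMap(
        snp_id=np.array([f"snp{j + 1}" for j in range(m)], dtype=object),
        chromosome=chroms,
        position_bp=positions,
        allele1=np.full(m, "A", dtype=object),
        allele2=np.full(m, "B", dtype=object),
    )
    return GenotypeMatrix(
        sample_ids=tuple(ped.animal),
        snp_ids=tuple(snp_map.snp_id),
        values=values,
    ), snp_map


# ---------------------------------------------------------------------------
# Breeding values and phenotypes
# ---------------------------------------------------------------------------

def draw_breeding_values(
    ped: PedigreeTable,
    G0: np.ndarray,
    rng: np.random.Generator,
    inbreeding: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Gene-drop polygenic values with covariance ``G0`` between traits and
    the pedigree relationship between animals.  Returns (n_animals, n_traits).
    """
    G0 = np.atleast_2d(np.asarray(G0, dtype=float))
    t = G0.shape[0]
    L = np.linalg.cholesky(G0 + 1e-12 * np.eye(t))
    F = dict(zip(ped.animal, inbreeding)) if inbreeding is not None else {}
    bv = np.zeros((len(ped), t))
    index = ped.index
    for i, a in enumerate(ped.animal):
        s, d = ped.sire[i], ped.dam[i]
        if s is None and d is None:
            bv[i] = L @ rng.standard_normal(t)
            continue
        mean = np.zeros(t)
        ms_var = 1.0
        if s is not None:
            mean += 0.5 * bv[index[s]]
            ms_var -= 0.25 * (1.0 + F.get(s, 0.0))
        if d is not None:
            mean += 0.5 * bv[index[d]]
            ms_var -= 0.25 * (1.0 + F.get(d, 0.0))
        bv[i] = mean + np.sqrt(max(ms_var, 0.0)) * (L @ rng.standard_normal(t))
    return bv


def simulate_trait_records(
    assignments: pd.DataFrame,
    bv: np.ndarray,
    bv_ids: Sequence,
    config: SimConfig,
    rng: np.random.Generator,
    *,
    causal_values: Optional[np.ndarray] = None,
):
    """Per-animal ADG values from the additive model underlying the fits.

    ``causal_values`` (optional, aligned with ``assignments`` rows) is the
    already-scaled causal-SNP contribution to add to the breeding value.
    Returns ``(adg, effects)`` where ``effects`` records every fixed and
    random draw used (for the truth file).
    """
    df = assignments
    n = len(df)
    idx = {a: i for i, a in enumerate(bv_ids)}
    a_adg = np.array([bv[idx[a], 0] for a in df["animal"]])
    if causal_values is not None:
        a_adg = a_adg + np.asarray(causal_values, dtype=float)

    def factor_effects(col):
        levels = sorted(pd.unique(df[col]), key=str)
        vals = rng.normal(0.0, config.fixed_effect_sd, size=len(levels))
        vals[0] = 0.0
        return dict(zip(levels, vals))

    eff = {
        "batch": factor_effects("batch"),
        "parity": factor_effects("parity"),
        "litter_size_class": factor_effects("litter_size_class"),
        "cage_size_class": factor_effects("cage_size_class"),
    }
    cages = pd.unique(df["cage"].dropna())
    litters = pd.unique(df["litter"])
    cage_eff = dict(
        zip(cages, rng.normal(0, np.sqrt(config.sigma2_cage), len(cages)))
    )
    litter_eff = dict(
        zip(litters, rng.normal(0, np.sqrt(config.sigma2_litter), len(litters)))
    )
    mean = np.where(df["regime"] == "F", config.adg_mean_f, config.adg_mean_r)
    adg = (
        mean
        + df["batch"].map(eff["batch"]).to_numpy()
        + df["parity"].map(eff["parity"]).to_numpy()
        + df["litter_size_class"].map(eff["litter_size_class"]).to_numpy()
        + df["cage_size_class"].map(eff["cage_size_class"]).to_numpy()
        + df["cage"].map(cage_eff).fillna(0.0).to_numpy()
        + df["litter"].map(litter_eff).to_numpy()
        + a_adg
        + rng.normal(0, np.sqrt(config.sigma2_e_adg), n)
    )
    effects = {
        "fixed": {k: {str(kk): vv for kk, vv in v.items()} for k, v in eff.items()},
        "cage": {str(c): float(v) for c, v in cage_eff.items()},
        "litter": {str(l): float(v) for l, v in litter_eff.items()},
    }
    return adg, effects


def cage_mean_records(values: np.ndarray, assignments: pd.DataFrame):
    """Average a per-animal vector within cages (caged animals only)."""
    df = assignments.assign(_v=values).dropna(subset=["cage"])
    return df.groupby("cage")["_v"].mean()


def simulate_phenotypes(
    ped: PedigreeTable,
    genotypes: Optional[GenotypeMatrix],
    assignments: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
):
    """Raw weekly records: per-animal body weights and per-cage weekly feed.

    Returns ``(bw, feed, truth)``.  Body weights are linear in age around
    the simulated ADG; ad-libitum cage feed follows the target feed
    conversion ratio with a 10 %/week growth trend plus the members' RFI
    genetic deviations; restricted cages receive the ration rule applied to
    the previous week's ad-libitum per-animal intake of their batch x size
    class group.
    """
    caged = assignments.dropna(subset=["cage"]).reset_index(drop=True)
    corr = config.genetic_corr_adg_rfi
    G0 = np.array(
        [
            [config.sigma2_a_adg,
             corr * np.sqrt(config.sigma2_a_adg * config.sigma2_a_rfi)],
            [corr * np.sqrt(config.sigma2_a_adg * config.sigma2_a_rfi),
             config.sigma2_a_rfi],
        ]
    )
    A = build_A(ped)
    bv = draw_breeding_values(ped, G0, rng, inbreeding=A.inbreeding)
    bv_index = {a: i for i, a in enumerate(ped.animal)}

    causal_vals = np.zeros(len(caged))
    causal_truth = []
    if genotypes is not None and config.causal:
        gidx = {a: i for i, a in enumerate(genotypes.sample_ids)}
        for snp_index, trait, effect in config.causal:
            g = genotypes.values[:, snp_index]
            f = np.nanmean(g) / 2.0
            centred = np.array(
                [g[gidx[a]] - 2.0 * f for a in caged["animal"]]
            )
            if trait == "adg":
                causal_vals = causal_vals + effect * centred
            causal_truth.append(
                {
                    "snp_id": genotypes.snp_ids[snp_index],
                    "snp_index": int(snp_index),
                    "trait": trait,
                    "effect": float(effect),
                    "freq": float(f),
                }
            )

    adg, effects = simulate_trait_records(
        caged, bv, ped.animal, config, rng, causal_values=causal_vals
    )

    # weekly body weights, linear in age
    bw_rows = []
    for (animal, wbw), a in zip(zip(caged["animal"], caged["weaning_bw"]), adg):
        for day in WEIGH_DAYS:
            bw_rows.append(
                {
                    "animal": animal,
                    "age_days": day,
                    "bw_g": wbw + a * (day - 30)
                    + rng.normal(0, config.bw_noise_sd),
                }
            )
    bw = pd.DataFrame(bw_rows)

    # cage feed
    u_rfi = np.array([bv[bv_index[a], 1] for a in caged["animal"]])
    cage_adg = cage_mean_records(adg, caged)
    cage_rfi = cage_mean_records(u_rfi, caged)
    cage_info = (
        caged.groupby("cage")
        .agg(
            batch=("batch", "first"),
            size_class=("cage_size_class", "first"),
            regime=("regime", "first"),
            n=("animal", "count"),
        )
        .reset_index()
    )
    growth = (1.0 + config.growth_allowance) ** np.arange(N_FEED_WEEKS)
    growth = growth / growth.mean()
    feed_rows = []
    f_week_intake = {}  # (batch, size_class, week) -> list of per-animal FI
    for _, row in cage_info[cage_info["regime"] == "F"].iterrows():
        base = config.fcr_target * cage_adg[row["cage"]] + cage_rfi[row["cage"]]
        for week in range(1, N_FEED_WEEKS + 1):
            fi = max(
                base * growth[week - 1] + rng.normal(0, config.fi_noise_sd), 1.0
            )
            f_week_intake.setdefault(
                (row["batch"], row["size_class"], week), []
            ).append(fi)
            feed_rows.append(
                {
                    "cage": row["cage"],
                    "week": week,
                    "feed_g": fi * row["n"] * 7.0,
                    "animal_days": row["n"] * 7.0,
                }
            )
    baseline = config.fcr_target * config.adg_mean_f / (
        1.0 + config.growth_allowance
    )
    for _, row in cage_info[cage_info["regime"] == "R"].iterrows():
        for week in range(1, N_FEED_WEEKS + 1):
            prev = f_week_intake.get((row["batch"], row["size_class"], week - 1))
            prev_fi = float(np.mean(prev)) if prev else baseline
            allowance = (
                config.restriction * (1.0 + config.growth_allowance) * prev_fi
            )
            feed_rows.append(
                {
                    "cage": row["cage"],
                    "week": week,
                    "feed_g": allowance * row["n"] * 7.0,
                    "animal_days": row["n"] * 7.0,
                }
            )
    feed = pd.DataFrame(feed_rows)

    truth = {
        "seed": config.seed,
        "variance_components": {
            "sigma2_a_adg": config.sigma2_a_adg,
            "sigma2_a_rfi": config.sigma2_a_rfi,
            "genetic_corr_adg_rfi": config.genetic_corr_adg_rfi,
            "sigma2_cage": config.sigma2_cage,
            "sigma2_litter": config.sigma2_litter,
            "sigma2_e_adg": config.sigma2_e_adg,
        },
        "causal": causal_truth,
        "breeding_values": {
            str(a): [float(x) for x in bv[i]]
            for a, i in bv_index.items()
        },
        "adg": {str(a): float(v) for a, v in zip(caged["animal"], adg)},
        "effects": effects,
        "assignments": caged[
            ["animal", "batch", "parity", "litter", "litter_size_class",
             "regime", "cage_size_class", "cage"]
        ].to_dict(orient="list"),
    }
    return bw, feed, truth


# ---------------------------------------------------------------------------
# Orchestration and emission
# ---------------------------------------------------------------------------

@dataclass
class SimData:
    config: SimConfig
    pedigree: PedigreeTable
    assignments: pd.DataFrame       # caged animals only
    genotypes: GenotypeMatrix       # all pedigree members
    snp_map: SnpMap
    genotyped_ids: tuple
    bw: pd.DataFrame
    feed: pd.DataFrame
    truth: dict


def simulate_all(config: SimConfig) -> SimData:
    """Run the full generator with one seed-driven generator."""
    rng = np.random.default_rng(config.seed)
    ped, kits = simulate_pedigree(config, rng)
    genotypes, snp_map = simulate_genotypes(ped, config, rng)
    bw, feed, truth = simulate_phenotypes(ped, genotypes, kits, config, rng)
    caged = kits.dropna(subset=["cage"]).reset_index(drop=True)
    genotyped = []
    for _, grp in caged.groupby("cage"):
        k = max(1, int(round(config.fraction_genotyped * len(grp))))
        pick = rng.choice(grp["animal"].to_numpy(), size=k, replace=False)
        genotyped.extend(pick.tolist())
    genotyped = tuple(sorted(genotyped))
    truth["genotyped"] = list(genotyped)
    return SimData(
        config=config,
        pedigree=ped,
        assignments=caged,
        genotypes=genotypes,
        snp_map=snp_map,
        genotyped_ids=genotyped,
        bw=bw,
        feed=feed,
        truth=truth,
    )


def emit(sim: SimData, outdir) -> dict:
    """Write every file the pipeline reads, plus the truth JSON.

    Genotypes are emitted for the genotyped subset only (bed/bim/fam);
    the pedigree covers everyone.  Returns the path map.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sample_index = {a: i for i, a in enumerate(sim.genotypes.sample_ids)}
    rows = [sample_index[g] for g in sim.genotyped_ids]
    G_sub = sim.genotypes.subset(samples=np.array(rows))
    write_genotypes(out / "genotypes", G_sub, sim.snp_map)
    write_pedigree(sim.pedigree, out / "pedigree.csv")
    sim.assignments.to_csv(out / "animals.csv", index=False)
    sim.bw.to_csv(out / "body_weights.csv", index=False)
    sim.feed.to_csv(out / "cage_feed.csv", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(sim.truth, fh, indent=1)
    return {
        "genotypes": out / "genotypes",
        "pedigree": out / "pedigree.csv",
        "animals": out / "animals.csv",
        "body_weights": out / "body_weights.csv",
        "cage_feed": out / "cage_feed.csv",
        "truth": out / "truth.json",
    }
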