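"""Shared builders: cage-mean datasets drawn exactly from the bivariate
model's generating process (used by module and acceptance tests)."""

import numpy as np

from cagewas.pedigree import build_A
from cagewas.simdata import (
    SimConfig,
    cage_mean_records,
    draw_breeding_values,
    simulate_genotypes,
    simulate_pedigree,
    simulate_trait_records,
)
from cagewas.traits import CagePhenotypes


def build_cage_population(
    seed,
    *,
    cages_per_batch=40,
    n_batches=3,
    animals_per_cage=7,
    n_snps=50,
    fraction_genotyped=0.3,
    ld_decay_bp=1.0,
):
    """Pedigree + F-regime cage structure + gene-dropped genotypes.

    ``ld_decay_bp=1`` makes SNPs effectively independent (null scans).
    Returns a dict with everything needed to draw traits and fit models.
    """
    rng = np.random.default_rng(seed)
    cfg = SimConfig(
        n_batches=n_batches,
        cages_per_batch=cages_per_batch,
        animals_per_cage=animals_per_cage,
        n_snps=n_snps,
        ld_decay_bp=ld_decay_bp,
        seed=seed,
        sigma2_cage=0.0,
    )
    ped, kits = simulate_pedigree(cfg, rng)
    caged = kits[kits.cage.notna() & (kits.regime == "F")].reset_index(drop=True)
    G, snp_map = simulate_genotypes(ped, cfg, rng)
    A = build_A(ped)
    genotyped = []
    for _, grp in caged.groupby("cage"):
        k = max(1, round(fraction_genotyped * len(grp)))
        genotyped += list(
            rng.choice(grp["animal"].to_numpy(), size=k, replace=False)
        )
    return {
        "config": cfg,
        "rng": rng,
        "pedigree": ped,
        "caged": caged,
        "G": G,
        "snp_map": snp_map,
        "A": A,
        "genotyped": genotyped,
    }


def draw_cage_trait(
    pop,
    *,
    g11=16.0,
    sigma2_litter=10.0,
    sigma2_e=44.0,
    causal_snp=None,
    causal_alpha=0.0,
    seed=None,
):
    """Cage-mean trait drawn from the additive model (no cage effect, so
    the cage-record model is exactly right).  Returns CagePhenotypes with
    the trait in column 'y'."""
    rng = np.random.default_rng(seed) if seed is not None else pop["rng"]
    caged = pop["caged"]
    ped = pop["pedigree"]
    A = pop["A"]
    cfg = SimConfig(
        sigma2_cage=0.0,
        sigma2_litter=sigma2_litter,
        sigma2_e_adg=sigma2_e,
        seed=0,
    )
    bv = draw_breeding_values(ped, np.array([[g11]]), rng, inbreeding=A.inbreeding)
    causal_vals = None
    if causal_snp is not None:
        gidx = {a: i for i, a in enumerate(pop["G"].sample_ids)}
        g = pop["G"].values[:, causal_snp]
        f = np.nanmean(g) / 2.0
        causal_vals = np.array(
            [causal_alpha * (g[gidx[a]] - 2 * f) for a in caged["animal"]]
        )
    adg, _ = simulate_trait_records(
        caged, bv, ped.animal, cfg, rng, causal_values=causal_vals
    )
    cm = cage_mean_records(adg, caged)
    info = (
        caged.groupby("cage")
        .agg(
            batch=("batch", "first"),
            cage_size_class=("cage_size_class", "first"),
            n_members=("animal", "count"),
        )
        .reset_index()
    )
    frame = info.assign(y=info["cage"].map(cm))
    members = {c: tuple(grp["animal"]) for c, grp in caged.groupby("cage")}
    return CagePhenotypes(frame=frame, members=members)
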