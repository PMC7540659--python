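"""Derivation of the five analysed traits from raw weekly records.

Individual average daily gain (ADG) is the within-animal OLS slope of body
weight on age.  Cage traits: average daily feed intake (ADFI) = total cage
feed / animal-days; feed conversion ratio (FCR) = ADFI / cage-mean ADG;
residual feed intake (RFI) = residual of a batch-nested regression of ADFI
on cage-mean ADG and cage-mean mid-period metabolic weight.  The restricted
ration rule supplies 0.75 x (1 + 0.10) x the previous week's ad-libitum
per-animal intake, scaled by the number of animals in the cage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TraitError",
    "IndividualPhenotypes",
    "CagePhenotypes",
    "adg",
    "adfi",
    "fcr",
    "metabolic_weight",
    "restricted_ration",
    "rfi",
    "derive_traits",
]

#: factor levels accepted for individual records
BATCH_LEVELS = 5
PARITY_LEVELS = 4
LITTER_SIZE_LEVELS = 7
CAGE_SIZE_LEVELS = ("LS", "SS")  # >700 g vs <=700 g at weaning
REGIMES = ("F", "R")


class TraitError(ValueError):
    """Raised when a trait is undefined for the given records."""


@dataclass(frozen=True)
class IndividualPhenotypes:
    """One record per animal: trait value plus fixed/random-effect labels."""

    frame: pd.DataFrame  # animal, batch, parity, litter_size_class,
    #                      cage_size_class, cage, litter, regime, adg

    REQUIRED = (
        "animal", "batch", "parity", "litter_size_class",
        "cage_size_class", "cage", "litter", "regime", "adg",
    )

    def __post_init__(self):
        missing = set(self.REQUIRED) - set(self.frame.columns)
        if missing:
            raise TraitError(f"individual phenotypes lack columns {sorted(missing)}")
        if self.frame["animal"].duplicated().any():
            raise TraitError("duplicate animal records")
        bad = set(self.frame["regime"]) - set(REGIMES)
        if bad:
            raise TraitError(f"unknown feeding regime labels {sorted(bad)}")
        bad = set(self.frame["cage_size_class"]) - set(CAGE_SIZE_LEVELS)
        if bad:
            raise TraitError(f"unknown cage-size classes {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class CagePhenotypes:
    """One record per cage: mean traits plus member list and group size."""

    frame: pd.DataFrame  # cage, batch, cage_size_class, n_members, adfi, fcr, rfi
    members: dict  # cage id -> tuple of member animal ids

    def __post_init__(self):
        missing = {"cage", "batch", "cage_size_class", "n_members"} - set(
            self.frame.columns
        )
        if missing:
            raise TraitError(f"cage phenotypes lack columns {sorted(missing)}")
        for cage, ids in self.members.items():
            if len(ids) < 1:
                raise TraitError(f"cage {cage!r} has no members")
            if len(set(ids)) != len(ids):
                raise TraitError(f"cage {cage!r} has duplicate members")
        n = dict(zip(self.frame["cage"], self.frame["n_members"]))
        for cage, ids in self.members.items():
            if cage in n and n[cage] != len(ids):
                raise TraitError(f"cage {cage!r}: n_members disagrees with member list")
        if "fcr" in self.frame.columns:
            f = self.frame["fcr"].dropna()
            if (f <= 0).any():
                raise TraitError("FCR must be > 0 when defined")

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# Elementary trait operations
# ---------------------------------------------------------------------------

def adg(weights: Sequence[tuple]) -> float:
    """Average daily gain: OLS slope of body weight (g) on age (days)."""
    pts = list(weights)
    if len(pts) < 2:
        raise TraitError("ADG needs at least two body-weight records")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0.0:
        raise TraitError("ADG undefined: all records at the same age")
    return float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)


def adfi(total_feed_g: float, days: float, rabbits: float) -> float:
    """Cage average daily feed intake: total feed / (days x rabbits).

    ``rabbits`` may be fractional (animal-days / days) to prorate deaths.
    """
    if days <= 0 or rabbits <= 0:
        raise TraitError("ADFI denominator must be positive")
    if total_feed_g < 0:
        raise TraitError("negative feed total")
    return float(total_feed_g) / (float(days) * float(rabbits))


def fcr(adfi_value: float, cage_mean_adg: float) -> float:
    """Feed conversion ratio: ADFI over the cage-average ADG."""
    if cage_mean_adg <= 0:
        raise TraitError("FCR undefined for non-positive cage-mean ADG")
    return float(adfi_value) / float(cage_mean_adg)


def metabolic_weight(bw_g: float, exponent: float = 0.75) -> float:
    """Metabolic weight (kg^exponent) of a body weight given in grams."""
    if bw_g <= 0:
        raise TraitError("metabolic weight undefined for non-positive BW")
    return float((bw_g / 1000.0) ** exponent)


def restricted_ration(
    prev_week_adlib_fi_per_animal: float,
    n_animals: int = 1,
    *,
    restriction: float = 0.75,
    growth_allowance: float = 0.10,
) -> float:
    """Cage feed allowance under restriction.

    ``restriction x (1 + growth_allowance) x`` previous-week ad-libitum
    per-animal intake, multiplied by the number of animals in the cage.
    """
    if prev_week_adlib_fi_per_animal < 0 or n_animals < 1:
        raise TraitError("ration inputs must be positive")
    return float(
        restriction * (1.0 + growth_allowance)
        * prev_week_adlib_fi_per_animal * n_animals
    )


def rfi(
    cages: pd.DataFrame,
    *,
    common_slopes: bool = False,
) -> np.ndarray:
    """Residual feed intake per cage (input row order preserved).

    ``cages`` needs columns adfi, mean_adg, mean_mw and batch.  The default
    is the batch-nested regression: separate intercept *and* slopes per
    batch.  ``common_slopes=True`` keeps batch intercepts but shares the two
    slopes across batches.  Within-batch residual means are exactly zero.
    """
    required = {"adfi", "mean_adg", "mean_mw", "batch"}
    missing = required - set(cages.columns)
    if missing:
        raise TraitError(f"rfi input lacks columns {sorted(missing)}")
    y = cages["adfi"].to_numpy(dtype=float)
    batches = cages["batch"].to_numpy()
    resid = np.empty(len(cages))
    if common_slopes:
        cols = [
            (batches == b).astype(float) for b in pd.unique(batches)
        ] + [cages["mean_adg"].to_numpy(float), cages["mean_mw"].to_numpy(float)]
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise TraitError("rank-deficient RFI design (common slopes)")
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid[:] = y - X @ beta
        return resid
    for b in pd.unique(batches):
        sel = batches == b
        Xb = np.column_stack(
            [
                np.ones(sel.sum()),
                cages.loc[sel, "mean_adg"].to_numpy(float),
                cages.loc[sel, "mean_mw"].to_numpy(float),
            ]
        )
        if sel.sum() < 4:
            raise TraitError(
                f"batch {b!r} has {int(sel.sum())} cages; need >= 4 for RFI"
            )
        if np.linalg.matrix_rank(Xb) < Xb.shape[1]:
            raise TraitError(f"rank-deficient RFI design in batch {b!r}")
        beta, *_ = np.linalg.lstsq(Xb, y[sel], rcond=None)
        resid[sel] = y[sel] - Xb @ beta
    return resid


# ---------------------------------------------------------------------------
# Full derivation from raw records
# ---------------------------------------------------------------------------

def _interp_bw(ages: np.ndarray, bws: np.ndarray, day: float) -> float:
    """Body weight at ``day`` from the within-animal linear fit."""
    slope = adg(list(zip(ages, bws)))
    intercept = bws.mean() - slope * ages.mean()
    return intercept + slope * day


def derive_traits(
    bw: pd.DataFrame,
    animals: pd.DataFrame,
    feed: Optional[pd.DataFrame] = None,
    *,
    mid_fattening_day: float = 43.0,
    metabolic_exponent: float = 0.75,
    rfi_common_slopes: bool = False,
    days_on_feed: float = 21.0,
):
    """Derive individual and cage phenotypes from raw weekly records.

    Parameters
    ----------
    bw : long body-weight table (animal, age_days, bw_g), already trimmed of
        the discarded last fattening week.
    animals : per-animal labels (animal, batch, parity, litter_size_class,
        cage_size_class, cage, litter, regime).
    feed : weekly cage feed (cage, week, feed_g, animal_days); only cages of
        ad-libitum animals get feed-based traits.
    days_on_feed : length in days of the recorded feeding period (three
        weekly records -> 21 days).

    Returns ``(IndividualPhenotypes, CagePhenotypes or None)``.  Cage-mean
    ADG averages every member with at least two BW records.
    """
    animals = animals.copy()
    animals["animal"] = animals["animal"].astype(str)
    bw = bw.copy()
    bw["animal"] = bw["animal"].astype(str)

    per_animal = {}
    mw_per_animal = {}
    for animal_id, grp in bw.groupby("animal"):
        ages = grp["age_days"].to_numpy(float)
        bws = grp["bw_g"].to_numpy(float)
        if len(grp) < 2 or np.all(ages == ages[0]):
            continue
        per_animal[animal_id] = adg(list(zip(ages, bws)))
        mw_per_animal[animal_id] = metabolic_weight(
            _interp_bw(ages, bws, mid_fattening_day), metabolic_exponent
        )

    ind = animals.copy()
    ind["adg"] = ind["animal"].map(per_animal)
    ind = ind.dropna(subset=["adg"]).reset_index(drop=True)
    individual = IndividualPhenotypes(ind)

    if feed is None:
        return individual, None

    feed = feed.copy()
    feed["cage"] = feed["cage"].astype(str)
    members = {
        cage: tuple(grp["animal"]) for cage, grp in ind.groupby("cage")
    }
    cage_rows = []
    totals = feed.groupby("cage")[["feed_g", "animal_days"]].sum()
    for cage, grp in ind.groupby("cage"):
        if (grp["regime"] != "F").any() or cage not in totals.index:
            continue  # feed traits exist only for ad-libitum cages
        feed_g = totals.loc[cage, "feed_g"]
        animal_days = totals.loc[cage, "animal_days"]
        rabbits = animal_days / days_on_feed
        adfi_value = adfi(feed_g, days_on_feed, rabbits)
        mean_adg = grp["adg"].mean()
        mean_mw = np.mean([mw_per_animal[a] for a in grp["animal"]])
        cage_rows.append(
            {
                "cage": cage,
                "batch": grp["batch"].iloc[0],
                "cage_size_class": grp["cage_size_class"].iloc[0],
                "n_members": len(grp),
                "adfi": adfi_value,
                "mean_adg": mean_adg,
                "mean_mw": mean_mw,
                "fcr": fcr(adfi_value, mean_adg),
            }
        )
    if not cage_rows:
        return individual, None
    cage_frame = pd.DataFrame(cage_rows)
    cage_frame["rfi"] = rfi(cage_frame, common_slopes=rfi_common_slopes)
    cages = CagePhenotypes(
        frame=cage_frame,
        members={c: members[c] for c in cage_frame["cage"]},
    )
    return individual, cages
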