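"""Classification of o/p/a trait triplets into plasticity/adaptation categories.

For a trait measured at three stages — original environment (o), immediately
after the environmental shift (p, plastic stage), and after adaptation to the
new environment (a) — define

    PC = |L_p - L_o|   (plastic change)
    GC = |L_a - L_p|   (genetic change)
    TC = |L_a - L_o|   (total change)

A change is *appreciable* when it exceeds the effective cutoff
``max(theta * |L_o|, eps)``, where ``theta`` is a fraction of the original
trait value (0.2 by default) and ``eps`` an absolute floor (used for fluxes,
where tiny numerical differences are ignored).

Categories:

* reinforcing — PC and GC appreciable, same direction;
* reversing — PC and GC appreciable, opposite directions;
* plastic_only — only PC appreciable;
* genetic_only — only GC appreciable;
* unchanged — neither appreciable.

Reversing traits subdivide by how far the genetic change restores the
original value: restored (TC at or below the cutoff), over_restored
(GC > PC), under_restored (otherwise). When PC and GC are both appreciable,
plasticity is facilitating if GC < TC (plasticity reduced the genetic change
needed) and hindering if GC > TC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

CATEGORIES = ("reinforcing", "reversing", "plastic_only", "genetic_only", "unchanged")

#: Column order of the per-trait classification table.
TRAIT_COLUMNS = [
    "trait_id",
    "L_o",
    "L_p",
    "L_a",
    "PC",
    "GC",
    "TC",
    "cutoff",
    "category",
    "restoration",
    "plasticity_role",
    "pc_exceeds_tc",
]


@dataclass(frozen=True)
class TraitChange:
    """One trait's o/p/a values with change magnitudes and category labels."""

    trait_id: str
    L_o: float
    L_p: float
    L_a: float
    PC: float
    GC: float
    TC: float
    cutoff: float
    category: str
    restoration: str  # restored | over_restored | under_restored | n/a
    plasticity_role: str  # facilitating | hindering | n/a
    pc_exceeds_tc: bool


def classify_triplets(
    L_o,
    L_p,
    L_a,
    theta: float = 0.2,
    eps: float = 0.0,
    trait_ids=None,
) -> pd.DataFrame:
    """Classify arrays of o/p/a triplets; returns one row per trait.

    Parameters
    ----------
    theta
        Cutoff as a fraction of |L_o| (must be positive).
    eps
        Absolute floor of the effective cutoff; use the numeric flux
        tolerance (1e-4) for flux traits and 0 for expression traits.
    """
    if theta <= 0:
        raise ValueError(f"cutoff fraction theta must be positive, got {theta}")
    if eps < 0:
        raise ValueError(f"eps must be non-negative, got {eps}")
    L_o = np.asarray(L_o, dtype=float)
    L_p = np.asarray(L_p, dtype=float)
    L_a = np.asarray(L_a, dtype=float)
    if not (np.isfinite(L_o).all() and np.isfinite(L_p).all() and np.isfinite(L_a).all()):
        raise ValueError("non-finite trait values")
    if trait_ids is None:
        trait_ids = [f"t{i}" for i in range(L_o.size)]

    d_p = L_p - L_o
    d_g = L_a - L_p
    pc = np.abs(d_p)
    gc = np.abs(d_g)
    tc = np.abs(L_a - L_o)
    cutoff = np.maximum(theta * np.abs(L_o), eps)

    pc_app = pc > cutoff
    gc_app = gc > cutoff
    same_dir = d_p * d_g > 0

    category = np.full(L_o.shape, "unchanged", dtype=object)
    category[pc_app & ~gc_app] = "plastic_only"
    category[~pc_app & gc_app] = "genetic_only"
    category[pc_app & gc_app & same_dir] = "reinforcing"
    category[pc_app & gc_app & ~same_dir] = "reversing"

    restoration = np.full(L_o.shape, "n/a", dtype=object)
    rev = category == "reversing"
    restoration[rev & (tc <= cutoff)] = "restored"
    restoration[rev & (tc > cutoff) & (gc > pc)] = "over_restored"
    restoration[rev & (tc > cutoff) & (gc <= pc)] = "under_restored"

    role = np.full(L_o.shape, "n/a", dtype=object)
    both = pc_app & gc_app
    role[both & (gc < tc)] = "facilitating"
    role[both & (gc > tc)] = "hindering"

    return pd.DataFrame(
        {
            "trait_id": list(trait_ids),
            "L_o": L_o,
            "L_p": L_p,
            "L_a": L_a,
            "PC": pc,
            "GC": gc,
            "TC": tc,
            "cutoff": cutoff,
            "category": category,
            "restoration": restoration,
            "plasticity_role": role,
            "pc_exceeds_tc": pc > tc,
        },
        columns=TRAIT_COLUMNS,
    )


def classify_trait(
    L_o: float,
    L_p: float,
    L_a: float,
    theta: float = 0.2,
    eps: float = 0.0,
    trait_id: str = "trait",
) -> TraitChange:
    """Classify a single o/p/a triplet (scalar front-end of classify_triplets)."""
    row = classify_triplets([L_o], [L_p], [L_a], theta, eps, [trait_id]).iloc[0]
    return TraitChange(**{k: row[k] for k in TRAIT_COLUMNS})


# ---------------------------------------------------------------------- #
def binom_two_tailed(k: int, n: int) -> float:
    """Exact two-tailed binomial p-value at null probability 0.5.

    Doubled smaller tail, capped at 1: min(1, 2*min(P(X<=k), P(X>=k))).
    """
    _check_kn(k, n)
    lo = binom.cdf(k, n, 0.5)
    hi = binom.sf(k - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lo, hi)))


def binom_one_tailed(k: int, n: int) -> float:
    """Exact one-tailed binomial p-value: P(X >= k) under Binomial(n, 0.5)."""
    _check_kn(k, n)
    return float(binom.sf(k - 1, n, 0.5))


def _check_kn(k: int, n: int) -> None:
    if n < 1 or not (0 <= k <= n) or int(k) != k or int(n) != n:
        raise ValueError(f"invalid binomial counts k={k}, n={n}")


def expected_ratio(q: float) -> float:
    """Expected C_RI/C_RV when a fraction q of traits is forced to reverse.

    When PC > TC the genetic change must reverse the plastic change; the
    remaining traits split evenly between reinforcement and reversion under
    no other bias, giving E[C_RI/C_RV] = (1 - q)/(1 + q).
    """
    if not 0 <= q <= 1:
        raise ValueError(f"q must be in [0, 1], got {q}")
    return (1.0 - q) / (1.0 + q)


# ---------------------------------------------------------------------- #
@dataclass
class AdaptationSummary:
    """Per-adaptation category fractions and tests over a set of traits.

    All fractions use the full analyzed trait set as denominator.
    """

    n_traits: int
    n_reinforcing: int
    n_reversing: int
    c_ri: float
    c_rv: float
    ri_rv_ratio: float  # NaN when no reversing traits
    restored: float
    over_restored: float
    under_restored: float
    c_fac: float
    c_hin: float
    q: float
    plastic_only: float
    genetic_only: float
    mean_pc: float
    mean_tc: float
    p_two_tailed: float
    zero_counts: bool  # True when no trait was reinforcing or reversing

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def summarize(traits: pd.DataFrame) -> AdaptationSummary:
    """Summarize a classified trait table into an :class:`AdaptationSummary`."""
    n = len(traits)
    if n == 0:
        raise ValueError("cannot summarize an empty trait set")
    cat = traits["category"]
    n_ri = int((cat == "reinforcing").sum())
    n_rv = int((cat == "reversing").sum())
    k = n_ri + n_rv
    return AdaptationSummary(
        n_traits=n,
        n_reinforcing=n_ri,
        n_reversing=n_rv,
        c_ri=n_ri / n,
        c_rv=n_rv / n,
        ri_rv_ratio=(n_ri / n_rv) if n_rv else float("nan"),
        restored=float((traits["restoration"] == "restored").sum()) / n,
        over_restored=float((traits["restoration"] == "over_restored").sum()) / n,
        under_restored=float((traits["restoration"] == "under_restored").sum()) / n,
        c_fac=float((traits["plasticity_role"] == "facilitating").sum()) / n,
        c_hin=float((traits["plasticity_role"] == "hindering").sum()) / n,
        q=float(traits["pc_exceeds_tc"].sum()) / n,
        plastic_only=float((cat == "plastic_only").sum()) / n,
        genetic_only=float((cat == "genetic_only").sum()) / n,
        mean_pc=float(traits["PC"].mean()),
        mean_tc=float(traits["TC"].mean()),
        p_two_tailed=binom_two_tailed(n_ri, k) if k else 1.0,
        zero_counts=k == 0,
    )


def condition_on_tc(traits: pd.DataFrame) -> pd.DataFrame:
    """Subset of traits with appreciable total change (TC above the cutoff).

    This is the view available to comparative biology, where the plastic
    stage is unobserved and only o-vs-a differences are visible. Restored
    reversing traits are always excluded (their TC is at or below the cutoff).
    """
    return traits[traits["TC"] > traits["cutoff"]].reset_index(drop=True)


def drop_pc_gt_tc(traits: pd.DataFrame) -> pd.DataFrame:
    """Subset of traits with PC <= TC.

    Removing the PC > TC traits removes every geometrically forced reversion;
    if the reversion excess disappears on the remainder, the excess is fully
    explained by the PC > TC mechanism.
    """
    return traits[~traits["pc_exceeds_tc"]].reset_index(drop=True)
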