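"""NAD(P)H-enzyme binding equilibria and solution design.

To make solutions with a prescribed fraction of free (unbound) NAD(P)H,
the enzyme concentration is chosen from the ligand concentration L, the
dissociation constant K_D, and the number of binding sites per enzyme S:

    F   = alpha1 * L / (alpha1 * L + K_D)        (site occupancy at the
                                                  target free concentration)
    [E] = (1 - alpha1) * L / (F * S)             (enzyme needed to soak up
                                                  the bound ligand)

The forward direction — predicting the free fraction alpha1 from known
concentrations — solves the single-site mass balance

    L_free + S * E * L_free / (L_free + K_D) = L

in closed form (positive quadratic root); a competitive two-enzyme variant
solves the analogous balance by bisection.  All concentrations are in uM.

K_D values for specific enzymes are not bundled as authoritative constants:
they vary with buffer, temperature and isoform, and are required inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "BindingSystem",
    "site_occupancy",
    "required_enzyme_concentration",
    "predict_free_fraction",
    "predict_free_fraction_competitive",
    "mixture_table",
]


@dataclass
class BindingSystem:
    """One NAD(P)H-enzyme equilibrium: concentrations (uM), K_D (uM), sites."""

    ligand_total: float
    enzyme_total: float
    k_d: float
    sites: int = 1
    alpha1: float | None = None

    def __post_init__(self) -> None:
        if self.ligand_total < 0 or self.enzyme_total < 0 or self.k_d < 0:
            raise ValueError("concentrations and K_D must be >= 0")
        if self.sites < 1:
            raise ValueError("sites must be a positive integer")
        if self.alpha1 is not None and not 0 <= self.alpha1 <= 1:
            raise ValueError("alpha1 must be in [0, 1]")

    def free_fraction(self) -> float:
        return predict_free_fraction(
            self.ligand_total, self.enzyme_total, self.k_d, self.sites
        )


def site_occupancy(alpha1: float, ligand_total: float, k_d: float) -> float:
    """Fraction of enzyme binding sites occupied at free-ligand fraction alpha1.

    F = alpha1*L / (alpha1*L + K_D).  The free ligand concentration alpha1*L
    is what the sites equilibrate against.
    """
    if not 0 <= alpha1 <= 1:
        raise ValueError("alpha1 must be in [0, 1]")
    if ligand_total < 0 or k_d < 0:
        raise ValueError("concentrations must be >= 0")
    denom = alpha1 * ligand_total + k_d
    if denom == 0:
        raise ValueError("alpha1*L + K_D is zero; occupancy undefined")
    return alpha1 * ligand_total / denom


def required_enzyme_concentration(
    ligand_total: float, alpha1: float, k_d: float, sites: int
) -> float:
    """Enzyme concentration (uM) giving free-ligand fraction alpha1.

    The bound ligand (1 - alpha1)*L must equal occupied sites F*S*[E], so
    [E] = (1 - alpha1)*L / (F*S) with F the site occupancy at the target.
    """
    if not 0 < alpha1 < 1:
        raise ValueError("alpha1 must be strictly between 0 and 1")
    if sites < 1:
        raise ValueError("sites must be >= 1")
    occupancy = site_occupancy(alpha1, ligand_total, k_d)
    if occupancy == 0:
        raise ValueError("zero site occupancy: target free fraction unreachable")
    bound = (1.0 - alpha1) * ligand_total
    return bound / (occupancy * sites)


def predict_free_fraction(
    ligand_total: float, enzyme_total: float, k_d: float, sites: int = 1
) -> float:
    """Free-ligand fraction alpha1 at equilibrium with one enzyme.

    Solves L_free + S*E*L_free/(L_free + K_D) = L for L_free via the
    positive root of the quadratic and returns L_free / L.
    """
    if ligand_total < 0 or enzyme_total < 0 or k_d < 0:
        raise ValueError("concentrations must be >= 0")
    if ligand_total == 0:
        return 1.0
    if enzyme_total == 0:
        return 1.0
    site_total = sites * enzyme_total
    # L_free^2 + (K_D + S*E - L) L_free - K_D * L = 0; the positive root is
    # written in the cancellation-free form when b > 0 (large enzyme excess)
    b = k_d + site_total - ligand_total
    disc = np.sqrt(b * b + 4.0 * k_d * ligand_total)
    if b > 0:
        free = 2.0 * k_d * ligand_total / (b + disc)
    else:
        free = 0.5 * (-b + disc)
    return float(free / ligand_total)


def predict_free_fraction_competitive(
    ligand_total: float,
    enzyme_totals: Sequence[float],
    k_ds: Sequence[float],
    sites: Sequence[int],
) -> tuple[float, np.ndarray]:
    """Free fraction and per-enzyme bound ligand with several competing enzymes.

    Bisection on the free-ligand concentration in the mass balance
    L_free + sum_i S_i*E_i*L_free/(L_free + K_Di) = L.  Returns
    (alpha1, bound-ligand concentrations per enzyme, uM).
    """
    enzyme_totals = np.asarray(enzyme_totals, dtype=float)
    k_ds = np.asarray(k_ds, dtype=float)
    sites_arr = np.asarray(sites, dtype=float)
    if ligand_total <= 0:
        return 1.0, np.zeros_like(enzyme_totals)

    def balance(free: float) -> float:
        occupied = sites_arr * enzyme_totals * free / (free + k_ds)
        return free + occupied.sum() - ligand_total

    if balance(ligand_total) <= 0:  # no binding capacity at all
        return 1.0, np.zeros_like(enzyme_totals)
    free = brentq(balance, 0.0, ligand_total, xtol=1e-14, rtol=1e-14)
    bound = sites_arr * enzyme_totals * free / (free + k_ds)
    return float(free / ligand_total), bound


def mixture_table(
    ldh_um: Sequence[float],
    mdh_um: Sequence[float],
    mixture_ids: Sequence | None = None,
    ligand_um: float = 50.0,
) -> pd.DataFrame:
    """Two-enzyme mixture design table with derived ratio and total columns.

    Returns a DataFrame with full-precision ``ldh_fraction`` ([LDH]/([LDH]+
    [MDH])) and ``total_enzyme_um`` columns plus 2-decimal display-rounded
    ``ldh_fraction_display``.
    """
    ldh = np.asarray(ldh_um, dtype=float)
    mdh = np.asarray(mdh_um, dtype=float)
    if ldh.shape != mdh.shape:
        raise ValueError("LDH and MDH concentration lists differ in length")
    if np.any(ldh < 0) or np.any(mdh < 0):
        raise ValueError("concentrations must be >= 0")
    total = ldh + mdh
    if np.any(total == 0):
        raise ValueError("each mixture needs at least one nonzero enzyme")
    if mixture_ids is None:
        mixture_ids = [f"Mixture {i + 1}" for i in range(len(ldh))]
    frac = ldh / total
    return pd.DataFrame(
        {
            "mixture": list(mixture_ids),
            "ldh_um": ldh,
            "mdh_um": mdh,
            "ligand_um": ligand_um,
            "ldh_fraction": frac,
            "ldh_fraction_display": np.round(frac, 2),
            "total_enzyme_um": total,
        }
    )
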