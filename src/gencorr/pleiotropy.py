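"""Derived quantities: correlation decomposition and the shared-variant bound.

Two ideas live here. First, for standardized traits the phenotypic
correlation splits additively over components, so the fraction contributed by
the genetic component is rho * sqrt(h2_1 * h2_2) / r_p. Second, if causal
variants are classified as trait-specific or pleiotropic with equal
per-variant effect variance, a genetic correlation rho pins down how many
variants the traits must share: the shared fraction c/(c+s1+s2) cannot fall
below rho^2.
"""

from __future__ import annotations

import warnings

import numpy as np

from .errors import ParameterError
from .twin_ace import AceParams, implied_phenotypic_corr


def genetic_share(rho: float, h2_1: float, h2_2: float, r_p: float) -> float:
    """Fraction of the phenotypic correlation attributable to the genetic component.

    ``rho`` is the cross-trait genetic correlation, ``h2_1``/``h2_2`` the
    per-trait heritabilities (twin or SNP-based), ``r_p`` the observed
    phenotypic correlation; traits are assumed standardized. A result outside
    [-1, 1] signals mutually inconsistent inputs and is returned with a
    warning rather than suppressed.
    """
    if not (-1.0 <= rho <= 1.0 and 0.0 <= h2_1 <= 1.0 and 0.0 <= h2_2 <= 1.0):
        raise ParameterError("rho must lie in [-1,1] and heritabilities in [0,1]")
    if r_p == 0.0:
        raise ParameterError("r_p must be nonzero")
    share = rho * np.sqrt(h2_1 * h2_2) / r_p
    if abs(share) > 1.0 + 1e-9:
        warnings.warn(
            f"genetic share {share:.3f} exceeds 1 in magnitude; inputs are inconsistent",
            stacklevel=2,
        )
    return float(share)


def component_shares(params: AceParams, r_p: float | None = None) -> dict[str, float]:
    """A/C/E shares of the phenotypic correlation implied by twin estimates.

    With ``r_p`` left at the model-implied correlation the three shares sum to
    one exactly.
    """
    if r_p is None:
        r_p = implied_phenotypic_corr(params)
    vy = np.sqrt(params.total_variance(1) * params.total_variance(2))
    out = {}
    for comp, rho in (("A", params.rho_A), ("C", params.rho_C), ("E", params.rho_E)):
        v1 = getattr(params, f"V_{comp}1")
        v2 = getattr(params, f"V_{comp}2")
        out[comp] = float(rho * np.sqrt(v1 * v2) / (vy * r_p))
    return out


def implied_genetic_corr(c: float, s1: float, s2: float) -> float:
    """Genetic correlation implied by variant counts under equal effect variance.

    ``c`` pleiotropic variants shared by both traits and ``s1``/``s2``
    trait-specific ones give corr = c / sqrt((c+s1)(c+s2)).
    """
    if c < 0 or s1 < 0 or s2 < 0:
        raise ParameterError("variant counts must be >= 0")
    if c + s1 <= 0 or c + s2 <= 0:
        raise ParameterError("each trait needs at least one causal variant")
    return float(c / np.sqrt((c + s1) * (c + s2)))


def min_shared_fraction(rho: float) -> float:
    """Smallest possible shared-variant fraction consistent with ``rho``.

    Minimizes c/(c+s1+s2) over all non-negative counts with
    implied_genetic_corr(c, s1, s2) = rho. The minimum is rho**2, attained
    when one trait carries no specific variants (verified against the numeric
    scan in :func:`min_shared_fraction_scan`).
    """
    if not 0.0 <= rho <= 1.0:
        raise ParameterError("rho must lie in [0, 1]")
    return float(rho * rho)


def min_shared_fraction_scan(rho: float, n_grid: int = 20_001) -> float:
    """Brute-force minimum of the shared fraction over the constraint surface.

    Both the constraint and the objective are scale-invariant in (c, s1, s2),
    so fix c = 1 and scan s1 on a grid; s2 then follows exactly from
    rho = 1/sqrt((1+s1)(1+s2)), feasible while s2 >= 0. Serves as the
    independent oracle for the closed form.
    """
    if not 0.0 < rho <= 1.0:
        raise ParameterError("the scan requires rho in (0, 1]")
    s1_max = 1.0 / (rho * rho) - 1.0
    s1 = np.linspace(0.0, s1_max, n_grid)
    s2 = 1.0 / (rho * rho * (1.0 + s1)) - 1.0
    frac = 1.0 / (1.0 + s1 + s2)
    return float(frac.min())
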