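"""Bivariate ACE twin model fitted by full-information maximum likelihood.

The model partitions each standardized trait into additive-genetic (A),
shared-environment (C) and non-shared-environment (E) components, with three
cross-trait correlations (rho_A, rho_C, rho_E) linking the two traits'
components. Cross-twin genetic sharing is 1 for MZ pairs and 1/2 for DZ pairs;
C is shared fully within a pair regardless of zygosity, E not at all.
Dominance and interaction components are fixed at zero.

Likelihood evaluation marginalizes missing trait cells per family (true FIML):
families are grouped by (zygosity, missingness pattern) so each distinct
pattern costs one Cholesky factorization regardless of sample size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .core_io import TwinTable
from .errors import FitError, ParameterError

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)
PARAM_NAMES = ["V_A1", "V_C1", "V_E1", "V_A2", "V_C2", "V_E2", "rho_A", "rho_C", "rho_E"]


@dataclass
class AceParams:
    """Six variance components plus the three cross-trait correlations."""

    V_A1: float
    V_C1: float
    V_E1: float
    V_A2: float
    V_C2: float
    V_E2: float
    rho_A: float
    rho_C: float
    rho_E: float

    def __post_init__(self):
        for name in ("V_A1", "V_C1", "V_E1", "V_A2", "V_C2", "V_E2"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("rho_A", "rho_C", "rho_E"):
            r = getattr(self, name)
            if not -1.0 <= r <= 1.0:
                raise ParameterError(f"{name} must lie in [-1, 1], got {r}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES])

    @classmethod
    def from_array(cls, arr) -> "AceParams":
        return cls(**dict(zip(PARAM_NAMES, map(float, arr))))

    def total_variance(self, trait: int) -> float:
        return (
            getattr(self, f"V_A{trait}")
            + getattr(self, f"V_C{trait}")
            + getattr(self, f"V_E{trait}")
        )

    def h2(self, trait: int) -> float:
        vy = self.total_variance(trait)
        if vy <= 0:
            raise ParameterError(f"trait {trait} has zero total variance")
        return getattr(self, f"V_A{trait}") / vy


def expected_pair_cov(params: AceParams, zygosity: str) -> np.ndarray:
    """Model 4x4 covariance, ordered (twin1.t1, twin1.t2, twin2.t1, twin2.t2).

    Cross-twin same-trait covariance is r*V_A + V_C with r = 1 (MZ) or 1/2
    (DZ); cross-twin cross-trait replaces V_A, V_C by their cross-trait
    covariances rho_A*sqrt(V_A1 V_A2) and rho_C*sqrt(V_C1 V_C2).
    """
    if zygosity == "MZ":
        r = 1.0
    elif zygosity == "DZ":
        r = 0.5
    else:
        raise ParameterError(f"zygosity must be 'MZ' or 'DZ', got {zygosity!r}")
    cov_a = params.rho_A * np.sqrt(params.V_A1 * params.V_A2)
    cov_c = params.rho_C * np.sqrt(params.V_C1 * params.V_C2)
    cov_e = params.rho_E * np.sqrt(params.V_E1 * params.V_E2)
    within = np.array(
        [
            [params.total_variance(1), cov_a + cov_c + cov_e],
            [cov_a + cov_c + cov_e, params.total_variance(2)],
        ]
    )
    between = np.array(
        [
            [r * params.V_A1 + params.V_C1, r * cov_a + cov_c],
            [r * cov_a + cov_c, r * params.V_A2 + params.V_C2],
        ]
    )
    return np.block([[within, between], [between, within]])


def _pattern_groups(twins: TwinTable):
    """Group family rows by (zygosity, observed-cell pattern).

    Returns a list of (zygosity, observed index tuple, data submatrix) with
    all-missing families dropped (they contribute zero to the likelihood).
    """
    y = twins.trait_matrix()
    zyg = twins.data["zygosity"].to_numpy()
    observed = ~np.isnan(y)
    groups = []
    for z in ("MZ", "DZ"):
        zmask = zyg == z
        if not zmask.any():
            continue
        pats, inverse = np.unique(observed[zmask], axis=0, return_inverse=True)
        yz = y[zmask]
        for k, pat in enumerate(pats):
            idx = np.flatnonzero(pat)
            if idx.size == 0:
                continue
            groups.append((z, tuple(idx), yz[inverse == k][:, idx]))
    return groups


def ace_loglik(params: AceParams, twins: TwinTable) -> float:
    """FIML log-likelihood of the twin table under a zero-mean bivariate ACE model."""
    return _loglik_groups(params, _pattern_groups(twins))


_singular_warned = False


def _loglik_groups(params: AceParams, groups) -> float:
    global _singular_warned
    total = 0.0
    covs = {z: expected_pair_cov(params, z) for z in ("MZ", "DZ")}
    for z, idx, ysub in groups:
        sub = covs[z][np.ix_(idx, idx)]
        try:
            chol = np.linalg.cholesky(sub)
        except np.linalg.LinAlgError:
            if not _singular_warned:
                logger.warning("singular model covariance encountered; loglik = -inf")
                _singular_warned = True
            return -np.inf
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        sol = np.linalg.solve(chol, ysub.T)  # k x g
        quad = np.sum(sol * sol)
        k, g = len(idx), ysub.shape[0]
        total += -0.5 * (g * (k * _LOG2PI + logdet) + quad)
    return float(total)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_VAR_FLOOR = 1e-8


def _to_theta(params: AceParams) -> np.ndarray:
    a = params.as_array()
    theta = np.empty(9)
    theta[:6] = np.log(np.maximum(a[:6], _VAR_FLOOR))
    theta[6:] = np.arctanh(np.clip(a[6:], -1 + 1e-10, 1 - 1e-10))
    return theta


def _from_theta(theta: np.ndarray) -> AceParams:
    a = np.empty(9)
    a[:6] = np.exp(np.clip(theta[:6], -40.0, 40.0))
    a[6:] = np.tanh(theta[6:])
    return AceParams.from_array(a)


@dataclass
class AceFit:
    """Result of a bivariate ACE fit."""

    estimates: AceParams
    loglik: float
    n_pairs_used: dict[str, int]
    h2: tuple[float, float]
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_starts: int = 0


def _standardize_traits(twins: TwinTable) -> TwinTable:
    df = twins.data.copy()
    for t in (1, 2):
        cols = [f"twin1_trait{t}", f"twin2_trait{t}"]
        vals = df[cols].to_numpy(dtype=float)
        mu = np.nanmean(vals)
        sd = np.nanstd(vals)
        if sd <= 0:
            raise ParameterError(f"trait{t} has zero variance; cannot standardize")
        for c in cols:
            df[c] = (df[c] - mu) / sd
    return TwinTable(df)


def _moment_start(twins: TwinTable) -> AceParams:
    y = twins.trait_matrix()
    vy = [np.nanvar(y[:, [0, 2]]), np.nanvar(y[:, [1, 3]])]
    t1 = np.concatenate([y[:, 0], y[:, 2]])
    t2 = np.concatenate([y[:, 1], y[:, 3]])
    ok = ~(np.isnan(t1) | np.isnan(t2))
    r = float(np.corrcoef(t1[ok], t2[ok])[0, 1]) if ok.sum() > 2 else 0.0
    r = float(np.clip(r, -0.95, 0.95))
    return AceParams(
        vy[0] / 3, vy[0] / 3, vy[0] / 3, vy[1] / 3, vy[1] / 3, vy[1] / 3, r, r, r
    )


def fit_ace(
    twins: TwinTable,
    standardize: bool = False,
    n_starts: int = 5,
    seed: int = 0,
) -> AceFit:
    """Maximize the FIML likelihood over (log-variance, atanh-correlation) space.

    Multi-start: one start at equal component thirds with all correlations at
    the observed phenotypic correlation, the rest jittered with ``seed``.
    Variance estimates below the numerical floor are reported as exactly 0.
    """
    if standardize:
        twins = _standardize_traits(twins)
    counts = twins.counts_by_zygosity()
    if counts["MZ"] < 2 or counts["DZ"] < 2:
        logger.warning("fewer than 2 families of some zygosity: %s", counts)
    groups = _pattern_groups(twins)
    theta0 = _to_theta(_moment_start(twins))
    rng = np.random.default_rng(seed)
    starts = [theta0] + [
        theta0 + rng.normal(scale=0.5, size=9) for _ in range(max(0, n_starts - 1))
    ]

    def nll(theta):
        ll = _loglik_groups(_from_theta(theta), groups)
        return np.inf if not np.isfinite(ll) else -ll

    best = None
    for th in starts:
        res = optimize.minimize(nll, th, method="L-BFGS-B")
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitError("all optimisation starts failed to produce a finite likelihood")
    est = _from_theta(best.x)
    arr = est.as_array()
    arr[:6] = np.where(arr[:6] < 10 * _VAR_FLOOR, 0.0, arr[:6])
    est = AceParams.from_array(arr)
    return AceFit(
        estimates=est,
        loglik=-float(best.fun),
        n_pairs_used=counts,
        h2=(est.h2(1), est.h2(2)),
        n_starts=len(starts),
    )


# ---------------------------------------------------------------------------
# profile confidence intervals
# ---------------------------------------------------------------------------

def _profile_nll(twins_groups, fixed_name: str, fixed_value: float, theta_start):
    """Maximized loglik with one natural parameter held fixed."""
    i = PARAM_NAMES.index(fixed_name)
    free = [j for j in range(9) if j != i]

    def build(theta_free):
        full = np.empty(9)
        full[free] = theta_free
        if i < 6:
            full[i] = np.log(max(fixed_value, _VAR_FLOOR))
        else:
            full[i] = np.arctanh(np.clip(fixed_value, -1 + 1e-10, 1 - 1e-10))
        return full

    def nll(theta_free):
        ll = _loglik_groups(_from_theta(build(theta_free)), twins_groups)
        return np.inf if not np.isfinite(ll) else -ll

    res = optimize.minimize(nll, theta_start[free], method="L-BFGS-B")
    return float(res.fun)


def profile_ci(
    fit: AceFit,
    twins: TwinTable,
    param: str,
    level: float = 0.95,
    tol: float = 1e-4,
) -> tuple[float, float, dict]:
    """Likelihood-profile interval: bounds where 2*(loglik drop) hits chi2_1(level).

    Returns (lo, hi, flags); a bound that runs into the parameter's domain edge
    is reported at the edge with ``flags['lo_at_edge']``/``['hi_at_edge']`` set.
    """
    if param not in PARAM_NAMES:
        raise ParameterError(f"unknown parameter {param!r}")
    est = float(getattr(fit.estimates, param))
    if level <= 0:
        return est, est, {}
    groups = _pattern_groups(twins)
    target = -fit.loglik + 0.5 * stats.chi2.ppf(level, df=1)
    theta_hat = _to_theta(fit.estimates)
    is_var = PARAM_NAMES.index(param) < 6

    def drop_at(value: float) -> float:
        return _profile_nll(groups, param, value, theta_hat) - target

    flags = {}
    bounds = []
    for direction in (-1, +1):
        # expand outward from the estimate until the profile crosses the target
        lo_edge, hi_edge = (0.0, np.inf) if is_var else (-1.0, 1.0)
        step = max(0.1 * max(abs(est), 0.1), tol * 10)
        x_in, x_out = est, est
        crossed = False
        for _ in range(60):
            x_try = x_out + direction * step
            if is_var:
                x_try = max(x_try, lo_edge)
            else:
                x_try = float(np.clip(x_try, lo_edge, hi_edge))
            if drop_at(x_try) > 0:
                x_in, x_out = x_out, x_try
                crossed = True
                break
            x_out = x_try
            at_edge = (x_try <= lo_edge + 1e-12) or (x_try >= hi_edge - 1e-12)
            if at_edge:
                break
            step *= 1.6
        if not crossed:
            bounds.append(x_out)
            flags["lo_at_edge" if direction < 0 else "hi_at_edge"] = True
            continue
        a, b = sorted((x_in, x_out))
        while b - a > tol:
            mid = 0.5 * (a + b)
            if drop_at(mid) > 0:
                if direction < 0:
                    a = mid
                else:
                    b = mid
            else:
                if direction < 0:
                    b = mid
                else:
                    a = mid
        bounds.append(0.5 * (a + b))
    lo, hi = sorted(bounds)
    return lo, hi, flags


def implied_phenotypic_corr(params: AceParams) -> float:
    """Phenotypic correlation implied by the fitted components:
    [rho_A sqrt(V_A1 V_A2) + rho_C sqrt(V_C1 V_C2) + rho_E sqrt(V_E1 V_E2)]
    / sqrt(V_Y1 V_Y2).
    """
    vy1, vy2 = params.total_variance(1), params.total_variance(2)
    if vy1 <= 0 or vy2 <= 0:
        raise ParameterError("total variance must be positive for both traits")
    num = (
        params.rho_A * np.sqrt(params.V_A1 * params.V_A2)
        + params.rho_C * np.sqrt(params.V_C1 * params.V_C2)
        + params.rho_E * np.sqrt(params.V_E1 * params.V_E2)
    )
    return float(num / np.sqrt(vy1 * vy2))
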