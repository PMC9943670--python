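"""Equilibrium model of a bipartite TF homodimerizing on a palindromic probe.

A palindromic probe D carries two equivalent half-sites. A protein monomer P
binds one half-site with dissociation constant ``Kd``; a second monomer binds
the remaining half-site with its affinity modulated by the dimensionless
cooperativity factor ``omega`` (omega > 1: positive cooperativity, omega = 1:
independent half-sites, omega < 1: negative cooperativity, omega = 0: dimer
formation forbidden). With free-protein concentration ``p`` the three probe
species have relative equilibrium abundances::

    free : monomer : dimer  =  1 : 2 p/Kd : omega (p/Kd)^2

The statistical factor 2 on the monomer term aggregates the two singly-bound
configurations, which co-migrate as one gel band. Because probe (tens of nM)
and protein (tens to hundreds of nM) are comparable, protein depletion is not
negligible: ``p`` is obtained by root-finding on the protein conservation
equation rather than approximated by the total concentration.

The per-lane cooperativity estimator inverts the model from observed band
fractions: ``omega_hat = 4 f_dim f_free / f_mon**2``, exact at every
concentration (the ratio f_dim*f_free/f_mon**2 equals omega/4 independently
of p and Kd). Lanes where any band fraction falls below an inclusion
threshold (default 0.05) are excluded from the summary; if no lane passes,
the estimate is Not Determined.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "BindingParameters",
    "TitrationCondition",
    "SpeciesFractions",
    "LaneQuantification",
    "CooperativityEstimate",
    "FitResult",
    "IdentifiabilityWarning",
    "NOT_DETERMINED",
    "OMEGA_STATISTICAL_FACTOR",
    "solve_species",
    "quantify_lane",
    "estimate_omega",
    "fit_titration",
    "dual_probe_preference",
]

#: Combinatorial constant of the per-lane estimator: with relative abundances
#: 1 : 2p/Kd : omega (p/Kd)^2, f_dim*f_free/f_mon^2 = omega/4, hence the 4.
OMEGA_STATISTICAL_FACTOR = 4.0

#: Sentinel returned when no lane satisfies the inclusion rule.
NOT_DETERMINED = "ND"


class IdentifiabilityWarning(UserWarning):
    """Raised when a titration carries no information about (Kd, omega)."""


@dataclass(frozen=True)
class BindingParameters:
    """Half-site dissociation constant (nM) and cooperativity factor."""

    kd_half_site: float
    omega: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.kd_half_site) and self.kd_half_site > 0):
            raise ValueError(f"kd_half_site must be finite and > 0, got {self.kd_half_site}")
        if not (math.isfinite(self.omega) and self.omega >= 0):
            raise ValueError(f"omega must be finite and >= 0, got {self.omega}")


@dataclass(frozen=True)
class TitrationCondition:
    """Probe concentration (nM) and an increasing protein series (nM)."""

    probe_total: float
    protein_totals: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (math.isfinite(self.probe_total) and self.probe_total > 0):
            raise ValueError(f"probe_total must be > 0, got {self.probe_total}")
        pt = tuple(float(x) for x in self.protein_totals)
        if any(x < 0 or not math.isfinite(x) for x in pt):
            raise ValueError("protein_totals must be finite and >= 0")
        if any(b <= a for a, b in zip(pt, pt[1:])):
            raise ValueError("protein_totals must be strictly increasing")
        object.__setattr__(self, "protein_totals", pt)


@dataclass(frozen=True)
class SpeciesFractions:
    """Fractions of probe molecules that are unbound, singly or doubly bound."""

    f_free: float
    f_mon: float
    f_dim: float

    def __post_init__(self) -> None:
        for name, v in (("f_free", self.f_free), ("f_mon", self.f_mon), ("f_dim", self.f_dim)):
            if not (math.isfinite(v) and -1e-12 <= v <= 1 + 1e-12):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if abs(self.f_free + self.f_mon + self.f_dim - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1 within 1e-9")

    def as_array(self) -> np.ndarray:
        return np.array([self.f_free, self.f_mon, self.f_dim])


@dataclass(frozen=True)
class LaneQuantification:
    """One gel lane: band volumes plus the derived species fractions."""

    intensity_free: float
    intensity_mon: float
    intensity_dim: float
    protein_total: float
    fractions: SpeciesFractions = field(init=False)

    def __post_init__(self) -> None:
        ints = (self.intensity_free, self.intensity_mon, self.intensity_dim)
        if any(not math.isfinite(v) or v < 0 for v in ints):
            raise ValueError(f"band intensities must be finite and >= 0, got {ints}")
        total = sum(ints)
        if total <= 0:
            raise ValueError("empty lane: all three band intensities are zero")
        if not (math.isfinite(self.protein_total) and self.protein_total >= 0):
            raise ValueError(f"protein_total must be >= 0, got {self.protein_total}")
        object.__setattr__(
            self,
            "fractions",
            SpeciesFractions(ints[0] / total, ints[1] / total, ints[2] / total),
        )


@dataclass(frozen=True)
class CooperativityEstimate:
    """Per-lane omega estimates with the inclusion mask and summary stats.

    ``mean``/``sd`` are ``NOT_DETERMINED`` when no lane passes the inclusion
    rule (mirroring "ND" in published figures); they are never NaN.
    """

    per_lane_omega: tuple[float, ...]
    included_lanes: tuple[bool, ...]
    inclusion_threshold: float
    mean: float | str
    sd: float | str
    n: int

    @property
    def determined(self) -> bool:
        return self.n > 0


def solve_species(
    params: BindingParameters, protein_total: float, probe_total: float
) -> SpeciesFractions:
    """Solve the mass-action equilibrium for the three probe species.

    Finds the free-protein concentration ``p`` satisfying conservation
    ``P_tot = p + [PD] + 2 [P2D]`` by bracketed root-finding on
    ``[0, P_tot]`` (the residual is strictly increasing in p), then returns
    the normalized probe fractions ``1 : 2p/Kd : omega (p/Kd)^2``.

    Parameters are in nM. Converges to ``|residual| < 1e-10 * P_tot``.
    """
    if not (math.isfinite(protein_total) and protein_total >= 0):
        raise ValueError(f"protein_total must be finite and >= 0, got {protein_total}")
    if not (math.isfinite(probe_total) and probe_total > 0):
        raise ValueError(f"probe_total must be finite and > 0, got {probe_total}")

    kd, omega, d_tot = params.kd_half_site, params.omega, probe_total

    if protein_total == 0.0:
        return SpeciesFractions(1.0, 0.0, 0.0)

    def bound_protein(p: float) -> float:
        x = p / kd
        z = 1.0 + 2.0 * x + omega * x * x
        # protein molecules sequestered per probe: 1 in PD, 2 in P2D
        return d_tot * (2.0 * x + 2.0 * omega * x * x) / z

    def residual(p: float) -> float:
        return p + bound_protein(p) - protein_total

    # residual(0) = -P_tot < 0, residual(P_tot) = bound >= 0: bracketed.
    p_free = brentq(residual, 0.0, protein_total, xtol=1e-15, rtol=1e-14, maxiter=200)

    def residual_prime(p: float) -> float:
        x = p / kd
        u = 2.0 * x + 2.0 * omega * x * x
        z = 1.0 + 2.0 * x + omega * x * x
        du = 2.0 + 4.0 * omega * x
        dz = 2.0 + 2.0 * omega * x
        return 1.0 + d_tot * (du * z - u * dz) / (z * z * kd)

    # Newton polish: brentq's absolute xtol can leave a residual above the
    # target when the residual slope is steep (tiny p at huge omega)
    for _ in range(5):
        r = residual(p_free)
        if abs(r) <= 1e-12 * protein_total:
            break
        step = r / residual_prime(p_free)
        p_new = p_free - step
        if 0.0 <= p_new <= protein_total:
            p_free = p_new
        else:
            break

    if abs(residual(p_free)) > 1e-10 * protein_total:
        raise ArithmeticError(
            f"conservation solver did not converge: residual={residual(p_free):.3e} "
            f"at p={p_free:.6e} (P_tot={protein_total}, Kd={kd}, omega={omega})"
        )

    x = p_free / kd
    z = 1.0 + 2.0 * x + omega * x * x
    return SpeciesFractions(1.0 / z, 2.0 * x / z, omega * x * x / z)


def quantify_lane(
    intensities: Sequence[float], protein_total: float
) -> LaneQuantification:
    """Normalize three band volumes (free, monomer, dimer) into fractions."""
    free, mon, dim = intensities
    return LaneQuantification(float(free), float(mon), float(dim), float(protein_total))


def omega_from_fractions(fr: SpeciesFractions) -> float:
    """Per-lane inversion of the dimer model: 4 f_dim f_free / f_mon^2."""
    if fr.f_mon == 0:
        raise ZeroDivisionError("monomer fraction is zero; omega undefined for this lane")
    return OMEGA_STATISTICAL_FACTOR * fr.f_dim * fr.f_free / (fr.f_mon * fr.f_mon)


def estimate_omega(
    lanes: Sequence[LaneQuantification], inclusion_threshold: float = 0.05
) -> CooperativityEstimate:
    """Per-lane cooperativity estimates with the band-fraction inclusion rule.

    A lane enters the summary only if all three band fractions are at least
    ``inclusion_threshold``. With no passing lane the summary is reported as
    Not Determined rather than NaN.
    """
    if not lanes:
        raise ValueError("at least one lane is required")
    if not (0.0 < inclusion_threshold <= 1.0 / 3.0):
        raise ValueError(
            f"inclusion_threshold must lie in (0, 1/3], got {inclusion_threshold}"
        )

    omegas: list[float] = []
    included: list[bool] = []
    for lane in lanes:
        fr = lane.fractions
        ok = min(fr.f_free, fr.f_mon, fr.f_dim) >= inclusion_threshold
        included.append(ok)
        omegas.append(omega_from_fractions(fr) if fr.f_mon > 0 else math.nan)

    kept = [w for w, ok in zip(omegas, included) if ok]
    if kept:
        mean: float | str = float(np.mean(kept))
        sd: float | str = float(np.std(kept, ddof=1)) if len(kept) > 1 else 0.0
    else:
        mean = sd = NOT_DETERMINED
    return CooperativityEstimate(
        per_lane_omega=tuple(omegas),
        included_lanes=tuple(included),
        inclusion_threshold=inclusion_threshold,
        mean=mean,
        sd=sd,
        n=len(kept),
    )


@dataclass(frozen=True)
class FitResult:
    """Global titration fit: point estimates with approximate standard errors."""

    params: BindingParameters
    kd_stderr: float
    omega_stderr: float
    cost: float
    n_lanes: int


def _titration_residuals(
    log_params: np.ndarray, lanes: Sequence[LaneQuantification], probe_total: float
) -> np.ndarray:
    kd, omega = np.exp(log_params)
    res = []
    bp = BindingParameters(kd, omega)
    for lane in lanes:
        model = solve_species(bp, lane.protein_total, probe_total).as_array()
        res.append(lane.fractions.as_array() - model)
    return np.concatenate(res)


def fit_titration(
    lanes: Sequence[LaneQuantification], condition: TitrationCondition
) -> FitResult:
    """Global least-squares fit of (Kd, omega) to a full titration series.

    Minimizes the squared deviation between observed and model band fractions
    over all lanes, optimizing in log-space (positivity by construction) with
    a multistart grid over Kd in {10, 100, 1000} nM and omega in
    {0.1, 1, 10}. Degenerate series (all lanes essentially free, or all
    essentially saturated) trigger an ``IdentifiabilityWarning``.
    """
    if len(lanes) < 3:
        raise ValueError("fit_titration needs at least 3 lanes")
    if len(lanes) != len(condition.protein_totals):
        raise ValueError("lane count does not match the titration condition")

    frees = [lane.fractions.f_free for lane in lanes]
    if all(f > 0.99 for f in frees):
        warnings.warn(
            "all lanes are >99% free probe: no binding signal, (Kd, omega) "
            "are not identifiable",
            IdentifiabilityWarning,
            stacklevel=2,
        )
    elif all(f < 0.01 for f in frees):
        warnings.warn(
            "all lanes are saturated: Kd is not identifiable from this series",
            IdentifiabilityWarning,
            stacklevel=2,
        )

    best = None
    for kd0 in (10.0, 100.0, 1000.0):
        for om0 in (0.1, 1.0, 10.0):
            sol = least_squares(
                _titration_residuals,
                x0=np.log([kd0, om0]),
                args=(lanes, condition.probe_total),
                method="lm",
                xtol=1e-14,
                ftol=1e-14,
            )
            if best is None or sol.cost < best.cost:
                best = sol
    assert best is not None

    kd, omega = np.exp(best.x)
    # delta-method SEs: cov(log params) from the residual jacobian
    dof = max(best.fun.size - 2, 1)
    s2 = 2.0 * best.cost / dof
    jtj = best.jac.T @ best.jac
    try:
        cov_log = s2 * np.linalg.inv(jtj)
        kd_se = kd * math.sqrt(max(cov_log[0, 0], 0.0))
        om_se = omega * math.sqrt(max(cov_log[1, 1], 0.0))
    except np.linalg.LinAlgError:
        kd_se = om_se = math.inf
    return FitResult(
        params=BindingParameters(float(kd), float(omega)),
        kd_stderr=float(kd_se),
        omega_stderr=float(om_se),
        cost=float(best.cost),
        n_lanes=len(lanes),
    )


def dual_probe_preference(
    lanes_probe_a: Sequence[LaneQuantification],
    lanes_probe_b: Sequence[LaneQuantification],
) -> tuple[np.ndarray, float]:
    """Per-concentration dimer-fraction difference between two probes.

    Emulates a single-tube dual-color experiment where both probes see the
    same protein series. Returns ``index(c) = f_dim_A(c) - f_dim_B(c)`` per
    concentration and its mean; positive values mean the protein prefers to
    dimerize on probe A.
    """
    if len(lanes_probe_a) != len(lanes_probe_b):
        raise ValueError("probe A and probe B need the same number of lanes")
    for la, lb in zip(lanes_probe_a, lanes_probe_b):
        if not math.isclose(la.protein_total, lb.protein_total, rel_tol=1e-9):
            raise ValueError(
                f"mismatched protein concentrations: {la.protein_total} vs {lb.protein_total}"
            )
    index = np.array(
        [la.fractions.f_dim - lb.fractions.f_dim for la, lb in zip(lanes_probe_a, lanes_probe_b)]
    )
    return index, float(index.mean())
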