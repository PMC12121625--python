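"""Lambda schedules, gradient integration, bootstrap errors and
thermodynamic-cycle assembly.

The free energy of an alchemical transformation is the thermodynamic
integral of the mean gradient over the coupling parameter,

    dG = int_0^1 <dV/dlambda> dlambda  ~=  sum_i w_i <dV/dlambda>_i,

with nodes and weights w_i set by the integration rule: Gauss-Legendre
quadrature mapped to [0, 1], or the composite trapezoid rule on an
explicit node list. Relative binding free energies subtract the
solvated-ligand leg from the complex leg; absolute binding free
energies combine three alchemical legs with an analytic term for
releasing the orientational (Boresch-style) restraints of the
noninteracting ligand into the standard-state volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import ThermoConstants

__all__ = [
    "LambdaSchedule",
    "FreeEnergyResult",
    "RbfeCycle",
    "AbfeCycle",
    "BoreschParameters",
    "gauss_legendre_schedule",
    "trapezoid_schedule",
    "bootstrap_mean",
    "integrate",
    "rbfe_assemble",
    "abfe_assemble",
    "boresch_analytic",
]


@dataclass(frozen=True)
class LambdaSchedule:
    """Lambda nodes with integration weights.

    ``truncated_domain`` flags a trapezoid schedule whose nodes do not
    span [0, 1] (the integral then covers only the node range and the
    weights sum to less than 1); endpoint handling is the caller's
    responsibility.
    """

    lambdas: np.ndarray
    weights: np.ndarray
    rule: str  # "gaussian_quadrature" | "trapezoid"
    truncated_domain: bool = False

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambdas, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "lambdas", lam)
        object.__setattr__(self, "weights", w)
        if lam.shape != w.shape:
            raise ValueError("lambdas and weights must have equal length")
        if lam.size and (lam.min() < 0 or lam.max() > 1):
            raise ValueError("lambda nodes must lie in [0, 1]")
        if np.any(np.diff(lam) <= 0):
            raise ValueError("lambda nodes must be strictly increasing")


@dataclass(frozen=True)
class FreeEnergyResult:
    """Integrated free energy with per-window components, kcal/mol."""

    delta_g: float
    std_err: float
    window_means: np.ndarray
    window_errs: np.ndarray
    rule: str

    def to_dict(self) -> dict:
        return {
            "delta_g": self.delta_g,
            "std_err": self.std_err,
            "window_means": list(map(float, self.window_means)),
            "window_errs": list(map(float, self.window_errs)),
            "rule": self.rule,
        }


@dataclass(frozen=True)
class RbfeCycle:
    """Relative binding free energy from its two alchemical legs."""

    dg_prot: float
    dg_wat: float

    @property
    def ddg(self) -> float:
        return self.dg_prot - self.dg_wat


@dataclass(frozen=True)
class AbfeCycle:
    """Absolute binding free energy from three alchemical legs plus the
    analytic restraint-release term.

    dg_bind = dg_int_solv - dg_vb_add - dg_int_prot - dg_vb_remove_analytic:
    annihilation of the ligand in solution, minus addition of the
    virtual-bond restraints in the complex, minus annihilation of the
    restrained ligand in the complex, minus the analytic free energy of
    removing the restraints from the noninteracting ligand.
    """

    dg_int_solv: float
    dg_vb_add: float
    dg_int_prot: float
    dg_vb_remove_analytic: float

    @property
    def dg_bind(self) -> float:
        return self.dg_int_solv - self.dg_vb_add - self.dg_int_prot - self.dg_vb_remove_analytic


@dataclass(frozen=True)
class BoreschParameters:
    """Geometry and force constants of the six-restraint virtual bond.

    One distance (r0, k_r), two angles (theta_A/B, k_thetaA/B) and
    three dihedrals (k_phiA/B/C) harmonically restrained with
    U = (k/2) (x - x0)^2. Angles in radians; k in kcal/(mol A^2) or
    kcal/(mol rad^2).
    """

    r0: float
    theta_A: float
    theta_B: float
    k_r: float
    k_thetaA: float
    k_thetaB: float
    k_phiA: float
    k_phiB: float
    k_phiC: float
    tc: ThermoConstants = ThermoConstants()

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        for th in (self.theta_A, self.theta_B):
            if not 0.0 < th < math.pi:
                raise ValueError("restraint angles must lie strictly inside (0, pi)")
        ks = (self.k_r, self.k_thetaA, self.k_thetaB, self.k_phiA, self.k_phiB, self.k_phiC)
        if any(k <= 0 for k in ks):
            raise ValueError("all force constants must be positive")


def gauss_legendre_schedule(n: int) -> LambdaSchedule:
    """n-point Gauss-Legendre quadrature mapped from [-1, 1] to [0, 1].

    Weights are positive and sum to 1; nodes are symmetric about 1/2.
    Exact for polynomial integrands up to degree 2n - 1.
    """
    if n < 1:
        raise ValueError("need at least one quadrature node")
    x, w = np.polynomial.legendre.leggauss(n)
    return LambdaSchedule(lambdas=(x + 1.0) / 2.0, weights=w / 2.0, rule="gaussian_quadrature")


def trapezoid_schedule(lambdas: np.ndarray) -> LambdaSchedule:
    """Composite trapezoid weights for an explicit sorted node list.

    Nodes need not span [0, 1]; when they do not, the schedule is
    flagged ``truncated_domain`` and integrates only the covered range.
    """
    lam = np.asarray(lambdas, dtype=float)
    if lam.size < 2:
        raise ValueError("need at least 2 nodes for the trapezoid rule")
    if np.any(np.diff(lam) <= 0):
        raise ValueError("nodes must be strictly increasing without duplicates")
    if lam.min() < 0 or lam.max() > 1:
        raise ValueError("nodes must lie in [0, 1]")
    d = np.diff(lam)
    w = np.zeros_like(lam)
    w[:-1] += d / 2.0
    w[1:] += d / 2.0
    truncated = not (math.isclose(lam[0], 0.0) and math.isclose(lam[-1], 1.0))
    return LambdaSchedule(lambdas=lam, weights=w, rule="trapezoid", truncated_domain=truncated)


def bootstrap_mean(
    values: np.ndarray, n_boot: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Mean of a decorrelated sample with a bootstrap standard error.

    The error is the standard deviation of ``n_boot`` means of
    with-replacement resamples of the full sample size.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to bootstrap")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    return float(x.mean()), float(x[idx].mean(axis=1).std())


def integrate(
    schedule: LambdaSchedule, window_means: np.ndarray, window_errs: np.ndarray | None = None
) -> FreeEnergyResult:
    """Weighted sum of window gradient means: dG = sum_i w_i <dV/dl>_i.

    Window errors propagate in quadrature assuming independent windows:
    std_err = sqrt(sum w_i^2 err_i^2).
    """
    means = np.asarray(window_means, dtype=float)
    errs = np.zeros_like(means) if window_errs is None else np.asarray(window_errs, float)
    if means.shape != schedule.weights.shape or errs.shape != means.shape:
        raise ValueError("window_means/window_errs length must match the schedule")
    dg = float(np.dot(schedule.weights, means))
    se = float(np.sqrt(np.dot(schedule.weights**2, errs**2)))
    return FreeEnergyResult(
        delta_g=dg, std_err=se, window_means=means, window_errs=errs, rule=schedule.rule
    )


def rbfe_assemble(dg_prot: float, dg_wat: float) -> RbfeCycle:
    """Relative binding free energy: ddG = dG_prot - dG_wat."""
    if not (math.isfinite(dg_prot) and math.isfinite(dg_wat)):
        raise ValueError("cycle legs must be finite")
    return RbfeCycle(dg_prot=dg_prot, dg_wat=dg_wat)


def abfe_assemble(
    dg_int_solv: float, dg_vb_add: float, dg_int_prot: float, dg_vb_remove_analytic: float
) -> AbfeCycle:
    """Absolute binding free energy from its three legs plus the
    analytic restraint-release term (see :class:`AbfeCycle`)."""
    legs = (dg_int_solv, dg_vb_add, dg_int_prot, dg_vb_remove_analytic)
    if not all(math.isfinite(v) for v in legs):
        raise ValueError("cycle legs must be finite")
    return AbfeCycle(*legs)


def boresch_analytic(p: BoreschParameters) -> float:
    """Analytic free energy of removing the six harmonic restraints
    from a noninteracting ligand into the standard-state volume.

    Stiff-spring closed form:

        dG = -RT ln[ 8 pi^2 V_std sqrt(k_r k_tA k_tB k_pA k_pB k_pC)
                     / ( r0^2 sin(tA) sin(tB) (2 pi RT)^3 ) ]

    Negative for stiff restraints (releasing them is favorable). The
    sign convention matches the subtraction of this term in the
    absolute-binding cycle.
    """
    sin_a = math.sin(p.theta_A)
    sin_b = math.sin(p.theta_B)
    if sin_a <= 0 or sin_b <= 0:
        raise ValueError("sin(theta) must be positive")
    rt = p.tc.RT
    kprod = p.k_r * p.k_thetaA * p.k_thetaB * p.k_phiA * p.k_phiB * p.k_phiC
    arg = (
        8.0
        * math.pi**2
        * p.tc.V_std
        * math.sqrt(kprod)
        / (p.r0**2 * sin_a * sin_b * (2.0 * math.pi * rt) ** 3)
    )
    return -rt * math.log(arg)
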