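"""Analytic Twiss-parameter beam optics.

A round proton beam is described, plane by plane, by the transverse phase
space ``(u, u')`` where ``u`` is the displacement from the beam axis (mm) and
``u' = du/dz`` the slope (rad).  A centered bivariate-Gaussian beam is fully
specified by the Twiss parameters ``alpha`` (position-slope correlation),
``beta`` (envelope, mm), ``gamma = (1 + alpha^2)/beta`` (1/mm) and the
geometric RMS emittance ``epsilon`` (mm rad), via the covariance matrix

    Sigma = epsilon * [[beta, -alpha], [-alpha, gamma]].

Units are mm, rad and MeV throughout; :func:`quad_focal_length` alone works
in SI (m, T) because magnet parameters are conventionally quoted that way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "TwissState",
    "CovarianceMatrix",
    "make_twiss",
    "parallel_twiss",
    "covariance_from_twiss",
    "drift_twiss",
    "magnification",
    "beam_divergence",
    "quad_focal_length",
    "proton_momentum",
    "proton_beta",
    "magnetic_rigidity",
]

PROTON_MASS_MEV = 938.27208816
#: speed of light factor converting pc [GeV] to magnetic rigidity [T m]
_RIGIDITY_GEV_TO_TM = 1.0 / 0.299792458

_REL_TOL = 1e-12


@dataclass(frozen=True)
class TwissState:
    """Twiss parameters of one transverse plane at one longitudinal position.

    Attributes
    ----------
    alpha : float
        Dimensionless position-slope correlation parameter; ``alpha > 0``
        means the beam is converging.
    beta : float
        Envelope parameter in mm; ``sigma = sqrt(emittance * beta)``.
    emittance : float
        Geometric RMS emittance in mm rad (phase-space area / pi).
    """

    alpha: float
    beta: float
    emittance: float

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if not self.emittance > 0:
            raise ValueError(f"emittance must be positive, got {self.emittance}")

    @property
    def gamma(self) -> float:
        """Divergence parameter (1/mm), fixed by ``(1 + alpha^2)/beta``."""
        return (1.0 + self.alpha**2) / self.beta

    @property
    def sigma(self) -> float:
        """RMS beam size ``sqrt(emittance * beta)`` in mm."""
        return math.sqrt(self.emittance * self.beta)

    @property
    def sigma_prime(self) -> float:
        """RMS beam divergence ``sqrt(emittance * gamma)`` in rad."""
        return math.sqrt(self.emittance * self.gamma)


@dataclass(frozen=True)
class CovarianceMatrix:
    """Second moments of the (u, u') distribution in one plane.

    ``var_u`` is <u^2> (mm^2), ``cov_uup`` is <u u'> (mm rad) and ``var_up``
    is <u'^2> (rad^2).  For a valid beam the matrix is symmetric positive
    definite with determinant equal to the squared emittance.
    """

    var_u: float
    cov_uup: float
    var_up: float

    def __post_init__(self) -> None:
        if self.var_u <= 0 or self.var_up <= 0:
            raise ValueError("diagonal covariance entries must be positive")
        if self.determinant <= 0:
            raise ValueError("covariance matrix must be positive definite")

    @property
    def determinant(self) -> float:
        return self.var_u * self.var_up - self.cov_uup**2

    @property
    def emittance(self) -> float:
        return math.sqrt(self.determinant)

    def as_array(self):
        import numpy as np

        return np.array(
            [[self.var_u, self.cov_uup], [self.cov_uup, self.var_up]]
        )


def make_twiss(sigma0: float, alpha0: float, d_T: float) -> TwissState:
    """Build the entrance Twiss state of a beam focused at depth ``d_T``.

    The waist (focal point) of a drifting beam sits at
    ``d_T = alpha0 * beta0 / (1 + alpha0^2)`` downstream of the reference
    plane, so choosing the entrance size ``sigma0`` (mm), the focusing
    strength ``alpha0`` and the target distance ``d_T`` (mm) fixes
    ``beta0 = d_T (1 + alpha0^2) / alpha0`` and the emittance
    ``epsilon = sigma0^2 / beta0``.

    Raises
    ------
    ValueError
        If ``alpha0 == 0``: a parallel beam has no downstream focal point
        (use :func:`parallel_twiss` instead).
    """
    if sigma0 <= 0:
        raise ValueError("sigma0 must be positive")
    if d_T <= 0:
        raise ValueError("d_T must be positive")
    if alpha0 < 0:
        raise ValueError("alpha0 must be >= 0 (converging convention)")
    if alpha0 == 0:
        raise ValueError("no focal point for parallel beam (alpha0 = 0)")
    beta0 = d_T * (1.0 + alpha0**2) / alpha0
    emittance = sigma0**2 / beta0
    return TwissState(alpha=alpha0, beta=beta0, emittance=emittance)


def parallel_twiss(sigma0: float, beta0: float) -> TwissState:
    """Twiss state of a parallel (waist) beam given directly by its beta.

    Used for the collimated scenario, where the source is a parallel
    Gaussian beam specified by ``sigma0`` and a machine beta (e.g. 18.8 m
    = 18800 mm), hence ``epsilon = sigma0^2 / beta0`` and ``alpha = 0``.
    """
    if sigma0 <= 0 or beta0 <= 0:
        raise ValueError("sigma0 and beta0 must be positive")
    return TwissState(alpha=0.0, beta=beta0, emittance=sigma0**2 / beta0)


def covariance_from_twiss(t: TwissState) -> CovarianceMatrix:
    """Second-moment matrix of the phase-space distribution for ``t``."""
    return CovarianceMatrix(
        var_u=t.emittance * t.beta,
        cov_uup=-t.emittance * t.alpha,
        var_up=t.emittance * t.gamma,
    )


def drift_twiss(t: TwissState, s: float) -> TwissState:
    """Propagate a Twiss state through a field-free drift of length ``s`` mm.

    In free space ``beta(s) = beta0 - 2 alpha0 s + gamma0 s^2`` and
    ``alpha(s) = alpha0 - gamma0 s``; the emittance is conserved
    (Liouville).
    """
    if s < 0:
        raise ValueError("drift length must be non-negative")
    g0 = t.gamma
    beta = t.beta - 2.0 * t.alpha * s + g0 * s**2
    alpha = t.alpha - g0 * s
    return TwissState(alpha=alpha, beta=beta, emittance=t.emittance)


def magnification(alpha0: float) -> float:
    """Transverse magnification ``sigma_T / sigma_0 = 1/sqrt(1 + alpha0^2)``.

    For any nonzero focusing the in-vacuum beam size at the waist is smaller
    than at the entrance, independent of the target distance.
    """
    return 1.0 / math.sqrt(1.0 + alpha0**2)


def beam_divergence(sigma0: float, d_T: float, alpha0: float) -> float:
    """Entrance RMS divergence (rad) of a beam focused at ``d_T``.

    ``sigma_u' = (sigma0 / d_T) * sqrt(alpha0^2 / (1 + alpha0^2))``; tends
    to ``sigma0 / d_T`` for strong focusing and to 0 for a parallel beam.
    """
    if d_T <= 0:
        raise ValueError("d_T must be positive")
    return (sigma0 / d_T) * math.sqrt(alpha0**2 / (1.0 + alpha0**2))


def proton_momentum(kinetic_energy: float) -> float:
    """Proton momentum times c, in MeV, from the kinetic energy in MeV."""
    if kinetic_energy <= 0:
        raise ValueError("kinetic energy must be positive")
    total = kinetic_energy + PROTON_MASS_MEV
    return math.sqrt(total**2 - PROTON_MASS_MEV**2)


def proton_beta(kinetic_energy: float) -> float:
    """Proton speed as a fraction of c."""
    total = kinetic_energy + PROTON_MASS_MEV
    return proton_momentum(kinetic_energy) / total


def magnetic_rigidity(kinetic_energy: float) -> float:
    """Magnetic rigidity B*rho in T m for a proton of given kinetic energy (MeV)."""
    return proton_momentum(kinetic_energy) * 1e-3 * _RIGIDITY_GEV_TO_TM


def quad_focal_length(gradient: float, length: float, kinetic_energy: float) -> float:
    """Thick-lens focal length (m) of a single quadrupole, focusing plane.

    Parameters
    ----------
    gradient : float
        Field gradient G in T/m.
    length : float
        Magnetic length L in m.
    kinetic_energy : float
        Proton kinetic energy in MeV.

    The focusing strength is ``k = G / (B rho)`` with the rigidity from
    relativistic proton kinematics; the focal length in the focusing plane
    is ``f = 1 / (sqrt(k) sin(sqrt(k) L))``, which tends to the thin-lens
    ``1/(k L)`` as the gradient vanishes.
    """
    if gradient < 0 or length <= 0:
        raise ValueError("gradient must be >= 0 and length positive")
    if gradient == 0:
        return math.inf
    k = gradient / magnetic_rigidity(kinetic_energy)
    phase = math.sqrt(k) * length
    if phase >= math.pi / 2:
        raise ValueError("over-focused in magnet (sqrt(k) L >= pi/2)")
    return 1.0 / (math.sqrt(k) * math.sin(phase))
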