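"""Closed-form relaxation models for proton NMR in neat lipid liquids.

The magnetization observables are sums of exponential components
(inversion recovery for T1, CPMG / spin echo for T2).  The field
dependence of the spin-lattice rate R1 = 1/T1 is modelled as the sum of
rotational Bloembergen-Purcell-Pound (BPP) terms and a translational
self-diffusion term built on the force-free hard-sphere spectral
density (Torrey / Hwang-Freed / Ayant).  Contributions from distinct
motions are additive.

All public functions take the Larmor frequency ``nu`` in Hz; the
angular frequency is always ``omega = 2*pi*nu``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ExponentialComponent",
    "BPPParams",
    "SDParams",
    "DispersionModelParams",
    "bpp_rate",
    "sd_rate",
    "composite_rate",
    "ir_signal",
    "cpmg_signal",
    "bpp_spectral_density",
    "sd_spectral_density",
]


class ModelDomainError(ValueError):
    """Raised when model parameters or arguments leave the physical domain."""


def _check_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ModelDomainError(f"{name}: non-finite parameter value {v!r}")


@dataclass(frozen=True)
class ExponentialComponent:
    """One relaxation component: signal amplitude and time constant.

    ``time_constant`` holds T1 or T2 in seconds depending on the
    sequence the component describes; ``amplitude`` is in arbitrary
    magnetization units.  Uncertainties are optional 1-sigma values.
    """

    amplitude: float
    time_constant: float
    amplitude_err: float | None = None
    time_constant_err: float | None = None

    def __post_init__(self) -> None:
        _check_finite("ExponentialComponent", self.amplitude, self.time_constant)
        if self.amplitude <= 0:
            raise ModelDomainError(f"amplitude must be > 0, got {self.amplitude}")
        if self.time_constant <= 0:
            raise ModelDomainError(
                f"time_constant must be > 0, got {self.time_constant}"
            )

    @property
    def rate(self) -> float:
        """Relaxation rate 1/time_constant in s^-1."""
        return 1.0 / self.time_constant


@dataclass(frozen=True)
class BPPParams:
    """Rotational BPP term: prefactor ``a_rot`` (s^-2) and correlation
    time ``tau_rot`` (s).

    The dipolar constant (gyromagnetic ratios, inter-proton distance) is
    absorbed into ``a_rot``, which is treated as a free prefactor.
    """

    a_rot: float
    tau_rot: float

    def __post_init__(self) -> None:
        _check_finite("BPPParams", self.a_rot, self.tau_rot)
        if self.a_rot < 0:
            raise ModelDomainError(f"a_rot must be >= 0, got {self.a_rot}")
        if self.tau_rot <= 0:
            raise ModelDomainError(f"tau_rot must be > 0, got {self.tau_rot}")


@dataclass(frozen=True)
class SDParams:
    """Translational self-diffusion term.

    ``d_const`` is the self-diffusion constant D in m^2/s (for olive oil
    measured independently by DOSY and normally held fixed),
    ``jump_distance`` the distance scale d of the translational spectral
    density in m, and ``a_sd`` the amplitude prefactor in s^-2.  The
    translational correlation time is ``tau_d = jump_distance**2 / d_const``.
    """

    d_const: float
    jump_distance: float = 1e-9
    a_sd: float = 0.0
    fixed_d: bool = True

    def __post_init__(self) -> None:
        _check_finite("SDParams", self.d_const, self.jump_distance, self.a_sd)
        if self.d_const <= 0:
            raise ModelDomainError(f"d_const must be > 0, got {self.d_const}")
        if self.jump_distance <= 0:
            raise ModelDomainError(
                f"jump_distance must be > 0, got {self.jump_distance}"
            )
        if self.a_sd < 0:
            raise ModelDomainError(f"a_sd must be >= 0, got {self.a_sd}")

    @property
    def tau_d(self) -> float:
        """Translational correlation time d^2/D in seconds."""
        return self.jump_distance**2 / self.d_const


@dataclass(frozen=True)
class DispersionModelParams:
    """Composite dispersion model: two BPP terms plus self-diffusion.

    Convention: ``bpp1`` is the slow-motion term, ``bpp1.tau_rot >=
    bpp2.tau_rot``.
    """

    bpp1: BPPParams
    bpp2: BPPParams
    sd: SDParams

    def __post_init__(self) -> None:
        if self.bpp1.tau_rot < self.bpp2.tau_rot:
            raise ModelDomainError(
                "bpp1 must be the slow-motion term: "
                f"tau_rot1={self.bpp1.tau_rot} < tau_rot2={self.bpp2.tau_rot}"
            )


def _as_nu(nu) -> np.ndarray:
    nu = np.asarray(nu, dtype=float)
    if np.any(nu < 0) or not np.all(np.isfinite(nu)):
        raise ModelDomainError("nu must be finite and >= 0")
    return nu


def bpp_spectral_density(tau: float, omega) -> np.ndarray:
    """Lorentzian spectral density J(omega) = tau / (1 + omega^2 tau^2)."""
    omega = np.asarray(omega, dtype=float)
    return tau / (1.0 + (omega * tau) ** 2)


def bpp_rate(p: BPPParams, nu) -> float | np.ndarray:
    """Rotational BPP relaxation rate at Larmor frequency ``nu`` (Hz).

    R1 = a_rot * [J(omega) + 4 J(2 omega)] with omega = 2 pi nu and
    J(omega) = tau_rot / (1 + omega^2 tau_rot^2).  At nu = 0 this gives
    the plateau 5 * a_rot * tau_rot.
    """
    nu = _as_nu(nu)
    omega = 2.0 * np.pi * nu
    r = p.a_rot * (
        bpp_spectral_density(p.tau_rot, omega)
        + 4.0 * bpp_spectral_density(p.tau_rot, 2.0 * omega)
    )
    return r if r.ndim else float(r)


def _ayant_reduced(z: np.ndarray) -> np.ndarray:
    # closed form of the force-free translational spectral density,
    # normalized to 1 at z = 0; z = sqrt(2 * omega * tau_d)
    num = 1.0 + (5.0 / 8.0) * z + (1.0 / 8.0) * z**2
    den = (
        1.0
        + z
        + z**2 / 2.0
        + z**3 / 6.0
        + (4.0 / 81.0) * z**4
        + z**5 / 81.0
        + z**6 / 648.0
    )
    return num / den


def sd_spectral_density(tau_d: float, omega) -> np.ndarray:
    """Force-free hard-sphere translational spectral density.

    Closed form of Ayant/Hwang-Freed, normalized so that
    J(0) = tau_d, mirroring the BPP convention J(0) = tau_rot.
    """
    omega = np.asarray(omega, dtype=float)
    z = np.sqrt(2.0 * omega * tau_d)
    return tau_d * _ayant_reduced(z)


def sd_rate(p: SDParams, nu) -> float | np.ndarray:
    """Translational self-diffusion relaxation rate at ``nu`` (Hz).

    R1 = a_sd * [J(omega) + 4 J(2 omega)] with the force-free
    translational J and correlation time tau_d = jump_distance^2 / D.
    Faster diffusion (larger D) shortens tau_d and weakens the
    low-frequency relaxation.
    """
    nu = _as_nu(nu)
    omega = 2.0 * np.pi * nu
    tau_d = p.tau_d
    r = p.a_sd * (
        sd_spectral_density(tau_d, omega) + 4.0 * sd_spectral_density(tau_d, 2.0 * omega)
    )
    return r if r.ndim else float(r)


def composite_rate(m: DispersionModelParams, nu) -> float | np.ndarray:
    """Total R1(nu): sum of the two BPP terms and the SD term."""
    return bpp_rate(m.bpp1, nu) + bpp_rate(m.bpp2, nu) + sd_rate(m.sd, nu)


def _check_components(components: Sequence[ExponentialComponent]) -> None:
    if len(components) == 0:
        raise ModelDomainError("components must be nonempty")


def ir_signal(
    components: Sequence[ExponentialComponent],
    tau,
    inversion_eff: float = 1.0,
) -> float | np.ndarray:
    """Inversion-recovery magnetization at recovery delay ``tau`` (s).

    M(tau) = sum_i a_i * (1 - 2 * inversion_eff * exp(-tau / T1_i)).
    ``inversion_eff`` is a single shared inversion factor in (0, 1].
    """
    _check_components(components)
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ModelDomainError("tau must be >= 0")
    m = sum(
        c.amplitude * (1.0 - 2.0 * inversion_eff * np.exp(-tau / c.time_constant))
        for c in components
    )
    m = np.asarray(m)
    return m if m.ndim else float(m)


def cpmg_signal(components: Sequence[ExponentialComponent], t) -> float | np.ndarray:
    """CPMG / spin-echo magnetization at cumulative echo time ``t`` (s).

    M(t) = sum_i a_i * exp(-t / T2_i); M(0) equals the total amplitude.
    """
    _check_components(components)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ModelDomainError("t must be >= 0")
    m = sum(c.amplitude * np.exp(-t / c.time_constant) for c in components)
    m = np.asarray(m)
    return m if m.ndim else float(m)
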