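"""NMRD profile assembly and composite dispersion-model fitting.

A fast-field-cycling relaxometer yields T1 at many Larmor frequencies
(10 kHz - 10 MHz); conventional spectrometers supply supplementary
points at 100 and 400 MHz.  The assembled R1(nu) profile is fitted
with two rotational BPP terms plus a translational self-diffusion term
whose diffusion constant D is held at an independently measured value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import lmfit
import numpy as np
import pandas as pd

from .decay import RelaxationFit
from .models import (
    BPPParams,
    DispersionModelParams,
    SDParams,
    bpp_rate,
    composite_rate,
    sd_rate,
)

__all__ = [
    "DispersionProfile",
    "DispersionFitResult",
    "DispersionError",
    "build_dispersion",
    "fit_dispersion",
    "decompose_contributions",
    "MIN_POINTS",
    "MIN_DECADES",
]

#: minimum profile size / frequency span for a composite fit
MIN_POINTS = 8
MIN_DECADES = 1.5

#: proton groups averaged into the high-field supplement points
SUPPLEMENT_GROUPS = ("CH", "CH2")


class DispersionError(ValueError):
    """Raised for invalid profiles or fit preconditions."""


@dataclass
class DispersionProfile:
    """R1 vs Larmor frequency for one relaxation component of one sample."""

    freqs_mhz: np.ndarray
    r1: np.ndarray
    component_label: Literal["a", "b"] = "a"
    sample_id: str = ""
    r1_err: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs_mhz = np.asarray(self.freqs_mhz, dtype=float)
        self.r1 = np.asarray(self.r1, dtype=float)
        if self.freqs_mhz.size == 0:
            raise DispersionError("empty profile")
        if self.freqs_mhz.shape != self.r1.shape:
            raise DispersionError("freqs_mhz and r1 must have the same length")
        if np.any(np.diff(self.freqs_mhz) <= 0):
            raise DispersionError("freqs_mhz must be strictly increasing")
        if np.any(self.r1 <= 0):
            raise DispersionError("r1 values must be > 0")
        if self.r1_err is not None:
            self.r1_err = np.asarray(self.r1_err, dtype=float)
            if self.r1_err.shape != self.r1.shape:
                raise DispersionError("r1_err must match r1 in length")
            if np.any(self.r1_err <= 0):
                raise DispersionError("r1_err values must be > 0")

    def __len__(self) -> int:
        return self.freqs_mhz.size

    @property
    def freqs_hz(self) -> np.ndarray:
        return self.freqs_mhz * 1e6

    @property
    def decades(self) -> float:
        """Frequency span in decades."""
        return float(np.log10(self.freqs_mhz[-1] / self.freqs_mhz[0]))


@dataclass
class DispersionFitResult:
    """Composite-model fit of an NMRD profile.

    ``uncertainties`` maps free-parameter names to 1-sigma errors (nan
    when the covariance was unavailable).  ``weakly_identified`` flags
    fits whose two rotational correlation times are within a factor of
    3, i.e. profiles too narrow to separate the BPP terms.
    """

    params: DispersionModelParams
    uncertainties: dict[str, float]
    residual_ss: float
    chi2_reduced: float
    converged: bool
    n_starts_used: int
    seed: int
    weakly_identified: bool = False
    message: str = ""


def build_dispersion(
    ffc_fits: Sequence[RelaxationFit],
    highfield_fits: Sequence[tuple[str, RelaxationFit]] = (),
    component: Literal["a", "b"] = "a",
    sample_id: str = "",
) -> DispersionProfile:
    """Assemble an R1 dispersion profile from per-frequency fits.

    Each FFC fit contributes R1 = 1/T1 of the selected component at its
    own Larmor frequency.  High-field fits are (proton-group, fit)
    pairs; at each high-field frequency one supplement point is added,
    the mean R1 over the CH and CH2 assigned peaks.  Frequencies where
    the selected component is missing are recorded in
    ``profile.meta["gaps"]`` rather than silently dropped.
    """
    if not ffc_fits and not highfield_fits:
        raise DispersionError("no fits supplied")
    freqs: list[float] = []
    rates: list[float] = []
    errs: list[float] = []
    gaps: list[str] = []

    for fit in ffc_fits:
        try:
            comp = fit.component(component)
        except KeyError:
            gaps.append(
                f"{fit.sample_id or 'sample'}@{fit.larmor_mhz} MHz: "
                f"component {component!r} missing"
            )
            continue
        freqs.append(fit.larmor_mhz)
        rates.append(1.0 / comp.time_constant)
        errs.append(
            comp.time_constant_err / comp.time_constant**2
            if comp.time_constant_err
            else math.nan
        )

    by_field: dict[float, list[float]] = {}
    for group, fit in highfield_fits:
        if group not in SUPPLEMENT_GROUPS:
            continue
        try:
            comp = fit.components[0]
        except IndexError:
            gaps.append(f"high-field fit at {fit.larmor_mhz} MHz has no components")
            continue
        by_field.setdefault(fit.larmor_mhz, []).append(1.0 / comp.time_constant)
    for mhz, r1s in by_field.items():
        freqs.append(mhz)
        rates.append(float(np.mean(r1s)))
        errs.append(math.nan)

    if not freqs:
        raise DispersionError("no usable points (see gap report)")
    freqs_a = np.asarray(freqs)
    if np.unique(freqs_a).size != freqs_a.size:
        raise DispersionError("duplicate frequencies in dispersion input")
    order = np.argsort(freqs_a)
    errs_a = np.asarray(errs)[order]
    return DispersionProfile(
        freqs_mhz=freqs_a[order],
        r1=np.asarray(rates)[order],
        component_label=component,
        sample_id=sample_id,
        r1_err=None if np.all(np.isnan(errs_a)) else np.where(
            np.isnan(errs_a), np.nanmedian(errs_a), errs_a
        ),
        meta={"gaps": gaps},
    )


def _params_from_values(
    v: Mapping[str, float], d_const: float, jump_distance: float
) -> DispersionModelParams:
    tau1 = 10.0 ** v["lg_tau1"]
    tau2 = tau1 * 10.0 ** v["lg_f"]
    return DispersionModelParams(
        bpp1=BPPParams(a_rot=10.0 ** v["lg_a1"], tau_rot=tau1),
        bpp2=BPPParams(a_rot=10.0 ** v["lg_a2"], tau_rot=tau2),
        sd=SDParams(
            d_const=d_const,
            jump_distance=jump_distance,
            a_sd=10.0 ** v["lg_asd"],
            fixed_d=True,
        ),
    )


def _dispersion_residual(params, profile: DispersionProfile, w, d_const, jump_distance):
    m = _params_from_values(params.valuesdict(), d_const, jump_distance)
    return (composite_rate(m, profile.freqs_hz) - profile.r1) * w


def fit_dispersion(
    profile: DispersionProfile,
    d_const: float,
    init: DispersionModelParams | None = None,
    n_starts: int = 8,
    jump_distance: float = 1e-9,
    fit_a_sd: bool = True,
    a_sd_fixed: float | None = None,
    seed: int = 2021,
) -> DispersionFitResult:
    """Fit the two-BPP + self-diffusion model to an R1 profile.

    Free parameters: a_rot1, tau_rot1, a_rot2, tau_rot2 and (by
    default) the SD amplitude a_sd; the diffusion constant ``d_const``
    and the distance scale ``jump_distance`` are held fixed.  The fit
    works in log10 of each positive parameter, with the second
    correlation time parameterized as tau_rot2 = tau_rot1 * f, f in
    (0, 1], which pins BPP1 as the slow-motion term and removes label
    switching.  ``n_starts`` log-uniform random restarts (seeded) guard
    against local minima; the best solution is kept and the seed is
    recorded in the result.
    """
    if len(profile) < MIN_POINTS:
        raise DispersionError(
            f"need >= {MIN_POINTS} points, got {len(profile)}"
        )
    if profile.decades < MIN_DECADES:
        raise DispersionError(
            f"profile spans {profile.decades:.2f} decades, "
            f"need >= {MIN_DECADES}"
        )
    if d_const <= 0:
        raise DispersionError("d_const must be > 0")

    w = 1.0 / profile.r1_err if profile.r1_err is not None else np.ones(len(profile))
    rng = np.random.default_rng(seed)

    plateau = float(profile.r1[0])
    f_lo, f_hi = profile.freqs_hz[0], profile.freqs_hz[-1]
    # correlation times bracketed by the observed frequency window
    lg_tau_lo = math.log10(1.0 / (2 * math.pi * f_hi)) - 1.5
    lg_tau_hi = math.log10(1.0 / (2 * math.pi * f_lo)) + 1.5

    starts: list[dict[str, float]] = []
    if init is not None:
        starts.append(
            {
                "lg_a1": math.log10(max(init.bpp1.a_rot, 1e-6)),
                "lg_tau1": math.log10(init.bpp1.tau_rot),
                "lg_a2": math.log10(max(init.bpp2.a_rot, 1e-6)),
                "lg_f": math.log10(init.bpp2.tau_rot / init.bpp1.tau_rot),
                "lg_asd": math.log10(max(init.sd.a_sd, 1e-6)),
            }
        )
    while len(starts) < max(n_starts, 1):
        lg_tau1 = rng.uniform(lg_tau_lo + 1.0, lg_tau_hi)
        lg_f = rng.uniform(-3.0, 0.0)
        # amplitude scale from the low-frequency plateau: R1(0) ~ 5 A tau
        lg_a1 = math.log10(plateau / 5.0) - lg_tau1 + rng.uniform(-1, 1)
        lg_a2 = lg_a1 - lg_f + rng.uniform(-1, 1)
        tau_d = jump_distance**2 / d_const
        lg_asd = math.log10(plateau / (5.0 * tau_d)) + rng.uniform(-2, 0)
        starts.append(
            {
                "lg_a1": lg_a1,
                "lg_tau1": lg_tau1,
                "lg_a2": lg_a2,
                "lg_f": lg_f,
                "lg_asd": lg_asd,
            }
        )

    if a_sd_fixed is not None:
        fit_a_sd = False

    best = None
    n_used = 0
    for start in starts:
        p = lmfit.Parameters()
        p.add("lg_a1", value=start["lg_a1"], min=-8, max=16)
        p.add("lg_tau1", value=start["lg_tau1"], min=lg_tau_lo, max=lg_tau_hi)
        p.add("lg_a2", value=start["lg_a2"], min=-8, max=16)
        p.add("lg_f", value=start["lg_f"], min=-6, max=0)
        lg_asd0 = (
            math.log10(max(a_sd_fixed, 1e-12))
            if a_sd_fixed is not None
            else start["lg_asd"]
        )
        p.add("lg_asd", value=lg_asd0, min=-12, max=16, vary=fit_a_sd)
        n_used += 1
        try:
            res = lmfit.minimize(
                _dispersion_residual,
                p,
                args=(profile, w, d_const, jump_distance),
                method="leastsq",
                nan_policy="raise",
            )
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res

    if best is None or not np.isfinite(best.chisqr):
        return DispersionFitResult(
            params=_params_from_values(
                starts[0], d_const, jump_distance
            ),
            uncertainties={},
            residual_ss=math.nan,
            chi2_reduced=math.nan,
            converged=False,
            n_starts_used=n_used,
            seed=seed,
            message="no start converged",
        )

    v = best.params
    m = _params_from_values(v.valuesdict(), d_const, jump_distance)

    def _err(lg_name: str, value: float) -> float:
        s = v[lg_name].stderr
        # delta method for y = 10**x: sigma_y = y ln(10) sigma_x
        return value * math.log(10.0) * s if s is not None else math.nan

    tau_ratio = m.bpp1.tau_rot / m.bpp2.tau_rot
    unc = {
        "a_rot1": _err("lg_a1", m.bpp1.a_rot),
        "tau_rot1": _err("lg_tau1", m.bpp1.tau_rot),
        "a_rot2": _err("lg_a2", m.bpp2.a_rot),
        "tau_rot2": math.nan,
        "a_sd": _err("lg_asd", m.sd.a_sd) if fit_a_sd else 0.0,
    }
    if v["lg_tau1"].stderr is not None and v["lg_f"].stderr is not None:
        s = math.hypot(v["lg_tau1"].stderr, v["lg_f"].stderr)
        unc["tau_rot2"] = m.bpp2.tau_rot * math.log(10.0) * s

    ndata = len(profile)
    nvary = best.nvarys
    return DispersionFitResult(
        params=m,
        uncertainties=unc,
        residual_ss=float(
            np.sum((composite_rate(m, profile.freqs_hz) - profile.r1) ** 2)
        ),
        chi2_reduced=float(best.chisqr / max(ndata - nvary, 1)),
        converged=True,
        n_starts_used=n_used,
        seed=seed,
        weakly_identified=bool(tau_ratio < 3.0),
        message=best.message or "",
    )


def decompose_contributions(
    params: DispersionModelParams, freqs_hz: Sequence[float]
) -> pd.DataFrame:
    """Tabulate per-mechanism R1 at each frequency.

    Columns: freq_hz, bpp1, bpp2, sd and their row-wise sum ``total``
    (identical to ``composite_rate`` by construction).
    """
    freqs_hz = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    bpp1 = np.atleast_1d(bpp_rate(params.bpp1, freqs_hz))
    bpp2 = np.atleast_1d(bpp_rate(params.bpp2, freqs_hz))
    sd = np.atleast_1d(sd_rate(params.sd, freqs_hz))
    return pd.DataFrame(
        {
            "freq_hz": freqs_hz,
            "bpp1": bpp1,
            "bpp2": bpp2,
            "sd": sd,
            "total": bpp1 + bpp2 + sd,
        }
    )
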