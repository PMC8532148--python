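"""Synthetic data generation for the full relaxation pipeline.

Generates every input the analysis consumes — inversion-recovery and
CPMG decay curves, NMRD dispersion profiles, low/high-resolution
spectra and two-region sample cohorts — with explicit seeds and with
the planted ground truth recorded in each object's metadata.  A
fixture library collects the reference-sample (at_28) parameter sets
used throughout the test and acceptance suites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .cohort import SampleRecord
from .decay import DecayCurve, FitError, SequenceKind
from .dispersion import MIN_DECADES, DispersionProfile
from .models import (
    BPPParams,
    DispersionModelParams,
    ExponentialComponent,
    SDParams,
    composite_rate,
    cpmg_signal,
    ir_signal,
)

__all__ = [
    "NoiseSpec",
    "FIXTURES",
    "SCHEDULES",
    "get_fixture",
    "log_schedule",
    "cpmg_schedule",
    "simulate_decay",
    "simulate_dispersion",
    "simulate_cohort",
    "simulate_spectrum",
    "CohortTemplate",
    "DEFAULT_COHORT_TEMPLATE",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian noise description with a mandatory seed.

    ``additive_gaussian``: one sigma for all points, ``level`` times the
    maximum absolute signal.  ``relative_gaussian``: per-point sigma,
    ``level`` times each absolute value (floored at 1e-3 of the maximum
    so weights stay finite near zero crossings).
    """

    kind: Literal["additive_gaussian", "relative_gaussian"]
    level: float
    seed: int

    def __post_init__(self) -> None:
        if self.kind not in ("additive_gaussian", "relative_gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.level < 0:
            raise ValueError("noise level must be >= 0")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an explicit integer")

    def sigmas(self, signal: np.ndarray) -> np.ndarray:
        scale = float(np.max(np.abs(signal)))
        if self.kind == "additive_gaussian":
            return np.full_like(signal, self.level * scale)
        return np.maximum(self.level * np.abs(signal), self.level * scale * 1e-3)


# ---------------------------------------------------------------------------
# delay schedules (instrument acquisition grids)

def log_schedule(lo_s: float, hi_s: float, n: int) -> np.ndarray:
    """Logarithmically spaced recovery/echo delays from lo to hi seconds."""
    if not (0 < lo_s < hi_s) or n < 2:
        raise FitError("invalid schedule bounds")
    return np.geomspace(lo_s, hi_s, n)


def cpmg_schedule(tau_echo_s: float = 200e-6, n_echoes: int = 1000) -> np.ndarray:
    """Cumulative CPMG echo times t_n = 2 n tau_echo."""
    if tau_echo_s <= 0 or n_echoes < 1:
        raise FitError("invalid CPMG schedule")
    return 2.0 * tau_echo_s * np.arange(1, n_echoes + 1)


#: acquisition grids of the instruments emulated by the generator
SCHEDULES: dict[str, np.ndarray] = {
    # 2 MHz permanent magnet: IR 1 ms - 1 s in 20 steps; CPMG 200 us echo
    # spacing, 1000 echoes
    "ir_2mhz": log_schedule(1e-3, 1.0, 20),
    "cpmg_2mhz": cpmg_schedule(200e-6, 1000),
    # 100 MHz magnet: IR 0.2 ms - 3 s in 21 steps; spin echo 0.02 ms - 2 s
    # in 12 steps
    "ir_100mhz": log_schedule(0.2e-3, 3.0, 21),
    "se_100mhz": log_schedule(0.02e-3, 2.0, 12),
    # 400 MHz spectrometer: IR 1 ms - 10 s in 16 steps
    "ir_400mhz": log_schedule(1e-3, 10.0, 16),
}


# ---------------------------------------------------------------------------
# fixture library: reference-sample (at_28) parameter sets

#: Published NMRD fits report only the rotational terms and the (fixed)
#: diffusion constant; the translational amplitude below is a synthetic
#: choice giving the self-diffusion mechanism a low-frequency
#: contribution of ~2 s^-1 (5 * a_sd * tau_d with tau_d = d^2/D =
#: 1.3e-7 s), comparable to the rotational plateaus.
A_SD_SYNTHETIC = 3.0e6

AT28_DISPERSION = DispersionModelParams(
    bpp1=BPPParams(a_rot=1.08e8, tau_rot=1.5e-8),
    bpp2=BPPParams(a_rot=3.15e9, tau_rot=2.15e-10),
    sd=SDParams(d_const=7.7e-12, jump_distance=1e-9, a_sd=A_SD_SYNTHETIC, fixed_d=True),
)

FIXTURES: dict[str, dict] = {
    "at28_dispersion": {
        "value": AT28_DISPERSION,
        "units": "a_rot: s^-2, tau_rot: s, D: m^2/s",
        "note": (
            "Composite NMRD fit for the reference EVOO sample at_28: "
            "A_Rot1=1.08e8 s^-2, tau_1=1.5e-8 s; A_Rot2=3.15e9 s^-2, "
            "tau_2=2.15e-10 s; D fixed at 7.7e-12 m^2/s (DOSY). The "
            "translational amplitude and 1 nm distance scale are "
            "synthetic choices (not measured values)."
        ),
    },
    "at28_t2_2mhz": {
        "value": (
            ExponentialComponent(amplitude=1.0, time_constant=0.043),
            ExponentialComponent(amplitude=1.0, time_constant=0.147),
        ),
        "units": "s",
        "note": (
            "Two-component T2 of at_28 at 2 MHz: 43 and 147 ms, "
            "comparable amplitudes (planted equal)."
        ),
    },
    "at28_t2_100mhz": {
        "value": {
            "5.5-5.1": 0.040,
            "4.3-4.1": 0.022,
            "2.7-1.6": 0.033,
            "1.2": 0.056,
            "<1.0": 0.047,
        },
        "units": "s",
        "note": "Per-region mono-exponential T2 of at_28 at 100 MHz.",
    },
    "at28_t1_100mhz": {
        "value": (0.295, 0.122, 0.191, 0.235, 0.352),
        "units": "s",
        "note": (
            "T1 per spectral region of at_28 at 100 MHz; five values "
            "against ten 400 MHz regions because several peaks overlap "
            "at this field — stored positionally (leftmost = olefinic "
            "5.5-5.2 ppm region)."
        ),
    },
    "at28_t1_400mhz": {
        "value": (
            0.873, 0.493, 0.413, 0.445, 0.437,
            0.504, 0.462, 0.466, 0.656, 0.740,
        ),
        "units": "s",
        "note": (
            "T1 per proton group of at_28 at 400 MHz, ordered by "
            "descending chemical shift (5.5-5.2, 5.1, 4.3-4.0, 2.7, "
            "2.3, 2.0, 1.6, 1.2, 0.9, 0.8 ppm)."
        ),
    },
}


def get_fixture(name: str):
    """Return the planted value of a named fixture."""
    try:
        return FIXTURES[name]["value"]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None


# ---------------------------------------------------------------------------
# generators

def simulate_decay(
    components: Sequence[ExponentialComponent],
    sequence_kind: SequenceKind,
    delay_schedule: np.ndarray,
    noise: NoiseSpec,
    larmor_mhz: float = 2.0,
    sample_id: str = "synthetic",
    inversion_eff: float = 1.0,
) -> DecayCurve:
    """Simulate a magnetization decay on a given acquisition schedule.

    Deterministic for a fixed seed; noiseless when ``noise.level`` is
    zero.  The planted components and settings are recorded in
    ``curve.meta["truth"]``.
    """
    delays = np.asarray(delay_schedule, dtype=float)
    if delays.size == 0 or np.any(np.diff(delays) <= 0):
        raise FitError("delay schedule must be nonempty and strictly increasing")
    if sequence_kind == "inversion_recovery":
        clean = np.asarray(ir_signal(components, delays, inversion_eff))
    elif sequence_kind in ("cpmg", "spin_echo"):
        clean = np.asarray(cpmg_signal(components, delays))
    else:
        raise FitError(f"unknown sequence kind {sequence_kind!r}")

    rng = np.random.default_rng(noise.seed)
    if noise.level > 0:
        sig = noise.sigmas(clean)
        signal = clean + rng.normal(0.0, 1.0, clean.shape) * sig
        sigma = sig
    else:
        signal, sigma = clean, None

    return DecayCurve(
        delays=delays,
        magnetization=signal,
        sigma=sigma,
        sequence_kind=sequence_kind,
        larmor_mhz=larmor_mhz,
        sample_id=sample_id,
        meta={
            "truth": {
                "components": tuple(components),
                "inversion_eff": inversion_eff,
                "noise": noise,
            }
        },
    )


def simulate_dispersion(
    params: DispersionModelParams,
    freqs_mhz: Sequence[float],
    noise: NoiseSpec,
    component_label: Literal["a", "b"] = "a",
    sample_id: str = "synthetic",
) -> DispersionProfile:
    """Simulate an R1(nu) profile from the composite dispersion model.

    The noiseless profile equals ``composite_rate`` pointwise.  Profiles
    narrower than the fitting precondition get ``meta["narrow_band"]``.
    """
    freqs_mhz = np.asarray(freqs_mhz, dtype=float)
    if freqs_mhz.size == 0:
        raise ValueError("freqs_mhz must be nonempty")
    clean = np.asarray(composite_rate(params, freqs_mhz * 1e6))
    rng = np.random.default_rng(noise.seed)
    if noise.level > 0:
        sig = noise.sigmas(clean)
        r1 = clean + rng.normal(0.0, 1.0, clean.shape) * sig
        r1 = np.maximum(r1, 1e-12)
        r1_err = sig
    else:
        r1, r1_err = clean, None
    decades = float(np.log10(freqs_mhz.max() / freqs_mhz.min()))
    return DispersionProfile(
        freqs_mhz=freqs_mhz,
        r1=r1,
        r1_err=r1_err,
        component_label=component_label,
        sample_id=sample_id,
        meta={
            "truth": {"params": params, "noise": noise},
            "narrow_band": decades < MIN_DECADES,
        },
    )


# ---------------------------------------------------------------------------
# cohort generation

@dataclass(frozen=True)
class CohortTemplate:
    """Group-wise distributions (mean, SD in seconds) for the planted
    relaxation quantities of a simulated two-region cohort.

    ``groups`` maps group name to a dict with keys T1a_2MHz, T1b_2MHz,
    T2a_2MHz, T2b_2MHz, T1_100MHz, T2_100MHz.  ``t1_amp_ratio`` is the
    short:long amplitude ratio of the planted T1 components,
    ``t2_amp_ratio`` the same for T2.
    """

    groups: tuple[tuple[str, dict[str, tuple[float, float]]], ...]
    t1_amp_ratio: float = 2.0
    t2_amp_ratio: float = 1.0

    def validate(self) -> None:
        if len(self.groups) < 1:
            raise ValueError("template needs at least one group")
        required = {
            "T1a_2MHz", "T1b_2MHz", "T2a_2MHz", "T2b_2MHz",
            "T1_100MHz", "T2_100MHz",
        }
        for name, dists in self.groups:
            missing = required - set(dists)
            if missing:
                raise ValueError(f"group {name!r} missing quantities {missing}")
            for q, (mu, sd) in dists.items():
                if mu <= 0 or sd < 0:
                    raise ValueError(f"group {name!r}, {q}: invalid (mu, sd)")


def _default_group(shift: float) -> dict[str, tuple[float, float]]:
    # means anchored to the reference-sample values; the small shift
    # keeps the two regions distinguishable in the planted truth while
    # their ranges overlap almost completely
    return {
        "T1a_2MHz": (0.090 * shift, 0.008),
        "T1b_2MHz": (0.280 * shift, 0.028),
        "T2a_2MHz": (0.043 * shift, 0.004),
        "T2b_2MHz": (0.147 * shift, 0.012),
        "T1_100MHz": (0.235 * shift, 0.012),
        "T2_100MHz": (0.056 * shift, 0.004),
    }


#: two regional groups with near-identical, heavily overlapping
#: distributions — the structure the regional screening reports
DEFAULT_COHORT_TEMPLATE = CohortTemplate(
    groups=(
        ("tuscany", _default_group(1.00)),
        ("apulia", _default_group(1.02)),
    )
)

FIXTURES["cohort_template"] = {
    "value": DEFAULT_COHORT_TEMPLATE,
    "units": "quantity distributions: (mean, SD) in s",
    "note": (
        "Two-region cohort template (32 Tuscany / 35 Apulia scale). "
        "Group distributions are synthetic: means anchored to the "
        "reference-sample values, near-identical between regions so "
        "that the planted ranges overlap heavily. No per-sample "
        "measured values exist to plant."
    ),
}


def simulate_cohort(
    template: CohortTemplate = DEFAULT_COHORT_TEMPLATE,
    n_samples_per_group: dict[str, int] | int = 1,
    noise_level: float = 0.02,
    seed: int = 0,
) -> list[SampleRecord]:
    """Simulate a cohort of oil samples with curves at 2 and 100 MHz.

    Each sample gets four decay curves (IR and CPMG at 2 MHz, both
    bi-exponential; IR and spin echo at 100 MHz, mono-exponential) with
    per-sample time constants drawn from the template's group
    distributions.  Planted truths are stored on each record; the whole
    cohort is bit-reproducible for a fixed seed.
    """
    template.validate()
    rng = np.random.default_rng(seed)
    records: list[SampleRecord] = []
    prefix = {"tuscany": "at", "apulia": "ap"}
    for group, dists in template.groups:
        if isinstance(n_samples_per_group, dict):
            n = n_samples_per_group.get(group, 0)
        else:
            n = int(n_samples_per_group)
        if n < 1:
            raise ValueError(f"need >= 1 sample for group {group!r}")
        tag = prefix.get(group, group[:2])
        for i in range(1, n + 1):
            truth = {
                q: max(rng.normal(mu, sd), mu * 0.2)
                for q, (mu, sd) in dists.items()
            }
            r_t1, r_t2 = template.t1_amp_ratio, template.t2_amp_ratio
            comps = {
                "ir_2mhz": (
                    ExponentialComponent(r_t1, truth["T1a_2MHz"]),
                    ExponentialComponent(1.0, truth["T1b_2MHz"]),
                ),
                "cpmg_2mhz": (
                    ExponentialComponent(r_t2, truth["T2a_2MHz"]),
                    ExponentialComponent(1.0, truth["T2b_2MHz"]),
                ),
                "ir_100mhz": (ExponentialComponent(1.0, truth["T1_100MHz"]),),
                "se_100mhz": (ExponentialComponent(1.0, truth["T2_100MHz"]),),
            }
            seq = {
                "ir_2mhz": ("inversion_recovery", 2.0),
                "cpmg_2mhz": ("cpmg", 2.0),
                "ir_100mhz": ("inversion_recovery", 100.0),
                "se_100mhz": ("spin_echo", 100.0),
            }
            sample_id = f"{tag}_{i}"
            curves = {}
            for key, components in comps.items():
                kind, mhz = seq[key]
                curves[key] = simulate_decay(
                    components,
                    kind,
                    SCHEDULES[key],
                    NoiseSpec(
                        "relative_gaussian",
                        noise_level,
                        int(rng.integers(0, 2**31 - 1)),
                    ),
                    larmor_mhz=mhz,
                    sample_id=sample_id,
                )
            records.append(
                SampleRecord(
                    sample_id=sample_id, group=group, curves=curves, truth=truth
                )
            )
    return records


# ---------------------------------------------------------------------------
# spectra

def simulate_spectrum(
    regions: Sequence[tuple[float, float]],
    ppm_grid: np.ndarray,
    linewidth_ppm: float,
    noise: NoiseSpec,
) -> pd.DataFrame:
    """Simulate a 1D spectrum as a sum of Lorentzian lines.

    ``regions`` is a sequence of (center_ppm, integrated_intensity)
    pairs; each line is a Lorentzian of half-width-at-half-maximum
    ``linewidth_ppm / 2`` whose integral equals the planted intensity.
    At a broad low-field linewidth the lines merge into a single
    unresolved line, as seen on permanent-magnet instruments.
    """
    ppm = np.asarray(ppm_grid, dtype=float)
    if ppm.size < 2 or np.any(np.diff(ppm) <= 0):
        raise ValueError("ppm_grid must be increasing with >= 2 points")
    if linewidth_ppm <= 0:
        raise ValueError("linewidth_ppm must be > 0")
    hwhm = linewidth_ppm / 2.0
    intensity = np.zeros_like(ppm)
    for center, area in regions:
        intensity += area / math.pi * hwhm / ((ppm - center) ** 2 + hwhm**2)
    rng = np.random.default_rng(noise.seed)
    if noise.level > 0:
        intensity = intensity + rng.normal(
            0.0, noise.level * intensity.max(), ppm.shape
        )
    return pd.DataFrame({"ppm": ppm, "intensity": intensity})
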