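"""Mono/bi-exponential decomposition of magnetization decay curves.

Low-field instruments see the whole proton spectrum as a single line,
so T1 (inversion recovery) and T2 (CPMG) curves of a neat oil are
fitted with one or two exponential components with free amplitudes.
Initialisation comes from a log-spaced grid of candidate time constants
with amplitudes solved linearly, followed by nonlinear refinement
(multi-start for two-component fits); model order is chosen by
corrected AIC.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import lmfit
import numpy as np

from .models import ExponentialComponent, ModelDomainError

__all__ = [
    "SequenceKind",
    "DecayCurve",
    "RelaxationFit",
    "FitError",
    "fit_decay",
    "select_model",
    "amplitude_ratio",
]

SequenceKind = Literal["inversion_recovery", "cpmg", "spin_echo"]
_SEQUENCE_KINDS = ("inversion_recovery", "cpmg", "spin_echo")

#: minimum number of points per model order
MIN_POINTS = {1: 6, 2: 10}


class FitError(ValueError):
    """Raised for curves that cannot be fitted at all (bad input)."""


@dataclass
class DecayCurve:
    """A measured or simulated magnetization decay.

    ``delays`` are recovery delays (inversion recovery) or cumulative
    echo times (CPMG: t_n = 2 n tau_echo) in seconds, strictly
    increasing.  ``sigma`` is an optional per-point noise estimate used
    for 1/sigma^2 weighting.
    """

    delays: np.ndarray
    magnetization: np.ndarray
    sequence_kind: SequenceKind
    larmor_mhz: float
    sample_id: str = ""
    sigma: np.ndarray | None = None
    temperature_c: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.magnetization = np.asarray(self.magnetization, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.delays.shape:
                raise FitError("sigma must match delays in length")
            if np.any(self.sigma <= 0):
                raise FitError("sigma values must be > 0")
        if self.delays.ndim != 1 or self.magnetization.ndim != 1:
            raise FitError("delays and magnetization must be 1-D")
        if self.delays.shape != self.magnetization.shape:
            raise FitError(
                f"length mismatch: {self.delays.size} delays vs "
                f"{self.magnetization.size} magnetization values"
            )
        if np.any(np.diff(self.delays) <= 0):
            raise FitError("delays must be strictly increasing")
        if np.any(self.delays < 0):
            raise FitError("delays must be >= 0")
        if self.sequence_kind not in _SEQUENCE_KINDS:
            raise FitError(f"unknown sequence kind {self.sequence_kind!r}")
        if not self.larmor_mhz > 0:
            raise FitError("larmor_mhz must be > 0")

    def __len__(self) -> int:
        return self.delays.size


@dataclass
class RelaxationFit:
    """Result of a mono or bi-exponential fit.

    ``components`` are sorted by ascending time constant and labelled
    "a" (shorter) then "b" (longer).  ``aicc`` is the corrected Akaike
    criterion under a Gaussian likelihood.  A failed fit has
    ``converged=False``, empty ``components`` and a diagnostic
    ``message``.
    """

    components: tuple[ExponentialComponent, ...]
    model_kind: Literal["mono", "bi"]
    sequence_kind: SequenceKind
    larmor_mhz: float
    sample_id: str = ""
    inversion_eff: float = 1.0
    residual_ss: float = math.nan
    aicc: float = math.nan
    converged: bool = False
    message: str = ""

    @property
    def component_labels(self) -> tuple[str, ...]:
        return ("a", "b")[: len(self.components)]

    def component(self, label: str) -> ExponentialComponent:
        """Return the component with label "a" (short) or "b" (long)."""
        try:
            return self.components[self.component_labels.index(label)]
        except ValueError:
            raise KeyError(f"no component {label!r} in a {self.model_kind} fit")


def _failure(curve: DecayCurve, n_components: int, message: str) -> RelaxationFit:
    return RelaxationFit(
        components=(),
        model_kind="mono" if n_components == 1 else "bi",
        sequence_kind=curve.sequence_kind,
        larmor_mhz=curve.larmor_mhz,
        sample_id=curve.sample_id,
        converged=False,
        message=message,
    )


def _basis(curve: DecayCurve, t_const: float, eff: float) -> np.ndarray:
    if curve.sequence_kind == "inversion_recovery":
        return 1.0 - 2.0 * eff * np.exp(-curve.delays / t_const)
    return np.exp(-curve.delays / t_const)


def _grid_candidates(curve: DecayCurve, n_grid: int = 40) -> np.ndarray:
    lo = max(curve.delays[1], 1e-12) if curve.delays[0] == 0 else curve.delays[0]
    lo = min(lo, curve.delays[1])
    hi = 10.0 * curve.delays[-1]
    return np.geomspace(lo, hi, n_grid)

def _linear_amplitudes(
    curve: DecayCurve, t_consts: Sequence[float], eff: float, w: np.ndarray
) -> tuple[np.ndarray, float]:
    """Solve amplitudes by weighted linear least squares at fixed T."""
    basis = np.column_stack([_basis(curve, t, eff) for t in t_consts])
    a, *_ = np.linalg.lstsq(basis * w[:, None], curve.magnetization * w, rcond=None)
    resid = curve.magnetization - basis @ a
    return a, float(np.sum((resid * w) ** 2))


def _aicc(rss: float, n: int, k: int, scale: float = 1.0) -> float:
    # floor the residual at numerical precision of the signal so that
    # noiseless curves do not produce log-of-zero artifacts that favour
    # the more complex model
    rss = max(rss, n * (1e-10 * scale) ** 2, np.finfo(float).tiny)
    aic = n * math.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return aic


def _make_params(
    t_init: Sequence[float],
    a_init: Sequence[float],
    t_lo: float,
    t_hi: float,
    fit_inversion_eff: bool,
) -> lmfit.Parameters:
    params = lmfit.Parameters()
    params.add("t_a", value=float(t_init[0]), min=t_lo * 1e-3, max=t_hi * 1e3)
    params.add("a_a", value=float(max(a_init[0], 1e-12)), min=0.0)
    if len(t_init) == 2:
        # T_b = ratio * T_a with ratio >= 1 keeps components ordered
        params.add("ratio", value=float(t_init[1] / t_init[0]), min=1.0, max=1e6)
        params.add("t_b", expr="t_a * ratio")
        params.add("a_b", value=float(max(a_init[1], 1e-12)), min=0.0)
    params.add(
        "eff",
        value=1.0,
        vary=fit_inversion_eff,
        min=0.7,
        max=1.0,
    )
    return params


def _residual(params: lmfit.Parameters, curve: DecayCurve, w: np.ndarray, n_comp: int):
    v = params.valuesdict()
    model = v["a_a"] * _basis(curve, v["t_a"], v["eff"])
    if n_comp == 2:
        model = model + v["a_b"] * _basis(curve, v["t_b"], v["eff"])
    return (curve.magnetization - model) * w


def fit_decay(
    curve: DecayCurve,
    n_components: int,
    fit_inversion_eff: bool = False,
) -> RelaxationFit:
    """Weighted least-squares fit of 1 or 2 exponential components.

    Weights are 1/sigma when the curve carries per-point noise
    estimates, else uniform.  Amplitudes and time constants are bounded
    positive; a two-component fit constrains T_b >= T_a.  Returns a
    failure result (``converged=False`` plus a message) on degenerate
    input or non-convergence rather than raising.
    """
    if n_components not in (1, 2):
        raise FitError(f"n_components must be 1 or 2, got {n_components}")
    n = len(curve)
    if n < MIN_POINTS[n_components]:
        return _failure(
            curve,
            n_components,
            f"need >= {MIN_POINTS[n_components]} points for a "
            f"{n_components}-component fit, got {n}",
        )
    if np.ptp(curve.magnetization) == 0:
        return _failure(curve, n_components, "constant signal: nothing to fit")
    if fit_inversion_eff and curve.sequence_kind != "inversion_recovery":
        raise FitError("inversion efficiency applies to inversion recovery only")

    w = 1.0 / curve.sigma if curve.sigma is not None else np.ones(n)
    grid = _grid_candidates(curve)

    # rank starting points on the grid (amplitudes solved linearly)
    if n_components == 1:
        scored = []
        for t in grid:
            a, rss = _linear_amplitudes(curve, [t], 1.0, w)
            if a[0] > 0:
                scored.append((rss, [t], a))
        starts = [min(scored, key=lambda s: s[0])] if scored else []
        if not starts:
            # fall back to a mid-grid start with unit amplitude
            t0 = grid[len(grid) // 2]
            starts = [(math.inf, [t0], np.array([abs(curve.magnetization).max()]))]
    else:
        scored = []
        for t1, t2 in itertools.combinations(grid[::2], 2):
            a, rss = _linear_amplitudes(curve, [t1, t2], 1.0, w)
            if np.all(a > 0):
                scored.append((rss, [t1, t2], a))
        scored.sort(key=lambda s: s[0])
        starts = scored[:5]
        if not starts:
            t_mid = math.sqrt(grid[0] * grid[-1])
            a0 = abs(curve.magnetization).max() / 2
            starts = [(math.inf, [t_mid, 4 * t_mid], np.array([a0, a0]))]

    best = None
    for _, t_init, a_init in starts:
        params = _make_params(t_init, a_init, grid[0], grid[-1], fit_inversion_eff)
        try:
            res = lmfit.minimize(
                _residual,
                params,
                args=(curve, w, n_components),
                method="leastsq",
                nan_policy="raise",
            )
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res

    if best is None or not np.isfinite(best.chisqr):
        return _failure(curve, n_components, "nonlinear fit did not converge")

    v = best.params
    k = best.nvarys
    rss = float(np.sum(_residual(best.params, curve, np.ones(n), n_components) ** 2))

    def _comp(t_key: str, a_key: str) -> ExponentialComponent:
        t_err = v[t_key].stderr
        a_err = v[a_key].stderr
        return ExponentialComponent(
            amplitude=max(float(v[a_key].value), np.finfo(float).tiny),
            time_constant=float(v[t_key].value),
            amplitude_err=float(a_err) if a_err is not None else None,
            time_constant_err=float(t_err) if t_err is not None else None,
        )

    try:
        comps = [_comp("t_a", "a_a")]
        if n_components == 2:
            comps.append(_comp("t_b", "a_b"))
    except ModelDomainError as exc:
        return _failure(curve, n_components, f"unphysical fit result: {exc}")
    comps.sort(key=lambda c: c.time_constant)

    return RelaxationFit(
        components=tuple(comps),
        model_kind="mono" if n_components == 1 else "bi",
        sequence_kind=curve.sequence_kind,
        larmor_mhz=curve.larmor_mhz,
        sample_id=curve.sample_id,
        inversion_eff=float(v["eff"].value),
        residual_ss=rss,
        aicc=_aicc(float(best.chisqr), n, k, float(np.max(np.abs(curve.magnetization * w)))),
        converged=True,
        message=best.message or "",
    )


def select_model(curve: DecayCurve, fit_inversion_eff: bool = False) -> RelaxationFit:
    """Fit mono and bi models and keep the lower corrected AIC.

    A bi fit must beat the mono fit by more than 2 AICc units to be
    selected, so near-degenerate two-component solutions fall back to
    the mono description.  Deterministic given the curve.
    """
    mono = fit_decay(curve, 1, fit_inversion_eff)
    bi = fit_decay(curve, 2, fit_inversion_eff)
    if not mono.converged and not bi.converged:
        return mono
    if not bi.converged:
        return mono
    if not mono.converged:
        return bi
    if bi.aicc < mono.aicc - 2.0:
        return bi
    return mono


def amplitude_ratio(fit: RelaxationFit) -> float:
    """Short-to-long amplitude ratio a_short / a_long of a bi fit."""
    if len(fit.components) != 2:
        raise FitError("amplitude_ratio requires a two-component fit")
    return fit.components[0].amplitude / fit.components[1].amplitude
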