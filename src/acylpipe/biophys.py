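"""Two-state thermal-unfolding model: curve container, fitting, Tm deltas.

The observable is modeled as a population-weighted average of two linear
baselines, with the native/unfolded equilibrium constant following a
van't Hoff temperature dependence:

    K(T) = exp[-(dH/R) * (1/T - 1/Tm)]   (T in kelvin)
    signal(T) = [(yN + mN*t) + (yU + mU*t) * K(T)] / (1 + K(T))

where t is the temperature in Celsius for the baseline terms. The raw
signal is fitted directly; fraction-unfolded is an output transform only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import AcylPipeError, InvalidConfigError

__all__ = ["R_KJ", "MeltingCurve", "TwoStateFit", "two_state_signal",
           "fit_two_state", "fraction_unfolded", "delta_tm"]

#: gas constant, kJ/(mol*K)
R_KJ = 8.314e-3
_KELVIN = 273.15


@dataclass
class MeltingCurve:
    """(temperature, signal) pairs from a constant-rate thermal ramp."""

    temp_c: np.ndarray
    signal: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.temp_c = np.asarray(self.temp_c, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temp_c.shape != self.signal.shape:
            raise InvalidConfigError("temp_c and signal lengths differ")
        if self.temp_c.size < 15:
            raise InvalidConfigError("melting curve needs >=15 points")
        if not np.all(np.diff(self.temp_c) > 0):
            raise InvalidConfigError("temperatures must be strictly increasing")


@dataclass
class TwoStateFit:
    """Fitted two-state parameters; ``converged`` gates downstream use."""

    tm_c: float
    dh_vh: float  # van't Hoff enthalpy, kJ/mol
    yN: float
    mN: float
    yU: float
    mU: float
    rss: float
    converged: bool
    message: str = ""


def two_state_signal(
    temp_c: np.ndarray,
    tm_c: float,
    dh_vh: float,
    yN: float,
    mN: float,
    yU: float,
    mU: float,
) -> np.ndarray:
    """Evaluate the two-state model at the given temperatures (Celsius)."""
    t = np.asarray(temp_c, dtype=float)
    T = t + _KELVIN
    Tm = tm_c + _KELVIN
    K = np.exp(-(dh_vh / R_KJ) * (1.0 / T - 1.0 / Tm))
    return ((yN + mN * t) + (yU + mU * t) * K) / (1.0 + K)


def _initial_guess(curve: MeltingCurve) -> np.ndarray:
    t, y = curve.temp_c, curve.signal
    n_edge = max(3, t.size // 6)
    mN, yN = np.polyfit(t[:n_edge], y[:n_edge], 1)
    mU, yU = np.polyfit(t[-n_edge:], y[-n_edge:], 1)
    # Tm guess: steepest point of the raw signal
    dy = np.gradient(y, t)
    tm0 = float(t[np.argmax(np.abs(dy))])
    tm0 = float(np.clip(tm0, t[1], t[-2]))
    return np.array([tm0, 300.0, yN, mN, yU, mU])


def fit_two_state(curve: MeltingCurve, init: np.ndarray | None = None) -> TwoStateFit:
    """Nonlinear least squares fit of the two-state model to a melting curve.

    Default initialization: Tm at the temperature of steepest signal change,
    baselines from linear fits to the curve's end segments, dH = 300 kJ/mol.
    Non-convergence (including a degenerate transition indistinguishable
    from its baselines) is reported via ``converged=False``, not raised.
    """
    p0 = _initial_guess(curve) if init is None else np.asarray(init, dtype=float)

    def residuals(p: np.ndarray) -> np.ndarray:
        return two_state_signal(curve.temp_c, *p) - curve.signal

    lo = [curve.temp_c[0], 1e-3, -np.inf, -np.inf, -np.inf, -np.inf]
    hi = [curve.temp_c[-1], 5e4, np.inf, np.inf, np.inf, np.inf]
    p0[0] = np.clip(p0[0], lo[0], hi[0])
    p0[1] = np.clip(p0[1], lo[1], hi[1])
    try:
        sol = least_squares(
            residuals, p0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14,
            max_nfev=20000,
        )
    except Exception as exc:  # pragma: no cover - optimizer failure path
        return TwoStateFit(
            tm_c=float("nan"), dh_vh=float("nan"), yN=float("nan"), mN=float("nan"),
            yU=float("nan"), mU=float("nan"), rss=float("nan"),
            converged=False, message=f"optimizer error: {exc}",
        )

    tm, dh, yN, mN, yU, mU = (float(v) for v in sol.x)
    rss = float(np.sum(sol.fun**2))
    resid_sd = np.sqrt(rss / curve.temp_c.size)
    amplitude = abs((yU + mU * tm) - (yN + mN * tm))
    span = float(np.ptp(curve.signal))
    converged = bool(sol.success)
    message = sol.message
    interior = curve.temp_c[0] + 1e-6 < tm < curve.temp_c[-1] - 1e-6
    if amplitude <= max(5.0 * resid_sd, 1e-9 * max(span, 1.0)):
        converged = False
        message = "degenerate transition: amplitude indistinguishable from noise"
    elif not interior or dh <= 1e-3:
        converged = False
        message = "fit hit a parameter bound"
    return TwoStateFit(
        tm_c=tm, dh_vh=dh, yN=yN, mN=mN, yU=yU, mU=mU,
        rss=rss, converged=converged, message=message,
    )


def fraction_unfolded(curve: MeltingCurve, fit: TwoStateFit) -> np.ndarray:
    """Transform a raw curve to fraction unfolded using fitted baselines."""
    t = curve.temp_c
    native = fit.yN + fit.mN * t
    unfolded = fit.yU + fit.mU * t
    return (curve.signal - native) / (unfolded - native)


def delta_tm(fit_a: TwoStateFit, fit_b: TwoStateFit) -> float:
    """Signed melting-temperature difference tm(a) - tm(b), degrees C.

    Call as ``delta_tm(modified, unmodified)`` to report the shift the
    modification confers.
    """
    if not (fit_a.converged and fit_b.converged):
        raise AcylPipeError("delta_tm requires two converged fits")
    return float(fit_a.tm_c - fit_b.tm_c)
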