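"""Deterministic arithmetic for enzymatic, radiometric, and qPCR readouts."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AssayDirectionError, InvalidConfigError

__all__ = [
    "ActivityTrace",
    "OxidationAssay",
    "QpcrMeasurement",
    "specific_activity",
    "percent_of_control",
    "oxidation_percent",
    "relative_expression",
]

log = logging.getLogger(__name__)

#: default dye extinction coefficient at 600 nm, mM^-1 cm^-1 (literature value)
EPS_DCPIP_600 = 21.0


@dataclass
class ActivityTrace:
    """Absorbance-decay trace of a dye-reduction activity assay."""

    time_s: np.ndarray
    a600: np.ndarray
    eps_mM_cm: float = EPS_DCPIP_600
    path_cm: float = 1.0
    volume_ml: float = 1.0
    protein_mg: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.a600 = np.asarray(self.a600, dtype=float)
        if self.time_s.shape != self.a600.shape or self.time_s.size < 3:
            raise InvalidConfigError("trace needs >=3 aligned (time, A600) points")
        if self.eps_mM_cm <= 0 or self.path_cm <= 0 or self.volume_ml <= 0:
            raise InvalidConfigError("eps, path length and volume must be positive")


@dataclass
class OxidationAssay:
    """Scintillation counts for a radiolabel-release assay."""

    dpm_sample: float
    dpm_background: float
    dpm_total_added: float

    def __post_init__(self) -> None:
        if self.dpm_total_added <= 0:
            raise InvalidConfigError("dpm_total_added must be positive")


@dataclass
class QpcrMeasurement:
    """Ct table for relative quantification against an endogenous control.

    ``ct`` has columns sample_id, ct_target, ct_ref.
    """

    ct: pd.DataFrame
    calibrator: str

    def __post_init__(self) -> None:
        required = {"sample_id", "ct_target", "ct_ref"}
        if not required.issubset(self.ct.columns):
            raise InvalidConfigError(f"Ct table needs columns {sorted(required)}")
        if (self.ct[["ct_target", "ct_ref"]] <= 0).any().any():
            raise InvalidConfigError("Ct values must be positive")
        if self.calibrator not in set(self.ct["sample_id"]):
            raise InvalidConfigError(f"calibrator {self.calibrator!r} not in table")


def specific_activity(
    trace: ActivityTrace,
    fit_window: tuple[float, float] | None = None,
    slope_tolerance: float = 1e-9,
) -> float:
    """Initial-rate activity in nmol dye reduced per minute.

    A least-squares line is fitted to A600 over ``fit_window`` (seconds;
    default the first 20% of the trace) and converted via Beer-Lambert:

        rate [nmol/min] = 1000 * |slope per min| * volume_ml / (eps * path)

    Returned per mg protein when the trace carries ``protein_mg``. A slope
    that is positive beyond ``slope_tolerance`` (absorbance per minute)
    means the dye is being oxidized, not reduced, and raises.
    """
    t, a = trace.time_s, trace.a600
    if fit_window is None:
        fit_window = (t[0], t[0] + 0.2 * (t[-1] - t[0]))
    lo, hi = fit_window
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9 or hi <= lo:
        raise InvalidConfigError("fit window must lie within the trace")
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 3:
        raise InvalidConfigError("fit window covers <3 points")
    slope_per_s = float(np.polyfit(t[mask], a[mask], 1)[0])
    slope_per_min = slope_per_s * 60.0
    if slope_per_min > slope_tolerance:
        raise AssayDirectionError(
            f"A600 increases ({slope_per_min:.4g}/min); dye is not being reduced"
        )
    rate_nmol_min = (
        1000.0 * abs(slope_per_min) * trace.volume_ml
        / (trace.eps_mM_cm * trace.path_cm)
    )
    if trace.protein_mg is not None:
        if trace.protein_mg <= 0:
            raise InvalidConfigError("protein_mg must be positive")
        return rate_nmol_min / trace.protein_mg
    return rate_nmol_min


def percent_of_control(value: float, control: float) -> float:
    """Activity as a percentage of the unmodified control: 100*value/control."""
    if control <= 0:
        raise InvalidConfigError("control activity must be positive")
    return 100.0 * value / control


def oxidation_percent(assay: OxidationAssay) -> float:
    """Background-subtracted label release as % of total label added.

    Negative background-subtracted counts are clamped to zero (and logged):
    they are counting noise, not negative release.
    """
    net = assay.dpm_sample - assay.dpm_background
    if net < 0:
        log.info("net DPM %.3g below zero; clamping to 0", net)
        net = 0.0
    return 100.0 * net / assay.dpm_total_added


def relative_expression(q: QpcrMeasurement) -> pd.Series:
    """Fold change per sample by the delta-delta-Ct method: 2^(-ddCt).

    ddCt = (Ct_target - Ct_ref)_sample - (Ct_target - Ct_ref)_calibrator;
    the calibrator sample maps to exactly 1.0.
    """
    ct = q.ct.set_index("sample_id")
    dct = ct["ct_target"] - ct["ct_ref"]
    ddct = dct - dct.loc[q.calibrator]
    return np.power(2.0, -ddct).rename("fold_change")
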