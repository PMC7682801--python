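"""Closed-form vascular and anthropometric index calculators.

Aortic compliance is the fractional pulsatile area change of the aortic
lumen, ``(A_max − A_min) / A_min`` (dimensionless); distensibility divides
compliance by the central pulse pressure (per mmHg).  Global values are the
mean of the local measurements along the aorta.  Carotid–femoral pulse wave
velocity uses the subtracted-distance convention: both path lengths are
measured from the sternal notch, so the wave travels the *difference* of the
two distances in the difference of the two R-wave-gated transit times.
Capillary density is the mean of six capillaroscopy fields, computed
separately for the resting (functional) and post-venous-congestion
(anatomic) field sets.

All functions are plain scalar formulas; :func:`append_indices` vectorises
them over a cohort table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AORTIC_SITES",
    "AorticSiteMeasurement",
    "PWVMeasurement",
    "aortic_compliance",
    "aortic_distensibility",
    "global_aortic_index",
    "pulse_wave_velocity",
    "capillary_density",
    "body_surface_area",
    "bsa_and_index",
    "append_indices",
]

#: Imaging planes at which the aortic lumen is measured: ascending aorta,
#: proximal descending aorta, distal descending aorta, abdominal aorta.
AORTIC_SITES = ("AA", "PDA", "DDA", "AbA")


@dataclass(frozen=True)
class AorticSiteMeasurement:
    """Per-site aortic lumen areas (mm^2) and central pulse pressure (mmHg)."""

    site: str
    a_max: float
    a_min: float
    pulse_pressure: float

    def __post_init__(self) -> None:
        if self.a_min <= 0:
            raise ValueError(f"minimum aortic area must be positive, got {self.a_min}")
        if self.a_max < self.a_min:
            raise ValueError(
                f"maximum area ({self.a_max}) smaller than minimum ({self.a_min})"
            )
        if self.pulse_pressure <= 0:
            raise ValueError(
                f"pulse pressure must be positive, got {self.pulse_pressure}"
            )


@dataclass(frozen=True)
class PWVMeasurement:
    """Sternal-notch path lengths (m) and R-wave-gated arrival times (s)."""

    d_notch_carotid: float
    d_notch_femoral: float
    t_carotid: float
    t_femoral: float

    def __post_init__(self) -> None:
        if self.d_notch_carotid <= 0 or self.d_notch_femoral <= 0:
            raise ValueError("path distances must be positive")
        if self.t_femoral <= self.t_carotid:
            raise ValueError(
                "femoral arrival time must exceed carotid arrival time "
                f"({self.t_femoral} <= {self.t_carotid})"
            )


def aortic_compliance(m: AorticSiteMeasurement) -> float:
    """Fractional area change (A_max − A_min) / A_min, dimensionless."""
    return (m.a_max - m.a_min) / m.a_min


def aortic_distensibility(m: AorticSiteMeasurement) -> float:
    """Compliance divided by central pulse pressure, per mmHg."""
    return aortic_compliance(m) / m.pulse_pressure


def global_aortic_index(values: Sequence[float]) -> tuple[float, dict]:
    """Mean of the available per-site values.

    Returns ``(mean, meta)`` where ``meta`` records how many sites entered
    the mean and whether any were missing (NaN values are dropped under the
    available-case rule).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("global aortic index needs at least one site value")
    present = arr[np.isfinite(arr)]
    if present.size == 0:
        raise ValueError("all site values are missing")
    meta = {
        "n_sites": int(present.size),
        "n_missing": int(arr.size - present.size),
        "complete": bool(present.size == arr.size),
    }
    return float(present.mean()), meta


def pulse_wave_velocity(m: PWVMeasurement) -> float:
    """Carotid–femoral PWV (m/s), subtracted-distance convention."""
    dd = m.d_notch_femoral - m.d_notch_carotid
    dt = m.t_femoral - m.t_carotid
    if dt <= 0:
        raise ValueError("transit-time difference must be positive")
    if dd <= 0:
        raise ValueError("femoral path must be longer than carotid path")
    return dd / dt


def capillary_density(fields: Iterable[float], strict: bool = True) -> float:
    """Mean capillary density (capillaries/mm^2) over a set of image fields.

    The protocol records exactly 6 fields; ``strict=False`` relaxes that to
    any non-empty set (available-case mean) for incomplete acquisitions.
    """
    arr = np.asarray(list(fields), dtype=float)
    if strict and arr.size != 6:
        raise ValueError(f"expected exactly 6 capillaroscopy fields, got {arr.size}")
    if arr.size == 0:
        raise ValueError("no capillaroscopy fields supplied")
    if np.any(arr < 0):
        raise ValueError("capillary counts cannot be negative")
    return float(arr.mean())


def body_surface_area(height_cm: float, weight_kg: float, formula: str = "dubois") -> float:
    """Body surface area in m^2 (Du Bois by default, Mosteller optional)."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    if formula == "dubois":
        return 0.007184 * height_cm**0.725 * weight_kg**0.425
    if formula == "mosteller":
        return float(np.sqrt(height_cm * weight_kg / 3600.0))
    raise ValueError(f"unknown BSA formula: {formula!r}")


def bsa_and_index(
    value: float, height_cm: float, weight_kg: float, formula: str = "dubois"
) -> tuple[float, float]:
    """Return ``(value / BSA, BSA)`` for body-size indexing (e.g. g/m^2)."""
    bsa = body_surface_area(height_cm, weight_kg, formula)
    return value / bsa, bsa


# ---------------------------------------------------------------------------
# cohort-table vectorisation
# ---------------------------------------------------------------------------

def append_indices(frame: pd.DataFrame) -> pd.DataFrame:
    """Append derived index columns to a cohort table.

    Expects the column layout written by the synthetic generator (or any
    table following the documented dictionary): per-site ``{site}_a_max``,
    ``{site}_a_min``, ``central_pp``, capillaroscopy fields
    ``cap_func_1..6`` / ``cap_anat_1..6``, PWV raw columns, ``height`` and
    ``weight``.  Missing sites (NaN) are dropped from the global means under
    the available-case rule and flagged in ``aortic_sites_complete``.
    """
    out = frame.copy()
    comp_cols, dist_cols = [], []
    for site in AORTIC_SITES:
        amax, amin = out[f"{site}_a_max"], out[f"{site}_a_min"]
        comp = (amax - amin) / amin
        out[f"{site}_compliance"] = comp
        out[f"{site}_distensibility"] = comp / out["central_pp"]
        comp_cols.append(f"{site}_compliance")
        dist_cols.append(f"{site}_distensibility")
    out["global_compliance"] = out[comp_cols].mean(axis=1)
    out["global_distensibility"] = out[dist_cols].mean(axis=1)
    out["aortic_sites_complete"] = out[comp_cols].notna().all(axis=1)

    func = [f"cap_func_{i}" for i in range(1, 7)]
    anat = [f"cap_anat_{i}" for i in range(1, 7)]
    out["functional_capillary_density"] = out[func].mean(axis=1)
    out["anatomic_capillary_density"] = out[anat].mean(axis=1)

    out["pwv"] = (out["pwv_d_femoral"] - out["pwv_d_carotid"]) / (
        out["pwv_t_femoral"] - out["pwv_t_carotid"]
    )
    out["bsa"] = 0.007184 * out["height"] ** 0.725 * out["weight"] ** 0.425
    return out
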