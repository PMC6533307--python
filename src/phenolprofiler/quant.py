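"""Calibration, method-validation statistics, and RRF-based quantification.

Compounds with authentic standards (apigenin, acacetin, luteolin) are
quantified from external calibration lines ``area = slope * conc +
intercept``. The remaining phenolics are quantified against structurally
similar internal standards through a relative response factor

    RRF = (A_k / A_i) / (C_k / C_i)

measured once from a known compound k spiked alongside the internal
standard i, after which an unknown with peak area A is back-calculated as

    conc = (A / A_i) * C_i / RRF / R

where R is the recovery-rate correction (fraction, default 1). Solution
concentrations (ug/mL) convert to dry-weight contents (mg/g DW) through
the extract volume, the dry mass extracted, and any dilution. Validation
helpers cover LOD/LOQ from baseline noise (3 sigma/slope and 10
sigma/slope), spiked recovery, and replicate RSD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _scistats

from .annotator import CompoundClass, PHENOLIC_CLASSES
from .errors import (
    InsufficientCalibrationError,
    InvalidCurveError,
    InvalidMeasurementError,
    InvalidRecoveryError,
    InvalidSpikeError,
    UndefinedRSDError,
)

__all__ = [
    "CalibrationCurve",
    "InternalStandardSpec",
    "RRFSpec",
    "QuantMethod",
    "QuantRecord",
    "ClassSummary",
    "DEFAULT_IS_ASSIGNMENTS",
    "fit_calibration",
    "lod_loq",
    "concentration_from_curve",
    "relative_response_factor",
    "quantify_unknown",
    "recovery_rate",
    "rsd",
    "content_per_dw",
    "folin_tp",
    "aggregate_by_class",
]

#: Extraction geometry of the optimized protocol: 0.5 g dry flower in 15 mL
#: solvent (the 1:30 g/mL optimum).
DEFAULT_EXTRACT_VOLUME_ML = 15.0
DEFAULT_DRY_MASS_G = 0.5

#: Which internal standard quantifies which compound lacking a standard.
DEFAULT_IS_ASSIGNMENTS: dict[str, str] = {
    "3-O-Caffeoyl-5-O-p-coumaroylquinic acid": "Protocatechuic acid",
    "Gallic acid monohydrate": "Protocatechuic acid",
    "Shikimic acid isomer": "Protocatechuic acid",
    "Coumaroyloleuropein": "Ferulic acid",
    "3,5-Dicaffeoylquinic acid monohydrate": "Ferulic acid",
    "3,5-Dicaffeoylquinic acid": "Ferulic acid",
    "Methoxyoleuropein isomer": "Ferulic acid",
    "Prenyl-dimethoxy-caffeoyl-p-coumaric acid": "Ferulic acid",
    "Tricin": "Hesperidin",
    "Luteolin-O-glucoside": "Hesperidin",
    "Chrysoeriol": "Hesperidin",
}


class QuantMethod(str, Enum):
    EXTERNAL_STANDARD = "external_standard"
    RRF = "rrf"


@dataclass(frozen=True)
class CalibrationCurve:
    """External-standard line in area-vs-concentration (ug/mL) space."""

    analyte: str
    wavelength: float
    slope: float
    intercept: float
    r_squared: float
    lod: float = 0.0
    loq: float = 0.0

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise InvalidCurveError(f"{self.analyte}: slope must be nonzero")
        if self.lod < 0 or self.loq < self.lod:
            raise InvalidCurveError(f"{self.analyte}: need 0 <= LOD <= LOQ")

    def predict_area(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept


@dataclass(frozen=True)
class InternalStandardSpec:
    """An internal standard at fixed solution concentration with measured area."""

    name: str
    concentration: float  # ug/mL
    area: float

    def __post_init__(self) -> None:
        if self.concentration <= 0 or self.area <= 0:
            raise InvalidMeasurementError(
                f"{self.name}: internal-standard concentration and area must be > 0"
            )


@dataclass(frozen=True)
class RRFSpec:
    """Measured relative response of a known compound vs its internal standard."""

    known_compound: str
    known_area: float
    known_concentration: float
    internal_standard: InternalStandardSpec
    rrf: float

    @classmethod
    def measure(
        cls,
        known_compound: str,
        known_area: float,
        known_concentration: float,
        internal_standard: InternalStandardSpec,
    ) -> "RRFSpec":
        value = relative_response_factor(
            known_area,
            internal_standard.area,
            known_concentration,
            internal_standard.concentration,
        )
        return cls(known_compound, known_area, known_concentration, internal_standard, value)


def fit_calibration(
    points: Sequence[tuple[float, float]],
    analyte: str = "",
    wavelength: float = float("nan"),
) -> CalibrationCurve:
    """Least-squares line through (concentration ug/mL, area) standards.

    Needs at least three distinct concentration levels to say anything
    about linearity.
    """
    if len(points) < 3:
        raise InsufficientCalibrationError("need >= 3 calibration points")
    conc = np.array([p[0] for p in points], dtype=float)
    area = np.array([p[1] for p in points], dtype=float)
    if len(np.unique(conc)) < 3:
        raise InsufficientCalibrationError("need >= 3 distinct concentrations")
    res = _scistats.linregress(conc, area)
    if res.slope == 0:
        raise InsufficientCalibrationError("degenerate calibration: zero slope")
    return CalibrationCurve(
        analyte=analyte,
        wavelength=wavelength,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def lod_loq(noise_sd: float, curve: CalibrationCurve) -> tuple[float, float]:
    """Detection and quantification limits at signal-to-noise 3 and 10.

    ``noise_sd`` is the baseline noise standard deviation in area units;
    the limits are 3 sigma/slope and 10 sigma/slope in ug/mL.
    """
    if noise_sd < 0:
        raise InvalidMeasurementError("noise_sd must be >= 0")
    if curve.slope <= 0:
        raise InvalidCurveError("LOD/LOQ need a positive calibration slope")
    return 3.0 * noise_sd / curve.slope, 10.0 * noise_sd / curve.slope


def concentration_from_curve(
    area: float, curve: CalibrationCurve
) -> tuple[float, bool]:
    """Invert the calibration line; clamp negatives to 0.

    Returns (concentration ug/mL, clamped flag). Areas below the intercept
    back-calculate negative and are routine for blank-level signals, so
    they clamp to zero with the flag set instead of raising.
    """
    conc = (area - curve.intercept) / curve.slope
    if conc < 0:
        return 0.0, True
    return conc, False


def relative_response_factor(
    a_k: float, a_i: float, c_k: float, c_i: float
) -> float:
    """RRF = (A_k/A_i) / (C_k/C_i) for known compound k vs internal standard i."""
    if min(a_k, a_i, c_k, c_i) <= 0:
        raise InvalidMeasurementError("RRF inputs must all be positive")
    return (a_k / a_i) / (c_k / c_i)


def quantify_unknown(
    area: float,
    is_spec: InternalStandardSpec,
    rrf: float,
    recovery: float = 1.0,
) -> float:
    """Solution concentration (ug/mL) of an unknown from its peak area.

    conc = (A / A_i) * C_i / RRF / R, with R a recovery fraction in (0, 1.2].
    """
    if area < 0:
        raise InvalidMeasurementError("peak area must be >= 0")
    if rrf <= 0:
        raise InvalidMeasurementError("RRF must be > 0")
    if not 0 < recovery <= 1.2:
        raise InvalidRecoveryError("recovery must lie in (0, 1.2]")
    return (area / is_spec.area) * is_spec.concentration / rrf / recovery


def recovery_rate(before: float, after: float, spiked: float) -> float:
    """Spiked-recovery accuracy in percent: 100 * (after - before) / spiked."""
    if spiked <= 0:
        raise InvalidSpikeError("spiked amount must be > 0")
    return (after - before) / spiked * 100.0


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation in percent, sample (n-1) convention."""
    if len(values) < 2:
        raise UndefinedRSDError("RSD needs at least 2 replicates")
    arr = np.asarray(values, dtype=float)
    mean = arr.mean()
    if mean == 0:
        raise UndefinedRSDError("RSD undefined for zero mean")
    return float(arr.std(ddof=1) / mean * 100.0)


def content_per_dw(
    concentration: float,
    extract_volume: float = DEFAULT_EXTRACT_VOLUME_ML,
    dry_mass: float = DEFAULT_DRY_MASS_G,
    dilution: float = 1.0,
) -> float:
    """Convert a solution concentration (ug/mL) to mg per g dry weight."""
    if min(extract_volume, dry_mass, dilution) <= 0:
        raise InvalidMeasurementError("volume, mass and dilution must be > 0")
    return concentration * dilution * extract_volume / dry_mass / 1000.0


def folin_tp(
    absorbance: float,
    gallic_curve: CalibrationCurve,
    dilution: float = 1.0,
    extract_volume: float = DEFAULT_EXTRACT_VOLUME_ML,
    dry_mass: float = DEFAULT_DRY_MASS_G,
) -> float:
    """Total phenolics by the Folin-Ciocalteu assay, in g GAE / 100 g DW.

    The gallic-acid calibration (signal vs ug GAE/mL) is inverted at the
    measured absorbance and scaled through the extraction geometry; the
    mg/g figure divides by 10 to land on g per 100 g.
    """
    conc, _ = concentration_from_curve(absorbance, gallic_curve)
    return content_per_dw(conc, extract_volume, dry_mass, dilution) / 10.0


_GROUP_TO_CLASS = {
    "hydroxybenzoic acid": CompoundClass.HYDROXYBENZOIC,
    "hydroxycinnamic acid": CompoundClass.HYDROXYCINNAMIC,
    "flavonoid": CompoundClass.FLAVONOID,
    "hydroxy fatty acid": CompoundClass.HYDROXY_FATTY_ACID,
    "unknown": CompoundClass.UNKNOWN,
}


def class_from_group(group: str) -> CompoundClass:
    """Map a free-text group label (e.g. 'Hydroxycinnamic acid') to the enum."""
    try:
        return _GROUP_TO_CLASS[group.strip().lower()]
    except KeyError:
        raise InvalidMeasurementError(f"unrecognized compound group {group!r}") from None


@dataclass(frozen=True)
class QuantRecord:
    """One quantified compound: solution concentration and dry-weight content."""

    compound: str
    compound_class: CompoundClass
    content: float  # mg/g DW
    method: QuantMethod
    concentration: float | None = None  # ug/mL in the extract, when known
    clamped: bool = False

    def __post_init__(self) -> None:
        if self.content < 0:
            raise InvalidMeasurementError(
                f"{self.compound}: content must be >= 0"
            )


@dataclass(frozen=True)
class ClassSummary:
    """Per-class content sums (mg/g DW), phenolic total, and the top compound."""

    class_totals: Mapping[str, float]
    total_phenolics: float
    top_compound: str | None
    top_content: float

    def phenolic_fraction(self, record_content: float) -> float:
        if self.total_phenolics == 0:
            return math.nan
        return record_content / self.total_phenolics


def aggregate_by_class(records: Sequence[QuantRecord]) -> ClassSummary:
    """Sum contents per compound class and locate the most abundant compound.

    The phenolic total covers the hydroxybenzoic, hydroxycinnamic and
    flavonoid classes; the top compound is the arg-max by content over all
    records (ties broken by compound name for determinism).
    """
    # summation in a canonical order makes the result independent of how
    # the caller happened to order the records
    ordered = sorted(records, key=lambda r: (r.compound, r.content))
    totals = {c.value: 0.0 for c in CompoundClass}
    for r in ordered:
        totals[r.compound_class.value] += r.content
    total_phenolics = sum(totals[c.value] for c in PHENOLIC_CLASSES)
    if records:
        top = max(records, key=lambda r: (r.content, r.compound))
        top_compound, top_content = top.compound, top.content
    else:
        top_compound, top_content = None, 0.0
    return ClassSummary(
        class_totals=totals,
        total_phenolics=total_phenolics,
        top_compound=top_compound,
        top_content=top_content,
    )


def quantify_peak_table(
    peaks: Sequence[tuple[str, float]],
    curves: Mapping[str, CalibrationCurve],
    internal_standards: Mapping[str, InternalStandardSpec],
    rrf_specs: Mapping[str, RRFSpec],
    classes: Mapping[str, CompoundClass],
    recovery_map: Mapping[str, float] | None = None,
    is_assignments: Mapping[str, str] = DEFAULT_IS_ASSIGNMENTS,
    extract_volume: float = DEFAULT_EXTRACT_VOLUME_ML,
    dry_mass: float = DEFAULT_DRY_MASS_G,
    dilution: float = 1.0,
) -> list[QuantRecord]:
    """Quantify a (compound, area) peak table end to end.

    Compounds with their own calibration curve use it; compounds mapped to
    an internal standard use the RRF route with an optional per-compound
    recovery correction (default 1.0). Compounds with neither raise.
    """
    recovery_map = recovery_map or {}
    out: list[QuantRecord] = []
    for compound, area in peaks:
        cls = classes.get(compound, CompoundClass.UNKNOWN)
        if compound in curves:
            conc, clamped = concentration_from_curve(area, curves[compound])
            method = QuantMethod.EXTERNAL_STANDARD
        elif compound in is_assignments:
            is_name = is_assignments[compound]
            try:
                is_spec = internal_standards[is_name]
                rrf_value = rrf_specs[is_name].rrf
            except KeyError as exc:
                raise InvalidMeasurementError(
                    f"{compound}: missing internal standard data for {is_name}"
                ) from exc
            conc = quantify_unknown(
                area, is_spec, rrf_value, recovery_map.get(compound, 1.0)
            )
            clamped = False
            method = QuantMethod.RRF
        else:
            raise InvalidMeasurementError(
                f"{compound}: no calibration curve or internal-standard assignment"
            )
        out.append(
            QuantRecord(
                compound=compound,
                compound_class=cls,
                content=content_per_dw(conc, extract_volume, dry_mass, dilution),
                method=method,
                concentration=conc,
                clamped=clamped,
            )
        )
    return out
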