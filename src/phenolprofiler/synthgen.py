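"""Synthetic inputs with the statistical structure each pipeline stage assumes.

Three generators mirror the three data-generating processes:

* quadratic response surfaces with additive Gaussian noise, evaluated on a
  CCC design (what the extraction experiment measures);
* MS^n spectral trees realized from per-compound fragmentation templates,
  with a uniform mass-axis calibration offset and multiplicative intensity
  noise (what the ion trap records);
* peak areas produced by inverting the calibration / RRF quantification
  relations and multiplying by lognormal noise (what the PDA integrator
  reports).

Everything is driven by an explicit seed and is bit-reproducible. The m/z
perturbation is modelled as a single per-spectrum-tree calibration offset
drawn uniformly in +/-jitter: it shifts every ion together, the way a
drifting mass axis does on a unit-resolution trap, so neutral-loss
differences stay intact while absolute masses move.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .annotator import CompoundClass, FragmentNode, SpectralTree
from .quant import CalibrationCurve, InternalStandardSpec, RRFSpec
from .rsm import CCCDesign, quadratic_design_matrix

__all__ = [
    "SurfaceSpec",
    "CompoundSpec",
    "MixtureSpec",
    "gen_response_surface",
    "gen_spectral_tree",
    "gen_peak_table",
    "compound_library",
]


@dataclass(frozen=True)
class SurfaceSpec:
    """True coefficients of a quadratic surface plus response noise level."""

    coefficients: tuple[float, ...]  # 10 values, coded basis order
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.coefficients) != 10:
            raise ValueError("a 3-factor quadratic surface has 10 coefficients")


def gen_response_surface(spec: SurfaceSpec, design: CCCDesign) -> CCCDesign:
    """Evaluate the surface on the design and add Gaussian response noise."""
    X = quadratic_design_matrix(design.coded_matrix())
    y = X @ np.asarray(spec.coefficients, dtype=float)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        y = y + rng.normal(0.0, spec.noise_sd, size=y.shape)
    return design.with_responses(y)


@dataclass(frozen=True)
class CompoundSpec:
    """A compound's identity plus the fragment-tree template it produces."""

    name: str
    compound_class: CompoundClass
    precursor_mz: float | None
    uv_bands: tuple[float, ...]
    template: tuple[FragmentNode, ...]
    retention_time: float | None = None

    def to_tree(self, peak_id: str) -> SpectralTree:
        return SpectralTree(
            peak_id=peak_id,
            precursor_mz=self.precursor_mz,
            uv_lambda_max=self.uv_bands,
            retention_time=self.retention_time,
            fragments=self.template,
        )


def compound_library() -> tuple[CompoundSpec, ...]:
    """All 23 observed peaks as generation templates.

    The 20 named compounds plus the 3 unidentifiable peaks, which are kept
    as distractors so batches contain spectra the cascade must refuse to
    name.
    """
    from .io import load_spectral_trees, load_reference_annotations

    refs = load_reference_annotations()
    specs = []
    for tree in load_spectral_trees():
        name, group = refs[tree.peak_id]
        specs.append(
            CompoundSpec(
                name=name,
                compound_class=group,
                precursor_mz=tree.precursor_mz,
                uv_bands=tree.uv_lambda_max,
                template=tree.fragments,
                retention_time=tree.retention_time,
            )
        )
    return tuple(specs)


def _perturb(
    nodes: Sequence[FragmentNode],
    offset: float,
    intensity_noise: float,
    rng: np.random.Generator,
) -> tuple[FragmentNode, ...]:
    out = []
    for node in nodes:
        rel = node.rel_intensity
        if intensity_noise > 0 and rel < 100:
            # base peaks stay at 100 by definition; others wobble and clip
            rel = float(
                np.clip(rel * rng.lognormal(0.0, intensity_noise / 100.0), 0.1, 99.9)
            )
        out.append(
            FragmentNode(
                mz=node.mz + offset,
                rel_intensity=rel,
                children=_perturb(node.children, offset, intensity_noise, rng),
            )
        )
    return tuple(out)


def gen_spectral_tree(
    spec: CompoundSpec,
    mz_jitter: float = 0.0,
    intensity_noise: float = 0.0,
    seed: int = 0,
    peak_id: str | None = None,
) -> SpectralTree:
    """Realize one spectral tree from a compound template.

    ``mz_jitter`` (Da) bounds a uniform mass-axis offset applied to the
    whole tree; ``intensity_noise`` is the lognormal sigma (in percent) of
    non-base relative intensities. Zero perturbation returns the template
    exactly.
    """
    if mz_jitter < 0 or intensity_noise < 0:
        raise ValueError("jitter and intensity noise must be >= 0")
    rng = np.random.default_rng(seed)
    offset = float(rng.uniform(-mz_jitter, mz_jitter)) if mz_jitter > 0 else 0.0
    pid = peak_id if peak_id is not None else f"synthetic-{spec.name}"
    if spec.precursor_mz is None:
        return spec.to_tree(pid)
    return SpectralTree(
        peak_id=pid,
        precursor_mz=spec.precursor_mz + offset,
        uv_lambda_max=spec.uv_bands,
        retention_time=spec.retention_time,
        fragments=_perturb(spec.template, offset, intensity_noise, rng),
    )


@dataclass(frozen=True)
class MixtureSpec:
    """True composition of a synthetic extract plus the measurement model."""

    concentrations: Mapping[str, float]  # compound -> true ug/mL in solution
    curves: Mapping[str, CalibrationCurve]
    internal_standards: Mapping[str, InternalStandardSpec]
    rrf_specs: Mapping[str, RRFSpec]
    is_assignments: Mapping[str, str]
    recovery_map: Mapping[str, float] = field(default_factory=dict)
    area_noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.concentrations.values()):
            raise ValueError("true concentrations must be >= 0")
        if self.area_noise_cv < 0:
            raise ValueError("area_noise_cv must be >= 0")


def gen_peak_table(spec: MixtureSpec) -> list[tuple[str, float]]:
    """Peak areas implied by the true concentrations, with lognormal noise.

    Inverts the quantification relations: external-standard compounds get
    ``area = slope * conc + intercept``; RRF compounds get ``area = conc *
    RRF * R * A_i / C_i``. Multiplicative lognormal noise with coefficient
    of variation ``area_noise_cv`` emulates integration variability.
    """
    rng = np.random.default_rng(spec.seed)
    sigma = (
        float(np.sqrt(np.log1p(spec.area_noise_cv**2))) if spec.area_noise_cv else 0.0
    )
    out = []
    for compound, conc in spec.concentrations.items():
        if compound in spec.curves:
            area = spec.curves[compound].predict_area(conc)
        elif compound in spec.is_assignments:
            is_spec = spec.internal_standards[spec.is_assignments[compound]]
            rrf = spec.rrf_specs[spec.is_assignments[compound]].rrf
            recovery = spec.recovery_map.get(compound, 1.0)
            area = conc * rrf * recovery * is_spec.area / is_spec.concentration
        else:
            raise KeyError(f"{compound}: no quantification route in the mixture spec")
        if sigma > 0:
            # mean-one lognormal: E[area * noise] = area
            area *= float(rng.lognormal(-sigma**2 / 2.0, sigma))
        out.append((compound, float(area)))
    return out
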