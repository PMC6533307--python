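"""Readers, writers, packaged reference tables, and the end-to-end pipeline.

Delimited text is accepted with comma or tab separators (sniffed from the
header line), UTF-8, header row required, decimal points only. Spectral
trees travel as JSON with nested ``{mz, rel_intensity, children}`` fragment
records; flat MS2 peak lists can also be ingested from MGF. All writers
round-trip losslessly through their paired reader.

The packaged data files transcribe the published experiment: the 20-run
CCC extraction design with total-phenolic responses, the 23 MS^n spectral
trees with their reference assignments, the five calibration curves with
validation figures, and the 14 reported compound contents.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import rsm
from .annotator import (
    Annotation,
    BatchResult,
    CompoundClass,
    FragmentNode,
    SpectralTree,
    annotate_batch,
)
from .errors import ParseError
from .quant import (
    CalibrationCurve,
    ClassSummary,
    QuantRecord,
    aggregate_by_class,
    class_from_group,
)
from .rsm import CCCDesign, DEFAULT_FACTORS, FactorSpec

__all__ = [
    "read_design",
    "write_design",
    "read_spectra",
    "write_spectra",
    "read_mgf",
    "write_annotations",
    "read_peaks",
    "write_quant_report",
    "load_extraction_design",
    "load_spectral_trees",
    "load_reference_annotations",
    "load_calibration_table",
    "load_reported_contents",
    "run_pipeline",
    "PipelineConfig",
]

_DATA = resources.files("phenolprofiler") / "data"


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Comma- or tab-separated UTF-8 table with a required header row."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    if not header.strip():
        raise ParseError(f"{path}: empty file or missing header")
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    return pd.read_csv(path, sep=sep)


# ---------------------------------------------------------------- designs


def read_design(
    path: str | Path, factors: Sequence[FactorSpec] = DEFAULT_FACTORS
) -> CCCDesign:
    """Load a design/response table (run, x*_coded, x*_uncoded, response)."""
    df = _read_delimited(path)
    k = len(factors)
    coded_cols = [f"x{j+1}_coded" for j in range(k)]
    missing = [c for c in coded_cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    points = []
    alpha = 1.0
    for i, row in df.iterrows():
        coded = tuple(float(row[c]) for c in coded_cols)
        alpha = max(alpha, max(abs(z) for z in coded))
        if "role" in df.columns:
            role = str(row["role"])
        elif all(z == 0 for z in coded):
            role = "center"
        elif any(abs(z) > 1 for z in coded):
            role = "axial"
        else:
            role = "factorial"
        if role not in ("factorial", "axial", "center"):
            raise ParseError(f"{path}: row {i + 1}: unknown role {role!r}")
        resp = row.get("response", np.nan)
        uncoded = tuple(rsm.uncode_value(z, f) for z, f in zip(coded, factors))
        points.append(
            rsm.DesignPoint(
                coded=coded,
                uncoded=uncoded,
                role=role,  # type: ignore[arg-type]
                response=None if pd.isna(resp) else float(resp),
            )
        )
    return CCCDesign(factors=tuple(factors), alpha=alpha, points=tuple(points))


def write_design(design: CCCDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------- spectra


def _fragment_from_json(obj: dict, context: str) -> FragmentNode:
    try:
        mz = float(obj["mz"])
        rel = float(obj["rel_intensity"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"{context}: fragment needs numeric mz and rel_intensity") from exc
    children = tuple(
        _fragment_from_json(c, context) for c in obj.get("children", ())
    )
    return FragmentNode(mz=mz, rel_intensity=rel, children=children)


def _tree_from_json(obj: dict) -> SpectralTree:
    pid = str(obj.get("peak_id", "?"))
    prec = obj.get("precursor_mz")
    try:
        return SpectralTree(
            peak_id=pid,
            precursor_mz=None if prec is None else float(prec),
            uv_lambda_max=tuple(float(b) for b in obj.get("uv_lambda_max", ())),
            retention_time=(
                None if obj.get("rt_min") is None else float(obj["rt_min"])
            ),
            fragments=tuple(
                _fragment_from_json(f, f"peak {pid}") for f in obj.get("fragments", ())
            ),
        )
    except (TypeError, ValueError) as exc:
        raise ParseError(f"peak {pid}: {exc}") from exc


def read_spectra(path: str | Path) -> list[SpectralTree]:
    """Load spectral trees from the JSON schema, validating invariants."""
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    entries = payload["trees"] if isinstance(payload, dict) else payload
    return [_tree_from_json(e) for e in entries]


def _fragment_to_json(node: FragmentNode) -> dict:
    out: dict = {"mz": node.mz, "rel_intensity": node.rel_intensity}
    if node.children:
        out["children"] = [_fragment_to_json(c) for c in node.children]
    return out


def write_spectra(trees: Sequence[SpectralTree], path: str | Path) -> None:
    payload = {
        "trees": [
            {
                "peak_id": t.peak_id,
                "rt_min": t.retention_time,
                "uv_lambda_max": list(t.uv_lambda_max),
                "precursor_mz": t.precursor_mz,
                "fragments": [_fragment_to_json(f) for f in t.fragments],
            }
            for t in trees
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def read_mgf(path: str | Path) -> list[SpectralTree]:
    """Ingest flat MS2 spectra from an MGF file as single-level trees.

    Peak intensities are rescaled to percent of the spectrum base peak;
    fragments at or above the precursor m/z are dropped (they are isotope
    or unreacted-precursor signals, not products).
    """
    from pyteomics import mgf as _mgf

    trees = []
    with _mgf.MGF(str(path)) as reader:
        for i, spectrum in enumerate(reader, start=1):
            params = spectrum.get("params", {})
            pid = str(params.get("title", f"scan-{i}"))
            pepmass = params.get("pepmass")
            if pepmass is None:
                raise ParseError(f"{path}: spectrum {pid}: missing PEPMASS")
            prec = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            mzs = np.asarray(spectrum["m/z array"], dtype=float)
            ints = np.asarray(spectrum["intensity array"], dtype=float)
            keep = mzs < prec
            mzs, ints = mzs[keep], ints[keep]
            frags: tuple[FragmentNode, ...] = ()
            if len(mzs) and ints.max() > 0:
                rel = ints / ints.max() * 100.0
                frags = tuple(
                    FragmentNode(mz=float(m), rel_intensity=float(r))
                    for m, r in zip(mzs, rel)
                    if r > 0
                )
            rt = params.get("rtinseconds")
            trees.append(
                SpectralTree(
                    peak_id=pid,
                    precursor_mz=prec,
                    retention_time=None if rt is None else float(rt) / 60.0,
                    fragments=frags,
                )
            )
    return trees


def write_annotations(
    result: BatchResult, path: str | Path, trees: Sequence[SpectralTree] | None = None
) -> None:
    result.to_frame(trees).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------ peak tables


def read_peaks(path: str | Path) -> list[tuple[str, float]]:
    """Load a (compound, area) peak table; extra columns are ignored."""
    df = _read_delimited(path)
    for col in ("compound", "area"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return [(str(r["compound"]), float(r["area"])) for _, r in df.iterrows()]


def write_quant_report(
    records: Sequence[QuantRecord],
    summary: ClassSummary,
    path: str | Path,
    provenance: Mapping | None = None,
) -> None:
    """JSON quant report plus a TSV mirror alongside it."""
    path = Path(path)
    payload = {
        "records": [
            {
                "compound": r.compound,
                "compound_class": r.compound_class.value,
                "concentration_ug_ml": r.concentration,
                "content_mg_per_g_dw": r.content,
                "method": r.method.value,
            }
            for r in records
        ],
        "class_totals_mg_per_g_dw": dict(summary.class_totals),
        "total_phenolics_mg_per_g_dw": summary.total_phenolics,
        "top_compound": summary.top_compound,
        "top_content_mg_per_g_dw": summary.top_content,
        "provenance": dict(provenance or {}),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
    tsv = path.with_suffix(".tsv")
    pd.DataFrame(payload["records"]).to_csv(tsv, sep="\t", index=False)


# ------------------------------------------------------- packaged fixtures


def load_extraction_design() -> CCCDesign:
    """The 20-run CCC design of the flower extraction, with TP responses."""
    with resources.as_file(_DATA / "ccc_design_tp.csv") as p:
        return read_design(p)


def load_spectral_trees() -> list[SpectralTree]:
    """The 23 observed spectral trees (precursor, UV bands, MS^n fragments)."""
    with resources.as_file(_DATA / "spectral_trees.json") as p:
        return read_spectra(p)


def load_reference_annotations() -> dict[str, tuple[str, CompoundClass]]:
    """Published identification and group per peak id, for validation."""
    with (_DATA / "spectral_trees.json").open(encoding="utf-8") as fh:
        payload = json.load(fh)
    out = {}
    for entry in payload["trees"]:
        out[str(entry["peak_id"])] = (
            entry["reference_identification"],
            class_from_group(entry["reference_group"]),
        )
    return out


def load_calibration_table() -> pd.DataFrame:
    """Calibration lines and validation statistics of the five standards."""
    with resources.as_file(_DATA / "calibration_curves.csv") as p:
        return _read_delimited(p)


def load_calibration_curves() -> dict[str, CalibrationCurve]:
    curves = {}
    for _, row in load_calibration_table().iterrows():
        curves[row["standard"]] = CalibrationCurve(
            analyte=row["standard"],
            wavelength=float(row["wavelength_nm"]),
            slope=float(row["slope"]),
            intercept=float(row["intercept"]),
            r_squared=float(row["r_squared"]),
            lod=float(row["lod_ug_ml"]),
            loq=float(row["loq_ug_ml"]),
        )
    return curves


def load_reported_contents() -> list[QuantRecord]:
    """The 14 reported compound contents (mg/g DW) as quantification records."""
    from .quant import QuantMethod

    with resources.as_file(_DATA / "phenolic_contents.csv") as p:
        df = _read_delimited(p)
    records = []
    for _, row in df.iterrows():
        compound = str(row["compound"])
        method = (
            QuantMethod.EXTERNAL_STANDARD
            if compound in ("Apigenin", "Acacetin", "Luteolin")
            else QuantMethod.RRF
        )
        records.append(
            QuantRecord(
                compound=compound,
                compound_class=class_from_group(str(row["group"])),
                content=float(row["content_mg_per_g"]),
                method=method,
            )
        )
    return records


# ---------------------------------------------------------------- pipeline


@dataclass(frozen=True)
class PipelineConfig:
    """Paths and options steering a full three-stage run.

    Any stage whose input path is None falls back to the packaged
    reference tables; set a path to analyse your own files.
    """

    design_path: str | None = None
    spectra_path: str | None = None
    contents_path: str | None = None
    region: tuple[tuple[float, float], ...] | None = None
    tolerance: float = 0.5
    seed: int = 0


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute design fit + optimization, annotation, and quantification.

    The three stages are independent analyses of their respective inputs;
    the report bundle collects the fitted surface and its optimum, the
    annotation table with class counts, and the per-class content summary.
    Outputs land in ``out_dir`` (surface.json, annotations.tsv,
    quant_report.json/.tsv, report.json).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    design = (
        read_design(config.design_path) if config.design_path else load_extraction_design()
    )
    model = rsm.fit_quadratic(design)
    anova = rsm.anova_table(model, design)
    opt = rsm.optimize_surface(model, region=config.region, factors=design.factors)

    trees = (
        read_spectra(config.spectra_path) if config.spectra_path else load_spectral_trees()
    )
    batch = annotate_batch(trees, tolerance=config.tolerance)
    write_annotations(batch, out_dir / "annotations.tsv", trees)

    if config.contents_path:
        from .quant import QuantMethod

        df = _read_delimited(config.contents_path)
        records = [
            QuantRecord(
                compound=str(r["compound"]),
                compound_class=class_from_group(str(r["group"])),
                content=float(r["content_mg_per_g"]),
                method=QuantMethod.RRF,
            )
            for _, r in df.iterrows()
        ]
    else:
        records = load_reported_contents()
    summary = aggregate_by_class(records)
    provenance = {"config_hash": _config_hash(config), "seed": config.seed}
    write_quant_report(records, summary, out_dir / "quant_report.json", provenance)

    report = {
        "rsm": {
            "r_squared": model.r_squared,
            "model_p_value": model.p_value,
            "coded_optimum": list(opt.coded_opt),
            "uncoded_optimum": list(opt.uncoded_opt),
            "predicted_response_g_gae_per_100g": opt.predicted_response,
            "anova": {
                row: {k: (None if pd.isna(v) else float(v)) for k, v in vals.items()}
                for row, vals in anova.to_dict(orient="index").items()
            },
        },
        "annotation": {
            "n_peaks": len(trees),
            "n_phenolics": batch.n_phenolics,
            "class_counts": batch.class_counts,
        },
        "quantification": {
            "class_totals_mg_per_g_dw": dict(summary.class_totals),
            "total_phenolics_mg_per_g_dw": summary.total_phenolics,
            "top_compound": summary.top_compound,
            "top_content_mg_per_g_dw": summary.top_content,
        },
        "provenance": provenance,
    }
    with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1)
    with open(out_dir / "surface.json", "w", encoding="utf-8") as fh:
        json.dump(report["rsm"], fh, indent=1)
    return report
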