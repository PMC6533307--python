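"""Rule-based identification of phenolics from negative-mode MS^n spectral trees.

Each chromatographic peak carries a deprotonated precursor ([M-H]-), a list
of PDA absorbance maxima, and a hierarchy of fragment ions (MS2, MS3, ...)
with intensities relative to the base peak of their stage. Identification
works the way an analyst reads an ion-trap spectrum at unit resolution:

* neutral losses between parent and product ions are matched against a
  small table of diagnostic moieties (water 18, CO2 44, methyl 15,
  coumaroyl/deoxyhexosyl 146, caffeoyl/hexosyl 162 Da);
* marker ions anchor compound families (m/z 191 for the quinic acid core,
  539 -> 377 for the oleuropein skeleton);
* UV band positions gate the flavone pathway (a band near 330-360 nm plus
  one near 240-280 nm) and are uninformative for aliphatic hydroxy acids.

The cascade applies family detectors in a fixed priority order and the
first one that fires wins, mirroring how aglycone matches take precedence
over generic loss matching. Everything is deterministic: identical trees
always produce identical annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .errors import DuplicatePeakError, MalformedTreeError

__all__ = [
    "CompoundClass",
    "Confidence",
    "FragmentNode",
    "SpectralTree",
    "NeutralLossRule",
    "Annotation",
    "BatchResult",
    "DEFAULT_LOSS_RULES",
    "AGLYCONE_LIBRARY",
    "HYDROXY_FATTY_ACID_MASSES",
    "DEFAULT_TOLERANCE",
    "neutral_losses",
    "match_loss",
    "classify_uv",
    "identify_flavone",
    "identify_quinic_ester",
    "identify_oleuropein_derivative",
    "detect_hydroxy_fatty_acid",
    "annotate",
    "annotate_batch",
]

#: Unit-resolution ion-trap data: nominal masses, half-Dalton window.
DEFAULT_TOLERANCE = 0.5


class CompoundClass(str, Enum):
    HYDROXYBENZOIC = "hydroxybenzoic_acid"
    HYDROXYCINNAMIC = "hydroxycinnamic_acid"
    FLAVONOID = "flavonoid"
    HYDROXY_FATTY_ACID = "hydroxy_fatty_acid"
    UNKNOWN = "unknown"


#: Classes counted as phenolic compounds in summary statistics.
PHENOLIC_CLASSES = frozenset(
    {CompoundClass.HYDROXYBENZOIC, CompoundClass.HYDROXYCINNAMIC, CompoundClass.FLAVONOID}
)


class Confidence(str, Enum):
    STANDARD_MATCHED = "standard_matched"
    DEDUCED = "deduced"
    TENTATIVE_ISOMER = "tentative_isomer"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class FragmentNode:
    """A product ion: m/z, intensity relative to its stage's base peak, children."""

    mz: float
    rel_intensity: float
    children: tuple["FragmentNode", ...] = ()

    def __post_init__(self) -> None:
        if not 0 < self.rel_intensity <= 100:
            raise MalformedTreeError(
                f"fragment m/z {self.mz}: relative intensity must be in (0, 100]"
            )


@dataclass(frozen=True)
class SpectralTree:
    """Precursor ion, UV maxima and the MS^n fragment hierarchy of one peak.

    ``precursor_mz`` may be None for peaks with no usable MS signal; such
    trees always annotate as unknown.
    """

    peak_id: str
    precursor_mz: float | None
    uv_lambda_max: tuple[float, ...] = ()
    retention_time: float | None = None
    fragments: tuple[FragmentNode, ...] = ()

    def __post_init__(self) -> None:
        if self.precursor_mz is None and self.fragments:
            raise MalformedTreeError(
                f"peak {self.peak_id}: fragments present but precursor missing"
            )
        if self.precursor_mz is not None:
            _check_descending(self.peak_id, self.precursor_mz, self.fragments)

    def edges(self) -> Iterator[tuple[float, float]]:
        """All parent -> child ion pairs, starting from the precursor."""
        if self.precursor_mz is None:
            return
        stack = [(self.precursor_mz, f) for f in self.fragments]
        while stack:
            parent_mz, node = stack.pop()
            yield parent_mz, node.mz
            stack.extend((node.mz, c) for c in node.children)

    def walk(self) -> Iterator[tuple[int, FragmentNode]]:
        """Depth-first traversal yielding (MS stage, node); top level is MS2."""
        stack = [(2, f) for f in reversed(self.fragments)]
        while stack:
            level, node = stack.pop()
            yield level, node
            stack.extend((level + 1, c) for c in reversed(node.children))

    def ms2_base_peak(self) -> FragmentNode | None:
        if not self.fragments:
            return None
        return max(self.fragments, key=lambda f: f.rel_intensity)

    def contains_mz(self, mz: float, tol: float = DEFAULT_TOLERANCE) -> bool:
        return any(abs(node.mz - mz) <= tol for _, node in self.walk())


def _check_descending(
    peak_id: str, parent_mz: float, nodes: Iterable[FragmentNode]
) -> None:
    for node in nodes:
        if node.mz >= parent_mz:
            raise MalformedTreeError(
                f"peak {peak_id}: fragment m/z {node.mz} >= parent m/z {parent_mz}"
            )
        _check_descending(peak_id, node.mz, node.children)


@dataclass(frozen=True)
class NeutralLossRule:
    """A diagnostic neutral loss: mass difference, moiety name, match window."""

    delta: float
    moiety: str
    tolerance: float = DEFAULT_TOLERANCE

    def __post_init__(self) -> None:
        if self.delta <= 0 or self.tolerance < 0:
            raise ValueError("loss delta must be > 0 and tolerance >= 0")


DEFAULT_LOSS_RULES: tuple[NeutralLossRule, ...] = (
    NeutralLossRule(15.0, "methyl"),
    NeutralLossRule(18.0, "water"),
    NeutralLossRule(44.0, "carbon dioxide"),
    NeutralLossRule(146.0, "coumaroyl/deoxyhexosyl"),
    NeutralLossRule(162.0, "caffeoyl/hexosyl"),
)

#: Deprotonated flavone aglycones recognized at nominal mass.
AGLYCONE_LIBRARY: dict[float, str] = {
    285.0: "Luteolin",
    269.0: "Apigenin",
    283.0: "Acacetin",
    299.0: "Chrysoeriol",
    329.0: "Tricin",
}

#: Aglycones only accepted when a methyl-loss chain of base peaks confirms
#: the methoxylated skeleton (one -15 stage for chrysoeriol, two for tricin).
_METHYL_CHAIN_REQUIRED: dict[str, int] = {"Chrysoeriol": 1, "Tricin": 2}

#: Aglycones whose identity was settled against authentic standards.
_STANDARD_AGLYCONES = frozenset({"Luteolin", "Apigenin", "Acacetin"})

#: Oxygenated C18 fatty acids at nominal [M-H]- mass. The first entry keeps
#: the published spelling of its name; see the note emitted with it.
HYDROXY_FATTY_ACID_MASSES: dict[float, str] = {
    293.0: "Monohydroxy-octadecaditrienoic acid",
    295.0: "Monohydroxy-octadecadienoic acid",
    297.0: "Monohydroxy-octadecenoic acid",
    309.0: "Dihydroxy-octadecatrienoic acid",
    313.0: "Dihydroxy-octadecenoic acid",
}

_QUINIC_MARKER = 191.0
_QUINIC_SECONDARY = (179.0, 173.0, 135.0)
_OLEUROPEIN_MZ = 539.0
_OLEUROPEIN_CORE = 377.0


@dataclass(frozen=True)
class Annotation:
    """Outcome of the cascade for one peak: name, class, and evidence chain."""

    peak_id: str
    name: str
    compound_class: CompoundClass
    confidence: Confidence
    evidence: tuple[str, ...] = ()
    notes: tuple[str, ...] = ()

    @property
    def is_phenolic(self) -> bool:
        return self.compound_class in PHENOLIC_CLASSES


def _unknown(tree: SpectralTree, why: str) -> Annotation:
    return Annotation(
        peak_id=tree.peak_id,
        name="Unknown",
        compound_class=CompoundClass.UNKNOWN,
        confidence=Confidence.UNKNOWN,
        evidence=(),
        notes=(why,),
    )


def neutral_losses(tree: SpectralTree) -> list[tuple[float, float, float]]:
    """All (parent_mz, child_mz, delta) triples of the tree, delta > 0."""
    out = []
    for parent, child in tree.edges():
        delta = parent - child
        if delta <= 0:
            raise MalformedTreeError(
                f"peak {tree.peak_id}: non-positive loss {parent} -> {child}"
            )
        out.append((parent, child, delta))
    return out


def match_loss(
    delta: float, rules: Sequence[NeutralLossRule] = DEFAULT_LOSS_RULES
) -> str | None:
    """Name of the moiety whose loss best matches ``delta``, or None.

    The nearest rule within its own tolerance wins when windows overlap.
    """
    best: tuple[float, str] | None = None
    for rule in rules:
        gap = abs(delta - rule.delta)
        if gap <= rule.tolerance and (best is None or gap < best[0]):
            best = (gap, rule.moiety)
    return best[1] if best else None


def classify_uv(uv_lambda_max: Sequence[float]) -> set[CompoundClass]:
    """Candidate compound classes compatible with the PDA band positions.

    Heuristic windows inferred from the observed spectra: flavones show a
    band at 330-360 nm (band II... band I) together with one at 240-280 nm;
    hydroxycinnamates absorb at 300-335 nm; hydroxybenzoates keep all bands
    below 330 nm or show the 250/270/320 triple pattern. Aliphatic hydroxy
    fatty acids impose no UV requirement, and an empty band list is
    uninformative, so every class stays candidate.
    """
    bands = tuple(uv_lambda_max)
    if not bands:
        return {c for c in CompoundClass if c is not CompoundClass.UNKNOWN}
    candidates = {CompoundClass.HYDROXY_FATTY_ACID}
    if any(330 <= b <= 360 for b in bands) and any(240 <= b <= 280 for b in bands):
        candidates.add(CompoundClass.FLAVONOID)
    if any(300 <= b <= 335 for b in bands):
        candidates.add(CompoundClass.HYDROXYCINNAMIC)
    triple = all(
        any(abs(b - target) <= 5 for b in bands) for target in (250.0, 270.0, 320.0)
    )
    if all(b < 330 for b in bands) or triple:
        candidates.add(CompoundClass.HYDROXYBENZOIC)
    return candidates


def _aglycone_at(mz: float, tol: float) -> str | None:
    for mass, name in AGLYCONE_LIBRARY.items():
        if abs(mz - mass) <= tol:
            return name
    return None


def _has_methyl_chain(tree: SpectralTree, depth: int, tol: float) -> bool:
    """True if ``depth`` consecutive stages lose 15 Da as base peaks."""
    parent_mz = tree.precursor_mz
    nodes = tree.fragments
    for _ in range(depth):
        if not nodes:
            return False
        base = max(nodes, key=lambda f: f.rel_intensity)
        if abs((parent_mz - base.mz) - 15.0) > tol:
            return False
        parent_mz, nodes = base.mz, base.children
    return True


def identify_flavone(
    tree: SpectralTree,
    aglycone_library: dict[float, str] | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
) -> Annotation | None:
    """Flavone pathway: aglycone precursor match, or a hexosyl loss onto one.

    Only runs when the UV bands admit a flavone. Methoxylated aglycones
    (chrysoeriol, tricin) additionally require their characteristic chain
    of methyl-loss base peaks.
    """
    if tree.precursor_mz is None or not tree.fragments:
        return None
    if CompoundClass.FLAVONOID not in classify_uv(tree.uv_lambda_max):
        return None
    library = AGLYCONE_LIBRARY if aglycone_library is None else aglycone_library

    name = None
    for mass, aglycone in library.items():
        if abs(tree.precursor_mz - mass) <= tolerance:
            name = aglycone
            break
    if name is not None:
        chain = _METHYL_CHAIN_REQUIRED.get(name, 0)
        if chain and not _has_methyl_chain(tree, chain, tolerance):
            return None
        evidence = [f"[M-H]- {tree.precursor_mz:g} matches {name.lower()} aglycone"]
        if chain:
            evidence.append(f"{chain} consecutive 15 Da (methyl) base-peak losses")
        conf = (
            Confidence.STANDARD_MATCHED
            if name in _STANDARD_AGLYCONES
            else Confidence.DEDUCED
        )
        return Annotation(
            tree.peak_id, name, CompoundClass.FLAVONOID, conf, tuple(evidence)
        )

    # Glycoside: a 162 Da (hexosyl) loss landing on a library aglycone.
    for frag in tree.fragments:
        delta = tree.precursor_mz - frag.mz
        if abs(delta - 162.0) <= tolerance:
            aglycone = _aglycone_at(frag.mz, tolerance)
            if aglycone is not None:
                return Annotation(
                    tree.peak_id,
                    f"{aglycone}-O-glucoside",
                    CompoundClass.FLAVONOID,
                    Confidence.DEDUCED,
                    (
                        f"162 Da (hexosyl) loss {tree.precursor_mz:g} -> {frag.mz:g}",
                        f"product ion matches {aglycone.lower()} aglycone",
                    ),
                )
    return None


def _regio_35_pattern(tree: SpectralTree, tol: float) -> bool:
    """MS2 base peak 353 whose own spectrum has base 191 with 179 >= 10%.

    The simplified intensity key separating the 3,5-diacyl regiochemistry
    of quinic acid esters from the other positional isomers.
    """
    base = tree.ms2_base_peak()
    if base is None or abs(base.mz - 353.0) > tol or not base.children:
        return False
    ms3_base = max(base.children, key=lambda f: f.rel_intensity)
    if abs(ms3_base.mz - _QUINIC_MARKER) > tol:
        return False
    return any(
        abs(c.mz - 179.0) <= tol and c.rel_intensity >= 10 for c in base.children
    )


def identify_quinic_ester(
    tree: SpectralTree, tolerance: float = DEFAULT_TOLERANCE
) -> Annotation | None:
    """Acyl quinic acid esters: caffeoyl/coumaroyl losses plus the m/z 191 core.

    The quinic acid marker at m/z 191 (with 179/173/135 satellites) must be
    present somewhere in the tree. Names follow the precursor mass: 499 is
    the mixed caffeoyl/coumaroyl diester, 515 the dicaffeoyl ester (3,5-
    regiochemistry assigned by the MS2/MS3 intensity key), and 533 its
    18-Da-heavier hydrate following the same cascade.
    """
    if tree.precursor_mz is None or not tree.fragments:
        return None
    if not tree.contains_mz(_QUINIC_MARKER, tolerance):
        return None
    prec = tree.precursor_mz
    deltas = [d for _, _, d in neutral_losses(tree)]
    has_coumaroyl = any(abs(d - 146.0) <= tolerance for d in deltas)

    if abs(prec - 499.0) <= tolerance and has_coumaroyl:
        return Annotation(
            tree.peak_id,
            "3-O-Caffeoyl-5-O-p-coumaroylquinic acid",
            CompoundClass.HYDROXYCINNAMIC,
            Confidence.DEDUCED,
            (
                "146 Da (coumaroyl) and 162 Da (caffeoyl) losses from [M-H]- 499",
                "quinic acid marker ion m/z 191",
            ),
        )
    for target, hydrate in ((515.0, False), (533.0, True)):
        if abs(prec - target) <= tolerance:
            if not tree.contains_mz(353.0, tolerance):
                return None
            name = "3,5-Dicaffeoylquinic acid"
            evidence = [
                "two 162 Da (caffeoyl) losses terminating at quinic acid m/z 191",
            ]
            if _regio_35_pattern(tree, tolerance):
                evidence.append(
                    "MS2 base 353 with MS3 base 191 and 179 >= 10% (3,5-diacyl key)"
                )
                confidence = Confidence.DEDUCED
            else:
                name = "Dicaffeoylquinic acid"
                confidence = Confidence.TENTATIVE_ISOMER
            if hydrate:
                name += " monohydrate"
                evidence.append("[M-H]- 18 Da above the anhydrous ester")
            return Annotation(
                tree.peak_id,
                name,
                CompoundClass.HYDROXYCINNAMIC,
                confidence,
                tuple(evidence),
            )
    return None


def identify_oleuropein_derivative(
    tree: SpectralTree, tolerance: float = DEFAULT_TOLERANCE
) -> Annotation | None:
    """Oleuropein esters: acyl loss to m/z 539 whose spectrum loses glucosyl to 377.

    A precursor 30 Da above oleuropein lacking the 539/377 signature is
    reported as a methoxyoleuropein isomer with tentative confidence.
    """
    if tree.precursor_mz is None or not tree.fragments:
        return None
    prec = tree.precursor_mz
    for frag in tree.fragments:
        if abs(frag.mz - _OLEUROPEIN_MZ) > tolerance or not frag.children:
            continue
        core = max(frag.children, key=lambda f: f.rel_intensity)
        if abs(core.mz - _OLEUROPEIN_CORE) > tolerance:
            continue
        acyl = match_loss(prec - frag.mz)
        if acyl and acyl.startswith("coumaroyl"):
            return Annotation(
                tree.peak_id,
                "Coumaroyloleuropein",
                CompoundClass.HYDROXYCINNAMIC,
                Confidence.DEDUCED,
                (
                    f"146 Da (coumaroyl) loss {prec:g} -> 539",
                    "glucosyl cleavage 539 -> 377 (oleuropein skeleton)",
                ),
            )
    if abs(prec - (_OLEUROPEIN_MZ + 30.0)) <= tolerance and not (
        tree.contains_mz(_OLEUROPEIN_MZ, tolerance)
        and tree.contains_mz(_OLEUROPEIN_CORE, tolerance)
    ):
        return Annotation(
            tree.peak_id,
            "Methoxyoleuropein isomer",
            CompoundClass.HYDROXYCINNAMIC,
            Confidence.TENTATIVE_ISOMER,
            ("[M-H]- 30 Da above oleuropein; 539/377 signature absent",),
        )
    return None


def _identify_hydroxybenzoic(
    tree: SpectralTree, tolerance: float = DEFAULT_TOLERANCE
) -> Annotation | None:
    """Special cases keyed to small-acid precursors 187 and 173."""
    prec = tree.precursor_mz
    if prec is None or not tree.fragments:
        return None
    if abs(prec - 187.0) <= tolerance:
        # Gallic acid + 18: water loss to the gallate ion 169, then CO2 to 125.
        if tree.contains_mz(169.0, tolerance) and tree.contains_mz(125.0, tolerance):
            return Annotation(
                tree.peak_id,
                "Gallic acid monohydrate",
                CompoundClass.HYDROXYBENZOIC,
                Confidence.DEDUCED,
                (
                    "[M-H]- 18 Da above gallic acid (169)",
                    "water loss to 169 and CO2 loss to base ion 125",
                ),
            )
    if abs(prec - 173.0) <= tolerance:
        base = tree.ms2_base_peak()
        if base is not None and abs(base.mz - 131.0) <= tolerance:
            return Annotation(
                tree.peak_id,
                "Shikimic acid isomer",
                CompoundClass.HYDROXYBENZOIC,
                Confidence.TENTATIVE_ISOMER,
                (
                    "[M-H]- matches shikimic acid (173)",
                    "MS2 base ion 131 inconsistent with the authentic standard",
                ),
            )
    return None


def _identify_prenyl_coumarate(
    tree: SpectralTree, tolerance: float = DEFAULT_TOLERANCE
) -> Annotation | None:
    """Precursor 453 with a 60 Da loss to the MS2 base ion 393.

    The 60 Da loss is read as two 30 Da methoxy-pair units; the arithmetic
    is chemically loose but kept as the family's published decision rule,
    and the annotation carries a note saying so.
    """
    prec = tree.precursor_mz
    if prec is None or not tree.fragments:
        return None
    if abs(prec - 453.0) > tolerance:
        return None
    base = tree.ms2_base_peak()
    if base is None or abs((prec - base.mz) - 60.0) > tolerance:
        return None
    return Annotation(
        tree.peak_id,
        "Prenyl-dimethoxy-caffeoyl-p-coumaric acid",
        CompoundClass.HYDROXYCINNAMIC,
        Confidence.DEDUCED,
        ("60 Da loss 453 -> base ion 393, read as two methoxy units",),
        notes=("60 Da as two methoxy losses is a loose mass assignment",),
    )


def detect_hydroxy_fatty_acid(
    tree: SpectralTree, tolerance: float = DEFAULT_TOLERANCE
) -> Annotation | None:
    """Oxygenated C18 fatty acids: nominal-mass lookup plus MS2 water loss.

    Fires for precursors in the 290-320 Da window matching the nominal-mass
    table when the MS2 spectrum contains a water loss (consecutive
    dehydration of the aliphatic chain) and the precursor is not a flavone
    aglycone.
    """
    prec = tree.precursor_mz
    if prec is None or not tree.fragments:
        return None
    if not 290.0 <= prec <= 320.0 or _aglycone_at(prec, tolerance) is not None:
        return None
    name = None
    for mass, candidate in HYDROXY_FATTY_ACID_MASSES.items():
        if abs(prec - mass) <= tolerance:
            name = candidate
            break
    if name is None:
        return None
    if not any(
        abs((prec - f.mz) - 18.0) <= tolerance for f in tree.fragments
    ):
        return None
    notes = ()
    if abs(prec - 293.0) <= tolerance:
        notes = ("name kept as published; 'octadecaditrienoic' is likely a typographic variant",)
    return Annotation(
        tree.peak_id,
        name,
        CompoundClass.HYDROXY_FATTY_ACID,
        Confidence.DEDUCED,
        ("consecutive water losses from the aliphatic chain in MS2",),
        notes=notes,
    )


#: The cascade, in priority order; the first detector that fires wins.
_CASCADE = (
    identify_flavone,
    identify_quinic_ester,
    identify_oleuropein_derivative,
    _identify_hydroxybenzoic,
    _identify_prenyl_coumarate,
    detect_hydroxy_fatty_acid,
)


def annotate(tree: SpectralTree, tolerance: float = DEFAULT_TOLERANCE) -> Annotation:
    """Run the full decision cascade on one spectral tree.

    Always returns exactly one Annotation; trees without usable fragments
    or matching no detector come back as unknown.
    """
    if tree.precursor_mz is None or not tree.fragments:
        return _unknown(tree, "no usable MS signal")
    neutral_losses(tree)  # re-validates edge monotonicity
    for detector in _CASCADE:
        if detector is identify_flavone:
            result = detector(tree, None, tolerance)
        else:
            result = detector(tree, tolerance)
        if result is not None:
            return result
    return _unknown(tree, "no identification rule matched")


@dataclass(frozen=True)
class BatchResult:
    """Annotations for a batch of peaks plus per-class counts."""

    annotations: tuple[Annotation, ...]
    class_counts: dict
    n_phenolics: int

    def to_frame(self, trees: Sequence[SpectralTree] | None = None) -> pd.DataFrame:
        rt = {}
        prec = {}
        if trees is not None:
            rt = {t.peak_id: t.retention_time for t in trees}
            prec = {t.peak_id: t.precursor_mz for t in trees}
        rows = [
            {
                "peak_id": a.peak_id,
                "rt_min": rt.get(a.peak_id),
                "precursor_mz": prec.get(a.peak_id),
                "name": a.name,
                "compound_class": a.compound_class.value,
                "confidence": a.confidence.value,
                "evidence": "; ".join(a.evidence),
                "notes": "; ".join(a.notes),
            }
            for a in self.annotations
        ]
        return pd.DataFrame(rows)


def annotate_batch(
    trees: Sequence[SpectralTree], tolerance: float = DEFAULT_TOLERANCE
) -> BatchResult:
    """Annotate every tree and tally compound classes.

    Distinct peaks resolving to the same identified name (positional
    isomers separated in time) receive Roman-numeral suffixes in retention
    order, the way isomer pairs are reported in chromatographic tables.
    """
    ids = [t.peak_id for t in trees]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise DuplicatePeakError(f"duplicate peak ids: {', '.join(dup)}")

    annotations = [annotate(t, tolerance) for t in trees]
    annotations = _suffix_isomers(annotations, trees)

    counts = {c: 0 for c in CompoundClass}
    for a in annotations:
        counts[a.compound_class] += 1
    n_phenolics = sum(counts[c] for c in PHENOLIC_CLASSES)
    return BatchResult(
        annotations=tuple(annotations),
        class_counts={c.value: n for c, n in counts.items()},
        n_phenolics=n_phenolics,
    )


_ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")


def _suffix_isomers(
    annotations: list[Annotation], trees: Sequence[SpectralTree]
) -> list[Annotation]:
    rt = {t.peak_id: (t.retention_time if t.retention_time is not None else 0.0) for t in trees}
    by_name: dict[str, list[int]] = {}
    for i, a in enumerate(annotations):
        if a.compound_class is not CompoundClass.UNKNOWN:
            by_name.setdefault(a.name, []).append(i)
    out = list(annotations)
    for name, idxs in by_name.items():
        if len(idxs) < 2:
            continue
        ordered = sorted(idxs, key=lambda i: rt[annotations[i].peak_id])
        for rank, i in enumerate(ordered):
            a = out[i]
            out[i] = Annotation(
                a.peak_id,
                f"{name} {_ROMAN[rank]}",
                a.compound_class,
                a.confidence,
                a.evidence,
                a.notes,
            )
    return out
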