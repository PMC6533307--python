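"""Neutral-loss matching, UV gating, and the identification cascade."""

import random

import pytest

from phenolprofiler.annotator import (
    AGLYCONE_LIBRARY,
    CompoundClass,
    Confidence,
    DEFAULT_LOSS_RULES,
    FragmentNode,
    NeutralLossRule,
    SpectralTree,
    annotate,
    annotate_batch,
    classify_uv,
    detect_hydroxy_fatty_acid,
    identify_flavone,
    identify_oleuropein_derivative,
    identify_quinic_ester,
    match_loss,
    neutral_losses,
)
from phenolprofiler.errors import DuplicatePeakError, MalformedTreeError


def tree(peak_id, precursor, fragments=(), uv=(), rt=None):
    return SpectralTree(
        peak_id=peak_id,
        precursor_mz=precursor,
        uv_lambda_max=tuple(uv),
        retention_time=rt,
        fragments=tuple(fragments),
    )


def frag(mz, rel=100, children=()):
    return FragmentNode(mz=mz, rel_intensity=rel, children=tuple(children))


# ------------------------------------------------------------ neutral losses


def test_neutral_losses_chained_diester():
    """A 499 -> 353 -> 191 chain shows coumaroyl (146) then caffeoyl (162)."""
    t = tree("c1", 499, [frag(353, 10, [frag(191)])])
    deltas = {round(d) for _, _, d in neutral_losses(t)}
    assert {146, 162} <= deltas


def test_neutral_losses_gallate_pattern(trees_by_id):
    t = trees_by_id["6"]
    deltas = sorted(round(d) for _, _, d in neutral_losses(t))
    assert deltas == [18, 62]
    chained = tree("6h", 187, [frag(169, 6, [frag(125)])])
    assert {18, 44} == {round(d) for _, _, d in neutral_losses(chained)}


def test_neutral_losses_empty_tree():
    assert neutral_losses(tree("x", 300)) == []


def test_mass_monotonicity_all_fixture_trees(spectral_trees):
    for t in spectral_trees:
        assert all(d > 0 for _, _, d in neutral_losses(t))


def test_malformed_tree_rejected():
    with pytest.raises(MalformedTreeError):
        tree("bad", 200, [frag(250)])
    with pytest.raises(MalformedTreeError):
        frag(100, rel=150)


# ---------------------------------------------------------------- match_loss


@pytest.mark.parametrize(
    "delta, expected",
    [
        (146.0, "coumaroyl/deoxyhexosyl"),
        (18.0, "water"),
        (162.3, "caffeoyl/hexosyl"),
        (146.6, None),
        (100.0, None),
    ],
)
def test_match_loss(delta, expected):
    assert match_loss(delta, DEFAULT_LOSS_RULES) == expected


def test_match_loss_nearest_wins_on_overlap():
    rules = (NeutralLossRule(18.0, "water", 2.0), NeutralLossRule(17.0, "ammonia", 2.0))
    assert match_loss(17.9, rules) == "water"
    assert match_loss(17.2, rules) == "ammonia"


# ---------------------------------------------------------------- classify_uv


def test_classify_uv_windows():
    assert CompoundClass.FLAVONOID in classify_uv([250, 340])
    assert CompoundClass.HYDROXYCINNAMIC in classify_uv([240, 330])
    assert CompoundClass.HYDROXYBENZOIC in classify_uv([250, 270, 320])
    assert classify_uv([]) == {
        CompoundClass.FLAVONOID,
        CompoundClass.HYDROXYCINNAMIC,
        CompoundClass.HYDROXYBENZOIC,
        CompoundClass.HYDROXY_FATTY_ACID,
    }


def test_classify_uv_fatty_acids_unconstrained():
    assert CompoundClass.HYDROXY_FATTY_ACID in classify_uv([500.0])


# ------------------------------------------------------------- family rules


def test_hydroxy_fatty_acid_detection(trees_by_id):
    a22 = detect_hydroxy_fatty_acid(trees_by_id["22"])
    assert a22 is not None and a22.name == "Monohydroxy-octadecadienoic acid"
    a20 = detect_hydroxy_fatty_acid(trees_by_id["20"])
    assert a20 is not None and a20.name == "Dihydroxy-octadecatrienoic acid"
    # a flavone aglycone mass never enters the fatty-acid path
    luteolin_like = tree("x", 285, [frag(267)], uv=[250, 350])
    assert detect_hydroxy_fatty_acid(luteolin_like) is None


def test_quinic_ester_identification(trees_by_id):
    a5 = identify_quinic_ester(trees_by_id["5"])
    assert a5 is not None and a5.name == "3,5-Dicaffeoylquinic acid"
    assert a5.compound_class is CompoundClass.HYDROXYCINNAMIC
    a4 = identify_quinic_ester(trees_by_id["4"])
    assert a4 is not None and a4.name == "3,5-Dicaffeoylquinic acid monohydrate"
    no_marker = tree("x", 515, [frag(353)])
    assert identify_quinic_ester(no_marker) is None


def test_flavone_identification(trees_by_id):
    a3 = identify_flavone(trees_by_id["3"])
    assert a3 is not None and a3.name == "Luteolin-O-glucoside"
    a13 = identify_flavone(trees_by_id["13"])
    assert a13 is not None and a13.name == "Tricin"
    stranger = tree("x", 271, [frag(200)], uv=[250, 340])
    assert identify_flavone(stranger) is None


def test_flavone_requires_methyl_chain_for_methoxylated_aglycones():
    # precursor at the chrysoeriol mass but no 15 Da base-peak loss
    t = tree("x", 299, [frag(255)], uv=[250, 330])
    assert identify_flavone(t) is None


def test_standard_matched_confidence(trees_by_id):
    assert annotate(trees_by_id["9"]).confidence is Confidence.STANDARD_MATCHED
    assert annotate(trees_by_id["12"]).confidence is Confidence.DEDUCED


def test_oleuropein_derivatives(trees_by_id):
    a2 = identify_oleuropein_derivative(trees_by_id["2"])
    assert a2 is not None and a2.name == "Coumaroyloleuropein"
    a8 = identify_oleuropein_derivative(trees_by_id["8"])
    assert a8 is not None and a8.name == "Methoxyoleuropein isomer"
    assert a8.confidence is Confidence.TENTATIVE_ISOMER
    plain = tree("x", 685, [frag(500)])
    assert identify_oleuropein_derivative(plain) is None


# ------------------------------------------------------------------ cascade


def test_annotate_hydroxybenzoic_specials(trees_by_id):
    a6 = annotate(trees_by_id["6"])
    assert a6.name == "Gallic acid monohydrate"
    assert a6.compound_class is CompoundClass.HYDROXYBENZOIC
    a7 = annotate(trees_by_id["7"])
    assert a7.name == "Shikimic acid isomer"
    assert a7.confidence is Confidence.TENTATIVE_ISOMER


def test_annotate_unknowns(trees_by_id):
    a14 = annotate(trees_by_id["14"])
    assert a14.compound_class is CompoundClass.UNKNOWN
    empty = tree("e", None)
    assert annotate(empty).name == "Unknown"


def test_unknown_iff_unnamed(spectral_trees):
    for a in annotate_batch(spectral_trees).annotations:
        assert (a.compound_class is CompoundClass.UNKNOWN) == (a.name == "Unknown")
        if a.compound_class is not CompoundClass.UNKNOWN:
            assert a.evidence


def test_batch_reproduces_published_table(spectral_trees, reference_annotations):
    """All 23 peaks resolve to the published names and class tallies."""
    batch = annotate_batch(spectral_trees)
    assert batch.n_phenolics == 14
    counts = batch.class_counts
    assert counts["hydroxybenzoic_acid"] == 2
    assert counts["hydroxycinnamic_acid"] == 6
    assert counts["flavonoid"] == 6
    assert counts["hydroxy_fatty_acid"] == 6
    assert counts["unknown"] == 3
    for a in batch.annotations:
        ref_name, ref_class = reference_annotations[a.peak_id]
        assert a.name == ref_name, a.peak_id
        assert a.compound_class is ref_class, a.peak_id


def test_batch_order_independent(spectral_trees):
    shuffled = list(spectral_trees)
    random.Random(5).shuffle(shuffled)
    by_id = {a.peak_id: a for a in annotate_batch(shuffled).annotations}
    reference = {a.peak_id: a for a in annotate_batch(spectral_trees).annotations}
    assert by_id == reference


def test_batch_empty_and_duplicates(spectral_trees):
    empty = annotate_batch([])
    assert empty.n_phenolics == 0 and not empty.annotations
    with pytest.raises(DuplicatePeakError):
        annotate_batch([spectral_trees[0], spectral_trees[0]])


def test_isomer_suffixing_in_retention_order(trees_by_id):
    pair = [trees_by_id["21"], trees_by_id["20"]]  # deliberately out of rt order
    names = {a.peak_id: a.name for a in annotate_batch(pair).annotations}
    assert names["20"] == "Dihydroxy-octadecatrienoic acid I"
    assert names["21"] == "Dihydroxy-octadecatrienoic acid II"


def test_annotation_never_cites_loss_exceeding_precursor(spectral_trees):
    for t in spectral_trees:
        if t.precursor_mz is None:
            continue
        for parent, child, delta in neutral_losses(t):
            assert delta < t.precursor_mz
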