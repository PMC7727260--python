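"""Comparative-Ct arithmetic, splicing efficiency, RT-PCR amplifiability."""

import pytest
from hypothesis import given, settings, strategies as st

from mitoedit.simulate import planted_splicing_abundances, simulate_qpcr
from mitoedit.splicing import (
    CtRecord,
    GeneModel,
    Segment,
    amplifiability_pattern,
    ct_records_from_frame,
    nad1_model,
    nad4_model,
    read_gene_models_tsv,
    relative_expression,
    rt_pcr_products,
    splicing_efficiency,
    write_gene_models_tsv,
)

cts = st.floats(10, 35, allow_nan=False)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(a=cts, b=cts)
def test_self_comparison_identity(a, b):
    assert relative_expression(a, b, a, b) == pytest.approx(1.0)


@pytest.mark.parametrize(
    "ddct,expected", [(0.0, 1.0), (-9.0, 512.0), (1.0, 0.5)]
)
def test_fold_change_from_ddct(ddct, expected):
    # arrange Ct values so (t_test - r_test) - (t_ctrl - r_ctrl) = ddct
    assert relative_expression(20 + ddct, 20, 25, 25) == pytest.approx(expected)


def test_replicates_averaged_before_differencing():
    fold = relative_expression([19, 20, 21], [20, 20, 20], [25, 25], [25.0])
    assert fold == pytest.approx(1.0)


def _ct(sample, amplicon, ct, role="target"):
    return CtRecord(sample, amplicon, (ct,), role)


def test_identical_ct_gives_unit_ratio():
    result = splicing_efficiency(
        spliced=[_ct("WT", "s", 22), _ct("mut", "s", 22)],
        unspliced=[_ct("WT", "u", 25), _ct("mut", "u", 25)],
        reference=[_ct("WT", "actin", 18, "reference"), _ct("mut", "actin", 18, "reference")],
        mutant_sample="mut",
        wt_sample="WT",
    )
    assert result.ratio == pytest.approx(1.0)
    assert result.efficiency_wt == pytest.approx(2 ** 3)


def test_two_cycle_spliced_shift_quarters_the_ratio():
    result = splicing_efficiency(
        spliced=[_ct("WT", "s", 22), _ct("mut", "s", 24)],
        unspliced=[_ct("WT", "u", 25), _ct("mut", "u", 25)],
        reference=[_ct("WT", "actin", 18, "reference"), _ct("mut", "actin", 18, "reference")],
        mutant_sample="mut",
        wt_sample="WT",
    )
    assert result.ratio == pytest.approx(0.25)


def test_constant_ct_offset_cancels_within_sample():
    """Shifting every Ct of one sample (e.g. input amount) leaves its efficiency."""
    base = splicing_efficiency(
        spliced=[_ct("WT", "s", 22), _ct("mut", "s", 23)],
        unspliced=[_ct("WT", "u", 25), _ct("mut", "u", 24)],
        reference=[_ct("WT", "actin", 18, "reference"), _ct("mut", "actin", 18, "reference")],
        mutant_sample="mut",
        wt_sample="WT",
    )
    shifted = splicing_efficiency(
        spliced=[_ct("WT", "s", 22), _ct("mut", "s", 23 + 1.7)],
        unspliced=[_ct("WT", "u", 25), _ct("mut", "u", 24 + 1.7)],
        reference=[_ct("WT", "actin", 18, "reference"), _ct("mut", "actin", 18 + 1.7, "reference")],
        mutant_sample="mut",
        wt_sample="WT",
    )
    assert shifted.efficiency_mut == pytest.approx(base.efficiency_mut)
    assert shifted.ratio == pytest.approx(base.ratio)


def test_missing_unspliced_amplicon_points_to_amplifiability():
    with pytest.raises(KeyError, match="rt_pcr_products"):
        splicing_efficiency(
            spliced=[_ct("WT", "s", 22), _ct("mut", "s", 22)],
            unspliced=[_ct("WT", "u", 25)],
            reference=[_ct("WT", "actin", 18, "reference"), _ct("mut", "actin", 18, "reference")],
            mutant_sample="mut",
            wt_sample="WT",
        )


@pytest.mark.parametrize("ratio", [0.25, 1.0, 3.0])
def test_round_trip_with_noise_free_qpcr_generator(ratio):
    """simulate_qpcr with a planted ratio r is recovered to floating precision."""
    abundances = planted_splicing_abundances({("nad4", 1): ratio})
    table = simulate_qpcr(abundances, ct_noise_sd=0.0, seed=0)
    records = ct_records_from_frame(table)
    by_amp = {}
    for rec in records:
        by_amp.setdefault(rec.amplicon_id, []).append(rec)
    result = splicing_efficiency(
        by_amp["nad4_intron1_spliced"],
        by_amp["nad4_intron1_unspliced"],
        by_amp["actin"],
        mutant_sample="mut",
        wt_sample="WT",
    )
    assert result.ratio == pytest.approx(ratio)


# ---------------------------------------------------------------------------
# Gene models and RT-PCR product classes


def test_nad1_exon1_exon2_spans_trans_intron():
    products = rt_pcr_products(nad1_model(), ("exon", 1), ("exon", 2))
    assert products == {"mature_spliced"}


def test_nad4_exon1_exon2_spans_cis_intron():
    products = rt_pcr_products(nad4_model(), ("exon", 1), ("exon", 2))
    assert products == {"mature_spliced", "unspliced_precursor"}


def test_same_exon_anchors_identical_products():
    products = rt_pcr_products(nad1_model(), ("exon", 3), ("exon", 3))
    assert products == {"mature_spliced", "unspliced_precursor"}


def test_reversed_anchors_rejected():
    with pytest.raises(ValueError, match="upstream"):
        rt_pcr_products(nad1_model(), ("exon", 3), ("exon", 1))


def test_intron_anchor_cannot_amplify_mature_transcript():
    # primer inside nad1 intron 2 (cis): only the precursor template exists
    assert rt_pcr_products(nad1_model(), ("intron", 2), ("exon", 3)) == {
        "unspliced_precursor"
    }
    # primer inside a trans intron: no contiguous template at all
    assert rt_pcr_products(nad1_model(), ("intron", 1), ("exon", 2)) == {"none"}


def test_packaged_models_reproduce_amplifiability_pattern():
    """nad1 introns 1/3/4 (trans) are precursor-silent; nad1 intron 2 and all
    three nad4 introns (cis) show the unspliced band."""
    assert amplifiability_pattern(nad1_model()) == {1: False, 2: True, 3: False, 4: False}
    assert amplifiability_pattern(nad4_model()) == {1: True, 2: True, 3: True}
    assert [i.splice_mode for i in nad1_model().introns] == ["trans", "cis", "trans", "trans"]
    assert [i.splice_mode for i in nad4_model().introns] == ["cis", "cis", "cis"]


def test_gene_model_validation():
    with pytest.raises(ValueError, match="start and end with an exon"):
        GeneModel("g", (Segment("intron", 1, 10, "cis"),))
    with pytest.raises(ValueError, match="alternate"):
        GeneModel("g", (Segment("exon", 1, 10), Segment("exon", 2, 10)))
    with pytest.raises(ValueError, match="splice_mode"):
        Segment("intron", 1, 10, None)
    with pytest.raises(ValueError, match="indices"):
        GeneModel(
            "g",
            (Segment("exon", 1, 10), Segment("intron", 2, 10, "cis"), Segment("exon", 2, 10)),
        )


def test_gene_model_tsv_round_trip(tmp_path):
    path = tmp_path / "models.tsv"
    write_gene_models_tsv([nad1_model(), nad4_model()], path)
    models = read_gene_models_tsv(path)
    assert models["nad1"] == nad1_model()
    assert models["nad4"] == nad4_model()


def test_ct_record_validation():
    with pytest.raises(ValueError, match="replicate"):
        CtRecord("s", "a", ())
    with pytest.raises(ValueError, match="positive"):
        CtRecord("s", "a", (0.0,))
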