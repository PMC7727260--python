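"""Editing statistic, threshold/overlap caller, strong flags, consequences."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mitoedit.editing import (
    DifferentialEditing,
    annotate_editing_consequence,
    call_differential_sites,
    classify_deltas,
    editing_percentage,
    strong_reduction,
)
from mitoedit.sites import EditingSite

WT = ("WT-1", "WT-2")
MUT = ("mut-1", "mut-2")


@pytest.mark.parametrize(
    "n_T,n_C,expected",
    [
        (0, 50, 0.0),
        (25, 25, 50.0),
        (5, 95, 5.0),  # the atp8-123 efficiency in the dek55-2 library
        (242, 758, 24.2),  # the nad4-77 efficiency in the dek55-1 library
    ],
)
def test_editing_percentage_values(n_T, n_C, expected):
    assert editing_percentage(n_T, n_C) == pytest.approx(expected)


def test_editing_percentage_low_coverage_is_undefined():
    assert editing_percentage(3, 4, min_depth=10) is None
    assert editing_percentage(3, 4, min_depth=0) == pytest.approx(300 / 7)


def test_editing_percentage_other_bases_never_enter():
    # n_other is simply not an argument; T+C defines the denominator
    assert editing_percentage(10, 30) == pytest.approx(25.0)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    n_T=st.integers(0, 1000),
    n_C=st.integers(0, 1000),
    k=st.integers(1, 50),
)
def test_editing_percentage_scale_invariant(n_T, n_C, k):
    base = editing_percentage(n_T, n_C, min_depth=1)
    scaled = editing_percentage(k * n_T, k * n_C, min_depth=1)
    if base is None:
        assert scaled is None
    else:
        assert scaled == pytest.approx(base)


def _table(wt1, wt2, mut1, mut2, site="s1"):
    return pd.DataFrame(
        {"WT-1": [wt1], "WT-2": [wt2], "mut-1": [mut1], "mut-2": [mut2]},
        index=pd.Index([site], name="site_id"),
        dtype=float,
    )


@pytest.mark.parametrize(
    "deltas,expected",
    [
        ((-12, -15, -11, -20), "decreased"),
        ((-12, -12, -12, -8), "unchanged"),  # overlap fails in one comparison
        ((-10, -10, -10, -10), "decreased"),  # inclusive boundary
        ((12, 12, -12, 12), "unchanged"),  # mixed direction
        ((10, 10, 10, 10), "increased"),  # inclusive boundary, upward
        ((float("nan"), -12, -12, -12), "low_coverage"),
    ],
)
def test_overlap_rule_on_delta_tuples(deltas, expected):
    """A site is affected only when all four mutant-vs-WT deltas agree."""
    assert classify_deltas(deltas) == expected


def test_overlap_rule_through_efficiency_table():
    # deltas (m1-w1, m1-w2, m2-w1, m2-w2) = (-12, -17, -11, -16): all <= -10
    out = call_differential_sites(_table(50, 55, 38, 39), WT, MUT)
    assert out["call"].iloc[0] == "decreased"
    assert [out[f"delta_{i}"].iloc[0] for i in range(1, 5)] == [-12, -17, -11, -16]
    # one comparison short of the threshold -> unchanged
    out = call_differential_sites(_table(50, 46, 38, 39), WT, MUT)
    assert out["call"].iloc[0] == "unchanged"


def test_low_coverage_propagates():
    out = call_differential_sites(_table(50, 50, np.nan, 20), WT, MUT)
    assert out["call"].iloc[0] == "low_coverage"


def test_duplicated_site_ids_rejected():
    table = pd.concat([_table(50, 50, 30, 30), _table(50, 50, 30, 30)])
    with pytest.raises(ValueError, match="duplicated"):
        call_differential_sites(table, WT, MUT)


@st.composite
def efficiency_tables(draw):
    n = draw(st.integers(1, 8))
    data = {
        lib: draw(
            st.lists(st.floats(0, 100, allow_nan=False), min_size=n, max_size=n)
        )
        for lib in (*WT, *MUT)
    }
    return pd.DataFrame(data, index=pd.Index([f"s{i}" for i in range(n)], name="site_id"))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(table=efficiency_tables(), t_lo=st.floats(1, 30), t_hi=st.floats(1, 30))
def test_threshold_monotonicity(table, t_lo, t_hi):
    """Raising the threshold never turns an unchanged site into an affected one."""
    lo, hi = sorted((t_lo, t_hi))
    calls_lo = call_differential_sites(table, WT, MUT, threshold=lo)["call"]
    calls_hi = call_differential_sites(table, WT, MUT, threshold=hi)["call"]
    affected_lo = set(calls_lo[calls_lo.isin(["decreased", "increased"])].index)
    affected_hi = set(calls_hi[calls_hi.isin(["decreased", "increased"])].index)
    assert affected_hi <= affected_lo


@settings(max_examples=60, deadline=None, derandomize=True)
@given(table=efficiency_tables())
def test_mutant_wt_symmetry(table):
    """Swapping mutant and WT roles maps decreased <-> increased exactly."""
    forward = call_differential_sites(table, WT, MUT)["call"]
    swapped = call_differential_sites(table, MUT, WT)["call"]
    flip = {"decreased": "increased", "increased": "decreased"}
    assert (swapped == forward.map(lambda c: flip.get(c, c))).all()


@pytest.mark.parametrize(
    "wt,mut,expected",
    [
        (60.0, 24.2, True),  # more than 50% lower
        (60.0, 30.0, False),  # exactly 50% is not "more than"
        (10.0, 0.0, True),
    ],
)
def test_strong_reduction_rule(wt, mut, expected):
    assert strong_reduction(wt, mut) is expected


def test_strong_reduction_zero_wt_warns():
    with pytest.warns(UserWarning):
        assert strong_reduction(0.0, 0.0) is False


def test_strong_flags_use_mean_of_wt_libraries():
    out = call_differential_sites(_table(80, 40, 25, 35), WT, MUT)
    # WT mean 60: mut-1 at 25 (< 30) flagged, mut-2 at 35 not
    assert bool(out["strong_mut1"].iloc[0]) is True
    assert bool(out["strong_mut2"].iloc[0]) is False


# ---------------------------------------------------------------------------
# Codon consequences of editing


def _site(position, cds_offset=1, name="g-1"):
    return EditingSite(name, "g", position, cds_offset=cds_offset)


@pytest.mark.parametrize(
    "cds,pos,ref_codon,edited_codon,aa_before,aa_after,stop,syn",
    [
        ("ATGTCAGGG", 5, "TCA", "TTA", "S", "L", False, False),
        ("ATGCAAGGG", 4, "CAA", "TAA", "Q", "*", True, False),
        ("ATGCCCGGG", 6, "CCC", "CCT", "P", "P", False, True),
    ],
)
def test_editing_consequences(cds, pos, ref_codon, edited_codon, aa_before, aa_after, stop, syn):
    result = annotate_editing_consequence(cds, _site(pos))
    assert (result.ref_codon, result.edited_codon) == (ref_codon, edited_codon)
    assert (result.aa_before, result.aa_after) == (aa_before, aa_after)
    assert result.creates_stop is stop
    assert result.synonymous is syn


def test_site_upstream_of_cds_is_non_coding():
    result = annotate_editing_consequence("ATGAAA", _site(2, cds_offset=10))
    assert result.coding is False
    assert result.codon_index is None


def test_non_c_reference_base_rejected():
    with pytest.raises(ValueError, match="expected 'C'"):
        annotate_editing_consequence("ATGAAA", _site(1))


# ---------------------------------------------------------------------------
# Model / results surface


def test_model_fit_from_counts_and_summary(planted_small):
    config, expected = planted_small
    from _helpers import fit_planted

    results = fit_planted(config)
    assert results.calls.to_dict() == expected
    text = results.summary()
    assert "decreased" in text and str(results.n_decreased) in text


def test_model_from_efficiency_table_matches_direct_call():
    table = pd.concat(
        [_table(50, 50, 30, 30, "down"), _table(50, 50, 75, 75, "up")]
    )
    results = DifferentialEditing.from_efficiency_table(table).fit()
    assert results.calls.to_dict() == {"down": "decreased", "up": "increased"}
    assert results.n_affected == 2


def test_model_rejects_single_wt_library():
    with pytest.raises(ValueError, match="exactly two"):
        DifferentialEditing(
            pd.DataFrame(columns=["site_id", "library", "n_C", "n_T"]),
            wt_libraries=("WT-1",),
        )
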