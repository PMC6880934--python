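"""Fusion merging, filter cascade, driver scavenge, partner annotation."""

import numpy as np
import pandas as pd
import pytest

from pdxharmonizer import ValidationError
from pdxharmonizer.fusion_consensus import (ReferenceLists, annotate_partners,
                                            consensus_fusions, filter_fusions,
                                            merge_callers, scavenge_drivers)


def call(model="M1", hist="NBL", caller="starfusion", g5="A", g3="B",
         frame="in-frame", rt=False):
    return {"model_id": model, "histology": hist, "caller": caller,
            "gene5": g5, "gene3": g3, "frame": frame, "read_through": rt,
            "breakpoint5": "chr1:100", "breakpoint3": "chr2:200"}


def calls_frame(rows):
    return pd.DataFrame(rows)


def tpm_matrix(genes, models=("M1", "M2"), value=10.0):
    return pd.DataFrame(value, index=pd.Index(genes, name="gene"),
                        columns=list(models))


EMPTY_REFS = ReferenceLists()


# --------------------------------------------------------------------- merge

def test_merge_aggregates_caller_support():
    rows = [call(caller=c) for c in ("starfusion", "defuse", "soapfuse")]
    merged = merge_callers(calls_frame(rows))
    assert len(merged) == 1
    assert merged.loc[0, "n_callers"] == 3
    assert merged.loc[0, "callers"] == frozenset(
        {"starfusion", "defuse", "soapfuse"})


def test_merge_collapses_duplicate_rows_from_one_caller():
    merged = merge_callers(calls_frame([call(), call()]))
    assert len(merged) == 1 and merged.loc[0, "n_callers"] == 1


def test_merge_preserves_gene_orientation():
    merged = merge_callers(calls_frame([call(g5="A", g3="B"),
                                        call(g5="B", g3="A")]))
    assert len(merged) == 2


def test_merge_frame_is_in_frame_if_any_caller_says_so():
    merged = merge_callers(calls_frame([call(frame="frameshift"),
                                        call(caller="defuse", frame="in-frame")]))
    assert merged.loc[0, "frame"] == "in-frame"


def test_merge_rejects_unknown_caller():
    with pytest.raises(ValidationError, match="caller"):
        merge_callers(calls_frame([call(caller="arriba")]))


def test_merged_count_matches_distinct_triple_oracle():
    rng = np.random.default_rng(21)
    callers = ("starfusion", "fusioncatcher", "defuse", "soapfuse")
    rows = [call(model=f"M{rng.integers(5)}",
                 caller=callers[rng.integers(4)],
                 g5=f"G{rng.integers(8)}", g3=f"H{rng.integers(8)}")
            for _ in range(300)]
    df = calls_frame(rows)
    merged = merge_callers(df)
    distinct = df[["model_id", "gene5", "gene3"]].drop_duplicates()
    assert len(merged) == len(distinct)


# ------------------------------------------------------------- filter cascade

def test_two_caller_singleton_retained():
    rows = [call(caller="starfusion"), call(caller="defuse")]
    merged = merge_callers(calls_frame(rows))
    res = filter_fusions(merged, tpm_matrix(["A", "B"]), EMPTY_REFS)
    assert len(res.high_confidence) == 1 and len(res.audit) == 0


def test_single_caller_singleton_removed_for_support():
    merged = merge_callers(calls_frame([call()]))
    res = filter_fusions(merged, tpm_matrix(["A", "B"]), EMPTY_REFS)
    assert len(res.high_confidence) == 0
    assert res.audit.loc[0, "reason"] == "recurrence/support"


def test_recurrent_in_histology_retained_with_single_caller_support():
    rows = [call(model="M1"), call(model="M2")]
    merged = merge_callers(calls_frame(rows))
    res = filter_fusions(merged, tpm_matrix(["A", "B"]), EMPTY_REFS)
    assert len(res.high_confidence) == 2


def test_promiscuous_partner_rescues_out_of_frame_fusions():
    rows = [call(model="M1", g5="P", g3="Q1", frame="frameshift"),
            call(model="M2", g5="P", g3="Q2", frame="frameshift")]
    merged = merge_callers(calls_frame(rows))
    res = filter_fusions(merged, tpm_matrix(["P", "Q1", "Q2"]), EMPTY_REFS)
    assert len(res.high_confidence) == 2


def test_cross_histology_pair_removed():
    rows = [call(model="M1", hist="NBL", caller="starfusion"),
            call(model="M1", hist="NBL", caller="defuse"),
            call(model="M2", hist="OS", caller="starfusion"),
            call(model="M2", hist="OS", caller="defuse")]
    merged = merge_callers(calls_frame(rows))
    res = filter_fusions(merged, tpm_matrix(["A", "B"]), EMPTY_REFS)
    assert len(res.high_confidence) == 0
    assert set(res.audit["reason"]) == {"cross-histology"}


def test_unexpressed_pair_removed():
    rows = [call(caller="starfusion"), call(caller="defuse")]
    merged = merge_callers(calls_frame(rows))
    res = filter_fusions(merged, tpm_matrix(["A", "B"], value=0.3), EMPTY_REFS)
    assert res.audit.loc[0, "reason"] == "expression"


def test_one_expressed_partner_is_enough():
    rows = [call(caller="starfusion"), call(caller="defuse")]
    merged = merge_callers(calls_frame(rows))
    tpm = tpm_matrix(["A", "B"], value=0.3)
    tpm.loc["A", "M2"] = 5.0    # expressed in another model counts
    res = filter_fusions(merged, tpm, EMPTY_REFS)
    assert len(res.high_confidence) == 1


def test_gene_missing_from_quantification_counts_as_unexpressed():
    rows = [call(caller="starfusion"), call(caller="defuse")]
    merged = merge_callers(calls_frame(rows))
    res = filter_fusions(merged, tpm_matrix(["OTHER"]), EMPTY_REFS)
    assert res.audit.loc[0, "reason"] == "expression"


def test_read_through_removed():
    rows = [call(caller="starfusion", rt=True), call(caller="defuse", rt=True)]
    merged = merge_callers(calls_frame(rows))
    res = filter_fusions(merged, tpm_matrix(["A", "B"]), EMPTY_REFS)
    assert res.audit.loc[0, "reason"] == "read_through"


def test_gtex_normal_pair_removed():
    refs = ReferenceLists(gtex_normal_fusions={("A", "B")})
    rows = [call(caller="starfusion"), call(caller="defuse")]
    merged = merge_callers(calls_frame(rows))
    res = filter_fusions(merged, tpm_matrix(["A", "B"]), refs)
    assert res.audit.loc[0, "reason"] == "gtex_normal"


def test_missing_tpm_with_expression_filter_is_config_error():
    from pdxharmonizer import ConfigurationError
    merged = merge_callers(calls_frame([call()]))
    with pytest.raises(ConfigurationError):
        filter_fusions(merged, None, EMPTY_REFS)


# ------------------------------------------------------------------- scavenge

def test_driver_restored_after_removal():
    refs = ReferenceLists(driver_fusions={("EWSR1", "FLI1")})
    merged = merge_callers(calls_frame(
        [call(g5="EWSR1", g3="FLI1", frame="unknown")]))
    filtered = filter_fusions(merged, tpm_matrix(["EWSR1", "FLI1"]), refs)
    assert len(filtered.high_confidence) == 0
    final = scavenge_drivers(merged, filtered, refs)
    assert len(final.high_confidence) == 1
    assert final.high_confidence.loc[0, "provenance"] == "driver_scavenge"
    assert len(final.audit) == 0


def test_empty_driver_list_is_identity():
    merged = merge_callers(calls_frame([call(), call(caller="defuse")]))
    filtered = filter_fusions(merged, tpm_matrix(["A", "B"]), EMPTY_REFS)
    final = scavenge_drivers(merged, filtered, EMPTY_REFS)
    pd.testing.assert_frame_equal(
        final.high_confidence.drop(columns="provenance"),
        filtered.high_confidence)


def test_driver_retained_by_filters_appears_once_flagged_both_ways():
    refs = ReferenceLists(driver_fusions={("A", "B")})
    merged = merge_callers(calls_frame([call(), call(caller="defuse")]))
    filtered = filter_fusions(merged, tpm_matrix(["A", "B"]), refs)
    final = scavenge_drivers(merged, filtered, refs)
    assert len(final.high_confidence) == 1
    assert final.high_confidence.loc[0, "provenance"] == "filters+driver"


# ----------------------------------------------------------------- annotation

def test_partner_annotation_matches_membership_oracle():
    rng = np.random.default_rng(31)
    genes = [f"G{i}" for i in range(20)]
    refs = ReferenceLists(oncogenes=set(genes[:5]), kinases=set(genes[5:9]),
                          transcription_factors=set(genes[9:14]))
    rows = [call(g5=genes[rng.integers(20)], g3=genes[rng.integers(20)],
                 model=f"M{i}") for i in range(30)]
    final = merge_callers(calls_frame(rows))
    annotated = annotate_partners(final, refs)
    for suffix in ("5", "3"):
        for col, ref in (("oncogene", refs.oncogenes),
                         ("kinase", refs.kinases),
                         ("tf", refs.transcription_factors)):
            expected = [g.upper() in ref for g in annotated[f"gene{suffix}"]]
            assert list(annotated[f"{col}{suffix}"]) == expected


def test_empty_annotation_sets_give_all_false():
    final = merge_callers(calls_frame([call()]))
    annotated = annotate_partners(final, EMPTY_REFS)
    flags = annotated[[c for c in annotated.columns
                       if c.startswith(("oncogene", "kinase", "tf"))]]
    assert not flags.to_numpy().any()


# ----------------------------------------------------- properties & invariants

def test_every_input_fusion_accounted_for(bundle):
    res = consensus_fusions(bundle.fusion_calls, bundle.tpm)
    n = len(res["high_confidence"]) + len(res["audit"])
    assert n == len(res["merged"])
    key_cols = ["model_id", "gene5", "gene3"]
    final_keys = set(map(tuple, res["high_confidence"][key_cols].to_numpy()))
    audit_keys = set(map(tuple, res["audit"][key_cols].to_numpy()))
    merged_keys = set(map(tuple, res["merged"][key_cols].to_numpy()))
    assert final_keys | audit_keys == merged_keys
    assert final_keys.isdisjoint(audit_keys)


def test_planted_truth_recovered_exactly(bundle):
    res = consensus_fusions(bundle.fusion_calls, bundle.tpm)
    gt = bundle.ground_truth.fusions
    final = set(map(tuple, res["high_confidence"][
        ["model_id", "gene5", "gene3"]].to_numpy()))
    expected = set(map(tuple, gt.loc[gt["expected_in_final"],
                                     ["model_id", "gene5", "gene3"]].to_numpy()))
    assert final == expected


def test_enlarging_driver_list_never_shrinks_final_set(bundle):
    base = consensus_fusions(bundle.fusion_calls, bundle.tpm,
                             refs=ReferenceLists())
    merged = base["merged"]
    some_removed = merged.merge(base["audit"][["model_id", "gene5", "gene3"]])
    bigger = ReferenceLists(driver_fusions={
        (r.gene5, r.gene3) for r in some_removed.head(3).itertuples()})
    grown = consensus_fusions(bundle.fusion_calls, bundle.tpm, refs=bigger)
    assert len(grown["high_confidence"]) >= len(base["high_confidence"])


def test_raising_min_tpm_never_grows_final_set(bundle):
    lo = consensus_fusions(bundle.fusion_calls, bundle.tpm,
                           refs=ReferenceLists(), min_tpm=0.5)
    hi = consensus_fusions(bundle.fusion_calls, bundle.tpm,
                           refs=ReferenceLists(), min_tpm=100.0)
    assert len(hi["high_confidence"]) <= len(lo["high_confidence"])


def test_final_set_invariant_to_input_row_order(bundle):
    shuffled = bundle.fusion_calls.sample(frac=1.0, random_state=13)
    a = consensus_fusions(bundle.fusion_calls, bundle.tpm)
    b = consensus_fusions(shuffled, bundle.tpm)
    key = ["model_id", "gene5", "gene3"]
    assert (set(map(tuple, a["high_confidence"][key].to_numpy()))
            == set(map(tuple, b["high_confidence"][key].to_numpy())))
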