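"""Breakpoint counting, HBD flags, focal events, exon FPKM."""

import numpy as np
import pandas as pd
import pytest

from pdxharmonizer import ValidationError
from pdxharmonizer.copy_number import (call_focal_events, call_hbd,
                                       count_breakpoints, exon_fpkm,
                                       flag_exon_deletion)


def seg_rows(model, chrom, lrrs, length=1_000_000):
    """Contiguous equal-width segments with the given LRR sequence."""
    n = len(lrrs)
    edges = np.linspace(0, length, n + 1, dtype=int)
    return pd.DataFrame({
        "model_id": model, "chrom": chrom,
        "start": edges[:-1] + 1, "end": edges[1:],
        "num_probes": 50, "lrr": lrrs,
    })


def breakpoint_scan_oracle(segments, change_fraction=0.10):
    """Independent exhaustive adjacent-pair scan on the linear scale."""
    counts = {}
    autosomes = {str(i) for i in range(1, 23)}
    for (model, chrom), grp in segments.groupby(["model_id", "chrom"]):
        c = str(chrom).removeprefix("chr")
        if c not in autosomes:
            continue
        lrrs = grp.sort_values("start")["lrr"].to_numpy()
        n = 0
        for a, b in zip(lrrs[:-1], lrrs[1:]):
            if abs(2.0 ** b / 2.0 ** a - 1.0) >= change_fraction:
                n += 1
        counts[(model, c)] = n
    return counts


def test_single_segment_per_chromosome_has_no_breakpoints():
    seg = pd.concat([seg_rows("M1", str(c), [0.3]) for c in range(1, 23)])
    out = count_breakpoints(seg)
    assert (out["n_breakpoints"] == 0).all()


def test_twenty_percent_then_flat_counts_one():
    # linear ratios 1.00 -> 1.20 -> 1.20: one 20% change, then none
    lrrs = [0.0, np.log2(1.2), np.log2(1.2)]
    out = count_breakpoints(seg_rows("M1", "1", lrrs))
    assert out.loc[0, "n_breakpoints"] == 1


def test_five_percent_change_is_not_a_breakpoint():
    out = count_breakpoints(seg_rows("M1", "1", [0.0, np.log2(1.05)]))
    assert out.loc[0, "n_breakpoints"] == 0


def test_exact_ten_percent_change_counts():
    out = count_breakpoints(seg_rows("M1", "1", [0.0, np.log2(1.10)]))
    assert out.loc[0, "n_breakpoints"] == 1


def test_sex_chromosomes_excluded():
    seg = pd.concat([seg_rows("M1", "X", [0.0, 1.0, 0.0]),
                     seg_rows("M1", "1", [0.0, 1.0])])
    out = count_breakpoints(seg)
    assert set(out["chrom"]) == {"1"}
    assert out["n_breakpoints"].sum() == 1


def random_profiles(rng, n_models=30):
    frames = []
    for m in range(n_models):
        for chrom in map(str, range(1, 23)):
            k = int(rng.integers(1, 8))
            lrrs = rng.normal(0, 0.5, size=k)
            frames.append(seg_rows(f"M{m}", chrom, lrrs))
    return pd.concat(frames, ignore_index=True)


def test_counts_match_exhaustive_scan_oracle():
    rng = np.random.default_rng(3)
    seg = random_profiles(rng, n_models=30)
    out = count_breakpoints(seg)
    got = {(r.model_id, r.chrom): r.n_breakpoints
           for r in out.itertuples(index=False)}
    assert got == breakpoint_scan_oracle(seg)


def test_counting_invariant_to_row_order():
    rng = np.random.default_rng(4)
    seg = random_profiles(rng, n_models=5)
    shuffled = seg.sample(frac=1.0, random_state=1).reset_index(drop=True)
    a = count_breakpoints(seg).reset_index(drop=True)
    b = count_breakpoints(shuffled).reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b)


def test_counting_invariant_to_global_lrr_offset():
    rng = np.random.default_rng(5)
    seg = random_profiles(rng, n_models=5)
    shifted = seg.assign(lrr=seg["lrr"] + 0.7)
    pd.testing.assert_frame_equal(count_breakpoints(seg),
                                  count_breakpoints(shifted))


def test_overlapping_segments_rejected():
    seg = seg_rows("M1", "1", [0.0, 0.5])
    seg.loc[1, "start"] = seg.loc[0, "end"]  # overlap by one base
    with pytest.raises(ValidationError, match="overlap"):
        count_breakpoints(seg)


# ----------------------------------------------------------------------- HBD

def counts_frame(model, chrom_counts):
    return pd.DataFrame([{"model_id": model, "chrom": c, "n_breakpoints": n}
                         for c, n in chrom_counts.items()])


def test_hbd_boundary_is_inclusive_at_ten():
    nine = call_hbd(counts_frame("M1", {"1": 9}))
    ten = call_hbd(counts_frame("M1", {"1": 10}))
    assert not nine.loc[0, "hbd_flag"]
    assert ten.loc[0, "hbd_flag"]
    assert ten.loc[0, "hbd_chromosomes"] == "1"


def test_hbd_all_zero_is_unflagged():
    out = call_hbd(counts_frame("M1", {str(c): 0 for c in range(1, 23)}))
    assert not out.loc[0, "hbd_flag"]
    assert out.loc[0, "hbd_bucket"] == "none"


def test_hbd_five_or_more_bucket():
    out = call_hbd(counts_frame("M1", {"1": 12, "2": 11, "3": 10, "4": 15,
                                       "5": 10, "6": 2}))
    assert out.loc[0, "n_hbd_chromosomes"] == 5
    assert out.loc[0, "hbd_bucket"] == "five_or_more"
    four = call_hbd(counts_frame("M1", {"1": 12, "2": 11, "3": 10, "4": 15}))
    assert four.loc[0, "hbd_bucket"] == "four_or_fewer"


# --------------------------------------------------------------- focal events

GENES = pd.DataFrame([
    {"gene": "MYCN", "chrom": "2", "start": 400_000, "end": 500_000},
    {"gene": "CDKN2A", "chrom": "9", "start": 400_000, "end": 500_000},
])


def focal_fixture(lrr2, lrr9):
    return pd.concat([seg_rows("M1", "2", [0.0, lrr2, 0.0]),
                      seg_rows("M1", "9", [0.0, lrr9, 0.0])],
                     ignore_index=True).assign(
        start=lambda d: d["start"], end=lambda d: d["end"])


def wide_segments(model, chrom, lrr):
    return pd.DataFrame([{"model_id": model, "chrom": chrom, "start": 1,
                          "end": 1_000_000, "num_probes": 50, "lrr": lrr}])


@pytest.mark.parametrize("lrr,expected_amp", [
    (0.538578182, True),     # inclusive at the printed cutoff
    (0.538578181, False),
    (0.54, True),
    (0.50, False),
])
def test_amplification_threshold_bit_exact(lrr, expected_amp):
    calls, _ = call_focal_events(wide_segments("M1", "2", lrr), GENES)
    amps = calls[calls["event"] == "amplification"]
    assert (len(amps) == 1) == expected_amp


@pytest.mark.parametrize("lrr,expected_del", [
    (-1.739, True),          # inclusive at the printed magnitude
    (-1.7389999, False),
    (-1.8, True),
])
def test_deletion_threshold_bit_exact(lrr, expected_del):
    calls, _ = call_focal_events(wide_segments("M1", "9", lrr), GENES)
    dels = calls[calls["event"] == "homozygous_deletion"]
    assert (len(dels) == 1) == expected_del


def fpkm_matrix(value):
    return pd.DataFrame({"M1": [value, value]},
                        index=pd.Index(["MYCN", "CDKN2A"], name="gene"))


def test_deletion_rescued_when_silent():
    calls, audit = call_focal_events(wide_segments("M1", "9", -1.8), GENES,
                                     fpkm=fpkm_matrix(0.2))
    dels = calls[calls["event"] == "homozygous_deletion"]
    assert len(dels) == 1 and bool(dels.iloc[0]["rescued"])


def test_deletion_dropped_when_expressed():
    calls, audit = call_focal_events(wide_segments("M1", "9", -1.8), GENES,
                                     fpkm=fpkm_matrix(7.3))
    assert len(calls[calls["event"] == "homozygous_deletion"]) == 0
    dropped = audit[audit["reason"] == "expressed"]
    assert len(dropped) == 1 and dropped.iloc[0]["gene"] == "CDKN2A"


def test_deletion_rescue_boundary_fpkm_five_drops():
    # rescue requires FPKM strictly below 5
    _, audit = call_focal_events(wide_segments("M1", "9", -1.8), GENES,
                                 fpkm=fpkm_matrix(5.0))
    assert (audit["reason"] == "expressed").sum() == 1


def test_deletion_kept_without_rna():
    calls, _ = call_focal_events(wide_segments("M1", "9", -1.8), GENES,
                                 fpkm=fpkm_matrix(7.3), rna_models=set())
    dels = calls[calls["event"] == "homozygous_deletion"]
    assert len(dels) == 1 and bool(dels.iloc[0]["rescued"])


def test_uncovered_gene_reported_not_raised():
    seg = wide_segments("M1", "2", 0.0)   # nothing on chr9
    _, audit = call_focal_events(seg, GENES)
    assert ((audit["gene"] == "CDKN2A")
            & (audit["reason"] == "uncovered")).any()


def test_weighted_gene_lrr_mode():
    # two half-overlapping segments: extreme picks the amp, weighted averages
    seg = pd.DataFrame([
        {"model_id": "M1", "chrom": "2", "start": 1, "end": 450_000,
         "num_probes": 50, "lrr": 0.9},
        {"model_id": "M1", "chrom": "2", "start": 450_001, "end": 1_000_000,
         "num_probes": 50, "lrr": 0.0},
    ])
    extreme, _ = call_focal_events(seg, GENES, gene_lrr_mode="extreme")
    weighted, _ = call_focal_events(seg, GENES, gene_lrr_mode="weighted")
    assert len(extreme[extreme["event"] == "amplification"]) == 1
    assert len(weighted) == 0   # mean over the gene interval is 0.45


# ------------------------------------------------------------------ exon FPKM

def test_exon_fpkm_worked_example():
    cov = pd.DataFrame([{"model_id": "M1", "gene": "ATRX", "exon_id": "e1",
                         "exon_length": 1000, "fragment_count": 500,
                         "library_size": 50_000_000}])
    assert exon_fpkm(cov).loc[0, "fpkm"] == pytest.approx(10.0)


def test_exon_fpkm_zero_fragments():
    cov = pd.DataFrame([{"model_id": "M1", "gene": "ATRX", "exon_id": "e1",
                         "exon_length": 500, "fragment_count": 0,
                         "library_size": 1_000_000}])
    assert exon_fpkm(cov).loc[0, "fpkm"] == 0.0


def test_exon_fpkm_matches_independent_formula():
    rng = np.random.default_rng(9)
    cov = pd.DataFrame({
        "model_id": "M1", "gene": "ATRX",
        "exon_id": [f"e{i}" for i in range(50)],
        "exon_length": rng.integers(50, 5000, size=50),
        "fragment_count": rng.integers(0, 10_000, size=50),
        "library_size": int(4e7),
    })
    got = exon_fpkm(cov)["fpkm"].to_numpy()
    expected = np.array([
        r.fragment_count * 1e9 / (r.library_size * r.exon_length)
        for r in cov.itertuples(index=False)])
    np.testing.assert_allclose(got, expected, rtol=1e-12)


def test_exon_fpkm_rejects_degenerate_inputs():
    cov = pd.DataFrame([{"model_id": "M1", "gene": "ATRX", "exon_id": "e1",
                         "exon_length": 0, "fragment_count": 5,
                         "library_size": 100}])
    with pytest.raises(ValidationError):
        exon_fpkm(cov)


def test_exon_deletion_flag_uses_median():
    fpkm = pd.DataFrame({
        "model_id": "M1", "gene": "ATRX", "exon_id": list("abcde"),
        "fpkm": [0.0, 0.2, 0.4, 0.9, 30.0],
    })
    out = flag_exon_deletion(fpkm)
    assert bool(out.loc[0, "deletion_flag"])   # median 0.4 < 1
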