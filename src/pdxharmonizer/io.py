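"""Plain-text readers/writers for the tabular formats the pipeline exchanges.

All tables are tab-separated.  The MAF and SEG layouts follow the field
conventions (Hugo_Symbol/.../t_depth and ID/chrom/loc.start/loc.end/num.mark/
seg.mean); the four fusion-caller dialects are simplified, documented column
maps of the real callers' outputs, each carrying an explicit sample column so
cohort-level files are self-contained.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ._common import ValidationError
from .copy_number import SEGMENT_COLUMNS
from .fusion_consensus import CALLERS, FUSION_CALL_COLUMNS
from .sample_qc import CT_COLUMNS, VAF_OBS_COLUMNS
from .variant_harmonization import MAF_COLUMNS

_SEG_FILE_COLUMNS = ["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]


def _write(df: pd.DataFrame, path, index: bool = False) -> int:
    df.to_csv(path, sep="\t", index=index)
    return len(df)


def _coerce(df: pd.DataFrame, ints=(), floats=(), bools=()) -> pd.DataFrame:
    for c in ints:
        if c in df.columns:
            df[c] = df[c].astype("int64") if len(df) else df[c].astype("int64")
    for c in floats:
        if c in df.columns:
            df[c] = df[c].astype(float)
    for c in bools:
        if c in df.columns:
            df[c] = df[c].map({"True": True, "False": False, True: True,
                               False: False}).astype(bool) if len(df) else \
                df[c].astype(bool)
    return df


# ---------------------------------------------------------------- MAF / panel

def write_maf(maf: pd.DataFrame, path) -> int:
    return _write(maf.reindex(columns=MAF_COLUMNS), path)


def read_maf(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"Chromosome": str,
                                            "Tumor_Sample_Barcode": str})
    return _coerce(df, ints=["Start_Position", "End_Position", "t_alt_count",
                             "t_depth"],
                   floats=["ExAC_AF", "TG_AF", "ESP_AF"], bools=["COSMIC_flag"])


def write_pon(pon: pd.DataFrame, path) -> int:
    return _write(pon, path)


def read_pon(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"Chromosome": str})
    return _coerce(df, ints=["Start_Position", "n_carriers"])


# ----------------------------------------------------------------------- SEG

def write_seg(segments: pd.DataFrame, path) -> int:
    """Write canonical segments (model_id/chrom/start/end/num_probes/lrr) in
    SEG layout (ID/chrom/loc.start/loc.end/num.mark/seg.mean)."""
    out = segments.reindex(columns=SEGMENT_COLUMNS)
    out.columns = _SEG_FILE_COLUMNS
    return _write(out, path)


def read_seg(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ID": str})
    missing = set(_SEG_FILE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"SEG file {path} lacks columns {sorted(missing)}")
    df = df[_SEG_FILE_COLUMNS]
    df.columns = SEGMENT_COLUMNS
    return _coerce(df, ints=["start", "end", "num_probes"], floats=["lrr"])


# ------------------------------------------------------------------- matrices

def write_expression(matrix: pd.DataFrame, path) -> int:
    out = matrix.copy()
    out.index.name = "gene"
    return _write(out, path, index=True)


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene").astype(float)


# ------------------------------------------------------------------ small tsv

def write_metadata(metadata: pd.DataFrame, path) -> int:
    return _write(metadata, path)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"model_id": str})
    return _coerce(df, bools=["has_rna"])


def write_gene_models(genes: pd.DataFrame, path) -> int:
    return _write(genes, path)


def read_gene_models(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return _coerce(df, ints=["start", "end"])


def write_ct(ct: pd.DataFrame, path) -> int:
    return _write(ct.reindex(columns=CT_COLUMNS), path)


def read_ct(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "species": str})
    return _coerce(df, ints=["replicate"], floats=["ct"])


def write_vaf_observations(vafs: pd.DataFrame, path) -> int:
    return _write(vafs.reindex(columns=VAF_OBS_COLUMNS), path)


def read_vaf_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"model_id": str, "chrom": str})
    return _coerce(df, ints=["pos", "depth"], floats=["vaf"])


# -------------------------------------------------------- fusion caller files

_FRAME_TO_DIALECT = {
    "starfusion": {"in-frame": "INFRAME", "frameshift": "FRAMESHIFT", "unknown": "."},
    "fusioncatcher": {"in-frame": "in-frame", "frameshift": "out-of-frame",
                      "unknown": "unknown"},
    "defuse": {"in-frame": "Y", "frameshift": "N", "unknown": "NA"},
    "soapfuse": {"in-frame": "in-frame", "frameshift": "frame-shift",
                 "unknown": "unknown"},
}
_FRAME_FROM_DIALECT = {
    caller: {v: k for k, v in m.items()} for caller, m in _FRAME_TO_DIALECT.items()
}

_DIALECT_COLUMNS = {
    "starfusion": ["Sample", "#FusionName", "LeftBreakpoint", "RightBreakpoint",
                   "PROT_FUSION_TYPE", "annots"],
    "fusioncatcher": ["Sample", "Gene_1_symbol(5end_fusion_partner)",
                      "Gene_2_symbol(3end_fusion_partner)",
                      "Fusion_point_for_gene_1(5end_fusion_partner)",
                      "Fusion_point_for_gene_2(3end_fusion_partner)",
                      "Predicted_effect", "Fusion_description"],
    "defuse": ["library_name", "gene_name1", "gene_name2", "breakpoint1",
               "breakpoint2", "orf", "read_through"],
    "soapfuse": ["Sample", "up_gene", "dw_gene", "up_junction", "dw_junction",
                 "frame", "fusion_type"],
}


def write_fusion_calls(calls: pd.DataFrame, caller: str, path) -> int:
    """Write the subset of canonical calls belonging to ``caller`` in that
    caller's dialect; rows for other callers are ignored."""
    if caller not in CALLERS:
        raise ValidationError(f"unknown caller {caller!r}")
    sub = calls[calls["caller"] == caller] if len(calls) else calls
    fmap = _FRAME_TO_DIALECT[caller]
    frame = sub["frame"].map(fmap) if len(sub) else sub.get("frame", pd.Series(dtype=str))
    bp5 = sub["breakpoint5"].replace("", ".") if len(sub) else pd.Series(dtype=str)
    bp3 = sub["breakpoint3"].replace("", ".") if len(sub) else pd.Series(dtype=str)
    rt = sub["read_through"] if len(sub) else pd.Series(dtype=bool)
    if caller == "starfusion":
        out = pd.DataFrame({
            "Sample": sub["model_id"],
            "#FusionName": sub["gene5"] + "--" + sub["gene3"] if len(sub) else [],
            "LeftBreakpoint": bp5, "RightBreakpoint": bp3,
            "PROT_FUSION_TYPE": frame,
            "annots": np.where(rt, "READTHRU", "."),
        })
    elif caller == "fusioncatcher":
        out = pd.DataFrame({
            "Sample": sub["model_id"],
            "Gene_1_symbol(5end_fusion_partner)": sub["gene5"],
            "Gene_2_symbol(3end_fusion_partner)": sub["gene3"],
            "Fusion_point_for_gene_1(5end_fusion_partner)": bp5,
            "Fusion_point_for_gene_2(3end_fusion_partner)": bp3,
            "Predicted_effect": frame,
            "Fusion_description": np.where(rt, "readthrough", "."),
        })
    elif caller == "defuse":
        out = pd.DataFrame({
            "library_name": sub["model_id"],
            "gene_name1": sub["gene5"], "gene_name2": sub["gene3"],
            "breakpoint1": bp5, "breakpoint2": bp3,
            "orf": frame,
            "read_through": np.where(rt, "Y", "N"),
        })
    else:  # soapfuse
        out = pd.DataFrame({
            "Sample": sub["model_id"],
            "up_gene": sub["gene5"], "dw_gene": sub["gene3"],
            "up_junction": bp5, "dw_junction": bp3,
            "frame": frame,
            "fusion_type": np.where(rt, "READTHROUGH", "NORMAL"),
        })
    out = out.reindex(columns=_DIALECT_COLUMNS[caller])
    return _write(out, path)


def read_fusion_calls(path, caller: str,
                      metadata: "pd.DataFrame | None" = None) -> pd.DataFrame:
    """Parse one caller's dialect back into the canonical call layout.

    ``metadata`` (model_id, histology) fills the histology column; without it
    histology is left empty.
    """
    if caller not in CALLERS:
        raise ValidationError(f"unknown caller {caller!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    fmap = _FRAME_FROM_DIALECT[caller]
    if caller == "starfusion":
        split = df["#FusionName"].str.split("--", n=1, expand=True) if len(df) \
            else pd.DataFrame(columns=[0, 1])
        out = pd.DataFrame({
            "model_id": df["Sample"] if len(df) else [],
            "gene5": split[0] if len(df) else [],
            "gene3": split[1] if len(df) else [],
            "frame": df["PROT_FUSION_TYPE"].map(fmap) if len(df) else [],
            "read_through": df["annots"].str.contains("READTHRU") if len(df) else [],
            "breakpoint5": df["LeftBreakpoint"] if len(df) else [],
            "breakpoint3": df["RightBreakpoint"] if len(df) else [],
        })
    elif caller == "fusioncatcher":
        out = pd.DataFrame({
            "model_id": df["Sample"] if len(df) else [],
            "gene5": df["Gene_1_symbol(5end_fusion_partner)"] if len(df) else [],
            "gene3": df["Gene_2_symbol(3end_fusion_partner)"] if len(df) else [],
            "frame": df["Predicted_effect"].map(fmap) if len(df) else [],
            "read_through": df["Fusion_description"].str.contains("readthrough")
            if len(df) else [],
            "breakpoint5": df["Fusion_point_for_gene_1(5end_fusion_partner)"]
            if len(df) else [],
            "breakpoint3": df["Fusion_point_for_gene_2(3end_fusion_partner)"]
            if len(df) else [],
        })
    elif caller == "defuse":
        out = pd.DataFrame({
            "model_id": df["library_name"] if len(df) else [],
            "gene5": df["gene_name1"] if len(df) else [],
            "gene3": df["gene_name2"] if len(df) else [],
            "frame": df["orf"].map(fmap) if len(df) else [],
            "read_through": df["read_through"].eq("Y") if len(df) else [],
            "breakpoint5": df["breakpoint1"] if len(df) else [],
            "breakpoint3": df["breakpoint2"] if len(df) else [],
        })
    else:  # soapfuse
        out = pd.DataFrame({
            "model_id": df["Sample"] if len(df) else [],
            "gene5": df["up_gene"] if len(df) else [],
            "gene3": df["dw_gene"] if len(df) else [],
            "frame": df["frame"].map(fmap) if len(df) else [],
            "read_through": df["fusion_type"].eq("READTHROUGH") if len(df) else [],
            "breakpoint5": df["up_junction"] if len(df) else [],
            "breakpoint3": df["dw_junction"] if len(df) else [],
        })
    out["caller"] = caller
    for col in ("breakpoint5", "breakpoint3"):
        out[col] = out[col].replace(".", "") if len(out) else out[col]
    if metadata is not None and len(out):
        hist = metadata.set_index("model_id")["histology"]
        out["histology"] = out["model_id"].map(hist).fillna("")
    else:
        out["histology"] = pd.Series([""] * len(out), dtype=object)
    if len(out):
        out["read_through"] = out["read_through"].astype(bool)
    return out.reindex(columns=FUSION_CALL_COLUMNS)
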