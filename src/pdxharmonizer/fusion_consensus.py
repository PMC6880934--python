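"""Multi-caller gene-fusion consensus filtering with driver scavenge-back.

Fusion callers run on RNA-seq produce tens of thousands of candidate chimeras,
most of them artifacts.  Predictions from four callers (STAR-Fusion,
FusionCatcher, deFuse, SOAPFuse) are merged on the ordered 5'->3' gene pair per
model and pushed through a filter cascade:

1. keep in-frame fusions that are recurrent (same pair in >= 2 models of one
   histology) or supported by >= 2 callers, union fusions whose 5' or 3' gene
   fuses promiscuously (>= 2 distinct partners) within one histology;
2. drop pairs where both genes are expressed < 1 TPM across all models (or are
   absent from the quantification);
3. drop pairs predicted in more than one histology (pediatric driver fusions
   are histology-specific; cross-histology pairs are recurrent artifacts);
4. drop read-through chimeras of adjacent genes, and pairs observed in normal
   tissue (GTEx);
5. scavenge back known driver fusions regardless of the filters, then annotate
   partners as oncogene / kinase / transcription factor.

Every removed fusion is recorded in an audit table with the rule that removed
it, so final + audit always account for each merged input exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from ._common import ConfigurationError, ValidationError

CALLERS = ("starfusion", "fusioncatcher", "defuse", "soapfuse")
FRAMES = ("in-frame", "frameshift", "unknown")

#: Canonical in-memory layout of a single caller prediction.
FUSION_CALL_COLUMNS = ["model_id", "histology", "caller", "gene5", "gene3",
                       "frame", "read_through", "breakpoint5", "breakpoint3"]

# audit reasons, in cascade order
REASON_SUPPORT = "recurrence/support"
REASON_FRAME = "frame/promiscuity"
REASON_EXPRESSION = "expression"
REASON_CROSS_HISTOLOGY = "cross-histology"
REASON_READTHROUGH = "read_through"
REASON_GTEX = "gtex_normal"


def _read_pairs(path) -> set[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return {(str(a).upper(), str(b).upper())
            for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])}


def _read_genes(path) -> set[str]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return {str(g).upper() for g in df.iloc[:, 0]}


@dataclass
class ReferenceLists:
    """Case-normalized reference sets driving the filter and annotation steps."""

    driver_fusions: set = field(default_factory=set)
    gtex_normal_fusions: set = field(default_factory=set)
    oncogenes: set = field(default_factory=set)
    kinases: set = field(default_factory=set)
    transcription_factors: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.driver_fusions = {(a.upper(), b.upper()) for a, b in self.driver_fusions}
        self.gtex_normal_fusions = {(a.upper(), b.upper())
                                    for a, b in self.gtex_normal_fusions}
        self.oncogenes = {g.upper() for g in self.oncogenes}
        self.kinases = {g.upper() for g in self.kinases}
        self.transcription_factors = {g.upper() for g in self.transcription_factors}

    @classmethod
    def load_default(cls) -> "ReferenceLists":
        """Load the starter reference lists shipped with the package.

        These are small editable seed lists (canonical pediatric drivers,
        published normal-tissue chimeras, and a few dozen well-known
        oncogenes/kinases/TFs), not the exhaustive curated resources.
        """
        root = resources.files("pdxharmonizer").joinpath("data")
        return cls(
            driver_fusions=_read_pairs(root / "driver_fusions.tsv"),
            gtex_normal_fusions=_read_pairs(root / "gtex_fusions.tsv"),
            oncogenes=_read_genes(root / "oncogenes.tsv"),
            kinases=_read_genes(root / "kinases.tsv"),
            transcription_factors=_read_genes(root / "transcription_factors.tsv"),
        )

    @classmethod
    def from_dir(cls, directory: str | Path) -> "ReferenceLists":
        d = Path(directory)
        return cls(
            driver_fusions=_read_pairs(d / "driver_fusions.tsv"),
            gtex_normal_fusions=_read_pairs(d / "gtex_fusions.tsv"),
            oncogenes=_read_genes(d / "oncogenes.tsv"),
            kinases=_read_genes(d / "kinases.tsv"),
            transcription_factors=_read_genes(d / "transcription_factors.tsv"),
        )


def merge_callers(calls: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-caller predictions to unique (model, gene5, gene3) fusions.

    Gene order is preserved (A->B and B->A are distinct fusions).  Duplicate
    rows from one caller collapse; frame is 'in-frame' if any caller reports
    in-frame (else 'frameshift' if any, else 'unknown'); read_through is true
    if any caller annotates it.  Same-gene events are kept but flagged.
    """
    unknown = set(calls["caller"].unique()) - set(CALLERS) if len(calls) else set()
    if unknown:
        raise ValidationError(f"unknown caller labels: {sorted(unknown)}")
    cols = ["model_id", "histology", "gene5", "gene3", "callers", "n_callers",
            "frame", "read_through", "same_gene"]
    if len(calls) == 0:
        return pd.DataFrame(columns=cols)

    def _frame(frames: pd.Series) -> str:
        s = set(frames)
        if "in-frame" in s:
            return "in-frame"
        if "frameshift" in s:
            return "frameshift"
        return "unknown"

    grouped = calls.groupby(["model_id", "gene5", "gene3"], sort=True)
    merged = grouped.agg(
        histology=("histology", "first"),
        callers=("caller", lambda c: frozenset(c)),
        frame=("frame", _frame),
        read_through=("read_through", "any"),
    ).reset_index()
    merged["n_callers"] = merged["callers"].map(len)
    merged["same_gene"] = merged["gene5"] == merged["gene3"]
    return merged[cols]


@dataclass
class FilterResult:
    high_confidence: pd.DataFrame
    audit: pd.DataFrame


def filter_fusions(
    merged: pd.DataFrame,
    expression_tpm: "pd.DataFrame | None",
    refs: ReferenceLists,
    min_tpm: float = 1.0,
    min_callers: int = 2,
    min_recurrent_models: int = 2,
    expression_filter: bool = True,
) -> FilterResult:
    """Apply the high-confidence filter cascade to merged fusions.

    ``expression_tpm`` is a gene-by-model TPM matrix; a pair is dropped when
    both genes have max-over-models TPM < ``min_tpm`` (genes missing from the
    quantification count as below threshold).  See the module docstring for
    the cascade.  Returns the retained set plus an audit table in which every
    removed fusion carries the name of the rule that removed it.
    """
    if expression_filter and expression_tpm is None:
        raise ConfigurationError(
            "expression filter is enabled but no TPM matrix was provided")
    if len(merged) == 0:
        return FilterResult(merged.copy(), merged.assign(reason=pd.Series(dtype=str)))

    df = merged.reset_index(drop=True)
    in_frame = df["frame"] == "in-frame"

    # recurrence: same ordered pair in >= N distinct models within one histology
    rec_counts = (df.groupby(["histology", "gene5", "gene3"])["model_id"]
                  .nunique())
    recurrent = pd.Series(
        [rec_counts[(h, g5, g3)] >= min_recurrent_models
         for h, g5, g3 in zip(df["histology"], df["gene5"], df["gene3"])],
        index=df.index)

    # promiscuity over the full merged (pre-filter) set, any frame
    p5 = df.groupby(["histology", "gene5"])["gene3"].nunique()
    p3 = df.groupby(["histology", "gene3"])["gene5"].nunique()
    promiscuous = pd.Series(
        [p5[(h, g5)] >= 2 or p3[(h, g3)] >= 2
         for h, g5, g3 in zip(df["histology"], df["gene5"], df["gene3"])],
        index=df.index)

    approach_a = in_frame & (recurrent | (df["n_callers"] >= min_callers))
    keep = approach_a | promiscuous
    reason = pd.Series("", index=df.index, dtype=object)
    reason[~keep & in_frame] = REASON_SUPPORT
    reason[~keep & ~in_frame] = REASON_FRAME

    if expression_filter:
        max_tpm = expression_tpm.max(axis=1) if expression_tpm.shape[1] else \
            pd.Series(dtype=float)

        def expressed(gene: str) -> bool:
            return gene in max_tpm.index and float(max_tpm[gene]) >= min_tpm

        silent = ~df["gene5"].map(expressed) & ~df["gene3"].map(expressed)
        newly = keep & silent
        reason[newly] = REASON_EXPRESSION
        keep &= ~silent

    # cross-histology: ordered pair observed in > 1 histology over the cohort
    hist_counts = df.groupby(["gene5", "gene3"])["histology"].nunique()
    cross = pd.Series(
        [hist_counts[(g5, g3)] > 1
         for g5, g3 in zip(df["gene5"], df["gene3"])], index=df.index)
    reason[keep & cross] = REASON_CROSS_HISTOLOGY
    keep &= ~cross

    rt = df["read_through"].astype(bool)
    reason[keep & rt] = REASON_READTHROUGH
    keep &= ~rt

    gtex = pd.Series(
        [(g5.upper(), g3.upper()) in refs.gtex_normal_fusions
         for g5, g3 in zip(df["gene5"], df["gene3"])], index=df.index)
    reason[keep & gtex] = REASON_GTEX
    keep &= ~gtex

    audit = df.loc[~keep].assign(reason=reason[~keep])
    return FilterResult(df.loc[keep].copy(), audit.reset_index(drop=True))


def flag_adjacent_pairs(
    merged: pd.DataFrame,
    gene_models: pd.DataFrame,
    max_distance: int = 100_000,
) -> pd.Series:
    """Optional read-through surrogate for callers lacking the annotation:
    True where both genes lie on the same chromosome less than ``max_distance``
    bp apart (gene_models columns: gene, chrom, start, end)."""
    loc = gene_models.set_index("gene")[["chrom", "start", "end"]]

    def adjacent(g5: str, g3: str) -> bool:
        if g5 not in loc.index or g3 not in loc.index:
            return False
        a, b = loc.loc[g5], loc.loc[g3]
        if a["chrom"] != b["chrom"]:
            return False
        gap = max(a["start"], b["start"]) - min(a["end"], b["end"])
        return gap < max_distance

    return pd.Series([adjacent(g5, g3) for g5, g3
                      in zip(merged["gene5"], merged["gene3"])],
                     index=merged.index)


def scavenge_drivers(
    merged: pd.DataFrame,
    filtered: FilterResult,
    refs: ReferenceLists,
) -> FilterResult:
    """Restore known driver fusions removed by any filter.

    Any merged fusion whose (gene5, gene3) pair is in the driver list enters
    the final set with provenance 'driver_scavenge' (or 'filters+driver' when
    it also survived the cascade); everything retained by the cascade alone is
    marked 'filters'.  Restored fusions leave the audit table so that
    final + audit still partition the merged input.
    """
    def is_driver(g5: str, g3: str) -> bool:
        return (g5.upper(), g3.upper()) in refs.driver_fusions

    hc = filtered.high_confidence.copy()
    hc["provenance"] = [
        "filters+driver" if is_driver(g5, g3) else "filters"
        for g5, g3 in zip(hc["gene5"], hc["gene3"])]

    audit = filtered.audit
    restore = pd.Series([is_driver(g5, g3) for g5, g3
                         in zip(audit["gene5"], audit["gene3"])],
                        index=audit.index, dtype=bool) if len(audit) else \
        pd.Series(dtype=bool)
    restored = audit.loc[restore].drop(columns="reason").assign(
        provenance="driver_scavenge")
    final = pd.concat([hc, restored], ignore_index=True)
    return FilterResult(final, audit.loc[~restore].reset_index(drop=True))


def annotate_partners(final: pd.DataFrame, refs: ReferenceLists) -> pd.DataFrame:
    """Add oncogene/kinase/transcription-factor membership flags per partner."""
    out = final.copy()
    for suffix in ("5", "3"):
        genes = out[f"gene{suffix}"].astype(str).str.upper()
        out[f"oncogene{suffix}"] = genes.isin(refs.oncogenes)
        out[f"kinase{suffix}"] = genes.isin(refs.kinases)
        out[f"tf{suffix}"] = genes.isin(refs.transcription_factors)
    return out


def summarize_by_histology(annotated: pd.DataFrame) -> pd.DataFrame:
    """Per-histology counts of high-confidence fusions and annotated partners."""
    if len(annotated) == 0:
        return pd.DataFrame(columns=["histology", "n_fusions", "n_oncogene",
                                     "n_kinase", "n_tf"])
    g = annotated.groupby("histology")
    return pd.DataFrame({
        "n_fusions": g.size(),
        "n_oncogene": g.apply(lambda d: int((d["oncogene5"] | d["oncogene3"]).sum()),
                              include_groups=False),
        "n_kinase": g.apply(lambda d: int((d["kinase5"] | d["kinase3"]).sum()),
                            include_groups=False),
        "n_tf": g.apply(lambda d: int((d["tf5"] | d["tf3"]).sum()),
                        include_groups=False),
    }).reset_index()


def consensus_fusions(
    calls: pd.DataFrame,
    expression_tpm: "pd.DataFrame | None",
    refs: "ReferenceLists | None" = None,
    **filter_kwargs,
) -> dict:
    """End-to-end convenience: merge -> filter -> scavenge -> annotate.

    Returns a dict with 'merged', 'high_confidence' (annotated final set) and
    'audit' DataFrames.
    """
    if refs is None:
        refs = ReferenceLists.load_default()
    merged = merge_callers(calls)
    filtered = filter_fusions(merged, expression_tpm, refs, **filter_kwargs)
    final = scavenge_drivers(merged, filtered, refs)
    annotated = annotate_partners(final.high_confidence, refs)
    return {"merged": merged, "high_confidence": annotated, "audit": final.audit}
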