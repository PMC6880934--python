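"""End-to-end orchestration and oncoprint-style summarization.

:func:`run_pipeline` drives the full analysis over a fixture directory —
variant harmonization, TMB and phase comparison, breakpoints/HBD, focal
events, fusion consensus, sample QC — writes every stage output as TSV, and
records a JSON manifest with parameters, SHA-256 hashes of all inputs and
outputs, and row counts.  Re-running on identical inputs reproduces identical
outputs byte for byte.

:func:`build_alteration_matrix` condenses the stage outputs into a gene-by-
model matrix whose cells are sets of alteration labels (missense, nonsense,
frameshift, splice, amplification, homozygous_deletion, fusion); only the 5'
fusion partner contributes a fusion label to its gene.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as pio
from ._common import ValidationError, sha256_file
from . import copy_number as cn
from . import fusion_consensus as fc
from . import sample_qc as qc
from . import variant_harmonization as vh
from .synthetic_data import REFERENCE_SAMPLE_ID, read_fixtures

logger = logging.getLogger("pdxharmonizer")

#: Variant_Classification -> oncoprint label; classes absent here are omitted.
CLASSIFICATION_LABELS = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Frame_Shift_Del": "frameshift",
    "Frame_Shift_Ins": "frameshift",
    "Splice_Site": "splice",
}


class PipelineError(RuntimeError):
    """A stage failed validation; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Input location, output location, and every stage threshold.

    Threshold defaults are the analysis' published operating points (panel
    carrier count > 5, population AF > 0.005, 45.1 Mb capture, 10% copy
    change, HBD >= 10, amplification LRR >= 0.538578182, deletion LRR <=
    -1.739, FPKM-5 rescue, 1 TPM fusion expression floor, identity r >= 0.61
    at depth >= 10).
    """

    input_dir: str = ""
    out_dir: str = ""
    pon_threshold: int = 5
    common_af: float = 0.005
    af_mode: str = "any_db"
    capture_mb: float = vh.DEFAULT_CAPTURE_MB
    change_fraction: float = cn.DEFAULT_CHANGE_FRACTION
    hbd_threshold: int = cn.DEFAULT_HBD_THRESHOLD
    amp_cutoff: float = cn.DEFAULT_AMP_CUTOFF
    del_cutoff: float = cn.DEFAULT_DEL_CUTOFF
    rescue_fpkm: float = cn.DEFAULT_RESCUE_FPKM
    min_tpm: float = 1.0
    min_callers: int = 2
    min_recurrent_models: int = 2
    skew_threshold: float = -0.5
    min_sites: int = 100
    min_depth: int = 10
    match_threshold: float = 0.61
    gene_list: list = field(default_factory=list)   # empty -> derive from data
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def build_alteration_matrix(
    somatic_maf: pd.DataFrame,
    focal_calls: pd.DataFrame,
    fusions: pd.DataFrame,
    metadata: pd.DataFrame,
    gene_list: "list[str] | None" = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-by-model alteration matrix plus per-histology frequencies.

    Cells hold the comma-joined sorted union of alteration labels for that
    gene and model (empty string when unaltered).  ``gene_list`` fixes the
    row order; when omitted it is derived as the sorted set of genes carrying
    at least one alteration.  Returns (matrix, frequency) where frequency has
    one row per (gene, histology) with the altered-model fraction.
    """
    models = list(metadata["model_id"])
    model_set = set(models)

    events: list[tuple[str, str, str]] = []   # (gene, model, label)
    if len(somatic_maf):
        for r in somatic_maf.itertuples(index=False):
            label = CLASSIFICATION_LABELS.get(r.Variant_Classification)
            if label:
                events.append((r.Hugo_Symbol, r.Tumor_Sample_Barcode, label))
    if len(focal_calls):
        for r in focal_calls.itertuples(index=False):
            events.append((r.gene, r.model_id, r.event))
    if len(fusions):
        for r in fusions.itertuples(index=False):
            events.append((r.gene5, r.model_id, "fusion"))

    stray = {m for _, m, _ in events} - model_set
    if stray:
        raise ValidationError(f"models absent from metadata: {sorted(stray)}")

    if gene_list is None or len(gene_list) == 0:
        gene_list = sorted({g for g, _, _ in events})

    cells: dict = {}
    gene_set = set(gene_list)
    for gene, model, label in events:
        if gene in gene_set:
            cells.setdefault((gene, model), set()).add(label)
    matrix = pd.DataFrame("", index=pd.Index(gene_list, name="gene"),
                          columns=models, dtype=object)
    for (gene, model), labels in cells.items():
        matrix.at[gene, model] = ",".join(sorted(labels))

    hist = metadata.set_index("model_id")["histology"]
    freq_rows = []
    for gene in gene_list:
        altered_models = {m for (g, m) in cells if g == gene}
        for h, grp in metadata.groupby("histology"):
            ms = set(grp["model_id"])
            n_alt = len(ms & altered_models)
            freq_rows.append({"gene": gene, "histology": h,
                              "n_models": len(ms), "n_altered": n_alt,
                              "frequency": n_alt / len(ms) if len(ms) else 0.0})
    freq = pd.DataFrame(freq_rows, columns=["gene", "histology", "n_models",
                                            "n_altered", "frequency"])
    return matrix, freq


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> int:
    df.to_csv(path, sep="\t", index=index)
    return len(df)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage over a fixture directory; returns the run manifest."""
    t0 = time.perf_counter()
    in_dir = Path(config.input_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    input_hashes = {p.name: sha256_file(p)
                    for p in sorted(in_dir.iterdir()) if p.is_file()}

    def stage(name):
        def deco(fn):
            try:
                t = time.perf_counter()
                result = fn()
                logger.info("stage %s finished in %.2fs", name,
                            time.perf_counter() - t)
                return result
            except (ValidationError, vh.ConfigurationError) as exc:
                raise PipelineError(name, exc) from exc
        return deco

    bundle = stage("load")(lambda: read_fixtures(in_dir))
    metadata = bundle.metadata
    counts: dict = {}
    outputs: dict = {}

    def emit(name, df, index=False):
        path = out_dir / name
        counts[name] = _write_tsv(df, path, index=index)
        outputs[name] = path

    # ---- variants -----------------------------------------------------------
    def _variants():
        pon = bundle.pon_object()
        germline, somatic = vh.split_germline_somatic(
            bundle.variants, pon, pon_threshold=config.pon_threshold,
            common_af=config.common_af, af_mode=config.af_mode)
        tmb = vh.compute_tmb(somatic, capture_mb=config.capture_mb,
                             model_ids=list(metadata["model_id"]))
        if len(tmb) and set(metadata["phase"]) >= {"diagnosis", "relapse"}:
            phase_cmp = vh.compare_tmb_by_phase(tmb, metadata, group_by="all")
        else:
            phase_cmp = pd.DataFrame(columns=["group", "n_dx", "n_rel",
                                              "median_dx", "median_rel",
                                              "wilcoxon_p", "flagged"])
        return germline, somatic, tmb, phase_cmp

    germline, somatic, tmb, phase_cmp = stage("variant_harmonization")(_variants)
    emit("germline_maf.tsv", germline)
    emit("somatic_maf.tsv", somatic)
    emit("tmb.tsv", tmb)
    emit("tmb_by_phase.tsv", phase_cmp)

    # ---- copy number --------------------------------------------------------
    def _cnv():
        bp_counts, hbd = cn.breakpoint_summary(
            bundle.segments, change_fraction=config.change_fraction,
            hbd_threshold=config.hbd_threshold)
        focal, audit = cn.call_focal_events(
            bundle.segments, bundle.gene_models, fpkm=bundle.fpkm,
            amp_cutoff=config.amp_cutoff, del_cutoff=config.del_cutoff,
            rescue_fpkm=config.rescue_fpkm)
        return bp_counts, hbd, focal, audit

    bp_counts, hbd, focal, focal_audit = stage("copy_number")(_cnv)
    emit("breakpoint_counts.tsv", bp_counts)
    emit("hbd_summary.tsv", hbd)
    emit("focal_calls.tsv", focal)
    emit("focal_audit.tsv", focal_audit)

    # ---- fusions ------------------------------------------------------------
    def _fusions():
        return fc.consensus_fusions(
            bundle.fusion_calls, bundle.tpm,
            min_tpm=config.min_tpm, min_callers=config.min_callers,
            min_recurrent_models=config.min_recurrent_models)

    fus = stage("fusion_consensus")(_fusions)
    emit("fusions_high_confidence.tsv",
         fus["high_confidence"].assign(
             callers=fus["high_confidence"]["callers"].map(
                 lambda s: ",".join(sorted(s)))))
    emit("fusion_audit.tsv",
         fus["audit"].assign(callers=fus["audit"]["callers"].map(
             lambda s: ",".join(sorted(s))) if len(fus["audit"]) else
             fus["audit"].get("callers", pd.Series(dtype=object))))

    # ---- sample QC ----------------------------------------------------------
    def _qc():
        verdicts = []
        germ_vaf = germline.assign(vaf=germline["t_alt_count"] / germline["t_depth"]) \
            if len(germline) else germline.assign(vaf=pd.Series(dtype=float))
        for model in metadata["model_id"]:
            v = germ_vaf.loc[germ_vaf["Tumor_Sample_Barcode"] == model, "vaf"]
            verdicts.append(qc.vaf_skewness(
                v, model_id=model, min_sites=config.min_sites,
                flag_threshold=config.skew_threshold))
        obs = bundle.vaf_observations
        for model in metadata.loc[metadata["has_rna"], "model_id"]:
            wes = obs[(obs["model_id"] == model) & (obs["source"] == "WES")]
            rna = obs[(obs["model_id"] == model) & (obs["source"] == "RNA")]
            verdicts.append(qc.identity_correlation(
                wes, rna, model_id=model, min_depth=config.min_depth,
                match_threshold=config.match_threshold))
        verdict_df = qc.verdicts_to_frame(verdicts)
        samples_ct = bundle.ct[bundle.ct["sample_id"] != REFERENCE_SAMPLE_ID]
        if len(samples_ct):
            human = qc.percent_human_table(samples_ct, bundle.reference_cts())
        else:
            human = pd.DataFrame(columns=["sample_id", "relative_human",
                                          "relative_mouse",
                                          "percent_human_printed",
                                          "fraction_human"])
        return verdict_df, human

    verdict_df, human = stage("sample_qc")(_qc)
    emit("qc_verdicts.tsv", verdict_df)
    emit("human_content.tsv", human)

    # ---- report -------------------------------------------------------------
    def _report():
        return build_alteration_matrix(
            somatic, focal, fus["high_confidence"], metadata,
            gene_list=config.gene_list or None)

    matrix, freq = stage("report")(_report)
    emit("alteration_matrix.tsv", matrix, index=True)
    emit("alteration_frequency.tsv", freq)

    from . import __version__
    manifest = {
        "version": __version__,
        "parameters": config.to_dict(),
        "inputs": input_hashes,
        "outputs": {name: sha256_file(path) for name, path in sorted(outputs.items())},
        "row_counts": dict(sorted(counts.items())),
    }
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline finished in %.2fs", time.perf_counter() - t0)
    return manifest
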