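"""Synthetic PDX cohorts with planted, labelled ground truth.

The generator emulates the statistical structure the downstream analyses
assume — not reads, not realistic mutational spectra.  Per model it plants:

* common germline SNPs drawn from a shared site pool (each pool site is carried
  by >5 panel normals and exceeds 0.005 allele frequency in at least one
  population database), rare germline variants (few/no panel carriers, AF
  below 0.005), private somatic variants, and COSMIC-flagged variants that the
  germline rules would otherwise misclassify (scavenge-back cases);
* qualifying somatic substitution counts drawn Poisson with phase-of-therapy-
  specific means (mutations/Mb x capture size), so relapse models carry more
  mutations than diagnosis models when so configured;
* copy-number segment profiles with an exact requested number of >=10%
  adjacent-segment transitions per chromosome, plus focal amplification /
  homozygous-deletion segments over named genes with controlled expression;
* fusion calls across the four caller dialects covering every planted class:
  true recurrent pairs, two-caller singletons, a filtered-then-scavenged
  driver, promiscuous partners, single-caller noise, read-throughs, GTEx
  normal chimeras, cross-histology artifacts, and unexpressed pairs;
* contamination scenarios: a per-model contaminant fraction c that left-shifts
  heterozygous VAFs to 0.5*(1-c) and contributes mouse template to the qPCR
  CT table.

Every planted entity is recorded in the ground-truth tables, so recovery can
be checked class by class.  All randomness flows from the single config seed;
identical (config, seed) yields byte-identical fixtures.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from ._common import (AUTOSOMES, CHROM_LENGTHS, ConfigurationError,
                      normalize_chrom)
from .fusion_consensus import CALLERS, FUSION_CALL_COLUMNS
from .sample_qc import CT_COLUMNS, VAF_OBS_COLUMNS
from .variant_harmonization import MAF_COLUMNS, PanelOfNormals

_BASES = np.array(list("ACGT"))

# variant classifications used for non-qualifying plantings; rare germline and
# scavenged variants are drawn from these so the planted qualifying-SNV count
# per model is exactly recoverable as the TMB numerator
_NONQUALIFYING = ["Silent", "Intron", "Splice_Site", "In_Frame_Del"]
_OTHER_SOMATIC = ["Silent", "Splice_Site", "Frame_Shift_Del", "Frame_Shift_Ins",
                  "In_Frame_Del", "Intron"]
_OTHER_SOMATIC_P = [0.30, 0.10, 0.20, 0.15, 0.10, 0.15]

GT_VARIANT_CLASSES = ("common_germline", "rare_germline", "somatic",
                      "cosmic_scavenged")

REFERENCE_SAMPLE_ID = "REFERENCE"


@dataclass
class FocalEventSpec:
    """One planted focal copy-number event."""
    model_id: str
    gene: str
    event: str                      # amplification | homozygous_deletion
    lrr: float = None               # default: +1.0 amp, -2.5 deletion
    expressed: bool = False         # deletions: FPKM >= 5 in this model?

    def __post_init__(self) -> None:
        if self.event not in ("amplification", "homozygous_deletion"):
            raise ConfigurationError(
                f"focal_plan: unknown event {self.event!r} for {self.gene}")
        if self.lrr is None:
            self.lrr = 1.0 if self.event == "amplification" else -2.5


@dataclass
class FusionPlan:
    """Counts of planted fusion entities per class (see module docstring)."""
    n_true_recurrent: int = 2       # pairs, each planted in 2 models of one histology
    n_true_two_caller: int = 2
    n_driver: int = 1
    driver_pair: list = field(default_factory=lambda: ["EWSR1", "FLI1"])
    n_promiscuous: int = 1          # 5' gene fused to 2 partners in one histology
    n_single_caller: int = 3
    n_read_through: int = 2
    n_gtex: int = 1
    n_cross_histology: int = 2
    n_unexpressed: int = 2

    def __post_init__(self) -> None:
        for f in ("n_true_recurrent", "n_true_two_caller", "n_driver",
                  "n_promiscuous", "n_single_caller", "n_read_through",
                  "n_gtex", "n_cross_histology", "n_unexpressed"):
            if getattr(self, f) < 0:
                raise ConfigurationError(f"fusion_plan.{f} must be >= 0")


# pairs re-used for planted GTEx artifacts (subset of the shipped GTEx list)
_GTEX_PAIRS = [["KANSL1", "ARL17A"], ["TFG", "GPR128"], ["CTBS", "GNG5"],
               ["SLC45A3", "ELK4"]]


@dataclass
class CohortConfig:
    """Everything the generator needs; all rates are per-model expectations."""
    n_models: int = 30
    histologies: dict = None    # label -> model count; default: even 3-way split
    diagnosis_fraction: float = 0.63      # remainder labelled relapse
    tmb_diagnosis_rate: float = 2.57      # qualifying mutations per Mb
    tmb_relapse_rate: float = 3.08
    capture_mb: float = 45.1
    n_normals: int = 809
    germline_common_rate: float = 200.0
    rare_germline_rate: float = 25.0
    somatic_rate: float = 40.0            # non-qualifying somatic variants
    cosmic_scavenge_rate: float = 2.0     # panel/population hits in COSMIC
    rna_fraction: float = 0.9
    mean_depth: float = 120.0
    vaf_concentration: float = 60.0       # beta concentration of clonal VAFs
    rna_vaf_sigma: float = 0.03
    ct_sigma: float = 0.1                 # qPCR replicate noise, cycles
    breakpoint_plan: dict = field(default_factory=dict)   # model -> chrom -> k
    focal_plan: list = field(default_factory=list)        # FocalEventSpec
    fusion_plan: FusionPlan = field(default_factory=FusionPlan)
    contamination_plan: dict = field(default_factory=dict)  # model -> fraction
    seed: int = 0

    def resolved_histologies(self) -> dict:
        if self.histologies is not None:
            return dict(self.histologies)
        if self.n_models == 0:
            return {}
        labels = ["NBL", "OS", "BCP-ALL"][:max(1, min(3, self.n_models))]
        base, extra = divmod(self.n_models, len(labels))
        return {h: base + (1 if i < extra else 0)
                for i, h in enumerate(labels)}

    def validate(self) -> None:
        for f in ("tmb_diagnosis_rate", "tmb_relapse_rate", "germline_common_rate",
                  "rare_germline_rate", "somatic_rate", "cosmic_scavenge_rate",
                  "mean_depth", "vaf_concentration", "rna_vaf_sigma", "ct_sigma"):
            if getattr(self, f) < 0:
                raise ConfigurationError(f"config field {f} must be >= 0")
        for f in ("diagnosis_fraction", "rna_fraction"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"config field {f} must be in [0, 1]")
        if self.n_models < 0:
            raise ConfigurationError("config field n_models must be >= 0")
        if self.capture_mb <= 0:
            raise ConfigurationError("config field capture_mb must be > 0")
        hist = self.resolved_histologies()
        if sum(hist.values()) != self.n_models:
            raise ConfigurationError(
                "config field histologies: counts must sum to n_models "
                f"({sum(hist.values())} != {self.n_models})")
        for model, frac in self.contamination_plan.items():
            if not 0.0 <= frac < 1.0:
                raise ConfigurationError(
                    f"config field contamination_plan[{model!r}] must be in [0, 1)")
        for model, chroms in self.breakpoint_plan.items():
            for chrom, k in chroms.items():
                if k < 0:
                    raise ConfigurationError(
                        f"config field breakpoint_plan[{model!r}][{chrom!r}] "
                        "must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "focal_plan" in d:
            d["focal_plan"] = [e if isinstance(e, FocalEventSpec)
                               else FocalEventSpec(**e) for e in d["focal_plan"]]
        if "fusion_plan" in d and not isinstance(d["fusion_plan"], FusionPlan):
            d["fusion_plan"] = FusionPlan(**d["fusion_plan"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted labels for every generated entity."""
    variants: pd.DataFrame        # model, chrom, pos, ref, alt, cls, expected_split
    tmb: pd.DataFrame             # model, phase, n_qualifying
    breakpoints: pd.DataFrame     # model, chrom, n_planted
    focal: pd.DataFrame           # model, gene, event, lrr, expressed, expected_retained
    fusions: pd.DataFrame         # model, histology, gene5, gene3, cls, expected_in_final
    contamination: pd.DataFrame   # model, fraction_contaminant, fraction_human


@dataclass
class CohortBundle:
    """A complete synthetic cohort plus its ground truth."""
    config: CohortConfig
    metadata: pd.DataFrame
    variants: pd.DataFrame
    pon: pd.DataFrame
    segments: pd.DataFrame
    gene_models: pd.DataFrame
    fpkm: pd.DataFrame
    tpm: pd.DataFrame
    fusion_calls: pd.DataFrame
    ct: pd.DataFrame
    vaf_observations: pd.DataFrame
    ground_truth: GroundTruth

    def pon_object(self) -> PanelOfNormals:
        return PanelOfNormals.from_dataframe(self.pon, n_normals=self.config.n_normals)

    def reference_cts(self) -> dict:
        ref = self.ct[self.ct["sample_id"] == REFERENCE_SAMPLE_ID]
        return {sp: float(g["ct"].mean()) for sp, g in ref.groupby("species")}

    def equals(self, other: "CohortBundle") -> bool:
        """Field-for-field equality (exact values, lax dtypes on empties)."""
        from pandas.testing import assert_frame_equal
        if self.config.to_dict() != other.config.to_dict():
            return False
        for name in ("metadata", "variants", "pon", "segments", "gene_models",
                     "fpkm", "tpm", "fusion_calls", "ct", "vaf_observations"):
            try:
                assert_frame_equal(getattr(self, name), getattr(other, name),
                                   check_dtype=False, check_index_type=False,
                                   check_column_type=False)
            except AssertionError:
                return False
        for name in ("variants", "tmb", "breakpoints", "focal", "fusions",
                     "contamination"):
            try:
                assert_frame_equal(getattr(self.ground_truth, name),
                                   getattr(other.ground_truth, name),
                                   check_dtype=False, check_index_type=False,
                                   check_column_type=False)
            except AssertionError:
                return False
        return True


def default_gene_models() -> pd.DataFrame:
    """Toy gene annotation: hallmark pediatric-cancer genes at roughly their
    real loci plus background genes spread over the autosomes."""
    rows = [
        ("MYCN", "2", 15_800_000, 16_100_000),
        ("ALK", "2", 29_000_000, 30_000_000),
        ("CDKN2A", "9", 21_900_000, 22_000_000),
        ("CDKN2B", "9", 22_000_001, 22_100_000),
        ("WT1", "11", 32_400_000, 32_500_000),
        ("CDK4", "12", 58_100_000, 58_200_000),
        ("MDM2", "12", 69_200_000, 69_300_000),
        ("TP53", "17", 7_500_000, 7_600_000),
        ("SMARCB1", "22", 24_100_000, 24_200_000),
        ("ATRX", "X", 76_700_000, 76_900_000),
    ]
    for j in range(40):
        chrom = AUTOSOMES[j % 22]
        start = CHROM_LENGTHS[chrom] // 2 + (j // 22) * 3_000_000
        rows.append((f"BG{j:03d}", chrom, start, start + 50_000))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


# --------------------------------------------------------------------------
# generation helpers
# --------------------------------------------------------------------------

def _empty_bundle(config: CohortConfig) -> CohortBundle:
    gt = GroundTruth(
        variants=pd.DataFrame(columns=["model_id", "chrom", "pos", "ref", "alt",
                                       "cls", "expected_split"]),
        tmb=pd.DataFrame(columns=["model_id", "phase", "n_qualifying"]),
        breakpoints=pd.DataFrame(columns=["model_id", "chrom", "n_planted"]),
        focal=pd.DataFrame(columns=["model_id", "gene", "event", "lrr",
                                    "expressed", "expected_retained"]),
        fusions=pd.DataFrame(columns=["model_id", "histology", "gene5", "gene3",
                                      "cls", "expected_in_final"]),
        contamination=pd.DataFrame(columns=["model_id", "fraction_contaminant",
                                            "fraction_human"]),
    )
    return CohortBundle(
        config=config,
        metadata=pd.DataFrame(columns=["model_id", "histology", "phase", "has_rna"]),
        variants=pd.DataFrame(columns=MAF_COLUMNS),
        pon=pd.DataFrame(columns=["Chromosome", "Start_Position",
                                  "Reference_Allele", "Tumor_Seq_Allele2",
                                  "n_carriers"]),
        segments=pd.DataFrame(columns=["model_id", "chrom", "start", "end",
                                       "num_probes", "lrr"]),
        gene_models=default_gene_models(),
        fpkm=pd.DataFrame(index=pd.Index([], name="gene")),
        tpm=pd.DataFrame(index=pd.Index([], name="gene")),
        fusion_calls=pd.DataFrame(columns=FUSION_CALL_COLUMNS),
        ct=pd.DataFrame(columns=CT_COLUMNS),
        vaf_observations=pd.DataFrame(columns=VAF_OBS_COLUMNS),
        ground_truth=gt,
    )


def _random_site(rng: np.random.Generator) -> tuple:
    chrom = AUTOSOMES[rng.integers(22)]
    pos = int(rng.integers(1_000_000, CHROM_LENGTHS[chrom] - 1_000_000))
    ref, alt = rng.choice(4, size=2, replace=False)
    return chrom, pos, str(_BASES[ref]), str(_BASES[alt])


def _make_site_pool(rng, n_sites, carrier_range, af_common) -> pd.DataFrame:
    """Pool of germline sites shared across models.

    ``carrier_range`` is the inclusive panel-carrier range; ``af_common=True``
    plants ExAC AF > 0.005 (common), otherwise all AFs < 0.005 (rare).
    """
    rows = []
    for _ in range(n_sites):
        chrom, pos, ref, alt = _random_site(rng)
        carriers = int(rng.integers(carrier_range[0], carrier_range[1] + 1))
        if af_common:
            exac = float(rng.uniform(0.006, 0.5))
            tg = float(rng.uniform(0.0, 0.5)) if rng.random() < 0.5 else np.nan
            esp = float(rng.uniform(0.0, 0.5)) if rng.random() < 0.5 else np.nan
        else:
            exac = float(rng.uniform(0.0, 0.0049)) if rng.random() < 0.7 else np.nan
            tg = float(rng.uniform(0.0, 0.0049)) if rng.random() < 0.3 else np.nan
            esp = np.nan
        rows.append((chrom, pos, ref, alt, carriers, exac, tg, esp))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "carriers",
                                       "exac", "tg", "esp"])


def _observe_vaf(rng, p_true: float, depth: float, contamination: float) -> tuple:
    d = max(10, int(rng.poisson(depth)))
    p = min(1.0, p_true * (1.0 - contamination))
    alt = int(rng.binomial(d, p))
    return alt, d


def _variant_classification_alleles(rng, classification: str) -> tuple:
    """(variant_type, ref, alt) consistent with the classification."""
    b = rng.choice(4, size=3, replace=False)
    b0, b1, b2 = (str(_BASES[i]) for i in b)
    if classification in ("Frame_Shift_Del", "In_Frame_Del"):
        return "DEL", b0 + b1, b0
    if classification == "Frame_Shift_Ins":
        return "INS", b0, b0 + b2
    return "SNP", b0, b1


def _build_chromosome_segments(rng, model, chrom, plan_k, focal_events,
                               gene_loc) -> tuple:
    """Segments for one (model, chromosome); returns (rows, n_transitions)
    where n_transitions counts adjacent pairs with >= 10% linear copy change."""
    length = CHROM_LENGTHS[chrom]
    rows = []

    def seg(start, end, lrr):
        rows.append({"model_id": model, "chrom": chrom, "start": int(start),
                     "end": int(end), "num_probes": max(5, int((end - start) // 50_000)),
                     "lrr": float(lrr)})

    if focal_events:
        events = sorted(focal_events, key=lambda e: gene_loc[e.gene][0])
        lrrs = [0.0]
        prev_end = 0
        for e in events:
            gstart, gend = gene_loc[e.gene]
            if gstart <= prev_end:
                raise ConfigurationError(
                    f"focal_plan: overlapping/boundary genes on chr{chrom} "
                    f"for model {model}")
            if gstart > prev_end + 1:
                seg(prev_end + 1, gstart - 1, rng.normal(0, 0.02))
                lrrs.append(rows[-1]["lrr"])
            seg(gstart, gend, e.lrr)
            lrrs.append(e.lrr)
            prev_end = gend
        if prev_end < length:
            seg(prev_end + 1, length, rng.normal(0, 0.02))
            lrrs.append(rows[-1]["lrr"])
        arr = np.asarray(lrrs[1:]) - np.asarray(lrrs[:-1])
        n_transitions = int((np.abs(np.exp2(arr) - 1.0) >= 0.10).sum())
        return rows, n_transitions

    if plan_k > 0:
        # draw k distinct cut positions; segment i is [cut_{i-1}+1, cut_i]
        cut_set: set = set()
        while len(cut_set) < plan_k:
            cut_set.add(int(rng.integers(2, length - 1)))
        cuts = sorted(cut_set)
        starts = [1] + [c + 1 for c in cuts]
        ends = cuts + [length]
        lrr = 0.0
        sign = 1.0 if rng.random() < 0.5 else -1.0
        for i, (s, e) in enumerate(zip(starts, ends)):
            seg(s, e, lrr)
            if i < plan_k:
                # every step is >= 0.25 in log2, i.e. >= 18.9% linear change
                step = float(rng.uniform(0.25, 0.8))
                if not -1.2 <= lrr + sign * step <= 1.5:
                    sign = -sign
                lrr = lrr + sign * step
                if rng.random() < 0.4:
                    sign = -sign
        return rows, plan_k

    seg(1, length, rng.normal(0, 0.02))
    return rows, 0


# --------------------------------------------------------------------------
# main entry points
# --------------------------------------------------------------------------

def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate a complete synthetic cohort (see module docstring)."""
    config.validate()
    if config.n_models == 0:
        return _empty_bundle(config)
    rng = np.random.default_rng(config.seed)

    # ---- metadata -----------------------------------------------------------
    model_ids = [f"M{i + 1:03d}" for i in range(config.n_models)]
    hist_counts = config.resolved_histologies()
    histology = []
    for h in sorted(hist_counts):
        histology += [h] * hist_counts[h]
    n_dx = int(round(config.diagnosis_fraction * config.n_models))
    phase_pool = np.array(["diagnosis"] * n_dx
                          + ["relapse"] * (config.n_models - n_dx))
    phase = phase_pool[rng.permutation(config.n_models)]
    has_rna = rng.random(config.n_models) < config.rna_fraction
    metadata = pd.DataFrame({"model_id": model_ids, "histology": histology,
                             "phase": phase, "has_rna": has_rna})
    meta_idx = metadata.set_index("model_id")

    unknown_models = (set(config.breakpoint_plan) | set(config.contamination_plan)
                      | {e.model_id for e in config.focal_plan}) - set(model_ids)
    if unknown_models:
        raise ConfigurationError(
            f"plans reference unknown model ids: {sorted(unknown_models)}")

    gene_models = default_gene_models()
    extra = [e.gene for e in config.focal_plan
             if e.gene not in set(gene_models["gene"])]
    if extra:
        raise ConfigurationError(f"focal_plan: unknown genes {sorted(set(extra))}")
    gene_loc = {r.gene: (r.start, r.end) for r in gene_models.itertuples(index=False)}
    gene_chrom = {r.gene: r.chrom for r in gene_models.itertuples(index=False)}

    contamination = {m: float(config.contamination_plan.get(m, 0.0))
                     for m in model_ids}

    # ---- germline site pools and panel of normals ---------------------------
    n_common_pool = max(50, int(3 * config.germline_common_rate))
    n_rare_pool = max(20, int(3 * config.rare_germline_rate))
    common_pool = _make_site_pool(rng, n_common_pool,
                                  (6, min(120, config.n_normals)), af_common=True)
    rare_pool = _make_site_pool(rng, n_rare_pool, (0, 5), af_common=False)
    scavenge_pool = _make_site_pool(
        rng, max(10, int(3 * config.cosmic_scavenge_rate)),
        (6, min(120, config.n_normals)), af_common=True)

    pon_rows = []
    for pool in (common_pool, rare_pool, scavenge_pool):
        carried = pool[pool["carriers"] >= 1]
        for r in carried.itertuples(index=False):
            pon_rows.append((r.chrom, r.pos, r.ref, r.alt, r.carriers))
    pon = (pd.DataFrame(pon_rows, columns=["Chromosome", "Start_Position",
                                           "Reference_Allele",
                                           "Tumor_Seq_Allele2", "n_carriers"])
           .drop_duplicates(subset=["Chromosome", "Start_Position",
                                    "Reference_Allele", "Tumor_Seq_Allele2"])
           .sort_values(["Chromosome", "Start_Position"]).reset_index(drop=True))

    # ---- variants -----------------------------------------------------------
    genes_for_variants = list(gene_models["gene"])
    maf_rows, gt_var_rows, gt_tmb_rows = [], [], []

    def add_variant(model, chrom, pos, ref, alt, classification, vtype,
                    p_true, exac, tg, esp, cosmic, cls, expected_split, gene=None):
        alt_n, depth = _observe_vaf(rng, p_true, config.mean_depth,
                                    contamination[model])
        maf_rows.append({
            "Hugo_Symbol": gene or genes_for_variants[
                rng.integers(len(genes_for_variants))],
            "Chromosome": chrom, "Start_Position": pos,
            "End_Position": pos + len(ref) - 1,
            "Reference_Allele": ref, "Tumor_Seq_Allele2": alt,
            "Variant_Classification": classification, "Variant_Type": vtype,
            "Tumor_Sample_Barcode": model,
            "t_alt_count": alt_n, "t_depth": depth,
            "ExAC_AF": exac, "TG_AF": tg, "ESP_AF": esp, "COSMIC_flag": cosmic,
        })
        gt_var_rows.append({"model_id": model, "chrom": chrom, "pos": pos,
                            "ref": ref, "alt": alt, "cls": cls,
                            "expected_split": expected_split})

    for mi, model in enumerate(model_ids):
        ph = meta_idx.at[model, "phase"]
        rate = (config.tmb_diagnosis_rate if ph == "diagnosis"
                else config.tmb_relapse_rate)

        # common germline from the shared pool
        k = min(int(rng.poisson(config.germline_common_rate)), n_common_pool)
        for i in rng.choice(n_common_pool, size=k, replace=False):
            s = common_pool.iloc[int(i)]
            het = rng.random() < 2 / 3
            add_variant(model, s.chrom, int(s.pos), s.ref, s.alt,
                        "Missense_Mutation" if rng.random() < 0.5 else "Silent",
                        "SNP", 0.5 if het else 1.0, s.exac, s.tg, s.esp,
                        False, "common_germline", "germline")

        # rare germline (kept in the somatic MAF by design)
        k = min(int(rng.poisson(config.rare_germline_rate)), n_rare_pool)
        for i in rng.choice(n_rare_pool, size=k, replace=False):
            s = rare_pool.iloc[int(i)]
            cl = _NONQUALIFYING[rng.integers(len(_NONQUALIFYING))]
            vtype, ref, alt = (("SNP", s.ref, s.alt) if cl not in
                               ("In_Frame_Del",) else
                               ("DEL", s.ref + s.alt, s.ref))
            add_variant(model, s.chrom, int(s.pos), ref, alt, cl, vtype,
                        0.5 if rng.random() < 2 / 3 else 1.0,
                        s.exac, s.tg, s.esp, False, "rare_germline", "somatic")

        # COSMIC scavenge-back cases: look germline, flagged COSMIC
        n_pool = len(scavenge_pool)
        k = min(int(rng.poisson(config.cosmic_scavenge_rate)), n_pool)
        for i in rng.choice(n_pool, size=k, replace=False):
            s = scavenge_pool.iloc[int(i)]
            add_variant(model, s.chrom, int(s.pos), s.ref, s.alt,
                        "Silent", "SNP", 0.5, s.exac, s.tg, s.esp, True,
                        "cosmic_scavenged", "somatic")

        # qualifying somatic substitutions (drive TMB)
        n_qual = int(rng.poisson(rate * config.capture_mb))
        gt_tmb_rows.append({"model_id": model, "phase": ph,
                            "n_qualifying": n_qual})
        for _ in range(n_qual):
            chrom, pos, ref, alt = _random_site(rng)
            cl = "Missense_Mutation" if rng.random() < 0.8 else "Nonsense_Mutation"
            p = float(rng.beta(0.5 * config.vaf_concentration,
                               0.5 * config.vaf_concentration))
            cosmic = bool(rng.random() < 0.05)
            add_variant(model, chrom, pos, ref, alt, cl, "SNP", p,
                        np.nan, np.nan, np.nan, cosmic, "somatic", "somatic")

        # other somatic variant classes (do not count toward TMB)
        n_other = int(rng.poisson(config.somatic_rate))
        for _ in range(n_other):
            chrom, pos, _, _ = _random_site(rng)
            cl = _OTHER_SOMATIC[rng.choice(len(_OTHER_SOMATIC),
                                           p=_OTHER_SOMATIC_P)]
            vtype, ref, alt = _variant_classification_alleles(rng, cl)
            p = float(rng.beta(0.5 * config.vaf_concentration,
                               0.5 * config.vaf_concentration))
            add_variant(model, chrom, pos, ref, alt, cl, vtype, p,
                        np.nan, np.nan, np.nan, False, "somatic", "somatic")

    variants = pd.DataFrame(maf_rows, columns=MAF_COLUMNS)
    gt_variants = pd.DataFrame(gt_var_rows)
    gt_tmb = pd.DataFrame(gt_tmb_rows)

    # ---- segments -----------------------------------------------------------
    focal_by_model_chrom: dict = {}
    for e in config.focal_plan:
        focal_by_model_chrom.setdefault(
            (e.model_id, normalize_chrom(gene_chrom[e.gene])), []).append(e)
    seg_rows, gt_bp_rows, gt_focal_rows = [], [], []
    for model in model_ids:
        plan = {normalize_chrom(c): int(k)
                for c, k in config.breakpoint_plan.get(model, {}).items()}
        for chrom in list(AUTOSOMES) + ["X", "Y"]:
            focal_here = focal_by_model_chrom.get((model, chrom), [])
            if focal_here and plan.get(chrom, 0) > 0:
                raise ConfigurationError(
                    f"breakpoint_plan and focal_plan both target model {model} "
                    f"chr{chrom}; plant them on different chromosomes")
            rows, n_trans = _build_chromosome_segments(
                rng, model, chrom, plan.get(chrom, 0), focal_here, gene_loc)
            seg_rows += rows
            if chrom in AUTOSOMES and (plan.get(chrom, 0) > 0 or focal_here):
                gt_bp_rows.append({"model_id": model, "chrom": chrom,
                                   "n_planted": n_trans})
    for e in config.focal_plan:
        has_rna_m = bool(meta_idx.at[e.model_id, "has_rna"])
        retained = (e.event == "amplification"
                    or not has_rna_m or not e.expressed)
        gt_focal_rows.append({"model_id": e.model_id, "gene": e.gene,
                              "event": e.event, "lrr": e.lrr,
                              "expressed": bool(e.expressed),
                              "expected_retained": retained})
    segments = pd.DataFrame(seg_rows, columns=["model_id", "chrom", "start",
                                               "end", "num_probes", "lrr"])
    gt_breakpoints = pd.DataFrame(
        gt_bp_rows, columns=["model_id", "chrom", "n_planted"])
    gt_focal = pd.DataFrame(
        gt_focal_rows, columns=["model_id", "gene", "event", "lrr",
                                "expressed", "expected_retained"])

    # ---- fusions ------------------------------------------------------------
    rna_models = metadata.loc[metadata["has_rna"], "model_id"].tolist()
    by_hist: dict = {}
    for m in rna_models:
        by_hist.setdefault(meta_idx.at[m, "histology"], []).append(m)
    hists = sorted(by_hist)
    plan = config.fusion_plan

    need_two_models = plan.n_true_recurrent + plan.n_promiscuous
    if need_two_models and not any(len(v) >= 2 for v in by_hist.values()):
        raise ConfigurationError(
            "fusion_plan: recurrent/promiscuous classes need a histology with "
            ">= 2 RNA models")
    if plan.n_cross_histology and len(hists) < 2:
        raise ConfigurationError(
            "fusion_plan.n_cross_histology needs >= 2 histologies with RNA models")
    if plan.n_gtex > len(_GTEX_PAIRS):
        raise ConfigurationError(
            f"fusion_plan.n_gtex must be <= {len(_GTEX_PAIRS)}")

    gene_counter = [0]

    def new_gene() -> str:
        gene_counter[0] += 1
        return f"FG{gene_counter[0]:04d}"

    call_rows, gt_fusion_rows = [], []
    expressed_fusion_genes: set = set()
    silent_fusion_genes: set = set()
    expressed_in_model: list = []   # (gene, model) pairs to boost

    def pick_model(pool_hists=None, k=1):
        pool_hists = pool_hists or hists
        h = pool_hists[int(rng.integers(len(pool_hists)))]
        ms = by_hist[h]
        idx = rng.choice(len(ms), size=min(k, len(ms)), replace=False)
        return h, [ms[int(i)] for i in idx]

    def add_call(model, hist, g5, g3, caller, frame, rt):
        bp_c5 = AUTOSOMES[rng.integers(22)]
        bp_c3 = AUTOSOMES[rng.integers(22)]
        call_rows.append({
            "model_id": model, "histology": hist, "caller": caller,
            "gene5": g5, "gene3": g3, "frame": frame, "read_through": rt,
            "breakpoint5": f"chr{bp_c5}:{int(rng.integers(1e6, 1e8))}",
            "breakpoint3": f"chr{bp_c3}:{int(rng.integers(1e6, 1e8))}",
        })

    def add_gt(model, hist, g5, g3, cls, in_final):
        gt_fusion_rows.append({"model_id": model, "histology": hist,
                               "gene5": g5, "gene3": g3, "cls": cls,
                               "expected_in_final": in_final})

    def callers_sample(k):
        idx = rng.choice(len(CALLERS), size=k, replace=False)
        return [CALLERS[int(i)] for i in sorted(idx)]

    multi = [h for h in hists if len(by_hist[h]) >= 2]
    if rna_models:
        for j in range(plan.n_true_recurrent):
            g5, g3 = new_gene(), new_gene()
            h = multi[int(rng.integers(len(multi)))]
            ms = [by_hist[h][int(i)]
                  for i in rng.choice(len(by_hist[h]), size=2, replace=False)]
            for m in ms:
                c = callers_sample(1)[0]
                add_call(m, h, g5, g3, c, "in-frame", False)
                add_gt(m, h, g5, g3, "true_recurrent", True)
            if j == 0:   # exact duplicate row from one caller: must collapse
                last = dict(call_rows[-1])
                call_rows.append(last)
            expressed_fusion_genes.update([g5, g3])
            expressed_in_model += [(g5, m) for m in ms] + [(g3, m) for m in ms]

        for _ in range(plan.n_true_two_caller):
            g5, g3 = new_gene(), new_gene()
            h, (m,) = pick_model(k=1)
            for c in callers_sample(2):
                add_call(m, h, g5, g3, c, "in-frame", False)
            add_gt(m, h, g5, g3, "true_two_caller", True)
            expressed_fusion_genes.update([g5, g3])
            expressed_in_model += [(g5, m), (g3, m)]

        driver_pairs = [list(plan.driver_pair)]
        for j in range(plan.n_driver):
            g5, g3 = driver_pairs[j % len(driver_pairs)]
            h, (m,) = pick_model(k=1)
            add_call(m, h, g5, g3, callers_sample(1)[0], "unknown", False)
            add_gt(m, h, g5, g3, "driver", True)
            expressed_fusion_genes.update([g5, g3])
            expressed_in_model += [(g5, m), (g3, m)]

        for _ in range(plan.n_promiscuous):
            gp, q1, q2 = new_gene(), new_gene(), new_gene()
            h = multi[int(rng.integers(len(multi)))]
            ms = [by_hist[h][int(i)]
                  for i in rng.choice(len(by_hist[h]), size=2, replace=False)]
            for m, q in zip(ms, (q1, q2)):
                add_call(m, h, gp, q, callers_sample(1)[0], "frameshift", False)
                add_gt(m, h, gp, q, "true_promiscuous", True)
            expressed_fusion_genes.update([gp, q1, q2])
            expressed_in_model += [(gp, ms[0]), (gp, ms[1]),
                                   (q1, ms[0]), (q2, ms[1])]

        for _ in range(plan.n_single_caller):
            g5, g3 = new_gene(), new_gene()
            h, (m,) = pick_model(k=1)
            add_call(m, h, g5, g3, callers_sample(1)[0], "in-frame", False)
            add_gt(m, h, g5, g3, "artifact_single_caller", False)
            expressed_fusion_genes.update([g5, g3])

        for _ in range(plan.n_read_through):
            g5, g3 = new_gene(), new_gene()
            h, (m,) = pick_model(k=1)
            for c in callers_sample(2):
                add_call(m, h, g5, g3, c, "in-frame", True)
            add_gt(m, h, g5, g3, "artifact_read_through", False)
            expressed_fusion_genes.update([g5, g3])

        for j in range(plan.n_gtex):
            g5, g3 = _GTEX_PAIRS[j]
            h, (m,) = pick_model(k=1)
            for c in callers_sample(2):
                add_call(m, h, g5, g3, c, "in-frame", False)
            add_gt(m, h, g5, g3, "artifact_gtex", False)
            expressed_fusion_genes.update([g5, g3])

        for _ in range(plan.n_cross_histology):
            g5, g3 = new_gene(), new_gene()
            h1, h2 = [hists[int(i)]
                      for i in rng.choice(len(hists), size=2, replace=False)]
            for h in (h1, h2):
                m = by_hist[h][int(rng.integers(len(by_hist[h])))]
                for c in callers_sample(2):
                    add_call(m, h, g5, g3, c, "in-frame", False)
                add_gt(m, h, g5, g3, "artifact_cross_histology", False)
            expressed_fusion_genes.update([g5, g3])

        for _ in range(plan.n_unexpressed):
            g5, g3 = new_gene(), new_gene()
            h, (m,) = pick_model(k=1)
            for c in callers_sample(2):
                add_call(m, h, g5, g3, c, "in-frame", False)
            add_gt(m, h, g5, g3, "artifact_unexpressed", False)
            silent_fusion_genes.update([g5, g3])

    # canonical row order so per-caller serialization round-trips exactly
    fusion_calls = (pd.DataFrame(call_rows, columns=FUSION_CALL_COLUMNS)
                    .sort_values(["caller", "model_id", "gene5", "gene3"],
                                 kind="mergesort").reset_index(drop=True))
    gt_fusions = pd.DataFrame(gt_fusion_rows,
                              columns=["model_id", "histology", "gene5",
                                       "gene3", "cls", "expected_in_final"])

    # ---- expression matrices ------------------------------------------------
    all_genes = (list(gene_models["gene"])
                 + sorted(expressed_fusion_genes - set(gene_models["gene"]))
                 + sorted(silent_fusion_genes))
    fpkm = pd.DataFrame(
        rng.lognormal(np.log(8.0), 1.0, size=(len(all_genes), len(rna_models))),
        index=pd.Index(all_genes, name="gene"), columns=rna_models)
    tpm = pd.DataFrame(
        rng.lognormal(np.log(10.0), 1.0, size=(len(all_genes), len(rna_models))),
        index=pd.Index(all_genes, name="gene"), columns=rna_models)
    for g in sorted(silent_fusion_genes):
        if len(rna_models):
            tpm.loc[g] = rng.uniform(0.01, 0.5, size=len(rna_models))
            fpkm.loc[g] = rng.uniform(0.01, 0.5, size=len(rna_models))
    for g, m in expressed_in_model:
        if m in tpm.columns:
            tpm.at[g, m] = float(rng.uniform(5.0, 50.0))
    for e in config.focal_plan:
        if e.model_id in fpkm.columns:
            if e.event == "homozygous_deletion":
                fpkm.at[e.gene, e.model_id] = float(
                    rng.uniform(20.0, 80.0) if e.expressed
                    else rng.uniform(0.1, 1.0))
            else:
                fpkm.at[e.gene, e.model_id] = float(rng.uniform(30.0, 100.0))

    # ---- qPCR CT table ------------------------------------------------------
    ref_cts = {"human": 25.0, "mouse": 24.5}
    ct_rows = []
    for sp in ("human", "mouse"):
        for rep in range(1, 4):
            ct_rows.append({"sample_id": REFERENCE_SAMPLE_ID, "species": sp,
                            "replicate": rep,
                            "ct": float(ref_cts[sp] + rng.normal(0, config.ct_sigma))})
    gt_cont_rows = []
    for model in model_ids:
        c = contamination[model]
        scale = float(rng.uniform(0.5, 2.0))     # total template amount
        rel = {"human": scale * (1.0 - c), "mouse": scale * c}
        for sp in ("human", "mouse"):
            for rep in range(1, 4):
                if rel[sp] <= 0:
                    ct = 40.0 + float(rng.normal(0, config.ct_sigma))
                else:
                    ct = float(ref_cts[sp] - np.log2(rel[sp])
                               + rng.normal(0, config.ct_sigma))
                ct_rows.append({"sample_id": model, "species": sp,
                                "replicate": rep, "ct": ct})
        gt_cont_rows.append({"model_id": model, "fraction_contaminant": c,
                             "fraction_human": 1.0 - c})
    ct = pd.DataFrame(ct_rows, columns=CT_COLUMNS)
    gt_contamination = pd.DataFrame(gt_cont_rows,
                                    columns=["model_id", "fraction_contaminant",
                                             "fraction_human"])

    # ---- VAF observations (WES + RNA) --------------------------------------
    vaf_rows = []
    for r in variants.itertuples(index=False):
        vaf_rows.append({"model_id": r.Tumor_Sample_Barcode,
                         "chrom": r.Chromosome, "pos": r.Start_Position,
                         "ref": r.Reference_Allele, "alt": r.Tumor_Seq_Allele2,
                         "source": "WES",
                         "vaf": r.t_alt_count / r.t_depth, "depth": r.t_depth})
    rna_set = set(rna_models)
    for row in list(vaf_rows):
        if row["model_id"] in rna_set and rng.random() < 0.85:
            vaf_rows.append({**row, "source": "RNA",
                             "vaf": float(np.clip(
                                 row["vaf"] + rng.normal(0, config.rna_vaf_sigma),
                                 0.0, 1.0)),
                             "depth": max(1, int(rng.poisson(60)))})
    vaf_observations = pd.DataFrame(vaf_rows, columns=VAF_OBS_COLUMNS)

    gt = GroundTruth(variants=gt_variants, tmb=gt_tmb,
                     breakpoints=gt_breakpoints, focal=gt_focal,
                     fusions=gt_fusions, contamination=gt_contamination)
    return CohortBundle(config=config, metadata=metadata, variants=variants,
                        pon=pon, segments=segments, gene_models=gene_models,
                        fpkm=fpkm, tpm=tpm, fusion_calls=fusion_calls, ct=ct,
                        vaf_observations=vaf_observations, ground_truth=gt)


# --------------------------------------------------------------------------
# fixtures on disk
# --------------------------------------------------------------------------

FIXTURE_FILES = {
    "metadata": "metadata.tsv",
    "maf": "maf.tsv",
    "pon": "pon.tsv",
    "seg": "seg.tsv",
    "gene_models": "gene_models.tsv",
    "fpkm": "fpkm.tsv",
    "tpm": "tpm.tsv",
    "ct": "ct.tsv",
    "vaf_observations": "vaf_observations.tsv",
    "gt_variants": "gt_variants.tsv",
    "gt_tmb": "gt_tmb.tsv",
    "gt_breakpoints": "gt_breakpoints.tsv",
    "gt_focal": "gt_focal.tsv",
    "gt_fusions": "gt_fusions.tsv",
    "gt_contamination": "gt_contamination.tsv",
}


def write_fixtures(bundle: CohortBundle, out_dir) -> dict:
    """Serialize a bundle to plain-text fixtures; returns {filename: n_rows}.

    Writes the MAF, panel, SEG, expression, per-caller fusion, CT, VAF and
    ground-truth tables plus config.yaml and manifest.json.  Reading the
    directory back with :func:`read_fixtures` reproduces the bundle exactly.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"fixture directory {out} is not writable: {exc}") from exc

    manifest: dict = {}
    manifest[FIXTURE_FILES["metadata"]] = pio.write_metadata(
        bundle.metadata, out / FIXTURE_FILES["metadata"])
    manifest[FIXTURE_FILES["maf"]] = pio.write_maf(bundle.variants,
                                                   out / FIXTURE_FILES["maf"])
    manifest[FIXTURE_FILES["pon"]] = pio.write_pon(bundle.pon,
                                                   out / FIXTURE_FILES["pon"])
    manifest[FIXTURE_FILES["seg"]] = pio.write_seg(bundle.segments,
                                                   out / FIXTURE_FILES["seg"])
    manifest[FIXTURE_FILES["gene_models"]] = pio.write_gene_models(
        bundle.gene_models, out / FIXTURE_FILES["gene_models"])
    manifest[FIXTURE_FILES["fpkm"]] = pio.write_expression(
        bundle.fpkm, out / FIXTURE_FILES["fpkm"])
    manifest[FIXTURE_FILES["tpm"]] = pio.write_expression(
        bundle.tpm, out / FIXTURE_FILES["tpm"])
    for caller in CALLERS:
        fn = f"fusions_{caller}.tsv"
        manifest[fn] = pio.write_fusion_calls(bundle.fusion_calls, caller,
                                              out / fn)
    manifest[FIXTURE_FILES["ct"]] = pio.write_ct(bundle.ct,
                                                 out / FIXTURE_FILES["ct"])
    manifest[FIXTURE_FILES["vaf_observations"]] = pio.write_vaf_observations(
        bundle.vaf_observations, out / FIXTURE_FILES["vaf_observations"])
    gt = bundle.ground_truth
    for name in ("variants", "tmb", "breakpoints", "focal", "fusions",
                 "contamination"):
        fn = FIXTURE_FILES[f"gt_{name}"]
        df = getattr(gt, name)
        df.to_csv(out / fn, sep="\t", index=False)
        manifest[fn] = len(df)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(bundle.config.to_dict(), fh, sort_keys=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump({"files": manifest}, fh, indent=2, sort_keys=True)
    return manifest


_GT_BOOLS = {"focal": ["expressed", "expected_retained"],
             "fusions": ["expected_in_final"]}
_GT_INTS = {"variants": ["pos"], "tmb": ["n_qualifying"],
            "breakpoints": ["n_planted"]}


def read_fixtures(fixture_dir) -> CohortBundle:
    """Reconstruct a CohortBundle from a fixture directory."""
    d = Path(fixture_dir)
    config = CohortConfig.from_dict(yaml.safe_load((d / "config.yaml").read_text()))
    metadata = pio.read_metadata(d / FIXTURE_FILES["metadata"])
    calls = (pd.concat(
        [pio.read_fusion_calls(d / f"fusions_{c}.tsv", c, metadata=metadata)
         for c in CALLERS], ignore_index=True)
        .sort_values(["caller", "model_id", "gene5", "gene3"], kind="mergesort")
        .reset_index(drop=True))
    gt_frames = {}
    for name in ("variants", "tmb", "breakpoints", "focal", "fusions",
                 "contamination"):
        df = pd.read_csv(d / FIXTURE_FILES[f"gt_{name}"], sep="\t",
                         dtype={"model_id": str, "chrom": str})
        for c in _GT_BOOLS.get(name, []):
            if c in df.columns and len(df):
                df[c] = df[c].map({"True": True, "False": False, True: True,
                                   False: False}).astype(bool)
        for c in _GT_INTS.get(name, []):
            if c in df.columns and len(df):
                df[c] = df[c].astype("int64")
        gt_frames[name] = df
    return CohortBundle(
        config=config,
        metadata=metadata,
        variants=pio.read_maf(d / FIXTURE_FILES["maf"]),
        pon=pio.read_pon(d / FIXTURE_FILES["pon"]),
        segments=pio.read_seg(d / FIXTURE_FILES["seg"]),
        gene_models=pio.read_gene_models(d / FIXTURE_FILES["gene_models"]),
        fpkm=pio.read_expression(d / FIXTURE_FILES["fpkm"]),
        tpm=pio.read_expression(d / FIXTURE_FILES["tpm"]),
        fusion_calls=calls,
        ct=pio.read_ct(d / FIXTURE_FILES["ct"]),
        vaf_observations=pio.read_vaf_observations(
            d / FIXTURE_FILES["vaf_observations"]),
        ground_truth=GroundTruth(**gt_frames),
    )
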