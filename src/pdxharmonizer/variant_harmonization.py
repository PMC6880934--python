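"""Tumor-only germline/somatic splitting, TMB, and phase-of-therapy comparisons.

PDX models usually lack a matched normal, so germline variation must be removed
with population resources instead of a paired sample: a variant is considered
common germline when it is carried by more than ``pon_threshold`` samples of a
panel of normals, or when its minor allele frequency exceeds ``common_af`` in
any of three population databases (ExAC, 1000 Genomes, ESP).  Variants known to
COSMIC are scavenged back into the somatic set regardless, because recurrent
hotspot mutations can contaminate population panels.  Rare germline variants
(AF below the cutoff, few panel carriers) cannot be distinguished from somatic
events without a matched normal and stay in the somatic MAF.

Tumor mutation burden (TMB) counts only mononucleotide substitutions that
change the protein (missense + nonsense SNVs) divided by the size of the
capture region in megabases (45.1 Mb for the VCRome v2.1 exome design).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._common import ConfigurationError, ValidationError

#: Column layout of the MAF-style variant tables used throughout the package.
MAF_COLUMNS = [
    "Hugo_Symbol", "Chromosome", "Start_Position", "End_Position",
    "Reference_Allele", "Tumor_Seq_Allele2", "Variant_Classification",
    "Variant_Type", "Tumor_Sample_Barcode", "t_alt_count", "t_depth",
    "ExAC_AF", "TG_AF", "ESP_AF", "COSMIC_flag",
]

POPULATION_AF_COLUMNS = ["ExAC_AF", "TG_AF", "ESP_AF"]

#: Variant classifications that count toward TMB (amino-acid-changing SNVs).
TMB_CLASSIFICATIONS = frozenset({"Missense_Mutation", "Nonsense_Mutation"})

#: Default capture size of the VCRome v2.1 exome design, in Mb.
DEFAULT_CAPTURE_MB = 45.1

VARIANT_KEY = ["Chromosome", "Start_Position", "Reference_Allele", "Tumor_Seq_Allele2"]

PHASES = ("diagnosis", "relapse")


@dataclass(frozen=True)
class PanelOfNormals:
    """Carrier counts of variants across a panel of normal samples.

    ``counts`` maps a variant key ``(chrom, start, ref, alt)`` to the number of
    distinct normal samples carrying that variant (1..n_normals).
    """

    counts: Mapping[tuple, int] = field(default_factory=dict)
    n_normals: int = 809

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.counts.items() if not 1 <= v <= self.n_normals}
        if bad:
            raise ConfigurationError(
                f"panel carrier counts outside [1, {self.n_normals}]: {sorted(bad)[:5]}"
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, n_normals: int = 809) -> "PanelOfNormals":
        """Build from a table with columns Chromosome, Start_Position,
        Reference_Allele, Tumor_Seq_Allele2, n_carriers."""
        counts = {
            (str(r.Chromosome), int(r.Start_Position), str(r.Reference_Allele),
             str(r.Tumor_Seq_Allele2)): int(r.n_carriers)
            for r in df.itertuples(index=False)
        }
        return cls(counts=counts, n_normals=n_normals)

    def lookup(self, variants: pd.DataFrame) -> np.ndarray:
        """Carrier count for every row of a MAF-style table (0 if absent)."""
        keys = zip(
            variants["Chromosome"].astype(str),
            variants["Start_Position"].astype(int),
            variants["Reference_Allele"].astype(str),
            variants["Tumor_Seq_Allele2"].astype(str),
        )
        return np.fromiter((self.counts.get(k, 0) for k in keys), dtype=int,
                           count=len(variants))


def _validate_variant_keys(variants: pd.DataFrame) -> None:
    required = ["Chromosome", "Start_Position", "Reference_Allele", "Tumor_Seq_Allele2"]
    missing_cols = [c for c in required if c not in variants.columns]
    if missing_cols:
        raise ValidationError(f"variant table lacks key columns {missing_cols}")
    bad = variants.index[
        variants[required].isna().any(axis=1)
        | (variants["Reference_Allele"].astype(str).str.len() == 0)
        | (variants["Tumor_Seq_Allele2"].astype(str).str.len() == 0)
    ]
    if len(bad):
        raise ValidationError(
            f"{len(bad)} variant rows with malformed keys (missing chrom/position/"
            f"alleles); offending rows: {list(bad[:10])}"
        )


def split_germline_somatic(
    variants: pd.DataFrame,
    pon: PanelOfNormals,
    pon_threshold: int = 5,
    common_af: float = 0.005,
    af_mode: str = "any_db",
    cosmic_scavenge: str = "all",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition tumor-only calls into (germline, somatic) MAF tables.

    A variant is germline iff it is a panel hit (carried by strictly more than
    ``pon_threshold`` normals) or a population hit (AF > ``common_af``), and it
    is not scavenged back by COSMIC membership.  ``af_mode='any_db'`` (default)
    treats an excess frequency in any one database as a population hit;
    ``'all_db'`` requires all three.  ``cosmic_scavenge`` controls which rules
    COSMIC overrides: ``'all'`` (default) or ``'pop_only'`` (panel hits stay
    germline even when in COSMIC).

    The two outputs are disjoint and their concatenation equals the input.
    """
    if af_mode not in ("any_db", "all_db"):
        raise ConfigurationError(f"af_mode must be any_db or all_db, got {af_mode!r}")
    if cosmic_scavenge not in ("all", "pop_only"):
        raise ConfigurationError(
            f"cosmic_scavenge must be all or pop_only, got {cosmic_scavenge!r}")
    if len(variants) == 0:
        return variants.copy(), variants.copy()
    _validate_variant_keys(variants)

    afs = variants.reindex(columns=POPULATION_AF_COLUMNS).astype(float).fillna(0.0)
    if af_mode == "any_db":
        pop_hit = (afs > common_af).any(axis=1).to_numpy()
    else:
        pop_hit = (afs > common_af).all(axis=1).to_numpy()
    panel_hit = pon.lookup(variants) > pon_threshold
    cosmic = variants["COSMIC_flag"].fillna(False).astype(bool).to_numpy() \
        if "COSMIC_flag" in variants.columns else np.zeros(len(variants), bool)

    if cosmic_scavenge == "all":
        germline = (panel_hit | pop_hit) & ~cosmic
    else:
        germline = panel_hit | (pop_hit & ~cosmic)
    return variants.loc[germline].copy(), variants.loc[~germline].copy()


def compute_tmb(
    somatic: pd.DataFrame,
    capture_mb: float = DEFAULT_CAPTURE_MB,
    model_ids: "list[str] | None" = None,
) -> pd.DataFrame:
    """Tumor mutation burden per model: qualifying substitutions / capture Mb.

    Qualifying variants are SNVs (Variant_Type == 'SNP') classified as missense
    or nonsense.  ``model_ids`` (e.g. from cohort metadata) ensures models with
    zero somatic variants appear with TMB 0.
    """
    if capture_mb <= 0:
        raise ConfigurationError(f"capture_mb must be > 0, got {capture_mb}")
    if len(somatic):
        qualifying = somatic[
            (somatic["Variant_Type"] == "SNP")
            & somatic["Variant_Classification"].isin(TMB_CLASSIFICATIONS)
        ]
        counts = qualifying.groupby("Tumor_Sample_Barcode").size()
    else:
        counts = pd.Series(dtype=int)
    index = counts.index
    if model_ids is not None:
        index = pd.Index(model_ids).union(index)
    counts = counts.reindex(index, fill_value=0).sort_index()
    out = pd.DataFrame({
        "model_id": counts.index,
        "qualifying_count": counts.to_numpy(dtype=int),
        "capture_mb": capture_mb,
    })
    out["tmb"] = out["qualifying_count"] / capture_mb
    return out.reset_index(drop=True)


def compare_tmb_by_phase(
    tmb: pd.DataFrame,
    metadata: pd.DataFrame,
    group_by: str = "all",
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum comparison of TMB between diagnosis and
    relapse models, overall (``group_by='all'``) or per histology.

    Returns one row per group: sample sizes, medians per arm, the rank-sum p
    value, and a ``flagged`` column marking groups with fewer than two models
    in either arm (reported, never silently dropped).
    """
    if group_by not in ("all", "histology"):
        raise ConfigurationError(f"group_by must be all or histology, got {group_by!r}")
    merged = tmb.merge(metadata[["model_id", "histology", "phase"]], on="model_id")
    unknown = set(merged["phase"].unique()) - set(PHASES)
    if unknown:
        raise ValidationError(f"unknown phase labels: {sorted(unknown)}")

    rows = []
    groups = [("all", merged)] if group_by == "all" else merged.groupby("histology")
    for name, grp in groups:
        dx = grp.loc[grp["phase"] == "diagnosis", "tmb"].to_numpy()
        rel = grp.loc[grp["phase"] == "relapse", "tmb"].to_numpy()
        if len(dx) and len(rel):
            p = float(stats.mannwhitneyu(dx, rel, alternative="two-sided").pvalue)
        else:
            p = float("nan")
        rows.append({
            "group": name,
            "n_dx": len(dx), "n_rel": len(rel),
            "median_dx": float(np.median(dx)) if len(dx) else float("nan"),
            "median_rel": float(np.median(rel)) if len(rel) else float("nan"),
            "wilcoxon_p": p,
            "flagged": len(dx) < 2 or len(rel) < 2,
        })
    return pd.DataFrame(rows)
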