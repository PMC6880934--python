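import numpy as np
import pandas as pd
import pytest

from pdxharmonizer.synthetic_data import (CohortConfig, FocalEventSpec,
                                          FusionPlan, generate_cohort)
from pdxharmonizer.variant_harmonization import MAF_COLUMNS, PanelOfNormals


def small_cohort_config(seed: int = 7) -> CohortConfig:
    """12-model cohort exercising every planted entity class."""
    return CohortConfig(
        n_models=12,
        seed=seed,
        rna_fraction=0.85,
        breakpoint_plan={"M001": {"2": 12, "5": 3}, "M006": {"17": 10}},
        focal_plan=[
            FocalEventSpec("M002", "MYCN", "amplification"),
            FocalEventSpec("M003", "CDKN2A", "homozygous_deletion",
                           expressed=False),
            FocalEventSpec("M004", "CDKN2A", "homozygous_deletion",
                           expressed=True),
        ],
        contamination_plan={"M005": 0.25},
    )


@pytest.fixture(scope="session")
def bundle():
    return generate_cohort(small_cohort_config())


@pytest.fixture(scope="session")
def split_inputs(bundle):
    return bundle.variants, bundle.pon_object()


def make_random_variants(rng: np.random.Generator, n: int,
                         n_normals: int = 809):
    """Random MAF rows plus a matching panel, spanning every rule region:
    panel counts around the >5 boundary, population AFs around 0.005, and a
    random COSMIC flag."""
    rows = []
    pon_counts = {}
    for i in range(n):
        chrom = str(rng.integers(1, 23))
        pos = int(rng.integers(1, 10_000_000))
        ref, alt = "A", "G"
        panel = int(rng.choice([0, 1, 4, 5, 6, 7, 50]))
        if panel:
            pon_counts[(chrom, pos, ref, alt)] = panel

        def af():
            r = rng.random()
            if r < 0.4:
                return np.nan
            if r < 0.7:
                return float(rng.uniform(0, 0.005))
            return float(rng.uniform(0.005, 0.5))

        rows.append({
            "Hugo_Symbol": f"G{i}", "Chromosome": chrom, "Start_Position": pos,
            "End_Position": pos, "Reference_Allele": ref,
            "Tumor_Seq_Allele2": alt,
            "Variant_Classification": "Missense_Mutation",
            "Variant_Type": "SNP", "Tumor_Sample_Barcode": "M1",
            "t_alt_count": 30, "t_depth": 60,
            "ExAC_AF": af(), "TG_AF": af(), "ESP_AF": af(),
            "COSMIC_flag": bool(rng.random() < 0.2),
        })
    variants = pd.DataFrame(rows, columns=MAF_COLUMNS)
    pon = PanelOfNormals(counts=pon_counts, n_normals=n_normals)
    return variants, pon


def split_rule_oracle(variants: pd.DataFrame, pon: PanelOfNormals,
                      pon_threshold: int = 5, common_af: float = 0.005):
    """Independent row-by-row evaluation of the germline rules (oracle)."""
    labels = []
    for r in variants.itertuples(index=False):
        count = pon.counts.get((str(r.Chromosome), int(r.Start_Position),
                                str(r.Reference_Allele),
                                str(r.Tumor_Seq_Allele2)), 0)
        afs = [r.ExAC_AF, r.TG_AF, r.ESP_AF]
        pop_hit = any((not pd.isna(a)) and a > common_af for a in afs)
        germline = (count > pon_threshold or pop_hit) and not r.COSMIC_flag
        labels.append("germline" if germline else "somatic")
    return labels
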