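"""Contamination, identity and human-content QC for xenograft samples.

Four quantitative checks:

* **VAF skewness** — in an uncontaminated diploid sample, heterozygous common
  germline SNPs cluster symmetrically around VAF 0.5.  DNA from a second
  individual (or residual mouse reads) dilutes the alternate allele and drags
  the heterozygous band left, producing a negatively skewed distribution.  The
  check computes the adjusted Fisher-Pearson sample skewness of the
  heterozygous-band VAFs and flags models below a threshold.
* **WES-RNA identity** — variant allele frequencies measured independently by
  exome and RNA sequencing of the same model should correlate strongly; the
  published decision boundary (Pearson r >= 0.61 at read depth >= 10) declares
  a model matched.
* **Paired-model concordance** — models derived from the same patient at
  different phases of therapy should share most clonal mutations; reported as
  the Pearson r of shared-site VAFs plus the Jaccard fraction of shared keys.
* **Human DNA content** — species-specific qPCR: relative genome copies per
  species are 2^-(CT_unknown - CT_reference), the printed percent human is
  100 * human/mouse copies (a ratio, so it can exceed 100), and the normalized
  fraction human/(human+mouse) is reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._common import ValidationError

VAF_OBS_COLUMNS = ["model_id", "chrom", "pos", "ref", "alt", "source", "vaf", "depth"]
CT_COLUMNS = ["sample_id", "species", "replicate", "ct"]

PASS, FAIL, INDETERMINATE = "pass", "fail", "indeterminate"


@dataclass(frozen=True)
class QcVerdict:
    model_id: str
    check: str
    statistic: float
    threshold: float
    status: str  # pass | fail | indeterminate
    notes: str = ""


def vaf_skewness(
    vafs,
    model_id: str = "",
    min_sites: int = 100,
    flag_threshold: float = -0.5,
    het_band: tuple = (0.05, 0.95),
) -> QcVerdict:
    """Contamination check from the skewness of common-SNP VAFs.

    ``vafs`` are the VAFs of common germline SNPs for one model.  Sites
    outside ``het_band`` (homozygous) are excluded; below ``min_sites``
    remaining observations the verdict is indeterminate.  The statistic is
    the adjusted Fisher-Pearson sample skewness; values below
    ``flag_threshold`` fail (left-shifted heterozygous band).
    """
    v = np.asarray(vafs, dtype=float)
    band = v[(v > het_band[0]) & (v < het_band[1])]
    if len(band) < min_sites:
        return QcVerdict(model_id, "vaf_skewness", float("nan"), flag_threshold,
                         INDETERMINATE, f"only {len(band)} heterozygous-band sites "
                                        f"(min {min_sites})")
    skew = float(stats.skew(band, bias=False))
    return QcVerdict(model_id, "vaf_skewness", skew, flag_threshold,
                     FAIL if skew < flag_threshold else PASS,
                     f"{len(band)} sites")


def identity_correlation(
    wes: pd.DataFrame,
    rna: pd.DataFrame,
    model_id: str = "",
    min_depth: int = 10,
    match_threshold: float = 0.61,
    min_shared_sites: int = 10,
) -> QcVerdict:
    """WES-vs-RNA identity check via Pearson VAF correlation at shared sites.

    Both inputs are VAF observation tables (columns chrom, pos, ref, alt, vaf,
    depth) for one model.  Sites present in both sources at depth >=
    ``min_depth`` in each are correlated; the model is matched (pass) iff
    r >= ``match_threshold`` (boundary inclusive).  Fewer than
    ``min_shared_sites`` qualifying sites yields an indeterminate verdict.
    The check is symmetric in its two inputs.
    """
    key = ["chrom", "pos", "ref", "alt"]
    a = wes.loc[wes["depth"] >= min_depth, key + ["vaf"]]
    b = rna.loc[rna["depth"] >= min_depth, key + ["vaf"]]
    shared = a.merge(b, on=key, suffixes=("_wes", "_rna"))
    if len(shared) < min_shared_sites:
        return QcVerdict(model_id, "identity_correlation", float("nan"),
                         match_threshold, INDETERMINATE,
                         f"only {len(shared)} shared sites at depth >= {min_depth}")
    r = float(stats.pearsonr(shared["vaf_wes"], shared["vaf_rna"]).statistic)
    return QcVerdict(model_id, "identity_correlation", r, match_threshold,
                     PASS if r >= match_threshold else FAIL,
                     f"{len(shared)} shared sites")


@dataclass(frozen=True)
class PairConcordance:
    r: float            # NaN when no shared mutations
    jaccard: float
    n_shared: int
    n_union: int


def paired_model_concordance(maf_a: pd.DataFrame, maf_b: pd.DataFrame) -> PairConcordance:
    """Mutation concordance between two models derived from the same patient.

    Mutations are keyed on (chrom, start, ref, alt); the result reports the
    Pearson correlation of VAFs over shared mutations and the Jaccard fraction
    of shared keys.  With zero shared mutations the correlation is undefined
    (NaN) and Jaccard is 0.
    """
    def keyed(maf: pd.DataFrame) -> pd.DataFrame:
        out = maf[["Chromosome", "Start_Position", "Reference_Allele",
                   "Tumor_Seq_Allele2"]].copy()
        out["vaf"] = maf["t_alt_count"] / maf["t_depth"]
        return out.drop_duplicates(subset=out.columns[:4])

    a, b = keyed(maf_a), keyed(maf_b)
    key = list(a.columns[:4])
    shared = a.merge(b, on=key, suffixes=("_a", "_b"))
    n_union = len(pd.concat([a[key], b[key]]).drop_duplicates())
    jaccard = len(shared) / n_union if n_union else 0.0
    if len(shared) >= 2:
        r = float(stats.pearsonr(shared["vaf_a"], shared["vaf_b"]).statistic)
    else:
        r = float("nan")
    return PairConcordance(r=r, jaccard=jaccard, n_shared=len(shared),
                           n_union=n_union)


@dataclass(frozen=True)
class HumanContent:
    sample_id: str
    relative_human: float
    relative_mouse: float
    percent_human_printed: float  # 100 * human/mouse; a ratio, can exceed 100
    fraction_human: float         # human / (human + mouse)


def percent_human(
    cts: pd.DataFrame,
    reference_cts: dict,
    sample_id: str = "",
    efficiency: float = 1.0,
) -> HumanContent:
    """Human DNA content of one sample from species-specific qPCR CTs.

    ``cts`` holds the technical replicates for one sample (columns species,
    ct); ``reference_cts`` maps species -> mean CT of the one-diploid-copy
    reference.  Replicates are averaged before the exponential transform:
    relative copies = (1 + efficiency)^-(mean CT - reference CT), i.e. 2^-dCT
    at the assumed 100% amplification efficiency.  Returns both the printed
    percent human (100 * human/mouse relative copies) and the normalized
    fraction human/(human+mouse).
    """
    present = set(cts["species"].unique())
    missing = {"human", "mouse"} - present
    if missing:
        raise ValidationError(f"sample {sample_id!r}: missing CT measurements for "
                              f"species {sorted(missing)}")
    if (cts["ct"] <= 0).any():
        raise ValidationError(f"sample {sample_id!r}: CT values must be > 0")
    base = 1.0 + efficiency
    rel = {}
    for species in ("human", "mouse"):
        mean_ct = float(cts.loc[cts["species"] == species, "ct"].mean())
        rel[species] = base ** -(mean_ct - float(reference_cts[species]))
    if rel["mouse"] == 0.0:
        warnings.warn(f"sample {sample_id!r}: relative mouse copies is zero; "
                      "printed percent human is infinite", stacklevel=2)
        pct = float("inf")
        frac = 1.0
    else:
        pct = 100.0 * rel["human"] / rel["mouse"]
        frac = rel["human"] / (rel["human"] + rel["mouse"])
    return HumanContent(sample_id=sample_id, relative_human=rel["human"],
                        relative_mouse=rel["mouse"],
                        percent_human_printed=pct, fraction_human=frac)


def percent_human_table(
    cts: pd.DataFrame,
    reference_cts: dict,
    efficiency: float = 1.0,
) -> pd.DataFrame:
    """Vectorized :func:`percent_human` over a multi-sample CT table."""
    rows = []
    for sample, grp in cts.groupby("sample_id", sort=True):
        hc = percent_human(grp, reference_cts, sample_id=sample,
                           efficiency=efficiency)
        rows.append(vars(hc))
    return pd.DataFrame(rows, columns=["sample_id", "relative_human",
                                       "relative_mouse", "percent_human_printed",
                                       "fraction_human"])


def verdicts_to_frame(verdicts) -> pd.DataFrame:
    """Serialize QcVerdict records to a tidy table."""
    return pd.DataFrame([vars(v) for v in verdicts],
                        columns=["model_id", "check", "statistic", "threshold",
                                 "status", "notes"])
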