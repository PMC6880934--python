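"""Shared constants, exceptions and small helpers."""

from __future__ import annotations

import hashlib
from pathlib import Path


class ConfigurationError(ValueError):
    """A parameter or configuration value is out of its documented range."""


class ValidationError(ValueError):
    """Input data violate a documented invariant (offending rows are named)."""


# Toy chromosome lengths (bp), roughly hg19-proportioned. Autosomes 1-22 are
# analysed; X and Y are generated but excluded from breakpoint and focal-event
# calling because the cohort has no matched normals to calibrate sex chromosomes.
CHROM_LENGTHS: dict[str, int] = {
    "1": 249_000_000, "2": 243_000_000, "3": 198_000_000, "4": 191_000_000,
    "5": 181_000_000, "6": 171_000_000, "7": 159_000_000, "8": 146_000_000,
    "9": 141_000_000, "10": 136_000_000, "11": 135_000_000, "12": 134_000_000,
    "13": 115_000_000, "14": 107_000_000, "15": 103_000_000, "16": 90_000_000,
    "17": 81_000_000, "18": 78_000_000, "19": 59_000_000, "20": 63_000_000,
    "21": 48_000_000, "22": 51_000_000, "X": 155_000_000, "Y": 59_000_000,
}

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))
SEX_CHROMOSOMES: frozenset[str] = frozenset({"X", "Y"})


def normalize_chrom(chrom: object) -> str:
    """Map 'chr17', 17, 'x' etc. onto the canonical labels '1'..'22', 'X', 'Y'."""
    s = str(chrom).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s.upper() if s.upper() in SEX_CHROMOSOMES else s


def is_autosome(chrom: object) -> bool:
    return normalize_chrom(chrom) in AUTOSOMES


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
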