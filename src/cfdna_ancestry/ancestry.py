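"""Ancestry-informed classification of significantly differential variants.

Each significant variant with a dominance call is joined to reference
population allele frequencies — AFR (African/African American) as the
baseline for the AAM cohort, NFE (Non-Finnish European) for the CM cohort.
The absolute AF difference |AF_AFR - AF_NFE| is the ancestry-informative
marker (AIM); a variant is *aligned* when the signed difference favours the
dominant cohort's reference population by at least the AIM threshold
(default 0.01), *not aligned* otherwise, and *no data* when either AF is
missing.

Alignment x COSMIC-confirmed somatic status x PC-pathway membership yields
the eight-group classification:

1. aligned, somatic, PC-related        5. not aligned, somatic, PC-related
2. aligned, somatic, not PC-related    6. not aligned, somatic, not PC-related
3. aligned, not somatic, PC-related    7. not aligned, not somatic, PC-related
4. aligned, not somatic, not PC-related 8. not aligned, not somatic, not PC-related
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import CfdnaAncestryError, ValidationError
from .diff import VariantTestResult
from .variants import VariantKey

ALIGNMENTS = ("aligned", "not_aligned", "no_data")


@dataclass(frozen=True)
class PopulationAF:
    """Reference allele frequencies for one variant (either may be missing)."""

    key: VariantKey
    af_afr: float | None
    af_nfe: float | None

    def __post_init__(self) -> None:
        for name, af in (("af_afr", self.af_afr), ("af_nfe", self.af_nfe)):
            if af is not None and not (0.0 <= af <= 1.0):
                raise ValidationError(f"{name}={af} outside [0, 1] for {self.key}")


@dataclass(frozen=True)
class AncestryClassification:
    key: VariantKey
    dominant: str  # AAM | CM
    aim: float | None
    alignment: str  # aligned | not_aligned | no_data
    somatic_confirmed: bool
    pc_related: bool
    group: int | None  # 1..8, or None for no_data


def compute_aim(af_afr: float | None, af_nfe: float | None, threshold: float = 0.01) -> tuple[float | None, bool]:
    """AIM = |AF_AFR - AF_NFE|; meaningful when >= threshold.

    Either frequency missing -> (None, False): direction cannot be assessed.
    """
    if af_afr is None or af_nfe is None:
        return None, False
    for af in (af_afr, af_nfe):
        if not (0.0 <= af <= 1.0):
            raise ValidationError(f"allele frequency {af} outside [0, 1]")
    aim = abs(af_afr - af_nfe)
    return aim, aim >= threshold


def alignment_status(
    dominant: str,
    af_afr: float | None,
    af_nfe: float | None,
    threshold: float = 0.01,
    comparator: str = "ge",
) -> str:
    """Concordance between cfDNA dominance and the population AF direction.

    An AAM-dominant variant is aligned when AF_AFR - AF_NFE clears the
    threshold (>= by default; "gt" uses strict >); CM-dominant symmetric.
    Sub-threshold or opposite-direction differences are not aligned;
    missing data is no_data.
    """
    if dominant not in ("AAM", "CM"):
        raise ValidationError(f"dominant must be AAM or CM, got {dominant!r}")
    if comparator not in ("ge", "gt"):
        raise ValidationError(f"comparator must be 'ge' or 'gt', got {comparator!r}")
    if af_afr is None or af_nfe is None:
        return "no_data"
    delta = (af_afr - af_nfe) if dominant == "AAM" else (af_nfe - af_afr)
    clears = delta >= threshold if comparator == "ge" else delta > threshold
    return "aligned" if clears else "not_aligned"


def classify_eight_groups(alignment: str, somatic_confirmed: bool, pc_related: bool) -> int:
    """Map (alignment, somatic, PC-related) onto groups 1-8 (see module docs)."""
    if alignment == "no_data":
        raise CfdnaAncestryError(
            "contract violation: no_data alignment must be routed before grouping"
        )
    if alignment not in ("aligned", "not_aligned"):
        raise ValidationError(f"unknown alignment {alignment!r}")
    group = 1
    if alignment == "not_aligned":
        group += 4
    if not somatic_confirmed:
        group += 2
    if not pc_related:
        group += 1
    return group


def read_population_af(path: str | Path) -> dict[VariantKey, PopulationAF]:
    """Read the population-AF TSV (chrom, pos, ref, alt, af_afr, af_nfe).

    Missing frequencies are encoded as empty fields. Duplicate keys are an
    ingestion error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    table: dict[VariantKey, PopulationAF] = {}
    for row in df.itertuples(index=False):
        key = VariantKey(str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
        if key in table:
            raise ValidationError(f"duplicate key in population AF table: {key}")
        af_afr = None if pd.isna(row.af_afr) else float(row.af_afr)
        af_nfe = None if pd.isna(row.af_nfe) else float(row.af_nfe)
        table[key] = PopulationAF(key, af_afr, af_nfe)
    return table


def classify_cohort(
    significant_results: Sequence[VariantTestResult],
    pop_afs: Mapping[VariantKey, PopulationAF],
    shared_flags: Mapping[VariantKey, bool],
    pc_flags: Mapping[VariantKey, bool],
    threshold: float = 0.01,
    comparator: str = "ge",
) -> tuple[list[AncestryClassification], dict[str, dict[int, int]], list[AncestryClassification]]:
    """Classify every significant variant with a dominance call.

    Returns (classifications, per-population group tallies, no_data report).
    Tallies are keyed by dominant cohort then group id; variants without
    population AF data are listed separately and excluded from the tallies.
    Results with dominance "none" (ties) are skipped — they have no
    population baseline to align with.
    """
    classifications: list[AncestryClassification] = []
    no_data: list[AncestryClassification] = []
    tallies: dict[str, dict[int, int]] = {"AAM": {}, "CM": {}}
    for res in significant_results:
        if not res.significant or res.dominant == "none":
            continue
        pop = pop_afs.get(res.key)
        af_afr = pop.af_afr if pop else None
        af_nfe = pop.af_nfe if pop else None
        aim, _ = compute_aim(af_afr, af_nfe, threshold)
        alignment = alignment_status(res.dominant, af_afr, af_nfe, threshold, comparator)
        somatic = bool(shared_flags.get(res.key, False))
        pc = bool(pc_flags.get(res.key, False))
        if alignment == "no_data":
            record = AncestryClassification(res.key, res.dominant, None, "no_data", somatic, pc, None)
            no_data.append(record)
            continue
        group = classify_eight_groups(alignment, somatic, pc)
        record = AncestryClassification(res.key, res.dominant, aim, alignment, somatic, pc, group)
        classifications.append(record)
        tallies[res.dominant][group] = tallies[res.dominant].get(group, 0) + 1
    return classifications, tallies, no_data


def classification_to_frame(
    classifications: Sequence[AncestryClassification],
    pop_afs: Mapping[VariantKey, PopulationAF] | None = None,
) -> pd.DataFrame:
    pop_afs = pop_afs or {}

    def _af(key, attr):
        pop = pop_afs.get(key)
        val = getattr(pop, attr) if pop else None
        return math.nan if val is None else val

    return pd.DataFrame(
        {
            "chrom": [c.key.contig for c in classifications],
            "pos": [c.key.pos for c in classifications],
            "ref": [c.key.ref for c in classifications],
            "alt": [c.key.alt for c in classifications],
            "dominant": [c.dominant for c in classifications],
            "af_afr": [_af(c.key, "af_afr") for c in classifications],
            "af_nfe": [_af(c.key, "af_nfe") for c in classifications],
            "aim": [math.nan if c.aim is None else c.aim for c in classifications],
            "alignment": [c.alignment for c in classifications],
            "somatic_confirmed": [c.somatic_confirmed for c in classifications],
            "pc_related": [c.pc_related for c in classifications],
            "group": ["no_data" if c.group is None else c.group for c in classifications],
        }
    )
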