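"""Variant identity, VCF ingestion, consensus filtering and the cohort matrix.

The unit of analysis is the *carrier*: a patient in whose plasma cfDNA a
variant was detected by both variant callers at adequate depth and quality.
Variant identity is a normalized key (contig, 1-based position, ref, alt)
on hg38, used for every cross-dataset join (somatic catalogue, population
allele frequencies, annotations).

Normalization follows the standard parsimony algorithm: shared trailing
bases are trimmed first, then shared leading bases are trimmed with the
position advanced one base per trimmed leading base; at least one base
always remains in each allele, so the representation is left-anchored and
minimal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

_ALLELE_ALPHABET = frozenset("ACGT")

#: Cohort labels: African American men and Caucasian men.
COHORT_LABELS = ("AAM", "CM")

#: Fixed consequence vocabulary; anything else maps to "unannotated".
CONSEQUENCE_VOCABULARY = (
    "intronic",
    "ncRNA",
    "promoter_upstream",
    "missense",
    "synonymous",
    "UTR",
    "intergenic",
    "unannotated",
)

#: hg38 karyotype order used for all per-contig reports.
KARYOTYPE_ORDER = tuple(f"chr{c}" for c in list(range(1, 23)) + ["X", "Y"])


@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalized variant identity: contig, 1-based position, ref, alt.

    Ordering is lexicographic on (contig, pos, ref, alt) so that every
    report the pipeline writes is deterministically sorted.
    """

    contig: str
    pos: int
    ref: str
    alt: str

    def __str__(self) -> str:  # "chr7:100:A>G"
        return f"{self.contig}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class VariantCall:
    """One caller's observation of a variant in one sample."""

    key: VariantKey
    sample_id: str
    caller: str  # "freebayes" | "lofreq"
    depth: int
    quality: float

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValidationError(f"negative depth {self.depth} for {self.key}")
        if self.quality < 0:
            raise ValidationError(f"negative quality {self.quality} for {self.key}")


@dataclass(frozen=True)
class AnnotatedVariant:
    """Gene / functional-consequence annotation attached to a variant key."""

    key: VariantKey
    gene: str = ""
    consequence: str = "unannotated"
    aa_change: str | None = None

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCE_VOCABULARY:
            object.__setattr__(self, "consequence", "unannotated")


def harmonize_contig(contig: str) -> str:
    """Rewrite bare contig names ("7", "X", "MT") to the "chr" dialect."""
    contig = str(contig)
    if contig.startswith("chr"):
        return contig
    if contig in ("MT", "M"):
        return "chrM"
    return f"chr{contig}"


def normalize_variant(contig: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Return the minimal left-anchored representation of a variant.

    Shared trailing bases are trimmed while both alleles keep >= 1 base;
    shared leading bases are then trimmed (position incremented per base)
    while both alleles keep >= 1 base afterwards.

    Raises
    ------
    ValidationError
        If an allele is empty, contains a non-ACGT character, ref == alt
        after upcasing, or pos < 1.
    """
    ref = str(ref).upper()
    alt = str(alt).upper()
    if not ref or not alt:
        raise ValidationError(f"malformed allele: empty ref/alt at {contig}:{pos}")
    if not (_ALLELE_ALPHABET.issuperset(ref) and _ALLELE_ALPHABET.issuperset(alt)):
        raise ValidationError(
            f"malformed allele: non-ACGT character in {ref!r}/{alt!r} at {contig}:{pos}"
        )
    pos = int(pos)
    if pos < 1:
        raise ValidationError(f"position must be >= 1, got {pos}")
    if ref == alt:
        raise ValidationError(f"ref == alt ({ref}) at {contig}:{pos}")

    # trailing trim
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # leading trim, advancing pos
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantKey(harmonize_contig(contig), pos, ref, alt)


def read_sample_vcf(path: str | Path, caller: str, sample_id: str | None = None) -> list[VariantCall]:
    """Read one caller's VCF for one sample into normalized VariantCalls.

    Multi-allelic records are split into one call per alternate allele,
    each normalized independently; the record's depth and quality are
    shared across the split alleles. Depth is taken from INFO/DP when
    present, else the first sample's FORMAT/DP, else 0 (read-level depth,
    not UMI-consensus depth). Quality is the record QUAL (0 if missing).

    ``sample_id`` defaults to the VCF sample name when the file has one,
    else the file stem.
    """
    from cyvcf2 import VCF

    path = Path(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise FormatError(f"unreadable VCF {path}: {exc}") from exc
    if sample_id is None:
        sample_id = vcf.samples[0] if vcf.samples else path.stem
    calls: list[VariantCall] = []
    for rec in vcf:
        depth = rec.INFO.get("DP")
        if depth is None and len(vcf.samples) > 0:
            fmt_dp = rec.format("DP")
            if fmt_dp is not None:
                v = int(fmt_dp[0][0])
                depth = v if v >= 0 else None
        depth = int(depth) if depth is not None else 0
        quality = float(rec.QUAL) if rec.QUAL is not None else 0.0
        for alt in rec.ALT:
            if alt is None or set(alt.upper()) - _ALLELE_ALPHABET:
                continue  # symbolic / spanning-deletion alleles are not point variants
            key = normalize_variant(rec.CHROM, rec.POS, rec.REF, alt)
            calls.append(VariantCall(key, sample_id, caller, depth, quality))
    vcf.close()
    return calls


def filter_calls(
    calls: Iterable[VariantCall], min_depth: int = 199, min_quality: float = 30.0
) -> list[VariantCall]:
    """Drop calls with depth or quality strictly below the thresholds.

    Boundary values are retained: only calls with depth < min_depth or
    quality < min_quality are excluded.
    """
    return [c for c in calls if c.depth >= min_depth and c.quality >= min_quality]


def intersect_callers(
    calls_freebayes: Sequence[VariantCall], calls_lofreq: Sequence[VariantCall]
) -> list[VariantKey]:
    """Consensus keys for one sample: present in both callers' call sets.

    Raises ValidationError when either list mixes sample ids.
    """
    for calls, name in ((calls_freebayes, "freebayes"), (calls_lofreq, "lofreq")):
        ids = {c.sample_id for c in calls}
        if len(ids) > 1:
            raise ValidationError(f"mixed sample_ids in {name} call list: {sorted(ids)}")
    both = {c.key for c in calls_freebayes} & {c.key for c in calls_lofreq}
    return sorted(both)


@dataclass
class CohortVariantMatrix:
    """Presence/absence of each variant across the patients of two cohorts."""

    variants: list[VariantKey]
    patients: list[tuple[str, str]]  # (sample_id, cohort label)
    carrier: np.ndarray = field(repr=False)  # shape (n_variants, n_patients), 0/1

    def __post_init__(self) -> None:
        self.carrier = np.asarray(self.carrier, dtype=np.int8)
        if self.carrier.shape != (len(self.variants), len(self.patients)):
            raise ValidationError(
                f"carrier shape {self.carrier.shape} does not match "
                f"{len(self.variants)} variants x {len(self.patients)} patients"
            )
        labels = {c for _, c in self.patients}
        if not labels.issubset(set(COHORT_LABELS)):
            raise ValidationError(f"unknown cohort labels: {labels - set(COHORT_LABELS)}")

    @property
    def cohort_sizes(self) -> dict[str, int]:
        sizes = {lab: 0 for lab in COHORT_LABELS}
        for _, lab in self.patients:
            sizes[lab] += 1
        return sizes

    def cohort_columns(self, label: str) -> np.ndarray:
        return np.array([i for i, (_, lab) in enumerate(self.patients) if lab == label])

    def carrier_counts(self, label: str) -> np.ndarray:
        """Per-variant carrier count within one cohort."""
        cols = self.cohort_columns(label)
        if cols.size == 0:
            return np.zeros(len(self.variants), dtype=int)
        return self.carrier[:, cols].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Wide TSV layout: chrom,pos,ref,alt + one 0/1 column per sample."""
        df = pd.DataFrame(
            {
                "chrom": [v.contig for v in self.variants],
                "pos": [v.pos for v in self.variants],
                "ref": [v.ref for v in self.variants],
                "alt": [v.alt for v in self.variants],
            }
        )
        for j, (sid, _) in enumerate(self.patients):
            df[sid] = self.carrier[:, j]
        return df


def build_cohort_matrix(
    per_sample_consensus: Mapping[str, Iterable[VariantKey]],
    metadata: pd.DataFrame,
) -> CohortVariantMatrix:
    """Assemble the carrier matrix from per-sample consensus key sets.

    ``metadata`` must carry columns ``sample_id`` and ``race`` (AAM|CM) and
    cover every sample in the consensus mapping. Variants observed in zero
    patients are absent by construction; patients follow metadata order,
    variants sorted by key.
    """
    meta = metadata.set_index("sample_id")
    missing = [s for s in per_sample_consensus if s not in meta.index]
    if missing:
        raise ValidationError(f"samples without metadata: {missing}")
    patients = [(sid, str(meta.loc[sid, "race"])) for sid in per_sample_consensus]
    bad = [sid for sid, lab in patients if lab not in COHORT_LABELS]
    if bad:
        raise ValidationError(f"samples with unknown cohort label: {bad}")

    consensus_sets = {s: set(v) for s, v in per_sample_consensus.items()}
    variants = sorted(set().union(*consensus_sets.values())) if consensus_sets else []
    index = {v: i for i, v in enumerate(variants)}
    carrier = np.zeros((len(variants), len(patients)), dtype=np.int8)
    for j, (sid, _) in enumerate(patients):
        for key in consensus_sets[sid]:
            carrier[index[key], j] = 1
    return CohortVariantMatrix(variants, patients, carrier)


def write_matrix_tsv(matrix: CohortVariantMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path: str | Path, metadata: pd.DataFrame) -> CohortVariantMatrix:
    """Read a matrix TSV written by :func:`write_matrix_tsv`."""
    df = pd.read_csv(path, sep="\t")
    sample_cols = [c for c in df.columns if c not in ("chrom", "pos", "ref", "alt")]
    meta = metadata.set_index("sample_id")
    patients = [(sid, str(meta.loc[sid, "race"])) for sid in sample_cols]
    variants = [
        VariantKey(r.chrom, int(r.pos), r.ref, r.alt) for r in df.itertuples(index=False)
    ]
    carrier = df[sample_cols].to_numpy(dtype=np.int8)
    return CohortVariantMatrix(variants, patients, carrier)


def ingest_sample_pair(
    freebayes_vcf: str | Path,
    lofreq_vcf: str | Path,
    sample_id: str,
    min_depth: int = 199,
    min_quality: float = 30.0,
) -> tuple[list[VariantKey], dict[str, int]]:
    """Read, filter, and intersect one sample's caller pair.

    Returns the consensus key list and a small count dict used for the
    filter-report sidecar.
    """
    fb = read_sample_vcf(freebayes_vcf, "freebayes", sample_id)
    lf = read_sample_vcf(lofreq_vcf, "lofreq", sample_id)
    fb_kept = filter_calls(fb, min_depth, min_quality)
    lf_kept = filter_calls(lf, min_depth, min_quality)
    consensus = intersect_callers(fb_kept, lf_kept)
    counts = {
        "freebayes_raw": len(fb),
        "lofreq_raw": len(lf),
        "freebayes_pass": len(fb_kept),
        "lofreq_pass": len(lf_kept),
        "consensus": len(consensus),
    }
    return consensus, counts


def ingest_cohort(
    manifest: pd.DataFrame,
    metadata: pd.DataFrame,
    min_depth: int = 199,
    min_quality: float = 30.0,
    base_dir: str | Path | None = None,
) -> tuple[CohortVariantMatrix, dict[str, dict[str, int]]]:
    """Ingest a whole cohort from a manifest.

    ``manifest`` columns: sample_id, freebayes_vcf, lofreq_vcf (paths;
    relative paths are resolved against ``base_dir`` when given, so a
    manifest can travel with its VCF directory). Returns the cohort matrix
    and per-sample filter counts.
    """

    def _resolve(p: str) -> Path:
        p = Path(p)
        return p if p.is_absolute() or base_dir is None else Path(base_dir) / p

    consensus: dict[str, list[VariantKey]] = {}
    reports: dict[str, dict[str, int]] = {}
    for row in manifest.itertuples(index=False):
        keys, counts = ingest_sample_pair(
            _resolve(row.freebayes_vcf), _resolve(row.lofreq_vcf),
            row.sample_id, min_depth, min_quality,
        )
        consensus[row.sample_id] = keys
        reports[row.sample_id] = counts
    return build_cohort_matrix(consensus, metadata), reports


def write_filter_report(reports: Mapping[str, Mapping[str, int]], path: str | Path) -> None:
    Path(path).write_text(json.dumps(reports, indent=2, sort_keys=True) + "\n")
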