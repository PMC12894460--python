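"""Curation of a somatic-mutation catalogue and intersection with cfDNA variants.

A COSMIC-like export (one row per observed mutation, with sample gender,
primary site, histology and a somatic-status string) is restricted to a
male prostate-cancer context by three independent predicate filters:

* gender restriction — only records from male samples are retained;
* primary-site exclusion — sites indicative of female reproductive
  cancers (ovary, breast, endometrium, cervix by default) are removed;
* histology exclusion — histologies/subtypes unequivocally unrelated to
  prostate cancer (sex cord-stromal tumor, ductal carcinoma, serous
  carcinoma by default) are removed.

Because the filters are independent predicates they commute and are
idempotent. cfDNA variants are then matched against the curated records by
normalized variant key (coordinate-level, not gene-level); a shared variant
is "somatic confirmed" when at least one matching curated record carries a
confirmed-somatic status.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigError, FormatError
from .variants import VariantKey, normalize_variant

DEFAULT_EXCLUDED_SITES = ("ovary", "breast", "endometrium", "cervix")
DEFAULT_EXCLUDED_HISTOLOGIES = (
    "sex cord-stromal tumor",
    "ductal carcinoma",
    "serous carcinoma",
)
#: Raw somatic-status strings containing any of these (case-insensitive)
#: map to confirmed_somatic; "variant of unknown origin" etc. fall through.
DEFAULT_CONFIRMED_MARKERS = ("confirmed somatic",)

SOMATIC_STATUSES = ("confirmed_somatic", "not_confirmed", "other")

REQUIRED_COLUMNS = (
    "gene", "chrom", "pos", "ref", "alt",
    "sample_gender", "primary_site", "histology", "histology_subtype",
    "somatic_status",
)


@dataclass(frozen=True)
class CosmicRecord:
    """One catalogue mutation observation."""

    key: VariantKey
    gene: str
    sample_gender: str  # male | female | unknown
    primary_site: str
    histology: str
    histology_subtype: str = ""
    somatic_status: str = "other"


@dataclass
class SharedVariant:
    """A cfDNA variant also present in the curated catalogue."""

    key: VariantKey
    somatic_confirmed: bool
    pc_related: bool = False
    supporting_sites: list[str] = field(default_factory=list)
    supporting_histologies: list[str] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)


def map_somatic_status(raw: str, confirmed_markers: Sequence[str] = DEFAULT_CONFIRMED_MARKERS) -> str:
    """Map a raw catalogue status string onto the three-way vocabulary."""
    low = str(raw).strip().lower()
    if ("not confirmed" in low or "unknown origin" in low
            or low in ("germline", "polymorphism")):
        return "not_confirmed"
    if any(m in low for m in confirmed_markers):
        return "confirmed_somatic"
    return "other"


def read_cosmic_table(path: str | Path) -> list[CosmicRecord]:
    """Read a COSMIC-like TSV into normalized records.

    Required columns: gene, chrom, pos, ref, alt, sample_gender,
    primary_site, histology, histology_subtype, somatic_status.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"catalogue table {path} missing columns: {missing}")
    return records_from_frame(df)


def records_from_frame(df: pd.DataFrame) -> list[CosmicRecord]:
    if "sample_gender" not in df.columns:
        raise FormatError("catalogue table missing gender column 'sample_gender'")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            CosmicRecord(
                key=normalize_variant(row.chrom, int(row.pos), row.ref, row.alt),
                gene=str(row.gene),
                sample_gender=str(row.sample_gender).strip().lower(),
                primary_site=str(row.primary_site).strip().lower(),
                histology=str(row.histology).strip().lower(),
                histology_subtype=str(getattr(row, "histology_subtype", "")).strip().lower(),
                somatic_status=map_somatic_status(row.somatic_status),
            )
        )
    return records


def curate_cosmic(
    records: Iterable[CosmicRecord],
    excluded_sites: Sequence[str] = DEFAULT_EXCLUDED_SITES,
    excluded_histologies: Sequence[str] = DEFAULT_EXCLUDED_HISTOLOGIES,
) -> tuple[list[CosmicRecord], set[VariantKey]]:
    """Apply the three context filters; return (curated records, distinct keys).

    Duplicate same-key records are retained as separate observations (the
    per-gene site/histology distributions need the multiset); the distinct
    key set is returned alongside for bookkeeping.
    """
    sites = {s.strip().lower() for s in excluded_sites}
    hists = {h.strip().lower() for h in excluded_histologies}
    curated = [
        r
        for r in records
        if r.sample_gender == "male"
        and r.primary_site not in sites
        and r.histology not in hists
        and r.histology_subtype not in hists
    ]
    return curated, {r.key for r in curated}


def pc_gene_membership(gene: str, kegg_pc_list: Iterable[str]) -> bool:
    """Case-insensitive exact-symbol membership in the PC pathway gene list."""
    gene_up = str(gene).strip().upper()
    return gene_up in {str(g).strip().upper() for g in kegg_pc_list}


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines ignored; must be non-empty."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    genes = [ln for ln in lines if ln]
    if not genes:
        raise ConfigError(f"empty gene list file: {path}")
    return genes


def intersect_with_cosmic(
    cfdna_keys: Iterable[VariantKey],
    curated: Sequence[CosmicRecord],
    pc_genes: Iterable[str] = (),
) -> list[SharedVariant]:
    """Match cfDNA keys against curated records by normalized key.

    Returns one SharedVariant per matched key, sorted by key; the
    somatic/not-somatic split partitions the shared set exactly
    (somatic_confirmed is true iff >= 1 matching record is confirmed
    somatic). pc_related is true when any supporting record's gene is in
    the PC pathway list.
    """
    by_key: dict[VariantKey, list[CosmicRecord]] = {}
    for rec in curated:
        by_key.setdefault(rec.key, []).append(rec)
    pc_set = {str(g).strip().upper() for g in pc_genes}
    shared = []
    for key in sorted(set(cfdna_keys)):
        recs = by_key.get(key)
        if not recs:
            continue
        shared.append(
            SharedVariant(
                key=key,
                somatic_confirmed=any(r.somatic_status == "confirmed_somatic" for r in recs),
                pc_related=any(r.gene.strip().upper() in pc_set for r in recs),
                supporting_sites=sorted(r.primary_site for r in recs),
                supporting_histologies=sorted(r.histology for r in recs),
                genes=sorted({r.gene for r in recs}),
            )
        )
    return shared


def site_histology_distribution(
    shared_variants: Sequence[SharedVariant], by: str = "primary_site"
) -> pd.DataFrame:
    """Per-gene frequency table over the supporting site/histology multisets.

    Ordering is deterministic: gene name ascending, then descending count,
    then value name.
    """
    if by not in ("primary_site", "histology"):
        raise ConfigError(f"'by' must be primary_site or histology, got {by!r}")
    attr = "supporting_sites" if by == "primary_site" else "supporting_histologies"
    tallies: dict[tuple[str, str], int] = {}
    for sv in shared_variants:
        for gene in sv.genes:
            for value in getattr(sv, attr):
                tallies[(gene, value)] = tallies.get((gene, value), 0) + 1
    rows = [
        {"gene": g, by: v, "count": n}
        for (g, v), n in tallies.items()
    ]
    rows.sort(key=lambda r: (r["gene"], -r["count"], r[by]))
    return pd.DataFrame(rows, columns=["gene", by, "count"])


def shared_to_frame(shared: Sequence[SharedVariant]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [s.key.contig for s in shared],
            "pos": [s.key.pos for s in shared],
            "ref": [s.key.ref for s in shared],
            "alt": [s.key.alt for s in shared],
            "genes": [",".join(s.genes) for s in shared],
            "somatic_confirmed": [s.somatic_confirmed for s in shared],
            "pc_related": [s.pc_related for s in shared],
            "n_supporting_records": [len(s.supporting_sites) for s in shared],
        }
    )
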