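"""End-to-end orchestration: ingest -> cohort stats -> differential testing
-> catalogue curation/intersection -> ancestry classification -> enrichment.

Driven by a :class:`RunConfig` (loadable from YAML). All output tables are
sorted by variant key and floating values printed with fixed precision, so
identical inputs and configuration produce byte-identical outputs. Any
module failure aborts the run with the module name; partially written
outputs are removed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .ancestry import classification_to_frame, classify_cohort, read_population_af
from .cohort import (
    categorical_summary,
    compare_ages,
    compare_category_frequency,
    records_from_metadata,
)
from .cosmic import (
    DEFAULT_EXCLUDED_HISTOLOGIES,
    DEFAULT_EXCLUDED_SITES,
    curate_cosmic,
    intersect_with_cosmic,
    read_cosmic_table,
    read_gene_list,
    shared_to_frame,
    site_histology_distribution,
)
from .diff import (
    chromosome_distribution,
    consequence_proportions,
    results_to_frame,
    test_all_variants,
)
from .enrichment import enrichment_to_frame, hypergeometric_enrichment, read_gmt
from .errors import CfdnaAncestryError, ConfigError
from .variants import (
    AnnotatedVariant,
    VariantKey,
    ingest_cohort,
    normalize_variant,
    write_filter_report,
    write_matrix_tsv,
)

log = logging.getLogger("cfdna_ancestry")


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run."""

    manifest: Path
    metadata: Path
    out_dir: Path
    cosmic_table: Path | None = None
    population_af: Path | None = None
    pc_gene_list: Path | None = None
    gmt_files: list[Path] = field(default_factory=list)
    annotations: Path | None = None
    min_depth: int = 199
    min_quality: float = 30.0
    alpha: float = 0.05
    aim_threshold: float = 0.01
    aim_comparator: str = "ge"  # "ge" | "gt"
    excluded_sites: tuple[str, ...] = DEFAULT_EXCLUDED_SITES
    excluded_histologies: tuple[str, ...] = DEFAULT_EXCLUDED_HISTOLOGIES
    enrichment_background: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ConfigError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.aim_threshold < 0:
            raise ConfigError("aim_threshold must be non-negative")
        if self.aim_comparator not in ("ge", "gt"):
            raise ConfigError(f"aim_comparator must be 'ge' or 'gt', got {self.aim_comparator!r}")
        for name in ("manifest", "metadata", "cosmic_table", "population_af",
                     "pc_gene_list", "annotations"):
            val = getattr(self, name)
            if val is not None:
                setattr(self, name, Path(val))
        self.gmt_files = [Path(p) for p in self.gmt_files]
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} is not a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate_paths(self) -> None:
        for p in [self.manifest, self.metadata, self.cosmic_table,
                  self.population_af, self.pc_gene_list, self.annotations,
                  *self.gmt_files]:
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")


def read_annotations(path: str | Path) -> dict[VariantKey, AnnotatedVariant]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str},
                     keep_default_na=False)
    out: dict[VariantKey, AnnotatedVariant] = {}
    for row in df.itertuples(index=False):
        key = normalize_variant(row.chrom, int(row.pos), row.ref, row.alt)
        aa = getattr(row, "aa_change", "") or None
        out[key] = AnnotatedVariant(key, str(row.gene), str(row.consequence), aa)
    return out


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def _fmt(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a summary dict of headline counts."""
    config.validate_paths()
    out = config.out_dir
    fresh = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        # --- ingest ---------------------------------------------------
        stage = "variant ingestion"
        log.info("ingesting VCF pairs")
        manifest = pd.read_csv(config.manifest, sep="\t")
        metadata = pd.read_csv(config.metadata, sep="\t")
        matrix, filter_reports = ingest_cohort(
            manifest, metadata, config.min_depth, config.min_quality,
            base_dir=Path(config.manifest).parent,
        )
        write_matrix_tsv(matrix, out / "cohort_matrix.tsv")
        write_filter_report(filter_reports, out / "filter_counts.json")

        # --- cohort statistics ---------------------------------------
        stage = "cohort statistics"
        records = records_from_metadata(metadata)
        stats_json: dict = {}
        for fld in ("metastasis_site", "metastasis_time"):
            _fmt(categorical_summary(records, fld), out / f"table1_{fld}.tsv")
        stats_json["metastasis_at_diagnosis"] = compare_category_frequency(
            records, "metastasis_time", "at_diagnosis"
        )
        try:
            stats_json["age"] = compare_ages(records)
        except CfdnaAncestryError:
            stats_json["age"] = {"test": "welch_t", "p": None, "note": "insufficient age data"}
        _write_json(stats_json, out / "cohort_stats.json")

        # --- differential testing ------------------------------------
        stage = "differential testing"
        log.info("testing %d variants", len(matrix.variants))
        results = test_all_variants(matrix, config.alpha)
        annotations = read_annotations(config.annotations) if config.annotations else {}
        _fmt(results_to_frame(results, annotations), out / "variant_tests.tsv")
        significant = [r for r in results if r.significant]
        sig_keys = [r.key for r in significant]
        if annotations:
            sets = {
                "all": [r.key for r in results],
                "significant": sig_keys,
                "non_significant": [r.key for r in results if not r.significant],
            }
            prop_frame, homog_p = consequence_proportions(annotations, sets)
            _fmt(prop_frame, out / "consequence_proportions.tsv")
            _write_json({"homogeneity_p": None if homog_p != homog_p else homog_p},
                        out / "consequence_homogeneity.json")
        _fmt(chromosome_distribution(results), out / "chromosome_distribution.tsv")

        # --- catalogue curation & intersection ------------------------
        stage = "catalogue curation"
        shared = []
        pc_genes: list[str] = []
        if config.pc_gene_list:
            pc_genes = read_gene_list(config.pc_gene_list)
        if config.cosmic_table:
            raw_records = read_cosmic_table(config.cosmic_table)
            curated, distinct = curate_cosmic(
                raw_records, config.excluded_sites, config.excluded_histologies
            )
            all_keys = [r.key for r in results]
            shared = intersect_with_cosmic(all_keys, curated, pc_genes)
            _fmt(shared_to_frame(shared), out / "shared_variants.tsv")
            for by in ("primary_site", "histology"):
                _fmt(site_histology_distribution(shared, by),
                     out / f"shared_{by}_distribution.tsv")

        # --- ancestry classification ----------------------------------
        stage = "ancestry classification"
        classifications, tallies, no_data = [], {"AAM": {}, "CM": {}}, []
        if config.population_af:
            pop_afs = read_population_af(config.population_af)
            shared_flags = {s.key: s.somatic_confirmed for s in shared}
            if annotations:
                pc_upper = {g.upper() for g in pc_genes}
                pc_flags = {
                    k: a.gene.upper() in pc_upper for k, a in annotations.items()
                }
            else:
                pc_flags = {s.key: s.pc_related for s in shared}
            classifications, tallies, no_data = classify_cohort(
                significant, pop_afs, shared_flags, pc_flags,
                config.aim_threshold, config.aim_comparator,
            )
            _fmt(classification_to_frame(classifications, pop_afs),
                 out / "ancestry_classification.tsv")
            _fmt(classification_to_frame(no_data), out / "ancestry_no_data.tsv")
            _write_json(
                {pop: {str(g): n for g, n in sorted(t.items())} for pop, t in tallies.items()},
                out / "group_tallies.json",
            )

        # --- enrichment ------------------------------------------------
        stage = "enrichment"
        if config.gmt_files and annotations:
            query = sorted({
                annotations[k].gene for k in sig_keys
                if k in annotations and annotations[k].gene
            })
            (out / "enrichment_query_genes.txt").write_text("\n".join(query) + "\n")
            for gmt in config.gmt_files:
                collection = read_gmt(gmt, config.enrichment_background)
                enriched = hypergeometric_enrichment(query, collection) if query else []
                _fmt(enrichment_to_frame(enriched), out / f"enrichment_{Path(gmt).stem}.tsv")

        # --- manifest ---------------------------------------------------
        stage = "manifest"
        ties = sum(1 for r in significant if r.dominant == "none")
        summary = {
            "n_patients": len(matrix.patients),
            "cohort_sizes": matrix.cohort_sizes,
            "n_variants": len(matrix.variants),
            "n_significant": len(significant),
            "n_aam_dominant": sum(1 for r in significant if r.dominant == "AAM"),
            "n_cm_dominant": sum(1 for r in significant if r.dominant == "CM"),
            "n_dominance_ties": ties,
            "n_shared": len(shared),
            "n_shared_somatic": sum(1 for s in shared if s.somatic_confirmed),
            "n_classified": len(classifications),
            "n_no_data": len(no_data),
            "group_tallies": {p: {str(g): n for g, n in sorted(t.items())}
                              for p, t in tallies.items()},
        }
        run_manifest = {
            "version": __version__,
            "thresholds": {
                "min_depth": config.min_depth,
                "min_quality": config.min_quality,
                "alpha": config.alpha,
                "aim_threshold": config.aim_threshold,
                "aim_comparator": config.aim_comparator,
            },
            "inputs": {
                str(p): _hash_file(Path(p))
                for p in [config.manifest, config.metadata, config.cosmic_table,
                          config.population_af, config.pc_gene_list,
                          config.annotations, *config.gmt_files]
                if p is not None
            },
            "summary": summary,
        }
        _write_json(run_manifest, out / "run_manifest.json")
        return summary
    except Exception as exc:
        if fresh:
            shutil.rmtree(out, ignore_errors=True)
        raise CfdnaAncestryError(f"pipeline failed during {stage}: {exc}") from exc
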