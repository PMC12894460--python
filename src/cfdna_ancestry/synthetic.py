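"""Ground-truth-labeled synthetic cohorts for the cfDNA ancestry pipeline.

The generator emulates the statistical structure the analysis assumes:

* two imbalanced cohorts (22 AAM vs 66 CM patients by default) with
  per-variant Bernoulli carrier status;
* effect classes per variant — ``null`` (equal carrier probability in both
  cohorts), ``differential`` (divergent carrier probabilities, 0.8 vs 0.05
  by default), ``somatic_spike`` (differential and catalogued as a
  confirmed-somatic mutation), and ``missing_af`` (differential but absent
  from the population allele-frequency table, exercising the no-data
  routing);
* reference allele frequencies drawn so that a configurable fraction of
  differential variants is ancestry-aligned with its dominant cohort and
  the rest is discordant (opposite direction or sub-threshold);
* per-sample VCF pairs (freebayes/lofreq dialect: INFO/DP depth and QUAL)
  with read depth overdispersed around 500x, and a configurable fraction of
  carrier calls deliberately failing the depth, quality, or two-caller
  consensus filters to exercise ingestion;
* a COSMIC-like catalogue containing confirmed-somatic male records exactly
  for truth-somatic variants, not-confirmed records for a fraction of the
  remaining variants, and decoy confirmed-somatic records violating each
  curation filter (female gender, excluded site, excluded histology);
* gene annotations, a PC-pathway gene list and a small GMT collection
  realizing the truth flags.

All randomness flows from one master seed through named child streams, so
adding an output type never perturbs earlier draws, and identical
configurations produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ancestry import classify_eight_groups
from .errors import ConfigError
from .variants import CohortVariantMatrix, VariantKey

EFFECT_CLASSES = ("null", "differential", "somatic_spike", "missing_af")

_STREAMS = ("variants", "carriers", "afs", "metadata", "vcf", "cosmic", "genesets")

# Observed study-scale metastasis category counts used as generator defaults
# (site -> (AAM count, CM count)); cohort sizes 22 and 66.
DEFAULT_METASTASIS_SITES = {
    "bone": (6, 27),
    "regional_ln_distant_ln_bone": (6, 9),
    "regional_ln_distant_ln": (1, 9),
    "regional_ln_bone": (4, 7),
    "not_reported": (3, 6),
    "liver_bone": (0, 3),
    "regional_ln": (1, 2),
    "bone_brain": (0, 1),
    "distant_ln": (0, 1),
    "lungs_bone": (0, 1),
    "regional_ln_liver_bone": (1, 0),
}
DEFAULT_METASTASIS_TIMES = {
    "at_diagnosis": (13, 24),
    "at_relapse": (8, 38),
    "not_reported": (1, 4),
}

_REAL_GENES = (
    "TMPRSS2", "MTOR", "MET", "NKX3-1", "AKT3", "KMT2C", "BRAF", "PIK3C2B",
    "PIK3CG", "ETV1", "KMT2D", "FANCA", "DOT1L", "ASXL1", "ATM", "EP300",
    "RB1", "SETD2", "CHEK2", "TP53", "AR", "ERG", "ETV5", "KLK3", "KRAS",
    "AKT1", "AKT2", "CTNNB1", "CCND1", "PREX2", "XRCC5", "XRCC6", "KLK2",
    "ELK4", "NDRG1", "RAD51", "XRCC1", "ESRP1", "KAT6A",
)
#: genes treated as PC-pathway members by default (subset of the pool)
_DEFAULT_PC_GENES = (
    "TMPRSS2", "MTOR", "MET", "NKX3-1", "AKT3", "BRAF", "PIK3CG", "ETV1",
    "AR", "ERG", "ETV5", "KLK3", "KRAS", "AKT1", "AKT2", "CTNNB1", "CCND1",
    "EP300", "RB1", "TP53", "PIK3C2B", "ELK4", "KLK2",
)

_CONSEQUENCE_PROBS = {
    "intronic": 0.45,
    "ncRNA": 0.15,
    "promoter_upstream": 0.12,
    "UTR": 0.10,
    "intergenic": 0.08,
    "synonymous": 0.05,
    "missense": 0.05,
}

_BASES = "ACGT"


@dataclass
class SyntheticConfig:
    """Tunable generator parameters; defaults are the study-scale conditions."""

    seed: int
    n_aam: int = 22
    n_cm: int = 66
    n_variants: int = 500
    # effect-class proportions (must sum to 1)
    prop_null: float = 0.70
    prop_differential: float = 0.18
    prop_somatic_spike: float = 0.08
    prop_missing_af: float = 0.04
    # differential carrier probabilities (dominant vs other cohort)
    diff_carrier_high: float = 0.8
    diff_carrier_low: float = 0.05
    # null carrier probability range
    null_carrier_range: tuple[float, float] = (0.05, 0.5)
    # AF model
    aligned_fraction: float = 0.7  # of non-missing differential variants
    aim_threshold: float = 0.01
    af_missing_null_fraction: float = 0.1  # null variants lacking AF rows
    # ingestion stress
    dropout_fraction: float = 0.05  # carrier calls failing depth/quality/consensus
    pad_fraction: float = 0.1  # VCF rows written suffix-padded (normalization test)
    # depth/quality model (read-level, around 500x)
    mean_depth: float = 500.0
    depth_dispersion: float = 8.0  # negative-binomial size parameter
    min_depth: int = 199
    min_quality: float = 30.0
    # catalogue model
    shared_not_confirmed_fraction: float = 0.3  # non-somatic variants with records
    n_decoys: int = 30
    indel_fraction: float = 0.1

    def __post_init__(self) -> None:
        props = (self.prop_null, self.prop_differential,
                 self.prop_somatic_spike, self.prop_missing_af)
        if any(p < 0 for p in props) or abs(sum(props) - 1.0) > 1e-9:
            raise ConfigError(f"effect-class proportions must be >= 0 and sum to 1, got {props}")
        for p in (self.diff_carrier_high, self.diff_carrier_low, *self.null_carrier_range):
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"carrier probability {p} outside [0, 1]")
        if self.seed is None:
            raise ConfigError("seed is mandatory")


@dataclass
class SyntheticTruth:
    """Per-variant ground truth for a generated cohort."""

    table: pd.DataFrame = field(repr=False)
    # columns: chrom,pos,ref,alt,gene,consequence,effect_class,
    # p_carrier_aam,p_carrier_cm,af_afr,af_nfe,somatic,pc_related,
    # expected_dominant,expected_alignment,expected_group

    def key_of(self, row) -> VariantKey:
        return VariantKey(row.chrom, int(row.pos), row.ref, row.alt)

    @property
    def keys(self) -> list[VariantKey]:
        return [self.key_of(r) for r in self.table.itertuples(index=False)]


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _draw_variant_sites(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Distinct normalized variant sites with gene and consequence labels."""
    contigs = [f"chr{c}" for c in list(range(1, 23)) + ["X", "Y"]]
    weights = np.array([1.6 if c == "chr7" else (0.3 if c in ("chrX", "chrY") else 1.0)
                        for c in contigs])
    weights /= weights.sum()
    gene_pool = list(_REAL_GENES) + [f"GENE{i:03d}" for i in range(1, 62)]
    rows, used = [], set()
    while len(rows) < cfg.n_variants:
        contig = contigs[rng.choice(len(contigs), p=weights)]
        pos = int(rng.integers(1_000_000, 200_000_000))
        if (contig, pos) in used:
            continue
        used.add((contig, pos))
        ref = _BASES[rng.integers(4)]
        if rng.random() < cfg.indel_fraction:
            if rng.random() < 0.5:  # insertion
                alt = ref + "".join(_BASES[i] for i in rng.integers(0, 4, rng.integers(1, 4)))
            else:  # deletion
                ref = ref + "".join(_BASES[i] for i in rng.integers(0, 4, rng.integers(1, 4)))
                alt = ref[0]
        else:
            alt = _BASES[(rng.integers(1, 4) + _BASES.index(ref)) % 4]
        cons_names = list(_CONSEQUENCE_PROBS)
        consequence = cons_names[rng.choice(len(cons_names), p=list(_CONSEQUENCE_PROBS.values()))]
        gene = "" if consequence == "intergenic" and rng.random() < 0.5 else \
            gene_pool[rng.integers(len(gene_pool))]
        rows.append({"chrom": contig, "pos": pos, "ref": ref, "alt": alt,
                     "gene": gene, "consequence": consequence})
    df = pd.DataFrame(rows)
    return df.sort_values(["chrom", "pos", "ref", "alt"]).reset_index(drop=True)


def build_truth(cfg: SyntheticConfig) -> SyntheticTruth:
    """Draw the per-variant ground truth (no sampling of patients yet)."""
    streams = _streams(cfg.seed)
    rng_v, rng_af = streams["variants"], streams["afs"]
    sites = _draw_variant_sites(cfg, rng_v)
    n = len(sites)
    classes = rng_v.choice(
        EFFECT_CLASSES, size=n,
        p=[cfg.prop_null, cfg.prop_differential, cfg.prop_somatic_spike, cfg.prop_missing_af],
    )
    p_aam = np.empty(n)
    p_cm = np.empty(n)
    dominant = np.array([""] * n, dtype=object)
    lo, hi = cfg.null_carrier_range
    for i, cls in enumerate(classes):
        if cls == "null":
            p = rng_v.uniform(lo, hi)
            p_aam[i] = p_cm[i] = p
        else:
            if rng_v.random() < 0.5:
                dominant[i] = "AAM"
                p_aam[i], p_cm[i] = cfg.diff_carrier_high, cfg.diff_carrier_low
            else:
                dominant[i] = "CM"
                p_aam[i], p_cm[i] = cfg.diff_carrier_low, cfg.diff_carrier_high

    af_afr = np.full(n, np.nan)
    af_nfe = np.full(n, np.nan)
    alignment = np.array(["no_data"] * n, dtype=object)
    for i, cls in enumerate(classes):
        if cls == "missing_af":
            continue
        if cls == "null":
            if rng_af.random() < cfg.af_missing_null_fraction:
                continue
            base = rng_af.uniform(0.01, 0.6)
            jitter = rng_af.uniform(-0.05, 0.05)
            af_afr[i] = float(np.clip(base + jitter, 0.0, 1.0))
            af_nfe[i] = float(np.clip(base - jitter, 0.0, 1.0))
            continue
        # differential / somatic_spike: aligned or discordant w.r.t. dominance
        base = rng_af.uniform(0.05, 0.5)
        if rng_af.random() < cfg.aligned_fraction:
            delta = rng_af.uniform(cfg.aim_threshold * 2, 0.3)
            alignment[i] = "aligned"
        else:
            if rng_af.random() < 0.5:  # opposite direction
                delta = -rng_af.uniform(cfg.aim_threshold * 2, 0.3)
            else:  # sub-threshold concordance
                delta = rng_af.uniform(0.0, cfg.aim_threshold * 0.9)
            alignment[i] = "not_aligned"
        favoured_af = float(np.clip(base + delta, 0.0, 1.0))
        other_af = float(np.clip(base, 0.0, 1.0))
        if abs(favoured_af - other_af) >= cfg.aim_threshold and alignment[i] == "not_aligned" and delta >= 0:
            # clipping can promote a sub-threshold draw; re-pin just below
            favoured_af = other_af + cfg.aim_threshold * 0.5
        if dominant[i] == "AAM":
            af_afr[i], af_nfe[i] = favoured_af, other_af
        else:
            af_nfe[i], af_afr[i] = favoured_af, other_af

    somatic = classes == "somatic_spike"
    pc_set = set(_DEFAULT_PC_GENES)
    pc_related = sites["gene"].isin(pc_set).to_numpy()

    expected_group: list[object] = []
    for i in range(n):
        if classes[i] == "null" or alignment[i] == "no_data":
            expected_group.append(pd.NA)
        else:
            expected_group.append(
                classify_eight_groups(alignment[i], bool(somatic[i]), bool(pc_related[i]))
            )

    table = sites.assign(
        effect_class=classes,
        p_carrier_aam=p_aam,
        p_carrier_cm=p_cm,
        af_afr=af_afr,
        af_nfe=af_nfe,
        somatic=somatic,
        pc_related=pc_related,
        expected_dominant=dominant,
        expected_alignment=[alignment[i] if classes[i] != "null" else "" for i in range(n)],
        expected_group=expected_group,
    )
    return SyntheticTruth(table)


def sample_ids(cfg: SyntheticConfig) -> list[tuple[str, str]]:
    return [(f"AAM{i:02d}", "AAM") for i in range(1, cfg.n_aam + 1)] + [
        (f"CM{i:02d}", "CM") for i in range(1, cfg.n_cm + 1)
    ]


def generate_carrier_matrix(
    cfg: SyntheticConfig, truth: SyntheticTruth | None = None
) -> tuple[CohortVariantMatrix, SyntheticTruth]:
    """Bernoulli carrier draws for every (variant, patient) pair.

    Variants drawn with zero carriers overall are given one forced carrier
    (in the dominant cohort for differential classes) so the matrix
    invariant "every variant has >= 1 carrier" holds.
    """
    truth = truth or build_truth(cfg)
    rng = _streams(cfg.seed)["carriers"]
    patients = sample_ids(cfg)
    labels = np.array([lab for _, lab in patients])
    p_rows = np.where(labels == "AAM",
                      truth.table["p_carrier_aam"].to_numpy()[:, None],
                      truth.table["p_carrier_cm"].to_numpy()[:, None])
    carrier = (rng.random((len(truth.table), len(patients))) < p_rows).astype(np.int8)
    for i in np.flatnonzero(carrier.sum(axis=1) == 0):
        dom = truth.table["expected_dominant"].iat[i]
        cols = np.flatnonzero(labels == dom) if dom else np.arange(len(patients))
        carrier[i, cols[rng.integers(len(cols))]] = 1
    matrix = CohortVariantMatrix(truth.keys, patients, carrier)
    return matrix, truth


def _metadata_frame(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Patient metadata; clinical categories follow the study-scale counts.

    For the default 22/66 cohort the metastasis site/time counts are the
    study's exactly; other cohort sizes draw from the same proportions.
    """
    patients = sample_ids(cfg)
    rows = []
    for cohort, n_total in (("AAM", cfg.n_aam), ("CM", cfg.n_cm)):
        idx = 0 if cohort == "AAM" else 1
        ref_n = 22 if cohort == "AAM" else 66
        sites: list[str] = []
        times: list[str] = []
        for cat, counts in DEFAULT_METASTASIS_SITES.items():
            k = counts[idx] if n_total == ref_n else int(round(counts[idx] * n_total / ref_n))
            sites.extend([cat] * k)
        for cat, counts in DEFAULT_METASTASIS_TIMES.items():
            k = counts[idx] if n_total == ref_n else int(round(counts[idx] * n_total / ref_n))
            times.extend([cat] * k)
        # pad/trim to exactly n_total (rounding drift for non-default sizes)
        while len(sites) < n_total:
            sites.append("not_reported")
        while len(times) < n_total:
            times.append("not_reported")
        sites, times = sites[:n_total], times[:n_total]
        rng.shuffle(sites)
        rng.shuffle(times)
        mean, sd = (59.45, 8.4) if cohort == "AAM" else (62.3, 7.9)
        ages = np.clip(rng.normal(mean, sd, n_total), 40, 90).round(1)
        members = [sid for sid, lab in patients if lab == cohort]
        for sid, site, time, age in zip(members, sites, times, ages):
            rows.append({"sample_id": sid, "race": cohort, "age": age,
                         "metastasis_site": site, "metastasis_time": time})
    return pd.DataFrame(rows)


def _vcf_header(contigs: list[str]) -> str:
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    return "\n".join(lines) + "\n"


def _draw_depth(cfg: SyntheticConfig, rng: np.random.Generator, passing: bool) -> int:
    """Overdispersed read depth around the configured mean (negative binomial)."""
    size = cfg.depth_dispersion
    p = size / (size + cfg.mean_depth)
    for _ in range(100):
        d = int(rng.negative_binomial(size, p))
        if passing and d >= cfg.min_depth:
            return d
        if not passing and d < cfg.min_depth:
            return d
    return cfg.min_depth if passing else cfg.min_depth - 1


def generate_cohort(
    cfg: SyntheticConfig, out_dir: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Write per-sample VCF pairs, metadata and annotation TSVs.

    Returns (manifest, metadata, annotations, truth). The manifest maps
    sample_id -> freebayes/lofreq VCF paths. A ``dropout_fraction`` of
    carrier calls is written so as to fail ingestion (sub-threshold depth,
    sub-threshold quality, or present in a single caller only); a
    ``pad_fraction`` of VCF rows is suffix-padded to exercise key
    normalization.
    """
    out_dir = Path(out_dir)
    vcf_dir = out_dir / "vcf"
    vcf_dir.mkdir(parents=True, exist_ok=True)
    matrix, truth = generate_carrier_matrix(cfg)
    streams = _streams(cfg.seed)
    rng_vcf, rng_meta = streams["vcf"], streams["metadata"]

    metadata = _metadata_frame(cfg, rng_meta)
    metadata.to_csv(out_dir / "metadata.tsv", sep="\t", index=False)

    annotations = truth.table[["chrom", "pos", "ref", "alt", "gene", "consequence"]].copy()
    annotations["aa_change"] = [
        f"p.{_BASES[i % 4]}{i}{_BASES[(i + 1) % 4]}" if c == "missense" else ""
        for i, c in enumerate(truth.table["consequence"])
    ]
    annotations.to_csv(out_dir / "annotations.tsv", sep="\t", index=False)

    contigs = sorted({v.contig for v in matrix.variants})
    manifest_rows = []
    for j, (sid, _) in enumerate(matrix.patients):
        records: dict[str, list[tuple]] = {"freebayes": [], "lofreq": []}
        for i in np.flatnonzero(matrix.carrier[:, j]):
            key = matrix.variants[int(i)]
            fail_mode = None
            if rng_vcf.random() < cfg.dropout_fraction:
                fail_mode = ("depth", "quality", "single")[rng_vcf.integers(3)]
            ref, alt, pos = key.ref, key.alt, key.pos
            if rng_vcf.random() < cfg.pad_fraction:  # suffix pad; normalizes back
                pad = _BASES[rng_vcf.integers(4)]
                ref, alt = ref + pad, alt + pad
            for caller in ("freebayes", "lofreq"):
                if fail_mode == "single" and caller == "lofreq":
                    continue
                passing = fail_mode not in ("depth", "quality")
                depth = _draw_depth(cfg, rng_vcf, fail_mode != "depth")
                if fail_mode == "quality":
                    qual = float(rng_vcf.uniform(0, cfg.min_quality - 0.1))
                else:
                    qual = float(rng_vcf.uniform(cfg.min_quality, 95))
                records[caller].append((key.contig, pos, ref, alt, qual, depth))
        manifest_row = {"sample_id": sid}
        for caller in ("freebayes", "lofreq"):
            path = vcf_dir / f"{sid}.{caller}.vcf"
            body = ""
            recs = sorted(records[caller], key=lambda r: (contigs.index(r[0]), r[1], r[2], r[3]))
            for contig, pos, ref, alt, qual, depth in recs:
                body += f"{contig}\t{pos}\t.\t{ref}\t{alt}\t{qual:.1f}\tPASS\tDP={depth}\n"
            path.write_text(_vcf_header(contigs) + body)
            manifest_row[f"{caller}_vcf"] = str(path.relative_to(out_dir))
        manifest_rows.append(manifest_row)
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    truth.table.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return manifest, metadata, annotations, truth


def generate_reference_tables(
    cfg: SyntheticConfig, truth: SyntheticTruth, out_dir: str | Path
) -> dict[str, Path]:
    """Write the COSMIC-like table, population-AF table, PC gene list and GMT.

    Confirmed-somatic male records are emitted exactly for truth-somatic
    variants; a fraction of the remaining variants get not-confirmed
    records (shared but germline-like); decoy confirmed-somatic records
    violating each curation filter are planted on truth-non-somatic
    variants so that skipping curation would corrupt the somatic flags.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = _streams(cfg.seed)["cosmic"]
    rng_sets = _streams(cfg.seed)["genesets"]
    t = truth.table

    site_pool = ["prostate", "lung", "large_intestine", "skin", "haematopoietic_and_lymphoid_tissue"]
    hist_pool = ["carcinoma", "adenocarcinoma", "malignant_melanoma", "lymphoid_neoplasm"]
    rows = []
    for row in t.itertuples(index=False):
        if row.somatic:
            for _ in range(int(rng.integers(1, 4))):
                rows.append({
                    "gene": row.gene or "UNKNOWN",
                    "chrom": row.chrom, "pos": row.pos, "ref": row.ref, "alt": row.alt,
                    "sample_gender": "male",
                    "primary_site": "prostate" if rng.random() < 0.6 else site_pool[rng.integers(1, len(site_pool))],
                    "histology": hist_pool[rng.integers(2)],
                    "histology_subtype": "NS",
                    "somatic_status": "Confirmed somatic variant",
                })
        elif rng.random() < cfg.shared_not_confirmed_fraction:
            rows.append({
                "gene": row.gene or "UNKNOWN",
                "chrom": row.chrom, "pos": row.pos, "ref": row.ref, "alt": row.alt,
                "sample_gender": "male",
                "primary_site": site_pool[rng.integers(len(site_pool))],
                "histology": hist_pool[rng.integers(len(hist_pool))],
                "histology_subtype": "NS",
                "somatic_status": "Variant of unknown origin",
            })
    # decoys: confirmed-somatic records that each violate one curation filter,
    # planted on non-somatic variants
    non_somatic = t[~t["somatic"]].reset_index(drop=True)
    decoy_modes = [("female", "prostate", "carcinoma"),
                   ("male", "ovary", "carcinoma"),
                   ("male", "breast", "carcinoma"),
                   ("male", "prostate", "ductal carcinoma"),
                   ("male", "prostate", "serous carcinoma")]
    for d in range(min(cfg.n_decoys, len(non_somatic))):
        row = non_somatic.iloc[int(rng.integers(len(non_somatic)))]
        gender, site, hist = decoy_modes[d % len(decoy_modes)]
        rows.append({
            "gene": row.gene or "UNKNOWN",
            "chrom": row.chrom, "pos": row.pos, "ref": row.ref, "alt": row.alt,
            "sample_gender": gender, "primary_site": site,
            "histology": hist, "histology_subtype": "NS",
            "somatic_status": "Confirmed somatic variant",
        })
    cosmic = pd.DataFrame(rows).sort_values(["chrom", "pos", "ref", "alt", "sample_gender"])
    cosmic_path = out_dir / "cosmic_like.tsv"
    cosmic.to_csv(cosmic_path, sep="\t", index=False)

    af = t.loc[t["af_afr"].notna() | t["af_nfe"].notna(),
               ["chrom", "pos", "ref", "alt", "af_afr", "af_nfe"]]
    af_path = out_dir / "population_af.tsv"
    af.to_csv(af_path, sep="\t", index=False, float_format="%.6f")

    pc_path = out_dir / "kegg_pc_genes.txt"
    pc_path.write_text("\n".join(sorted(_DEFAULT_PC_GENES)) + "\n")

    # a small Hallmark-style GMT over the gene pool: one androgen-like set
    # concentrated on PC genes plus random sets
    pool = sorted({g for g in t["gene"] if g})
    gmt_lines = []
    pc_members = sorted(set(_DEFAULT_PC_GENES) & set(pool)) or sorted(_DEFAULT_PC_GENES)[:10]
    gmt_lines.append("SYNTH_ANDROGEN_RESPONSE\tsynthetic PC-gene-heavy set\t" + "\t".join(pc_members))
    for s in range(1, 6):
        members = sorted(rng_sets.choice(pool, size=min(15, len(pool)), replace=False))
        gmt_lines.append(f"SYNTH_SET_{s}\tsynthetic random set\t" + "\t".join(members))
    gmt_path = out_dir / "genesets.gmt"
    gmt_path.write_text("\n".join(gmt_lines) + "\n")

    return {"cosmic": cosmic_path, "population_af": af_path,
            "pc_genes": pc_path, "gmt": gmt_path}
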