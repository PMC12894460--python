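import pathlib

import pandas as pd
import pytest

from cfdna_ancestry.synthetic import (
    SyntheticConfig,
    generate_cohort,
    generate_reference_tables,
)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory) -> dict:
    """One small synthetic cohort bundle shared across the session."""
    out = tmp_path_factory.mktemp("bundle")
    cfg = SyntheticConfig(seed=20240817, n_variants=150)
    manifest, metadata, annotations, truth = generate_cohort(cfg, out)
    paths = generate_reference_tables(cfg, truth, out)
    return {
        "dir": pathlib.Path(out),
        "cfg": cfg,
        "manifest": manifest,
        "metadata": metadata,
        "annotations": annotations,
        "truth": truth,
        "paths": paths,
    }


@pytest.fixture()
def metadata_frame() -> pd.DataFrame:
    """Tiny two-cohort metadata table for matrix-construction tests."""
    return pd.DataFrame(
        {
            "sample_id": ["A1", "A2", "C1", "C2", "C3"],
            "race": ["AAM", "AAM", "CM", "CM", "CM"],
            "age": [61.0, 55.5, 70.2, 64.0, 58.1],
            "metastasis_site": ["bone", "bone", "liver_bone", "bone", "not_reported"],
            "metastasis_time": ["at_diagnosis", "at_relapse", "at_relapse",
                                "at_diagnosis", "not_reported"],
        }
    )


def write_vcf(path: pathlib.Path, rows: list[str], contigs=("chr1", "chr2", "chr7")) -> pathlib.Path:
    """Write a minimal VCF 4.2 file; each row is a pre-formatted body line."""
    header = ["##fileformat=VCFv4.2"]
    header += [f"##contig=<ID={c}>" for c in contigs]
    header.append('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    path.write_text("\n".join(header + rows) + "\n")
    return path
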