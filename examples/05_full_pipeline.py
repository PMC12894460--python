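"""The full analysis end to end on a generated synthetic cohort.

Writes per-sample VCF pairs, metadata and reference tables, then runs
ingestion -> cohort stats -> differential testing -> catalogue curation ->
ancestry classification -> enrichment, and prints the headline counts.
"""

import json
import tempfile
from pathlib import Path

from cfdna_ancestry import RunConfig, SyntheticConfig, run_pipeline
from cfdna_ancestry.synthetic import generate_cohort, generate_reference_tables

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    cfg = SyntheticConfig(seed=3, n_variants=200)
    _, _, _, truth = generate_cohort(cfg, tmp)
    paths = generate_reference_tables(cfg, truth, tmp)

    summary = run_pipeline(RunConfig(
        manifest=tmp / "manifest.tsv",
        metadata=tmp / "metadata.tsv",
        annotations=tmp / "annotations.tsv",
        cosmic_table=paths["cosmic"],
        population_af=paths["population_af"],
        pc_gene_list=paths["pc_genes"],
        gmt_files=[paths["gmt"]],
        out_dir=tmp / "results",
    ))
    print(json.dumps(summary, indent=2))

# n_significant splits into AAM-dominant + CM-dominant (+ ties); classified
# variants fall into groups 1-8 per dominant cohort, with variants lacking
# reference AFs counted under n_no_data. All tables live in results/.
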