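"""Offline hypergeometric gene-set enrichment from a GMT file."""

import tempfile
from pathlib import Path

from cfdna_ancestry import GeneSetCollection, hypergeometric_enrichment, read_gmt

gmt_text = (
    "ANDROGEN_LIKE\tandrogen-response-like set\tKLK2\tKLK3\tTMPRSS2\tNKX3-1\tAR\tELK4\n"
    "DNA_REPAIR\trepair set\tATM\tRAD51\tXRCC1\tXRCC5\tXRCC6\tFANCA\n"
    "RANDOM\tunrelated set\tGENE1\tGENE2\tGENE3\tGENE4\n"
)
with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "sets.gmt"
    path.write_text(gmt_text)
    collection = read_gmt(path, background=20_000)

query = ["KLK2", "TMPRSS2", "AR", "ATM", "BRAF"]
for r in hypergeometric_enrichment(query, collection):
    print(f"{r.set_name:15s} overlap {r.overlap}/{r.set_size}  "
          f"p = {r.p:.3g}  q = {r.q:.3g}")

# p is the upper-tail hypergeometric probability of drawing at least the
# observed overlap from a 20,000-gene background; q is BH-adjusted across
# the three sets in this collection.
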