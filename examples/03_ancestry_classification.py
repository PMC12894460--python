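"""Ancestry alignment and the eight-group classification.

For each significantly differential variant, the AFR vs NFE allele
frequency difference (the ancestry-informative marker, AIM) determines
whether cfDNA dominance is concordant with the reference populations; the
cross with somatic status and PC-pathway membership yields groups 1-8.
"""

from cfdna_ancestry import (
    alignment_status,
    classify_eight_groups,
    compute_aim,
)

cases = [
    # dominant, AF_AFR, AF_NFE, somatic, PC-related
    ("AAM", 0.24, 0.05, True, True),    # concordant, catalogued, pathway gene
    ("AAM", 0.02, 0.18, False, False),  # discordant germline-like variant
    ("CM", 0.050, 0.055, False, True),  # sub-threshold difference
    ("CM", 0.01, 0.30, True, False),    # concordant somatic, non-pathway
    ("AAM", None, 0.30, False, False),  # no reference AF available
]

print(f"{'dominant':>8s} {'AIM':>6s} {'alignment':>12s} {'somatic':>8s} {'PC':>4s} {'group':>6s}")
for dominant, afr, nfe, somatic, pc in cases:
    aim, _ = compute_aim(afr, nfe)
    alignment = alignment_status(dominant, afr, nfe)
    group = (
        "no_data" if alignment == "no_data"
        else classify_eight_groups(alignment, somatic, pc)
    )
    aim_s = "NA" if aim is None else f"{aim:.3f}"
    print(f"{dominant:>8s} {aim_s:>6s} {alignment:>12s} {str(somatic):>8s} {str(pc):>4s} {str(group):>6s}")

# Group 1 = aligned+somatic+PC-related ... group 8 = discordant, germline-like,
# non-pathway. Variants without population AFs are reported separately.
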