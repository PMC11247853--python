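"""PGT-A ploidy classification from copy-number aberration fractions.

A segment is aneuploid above 70% aberrant-cell fraction, euploid below a
chromosome-specific lower limit (30% for chr 13/16/18/21, 50% for chr 19,
40% otherwise) and mosaic in between.  Aneuploid embryos are subtyped by
their chromosome variation.
"""

from blastotrace import CopyNumberProfile, Segment, classify_embryo_ploidy, classify_segment

for chrom, frac in [("5", 0.75), ("19", 0.45), ("13", 0.35)]:
    print(f"chr{chrom} at {frac:.0%}: {classify_segment(chrom, frac)}")

profiles = {
    "monosomy 16": CopyNumberProfile([Segment("16", "whole_chromosome", "loss", 0.9)]),
    "segmental dup": CopyNumberProfile([Segment("4", "segmental", "gain", 0.8)]),
    "mosaic": CopyNumberProfile([Segment("7", "whole_chromosome", "loss", 0.55)]),
    "euploid": CopyNumberProfile([Segment("1", "segmental", "loss", 0.05)]),
}
for name, prof in profiles.items():
    call = classify_embryo_ploidy(prof)
    print(f"{name:>14}: label={call.label}" + (f", subtype={call.subtype}" if call.subtype else ""))
# Embryo-level rule: any aneuploid segment makes the embryo aneuploid;
# whole-chromosome events (monosomy/trisomy) take precedence over the
# fragment classes when subtyping.
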