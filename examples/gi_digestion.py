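"""Predict gastrointestinal digestion products of candidate inhibitors.

Runs the two-stage digestion model — gastric pepsin, then intestinal
trypsin + chymotrypsin — on two candidate peptides.  With
missed_cleavages > 0 the stages are treated as incomplete, so partial
products that coexist with terminal fragments in a real digest are
retained.
"""

from peptiforge import DigestConfig, get_rule, sequential_digest

gastric = [get_rule("pepsin")]
intestinal = [get_rule("trypsin"), get_rule("chymotrypsin")]

for peptide in ("FPL", "FPHFDL"):
    complete = sequential_digest(peptide, gastric, intestinal, DigestConfig(missed_cleavages=0))
    partial = sequential_digest(peptide, gastric, intestinal, DigestConfig(missed_cleavages=1))
    print(f"{peptide}:")
    print(f"  complete digestion : {sorted(complete, key=len)}")
    print(f"  incomplete (partial products retained): {sorted(partial, key=len)}")
# A peptide whose fragments are themselves known inhibitors can retain or
# even gain activity after digestion; one that is reduced to free amino
# acids loses it.  Intermediates like FPHF and FPHFD appear only when the
# gastric phase is allowed to be incomplete.
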