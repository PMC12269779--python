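"""Published ascidian-specific COI mini-barcode primer pairs.

The original pair (AscCOI) and the redesigned pair (AscCOI2) target a
short fragment of the mitochondrial COI gene in ascidians (Tunicata).
The redesign kept the forward binding site and moved the reverse site
21 bp in the 3' direction onto a better-conserved region.

Forward binding-site coordinates (1-based alignment columns 361-380 on
the reference ascidian alignment) are recorded on the pairs; reverse
sites are left unset because the published coordinate span does not
equal the reverse primer length, so placement is better determined by
the mismatch-minimising scan against a given alignment's consensus.
Amplicon sizes are stored as published.
"""

from .model import DegeneratePrimer, PrimerPair

ASCCOI_F = DegeneratePrimer("AscCOI_F", "CCTGATATGGCNTTYCCHCG", "forward")
ASCCOI_R = DegeneratePrimer("AscCOI_R", "GCTAAATGHAAHGAAAAAATWGC", "reverse")
ASCCOI2_F = DegeneratePrimer("AscCOI2_F", "CCDGATATAGCHTTYCCWCG", "forward")
ASCCOI2_R = DegeneratePrimer("AscCOI2_R", "CYTAAAATACTWGAAACNCTHGC", "reverse")

ASCCOI = PrimerPair(ASCCOI_F, ASCCOI_R, forward_site=(361, 380), expected_amplicon=197)
ASCCOI2 = PrimerPair(ASCCOI2_F, ASCCOI2_R, forward_site=(361, 380), expected_amplicon=216)

PAIRS = {"AscCOI": ASCCOI, "AscCOI2": ASCCOI2}
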