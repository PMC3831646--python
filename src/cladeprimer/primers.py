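"""Packaged primer fixtures.

The shipped pair targets the Deinococcus-Thermus phylum on the 16S rRNA
gene; the names carry the 1-based binding coordinates on the reference
gene (forward site 326-350, reverse site 758-785), which imply a 460 bp
product (785 - 326 + 1).
"""

from .iupac import DegeneratePrimer
from .scan import PrimerPair

DEINO_F_326_350 = DegeneratePrimer(
    "Deino-f-326-350", "CGGGAGGCAGCAGTTAGGAATCTTC", 326, 350
)
DEINO_R_758_785 = DegeneratePrimer(
    "Deino-r-758-785", "GTTTAGGGYGTGGACTACCCGGGTATCT", 758, 785
)

DEINO_PAIR = PrimerPair(DEINO_F_326_350, DEINO_R_758_785, min_amplicon=50, max_amplicon=2000)
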