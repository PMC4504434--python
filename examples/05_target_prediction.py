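"""Plant-style miRNA target prediction on a transcript.

Scans every ungapped transcript window against the miRNA in the
antiparallel register. Watson-Crick pairs cost 0, G:U wobbles 0.5 and
mismatches 1.0, doubled within miRNA positions 2-13; sites scoring at or
under 3.0 are reported. A true mismatch at positions 9-11 switches the
predicted mode from cleavage to translational inhibition.
"""

import random

from srnakit._seq import revcomp
from srnakit.targets import scan_targets

mirna = "TTGACCGGATCCGATTACCGG"
rng = random.Random(8)
transcript = "".join(rng.choices("ACGT", k=400))

# plant a perfect site and a central-mismatch site
perfect = revcomp(mirna)
central = list(perfect)
central[len(mirna) - 10] = mirna[9]  # opposite miRNA position 10, unpairable
transcript = (
    transcript[:100] + perfect + transcript[121:250]
    + "".join(central) + transcript[271:]
)

for site in scan_targets(mirna, transcript, mirna_id="miR-demo"):
    m_rev, bonds, target = site.alignment
    print(f"site [{site.start}, {site.end})  penalty={site.score:.1f}  "
          f"mode={site.inhibition}")
    print(f"  miRNA 3'-{m_rev}-5'")
    print(f"           {bonds}")
    print(f"  target 5'-{target}-3'")
print("\n'|' marks a Watson-Crick pair, 'o' a G:U wobble, a space a mismatch.")
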