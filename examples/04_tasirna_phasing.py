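"""Phased siRNA (tasiRNA) detection and trigger assignment.

Plants a TAS locus by hand: a miR390-style trigger site whose cleavage
point (opposite trigger nucleotide 10) starts five consecutive 21-nt
phased units. Detection scores the register with an exact hypergeometric
tail; the trigger is accepted only if its predicted cleavage coincides
with the first phased position (D1), and the tasiRNAs are named in
D-register nomenclature.
"""

import random

from srnakit._seq import revcomp
from srnakit.mapping import GenomeHit
from srnakit.phasing import (
    assign_phase_initiator,
    detect_phased_clusters,
    name_tasirnas,
    phasing_pvalue,
)

trigger = "TTGACCGGATCCGATTACCGG"  # 21-nt trigger miRNA
rng = random.Random(4)
pad = 30
site = revcomp(trigger)
cleavage = pad + len(trigger) - 10  # base paired to trigger nt 10
n_units = 5

tas = list("".join(rng.choices("ACGT", k=cleavage + 21 * n_units + 40)))
tas[pad : pad + len(trigger)] = list(site)
tas = "".join(tas)

hits = [GenomeHit(f"u{i}", "c", cleavage + 21 * i, cleavage + 21 * (i + 1), "+")
        for i in range(n_units)]
counts = {h.read_id: 8 for h in hits}
seqs = {h.read_id: tas[h.start : h.end] for h in hits}

clusters = detect_phased_clusters(hits, counts, seqs)
cl = clusters[0]
print(f"cluster: [{cl.start}, {cl.end}) register={cl.register_offset} "
      f"k={cl.k} n={cl.n} p={cl.pvalue:.3g}")
print(f"  (exact tail: P(X >= {cl.k}) with {cl.m} in-register of "
      f"{21 * cl.m} positions = {phasing_pvalue(cl.m, cl.n, cl.k):.3g})")

trig = assign_phase_initiator(
    cl, {"miR390": trigger}, tas, {"miR390": "miR390"}, seq_start=0
)
print(f"trigger: {trig.mirna_id} site=[{trig.site_start},{trig.site_end}) "
      f"cleavage@{trig.cleavage} model={trig.hit_model}")

print("tasiRNAs (D-register names, 3' side of the cleavage, + strand):")
for t in name_tasirnas(cl, trig):
    print(f"  {t.name:24s} {t.sequence}")
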