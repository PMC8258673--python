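"""Classify tRF intervals into the six types and name them.

Shows the coordinate rules on a single gene model: fragments anchored at
the 5' end, fragments ending at the CCA-extended 3' end, anticodon-loop
halves, trailer read-throughs, and internal fragments.
"""

import numpy as np

from trfclash import TRNAGeneModel, make_trf_record

rng = np.random.default_rng(0)
seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 76))
gene = TRNAGeneModel(
    gene_id="GluCTC-002", origin="N", sequence=seq,
    anticodon_loop=(32, 38), trailer="ACGTTAGGCA",
)

cases = [
    (1, 20, "body"),          # 5' fragment ending before the loop
    (1, 33, "body"),          # 5' half ending inside the anticodon loop
    (62, 79, "body+CCA"),     # 3' fragment ending at the CCA end
    (66, 84, "body+trailer"), # read-through into the genomic trailer
    (10, 29, "body"),         # internal fragment
]
print(f"gene {gene.gene_id}: length {gene.length}, loop {gene.anticodon_loop}")
for start, end, space in cases:
    rec = make_trf_record(gene, start, end, space=space)
    print(f"  [{start:>2},{end:>2}] in {space:<14} -> {rec.type:<3} {rec.name}")
# The name encodes host gene, nuclear/mitochondrial origin, type and the
# 1-based gene coordinates, so it can be parsed back without the model.
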