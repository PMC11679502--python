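"""Batch mode: design gRNAs for a headerless list of gene symbols / RefSeq IDs.

Unknown names are reported and skipped without aborting the rest of the
batch, mirroring how large CRISPR-screening gene lists are processed.
"""

import tempfile
from pathlib import Path

from knockaid import build_caches, run_batch
from knockaid.toy_fixtures import ToyGeneSpec, make_toy_genome

tmp = Path(tempfile.mkdtemp())
specs = [
    ToyGeneSpec("Alpha", "NM_A1", "+", (120,), (), (("CAA_with_PAM", 1, 30),)),
    ToyGeneSpec("Charlie", "NM_C1", "+", (150,), (), (("TGG_with_antisense_PAM", 1, 60),)),
]
make_toy_genome(specs, seed=5, out_dir=tmp)
caches = build_caches(tmp / "toy.refflat", tmp / "toy.fa", tmp / "caches", assembly_tag="toy")

gene_list = tmp / "genes.csv"
gene_list.write_text("Alpha\nNM_C1\nNoSuchGene\n")  # symbol, RefSeq ID, and a typo

results = run_batch(gene_list, caches, tmp / "output")
print(f"\n{len(results)} of 3 queries produced reports; one CSV per query in {tmp/'output'}.")
print("The skipped line shows batch mode tolerates unknown gene names.")
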