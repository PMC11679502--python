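"""Design knockout gRNAs for a single gene on a generated toy genome.

Builds a small annotation (one single-exon gene with a plantable CAA codon
and one 4-exon gene with splice targets), preprocesses it into caches, and
queries one gene.  Each printed row is a 23-nt sequence (20-nt spacer +
NGG PAM) whose single C-to-T edit either installs a premature stop codon
(PTC rows, with the targeted amino acid) or destroys a GT/AG splice
consensus base so the targeted exon is skipped with a frameshift.
"""

import tempfile
from pathlib import Path

from knockaid import build_caches, run_single
from knockaid.toy_fixtures import ToyGeneSpec, make_toy_genome

tmp = Path(tempfile.mkdtemp())
specs = [
    ToyGeneSpec("Alpha", "NM_A1", "+", (120,), (), (("CAA_with_PAM", 1, 30),)),
    ToyGeneSpec(
        "Bravo", "NM_B1", "-", (90, 100, 90, 90), (40, 40, 40),
        (
            ("acceptor_G_with_antisense_PAM", 2, 0),
            ("donor_G_with_antisense_PAM", 2, 0),
            ("CAA_with_PAM", 1, 40),
        ),
    ),
]
make_toy_genome(specs, seed=5, out_dir=tmp)
caches = build_caches(tmp / "toy.refflat", tmp / "toy.fa", tmp / "caches", assembly_tag="toy")

for gene in ("Alpha", "Bravo"):
    result = run_single(gene, caches, tmp / "output")
    print(f"-> {len(result.ptc_rows)} PTC gRNA(s), {len(result.splice_rows)} splice gRNA(s); "
          f"CSV written to {tmp / 'output' / (gene + '.csv')}\n")

print("A 'target Q9' label means the guide converts glutamine 9 to a stop codon;")
print("'exon 2' on a splice row means the edit forces skipping of exon 2.")
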