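"""Encode a small genome collection as a presence/absence matrix.

Builds three toy genomes one inversion apart, extracts their adjacencies,
and prints the binary encoding used as the pseudo-alignment for tree
inference.
"""

import orderphy as op

doc = op.read_genomes(""">alpha
1 2 3 4 5 $
>beta
1 -3 -2 4 5 $
>gamma
1 2 3 -5 -4 $
""")

for genome in doc:
    adjacencies = op.extract_adjacencies(genome)
    print(f"{genome.name}: {sum(adjacencies.values())} adjacencies+telomeres")

enc = op.build_encoding(list(doc))
print()
print(enc.to_tsv())
print("Each row is a genome, each adjacency/telomere or gene-family column "
      "is 1 when present.\nbeta's inversion of [2,3] breaks (1,2) and (3,4) "
      "and creates (1,-3) and (-2,4).")
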