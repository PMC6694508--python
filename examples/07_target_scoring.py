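"""Score miRNA target sites with the plant complementarity penalty scheme.

Builds a transcript carrying a perfect site, a site with a single G:U
wobble in the 3' region and a site with a seed-region mismatch, scores them
(match 0, G:U 0.5, mismatch 1, doubled at positions 2-13, cutoff 4.0) and
prints the resulting table plus the bipartite network degrees.
"""

from polymir.io import revcomp
from polymir.targets import build_network, scan_transcripts

mirna = "TGACAGAAGAGAGTGAGCAC"          # a miR156-family mature, 20 nt

perfect = revcomp(mirna)
wobble = list(perfect)
wobble[len(mirna) - 15] = "T"           # G:U facing miRNA position 15 -> +0.5
seed_mm = list(perfect)
seed_mm[len(mirna) - 5] = "C"           # mismatch at position 5 -> +2.0 (doubled)

transcripts = {
    "tx_perfect": "AAAAG" + perfect + "GAAAA",
    "tx_wobble": "CCCCC" + "".join(wobble) + "GGGGG",
    "tx_seed_mm": "TTTTT" + "".join(seed_mm) + "AAAAA",
}
hits = scan_transcripts({"miR156": mirna}, transcripts, max_score=4.0)
print(hits.to_string(index=False))

edges, nodes = build_network(["miR156"], hits, highlight={"tx_seed_mm"})
print("\nnode degrees:")
print(nodes.to_string(index=False))
# Annotation strings read 5'->3' along the miRNA: "|" perfect pair,
# "o" G:U wobble, "x" mismatch.
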