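"""Compute assembly-integrity statistics on a synthetic genome.

Builds a stand-in with the worked type genome's dimensions (27 contigs,
1,277,965 bp, 52 % GC target) and prints the statistics that the
recommended integrity thresholds (contigs < 100, N50 > 25 kb, largest
contig > 100 kb) are tested against.
"""

from seqcode import compute_stats
from seqcode.synthetic import type_genome_standin

assembly = type_genome_standin(seed=0)
stats = compute_stats(assembly)

print(f"total length   : {stats.total_length:,} bp")
print(f"contigs        : {stats.n_contigs}")
print(f"largest contig : {stats.largest_contig:,} bp")
print(f"N50 / L50      : {stats.n50:,} bp / {stats.l50}")
print(f"G+C            : {stats.gc_percent:.2f} % (reported as {stats.gc_percent_rounded} %)")
print(f"ambiguous bases: {stats.ambiguous_bases}")
# The three integrity numbers feed the recommended checks; N50 and the
# largest contig must clear 25 kb and 100 kb for a warning-free report.
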