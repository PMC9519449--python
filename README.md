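# seqcode-tools

Tooling for nomenclature of prokaryotes described from sequence data: most
archaea and bacteria have never been cultured, so their genomes — isolate
assemblies, metagenome-assembled genomes (MAGs) and single-amplified genomes
(SAGs) — serve as the nomenclatural types that anchor their names. This
package implements the automated machinery such a registration system needs,
as a tested Python library with a thin `seqcode` command-line interface:

* **Assembly statistics** (`seqcode.assembly`) — FASTA input (plain or
  gzip), total length, contig count, largest contig, N50/L50, G+C content
  with ambiguous bases excluded from the denominator.
* **Quality control** (`seqcode.qc`) — tiered verdicts on whether a genome
  may serve as a type. Required: MAG/SAG completeness > 90 % and
  contamination < 5 % (CheckM-style estimates consumed as inputs), isolate
  read coverage ≥ 10×, assembly and raw-read deposition in INSDC (raw reads
  waived for names effectively published before 2023-01-01). Recommended
  (warnings only): 16S gene > 75 % complete and non-chimaeric, > 80 % of the
  20 tRNA isoacceptor types, < 100 contigs, N50 > 25 kb, largest contig
  > 100 kb, MAG/SAG coverage ≥ 10×, genome/16S taxonomy concordance.
  Equality at a strict bound fails (exactly 90 % complete is ineligible).
* **Nomenclature** (`seqcode.nomenclature`) — parsing of binomials and
  higher-rank names, orthography checks (Latin letters, capitalization),
  rank suffixes (family *-aceae*, order *-ales*, class *-ia*, phylum
  *-ota*), *Candidatus* stripping, casefolded homonym keys and an advisory
  edit-distance report for minor orthographic variants.
* **Registry** (`seqcode.registry`) — the registration state machine
  (draft → provisionally accepted → valid, with rejection from the
  non-terminal states), path 1 (preregistration; the DOI-entry date is the
  priority date) and path 2 (intake of already-published names, including
  *Candidatus* names, validated on curator acceptance), earliest-date
  priority resolution in which names from the culture-based code (ICNP)
  compete with their own dates but never displace an earlier entry,
  protologue rendering with the superscript-Ts type marker, and
  schema-versioned JSON import/export.
* **Dereplication** (`seqcode.dereplication`) — pairwise ANI from external
  FastANI-style tables or a built-in MinHash estimator (canonical k-mers,
  bottom sketch; Mash distance d = −ln(2j/(1+j))/k, ANI = 100(1−d)), and
  single-linkage species clusters at the conventional > 95 % ANI threshold
  with quality-scored representatives (completeness − 5 × contamination).
* **Synthetic fixtures** (`seqcode.synthetic`) — seeded generators for
  assemblies with target GC and contig-length laws, substitution-only
  mutation (expected ANI exactly 100·(1 − rate)), random metric vectors and
  populated registries with answer keys, so everything is testable offline.

## Worked example

```python
from seqcode import compute_stats
from seqcode.synthetic import type_genome_standin

stats = compute_stats(type_genome_standin(seed=0))
print(stats.total_length, stats.n_contigs, stats.gc_percent_rounded)
# 1277965 27 52
```

Those are the published headline statistics of the worked type genome — a
1,277,965 bp, 27-contig archaeal MAG with 52 % G+C — recomputed here on a
synthetic stand-in generated to the same dimensions (the real assembly is
public under INSDC accession `GCA_021323375.2` and can be substituted via
`seqcode stats <file.fna>`).

Registration end to end (see `examples/04_registry_workflow.py` for the
full script):

```text
registered Wolframiiraptor gerlachensis: provisionally_accepted
DOI recorded -> valid, priority date 2022-09-19

Wolframiiraptor gerlachensis^Ts (ger.lach.en'sis N.L. masc. adj. gerlachensis, of Gerlach)

The genome available under the assembly accession number (GCA_021323375.2^Ts) is the designated nomenclatural type for the species.
```

The `^Ts` marker is the plain-text rendering of the superscript that flags
a nomenclatural type whose own type is a DNA sequence. The `examples/`
directory holds one short script per capability (statistics, QC, name
checks, registry workflow, dereplication), each printing the numbers it
computes and what they mean.

## Command line

```bash
seqcode stats assembly.fna --json
seqcode qc --category MAG --completeness 98.06 --contamination 0.49 \
           --assembly-deposited --raw-reads-deposited
seqcode name check "Candidatus Wolframiiraptor" --rank genus
seqcode register draft|attach-doi|validate-path2|priority|protologue --registry reg.json ...
seqcode derep --ani-table fastani.tsv --threshold 95
seqcode synth assembly|mutate|registry --seed 1 ...
```

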