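# gdrkit

A toolkit for working with standardized terminology for Mendelian
gene–disease relationships, and for putting that terminology to work in
variant filtering.

Clinical genomics resources have historically described the same inheritance
pattern in incompatible ways ("autosomal dominant", "AD", "monoallelic", ...),
which makes curated gene–disease knowledge hard to use computationally. This
package implements a harmonized model built around three ideas:

1. **Allelic requirement.** Each Mendelian gene–disease pair is annotated with
   one of eight *allelic requirement* tokens (e.g. `monoallelic_autosomal`,
   `biallelic_autosomal`, `monoallelic_X_hemizygous`), each paired one-to-one
   with a classic mode-of-inheritance term (Autosomal Dominant, Autosomal
   Recessive, X-linked Recessive, ...) under a single HPO identifier. The
   requirement spelling states *what genotype an individual needs* to manifest
   disease, which is directly actionable in a filtering pipeline. A
   cross-cutting set of HPO *inheritance qualifiers* (penetrance bands,
   imprinting direction, "typically de novo", "requires heterozygosity",
   sex-limited expression, anticipation, ...) refines the requirement.
2. **Disease-associated variant consequence.** What a pathogenic variant does
   to the gene product is described with six high-level Sequence Ontology
   terms: altered / decreased / increased gene product **level**, absent gene
   product, altered gene product **sequence**, and functionally normal.
   A likelihood matrix maps every variant class of the standard VEP
   consequence vocabulary (33 terms, with `stop_gained` and
   `frameshift_variant` split into NMD-triggering and NMD-escaping rows) onto
   those six consequences with a 5-level ordinal scale (1 = almost never …
   5 = almost always).
3. **Requirement-aware prioritization.** Given a sample's VCF, transcript
   models, and curated gene–disease records, the engine classifies each
   variant from first principles (including nonsense-mediated decay
   assessment of premature termination codons), keeps variants whose
   consequence profile matches the curation, and decides whether the
   observed genotypes *satisfy* the allelic requirement — handling compound
   heterozygote phase, hemizygosity, pseudoautosomal regions, and qualifier
   effects.

## Worked example

A hypothetical X-linked gene `TOYX` carries two distinct curations: biallelic
or hemizygous loss of function causes congenital heart disease
(`monoallelic_X_hemizygous`, i.e. X-linked recessive), while heterozygous loss
of function causes later-onset cardiomyopathy (`monoallelic_X_heterozygous`,
X-linked dominant). The same variant therefore means different things in
different individuals:

```python
from gdrkit import (synth_transcript, synth_variants, VariantRecipe,
                    SampleContext, PARConfig, exemplar_curations, prioritize)

# a reproducible toy transcript on chrX and one hemizygous PTC variant
tx = synth_transcript(n_exons=3, seed=21, chromosome="chrX", gene_symbol="TOYX")
curations = [c for c in exemplar_curations() if c.gene_symbol == "TOYX"]
synth_variants(tx, VariantRecipe(counts={"stop_gained|NMD_triggering": 1},
                                 seed=5, zygosities=("hemizygous",)),
               out_path="proband.vcf", sample="PROBAND")

context = SampleContext("PROBAND", sex_karyotype="XY",
                        par_config=PARConfig.default_grch38())
report = prioritize("proband.vcf", curations, [tx], context)
print(report[["gene", "disease", "allelic_requirement", "variant", "class",
              "score", "status", "rationale_codes"]].to_string(index=False))
```

Output:

```
gene                        disease        allelic_requirement      variant                      class  score    status      rationale_codes
TOYX congenital heart disease (toy)   monoallelic_X_hemizygous chrX:233:A>T stop_gained|NMD_triggering      5 satisfied hemizygous_satisfies
TOYX   dilated cardiomyopathy (toy) monoallelic_X_heterozygous chrX:233:A>T stop_gained|NMD_triggering      5 satisfied hemizygous_satisfies
```

The hemizygous male satisfies *both* curations. Rerunning with
`sex_karyotype="XX"` and a heterozygous genotype leaves the X-linked-recessive
curation `unsatisfied` (rationale `het_carrier_only`: the individual is a
carrier) while the heterozygous curation stays `satisfied`.

The likelihood matrix is available directly and on the command line:

```console
$ gdr matrix lookup "stop_gained|NMD_triggering" "absent gene product"
5	almost always

$ gdr matrix suggest --observed "stop_gained|NMD_triggering"
transcript_ablation
splice_acceptor_variant
splice_donor_variant
frameshift_variant|NMD_triggering
start_lost
5_prime_UTR_variant
```

`suggest` answers "a gene is known to act through these pathogenic classes —
which other, never-yet-reported classes share the same high-level consequence
and deserve attention?" (e.g. an NMD-triggering frameshift acts like an
NMD-triggering nonsense variant).

Other CLI commands: `gdr validate curations.tsv` (schema + vocabulary
validation, exit code 0 iff clean), `gdr annotate` (classify a VCF against
transcript models), `gdr prioritize` (the full report above).

## Package layout

| module | contents |
| --- | --- |
| `gdrkit.terms` | requirement/inheritance vocabulary, qualifier terms, lookups with typo suggestions |
| `gdrkit.curation` | `GeneDiseaseCuration` schema, validation, TSV/JSON round-tripping |
| `gdrkit.matrix` | consequence hierarchy, likelihood matrix, `infer_consequences`, `suggest_classes` |
| `gdrkit.transcripts` | transcript models, GFF3+FASTA / JSON loaders |
| `gdrkit.annotate` | first-principles variant classification, NMD assessment, VEP CSQ parsing, VCF input |
| `gdrkit.engine` | requirement satisfaction, qualifier application, `prioritize` |
| `gdrkit.fixtures` | seeded toy transcripts, recipe-driven variant/VCF synthesis, exemplar curations |

See `docs/methods.md` for the model, parameter choices, and their rationale.

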