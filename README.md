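# rdnsv

Estimate the **relative density of nonsynonymous variants (rdnsv)** in sets of
genes from coding SNV data, compared with the neutral expectation inferred
from synonymous variants.

The method counts synonymous and nonsynonymous mutational opportunities
("sites", each basepair contributing three 1/3-weighted substitution
opportunities), computes the per-site SNV rates `Rn = nsSNV/nsSite` and
`Rs = sSNV/sSite`, and corrects their ratio for the genetic code's enrichment
of transitions among synonymous changes together with the higher mutation
rate of transitions (per-opportunity transition weight `w = 4`, i.e. a
per-basepair ts/tv rate ratio of 2):

```
rdnsv = f · Rn / Rs        with  f = f_s / f_ns
```

For typical gene sets (`sSite/nsSite ≈ 0.3`, `f_s = 1.25`, `f_ns = 0.925`)
this reduces to the rule of thumb `rdnsv ≈ 0.4 · nsSNV/sSNV`.

To separate strongly deleterious sites from weak selection on segregating
variants, rdnsv is additionally estimated in derived-allele-frequency bins
(upper edges 2%, 5%, 10%, 20%, 40%, 80%, 95%) and an unweighted OLS line is
fitted over `x = ln(p/0.01)`. The intercept `rdnsv_0` (prediction near
frequency 0) approximates the proportion of nonsynonymous sites where
variants are tolerated to segregate; `rdnsv_1 = rdnsv_0 + slope·ln(100)`
(prediction at frequency 1) approximates the proportion of sites where
variants may reach fixation.

## Package layout

| module | contents |
|---|---|
| `rdnsv.code_sites` | genetic code, substitution classification, exact-rational site counting |
| `rdnsv.annotation` | transcript models, SNV→codon mapping, effect classification, allele polarization |
| `rdnsv.core` | correction factors (`f_s`, `f_ns`, `f`, `f'`), pooled rdnsv estimator |
| `rdnsv.spectrum` | frequency bins, per-bin estimates, spectrum regression (`rdnsv_0`, `rdnsv_1`) |
| `rdnsv.genesets` | permutation tests, random-set background envelopes, expression-based gene selection |
| `rdnsv.simulate` | selection-aware synthetic CDS/VCF generator with recorded ground truth |
| `rdnsv.io`, `rdnsv.cli` | FASTA/VCF/BED12/TSV adapters and the `rdnsv` command line |

## Command line

```sh
# synthetic dataset with 40% intolerant nonsynonymous sites and purifying
# selection on the tolerated ones
rdnsv simulate --out sim/ --seed 7 --pi-intolerant 0.4 --gamma 6

# site counts per gene
rdnsv sites --cds sim/cds.fasta --out sites.tsv

# annotate SNVs and estimate pooled rdnsv
rdnsv annotate --vcf sim/snvs.vcf --genome sim/genome.fasta \
               --transcripts sim/transcripts.tsv --out annotated.tsv
rdnsv estimate --vcf sim/snvs.vcf --genome sim/genome.fasta \
               --transcripts sim/transcripts.tsv --out estimate.tsv

# frequency-spectrum regression (rdnsv_0 / rdnsv_1)
rdnsv spectrum --vcf sim/snvs.vcf --genome sim/genome.fasta \
               --transcripts sim/transcripts.tsv --out spectrum.tsv

# permutation comparison of two gene sets and a random-set background
rdnsv compare --vcf sim/snvs.vcf --genome sim/genome.fasta \
              --transcripts sim/transcripts.tsv \
              --set-a a.txt --set-b b.txt --n-perm 10000 --seed 1 --out cmp.json
rdnsv background --vcf sim/snvs.vcf --genome sim/genome.fasta \
                 --transcripts sim/transcripts.tsv \
                 --set-size 1500 --n-draws 10000 --seed 1 --out bg.json

# tissue-specific gene selection from an expression matrix
rdnsv select-genes --expression expr.tsv --tissue-groups groups.tsv \
                   --k 1500 --out selected.txt
```

Transcript models are accepted either as a 5-column TSV
(`gene_id, transcript_id, chrom, strand, start-end[,start-end...]`,
0-based half-open) or as BED12. VCF allele counts come from `AC`/`AN` INFO
or genotypes; the ancestral allele from the `AA` INFO key or a sidecar TSV,
with a minor-allele fallback when absent. `--fixed-factors` switches from
factors computed on the input's own site counts to the published constants.

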