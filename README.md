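# apygwas

Single-step GWAS for large genotyped livestock populations: genotype
quality control, a VanRaden genomic relationship matrix with blending, the
**Algorithm for Proven and Young (APY)** factored inverse, **SNP-effect
back-solving** from genomic estimated breeding values (GEBVs), sliding-window
variance ranking, and positional candidate-gene annotation.

The intended users are animal-breeding and quantitative-genetics
researchers who receive GEBVs and variance components from a national
genetic evaluation and want to map which genomic regions carry the additive
variance — at population sizes (10⁵–10⁶ genotyped animals) where a dense
inverse of the genomic relationship matrix **G** is infeasible.

## The method

With dosage codes centered by twice the allele frequency,
`Z[i,j] = codes[i,j] − 2p_j`, the relationship matrix is

```
G = Z Zᵀ / (2 Σ p_j (1 − p_j)),      G_b = (1 − β) G + β I   (β = 0.05)
```

APY partitions animals into a *core* set c and *noncore* set n and stores

```
G_APY⁻¹ = [Gcc⁻¹ 0; 0 0] + [−Gcc⁻¹Gcn; I] Mnn⁻¹ [−GncGcc⁻¹, I],
m_jj = g_jj − g_jcᵀ Gcc⁻¹ g_jc
```

so only the core block is ever inverted. The core size is the number of
leading eigenvalues of **G** (squared singular values of **Z**) explaining
98% of its variance. SNP effects are back-solved from GEBVs û as

```
â = (1 − β) · b · (σ²_u / σ²_a) · Zᵀ G_APY⁻¹ û
```

the variance attributed to SNP *i* is `σ²_ai = â_i² · 2 p_i (1 − p_i)`, and
moving windows of adjacent SNPs are ranked by the percentage of the
additive variance σ²_a their summed σ²_ai explain. Window span can be
derived from effective population size: independent chromosome segments
have expected length 1/(4·Ne) Morgans, and eight such segments capture most
QTL variance — for Ne = 196 that is 0.00128 Morgans per segment and a
1.02 Mb window. Top-ranked windows are intersected with a gene annotation
(BED/GFF3) to list positional candidate genes.

A synthetic-data module simulates multi-chromosome genotypes with
half/full-sib family structure, sparse QTL, phenotypes at a stated
heritability, and GEBVs from an actual GBLUP solve, so the entire pipeline
is testable without proprietary evaluation data.

## Worked example

```sh
apygwas simulate --n-animals 200 --n-snps 1000 --n-chromosomes 3 \
    --seed 11 --outdir study
cat > config.yaml <<EOF
genotypes: study/genotypes.tsv
snp_map: study/snp_map.tsv
gebvs: study/gebvs.tsv
outdir: out
core_variance_threshold: 0.98
window_snps: 25
top_mode: count
top_value: 10
seed: 11
traits: [sim_trait]
sigma_a2: {sim_trait: 1.0}
EOF
apygwas run --config config.yaml
```

which prints

```
{"n_core": 170, "window_snps": 25, "traits": ["sim_trait"], "outdir": "out"}
```

— 170 of the 200 animals carry 98% of the variance in **G** and become the
APY core. `out/top_windows_sim_trait.tsv` then starts

```
window_id  chromosome  start_bp  end_bp   first_snp_index  n_snps  variance        pct_of_additive  rank
886        3           2870000   3110000  934              25      0.006127809498  0.6127809498     1
305        2           20000     270000   329              25      0.00476186366   0.476186366      26
```

the best 25-SNP window sits on chromosome 3 at 2.87–3.11 Mb and explains
0.61% of the additive genetic variance; lower rows are the best remaining
windows that do not share SNPs with a better one (rank gaps mark skipped
overlapping windows). With gene intervals supplied, `annotation_<trait>.tsv`
lists the genes overlapping each kept window.

Every stage is also available stand-alone (`apygwas qc`, `grm`, `apy`,
`backsolve`, `windows`, `annotate`) and as library functions.

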