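# Methods

## Model and procedure

The pipeline assumes an additive infinitesimal-plus-QTL model. Animal-level
genomic estimated breeding values (GEBVs) û for each trait, together with
the trait's additive genetic variance σ²_a, are inputs produced by an
external evaluation; the pipeline's job is to decompose them into per-SNP
and per-region contributions.

Stages, in order:

1. **Marker QC** (`genotype_qc`). SNPs — never animals — are removed by
   four rules: non-autosomal position, call rate < 0.90, minor allele
   frequency < 0.05, and Hardy–Weinberg deviation, measured as
   |observed − expected heterozygote frequency|, > 0.15. Allele and
   heterozygote frequencies use non-missing calls only. Attribution order
   (autosome → call rate → MAF → HWE) is fixed so audit reports are
   reproducible; the rules themselves are order-independent, which the
   idempotence test confirms.
2. **GRM** (`grm_apy`). VanRaden's first method, G = ZZᵀ/2Σp(1−p), with Z
   centered by 2p and missing calls mean-imputed (zero after centering).
   Allele frequencies are observed post-QC frequencies; base-population
   frequencies are never available in practice. G is blended with the
   identity, G_b = (1−β)G + βI, β = 0.05, to guarantee positive
   definiteness; a pedigree-derived target matrix can be supplied instead
   but is not required.
3. **APY inverse**. Core animals are chosen uniformly at random (a seed is
   part of the configuration and recorded in the manifest); the core
   *size* is the number of leading eigenvalues of G explaining a requested
   fraction (default 98%) of its variance, computed as squared singular
   values of Z. The factored inverse stores G_cc⁻¹, G_cn, and the noncore
   conditional variances m_jj = g_jj − g_jcᵀG_cc⁻¹g_jc; matrix–vector
   products against G_APY⁻¹ cost O(n_c² + n_c·n_n) and never materialize
   the inverse.
4. **Back-solving** (`gwas_windows`).
   â = (1−β)·b·(σ²_u/σ²_a)·Zᵀ·G_APY⁻¹·û. When σ²_u is not supplied it
   defaults to σ²_a/2Σp(1−p), the standard SNP-variance relation; the
   tuning parameter b defaults to 1. Per-SNP variance is
   σ²_ai = â_i²·2p_i(1−p_i).
5. **Windows**. Moving windows of a fixed number of adjacent SNPs within a
   chromosome (default step 1; step = window size gives a disjoint tiling,
   under which window sums conserve Σσ²_ai exactly). Window variance is
   reported as a percentage of σ²_a (or of Σσ²_ai, configurable) and
   ranked descending with ties broken by (chromosome, start position).
   Because step-1 windows overlap heavily, the default reporting policy
   keeps the top fraction/count *greedily without SNP overlap*: walking
   ranks in order and discarding windows sharing a SNP with a kept one.
   A keep-all policy exposes the raw ranking.
6. **Annotation** (`annotation`). Genes (BED 0-based half-open or GFF3
   `gene` records, both normalized to 1-based inclusive) are reported for
   a window on any ≥1 bp same-chromosome overlap, since genes routinely
   exceed single windows; a containment flag restricts to genes fully
   inside. Biotypes are pass-through strings.

## Window size from effective population size

Independent chromosome segments in a population of effective size Ne have
expected length 1/(4·Ne) Morgans, and eight such segments span the region
capturing the bulk of QTL variance. For Ne = 196 this gives 0.0012755…
Morgans per segment and 0.010204… Morgans ≈ 1.02 Mb per window at the
1 cM ≈ 1 Mb default. Given a SNP density the span converts to a SNP count;
the calculator reports values rounded to 5/4/2 decimals alongside full
precision.

## Synthetic data: what it does and does not emulate

`synthetic_data` emulates the statistical structure downstream stages
assume: per-locus base allele frequencies uniform on [maf_low, maf_high];
founders drawn binomially; non-founders gene-dropped from one sire and a
few dam founders per family (two-generation half/full-sib mixture), which
produces the off-diagonal G structure that makes core selection
non-trivial; sparse standard-normal QTL effects rescaled so var(Z·effects)
equals σ²_a exactly; phenotypes y = μ + bv + e with σ²_e fixed by the
heritability; and GEBVs from a single-trait GBLUP solve
û = σ²_a·G_b(σ²_a·G_b + σ²_e·I)⁻¹(y − ȳ) on genotyped animals with a
single mean fixed effect. Fixed-effect structure richer than a mean is
deliberately absent: fixed effects are absorbed before back-solving and do
not enter the implemented equations, and for the same reason no pedigree
enters the simulator — back-solving consumes only û, σ²_a and G.

Not emulated: linkage-disequilibrium decay with genetic distance (loci are
independent given pedigree, so within-window LD is purely familial),
selection, multi-breed structure, genotyping error, imputation artifacts,
and categorical traits. Passing tests therefore demonstrate the algebra
and the pipeline's statistical behaviour under idealized architecture, not
performance on real LD patterns.

Default study conditions used by the validation suite: 1,000 animals,
5,000 SNPs on 5 chromosomes, 50 families, MAF ∈ [0.05, 0.5], 20 QTL,
σ²_a = 1, h² = 0.5, β = 0.05, 25-SNP windows, top 20 windows — sizes at
which a dense-inverse oracle is still computable for cross-checking.

## Numerical choices

- Blending precedes APY: the noncore recursion runs on the blended G, since
  β and G_APY⁻¹ are applied together at back-solving time.
- m_jj must exceed 1e−10 × max diag(G); smaller values raise, naming the
  animal, as the signature of a too-small core or an indefinite G.
- The core-size rule uses a 1e−12 slack inside the cumulative-variance
  comparison so that round-off in trailing singular values cannot inflate
  the core at threshold 1.0.
- GBLUP solves use a symmetric positive-definite solver on
  σ²_a·G_b + σ²_e·I.
- Ranking ties and greedy selection are fully deterministic; reruns with
  the same config are bit-identical (tested by hash comparison).
- Degenerate inputs: all-fixed loci make the GRM scale zero and raise;
  an all-missing SNP column raises in frequency computation but is caught
  by the call-rate filter during QC; QC removing every SNP warns rather
  than raises.

## Design choices where the design was open

- **HWE statistic**: absolute heterozygote-frequency deviation, not an
  exact test; the sign of the deviation is not used.
- **Single MAF threshold** (default 0.05): imputation is out of scope, so
  no separate pre-/post-imputation thresholds exist.
- **VanRaden method I** for G, matching the 2p-centering convention used
  throughout.
- **Identity blend target** by default; a supplied matrix is accepted.
- **Greedy non-overlap** as the default top-window policy: with step-1
  windows the raw top 1% would be near-duplicates of a few peaks, while
  greedy selection reports distinct regions. The exhaustive-search test
  confirms greedy selection is optimal for strictly decreasing variance
  profiles.
- **One shared Z per panel** across traits; per-trait â differ only
  through û and the variance ratio.
- A known limitation of partial-core APY with blending: core rows of
  G_APY⁻¹·G_b are not exactly identity rows even when the core exceeds the
  rank of the unblended G, because blending makes the noncore Schur
  complement non-diagonal. The deviation shrinks monotonically with core
  size and vanishes at all-core, which is what the tests assert.

## Limitations

- Dense G construction bounds practical size to ~10⁴ animals in this
  implementation; the APY *representation* is matrix-free but its inputs
  here are dense blocks of an in-memory G. Out-of-core G is out of scope.
- No p-values or multiple-testing control: the method ranks variance
  contributions; inference is positional, not significance-based.
- GEBV reliabilities are not modelled; heritability and sample size are
  the knobs controlling GEBV accuracy in simulation.
- Functional enrichment, Ensembl access and QTL-database cross-referencing
  are out of scope; annotation is interval overlap only.
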