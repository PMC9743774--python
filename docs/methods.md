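# Methods

## Data model

Genotypes follow the HipSTR convention: each STR allele is recorded as its
base-pair deviation from the reference allele (the `GB` FORMAT field), so a
genotype of `0|2` at a dinucleotide locus means one reference-length allele
and one allele 2 bp (one repeat unit) longer. Internally a cohort is a
catalog of loci, a pedigree, and one call matrix (loci × samples) per
family, with per-call quality, depth, stutter fraction, flanking-indel
fraction and per-allele read depths (FORMAT tag `ADC`; the reserved `AD`
tag is defined per REF/ALT allele, ours is per called allele).

Pedigrees are three-generation family units: four G1 grandparents, a G2
couple, and the G3 children. Generations are inferred structurally from
parent links, so input order and ID naming are irrelevant.

## Call filtering

A call passes when all of the following hold:

- genotype present;
- quality strictly greater than 0.9;
- flanking-indel fraction strictly below 0.15;
- stutter fraction strictly below 0.15;
- depth between 10 and 1000 inclusive.

Loci overlapping segmental duplications (half-open interval overlap) are
excluded for every sample. The strict/inclusive boundary choices are pinned
by tests. The *denominator* of every rate is per trio: a locus counts for a
G2 parent only when the parent and both of that parent's parents pass.

## De novo calling

A candidate allele of a G2 parent is one whose deviation equals no allele
of the pooled four parental alleles. Validation requires: ≥ 2 genotyped G3
carriers of the allele (children failing filters count toward neither
carriers nor the genotyped total), the partner genotyped and not carrying
the allele, and ≥ 10 supporting reads (per-allele depth when available,
total depth otherwise). Rejection reasons are recorded separately
(untransmitted / shared with partner / partner missing / low support).

### False-negative correction

A true heterozygous de novo allele reaches < 2 of n children with
probability `binom.cdf(1, n, 1/2)`; for n = 9 this is 10/512 ≈ 0.0195.
Corrected rates divide by (1 − that probability). The expected count of
missed mutations is reported as the integer part (floor) of
`n_putative × rate` — the expectation covers at least that many whole
events, and the published arithmetic (5249 × 10/512 = 102.52 → 102) is a
truncation.

## Grandparent-of-origin phasing

The de novo allele itself cannot be phased (it is by construction
misinherited), so the flanking-marker haplotype co-transmitted with it is
used instead:

1. **Trio phasing** is exact Mendelian logic: a biallelic site is assigned
   a parental origin when exactly one assignment of the child's alleles to
   the parents is consistent; the all-three-heterozygous configuration is
   uninformative; violations are flagged and excluded. No population LD,
   imputation or statistical phasing is involved.
2. The haplotype each carrier grandchild inherited from the carrier parent
   is extracted and a per-site **majority consensus** over the ≥ 2 carrier
   haplotypes is built (ties unresolved).
3. The consensus is scored against the four grandparental haplotypes
   (transmitted/untransmitted for each of the carrier's parents, phased via
   the carrier trio). The likelihood of each is the fraction of mutually
   resolved sites that agree; the **unique solution score**
   uss = 100 × (best − second best). With fewer than two defined
   likelihoods the window is unresolvable.
4. The scan runs over window half-widths 10–300 kb in 10 kb steps;
   the window with the highest uss wins, the smallest window on exact ties
   (ascending scan with a strict `>`). An assignment is accepted at
   uss ≥ 10.

Note that even error-free markers give uss far below 100: the runner-up
haplotype matches the consensus at roughly half its sites by chance, so
uss concentrates near 50 under perfect data.

The **size change** (original allele → de novo allele) is resolvable only
when the donor grandparent is homozygous at the STR; a change that is not a
whole number of repeat units is flagged as a within-unit indel and gets no
step count.

## Statistics

- Per-trio rate = validated events / passing loci of that trio; per-motif
  rate counts unique mutated loci (a locus mutated in several trios counts
  once) over pooled passing locus-trios of that period.
- Perfect vs interrupted mutability uses a pooled two-proportion Z test;
  purity of a locus is classified from its sequence (perfect = longest
  tandem run of any rotation of the motif, trailing partial unit allowed,
  spans the full locus).
- Transmission sex bias is a two-sided exact binomial test at 1/2
  (overall, or per family with Bonferroni correction), expansion vs
  contraction likewise.
- Feature enrichment is an exact binomial test of observed event counts
  against the genomic fraction of each (merged) annotation track.
- Genome-wide extrapolation divides the mean per-individual event count by
  the assayable catalog fraction.
- The power helper is Monte-Carlo over the same binomial test.

## Simulator

The simulator is the package's verification instrument: it generates
catalogs, founder haplotypes, meioses, markers and calls with an exact
truth table, so the caller and phaser can be tested against known ground
truth. Defaults are study conditions, not tuning knobs.

What it emulates:

- catalogs with configurable loci per motif length and a perfect/imperfect
  sequence mix (default 60% perfect);
- founder STR alleles drawn per locus (geometric toward the reference by
  default, uniform optionally) with non-negative offsets — the reference
  is the shortest allele, keeping every allele representable as sequence;
  a configurable lattice spacing (in repeat units) lets calibration runs
  make single-step mutants collision-free;
- mutation as a generalized stepwise model: per-generation rate halved per
  meiosis, step count geometric with p = 0.9 (single steps dominate),
  expansion probability 0.55;
- phased biallelic flanking markers every 2 kb within ±300 kb, MAF 0.5,
  with optional genotype error;
- calls at configurable depth with optional random call failure
  (`call_failure_rate`), which the filters then remove;
- per-allele read depths splitting total depth.

What it does **not** emulate: stutter artifacts as miscalled genotypes
(stutter/flank fractions are drawn as passing metadata, not as errors),
recombination inside marker windows, linkage disequilibrium between
markers, locus-length- or purity-dependent rate variation (off by
default; `purity_rate_scaling` adds a simple scaling), sequencing of
physically impossible alleles, and parental-age effects.

`implant_mutation` forces a single mutation into a rate-zero family with
guaranteed novelty of the allele, consistent re-inheritance by the
children, marker co-segregation, and truth-table bookkeeping; fixture
scenarios (`clean`, `shared_with_partner`, `untransmitted`,
`donor_ambiguous`, `within_unit_indel`) construct the pipeline's edge
cases deterministically. The `clean` and `within_unit_indel` scenarios
force a homozygous donor so that the size change is resolvable.

## Numerical choices

- Deviations are stored as int32 with a large negative sentinel for
  missing; haplotype choices as int8. `analyze_sim_streaming` simulates
  and analyzes one family at a time with an identical random stream to the
  retained path, keeping memory constant for large calibration runs.
- All randomness flows through `numpy.random.default_rng` seeded
  explicitly; identical seeds give bit-identical cohorts, VCFs and
  results.
- VCF floats round-trip through htslib single precision; comparisons use
  1e-6 tolerances.
- Rate calibration uses dinucleotide-only catalogs sized to ≈ 30 expected
  events per replicate and founder spacing of 5 units, so estimator error
  reflects only sampling noise and the (corrected) transmission filter.

## Limitations

- The caller assumes exact bp-deviation matches; it does not model calling
  uncertainty beyond the pass/fail filters, nor somatic mosaicism.
- Phasing needs ≥ 2 carrier grandchildren by design; events in G3
  themselves (truth rows with meiosis `G2->G3`) are simulated but not
  callable by the G1/G2/G3 design and are excluded from rate targets.
- The binomial correction assumes independent Mendelian transmission and
  heterozygous carriers.
- The expansion/contraction and step-size analyses use only events with a
  resolvable (homozygous-donor) size change, which is a non-random subset.
- Window-grid phasing handles recombination only indirectly (a recombined
  window shows depressed likelihoods and loses to a cleaner window).
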