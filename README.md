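# strdenovo

Detection, validation, phasing and population-dynamics analysis of de novo
short tandem repeat (STR) mutations in large three-generation families.

## The problem

STRs mutate orders of magnitude faster than point variants, mostly by
slippage that adds or removes whole repeat units. Calling a *de novo* STR
mutation from sequencing data is error-prone: stutter artifacts, flanking
indels and low-quality genotypes mimic novel alleles. Three-generation
pedigrees (four grandparents, a central couple, many grandchildren) allow a
far stricter design:

1. a **candidate** is an allele of a second-generation (G2) parent that
   matches neither allele of either of that parent's own parents (G1);
2. a candidate is **validated** only if it was transmitted to at least two
   genotyped grandchildren (G3), the other G2 parent is genotyped and does
   not carry the same allele, and at least ten reads support the allele —
   a sequencing artifact virtually never satisfies all three;
3. the validated allele is then **phased to its grandparent of origin** by
   reconstructing, from the carrier grandchildren, the flanking-marker
   haplotype that travels with it and matching that haplotype against the
   four phased grandparental haplotypes.

The transmission requirement discards real mutations that reached fewer
than two of the children by Mendelian chance; with nine children that
probability is `binom.cdf(1, 9, 1/2) = 10/512 ≈ 0.0195`, and mutation-rate
estimates are corrected for it.

The package implements the full pipeline (catalog handling with repeat
purity classification, HipSTR-style VCF and pedigree I/O, call filtering,
de novo calling, pedigree-exact phasing, dynamics statistics) plus a
simulator that generates cohorts with known ground truth for end-to-end
verification.

## Worked example

Generate a one-family fixture containing a single constructed de novo
mutation, then run the whole pipeline on the emitted files:

```python
from strdenovo.sim import build_scenario, write_outputs

sim, row, _ = build_scenario("clean", seed=11)
write_outputs(sim, "example_data")
print("implanted:", row.donor, "->", row.recipient, "allele", row.denovo_allele, "bp")
```

```
implanted: F000_gm1 -> F000_fa allele -2 bp
```

So the ground truth is: grandmother `F000_gm1` passed a mutated allele
(2 bp shorter than her own) to the father `F000_fa`. Now recover it from
the files alone:

```
$ strdenovo all --catalog example_data/catalog.tsv \
                --vcf example_data/str_calls.vcf \
                --ped example_data/families.ped \
                --markers example_data/markers.vcf \
                --out example_out
1 candidates -> 1 validated -> 1 phased -> example_out
```

The event table confirms the carrier and allele, and the phase table
recovers the donor grandparent, her sex, and the single-step contraction:

```
$ cut -f6,9,13,14 example_out/denovo_events.tsv
carrier   denovo_allele  status     n_g3_carriers
F000_fa   -2             validated  6

$ cut -f5,10,11,12,18 example_out/phase_results.tsv
window_kb  uss                donor     donor_sex  step_flag
90         41.77215189873418  F000_gm1  2          step
```

`uss` is the unique solution score: 100 × (best − second best) grandparental
haplotype match likelihood; assignments with uss ≥ 10 are accepted. Every
stage also writes a `manifest.json` with the funnel counts
(`n_candidate_events`, `n_validated`, `n_phase_resolved`, ...).

The same pipeline is available stage by stage (`strdenovo simulate`,
`filter`, `call-denovo`, `phase`, `stats`) and as a Python API
(`strdenovo.pipeline.analyze_families`, `phase_marker_events`,
`strdenovo.stats.mutation_rates`, ...).

## Layout

- `src/strdenovo/catalog.py` — STR catalog, motif canonicalisation, repeat
  purity classification (perfect vs interrupted).
- `src/strdenovo/pedio.py` — pedigree, HipSTR-convention STR VCF (GB
  bp-deviation genotypes), phased marker VCF, BED/annotation helpers.
- `src/strdenovo/filtering.py` — per-call quality filters, per-trio
  denominators, segmental-duplication exclusion.
- `src/strdenovo/denovo.py` — candidate detection, transmission validation,
  binomial false-negative model, concordance.
- `src/strdenovo/phasing.py` — pedigree-exact trio phasing, consensus over
  carrier haplotypes, grandparent matching over a window grid.
- `src/strdenovo/stats.py` — rates, purity mutability, transmission bias,
  expansion/contraction, enrichment, extrapolation, power.
- `src/strdenovo/sim.py` — generative pedigree/STR/marker simulator with
  exact truth tables and fixture scenarios.
- `src/strdenovo/pipeline.py`, `src/strdenovo/cli.py` — orchestration and
  the `strdenovo` command.

See `docs/methods.md` for the underlying model, parameter choices and
limitations.
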