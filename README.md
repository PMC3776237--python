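# msimpute

Impute microsatellite (MS/STR) alleles from dense SNP genotypes, and use the
imputed genotypes for parentage verification.

## Why

Livestock parentage testing is migrating from microsatellite panels (alleles
called as PCR fragment sizes in bp, with a 1–5% per-marker genotyping error
rate) to SNP chips. During the transition, an animal genotyped only on SNPs
still needs MS genotypes to be compared against its parents' legacy MS
records. Because the SNP haplotypes flanking an MS locus are in strong
linkage disequilibrium with the MS allele carried in cis — many haplotypes
are identical by descent from ancestors predating breed formation, and so
are shared across breeds — an MS allele can be read off a phased SNP
haplotype by table lookup.

`msimpute` implements that method end to end:

1. **Reference panel construction.** Animals with both MS and SNP genotypes
   are phased jointly (the MS is treated as one extra multi-allelic locus),
   giving, for each phased SNP haplotype *h* over a window centered on the
   MS, per-breed counts of the MS alleles observed in cis. A haplotype is
   *tallied* (usable for imputation) when it occurs ≥ 4 times and is linked
   to a single allele 100% of the time (`unique`) or to one allele ≥ 90% of
   the time (`concordant`).
2. **Window-size optimization.** Candidate window sizes are scanned in
   increasing order; the scan stops when the tallied count reaches a
   confirmed maximum or when growing the window adds ≤ 1% more tallied
   haplotypes.
3. **Imputation.** Each of a SNP-only animal's two phased haplotypes is
   looked up independently; a hit returns the entry's most common allele
   with its confidence (primary-allele fraction) and support (observation
   count). Unseen haplotypes are retried at shorter, centered sub-windows
   (back-off), each such match flagged with its depth.
4. **Parentage verification.** A marker conflicts with a parent when the
   offspring shares no allele with that parent; with per-marker error rates
   of 1%, the probability of ≥ 1 error across 11 markers is
   1 − 0.99¹¹ ≈ 10.5%, so exclusion requires ≥ 2 conflicting markers.
5. **Self-correcting workflow.** Animals that fail verification are MS
   genotyped; confirmed genotypes that contradict the imputation are merged
   back into the reference panel (with a version bump), so rare haplotypes
   and mis-scored parents are captured over time.

A bundled simulator generates multi-breed cohorts with known truth —
ancestral haplotypes partially shared across breeds, Dirichlet drift,
recombination, stepwise MS mutation, and the three fragment-calling error
modes (mis-calls, ±2 bp size rounding, allele dropout) — so every stage is
testable without access to proprietary cattle data.

## Worked example

A validation animal's imputed genotype *123/115* conflicts with its sire's
reported *117/117*, yet the two animals share a SNP haplotype. The
reference panel shows that haplotype linked to allele *123* 937 times out of
940 observations and to *117* only once:

```python
from msimpute import AssociationTable, impute_animal

hap = "AB" * 20
table = AssociationTable("TGLA126", len(hap))
for allele, count in ((123, 937), (117, 1), (121, 2)):
    table.add_observation(hap, "pooled", allele, count)

entry = table.entries[hap]
print(f"{100 * entry.primary_fraction:.2f}%")  # 99.68%
print(f"{100 * entry.allele_totals[117] / entry.total_count:.2f}%")  # 0.11%
print(table.classify(hap))  # concordant

result = impute_animal((hap, hap), table, "query")
print(result.call_1.allele)  # 123
```

The shared haplotype carries *123* at 99.68%, so the imputation stands and
the sire's reported *117/117* is the probable mis-score (e.g. the *123*
allele failed to amplify). `msimpute.parentage.haplotype_assisted_review`
automates exactly this diagnosis.

## Command line

```sh
msimpute simulate --seed 4 --out data/
msimpute optimize --snp data/snp_genotypes.tsv --ms data/ms_genotypes.tsv \
    --snp-map data/snp_map.tsv --ms-map data/ms_map.tsv \
    --marker MS1 --sizes 20,40,50,60 --out trace.json
msimpute verify --ms data/ms_genotypes.tsv --pedigree data/pedigree.tsv \
    --out conflicts.tsv
msimpute run-all --seed 3 --out run/
```

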