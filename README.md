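# ppgwas — privacy-preserving GWAS on secret-shared genotypes

`ppgwas` runs case-control and family-based association tests on genotype
data that no single party can read.  Genotypes and phenotypes are split
into three additive shares (one per simulated host) over the ring
Z_{2^k}; case and control groups are marked by secret-shared 0/1 index
vectors; contingency tables are assembled by secure inner products; and
the χ², Cochran–Armitage trend and transmission disequilibrium (TDT)
statistics are carried as exact integer fractions m/n so that
significance at level α reduces to one secure integer comparison

    m/n ≥ p/q      ⇔      m·q ≥ p·n,

where p/q is a public rational approximation of the χ²(1) critical value
t(α).  Nothing is ever made public except the per-SNP decision bits (and,
for the FDR procedure, the rejection count).  Bonferroni and an oblivious
Benjamini–Hochberg correction are built in.

The intended users are methodologists and infrastructure groups studying
cryptographically secure genomic analysis: the package is a faithful,
fully testable single-process simulation of the three-host workflow
(honest-but-curious hosts, trusted offline dealer, recorded message bus),
not a hardened network deployment.

## The statistics

With allele counts a, c (cases) and b, d (controls) at one SNP:

* χ² of independence: `T₁ = N(ad−bc)² / [(a+b)(c+d)(a+c)(b+d)]`, N = a+b+c+d
* two-proportion z² for allele A (identical on 2×2 tables, verified not assumed)
* Cochran–Armitage trend over the 2×3 genotype table with weights (0,1,2)
* TDT: `T₄ = (u−v)²/(u+v)` over trios with two heterozygous parents, where
  u, v count AA and BB children

All are asymptotically χ²(1) under the null; each is computed on shares as
an exact integer fraction (see `docs/methods.md` for the closed forms and
the overflow analysis behind the default ring width k = 128).

## Worked example

Simulate a HapMap-style study (270 donors × 1000 SNPs, one planted
association at SNP 42 with case/control allele-A frequencies 0.60/0.25),
share it across three host directories, form the cohort obliviously from
the shared phenotypes, and run the secure χ² test with Bonferroni
correction:

```sh
ppgwas simulate --n-donors 270 --n-snps 1000 --plant 42:0.6:0.25 \
       --seed 11 --out-dir study
ppgwas encode-share --genotypes study/genotypes.tsv \
       --phenotypes study/phenotypes.csv --out-dir stores --seed 11
ppgwas filter --store-dir stores --criterion "has_disease" --seed 11
ppgwas test --store-dir stores --test chi2 --correction bonferroni \
       --seed 11 --out-dir results
```

which prints

```
wrote 1000 SNPs x 270 donors to study
shared 1000 SNPs x 270 donors into stores/host{0,1,2}
index vectors written into stores/host{0,1,2}
1 significant / 1000 SNPs (0 undefined); opened value kinds: ['decision', 'undefined_flag']
```

Exactly one SNP survives the Bonferroni-corrected level α/1000 = 5×10⁻⁵ —
the planted one, as `results/decisions.tsv` shows:

```
snp0041	chi2	0	0
snp0042	chi2	1	0
snp0043	chi2	0	0
```

The third column is the released decision bit, the fourth flags SNPs whose
statistic was undefined (monomorphic sites; such SNPs are never called
significant).  `results/run_metadata.json` records the public run
parameters (test, α = 5×10⁻⁵ after correction, q = 10⁶, ring k, seeds,
message-bus counts per protocol stage).  Each `stores/host{0,1,2}/`
directory alone is uniform noise; deleting any one of them makes
reconstruction fail — three of three shares are required.

Swap `--correction bh` for the oblivious Benjamini–Hochberg procedure,
`--test catt` for the trend test, or simulate trios
(`ppgwas simulate --trios ...`) and run `--test tdt --trios-file
study/trios.tsv`.  Analysts with direct phenotype access can instead pass
`--cases-file` to `ppgwas filter` (scenario 1); the criterion grammar for
scenario 2 is `attr >= const`, `<=`, `<`, `>`, `==`, combined with `&`,
`|`, `!` and parentheses.

### Genotype TSV dialect

Header `snp_id<TAB><donor>...`, one row per SNP with calls AA/AB/BB/NN.
VCF input (biallelic GT fields) is also accepted: REF maps to allele A,
the first ALT to allele B, half-calls to NN, and multi-allelic sites are
skipped with a warning.  Phenotypes are a CSV with a `donor_id` column;
0/1 columns are treated as booleans, others as non-negative integers.

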