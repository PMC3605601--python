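# Methods

## The problem

A genome-wide association study (GWAS) compares genotype frequencies between
a case group and a control group, SNP by SNP, and reports the loci whose
allele or genotype distributions differ significantly.  Pooling cohorts
across biobanks improves power but collides with the fact that a genotype is
an identity code: even aggregate allele frequencies can reveal whether a
person participated.  `ppgwas` runs the whole analysis on data that no
single party can read: every genotype and phenotype value is split into
three additive shares, the hosts compute obliviously on the shares, and the
only values ever made public are the per-SNP significance bits (plus, for
the FDR procedure, the number of rejections).

## Secure computation model

**Sharing.**  A value `x` lives on the ring Z\_{2^k} as three summands
`s0 + s1 + s2 ≡ x (mod 2^k)`, one per host.  `s0, s1` are uniform draws, so
each share — and each pair of shares — is marginally uniform: any single
host (or any two, in this 3-out-of-3 scheme) sees noise.  Addition,
subtraction, and multiplication or addition by public constants are local.

**Multiplication.**  Beaver-triple protocol with a trusted offline dealer:
for a precomputed shared triple `(a, b, c = a·b)` the hosts open the masked
differences `d = x − a` and `e = y − b` (both uniform, so the opening leaks
nothing) and locally assemble `c + d·b + e·a + d·e`.  Triples are never
reused; the dealer stream is seedable so runs are reproducible.

**Comparison.**  `[x ≥ y]` for operands below `2^(k−2)`: the hosts form
`D = x − y + 2^(k−2)` (whose bit k−2 is exactly the answer, since the
offset keeps D in `(0, 2^(k−1))`), mask it with a dealer-supplied random
ring element `r` whose bits they hold in shared form, open the uniform
value `c = D + r`, and recover bit k−2 of `c − r` with a shared borrow
chain driven by the public bits of `c` (k−1 secure multiplications).  The
`2^(k−2)` operand bound is a caller contract: violations produce an
undefined bit and are prevented at run level by the ring-width check below.

**Execution model.**  The three hosts are in-process actors; every step
that would cross the network is recorded on a message bus (round, message
and payload counts per protocol tag).  The schedule of secure operations
depends only on input *shapes* — donor count, SNP count, criterion shape,
list length — never on data, and the bus log is the test surface for that
claim.  This is a functional simulation of an honest-but-curious
three-party deployment: no real networking, no malicious security, no
timing-channel defences, and the dealer is trusted for preprocessing only.

## Genotype encoding and storage

Each biallelic call becomes a pair of allele counts: AA → (2,0),
AB → (1,1), BB → (0,2), and missing NN → (0,0).  The shared database holds
two count rows per SNP (`fA`, `fB`) with one column per donor, plus two
redundant 0/1 flag rows `hAA = [call = AA]` and `hBB = [call = BB]` written
at import time (share-store format version 2).  The flags exist because the
2×3 genotype table needs per-class indicators, and the natural polynomial
`fA(fA−1)/2` cannot be evaluated on the ring — 2 has no multiplicative
inverse modulo 2^k.  With the flags, every cell of every table is a plain
inner product:

* allele 2×2: `a = x·fA`, `c = x·fB` (cases), `b = y·fA`, `d = y·fB`
  (controls), for index vectors x, y;
* genotype 2×3: `r_j = x·i_j`, `s_j = y·i_j` with `i_AA = hAA`,
  `i_AB = fA∘fB` (elementwise; equals 1 exactly for heterozygotes),
  `i_BB = hBB`;
* TDT: informativeness `z = (fA^mother∘fB^mother)∘(fA^father∘fB^father)`
  is 1 iff both parents are heterozygous, and `u = z·hAA^child`,
  `v = z·hBB^child`.

A missing call contributes zero to every count, so NN donors silently drop
out of that SNP's margins (N shrinks accordingly); the importer maps any
VCF half-call to NN rather than guessing.

## Statistics as exact integer fractions

Floating point never touches shares.  Each statistic is carried as a shared
fraction m/n whose rational value equals the real statistic exactly
(allele table `a, c` cases / `b, d` controls, `N' = a+b+c+d`):

* Pearson χ²: `m = N'(ad − bc)²`, `n = (a+b)(c+d)(a+c)(b+d)`;
* pooled two-proportion z² for allele A: `m = N'(a(b+d) − b(a+c))²`, same
  denominator — algebraically identical on 2×2 tables, computed along its
  own route so the identity is *verified* by tests rather than assumed;
* Cochran–Armitage trend with public weights w (default (0,1,2), the
  additive dose-response choice):
  `m = N(Σ_j w_j(m₂r_j − m₁s_j))²`,
  `n = m₁m₂(N Σ_j w_j²n_j − (Σ_j w_j n_j)²)`;
* TDT: `m = (u − v)²`, `n = u + v`.

Signed intermediates wrap in two's complement and are squared before any
comparison, so m and n are non-negative.  All four statistics are
asymptotically χ² with one degree of freedom under their nulls.

A zero denominator (monomorphic SNP, empty group, no informative trios)
marks the statistic *undefined*; the decision stage forces such SNPs to
"not significant" and releases a per-SNP undefined flag, so a genome-wide
run never aborts.

## Significance with a rational threshold

With t(α) the χ²(1) critical value approximated from below by the public
fraction p/q (`p = floor(t·q)`), the release decision is one secure
comparison: `m·q ≥ p·n`.  Ties count as significant.  Rounding errs toward
significance by at most 1/q; decisions can disagree with the
exact real-valued rule only for statistics inside `[p/q, t(α))`, a band of
width < 1/q (q defaults to 10⁶).  Bonferroni rebuilds the threshold at
α/#tests.

**Overflow bound.**  `16(2N)⁵q` bounds both sides of the comparison over
all four tests at N donors; the run aborts at configuration time unless it
is below `2^(k−2)`.  The default k = 128 accommodates N = 1080 donors at
q = 10⁶ with two orders of magnitude to spare; k is configurable per store.
The FDR comparators below cross-multiply two statistics, so their bound is
the stricter `16(2N)⁹` — still comfortably inside k = 128 at N = 1080.

**Oblivious Benjamini–Hochberg.**  The shared fractions are sorted in
descending order by a Batcher odd-even merge network (comparator sequence
depends only on the list length; each comparator is
`m_i·n_j ≥ m_j·n_i` plus a conditional swap).  Undefined statistics are
first normalized obliviously to the neutral fraction 0/1, as is the
padding to a power of two, so they sink and never reject.  Rank i is
compared against the public threshold for level α·i/m; a shared suffix-OR
closes the rejection region downward; and because a conditional swap is an
involution, replaying the recorded network in reverse maps the rank-space
rejection bits back to SNP order without revealing the permutation.  Only
the per-SNP bits and the total rejection count are opened.

## Cohort formation

Scenario 1: the analyst knows the clinical data, supplies member IDs, and
only the 0/1 membership vector is shared.  Scenario 2: phenotypes are
themselves shared, and the hosts evaluate the analyst's inclusion criterion
obliviously — integer comparisons against public constants via secure ≥
(strict and equality forms are derived from the one primitive), AND as a
product, OR as `a + b − ab`, NOT as `1 − a`.  Controls default to the
in-cohort complement of the cases; the package does not require
case/control disjointness beyond that construction.  The criterion grammar
(`age >= 50 & has_diabetes`, versioned) is documented in the README.

## Synthetic study generator

The generator emulates a HapMap-style panel: per SNP an allele-A frequency
f is drawn (default uniform on [0.1, 0.5], a common post-QC MAF window) and
genotypes follow Hardy–Weinberg proportions f², 2f(1−f), (1−f)²;
calls go missing independently at rate 0.01.  Defaults: 270 donors (the
classic HapMap cohort size) and a 1000-SNP panel standing in for a 500K
array at tractable cost; 500 trios in trio mode.  Case/control effects are
planted by regenerating chosen SNPs at group-specific frequencies.  Trio
children inherit one allele per parent, with heterozygous parents
transmitting allele A with probability τ (0.5 = null; distortion can be
restricted to listed SNPs).  Phenotypes are built so the documented
criterion `has_disease` recovers the intended case set exactly, plus an
independent integer `age` for compound criteria.

Deliberately not modelled: linkage disequilibrium, population
stratification, genotyping-error structure, realistic MAF spectra.
Passing tests therefore certify the *protocols and statistics* — exact
agreement with the plaintext reference, calibration of the released
decisions under an idealised null — not robustness to confounding in real
cohorts, which would require the usual plaintext-world answers
(stratification correction, genomic control) that are out of scope here.

## Numerical and design notes

* Shares are Python integers; k = 128 exceeds machine words, and exactness
  matters more than vector speed.  Vector operations batch all per-element
  openings of one protocol round into a single message.
* One root seed per run is split (SHA-256) into independent streams for
  input sharing, the triple dealer and comparison masks; every run is
  bit-reproducible from (inputs, seed).
* Threshold rounding is floor(t·q): the decision errs toward *more*
  significance by < 1/q, never less.
* Ties: `≥` at the threshold is significant; in the sorting network, equal
  keys keep their order (the comparator outputs 1), which cannot split tied
  values across the BH cutoff because thresholds relax with rank.
* Test-suite problem sizes: pipeline-equivalence runs use 270 donors (or 90
  trios) × 1000 SNPs; calibration uses 5000 null SNPs at 200+200 donors
  (case-control) and 500 trios (TDT), streamed per SNP so no full shared
  database is materialised; power uses 100 single-SNP replicates at
  200+200.  These sizes give Monte-Carlo error well below the asserted
  bands while keeping a full run in minutes on one core.
* Calibration checks: the allele/genotype statistics at 800 alleles per
  group are dense enough for a Kolmogorov–Smirnov test against χ²(1).  The
  TDT statistic is not: its exact null is a lattice distribution (u−v has
  the parity of u+v, and there is a point mass of order 1/√(u+v) at zero),
  so a KS test against the continuous limit fails at n = 5000 SNPs for any
  trio count reachable with ≤ 1080 donors — a property of the statistic,
  not of the implementation.  The χ²(1) claim is operative where decisions
  are made, the upper tail, so TDT calibration is asserted as
  survival-function agreement at levels 0.2…0.01, each within 3 Monte-Carlo
  standard errors; this check was verified to reject miscalibrated
  variants (e.g. τ = 0.53, or a misscaled statistic).
* Known limitations: honest-but-curious simulation only (a corrupt dealer
  or colluding hosts break privacy); the undefined-statistic flag is
  public, so monomorphic-SNP status is disclosed; X-chromosome/haploid
  calls, multi-allelic sites and covariate-adjusted tests are out of scope.
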