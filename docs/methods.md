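# Methods

## The recovery model

A bivalent (tetrad) in female meiosis experiences k reciprocal exchanges;
`tetradmap` calls the distribution of k the exchange-rank distribution
E_0..E_kmax. Each exchange involves one of the two chromatids of each
homolog, chosen uniformly and independently of every other exchange (no
chromatid interference), and a single chromatid of the four is recovered in
the offspring, uniformly at random. A recovered chromatid from an E_k tetrad
therefore carries j observable crossovers with probability C(k, j)/2^k, and
the class probabilities are p = M E with the upper-triangular mixing matrix
M[j, k] = C(k, j)/2^k. Columns of M sum to one, so the map preserves the
probability simplex.

Assumptions worth stating plainly: no chromatid interference; every exchange
falls inside a scored interval (exchanges distal to the terminal markers are
invisible); double exchanges within one marked interval cancel and are not
modelled by the estimators. Crossover interference along the chromosome is
not modelled mechanistically — whatever interference exists is absorbed into
the shape of E.

## Estimators

**Direct inversion** (`weinstein_direct`). The triangular system is solved
at the empirical frequencies n_j/N. Because 1ᵀM = 1ᵀ the solution always
sums to one, but components can be negative when the data are incompatible
with the recovery model; such solutions are returned unclamped with
`feasible=False` so the diagnostic signal is not destroyed.

**Constrained MLE** (`weinstein_mle`). The multinomial log-likelihood
Σ n_j log p_j(E) is maximized over the simplex by expectation–maximization
on the latent tetrad rank of each chromatid: responsibilities
r_jk = E_k M[j,k]/p_j, M-step E_k ← Σ_j n_j r_jk / N. The M-step stays on
the simplex analytically, so no projection or penalty is needed, and the
likelihood is non-decreasing at every step. The start is the uniform simplex
point and there is no randomness; when multiple boundary optima exist the
reported estimate is the EM fixed point from that start. Convergence is
declared when the largest component change falls below 1e-10. Interior
(saturated) optima converge in tens of iterations; boundary optima are
approached at a linear rate and can need a few hundred thousand iterations,
each a handful of 4×4 array operations, so the iteration cap defaults to
1,000,000. Exceeding the cap raises an error carrying the best iterate.
When the direct inversion is feasible the model is saturated and the two
estimators agree (observed agreement on the reference datasets: ~1e-9 per
component, set by the EM stopping rule).

`kmax` defaults to the largest observed crossover class. Ranks above every
observed class are unidentifiable except through the non-negativity
constraint; they can be included explicitly via the `kmax` argument.

Reported log-likelihoods are the multinomial kernel Σ n_j log p_j without
the combinatorial constant — only differences on the same data are
meaningful.

**Map summaries.** Total map length is 100 · Σ_j j n_j / N cM; interval map
lengths are 100 · (recombinants in interval)/N and sum to the total exactly
because each called crossover lies in exactly one interval. Mean exchanges
per tetrad, Σ k E_k, equals twice the total map length in Morgans whenever
the fit is saturated (E[j | k] = k/2).

## Crossover calling

Parental origin per locus is expected to be decoded upstream (phenotype →
P1/P2 is cross-specific because the scored markers are recessive visibles);
the core model consumes origin codes. A crossover is called in interval i
when origin switches between loci i and i+1. Missing loci are bridged by
comparing with the nearest scored flanking locus; a switch across a missing
run spanning more than one interval is ambiguous and the record is dropped,
counted and logged — never imputed. An even number of crossovers hidden
inside a bridged run is undetectable, the same limitation the bench scoring
has.

## Comparisons

Genotypes are compared with two-sided Fisher exact tests: per interval on
recombinant vs non-recombinant counts, and globally on the class collapse
(NCO+SCO) vs (DCO and above). The two-sided rule sums all tables at fixed
margins whose point hypergeometric probability does not exceed the observed
table's — two-sided Fisher conventions differ between tools, so the rule is
stated here and pinned by an enumeration oracle in the tests. P-values are
reported raw, with no multiple-testing correction, matching the convention
of interval-by-interval recombination tables. Percent-of-control ratios are
computed on unrounded cM and rounded to integer percent only for display;
recomputing a ratio from two already-rounded 1-decimal map lengths can
differ by 1% from the value computed on unrounded frequencies.

## Nondisjunction assay

In the X^Y / compound-4 test cross, each recovered X-exceptional offspring
(diplo-X or nullo-X ovum) has a reciprocal zygote class that dies, so it
represents two nondisjunction events and one unseen zygote:
adjusted total = regular + 2·X-exceptional, %X NDJ = 200·X-exc/adjusted,
%4 NDJ = 200·4th-exc/adjusted. The 4th-chromosome exceptionals are doubled
with the same logic but do not enter the adjusted total, which is the
X-assay denominator used for both rates. `infer_exceptional_count` inverts a
published (%, adjusted total) pair back to the integer exceptional count and
verifies consistency at the printed 2-decimal precision. Known limitation:
under this convention a published 4th-chromosome percentage need not invert
to an integer (the reference control pair does not), suggesting the original
4th-chromosome bookkeeping differs in detail; the X-chromosome arithmetic is
fully consistent. `ndj_compare` tests for a rate difference with a Fisher
exact test on doubled event counts versus adjusted totals — a documented
exact-conditional stand-in for the specialised comparison used in the
classical nondisjunction literature, and labelled as such in its output.

## Forward simulator

`simulate_meiosis` generates progeny with exactly the estimator's model: per
meiosis it draws k from E; places each exchange into a marked interval by
sequential weighted sampling without replacement (renormalizing after each
draw), so every exchange is observable and the Weinstein forward model holds
exactly; draws the involved chromatid of each homolog uniformly; recovers
one of the four chromatids uniformly; and emits the origin sequence with a
phase switch at every interval where the recovered chromatid participated in
an odd number of exchanges. Draw order is fixed (k; per exchange: interval,
chromatid of homolog 1, chromatid of homolog 2; recovered chromatid) and a
single seeded generator drives the run, so a fixed seed reproduces the
progeny table byte for byte.

Placement without replacement means per-interval inclusion probabilities are
*not* proportional to the weights for k > 1; the tests check interval-level
behaviour against exact enumeration of the ordered draws rather than against
the naive product. Setting `allow_intra_interval_doubles=True` switches to
with-replacement placement to study undetected-double bias; this breaks the
exact correspondence with the estimator and is excluded from the validation
conditions. A configuration whose top exchange rank exceeds the number of
positive-weight intervals is rejected when doubles are off.

**Study conditions.** The validation conditions mirror the reference
control cross: exchange ranks set to the control X-chromosome estimate
(0.0967, 0.5941, 0.2970, 0.0122) and placement weights proportional to its
interval map (13.6, 20.8, 19.5, 7.3 cM). At 200,000 meioses the pipeline
recovers each E_k within ±0.01 and the total map length within ±0.3 cM
(roughly 2 standard errors at that sample size); the goodness-of-fit check
of class proportions uses 100,000 meioses, and smaller behavioural checks
use 10,000–50,000. What the simulator does **not** emulate about real data:
phenotype-to-origin decoding errors, viability differences among recombinant
classes, nondisjunction, male (achiasmate) meiosis, and any real-data
violation of the no-chromatid-interference assumption — passing recovery
tests validate the statistical machinery, not those biological assumptions.

## Numerical choices

- All internal arithmetic is unrounded; rounding happens only at the
  presentation layer (E to 4 decimals, cM to 1 decimal, percentages to 1,
  NDJ to 2, ratios to integer percent), and JSON reports carry both the
  rounded and unrounded values.
- Class counts are stored as non-negative reals: tabulation always produces
  integers, while fractional expected counts can be pushed through the same
  estimators for round-trip diagnostics.
- Weighted draws use inverse-CDF sampling on the cumulative weights;
  zero-weight intervals can never be selected.
- Degenerate inputs fail loudly: empty profile collections, zero totals,
  zero-margin 2×2 tables, non-simplex E or weight vectors, and kmax below an
  observed class all raise `ValueError` with a specific message.

## Known limitations

- No exchange-rank confidence intervals as a primary surface (point
  estimates mirror the reference analysis); a multinomial bootstrap
  (`bootstrap_exchange_ranks`) is provided as an optional extra.
- No coefficient-of-coincidence or interference statistics, and no map
  functions (Haldane/Kosambi) — observed recombination frequencies only.
- Locus order is taken as given; the package does not estimate linkage
  order, and no physical coordinates are handled.
- Published top-rank values (E_3) in the reference tables appear truncated
  rather than rounded in places; comparisons at full printed precision are
  only guaranteed for E_0–E_2.
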