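# tetradmap

Crossover-patterning analysis for multiply-marked *Drosophila* crosses.

In *Drosophila melanogaster* females, only one of the four chromatids of a
bivalent is recovered in each offspring, so the distribution of **tetrad
exchange ranks** — the fraction E_k of bivalents experiencing exactly k
exchanges — cannot be read directly from progeny. It must be inferred from
the observed crossover classes of recovered chromatids (NCO, SCO, DCO, TCO:
chromatids with 0, 1, 2, 3 observable crossovers). `tetradmap` implements
this classical **Weinstein tetrad analysis** together with everything around
it that a recombination-mapping study needs:

- crossover calling from per-progeny marker phenotype tables (phase switches
  between adjacent scored loci), with explicit handling of missing and
  ambiguous records;
- interval genetic maps (cM = 100 × recombinants / N) and chromosome totals;
- exchange-rank estimation two ways: the closed-form Weinstein inversion and
  a constrained multinomial maximum-likelihood estimate computed by EM on the
  simplex;
- genotype comparisons by two-sided Fisher exact tests (per interval and on
  the NCO+SCO vs DCO+TCO class collapse) and percent-of-control ratios, the
  standard readout for changes in the centromere effect;
- viability-adjusted X and 4th chromosome nondisjunction rates for the
  classical X^Y / compound-chromosome test cross;
- a forward meiosis simulator that generates progeny tables with exactly the
  statistical structure the estimator assumes, for end-to-end validation.

## The model

Under no chromatid interference, each exchange in a tetrad involves one
randomly chosen chromatid per homolog, so a chromatid sampled uniformly from
an E_k tetrad carries j crossovers with probability C(k, j) / 2^k. The
observable class probabilities are therefore

    p_j = Σ_{k ≥ j} E_k · C(k, j) / 2^k,

an upper-triangular linear system. `weinstein_direct` inverts it at the
empirical frequencies n_j / N (possibly yielding negative E_k, reported
unclamped and flagged infeasible); `weinstein_mle` maximizes the multinomial
likelihood subject to E_k ≥ 0, Σ E_k = 1, and agrees with the inversion
whenever the inversion is feasible. A useful identity: mean exchanges per
tetrad Σ k·E_k equals twice the total map length in Morgans.

## Worked example

Exchange ranks of a published control genotype, from its crossover class
counts (NCO 1233, SCO 1182, DCO 207, TCO 4; N = 2626), stored as a TSV with
`class_index` and `count` columns:

```
$ tetradmap tetrad --counts x_control.tsv
E = (0.0967, 0.5941, 0.2970, 0.0122)
total map length = 61.2 cM
mean exchanges per tetrad = 1.2247
```

Read: about 9.7% of X bivalents had no exchange, 59.4% one, 29.7% two and
1.2% three; the recovered chromatids carry half the exchanges, giving a
61.2 cM map. The same estimates are available in the library as

```python
from tetradmap import ClassCounts, weinstein_mle, total_map_length
counts = ClassCounts.of(1233, 1182, 207, 4)
ranks = weinstein_mle(counts)        # ranks.E ≈ (0.0967, 0.5941, 0.2970, 0.0122)
total_map_length(counts)             # 61.23 cM
```

A nondisjunction assay with 1866 regular and 6 X-exceptional offspring (each
recovered exceptional implies one inviable reciprocal zygote, hence the
adjusted total):

```
$ tetradmap ndj --regular 1866 --x-exceptional 6
% X NDJ = 0.64
% 4 NDJ = 0.00
adjusted total = 1878
```

Other subcommands: `classify` (class counts from a progeny table), `map`
(interval map), `compare` (two genotypes: ratios + Fisher tests), `simulate`
(forward meiosis from a YAML config), `report` (full pipeline to JSON),
`ndj-compare`. See `tetradmap --help`.

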