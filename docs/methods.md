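# Methods

## Model

The genome is a circular haploid chromosome of `L = zc + znc` base pairs
carrying `g` identical genes of `zc/g` bases, each starting with a one-base
promoter and followed by an intergenic tract of `znc/g` bases. Fitness is
binary: a mutation is either perfectly neutral or lethal. Deleting any
coding base, duplicating any promoter, or inserting/breaking inside a gene
is lethal; everything else is neutral. The equal-spacing idealization is
re-imposed after every size change (neutral inversions reshuffle the
genome), so three numbers (`g`, `zc`, `znc`) fully describe a genome, and
only `znc` evolves.

Six mutation types initiate per base (or per junction) at rate
`lambda_t * mu` per generation: duplications, deletions and inversions with
breakpoints uniform over the genome (structural — their size scales with
`L`), small insertions/deletions with size uniform on `1..lm`, and point
mutations. The event measure is: a deletion is an ordered pair (start,
size) with start uniform over the `L` bases and size uniform over `1..L`
(`L^2` equiprobable events); a duplication adds an independent uniform
insertion junction (`L^3` events); junctions are the `L` inter-base
positions, and a junction is "inside a gene" iff both flanking bases belong
to the same gene, so exactly `zc - g` junctions are lethal and `znc + g`
neutral. This is the unique convention under which the closed forms equal
the exact event counts and the expected raw size change of one
duplication-plus-deletion event pair is zero.

Two conventions are reconstructions rather than givens and are flagged as
such: (i) inversion neutrality depends only on its two breakpoint junctions
(genes inside a neutrally inverted segment are re-orientable without
effect); (ii) indel deletion counts are truncated at zero when `lm` exceeds
the intergenic tract length.

## Effective fitness, fixation, flux

The effective fitness is the probability that a replication produces a
viable offspring, with mutation types and positions independent:
`log fe = sum_t sum_i log[(1 - lambda_t mu) + lambda_t mu nu_{t,i}]`.
Positions group into at most `period = L/g` classes per type, so evaluation
is O(period + znc/g), not O(L). Point mutations and small insertions
contribute `znc`-independent factors, so they alter `fe` but cancel from
every fitness ratio — they never move the equilibrium directly.

A mutant adding `k` noncoding bases fixes with the haploid Wright-Fisher
closed form `Pfix = (1 - r^2)/(1 - r^(2N))`, `r = fe(znc)/fe(znc+k)`,
implemented exactly as printed (the exponent-2 convention matches the
standard haploid Wright-Fisher result for a mutant sampled with linear
weight `1/r`; the forward simulator uses that linear weight and reproduces
the formula within Monte-Carlo error).

Under the origination-fixation approximation each type's expected fixed
flux is the size- and fixation-weighted neutral count (see the flux module
docstring for the four sums). The bias `B` is the rate-weighted ratio of
deletion to insertion flux; the common `mu L N` origination factors cancel.
The model variants are: `structural_only` (duplications + deletions),
`expanded` (all six types; inversions and point mutations enter through
`fe` only, since they do not change size — the flux composition of the
expanded bias is a design choice consistent with weighting each flux by its
origination rate), and `indel_only`.

## Numerics

* **Cancellation-free log ratios.** `log r` is a difference of two
  large, nearly equal sums; computing them separately in double precision
  would lose the `~2 k mu` signal entirely at realistic rates. The `exact`
  engine pairs the per-position-class log terms of the two genomes and sums
  `log1p` of analytically factored term ratios (every difference carries an
  explicit factor `k`); sums use compensated (`fsum`) accumulation. The
  `series` engine expands `log fe` to third order in `lambda*mu` with
  closed-form (Faulhaber) coefficients, the first-order difference in
  factored form, and adaptive truncation once the next order falls below
  1e-10 relative; it vectorizes over `k` and is exact to
  O((lambda*mu)^3) relative. Both agree with a 50-significant-digit
  `decimal` reference (the same extended-precision approach as the original
  numerical treatment of this model) to better than 1e-12 relative on the
  test grid.
* **Stable fixation evaluation.** `Pfix` is computed as
  `expm1(2 log r)/expm1(2N log r)` with the neutral limit `1/N` at
  `log r = 0` and an overflow branch for `2N log r > 700`; no silent
  infinities.
* **Real-valued sizes.** The solver varies `znc` continuously, so per-tract
  sums `sum_{r=1..n} f(r)` with real `n` are defined as the full sum to
  `floor(n)` plus a fractional last term — the continuation that matches
  the closed-form polynomials at integers and keeps `B` continuous in
  `znc`. Flux sums run to their architectural limits with no truncation;
  beyond desk scale they are evaluated in fixed-size blocks to bound
  memory.
* **Bisection.** `B` is monotone nondecreasing in `znc` over the bracket
  (checked numerically on a 5-point grid before iterating); the root of
  `B = 1` is found by bisection on `log10(znc)` to a relative tolerance of
  1e-6 on `znc` (default bracket `[1e3, 1e9]`, geometric expansion up to
  `[1, 1e11]` on request). Absence of a sign change — the indel-only model,
  or insertion-biased rates in the neutral limit — is reported as a
  non-converged result, never as a root.
* **Asymptotic fixation form.** The small-`mu` limit
  `(1 - exp(4 k mu))/(1 - exp(4 N k mu))` is exposed for the
  compound-parameter analysis; its displayed numerator is taken in the
  internally sign-consistent `1 - exp(4 k mu)` form. It drops the
  neutrality corrections to `log fe` (relative size ~`1/(2g)`), which the
  `2N` exponent amplifies by `4 N |k| mu`; it therefore tracks the exact
  form to ~1e-3 relative only while that amplification is small (|k| up to
  ~1e2 at the default parameters) and degrades in the deep-suppression
  tail where `Pfix` is astronomically small. Tests assert it in its valid
  regime; it is never used inside the exact pipeline.

## Parameters and defaults

| parameter | meaning | default | rationale |
|---|---|---|---|
| `g` | number of genes | 2000 | standard exploration value |
| `zc` | coding size (bp) | 1e6 | 500 bp genes, a conserved gene length |
| `mu` | per-base per-type rate | 1e-10 | realistic structural-rate scale |
| `N` | population size | 1e8 | prokaryote-like effective size |
| `lm` | max indel size (bp) | 50 | boundary between indels and SVs |
| `kappa` | deletion bias | 1 (unbiased) | `lambda_del = lambda_ind- = 2k/(1+k)`, `lambda_dupl = lambda_ind+ = 2/(1+k)`; the four sum to 4 |
| `lambda_pm`, `lambda_inv` | point/inversion multipliers | 1 in kappa mode | robustness contributors only |
| solver tolerance | relative on `znc` | 1e-6 | bias residual reported alongside |

The equilibrium-curve grids realise each `N x mu` as `mu = 1e-9` with
`N = N_mu / mu_ref`, matching one of the two sweeps used to explore the
six-type model (the compound-parameter tests confirm the pairing is
immaterial at these rates).

## Oracles and what passing tests show

* **Enumeration** iterates every event coordinate on small enumerable
  genomes and reports exact rational fractions; the closed forms equal
  these counts *exactly* on an 11-architecture matrix and on
  randomly drawn architectures (property tests). An even more literal
  brute force (plain loops through the event classifier) backs the
  run-length enumeration itself.
* **Monte-Carlo breakpoint sampling** extends the check to `L = 2e6`
  genomes (agreement within 4 binomial standard errors at 2e6 draws).
* **Wright-Fisher simulation** validates the fixation closed form at
  `N = 50` within 3 standard errors over 1e5 replicate introductions, and
  a tiny forward simulator with explicit mutation draws shows mean
  noncoding size drifting toward the analytic root from both sides
  (qualitative only).

The synthetic species-table generator emulates only the *structure* of an
empirical comparison: log-uniform `(Ne, mu)` draws with observed fractions
equal to the model's own prediction plus logit-scale noise. It contains no
real annotation data, no phylogenetic correlation, no functional noncoding
DNA and no per-species coding architectures, so tests passing on it show
the overlay pipeline works — not that the model fits real genomes.

## Problem sizes

Desk-scale throughout: enumeration is guarded at `L <= 1e4` (`L <= 200`
for the cubic duplication space), the fixation simulator at `N <= 1e3` and
1e6 replicates, the trajectory simulator at `N <= 200`. Equilibrium solves
at the default parameters take ~25 bias evaluations (about a second);
curve grids over 4 compound values x 3 biases run in ~15 s.

## Known limitations

* No transposable elements, horizontal transfer, recombination, functional
  noncoding DNA, diploidy or clonal interference; fitness is binary.
* Mutation-type independence ignores mechanical interference between
  overlapping rearrangements (negligible when neutral rates per genome are
  << 1).
* Gene duplications are always lethal; relaxing this would strengthen the
  growth bias without removing robustness selection.
* The `kappa <= 1` divergence means equilibria at very small `N x mu` sit
  beyond any finite bracket; the solver reports these honestly as
  no-sign-change results once expansion is exhausted.
* Mutation rates are fixed parameters; their own evolution (drift-barrier
  dynamics) is out of scope.
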