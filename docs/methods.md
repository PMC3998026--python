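# Methods

## Model

A codon substitution matrix is read as a discrete memoryless channel: the
input symbol is the ancestral sense codon x, the output the derived codon
y, and the matrix entry p(y|x) the transition probability. Stop codons are
excluded — empirical codon matrices are block-diagonal with a 61×61 sense
block and a 3×3 stop block, and substitutions between the blocks are not
modeled — so all channel computations run on the 61 sense codons. When a
64×64 matrix is supplied, `restrict_to_sense` removes the stop rows/columns
and renormalizes each surviving row; any sense→stop leakage above 10⁻³ is
reported with a warning because it indicates the file was not actually
block-diagonal.

Three quantities drive the analysis, all in bits:

* **Required rate.** From a substitution count matrix C, the input codon
  distribution is the row marginal pₓ(i) = Σⱼ C_ij / Σ_ij C_ij. Summing
  synonymous codons gives the amino-acid distribution pₐ, and
  R₂₀ = H(pₐ) is the information per codon position that must survive
  transmission. Merging symbols cannot increase entropy, so R₂₀ ≤ H(pₓ),
  and R₂₀ ≤ log₂ 20 ≈ 4.3219.
* **Mutual information and capacity.** I(X;Y) = H(Y) − H(Y|X) for a fixed
  input; C = sup_pₓ I(X;Y) via Arimoto–Blahut (below).
* **Divergence-time scaling.** P^(F) = U Σᶠ V* from the singular value
  decomposition P = U Σ V*, with F ∈ [0, 1]. F = 1 is the matrix as
  estimated; smaller F emulates a cleaner channel.

The headline pipeline sweeps F, records the optimized capacity and the
biological-input mutual information at each grid point, and reports
F\* — the maximal exponent whose *biological-input* MI still meets R₂₀.
F\* is deliberately defined against the biological input rather than the
optimized capacity: organisms do not get to choose a codon distribution to
match the channel, so the relevant question is whether the distribution
nature uses clears the rate. The optimized capacity at F\* is reported
alongside.

## Stop-codon handling

Observed codon frequency tables can carry tiny stop-codon mass (the
packaged biological table has 0.0007 in total, from counts of alignment
artifacts). R₂₀ is a sum over exactly 20 amino acids, so stop mass is
dropped and the vector renormalized before aggregation rather than being
silently kept or silently discarded without renormalization.

## Arimoto–Blahut

Starting from a strictly positive input distribution p (uniform by
default; a seeded Dirichlet start is available and converges to the same
value), each iteration computes, with q = pᵀP the output distribution,

    ln c(x_j) = Σ_k p(y_k|x_j) ln[ p(y_k|x_j) / q(y_k) ]
    p(x_j)   ← p(x_j) c(x_j) / Σ_j p(x_j) c(x_j)

and the capacity is sandwiched by ln Σⱼ p c ≤ C ≤ ln maxⱼ c. Numerical
choices:

* Everything is computed in natural-log domain (log-sum-exp for the lower
  bound); reported values are converted to bits. Default tolerance on the
  bound gap is 10⁻⁹ bit with a 10⁵ iteration cap — a 61-codon channel of
  the kind studied here converges in tens of iterations.
* 0·log 0 terms are dropped; an output column with zero total probability
  under a strictly positive input can only arise from an all-zero channel
  column and contributes nothing.
* Iterates are floored at 10⁻³⁰⁰ so inputs that the optimum excludes
  cannot underflow to exactly zero and break the update.
* Convergence is slow for channels whose optimal input excludes many
  symbols (the upper bound maxⱼ c decays slowly over inactive symbols);
  this is a property of the algorithm, not a defect of a particular
  matrix. The tight default tolerance keeps scan results stable to four
  decimals.

## SVD fractional power and repair

U Σᶠ V* is not a matrix function in the eigendecomposition sense unless P
is symmetric positive definite (where the two coincide — this is the test
oracle). For a general stochastic matrix the result can have small
negative entries and row sums off 1, and the construction is therefore a
*definition*, not an approximation of P raised to a Markov power. Because
Arimoto–Blahut needs a valid conditional-probability matrix, the raw
result is repaired: negative entries clipped to zero, rows renormalized.
The clipped mass and renormalization factor of every row are returned in a
`RepairReport`, so the severity of the repair at each exponent is
measurable rather than hidden (on ECM-like matrices it is at the 10⁻²
level per row at mid-range F). Sign flips of paired singular vectors leave
the product invariant for distinct singular values; near-degenerate
singular values (gap < 10⁻¹²) are flagged since the result can then depend
on the linear-algebra backend. F = 0 yields the orthogonal polar factor
UV*, not the identity, so scan grids start strictly above zero.

## Exponent search

The scan grid runs from 0.01 to 1.00 in steps of 0.01 (fine enough to
resolve the capacity curve; the step is configurable). F\* is located by
taking the largest grid point whose biological-input MI meets R, then
bisecting against the next grid point to a width of 10⁻⁴. MI is expected
to decrease in F; the coarse grid verifies this and warns if violated
(repair artifacts could in principle produce local non-monotonicity, in
which case the bracketing answer is still returned).

## Synthetic data

The generators exist so that every stage has a ground-truth oracle:

* **Symmetric channel** (uniform off-diagonal error noise/(K−1)):
  capacity log₂ K − H(row), optimal input uniform.
* **Weakly symmetric channel** (circulant rows from a random simplex
  vector, equal column sums): same closed form.
* **Z-channel**: no closed form used; the oracle is scalar maximization of
  I over the one-parameter input family.
* **Reversible codon channel**: a seeded symmetric exchangeability matrix
  S = (A + Aᵀ)/2, A_ij ~ 1 + roughness·U(−1,1), defines an exchange kernel
  p(y|x) ∝ S_xy·π_y, which is row-normalized and mixed with the identity,
  P = w·I + (1−w)·M, default self-weight w = 0.85. The mix mimics the
  strong diagonal dominance of empirical codon matrices, where most codons
  are conserved over the estimation period; the kernel satisfies detailed
  balance with respect to a distribution proportional to π_x·Z_x (Z_x the
  row normalizer), and mixing with the identity preserves reversibility.
  This surrogate is **not** the published empirical codon mutation matrix;
  it only shares its structural character (reversibility, strictly
  positive entries, codon-frequency-shaped equilibrium, dominant
  diagonal).
* **Count sampling**: n substitution events drawn multinomially from the
  joint pₓ(i)·p(y_j|x_i); at n = 10⁶ the row-marginal estimator recovers
  pₓ to within a few multinomial standard errors per codon.

All generators are driven by a single integer seed through NumPy's
`default_rng`, so identical seeds give byte-identical outputs.

What passing these tests does **not** show: the surrogate cannot validate
conclusions that depend on the specific noise geometry of a real empirical
matrix (e.g. the numerical value of F\* for vertebrates, which requires the
externally distributed matrix placed at `data/ecm61.tsv`; the corresponding
test activates automatically when the file is present).

## Fixtures and printed precision

The two packaged codon-frequency tables are shipped verbatim at their
4-decimal printed precision and renormalized on load (their raw sums are
1.0004 and 0.9998). All fixture-derived quantities therefore carry
rounding noise of order 10⁻³ and the checks on them use tolerances of
±0.01 bit (entropy) and ±0.005 bit (KL). The KL divergence between the
capacity-achieving distribution Q and the biological distribution P is
direction-dependent: D_KL(Q‖P) = 0.0927 bit and D_KL(P‖Q) = 0.0801 bit.
Both are always reported; the comparison report exposes them as
`kl_q_vs_p` and `kl_p_vs_q`.

## File conventions

Matrices are labeled CSV/TSV (header row + label column), rows = ancestral
codon, columns = derived codon; headerless whitespace matrices are
accepted with an explicit order declaration (`table`: first base T,C,A,G
outermost, as in printed codon tables; or strict `alphabetical`). Channel
rows are validated to sum to 1 within 10⁻⁶ (renormalized within that
tolerance, rejected beyond it — large deviations mean a wrong or
transposed file, which silent repair would mask). DNA is canonical; RNA
input (U) is normalized to T on read.

## Known limitations

* Single standard genetic code; no mitochondrial or other variant tables.
* No input-constrained or continuous capacity variants; plain
  Arimoto–Blahut only, no accelerated schemes.
* The fractional power is the SVD construction described above; matrix
  logarithms / rate-matrix estimation are out of scope.
* Amino-acid-level (20×20) matrices and PAML triangular formats are not
  read.
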