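# Methods

## Statistical model

Let X be an alignment of N rows and L columns over the 20 standard amino
acids and a gap symbol.  The package treats each column as a categorical
variable and estimates the 20L × 20L covariance of indicator variables

    C[(i,a),(j,b)] = f2_ij(a,b) − f1_i(a) · f1_j(b),

where f1 and f2 are weighted relative frequencies.  Rows gapped at a
column are excluded from that column's counts, and rows gapped at either
member of a pair from the pair's counts; there is no 21st gap state.
Diagonal blocks take the multinomial form diag(f1) − f1 f1ᵀ.

Redundancy weighting follows the PSICOV convention: the weight of a row
is the reciprocal of the number of rows (itself included) within identity
θ of it, with identity defined over mutually non-gap columns.  The sum of
weights is the effective depth n_eff.  Frequencies are regularised by a
uniform pseudocount of total mass λ, mixed as
f ← (1−λ′)·f_obs + λ′·(1/20 or 1/400) with λ′ = λ/(λ+n_eff).

The precision matrix Θ is the graphical-lasso estimate with penalty ρ;
the coupling score of a column pair is the L1 norm of its 20 × 20 block,
PS_ij = Σ_ab |Θ_ij^ab|.  Average product correction subtracts
(row mean · column mean)/overall mean from every entry (means over
off-diagonal entries), and z-scores are computed over all pairs with
|i−j| ≥ min_separation.  Couplings with z above the σ cut-off are
reported, with the fraction of pairs above 2.5σ and 3σ always included so
the tail mass can be compared across alignments.

The randomisation control permutes residues independently within each
column.  Column compositions — and hence single-column statistics — are
exactly preserved while all inter-column covariance is destroyed, so the
rescored matrix gives the null distribution.  (Permuting entries of the
score matrix itself would leave its histogram unchanged, which is why the
null is built at the alignment level.)

## Parameter defaults

| parameter | default | meaning / rationale |
|---|---|---|
| θ (weighting identity) | 0.62 | standard redundancy threshold for coevolution analyses |
| λ (pseudocount mass) | 1.0 | weak uniform smoothing; keeps zero-count cells finite |
| ρ (lasso penalty) | 0.005 | sparse but sensitive; planted-pair benchmarks are flat in 0.001–0.01 |
| shrink | 0.1 | covariance shrinkage toward its diagonal (see below) |
| σ cut | 3.0 | stringent threshold; 2.5 selectable for permissive runs |
| min_separation | 5 | excludes trivial near-diagonal couplings |
| contact cutoff | 10 Å, strict < | Cα–Cα contact definition used for fold/interface classes |
| restraint upper bound | 10 Å | Cα–Cα upper bound written into exported restraints |
| score_min (interface candidates) | 0.2 | min–max-normalised score floor for restraint candidates |
| exposure_max_neighbors | 14 | Cα coordination number ceiling for "surface-exposed" |
| γ (specific volume) | 1.28 Å³/Da | calibrated so a 100 kDa 26-mer gives 3.33 × 10⁶ Å³; the common literature value 1.21 is selectable |
| clash cutoff (rings) | 3.0 Å | Cα pairs of non-adjacent subunits closer than this count as clashes |

The depth rule N/L > 0.3 (strict) gates reliable signal; N is the raw row
count, with n_eff reported alongside, since the published rule is stated
in raw counts.  σ thresholds are applied to APC-corrected scores; raw,
APC, z and a min–max-normalised score are all emitted because published
"normalised" scores are not uniquely defined.

## Numerical choices

* **Shrinkage.**  With gap-excluded pair counts the empirical covariance
  is indefinite (each block is normalised by a different effective row
  set).  Before estimation the covariance is shrunk toward its diagonal,
  C ← (1−s)·C + s·diag(C) with s = 0.1, which restores positive
  definiteness on realistic alignments and conditions the solver.
* **Ridge.**  At ρ = 0 the estimator must reduce to plain inversion, so
  the input is only repaired (by escalating ridges of 10⁻⁴·mean diag)
  when a Cholesky factorisation fails.  For ρ > 0 a ridge of
  10⁻³·mean diag is always added — far below the penalty scale — and
  escalated tenfold if the coordinate-descent solver still reports a
  non-SPD system.
* **Convergence.**  tol = 10⁻², max_iter = 30 by default.  Coupling
  *ranks* stabilise long before the duality gap closes, so hitting
  max_iter is logged as a warning rather than raised;
  `raise_on_nonconvergence=True` upgrades it to an error carrying
  iteration diagnostics.  A non-finite result always raises.
* **z-scores.**  Population standard deviation (ddof 0) over eligible
  pairs; at least 10 eligible pairs are required by default
  (configurable); a zero spread is an error ("degenerate score
  distribution").
* **Validation sem.**  sd/√n with sample sd (ddof 1); a single distance
  reports sem 0 with n = 1 visible in the report.
* **Mapping.**  The ungapped reference row is globally aligned to the
  chain sequence (match +1, mismatch 0, gap −1).  Mapping fails when
  under 30% of columns map or under 30% of aligned positions are
  identical — the latter catches unrelated sequences, which a
  mismatch-score of 0 would otherwise align happily.
* **Homo-oligomer convention.**  Couplings are projected onto partner
  chains by author residue number; d_intra is minimised over chains,
  d_inter over the two ordered cross-chain pairings per partner.
* **Ring clash adjacency.**  For n ≥ 4, pairs from ring-adjacent
  subunits are excluded from the clash count (their interfaces
  legitimately approach).  For n ∈ {2, 3} every distinct-subunit pair is
  checked — in a C2 "ring" the only pair is adjacent, and a superposed
  dimer must still register as a clash.
* **Axis point.**  The point on the rotation axis is the minimum-norm
  least-squares solution of (I − R)x = t.

## Synthetic data

`simulate_msa` emulates: per-column Dirichlet(0.5) amino-acid profiles;
phylogenetic redundancy via M founder sequences copied with per-site
resampling probability `founder_divergence`; i.i.d. gaps at `gap_rate`
(the reference row is kept gap-free so column numbering is the
identity); and K planted column pairs drawn jointly, with probability
p_c, from k fixed chemically compatible combinations sampled equally
from ionic, polar and hydrophobic pairings.  Planted columns are drawn
i.i.d. per sequence rather than inherited from founders, so the planted
signal strength depends only on p_c.  The generator is a
compatibility-set mixture, not a Potts sampler: it produces exact,
controllable signal but no indirect (chained) couplings, no
covariation–conservation coupling, and no realistic phylogenetic tree.
Passing benchmarks therefore demonstrate correct estimation under the
model's own assumptions, not performance on real families, where
phylogenetic structure and indirect couplings are harsher.

`simulate_ring_structure` grows one compact self-avoiding Cα chain
(3.8 Å steps, 3.0 Å exclusion) and replicates it n times about z.  When
no radius is given, the smallest radius is chosen at which adjacent
copies are clash-free (> 3.2 Å) and non-adjacent copies lie beyond the
contact cutoff (+0.5 Å margin); adjacent surfaces then sit within
contact range.  Ground-truth interface pairs are computed from direct
pairwise distances between adjacent copies, independently of the
contact-map code they are later compared against.  The toys have no side
chains and no realistic packing; they validate geometry bookkeeping, not
energetics.

## Problem sizes

The test suite exercises the full scoring chain at L = 50, N = 2000 with
5 planted pairs over 20 seeds (both for recovery and for the shuffle
null), and smaller L = 25–30 alignments for property checks; the
acceptance script uses 5 replicate seeds per stochastic quantity.  These
sizes give stable pass/fail behaviour at a few seconds per scoring run.

## Known limitations

* Inference is inverse-covariance only; pseudolikelihood/Potts and
  deep-learning predictors are out of scope.
* The minimal PDB reader/writer handles Cα-trace ATOM records, altlocs
  and insertion codes, but not mmCIF beyond what Bio.PDB provides.
* Exposure uses a coordination-number proxy, not SASA; "opposing sides
  of the monomer" is approximated as "not a fold contact and exposed"
  (a direction-cosine check is configurable but off by default).
* `estimate_stoichiometry` reports the real-valued estimate and its
  rounding; with γ = 1.28 and 78% coverage a 3.81 × 10⁶ Å³ volume gives
  38.2, and no attempt is made to reproduce published corrections that
  are not fully specified.
* Docking itself (and scoring of docked poses) is external; the package
  stops at restraint export.
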