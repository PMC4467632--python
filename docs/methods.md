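# Methods

## The model

The data are a heterogeneous undirected network with two node kinds:
proteins, joined by protein–protein interaction (PPI) edges of weight 1, and
diseases, each attached to the proteins encoded by its associated genes via
attachment edges of weight β (> 0, default 1; the neutral choice that makes
an attachment count as much as an interaction). Genes associated with a
disease but absent from the PPI graph are kept as isolated protein nodes, so
two diseases sharing such a gene still obtain a nonzero similarity — pure
gene sharing is a special case of the network similarity rather than being
lost.

A walker starts at a disease node, steps to one of the disease's proteins
uniformly at random (forced by equal attachment weights), and then walks the
protein subgraph: at protein *i* with total incident weight
*s<sub>i</sub>* (PPI degree plus β per attached disease) it moves to
neighbor *j* with probability *w<sub>ij</sub>*/*s<sub>i</sub>* and is
absorbed with probability β·*n*<sub>att</sub>(*i*)/*s<sub>i</sub>*. **Every**
disease node is absorbing, not just the start disease. This choice is
deliberate: if only the start disease absorbed, the expected visit counts on
an undirected graph would be proportional to the stationary distribution for
every start, making all profiles parallel and all similarities equal to 1.
Treating disease nodes as the places where walks both start and terminate
yields informative, start-dependent profiles.

The **weight vector** w(d) of disease *d* collects the expected number of
visits to each protein before absorption. With Q the protein-to-protein
transition matrix and s(d) the start distribution, w(d)ᵀ = s(d)ᵀ(I − Q)⁻¹,
computed by one sparse LU factorization of (I − Q)ᵀ shared across diseases.
Proteins whose PPI component contains no disease-attached protein are pruned
first; afterwards the spectral radius of Q is < 1 and the solve is
well-posed. Two invariants are enforced in tests: every row of Q plus its
absorption probability sums to 1 (1e-12), and Σᵢ wᵢ(d)·aᵢ = 1 (1e-10) —
every walk is absorbed exactly once.

A vectorized Monte-Carlo simulator implements the same walk by direct
sampling and serves purely as an independent oracle for the linear algebra;
agreement is checked entrywise within four standard errors at 10⁵ walks.

## Correlation and queries

The correlation of two diseases is the cosine of the angle between their
weight vectors. Weights are nonnegative, so the value lies in [0, 1]; it is
scale invariant, so vectors are stored unnormalized. Queries cut either at a
lowest acceptable rank — expanding the list to include every disease whose
correlation exactly ties the boundary value (tie detection is exact float
equality; the deterministic pipeline makes genuinely tied inputs bitwise
equal, and near-ties at 1e-12 are intentionally not expanded) — or at an
inclusive minimum correlation. A correlation above an advisory significance
floor (default 1e-6) is annotated as significant; the floor never filters.
On a production-scale interactome correlations are small because the space
has ~10⁴ dimensions; on the small synthetic networks used in tests they are
large. Both the floor and any correlation cutoff are therefore user
parameters, not constants of the method.

## Overlapping clustering

Clusters live in the same space as diseases: each cluster is a unit weight
vector over proteins. Fitting alternates

- E step: P[d,k] = C(ŵ(d), v_k)^γ / Σⱼ C(ŵ(d), v_j)^γ (uniform row if every
  cosine is 0), and
- M step: v_k = normalize(Σ_d P[d,k] ŵ(d)),

until the largest membership change falls below `tol` (1e-6) or `max_iter`
(500) is hit, in which case the model is returned flagged unconverged.
Initialization is greedy farthest-first on cosine distance (first center =
the max-total-weight disease; each next center maximizes its minimum cosine
distance to the chosen ones; a seeded random permutation breaks exact ties),
so the fit is deterministic given the seed. After convergence, cluster pairs
with mutual cosine > 0.999 are merged by summing memberships, the merged
vectors are rebuilt from the summed memberships, and one final E step
refreshes P. K defaults to ⌈√(#diseases)⌉; model selection is out of scope.

**Sharpness γ (default 4).** Weight vectors are entrywise nonnegative, so
every pairwise cosine is positive and typically carries a large shared
background from hub proteins (planted-module fixtures: within-module cosine
≈ 0.89 against ≈ 0.26 between modules). With γ = 1 the linear
responsibilities are so diffuse that the M step contracts every center
toward the global barycenter and the merge step collapses the fit to a
single cluster — on this data class the γ = 1 iteration is degenerate
regardless of how well separated the structure is. Raising the exponent
sharpens responsibilities (ratio^γ contrast); γ = 4 recovers planted
structure reliably while leaving memberships genuinely soft (overlap
persists for diseases straddling modules). The half-step that is a theorem —
the M step never decreases Σ P·C for fixed P — is tested; the full E/M round
is not an ascent method for that objective and no such claim is made.

## What-if edits and certified error bounds

An edit replaces one disease's gene associations (or adds a new disease);
PPI edits are out of scope. The approximate path computes the edited
disease's weight vector **exactly** in the edited network and freezes every
other disease vector and all cluster vectors at their base values. Each
reported correlation and membership carries a certified upper bound on the
error of that freeze.

Q and Q′ differ only in the rows of the proteins A whose attachment count
changed (each row rescaled by s_p/s′_p). The exact identity
w′(e) − w(e) = [w(e)ᵀ(Q′ − Q)(I − Q′)⁻¹]ᵀ gives, with
uᵀ = w(e)ᵀ(Q′ − Q) and ℓ′ = (I − Q′)⁻¹·1 (expected total visits of the
edited walk from each protein; one extra solve),

    ‖w′(e) − w(e)‖₁ ≤ Δ₁(e) = Σⱼ |uⱼ|·ℓ′ⱼ,

since (I − Q′)⁻¹ is nonnegative with row sums ℓ′. |uⱼ| is the probability
mass diverted through the edited proteins into j; each diverted unit changes
subsequent expected visits by at most a restart at j. From the normalization
lemma ‖y/‖y‖ − y′/‖y′‖‖ ≤ 2‖y − y′‖/max(‖y‖, ‖y′‖) follow the correlation
bound min(1, 2Δ₁(e)/‖w(e)‖₂), the cluster-vector drift bound (memberships
frozen; the edited disease's own drift is computed exactly since both its
vectors are in hand), and the membership bound
min(1, (e_k + P_k·ΔS)/(S − ΔS)) with e_k = min(1, γδ_k), ΔS = Σ e_k,
S = Σ C_jᵞ. δ_k additionally includes the exactly computed convergence
residual ‖v_k − normalize(Σ_d P[d,k]ŵ(d))‖ — the fitted cluster vectors sit
one M half-step away from their reconstruction, and the bound must cover
that offset.

The membership bounds certify the *frozen-responsibility re-score*: cluster
vectors rebuilt from exactly recomputed disease vectors with the base
membership matrix held fixed, then one E step. A full clustering refit is an
EM restart whose outcome (label order, local optimum, merges) is not a
continuous function of the input, so no finite bound can cover it; the full
refit exists as the exact path and is the oracle for weight vectors and
correlations. No-op edits (the supplied gene set equals the existing one)
are detected and answered exactly from the base model with all bounds 0.

The bounds are sound but deliberately conservative: on small dense test
networks, where every walk repeatedly crosses the edited proteins, they
often clamp at 1; they become informative when the edit's diversion mass is
small relative to the network (the regime of a production-scale
interactome, and of localized edits such as adding one gene to a large
module).

## Synthetic data

The generator plants `n_modules` protein modules (default 3 × 15 proteins):
a random spanning tree per module guarantees connectivity, extra
within-module edges appear at `p_within` = 0.3, and cross-module edges at
`p_between` = 0.01; each of the 4 diseases per module draws 3 genes without
replacement from its module. These defaults give dense, well-separated
modules — the regime where diffusion profiles should cluster by module — and
the module labels are returned as ground truth for recovery tests. What the
generator does **not** emulate: scale-free degree distributions, the
~10⁴-node scale of a curated interactome, study bias in PPI coverage,
multi-module (pleiotropic) diseases, or noisy/false-positive interactions.
Tests passing on these fixtures show the machinery is correct and that
module structure is recoverable under favorable conditions; they do not
calibrate performance on real interactome data.

Problem sizes throughout the default test run and the acceptance script are
chosen to exercise every code path at desk scale: networks of ≤ 60 proteins,
10⁵ Monte-Carlo walks per cross-check, 10 clustering seeds, 100 random
edits.

## Numerical choices

- Node ordering is lexicographic by ID, fixed at build time; all output is
  byte-stable given identical inputs and seeds (floats printed with %.17g
  where a bit-exact round trip matters, %.12g otherwise).
- Sparse direct LU (SuperLU) for all solves; networks of the supported scale
  never need an iterative fallback.
- Zero-correlation E-step rows fall back to uniform membership, preserving
  the row-sum invariant.
- Degenerate inputs: empty association tables, β ≤ 0, empty edit gene lists,
  out-of-range cutoffs, and unknown IDs all raise typed errors; unpruned
  networks are rejected by the transition-model builder rather than
  producing a singular solve.

## Known limitations

- The clustering is a self-defined contract (soft spherical E/M with
  sharpness): overlapping clusters represented by weight vectors with
  memberships derived from correlations. Other algorithms satisfying the
  same description exist.
- Error bounds certify the frozen re-score, not a refit; and they are upper
  bounds, not estimates — treat them as certificates, not accuracies.
- Associations are unweighted; directed or confidence-weighted interactions
  are out of scope.
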