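# Methods

This note records the models implemented by `rabn`, the conventions chosen
where more than one reasonable convention exists, and what the synthetic
data generator does and does not establish.

## Model families and their semantics

**RA structures.** A structure over a variable system is an antichain of
relations (variable subsets) covering every variable. Its semantics are
maximum entropy: given data, the fitted distribution matches the observed
margin of every relation and maximizes Shannon entropy subject to those
constraints. Independence semantics are read off the *co-occurrence
graph* (variables adjacent when they share a relation): (X ⟂ Y | S) holds
when S separates X and Y. A structure is **loopless** when its relation
hypergraph is acyclic, decided by Graham reduction (repeatedly delete
variables occurring in a single relation and relations embedded in
others; acyclic iff the reduction empties the structure). Looplessness is
equivalent to the existence of a closed-form factorized solution via a
running-intersection ordering of the relations, and the implementation
verifies this equivalence rather than assuming it: the IPF fixed point and
the closed-form product agree to 1e-10 total variation on every loopless
four-variable structure in the test suite.

For non-conformal structures (relations that are not the cliques of the
co-occurrence graph, e.g. the loop `AB:BC:CA`), graph separation
understates nothing: the no-higher-order-interaction constraint adds no
conditional independencies, so the co-occurrence reading is the correct
independence fingerprint for equivalence tests.

**Bayesian networks.** Standard: DAGs, node-given-parents factorization,
d-separation by active-trail reachability (ancestors of the conditioning
set open colliders). Markov equivalence is decided by the skeleton /
V-structure criterion and, as a property test, cross-checked against
equality of the full elementary independence sets ({(X ⟂ Y | S)} for all
pairs and all conditioning sets). Classes are summarized by CPDAGs (edge
directed only when every class member orients it identically).

**Extended notation.** BN classes print in RA notation extended with
subscripts: relations are the maximal cliques of the moral graph
(isolated variables as singletons); for each clique, pairs separable by a
conditioning set inside the clique contribute an internal substructure —
the graph on the involved variables with the separable pairs deleted,
printed between underscores (so B→D←C prints `BCD_B:C_`, and a collider
with three mutually non-adjacent parents prints `ABCD_A:B:C_`).
Independencies spanning cliques are carried by the colon structure itself.
This rule is validated against all twenty published four-variable rows
rather than asserted from first principles.

## Equivalence between the families

Two classes (RA or BN) are equivalent when their elementary independence
sets coincide — under the identity labeling at the specific level, under
some variable bijection at the general level — **and** the RA side is
loopless. The looplessness condition is substantive, not cosmetic: a
loopy structure such as `ABC:ABD:ACD:BCD` has the same (empty) separation
independencies as the saturated model, but its maximum-entropy
distribution is a strictly constrained, non-factorizable object, so it is
statistically distinct from every BN. With that condition, equivalence at
four variables pairs exactly the 61 loopless specific structures (10
general classes) with their BN counterparts, and the joint lattice counts
follow: 114 + 185 − 61 = 238 specific, 10 + 10 + 10 = 30 general,
organized under the 11 four-node Rho (adjacency) graphs.

## Minimized independence displays

Equivalence testing always uses full elementary sets; the minimized lists
are display only. The display algorithm: (1) connected components of the
skeleton yield block statements (K₁ ⟂ K₂ ∪ …); (2) within a component the
candidates are the local-Markov statements (X ⟂ nondescendants ∖ parents |
parents), and a greedy cover of all separable pairs retains as few as
possible, trimming each retained statement to the pairs it newly covers.
Ties prefer more new pairs, then candidates covering only new pairs, then
smaller conditioning sets, then deeper nodes, then alphabetical order.
For loopless RA structures the same algorithm runs on an
independence-equivalent DAG — the no-V-structure orientation of the
(chordal) co-occurrence graph whose factorization term list is
lexicographically greatest, which matches the drawing convention of the
published class representatives. Loopy structures use Markov-blanket
candidates instead. The algorithm reproduces the twenty published
specific-graph rows and the ten equivalent-pair rows; the trimming order
is a convention, and other irredundant covers would be equally valid
logically.

## Directed (prediction) lattices

With IVs {A, B, C} and DV Z:

* The **conventional directed RA lattice** consists of the IV relation
  `ABC` together with every non-empty antichain of Z-containing relations
  (19 specific structures; 9 general classes permuting IVs only).
* The **augmented lattice** adds each structure's *primed* variant (IV
  relation removed, orphaned IVs re-covered by singletons) whenever the
  variant keeps at least two Z-containing relations — with a single
  predictive relation, dropping the IV relation provably leaves the
  maximum-entropy conditional p(Z | IVs) unchanged, and the tests audit
  this retention rule numerically in both directions. The
  full-independence structure joins as the primed sub-lattice's reference.
  Result: 31 specific structures. General classes here use full unlabeled
  isomorphism (not Z-fixed), because the naive-Bayes-type additions are
  shape-identical to conventional classes and group with them; this
  reproduces the published count of 12.
* The **BN directed lattice** partitions the Z-eligible specific classes
  by their fitted conditional p(Z | A, B, C) and keeps the least-df member
  of each partition (ties by canonical edge order). Eligibility is the
  class-invariant rule `dv_free_of_v_structure`: Z may not occur in any
  subscripted (V-structure-encoded) independence statement of the class
  notation. This subsumes the simpler "Z not a V-structure parent" ban
  and additionally excludes classes such as `ABCZ_AZ:CZ_`, whose
  prediction runs through a subscripted term and therefore has no RA
  equivalent; with it the lattice has exactly 18 specific and 8 general
  members, every one of which maps onto an augmented-lattice RA structure
  with a numerically identical prediction (ties in that mapping resolve
  to the conventional, hierarchically nested structure). The excluded
  family is demonstrated, not silently dropped:
  `v_structure_parent_dv_demo` exhibits the diverging conditionals for
  A→Z←B versus A→B←Z on a synthetic joint.

Prediction equivalence is decided numerically: fitted conditionals are
compared on seeded strictly positive random tables (identical predictions
agree exactly as functions of the data; generic tables separate distinct
ones, and the partition is built by union-find over pairwise agreement at
1e-9 so that floating-point jitter cannot split a true group).

## Fitting and statistics

* **BN fit**: product of empirical p(node | parents); parent
  configurations with zero mass get a uniform conditional (they carry no
  probability in the joint, so the choice only keeps the factor proper).
* **RA fit (IPF)**: uniform initialization, cyclic margin sweeps,
  convergence when every fitted margin is within 1e-9 of its target, cap
  10,000 sweeps (RuntimeError with the residual beyond that). Zero cells
  in a target margin zero the corresponding fitted cells; no smoothing is
  applied by default.
* **Information quantities** are in bits. Transmission T(p : q) =
  Σ p log₂(p/q); the likelihood-ratio statistic of a fit against the
  saturated model is 2 n ln2 · T(data : fit). `lr_test` between two fits
  is twice their log-likelihood difference on the data, which for nested
  hierarchical fits equals the 2 n Σ p ln(p/q) form between the fitted
  distributions.
* **Degrees of freedom**: RA structures count one u-term per non-empty
  subset in the down-closure of the relations, each worth ∏(cardinality −
  1); BNs count (cardinality − 1) × ∏ parent cardinalities per node. The
  two formulas agree on every equivalent RA/BN pair, which is what makes
  least-df selection meaningful across families.
* **Search** is greedy (beam width 1 by default) along the deletion
  hierarchy, upward from the independence model or downward from the
  saturated one; BIC/AIC moves must improve the score, the chi-square
  criterion requires significant improvement going up (p < α) and
  non-significant loss going down (p > α), α = 0.05 by default.

## Synthetic data

`SyntheticSpec(model, n, seed, alpha)` states a world: the generating
distribution is the maximum-entropy projection of a symmetric
Dirichlet(α)-drawn joint onto an RA structure (projecting one joint keeps
all margins mutually consistent), or Dirichlet(α) conditional tables
multiplied along a DAG. α defaults to 1.0; 0.2 is the "strong effects"
setting used in the recovery experiments. Samples are seeded multinomial
draws, returned together with the exact generating distribution.

The generator emulates multinomial sampling from a distribution that
satisfies the stated structure *exactly*. Real data differ in ways the
green tests therefore do not cover: structures only approximately true,
sparse cells at realistic sample sizes, ordinal or continuous variables
discretized post hoc, and selection or measurement artifacts. A passing
recovery test says the search machinery finds a structure that is exactly
present at n = 10⁵ with strong effects — not that it will resolve weak
effects at small n (at n = 2·10⁴ with moderate draws, BIC will sometimes
prefer dropping a weak relation, as it should).

## Degenerate inputs and numerical conventions

Structures must cover every variable (singletons re-cover orphans);
duplicate and embedded relations are merged silently on parse. Zero-mass
IV configurations make p(DV | IVs) undefined and are returned as NaN.
Statements are symmetric in their two sides and canonicalized at
construction. Canonical printing sorts variables into system order inside
relations and relations by descending size then alphabetically; printed
comparisons in the tests are structural (parse-then-compare), since
relation order in the notation is semantically arbitrary.

## Known limitations

Everything is exhaustive: DAG enumeration is refused beyond n = 5 and
permutation-based isomorphism beyond n = 8; the joint lattice is only
practical for the small systems it was designed to census. IPF runs on
dense state-space arrays, so total state-space size, not variable count,
is the real bound. Cardinalities are carried through all fitting code but
the published censuses are all binary/four-variable. The BN-class search
lattice links classes by single-edge deletion between members; the joint
search space represents each equivalent pair by its RA side and keeps
each family's own hierarchy (no cross-family edges, mirroring the joint
lattice diagrams, whose arrows follow the RA hierarchy only).
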