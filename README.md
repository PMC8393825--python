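# rabn — RA and BN structure lattices for discrete variables

`rabn` unifies two families of probabilistic graphical models over discrete
(nominal) variables:

* **Reconstructability-analysis (RA) structures** — undirected hypergraphs of
  *relations* (jointly constrained variable subsets), written `AD:BD:CD`,
  with maximum-entropy semantics: the fitted distribution matches every
  relation's margin and is otherwise as uniform as possible.
* **Bayesian networks (BN)** — directed acyclic graphs with the usual
  node-given-parents factorization and d-separation semantics.

The two families overlap exactly where RA structures are *loopless*
(acyclic hypergraphs, hence closed-form factorizable) and BNs have no
*V-structures* (two non-adjacent parents converging on a child). The
package enumerates both families exhaustively for small systems, classifies
them into labeled ("specific") and unlabeled ("general") equivalence
classes, merges them into a joint lattice organized by variable-adjacency
(Rho) graphs, reduces the BN lattice to unique-prediction representatives
when one dependent variable (DV) is the target, and fits and searches all
of these lattices on contingency data with information-theoretic scores.

Who it is for: modelers of small discrete systems (systems science,
epidemiology, machine-learning pedagogy) who want the *complete* candidate
space of independence structures — including hypergraph relations and
loopy RA models that BNs cannot express, and V-structure models that RA
cannot express — rather than the output of a heuristic structure learner.

## The core objects, in standard notation

For variables A, B, C, D each with finitely many states:

* An RA structure is an antichain of relations covering all variables.
  `AD:BD:CD` asserts (A ⟂ B, C | D), (B ⟂ C | D); its maximum-entropy
  distribution is p(A|D)p(B|D)p(C|D)p(D). Loopless structures factorize in
  closed form; loopy ones (e.g. `AB:BC:CD:AD`) need iterative proportional
  fitting (IPF).
* A BN is a DAG; Markov-equivalent DAGs (same skeleton, same V-structures)
  form one specific graph. V-structure independencies are written as
  subscripts in extended notation: `BCD_B:C_:A` is the graph B→D←C with A
  isolated, carrying the internal statement (B ⟂ C).
* At four variables there are 543 labeled DAGs, 185 BN specific graphs, 20
  BN general graphs; 114 RA specific structures in 20 general classes; the
  merged lattice has 238 specific and 30 general structures, of which 61
  and 10 respectively are RA-BN equivalent.

## Worked example

Generate data from a stated star structure (strong effects, Dirichlet
concentration 0.2), fit the true model, and search the neutral lattice:

```bash
rabn simulate --model "AD:BD:CD" --nodes A,B,C,D --n 100000 --seed 3 \
    --alpha 0.2 --out demo.csv
rabn fit --model "AD:BD:CD" --data demo.csv --format contingency
```

```json
{
  "aic": 460933.9690579688,
  "bic": 461000.5595362236,
  "ddf": 8,
  "df": 7,
  "entropy_bits": 3.3248347680331305,
  "ipf_iterations": 1,
  "lr_stat": 8.544836174263466,
  "model": "AD:BD:CD",
  "p_value": 0.38213376593043646,
  "transmission_bits": 6.163796386909263e-05
}
```

The model uses 7 degrees of freedom (the u-terms of AD, BD, CD and the four
main effects), loses only 0.00006 bits of transmission against the data,
and the likelihood-ratio statistic against the saturated model (8.54 on 8
df, p = 0.38) says the star reproduces the sample within noise. A
bottom-up BIC search recovers the generator, climbing one relation at a
time:

```
$ rabn search --lattice ra --data demo.csv --format contingency
selected: AD:BD:CD
  A:B:C:D    490462.0
  BD:A:C     467452.7
  AD:BD:C    463346.5
  AD:BD:CD   461000.6
```

The same things are available as library calls:

```python
from rabn import VariableSystem, parse_structure, ra_lattice, build_joint
from rabn.bn import Dag, bn_notation, minimal_independencies

sys4 = VariableSystem(("A", "B", "C", "D"))
dag = Dag(sys4, [("B", "D"), ("C", "D")])
print(bn_notation(dag))                     # BCD_B:C_:A
print(build_joint(sys4).general_counts)     # {'ra_only': 10, 'bn_only': 10,
                                            #  'equivalent': 10, 'total': 30}
```

## Command line

`rabn enumerate {dags,classes,ra,rho,joint}`, `rabn notation`, `rabn dsep`,
`rabn lattice` (JSON/DOT export), `rabn fit`, `rabn search`,
`rabn simulate`. All JSON outputs are schema-versioned and deterministic
given `--seed`.

## Scope

Exhaustive enumeration is deliberate and therefore limited to small n
(DAG enumeration refuses n > 5; isomorphism grouping n > 8). Continuous
variables, state-based RA models, causal reading of edge directions, and
hybrid RA-BN graphs are out of scope. See `docs/methods.md` for the model
conventions, numerical choices, and known limitations.
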