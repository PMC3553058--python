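# molcode

Detection of *molecular codes* — contingent sign→meaning mappings — in
chemical reaction networks.

A reaction network can *realize a mapping* from a set of signs **S** to a
set of meanings **M** when there is a context set **C** such that the
closure of **C** contains no meaning, while the closure of **C** plus one
sign contains exactly one meaning. If a second context realizes the
*crossed* mapping on the same two signs and meanings, the pair forms a
**binary molecular code (BMC)**: the assignment is contingent, not forced
by the chemistry. The number of such code pairs is the network's
**semantic capacity** `n_cp` (logarithmic form `L = log2(n_cp + 1)`).

The package provides:

- `network_core` — reaction-network model, plain-text (`.rxn`) and
  CHEMKIN-II parsing, the closure operator, lectic (next-closure)
  enumeration of all closed sets, and deterministic k-shortest-path
  machinery on the bipartite species–reaction graph.
- `code_finder` — two BMC-identification algorithms: closure-based
  (contexts range over all closed sets; exact) and path-based (contexts
  assembled from k-shortest-path reactant sets; converges to the exact
  result for large k), plus merging of BMCs into larger codes.
- `model_builders` — the model chemistries: merged genetic-code
  translation networks (the 17 NCBI translation tables ship as packaged
  data), the aaRS-refined translation model, gene regulatory networks,
  phosphorylation cascades, and the closed-form code-count formulas.
- `random_nets` — seeded random bimolecular networks (null model),
  density surveys, and arity-preserving network randomization.
- `dynamics` — mass-action ODE simulation of the two-step phosphorylation
  cascade and the high/low concentration-level code check.

## CLI

```sh
# build model chemistries
molcode build grn --n 2 --out grn.rxn
molcode build translation --variant merged --out genetic.rxn
molcode build cascade --two-step --out cascade.rxn

# closed sets and code finding
molcode closed-sets --input grn.rxn --cap 100000 --out closed.json
molcode find --input genetic.rxn --method paths --k 4 --merge --out report.json

# null model / surveys / randomization
molcode random --species 10 --reactions 38 --replicates 50 --seed 42 --out row.json
molcode survey --sizes 8,12,16 --densities 0.75:3.0:0.25 --replicates 50 --out survey.tsv
molcode randomize --input net.rxn --replace 5 --reps 100 --seed 7

# cascade dynamics (steady-state Tp/T response)
molcode simulate cascade --context A --x0-grid 0:5:0.25 --out curve.tsv
```

`.rxn` files contain one reaction per line (`[label :] 2 A + B -> C`),
`#` comments, and an optional `species:` directive for species that occur
in no reaction. Empty left-hand sides are inflows (fire unconditionally),
empty right-hand sides are outflows. CHEMKIN mechanisms (SPECIES/REACTIONS
blocks) are parsed with reversible reactions split into both directions.

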