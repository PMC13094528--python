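# enzedit

Site-specific reaction edits for enzymatic retrosynthesis: a codec that
losslessly interconverts atom-mapped enzymatic reactions and typed edit
scripts, the self-supervised corpus constructions and sequence-model
harness that learn to generate those scripts, an EC-number evaluation
protocol, and a multi-objective Monte Carlo tree search planner for
multi-step biosynthetic routes.

## Who this is for

Biocatalysis and computational chemistry groups who want to work with
retrosynthesis as *edit generation* rather than free-form SMILES
generation: a single retro step is expressed as a short script of typed
actions addressed to the numbered atoms of the product, ending with a
hydrogen-repair terminator and, for enzymatic steps, the Enzyme
Commission (EC) number of the catalyzing enzyme.

## The edit representation

A product molecule is parsed and its heavy atoms given deterministic
canonical IDs `0..n-1`. A retro step is then an ordered script over
eight actions:

| action | operands | meaning |
|---|---|---|
| `[Delete][Bond]` | element pair, `i.j` | break the bond between atoms i and j |
| `[Change][Bond]` | element pair, `i.j`, order | retarget a bond order (`-`, `=`, `#`) |
| `[Add][Bond]` | element pair, `i.j`, order | form a new bond |
| `[Attach][Group]` | wildcard-anchored SMILES, `i` | splice a substructure onto atom i at its `*` |
| `[Leave][Group]` | wildcard-anchored SMILES | excise a substructure; `*` marks where it was attached |
| `[Change][Atom]` | element + charge/stereo descriptor, `i` | retarget formal charge or CIP stereocenter |
| `[Terminate]` | — | recompute implicit hydrogens so every atom satisfies valence |
| `[EC]` | four fields | annotate the enzyme class, e.g. `[EC] 2 1 1 71` |

For example, `[Delete][Bond]CN: 7.8` breaks the C–N bond between atoms
7 and 8. Scripts extracted from the same transformation are identical
across substrates up to atom sites, which is what makes them a useful
learning target for linking reaction mechanism to enzyme identity.

The codec guarantees the round trip: for an atom-mapped reaction `r`,
`apply_edits(product, extract_edits(r))` reproduces the reactant set
under canonical SMILES.

## Worked example

```python
from enzedit import parse_reaction, extract_edits, apply_edits, script_text

rxn = parse_reaction(
    "[CH3:1][C:2](=[O:3])[OH:7].[OH:4][CH2:5][CH3:6]"
    ">>[CH3:1][C:2](=[O:3])[O:4][CH2:5][CH3:6]"   # ester, atom-mapped
)
script = extract_edits(rxn)
print(script_text(script))
# [Delete][Bond]OC: 4.5 [Attach][Group]*O: 5 [Terminate]

print(sorted(m.smiles() for m in apply_edits(rxn.product, script)))
# ['CC(=O)O', 'CCO']
```

The extracted script reads: break the acyl C–O ester bond (atoms 4 and
5), attach a hydroxyl (`*O`) to the acyl carbon, then repair hydrogens —
i.e. retro ester hydrolysis into acetic acid and ethanol, which the
second line reproduces exactly.

Planning works over an AND-OR tree (OR-nodes = molecules, AND-nodes =
reactions with EC numbers). On the shipped putrescine biosynthesis
network, with default budgets (beam 10, max depth 10, 100 MCTS
iterations):

```sh
enzedit fixtures --out fx --seed 1
enzedit plan --target NCCCCN --blocks fx/building_blocks.smi \
             --universe fx/universe.json --seed 1
```

returns a Pareto front of three complete routes from L-arginine —
2 steps via EC 4.1.1.19 + 3.5.3.11, 3 steps via EC 4.1.1.19 + 3.5.3.12 +
3.5.1.53, and 2 steps via EC 3.5.3.1 + 4.1.1.17 — each with its
objective vector (pathway length, mean step confidence, mean Tanimoto
similarity of precursors to the building-block set).

## Command line

`enzedit encode | decode | make-corpus | train | predict | evaluate |
plan | fixtures` — each a thin wrapper over the library; every command
is byte-deterministic under a fixed `--seed`.

## Layout

- `src/enzedit/chemgraph.py` — molecules with canonical atom IDs, SMILES
  tokenization, reactions and atom maps, fingerprints
- `src/enzedit/ssredits.py` — the edit codec: extract, apply, serialize, parse
- `src/enzedit/pretrain.py` — FillMASK / MakeSSREdits / MakeSMILES corpus builders
- `src/enzedit/autograd.py`, `src/enzedit/seq2seq.py` — the sequence model harness
- `src/enzedit/enzyme_eval.py` — EC numbers, input configurations, metrics
- `src/enzedit/planner.py` — AND-OR tree, Pareto front, MCTS
- `src/enzedit/fixtures.py` — seeded synthetic reactions, universes, the
  putrescine network
- `docs/methods.md` — model and design notes
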