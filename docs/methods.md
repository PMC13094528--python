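# Methods and design notes

## Atom identity

All site-specific edits are addressed to integer atom IDs. IDs are
0-based and assigned by RDKit canonical atom ranking of the parsed
product, so any SMILES spelling of the same molecule yields the same
IDs. Only heavy atoms are numbered; hydrogens are implicit and managed
by valence rules at script termination. Wildcard `*` atoms are
first-class, degree ≤ 1, and mark the attachment points of group
operands.

## The edit codec

**Extraction** diffs an atom-mapped reaction in product coordinates:

- bonds between two mapped product atoms whose images are unbonded or in
  different reactants → `DeleteBond`; order differences → `ChangeBond`
  to the reactant order; reactant-only bonds between mapped images →
  `AddBond`;
- maximal connected unmapped product substructures → `LeaveGroup`, with
  one wildcard per boundary bond;
- maximal connected unmapped reactant substructures anchored at one
  mapped atom → `AttachGroup` with the wildcard at the anchor bond;
- mapped atoms differing in formal charge or CIP stereo label →
  `ChangeAtom` carrying the target state;
- `Terminate` closes the script, and the reaction's EC label (if any)
  appends the `EC` action.

Edits are emitted in a fixed phase order — DeleteBond, ChangeBond,
AddBond, LeaveGroup, AttachGroup, ChangeAtom, Terminate, EC — sorted by
atom site within each phase, so a given transformation has exactly one
canonical script and the learning target is unambiguous.

**Application** replays a script on a working copy of the product while
tracking original IDs through atom insertions and deletions. At
`[Terminate]`, every atom touched by an edit has its hydrogen
bookkeeping reset and re-derived by sanitization; failure to satisfy
standard valence raises a `ValidityError`, which is exactly the filter
used to discard chemically infeasible generated scripts. The result is
the set of connected components with their own canonical IDs, plus the
surviving-atom map (which is how fixture reactions obtain ground-truth
atom maps without an external mapper).

Numerical/chemical corner cases:

- *Aromaticity changes.* When a bond is aromatic on only one side of the
  reaction, the edit carries the kekulized explicit order of the target
  side; terminate-stage sanitization re-perceives aromaticity. Bonds
  aromatic on both sides are never diffed (kekulization is resonance-
  ambiguous).
- *Stereo.* `ChangeAtom` encodes target chirality as a CIP label
  (`@R`/`@S`, `@0` clears), because RDKit parity tags depend on neighbor
  order and would not survive renumbering; application sets the tag that
  realizes the requested CIP label on the current graph. Double-bond
  cis/trans is outside the grammar and canonicalized away.
- *Site-less leave groups.* `[Leave][Group]` carries no atom site (the
  wildcard-anchored substructure is matched at apply time). Among valid
  matches — those whose only external bonds pass through wildcard
  anchors — the first in sorted atom order that does not remove an atom
  addressed by a later edit is taken, which resolves symmetric-molecule
  ambiguity deterministically.
- *Free cofactor reactants.* A wholly unmapped reactant has no bond to
  any mapped atom, so its operand is a dot-disconnected wildcard group
  (`*.SMILES`) and application adds it as a separate component; the
  recorded site is informational. A reactant fragment bonded to two or
  more mapped atoms is not expressible in the single-site grammar and
  extraction reports it as such.

**Serialization** emits whitespace-delimited field tokens whose joined
text is the printed grammar (e.g. `[Delete][Bond]CN: 7.8`); parsing is
total over whitespace-split text and is the exact inverse on valid
scripts.

## Pretraining corpus builders

- **FillMASK**: spans of 1–4 tokens are masked left to right, each span
  start drawn uniformly at or after the end of the previous span, for at
  most five spans or until no token remains after the last mask. The
  sentinel is a bare `[MASK]` in both input and target; the target lists
  each masked span behind its sentinel in order. Span starts and lengths
  are uniform — no distributional shaping is attempted.
- **MakeSSREdits / MakeSMILES**: a random structural edit is drawn
  uniformly over the applicable action types, then uniformly over valid
  sites/operands; attach/leave operands come from a shipped pool of ~50
  common groups (`data/fragments.smi`). The two tasks share the draw
  under the same seed, so one task's target provably maps the shared
  original onto the other's (`input = orig>>edited` vs
  `orig [SEP] script`). The edited SMILES is always the canonical output
  of applying the script, which makes the pair self-consistent even when
  a site-less leave group is ambiguous.
- Every builder is reproducible from an integer seed; `build_corpus`
  derives one seed per attempt so output files are byte-identical across
  runs, skipping unusable inputs (too short, no applicable edit) and
  drawing more until the requested count is met. Inputs and targets are
  capped at the 256-token model context.

## Sequence model harness

The generator is an encoder-decoder transformer with bucketed relative
position bias, pre-RMSNorm blocks, ReLU feed-forward layers, and tied
input/output embeddings. The published-scale configuration (6+6 blocks,
model dim 256, 12 heads × 64, FFN 2048, 32 relative buckets, max
relative distance 128, 256-token context, dropout 0.10) is the default
`ModelConfig`; desk-scale work uses `ModelConfig.tiny()` (2+2 blocks,
dim 64, 4 heads × 16, FFN 128, dropout 0) — small enough to train on one
CPU in about a minute. The whole stack runs on a minimal reverse-mode
autodiff engine over NumPy arrays written for this package
(`autograd.py`), verified against numerical differentiation in the test
suite.

Optimization is AdamW (β₁ = 0.9, β₂ = 0.999) with a linear warmup to the
peak learning rate and a 2% multiplicative decay after every 10,000
steps; the schedule is exposed in closed form (`learning_rate`) so the
boundary behavior is directly checkable. The warmup length is a free
parameter (default 100 steps; 20 at desk scale with peak 3e-3, chosen so
a 50-example corpus is memorized within a few hundred steps). Divergence
(non-finite loss) aborts with a diagnostic.

Beam search keeps the `beam_size` highest-scoring partials per step;
sequence score is the mean of per-token log confidences (length
normalization, since the grammar mixes short and long targets), ties
broken lexicographically for determinism. Candidates are deduplicated by
canonical decoded output (script text if it parses, else canonical
SMILES, else raw text); a validator hook drops candidates whose decoded
script fails parsing or application, with ranks refilled from the
remaining beam. EC numbers decode as four separate field tokens after
`[EC]`, keeping the vocabulary small.

## EC evaluation

EC numbers are four positive integer fields with wildcard suffixes;
level = number of specified leading fields. Comparison at level L
truncates both sides to L, and a label printed with a wildcard suffix is
only comparable at levels up to its own specificity. Three input
configurations are supported: product only, product `[SEP]` reactants
(molecules joined by `.`), and product `[SEP]` edit script; over-length
inputs raise rather than silently truncate. Top-k exact match counts a
record as a hit when the truth appears within ranks 1..k — for joint
(script, EC) records both the canonical script text and the EC must
match. Classification scores are multiclass accuracy, the multiclass
Matthews correlation computed from the full confusion matrix (defined as
0 when either side has zero variance), and macro-averaged F1 (the
averaging choice is configurable in principle; macro is the default and
the one tested against reference implementations).

## Planner

The search space is an AND-OR graph: OR-nodes are molecules
(deduplicated globally by canonical SMILES), AND-nodes are single retro
steps (precursor set + EC + step confidence). Pathways are scored by
three objectives: length (minimize), RAscore — the geometric-mean token
confidence of each step, averaged over steps with uniform weights
(maximize) — and substrate similarity — each precursor's best Tanimoto
match (Morgan radius 2, 2048 bits) against the building-block set,
averaged (maximize). The empty pathway (target already a building
block) scores (0, 1, 1) by convention.

MCTS selection is single-tree UCT on a scalarized value, with fresh
Dirichlet(1,1,1) objective weights drawn each iteration so exploration
stays spread across the Pareto front rather than collapsing onto one
trade-off; rollouts follow the highest-confidence candidate greedily to
the depth limit. Candidates that would reintroduce a molecule already on
the path are rejected at expansion, and duplicate precursor-set/EC pairs
in a beam are merged. After each iteration, complete pathways present in
the expanded tree are harvested (bounded enumeration) into the front,
which is finally trimmed to `pathway_top_k` by non-dominated sorting
with crowding-distance truncation. Defaults: beam 10, max depth 10, 100
iterations, top-k 10. The search is deterministic per seed.

## Synthetic data, and what it does not show

Fixture reactions are built constructively: a known random edit script
is applied to a molecule from a shipped pool of ~40 small structures,
the resulting components become the reactants, and the surviving-atom
map provides the ground-truth atom mapping. This guarantees that each of
the six structural action types appears at least 10 times per 60
reactions and that extraction targets are known without an external atom
mapper. The putrescine network ships the real metabolite structures
(putrescine, agmatine, N-carbamoylputrescine, L-ornithine, L-arginine)
with the literature EC numbers for its three routes; step confidences
are synthetic, calibrated so the three routes are mutually non-dominated
under the three objectives (ra-score order II > I > III against
similarity order III > I > II), since a Pareto front can only be
expected to retain routes that are actually Pareto-optimal.

What passing these tests shows: the codec, grammars, metrics, optimizer
schedule, and planner behave exactly as specified on inputs with known
ground truth, and a small model can learn the representation end to end.
What they do not show: accuracy on real reaction corpora (USPTO,
ECREACT, BioCyc), which requires external data and large-scale training
outside this package's scope; the toy molecule pool also lacks the size,
stereochemical richness, and mechanistic diversity of real enzymatic
substrates, and the oracle predictor sidesteps model error entirely
except where noise is injected deliberately.

## Problem sizes used

Desk-scale defaults throughout: 200 fixture reactions per codec sweep,
1,000 scripts for grammar checks, 10,000 masking draws and 1,000
edit-pair draws for corpus properties, a 50-example corpus and 300
training steps for the memorization check, and 20 seeded planner runs on
the putrescine network. These sizes make the full suite and the
acceptance script each complete in a few minutes on one CPU while still
exercising every guarantee.

## Known limitations

- Multi-anchor attach fragments (one reactant fragment bonded to two or
  more mapped atoms) are outside the single-site grammar.
- Bond stereo (E/Z) is not represented in edits.
- Leave-group matching is substructure-based; on molecules with many
  isomorphic fragments the deterministic tie-break may excise a
  different but symmetric copy when no later edit disambiguates.
- The beam does not cache decoder states; decoding cost grows
  quadratically with target length (irrelevant at desk scale).
- The planner's multi-objective selection rule (random scalarization) is
  one defensible choice among several; it preserves front diversity but
  is not a reimplementation of any particular published variant.
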