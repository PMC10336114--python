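# Methods

## The model

`cocosim` simulates a cell's phenotype trajectory as a discrete dynamical
system over a fixed population of N = 1000 addressable elements
(macromolecules).  At each time step an **Active subset** of S distinct
elements (default S = 6) stands for the set of factors determining the
phenotype.  Two per-element multisets of addresses encode the system's
connectivity:

* the **Now field** — partners an element tends to be co-active with
  (within-state coherence);
* the **Next field** — elements that tend to follow it in the next state
  (state-to-state coherence).

Multiplicity is connection strength: the score of a candidate element is
the total number of times its address occurs in the relevant fields, summed
over the members doing the scoring.  Each field is capped at 8 *distinct*
addresses (capacity; multiplicities are unbounded), and **Downtime**
(default 12 states) makes a just-active element ineligible, modelling
degradation and resynthesis delay.

### State selection

The state at t+1 is built seat by seat.  The first seat goes to the top of
the Next ranking computed from the state at t.  Every further seat is a
two-candidate contest: the best remaining Next candidate against the best
Now candidate scored by the members already seated.  Higher score wins; a
Next-vs-Now tie goes to the Next candidate; ties inside a ranking go to the
lower address, making runs reproducible.  When every candidate scores zero
the seat is exploratory noise: a uniform draw from the *naive* pool (never
active, no connections — unengaged regulatory material), falling back to
all eligible elements once no naive ones remain.  This interleaving of the
two rankings is a reconstruction; only its ingredients (the two scores, the
ranking competition, the role of noise) are fixed by the model description.

### The learning task

The environment presents the input cycle (1, 2, 3, 2, 3), one input every
3 steps, each seated directly into the state it opens (the scheduled input
anchors its window; the rest of the state develops around it).  The input
must be answered by the paired output from (1000, 999, 999, 1000, 998)
within a three-state window.  When the window closes:

* if **no** output address appeared at all, a uniformly random output is
  forced into the last state, and the window is then judged like any other
  — a forced output that happens to match the expectation is rewarded (the
  forcing is a teaching signal, not merely an accounting device);
* **reward** iff the expected output is present; otherwise **punish**.

Reward adds one occurrence for every ordered co-active pair (Now) and every
cross-step pair (Next), and grows every participating learnable field's
capacity by one (max 8).  Punishment removes the same pairs (floored at
zero) and shrinks capacities (min 1).  A shrinking capacity clamps future
growth but never evicts surviving content — with eviction, every freshly
rewarded output link is the lowest-multiplicity entry in its field and dies
in the next punished window, so the reward signal cannot bootstrap at all.
Next-pair updates include the transition *entering* the window, so that
consecutive windows tile every transition of the sequence exactly once; a
link sitting on a window boundary would otherwise be invisible to learning
forever.  PPDP fields (below) are fixed and exempt from all of this.

Convergence is declared after 10 consecutive task cycles in which all five
windows are rewarded without forcing.

### Environment-coupled elements

The input and output elements carry a shorter Downtime of 4 (config
`io_downtime`).  This is forced by the task's arithmetic: output 999 must
appear in two adjacent three-state windows, so its two appearances can be
at most 5 steps apart, bounding its Downtime at 4; a Downtime below 3 would
let an output recur inside its own window and drift parasitically into
every rewarded state.  Downtime 4 is the unique value compatible with both
constraints.

### The PPDP element

A Phenotype-Preserving Disordered Protein is modelled as element 10 with

* Downtime 0 (a stable protein, present in consecutive states),
* a guaranteed top rank in the Next competition (implemented as a rank
  override, not a large score, so learning can never accidentally exceed
  it),
* fixed Now/Next fields of 60 occurrences each: addresses 111–140 (Now) and
  141–170 (Next), each twice — the many partners of a disordered hub.

Because element 10 is in every state and its fields always give its
partners a baseline score of 2, learning with the PPDP confines the active
states almost entirely to elements 111–170; without it the states draw on
the whole population.

## Experiments

All experiments are reproducible bit-exactly per seed; the population seed
and the dynamics generator are both derived from the experiment seed
through a `SeedSequence`.

**Learning** (`run_learning`): learning mode for up to `max_steps` (3000)
or convergence.  *Restriction* is the fraction of seated addresses in the
last 30 states (two task cycles) that lie in 111–170, after removing
inputs, outputs and the PPDP address itself.

**Perturbation** (`run_perturbation`): learning until convergence or step
900, then free running (no inputs, no outputs, no learning — the
connectivity is conserved exactly).  At step 999 the Active subset doubles
to 12; at the next would-be input-1 step the state is overwritten with 12
elements from outside the learnt membership (naive ones where available).
*Overlap* is containment: the fraction of the learnt membership (union of
the final full cycle) re-observed in the 30 states following the
overwrite.  Containment is used instead of a symmetric index because the
doubled states necessarily contain ~6 extra rotating members each; a
Jaccard index is then bounded near 0.3 for both arms regardless of whether
the learnt membership survived, and cannot express the claim being tested.

**Second PPDP** (`run_second_ppdp`): after learning with the PPDP, the
connectivity among the elements active in the last 24 states is recorded
and mimicked, via a random address bijection, onto never-active hosts; the
image of element 10 becomes the second PPDP (guaranteed rank, fixed
fields).  The hosts model the ready-made factors of a competing phenotype
and are downtime-exempt.  The second PPDP and its five strongest partners
are written into the state at step 1000.  Disruption is the overlap between
the learnt membership and the 30 states before step 1500.  With
`then_remove`, the second PPDP's Next score is zeroed at step 1500 (its
fields, and hence its partners' Now-mediated pull, are untouched) and input
1 is forced once; recovery means overlap above 0.8 over the final 30 states
of the run (step 1800).

## Network statistics

`netgraph` operates on simple undirected labelled graphs
(`networkx.Graph`) read from STRING-style tab-separated edge lists.
Average node degree is 2|E|/|V|; the local clustering coefficient of a node
is the fraction of realised edges among its neighbours, with degree-<2
nodes contributing 0 to the average (one common convention; the database's
own convention is not documented).  Markov clustering (MCL) is implemented
densely in numpy: self-loops of weight 1, column-stochastic normalisation,
then alternating expansion (matrix power 2) and inflation (entrywise power,
default 2, followed by renormalisation) with pruning below 1e-6 until the
matrix changes by less than 1e-8 or 100 iterations (non-convergence returns
the current partition with a warning).  Clusters are the connected overlaps
of attractor rows; every node is assigned exactly once.  Edge weights
(confidence scores) are ignored.

## What the defaults represent, and what they do not

The default configuration *is* the study condition: 1000 elements, nine
groups of 36 consecutive addresses anchored at 150, 250, …, 950 carrying
the initial random connectivity (4 distinct partners per field,
multiplicity 1, drawn within the group), inputs {1,2,3}, outputs
{998,999,1000}, the (1,2,3,2,3)/(1000,999,999,1000,998) task, Downtime 12,
Active size 6 doubling to 12 at step 999, the PPDP spec above, pattern
recording over 24 states, and the step-1500 removal.  The initial state is
drawn from the initially connected (group) elements: a phenotype is a set
of *interacting* factors.

The generator emulates the qualitative logic of phenotype maintenance, not
any molecular mechanism: no concentrations, no binding kinetics, no
post-translational modification.  Passing tests show that the
coherence-competition architecture produces the claimed hub effects
(restriction, protection, disruption, recovery) under these conditions;
they say nothing quantitative about real interactomes.

## Known limitations

* The selection/learning loop is a reconstruction; several details (tie
  breaks, the ranking interleaving, reward magnitudes, the input period)
  are fixed here by explicit choices documented above, and a different
  reconstruction could behave differently in degree.
* Learning reliably reaches a high reward rate but the strict
  all-five-windows convergence criterion is reached in only a minority of
  runs within the default budget; the experiment protocols therefore
  proceed from the stable attractor at the learning cutoff rather than
  requiring formal convergence.
* In the no-PPDP arm the learnt attractor is highly re-ignitable: by
  perturbation time most of the population carries learnt-era links (the
  input/output elements especially act as re-entry hubs), so the doubling
  + overwrite perturbation does not erase the learnt membership the way a
  fragile, narrowly-wired learner would lose it.  The protection contrast
  between the two arms is correspondingly weaker than the all-or-nothing
  picture one might expect; the restriction, disruption and recovery
  effects are robust.
* The second-PPDP recovery is genuinely stochastic (~70% of seeds at the
  defaults): removal *can* restore the trajectory, not must.

## Problem sizes

The test-suite and acceptance runs use the full default population
(N = 1000) with 11 independent seeds per condition; a learning run is
≤ 3000 steps and the perturbation/second-PPDP timelines end at steps 1200
and 1800.  One full experiment battery runs in well under a minute on one
CPU.
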