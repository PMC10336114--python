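# cocosim

A coherence-competition simulator for testing how a stable, highly
connected disordered-protein hub — a *Phenotype-Preserving Disordered
Protein* (PPDP), with α-synuclein (SYN) and TPPP/p25 as the biological
archetypes — constrains and protects a cell's phenotype trajectory, plus
the protein–protein-interaction network statistics (average node degree,
local clustering coefficient, Markov clustering) used to characterise such
hubs in STRING-style edge lists.

## Who this is for

Systems biologists and modellers who want a reproducible, seedable
implementation of the phenotype-learning thought experiment behind the
"Sherpa" picture of disordered hub proteins: a population of 1000
addressable elements (macromolecules), an **Active subset** of 6 elements
standing for the current phenotype, and reward/punishment learning of an
environmental input/output task.

## The model in brief

Each element carries two multisets of addresses: a **Now field**
(within-state coherence) and a **Next field** (state-to-state coherence);
multiplicity is connection strength.  The state at t+1 is built seat by
seat from two rankings:

* Next score of candidate c: `Σ_{e ∈ state(t)} count(e.next, c)`
* Now score of candidate c: `Σ_{e ∈ developing state} count(e.now, c)`

with the higher score seated (ties to Next, then to the lower address), a
12-step **Downtime** after activity, and uniform noise on all-zero seats.
Reward (+1 per co-active and per consecutive pair, field capacity +1 up to
8 distinct addresses) and punishment (the mirror image) train the task
input (1, 2, 3, 2, 3) → output (1000, 999, 999, 1000, 998), each response
judged within a three-state window.

A PPDP is element 10 with Downtime 0, a guaranteed top Next rank, and
fixed fields holding addresses 111–140 (Now) and 141–170 (Next) twice
each.  The package scripts four experiments: learning with/without the
PPDP (restriction of states to the hub's partner range), a subset-doubling
+ state-overwrite perturbation (protection), the grafting of a mimicking
second PPDP (disruption), and its silencing (recovery).  See
`docs/methods.md` for the full model description and design rationale.

## Worked example

```python
from cocosim import Config, run_learning, run_perturbation

trace, rep = run_learning(Config(), with_ppdp=True, seed=1)
print("restriction:", round(rep.restriction, 3))
print("last state:", trace.states[-1].members)

pert = run_perturbation(Config(), with_ppdp=True, seed=1)
print("overlap after perturbation:", round(pert.overlap_pre_post, 3))
```

prints

```
restriction: 1.0
last state: [10, 164, 160, 165, 2, 158]
overlap after perturbation: 1.0
```

Restriction 1.0 means every non-input/output element seated late in
learning lies in the PPDP's partner range 111–170 — the hub has confined
the phenotype to its own interaction neighbourhood (the last state shows
the PPDP 10, four partners and input 2).  The post-perturbation overlap of
1.0 means the entire learnt membership is re-observed within two task
cycles of a perturbation that doubled the state size and overwrote a state
with foreign elements.  Running `run_learning(..., with_ppdp=False, ...)`
instead gives restrictions near 0.05: without the hub, the phenotype draws
on the whole population.

The same protocols are available from a shell:

```
coco learn --seed 1 --ppdp --out-dir out/
coco perturb --seed 1 --no-ppdp
coco second-ppdp --seed 1
coco recover --seed 1
```

### Network statistics

```
$ coco net-stats edges.tsv --mcl
{
  "nodes": 4,
  "edges": 4,
  "avg_degree": 2.0,
  "avg_clustering": 0.5833,
  "clusters": [["HDAC6", "MAPT", "SNCA", "TPPP"]],
  "n_clusters": 1,
  "mcl_converged": true
}
```

for a toy edge list containing SNCA–TPPP, SNCA–HDAC6, TPPP–HDAC6 and
SNCA–MAPT.  The input is a two-column tab-separated edge list (STRING
export dialect: header tolerated, extra columns ignored, duplicate and
self-loop rows cleaned up).

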