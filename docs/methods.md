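# Methods

## The model class

`molcluster` simulates supply-limited clustering of multivalent
biomolecules.  A system is a fixed pool of molecules, each an instance of a
declared type with a named set of binding sites (its valence), together with
reversible bimolecular site–site binding rules.  A rule connects one site of
one type to one site of the same or another type, and every bond a rule can
form shares that rule's two stochastic rate constants: `kon`, per eligible
free site pair per time unit, and `koff`, per existing bond per time unit.
Rates are copy-number (stochastic) rate constants; converting from molar
units is the user's responsibility (`kon_stoch = kon_molar / (N_A · V)` for
a bimolecular rule in a volume `V`).  `koff = 0` encodes irreversible
binding.

A *cluster* is a connected component of the molecular network: nodes are
molecule instances, edges are bonds.  The degree of a node is its bond
count, bounded by its valence.  Two bound-fraction statistics exist and both
are implemented: the per-cluster bound fraction BF = (2 · bonds) / (total
sites in the cluster), used by the BF-by-size matrix, and the per-molecule
bound fraction (occupied sites / valence), exposed as
`molecule_bound_fraction`.

## Simulation algorithm

The simulator is an exact SSA (Gillespie direct method) over the molecule
pool, tracking individual molecules and bonds ("network-free": no reaction
network is ever enumerated).  Each rule contributes two channels:

* **binding**: propensity `kon · P`, where `P` is the number of eligible
  free site pairs *between distinct clusters*:
  `P = T_a·T_b − Σ_c f_a(c)·f_b(c)` with `T` the global and `f(c)` the
  per-cluster free-site tallies of the two endpoints.  A symmetric rule
  (identical endpoints) counts unordered pairs,
  `P = C(T,2) − Σ_c C(f(c),2)`.
* **dissociation**: propensity `koff · B_r`, with `B_r` the rule's current
  bond count.

Waiting times are exponential in the total propensity; the channel is chosen
proportionally.  A binding event picks a uniformly random eligible pair —
two-stage uniform draws over free-site instances with rejection of
intra-cluster hits, falling back after 40 rejections to an exact weighted
draw over clusters (both procedures are uniform over eligible pairs; the
fallback keeps the worst case near gelation cheap) — and merges the two
clusters.  A dissociation removes a uniformly random bond of the rule and
splits its cluster; the smaller fragment is found by a two-sided BFS so the
cost is proportional to the smaller side.

Because bimolecular rules act only between distinct clusters (the `+`
reactant semantics of network-free simulation engines), ring closure never
occurs and **every cluster is a tree**: bonds = size − 1.  This has a
visible consequence: in a fully gelled system the per-cluster BF saturates
at `2(n−1)/Σ valences`, not at 1, and the mean bonds per molecule
approaches 2 from below.  Cyclic complexes are still *readable* (e.g. from
external simulator output) and are flagged `is_tree=False` in summaries.

Degenerate models (no rules, `kon = 0`, zero copies) fast-forward to
`t_end` with flat observables rather than erroring.

### Sampling and seeding

Observables (monomer counts per type, free copies of a named site, bonds
per rule, total cluster count) are recorded on the even grid
`t = 0, t_end/n_steps, …, t_end` as the state *as of* each scheduled time
(left-continuous: an event at exactly a scheduled time is recorded after
the snapshot).  Final clusters are the state at `t_end`.

Trial generators are spawned with
`numpy.random.SeedSequence(master_seed).spawn(n_runs)`, so ensembles are
bit-reproducible, trials are independent, and trial *i* does not depend on
`n_runs`.  Per-trial species files list canonical complex strings with
exact duplicates aggregated, sorted by descending count then string, so
reruns are byte-identical.

## Canonical complex strings

Tree clusters are emitted canonically: the traversal is rooted at the tree
center (for the two-center case, the lexicographically smaller of the two
candidate strings is kept), and children are visited in the declared site
order of each node — unambiguous because one site holds at most one bond.
The emitted string therefore depends only on the abstract tree, never on
node ordering, which is what makes duplicate aggregation in species files
exact for all trees.  We deliberately root at the center rather than at a
"smallest node", because smallest-node selection is ambiguous when several
identical-looking molecules occupy symmetric positions.  Cyclic clusters
(read side only) are emitted deterministically by minimizing over all roots
up to 200 nodes; beyond that only exact-string duplicate detection is
claimed.  Exact graph-isomorphism deduplication for arbitrary cyclic
clusters is out of scope.

## Statistics

All statistics pool the final clusters of every trial into one combined
dataset (species-file entries are expanded by their counts); per-trial
analysis is available by passing a single trial.

* **Occupancy distribution**: fraction(s) = s · (#clusters of size s) /
  total molecules — the probability that a random molecule sits in a size-s
  cluster.  Its mean is the average cluster occupancy (ACO).  Pooled ACO
  equals the molecule-weighted mean of per-trial ACOs (tested identity).
* **Binned distribution**: default bins are monomer-resolved to size 10,
  then doubling ranges (11–20, 21–40, …) with a final open-ended bin.
  Fractions are conserved under binning.
* **Bond histograms**: distribution of node degree over pooled molecules,
  for all molecules or one type; `mean_bonds` is the mean degree.
* **BF matrix**: per-cluster (size, BF) pairs histogrammed with BF bin
  width 0.05 by default (BF = 1 falls in the last bin) and normalized
  *within each size bin* — the conditional distribution of BF given size.
  The normalization per column keeps sparse large-size columns readable;
  an unconditional normalization would be dominated by small clusters.
* **Composition**: per cluster size (or size bin), the fraction of member
  molecules of each type; each row sums to 1.
* **Time courses**: pointwise mean and sample standard deviation (n−1
  divisor; zero for a single trial by convention) across trials.

Tables are exported as single-header TSV files with fixed names
(`occupancy.tsv`, `aco.txt`, `bonds_<scope>.tsv`, `bf_matrix.tsv`,
`composition.tsv`, `timecourse_stats.tsv`); figures are drawn from these
tables only and never recompute statistics.

## The packaged example and what it emulates

The canonical example is the Nephrin / Nck / NWASP system: Nephrin with
three phosphotyrosines, Nck with one SH2 and three SH3 domains, NWASP with
six proline-rich motifs.  Binding is site-specific, so the model carries 3
pY–SH2 rules and 18 SH3–PRM rules, all sharing one `kon`/`koff` pair.

Copy numbers (180 / 540 / 270; 990 molecules) were chosen once to balance
binding-site stoichiometry — 540 pY against 540 SH2 and 1620 SH3 against
1620 PRM — which places the strong-affinity system deep in the clustered
regime.  With `kon = koff = 0.01` the per-pair equilibrium constant is 1
and, with hundreds of partner sites available per site, site occupancy
approaches saturation: essentially all molecules join one supply-limited
giant cluster (> 50 % of molecules in the largest size bin, the bimodal
"clustered" regime).  The weak variant lowers `kon` to 1e−7 (per-site
binding probability ~1e−4 · 1600 ≈ 0.1 ≪ 1), giving a monomer-dominated,
exponentially decaying unimodal distribution — the "dispersed" regime.
`t_end = 30` exceeds both the gelation time (≪ 1 time unit at strong
affinity) and the bond turnover time (1/koff = 100 per bond, but ~20
dissociation events per time unit system-wide), and 10 trials of 990
molecules keep a full two-regime comparison to seconds of CPU.

What the synthetic conditions do *not* emulate: spatial structure (steric
exclusion, crowding, site geometry, disordered linkers), allosteric or
cooperative rate modulation, internal site states, and ring closure within
clusters.  Passing tests therefore validate the combinatorial/stochastic
bookkeeping and the statistics, not spatial realism of any particular
biological condensate.

## Numerical choices and edge cases

* Propensity bookkeeping is exact integer arithmetic (pair counts and
  cross-terms are maintained incrementally as ints), so no drift
  accumulates over long trajectories.
* Occupancy/composition normalization checks use a 1e−9 absolute
  tolerance.
* The synthetic-cluster generator grows trees by uniform random
  rule-respecting attachment; a requested size is declared unreachable
  after 50 failed growth attempts (reachability can be blocked by
  valence, e.g. size 3 on a model of two monovalent types).
* Chi-square validation of the 2A+2B dimerization benchmark samples one
  long trajectory every 5 time units — an order of magnitude beyond the
  chain's relaxation time (spectral gap ≥ 1 at kon = koff = 1) — with the
  first 400 samples discarded as burn-in.

## Known limitations

* No compartments, internal site states, synthesis/degradation, or
  functional (state-dependent) rates; the dialect is deliberately the
  minimal one that exercises multivalent clustering statistics.
* Tree-only dynamics: systems where ring closure matters (high local
  concentration within a cluster) are outside the simulator's semantics,
  though their outputs can still be read and analyzed.
* The simulator targets desk scale (≤ ~10⁵ molecules); no performance
  engineering beyond the incremental tallies described above.
* Statistical-factor conventions for symmetric self-binding rules follow
  the unordered-pair count documented above; exact parity with other
  engines' symmetric-rule conventions is not claimed.
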