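# Methods

This note documents the models implemented in `tumorspace`, the numerical
choices behind them, and what the validation suite does and does not
demonstrate.

## Spatial birth–death dynamics

The tumour is a configuration of cells on a fixed graph, one cell per
node. Node states are integers 0..n_pop (0 = empty); clone 1 is the
driver-free wild type. Two graph constructors are provided:

- **Regular lattices** (2D/3D), unit spacing, non-periodic (hard-wall)
  boundaries. A tumour grown from a central seed never "wraps", which is
  the natural reading of a bounded tissue section. The neighbourhood is
  von Neumann by default (4 neighbours in 2D, 6 in 3D) and configurable to
  Moore; the von Neumann choice is the minimal nearest-neighbour
  convention and matches a range-adjacency build with J slightly above 1.
- **Point clouds** with range adjacency: i ~ j iff ‖p_i − p_j‖ < J, with
  strict inequality (a pair at exactly distance J is not connected).
  Adjacency is built with a k-d tree and cross-checked in the tests
  against an O(n²) pairwise scan.

Node indexing is 0-based row-major, so event logs are bitwise reproducible
across runs for a fixed seed.

The dynamics is a continuous-time multi-type birth–death process: death at
rate β per cell, division at rate α_i per cell of clone i. The event loop
draws exponential waiting times from the *total* rate Σ_cells (α_i + β),
including proposals that the interaction rule will reject ("phantom
events", which advance time only). This avoids re-enumerating the feasible
event set after every event and is statistically exact — the validation
suite compares final-state distributions against a naive Gillespie that
recomputes the feasible set each step (two-sample KS, 5000 replicates).

Implementation notes:

- Cells are grouped by clone: every cell of clone i carries the same rate
  α_i + β, so an event draw is "clone ∝ n_i(α_i + β), then uniform member"
  at O(#clones) cost. The total rate is maintained incrementally and
  recomputed from scratch every 10⁴ events to bound floating-point drift.
- Interaction rules and their phantom conditions: contact — occupied
  target; voter — target of the same clone (displacement kills the
  resident otherwise); hierarchical voter — target with equal or higher
  birth rate. An empty target is a valid birth under every rule, so a
  fitter clone colonises free space as well as displacing weaker
  neighbours. Deaths at rate β occur under every rule.
- Driver advantages are drawn from a Gaussian(mean, sd) *resampled* until
  positive: clamping at zero would put an atom at "no advantage",
  contradicting the premise that a driver increases fitness. The clone's
  rate is the wild-type rate plus the unweighted sum of its drivers'
  advantages. μ_dri is interpreted per division event (not per unit time).
  When a driver tree with per-clone rates is supplied, new clones follow
  the tree's unused edges; a clone whose edge was consumed cannot
  re-emerge, so the realised clonal structure is a subtree of the input.
- The default initial condition is one wild-type cell at the node nearest
  the coordinate centroid — an O(N) stand-in for "minimum total distance
  to all nodes" that coincides with it on the symmetric lattices used
  here. Arbitrary `{node: clone}` occupancies are accepted; clones named
  there without a driver tree default to the wild-type rate (neutral
  labels, used e.g. for Moran-process validation).
- Bottlenecks kill uniformly chosen cells at scheduled times so that
  round(fraction · N) survive; no spatial structure is imposed on the
  victims. The exponential clock is memoryless, so jumping the clock to
  the bottleneck time and redrawing is exact.
- `stop_when_monoclonal` ends a run once a single clone remains (after at
  least one division) — without it, a voter run at β = 0 would generate
  phantom events forever after fixation.

Every division retires the parent's label and mints two fresh labels;
labels are never reused. The event log records births (parent label,
daughter labels, nodes, clones, timestamp), deaths (with cause: rate
death, displacement, bottleneck) and driver acquisitions, and serialises
to TSV.

## Sampling and phylogeny reconstruction

A biopsy is either n cells uniformly without replacement or all cells in a
Euclidean ball. Reconstruction walks the birth records backwards from the
sampled labels, counting sampled descendants per ancestral label: labels
subtending two sampled lineages become internal nodes, single-lineage
ancestors are collapsed with their branch lengths accumulated (driver
events on collapsed chains are kept as edge annotations), and the root is
the *founding* event of the samples' least recent common ancestor, so the
stem edge down to the first coalescence is retained — this is what makes
the long initial branch of a late selective sweep visible in the output
tree. Leaves extend to the sampling time, so reconstructed trees are
ultrametric. Trees serialise to Newick with 15 significant digits, enough
to round-trip branch lengths to well below the 1e-9 validation tolerance;
a one-leaf sample serialises as `(label:length);`.

Balance statistics operate on the topology below the first bifurcation
(the retained stem is a unifurcation and is excluded, the standard
convention):

- **Sackin index**: sum of leaf depths in edge counts; the normalised
  variant divides by the analytic Yule expectation 2n Σ_{k=2..n} 1/k
  rather than by Monte-Carlo quantiles, for determinism. Calibration: the
  mean normalised index over 5000 simulated Yule trees with 100 leaves is
  1 within 1%.
- **Beta-splitting MLE**: Aldous' model assigns each internal split (a, b)
  probability ∝ Γ(β+a+1)Γ(β+b+1)/(Γ(a+1)Γ(b+1)), normalised per split
  size. The log-likelihood is maximised by bounded scalar search on
  β ∈ (−2, 10]; estimates at the search boundary are flagged. Splits may
  be pooled across an ensemble. Yule ensembles recover β ≈ 0; perfect
  caterpillars pin the lower bound.
- **Logistic fit** N(t) = K/(1+e^{−r(t−t0)}) by bounded least squares,
  with a degenerate-flat-trace short-circuit (r = 0). Used for the
  2D-vs-3D growth comparison.

## Molecular evolution

Sequences evolve from an ancestral genome (user FASTA or i.i.d. draws from
base frequencies ν) along the tree, root to leaves; a child's sequence is
produced from its parent's realised sequence, and a test replays each
branch's mutation records to confirm exact heritability.

- **Infinite sites**: per branch, exponential waiting times at rate
  L·μ_neut accumulate until the branch length is exceeded (equivalently
  Poisson counts, which the tests verify in mean and variance); each
  mutation takes a globally fresh site and a uniformly chosen different
  base. Requesting more than L mutations raises a saturation error. Indels
  are not combined with this mode.
- **Finite sites**: the whole-sequence Gillespie scheme uses the total
  rate R = Σ_k (μ_indel + Σ_{i≠s(k)} q_{s(k),i}). With indels disabled the
  implementation tracks per-base counts only (event choice O(1), site
  choice by rejection); with indels the sequence and rate are updated
  after every event, and a `validate` flag asserts at each step that the
  incremental rate equals a from-scratch recomputation to 1e-9. The six
  substitution models are parameterised canonically (see the API
  docstring); nesting identities (HKY85 κ=1 ≡ F81, TN93 with equal
  transition factors ≡ HKY85) are asserted entrywise.
- **Indels**: lengths follow the Lavalette law on 1..L_indel with exactly
  enumerated, cached weights; the insertion/deletion split defaults to
  50/50. Insertions place i.i.d. ν-distributed bases to the right of the
  chosen site; deletions truncate at the sequence end, and erasing the
  entire sequence aborts the branch with a diagnostic. The *joint* mode
  runs indels in the same Gillespie clock as substitutions (exact, slow);
  the *independent* mode (default) first places substitutions, then
  overlays a per-branch Poisson(L·μ_indel·t) indel process — the two agree
  in expectation at first order in the rate, which is tested. Mutation
  positions are recorded 1-based in the sequence frame at the event time;
  an alignment map back to ancestral coordinates is carried along (None
  inside inserted material) for downstream VCF-style comparison.
- **Mutational signatures**: the 96 channels follow the COSMIC layout
  (substitution-class-major, pyrimidine-strand folded; purine-centred
  trinucleotides are reverse-complemented). Channel rates are
  μ_avg · n_NKP · [(1−ξ)P⁰ + ξ Σ_i A_i(t)P^i] with P⁰ uniform and
  activities piecewise-constant in *absolute* simulation time (for trees
  without event times, cumulative branch lengths define the frame, which
  matches depth-normalised trees with activities over [0, 1]). The
  Gillespie clock truncates at activity change points and rebuilds the
  rates — exact by memorylessness. After each substitution the ±1-window
  trinucleotide contexts are updated incrementally. The first and last
  base of the sequence lack a full context and are never substituted under
  this engine (negligible for L ≫ 3); indel sites, by contrast, include
  the termini. Tests pin the ξ = 0 and ξ = 1 limits, the linearity in the
  activities, and the before/after spectrum split across a change point
  with swapped one-channel signatures.

## Read simulation

The built-in generator draws fragment start positions uniformly; paired
fragments have length round(Normal(mean, sd)) truncated to
[read length, genome length], with mate 2 reverse-complemented from the
fragment's 3' end. Each base is flipped to a uniformly chosen different
base with the configured error probability. Noisy and error-free SAM files
(written through pysam) carry the true 1-based positions, proper-pair
flags (99/147) and all-match CIGARs; quality strings are a constant Q30
symbol because the uniform error model has no positional structure —
realistic profiles are delegated to the ART wrapper, which builds the
`art_illumina` command from the same configuration (platform profile,
pairing, fragment model, seed, verbatim passthrough arguments) and reports
missing executables or failed runs with the full command line. Read counts
are per sample ("reads per cell"), with a mean-coverage alternative.

## Configuration, orchestration and reproducibility

One YAML file carries two sections, `general` (paths, per-artifact output
toggles, seed, log level) and `simulation` (graph, dynamics, sampling,
molecular, reads); a two-file variant is accepted. Validation is strict:
unknown keys anywhere are errors. All randomness flows from one root seed
through named per-stage substreams (SeedSequence spawn keys), so disabling
the read stage cannot perturb the dynamics stream; the manifest records
seed, config hash and versions, and re-running a configuration with the
same seed reproduces every artifact byte-for-byte (tested). The CLI
(`tumorspace simulate|sample|sequences|reads|all|fixtures`) is a thin
layer that toggles late stages off.

The fixture generator emits synthetic COSMIC-layout signature tables
(valid 96-row probability columns, optionally degenerate one-channel
signatures), a demo configuration, and a hand-built 7-event genealogy with
a documented expected Newick string — so no external downloads are needed
to exercise any code path. The synthetic signatures are Dirichlet draws,
not COSMIC entries; they are labelled `SBS_SYN*` accordingly.

## Validation scales and limitations

The statistical acceptance tests run at reduced but adequate problem
sizes, chosen so the whole suite completes in minutes on one core: OGA
exactness on a 3×3 lattice (5000 + 5000 replicates, birth 0.4 / death 0.01
over 5 time units), Moran fixation on a 20-node complete graph (5000
runs), JC69 divergence at L = 2000 over 500 branches, Lavalette
frequencies over 10⁵ draws, the phylogeny oracle over 100 random runs, and
the 2D-vs-3D growth comparison on 21² and 7³ lattices with 30 runs per
ensemble — the dimensional ordering of logistic steepness is
neighbourhood-driven and already unambiguous at this scale.

What the synthetic validation does *not* show: the generator emulates
idealised study conditions — memoryless division, spatially uniform death,
a single static graph, error-free labels. Real tumours add cell motility
and pushing, microenvironment heterogeneity, copy-number and structural
variation, and sequencing artefacts far richer than uniform base flips
(those are deliberately left to ART). Passing tests certify the simulator
against its own mathematical specification, not against biology. Known
limitations, by design: no polytomies beyond the root stem, no
site-rate heterogeneity (Γ), no codon models, no PCR-duplicate or
indel sequencing errors in the built-in read model, and ISA mode pairs
with substitutions only.
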