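# Methods

## The model

`altrin` treats coupled alternate conformations in crystallographic
multiconformer models as evidence of residue–residue interaction.  The
underlying assumption is that when two residues both populate alternate
conformations whose atoms are in van der Waals contact, the conformational
substates are not independent: the pair of residues exchanges steric,
H-bonding or electrostatic constraints, and collections of such pairs form
the pathways along which conformational heterogeneity — a proxy for
dynamics, and potentially for allosteric communication — propagates.

Nothing in the model distinguishes interaction types: the distance
criterion implicitly pools clashes, H-bonds, salt bridges and packing.
This is deliberate (simplicity, and coverage of favourable as well as
unfavourable couplings) and is also the model's main coarseness: a 3.9 Å
carbonyl–methyl contact and a 2.8 Å salt bridge contribute equally.

## Per-structure networks

**Atoms considered.**  Heavy atoms only; hydrogens are stripped at parse
time because deposition practice for riding hydrogens varies with
resolution and refinement program, and including them would make edge
weights depend on that practice rather than on structure.  Waters and
non-protein heteroatoms never contribute; residues other than the twenty
standard amino acids and selenomethionine are dropped with a warning.

**Altloc bookkeeping.**  Atoms with a blank altloc belong to every
conformer of their own residue (a residue whose side chain alone is split
still has a complete backbone per conformer).  Only atoms carrying a
non-blank altloc generate contacts: the method is about interactions
*between alternate conformations*, and blank-atom contacts would swamp the
signal in well-ordered structures.  Zero-occupancy conformers are retained
by default (`keep_zero_occupancy=False` drops them); edge weights are
occupancy-agnostic.

**Spatial rule.**  For residues A, B that are not sequence-adjacent, the
contact count *P* is the number of distinct
(atom-name_A, altloc_A, atom-name_B, altloc_B) combinations within the
cutoff (default 4.0 Å), and the weight is *P / (U_A + U_B)* with *U_X* the
number of unique atom names in residue X.  The size normalization stops
large residues from dominating purely by atom count; a geometric-mean
variant (√(U_A·U_B)) is available as `size_normalization`.  At least one of
the two residues must have ≥ `min_conformers` (default 2) conformers —
a flexible residue packing against a rigid one is still a coupling
candidate; `require_both=True` demands flexibility on both sides.

**Sequential rule.**  Backbone alternate conformations of consecutive
residues are mechanically coupled through the peptide bond regardless of
side-chain behaviour, so they are handled by a separate rule and excluded
from the spatial one.  The chain is scanned for maximal runs of
consecutive residues that each carry ≥ 2 backbone (N/CA/C/O) altlocs; a
run keeps extending while that condition holds, and each adjacent pair
inside a run receives an edge weighted by its backbone altloc contact
count, normalized by residue size as above.  Runs of length 1 produce no
edges.  This run-based treatment is the package's largest interpretive
choice in network construction; the run membership is recoverable from the
edge provenance labels.

**Determinism and the pre-filter.**  Edges are stored with the lower
residue key first.  The builder prunes residue pairs whose altloc-atom
bounding spheres are separated by more than the cutoff; this is exact, and
the test suite holds the builder to bit-level agreement with a naive
all-pairs oracle.

## Alignment and normalization

Residues are mapped to the columns of a structure-based MSA by pairing the
i-th non-gap character of a structure's row with its i-th residue; up to
2% sequence mismatch is tolerated (engineered mutants) and logged.
Columns are labelled with reference numbering — the 1-based ungapped
position of a designated reference row — and residues aligned to reference
gaps keep their column but have no analogous reference residue; they are
reported separately in every profile.

Each aligned network with total edge weight T > 1 is scaled by
ln(1+T)/T, so its total becomes ln(1+T).  Totals ≤ 1 are left unchanged
(the transform would amplify them).  The raw total and scale factor are
recorded per structure, making the normalization invertible and
auditable.  The logarithmic compression is what lets structures of very
different resolution (and hence altloc richness) coexist in one sum; the
base-e/+1 form is one reasonable realization of "log normalization by
total weight" and is the package's convention.

## Sums, Δdegree and the control

Sum networks add normalized weights edge-wise over a metadata-selected
subset.  Δdegree between two subsets is computed on *per-structure
averaged*, untrimmed subset sums — without the averaging, comparing
subsets of different sizes (e.g. 80 vs 57 structures) would conflate
subset size with signal.  The sign convention is first subset minus
second.  Because log-normalization couples the edges of a structure
through its total T, a subset-specific edge shifts the Δdegree of *other*
residues slightly; the synthetic-family tests assert only that the planted
residues dominate strictly, which is the scientifically meaningful
statement.

The random-half control partitions all structures into complementary
random halves (⌊n/2⌋/⌈n/2⌉, uniform, without replacement), computes
Δdegree per split and averages over 70 samples by default; a featureless
mean is the negative control against which subset contrasts are read.  All
sampling goes through one seeded NumPy generator, and identical member
networks give an exactly zero profile.

Before interpreting a subset contrast, `resolution_balance_test` runs a
one-tailed Mann–Whitney U on the two subsets' resolutions (better
resolution ⇒ more altlocs ⇒ heavier networks); the caller uses the p-value
to decide whether to restrict resolution ranges, which are exposed as
plain min/max metadata filters rather than any automatic adjustment.

Trimming keeps the ⌈f·n_edges⌉ highest-weight edges and retains every edge
tied with the threshold weight — determinism without arbitrary
tie-breaking — so the kept count can exceed the nominal one.  A trimmed
network remembers its fraction, and re-trimming at that fraction is a
no-op: trimming restricts the underlying sum once, it is not a repeatable
shrink.

## Communities and colocalization

Girvan–Newman division iteratively removes the edge with the highest
betweenness, treating edge weight as connection strength (path length
1/weight; an unweighted mode exists).  At each increase of the component
count the partition and weighted modularity are recorded; the chosen level
is the first whose modularity is within ε (default 0.005) of the running
maximum and whose successor gains less than ε — the "plateau".  Betweenness
ties are broken by canonical edge order.  On small graphs with clean
modular structure this coincides with exhaustive modularity maximization,
which the tests verify by full partition enumeration.

Colocalization asks whether a residue set of interest sits near the
network in 3D.  On a single representative structure, every residue gets
the count of network residues (self excluded) within 4 Å minimum
heavy-atom distance.  The counts of the set of interest are compared to
counts of size-matched random residue sets — drawn uniformly without
replacement from all counted residues, pooled over n_random draws — by a
two-sample KS test; pooling is the default, per-draw aggregation is
available.  The Jaccard ratio |network ∩ set| / |network ∪ set| reports
direct membership overlap.  Mutation-bin analysis bins curated mutations
by their residue's count (left-inclusive bins, last bin closed) and
reports the per-bin fraction that are functionally influential, with empty
bins undefined rather than zero.  Degree-vs-conservation uses OLS with the
modal-residue-fraction conservation score (gaps counted in the
denominator by default; a gap-excluded variant is available since either
convention appears in practice).

## The synthetic-data generator

Fixtures are built, not downloaded.  Residues sit on a coarse extended
template (consecutive 4.5 Å spacing — chosen so adjacent backbones fall
inside a 4 Å cutoff while residues two apart stay beyond cutoff + 2 Å);
planted spatial contacts are realized as altloc stub-atom pairs 2 Å apart
near contact points on a 12 Å ring around the chain axis, with the B
conformer displaced ~0.5–1 Å from A (the length scale of alternate
conformations in multiconformer models); planted backbone runs split all
four backbone atoms into A/B.  Every generated structure is validated by
brute-force distance enumeration — planted pairs within the cutoff,
everything else beyond it — before any test consumes it, and infeasible
recipes raise an error.  Families share a core sequence with per-structure
substitutions and an optional insertion (exercising alignment gaps), and
subset-A structures carry one extra planted contact, giving Δdegree a
known sign at known residues.

What the generator does *not* emulate: real protein geometry, occupancy
refinement, electron density, correlated noise between structures, or the
heavy-tailed edge-weight distributions of real multiconformer models.
Passing tests therefore demonstrate the correctness of the bookkeeping,
algebra and statistics — not that the biological conclusions drawn from
any particular real dataset are right.

## Problem sizes and numerical choices

The test suite and acceptance script use families of 8–10 structures of
20–30 residues, oracle fixtures up to 50 residues, 70 random-half samples,
2000 null draws for the KS calibration (against a 1000-residue universe
with 30-residue sets, keeping the sampling fraction small enough that
draws are nearly independent), and exhaustive community enumeration up to
8 nodes — sizes at which every independent oracle (all-pairs distance
enumeration, full partition search, exact U-statistic enumeration) is
itself cheap to run.  Tolerances: weight agreement to 1e-9; normalized
totals to 1e-9; Δdegree antisymmetry and identical-member controls exact
(same-order floating-point sums).  Degenerate inputs are defined, not
crashed: empty networks sum and trim to errors with named causes,
constant conservation yields a flagged R² = 0 fit, empty mutation bins are
undefined rather than zero.

## Known limitations

- Edge weights are contact counts, not energies; physics-based scoring is
  out of scope by design.
- The sequential-run treatment and the exact log-normalization form are
  conventions; alternative published realizations of the same ideas could
  differ in detail, so absolute weights are comparable only within one
  convention.
- Colocalization counts depend on the chosen representative structure.
- Community detection cost grows steeply with network size; the intended
  inputs are pruned sum networks (tens to low hundreds of edges).
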