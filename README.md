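# altrin

**Residue interaction networks from alternate conformations in related
crystallographic multiconformer models.**

High-resolution crystallographic electron density often supports more than
one conformation per residue.  Multiconformer models (e.g. from qFit)
encode this as PDB altloc groups with fractional occupancies.  When the
alternate conformations of *spatially or sequentially adjacent* residues
are coupled, they trace out the pathways by which conformational
heterogeneity — and potentially allosteric signalling — propagates through
a protein fold.  `altrin` turns collections of such models for a protein
family into quantitative, comparable networks:

1. **Per-structure network.**  Nodes are residues; an edge connects two
   residues whose alternate-conformation heavy atoms lie within a distance
   cutoff (default 4 Å).  The edge weight is the number of distinct altloc
   atom pairs in contact, *P*, normalized by residue size:
   *w = P / (U_A + U_B)*, with *U_X* the number of unique atom names in
   residue *X*.  Sequence-adjacent residues whose backbones are split into
   altlocs are coupled through a separate rule: maximal runs of consecutive
   backbone-altloc residues contribute per-peptide-bond edges weighted by
   their backbone altloc contact count, normalized the same way.
2. **Multinetwork.**  Per-structure networks are re-indexed onto the
   columns of a structure-based multiple sequence alignment, so analogous
   residues across homologs share a node, labelled with the numbering of a
   designated reference sequence.  Each network is then log-normalized —
   every edge scaled by ln(1+T)/T, where T is the network's total edge
   weight — so structures with many alternate conformations (typically the
   best-resolved ones) do not dominate.
3. **Comparison.**  Sum networks over metadata-defined structure subsets
   (conformational state, ligand class, protein identity); pruning to the
   top fraction of edges by weight; per-residue weighted degree
   (deg(v) = Σ incident weights) and the subset difference
   **Δdegree(r) = deg_A(r) − deg_B(r)** on per-structure-averaged sums;
   a random-half negative control; Girvan–Newman communities at the
   modularity plateau; colocalization of the network with external residue
   sets (KS test against size-matched random sets, Jaccard overlap);
   and weighted degree vs sequence conservation regression.

It is aimed at structural biologists studying how allosteric wiring is
conserved or rewired across a protein family with many deposited crystal
structures.

## Worked example

`altrin` ships a synthetic-fixture generator that plants a known network
(shared contacts, one backbone-coupled run, and one contact present only in
structure subset A), so the whole pipeline can be exercised without any
downloads:

```python
from altrin import FixtureSpec, generate_family, write_family

spec = FixtureSpec(seed=11, n_structures=10, n_residues=30,
                   planted_contacts=[(3, 17), (5, 22)],
                   backbone_runs=[(8, 10)], subset_contact=(6, 25),
                   noise_sigma=0.1)
write_family(generate_family(spec), "fixture")
```

```console
$ altrin multinet --structures-dir fixture/structures \
    --msa fixture/family.fasta --metadata fixture/metadata.csv \
    --reference-id syn000 --out mn.json
multinetwork with 10 structures -> mn.json
$ altrin delta mn.json --subset-a subset=A --subset-b subset=B --out delta.tsv
subset=A (5) vs subset=B (5); mean Δdegree 0.0127 -> delta.tsv
$ altrin control mn.json --samples 70 --seed 11 --out control.tsv
70 random halves -> control.tsv
$ head -5 delta.tsv
reference_residue	delta_degree
3	-0.0044494441
5	-0.0044494441
6	0.119450631
8	-0.0266966646
```

Residues 6 and 25 — the endpoints of the subset-A-only planted contact —
carry the largest positive Δdegree (+0.119); every other residue is an
order of magnitude closer to zero, and the random-half control profile is
flat.  The other subcommands (`build`, `sum`, `trim`, `communities`,
`coloc`, `degree-conservation`, `attribute`) cover the remaining analyses;
`altrin run config.yaml` drives the whole pipeline from one declarative
config.

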