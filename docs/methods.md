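# Methods

## Model

The predictor treats a catalytic site as a small region of space at which
several residues aim their functional side-chain atoms, embedded in a rigid
neighborhood, occupied by amino-acid types that habitually co-occur in
catalytic sites. It makes three assumptions worth stating explicitly:

1. **Orientation.** The displacement from a residue's Cα to one designated
   side-chain atom is a usable proxy for "where the side chain points".
   Only 12 amino-acid types get a vector atom (Arg CZ, Asn CG, Asp CG,
   Cys SG, Gln CD, Glu CD, His NE2, Lys NZ, Ser OG, Thr OG1, Trp CZ2,
   Tyr OH); the other 8 types are usually catalytic through backbone atoms
   and are excluded from orientation scoring but kept everywhere else.
   His, Trp and Thr need a nomenclature decision because "NE", "CZ" and
   "OG" are not standard PDB atom names for them; NE2 (the canonical His
   catalytic nitrogen), CZ2 and OG1 are the nearest standard atoms. The
   choice moves θ by a few degrees for those three types.
2. **Rigidity.** The weighted contact number w_k = Σ_{m≠k} 1/r²_km over
   Cα–Cα distances of *all* residues (not only vector-bearing ones) stands
   in for structural flexibility; crystallographic B-factors are
   deliberately not used (inconsistent across crystal forms, absent in NMR
   models).
3. **Composition.** A 20×20 row-normalized co-occurrence table p_x^y built
   from annotated catalytic sites captures which types appear together.
   Within a site, every unordered pair of distinct residue *instances*
   counts once in each direction, so duplicated types (His-His-Glu)
   preserve their composition signal.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| grid points per axis | 30 | – | fixed grid size; spacing adapts to protein size |
| grid spacing | extent/29, floored at 0.5 | Å | spans the Cα bounding box inclusively; the floor guards flat/degenerate boxes |
| surrounding radius | 10 | Å | Cα within this distance of a grid point (strict `<`) |
| mean-angle cutoff | 80 | deg | points with θ̄ strictly above are removed; ≈80% of catalytic residues satisfy θ ≤ 80° at their site center |
| min surrounding residues | 3 | – | a triplet needs three members |
| conservation weight | 1.6 | – | weight on z-scored PSSM information content in S′ |
| residue-count guard | 5000 | – | refuses pathological inputs; overridable |

All z-normalizations (WCN, combination score, conservation) use population
(divide-by-n) statistics. The normalization population for the combination
score is the multiset of every triplet-membership a-value generated for the
protein — the only population in which each a_j actually lives; it is
computed exactly in a first pass (closed forms below), never sampled.

## Fast accumulation

Per candidate point with surrounding set R (N = |R|, T = Σ z^w, and
q_j = Σ_{m∈R∖{j}} p_{x(j)}^{x(m)}, q2_j its squared-entry analogue):

- Σ over triplets containing j of (w_n + z^w_j) =
  (4/3)·C(N−1,2)·z^w_j + (N−2)/3·(T − z^w_j)
- Σ a_j = (N−2)·q_j and Σ a_j² = (N−3)·q2_j + q_j², giving the exact
  population mean/SD of the a multiset (each point contributes
  N·C(N−1,2) membership values).

These were re-derived and are continuously verified against an explicit
brute-force enumerator (|ΔS| < 1e-9 over 100+ random fixtures; observed
agreement ~1e-13).

## Numerical and degenerate-input choices

- Cosines are clamped to [−1, 1] before arccos; angles are double
  precision. A grid point coinciding exactly with a Cα has no defined angle
  and is dropped.
- Altloc resolution: highest occupancy, ties prefer altloc `A`, then first
  seen. First model only in multi-model files. MSE is kept as Met with no
  side-chain vector; other nonstandard residues are stripped.
- Zero-spread degeneracies: constant WCN raises (normalization undefined)
  unless raw values are requested; constant combination or conservation
  scores set the corresponding z to 0 with a warning.
- Ranking ties break by residue identity (chain, number, insertion code);
  residues in no triplet keep S = 0 and are listed after all scored
  residues. Inequalities ("< 10 Å", "θ̄ > 80°") are strict exactly as
  stated, so θ̄ = 80° survives.
- Grid anchoring is a genuinely open choice (only the grid size and the
  observed spacing range constrain it); this implementation anchors the
  origin at the Cα bounding-box minimum with no padding. Rank positions of
  individual residues in real structures can shift under a different
  anchor.
- The evaluation module averages per-protein curves vertically on a fixed
  101-point x grid (fixed-FPR for ROC, fixed-recall for recall–precision);
  the point at recall 0 carries the precision of the top-ranked prediction
  group. Proteins lacking a positive (or negative) label are excluded from
  averaging with a warning.

## Synthetic data

`orisite.fixtures` emits idealized PDB structures: a planted site of 3
classic catalytic types (His, Asp, Glu) with Cα on a 3.5 Å ring (≈6 Å
Cα–Cα, as in real catalytic triads) and side chains of 3.5 Å reach
displaced toward the ring center, among 24 decoys in a spherical shell
outside the site's interaction sphere (ring radius + 10 Å surrounding
radius, 10 Å thick). Decoys draw from all 20 amino-acid types — the ~40%
backbone-functional ones contribute packing mass but no orientation vector,
as in real chains — keep ≥ 6 Å Cα separation (non-bonded packing), and
point their side chains in random directions re-drawn whenever a tip would
land within 3 Å of another Cα (side chains cannot point into an occupied
neighbor). Positions carry 0.3 Å Gaussian jitter and directions ~0.1 rad of
angular noise. Atoms are ideal: Cα, the vector atom and dummy N/C/O for
format validity; no rotamers, no sequence connectivity, no solvent, no
crystallographic noise.

What passing on these fixtures shows: the geometry → candidate-point →
triplet-score → ranking chain is implemented correctly and recovers a
cleanly planted orientation signal against random backgrounds. What it does
not show: performance on real enzymes, where catalytic sites are lined by
many noncatalytic residues that legitimately score high, where the
co-occurrence profile should be built from curated site annotations rather
than the bundled synthetic table, and where chain selection and grid
anchoring matter. The bundled default profile
(`data/*.synthetic.tsv`) is a hand-curated list of classic catalytic-site
compositions — enough to exercise the scoring path and to encode broad
preferences (His/Asp/Glu/Ser/Lys-heavy), not a survey of any database;
supply your own annotation TSV for production use. Residual failures of the
planted-site recovery property (a few percent of seeds) are decoy chance
clusters that genuinely form inward-pointing pseudo-sites — the method is
designed to flag such geometry.

## Problem sizes

The test suite and `scripts/acceptance.py` run entirely on synthetic
structures of 27 residues (3 site + 24 decoys) over a full 27,000-point
grid, 100 replicates for the recovery rate, 100 random fixtures for oracle
equivalence, 20 seeds for the orientation contrast and a 25-structure
benchmark for the mean per-protein AUCROC; the whole acceptance run takes
well under a minute on one CPU. These sizes exercise every code path at
full grid resolution; they are not a statement about maximum supported
input (the pipeline accepts structures up to the 5000-residue guard).

## Known limitations

- One PSSM maps to one chain; other chains keep z^c = 0 in fused scoring.
  Mapping requires an exact or contiguous-offset sequence match.
- No probability calibration: S is a ranking score, comparable within one
  structure only.
- No clustering of top residues into discrete predicted sites; no
  solvent-accessibility or electrostatics features; no structure repair.
- The co-occurrence profile is global (not EC-class- or fold-specific) and
  unsmoothed beyond the zero-row rule.
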