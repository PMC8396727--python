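# Methods

This note documents the models, conventions and numerical choices behind
`topoclan`, in the order the pipeline uses them, together with what the
synthetic-data generator does and does not emulate.

## Topology model

A topology is an ordered, gap-free, 1-based segmentation of a chain into
inside/outside loops, TM helices, broken helices, reentrant helices and an
optional N-terminal signal peptide. The per-residue encoding is the
TOPCONS dialect (`i`, `o`, `M`) extended with `B`, `R`, `S`. Invariants
enforced on construction and parse:

- segments tile the chain contiguously;
- a TM or broken helix flips the loop side, a reentrant helix returns to
  its entry side, a signal peptide is side-neutral;
- helix runs must be flanked by loops and be at least **5 residues** long
  (parse error below that); TM runs shorter than 12 residues parse with a
  warning, since they are unlikely to span the bilayer;
- a broken helix is a *single* segment with an optional `break_pos`, not
  two half-helices — family labels count it as one unit. `break_pos`
  cannot be recovered from the one-letter encoding and is left unset on
  parse.

Family labels serialize as `<n>H[-<m>BH|-<m>RH]-N<in|out>` (e.g.
`10H-2BH-Nin`). The orientation subscripts used in print are flattened to
the plain-text forms `Nin`/`Nout`, which are the canonical forms
everywhere in this package. All helices — canonical and non-canonical —
count toward the helix total; membrane crossings exclude reentrant
helices. Chains mixing broken and reentrant helices are rejected: no known
family does this, and the downstream broken-vs-reentrant machinery is a
two-way choice.

## Preprocessing

Family sets are filtered before alignment: records with domain coverage
below 75% of the reference domain length are dropped (the "fragment"
category is treated as identical to this rule), then a linear scan drops
the later member of any pair above 90% identity. Both thresholds use the
strict inequalities of their printed forms, so exactly-75% coverage and
exactly-90% identity survive.

Pairwise identity is identical aligned positions over the shorter
ungapped length; for unaligned pairs the aligned positions come from a
unit-score global alignment (match 1, everything else 0). The exact
scores of blastclust/cd-hit are tool-internal and are not reproduced;
cd-hit's word-length heuristic only affects speed and is omitted.

Greedy clustering scans candidates by descending ungapped length (ties by
id), joining the first centroid at or above the threshold. Meff is the
cluster count at 62% identity on the MSA rows. Clustering is deterministic
given the input, and the cluster count is invariant to input order because
the scan order is canonical.

## Evolution-guided consensus

Predicted topologies are projected onto the seed MSA (topology characters
at residue columns, `-` at gaps) and rows are ordered by the tree's
left-to-right leaf order. Trees are consumed, never inferred.

Subfamily detection walks the tree from the root and accepts every
maximal clade in which at least **75%** of the members share one topology
label and which has at least **3** members; minority rows inside an
accepted clade, rows whose predictions do not parse, and rows in no
accepted clade are deviants. Both thresholds are configuration, not
biology: no numeric rule exists in the literature for what counts as
"systematic" topology variation, and the defaults are deliberately
permissive so that single-predictor errors do not split families. Without
a tree the split degrades to label equality (documented degraded mode).

The consensus ("initial") topology of a group is the per-column majority
state, computed on the columns where the group representative (member
with fewest gaps, ties by id) has residues; ties — and gap-majority
columns — resolve toward the representative. Runs shorter than **5**
residues are then merged into their flanking state (shortest first, ties
toward the preceding run); terminal loop runs are exempt, because short
tails are real. Finally all loop sides are re-propagated from the majority
N-terminal side, so the result is a valid topology by construction; an
unparseable result after repair raises a consensus failure carrying the
offending column ranges.

## Template refinement

Pairwise query-template alignments (with E-values) are inputs; the
profile-profile search that produces them is out of scope. A template
helix is *aligned* when ≥ 5 residues of both helices are aligned;
otherwise its class is the dominating query state over its columns (gap /
inside loop / outside loop / signal peptide), ties broken by the fixed
precedence gap > inside loop > outside loop > signal peptide (rarest
last).

The transporter type (broken vs reentrant) follows the template hit with
the lowest E-value; an exact tie defers to KR-bias arbitration. Template
helices opposite query loops are inserted at the aligned span, clipped to
the hosting loop with at least one loop residue kept on each side and a
minimum inserted length of 5; the insertion length target is the template
helix length. Downstream loop sides are always re-propagated from the
query's N-terminal side ("orientation follows the N-terminus"). The
operation is idempotent: re-classifying against the refined topology finds
nothing left to insert.

Subdomain transfer copies scaffold/core tags and repeat roles across the
aligned helix map; unaligned query helices inherit from the nearest
aligned neighbour (preferring the same repeat) and are flagged
extrapolated. Transfer is refused when fewer than half the template
helices are aligned (configurable). Repeat shuffling is reported when the
majority of aligned query helices inherit the role opposite to their
positional half of the chain; tags still follow the template.

## KR-bias (positive-inside) statistics

For each membrane-crossing helix two windows are counted — entry side and
exit side — each reaching min(10, helix length) residues into the helix
and up to 25 loop residues beyond it, truncated at the neighbouring
segment. A reentrant helix contributes a single window on its shared
entry/exit side covering both flanks. The 25-residue flank is always the
loop stretch *adjacent* to the helix (for tails of ≤ 25 residues, the
whole tail). Positions are counted once per side even when windows
overlap. The bias is the raw difference inside-K/R minus outside-K/R; a
ratio form was rejected because it is undefined when the outside count is
zero.

Model selection projects both candidate models' windows through the
representative row onto MSA columns, scores every row under both (rows
with > 50% gaps in the window columns are skipped), and picks the model
with the higher family-mean bias; means within **0.5** of each other are
ambiguous. Flipping every loop side of a topology exactly swaps the two
counts, which the tests assert as an antisymmetry property.

## Motifs and hydrophobicity

Core-helix motifs are position-frequency matrices over the MSA columns
spanned by the non-canonical core helix of one repeat, with a default
pseudocount of 0.5/20 per cell and information content
log2(20) − entropy per column; gaps are ignored in the counts.

The ΔG score is the *position-independent additive* form of the
biological (translocon) hydrophobicity scale, shipped as
`data/dg_scale.json`; lower is more insertion-favourable. The full
position-dependent DGpred polynomial with its length scan is deliberately
not reproduced: the score is used only comparatively (broken vs reentrant
vs TM helices), so relative order, not absolute value, is the tested
surface.

## Networks and visual reports

Family/repeat hits are deduplicated per unordered pair keeping the lowest
E-value, then thresholded: edges below E = 0.1, thick below E = 0.001,
weight log10 E stored raw (negative for significant hits; consumers may
negate for layout). Declared node lists keep isolated families visible.
The hit's repeat role is the repeat containing the majority of its
hit-side span, `full` on an exact tie.

Dotplots list one point per aligned residue pair, binned by
floor(log10 E); distance maps are Euclidean CA-CA distances (Biopython
PDB reader: first model, first altloc), clipped to 4-10 Å at render time
only. For mapped comparisons both readings of "distance between the
mutual distances" are provided — cross-chain aligned-pair distances and
the absolute difference of intra-chain distance matrices — without
claiming either reproduces any particular published panel.

## Synthetic-family generator

The generator emulates exactly the statistical structure the pipeline
assumes, and nothing more:

- **Blueprints** are two inverted repeat units, each "scaffold TMs + core
  (TM, non-canonical, TM)", with defaults TM 21, reentrant 12, broken 21,
  loops 15, tails 20 residues — typical magnitudes for this protein class.
- **Residues**: TM helices draw from a strongly hydrophobic pool;
  non-canonical cores mix Gly/Pro (enrichment fraction, default 0.5,
  Gly:Pro 3:1) with a moderately hydrophobic filler, making them less
  hydrophobic than TM helices by construction; broken helices carry a
  polar 3-residue discontinuity.
- **Positive-inside signal**: the loop pool itself is K/R-free; inside-loop
  sites are forced to K/R at a per-site rate chosen so the expected excess
  per inside loop equals `positive_inside_strength` (default 2). Strength
  0 therefore means exactly no signal — important because the bias
  statistic is a raw count difference and the inside/outside window areas
  of a blueprint need not balance. Real outside loops contain some K/R;
  only the *excess* matters to every statistic computed here.
- **Evolution**: balanced/caterpillar/star trees; per-branch per-site
  substitution resamples loop sites from the side-aware stationary pool
  (refreshing the positive-inside signal rather than freezing the root's
  draw) and helix sites within their residue class (preserving
  hydrophobicity); indels are loop-only with geometric length (mean 2), so
  helices stay alignable and the true alignment is known by construction
  from a global column registry.
- **Prediction errors** act on segments: a missed non-canonical helix
  becomes loop, a merge fuses two TM helices across their loop, a flip
  inverts orientation; sides are re-propagated so corrupted predictions
  are still parseable, as real predictor output is.
- **Per-column noise** (used in the consensus-robustness experiments) is
  the symmetric channel over the 6-letter topology alphabet.
- **Subfamily mixtures** share a root; one clade loses its leading
  N-terminal scaffold helices (the gain/loss mode actually observed
  between subfamilies) and its loop sides are re-anchored at its own
  N-terminal side, since in the real proteins the rest of the chain keeps
  its orientation when a scaffold helix is gained or lost.

What the generator does **not** emulate: realistic substitution matrices
or rate heterogeneity, alignment uncertainty (the true MSA is emitted),
structural coordinates beyond toy cases, compositional biases other than
the three signals above, and non-canonical helices on one repeat only.
Passing tests therefore demonstrate that the pipeline's logic recovers
planted signals of realistic strength — not that any particular real
family is annotated correctly.

## Problem sizes and determinism

The test suite and the acceptance script use families of 10-20 sequences
with ~440-residue chains, 100-trial recovery experiments, 50-seed mixture
splits, and 200-instance oracle comparisons; these sizes give stable
rates (binomial SE ≤ 5%) while keeping the whole suite in seconds. All
randomness flows through explicitly threaded numpy generators; a fixed
seed reproduces every output byte for byte.

## Known limitations

- Identity scores differ from blastclust/cd-hit internals; only the
  documented definition is guaranteed.
- Consensus repair anchors at the majority N-terminal side; a family
  whose predictions are mostly orientation-flipped will be repaired to
  the flipped orientation (KR-bias validation is the intended corrective).
- Missing-helix insertion assumes the hosting loop can accommodate at
  least 5 helix residues plus one loop residue per side; denser
  architectures raise an inference conflict rather than guessing.
- Partial-template transfer (a template covering one repeat only)
  interacts with orientation correction in ways the literature leaves
  unspecified; the transfer quality gate (≥ 50% template helices aligned)
  refuses rather than extrapolating across an unaligned repeat.
- The CLI's `prep` reads plain FASTA and treats each record as its domain
  span; richer domain-boundary formats are library-level inputs.
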