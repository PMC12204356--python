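# Methods

## Scope and data model

foldpool operates on CA-only single-chain models. Every score it computes
(GDT-TS, TM-score) is defined on alpha-carbon positions, so full-atom
geometry would add cost without changing any result. Models of one target
are assumed to share the target's residue numbering; residue number — not
sequence alignment — is the correspondence key, and models of different
lengths are intersected, never aligned. A shared residue number with two
different amino acids is a hard error, because it indicates the models do
not come from the same target sequence.

Per-residue plDDT (0–100) is read from the PDB B-factor column only behind
an explicit flag: the convention is common for AlphaFold output but not
universal, and silently misreading crystallographic B-factors as confidences
would corrupt every downstream ranking. Altloc'd CA atoms resolve to the
first occurrence; insertion codes are rejected (predictor output has none).

## Superposition and the similarity search

Rigid superposition is Kabsch's SVD solution with the reflection suppressed
by sign-correcting the smallest singular vector. The public `kabsch` rejects
collinear point sets (the rotation is not unique there), but the internal
superposition used by the score searches tolerates them: a rank-deficient
SVD still minimizes RMSD, and for distance counting any minimizer is as good
as any other. This matters in practice — 3-residue window seeds on extended
chains are nearly collinear.

GDT-TS's inner problem — for each cutoff d, the maximal number of
corresponding CA pairs a rigid superposition brings within d — is
combinatorial. The search has two regimes, controlled by
`ScoreParams.exhaustive_max_n` (default 10):

- **n ≤ 10**: every residue subset of size ≥ 3 seeds one superposition
  (batched SVD over gathered coordinates). At this scale enumeration is
  cheap (≤ 968 subsets) and the result is exact.
- **n > 10**: LGA-style heuristic. Seeds are every contiguous window of
  lengths 3/5/7 plus the all-residue set, fitted in one batched SVD via
  sliding-window cross-covariance sums. Each seed's within-cutoff residue
  set is refined to a fixed point (superimpose on the subset, re-select
  residues within the cutoff, repeat, ≤ 10 iterations), with a visited-set
  cache since refinement is deterministic. An iterative trimming walk
  (drop the worst-fitting residue, re-superimpose, down to 3) complements
  the grow-refinement. Every candidate count comes from a superposition
  fitted on some visited subset, so the heuristic is a lower bound of the
  enumeration optimum by construction. All four thresholds are scored at
  every visited superposition, which makes P₁ ≤ P₂ ≤ P₄ ≤ P₈ hold exactly
  rather than only usually.

TM-score uses the same seeding with score-driven refinement (residues within
max(d₀, 3.5 Å), widened in 0.5 Å steps if fewer than 3 qualify) and is
normalized by the target length, so a model missing residues is penalized.
d₀ = 1.24·(L−15)^⅓ − 1.8 floored at 0.5 Å; at L ≤ 15 the raw formula is
non-positive and the floor takes over.

The pool matrix symmetrizes by the maximum of the two directional scores.
For two models covering identical residue sets the directions coincide
analytically (the distance sets under the optimal fit are mirror images), so
the reverse computation is skipped there.

## Consensus, clustering and selection

PSSᵢ is the mean of row i of the similarity matrix excluding the diagonal.
K-means operates on rows of (1 − similarity): each model is embedded by its
dissimilarity profile, which needs no extra structural features and is
deterministic given the matrix and seed. When k is unspecified, k ∈
[2, min(10, n−1)] maximizing mean silhouette is chosen; a pool of
(near-)identical models degenerates to k = 1 with a warning. Cluster labels
are relabelled in order of first appearance so results are stable.

Score combination is a weighted mean of normalized columns (plDDT divided
by 100 first — otherwise any blend is dominated by the 0–100 scale).
Models missing a needed score drop out of that particular ranking only,
not globally: in a mixed pool an AF3 ranking score exists only for
AF3-generated models, and discarding everything else would be wrong.

The four selection strategies are implemented exactly as deterministic
procedures; all ties break by lexicographic model id, and each slot carries
a provenance string. The forced-AF3 rule replaces the last slot (or appends,
if fewer than five were selected) with the best AF3 model under the
strategy's own primary score — plDDT for `plddt_diverse`, GATE for
`gate_cluster` — and fires only when no AF3 model was otherwise selected.
The `multicom_ensemble` slot rota (GATE+plDDT blend, GATE, GCPNet-EMA with
EnQA fallback, PSS, back-filled from the blend) is a fixed convention of
this implementation; the underlying procedure it reflects allowed manual
adjustment, which is out of scope here. The diversity rule of
`plddt_diverse` is enforced against *all* already-selected models (the
stricter reading of pairwise diversity).

## Z-score protocol

Per domain: standardize all non-missing predictor scores (population 1/n
standard deviation — the assessors' convention), exclude scores with z < −2,
recompute mean/sd over the survivors once (no iteration), and re-score
everyone against the trimmed statistics, flagging the excluded. With
population sd the largest attainable |z| among n scores is √(n−1), so no
exclusion can fire for n ≤ 5. A zero-spread domain (sd ≤ 1e−12, which also
absorbs float noise on identical scores) sets every z to 0 with a warning;
a domain with fewer than two usable scores is skipped. The per-predictor
headline number is Σ max(z, 0) over domains; missing domains contribute 0,
which under positive-only summation is equivalent to any non-positive z.
Alternative-conformation pairs are collapsed to pseudo-domains by averaging
their z vectors before accumulation; exclusion flags are OR-combined. The
pair list is an explicit input — no assumption is made about how many pairs
a given evaluation has.

## Stitching

Regions are merged left-to-right: region 1 is fixed; each next region is
superimposed onto the growing model via the Kabsch fit of the shared
residues and its new residues appended. Overlap coordinates come from the
earlier side — averaging two versions of an overlap can create nonphysical
CA–CA distances — and the per-junction overlap RMSD is reported so that
disagreement between regions stays visible instead of being blended away.
The overlap fit uses the strict (degeneracy-rejecting) Kabsch: stitching
through a collinear overlap would silently pick an arbitrary rotation about
the overlap axis. The default minimum overlap of 10 residues is a
convention; exact reassembly of a cut-up structure works from 3.

## Synthetic generators

`make_reference` draws a helix-like random CA walk with exact 3.8 Å
consecutive spacing (a correlated direction walk; no side chains, no
secondary-structure realism — deliberately). `make_pool` builds clusters
around deformed copies of the reference: each non-correct cluster gets an
internal hinge rotation of the C-terminal half (6°/Å × `cluster_displacement`,
so the 10 Å default gives a 60° hinge) plus a rigid motion (4°/Å rotation,
`cluster_displacement` Å translation). The hinge is essential: purely rigid
cluster motions are invisible to superposition-based similarity. Per-model
iid Gaussian coordinate noise (default σ = 0.5 Å) sets the within-cluster
spread. Synthetic QA columns equal the model's true TM-score to the
reference plus Gaussian noise (`qa_noise`, default 0.05), clipped to [0, 1],
with plDDT scaled ×100 and AF3 ranking scores present only for AF3-tagged
models (tags alternate AF2/AF3 round-robin). `correct_cluster` selects which
cluster is the undeformed one, enabling the minority-correct regime (90/10
wrong/correct) in which consensus scoring provably prefers the majority.

What this emulates — and what it does not: the generators reproduce the
*pool structure* that selection strategies care about (clusters, a known
quality ordering, QA scores correlated with truth) but not real protein
geometry, real QA-method error structure, or real MSA phylogenetics
(homolog rows are iid point substitutions at 30%). Passing tests therefore
demonstrate the correctness and the qualitative failure modes of the
ranking/selection machinery, not predictive performance on real targets.

`make_msa` arranges full-length rows so the query-inclusive depth profile
hits per-region targets exactly (each row covers exactly one region), and
builds per-domain MSAs whose identifier sets overlap by a controlled
fraction — the lever for exercising paired vs gap-padded blocks in
domain-based MSA construction. `make_panel` draws per-domain Beta(8, 3)
difficulties with 0.05-sd predictor jitter and injects outliers verbatim.

## Domain-based MSA construction

Identifiers are matched on the first whitespace-delimited token of the
header — the least surprising rule when all that is known is "shared
sequence identifiers". The combined alignment has three blocks: the
full-length MSA verbatim, rows paired across ≥ 2 domain MSAs (each domain's
residues placed into its range, '-' elsewhere), and unpaired rows gap-padded
outside their single domain. Lowercase insertion columns from domain rows
are preserved; linkers between domains are match-column gaps. The query
appears exactly once, as row 0, with the full target sequence; an identifier
recurring across blocks is kept with a block-suffixed name, and no
deduplication is performed between the full-length and domain blocks.
One combined MSA is produced per (segmentation, full-length source) pair —
four segmentation strategies × two sources yields eight.

## Problem sizes and determinism

Defaults used by the test suite and acceptance script: consensus-failure
pool of 100 models of length 60 (90/10 split, QA noise 0.02 so scores track
truth); 50 selection-contract pools of 10 models of length 30; GDT
oracle-parity suite of 20 instances of 8 residues perturbed by σ = 1.0 Å
(decoy-scale deformation); 50 Z-protocol panels of 5 domains × 12
predictors; stitching cases of 2–3 regions with overlaps of 3 and 10.
Every generator is a pure function of its parameters and a seed; identical
inputs give byte-identical outputs, including selection rationale strings.

## Known limitations

- CA-only: no lDDT, CAD-score or any all-atom/local score.
- No sequence-independent structure alignment (TM-align-style search);
  models must share the target numbering.
- The heuristic GDT regime is a lower bound, not certified optimal, for
  chains longer than `exhaustive_max_n`.
- Single-chain stitching only; no clash relaxation or loop rebuilding at
  junctions.
- Learned QA scorers and MSA search tools are inputs, not components.
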