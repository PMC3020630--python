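# Methods

This note records the models, procedures, parameter choices and known
limitations behind `lhc_origins`. The package studies the extended
light-harvesting-complex (LHC) protein superfamily: proteins built
around a chlorophyll-binding (CB) motif embedded in a transmembrane
(TM) helix — one-helix HLIP/OHP proteins, two-helix stress-enhanced
proteins (SEPs), three-helix ELIP/RedCAP/LHC proteins, the four-helix
PSBS, and the ferrochelatase II / Rieske-like CAB fusion proteins. The
central scientific question is whether LHC and PSBS descend from one
four-helix ancestor or from two independent internal gene duplications
of two-helix (SEP-like) ancestors.

## Motifs and transmembrane architecture

The CB motif is modelled as an anchor glutamate (E at offset 0) with
H/N expected at +3 and R at +5; weakly conserved T+21, G+22 and Q+28
mark the C-terminal context in several families. By default one
mismatch is tolerated over the +3/+5 offsets (the anchor E never
mismatches) because the motif degenerates in fusion proteins. The
carotenoid-binding motif is FDPLGL (one mismatch allowed outside the
FDP core, or the exact core alone) starting 10–20 residues upstream of
a CB anchor; the window is centred on the canonical ~15-residue
spacing, measured anchor-to-motif-start.

TM helices are predicted from Kyte–Doolittle hydropathy with a
19-residue window: maximal runs of window centres with mean hydropathy
at or above 1.0 are expanded by half a window per side, merged, and
kept if at least 17 residues long. The threshold of 1.0 was fixed once
against the synthetic templates so that designed helices are detected
with sensitivity well above 0.95 while random hydrophilic linkers stay
clearly below it; it is exposed as configuration. The predictor is
deliberately simple — downstream logic uses only the count and order of
helices, not their precise boundaries.

Because the CB helix is membrane-embedded by crystallographic evidence,
an exact CB match outside every predicted helix forces a 17-residue
helix centred on it (merged with neighbours on overlap). Degenerate
(one-mismatch) matches do not force helices, and a degenerate match
that ends up outside every helix is dropped from the architecture: an
isolated partial motif with no membrane context is treated as noise.
This keeps the invariant that every retained CB anchor lies inside a
helix.

## Profile HMMs

Each of the 18 family profiles is built from a seed alignment of
exactly 54 columns centred on the first CB motif (anchor at column 25,
i.e. window −25…+28). Match emissions are observed counts plus
background-weighted Dirichlet pseudocounts of total weight 20 (Laplace
available as a fallback); transitions are counted from the seed's gap
structure with add-one smoothing, so heavily gapped columns route
probability through delete chains rather than shrinking the profile.

Scoring is local forward log-odds in bits against the background
(Dayhoff stationary frequencies). Entry and exit probabilities follow
the uniform-fragment parameterization: absent informative transitions,
every (start, end) fragment of the profile is a priori equally likely,
and flanking query residues cancel against the null. Delete chains are
folded into an effective match-to-match transfer matrix, making the
recursion a dense linear map per emitted residue; this enables scoring
one query against the whole stacked database in a single pass, and
batches of equal-length random sequences during calibration. Unknown
residues ('X') are marginalized out of the query before scoring, which
makes scores exactly invariant to X padding.

Calibration fits a Gumbel (type-I extreme value) law to forward scores
of i.i.d. background sequences (default length 160, 2000 draws in the
bundled database; more can be requested) and reports p-values from its
survival function, never from asymptotic theory.

## Family classification

Evidence per record: profile-HMM top hits, helix architecture, motif
hits, genome compartment/lineage metadata, and a full-length similarity
score. The rule ladder, in order: (1) fusion proteins (FCII,
Rieske-like CAB) when full-length similarity to labelled references
dominates — their CB motif can be absent, so similarity outranks helix
counting; (2) one helix: HLIP if plastid-encoded or
cyanobacterial/phage, else OHP1 or OHP2 by a significant top hit, else
OHP1-like; (3) two helices with the CB motif in the first: SEP, with
SEP1–5 subgroup from the best significant subfamily profile, SEPx
otherwise; (4) three helices: ELIP / RedCAP / LHC by the best
significant admissible hit (RedCAP additionally requires red or
complex-red lineage); (5) four helices: PSBS on a significant hit,
PSBS-like on a weak one; (6) otherwise unclassified. Every fired rule
is appended to an auditable rationale.

Significance defaults are alpha = 1e-3 for a confident hit and
beta = 0.05 for the weak PSBS-like call. Full-length similarity is a
4-mer containment score (fraction of the query's 4-mers present in the
reference), a deliberately simple stand-in for full-length BLASTP whose
only role downstream is ranking; its fusion gate defaults to 0.35,
which sits far above the cross-family containment of unrelated
sequences (about 0.01) and comfortably below within-family containment
at the fixture divergence (about 0.42–0.63). The classified set grows
monotonically with alpha; a stricter threshold never classifies a
record a laxer one rejected.

## Substitution models and likelihoods

Dayhoff and WAG are general time-reversible matrices Q_ij = s_ij π_j
built from the published exchangeability tables, scaled to one expected
substitution per site at stationarity. Rate heterogeneity uses
equal-probability discrete-gamma categories represented by conditional
means (k = 4, shape alpha defaulting to 1.0; a one-dimensional ML
estimator for alpha is provided). Transition matrices come from the
symmetric eigendecomposition, so detailed balance and
Chapman–Kolmogorov hold to near machine precision.

Pairwise ML distances maximize the gamma-mixture likelihood of the
count matrix by bounded Brent search (floor 1e-8, ceiling 20 expected
substitutions per site, tolerance 1e-6). Tree likelihoods use
Felsenstein pruning with per-site scaling; 'X' and '-' are marginalized
per column, never dropped sequence-wide. Branch lengths are optimized
coordinate-wise (bounded Brent per edge, sweeps until the
log-likelihood gain falls below 1e-4, capped at 50); per-edge transition
matrices are cached so single-branch updates only recompute what
changed. The log-likelihood never decreases across sweeps.

## Four-cluster likelihood mapping

Helix blocks are the 32 gapless residues E−25…E+6 around each CB
anchor, covering the TM helix; helix I is the first anchor of a
protein, helix III the last. Blocks from LHC and PSBS proteins form
four clusters (LHC_I, LHC_III, PSBS_I, PSBS_III). For each quartet —
one block drawn uniformly with replacement per cluster — the three
resolved 4-taxon topologies are scored by ML:

* T1 (LHC_I,LHC_III)|(PSBS_I,PSBS_III): within-protein pairing,
  expected under independent duplications;
* T2 (LHC_I,PSBS_I)|(LHC_III,PSBS_III): cross-protein pairing,
  expected under a common four-helix ancestor;
* T3: the hybrid pairing, predicted by neither hypothesis.

All five branch lengths restart from 0.1 and get two coordinate sweeps
at tolerance 1e-4 — a speed/accuracy trade-off validated against a 5-D
grid-search oracle (agreement within 0.1 nats on random 8-column
quartets). Likelihood weights w_i = exp(L_i − logsumexp L) are
barycentric coordinates on the 2-simplex. The 3-region summary is the
argmax basin (ties to the lexicographically first topology, recorded);
the 7-region summary assigns each point to the nearest of seven
attractors (three corners, three edge midpoints, the centroid) in
Euclidean distance. The published tool's exact 7-region boundaries are
not printed anywhere we could find, so an alternative threshold rule
(corner iff max weight ≥ 2/3 and runner-up ≤ 1/6) is provided behind a
switch; the qualitative layout is the same. An optional mask drops the
three functional-site columns (anchor, +3, +5) to mirror the control in
which conserved functional sites are excluded.

## Topology tests and trees

The Shimodaira–Hasegawa test and expected likelihood weights operate on
a topologies-by-sites matrix of per-site log-likelihoods via RELL
(resampling estimated log-likelihoods, with replacement at original
length): SH centres replicate totals per topology and compares the
max-minus-self statistic with the observed deltas, so the ML topology
has p = 1 by construction; ELW averages the replicate softmax weights,
which sum to one.

Neighbor joining is the Saitou–Nei agglomeration on ML distances;
negative branch-length estimates are clamped to zero with the deficit
moved to the sister branch, and Q-criterion ties break on the
lexicographically smallest label pair so the result is independent of
input order (the topology is cross-checked against an independent NJ
implementation in the test suite). Bootstrap support resamples columns
with replacement, recomputes distances and the NJ tree, and annotates
each full-data bipartition with its replicate frequency. The consensus
is strict-majority (frequency > 0.5 by default; 50/50 conflicts are
excluded).

## Character evolution

Family presence/absence over the fifteen study taxa evolves under
unordered parsimony (gain and loss both cost 1) on a rooted species
tree. The implementation is a Sankoff-style dynamic program computing,
for every node, the exact set of states attained across *all*
most-parsimonious reconstructions (verified against exhaustive
enumeration on small trees); a node is "ambiguous" when that set is
{0,1}, and ambiguity is reported rather than silently resolved. The
origin of a family is the most ancestral node whose state set is
exactly {present}; loss counts come from one optimal labelling with
ties resolved toward the parent state.

The bundled species tree and character matrix are synthetic stand-ins
assembled from published statements about the fifteen organisms (three
cyanobacteria with Gloeobacter rooting the tree, glaucophytes as the
deepest Plantae branch, diatoms nested with red algae; SEP present in
all eukaryotes except *Cyanidioschyzon*; ELIP/PSBS/OHP1 restricted to
the green lineage; RedCAP to the red lineage; LHC in red plus green but
not glaucophytes). Where relationships are not stated the tree uses a
reasonable fully-bifurcating resolution; origin nodes are insensitive
to those choices because the characters vary only across the named
lineage-level splits.

## Synthetic data: what it emulates, and what it does not

Templates generate idealized family members: TM helices of 27 residues
drawn from a membrane-biased composition (enriched L/I/V/F/A/M/W),
hydrophilic linkers (background frequencies with hydrophobics
down-weighted), an exact CB motif per designated helix (anchor 20
residues into the helix), extended T/G/Q sites for the families that
carry them, and FDPLGL 15 residues upstream of the anchor for the LHC
subfamilies. Each template owns a fixed base seed, so family consensus
sequences are reproducible; all generators are pure functions of
(configuration, seed).

Evolution is a site-independent CTMC under Dayhoff or WAG with
per-site gamma categories drawn once at the root. The three CB
functional sites are held invariant — emulating the strong purifying
selection that, in real data, leaves these columns phylogenetically
uninformative. No indels are simulated: the analyzed blocks are
essentially gapless in real alignments, and keeping coordinates fixed
lets truth tables carry exact anchor positions.

Internal gene duplication copies the two-helix unit (helix 1 through
the linker after helix 2) in place, so helix I and the new helix III
are identical at creation. Scenario defaults: pre-duplication
divergence 0.8 and post-duplication clade depth 0.5 expected
substitutions per site — deep enough that clusters are nontrivial,
shallow enough that 32-column quartets resolve; clade sizes 41 LHC and
19 PSBS proteins follow the real dataset's composition. Under
"independent", two SEP lineages diverge and each duplicates at its
clade root; under "common", one SEP duplicates and the four-helix
ancestor runs down a 0.8-long stem before the LHC/PSBS split. The two
scenarios are symmetric in total depth, differing only in the order of
duplication and speciation.

Passing tests on these data show that the pipeline recovers the
topology signal its inputs contain; they do not show robustness to
alignment error, indels, compositional heterogeneity, rate variation
across lineages, or the long-branch effects present in the real
sequences.

## Problem sizes and numerical choices

The bundled analyses use 500 quartets per scenario, 500 classifier
records, 2000 calibration sequences per profile, and 10,000 RELL
replicates — sizes chosen so each driver completes in minutes on one
core while keeping Monte-Carlo error far below the effect sizes
involved (T1 support under the independent scenario is near 100%,
against a 50% majority criterion). Branch lengths live in
[1e-8, 20]; emission/transition rows are validated to sum to 1; the
simplex weights are computed via logsumexp and validated to 1e-12.

## Known limitations

* The profile database, seeds and reference set are synthetic; real
  seed alignments can be dropped in as aligned FASTA but none are
  bundled, so per-accession reproduction of the published
  classification tables is out of scope.
* The hydropathy predictor ignores topology (inside/outside) and
  signal peptides; records with unusual N-terminal extensions may gain
  or lose a helix.
* Quartet branch-length optimization uses two coordinate sweeps; on
  pathological quartets the ML value can sit slightly below the global
  optimum (bounded by the grid-oracle check).
* The 7-region partition is a reconstruction of the published
  diagram's geometry, not a byte-identical reimplementation of the
  original tool.
* Profile calibration uses a composition-unmatched background null, so
  any one-helix CB protein shares enough TM composition and motif with
  the OHP1 profile to reach nominal significance occasionally; in the
  fixture set about half of the deliberately dissimilar "OHP1-like"
  records are pulled into OHP1 for this reason. Family-level recovery
  stays at ~97%.
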