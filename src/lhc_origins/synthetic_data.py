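"""Synthetic sequence-evolution generator for the LHC superfamily.

Generates every test input the pipeline needs: family-labeled protein
fixtures for the classifier and profile database, and duplication-
scenario datasets for quartet mapping.

Family templates describe idealized member proteins: hydrophobic TM
helices (drawn from a membrane-biased residue distribution) separated by
hydrophilic linkers, with an exact chlorophyll-binding motif embedded in
the designated helices and, where the family has one, a carotenoid-
binding motif ~15 residues upstream.  Each template owns a fixed base
seed so the family consensus is reproducible; evolution along trees is a
site-independent CTMC under the package's substitution models with
per-site gamma rates drawn once at the root.  The three functional CB
sites (anchor, +3, +5) are held invariant during evolution, emulating
the strong purifying selection on chlorophyll ligation.

Two duplication scenarios feed the quartet-mapping analysis:

* ``independent`` — two SEP-like lineages diverge, then each undergoes
  its own internal gene duplication and radiates into the "LHC" and
  "PSBS" clades (within-protein helices I/III are the youngest pair);
* ``common`` — one SEP duplicates once and the resulting four-helix
  ancestor later splits into the two clades (like-numbered helices of
  the two families are the youngest pair).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .evolve_models import AA_INDEX, AA_ORDER, RateModel
from .profile_hmm import SeedAlignment
from .quartet_mapping import ClusterSet, build_clusters, extract_blocks
from .seqio import Alignment, SeqRecord

#: membrane-biased residue distribution for TM helices
TM_RESIDUES = "LIVFAMWGST"
TM_WEIGHTS = (0.22, 0.15, 0.15, 0.12, 0.12, 0.06, 0.04, 0.05, 0.04, 0.05)

#: CB motif stamped into designated helices: anchor E, H at +3, R at +5
CB_CORE = {0: "E", 3: "H", 5: "R"}
#: weakly conserved extended positions shared by several families
CB_EXTENDED = {21: "T", 22: "G", 28: "Q"}
CAROTENOID_MOTIF = "FDPLGL"
CAROTENOID_UPSTREAM = 15  # anchor minus motif start

HELIX_LEN = 32
#: anchor offset from helix start; the helix covers anchor-25 .. anchor+6,
#: i.e. exactly the 32-column block window used by quartet mapping — so an
#: internal duplication of the helix unit copies whole blocks verbatim
ANCHOR_IN_HELIX = 25


@dataclass(frozen=True)
class FamilyTemplate:
    """Layout and metadata of one synthetic protein family."""

    family: str
    n_helices: int
    cb_helices: tuple
    lineage: str = "green"
    compartment: str = "nuclear"
    carotenoid: bool = False
    extended_sites: bool = False
    nterm: int = 30
    linker: int = 30
    cterm: int = 35
    base_seed: int = 0

    def helix_intervals(self) -> list[tuple[int, int]]:
        out = []
        pos = self.nterm
        for _ in range(self.n_helices):
            out.append((pos, pos + HELIX_LEN))
            pos += HELIX_LEN + self.linker
        return out

    def length(self) -> int:
        return (self.nterm + self.n_helices * HELIX_LEN
                + (self.n_helices - 1) * self.linker + self.cterm)


def default_templates() -> list[FamilyTemplate]:
    """The bundled family templates (one per profile plus extras)."""
    spec = [
        # family, n_helices, cb_helices, lineage, compartment, caro, ext
        ("HLIP", 1, (0,), "cyanobacteria", "plastid", False, False),
        ("OHP1", 1, (0,), "green", "nuclear", False, False),
        ("OHP2", 1, (0,), "green", "nuclear", False, True),
        ("SEP1", 2, (0,), "green", "nuclear", False, True),
        ("SEP2", 2, (0,), "green", "nuclear", False, True),
        ("SEP3", 2, (0,), "green", "nuclear", False, True),
        ("SEP4", 2, (0,), "green", "nuclear", False, True),
        ("SEP5", 2, (0,), "green", "nuclear", False, True),
        ("SEPx", 2, (0,), "glaucophyte", "nuclear", False, True),
        ("ELIP", 3, (0, 2), "green", "nuclear", False, True),
        ("RedCAP", 3, (0, 2), "red", "nuclear", False, False),
        ("CAB", 3, (0, 2), "green", "nuclear", True, False),
        ("FCP", 3, (0, 2), "complex_red", "nuclear", True, False),
        ("LI818", 3, (0, 2), "green", "nuclear", True, False),
        ("LHCz", 3, (0, 2), "complex_red", "nuclear", True, False),
        ("RED_LHC", 3, (0, 2), "red", "nuclear", True, False),
        ("PSBS", 4, (0, 2), "green", "nuclear", False, True),
        ("FCII", 1, (0,), "green", "nuclear", False, False),
        ("RIESKE_CAB", 3, (0,), "cyanobacteria", "plastid", False, False),
    ]
    out = []
    for i, (fam, n, cb, lin, comp, caro, ext) in enumerate(spec):
        kwargs = {}
        if fam == "FCII":
            kwargs["cterm"] = 180  # enzyme domain tail of the fusion protein
        out.append(FamilyTemplate(fam, n, cb, lin, comp, caro, ext,
                                  base_seed=1000 + i, **kwargs))
    return out


#: profile database membership: 18 families (no OHP1-like, no Rieske —
#: the former is defined by absence of similarity, the latter is
#: classified by full-length similarity)
PROFILE_FAMILIES = ("HLIP", "OHP1", "OHP2", "SEP1", "SEP2", "SEP3", "SEP4",
                    "SEP5", "SEPx", "ELIP", "RedCAP", "CAB", "FCP", "LI818",
                    "LHCz", "RED_LHC", "PSBS", "FCII")

#: expected classifier call per template family (family, subgroup)
TRUE_LABELS = {
    "HLIP": ("HLIP", None), "OHP1": ("OHP1", None),
    "OHP1_LIKE": ("OHP1_LIKE", None), "OHP2": ("OHP2", None),
    "SEP1": ("SEP", "SEP1"), "SEP2": ("SEP", "SEP2"),
    "SEP3": ("SEP", "SEP3"), "SEP4": ("SEP", "SEP4"),
    "SEP5": ("SEP", "SEP5"), "SEPx": ("SEP", "SEPx"),
    "ELIP": ("ELIP", None), "RedCAP": ("RedCAP", None),
    "CAB": ("LHC", "CAB"), "FCP": ("LHC", "FCP"),
    "LI818": ("LHC", "LI818"), "LHCz": ("LHC", "LHCz"),
    "RED_LHC": ("LHC", "RED_LHC"), "PSBS": ("PSBS", None),
    "FCII": ("FCII", None), "RIESKE_CAB": ("RIESKE_CAB", None),
}


def _draw(rng: np.random.Generator, letters: str, weights, n: int) -> list:
    idx = rng.choice(len(letters), size=n, p=np.asarray(weights))
    return [letters[i] for i in idx]


def _linker_distribution(model: RateModel) -> tuple[str, np.ndarray]:
    """Background frequencies with hydrophobics down-weighted.

    Inter-helix loops and tails are predominantly polar; halving the
    hydrophobic mass keeps linkers clearly below the hydropathy
    threshold without hard-coding the predictor's outcome.
    """
    from .motif_structure import KYTE_DOOLITTLE

    freqs = model.freqs.copy()
    for i, aa in enumerate(AA_ORDER):
        if KYTE_DOOLITTLE[aa] > 1.0:
            freqs[i] *= 0.4
    freqs /= freqs.sum()
    return AA_ORDER, freqs


def make_ancestor(template: FamilyTemplate,
                  seed: int | np.random.Generator | None = None,
                  model: RateModel | None = None):
    """Draw one ancestor sequence from a template.

    Returns ``(record, truth)`` where truth holds the helix intervals and
    CB anchor positions.  Deterministic under the seed (defaults to the
    template's base seed).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(template.base_seed if seed is None else seed))
    model = model or RateModel("dayhoff")
    helices = template.helix_intervals()
    length = template.length()
    bg_letters, bg_freqs = _linker_distribution(model)
    seq = _draw(rng, bg_letters, bg_freqs, length)
    for (s, e) in helices:
        seq[s:e] = _draw(rng, TM_RESIDUES, TM_WEIGHTS, e - s)
    anchors = []
    for hi in template.cb_helices:
        s, e = helices[hi]
        anchor = s + ANCHOR_IN_HELIX
        for off, aa in CB_CORE.items():
            if anchor + off >= length:
                raise ValueError("layout cannot host the CB offsets")
            seq[anchor + off] = aa
        if template.extended_sites:
            for off, aa in CB_EXTENDED.items():
                if anchor + off < length:
                    seq[anchor + off] = aa
        if template.carotenoid:
            start = anchor - CAROTENOID_UPSTREAM
            if start < 0:
                raise ValueError("layout cannot host the carotenoid motif")
            seq[start:start + len(CAROTENOID_MOTIF)] = CAROTENOID_MOTIF
        anchors.append(anchor)
    record = SeqRecord(
        id=f"{template.family}_anc", residues="".join(seq),
        organism="synthetic", lineage=template.lineage,
        compartment=template.compartment,
    )
    truth = {"id": record.id, "family": template.family,
             "helices": list(helices), "anchors": anchors}
    return record, truth


def functional_sites(anchors: list) -> list:
    """Positions held invariant during evolution (CB anchor, +3, +5)."""
    return sorted({a + off for a in anchors for off in CB_CORE})


def internal_duplicate(record: SeqRecord, truth: dict):
    """Duplicate the two-helix unit in place.

    The segment from the start of helix 1 through the end of the linker
    after helix 2 is copied immediately after itself, so helix I and the
    new helix III are identical at creation.  Returns updated
    ``(record, truth)``; truth gains a paralogy map.
    """
    helices = [tuple(h) for h in truth["helices"]]
    if len(helices) < 2:
        raise ValueError("internal duplication needs at least two helices")
    gap = helices[1][0] - helices[0][1]
    seg_start = helices[0][0]
    seg_end = helices[1][1] + gap
    seq = record.residues
    if seg_end > len(seq):
        raise ValueError("sequence too short to duplicate through the linker")
    shift = seg_end - seg_start
    new_seq = seq[:seg_end] + seq[seg_start:seg_end] + seq[seg_end:]
    new_helices = sorted(helices + [(s + shift, e + shift) for s, e in helices[:2]])
    new_anchors = sorted(truth["anchors"]
                         + [a + shift for a in truth["anchors"]
                            if seg_start <= a < seg_end])
    new_truth = dict(truth)
    new_truth.update({
        "helices": new_helices,
        "anchors": new_anchors,
        "paralogy": {0: 2, 1: 3},  # helix I -> helix III, II -> IV
    })
    return replace(record, residues=new_seq), new_truth


# ---------------------------------------------------------------------------
# sequence evolution along trees
# ---------------------------------------------------------------------------

def _evolve_states(states: np.ndarray, t: float, model: RateModel,
                   cat_of_site: np.ndarray, rng: np.random.Generator,
                   fixed: np.ndarray) -> np.ndarray:
    out = states.copy()
    for c, rate in enumerate(model.site_rates.rates):
        sites = np.where((cat_of_site == c) & ~fixed)[0]
        if sites.size == 0:
            continue
        p = model.transition_matrix(t, rate)
        cdf = np.cumsum(p[states[sites]], axis=1)
        u = rng.random(sites.size)
        out[sites] = np.minimum((u[:, None] > cdf).sum(axis=1), 19)
    return out


def evolve(record: SeqRecord, tree: dendropy.Tree, model: RateModel,
           seed: int | np.random.Generator,
           fixed_sites: list | None = None) -> list[SeqRecord]:
    """Simulate the record down the tree; returns one record per tip.

    Site-independent CTMC with per-site gamma categories drawn once at
    the root; *fixed_sites* positions never change (invariant functional
    sites).  Deterministic under the seed.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    root_states = np.array([AA_INDEX[c] for c in record.residues],
                           dtype=np.int64)
    n = root_states.size
    cat_of_site = rng.integers(0, model.k, size=n)
    fixed = np.zeros(n, dtype=bool)
    if fixed_sites:
        fixed[np.asarray(fixed_sites, dtype=int)] = True
    node_states = {id(tree.seed_node): root_states}
    tips = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_states = node_states[id(node.parent_node)]
        t = node.edge.length or 0.0
        st = (_evolve_states(parent_states, t, model, cat_of_site, rng, fixed)
              if t > 0 else parent_states.copy())
        node_states[id(node)] = st
        if node.is_leaf():
            residues = "".join(AA_ORDER[i] for i in st)
            tips.append(replace(record, id=node.taxon.label,
                                residues=residues))
    return tips


def random_ultrametric_tree(labels: list, depth: float,
                            rng: np.random.Generator) -> dendropy.Tree:
    """Random coalescent-style topology with all tips at the given depth."""
    taxa = dendropy.TaxonNamespace(list(labels))
    lineages = [(dendropy.Node(taxon=taxa.get_taxon(l)), 0.0) for l in labels]
    n = len(lineages)
    if n == 1:
        node, _ = lineages[0]
        node.edge.length = depth
        root = dendropy.Node()
        root.add_child(node)
        tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
        tree.is_rooted = True
        return tree
    heights = np.sort(rng.uniform(0, depth, size=max(n - 2, 0)))
    heights = np.append(heights, depth)
    for h in heights:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        (na, ha), (nb, hb) = lineages[i], lineages[j]
        parent = dendropy.Node()
        for child, ch in ((na, ha), (nb, hb)):
            parent.add_child(child)
            child.edge.length = max(h - ch, 0.0)
        lineages = [l for k, l in enumerate(lineages) if k not in (i, j)]
        lineages.append((parent, h))
    root = lineages[0][0]
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# duplication scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one duplication scenario.

    Times are expected substitutions per site.  The clade sizes follow
    the real dataset's composition (41 LHC and 19 PSBS proteins, each
    contributing helices I and III).
    """

    scenario: str  # independent | common
    seed: int
    pre_dup: float = 0.8
    clade_depth: float = 0.5
    n_lhc: int = 41
    n_psbs: int = 19
    model_name: str = "dayhoff"
    alpha: float = 1.0
    k: int = 4

    def __post_init__(self) -> None:
        if self.scenario not in ("independent", "common"):
            raise ValueError("scenario must be 'independent' or 'common'")
        if self.pre_dup < 0 or self.clade_depth < 0:
            raise ValueError("divergence times must be non-negative")


@dataclass
class SimulationResult:
    records: list
    anchors: pd.DataFrame  # id, anchor_I, anchor_III, family
    clusters: ClusterSet
    truth: pd.DataFrame


def _two_branch(rec, truth, t, model, rng, tags):
    """Evolve one ancestor along two independent branches of length t."""
    taxa = dendropy.TaxonNamespace(list(tags))
    root = dendropy.Node()
    for tag in tags:
        child = dendropy.Node(taxon=taxa.get_taxon(tag))
        root.add_child(child)
        child.edge.length = t
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = True
    fixed = functional_sites(truth["anchors"])
    return evolve(rec, tree, model, rng, fixed_sites=fixed)


def simulate_scenario(cfg: ScenarioConfig) -> SimulationResult:
    """Generate LHC/PSBS clades under one duplication scenario.

    Blocks are cut with the production ``extract_blocks`` path using the
    true anchor positions, then grouped into the four mapping clusters.
    """
    rng = np.random.default_rng(cfg.seed)
    model = RateModel(cfg.model_name, alpha=cfg.alpha, k=cfg.k)
    templates = {t.family: t for t in default_templates()}
    sep_lhc = replace(templates["SEP1"], family="SEPanc_LHC", carotenoid=True,
                      base_seed=771)
    sep_psbs = replace(templates["SEP1"], family="SEPanc_PSBS", base_seed=772)

    records: list[SeqRecord] = []
    rows = []
    truth_rows = []

    def radiate(proto, proto_truth, family: str, n_tips: int, donor: str):
        labels = [f"{family}{i + 1}" for i in range(n_tips)]
        tree = random_ultrametric_tree(labels, cfg.clade_depth, rng)
        fixed = functional_sites(proto_truth["anchors"])
        tips = evolve(proto, tree, model, rng, fixed_sites=fixed)
        anchors = proto_truth["anchors"]
        cb = [a for a in anchors]
        for tip in tips:
            records.append(replace(tip, lineage="green"))
            rows.append({"id": tip.id, "anchor_I": cb[0],
                         "anchor_III": cb[-1], "family": family})
            truth_rows.append({
                "id": tip.id, "family": family, "scenario": cfg.scenario,
                "donor": donor, "n_helices": len(proto_truth["helices"]),
                "cb_anchors": ",".join(map(str, anchors)),
                "n_blocks": 2,
            })

    if cfg.scenario == "independent":
        anc, anc_truth = make_ancestor(sep_lhc, seed=rng)
        anc = replace(anc, id="SEP_pool_anc")
        anc_truth = dict(anc_truth, id=anc.id)
        proto_l, proto_p = _two_branch(anc, anc_truth, cfg.pre_dup, model,
                                       rng, ("protoLHC", "protoPSBS"))
        lhc4, lhc_truth = internal_duplicate(proto_l, anc_truth)
        psbs4, psbs_truth = internal_duplicate(proto_p, anc_truth)
        radiate(lhc4, lhc_truth, "LHC", cfg.n_lhc, donor="protoLHC")
        radiate(psbs4, psbs_truth, "PSBS", cfg.n_psbs, donor="protoPSBS")
    else:  # common four-helix ancestor
        anc, anc_truth = make_ancestor(sep_lhc, seed=rng)
        anc = replace(anc, id="SEP_anc")
        anc_truth = dict(anc_truth, id=anc.id)
        four, four_truth = internal_duplicate(anc, anc_truth)
        # the duplication predates the LHC/PSBS split by pre_dup: the
        # four-helix ancestor evolves down a single stem, then splits
        (stem,) = _two_branch(four, four_truth, cfg.pre_dup, model, rng,
                              ("stem",))
        radiate(stem, four_truth, "LHC", cfg.n_lhc, donor="four_helix_anc")
        radiate(stem, four_truth, "PSBS", cfg.n_psbs,
                donor="four_helix_anc")

    anchors = pd.DataFrame(rows)
    blocks = extract_blocks(records, anchors)
    clusters = build_clusters(blocks)
    truth = pd.DataFrame(truth_rows)
    return SimulationResult(records, anchors, clusters, truth)


# ---------------------------------------------------------------------------
# classifier fixtures and seed alignments
# ---------------------------------------------------------------------------

SEED_WINDOW_BEFORE = 25  # seed window = anchor-25 .. anchor+29 (54 columns)


def _star_tree(labels: list, depth: float) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace(list(labels))
    root = dendropy.Node()
    for l in labels:
        child = dendropy.Node(taxon=taxa.get_taxon(l))
        root.add_child(child)
        child.edge.length = depth
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = True
    return tree


def make_seed_alignments(seed: int = 0, n_seqs: int = 8,
                         depth: float = 0.2,
                         model: RateModel | None = None) -> list[SeedAlignment]:
    """Regenerate the 18 family seed alignments from the templates.

    Each family consensus is evolved into shallow variants and the
    54-column window around the first CB anchor is cut (anchor at
    column 25).
    """
    model = model or RateModel("dayhoff")
    rng = np.random.default_rng(seed)
    templates = {t.family: t for t in default_templates()}
    seeds = []
    for fam in PROFILE_FAMILIES:
        tpl = templates[fam]
        anc, truth = make_ancestor(tpl, model=model)
        anchor = truth["anchors"][0]
        labels = [f"{fam}_s{i + 1}" for i in range(n_seqs)]
        tips = evolve(anc, _star_tree(labels, depth), model, rng,
                      fixed_sites=functional_sites(truth["anchors"]))
        lo = anchor - SEED_WINDOW_BEFORE
        window = [replace(t, residues=t.residues[lo:lo + 54]) for t in tips]
        seeds.append(SeedAlignment(fam, Alignment(window),
                                   anchor_col=SEED_WINDOW_BEFORE))
    return seeds


def make_profile_db(seed: int = 0, n_random: int = 2000,
                    calibration_length: int = 160,
                    model: RateModel | None = None):
    """Build and calibrate the default 18-profile database."""
    from .profile_hmm import ProfileDB, build_profile

    seeds = make_seed_alignments(seed=seed, model=model)
    db = ProfileDB([build_profile(s) for s in seeds])
    db.calibrate(n_random=n_random, length_dist=calibration_length,
                 seed=seed + 1)
    return db


def make_reference_set(model: RateModel | None = None) -> list[SeqRecord]:
    """Labeled full-length references (one consensus per family)."""
    refs = []
    for tpl in default_templates():
        rec, _ = make_ancestor(tpl, model=model)
        refs.append(replace(rec, id=f"ref_{tpl.family}",
                            description=tpl.family))
    return refs


def make_classifier_fixtures(n_records: int = 500, seed: int = 0,
                             depth: float = 0.2,
                             model: RateModel | None = None):
    """Clean labeled records for classifier recovery, plus a truth table.

    Also generates one-helix nuclear records with a family-unrelated CB
    window ("OHP1-like"), which the classifier should leave in the
    OHP1_LIKE bin.  Records are distributed round-robin over templates.
    """
    model = model or RateModel("dayhoff")
    rng = np.random.default_rng(seed)
    templates = list(default_templates())
    templates.append(FamilyTemplate("OHP1_LIKE", 1, (0,), "red", "nuclear",
                                    base_seed=1900))
    counts = {t.family: 0 for t in templates}
    for i in range(n_records):
        counts[templates[i % len(templates)].family] += 1
    records, truth_rows = [], []
    for tpl in templates:
        n = counts[tpl.family]
        if n == 0:
            continue
        anc, truth = make_ancestor(tpl, model=model)
        labels = [f"{tpl.family}_q{i + 1}" for i in range(n)]
        tips = evolve(anc, _star_tree(labels, depth), model, rng,
                      fixed_sites=functional_sites(truth["anchors"]))
        fam, sub = TRUE_LABELS[tpl.family]
        for tip in tips:
            records.append(tip)
            truth_rows.append({"id": tip.id, "template": tpl.family,
                               "true_family": fam,
                               "true_subgroup": sub or ""})
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    truth = pd.DataFrame([truth_rows[i] for i in order])
    return records, truth
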