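"""Four-cluster likelihood mapping of CB helix blocks.

The central question: did the four-helix PSBS protein and the three-helix
LHC proteins arise from one internal gene duplication in a common
four-helix ancestor, or from two independent duplications of two-helix
(SEP-like) ancestors?  The two hypotheses predict different phylogenies
for the chlorophyll-binding helices I and III of the two families.
For each sampled quartet — one 32-residue helix block from each of the
four clusters LHC_I, LHC_III, PSBS_I, PSBS_III — the maximum-likelihood
score of the three resolved quartet topologies is computed and the
normalized likelihood weights are mapped onto the 2-simplex:

* T1  (LHC_I,LHC_III) | (PSBS_I,PSBS_III) — within-protein pairing, as
  expected under two independent duplications;
* T2  (LHC_I,PSBS_I) | (LHC_III,PSBS_III) — cross-protein pairing of
  like-numbered helices, as expected under a common four-helix ancestor;
* T3  (LHC_I,PSBS_III) | (LHC_III,PSBS_I) — the hybrid pairing, not
  predicted by either hypothesis.

Occupancy is summarized over three regions (argmax basins) and over a
seven-region partition (three corners, three edges, one center).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .evolve_models import RateModel, TreeLikelihood
from .seqio import Alignment, SeqRecord

CLUSTER_NAMES = ("LHC_I", "LHC_III", "PSBS_I", "PSBS_III")

#: cluster pairing per topology (indices into CLUSTER_NAMES)
TOPOLOGY_PAIRS = {
    "T1": ((0, 1), (2, 3)),
    "T2": ((0, 2), (1, 3)),
    "T3": ((0, 3), (1, 2)),
}

#: barycentric attractors of the seven-region partition
REGION7_ATTRACTORS = {
    "corner_T1": (1.0, 0.0, 0.0),
    "corner_T2": (0.0, 1.0, 0.0),
    "corner_T3": (0.0, 0.0, 1.0),
    "edge_T1T2": (0.5, 0.5, 0.0),
    "edge_T1T3": (0.5, 0.0, 0.5),
    "edge_T2T3": (0.0, 0.5, 0.5),
    "center": (1 / 3, 1 / 3, 1 / 3),
}


@dataclass(frozen=True)
class HelixBlock:
    source_id: str
    helix_tag: str          # "I" or "III"
    family: str             # LHC | PSBS | SEP | OTHER
    residues: str           # exactly 32 gapless letters
    anchor_offset: int = 25  # index of the CB anchor within the block

    def __post_init__(self) -> None:
        if "-" in self.residues:
            raise ValueError("helix blocks must be gapless")

    @property
    def block_id(self) -> str:
        return f"{self.source_id}|{self.helix_tag}"


@dataclass
class ClusterSet:
    clusters: dict  # name -> list[HelixBlock]

    def __post_init__(self) -> None:
        for name in CLUSTER_NAMES:
            if not self.clusters.get(name):
                raise ValueError(f"cluster {name} is empty")

    def __getitem__(self, name: str) -> list:
        return self.clusters[name]

    def sizes(self) -> dict:
        return {k: len(v) for k, v in self.clusters.items()}


@dataclass
class QuartetResult:
    block_ids: tuple
    logl: dict        # topology -> optimized logL
    weights: tuple    # (w1, w2, w3)
    region3: str
    region7: str


@dataclass
class MappingSummary:
    n_quartets: int
    seed: int
    region3: dict  # topology -> percent
    region7: dict  # region -> percent


def extract_blocks(records: list[SeqRecord], cb_anchors, width: int = 32,
                   start_offset: int = -25) -> list[HelixBlock]:
    """Cut helix-I and helix-III blocks around the CB anchors.

    *cb_anchors* maps record id to a dict with keys ``anchors`` (sorted
    anchor positions) and ``family``, or is a DataFrame with columns
    ``id, anchor_I, anchor_III, family``.  The first anchor becomes helix
    I, the last helix III; the block is the gapless window
    ``[anchor+start_offset, anchor+start_offset+width)``.  Records whose
    window does not fit are skipped with a warning.
    """
    if isinstance(cb_anchors, pd.DataFrame):
        table = {}
        for _, row in cb_anchors.iterrows():
            anchors = [int(row["anchor_I"])]
            if not pd.isna(row.get("anchor_III")):
                anchors.append(int(row["anchor_III"]))
            table[str(row["id"])] = {"anchors": anchors,
                                     "family": str(row.get("family", "OTHER"))}
    else:
        table = cb_anchors

    blocks = []
    for rec in records:
        info = table.get(rec.id)
        if info is None:
            continue
        anchors = sorted(info["anchors"])
        family = info.get("family", "OTHER")
        if len(anchors) < 2:
            warnings.warn(f"{rec.id}: fewer than 2 CB anchors; skipped")
            continue
        for tag, anchor in (("I", anchors[0]), ("III", anchors[-1])):
            s = anchor + start_offset
            e = s + width
            if s < 0 or e > len(rec.residues):
                warnings.warn(f"{rec.id}: block window [{s},{e}) out of "
                              "bounds; skipped")
                continue
            frag = rec.residues[s:e].replace("-", "")
            if len(frag) != width:
                warnings.warn(f"{rec.id}: gapped window; skipped")
                continue
            blocks.append(HelixBlock(rec.id, tag, family, frag,
                                     anchor_offset=-start_offset))
    return blocks


def build_clusters(blocks: list[HelixBlock]) -> ClusterSet:
    """Group LHC/PSBS blocks into the four mapping clusters."""
    clusters = {name: [] for name in CLUSTER_NAMES}
    for b in blocks:
        if b.family in ("LHC", "PSBS"):
            clusters[f"{b.family}_{b.helix_tag}"].append(b)
    return ClusterSet(clusters)


def _quartet_tree(topology: str, taxa: dendropy.TaxonNamespace,
                  init_length: float = 0.1) -> dendropy.Tree:
    (a, b), (c, d) = TOPOLOGY_PAIRS[topology]
    names = [t.label for t in taxa]
    newick = (f"(({names[a]}:{init_length},{names[b]}:{init_length})"
              f":{init_length},{names[c]}:{init_length},"
              f"{names[d]}:{init_length});")
    return dendropy.Tree.get(data=newick, schema="newick",
                             taxon_namespace=taxa,
                             preserve_underscores=True)


def _mask_block(residues: str, anchor_offset: int,
                offsets: tuple = (0, 3, 5)) -> str:
    drop = {anchor_offset + o for o in offsets}
    return "".join(c for i, c in enumerate(residues) if i not in drop)


def quartet_logl(blocks: tuple, topology: str, model: RateModel,
                 sweeps: int = 2, mask_functional_sites: bool = False) -> float:
    """ML log-likelihood of one quartet under one of the three topologies.

    The four blocks are taken in cluster order (LHC_I, LHC_III, PSBS_I,
    PSBS_III); all five branch lengths are optimized from 0.1 by
    coordinate sweeps.
    """
    seqs = []
    for name, b in zip(CLUSTER_NAMES, blocks):
        res = (_mask_block(b.residues, b.anchor_offset)
               if mask_functional_sites else b.residues)
        seqs.append(SeqRecord(id=name, residues=res))
    aln = Alignment(seqs)
    taxa = dendropy.TaxonNamespace(CLUSTER_NAMES)
    tree = _quartet_tree(topology, taxa)
    tl = TreeLikelihood(tree, aln, model)
    logl, _ = tl.optimize_branch_lengths(tol=1e-4, sweeps=sweeps)
    return float(logl)


def map_point(logl_t1: float, logl_t2: float, logl_t3: float) -> tuple:
    """Barycentric likelihood weights of the three topologies."""
    l = np.array([logl_t1, logl_t2, logl_t3], dtype=float)
    if np.isnan(l).any():
        raise ValueError("NaN log-likelihood")
    l -= l.max()
    w = np.exp(l)
    w /= w.sum()
    return tuple(float(x) for x in w)


def assign_regions(w: tuple, scheme: str = "nearest") -> tuple[str, str]:
    """Assign a simplex point to its 3-region and 7-region bins.

    ``scheme='nearest'`` uses the nearest attractor in barycentric
    Euclidean distance; ``scheme='threshold'`` calls a corner iff the
    max weight is >= 2/3 and the runner-up <= 1/6, an edge iff the two
    top weights both exceed 1/4 with the third below 1/6, else center.
    """
    w = np.asarray(w, dtype=float)
    topo = ("T1", "T2", "T3")
    order = np.argsort(-w)
    region3 = topo[int(np.argmax(w))]  # argmax; ties -> lexicographically first
    if scheme == "nearest":
        best, best_d = None, np.inf
        for name, attr in REGION7_ATTRACTORS.items():
            d = float(np.sum((w - np.asarray(attr)) ** 2))
            if d < best_d - 1e-15:
                best, best_d = name, d
        region7 = best
    elif scheme == "threshold":
        i, j, k = order
        if w[i] >= 2 / 3 and w[j] <= 1 / 6:
            region7 = f"corner_{topo[i]}"
        elif w[k] < 1 / 6 and w[j] > 1 / 4:
            pair = "".join(sorted([topo[i], topo[j]]))
            region7 = f"edge_{pair}"
        else:
            region7 = "center"
    else:
        raise ValueError(f"unknown region scheme {scheme!r}")
    return region3, region7


def run_mapping(clusters: ClusterSet, model: RateModel,
                n_quartets: int = 10000, seed: int = 0, sweeps: int = 2,
                mask_functional_sites: bool = False,
                region_scheme: str = "nearest"):
    """Sample random quartets and tally simplex-region occupancy.

    One block is drawn uniformly (with replacement across quartets) from
    each cluster per quartet; all three topology likelihoods are
    optimized per quartet.  Returns (summary, per-quartet DataFrame).
    """
    rng = np.random.default_rng(seed)
    names = CLUSTER_NAMES
    sizes = clusters.sizes()
    draws = {name: rng.integers(0, sizes[name], size=n_quartets)
             for name in names}
    results = []
    r3_counts = {t: 0 for t in TOPOLOGY_PAIRS}
    r7_counts = {r: 0 for r in REGION7_ATTRACTORS}
    for q in range(n_quartets):
        blocks = tuple(clusters[name][int(draws[name][q])] for name in names)
        logl = {t: quartet_logl(blocks, t, model, sweeps=sweeps,
                                mask_functional_sites=mask_functional_sites)
                for t in TOPOLOGY_PAIRS}
        w = map_point(logl["T1"], logl["T2"], logl["T3"])
        region3, region7 = assign_regions(w, scheme=region_scheme)
        r3_counts[region3] += 1
        r7_counts[region7] += 1
        results.append(QuartetResult(
            tuple(b.block_id for b in blocks), logl, w, region3, region7))
    pct3 = {t: 100.0 * c / n_quartets for t, c in r3_counts.items()}
    pct7 = {r: 100.0 * c / n_quartets for r, c in r7_counts.items()}
    summary = MappingSummary(n_quartets=n_quartets, seed=seed,
                             region3=pct3, region7=pct7)
    table = pd.DataFrame([
        {"lhc_i": r.block_ids[0], "lhc_iii": r.block_ids[1],
         "psbs_i": r.block_ids[2], "psbs_iii": r.block_ids[3],
         "logl_t1": r.logl["T1"], "logl_t2": r.logl["T2"],
         "logl_t3": r.logl["T3"], "w1": r.weights[0], "w2": r.weights[1],
         "w3": r.weights[2], "region3": r.region3, "region7": r.region7}
        for r in results
    ])
    return summary, table
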