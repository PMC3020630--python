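"""Rule-based family classification of LHC-superfamily proteins.

A record is assigned to a family by combining (i) similarity — profile-HMM
hits against the 54-column CB-window database plus a full-length k-mer
similarity against a labeled reference set, (ii) predicted secondary
structure — the number and order of TM helices, and (iii) sequence motifs
and genome compartment.  The ladder mirrors how practitioners separate
these families: fusion proteins (ferrochelatase II, Rieske-like CAB) by
full-length similarity first because their CB motif may be missing; then
helix-count gates (one-helix HLIP/OHP, two-helix SEP, three-helix
ELIP/RedCAP/LHC, four-helix PSBS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .motif_structure import Architecture
from .profile_hmm import HMMHit, ProfileDB
from .seqio import SeqRecord

FAMILIES = ("HLIP", "OHP1", "OHP1_LIKE", "OHP2", "SEP", "ELIP", "RedCAP",
            "LHC", "PSBS", "PSBS_LIKE", "FCII", "RIESKE_CAB", "UNCLASSIFIED")
SEP_SUBGROUPS = ("SEP1", "SEP2", "SEP3", "SEP4", "SEP5", "SEPx")
LHC_SUBGROUPS = ("CAB", "FCP", "LI818", "LHCz", "RED_LHC")

#: profile families that mean "LHC" at the family level
_LHC_PROFILE_SET = set(LHC_SUBGROUPS)
_SEP_PROFILE_SET = set(SEP_SUBGROUPS)


@dataclass(frozen=True)
class FamilyLabel:
    family: str
    subgroup: str | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.subgroup is not None and self.family not in ("SEP", "LHC"):
            raise ValueError("subgroup only applies to SEP and LHC")

    def __str__(self) -> str:
        return f"{self.family}/{self.subgroup}" if self.subgroup else self.family


@dataclass
class Evidence:
    hmm_hits: list[HMMHit]
    architecture: Architecture
    compartment: str = "unknown"
    lineage: str = "other"
    fulllen_sim: tuple[str, float] | None = None  # (label, score)


@dataclass
class FamilyCall:
    label: FamilyLabel
    confidence: str  # strong | weak
    rationale: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class Thresholds:
    alpha: float = 1e-3    # significant profile hit
    beta: float = 0.05     # weak hit (PSBS-like)
    fusion_sim: float = 0.35  # full-length similarity gate for fusion proteins

    def __post_init__(self) -> None:
        if not self.alpha <= self.beta:
            raise ValueError("alpha must not exceed beta")


DEFAULT_THRESHOLDS = Thresholds()


def kmer_set(seq: str, k: int = 4) -> set:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def fulllen_similarity(query: str, reference_set: list[SeqRecord],
                       k: int = 4) -> tuple[str, float]:
    """Best full-length k-mer containment score against labeled references.

    Score is |k-mers(query) ∩ k-mers(ref)| / |k-mers(query)| in [0, 1];
    a stand-in for full-length BLASTP whose only downstream role is
    ranking.  Reference labels are taken from the record description.
    """
    if not reference_set:
        raise ValueError("empty reference set")
    q = kmer_set(query, k)
    if not q:
        return reference_set[0].description or reference_set[0].id, 0.0
    best_label, best_score = "", -1.0
    for ref in sorted(reference_set, key=lambda r: r.id):
        label = ref.description or ref.id
        score = len(q & kmer_set(ref.residues, k)) / len(q)
        if score > best_score:
            best_label, best_score = label, score
    return best_label, best_score


def _top_hit(hits: list[HMMHit], families: set | None = None) -> HMMHit | None:
    for h in hits:
        if families is None or h.family in families:
            return h
    return None


def _subgroup_from_hits(hits, subgroup_set, alpha) -> str | None:
    h = _top_hit(hits, subgroup_set)
    if h is not None and h.p_value <= alpha:
        return h.family
    return None


def classify(record: SeqRecord, ev: Evidence,
             thresholds: Thresholds = DEFAULT_THRESHOLDS) -> FamilyCall:
    """Apply the classification rule ladder to one record."""
    if ev.architecture is None:
        raise ValueError("classification requires an architecture")
    th = thresholds
    rat: list[str] = []
    arch = ev.architecture
    n = arch.n_helices
    hits = ev.hmm_hits

    # (1) fusion proteins by full-length similarity
    if ev.fulllen_sim is not None:
        label, score = ev.fulllen_sim
        if label in ("FCII", "RIESKE_CAB") and score >= th.fusion_sim:
            rat.append(f"fulllen_sim:{label}:{score:.3f}>={th.fusion_sim}")
            return FamilyCall(FamilyLabel(label), "strong", rat)

    # (2) one helix
    if n == 1:
        if ev.compartment == "plastid" or ev.lineage in ("cyanobacteria", "phage"):
            rat.append(f"one_helix;plastid_or_cyano({ev.compartment},{ev.lineage})")
            return FamilyCall(FamilyLabel("HLIP"), "strong", rat)
        top = _top_hit(hits)
        if top is not None and top.family == "OHP1" and top.p_value <= th.alpha:
            rat.append(f"one_helix;top_hit:OHP1:p={top.p_value:.2e}")
            return FamilyCall(FamilyLabel("OHP1"), "strong", rat)
        if top is not None and top.family == "OHP2" and top.p_value <= th.alpha:
            rat.append(f"one_helix;top_hit:OHP2:p={top.p_value:.2e}")
            return FamilyCall(FamilyLabel("OHP2"), "strong", rat)
        rat.append("one_helix;no_OHP_hit")
        return FamilyCall(FamilyLabel("OHP1_LIKE"), "weak", rat)

    # (3) two helices, CB motif in the first
    if n == 2 and arch.cb_first:
        sub = _subgroup_from_hits(hits, set(SEP_SUBGROUPS) - {"SEPx"}, th.alpha)
        rat.append("two_helices;cb_first")
        if sub is None:
            rat.append("no_SEP1-5_hit->SEPx")
            return FamilyCall(FamilyLabel("SEP", "SEPx"), "weak", rat)
        rat.append(f"subgroup:{sub}")
        return FamilyCall(FamilyLabel("SEP", sub), "strong", rat)

    # (4) three helices
    if n == 3:
        for h in hits:
            if h.p_value > th.alpha:
                break
            if h.family == "ELIP":
                rat.append(f"three_helices;top_hit:ELIP:p={h.p_value:.2e}")
                return FamilyCall(FamilyLabel("ELIP"), "strong", rat)
            if h.family == "RedCAP":
                if ev.lineage in ("red", "complex_red"):
                    rat.append(f"three_helices;top_hit:RedCAP:p={h.p_value:.2e}")
                    return FamilyCall(FamilyLabel("RedCAP"), "strong", rat)
                rat.append("RedCAP_hit_rejected:lineage")
                continue
            if h.family in _LHC_PROFILE_SET:
                sub = _subgroup_from_hits(hits, _LHC_PROFILE_SET, th.alpha)
                rat.append(f"three_helices;top_hit:{h.family}:p={h.p_value:.2e}")
                if sub:
                    rat.append(f"subgroup:{sub}")
                return FamilyCall(FamilyLabel("LHC", sub), "strong", rat)
        rat.append("three_helices;no_significant_hit")
        return FamilyCall(FamilyLabel("UNCLASSIFIED"), "weak", rat)

    # (5) four helices
    if n == 4:
        top = _top_hit(hits)
        if top is not None and top.family == "PSBS":
            if top.p_value <= th.alpha:
                rat.append(f"four_helices;top_hit:PSBS:p={top.p_value:.2e}")
                return FamilyCall(FamilyLabel("PSBS"), "strong", rat)
            if top.p_value <= th.beta:
                rat.append(f"four_helices;weak_PSBS:p={top.p_value:.2e}")
                return FamilyCall(FamilyLabel("PSBS_LIKE"), "weak", rat)
        rat.append("four_helices;no_PSBS_hit")
        return FamilyCall(FamilyLabel("UNCLASSIFIED"), "weak", rat)

    rat.append(f"n_helices={n};no_rule")
    return FamilyCall(FamilyLabel("UNCLASSIFIED"), "weak", rat)


def classify_batch(records: list[SeqRecord], db: ProfileDB,
                   reference_set: list[SeqRecord] | None = None,
                   thresholds: Thresholds = DEFAULT_THRESHOLDS,
                   top_k: int = 3, **scan_kwargs):
    """Classify a record collection; returns (calls dict, summary table).

    Per-record errors are recorded as UNCLASSIFIED with the error message
    in the rationale; the batch continues.  Calls are keyed by record id
    and independent of input order.
    """
    from .motif_structure import scan_record

    calls: dict[str, FamilyCall] = {}
    rows = []
    for rec in records:
        try:
            arch = scan_record(rec.residues, **scan_kwargs)
            hits = db.search(rec.residues, top_k=top_k)
            sim = (fulllen_similarity(rec.residues, reference_set)
                   if reference_set else None)
            ev = Evidence(hits, arch, rec.compartment, rec.lineage, sim)
            call = classify(rec, ev, thresholds)
        except Exception as exc:
            call = FamilyCall(FamilyLabel("UNCLASSIFIED"), "weak",
                              [f"error:{exc}"])
        calls[rec.id] = call
        rows.append({"id": rec.id, "organism": rec.organism,
                     "family": call.label.family,
                     "subgroup": call.label.subgroup or "",
                     "confidence": call.confidence})
    table = pd.DataFrame(rows)
    if len(table):
        summary = (table.groupby(["organism", "family"]).size()
                   .rename("count").reset_index())
    else:
        summary = pd.DataFrame(columns=["organism", "family", "count"])
    return calls, summary
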