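"""Chlorophyll-binding motifs, hydropathy helix prediction, architectures.

The chlorophyll-binding (CB) motif is anchored on a conserved glutamate
(E at offset 0) with histidine/asparagine at +3 and arginine at +5; an
extended set of weakly conserved positions (T+21, G+22, Q+28) marks the
C-terminal context in several families.  A carotenoid-binding motif
(FDPLGL, or its FDP core) sits roughly 15 residues upstream of the CB
anchor in most LHC proteins.

Transmembrane (TM) helices are predicted with a Kyte-Doolittle sliding
window.  Because the CB helix is known to be membrane-embedded from
crystallography, any CB anchor that falls outside a predicted helix
forces a helix around it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Kyte & Doolittle (1982) hydropathy index.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}


@dataclass(frozen=True)
class CBMotifSpec:
    """Definition of the chlorophyll-binding motif around the E-0 anchor."""

    anchor: frozenset = frozenset("E")
    required: tuple = ((3, frozenset("HN")), (5, frozenset("R")))
    extended: tuple = ((21, frozenset("T")), (22, frozenset("G")),
                       (28, frozenset("Q")))
    #: mismatches tolerated over the required offsets; the E-0 anchor
    #: itself never mismatches.
    max_mismatch: int = 1


DEFAULT_CB_SPEC = CBMotifSpec()
STRICT_CB_SPEC = CBMotifSpec(max_mismatch=0)


@dataclass(frozen=True)
class MotifHit:
    anchor_index: int
    matched_offsets: tuple
    n_mismatches: int
    kind: str = "cb"  # cb | carotenoid_full | carotenoid_core
    linked_anchor: int | None = None  # CB anchor a carotenoid hit points at


@dataclass
class TMHelix:
    start: int
    end: int  # half-open
    mean_hydropathy: float
    contains_cb: bool = False
    forced: bool = False

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Architecture:
    helices: list[TMHelix]
    cb_hits: list[MotifHit]
    carotenoid_hits: list[MotifHit] = field(default_factory=list)

    @property
    def n_helices(self) -> int:
        return len(self.helices)

    @property
    def cb_helix_indices(self) -> list[int]:
        return [i for i, h in enumerate(self.helices) if h.contains_cb]

    @property
    def cb_first(self) -> bool:
        return bool(self.helices) and self.helices[0].contains_cb


def find_cb_motifs(seq: str, spec: CBMotifSpec = DEFAULT_CB_SPEC) -> list[MotifHit]:
    """Report every anchor position matching the CB motif definition.

    A position qualifies when the residue there is in the anchor set and
    at most ``spec.max_mismatch`` of the required offsets mismatch.
    Overlapping hits are allowed; hits are sorted by anchor position.
    """
    hits = []
    max_off = max(off for off, _ in spec.required) if spec.required else 0
    for i, ch in enumerate(seq):
        if ch not in spec.anchor or i + max_off >= len(seq):
            continue
        matched = [0]
        mism = 0
        for off, allowed in spec.required:
            if seq[i + off] in allowed:
                matched.append(off)
            else:
                mism += 1
        if mism <= spec.max_mismatch:
            for off, allowed in spec.extended:
                if i + off < len(seq) and seq[i + off] in allowed:
                    matched.append(off)
            hits.append(MotifHit(i, tuple(matched), mism))
    return hits


def find_carotenoid_motifs(seq: str, cb_hits: list[MotifHit], core: str = "FDP",
                           full: str = "FDPLGL",
                           window: tuple[int, int] = (10, 20)) -> list[MotifHit]:
    """Carotenoid-binding motif upstream of a CB anchor.

    Accepts the full motif with at most one mismatch outside the core, or
    the exact core alone, starting ``window`` residues upstream of the
    anchor (distance measured anchor minus motif start).
    """
    out = []
    lo, hi = window
    for cb in cb_hits:
        a = cb.anchor_index
        for dist in range(lo, hi + 1):
            s = a - dist
            if s < 0:
                continue
            frag_full = seq[s:s + len(full)]
            if len(frag_full) == len(full):
                mism = sum(x != y for x, y in zip(frag_full, full))
                core_ok = frag_full[:len(core)] == core
                if core_ok and mism <= 1:
                    out.append(MotifHit(s, (), mism, kind="carotenoid_full",
                                        linked_anchor=a))
                    continue
            if seq[s:s + len(core)] == core:
                out.append(MotifHit(s, (), 0, kind="carotenoid_core",
                                    linked_anchor=a))
    # dedupe (same start may serve several anchors after duplication)
    seen, uniq = set(), []
    for h in out:
        key = (h.anchor_index, h.linked_anchor)
        if key not in seen:
            seen.add(key)
            uniq.append(h)
    return sorted(uniq, key=lambda h: (h.anchor_index, h.linked_anchor))


def hydropathy_profile(seq: str, window: int = 19) -> np.ndarray:
    """Windowed mean hydropathy, indexed by window-center position.

    Positions whose window does not fit inside the sequence get -inf.
    """
    vals = np.array([KYTE_DOOLITTLE[c] for c in seq], dtype=float)
    n = len(seq)
    prof = np.full(n, -np.inf)
    if n < window:
        return prof
    half = window // 2
    kernel = np.ones(window) / window
    means = np.convolve(vals, kernel, mode="valid")  # length n-window+1
    prof[half:half + len(means)] = means
    return prof


def predict_tm(seq: str, window: int = 19, threshold: float = 1.0,
               min_len: int = 17) -> list[TMHelix]:
    """Predict TM helices as maximal above-threshold hydropathy runs.

    A run of qualifying window centers ``[a, b]`` is expanded by half a
    window on each side; overlapping intervals are merged and intervals
    shorter than *min_len* dropped.
    """
    if len(seq) < window:
        warnings.warn("sequence shorter than hydropathy window; no helices")
        return []
    prof = hydropathy_profile(seq, window)
    above = prof >= threshold
    half = window // 2
    intervals = []
    i = 0
    n = len(seq)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            intervals.append([max(0, i - half), min(n, j + half + 1)])
            i = j + 1
        else:
            i += 1
    merged = _merge_intervals(intervals)
    vals = np.array([KYTE_DOOLITTLE[c] for c in seq], dtype=float)
    return [
        TMHelix(s, e, float(vals[s:e].mean()))
        for s, e in merged if e - s >= min_len
    ]


def _merge_intervals(intervals: list) -> list:
    out: list[list[int]] = []
    for s, e in sorted(map(list, intervals)):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return out


def build_architecture(seq: str, helices: list[TMHelix],
                       cb_hits: list[MotifHit],
                       carotenoid_hits: list[MotifHit] | None = None,
                       min_len: int = 17) -> Architecture:
    """Combine predicted helices and motif hits into an architecture.

    CB anchors are membrane-embedded by definition, so an anchor outside
    every predicted helix forces a helix of *min_len* centered on it;
    overlaps are resolved by merging (union).  Only exact motif matches
    (no mismatches) force helices, and degenerate matches that end up
    outside every helix are dropped from the architecture: an isolated
    partial motif with no membrane context is treated as noise rather
    than a CB helix.
    """
    intervals = [[h.start, h.end, h.forced] for h in helices]
    for cb in cb_hits:
        a = cb.anchor_index
        if cb.n_mismatches > 0 or any(s <= a < e for s, e, _ in intervals):
            continue
        half = min_len // 2
        s = max(0, a - half)
        e = min(len(seq), s + min_len)
        s = max(0, e - min_len)
        intervals.append([s, e, True])
    merged: list[list] = []
    for s, e, forced in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][2] = merged[-1][2] or forced
        else:
            merged.append([s, e, forced])
    vals = np.array([KYTE_DOOLITTLE[c] for c in seq], dtype=float) if seq else np.zeros(0)
    kept = [cb for cb in cb_hits
            if any(s <= cb.anchor_index < e for s, e, _ in merged)]
    anchors = [cb.anchor_index for cb in kept]
    out = [
        TMHelix(s, e, float(vals[s:e].mean()),
                contains_cb=any(s <= a < e for a in anchors), forced=forced)
        for s, e, forced in merged
    ]
    return Architecture(out, kept, list(carotenoid_hits or []))


def scan_record(seq: str, cb_spec: CBMotifSpec = DEFAULT_CB_SPEC,
                tm_window: int = 19, tm_threshold: float = 1.0,
                tm_min_len: int = 17,
                car_window: tuple[int, int] = (10, 20)) -> Architecture:
    """One-call pipeline: motifs, TM prediction, architecture assembly."""
    cb = find_cb_motifs(seq, cb_spec)
    car = find_carotenoid_motifs(seq, cb, window=car_window)
    helices = predict_tm(seq, tm_window, tm_threshold, tm_min_len)
    return build_architecture(seq, helices, cb, car, min_len=tm_min_len)
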