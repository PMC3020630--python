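"""Profile hidden Markov models for the 54-column CB-window families.

Each family profile is built from a seed alignment of exactly 54 columns
centred on the chlorophyll-binding motif.  Scoring is local (fragment)
forward log-odds against a background null: entry/exit probabilities are
set so that, absent informative transitions, every (start, end) fragment
of the profile is a priori equally likely, and flanking query residues
are emitted by the null and cancel.  Delete chains are folded into an
effective match-to-match transfer matrix so the forward recursion is a
dense linear map per emitted residue, which also lets one query be scored
against the whole profile database in a single pass.

Scores are reported in bits; p-values come from a Gumbel
(extreme-value) law fitted to scores of random background sequences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gumbel_r

from .evolve_models import AA_INDEX, AA_ORDER, MISSING, RateModel
from .seqio import Alignment

LN2 = float(np.log(2.0))

#: default background: Dayhoff stationary frequencies
def _default_background() -> np.ndarray:
    return RateModel("dayhoff").freqs.copy()


@dataclass
class SeedAlignment:
    """A family seed: 54 aligned columns with the CB anchor marked."""

    family: str
    alignment: Alignment
    anchor_col: int

    def __post_init__(self) -> None:
        if self.alignment.n_columns != 54:
            raise ValueError(
                f"seed for {self.family} has {self.alignment.n_columns} "
                "columns; expected 54")
        if len(self.alignment) < 2:
            raise ValueError("seed needs at least 2 sequences")
        if not 0 <= self.anchor_col < 54:
            raise ValueError("anchor column outside seed window")


@dataclass
class HMMHit:
    family: str
    score: float  # bits
    p_value: float
    rank: int = 0


class ProfileHMM:
    """Per-family profile with match/insert/delete states."""

    def __init__(self, family: str, match_emissions: np.ndarray,
                 transitions: dict, background: np.ndarray,
                 anchor_col: int = 0):
        self.family = family
        self.em = np.asarray(match_emissions, dtype=float)  # (L, 20)
        self.L = self.em.shape[0]
        if not np.allclose(self.em.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("emission rows must sum to 1")
        self.bg = np.asarray(background, dtype=float)
        self.trans = {k: np.asarray(v, dtype=float) for k, v in transitions.items()}
        self.anchor_col = anchor_col
        self.calibration: tuple[float, float] | None = None  # Gumbel loc, scale
        self._build_scoring()

    # -- scoring machinery ----------------------------------------------
    def _build_scoring(self) -> None:
        L = self.L
        # emission odds, with column 20 = X marginalized to odds 1
        eo = np.ones((L, 21))
        eo[:, :20] = self.em / self.bg[None, :]
        self.em_odds = eo
        # uniform-fragment local entry/exit
        ks = np.arange(L)
        self.entry = 2.0 * (L - ks) / (L * (L + 1))
        self.exit = 1.0 / (L - ks)
        keep = 1.0 - self.exit  # mass left for core transitions out of Mj
        tmm, tmi, tmd = self.trans["MM"], self.trans["MI"], self.trans["MD"]
        tim, tii = self.trans["IM"], self.trans["II"]
        tdm, tdd = self.trans["DM"], self.trans["DD"]
        # effective M->M transfer with delete chains folded in
        T = np.zeros((L, L))
        for j in range(L - 1):
            T[j, j + 1] = keep[j] * tmm[j]
            chain = keep[j] * tmd[j]
            for j2 in range(j + 2, L):
                T[j, j2] += chain * tdm[j2 - 1]
                chain *= tdd[j2 - 1]
        self.T = T
        self.tMI = keep[:-1] * tmi[:-1] if L > 1 else np.zeros(0)
        self.tII = tii[:-1] if L > 1 else np.zeros(0)
        self.tIM = tim[:-1] if L > 1 else np.zeros(0)

    def forward_score(self, seq: str) -> float:
        """Local forward log-odds score in bits."""
        return _dp_scores(_stack([self]), encode_query(seq), viterbi=False)[0]

    def viterbi_score(self, seq: str) -> float:
        """Best-single-path analogue of :meth:`forward_score` (bits)."""
        return _dp_scores(_stack([self]), encode_query(seq), viterbi=True)[0]

    # -- calibration -----------------------------------------------------
    def calibrate(self, n_random: int = 10000, length_dist=150,
                  seed: int | np.random.Generator = 0) -> None:
        """Fit a Gumbel law to random background-sequence scores."""
        if n_random < 100:
            raise ValueError("need at least 100 calibration sequences")
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        if callable(length_dist):
            lengths = np.asarray(length_dist(rng, n_random), dtype=int)
        else:
            lengths = np.full(n_random, int(length_dist))
        scores = []
        for ln in np.unique(lengths):
            m = int((lengths == ln).sum())
            batch = rng.choice(20, size=(m, int(ln)), p=self.bg)
            scores.append(_dp_batch(_stack([self]), batch)[:, 0])
        scores = np.concatenate(scores)
        loc, scale = gumbel_r.fit(scores)
        self.calibration = (float(loc), float(scale))

    def p_value(self, score: float) -> float:
        if self.calibration is None:
            raise RuntimeError(f"profile {self.family} is not calibrated")
        loc, scale = self.calibration
        return float(np.clip(gumbel_r.sf(score, loc, scale), 1e-300, 1.0))

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "anchor_col": self.anchor_col,
            "match_emissions": self.em.tolist(),
            "background": self.bg.tolist(),
            "transitions": {k: v.tolist() for k, v in self.trans.items()},
            "calibration": self.calibration,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProfileHMM":
        p = cls(d["family"], np.array(d["match_emissions"]), d["transitions"],
                np.array(d["background"]), d["anchor_col"])
        if d.get("calibration"):
            p.calibration = tuple(d["calibration"])
        return p


def build_profile(seed: SeedAlignment, pseudocount_scheme: str = "dirichlet",
                  background: np.ndarray | None = None) -> ProfileHMM:
    """Estimate a profile from a seed alignment.

    Match emissions are normalized (counts + pseudocounts); the Dirichlet
    scheme adds pseudocounts of total weight 20 distributed by the
    background frequencies, the Laplace fallback adds one per letter.
    Transitions are counted from the seed's gap structure (gap = delete)
    with add-one smoothing; heavily gapped columns therefore route mass
    through delete chains.
    """
    bg = _default_background() if background is None else np.asarray(background)
    aln = seed.alignment
    L = aln.n_columns
    counts = np.zeros((L, 20))
    gaps = np.zeros(L)
    for rec in aln.records:
        for j, ch in enumerate(rec.residues):
            if ch == "-":
                gaps[j] += 1
            elif ch in AA_INDEX:
                counts[j, AA_INDEX[ch]] += 1
    if pseudocount_scheme == "dirichlet":
        pseudo = 20.0 * bg[None, :]
    elif pseudocount_scheme == "laplace":
        pseudo = np.ones((1, 20))
    else:
        raise ValueError(f"unknown pseudocount scheme {pseudocount_scheme!r}")
    em = counts + pseudo
    em /= em.sum(axis=1, keepdims=True)

    # transition counts from gap structure
    cMM = np.ones(L); cMI = np.ones(L); cMD = np.ones(L)
    cDM = np.ones(L); cDD = np.ones(L)
    for rec in aln.records:
        isgap = [c == "-" for c in rec.residues]
        for j in range(L - 1):
            a, b = isgap[j], isgap[j + 1]
            if not a and not b:
                cMM[j] += 1
            elif not a and b:
                cMD[j] += 1
            elif a and not b:
                cDM[j] += 1
            else:
                cDD[j] += 1
    msum = cMM + cMI + cMD
    dsum = cDM + cDD
    trans = {
        "MM": cMM / msum, "MI": cMI / msum, "MD": cMD / msum,
        "IM": np.full(L, 0.5), "II": np.full(L, 0.5),
        "DM": cDM / dsum, "DD": cDD / dsum,
    }
    return ProfileHMM(seed.family, em, trans, bg, anchor_col=seed.anchor_col)


# ---------------------------------------------------------------------------
# shared DP over one or many profiles / sequences
# ---------------------------------------------------------------------------

def encode_query(seq: str) -> np.ndarray:
    """Encode a query for scoring; 'X' positions are marginalized out.

    An unknown residue carries no information either for the profile or
    for the null, so it is dropped before the DP — this makes scores
    exactly invariant to X padding.
    """
    out = np.array([AA_INDEX.get(c, MISSING) for c in seq], dtype=np.int64)
    return out[out != MISSING]


@dataclass
class _Stacked:
    em_odds: np.ndarray  # (P, L, 21)
    T: np.ndarray        # (P, L, L)
    entry: np.ndarray    # (P, L)
    exit: np.ndarray     # (P, L)
    tMI: np.ndarray      # (P, L-1)
    tII: np.ndarray
    tIM: np.ndarray


def _stack(profiles: list[ProfileHMM]) -> _Stacked:
    return _Stacked(
        em_odds=np.stack([p.em_odds for p in profiles]),
        T=np.stack([p.T for p in profiles]),
        entry=np.stack([p.entry for p in profiles]),
        exit=np.stack([p.exit for p in profiles]),
        tMI=np.stack([p.tMI for p in profiles]),
        tII=np.stack([p.tII for p in profiles]),
        tIM=np.stack([p.tIM for p in profiles]),
    )


def _dp_scores(st: _Stacked, query: np.ndarray, viterbi: bool = False) -> np.ndarray:
    """Forward (or Viterbi) bit scores of one query against P profiles."""
    P, L, _ = st.em_odds.shape
    fM = np.zeros((P, L))
    fI = np.zeros((P, max(L - 1, 1)))
    total = np.zeros(P)
    comb = np.maximum if viterbi else np.add
    for x in query:
        eo = st.em_odds[:, :, x]  # (P, L)
        if viterbi:
            core = (fM[:, :, None] * st.T).max(axis=1)
        else:
            core = np.einsum("pj,pjl->pl", fM, st.T)
        ins = np.zeros((P, L))
        if L > 1:
            ins[:, 1:] = fI * st.tIM
        newM = eo * comb(comb(core, ins), np.broadcast_to(st.entry, core.shape))
        if L > 1:
            fI = comb(fM[:, :-1] * st.tMI, fI * st.tII)
        fM = newM
        exits = fM * st.exit
        total = comb(total, exits.max(axis=1) if viterbi else exits.sum(axis=1))
    with np.errstate(divide="ignore"):
        return np.log(total) / LN2


def _dp_batch(st: _Stacked, queries: np.ndarray) -> np.ndarray:
    """Forward bit scores of N equal-length queries; returns (N, P)."""
    P, L, _ = st.em_odds.shape
    N, n = queries.shape
    fM = np.zeros((N, P, L))
    fI = np.zeros((N, P, max(L - 1, 1)))
    total = np.zeros((N, P))
    for i in range(n):
        x = queries[:, i]
        eo = np.transpose(st.em_odds[:, :, x], (2, 0, 1))  # (N, P, L)
        core = np.einsum("npj,pjl->npl", fM, st.T)
        ins = np.zeros((N, P, L))
        if L > 1:
            ins[:, :, 1:] = fI * st.tIM[None]
        newM = eo * (core + ins + st.entry[None])
        if L > 1:
            fI = fM[:, :, :-1] * st.tMI[None] + fI * st.tII[None]
        fM = newM
        total += (fM * st.exit[None]).sum(axis=2)
    with np.errstate(divide="ignore"):
        return np.log(total) / LN2


def forward_score(profile: ProfileHMM, seq: str) -> float:
    return profile.forward_score(seq)


def calibrate(profile: ProfileHMM, n_random: int = 10000, length_dist=150,
              seed=0) -> None:
    profile.calibrate(n_random=n_random, length_dist=length_dist, seed=seed)


class ProfileDB:
    """A searchable collection of calibrated family profiles."""

    def __init__(self, profiles: list[ProfileHMM]):
        labels = [p.family for p in profiles]
        if len(set(labels)) != len(labels):
            raise ValueError("family labels must be unique")
        self.profiles = list(profiles)
        self._stacked = _stack(self.profiles) if self.profiles else None

    def __len__(self) -> int:
        return len(self.profiles)

    def __getitem__(self, family: str) -> ProfileHMM:
        for p in self.profiles:
            if p.family == family:
                return p
        raise KeyError(family)

    def calibrate(self, n_random: int = 10000, length_dist=150, seed=0) -> None:
        rng = np.random.default_rng(seed)
        for p in self.profiles:
            p.calibrate(n_random=n_random, length_dist=length_dist, seed=rng)

    def search(self, seq: str, top_k: int = 3) -> list[HMMHit]:
        """Top-k hits sorted by score (ties broken by family label)."""
        if not self.profiles:
            raise ValueError("empty profile database")
        scores = _dp_scores(self._stacked, encode_query(seq))
        hits = [HMMHit(p.family, float(s), p.p_value(float(s)))
                for p, s in zip(self.profiles, scores)]
        hits.sort(key=lambda h: (-h.score, h.family))
        hits = hits[:top_k]
        for r, h in enumerate(hits, start=1):
            h.rank = r
        return hits

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([p.to_dict() for p in self.profiles], fh)

    @classmethod
    def from_json(cls, path) -> "ProfileDB":
        with open(path) as fh:
            return cls([ProfileHMM.from_dict(d) for d in json.load(fh)])


def search(db: ProfileDB, seq: str, top_k: int = 3) -> list[HMMHit]:
    return db.search(seq, top_k=top_k)
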