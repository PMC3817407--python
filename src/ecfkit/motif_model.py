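"""Bipartite promoter models for ECF sigma factors.

An ECF promoter is modelled as two position weight matrices — one for the
-35 element (read by sigma domain 4) and one for the -10 element (read by
domain 2) — joined by a variable-length spacer whose length distribution is
summarised as a log-odds penalty relative to the modal spacing. Scores are
log2-odds throughout, so a score reads directly as bits of preference over
the background composition.

The module also contains a collapsed Gibbs sampler that discovers such
two-block gapped motifs de novo from a set of unaligned promoter regions
(one occurrence per sequence), the classic approach for bacterial promoter
elements where the -35/-10 spacing varies by a few bases.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._seq import BASES, decode, encode, validate_dna
from .errors import ValidationError

UNIFORM = np.full(4, 0.25)

# ---------------------------------------------------------------------------
# PWM


@dataclass(frozen=True)
class PWM:
    """Position probability matrix with derived log2-odds scores.

    probs has shape (width, 4) with rows summing to 1; logodds is
    log2(probs / background) and may contain -inf when pseudocount is 0.
    """

    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM.copy())
    pseudocount: float = 0.0
    logodds: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] == 0:
            raise ValidationError("PWM probs must have shape (width>=1, 4)")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("PWM probability columns must each sum to 1")
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0, atol=1e-9) or (bg <= 0).any():
            raise ValidationError("background must be 4 positive frequencies summing to 1")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)
        with np.errstate(divide="ignore"):
            object.__setattr__(self, "logodds", np.log2(probs / bg))

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        """Most probable base at each position (ties -> alphabetically first)."""
        return decode(self.probs.argmax(axis=1))

    @property
    def max_score(self) -> float:
        """Score of the consensus sequence (per-column maxima summed)."""
        return float(self.logodds.max(axis=1).sum())


def build_pwm(
    sites: Sequence[str],
    background: Optional[np.ndarray] = None,
    pseudocount: float = 1.0,
) -> PWM:
    """Estimate a PWM from aligned, equal-length binding sites.

    Pseudocount mass is distributed according to the background:
    p[i][b] = (count[i][b] + pseudocount * background[b]) / (n + pseudocount).
    """
    if len(sites) == 0:
        raise ValidationError("build_pwm requires at least one site")
    width = len(sites[0])
    if width == 0:
        raise ValidationError("build_pwm: sites must be non-empty strings")
    if any(len(s) != width for s in sites):
        raise ValidationError("build_pwm: all sites must have equal length")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be nonnegative")
    bg = UNIFORM.copy() if background is None else np.asarray(background, dtype=float)
    counts = np.zeros((width, 4))
    for s in sites:
        idx = encode(validate_dna(s, context="site"))
        counts[np.arange(width), idx] += 1
    probs = (counts + pseudocount * bg) / (len(sites) + pseudocount)
    return PWM(probs=probs, background=bg, pseudocount=pseudocount)


def score_block(pwm: PWM, subseq: str) -> float:
    """Log2-odds score of one candidate block (length must equal pwm.width)."""
    if len(subseq) != pwm.width:
        raise ValidationError(
            f"score_block: sequence length {len(subseq)} != PWM width {pwm.width}"
        )
    idx = encode(validate_dna(subseq, context="block"))
    return float(pwm.logodds[np.arange(pwm.width), idx].sum())


def information_content(pwm: PWM) -> Tuple[np.ndarray, float]:
    """Per-position and total information content in bits.

    Uniform background: IC_i = 2 + sum_b p log2 p. Non-uniform background:
    the KL form sum_b p log2(p / bg).
    """
    p = pwm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
        if np.allclose(pwm.background, UNIFORM):
            per_pos = 2.0 + plogp.sum(axis=1)
        else:
            per_pos = np.where(p > 0, p * np.log2(p / pwm.background), 0.0).sum(axis=1)
    return per_pos, float(per_pos.sum())


# ---------------------------------------------------------------------------
# Spacer model


@dataclass(frozen=True)
class SpacerModel:
    """Spacer-length histogram turned into a log2 penalty, 0 at the mode."""

    counts: Dict[int, int]
    pseudocount: float = 1.0
    support: Tuple[int, int] = None  # inclusive (min, max)

    def __post_init__(self):
        if self.support is None:
            if not self.counts:
                raise ValidationError("SpacerModel needs counts or an explicit support")
            object.__setattr__(self, "support", (min(self.counts), max(self.counts)))
        lo, hi = self.support
        if lo > hi or lo < 0:
            raise ValidationError(f"invalid spacer support {self.support}")
        if self.pseudocount < 0:
            raise ValidationError("spacer pseudocount must be nonnegative")
        if any(length < lo or length > hi for length in self.counts):
            raise ValidationError("spacer counts outside declared support")

    def _smoothed(self, length: int) -> float:
        return self.counts.get(length, 0) + self.pseudocount

    @property
    def modal_length(self) -> int:
        lo, hi = self.support
        lengths = range(lo, hi + 1)
        return max(lengths, key=lambda L: (self._smoothed(L), -L))

    def penalty(self, length: int) -> float:
        """log2 p(L) / p(mode); -inf outside the support (placement disallowed)."""
        lo, hi = self.support
        if length < lo or length > hi:
            return float("-inf")
        num = self._smoothed(length)
        if num == 0:
            return float("-inf")
        return float(np.log2(num / self._smoothed(self.modal_length)))


def spacer_penalty(model: SpacerModel, length: int) -> float:
    return model.penalty(length)


# ---------------------------------------------------------------------------
# Promoter model and scanning


@dataclass(frozen=True)
class PromoterModel:
    """Full bipartite promoter model: PWM(-35) + spacer penalty + PWM(-10).

    ``up_bonus`` is an optional A/T-richness term for the UP-element region
    upstream of the -35 block: up_bonus * (AT fraction of up to ``up_width``
    bases immediately 5' of the -35 placement). It defaults to off.
    """

    subgroup: int
    pwm35: PWM
    pwm10: PWM
    spacer: SpacerModel
    up_bonus: float = 0.0
    up_width: int = 23

    def __post_init__(self):
        if self.pwm35.width < 4 or self.pwm10.width < 4:
            raise ValidationError("PWM widths must be >= 4")

    @property
    def min_footprint(self) -> int:
        return self.pwm35.width + self.spacer.support[0] + self.pwm10.width

    def consensus_score(self) -> float:
        """Best achievable block score (consensus -35 + consensus -10, modal spacer)."""
        return self.pwm35.max_score + self.pwm10.max_score

    def consensus_sequence(self, spacer: Optional[int] = None, fill: str = "A") -> str:
        L = self.spacer.modal_length if spacer is None else spacer
        return self.pwm35.consensus + fill * L + self.pwm10.consensus


@dataclass(frozen=True)
class PromoterHit:
    """Best-scoring placement of a bipartite model on one sequence."""

    start35: int
    start10: int
    spacer_length: int
    score35: float
    score10: float
    spacer_penalty: float
    up_term: float
    total: float


def _sliding_scores(pwm: PWM, idx: np.ndarray) -> np.ndarray:
    """Score every length-w window of an encoded sequence against a PWM."""
    w = pwm.width
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    return pwm.logodds[np.arange(w), windows].sum(axis=1)


def scan_promoter(model: PromoterModel, seq: str) -> PromoterHit:
    """Maximum-total placement of the bipartite model over a single strand.

    Enumerates every (-35 start, spacer in support) placement; ties are
    broken by smallest -35 start, then smallest spacer, so output is
    deterministic. Promoters are directional: callers reverse-complement
    minus-strand regions before scanning.
    """
    seq = validate_dna(seq, context="promoter scan")
    idx = encode(seq)
    n = len(seq)
    w35, w10 = model.pwm35.width, model.pwm10.width
    lo, hi = model.spacer.support
    if n < w35 + lo + w10:
        raise ValidationError(
            f"sequence length {n} shorter than minimal footprint {w35 + lo + w10}"
        )
    s35 = _sliding_scores(model.pwm35, idx)
    s10 = _sliding_scores(model.pwm10, idx)

    up = np.zeros(len(s35))
    if model.up_bonus != 0.0:
        is_at = np.concatenate([[0.0], np.cumsum((idx == 0) | (idx == 3))])
        for o in range(len(s35)):
            a = max(0, o - model.up_width)
            if o > a:
                up[o] = model.up_bonus * (is_at[o] - is_at[a]) / (o - a)

    best: Optional[PromoterHit] = None
    for spacer in range(lo, hi + 1):
        pen = model.spacer.penalty(spacer)
        if pen == float("-inf"):
            continue
        m = n - (w35 + spacer + w10) + 1
        if m <= 0:
            continue
        totals = s35[:m] + s10[w35 + spacer : w35 + spacer + m] + pen + up[:m]
        o = int(totals.argmax())
        # enforce smallest start35 among numerical ties within this spacer
        ties = np.flatnonzero(totals >= totals[o] - 1e-12)
        o = int(ties[0])
        tot = float(totals[o])
        if (
            best is None
            or tot > best.total + 1e-12
            or (abs(tot - best.total) <= 1e-12 and o < best.start35)
        ):
            best = PromoterHit(
                start35=o,
                start10=o + w35 + spacer,
                spacer_length=spacer,
                score35=float(s35[o]),
                score10=float(s10[o + w35 + spacer]),
                spacer_penalty=pen,
                up_term=float(up[o]),
                total=tot,
            )
    if best is None:
        raise ValidationError("no feasible placement (spacer support outside sequence)")
    return best


# ---------------------------------------------------------------------------
# Two-block Gibbs discovery


@dataclass
class DiscoveryDetails:
    """Diagnostics from discover_two_block (per-restart and final IC)."""

    restart_ic: List[float]
    ic_after_sampling: float
    ic_after_finalize: float
    ic_final: float
    sites35: List[str] = dataclasses.field(default_factory=list)
    sites10: List[str] = dataclasses.field(default_factory=list)


def _placement_tables(enc, w35, w10, lo, hi):
    """Per sequence: arrays of (-35 start, spacer) placements ordered by
    (start, spacer) plus precomputed window base indices for fast scoring."""
    tables = []
    a35 = np.arange(w35)
    a10 = np.arange(w10)
    for e in enc:
        os, Ls = [], []
        for o in range(0, len(e) - (w35 + lo + w10) + 1):
            for L in range(lo, hi + 1):
                if o + w35 + L + w10 <= len(e):
                    os.append(o)
                    Ls.append(L)
        if not os:
            raise ValidationError("sequence too short for the requested footprint")
        os = np.array(os)
        Ls = np.array(Ls)
        win35 = e[os[:, None] + a35]
        win10 = e[(os + w35 + Ls)[:, None] + a10]
        tables.append((os, Ls, win35, win10))
    return tables


class _GibbsState:
    """Mutable site assignment plus incrementally maintained count matrices."""

    def __init__(self, tables, w35, w10, lo, hi, bg, pc, spc_pc):
        self.tables = tables
        self.n = len(tables)
        self.w35, self.w10, self.lo, self.hi = w35, w10, lo, hi
        self.bg, self.pc, self.spc_pc = bg, pc, spc_pc
        self.counts35 = np.zeros((w35, 4))
        self.counts10 = np.zeros((w10, 4))
        self.spc = np.zeros(hi - lo + 1)
        self.state = np.zeros(self.n, dtype=int)
        self._a35 = np.arange(w35)
        self._a10 = np.arange(w10)

    def _delta(self, i, sign):
        os, Ls, win35, win10 = self.tables[i]
        j = self.state[i]
        self.counts35[self._a35, win35[j]] += sign
        self.counts10[self._a10, win10[j]] += sign
        self.spc[Ls[j] - self.lo] += sign

    def set_all(self, assignment):
        self.counts35[:] = 0
        self.counts10[:] = 0
        self.spc[:] = 0
        self.state = np.asarray(assignment, dtype=int).copy()
        for i in range(self.n):
            self._delta(i, +1)

    def scores_without(self, i):
        """Predictive log2 score of every placement of sequence i, with i held out."""
        self._delta(i, -1)
        m = self.n - 1
        p35 = (self.counts35 + self.pc * self.bg) / (m + self.pc)
        p10 = (self.counts10 + self.pc * self.bg) / (m + self.pc)
        lo35 = np.log2(p35 / self.bg)
        lo10 = np.log2(p10 / self.bg)
        spc_p = (self.spc + self.spc_pc) / (m + self.spc_pc * len(self.spc))
        os, Ls, win35, win10 = self.tables[i]
        sc = (
            lo35[self._a35, win35].sum(axis=1)
            + lo10[self._a10, win10].sum(axis=1)
            + np.log2(spc_p[Ls - self.lo])
        )
        return sc

    def assign(self, i, j):
        self.state[i] = j
        self._delta(i, +1)

    def total_ic(self) -> float:
        p35 = (self.counts35 + self.pc * self.bg) / (self.n + self.pc)
        p10 = (self.counts10 + self.pc * self.bg) / (self.n + self.pc)
        ic35 = (p35 * np.log2(p35 / self.bg)).sum()
        ic10 = (p10 * np.log2(p10 / self.bg)).sum()
        return float(ic35 + ic10)

    def sites(self, seqs):
        s35, s10, spacers = [], [], []
        for i, (os, Ls, _, _) in enumerate(self.tables):
            j = self.state[i]
            o, L = int(os[j]), int(Ls[j])
            s35.append(seqs[i][o : o + self.w35])
            s10.append(seqs[i][o + self.w35 + L : o + self.w35 + L + self.w10])
            spacers.append(L)
        return s35, s10, spacers


def _greedy_finalize(st: _GibbsState):
    """Deterministic hill-climb: each sequence takes its argmax placement.

    Passes are only kept while total information content increases, so the
    reported model's IC never drops below its pre-finalisation value.
    """
    best_ic = st.total_ic()
    best_state = st.state.copy()
    for _ in range(30):
        for i in range(st.n):
            sc = st.scores_without(i)
            st.assign(i, int(sc.argmax()))
        ic = st.total_ic()
        if ic > best_ic + 1e-12:
            best_ic = ic
            best_state = st.state.copy()
        else:
            break
    st.set_all(best_state)
    return best_ic


def _phase_polish(st: _GibbsState):
    """Try small coordinated register shifts of all sites; keep improvements.

    Gibbs alignments of gapped motifs commonly converge one or two bases off
    register; shifting every site jointly (whole motif, -10 block only via
    the spacer, or -35 block only) fixes this deterministically.
    """
    def shifted(delta_o, delta_L):
        new = []
        for i, (os, Ls, _, _) in enumerate(st.tables):
            j = st.state[i]
            o, L = int(os[j]) + delta_o, int(Ls[j]) + delta_L
            hits = np.flatnonzero((os == o) & (Ls == L))
            if len(hits) == 0:
                return None
            new.append(int(hits[0]))
        return new

    moves = [(-2, 0), (-1, 0), (1, 0), (2, 0), (0, -1), (0, 1), (-1, 1), (1, -1)]
    for _ in range(6):
        base_ic = st.total_ic()
        best = None
        for do, dL in moves:
            cand = shifted(do, dL)
            if cand is None:
                continue
            saved = st.state.copy()
            st.set_all(cand)
            ic = st.total_ic()
            if ic > base_ic + 1e-9 and (best is None or ic > best[0]):
                best = (ic, cand)
            st.set_all(saved)
        if best is None:
            break
        st.set_all(best[1])
    return st.total_ic()


def discover_two_block(
    seqs: Sequence[str],
    w35: int,
    w10: int,
    spacer_range: Tuple[int, int],
    n_restarts: int = 5,
    iters: int = 150,
    seed: int = 0,
    pseudocount: float = 1.0,
    spacer_pseudocount: float = 1.0,
    background: Optional[np.ndarray] = None,
    subgroup: int = 0,
    return_details: bool = False,
):
    """Discover a two-block gapped motif by collapsed Gibbs sampling.

    One site per sequence; each sweep resamples every sequence's placement
    from the predictive distribution given all other sites. The restart
    with the highest total information content wins; a greedy finalisation
    and register-polish step then sharpen the alignment deterministically.
    Fully reproducible for a fixed seed.
    """
    if len(seqs) < 5:
        raise ValidationError("discover_two_block needs at least 5 sequences")
    lo, hi = spacer_range
    if lo > hi or lo < 0:
        raise ValidationError(f"invalid spacer_range {spacer_range}")
    if w35 < 4 or w10 < 4:
        raise ValidationError("block widths must be >= 4")
    seqs = [validate_dna(s, context=f"sequence {i}") for i, s in enumerate(seqs)]
    footprint = w35 + lo + w10
    if min(len(s) for s in seqs) < footprint:
        raise ValidationError("a sequence is shorter than the minimal footprint")
    enc = [encode(s) for s in seqs]
    if background is None:
        allb = np.concatenate(enc)
        background = np.bincount(allb, minlength=4) / len(allb)
        background = np.clip(background, 1e-3, None)
        background = background / background.sum()
    tables = _placement_tables(enc, w35, w10, lo, hi)

    best = None  # (ic, state snapshot, details)
    restart_ic = []
    for r in range(n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), r]))
        st = _GibbsState(tables, w35, w10, lo, hi, background, pseudocount, spacer_pseudocount)
        st.set_all([rng.integers(len(t[0])) for t in tables])
        for _ in range(iters):
            for i in range(st.n):
                sc = st.scores_without(i)
                w = np.exp2(sc - sc.max())
                st.assign(i, int(rng.choice(len(sc), p=w / w.sum())))
        ic_sampling = st.total_ic()
        ic_greedy = _greedy_finalize(st)
        ic_final = _phase_polish(st)
        restart_ic.append(ic_final)
        if best is None or ic_final > best[0]:
            best = (ic_final, st.state.copy(), ic_sampling, ic_greedy)

    st = _GibbsState(tables, w35, w10, lo, hi, background, pseudocount, spacer_pseudocount)
    st.set_all(best[1])
    sites35, sites10, spacers = st.sites(seqs)
    counts: Dict[int, int] = {}
    for L in spacers:
        counts[L] = counts.get(L, 0) + 1
    model = PromoterModel(
        subgroup=subgroup,
        pwm35=build_pwm(sites35, background, pseudocount),
        pwm10=build_pwm(sites10, background, pseudocount),
        spacer=SpacerModel(counts=counts, pseudocount=spacer_pseudocount, support=(lo, hi)),
    )
    if return_details:
        details = DiscoveryDetails(
            restart_ic=restart_ic,
            ic_after_sampling=best[2],
            ic_after_finalize=best[3],
            ic_final=best[0],
            sites35=sites35,
            sites10=sites10,
        )
        return model, details
    return model
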