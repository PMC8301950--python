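"""RNA secondary-structure services: MFE folding, hairpin decomposition,
miRNA/miRNA* duplex geometry.

Two folding backends satisfy the same contract:

* ``ViennaBackend`` — ViennaRNA's nearest-neighbor model (package default;
  what the miRNA-calling stages use).
* ``StackingBackend`` — a deliberately simple additive stacking model
  (pair-strength stacks, logarithmic hairpin penalties, linear
  bulge/internal penalties, affine multiloops) folded exactly by a
  Zuker-style dynamic program.  Its single source of truth is
  :func:`structure_energy`, which scores *any* structure, so an exhaustive
  enumeration of non-crossing pairings (:func:`enumerate_structures`)
  provides an independent optimality oracle on short sequences.

Coordinates are 0-based inclusive internally; exported JSON/GFF3 use
1-based inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator, Sequence

MIN_LOOP = 3

_LEGAL_PAIRS = {"AU", "UA", "GC", "CG", "GU", "UG"}

# Additive pair strengths: a stack of two pairs contributes the sum of the
# two strengths.  Coarse but ordered like nearest-neighbor tables
# (GC stacks ~ -3.2, AU ~ -1.1, GU weakest).
_PAIR_STRENGTH = {"GC": -1.6, "CG": -1.6, "AU": -0.55, "UA": -0.55,
                  "GU": -0.35, "UG": -0.35}

_ML_CLOSE = 4.6       # multiloop closing penalty
_ML_BRANCH = 0.4      # per branch (incl. closing pair)
_ML_UNPAIRED = 0.1    # per unpaired multiloop base
_INTERIOR_CAP = 30    # max unpaired bases in one bulge/internal loop (DP)


class FoldError(ValueError):
    pass


class GeometryError(ValueError):
    pass


def _check_rna(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    if not seq or set(seq) - set("ACGU"):
        raise FoldError(f"sequence contains non-ACGU characters: {seq!r}")
    return seq


def can_pair(a: str, b: str) -> bool:
    return a + b in _LEGAL_PAIRS


# --------------------------------------------------------------- containers

@dataclass
class FoldResult:
    """A sequence with its predicted structure.

    ``partner[i]`` is the 0-based pairing partner of position ``i`` or -1.
    ``energy`` is in kcal/mol and is <= 0 (0 for the open chain).
    """
    seq: str
    dotbracket: str
    energy: float
    partner: tuple[int, ...]

    @property
    def n_pairs(self) -> int:
        return sum(1 for i, j in enumerate(self.partner) if j > i)

    def vienna(self) -> str:
        return f"{self.seq}\n{self.dotbracket} ({self.energy:.2f})"


@dataclass
class HairpinDecomposition:
    is_single_stem: bool
    arm5: tuple[int, int] | None      # outermost paired pos .. loop-closing pos
    arm3: tuple[int, int] | None
    loop: tuple[int, int] | None      # unpaired terminal-loop interval
    partner: tuple[int, ...]

    def to_dict(self) -> dict:
        one = lambda iv: None if iv is None else [iv[0] + 1, iv[1] + 1]
        return {
            "is_single_stem": self.is_single_stem,
            "arm5": one(self.arm5), "arm3": one(self.arm3),
            "loop": one(self.loop),
            "partner": [p + 1 if p >= 0 else 0 for p in self.partner],
        }


def pairs_to_dotbracket(n: int, partner: Sequence[int]) -> str:
    out = []
    for i, j in enumerate(partner):
        out.append("." if j < 0 else ("(" if j > i else ")"))
    return "".join(out)


def dotbracket_to_pairs(db: str) -> tuple[int, ...]:
    partner = [-1] * len(db)
    stack: list[int] = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            partner[i], partner[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return tuple(partner)


# ------------------------------------------------------- simple energy model

def _hairpin_e(u: int) -> float:
    return 4.5 + 1.6 * math.log(u / 3.0) if u > 3 else 4.5


def _bulge_e(u: int) -> float:
    return 3.3 + 0.55 * u


def _internal_e(u1: int, u2: int) -> float:
    return 2.6 + 0.45 * (u1 + u2) + 0.35 * abs(u1 - u2)


def _stack_e(seq: str, i: int, j: int, k: int, l: int) -> float:
    return _PAIR_STRENGTH[seq[i] + seq[j]] + _PAIR_STRENGTH[seq[k] + seq[l]]


def _interior_e(seq: str, i: int, j: int, k: int, l: int) -> float:
    """Cost of the loop closed by (i,j) with single inner pair (k,l)."""
    u1, u2 = k - i - 1, j - l - 1
    if u1 == 0 and u2 == 0:
        return _stack_e(seq, i, j, k, l)
    if u1 == 0 or u2 == 0:
        return _bulge_e(u1 + u2)
    return _internal_e(u1, u2)


def structure_energy(seq: str, partner: Sequence[int]) -> float:
    """Score an arbitrary (non-crossing) structure under the simple model.

    This is the definition the :class:`StackingBackend` DP minimises and
    the enumeration oracle evaluates; both routes share it.
    """
    seq = _check_rna(seq)
    n = len(seq)
    energy = 0.0
    for i in range(n):
        j = partner[i]
        if j <= i:
            continue
        if not can_pair(seq[i], seq[j]):
            raise ValueError(f"illegal pair {seq[i]}{seq[j]} at ({i},{j})")
        children: list[tuple[int, int]] = []
        unpaired = 0
        k = i + 1
        while k < j:
            if partner[k] > k:
                children.append((k, partner[k]))
                k = partner[k] + 1
            else:
                unpaired += 1
                k += 1
        if not children:
            energy += _hairpin_e(j - i - 1)
        elif len(children) == 1:
            energy += _interior_e(seq, i, j, children[0][0], children[0][1])
        else:
            energy += _ML_CLOSE + _ML_BRANCH * (len(children) + 1) \
                + _ML_UNPAIRED * unpaired
    return round(energy, 6)


def enumerate_structures(seq: str, limit: int | None = None) -> Iterator[tuple[int, ...]]:
    """Yield every non-crossing pairing (min loop 3, legal pairs) as a
    partner tuple.  Exponential; intended for sequences of ~<= 40 nt."""
    seq = _check_rna(seq)
    n = len(seq)
    count = 0

    def rec(i: int, j: int) -> Iterator[tuple[tuple[int, int], ...]]:
        if j - i < MIN_LOOP + 1:
            yield ()
            return
        yield from rec(i + 1, j)
        for k in range(i + MIN_LOOP + 1, j + 1):
            if can_pair(seq[i], seq[k]):
                for inner in rec(i + 1, k - 1):
                    for outer in rec(k + 1, j):
                        yield ((i, k),) + inner + outer

    for pairs in rec(0, n - 1):
        partner = [-1] * n
        for a, b in pairs:
            partner[a], partner[b] = b, a
        yield tuple(partner)
        count += 1
        if limit is not None and count >= limit:
            return


def brute_force_mfe(seq: str) -> tuple[float, tuple[int, ...]]:
    """Minimum energy over *all* enumerated structures (independent oracle)."""
    seq = _check_rna(seq)
    best_e, best_p = 0.0, tuple([-1] * len(seq))
    for partner in enumerate_structures(seq):
        e = structure_energy(seq, partner)
        if e < best_e - 1e-9:
            best_e, best_p = e, partner
    return best_e, best_p


def _loop_energy(seq: str, i: int, j: int,
                 children: Sequence[tuple[int, int]]) -> float:
    """Energy of the loop closed by pair (i, j) given its direct children."""
    if not children:
        return _hairpin_e(j - i - 1)
    if len(children) == 1:
        return _interior_e(seq, i, j, children[0][0], children[0][1])
    unpaired = (j - i - 1) - sum(b - a + 1 for a, b in children)
    return _ML_CLOSE + _ML_BRANCH * (len(children) + 1) + _ML_UNPAIRED * unpaired


def oracle_min_energy(seq: str) -> float:
    """Exhaustive-enumeration minimum energy, accumulated incrementally.

    Walks every non-crossing pairing exactly once and scores each loop with
    the same primitives as :func:`structure_energy`; no interval memoisation
    or Zuker recursion is involved, so it is an independent check of the
    :class:`StackingBackend` DP.  Cost is proportional to the number of
    structures — gate long sequences with :func:`count_structures`.
    """
    seq = _check_rna(seq)
    n = len(seq)

    def rec(i: int, j: int) -> Iterator[tuple[tuple[tuple[int, int], ...], float]]:
        """Yield (top-level branch spans, total energy of pairs within)."""
        if j - i < MIN_LOOP + 1:
            yield ((), 0.0)
            return
        yield from rec(i + 1, j)
        for k in range(i + MIN_LOOP + 1, j + 1):
            if can_pair(seq[i], seq[k]):
                for cin, ein in rec(i + 1, k - 1):
                    base = ein + _loop_energy(seq, i, k, cin)
                    span = ((i, k),)
                    for cout, eout in rec(k + 1, j):
                        yield (span + cout, base + eout)

    best = 0.0
    for _, e in rec(0, n - 1):
        if e < best:
            best = e
    return round(best, 6)


def count_structures(seq: str) -> int:
    """Number of non-crossing pairings (min loop 3) of ``seq``."""
    seq = _check_rna(seq)
    n = len(seq)
    memo: dict[tuple[int, int], int] = {}

    def c(i: int, j: int) -> int:
        if j - i < MIN_LOOP + 1:
            return 1
        key = (i, j)
        if key in memo:
            return memo[key]
        tot = c(i + 1, j)
        for k in range(i + MIN_LOOP + 1, j + 1):
            if can_pair(seq[i], seq[k]):
                tot += c(i + 1, k - 1) * c(k + 1, j)
        memo[key] = tot
        return tot

    return c(0, n - 1)


def sample_structures(seq: str, k: int, rng) -> Iterator[tuple[int, ...]]:
    """Draw ``k`` structures uniformly at random (with replacement) from the
    full non-crossing structure space, by unranking against the counting DP.
    """
    seq = _check_rna(seq)
    n = len(seq)
    memo: dict[tuple[int, int], int] = {}

    def c(i: int, j: int) -> int:
        if j - i < MIN_LOOP + 1:
            return 1
        key = (i, j)
        if key not in memo:
            tot = c(i + 1, j)
            for m in range(i + MIN_LOOP + 1, j + 1):
                if can_pair(seq[i], seq[m]):
                    tot += c(i + 1, m - 1) * c(m + 1, j)
            memo[key] = tot
        return memo[key]

    def unrank(i: int, j: int, r: int) -> list[tuple[int, int]]:
        if j - i < MIN_LOOP + 1:
            return []
        c1 = c(i + 1, j)
        if r < c1:
            return unrank(i + 1, j, r)
        r -= c1
        for m in range(i + MIN_LOOP + 1, j + 1):
            if can_pair(seq[i], seq[m]):
                cin, cout = c(i + 1, m - 1), c(m + 1, j)
                block = cin * cout
                if r < block:
                    rin, rout = divmod(r, cout)
                    return [(i, m)] + unrank(i + 1, m - 1, rin) + unrank(m + 1, j, rout)
                r -= block
        raise AssertionError("unrank out of range")  # pragma: no cover

    total = c(0, n - 1)
    for _ in range(k):
        r = int(rng.integers(total)) if total < 2**63 else rng.integers(0, total)
        pairs = unrank(0, n - 1, int(r))
        partner = [-1] * n
        for a, b in pairs:
            partner[a], partner[b] = b, a
        yield tuple(partner)


# ------------------------------------------------------------------ backends

class StackingBackend:
    """Exact MFE under the simple model via a Zuker-style DP (O(n^4)).

    Interior loops are capped at 30 unpaired bases, which cannot exclude
    the optimum on the short sequences this backend targets (the loop
    penalty alone exceeds any attainable stabilisation of the remainder).
    """

    name = "stacking"

    def fold(self, seq: str) -> FoldResult:
        seq = _check_rna(seq)
        n = len(seq)
        INF = float("inf")
        V = [[INF] * n for _ in range(n)]
        M = [[INF] * n for _ in range(n)]   # >=1 branch, multiloop interior
        M2 = [[INF] * n for _ in range(n)]  # >=2 branches

        pairable = [[can_pair(seq[i], seq[j]) and j - i > MIN_LOOP
                     for j in range(n)] for i in range(n)]

        for span in range(MIN_LOOP + 1, n):
            for i in range(0, n - span):
                j = i + span
                # --- V
                if pairable[i][j]:
                    best = _hairpin_e(j - i - 1)
                    for k in range(i + 1, j):
                        if k - i - 1 > _INTERIOR_CAP:
                            break
                        for l in range(max(k + MIN_LOOP + 1,
                                           j - 1 - _INTERIOR_CAP + (k - i - 1)), j):
                            if pairable[k][l] and V[k][l] < INF:
                                e = V[k][l] + _interior_e(seq, i, j, k, l)
                                if e < best:
                                    best = e
                    if M2[i + 1][j - 1] < INF:
                        e = _ML_CLOSE + _ML_BRANCH + M2[i + 1][j - 1]
                        if e < best:
                            best = e
                    V[i][j] = best
                # --- M / M2
                bm, bm2 = INF, INF
                if j > i:
                    if M[i][j - 1] < INF:
                        bm = M[i][j - 1] + _ML_UNPAIRED
                    if M2[i][j - 1] < INF:
                        bm2 = M2[i][j - 1] + _ML_UNPAIRED
                for k in range(i, j - MIN_LOOP):
                    if pairable[k][j] and V[k][j] < INF:
                        branch = V[k][j] + _ML_BRANCH
                        e = branch + _ML_UNPAIRED * (k - i)
                        if e < bm:
                            bm = e
                        if k > i and M[i][k - 1] < INF:
                            e = M[i][k - 1] + branch
                            if e < bm:
                                bm = e
                            if e < bm2:
                                bm2 = e
                M[i][j], M2[i][j] = bm, bm2

        W = [0.0] * (n + 1)  # W[j+1] = best over prefix 0..j
        for j in range(n):
            best = W[j]
            for k in range(0, j - MIN_LOOP):
                if pairable[k][j] and V[k][j] < INF:
                    e = W[k] + V[k][j]
                    if e < best:
                        best = e
            W[j + 1] = best

        energy = min(0.0, W[n])
        partner = [-1] * n
        if energy < 0.0:
            self._trace_w(seq, V, M, M2, W, n - 1, partner)
        db = pairs_to_dotbracket(n, partner)
        return FoldResult(seq, db, round(energy, 6), tuple(partner))

    # traceback helpers -----------------------------------------------------
    def _trace_w(self, seq, V, M, M2, W, j, partner):
        while j >= 0:
            if abs(W[j + 1] - W[j]) < 1e-9:
                j -= 1
                continue
            for k in range(0, j - MIN_LOOP):
                if V[k][j] < float("inf") and abs(W[j + 1] - (W[k] + V[k][j])) < 1e-9:
                    self._trace_v(seq, V, M, M2, k, j, partner)
                    j = k - 1
                    break
            else:  # pragma: no cover - defensive
                j -= 1

    def _trace_v(self, seq, V, M, M2, i, j, partner):
        partner[i], partner[j] = j, i
        target = V[i][j]
        if abs(target - _hairpin_e(j - i - 1)) < 1e-9:
            return
        for k in range(i + 1, j):
            if k - i - 1 > _INTERIOR_CAP:
                break
            for l in range(k + MIN_LOOP + 1, j):
                if j - 1 - l > _INTERIOR_CAP - (k - i - 1):
                    continue
                if V[k][l] < float("inf") and \
                        abs(target - (V[k][l] + _interior_e(seq, i, j, k, l))) < 1e-9:
                    self._trace_v(seq, V, M, M2, k, l, partner)
                    return
        if M2[i + 1][j - 1] < float("inf") and \
                abs(target - (_ML_CLOSE + _ML_BRANCH + M2[i + 1][j - 1])) < 1e-9:
            self._trace_m(seq, V, M, M2, i + 1, j - 1, partner, need_two=True)
            return
        raise AssertionError("traceback failed")  # pragma: no cover

    def _trace_m(self, seq, V, M, M2, i, j, partner, need_two=False):
        tab = M2 if need_two else M
        target = tab[i][j]
        if j > i and (M2 if need_two else M)[i][j - 1] < float("inf") and \
                abs(target - (tab[i][j - 1] + _ML_UNPAIRED)) < 1e-9:
            self._trace_m(seq, V, M, M2, i, j - 1, partner, need_two)
            return
        for k in range(i, j - MIN_LOOP):
            if not (V[k][j] < float("inf")):
                continue
            branch = V[k][j] + _ML_BRANCH
            if not need_two and abs(target - (branch + _ML_UNPAIRED * (k - i))) < 1e-9:
                self._trace_v(seq, V, M, M2, k, j, partner)
                return
            if k > i and M[i][k - 1] < float("inf") and \
                    abs(target - (M[i][k - 1] + branch)) < 1e-9:
                self._trace_m(seq, V, M, M2, i, k - 1, partner, need_two=False)
                self._trace_v(seq, V, M, M2, k, j, partner)
                return
        raise AssertionError("traceback failed")  # pragma: no cover


class ViennaBackend:
    """MFE folding through the ViennaRNA python bindings."""

    name = "vienna"

    def fold(self, seq: str) -> FoldResult:
        import RNA
        seq = _check_rna(seq)
        db, energy = RNA.fold(seq)
        if energy >= 0.0:
            return FoldResult(seq, "." * len(seq), 0.0, tuple([-1] * len(seq)))
        return FoldResult(seq, db, round(float(energy), 6), dotbracket_to_pairs(db))


_BACKENDS = {"vienna": ViennaBackend, "stacking": StackingBackend}


@lru_cache(maxsize=4)
def get_backend(name: str = "vienna"):
    try:
        return _BACKENDS[name]()
    except KeyError:
        raise ValueError(f"unknown folding backend {name!r}") from None


def fold(seq: str, backend: str | object = "vienna") -> FoldResult:
    """Fold an RNA (or T-form DNA) sequence to its MFE structure.

    Sequences shorter than 15 nt are refused: they cannot host a
    miRNA-bearing hairpin and usually signal a caller bug.
    """
    seq = _check_rna(seq)
    if len(seq) < 15:
        raise FoldError(f"sequence too short to fold ({len(seq)} < 15 nt)")
    be = get_backend(backend) if isinstance(backend, str) else backend
    return be.fold(seq)


# ------------------------------------------------------- hairpin geometry

def decompose_hairpin(fr: FoldResult) -> HairpinDecomposition:
    """Classify a fold as a single-stem hairpin and locate its arms.

    A structure is a single stem iff it contains exactly one terminal
    (hairpin) loop; multiloops, side stems and open chains all fail.
    """
    partner = fr.partner
    n = len(partner)
    paired = [i for i in range(n) if partner[i] >= 0]
    loops = []
    for i in paired:
        j = partner[i]
        if j > i and all(partner[k] < 0 for k in range(i + 1, j)):
            loops.append((i, j))
    if len(loops) != 1:
        return HairpinDecomposition(False, None, None, None, partner)
    a, b = loops[0]
    p0 = paired[0]
    pn = paired[-1]
    if partner[p0] != pn:  # paired region not fully nested in one stem
        return HairpinDecomposition(False, None, None, None, partner)
    return HairpinDecomposition(True, (p0, a), (b, pn), (a + 1, b - 1), partner)


def _mature_arm(mature: tuple[int, int], decomp: HairpinDecomposition) -> str:
    """'5p' / '3p' if the mature sits in one arm, else GeometryError."""
    if not decomp.is_single_stem:
        raise GeometryError("structure is not a single-stem hairpin")
    ms, me = mature
    partner = decomp.partner
    paired = [i for i in range(ms, me + 1) if partner[i] >= 0]
    if not paired:
        raise GeometryError("mature has no paired base (lies in the loop)")
    a5s, a5e = decomp.arm5
    a3s, a3e = decomp.arm3
    if all(a5s <= i <= a5e for i in paired) and me <= decomp.loop[1]:
        return "5p"
    if all(a3s <= i <= a3e for i in paired) and ms >= decomp.loop[0]:
        return "3p"
    raise GeometryError("mature spans the terminal loop")


def duplex_overhang(mature: tuple[int, int], decomp: HairpinDecomposition,
                    window_end: int | None = None
                    ) -> tuple[tuple[int, int], int, int]:
    """Realized miRNA/miRNA* duplex overhangs.

    Returns ``(star_interval, overhang_at_mature_5p_end,
    overhang_at_mature_3p_end)``.  At the loop-side end the overhang is the
    number of mature bases past its outermost pair.  At the base-side end
    the star's 3' tail is not directly observable, so the star is taken to
    extend up to 2 nt past its last pair provided those bases are unpaired
    (a paired continuation leaves no room for an overhang); unpaired mature
    lead-in shifts the register and is added.  A canonical Dicer duplex
    yields (2, 2).
    """
    arm = _mature_arm(mature, decomp)
    partner = decomp.partner
    n = len(partner)
    if window_end is None:
        window_end = n - 1
    ms, me = mature
    paired = [i for i in range(ms, me + 1) if partner[i] >= 0]
    a, b = paired[0], paired[-1]
    if arm == "5p":
        o_loop = me - b                      # mature 3' side
        t = 0
        k = partner[a] + 1
        while k <= window_end and partner[k] < 0 and t < 2:
            t += 1
            k += 1
        o_base = (a - ms) + t                # mature 5' side (star 3' tail)
        star = (partner[b], partner[a] + t)
        return star, o_base, o_loop
    o_loop = a - ms                          # mature 5' side
    t = 0
    k = partner[b] - 1
    while k >= 0 and partner[k] < 0 and t < 2:
        t += 1
        k -= 1
    o_base = (me - b) + t                    # mature 3' side
    star = (partner[b] - t, partner[a])
    return star, o_loop, o_base


def max_defect(mature: tuple[int, int], star: tuple[int, int],
               partner: Sequence[int]) -> tuple[int, int]:
    """Largest internal loop and largest one-sided bulge within the
    mature/star duplex (sizes in nt; internal-loop size = larger side)."""
    ms, me = mature
    paired = [i for i in range(ms, me + 1) if partner[i] >= 0]
    worst_internal = worst_bulge = 0
    for p, q in zip(paired, paired[1:]):
        um = q - p - 1
        us = abs(partner[p] - partner[q]) - 1
        if um > 0 and us > 0:
            worst_internal = max(worst_internal, max(um, us))
        elif um > 0 or us > 0:
            worst_bulge = max(worst_bulge, um + us)
    return worst_internal, worst_bulge
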