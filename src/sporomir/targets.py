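"""miRNA target prediction by complementarity expectation scoring.

A target site is scored by aligning the miRNA (5'->3') against the site in
antiparallel orientation: perfect Watson-Crick pairs cost 0, G:U wobbles
0.5, other mismatches 1, gaps 2 to open and 1 to extend, and every
substitution or miRNA-side gap is doubled when the miRNA position falls in
the seed region (positions 2-7 from the 5' end).  The expectation score is
the minimal total cost; sites at or below the cutoff (default 3) are
reported.  A site is classed as *translation inhibition* when the duplex
is disrupted (mismatch or gap) across the central cleavage positions
10-11, and as *cleavage* otherwise.

The alignment is a semiglobal affine-gap dynamic program (target ends
free, miRNA fully consumed), vectorised row-wise; an exhaustive ungapped
position-wise scan is provided both as a fast screen and as an oracle
surface for validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .seqio import revcomp, to_rna

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}


class TargetDesignError(ValueError):
    """A requested site score/mode has no legal edit pattern."""


@dataclass
class ScoringConfig:
    cutoff: float = 3.0
    seed_start: int = 2          # miRNA positions, 1-based from the 5' end
    seed_end: int = 7
    hsp_len: int = 19
    gap_open: float = 2.0
    gap_extend: float = 1.0
    mismatch: float = 1.0
    gu_wobble: float = 0.5
    seed_multiplier: float = 2.0
    central: tuple[int, int] = (10, 11)

    def validate(self, mirna_len: int | None = None) -> None:
        if min(self.gap_open, self.gap_extend, self.mismatch,
               self.gu_wobble) < 0:
            raise ValueError("penalties must be non-negative")
        if self.seed_start > self.seed_end:
            raise ValueError("empty seed interval")
        if mirna_len is not None and self.seed_end > mirna_len:
            raise ValueError("seed interval exceeds miRNA length")


@dataclass
class TargetAlignment:
    expectation: float
    site_start: int              # 1-based on the scored sequence
    site_end: int
    mirna_aln: str               # miRNA 5'->3'
    pair_aln: str                # '|' WC, 'o' G:U, ' ' mismatch, '-' gap
    target_aln: str              # target 3'->5' under the miRNA
    mirna_states: list           # per miRNA position: 'wc'|'gu'|'mm'|'gap'


@dataclass
class TargetModule:
    mirna_id: str
    gene_id: str
    site_start: int
    site_end: int
    expectation: float
    mode: str
    alignment: TargetAlignment


def pair_cost(m_base: str, t_base: str, cfg: ScoringConfig) -> float:
    """Unweighted cost of pairing one miRNA base with one target base."""
    pair = m_base + t_base
    if pair in ("AU", "UA", "GC", "CG"):
        return 0.0
    if pair in ("GU", "UG"):
        return cfg.gu_wobble
    return cfg.mismatch


def _multipliers(m: int, cfg: ScoringConfig) -> np.ndarray:
    mult = np.ones(m)
    mult[cfg.seed_start - 1:cfg.seed_end] = cfg.seed_multiplier
    return mult


def _cost_rows(mirna: str, target_rev: str, cfg: ScoringConfig) -> np.ndarray:
    """cost[i, j] of pairing miRNA position i+1 with reversed-target j."""
    lut = np.empty((4, 4))
    for a, ca in _CODE.items():
        for b, cb in _CODE.items():
            lut[ca, cb] = pair_cost(a, b, cfg)
    mi = np.array([_CODE[c] for c in mirna])
    tj = np.array([_CODE[c] for c in target_rev])
    return lut[mi][:, tj] * _multipliers(len(mirna), cfg)[:, None]


def _semiglobal(mirna: str, target_rev: str, cfg: ScoringConfig,
                gaps: bool = True):
    """Gotoh DP: miRNA global, target local.  Returns (M, X, Y, cost)."""
    m, L = len(mirna), len(target_rev)
    INF = 1e18
    cost = _cost_rows(mirna, target_rev, cfg)
    mult = _multipliers(m, cfg)
    M = np.full((m + 1, L + 1), INF)
    X = np.full((m + 1, L + 1), INF)
    Y = np.full((m + 1, L + 1), INF)
    M[0, :] = 0.0                      # free target prefix
    for i in range(1, m + 1):
        prev_best = np.minimum(np.minimum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = cost[i - 1] + prev_best[:-1]
        if gaps:
            go = cfg.gap_open * mult[i - 1]
            ge = cfg.gap_extend * mult[i - 1]
            Y[i] = np.minimum(M[i - 1] + go, Y[i - 1] + ge)
            # X[i, j] = min(M[i, j-1] + open, X[i, j-1] + extend)
            ext = cfg.gap_extend
            j_idx = np.arange(L + 1)
            shifted = np.minimum.accumulate(M[i, :-1] - ext * j_idx[:-1])
            X[i, 1:] = shifted + ext * j_idx[1:] + cfg.gap_open - ext
    return M, X, Y, cost


def _traceback(mirna: str, target_rev: str, cfg: ScoringConfig,
               M, X, Y, cost, j_end: int) -> TargetAlignment:
    m, L = len(mirna), len(target_rev)
    mult = _multipliers(m, cfg)
    i, j = m, j_end
    state = "M" if M[i, j] <= Y[i, j] else "Y"
    cols = []                     # (mirna char or '-', target char or '-')
    eps = 1e-9
    while i > 0:
        if state == "M":
            cols.append((mirna[i - 1], target_rev[j - 1]))
            prevs = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            best = min(prevs)
            state = "MXY"[prevs.index(best)]
            i, j = i - 1, j - 1
        elif state == "Y":        # miRNA base unpaired
            cols.append((mirna[i - 1], "-"))
            go = cfg.gap_open * mult[i - 1]
            ge = cfg.gap_extend * mult[i - 1]
            state = "M" if abs(Y[i, j] - (M[i - 1, j] + go)) < eps else "Y"
            i -= 1
        else:                     # X: target base inserted
            cols.append(("-", target_rev[j - 1]))
            state = ("M" if abs(X[i, j] - (M[i, j - 1] + cfg.gap_open)) < eps
                     else "X")
            j -= 1
    j_start = j                   # alignment spans target_rev[j_start..j_end-1]
    cols.reverse()
    mirna_aln = "".join(c[0] for c in cols)
    target_aln = "".join(c[1] for c in cols)
    pair, states = [], []
    for mc, tc in cols:
        if mc == "-" or tc == "-":
            pair.append("-")
            if mc != "-":
                states.append("gap")
        else:
            c = pair_cost(mc, tc, cfg)
            pair.append("|" if c == 0 else ("o" if c == cfg.gu_wobble else " "))
            states.append("wc" if c == 0
                          else ("gu" if c == cfg.gu_wobble else "mm"))
    # reversed-target cols [j_start+1 .. j_end] (1-based) -> original coords
    site_start = L - j_end + 1
    site_end = L - j_start
    return TargetAlignment(0.0, site_start, site_end, mirna_aln,
                           "".join(pair), target_aln, states)


def score_alignment(mirna: str, site: str, cfg: ScoringConfig | None = None,
                    gaps: bool = True) -> TargetAlignment | None:
    """Optimal expectation score of a miRNA against one candidate site.

    Returns ``None`` when the site is shorter than the complementarity-
    scoring span (``hsp_len``); otherwise a :class:`TargetAlignment` whose
    ``expectation`` is the minimal total penalty.
    """
    cfg = cfg or ScoringConfig()
    mirna = to_rna(mirna)
    site = to_rna(site)
    cfg.validate(len(mirna))
    if len(site) < cfg.hsp_len:
        return None
    rev = site[::-1]
    M, X, Y, cost = _semiglobal(mirna, rev, cfg, gaps)
    end = np.minimum(M[len(mirna)], Y[len(mirna)])
    j_end = int(np.argmin(end))
    aln = _traceback(mirna, rev, cfg, M, X, Y, cost, j_end)
    aln.expectation = round(float(end[j_end]), 6)
    return aln


def ungapped_score(mirna: str, site: str, cfg: ScoringConfig | None = None
                   ) -> float:
    """Position-wise score of an equal-length, gap-free duplex (oracle)."""
    cfg = cfg or ScoringConfig()
    mirna = to_rna(mirna)
    site = to_rna(site)
    if len(mirna) != len(site):
        raise ValueError("ungapped scoring needs equal lengths")
    total = 0.0
    for p, mc in enumerate(mirna, start=1):
        tc = site[len(site) - p]          # antiparallel partner
        c = pair_cost(mc, tc, cfg)
        if cfg.seed_start <= p <= cfg.seed_end:
            c *= cfg.seed_multiplier
        total += c
    return round(total, 6)


def ungapped_scan(mirna: str, transcript: str,
                  cfg: ScoringConfig | None = None,
                  max_score: float | None = None) -> list[tuple[int, float]]:
    """All ungapped windows scoring <= cutoff: (1-based start, score)."""
    cfg = cfg or ScoringConfig()
    limit = cfg.cutoff if max_score is None else max_score
    mirna_r = to_rna(mirna)
    tr = to_rna(transcript)
    m, L = len(mirna_r), len(tr)
    if L < m:
        return []
    cost = _cost_rows(mirna_r, tr[::-1], cfg)       # [i, j] over reversed tr
    S = L - m + 1
    totals = np.zeros(S)
    for i in range(m):
        # window starting at s (0-based): miRNA i+1 pairs tr[s+m-1-i],
        # i.e. reversed-tr index L-1-(s+m-1-i)
        row = cost[i, ::-1]                          # back to tr orientation
        totals += row[m - 1 - i: m - 1 - i + S]
    hits = np.flatnonzero(totals <= limit + 1e-9)
    return [(int(s) + 1, round(float(totals[s]), 6)) for s in hits]


def classify_mode(alignment: TargetAlignment,
                  cfg: ScoringConfig | None = None) -> str:
    """Cleavage unless the duplex is disrupted at the central positions."""
    cfg = cfg or ScoringConfig()
    for p in cfg.central:
        if p <= len(alignment.mirna_states) and \
                alignment.mirna_states[p - 1] in ("mm", "gap"):
            return "translation_inhibition"
    return "cleavage"


def scan_transcript(mirna: str, transcript: str,
                    cfg: ScoringConfig | None = None,
                    mirna_id: str = "", gene_id: str = ""
                    ) -> list[TargetModule]:
    """All non-overlapping sites with expectation <= cutoff on a transcript.

    Sites are selected greedily best-score-first with a leftmost tie-break.
    Gapped alignments are searched in full when the cutoff could admit a
    gap (cutoff >= gap_open); candidate regions are pre-screened with the
    exhaustive ungapped scan plus a gap allowance.
    """
    cfg = cfg or ScoringConfig()
    mirna_rna = to_rna(mirna)
    tr = to_rna(transcript)
    m = len(mirna_rna)
    if len(tr) < cfg.hsp_len:
        return []
    gap_allow = cfg.gap_open + 2 * cfg.gap_extend
    pre = ungapped_scan(mirna_rna, tr, cfg, max_score=cfg.cutoff + gap_allow)
    pad = 3
    candidates = []
    for s1, _score in pre:
        lo = max(0, s1 - 1 - pad)
        hi = min(len(tr), s1 - 1 + m + pad)
        aln = score_alignment(mirna_rna, tr[lo:hi], cfg, gaps=True)
        if aln is None or aln.expectation > cfg.cutoff + 1e-9:
            continue
        start = lo + aln.site_start
        end = lo + aln.site_end
        candidates.append((aln.expectation, start, end, aln))
    # greedy non-overlapping selection, best score first then leftmost
    candidates.sort(key=lambda c: (c[0], c[1]))
    chosen: list[TargetModule] = []
    occupied: list[tuple[int, int]] = []
    for exp, start, end, aln in candidates:
        if any(not (end < s or start > e) for s, e in occupied):
            continue
        aln.site_start, aln.site_end = start, end
        chosen.append(TargetModule(mirna_id, gene_id, start, end, exp,
                                   classify_mode(aln, cfg), aln))
        occupied.append((start, end))
    chosen.sort(key=lambda t: t.site_start)
    return chosen


def predict_targets(dems: dict[str, str], transcriptome: dict[str, str],
                    cfg: ScoringConfig | None = None
                    ) -> tuple[pd.DataFrame, dict]:
    """Scan every transcript with every miRNA; classify inhibition modes.

    ``dems`` maps miRNA id -> mature sequence.  Returns the module table
    and a summary (genes, modules, per-mode counts).
    """
    cfg = cfg or ScoringConfig()
    rows = []
    for mid, mature in sorted(dems.items()):
        for gene, seq in transcriptome.items():
            for mod in scan_transcript(mature, seq, cfg, mid, gene):
                rows.append(dict(
                    mirna_id=mid, gene_id=gene, site_start=mod.site_start,
                    site_end=mod.site_end, expectation=mod.expectation,
                    mode=mod.mode, mirna_aln=mod.alignment.mirna_aln,
                    pairing=mod.alignment.pair_aln,
                    target_aln=mod.alignment.target_aln))
    table = pd.DataFrame(rows, columns=["mirna_id", "gene_id", "site_start",
                                        "site_end", "expectation", "mode",
                                        "mirna_aln", "pairing", "target_aln"])
    summary = {
        "n_modules": len(table),
        "n_genes": int(table.gene_id.nunique()) if len(table) else 0,
        "n_mirnas": int(table.mirna_id.nunique()) if len(table) else 0,
        "n_cleavage": int((table["mode"] == "cleavage").sum()) if len(table) else 0,
        "n_translation_inhibition":
            int((table["mode"] == "translation_inhibition").sum())
            if len(table) else 0,
    }
    return table, summary


# ----------------------------------------------------------- site designer

_EDIT_POSITIONS = (15, 17, 13, 9, 19, 14, 16, 12, 18, 8, 20)


def build_site(mature: str, score: float, mode: str,
               cfg: ScoringConfig | None = None, rng=None) -> str:
    """Design a target site (transcript sense, 5'->3') whose expectation
    against ``mature`` is exactly ``score`` and whose central pairing
    matches ``mode``.

    Starts from the perfect reverse complement and applies non-seed edits:
    mismatches cost 1, G:U wobbles 0.5; translation-inhibition designs put
    one mismatch at central position 10 and therefore need score >= 1.
    Raises :class:`TargetDesignError` when no legal edit pattern exists.
    """
    cfg = cfg or ScoringConfig()
    m = len(mature)
    if round(score * 2) != score * 2 or not 0 <= score <= cfg.cutoff:
        raise TargetDesignError(f"score {score} not reachable in 0.5 steps "
                                f"within the cutoff")
    central = set(cfg.central)
    site = list(revcomp(mature))          # DNA, site[0] pairs mature 3' end

    def site_idx(p: int) -> int:          # miRNA position -> site index
        return m - p

    edits: list[tuple[str, int]] = []
    remaining = score
    used: set[int] = set()
    if mode == "translation_inhibition":
        if remaining < cfg.mismatch:
            raise TargetDesignError(
                "translation-inhibition sites need a central defect "
                f"(score >= {cfg.mismatch})")
        p = cfg.central[0]
        edits.append(("mm", p))
        used.add(p)
        remaining -= cfg.mismatch
    elif mode != "cleavage":
        raise TargetDesignError(f"unknown mode {mode!r}")

    cand = [p for p in _EDIT_POSITIONS
            if p <= m - 1 and p > cfg.seed_end and p not in central]
    n_mm = int(remaining // cfg.mismatch)
    half = remaining - n_mm * cfg.mismatch
    for _ in range(n_mm):
        free = [p for p in cand if p not in used]
        if not free:
            raise TargetDesignError("not enough editable positions")
        p = free[0]
        edits.append(("mm", p))
        used.add(p)
    if half > 1e-9:
        gu_ok = [p for p in cand + [c for c in sorted(central)
                                    if mode == "cleavage" and c <= m - 1]
                 if p not in used and mature[p - 1] in "GT"]
        if not gu_ok:
            raise TargetDesignError("no G/U-capable position for a 0.5 edit")
        edits.append(("gu", gu_ok[0]))
        used.add(gu_ok[0])

    for kind, p in edits:
        b = mature[p - 1]
        if kind == "mm":
            site[site_idx(p)] = b          # X:X never pairs, never wobbles
        else:
            site[site_idx(p)] = "T" if b == "G" else "G"
    return "".join(site)
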