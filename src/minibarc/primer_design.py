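"""Primer design on conserved anchor windows.

Pipeline: merge zero-diversity windows into maximal conserved stretches,
enumerate candidate oligos from the stretch consensus, annotate GC /
melting temperature / secondary-structure scores, pair forward and
reverse candidates under amplicon-length and compatibility constraints,
and rank pairs by the information content (variable sites) of the
inter-primer region.

The duplex scores are simple ungapped complementarity maxima (match +1,
mismatch -1, a matched 3'-terminal base counts double); they are screening
heuristics, not thermodynamic foldings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .diversity import WindowTable
from .errors import GeneLookupError, MinibarcError
from .seqio import GeneAlignment, revcomp

_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}


# ---------------------------------------------------------------------------
# elementary metrics
# ---------------------------------------------------------------------------

def gc_content(seq: str) -> float:
    """G+C percentage, rounded to 1 decimal. Degenerate bases are an error."""
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq.upper()) - set("ACGT")
    if bad:
        raise MinibarcError(
            f"gc_content: non-canonical base(s) {sorted(bad)} — "
            "candidates are never degenerate"
        )
    s = seq.upper()
    return round(100.0 * (s.count("G") + s.count("C")) / len(s), 1)


def melting_temp(seq: str, method: str = "nn",
                 na_mM: float = 50.0, oligo_nM: float = 250.0) -> float:
    """Melting temperature in degrees C.

    method="wallace": 2(A+T) + 4(G+C).
    method="nn": unified nearest-neighbor parameters (SantaLucia-style)
    with monovalent-salt correction at the given Na+ and oligo
    concentrations.
    """
    s = seq.upper()
    if set(s) - set("ACGT"):
        raise MinibarcError(f"melting_temp: non-canonical base in {seq!r}")
    if method == "wallace":
        return float(2 * (s.count("A") + s.count("T"))
                     + 4 * (s.count("G") + s.count("C")))
    if method == "nn":
        if len(s) < 8:
            raise MinibarcError("nearest-neighbor Tm needs length >= 8")
        from Bio.SeqUtils import MeltingTemp as mt
        return float(mt.Tm_NN(s, nn_table=mt.DNA_NN3,
                              Na=na_mM, dnac1=oligo_nM, dnac2=0))
    raise MinibarcError(f"unknown Tm method {method!r}")


def max_homopolymer(seq: str) -> int:
    return max((len(m.group(0)) for m in re.finditer(r"(.)\1*", seq)), default=0)


def _duplex_best(a: str, b: str) -> float:
    """Best ungapped antiparallel complementarity score of a vs b.

    For every offset, b is laid 3'->5' against a (5'->3'); each
    complementary pair scores +1, each non-pair -1, summed over the
    overlap. A matched pair involving the 3'-terminal base of either
    oligo gains +1 (i.e. weight x2). Returns the maximum over offsets.
    """
    la, lb = len(a), len(b)
    best = float("-inf")
    for k in range(-(lb - 1), la):
        score = 0.0
        lo, hi = max(0, k), min(la, k + lb)
        if lo >= hi:
            continue
        for i in range(lo, hi):
            j = lb - 1 - (i - k)  # index on b (antiparallel)
            if _PAIR.get(a[i]) == b[j]:
                score += 1.0
                if i == la - 1:
                    score += 1.0
                if j == lb - 1:
                    score += 1.0
            else:
                score -= 1.0
        best = max(best, score)
    return best


def self_dimer_score(seq: str) -> float:
    """Self-annealing score (higher = worse)."""
    return _duplex_best(seq.upper(), seq.upper())


def cross_dimer_score(a: str, b: str) -> float:
    """Primer-primer annealing score; symmetric in its arguments."""
    return _duplex_best(a.upper(), b.upper())


def hairpin_score(seq: str, loop_min: int = 3) -> float:
    """Best self-folding stem score with a minimum loop of `loop_min`.

    Pairs position i with position j (i < j, j - i - 1 >= loop_min);
    contiguous stems score +1 per complementary pair and -1 otherwise
    (best contiguous run per fold diagonal); a stem pair using the
    3'-terminal base counts double. Returns max over folds (>= 0).
    """
    s = seq.upper()
    L = len(s)
    best = 0.0
    for c in range(2 * L - 1):  # i + j = c
        run = 0.0
        diag_best = 0.0
        i_lo = max(0, c - L + 1)
        i_hi = (c - loop_min - 1) // 2  # i < j - loop_min, j = c - i
        for i in range(i_lo, i_hi + 1):
            j = c - i
            if j >= L:
                continue
            if _PAIR.get(s[i]) == s[j]:
                gain = 2.0 if j == L - 1 else 1.0
                run += gain
            else:
                run -= 1.0
            run = max(run, 0.0)
            diag_best = max(diag_best, run)
        best = max(best, diag_best)
    return best


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConservedWindow:
    """A maximal gap-free zero-diversity stretch of alignment columns."""

    gene: str
    start: int
    end: int
    consensus: str

    def __post_init__(self) -> None:
        if len(self.consensus) != self.end - self.start:
            raise MinibarcError("consensus length must equal end - start")


@dataclass(frozen=True)
class PrimerCandidate:
    """One oligo anchored on a conserved stretch.

    ``seq`` is the oligo 5'->3': the sense consensus for orientation F,
    its reverse complement for orientation R. ``source`` gives the
    alignment columns of the anchor.
    """

    seq: str
    orientation: str  # "F" or "R"
    source: tuple[str, int, int]  # (gene, start col, end col)
    gc_pct: float
    tm_c: float
    hairpin: float
    self_dimer: float

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ResolutionReport:
    """Pairwise barcode differences between species over a region."""

    species_ids: tuple[str, ...]
    pairwise_diffs: tuple[tuple[int, ...], ...]
    min_diff: int
    resolved: bool


@dataclass
class PrimerPair:
    fwd: PrimerCandidate
    rev: PrimerCandidate
    insert_len: int
    insert_len_by_species: dict[str, int]
    variable_sites: int
    cross_dimer: float
    tm_diff: float
    resolution: ResolutionReport
    rank_score: float = 0.0

    @property
    def name(self) -> str:
        return f"{self.fwd.source[1] + 1}F/{self.rev.source[1] + 1}R"


@dataclass
class DesignConfig:
    """Tunable primer-design thresholds (conventional screening defaults)."""

    primer_len: tuple[int, int] = (16, 22)
    gc_range: tuple[float, float] = (30.0, 60.0)
    max_homopolymer: int = 5
    max_hairpin: float = 5.0
    max_self_dimer: float = 10.0
    max_cross_dimer: float = 10.0
    max_tm_diff: float = 5.0
    insert_range: tuple[int, int] = (100, 250)
    tm_method: str = "nn"


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def find_conserved_windows(wt: WindowTable, aln: GeneAlignment) -> list[ConservedWindow]:
    """Merge runs of conserved windows into maximal conserved stretches."""
    out: list[ConservedWindow] = []
    w = wt.window
    run_start: Optional[int] = None
    prev_start: Optional[int] = None
    starts = [int(s) for s, c in zip(wt.starts, wt.conserved) if c]
    for s in starts:
        if run_start is None:
            run_start, prev_start = s, s
        elif s - prev_start <= wt.step and s - prev_start <= w:
            prev_start = s
        else:
            out.append(_make_stretch(aln, run_start, prev_start + w))
            run_start, prev_start = s, s
    if run_start is not None:
        out.append(_make_stretch(aln, run_start, prev_start + w))
    return out


def _make_stretch(aln: GeneAlignment, start: int, end: int) -> ConservedWindow:
    consensus = aln.rows[0][start:end]
    for sid, row in zip(aln.species_ids, aln.rows):
        if row[start:end] != consensus:
            raise MinibarcError(
                f"{aln.gene}: columns [{start},{end}) flagged conserved but "
                f"{sid!r} disagrees — window table does not match alignment"
            )
    return ConservedWindow(gene=aln.gene, start=start, end=end, consensus=consensus)


def enumerate_primers(windows: Sequence[ConservedWindow],
                      len_range: tuple[int, int] = (16, 22),
                      config: Optional[DesignConfig] = None,
                      ) -> list[PrimerCandidate]:
    """All filtered substrings of conserved stretches, in F and R senses."""
    cfg = config or DesignConfig()
    lo, hi = len_range
    cands: list[PrimerCandidate] = []
    for win in windows:
        stretch = win.consensus
        for L in range(lo, hi + 1):
            for off in range(0, len(stretch) - L + 1):
                sub = stretch[off:off + L]
                src = (win.gene, win.start + off, win.start + off + L)
                for orientation in ("F", "R"):
                    oligo = sub if orientation == "F" else revcomp(sub)
                    cand = _annotate(oligo, orientation, src, cfg)
                    if cand is not None:
                        cands.append(cand)
    return cands


def _annotate(oligo: str, orientation: str, src: tuple[str, int, int],
              cfg: DesignConfig) -> Optional[PrimerCandidate]:
    gc = gc_content(oligo)
    if not cfg.gc_range[0] <= gc <= cfg.gc_range[1]:
        return None
    if max_homopolymer(oligo) > cfg.max_homopolymer:
        return None
    hp = hairpin_score(oligo)
    if hp > cfg.max_hairpin:
        return None
    sd = self_dimer_score(oligo)
    if sd > cfg.max_self_dimer:
        return None
    return PrimerCandidate(
        seq=oligo, orientation=orientation, source=src,
        gc_pct=gc, tm_c=melting_temp(oligo, cfg.tm_method),
        hairpin=hp, self_dimer=sd,
    )


def count_variable_sites(aln: GeneAlignment, start: int, end: int,
                         gaps_as_state: bool = True) -> int:
    """Columns in [start, end) with >= 2 distinct states.

    With ``gaps_as_state`` (default) a gap is a fifth state, so indel
    columns count as variable; otherwise columns containing any gap are
    skipped entirely.
    """
    if not 0 <= start < end <= aln.L_aln:
        raise IndexError(f"region [{start},{end}) outside [0,{aln.L_aln}]")
    count = 0
    for c in range(start, end):
        states = {row[c] for row in aln.rows}
        if not gaps_as_state and "-" in states:
            continue
        if len(states) >= 2:
            count += 1
    return count


def assess_resolution(aln: GeneAlignment, start: int, end: int) -> ResolutionReport:
    """Pairwise difference counts over [start, end); gap is a state."""
    if not 0 <= start < end <= aln.L_aln:
        raise IndexError(f"region [{start},{end}) outside [0,{aln.L_aln}]")
    n = aln.n
    diffs = [[0] * n for _ in range(n)]
    slices = [row[start:end] for row in aln.rows]
    for i in range(n):
        for j in range(i + 1, n):
            d = sum(a != b for a, b in zip(slices[i], slices[j]))
            diffs[i][j] = diffs[j][i] = d
    pair_values = [diffs[i][j] for i in range(n) for j in range(i + 1, n)]
    min_diff = min(pair_values) if pair_values else 0
    return ResolutionReport(
        species_ids=tuple(aln.species_ids),
        pairwise_diffs=tuple(tuple(r) for r in diffs),
        min_diff=min_diff,
        resolved=min_diff >= 1,
    )


def pair_primers(cands: Sequence[PrimerCandidate], aln: GeneAlignment,
                 insert_range: Optional[tuple[int, int]] = None,
                 ref_species: Optional[str] = None,
                 config: Optional[DesignConfig] = None,
                 gaps_as_state: bool = True) -> list[PrimerPair]:
    """Combine forward/reverse candidates into accepted pairs.

    insert_len is the inter-primer span measured in ungapped coordinates
    of the reference species (default: first row); per-species lengths
    are also recorded.
    """
    cfg = config or DesignConfig()
    rng = insert_range or cfg.insert_range
    if ref_species is None:
        ref_species = aln.species_ids[0]
    if ref_species not in aln.species_ids:
        raise GeneLookupError(
            f"reference species {ref_species!r} not in alignment "
            f"(have {aln.species_ids})"
        )
    fwd_cands = [c for c in cands if c.orientation == "F"]
    rev_cands = [c for c in cands if c.orientation == "R"]
    pairs: list[PrimerPair] = []
    for f in fwd_cands:
        for r in rev_cands:
            if f.source[0] != r.source[0] or f.source[0] != aln.gene:
                continue
            if f.source[2] > r.source[1]:
                continue
            lo_col, hi_col = f.source[2], r.source[1]
            lens = {
                sid: sum(ch != "-" for ch in row[lo_col:hi_col])
                for sid, row in zip(aln.species_ids, aln.rows)
            }
            insert_len = lens[ref_species]
            if not rng[0] <= insert_len <= rng[1]:
                continue
            tm_diff = abs(f.tm_c - r.tm_c)
            if tm_diff > cfg.max_tm_diff:
                continue
            xd = cross_dimer_score(f.seq, r.seq)
            if xd > cfg.max_cross_dimer:
                continue
            vs = count_variable_sites(aln, lo_col, hi_col, gaps_as_state)
            pairs.append(PrimerPair(
                fwd=f, rev=r,
                insert_len=insert_len,
                insert_len_by_species=lens,
                variable_sites=vs,
                cross_dimer=xd,
                tm_diff=tm_diff,
                resolution=assess_resolution(aln, lo_col, hi_col),
                rank_score=float(vs),
            ))
    return pairs


def rank_pairs(pairs: Sequence[PrimerPair]) -> list[PrimerPair]:
    """Deterministic total order: most variable sites first; ties by
    smaller Tm difference, insert length closest to 175, then primer
    sequences lexicographically."""
    if not pairs:
        raise ValueError("no primer pairs to rank")
    return sorted(pairs, key=lambda p: (
        -p.variable_sites,
        p.tm_diff,
        abs(p.insert_len - 175),
        p.fwd.seq,
        p.rev.seq,
    ))


def pairs_frame(pairs: Sequence[PrimerPair]) -> pd.DataFrame:
    """Report table (one row per oligo, grouped by pair, 1-based coords)."""
    rows = []
    for rank, p in enumerate(pairs, 1):
        for cand, role in ((p.fwd, "F"), (p.rev, "R")):
            rows.append({
                "pair_rank": rank,
                "pair": p.name,
                "role": role,
                "sequence_5to3": cand.seq,
                "anchor_start_1based": cand.source[1] + 1,
                "anchor_end_1based": cand.source[2],
                "insert_bp": p.insert_len,
                "variable_sites": p.variable_sites,
                "gc_pct": cand.gc_pct,
                "tm_c": round(cand.tm_c, 1),
                "hairpin": cand.hairpin,
                "self_dimer": cand.self_dimer,
                "cross_dimer": p.cross_dimer,
                "min_pair_diff": p.resolution.min_diff,
                "resolved": p.resolution.resolved,
            })
    return pd.DataFrame(rows)
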