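"""Amplicon-read classification into a species composition table.

Stages: primer trimming with orientation normalization, exact
dereplication, a lite greedy denoiser (UNOISE-style absorption of
low-count neighbours — a deliberate stand-in for a full error model),
best-hit assignment against a reference amplicon panel by end-gap-free
global identity, and abundance filtering of the composition table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .insilico_pcr import Amplicon
from .primer_design import PrimerPair
from .seqio import ReadSet, revcomp

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class DereplicatedSet:
    """Unique sequences with counts, descending (ties by sequence)."""

    sequences: list[tuple[str, int]]
    total_reads: int

    def __post_init__(self) -> None:
        if sum(c for _, c in self.sequences) != self.total_reads:
            raise ValueError("counts do not sum to total_reads")
        if len({s for s, _ in self.sequences}) != len(self.sequences):
            raise ValueError("duplicate sequences in dereplicated set")


@dataclass(frozen=True)
class AssignmentResult:
    query: str
    best_ref: str  # species id or "unassigned"
    identity_pct: float
    ties: tuple[str, ...] = ()


@dataclass
class CompositionTable:
    """Species read counts/proportions after abundance filtering.

    Proportions are of total *assigned* reads and are not renormalized
    after filtering, so retained rows may sum to < 1.
    """

    rows: list[tuple[str, int, float]]  # (species, reads, proportion)
    min_prop: float
    total_assigned: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["species", "reads", "proportion"])

    def proportions(self) -> dict[str, float]:
        return {sp: p for sp, _, p in self.rows}


# ---------------------------------------------------------------------------
# trimming / dereplication / denoising
# ---------------------------------------------------------------------------

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _pair_seqs(pair: Union[PrimerPair, tuple[str, str]]) -> tuple[str, str]:
    if isinstance(pair, PrimerPair):
        return pair.fwd.seq, pair.rev.seq
    f, r = pair
    return f.upper(), r.upper()


def trim_primers(reads: ReadSet, pair: Union[PrimerPair, tuple[str, str]],
                 max_mm: int = 2) -> ReadSet:
    """Strip primer prefix/suffix and orientation-normalize to sense.

    A read is kept iff, in one orientation, it starts with the forward
    primer and ends with the reverse complement of the reverse primer
    (each within `max_mm` Hamming mismatches). Dropped reads are counted
    in ``result.meta['dropped']``.
    """
    fwd, rev = _pair_seqs(pair)
    rev_rc = revcomp(rev)
    lf, lr = len(fwd), len(rev_rc)
    kept: list[tuple[str, str, Optional[str]]] = []
    dropped = 0
    for rid, seq, qual in reads.reads:
        hit = None
        for oriented, oqual in ((seq, qual),
                                (revcomp(seq), qual[::-1] if qual else None)):
            if len(oriented) < lf + lr:
                continue
            if (_hamming(oriented[:lf], fwd) <= max_mm
                    and _hamming(oriented[-lr:], rev_rc) <= max_mm):
                hit = (oriented[lf:-lr], oqual[lf:-lr] if oqual else None)
                break
        if hit is None:
            dropped += 1
        else:
            kept.append((rid, hit[0], hit[1]))
    if dropped:
        logger.info("trim_primers: dropped %d/%d reads lacking primer sites",
                    dropped, len(reads.reads))
    return ReadSet(reads=kept, source=reads.source,
                   meta={**reads.meta, "dropped": dropped})


def dereplicate(reads: ReadSet) -> DereplicatedSet:
    """Exact-sequence grouping; counts descending, ties by sequence."""
    counts: dict[str, int] = {}
    for _, seq, _ in reads.reads:
        counts[seq] = counts.get(seq, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return DereplicatedSet(sequences=ordered, total_reads=len(reads.reads))


def denoise_lite(ds: DereplicatedSet, max_diff: int = 1,
                 ratio: float = 4.0) -> DereplicatedSet:
    """Greedy absorption of likely error variants.

    Processing uniques in descending-count order, a sequence is absorbed
    into the first already-retained sequence that lies within
    ``max_diff`` Hamming distance (equal lengths only) and whose current
    count is at least ``ratio`` times the candidate's; its reads are
    added to the absorber. Deterministic.
    """
    retained_seqs: list[str] = []
    retained_counts: list[int] = []
    by_len: dict[int, list[int]] = {}  # length -> indices into retained
    enc: list[np.ndarray] = []

    for seq, count in ds.sequences:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        absorbed = False
        idxs = by_len.get(len(seq), [])
        if idxs:
            # candidates must be sufficiently more abundant
            cand_idx = [i for i in idxs if retained_counts[i] >= ratio * count]
            if cand_idx:
                stack = np.stack([enc[i] for i in cand_idx])
                dists = (stack != arr).sum(axis=1)
                # absorb into the first qualifying neighbour in retained
                # order (descending original count, so most abundant first)
                for pos, i in enumerate(cand_idx):
                    if dists[pos] <= max_diff:
                        retained_counts[i] += count
                        absorbed = True
                        break
        if not absorbed:
            by_len.setdefault(len(seq), []).append(len(retained_seqs))
            retained_seqs.append(seq)
            retained_counts.append(count)
            enc.append(arr)
    merged = sorted(zip(retained_seqs, retained_counts),
                    key=lambda kv: (-kv[1], kv[0]))
    return DereplicatedSet(sequences=list(merged), total_reads=ds.total_reads)


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

def _make_aligner():
    from Bio import Align
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    if hasattr(aligner, "end_insertion_score"):  # biopython >= 1.86 naming
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    else:
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0
    return aligner


def global_identity(query: str, ref: str, _aligner_cache=[]) -> float:
    """Percent identity under end-gap-free global alignment.

    Scoring: match +1, mismatch -1, gap -2, terminal gaps free. Identity
    is 100 * matches / alignment columns, counting terminal-gap columns,
    so degenerate short-overlap alignments of unrelated sequences score
    low rather than spuriously high.
    """
    if query == ref:
        return 100.0
    if not _aligner_cache:
        _aligner_cache.append(_make_aligner())
    aligner = _aligner_cache[0]
    aln = aligner.align(ref, query)[0]
    s_ref, s_qry = str(aln[0]), str(aln[1])
    cols = len(s_ref)
    if cols == 0:
        return 0.0
    matches = sum(a == b and a != "-" for a, b in zip(s_ref, s_qry))
    return 100.0 * matches / cols


def _ref_seq(ref: Union[str, Amplicon]) -> str:
    return ref.insert_seq if isinstance(ref, Amplicon) else ref.upper()


def assign(ds: DereplicatedSet, panel: Mapping[str, Union[str, Amplicon]],
           min_ident: float = 90.0) -> list[AssignmentResult]:
    """Best-hit species per unique sequence.

    Ties are recorded and broken lexicographically; best identity below
    `min_ident` yields "unassigned". Order matches the input set and is
    invariant to panel iteration order.
    """
    if not panel:
        raise ValueError("empty reference panel")
    refs = sorted((sp, _ref_seq(r)) for sp, r in panel.items())
    out: list[AssignmentResult] = []
    for seq, _count in ds.sequences:
        idents = [(sp, global_identity(seq, ref)) for sp, ref in refs]
        best = max(i for _, i in idents)
        winners = tuple(sp for sp, i in idents if i == best)
        if best < min_ident:
            out.append(AssignmentResult(query=seq, best_ref="unassigned",
                                        identity_pct=best, ties=()))
        else:
            out.append(AssignmentResult(
                query=seq, best_ref=winners[0], identity_pct=best,
                ties=winners if len(winners) > 1 else (),
            ))
    return out


def composition(assignments: Sequence[AssignmentResult], ds: DereplicatedSet,
                min_prop: float = 0.01) -> CompositionTable:
    """Species read sums over assigned uniques, filtered at `min_prop`.

    Proportions are of total assigned reads; rows below the threshold
    are dropped without renormalizing the rest.
    """
    if len(assignments) != len(ds.sequences):
        raise ValueError("assignments do not match dereplicated set")
    reads_by_species: dict[str, int] = {}
    total_assigned = 0
    for res, (seq, count) in zip(assignments, ds.sequences):
        if res.query != seq:
            raise ValueError("assignment order does not match dereplicated set")
        if res.best_ref == "unassigned":
            continue
        reads_by_species[res.best_ref] = (
            reads_by_species.get(res.best_ref, 0) + count)
        total_assigned += count
    rows: list[tuple[str, int, float]] = []
    for sp, reads in reads_by_species.items():
        prop = reads / total_assigned if total_assigned else 0.0
        if prop >= min_prop:
            rows.append((sp, reads, prop))
    rows.sort(key=lambda r: (-r[2], r[0]))
    return CompositionTable(rows=rows, min_prop=min_prop,
                            total_assigned=total_assigned)
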