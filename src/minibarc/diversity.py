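"""Nucleotide diversity (pi) on gene alignments.

Per-column pi is the fraction of mismatching unordered sequence pairs at
that column; the gene-wide value is the mean over included columns, which
equals the average pairwise p-distance restricted to those columns.

Columns containing a gap or any ambiguity code in *any* row are excluded
by default ("complete deletion"); a pairwise-deletion mode is available
for gene-wide pi but windows always use complete deletion because primers
must anneal contiguously on every species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MinibarcError
from .seqio import GeneAlignment

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _matrix(aln: GeneAlignment) -> np.ndarray:
    """Alignment as an (n, L) uint8 matrix of ASCII codes."""
    return np.frombuffer(
        "".join(aln.rows).encode("ascii"), dtype=np.uint8
    ).reshape(aln.n, aln.L_aln)


def _column_stats(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (included mask, per-column pi) for complete deletion.

    pi is NaN where a column is excluded.
    """
    n = mat.shape[0]
    counts = np.stack([(mat == b).sum(axis=0) for b in _BASES])  # (4, L)
    included = counts.sum(axis=0) == n
    pairs = n * (n - 1) // 2
    same = (counts * (counts - 1) // 2).sum(axis=0)
    with np.errstate(invalid="ignore"):
        pi = (pairs - same) / pairs
    pi = pi.astype(float)
    pi[~included] = np.nan
    return included, pi


@dataclass
class DiversityProfile:
    """Per-column and gene-wide nucleotide diversity for one alignment."""

    gene: str
    n: int
    L_aln: int
    included_mask: np.ndarray  # bool, length L_aln
    pi_per_column: np.ndarray  # float, NaN where excluded
    Pi: float
    L_incl: int


@dataclass
class WindowTable:
    """Sliding-window pi values over alignment columns.

    A window is ``conserved`` iff all ``w`` columns are included (no
    gap/ambiguity anywhere) and every one of them is monomorphic.
    """

    gene: str
    window: int
    step: int
    starts: np.ndarray    # int, window start columns
    included: np.ndarray  # int, number of included columns per window
    pi: np.ndarray        # float, NaN where no included columns
    conserved: np.ndarray  # bool

    def to_frame(self) -> pd.DataFrame:
        """1-based inclusive coordinates for human-facing reports."""
        return pd.DataFrame({
            "gene": self.gene,
            "start_1based": self.starts + 1,
            "end_1based": self.starts + self.window,
            "included": self.included,
            "Pi_w": np.round(self.pi, 4),
            "conserved": self.conserved,
        })


def column_pi(aln: GeneAlignment, c: int) -> tuple[bool, float]:
    """(included, pi) for a single alignment column.

    pi is 0.0 when the column is excluded (complete deletion).
    """
    if not 0 <= c < aln.L_aln:
        raise IndexError(f"column {c} outside [0, {aln.L_aln})")
    mat = _matrix(aln)[:, c:c + 1]
    included, pi = _column_stats(mat)
    if not included[0]:
        return False, 0.0
    return True, float(pi[0])


def gene_pi(aln: GeneAlignment, mode: str = "complete") -> DiversityProfile:
    """Gene-wide nucleotide diversity.

    mode="complete" (default) excludes any column with a gap/ambiguity in
    any row; mode="pairwise" averages, per column, over the pairs whose
    two rows are both canonical bases there.
    """
    mat = _matrix(aln)
    included, pi = _column_stats(mat)
    if mode == "complete":
        L_incl = int(included.sum())
        if L_incl == 0:
            raise MinibarcError(
                f"{aln.gene}: alignment entirely gapped/ambiguous — "
                "no columns left after complete deletion"
            )
        Pi = float(np.nanmean(pi[included])) if L_incl else float("nan")
    elif mode == "pairwise":
        valid = np.isin(mat, _BASES)  # (n, L)
        counts = np.stack([(mat == b).sum(axis=0) for b in _BASES])
        nv = valid.sum(axis=0)
        pairs = nv * (nv - 1) // 2
        same = (counts * (counts - 1) // 2).sum(axis=0)
        usable = pairs > 0
        L_incl = int(usable.sum())
        if L_incl == 0:
            raise MinibarcError(
                f"{aln.gene}: no column has two comparable sequences"
            )
        pi = np.full(mat.shape[1], np.nan)
        pi[usable] = (pairs[usable] - same[usable]) / pairs[usable]
        included = usable
        Pi = float(np.mean(pi[usable]))
    else:
        raise ValueError(f"unknown deletion mode {mode!r}")
    return DiversityProfile(
        gene=aln.gene, n=aln.n, L_aln=aln.L_aln,
        included_mask=included, pi_per_column=pi, Pi=Pi, L_incl=L_incl,
    )


def sliding_windows(aln: GeneAlignment, w: int = 20, s: int = 1) -> WindowTable:
    """Window scan of per-column pi (window ``w`` columns, step ``s``)."""
    if w < 1 or s < 1:
        raise ValueError("window and step must be >= 1")
    if w > aln.L_aln:
        raise MinibarcError(
            f"{aln.gene}: window {w} exceeds alignment length {aln.L_aln}"
        )
    mat = _matrix(aln)
    included, pi = _column_stats(mat)
    pi_filled = np.where(included, pi, 0.0)

    inc_cum = np.concatenate([[0], np.cumsum(included)])
    pi_cum = np.concatenate([[0.0], np.cumsum(pi_filled)])

    starts = np.arange(0, aln.L_aln - w + 1, s)
    inc_w = inc_cum[starts + w] - inc_cum[starts]
    pi_sum = pi_cum[starts + w] - pi_cum[starts]
    with np.errstate(invalid="ignore"):
        pi_w = np.where(inc_w > 0, pi_sum / np.maximum(inc_w, 1), np.nan)
    conserved = (inc_w == w) & (pi_sum == 0.0)
    return WindowTable(
        gene=aln.gene, window=w, step=s,
        starts=starts, included=inc_w.astype(int),
        pi=pi_w, conserved=conserved,
    )


def rank_genes(profiles: list[DiversityProfile]) -> list[tuple[str, float]]:
    """Genes ordered by descending Pi, ties broken alphabetically."""
    if not profiles:
        raise ValueError("no profiles to rank")
    ordered = sorted(profiles, key=lambda p: (-p.Pi, p.gene))
    return [(p.gene, p.Pi) for p in ordered]


def profiles_frame(profiles: list[DiversityProfile]) -> pd.DataFrame:
    """Per-gene summary table (Pi to 4 decimals, descending)."""
    rows = [
        {"gene": p.gene, "n": p.n, "L_aln": p.L_aln,
         "L_incl": p.L_incl, "Pi": round(p.Pi, 4)}
        for p in sorted(profiles, key=lambda p: (-p.Pi, p.gene))
    ]
    return pd.DataFrame(rows)
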