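"""Mismatch-tolerant in-silico PCR.

The annealing model is ungapped Hamming matching with an exact-match
requirement on the primer's 3'-terminal bases. IUPAC ambiguity codes in
the template match a primer base iff the base belongs to the code's set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

from .errors import AmplificationError
from .primer_design import PrimerCandidate, PrimerPair
from .seqio import IUPAC_SETS, SequenceRecord, revcomp

PrimerLike = Union[str, PrimerCandidate]


def _primer_seq(primer: PrimerLike) -> str:
    return primer.seq if isinstance(primer, PrimerCandidate) else primer.upper()


@dataclass(frozen=True)
class PrimerMatch:
    """An annealing site on the + strand of a template.

    ``strand`` is '+' when the primer anneals in forward sense (its 3'
    end points right on the + strand) and '-' for reverse sense.
    """

    template_id: str
    strand: str
    start: int
    end: int
    mismatches: int
    three_prime_ok: bool = True


@dataclass(frozen=True)
class Amplicon:
    """An in-silico PCR product.

    ``insert_seq`` is the inter-primer sequence on the product's sense
    strand (orientation-normalized: forward primer on the left).
    For '+' products ``insert_len == rev_match.start - fwd_match.end``;
    '-' products mirror this on the reverse strand.
    """

    template_id: str
    fwd_match: PrimerMatch
    rev_match: PrimerMatch
    insert_seq: str
    insert_len: int
    full_len: int
    product_strand: str = "+"

    @property
    def full_seq_span(self) -> tuple[int, int]:
        """Template + strand coordinates covered by the product."""
        lo = min(self.fwd_match.start, self.rev_match.start)
        hi = max(self.fwd_match.end, self.rev_match.end)
        return lo, hi


def _base_match(template_base: str, primer_base: str) -> bool:
    return primer_base in IUPAC_SETS.get(template_base, frozenset())


def find_matches(template: SequenceRecord, primer: PrimerLike,
                 max_mm: int = 3, anchor_3p: int = 1) -> list[PrimerMatch]:
    """All annealing sites of `primer` on both senses of the template.

    Forward sense scans the primer against the + strand; reverse sense
    scans its reverse complement. The `anchor_3p` 3'-terminal primer
    bases must match exactly; elsewhere up to `max_mm` mismatches are
    tolerated.
    """
    p = _primer_seq(primer)
    tseq = template.seq
    L, k = len(tseq), len(p)
    if k == 0:
        raise ValueError("empty primer")
    if k > L:
        return []
    matches: list[PrimerMatch] = []
    prc = revcomp(p)
    for start in range(L - k + 1):
        window = tseq[start:start + k]
        # forward sense: primer 3' end at the right edge of the window
        mm = sum(not _base_match(t, b) for t, b in zip(window, p))
        if mm <= max_mm:
            tail_ok = all(
                _base_match(window[k - 1 - i], p[k - 1 - i])
                for i in range(anchor_3p)
            )
            if tail_ok:
                matches.append(PrimerMatch(
                    template_id=template.id, strand="+",
                    start=start, end=start + k, mismatches=mm,
                ))
        # reverse sense: revcomp(primer) on + strand; primer 3' end maps
        # to the left edge of the window
        mm = sum(not _base_match(t, b) for t, b in zip(window, prc))
        if mm <= max_mm:
            tail_ok = all(
                _base_match(window[i], prc[i]) for i in range(anchor_3p)
            )
            if tail_ok:
                matches.append(PrimerMatch(
                    template_id=template.id, strand="-",
                    start=start, end=start + k, mismatches=mm,
                ))
    matches.sort(key=lambda m: (m.start, m.strand))
    return matches


def _pair_seqs(pair: Union[PrimerPair, tuple[str, str]]) -> tuple[str, str]:
    if isinstance(pair, PrimerPair):
        return pair.fwd.seq, pair.rev.seq
    f, r = pair
    return f.upper(), r.upper()


def amplify(template: SequenceRecord, pair: Union[PrimerPair, tuple[str, str]],
            max_mm: int = 3, anchor_3p: int = 1,
            max_product: int = 2000) -> list[Amplicon]:
    """All products of a primer pair on the template (either strand).

    A product needs the forward primer and the reverse primer annealing
    on opposite senses, 3' ends facing each other, with total product
    length <= `max_product`. Products found on the - strand are
    orientation-normalized so `insert_seq` always runs forward-primer ->
    reverse-primer.
    """
    fwd, rev = _pair_seqs(pair)
    fhits = find_matches(template, fwd, max_mm, anchor_3p)
    rhits = find_matches(template, rev, max_mm, anchor_3p)
    out: list[Amplicon] = []
    # + strand product: fwd '+' upstream of rev '-'
    for f in (m for m in fhits if m.strand == "+"):
        for r in (m for m in rhits if m.strand == "-"):
            if f.end <= r.start and r.end - f.start <= max_product:
                insert = template.seq[f.end:r.start]
                out.append(Amplicon(
                    template_id=template.id, fwd_match=f, rev_match=r,
                    insert_seq=insert, insert_len=len(insert),
                    full_len=r.end - f.start, product_strand="+",
                ))
    # - strand product: rev '+' upstream of fwd '-'
    for f in (m for m in fhits if m.strand == "-"):
        for r in (m for m in rhits if m.strand == "+"):
            if r.end <= f.start and f.end - r.start <= max_product:
                insert = revcomp(template.seq[r.end:f.start])
                out.append(Amplicon(
                    template_id=template.id, fwd_match=f, rev_match=r,
                    insert_seq=insert, insert_len=len(insert),
                    full_len=f.end - r.start, product_strand="-",
                ))
    out.sort(key=lambda a: (a.full_seq_span, a.product_strand))
    return out


def product_seq(template: SequenceRecord, amp: Amplicon) -> str:
    """Full product sequence, sense strand (fwd primer first)."""
    lo, hi = amp.full_seq_span
    s = template.seq[lo:hi]
    return s if amp.product_strand == "+" else revcomp(s)


def panel_amplicons(templates: Sequence[SequenceRecord],
                    pair: Union[PrimerPair, tuple[str, str]],
                    max_mm: int = 3, anchor_3p: int = 1,
                    max_product: int = 2000) -> dict[str, Amplicon]:
    """One unambiguous amplicon per template; anything else is an error."""
    result: dict[str, Amplicon] = {}
    bad: list[str] = []
    for rec in templates:
        amps = amplify(rec, pair, max_mm, anchor_3p, max_product)
        if len(amps) != 1:
            bad.append(f"{rec.id} ({len(amps)} products)")
        else:
            result[rec.id] = amps[0]
    if bad:
        raise AmplificationError(
            "panel amplification must yield exactly one product per "
            "template; offenders: " + ", ".join(bad)
        )
    return result
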