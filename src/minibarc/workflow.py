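"""Convenience workflows tying the modules together for annotated
genome panels: extract a gene across records, align it, and map a primer
pair onto alignment columns."""

from __future__ import annotations

from typing import Optional, Sequence

from .align import mafft_align
from .errors import AmplificationError, GeneLookupError
from .insilico_pcr import find_matches
from .seqio import GeneAlignment, SequenceRecord, extract_gene


def build_gene_alignment(records: Sequence[SequenceRecord], gene: str,
                         strategy: str = "auto") -> GeneAlignment:
    """Extract `gene` from every record and align with MAFFT."""
    seqs = [SequenceRecord(id=r.id, seq=extract_gene(r, gene))
            for r in records]
    return mafft_align(seqs, gene=gene, strategy=strategy)


def shared_genes(records: Sequence[SequenceRecord]) -> list[str]:
    """Canonical gene names annotated on every record (genes/rRNAs only)."""
    from .seqio import canonical_gene_name
    per_record = [
        {canonical_gene_name(f.name) for f in r.features
         if f.kind in ("gene", "CDS", "rRNA")}
        for r in records
    ]
    common = set.intersection(*per_record) if per_record else set()
    return sorted(common)


def locate_pair_columns(aln: GeneAlignment, fwd: str, rev: str,
                        ref_species: Optional[str] = None,
                        max_mm: int = 3,
                        ) -> tuple[tuple[int, int], tuple[int, int]]:
    """Alignment-column spans of a primer pair's annealing sites.

    The primers are located on the ungapped reference row (forward sense
    for `fwd`, reverse sense for `rev`) and the ungapped positions are
    mapped back to alignment columns. Each primer must match exactly
    once. Returns ((fwd_start, fwd_end), (rev_start, rev_end)).
    """
    if ref_species is None:
        ref_species = aln.species_ids[0]
    row = aln.row(ref_species)
    degapped = row.replace("-", "")
    template = SequenceRecord(id=ref_species, seq=degapped)
    fhits = [m for m in find_matches(template, fwd, max_mm) if m.strand == "+"]
    rhits = [m for m in find_matches(template, rev, max_mm) if m.strand == "-"]
    if len(fhits) != 1 or len(rhits) != 1:
        raise AmplificationError(
            f"{aln.gene}/{ref_species}: expected one site per primer, got "
            f"{len(fhits)} forward and {len(rhits)} reverse"
        )
    # ungapped position -> alignment column
    col_of: list[int] = [c for c, ch in enumerate(row) if ch != "-"]

    def span(m) -> tuple[int, int]:
        return col_of[m.start], col_of[m.end - 1] + 1

    return span(fhits[0]), span(rhits[0])
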