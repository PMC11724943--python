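"""Thin wrapper around an external multiple aligner (MAFFT).

Used for gene panels extracted from annotated genomes; the synthetic
fixtures never need it because their true alignments are known.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path
from typing import Sequence

from .errors import MinibarcError
from .seqio import GeneAlignment, SequenceRecord, load_alignment, write_fasta


def mafft_available() -> bool:
    return shutil.which("mafft") is not None


def mafft_align(records: Sequence[SequenceRecord], gene: str,
                strategy: str = "auto") -> GeneAlignment:
    """Align records with MAFFT and return a :class:`GeneAlignment`.

    strategy "auto" maps to ``--auto``; "linsi" to ``--localpair
    --maxiterate 1000`` (the accurate L-INS-i mode).
    """
    if not mafft_available():
        raise MinibarcError("mafft not found on PATH")
    if strategy == "auto":
        args = ["--auto"]
    elif strategy == "linsi":
        args = ["--localpair", "--maxiterate", "1000"]
    else:
        raise MinibarcError(f"unknown MAFFT strategy {strategy!r}")
    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "in.fasta"
        outfile = Path(tmp) / "out.fasta"
        write_fasta(records, infile)
        with open(outfile, "w") as out:
            proc = subprocess.run(
                ["mafft", *args, "--quiet", str(infile)],
                stdout=out, stderr=subprocess.PIPE, text=True,
            )
        if proc.returncode != 0:
            raise MinibarcError(f"mafft failed: {proc.stderr[-500:]}")
        return load_alignment(outfile, gene=gene)
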