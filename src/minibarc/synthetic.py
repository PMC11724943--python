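"""Synthetic fixtures with known ground truth.

Generates multi-species gene panels in which hypervariable cores evolve
by independent per-site substitution while planted anchor windows stay
perfectly conserved, plus error-bearing amplicon read mixtures with known
species weights. Everything is deterministic given the seed.

Under the substitution model each non-anchor site of each species mutates
from the ancestral base with probability theta to a uniformly chosen
different base, so two species differ at a site with probability

    p_diff(theta) = 2*theta*(1 - theta) + (2/3)*theta**2

(the theta**2 term carries the 1/3 chance both picked the same base).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError
from .insilico_pcr import Amplicon, panel_amplicons, product_seq
from .seqio import (GeneAlignment, GeneFeature, ReadSet, SequenceRecord,
                    revcomp, write_alignment, write_fasta, write_fastq)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def expected_pairwise_diff(theta: float) -> float:
    """Closed-form P(two species differ at a non-anchor site)."""
    return 2 * theta * (1 - theta) + (2.0 / 3.0) * theta ** 2


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnchorSpec:
    """A planted zero-diversity window inside a gene.

    If `primer_seq` is given it is written into the ancestral sequence at
    the anchor start (it must fit inside the anchor).
    """

    gene: str
    position: int
    length: int = 20
    primer_seq: Optional[str] = None


@dataclass(frozen=True)
class GeneSpec:
    name: str
    length: int
    theta: float  # per-site, per-species substitution probability


@dataclass
class SimulationConfig:
    n_species: int
    genes: list[GeneSpec]
    anchors: list[AnchorSpec] = field(default_factory=list)
    weights: Optional[list[float]] = None
    read_count: int = 0
    error_rate: float = 0.0
    seed: int = 0
    fwd_primer: Optional[str] = None
    rev_primer: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ConfigError("need at least 2 species")
        gene_names = [g.name for g in self.genes]
        if len(set(gene_names)) != len(gene_names):
            raise ConfigError("duplicate gene names")
        for g in self.genes:
            if not 0.0 <= g.theta <= 1.0:
                raise ConfigError(f"{g.name}: theta must be in [0,1]")
        by_gene: dict[str, list[AnchorSpec]] = {}
        for a in self.anchors:
            gene = next((g for g in self.genes if g.name == a.gene), None)
            if gene is None:
                raise ConfigError(f"anchor references unknown gene {a.gene!r}")
            if a.position < 0 or a.position + a.length > gene.length:
                raise ConfigError(
                    f"anchor at {a.position} (len {a.length}) outside "
                    f"gene {a.gene!r} of length {gene.length}"
                )
            if a.primer_seq is not None and len(a.primer_seq) > a.length:
                raise ConfigError(
                    f"anchor primer longer than anchor ({a.gene}@{a.position})"
                )
            by_gene.setdefault(a.gene, []).append(a)
        for gene, specs in by_gene.items():
            spans = sorted((a.position, a.position + a.length) for a in specs)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise ConfigError(f"overlapping anchors in gene {gene!r}")
        if self.weights is not None:
            if len(self.weights) != self.n_species:
                raise ConfigError("weights length must equal n_species")
            if any(w < 0 for w in self.weights):
                raise ConfigError("weights must be non-negative")
            if abs(sum(self.weights) - 1.0) > 1e-9:
                raise ConfigError("weights must sum to 1")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ConfigError("error_rate must be in [0, 0.1]")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(
            n_species=d["n_species"],
            genes=[GeneSpec(**g) for g in d["genes"]],
            anchors=[AnchorSpec(**a) for a in d.get("anchors", [])],
            weights=d.get("weights"),
            read_count=d.get("read_count", 0),
            error_rate=d.get("error_rate", 0.0),
            seed=d.get("seed", 0),
            fwd_primer=d.get("fwd_primer"),
            rev_primer=d.get("rev_primer"),
        )


@dataclass
class TruthRecord:
    """Ground truth of a simulation run."""

    ancestral: dict[str, str]                  # gene -> ancestral sequence
    species_genes: dict[str, dict[str, str]]   # species -> gene -> sequence
    anchors: dict[str, list[tuple[int, int]]]  # gene -> [(start, end), ...]
    p_distances: dict[str, float]              # gene -> mean realized p-distance
    read_sources: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "ancestral": self.ancestral,
            "species_genes": self.species_genes,
            "anchors": {g: [list(t) for t in v] for g, v in self.anchors.items()},
            "p_distances": self.p_distances,
            "read_sources": self.read_sources,
        }, indent=1)


# ---------------------------------------------------------------------------
# panel simulation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, anc: np.ndarray, theta: float,
            mutable: np.ndarray) -> np.ndarray:
    """Substitute each mutable site with probability theta to a uniformly
    chosen *different* base."""
    out = anc.copy()
    hit = mutable & (rng.random(anc.size) < theta)
    idx = np.flatnonzero(hit)
    if idx.size:
        # offset 1..3 within ACGT, relative to current base
        cur = np.searchsorted(_BASES, anc[idx])
        shift = rng.integers(1, 4, size=idx.size)
        out[idx] = _BASES[(cur + shift) % 4]
    return out


def simulate_panel(cfg: SimulationConfig
                   ) -> tuple[list[SequenceRecord], TruthRecord]:
    """Simulate the species panel; genes are concatenated per species and
    annotated with features so ``extract_gene`` works on the records."""
    rng = np.random.default_rng(cfg.seed)
    species_ids = [f"sp{i + 1}" for i in range(cfg.n_species)]
    ancestral: dict[str, str] = {}
    species_genes: dict[str, dict[str, str]] = {sid: {} for sid in species_ids}
    anchors: dict[str, list[tuple[int, int]]] = {g.name: [] for g in cfg.genes}
    p_dist: dict[str, float] = {}

    for gene in cfg.genes:
        anc = _random_seq(rng, gene.length)
        mutable = np.ones(gene.length, dtype=bool)
        for a in cfg.anchors:
            if a.gene != gene.name:
                continue
            if a.primer_seq is not None:
                planted = np.frombuffer(a.primer_seq.upper().encode(),
                                        dtype=np.uint8)
                anc[a.position:a.position + len(planted)] = planted
            mutable[a.position:a.position + a.length] = False
            anchors[gene.name].append((a.position, a.position + a.length))
        ancestral[gene.name] = anc.tobytes().decode()
        rows = []
        for sid in species_ids:
            row = _mutate(rng, anc, gene.theta, mutable)
            species_genes[sid][gene.name] = row.tobytes().decode()
            rows.append(row)
        mat = np.stack(rows)
        dists = [
            (mat[i] != mat[j]).mean()
            for i in range(len(rows)) for j in range(i + 1, len(rows))
        ]
        p_dist[gene.name] = float(np.mean(dists))
        anchors[gene.name].sort()

    records = []
    for sid in species_ids:
        parts, feats, pos = [], [], 0
        for gene in cfg.genes:
            seq = species_genes[sid][gene.name]
            feats.append(GeneFeature(name=gene.name, start=pos,
                                     end=pos + len(seq), strand=1))
            parts.append(seq)
            pos += len(seq)
        records.append(SequenceRecord(id=sid, seq="".join(parts),
                                      description="synthetic panel member",
                                      features=feats))
    truth = TruthRecord(ancestral=ancestral, species_genes=species_genes,
                        anchors=anchors, p_distances=p_dist)
    return records, truth


def panel_alignment(records: Sequence[SequenceRecord], gene: str,
                    truth: TruthRecord) -> GeneAlignment:
    """The trivially true alignment of a simulated gene (no indels)."""
    return GeneAlignment(
        gene=gene,
        species_ids=[r.id for r in records],
        rows=[truth.species_genes[r.id][gene] for r in records],
    )


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def simulate_reads(amplicon_seqs: dict[str, str], weights: Sequence[float],
                   n_reads: int, error_rate: float, seed: int,
                   ) -> tuple[ReadSet, list[str]]:
    """Error-bearing reads from full amplicon sequences.

    Each read's species is Categorical(weights) (species in sorted id
    order); each base substitutes with probability `error_rate` to a
    uniformly chosen different base. Returns the reads and per-read true
    species labels.
    """
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ConfigError("weights must sum to 1")
    species = sorted(amplicon_seqs)
    if len(weights) != len(species):
        raise ConfigError("one weight per species required")
    rng = np.random.default_rng(seed)
    choice = rng.choice(len(species), size=n_reads, p=list(weights))
    reads: list[tuple[str, str, Optional[str]]] = []
    sources: list[str] = []
    for i in range(n_reads):
        sp = species[choice[i]]
        arr = np.frombuffer(amplicon_seqs[sp].encode(), dtype=np.uint8).copy()
        if error_rate > 0:
            arr = _mutate(rng, arr, error_rate,
                          np.ones(arr.size, dtype=bool))
        reads.append((f"read{i + 1:06d}", arr.tobytes().decode(),
                      "I" * arr.size))
        sources.append(sp)
    return ReadSet(reads=reads, source="simulate_reads"), sources


# ---------------------------------------------------------------------------
# fixture writer
# ---------------------------------------------------------------------------

def write_fixture(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate a full fixture and write it as plain-text files.

    Emits ``panel.fasta``, one ``<gene>.aln.fasta`` per gene, optionally
    ``reads.fastq`` (when the config carries primers, weights and a read
    count), and ``truth.json``. Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, truth = simulate_panel(cfg)
    paths: dict[str, Path] = {}

    panel_path = outdir / "panel.fasta"
    write_fasta(records, panel_path)
    paths["panel"] = panel_path

    for gene in cfg.genes:
        aln = panel_alignment(records, gene.name, truth)
        p = outdir / f"{gene.name}.aln.fasta"
        write_alignment(aln, p)
        paths[f"alignment:{gene.name}"] = p

    if cfg.fwd_primer and cfg.rev_primer and cfg.read_count > 0:
        weights = cfg.weights or [1.0 / cfg.n_species] * cfg.n_species
        amps = panel_amplicons(records, (cfg.fwd_primer, cfg.rev_primer))
        amp_seqs = {rec.id: product_seq(rec, amps[rec.id]) for rec in records}
        reads, sources = simulate_reads(amp_seqs, weights, cfg.read_count,
                                        cfg.error_rate, cfg.seed + 1)
        truth.read_sources = sources
        reads_path = outdir / "reads.fastq"
        write_fastq(reads, reads_path)
        paths["reads"] = reads_path

    truth_path = outdir / "truth.json"
    truth_path.write_text(truth.to_json() + "\n")
    paths["truth"] = truth_path
    return paths


def default_config(seed: int = 0, n_reads: int = 2000,
                   error_rate: float = 0.003) -> SimulationConfig:
    """A 5-species, single-gene fixture with two planted primer anchors
    bracketing a 196-nt hypervariable insert."""
    fwd = "AGAAGACCCTATAAAGC"
    rev = "TTAAGTCAACATCGAGG"
    return SimulationConfig(
        n_species=5,
        genes=[GeneSpec(name="geneA", length=800, theta=0.15)],
        anchors=[
            AnchorSpec(gene="geneA", position=100, length=20, primer_seq=fwd),
            AnchorSpec(gene="geneA", position=313, length=20,
                       primer_seq=revcomp(rev)),
        ],
        weights=[0.2] * 5,
        read_count=n_reads,
        error_rate=error_rate,
        seed=seed,
        fwd_primer=fwd,
        rev_primer=rev,
    )
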