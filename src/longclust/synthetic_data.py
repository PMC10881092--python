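"""Synthetic multi-isoform gene families and error-corrupted long reads.

The generator emulates the statistical structure the clustering algorithm
relies on: genes are independent random exon sets (so reads from distinct
genes share essentially no k-mers), while isoforms of one gene are
exon-skipping variants of a common exon chain (so reads from one gene share
most of their sequence).  Reads are drawn from genes with skewed expression
weights, optionally 3'-truncated, pushed through a per-base substitution/
insertion/deletion error channel, and — in cDNA mode — reverse-complemented
with probability 1/2.  A truth table mapping read index to gene id accompanies
the FASTQ.

Everything is fully reproducible from ``SimConfig.seed``.  Two error presets
are provided: an ONT-like 7% channel (40/30/30 sub/ins/del) and a clean
PacBio-like 1% channel.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .io_formats import Read, reverse_complement, write_fasta, write_fastq, write_truth_table

_BASES = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    """Simulation conditions.

    Defaults model a small ONT cDNA experiment: 20 expressed genes, 2000
    reads, 7% error with an ONT-like sub/ins/del mix, log-normal expression
    skew, full-length reads.
    """

    n_genes: int = 20
    n_reads: int = 2000
    error_rate: float = 0.07
    error_mix: tuple[float, float, float] = (0.4, 0.3, 0.3)  # sub, ins, del
    expression: str = "lognormal"  # or "uniform"
    lognormal_sigma: float = 1.0
    length_model: str = "full"  # or "trunc3"
    truncation_max: float = 0.5  # trunc3: up to this fraction lost from the 5' side
    mode: str = "cdna"  # or "drna" (no reverse complementing)
    exons_per_gene: tuple[int, int] = (3, 8)
    exon_length_range: tuple[int, int] = (80, 400)
    max_isoforms: int = 5
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 0.3:
            raise ValueError("error_rate must be in [0, 0.3)")
        if abs(sum(self.error_mix) - 1.0) > 1e-9:
            raise ValueError("error_mix proportions must sum to 1")
        if self.expression not in ("uniform", "lognormal"):
            raise ValueError("expression must be 'uniform' or 'lognormal'")
        if self.length_model not in ("full", "trunc3"):
            raise ValueError("length_model must be 'full' or 'trunc3'")
        if self.mode not in ("cdna", "drna"):
            raise ValueError("mode must be 'cdna' or 'drna'")


PRESETS = {
    "ont-cdna": {"error_rate": 0.07, "error_mix": (0.4, 0.3, 0.3), "mode": "cdna"},
    "ont-drna": {"error_rate": 0.07, "error_mix": (0.4, 0.3, 0.3), "mode": "drna"},
    "pacbio": {"error_rate": 0.01, "error_mix": (0.4, 0.3, 0.3), "mode": "cdna"},
}


def preset_config(name: str, **overrides) -> SimConfig:
    """A :class:`SimConfig` from a platform preset, with keyword overrides."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(SimConfig(), **{**PRESETS[name], **overrides})


@dataclass
class GeneModel:
    """One gene: an ordered exon chain and its isoforms (exon-index subsets)."""

    gene_id: int
    exons: list[str]
    isoforms: list[tuple[int, ...]]
    expression_weight: float = 1.0

    def isoform_sequence(self, i: int) -> str:
        return "".join(self.exons[e] for e in self.isoforms[i])


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def generate_genes(config: SimConfig, rng: np.random.Generator | None = None) -> list[GeneModel]:
    """Generate independent gene models, deterministic under ``config.seed``.

    Each gene gets 3-8 exons of 80-400 bp and 1-5 isoforms.  The first
    isoform is the full exon chain; each additional isoform skips one or two
    exons (never leaving fewer than two), so every isoform pair of a gene
    shares most of its exons while distinct genes share none.
    """
    if config.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    genes: list[GeneModel] = []
    for g in range(config.n_genes):
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        lo, hi = config.exon_length_range
        exons = [_random_dna(rng, int(rng.integers(lo, hi + 1))) for _ in range(n_exons)]
        full = tuple(range(n_exons))
        isoforms = [full]
        n_iso = int(rng.integers(1, config.max_isoforms + 1))
        for _ in range(n_iso - 1):
            max_skip = min(2, n_exons - 2)
            if max_skip < 1:
                break
            n_skip = int(rng.integers(1, max_skip + 1))
            skipped = set(rng.choice(n_exons, size=n_skip, replace=False).tolist())
            iso = tuple(e for e in full if e not in skipped)
            if iso not in isoforms:
                isoforms.append(iso)
        if config.expression == "lognormal":
            weight = float(rng.lognormal(0.0, config.lognormal_sigma))
        else:
            weight = 1.0
        genes.append(GeneModel(g, exons, isoforms, weight))
    return genes


def _apply_errors(
    template: str, rng: np.random.Generator, rate: float, mix: tuple[float, float, float]
) -> str:
    """Per-base error channel: substitution to a different base, insertion of a
    uniform base after the position, or deletion."""
    if rate == 0.0:
        return template
    n = len(template)
    draws = rng.random(n)
    p_sub = rate * mix[0]
    p_ins = rate * mix[1]
    p_del = rate * mix[2]
    event_pos = np.nonzero(draws < p_sub + p_ins + p_del)[0]
    if event_pos.size == 0:
        return template
    out = list(template)
    # walk backwards so earlier indices stay valid
    for pos in event_pos[::-1]:
        d = draws[pos]
        if d < p_sub:
            old = out[pos]
            choices = [b for b in _BASES if b != old]
            out[pos] = choices[int(rng.integers(0, len(choices)))]
        elif d < p_sub + p_ins:
            out.insert(pos + 1, _BASES[int(rng.integers(0, 4))])
        else:
            del out[pos]
    return "".join(out)


def simulate_reads(
    genes: list[GeneModel],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[Read], dict[int, int]]:
    """Draw reads from gene models and return (reads, truth read_index -> gene_id).

    A gene is drawn by expression weight, an isoform uniformly within the
    gene; 3'-truncation (when enabled) keeps a suffix of the template, then
    the error channel runs, then cDNA reads flip strand with probability 1/2.
    """
    if not genes:
        raise ValueError("no gene models to simulate from")
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    weights = np.array([g.expression_weight for g in genes], dtype=float)
    weights /= weights.sum()
    reads: list[Read] = []
    truth: dict[int, int] = {}
    gene_draws = rng.choice(len(genes), size=config.n_reads, p=weights)
    for i, gi in enumerate(gene_draws, start=1):
        gene = genes[int(gi)]
        iso = int(rng.integers(0, len(gene.isoforms)))
        template = gene.isoform_sequence(iso)
        if config.length_model == "trunc3":
            lost = rng.random() * config.truncation_max
            keep = max(int(round(len(template) * (1.0 - lost))), 50)
            template = template[-keep:]
        seq = _apply_errors(template, rng, config.error_rate, config.error_mix)
        if config.mode == "cdna" and rng.random() < 0.5:
            seq = reverse_complement(seq)
        reads.append(Read(i, f"read{i}", seq, "I" * len(seq)))
        truth[i] = gene.gene_id
    return reads, truth


def write_simulation(
    outdir: str | os.PathLike,
    genes: list[GeneModel],
    reads: list[Read],
    truth: dict[int, int],
) -> dict[str, Path]:
    """Write reads.fq, truth.tsv, isoforms.fa and genes.tsv into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fastq(reads, outdir / "reads.fq")
    write_truth_table(truth, outdir / "truth.tsv")
    iso_records = []
    for gene in genes:
        for i, iso in enumerate(gene.isoforms):
            iso_records.append(
                Read(0, f"gene{gene.gene_id}_iso{i}", gene.isoform_sequence(i))
            )
    write_fasta(iso_records, outdir / "isoforms.fa")
    with open(outdir / "genes.tsv", "wt") as fh:
        fh.write("#gene_id\tn_exons\tn_isoforms\texpression_weight\tisoforms\n")
        for gene in genes:
            iso_str = ";".join(",".join(map(str, iso)) for iso in gene.isoforms)
            fh.write(
                f"{gene.gene_id}\t{len(gene.exons)}\t{len(gene.isoforms)}"
                f"\t{gene.expression_weight:.6g}\t{iso_str}\n"
            )
    return {
        "reads.fq": outdir / "reads.fq",
        "truth.tsv": outdir / "truth.tsv",
        "isoforms.fa": outdir / "isoforms.fa",
        "genes.tsv": outdir / "genes.tsv",
    }


def simulate(config: SimConfig) -> tuple[list[GeneModel], list[Read], dict[int, int]]:
    """Convenience wrapper: generate genes then reads under one config."""
    genes = generate_genes(config)
    reads, truth = simulate_reads(genes, config)
    return genes, reads, truth
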