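"""Synthetic endosymbiont genomes, abundance tables and cohort fixtures.

The generators emulate the statistical shape of a bacterial proteome with
measured abundances — the input the transfer-energetics analysis consumes —
so the full pipeline runs without any downloaded data.  Gene lengths are
log-normal (codon-complete, i.e. multiples of 3), GC fractions are normal
truncated to [0, 1], and abundances are drawn log-normal and normalised to
parts-per-million of the proteome (sum = 1e6): protein abundance
distributions are heavy-tailed, and the retention/transfer trade-off hinges
on that high-abundance tail.

All randomness flows from the seed stored in the spec; there is no global
random state.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from egtcost.energetics import GeneRecord

# ~950 bp mean CDS, the average over alphaproteobacterial and cyanobacterial
# model genomes; exp(mu + sd^2/2) with sd = 0.45 gives that mean.
_DEFAULT_LENGTH_LOG_SD = 0.45
_DEFAULT_LENGTH_LOG_MEAN = math.log(950.0) - _DEFAULT_LENGTH_LOG_SD**2 / 2

#: Minimum generated CDS length (bp); keeps proteins biologically sensible.
MIN_CDS_BP = 90

#: Fake taxon prefix used in PAXdb-dialect fixture files.
FIXTURE_TAXON = "99999"


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of a synthetic endosymbiont genome.

    ``n_genes`` ~1500 mimics an alphaproteobacterium-like (pre-mitochondrial)
    genome; ~6000 a cyanobacterium-like (pre-chloroplast) one.  Length
    parameters are in natural-log space; ``abundance_log_sd`` sets the
    heavy-tailedness of the ppm distribution.
    """

    n_genes: int = 1500
    length_log_mean: float = _DEFAULT_LENGTH_LOG_MEAN
    length_log_sd: float = _DEFAULT_LENGTH_LOG_SD
    gc_mean: float = 0.40
    gc_sd: float = 0.05
    abundance_log_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.length_log_sd < 0 or self.gc_sd < 0 or self.abundance_log_sd < 0:
            raise ValueError("spread parameters must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a labelled lost/transferred/retained abundance table.

    The retained (R) group's mean log10 ppm is shifted up by
    ``retained_shift`` relative to the lost (L) and transferred (T) groups,
    mirroring the observation that organellar genomes keep the genes of
    high-abundance proteins.
    """

    n_per_group: int = 50
    base_log10_ppm: float = 2.0
    retained_shift: float = 1.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def generate_genome(spec: GenomeSpec) -> List[GeneRecord]:
    """Draw a synthetic genome of codon-complete genes with ppm abundances.

    Protein length is length/3 - 1 (the stop codon encodes no residue);
    abundances are normalised so the proteome sums to exactly 1e6 ppm.
    Deterministic for a fixed spec (including seed).
    """
    rng = np.random.default_rng(spec.seed)
    raw_len = rng.lognormal(spec.length_log_mean, spec.length_log_sd, spec.n_genes)
    lengths = np.maximum(np.round(raw_len / 3).astype(int) * 3, MIN_CDS_BP)
    gc = np.clip(rng.normal(spec.gc_mean, spec.gc_sd, spec.n_genes), 0.0, 1.0)
    ppm = rng.lognormal(0.0, spec.abundance_log_sd, spec.n_genes)
    ppm = ppm / ppm.sum() * 1e6
    width = len(str(spec.n_genes))
    return [
        GeneRecord(
            id=f"g{i + 1:0{width}d}",
            length_bp=int(lengths[i]),
            gc=float(gc[i]),
            protein_length=int(lengths[i]) // 3 - 1,
            abundance_ppm=float(ppm[i]),
        )
        for i in range(spec.n_genes)
    ]


def generate_cohorts(spec: CohortSpec) -> pd.DataFrame:
    """Labelled abundance table with groups L, T, R.

    Returns a frame with columns ``gene_id``, ``label``, ``abundance_ppm``;
    3 * n_per_group rows, R shifted up by ``retained_shift`` in log10 ppm.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for label in ("L", "T", "R"):
        shift = spec.retained_shift if label == "R" else 0.0
        log10_ppm = rng.normal(
            spec.base_log10_ppm + shift, spec.noise_sd, spec.n_per_group
        )
        for j, v in enumerate(log10_ppm):
            rows.append((f"{label}{j + 1:04d}", label, 10.0**v))
    return pd.DataFrame(rows, columns=["gene_id", "label", "abundance_ppm"])


def _random_cds(length_bp: int, gc: float, rng: np.random.Generator) -> str:
    """Random sequence with GC count round(gc * length) — no codon model."""
    n_gc = int(round(gc * length_bp))
    bases = np.concatenate(
        [
            rng.choice(np.array(["G", "C"]), n_gc),
            rng.choice(np.array(["A", "T"]), length_bp - n_gc),
        ]
    )
    return "".join(rng.permutation(bases))


def write_fixture_bundle(
    genome: Sequence[GeneRecord],
    cohorts: Optional[pd.DataFrame],
    out_dir: str,
    seed: int = 0,
) -> Dict[str, str]:
    """Write a genome (FASTA + GFF3), a PAXdb-dialect abundance TSV and an
    optional cohort table to ``out_dir``; returns the paths written.

    Each gene is written as its own contig with a single full-length CDS
    feature (1-based inclusive coordinates, '+' strand).  The realised
    sequence matches each record's GC fraction to within 1/length.  The
    bundle round-trips losslessly through the package's readers.
    """
    if not genome:
        raise ValueError("cannot write an empty genome")
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths = {
        "fasta": os.path.join(out_dir, "genes.fasta"),
        "gff3": os.path.join(out_dir, "genes.gff3"),
        "abundance": os.path.join(out_dir, "abundance.tsv"),
    }
    with open(paths["fasta"], "w") as fa, open(paths["gff3"], "w") as gff:
        gff.write("##gff-version 3\n")
        for gene in genome:
            seq = _random_cds(gene.length_bp, gene.gc, rng)
            fa.write(f">{gene.id}\n")
            for i in range(0, len(seq), 60):
                fa.write(seq[i : i + 60] + "\n")
            gff.write(
                f"{gene.id}\tegtcost\tgene\t1\t{gene.length_bp}\t.\t+\t.\t"
                f"ID=gene:{gene.id}\n"
            )
            gff.write(
                f"{gene.id}\tegtcost\tCDS\t1\t{gene.length_bp}\t.\t+\t0\t"
                f"ID=cds:{gene.id};Parent=gene:{gene.id}\n"
            )
    with open(paths["abundance"], "w") as ab:
        ab.write("# synthetic PAXdb-dialect abundance table\n")
        ab.write("# internal_id\tstring_external_id\tabundance_ppm\n")
        for i, gene in enumerate(genome, start=1):
            ab.write(f"{i}\t{FIXTURE_TAXON}.{gene.id}\t{gene.abundance_ppm!r}\n")
    if cohorts is not None:
        paths["cohorts"] = os.path.join(out_dir, "cohorts.tsv")
        cohorts.to_csv(paths["cohorts"], sep="\t", index=False)
    return paths
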