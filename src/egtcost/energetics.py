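"""Per-gene ATP and elemental accounting for organellar vs nuclear encoding.

The central quantity is the free energy of endosymbiotic gene transfer,

    dE_EGT = A_DNA * (C_end - C_nuc) - L_prot * C_import * N_p

where ``A_DNA`` is the ATP cost of biosynthesising one double-stranded copy
of the gene's DNA, ``C_end`` / ``C_nuc`` are the per-cell copy numbers of
the endosymbiont (organellar) and nuclear genomes, ``L_prot`` is the protein
length in residues, ``C_import`` the ATP cost of translocating one residue
across the organellar membranes, and ``N_p`` the number of protein copies
that must be produced — and, after transfer, imported — per cell doubling.

Positive ``dE_EGT`` means nuclear encoding is energetically favourable
(transfer saves ATP); negative values favour retention in the organellar
genome.  Protein production cost is assumed identical inside the organelle
and in the cytosol, so production terms cancel and only the import cost
remains on the protein side.

All functions accept scalars or numpy arrays for the numeric arguments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence, Tuple, Union

import numpy as np

Number = Union[float, np.ndarray]

#: ATP cost of complete biosynthesis of one A:T base pair.
ATP_PER_AT_BP = 40.55
#: ATP cost of complete biosynthesis of one G:C base pair.
ATP_PER_GC_BP = 40.14
#: Mean pair cost, used when the GC fraction of a sequence is unknown.
ATP_PER_BP_MEAN = (ATP_PER_AT_BP + ATP_PER_GC_BP) / 2.0

#: ATP opportunity cost of amino-acid biosynthesis (ATP equivalents per
#: residue) for an aerobic heterotroph — the standard cost accounting used
#: throughout cellular-economics work.  Configurable via ``CostTable``.
AMINO_ACID_ATP: Dict[str, float] = {
    "A": 11.7, "R": 27.3, "N": 14.7, "D": 12.7, "C": 24.7,
    "Q": 16.3, "E": 15.3, "G": 11.7, "H": 38.3, "I": 32.3,
    "L": 27.3, "K": 30.3, "M": 34.3, "F": 52.0, "P": 20.3,
    "S": 11.7, "T": 18.7, "W": 74.3, "Y": 50.0, "V": 23.3,
}

#: (carbon, nitrogen, phosphorus) atoms per nucleoside monophosphate.
ATOMS_PER_NUCLEOTIDE: Dict[str, Tuple[int, int, int]] = {
    "A": (10, 5, 1),
    "C": (9, 3, 1),
    "G": (10, 5, 1),
    "T": (10, 2, 1),
}

#: Residue counts of the four core histones (S. cerevisiae); one nucleosome
#: holds two copies of each.  Entries may be replaced by full residue
#: sequences, in which case per-residue costs are summed exactly.
HISTONE_LENGTHS: Dict[str, int] = {"H2A": 132, "H2B": 131, "H3": 136, "H4": 103}

#: One nucleosome (147 bp wrap + 33 bp spacer) per this many bp of nuclear DNA.
NUCLEOSOME_SPACING_BP = 180


@dataclass(frozen=True)
class CostTable:
    """Biosynthetic cost constants used by all accounting operations.

    Every operation reads costs only through this table, so alternative
    published cost sets can be swapped in wholesale.
    """

    atp_per_AT_bp: float = ATP_PER_AT_BP
    atp_per_GC_bp: float = ATP_PER_GC_BP
    atp_per_amino_acid: Mapping[str, float] = field(
        default_factory=lambda: dict(AMINO_ACID_ATP)
    )
    atoms_per_nucleotide: Mapping[str, Tuple[int, int, int]] = field(
        default_factory=lambda: dict(ATOMS_PER_NUCLEOTIDE)
    )
    histones: Mapping[str, Union[int, str]] = field(
        default_factory=lambda: dict(HISTONE_LENGTHS)
    )
    nucleosome_spacing_bp: int = NUCLEOSOME_SPACING_BP

    def __post_init__(self) -> None:
        if self.atp_per_AT_bp <= 0 or self.atp_per_GC_bp <= 0:
            raise ValueError("base-pair ATP costs must be positive")
        if any(c <= 0 for c in self.atp_per_amino_acid.values()):
            raise ValueError("amino-acid ATP costs must be positive")
        if self.nucleosome_spacing_bp <= 0:
            raise ValueError("nucleosome spacing must be positive")

    @property
    def mean_residue_cost(self) -> float:
        """Unweighted mean ATP cost over the 20 amino acids."""
        return float(np.mean(list(self.atp_per_amino_acid.values())))

    def protein_cost(self, protein: Union[int, str]) -> float:
        """ATP biosynthesis cost of one protein copy.

        ``protein`` is either a residue sequence (costs summed exactly) or a
        residue count (count times the mean residue cost).
        """
        if isinstance(protein, str):
            try:
                return sum(self.atp_per_amino_acid[aa] for aa in protein.upper())
            except KeyError as exc:
                raise KeyError(f"no ATP cost for residue {exc.args[0]!r}") from exc
        if protein < 0:
            raise ValueError("protein length must be non-negative")
        return float(protein) * self.mean_residue_cost


@dataclass(frozen=True)
class GeneRecord:
    """One endosymbiont gene: CDS length, GC, protein length, abundance."""

    id: str
    length_bp: int
    gc: float
    protein_length: int
    abundance_ppm: float = 0.0

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"{self.id}: length_bp must be positive")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError(f"{self.id}: gc must lie in [0, 1]")
        if self.protein_length <= 0:
            raise ValueError(f"{self.id}: protein_length must be positive")
        if self.abundance_ppm < 0:
            raise ValueError(f"{self.id}: abundance_ppm must be non-negative")


@dataclass(frozen=True)
class CellModel:
    """One host-cell scenario.

    Parameters
    ----------
    total_proteins
        Total protein molecules per cell (1e7 yeast-like to 1e9
        metazoan/plant-like).
    organellar_fraction
        Fraction of total cellular protein residing in the organelle.
    c_end, c_nuc
        Per-cell copy number of the endosymbiont and nuclear genomes
        (diploid host by default).
    import_cost
        ATP per residue translocated into the organelle.  Measured
        estimates span ~0.05-5; up to 50 is modelled as an extreme.
    turnover
        Times the organellar protein pool is replaced per cell doubling
        (1 = turnover by replicative dilution only).
    doubling_time_h
        Cell doubling time in hours.
    protein_density
        Proteins per cubic micron, used to convert protein count to cell
        volume for the energy budget.
    """

    total_proteins: float
    organellar_fraction: float
    c_end: float
    import_cost: float
    c_nuc: float = 2.0
    turnover: float = 1.0
    doubling_time_h: float = 24.0
    protein_density: float = 1e6

    def __post_init__(self) -> None:
        if self.total_proteins < 1:
            raise ValueError("total_proteins must be >= 1")
        if not 0.0 < self.organellar_fraction <= 1.0:
            raise ValueError("organellar_fraction must lie in (0, 1]")
        if self.c_end < 0:
            raise ValueError("c_end must be non-negative")
        if self.c_nuc < 1:
            raise ValueError("c_nuc must be >= 1")
        if self.import_cost < 0:
            raise ValueError("import_cost must be non-negative")
        if self.turnover < 1:
            raise ValueError("turnover must be >= 1")
        if self.doubling_time_h <= 0:
            raise ValueError("doubling_time_h must be positive")
        if self.protein_density <= 0:
            raise ValueError("protein_density must be positive")


@dataclass(frozen=True)
class ChromosomeRecord:
    """A chromosome whose total cost is amortised over its genes."""

    length_bp: int
    gc: float
    n_genes: int
    copies_per_cell: float
    nucleosomes: bool = False

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.length_bp < self.n_genes:
            raise ValueError("length_bp must be >= n_genes")


@dataclass(frozen=True)
class EGTResult:
    """Per-gene energy balance of a transfer event.

    ``delta_E_EGT = delta_D - p_import`` holds exactly; classification is
    'transfer' for positive, 'retention' for negative, 'neutral' at zero.
    """

    gene_id: str
    delta_D: float
    p_import: float
    delta_E_EGT: float
    n_p: float

    @property
    def classification(self) -> str:
        if self.delta_E_EGT > 0:
            return "transfer"
        if self.delta_E_EGT < 0:
            return "retention"
        return "neutral"


def dna_atp_cost(length_bp: Number, gc: Number, table: CostTable = CostTable()) -> Number:
    """ATP cost of one double-stranded copy of a sequence (A_DNA).

    GC pairs cost slightly less than AT pairs (40.14 vs 40.55 ATP with the
    default table), so the cost is a GC-weighted mean times the length.
    """
    gc_arr = np.asarray(gc, dtype=float)
    if np.any(gc_arr < 0) or np.any(gc_arr > 1):
        raise ValueError("gc must lie in [0, 1]")
    length = np.asarray(length_bp, dtype=float)
    if np.any(length < 0):
        raise ValueError("length_bp must be non-negative")
    cost = length * (gc_arr * table.atp_per_GC_bp + (1.0 - gc_arr) * table.atp_per_AT_bp)
    return float(cost) if np.isscalar(length_bp) and np.isscalar(gc) else cost


def nucleosome_atp_cost(length_bp: int, table: CostTable = CostTable()) -> float:
    """ATP cost of the histones packaging one chromosome copy.

    One octamer — two copies each of H2A, H2B, H3, H4 — per 180 bp window,
    counting partial windows (ceiling), so all DNA is covered.
    """
    if length_bp < 0:
        raise ValueError("length_bp must be non-negative")
    if length_bp == 0:
        return 0.0
    for name in ("H2A", "H2B", "H3", "H4"):
        if name not in table.histones:
            raise KeyError(f"histone table is missing {name}")
    octamer = 2.0 * sum(
        table.protein_cost(table.histones[name]) for name in ("H2A", "H2B", "H3", "H4")
    )
    n_nucleosomes = math.ceil(length_bp / table.nucleosome_spacing_bp)
    return n_nucleosomes * octamer


def per_gene_chromosome_cost(chrom: ChromosomeRecord, table: CostTable = CostTable()) -> float:
    """Per-cell ATP cost of a gene, as chromosome cost amortised over genes.

    Amortising the whole chromosome (introns, structural and regulatory
    elements included) over its gene count makes organellar and nuclear
    chromosomes comparable despite their different architectures.  Histone
    costs are charged only when the chromosome is nucleosome-packaged.
    """
    per_copy = dna_atp_cost(chrom.length_bp, chrom.gc, table)
    if chrom.nucleosomes:
        per_copy += nucleosome_atp_cost(chrom.length_bp, table)
    return chrom.copies_per_cell * per_copy / chrom.n_genes


def dna_savings_bp(length_bp: Number, c_end: Number) -> Number:
    """Base pairs of DNA saved per cell by removing a gene from the
    organellar genome — the headline back-of-envelope metric.

    Deliberately omits the two nuclear copies gained on transfer; the exact
    copy-number difference is carried by :func:`delta_D`.
    """
    out = np.asarray(length_bp) * np.asarray(c_end)
    return out.item() if out.ndim == 0 else out


def delta_D(gene: GeneRecord, cell: CellModel, table: CostTable = CostTable()) -> Number:
    """DNA-side ATP saving of transfer: A_DNA * (C_end - C_nuc).

    Negative when the organellar genome has fewer copies than the nucleus.
    """
    return dna_atp_cost(gene.length_bp, gene.gc, table) * (cell.c_end - cell.c_nuc)


def abundance_to_copies(gene: GeneRecord, cell: CellModel) -> float:
    """Protein copies to produce per cell doubling (N_p).

    The gene's ppm share of the organellar proteome, scaled by the
    organellar fraction of the cell's protein content and by the turnover
    multiplier.  Kept continuous: abundances are ratio-scale estimates.
    """
    return (
        gene.abundance_ppm
        / 1e6
        * cell.organellar_fraction
        * cell.total_proteins
        * cell.turnover
    )


def protein_import_cost(gene: GeneRecord, cell: CellModel) -> float:
    """ATP to import the gene's full per-doubling protein output (delta P).

    delta_P = P_import = L_prot * C_import * N_p; production costs inside
    and outside the organelle are assumed equal and cancel.
    """
    if cell.import_cost < 0:
        raise ValueError("import_cost must be non-negative")
    return gene.protein_length * cell.import_cost * abundance_to_copies(gene, cell)


def delta_E_EGT(gene: GeneRecord, cell: CellModel, table: CostTable = CostTable()) -> EGTResult:
    """Free energy of endosymbiotic gene transfer for one gene.

    Positive values mean nuclear encoding (transfer + import) saves ATP;
    negative values mean organellar retention is cheaper.
    """
    dd = delta_D(gene, cell, table)
    n_p = abundance_to_copies(gene, cell)
    dp = gene.protein_length * cell.import_cost * n_p
    return EGTResult(
        gene_id=gene.id,
        delta_D=float(dd),
        p_import=float(dp),
        delta_E_EGT=float(dd - dp),
        n_p=float(n_p),
    )


def retention_threshold(gene: GeneRecord, cell: CellModel, table: CostTable = CostTable()) -> float:
    """Protein copy number N* above which retention is favoured.

    Setting dE_EGT = 0 and solving for N_p gives
    N* = A_DNA (C_end - C_nuc) / (L_prot C_import): a gene whose required
    per-doubling output exceeds N* costs more to import than its DNA saves.
    """
    if cell.import_cost <= 0:
        raise ValueError("retention threshold undefined at zero import cost")
    if gene.protein_length <= 0:
        raise ValueError("retention threshold undefined at zero protein length")
    return dna_atp_cost(gene.length_bp, gene.gc, table) * (cell.c_end - cell.c_nuc) / (
        gene.protein_length * cell.import_cost
    )


def machinery_overhead_per_residue(
    machinery_proteins: Iterable[Tuple[float, float, float]],
    total_imported_residues: float,
) -> float:
    """Import-machinery biosynthesis cost amortised per imported residue.

    Each machinery entry is (protein_length, copies_per_cell,
    ATP_per_residue); the full biosynthesis cost of the machinery at its
    cellular abundance is spread evenly over all residues imported per
    doubling.  For real TOC/TIC or TOM/TIM complexes this overhead is a few
    tenths of an ATP per residue, well inside the modelled import-cost range.
    """
    machinery = list(machinery_proteins)
    if not machinery:
        return 0.0
    if total_imported_residues <= 0:
        raise ValueError("total_imported_residues must be positive")
    total = sum(length * copies * cost for length, copies, cost in machinery)
    return total / total_imported_residues


def elemental_savings(
    gene: GeneRecord, c_end: Number, table: CostTable = CostTable()
) -> Tuple[float, float, float]:
    """(carbon, nitrogen, phosphorus) atoms saved per cell by gene removal.

    Assumes Watson-Crick pairing, so the double-stranded composition is
    fully determined by length and GC: each A:T pair contributes the atoms
    of one A and one T nucleotide, each G:C pair those of one G and one C.
    """
    c_end_arr = np.asarray(c_end, dtype=float)
    if np.any(c_end_arr < 0):
        raise ValueError("c_end must be non-negative")
    at_pair = tuple(
        a + t for a, t in zip(table.atoms_per_nucleotide["A"], table.atoms_per_nucleotide["T"])
    )
    gc_pair = tuple(
        g + c for g, c in zip(table.atoms_per_nucleotide["G"], table.atoms_per_nucleotide["C"])
    )
    n_gc = gene.length_bp * gene.gc
    n_at = gene.length_bp * (1.0 - gene.gc)
    return tuple(
        float((n_at * at + n_gc * gc) * c_end_arr)
        for at, gc in zip(at_pair, gc_pair)
    )
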