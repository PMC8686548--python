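"""Grid sweeps of transfer energetics over host-cell parameter space.

For every combination of host protein count, organellar fraction,
organellar genome copy number, import cost and turnover, the transfer free
energy is evaluated for every gene in the genome, and the genes are counted
as retention-favourable (dE_EGT < 0), transfer-favourable (> 0) or neutral
(= 0).  The evaluation is vectorised over genes but exactly equivalent to
gene-by-gene scalar evaluation; grids are deterministic and keyed by their
parameter values, not list positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from egtcost.budget import EnergyBudget, SelectionRecord, selection_coefficient
from egtcost.energetics import CellModel, CostTable, EGTResult, GeneRecord, dna_atp_cost

GRID_COLUMNS = [
    "total_proteins",
    "organellar_fraction",
    "c_end",
    "import_cost",
    "turnover",
]
COUNT_COLUMNS = ["n_retained", "n_transferred", "n_neutral"]


@dataclass(frozen=True)
class SweepGrid:
    """Factorial host-cell parameter grid.

    Defaults span the modelled eukaryotic range: yeast-like (1e7 proteins)
    to metazoan/plant-like (1e9) hosts, 2-50% organellar fraction, 1 to
    10,000 organellar genome copies (log-spaced), measured import costs
    0.05-5 ATP/residue, and turnover of the organellar protein pool 1 to 50
    times per doubling.  The host is diploid unless overridden.
    """

    host_protein_counts: Tuple[float, ...] = (1e7, 1e8, 1e9)
    organellar_fractions: Tuple[float, ...] = (0.02, 0.05, 0.2, 0.5)
    c_end_values: Tuple[float, ...] = (1, 3, 10, 30, 100, 300, 1000, 3000, 10000)
    import_costs: Tuple[float, ...] = (0.05, 2.0, 5.0)
    turnover_values: Tuple[float, ...] = (1.0, 5.0, 50.0)
    c_nuc: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "host_protein_counts",
            "organellar_fractions",
            "c_end_values",
            "import_costs",
            "turnover_values",
        ):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")

    def points(self):
        """Yield grid points as parameter tuples, in deterministic order."""
        for total in self.host_protein_counts:
            for frac in self.organellar_fractions:
                for c_end in self.c_end_values:
                    for imp in self.import_costs:
                        for turn in self.turnover_values:
                            yield total, frac, c_end, imp, turn


def _gene_arrays(genome: Sequence[GeneRecord], costs: CostTable):
    a_dna = np.array([dna_atp_cost(g.length_bp, g.gc, costs) for g in genome])
    l_prot = np.array([g.protein_length for g in genome], dtype=float)
    ppm = np.array([g.abundance_ppm for g in genome], dtype=float)
    return a_dna, l_prot, ppm


def _delta_e_vector(a_dna, l_prot, ppm, total, frac, c_end, c_nuc, imp, turn):
    n_p = ppm / 1e6 * frac * total * turn
    return a_dna * (c_end - c_nuc) - l_prot * imp * n_p


def run_sweep(
    genome: Sequence[GeneRecord],
    grid: SweepGrid = SweepGrid(),
    costs: CostTable = CostTable(),
    per_gene: bool = False,
) -> pd.DataFrame:
    """Count retention/transfer-favourable genes at every grid point.

    Returns a long-format frame with one row per grid point: the five
    parameters plus n_retained, n_transferred, n_neutral (summing to the
    genome size).  With ``per_gene=True`` a ``delta_E_EGT`` column holding
    the per-gene vector is attached (memory scales with grid x genes).
    """
    if not genome:
        raise ValueError("genome must be non-empty")
    a_dna, l_prot, ppm = _gene_arrays(genome, costs)
    rows = []
    detail = [] if per_gene else None
    for total, frac, c_end, imp, turn in grid.points():
        de = _delta_e_vector(a_dna, l_prot, ppm, total, frac, c_end, grid.c_nuc, imp, turn)
        rows.append(
            (
                total,
                frac,
                c_end,
                imp,
                turn,
                int(np.sum(de < 0)),
                int(np.sum(de > 0)),
                int(np.sum(de == 0)),
            )
        )
        if per_gene:
            detail.append(de)
    out = pd.DataFrame(rows, columns=GRID_COLUMNS + COUNT_COLUMNS)
    if per_gene:
        out["delta_E_EGT"] = detail
    return out


def egt_table(
    genome: Sequence[GeneRecord],
    cell: CellModel,
    costs: CostTable = CostTable(),
) -> pd.DataFrame:
    """Full per-gene transfer-energetics table for one cell scenario.

    Columns: gene_id, length_bp, gc, protein_length, ppm, n_p, delta_D,
    p_import, delta_E_EGT, class.
    """
    from egtcost.energetics import delta_E_EGT as _degt

    rows = []
    for g in genome:
        r = _degt(g, cell, costs)
        rows.append(
            (
                g.id,
                g.length_bp,
                g.gc,
                g.protein_length,
                g.abundance_ppm,
                r.n_p,
                r.delta_D,
                r.p_import,
                r.delta_E_EGT,
                r.classification,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "length_bp",
            "gc",
            "protein_length",
            "ppm",
            "n_p",
            "delta_D",
            "p_import",
            "delta_E_EGT",
            "class",
        ],
    )


def selection_spectrum(
    genome: Sequence[GeneRecord],
    cell: CellModel,
    budget: EnergyBudget,
    costs: CostTable = CostTable(),
) -> List[SelectionRecord]:
    """Per-gene selection coefficients, strongest first.

    One record per gene, sorted by decreasing |s| with gene_id as a stable
    tiebreak — the spectrum view used to read off how much of the genome
    sits above a given selection strength.
    """
    from egtcost.energetics import delta_E_EGT as _degt

    records = [selection_coefficient(_degt(g, cell, costs), budget) for g in genome]
    records.sort(key=lambda r: (-abs(r.s), r.gene_id))
    return records


def turnover_comparison(
    genome: Sequence[GeneRecord],
    grid: SweepGrid = SweepGrid(),
    costs: CostTable = CostTable(),
) -> pd.DataFrame:
    """Sweep stratified by turnover, for contrasting dividing cells
    (turnover 1) with long-lived or non-dividing cells (turnover 5-50).

    Higher turnover inflates the protein copies to import and so can only
    move genes toward retention: n_retained is non-decreasing in turnover
    at every other-parameter combination.
    """
    out = run_sweep(genome, grid, costs)
    return out.sort_values(
        ["total_proteins", "organellar_fraction", "c_end", "import_cost", "turnover"]
    ).reset_index(drop=True)
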