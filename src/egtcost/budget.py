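"""Host-cell energy budgets and selection coefficients.

The energetic gain of a single gene transfer only matters relative to the
cell's total energy turnover.  Growth and maintenance costs scale with cell
volume V (in cubic microns) as

    C_r = 26.92 V^0.97          (growth, units of 1e9 ATP)
    C_m = 0.39  V^0.88          (maintenance, units of 1e9 ATP per hour)

so the total replication energy over a doubling time t hours is
E_R = C_r + t * C_m.  The proportional energetic advantage of a transfer,
dE_EGT / E_R, is read directly as the selection coefficient s acting on the
transfer allele: positive s favours transfer (class ``S_EGT``), negative s
favours organellar retention (class ``S_R``, reported by magnitude).
"""

from __future__ import annotations

from dataclasses import dataclass

from egtcost.energetics import CellModel, EGTResult

GROWTH_COEF = 26.92
GROWTH_EXP = 0.97
MAINTENANCE_COEF = 0.39
MAINTENANCE_EXP = 0.88
#: C_r and C_m are expressed in units of this many ATP.
ATP_UNIT = 1e9


@dataclass(frozen=True)
class EnergyBudget:
    """Growth, maintenance and total replication energy of one cell.

    ``c_r`` and ``e_r`` are in units of 1e9 ATP; ``c_m`` in 1e9 ATP per
    hour.  ``e_r = c_r + doubling_time_h * c_m`` by construction.
    """

    volume_um3: float
    c_r: float
    c_m: float
    e_r: float

    @property
    def e_r_atp(self) -> float:
        """Total replication energy in plain ATP molecules."""
        return self.e_r * ATP_UNIT


@dataclass(frozen=True)
class SelectionRecord:
    """Selection coefficient of a transfer allele for one gene.

    ``s`` is stored with its sign; ``class_`` is ``S_EGT`` (s > 0),
    ``S_R`` (s < 0, magnitude reported as retention strength) or
    ``neutral`` (s == 0).
    """

    gene_id: str
    s: float
    class_: str

    @property
    def magnitude(self) -> float:
        return abs(self.s)


def volume_from_proteins(total_proteins: float, protein_density: float = 1e6) -> float:
    """Cell volume in cubic microns implied by a protein count.

    Protein density defaults to 1e6 proteins per cubic micron (a yeast cell
    of ~4e7 proteins occupies ~40 um^3).
    """
    if protein_density <= 0:
        raise ValueError("protein_density must be positive")
    if total_proteins < 0:
        raise ValueError("total_proteins must be non-negative")
    return total_proteins / protein_density


def replication_energy(volume_um3: float, doubling_time_h: float = 24.0) -> EnergyBudget:
    """Total energy to replicate a cell of the given volume once."""
    if volume_um3 <= 0:
        raise ValueError("volume must be positive")
    if doubling_time_h <= 0:
        raise ValueError("doubling_time_h must be positive")
    c_r = GROWTH_COEF * volume_um3**GROWTH_EXP
    c_m = MAINTENANCE_COEF * volume_um3**MAINTENANCE_EXP
    return EnergyBudget(
        volume_um3=volume_um3,
        c_r=c_r,
        c_m=c_m,
        e_r=c_r + doubling_time_h * c_m,
    )


def cell_energy_budget(cell: CellModel) -> EnergyBudget:
    """Energy budget of a :class:`CellModel`, via its protein density."""
    return replication_energy(
        volume_from_proteins(cell.total_proteins, cell.protein_density),
        cell.doubling_time_h,
    )


def selection_coefficient(egt: EGTResult, budget: EnergyBudget) -> SelectionRecord:
    """Selection coefficient of one transfer event.

    The fraction of the cell's replication energy saved (or lost) by the
    transfer is taken directly as the fitness effect.
    """
    if budget.e_r <= 0:
        raise ValueError("replication energy must be positive")
    s = egt.delta_E_EGT / budget.e_r_atp
    if s > 0:
        class_ = "S_EGT"
    elif s < 0:
        class_ = "S_R"
    else:
        class_ = "neutral"
    return SelectionRecord(gene_id=egt.gene_id, s=s, class_=class_)
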