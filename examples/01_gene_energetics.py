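"""Energy balance of transferring one organellar gene to the nucleus.

Builds a single 1-kb gene with a 300-residue product and walks through the
accounting: the ATP its DNA costs per cell at organellar copy numbers, the
import bill for its protein, and the resulting free energy of transfer.
"""

from egtcost import (
    CellModel,
    GeneRecord,
    delta_E_EGT,
    dna_atp_cost,
    dna_savings_bp,
    retention_threshold,
)

gene = GeneRecord(id="demo", length_bp=1000, gc=0.5, protein_length=300, abundance_ppm=1000.0)

# A plant-like chloroplast scenario: 1500 genome copies per cell.
cell = CellModel(
    total_proteins=1e7, organellar_fraction=0.02, c_end=1500, c_nuc=2, import_cost=2.0
)

a_dna = dna_atp_cost(gene.length_bp, gene.gc)
print(f"DNA cost of one double-stranded gene copy: {a_dna:,.0f} ATP")
print(f"DNA saved per cell by removing the organellar copies: "
      f"{dna_savings_bp(gene.length_bp, cell.c_end):,.0f} bp")

result = delta_E_EGT(gene, cell)
print(f"DNA-side saving  (dD):          {result.delta_D:,.0f} ATP")
print(f"protein import bill (dP):       {result.p_import:,.0f} ATP "
      f"({result.n_p:,.0f} copies imported per doubling)")
print(f"free energy of transfer (dE):   {result.delta_E_EGT:,.0f} ATP -> {result.classification}")

n_star = retention_threshold(gene, cell)
print(f"retention threshold N*: {n_star:,.0f} protein copies per doubling")
print("Above N*, the import bill exceeds the DNA saving and the gene is")
print("cheaper to keep in the organellar genome.")
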