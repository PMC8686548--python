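"""Readers and writers for the formats the pipeline touches.

Genome input is accepted either as FASTA + GFF3 (lengths, GC and protein
lengths are derived from the CDS features) or as a pre-digested 5-column
gene TSV (id, length_bp, gc, protein_length, ppm), so the accounting core
is testable without sequence parsing.  Abundances come from PAXdb-dialect
TSVs: '#'-prefixed comment lines, then internal_id, string_id, abundance
columns, with string ids of the form ``<taxon>.<protein_id>``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gffutils
import pandas as pd
import yaml
from Bio import SeqIO

from egtcost.energetics import CostTable, GeneRecord

logger = logging.getLogger(__name__)

GENE_TSV_COLUMNS = ["id", "length_bp", "gc", "protein_length", "ppm"]


def _gc_fraction(seq: str) -> float:
    seq = seq.upper()
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


def read_gene_models(fasta_path: str, gff3_path: str) -> List[GeneRecord]:
    """Build gene records from a FASTA and its GFF3 gene models.

    CDS parts sharing a parent gene are concatenated (multi-exon genes);
    coordinates are 1-based inclusive per GFF3 and converted internally.
    GC is computed from the concatenated CDS (strand does not change GC,
    but minus-strand features are reverse-complemented for correctness).
    Genes whose total CDS length is not a multiple of 3 are kept with a
    warning and a floor-division protein length.
    """
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(fasta_path, "fasta")}
    if not seqs:
        raise ValueError(f"no sequences parsed from {fasta_path}")
    db = gffutils.create_db(
        gff3_path, dbfn=":memory:", merge_strategy="create_unique", keep_order=True
    )
    by_gene: Dict[str, List] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent") or [cds.id or "cds"]
        by_gene.setdefault(parents[0], []).append(cds)
    if not by_gene:
        raise ValueError(f"no CDS features found in {gff3_path}")

    records = []
    for parent, parts in sorted(by_gene.items()):
        parts.sort(key=lambda f: f.start)
        chunks = []
        for f in parts:
            if f.seqid not in seqs:
                raise ValueError(
                    f"GFF3 references contig {f.seqid!r} absent from {fasta_path}"
                )
            chunk = seqs[f.seqid][f.start - 1 : f.end]  # 1-based inclusive
            if f.strand == "-":
                chunk = _revcomp(chunk)
            chunks.append(chunk)
        cds_seq = "".join(chunks)
        length = len(cds_seq)
        if length % 3 != 0:
            logger.warning("gene %s: CDS length %d not divisible by 3", parent, length)
        gene_id = parent.split(":", 1)[-1]
        records.append(
            GeneRecord(
                id=gene_id,
                length_bp=length,
                gc=_gc_fraction(cds_seq),
                protein_length=max(length // 3 - 1, 1),
                abundance_ppm=0.0,
            )
        )
    return records


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_abundances(paxdb_tsv_path: str) -> Dict[str, float]:
    """Parse a PAXdb-dialect abundance file into protein_id -> ppm.

    Taxon prefixes (everything up to the first '.') are stripped from the
    identifier column.  Malformed or negative rows are skipped with a
    logged count; a file with no parseable rows is an error.
    """
    abundances: Dict[str, float] = {}
    skipped = 0
    with open(paxdb_tsv_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                skipped += 1
                continue
            try:
                ppm = float(fields[2])
            except ValueError:
                skipped += 1
                continue
            if ppm < 0:
                skipped += 1
                continue
            protein_id = fields[1]
            if "." in protein_id:
                protein_id = protein_id.split(".", 1)[1]
            abundances[protein_id] = ppm
    if skipped:
        logger.info("read_abundances: skipped %d malformed rows", skipped)
    if not abundances:
        raise ValueError(f"no abundance rows parsed from {paxdb_tsv_path}")
    return abundances


def join_genome_abundance(
    genes: Sequence[GeneRecord],
    abundances: Dict[str, float],
    policy: str = "drop_unmatched",
) -> List[GeneRecord]:
    """Attach ppm abundances to gene records.

    ``drop_unmatched`` keeps only genes with a measured abundance (the
    conservative default); ``zero_fill`` keeps all genes, assigning 0 ppm
    to unmatched ones (which then have no import cost at all).  Published
    ppm values are kept as-is: no re-normalisation after the join.
    """
    if policy not in ("drop_unmatched", "zero_fill"):
        raise ValueError(f"unknown join policy {policy!r}")
    out = []
    unmatched = 0
    for gene in genes:
        if gene.id in abundances:
            out.append(
                GeneRecord(
                    id=gene.id,
                    length_bp=gene.length_bp,
                    gc=gene.gc,
                    protein_length=gene.protein_length,
                    abundance_ppm=abundances[gene.id],
                )
            )
        else:
            unmatched += 1
            if policy == "zero_fill":
                out.append(gene)
    if unmatched:
        logger.info("join_genome_abundance: %d unmatched genes (%s)", unmatched, policy)
    return out


def read_gene_tsv(path: str) -> List[GeneRecord]:
    """Read a pre-digested 5-column gene table."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(GENE_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene TSV {path} is missing columns: {sorted(missing)}")
    return [
        GeneRecord(
            id=str(r.id),
            length_bp=int(r.length_bp),
            gc=float(r.gc),
            protein_length=int(r.protein_length),
            abundance_ppm=float(r.ppm),
        )
        for r in df.itertuples(index=False)
    ]


def write_gene_tsv(genes: Sequence[GeneRecord], path: str) -> None:
    pd.DataFrame(
        [
            (g.id, g.length_bp, g.gc, g.protein_length, g.abundance_ppm)
            for g in genes
        ],
        columns=GENE_TSV_COLUMNS,
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_cost_table(path: str) -> CostTable:
    """Build a :class:`CostTable` from a YAML config file.

    Schema (all keys optional; omitted keys keep the built-in defaults)::

        atp_per_AT_bp: 40.55
        atp_per_GC_bp: 40.14
        atp_per_amino_acid: {A: 11.7, R: 27.3, ...}   # 20 single-letter keys
        atoms_per_nucleotide: {A: [10, 5, 1], ...}    # [C, N, P] per base
        histones: {H2A: 132, H2B: 131, H3: 136, H4: 103}  # lengths or sequences
        nucleosome_spacing_bp: 180
    """
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    kwargs = {}
    for key in ("atp_per_AT_bp", "atp_per_GC_bp", "nucleosome_spacing_bp"):
        if key in config:
            kwargs[key] = config[key]
    if "atp_per_amino_acid" in config:
        kwargs["atp_per_amino_acid"] = {
            str(k): float(v) for k, v in config["atp_per_amino_acid"].items()
        }
    if "atoms_per_nucleotide" in config:
        kwargs["atoms_per_nucleotide"] = {
            str(k): tuple(int(x) for x in v)
            for k, v in config["atoms_per_nucleotide"].items()
        }
    if "histones" in config:
        kwargs["histones"] = dict(config["histones"])
    unknown = set(config) - {
        "atp_per_AT_bp",
        "atp_per_GC_bp",
        "atp_per_amino_acid",
        "atoms_per_nucleotide",
        "histones",
        "nucleosome_spacing_bp",
    }
    if unknown:
        raise ValueError(f"unknown cost-table keys in {path}: {sorted(unknown)}")
    return CostTable(**kwargs)


def write_provenance(out_dir: str, config: dict, seed: Optional[int]) -> str:
    """Record the run configuration (hash, seed, version) alongside outputs."""
    from egtcost import __version__

    os.makedirs(out_dir, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    payload = {
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "config": config,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = os.path.join(out_dir, "provenance.json")
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
    return path
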