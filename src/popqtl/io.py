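"""Readers and writers for the pipeline's on-disk formats.

Formats are deliberately plain text: map TSV, genotype/phenotype CSV, GFF3
for the gene catalog, BLAST outfmt-6 TSV for homology tables, aligned FASTA
for codon pairs, BED for physical intervals, and JSON for truth records and
run reports.  E-values are converted to log10 on read by parsing the
printed exponent, so scores far beyond double-precision underflow ("1e-320"
or BLAST's literal "0.0") survive the round trip.
"""

from __future__ import annotations

import json
import math
import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .qtl import PhysicalInterval
from .simulate import GeneticMap, TruthRecord

__all__ = [
    "evalue_to_log10",
    "log10_to_evalue_str",
    "write_map_tsv",
    "read_map_tsv",
    "write_genotypes_csv",
    "read_genotypes_csv",
    "write_phenotypes_csv",
    "read_phenotypes_csv",
    "write_gff3",
    "read_gff3",
    "write_blast_tsv",
    "read_blast_tsv",
    "write_cds_pairs_fasta",
    "read_cds_pairs_fasta",
    "write_intervals_bed",
    "read_intervals_bed",
    "write_truth_json",
    "write_terms_tsv",
    "read_terms_tsv",
]

BLAST6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]

_EVALUE_RE = re.compile(r"^\s*([0-9.]+)[eE]([+-]?\d+)\s*$")


def evalue_to_log10(text: str) -> float:
    """log10 of a printed E-value; '0.0' becomes -inf, exponents are exact."""
    s = str(text).strip()
    m = _EVALUE_RE.match(s)
    if m:
        mant = float(m.group(1))
        if mant == 0.0:
            return -math.inf
        return math.log10(mant) + int(m.group(2))
    v = float(s)
    if v == 0.0:
        return -math.inf
    return math.log10(v)


def log10_to_evalue_str(log10_e: float) -> str:
    if log10_e == -math.inf:
        return "0.0"
    exp = math.floor(log10_e)
    mant = 10.0 ** (log10_e - exp)
    return f"{mant:.3f}e{exp:+03d}"


# --- genetic map -----------------------------------------------------------


def write_map_tsv(gmap: GeneticMap, path) -> None:
    t = gmap.table.copy()
    t["chrom_length_cM"] = t["chrom"].map(gmap.chrom_length_cM)
    t["chrom_length_bp"] = t["chrom"].map(gmap.chrom_length_bp)
    t.to_csv(path, sep="\t", index=False)


def read_map_tsv(path) -> GeneticMap:
    t = pd.read_csv(path, sep="\t")
    len_cm = t.groupby("chrom")["chrom_length_cM"].first().to_dict()
    len_bp = t.groupby("chrom")["chrom_length_bp"].first().astype(int).to_dict()
    return GeneticMap(
        t[["marker", "chrom", "cM", "bp"]],
        {int(k): float(v) for k, v in len_cm.items()},
        {int(k): int(v) for k, v in len_bp.items()},
    )


# --- genotypes and phenotypes ---------------------------------------------


def write_genotypes_csv(geno: pd.DataFrame, path) -> None:
    geno.to_csv(path, na_rep="NA")


def read_genotypes_csv(path) -> pd.DataFrame:
    g = pd.read_csv(path, index_col=0, na_values=["NA"], dtype=str)
    g.index.name = "genotype_id"
    return g


def write_phenotypes_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, na_rep="NA")


def read_phenotypes_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, na_values=["NA"])


# --- gene catalog (GFF3) ---------------------------------------------------


def write_gff3(catalog: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, r in catalog.iterrows():
            fh.write(
                f"Chr{int(r['chrom']):02d}\tpopqtl\tgene\t{int(r['start'])}\t"
                f"{int(r['end'])}\t.\t{r['strand']}\t.\tID={r['gene_id']}\n"
            )


def read_gff3(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9 or f[2] != "gene":
                continue
            m = re.search(r"ID=([^;]+)", f[8])
            if not m:
                raise ValueError(f"gene feature without ID attribute: {line!r}")
            chrom = int(re.sub(r"[^0-9]", "", f[0]))
            rows.append((m.group(1), chrom, int(f[3]), int(f[4]), f[6]))
    cat = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    cat = cat.sort_values(["chrom", "start"]).reset_index(drop=True)
    cat["index"] = cat.groupby("chrom").cumcount()
    return cat


# --- homology (BLAST outfmt 6) --------------------------------------------


def write_blast_tsv(homology: pd.DataFrame, path) -> None:
    """Write the internal homology frame as BLAST outfmt-6 rows."""
    with open(path, "w") as fh:
        for _, r in homology.iterrows():
            length = int(r.get("length", 300))
            fh.write(
                "\t".join(
                    [
                        str(r["query"]),
                        str(r["subject"]),
                        f"{float(r['pident']):.2f}",
                        str(length),
                        str(int(length * (1 - float(r["pident"]) / 100))),
                        "0",
                        "1",
                        str(length),
                        "1",
                        str(length),
                        log10_to_evalue_str(float(r["log10_evalue"])),
                        "500",
                    ]
                )
                + "\n"
            )


def read_blast_tsv(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS, dtype={"evalue": str})
    return pd.DataFrame(
        {
            "query": t["qseqid"],
            "subject": t["sseqid"],
            "log10_evalue": t["evalue"].map(evalue_to_log10),
            "pident": t["pident"].astype(float),
            "length": t["length"].astype(int),
        }
    )


# --- codon-aligned CDS pairs ----------------------------------------------


def write_cds_pairs_fasta(pairs: list[tuple[str, str]], path) -> None:
    records = []
    for i, (a, b) in enumerate(pairs, start=1):
        records.append(SeqRecord(Seq(a), id=f"pair{i:04d}_a", description=""))
        records.append(SeqRecord(Seq(b), id=f"pair{i:04d}_b", description=""))
    SeqIO.write(records, path, "fasta")


def read_cds_pairs_fasta(path) -> list[tuple[str, str]]:
    records = list(SeqIO.parse(path, "fasta"))
    if len(records) % 2:
        raise ValueError("odd record count; expected _a/_b pairs")
    return [
        (str(records[i].seq), str(records[i + 1].seq))
        for i in range(0, len(records), 2)
    ]


# --- intervals (BED) -------------------------------------------------------


def write_intervals_bed(intervals: list[PhysicalInterval], path) -> None:
    """BED is 0-based half-open; internal intervals are 1-based inclusive."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"Chr{iv.chrom:02d}\t{iv.start - 1}\t{iv.end}\n")


def read_intervals_bed(path) -> list[PhysicalInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom_s, start_s, end_s = line.split()[:3]
            chrom = int(re.sub(r"[^0-9]", "", chrom_s))
            out.append(PhysicalInterval(chrom, int(start_s) + 1, int(end_s)))
    return out


# --- term annotations ------------------------------------------------------


def write_terms_tsv(term_map: pd.DataFrame, path) -> None:
    term_map.to_csv(path, sep="\t", index=False)


def read_terms_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --- truth / reports -------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_truth_json(truth: TruthRecord, path) -> None:
    payload = {
        "qtl": [
            {"chrom": q.chrom, "pos_cM": q.pos_cM, "effect": q.effect, "trait": q.trait}
            for q in truth.qtl
        ],
        "genetic_values": _jsonable(truth.genetic_values),
        "true_h2": _jsonable(truth.true_h2),
        "surface": _jsonable(truth.surface),
        "tandem_clusters": truth.tandem_clusters,
        "interval_bp": [list(t) for t in truth.interval_bp],
        "omegas": truth.omegas,
    }
    Path(path).write_text(json.dumps(payload, indent=1))
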