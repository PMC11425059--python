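"""File-format helpers: FASTA/FASTQ (plain or gzip), TSV tables, newick."""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_sequences(path) -> dict[str, str]:
    """FASTA or FASTQ (by extension), plain or gzipped."""
    path = Path(path)
    stem = path.name[:-3] if path.suffix == ".gz" else path.name
    fmt = "fastq" if stem.endswith((".fq", ".fastq")) else "fasta"
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(fh, fmt)}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_kmer_table(path) -> dict[str, int]:
    """Two-column TSV: kmer, count."""
    df = pd.read_csv(path, sep="\t", header=None, names=["kmer", "count"],
                     dtype={"kmer": str, "count": int})
    return dict(zip(df["kmer"], df["count"]))


def write_kmer_table(table: dict[str, int], path) -> None:
    with _open_text(path, "wt") as fh:
        for kmer in sorted(table):
            fh.write(f"{kmer}\t{table[kmer]}\n")


def read_variant_table(path) -> pd.DataFrame:
    """TSV: site_id, depth, minor_count."""
    return pd.read_csv(path, sep="\t")


def read_variant_vcf(path) -> pd.DataFrame:
    """Minimal VCF import reading AD-style allele depths from sample 1."""
    rows = []
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 10:
                continue
            fmt_keys = parts[8].split(":")
            if "AD" not in fmt_keys:
                continue
            ad = parts[9].split(":")[fmt_keys.index("AD")]
            depths = sorted((int(x) for x in ad.split(",")), reverse=True)
            if len(depths) < 2 or sum(depths) == 0:
                continue
            rows.append((f"{parts[0]}:{parts[1]}", sum(depths[:2]),
                         depths[1]))
    return pd.DataFrame(rows, columns=["site_id", "depth", "minor_count"])


def read_ssr_table(path) -> dict[str, list]:
    """TSV: locus_id, individual, alleles (comma-separated lengths)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, list] = {}
    for rec in df.itertuples():
        out.setdefault(rec.locus_id, []).extend(
            int(a) for a in str(rec.alleles).split(","))
    return out


def read_newick(path) -> str:
    return Path(path).read_text().strip()


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)
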