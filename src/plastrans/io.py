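"""File input/output: genome records, label tables, fragment FASTA, manifests."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulator import Fragment

__all__ = [
    "read_genomes",
    "write_genomes",
    "read_label_table",
    "apply_labels",
    "write_fragments_fasta",
    "read_fragments_fasta",
    "write_manifest",
]


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _sniff_format(path: str | Path) -> str:
    name = Path(path).name.removesuffix(".gz")
    if name.endswith((".gb", ".gbk", ".gbff", ".genbank")):
        return "genbank"
    return "fasta"


def read_genomes(path: str | Path, fmt: str | None = None) -> list[SeqRecord]:
    """Read GenBank or FASTA genome records (gzip-transparent, format by suffix)."""
    fmt = fmt or _sniff_format(path)
    with _open_text(path) as handle:
        records = list(SeqIO.parse(handle, fmt))
    if not records:
        raise ValueError(f"no records parsed from {path}")
    for rec in records:
        rec.annotations.setdefault("molecule_type", "DNA")
    return records


def write_genomes(records: list[SeqRecord], path: str | Path, fmt: str | None = None) -> None:
    fmt = fmt or _sniff_format(path)
    with open(path, "w") as handle:
        SeqIO.write(records, handle, fmt)


def read_label_table(path: str | Path) -> pd.DataFrame:
    """Label table TSV with columns genome_id, label[, split]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"genome_id", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"label table {path} lacks columns: {sorted(missing)}")
    return df


def apply_labels(records: list[SeqRecord], labels: pd.DataFrame) -> list[SeqRecord]:
    """Attach transmissibility label (and split, when present) to records."""
    table = labels.set_index("genome_id")
    for rec in records:
        if rec.id not in table.index:
            raise ValueError(f"genome {rec.id!r} missing from the label table")
        rec.annotations["transmissibility"] = table.loc[rec.id, "label"]
        if "split" in table.columns and pd.notna(table.loc[rec.id, "split"]):
            rec.annotations["split"] = table.loc[rec.id, "split"]
    return records


def write_fragments_fasta(fragments: list[Fragment], path: str | Path) -> None:
    records = (
        SeqRecord(Seq(f.sequence), id=f.fragment_id or f"frag{i}",
                  description=f"label={f.label} genome={f.genome_id} group={f.group}")
        for i, f in enumerate(fragments)
    )
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


def _desc_fields(description: str) -> dict[str, str]:
    return dict(tok.split("=", 1) for tok in description.split() if "=" in tok)


def read_fragments_fasta(path: str | Path) -> Iterator[Fragment]:
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            fields = _desc_fields(rec.description)
            yield Fragment(
                sequence=str(rec.seq), label=fields.get("label", ""),
                genome_id=fields.get("genome", ""), start=0,
                strand="+", group=fields.get("group", "train"),
                fragment_id=rec.id,
            )


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, sep="\t", index=False)
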