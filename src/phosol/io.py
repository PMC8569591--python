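"""Readers and writers for the pipeline's plain-text formats.

FASTA (UniProt ``sp|ACC|NAME`` or plain headers), phosphosite TSV
(protein_id, position, residue), sample-design CSV, candidate-set TSV, and
the TSV table writers consumed by the reporting stage.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping, Union

import pandas as pd
from Bio import SeqIO

from .charge import ChargeProfile, PhosphoSiteSet, ProteinRecord, ProteomeChargeSummary

PathLike = Union[str, os.PathLike]


def _accession_from_header(header_id: str) -> str:
    # UniProt convention: sp|P12345|NAME_HUMAN or tr|...; otherwise first token
    parts = header_id.split("|")
    if len(parts) >= 3 and parts[0] in ("sp", "tr"):
        return parts[1]
    return header_id


def read_fasta(path: PathLike) -> list[ProteinRecord]:
    """Read protein sequences; accession extracted from UniProt-style headers."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = _accession_from_header(rec.id)
        if acc in seen:
            raise ValueError(f"duplicate accession {acc!r} in {path}")
        seen.add(acc)
        gene = None
        for token in rec.description.split():
            if token.startswith("GN="):
                gene = token[3:]
        records.append(ProteinRecord(acc, str(rec.seq), gene_symbol=gene))
    if not records:
        raise ValueError(f"no sequences read from {path}")
    return records


def write_fasta(path: PathLike, records: Iterable[ProteinRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if rec.gene_symbol is None else f"{rec.id} GN={rec.gene_symbol}"
            fh.write(f">{header}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_phosphosites(
    path: PathLike, records: Mapping[str, ProteinRecord]
) -> dict[str, PhosphoSiteSet]:
    """Read a phosphosite TSV (protein_id, position, residue).

    Every row is cross-checked against the sequence: the position must carry
    the stated residue and that residue must be S, T or Y.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "residue": str})
    required = {"protein_id", "position", "residue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phosphosite file missing columns {sorted(missing)}")
    by_protein: dict[str, set[int]] = {}
    for row in df.itertuples(index=False):
        pid = row.protein_id
        pos = int(row.position)
        if pid not in records:
            raise ValueError(f"phosphosite for unknown protein {pid!r}")
        seq = records[pid].sequence
        if pos < 1 or pos > len(seq):
            raise ValueError(f"{pid}: position {pos} outside sequence (1..{len(seq)})")
        if seq[pos - 1] != row.residue.upper():
            raise ValueError(
                f"{pid}: residue mismatch at {pos}: file says {row.residue}, "
                f"sequence has {seq[pos - 1]}"
            )
        by_protein.setdefault(pid, set()).add(pos)
    sets = {pid: PhosphoSiteSet(pid, frozenset(pos)) for pid, pos in by_protein.items()}
    for pid, sset in sets.items():
        sset.validate_against(records[pid])
    return sets


def write_phosphosites(path: PathLike, sites: Mapping[str, PhosphoSiteSet],
                       records: Mapping[str, ProteinRecord]) -> None:
    rows = []
    for pid in sorted(sites):
        seq = records[pid].sequence
        for pos in sorted(sites[pid].positions):
            rows.append((pid, pos, seq[pos - 1]))
    pd.DataFrame(rows, columns=["protein_id", "position", "residue"]).to_csv(
        path, sep="\t", index=False
    )


def read_candidate_set(path: PathLike) -> dict[str, set[str]]:
    """Candidate-set TSV: one id per line, or two columns id/set_name."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] == 1:
        return {"candidate": set(df[0].dropna())}
    out: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(row[1], set()).add(row[0])
    return out


def write_ncpr_table(path: PathLike, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_density_track(path: PathLike, profiles: Iterable[ChargeProfile]) -> None:
    frames = [p.as_density_frame() for p in profiles]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_sgraph(path: PathLike, summary: ProteomeChargeSummary) -> None:
    summary.table.to_csv(path, sep="\t", index=False)


def ensure_dir(path: PathLike) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
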