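"""Hydrogenase/reductase gene content of isolate genome collections.

Genomes pass quality control when completeness exceeds 90% and contamination
is below 5% (strict inequalities).  Each predicted protein of a retained
proteome is aligned against the reference database with the same local
aligner as the read classifier; a protein counts toward its best-hit family
only when query coverage and subject coverage both reach 80% and the identity
meets the family threshold.  Every protein contributes to at most one family
(its best hit), so closely related subgroups are never double-counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .read_classify import ClassifyParams, ReferenceIndex, _aligner_for, local_align
from .reference_db import ReferenceDB, threshold_for

__all__ = [
    "GenomeRecord",
    "GenomeHydrogenaseProfile",
    "qc_filter",
    "profile_genome",
    "profile_collection",
    "prevalence",
    "load_genome_collection",
    "presence_absence",
    "write_copy_table",
]


@dataclass
class GenomeRecord:
    genome_id: str
    proteome: list[tuple[str, str]]  # (protein_id, peptide)
    completeness_pct: float | None
    contamination_pct: float | None
    taxonomy: tuple[str, ...] = ()


@dataclass
class GenomeHydrogenaseProfile:
    genome_id: str
    family_copies: dict[str, int]
    passed_qc: bool


def qc_filter(
    records: Sequence[GenomeRecord],
    min_completeness: float = 90.0,
    max_contamination: float = 5.0,
) -> list[GenomeRecord]:
    """Retain genomes with completeness > min and contamination < max.

    Inequalities are strict on both sides; records with missing quality
    fields raise rather than silently passing.
    """
    retained = []
    for rec in records:
        if rec.completeness_pct is None or rec.contamination_pct is None:
            raise ValueError(f"genome {rec.genome_id}: missing quality fields")
        if rec.completeness_pct > min_completeness and rec.contamination_pct < max_contamination:
            retained.append(rec)
    return retained


def profile_genome(
    record: GenomeRecord,
    db: ReferenceDB,
    min_qcov: float = 80.0,
    min_scov: float = 80.0,
    params: ClassifyParams | None = None,
    index: ReferenceIndex | None = None,
    passed_qc: bool = True,
) -> GenomeHydrogenaseProfile:
    """Count per-family gene copies in one proteome.

    Coverage is aligned span over full sequence length, per side, on the best
    local alignment (>= at the threshold).  A protein failing coverage or
    identity for its best hit is not reassigned to a weaker hit.
    """
    params = params or ClassifyParams()
    if index is None:
        index = ReferenceIndex(db, params.seed_len)
    aligner = _aligner_for(params)
    copies: dict[str, int] = {}
    for protein_id, peptide in record.proteome:
        if not peptide:
            continue
        best_score = 0.0
        best_ids: list[str] = []
        for seq_id in index.candidates(peptide):
            score = aligner.score(db.sequences[seq_id].protein, peptide)
            if score > best_score:
                best_score, best_ids = score, [seq_id]
            elif score == best_score and score > 0:
                best_ids.append(seq_id)
        if not best_ids:
            continue
        scored = []
        for seq_id in best_ids:
            aln = local_align(peptide, db.sequences[seq_id].protein, params)
            scored.append((-aln.identity_pct, seq_id, aln))
        scored.sort(key=lambda item: (item[0], item[1]))
        _, seq_id, aln = scored[0]
        target = db.sequences[seq_id]
        qcov = 100.0 * aln.aligned_len_aa / len(peptide)
        scov = 100.0 * (aln.t_range[1] - aln.t_range[0]) / target.length_aa
        if qcov < min_qcov or scov < min_scov:
            continue
        if aln.identity_pct < threshold_for(db, target.family_id):
            continue
        copies[target.family_id] = copies.get(target.family_id, 0) + 1
    return GenomeHydrogenaseProfile(record.genome_id, copies, passed_qc)


def profile_collection(
    records: Sequence[GenomeRecord],
    db: ReferenceDB,
    min_completeness: float = 90.0,
    max_contamination: float = 5.0,
    min_qcov: float = 80.0,
    min_scov: float = 80.0,
    params: ClassifyParams | None = None,
) -> list[GenomeHydrogenaseProfile]:
    """QC-flag and profile every genome; failing genomes are kept, flagged."""
    params = params or ClassifyParams()
    index = ReferenceIndex(db, params.seed_len)
    retained = {r.genome_id for r in qc_filter(records, min_completeness, max_contamination)}
    return [
        profile_genome(
            rec, db, min_qcov, min_scov, params, index,
            passed_qc=rec.genome_id in retained,
        )
        for rec in records
    ]


def prevalence(profiles: Sequence[GenomeHydrogenaseProfile], family_id: str) -> float:
    """Fraction of QC-passing genomes carrying at least one copy of a family."""
    passed = [p for p in profiles if p.passed_qc]
    if not passed:
        raise ValueError("no QC-passing genomes in collection")
    carrying = sum(1 for p in passed if p.family_copies.get(family_id, 0) >= 1)
    return carrying / len(passed)


def load_genome_collection(manifest_tsv: str | Path) -> list[GenomeRecord]:
    """Read a collection manifest: genome_id, fasta_path, completeness_pct,
    contamination_pct, taxonomy (semicolon-separated)."""
    manifest_tsv = Path(manifest_tsv)
    meta = pd.read_csv(manifest_tsv, sep="\t", dtype=str)
    records = []
    for row in meta.itertuples(index=False):
        fasta = Path(row.fasta_path)
        if not fasta.is_absolute():
            fasta = manifest_tsv.parent / fasta
        proteome = [
            (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(fasta), "fasta")
        ]
        taxonomy = tuple(str(row.taxonomy).split(";")) if pd.notna(row.taxonomy) else ()
        records.append(
            GenomeRecord(
                genome_id=row.genome_id,
                proteome=proteome,
                completeness_pct=float(row.completeness_pct) if pd.notna(row.completeness_pct) else None,
                contamination_pct=float(row.contamination_pct) if pd.notna(row.contamination_pct) else None,
                taxonomy=taxonomy,
            )
        )
    return records


def presence_absence(profiles: Sequence[GenomeHydrogenaseProfile], db: ReferenceDB) -> pd.DataFrame:
    """Genomes x families 0/1 matrix over QC-passing genomes."""
    passed = [p for p in profiles if p.passed_qc]
    families = sorted(db.families)
    data = {
        p.genome_id: [1 if p.family_copies.get(f, 0) >= 1 else 0 for f in families]
        for p in passed
    }
    df = pd.DataFrame(data, index=families).T
    df.index.name = "genome_id"
    return df


def write_copy_table(profiles: Sequence[GenomeHydrogenaseProfile], db: ReferenceDB, path: str | Path) -> None:
    families = sorted(db.families)
    with open(path, "w") as fh:
        fh.write("genome_id\tpassed_qc\t" + "\t".join(families) + "\n")
        for p in profiles:
            counts = "\t".join(str(p.family_copies.get(f, 0)) for f in families)
            fh.write(f"{p.genome_id}\t{int(p.passed_qc)}\t{counts}\n")
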