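"""Reference protein database: families, identity thresholds, taxonomy, markers.

The database couples a protein FASTA (one record per reference sequence) with
a metadata TSV assigning every sequence to a gene family.  Families carry the
per-protein minimum percent-identity threshold used downstream when filtering
translated-search hits, a coarse category, and free-text description.  A
distinguished subset of 14 families — universal single-copy ribosomal
proteins — serves as the genome-count proxy for copies-per-genome
normalization.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FamilySpec",
    "ReferenceSequence",
    "ReferenceDB",
    "ReferenceDBError",
    "DEFAULT_MARKER_FAMILIES",
    "default_identity_threshold",
    "load_reference",
    "save_reference",
    "threshold_for",
    "validate",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
#: residues tolerated in reference proteins (standard 20 plus ambiguity X)
ALLOWED_AA = STANDARD_AA | {"X"}

TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: Default set of 14 universal single-copy ribosomal protein families used as
#: the genome-count denominator.  The concrete membership is configuration —
#: any 14 single-copy families can stand in — and this shipped default covers
#: large- and small-subunit ribosomal proteins conserved across bacteria and
#: archaea.
DEFAULT_MARKER_FAMILIES: tuple[str, ...] = (
    "marker_rpl2",
    "marker_rpl3",
    "marker_rpl4",
    "marker_rpl5",
    "marker_rpl6",
    "marker_rpl14",
    "marker_rpl15",
    "marker_rpl16",
    "marker_rpl18",
    "marker_rpl22",
    "marker_rpl24",
    "marker_rps3",
    "marker_rps8",
    "marker_rps17",
)

# Default identity-threshold profile: 50% for most H2-linked reductases and
# [NiFe]-hydrogenases (except group 4 at 60%), 60% for [FeFe]-hydrogenases and
# NuoF, 70% for AtpA and YgfK.
_THRESHOLD_50_PREFIXES = (
    "AcsB", "ArsC", "AsrA", "CcoN", "CooS", "CoxA", "CydA", "CyoA", "DsrA",
    "FdhA", "NapA", "NarG", "NifH", "NirK", "NorB", "NosZ", "NrfA", "RHO",
    "SdhA", "FrdA", "Sqr",
)


class ReferenceDBError(ValueError):
    """Raised for malformed or inconsistent reference databases."""


def default_identity_threshold(family_id: str) -> float:
    """Return the shipped default minimum percent identity for a family.

    [FeFe]-hydrogenases and NuoF use 60; [NiFe]-hydrogenases use 50 except
    group 4 (60); AtpA and YgfK use 70; the remaining reductase/oxidase
    families use 50.  Marker families use 60.
    """
    if family_id.startswith("marker_"):
        return 60.0
    if family_id.startswith("FeFe") or family_id.startswith("NuoF"):
        return 60.0
    if family_id.startswith("NiFe"):
        return 60.0 if family_id.startswith("NiFe_4") else 50.0
    if family_id.startswith("Fe_hyd"):
        return 50.0
    if family_id.startswith("AtpA") or family_id.startswith("YgfK"):
        return 70.0
    for prefix in _THRESHOLD_50_PREFIXES:
        if family_id.startswith(prefix):
            return 50.0
    return 50.0


@dataclass(frozen=True)
class FamilySpec:
    family_id: str
    category: str  # hydrogenase | reductase | nitrogenase | marker | other
    min_identity_pct: float
    description: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.min_identity_pct <= 100:
            raise ReferenceDBError(
                f"family {self.family_id}: min_identity_pct must be in (0, 100], "
                f"got {self.min_identity_pct}"
            )


@dataclass(frozen=True)
class ReferenceSequence:
    seq_id: str
    family_id: str
    taxonomy: tuple[str, ...]
    protein: str

    @property
    def length_aa(self) -> int:
        return len(self.protein)

    def rank(self, rank_name: str) -> str:
        """Taxon label at a named rank, or ``"unclassified"`` if absent/empty."""
        try:
            idx = TAXONOMY_RANKS.index(rank_name)
        except ValueError:
            raise KeyError(f"unknown taxonomic rank: {rank_name!r}") from None
        if idx < len(self.taxonomy) and self.taxonomy[idx]:
            return self.taxonomy[idx]
        return "unclassified"


@dataclass
class ReferenceDB:
    """Validated reference database: families, sequences, marker set."""

    families: dict[str, FamilySpec]
    sequences: dict[str, ReferenceSequence]
    marker_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for seq in self.sequences.values():
            if seq.family_id not in self.families:
                raise ReferenceDBError(
                    f"sequence {seq.seq_id} references unknown family "
                    f"{seq.family_id!r}"
                )
        for fid in self.marker_ids:
            fam = self.families.get(fid)
            if fam is None:
                raise ReferenceDBError(f"marker family {fid!r} not in family table")
            if fam.category != "marker":
                raise ReferenceDBError(
                    f"marker family {fid!r} has category {fam.category!r}, "
                    "expected 'marker'"
                )

    @property
    def family_ids(self) -> list[str]:
        return list(self.families)

    def sequences_of_family(self, family_id: str) -> list[ReferenceSequence]:
        return [s for s in self.sequences.values() if s.family_id == family_id]

    def __len__(self) -> int:
        return len(self.sequences)


def threshold_for(db: ReferenceDB, family_id: str) -> float:
    """Minimum percent identity required for hits assigned to ``family_id``."""
    try:
        return db.families[family_id].min_identity_pct
    except KeyError:
        raise KeyError(f"unknown family: {family_id!r}") from None


def _parse_taxonomy(text: str) -> tuple[str, ...]:
    if not text or pd.isna(text):
        return ()
    return tuple(part.strip() for part in str(text).split(";"))


def load_reference(
    protein_fasta: str | Path | io.TextIOBase,
    family_tsv: str | Path | io.TextIOBase,
    marker_ids: Iterable[str] | None = None,
) -> ReferenceDB:
    """Load and validate a reference database from FASTA + metadata TSV.

    The TSV needs columns ``seq_id``, ``family_id``, ``category``,
    ``min_identity_pct`` and ``taxonomy`` (semicolon-separated ranks, may be
    empty).  Every FASTA record must have a metadata row and vice versa.
    ``marker_ids`` defaults to the marker-category families found in the TSV.
    """
    meta = pd.read_csv(family_tsv, sep="\t", dtype=str)
    required = {"seq_id", "family_id", "category", "min_identity_pct", "taxonomy"}
    missing = required - set(meta.columns)
    if missing:
        raise ReferenceDBError(f"family TSV missing columns: {sorted(missing)}")
    if meta["seq_id"].duplicated().any():
        dups = meta.loc[meta["seq_id"].duplicated(), "seq_id"].tolist()
        raise ReferenceDBError(f"duplicate seq_id in family TSV: {dups}")

    proteins: dict[str, str] = {}
    for record in SeqIO.parse(protein_fasta, "fasta"):
        if record.id in proteins:
            raise ReferenceDBError(f"duplicate seq_id in FASTA: {record.id}")
        proteins[record.id] = str(record.seq).upper()

    families: dict[str, FamilySpec] = {}
    sequences: dict[str, ReferenceSequence] = {}
    for row in meta.itertuples(index=False):
        if row.seq_id not in proteins:
            raise ReferenceDBError(
                f"TSV row for {row.seq_id} has no matching FASTA record"
            )
        fid = row.family_id
        thr = float(row.min_identity_pct)
        spec = FamilySpec(family_id=fid, category=row.category, min_identity_pct=thr)
        prior = families.get(fid)
        if prior is not None and prior != spec:
            raise ReferenceDBError(
                f"family {fid} has inconsistent metadata across rows"
            )
        families[fid] = spec
        sequences[row.seq_id] = ReferenceSequence(
            seq_id=row.seq_id,
            family_id=fid,
            taxonomy=_parse_taxonomy(row.taxonomy),
            protein=proteins[row.seq_id],
        )

    orphans = set(proteins) - set(sequences)
    if orphans:
        raise ReferenceDBError(
            f"FASTA records without metadata rows: {sorted(orphans)}"
        )

    if marker_ids is None:
        marker_ids = [f for f, s in families.items() if s.category == "marker"]
    db = ReferenceDB(
        families=families,
        sequences=sequences,
        marker_ids=frozenset(marker_ids),
    )
    return db


def save_reference(db: ReferenceDB, protein_fasta: str | Path, family_tsv: str | Path) -> None:
    """Write a database back to FASTA + TSV; inverse of :func:`load_reference`."""
    records = [
        SeqRecord(Seq(s.protein), id=s.seq_id, description="")
        for s in db.sequences.values()
    ]
    with open(protein_fasta, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    rows = []
    for s in db.sequences.values():
        fam = db.families[s.family_id]
        rows.append(
            {
                "seq_id": s.seq_id,
                "family_id": s.family_id,
                "category": fam.category,
                "min_identity_pct": fam.min_identity_pct,
                "taxonomy": ";".join(s.taxonomy),
            }
        )
    pd.DataFrame(rows).to_csv(family_tsv, sep="\t", index=False)


def validate(db: ReferenceDB) -> list[str]:
    """Consistency report: empty list iff all invariants hold.

    Flags families with zero sequences, proteins containing non-standard
    residues, and sequences lacking any taxonomy.
    """
    report: list[str] = []
    populated = {s.family_id for s in db.sequences.values()}
    for fid in db.families:
        if fid not in populated:
            report.append(f"family {fid} has zero sequences")
    for s in db.sequences.values():
        bad = sorted(set(s.protein) - ALLOWED_AA)
        if bad:
            report.append(
                f"sequence {s.seq_id} contains non-standard residues: {''.join(bad)}"
            )
        if not s.taxonomy:
            report.append(f"sequence {s.seq_id} lacks taxonomy")
    if db.marker_ids and len(db.marker_ids) != 14:
        report.append(
            f"marker set has {len(db.marker_ids)} families (default profile expects 14)"
        )
    return report
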