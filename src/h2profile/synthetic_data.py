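"""Mock communities with known ground truth for exercising the pipeline.

Everything the pipeline consumes can be generated here with closed-form
expected values: a synthetic reference database (seeded random proteins per
family under the default 50/60/70 threshold profile, 14 single-copy marker
families), homologs mutated to controlled percent identity, communities of
genomes with specified per-genome gene copy numbers and relative abundances,
paired DNA/RNA read sets with per-family expression multipliers, and
two-cohort copies-per-genome designs with known multiplicative effects.

The read model is deliberately simple: read start positions are uniform over
the source sequence (reads truncate at the 3' end), substitution errors are
i.i.d. per base, and there are no indels, quality-score error profiles or GC
bias.  Background (non-target) genomic sequence is i.i.d. uniform
nucleotides.  Every generator is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_stats import CohortTable
from .read_classify import Read
from .reference_db import (
    DEFAULT_MARKER_FAMILIES,
    FamilySpec,
    ReferenceDB,
    ReferenceSequence,
    default_identity_threshold,
)

__all__ = [
    "CommunitySpec",
    "GenomeSpec",
    "GeneInstance",
    "TruthTable",
    "FIXED_CODONS",
    "mutate_protein_to_identity",
    "reverse_translate",
    "example_reference_db",
    "example_community",
    "build_gene_instances",
    "simulate_reads",
    "write_fastq",
    "generate_case_control",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Deterministic reverse-translation table: one fixed codon per residue,
#: compatible with translation table 11 so that
#: translate(reverse_translate(p)) == p in frame +1.
FIXED_CODONS: dict[str, str] = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCG", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

DEFAULT_HYDROGENASE_FAMILIES = (
    "FeFe_A1", "FeFe_A2", "FeFe_A3", "FeFe_B", "FeFe_C",
    "NiFe_1a", "NiFe_1d", "NiFe_3", "NiFe_4a", "NiFe_4e", "Fe_hyd",
)
DEFAULT_REDUCTASE_FAMILIES = (
    "AcsB", "DsrA", "NarG", "NapA", "NrfA", "SdhA_FrdA", "NifH",
)

_CATEGORY = {
    **{f: "hydrogenase" for f in DEFAULT_HYDROGENASE_FAMILIES},
    **{f: "reductase" for f in DEFAULT_REDUCTASE_FAMILIES},
    "NifH": "nitrogenase",
    **{f: "marker" for f in DEFAULT_MARKER_FAMILIES},
}

_SYNTH_GENERA = ("Bacteroides", "Phocaeicola", "Faecalibacterium", "Roseburia", "Blautia")


def mutate_protein_to_identity(
    seq: str,
    target_identity_pct: float,
    seed: int = 0,
    positions: str = "random",
) -> str:
    """Substitute residues so global identity to ``seq`` equals the target.

    Exactly ``round((1 - target/100) * L)`` positions are replaced with a
    different residue; no indels, so the gapless alignment has identity equal
    to the target within 100/L.  ``positions`` is ``"random"`` (seeded) or
    ``"even"`` (mutations spread uniformly along the sequence, which keeps
    every local window close to the global identity).
    """
    L = len(seq)
    if L < 10:
        raise ValueError("sequence too short to mutate to a controlled identity")
    if not 0 <= target_identity_pct <= 100:
        raise ValueError("target identity must be in [0, 100]")
    n_mut = round((1 - target_identity_pct / 100.0) * L)
    if n_mut == 0:
        return seq
    rng = np.random.default_rng(seed)
    if positions == "random":
        sites = rng.choice(L, size=n_mut, replace=False)
    elif positions == "even":
        sites = np.unique(np.floor(np.arange(n_mut) * L / n_mut).astype(int))
        if len(sites) != n_mut:  # collision fallback for odd ratios
            sites = np.linspace(0, L - 1, n_mut).round().astype(int)
            if len(np.unique(sites)) != n_mut:
                raise ValueError("cannot place evenly spaced mutations distinctly")
    else:
        raise ValueError(f"unknown positions mode {positions!r}")
    out = list(seq)
    for site in sites:
        choices = [a for a in AMINO_ACIDS if a != seq[site]]
        out[site] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def reverse_translate(pep: str) -> str:
    """Deterministic coding sequence for a peptide via the fixed codon table."""
    try:
        return "".join(FIXED_CODONS[a] for a in pep)
    except KeyError as exc:
        raise ValueError(f"cannot reverse-translate non-standard residue {exc}") from exc


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def example_reference_db(
    seed: int = 17,
    families: Sequence[str] | None = None,
    n_per_family: int = 2,
    length_range: tuple[int, int] = (300, 360),
) -> ReferenceDB:
    """A fully synthetic reference database for tests and simulations.

    Proteins are seeded random sequences (unrelated across families), so
    family assignments are unambiguous by construction; thresholds follow the
    default 50/60/70 profile and all 14 marker families are present.  This is
    a synthetic stand-in for a curated hydrogenase/reductase database, not a
    set of real sequences.
    """
    rng = np.random.default_rng(seed)
    if families is None:
        families = (
            tuple(DEFAULT_HYDROGENASE_FAMILIES)
            + tuple(DEFAULT_REDUCTASE_FAMILIES)
            + tuple(DEFAULT_MARKER_FAMILIES)
        )
    family_table: dict[str, FamilySpec] = {}
    sequences: dict[str, ReferenceSequence] = {}
    for fam in families:
        category = _CATEGORY.get(fam, "other")
        family_table[fam] = FamilySpec(
            family_id=fam,
            category=category,
            min_identity_pct=default_identity_threshold(fam),
        )
        for i in range(n_per_family):
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            genus = _SYNTH_GENERA[i % len(_SYNTH_GENERA)]
            seq_id = f"{fam}__ref{i}"
            sequences[seq_id] = ReferenceSequence(
                seq_id=seq_id,
                family_id=fam,
                taxonomy=(
                    "Bacteria", "Bacteroidota", "Bacteroidia", "Bacteroidales",
                    "Bacteroidaceae", genus, f"{genus} synthsp{i}",
                ),
                protein=_random_protein(rng, length),
            )
    markers = frozenset(f for f in families if f.startswith("marker_"))
    return ReferenceDB(families=family_table, sequences=sequences, marker_ids=markers)


@dataclass
class GenomeSpec:
    genome_id: str
    relative_abundance: float
    family_copies: dict[str, int] = field(default_factory=dict)


@dataclass
class CommunitySpec:
    """Definition of a mock community.

    Every genome implicitly carries one copy of each of the 14 marker
    families.  ``divergence_pct`` gives per-family percent divergence of each
    gene copy from its source reference protein (0 = identical).
    ``expression`` gives per-family RNA multipliers for paired RNA samples.
    """

    genomes: list[GenomeSpec]
    divergence_pct: dict[str, float] = field(default_factory=dict)
    expression: dict[str, float] = field(default_factory=dict)
    read_length: int = 150
    error_rate: float = 0.0
    background_len_nt: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(g.relative_abundance for g in self.genomes)
        if self.genomes and abs(total - 1.0) > 1e-9:
            raise ValueError(f"relative abundances must sum to 1, got {total}")
        for g in self.genomes:
            for fam, c in g.family_copies.items():
                if c < 0 or c != int(c):
                    raise ValueError(f"{g.genome_id}/{fam}: copy numbers are non-negative integers")

    def expected_cpg(self, marker_ids: Sequence[str] = DEFAULT_MARKER_FAMILIES) -> dict[str, float]:
        """Abundance-weighted mean copy number per family (markers = 1)."""
        out: dict[str, float] = {m: 1.0 for m in marker_ids}
        for g in self.genomes:
            for fam, c in g.family_copies.items():
                out[fam] = out.get(fam, 0.0) + g.relative_abundance * c
        return out

    def expected_rna_dna(self) -> dict[str, float]:
        return dict(self.expression)


@dataclass
class GeneInstance:
    genome_id: str
    family_id: str | None  # None = background sequence
    source_seq_id: str | None
    nt: str


@dataclass
class TruthTable:
    expected_cpg: dict[str, float]
    expected_rna_dna: dict[str, float]
    read_origins: list[tuple[str, str | None]]  # (genome_id, family_id or None)

    def origin_family_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, fam in self.read_origins:
            if fam is not None:
                counts[fam] = counts.get(fam, 0) + 1
        return counts


def build_gene_instances(
    spec: CommunitySpec, db: ReferenceDB, seed: int | None = None
) -> list[GeneInstance]:
    """Materialize every gene copy (and background) of every genome as DNA.

    Each copy derives from one reference protein of its family (cycling
    through the family's references), mutated to the spec's per-family
    divergence at seeded-random positions, then reverse-translated.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    marker_ids = sorted(db.marker_ids)
    instances: list[GeneInstance] = []
    for g in spec.genomes:
        wanted = {m: 1 for m in marker_ids}
        for fam, c in g.family_copies.items():
            if fam not in db.families:
                raise KeyError(f"community family {fam!r} absent from reference DB")
            wanted[fam] = wanted.get(fam, 0) + c
        for fam, copies in wanted.items():
            refs = db.sequences_of_family(fam)
            if not refs:
                raise ValueError(f"family {fam} has no reference sequences")
            divergence = spec.divergence_pct.get(fam, 0.0)
            for i in range(copies):
                ref = refs[i % len(refs)]
                protein = ref.protein
                if divergence > 0:
                    protein = mutate_protein_to_identity(
                        protein,
                        100.0 - divergence,
                        seed=int(rng.integers(2**31)),
                    )
                instances.append(
                    GeneInstance(g.genome_id, fam, ref.seq_id, reverse_translate(protein))
                )
        if spec.background_len_nt > 0:
            bg = "".join(rng.choice(list("ACGT"), size=spec.background_len_nt))
            instances.append(GeneInstance(g.genome_id, None, None, bg))
    return instances


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def simulate_reads(
    spec: CommunitySpec,
    n_reads: int,
    db: ReferenceDB,
    material: str = "dna",
    seed: int | None = None,
) -> tuple[list[Read], TruthTable]:
    """Draw reads from a mock community; returns reads plus the truth table.

    Read origins are sampled proportionally to genome abundance x copy
    number x sequence length (RNA additionally x the family's expression
    multiplier); start positions are uniform, reads truncate at sequence
    ends, and substitution errors occur at ``spec.error_rate`` per base.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if material not in ("dna", "rna"):
        raise ValueError("material must be 'dna' or 'rna'")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    instances = build_gene_instances(spec, db, seed=int(rng.integers(2**31)))
    abundance = {g.genome_id: g.relative_abundance for g in spec.genomes}
    weights = np.array(
        [
            abundance[inst.genome_id]
            * len(inst.nt)
            * (
                spec.expression.get(inst.family_id, 1.0)
                if material == "rna" and inst.family_id is not None
                else 1.0
            )
            for inst in instances
        ],
        dtype=float,
    )
    probs = weights / weights.sum()
    counts = rng.multinomial(n_reads, probs)

    reads: list[Read] = []
    origins: list[tuple[str, str | None]] = []
    read_no = 0
    for inst, count in zip(instances, counts):
        if count == 0:
            continue
        L = len(inst.nt)
        starts = rng.integers(0, L, size=count)
        for s in starts:
            fragment = inst.nt[s : s + spec.read_length]
            if spec.error_rate > 0:
                arr = np.frombuffer(fragment.encode(), dtype="S1").copy()
                n_err = rng.binomial(len(arr), spec.error_rate)
                if n_err > 0:
                    sites = rng.choice(len(arr), size=n_err, replace=False)
                    for site in sites:
                        alternatives = _BASES[_BASES != arr[site]]
                        arr[site] = alternatives[int(rng.integers(len(alternatives)))]
                fragment = arr.tobytes().decode()
            reads.append(
                Read(f"{material}_read_{read_no}", fragment, "I" * len(fragment))
            )
            origins.append((inst.genome_id, inst.family_id))
            read_no += 1
    truth = TruthTable(
        expected_cpg=spec.expected_cpg(sorted(db.marker_ids)),
        expected_rna_dna=spec.expected_rna_dna(),
        read_origins=origins,
    )
    return reads, truth


def write_fastq(reads: Sequence[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{r.qual or 'I' * len(r.seq)}\n")


def example_community(
    seed: int = 0,
    error_rate: float = 0.005,
    divergence_pct: float = 10.0,
    expression: Mapping[str, float] | None = None,
) -> CommunitySpec:
    """Five-genome mock community with truth cpg {2.0, 1.0, 0.5, 0.25}.

    Four hydrogenase families at graded abundance-weighted copy numbers
    (FeFe_B 2.0, FeFe_A1 1.0, FeFe_A3 0.5, NiFe_4a 0.25) over genomes at
    abundances 0.30/0.25/0.20/0.15/0.10; markers at 1 cpg by construction.
    Gene copies diverge ``divergence_pct`` percent from their references
    (identity comfortably above the family thresholds).
    """
    copies = {
        "g1": {"FeFe_B": 2, "FeFe_A1": 1, "FeFe_A3": 1},
        "g2": {"FeFe_B": 2, "FeFe_A1": 1, "NiFe_4a": 1},
        "g3": {"FeFe_B": 2, "FeFe_A1": 1, "FeFe_A3": 1},
        "g4": {"FeFe_B": 2, "FeFe_A1": 1},
        "g5": {"FeFe_B": 2, "FeFe_A1": 1},
    }
    abundances = {"g1": 0.30, "g2": 0.25, "g3": 0.20, "g4": 0.15, "g5": 0.10}
    genomes = [
        GenomeSpec(gid, abundances[gid], copies[gid]) for gid in sorted(copies)
    ]
    families = {"FeFe_B", "FeFe_A1", "FeFe_A3", "NiFe_4a"}
    return CommunitySpec(
        genomes=genomes,
        divergence_pct={f: divergence_pct for f in families},
        expression=dict(expression or {}),
        error_rate=error_rate,
        seed=seed,
    )


def generate_case_control(
    spec_base: CommunitySpec,
    effect: Mapping[str, float],
    n_case: int,
    n_control: int,
    seed: int = 0,
    sigma: float = 0.5,
    marker_ids: Sequence[str] = DEFAULT_MARKER_FAMILIES,
) -> tuple[CohortTable, dict[str, float]]:
    """Two-cohort cpg design with multiplicative effects on chosen families.

    Per-sample cpg values are drawn log-normally around the cohort mean
    (control mean = the community's truth cpg; case mean = truth x fold) with
    log-scale dispersion ``sigma``; the mean is preserved exactly via the
    -sigma^2/2 offset.  Returns the table plus the truth folds.
    """
    if n_case <= 0 or n_control <= 0:
        raise ValueError("cohort sizes must be positive")
    for fam, fold in effect.items():
        if fold <= 0:
            raise ValueError(f"effect fold for {fam} must be positive")
    rng = np.random.default_rng(seed)
    truth_cpg = spec_base.expected_cpg(marker_ids)
    families = sorted(truth_cpg)
    labels: dict[str, str] = {}
    columns: dict[str, list[float]] = {}
    for cohort, n in (("case", n_case), ("control", n_control)):
        for i in range(n):
            sample_id = f"{cohort}_{i}"
            labels[sample_id] = cohort
            vals = []
            for fam in families:
                mean = truth_cpg[fam] * (effect.get(fam, 1.0) if cohort == "case" else 1.0)
                vals.append(mean * float(np.exp(sigma * rng.standard_normal() - sigma**2 / 2)))
            columns[sample_id] = vals
    table = CohortTable(
        values=pd.DataFrame(columns, index=pd.Index(families, name="family_id")),
        labels=labels,
    )
    return table, dict(effect)
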