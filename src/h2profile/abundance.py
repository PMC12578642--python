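"""Normalized abundances from classified hits.

Quantities, in the order the pipeline produces them:

* **RPKM** — reads per kilobase of gene per million screened reads.  Each hit
  contributes ``1e9 / (total_reads * L_nt)`` where ``L_nt`` is three times the
  amino-acid length of the read's best-hit reference (a translated search has
  no per-family canonical gene length, so each read is normalized by its own
  best hit).
* **copies per genome (cpg)** — a family's RPKM divided by the arithmetic
  mean RPKM of the 14 single-copy ribosomal marker families (zeros included).
  Approximates the average per-organism copy number of the gene in the
  community; defined for DNA samples only.
* **TPM** — length-normalized relative transcript abundance summing to 1e6,
  computed from externally supplied per-gene counts.
* **RNA:DNA ratio** — per-family transcript abundance over gene abundance
  across paired metatranscriptome/metagenome samples; >1 means the family is
  transcribed above its gene dosage.

Rarefaction (uniform subsampling without replacement to a fixed depth) is
provided to remove sequencing-depth effects before screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .read_classify import HitSet, Read
from .reference_db import ReferenceDB

__all__ = [
    "SampleProfile",
    "PairedProfile",
    "rarefy",
    "rpkm_per_family",
    "copies_per_genome",
    "tpm",
    "rna_dna_ratios",
    "summarize_taxa",
    "profile_sample",
    "write_profile_tsv",
]


@dataclass
class SampleProfile:
    sample_id: str
    material: str  # "dna" | "rna"
    total_reads: int
    family_counts: dict[str, int]
    family_rpkm: dict[str, float]
    marker_rpkm: dict[str, float]
    family_cpg: dict[str, float] | None = None  # DNA only
    taxon_rpkm: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.material not in ("dna", "rna"):
            raise ValueError(f"material must be 'dna' or 'rna', got {self.material!r}")
        if self.material == "rna" and self.family_cpg is not None:
            raise ValueError("copies-per-genome is undefined for RNA samples")
        if sum(self.family_counts.values()) > self.total_reads:
            raise ValueError("classified counts exceed total reads")


@dataclass
class PairedProfile:
    dna: SampleProfile
    rna: SampleProfile
    rna_dna: dict[str, float]

    def __post_init__(self) -> None:
        if self.dna.material != "dna" or self.rna.material != "rna":
            raise ValueError("PairedProfile requires one DNA and one RNA profile")


def rarefy(reads: Iterable[Read], depth: int, seed: int) -> list[Read]:
    """Uniform subsample of exactly ``depth`` reads, without replacement.

    Reservoir sampling with numpy's PCG64 generator; the subsample preserves
    the input order and is reproducible for a fixed seed.  Asking for more
    reads than are available is an error rather than a silent pass-through.
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    rng = np.random.default_rng(seed)
    reservoir: list[tuple[int, Read]] = []
    n = 0
    for read in reads:
        if n < depth:
            reservoir.append((n, read))
        else:
            j = int(rng.integers(0, n + 1))
            if j < depth:
                reservoir[j] = (n, read)
        n += 1
    if depth > n:
        raise ValueError(f"rarefaction depth {depth} exceeds available reads ({n})")
    reservoir.sort(key=lambda item: item[0])
    return [read for _, read in reservoir]


def rpkm_per_family(hits: HitSet, db: ReferenceDB) -> dict[str, float]:
    """Per-family RPKM; families with zero hits are present with value 0."""
    if hits.total_reads <= 0:
        raise ValueError("cannot compute RPKM with zero screened reads")
    rpkm = {fid: 0.0 for fid in db.families}
    scale = 1e9 / hits.total_reads
    for hit in hits.hits:
        length_nt = 3 * db.sequences[hit.seq_id].length_aa
        rpkm[hit.family_id] += scale / length_nt
    return rpkm


def copies_per_genome(
    profile: SampleProfile,
    marker_ids: Iterable[str] | None = None,
    min_markers_detected: int = 7,
) -> dict[str, float]:
    """Family RPKM normalized by the mean RPKM of the single-copy markers.

    The marker mean includes zero-RPKM markers: an undetected marker honestly
    shrinks the genome-count denominator.  Samples where fewer than
    ``min_markers_detected`` markers are seen (or the mean is zero) are
    unquantifiable and raise.
    """
    if profile.material != "dna":
        raise ValueError("copies-per-genome is defined for DNA samples only")
    marker_ids = list(marker_ids) if marker_ids is not None else list(profile.marker_rpkm)
    if not marker_ids:
        raise ValueError("no marker families supplied")
    missing = [m for m in marker_ids if m not in profile.marker_rpkm]
    if missing:
        raise ValueError(f"marker families absent from profile: {missing}")
    values = np.array([profile.marker_rpkm[m] for m in marker_ids], dtype=float)
    detected = int((values > 0).sum())
    mean = float(values.mean())
    if mean == 0:
        raise ValueError("marker mean RPKM is zero; sample unquantifiable")
    if detected < min_markers_detected:
        raise ValueError(
            f"only {detected}/{len(marker_ids)} marker families detected "
            f"(minimum {min_markers_detected})"
        )
    return {fid: v / mean for fid, v in profile.family_rpkm.items()}


def tpm(counts: Mapping[str, float], lengths_nt: Mapping[str, float]) -> dict[str, float]:
    """Transcripts per million from per-gene counts and lengths; sums to 1e6."""
    genes = list(counts)
    for g in genes:
        if g not in lengths_nt:
            raise KeyError(f"no length for gene {g!r}")
        if lengths_nt[g] <= 0:
            raise ValueError(f"gene {g!r} has non-positive length")
    rates = {g: counts[g] / lengths_nt[g] for g in genes}
    total = sum(rates.values())
    if total <= 0:
        raise ValueError("zero total count; TPM undefined")
    return {g: rates[g] / total * 1e6 for g in genes}


def rna_dna_ratios(
    dna: Sequence[SampleProfile] | SampleProfile,
    rna: Sequence[SampleProfile] | SampleProfile,
    mode: str = "cohort",
    eps: float = 1e-6,
) -> dict[str, float]:
    """Per-family transcription ratios across paired DNA/RNA samples.

    ``cohort`` mode (default): mean RNA RPKM over samples divided by mean DNA
    RPKM — one ratio per family for the whole cohort.  ``per_sample`` mode:
    the mean over pairs of per-pair ratios, each with pseudocount ``eps`` on
    the denominator (zero-DNA families thus give finite, large ratios).
    """
    dna_list = [dna] if isinstance(dna, SampleProfile) else list(dna)
    rna_list = [rna] if isinstance(rna, SampleProfile) else list(rna)
    if not dna_list or not rna_list:
        raise ValueError("need at least one DNA and one RNA profile")
    if mode == "per_sample" and len(dna_list) != len(rna_list):
        raise ValueError("per_sample mode requires equal numbers of paired profiles")
    families = sorted({f for p in dna_list + rna_list for f in p.family_rpkm})
    out: dict[str, float] = {}
    if mode == "cohort":
        for f in families:
            d = np.mean([p.family_rpkm.get(f, 0.0) for p in dna_list])
            r = np.mean([p.family_rpkm.get(f, 0.0) for p in rna_list])
            out[f] = float(r / d) if d > 0 else float(r / eps)
    elif mode == "per_sample":
        for f in families:
            ratios = [
                rp.family_rpkm.get(f, 0.0) / (dp.family_rpkm.get(f, 0.0) + eps)
                for dp, rp in zip(dna_list, rna_list)
            ]
            out[f] = float(np.mean(ratios))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def summarize_taxa(
    hits: HitSet, db: ReferenceDB, rank: str = "genus"
) -> dict[tuple[str, str], float]:
    """Best-hit taxonomy summarized in RPKM at a chosen rank.

    Each hit's RPKM contribution is booked under (family, taxon-of-best-hit);
    references lacking the rank bucket to "unclassified".  Summing over taxa
    recovers the family RPKM exactly.
    """
    if hits.total_reads <= 0:
        raise ValueError("cannot summarize taxa with zero screened reads")
    scale = 1e9 / hits.total_reads
    out: dict[tuple[str, str], float] = {}
    for hit in hits.hits:
        ref = db.sequences[hit.seq_id]
        taxon = ref.rank(rank)
        key = (hit.family_id, taxon)
        out[key] = out.get(key, 0.0) + scale / (3 * ref.length_aa)
    return out


def profile_sample(
    hits: HitSet,
    db: ReferenceDB,
    sample_id: str,
    material: str = "dna",
    rank: str = "genus",
    min_markers_detected: int = 7,
) -> SampleProfile:
    """Assemble a full SampleProfile from a screened HitSet."""
    rpkm = rpkm_per_family(hits, db)
    marker_rpkm = {m: rpkm.get(m, 0.0) for m in sorted(db.marker_ids)}
    profile = SampleProfile(
        sample_id=sample_id,
        material=material,
        total_reads=hits.total_reads,
        family_counts=dict(hits.family_counts),
        family_rpkm=rpkm,
        marker_rpkm=marker_rpkm,
        taxon_rpkm=summarize_taxa(hits, db, rank),
    )
    if material == "dna":
        profile.family_cpg = copies_per_genome(
            profile, db.marker_ids, min_markers_detected
        )
    return profile


def write_profile_tsv(profiles: Sequence[SampleProfile], path: str | Path, value: str = "cpg") -> None:
    """Write a families x samples matrix TSV of counts, RPKM or cpg."""
    columns = {}
    for p in profiles:
        if value == "cpg":
            if p.family_cpg is None:
                raise ValueError(f"sample {p.sample_id} has no cpg values")
            columns[p.sample_id] = p.family_cpg
        elif value == "rpkm":
            columns[p.sample_id] = p.family_rpkm
        elif value == "counts":
            columns[p.sample_id] = p.family_counts
        else:
            raise ValueError(f"unknown value type {value!r}")
    df = pd.DataFrame(columns).fillna(0.0)
    df.index.name = "family_id"
    df.sort_index().to_csv(path, sep="\t")
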