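"""Readers/writers for the tabular and sequence formats the pipeline consumes.

Internal coordinates are 0-based half-open; the annotation-file dialect
(InterProScan-style TSV) is 1-based inclusive. Gene-origin tagging follows
the eukaryote/prokaryote/unknown (E/P/X) rule used to separate bona fide
host genes from symbiont contamination in hologenome assemblies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

EUKARYOTE = "eukaryote"
PROKARYOTE = "prokaryote"

#: amino-acid alphabet accepted throughout (20 canonical residues plus X)
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class DomainRecord(NamedTuple):
    """One domain occurrence on a protein, 0-based half-open coordinates."""

    protein_id: str
    domain_id: str
    start: int
    end: int


@dataclass
class ProteinDomainTable:
    """Per-species catalogue of proteins and their domain occurrences."""

    species_id: str
    records: list[DomainRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[DomainRecord] = set()
        for rec in self.records:
            if not rec.protein_id or not rec.domain_id:
                raise ValueError(f"empty protein or domain id in record {rec!r}")
            if rec.start >= rec.end:
                raise ValueError(f"start >= end in record {rec!r}")
            if rec in seen:
                raise ValueError(f"duplicate record {rec!r}")
            seen.add(rec)

    def proteins(self) -> set[str]:
        return {r.protein_id for r in self.records}

    def domains(self) -> set[str]:
        return {r.domain_id for r in self.records}

    def __len__(self) -> int:
        return len(self.records)


class Hit(NamedTuple):
    query_id: str
    subject_taxon_class: str
    e_value: float


@dataclass
class HitTable:
    """Homology-search best hits with a binary eukaryote/prokaryote label.

    Hits whose taxon class is neither eukaryote nor prokaryote (viruses,
    unplaced sequences) are dropped with a warning at construction: the
    tagging rule only defines the binary split.
    """

    hits: list[Hit] = field(default_factory=list)

    def __post_init__(self) -> None:
        kept = []
        n_dropped = 0
        for h in self.hits:
            if h.e_value < 0:
                raise ValueError(f"negative e-value in hit {h!r}")
            if h.subject_taxon_class not in (EUKARYOTE, PROKARYOTE):
                n_dropped += 1
                continue
            kept.append(h)
        if n_dropped:
            warnings.warn(
                f"dropped {n_dropped} hit(s) with taxon class outside "
                f"{{eukaryote, prokaryote}}",
                stacklevel=2,
            )
        self.hits = kept

    def queries(self) -> set[str]:
        return {h.query_id for h in self.hits}


def read_domain_tsv(path: str | Path, species_id: str | None = None) -> ProteinDomainTable:
    """Read an InterProScan-style domain annotation TSV.

    Expects >=5 tab-separated columns: protein id, domain accession,
    description, start, end (1-based inclusive). Coordinates are converted
    to 0-based half-open. Malformed lines and duplicates are dropped with a
    warning; an unreadable file is fatal.
    """
    path = Path(path)
    species = species_id if species_id is not None else path.stem
    records: list[DomainRecord] = []
    seen: set[DomainRecord] = set()
    n_malformed = 0
    n_duplicate = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                n_malformed += 1
                continue
            protein, domain, _desc, start_s, end_s = fields[:5]
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                n_malformed += 1
                continue
            if not protein or not domain or end1 < start1 or start1 < 1:
                n_malformed += 1
                continue
            rec = DomainRecord(protein, domain, start1 - 1, end1)
            if rec in seen:
                n_duplicate += 1
                continue
            seen.add(rec)
            records.append(rec)
    if n_malformed:
        warnings.warn(f"{path}: {n_malformed} malformed line(s) dropped", stacklevel=2)
    if n_duplicate:
        warnings.warn(f"{path}: {n_duplicate} duplicate record(s) dropped", stacklevel=2)
    if not records:
        warnings.warn(f"{path}: no domain records read", stacklevel=2)
    return ProteinDomainTable(species_id=species, records=records)


def read_hits_tsv(path: str | Path) -> HitTable:
    """Read a 3-column hit table: query id, taxon class, e-value."""
    hits = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            query, taxon, evalue = line.split("\t")[:3]
            hits.append(Hit(query, taxon, float(evalue)))
    return HitTable(hits)


def tag_gene_origin(hits: HitTable, e_threshold: float = 1e-4) -> dict[str, str]:
    """Assign every query an origin tag: E (eukaryotic), P (prokaryotic) or X.

    E if any eukaryote hit with e-value strictly below ``e_threshold``; else
    P if any prokaryote hit below the threshold; else X (no significant
    hit). Total: every query in the table receives exactly one tag.
    """
    if e_threshold <= 0:
        raise ValueError("e_threshold must be positive")
    tags = {q: "X" for q in hits.queries()}
    for h in hits.hits:
        if h.e_value >= e_threshold:
            continue
        if h.subject_taxon_class == EUKARYOTE:
            tags[h.query_id] = "E"
        elif tags[h.query_id] != "E":
            tags[h.query_id] = "P"
    return tags


def write_tags_tsv(tags: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(tags):
            fh.write(f"{gene}\t{tags[gene]}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into an id -> sequence mapping.

    Duplicate ids are fatal; sequences are upper-cased.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for id {rec.id!r} in {path}")
        seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def validate_protein_sequences(seqs: Mapping[str, str]) -> None:
    """Check that all sequences use the 20-letter alphabet plus X."""
    for name, seq in seqs.items():
        bad = set(seq) - AA_ALPHABET
        if bad:
            raise ValueError(f"sequence {name!r} contains invalid residues {sorted(bad)}")


def concat_tables(tables: Iterable[ProteinDomainTable], species_id: str) -> ProteinDomainTable:
    """Concatenate disjoint tables into one (used by additivity checks)."""
    records: list[DomainRecord] = []
    for t in tables:
        records.extend(t.records)
    return ProteinDomainTable(species_id=species_id, records=records)
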