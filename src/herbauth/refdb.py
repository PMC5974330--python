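"""Curated, species-labelled ITS2 reference database.

A database is built from a FASTA of candidate reference sequences plus a flat
two-rank taxonomy table (id, species, genus). Curation trims residual
5.8S/28S rRNA flanks with the profile HMMs, deduplicates identical
(species, sequence) pairs, flags identical sequences labelled with different
species, and builds a k-mer index used by the classifier's prefilter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from ._dp import revcomp
from .its2_hmm import ProfileHMM, trim_batch, viterbi_locate

MIN_REFERENCE_LENGTH = 100


@dataclass(frozen=True)
class ReferenceRecord:
    id: str
    species: str
    genus: str
    sequence: str
    source: str = ""
    conflict: bool = False

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError(f"record {self.id!r}: species must be non-empty")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"record {self.id!r}: invalid characters {sorted(bad)}")


@dataclass
class ReferenceDB:
    records: list[ReferenceRecord]
    k: int = 8
    species_index: dict[str, list[str]] = field(default_factory=dict)
    kmer_index: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.species_index and not self.kmer_index:
            self._build_indices()

    def _build_indices(self) -> None:
        self.species_index = {}
        self.kmer_index = {}
        for rec in self.records:
            self.species_index.setdefault(rec.species, []).append(rec.id)
            for kmer in kmers(rec.sequence, self.k):
                self.kmer_index.setdefault(kmer, set()).add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def get(self, record_id: str) -> ReferenceRecord:
        return self._by_id()[record_id]

    def _by_id(self) -> dict[str, ReferenceRecord]:
        if not hasattr(self, "_id_map"):
            self._id_map = {rec.id: rec for rec in self.records}
        return self._id_map

    def genus_of(self, species: str) -> str:
        for rec in self.records:
            if rec.species == species:
                return rec.genus
        return species.split()[0]


def kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1) if "N" not in seq[i : i + k]}


def load_references(fasta_path: str | Path, taxonomy_path: str | Path) -> list[ReferenceRecord]:
    """Join a FASTA with a taxonomy TSV (columns: id, species, genus[, source]).

    Every FASTA id must appear in the taxonomy table; duplicated FASTA ids
    are an error.
    """
    tax = pd.read_csv(taxonomy_path, sep="\t", dtype=str).fillna("")
    required = {"id", "species", "genus"}
    missing_cols = required - set(tax.columns)
    if missing_cols:
        raise ValueError(f"taxonomy table missing columns: {sorted(missing_cols)}")
    tax_by_id = tax.set_index("id", verify_integrity=True)

    records: list[ReferenceRecord] = []
    seen: set[str] = set()
    missing: list[str] = []
    for entry in SeqIO.parse(str(fasta_path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate FASTA id {entry.id!r}")
        seen.add(entry.id)
        if entry.id not in tax_by_id.index:
            missing.append(entry.id)
            continue
        row = tax_by_id.loc[entry.id]
        records.append(
            ReferenceRecord(
                id=entry.id,
                species=row["species"],
                genus=row["genus"],
                sequence=str(entry.seq).upper(),
                source=row.get("source", ""),
            )
        )
    if missing:
        raise ValueError(f"FASTA ids missing from taxonomy table: {missing}")
    return records


def curate(
    records: list[ReferenceRecord],
    hmm_5p8s: ProfileHMM,
    hmm_28s: ProfileHMM,
    k: int = 8,
) -> tuple[ReferenceDB, list[dict]]:
    """Trim flanks, deduplicate, flag cross-species identical sequences, index.

    Identical sequences labelled with different species are kept but marked
    ``conflict=True`` — the classifier's tie logic is where that ambiguity
    belongs. Records trimming below the minimum reference length are dropped
    and reported.
    """
    trimmed, trim_report = trim_batch(
        [(rec.id, rec.sequence) for rec in records],
        hmm_5p8s,
        hmm_28s,
        min_trimmed_length=MIN_REFERENCE_LENGTH,
    )
    trimmed_seq = dict(trimmed)
    report: list[dict] = []
    for row in trim_report:
        if not row["kept"]:
            report.append({"id": row["id"], "event": "dropped_short", **row})

    by_id = {rec.id: rec for rec in records}
    dedup: dict[tuple[str, str], ReferenceRecord] = {}
    for rid, seq in trimmed:
        rec = by_id[rid]
        key = (rec.species, seq)
        if key in dedup:
            report.append({"id": rid, "event": "duplicate_of", "other": dedup[key].id})
            continue
        dedup[key] = ReferenceRecord(
            id=rec.id, species=rec.species, genus=rec.genus, sequence=seq, source=rec.source
        )

    # identical sequence under >= 2 species -> conflict flag on all of them
    seq_species: dict[str, set[str]] = {}
    for (species, seq) in dedup:
        seq_species.setdefault(seq, set()).add(species)
    final: list[ReferenceRecord] = []
    for (species, seq), rec in dedup.items():
        conflict = len(seq_species[seq]) > 1
        if conflict:
            report.append(
                {"id": rec.id, "event": "species_conflict", "species": sorted(seq_species[seq])}
            )
        final.append(
            ReferenceRecord(
                id=rec.id,
                species=rec.species,
                genus=rec.genus,
                sequence=seq,
                source=rec.source,
                conflict=conflict,
            )
        )
    return ReferenceDB(records=final, k=k), report


def validate_db(db: ReferenceDB, hmm_5p8s: ProfileHMM, hmm_28s: ProfileHMM) -> list[dict]:
    """Rescan every record with both flank models; report residual flanks.

    An empty report means the database is clean (no record retains a scoring
    5.8S or 28S fragment).
    """
    report: list[dict] = []
    for rec in db.records:
        for hmm in (hmm_5p8s, hmm_28s):
            hit = viterbi_locate(hmm, rec.sequence, both_strands=False)
            if hit is not None:
                report.append(
                    {
                        "id": rec.id,
                        "model": hmm.name,
                        "start": hit.start,
                        "end": hit.end,
                        "score": hit.score,
                    }
                )
    return report


def save_db(db: ReferenceDB, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "references.fasta", "w") as fa:
        for rec in db.records:
            fa.write(f">{rec.id}\n{rec.sequence}\n")
    pd.DataFrame(
        [
            {
                "id": r.id,
                "species": r.species,
                "genus": r.genus,
                "source": r.source,
                "conflict": r.conflict,
            }
            for r in db.records
        ]
    ).to_csv(directory / "taxonomy.tsv", sep="\t", index=False)
    meta = {"k": db.k, "n_records": len(db.records)}
    (directory / "index.json").write_text(json.dumps(meta, indent=1))


def load_db(directory: str | Path) -> ReferenceDB:
    directory = Path(directory)
    meta = json.loads((directory / "index.json").read_text())
    tax = pd.read_csv(directory / "taxonomy.tsv", sep="\t", dtype={"conflict": bool}).fillna("")
    tax_by_id = tax.set_index("id")
    records = []
    for entry in SeqIO.parse(str(directory / "references.fasta"), "fasta"):
        row = tax_by_id.loc[entry.id]
        records.append(
            ReferenceRecord(
                id=entry.id,
                species=row["species"],
                genus=row["genus"],
                sequence=str(entry.seq).upper(),
                source=str(row.get("source", "")),
                conflict=bool(row["conflict"]),
            )
        )
    return ReferenceDB(records=records, k=int(meta["k"]))
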