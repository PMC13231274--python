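"""Gene-mapping tables: PSL input, best-hit and overlap filtering, TSV I/O.

Cross-species gene placement starts from translated BLAT alignments of
reference (*D. melanogaster*) gene models against a target assembly.  This
module turns raw hits into one clean placement table per species: one hit
per gene (the highest-scoring one) and no two retained genes overlapping by
20 bp or more on the same target sequence.

Coordinates are 0-based half-open throughout (the PSL convention); overlap
length between two placements is ``max(0, min(end) - max(start))``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger("mullerx")

MULLER_ELEMENTS = ("A", "B", "C", "D", "E", "F")
UNKNOWN_ELEMENT = "unknown"

#: columns of a gene-map TSV, in file order
GENE_MAP_COLUMNS = ["gene_id", "muller_element", "chromosome", "start", "end", "score", "strand"]


class PSLFormatError(ValueError):
    """Raised for malformed PSL input, carrying the offending line number."""


@dataclass(frozen=True)
class HitRecord:
    """A single gene placement on a target assembly.

    ``muller_element`` is the element of the gene in the reference species,
    carried over from the reference annotation — it is never inferred from
    the target location.
    """

    gene_id: str
    muller_element: str
    chromosome: str
    start: int
    end: int
    score: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval for {self.gene_id}: [{self.start}, {self.end})"
            )
        if self.score < 0:
            raise ValueError(f"negative score for {self.gene_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r} for {self.gene_id}")

    def overlap(self, other: "HitRecord") -> int:
        if self.chromosome != other.chromosome:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class GeneMapTable:
    """Filtered gene placements for one species.

    Invariants (enforced by :meth:`validate`): at most one record per gene,
    no two records on the same chromosome overlapping by >= ``max_overlap_bp``
    (default 20), and every record's chromosome present in
    ``chromosome_lengths``.  Genes on unassembled scaffolds stay in the table
    with ``placed[chrom] == False``; downstream stages decide whether to use
    them.
    """

    species_id: str
    records: list[HitRecord]
    chromosome_lengths: dict[str, int]
    placed: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom in self.chromosome_lengths:
            self.placed.setdefault(chrom, True)

    # -- accessors ---------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                (r.gene_id, r.muller_element, r.chromosome, r.start, r.end, r.score, r.strand)
                for r in self.records
            ],
            columns=GENE_MAP_COLUMNS,
        )
        return df

    def gene_ids(self) -> set[str]:
        return {r.gene_id for r in self.records}

    def record_for(self, gene_id: str) -> HitRecord | None:
        for r in self.records:
            if r.gene_id == gene_id:
                return r
        return None

    def placed_chromosomes(self) -> set[str]:
        return {c for c, p in self.placed.items() if p}

    # -- validation --------------------------------------------------------

    def validate(self, max_overlap_bp: int = 20) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.gene_id in seen:
                raise ValueError(f"duplicate gene {r.gene_id!r} in table for {self.species_id}")
            seen.add(r.gene_id)
            if r.chromosome not in self.chromosome_lengths:
                raise ValueError(
                    f"record {r.gene_id!r} on chromosome {r.chromosome!r} "
                    "absent from chromosome lengths"
                )
        by_chrom: dict[str, list[HitRecord]] = {}
        for r in self.records:
            by_chrom.setdefault(r.chromosome, []).append(r)
        for chrom, recs in by_chrom.items():
            recs.sort(key=lambda r: r.start)
            for a, b in zip(recs, recs[1:]):
                if a.overlap(b) >= max_overlap_bp:
                    raise ValueError(
                        f"genes {a.gene_id!r} and {b.gene_id!r} overlap by "
                        f"{a.overlap(b)} bp (>= {max_overlap_bp}) on {chrom}"
                    )


# ---------------------------------------------------------------------------
# PSL input
# ---------------------------------------------------------------------------

_PSL_NCOLS = 21


def read_psl_hits(
    path: str | Path,
    reference_elements: Mapping[str, str],
) -> list[HitRecord]:
    """Read BLAT PSL hits into :class:`HitRecord` objects.

    One record per alignment line (no filtering here).  ``score`` is the PSL
    "matches" column; target coordinates are kept 0-based half-open as in the
    file.  Queries absent from ``reference_elements`` get
    ``muller_element='unknown'`` with a logged warning.
    """
    hits: list[HitRecord] = []
    warned: set[str] = set()
    with open(path) as fh:
        in_header = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if lineno == 1 and line.startswith("psLayout"):
                in_header = True
                continue
            if in_header:
                # header block ends with a dashes line
                if set(line.strip()) <= {"-", " "}:
                    in_header = False
                continue
            fields = line.split("\t")
            if len(fields) != _PSL_NCOLS:
                raise PSLFormatError(
                    f"{path}: line {lineno}: expected {_PSL_NCOLS} tab-separated "
                    f"columns, got {len(fields)}"
                )
            try:
                matches = int(fields[0])
                strand = fields[8]
                q_name = fields[9]
                t_name = fields[13]
                t_start = int(fields[15])
                t_end = int(fields[16])
            except ValueError as exc:
                raise PSLFormatError(f"{path}: line {lineno}: {exc}") from exc
            # translated alignments report strand as e.g. "+-"; query strand leads
            strand = "+" if strand[:1] != "-" else "-"
            element = reference_elements.get(q_name)
            if element is None:
                element = UNKNOWN_ELEMENT
                if q_name not in warned:
                    logger.warning("gene %s not in reference element map; marked unknown", q_name)
                    warned.add(q_name)
            hits.append(
                HitRecord(
                    gene_id=q_name,
                    muller_element=element,
                    chromosome=t_name,
                    start=t_start,
                    end=t_end,
                    score=matches,
                    strand=strand,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def best_hit_filter(hits: Iterable[HitRecord]) -> list[HitRecord]:
    """Keep the single best hit per gene (maximal score).

    Ties are broken deterministically by lexicographically smallest
    ``(chromosome, start)``.  Idempotent.
    """
    best: dict[str, HitRecord] = {}
    for h in hits:
        cur = best.get(h.gene_id)
        if cur is None:
            best[h.gene_id] = h
            continue
        key_new = (-h.score, h.chromosome, h.start)
        key_cur = (-cur.score, cur.chromosome, cur.start)
        if key_new < key_cur:
            best[h.gene_id] = h
    return sorted(best.values(), key=lambda h: (h.chromosome, h.start, h.gene_id))


def overlap_filter(hits: Iterable[HitRecord], max_overlap_bp: int = 20) -> list[HitRecord]:
    """Drop genes whose placements overlap by >= ``max_overlap_bp``.

    Expects best-hit-filtered input (one record per gene).  Each offending
    pair is resolved by dropping its lower-scoring member (score ties: drop
    the lexicographically larger gene_id), re-checking until no pair on the
    same chromosome overlaps by ``max_overlap_bp`` or more.
    """
    kept: dict[str, HitRecord] = {}
    for h in hits:
        if h.gene_id in kept:
            raise ValueError(f"multiple hits for gene {h.gene_id!r}; run best_hit_filter first")
        kept[h.gene_id] = h

    changed = True
    while changed:
        changed = False
        by_chrom: dict[str, list[HitRecord]] = {}
        for r in kept.values():
            by_chrom.setdefault(r.chromosome, []).append(r)
        for recs in by_chrom.values():
            recs.sort(key=lambda r: (r.start, r.end))
            drop: set[str] = set()
            for i, a in enumerate(recs):
                if a.gene_id in drop:
                    continue
                for b in recs[i + 1:]:
                    if b.start >= a.end:
                        break
                    if b.gene_id in drop:
                        continue
                    if a.overlap(b) >= max_overlap_bp:
                        loser = _overlap_loser(a, b)
                        drop.add(loser.gene_id)
                        changed = True
                        if loser is a:
                            break
            for g in drop:
                del kept[g]
    return sorted(kept.values(), key=lambda h: (h.chromosome, h.start, h.gene_id))


def _overlap_loser(a: HitRecord, b: HitRecord) -> HitRecord:
    if a.score != b.score:
        return a if a.score < b.score else b
    return a if a.gene_id > b.gene_id else b


def filter_hits(
    hits: Iterable[HitRecord],
    species_id: str,
    chromosome_lengths: Mapping[str, int],
    placed: Mapping[str, bool] | None = None,
    max_overlap_bp: int = 20,
) -> GeneMapTable:
    """Best-hit then overlap filter, assembled into a validated table."""
    records = overlap_filter(best_hit_filter(hits), max_overlap_bp=max_overlap_bp)
    table = GeneMapTable(
        species_id=species_id,
        records=list(records),
        chromosome_lengths=dict(chromosome_lengths),
        placed=dict(placed) if placed is not None else {},
    )
    table.validate(max_overlap_bp=max_overlap_bp)
    return table


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def load_gene_map(
    path: str | Path,
    lengths_path: str | Path | None = None,
    species_id: str | None = None,
    max_overlap_bp: int = 20,
) -> GeneMapTable:
    """Load a gene-map TSV (with companion chromosome-lengths TSV).

    The lengths file has columns ``chromosome``, ``length_bp``, ``placed``;
    by default it is looked up next to ``path`` with suffix ``.lengths.tsv``.
    Invariant violations (duplicate genes, >=20 bp overlaps, unknown
    chromosomes) are rejected with explicit messages.
    """
    path = Path(path)
    if lengths_path is None:
        lengths_path = path.with_suffix(".lengths.tsv")
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str})
    missing = set(GENE_MAP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    lengths_df = pd.read_csv(lengths_path, sep="\t", dtype={"chromosome": str})
    lengths = dict(zip(lengths_df["chromosome"], lengths_df["length_bp"].astype(int)))
    if "placed" in lengths_df.columns:
        placed = dict(zip(lengths_df["chromosome"], lengths_df["placed"].astype(bool)))
    else:
        placed = {c: True for c in lengths}
    records = [
        HitRecord(
            gene_id=row.gene_id,
            muller_element=row.muller_element,
            chromosome=row.chromosome,
            start=int(row.start),
            end=int(row.end),
            score=int(row.score),
            strand=row.strand,
        )
        for row in df.itertuples(index=False)
    ]
    table = GeneMapTable(
        species_id=species_id or path.stem,
        records=records,
        chromosome_lengths=lengths,
        placed=placed,
    )
    table.validate(max_overlap_bp=max_overlap_bp)
    return table


def write_gene_map(table: GeneMapTable, path: str | Path, lengths_path: str | Path | None = None) -> None:
    """Write a table back to TSV (+ companion lengths TSV); inverse of load."""
    path = Path(path)
    if lengths_path is None:
        lengths_path = path.with_suffix(".lengths.tsv")
    table.to_frame().to_csv(path, sep="\t", index=False)
    lengths_df = pd.DataFrame(
        {
            "chromosome": list(table.chromosome_lengths),
            "length_bp": [table.chromosome_lengths[c] for c in table.chromosome_lengths],
            "placed": [table.placed.get(c, True) for c in table.chromosome_lengths],
        }
    )
    lengths_df.to_csv(lengths_path, sep="\t", index=False)


def table_from_frame(
    df: pd.DataFrame,
    species_id: str,
    chromosome_lengths: Mapping[str, int],
    placed: Mapping[str, bool] | None = None,
    validate: bool = True,
) -> GeneMapTable:
    """Build a table from an in-memory DataFrame with the standard columns."""
    records = [
        HitRecord(
            gene_id=str(row.gene_id),
            muller_element=str(row.muller_element),
            chromosome=str(row.chromosome),
            start=int(row.start),
            end=int(row.end),
            score=int(row.score),
            strand=str(row.strand),
        )
        for row in df.itertuples(index=False)
    ]
    table = GeneMapTable(
        species_id=species_id,
        records=records,
        chromosome_lengths=dict(chromosome_lengths),
        placed=dict(placed) if placed is not None else {},
    )
    if validate:
        table.validate()
    return table
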