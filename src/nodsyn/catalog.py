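"""Gene catalogs: annotation parsing and homology-hit filtering.

Functionally characterized nodulation genes are published under legacy
identifiers that predate current genome releases.  To place them on a
current assembly, their sequences are searched against the release and the
tabular hits are filtered with strict thresholds (e-value < 1e-12 AND bit
score > 100); each seed gene is then assigned to its best surviving hit.
Seeds with no surviving hit are reported as unmapped and excluded from all
downstream stages rather than aborting the run.

Coordinates are 1-based inclusive on disk (GFF3) and 0-based half-open in
memory.  A gene's point position, used by the window/density analysis, is
the integer midpoint ``(start + end) // 2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)

#: strict defaults for homology-hit filtering
EVALUE_MAX = 1e-12
SCORE_MIN = 100.0

#: BLAST tabular (outfmt 6) column order; only qseqid, sseqid, pident,
#: evalue and bitscore are consumed.
OUTFMT6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)

HITS_COLUMNS = ("qseqid", "sseqid", "pident", "evalue", "bitscore")


@dataclass
class GeneModel:
    """One annotated gene (0-based half-open coordinates in memory)."""

    gene_id: str
    species: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    legacy_id: str | None = None
    is_nodulation: bool = False

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def midpoint(self) -> int:
        """Integer midpoint used as the gene's point position."""
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class HomologyHit:
    """One tabular similarity hit (query, subject, e-value, bit score)."""

    query_id: str
    subject_id: str
    pident: float
    evalue: float
    score: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("e-value must be non-negative")
        if not 0.0 <= self.pident <= 100.0:
            raise ValueError("pident must lie in [0, 100]")


# ---------------------------------------------------------------------------
# GFF3 IO
# ---------------------------------------------------------------------------

def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def parse_gff3(path: str | Path, species: str | None = None) -> list[GeneModel]:
    """Read ``gene``-type features from a GFF3 file.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    Non-gene feature types are skipped (a count is logged).  A malformed
    line (fewer than 9 tab-separated columns) or a gene without an ``ID``
    attribute raises ``ValueError`` naming the offending line.
    """
    path = Path(path)
    if species is None:
        species = path.stem.replace("_", " ")
    genes: list[GeneModel] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            if cols[2] != "gene":
                skipped += 1
                continue
            start_1 = int(cols[3])
            end_1 = int(cols[4])
            if start_1 < 1 or end_1 < start_1:
                raise ValueError(f"{path}:{lineno}: invalid coordinates {start_1}..{end_1}")
            attrs = _parse_attributes(cols[8])
            if "ID" not in attrs:
                raise ValueError(f"{path}:{lineno}: gene feature without ID attribute")
            genes.append(
                GeneModel(
                    gene_id=attrs["ID"],
                    species=species,
                    chromosome=cols[0],
                    start=start_1 - 1,
                    end=end_1,
                    strand=cols[6] if cols[6] in {"+", "-"} else "+",
                    legacy_id=attrs.get("Alias") or None,
                    is_nodulation=attrs.get("nodulation", "").lower() == "true",
                )
            )
    if skipped:
        log.info("parse_gff3(%s): skipped %d non-gene features", path, skipped)
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"{path}: duplicate gene id {g.gene_id}")
        seen.add(g.gene_id)
    return genes


def parse_sequence_regions(path: str | Path) -> dict[str, int]:
    """Read ``##sequence-region`` pragmas -> chromosome lengths (bp)."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    lengths[parts[1]] = int(parts[3])
            elif not line.startswith("#"):
                break
    return lengths


def write_gff3(
    genes: Sequence[GeneModel],
    path: str | Path,
    chrom_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write gene features as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if chrom_lengths:
            for chrom in sorted(chrom_lengths):
                fh.write(f"##sequence-region {chrom} 1 {chrom_lengths[chrom]}\n")
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start, g.gene_id)):
            attrs = [f"ID={g.gene_id}"]
            if g.legacy_id:
                attrs.append(f"Alias={g.legacy_id}")
            if g.is_nodulation:
                attrs.append("nodulation=true")
            fh.write(
                "\t".join(
                    [
                        g.chromosome, ".", "gene",
                        str(g.start + 1), str(g.end), ".", g.strand, ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Homology-hit IO
# ---------------------------------------------------------------------------

def read_hits(path: str | Path) -> list[HomologyHit]:
    """Read a homology-hit table.

    Accepts either the 5-column headered dialect written by this package
    (qseqid, sseqid, pident, evalue, bitscore) or a headerless 12-column
    BLAST outfmt-6 table.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("qseqid"):
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    else:
        df = pd.read_csv(path, sep="\t", header=None, names=list(OUTFMT6_COLUMNS),
                         float_precision="round_trip")
    return [
        HomologyHit(
            query_id=str(r.qseqid),
            subject_id=str(r.sseqid),
            pident=float(r.pident),
            evalue=float(r.evalue),
            score=float(r.bitscore),
        )
        for r in df.itertuples(index=False)
    ]


def write_hits(hits: Iterable[HomologyHit], path: str | Path) -> None:
    df = pd.DataFrame(
        [(h.query_id, h.subject_id, h.pident, h.evalue, h.score) for h in hits],
        columns=list(HITS_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filtering and seed re-annotation
# ---------------------------------------------------------------------------

def filter_hits(
    hits: Iterable[HomologyHit],
    evalue_max: float = EVALUE_MAX,
    score_min: float = SCORE_MIN,
) -> list[HomologyHit]:
    """Keep hits with e-value < ``evalue_max`` AND score > ``score_min``.

    Both comparisons are strict; input order is preserved.  Idempotent.
    """
    return [h for h in hits if h.evalue < evalue_max and h.score > score_min]


def assign_gene_model(seed_gene_id: str, kept_hits: Sequence[HomologyHit]) -> str | None:
    """Best-hit assignment of a seed gene to a current-annotation gene.

    Returns the subject of the maximum-score hit; ties broken by higher
    percent identity, then lexicographically smallest subject id.  Returns
    ``None`` (unmapped) when no hit survives filtering.
    """
    mine = [h for h in kept_hits if h.query_id == seed_gene_id]
    if any(h.query_id != seed_gene_id for h in kept_hits):
        raise ValueError("kept_hits must all share query_id = seed_gene_id")
    if not mine:
        log.warning("seed gene %s: no passing hit, marked unmapped", seed_gene_id)
        return None
    best = sorted(mine, key=lambda h: (-h.score, -h.pident, h.subject_id))[0]
    return best.subject_id


def map_seed_genes(
    seeds: pd.DataFrame,
    hits: Iterable[HomologyHit],
    evalue_max: float = EVALUE_MAX,
    score_min: float = SCORE_MIN,
) -> pd.DataFrame:
    """Re-anchor a curated seed list onto current gene models.

    ``seeds`` needs columns ``seed_id`` and ``species``.  Returns a table
    (seed_id, species, mapped_gene_id, status) with status ``mapped`` or
    ``unmapped``.
    """
    kept = filter_hits(hits, evalue_max=evalue_max, score_min=score_min)
    by_query: dict[str, list[HomologyHit]] = {}
    for h in kept:
        by_query.setdefault(h.query_id, []).append(h)
    rows = []
    for r in seeds.itertuples(index=False):
        mapped = assign_gene_model(r.seed_id, by_query.get(r.seed_id, []))
        rows.append(
            (r.seed_id, r.species, mapped or "", "mapped" if mapped else "unmapped")
        )
    return pd.DataFrame(rows, columns=["seed_id", "species", "mapped_gene_id", "status"])
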