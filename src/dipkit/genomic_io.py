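"""Genomic data types and file I/O for the DIP-Seq analysis pipeline.

All coordinates are 0-based half-open (BED-native) everywhere in the
package, so conversion to and from BED is the identity.  refFlat input is
assumed to use the same convention (as UCSC refFlat dumps do for txStart/
txEnd).  Tags are stored as 5' positions; any fragment-extension
adjustment is the segmentation module's business, not I/O's.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Iterator, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

VALID_STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """Raised for malformed BED/refFlat lines; carries the line number."""


@dataclasses.dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclasses.dataclass(frozen=True)
class GeneModel:
    """A transcript with strand-aware TSS.

    ``tss`` is ``start`` for plus-strand genes and ``end - 1`` for
    minus-strand genes (the last covered base, 0-based).
    """

    gene_id: str
    interval: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def chrom(self) -> str:
        return self.interval.chrom


class TagSet:
    """Genome-mapped single-end tag coordinates for one library.

    Tags are kept per chromosome as sorted position arrays together with
    parallel strand arrays; ordering within a chromosome is by position.

    Parameters
    ----------
    library_id : str
        Library label, e.g. ``"5hmC_sham_rep1"``.
    mark : str
        One of ``"5mC"``, ``"5hmC"``, ``"RNA"``.
    condition : str
        One of ``"sham"``, ``"irradiated"``.
    tags : iterable of (chrom, position, strand)
        5' tag coordinates.
    genome : mapping chrom -> length (bp)
        Chromosome sizes; every tag must lie in ``[0, genome[chrom])``.
    """

    MARKS = ("5mC", "5hmC", "RNA")
    CONDITIONS = ("sham", "irradiated")

    def __init__(
        self,
        library_id: str,
        mark: str,
        condition: str,
        tags: Iterable[tuple[str, int, str]],
        genome: Mapping[str, int],
    ) -> None:
        if mark not in self.MARKS:
            raise ValueError(f"unknown mark {mark!r}")
        if condition not in self.CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        self.library_id = library_id
        self.mark = mark
        self.condition = condition
        self.genome = dict(genome)
        by_chrom: dict[str, list[tuple[int, str]]] = {c: [] for c in self.genome}
        for chrom, pos, strand in tags:
            if chrom not in self.genome:
                raise ValueError(f"tag on unknown chromosome {chrom!r}")
            if not (0 <= pos < self.genome[chrom]):
                raise ValueError(
                    f"tag position {pos} outside [0, {self.genome[chrom]}) on {chrom}"
                )
            by_chrom[chrom].append((int(pos), strand))
        self._positions: dict[str, np.ndarray] = {}
        self._strands: dict[str, np.ndarray] = {}
        for chrom, items in by_chrom.items():
            if items:
                items.sort(key=lambda t: t[0])
                pos_arr = np.array([p for p, _ in items], dtype=np.int64)
                strand_arr = np.array([s for _, s in items], dtype="U1")
            else:
                pos_arr = np.empty(0, dtype=np.int64)
                strand_arr = np.empty(0, dtype="U1")
            self._positions[chrom] = pos_arr
            self._strands[chrom] = strand_arr

    @classmethod
    def from_arrays(
        cls,
        library_id: str,
        mark: str,
        condition: str,
        positions: Mapping[str, np.ndarray],
        genome: Mapping[str, int],
        strands: Mapping[str, np.ndarray] | None = None,
    ) -> "TagSet":
        """Fast constructor from per-chromosome position arrays."""
        ts = cls(library_id, mark, condition, [], genome)
        for chrom, pos in positions.items():
            if chrom not in ts.genome:
                raise ValueError(f"unknown chromosome {chrom!r}")
            pos = np.asarray(pos, dtype=np.int64)
            if pos.size and (pos.min() < 0 or pos.max() >= ts.genome[chrom]):
                raise ValueError(f"tag position outside chromosome {chrom}")
            order = np.argsort(pos, kind="stable")
            ts._positions[chrom] = pos[order]
            if strands is not None and chrom in strands:
                ts._strands[chrom] = np.asarray(strands[chrom], dtype="U1")[order]
            else:
                ts._strands[chrom] = np.full(pos.size, ".", dtype="U1")
        return ts

    @property
    def chroms(self) -> list[str]:
        return list(self.genome)

    def positions(self, chrom: str) -> np.ndarray:
        """Sorted tag positions on one chromosome."""
        return self._positions[chrom]

    def strands(self, chrom: str) -> np.ndarray:
        return self._strands[chrom]

    @property
    def n_tags(self) -> int:
        return sum(arr.size for arr in self._positions.values())

    def __len__(self) -> int:
        return self.n_tags

    def iter_tags(self) -> Iterator[tuple[str, int, str]]:
        for chrom in self.genome:
            for pos, strand in zip(self._positions[chrom], self._strands[chrom]):
                yield chrom, int(pos), str(strand)

    def count_in(self, interval: GenomicInterval) -> int:
        pos = self._positions.get(interval.chrom)
        if pos is None:
            return 0
        lo = np.searchsorted(pos, interval.start, side="left")
        hi = np.searchsorted(pos, interval.end, side="left")
        return int(hi - lo)


@dataclasses.dataclass
class Config:
    """Pipeline run configuration.

    Defaults mirror the published analysis settings: 1000 bp sliding
    windows, FDR 0.01 significance, a permissive p < 0.1 tier for density
    analyses, 50 kb TSS annotation windows, 25 kb TSS proximity, the
    200 kb minimum gene length with four 50 kb density bins, and the
    top-2000 region cut.
    """

    window_bp: int = 1000
    window_step_bp: int = 500
    n_permutations: int = 100
    enrichment_alpha: float = 0.001
    fdr_threshold: float = 0.01
    permissive_p: float = 0.1
    tss_window_bp: int = 50_000
    proximity_bp: int = 25_000
    min_gene_length_bp: int = 200_000
    density_bin_bp: int = 50_000
    n_density_bins: int = 4
    top_n_regions: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "window_bp",
            "window_step_bp",
            "n_permutations",
            "tss_window_bp",
            "proximity_bp",
            "min_gene_length_bp",
            "density_bin_bp",
            "n_density_bins",
            "top_n_regions",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("enrichment_alpha", "fdr_threshold", "permissive_p"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file into intervals, in file order.

    Column 6 (strand), when present, is preserved; track/browser/comment
    lines are skipped.  Raises :class:`BedParseError` naming the offending
    line on malformed input or ``start >= end``.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in VALID_STRANDS else "."
            try:
                intervals.append(GenomicInterval(fields[0], start, end, strand))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    scores: Sequence[float] | None = None,
    names: Sequence[str] | None = None,
) -> None:
    """Write intervals as BED6 (name, score and strand filled in)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"region_{i + 1}"
            score = f"{scores[i]:.6g}" if scores is not None else "0"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def read_genome_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` table."""
    genome: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise BedParseError(f"{path}:{lineno}: expected chrom<TAB>length")
            genome[fields[0]] = int(fields[1])
    return genome


def read_tags_bed(
    path: str | Path,
    genome: Mapping[str, int],
    library_id: str,
    mark: str,
    condition: str,
) -> TagSet:
    """Read single-end tags from BED6; the 5' position is the interval
    start on plus/unstranded tags and ``end - 1`` on minus-strand tags."""
    intervals = read_bed(path)
    tags = [
        (iv.chrom, iv.start if iv.strand != "-" else iv.end - 1, iv.strand)
        for iv in intervals
    ]
    return TagSet(library_id, mark, condition, tags, genome)


def write_tags_bed(tags: TagSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        i = 0
        for chrom, pos, strand in tags.iter_tags():
            i += 1
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\ttag_{i}\t0\t{strand if strand in '+-' else '.'}\n")


def _collapse_longest(genes: list[GeneModel]) -> list[GeneModel]:
    """Collapse duplicate gene_ids to the longest transcript, keeping
    first-seen order of gene_ids."""
    best: dict[str, GeneModel] = {}
    order: list[str] = []
    for g in genes:
        if g.gene_id not in best:
            best[g.gene_id] = g
            order.append(g.gene_id)
        elif g.length > best[g.gene_id].length:
            best[g.gene_id] = g
    return [best[gid] for gid in order]


def read_gene_models(path: str | Path, dialect: str = "refFlat") -> list[GeneModel]:
    """Read gene models from a refFlat or BED12 file.

    refFlat columns used: geneName, name, chrom, strand, txStart, txEnd.
    BED12 columns used: chrom, start, end, name, score, strand.  Duplicate
    gene_ids are collapsed to the longest transcript.
    """
    if dialect not in ("refFlat", "BED12"):
        raise ValueError(f"unknown gene-model dialect {dialect!r}")
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "refFlat":
                    if len(fields) < 6:
                        raise BedParseError("expected >= 6 refFlat columns")
                    gene_id, _tx, chrom, strand = fields[0], fields[1], fields[2], fields[3]
                    start, end = int(fields[4]), int(fields[5])
                else:
                    if len(fields) < 6:
                        raise BedParseError("expected >= 6 BED12 columns")
                    chrom, gene_id, strand = fields[0], fields[3], fields[5]
                    start, end = int(fields[1]), int(fields[2])
                genes.append(GeneModel(gene_id, GenomicInterval(chrom, start, end, strand), strand))
            except (ValueError, BedParseError) as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return _collapse_longest(genes)


def write_gene_models_refflat(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            fh.write(
                f"{g.gene_id}\t{g.gene_id}.1\t{iv.chrom}\t{g.strand}"
                f"\t{iv.start}\t{iv.end}\t{iv.start}\t{iv.end}\t1\t{iv.start},\t{iv.end},\n"
            )


REGION_TABLE_COLUMNS = [
    "chrom",
    "start",
    "end",
    "mark",
    "base_mean",
    "log2fc",
    "p",
    "q",
    "direction",
    "dispersion",
]


def write_region_table(regions: Sequence, path: str | Path) -> None:
    """Write DifferentialRegion records as a TSV with a named header.

    Floats are serialized with enough digits (repr-faithful) that the
    paired :func:`read_region_table` round-trips losslessly.
    """
    rows = []
    for r in regions:
        iv = r.interval
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "mark": r.mark,
                "base_mean": repr(float(r.base_mean)),
                "log2fc": repr(float(r.log2fc)),
                "p": repr(float(r.p)),
                "q": repr(float(r.q)),
                "direction": r.direction,
                "dispersion": repr(float(r.dispersion)),
            }
        )
    pd.DataFrame(rows, columns=REGION_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_region_table(path: str | Path) -> list:
    from .differential import DifferentialRegion  # local import avoids a cycle

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "mark": str, "direction": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(
            DifferentialRegion(
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
                mark=row.mark,
                base_mean=float(row.base_mean),
                log2fc=float(row.log2fc),
                p=float(row.p),
                q=float(row.q),
                direction=row.direction,
                dispersion=float(row.dispersion),
            )
        )
    return out
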