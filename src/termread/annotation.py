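"""Gene annotations with strand, poly(A) sites, and neighbor-orientation relations.

Coordinates are 0-based half-open (BED convention) throughout.  Each gene
carries a single poly(A) site: the 3'-terminal boundary of its interval
(``end`` for plus-strand genes, ``start`` for minus-strand genes) unless a
position inside the interval is given explicitly.

Adjacent genes on a chromosome define a *junction* whose orientation class
follows from the two strands:

* ``codirectional`` — both genes on the same strand;
* ``convergent``    — left gene on ``+``, right gene on ``-`` (3' ends facing);
* ``divergent``     — left gene on ``-``, right gene on ``+`` (5' ends facing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import gffutils

CODIRECTIONAL = "codirectional"
CONVERGENT = "convergent"
DIVERGENT = "divergent"
CHROMOSOME_END = "chromosome-end"

_RELATIONS = {
    ("+", "+"): CODIRECTIONAL,
    ("-", "-"): CODIRECTIONAL,
    ("+", "-"): CONVERGENT,
    ("-", "+"): DIVERGENT,
}


@dataclass(frozen=True)
class Gene:
    """A gene interval with its poly(A) site.

    ``polya_site`` lies within ``[start, end]`` and marks the pre-mRNA
    cleavage position used as the metagene anchor.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    polya_site: int = -1

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.polya_site < 0:
            object.__setattr__(
                self, "polya_site", self.end if self.strand == "+" else self.start
            )
        if not (self.start <= self.polya_site <= self.end):
            raise ValueError(f"{self.gene_id}: polya_site outside [start, end]")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start position (5' boundary)."""
        return self.start if self.strand == "+" else self.end


def junction_relation(left_strand: str, right_strand: str) -> str:
    """Orientation class of a junction between two adjacent genes."""
    return _RELATIONS[(left_strand, right_strand)]


@dataclass
class GenomeAnnotation:
    """An ordered collection of non-overlapping (per strand) gene intervals.

    ``chrom_lengths`` is optional; when absent, consumers fall back to the
    rightmost gene end per chromosome.
    """

    genes: list[Gene] = field(default_factory=list)
    chrom_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.chrom, g.start, g.end))
        self._check_overlaps()

    def chrom_length(self, chrom: str) -> int:
        if self.chrom_lengths and chrom in self.chrom_lengths:
            return self.chrom_lengths[chrom]
        return max(g.end for g in self.genes if g.chrom == chrom)

    def _check_overlaps(self) -> None:
        last: dict[tuple[str, str], int] = {}
        for g in self.genes:
            key = (g.chrom, g.strand)
            if key in last and g.start < last[key]:
                raise ValueError(
                    f"overlapping same-strand genes on {g.chrom}{g.strand} at {g.gene_id}"
                )
            last[key] = g.end

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(g.chrom, None)
        return list(seen)

    def by_chrom(self, chrom: str) -> list[Gene]:
        return [g for g in self.genes if g.chrom == chrom]

    def junctions(self) -> list[tuple[Gene, Gene, str]]:
        """(left gene, right gene, relation) for every adjacent pair per chromosome."""
        out = []
        for chrom in self.chroms():
            genes = self.by_chrom(chrom)
            for left, right in zip(genes, genes[1:]):
                out.append((left, right, junction_relation(left.strand, right.strand)))
        return out

    def convergent_pairs(self) -> list[tuple[Gene, Gene]]:
        """Adjacent (plus, minus) pairs whose 3' ends face each other."""
        return [(l, r) for l, r, rel in self.junctions() if rel == CONVERGENT]

    def flanking_relations(self, mirror: bool = False) -> dict[str, tuple[str, str]]:
        """Per gene, the orientation relations at its two flanking junctions.

        Returned as ``(left, right)`` in genomic coordinates; genes at a
        chromosome boundary get ``chromosome-end`` on the open side.  With
        ``mirror=True`` the tuple is given in the gene's own 5'->3' reading
        (upstream junction first), which is what transcription-polarity
        analyses want.
        """
        out: dict[str, tuple[str, str]] = {}
        for chrom in self.chroms():
            genes = self.by_chrom(chrom)
            for i, g in enumerate(genes):
                left = (
                    junction_relation(genes[i - 1].strand, g.strand)
                    if i > 0
                    else CHROMOSOME_END
                )
                right = (
                    junction_relation(g.strand, genes[i + 1].strand)
                    if i < len(genes) - 1
                    else CHROMOSOME_END
                )
                if mirror and g.strand == "-":
                    left, right = right, left
                out[g.gene_id] = (left, right)
        return out


# ---------------------------------------------------------------------------
# GFF3 / BED6 round trip
# ---------------------------------------------------------------------------

def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write genes as GFF3 with a ``polyA_site`` attribute (1-based coords)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation:
            attrs = f"ID={g.gene_id};polyA_site={g.polya_site}"
            fh.write(
                f"{g.chrom}\ttermread\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def read_gff3(path: str | Path) -> GenomeAnnotation:
    """Read gene records (feature type ``gene``) from a GFF3 file."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        polya = feat.attributes.get("polyA_site", [None])[0]
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            Gene(
                gene_id=gene_id,
                chrom=feat.seqid,
                start=feat.start - 1,  # GFF3 is 1-based closed
                end=feat.end,
                strand=feat.strand,
                polya_site=int(polya) if polya is not None else -1,
            )
        )
    return GenomeAnnotation(genes)


def write_bed6(annotation: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in annotation:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_bed6(path: str | Path) -> GenomeAnnotation:
    """Read a BED6 file; poly(A) sites default to the 3' interval boundary."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected >=6 BED fields")
            chrom, start, end, name, _score, strand = fields[:6]
            genes.append(Gene(name, chrom, int(start), int(end), strand))
    return GenomeAnnotation(genes)


def read_annotation(path: str | Path) -> GenomeAnnotation:
    """Dispatch on extension: ``.gff``/``.gff3`` vs ``.bed``."""
    suffix = Path(path).suffix.lower()
    if suffix in (".gff", ".gff3"):
        return read_gff3(path)
    if suffix == ".bed":
        return read_bed6(path)
    raise ValueError(f"unrecognized annotation format: {path}")


def write_annotation(annotation: GenomeAnnotation, path: str | Path) -> None:
    suffix = Path(path).suffix.lower()
    if suffix in (".gff", ".gff3"):
        write_gff3(annotation, path)
    elif suffix == ".bed":
        write_bed6(annotation, path)
    else:
        raise ValueError(f"unrecognized annotation format: {path}")


def mirror_annotation(annotation: GenomeAnnotation, chrom_lengths: dict[str, int]) -> GenomeAnnotation:
    """Reflect all coordinates through the chromosome end and flip strands.

    Orientation classes are invariant under this transformation; used for
    consistency checks.
    """
    genes = []
    for g in annotation:
        L = chrom_lengths[g.chrom]
        genes.append(
            Gene(
                g.gene_id,
                g.chrom,
                L - g.end,
                L - g.start,
                "-" if g.strand == "+" else "+",
                L - g.polya_site,
            )
        )
    return GenomeAnnotation(genes, dict(chrom_lengths))
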