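"""Virtual reference tag library: CATG-anchored 21-nt tag extraction and resolution.

In NlaIII/MmeI DGE tag profiling every transcript is represented by short
tags anchored at a CATG restriction site: the tag is the CATG plus the 17 nt
immediately downstream (21 nt total).  The reference "virtual tag library"
enumerates *all* CATG + 17 nt windows of every transcript; sequenced tags are
then resolved against it either by perfect match or by allowing a single
mismatch in the 17-nt variable region (SNP tolerance between varieties).
A tag whose governing match level hits more than one gene is ambiguous and
is discarded from expression analysis.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ANCHOR = "CATG"
TAG_LENGTH = 21
_SUFFIX_LENGTH = TAG_LENGTH - len(ANCHOR)  # 17
_BASES = ("A", "C", "G", "T")

__all__ = [
    "ANCHOR",
    "TAG_LENGTH",
    "TranscriptSet",
    "VirtualTagIndex",
    "TagResolution",
    "extract_virtual_tags",
    "resolve_tag",
]


@dataclass
class TranscriptSet:
    """An ordered gene-id -> nucleotide sequence mapping (unigene-style reference).

    Sequences are uppercase A/C/G/T/N; one oriented (sense-strand) sequence
    per gene, as in an EST/unigene collection.
    """

    records: dict[str, str]

    def __post_init__(self) -> None:
        for gene_id, seq in self.records.items():
            if not gene_id:
                raise ValueError("empty gene identifier")
            if not seq:
                raise ValueError(f"empty sequence for gene {gene_id!r}")
            up = seq.upper()
            if set(up) - {"A", "C", "G", "T", "N"}:
                raise ValueError(f"non-ACGTN characters in sequence of {gene_id!r}")
            self.records[gene_id] = up

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.records.items())

    def __getitem__(self, gene_id: str) -> str:
        return self.records[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.records)

    @classmethod
    def from_fasta(cls, path) -> "TranscriptSet":
        records: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in records:
                raise ValueError(f"duplicate gene id in FASTA: {rec.id!r}")
            records[rec.id] = str(rec.seq).upper()
        return cls(records)

    def to_fasta(self, path) -> None:
        recs = [
            SeqRecord(Seq(seq), id=gene_id, description="")
            for gene_id, seq in self.records.items()
        ]
        SeqIO.write(recs, str(path), "fasta")


@dataclass
class VirtualTagIndex:
    """All CATG + 17 nt reference tags with their gene assignments.

    ``tag_to_genes`` maps each 21-nt tag to the set of genes containing it on
    the sense strand; ``sites`` lists every (gene_id, 0-based CATG offset,
    strand) extraction site; ``ambiguous_tags`` are tags shared by more than
    one gene.  ``genes_without_sites`` reports genes contributing no tag.
    """

    tag_to_genes: dict[str, frozenset[str]]
    sites: list[tuple[str, int, str]]
    ambiguous_tags: frozenset[str]
    genes_without_sites: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def genes_with_sites(self) -> frozenset[str]:
        return frozenset(g for g, _, _ in self.sites)

    def to_tsv(self, path) -> None:
        """Write the index as (tag, semicolon-joined gene ids, ambiguous flag)."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["tag", "gene_ids", "ambiguous"])
            for tag in sorted(self.tag_to_genes):
                genes = ";".join(sorted(self.tag_to_genes[tag]))
                flag = int(tag in self.ambiguous_tags)
                writer.writerow([tag, genes, flag])

    def summary(self) -> dict[str, int]:
        return {
            "n_genes_with_sites": len(self.genes_with_sites),
            "n_genes_without_sites": len(self.genes_without_sites),
            "n_sites": self.n_sites,
            "n_distinct_tags": len(self.tag_to_genes),
            "n_ambiguous_tags": len(self.ambiguous_tags),
        }


def _scan_sites(sequence: str) -> Iterator[tuple[int, str]]:
    """Yield (offset, tag) for every CATG with >=17 valid downstream nt.

    Overlapping CATG occurrences are all taken; a window containing N is
    skipped (an undetermined reference base cannot define a tag).
    """
    start = 0
    while True:
        offset = sequence.find(ANCHOR, start)
        if offset == -1:
            return
        start = offset + 1
        tag = sequence[offset : offset + TAG_LENGTH]
        if len(tag) == TAG_LENGTH and "N" not in tag:
            yield offset, tag


def extract_virtual_tags(
    transcripts: TranscriptSet, include_antisense: bool = False
) -> VirtualTagIndex:
    """Build the virtual tag index from every CATG + 17 nt window.

    Parameters
    ----------
    transcripts
        Oriented reference sequences.
    include_antisense
        Also scan the reverse complement of each transcript.  Off by
        default: unigene ESTs are oriented and the bead-capture chemistry
        reads the mRNA 3' end, so sense-strand scanning is the standard
        configuration.  Antisense sites are recorded with strand ``'-'`` and
        offsets on the reverse-complement string.
    """
    tag_to_genes: dict[str, set[str]] = {}
    sites: list[tuple[str, int, str]] = []
    empty_genes: list[str] = []
    for gene_id, seq in transcripts:
        strands = [("+", seq)]
        if include_antisense:
            strands.append(("-", str(Seq(seq).reverse_complement())))
        n_before = len(sites)
        for strand, s in strands:
            for offset, tag in _scan_sites(s):
                sites.append((gene_id, offset, strand))
                tag_to_genes.setdefault(tag, set()).add(gene_id)
        if len(sites) == n_before:
            empty_genes.append(gene_id)
    frozen = {tag: frozenset(genes) for tag, genes in tag_to_genes.items()}
    ambiguous = frozenset(tag for tag, genes in frozen.items() if len(genes) > 1)
    return VirtualTagIndex(
        tag_to_genes=frozen,
        sites=sites,
        ambiguous_tags=ambiguous,
        genes_without_sites=tuple(empty_genes),
    )


@dataclass(frozen=True)
class TagResolution:
    """Outcome of resolving one query tag against the index.

    ``status`` is ``'gene'`` (exactly one gene at the governing match level),
    ``'ambiguous'`` (>1 gene at that level) or ``'unmapped'``.  ``match_class``
    is ``'perfect'`` or ``'mismatch1'`` when a hit exists, else ``None``.
    """

    status: str
    gene_id: str | None = None
    match_class: str | None = None
    genes: frozenset[str] = frozenset()


_UNMAPPED = TagResolution(status="unmapped")


def _mismatch1_neighbours(tag: str) -> Iterator[str]:
    # mismatch allowed only in the 17-nt variable region; CATG anchor fixed
    for pos in range(len(ANCHOR), TAG_LENGTH):
        original = tag[pos]
        for base in _BASES:
            if base != original:
                yield tag[:pos] + base + tag[pos + 1 :]


def resolve_tag(tag: str, index: VirtualTagIndex) -> TagResolution:
    """Resolve a 21-nt tag to a gene under the perfect / 1-mismatch policy.

    A perfect hit governs: 1-mismatch neighbours are consulted only when the
    tag itself is absent from the index.  At the governing level the tag is
    assigned to a gene only when exactly one gene carries it; with several
    genes it is ambiguous (and will be dropped from expression analysis); no
    hit at either level is unmapped.  The single mismatch is confined to the
    17-nt variable region -- the CATG anchor is the restriction site that
    defines the read, so a tag not beginning with CATG cannot map.
    """
    if len(tag) != TAG_LENGTH:
        raise ValueError(f"tag must be {TAG_LENGTH} nt, got {len(tag)}")
    if not tag.startswith(ANCHOR):
        return _UNMAPPED
    perfect = index.tag_to_genes.get(tag)
    if perfect:
        if len(perfect) == 1:
            return TagResolution("gene", next(iter(perfect)), "perfect", perfect)
        return TagResolution("ambiguous", None, "perfect", perfect)
    genes: set[str] = set()
    for neighbour in _mismatch1_neighbours(tag):
        hit = index.tag_to_genes.get(neighbour)
        if hit:
            genes.update(hit)
            if len(genes) > 1:
                # already ambiguous; further neighbours cannot undo that
                break
    if not genes:
        return _UNMAPPED
    if len(genes) == 1:
        return TagResolution("gene", next(iter(genes)), "mismatch1", frozenset(genes))
    return TagResolution("ambiguous", None, "mismatch1", frozenset(genes))
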