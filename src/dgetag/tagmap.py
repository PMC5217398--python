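"""Clean-tag to gene mapping and the gene x library count matrix.

Each distinct clean tag is resolved once against the virtual tag index
(perfect match governing, otherwise a single mismatch in the 17-nt variable
region).  A tag resolving to exactly one gene credits its whole copy number
to that gene; a tag hitting several genes is ambiguous and discarded; a tag
hitting none is unmapped.  The accounting identity

    unmapped + ambiguous + unambiguous = total clean tags

holds exactly for every library.  Mapping percentages use total clean tags
as the denominator, and a gene counts as detected when it receives at least
one unambiguous tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .refindex import VirtualTagIndex, resolve_tag
from .tagprep import TagLibrary

__all__ = ["MappingStats", "MappedLibrary", "CountMatrix", "map_library", "assemble_matrix"]


@dataclass
class MappingStats:
    """Per-library mapping statistics in the layout of a DGE library table."""

    library_id: str
    clean_total: int
    mapped_count: int        # clean tags hitting >=1 gene (incl. ambiguous)
    unambiguous_count: int   # clean tags credited to exactly one gene
    ambiguous_count: int
    unmapped_count: int
    genes_detected: int
    perfect_count: int = 0
    mismatch1_count: int = 0

    @property
    def mapped_pct(self) -> float:
        return 100.0 * self.mapped_count / self.clean_total if self.clean_total else 0.0

    @property
    def unambiguous_pct(self) -> float:
        return 100.0 * self.unambiguous_count / self.clean_total if self.clean_total else 0.0

    def as_row(self) -> dict:
        return {
            "library": self.library_id,
            "total_clean_tags": self.clean_total,
            "clean_tags_mapped_to_gene": self.mapped_count,
            "pct_clean_tags_mapped_to_gene": self.mapped_pct,
            "unambiguous_tags_mapped_to_gene": self.unambiguous_count,
            "pct_unambiguous_tags_mapped_to_gene": self.unambiguous_pct,
            "unambiguous_tag_mapped_genes": self.genes_detected,
            "ambiguous_tags": self.ambiguous_count,
            "unmapped_tags": self.unmapped_count,
        }


@dataclass
class MappedLibrary:
    library_id: str
    gene_counts: dict[str, int]
    stats: MappingStats
    audit: pd.DataFrame | None = None


def map_library(
    lib: TagLibrary, index: VirtualTagIndex, keep_audit: bool = False
) -> MappedLibrary:
    """Resolve every distinct clean tag and accumulate per-gene counts.

    Resolution is strictly per tag: each tag's fate depends only on its own
    perfect/1-mismatch hits, and its whole copy number is either credited to
    one gene or dropped (no fractional allocation of ambiguous tags).
    """
    gene_counts: dict[str, int] = {}
    n_unamb = n_ambig = n_unmapped = n_perfect = n_mm1 = 0
    audit_rows = [] if keep_audit else None
    for tag, count in lib.clean_counts.items():
        res = resolve_tag(tag, index)
        if res.status == "gene":
            gene_counts[res.gene_id] = gene_counts.get(res.gene_id, 0) + count
            n_unamb += count
            if res.match_class == "perfect":
                n_perfect += count
            else:
                n_mm1 += count
        elif res.status == "ambiguous":
            n_ambig += count
        else:
            n_unmapped += count
        if audit_rows is not None:
            audit_rows.append((tag, count, res.status, res.gene_id or "", res.match_class or ""))
    stats = MappingStats(
        library_id=lib.library_id,
        clean_total=lib.total_clean,
        mapped_count=n_unamb + n_ambig,
        unambiguous_count=n_unamb,
        ambiguous_count=n_ambig,
        unmapped_count=n_unmapped,
        genes_detected=len(gene_counts),
        perfect_count=n_perfect,
        mismatch1_count=n_mm1,
    )
    audit = None
    if audit_rows is not None:
        audit = pd.DataFrame(
            audit_rows, columns=["tag", "count", "status", "gene_id", "match_class"]
        ).sort_values("tag", ignore_index=True)
    return MappedLibrary(lib.library_id, gene_counts, stats, audit)


@dataclass
class CountMatrix:
    """Gene x library unambiguous tag counts plus per-library clean totals.

    Genes with all-zero rows are retained: the full tag-mapped reference set
    is the background universe for enrichment analysis.
    """

    counts: pd.DataFrame          # genes x libraries, int
    clean_totals: pd.Series       # per library

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(int)
        self.clean_totals = self.clean_totals.astype(int)
        missing = [c for c in self.counts.columns if c not in self.clean_totals.index]
        if missing:
            raise ValueError(f"clean totals missing for libraries: {missing}")
        bad = [
            c for c in self.counts.columns if self.counts[c].sum() > self.clean_totals[c]
        ]
        if bad:
            raise ValueError(f"column sum exceeds clean total for: {bad}")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_arrays(
        cls, genes: list[str], libraries: list[str], counts: np.ndarray, clean_totals: list[int]
    ) -> "CountMatrix":
        return cls(
            counts=pd.DataFrame(counts, index=genes, columns=libraries),
            clean_totals=pd.Series(clean_totals, index=libraries),
        )


def assemble_matrix(
    mapped: list[MappedLibrary], genes: list[str] | None = None
) -> CountMatrix:
    """Join per-library gene counts into one matrix.

    The gene universe defaults to the union of genes seen across libraries;
    pass the index's full gene list to retain all-zero background genes.
    Missing entries are zero; clean totals are carried through per library.
    """
    if not mapped:
        raise ValueError("at least one mapped library is required")
    ids = [m.library_id for m in mapped]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate library ids: {sorted(ids)}")
    if genes is None:
        universe: list[str] = sorted({g for m in mapped for g in m.gene_counts})
    else:
        universe = list(genes)
        seen = set(universe)
        stray = {g for m in mapped for g in m.gene_counts} - seen
        if stray:
            raise ValueError(f"mapped genes missing from supplied gene list: {sorted(stray)[:5]}")
    data = {
        m.library_id: [m.gene_counts.get(g, 0) for g in universe] for m in mapped
    }
    counts = pd.DataFrame(data, index=universe)
    totals = pd.Series({m.library_id: m.stats.clean_total for m in mapped})
    return CountMatrix(counts=counts, clean_totals=totals)


def mapping_stats_table(mapped: list[MappedLibrary]) -> pd.DataFrame:
    """Library-statistics table with one row per library (Table-1-style layout)."""
    return pd.DataFrame([m.stats.as_row() for m in mapped])
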