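"""Raw-read cleaning, copy-number statistics and library saturation.

Raw 21-nt tag reads pass five filters, applied in a fixed order so that each
read is charged to exactly one removal class and read accounting is exact:

1. adaptor    -- the read contains the 3' adaptor (adaptor k-mer at position > 0);
2. empty      -- the read is adaptor only, with no tag content (k-mer at position 0);
3. low-quality -- the read carries an ambiguous base call (N);
4. length     -- the read is longer or shorter than 21 nt;
5. singleton  -- after aggregation, tags with library copy number < 2.

What survives is the clean-tag library: a multiset of 21-nt tags, each with
copy number >= 2, whose total is the denominator of all per-library
percentages and of the TPM normalization downstream.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO

from .refindex import TAG_LENGTH, VirtualTagIndex, resolve_tag

FILTER_CLASSES = ("adaptor", "empty", "low_quality", "length", "singleton")

__all__ = ["TagLibrary", "clean_tags", "copy_number_distribution", "saturation_curve", "read_sequences"]


@dataclass
class TagLibrary:
    """A cleaned tag library: tag -> copy number plus filter accounting."""

    library_id: str
    clean_counts: dict[str, int]
    filter_stats: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cls in FILTER_CLASSES:
            self.filter_stats.setdefault(cls, 0)
        self.filter_stats.setdefault("raw_total", self.total_clean + self.total_removed)

    @property
    def total_clean(self) -> int:
        return sum(self.clean_counts.values())

    @property
    def total_removed(self) -> int:
        return sum(self.filter_stats.get(cls, 0) for cls in FILTER_CLASSES)

    @property
    def n_distinct(self) -> int:
        return len(self.clean_counts)

    def to_tsv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["tag", "count"])
            for tag in sorted(self.clean_counts):
                writer.writerow([tag, self.clean_counts[tag]])

    @classmethod
    def from_counts_tsv(cls, path, library_id: str) -> "TagLibrary":
        """Load an already-clean (tag, count) TSV as a library."""
        counts: dict[str, int] = {}
        with open(path, newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader)
            if header and header[0] != "tag":  # headerless file: first row is data
                counts[header[0]] = int(header[1])
            for tag, count in reader:
                counts[tag] = int(count)
        return cls(library_id=library_id, clean_counts=counts)

    def stats_row(self) -> dict[str, int]:
        return {
            "library": self.library_id,
            "raw_total": self.filter_stats["raw_total"],
            **{cls: self.filter_stats[cls] for cls in FILTER_CLASSES},
            "total_clean": self.total_clean,
            "distinct_clean_tags": self.n_distinct,
        }


def read_sequences(path) -> Iterator[str]:
    """Stream read sequences from FASTA or FASTQ, inferred from the extension."""
    p = str(path)
    fmt = "fastq" if p.endswith((".fastq", ".fq")) else "fasta"
    for rec in SeqIO.parse(p, fmt):
        yield str(rec.seq).upper()


def clean_tags(
    reads: Iterable[str],
    library_id: str = "lib",
    adaptor: str | None = None,
    adaptor_kmer: int = 8,
) -> TagLibrary:
    """Apply the five cleaning filters to a raw read stream.

    ``adaptor`` is matched by exact substring search of its first
    ``adaptor_kmer`` nt; a match at position 0 means the read is adaptor
    only (empty), a match further in means adaptor contamination.  Counts
    are aggregated by exact sequence before the copy-number filter, so the
    singleton statistic counts reads whose tag occurred exactly once in the
    library.  An empty input yields an empty library with zeroed statistics.
    """
    if adaptor is not None and not adaptor:
        raise ValueError("adaptor must be non-empty when given")
    key = adaptor[:adaptor_kmer] if adaptor else None
    stats = {cls: 0 for cls in FILTER_CLASSES}
    counts: dict[str, int] = {}
    raw_total = 0
    for read in reads:
        raw_total += 1
        read = read.upper()
        if key is not None:
            pos = read.find(key)
            if pos == 0:
                stats["empty"] += 1
                continue
            if pos > 0:
                stats["adaptor"] += 1
                continue
        if any(c not in "ACGT" for c in read):
            stats["low_quality"] += 1
            continue
        if len(read) != TAG_LENGTH:
            stats["length"] += 1
            continue
        counts[read] = counts.get(read, 0) + 1
    singles = [tag for tag, c in counts.items() if c < 2]
    stats["singleton"] = len(singles)  # each singleton tag is one removed read
    for tag in singles:
        del counts[tag]
    stats["raw_total"] = raw_total
    return TagLibrary(library_id=library_id, clean_counts=counts, filter_stats=stats)


def copy_number_distribution(
    lib: TagLibrary, bin_edges: tuple[int, ...] = (5, 10, 20, 50, 100)
) -> pd.DataFrame:
    """Classify clean tags by copy number.

    ``bin_edges`` are inclusive upper bounds; bins are [2, e1], (e1, e2], ...,
    (e_last, inf), covering the whole clean range [2, inf).  Per bin the frame
    reports the distinct-tag count, the summed copies and the percentage of
    total clean tags (copies / total_clean * 100); percentages sum to 100.
    An empty library reports zeros and sets ``attrs['empty_library']``.
    """
    edges = sorted(bin_edges)
    if edges and edges[0] < 2:
        raise ValueError("bins must start at copy number 2")
    lowers = [2] + [e + 1 for e in edges]
    uppers = list(edges) + [None]
    labels = [f"{lo}-{hi}" if hi is not None else f">{lo - 1}" for lo, hi in zip(lowers, uppers)]
    n_tags = [0] * len(labels)
    n_copies = [0] * len(labels)
    for count in lib.clean_counts.values():
        for i, (lo, hi) in enumerate(zip(lowers, uppers)):
            if count >= lo and (hi is None or count <= hi):
                n_tags[i] += 1
                n_copies[i] += count
                break
    total = lib.total_clean
    pct = [100.0 * c / total if total else 0.0 for c in n_copies]
    out = pd.DataFrame(
        {"copy_number": labels, "n_tags": n_tags, "n_copies": n_copies, "pct_of_clean": pct}
    )
    out.attrs["empty_library"] = total == 0
    return out


def saturation_curve(
    lib: TagLibrary,
    index: VirtualTagIndex,
    depth_fractions: tuple[float, ...] = (0.1, 0.2, 0.4, 0.6, 0.8, 1.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Detected-gene count as a function of subsampled clean-tag depth.

    Clean tags are expanded to reads and subsampled *without replacement*
    through one shared random permutation, so the subsamples are nested and
    the curve is monotone for each seed.  A gene counts as detected when at
    least one unambiguously mapping tag hits it.  Reported per fraction:
    reads used, genes detected, and the new-gene rate (genes gained per
    read relative to the previous fraction).
    """
    fracs = sorted(depth_fractions)
    if not fracs or fracs[-1] != 1.0 or fracs[0] <= 0:
        raise ValueError("depth_fractions must lie in (0, 1] and include 1.0")
    tags = sorted(lib.clean_counts)
    gene_index: dict[str, int] = {}
    per_tag_gene = np.full(len(tags), -1, dtype=int)
    for i, tag in enumerate(tags):
        res = resolve_tag(tag, index)
        if res.status == "gene":
            per_tag_gene[i] = gene_index.setdefault(res.gene_id, len(gene_index))
    reads_gene = np.repeat(per_tag_gene, [lib.clean_counts[t] for t in tags])
    rng = np.random.default_rng(seed)
    permuted = reads_gene[rng.permutation(len(reads_gene))]
    rows = []
    prev_detected, prev_reads = 0, 0
    for f in fracs:
        n_reads = int(round(f * len(permuted)))
        prefix = permuted[:n_reads]
        detected = len(np.unique(prefix[prefix >= 0]))
        gained = detected - prev_detected
        dn = n_reads - prev_reads
        rows.append(
            {
                "fraction": f,
                "n_reads": n_reads,
                "genes_detected": detected,
                "new_genes_per_read": gained / dn if dn else 0.0,
            }
        )
        prev_detected, prev_reads = detected, n_reads
    return pd.DataFrame(rows)
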