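"""Synthetic transcriptomes, expression scenarios and noisy tag libraries.

Every downstream stage of the pipeline (cleaning, mapping, differential
calling, enrichment) is testable without external data because this module
generates the inputs with a complete ground truth: a random transcriptome in
which every gene carries at least one extractable CATG + 17 nt tag, a
two-condition expression scenario with planted log2 fold changes, and raw
21-nt read libraries drawn multinomially from the scenario and pushed through
a configurable noise channel (per-base substitution error plus the junk-read
classes removed by the cleaning filters: adaptor-contaminated, adaptor-only,
ambiguous-base and wrong-length reads).

Ground truth for each emitted read (its class, source gene and tag site) is
recorded in a :class:`TruthManifest`, so recovery can be checked exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .refindex import ANCHOR, TAG_LENGTH, TranscriptSet, _scan_sites

_BASES = np.array(list("ACGT"))

#: Synthetic Illumina-style 3' adaptor used by default throughout the package.
#: The real study does not publish its adaptor; any fixed sequence with a
#: distinctive prefix works because cleaning matches an adaptor k-mer.
DEFAULT_ADAPTOR = "TCGTATGCCGTCTTCTGCTTG"

__all__ = [
    "DEFAULT_ADAPTOR",
    "ExpressionScenario",
    "NoiseProfile",
    "TruthManifest",
    "generate_transcriptome",
    "make_de_scenario",
    "simulate_tag_library",
    "sample_counts",
    "make_annotation",
]


@dataclass
class ExpressionScenario:
    """Two-condition expression truth model with planted fold changes.

    ``baseline_abundance`` is the condition-A relative abundance (a
    probability vector); ``condition_log2fc`` holds the *planted* per-gene
    log2 fold change applied before per-condition renormalization (0 for
    null genes); ``de_labels`` is the truth flag ``'up'``/``'down'``/``'null'``.
    """

    gene_ids: list[str]
    baseline_abundance: np.ndarray
    condition_log2fc: np.ndarray
    de_labels: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        self.baseline_abundance = np.asarray(self.baseline_abundance, dtype=float)
        self.condition_log2fc = np.asarray(self.condition_log2fc, dtype=float)
        self.de_labels = np.asarray(self.de_labels, dtype=object)
        if not (len(self.baseline_abundance) == len(self.condition_log2fc) == len(self.de_labels) == n):
            raise ValueError("scenario field lengths disagree")
        if np.any(self.baseline_abundance < 0):
            raise ValueError("abundances must be non-negative")
        if not math.isclose(self.baseline_abundance.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("baseline abundance must sum to 1")
        planted = self.condition_log2fc != 0
        labelled = self.de_labels != "null"
        if np.any(planted != labelled):
            raise ValueError("|log2fc| > 0 must hold exactly for non-null labels")

    @property
    def treated_abundance(self) -> np.ndarray:
        """Condition-B abundance: baseline scaled by 2**log2fc, renormalized."""
        raw = self.baseline_abundance * np.exp2(self.condition_log2fc)
        return raw / raw.sum()

    def abundance(self, condition: str) -> np.ndarray:
        if condition == "baseline":
            return self.baseline_abundance
        if condition == "treated":
            return self.treated_abundance
        raise ValueError(f"unknown condition {condition!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "baseline_abundance": self.baseline_abundance,
                "log2fc": self.condition_log2fc,
                "de_label": self.de_labels,
            }
        )


@dataclass(frozen=True)
class NoiseProfile:
    """Noise channel for the read simulator.

    Fractions give the expected share of reads emitted as each junk class;
    they must jointly leave room for informative reads.  ``per_base_error_rate``
    applies independent substitution errors to informative reads only (junk
    classes are already unusable by construction).
    """

    per_base_error_rate: float = 0.0
    adaptor_fraction: float = 0.0
    empty_fraction: float = 0.0
    ambiguous_base_fraction: float = 0.0
    length_anomaly_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.adaptor_fraction,
            self.empty_fraction,
            self.ambiguous_base_fraction,
            self.length_anomaly_fraction,
        )
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("junk fractions must lie in [0, 1]")
        if sum(fracs) > 1:
            raise ValueError("junk fractions must jointly be <= 1")
        if not 0 <= self.per_base_error_rate <= 0.25:
            raise ValueError("per_base_error_rate must lie in [0, 0.25]")

    @property
    def junk_fraction(self) -> float:
        return (
            self.adaptor_fraction
            + self.empty_fraction
            + self.ambiguous_base_fraction
            + self.length_anomaly_fraction
        )


@dataclass
class TruthManifest:
    """Per-read ground truth for one simulated library.

    ``reads`` holds one row per emitted read: its class (``informative``,
    ``adaptor``, ``empty``, ``length``, ``ambiguous_base``), source gene and
    tag site for informative-derived reads, the error-free true tag and the
    emitted sequence.  ``true_counts`` are the per-gene informative-read
    counts; ``params`` records the scenario parameters and seed.
    """

    library_id: str
    reads: pd.DataFrame
    true_counts: pd.Series
    params: dict = field(default_factory=dict)

    @property
    def n_informative(self) -> int:
        return int((self.reads["read_class"] == "informative").sum())

    @property
    def n_junk(self) -> int:
        return len(self.reads) - self.n_informative

    def to_tsv(self, path) -> None:
        self.reads.to_csv(path, sep="\t", index=False)

    def write_descriptor(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"library_id": self.library_id, **self.params}, fh, sort_keys=True)


def _random_sequences(n: int, lengths: np.ndarray, rng: np.random.Generator) -> list[str]:
    return ["".join(_BASES[rng.integers(0, 4, size=int(m))]) for m in lengths]


def generate_transcriptome(
    n_genes: int,
    length_range: tuple[int, int] = (200, 600),
    seed: int = 0,
) -> TranscriptSet:
    """Generate a random transcript set where every gene hosts >=1 valid tag site.

    Sequences are uniform random A/C/G/T of lengths drawn uniformly from
    ``length_range``; any sequence lacking a CATG with 17 downstream nt gets a
    CATG planted 21 nt from its 3' end.  Deterministic for a fixed seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = length_range
    if lo < 25:
        raise ValueError("minimum transcript length is 25 nt (CATG + 17 nt tag plus margin)")
    if hi < lo:
        raise ValueError("length_range must be (min, max) with max >= min")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(lo, hi + 1, size=n_genes)
    width = max(4, len(str(n_genes)))
    records: dict[str, str] = {}
    for i, seq in enumerate(_random_sequences(n_genes, lengths, rng)):
        if next(_scan_sites(seq), None) is None:
            pos = len(seq) - TAG_LENGTH
            seq = seq[:pos] + ANCHOR + seq[pos + len(ANCHOR) :]
        records[f"g{i + 1:0{width}d}"] = seq
    return TranscriptSet(records)


def make_de_scenario(
    transcripts: TranscriptSet,
    frac_de: float,
    log2fc_magnitude: float,
    seed: int = 0,
    baseline_abundance: np.ndarray | None = None,
    abundance_sigma: float = 1.0,
) -> ExpressionScenario:
    """Plant differential expression into a transcript set.

    ``frac_de`` of the genes (split evenly up/down, ties toward up) receive a
    log2 fold change of ``+/-log2fc_magnitude``; the rest are null.  The
    baseline abundance defaults to a normalized log-normal draw with shape
    ``abundance_sigma`` (right-skewed, as real tag libraries are); pass an
    explicit vector (e.g. uniform) to control it.
    """
    n = len(transcripts)
    if n == 0:
        raise ValueError("empty transcript set")
    if not 0 <= frac_de <= 0.5:
        raise ValueError("frac_de must lie in [0, 0.5]")
    if log2fc_magnitude <= 0:
        raise ValueError("log2fc_magnitude must be > 0")
    rng = np.random.default_rng(seed)
    if baseline_abundance is None:
        baseline = rng.lognormal(mean=0.0, sigma=abundance_sigma, size=n)
    else:
        baseline = np.asarray(baseline_abundance, dtype=float).copy()
        if len(baseline) != n:
            raise ValueError("baseline_abundance length must match transcript count")
    baseline = baseline / baseline.sum()
    n_de = round(frac_de * n)
    de_idx = rng.choice(n, size=n_de, replace=False)
    n_up = (n_de + 1) // 2
    lfc = np.zeros(n)
    labels = np.full(n, "null", dtype=object)
    lfc[de_idx[:n_up]] = log2fc_magnitude
    labels[de_idx[:n_up]] = "up"
    lfc[de_idx[n_up:]] = -log2fc_magnitude
    labels[de_idx[n_up:]] = "down"
    return ExpressionScenario(
        gene_ids=transcripts.gene_ids,
        baseline_abundance=baseline,
        condition_log2fc=lfc,
        de_labels=labels,
        seed=seed,
    )


def sample_counts(abundance: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Multinomial per-gene tag counts at the given sequencing depth."""
    return rng.multinomial(depth, np.asarray(abundance, dtype=float))


def _three_prime_tags(transcripts: TranscriptSet) -> tuple[dict[str, str], dict[str, list[tuple[int, str]]]]:
    """Per-gene 3'-most tag and full site list (offset, tag)."""
    best: dict[str, str] = {}
    all_sites: dict[str, list[tuple[int, str]]] = {}
    for gene_id, seq in transcripts:
        sites = list(_scan_sites(seq))
        if sites:
            all_sites[gene_id] = sites
            best[gene_id] = sites[-1][1]  # largest offset = 3'-most
    return best, all_sites


def _apply_errors(tags: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Independent per-base substitution errors on an array of 21-nt strings."""
    if rate == 0 or len(tags) == 0:
        return tags
    mask = rng.random((len(tags), TAG_LENGTH)) < rate
    hit_rows = np.nonzero(mask.any(axis=1))[0]
    out = tags.copy()
    for i in hit_rows:
        chars = list(out[i])
        for pos in np.nonzero(mask[i])[0]:
            choices = [b for b in "ACGT" if b != chars[pos]]
            chars[pos] = choices[rng.integers(0, 3)]
        out[i] = "".join(chars)
    return out


def simulate_tag_library(
    transcripts: TranscriptSet,
    abundance: np.ndarray,
    depth: int,
    noise: NoiseProfile,
    library_id: str = "lib",
    leaky_site_rate: float = 0.0,
    adaptor: str = DEFAULT_ADAPTOR,
) -> tuple[list[str], TruthManifest]:
    """Simulate one raw 21-nt tag library with full ground truth.

    Each informative read carries the 3'-most CATG + 17 nt tag of a gene
    drawn multinomially by ``abundance`` (polyT bead capture retains the
    3'-most NlaIII fragment), then passes through the per-base error channel.
    With probability ``leaky_site_rate`` a read is drawn from a uniformly
    chosen non-3' CATG site instead, creating realistic multi-site and
    ambiguous-tag cases.  Junk reads are emitted at the profile's fractions,
    one mutually exclusive class per read, so that informative + junk reads
    equal ``depth`` exactly.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    abundance = np.asarray(abundance, dtype=float)
    if len(abundance) != len(transcripts):
        raise ValueError("abundance length must match transcript count")
    gene_ids = np.array(transcripts.gene_ids, dtype=object)
    best_tag, all_sites = _three_prime_tags(transcripts)
    expressed = [g for g, a in zip(gene_ids, abundance) if a > 0]
    missing = [g for g in expressed if g not in best_tag]
    if missing:
        raise ValueError(
            f"genes with positive abundance but no valid CATG site: {missing[:5]}"
        )
    rng = np.random.default_rng(noise.seed)
    probs = [
        noise.adaptor_fraction,
        noise.empty_fraction,
        noise.length_anomaly_fraction,
        noise.ambiguous_base_fraction,
    ]
    probs.append(1.0 - sum(probs))
    n_adaptor, n_empty, n_length, n_ambig, n_inf = rng.multinomial(depth, probs)

    # informative reads: gene draw, site choice, error channel
    gene_idx = rng.choice(len(gene_ids), size=n_inf, p=abundance / abundance.sum()) if n_inf else np.array([], dtype=int)
    true_tags = np.empty(n_inf, dtype=object)
    offsets = np.empty(n_inf, dtype=int)
    leaky = rng.random(n_inf) < leaky_site_rate if leaky_site_rate > 0 else np.zeros(n_inf, dtype=bool)
    for i in range(n_inf):
        g = gene_ids[gene_idx[i]]
        sites = all_sites[g]
        if leaky[i] and len(sites) > 1:
            off, tag = sites[rng.integers(0, len(sites) - 1)]  # any non-3'-most site
        else:
            off, tag = sites[-1]
        true_tags[i] = tag
        offsets[i] = off
    emitted = _apply_errors(true_tags, noise.per_base_error_rate, rng)

    def _junk_base_tags(n: int) -> list[str]:
        if n == 0:
            return []
        idx = rng.choice(len(gene_ids), size=n, p=abundance / abundance.sum())
        return [best_tag[gene_ids[j]] for j in idx]

    rows: list[tuple] = []
    reads: list[str] = []
    for tag_seq, g_i, off in zip(emitted, gene_idx, offsets):
        rows.append(("informative", gene_ids[g_i], int(off), true_tags[len(rows)]))
        reads.append(tag_seq)
    # adaptor-contaminated: partial tag followed by adaptor, padded to 21 nt
    for base in _junk_base_tags(n_adaptor):
        j = int(rng.integers(1, TAG_LENGTH - len(adaptor[:8]) + 1))  # adaptor never at pos 0
        read = (base[:j] + adaptor)[:TAG_LENGTH]
        rows.append(("adaptor", None, -1, None))
        reads.append(read)
    # empty: adaptor-only read, no tag content
    empty_read = (adaptor * 2)[:TAG_LENGTH]
    for _ in range(n_empty):
        rows.append(("empty", None, -1, None))
        reads.append(empty_read)
    # wrong length: valid-looking tag truncated or extended by 1 nt
    for base in _junk_base_tags(n_length):
        if rng.random() < 0.5:
            read = base[:-1]
        else:
            read = base + str(_BASES[rng.integers(0, 4)])
        rows.append(("length", None, -1, None))
        reads.append(read)
    # ambiguous base: one position replaced by N
    for base in _junk_base_tags(n_ambig):
        pos = int(rng.integers(0, TAG_LENGTH))
        rows.append(("ambiguous_base", None, -1, None))
        reads.append(base[:pos] + "N" + base[pos + 1 :])

    manifest_df = pd.DataFrame(rows, columns=["read_class", "gene_id", "site_offset", "true_tag"])
    manifest_df.insert(0, "read_id", [f"{library_id}_r{i}" for i in range(len(reads))])
    manifest_df["read_seq"] = reads
    informative = manifest_df[manifest_df["read_class"] == "informative"]
    true_counts = (
        informative.groupby("gene_id")["read_id"].count().reindex(gene_ids, fill_value=0)
    )
    true_counts.name = "true_count"
    manifest = TruthManifest(
        library_id=library_id,
        reads=manifest_df,
        true_counts=true_counts,
        params={
            "depth": int(depth),
            "seed": int(noise.seed),
            "per_base_error_rate": noise.per_base_error_rate,
            "adaptor_fraction": noise.adaptor_fraction,
            "empty_fraction": noise.empty_fraction,
            "ambiguous_base_fraction": noise.ambiguous_base_fraction,
            "length_anomaly_fraction": noise.length_anomaly_fraction,
            "leaky_site_rate": leaky_site_rate,
        },
    )
    return reads, manifest


def write_reads_fasta(reads: list[str], path, library_id: str = "lib") -> None:
    """Write raw reads as plain FASTA (one record per read)."""
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f">{library_id}_r{i}\n{seq}\n")


def make_annotation(
    gene_ids: list[str],
    n_terms: int = 40,
    mean_genes_per_term: int = 25,
    seed: int = 0,
    planted_term: str | None = None,
    planted_genes: list[str] | None = None,
) -> dict[str, set[str]]:
    """Random gene -> GO-term annotation, optionally with one planted term.

    Terms ``GO:SYN0001..`` annotate Poisson-sized random gene subsets; when
    ``planted_term``/``planted_genes`` are given that term annotates exactly
    those genes, letting enrichment recovery be checked against truth.
    """
    rng = np.random.default_rng(seed)
    annotation: dict[str, set[str]] = {g: set() for g in gene_ids}
    genes = np.array(gene_ids, dtype=object)
    for t in range(n_terms):
        term = f"GO:SYN{t + 1:04d}"
        size = max(1, int(rng.poisson(mean_genes_per_term)))
        size = min(size, len(genes))
        for g in rng.choice(genes, size=size, replace=False):
            annotation[g].add(term)
    if planted_term is not None:
        for g in planted_genes or []:
            annotation[g].add(planted_term)
    return annotation
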