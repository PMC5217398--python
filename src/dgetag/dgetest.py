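"""TPM normalization, the Audic-Claverie test, DE calling and set decomposition.

For two libraries with clean-tag totals N1 and N2 and per-gene tag counts x
and y, Audic & Claverie's exact statistic is built on the conditional
probability of observing y tags in library 2 given x in library 1 (flat
prior on the unknown transcription rate):

    p(y|x) = (N2/N1)^y * (x+y)! / ( x! * y! * (1 + N2/N1)^(x+y+1) )

which is algebraically the conditional-binomial / negative-binomial form
C(x+y, y) * q^y * (1-q)^(x+1) with q = N2/(N1+N2).  The one-sided tail sums
p(k|x) over k >= y when y/N2 >= x/N1 and over k <= y otherwise (the observed
point included in its tail); the two-sided p-value is min(1, 2 * tail).  All
arithmetic is in log space (log-gamma), so overflow is impossible by
construction.

Differential transcription is declared at FDR < 0.001 (Benjamini-Hochberg
over the genes with x + y > 0) together with |log2 ratio| >= 1 on TPM
(tags per million clean tags).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "tpm_normalize",
    "audic_claverie_p",
    "Contrast",
    "call_de",
    "VennDecomposition",
    "venn_decompose",
    "ddct_relative_expression",
]

DEFAULT_FDR_THRESHOLD = 0.001
DEFAULT_LFC_THRESHOLD = 1.0
DEFAULT_ZERO_FLOOR = 0.5


def tpm_normalize(count, clean_total):
    """Tags per million clean tags: count / clean_total * 1e6.

    This is the SAGE/DGE library-size normalization, not the modern
    transcript-length-aware TPM.
    """
    count = np.asarray(count, dtype=float)
    if np.any(count < 0):
        raise ValueError("counts must be non-negative")
    if clean_total < 1:
        raise ValueError("clean_total must be >= 1")
    result = count / clean_total * 1e6
    return float(result) if result.ndim == 0 else result


def _log_pmf_start(y: int, x: int, log_q: float, log_1mq: float) -> float:
    # log p(y|x) via log-gamma
    return (
        gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        + y * log_q
        + (x + 1) * log_1mq
    )


def _logsumexp(terms: list[float]) -> float:
    m = max(terms)
    if m == -math.inf:
        return -math.inf
    return m + math.log(math.fsum(math.exp(t - m) for t in terms))


def _lower_tail_log(x: int, y: int, log_q: float, log_1mq: float) -> float:
    # sum_{k=0..y} p(k|x); term ratio p(k)/p(k-1) = q*(x+k)/k
    lt = (x + 1) * log_1mq
    terms = [lt]
    for k in range(1, y + 1):
        lt += log_q + math.log(x + k) - math.log(k)
        terms.append(lt)
    return _logsumexp(terms)

def _upper_tail_log(x: int, y: int, log_q: float, log_1mq: float) -> float:
    # sum_{k>=y} p(k|x); entered only when y/N2 >= x/N1, i.e. at or above the
    # mode, where terms decrease and the series is dominated geometrically.
    lt = _log_pmf_start(y, x, log_q, log_1mq)
    terms = [lt]
    peak = lt
    k = y
    while True:
        k += 1
        lt += log_q + math.log(x + k) - math.log(k)
        peak = max(peak, lt)
        terms.append(lt)
        if lt < peak - 45.0:  # remaining geometric tail < 1e-19 of the sum
            break
    return _logsumexp(terms)


def audic_claverie_p(x: int, N1: int, y: int, N2: int) -> float:
    """Two-sided Audic-Claverie p-value for counts x (total N1) vs y (total N2).

    Exact tail summation of the conditional distribution in log space; the
    observed point is included in its tail and the two-sided value is
    min(1, 2 * one-sided tail).
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if N1 < 1 or N2 < 1:
        raise ValueError("library totals must be >= 1")
    q = N2 / (N1 + N2)
    log_q = math.log(q)
    log_1mq = math.log1p(-q)
    if y * N1 >= x * N2:  # observed rate in library 2 at or above library 1
        tail = _upper_tail_log(x, y, log_q, log_1mq)
    else:
        tail = _lower_tail_log(x, y, log_q, log_1mq)
    return min(1.0, 2.0 * math.exp(tail))


@dataclass(frozen=True)
class Contrast:
    """A two-library comparison: a is the reference (e.g. CK), b the treatment."""

    library_a: str
    library_b: str
    label: str = ""

    def name(self) -> str:
        return self.label or f"{self.library_b}_vs_{self.library_a}"


def call_de(
    contrast: Contrast,
    matrix,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    zero_floor: float = DEFAULT_ZERO_FLOOR,
) -> pd.DataFrame:
    """Per-gene differential-expression table for one contrast.

    Genes with x + y = 0 are untestable and excluded from both the table and
    the Benjamini-Hochberg family.  The log2 ratio is computed on TPM; a
    zero count is floored at ``zero_floor`` tags *for the ratio only* (the
    p-value always uses the raw integers), keeping the ratio finite while
    the test stays exact.

    Returns a frame with columns gene, x, y, tpm_a, tpm_b, log2_ratio,
    p_value, fdr and call (``up``/``down``/``ns``), sorted by gene id.
    """
    for lib in (contrast.library_a, contrast.library_b):
        if lib not in matrix.counts.columns:
            raise KeyError(f"library {lib!r} not present in count matrix")
    N1 = int(matrix.clean_totals[contrast.library_a])
    N2 = int(matrix.clean_totals[contrast.library_b])
    if N1 < 1 or N2 < 1:
        raise ValueError("clean totals must be >= 1")
    x = matrix.counts[contrast.library_a]
    y = matrix.counts[contrast.library_b]
    tested = (x + y) > 0
    genes = matrix.counts.index[tested]
    xv = x[tested].to_numpy()
    yv = y[tested].to_numpy()
    p_values = np.array([audic_claverie_p(int(a), N1, int(b), N2) for a, b in zip(xv, yv)])
    fdr = multipletests(p_values, method="fdr_bh")[1] if len(p_values) else np.array([])
    tpm_a = tpm_normalize(xv, N1)
    tpm_b = tpm_normalize(yv, N2)
    x_eff = np.where(xv == 0, zero_floor, xv)
    y_eff = np.where(yv == 0, zero_floor, yv)
    log2_ratio = np.log2((y_eff / N2) / (x_eff / N1))
    call = np.full(len(genes), "ns", dtype=object)
    call[(fdr < fdr_threshold) & (log2_ratio >= lfc_threshold)] = "up"
    call[(fdr < fdr_threshold) & (log2_ratio <= -lfc_threshold)] = "down"
    out = pd.DataFrame(
        {
            "gene": genes,
            "x": xv,
            "y": yv,
            "tpm_a": tpm_a,
            "tpm_b": tpm_b,
            "log2_ratio": log2_ratio,
            "p_value": p_values,
            "fdr": fdr,
            "call": call,
        }
    ).sort_values("gene", ignore_index=True)
    out.attrs["contrast"] = contrast.name()
    out.attrs["N1"] = N1
    out.attrs["N2"] = N2
    return out


def de_sets(de_table: pd.DataFrame) -> tuple[set[str], set[str]]:
    """(up, down) gene-id sets of a DE table."""
    up = set(de_table.loc[de_table["call"] == "up", "gene"])
    down = set(de_table.loc[de_table["call"] == "down", "gene"])
    return up, down


@dataclass
class VennDecomposition:
    """Disjoint partition of DE genes across two stress durations.

    The eight sets partition the union of genes called at either time point:
    concordant at both times (common_up / common_down), sign-reversing
    (up_then_down / down_then_up), and time-point-specific sets.
    """

    common_up: set[str]
    common_down: set[str]
    up_then_down: set[str]
    down_then_up: set[str]
    only_t1_up: set[str]
    only_t1_down: set[str]
    only_t2_up: set[str]
    only_t2_down: set[str]

    _FIELDS = (
        "common_up",
        "common_down",
        "up_then_down",
        "down_then_up",
        "only_t1_up",
        "only_t1_down",
        "only_t2_up",
        "only_t2_down",
    )

    def sets(self) -> dict[str, set[str]]:
        return {f: getattr(self, f) for f in self._FIELDS}

    def counts(self) -> dict[str, int]:
        return {f: len(s) for f, s in self.sets().items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"set": f, "n_genes": len(s), "genes": ";".join(sorted(s))}
                for f, s in self.sets().items()
            ]
        )


def venn_decompose(de_t1: pd.DataFrame, de_t2: pd.DataFrame) -> VennDecomposition:
    """Partition DE calls of two time points into the eight disjoint classes."""
    up1, down1 = de_sets(de_t1)
    up2, down2 = de_sets(de_t2)
    return VennDecomposition(
        common_up=up1 & up2,
        common_down=down1 & down2,
        up_then_down=up1 & down2,
        down_then_up=down1 & up2,
        only_t1_up=up1 - up2 - down2,
        only_t1_down=down1 - up2 - down2,
        only_t2_up=up2 - up1 - down1,
        only_t2_down=down2 - up1 - down1,
    )


def ddct_relative_expression(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """qRT-PCR fold change by the 2^-ddCt method.

    dCt = Ct(target) - Ct(reference gene) within each sample; ddCt is the
    sample dCt minus the calibrator dCt; the fold change is 2**-ddCt.
    """
    for v in (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_calibrator - ct_ref_calibrator)
    return 2.0 ** (-ddct)
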