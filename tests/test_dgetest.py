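"""Audic-Claverie test, DE calling, Venn decomposition and the ddCt helper."""

import math
from math import comb

import numpy as np
import pandas as pd
import pytest

from dgetag import (
    Contrast,
    CountMatrix,
    audic_claverie_p,
    call_de,
    ddct_relative_expression,
    tpm_normalize,
    venn_decompose,
)
from dgetag.dgetest import de_sets


# --- independent oracle: conditional-binomial form, term-by-term ---------

def oracle_pmf(k: int, x: int, N1: int, N2: int) -> float:
    q = N2 / (N1 + N2)
    return comb(x + k, k) * q**k * (1 - q) ** (x + 1)


def oracle_p(x: int, N1: int, y: int, N2: int) -> float:
    if y * N1 >= x * N2:
        total, k = 0.0, y
        while True:
            term = oracle_pmf(k, x, N1, N2)
            total += term
            k += 1
            if term < 1e-18 and k > y + x + 10:
                break
    else:
        total = sum(oracle_pmf(k, x, N1, N2) for k in range(y + 1))
    return min(1.0, 2.0 * total)


def test_tpm_examples():
    assert tpm_normalize(100, 10**6) == 100.0
    assert tpm_normalize(0, 12345) == 0.0
    assert tpm_normalize(57, 5943058) == pytest.approx(57 / 5943058 * 1e6)
    with pytest.raises(ValueError):
        tpm_normalize(-1, 100)


def test_ac_zero_zero_equal_totals():
    # p(0|0) = 0.5 and the upper tail from 0 is the whole mass
    assert audic_claverie_p(0, 10**5, 0, 10**5) == 1.0


def test_ac_matches_oracle_small_grid():
    for N1, N2 in ((10**5, 10**5), (10**5, 2 * 10**5)):
        for x in range(0, 21, 4):
            for y in range(0, 21, 4):
                impl = audic_claverie_p(x, N1, y, N2)
                assert impl == pytest.approx(oracle_p(x, N1, y, N2), abs=1e-9)


def test_ac_distribution_normalizes():
    for x in (0, 1, 10, 100):
        for N1, N2 in ((10**5, 10**5), (10**5, 3 * 10**5)):
            total = 0.0
            k = 0
            while True:
                term = oracle_pmf(k, x, N1, N2)
                total += term
                k += 1
                if term < 1e-16 and k > 4 * (x + 1):
                    break
            assert total == pytest.approx(1.0, abs=1e-9)


def test_ac_exchange_mirrors_tails():
    """Swapping the libraries mirrors the tail construction.

    The conditional distribution is conditioned on one library, so the
    point-included tails of the swapped call are not algebraically identical;
    they agree within the discreteness of the distribution (a bounded factor),
    and equal-count cases are exactly symmetric.
    """
    for x in (0, 3, 25):
        assert audic_claverie_p(x, 10**5, x, 10**5) == audic_claverie_p(x, 10**5, x, 10**5)
    for x, y in ((5, 20), (20, 80), (40, 90), (100, 150)):
        p1 = audic_claverie_p(x, 10**5, y, 10**5)
        p2 = audic_claverie_p(y, 10**5, x, 10**5)
        assert 0.3 < p1 / p2 < 3.0


def _matrix(x, y, N1, N2):
    genes = [f"g{i}" for i in range(len(x))]
    return CountMatrix(
        counts=pd.DataFrame({"A": x, "B": y}, index=genes),
        clean_totals=pd.Series({"A": N1, "B": N2}),
    )


def test_equal_counts_never_called():
    x = [10, 100, 0, 7]
    m = _matrix(x, x, 10**5, 10**5)
    table = call_de(Contrast("A", "B"), m)
    assert len(table) == 3  # the all-zero gene is excluded from the family
    assert set(table["call"]) == {"ns"}
    assert (table["log2_ratio"] == 0).all()


def test_zero_versus_many_called_up():
    m = _matrix([0, 50], [64, 50], 10**5, 10**5)
    table = call_de(Contrast("A", "B"), m).set_index("gene")
    row = table.loc["g0"]
    assert row["p_value"] == pytest.approx(oracle_p(0, 10**5, 64, 10**5), abs=1e-12)
    # ratio uses the 0.5-tag floor for the zero side: log2(64/0.5) = 7
    assert row["log2_ratio"] == pytest.approx(7.0)
    assert row["call"] == "up"


def test_exchange_flips_every_call_sign():
    rng = np.random.default_rng(5)
    x = rng.poisson(60, size=300)
    x[:30] = rng.poisson(240, size=30)  # strong up genes
    y = rng.poisson(60, size=300)
    m_ab = _matrix(x, y, 2 * 10**5, 2 * 10**5)
    m_ba = _matrix(y, x, 2 * 10**5, 2 * 10**5)
    t_ab = call_de(Contrast("A", "B"), m_ab)
    t_ba = call_de(Contrast("A", "B"), m_ba)
    np.testing.assert_allclose(t_ab["log2_ratio"], -t_ba["log2_ratio"])
    flip = {"up": "down", "down": "up", "ns": "ns"}
    assert list(t_ab["call"].map(flip)) == list(t_ba["call"])


def test_tpm_column_identity(transcripts):
    x = np.arange(1, 51)
    m = _matrix(x, x[::-1], 10**5, 2 * 10**5)
    table = call_de(Contrast("A", "B"), m)
    assert table["tpm_a"].sum() == pytest.approx(x.sum() / 10**5 * 1e6)
    assert table["tpm_b"].sum() == pytest.approx(x.sum() / (2 * 10**5) * 1e6)


def test_null_simulation_type_i_error_single_run():
    """One null run: fraction of genes with p < 0.05 within 3 binomial SE."""
    rng = np.random.default_rng(77)
    n_genes, depth = 2000, 2 * 10**5
    abundance = np.full(n_genes, 1 / n_genes)
    x = rng.multinomial(depth, abundance)
    y = rng.multinomial(depth, abundance)
    m = _matrix(x, y, depth, depth)
    table = call_de(Contrast("A", "B"), m)
    frac = (table["p_value"] < 0.05).mean()
    se = math.sqrt(0.05 * 0.95 / len(table))
    assert abs(frac - 0.05) < 3 * se
    assert (table["call"] != "ns").sum() <= 2


def test_bh_family_excludes_all_zero_genes():
    m = _matrix([0, 0, 30], [0, 40, 0], 10**5, 10**5)
    table = call_de(Contrast("A", "B"), m)
    assert set(table["gene"]) == {"g1", "g2"}
    # BH over two tests only
    p_sorted = np.sort(table["p_value"].to_numpy())
    expected = np.minimum.accumulate((p_sorted * 2 / np.arange(1, 3))[::-1])[::-1]
    np.testing.assert_allclose(np.sort(table["fdr"].to_numpy()), np.minimum(expected, 1))


def test_missing_library_rejected():
    m = _matrix([1], [2], 10, 10)
    with pytest.raises(KeyError):
        call_de(Contrast("A", "Z"), m)


# --- Venn decomposition --------------------------------------------------

def _de_frame(up, down, universe):
    call = ["up" if g in up else "down" if g in down else "ns" for g in universe]
    return pd.DataFrame({"gene": list(universe), "call": call})


def test_venn_trivial_examples():
    uni = list("abcdef")
    v = venn_decompose(_de_frame({"a", "b"}, set(), uni), _de_frame({"b", "c"}, set(), uni))
    assert v.common_up == {"b"}
    assert v.only_t1_up == {"a"}
    assert v.only_t2_up == {"c"}
    v2 = venn_decompose(_de_frame({"d"}, set(), uni), _de_frame(set(), {"d"}, uni))
    assert v2.up_then_down == {"d"}


def test_venn_matches_per_gene_case_analysis():
    rng = np.random.default_rng(123)
    genes = [f"g{i}" for i in range(200)]
    s1 = rng.choice(["up", "down", "ns"], size=200, p=[0.2, 0.2, 0.6])
    s2 = rng.choice(["up", "down", "ns"], size=200, p=[0.2, 0.2, 0.6])
    t1 = pd.DataFrame({"gene": genes, "call": s1})
    t2 = pd.DataFrame({"gene": genes, "call": s2})
    v = venn_decompose(t1, t2)
    expected = {name: set() for name in v.sets()}
    for g, a, b in zip(genes, s1, s2):
        if a == "up" and b == "up":
            expected["common_up"].add(g)
        elif a == "down" and b == "down":
            expected["common_down"].add(g)
        elif a == "up" and b == "down":
            expected["up_then_down"].add(g)
        elif a == "down" and b == "up":
            expected["down_then_up"].add(g)
        elif a == "up":
            expected["only_t1_up"].add(g)
        elif a == "down":
            expected["only_t1_down"].add(g)
        elif b == "up":
            expected["only_t2_up"].add(g)
        elif b == "down":
            expected["only_t2_down"].add(g)
    assert v.sets() == expected
    # disjoint cover of the DE union
    sets = list(v.sets().values())
    union = set().union(*sets)
    assert sum(len(s) for s in sets) == len(union)
    assert union == {g for g, a, b in zip(genes, s1, s2) if a != "ns" or b != "ns"}


# --- qRT-PCR helper ------------------------------------------------------

def test_ddct_examples():
    assert ddct_relative_expression(5, 3, 7, 5) == pytest.approx(1.0)
    assert ddct_relative_expression(4, 3, 7, 5) == pytest.approx(2.0)
    assert ddct_relative_expression(8.32, 3.0, 7.0, 5.0) == pytest.approx(2**-3.32)
    assert 2**-3.32 == pytest.approx(0.1, abs=0.001)
    with pytest.raises(ValueError):
        ddct_relative_expression(float("nan"), 1, 1, 1)
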