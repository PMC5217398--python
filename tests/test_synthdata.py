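"""Generator determinism, scenario construction and noise-channel accounting."""

import math

import numpy as np
import pytest

from dgetag import (
    DEFAULT_ADAPTOR,
    NoiseProfile,
    TranscriptSet,
    clean_tags,
    extract_virtual_tags,
    generate_transcriptome,
    make_de_scenario,
    map_library,
    simulate_tag_library,
)
from dgetag.refindex import _scan_sites
from dgetag.synthdata import _three_prime_tags


def test_every_gene_has_valid_site_by_naive_scan():
    ts = generate_transcriptome(50, seed=3)
    for _, seq in ts:
        hits = [
            i
            for i in range(len(seq) - 20)
            if seq[i : i + 4] == "CATG" and "N" not in seq[i : i + 21]
        ]
        assert hits, "every synthetic transcript must host >=1 valid tag site"


def test_transcriptome_deterministic_fasta(tmp_path):
    a, b = tmp_path / "a.fasta", tmp_path / "b.fasta"
    generate_transcriptome(100, seed=7).to_fasta(a)
    generate_transcriptome(100, seed=7).to_fasta(b)
    assert a.read_bytes() == b.read_bytes()


def test_transcriptome_rejects_too_short_range():
    with pytest.raises(ValueError):
        generate_transcriptome(5, length_range=(20, 24), seed=0)


def test_forced_single_gene_fixture_tag():
    ts = TranscriptSet({"g1": "AACATG" + "T" * 17 + "GG"})
    idx = extract_virtual_tags(ts)
    assert list(idx.tag_to_genes) == ["CATG" + "T" * 17]


def test_null_scenario_shares_abundance(transcripts):
    sc = make_de_scenario(transcripts, frac_de=0.0, log2fc_magnitude=1.0, seed=1)
    assert set(sc.de_labels) == {"null"}
    np.testing.assert_array_equal(sc.baseline_abundance, sc.treated_abundance)


def test_planted_fold_change_before_renormalization(transcripts):
    sc = make_de_scenario(transcripts, frac_de=0.1, log2fc_magnitude=2.0, seed=2)
    raw_b = sc.baseline_abundance * np.exp2(sc.condition_log2fc)
    up = sc.de_labels == "up"
    np.testing.assert_allclose(raw_b[up] / sc.baseline_abundance[up], 4.0)
    down = sc.de_labels == "down"
    np.testing.assert_allclose(raw_b[down] / sc.baseline_abundance[down], 0.25)
    n_de = int((sc.de_labels != "null").sum())
    assert n_de == round(0.1 * len(transcripts))
    assert abs(int(up.sum()) - int(down.sum())) <= 1


def test_scenario_deterministic(transcripts):
    a = make_de_scenario(transcripts, 0.2, 1.5, seed=9)
    b = make_de_scenario(transcripts, 0.2, 1.5, seed=9)
    assert a.to_frame().equals(b.to_frame())


def test_noise_profile_validation():
    with pytest.raises(ValueError):
        NoiseProfile(per_base_error_rate=0.3)
    with pytest.raises(ValueError):
        NoiseProfile(adaptor_fraction=0.6, empty_fraction=0.6)


def test_noise_free_single_gene_emits_three_prime_tag():
    seq = "CATG" + "A" * 17 + "CC" + "CATG" + "C" * 17 + "TT"
    ts = TranscriptSet({"g1": seq})
    reads, manifest = simulate_tag_library(
        ts, np.array([1.0]), depth=10, noise=NoiseProfile(seed=0)
    )
    assert reads == ["CATG" + "C" * 17] * 10  # 3'-most site wins
    assert manifest.true_counts["g1"] == 10


def test_all_adaptor_noise_gives_zero_clean(transcripts, scenario):
    noise = NoiseProfile(adaptor_fraction=1.0, seed=1)
    reads, manifest = simulate_tag_library(
        transcripts, scenario.baseline_abundance, depth=200, noise=noise
    )
    assert manifest.n_informative == 0
    lib = clean_tags(reads, adaptor=DEFAULT_ADAPTOR)
    assert lib.total_clean == 0
    assert lib.filter_stats["adaptor"] == 200


def test_positive_abundance_without_site_rejected():
    ts = TranscriptSet({"g1": "CATG" + "C" * 17, "g2": "T" * 30})
    with pytest.raises(ValueError, match="no valid CATG site"):
        simulate_tag_library(ts, np.array([0.5, 0.5]), 10, NoiseProfile(seed=0))
    # zero abundance for the siteless gene is fine
    simulate_tag_library(ts, np.array([1.0, 0.0]), 10, NoiseProfile(seed=0))


def test_manifest_conservation_and_determinism(transcripts, scenario):
    noise = NoiseProfile(
        per_base_error_rate=0.01,
        adaptor_fraction=0.05,
        empty_fraction=0.02,
        ambiguous_base_fraction=0.02,
        length_anomaly_fraction=0.02,
        seed=17,
    )
    reads, manifest = simulate_tag_library(
        transcripts, scenario.baseline_abundance, depth=5000, noise=noise
    )
    assert len(reads) == 5000
    assert manifest.n_informative + manifest.n_junk == 5000
    assert manifest.true_counts.sum() == manifest.n_informative
    reads2, manifest2 = simulate_tag_library(
        transcripts, scenario.baseline_abundance, depth=5000, noise=noise
    )
    assert reads == reads2
    assert manifest.reads.equals(manifest2.reads)


def test_noise_free_counts_recovered_exactly(transcripts, index, scenario):
    """With all noise off, downstream clean+map counts equal manifest truth."""
    reads, manifest = simulate_tag_library(
        transcripts, scenario.baseline_abundance, depth=20000, noise=NoiseProfile(seed=4)
    )
    lib = clean_tags(reads, adaptor=DEFAULT_ADAPTOR)
    # depth >> genes: every expressed gene has copy number >= 2
    assert lib.total_clean == manifest.n_informative
    mapped = map_library(lib, index)
    truth = manifest.true_counts
    # only genes whose 3'-most tag is gene-unique are recovered verbatim;
    # this transcriptome has no shared tags, so recovery is exact
    for gene, count in truth.items():
        assert mapped.gene_counts.get(gene, 0) == count


def test_per_base_error_rate_matches_binomial_oracle(transcripts, scenario):
    e = 0.005
    depth = 30000
    noise = NoiseProfile(per_base_error_rate=e, seed=23)
    reads, manifest = simulate_tag_library(
        transcripts, scenario.baseline_abundance, depth=depth, noise=noise
    )
    inf = manifest.reads[manifest.reads["read_class"] == "informative"]
    changed = (inf["read_seq"] != inf["true_tag"]).mean()
    expected = 1 - (1 - e) ** 21
    se = math.sqrt(expected * (1 - expected) / len(inf))
    assert abs(changed - expected) < 3 * se


def test_three_prime_tag_is_largest_offset(transcripts):
    best, all_sites = _three_prime_tags(transcripts)
    for gene, sites in all_sites.items():
        assert best[gene] == max(sites, key=lambda s: s[0])[1]
        assert sites == sorted(sites), "scan order is 5'->3'"


def test_leaky_sites_emit_non_three_prime_tags():
    seq = "CATG" + "A" * 17 + "CC" + "CATG" + "C" * 17
    ts = TranscriptSet({"g1": seq})
    reads, _ = simulate_tag_library(
        ts, np.array([1.0]), depth=2000, noise=NoiseProfile(seed=2), leaky_site_rate=0.3
    )
    non3 = sum(r == "CATG" + "A" * 17 for r in reads)
    assert 0 < non3 < 2000
    assert abs(non3 / 2000 - 0.3) < 0.05
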