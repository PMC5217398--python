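"""End-to-end orchestration: config-driven runs over synthetic or user data.

A run reproduces the full tag-profiling analysis: reference transcripts ->
virtual tag index -> per-library cleaning -> tag-to-gene mapping -> count
matrix -> per-contrast differential-expression tables -> time-point Venn
decomposition -> GO enrichment, writing TSV artifacts plus a plain-text
summary and a manifest of output hashes.  All randomness flows from the
single config seed, so a run is deterministic: the same config and seed
produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dgetest, goenrich, refindex, synthdata, tagmap, tagprep

logger = logging.getLogger("dgetag")

__all__ = ["ConfigError", "RunConfig", "run"]

_CONDITIONS = ("baseline", "treated_t1", "treated_t2")


class ConfigError(ValueError):
    """A run configuration failed validation."""


@dataclass
class LibrarySpec:
    library_id: str
    depth: int = 0
    condition: str = "baseline"
    reads_path: str | None = None


@dataclass
class RunConfig:
    """Validated run configuration (see ``demo_config`` for the shape)."""

    seed: int = 0
    adaptor: str = synthdata.DEFAULT_ADAPTOR
    reference_fasta: str | None = None
    synthetic_reference: dict = field(default_factory=dict)
    scenario: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    libraries: list[LibrarySpec] = field(default_factory=list)
    contrasts: list[dict] = field(default_factory=list)
    venn: list[dict] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)
    saturation_fractions: tuple[float, ...] = ()

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        ref = raw.get("reference", {})
        libs = [
            LibrarySpec(
                library_id=str(spec["id"]),
                depth=int(spec.get("depth", 0)),
                condition=spec.get("condition", "baseline"),
                reads_path=spec.get("reads"),
            )
            for spec in raw.get("libraries", [])
        ]
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            adaptor=raw.get("adaptor", synthdata.DEFAULT_ADAPTOR),
            reference_fasta=ref.get("fasta"),
            synthetic_reference=ref.get("synthetic", {}),
            scenario=raw.get("scenario", {}),
            noise=raw.get("noise", {}),
            libraries=libs,
            contrasts=list(raw.get("contrasts", [])),
            venn=list(raw.get("venn", [])),
            thresholds=dict(raw.get("thresholds", {})),
            enrichment=dict(raw.get("enrichment", {})),
            saturation_fractions=tuple(raw.get("saturation", {}).get("fractions", ())),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def validate(self) -> None:
        if not self.libraries:
            raise ConfigError("no libraries configured")
        ids = [l.library_id for l in self.libraries]
        if len(set(ids)) != len(ids):
            raise ConfigError(f"duplicate library ids: {ids}")
        if self.reference_fasta is None and not self.synthetic_reference:
            raise ConfigError("a reference (fasta or synthetic) is required")
        for lib in self.libraries:
            if lib.reads_path is None:
                if lib.depth < 1:
                    raise ConfigError(
                        f"synthetic library {lib.library_id!r} needs a positive depth"
                    )
                if lib.condition not in _CONDITIONS:
                    raise ConfigError(
                        f"library {lib.library_id!r}: unknown condition {lib.condition!r} "
                        f"(expected one of {_CONDITIONS})"
                    )
        known = set(ids)
        labels = set()
        for c in self.contrasts:
            for end in ("a", "b"):
                if c.get(end) not in known:
                    raise ConfigError(
                        f"contrast endpoint {c.get(end)!r} is not a configured library"
                    )
            labels.add(c.get("label") or f"{c['b']}_vs_{c['a']}")
        for v in self.venn:
            for end in ("t1", "t2"):
                if v.get(end) not in labels:
                    raise ConfigError(
                        f"venn endpoint {v.get(end)!r} is not a configured contrast label"
                    )
        for key, value in self.thresholds.items():
            if not value > 0:
                raise ConfigError(f"threshold {key!r} must be positive")


def demo_config(n_genes: int = 200, depth: int = 20000, seed: int = 7) -> dict:
    """The bundled demo: a 200-gene scenario, 6 libraries (2 genotypes x 3 time points)."""
    libs = []
    for genotype in ("JN", "SR"):
        for cond, tp in (("baseline", "CK"), ("treated_t1", "05"), ("treated_t2", "24")):
            libs.append({"id": f"{genotype}{tp}", "condition": cond, "depth": depth})
    contrasts = [
        {"a": "JNCK", "b": "JN05", "label": "JN_t1"},
        {"a": "JNCK", "b": "JN24", "label": "JN_t2"},
        {"a": "SRCK", "b": "SR05", "label": "SR_t1"},
        {"a": "SRCK", "b": "SR24", "label": "SR_t2"},
    ]
    return {
        "seed": seed,
        "reference": {"synthetic": {"n_genes": n_genes, "length_range": [200, 600]}},
        "scenario": {"frac_de": 0.1, "log2fc_magnitude": 2.0, "abundance_sigma": 1.0},
        "noise": {
            "per_base_error_rate": 0.005,
            "adaptor_fraction": 0.02,
            "empty_fraction": 0.01,
            "ambiguous_base_fraction": 0.01,
            "length_anomaly_fraction": 0.01,
        },
        "libraries": libs,
        "contrasts": contrasts,
        "venn": [
            {"t1": "JN_t1", "t2": "JN_t2", "label": "JN"},
            {"t1": "SR_t1", "t2": "SR_t2", "label": "SR"},
        ],
        "thresholds": {"fdr": 0.001, "lfc": 1.0, "go_p": 0.01, "go_fdr": 0.05},
        "enrichment": {"synthetic": {"n_terms": 40, "mean_genes_per_term": 25}},
        "saturation": {"fractions": [0.2, 0.4, 0.6, 0.8, 1.0]},
    }


def _child_seed(root_seed: int, index: int) -> int:
    """Deterministic per-stage seed derived from (run seed, stage index)."""
    return int(np.random.SeedSequence([root_seed, index]).generate_state(1)[0] % (2**31))


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run(config: RunConfig, outdir) -> dict:
    """Execute all stages and write artifacts into ``outdir``.

    Returns a report dict with per-stage key numbers (also written as
    ``summary.txt``) and the paths of every artifact.  Raises
    :class:`ConfigError` on an invalid configuration; any stage error
    propagates with the stage recorded in the log.
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.monotonic()
    root_seed = config.seed
    report: dict = {"seed": config.seed, "stages": {}}

    # --- reference ------------------------------------------------------
    if config.reference_fasta:
        transcripts = refindex.TranscriptSet.from_fasta(config.reference_fasta)
    else:
        syn = config.synthetic_reference
        transcripts = synthdata.generate_transcriptome(
            n_genes=int(syn.get("n_genes", 200)),
            length_range=tuple(syn.get("length_range", (200, 600))),
            seed=_child_seed(root_seed, 0),
        )
    transcripts.to_fasta(out / "transcripts.fasta")
    logger.info("stage reference: %d transcripts", len(transcripts))

    # --- index ----------------------------------------------------------
    index = refindex.extract_virtual_tags(transcripts)
    index.to_tsv(out / "index.tsv")
    report["stages"]["index"] = index.summary()
    logger.info("stage index: %s", index.summary())

    # --- scenarios (synthetic libraries only) ---------------------------
    scenarios: dict[str, synthdata.ExpressionScenario] = {}
    any_synthetic = any(l.reads_path is None for l in config.libraries)
    if any_synthetic:
        sc = config.scenario
        s_t1 = synthdata.make_de_scenario(
            transcripts,
            frac_de=float(sc.get("frac_de", 0.1)),
            log2fc_magnitude=float(sc.get("log2fc_magnitude", 2.0)),
            seed=_child_seed(root_seed, 1),
            abundance_sigma=float(sc.get("abundance_sigma", 1.0)),
        )
        # the late time point shares the baseline but replants DE genes
        s_t2 = synthdata.make_de_scenario(
            transcripts,
            frac_de=float(sc.get("frac_de", 0.1)),
            log2fc_magnitude=float(sc.get("log2fc_magnitude", 2.0)),
            seed=_child_seed(root_seed, 2),
            baseline_abundance=s_t1.baseline_abundance,
        )
        scenarios = {"treated_t1": s_t1, "treated_t2": s_t2}
        s_t1.to_frame().to_csv(out / "scenario_t1.tsv", sep="\t", index=False, float_format="%.6g")
        s_t2.to_frame().to_csv(out / "scenario_t2.tsv", sep="\t", index=False, float_format="%.6g")

    # --- libraries: simulate or load, then clean ------------------------
    libraries: list[tagprep.TagLibrary] = []
    conservation: dict[str, dict] = {}
    for i, spec in enumerate(config.libraries):
        if spec.reads_path is not None:
            if str(spec.reads_path).endswith((".tsv", ".txt")):
                lib = tagprep.TagLibrary.from_counts_tsv(spec.reads_path, spec.library_id)
                libraries.append(lib)
                continue
            reads = list(tagprep.read_sequences(spec.reads_path))
        else:
            if spec.condition == "baseline":
                abundance = scenarios["treated_t1"].baseline_abundance
            else:
                abundance = scenarios[spec.condition].treated_abundance
            noise = synthdata.NoiseProfile(
                per_base_error_rate=float(config.noise.get("per_base_error_rate", 0.0)),
                adaptor_fraction=float(config.noise.get("adaptor_fraction", 0.0)),
                empty_fraction=float(config.noise.get("empty_fraction", 0.0)),
                ambiguous_base_fraction=float(config.noise.get("ambiguous_base_fraction", 0.0)),
                length_anomaly_fraction=float(config.noise.get("length_anomaly_fraction", 0.0)),
                seed=_child_seed(root_seed, 10 + i),
            )
            reads, manifest = synthdata.simulate_tag_library(
                transcripts,
                abundance,
                depth=spec.depth,
                noise=noise,
                library_id=spec.library_id,
                adaptor=config.adaptor,
            )
            synthdata.write_reads_fasta(reads, out / f"reads_{spec.library_id}.fasta", spec.library_id)
            manifest.to_tsv(out / f"manifest_{spec.library_id}.tsv")
            manifest.write_descriptor(out / f"scenario_{spec.library_id}.yaml")
        lib = tagprep.clean_tags(reads, spec.library_id, adaptor=config.adaptor)
        if lib.filter_stats["raw_total"] != lib.total_clean + lib.total_removed:
            raise AssertionError(f"filter accounting broken for {spec.library_id}")
        conservation[spec.library_id] = {"raw_total": lib.filter_stats["raw_total"]}
        lib.to_tsv(out / f"clean_{spec.library_id}.tsv")
        libraries.append(lib)
    filter_stats = pd.DataFrame([lib.stats_row() for lib in libraries])
    _write_tsv(filter_stats, out / "filter_stats.tsv")
    logger.info("stage clean: %d libraries", len(libraries))

    # --- mapping --------------------------------------------------------
    mapped = [tagmap.map_library(lib, index) for lib in libraries]
    for m, lib in zip(mapped, libraries):
        s = m.stats
        if s.unmapped_count + s.ambiguous_count + s.unambiguous_count != s.clean_total:
            raise AssertionError(f"mapping accounting broken for {m.library_id}")
        if m.library_id in conservation:
            conservation[m.library_id].update(
                removed=lib.total_removed,
                unmapped=s.unmapped_count,
                ambiguous=s.ambiguous_count,
                gene_tags=s.unambiguous_count,
            )
    stats_table = tagmap.mapping_stats_table(mapped)
    _write_tsv(stats_table, out / "mapping_stats.tsv")
    genes = sorted(index.genes_with_sites)
    matrix = tagmap.assemble_matrix(mapped, genes=genes)
    matrix.to_tsv(out / "counts.tsv")
    report["stages"]["mapping"] = stats_table.to_dict(orient="records")
    logger.info("stage map: %d genes x %d libraries", len(matrix.genes), len(matrix.libraries))

    # --- saturation (optional) ------------------------------------------
    if config.saturation_fractions:
        for lib in libraries:
            curve = tagprep.saturation_curve(
                lib, index, tuple(config.saturation_fractions), seed=_child_seed(root_seed, 3)
            )
            _write_tsv(curve, out / f"saturation_{lib.library_id}.tsv")

    # --- differential expression ---------------------------------------
    th = config.thresholds
    de_tables: dict[str, pd.DataFrame] = {}
    for c in config.contrasts:
        contrast = dgetest.Contrast(c["a"], c["b"], c.get("label", ""))
        table = dgetest.call_de(
            contrast,
            matrix,
            fdr_threshold=float(th.get("fdr", dgetest.DEFAULT_FDR_THRESHOLD)),
            lfc_threshold=float(th.get("lfc", dgetest.DEFAULT_LFC_THRESHOLD)),
        )
        de_tables[contrast.name()] = table
        _write_tsv(table, out / f"de_{contrast.name()}.tsv")
    report["stages"]["de"] = {
        name: {"up": int((t["call"] == "up").sum()), "down": int((t["call"] == "down").sum())}
        for name, t in de_tables.items()
    }
    logger.info("stage de: %s", report["stages"]["de"])

    # --- venn decomposition ---------------------------------------------
    venn_counts = {}
    for v in config.venn:
        decomposition = dgetest.venn_decompose(de_tables[v["t1"]], de_tables[v["t2"]])
        label = v.get("label") or f"{v['t1']}__{v['t2']}"
        _write_tsv(decomposition.to_frame(), out / f"venn_{label}.tsv")
        venn_counts[label] = decomposition.counts()
    report["stages"]["venn"] = venn_counts

    # --- GO enrichment (optional) ----------------------------------------
    if config.enrichment:
        universe = set(matrix.genes)
        if "annotation" in config.enrichment:
            annotation = goenrich.load_annotation_tsv(config.enrichment["annotation"])
            annotation = {g: t for g, t in annotation.items() if g in universe}
        else:
            syn = config.enrichment.get("synthetic", {})
            planted_genes: list[str] = []
            planted_term = None
            if scenarios:
                planted_term = "GO:PLANTED"
                planted_genes = [
                    g
                    for g, lab in zip(scenarios["treated_t1"].gene_ids, scenarios["treated_t1"].de_labels)
                    if lab == "up" and g in universe
                ]
            annotation = synthdata.make_annotation(
                sorted(universe),
                n_terms=int(syn.get("n_terms", 40)),
                mean_genes_per_term=int(syn.get("mean_genes_per_term", 25)),
                seed=_child_seed(root_seed, 4),
                planted_term=planted_term,
                planted_genes=planted_genes,
            )
        enrich_counts = {}
        for name, table in de_tables.items():
            up, down = dgetest.de_sets(table)
            deg = (up | down) & universe
            result = goenrich.enrich(
                deg,
                annotation,
                universe,
                p_threshold=float(th.get("go_p", 0.01)),
                fdr_threshold=float(th.get("go_fdr", 0.05)),
            )
            _write_tsv(result, out / f"enrichment_{name}.tsv")
            enrich_counts[name] = int(result["enriched"].sum()) if len(result) else 0
        report["stages"]["enrichment"] = enrich_counts

    # --- end-to-end conservation ----------------------------------------
    for lib_id, acc in conservation.items():
        if len(acc) > 1:
            total = acc["removed"] + acc["unmapped"] + acc["ambiguous"] + acc["gene_tags"]
            if total != acc["raw_total"]:
                raise AssertionError(f"end-to-end conservation broken for {lib_id}")
    report["conservation"] = conservation

    # --- summary + manifest ---------------------------------------------
    summary_lines = [
        "dgetag run summary",
        f"seed: {config.seed}",
        f"transcripts: {len(transcripts)}",
        f"index: {json.dumps(index.summary(), sort_keys=True)}",
        "library stats:",
        filter_stats.to_string(index=False),
        "mapping stats:",
        stats_table.to_string(index=False, float_format=lambda v: f"{v:.2f}"),
        "DE calls per contrast:",
        json.dumps(report["stages"]["de"], sort_keys=True),
        "venn decomposition:",
        json.dumps(report["stages"].get("venn", {}), sort_keys=True),
    ]
    (out / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    manifest = {}
    for path in sorted(out.iterdir()):
        if path.name == "manifest.json" or not path.is_file():
            continue
        manifest[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("run finished in %.1f s", time.monotonic() - t0)
    report["artifacts"] = sorted(manifest)
    return report
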