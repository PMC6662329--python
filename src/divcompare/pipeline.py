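"""End-to-end orchestration: inputs (real or simulated) -> statistics ->
report tables shaped like the five panels of the comparative analysis.

A single YAML config drives a run:

.. code-block:: yaml

    seed: 1
    out_dir: results
    scenario: paper_like        # or "null", or omit and give inputs:
    # inputs:
    #   alignment: aln.fasta
    #   genotypes: geno.csv
    #   metadata: meta.csv
    #   partition: pbr.json
    #   frame_offset: 2
    populations: [A, B]         # larger population first
    plan:
      n_conservative_draws: 3
      subsample_size: 11
    selection:
      n_bootstrap: 1000
    hwe_alpha: 0.05

Outputs: ``table1.tsv`` (dN/dS z-tests), ``table2.tsv`` (Tajima's D),
``table3.tsv`` (sequence diversity), ``table4.tsv`` (microsatellite
diversity; ``table4_loci.tsv`` per-locus detail), ``table5.tsv`` (t-tests),
``summary.json`` (full precision) and ``run_manifest.json``.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .codon_selection import pbr_variable_site_tally, selection_z_test
from .io_formats import (
    read_codon_partition,
    read_genotype_csv,
    read_metadata_csv,
    read_phased_fasta,
)
from .msat_stats import hwe_test, locus_qc_filter, missing_and_deficit_warnings
from .sampling_compare import SamplingPlan, compare_populations
from .synthetic_data import (
    ScenarioConfig,
    default_partition,
    generate_scenario,
    null_config,
    paper_like_config,
)
from .tajima_test import tajima_D

FLOAT_FMT = "%.4f"


@dataclass
class RunManifest:
    config_hash: str
    input_digests: dict[str, str]
    package_version: str
    master_seed: int
    timings: dict[str, float] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(cfg: dict, out_dir: Path, seed: int):
    """Load the four inputs, simulating a scenario bundle if requested."""
    digests: dict[str, str] = {}
    if "inputs" in cfg:
        paths = cfg["inputs"]
        frame_offset = int(paths.get("frame_offset", 0))
        alignment = read_phased_fasta(paths["alignment"], frame_offset)
        msat = read_genotype_csv(paths["genotypes"])
        metadata = read_metadata_csv(paths["metadata"])
        n_codons = (alignment.L - frame_offset) // 3
        partition = read_codon_partition(paths["partition"], n_codons)
        # alignment population labels come from metadata in file mode
        pop_of = dict(zip(metadata["id"], metadata["population"]))
        alignment.populations = [
            pop_of.get(i, p)
            for i, p in zip(alignment.individual_ids, alignment.populations)
        ]
        msat.populations = [
            pop_of.get(i, p) for i, p in zip(msat.individuals, msat.populations)
        ]
        for key in ("alignment", "genotypes", "metadata", "partition"):
            digests[key] = _digest(Path(paths[key]))
    else:
        scenario = cfg.get("scenario", "paper_like")
        if scenario == "paper_like":
            scfg = paper_like_config(seed)
        elif scenario in ("null", None):
            scfg = null_config(seed)
        else:
            scfg = ScenarioConfig.from_yaml(scenario)
            scfg.seed = seed
        bundle_dir = out_dir / "simulated_inputs"
        generate_scenario(scfg, bundle_dir)
        alignment = read_phased_fasta(
            bundle_dir / "alignment.fasta", frame_offset=2
        )
        msat = read_genotype_csv(bundle_dir / "genotypes.csv")
        metadata = read_metadata_csv(bundle_dir / "metadata.csv")
        partition = default_partition()
        pop_of = dict(zip(metadata["id"], metadata["population"]))
        alignment.populations = [
            pop_of[i] for i in alignment.individual_ids
        ]
        msat.populations = [pop_of[i] for i in msat.individuals]
        for name in ("alignment.fasta", "genotypes.csv", "metadata.csv"):
            digests[name] = _digest(bundle_dir / name)
    return alignment, msat, metadata, partition, digests


def run_analysis(config_path: str | Path) -> RunManifest:
    """Execute a full comparative run from a YAML config; returns the
    manifest after writing all report files."""
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text())
    seed = int(cfg.get("seed", 0))
    out_dir = Path(cfg.get("out_dir", "results"))
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(config_path.read_bytes()).hexdigest(),
        input_digests={},
        package_version=__version__,
        master_seed=seed,
    )
    t0 = time.perf_counter()
    alignment, msat, metadata, partition, digests = _load_inputs(
        cfg, out_dir, seed
    )
    manifest.input_digests = digests
    manifest.timings["load"] = time.perf_counter() - t0

    pops = cfg.get("populations") or sorted(set(metadata["population"]))
    if len(pops) != 2:
        raise ValueError(f"exactly two populations required, got {pops}")
    pop_a, pop_b = pops

    # --- microsatellite QC: HWE screen + Bonferroni locus filter ---------
    t0 = time.perf_counter()
    hwe_alpha = float(cfg.get("hwe_alpha", 0.05))
    hwe_results = {}
    for pop in pops:
        sub = msat.subset_population(pop)
        for locus in msat.loci:
            try:
                hwe_results[(locus, pop)] = hwe_test(sub, locus)
            except Exception:
                hwe_results[(locus, pop)] = None
    retained, dropped = locus_qc_filter(msat, hwe_results, alpha=hwe_alpha)
    msat_f = msat.subset_loci(retained)
    qc_warnings = missing_and_deficit_warnings(msat_f)
    manifest.timings["msat_qc"] = time.perf_counter() - t0

    # --- selection panel (table 1) ---------------------------------------
    t0 = time.perf_counter()
    n_bootstrap = int(cfg.get("selection", {}).get("n_bootstrap", 1000))
    sel_rows = []
    tallies = {}
    for pop in pops:
        sub = alignment.subset_population(pop)
        for site_class in ("pbr", "nonpbr", "all"):
            r = selection_z_test(
                sub, partition, site_class, n_bootstrap=n_bootstrap, seed=seed
            )
            sel_rows.append(
                {
                    "population": pop,
                    "sites": site_class,
                    "N": r.n_codons,
                    "dN": r.dN,
                    "dN_se": r.dN_se,
                    "dS": r.dS,
                    "dS_se": r.dS_se,
                    "dN_dS": r.ratio,
                    "z": r.z,
                    "p": r.p,
                }
            )
        tallies[pop] = pbr_variable_site_tally(sub, partition)
    table1 = pd.DataFrame(sel_rows)
    manifest.timings["selection"] = time.perf_counter() - t0

    # --- Tajima's D (table 2) --------------------------------------------
    t0 = time.perf_counter()
    taj_rows = []
    for pop in pops:
        sub = alignment.subset_population(pop)
        for flt in ("all", "nonsynonymous"):
            r = tajima_D(sub, flt)
            taj_rows.append(
                {
                    "population": pop,
                    "sites": flt,
                    "n": r.n,
                    "S": r.S_used,
                    "D": r.D,
                    "p": r.p,
                    "significance": r.significance_class,
                }
            )
    table2 = pd.DataFrame(taj_rows)
    manifest.timings["tajima"] = time.perf_counter() - t0

    # --- sampling tiers + comparisons (tables 3-5) ------------------------
    t0 = time.perf_counter()
    plan_cfg = cfg.get("plan", {})
    plan = SamplingPlan(
        n_conservative_draws=int(plan_cfg.get("n_conservative_draws", 3)),
        subsample_size=int(plan_cfg.get("subsample_size", 11)),
        n_subsamples=plan_cfg.get("n_subsamples"),
        seed=seed,
    )
    report = compare_populations(alignment, msat_f, metadata, pop_a, pop_b, plan)
    manifest.timings["compare"] = time.perf_counter() - t0

    # --- write outputs ----------------------------------------------------
    def _write(df: pd.DataFrame, name: str):
        path = out_dir / name
        df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
        manifest.outputs.append(name)

    _write(table1, "table1.tsv")
    _write(table2, "table2.tsv")
    _write(report.seq_table, "table3.tsv")
    _write(report.msat_table, "table4.tsv")
    _write(report.msat_locus_table, "table4_loci.tsv")
    _write(report.t_tests, "table5.tsv")
    _write(report.chi_square, "sex_ratio.tsv")

    summary = {
        "seed": seed,
        "populations": pops,
        "selection": table1.to_dict(orient="records"),
        "tajima": table2.to_dict(orient="records"),
        "seq_diversity": report.seq_table.to_dict(orient="records"),
        "msat_diversity": report.msat_table.to_dict(orient="records"),
        "t_tests": report.t_tests.to_dict(orient="records"),
        "sex_ratio": report.chi_square.to_dict(orient="records"),
        "pbr_variable_site_tally": {
            p: {"in_pbr": t[0], "total": t[1]} for p, t in tallies.items()
        },
        "loci_retained": retained,
        "loci_dropped": dropped,
        "qc_warnings": qc_warnings,
        "sampling_seeds": report.seeds,
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    manifest.outputs.append("summary.json")
    manifest.write(out_dir / "run_manifest.json")
    return manifest
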