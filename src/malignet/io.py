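"""File formats, pipeline configuration, and the end-to-end pipeline.

Readers/writers for the plain-text formats the pipeline consumes
(expression TSV, GMT gene sets, BED peaks, survival/probe/dose CSV) plus
:class:`PipelineConfig` and :func:`run_pipeline`, which executes the
staged analysis simulate -> modules -> upstream -> gsea -> stratify ->
survival -> cna -> synergy on a synthetic cohort and writes per-stage
tables and a resolved run log. All randomness flows from the config
seeds, so re-running an identical config reproduces the bundle
bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cna as cna_mod
from . import coexpnet, enrich, gsea, stratify, survstats, synergy, synthio
from .errors import ConfigurationError, InputError

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "read_bed",
    "PipelineConfig",
    "run_pipeline",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- readers


def read_expression(path) -> pd.DataFrame:
    """Expression TSV: first column gene IDs, header = sample IDs."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise InputError(f"duplicate gene IDs: {dupes}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad][0]
            raise InputError(f"non-numeric value at gene {gene!r}, sample {col!r}")
        df[col] = coerced
    return df


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_gmt(path) -> list[enrich.GeneSet]:
    """GMT gene sets: name, description, then members, tab-separated."""
    sets: list[enrich.GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"GMT parse error at line {lineno}: fewer than 3 fields")
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise InputError(f"GMT parse error at line {lineno}: empty member list")
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                log.info("line %d: deduplicated %d member(s)", lineno, len(members) - len(unique))
            sets.append(enrich.GeneSet(name=name, description=desc, members=frozenset(unique)))
    if not sets:
        log.warning("GMT file %s contains no gene sets", path)
    return sets


def read_bed(path) -> pd.DataFrame:
    """BED3+ peak intervals, 0-based half-open [start, end)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"BED parse error at line {lineno}: fewer than 3 fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise InputError(f"BED parse error at line {lineno}: {exc}") from exc
            if start < 0:
                raise InputError(f"BED parse error at line {lineno}: negative start")
            if end <= start:
                raise InputError(f"BED parse error at line {lineno}: end <= start")
            rows.append((chrom, start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ------------------------------------------------------------ configuration


@dataclass
class PipelineConfig:
    """Stage toggles and parameters of the end-to-end synthetic pipeline."""

    out_dir: str = "results/pipeline"
    simulation: synthio.SimulationConfig = field(default_factory=synthio.SimulationConfig)

    run_modules: bool = True
    run_upstream: bool = True
    run_gsea: bool = True
    run_stratify: bool = True
    run_survival: bool = True
    run_cna: bool = True
    run_synergy: bool = True

    powers: tuple[int, ...] = tuple(range(1, 13))
    target_r2: float = 0.8
    # fixed soft power for network construction (the unsigned-network
    # convention); set to None to use the scale-free criterion's choice
    soft_power: int | None = 6
    cut_height: float = 0.95
    min_module_size: int = 30
    tom_hub_threshold: float = 0.13
    hub_top_n: int = 59

    gsea_permutations: int = 1000
    gsea_weight_p: float = 1.0
    gsea_seed: int = 11

    log2fc_cutoff: float = stratify.DEFAULT_LOG2FC_CUTOFF
    p_cutoff: float = stratify.DEFAULT_P_CUTOFF
    kmeans_seed: int = 13

    cna_penalty: float | None = None
    probe_file: str | None = None

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        if isinstance(data.get("simulation"), dict):
            sim_known = {f.name for f in dataclasses.fields(synthio.SimulationConfig)}
            sim_unknown = set(data["simulation"]) - sim_known
            if sim_unknown:
                raise ConfigurationError(f"unknown simulation keys: {sorted(sim_unknown)}")
            data["simulation"] = synthio.SimulationConfig(**data["simulation"])
        return cls(**data)


# ---------------------------------------------------------------- pipeline


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the staged synthetic analysis and write the report bundle.

    Returns a dict of in-memory stage results; per-stage tables, a truth
    JSON, and a run log with the resolved configuration are written under
    ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    results: dict = {}

    # -- simulate
    expr, truth = synthio.generate_cohort(sim)
    write_expression(expr, out / "expression.tsv")
    truth_json = {
        "activity": {s: float(v) for s, v in truth.activity.items()},
        "module_labels": {g: int(m) for g, m in truth.module_labels.items()},
        "amplified_samples": sorted(truth.amplified_samples),
        "true_ci": truth.true_ci,
    }
    (out / "truth.json").write_text(json.dumps(truth_json, indent=1))
    results["expression"] = expr
    results["truth"] = truth

    assignment = None
    if config.run_modules:
        report = coexpnet.pick_soft_threshold(
            expr, list(config.powers), config.target_r2
        )
        power = config.soft_power if config.soft_power is not None else report.chosen_power
        adj = coexpnet.adjacency_matrix(expr, power)
        tom = coexpnet.topological_overlap(adj)
        assignment = coexpnet.detect_modules(
            tom, config.min_module_size, config.cut_height
        )
        assignment = coexpnet.module_eigengene_and_membership(expr, assignment)
        module_table = pd.DataFrame(
            {"module": assignment.labels, "kME": assignment.membership}
        )
        module_table.to_csv(out / "modules.tsv", sep="\t", index_label="gene")
        results["soft_threshold"] = report
        results["assignment"] = assignment
        results["tom"] = tom

    target_module = None
    network = annotations = None
    if config.run_upstream:
        if assignment is None:
            raise InputError("upstream stage requires the modules stage output")
        network, annotations = synthio.generate_regulator_network(truth, sim)
        target_module = _best_matching_module(assignment, set(network["target"]))
        upstream = enrich.rank_upstream_regulators(
            assignment, target_module, network, annotations
        )
        upstream.to_csv(out / "upstream.tsv", sep="\t")
        hub_edges, hub_rank = coexpnet.hub_network(
            results["tom"], assignment, target_module,
            config.hub_top_n, config.tom_hub_threshold,
        )
        hub_edges.to_csv(out / "hub_edges.tsv", sep="\t", index=False)
        results["upstream"] = upstream
        results["target_module"] = target_module
        results["hub_ranking"] = hub_rank

    if config.run_gsea:
        if assignment is None or target_module is None:
            raise InputError("gsea stage requires the upstream stage output")
        eg = assignment.eigengenes.loc[target_module]
        high = list(eg.index[eg > eg.median()])
        low = [s for s in eg.index if s not in high]
        ranked = gsea.rank_genes(expr, high, low)
        module_set = set(assignment.module_genes(target_module))
        gres = gsea.normalize_and_test(
            ranked, module_set, config.gsea_permutations,
            config.gsea_seed, config.gsea_weight_p,
        )
        (out / "gsea.json").write_text(
            json.dumps(
                {
                    "es": gres.es,
                    "nes": gres.nes,
                    "nominal_p": gres.nominal_p,
                    "fdr_q": gres.fdr_q,
                    "leading_edge_size": len(gres.leading_edge),
                },
                indent=1,
            )
        )
        results["gsea"] = gres

    groups = None
    if config.run_stratify:
        if network is None:
            raise InputError("stratify stage requires the upstream stage output")
        targets = sorted(set(network.loc[network["regulator"] == "REG_TRUE", "target"]))
        act = stratify.activity_score(expr, targets)
        groups = stratify.kmeans_two_groups(act, seed=config.kmeans_seed)
        pd.DataFrame({"activity_score": act.scores, "group": groups}).to_csv(
            out / "groups.csv", index_label="sample_id"
        )
        results["activity"] = act
        results["groups"] = groups

    surv = None
    if config.run_survival:
        if groups is None:
            raise InputError("survival stage requires the stratify stage output")
        surv = synthio.generate_survival(truth.activity, sim)
        surv = surv.set_index("sample_id")
        chi2, p = survstats.logrank_test(
            surv["time"], surv["event"], groups.loc[surv.index]
        )
        surv.to_csv(out / "survival.csv")
        (out / "logrank.json").write_text(
            json.dumps({"chi_square": chi2, "p": p}, indent=1)
        )
        results["survival"] = surv
        results["logrank"] = (chi2, p)

    if config.run_cna:
        if config.probe_file is not None:
            probes = pd.read_csv(config.probe_file)
        else:
            probes = synthio.generate_cna_profiles(sim, truth)
        locus = synthio.amplified_locus(sim)
        calls = {}
        for s in truth.activity.index:
            if s not in probes.columns:
                raise InputError(f"cna stage missing probe column for sample {s}")
            segs = cna_mod.segment_profile(
                probes["pos"], probes[s], penalty=config.cna_penalty
            )
            calls[s] = bool(cna_mod.amplification_call(segs, locus))
        call_series = pd.Series(calls, name="amplified")
        call_series.to_csv(out / "cna_calls.csv", index_label="sample_id")
        results["cna_calls"] = call_series
        if surv is not None:
            chi2, p = survstats.logrank_test(
                surv["time"], surv["event"], call_series.loc[surv.index]
            )
            results["cna_logrank"] = (chi2, p)

    if config.run_synergy:
        singles, combos, true_ci = synthio.generate_dose_response(sim)
        fits = [synergy.fit_median_effect(t["dose"], t["viability"]) for t in singles]
        records = synergy.combination_index(fits[0], fits[1], combos)
        ci_table = pd.DataFrame(
            [
                {
                    "dose_a": r.dose_a,
                    "dose_b": r.dose_b,
                    "fa": r.fa,
                    "ci": r.ci,
                    "classification": r.classification,
                }
                for r in records
            ]
        )
        ci_table.to_csv(out / "combination_index.tsv", sep="\t", index=False)
        results["median_effect_fits"] = fits
        results["ci_records"] = records
        results["true_ci"] = true_ci

    run_log = {
        "config": _config_to_jsonable(config),
        "stages": sorted(k for k in results if not isinstance(results[k], pd.DataFrame)),
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=1, default=str))
    return results


def _best_matching_module(
    assignment: coexpnet.ModuleAssignment, targets: set[str]
) -> int:
    labels = assignment.labels
    modules = sorted(set(labels) - {0})
    if not modules:
        raise InputError("no modules detected")
    overlaps = {
        m: len(targets & set(assignment.module_genes(m))) for m in modules
    }
    return max(modules, key=lambda m: (overlaps[m], -m))


def _config_to_jsonable(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d
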