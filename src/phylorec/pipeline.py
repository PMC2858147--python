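"""End-to-end orchestration: data -> trees -> tests -> scans -> reports.

A :class:`RunConfig` (usually parsed from a YAML file) describes the inputs,
the analyses to run and their parameters.  :func:`run_full_analysis` executes
the stages in a fixed order — assembly, optional column filter, concatenation,
NJ trees, GCPSR, the three recombination tests per configured group, border
scans, and population statistics — writing one TSV and/or JSON per stage plus
a combined summary.  Every stochastic stage derives its own seed from the
master seed by stage index, so re-running a config reproduces every output
byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import borderscan, gcpsr, popstats, recombtest, seqdata, simgen, treekit
from .errors import ConfigError, PhylorecError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative description of one analysis run."""

    seed: int = 0
    output_dir: str = "phylorec_out"
    #: per-locus FASTA paths keyed by locus name (ignored when simulating)
    loci: Mapping[str, str] = field(default_factory=dict)
    #: manifest TSV path, or "packaged" for the built-in 93-strain table
    manifest: str | None = None
    #: optional pre-computed newick gene trees keyed by locus name
    trees: Mapping[str, str] = field(default_factory=dict)
    #: simulation parameters (mode, n_strains, ...); used when no loci given
    simulate: Mapping[str, Any] | None = None
    max_gap_fraction: float | None = None
    support_threshold: float = 0.95
    bootstrap: int = 100
    alpha: float = 0.05
    phi: Mapping[str, Any] = field(default_factory=dict)
    ia: Mapping[str, Any] = field(default_factory=dict)
    pht: Mapping[str, Any] = field(default_factory=dict)
    #: named strain groups the recombination tests run on ("all" = everything)
    groups: Mapping[str, Sequence[str]] = field(default_factory=dict)
    #: border scans: list of {name, focal, controls, candidates?, mode?}
    scans: Sequence[Mapping[str, Any]] = field(default_factory=list)
    #: pairs of subclade labels to compare with FST
    fst_pairs: Sequence[Sequence[str]] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)


def _stage_seed(master: int, index: int) -> int:
    return (int(master) * 1_000_003 + 7919 * index) % (2 ** 31)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, frozenset):
        return sorted(obj)
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    return obj


def _write_json(payload, path: Path):
    path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True)
                    + "\n")


def _load_dataset(config: RunConfig):
    if config.simulate is not None:
        params = dict(config.simulate)
        params.setdefault("seed", _stage_seed(config.seed, 0))
        sim = simgen.simulate_multilocus(simgen.SimulationConfig(**params))
        return sim.dataset, sim
    if not config.loci:
        raise ConfigError("config needs either 'loci' paths or 'simulate'")
    alignments = {name: seqdata.read_fasta_alignment(path, name)
                  for name, path in config.loci.items()}
    if config.manifest == "packaged":
        manifest = seqdata.load_packaged_manifest()
    elif config.manifest:
        manifest = seqdata.read_strain_manifest(config.manifest)
    else:
        first = next(iter(alignments.values()))
        manifest = [seqdata.StrainRecord(strain_id=s) for s in first.strain_ids]
    dataset = seqdata.assemble_dataset(manifest, alignments, policy="intersect")
    return dataset, None


def run_full_analysis(config: RunConfig) -> dict:
    """Run every configured stage; returns the report bundle (also on disk).

    Any stage failure raises a :class:`PhylorecError` naming the stage;
    outputs of completed stages are left in place.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Any] = {"seed": config.seed}
    rows: list[dict] = []

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        _stage("assemble")
        dataset, sim = _load_dataset(config)
        if sim is not None:
            for aln in dataset.loci:
                seqdata.write_fasta_alignment(aln, out / f"{aln.locus_name}.fasta")
        bundle["n_strains"] = dataset.n_strains
        bundle["loci"] = list(dataset.locus_names)
    except PhylorecError as exc:
        raise type(exc)(f"[assemble] {exc}") from exc

    try:
        _stage("filter")
        drop_log = {}
        if config.max_gap_fraction is not None:
            loci = []
            for aln in dataset.loci:
                filtered, removed = seqdata.filter_columns(
                    aln, config.max_gap_fraction)
                loci.append(filtered)
                drop_log[aln.locus_name] = removed
            dataset = seqdata.MultiLocusDataset(tuple(loci), dataset.manifest)
            _write_json(drop_log, out / "filtered_columns.json")
        concat, partition = seqdata.concatenate(dataset)
        bundle["concatenated_length"] = concat.length
    except PhylorecError as exc:
        raise type(exc)(f"[filter/concatenate] {exc}") from exc

    try:
        _stage("trees")
        gene_trees = {}
        for k, aln in enumerate(dataset.loci):
            if aln.locus_name in config.trees:
                tree = treekit.read_tree(config.trees[aln.locus_name])
            else:
                tree = treekit.nj_tree(aln, model="p",
                                       bootstrap=config.bootstrap,
                                       seed=_stage_seed(config.seed, 10 + k))
            gene_trees[aln.locus_name] = tree
            treekit.write_tree(tree, out / f"{aln.locus_name}.nwk")
        combined_tree = treekit.nj_tree(concat, model="p",
                                        bootstrap=config.bootstrap,
                                        seed=_stage_seed(config.seed, 9))
        treekit.write_tree(combined_tree, out / "combined.nwk")
    except PhylorecError as exc:
        raise type(exc)(f"[trees] {exc}") from exc

    try:
        _stage("gcpsr")
        tables = [treekit.extract_clades(t, config.support_threshold, name)
                  for name, t in gene_trees.items()]
        hypotheses = gcpsr.recognize_species(
            tables, support_threshold=config.support_threshold)
        df = pd.DataFrame([
            {"clade": ";".join(sorted(h.clade)), "size": len(h.clade),
             "verdict": h.verdict,
             "supported_by": ";".join(h.supporting_loci),
             "contradicted_by": ";".join(h.contradicting_loci)}
            for h in hypotheses])
        df.to_csv(out / "gcpsr.tsv", sep="\t", index=False)
        bundle["gcpsr"] = {"n_candidates": len(hypotheses),
                           "n_recognized": sum(h.recognized for h in hypotheses)}
    except PhylorecError as exc:
        raise type(exc)(f"[gcpsr] {exc}") from exc

    _stage("recombination tests")
    groups = dict(config.groups) or {"all": list(dataset.strain_ids)}
    known = set(dataset.strain_ids)
    test_results: dict[str, dict] = {}
    for g, (name, strains) in enumerate(sorted(groups.items())):
        unknown = set(strains) - known
        if unknown:
            raise ConfigError(
                f"[tests] group {name!r} references unknown strains "
                f"{sorted(unknown)}")
        sub = dataset.subset(strains)
        sub_concat, sub_part = seqdata.concatenate(sub)
        entry: dict[str, Any] = {}
        base = _stage_seed(config.seed, 100 + g)
        try:
            phi = recombtest.phi_test(sub_concat, seed=base, **dict(config.phi))
            entry["phi"] = dataclasses.asdict(phi)
            rows.append({"stage": "phi", "group": name, "statistic": phi.phi,
                         "p": phi.p_permutation,
                         "significant": phi.p_permutation < config.alpha})
        except PhylorecError as exc:
            entry["phi"] = {"error": str(exc)}
        try:
            ia = recombtest.index_of_association(sub, seed=base + 1,
                                                 **dict(config.ia))
            entry["ia"] = dataclasses.asdict(ia)
            rows.append({"stage": "ia", "group": name, "statistic": ia.ia,
                         "p": ia.p_permutation,
                         "significant": ia.p_permutation < config.alpha})
        except PhylorecError as exc:
            entry["ia"] = {"error": str(exc)}
        try:
            pht = recombtest.pht_test(sub_concat, sub_part, seed=base + 2,
                                      **dict(config.pht))
            entry["pht"] = {k: v for k, v in dataclasses.asdict(pht).items()
                            if k != "replicate_lengths"}
            rows.append({"stage": "pht", "group": name, "statistic": pht.t_obs,
                         "p": pht.p_value,
                         "significant": pht.p_value < config.alpha})
        except PhylorecError as exc:
            entry["pht"] = {"error": str(exc)}
        test_results[name] = entry
    _write_json(test_results, out / "recombination_tests.json")
    # IA significance flags association (clonality), so only Phi and PHT count
    # toward a "recombination detected" call
    bundle["groups"] = {
        name: {"recombination_detected": any(
            r["significant"] for r in rows
            if r["group"] == name and r["stage"] in ("phi", "pht"))}
        for name in groups}

    try:
        _stage("border scans")
        scan_results = {}
        for k, spec_ in enumerate(config.scans):
            spec_ = dict(spec_)
            name = spec_.pop("name", f"scan{k + 1}")
            result = borderscan.scan_borders(
                dataset, combined_tree,
                focal_clade=spec_["focal"],
                distant_controls=spec_.get("controls", []),
                candidates=spec_.get("candidates"),
                alpha=config.alpha,
                phi_opts=dict(config.phi),
                mode=spec_.get("mode", "fixed-baseline"),
                seed=_stage_seed(config.seed, 200 + k))
            pd.DataFrame(result.to_rows()).to_csv(
                out / f"scan_{name}.tsv", sep="\t", index=False)
            scan_results[name] = result
            rows.append({"stage": "scan", "group": name,
                         "statistic": len(result.recombining_population),
                         "p": result.baseline_phi_p,
                         "significant": result.inner_border_trigger is not None})
        if scan_results:
            _write_json(scan_results, out / "border_scans.json")
    except (PhylorecError, KeyError) as exc:
        raise ConfigError(f"[scan] {exc}") from exc

    try:
        _stage("population statistics")
        stats = {"per_locus": {}, "fst": {}}
        for aln in dataset.loci:
            stats["per_locus"][aln.locus_name] = dataclasses.asdict(
                popstats.diversity_stats(aln))
        labels = {r.strain_id: r.subclade_label for r in dataset.manifest}
        for pair in config.fst_pairs:
            a, b = pair
            assignment = {s: lab for s, lab in labels.items() if lab in (a, b)}
            res = popstats.hudson_fst(concat, assignment)
            stats["fst"][f"{a}|{b}"] = dataclasses.asdict(res)
            rows.append({"stage": "fst", "group": f"{a}|{b}",
                         "statistic": res.fst, "p": float("nan"),
                         "significant": False})
        stats["min_recombination_events"] = {
            aln.locus_name: popstats.min_recombination_events(aln)
            for aln in dataset.loci}
        _write_json(stats, out / "popstats.json")
        bundle["popstats"] = stats["min_recombination_events"]
    except PhylorecError as exc:
        raise type(exc)(f"[popstats] {exc}") from exc

    report = make_report(rows)
    report.to_csv(out / "summary.tsv", sep="\t", index=False)
    bundle["summary_rows"] = len(report)
    _write_json(bundle, out / "bundle.json")
    return {"bundle": bundle, "summary": report, "tests": test_results}


def make_report(stage_rows: Sequence[Mapping[str, Any]]) -> pd.DataFrame:
    """One row per (stage, group): statistic, p, decision.

    Rows are sorted by stage then group name, so regenerating the report from
    stored stage outputs reproduces it exactly.
    """
    if not stage_rows:
        raise ConfigError("make_report needs at least one stage output")
    df = pd.DataFrame(list(stage_rows))
    return df.sort_values(["stage", "group"], kind="mergesort").reset_index(
        drop=True)
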