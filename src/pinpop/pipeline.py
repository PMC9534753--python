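"""End-to-end orchestration: simulate -> filter -> stats -> sfs -> fit ->
compare -> bootstrap, driven by a single YAML-able config dictionary with
per-stage sections and named seeds, producing a machine-readable manifest
with checksums so deterministic stages can be verified bit-for-bit."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

from . import __version__
from .demography import SearchRanges
from .filters import FilterConfig, run_cascade
from .genotypes import read_vcf
from .inference import FitSettings, maximize, model_select, parametric_bootstrap
from .sfs import joint_sfs
from .simulate import (SimulationConfig, generate_dataset, write_truth_sidecar,
                       write_vcf)
from .stats import diversity_table, pairwise_fst, region_mean_fst

__all__ = ["run_pipeline", "RunManifest"]

STAGES = ("simulate", "filter", "stats", "sfs", "fit", "compare", "bootstrap")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    version: str
    config: dict
    stages: list = dataclasses.field(default_factory=list)
    failed_stage: str | None = None

    def record(self, stage: str, outputs: dict[str, Path]) -> None:
        self.stages.append({
            "stage": stage,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "outputs": {k: {"path": str(p), "sha256": _sha256(Path(p))}
                        for k, p in outputs.items()},
        })

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _filter_config(cfg: dict) -> FilterConfig:
    kw = dict(cfg.get("filter", {}))
    if "hdplot_d_range" in kw:
        kw["hdplot_d_range"] = tuple(kw["hdplot_d_range"])
    return FilterConfig(**kw)


def run_pipeline(config: dict, out_dir) -> RunManifest:
    """Execute the requested stages in order.

    ``config['stages']`` lists the stages to run (default: all up to
    'fit'); a failure leaves completed outputs in place and marks the
    failed stage in the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", ["simulate", "filter", "stats", "sfs"])
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    manifest = RunManifest(version=__version__, config=config)
    state: dict = {}
    try:
        for stage in stages:
            outputs = _run_stage(stage, config, out, state)
            manifest.record(stage, outputs)
    except Exception:
        manifest.failed_stage = stage
        manifest.write(out / "manifest.json")
        raise
    manifest.write(out / "manifest.json")
    return manifest


def _run_stage(stage: str, config: dict, out: Path, state: dict) -> dict:
    if stage == "simulate":
        sim_cfg = SimulationConfig(**{k: (tuple(v) if k == "n_pops_per_region"
                                          else v)
                                      for k, v in config.get("simulate", {}).items()
                                      if k != "model"})
        ds = generate_dataset(sim_cfg)
        vcf = out / "sim.vcf"
        sidecar = out / "truth.tsv"
        write_vcf(ds, vcf)
        write_truth_sidecar(ds, sidecar)
        state["gm"] = ds.genotypes
        state["truth"] = ds.truth
        state["total_length"] = ds.implied_total_length
        return {"vcf": vcf, "truth": sidecar}
    if "gm" not in state:
        vcf_in = config.get("input_vcf")
        if vcf_in is None:
            raise ValueError(f"stage {stage!r} needs a simulate stage or input_vcf")
        state["gm"] = read_vcf(vcf_in)
    if stage == "filter":
        gm, ledger = run_cascade(state["gm"], _filter_config(config))
        state["gm"] = gm
        ledger_path = out / "ledger.tsv"
        ledger.to_tsv(ledger_path)
        from .genotypes import write_vcf as write_gm
        filtered = out / "filtered.vcf"
        write_gm(gm, filtered)
        return {"filtered_vcf": filtered, "ledger": ledger_path}
    if stage == "stats":
        scfg = config.get("stats", {})
        table = diversity_table(state["gm"],
                                total_length=scfg.get("total_length"))
        fst = pairwise_fst(state["gm"])
        grouping = dict(zip(state["gm"].pop_labels, state["gm"].region_labels))
        means = region_mean_fst(fst, grouping)
        t1, t2 = out / "diversity.tsv", out / "pairwise_fst.tsv"
        table.to_csv(t1, sep="\t", index=False)
        fst.to_csv(t2, sep="\t")
        with open(out / "region_fst.json", "w") as fh:
            json.dump(means, fh, indent=2)
        return {"diversity": t1, "pairwise_fst": t2,
                "region_fst": out / "region_fst.json"}
    if stage == "sfs":
        scfg = config.get("sfs", {})
        spec = joint_sfs(state["gm"], scfg.get("proj_a"), scfg.get("proj_b"),
                         folded=scfg.get("folded", True))
        state["sfs"] = spec
        path = out / "joint.sfs"
        spec.to_text(path)
        return {"sfs": path}
    if stage == "fit":
        fcfg = config.get("fit", {})
        ranges = SearchRanges.default().updated(**{
            k: tuple(v) for k, v in fcfg.get("ranges", {}).items()})
        settings = FitSettings(**fcfg.get("settings", {}))
        fits = []
        for scenario in fcfg.get("scenarios", ["DIV", "DIV_M"]):
            fit = maximize(state["sfs"], scenario, ranges, settings)
            path = out / f"fit_{scenario}.json"
            fit.to_json(path)
            fits.append(fit)
        state["fits"] = fits
        return {f"fit_{f.scenario}": out / f"fit_{f.scenario}.json"
                for f in fits}
    if stage == "compare":
        ranked = model_select(state["fits"])
        path = out / "model_selection.json"
        with open(path, "w") as fh:
            json.dump([{"scenario": f.scenario, "k": f.k,
                        "max_lnL": f.max_lnl, "AIC": f.aic,
                        "delta_AIC": f.delta_aic, "wAIC": f.waic}
                       for f in ranked], fh, indent=2)
        state["best"] = ranked[0]
        return {"model_selection": path}
    if stage == "bootstrap":
        bcfg = config.get("bootstrap", {})
        best = state.get("best") or state["fits"][0]
        n_a, n_b = state["sfs"].projected_sizes
        ranges = SearchRanges.default().updated(**{
            k: tuple(v) for k, v in bcfg.get("ranges", {}).items()})
        res = parametric_bootstrap(
            best.model, n_a, n_b,
            int(state["sfs"].total(segregating_only=True)),
            bcfg.get("B", 100), ranges,
            FitSettings(**bcfg.get("settings", {})))
        path = out / "bootstrap.json"
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(res), fh, indent=2)
        return {"bootstrap": path}
    raise ValueError(f"unknown stage {stage!r}")
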