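"""End-to-end pipeline: reference -> (simulate|ingest) -> assign -> quantify
-> differential abundance -> coupling -> codon enrichment.

A single YAML config drives the run; it is schema-validated (unknown keys
rejected) before any work starts.  Every stage writes its intermediate
artifacts under the output directory, a JSON-lines log records one entry per
stage with parameters and content hashes, and the resolved config (defaults
filled in) is saved next to the outputs.  With a fixed config and seed the
summary JSON is byte-identical across reruns.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import assign as asg
from . import coupling as cpl
from . import diffexp as dfx
from . import modquant as mq
from . import simulate as sim
from .reference import ReferenceSet, dependent_codon_table, load_reference


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ReferenceConfig(_Strict):
    fasta: Optional[str] = None  # None -> packaged demo reference
    annotation: Optional[str] = None
    append_cca: bool = True
    isodecoders_per_family: int = 2  # demo reference only


class GeneSetConfig(_Strict):
    multiplier: float = 1.5
    n_background: int = 1000
    n_target: int = 100


class SimulationBlock(_Strict):
    reads_per_replicate: int = 20_000
    n_replicates: int = 3
    dispersion: float = 0.05
    gene_sets: GeneSetConfig = Field(default_factory=GeneSetConfig)


class AssignConfig(_Strict):
    max_mismatch: int = 3
    mod_site_free: bool = True


class QuantifyConfig(_Strict):
    min_coverage: int = 20


class DiffexpConfig(_Strict):
    sig_threshold: float = 0.05


class CouplingConfig(_Strict):
    B: int = 2000


class EnrichmentConfig(_Strict):
    B: int = 2000
    length_match: bool = False


class RunConfig(_Strict):
    """Schema-validated pipeline configuration."""

    seed: int
    out_dir: str
    reference: ReferenceConfig = Field(default_factory=ReferenceConfig)
    simulation: Optional[SimulationBlock] = Field(default_factory=SimulationBlock)
    fastq: Optional[dict[str, str]] = None  # replicate column -> path
    assign: AssignConfig = Field(default_factory=AssignConfig)
    quantify: QuantifyConfig = Field(default_factory=QuantifyConfig)
    diffexp: DiffexpConfig = Field(default_factory=DiffexpConfig)
    coupling: CouplingConfig = Field(default_factory=CouplingConfig)
    enrichment: EnrichmentConfig = Field(default_factory=EnrichmentConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()[:16]


class _StageLog:
    def __init__(self, path: Path) -> None:
        self.path = path
        self.path.write_text("")

    def stage(self, name: str, t0: float, **info) -> None:
        entry = {"stage": name, "elapsed_s": round(time.time() - t0, 3), **info}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the summary dict (also written as JSON).

    Any stage failure raises after partial outputs are retained; the log's
    last entry names the failed stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _StageLog(out / "run.log")
    (out / "resolved_config.yaml").write_text(
        yaml.safe_dump(config.model_dump(), sort_keys=True)
    )
    summary: dict = {"seed": config.seed}

    def guarded(name, fn):
        t0 = time.time()
        try:
            info = fn() or {}
        except Exception as exc:
            log.stage(name, t0, status="failed", error=str(exc))
            raise
        log.stage(name, t0, status="ok", **info)

    state: dict = {}

    def stage_reference():
        rc = config.reference
        if rc.fasta is not None:
            if rc.annotation is None:
                raise ValueError("reference.annotation required with reference.fasta")
            for p in (rc.fasta, rc.annotation):
                if not Path(p).exists():
                    raise FileNotFoundError(f"reference input not found: {p}")
            refset = load_reference(rc.fasta, rc.annotation, append_cca=rc.append_cca)
        else:
            refset = sim.demo_reference(
                seed=config.seed, isodecoders_per_family=rc.isodecoders_per_family
            )
        state["refset"] = refset
        dependent_codon_table(refset.anticodon_table()).to_csv(
            out / "codon_sets.tsv", sep="\t", index=False
        )
        return {"n_isodecoders": len(refset), "n_families": len(refset.families)}

    def stage_simulate():
        refset: ReferenceSet = state["refset"]
        sb = config.simulation
        cfg = sim.demo_config(
            refset,
            seed=config.seed,
            reads_per_replicate=sb.reads_per_replicate,
            n_replicates=sb.n_replicates,
        )
        cfg.dispersion = sb.dispersion
        counts, truth = sim.simulate_counts(refset, cfg)
        paths = sim.simulate_reads(refset, counts, cfg, out / "fastq")
        truth.to_json(out / "ground_truth.json")
        state.update(sim_config=cfg, truth=truth, fastq=paths)
        return {
            "replicates": sorted(paths),
            "fastq_hashes": {k: _hash_file(p) for k, p in sorted(paths.items())},
        }

    def stage_ingest():
        paths = {}
        for col, p in config.fastq.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"FASTQ not found: {p}")
            paths[col] = Path(p)
        state["fastq"] = paths
        return {"replicates": sorted(paths)}

    def stage_assign():
        refset: ReferenceSet = state["refset"]
        params = asg.AssignParams(
            max_mismatch=config.assign.max_mismatch,
            mod_site_free=config.assign.mod_site_free,
        )
        results, piles, qc = {}, {}, {}
        for col in sorted(state["fastq"]):
            res, pile = asg.assign_reads(state["fastq"][col], refset, params)
            results[col] = res
            piles[col] = pile
            qc[col] = asg.qc_metrics(res).__dict__
        iso_counts, fam_counts = asg.stack_replicates(results)
        asg.write_counts(iso_counts, fam_counts, out)
        pd.concat(
            {col: piles[col].to_frame() for col in sorted(piles)}, names=["replicate"]
        ).reset_index(level=0).to_csv(out / "pileups.tsv", sep="\t", index=False)
        (out / "qc.json").write_text(json.dumps(qc, indent=1, sort_keys=True))
        state.update(assignments=results, pileups=piles, iso_counts=iso_counts,
                     fam_counts=fam_counts)
        summary["qc"] = qc
        return {"counts_hash": _hash_file(out / "counts_isodecoder.tsv")}

    def stage_quantify():
        refset: ReferenceSet = state["refset"]
        min_cov = config.quantify.min_coverage
        conditions = sorted({c.rsplit("_", 1)[0] for c in state["pileups"]})
        calls, pools = {}, {}
        for cond in conditions:
            pooled = asg.PositionPileup()
            for col, pile in state["pileups"].items():
                if col.rsplit("_", 1)[0] == cond:
                    pooled.add(pile)
            calls[cond] = mq.call_i34(pooled, refset, min_coverage=min_cov)
            pools[cond] = mq.aggregate_anticodon(calls[cond], refset, min_coverage=min_cov)
            mq.write_calls(calls[cond], out / f"i34_isodecoder_{cond}.tsv")
            mq.write_calls(pools[cond], out / f"i34_anticodon_{cond}.tsv")
            profile = mq.profile_modifications(pooled, refset)
            profile.to_csv(out / f"mod_profile_{cond}.tsv", sep="\t", index=False)
        state["calls"] = calls
        summary["i34_family"] = {
            cond: {
                c.unit: (round(c.theta, 4) if c.called else None)
                for c in pools[cond]
            }
            for cond in conditions
        }
        if len(conditions) == 2:
            control, case = conditions
            delta = mq.delta_mod(calls[case], calls[control])
            delta.to_csv(out / "i34_delta.tsv", sep="\t", index=False)
            state["delta"] = delta
        return {"conditions": conditions}

    def stage_diffexp():
        refset: ReferenceSet = state["refset"]
        res_iso = dfx.test_differential(
            state["iso_counts"], refset=refset,
            sig_threshold=config.diffexp.sig_threshold,
        )
        res_fam = dfx.test_differential(
            state["iso_counts"], level="anticodon", refset=refset,
            sig_threshold=config.diffexp.sig_threshold,
        )
        dfx.write_differential(res_iso, out / "differential_isodecoder.tsv")
        dfx.write_differential(res_fam, out / "differential_anticodon.tsv")
        dfx.volcano_table(res_fam, refset, level="anticodon").to_csv(
            out / "volcano_anticodon.tsv", sep="\t", index_label="unit"
        )
        state["diff_iso"] = res_iso
        for name, res in (("isodecoder", res_iso), ("anticodon", res_fam)):
            vc = res["direction"].value_counts()
            summary[f"differential_{name}"] = {
                "n_tested": int(len(res)),
                "n_up": int(vc.get("up", 0)),
                "n_down": int(vc.get("down", 0)),
                "n_unchanged": int(vc.get("unchanged", 0)),
            }
        return {"n_isodecoder": len(res_iso), "n_anticodon": len(res_fam)}

    def stage_coupling():
        if "delta" not in state:
            return {"skipped": "needs two conditions"}
        delta = state["delta"].set_index("unit")
        fc = state["diff_iso"]["log2fc"]
        shared = delta.index.intersection(fc.index)
        if len(shared) < 5:
            summary["coupling"] = None
            return {"skipped": f"only {len(shared)} matched units"}
        res = cpl.spearman_coupling(
            delta.loc[shared, "delta_log2"],
            fc.loc[shared],
            B=config.coupling.B,
            seed=config.seed,
        )
        res.table.to_csv(out / "coupling_table.tsv", sep="\t", index_label="unit")
        summary["coupling"] = {"n": res.n, "r": round(res.r, 4), "p": res.p}
        return {"n": res.n}

    def stage_enrichment():
        if config.simulation is None:
            return {"skipped": "no gene-set source configured"}
        gs = config.simulation.gene_sets
        model = sim.CodonUsageModel(multiplier=gs.multiplier)
        cds, target_ids, truth = sim.simulate_gene_sets(
            model, seed=config.seed,
            n_background=gs.n_background, n_target=gs.n_target,
        )
        sim.write_fasta(cds, out / "cds.fa")
        (out / "gene_set.txt").write_text("\n".join(target_ids) + "\n")
        usage = cpl.codon_usage(cds)
        results = []
        for fam in usage.attrs["families"]:
            results.append(
                cpl.enrichment_test(
                    target_ids, usage, fam,
                    B=config.enrichment.B, seed=config.seed,
                    length_match=config.enrichment.length_match,
                )
            )
        table = cpl.enrichment_summary(results)
        table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        summary["enrichment_p"] = {
            r.family: r.p for r in results
        }
        return {"n_families": len(results)}

    guarded("reference", stage_reference)
    if config.fastq:
        guarded("ingest", stage_ingest)
    elif config.simulation is not None:
        guarded("simulate", stage_simulate)
    else:
        raise ValueError("config needs either a simulation block or fastq paths")
    guarded("assign", stage_assign)
    guarded("quantify", stage_quantify)
    guarded("diffexp", stage_diffexp)
    guarded("coupling", stage_coupling)
    guarded("enrichment", stage_enrichment)

    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=1, sort_keys=True))
    log.stage("summary", time.time(), hash=_hash_file(summary_path))
    return summary
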