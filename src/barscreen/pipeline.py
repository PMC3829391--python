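"""Config-driven end-to-end orchestration: simulate/load -> summarize ->
call -> integrate -> report.

A single YAML config (or :class:`PipelineConfig`) drives every stage.  All
randomness flows from one seed through a named generator per stage, so
changing one stage's parameters never perturbs another stage's draws, and
rerunning an identical config reproduces the report byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from . import __version__
from .hit_calling import HitThresholds, call_genes, call_pools, write_gene_calls
from .integration import (
    EvidenceSet,
    harmonize,
    nominate,
    query_disease_genes,
    read_gene_dump,
    read_symbol_list,
    venn3,
    write_gene_dump,
)
from .screen_core import (
    build_volcano_table,
    read_pool_annotations,
    read_well_table,
    summarize_pools,
    write_volcano,
)
from .synthetic_data import (
    EvidenceOverlap,
    ScreenSimConfig,
    simulate_evidence,
    simulate_screen,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location for one pipeline run.

    Each input stage takes either file paths (``wells_path``/``pools_path``
    and ``phospho_path``/``dump_path``) or a simulation config; simulation
    is the default so a bare ``PipelineConfig(outdir=...)`` runs end to end.
    """

    outdir: str = "pipeline_out"
    seed: int = 0
    test: str = "student"
    cross_plate_controls: bool = False
    bh: bool = False
    thresholds: HitThresholds = field(default_factory=HitThresholds)
    keyword: str = "melanoma"
    whole_word: bool = True
    # screen input: paths take precedence over simulation
    wells_path: str | None = None
    pools_path: str | None = None
    screen_sim: ScreenSimConfig | None = field(default_factory=ScreenSimConfig)
    # evidence input
    phospho_path: str | None = None
    dump_path: str | None = None
    evidence_sim: EvidenceOverlap | None = field(default_factory=EvidenceOverlap)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "thresholds" in kwargs:
            kwargs["thresholds"] = HitThresholds(**kwargs["thresholds"])
        if kwargs.get("screen_sim") is not None:
            sim = kwargs["screen_sim"]
            if "effect_log2_range" in sim:
                sim["effect_log2_range"] = tuple(sim["effect_log2_range"])
            kwargs["screen_sim"] = ScreenSimConfig(**sim)
        if kwargs.get("evidence_sim") is not None:
            kwargs["evidence_sim"] = EvidenceOverlap(**kwargs["evidence_sim"])
        return cls(**kwargs)

    def validate(self) -> None:
        if self.wells_path is None and self.screen_sim is None:
            raise ValueError("config needs either wells_path or screen_sim")
        if self.wells_path is not None and self.pools_path is None:
            raise ValueError("wells_path requires pools_path")
        if (self.phospho_path is None) != (self.dump_path is None):
            raise ValueError("phospho_path and dump_path must be given together")
        if self.phospho_path is None and self.evidence_sim is None:
            raise ValueError("config needs either evidence paths or evidence_sim")


def run(config: PipelineConfig) -> dict:
    """Execute every stage, write per-stage artifacts and return the report.

    Writes to ``config.outdir``: the (simulated) input tables, the volcano
    TSV, gene-call TSV, candidate TSV and ``report.json``.  The returned
    dict equals the parsed report.  Any stage error propagates annotated
    with the stage name.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    truth = None
    try:
        if config.wells_path is not None:
            wells = read_well_table(config.wells_path)
            annotations = read_pool_annotations(config.pools_path)
        else:
            sim = replace(config.screen_sim, seed=config.seed)
            wells, annotations, truth = simulate_screen(sim)
            wells.to_csv(outdir / "wells.tsv", sep="\t", index=False)
            annotations.to_csv(outdir / "pool_annotations.tsv", sep="\t", index=False)
    except Exception as err:
        raise RuntimeError(f"stage 'screen input' failed: {err}") from err

    try:
        summaries = summarize_pools(
            wells,
            annotations,
            test=config.test,
            cross_plate_controls=config.cross_plate_controls,
            seed=config.seed,
        )
        volcano = build_volcano_table(summaries)
        write_volcano(volcano, outdir / "volcano.tsv")
    except Exception as err:
        raise RuntimeError(f"stage 'summarize' failed: {err}") from err

    try:
        pool_calls = call_pools(volcano, config.thresholds, bh=config.bh)
        gene_calls = call_genes(pool_calls, config.thresholds)
        write_gene_calls(gene_calls, outdir / "gene_calls.tsv")
    except Exception as err:
        raise RuntimeError(f"stage 'hit calling' failed: {err}") from err

    try:
        if config.phospho_path is not None:
            phospho_raw = read_symbol_list(config.phospho_path)
            dump = read_gene_dump(config.dump_path)
        else:
            if truth is None:
                raise ValueError(
                    "evidence simulation needs the screen truth table; "
                    "supply phospho_path/dump_path when loading wells from disk"
                )
            phospho_raw, dump, truth = simulate_evidence(
                truth, config.evidence_sim, seed=config.seed
            )
            with open(outdir / "phospho_hits.txt", "w") as fh:
                fh.write("\n".join(phospho_raw) + "\n")
            write_gene_dump(dump, outdir / "gene_records.jsonl")
        if truth is not None:
            truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)

        screen_set = harmonize(
            gene_calls.loc[gene_calls["is_hit"], "gene_symbol"],
            name="screen", provenance="consensus gene hits",
        )
        phospho_set = harmonize(phospho_raw, name="phospho",
                                provenance="phosphoproteomic hit list")
        disease_set = query_disease_genes(
            dump, config.keyword, whole_word=config.whole_word
        )
        disease_set = EvidenceSet("disease", disease_set.symbols,
                                  disease_set.provenance)
        venn = venn3(screen_set, phospho_set, disease_set)
        candidates = nominate(screen_set, phospho_set, disease_set)
    except Exception as err:
        raise RuntimeError(f"stage 'integration' failed: {err}") from err

    report = {
        "version": __version__,
        "seed": config.seed,
        "n_pools_screened": int(len(volcano)),
        "n_pool_hits": int((pool_calls["pool_call"] != "non_hit").sum()),
        "n_genes": int(len(gene_calls)),
        "n_gene_hits": int(gene_calls["is_hit"].sum()),
        "venn": venn.to_dict(),
        "candidates": [
            {
                "gene_symbol": c.gene_symbol,
                "in_screen": c.in_screen,
                "in_phospho": c.in_phospho,
                "in_disease": c.in_disease,
                "rank_key": c.rank_key,
            }
            for c in candidates
        ],
        "config": _config_echo(config),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info(
        "pipeline done: %d pools, %d pool hits, %d gene hits, %d candidate(s)",
        report["n_pools_screened"], report["n_pool_hits"],
        report["n_gene_hits"], len(report["candidates"]),
    )
    return report


def _config_echo(config: PipelineConfig) -> dict:
    echo = asdict(config)
    if echo.get("screen_sim") and isinstance(echo["screen_sim"].get(
            "effect_log2_range"), tuple):
        echo["screen_sim"]["effect_log2_range"] = list(
            echo["screen_sim"]["effect_log2_range"])
    return echo
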