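"""Seeded generators for every input the analysis consumes, with ground truth.

The screen simulator emulates the error structure of a plate-based
dual-luciferase screen:

* a shared log-normal "cell number" factor multiplies both channels of a
  well — exactly the nuisance the Renilla normalization is designed to
  cancel;
* independent log-normal measurement noise on each channel, parameterized
  by coefficient of variation;
* a planted knockdown effect multiplying the firefly channel of true
  regulator pools by ``2 ** log2_effect``.

Negative-control wells carry no effect; positive-control wells carry a
fixed known effect.  Every generator is a pure function of its
configuration and seed, so identical calls are byte-identical.

Defaults are the desk-scale study conditions used throughout the test
suite: 500 genes, one pool per gene, three replicate wells per pool on
384-well plates with 16 negative controls each, 10% true regulators with
|log2 effect| = 2, and CV 0.2 on both noise terms.  A ``paper_scale()``
preset produces a 28,044-pool / 19,490-gene layout for soak testing only.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .integration import GeneRecord, GeneRecordDump
from .screen_core import WELL_COLUMNS


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent generator per (seed, stage name); stable across runs."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(stage.encode())])


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _well_id(index: int) -> str:
    if index < 26 * 24:
        return f"{chr(ord('A') + index // 24)}{index % 24 + 1:02d}"
    return f"W{index + 1:05d}"


@dataclass(frozen=True)
class ScreenSimConfig:
    n_genes: int = 500
    pools_per_gene: int = 1
    replicates_per_pool: int = 3
    wells_per_plate: int = 384
    n_neg_controls_per_plate: int = 16
    n_pos_controls_per_plate: int = 4
    fraction_true_regulators: float = 0.1
    #: fraction of genes receiving one pool beyond ``pools_per_gene``
    #: (screening libraries rarely have a uniform pool count per gene)
    extra_pool_fraction: float = 0.0
    #: |log2 effect| of a true regulator is drawn uniformly from this range
    #: (a degenerate range plants a fixed magnitude); the sign is random.
    effect_log2_range: tuple[float, float] = (2.0, 2.0)
    pos_control_log2_effect: float = 2.0
    baseline_firefly: float = 1.0e4
    baseline_renilla: float = 1.0e4
    well_noise_cv: float = 0.2
    cell_number_cv: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if min(self.n_genes, self.pools_per_gene, self.replicates_per_pool,
               self.wells_per_plate) < 1:
            raise ValueError("all counts must be positive")
        if self.n_neg_controls_per_plate < 2:
            raise ValueError("need at least 2 negative controls per plate")
        if not 0 <= self.fraction_true_regulators <= 1:
            raise ValueError("fraction_true_regulators must be in [0, 1]")
        if not 0 <= self.extra_pool_fraction <= 1:
            raise ValueError("extra_pool_fraction must be in [0, 1]")
        if self.well_noise_cv < 0 or self.cell_number_cv < 0:
            raise ValueError("noise CVs must be >= 0")
        lo, hi = self.effect_log2_range
        if lo < 0 or hi < lo:
            raise ValueError("effect_log2_range must satisfy 0 <= lo <= hi")
        reserved = self.n_neg_controls_per_plate + self.n_pos_controls_per_plate
        if self.wells_per_plate - reserved < self.replicates_per_pool:
            raise ValueError("plate too small for controls plus one pool")


def paper_scale(seed: int = 0) -> ScreenSimConfig:
    """Full published-screen scale (28,044 pools over 19,490 genes on
    1536-well plates); for soak testing, not the test suite."""
    return ScreenSimConfig(
        n_genes=19_490,
        pools_per_gene=1,
        extra_pool_fraction=(28_044 - 19_490) / 19_490,
        wells_per_plate=1536,
        n_neg_controls_per_plate=32,
        seed=seed,
    )


def simulate_screen(
    cfg: ScreenSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a whole screen.

    Returns ``(wells, annotations, truth)``: a well table in the
    :mod:`barscreen.screen_core` schema, a pool->gene annotation table and a
    per-gene truth table (``gene_symbol``, ``is_regulator``,
    ``true_log2_effect``, ``in_phospho_truth``, ``in_disease_truth`` — the
    last two all-False placeholders until :func:`simulate_evidence` fills
    them).  A pool's replicate wells share a plate.
    """
    rng = _stage_rng(cfg.seed, "screen")
    genes = [f"GENE{i + 1:05d}" for i in range(cfg.n_genes)]
    n_reg = round(cfg.fraction_true_regulators * cfg.n_genes)
    reg_idx = rng.choice(cfg.n_genes, size=n_reg, replace=False)
    is_reg = np.zeros(cfg.n_genes, dtype=bool)
    is_reg[reg_idx] = True
    lo, hi = cfg.effect_log2_range
    magnitudes = rng.uniform(lo, hi, size=n_reg)
    signs = rng.choice([-1.0, 1.0], size=n_reg)
    effects = np.zeros(cfg.n_genes)
    effects[reg_idx] = magnitudes * signs

    truth = pd.DataFrame({
        "gene_symbol": genes,
        "is_regulator": is_reg,
        "true_log2_effect": effects,
        "in_phospho_truth": False,
        "in_disease_truth": False,
    })

    n_extra = round(cfg.extra_pool_fraction * cfg.n_genes)
    extra_pool = np.zeros(cfg.n_genes, dtype=bool)
    if n_extra:
        extra_pool[rng.choice(cfg.n_genes, size=n_extra, replace=False)] = True
    pools, pool_gene, pool_effect = [], [], []
    k = 0
    for g, gene in enumerate(genes):
        for _ in range(cfg.pools_per_gene + int(extra_pool[g])):
            k += 1
            pools.append(f"P{k:06d}")
            pool_gene.append(gene)
            pool_effect.append(effects[g])
    annotations = pd.DataFrame({
        "pool_id": pools,
        "gene_symbol": pool_gene,
        "gene_id": np.arange(1, len(pools) + 1),
    })

    reserved = cfg.n_neg_controls_per_plate + cfg.n_pos_controls_per_plate
    pools_per_plate = (cfg.wells_per_plate - reserved) // cfg.replicates_per_pool

    rows: list[tuple] = []

    def emit(plate, widx, kind, pool_id, log2_effect, replicate):
        cell = _lognormal_factor(rng, cfg.cell_number_cv, None)
        nf = _lognormal_factor(rng, cfg.well_noise_cv, None)
        nr = _lognormal_factor(rng, cfg.well_noise_cv, None)
        firefly = cfg.baseline_firefly * 2.0 ** log2_effect * cell * nf
        renilla = cfg.baseline_renilla * cell * nr
        rows.append((plate, _well_id(widx), kind, pool_id,
                     float(firefly), float(renilla), replicate))

    for start in range(0, len(pools), pools_per_plate):
        plate_pools = range(start, min(start + pools_per_plate, len(pools)))
        plate = f"PL{start // pools_per_plate + 1:04d}"
        widx = 0
        for j in range(cfg.n_neg_controls_per_plate):
            emit(plate, widx, "negative_control", None, 0.0, j + 1)
            widx += 1
        for j in range(cfg.n_pos_controls_per_plate):
            emit(plate, widx, "positive_control", None,
                 cfg.pos_control_log2_effect, j + 1)
            widx += 1
        for pi in plate_pools:
            for rep in range(cfg.replicates_per_pool):
                emit(plate, widx, "pool", pools[pi], pool_effect[pi], rep + 1)
                widx += 1

    wells = pd.DataFrame(rows, columns=WELL_COLUMNS)
    return wells, annotations, truth


@dataclass(frozen=True)
class EvidenceOverlap:
    """How regulators and non-regulators enter the two orthogonal evidence
    sets.  ``n_triple`` regulators are deterministically placed in both the
    phosphoproteomic and disease sets; every other gene enters at most one
    of the two, so the planted triple-overlap count is exact with respect
    to the true regulator set."""

    phospho_frac_regulators: float = 0.4
    phospho_frac_others: float = 0.02
    disease_frac_regulators: float = 0.4
    disease_frac_others: float = 0.05
    n_triple: int = 1

    def __post_init__(self):
        for f in (self.phospho_frac_regulators, self.phospho_frac_others,
                  self.disease_frac_regulators, self.disease_frac_others):
            if not 0 <= f <= 1:
                raise ValueError("overlap fractions must be in [0, 1]")
        if self.n_triple < 0:
            raise ValueError("n_triple must be >= 0")


_DISEASE_TEXT = "{sym} has been implicated in melanoma susceptibility and progression."
_DECOY_TEXT = ("{sym} is studied in melanomagenesis-adjacent keratinocyte models "
               "but has no established disease association.")
_NEUTRAL_TEXT = "{sym} encodes a protein of incompletely characterized function."


def simulate_evidence(
    truth: pd.DataFrame,
    overlap: EvidenceOverlap = EvidenceOverlap(),
    seed: int = 0,
) -> tuple[list[str], GeneRecordDump, pd.DataFrame]:
    """Build a phosphoproteomic hit list and a disease gene-record dump.

    Returns ``(phospho_symbols, dump, truth)`` where ``truth`` is a copy
    with ``in_phospho_truth`` / ``in_disease_truth`` realized.  Disease
    membership is encoded in the record text: member descriptions mention
    the disease keyword ("melanoma") as a whole word; one in five
    non-member records carries a compound-word decoy ("melanomagenesis")
    that must not match under whole-word querying.
    """
    rng = _stage_rng(seed, "evidence")
    truth = truth.copy().reset_index(drop=True)
    n = len(truth)
    reg_idx = np.flatnonzero(truth["is_regulator"].to_numpy())
    oth_idx = np.flatnonzero(~truth["is_regulator"].to_numpy())
    if overlap.n_triple > len(reg_idx):
        raise ValueError("n_triple exceeds the number of true regulators")

    in_ph = np.zeros(n, dtype=bool)
    in_di = np.zeros(n, dtype=bool)
    triple = rng.choice(reg_idx, size=overlap.n_triple, replace=False)
    in_ph[triple] = True
    in_di[triple] = True
    rest = np.setdiff1d(reg_idx, triple)
    draw_ph = rng.random(len(rest)) < overlap.phospho_frac_regulators
    draw_di = rng.random(len(rest)) < overlap.disease_frac_regulators
    both = draw_ph & draw_di
    # keep exactly n_triple genes in both sets: break accidental doubles
    drop_ph = rng.random(int(both.sum())) < 0.5
    draw_ph[np.flatnonzero(both)[drop_ph]] = False
    draw_di[np.flatnonzero(both)[~drop_ph]] = False
    in_ph[rest] = draw_ph
    in_di[rest] = draw_di
    draw_ph = rng.random(len(oth_idx)) < overlap.phospho_frac_others
    draw_di = rng.random(len(oth_idx)) < overlap.disease_frac_others
    both = draw_ph & draw_di
    drop_ph = rng.random(int(both.sum())) < 0.5
    draw_ph[np.flatnonzero(both)[drop_ph]] = False
    draw_di[np.flatnonzero(both)[~drop_ph]] = False
    in_ph[oth_idx] = draw_ph
    in_di[oth_idx] = draw_di

    truth["in_phospho_truth"] = in_ph
    truth["in_disease_truth"] = in_di

    symbols = truth["gene_symbol"].tolist()
    phospho = [symbols[i] for i in np.flatnonzero(in_ph)]
    records = []
    decoy_draw = rng.random(n) < 0.2
    for i, sym in enumerate(symbols):
        if in_di[i]:
            text = _DISEASE_TEXT.format(sym=sym)
        elif decoy_draw[i]:
            text = _DECOY_TEXT.format(sym=sym)
        else:
            text = _NEUTRAL_TEXT.format(sym=sym)
        records.append(GeneRecord(
            gene_id=i + 1,
            gene_symbol=sym,
            description=text,
            summary="",
        ))
    dump = GeneRecordDump(records, source_label="synthetic-gene-dump",
                          snapshot_date="simulated")
    return phospho, dump, truth


def simulate_apms(
    n_prey: int = 50,
    background_rate: float = 0.4,
    contaminant_list: Iterable[str] = (),
    bait: str = "BAIT",
    mean_counts: float = 5.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str], set[str]]:
    """Simulate one AP-MS run with known background structure.

    Returns ``(run, control_preys, truth_retained)``.  ``background_rate``
    of the preys also appear in the control purification; any prey named in
    ``contaminant_list`` is additionally present in the run.  Spectral
    counts follow a shifted Poisson (always >= 1).  The bait appears as its
    own prey row (purification positive control).  ``truth_retained`` is
    the prey set a correct background subtraction must keep.
    """
    if not 0 <= background_rate <= 1:
        raise ValueError("background_rate must be in [0, 1]")
    rng = _stage_rng(seed, "apms")
    preys = [f"PREY{i + 1:03d}" for i in range(n_prey)]
    for extra in contaminant_list:
        if extra not in preys:
            preys.append(extra)
    n_bg = round(background_rate * n_prey)
    control = sorted(rng.choice(preys[:n_prey], size=n_bg, replace=False).tolist())
    counts = 1 + rng.poisson(max(mean_counts - 1.0, 0.0), size=len(preys))
    run = pd.DataFrame({
        "bait": bait,
        "prey": preys + [bait],
        "spectral_counts": np.append(counts, 1 + rng.poisson(mean_counts * 4)),
    })
    truth = set(preys) - set(control) - set(contaminant_list)
    return run, control, truth


@dataclass(frozen=True)
class AssayEffects:
    """Planted per-condition effects for the validation-assay simulators.

    Reporter folds multiply a unit baseline firefly/Renilla ratio; qPCR
    folds are true RQ values relative to the calibrator; TUNEL rates are
    per-cell apoptosis probabilities; densitometry levels are relative
    signal ratios (max condition = 1).  Defaults emulate a Wnt-pathway
    knockdown experiment: conditioned-media stimulation activates the
    reporter ~10-fold and the target gene ~4-fold, knockdown suppresses
    both, and knockdown blunts stimulus-driven apoptosis.
    """

    reporter_folds: Mapping[str, float] = field(default_factory=lambda: {
        "siCTRL+L_CM": 1.0,
        "siCTRL+WNT3A_CM": 10.0,
        "siKD+WNT3A_CM": 2.5,
    })
    reporter_replicates: int = 6
    reporter_cv: float = 0.1
    qpcr_folds: Mapping[str, float] = field(default_factory=lambda: {
        "L_CM": 1.0,
        "WNT3A_CM": 4.0,
        "siKD+WNT3A_CM": 1.5,
    })
    qpcr_calibrator: str = "L_CM"
    qpcr_replicates: int = 6
    qpcr_ct_sd: float = 0.15
    tunel_rates: Mapping[str, float] = field(default_factory=lambda: {
        "siCTRL+WNT3A+PLX": 0.20,
        "siKD+WNT3A+PLX": 0.02,
    })
    tunel_fields: int = 5
    tunel_cells_per_field: int = 200
    densitometry_levels: Mapping[str, float] = field(default_factory=lambda: {
        "siCTRL+WNT3A+PLX": 1.0,
        "siKD+WNT3A+PLX": 0.3,
        "siCTRL+L+DMSO": 0.05,
    })
    densitometry_cv: float = 0.05


def simulate_assays(
    effects: AssayEffects = AssayEffects(), seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate (reporter, qpcr, tunel, densitometry) tables.

    Reporter rows carry shared cell-number noise on both channels plus
    independent channel noise; qPCR samples carry a per-sample global Ct
    shift (RNA input) on both target and reference, which ddCt must cancel;
    TUNEL counts are binomial per field with Poisson field cellularity.
    """
    rng = _stage_rng(seed, "assays")

    rep_rows = []
    for cond, fold in effects.reporter_folds.items():
        sirna, _, treatment = cond.partition("+")
        for r in range(effects.reporter_replicates):
            cell = _lognormal_factor(rng, 0.2, None)
            firefly = 1e4 * fold * cell * _lognormal_factor(rng, effects.reporter_cv, None)
            renilla = 1e4 * cell * _lognormal_factor(rng, effects.reporter_cv, None)
            rep_rows.append({
                "cell_line": "A375", "sirna": sirna,
                "treatment": treatment or cond,
                "condition": cond,
                "firefly": float(firefly), "renilla": float(renilla),
                "replicate": r + 1,
            })
    reporter = pd.DataFrame(rep_rows)

    qpcr_rows = []
    for cond, fold in effects.qpcr_folds.items():
        for r in range(effects.qpcr_replicates):
            shift = rng.normal(0.0, 0.5)  # RNA-input shift, hits both genes
            target = 26.0 - np.log2(fold) + shift + rng.normal(0.0, effects.qpcr_ct_sd)
            reference = 20.0 + shift + rng.normal(0.0, effects.qpcr_ct_sd)
            qpcr_rows.append({
                "sample": f"{cond}_rep{r + 1}", "condition": cond,
                "target_ct": float(target), "reference_ct": float(reference),
            })
    qpcr = pd.DataFrame(qpcr_rows)

    tunel_rows = []
    for cond, rate in effects.tunel_rates.items():
        for f in range(effects.tunel_fields):
            dapi = int(rng.poisson(effects.tunel_cells_per_field))
            tunel = int(rng.binomial(dapi, rate)) if dapi > 0 else 0
            tunel_rows.append({
                "condition": cond, "field_index": f + 1,
                "dapi_count": dapi, "tunel_count": tunel,
            })
    tunel = pd.DataFrame(tunel_rows)

    dens_rows = []
    for cond, level in effects.densitometry_levels.items():
        loading = 5e3 * _lognormal_factor(rng, effects.densitometry_cv, None)
        cc3 = 1e3 * level * _lognormal_factor(rng, effects.densitometry_cv, None)
        dens_rows.append({
            "condition": cond,
            "cc3_density": float(cc3 * loading / 5e3),
            "loading_density": float(loading),
        })
    densitometry = pd.DataFrame(dens_rows)

    return reporter, qpcr, tunel, densitometry


def with_seed(cfg: ScreenSimConfig, seed: int) -> ScreenSimConfig:
    return replace(cfg, seed=seed)
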