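"""End-to-end reproducible runs tying the analysis stages together.

Each run reads (or simulates) sorted-fraction quantitation tables, executes
the stage sequence for its design, writes tabular outputs plus a provenance
record (config hash, seed, package version) and a structured log of
per-stage counts, and is byte-reproducible given the same config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .accumulation import bulk_mean_profile, growth_fit_from_ratios
from .dynamics import (agglomerate_by_trough, choose_k_wss,
                       classify_early_risers, kmeans_cluster, motif_match,
                       prepare_profiles, residue_frequencies)
from .ergodic import PhaseFrequencyTable, build_timeline
from .quant import (correct_isotope_impurities, merge_datasets,
                    normalize_reporters, normalize_silac,
                    reference_ratios, replicate_median_profile)
from .selection import SelectionConfig, select_candidates
from .simulate import (DEFAULT_CHANNEL_MAP, SimulationConfig,
                       default_impurity_matrix, simulate_interphase_dataset,
                       simulate_mitotic_dataset, simulate_phosphosites)

__all__ = ["RunConfig", "PipelineError", "build_mitotic_matrix",
           "run_interphase_pipeline", "run_mitotic_pipeline"]

log = logging.getLogger("primmus.pipeline")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    When ``protein_table`` / ``phospho_table`` paths are given they are
    read; otherwise the synthetic generator produces the inputs from
    ``simulation`` (which also defines phase frequencies and the seed).
    """

    out_dir: str = "results/run"
    design: str = "interphase"
    protein_table: str | None = None
    phospho_table: str | None = None
    tmt_table: str | None = None
    impurity_matrix: str | None = None
    channel_map: dict = field(default_factory=lambda: dict(DEFAULT_CHANNEL_MAP))
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    selection: SelectionConfig | None = None
    cluster_k: int | None = None
    cluster_k_range: tuple = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14)
    cluster_restarts: int = 50
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        sim = payload.pop("simulation", {})
        sel = payload.pop("selection", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise PipelineError("config", f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**payload)
        cfg.simulation = SimulationConfig(**{**sim, "seed": payload.get("seed", 0)}) \
            if isinstance(sim, dict) else sim
        if sel is not None:
            cfg.selection = SelectionConfig(**sel)
        return cfg

    def digest(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            return str(o)
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_provenance(cfg: RunConfig, out: Path):
    from . import __version__
    record = {
        "config_hash": cfg.digest(),
        "seed": cfg.seed,
        "design": cfg.design,
        "package_version": __version__,
    }
    (out / "provenance.json").write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(name, str(exc)) from exc
    return wrap


def build_mitotic_matrix(sim: SimulationConfig, impurity_matrix=None):
    """Simulate and fully quantitate the three-replicate mitotic design.

    Two SILAC replicates (normalised to Pro of replicate 1) are merged with
    one TMT replicate (impurity-corrected, sum-normalised, referenced to
    Pro) on the protein identifier.  Returns ``(merged, truth)``.
    """
    ds = simulate_mitotic_dataset(sim, impurity_matrix=impurity_matrix)
    silac = normalize_silac(ds.matrix, "to-reference-of-replicate-1", "Pro")
    M = impurity_matrix if impurity_matrix is not None \
        else default_impurity_matrix(ds.tmt_reporters.shape[1])
    corrected, _ = correct_isotope_impurities(ds.tmt_reporters, M)
    ratios = reference_ratios(normalize_reporters(corrected),
                              DEFAULT_CHANNEL_MAP, "Pro")
    mito = [f for f in ("Pro", "PM1", "PM2", "Ana") if f in ratios.columns]
    tmt = ratios[mito].copy()
    tmt.columns = pd.MultiIndex.from_product([mito, ["r1"]],
                                             names=["fraction", "replicate"])
    merged, _stats = merge_datasets(silac, tmt)
    return merged, ds.truth


def run_interphase_pipeline(cfg: RunConfig) -> dict:
    """Timeline -> normalise -> accumulation -> selection -> phospho dynamics.

    Returns a dict of output paths; every stage writes its table under
    ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(cfg.simulation, seed=cfg.seed)
    outputs = {}

    # timeline
    freqs = PhaseFrequencyTable(phases=("G1", "S", "G2", "M"),
                                cumulative_freq=sim.phase_boundaries,
                                doubling_time=sim.doubling_time)
    timeline = _stage("timeline")(build_timeline, freqs)
    tl = timeline.to_frame()
    tl.to_csv(out / "timeline.csv", index=False)
    outputs["timeline"] = out / "timeline.csv"

    # inputs
    if cfg.protein_table:
        matrix, _meta = _stage("read")(pio.read_protein_groups, cfg.protein_table)
    else:
        ds = _stage("simulate")(simulate_interphase_dataset, sim)
        matrix = ds.matrix
        pio.write_protein_groups(out / "simulated_protein_groups.tsv", matrix)
        ds.truth.to_csv(out / "ground_truth_proteins.tsv", sep="\t")
    log.info("interphase input: %d proteins", len(matrix))

    # normalisation (per replicate to G1)
    normalized = _stage("normalize")(
        normalize_silac, matrix, "per-replicate-to-reference", "G1")
    pio.write_protein_groups(out / "normalized_protein_groups.tsv", normalized)
    outputs["normalized"] = out / "normalized_protein_groups.tsv"

    # accumulation: bulk profile on the raw (asynchronous-standard) scale
    profile = _stage("accumulation")(bulk_mean_profile, matrix, None)
    profile.to_csv(out / "bulk_profile.csv")
    fit = _stage("accumulation")(
        growth_fit_from_ratios, timeline,
        np.exp2(profile["mean_log2"]))
    (out / "growth_fit.json").write_text(json.dumps(
        {"m": fit.m, "r2": fit.r2, "fold_over_cycle": fit.fold_over_cycle},
        indent=2) + "\n")
    outputs["growth_fit"] = out / "growth_fit.json"

    # selection
    sel_cfg = cfg.selection or SelectionConfig(design="interphase")
    if sel_cfg.design != "interphase":
        sel_cfg = dataclasses.replace(sel_cfg, design="interphase")
    verdicts = _stage("select")(select_candidates, normalized, sel_cfg)
    verdicts.to_csv(out / "verdicts.csv")
    outputs["verdicts"] = out / "verdicts.csv"

    # phospho dynamics
    if cfg.phospho_table:
        meta, quant = _stage("read")(pio.read_phosphosites, cfg.phospho_table)
    else:
        meta, quant, truth = _stage("simulate")(simulate_phosphosites, sim)
        pio.write_phosphosites(out / "simulated_phosphosites.tsv", meta, quant)
        truth.to_csv(out / "ground_truth_sites.tsv", sep="\t")
    res = residue_frequencies(meta)
    motifs = pd.DataFrame([motif_match(w) for w in meta["sequence_window"]],
                          index=meta.index)
    summary = {
        "residue_frequencies": res.to_dict(),
        "proline_directed_fraction": float(motifs["proline_directed"].mean()),
        "full_cdk_fraction": float(motifs["full_cdk_consensus"].mean()),
    }
    (out / "phospho_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    median_sites = replicate_median_profile(quant)
    folds = median_sites.max(axis=1) / median_sites.min(axis=1)
    significant = folds > 2.0  # fold screen for riser classification
    risers = _stage("phospho")(classify_early_risers, quant, significant)
    risers.to_frame().join(meta).to_csv(out / "early_risers.csv")
    outputs["early_risers"] = out / "early_risers.csv"

    _write_provenance(cfg, out)
    return outputs


def run_mitotic_pipeline(cfg: RunConfig) -> dict:
    """Normalise SILAC and TMT -> merge -> select -> cluster -> troughs."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(cfg.simulation, seed=cfg.seed)
    outputs = {}

    tmt_raw = None
    if cfg.protein_table:
        silac, _meta = _stage("read")(pio.read_protein_groups, cfg.protein_table)
        if cfg.tmt_table:
            tmt_raw = pd.read_csv(cfg.tmt_table, sep="\t", index_col="protein_id")
    else:
        ds = _stage("simulate")(simulate_mitotic_dataset, sim)
        silac, tmt_raw = ds.matrix, ds.tmt_reporters
        pio.write_protein_groups(out / "simulated_silac.tsv", silac)
        ds.truth.to_csv(out / "ground_truth_proteins.tsv", sep="\t")
        if tmt_raw is not None:
            tmt_raw.to_csv(out / "simulated_tmt_reporters.tsv", sep="\t",
                           index_label="protein_id")

    silac_norm = _stage("normalize")(
        normalize_silac, silac, "to-reference-of-replicate-1", "Pro")

    if tmt_raw is not None:
        if "Pro" not in cfg.channel_map.values():
            raise PipelineError("normalize", "reference fraction Pro absent from channel map")
        if cfg.impurity_matrix:
            M, channels = pio.read_impurity_matrix(cfg.impurity_matrix)
            tmt_raw = tmt_raw[channels]
        else:
            M = default_impurity_matrix(tmt_raw.shape[1])
        corrected, _clamped = _stage("tmt")(correct_isotope_impurities, tmt_raw, M)
        normalized = _stage("tmt")(normalize_reporters, corrected)
        ratios = _stage("tmt")(reference_ratios, normalized, cfg.channel_map, "Pro")
        mito_cols = [f for f in ("Pro", "PM1", "PM2", "Ana") if f in ratios.columns]
        tmt_matrix = ratios[mito_cols].copy()
        tmt_matrix.columns = pd.MultiIndex.from_product(
            [mito_cols, ["r1"]], names=["fraction", "replicate"])
        merged, stats = _stage("merge")(merge_datasets, silac_norm, tmt_matrix)
        log.info("merge overlap: %d proteins (%.0f%%)", stats.n_overlap,
                 100 * stats.overlap_fraction)
    else:
        log.warning("TMT absent; proceeding with SILAC replicates only")
        merged = silac_norm

    pio.write_protein_groups(out / "normalized_merged.tsv", merged)
    outputs["normalized"] = out / "normalized_merged.tsv"

    sel_cfg = cfg.selection or SelectionConfig(design="mitotic")
    if sel_cfg.design != "mitotic":
        sel_cfg = dataclasses.replace(sel_cfg, design="mitotic")
    verdicts = _stage("select")(select_candidates, merged, sel_cfg)
    verdicts.to_csv(out / "verdicts.csv")
    outputs["verdicts"] = out / "verdicts.csv"

    median = replicate_median_profile(merged)
    hits = verdicts.index[verdicts["significant"] & ~verdicts["rescued"]]
    profiles = prepare_profiles(median.loc[hits])
    if len(profiles) < 2:
        raise PipelineError("cluster", "fewer than 2 significant complete profiles")
    if cfg.cluster_k is not None:
        k = cfg.cluster_k
        wss = None
    else:
        k_range = [k for k in cfg.cluster_k_range if k <= len(profiles)]
        k, wss = _stage("cluster")(choose_k_wss, profiles, k_range, cfg.seed)
    assignment = _stage("cluster")(kmeans_cluster, profiles, k, cfg.seed,
                                   cfg.cluster_restarts)
    clusters = assignment.labels.to_frame()
    clusters.to_csv(out / "clusters.csv")
    outputs["clusters"] = out / "clusters.csv"
    if wss:
        pd.Series(wss, name="wss").rename_axis("k").to_csv(out / "wss_scan.csv")

    groups = _stage("agglomerate")(agglomerate_by_trough, assignment,
                                   median.loc[profiles.index])
    groups.to_csv(out / "trough_groups.csv")
    outputs["trough_groups"] = out / "trough_groups.csv"

    _write_provenance(cfg, out)
    return outputs
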