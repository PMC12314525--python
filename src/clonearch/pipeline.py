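"""End-to-end pipeline orchestration.

Runs the stages of a barcoded drug-resistance analysis in dependency order —
simulate (synthetic inputs), dynamics (fitness + resistance-mode call),
aa (archetypal analysis of expression), atac (TF-IDF/LSI featurization plus
archetypes on the embedding), cnv (purity/ploidy fit and integer copy
numbers) — from a single YAML-serializable configuration.  Every run
directory receives the resolved configuration, a config hash, per-stage
outputs (TSV/JSON) and a log with seeds and wall times, and a rerun with the
same configuration reproduces all outputs byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import archetypes, atacfeat, barcode_io, cnv, dynamics, synthetic

__all__ = ["RunConfig", "run_pipeline", "default_demo_config"]


@dataclass
class RunConfig:
    """Pipeline configuration: stage toggles plus per-stage parameters."""

    out_dir: str = "clonearch_run"
    seed: int = 0
    stages: list[str] = field(
        default_factory=lambda: ["simulate", "dynamics", "aa", "atac", "cnv"]
    )

    # simulate: lineage dynamics + selection scenario
    n_lineages: int = 1000
    birth_rate: float = 0.6
    death_rate: float = 0.1
    duration: float = 30.0
    sample_interval: float = 2.0
    depth_per_timepoint: float = 5000.0
    initial_cells: int = 500
    selection_mode: str = "preexisting"
    n_replicates: int = 3
    resistant_fraction: float = 0.01
    selection_coefficient: float = 0.5
    drug_start: float = 5.0
    drug_end: float = 25.0

    # dynamics
    pseudo_count: float = 0.5
    fold_threshold: float = 5.0
    min_final_freq: float = 0.02
    overlap_threshold: float = 0.5
    smoothing_window: int = 7

    # aa: archetypal analysis on simulated expression
    aa_n_cells: int = 300
    aa_n_features: int = 20
    aa_k: int = 4
    aa_dirichlet_alpha: float = 0.3
    aa_noise_sd: float = 0.05
    aa_variant: str = "classical"
    aa_deep_epochs: int = 800
    aa_deep_hidden: list[int] = field(default_factory=lambda: [64, 64])
    aa_deep_lr: float = 5e-3

    # atac: accessibility simulation + TF-IDF/LSI
    atac_n_cells: int = 200
    atac_n_windows: int = 1000
    atac_n_clones: int = 2
    atac_open_fraction: float = 0.1
    atac_lsi_dim: int = 10

    # cnv
    # median-neutral layout: the median bin sits at the modal state, so the
    # autosome-median centering leaves the generated ratios unchanged
    cnv_segment_layout: list[list[int]] = field(
        default_factory=lambda: [[30, 2], [40, 3], [30, 4]]
    )
    cnv_purity: float = 1.0
    cnv_noise_sd: float = 0.03
    cnv_ploidy_range: list[float] = field(default_factory=lambda: [2.9, 3.3])
    cnv_ploidy_step: float = 0.01
    cnv_fallback_ploidy: float = 3.1

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        payload = asdict(self)
        payload.pop("out_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def default_demo_config(out_dir: str = "clonearch_demo") -> RunConfig:
    """The bundled small demo configuration (single-CPU, minutes)."""
    return RunConfig(out_dir=out_dir)


class PipelineError(RuntimeError):
    pass


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    log_lines: list[str] = []
    chash = config.config_hash()

    def log(msg: str) -> None:
        line = f"[{time.strftime('%H:%M:%S')}] {msg}"
        log_lines.append(line)

    log(f"config hash {chash}; seed {config.seed}")
    versions = {
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    stage_outputs: dict[str, object] = {}

    if "simulate" in config.stages:
        t0 = time.time()
        cfg = synthetic.LineageSimConfig(
            n_lineages=config.n_lineages,
            birth_rate=config.birth_rate,
            death_rate=config.death_rate,
            duration=config.duration,
            sample_interval=config.sample_interval,
            depth_per_timepoint=config.depth_per_timepoint,
            initial_cells=config.initial_cells,
            seed=config.seed,
        )
        scen = synthetic.SelectionScenario(
            mode=config.selection_mode,
            n_replicates=config.n_replicates,
            resistant_fraction=config.resistant_fraction,
            selection_coefficient=config.selection_coefficient,
            drug_start=config.drug_start,
            drug_end=config.drug_end,
        )
        tables = synthetic.simulate_selection_experiment(cfg, scen)
        merged = pd.concat(tables, ignore_index=True)
        barcode_io.write_count_table(merged, out / "counts.tsv")
        stage_outputs["tables"] = tables
        log(f"simulate: {len(tables)} replicates, "
            f"{config.n_lineages} lineages ({time.time() - t0:.1f}s)")

    if "dynamics" in config.stages:
        t0 = time.time()
        if "tables" not in stage_outputs:
            counts_path = out / "counts.tsv"
            if not counts_path.exists():
                raise PipelineError(
                    "dynamics stage needs counts.tsv from the simulate stage"
                )
            merged = barcode_io.read_count_table(counts_path)
            tables = [g for _, g in merged.groupby("replicate", sort=False)]
        else:
            tables = stage_outputs["tables"]  # type: ignore[assignment]
        fits = []
        for tab in tables:
            freqs = dynamics.relative_abundances(tab, config.pseudo_count)
            fits.append(dynamics.fit_fitness(freqs))
        fitness = pd.concat(fits, ignore_index=True)
        fitness.to_csv(out / "fitness.tsv", sep="\t", index=False)
        call = dynamics.analyze_selection_tables(
            tables,
            pseudo_count=config.pseudo_count,
            fold_threshold=config.fold_threshold,
            min_final_freq=config.min_final_freq,
            overlap_threshold=config.overlap_threshold,
        )
        report = call.to_dict()
        report["config_hash"] = chash
        report["versions"] = versions
        (out / "resistance_mode.json").write_text(json.dumps(report, indent=2))
        log(f"dynamics: mode={call.mode} ({time.time() - t0:.1f}s)")

    if "aa" in config.stages:
        t0 = time.time()
        acfg = synthetic.ArchetypeSimConfig(
            n_cells=config.aa_n_cells,
            n_features=config.aa_n_features,
            n_archetypes=config.aa_k,
            dirichlet_alpha=config.aa_dirichlet_alpha,
            noise_sd=config.aa_noise_sd,
            seed=config.seed,
        )
        X, _, _ = synthetic.simulate_archetype_expression(acfg)
        if config.aa_variant == "deep":
            model = archetypes.fit_archetypes_deep(
                X, config.aa_k,
                hidden_sizes=tuple(config.aa_deep_hidden),
                epochs=config.aa_deep_epochs,
                learning_rate=config.aa_deep_lr,
                seed=config.seed,
            )
        else:
            model = archetypes.fit_archetypes_classical(X, config.aa_k,
                                                        seed=config.seed)
        np.savetxt(out / "aa_A.tsv", model.A, delimiter="\t")
        np.savetxt(out / "aa_Z.tsv", model.Z, delimiter="\t")
        meta = {
            "variant": model.variant, "K": model.K, "loss": model.loss,
            "config_hash": chash,
            "fit_metadata": {
                k: v for k, v in model.fit_metadata.items() if k != "loss_history"
            },
        }
        (out / "aa_model.json").write_text(json.dumps(meta, indent=2))
        stage_outputs["aa_model"] = model
        log(f"aa: variant={model.variant} K={model.K} "
            f"loss={model.loss:.4g} ({time.time() - t0:.1f}s)")

    if "atac" in config.stages:
        t0 = time.time()
        rng = np.random.default_rng(config.seed)
        clones = [f"clone{i % config.atac_n_clones}" for i in range(config.atac_n_cells)]
        Xb, bed = synthetic.simulate_accessibility(
            config.atac_n_cells, config.atac_n_windows, clones,
            config.atac_open_fraction, seed=config.seed,
        )
        T = atacfeat.tfidf(Xb)
        emb = atacfeat.lsi(T, d=config.atac_lsi_dim, seed=config.seed)
        df = pd.DataFrame(
            emb.components,
            columns=[f"LSI{i + 1}" for i in range(emb.components.shape[1])],
        )
        df.insert(0, "clone", clones)
        df.to_csv(out / "atac_lsi.tsv", sep="\t", index=False)
        bed.to_csv(out / "atac_windows.bed", sep="\t", header=False, index=False)
        del rng
        log(f"atac: {config.atac_n_cells} cells x {config.atac_n_windows} windows, "
            f"d={config.atac_lsi_dim} ({time.time() - t0:.1f}s)")

    if "cnv" in config.stages:
        t0 = time.time()
        layout = [(int(l), int(c)) for l, c in config.cnv_segment_layout]
        ccfg = synthetic.CnSimConfig(
            segment_layout=layout, purity=config.cnv_purity,
            noise_sd=config.cnv_noise_sd, seed=config.seed,
        )
        track = synthetic.simulate_logratio_bins(ccfg)
        track = cnv.normalize_median(track)
        fit = cnv.fit_purity_ploidy(
            track,
            ploidy_range=tuple(config.cnv_ploidy_range),
            ploidy_step=config.cnv_ploidy_step,
            fallback_ploidy=config.cnv_fallback_ploidy,
        )
        calls = cnv.assign_integer_cn(fit)
        calls[["chrom", "start", "end", "copy_number"]].to_csv(
            out / "cnv_calls.bed", sep="\t", header=False, index=False
        )
        summary = {
            "purity": fit.purity, "ploidy": fit.ploidy, "ssd": fit.ssd,
            "used_fallback": fit.used_fallback, "true_ploidy": ccfg.true_ploidy,
            "config_hash": chash,
        }
        (out / "cnv_fit.json").write_text(json.dumps(summary, indent=2))
        log(f"cnv: purity={fit.purity:.3f} ploidy={fit.ploidy:.2f} "
            f"fallback={fit.used_fallback} ({time.time() - t0:.1f}s)")

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
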