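"""Synthetic data generators for lineage-barcode evolution experiments.

Every generator emulates one of the observables of a lentiviral-barcoded
drug-resistance evolution experiment on patient-derived organoids:

* longitudinal barcode read-count tables (live cells and "floating" barcodes
  released by dying cells into the culture medium),
* replicated selection experiments with preexisting, de-novo or plastic
  (nonheritable) resistance,
* single-cell expression matrices with convex-combination archetype structure,
* binary cell x 500-bp-window chromatin-accessibility matrices,
* low-pass WGS-style per-bin log2 copy-number ratios under a purity/ploidy
  mixture model.

All generators are deterministic under a fixed seed and return plain
numpy/pandas/scipy objects in the formats the analysis modules consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "LineageSimConfig",
    "SelectionScenario",
    "ArchetypeSimConfig",
    "CnSimConfig",
    "LineageTruth",
    "PopulationExtinctError",
    "simulate_lineage_truth",
    "simulate_barcode_drift",
    "simulate_selection_experiment",
    "simulate_floating_barcodes",
    "simulate_archetype_expression",
    "simulate_accessibility",
    "simulate_logratio_bins",
]

PHASE_PARENTAL = "parental"
PHASE_DRUG = "drug"
PHASE_REGROWTH = "regrowth"


class PopulationExtinctError(RuntimeError):
    """Raised when every lineage is extinct before the first requested sample."""


@dataclass
class LineageSimConfig:
    """Configuration of the latent birth-death lineage dynamics.

    Rates are per day.  ``depth_per_timepoint`` is the *expected* number of
    reads per sampled timepoint; the realized depth is Poisson distributed.
    ``initial_cells`` is the number of cells per lineage at day 0 (single-cell
    founders for a freshly infected library; hundreds of cells per lineage for
    an expanded population split into wells).
    """

    n_lineages: int
    birth_rate: float
    death_rate: float
    duration: float
    sample_interval: float = 2.0
    depth_per_timepoint: float = 5000.0
    initial_cells: int = 1
    dt: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lineages <= 0:
            raise ValueError("n_lineages must be positive")
        if self.birth_rate < 0 or self.death_rate < 0:
            raise ValueError("rates must be nonnegative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.depth_per_timepoint <= 0:
            raise ValueError("depth_per_timepoint must be positive")
        if self.initial_cells < 0:
            raise ValueError("initial_cells must be nonnegative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def sample_times(self) -> np.ndarray:
        n = int(np.floor(self.duration / self.sample_interval + 1e-9))
        return np.round(np.arange(n + 1) * self.sample_interval, 9)


@dataclass
class SelectionScenario:
    """A replicated drug-selection experiment design.

    ``mode`` selects how resistance is wired into the lineages:

    * ``preexisting`` — a single lineage subset (fraction ``resistant_fraction``)
      carries a heritable growth advantage ``selection_coefficient`` (per day)
      during the drug window, and that same subset is resistant in every
      replicate.
    * ``de_novo`` — an independently drawn subset per replicate becomes
      resistant at ``drug_start`` (resistance acquired under treatment).
    * ``plastic`` — no lineage has a heritable fitness difference; drug
      exposure is modeled as uniform random survival thinning at
      ``drug_start`` (surviving cell fraction = ``resistant_fraction``),
      which shrinks the population without enriching any barcode.

    ``drug_kill_rate`` is an extra death rate applied to drug-sensitive
    lineages inside the drug window for the two heritable modes, so the bulk
    population contracts under treatment as in a real experiment.
    """

    mode: str
    n_replicates: int = 3
    resistant_fraction: float = 0.01
    selection_coefficient: float = 0.5
    drug_start: float = 5.0
    drug_end: float = 25.0
    drug_kill_rate: float = 0.3

    def __post_init__(self) -> None:
        if self.mode not in {"preexisting", "de_novo", "plastic"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")
        if not 0.0 <= self.resistant_fraction <= 1.0:
            raise ValueError("resistant_fraction must be in [0, 1]")
        if self.resistant_fraction == 0.0 and self.mode != "plastic":
            raise ValueError(
                "resistant_fraction = 0 is only meaningful for plastic mode"
            )
        if not self.drug_start < self.drug_end:
            raise ValueError("drug_start must precede drug_end")


@dataclass
class ArchetypeSimConfig:
    """Cells as noisy convex combinations of K archetypal expression profiles."""

    n_cells: int
    n_features: int
    n_archetypes: int
    dirichlet_alpha: float = 0.3
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_archetypes < 1:
            raise ValueError("need at least one archetype")
        if self.n_archetypes > self.n_cells:
            raise ValueError("n_archetypes may not exceed n_cells")
        if self.dirichlet_alpha <= 0:
            raise ValueError("dirichlet_alpha must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class CnSimConfig:
    """Piecewise-constant integer copy-number genome observed as log2 ratios.

    ``segment_layout`` is a list of ``(length_in_bins, integer_copy_number)``
    pairs tiling the genome left to right.  The implied average (true) ploidy
    is the bin-length-weighted mean copy number.
    """

    segment_layout: Sequence[tuple[int, int]]
    purity: float = 1.0
    noise_sd: float = 0.0
    bin_size: int = 500_000
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.segment_layout:
            raise ValueError("segment_layout must be non-empty")
        for length, cn in self.segment_layout:
            if length <= 0:
                raise ValueError("segment lengths must be positive")
            if int(cn) != cn or cn < 0:
                raise ValueError("copy numbers must be nonnegative integers")
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @property
    def n_bins(self) -> int:
        return int(sum(length for length, _ in self.segment_layout))

    @property
    def true_ploidy(self) -> float:
        lengths = np.array([l for l, _ in self.segment_layout], dtype=float)
        cns = np.array([c for _, c in self.segment_layout], dtype=float)
        return float(np.sum(lengths * cns) / np.sum(lengths))


@dataclass
class LineageTruth:
    """Latent lineage trajectories from the birth-death engine.

    ``sizes`` holds live-cell counts per lineage at each sample time;
    ``deaths`` holds the number of cell deaths per lineage inside the interval
    ``(t_prev, t]`` ending at each sample time (zeros for the first sample).
    Death flux is what "floating" barcode DNA in the culture supernatant
    reports, since the medium is replaced at every sampling.
    """

    sample_times: np.ndarray  # (T,)
    sizes: np.ndarray  # (n_lineages, T) int64
    deaths: np.ndarray  # (n_lineages, T) int64
    lineage_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.lineage_ids:
            self.lineage_ids = make_lineage_ids(self.sizes.shape[0])


def make_lineage_ids(n: int) -> list[str]:
    width = max(4, len(str(n - 1)) if n > 1 else 4)
    return [f"BC{i:0{width}d}" for i in range(n)]


# ---------------------------------------------------------------------------
# birth-death engine


def _evolve(
    sizes0: np.ndarray,
    sample_times: np.ndarray,
    dt: float,
    rate_fn: Callable[[float], tuple[np.ndarray, np.ndarray]],
    rng: np.random.Generator,
    thinning_events: Sequence[tuple[float, float]] = (),
) -> LineageTruth:
    """Discrete-time branching process with Poisson birth/death increments.

    ``rate_fn(t)`` returns per-lineage (birth, death) rate vectors for the step
    starting at ``t``.  ``thinning_events`` are ``(time, survival_fraction)``
    pairs applied instantaneously (binomial survival per cell) the first time
    the clock passes ``time``.
    """
    sizes = np.asarray(sizes0, dtype=np.int64).copy()
    n = sizes.shape[0]
    times = np.asarray(sample_times, dtype=float)
    n_steps = int(np.ceil(times[-1] / dt - 1e-9))

    out_sizes = np.zeros((n, len(times)), dtype=np.int64)
    out_deaths = np.zeros((n, len(times)), dtype=np.int64)
    death_accum = np.zeros(n, dtype=np.int64)

    pending = sorted(thinning_events)
    next_sample = 0
    t = 0.0
    # record samples that fall exactly at t=0
    while next_sample < len(times) and times[next_sample] <= t + 1e-9:
        out_sizes[:, next_sample] = sizes
        out_deaths[:, next_sample] = death_accum
        death_accum[:] = 0
        next_sample += 1

    for step in range(n_steps):
        while pending and pending[0][0] <= t + 1e-9:
            _, surv = pending.pop(0)
            sizes = rng.binomial(sizes, surv)
        birth_r, death_r = rate_fn(t)
        step_dt = min(dt, times[-1] - t)
        births = rng.poisson(sizes * birth_r * step_dt)
        deaths = rng.poisson(sizes * death_r * step_dt)
        deaths = np.minimum(deaths, sizes + births)
        sizes = sizes + births - deaths
        death_accum += deaths
        t = round((step + 1) * dt, 12)
        while next_sample < len(times) and times[next_sample] <= t + 1e-9:
            out_sizes[:, next_sample] = sizes
            out_deaths[:, next_sample] = death_accum
            death_accum[:] = 0
            next_sample += 1
    return LineageTruth(sample_times=times, sizes=out_sizes, deaths=out_deaths)


def _sample_reads(
    weights: np.ndarray, depth: float, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial read sample at Poisson-realized depth; zero weights -> zeros."""
    total = weights.sum()
    counts = np.zeros(weights.shape[0], dtype=np.int64)
    if total <= 0:
        return counts
    n_reads = rng.poisson(depth)
    if n_reads == 0:
        return counts
    return rng.multinomial(n_reads, weights / total).astype(np.int64)


def _counts_table(
    sample_times: np.ndarray,
    counts: np.ndarray,
    lineage_ids: Sequence[str],
    phases: Sequence[str],
    replicate: str,
) -> pd.DataFrame:
    n, t = counts.shape
    return pd.DataFrame(
        {
            "barcode_id": np.repeat(list(lineage_ids), t),
            "replicate": replicate,
            "timepoint_day": np.tile(sample_times, n),
            "phase": np.tile(list(phases), n),
            "count": counts.reshape(-1),
        }
    )


def simulate_lineage_truth(cfg: LineageSimConfig) -> LineageTruth:
    """Run the neutral (constant-rate) birth-death process for all lineages."""
    rng = np.random.default_rng(cfg.seed)
    sizes0 = np.full(cfg.n_lineages, cfg.initial_cells, dtype=np.int64)
    birth = np.full(cfg.n_lineages, cfg.birth_rate)
    death = np.full(cfg.n_lineages, cfg.death_rate)
    return _evolve(
        sizes0, cfg.sample_times, cfg.dt, lambda t: (birth, death), rng
    )


def simulate_barcode_drift(
    cfg: LineageSimConfig,
    truth: LineageTruth | None = None,
    replicate: str = "R1",
) -> pd.DataFrame:
    """Neutral-drift barcode count table (live-cell sampling).

    Returns the standard long-format count table with one row per
    (barcode, timepoint).  Raises :class:`PopulationExtinctError` if the whole
    population is extinct at the first sample.
    """
    if truth is None:
        truth = simulate_lineage_truth(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    if truth.sizes[:, 0].sum() == 0:
        raise PopulationExtinctError("population extinct before first sample")
    counts = np.column_stack(
        [
            _sample_reads(truth.sizes[:, j].astype(float), cfg.depth_per_timepoint, rng)
            for j in range(len(truth.sample_times))
        ]
    )
    phases = [PHASE_PARENTAL] * len(truth.sample_times)
    return _counts_table(truth.sample_times, counts, truth.lineage_ids, phases, replicate)


def simulate_floating_barcodes(
    truth: LineageTruth, cfg: LineageSimConfig, replicate: str = "R1"
) -> pd.DataFrame:
    """Barcode reads from the death flux (supernatant DNA) between samples.

    Media are assumed replaced at every sampling, so each sample reflects only
    deaths since the previous one.  Intervals with zero deaths yield all-zero
    count rows (an empty sample, not an error).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    counts = np.column_stack(
        [
            _sample_reads(truth.deaths[:, j].astype(float), cfg.depth_per_timepoint, rng)
            for j in range(len(truth.sample_times))
        ]
    )
    phases = [PHASE_PARENTAL] * len(truth.sample_times)
    return _counts_table(truth.sample_times, counts, truth.lineage_ids, phases, replicate)


def _phase_labels(times: np.ndarray, scen: SelectionScenario) -> list[str]:
    labels = []
    for t in times:
        if t < scen.drug_start - 1e-9:
            labels.append(PHASE_PARENTAL)
        elif t <= scen.drug_end + 1e-9:
            labels.append(PHASE_DRUG)
        else:
            labels.append(PHASE_REGROWTH)
    return labels


def simulate_selection_experiment(
    cfg: LineageSimConfig, scen: SelectionScenario
) -> list[pd.DataFrame]:
    """Replicated drug-selection experiment; one count table per replicate.

    The resistant lineage subset is shared across replicates (preexisting),
    drawn independently per replicate (de_novo), or absent with survival
    thinning instead (plastic).  Resistant lineages gain
    ``selection_coefficient`` of birth rate inside the drug window; sensitive
    lineages suffer ``drug_kill_rate`` extra death there.
    """
    master = np.random.SeedSequence(cfg.seed)
    ids = make_lineage_ids(cfg.n_lineages)
    n_res = int(round(scen.resistant_fraction * cfg.n_lineages))

    pick_rng = np.random.default_rng(master.spawn(1)[0])
    shared_resistant = (
        pick_rng.choice(cfg.n_lineages, size=n_res, replace=False)
        if n_res > 0
        else np.array([], dtype=int)
    )

    times = cfg.sample_times
    phases = _phase_labels(times, scen)
    tables: list[pd.DataFrame] = []
    for r in range(scen.n_replicates):
        rep_seq = np.random.SeedSequence([cfg.seed, 100 + r])
        rng = np.random.default_rng(rep_seq)
        if scen.mode == "preexisting":
            resistant = shared_resistant
        elif scen.mode == "de_novo":
            resistant = rng.choice(cfg.n_lineages, size=n_res, replace=False)
        else:
            resistant = np.array([], dtype=int)

        res_mask = np.zeros(cfg.n_lineages, dtype=bool)
        res_mask[resistant] = True

        base_birth = np.full(cfg.n_lineages, cfg.birth_rate)
        base_death = np.full(cfg.n_lineages, cfg.death_rate)

        def rates(t: float) -> tuple[np.ndarray, np.ndarray]:
            if scen.drug_start - 1e-9 <= t < scen.drug_end - 1e-9:
                birth = base_birth + scen.selection_coefficient * res_mask
                if scen.mode == "plastic":
                    death = base_death
                else:
                    death = base_death + scen.drug_kill_rate * (~res_mask)
                return birth, death
            return base_birth, base_death

        thinning = (
            [(scen.drug_start, scen.resistant_fraction)]
            if scen.mode == "plastic"
            else []
        )
        sizes0 = np.full(cfg.n_lineages, cfg.initial_cells, dtype=np.int64)
        truth = _evolve(sizes0, times, cfg.dt, rates, rng, thinning_events=thinning)
        truth.lineage_ids = ids
        read_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 200 + r]))
        counts = np.column_stack(
            [
                _sample_reads(
                    truth.sizes[:, j].astype(float), cfg.depth_per_timepoint, read_rng
                )
                for j in range(len(times))
            ]
        )
        tables.append(_counts_table(times, counts, ids, phases, f"R{r + 1}"))
    return tables


# ---------------------------------------------------------------------------
# expression / accessibility / copy-number generators


def simulate_archetype_expression(
    cfg: ArchetypeSimConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cells as convex combinations of K archetypes plus Gaussian noise.

    Returns ``(X, A, Z)`` with ``X = A @ Z + noise`` where rows of ``A`` are
    Dirichlet(alpha) mixture weights and ``Z`` (K x M) holds the archetypal
    feature profiles (on a Z-scored expression scale).
    """
    rng = np.random.default_rng(cfg.seed)
    K, M, N = cfg.n_archetypes, cfg.n_features, cfg.n_cells
    # well-separated vertices on the Z-score scale
    Z = rng.normal(0.0, 2.0, size=(K, M))
    while K > 1 and np.min(
        np.linalg.norm(Z[:, None, :] - Z[None, :, :], axis=2) + np.eye(K) * 1e9
    ) < 1e-6:  # pragma: no cover - astronomically unlikely
        Z = rng.normal(0.0, 2.0, size=(K, M))
    A = rng.dirichlet(np.full(K, cfg.dirichlet_alpha), size=N)
    X = A @ Z + rng.normal(0.0, cfg.noise_sd, size=(N, M))
    return X, A, Z


def simulate_accessibility(
    n_cells: int,
    n_windows: int,
    clone_labels: Sequence[str],
    clone_specific_open_fraction: float,
    seed: int = 0,
    base_open_prob: float = 0.2,
    specific_open_prob: float = 0.8,
    background_open_prob: float = 0.02,
) -> tuple[sp.csr_matrix, pd.DataFrame]:
    """Binary cell x window accessibility with clone-specific open sets.

    Each clone receives a disjoint block of ``clone_specific_open_fraction``
    of the windows that are open with high probability in that clone and
    nearly closed in the others; remaining windows are shared background open
    with ``base_open_prob``.  Returns the sparse binary matrix and a BED-style
    window table (0-based half-open, width 500).
    """
    labels = list(clone_labels)
    if len(labels) != n_cells:
        raise ValueError("clone_labels length must equal n_cells")
    if not 0.0 <= clone_specific_open_fraction <= 1.0:
        raise ValueError("clone_specific_open_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    clones = sorted(set(labels))
    n_spec = int(round(clone_specific_open_fraction * n_windows))
    if n_spec * len(clones) > n_windows:
        raise ValueError("clone-specific sets exceed the window universe")

    open_prob = np.full((len(clones), n_windows), base_open_prob)
    pos = 0
    for ci in range(len(clones)):
        if n_spec == 0:
            break
        block = slice(pos, pos + n_spec)
        open_prob[:, block] = background_open_prob
        open_prob[ci, block] = specific_open_prob
        pos += n_spec

    clone_idx = np.array([clones.index(l) for l in labels])
    X = (rng.random((n_cells, n_windows)) < open_prob[clone_idx]).astype(np.int8)
    bed = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n_windows, dtype=np.int64) * 500,
            "end": (np.arange(n_windows, dtype=np.int64) + 1) * 500,
        }
    )
    return sp.csr_matrix(X), bed


def simulate_logratio_bins(cfg: CnSimConfig) -> pd.DataFrame:
    """Per-bin log2 ratios from an integer copy-number layout.

    The observed ratio follows the two-state purity mixture: a bin with tumor
    copy number ``n`` in a sample of purity ``rho`` and tumor ploidy ``psi``
    has expected log2 ratio ``log2((rho*n + 2(1-rho)) / (rho*psi + 2(1-rho)))``
    (normal contamination is diploid), plus Gaussian noise.
    """
    rng = np.random.default_rng(cfg.seed)
    rho, psi = cfg.purity, cfg.true_ploidy
    cn = np.concatenate(
        [np.full(length, c, dtype=float) for length, c in cfg.segment_layout]
    )
    seg_id = np.concatenate(
        [
            np.full(length, i, dtype=np.int64)
            for i, (length, _) in enumerate(cfg.segment_layout)
        ]
    )
    num = rho * cn + 2.0 * (1.0 - rho)
    den = rho * psi + 2.0 * (1.0 - rho)
    with np.errstate(divide="ignore"):
        r = np.log2(num / den)
    r = r + rng.normal(0.0, cfg.noise_sd, size=r.shape) if cfg.noise_sd > 0 else r
    starts = np.arange(cfg.n_bins, dtype=np.int64) * cfg.bin_size
    return pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "start": starts,
            "end": starts + cfg.bin_size,
            "log2_ratio": r,
            "segment_id": seg_id,
            "true_copy_number": cn.astype(np.int64),
        }
    )
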