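"""Absolute copy-number calling from low-pass log2-ratio tracks.

Read depth in fixed genomic bins (500 kb by default) is summarized as a log2
ratio against the sample average; given a segmentation, absolute integer copy
numbers are obtained by searching a (purity, ploidy) grid for the solution
whose implied continuous copy numbers

    n_b = ( 2^{r_b} * (rho * psi + 2 (1 - rho)) - 2 (1 - rho) ) / rho

fall closest to positive integers (sum of squared differences, SSD).  The
search runs on autosome segmented bins only; the X chromosome copy number is
inferred afterwards from the selected solution.  Organoid samples are
essentially pure, so the purity floor defaults to 0.98; when the SSD surface
has no strict local minimum (e.g. a flat genome carries no ploidy
information), a declared fallback ploidy with purity 1 is returned instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PurityPloidyFit",
    "normalize_median",
    "segment_means",
    "fit_purity_ploidy",
    "assign_integer_cn",
]

TRACK_COLUMNS = ["chrom", "start", "end", "log2_ratio", "segment_id"]

_SEX_CHROMS = {"chrX", "X", "chrY", "Y"}


def _is_autosome(chrom: pd.Series) -> np.ndarray:
    return ~chrom.astype(str).isin(_SEX_CHROMS).to_numpy()


@dataclass
class PurityPloidyFit:
    """Grid-search result for the absolute copy-number model."""

    purity: float
    ploidy: float
    ssd: float
    used_fallback: bool
    grid_purity: np.ndarray
    grid_ploidy: np.ndarray
    grid_ssd: np.ndarray  # (n_purity, n_ploidy)
    track: pd.DataFrame = field(repr=False, default=None)
    segmented_log2: np.ndarray = field(repr=False, default=None)


def normalize_median(track: pd.DataFrame) -> pd.DataFrame:
    """Subtract the median autosome log2 ratio from every bin.

    Centering uses autosome bins only but is applied to all bins including X,
    so the autosomal median of the output is exactly zero.  Idempotent.
    """
    auto = _is_autosome(track["chrom"])
    if not auto.any():
        raise ValueError("no autosome bins available for normalization")
    med = float(np.median(track.loc[auto, "log2_ratio"]))
    out = track.copy()
    out["log2_ratio"] = out["log2_ratio"] - med
    return out


def segment_means(track: pd.DataFrame) -> np.ndarray:
    """Per-bin segmented value: the mean log2 ratio of the bin's segment."""
    if "segment_id" not in track.columns:
        raise ValueError("track must carry a segment_id column")
    return (
        track.groupby("segment_id")["log2_ratio"].transform("mean").to_numpy()
    )


def _continuous_cn(r: np.ndarray, purity: float, ploidy: float) -> np.ndarray:
    """Invert the purity-mixture model: observed log2 ratio -> tumor copy number."""
    return (2.0**r * (purity * ploidy + 2.0 * (1.0 - purity))
            - 2.0 * (1.0 - purity)) / purity


def _round_positive(n_cont: np.ndarray, allow_zero: bool = False) -> np.ndarray:
    """Nearest integer with a floor at 1 (or 0 when allow_zero)."""
    floor = 0 if allow_zero else 1
    return np.maximum(np.rint(n_cont), floor).astype(np.int64)


def fit_purity_ploidy(
    track: pd.DataFrame,
    ploidy_range: tuple[float, float],
    purity_range: tuple[float, float] = (0.98, 1.0),
    ploidy_step: float = 0.005,
    purity_step: float = 0.002,
    fallback_ploidy: float = 3.1,
    allow_zero_cn: bool = False,
) -> PurityPloidyFit:
    """Purity/ploidy grid search on autosome segmented log2 ratios.

    For each grid point the SSD between the continuous copy number of every
    autosome bin (computed from the bin's segment-mean log2 ratio) and its
    nearest positive integer is evaluated.  A candidate solution is a grid
    point strictly smaller than all of its existing neighbors (8-connected;
    edge points compete against the neighbors they have, but points on the
    ploidy-range boundary are ineligible); the candidate with the smallest
    SSD wins, ties broken toward higher purity, then toward ploidy closest to
    the range midpoint.  With no candidate (e.g. a flat genome, where the SSD
    surface is constant in purity), the declared ``fallback_ploidy`` is
    returned with purity 1 and ``used_fallback`` set.
    """
    auto = _is_autosome(track["chrom"])
    if not auto.any():
        raise ValueError("no autosome bins to fit")
    lo_pl, hi_pl = ploidy_range
    lo_pu, hi_pu = purity_range
    if not (lo_pl < hi_pl and lo_pu < hi_pu):
        raise ValueError("ranges must be non-degenerate")

    seg = segment_means(track)
    r_auto = seg[auto]

    ploidies = np.round(np.arange(lo_pl, hi_pl + ploidy_step / 2, ploidy_step), 10)
    purities = np.round(np.arange(lo_pu, hi_pu + purity_step / 2, purity_step), 10)
    grid = np.empty((len(purities), len(ploidies)))
    for i, rho in enumerate(purities):
        for j, psi in enumerate(ploidies):
            n_cont = _continuous_cn(r_auto, rho, psi)
            n_int = _round_positive(n_cont, allow_zero=allow_zero_cn)
            grid[i, j] = float(np.sum((n_cont - n_int) ** 2))

    candidates = []
    for i in range(len(purities)):
        for j in range(1, len(ploidies) - 1):  # ploidy boundary ineligible
            val = grid[i, j]
            # ties within floating noise do not count as strict minima
            tie_tol = 1e-9 * (1.0 + abs(val))
            neigh = grid[max(i - 1, 0): i + 2, j - 1: j + 2]
            if np.sum(neigh < val - tie_tol) == 0 and \
                    np.sum(np.abs(neigh - val) <= tie_tol) == 1:
                candidates.append((val, -purities[i],
                                   abs(ploidies[j] - (lo_pl + hi_pl) / 2), i, j))
    if candidates:
        candidates.sort()
        _, _, _, i, j = candidates[0]
        fit = PurityPloidyFit(
            purity=float(purities[i]), ploidy=float(ploidies[j]),
            ssd=float(grid[i, j]), used_fallback=False,
            grid_purity=purities, grid_ploidy=ploidies, grid_ssd=grid,
            track=track, segmented_log2=seg,
        )
    else:
        n_cont = _continuous_cn(r_auto, 1.0, fallback_ploidy)
        n_int = _round_positive(n_cont, allow_zero=allow_zero_cn)
        fit = PurityPloidyFit(
            purity=1.0, ploidy=float(fallback_ploidy),
            ssd=float(np.sum((n_cont - n_int) ** 2)), used_fallback=True,
            grid_purity=purities, grid_ploidy=ploidies, grid_ssd=grid,
            track=track, segmented_log2=seg,
        )
    return fit


def assign_integer_cn(fit: PurityPloidyFit, allow_zero_cn: bool = False) -> pd.DataFrame:
    """Per-bin integer copy numbers (all chromosomes) at the selected solution.

    The continuous copy number of every bin's segment mean is converted at the
    fitted (purity, ploidy) and rounded to the nearest positive integer;
    bins whose continuous value fell below 0.5 are clamped to 1 and flagged
    ``low_cn`` (use ``allow_zero_cn`` to permit homozygous-deletion calls).
    The X chromosome is converted with the same solution.
    """
    track = fit.track
    n_cont = _continuous_cn(fit.segmented_log2, fit.purity, fit.ploidy)
    n_int = _round_positive(n_cont, allow_zero_cn)
    out = track.copy()
    out["copy_number_continuous"] = n_cont
    out["copy_number"] = n_int
    out["low_cn"] = (n_cont < 0.5) & ~allow_zero_cn
    return out
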