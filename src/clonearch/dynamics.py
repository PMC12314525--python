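"""Barcode evolutionary modeling.

Longitudinal barcode abundances are modeled under exponential growth: if
lineage i grows at effective rate w_i and the population average rate is
w-bar, the relative abundance obeys

    f_i(T) = f_i(0) * exp(Delta_w_i * T),       Delta_w_i = w_i - w_bar,

so ln f_i(T) is linear in time and Delta_w (per day) is the OLS slope of the
log relative abundance.  The module also provides the rolling-mean trajectory
smoother used for plotting floating-barcode dynamics, a discrete power-law
tail fit serving as the neutral-drift null for clone sizes, and the
replicate-concordance classification of resistance mode (preexisting vs
de-novo heritable vs plastic).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "EmptySampleError",
    "InsufficientTailError",
    "relative_abundances",
    "fit_fitness",
    "smooth_trajectories",
    "rolling_mean",
    "powerlaw_null_fit",
    "powerlaw_bootstrap",
    "sample_discrete_powerlaw",
    "call_enriched",
    "classify_resistance_mode",
    "analyze_selection_tables",
    "ResistanceModeCall",
]

COUNT_COLUMNS = ["barcode_id", "replicate", "timepoint_day", "phase", "count"]


class EmptySampleError(ValueError):
    """A (replicate, timepoint) sample contains zero reads in total."""


class InsufficientTailError(ValueError):
    """Too few observations above x_min for a power-law tail fit."""


# ---------------------------------------------------------------------------
# abundances and fitness


def relative_abundances(counts: pd.DataFrame, pseudo_count: float = 0.5) -> pd.DataFrame:
    """Convert a barcode count table to relative abundances.

    For each (replicate, timepoint) the frequency of barcode i is
    ``(c_i + pseudo_count) / sum_j (c_j + pseudo_count)`` over the barcode
    universe of that replicate, so frequencies sum to one at every timepoint.
    A timepoint whose raw counts are all zero raises
    :class:`EmptySampleError` naming the sample.
    """
    df = counts.copy()
    if (df["count"] < 0).any():
        raise ValueError("counts must be nonnegative")
    totals = df.groupby(["replicate", "timepoint_day"])["count"].sum()
    empty = totals[totals == 0]
    if len(empty) > 0:
        rep, t = empty.index[0]
        raise EmptySampleError(f"empty sample: replicate {rep!r} at day {t}")

    out = []
    for rep, sub in df.groupby("replicate", sort=False):
        wide = sub.pivot_table(
            index="barcode_id", columns="timepoint_day", values="count",
            aggfunc="sum", fill_value=0,
        )
        shifted = wide.to_numpy(dtype=float) + pseudo_count
        freq = shifted / shifted.sum(axis=0, keepdims=True)
        phase_of = dict(
            sub.drop_duplicates("timepoint_day")[["timepoint_day", "phase"]].values
        )
        long = pd.DataFrame(freq, index=wide.index, columns=wide.columns)
        long = long.reset_index().melt(
            id_vars="barcode_id", var_name="timepoint_day", value_name="frequency"
        )
        long["replicate"] = rep
        long["phase"] = long["timepoint_day"].map(phase_of)
        out.append(long)
    res = pd.concat(out, ignore_index=True)
    res["pseudo_count_used"] = pseudo_count
    return res[
        ["barcode_id", "replicate", "timepoint_day", "phase", "frequency",
         "pseudo_count_used"]
    ]


def _ols_slopes(t: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise OLS of Y (rows) on t; NaN entries in Y are excluded per row.

    Returns (slope, intercept, stderr).  Rows with fewer than two finite
    points get NaN slope; rows with exactly two points or a perfect fit get
    stderr 0.
    """
    mask = np.isfinite(Y)
    n = mask.sum(axis=1).astype(float)
    W = mask.astype(float)
    Y0 = np.where(mask, Y, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_mean = (W * t).sum(axis=1) / n
        y_mean = Y0.sum(axis=1) / n
        t_c = (t[None, :] - t_mean[:, None]) * W
        y_c = (Y0 - y_mean[:, None]) * W
        sxx = (t_c**2).sum(axis=1)
        sxy = (t_c * y_c).sum(axis=1)
        slope = sxy / sxx
        intercept = y_mean - slope * t_mean
        rss = (y_c**2).sum(axis=1) - slope * sxy
        rss = np.maximum(rss, 0.0)
        dof = np.maximum(n - 2.0, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            stderr = np.sqrt(np.where(dof > 0, rss / np.where(dof > 0, dof, 1.0), 0.0) / sxx)
    bad = (n < 2) | (sxx <= 0)
    slope[bad] = np.nan
    intercept[bad] = np.nan
    stderr[bad] = np.nan
    return slope, intercept, stderr


def fit_fitness(freqs: pd.DataFrame, by_phase: bool = True) -> pd.DataFrame:
    """Estimate per-barcode relative growth rates Delta_w by OLS on log abundance.

    One ordinary-least-squares line of ``ln f_i(T)`` on ``T`` (days) is fitted
    per barcode (and per contiguous experimental phase when ``by_phase``);
    the slope is Delta_w in 1/day.  Timepoints with zero frequency (possible
    only when the abundances were built with ``pseudo_count=0``) are excluded;
    barcodes with fewer than two usable timepoints are reported with NaN
    Delta_w rather than dropped.
    """
    group_cols = ["replicate", "phase"] if by_phase else ["replicate"]
    rows = []
    for keys, sub in freqs.groupby(group_cols, sort=False):
        wide = sub.pivot_table(
            index="barcode_id", columns="timepoint_day", values="frequency"
        )
        t = wide.columns.to_numpy(dtype=float)
        F = wide.to_numpy(dtype=float)
        with np.errstate(divide="ignore"):
            L = np.where(F > 0, np.log(np.where(F > 0, F, 1.0)), np.nan)
        if len(t) >= 2:
            slope, intercept, stderr = _ols_slopes(t, L)
        else:
            slope = np.full(len(wide), np.nan)
            intercept = np.full(len(wide), np.nan)
            stderr = np.full(len(wide), np.nan)
        res = pd.DataFrame(
            {
                "barcode_id": wide.index,
                "delta_omega": slope,
                "intercept": intercept,
                "stderr": stderr,
                "n_points_used": np.isfinite(L).sum(axis=1),
            }
        )
        if not isinstance(keys, tuple):
            keys = (keys,)
        for col, val in zip(group_cols, keys):
            res[col] = val
        rows.append(res)
    out = pd.concat(rows, ignore_index=True)
    return out[group_cols + ["barcode_id", "delta_omega", "intercept", "stderr",
                             "n_points_used"]]


# ---------------------------------------------------------------------------
# smoothing


def rolling_mean(values: np.ndarray, window: int = 7) -> np.ndarray:
    """Centered rolling mean with shrinking windows at the edges.

    ``window`` must be odd so the window is symmetric around each point; the
    output has the same length as the input.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    s = pd.Series(np.asarray(values, dtype=float))
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def smooth_trajectories(freqs: pd.DataFrame, window: int = 7) -> pd.DataFrame:
    """Apply the centered rolling mean to each barcode trajectory.

    Operates per (replicate, barcode) ordered by time; this is the smoothing
    used when plotting floating-barcode clonal dynamics.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    out = freqs.sort_values(["replicate", "barcode_id", "timepoint_day"]).copy()
    out["frequency"] = (
        out.groupby(["replicate", "barcode_id"], sort=False)["frequency"]
        .transform(lambda s: s.rolling(window, center=True, min_periods=1).mean())
    )
    return out


# ---------------------------------------------------------------------------
# power-law null


def _powerlaw_nll(alpha: float, log_sum: float, n: int, x_min: int) -> float:
    return n * np.log(special.zeta(alpha, x_min)) + alpha * log_sum


def _fit_alpha(tail: np.ndarray, x_min: int) -> float:
    log_sum = float(np.log(tail).sum())
    from scipy.optimize import minimize_scalar

    opt = minimize_scalar(
        _powerlaw_nll,
        bounds=(1.01, 8.0),
        args=(log_sum, len(tail), x_min),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(opt.x)


def _powerlaw_cdf(x: np.ndarray, alpha: float, x_min: int) -> np.ndarray:
    """P(X <= x) for the discrete power law with support {x_min, x_min+1, ...}."""
    z0 = special.zeta(alpha, x_min)
    return 1.0 - special.zeta(alpha, np.asarray(x, dtype=float) + 1.0) / z0


def _ks_distance(tail: np.ndarray, alpha: float, x_min: int) -> float:
    xs, counts = np.unique(tail, return_counts=True)
    ecdf = np.cumsum(counts) / len(tail)
    ecdf_lo = ecdf - counts / len(tail)
    model = _powerlaw_cdf(xs, alpha, x_min)
    model_lo = _powerlaw_cdf(xs - 1, alpha, x_min)
    return float(
        max(np.max(np.abs(ecdf - model)), np.max(np.abs(ecdf_lo - model_lo)))
    )


def powerlaw_null_fit(
    final_sizes: np.ndarray, x_min: int = 5
) -> tuple[float, float]:
    """Discrete power-law tail fit: MLE exponent and KS distance.

    Fits ``p(x) ~ x^(-alpha)`` on the tail ``x >= x_min`` by maximizing the
    zeta-normalized discrete likelihood, and reports the Kolmogorov-Smirnov
    distance between the empirical tail CDF and the fitted law.  Requires at
    least 50 tail observations and non-degenerate sizes.
    """
    sizes = np.asarray(final_sizes)
    if np.any(sizes < 0):
        raise ValueError("sizes must be nonnegative integers")
    tail = sizes[sizes >= x_min].astype(np.int64)
    if len(tail) < 50:
        raise InsufficientTailError(
            f"only {len(tail)} observations >= x_min={x_min}; need >= 50"
        )
    if np.all(tail == tail[0]):
        raise InsufficientTailError("degenerate tail: all sizes identical")
    alpha = _fit_alpha(tail, x_min)
    return alpha, _ks_distance(tail, alpha, x_min)


def sample_discrete_powerlaw(
    alpha: float, x_min: int, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Samples from the zeta-normalized discrete power law.

    Inverse-CDF sampling is exact over the body of the distribution
    (``x < x_min + 10^5``); the far tail (relative mass ``zeta(alpha, cap) /
    zeta(alpha, x_min)``, at most a fraction of a percent for tail exponents
    above 1.3) is drawn from the continuous Pareto density and floored, whose
    discretization error is negligible at that scale.
    """
    if alpha <= 1.0:
        raise ValueError("alpha must exceed 1")
    z0 = special.zeta(alpha, x_min)
    cap = x_min + 100_000
    support = np.arange(x_min, cap)
    pmf = support.astype(float) ** (-alpha) / z0
    cdf = np.cumsum(pmf)
    tail_mass = special.zeta(alpha, cap) / z0
    u = rng.random(size) * (cdf[-1] + tail_mass)
    out = np.empty(size, dtype=np.int64)
    body = u <= cdf[-1]
    out[body] = support[np.searchsorted(cdf, u[body])]
    n_tail = int((~body).sum())
    if n_tail:
        v = rng.random(n_tail)
        out[~body] = np.floor(cap * (1.0 - v) ** (-1.0 / (alpha - 1.0))).astype(np.int64)
    return out


def powerlaw_bootstrap(
    final_sizes: np.ndarray,
    x_min: int = 5,
    n_boot: int = 200,
    seed: int = 0,
) -> dict:
    """Parametric-bootstrap goodness of fit for the power-law tail.

    Refits the exponent on each synthetic tail drawn from the fitted law and
    compares KS distances; ``p_value`` is the fraction of resamples whose KS
    distance is at least the observed one (large p = data indistinguishable
    from a power law).
    """
    alpha, ks_obs = powerlaw_null_fit(final_sizes, x_min)
    tail_n = int(np.sum(np.asarray(final_sizes) >= x_min))
    rng = np.random.default_rng(seed)
    ks_boot = np.empty(n_boot)
    for b in range(n_boot):
        sim = sample_discrete_powerlaw(alpha, x_min, tail_n, rng)
        a_b = _fit_alpha(sim, x_min)
        ks_boot[b] = _ks_distance(sim, a_b, x_min)
    return {
        "alpha": alpha,
        "ks_distance": ks_obs,
        "ks_boot": ks_boot,
        "p_value": float(np.mean(ks_boot >= ks_obs)),
    }


# ---------------------------------------------------------------------------
# enrichment and resistance-mode classification


def call_enriched(
    parental: pd.Series,
    treated: pd.Series,
    fold_threshold: float = 5.0,
    min_final_freq: float = 0.02,
) -> set[str]:
    """Barcodes enriched by treatment.

    A barcode is called enriched when its treated/parental frequency ratio is
    at least ``fold_threshold`` and its treated frequency is at least
    ``min_final_freq`` (minor barcodes below a few percent abundance are not
    called even if their fold change is large).
    """
    if set(parental.index) != set(treated.index):
        raise ValueError("parental and treated must share the same barcode universe")
    treated = treated.reindex(parental.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            parental.to_numpy() > 0,
            treated.to_numpy() / parental.to_numpy(),
            np.where(treated.to_numpy() > 0, np.inf, 0.0),
        )
    keep = (ratio >= fold_threshold) & (treated.to_numpy() >= min_final_freq)
    return set(parental.index[keep])


@dataclass
class ResistanceModeCall:
    """Outcome of the replicate-concordance resistance-mode decision."""

    mode: str
    enriched_sets: list[set[str]]
    pairwise_jaccard: np.ndarray
    mean_jaccard: float
    overlap_threshold: float
    enrichment_test_summary: dict = dataclass_field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "enriched_sets": [sorted(s) for s in self.enriched_sets],
            "pairwise_jaccard": self.pairwise_jaccard.tolist(),
            "mean_jaccard": self.mean_jaccard,
            "overlap_threshold": self.overlap_threshold,
            "enrichment_test_summary": self.enrichment_test_summary,
        }


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return np.nan
    return len(a & b) / len(a | b)


def classify_resistance_mode(
    per_replicate_enriched: Sequence[set[str]],
    per_replicate_tests: Mapping | None = None,
    overlap_threshold: float = 0.5,
) -> ResistanceModeCall:
    """Classify resistance as preexisting, de-novo (heritable) or plastic.

    Heritable resistance enriches barcodes; when the *same* barcodes recur
    across independent replicates (mean pairwise Jaccard overlap at or above
    ``overlap_threshold``) the resistant lineages predated treatment, whereas
    discordant enriched sets indicate independently arising resistance.  No
    enrichment in any replicate indicates a nonheritable (plastic) mechanism.
    """
    sets = [set(s) for s in per_replicate_enriched]
    if len(sets) < 2:
        raise ValueError("resistance mode is not identifiable from a single replicate")
    n = len(sets)
    jac = np.full((n, n), np.nan)
    np.fill_diagonal(jac, 1.0)
    vals = []
    for i, j in combinations(range(n), 2):
        v = _jaccard(sets[i], sets[j])
        jac[i, j] = jac[j, i] = v
        vals.append(v)
    mean_j = float(np.nanmean(vals)) if not all(np.isnan(v) for v in vals) else np.nan

    if all(len(s) == 0 for s in sets):
        mode = "plastic"
    elif mean_j >= overlap_threshold:
        mode = "preexisting_heritable"
    else:
        mode = "de_novo_heritable"
    return ResistanceModeCall(
        mode=mode,
        enriched_sets=sets,
        pairwise_jaccard=jac,
        mean_jaccard=mean_j,
        overlap_threshold=overlap_threshold,
        enrichment_test_summary=dict(per_replicate_tests or {}),
    )


def analyze_selection_tables(
    tables: Sequence[pd.DataFrame],
    pseudo_count: float = 0.5,
    fold_threshold: float = 5.0,
    min_final_freq: float = 0.02,
    overlap_threshold: float = 0.5,
) -> ResistanceModeCall:
    """End-to-end mode call from per-replicate count tables.

    For each replicate the parental reference is the last parental-phase
    timepoint (the first timepoint if no parental phase is labeled) and the
    treated state is the final timepoint; enrichment is called per replicate
    and the replicate concordance decides the mode.  A per-replicate
    Mann-Whitney test comparing final against parental log frequencies is
    recorded as the population-level frequency-change summary.
    """
    enriched_sets = []
    tests = {}
    for k, tab in enumerate(tables):
        freqs = relative_abundances(tab, pseudo_count=pseudo_count)
        rep = freqs["replicate"].iloc[0]
        par = freqs[freqs["phase"] == "parental"]
        t_ref = par["timepoint_day"].max() if len(par) else freqs["timepoint_day"].min()
        t_fin = freqs["timepoint_day"].max()
        f0 = freqs[freqs["timepoint_day"] == t_ref].set_index("barcode_id")["frequency"]
        f1 = freqs[freqs["timepoint_day"] == t_fin].set_index("barcode_id")["frequency"]
        enriched_sets.append(
            call_enriched(f0, f1, fold_threshold=fold_threshold,
                          min_final_freq=min_final_freq)
        )
        mw = stats.mannwhitneyu(np.log(f1), np.log(f0), alternative="two-sided")
        tests[str(rep)] = {"mannwhitney_p": float(mw.pvalue),
                           "t_parental": float(t_ref), "t_final": float(t_fin)}
    return classify_resistance_mode(
        enriched_sets, per_replicate_tests=tests, overlap_threshold=overlap_threshold
    )
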