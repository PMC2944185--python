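"""Purity-aware five-state copy-number calling from per-clone log2 ratios.

The calling chain is:

1. ``average_replicates`` — mean of the non-missing spot replicates per clone.
2. ``segment_profile`` — exact least-squares piecewise-constant fit per
   chromosome (dynamic program minimizing SSE + penalty * n_segments).
3. ``profile_mode_sd`` — center (KDE mode) and robust spread (MAD about the
   mode) of the smoothed values.
4. ``estimate_tumor_cell_rate`` — invert the single-copy-loss displacement
   log2(1 - R/2) (gain-based and default fallbacks) to estimate the tumor
   cell rate R.
5. ``call_aberrations`` — five mutually exclusive states on the recentered
   smoothed values: gain/loss at mode +/- one (robust) SD, homozygous
   deletion at log2(1 - R), amplicon at log2(1 + 1.5 R).

Under the two-population mixture (tumor fraction R with copy number cn,
diploid otherwise) a clone's noiseless log2 ratio is
log2((R*cn + 2(1-R))/2); the homozygous-deletion threshold log2(1-R) is
exactly the cn=0 value and the amplicon threshold log2(1+1.5R) is exactly
the cn=5 value, so amp calls correspond to tumor copy number > 5 whatever
the purity.  Because the homdel level sits exactly on its threshold, the
decision boundary for homdel/amp additionally allows a standard-error margin
(z * noise_sd / sqrt(segment length), zero on noiseless data); see
docs/methods.md for the rationale and calibration of the default z.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .io_formats import CloneMap

__all__ = [
    "CallingParameters",
    "SegmentedProfile",
    "ProfileStats",
    "AberrationCalls",
    "average_replicates",
    "segment_profile",
    "profile_mode_sd",
    "estimate_tumor_cell_rate",
    "call_aberrations",
    "call_profile",
]

STATES = ("homdel", "loss", "neutral", "gain", "amp")


@dataclass
class CallingParameters:
    """Tunables of the caller.

    ``amp_factor`` is the 1.5 in the amplicon threshold log2(1 + 1.5 R);
    ``se_multiplier`` scales the standard-error allowance on the homdel/amp
    boundaries (0 disables it); ``tolerance`` makes the thresholds inclusive
    at machine scale so the exact noiseless boundary case is called.
    """

    sd_multiplier: float = 1.0
    amp_factor: float = 1.5
    tolerance: float = 1e-9
    se_multiplier: float = 3.0
    r_tc_clamp: tuple[float, float] = (0.1, 0.95)
    r_tc_default: float = 0.7

    def __post_init__(self) -> None:
        if self.sd_multiplier <= 0 or self.amp_factor <= 0:
            raise ValueError("sd_multiplier and amp_factor must be positive")
        lo, hi = self.r_tc_clamp
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("r_tc_clamp must satisfy 0 < lo < hi < 1")


@dataclass
class SegmentedProfile:
    """Piecewise-constant fit: per-clone smoothed values plus segment list.

    ``segments`` has columns (chrom, start_idx, end_idx, mean, n) with
    positional clone indices into the clone map's canonical order, half-open.
    ``noise_sd`` is the robust per-clone noise estimate used for the penalty
    (1.4826 * median |first differences| / sqrt(2)).
    """

    smoothed: np.ndarray
    segments: pd.DataFrame
    noise_sd: float
    penalty: float


@dataclass
class ProfileStats:
    """Profile-level statistics the thresholds are built from."""

    mode: float
    sd: float
    r_tc_hat: float | None = None
    estimation_source: str | None = None   # "loss" | "homdel" | "gain" | "default"


@dataclass
class AberrationCalls:
    """Per-clone five-state status with the thresholds that produced it."""

    status: np.ndarray
    thresholds: dict[str, float] = field(default_factory=dict)


def average_replicates(spot_table: pd.DataFrame,
                       clone_map: CloneMap) -> np.ndarray:
    """Average replicate spots per clone (quadruplicate arrays typically).

    ``spot_table`` needs columns (clone_id, replicate_index, log2_ratio);
    missing replicates (NaN) are dropped, a clone with no non-missing
    replicate comes back NaN.  Result is aligned to the clone map order.
    """
    required = {"clone_id", "replicate_index", "log2_ratio"}
    if not required <= set(spot_table.columns):
        raise ValueError(f"spot table needs columns {sorted(required)}")
    unknown = set(spot_table["clone_id"]) - set(clone_map.clone_ids)
    if unknown:
        raise ValueError(f"spot table clone {sorted(unknown)[0]!r} absent "
                         "from clone map")
    means = spot_table.groupby("clone_id")["log2_ratio"].mean()
    return means.reindex(clone_map.clone_ids).to_numpy()


def _segment_chromosome(y: np.ndarray, penalty: float) -> list[tuple[int, int, float]]:
    """Exact DP: minimize sum of squared residuals + penalty per segment.

    Returns (start, end, mean) with half-open positional bounds.  O(n^2)
    with vectorized inner loop; n is a few hundred clones per chromosome.
    """
    n = len(y)
    if n == 0:
        return []
    cs = np.concatenate([[0.0], np.cumsum(y)])
    cs2 = np.concatenate([[0.0], np.cumsum(y * y)])
    best = np.empty(n + 1)
    prev = np.zeros(n + 1, dtype=np.int64)
    best[0] = 0.0  # total objective: SSE + penalty * (number of segments)
    for j in range(1, n + 1):
        i = np.arange(j)
        seg_sum = cs[j] - cs[i]
        seg_sse = (cs2[j] - cs2[i]) - seg_sum * seg_sum / (j - i)
        cand = best[:j] + seg_sse + penalty
        k = int(np.argmin(cand))
        best[j] = cand[k]
        prev[j] = k
    bounds = []
    j = n
    while j > 0:
        i = int(prev[j])
        bounds.append((i, j, (cs[j] - cs[i]) / (j - i)))
        j = i
    return bounds[::-1]


def estimate_noise_sd(values: np.ndarray) -> float:
    """Robust per-clone noise from first differences of the raw profile."""
    v = values[~np.isnan(values)]
    if len(v) < 3:
        return 0.0
    d = np.abs(np.diff(v))
    return float(1.4826 * np.median(d) / np.sqrt(2.0))


def segment_profile(values: np.ndarray, clone_map: CloneMap,
                    penalty: float | None = None) -> SegmentedProfile:
    """Fit a piecewise-constant profile per chromosome by exact DP.

    ``values`` are per-clone log2 ratios in clone-map order (NaN = missing;
    missing clones are dropped from the fit and stay NaN in the smoothed
    output).  The default penalty is 2 * sigma^2 * ln(n) with the robust
    first-difference noise estimate sigma and n the number of informative
    clones in the profile.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != len(clone_map):
        raise ValueError(f"{len(values)} values for {len(clone_map)} clones")
    sigma = estimate_noise_sd(values)
    n_obs = int(np.sum(~np.isnan(values)))
    if penalty is None:
        penalty = 2.0 * sigma**2 * np.log(max(n_obs, 2))
        if penalty == 0.0:
            penalty = 1e-12  # noiseless data: any true jump still exceeds this
    smoothed = np.full_like(values, np.nan)
    rows = []
    for chrom in clone_map.chroms:
        idx = clone_map.chrom_indices(chrom)
        obs = idx[~np.isnan(values[idx])]
        if len(obs) == 0:
            continue
        if len(obs) < 2:
            warnings.warn(f"chromosome {chrom}: fewer than 2 informative "
                          "clones; single segment")
        for start, end, mean in _segment_chromosome(values[obs], penalty):
            smoothed[obs[start:end]] = mean
            rows.append((chrom, int(obs[start]), int(obs[end - 1]) + 1,
                         mean, end - start))
    segments = pd.DataFrame(rows, columns=["chrom", "start_idx", "end_idx",
                                           "mean", "n"])
    return SegmentedProfile(smoothed, segments, sigma, float(penalty))


def profile_mode_sd(segmented: SegmentedProfile) -> ProfileStats:
    """Mode (Gaussian KDE, Silverman bandwidth, 512-point grid) and robust SD
    (1.4826 * MAD about the mode) of the smoothed per-clone values."""
    v = segmented.smoothed[~np.isnan(segmented.smoothed)]
    if len(v) < 10:
        raise ValueError("need at least 10 informative clones for mode/SD")
    if np.ptp(v) == 0.0:
        return ProfileStats(mode=float(v[0]), sd=0.0)
    kde = gaussian_kde(v, bw_method="silverman")
    grid = np.linspace(v.min(), v.max(), 512)
    peak = float(grid[int(np.argmax(kde(grid)))])
    # snap the grid argmax to the nearest observed smoothed value so that
    # recentering is exact for piecewise-constant data (grid quantization
    # would otherwise shift every threshold by up to half a grid step)
    mode = float(v[int(np.argmin(np.abs(v - peak)))])
    sd = float(1.4826 * np.median(np.abs(v - mode)))
    return ProfileStats(mode=mode, sd=sd)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    return float(v[np.searchsorted(cw, 0.5 * cw[-1])])


def estimate_tumor_cell_rate(segmented: SegmentedProfile, stats: ProfileStats,
                             params: CallingParameters | None = None,
                             ) -> ProfileStats:
    """Estimate the tumor cell rate R from aberrant segment displacements.

    A single-copy loss is displaced by log2(1 - R/2) from the mode, so
    R = 2 (1 - 2^(m - mode)) for the (length-weighted) median loss
    displacement m.  A loss cluster deeper than any single-copy loss at the
    clamp ceiling can only be homozygous, and is inverted with
    R = 1 - 2^(m - mode) instead.  With no loss segments, single-copy gains
    give R = 2 (2^(m - mode) - 1); with neither, a configurable default is
    used.  The estimate is clamped to ``params.r_tc_clamp``.
    """
    params = params or CallingParameters()
    lo, hi = params.r_tc_clamp
    seg = segmented.segments
    mode, sd = stats.mode, stats.sd
    k = params.sd_multiplier

    # a segment nearer the mode than the shallowest admissible single-copy
    # displacement (purity at the clamp floor) cannot be a copy-number event;
    # without this floor, mode quantization lets near-zero neutral segments
    # masquerade as losses and wreck the weighted median
    min_disp = abs(np.log2(1.0 - lo / 2.0))
    losses = seg[seg["mean"] < mode - max(k * sd, min_disp)]
    gains = seg[seg["mean"] > mode + max(k * sd, min_disp)]
    r_hat, source = None, None
    if len(losses):
        m = _weighted_median(losses["mean"].to_numpy(),
                             losses["n"].to_numpy(dtype=float))
        depth = m - mode
        if depth < np.log2(1.0 - hi / 2.0):
            # deeper than any single-copy loss at maximal purity: the loss
            # cluster itself is homozygous
            r_hat, source = 1.0 - 2.0**depth, "homdel"
        else:
            r_hat, source = 2.0 * (1.0 - 2.0**depth), "loss"
    elif len(gains):
        m = _weighted_median(gains["mean"].to_numpy(),
                             gains["n"].to_numpy(dtype=float))
        lift = m - mode
        if lift <= np.log2(1.0 + hi / 2.0):
            r_hat, source = 2.0 * (2.0**lift - 1.0), "gain"
        # a lift beyond the single-copy band is an amplicon of unknown copy
        # number; it cannot be inverted, fall through to the default
    if r_hat is None:
        warnings.warn("no single-copy aberrant segments; using default "
                      f"tumor cell rate {params.r_tc_default}")
        r_hat, source = params.r_tc_default, "default"
    r_hat = float(np.clip(r_hat, lo, hi))
    return ProfileStats(mode=mode, sd=sd, r_tc_hat=r_hat,
                        estimation_source=source)


def call_aberrations(segmented: SegmentedProfile, stats: ProfileStats,
                     params: CallingParameters | None = None,
                     ) -> AberrationCalls:
    """Assign each clone one of homdel/loss/neutral/gain/amp.

    On recentered values v = smoothed - mode: homdel iff
    v <= log2(1 - R) + allowance, amp iff v >= log2(1 + amp_factor * R)
    - allowance, else loss/gain iff v beyond -/+ sd_multiplier * sd, else
    neutral.  The allowance is se_multiplier * noise_sd / sqrt(segment
    length) plus the machine tolerance; it vanishes on noiseless data.
    """
    params = params or CallingParameters()
    if stats.r_tc_hat is None:
        raise ValueError("stats.r_tc_hat missing; run estimate_tumor_cell_rate")
    r = stats.r_tc_hat
    if stats.sd == 0.0:
        warnings.warn("zero SD: gain/loss thresholds degenerate; only "
                      "homdel/amp/neutral are callable")
    homdel_thr = float(np.log2(1.0 - r))
    amp_thr = float(np.log2(1.0 + params.amp_factor * r))
    loss_thr = -params.sd_multiplier * stats.sd
    gain_thr = params.sd_multiplier * stats.sd

    v = segmented.smoothed - stats.mode
    seg_len = np.full(len(v), np.nan)
    for _, row in segmented.segments.iterrows():
        seg_len[int(row["start_idx"]):int(row["end_idx"])] = row["n"]
    se_allowance = np.where(
        np.isnan(seg_len), 0.0,
        params.se_multiplier * segmented.noise_sd / np.sqrt(seg_len))

    status = np.full(len(v), None, dtype=object)
    observed = ~np.isnan(v)
    # homdel boundary inclusive (cn=0 sits exactly at log2(1-R)); the amp
    # boundary is strict, because log2(1+1.5R) is exactly the cn=5 level and
    # amplicons are copy number above 5
    is_homdel = observed & (v <= homdel_thr + se_allowance + params.tolerance)
    is_amp = observed & ~is_homdel & (v > amp_thr - se_allowance
                                      + params.tolerance)
    if stats.sd > 0.0:
        is_loss = observed & ~is_homdel & ~is_amp & (v < loss_thr)
        is_gain = observed & ~is_homdel & ~is_amp & (v > gain_thr)
    else:
        is_loss = np.zeros(len(v), dtype=bool)
        is_gain = np.zeros(len(v), dtype=bool)
    status[is_homdel] = "homdel"
    status[is_amp] = "amp"
    status[is_loss] = "loss"
    status[is_gain] = "gain"
    status[observed & (status == None)] = "neutral"  # noqa: E711
    return AberrationCalls(status, thresholds={
        "mode": stats.mode, "sd": stats.sd, "r_tc_hat": r,
        "homdel": homdel_thr, "amp": amp_thr,
        "loss": loss_thr, "gain": gain_thr,
    })


def call_profile(values: np.ndarray, clone_map: CloneMap,
                 params: CallingParameters | None = None,
                 ) -> tuple[AberrationCalls, SegmentedProfile, ProfileStats]:
    """Convenience chain: segment, estimate statistics, call one profile."""
    params = params or CallingParameters()
    segmented = segment_profile(values, clone_map)
    stats = profile_mode_sd(segmented)
    stats = estimate_tumor_cell_rate(segmented, stats, params)
    calls = call_aberrations(segmented, stats, params)
    return calls, segmented, stats
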