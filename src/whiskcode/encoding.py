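"""Position tuning: linear rate-vs-position fits, gain, directionality.

The tuning curve is the occupancy-normalized rate in 1-degree position
bins over whisking epochs: SS spike counts per bin divided by the time
spent in the bin (bins with < 100 ms of occupancy are masked).  Binning
spike counts by the instantaneous position keeps the estimate unbiased
in the presence of the 6-30 Hz whisking rhythm; a smoothed-rate series
binned the same way would dilute the slope, because the rate estimator
averages the rhythm out of the rate but not out of the regressor.  An
optional lag aligns the position to the rate it drives (a cell leading
the whisker by 18 ms is tuned to the position 18 ms after each spike).

A cell encodes position *unidirectionally* when only one side of the
resting point modulates the rate (directionality ratio 0) and
*bidirectionally* when both do; the ratio divides the smaller of the two
extreme rate changes (relative to the spontaneous quiet rate) by the
larger.  The linear fit is restricted to the modulated side for
unidirectional cells and, for all cells, to the unsaturated (unclipped)
extent of a rectified-linear tuning model; significance requires
regression ANOVA p < 0.05 and R^2 > 0.86.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats as sps

from .kinematics import EpochSet, Kinematics
from .spikes import RateSeries

ALPHA = 0.05
R2_CRITERION = 0.86
BIDIRECTIONAL_RATIO_MIN = 0.2   # conservative: observed bidirectional ratios >= 0.4
SIDE_CHANGE_FLOOR_HZ = 5.0      # minimum extreme rate change to call a side modulated


@dataclass
class TuningCurve:
    position_bins: np.ndarray    # deg, bin centers
    rate: np.ndarray             # Hz, occupancy-weighted mean per bin (NaN = masked)
    occupancy: np.ndarray        # s per bin
    resting_point: float         # deg
    spontaneous_rate: float      # Hz, quiet-epoch rate

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.rate)


@dataclass
class EncodingFit:
    gain: float | None           # Hz/deg, signed slope
    r2: float | None
    p: float | None              # regression ANOVA p
    direction_class: str         # unidirectional-protraction / -retraction /
                                 # bidirectional / unclassified
    directionality_ratio: float | None
    significant: bool = False
    fit_range: tuple | None = None   # deg, (lo, hi) of the fitted linear range
    intercept: float | None = None   # Hz at the resting point
    encoding_range: float | None = None      # deg
    occupancy_fraction: float | None = None  # whisking time inside the range


def tuning_curve(
    train,
    kin: Kinematics,
    epochs: EpochSet,
    bin_deg: float = 1.0,
    min_occupancy_s: float = 0.1,
    min_whisk_s: float = 60.0,
    lag_s: float = 0.0,
) -> TuningCurve:
    """Occupancy-normalized rate in 1-degree position bins (whisking only).

    ``train`` is a :class:`~whiskcode.spikes.SpikeTrain`; spike counts per
    position bin are divided by the bin occupancy.  A
    :class:`~whiskcode.spikes.RateSeries` is also accepted, in which case
    each 1 ms sample contributes ``rate * dt`` expected spikes (exact for
    a noiseless rate model; a boxcar-smoothed rate estimate gives a
    slope-diluted curve and the spike train should be preferred).
    ``lag_s`` shifts the position series so that each spike is paired
    with the position at ``t_spike - lag_s`` (negative lag = cell leads).
    """
    if epochs.total("whisking") < min_whisk_s:
        raise ValueError("need >= 60 s of whisking data for a tuning curve")
    n = kin.n
    shift = int(round(lag_s * kin.fs))
    idx = np.clip(np.arange(n) - shift, 0, n - 1)
    pos_series = kin.angle_f[idx]

    whisk = epochs.sample_mask("whisking", n, kin.fs)
    quiet = epochs.sample_mask("quiet", n, kin.fs)
    pos = pos_series[whisk]

    lo = np.floor(pos.min() / bin_deg) * bin_deg
    hi = np.ceil(pos.max() / bin_deg) * bin_deg
    edges = np.arange(lo, hi + bin_deg / 2, bin_deg)
    centers = edges[:-1] + bin_deg / 2
    nbin = centers.size
    which = np.clip(np.digitize(pos, edges) - 1, 0, nbin - 1)
    occ_n = np.bincount(which, minlength=nbin).astype(float)
    occupancy = occ_n / kin.fs

    if isinstance(train, RateSeries):
        m = min(train.n, n)
        mask_m = whisk[:m]
        pos_m = pos_series[:m][mask_m]
        bin_m = np.clip(np.digitize(pos_m, edges) - 1, 0, nbin - 1)
        counts = np.bincount(bin_m, weights=train.rate[:m][mask_m] / kin.fs,
                             minlength=nbin)
        occ_n = np.bincount(bin_m, minlength=nbin).astype(float)
        occupancy = occ_n / kin.fs
        spont_source = train.rate[:m][quiet[:m]]
        spont = float(np.mean(spont_source)) if spont_source.size else float("nan")
    else:
        sp_idx = np.clip((train.ss_times * kin.fs).astype(int), 0, n - 1)
        in_whisk = whisk[sp_idx]
        sp_pos = pos_series[sp_idx[in_whisk]]
        sp_bin = np.clip(np.digitize(sp_pos, edges) - 1, 0, nbin - 1)
        counts = np.bincount(sp_bin, minlength=nbin).astype(float)
        quiet_t = epochs.total("quiet")
        n_quiet_spikes = int(np.count_nonzero(quiet[sp_idx]))
        spont = n_quiet_spikes / quiet_t if quiet_t > 0 else float("nan")

    with np.errstate(invalid="ignore"):
        mean_rate = np.where(occupancy > 0, counts / np.maximum(occupancy, 1e-12),
                             np.nan)
    mean_rate[occupancy < min_occupancy_s] = np.nan
    if not np.any(~np.isnan(mean_rate)):
        raise ValueError("all position bins are masked (insufficient occupancy)")

    resting = (
        float(np.mean(kin.angle_f[quiet])) if epochs.total("quiet") > 0
        else float(np.nanmean(kin.angle_f))
    )
    return TuningCurve(
        position_bins=centers, rate=mean_rate, occupancy=occupancy,
        resting_point=resting, spontaneous_rate=spont,
    )


def directionality_index(delta_plus: float, delta_minus: float) -> float:
    """min(|dr+|, |dr-|) / max(|dr+|, |dr-|): 0 = unidirectional, 1 = symmetric."""
    a, b = abs(delta_plus), abs(delta_minus)
    if max(a, b) == 0:
        return 0.0
    return min(a, b) / max(a, b)


def _wls(x, y, w):
    """Occupancy-weighted least squares; returns slope, intercept, r2, ANOVA p."""
    w = w / w.sum()
    xm, ym = np.sum(w * x), np.sum(w * y)
    sxx = np.sum(w * (x - xm) ** 2)
    sxy = np.sum(w * (x - xm) * (y - ym))
    if sxx == 0:
        return None
    slope = sxy / sxx
    inter = ym - slope * xm
    resid = y - (inter + slope * x)
    sse = np.sum(w * resid**2)
    sst = np.sum(w * (y - ym) ** 2)
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    k = x.size
    if k > 2 and sse > 0:
        f = (sst - sse) / (sse / (k - 2))
        p = float(sps.f.sf(f, 1, k - 2))
    else:
        p = 0.0 if r2 > 0.999999 else 1.0
    return slope, inter, r2, p


def _rect_fit(x, y, w):
    """Weighted rectified-line fit ``y ~ max(0, a + g x)``.

    The optimizer is started from the plain WLS line and from the
    steepest adjacent-bin slope (the WLS start alone can stall in a
    shallow basin when most bins are clipped at zero).  Returns
    ``(a, g, r2, p)`` with r2/p from the rectified model vs a constant.
    """
    lin = _wls(x, y, w)
    if lin is None:
        return None
    inits = [(lin[1], lin[0])]
    if x.size >= 2:
        order = np.argsort(x)
        dx = np.diff(x[order])
        dy = np.diff(y[order])
        steep = np.argmax(np.abs(dy) / np.maximum(dx, 1e-9))
        g0 = dy[steep] / max(dx[steep], 1e-9)
        x0 = 0.5 * (x[order][steep] + x[order][steep + 1])
        y0 = 0.5 * (y[order][steep] + y[order][steep + 1])
        inits.append((y0 - g0 * x0, g0))
    sw = np.sqrt(w / w.sum())
    best = None
    for a0, g0 in inits:
        try:
            res = optimize.least_squares(
                lambda p: sw * (_clipped_line(x, p[0], p[1]) - y), x0=[a0, g0]
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return None
    a, g = best.x
    wn = w / w.sum()
    ym = np.sum(wn * y)
    sse = float(np.sum(wn * (_clipped_line(x, a, g) - y) ** 2))
    sst = float(np.sum(wn * (y - ym) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    k = x.size
    if k > 2 and sse > 0:
        f = (sst - sse) / (sse / (k - 2))
        p = float(sps.f.sf(f, 1, k - 2))
    else:
        p = 0.0 if r2 > 0.999999 else 1.0
    return float(a), float(g), float(r2), p


def _side_change(curve: TuningCurve, side: str):
    """Fitted extreme rate change (Hz, signed) on one side of the resting
    point, or 0 when the side is not significantly modulated.  The change
    is read from a rectified-line fit at the far end of the side, so a
    rate clipped at zero contributes its true (bounded) change rather
    than a linear extrapolation."""
    x = curve.position_bins - curve.resting_point
    sel = curve.valid & ((x > 0) if side == "pro" else (x < 0))
    if sel.sum() < 3:
        return 0.0
    fit = _rect_fit(x[sel], curve.rate[sel], curve.occupancy[sel])
    if fit is None:
        return 0.0
    a, g, _, p = fit
    far = x[sel][np.argmax(np.abs(x[sel]))]
    change = max(a + g * far, 0.0) - curve.spontaneous_rate
    if p >= ALPHA or abs(change) < SIDE_CHANGE_FLOOR_HZ:
        return 0.0
    return float(change)


def directionality_ratio(curve: TuningCurve):
    """Directionality ratio and class from the tuning curve.

    Returns ``(ratio, direction_class, delta_pro, delta_ret)``.  A side
    whose fitted rate change is not significant contributes 0, so purely
    one-sided cells get ratio 0 (unidirectional); both sides modulated
    with ratio >= 0.2 is bidirectional.
    """
    x = curve.position_bins - curve.resting_point
    if not (np.any(curve.valid & (x > 0)) and np.any(curve.valid & (x < 0))):
        return None, "unclassified", 0.0, 0.0
    d_pro = _side_change(curve, "pro")
    d_ret = _side_change(curve, "ret")
    ratio = directionality_index(d_pro, d_ret)
    if d_pro == 0.0 and d_ret == 0.0:
        return 0.0, "unclassified", d_pro, d_ret
    if ratio >= BIDIRECTIONAL_RATIO_MIN:
        return ratio, "bidirectional", d_pro, d_ret
    # dominant side defines the unidirectional class; ratio reported as 0
    cls = ("unidirectional-protraction" if abs(d_pro) >= abs(d_ret)
           else "unidirectional-retraction")
    return 0.0, cls, d_pro, d_ret


def _clipped_line(x, a, g):
    return np.maximum(a + g * x, 0.0)


def fit_linear_encoding(curve: TuningCurve, min_bins: int = 5) -> EncodingFit:
    """Linear fit of rate vs position on the modulated, unclipped range.

    For unidirectional cells the regression is restricted to the
    modulated side of the resting point; for bidirectional cells it
    spans both sides.  A rectified-linear pre-fit identifies bins where
    the rate is clipped at zero, which are excluded from the final
    weighted regression.
    """
    ratio, cls, d_pro, d_ret = directionality_ratio(curve)
    if cls == "unclassified":
        return EncodingFit(None, None, None, "unclassified", ratio)
    x = curve.position_bins - curve.resting_point
    sel = curve.valid.copy()
    if cls == "unidirectional-protraction":
        sel &= x > 0
    elif cls == "unidirectional-retraction":
        sel &= x < 0
    if sel.sum() < min_bins:
        return EncodingFit(None, None, None, "unclassified", ratio)

    xs, ys, ws = x[sel], curve.rate[sel], curve.occupancy[sel]
    pre = _rect_fit(xs, ys, ws)
    if pre is None:
        return EncodingFit(None, None, None, "unclassified", ratio)
    a_hat, g_hat = pre[0], pre[1]
    unclipped = sel.copy()
    unclipped[sel] &= (a_hat + g_hat * xs) > 0.5

    if unclipped.sum() >= min_bins:
        xs, ys, ws = x[unclipped], curve.rate[unclipped], curve.occupancy[unclipped]
        fit = _wls(xs, ys, ws)
        if fit is None:
            return EncodingFit(None, None, None, "unclassified", ratio)
        gain, inter, r2, p = fit
    else:
        # linear range narrower than the bin grid resolves: report the
        # rectified-model fit over the whole side instead
        gain, inter, r2, p = g_hat, a_hat, pre[2], pre[3]
    significant = (p < ALPHA) and (r2 > R2_CRITERION)
    return EncodingFit(
        gain=float(gain), r2=float(r2), p=float(p),
        direction_class=cls, directionality_ratio=ratio,
        significant=significant,
        fit_range=(float(xs.min() + curve.resting_point),
                   float(xs.max() + curve.resting_point)),
        intercept=float(inter),
    )


def encoding_range_stats(
    curve: TuningCurve,
    fit: EncodingFit,
    kin: Kinematics,
    epochs: EpochSet,
) -> EncodingFit:
    """Linear encoding range and the fraction of whisking time inside it.

    The encoding range is the position extent over which the fitted line
    stays within the cell's modulated rate span, i.e. rate span / |gain|
    clipped to the observed position span; the occupancy fraction is the
    whisking time spent inside that range divided by all whisking time.
    """
    if not fit.significant or fit.gain in (None, 0.0):
        return fit
    rates = curve.rate[curve.valid]
    rate_span = float(np.nanmax(rates) - np.nanmin(rates))
    pos = curve.position_bins[curve.valid]
    full_span = float(pos.max() - pos.min())
    rng_deg = min(rate_span / abs(fit.gain), full_span)
    lo, hi = fit.fit_range
    # center the range on the fitted segment, clipped to the observed span
    mid = 0.5 * (lo + hi)
    r_lo = max(mid - rng_deg / 2, float(pos.min()))
    r_hi = min(r_lo + rng_deg, float(pos.max()))
    r_lo = max(r_hi - rng_deg, float(pos.min()))

    n = kin.n
    whisk = epochs.sample_mask("whisking", n, kin.fs)
    inside = whisk & (kin.angle_f >= r_lo) & (kin.angle_f <= r_hi)
    frac = float(inside.sum() / max(whisk.sum(), 1))
    fit.encoding_range = float(r_hi - r_lo)
    fit.occupancy_fraction = frac
    return fit
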