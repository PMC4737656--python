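"""Linear transfer-function decoding of whisker position from SS rate.

A ridge-regularized FIR filter (time-domain Wiener filter, lags
+/-500 ms at 1 ms) is estimated on a training split of the recording,
mapping the mean-centered instantaneous rate to the mean-centered
whisker position.  The normal equations use the rate autocorrelation
(Toeplitz) and the rate-position cross-correlation; the ridge weight is
chosen by generalized cross-validation on the training split only.  The
filter is then applied to the held-out rate and the reconstruction is
scored by its Pearson correlation with the 6 Hz set point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats as sps

from .kinematics import Kinematics
from .spikes import RateSeries

KERNEL_HALF_S = 0.5
MIN_DURATION_S = 300.0


@dataclass
class DecodingModel:
    kernel: np.ndarray          # weight per lag
    lags_s: np.ndarray          # symmetric around 0
    intercept: float            # deg (mean position of the training split)
    rate_mean: float            # Hz (mean rate of the training split)
    ridge_lambda: float
    train_interval: tuple       # s


@dataclass
class DecodingResult:
    reconstruction: np.ndarray  # deg, on the (trimmed) test split
    times: np.ndarray
    r_setpoint: float
    r_position: float
    test_interval: tuple


def estimate_transfer_function(
    rate: RateSeries,
    kin: Kinematics,
    split: float = 0.5,
    kernel_half_s: float = KERNEL_HALF_S,
    min_duration_s: float = MIN_DURATION_S,
    lambdas: np.ndarray | None = None,
    target: str = "position",
) -> DecodingModel:
    """Fit the FIR rate-to-position filter on the first ``split`` fraction.

    Recordings shorter than 300 s are refused (the standard eligibility
    rule for transfer-function analysis).  ``target`` may be
    ``"position"`` (default) or ``"setpoint"``.
    """
    if not 0.0 < split < 1.0:
        raise ValueError("split fraction must lie in (0, 1)")
    n = min(rate.n, kin.n)
    if n / kin.fs < min_duration_s:
        raise ValueError(
            f"recording {n / kin.fs:.0f} s < {min_duration_s:.0f} s eligibility"
        )
    fs = kin.fs
    half = int(round(kernel_half_s * fs))
    lags = np.arange(-half, half + 1)
    n_train = int(n * split)
    x = rate.rate[:n_train].astype(float)
    y = (kin.angle_f if target == "position" else kin.setpoint)[:n_train].astype(float)
    if np.std(x) < 1e-9:
        raise ValueError("rate variance ~ 0: degenerate regressor")
    xm, ym = x.mean(), y.mean()
    xc, yc = x - xm, y - ym

    # normal equations via FFT correlations (Wiener-Hopf with Toeplitz X'X)
    nfft = int(2 ** np.ceil(np.log2(n_train + 2 * half + 1)))
    xf = np.fft.rfft(xc, nfft)
    yf = np.fft.rfft(yc, nfft)
    acorr_full = np.fft.irfft(xf * np.conj(xf), nfft)
    auto = acorr_full[: 2 * half + 1] / n_train          # lags 0..2*half
    ccorr_full = np.fft.irfft(yf * np.conj(xf), nfft)    # sum y(t) x(t-k)
    cross = np.concatenate(
        [ccorr_full[nfft - half:], ccorr_full[: half + 1]]
    ) / n_train                                           # lags -half..half

    A = linalg.toeplitz(auto)
    evals, evecs = np.linalg.eigh(A)
    evals = np.maximum(evals, 0.0)
    b = evecs.T @ cross
    syy = float(np.mean(yc**2))
    if lambdas is None:
        lambdas = np.logspace(-6, 2, 25) * max(evals.max(), 1e-12)

    def gcv(lam):
        denom = evals + lam
        rss = syy - 2 * np.sum(b**2 / denom) + np.sum(evals * b**2 / denom**2)
        df = np.sum(evals / denom)
        return max(rss, 1e-15) / (1.0 - df / n_train) ** 2

    lam_best = min(lambdas, key=gcv)
    w = evecs @ (b / (evals + lam_best))
    return DecodingModel(
        kernel=w, lags_s=lags / fs, intercept=float(ym), rate_mean=float(xm),
        ridge_lambda=float(lam_best), train_interval=(0.0, n_train / fs),
    )


def reconstruct_position(
    model: DecodingModel, rate: RateSeries, interval: tuple | None = None
):
    """Apply the filter to a rate series; kernel-support edges are trimmed.

    Returns ``(times, reconstruction)`` over ``interval`` (default: the
    whole series) minus half a kernel support at each end.
    """
    fs = rate.fs
    half = (model.kernel.size - 1) // 2
    if interval is None:
        i0, i1 = 0, rate.n
    else:
        i0 = int(round((interval[0] - rate.t_start) * fs))
        i1 = int(round((interval[1] - rate.t_start) * fs))
    if i1 - i0 <= 2 * half:
        raise ValueError("interval shorter than the kernel support")
    lo, hi = max(i0 - half, 0), min(i1 + half, rate.n)
    xc = rate.rate[lo:hi] - model.rate_mean
    # y(t) = sum_k w_k x(t - k); with the kernel stored in lag order
    # -half..+half, "same"-mode convolution applies exactly this sum
    full = np.convolve(xc, model.kernel, mode="same")
    rec = full[(i0 - lo) : (i1 - lo)] + model.intercept
    times = rate.t_start + np.arange(i0, i1) / fs
    # trim edges lacking full kernel support
    trim0 = half - (i0 - lo)
    trim1 = half - (hi - i1)
    sl = slice(max(trim0, 0), rec.size - max(trim1, 0))
    return times[sl], rec[sl]


def evaluate_reconstruction(reconstruction: np.ndarray, setpoint: np.ndarray) -> float:
    """Pearson correlation between a reconstruction and the set point."""
    if reconstruction.size != setpoint.size:
        raise ValueError("series must be aligned and equal length")
    if np.std(reconstruction) == 0 or np.std(setpoint) == 0:
        return float("nan")
    return float(sps.pearsonr(reconstruction, setpoint).statistic)


def decode_session(
    rate: RateSeries,
    kin: Kinematics,
    split: float = 0.5,
    **kwargs,
) -> DecodingResult:
    """Train on the first split, reconstruct and score the remainder.

    The set-point score compares like with like: the reconstruction is
    low-passed at 6 Hz (the set-point band) before the correlation, so
    that supra-band estimation noise passed by the FIR filter does not
    depress the score of an otherwise faithful slow reconstruction.
    ``r_position`` is computed on the raw reconstruction.
    """
    if kin.setpoint is None:
        raise ValueError("kinematics must carry the set point")
    model = estimate_transfer_function(rate, kin, split=split, **kwargs)
    n = min(rate.n, kin.n)
    t_split = model.train_interval[1]
    times, rec = reconstruct_position(model, rate, interval=(t_split, n / kin.fs))
    idx = np.round(times * kin.fs).astype(int)
    idx = np.clip(idx, 0, n - 1)
    assert idx.min() >= int(t_split * kin.fs), "held-out scoring touched training data"
    from .kinematics import zero_phase_filter

    rec_slow = zero_phase_filter(rec, kin.fs, 6.0, "lowpass")
    r_sp = evaluate_reconstruction(rec_slow, kin.setpoint[idx])
    r_pos = evaluate_reconstruction(rec, kin.angle_f[idx])
    return DecodingResult(
        reconstruction=rec, times=times, r_setpoint=r_sp, r_position=r_pos,
        test_interval=(float(times[0]), float(times[-1])),
    )
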