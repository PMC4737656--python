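"""Whisking-modulation classification and the locomotion comparison.

A cell is rate-modulated when its per-epoch rates differ between
whisking and quiet epochs (two-sided Mann-Whitney-Wilcoxon, p < 0.05);
the direction is the sign of the median difference.  Spike-timing
changes are tested separately with a two-sample Kolmogorov-Smirnov test
on the ISI distributions.  No multiple-testing correction is applied
across cells; significance is reported per cell at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .kinematics import EpochSet
from .spikes import SpikeTrain, epoch_rates, isi_cv

ALPHA = 0.05


@dataclass
class ModulationResult:
    """Per-cell whisking-modulation summary."""

    p_rate: float
    direction: str              # increase / decrease / none
    rel_change: float           # % of quiet-epoch baseline
    rate_quiet: float
    rate_whisk: float
    p_cv: float | None = None
    cv_quiet: float | None = None
    cv_whisk: float | None = None
    n_quiet: int = 0
    n_whisk: int = 0
    underpowered: bool = False


def test_rate_modulation(
    train: SpikeTrain,
    epochs: EpochSet,
    min_epochs: int = 5,
    use_cs: bool = False,
) -> ModulationResult:
    """Mann-Whitney test of per-epoch rates, whisking vs quiet.

    ``use_cs=True`` runs the identical test on the complex-spike train.
    With fewer than ``min_epochs`` epochs in either pool the result is
    flagged underpowered and left unclassified.
    """
    t = train
    if use_cs:
        t = SpikeTrain(ss_times=train.cs_times, cs_times=np.empty(0),
                       t_start=train.t_start, t_end=train.t_end)
    rq = epoch_rates(t, epochs, "quiet")
    rw = epoch_rates(t, epochs, "whisking")
    if rq.size < min_epochs or rw.size < min_epochs:
        return ModulationResult(
            p_rate=float("nan"), direction="none", rel_change=float("nan"),
            rate_quiet=float(np.mean(rq)) if rq.size else float("nan"),
            rate_whisk=float(np.mean(rw)) if rw.size else float("nan"),
            n_quiet=rq.size, n_whisk=rw.size, underpowered=True,
        )
    if np.all(rq == rq[0]) and np.all(rw == rw[0]) and rq[0] == rw[0]:
        p = 1.0  # identical constant samples: exact tie
    else:
        p = float(sps.mannwhitneyu(rw, rq, alternative="two-sided").pvalue)
    mean_q, mean_w = float(np.mean(rq)), float(np.mean(rw))
    direction = "none"
    if p < ALPHA:
        direction = "increase" if np.median(rw) > np.median(rq) else "decrease"
    rel = 100.0 * (mean_w - mean_q) / mean_q if mean_q > 0 else float("nan")
    return ModulationResult(
        p_rate=p, direction=direction, rel_change=rel,
        rate_quiet=mean_q, rate_whisk=mean_w,
        n_quiet=rq.size, n_whisk=rw.size,
    )


def test_cv_change(isi_quiet: np.ndarray, isi_whisk: np.ndarray,
                   min_isis: int = 10) -> float:
    """Two-sample KS p-value comparing quiet vs whisking ISI distributions."""
    isi_quiet = np.asarray(isi_quiet, float)
    isi_whisk = np.asarray(isi_whisk, float)
    if isi_quiet.size < min_isis or isi_whisk.size < min_isis:
        return float("nan")
    return float(sps.ks_2samp(isi_quiet, isi_whisk).pvalue)


def modulation_report(train: SpikeTrain, epochs: EpochSet) -> ModulationResult:
    """Rate test plus CV/KS timing analysis in one record."""
    res = test_rate_modulation(train, epochs)
    cv_q, isi_q = isi_cv(train, epochs, "quiet")
    cv_w, isi_w = isi_cv(train, epochs, "whisking")
    res.cv_quiet, res.cv_whisk = cv_q, cv_w
    res.p_cv = test_cv_change(isi_q, isi_w)
    return res


@dataclass
class LocomotionResult:
    p: float | None
    mean_rate_shift: float | None   # Hz, whisking+locomotion minus whisking-only
    mean_angle_shift: float | None  # deg, same comparison
    n_cells: int
    applicable: bool


def test_locomotion_effect(rate_pairs, angle_pairs=None,
                           min_cells: int = 3) -> LocomotionResult:
    """Paired t-test of SS rate, whisking-only vs whisking+locomotion.

    ``rate_pairs`` is a sequence of (rate_whisk_only, rate_whisk_loco)
    per cell; ``angle_pairs`` optionally gives the matching mean whisker
    angles, from which the protraction shift during running is reported.
    """
    pairs = np.asarray(list(rate_pairs), dtype=float)
    if pairs.ndim != 2 or pairs.shape[0] < min_cells:
        return LocomotionResult(None, None, None,
                                n_cells=0 if pairs.ndim != 2 else pairs.shape[0],
                                applicable=False)
    a, b = pairs[:, 0], pairs[:, 1]
    if np.allclose(a, b):
        p = 1.0
    else:
        p = float(sps.ttest_rel(b, a).pvalue)
    angle_shift = None
    if angle_pairs is not None:
        ap = np.asarray(list(angle_pairs), dtype=float)
        angle_shift = float(np.mean(ap[:, 1] - ap[:, 0]))
    return LocomotionResult(
        p=p, mean_rate_shift=float(np.mean(b - a)),
        mean_angle_shift=angle_shift, n_cells=pairs.shape[0], applicable=True,
    )


def cs_ss_change_correlation(cs_changes, ss_changes):
    """Pearson correlation between per-cell CS and SS relative rate changes."""
    r, p = sps.pearsonr(np.asarray(cs_changes, float),
                        np.asarray(ss_changes, float))
    return float(r), float(p)
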