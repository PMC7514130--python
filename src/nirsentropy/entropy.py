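"""Sample Entropy and Multiscale Entropy of hemoglobin oscillations.

Sample Entropy (SampEn) of a series ``x_1..x_N`` is the negative natural
logarithm of the conditional probability that two delay-embedded template
vectors of length ``m`` that match within a tolerance ``r`` (Chebyshev
distance) still match when extended to length ``m + 1``.  Self-matches are
excluded.  Both the ``m``- and the ``(m+1)``-template counts are taken
over the common template index range ``i <= N - m*T`` (the
Richman-Moorman convention), which guarantees ``A <= B`` and hence
``SampEn = -ln(A/B) >= 0``, and yields exactly 0 for a constant series.

Multiscale Entropy (MSE) evaluates SampEn on coarse-grained versions of
the series: non-overlapping block averages of length ``tau``.  Following
standard MSE practice the tolerance ``r`` is fixed once from the standard
deviation of the original (``tau = 1``) series and reused at every scale,
so that MSE changes across scales reflect structure, not renormalized
tolerance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .recording import HemoglobinRecording, PhaseWindows

try:  # pragma: no cover - exercised implicitly
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


@dataclass(frozen=True)
class SampEnParams:
    """SampEn parameters.

    m
        Embedding (template) dimension; templates of length ``m`` and
        ``m + 1`` are compared.
    r_factor
        Tolerance as a multiple of the series SD: ``r = r_factor * SD``.
    delay
        Time delay ``T`` in samples between template components.
    """

    m: int = 2
    r_factor: float = 0.2
    delay: int = 1

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r_factor <= 0:
            raise ValueError("r_factor must be positive")
        if self.delay < 1:
            raise ValueError("delay must be >= 1")


def _count_matches_numpy(x: np.ndarray, m: int, T: int, r: float):
    """Count template pairs (i < j) within tolerance at dims m and m+1."""
    n = len(x) - m * T
    idx = np.arange(n)[:, None] + np.arange(m + 1)[None, :] * T
    templ = x[idx]  # (n, m+1); first m columns are the m-templates
    dist_m = np.zeros((n, n))
    for k in range(m):
        np.maximum(dist_m, np.abs(templ[:, k, None] - templ[None, :, k]), out=dist_m)
    dist_m1 = np.maximum(dist_m, np.abs(templ[:, m, None] - templ[None, :, m]))
    iu = np.triu_indices(n, k=1)
    b = int(np.count_nonzero(dist_m[iu] <= r))
    a = int(np.count_nonzero(dist_m1[iu] <= r))
    return b, a


if _HAVE_NUMBA:

    @numba.njit(cache=False, fastmath=False)
    def _count_matches_numba(x, m, T, r):  # pragma: no cover - jitted
        n = len(x) - m * T
        b = 0
        a = 0
        for i in range(n):
            for j in range(i + 1, n):
                d = 0.0
                for k in range(m):
                    dk = abs(x[i + k * T] - x[j + k * T])
                    if dk > d:
                        d = dk
                    if d > r:
                        break
                if d <= r:
                    b += 1
                    if abs(x[i + m * T] - x[j + m * T]) <= r:
                        a += 1
        return b, a


def _count_matches(x: np.ndarray, m: int, T: int, r: float):
    if _HAVE_NUMBA:
        return _count_matches_numba(x, m, T, float(r))
    return _count_matches_numpy(x, m, T, float(r))


def sample_entropy(
    series, params: SampEnParams = SampEnParams(), r: float | None = None
) -> float:
    """Sample Entropy of a 1-D series, in nats.

    Parameters
    ----------
    series
        1-D array-like, length ``N > (m + 1) * delay + 1``.
    params
        Embedding dimension, tolerance factor and delay.
    r
        Absolute tolerance override.  When ``None`` (the default) the
        tolerance is ``params.r_factor * SD(series)`` with the population
        (ddof=0) standard deviation.  Multiscale entropy passes the
        tolerance of the original series explicitly.

    Returns
    -------
    float
        ``-ln(A / B)`` where ``A`` and ``B`` are the total numbers of
        ``(m+1)``- and ``m``-template matches.  ``NaN`` when no
        ``(m+1)``-template pair matches (the conditional probability is
        undefined); 0.0 with a warning for a constant series.
    """
    x = np.ascontiguousarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    m, T = params.m, params.delay
    n_templates = len(x) - m * T
    if len(x) <= (m + 1) * T + 1 or n_templates < 2:
        raise ValueError(
            f"series of length {len(x)} too short for m={m}, delay={T}"
        )
    if r is None:
        sd = float(x.std())
        if sd == 0.0:
            warnings.warn(
                "constant series: SampEn defined as 0", RuntimeWarning, stacklevel=2
            )
            return 0.0
        r = params.r_factor * sd
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    b, a = _count_matches(x, m, T, r)
    if b == 0 or a == 0:
        warnings.warn(
            f"no template matches at m={m} (B={b}, A={a}); SampEn undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return math.nan
    return -math.log(a / b)


def coarse_grain(series, tau: int) -> np.ndarray:
    """Coarse-grain a series by non-overlapping block averages of length tau.

    ``y_j = mean(x[(j-1)*tau .. j*tau])`` for ``j = 1 .. floor(N/tau)``;
    trailing samples that do not fill a block are discarded.
    """
    if tau < 1:
        raise ValueError("scale factor tau must be >= 1")
    x = np.asarray(series, float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if len(x) < tau:
        raise ValueError(f"series of length {len(x)} shorter than tau={tau}")
    n = len(x) // tau
    return x[: n * tau].reshape(n, tau).mean(axis=1)


def multiscale_entropy(
    series,
    params: SampEnParams = SampEnParams(),
    scales=(2, 3),
) -> dict[int, float]:
    """SampEn of coarse-grained series at each scale factor.

    The tolerance is computed once from the SD of the original series and
    held fixed across scales.
    """
    x = np.asarray(series, float)
    sd = float(x.std())
    if sd == 0.0:
        warnings.warn("constant series: MSE defined as 0", RuntimeWarning, stacklevel=2)
        return {int(tau): 0.0 for tau in scales}
    r = params.r_factor * sd
    out = {}
    for tau in scales:
        try:
            out[int(tau)] = sample_entropy(coarse_grain(x, int(tau)), params, r=r)
        except ValueError as exc:
            raise ValueError(f"scale tau={tau}: {exc}") from exc
    return out


def homogenize_phase_lengths(
    windows_by_subject: dict[str, PhaseWindows],
) -> dict[str, PhaseWindows]:
    """Truncate each phase, from the end, to the cohort-minimum length.

    Entropy estimates depend on series length, so every subject's window
    for a given phase is cut to the shortest one in the cohort before any
    entropy is computed.
    """
    if not windows_by_subject:
        raise ValueError("empty cohort")
    labels = next(iter(windows_by_subject.values())).labels
    for sid, win in windows_by_subject.items():
        missing = set(labels) - set(win.labels)
        if missing:
            raise ValueError(f"subject {sid!r} missing phases {sorted(missing)}")
    min_len = {
        lab: min(win.length(lab) for win in windows_by_subject.values())
        for lab in labels
    }
    out = {}
    for sid, win in windows_by_subject.items():
        for lab in labels:
            win = win.truncate(lab, min_len[lab])
        out[sid] = win
    return out


@dataclass
class ComplexityTable:
    """Subject x channel entropy values for one phase and one metric."""

    values: pd.DataFrame  # index subject_id, columns channel index
    groups: pd.Series  # subject_id -> group label
    phase: str
    metric: str  # "sampen" or "mse"
    tau: int
    params: SampEnParams
    truncated_length: int

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def to_tidy(self) -> pd.DataFrame:
        """One row per (subject, channel) observation."""
        long = (
            self.values.rename_axis(index="subject_id", columns="channel")
            .stack(future_stack=True)
            .rename("value")
            .reset_index()
        )
        long.insert(1, "group", self.groups.loc[long["subject_id"]].to_numpy())
        long["phase"] = self.phase
        long["metric"] = self.metric
        long["tau"] = self.tau
        long["n_samples"] = self.truncated_length
        return long


def compute_complexity_table(
    cohort: list[HemoglobinRecording],
    phase: str,
    metric: str = "sampen",
    params: SampEnParams = SampEnParams(),
    tau: int = 1,
    windows: dict[str, PhaseWindows] | None = None,
    require_cbsi: bool = True,
) -> ComplexityTable:
    """Entropy of corrected O2Hb per subject and channel for one phase.

    Phase windows are homogenized across the cohort first (unless
    pre-homogenized windows are supplied).  ``metric="sampen"`` requires
    ``tau == 1``; ``metric="mse"`` coarse-grains at ``tau`` with the
    tolerance anchored to the original series SD.  Undefined entropies
    (no template matches) are recorded as missing, not clamped.
    """
    if metric not in ("sampen", "mse"):
        raise ValueError(f"unknown metric {metric!r}")
    if metric == "sampen" and tau != 1:
        raise ValueError("sampen is defined at tau=1; use metric='mse' for tau>1")
    if require_cbsi and not all(rec.cbsi_applied for rec in cohort):
        raise ValueError(
            "complexity is computed on CBSI-corrected O2Hb; run cbsi_correct first"
        )
    if windows is None:
        windows = homogenize_phase_lengths(
            {rec.subject_id: rec.events for rec in cohort}
        )
    lengths = {win.length(phase) for win in windows.values()}
    if len(lengths) != 1:
        raise ValueError(f"phase {phase!r} windows are not homogenized: {lengths}")
    (trunc_len,) = lengths

    rows, groups = {}, {}
    for rec in cohort:
        start, end = windows[rec.subject_id].get(phase)
        vals = np.empty(rec.n_channels)
        for ch in range(rec.n_channels):
            seg = rec.o2hb[ch, start:end]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                if metric == "sampen":
                    vals[ch] = sample_entropy(seg, params)
                else:
                    vals[ch] = multiscale_entropy(seg, params, scales=(tau,))[tau]
        rows[rec.subject_id] = vals
        groups[rec.subject_id] = rec.group_label
    values = pd.DataFrame.from_dict(rows, orient="index")
    values.index.name = "subject_id"
    return ComplexityTable(
        values=values,
        groups=pd.Series(groups, name="group"),
        phase=phase,
        metric=metric,
        tau=int(tau),
        params=params,
        truncated_length=int(trunc_len),
    )
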