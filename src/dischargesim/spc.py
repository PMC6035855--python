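"""Six Sigma statistical layer.

Individuals/moving-range (I-MR) control charts for subgroup-size-1 duration
data, normal-model process capability against an upper specification limit
(150 minutes by default — the longest acceptable discharge), the sigma
quality level under the conventional 1.5-sigma long-term shift, the
confidence-interval sample-size formula, and a two-population split of
discharge durations (standard vs. complex discharges).

I-MR limits use the textbook constants for a moving range of span 2:
``UCL_x/LCL_x = xbar +- 2.66 * mrbar`` and ``UCL_mr = 3.267 * mrbar``
(2.66 = 3/d2 with d2 = 1.128).  Only the beyond-limits rule is applied;
run rules are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .engine import DischargeRecord

E2 = 2.66  # 3 / d2(2), d2(2) = 1.128
D4 = 3.267


class InsufficientDataError(ValueError):
    pass


@dataclass
class ControlChartResult:
    xbar: float
    mrbar: float
    ucl_x: float
    lcl_x: float
    ucl_mr: float
    out_of_control_indices: List[int]
    n: int
    phase_label: Optional[str] = None


@dataclass
class CapabilityResult:
    usl: float
    mu_hat: float
    sigma_hat: float
    p_above_usl: float
    z_bench: float
    sql: float


def imr_chart(series: Sequence[float], phase_label: Optional[str] = None) -> ControlChartResult:
    """Individuals & moving-range chart statistics for an ordered series.

    Moving ranges are MR_i = |x_i - x_{i-1}|.  A point is out of control if
    the individual value falls outside [LCL_x, UCL_x] or its moving range
    exceeds UCL_mr.  A constant series collapses all limits onto the mean.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise InsufficientDataError("an I-MR chart needs at least 2 ordered observations")
    mr = np.abs(np.diff(x))
    xbar = float(x.mean())
    mrbar = float(mr.mean())
    ucl_x = xbar + E2 * mrbar
    lcl_x = xbar - E2 * mrbar
    ucl_mr = D4 * mrbar
    ooc = set(np.nonzero((x > ucl_x) | (x < lcl_x))[0].tolist())
    ooc |= set((np.nonzero(mr > ucl_mr)[0] + 1).tolist())
    return ControlChartResult(
        xbar=xbar, mrbar=mrbar, ucl_x=ucl_x, lcl_x=lcl_x, ucl_mr=ucl_mr,
        out_of_control_indices=sorted(ooc), n=len(x), phase_label=phase_label,
    )


def sql_from_zbench(z: float) -> float:
    """Sigma quality level: Z_bench plus the conventional 1.5-sigma shift."""
    return z + 1.5


def capability(
    series: Optional[Sequence[float]] = None,
    mu: Optional[float] = None,
    sigma: Optional[float] = None,
    usl: float = 150.0,
) -> CapabilityResult:
    """Normal-model capability against an upper specification limit.

    Give either a duration series (overall long-term mean/SD are estimated
    from it) or explicit ``mu`` and ``sigma``.  ``z_bench`` is the standard
    normal quantile whose upper tail equals the out-of-spec proportion,
    which under a one-sided normal model is (usl - mu) / sigma.
    """
    if series is not None:
        x = np.asarray(series, dtype=float)
        if len(x) < 2:
            raise InsufficientDataError("capability from a series needs >= 2 observations")
        mu = float(x.mean())
        sigma = float(x.std(ddof=1))
    if mu is None or sigma is None:
        raise ValueError("provide a series or both mu and sigma")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    z_bench = (usl - mu) / sigma
    p_above = float(stats.norm.sf(z_bench))
    return CapabilityResult(
        usl=usl, mu_hat=mu, sigma_hat=sigma,
        p_above_usl=p_above, z_bench=z_bench, sql=sql_from_zbench(z_bench),
    )


def required_sample_size(z: float, s: float, e: float) -> int:
    """Observations needed so a mean estimate has margin ``e`` at quantile ``z``.

    ceil((z * s / e)^2), at least 1.  With z = 1.96, s = 67 and e = 30 this
    gives the study's 20-patient minimum.
    """
    if e <= 0:
        raise ValueError("error bound e must be > 0")
    if s < 0:
        raise ValueError("sample SD s must be >= 0")
    return max(1, int(np.ceil((z * s / e) ** 2)))


def classify_populations(
    records: Union[Sequence[DischargeRecord], Sequence[float]],
    seed: int = 0,
) -> Tuple[np.ndarray, Dict[str, Dict[str, float]]]:
    """Split discharges into standard vs. complex populations.

    When full records with need flags are given, labels follow the profile
    rule exactly (complex iff equipment, supplies or add-on).  For a bare
    duration series the split is a two-component univariate Gaussian mixture
    fitted by EM with deterministic k-means initialisation; the component
    with the smaller mean is labelled standard.

    Returns (labels, stats): labels is an array of "standard"/"complex"
    strings, stats maps each label to {mean, sd, n} of total duration.
    """
    if len(records) == 0:
        raise InsufficientDataError("no records to classify")

    if isinstance(records[0], DischargeRecord):
        labels = np.array([r.profile.population for r in records])
        totals = np.array([r.total_minutes for r in records])
    else:
        totals = np.asarray(records, dtype=float)
        if len(totals) < 4:
            raise InsufficientDataError("mixture classification needs >= 4 durations")
        if np.ptp(totals) == 0.0:
            warnings.warn("degenerate fit: all durations identical; single effective component")
            labels = np.array(["standard"] * len(totals))
        else:
            from sklearn.mixture import GaussianMixture

            gm = GaussianMixture(
                n_components=2, covariance_type="full", n_init=1,
                init_params="kmeans", random_state=seed, max_iter=500,
            ).fit(totals.reshape(-1, 1))
            comp = gm.predict(totals.reshape(-1, 1))
            means = gm.means_.ravel()
            standard_comp = int(np.argmin(means))
            labels = np.where(comp == standard_comp, "standard", "complex")

    out: Dict[str, Dict[str, float]] = {}
    for lab in ("standard", "complex"):
        sel = totals[labels == lab]
        if len(sel):
            out[lab] = {
                "mean": float(sel.mean()),
                "sd": float(sel.std(ddof=1)) if len(sel) > 1 else 0.0,
                "n": int(len(sel)),
            }
    return labels, out
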