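"""Association analyses over per-patient DMP burdens.

Three tests mirror the downstream questions of a heterogeneity study:
Welch t between tumour-type groups (never computed against a group of one
sample — such comparisons return an explicit not-computable marker), Pearson
correlation between intratumour purity differences and DMP counts, and a
univariate Cox proportional-hazards regression of the time-to-relapse
against the temporal DMP count. The Cox fit is the classic Breslow partial
likelihood maximized by Newton–Raphson from β=0; with day-resolution
intervals ties are rare and Breslow's handling admits a simple closed-form
oracle. All subjects are treated as events by default (everyone relapsed),
though a censoring vector is accepted for generality.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .exceptions import NumericalError, ValidationError
from .io_formats import SampleSheet

logger = logging.getLogger(__name__)


@dataclass
class GroupComparison:
    """Welch two-sample t test between two groups of DMP burdens."""

    label_x: str
    label_y: str
    n_x: int
    n_y: int
    computable: bool
    reason: str | None = None
    mean_x: float | None = None
    mean_y: float | None = None
    var_x: float | None = None
    var_y: float | None = None
    t_statistic: float | None = None
    df: float | None = None
    p_value: float | None = None


@dataclass
class CorrelationResult:
    defined: bool
    r: float | None = None
    p_value: float | None = None
    n: int = 0
    reason: str | None = None


@dataclass
class CoxFit:
    identifiable: bool
    coefficient: float | None = None       # log hazard ratio per DMP
    standard_error: float | None = None
    wald_z: float | None = None
    p_value: float | None = None
    log_partial_likelihood: float | None = None
    null_log_partial_likelihood: float | None = None
    n_events: int = 0
    iterations: int = 0
    reason: str | None = None


# ---------------------------------------------------------------------------


def welch_t_test(
    x: Sequence[float], y: Sequence[float],
    label_x: str = "x", label_y: str = "y",
) -> GroupComparison:
    """Welch's unequal-variance t with Satterthwaite degrees of freedom.

    A group of size < 2 yields a not-computable result rather than a number.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        return GroupComparison(
            label_x, label_y, len(x), len(y), computable=False,
            reason="group with fewer than 2 samples",
        )
    res = stats.ttest_ind(x, y, equal_var=False)
    return GroupComparison(
        label_x, label_y, len(x), len(y), computable=True,
        mean_x=float(x.mean()), mean_y=float(y.mean()),
        var_x=float(x.var(ddof=1)), var_y=float(y.var(ddof=1)),
        t_statistic=float(res.statistic), df=float(res.df),
        p_value=float(res.pvalue),
    )


def group_comparisons(
    burdens: Mapping[str, float], groups: Mapping[str, str]
) -> list[GroupComparison]:
    """All pairwise Welch tests between group labels of per-patient burdens."""
    by_group: dict[str, list[float]] = {}
    for patient, burden in burdens.items():
        label = groups.get(patient)
        if label is None:
            continue
        by_group.setdefault(label, []).append(float(burden))
    labels = sorted(by_group)
    out = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            out.append(welch_t_test(by_group[a], by_group[b], a, b))
    return out


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Sample Pearson r with a two-sided p from the t transform (n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("pearson correlation needs paired vectors, n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite values in correlation input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(defined=False, n=len(x),
                                 reason="zero variance in one vector")
    res = stats.pearsonr(x, y)
    return CorrelationResult(defined=True, r=float(res.statistic),
                             p_value=float(res.pvalue), n=len(x))


def purity_dmp_association(
    summaries: Mapping[str, object],
    sheet: SampleSheet,
    mode: str,
) -> CorrelationResult:
    """Correlation between intratumour purity difference and DMP count.

    mode="spatial": per patient, x = max − min purity over the biopsies and
    y = the union DMP count. mode="temporal": x = |purity_relapse −
    purity_primary| and y = the pair's DMP count. Patients with missing
    purity are dropped with a warning. ``summaries`` maps patient to a
    summary object exposing ``union_count`` or ``count`` (a plain int also
    works).
    """
    if mode not in ("spatial", "temporal"):
        raise ValidationError(f"unknown mode {mode!r}")
    xs, ys = [], []
    for patient in sorted(summaries):
        summary = summaries[patient]
        count = getattr(summary, "union_count", None)
        if count is None:
            count = getattr(summary, "count", None)
        if count is None:
            count = int(summary)
        if mode == "spatial":
            sample_ids = sheet.samples_of(patient, roles=["spatial"])
        else:
            sample_ids = list(sheet.primary_relapse_pair(patient))
        purities = [sheet.row(s)["purity"] for s in sample_ids]
        if any(p is None or (isinstance(p, float) and math.isnan(p)) for p in purities):
            logger.warning("purity missing for patient %s; dropped", patient)
            continue
        if mode == "spatial":
            xs.append(max(purities) - min(purities))
        else:
            xs.append(abs(purities[1] - purities[0]))
        ys.append(count)
    return pearson_correlation(xs, ys)


# ---------------------------------------------------------------------------
# Cox proportional hazards (univariate, Breslow ties)


def _cox_quantities(beta_hat: float, times: np.ndarray, x: np.ndarray,
                    events: np.ndarray) -> tuple[float, float, float]:
    """Breslow log partial likelihood, score and information at beta_hat.

    Each event contributes b·x_i − log Σ_{j: t_j ≥ t_i} exp(b·x_j); tied
    event times share the same risk set but keep separate terms.
    """
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    x_sorted = x[order]
    e_sorted = events[order]
    ex = np.exp(beta_hat * x_sorted)
    # suffix sums over the risk set {j: t_j >= t_i}
    s0 = np.cumsum(ex[::-1])[::-1]
    s1 = np.cumsum((ex * x_sorted)[::-1])[::-1]
    s2 = np.cumsum((ex * x_sorted ** 2)[::-1])[::-1]
    # tied times: every event at time t uses the full risk set {t_j >= t}
    first_at_time = np.searchsorted(t_sorted, t_sorted, side="left")
    ll = score = info = 0.0
    for i in np.flatnonzero(e_sorted):
        k = first_at_time[i]
        ll += beta_hat * x_sorted[i] - math.log(s0[k])
        mean = s1[k] / s0[k]
        score += x_sorted[i] - mean
        info += s2[k] / s0[k] - mean ** 2
    return ll, score, info


def cox_relapse_vs_dmps(
    intervals: Sequence[float],
    dmp_counts: Sequence[float],
    events: Sequence[int] | None = None,
    log1p: bool = False,
    tol: float = 1e-9,
    max_iter: int = 50,
) -> CoxFit:
    """Univariate Cox PH regression of time-to-relapse on the DMP count.

    Newton–Raphson from β=0 with step halving; converged when |score| < tol.
    ``log1p=True`` fits log(1 + count) instead of the raw count.
    """
    times = np.asarray(intervals, dtype=float)
    x = np.asarray(dmp_counts, dtype=float)
    if len(times) != len(x) or len(times) < 2:
        raise ValidationError("need paired intervals and counts, n >= 2")
    if (times <= 0).any():
        raise ValidationError("all relapse intervals must be > 0")
    ev = (np.ones(len(times), dtype=int) if events is None
          else np.asarray(events, dtype=int))
    if log1p:
        x = np.log1p(x)
    if np.ptp(x[ev == 1]) == 0:
        return CoxFit(identifiable=False, n_events=int(ev.sum()),
                      reason="zero-variance covariate")
    x_centred = x - x.mean()  # invariant reparametrization, better conditioning

    beta_hat = 0.0
    ll0, _, _ = _cox_quantities(0.0, times, x_centred, ev)
    ll, score, info = ll0, None, None
    for iteration in range(1, max_iter + 1):
        ll, score, info = _cox_quantities(beta_hat, times, x_centred, ev)
        if abs(score) < tol:
            se = 1.0 / math.sqrt(info)
            z = beta_hat / se
            p = 2 * stats.norm.sf(abs(z))
            return CoxFit(
                identifiable=True, coefficient=beta_hat, standard_error=se,
                wald_z=z, p_value=float(p), log_partial_likelihood=ll,
                null_log_partial_likelihood=ll0, n_events=int(ev.sum()),
                iterations=iteration,
            )
        if info <= 0:
            raise NumericalError("Cox information non-positive; fit diverged")
        step = score / info
        # step-halving safeguard against overshooting; tolerance keeps
        # float-precision-level likelihood wobble from stalling the solver
        wobble = 1e-12 * (1.0 + abs(ll))
        new_ll, *_ = _cox_quantities(beta_hat + step, times, x_centred, ev)
        halvings = 0
        while new_ll < ll - wobble and halvings < 30:
            step /= 2
            new_ll, *_ = _cox_quantities(beta_hat + step, times, x_centred, ev)
            halvings += 1
        beta_hat += step
    raise NumericalError(
        f"Cox fit did not converge in {max_iter} iterations "
        f"(last beta={beta_hat:.6g}, score={score:.3g}, loglik={ll:.6g})"
    )
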