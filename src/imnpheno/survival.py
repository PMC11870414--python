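"""Single-cell tracking, censored lifelines and survival statistics.

Per-frame detections are linked into tracks by greedy mutual
nearest-neighbour matching (a deterministic stand-in honouring the same
contract as a learned multi-object tracker: per-frame positions in,
identity-stable tracks out).  A track becomes a lifeline: entry at the
first frame the cell is recognized as an iMN, an observed death event when
the cell disappears before the last frame, censoring at the last imaging
day otherwise.

The statistics are implemented from first principles:

* Kaplan-Meier product-limit estimator ``S(t) = prod_{t_i <= t} (1 - d_i / n_i)``;
* pairwise logrank tests (observed minus expected events under the pooled
  risk set, chi-square with 1 df, Bonferroni-adjusted across pairs);
* Cox proportional hazards by Newton maximization of the partial
  likelihood with the Efron correction for tied event times, standard
  errors from the inverse observed information.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ParameterError, PipelineError
from .synth.scene import CLASS_IMN

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Detection:
    """One detected cell body in one frame."""

    frame: int
    row: float
    col: float
    cell_class: str = CLASS_IMN
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ParameterError("frame index must be >= 0")
        if not 0.0 <= self.confidence <= 1.0:
            raise ParameterError("confidence must be in [0, 1]")


@dataclass
class Track:
    """An identity-linked sequence of detections."""

    track_id: int
    detections: list = field(default_factory=list)

    @property
    def frames(self) -> list:
        return [d.frame for d in self.detections]

    @property
    def first_imn_frame(self):
        for d in self.detections:
            if d.cell_class == CLASS_IMN:
                return d.frame
        return None

    @property
    def last_seen_frame(self) -> int:
        return self.detections[-1].frame


@dataclass(frozen=True)
class Lifeline:
    """One subject's time at risk with an event or censoring flag."""

    subject_id: str
    group: str
    entry_day: float
    duration_days: float
    event: int  # 1 = death observed, 0 = censored

    def __post_init__(self) -> None:
        if self.duration_days < 0:
            raise ParameterError("duration must be >= 0")
        if self.event not in (0, 1):
            raise ParameterError("event must be 0 or 1")


# ---------------------------------------------------------------------------
# tracking


def link_detections(
    detections_by_frame,
    max_dist_um: float = 20.0,
    max_gap: int = 1,
    pixel_size: float = 1.0,
) -> list:
    """Greedy mutual nearest-neighbour linking across frames.

    ``detections_by_frame`` is a sequence (one entry per frame, possibly
    empty) of :class:`Detection` lists.  Unmatched detections start new
    tracks; a track unmatched for more than ``max_gap`` frames terminates.
    Distances are physical (µm) via ``pixel_size``.
    """
    active: list = []  # (track, last_frame)
    finished: list = []
    next_id = 0
    for f, dets in enumerate(detections_by_frame):
        pairs = []
        for ai, track in enumerate(active):
            last = track.detections[-1]
            for di, det in enumerate(dets):
                dist = math.hypot(det.row - last.row, det.col - last.col) * pixel_size
                if dist <= max_dist_um:
                    pairs.append((dist, ai, di))
        pairs.sort()
        used_a, used_d = set(), set()
        for _, ai, di in pairs:
            if ai in used_a or di in used_d:
                continue
            used_a.add(ai)
            used_d.add(di)
            active[ai].detections.append(dets[di])
        for di, det in enumerate(dets):
            if di not in used_d:
                active.append(Track(track_id=next_id, detections=[det]))
                next_id += 1
        still = []
        for track in active:
            if f - track.last_seen_frame > max_gap:
                finished.append(track)
            else:
                still.append(track)
        active = still
    finished.extend(active)
    finished.sort(key=lambda t: t.track_id)
    return finished


def tracks_to_lifelines(
    tracks, frame_days, group: str = "", id_prefix: str = "cell"
):
    """Convert tracks to censored lifelines; returns ``(lifelines, n_excluded)``.

    Entry is the day of the first iMN-classified detection.  A track last
    seen before the final frame is an observed death at its last-seen day;
    a track surviving to the final frame is censored there.  Tracks never
    classified iMN are excluded and counted.
    """
    days = [float(d) for d in frame_days]
    last_idx = len(days) - 1
    out = []
    excluded = 0
    for track in tracks:
        first = track.first_imn_frame
        if first is None:
            excluded += 1
            continue
        entry = days[first]
        last_seen = track.last_seen_frame
        if last_seen < last_idx:
            duration = days[last_seen] - entry
            event = 1
        else:
            duration = days[last_idx] - entry
            event = 0
        out.append(
            Lifeline(
                subject_id=f"{id_prefix}{track.track_id}",
                group=group,
                entry_day=entry,
                duration_days=duration,
                event=event,
            )
        )
    if excluded:
        log.info("%d tracks never classified iMN; excluded from lifelines", excluded)
    return out, excluded


def sample_lifelines(lifelines, n: int, seed: int = 0):
    """Uniform sample without replacement, seed-reproducible, order-stable."""
    if n <= 0:
        raise ParameterError("sample size must be > 0")
    if n >= len(lifelines):
        if n > len(lifelines):
            log.warning("requested %d lifelines but only %d available", n, len(lifelines))
        return list(lifelines)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(lifelines), size=n, replace=False))
    return [lifelines[i] for i in idx]


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KMCurve:
    """Product-limit survival estimate with at-risk counts."""

    times: np.ndarray  # event times, prefixed by 0
    survival: np.ndarray  # S(t) at those times; S(0) = 1
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        i = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(i, 0)])


def _durations_events(lifelines):
    dur = np.array([l.duration_days for l in lifelines], dtype=float)
    ev = np.array([l.event for l in lifelines], dtype=int)
    return dur, ev


def fit_km(lifelines) -> KMCurve:
    """Kaplan-Meier estimator on the duration scale (time since entry)."""
    if len(lifelines) == 0:
        raise ParameterError("no lifelines to fit")
    dur, ev = _durations_events(lifelines)
    order = np.argsort(dur, kind="stable")
    dur, ev = dur[order], ev[order]
    event_times = np.unique(dur[ev == 1])
    times = [0.0]
    surv = [1.0]
    at_risk = [len(dur)]
    n_events = [0]
    s = 1.0
    for t in event_times:
        n_i = int(np.sum(dur >= t))
        d_i = int(np.sum((dur == t) & (ev == 1)))
        s *= 1.0 - d_i / n_i
        times.append(float(t))
        surv.append(s)
        at_risk.append(n_i)
        n_events.append(d_i)
    return KMCurve(
        times=np.array(times),
        survival=np.array(surv),
        at_risk=np.array(at_risk),
        n_events=np.array(n_events),
    )


# ---------------------------------------------------------------------------
# logrank


def logrank_statistic(dur1, ev1, dur2, ev2) -> tuple:
    """Two-sample logrank chi-square and p-value (1 df)."""
    dur1 = np.asarray(dur1, dtype=float)
    dur2 = np.asarray(dur2, dtype=float)
    ev1 = np.asarray(ev1, dtype=int)
    ev2 = np.asarray(ev2, dtype=int)
    all_event_times = np.unique(np.concatenate([dur1[ev1 == 1], dur2[ev2 == 1]]))
    if all_event_times.size == 0:
        return 0.0, 1.0
    o_minus_e = 0.0
    var = 0.0
    for t in all_event_times:
        n1 = np.sum(dur1 >= t)
        n2 = np.sum(dur2 >= t)
        d1 = np.sum((dur1 == t) & (ev1 == 1))
        d2 = np.sum((dur2 == t) & (ev2 == 1))
        n = n1 + n2
        d = d1 + d2
        if n < 2:
            continue
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def logrank_pairwise(groups: dict) -> pd.DataFrame:
    """All-pairs logrank tests; raw and Bonferroni-adjusted p-values."""
    labels = sorted(groups)
    if len(labels) < 2:
        raise ParameterError("pairwise logrank needs >= 2 groups")
    for lab in labels:
        if len(groups[lab]) == 0:
            raise ParameterError(f"group {lab!r} is empty")
    rows = []
    n_pairs = len(labels) * (len(labels) - 1) // 2
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            da, ea = _durations_events(groups[a])
            db, eb = _durations_events(groups[b])
            chi2, p = logrank_statistic(da, ea, db, eb)
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "chi2": chi2,
                    "p": p,
                    "p_bonferroni": min(1.0, p * n_pairs),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties)


class ConvergenceError(PipelineError):
    """Newton iteration failed to converge."""


class SeparationError(PipelineError):
    """Monotone partial likelihood: a covariate separates events perfectly."""


@dataclass
class CoxResult:
    """Fitted Cox model: per-covariate log hazard ratios and Wald inference."""

    names: list
    coef: np.ndarray  # log hazard ratios
    se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p: np.ndarray
    log_likelihood: float
    n: int
    n_events: int
    iterations: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.names,
                "log_hr": self.coef,
                "hr": np.exp(self.coef),
                "se": self.se,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p": self.p,
            }
        )


def cox_partial_loglik(beta, durations, events, X):
    """Efron partial log-likelihood and its gradient/Hessian.

    Returns ``(loglik, gradient, hessian)``; the Hessian is of the
    log-likelihood (negative definite away from degeneracy).
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    dur = np.asarray(durations, dtype=float)
    ev = np.asarray(events, dtype=int)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != dur.size:
        X = X.T
    n, p = X.shape

    eta = X @ beta
    # cap to keep exp finite during aggressive Newton steps
    w = np.exp(np.clip(eta, -500, 500))
    wX = w[:, None] * X
    wXX = np.einsum("i,ij,ik->ijk", w, X, X)

    # process event times in decreasing order, accumulating risk-set sums
    order = np.argsort(-dur, kind="stable")
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    i = 0
    idx = order
    while i < n:
        t = dur[idx[i]]
        j = i
        tied = []
        while j < n and dur[idx[j]] == t:
            k = idx[j]
            S0 += w[k]
            S1 += wX[k]
            S2 += wXX[k]
            if ev[k] == 1:
                tied.append(k)
            j += 1
        d = len(tied)
        if d:
            D0 = float(np.sum(w[tied]))
            D1 = wX[tied].sum(axis=0)
            D2 = wXX[tied].sum(axis=0)
            xsum = X[tied].sum(axis=0)
            ll += float(eta[tied].sum())
            grad += xsum
            for l in range(d):
                frac = l / d
                a0 = S0 - frac * D0
                a1 = S1 - frac * D1
                a2 = S2 - frac * D2
                ll -= math.log(a0)
                grad -= a1 / a0
                hess -= a2 / a0 - np.outer(a1, a1) / a0**2
        i = j
    return ll, grad, hess


def cox_fit(
    durations,
    events,
    X,
    names=None,
    tol: float = 1e-8,
    max_iter: int = 100,
    alpha: float = 0.05,
) -> CoxResult:
    """Newton-Raphson fit of the Efron partial likelihood.

    Convergence when the gradient max-norm drops below ``tol``.  Diverging
    coefficients (monotone likelihood from perfect separation) raise
    :class:`SeparationError` naming the covariate; non-convergence raises
    :class:`ConvergenceError` with the iteration log.
    """
    dur = np.asarray(durations, dtype=float)
    ev = np.asarray(events, dtype=int)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != dur.size:
        X = X.T
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if ev.sum() < 1:
        raise ParameterError("Cox model needs at least one observed event")

    beta = np.zeros(p)
    ll, grad, hess = cox_partial_loglik(beta, dur, ev, X)
    history = [f"iter 0: loglik={ll:.6f} |grad|={np.abs(grad).max():.3g}"]
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        if np.abs(grad).max() < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                f"singular information matrix (covariate {names[int(np.argmax(np.abs(grad)))]})"
            ) from exc
        new_beta = beta - step
        new_ll, new_grad, new_hess = cox_partial_loglik(new_beta, dur, ev, X)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step *= 0.5
            new_beta = beta - step
            new_ll, new_grad, new_hess = cox_partial_loglik(new_beta, dur, ev, X)
            halvings += 1
        delta_ll = abs(new_ll - ll)
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        history.append(f"iter {it}: loglik={ll:.6f} |grad|={np.abs(grad).max():.3g}")
        if np.abs(beta).max() > 50:
            worst = names[int(np.argmax(np.abs(beta)))]
            raise SeparationError(
                f"monotone partial likelihood: covariate {worst!r} separates events"
            )
        # floating-point plateau: the gradient criterion can sit just above
        # tol for large log-likelihood magnitudes even at the optimum
        if np.abs(step).max() < 1e-10 and delta_ll < 1e-10:
            converged = True
            break
    if not converged and np.abs(grad).max() >= tol:
        raise ConvergenceError("Newton did not converge:\n" + "\n".join(history))

    if np.abs(beta).max() > 10:
        # |logHR| > 10 with a survival-scale design means the likelihood is
        # effectively monotone: the gradient vanished on a flat shoulder
        worst = names[int(np.argmax(np.abs(beta)))]
        raise SeparationError(
            f"monotone partial likelihood: covariate {worst!r} separates events"
        )
    info = -hess
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise SeparationError("observed information is singular at the optimum") from exc
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    z = stats.norm.ppf(1 - alpha / 2)
    pvals = 2 * stats.norm.sf(np.abs(beta / np.where(se > 0, se, np.nan)))
    return CoxResult(
        names=list(names),
        coef=beta,
        se=se,
        ci_lower=beta - z * se,
        ci_upper=beta + z * se,
        p=pvals,
        log_likelihood=ll,
        n=n,
        n_events=int(ev.sum()),
        iterations=it,
    )


def fit_cox(lifelines, reference_group: str | None = None) -> CoxResult:
    """Cox model on lifelines with group-indicator covariates.

    Groups are taken from each lifeline's ``group`` field; the reference
    (default: alphabetically first) is absorbed into the baseline hazard
    and every other group gets an indicator covariate whose coefficient is
    its log hazard ratio versus the reference.
    """
    if len(lifelines) == 0:
        raise ParameterError("no lifelines")
    groups = sorted({l.group for l in lifelines})
    ref = reference_group if reference_group is not None else groups[0]
    if ref not in groups:
        raise ParameterError(f"reference group {ref!r} not present")
    others = [g for g in groups if g != ref]
    if not others:
        raise ParameterError("Cox model needs >= 2 groups")
    X = np.array([[1.0 if l.group == g else 0.0 for g in others] for l in lifelines])
    dur, ev = _durations_events(lifelines)
    return cox_fit(dur, ev, X, names=[f"{g}_vs_{ref}" for g in others])
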