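"""Scoring predicted division timelines against ground truth.

Predicted and annotated events are paired one-to-one by the Hungarian
algorithm (minimum total frame offset, pairings allowed only within
``max_gap`` frames), giving tolerance-window precision/recall/F1, the
exact/early/late/unmatched breakdown with mean signed error, per-cell
replicative-lifespan agreement (least-squares R², error SD), and
Savitzky-Golay-smoothed cell-cycle trajectories. A randomly initialized
detector run through the identical post-processing serves as the diagnostic
untrained baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.signal import savgol_filter

from .core import DivisionTimeline

__all__ = [
    "MatchReport",
    "DetectionScores",
    "LifespanAgreement",
    "match_events",
    "detection_scores",
    "pool_reports",
    "lifespan_agreement",
    "smooth_cycle_trajectory",
    "untrained_baseline",
]

_BIG = 1e9  # cost of a disallowed pairing; any allowed offset is < max_gap << _BIG


@dataclass(frozen=True)
class MatchReport:
    """One-to-one event matching between ground truth and prediction."""

    pairs: tuple[tuple[int, int, int], ...]  # (gt_frame, pred_frame, signed_error)
    unmatched_gt: tuple[int, ...]
    unmatched_pred: tuple[int, ...]
    max_gap: int

    @property
    def n_gt(self) -> int:
        return len(self.pairs) + len(self.unmatched_gt)

    @property
    def n_pred(self) -> int:
        return len(self.pairs) + len(self.unmatched_pred)

    @property
    def total_cost(self) -> int:
        return sum(abs(e) for *_, e in self.pairs)


@dataclass(frozen=True)
class DetectionScores:
    """Tolerance-window detection metrics from a match report.

    ``precision``/``recall``/``f1`` are ``None`` (with the degenerate reason
    recorded in ``flags``) when a denominator is zero — never silent NaN.
    Exact/early/late/within-k/unmatched fractions are denominated by the
    number of predictions by default (unmatched predictions form their own
    class); ``denominator="gt"`` switches to ground-truth denomination.
    """

    tp: int
    fp: int
    fn: int
    tolerance: int
    precision: float | None
    recall: float | None
    f1: float | None
    fraction_exact: float
    fraction_within_1: float
    fraction_within_2: float
    fraction_early: float
    fraction_late: float
    fraction_unmatched: float
    mean_signed_error: float | None
    flags: tuple[str, ...] = ()

    def f1_or_zero(self) -> float:
        return 0.0 if self.f1 is None else self.f1


def match_events(gt: DivisionTimeline, pred: DivisionTimeline,
                 max_gap: int = 5) -> MatchReport:
    """Optimal one-to-one pairing of events by the Hungarian algorithm.

    Minimizes total |pred - gt| over pairs with offset at most ``max_gap``
    (disallowed pairings carry effectively infinite cost, so the number of
    valid pairs is maximized first). Signed error is ``pred - gt``.
    """
    g = np.asarray(gt.event_frames)
    p = np.asarray(pred.event_frames)
    if len(g) == 0 or len(p) == 0:
        return MatchReport(pairs=(), unmatched_gt=tuple(int(x) for x in g),
                           unmatched_pred=tuple(int(x) for x in p), max_gap=max_gap)
    cost = np.abs(g[:, None] - p[None, :]).astype(np.float64)
    cost[cost > max_gap] = _BIG
    rows, cols = linear_sum_assignment(cost)
    n_pairs, total = 0, 0
    for r, c in zip(rows, cols):
        if cost[r, c] < _BIG:
            n_pairs += 1
            total += int(cost[r, c])
    # The Hungarian solver fixes the optimal value but returns an arbitrary
    # member of the optimal set when ties exist; derive a canonical optimal
    # assignment (deterministic and symmetric under swapping gt and pred)
    # and check it achieves the same pair count and total cost.
    pairs = _canonical_matching(g.tolist(), p.tolist(), max_gap)
    assert len(pairs) == n_pairs and sum(abs(e) for *_, e in pairs) == total
    used_g = {a for a, _, _ in pairs}
    used_p = {b for _, b, _ in pairs}
    return MatchReport(
        pairs=pairs,
        unmatched_gt=tuple(int(x) for x in g if int(x) not in used_g),
        unmatched_pred=tuple(int(x) for x in p if int(x) not in used_p),
        max_gap=max_gap,
    )


def _canonical_matching(g: list[int], p: list[int], max_gap: int
                        ) -> tuple[tuple[int, int, int], ...]:
    """Canonical maximum/minimum-cost one-to-one matching of sorted event
    lists.

    For |gt - pred| costs on a line an optimal assignment can always be
    uncrossed without increasing its cost or any single offset, so a
    non-crossing dynamic program attains the global optimum (maximum pairs,
    then minimum total offset). Ties are resolved by a fixed rule — match if
    possible, otherwise leave the *earlier* event unmatched — which is
    invariant under exchanging the two lists, making every derived score
    exactly symmetric.
    """
    n, m = len(g), len(p)
    # value[i][j] = (-pairs, cost) achievable from suffixes g[i:], p[j:]
    value = [[(0, 0)] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            best = min(value[i + 1][j], value[i][j + 1])
            d = abs(g[i] - p[j])
            if d <= max_gap:
                down = value[i + 1][j + 1]
                best = min(best, (down[0] - 1, down[1] + d))
            value[i][j] = best
    pairs = []
    i = j = 0
    while i < n and j < m:
        target = value[i][j]
        d = abs(g[i] - p[j])
        if d <= max_gap and (value[i + 1][j + 1][0] - 1,
                             value[i + 1][j + 1][1] + d) == target:
            pairs.append((g[i], p[j], p[j] - g[i]))
            i += 1
            j += 1
            continue
        skip_g_ok = value[i + 1][j] == target
        skip_p_ok = value[i][j + 1] == target
        if skip_g_ok and (not skip_p_ok or g[i] <= p[j]):
            i += 1
        else:
            j += 1
    return tuple(pairs)


def detection_scores(report: MatchReport, tolerance: int = 1,
                     denominator: str = "pred") -> DetectionScores:
    """Tolerance-window scores: a pair counts as a true positive when its
    absolute signed error is at most ``tolerance`` frames."""
    if denominator not in ("pred", "gt"):
        raise ValueError("denominator must be 'pred' or 'gt'")
    errs = np.asarray([e for *_, e in report.pairs], dtype=int)
    tp = int((np.abs(errs) <= tolerance).sum())
    fp = report.n_pred - tp
    fn = report.n_gt - tp
    flags: list[str] = []

    precision = recall = f1 = None
    if report.n_pred == 0:
        flags.append("no_predictions")
    else:
        precision = tp / report.n_pred
    if report.n_gt == 0:
        flags.append("no_ground_truth")
    else:
        recall = tp / report.n_gt
    if precision is not None and recall is not None:
        if precision + recall > 0:
            f1 = 2 * precision * recall / (precision + recall)
        else:
            f1 = 0.0
            flags.append("zero_precision_and_recall")

    denom = report.n_pred if denominator == "pred" else report.n_gt
    unmatched = len(report.unmatched_pred) if denominator == "pred" else len(report.unmatched_gt)
    if denom == 0:
        flags.append("empty_fraction_denominator")
        fr = dict(exact=0.0, w1=0.0, w2=0.0, early=0.0, late=0.0, unmatched=0.0)
    else:
        fr = dict(
            exact=float((errs == 0).sum()) / denom,
            w1=float((np.abs(errs) <= 1).sum()) / denom,
            w2=float((np.abs(errs) <= 2).sum()) / denom,
            early=float((errs < 0).sum()) / denom,
            late=float((errs > 0).sum()) / denom,
            unmatched=unmatched / denom,
        )
    return DetectionScores(
        tp=tp, fp=fp, fn=fn, tolerance=tolerance,
        precision=precision, recall=recall, f1=f1,
        fraction_exact=fr["exact"], fraction_within_1=fr["w1"],
        fraction_within_2=fr["w2"], fraction_early=fr["early"],
        fraction_late=fr["late"], fraction_unmatched=fr["unmatched"],
        mean_signed_error=float(errs.mean()) if errs.size else None,
        flags=tuple(flags),
    )


def pool_reports(reports: list[MatchReport]) -> MatchReport:
    """Pool per-cell match reports into one dataset-level report."""
    max_gap = reports[0].max_gap if reports else 0
    pairs, ug, up = [], [], []
    for r in reports:
        pairs += list(r.pairs)
        ug += list(r.unmatched_gt)
        up += list(r.unmatched_pred)
    return MatchReport(pairs=tuple(pairs), unmatched_gt=tuple(ug),
                       unmatched_pred=tuple(up), max_gap=max_gap)


@dataclass(frozen=True)
class LifespanAgreement:
    records: tuple[tuple[int, int], ...]  # (gt_rls, pred_rls) per cell
    r_squared: float
    identity_r_squared: float
    error_sd: float
    slope: float
    intercept: float


def lifespan_agreement(records) -> LifespanAgreement:
    """Per-cell RLS agreement: OLS fit of predicted on ground-truth lifespan.

    ``r_squared`` is the coefficient of determination of the least-squares
    fit with intercept (in [0, 1]); ``identity_r_squared`` scores the y = x
    line instead (can be negative); ``error_sd`` is the sample SD of
    (pred - gt) in divisions.
    """
    records = [(int(g), int(p)) for g, p in records]
    if len(records) < 3:
        raise ValueError("need at least 3 cells for lifespan agreement")
    g = np.asarray([r[0] for r in records], dtype=float)
    p = np.asarray([r[1] for r in records], dtype=float)
    if np.ptp(g) == 0:
        raise ValueError("ground-truth lifespans are constant (zero variance)")
    slope, intercept = np.polyfit(g, p, 1)
    fitted = slope * g + intercept
    ss_tot = float(((p - p.mean()) ** 2).sum())
    ss_res = float(((p - fitted) ** 2).sum())
    # constant predictions: R^2 is 0/0; score 1 only for an exact fit
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    id_r2 = 1.0 - float(((p - g) ** 2).sum()) / float(((g - g.mean()) ** 2).sum())
    err = p - g
    sd = float(err.std(ddof=1)) if len(err) > 1 else 0.0
    return LifespanAgreement(records=tuple(records), r_squared=r2,
                             identity_r_squared=id_r2, error_sd=sd,
                             slope=float(slope), intercept=float(intercept))


def smooth_cycle_trajectory(points, window: int = 11, polyorder: int = 2,
                            bin_width: float | None = 2.0
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Savitzky-Golay smoothing of a cycle-length-vs-lifespan-fraction cloud.

    ``points``: iterable of (pct_lifespan, gap) pairs. With ``bin_width``
    (percent), points are first averaged in bins along the %-lifespan axis;
    ``bin_width=None`` smooths the x-sorted raw series directly. Returns
    (x, smoothed) of equal length (same-length filtering).
    """
    pts = np.asarray(list(points), dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (pct_lifespan, gap) pairs")
    if bin_width is not None:
        edges = np.arange(0.0, 100.0 + bin_width, bin_width)
        which = np.clip(np.digitize(pts[:, 0], edges) - 1, 0, len(edges) - 2)
        xs, ys = [], []
        for b in range(len(edges) - 1):
            sel = which == b
            if sel.any():
                xs.append(0.5 * (edges[b] + edges[b + 1]))
                ys.append(pts[sel, 1].mean())
        x, y = np.asarray(xs), np.asarray(ys)
    else:
        order = np.argsort(pts[:, 0], kind="stable")
        x, y = pts[order, 0], pts[order, 1]
    if len(y) < window:
        raise ValueError(f"need at least {window} points after binning, got {len(y)}")
    return x, savgol_filter(y, window_length=window, polyorder=polyorder, mode="interp")


def untrained_baseline(mae_cfg, det_cfg, movies: dict[str, np.ndarray],
                       seed: int = 0) -> dict[str, "FrameProbabilities"]:
    """Frame probabilities from a randomly initialized detector (fixed seed),
    run through the identical inference path — the diagnostic control against
    which the trained model's F1 gap is measured."""
    from .detector import Detector, predict_timeline

    detector = Detector(mae_cfg, det_cfg, seed=seed)
    return {c: predict_timeline(detector, m, cell_id=c) for c, m in movies.items()}
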