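"""Bootstrap PLS-DA engine and the VIP / selectivity-ratio variable selection.

Each bootstrap replicate resamples the balanced model set with replacement,
stratified within each diagnostic group, refits the autoscaling on the
resample, re-selects the model complexity by leave-one-out cross-validation
(capped at ``A_max``), fits the model and records the AUC of the replicate
on its out-of-bag model-set samples together with the replicate's VIP and/or
SR profiles.  Averaging over the replicates gives the model-set AUC, its
standard error ``sqrt(sum (theta_i - mean)^2 / (B - 1))``, and the average
per-variable scores that drive the two selection procedures:

* VIP-PLS-DA: variables with average VIP below the cut-off (0.8) are
  dropped and the whole bootstrap is repeated, three rounds by default.
* SR-PLS-DA: a single bootstrap pass; variables with average SR below a
  cut-off — chosen by the discriminating-variable (DIVA) test relating SR
  intervals to the mean correct classification rate (MCCR) of univariate
  classifiers — are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .evaluate import auc
from .plsda import (
    fit_plsda,
    select_complexity_loo,
    selectivity_ratio,
    target_projection,
    vip_scores,
)
from .table import MetaboliteTable

__all__ = [
    "BootstrapRun",
    "SelectionResult",
    "MCCRCurve",
    "bootstrap_plsda",
    "auc_se",
    "vip_selection_rounds",
    "sr_selection",
    "diva_mccr",
]

logger = logging.getLogger(__name__)


def auc_se(aucs) -> float:
    """Bootstrap standard error of the AUC: sqrt(sum (x_i - mean)^2 / (b-1))."""
    a = np.asarray(aucs, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 bootstrap AUC values")
    return float(np.sqrt(np.sum((a - a.mean()) ** 2) / (a.size - 1)))


@dataclass
class BootstrapRun:
    """Aggregated result of one bootstrap pass over the model set."""

    B: int
    seed: int
    variable_names: list[str]
    aucs: np.ndarray
    complexities: np.ndarray
    vip: np.ndarray | None = None
    sr: np.ndarray | None = None
    oob: bool = True
    in_bag_counts: np.ndarray | None = None  # replicates x groups, class order

    @property
    def mean_auc(self) -> float:
        return float(self.aucs.mean())

    @property
    def se(self) -> float:
        return auc_se(self.aucs)

    @property
    def avg_vip(self) -> np.ndarray:
        if self.vip is None:
            raise ValueError("VIP profiles were not collected")
        return self.vip.mean(axis=0)

    @property
    def avg_sr(self) -> np.ndarray:
        if self.sr is None:
            raise ValueError("SR profiles were not collected")
        return self.sr.mean(axis=0)  # +inf in any replicate propagates to +inf

    def theta_histogram(self, bins: int = 20):
        """Histogram of the per-replicate AUC values (counts, bin edges)."""
        return np.histogram(self.aucs, bins=bins, range=(0.0, 1.0))

    def to_json(self, path) -> None:
        """Aggregate summary (not the per-replicate profile matrices)."""
        import json
        from pathlib import Path

        Path(path).write_text(
            json.dumps(
                {
                    "B": self.B,
                    "seed": self.seed,
                    "oob": self.oob,
                    "mean_auc": self.mean_auc,
                    "se": self.se,
                    "aucs": self.aucs.tolist(),
                    "complexities": self.complexities.tolist(),
                    "variable_names": self.variable_names,
                    "avg_vip": None if self.vip is None else self.avg_vip.tolist(),
                    "avg_sr": None if self.sr is None else [
                        None if not np.isfinite(v) else float(v)
                        for v in self.avg_sr
                    ],
                },
                indent=1,
            )
        )

    def theta_histogram_csv(self, path, bins: int = 20) -> None:
        counts, edges = self.theta_histogram(bins)
        with open(path, "w") as fh:
            fh.write("bin_low,bin_high,count\n")
            for lo, hi, c in zip(edges[:-1], edges[1:], counts):
                fh.write(f"{lo:.6f},{hi:.6f},{int(c)}\n")


def _encode_labels(table: MetaboliteTable, positive_class: str | None = None):
    """+1/-1 coding; the positive class defaults to the larger group."""
    classes = table.classes
    sizes = {g: table.group_indices(g).size for g in classes}
    if positive_class is None:
        positive_class = max(classes, key=lambda g: (sizes[g], g))
    if positive_class not in classes:
        raise ValueError(f"positive class {positive_class!r} not among {classes}")
    negative_class = next(g for g in classes if g != positive_class)
    coding = {positive_class: 1, negative_class: -1}
    y = np.where(table.group_labels == positive_class, 1.0, -1.0)
    return y, coding


def bootstrap_plsda(
    model_table: MetaboliteTable,
    A_max: int = 5,
    B: int = 1000,
    seed: int = 0,
    collect: str = "both",
    oob: bool = True,
    refit_scaling: bool = True,
    positive_class: str | None = None,
) -> BootstrapRun:
    """Stratified bootstrap of PLS-DA over the balanced model set.

    ``collect`` is ``"vip"``, ``"sr"``, ``"both"`` or ``"none"``.  Per
    replicate the AUC is evaluated on the out-of-bag model-set samples by
    default (``oob=False`` scores the in-bag resample instead, the optimistic
    variant).  A replicate whose out-of-bag set misses a group is redrawn.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if collect not in ("vip", "sr", "both", "none"):
        raise ValueError("collect must be vip|sr|both|none")
    y, coding = _encode_labels(model_table, positive_class)
    X = model_table.values
    p = model_table.n_variables
    group_idx = [model_table.group_indices(g) for g in model_table.classes]

    rng = np.random.default_rng(seed)
    aucs = np.empty(B)
    complexities = np.empty(B, dtype=int)
    in_bag_counts = np.empty((B, len(group_idx)), dtype=int)
    vip_mat = np.empty((B, p)) if collect in ("vip", "both") else None
    sr_mat = np.empty((B, p)) if collect in ("sr", "both") else None

    fixed_scale = None
    if not refit_scaling:
        from .preprocess import fit_scaling

        fixed_scale = fit_scaling(X, model_table.variable_names, on_zero_variance="unit")

    for b in range(B):
        while True:
            in_bag = np.concatenate(
                [rng.choice(g, size=g.size, replace=True) for g in group_idx]
            )
            oob_mask = np.ones(model_table.n_samples, dtype=bool)
            oob_mask[in_bag] = False
            if not oob:
                break
            if all(oob_mask[g].any() for g in group_idx):
                break
            logger.info("replicate %d: empty out-of-bag group, redrawn", b)

        for gi, g in enumerate(group_idx):
            in_bag_counts[b, gi] = np.isin(in_bag, g).sum()
        Xb, yb = X[in_bag], y[in_bag]
        if fixed_scale is None:
            m = Xb.mean(axis=0)
            s = Xb.std(axis=0, ddof=1)
            s[s <= 0] = 1.0  # a constant resampled column carries no signal
        else:
            m, s = fixed_scale.mean, fixed_scale.sd
        Xbs = (Xb - m) / s

        A = select_complexity_loo(Xb if fixed_scale is None else Xbs, yb, A_max,
                                  refit_scaling=fixed_scale is None)
        model = fit_plsda(Xbs, yb, A)
        complexities[b] = A

        if oob:
            scores = ((X[oob_mask] - m) / s) @ model.b
            aucs[b] = auc(scores, y[oob_mask])
        else:
            aucs[b] = auc(Xbs @ model.b, yb)

        if vip_mat is not None:
            vip_mat[b] = vip_scores(model)
        if sr_mat is not None:
            sr_mat[b] = selectivity_ratio(target_projection(model, Xbs))

    return BootstrapRun(
        B=B,
        seed=seed,
        variable_names=list(model_table.variable_names),
        aucs=aucs,
        complexities=complexities,
        vip=vip_mat,
        sr=sr_mat,
        oob=oob,
        in_bag_counts=in_bag_counts,
    )


@dataclass
class SelectionResult:
    """Outcome of a variable-selection procedure."""

    criterion: str
    cutoff: float
    rounds_applied: int
    retained: list[str]  # ordered by decreasing average score
    audit: list[dict] = field(default_factory=list)
    final_run: BootstrapRun | None = None

    def __post_init__(self) -> None:
        if self.rounds_applied < 1:
            raise ValueError("at least one round must have been applied")

    def to_json(self, path) -> None:
        import json
        from pathlib import Path

        Path(path).write_text(
            json.dumps(
                {
                    "criterion": self.criterion,
                    "cutoff": self.cutoff,
                    "rounds_applied": self.rounds_applied,
                    "retained": self.retained,
                    "audit": self.audit,
                },
                indent=1,
            )
        )


def _order_by_score(names, scores) -> list[str]:
    order = np.argsort(-np.nan_to_num(scores, posinf=np.finfo(float).max))
    return [names[i] for i in order]


def vip_selection_rounds(
    model_table: MetaboliteTable,
    cutoff: float = 0.8,
    rounds: int = 3,
    B: int = 1000,
    seed: int = 0,
    A_max: int = 5,
    positive_class: str | None = None,
) -> SelectionResult:
    """Iterative bootstrap VIP-PLS-DA selection.

    Each round bootstraps the currently retained variables and removes those
    with average VIP below ``cutoff``; the procedure stops early when nothing
    is dropped or fewer than 2 variables remain.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative (0.8 is the workflow default)")
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    rng = np.random.default_rng(seed)
    round_seeds = rng.integers(0, 2**31 - 1, size=rounds)
    current = model_table
    audit: list[dict] = []
    run: BootstrapRun | None = None
    applied = 0
    for r in range(rounds):
        run = bootstrap_plsda(
            current, A_max=A_max, B=B, seed=int(round_seeds[r]),
            collect="vip", positive_class=positive_class,
        )
        applied += 1
        avg = run.avg_vip
        keep = avg >= cutoff
        dropped = [v for v, k in zip(current.variable_names, keep) if not k]
        audit.append(
            {
                "round": r + 1,
                "mean_auc": run.mean_auc,
                "se": run.se,
                "dropped": dropped,
                "n_retained": int(keep.sum()),
            }
        )
        logger.info("VIP round %d: dropped %d of %d variables",
                    r + 1, len(dropped), current.n_variables)
        if not keep.any():
            raise ValueError(
                f"VIP cutoff {cutoff} removed every variable; lower the cutoff"
            )
        if not dropped:
            break
        retained_names = _order_by_score(
            [v for v, k in zip(current.variable_names, keep) if k],
            avg[keep],
        )
        current = current.select_variables(sorted(retained_names,
                                                  key=current.variable_names.index))
        if current.n_variables < 2:
            break
    avg = run.avg_vip
    keep = avg >= cutoff
    names = [v for v, k in zip(run.variable_names, keep) if k]
    return SelectionResult(
        criterion="VIP",
        cutoff=cutoff,
        rounds_applied=applied,
        retained=_order_by_score(names, avg[keep]),
        audit=audit,
        final_run=run,
    )


def sr_selection(
    model_table: MetaboliteTable,
    cutoff: float | None = None,
    B: int = 1000,
    seed: int = 0,
    A_max: int = 5,
    positive_class: str | None = None,
    diva_intervals: int = 10,
    diva_reps: int = 100,
    mccr_threshold: float = 60.0,
) -> tuple[SelectionResult, "MCCRCurve | None"]:
    """Single-pass bootstrap SR-PLS-DA selection.

    With ``cutoff=None`` the cut-off is taken from the DIVA/MCCR curve
    computed on the bootstrap's average SRs.  Variables with infinite average
    SR are always retained.  Returns the selection and the MCCR curve (None
    when an explicit cutoff was given).
    """
    run = bootstrap_plsda(
        model_table, A_max=A_max, B=B, seed=seed, collect="sr",
        positive_class=positive_class,
    )
    curve = None
    if cutoff is None:
        curve = diva_mccr(
            run, model_table, intervals=diva_intervals, reps=diva_reps,
            seed=seed, mccr_threshold=mccr_threshold,
        )
        cutoff = curve.cutoff
    if cutoff < 0:
        raise ValueError("SR cutoff must be non-negative")
    avg = run.avg_sr
    keep = (avg >= cutoff) | np.isinf(avg)
    if not keep.any():
        raise ValueError(f"SR cutoff {cutoff} removed every variable; lower it")
    names = [v for v, k in zip(run.variable_names, keep) if k]
    result = SelectionResult(
        criterion="SR",
        cutoff=float(cutoff),
        rounds_applied=1,
        retained=_order_by_score(names, avg[keep]),
        audit=[{
            "round": 1,
            "mean_auc": run.mean_auc,
            "se": run.se,
            "dropped": [v for v, k in zip(run.variable_names, keep) if not k],
            "n_retained": int(keep.sum()),
        }],
        final_run=run,
    )
    return result, curve


# ---------------------------------------------------------------------------
# DIVA / MCCR
# ---------------------------------------------------------------------------

@dataclass
class MCCRCurve:
    """MCCR per SR interval and the derived cut-off."""

    edges: list[tuple[float, float]]  # (lower, upper) SR edge per interval
    mccr: list[float]  # percent, aligned with edges, increasing SR order
    cutoff: float
    threshold: float

    def __post_init__(self) -> None:
        if any(not 0.0 <= m <= 100.0 for m in self.mccr):
            raise ValueError("MCCR values must lie in [0, 100]")


def _univariate_mccr(x: np.ndarray, y: np.ndarray, rng, reps: int) -> float:
    """Mean held-out accuracy of an optimal-threshold single-variable rule.

    For each of ``reps`` stratified half/half splits the threshold and
    direction maximizing training accuracy are found by scanning the sorted
    training values; accuracy is then measured on the held-out half.
    """
    pos = np.flatnonzero(y > 0)
    neg = np.flatnonzero(y < 0)
    acc = 0.0
    for _ in range(reps):
        tr = np.concatenate([
            rng.permutation(pos)[: pos.size // 2],
            rng.permutation(neg)[: neg.size // 2],
        ])
        te_mask = np.ones(y.size, dtype=bool)
        te_mask[tr] = False
        xt, yt = x[tr], y[tr]
        order = np.argsort(xt, kind="stable")
        ys = yt[order]
        xs = xt[order]
        npos = float((ys > 0).sum())
        # pos_left[i] = positives among the i smallest training values
        pos_left = np.concatenate([[0.0], np.cumsum(ys > 0)])
        neg_left = np.concatenate([[0.0], np.cumsum(ys < 0)])
        # rule "predict + if x > cut", cut after position i
        correct_hi = (npos - pos_left) + neg_left
        # rule "predict + if x <= cut"
        correct_lo = pos_left + (neg_left[-1] - neg_left)
        best = np.argmax(np.maximum(correct_hi, correct_lo))
        hi_rule = correct_hi[best] >= correct_lo[best]
        if best == 0:
            cut = xs[0] - 1.0
        elif best == xs.size:
            cut = xs[-1] + 1.0
        else:
            cut = 0.5 * (xs[best - 1] + xs[best])
        pred = np.where(x[te_mask] > cut, 1.0, -1.0)
        if not hi_rule:
            pred = -pred
        acc += float((pred == y[te_mask]).mean())
    return 100.0 * acc / reps


def diva_mccr(
    run: BootstrapRun,
    model_table: MetaboliteTable,
    intervals: int = 10,
    reps: int = 100,
    seed: int = 0,
    mccr_threshold: float = 60.0,
    positive_class: str | None = None,
) -> MCCRCurve:
    """Discriminating-variable test: MCCR across SR intervals, and a cut-off.

    Variables are sorted by average SR and partitioned into ``intervals``
    near-equal-count groups (reduced when there are fewer variables).  The
    MCCR of an interval is the mean correct classification rate of
    single-variable optimal-threshold classifiers over ``reps`` seeded
    stratified half/half resampled evaluations.  The cut-off is the lower SR
    edge of the first interval (in increasing SR order) whose MCCR exceeds
    ``mccr_threshold``; if none does, the best interval's lower edge is used.
    """
    avg_sr = run.avg_sr
    names = run.variable_names
    if model_table.variable_names != names:
        raise ValueError("bootstrap run and model table disagree on variables")
    n_vars = len(names)
    if n_vars < intervals:
        logger.info("DIVA: reducing intervals from %d to %d", intervals, n_vars)
        intervals = max(1, n_vars)
    order = np.argsort(np.nan_to_num(avg_sr, posinf=np.finfo(float).max),
                       kind="stable")
    groups = np.array_split(order, intervals)

    y, _ = _encode_labels(model_table, positive_class)
    rng = np.random.default_rng(seed)
    edges: list[tuple[float, float]] = []
    mccr: list[float] = []
    for g in groups:
        srs = avg_sr[g]
        finite = srs[np.isfinite(srs)]
        lo = float(srs.min()) if finite.size == srs.size else float(finite.min()) if finite.size else float("inf")
        hi = float(srs.max())
        rates = [
            _univariate_mccr(model_table.values[:, j], y, rng, reps) for j in g
        ]
        edges.append((lo, hi))
        mccr.append(float(np.mean(rates)))

    cutoff = None
    for (lo, _hi), m in zip(edges, mccr):
        if m > mccr_threshold:
            cutoff = lo
            break
    if cutoff is None:
        best = int(np.argmax(mccr))
        cutoff = edges[best][0]
        logger.info("DIVA: no interval exceeded MCCR %.1f%%; using best interval",
                    mccr_threshold)
    if not np.isfinite(cutoff):
        cutoff = float(np.nanmax(np.where(np.isfinite(avg_sr), avg_sr, np.nan)))
    return MCCRCurve(edges=edges, mccr=mccr, cutoff=float(cutoff),
                     threshold=mccr_threshold)
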