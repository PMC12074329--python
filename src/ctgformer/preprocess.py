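"""Signal conditioning, quality filtering, windowing and cohort balancing.

The preparation pipeline mirrors standard antepartum CTG practice: clip the
fetal heart rate to the physiological band [50, 250] bpm and uterine tone
to [0, 100]; rescale both channels to the unit interval; drop traces that
miss more than 30% of their samples; cut traces into fixed one-hour
(960-step) windows anchored at the delivery-proximal end; balance cases
against controls with one-to-one propensity-score matching audited by
standardised mean differences (SMD < 0.10); and split 80-20 for training
and evaluation, stratified by outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .containers import MISSING, WINDOW_LEN, CTGTrace, CTGWindow, ScaledTrace
from .exceptions import ParameterError, SplitError, ValidationError
from .simulate import FHR_HI, FHR_LO, TOCO_HI, TOCO_LO

__all__ = [
    "clean_channels",
    "scale_unit",
    "quality_filter",
    "windowize",
    "compute_smd",
    "propensity_match",
    "split_cohort",
    "select_by_days_to_delivery",
    "MatchResult",
    "MAX_MISSING_FRACTION",
    "MIN_OBSERVED_PADDED",
    "SMD_BALANCE_THRESHOLD",
]

#: Traces missing more than this fraction of samples (both channels pooled)
#: are excluded.
MAX_MISSING_FRACTION = 0.30

#: A leading partial window is kept (padded) only with at least this many
#: observed steps — half a window, so near-empty remainders are dropped.
MIN_OBSERVED_PADDED = WINDOW_LEN // 2

#: Post-matching covariate balance is declared when every SMD falls below
#: this conventional threshold.
SMD_BALANCE_THRESHOLD = 0.10


# --------------------------------------------------------------- signal side
def clean_channels(trace: CTGTrace, out_of_range: str = "clip") -> CTGTrace:
    """Adjust channels into their physiological ranges.

    Non-missing FHR is clipped into [50, 250] bpm and TOCO into [0, 100];
    the missing sentinel ``-1`` passes through untouched.  With
    ``out_of_range="missing"`` out-of-range samples are marked missing
    instead of clipped.
    """
    if len(trace) == 0:
        raise ValidationError("empty trace")
    if out_of_range not in ("clip", "missing"):
        raise ParameterError("out_of_range must be 'clip' or 'missing'")
    fhr, toco = trace.fhr.copy(), trace.toco.copy()
    fhr_obs = fhr != MISSING
    toco_obs = toco != MISSING
    if out_of_range == "clip":
        fhr[fhr_obs] = np.clip(fhr[fhr_obs], FHR_LO, FHR_HI)
        toco[toco_obs] = np.clip(toco[toco_obs], TOCO_LO, TOCO_HI)
    else:
        fhr[fhr_obs & ((fhr < FHR_LO) | (fhr > FHR_HI))] = MISSING
        toco[toco_obs & ((toco < TOCO_LO) | (toco > TOCO_HI))] = MISSING
    return replace(trace, fhr=fhr, toco=toco)


def scale_unit(trace: CTGTrace) -> ScaledTrace:
    """Map cleaned channels onto [0, 1] and extract the validity mask.

    FHR maps by (x - 50) / 200 and TOCO by x / 100.  Missing samples become
    mask-false with fill value 0.0; the raw sentinel does not survive past
    this point.  Raises if any observed sample is still out of range
    (i.e., :func:`clean_channels` was skipped).
    """
    mask = ~trace.missing_mask
    fhr, toco = trace.fhr, trace.toco
    if np.any((fhr[mask[0]] < FHR_LO) | (fhr[mask[0]] > FHR_HI)):
        raise ValidationError("FHR out of [50, 250]; run clean_channels first")
    if np.any((toco[mask[1]] < TOCO_LO) | (toco[mask[1]] > TOCO_HI)):
        raise ValidationError("TOCO out of [0, 100]; run clean_channels first")
    values = np.zeros((2, len(trace)))
    values[0, mask[0]] = (fhr[mask[0]] - FHR_LO) / (FHR_HI - FHR_LO)
    values[1, mask[1]] = toco[mask[1]] / TOCO_HI
    return ScaledTrace(
        trace_id=trace.trace_id, values=values, valid_mask=mask,
        label=trace.label, days_to_delivery=trace.days_to_delivery,
    )


def quality_filter(trace: CTGTrace, max_missing: float = MAX_MISSING_FRACTION) -> bool:
    """True iff the trace passes the missingness filter.

    The fraction is pooled over both channels; exclusion is strict
    ("more than 30%"), so exactly 30% missing still passes.
    """
    return trace.missing_fraction() <= max_missing


def windowize(scaled: ScaledTrace) -> list[CTGWindow]:
    """Cut a unit-scaled trace into fixed 960-step windows.

    Full windows are taken from the END of the trace backwards, so window
    index 0 is the delivery-proximal hour.  A leading remainder shorter
    than 960 steps is kept as a single left-padded window (padding is
    mask-false) iff it has at least 480 observed steps, else dropped.
    """
    values, mask = scaled.values, scaled.valid_mask
    T = values.shape[1]
    windows: list[CTGWindow] = []
    n_full = T // WINDOW_LEN
    for k in range(n_full):
        stop = T - k * WINDOW_LEN
        sl = slice(stop - WINDOW_LEN, stop)
        windows.append(
            CTGWindow(values[:, sl], mask[:, sl], scaled.trace_id, k,
                      scaled.label, scaled.days_to_delivery)
        )
    remainder = T - n_full * WINDOW_LEN
    if remainder > 0:
        vals_r = values[:, :remainder]
        mask_r = mask[:, :remainder]
        observed_steps = int(mask_r.any(axis=0).sum())
        if observed_steps >= MIN_OBSERVED_PADDED:
            pad = WINDOW_LEN - remainder
            vals_p = np.pad(vals_r, ((0, 0), (pad, 0)))
            mask_p = np.pad(mask_r, ((0, 0), (pad, 0)))
            windows.append(
                CTGWindow(vals_p, mask_p, scaled.trace_id, n_full,
                          scaled.label, scaled.days_to_delivery)
            )
    return windows


# --------------------------------------------------------------- cohort side
@dataclass
class MatchResult:
    """Outcome of one-to-one propensity matching with its balance audit."""

    pairs: list[tuple[str, str]]
    smd_before: dict[str, float]
    smd_after: dict[str, float]
    balanced: bool = False
    warning: str | None = None
    propensity: pd.Series | None = field(default=None, repr=False)

    @property
    def matched_ids(self) -> list[str]:
        return [i for pair in self.pairs for i in pair]


def compute_smd(table: pd.DataFrame, covariate: str, group: str = "label") -> float:
    """Standardised mean difference between the two label groups.

    ``|mu1 - mu0| / sqrt((s1^2 + s0^2) / 2)`` with unbiased sample
    variances — the usual two-group balance diagnostic.
    """
    g1 = table.loc[table[group] == 1, covariate].to_numpy(dtype=float)
    g0 = table.loc[table[group] == 0, covariate].to_numpy(dtype=float)
    if len(g1) == 0 or len(g0) == 0:
        raise ValidationError("both groups must be non-empty")
    v1 = g1.var(ddof=1) if len(g1) > 1 else 0.0
    v0 = g0.var(ddof=1) if len(g0) > 1 else 0.0
    pooled = np.sqrt((v1 + v0) / 2.0)
    diff = abs(g1.mean() - g0.mean())
    if pooled == 0.0:
        if diff == 0.0:
            return 0.0
        raise ValidationError(f"zero pooled variance for covariate {covariate!r}")
    return float(diff / pooled)


def propensity_match(
    table: pd.DataFrame,
    covariates: list[str],
    caliper: float | None = None,
    seed: int = 0,
    id_col: str = "trace_id",
    group: str = "label",
) -> MatchResult:
    """Greedy 1:1 nearest-neighbour matching on the propensity logit.

    A logistic regression of the label on the covariates supplies the
    propensity score; cases are processed in descending propensity and each
    takes the unused control with the closest logit (optionally within
    ``caliper`` logit units).  SMDs for every covariate are reported before
    and after matching and a balance flag is set iff all post-match SMDs
    fall below 0.10.
    """
    cases = table[table[group] == 1]
    controls = table[table[group] == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise ValidationError("need at least one case and one control")

    X = StandardScaler().fit_transform(table[covariates].to_numpy(dtype=float))
    y = table[group].to_numpy(dtype=int)
    lr = LogisticRegression(max_iter=1000, random_state=seed)
    lr.fit(X, y)
    logit = pd.Series(X @ lr.coef_.ravel() + lr.intercept_[0], index=table[id_col])

    case_ids = cases[id_col].tolist()
    control_ids = controls[id_col].tolist()
    order = sorted(case_ids, key=lambda i: -logit[i])
    available = dict.fromkeys(control_ids)  # insertion-ordered set
    pairs: list[tuple[str, str]] = []
    for cid in order:
        if not available:
            break
        best, best_d = None, np.inf
        for ctrl in available:
            d = abs(logit[cid] - logit[ctrl])
            if d < best_d:
                best, best_d = ctrl, d
        if caliper is not None and best_d > caliper:
            continue
        pairs.append((cid, best))
        del available[best]

    def smd_or_nan(tbl, c):
        try:
            return compute_smd(tbl, c, group)
        except ValidationError:  # degenerate group variance (tiny cohorts)
            return float("nan")

    smd_before = {c: smd_or_nan(table, c) for c in covariates}
    matched = set(i for pair in pairs for i in pair)
    after_tbl = table[table[id_col].isin(matched)]
    smd_after = {c: smd_or_nan(after_tbl, c) for c in covariates}
    warning = None
    if len(pairs) < len(case_ids):
        warning = f"partial matching: {len(pairs)} of {len(case_ids)} cases matched"
    balanced = all(
        v < SMD_BALANCE_THRESHOLD for v in smd_after.values() if not np.isnan(v)
    )
    expit = 1.0 / (1.0 + np.exp(-logit))
    return MatchResult(pairs, smd_before, smd_after, balanced, warning, expit)


def split_cohort(
    ids: list, train_fraction: float = 0.8, seed: int = 0, stratify_by=None
) -> tuple[list, list]:
    """Deterministic stratified train/eval split.

    The train set has exactly ``floor(train_fraction * N)`` members: each
    stratum contributes its floor share and the strata with the largest
    fractional remainders absorb the residual ids.
    """
    ids = list(ids)
    n = len(ids)
    if n < 2:
        raise SplitError("need at least two ids to split")
    if len(set(ids)) != n:
        raise SplitError("ids must be unique")
    if not (0.0 < train_fraction < 1.0):
        raise ParameterError("train_fraction must be in (0, 1)")
    n_train_total = int(np.floor(train_fraction * n))
    rng = np.random.default_rng(seed)

    if stratify_by is None:
        strata = {None: ids}
    else:
        strata: dict = {}
        for i, s in zip(ids, stratify_by):
            strata.setdefault(s, []).append(i)

    quotas = {}
    remainders = {}
    for s, members in strata.items():
        exact = train_fraction * len(members)
        quotas[s] = int(np.floor(exact))
        remainders[s] = exact - quotas[s]
    # hand leftover slots to the largest remainders (stable order on ties)
    short = n_train_total - sum(quotas.values())
    for s in sorted(strata, key=lambda s: (-remainders[s], str(s)))[:short]:
        quotas[s] += 1

    train: list = []
    evaluation: list = []
    for s, members in strata.items():
        members = list(members)
        rng.shuffle(members)
        train.extend(members[: quotas[s]])
        evaluation.extend(members[quotas[s] :])
    return train, evaluation


def select_by_days_to_delivery(
    table: pd.DataFrame, max_days, keep_controls: bool = True, group: str = "label"
) -> pd.DataFrame:
    """Filter the adverse class by proximity to delivery.

    ``max_days`` may be an integer upper bound (inclusive) or a
    ``(lo, hi)`` inclusive range.  Controls are kept untouched by default;
    with ``keep_controls=False`` the same bound applies to them too.
    """
    if np.isscalar(max_days):
        lo, hi = 0, int(max_days)
    else:
        lo, hi = int(max_days[0]), int(max_days[1])
    in_range = table["days_to_delivery"].between(lo, hi)
    keep = in_range | ((table[group] == 0) if keep_controls else False)
    out = table[keep].copy()
    if len(out) == 0:
        out.attrs["warning"] = "empty subset after days-to-delivery filter"
    return out
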