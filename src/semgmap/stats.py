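"""Factorial bias statistics on the map-feature table.

The design crosses six window lengths with five overlaps; the replicates
inside each cell are individual maps, so cell sizes are unbalanced by
construction (high overlap yields many more maps). The layer provides:

* fixed-effects two-way ANOVA with interaction, sequential sums of
  squares (so the decomposition SS_window + SS_overlap + SS_interaction +
  SS_residual = SS_total holds exactly), and eta-squared effect sizes
  SS_effect / SS_total classified as small (< 0.04), medium (0.04-0.64)
  or large (> 0.64);
* Tukey-Kramer all-pairs comparisons of factor-level means using the
  studentized-range distribution with the unequal-n correction;
* PAM (partitioning around medoids) clustering with the number of
  clusters chosen by the elbow of the within-distance curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import studentized_range
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .exceptions import ValidationError


@dataclass(frozen=True)
class AnovaEffect:
    ss: float
    df: int
    F: float
    p: float
    eta_sq: float


@dataclass(frozen=True)
class AnovaResult:
    effects: dict  # name -> AnovaEffect for factor_a, factor_b, interaction, residual
    ss_total: float
    factor_a: str
    factor_b: str

    def eta_class(self, effect: str) -> str:
        return classify_eta(self.effects[effect].eta_sq)


def two_way_anova(
    rows: pd.DataFrame,
    response: str,
    factor_a: str = "window_ms",
    factor_b: str = "overlap_pct",
) -> AnovaResult:
    """Fixed-effects two-factor ANOVA with interaction (sequential SS).

    Raises when either factor has fewer than two levels, when any design
    cell is empty, or when the interaction term has no replication.
    """
    df = rows[[response, factor_a, factor_b]].dropna().copy()
    for fac in (factor_a, factor_b):
        if df[fac].nunique() < 2:
            raise ValidationError(f"factor {fac!r} needs at least 2 levels")
    cells = df.groupby([factor_a, factor_b], sort=True).size()
    full = (
        df[factor_a].nunique() * df[factor_b].nunique()
    )
    if len(cells) < full:
        have = set(cells.index)
        py = lambda v: v.item() if hasattr(v, "item") else v
        missing = [
            (py(a), py(b))
            for a in sorted(df[factor_a].unique())
            for b in sorted(df[factor_b].unique())
            if (a, b) not in have
        ]
        raise ValidationError(f"empty design cell(s): {missing}")
    if (cells < 2).any():
        thin = list(cells[cells < 2].index)
        raise ValidationError(
            f"interaction needs >= 2 replicates per cell; single-map cells: {thin}"
        )
    work = df.rename(columns={response: "_y", factor_a: "_a", factor_b: "_b"})
    model = smf.ols("_y ~ C(_a) + C(_b) + C(_a):C(_b)", data=work).fit()
    table = sm.stats.anova_lm(model, typ=1)
    ss_total = float(table["sum_sq"].sum())
    # a flat response leaves only rounding residue in every SS term
    scale = float((work["_y"] ** 2).sum())
    if ss_total <= 1e-20 * max(scale, 1.0):
        ss_total = 0.0
    name_map = {
        "C(_a)": factor_a,
        "C(_b)": factor_b,
        "C(_a):C(_b)": "interaction",
        "Residual": "residual",
    }
    effects: dict[str, AnovaEffect] = {}
    for raw, name in name_map.items():
        row = table.loc[raw]
        ss = float(row["sum_sq"])
        eta = ss / ss_total if ss_total > 0 else 0.0
        f_val = float(row["F"]) if np.isfinite(row["F"]) else float("nan")
        p_val = float(row["PR(>F)"]) if np.isfinite(row["PR(>F)"]) else float("nan")
        if ss_total == 0:
            f_val, p_val = 0.0, float("nan")
        effects[name] = AnovaEffect(
            ss=ss, df=int(row["df"]), F=f_val, p=p_val, eta_sq=eta
        )
    return AnovaResult(
        effects=effects, ss_total=ss_total, factor_a=factor_a, factor_b=factor_b
    )


def classify_eta(eta_sq: float) -> str:
    """Effect-size class: small < 0.04, medium 0.04-0.64, large > 0.64."""
    if not 0.0 <= eta_sq <= 1.0:
        raise ValidationError("eta squared must lie in [0, 1]")
    if eta_sq < 0.04:
        return "small"
    if eta_sq <= 0.64:
        return "medium"
    return "large"


def tukey_kramer(
    values: np.ndarray,
    groups: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All-pairs comparison of group means (studentized range, Kramer SE).

    The standard error of each pair uses the pooled within-group mean
    square with Kramer's correction for unequal group sizes:
    ``SE = sqrt(MSw/2 * (1/n_i + 1/n_j))``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValidationError("values and groups must align")
    levels = list(pd.unique(groups))
    k = len(levels)
    if k < 2:
        return pd.DataFrame(
            columns=["level_a", "level_b", "mean_diff", "q", "p_adj", "reject"]
        )
    means, ns, ss_within = {}, {}, 0.0
    for lev in levels:
        x = values[groups == lev]
        means[lev] = x.mean()
        ns[lev] = x.size
        ss_within += ((x - x.mean()) ** 2).sum()
    df_w = values.size - k
    if df_w < 1:
        raise ValidationError("residual degrees of freedom must be >= 1")
    ms_w = ss_within / df_w
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            diff = means[a] - means[b]
            se = np.sqrt(ms_w / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            q = np.abs(diff) / se if se > 0 else np.inf
            p = float(studentized_range.sf(q, k, df_w)) if np.isfinite(q) else 0.0
            rows.append(
                {
                    "level_a": a,
                    "level_b": b,
                    "mean_diff": float(diff),
                    "q": float(q),
                    "p_adj": p,
                    "reject": bool(p < alpha),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ClusterResult:
    k: int
    medoid_indices: np.ndarray
    medoids: np.ndarray
    assignments: np.ndarray
    criterion_curve: np.ndarray  # within-distance ratio per candidate k (1..k_max)


def _pam(x: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100):
    """Classic PAM: greedy BUILD then SWAP until no improving swap exists."""
    n = x.shape[0]
    dist = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    # BUILD: first medoid minimizes total distance; rest greedily
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        current = dist[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - dist, 0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = list(medoids)
    for _ in range(max_iter):
        best_delta, best_swap = 0.0, None
        base = dist[:, medoids].min(axis=1).sum()
        for mi, m in enumerate(medoids):
            others = [o for o in medoids if o != m]
            for h in range(n):
                if h in medoids:
                    continue
                trial = others + [h]
                cost = dist[:, trial].min(axis=1).sum()
                delta = cost - base
                if delta < best_delta - 1e-12:
                    best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
    medoids = sorted(medoids)
    assign = np.argmin(dist[:, medoids], axis=1)
    cost = dist[np.arange(n), np.asarray(medoids)[assign]].sum()
    return np.asarray(medoids), assign, float(cost)


def kmedoids_elbow(
    values: np.ndarray, k_max: int, seed: int = 0
) -> ClusterResult:
    """PAM over k = 1..k_max; k chosen at the elbow of the criterion curve.

    The criterion for each k is the total within-cluster Euclidean distance
    divided by its k = 1 value; the elbow is the k with the largest discrete
    second difference of that curve (ties and flat curves resolve toward
    smaller k).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if k_max >= n:
        raise ValidationError("k_max must be smaller than the number of observations")
    if k_max < 1:
        raise ValidationError("k_max must be >= 1")
    rng = np.random.default_rng(seed)
    runs = [_pam(x, k, rng) for k in range(1, k_max + 1)]
    costs = np.array([r[2] for r in runs])
    base = costs[0] if costs[0] > 0 else 1.0
    curve = costs / base
    if costs[0] <= 1e-12 or k_max <= 2:
        k_best = 1 if costs[0] <= 1e-12 else int(np.argmin(costs[: min(2, k_max)]) + 1)
        if k_max <= 2 and costs[0] > 1e-12:
            # too few candidates for a second difference; prefer the smaller k
            # unless adding a cluster removes essentially all within-distance
            k_best = 2 if k_max == 2 and curve[1] < 0.1 else 1
    else:
        second = curve[:-2] - 2 * curve[1:-1] + curve[2:]  # at k = 2..k_max-1
        k_best = int(np.argmax(second)) + 2
    medoid_idx, assign, _ = runs[k_best - 1]
    return ClusterResult(
        k=k_best,
        medoid_indices=medoid_idx,
        medoids=x[medoid_idx],
        assignments=assign,
        criterion_curve=curve,
    )
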