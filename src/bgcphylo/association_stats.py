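"""Distance-distance association statistics.

The central analyses regress one pairwise quantity on another: inhibition
zone vs phylogenetic distance, genome BGC distance vs patristic distance.
Three layers are provided:

* :func:`distance_lm` — simple OLS on unfolded pairs, reporting adjusted R²
  and the one-sided (upper-tail) F test, matching how such correlations are
  conventionally summarised.
* :func:`mantel_test` — a permutation test on the distance matrices
  themselves, robust to the non-independence of unfolded pairs.
* :func:`duncan_mrt` — Duncan's multiple range test with a compact letter
  display, for comparing inhibition across groups of targets.

:func:`per_strain_association` and :func:`meta_regression` implement the
two-level analysis: per-antagonist association strength (signed adjusted R²)
regressed on the antagonist's BGC count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import DistanceMatrix, InhibitionTable, ValidationError

__all__ = [
    "LMResult",
    "MantelResult",
    "distance_lm",
    "mantel_test",
    "duncan_mrt",
    "per_strain_association",
    "meta_regression",
]

log = logging.getLogger("bgcphylo")


@dataclass(frozen=True)
class LMResult:
    slope: float
    intercept: float
    adjusted_R2: float
    F_statistic: float
    df: tuple[int, int]
    p_value: float

    @property
    def signed_adjusted_R2(self) -> float:
        """Adjusted R² carrying the sign of the slope (association metric)."""
        return self.adjusted_R2 * (1.0 if self.slope >= 0 else -1.0)


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int


def distance_lm(x: Sequence[float], y: Sequence[float]) -> LMResult:
    """OLS fit y = a + b*x with adjusted R² and upper-tail F test.

    adjusted R² = 1 - (1-R²)(n-1)/(n-2);  F = R²(n-2)/(1-R²) on (1, n-2) df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D of equal length")
    n = len(x)
    if n < 3:
        raise ValidationError(f"need >= 3 observations, got {n}")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise ValidationError("x is constant: degenerate design")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    syy = float(np.sum((y - y.mean()) ** 2))
    if syy == 0.0:
        raise ValidationError("y is constant: degenerate design")
    ss_res = syy - slope * sxy
    r2 = 1.0 - ss_res / syy
    r2 = min(1.0, max(0.0, r2))
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    if r2 >= 1.0:
        f = np.inf
        p = 0.0
    else:
        f = r2 * (n - 2) / (1.0 - r2)
        p = float(stats.f.sf(f, 1, n - 2))
    p = max(p, np.nextafter(0.0, 1.0))  # p in (0, 1]
    return LMResult(slope, intercept, adj, float(f), (1, n - 2), p)


def mantel_test(
    dx: DistanceMatrix,
    dy: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> MantelResult:
    """One-sided (positive) Mantel test with joint row/column permutation.

    p = (1 + #{permuted r >= observed r}) / (n_perm + 1); never zero.
    """
    if n_perm < 99:
        raise ValidationError("n_perm must be >= 99")
    if set(dx.labels) != set(dy.labels):
        raise ValidationError("distance matrices must share labels")
    dy = dy.reorder(dx.labels)
    n = len(dx.labels)
    iu = np.triu_indices(n, k=1)
    vx = dx.values[iu]
    rng = np.random.default_rng(seed)

    def corr(vy: np.ndarray) -> float:
        return float(np.corrcoef(vx, vy)[0, 1])

    r_obs = corr(dy.values[iu])
    count = 0
    ym = dy.values
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr(ym[np.ix_(perm, perm)][iu]) >= r_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm, seed=seed)


def duncan_mrt(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> dict[str, str]:
    """Duncan's multiple range test with a compact letter display.

    One-way ANOVA pooled MSE; means ranked in descending order; a span of p
    consecutive ranked means differs significantly when the range of their
    means exceeds Duncan's critical range

        R_p = q(1 - (1-alpha)^(p-1); p, df_err) * sqrt(MSE / n_h)

    with ``n_h`` the harmonic mean group size.  Groups not separated by any
    significant range share a letter; letters are assigned in descending-mean
    order starting at 'a'.
    """
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    for g, vals in groups.items():
        if len(vals) < 2:
            raise ValidationError(f"group {g!r} has < 2 values")
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    k = len(names)
    ns = np.array([len(a) for a in arrays])
    df_err = int(ns.sum() - k)
    mse = float(sum(((a - a.mean()) ** 2).sum() for a in arrays) / df_err)
    n_h = k / float(np.sum(1.0 / ns))
    means = np.array([a.mean() for a in arrays])

    order = np.argsort(-means, kind="stable")  # descending
    ranked = [names[i] for i in order]
    m = means[order]

    def critical_range(span: int) -> float:
        if mse == 0.0:
            return 0.0  # zero error: any mean difference is significant
        protection = 1.0 - (1.0 - alpha) ** (span - 1)
        q = stats.studentized_range.ppf(1.0 - protection, span, df_err)
        return float(q * np.sqrt(mse / n_h))

    def differs(i: int, j: int) -> bool:
        """True if ranked means i..j (i < j) are declared different."""
        span = j - i + 1
        diff = m[i] - m[j]
        if mse == 0.0:
            return diff > 0.0
        return diff > critical_range(span)

    # homogeneous maximal runs of ranked means -> letters
    runs: list[tuple[int, int]] = []
    start = 0
    while start < k:
        end = start
        while end + 1 < k and not differs(start, end + 1):
            end += 1
        runs.append((start, end))
        start += 1
    # keep maximal runs only
    maximal = [
        (a, b)
        for (a, b) in runs
        if not any((c <= a and b <= d) and (c, d) != (a, b) for (c, d) in runs)
    ]
    maximal.sort()
    letters: dict[str, str] = {g: "" for g in names}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for idx, (a, b) in enumerate(maximal):
        ch = alphabet[idx % len(alphabet)]
        for pos in range(a, b + 1):
            letters[ranked[pos]] += ch
    return letters


def per_strain_association(
    inhibition: InhibitionTable,
    phylo_d: DistanceMatrix,
    bgc_d: DistanceMatrix,
    bgc_counts: Mapping[str, float],
) -> pd.DataFrame:
    """Per-antagonist LMs of mean inhibition zone vs each distance type.

    Replicates are averaged per (antagonist, target) before regression.
    Antagonists with fewer than 3 targets with available distances are
    skipped with a warning.  Returns one row per retained antagonist with
    slopes, adjusted R² (and their signed products) plus the strain's BGC
    count.
    """
    means = inhibition.mean_zones()
    rows = []
    for antagonist, grp in means.groupby("antagonist", sort=True):
        pts = []
        for _, row in grp.iterrows():
            t = row["target"]
            if t == antagonist:
                continue
            if (
                antagonist in phylo_d.labels
                and t in phylo_d.labels
                and antagonist in bgc_d.labels
                and t in bgc_d.labels
            ):
                pts.append(
                    (phylo_d[antagonist, t], bgc_d[antagonist, t], row["zone_mm"])
                )
        if len(pts) < 3:
            log.warning(
                "antagonist %s skipped: only %d targets with distances",
                antagonist, len(pts),
            )
            continue
        px, bx, z = map(np.array, zip(*pts))
        try:
            lm_p = distance_lm(px, z)
            lm_b = distance_lm(bx, z)
        except ValidationError as exc:
            log.warning("antagonist %s skipped: %s", antagonist, exc)
            continue
        rows.append(
            {
                "antagonist": antagonist,
                "n_targets": len(pts),
                "slope_phylo": lm_p.slope,
                "adj_r2_phylo": lm_p.adjusted_R2,
                "assoc_phylo": lm_p.signed_adjusted_R2,
                "p_phylo": lm_p.p_value,
                "slope_bgc": lm_b.slope,
                "adj_r2_bgc": lm_b.adjusted_R2,
                "assoc_bgc": lm_b.signed_adjusted_R2,
                "p_bgc": lm_b.p_value,
                "bgc_count": float(bgc_counts.get(antagonist, np.nan)),
            }
        )
    return pd.DataFrame(rows)


def meta_regression(summary: pd.DataFrame, response: str = "phylo_assoc") -> LMResult:
    """LM of per-strain association strength on the strain's BGC count.

    ``response``: ``phylo_assoc`` (signed adj. R² of zone~phylo-distance) or
    ``bgcdist_assoc`` (signed adj. R² of zone~BGC-distance).
    """
    col = {"phylo_assoc": "assoc_phylo", "bgcdist_assoc": "assoc_bgc"}.get(response)
    if col is None:
        raise ValidationError(f"unknown response {response!r}")
    if len(summary) < 3:
        raise ValidationError("meta_regression needs >= 3 strains")
    return distance_lm(summary["bgc_count"].to_numpy(), summary[col].to_numpy())
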