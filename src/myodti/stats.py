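"""Group statistics and Monte-Carlo eigenvector-uncertainty analysis.

Group differences use the two-sided Wilcoxon rank-sum (Mann-Whitney) test,
evaluated by exact permutation enumeration for small samples (min(n, m) <= 8,
the per-heart design of 8 infarcted vs 4 control hearts) and by the
tie-corrected normal approximation otherwise. Associations use Pearson
correlation. No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats

from .dti import GradientScheme, design_matrix, eigendecompose
from .phantom import prolate_eigenvalues

__all__ = [
    "GroupComparison",
    "UncertaintyPoint",
    "rank_sum_test",
    "pearson_r",
    "percent_change",
    "summarize_groups",
    "mc_eigenvector_uncertainty",
    "EXACT_ENUMERATION_MAX_N",
]

EXACT_ENUMERATION_MAX_N = 8  # exact permutation test when min(n, m) <= this


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    mean_a: float
    std_a: float
    mean_b: float
    std_b: float
    percent_change: float  # (a - b) / b * 100, b the reference group
    statistic: float
    p_value: float
    mode: str
    group_a: str = "infarcted"
    group_b: str = "control"


@dataclass(frozen=True)
class UncertaintyPoint:
    fa: float
    md: float
    snr: float
    mean_deg: float
    p95_deg: float
    n_reps: int
    seed: int


def _mann_whitney_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic of x via midranks (tie-safe)."""
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    w = ranks[: x.size].sum()
    return float(w - x.size * (x.size + 1) / 2)


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact permutation enumeration over all C(n+m, n) group labelings when
    min(n, m) <= 8; tie-corrected normal approximation (with continuity
    correction) otherwise. Returns (U statistic of the first sample, p).
    Identical pooled values give p = 1.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    u_obs = _mann_whitney_u(x, y)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return u_obs, 1.0

    n, m = x.size, y.size
    if min(n, m) <= EXACT_ENUMERATION_MAX_N:
        ranks = scipy.stats.rankdata(pooled)
        base = n * (n + 1) / 2
        center = n * m / 2
        obs_dev = abs(u_obs - center)
        hits = total = 0
        for idx in combinations(range(n + m), n):
            u = ranks[list(idx)].sum() - base
            total += 1
            if abs(u - center) >= obs_dev - 1e-12:
                hits += 1
        return u_obs, hits / total
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


def pearson_r(x, y) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(scipy.stats.pearsonr(x, y).statistic)


def percent_change(value: float, reference: float) -> float:
    """Signed percent change 100 * (value - reference) / reference."""
    if reference == 0:
        raise ValueError("zero reference: percent change undefined")
    return 100.0 * (value - reference) / reference


_DEFAULT_METRICS = [
    "wall_thickness_mm",
    "scar_transmurality",
    "inclination_range_deg",
    "slope_deg_per_mm",
    "intercept_deg",
    "r2",
    "imbrication_mean_deg",
    "inclination_incoherency_deg",
    "imbrication_incoherency_deg",
    "lh_ratio",
    "circ_ratio",
    "rh_ratio",
]


def summarize_groups(
    segment_table: pd.DataFrame,
    mode: str = "per_heart",
    metrics: list[str] | None = None,
    group_a: str = "infarcted",
    group_b: str = "control",
) -> pd.DataFrame:
    """Group comparison of segment metrics between infarcted and control segments.

    ``per_heart``: each metric is first averaged within heart, and the rank-sum
    test runs across heart means. ``per_segment``: pooled segment records are
    compared directly. Percent change is relative to the control group. Metrics
    undefined in a group (e.g. scar transmurality of controls) get NaN
    statistics.
    """
    if mode not in ("per_heart", "per_segment"):
        raise ValueError("mode must be 'per_heart' or 'per_segment'")
    metrics = metrics or [m for m in _DEFAULT_METRICS if m in segment_table.columns]
    sub_a = segment_table[segment_table["status"] == group_a]
    sub_b = segment_table[segment_table["status"] == group_b]
    if len(sub_a) == 0 or len(sub_b) == 0:
        raise ValueError(f"need segments of both statuses '{group_a}' and '{group_b}'")

    rows = []
    for metric in metrics:
        if mode == "per_heart":
            a = sub_a.groupby("heart_id")[metric].mean().to_numpy()
            b = sub_b.groupby("heart_id")[metric].mean().to_numpy()
        else:
            a = sub_a[metric].to_numpy()
            b = sub_b[metric].to_numpy()
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        mean_a = float(a.mean()) if a.size else np.nan
        mean_b = float(b.mean()) if b.size else np.nan
        if a.size and b.size:
            stat, p = rank_sum_test(a, b)
            pc = percent_change(mean_a, mean_b) if mean_b != 0 else np.nan
        else:
            stat, p, pc = np.nan, np.nan, np.nan
        rows.append(
            GroupComparison(
                metric=metric,
                mean_a=mean_a,
                std_a=float(a.std(ddof=1)) if a.size > 1 else np.nan,
                mean_b=mean_b,
                std_b=float(b.std(ddof=1)) if b.size > 1 else np.nan,
                percent_change=pc,
                statistic=stat,
                p_value=p,
                mode=mode,
                group_a=group_a,
                group_b=group_b,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def mc_eigenvector_uncertainty(
    fa: float,
    md: float,
    snr: float,
    scheme: GradientScheme,
    n_reps: int = 1000,
    seed: int = 0,
    s0: float = 1000.0,
) -> UncertaintyPoint:
    """Monte-Carlo angular uncertainty of the fitted primary eigenvector.

    A single-voxel prolate tensor with the given (FA, MD) and primary
    eigenvector along +x is simulated ``n_reps`` times with Rician noise at the
    given SNR, refit by log-linear OLS, and the angle between the fitted and
    true primary eigenvector recorded. Returns the mean and 95th-percentile
    deviation in degrees.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100 for stable percentiles")
    if fa <= 0:
        raise ValueError("fa = 0: primary eigenvector undefined (uniform deviation)")
    lam1, lam2, lam3 = prolate_eigenvalues(md, fa)
    d = np.diag([lam1, lam2, lam3])  # e1 along +x
    g = scheme.directions
    b = scheme.b_values
    clean = s0 * np.exp(-b * np.einsum("ij,jk,ik->i", g, d, g))

    dwi_idx = scheme.dwi_index
    b0_idx = scheme.b0_index
    pinv = np.linalg.pinv(design_matrix(g[dwi_idx], b[dwi_idx]))

    rng = np.random.default_rng(seed)
    sigma = s0 / snr
    if np.isfinite(snr):
        noise = rng.normal(0.0, sigma, size=(n_reps, 2, len(scheme)))
        sig = np.sqrt((clean + noise[:, 0]) ** 2 + noise[:, 1] ** 2)
    else:
        sig = np.broadcast_to(clean, (n_reps, len(scheme))).copy()
    sig = np.maximum(sig, 1e-12)

    s0_hat = sig[:, b0_idx].mean(axis=1)
    y = -np.log(sig[:, dwi_idx] / s0_hat[:, None])
    d6 = y @ pinv.T
    tensors = np.zeros((n_reps, 3, 3))
    tensors[:, 0, 0] = d6[:, 0]
    tensors[:, 1, 1] = d6[:, 1]
    tensors[:, 2, 2] = d6[:, 2]
    tensors[:, 0, 1] = tensors[:, 1, 0] = d6[:, 3]
    tensors[:, 0, 2] = tensors[:, 2, 0] = d6[:, 4]
    tensors[:, 1, 2] = tensors[:, 2, 1] = d6[:, 5]
    _, evecs = eigendecompose(tensors)
    v1 = evecs[:, 0, :]
    dev = np.degrees(np.arccos(np.clip(np.abs(v1[:, 0]), 0.0, 1.0)))
    return UncertaintyPoint(
        fa=fa,
        md=md,
        snr=snr,
        mean_deg=float(dev.mean()),
        p95_deg=float(np.percentile(dev, 95)),
        n_reps=n_reps,
        seed=seed,
    )
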