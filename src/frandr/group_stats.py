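"""Condition tests, channel-count permutation test, and SOZ contrast.

Per channel and HFO type, per-trial rates in the task condition are compared
with the control condition by a two-sided Wilcoxon rank-sum (Mann–Whitney)
test.  Because many channels are tested, the family-level question — "are
more channels modulated than chance would produce?" — is answered by a
permutation test with scrambled labels: trial condition labels are permuted
(one shuffle per session, shared by all channels of that session so that
inter-channel correlation survives), the per-channel tests are recomputed,
and the count of significant channels forms the null distribution.  The
permutation p-value is ``(1 + #{null >= observed}) / (n_permutations + 1)``,
so its floor is ``1/(n_permutations + 1)``.

Separately, channels inside and outside the clinician-defined seizure onset
zone are compared on their pooled whole-task rates (channel as the
statistical unit), again by rank-sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as ss

from .task_trials import pooled_channel_rates


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------


def _asymptotic_mwu(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann–Whitney p via normal approximation with mid-ranks,
    tie-corrected variance and continuity correction.  Returns (p, U1).

    Matches the scalar asymptotic result of :func:`scipy.stats.mannwhitneyu`;
    kept explicit here because the permutation engine reuses the same formula
    in vectorised form.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = ss.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    _, t = np.unique(pooled, return_counts=True)
    p = _mwu_p_from_u(np.asarray([u1]), n1, n2, float((t**3 - t).sum()))[0]
    return float(p), float(u1)


def _mwu_p_from_u(u1: np.ndarray, n1: int, n2: int, tie_term: float) -> np.ndarray:
    """Vectorised two-sided asymptotic p-values from U1 values."""
    n = n1 + n2
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    if var <= 0:
        return np.ones_like(np.asarray(u1, dtype=float))
    sigma = np.sqrt(var)
    u = np.maximum(u1, n1 * n2 - u1)
    z = (u - mu - 0.5) / sigma
    return np.clip(2.0 * ss.norm.sf(z), 0.0, 1.0)


def ranksum(x, y, method: str = "auto") -> tuple[float, str]:
    """Two-sided Wilcoxon rank-sum test; returns ``(p_value, direction)``.

    ``direction`` is ``"up"`` when x tends to exceed y (by rank sums),
    ``"down"`` for the reverse, ``"none"`` on an exact rank tie.  The exact
    null distribution is enumerated when the pooled sample has at most 20
    observations and no ties; otherwise the normal approximation with tie and
    continuity corrections is used.  ``method`` may force ``"exact"`` or
    ``"asymptotic"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatsError("rank-sum test undefined for an empty sample")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if method == "auto":
        method = "exact" if (pooled.size <= 20 and no_ties) else "asymptotic"
    if method == "exact":
        res = ss.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        p, u1 = float(res.pvalue), float(res.statistic)
    elif method == "asymptotic":
        p, u1 = _asymptotic_mwu(x, y)
    else:
        raise StatsError(f"unknown method {method!r}")
    mu = x.size * y.size / 2.0
    if u1 > mu:
        direction = "up"
    elif u1 < mu:
        direction = "down"
    else:
        direction = "none"
    return p, direction


# ---------------------------------------------------------------------------
# per-channel tests
# ---------------------------------------------------------------------------

TEST_COLUMNS = ["channel", "region", "soz", "hfo_type", "p_value", "direction",
                "n_task", "n_control", "total_count", "skipped"]


def test_channels(rt: pd.DataFrame, alpha: float = 0.05,
                  method: str = "auto") -> pd.DataFrame:
    """One rank-sum test per channel x HFO type (task vs. control trial rates).

    ``direction`` is "up"/"down" only when p < alpha, "none" otherwise (no
    per-channel multiple-testing correction: the family-wise control happens
    at the count level via :func:`permutation_count_test`).  Channels lacking
    trials in either condition are kept but flagged ``skipped``.
    """
    rows = []
    for (ch, region, soz, hfo_type), g in rt.groupby(
        ["channel", "region", "soz", "hfo_type"], sort=True
    ):
        x = g.loc[g.condition == "task", "rate_per_min"].to_numpy()
        y = g.loc[g.condition == "control", "rate_per_min"].to_numpy()
        total = int(g["count"].sum())
        if x.size == 0 or y.size == 0:
            rows.append((ch, region, soz, hfo_type, 1.0, "none", x.size, y.size, total, True))
            continue
        p, direction = ranksum(x, y, method=method)
        if p >= alpha:
            direction = "none"
        rows.append((ch, region, soz, hfo_type, p, direction, x.size, y.size, total, False))
    return pd.DataFrame(rows, columns=TEST_COLUMNS)


def count_modulated(tests: pd.DataFrame, region: str | None = None,
                    hfo_type: str | None = None) -> tuple[int, int, int]:
    """(n_up, n_down, n_detectable) among channels of a region and HFO type.

    ``n_detectable`` counts channels with at least one event of the type —
    the denominator used when reporting percentages of modulated channels.
    Pass ``None`` to pool over regions or types.
    """
    sub = tests
    if region is not None:
        sub = sub[sub.region == region]
    if hfo_type is not None:
        sub = sub[sub.hfo_type == hfo_type]
    n_up = int((sub.direction == "up").sum())
    n_down = int((sub.direction == "down").sum())
    n_detectable = int((sub.total_count > 0).sum())
    return n_up, n_down, n_detectable


# ---------------------------------------------------------------------------
# permutation test on channel counts
# ---------------------------------------------------------------------------


@dataclass
class PermutationResult:
    region: str | None
    hfo_type: str
    observed_count: int
    null_counts: np.ndarray
    p_value: float
    n_permutations: int
    seed: int
    alpha: float = 0.05
    scramble: str = "joint"
    n_up: int = 0
    n_down: int = 0
    n_detectable: int = 0
    n_channels: int = 0

    def summary(self) -> dict:
        nc = np.asarray(self.null_counts)
        return {
            "region": self.region,
            "hfo_type": self.hfo_type,
            "observed_count": self.observed_count,
            "n_up": self.n_up,
            "n_down": self.n_down,
            "n_detectable": self.n_detectable,
            "n_channels": self.n_channels,
            "p_value": self.p_value,
            "null_min": int(nc.min()),
            "null_median": float(np.median(nc)),
            "null_max": int(nc.max()),
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "alpha": self.alpha,
            "scramble": self.scramble,
        }


def _session_blocks(rt: pd.DataFrame):
    if "session" in rt.columns:
        for sess, g in rt.groupby("session", sort=True):
            yield str(sess), g
    else:
        yield "s1", rt


def permutation_count_test(rt: pd.DataFrame, region: str | None, hfo_type: str,
                           alpha: float = 0.05, n_perm: int = 200, seed: int = 0,
                           scramble: str = "joint",
                           statistic: str = "any") -> PermutationResult:
    """Scrambled-label permutation test on the count of modulated channels.

    The observed statistic is the number of channels whose task/control
    rank-sum is significant at ``alpha`` (``statistic``: "any" counts both
    directions, "up"/"down" one direction).  For each permutation the trial
    condition labels are shuffled once per session — by default jointly for
    all channels of the session, which preserves the inter-channel correlation
    that makes the count statistic non-binomial (``scramble="per_channel"``
    shuffles independently instead).  Within the permutation engine, observed
    and null counts both use the tie-corrected asymptotic rank-sum so the two
    sides of the comparison are exchangeable.
    """
    if n_perm < 200:
        raise StatsError("n_perm must be at least 200")
    if scramble not in ("joint", "per_channel"):
        raise StatsError(f"unknown scramble mode {scramble!r}")
    if statistic not in ("any", "up", "down"):
        raise StatsError(f"unknown statistic {statistic!r}")
    sub = rt[rt.hfo_type == hfo_type]
    if region is not None:
        sub = sub[sub.region == region]
    if sub.empty:
        raise StatsError(f"no rows for region={region!r}, hfo_type={hfo_type!r}")
    rng = np.random.default_rng(seed)
    obs_total = 0
    n_up_obs = 0
    n_down_obs = 0
    null_counts = np.zeros(n_perm, dtype=int)
    n_channels = 0
    n_detectable = int(
        sub.groupby("channel", sort=True)["count"].sum().gt(0).sum()
    )
    for _sess, g in _session_blocks(sub):
        mat = g.pivot_table(index="channel", columns="trial_id",
                            values="rate_per_min", sort=True)
        if mat.isna().any().any():
            raise StatsError("channels of one session must share the same trials")
        cond = (
            g.drop_duplicates("trial_id").set_index("trial_id")["condition"]
            .reindex(mat.columns)
        )
        is_task = (cond == "task").to_numpy()
        n1 = int(is_task.sum())
        n2 = int((~is_task).sum())
        if n1 == 0 or n2 == 0:
            continue
        data = mat.to_numpy()  # (n_ch, n_trials)
        n_ch, n_tr = data.shape
        n_channels += n_ch
        ranks = np.apply_along_axis(ss.rankdata, 1, data)
        tie_terms = np.array([
            float((t**3 - t).sum())
            for t in (np.unique(row, return_counts=True)[1] for row in data)
        ])
        def _counts(labels_bool: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
            # labels_bool: (n_rep, n_trials); returns per-rep (n_sig_up, n_sig_down)
            r1 = labels_bool.astype(float) @ ranks.T  # (n_rep, n_ch)
            u1 = r1 - n1 * (n1 + 1) / 2.0
            p = np.empty_like(u1)
            for j in range(n_ch):
                p[:, j] = _mwu_p_from_u(u1[:, j], n1, n2, tie_terms[j])
            sig = p < alpha
            up = sig & (u1 > n1 * n2 / 2.0)
            down = sig & (u1 < n1 * n2 / 2.0)
            return up.sum(axis=1), down.sum(axis=1), sig.sum(axis=1)
        up0, down0, _ = _counts(is_task[None, :])
        n_up_obs += int(up0[0])
        n_down_obs += int(down0[0])
        if scramble == "joint":
            perms = np.empty((n_perm, n_tr), dtype=bool)
            for i in range(n_perm):
                perms[i] = rng.permutation(is_task)
            up, down, _ = _counts(perms)
            null_part = _pick_stat(up, down, statistic)
        else:
            null_part = np.zeros(n_perm, dtype=int)
            for j in range(n_ch):
                perms = np.empty((n_perm, n_tr), dtype=bool)
                for i in range(n_perm):
                    perms[i] = rng.permutation(is_task)
                r1 = perms.astype(float) @ ranks[j]
                u1 = r1 - n1 * (n1 + 1) / 2.0
                p = _mwu_p_from_u(u1, n1, n2, tie_terms[j])
                sig = p < alpha
                up = (sig & (u1 > n1 * n2 / 2.0)).astype(int)
                down = (sig & (u1 < n1 * n2 / 2.0)).astype(int)
                null_part += _pick_stat(up, down, statistic)
        null_counts += null_part
    observed = _pick_stat(np.asarray([n_up_obs]), np.asarray([n_down_obs]), statistic)[0]
    p_value = (1.0 + float((null_counts >= observed).sum())) / (n_perm + 1.0)
    return PermutationResult(
        region=region, hfo_type=hfo_type, observed_count=int(observed),
        null_counts=null_counts, p_value=p_value, n_permutations=n_perm,
        seed=seed, alpha=alpha, scramble=scramble,
        n_up=n_up_obs, n_down=n_down_obs, n_detectable=n_detectable,
        n_channels=n_channels,
    )


def _pick_stat(up: np.ndarray, down: np.ndarray, statistic: str) -> np.ndarray:
    if statistic == "any":
        return up + down
    return up if statistic == "up" else down


# ---------------------------------------------------------------------------
# SOZ contrast
# ---------------------------------------------------------------------------


@dataclass
class SOZComparison:
    hfo_type: str
    n_soz: int
    n_nonsoz: int
    p_value: float
    direction: str
    median_soz: float = float("nan")
    median_nonsoz: float = float("nan")


def soz_test(rt: pd.DataFrame, hfo_type: str) -> SOZComparison:
    """Rank-sum of pooled whole-task channel rates, SOZ vs. non-SOZ.

    One pooled rate per channel (both conditions, all trials); the channel is
    the statistical unit.  ``direction="up"`` means SOZ rates tend higher.
    """
    pooled = pooled_channel_rates(rt)
    pooled = pooled[pooled.hfo_type == hfo_type]
    soz = pooled.loc[pooled.soz, "rate_per_min"].to_numpy()
    non = pooled.loc[~pooled.soz, "rate_per_min"].to_numpy()
    if soz.size == 0 or non.size == 0:
        raise StatsError(
            f"SOZ comparison for {hfo_type!r} needs channels in both groups "
            f"(got {soz.size} SOZ, {non.size} non-SOZ)"
        )
    p, direction = ranksum(soz, non)
    return SOZComparison(hfo_type=hfo_type, n_soz=soz.size, n_nonsoz=non.size,
                         p_value=p, direction=direction,
                         median_soz=float(np.median(soz)),
                         median_nonsoz=float(np.median(non)))
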