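"""Paired nonparametric statistics for small rehabilitation cohorts.

The two procedures the cohort stage needs are implemented from first
principles so their small-sample behaviour is fully specified:

* Wilcoxon signed-rank test (paired, two-sided).  Zero differences are
  discarded (the classical Wilcoxon convention), absolute differences are
  mid-ranked, and for n <= 15 the null distribution of W+ is obtained by
  full enumeration of the 2^n sign assignments, so the p-value is exact
  even under ties.  Larger n uses the normal approximation with tie
  correction and a continuity correction.
* Spearman rank correlation: Pearson correlation of mid-rank transforms;
  two-sided p from the t approximation with n - 2 df, or a seeded
  Monte-Carlo permutation test.

Significance convention follows the source setting: alpha = 0.05 per
test, no multiplicity correction by default (a Holm adjustment is
available but off).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm as _normal, rankdata, t as _t

ALPHA = 0.05


@dataclass
class StatResult:
    method: str  # wilcoxon_signed_rank | spearman
    n: int
    statistic: float
    p_value: float
    p_method: str  # exact | normal_approx | t_approx | permutation | degenerate
    rho: Optional[float] = None
    alpha: float = ALPHA
    note: str = ""

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.rho is not None and not np.isnan(self.rho) and abs(self.rho) > 1 + 1e-12:
            raise ValueError(f"|rho| = {abs(self.rho)} > 1")

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


def wilcoxon_signed_rank(
    paired: Sequence[tuple[float, float]],
    zero_method: str = "wilcoxon",
    exact_limit: int = 15,
) -> StatResult:
    """Two-sided paired Wilcoxon signed-rank test on (x_0w, x_4w) pairs.

    Differences are ``x_4w - x_0w``.  With ``zero_method='wilcoxon'`` zero
    differences are dropped before ranking; ``'pratt'`` ranks them but
    drops their contribution.  The statistic reported is
    ``W = min(W+, W-)``; the two-sided p doubles the smaller tail
    (clipped at 1), which for the enumerated null is the convention exact
    tests commonly use.
    """
    arr = np.asarray(paired, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("paired data must be (n, 2)")
    d = arr[:, 1] - arr[:, 0]
    if zero_method not in ("wilcoxon", "pratt"):
        raise ValueError(f"unknown zero_method {zero_method!r}")

    if zero_method == "wilcoxon":
        d = d[d != 0]
        ranks = rankdata(np.abs(d)) if d.size else np.array([])
    else:
        ranks_all = rankdata(np.abs(d))
        ranks = ranks_all[d != 0]
        d = d[d != 0]

    n = d.size
    if n == 0:
        return StatResult(
            method="wilcoxon_signed_rank", n=0, statistic=0.0, p_value=1.0,
            p_method="degenerate", note="all differences zero",
        )
    if n < 3:
        return StatResult(
            method="wilcoxon_signed_rank", n=n, statistic=float(ranks[d > 0].sum()),
            p_value=1.0, p_method="degenerate",
            note="fewer than 3 nonzero differences; test uninformative",
        )

    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)

    if n <= exact_limit:
        p = _exact_two_sided_p(ranks, w_plus)
        method = "exact"
    else:
        total = ranks.sum()
        mean = total / 2.0
        # variance with mid-rank ties baked in: sum(r_i^2) / 4
        var = float(np.square(ranks).sum()) / 4.0
        cc = 0.5 if w_plus != mean else 0.0
        z = (w_plus - mean - np.sign(w_plus - mean) * cc) / np.sqrt(var)
        p = float(min(1.0, 2.0 * _normal.sf(abs(z))))
        method = "normal_approx"
    return StatResult(
        method="wilcoxon_signed_rank", n=int(n), statistic=w, p_value=p, p_method=method,
    )


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p by enumerating all sign assignments of the ranks."""
    n = ranks.size
    # (2^n, n) sign matrix via bit tricks; n <= 15 keeps this under 1M rows
    patterns = np.arange(2**n, dtype=np.int64)
    bits = (patterns[:, None] >> np.arange(n)[None, :]) & 1
    w_dist = bits @ ranks  # W+ for every assignment
    total = ranks.sum()
    lo = np.mean(w_dist <= w_plus + 1e-9)
    hi = np.mean(w_dist >= w_plus - 1e-9)
    return float(min(1.0, 2.0 * min(lo, hi)))


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    p_method: str = "t_approx",
    n_permutations: int = 99_999,
    rng: np.random.Generator | int | None = None,
) -> StatResult:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of mid-rank transforms (so ties are
    handled); the default p uses the t approximation with n - 2 df, and
    ``p_method='permutation'`` runs a seeded Monte-Carlo permutation test
    (add-one corrected), the recommended option at small n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed; drop them explicitly")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 pairs")
    rx, ry = rankdata(x), rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return StatResult(
            method="spearman", n=n, statistic=float("nan"), p_value=float("nan"),
            p_method="degenerate", rho=float("nan"),
            note="zero variance in ranks; rho undefined",
        )
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = float(np.clip(rho, -1.0, 1.0))

    if p_method == "t_approx":
        if abs(rho) == 1.0:
            p = 0.0
        else:
            tstat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * _t.sf(abs(tstat), df=n - 2))
        return StatResult(
            method="spearman", n=n, statistic=rho, p_value=min(1.0, p),
            p_method="t_approx", rho=rho,
        )
    if p_method == "permutation":
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        count = 0
        # permute y's ranks; correlation of ranks is all that matters
        rx_c = rx - rx.mean()
        denom = np.sqrt((rx_c**2).sum())
        for _ in range(n_permutations):
            perm = gen.permutation(ry)
            r = float(rx_c @ (perm - perm.mean())) / (
                denom * np.sqrt(((perm - perm.mean()) ** 2).sum())
            )
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        p = (count + 1) / (n_permutations + 1)
        return StatResult(
            method="spearman", n=n, statistic=rho, p_value=p,
            p_method="permutation", rho=rho,
        )
    raise ValueError(f"unknown p_method {p_method!r}")


# ---------------------------------------------------------------------------
# Results tables
# ---------------------------------------------------------------------------

_MSDA_SCOPES = [("total", "msda_total"), ("training", "msda_training"),
                ("nontraining", "msda_nontraining")]
_WILCOXON_METRICS = [
    "minutes_lying", "minutes_sitting_standing", "minutes_walking",
    "hrr_mean_total", "hrr_mean_training", "hrr_mean_nontraining",
    "msda_total", "msda_training", "msda_nontraining",
]


@dataclass
class ResultsBundle:
    correlations: pd.DataFrame
    paired_tests: pd.DataFrame
    notes: list[str]

    def to_markdown(self) -> str:
        lines = ["# Cohort results", "", "## Spearman rank correlations (MSDA vs FIM motor / age)", ""]
        lines.append(self.correlations.to_string(index=False))
        lines += ["", "## Paired Wilcoxon signed-rank tests (0W vs 4W)", ""]
        lines.append(self.paired_tests.to_string(index=False))
        if self.notes:
            lines += ["", "## Notes", ""]
            lines += [f"- {n}" for n in self.notes]
        return "\n".join(lines) + "\n"


def build_results_tables(
    cohort: pd.DataFrame,
    p_method: str = "t_approx",
    rng: np.random.Generator | int | None = None,
    sessions: tuple[str, str] = ("0W", "4W"),
) -> ResultsBundle:
    """The cohort-statistics stage: a correlation grid (MSDA scope x
    {FIM motor, age} x session) and paired 0W-vs-4W Wilcoxon tests over
    posture minutes, %HRR means and MSDA metrics.

    Patients missing a metric in one session drop out of the paired test
    for that metric (counts are reported) but still enter cross-sectional
    correlations for sessions where they have data.
    """
    notes: list[str] = []
    corr_rows = []
    for scope, col in _MSDA_SCOPES:
        row: dict = {"msda_scope": scope}
        for vs, vs_col in (("fim", "fim_motor"), ("age", "age")):
            for sess in sessions:
                sub = cohort[(cohort["session"] == sess)][[col, vs_col]].dropna()
                key = f"rho_vs_{vs}_{sess.lower()}"
                if len(sub) >= 4:
                    res = spearman(sub[vs_col].to_numpy(), sub[col].to_numpy(),
                                   p_method=p_method, rng=rng)
                    row[key] = res.rho
                    row[f"p_vs_{vs}_{sess.lower()}"] = res.p_value
                    row[f"n_vs_{vs}_{sess.lower()}"] = res.n
                else:
                    row[key] = np.nan
                    row[f"p_vs_{vs}_{sess.lower()}"] = np.nan
                    row[f"n_vs_{vs}_{sess.lower()}"] = len(sub)
                    notes.append(f"{scope} vs {vs} ({sess}): fewer than 4 complete rows")
        corr_rows.append(row)

    s0, s1 = sessions
    wide = cohort.pivot(index="patient_id", columns="session", values=_WILCOXON_METRICS)
    test_rows = []
    for metric in _WILCOXON_METRICS:
        try:
            block = wide[metric][[s0, s1]].dropna()
        except KeyError:
            notes.append(f"{metric}: session column missing; paired test skipped")
            continue
        if len(block) < 3:
            notes.append(f"{metric}: fewer than 3 complete pairs; paired test skipped")
            continue
        res = wilcoxon_signed_rank(list(zip(block[s0], block[s1])))
        test_rows.append(
            {
                "metric": metric,
                "n_pairs": len(block),
                f"mean_{s0.lower()}": float(block[s0].mean()),
                f"mean_{s1.lower()}": float(block[s1].mean()),
                "W": res.statistic,
                "p_value": res.p_value,
                "p_method": res.p_method,
                "significant": res.significant if res.p_method != "degenerate" else False,
            }
        )
    return ResultsBundle(
        correlations=pd.DataFrame(corr_rows),
        paired_tests=pd.DataFrame(test_rows),
        notes=notes,
    )


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; off by default)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
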