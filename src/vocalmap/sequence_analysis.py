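"""Call-pair and caller-sequence statistics for multi-individual timelines.

Four linked analyses quantify whether calls are produced as antiphonal
exchanges (caller transitions, structured timing) or as independent
broadcasts (same-caller repetition):

* :func:`interval_threshold` — the inter-call-interval quantile that bounds
  "the next call" (temporally dependent transitions);
* :func:`build_pairs` + :func:`mdca` — multiple distinctive collocation
  analysis: signed −log10 binomial tail probabilities scoring over- or
  under-representation of each ordered call-category pair, optionally on the
  self-reply (same caller) or non-self-reply (different caller) subset;
* :func:`nonself_proportions` — per-category caller-transition probability
  with a Pearson chi-squared test and Bonferroni-corrected pairwise tests;
* :func:`triple_patterns` / :func:`permutation_null_patterns` — caller
  identity patterns (A-A-stop ... A-B-C) of 2–3 call sequences within a
  spatial radius of the initial caller, against a per-individual
  circular-time-shift permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PATTERNS = ("A-A-stop", "A-A-A", "A-A-B", "A-B-stop", "A-B-A", "A-B-B", "A-B-C")

#: Categories excluded from the caller-transition proportion analysis by
#: default (too few homogeneous pairs for robust inference).
LOW_SAMPLE_CATEGORIES = ("mo", "ld")


@dataclass
class TransitionMatrix:
    """Counts and signed log-binomial association scores for ordered pairs."""

    categories: list[str]
    counts: pd.DataFrame     # rows: first category, cols: second category
    pbin: pd.DataFrame       # signed -log10 binomial tail prob; NaN where n_a == 0
    subset: str = "all"      # 'all' | 'self' | 'nonself'


@dataclass
class CallerPatternResult:
    pattern: str
    observed_prop: float
    null_props: np.ndarray = field(default_factory=lambda: np.empty(0))
    p_over: float = float("nan")
    p_under: float = float("nan")

    @property
    def p_two_tailed(self) -> float:
        return min(1.0, 2.0 * min(self.p_over, self.p_under))


def _pooled_timeline(calls: pd.DataFrame) -> pd.DataFrame:
    """Group timeline sorted by onset; ties broken by (individual, event_id)."""
    return calls.sort_values(
        ["t_start", "individual_id", "event_id"], kind="stable"
    ).reset_index(drop=True)


def interval_threshold(calls: pd.DataFrame, quantile: float = 0.9,
                       override: float | None = None) -> float:
    """Quantile of gaps between each call and the next call by anyone.

    ``override`` short-circuits the computation (e.g. to pin the threshold to
    a previously estimated value such as 2.31 s).  Gaps are onset-to-onset in
    the pooled group timeline; the quantile uses the linear (type-7)
    convention.
    """
    if override is not None:
        return float(override)
    if len(calls) < 2:
        raise ValueError("need at least 2 calls to estimate an interval threshold")
    t = _pooled_timeline(calls)["t_start"].to_numpy()
    gaps = np.diff(t)
    return float(np.quantile(gaps, quantile))


def build_pairs(calls: pd.DataFrame, threshold_s: float, subset: str = "all") -> pd.DataFrame:
    """Consecutive call pairs of one group-session timeline.

    Each call is paired with the immediately next call by *anyone* iff the
    onset-to-onset gap is <= ``threshold_s``.  Returns a frame with columns
    (first_event, second_event, first_individual, second_individual,
    first_category, second_category, gap_s, same_caller), filtered to the
    requested subset ('all' | 'self' | 'nonself').
    """
    if subset not in ("all", "self", "nonself"):
        raise ValueError(f"unknown subset {subset!r}")
    tl = _pooled_timeline(calls)
    if len(tl) < 2:
        return pd.DataFrame(columns=[
            "first_event", "second_event", "first_individual", "second_individual",
            "first_category", "second_category", "gap_s", "same_caller"])
    first = tl.iloc[:-1].reset_index(drop=True)
    second = tl.iloc[1:].reset_index(drop=True)
    pairs = pd.DataFrame({
        "first_event": first["event_id"],
        "second_event": second["event_id"],
        "first_individual": first["individual_id"],
        "second_individual": second["individual_id"],
        "first_category": first["category"],
        "second_category": second["category"],
        "gap_s": second["t_start"].to_numpy() - first["t_start"].to_numpy(),
        "same_caller": (first["individual_id"] == second["individual_id"]).to_numpy(),
    })
    pairs = pairs[pairs["gap_s"] <= threshold_s].reset_index(drop=True)
    if subset == "self":
        pairs = pairs[pairs["same_caller"]].reset_index(drop=True)
    elif subset == "nonself":
        pairs = pairs[~pairs["same_caller"]].reset_index(drop=True)
    return pairs


def mdca(pairs: pd.DataFrame, categories: list[str] | None = None,
         subset: str = "all") -> TransitionMatrix:
    """Multiple distinctive collocation analysis of ordered category pairs.

    For each ordered pair (a, b): with n_a transitions initiating with a,
    global response margin p_b, and k observed a→b transitions, the score is
    the two-sided binomial tail probability of k (P(X>=k) when k exceeds the
    expectation n_a·p_b, else P(X<=k)), reported as a signed −log10 —
    positive for over-, negative for under-represented pairs.  Rows with
    n_a = 0 are NaN.
    """
    if len(pairs) == 0:
        raise ValueError("mdca requires at least one call pair")
    if categories is None:
        categories = sorted(set(pairs["first_category"]) | set(pairs["second_category"]))
    n = len(pairs)
    counts = (
        pairs.groupby(["first_category", "second_category"], observed=True)
        .size().unstack(fill_value=0)
        .reindex(index=categories, columns=categories, fill_value=0)
    )
    n_a = counts.sum(axis=1).to_numpy(dtype=float)
    p_b = counts.sum(axis=0).to_numpy(dtype=float) / n

    pbin = np.full(counts.shape, np.nan)
    for i in range(len(categories)):
        if n_a[i] == 0:
            continue
        for j in range(len(categories)):
            k = int(counts.iat[i, j])
            expect = n_a[i] * p_b[j]
            if k >= expect:
                p = float(stats.binom.sf(k - 1, int(n_a[i]), p_b[j]))
                sign = 1.0
            else:
                p = float(stats.binom.cdf(k, int(n_a[i]), p_b[j]))
                sign = -1.0
            p = min(max(p, 1e-300), 1.0)
            pbin[i, j] = sign * (-np.log10(p))
    pbin_df = pd.DataFrame(pbin, index=categories, columns=categories)
    # -0.0 from p == 1 normalizes to 0.0
    pbin_df = pbin_df + 0.0
    return TransitionMatrix(categories=list(categories), counts=counts, pbin=pbin_df, subset=subset)


@dataclass
class NonSelfResult:
    table: pd.DataFrame          # category, n_self, n_nonself, prop_nonself
    chi2: float
    df: int
    p_value: float
    pairwise: pd.DataFrame       # cat_a, cat_b, chi2, p_raw, p_bonferroni


def nonself_proportions(pairs: pd.DataFrame,
                        exclude: tuple[str, ...] = LOW_SAMPLE_CATEGORIES) -> NonSelfResult:
    """Caller-transition probability per category, with chi-squared tests.

    Uses homogeneous (same-category) pairs only.  The overall test is a
    Pearson chi-squared on the categories × {self, nonself} count table;
    post hoc pairwise 2×2 tests are Bonferroni-corrected (p multiplied by the
    number of comparisons, capped at 1).  Categories with zero homogeneous
    pairs — and by default the low-sample 'mo' and 'ld' categories — are
    excluded.
    """
    homog = pairs[pairs["first_category"] == pairs["second_category"]]
    homog = homog[~homog["first_category"].isin(exclude)]
    rows = []
    for cat, grp in homog.groupby("first_category", observed=True):
        n_self = int(grp["same_caller"].sum())
        n_nonself = int((~grp["same_caller"]).sum())
        rows.append({"category": cat, "n_self": n_self, "n_nonself": n_nonself,
                     "prop_nonself": n_nonself / (n_self + n_nonself)})
    table = pd.DataFrame(rows).sort_values("category").reset_index(drop=True)
    if len(table) < 2:
        raise ValueError("need homogeneous pairs for at least 2 categories")

    obs = table[["n_self", "n_nonself"]].to_numpy()
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=False)

    pw_rows = []
    cats = table["category"].tolist()
    n_comp = len(cats) * (len(cats) - 1) // 2
    for i in range(len(cats)):
        for j in range(i + 1, len(cats)):
            sub = obs[[i, j], :]
            c2, pr, _, _ = stats.chi2_contingency(sub, correction=False)
            pw_rows.append({"cat_a": cats[i], "cat_b": cats[j], "chi2": float(c2),
                            "p_raw": float(pr), "p_bonferroni": min(1.0, float(pr) * n_comp)})
    return NonSelfResult(table=table, chi2=float(chi2), df=int(df), p_value=float(p),
                         pairwise=pd.DataFrame(pw_rows))


# ---------------------------------------------------------------------------
# caller-sequence patterns


def _positions_at(trajs: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per individual: (sorted t, x, y) arrays of valid fixes."""
    out = {}
    use = trajs[trajs["valid"]] if "valid" in trajs.columns else trajs
    for ind, sub in use.groupby("individual_id", observed=True):
        sub = sub.sort_values("t")
        out[ind] = (sub["t"].to_numpy(), sub["x"].to_numpy(), sub["y"].to_numpy())
    return out


def _position_near(pos, ind: str, t: float, tol_s: float = 1.0):
    """Nearest fix within ±tol_s, or None."""
    if ind not in pos:
        return None
    ts, xs, ys = pos[ind]
    i = np.searchsorted(ts, t)
    best, best_dt = None, tol_s + 1e-9
    for j in (i - 1, i):
        if 0 <= j < len(ts):
            dt = abs(ts[j] - t)
            if dt < best_dt:
                best, best_dt = j, dt
    if best is None or best_dt > tol_s:
        return None
    return float(xs[best]), float(ys[best])


def triple_patterns(calls: pd.DataFrame, trajs: pd.DataFrame, threshold_s: float,
                    radius_m: float = 10.0, category: str | None = None) -> list[CallerPatternResult]:
    """Caller-identity patterns of 2–3 call chains within a spatial radius.

    Every call starts a candidate chain over the pooled same-category
    timeline: successive calls chain while the onset-to-onset gap is
    <= ``threshold_s`` AND the next caller is within ``radius_m`` of the
    *initial* caller (positions at the initial call's time).  An in-time but
    out-of-radius caller terminates the chain (counted as 'stop' when the
    chain already has two calls).  Chains of length 1 are not counted.
    Returns the proportion of each of the 7 identity patterns.
    """
    counts = _pattern_counts(calls, trajs, threshold_s, radius_m, category)
    total = sum(counts.values())
    return [
        CallerPatternResult(pattern=p, observed_prop=(counts[p] / total if total else 0.0))
        for p in PATTERNS
    ]


def _pattern_counts(calls, trajs, threshold_s, radius_m, category=None,
                    pos=None) -> dict[str, int]:
    """Vectorized chain construction over the pooled category timeline.

    For every start call i the chain needs the positions of callers i, i+1
    and i+2 *at time t[i]*; these are gathered per individual with one
    searchsorted pass per (individual, offset), after which the chain and
    labelling logic is pure boolean algebra.
    """
    if category is not None:
        calls = calls[calls["category"] == category]
    tl = _pooled_timeline(calls)
    t = tl["t_start"].to_numpy()
    who = tl["individual_id"].to_numpy()
    if pos is None:
        pos = _positions_at(trajs)
    counts = {p: 0 for p in PATTERNS}
    n = len(tl)
    if n < 2:
        return counts
    missing = sorted(set(who) - set(pos))
    if missing:
        logger.info("callers without GPS cannot start/extend chains: %s",
                    ", ".join(missing))

    # P[k][i] = position of caller who[i+k] at time t[i] (NaN if unavailable)
    P = [np.full((n, 2), np.nan) for _ in range(3)]
    for ind, (ts, xs, ys) in pos.items():
        if len(ts) == 0:
            continue
        ind_at = who == ind
        for k in range(3):
            starts = np.flatnonzero(ind_at[k:] if k else ind_at)
            if k:
                starts = starts[starts + k < n]
            if len(starts) == 0:
                continue
            times = t[starts]
            j = np.clip(np.searchsorted(ts, times), 0, len(ts) - 1)
            jp = np.clip(j - 1, 0, len(ts) - 1)
            pick = np.where(np.abs(ts[jp] - times) <= np.abs(ts[j] - times), jp, j)
            ok = np.abs(ts[pick] - times) <= 1.0
            P[k][starts[ok], 0] = xs[pick[ok]]
            P[k][starts[ok], 1] = ys[pick[ok]]

    i = np.arange(n - 1)
    gap1_ok = (t[i + 1] - t[i]) <= threshold_s
    d1 = np.hypot(P[1][i, 0] - P[0][i, 0], P[1][i, 1] - P[0][i, 1])
    len2 = gap1_ok & np.isfinite(P[0][i, 0]) & np.isfinite(d1) & (d1 <= radius_m)

    has3 = i + 2 < n
    gap2_ok = np.zeros(n - 1, dtype=bool)
    gap2_ok[has3] = (t[i[has3] + 2] - t[i[has3] + 1]) <= threshold_s
    d2 = np.full(n - 1, np.nan)
    d2[has3] = np.hypot(P[2][i[has3], 0] - P[0][i[has3], 0],
                        P[2][i[has3], 1] - P[0][i[has3], 1])
    len3 = len2 & gap2_ok & np.isfinite(d2) & (d2 <= radius_m)

    w0, w1 = who[i], who[i + 1]
    w2 = np.empty(n - 1, dtype=who.dtype)
    w2[has3] = who[i[has3] + 2]
    same2 = w0 == w1
    stop = len2 & ~len3
    counts["A-A-stop"] = int(np.sum(stop & same2))
    counts["A-B-stop"] = int(np.sum(stop & ~same2))
    third_is_first = np.zeros(n - 1, dtype=bool)
    third_is_second = np.zeros(n - 1, dtype=bool)
    third_is_first[has3] = w2[has3] == w0[has3]
    third_is_second[has3] = w2[has3] == w1[has3]
    counts["A-A-A"] = int(np.sum(len3 & same2 & third_is_first))
    counts["A-A-B"] = int(np.sum(len3 & same2 & ~third_is_first))
    counts["A-B-A"] = int(np.sum(len3 & ~same2 & third_is_first))
    counts["A-B-B"] = int(np.sum(len3 & ~same2 & third_is_second))
    counts["A-B-C"] = int(np.sum(len3 & ~same2 & ~third_is_first & ~third_is_second))
    return counts


def _pattern_label(chain: list[str]) -> str:
    a = chain[0]
    second = "A" if chain[1] == a else "B"
    if len(chain) == 2:
        return f"A-{second}-stop"
    c3 = chain[2]
    if second == "A":
        return "A-A-A" if c3 == a else "A-A-B"
    if c3 == a:
        return "A-B-A"
    if c3 == chain[1]:
        return "A-B-B"
    return "A-B-C"


def permutation_null_patterns(
    calls: pd.DataFrame,
    trajs: pd.DataFrame,
    threshold_s: float,
    *,
    radius_m: float = 10.0,
    category: str | None = None,
    t_window: tuple[float, float] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    scheme: str = "circular",
) -> list[CallerPatternResult]:
    """Caller patterns with p-values against a call-time permutation null.

    Two null schemes are available:

    * ``"circular"`` (default) — every individual's call-onset series is
      shifted circularly by an independent uniform offset within the session
      window.  Within-individual timing (burstiness, interval multiset) is
      preserved exactly; only cross-individual contingency is destroyed.
      This is the sharper null for detecting *temporal coupling between
      callers* (antiphonal exchange), but independent stationary streams are
      exchangeable with it, so it cannot flag single-caller burst structure.
    * ``"label"`` — the pooled call-time multiset is kept fixed and caller
      identities are permuted across calls (per-individual call counts
      preserved).  This breaks within-individual burst structure too, so
      same-caller repetition (broadcast-style A-A sequences) shows up as
      over-representation against it.

    p-values use the standard (1 + #{null >= obs}) / (1 + n_perm) form (and
    its <= analogue), reported as both tails.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if scheme not in ("circular", "label"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    if category is not None:
        calls = calls[calls["category"] == category].reset_index(drop=True)
    if t_window is None:
        t_window = (float(calls["t_start"].min()), float(calls["t_start"].max()) + 1e-6)
    span = t_window[1] - t_window[0]
    rng = np.random.default_rng(seed)

    observed = triple_patterns(calls, trajs, threshold_s, radius_m)
    obs_props = np.array([r.observed_prop for r in observed])
    pos = _positions_at(trajs)

    individuals = sorted(calls["individual_id"].unique())
    null = np.empty((n_perm, len(PATTERNS)))
    permuted = calls.copy()
    base_t = calls["t_start"].to_numpy()
    base_who = calls["individual_id"].to_numpy()
    for b in range(n_perm):
        if scheme == "circular":
            t_new = base_t.copy()
            for ind in individuals:
                m = base_who == ind
                delta = rng.uniform(0, span)
                t_new[m] = t_window[0] + np.mod(base_t[m] - t_window[0] + delta, span)
            permuted["t_start"] = t_new
            permuted["t_end"] = t_new  # offsets unused by the pattern analysis
        else:  # label: caller identities permuted over the fixed pooled times
            permuted["individual_id"] = base_who[rng.permutation(len(base_who))]
        counts = _pattern_counts(permuted, trajs, threshold_s, radius_m, pos=pos)
        total = sum(counts.values())
        null[b] = [counts[p] / total if total else 0.0 for p in PATTERNS]

    results = []
    for i, p in enumerate(PATTERNS):
        over = (1 + int((null[:, i] >= obs_props[i] - 1e-12).sum())) / (1 + n_perm)
        under = (1 + int((null[:, i] <= obs_props[i] + 1e-12).sum())) / (1 + n_perm)
        results.append(CallerPatternResult(
            pattern=p, observed_prop=float(obs_props[i]), null_props=null[:, i].copy(),
            p_over=min(1.0, over), p_under=min(1.0, under)))
    return results


def caller_transition_share(results: list[CallerPatternResult]) -> float:
    """Aggregate proportion of sequences involving a caller transition (A-B-*)."""
    return float(sum(r.observed_prop for r in results if r.pattern.startswith("A-B")))
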