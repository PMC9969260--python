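"""Permutation statistics for the state-metric tables, plus cohort-comparison
utilities (chi-square, pooled t, two-sample KS, group-mean imputation).

The main tool is a permutation repeated-measures ANOVA for a mixed design:
one between-subject factor (group) crossed with one or more within-subject
factors (condition, state, optionally to_state). Observed F statistics are
the classical mixed-design ratios — each effect tested against the error
stratum it belongs to (subjects within groups for the between effect;
effect x subject-within-group for within effects and interactions) — and
p-values come from permutation:

* effects involving group permute whole-subject group labels within the
  effect's stratum;
* within-subject main effects permute that factor's levels independently
  within each subject;
* within x within interactions permute, within each subject, the LEVELS of
  each involved factor on the subject's interaction-residual profile (the
  subject's data with its own lower-order within-factor means removed) — a
  Freedman-Lane-style residual permutation that preserves the zero-marginal
  constraints and the projection covariance of the residuals.

The add-one estimator p = (1 + #{F* >= F_obs}) / (1 + n_perm) avoids zero
p-values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "AnovaSpec",
    "EffectResult",
    "perm_rm_anova",
    "mixed_anova_F",
    "pairwise_perm_ttests",
    "bh_fdr",
    "chi_square_2x2",
    "pooled_t_from_summaries",
    "ks_two_sample",
    "group_mean_impute",
    "impute_metric_cells",
]


@dataclass
class AnovaSpec:
    """Configuration of one permutation repeated-measures ANOVA."""

    dependent: str = "value"
    subject: str = "subject_id"
    between: str = "group"
    within: tuple[str, ...] = ("condition", "state")
    n_perm: int = 10_000
    seed: int | None = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not self.within:
            raise ValueError("at least one within-subject factor is required")


@dataclass
class EffectResult:
    """One effect's observed F and permutation p."""

    effect: str
    F: float
    df_num: int
    df_den: int
    p_perm: float = np.nan
    ss: float = np.nan
    ss_err: float = np.nan


# ---------------------------------------------------------------------------
# cube construction and classical mixed-design decomposition
# ---------------------------------------------------------------------------


def _build_cube(df: pd.DataFrame, spec: AnovaSpec):
    """Pivot the long table into a (subjects x within-cells) data cube.

    Returns Y of shape (N, L1, ..., Lm), integer group codes per subject,
    group labels, subject ids, and the within-factor level lists. Raises if
    any subject x cell combination is missing or duplicated.
    """
    cols = [spec.subject, spec.between, *spec.within, spec.dependent]
    missing_cols = [c for c in cols if c not in df.columns]
    if missing_cols:
        raise ValueError(f"table lacks columns {missing_cols}")
    sub = df[cols].copy()
    keys = [spec.subject, *spec.within]
    if sub.duplicated(subset=keys).any():
        raise ValueError("duplicate (subject, within-cell) rows in ANOVA table")
    piv = sub.pivot(index=spec.subject, columns=list(spec.within), values=spec.dependent)
    levels = [sorted(sub[w].unique().tolist()) for w in spec.within]
    full_cols = (
        pd.MultiIndex.from_product(levels, names=list(spec.within))
        if len(spec.within) > 1
        else pd.Index(levels[0], name=spec.within[0])
    )
    piv = piv.reindex(columns=full_cols)
    if piv.isna().any().any():
        bad = piv.isna().stack(list(range(piv.columns.nlevels)), future_stack=True)
        bad = bad[bad].index.tolist()[:10]
        raise ValueError(f"incomplete cells (subject, {spec.within}): {bad}")
    subjects = piv.index.to_list()
    shape = (len(subjects), *[len(lv) for lv in levels])
    Y = piv.to_numpy(dtype=float).reshape(shape)
    gmap = sub.drop_duplicates(spec.subject).set_index(spec.subject)[spec.between]
    if sub.groupby(spec.subject)[spec.between].nunique().max() > 1:
        raise ValueError("a subject appears in more than one group")
    group_labels = sorted(gmap.unique().tolist())
    gcodes = np.array([group_labels.index(gmap[s]) for s in subjects])
    counts = np.bincount(gcodes, minlength=len(group_labels))
    if counts.min() < 2:
        raise ValueError("each group needs at least 2 subjects")
    return Y, gcodes, group_labels, subjects, levels


def _stratum_profiles(Y: np.ndarray) -> dict[tuple[int, ...], np.ndarray]:
    """Per-subject interaction-residual profiles for every within stratum.

    For a within-factor subset ``wset`` the profile t_i is the
    inclusion-exclusion combination of the subject's cell means over subsets
    of wset — the subject's data with its own lower-order within means
    removed. All sums of squares in the stratum are functions of these
    profiles. Key () holds the (N, 1) subject means (between stratum).
    """
    m = Y.ndim - 1
    out: dict[tuple[int, ...], np.ndarray] = {}
    out[()] = Y.reshape(Y.shape[0], -1).mean(axis=1, keepdims=True)
    for r in range(1, m + 1):
        for wset in itertools.combinations(range(m), r):
            t = np.zeros_like(Y)
            for k in range(len(wset) + 1):
                for f in itertools.combinations(wset, k):
                    axes = tuple(a + 1 for a in range(m) if a not in f)
                    term = Y.mean(axis=axes, keepdims=True) if axes else Y
                    t = t + ((-1) ** (len(wset) - k)) * term
            # t is constant along axes outside wset; collapse them
            drop = tuple(a + 1 for a in range(m) if a not in wset)
            t = t.mean(axis=drop) if drop else t
            out[wset] = t.reshape(Y.shape[0], -1)
    return out


def _stratum_ss(t: np.ndarray, gcodes: np.ndarray, n_groups: int):
    """(SS_within_effect, SS_group_by_effect, SS_error) for one stratum.

    ``t`` is the (N, cells) profile matrix. Scale constants common to the
    stratum cancel in every F ratio and are omitted.
    """
    grand = t.mean(axis=0)
    gmeans = np.empty((n_groups, t.shape[1]))
    ss_err = 0.0
    for g in range(n_groups):
        sel = gcodes == g
        gmeans[g] = t[sel].mean(axis=0)
        ss_err += float(((t[sel] - gmeans[g]) ** 2).sum())
    n_g = np.bincount(gcodes, minlength=n_groups)
    ss_within = float(t.shape[0] * (grand**2).sum())
    ss_group = float((n_g[:, None] * (gmeans - grand) ** 2).sum())
    return ss_within, ss_group, ss_err


def _effect_dfs(levels: list[list], n_subj: int, n_groups: int):
    """df for every effect and error stratum, keyed like _stratum_profiles."""
    m = len(levels)
    dfs = {}
    for r in range(0, m + 1):
        for wset in itertools.combinations(range(m), r):
            d = int(np.prod([len(levels[w]) - 1 for w in wset])) if wset else 1
            dfs[wset] = d
    return dfs, n_subj - n_groups


def mixed_anova_F(df: pd.DataFrame, spec: AnovaSpec) -> list[EffectResult]:
    """Classical mixed-design F statistics for every effect (no permutation).

    Effects are named with ':' joining factors, e.g. ``group:condition``.
    """
    Y, gcodes, glabels, subjects, levels = _build_cube(df, spec)
    profiles = _stratum_profiles(Y)
    dfs, df_subj_err = _effect_dfs(levels, len(subjects), len(glabels))
    results: list[EffectResult] = []
    for wset, t in profiles.items():
        ss_w, ss_g, ss_err = _stratum_ss(t, gcodes, len(glabels))
        df_eff = dfs[wset]
        df_err = df_subj_err * df_eff
        names = [spec.within[w] for w in wset]
        if wset:  # within-only effect
            F = (ss_w / df_eff) / (ss_err / df_err)
            results.append(
                EffectResult(":".join(names), F, df_eff, df_err, ss=ss_w, ss_err=ss_err)
            )
        F_g = (ss_g / ((len(glabels) - 1) * df_eff)) / (ss_err / df_err)
        results.append(
            EffectResult(
                ":".join([spec.between, *names]),
                F_g,
                (len(glabels) - 1) * df_eff,
                df_err,
                ss=ss_g,
                ss_err=ss_err,
            )
        )
    return results


# ---------------------------------------------------------------------------
# permutation layer
# ---------------------------------------------------------------------------


def _perm_within_levels(
    t: np.ndarray, shape: tuple[int, ...], rng: np.random.Generator
) -> np.ndarray:
    """Per subject, independently permute the levels of every stratum factor.

    The stratum profile t_i is the subject's interaction-residual cube over
    the factors in the stratum. Permuting whole factor levels (rows/columns
    of the cube), independently per subject and per factor, preserves the
    zero-marginal constraints and the projection-induced covariance of the
    residuals — an arbitrary cell shuffle would not, and makes interaction
    tests anti-conservative.
    """
    cube = t.reshape(t.shape[0], *shape)
    for ax in range(1, cube.ndim):
        idx = np.argsort(rng.random((cube.shape[0], cube.shape[ax])), axis=1)
        expand = [1] * cube.ndim
        expand[0] = cube.shape[0]
        expand[ax] = cube.shape[ax]
        take = np.broadcast_to(idx.reshape(expand), cube.shape)
        cube = np.take_along_axis(cube, take, axis=ax)
    return cube.reshape(t.shape)


def perm_rm_anova(table: pd.DataFrame, spec: AnovaSpec) -> list[EffectResult]:
    """Permutation repeated-measures ANOVA over a complete-cells long table.

    See the module docstring for the permutation scheme per effect class.
    Returns one :class:`EffectResult` per effect, observed F plus p_perm.
    """
    Y, gcodes, glabels, subjects, levels = _build_cube(table, spec)
    profiles = _stratum_profiles(Y)
    dfs, df_subj_err = _effect_dfs(levels, len(subjects), len(glabels))
    G = len(glabels)
    rng = np.random.default_rng(spec.seed)
    results: list[EffectResult] = []
    for wset, t in profiles.items():
        ss_w, ss_g, ss_err = _stratum_ss(t, gcodes, G)
        df_eff = dfs[wset]
        df_err = df_subj_err * df_eff
        names = [spec.within[w] for w in wset]

        if wset:
            F_obs = (ss_w / df_eff) / (ss_err / df_err)
            wshape = tuple(len(levels[w]) for w in wset)
            count = 0
            for _ in range(spec.n_perm):
                tp = _perm_within_levels(t, wshape, rng)
                pw, _, pe = _stratum_ss(tp, gcodes, G)
                if (pw / df_eff) / (pe / df_err) >= F_obs:
                    count += 1
            results.append(
                EffectResult(
                    ":".join(names), F_obs, df_eff, df_err,
                    p_perm=(1 + count) / (1 + spec.n_perm), ss=ss_w, ss_err=ss_err,
                )
            )

        df_geff = (G - 1) * df_eff
        F_gobs = (ss_g / df_geff) / (ss_err / df_err)
        count = 0
        for _ in range(spec.n_perm):
            gp = rng.permutation(gcodes)
            _, pg, pe = _stratum_ss(t, gp, G)
            if (pg / df_geff) / (pe / df_err) >= F_gobs:
                count += 1
        results.append(
            EffectResult(
                ":".join([spec.between, *names]), F_gobs, df_geff, df_err,
                p_perm=(1 + count) / (1 + spec.n_perm), ss=ss_g, ss_err=ss_err,
            )
        )
    return results


# ---------------------------------------------------------------------------
# post hoc pairwise permutation t-tests
# ---------------------------------------------------------------------------


def _paired_t(d: np.ndarray) -> float:
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(d.mean() / (sd / np.sqrt(d.size)))


def _pooled_t(x: np.ndarray, y: np.ndarray) -> float:
    n1, n2 = x.size, y.size
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        return 0.0 if x.mean() == y.mean() else np.inf
    return float((x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2)))


def paired_perm_ttest(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Paired permutation t-test via sign flips of within-subject differences.

    When ``2**n <= n_perm`` all sign patterns are enumerated and the p-value
    is exact (#{|t*| >= |t|} / 2**n, identity included); otherwise random
    sign flips with the add-one estimator.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    t_obs = _paired_t(d)
    if np.all(d == 0):
        return 0.0, 1.0
    if 2**n <= n_perm:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
        ts = np.array([_paired_t(d * s) for s in signs])
        p = float(np.mean(np.abs(ts) >= abs(t_obs) - 1e-12))
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            s = rng.choice((1.0, -1.0), size=n)
            if abs(_paired_t(d * s)) >= abs(t_obs) - 1e-12:
                count += 1
        p = (1 + count) / (1 + n_perm)
    return t_obs, p


def unpaired_perm_ttest(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Two-sample permutation t-test via group-label shuffles (pooled t)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    t_obs = _pooled_t(x, y)
    pooled = np.concatenate([x, y])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(_pooled_t(perm[: x.size], perm[x.size :])) >= abs(t_obs) - 1e-12:
            count += 1
    return t_obs, (1 + count) / (1 + n_perm)


def pairwise_perm_ttests(
    table: pd.DataFrame,
    pairs: list[tuple[dict, dict]],
    n_perm: int = 10_000,
    seed: int | None = 0,
    value_col: str = "value",
    subject_col: str = "subject_id",
    group_col: str = "group",
) -> pd.DataFrame:
    """Post hoc permutation t-tests over cell pairs, FDR-corrected as a family.

    Each pair is two cell selectors (column -> value dicts). Cells that
    differ in ``group_col`` are compared with an unpaired group-label
    permutation test; cells sharing the group constraint are matched by
    subject and compared with a paired sign-flip test. Cells with fewer than
    2 usable observations are flagged and excluded from the family.
    """

    def _select(cell: dict) -> pd.DataFrame:
        out = table
        for col, val in cell.items():
            out = out[out[col] == val]
        return out

    rows = []
    for i, (ca, cb) in enumerate(pairs):
        a, b = _select(ca), _select(cb)
        unpaired = group_col in ca and group_col in cb and ca[group_col] != cb[group_col]
        t = p = np.nan
        excluded = False
        if unpaired:
            xa = a[value_col].dropna().to_numpy()
            xb = b[value_col].dropna().to_numpy()
            if xa.size < 2 or xb.size < 2:
                excluded = True
            else:
                t, p = unpaired_perm_ttest(xa, xb, n_perm, None if seed is None else seed + i)
        else:
            merged = pd.merge(
                a[[subject_col, value_col]],
                b[[subject_col, value_col]],
                on=subject_col,
                suffixes=("_a", "_b"),
            ).dropna()
            if len(merged) < 2:
                excluded = True
            else:
                t, p = paired_perm_ttest(
                    merged[f"{value_col}_a"].to_numpy(),
                    merged[f"{value_col}_b"].to_numpy(),
                    n_perm,
                    None if seed is None else seed + i,
                )
        rows.append(
            dict(pair=f"{ca} vs {cb}", paired=not unpaired, t=t, p_perm=p, excluded=excluded)
        )
    out = pd.DataFrame(rows)
    ok = ~out["excluded"]
    out["p_fdr"] = np.nan
    if ok.any():
        out.loc[ok, "p_fdr"] = bh_fdr(out.loc[ok, "p_perm"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# utility statistics
# ---------------------------------------------------------------------------


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order kept)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1-D")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def chi_square_2x2(counts, yates: bool = True) -> tuple[float, int]:
    """Pearson chi-square for a 2x2 table, Yates-corrected by default."""
    c = np.asarray(counts, dtype=float)
    if c.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    if np.any(c.sum(axis=0) == 0) or np.any(c.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    res = sstats.chi2_contingency(c, correction=yates)
    return float(res.statistic), int(res.dof)


def pooled_t_from_summaries(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> tuple[float, int]:
    """Equal-variance two-sample t from group summaries; df = n1 + n2 - 2.

    Returns (nan, df) when both SDs are zero and the means are equal
    (statistic undefined).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    df = n1 + n2 - 2
    if sd1 == 0 and sd2 == 0:
        return (np.nan if m1 == m2 else np.inf * np.sign(m1 - m2)), df
    res = sstats.ttest_ind_from_stats(m1, sd1, n1, m2, sd2, n2, equal_var=True)
    return float(res.statistic), df


def ks_two_sample(x, y) -> float:
    """Two-sample Kolmogorov-Smirnov D (sup distance of empirical CDFs)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    return float(sstats.ks_2samp(x, y).statistic)


def group_mean_impute(values, groups) -> tuple[np.ndarray, list[int]]:
    """Replace NaNs with their group's observed mean; log imputed indices."""
    v = np.asarray(values, dtype=float).copy()
    g = np.asarray(groups)
    if v.shape != g.shape:
        raise ValueError("values/groups length mismatch")
    imputed = []
    for lbl in np.unique(g):
        sel = g == lbl
        miss = sel & np.isnan(v)
        if not miss.any():
            continue
        obs = v[sel & ~np.isnan(v)]
        if obs.size == 0:
            raise ValueError(f"group {lbl!r} has no observed values to impute from")
        v[miss] = obs.mean()
        imputed.extend(np.flatnonzero(miss).tolist())
    return v, imputed


def impute_metric_cells(
    df: pd.DataFrame,
    value_col: str = "value",
    cell_cols: tuple[str, ...] = ("group", "condition", "state"),
) -> tuple[pd.DataFrame, int]:
    """Fill missing metric values with their design-cell mean.

    The permutation ANOVA needs complete subject x cell data; a state never
    visited by one subject in one condition is filled with the mean of that
    (group x condition x state) cell across the subjects that did visit it.
    Returns the completed table and the number of imputed values.
    """
    out = df.copy()
    missing = out[value_col].isna()
    if not missing.any():
        return out, 0
    cell_means = out.groupby(list(cell_cols), dropna=False)[value_col].transform("mean")
    if cell_means[missing].isna().any():
        bad = out.loc[missing & cell_means.isna(), list(cell_cols)].drop_duplicates()
        raise ValueError(f"cells with no observed values:\n{bad}")
    out.loc[missing, value_col] = cell_means[missing]
    return out, int(missing.sum())
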