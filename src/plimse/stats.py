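"""Group statistics: t-maps with BH-FDR, mixed repeated-measures ANOVA with
Greenhouse-Geisser correction, and correlation grids.

The mixed ANOVA implements the classical univariate sums-of-squares
decomposition for one between-subject factor (group) and one or two
within-subject factors (electrode; electrode x temporal scale), balanced
within subjects but allowing unequal group sizes.  Sphericity of each
within-subject effect is corrected by the Greenhouse-Geisser (Box) epsilon
estimated from the pooled within-group covariance of the subject-level cell
scores; the F degrees of freedom are multiplied by epsilon before computing
the corrected p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import helmert
from statsmodels.stats.multitest import multipletests

DEFAULT_Q_LEVELS: tuple[float, ...] = (0.05, 0.01)


# ---------------------------------------------------------------------------
# Elementary tests
# ---------------------------------------------------------------------------

def ttest_independent(x_a: np.ndarray, x_b: np.ndarray,
                      welch: bool = False) -> tuple[float, float]:
    """Two-sample two-tailed t-test (pooled variance by default).

    Set ``welch=True`` for the unequal-variance variant.
    """
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    if x_a.size < 2 or x_b.size < 2:
        raise ValueError("need at least two observations per group")
    if np.var(x_a, ddof=1) == 0 and np.var(x_b, ddof=1) == 0:
        raise ValueError("degenerate data: zero variance in both groups")
    t, p = sps.ttest_ind(x_a, x_b, equal_var=not welch)
    return float(t), float(p)


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up rejection mask and realized p threshold.

    The realized threshold is the largest rejected p-value (0 when nothing is
    rejected); it is data-dependent and reported rather than fixed a priori.
    NaN entries (tests that could not be run) are never rejected.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("empty p-value array")
    finite = ~np.isnan(pvals)
    if np.any((pvals[finite] < 0) | (pvals[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    mask = np.zeros(pvals.shape, dtype=bool)
    if finite.any():
        reject, _, _, _ = multipletests(pvals[finite], alpha=q, method="fdr_bh")
        mask[finite] = reject
    threshold = float(pvals[mask].max()) if mask.any() else 0.0
    return mask, threshold


def linear_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line through (x, y); returns (slope, intercept, Pearson R)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.all(x == x[0]):
        raise ValueError("need at least two distinct x values")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


# ---------------------------------------------------------------------------
# Statistic grids
# ---------------------------------------------------------------------------

@dataclass
class StatGrid:
    """Statistics, p-values and FDR masks laid out over an analysis grid.

    ``layout`` maps axis names to their labels in array order, e.g.
    ``{"electrode": [...], "band": [...]}`` for a (16, 5) grid.
    """

    statistic: np.ndarray
    p: np.ndarray
    layout: dict[str, list]
    stat_name: str = "t"
    masks: dict[float, np.ndarray] = field(default_factory=dict)
    thresholds: dict[float, float] = field(default_factory=dict)
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.statistic = np.asarray(self.statistic, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.statistic.shape != self.p.shape:
            raise ValueError("statistic and p grids must share a shape")
        expected = tuple(len(v) for v in self.layout.values())
        if self.statistic.shape != expected:
            raise ValueError(
                f"grid shape {self.statistic.shape} does not match layout {expected}")

    @property
    def n_tests(self) -> int:
        return self.p.size

    def apply_fdr(self, q_levels: tuple[float, ...] = DEFAULT_Q_LEVELS) -> "StatGrid":
        """Pool all cells of the grid into one BH-FDR correction per q level."""
        for q in q_levels:
            mask_flat, thr = bh_fdr(self.p.reshape(-1), q)
            self.masks[q] = mask_flat.reshape(self.p.shape)
            self.thresholds[q] = thr
        return self

    def to_frame(self) -> pd.DataFrame:
        axes = list(self.layout.keys())
        rows = []
        for idx in product(*(range(len(self.layout[a])) for a in axes)):
            row = {a: self.layout[a][i] for a, i in zip(axes, idx)}
            row[self.stat_name] = self.statistic[idx]
            row["p"] = self.p[idx]
            for q, m in self.masks.items():
                row[f"q{q:g}_mask"] = bool(m[idx])
            rows.append(row)
        return pd.DataFrame(rows)


def posthoc_map(values: np.ndarray, groups: np.ndarray,
                layout: dict[str, list],
                q_levels: tuple[float, ...] = DEFAULT_Q_LEVELS,
                welch: bool = False) -> StatGrid:
    """Cell-wise independent t-tests over a feature grid with pooled BH-FDR.

    ``values`` has shape (n_subjects, *grid); ``groups`` holds two group
    labels; the first label in sorted order is the reference so t > 0 means
    that group scores higher.  Subjects with an undefined (NaN) value in a
    cell are dropped listwise for that cell; cells that cannot be tested are
    flagged NaN and counted in ``n_excluded``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape[0] != groups.shape[0]:
        raise ValueError("one group label per subject row required")
    uniq = sorted(set(groups.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {uniq}")
    grid_shape = values.shape[1:]
    tvals = np.full(grid_shape, np.nan)
    pvals = np.full(grid_shape, np.nan)
    n_excluded = 0
    mask_a = groups == uniq[0]
    mask_b = groups == uniq[1]
    for idx in np.ndindex(*grid_shape):
        cell = values[(slice(None),) + idx]
        a = cell[mask_a]
        b = cell[mask_b]
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        try:
            tvals[idx], pvals[idx] = ttest_independent(a, b, welch=welch)
        except ValueError:
            n_excluded += 1
    grid = StatGrid(statistic=tvals, p=pvals, layout=layout, stat_name="t",
                    n_excluded=n_excluded)
    return grid.apply_fdr(q_levels)


def corr_grid(sampen: np.ndarray, nd: np.ndarray,
              electrode_labels: list, band_labels: list, scale_labels: list,
              q_levels: tuple[float, ...] = DEFAULT_Q_LEVELS) -> StatGrid:
    """Pearson correlation between SampEn and node degree per (electrode, band, scale).

    ``sampen`` has shape (n_subjects, n_electrodes, n_scales); ``nd`` has
    shape (n_subjects, n_bands, n_electrodes).  Correlations run across the
    subjects of one group; call once per group.
    """
    sampen = np.asarray(sampen, dtype=float)
    nd = np.asarray(nd, dtype=float)
    if sampen.shape[0] != nd.shape[0]:
        raise ValueError("subject dimension mismatch between SampEn and ND tables")
    n_subj, n_elec, n_scales = sampen.shape
    n_bands = nd.shape[1]
    if n_subj < 3:
        raise ValueError("need at least three subjects for a correlation")
    r = np.full((n_elec, n_bands, n_scales), np.nan)
    p = np.full((n_elec, n_bands, n_scales), np.nan)
    for e in range(n_elec):
        for b in range(n_bands):
            y = nd[:, b, e]
            for s in range(n_scales):
                x = sampen[:, e, s]
                ok = ~(np.isnan(x) | np.isnan(y))
                if ok.sum() < 3:
                    continue
                res = sps.pearsonr(x[ok], y[ok])
                r[e, b, s] = res.statistic
                p[e, b, s] = res.pvalue
    grid = StatGrid(statistic=r, p=p,
                    layout={"electrode": list(electrode_labels),
                            "band": list(band_labels),
                            "scale": list(scale_labels)},
                    stat_name="R")
    return grid.apply_fdr(q_levels)


# ---------------------------------------------------------------------------
# Mixed repeated-measures ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """Effect table of a mixed repeated-measures ANOVA plus bookkeeping.

    ``table`` columns: effect, ss, df1, df2, F, eps, p_unc, p_gg.  ``p_gg``
    equals ``p_unc`` for the between-subject effect (no sphericity involved).
    """

    table: pd.DataFrame
    ss_total: float
    ss_decomposed: float

    def effect(self, name: str) -> pd.Series:
        rows = self.table[self.table["effect"] == name]
        if rows.empty:
            raise KeyError(f"no effect {name!r}; have {list(self.table['effect'])}")
        return rows.iloc[0]


def _gg_epsilon(scores: np.ndarray, group_idx: list[np.ndarray],
                contrast: np.ndarray) -> float:
    """Greenhouse-Geisser (Box) epsilon from pooled within-group covariance.

    ``scores`` is (n_subjects, n_cells); ``contrast`` is an orthonormal
    (d, n_cells) matrix spanning the effect subspace.
    """
    n_cells = scores.shape[1]
    pooled = np.zeros((n_cells, n_cells))
    dof = 0
    for idx in group_idx:
        z = scores[idx] - scores[idx].mean(axis=0)
        pooled += z.T @ z
        dof += idx.size - 1
    pooled /= max(dof, 1)
    m = contrast @ pooled @ contrast.T
    d = contrast.shape[0]
    denom = d * float(np.trace(m @ m))
    if denom <= 0:
        return 1.0
    eps = float(np.trace(m)) ** 2 / denom
    return float(np.clip(eps, 1.0 / d, 1.0))


def _orthonormal_contrast(n_levels: int) -> np.ndarray:
    """(n-1, n) matrix with orthonormal rows orthogonal to the constant."""
    if n_levels < 2:
        raise ValueError("a within factor needs at least 2 levels")
    return helmert(n_levels, full=False)


def _f_row(effect: str, ss: float, df1: float, ss_err: float, df_err: float,
           eps: float) -> dict:
    f = (ss / df1) / (ss_err / df_err)
    p_unc = float(sps.f.sf(f, df1, df_err))
    p_gg = float(sps.f.sf(f, eps * df1, eps * df_err))
    return {"effect": effect, "ss": ss, "df1": df1, "df2": df_err,
            "F": float(f), "eps": eps, "p_unc": p_unc, "p_gg": p_gg}


def rm_anova_mixed(table: pd.DataFrame, dv: str, subject: str,
                   between: str, within: list[str]) -> AnovaResult:
    """Mixed-design ANOVA: one between factor, one or two within factors.

    The design must be balanced within subjects (every subject observed in
    every within-factor cell exactly once); group sizes may differ.  Within
    effects and their group interactions are tested against their own
    subject-by-factor error terms, with Greenhouse-Geisser corrected degrees
    of freedom.
    """
    if len(within) not in (1, 2):
        raise ValueError("supported designs have 1 or 2 within factors")
    cols = [subject, between, dv, *within]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    wide = table.pivot_table(index=[subject, between], columns=within,
                             values=dv, aggfunc="mean")
    counts = table.groupby([subject, *within], observed=True)[dv].count()
    if wide.isna().any().any() or (counts != 1).any():
        raise ValueError("design must be balanced: every subject needs every "
                         "within-factor cell exactly once")
    levels = [sorted(table[w].unique().tolist()) for w in within]
    if len(within) == 1:
        order = pd.Index(levels[0])
    else:
        order = pd.MultiIndex.from_product(levels, names=within)
    wide = wide.reindex(columns=order)
    j_sizes = [len(lv) for lv in levels]
    j1 = j_sizes[0]
    j2 = j_sizes[1] if len(within) == 2 else 1
    j_total = j1 * j2

    group_labels = wide.index.get_level_values(between).to_numpy()
    uniq_groups = sorted(set(group_labels.tolist()))
    a = len(uniq_groups)
    if a < 2:
        raise ValueError("between factor needs at least two groups")
    group_idx = [np.flatnonzero(group_labels == g) for g in uniq_groups]
    if any(idx.size < 2 for idx in group_idx):
        raise ValueError("need at least two subjects per group")
    n_subj = wide.shape[0]
    y = wide.to_numpy().reshape(n_subj, j1, j2)

    subj_mean = y.mean(axis=(1, 2))
    grand = subj_mean.mean()
    group_mean = np.array([subj_mean[idx].mean() for idx in group_idx])
    n_per_group = np.array([idx.size for idx in group_idx])

    ss_total = float(((y - grand) ** 2).sum())
    ss_group = float(j_total * (n_per_group * (group_mean - grand) ** 2).sum())
    ss_subj_in_group = float(j_total * sum(
        ((subj_mean[idx] - gm) ** 2).sum()
        for idx, gm in zip(group_idx, group_mean)))
    ss_within_total = float(((y - subj_mean[:, None, None]) ** 2).sum())

    rows = [_f_row(between, ss_group, a - 1, ss_subj_in_group, n_subj - a, 1.0)]
    # the between test involves no repeated-measures sphericity
    rows[0]["p_gg"] = rows[0]["p_unc"]

    def within_block(marg: np.ndarray, name: str, mult: int) -> tuple[float, np.ndarray]:
        """SS/F rows for one within factor from subject x level marginal means."""
        j = marg.shape[1]
        level_mean = marg.mean(axis=0)
        cell_mean = np.vstack([marg[idx].mean(axis=0) for idx in group_idx])
        ss_main = float(mult * n_subj * ((level_mean - grand) ** 2).sum())
        inter = (cell_mean - group_mean[:, None]
                 - level_mean[None, :] + grand)
        ss_inter = float(mult * (n_per_group[:, None] * inter ** 2).sum())
        resid = 0.0
        for gi, idx in enumerate(group_idx):
            dev = (marg[idx] - subj_mean[idx, None]
                   - cell_mean[gi][None, :] + group_mean[gi])
            resid += (dev ** 2).sum()
        ss_err = float(mult * resid)
        eps = _gg_epsilon(marg, group_idx, _orthonormal_contrast(j))
        df_err = (j - 1) * (n_subj - a)
        rows.append(_f_row(name, ss_main, j - 1, ss_err, df_err, eps))
        rows.append(_f_row(f"{between} x {name}", ss_inter, (a - 1) * (j - 1),
                           ss_err, df_err, eps))
        return ss_main + ss_inter + ss_err, cell_mean

    marg1 = y.mean(axis=2)
    ss_w1_block, cells1 = within_block(marg1, within[0], j2)

    if len(within) == 1:
        ss_decomposed = ss_group + ss_subj_in_group + ss_w1_block
    else:
        marg2 = y.mean(axis=1)
        ss_w2_block, cells2 = within_block(marg2, within[1], j1)
        d1 = marg1.mean(axis=0)
        d2 = marg2.mean(axis=0)
        d12 = y.mean(axis=0)
        inter12 = d12 - d1[:, None] - d2[None, :] + grand
        ss_12 = float(n_subj * (inter12 ** 2).sum())
        g12 = np.stack([y[idx].mean(axis=0) for idx in group_idx])
        g_inter = (g12 - cells1[:, :, None] - cells2[:, None, :]
                   + group_mean[:, None, None]) - inter12[None, :, :]
        ss_g12 = float((n_per_group[:, None, None] * g_inter ** 2).sum())
        resid = 0.0
        for gi, idx in enumerate(group_idx):
            dev = (y[idx] - marg1[idx, :, None] - marg2[idx, None, :]
                   + subj_mean[idx, None, None])
            dev -= g12[gi][None] - cells1[gi][None, :, None] \
                - cells2[gi][None, None, :] + group_mean[gi]
            resid += (dev ** 2).sum()
        ss_err12 = float(resid)
        d_int = (j1 - 1) * (j2 - 1)
        contrast12 = np.kron(_orthonormal_contrast(j1), _orthonormal_contrast(j2))
        eps12 = _gg_epsilon(y.reshape(n_subj, j_total), group_idx, contrast12)
        df_err12 = d_int * (n_subj - a)
        name12 = f"{within[0]} x {within[1]}"
        rows.append(_f_row(name12, ss_12, d_int, ss_err12, df_err12, eps12))
        rows.append(_f_row(f"{between} x {name12}", ss_g12, (a - 1) * d_int,
                           ss_err12, df_err12, eps12))
        ss_decomposed = (ss_group + ss_subj_in_group + ss_w1_block
                         + ss_w2_block + ss_12 + ss_g12 + ss_err12)

    result = AnovaResult(table=pd.DataFrame(rows), ss_total=ss_total,
                         ss_decomposed=float(ss_decomposed))
    return result
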