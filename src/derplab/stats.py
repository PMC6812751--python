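"""Mixed-design ANOVA (between: GROUP; within: EXPERIMENT, ELECTRODE),
partial eta squared, Wilcoxon signed-rank post-hocs, and Holm correction.

The ANOVA is the classical univariate split-plot sums-of-squares
decomposition computed from marginal means.  With unequal group sizes the
within-subject marginals are observation-weighted (each subject weight 1);
groups must be balanced within subject (every subject contributes every
experiment x electrode cell) -- subjects with missing cells are dropped
listwise and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "AnovaResult",
    "mixed_anova",
    "partial_eta_sq",
    "wilcoxon_posthoc",
    "holm_correct",
    "report_corrected_pair",
    "posthoc_contrast",
    "ELECTRODE_CONTRASTS",
]

# Shipped electrode poolings for the named post-hoc contrasts.  The exact
# poolings are configurable; these defaults follow the ROI membership.
ELECTRODE_CONTRASTS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "occipital_vs_parietal": (("O1", "Oz", "O2"), ("P3", "Pz", "P4")),
    "left_vs_right": (("O1", "P3"), ("O2", "P4")),
    "central_vs_peripheral": (("Pz", "Cz"), ("Fpz",)),
}


@dataclass
class AnovaResult:
    table: pd.DataFrame
    dv: str
    n_subjects: dict[str, int]
    n_dropped_subjects: int = 0
    greenhouse_geisser: bool = False

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("effect").loc[name]


def partial_eta_sq(ss_effect: float, ss_error: float) -> float:
    """ss_effect / (ss_effect + ss_error)."""
    if ss_effect < 0 or ss_error < 0:
        raise ValueError("sums of squares must be >= 0")
    if ss_effect == 0 and ss_error == 0:
        raise ValueError("partial eta squared undefined for 0/0")
    return ss_effect / (ss_effect + ss_error)


def _f_row(name, ss_e, df_e, ss_r, df_r):
    ms_e = ss_e / df_e
    ms_r = ss_r / df_r
    f = ms_e / ms_r if ms_r > 0 else (np.inf if ms_e > 0 else 0.0)
    p = float(sstats.f.sf(f, df_e, df_r)) if np.isfinite(f) else 0.0
    return {"effect": name, "ss": ss_e, "df1": df_e, "ss_error": ss_r,
            "df2": df_r, "F": f, "p": p,
            "partial_eta_sq": partial_eta_sq(ss_e, ss_r)
            if (ss_e or ss_r) else 0.0}


def _gg_epsilon(scores: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from subject-level contrast scores
    (subjects x q), computed on the covariance of the scores."""
    q = scores.shape[1]
    if q < 2:
        return 1.0
    s = np.cov(scores, rowvar=False)
    tr = np.trace(s)
    denom = q * np.trace(s @ s)
    if denom <= 0:
        return 1.0
    eps = tr * tr / denom
    return float(min(1.0, max(eps, 1.0 / q)))


def mixed_anova(measures: pd.DataFrame, dv: str = "amplitude",
                greenhouse_geisser: bool = False) -> AnovaResult:
    """Three-factor mixed ANOVA on a peak-measure table.

    ``measures`` needs columns subject, group, experiment, electrode and
    the dependent variable (``amplitude_uv`` or ``latency_ms``; short
    names accepted).  For latency, fallback rows carry NaN and are
    excluded, which may drop subjects listwise.
    """
    col = {"amplitude": "amplitude_uv", "latency": "latency_ms"}.get(dv, dv)
    if col not in measures.columns:
        raise KeyError(f"no column {col!r} in measures table")
    df = measures.dropna(subset=[col]).copy()
    if "fallback" in df.columns and col == "latency_ms":
        df = df[~df["fallback"].astype(bool)]

    b_levels = sorted(df["experiment"].unique())
    c_levels = sorted(df["electrode"].unique())
    b, c = len(b_levels), len(c_levels)
    if b < 2 or c < 2:
        raise ValueError("need >=2 experiments and >=2 electrodes")

    # listwise deletion of subjects with incomplete within cells
    counts = df.groupby("subject")[col].count()
    complete = counts[counts == b * c].index
    n_dropped = int(df["subject"].nunique() - len(complete))
    df = df[df["subject"].isin(complete)]

    group_of = df.groupby("subject")["group"].first()
    groups = sorted(group_of.unique())
    a = len(groups)
    if a < 2:
        raise ValueError("need two groups")

    # per-group data cubes (n_i, b, c)
    cubes = []
    for g in groups:
        subs = sorted(group_of[group_of == g].index)
        if len(subs) < 2:
            raise ValueError(f"fewer than 2 complete subjects in group {g!r}")
        pivot = (df[df["subject"].isin(subs)]
                 .pivot_table(index="subject", columns=["experiment",
                                                        "electrode"],
                              values=col, aggfunc="mean")
                 .reindex(index=subs,
                          columns=pd.MultiIndex.from_product(
                              [b_levels, c_levels])))
        cubes.append(pivot.to_numpy().reshape(len(subs), b, c))

    n_i = np.array([cube.shape[0] for cube in cubes])
    n_total = int(n_i.sum())
    all_y = np.concatenate([cube.reshape(cube.shape[0], -1)
                            for cube in cubes])
    grand = all_y.mean()

    # between-subject stratum
    p_is = [cube.mean(axis=(1, 2)) for cube in cubes]            # subj means
    a_i = np.array([p.mean() for p in p_is])                     # group means
    ss_a = b * c * float(np.sum(n_i * (a_i - grand) ** 2))
    ss_s = b * c * float(sum(((p - m) ** 2).sum()
                             for p, m in zip(p_is, a_i)))

    # experiment stratum
    q_isj = [cube.mean(axis=2) for cube in cubes]                # (n_i, b)
    m_ij = np.stack([q.mean(axis=0) for q in q_isj])             # (a, b)
    mean_j = np.concatenate(q_isj).mean(axis=0)                  # weighted
    ss_b = c * n_total * float(np.sum((mean_j - grand) ** 2))
    ss_ab = c * float(np.sum(
        n_i[:, None] * (m_ij - a_i[:, None] - mean_j[None, :] + grand) ** 2))
    ss_bs = c * float(sum(
        ((q - m[None, :] - p[:, None] + gm) ** 2).sum()
        for q, m, p, gm in zip(q_isj, m_ij, p_is, a_i)))

    # electrode stratum
    r_isk = [cube.mean(axis=1) for cube in cubes]                # (n_i, c)
    m_ik = np.stack([r.mean(axis=0) for r in r_isk])             # (a, c)
    mean_k = np.concatenate(r_isk).mean(axis=0)
    ss_c = b * n_total * float(np.sum((mean_k - grand) ** 2))
    ss_ac = b * float(np.sum(
        n_i[:, None] * (m_ik - a_i[:, None] - mean_k[None, :] + grand) ** 2))
    ss_cs = b * float(sum(
        ((r - m[None, :] - p[:, None] + gm) ** 2).sum()
        for r, m, p, gm in zip(r_isk, m_ik, p_is, a_i)))

    # experiment x electrode stratum
    m_jk = np.mean(np.concatenate(cubes), axis=0)                # (b, c)
    bc_resid = m_jk - mean_j[:, None] - mean_k[None, :] + grand
    ss_bc = n_total * float(np.sum(bc_resid ** 2))
    g_ijk = np.stack([cube.mean(axis=0) for cube in cubes])      # (a, b, c)
    abc_resid = (g_ijk - m_ij[:, :, None] - m_ik[:, None, :]
                 + a_i[:, None, None]) - bc_resid[None, :, :]
    ss_abc = float(np.sum(n_i[:, None, None] * abc_resid ** 2))

    ss_total = float(((all_y - grand) ** 2).sum())
    ss_bcs = ss_total - (ss_a + ss_s + ss_b + ss_ab + ss_bs
                         + ss_c + ss_ac + ss_cs + ss_bc + ss_abc)
    ss_bcs = max(ss_bcs, 0.0)

    df_s = n_total - a
    rows = [
        _f_row("GROUP", ss_a, a - 1, ss_s, df_s),
        _f_row("EXPERIMENT", ss_b, b - 1, ss_bs, (b - 1) * df_s),
        _f_row("GROUP x EXPERIMENT", ss_ab, (a - 1) * (b - 1),
               ss_bs, (b - 1) * df_s),
        _f_row("ELECTRODE", ss_c, c - 1, ss_cs, (c - 1) * df_s),
        _f_row("GROUP x ELECTRODE", ss_ac, (a - 1) * (c - 1),
               ss_cs, (c - 1) * df_s),
        _f_row("EXPERIMENT x ELECTRODE", ss_bc, (b - 1) * (c - 1),
               ss_bcs, (b - 1) * (c - 1) * df_s),
        _f_row("GROUP x EXPERIMENT x ELECTRODE", ss_abc,
               (a - 1) * (b - 1) * (c - 1), ss_bcs,
               (b - 1) * (c - 1) * df_s),
    ]
    table = pd.DataFrame(rows)

    if greenhouse_geisser:
        # epsilon from subject-level contrast scores per within effect
        flat = [cube.reshape(cube.shape[0], b * c) for cube in cubes]
        h_b = _helmert(b)
        h_c = _helmert(c)
        k_b = np.kron(h_b, np.ones((1, c)) / c)
        k_c = np.kron(np.ones((1, b)) / b, h_c)
        k_bc = np.kron(h_b, h_c)
        eps_map = {}
        for eff_names, k in ((("EXPERIMENT", "GROUP x EXPERIMENT"), k_b),
                             (("ELECTRODE", "GROUP x ELECTRODE"), k_c),
                             (("EXPERIMENT x ELECTRODE",
                               "GROUP x EXPERIMENT x ELECTRODE"), k_bc)):
            scores = np.concatenate(
                [(y - y.mean(axis=0)) @ k.T for y in flat])
            eps = _gg_epsilon(scores)
            for name in eff_names:
                eps_map[name] = eps
        table["gg_epsilon"] = [eps_map.get(r, 1.0) for r in table["effect"]]
        table["p_gg"] = [
            float(sstats.f.sf(row.F, row.df1 * row.gg_epsilon,
                              row.df2 * row.gg_epsilon))
            for row in table.itertuples()]

    return AnovaResult(
        table=table, dv=dv,
        n_subjects={g: int(n) for g, n in zip(groups, n_i)},
        n_dropped_subjects=n_dropped,
        greenhouse_geisser=greenhouse_geisser)


def _helmert(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix."""
    h = np.zeros((k - 1, k))
    for i in range(k - 1):
        h[i, :i + 1] = 1.0
        h[i, i + 1] = -(i + 1)
        h[i] /= np.linalg.norm(h[i])
    return h


def wilcoxon_posthoc(a: np.ndarray, b: np.ndarray,
                     ) -> tuple[float, float]:
    """Two-tailed Wilcoxon signed-rank test on paired samples.

    Exact null distribution for n <= 25 nonzero differences, normal
    approximation above.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    nonzero = (a - b) != 0
    n = int(nonzero.sum())
    if n == 0:
        raise ValueError("all differences are zero: no information")
    if n < 5:
        raise ValueError(f"fewer than 5 nonzero differences (n={n})")
    method = "exact" if n <= 25 else "approx"
    res = sstats.wilcoxon(a[nonzero], b[nonzero], zero_method="wilcox",
                          alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def holm_correct(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        val = min(1.0, (m - rank) * p[idx])
        running_max = max(running_max, val)
        adjusted[idx] = running_max
    return adjusted


def report_corrected_pair(raw_p: float, corrected_p: float) -> dict:
    """Carry corrected and uncorrected p side by side (dual reporting)."""
    if corrected_p < raw_p:
        raise ValueError(
            f"corrected p ({corrected_p}) below raw p ({raw_p}): "
            "a multiplicity correction cannot decrease p")
    return {"p_uncorrected": float(raw_p), "p_corrected": float(corrected_p)}


def posthoc_contrast(measures: pd.DataFrame, contrast: str,
                     dv: str = "amplitude") -> tuple[float, float]:
    """Wilcoxon test of a named electrode-pool contrast.

    Per subject, the dependent variable is averaged over experiments and
    over each electrode pool; the two pooled values are compared pairwise
    across subjects.
    """
    col = {"amplitude": "amplitude_uv", "latency": "latency_ms"}.get(dv, dv)
    pool_a, pool_b = ELECTRODE_CONTRASTS[contrast]
    df = measures.dropna(subset=[col])
    mean_a = (df[df["electrode"].isin(pool_a)]
              .groupby("subject")[col].mean())
    mean_b = (df[df["electrode"].isin(pool_b)]
              .groupby("subject")[col].mean())
    common = mean_a.index.intersection(mean_b.index)
    return wilcoxon_posthoc(mean_a[common].to_numpy(),
                            mean_b[common].to_numpy())
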