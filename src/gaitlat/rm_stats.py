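"""Fully within-subject ANOVA with sphericity handling and the
simple-effects decomposition ladder.

The engine implements the univariate repeated-measures ANOVA for balanced,
fully crossed within-subject designs. Every effect is tested against its
own participant-by-effect interaction mean square (so a 2-level effect with
N participants has error df N-1). Effects with two or more numerator df
additionally get Mauchly's sphericity test on the orthonormal-contrast
covariance and the Greenhouse-Geisser epsilon with the correspondingly
adjusted p-value; the adjusted p replaces the uncorrected one for
significance decisions whenever Mauchly rejects.

Decomposition after a significant highest-order interaction follows the
convention common to repeated-measures packages: a simple (or
simple-simple) effect of a factor set E at fixed levels of the remaining
factors is the effect computed on the sliced cell means, tested against
the omnibus error term of E (same MSE and error df for every stratum).
Benjamini-Hochberg adjustment is applied within each decomposition tier's
family. Pairwise paired t-tests among segment levels follow a
simple-simple body-segment effect, with Cohen's d and observed power.

Observed power uses the SPSS/G*Power convention: noncentrality
lambda = F x df1 on the noncentral F distribution.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = [
    "WithinAnova", "AnovaReport", "rm_anova", "decompose_interactions",
    "decompose_two_way", "paired_comparisons", "partial_eta_squared",
    "observed_power", "mauchly_test", "gg_epsilon", "bh_adjust",
    "significance_glyph",
]


# ---------------------------------------------------------------------------
# small shared pieces
# ---------------------------------------------------------------------------

def partial_eta_squared(ss_effect: float, ss_error: float) -> float:
    """SS_effect / (SS_effect + SS_error); NaN when both are zero."""
    if ss_effect < 0 or ss_error < 0:
        raise ValidationError("sums of squares must be non-negative")
    denom = ss_effect + ss_error
    if denom == 0:
        return float("nan")
    return ss_effect / denom


def observed_power(F: float, df1: float, df2: float, alpha: float = 0.05) -> float:
    """Post-hoc power of the F test at noncentrality lambda = F x df1."""
    if F < 0:
        raise ValidationError(f"F must be >= 0, got {F}")
    if not np.isfinite(F):
        return 1.0
    crit = stats.f.isf(alpha, df1, df2)
    nc = F * df1
    if nc < 1e-12:  # scipy's ncf is unreliable at zero noncentrality
        return float(alpha)
    return float(stats.ncf.sf(crit, df1, df2, nc))


def _observed_power_t(t: float, df: float, alpha: float = 0.05) -> float:
    """Two-sided paired-t observed power at delta = observed t."""
    crit = stats.t.isf(alpha / 2, df)
    d = abs(t)
    power = stats.nct.sf(crit, df, d) + stats.nct.cdf(-crit, df, d)
    if not np.isfinite(power):  # scipy's nct overflows at large noncentrality
        return 1.0 if d > crit else 0.0
    return float(power)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def significance_glyph(p: float, alpha: float = 0.05) -> str:
    """ns / # (p<0.10 trend) / * / ** / *** labels used in report tables."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < alpha:
        return "*"
    if p < 0.10:
        return "#"
    return "ns"


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows, each orthogonal to the unit vector."""
    rows = []
    for i in range(1, k):
        v = np.zeros(k)
        v[:i] = 1.0
        v[i] = -float(i)
        rows.append(v / np.linalg.norm(v))
    return np.array(rows).reshape(k - 1, k)


def mauchly_test(contrast_cov: np.ndarray, n_subjects: int):
    """Mauchly's W with its chi-square approximation.

    ``contrast_cov`` is the (k x k) covariance of the orthonormally
    contrast-transformed subject scores. Returns (W, chi2, df, p).
    """
    k = contrast_cov.shape[0]
    if k < 2:
        raise ValidationError("Mauchly's test needs >= 2 contrasts (effect df >= 2)")
    tr = np.trace(contrast_cov)
    det = np.linalg.det(contrast_cov)
    if tr <= 0:
        return float("nan"), float("nan"), k * (k + 1) // 2 - 1, float("nan")
    W = float(det / (tr / k) ** k)
    df = k * (k + 1) // 2 - 1
    n1 = n_subjects - 1
    correction = 1.0 - (2 * k * k + k + 2) / (6.0 * k * n1)
    W_safe = max(W, np.finfo(float).tiny)
    chi2 = float(-n1 * correction * np.log(W_safe))
    p = float(stats.chi2.sf(chi2, df))
    return W, chi2, df, p


def gg_epsilon(contrast_cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from contrast-covariance eigen-structure.

    epsilon = tr(S)^2 / (k tr(S^2)), bounded in [1/k, 1].
    """
    k = contrast_cov.shape[0]
    tr = np.trace(contrast_cov)
    tr2 = np.trace(contrast_cov @ contrast_cov)
    if tr2 <= 0:
        return 1.0
    eps = float(tr * tr / (k * tr2))
    return float(np.clip(eps, 1.0 / k, 1.0))


# ---------------------------------------------------------------------------
# effect algebra on the data cube
# ---------------------------------------------------------------------------

def _effect_arrays(y: np.ndarray) -> dict[frozenset, np.ndarray]:
    """Inclusion-exclusion effect estimates for every axis subset.

    Axis 0 is the subject. Returns, for each subset A of axes, the
    centred effect array (broadcastable against y) such that the arrays
    sum exactly to y and are mutually orthogonal under the balanced
    design.
    """
    axes = tuple(range(y.ndim))
    effects: dict[frozenset, np.ndarray] = {}
    for r in range(len(axes) + 1):
        for subset in itertools.combinations(axes, r):
            A = frozenset(subset)
            others = tuple(ax for ax in axes if ax not in A)
            m = y.mean(axis=others, keepdims=True) if others else y.astype(float)
            e = m.copy()
            for B, eb in effects.items():
                if B < A:
                    e = e - eb
            effects[A] = e
    return effects


def _effect_ss(y: np.ndarray, effects: dict[frozenset, np.ndarray],
               A: frozenset) -> float:
    """Sum of squares for the effect on axis subset A."""
    mult = 1.0
    for ax in range(y.ndim):
        if ax not in A:
            mult *= y.shape[ax]
    return float(mult * np.sum(effects[A] ** 2))


# ---------------------------------------------------------------------------
# the engine
# ---------------------------------------------------------------------------

@dataclass
class AnovaReport:
    """Omnibus table plus the decomposition tiers and a decision trace."""

    response: str
    design: dict
    omnibus: pd.DataFrame
    simple_interactions: pd.DataFrame
    simple_simple: pd.DataFrame
    pairwise: pd.DataFrame
    trace: list[str]
    alpha: float
    n_participants: int


_EMPTY_SIMPLE = pd.DataFrame(columns=[
    "source", "ss", "df1", "df2", "mse", "ms", "F", "p", "p_adj",
    "partial_eta_sq", "glyph"])
_EMPTY_PAIRWISE = pd.DataFrame(columns=[
    "condition", "pair", "t", "df", "p", "p_adj", "cohens_d", "power", "glyph"])


class WithinAnova:
    """Balanced fully-within-subject ANOVA on a (subjects x levels...) cube.

    Parameters
    ----------
    y : ndarray
        Shape (N, n1, ..., nk): one response per participant per cell.
    factors : dict
        Ordered mapping factor name -> tuple of level labels, matching the
        trailing axes of ``y``.
    response : str
        Name of the response variable (reporting only).
    """

    def __init__(self, y: np.ndarray, factors: dict[str, tuple], response: str = "y"):
        y = np.asarray(y, dtype=float)
        if y.ndim != len(factors) + 1:
            raise ValidationError(
                f"y has {y.ndim} axes but {len(factors)} factors were named")
        for ax, (name, levels) in enumerate(factors.items(), start=1):
            if y.shape[ax] != len(levels):
                raise ValidationError(
                    f"factor {name!r} has {len(levels)} levels but axis {ax} "
                    f"has size {y.shape[ax]}")
        if np.isnan(y).any():
            raise ValidationError("response cube contains missing cells")
        self.y = y
        self.factors = {k: tuple(v) for k, v in factors.items()}
        self.names = list(factors)
        self.response = response
        self.n = y.shape[0]
        self._effects = _effect_arrays(y)

    @classmethod
    def from_table(cls, table: pd.DataFrame, dv: str = "value",
                   within: list[str] | None = None, subject: str = "participant",
                   levels: dict[str, tuple] | None = None,
                   response: str | None = None) -> "WithinAnova":
        """Build the cube from a long table (one value per subject per cell)."""
        within = within or ["sw", "sp"]
        levels = levels or {}
        factors = {}
        for f in within:
            factors[f] = tuple(levels.get(f) or
                               pd.unique(table[f]).tolist())
        subjects = pd.unique(table[subject]).tolist()
        shape = (len(subjects),) + tuple(len(v) for v in factors.values())
        y = np.full(shape, np.nan)
        sub_idx = {s: i for i, s in enumerate(subjects)}
        lev_idx = [{lv: i for i, lv in enumerate(v)} for v in factors.values()]
        for _, row in table.iterrows():
            idx = (sub_idx[row[subject]],) + tuple(
                lev_idx[j][row[f]] for j, f in enumerate(within))
            if not np.isnan(y[idx]):
                raise ValidationError(f"duplicate cell for subject {row[subject]!r}")
            y[idx] = row[dv]
        if np.isnan(y).any():
            bad = np.argwhere(np.isnan(y))[0]
            raise ValidationError(
                f"incomplete design: subject {subjects[bad[0]]!r} lacks cell "
                + str({f: list(factors[f])[bad[j + 1]] for j, f in enumerate(within)}))
        return cls(y, factors, response=response or dv)

    # -- internals ---------------------------------------------------------

    def _axes(self, effect: tuple[str, ...]) -> frozenset:
        return frozenset(self.names.index(f) + 1 for f in effect)

    def effect_ss(self, effect: tuple[str, ...]) -> float:
        return _effect_ss(self.y, self._effects, self._axes(effect))

    def error_ss(self, effect: tuple[str, ...]) -> float:
        return _effect_ss(self.y, self._effects, self._axes(effect) | {0})

    def effect_df(self, effect: tuple[str, ...]) -> int:
        d = 1
        for f in effect:
            d *= len(self.factors[f]) - 1
        return d

    def _contrast_cov(self, effect: tuple[str, ...]) -> np.ndarray:
        """Covariance of orthonormal contrast scores for one effect."""
        keep_axes = [0] + sorted(self._axes(effect))
        drop = tuple(ax for ax in range(self.y.ndim) if ax not in keep_axes)
        cells = self.y.mean(axis=drop) if drop else self.y
        cells = cells.reshape(self.n, -1)
        C = np.array([[1.0]])
        # kron in the order the effect factors appear in the cube
        mats = [_orthonormal_contrasts(len(self.factors[f]))
                for f in self.names if f in effect]
        C = mats[0]
        for m in mats[1:]:
            C = np.kron(C, m)
        scores = cells @ C.T
        return np.cov(scores, rowvar=False, ddof=1).reshape(C.shape[0], C.shape[0])

    # -- public tables -----------------------------------------------------

    def omnibus(self, alpha: float = 0.05) -> pd.DataFrame:
        """The full effect table: one row per within effect, ordered mains
        then interactions, with Mauchly/GG columns where applicable."""
        rows = []
        k = len(self.names)
        effect_list = []
        for r in range(1, k + 1):
            effect_list.extend(itertools.combinations(self.names, r))
        tiny = 1e-12 * max(1.0, float(np.sum(self.y ** 2)))
        for effect in effect_list:
            ss = self.effect_ss(effect)
            ss_err = self.error_ss(effect)
            ss = 0.0 if ss < tiny else ss
            ss_err = 0.0 if ss_err < tiny else ss_err
            df1 = self.effect_df(effect)
            df2 = df1 * (self.n - 1)
            ms = ss / df1
            mse = ss_err / df2
            if ss == 0 and ss_err == 0:
                F, p = 0.0, 1.0
            elif mse == 0:
                F, p = float("inf"), 0.0
            else:
                F = ms / mse
                p = float(stats.f.sf(F, df1, df2))
            row = {
                "source": " x ".join(effect), "effect": effect,
                "ss": ss, "df1": df1, "ms": ms,
                "ss_error": ss_err, "df2": df2, "mse": mse,
                "F": F, "p": p,
                "partial_eta_sq": partial_eta_squared(ss, ss_err),
                "power": observed_power(F if np.isfinite(F) else 0.0, df1, df2, alpha)
                if np.isfinite(F) else 1.0,
                "mauchly_w": float("nan"), "mauchly_chi2": float("nan"),
                "mauchly_p": float("nan"), "gg_epsilon": float("nan"),
                "gg_p": float("nan"),
            }
            if df1 >= 2 and self.n - 1 >= 2:
                S = self._contrast_cov(effect)
                W, chi2, mdf, mp = mauchly_test(S, self.n)
                eps = gg_epsilon(S)
                row.update(mauchly_w=W, mauchly_chi2=chi2, mauchly_p=mp,
                           gg_epsilon=eps,
                           gg_p=float(stats.f.sf(F, eps * df1, eps * df2))
                           if np.isfinite(F) else (1.0 if F == 0 else 0.0))
            # GG-corrected p governs when sphericity is rejected
            use_gg = (not np.isnan(row["mauchly_p"])) and row["mauchly_p"] < alpha
            row["p_used"] = row["gg_p"] if use_gg else row["p"]
            row["glyph"] = significance_glyph(row["p_used"], alpha)
            rows.append(row)
        return pd.DataFrame(rows)

    # slice-level sums of squares for the decomposition ladder --------------

    def _slice(self, fixed: dict[str, str]) -> np.ndarray:
        idx: list = [slice(None)] * self.y.ndim
        for f, level in fixed.items():
            idx[self.names.index(f) + 1] = self.factors[f].index(level)
        return self.y[tuple(idx)]

    def simple_effect_ss(self, effect: tuple[str, ...], fixed: dict[str, str]) -> float:
        """SS of ``effect`` computed on the cell means at ``fixed`` levels."""
        ysl = self._slice(fixed)
        remaining = [f for f in self.names if f not in fixed]
        eff = _effect_arrays(ysl)
        axes = frozenset(remaining.index(f) + 1 for f in effect)
        return _effect_ss(ysl, eff, axes)


def rm_anova(table: pd.DataFrame, dv: str = "value",
             within: list[str] | None = None, subject: str = "participant",
             levels: dict[str, tuple] | None = None,
             alpha: float = 0.05) -> pd.DataFrame:
    """Convenience wrapper: long table in, omnibus effect table out."""
    wa = WithinAnova.from_table(table, dv=dv, within=within, subject=subject,
                                levels=levels)
    return wa.omnibus(alpha=alpha)


# ---------------------------------------------------------------------------
# decomposition ladder
# ---------------------------------------------------------------------------

def _simple_row(wa: WithinAnova, effect: tuple[str, ...], fixed: dict[str, str],
                omni: pd.DataFrame) -> dict:
    """One simple-effect test against the omnibus error term of ``effect``."""
    source_effect = " x ".join(effect)
    orow = omni[omni.source == source_effect].iloc[0]
    ss = wa.simple_effect_ss(effect, fixed)
    df1 = wa.effect_df(effect)
    df2 = orow.df2
    mse = orow.mse
    ms = ss / df1
    if mse == 0:
        F, p = (0.0, 1.0) if ss == 0 else (float("inf"), 0.0)
    else:
        F = ms / mse
        p = float(stats.f.sf(F, df1, df2))
    label = " & ".join(fixed[f] for f in wa.names if f in fixed)
    return {
        "source": f"{source_effect} at {label}",
        "effect": effect, "fixed": dict(fixed),
        "ss": ss, "df1": df1, "df2": df2, "ms": ms, "mse": mse,
        "F": F, "p": p,
        "partial_eta_sq": partial_eta_squared(ss, mse * df2),
    }


def decompose_interactions(wa: WithinAnova, alpha: float = 0.05,
                           followup_alpha: float = 0.10,
                           d_variant: str = "av") -> AnovaReport:
    """Three-way omnibus plus the full decomposition ladder.

    Branching: (i) when the highest-order interaction is significant, all
    simple two-way interactions at each level of the third factor are
    tested (BH family = that tier); (ii) each significant simple
    interaction spawns simple-simple main effects of its constituent
    factors at fixed levels of the other two (deduplicated, BH within the
    tier); (iii) a simple-simple effect of a >=3-level factor whose
    adjusted p falls below ``followup_alpha`` (trend included, matching
    reporting practice) triggers pairwise paired t-tests among its levels,
    BH-adjusted within each condition cell.
    """
    if len(wa.names) != 3:
        raise ValidationError("decompose_interactions expects a three-factor design")
    trace: list[str] = []
    omni = wa.omnibus(alpha=alpha)
    three_way = tuple(wa.names)
    orow = omni[omni.source == " x ".join(three_way)].iloc[0]
    simple_df = _EMPTY_SIMPLE.copy()
    ss_df = _EMPTY_SIMPLE.copy()
    pw_df = _EMPTY_PAIRWISE.copy()

    if orow.p_used >= alpha:
        trace.append(
            f"three-way interaction not significant (p={orow.p_used:.4f} >= "
            f"{alpha}); decomposition not triggered")
        return AnovaReport(wa.response, {f: list(v) for f, v in wa.factors.items()},
                           omni, simple_df, ss_df, pw_df, trace, alpha, wa.n)
    trace.append(
        f"three-way interaction significant (p={orow.p_used:.4f} < {alpha}); "
        "testing all simple two-way interactions")

    # tier (i): seven simple interactions
    rows = []
    for pair in itertools.combinations(wa.names, 2):
        other = next(f for f in wa.names if f not in pair)
        for level in wa.factors[other]:
            rows.append(_simple_row(wa, pair, {other: level}, omni))
    simple_df = pd.DataFrame(rows)
    simple_df["p_adj"] = bh_adjust(simple_df["p"])
    simple_df["glyph"] = [significance_glyph(p, alpha) for p in simple_df["p_adj"]]

    # tier (ii): simple-simple main effects from each significant simple
    # interaction, deduplicated across triggers
    ss_rows: dict[str, dict] = {}
    for _, srow in simple_df.iterrows():
        if srow.p_adj >= alpha:
            continue
        f1, f2 = srow.effect
        fixed_level = srow.fixed
        trace.append(f"simple interaction {srow.source} significant "
                     f"(adj p={srow.p_adj:.4f}); testing simple-simple effects")
        for target, across in ((f1, f2), (f2, f1)):
            for level in wa.factors[across]:
                fixed = dict(fixed_level)
                fixed[across] = level
                row = _simple_row(wa, (target,), fixed, omni)
                ss_rows.setdefault(row["source"], row)
    if ss_rows:
        ss_df = pd.DataFrame(list(ss_rows.values()))
        ss_df["p_adj"] = bh_adjust(ss_df["p"])
        ss_df["glyph"] = [significance_glyph(p, alpha) for p in ss_df["p_adj"]]

    # tier (iii): pairwise comparisons among levels of multi-level factors
    pw_rows = []
    if len(ss_df):
        for _, row in ss_df.iterrows():
            (factor,) = row.effect
            if len(wa.factors[factor]) < 3 or row.p_adj >= followup_alpha:
                continue
            trace.append(
                f"simple-simple effect {row.source} (adj p={row.p_adj:.4f} < "
                f"{followup_alpha}); pairwise comparisons among "
                f"{factor} levels")
            pw_rows.extend(_pairwise_cell(wa, factor, row.fixed, alpha, d_variant))
    if pw_rows:
        pw_df = pd.DataFrame(pw_rows)
        pw_df["glyph"] = [significance_glyph(p, alpha) for p in pw_df["p_adj"]]

    return AnovaReport(wa.response, {f: list(v) for f, v in wa.factors.items()},
                       omni, simple_df, ss_df, pw_df, trace, alpha, wa.n)


def _pairwise_cell(wa: WithinAnova, factor: str, fixed: dict[str, str],
                   alpha: float, d_variant: str) -> list[dict]:
    levels = wa.factors[factor]
    cond = " & ".join(fixed[f] for f in wa.names if f in fixed)
    vectors = {}
    for level in levels:
        full = dict(fixed)
        full[factor] = level
        vectors[level] = wa._slice(full)
    pairs = list(itertools.combinations(levels, 2))
    rows = paired_comparisons({p: (vectors[p[0]], vectors[p[1]]) for p in pairs},
                              alpha=alpha, d_variant=d_variant)
    for r in rows:
        r["condition"] = cond
        r["pair"] = f"{r['pair'][0]} vs {r['pair'][1]}"
    return rows


def paired_comparisons(pairs: dict[tuple, tuple[np.ndarray, np.ndarray]],
                       alpha: float = 0.05, d_variant: str = "av") -> list[dict]:
    """Paired t-tests with BH adjustment across the supplied family.

    Cohen's d defaults to d_av — the mean difference divided by the
    average of the two level SDs, sign preserved (A - B); ``d_variant='z'``
    divides by the SD of the differences instead.
    """
    rows = []
    for pair, (a, b) in pairs.items():
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        diff = a - b
        n = len(diff)
        sd_diff = diff.std(ddof=1)
        if sd_diff == 0:
            t, p = (0.0, 1.0) if diff.mean() == 0 else (float("inf"), 0.0)
        else:
            t, p = stats.ttest_rel(a, b)
            t, p = float(t), float(p)
        if d_variant == "av":
            denom = 0.5 * (a.std(ddof=1) + b.std(ddof=1))
        elif d_variant == "z":
            denom = sd_diff
        else:
            raise ValidationError(f"d_variant must be av|z, got {d_variant!r}")
        d = 0.0 if denom == 0 else float(diff.mean() / denom)
        power = (_observed_power_t(t, n - 1, alpha)
                 if np.isfinite(t) else 1.0)
        rows.append({"pair": pair, "t": t, "df": n - 1, "p": p,
                     "cohens_d": d, "power": power})
    padj = bh_adjust([r["p"] for r in rows])
    for r, pa in zip(rows, padj):
        r["p_adj"] = float(pa)
    return rows


def decompose_two_way(wa: WithinAnova, alpha: float = 0.05) -> AnovaReport:
    """Two-way omnibus plus simple main effects after a significant
    interaction (each factor at each level of the other, tested against
    that factor's omnibus error term, BH over the family of four)."""
    if len(wa.names) != 2:
        raise ValidationError("decompose_two_way expects a two-factor design")
    trace: list[str] = []
    omni = wa.omnibus(alpha=alpha)
    inter = omni[omni.source == " x ".join(wa.names)].iloc[0]
    simple_df = _EMPTY_SIMPLE.copy()
    if inter.p_used < alpha:
        trace.append(f"interaction significant (p={inter.p_used:.4f}); "
                     "testing simple main effects")
        rows = []
        f1, f2 = wa.names
        for target, across in ((f1, f2), (f2, f1)):
            for level in wa.factors[across]:
                rows.append(_simple_row(wa, (target,), {across: level}, omni))
        simple_df = pd.DataFrame(rows)
        simple_df["p_adj"] = bh_adjust(simple_df["p"])
        simple_df["glyph"] = [significance_glyph(p, alpha)
                              for p in simple_df["p_adj"]]
    else:
        trace.append(f"interaction not significant (p={inter.p_used:.4f}); "
                     "no simple main effects")
    return AnovaReport(wa.response, {f: list(v) for f, v in wa.factors.items()},
                       omni, simple_df, _EMPTY_SIMPLE.copy(),
                       _EMPTY_PAIRWISE.copy(), trace, alpha, wa.n)
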