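"""Demographic tests and factorial ANCOVAs with Bonferroni post-hocs.

The microstructural analysis fits, separately per index, a fixed-effects
linear model on the long table of (subject x ROI x moment) observations
with factors DISEASE (2) x ROI (11) x FEAT (6 moments), all factor
interactions, and age, disease duration, and EDSS as covariate main
effects.  Morphometry uses the two-way DISEASE x ROI analogue.  Factors
are sum-to-zero coded and each term is tested with a Type III F
(full-versus-reduced residual sum of squares).  Post-hoc disease
contrasts within cells are covariate-adjusted differences of predicted
means, Bonferroni-multiplied by the number of cells in the family.

Observations within a subject are treated as independent rows (no
subject random effect), reproducing the classical factorial design this
analysis style implies; see the methods note for the caveat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ALPHA",
    "two_sample_t",
    "chi_square_2x2",
    "AncovaResult",
    "ancova",
    "posthoc_disease_within",
    "significance_stars",
    "long_table",
    "morphometry_long_table",
]

ALPHA = 0.05
COVARIATES = ("age", "disease_duration", "edss")


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < ALPHA:
        return "*"
    return ""


# --------------------------------------------------------------------------
# demographic tests
# --------------------------------------------------------------------------

def _summary(group):
    """(mean, sd, n) from raw values or a summary triple."""
    if isinstance(group, tuple) and len(group) == 3:
        return float(group[0]), float(group[1]), int(group[2])
    arr = np.asarray(group, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1)), arr.size


def two_sample_t(group_a, group_b):
    """Pooled-variance unpaired two-sample t-test.

    Accepts raw value arrays or ``(mean, sd, n)`` summaries, so printed
    demographic tables can be checked directly.

    Returns (t, df, p).
    """
    m1, s1, n1 = _summary(group_a)
    m2, s2, n2 = _summary(group_b)
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    df = n1 + n2 - 2
    pooled = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    if pooled == 0.0:
        # degenerate: identical constants -> no evidence; distinct -> certain
        return (0.0, df, 1.0) if m1 == m2 else (np.inf, df, 0.0)
    res = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    return float(res.statistic), df, float(res.pvalue)


def chi_square_2x2(counts):
    """Pearson chi-square on a 2x2 table, no continuity correction.

    Returns (chi2, df, p).
    """
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2) or (table < 0).any() or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be a 2x2 table of non-negative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


# --------------------------------------------------------------------------
# sum-to-zero factor encoding
# --------------------------------------------------------------------------

class _Encoder:
    """Sum-to-zero design-matrix builder for a factorial-plus-covariates model."""

    def __init__(self, factors: dict[str, list], covariates=COVARIATES):
        self.factors = {name: list(levels) for name, levels in factors.items()}
        self.covariates = tuple(covariates)
        names = list(self.factors)
        self.terms: list[tuple[str, ...]] = [(n,) for n in names]
        if len(names) >= 2:
            from itertools import combinations
            for k in range(2, len(names) + 1):
                self.terms.extend(combinations(names, k))

    def _factor_block(self, name: str, values) -> np.ndarray:
        levels = self.factors[name]
        values = np.asarray(values)
        k = len(levels)
        block = np.zeros((values.size, k - 1))
        for i, lev in enumerate(levels[:-1]):
            block[values == lev, i] = 1.0
        block[values == levels[-1], :] = -1.0
        return block

    def term_block(self, term: tuple[str, ...], df: pd.DataFrame) -> np.ndarray:
        blocks = [self._factor_block(name, df[name]) for name in term]
        out = blocks[0]
        for b in blocks[1:]:
            out = (out[:, :, None] * b[:, None, :]).reshape(len(df), -1)
        return out

    def design(self, df: pd.DataFrame):
        """Full design matrix, plus the column slice of every term."""
        cols = [np.ones((len(df), 1))]
        slices: dict[str, slice] = {}
        start = 1
        for cov in self.covariates:
            cols.append(df[cov].to_numpy(dtype=float)[:, None])
            slices[cov] = slice(start, start + 1)
            start += 1
        for term in self.terms:
            block = self.term_block(term, df)
            cols.append(block)
            name = ":".join(term)
            slices[name] = slice(start, start + block.shape[1])
            start += block.shape[1]
        return np.hstack(cols), slices

    def row(self, levels: dict[str, str], covariate_values: dict[str, float]) -> np.ndarray:
        """One encoded prediction row at given factor levels / covariates."""
        df = pd.DataFrame([{**levels, **covariate_values}])
        x, _ = self.design(df)
        return x[0]


@dataclass
class AncovaResult:
    """Fitted factorial ANCOVA: effect table plus everything post-hocs need."""

    effects: pd.DataFrame        # term, F, df_num, df_den, p
    design: str                  # "three_way" | "two_way"
    encoder: _Encoder
    beta: np.ndarray
    xtx_inv: np.ndarray
    sigma2: float
    df_resid: int
    covariate_means: dict[str, float]
    posthoc: pd.DataFrame | None = None


def _check_cells(df: pd.DataFrame, factor_names):
    sizes = df.groupby(list(factor_names), observed=True).size()
    full = 1
    for name in factor_names:
        full *= df[name].nunique()
    if len(sizes) < full or (sizes < 1).any():
        present = set(sizes.index if len(factor_names) > 1 else [(i,) for i in sizes.index])
        import itertools
        levels = [sorted(df[n].unique()) for n in factor_names]
        for cell in itertools.product(*levels):
            if cell not in present:
                raise ValueError(f"empty design cell {dict(zip(factor_names, cell))}")


def ancova(long: pd.DataFrame, design: str = "three_way") -> AncovaResult:
    """Type III factorial ANCOVA on a long table.

    ``long`` needs columns ``value``, ``disease``, ``roi`` (plus ``feat``
    for the three-way design) and the covariates ``age``,
    ``disease_duration``, ``edss``.
    """
    if design == "three_way":
        factor_names = ("disease", "roi", "feat")
    elif design == "two_way":
        factor_names = ("disease", "roi")
    else:
        raise ValueError(f"unknown design {design!r}")
    for col in ("value", *factor_names, *COVARIATES):
        if col not in long.columns:
            raise ValueError(f"long table is missing column {col!r}")
    _check_cells(long, factor_names)

    cov = long[list(COVARIATES)].to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(long)), cov])) < 1 + len(COVARIATES):
        raise ValueError("collinear covariates")

    factors = {n: sorted(long[n].unique()) for n in factor_names}
    enc = _Encoder(factors)
    x, slices = enc.design(long)
    y = long["value"].to_numpy(dtype=float)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient design matrix")

    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    rss_full = float(resid @ resid)
    df_resid = len(long) - x.shape[1]
    sigma2 = rss_full / df_resid

    rows = []
    tested = [*COVARIATES, *(":".join(t) for t in enc.terms)]
    for name in tested:
        sl = slices[name]
        keep = np.ones(x.shape[1], dtype=bool)
        keep[sl] = False
        xr = x[:, keep]
        br, _, _, _ = np.linalg.lstsq(xr, y, rcond=None)
        rss_r = float(np.sum((y - xr @ br) ** 2))
        df_num = sl.stop - sl.start
        f = ((rss_r - rss_full) / df_num) / sigma2
        p = float(sps.f.sf(f, df_num, df_resid))
        rows.append({"term": name, "F": f, "df_num": df_num,
                     "df_den": df_resid, "p": p,
                     "stars": significance_stars(p)})
    effects = pd.DataFrame(rows)
    xtx_inv = np.linalg.inv(x.T @ x)
    cov_means = {c: float(long[c].mean()) for c in COVARIATES}
    return AncovaResult(effects=effects, design=design, encoder=enc, beta=beta,
                        xtx_inv=xtx_inv, sigma2=sigma2, df_resid=df_resid,
                        covariate_means=cov_means)


def posthoc_disease_within(result: AncovaResult) -> pd.DataFrame:
    """Covariate-adjusted disease contrasts within each ROI (x FEAT) cell.

    The Bonferroni multiplier is the number of cells in the family: the
    full ROI x FEAT grid for the three-way design, the ROI list for the
    two-way design.  The contrast sign is PPMS minus RRMS.
    """
    if result is None or not isinstance(result, AncovaResult):
        raise ValueError("posthoc requires a fitted ancova result")
    enc = result.encoder
    diseases = enc.factors["disease"]
    if set(diseases) != {"PPMS", "RRMS"}:
        raise ValueError("disease factor must have levels PPMS and RRMS")
    cell_factors = [n for n in enc.factors if n != "disease"]
    import itertools
    grids = [enc.factors[n] for n in cell_factors]
    cells = list(itertools.product(*grids))
    n_cells = len(cells)
    rows = []
    for cell in cells:
        levels = dict(zip(cell_factors, cell))
        x_p = enc.row({"disease": "PPMS", **levels}, result.covariate_means)
        x_r = enc.row({"disease": "RRMS", **levels}, result.covariate_means)
        contrast = x_p - x_r
        diff = float(contrast @ result.beta)
        se = float(np.sqrt(result.sigma2 * contrast @ result.xtx_inv @ contrast))
        t = diff / se
        p_raw = 2.0 * float(sps.t.sf(abs(t), result.df_resid))
        p_adj = min(1.0, p_raw * n_cells)
        rows.append({
            "contrast": "PPMS-RRMS within " + ", ".join(f"{k}={v}" for k, v in levels.items()),
            **levels,
            "difference": diff, "se": se, "t": t,
            "p_raw": p_raw, "p_bonf": p_adj,
            "significant": p_adj < ALPHA,
            "stars": significance_stars(p_adj),
        })
    table = pd.DataFrame(rows)
    result.posthoc = table
    return table


# --------------------------------------------------------------------------
# long-table constructors
# --------------------------------------------------------------------------

def long_table(table, index: str) -> pd.DataFrame:
    """Long (subject x ROI x moment) rows for one microstructural index."""
    from .cohort import ROIS
    from .features import MOMENT_NAMES

    rows = []
    for _, rec in table.data.iterrows():
        for roi in ROIS:
            for moment in MOMENT_NAMES:
                rows.append({
                    "subject_id": rec["subject_id"], "disease": rec["group"],
                    "roi": roi, "feat": moment,
                    "value": rec[f"{index}_{moment}_{roi}"],
                    "age": rec["age"], "disease_duration": rec["disease_duration"],
                    "edss": rec["edss"],
                })
    return pd.DataFrame(rows)


def morphometry_long_table(table, kind: str) -> pd.DataFrame:
    """Long (subject x ROI) rows for 'volume' or 'thickness' morphometry."""
    from .cohort import CORTICAL_ROIS, SUBCORTICAL_ROIS

    if kind == "volume":
        rois, prefix = SUBCORTICAL_ROIS, "vol"
    elif kind == "thickness":
        rois, prefix = CORTICAL_ROIS, "thick"
    else:
        raise ValueError(f"kind must be 'volume' or 'thickness', got {kind!r}")
    rows = []
    for _, rec in table.data.iterrows():
        for roi in rois:
            rows.append({
                "subject_id": rec["subject_id"], "disease": rec["group"],
                "roi": roi, "value": rec[f"{prefix}_{roi}"],
                "age": rec["age"], "disease_duration": rec["disease_duration"],
                "edss": rec["edss"],
            })
    return pd.DataFrame(rows)
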