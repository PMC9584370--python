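"""Cohort I/O, summary statistics, and the two-group comparison panel.

A cohort is a pandas DataFrame with one row per patient (see
``REQUIRED_COLUMNS``/``OPTIONAL_COLUMNS`` for the canonical schema).
Group comparisons follow a fixed variable→test mapping: unpaired t-test
for approximately normal variables (age, IOP, time since surgery),
Fisher's exact test for counts, and the Mann-Whitney U test for skewed
variables (visual field MD, volumes, height); associations are Spearman
rank correlations.  Each variable is tested separately at α = 0.05 with
no multiplicity adjustment.

The hypothesis tests are delegated to scipy.stats behind this module's
interface; the exact-vs-approximate policies (enumeration for small
untied Mann-Whitney samples, permutation p-values for small Spearman
samples) are fixed here so results are reproducible across scipy
versions.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, SchemaError

__all__ = [
    "GroupComparison",
    "read_cohort",
    "write_cohort",
    "median_iqr",
    "mann_whitney",
    "fisher_exact",
    "unpaired_t",
    "spearman",
    "compare_groups",
    "comparisons_to_frame",
]

logger = logging.getLogger("blebquant")

REQUIRED_COLUMNS = ("diplopia", "volume_total")
OPTIONAL_COLUMNS = (
    "id", "eye", "age", "sex", "volume_inner", "volume_outer", "volume_plate",
    "height", "merged", "large_bleb", "md_study", "md_fellow",
    "iop_pre", "iop_6wk", "iop_3mo", "iop_mri",
    "restricted", "restriction_total", "strands_visible", "extra_fluid",
    "surgical_technique", "time_since_surgery",
)

_VOLUME_COLUMNS = ("volume_inner", "volume_outer", "volume_plate", "volume_total", "height")

#: Exact Mann-Whitney enumeration is used up to this combined sample size.
_MW_EXACT_MAX_N = 20
#: Exact Spearman permutation p-values are used up to this sample size.
_SPEARMAN_EXACT_MAX_N = 9


@dataclass
class GroupComparison:
    """One row of the comparison panel."""

    variable: str
    summary_a: str              # diplopia group
    summary_b: str              # control group
    test: str                   # "t", "fisher", "mann-whitney", "spearman"
    statistic: float
    p_value: float
    method: str = ""            # exact / asymptotic / pooled / welch ...
    extra: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1 or math.isnan(self.p_value)):
            raise ParameterError(f"p-value {self.p_value} outside [0, 1]")


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------


def _load_mapping(mapping) -> Optional[Dict[str, str]]:
    if mapping is None or isinstance(mapping, dict):
        return mapping
    path = Path(mapping)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


def read_cohort(path, mapping=None) -> pd.DataFrame:
    """Load and validate a per-patient cohort table (CSV or XLSX).

    ``mapping`` renames native column headers to the canonical schema;
    it may be a dict or a path to a JSON/YAML sidecar.  Unmapped extra
    columns are kept but reported.  Rows violating row-level invariants
    (negative volumes, inconsistent totals) are dropped with a logged
    message rather than failing the whole load.

    Raises
    ------
    SchemaError
        listing the mandatory columns that are absent after mapping.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    rename = _load_mapping(mapping)
    if rename:
        df = df.rename(columns=rename)

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file lacks mandatory columns: {missing}")
    unknown = [c for c in df.columns if c not in REQUIRED_COLUMNS + OPTIONAL_COLUMNS]
    if unknown:
        logger.info("read_cohort: unmapped columns kept as-is: %s", unknown)

    df["diplopia"] = df["diplopia"].astype(bool)
    keep = pd.Series(True, index=df.index)
    for col in _VOLUME_COLUMNS:
        if col in df.columns:
            bad = df[col].notna() & (pd.to_numeric(df[col], errors="coerce") < 0)
            for i in df.index[bad]:
                logger.warning("read_cohort: row %s rejected: %s = %s < 0", i, col, df.at[i, col])
            keep &= ~bad
    parts = [c for c in ("volume_inner", "volume_outer", "volume_plate") if c in df.columns]
    if len(parts) == 3:
        tot = pd.to_numeric(df["volume_total"], errors="coerce")
        psum = sum(pd.to_numeric(df[c], errors="coerce") for c in parts)
        bad = tot.notna() & psum.notna() & ((tot - psum).abs() > 0.05 * tot.abs() + 1.0)
        for i in df.index[bad]:
            logger.warning("read_cohort: row %s rejected: parts sum %.1f != total %.1f",
                           i, psum[i], tot[i])
        keep &= ~bad
    return df[keep].reset_index(drop=True)


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort as CSV or XLSX depending on the file suffix."""
    path = Path(path)
    if path.suffix.lower() == ".xlsx":
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False)


# --------------------------------------------------------------------------
# summaries and tests
# --------------------------------------------------------------------------


def median_iqr(values: Sequence[float]) -> Tuple[float, float, float]:
    """Median and quartiles (inclusive linear interpolation).

    Quartiles interpolate linearly between order statistics (the same
    rule as ``numpy.quantile``'s default), so a single value yields
    ``(x, x, x)``.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ParameterError("median_iqr needs at least one finite value")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
    return float(med), float(q1), float(q3)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float, str]:
    """Two-sided Mann-Whitney U test.

    Exact p by enumeration when the combined sample is ≤ 20 without
    ties; otherwise the normal approximation with tie and continuity
    corrections.  Returns ``(U, p, method)`` with U for the first
    sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("mann_whitney needs two non-empty samples")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        logger.warning("mann_whitney: all values identical; p = 1")
        return float(a.size * b.size / 2), 1.0, "degenerate"
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= _MW_EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue), method


def fisher_exact(table: Sequence[Sequence[int]]) -> Tuple[float, float]:
    """Two-sided Fisher exact test on a 2×2 count table.

    The p-value sums all hypergeometric tables (fixed margins) whose
    probability does not exceed the observed table's.  Returns
    ``(odds_ratio, p)``.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ParameterError("fisher_exact needs a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t < 0) or not np.allclose(t, np.round(t)):
            raise ParameterError("fisher_exact needs nonnegative integer counts")
        t = t.astype(int)
    res = stats.fisher_exact(t, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def unpaired_t(a: Sequence[float], b: Sequence[float], welch: bool = False) -> Tuple[float, float, str]:
    """Two-sided unpaired t-test (pooled variance; Welch by flag).

    Returns ``(t, p, method)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("unpaired_t needs at least two values per group")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ParameterError("unpaired_t degenerate: zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue), "welch" if welch else "pooled"


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, observed_r: float) -> float:
    """Permutation p-value: share of rank pairings with |r| ≥ |observed|."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    perms = np.array(list(itertools.permutations(ry)))  # (n!, n)
    rx_c = rx - rx.mean()
    pc = perms - ry.mean()
    num = pc @ rx_c
    den = np.sqrt((rx_c @ rx_c) * (pc * pc).sum(axis=1))
    r = num / den
    return float(np.mean(np.abs(r) >= abs(observed_r) - 1e-12))


def spearman(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float, str]:
    """Spearman rank correlation with two-sided p.

    Ties receive average ranks; r_s is the Pearson correlation of the
    ranks.  For n ≤ 9 the p-value is exact by permutation of the ranks,
    otherwise the t-distribution approximation.  Returns
    ``(r_s, p, method)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ParameterError("spearman needs equal-length samples of size >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ParameterError("spearman undefined for a constant sample")
    rs = float(np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1])
    if x.size <= _SPEARMAN_EXACT_MAX_N:
        return rs, _spearman_exact_p(x, y, rs), "exact"
    if abs(rs) >= 1.0:
        return rs, 0.0, "t-approx"
    n = x.size
    t = rs * math.sqrt((n - 2) / (1 - rs * rs))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return rs, float(p), "t-approx"


# --------------------------------------------------------------------------
# the comparison panel
# --------------------------------------------------------------------------


def _mean_sd(v: pd.Series) -> str:
    v = v.dropna()
    return f"{v.mean():.1f} ± {v.std(ddof=1):.1f}" if len(v) else "—"


def _med_iqr(v: pd.Series) -> str:
    v = v.dropna()
    if not len(v):
        return "—"
    med, q1, q3 = median_iqr(v.to_numpy())
    return f"{med:.1f} ({q1:.1f}–{q3:.1f})"


def _n_pct(v: pd.Series) -> str:
    v = v.dropna().astype(bool)
    return f"{int(v.sum())} ({100 * v.mean():.0f}%)" if len(v) else "—"


# variable -> (test, summary formatter); the paper's fixed mapping
_T_VARS = ("age", "iop_pre", "iop_6wk", "iop_3mo", "iop_mri", "time_since_surgery")
_MW_VARS = ("md_study", "md_fellow", "volume_total", "volume_outer", "volume_inner", "height")
_FISHER_VARS = ("sex", "eye", "surgical_technique", "restricted", "strands_visible",
                "extra_fluid", "large_bleb", "merged")
_CORR_PAIRS = (
    ("diplopia", "volume_total"),
    ("diplopia", "height"),
    ("restriction_total", "volume_total"),
    ("volume_total", "iop_pre"), ("volume_total", "iop_6wk"),
    ("volume_total", "iop_3mo"), ("volume_total", "iop_mri"),
    ("height", "iop_pre"), ("height", "iop_6wk"),
    ("height", "iop_3mo"), ("height", "iop_mri"),
)


def compare_groups(cohort: pd.DataFrame) -> List[GroupComparison]:
    """Emit the full baseline + morphometry comparison panel.

    Rows cover the demographic variables (t-test or Fisher), the skewed
    clinical and morphometric variables (Mann-Whitney), and the Spearman
    correlations of diplopia/restriction/IOP with the morphometry.
    Variables absent from the cohort are skipped with a warning.  The
    output is invariant to the row order of the input table.
    """
    if "diplopia" not in cohort.columns:
        raise SchemaError("cohort lacks the 'diplopia' group label")
    cohort = cohort.sort_index(axis=1)
    ga = cohort[cohort["diplopia"].astype(bool)]
    gb = cohort[~cohort["diplopia"].astype(bool)]
    out: List[GroupComparison] = []

    def _skip(var: str) -> bool:
        if var not in cohort.columns:
            logger.warning("compare_groups: variable '%s' absent; row skipped", var)
            return True
        return False

    for var in _T_VARS:
        if _skip(var):
            continue
        t, p, method = unpaired_t(ga[var].dropna(), gb[var].dropna())
        out.append(GroupComparison(var, _mean_sd(ga[var]), _mean_sd(gb[var]),
                                   "t", t, p, method))
    for var in _FISHER_VARS:
        if _skip(var):
            continue
        a = ga[var].dropna()
        b = gb[var].dropna()
        if a.dtype == object:  # dichotomize on the most common level
            levels = sorted(cohort[var].dropna().unique())
            if len(levels) != 2:
                logger.warning("compare_groups: '%s' not dichotomous; row skipped", var)
                continue
            a = a == levels[0]
            b = b == levels[0]
        table = [[int(a.astype(bool).sum()), int((~a.astype(bool)).sum())],
                 [int(b.astype(bool).sum()), int((~b.astype(bool)).sum())]]
        orr, p = fisher_exact(table)
        out.append(GroupComparison(var, _n_pct(a), _n_pct(b), "fisher", orr, p, "exact"))
    for var in _MW_VARS:
        if _skip(var):
            continue
        u, p, method = mann_whitney(ga[var].dropna(), gb[var].dropna())
        out.append(GroupComparison(var, _med_iqr(ga[var]), _med_iqr(gb[var]),
                                   "mann-whitney", u, p, method))
    for xv, yv in _CORR_PAIRS:
        if _skip(xv) or _skip(yv):
            continue
        pair = cohort[[xv, yv]].dropna()
        x = pair[xv].astype(float) if pair[xv].dtype != object else pair[xv]
        rs, p, method = spearman(np.asarray(x, dtype=float),
                                 pair[yv].to_numpy(dtype=float))
        out.append(GroupComparison(f"spearman[{xv}~{yv}]", "", "", "spearman",
                                   rs, p, method))
    return out


def comparisons_to_frame(comparisons: List[GroupComparison]) -> pd.DataFrame:
    """Comparison panel as a DataFrame (for CSV export / display)."""
    return pd.DataFrame([{
        "variable": c.variable,
        "diplopia": c.summary_a,
        "control": c.summary_b,
        "test": c.test,
        "statistic": c.statistic,
        "p_value": c.p_value,
        "method": c.method,
    } for c in comparisons])
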