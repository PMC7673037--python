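"""Condition-level summaries and inference for per-cell granule counts.

Summaries follow standard high-content reporting: percentage of
stress-granule-positive cells, mean granules per positive cell, and mean
granule intensity (a size proxy), each with SEM over replicates.  Inference on
per-cell counts uses a negative-binomial regression (log link, condition as
covariate, shared dispersion), the standard choice for overdispersed count
data (variance mu + mu**2/k); replicate-level comparisons use Welch t-tests
with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "ConditionSummary",
    "NBFit",
    "summarize_condition",
    "fit_negative_binomial",
    "replicate_ttest_fdr",
]

#: dispersion reported when counts show no overdispersion (Poisson limit)
K_UPPER_BOUND = 1e8


@dataclass
class ConditionSummary:
    condition: str
    n_fields: int
    n_cells: int
    pct_cells_with_sgs: float
    mean_sgs_per_positive_cell: float | None  # None when no cell is positive
    mean_sg_intensity: float | None
    replicate_pct: pd.Series
    sem_pct: float


@dataclass
class NBFit:
    mu: dict[str, float]  # fitted mean per condition
    k: float  # shared dispersion (variance = mu + mu^2/k)
    beta: dict[str, float]  # log-scale contrasts vs the reference condition
    se: dict[str, float]
    wald_z: dict[str, float]
    p_value: dict[str, float]
    poisson_limit: bool
    note: str = ""


def summarize_condition(
    cells: pd.DataFrame,
    condition: str,
    sg_intensity: pd.Series | None = None,
    replicate_col: str = "replicate",
) -> ConditionSummary:
    """Summarize one condition's cell table.

    ``cells`` needs columns cell_label, sg_count, sg_positive, field and the
    replicate column.  ``sg_intensity`` is an optional per-granule integrated
    intensity series.  SEM is computed over replicate-level percentages.
    Fields with zero cells are skipped with a warning.
    """
    if len(cells) == 0:
        raise ValueError("no cells to summarize")
    sizes = cells.groupby("field").size()
    empty = sizes[sizes == 0]
    if len(empty):
        log.warning("skipping %d empty fields", len(empty))
        cells = cells[~cells["field"].isin(empty.index)]

    n_cells = len(cells)
    n_pos = int(cells["sg_positive"].sum())
    pct = 100.0 * n_pos / n_cells
    pos = cells[cells["sg_positive"]]
    mean_per_pos = float(pos["sg_count"].mean()) if len(pos) else None
    mean_int = float(sg_intensity.mean()) if sg_intensity is not None and len(sg_intensity) else None

    rep_pct = cells.groupby(replicate_col).apply(
        lambda g: 100.0 * g["sg_positive"].sum() / len(g), include_groups=False
    )
    sem = float(rep_pct.std(ddof=1) / np.sqrt(len(rep_pct))) if len(rep_pct) > 1 else float("nan")
    return ConditionSummary(
        condition=condition,
        n_fields=cells["field"].nunique(),
        n_cells=n_cells,
        pct_cells_with_sgs=pct,
        mean_sgs_per_positive_cell=mean_per_pos,
        mean_sg_intensity=mean_int,
        replicate_pct=rep_pct,
        sem_pct=sem,
    )


def fit_negative_binomial(counts: np.ndarray, conditions: np.ndarray | None = None) -> NBFit:
    """Maximum-likelihood NB2 regression of per-cell counts on condition.

    Log link with treatment coding against the first condition (sorted order);
    a single dispersion k is shared across conditions.  Wald z-tests are
    reported per contrast.  When the counts show no overdispersion the model
    degenerates to Poisson: k is reported at an upper bound with a note.
    """
    import statsmodels.api as sm

    counts = np.asarray(counts, dtype=np.float64)
    if counts.size == 0:
        raise ValueError("no counts")
    if np.any(counts < 0) or np.any(counts != np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    if not counts.any():
        raise ValueError("all counts are zero; nothing to model")

    if conditions is None:
        conditions = np.repeat("all", counts.size)
    conditions = np.asarray(conditions, dtype=object)
    levels = sorted(set(conditions.tolist()))
    ref = levels[0]
    exog = np.column_stack(
        [np.ones(counts.size)] + [(conditions == lev).astype(float) for lev in levels[1:]]
    )
    names = ["intercept"] + [f"{lev}_vs_{ref}" for lev in levels[1:]]

    overdispersed = counts.var(ddof=1) > counts.mean()
    if overdispersed:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.NegativeBinomial(counts, exog, loglike_method="nb2")
            try:
                res = model.fit(disp=0, maxiter=200)
            except Exception:  # fall back to a derivative-free optimizer
                res = model.fit(disp=0, maxiter=2000, method="nm")
        alpha = float(res.params[-1])
        if alpha > 1e-6:
            params = res.params[:-1]
            bse = res.bse[:-1]
            k = 1.0 / alpha
            note = ""
            poisson_limit = False
        else:
            overdispersed = False
    if not overdispersed:
        res = sm.GLM(counts, exog, family=sm.families.Poisson()).fit()
        params = res.params
        bse = res.bse
        k = K_UPPER_BOUND
        note = "no overdispersion detected; dispersion at upper bound (Poisson limit)"
        poisson_limit = True
        log.info(note)

    beta = dict(zip(names, np.asarray(params, dtype=float)))
    se = dict(zip(names, np.asarray(bse, dtype=float)))
    wald = {n: beta[n] / se[n] if se[n] > 0 else np.nan for n in names}
    pvals = {n: float(2 * sps.norm.sf(abs(wald[n]))) for n in names}
    mu = {}
    for lev in levels:
        eta = beta["intercept"] + (beta.get(f"{lev}_vs_{ref}", 0.0) if lev != ref else 0.0)
        mu[lev] = float(np.exp(eta))
    contrast_names = names[1:]
    return NBFit(
        mu=mu,
        k=float(k),
        beta={n: beta[n] for n in contrast_names},
        se={n: se[n] for n in contrast_names},
        wald_z={n: float(wald[n]) for n in contrast_names},
        p_value={n: pvals[n] for n in contrast_names},
        poisson_limit=poisson_limit,
        note=note,
    )


def replicate_ttest_fdr(
    comparisons: dict[str, tuple[np.ndarray, np.ndarray]],
    q_star: float = 0.01,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Unpaired t-tests (Welch by default) with Benjamini-Hochberg adjustment.

    ``comparisons`` maps a comparison name to the two groups of replicate-level
    values.  Returns one row per comparison with t, p, BH q and a significance
    flag at ``q_star``.  Degenerate groups (zero variance with n = 2) still get
    a p-value but trigger a warning.
    """
    rows = []
    for name, (a, b) in comparisons.items():
        a = np.asarray(a, dtype=np.float64)
        b = np.asarray(b, dtype=np.float64)
        if a.size < 2 or b.size < 2:
            raise ValueError(f"{name}: need >= 2 replicates per group")
        if (a.std(ddof=1) == 0 or b.std(ddof=1) == 0) and min(a.size, b.size) <= 2:
            log.warning("%s: zero-variance group with n=2; p-value is degenerate", name)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t, p = sps.ttest_ind(a, b, equal_var=equal_var)
        if np.isnan(p):  # both groups constant and equal
            t, p = 0.0, 1.0
        rows.append((name, float(t), float(p)))
    df = pd.DataFrame(rows, columns=["comparison", "t", "p"])
    _, q, _, _ = multipletests(df["p"].to_numpy(), method="fdr_bh")
    df["q"] = q
    df["significant"] = df["q"] <= q_star
    return df
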