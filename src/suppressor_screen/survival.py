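"""Bulk-cohort replication: correlation with a bulk cytotoxicity score and
survival cut-point scanning.

The Kaplan-Meier product-limit estimator and the Mantel-Cox log-rank test
are implemented from scratch here (they are the statistical core of the
cut-point scan); the scan tries every observed expression value that leaves
at least a minimum fraction of samples on each side as a low/high split,
takes the minimum log-rank p, and Bonferroni-corrects by the number of
cutoffs actually tried. Because splits depend only on expression ranks, the
corrected p is invariant under strictly monotone transforms of expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from suppressor_screen.io import SurvivalCohort
from suppressor_screen.simulate import CYTOTOX_GENES


# ---------------------------------------------------------------------------
# Bulk cytotoxicity score and candidate replication
# ---------------------------------------------------------------------------


def bulk_cytotox_score(
    expression: pd.DataFrame, gene_set: Sequence[str] = CYTOTOX_GENES
) -> pd.Series:
    """Mean over score genes of per-gene z-scored log2(1+expression).

    Binned-control scoring is undefined for a 7-gene signature on bulk
    profiles, so the bulk score uses the standard z-mean construction.
    Genes constant across samples contribute 0 (with a warning).
    """
    missing = [g for g in gene_set if g not in expression.index]
    if missing:
        raise KeyError(f"score genes absent from cohort: {missing}")
    logx = np.log2(1.0 + expression.loc[list(gene_set)].astype(float))
    mu = logx.mean(axis=1)
    sd = logx.std(axis=1, ddof=0)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"constant score genes contribute 0: {list(logx.index[const])}",
            stacklevel=2,
        )
        sd = sd.mask(const, 1.0)
    z = logx.sub(mu, axis=0).div(sd, axis=0)
    return z.mean(axis=0)


def replicate_candidates(
    cohorts: Sequence[SurvivalCohort],
    candidate_genes: Sequence[str],
    alpha: float = 0.05,
    gene_set: Sequence[str] = CYTOTOX_GENES,
) -> pd.DataFrame:
    """Per gene per cohort: Pearson r of log2(1+expr) against the bulk score.

    ``replicated`` requires r < 0 and p < alpha in every cohort where the
    gene is present, with at least two cohorts contributing.
    """
    if not cohorts:
        raise ValueError("need at least one cohort")
    columns = ["gene", "cohort", "r", "pvalue", "n", "passes", "missing", "replicated"]
    if not list(candidate_genes):
        return pd.DataFrame(columns=columns)
    rows = []
    scores = [bulk_cytotox_score(c.expression, gene_set) for c in cohorts]
    for gene in candidate_genes:
        for ci, c in enumerate(cohorts):
            if gene not in c.expression.index:
                rows.append(
                    {"gene": gene, "cohort": c.name, "r": np.nan, "pvalue": np.nan,
                     "n": c.n_samples, "passes": False, "missing": True}
                )
                continue
            x = np.log2(1.0 + c.expression.loc[gene].astype(float).to_numpy())
            y = scores[ci].to_numpy()
            if np.ptp(x) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(x, y)
            passes = bool(r < 0 and p < alpha) if np.isfinite(r) else False
            rows.append(
                {"gene": gene, "cohort": c.name, "r": r, "pvalue": p,
                 "n": c.n_samples, "passes": passes, "missing": False}
            )
        # replication verdict is attached to every row of the gene below
    df = pd.DataFrame(rows)
    verdicts = {}
    for gene, grp in df.groupby("gene"):
        present = grp[~grp["missing"]]
        verdicts[gene] = bool(
            len(present) >= 2 and present["passes"].all()
        )
    df["replicated"] = df["gene"].map(verdicts)
    return df


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank, from scratch
# ---------------------------------------------------------------------------


def km_curve(time: np.ndarray, event: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit survival estimate with right censoring.

    Returns (event_times, S) where S[i] is the survival probability just
    after event_times[i]. At tied times deaths are processed before
    censorings (censored subjects at t remain in the risk set for t).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("empty sample")
    order = np.argsort(time, kind="stable")
    t_sorted, e_sorted = time[order], event[order]
    uniq = np.unique(t_sorted[e_sorted == 1])
    n = time.size
    times, surv = [], []
    s = 1.0
    for t in uniq:
        at_risk = np.sum(t_sorted >= t)
        deaths = np.sum((t_sorted == t) & (e_sorted == 1))
        s *= 1.0 - deaths / at_risk
        times.append(t)
        surv.append(s)
    return np.asarray(times), np.asarray(surv)


def logrank(
    time_a: np.ndarray,
    event_a: np.ndarray,
    time_b: np.ndarray,
    event_b: np.ndarray,
) -> tuple[float, float]:
    """Mantel-Cox log-rank statistic, (O-E)^2/V, with chi-square(1) p."""
    ta = np.asarray(time_a, dtype=float)
    tb = np.asarray(time_b, dtype=float)
    ea = np.asarray(event_a, dtype=int)
    eb = np.asarray(event_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        warnings.warn("no events in either group: chi2=0, p=1", stacklevel=2)
        return (0.0, 1.0)

    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    # risk-set sizes: number with time >= t, via searchsorted on sorted times
    ta_s, tb_s = np.sort(ta), np.sort(tb)
    n1 = ta.size - np.searchsorted(ta_s, event_times, side="left")
    n2 = tb.size - np.searchsorted(tb_s, event_times, side="left")
    dta_s = np.sort(ta[ea == 1])
    dtb_s = np.sort(tb[eb == 1])
    d1 = np.searchsorted(dta_s, event_times, side="right") - np.searchsorted(
        dta_s, event_times, side="left"
    )
    d2 = np.searchsorted(dtb_s, event_times, side="right") - np.searchsorted(
        dtb_s, event_times, side="left"
    )
    nj = n1 + n2
    dj = d1 + d2
    O1 = d1.sum()
    E1 = np.sum(dj * n1 / nj)
    ok = nj > 1
    V = np.sum(
        dj[ok] * (n1[ok] / nj[ok]) * (1 - n1[ok] / nj[ok]) * (nj[ok] - dj[ok]) / (nj[ok] - 1)
    )
    if V <= 0:
        warnings.warn("zero log-rank variance: chi2=0, p=1", stacklevel=2)
        return (0.0, 1.0)
    chi2 = float((O1 - E1) ** 2 / V)
    return (chi2, float(stats.chi2.sf(chi2, df=1)))


# ---------------------------------------------------------------------------
# Cut-point scan
# ---------------------------------------------------------------------------


@dataclass
class ScanResult:
    gene: str
    endpoint: str
    cutoff: float
    n_low: int
    n_high: int
    chi2: float
    p_raw: float
    p_bonferroni: float
    n_cutoffs_tested: int
    direction: str  # which group has worse survival: "high" or "low"


def kaplan_scan(
    expression_gene: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    min_group_frac: float = 0.10,
    gene: str = "",
    endpoint: str = "EFS",
) -> ScanResult:
    """Exhaustive expression cut-point scan with Bonferroni correction.

    Every observed expression value leaving at least
    ``ceil(min_group_frac * n)`` samples in both the "<= cutoff" and the
    "> cutoff" group is tried; the cutoff with the smallest raw log-rank p
    wins (ties broken toward the smaller cutoff) and the raw p is multiplied
    by the number of cutoffs tried.
    """
    x = np.asarray(expression_gene, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = x.size
    if n < 20:
        raise ValueError(f"cut-point scan needs n >= 20, have {n}")
    if np.ptp(x) == 0:
        raise ValueError("constant expression: no cut-point exists")
    m = int(np.ceil(min_group_frac * n))
    values = np.unique(x)
    n_low_arr = np.searchsorted(np.sort(x), values, side="right")
    admissible = values[(n_low_arr >= m) & (n - n_low_arr >= m)]
    if admissible.size == 0:
        raise ValueError("no admissible cutoff under min_group_frac")

    best = None
    for v in admissible:  # ascending, so strict '<' keeps the smaller cutoff
        low = x <= v
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chi2, p = logrank(time[low], event[low], time[~low], event[~low])
        if best is None or p < best[1]:
            best = (v, p, chi2, int(low.sum()))
    cutoff, p_raw, chi2, n_low = best

    low = x <= cutoff
    # direction: compare observed vs expected events in the high group
    et = np.unique(time[event == 1])
    th_s = np.sort(time[~low])
    tl_s = np.sort(time[low])
    n_hi_risk = th_s.size - np.searchsorted(th_s, et, side="left")
    n_lo_risk = tl_s.size - np.searchsorted(tl_s, et, side="left")
    d_hi = np.array([np.sum((time[~low] == t) & (event[~low] == 1)) for t in et])
    d_all = np.array([np.sum((time == t) & (event == 1)) for t in et])
    with np.errstate(invalid="ignore", divide="ignore"):
        e_hi = np.nansum(d_all * n_hi_risk / (n_hi_risk + n_lo_risk))
    direction = "high" if d_hi.sum() > e_hi else "low"

    return ScanResult(
        gene=gene,
        endpoint=endpoint,
        cutoff=float(cutoff),
        n_low=n_low,
        n_high=n - n_low,
        chi2=float(chi2),
        p_raw=float(p_raw),
        p_bonferroni=float(min(1.0, p_raw * admissible.size)),
        n_cutoffs_tested=int(admissible.size),
        direction=direction,
    )


def scan_cohort(
    cohort: SurvivalCohort,
    genes: Sequence[str],
    min_group_frac: float = 0.10,
) -> pd.DataFrame:
    """Run :func:`kaplan_scan` for each gene present in the cohort."""
    rows = []
    for gene in genes:
        if gene not in cohort.expression.index:
            continue
        res = kaplan_scan(
            cohort.expression.loc[gene].to_numpy(),
            cohort.time,
            cohort.event,
            min_group_frac=min_group_frac,
            gene=gene,
            endpoint=cohort.endpoint,
        )
        rows.append(
            {
                "gene": res.gene, "cohort": cohort.name, "endpoint": res.endpoint,
                "cutoff": res.cutoff, "n_low": res.n_low, "n_high": res.n_high,
                "chi2": res.chi2, "p_raw": res.p_raw,
                "p_bonferroni": res.p_bonferroni,
                "n_cutoffs_tested": res.n_cutoffs_tested,
                "direction": res.direction,
            }
        )
    return pd.DataFrame(rows)
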