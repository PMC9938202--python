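"""Cohort statistics: quartile phenotyping, Kruskal-Wallis, Spearman + BH.

Animals, not cells, are the statistical unit throughout: imaging data
from the fields of one animal are summed first and group statistics are
computed over animal-level values.

* :func:`phenotype_quartiles` classifies a cohort into High drinkers
  (HD, upper quartile of the mean water intake over the final three
  sessions), Low drinkers (LD, lower quartile) and intermediates.
* :func:`kruskal_wallis` compares animal-level values across groups
  (mid-ranks, tie correction, chi-square approximation), with optional
  pairwise 2-group follow-ups.
* :func:`spearman_bh` builds session x metric Spearman correlation
  matrices with Benjamini-Hochberg (step-up FDR) correction applied
  over all cells of one matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BehaviorTable",
    "PhenotypeAssignment",
    "KruskalResult",
    "CorrelationMatrix",
    "phenotype_quartiles",
    "kruskal_wallis",
    "pairwise_kruskal",
    "spearman_bh",
]


@dataclass
class BehaviorTable:
    """Animal x session water intake (mL).

    ``intake`` is a DataFrame indexed by animal_id with integer session
    columns 1..n (contiguous).  The first ``baseline_sessions`` columns
    are baseline; the phenotyping statistic is the mean over the last
    ``final_window`` sessions.  ``planted_escalators`` is ground-truth
    metadata carried by the synthetic generator (None for real data).
    """

    intake: pd.DataFrame
    baseline_sessions: int = 2
    final_window: int = 3
    planted_escalators: list[str] | None = None

    def __post_init__(self) -> None:
        if (self.intake.to_numpy() < 0).any():
            raise ValueError("intakes must be >= 0")
        sessions = list(self.intake.columns)
        if sessions != list(range(sessions[0], sessions[0] + len(sessions))):
            raise ValueError("sessions must be contiguous")

    @property
    def sessions(self) -> list[int]:
        return list(self.intake.columns)

    @property
    def n_animals(self) -> int:
        return len(self.intake)

    def final_mean(self) -> pd.Series:
        """Mean intake over the final window, per animal."""
        return self.intake.iloc[:, -self.final_window :].mean(axis=1)

    def earlier_mean(self) -> pd.Series:
        """Mean intake over all sessions before the final window."""
        return self.intake.iloc[:, : -self.final_window].mean(axis=1)


@dataclass
class PhenotypeAssignment:
    """Animal -> {HD, LD, intermediate} with the selection statistic."""

    phenotype: pd.Series  # animal_id -> label
    statistic: pd.Series  # animal_id -> final-window mean intake

    @property
    def hd(self) -> list[str]:
        return sorted(self.phenotype.index[self.phenotype == "HD"])

    @property
    def ld(self) -> list[str]:
        return sorted(self.phenotype.index[self.phenotype == "LD"])

    @property
    def intermediate(self) -> list[str]:
        return sorted(self.phenotype.index[self.phenotype == "intermediate"])


def phenotype_quartiles(behavior: BehaviorTable, quartile_size: int | None = None) -> PhenotypeAssignment:
    """Upper/lower-quartile phenotyping on the final-window mean intake.

    The top floor(N/4) animals are HD, the bottom floor(N/4) LD, the
    rest intermediate.  Ties at a quartile boundary are broken by the
    earlier-session mean, then by animal_id (ascending), so the
    assignment is deterministic and permutation-invariant.
    """
    n = behavior.n_animals
    if n < 4:
        raise ValueError("quartile phenotyping requires at least 4 animals")
    k = quartile_size if quartile_size is not None else n // 4
    stat = behavior.final_mean()
    earlier = behavior.earlier_mean()
    # mergesort is stable; pre-sorting by animal_id gives the last tie-break
    order = (
        pd.DataFrame({"final": stat, "earlier": earlier})
        .sort_index()
        .sort_values(["final", "earlier"], kind="mergesort")
    )
    labels = pd.Series("intermediate", index=stat.index, name="phenotype")
    if k > 0:
        labels[order.index[:k]] = "LD"
        labels[order.index[-k:]] = "HD"
    return PhenotypeAssignment(phenotype=labels, statistic=stat)


@dataclass
class KruskalResult:
    H: float
    df: int
    p: float
    degenerate: bool = False


def kruskal_wallis(*groups) -> KruskalResult:
    """Kruskal-Wallis H on mid-ranks with tie correction.

    ``df = k - 1``; p from the chi-square approximation.  If every
    observation is identical the statistic is returned as H = 0 with a
    degenerate flag (the tie-corrected formula is 0/0 there).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return KruskalResult(H=0.0, df=len(groups) - 1, p=1.0, degenerate=True)
    H, p = sps.kruskal(*groups)
    return KruskalResult(H=float(H), df=len(groups) - 1, p=float(p))


def pairwise_kruskal(groups: dict[str, "np.ndarray | list"], bh: bool = False) -> pd.DataFrame:
    """All pairwise 2-group Kruskal-Wallis contrasts.

    Contrasts are unadjusted by default; ``bh=True`` adds BH-adjusted
    q-values over the family of contrasts.
    """
    names = list(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            res = kruskal_wallis(groups[a], groups[b])
            rows.append({"group_a": a, "group_b": b, "H": res.H, "p": res.p})
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "H", "p"])
    if bh and len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


@dataclass
class CorrelationMatrix:
    """Session x metric Spearman correlations with BH correction.

    ``r``, ``p``, ``q`` and ``significant`` are DataFrames indexed by
    session with one column per metric.  Cells with an undefined
    correlation (constant vector) are NaN and excluded from the BH
    family; the family is all defined cells of this one matrix.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    significant: pd.DataFrame
    alpha: float = 0.05
    n_obs: pd.DataFrame = field(default=None)  # type: ignore[assignment]


def spearman_bh(
    drinking: pd.DataFrame,
    metrics: pd.DataFrame,
    alpha: float = 0.05,
    min_pairs: int = 4,
) -> CorrelationMatrix:
    """Correlate per-session drinking with animal-level metrics.

    ``drinking``: animals x sessions (mL); ``metrics``: animals x
    metric columns.  For every (session, metric) cell, Spearman r is
    computed over the animals present in both tables (mid-ranks for
    ties, two-sided p).  BH step-up q-values are computed over all
    defined cells of the matrix; ``significant`` flags BH rejections at
    ``alpha``.
    """
    animals = drinking.index.intersection(metrics.index)
    if len(animals) < min_pairs:
        raise ValueError(f"need at least {min_pairs} paired animals")
    drinking = drinking.loc[animals]
    metrics = metrics.loc[animals]

    sessions = list(drinking.columns)
    cols = list(metrics.columns)
    r = pd.DataFrame(np.nan, index=sessions, columns=cols, dtype=float)
    p = r.copy()
    nobs = pd.DataFrame(0, index=sessions, columns=cols, dtype=int)

    for s in sessions:
        x_all = drinking[s]
        for m in cols:
            pair = pd.concat([x_all, metrics[m]], axis=1).dropna()
            if len(pair) < min_pairs:
                continue
            x = pair.iloc[:, 0].to_numpy()
            y = pair.iloc[:, 1].to_numpy()
            nobs.loc[s, m] = len(pair)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue  # correlation undefined; cell stays NaN
            rho, pval = sps.spearmanr(x, y)
            r.loc[s, m] = rho
            p.loc[s, m] = pval

    q = p.copy()
    sig = pd.DataFrame(False, index=sessions, columns=cols)
    flat_p = p.to_numpy().ravel()
    defined = ~np.isnan(flat_p)
    if defined.any():
        reject, qvals, _, _ = multipletests(flat_p[defined], alpha=alpha, method="fdr_bh")
        flat_q = np.full_like(flat_p, np.nan)
        flat_q[defined] = qvals
        flat_sig = np.zeros_like(flat_p, dtype=bool)
        flat_sig[defined] = reject
        q = pd.DataFrame(flat_q.reshape(p.shape), index=sessions, columns=cols)
        sig = pd.DataFrame(flat_sig.reshape(p.shape), index=sessions, columns=cols)
    return CorrelationMatrix(r=r, p=p, q=q, significant=sig, alpha=alpha, n_obs=nobs)
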