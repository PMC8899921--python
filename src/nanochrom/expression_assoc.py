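"""TPM computation and CRE-expression association tests.

Genes are classified active/silent by a TPM threshold (default: active
iff TPM > 1, a common convention the threshold of which is exposed), and
the association between 5' CRE presence and expression is tested two
ways: a Mann-Whitney rank test on the TPM values of CRE+ vs CRE- genes,
and Fisher's exact test on the active/silent x CRE+/CRE- 2x2 table.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .genome_io import ExpressionRecord

logger = logging.getLogger(__name__)


def tpm_from_counts(records: Sequence[ExpressionRecord]) -> list[ExpressionRecord]:
    """Fill TPM from raw counts and effective lengths.

    ``tpm_i = 1e6 * (c_i / l_i) / sum_j (c_j / l_j)``; a table of all-zero
    counts yields all-zero TPM rather than a division error.
    """
    for r in records:
        if r.count is None or r.effective_length is None:
            raise ValueError(f"gene {r.gene_id}: count/effective_length missing")
        if r.effective_length <= 0:
            raise ValueError(f"gene {r.gene_id}: nonpositive effective length")
        if r.count < 0:
            raise ValueError(f"gene {r.gene_id}: negative count")
    rpk = np.array([r.count / r.effective_length for r in records])
    denom = rpk.sum()
    tpm = 1e6 * rpk / denom if denom > 0 else np.zeros_like(rpk)
    return [replace(r, tpm=float(t)) for r, t in zip(records, tpm)]


def classify_active(tpm: float, threshold: float = 1.0) -> str:
    """'active' iff TPM strictly exceeds the threshold, else 'silent'."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    if tpm < 0:
        raise ValueError("TPM must be nonnegative")
    return "active" if tpm > threshold else "silent"


def rank_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (U reported for sample x).

    Exact permutation distribution when the smaller group has <= 8
    observations and there are no ties; tie-corrected normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (min(len(x), len(y)) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Fisher's exact test for a 2x2 table of nonnegative integer counts.

    The odds ratio is the sample odds ratio ``n11*n22 / (n12*n21)`` (inf
    when only the denominator is zero, NaN for 0/0); the two-sided p-value
    sums hypergeometric probabilities no larger than that of the observed
    table, conditioning on the margins.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("table entries must be nonnegative")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("table entries must be integers")
        t = np.round(t).astype(int)
    n11, n12 = int(t[0, 0]), int(t[0, 1])
    n21, n22 = int(t[1, 0]), int(t[1, 1])

    num, den = n11 * n22, n12 * n21
    if den > 0:
        odds = num / den
    else:
        odds = np.inf if num > 0 else np.nan

    N = n11 + n12 + n21 + n22
    if N == 0:
        return odds, 1.0
    r1 = n11 + n12  # row-1 margin
    c1 = n11 + n21  # column-1 margin
    support = np.arange(max(0, r1 + c1 - N), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, N, c1, r1)
    p_obs = stats.hypergeom.pmf(n11, N, c1, r1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-12)].sum())
    if p > 1.0 - 1e-12:  # full-support sums carry float round-off
        p = 1.0
    return odds, min(p, 1.0)


@dataclass
class AssociationReport:
    n_cre_pos: int
    n_cre_neg: int
    pct_active_cre_pos: Optional[float]
    pct_active_cre_neg: Optional[float]
    u_statistic: Optional[float]
    p_rank: Optional[float]
    odds_ratio: Optional[float]
    p_fisher: Optional[float]
    table: Optional[np.ndarray] = None  # rows CRE+/CRE-, cols active/silent
    note: Optional[str] = None


def cre_expression_report(
    presence: Mapping[str, bool],
    expression: Sequence[ExpressionRecord],
    threshold: float = 1.0,
) -> AssociationReport:
    """Test whether 5' CRE presence associates with gene expression.

    ``presence`` maps gene id -> CRE+/CRE-.  Genes absent from the
    expression table are treated as unexpressed (TPM 0) and logged.  The
    report carries both the rank test on TPM and Fisher's exact test on
    the active/silent x CRE+/CRE- table.
    """
    if any(r.tpm is None for r in expression):
        expression = tpm_from_counts(list(expression))
    tpm_by_gene = {r.gene_id: r.tpm for r in expression}
    missing = [g for g in presence if g not in tpm_by_gene]
    if missing:
        logger.info(
            "cre_expression_report: %d gene(s) missing from the expression table, "
            "treated as TPM 0",
            len(missing),
        )
    tpm_pos = [tpm_by_gene.get(g, 0.0) for g, has in presence.items() if has]
    tpm_neg = [tpm_by_gene.get(g, 0.0) for g, has in presence.items() if not has]
    n_pos, n_neg = len(tpm_pos), len(tpm_neg)

    def pct_active(vals):
        if not vals:
            return None
        return 100.0 * np.mean([classify_active(t, threshold) == "active" for t in vals])

    pct_pos, pct_neg = pct_active(tpm_pos), pct_active(tpm_neg)
    if n_pos == 0 or n_neg == 0:
        return AssociationReport(
            n_cre_pos=n_pos,
            n_cre_neg=n_neg,
            pct_active_cre_pos=pct_pos,
            pct_active_cre_neg=pct_neg,
            u_statistic=None,
            p_rank=None,
            odds_ratio=None,
            p_fisher=None,
            note="one CRE class is empty; tests not performed",
        )
    u, p_rank = rank_test(tpm_pos, tpm_neg)
    act_pos = round(pct_pos / 100.0 * n_pos)
    act_neg = round(pct_neg / 100.0 * n_neg)
    table = np.array([[act_pos, n_pos - act_pos], [act_neg, n_neg - act_neg]])
    odds, p_fisher = fisher_exact_2x2(table)
    return AssociationReport(
        n_cre_pos=n_pos,
        n_cre_neg=n_neg,
        pct_active_cre_pos=pct_pos,
        pct_active_cre_neg=pct_neg,
        u_statistic=u,
        p_rank=p_rank,
        odds_ratio=odds,
        p_fisher=p_fisher,
        table=table,
    )
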