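"""Published 99-knee agreement data between grading methods.

Cross-tabulations of tibial AORI grades from a 99-patient revision-TKA
cohort: intraoperative grading (rows) against preoperative 3D-CT grading and
against preoperative radiograph grading (columns). Grades are on the ordinal
scale I = 1, IIa = 2, IIb = 3, III = 4. These counts parameterize the default
cohort simulator and serve as the packaged end-to-end fixture for the
agreement statistics.
"""

from __future__ import annotations

import numpy as np

GRADE_LEVELS = (1, 2, 3, 4)

#: intraoperative (rows) x preoperative 3D-CT (columns)
INTRAOP_CT_COUNTS = np.array(
    [
        [21, 0, 0, 0],
        [1, 23, 3, 2],
        [6, 7, 17, 5],
        [0, 1, 0, 13],
    ],
    dtype=int,
)

#: intraoperative (rows) x preoperative X-ray (columns)
INTRAOP_XRAY_COUNTS = np.array(
    [
        [20, 1, 0, 0],
        [14, 10, 3, 2],
        [15, 11, 5, 4],
        [1, 2, 0, 11],
    ],
    dtype=int,
)


def pairs_from_counts(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct the per-knee (row_grade, col_grade) vectors from a table."""
    counts = np.asarray(counts, dtype=int)
    a, b = [], []
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            a.extend([GRADE_LEVELS[i]] * counts[i, j])
            b.extend([GRADE_LEVELS[j]] * counts[i, j])
    return np.array(a), np.array(b)


def intraop_distribution() -> np.ndarray:
    """Relative frequency of intraoperative grades (21, 29, 35, 14 of 99)."""
    margin = INTRAOP_CT_COUNTS.sum(axis=1)
    return margin / margin.sum()


def ct_confusion() -> np.ndarray:
    """Row-stochastic P(CT grade | intraoperative grade)."""
    t = INTRAOP_CT_COUNTS.astype(float)
    return t / t.sum(axis=1, keepdims=True)


def xray_confusion() -> np.ndarray:
    """Row-stochastic P(X-ray grade | intraoperative grade)."""
    t = INTRAOP_XRAY_COUNTS.astype(float)
    return t / t.sum(axis=1, keepdims=True)


def agreement_report() -> dict:
    """Run the full agreement analysis on the packaged 99-knee counts.

    Returns kappa (with interpretation and p), tie-corrected Spearman
    correlation, ordinal median/IQR per method, and the percentage of
    intraoperative IIb defects each preoperative method predicted correctly.
    """
    from . import stats as ts

    out: dict = {}
    for method, counts in (("ct", INTRAOP_CT_COUNTS), ("xray", INTRAOP_XRAY_COUNTS)):
        table = ts.ContingencyTable(counts)
        agree = ts.cohens_kappa(table)
        a, b = table.to_pairs()
        rho, p_rho = ts.spearman_tied(a, b)
        iib = GRADE_LEVELS.index(3)
        out[method] = {
            "kappa": round(agree.kappa, 3),
            "interpretation": agree.interpretation,
            "kappa_p": agree.p_value,
            "spearman": round(rho, 2),
            "spearman_p": p_rho,
            "correct_iib_pct": round(100.0 * counts[iib, iib] / counts[iib].sum(), 1),
            "median_iqr": ts.ordinal_median_iqr(b),
        }
    intraop = np.repeat(GRADE_LEVELS, INTRAOP_CT_COUNTS.sum(axis=1))
    out["intraop"] = {"median_iqr": ts.ordinal_median_iqr(intraop)}
    return out
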