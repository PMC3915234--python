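"""Reference-based cell-composition estimation and adjustment.

Whole-blood methylation is a mixture over leukocyte subtypes, and smoking
shifts leukocyte proportions, so composition is a classic confounder of
smoking EWAS. Proportions are estimated per sample by projecting its
betas at composition-discriminating CpGs onto reference per-cell-type
profiles under simplex constraints (non-negative, sum-to-one least
squares), and methylation is adjusted by residualising M-values on the
estimated proportions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = ["validate_reference", "estimate_proportions", "adjust_for_composition"]

# weight of the sum-to-one constraint row in the augmented least-squares
# system; large relative to betas (O(1)) so the constraint is effectively
# hard before the final exact renormalisation.
_SUM_WEIGHT = 1000.0


def validate_reference(reference: pd.DataFrame) -> pd.DataFrame:
    """Check a cell reference (discriminating probes x cell types)."""
    if reference.shape[1] < 2:
        raise ValueError("need at least 2 cell types")
    values = reference.values
    if np.any((values <= 0) | (values >= 1)):
        raise ValueError("reference betas must lie in (0, 1)")
    rank = np.linalg.matrix_rank(values)
    if rank < reference.shape[1]:
        corr = np.corrcoef(values.T)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.abs(corr).argmax(), corr.shape)
        raise ValueError(
            "reference profiles are rank-deficient; cell types "
            f"{reference.columns[i]!r} and {reference.columns[j]!r} are collinear"
        )
    return reference


def estimate_proportions(beta: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Per-sample cell-type proportions on the simplex.

    Solves, for each sample, min ||A p - b||_2 subject to p >= 0 and
    sum(p) = 1, where A holds the reference betas at the discriminating
    probes and b the sample's betas there. The sum constraint is imposed
    as a heavily weighted row in the least-squares system solved by NNLS,
    followed by exact renormalisation.

    Returns a DataFrame (samples x cell types) whose rows sum to 1.
    """
    validate_reference(reference)
    missing = reference.index.difference(beta.index)
    if len(missing):
        raise ValueError(
            f"{len(missing)} discriminating probe(s) absent from the beta matrix "
            f"(e.g. {missing[:3].tolist()}); did they survive QC?"
        )
    A = reference.values
    aug = np.vstack([A, _SUM_WEIGHT * np.ones(A.shape[1])])
    B = beta.loc[reference.index].values
    out = np.empty((B.shape[1], A.shape[1]))
    for s in range(B.shape[1]):
        b_aug = np.append(B[:, s], _SUM_WEIGHT)
        x, _ = nnls(aug, b_aug)
        total = x.sum()
        if total <= 0:  # impossible: the constraint row forces mass
            raise RuntimeError("degenerate NNLS solution with zero total")
        out[s] = x / total
    props = pd.DataFrame(out, index=beta.columns, columns=reference.columns)
    assert np.allclose(props.sum(axis=1), 1.0, atol=1e-9)
    return props


def adjust_for_composition(m_matrix: pd.DataFrame, proportions: pd.DataFrame) -> pd.DataFrame:
    """Residualise M-values on cell proportions, preserving probe means.

    Per probe, M is regressed on the proportions (one reference cell type
    dropped to avoid the simplex collinearity) and the residuals are
    returned with the probe's grand mean added back. If proportions do not
    vary across samples the adjustment is a no-op (with a warning).
    """
    props = proportions.loc[m_matrix.columns]
    P = props.values[:, :-1]  # drop last type: simplex rows are collinear
    if np.allclose(props.values.std(axis=0), 0.0, atol=1e-12):
        warnings.warn("cell proportions are constant across samples; "
                      "composition adjustment is a no-op", stacklevel=2)
        return m_matrix.copy()
    n = P.shape[0]
    X = np.column_stack([np.ones(n), P])
    Y = m_matrix.values.T  # samples x probes
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    grand = m_matrix.values.mean(axis=1)
    out = resid.T + grand[:, None]
    return pd.DataFrame(out, index=m_matrix.index, columns=m_matrix.columns)
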