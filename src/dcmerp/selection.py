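"""Bayesian model selection: Laplace log-evidence and fixed-effects group BMS.

Under the fixed-effects assumption every subject expresses the same model,
so group evidence is the sum of per-subject log evidences; posterior model
probabilities are the softmax of the summed log evidences (log-sum-exp
stabilized, since the sums are large in magnitude).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .inversion import PosteriorEstimate

__all__ = ["log_evidence", "fixed_effects_bms", "evidence_table"]


def log_evidence(posterior: PosteriorEstimate) -> float:
    """Model log-evidence approximation: the final free energy (nats)."""
    if not posterior.converged:
        warnings.warn("posterior did not converge; evidence may be unreliable",
                      RuntimeWarning, stacklevel=2)
    return float(posterior.final_free_energy)


def evidence_table(evidences: dict[str, list[float]],
                   subjects: list[str] | None = None) -> pd.DataFrame:
    """Subjects x models table of log evidences (nats)."""
    df = pd.DataFrame(evidences)
    if subjects is not None:
        df.index = pd.Index(subjects, name="subject")
    else:
        df.index = pd.Index([f"sub{i + 1:02d}" for i in range(len(df))], name="subject")
    return df


def fixed_effects_bms(table: pd.DataFrame) -> dict:
    """Fixed-effects group BMS from a subjects x models log-evidence table.

    Returns summed log evidences per model and posterior model probabilities
    (uniform model prior).  Probabilities are invariant to adding a constant
    to all log evidences and sum to one.
    """
    table = pd.DataFrame(table)
    if table.shape[0] < 1 or table.shape[1] < 2:
        raise ValueError("need at least 1 subject and 2 models")
    if not np.all(np.isfinite(table.to_numpy(dtype=float))):
        raise ValueError("log evidences must be finite")
    sums = table.sum(axis=0)
    shifted = sums - sums.max()
    prob = np.exp(shifted) / np.exp(shifted).sum()
    return {
        "summed_log_evidence": sums.to_dict(),
        "posterior_probability": prob.to_dict(),
        "winning_model": str(sums.idxmax()),
    }
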