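"""Assessment metrics for ddG regression: PCC, RMSE, antisymmetry.

PCC is the Pearson correlation between experimental and predicted ddG;
RMSE is the root mean squared prediction error in kcal/mol.  The
antisymmetry diagnostics follow the established direct/inverse
benchmark convention: the correlation between direct predictions and
the negated predictions for the reverse mutations (1.0 for a perfectly
antisymmetric predictor), and the mean of (direct + inverse)/2 as a
bias in kcal/mol (0 for a perfectly antisymmetric predictor).

Degenerate inputs (zero variance) raise a typed error rather than
returning NaN, which would silently propagate into reports.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import scipy.stats

from .errors import DegenerateInputError, EmptyInputError, ShapeError


def _paired_arrays(a: Sequence[float], b: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(a, dtype=float).ravel()
    y = np.asarray(b, dtype=float).ravel()
    if x.shape != y.shape:
        raise ShapeError(f"paired inputs differ in length: {x.size} vs {y.size}")
    if x.size == 0:
        raise EmptyInputError("empty value lists")
    return x, y


def pearson(experimental: Sequence[float], predicted: Sequence[float]) -> float:
    """Pearson correlation coefficient between paired value lists.

    Requires n >= 2 and nonzero variance in both lists; otherwise a
    :class:`DegenerateInputError` is raised.
    """
    x, y = _paired_arrays(experimental, predicted)
    if x.size < 2:
        raise DegenerateInputError("Pearson correlation needs at least 2 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("Pearson correlation undefined for zero-variance input")
    return float(scipy.stats.pearsonr(x, y).statistic)


def rmse(experimental: Sequence[float], predicted: Sequence[float]) -> float:
    """Root mean squared difference between paired lists (kcal/mol)."""
    x, y = _paired_arrays(experimental, predicted)
    return float(np.sqrt(np.mean((y - x) ** 2)))


def antisymmetry_metrics(
    pred_direct: Sequence[float], pred_inverse: Sequence[float]
) -> dict:
    """Direct/inverse antisymmetry diagnostics.

    ``pred_inverse[i]`` must be the prediction for the reverse of
    mutation i.  Returns ``r_dir_inv`` = pearson(direct, -inverse) and
    ``bias`` = mean((direct + inverse)/2) in kcal/mol.
    """
    d, v = _paired_arrays(pred_direct, pred_inverse)
    return {
        "r_dir_inv": pearson(d, -v),
        "bias": float(np.mean((d + v) / 2.0)),
    }


@dataclass
class EvaluationReport:
    """PCC, RMSE and optional antisymmetry metrics for one prediction set."""

    n: int
    pcc: float
    rmse: float
    antisymmetry: Optional[dict] = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2) + "\n"

    def to_tsv(self, header: bool = True) -> str:
        """One-line TSV (n, pcc, rmse, r_dir_inv, bias) for cross-method tables."""
        anti = self.antisymmetry or {}
        cols = ["n", "pcc", "rmse", "r_dir_inv", "bias"]
        vals = [
            str(self.n),
            f"{self.pcc:.6f}",
            f"{self.rmse:.6f}",
            f"{anti['r_dir_inv']:.6f}" if "r_dir_inv" in anti else "NA",
            f"{anti['bias']:.6g}" if "bias" in anti else "NA",
        ]
        lines = []
        if header:
            lines.append("\t".join(cols))
        lines.append("\t".join(vals))
        return "\n".join(lines) + "\n"


def evaluate(
    experimental: Sequence[float],
    predicted: Sequence[float],
    pred_inverse: Optional[Sequence[float]] = None,
) -> EvaluationReport:
    """Bundle PCC and RMSE (and antisymmetry, if inverse predictions given)."""
    x, y = _paired_arrays(experimental, predicted)
    anti = antisymmetry_metrics(y, pred_inverse) if pred_inverse is not None else None
    return EvaluationReport(n=int(x.size), pcc=pearson(x, y), rmse=rmse(x, y), antisymmetry=anti)


def coefficient_correlations(named_vectors: Mapping[str, Sequence[float]]) -> "pd.DataFrame":
    """Pairwise Pearson correlations among residue-coefficient vectors.

    Used to compare fitted residue coefficients across base methods and
    against fixed hydrophobicity/solvation scales.  All vectors must be
    length 20 and residue-aligned (alphabetical one-letter order).
    Returns a symmetric DataFrame with unit diagonal.
    """
    import pandas as pd

    names = list(named_vectors)
    if not names:
        raise EmptyInputError("no vectors given")
    mat = []
    for name in names:
        v = np.asarray(named_vectors[name], dtype=float).ravel()
        if v.size != 20:
            raise ShapeError(f"vector {name!r} has length {v.size}, expected 20")
        mat.append(v)
    k = len(names)
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = pearson(mat[i], mat[j])
    return pd.DataFrame(out, index=names, columns=names)
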