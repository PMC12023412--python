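"""Mutation encoding, design matrices, ridge fitting and prediction.

The mass-balance correction retrofits a "potential-like" stability
predictor — one that scores only the folded state — with an additive
term approximating the neglected unfolded-state free-energy difference
as per-residue contributions of the two swapped amino acids.

A mutation w->m is encoded as a 20-element occurrence vector O with -1
at the wild-type residue, +1 at the mutant, 0 elsewhere.  Three model
modes share this machinery:

``dd``    ddG = a0 * (S_m - S_w) + sum_i a_i O_i      (21 coefficients)
``rose``  ddG = a0 * (S_m - S_w) + a1 * (R_m - R_w)   (2 coefficients,
          R a fixed per-residue scale, by default Rose mean area buried)
``only``  ddG = sum_i a_i O_i                          (no base method)

All three are antisymmetric by construction: reversing the mutation
negates O, the score delta and the scale delta, hence the prediction.
No intercept is fitted in any mode — a constant would break that exact
antisymmetry.  Because sum_i O_i = 0, the residue coefficients a_i are
identifiable only up to a shared additive constant (gauge freedom);
predictions are unaffected.

Coefficients are found by ridge regression in closed form (normal
equations), with the penalty configurable down to 0 (plain least
squares).
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dataset_io import MutationDataset, augment_antisymmetric
from .errors import (
    EmptyInputError,
    IncompleteRecordError,
    MBCError,
    SingularSystemError,
)
from .scales import AA_INDEX, AMINO_ACIDS, Scale, get_scale, validate_residue

logger = logging.getLogger(__name__)

MODES = ("dd", "rose", "only")

#: Default ridge penalty for the residue-coefficient modes, matching the
#: default of the standard ridge implementation the field reaches for.
DEFAULT_LAMBDA = 1.0
#: Default for the two-parameter scale mode: plain least squares.
DEFAULT_LAMBDA_ROSE = 0.0


def encode_mutation(wt: str, mut: str) -> np.ndarray:
    """20-element occurrence vector: -1 at wild-type, +1 at mutant.

    Residues are indexed in fixed alphabetical one-letter order
    (A, C, D, ..., Y).  An identity mutation encodes as all zeros; the
    vector always sums to zero, and swapping the residues negates it.
    """
    wt = validate_residue(wt)
    mut = validate_residue(mut)
    o = np.zeros(20, dtype=float)
    if wt != mut:
        o[AA_INDEX[wt]] = -1.0
        o[AA_INDEX[mut]] = 1.0
    return o


@dataclass
class DesignMatrix:
    """Feature matrix, targets and row ids for one model mode.

    Columns: ``dd`` -> [dS, O_A..O_Y] (n x 21); ``only`` -> [O_A..O_Y]
    (n x 20); ``rose`` -> [dS, dR] (n x 2).
    """

    X: np.ndarray
    y: np.ndarray
    row_ids: list[str]
    mode: str


def _mode_requires_score(mode: str) -> bool:
    return mode in ("dd", "rose")


def _check_mode(mode: str) -> str:
    if mode not in MODES:
        raise MBCError(f"unknown mode {mode!r}; expected one of {MODES}")
    return mode


def build_design_matrix(
    ds: MutationDataset,
    mode: str,
    scale: Optional[Scale] = None,
    require_targets: bool = True,
) -> DesignMatrix:
    """Assemble the regression design for a dataset and mode.

    Rows align one-to-one with the dataset's records.  Incomplete rows
    are never dropped silently: a record missing a field the mode needs
    aborts with :class:`IncompleteRecordError` listing the offenders.
    """
    _check_mode(mode)
    if mode == "rose" and scale is None:
        raise MBCError("mode 'rose' requires a scale")
    if len(ds) == 0:
        raise EmptyInputError("empty dataset")

    bad_score = []
    bad_y = []
    for r in ds:
        if _mode_requires_score(mode) and r.delta_score() is None:
            bad_score.append(r.record_id)
        if require_targets and r.ddg_exp is None:
            bad_y.append(r.record_id)
    if bad_score:
        raise IncompleteRecordError(
            f"{len(bad_score)} record(s) lack score data required by mode "
            f"{mode!r} (first: {bad_score[:5]})",
            record_ids=bad_score,
        )
    if bad_y:
        raise IncompleteRecordError(
            f"{len(bad_y)} record(s) lack ddg_exp (first: {bad_y[:5]})",
            record_ids=bad_y,
        )

    n = len(ds)
    occ = np.stack([encode_mutation(r.wt_aa, r.mut_aa) for r in ds])
    if mode == "dd":
        ds_col = np.array([r.delta_score() for r in ds], dtype=float)
        X = np.column_stack([ds_col, occ])
    elif mode == "only":
        X = occ
    else:  # rose
        ds_col = np.array([r.delta_score() for r in ds], dtype=float)
        dr_col = np.array(
            [scale[r.mut_aa] - scale[r.wt_aa] for r in ds], dtype=float
        )
        X = np.column_stack([ds_col, dr_col])
    y = (
        np.array([r.ddg_exp for r in ds], dtype=float)
        if require_targets
        else np.full(n, np.nan)
    )
    return DesignMatrix(X=X, y=y, row_ids=[r.record_id for r in ds], mode=mode)


def ridge_solve(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Minimize ||y - X b||^2 + lam ||b||^2 in closed form, no intercept.

    Solves the normal equations (X'X + lam I) b = X'y.  With lam = 0
    this is ordinary least squares and requires full column rank.

    Raises
    ------
    SingularSystemError
        lam = 0 and X is rank-deficient; use lam > 0 to regularize.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise MBCError("X must be 2-D")
    if y.shape[0] != X.shape[0]:
        raise MBCError(f"X has {X.shape[0]} rows but y has {y.shape[0]}")
    if X.shape[0] == 0:
        raise EmptyInputError("empty design matrix")
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise MBCError("non-finite values in design matrix or targets")
    if lam < 0:
        raise MBCError(f"ridge penalty must be >= 0, got {lam}")

    p = X.shape[1]
    if lam == 0.0:
        if np.linalg.matrix_rank(X) < p:
            raise SingularSystemError(
                f"design matrix is rank-deficient ({X.shape[0]}x{p}) with "
                "lambda = 0; set lambda > 0 to regularize"
            )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return beta
    A = X.T @ X + lam * np.eye(p)
    return np.linalg.solve(A, X.T @ y)


@dataclass
class MBCModel:
    """A fitted mass-balance correction model.

    Which coefficient fields are populated depends on ``mode``:
    ``dd`` has (a0, a); ``only`` has a alone; ``rose`` has (a0, a1,
    scale_name).  Residue coefficients ``a`` are in kcal/mol, indexed in
    alphabetical one-letter order; ``a0`` is dimensionless times the
    base method's units.
    """

    mode: str
    a0: Optional[float] = None
    a: Optional[np.ndarray] = None
    a1: Optional[float] = None
    scale_name: Optional[str] = None
    lam: float = DEFAULT_LAMBDA
    fit_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        _check_mode(self.mode)
        if self.a is not None:
            self.a = np.asarray(self.a, dtype=float)
            if self.a.shape != (20,):
                raise MBCError(f"residue coefficient vector must have 20 entries, got {self.a.shape}")
        if self.mode == "dd" and (self.a0 is None or self.a is None):
            raise MBCError("mode 'dd' requires a0 and 20 residue coefficients")
        if self.mode == "only" and self.a is None:
            raise MBCError("mode 'only' requires 20 residue coefficients")
        if self.mode == "rose" and (self.a0 is None or self.a1 is None or not self.scale_name):
            raise MBCError("mode 'rose' requires a0, a1 and a scale name")

    def coefficients(self) -> np.ndarray:
        """Coefficient vector in design-matrix column order."""
        if self.mode == "dd":
            return np.concatenate([[self.a0], self.a])
        if self.mode == "only":
            return np.asarray(self.a)
        return np.array([self.a0, self.a1], dtype=float)

    def predict(self, ds: MutationDataset) -> np.ndarray:
        """Corrected ddG (kcal/mol) for every record, in record order.

        Raises :class:`IncompleteRecordError` if records lack fields the
        mode needs (score data for ``dd``/``rose``).
        """
        scale = get_scale(self.scale_name) if self.mode == "rose" else None
        dm = build_design_matrix(ds, self.mode, scale=scale, require_targets=False)
        return dm.X @ self.coefficients()

    def predict_record(self, record) -> float:
        """Corrected ddG for a single record."""
        return float(self.predict(MutationDataset(records=[record]))[0])

    def to_json_dict(self) -> dict:
        doc = {
            "mode": self.mode,
            "lambda": self.lam,
            "fit_metadata": dict(self.fit_meta),
        }
        if self.a0 is not None:
            doc["a0"] = self.a0
        if self.a is not None:
            doc["a"] = {aa: float(v) for aa, v in zip(AMINO_ACIDS, self.a)}
        if self.a1 is not None:
            doc["a1"] = self.a1
        if self.scale_name is not None:
            doc["scale_name"] = self.scale_name
        return doc

    @classmethod
    def from_json_dict(cls, doc: dict) -> "MBCModel":
        a = doc.get("a")
        if a is not None:
            a = np.array([float(a[aa]) for aa in AMINO_ACIDS])
        return cls(
            mode=doc["mode"],
            a0=doc.get("a0"),
            a=a,
            a1=doc.get("a1"),
            scale_name=doc.get("scale_name"),
            lam=float(doc["lambda"]),
            fit_meta=dict(doc.get("fit_metadata", {})),
        )


def fit(
    ds: MutationDataset,
    mode: str = "dd",
    lam: Optional[float] = None,
    scale: Optional[Scale] = None,
    augment: bool = True,
) -> MBCModel:
    """Fit a correction model to a mutation dataset.

    Parameters
    ----------
    ds : MutationDataset
        Training data; every record needs ``ddg_exp``, and modes
        ``dd``/``rose`` need score data.
    mode : {"dd", "rose", "only"}
        Model form (see module docstring).
    lam : float, optional
        Ridge penalty.  Defaults to 1.0 for ``dd``/``only`` and 0.0
        (plain least squares) for the two-parameter ``rose`` mode.
        With no intercept, lam = 0 on 21 antisymmetric features is
        typically still well-posed once n is moderate.
    scale : Scale, optional
        Required for mode ``rose``; defaults to the Rose scale.
    augment : bool
        Add the antisymmetric complement of every record before fitting
        (default on).  With no intercept the fit is provably invariant
        to this augmentation; it is kept as the default training
        protocol and recorded in the model metadata.
    """
    _check_mode(mode)
    if len(ds) == 0:
        raise EmptyInputError("cannot fit on an empty dataset")
    if mode == "rose" and scale is None:
        scale = get_scale("rose")
    if lam is None:
        lam = DEFAULT_LAMBDA_ROSE if mode == "rose" else DEFAULT_LAMBDA

    train = augment_antisymmetric(ds) if augment else ds
    dm = build_design_matrix(train, mode, scale=scale)
    # The penalty is per input record: antisymmetric duplication doubles
    # the rows, so the raw penalty doubles with them.  This makes the
    # no-intercept fit exactly invariant to augmentation.
    lam_eff = lam * len(train) / len(ds)
    beta = ridge_solve(dm.X, dm.y, lam_eff)

    fit_meta = {
        "n": len(train),
        "n_input": len(ds),
        "augmented": bool(augment),
        "intercept": False,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    logger.info(
        "fit mode=%s lambda=%g n=%d augmented=%s", mode, lam, len(train), augment
    )
    if mode == "dd":
        return MBCModel(mode=mode, a0=float(beta[0]), a=beta[1:], lam=lam, fit_meta=fit_meta)
    if mode == "only":
        return MBCModel(mode=mode, a=beta, lam=lam, fit_meta=fit_meta)
    return MBCModel(
        mode=mode,
        a0=float(beta[0]),
        a1=float(beta[1]),
        scale_name=scale.name,
        lam=lam,
        fit_meta=fit_meta,
    )


def predict(model: MBCModel, ds: MutationDataset) -> np.ndarray:
    """Functional alias for :meth:`MBCModel.predict`."""
    return model.predict(ds)
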