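"""End-to-end modelling: fields -> descriptor block -> PLS -> validation.

The pipeline assumes an already-aligned molecule set (use
:func:`qsarfield.alignment.align_set` first when needed) with activity
records whose roles mark the training/test partition.  Field statistics
(column filter, variance scaling, clash substitution means) are learned on
the training rows only and applied unchanged to the test rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import CompoundRecord, Molecule
from .fields import (
    FieldBlock,
    GridSpec,
    ProbeSpec,
    apply_block,
    build_block,
    comfa_fields,
    comsia_fields,
    make_grid,
)
from .pls import (
    CrossValReport,
    PLSModel,
    field_contributions,
    fit_pls,
    fit_statistics,
    loo_q2,
    predict,
    select_onc,
)
from .validation import ExternalValidationReport, external_battery, rpred2

__all__ = ["PipelineResult", "run_pipeline", "compute_field_vectors", "make_fit_recipe",
           "DEFAULT_FILTER_SIGMA"]

# Minimum column standard deviation, in raw field units.  Probe energies are
# kcal/mol-scale, similarity indices are dimensionless and much smaller, so
# the dead-column cutoff differs per descriptor family.
DEFAULT_FILTER_SIGMA = {"comfa": 2.0, "comsia": 0.02}

_MODEL_KINDS = {
    "comfa": ("steric", "electrostatic"),
    "comsia": ("steric", "electrostatic", "hydrophobic", "donor", "acceptor"),
}


@dataclass
class PipelineResult:
    block: FieldBlock
    model: PLSModel
    crossval: CrossValReport
    r2: float
    see: float
    f_value: float
    contributions: dict[str, float]
    train_ids: list[str]
    test_ids: list[str]
    y_train: np.ndarray
    y_test: np.ndarray
    y_pred_test: np.ndarray
    rpred2: float | None
    battery: ExternalValidationReport | None

    @property
    def q2(self) -> float:
        return self.crossval.q2

    @property
    def onc(self) -> int:
        return self.crossval.onc


def compute_field_vectors(
    molecules: list[Molecule],
    grid: GridSpec,
    field_model: str = "comsia",
    kinds: tuple[str, ...] | None = None,
    probe: ProbeSpec | None = None,
) -> dict[str, np.ndarray]:
    """Per-kind (n_molecules, n_nodes) raw field arrays."""
    if field_model not in _MODEL_KINDS:
        raise ValueError("field_model must be 'comfa' or 'comsia'")
    kinds = kinds or _MODEL_KINDS[field_model]
    vectors: dict[str, list[np.ndarray]] = {k: [] for k in kinds}
    for mol in molecules:
        if field_model == "comfa":
            steric, elec = comfa_fields(mol, grid, probe)
            per_mol = {"steric": steric, "electrostatic": elec}
        else:
            per_mol = comsia_fields(mol, grid, probe, kinds)
        for k in kinds:
            vectors[k].append(per_mol[k])
    return {k: np.vstack(v) for k, v in vectors.items()}


def run_pipeline(
    molecules: list[Molecule],
    records: list[CompoundRecord],
    field_model: str = "comsia",
    kinds: tuple[str, ...] | None = None,
    grid: GridSpec | None = None,
    spacing: float = 2.0,
    margin: float = 4.0,
    filter_sigma: float | None = None,
    probe: ProbeSpec | None = None,
    max_components: int = 10,
    parsimony_tol: float = 0.05,
) -> PipelineResult:
    """Fit and validate one grid-field QSAR model.

    Training/test membership is read from the records' ``role``; when no
    record is flagged ``test`` the external statistics are skipped.
    """
    if len(molecules) != len(records) or any(
        m.id != r.id for m, r in zip(molecules, records)
    ):
        raise ValueError("molecules and records must match one-to-one, in order")
    grid = grid or make_grid(molecules, spacing, margin)
    if filter_sigma is None:
        filter_sigma = DEFAULT_FILTER_SIGMA[field_model]
    vectors = compute_field_vectors(molecules, grid, field_model, kinds, probe)

    roles = np.array([r.role for r in records])
    train_mask = roles == "training"
    test_mask = roles == "test"
    y = np.array([r.pic50 for r in records], dtype=float)
    train_vectors = {k: v[train_mask] for k, v in vectors.items()}
    block = build_block(train_vectors, grid, filter_sigma=filter_sigma)
    y_train = y[train_mask]

    n_train = int(train_mask.sum())
    max_a = min(max_components, n_train - 2, block.matrix.shape[1])
    crossval = loo_q2(block, y_train, max_a, parsimony_tol)
    model = fit_pls(block, y_train, crossval.onc)
    r2, see, f_value = fit_statistics(model, block, y_train)
    contributions = field_contributions(model, block)

    ids = [r.id for r in records]
    train_ids = [i for i, m in zip(ids, train_mask) if m]
    test_ids = [i for i, m in zip(ids, test_mask) if m]
    y_test = y[test_mask]
    if test_mask.any():
        x_test = apply_block({k: v[test_mask] for k, v in vectors.items()}, block)
        y_pred_test = predict(model, x_test)
        rp2 = rpred2(y_test, y_pred_test, float(y_train.mean())) if len(y_test) >= 2 else None
        battery = external_battery(y_test, y_pred_test) if len(y_test) >= 3 else None
        if battery is not None:
            battery.rpred2 = rp2
            battery.sd = float(np.sum((y_test - y_train.mean()) ** 2))
            battery.press = float(np.sum((y_pred_test - y_test) ** 2))
    else:
        y_pred_test = np.array([])
        rp2, battery = None, None

    return PipelineResult(
        block=block,
        model=model,
        crossval=crossval,
        r2=r2,
        see=see,
        f_value=f_value,
        contributions=contributions,
        train_ids=train_ids,
        test_ids=test_ids,
        y_train=y_train,
        y_test=y_test,
        y_pred_test=y_pred_test,
        rpred2=rp2,
        battery=battery,
    )


def make_fit_recipe(max_components: int = 10, parsimony_tol: float = 0.05):
    """Closure for Y-randomization: refits LOO + final model on (X, y) and
    returns (q^2 at the re-selected ONC, non-cross-validated r^2)."""

    def recipe(x, y):
        xm = x.matrix if isinstance(x, FieldBlock) else np.asarray(x, dtype=float)
        max_a = min(max_components, xm.shape[0] - 2, xm.shape[1])
        cv = loo_q2(xm, y, max_a, parsimony_tol)
        model = fit_pls(xm, y, cv.onc)
        r2, _, _ = fit_statistics(model, xm, y)
        return cv.q2, r2

    return recipe
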