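"""Bliss independence analysis of two-drug dose-matrix plates.

Raw fluorescence wells are normalized to plate controls to obtain
fractional growth inhibition, single-agent responses define the Bliss
expectation E = A + B - A*B per combination, and observed minus expected
("excess over Bliss") scores the interaction: >0 synergy, 0 additive,
<0 antagonism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PLATE_COLUMNS",
    "DoseMatrixPlate",
    "BlissGrid",
    "fractional_growth_inhibition",
    "bliss_expectation",
    "excess_over_bliss",
    "synergy_matrix",
    "combination_summary",
]

logger = logging.getLogger(__name__)

#: Long-format plate file dialect: one row per well.
PLATE_COLUMNS = ("drug_a_dose", "drug_b_dose", "replicate", "fluorescence", "well_role")
WELL_ROLES = ("assay", "pos_ctrl", "neg_ctrl")


class PlateError(ValueError):
    """Raised for malformed plates or degenerate controls."""


@dataclass(frozen=True)
class DoseMatrixPlate:
    """A two-drug grid of assay wells plus shared plate controls.

    Assay wells cover the full cross of ``doses_a`` x ``doses_b`` plus
    single-agent wells at dose 0 of the partner drug; the (0, 0) well is
    not required (the negative controls play that role).
    """

    drug_a: str
    drug_b: str
    doses_a: tuple[float, ...]
    doses_b: tuple[float, ...]
    wells: pd.DataFrame  # columns: drug_a_dose, drug_b_dose, replicate, fluorescence
    pos_controls: tuple[float, ...]
    neg_controls: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.pos_controls or not self.neg_controls:
            raise PlateError("plate needs nonempty positive and negative controls")
        if float(np.mean(self.neg_controls)) <= float(np.mean(self.pos_controls)):
            raise PlateError(
                "degenerate controls: mean(neg) must exceed mean(pos) "
                f"({np.mean(self.neg_controls):.3g} <= {np.mean(self.pos_controls):.3g})"
            )
        for name, doses in (("A", self.doses_a), ("B", self.doses_b)):
            if any(d <= 0 for d in doses):
                raise PlateError(f"drug {name} doses must be positive")
            if list(doses) != sorted(set(doses)):
                raise PlateError(f"drug {name} doses must be strictly increasing")

    @classmethod
    def from_table(cls, table: pd.DataFrame, drug_a: str = "drug_a", drug_b: str = "drug_b") -> "DoseMatrixPlate":
        missing = set(PLATE_COLUMNS) - set(table.columns)
        if missing:
            raise PlateError(f"plate table missing columns: {sorted(missing)}")
        bad_roles = set(table["well_role"]) - set(WELL_ROLES)
        if bad_roles:
            raise PlateError(f"unknown well roles: {sorted(bad_roles)}")
        assay = table[table["well_role"] == "assay"]
        return cls(
            drug_a=drug_a,
            drug_b=drug_b,
            doses_a=tuple(sorted(set(assay["drug_a_dose"]) - {0.0})),
            doses_b=tuple(sorted(set(assay["drug_b_dose"]) - {0.0})),
            wells=assay[list(PLATE_COLUMNS[:4])].reset_index(drop=True),
            pos_controls=tuple(table.loc[table["well_role"] == "pos_ctrl", "fluorescence"]),
            neg_controls=tuple(table.loc[table["well_role"] == "neg_ctrl", "fluorescence"]),
        )

    def to_table(self) -> pd.DataFrame:
        rows = self.wells.copy()
        rows["well_role"] = "assay"
        ctrl = pd.DataFrame(
            [
                {"drug_a_dose": 0.0, "drug_b_dose": 0.0, "replicate": i, "fluorescence": f, "well_role": role}
                for role, values in (("pos_ctrl", self.pos_controls), ("neg_ctrl", self.neg_controls))
                for i, f in enumerate(values)
            ]
        )
        return pd.concat([rows, ctrl], ignore_index=True)[list(PLATE_COLUMNS)]


@dataclass
class BlissGrid:
    """Per-combination inhibitions, Bliss expectations and excess scores."""

    doses_a: tuple[float, ...]
    doses_b: tuple[float, ...]
    single_a: np.ndarray  # clamped single-agent fractional inhibition of drug A
    single_b: np.ndarray
    observed: np.ndarray  # clamped combination inhibition, shape (len a, len b)
    observed_raw: np.ndarray  # unclamped, for the record
    expected: np.ndarray
    excess: np.ndarray
    n_clamped: int = 0
    drug_a: str = "drug_a"
    drug_b: str = "drug_b"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, da in enumerate(self.doses_a):
            for j, db in enumerate(self.doses_b):
                rows.append(
                    {
                        "drug_a_dose": da,
                        "drug_b_dose": db,
                        "inhibition_a": self.single_a[i],
                        "inhibition_b": self.single_b[j],
                        "observed": self.observed[i, j],
                        "observed_raw": self.observed_raw[i, j],
                        "expected": self.expected[i, j],
                        "excess": self.excess[i, j],
                    }
                )
        return pd.DataFrame(rows)


def fractional_growth_inhibition(f_well, pos, neg, clamp: bool = False):
    """Normalize fluorescence to controls: 0 at mean(neg), 1 at mean(pos).

    ``f_well`` may be scalar or array.  Raw values can leave [0, 1] under
    noise; pass ``clamp=True`` for the copy fed to the Bliss formula.
    """
    mean_pos = float(np.mean(pos))
    mean_neg = float(np.mean(neg))
    if mean_neg <= mean_pos:
        raise PlateError(
            f"degenerate controls: mean(neg)={mean_neg:.3g} <= mean(pos)={mean_pos:.3g}"
        )
    raw = (mean_neg - np.asarray(f_well, dtype=float)) / (mean_neg - mean_pos)
    out = np.clip(raw, 0.0, 1.0) if clamp else raw
    return float(out) if out.ndim == 0 else out


def bliss_expectation(a, b):
    """Independence expectation E = A + B - A*B for inhibition fractions."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any((a < 0) | (a > 1)) or np.any((b < 0) | (b > 1)):
        raise PlateError("fractional inhibitions must lie in [0, 1]")
    e = a + b - a * b
    return float(e) if e.ndim == 0 else e


def excess_over_bliss(observed, expected):
    """Observed minus expected inhibition; >0 synergy, <0 antagonism."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if np.any((observed < 0) | (observed > 1)) or np.any((expected < 0) | (expected > 1)):
        raise PlateError("inhibitions must lie in [0, 1]")
    x = observed - expected
    return float(x) if x.ndim == 0 else x


def _mean_inhibition(plate: DoseMatrixPlate, da: float, db: float) -> tuple[float, float]:
    """(clamped, raw) replicate-averaged inhibition for one dose pair."""
    sel = plate.wells[
        (plate.wells["drug_a_dose"] == da) & (plate.wells["drug_b_dose"] == db)
    ]
    if sel.empty:
        raise PlateError(f"missing assay well at doses ({da}, {db})")
    # replicates averaged on the inhibition scale, after normalization
    raw = fractional_growth_inhibition(
        sel["fluorescence"].to_numpy(), plate.pos_controls, plate.neg_controls
    )
    clamped = np.clip(raw, 0.0, 1.0)
    return float(np.mean(clamped)), float(np.mean(raw))


def synergy_matrix(plate: DoseMatrixPlate) -> BlissGrid:
    """Assemble the full excess-over-Bliss grid from a plate.

    Single-agent inhibitions come from the dedicated dose-0 wells of the
    partner drug; raw inhibitions outside [0, 1] are clamped for the
    Bliss computation (the raw values are kept in the output).
    """
    na, nb = len(plate.doses_a), len(plate.doses_b)
    single_a = np.empty(na)
    single_a_raw = np.empty(na)
    single_b = np.empty(nb)
    single_b_raw = np.empty(nb)
    for i, da in enumerate(plate.doses_a):
        single_a[i], single_a_raw[i] = _mean_inhibition(plate, da, 0.0)
    for j, db in enumerate(plate.doses_b):
        single_b[j], single_b_raw[j] = _mean_inhibition(plate, 0.0, db)

    observed = np.empty((na, nb))
    observed_raw = np.empty((na, nb))
    for i, da in enumerate(plate.doses_a):
        for j, db in enumerate(plate.doses_b):
            observed[i, j], observed_raw[i, j] = _mean_inhibition(plate, da, db)

    expected = bliss_expectation(single_a[:, None], single_b[None, :])
    excess = excess_over_bliss(observed, expected)
    n_clamped = int(
        np.sum(~np.isclose(observed, observed_raw))
        + np.sum(~np.isclose(single_a, single_a_raw))
        + np.sum(~np.isclose(single_b, single_b_raw))
    )
    if n_clamped:
        logger.info("clamped %d well inhibitions into [0, 1]", n_clamped)
    return BlissGrid(
        doses_a=plate.doses_a,
        doses_b=plate.doses_b,
        single_a=single_a,
        single_b=single_b,
        observed=observed,
        observed_raw=observed_raw,
        expected=expected,
        excess=excess,
        n_clamped=n_clamped,
        drug_a=plate.drug_a,
        drug_b=plate.drug_b,
    )


def combination_summary(grid: BlissGrid, delta: float = 0.0) -> dict:
    """Plate-level call from the excess grid.

    ``delta`` is a noise margin: synergy if mean excess > delta,
    antagonism if < -delta, otherwise additive.
    """
    mean_x = float(np.mean(grid.excess))
    if mean_x > delta:
        call = "synergy"
    elif mean_x < -delta:
        call = "antagonism"
    else:
        call = "additive"
    return {
        "mean_excess": mean_x,
        "max_excess": float(np.max(grid.excess)),
        "min_excess": float(np.min(grid.excess)),
        "n_wells_above_delta": int(np.sum(grid.excess > delta)),
        "n_clamped": grid.n_clamped,
        "call": call,
    }
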