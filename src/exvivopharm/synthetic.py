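"""Seeded generators for cohorts, gene-card Ct tables and dose-matrix plates.

Every generator is deterministic given its parameter block (which carries
the seed) and emits data with the statistical structure the downstream
stages assume: two latent response classes with disjoint relative Ki-67
ranges under drug, caspase-3 induction confined to the sensitive class,
stable reference genes with planted log-fold effects on chosen targets,
and Hill-response plates with an optional planted Bliss interaction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .bliss import DoseMatrixPlate
from .classify import GRADES, HISTOTYPES, TumorCase
from .expression import load_panel_fixture
from .ihc import IHCObservation

__all__ = [
    "CohortParams",
    "ExpressionParams",
    "PlateParams",
    "SyntheticCohort",
    "generate_cohort",
    "generate_ct_table",
    "generate_dose_matrix",
]


class GeneratorError(ValueError):
    """Raised for invalid generator parameters."""


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Derive an independent RNG stream from (seed, stream-name)."""
    import zlib

    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(stream.encode())]))


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with unit median and the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log(1.0 + cv * cv))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# Cohort + IHC time courses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortParams:
    """Parameters of the two-class tumor cohort generator.

    Defaults encode a 57.6% sensitive fraction of 33 cases, baseline
    Ki-67 means of 16% vs 26%, and disjoint final relative Ki-67 ranges
    (0-50% vs 70-180% of control) under drug.

    ``noise_cv`` covers both vehicle-arm drift and measurement noise on
    scores; the default (5%) keeps label recovery by the downstream
    classifier above 95% (10% drift makes the 50% boundary marginal).
    """

    n_cases: int = 33
    responder_fraction: float = 0.576
    ki67_mean_responder: float = 16.0
    ki67_mean_nonresponder: float = 26.0
    ki67_sd: float = 8.0
    rel_ki67_final_responder_range: tuple[float, float] = (0.0, 50.0)
    rel_ki67_final_nonresponder_range: tuple[float, float] = (70.0, 180.0)
    casp3_induction_fold_responder: float = 6.0
    timepoints: tuple[float, ...] = (0.0, 24.0, 48.0, 72.0)
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rel_ki67_final_responder_range", "rel_ki67_final_nonresponder_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise GeneratorError(f"{name}: low {lo} > high {hi}")
            if lo < 0:
                raise GeneratorError(f"{name}: percents must be >= 0")
        if self.rel_ki67_final_responder_range[1] > self.rel_ki67_final_nonresponder_range[0]:
            raise GeneratorError("responder range must lie below the non-responder range")
        if not 0 < self.responder_fraction < 1:
            raise GeneratorError("responder_fraction must lie strictly in (0, 1)")
        if min(self.ki67_mean_responder, self.ki67_mean_nonresponder, self.ki67_sd) < 0:
            raise GeneratorError("Ki-67 parameters must be >= 0")
        if self.casp3_induction_fold_responder <= 0:
            raise GeneratorError("caspase-3 induction fold must be > 0")
        if tuple(sorted(self.timepoints)) != self.timepoints or 0.0 not in self.timepoints:
            raise GeneratorError("timepoints must be sorted and include 0")


@dataclass
class SyntheticCohort:
    """Generated cases + observations, with the planted truth kept behind
    an explicit reveal accessor so recovery tests cannot leak it."""

    cases: list[TumorCase]
    observations: list[IHCObservation]
    params: CohortParams
    _true_classes: dict[str, str] = field(repr=False, default_factory=dict)
    _planted_relative: dict[str, float] = field(repr=False, default_factory=dict)

    def reveal_true_class(self, case_id: str) -> str:
        return self._true_classes[case_id]

    def reveal_all(self) -> dict[str, str]:
        return dict(self._true_classes)

    def reveal_planted_relative(self, case_id: str) -> float:
        """Planted final relative Ki-67 (% of control) for a case."""
        return self._planted_relative[case_id]

    def cases_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cases:
            rows.append(
                {
                    "case_id": c.case_id,
                    "histotype": c.histotype,
                    "t_stage": c.t_stage,
                    "n_stage": c.n_stage,
                    "grade": c.grade,
                    "er": "Neg" if c.er_percent is None else f"{c.er_percent:g}%",
                    "pr": "Neg" if c.pr_percent is None else f"{c.pr_percent:g}%",
                    "her2": c.her2,
                    "ki67_percent": c.ki67_diagnosis,
                    "p53": c.p53_status,
                    "doxo_class": c.doxo_class,
                }
            )
        return pd.DataFrame(rows)

    def observations_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "case_id": o.case_id,
                    "marker": o.marker,
                    "arm": o.arm,
                    "time_h": o.time_h,
                    "percent_positive": o.percent_positive,
                    "intensity": "" if o.intensity is None else o.intensity,
                }
                for o in self.observations
            ]
        )

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "case_id": cid,
                    "true_class": cls,
                    "planted_relative_ki67": self._planted_relative[cid],
                }
                for cid, cls in self._true_classes.items()
            ]
        )


def _random_clinical(rng: np.random.Generator, case_id: str, ki67: float) -> dict:
    """Clinicopathology fields drawn independently of the response class."""
    er = None if rng.random() < 0.12 else float(rng.choice([25, 70, 80, 90, 95]))
    pr = None if rng.random() < 0.2 else float(rng.choice([2, 5, 10, 40, 70, 90, 95]))
    return {
        "case_id": case_id,
        "histotype": str(rng.choice(HISTOTYPES, p=[0.85, 0.05, 0.05, 0.05])),
        "t_stage": str(rng.choice(["pT1c", "pT2", "pT3"], p=[0.45, 0.4, 0.15])),
        "n_stage": str(rng.choice(["N0", "N1a", "N2a", "N3a", "Nx"], p=[0.4, 0.25, 0.1, 0.1, 0.15])),
        "grade": str(rng.choice(GRADES, p=[0.15, 0.4, 0.45])),
        "er_percent": er,
        "pr_percent": pr,
        "her2": str(rng.choice(["Pos", "Neg"], p=[0.15, 0.85])),
        "ki67_diagnosis": ki67,
        "p53_status": "mutant" if rng.random() < 0.1 else "Wt",
        "doxo_class": "Unknown",
    }


def generate_cohort(params: CohortParams) -> SyntheticCohort:
    """Simulate a two-class cohort with Ki-67 and caspase-3 time courses.

    Per case: the vehicle arm fluctuates around the baseline score; the
    drug arm follows a log-linear path from baseline to a final relative
    value drawn uniformly from the class range; caspase-3 rises by the
    configured fold only in the sensitive class.  T0 observations are
    noise-free (the baseline slice defines the reference).
    """
    p = params
    if not float(p.n_cases).is_integer() or p.n_cases < 2:
        raise GeneratorError(f"n_cases must be an integer >= 2, got {p.n_cases}")
    n_resp = round(p.n_cases * p.responder_fraction)
    n_nonresp = p.n_cases - n_resp
    if n_resp == 0:
        raise GeneratorError("responder class empty after rounding")
    if n_nonresp == 0:
        raise GeneratorError("non-responder class empty after rounding")

    rng = _rng(p.seed, "cohort")
    t_final = max(p.timepoints)
    cases: list[TumorCase] = []
    observations: list[IHCObservation] = []
    truth: dict[str, str] = {}
    planted: dict[str, float] = {}

    labels = ["Responder"] * n_resp + ["NonResponder"] * n_nonresp
    for idx, label in enumerate(labels, start=1):
        case_id = f"SYN{idx:03d}"
        mean = p.ki67_mean_responder if label == "Responder" else p.ki67_mean_nonresponder
        baseline = float(np.clip(rng.normal(mean, p.ki67_sd), 1.0, 100.0))
        cases.append(TumorCase(**_random_clinical(rng, case_id, baseline)))
        truth[case_id] = label

        lo, hi = (
            p.rel_ki67_final_responder_range
            if label == "Responder"
            else p.rel_ki67_final_nonresponder_range
        )
        rel_final = float(rng.uniform(lo, hi))
        planted[case_id] = rel_final

        # caspase-3 baseline: percent + constant intensity per case
        casp3_base = float(np.clip(rng.uniform(2.0, 8.0), 0.5, 100.0))
        casp3_intensity = int(rng.integers(1, 3))
        casp3_fold = p.casp3_induction_fold_responder if label == "Responder" else 1.0

        for arm in ("vehicle", "doxo"):
            for t in p.timepoints:
                frac = t / t_final
                noise = 1.0 if t == 0.0 else float(_lognormal_factor(rng, p.noise_cv))
                if arm == "doxo":
                    # log-linear path from 100% (T0) to the planted relative value
                    ki_factor = (max(rel_final, 1e-6) / 100.0) ** frac
                    c_factor = casp3_fold**frac
                else:
                    ki_factor = 1.0
                    c_factor = 1.0
                ki = float(np.clip(baseline * ki_factor * noise, 0.0, 100.0))
                observations.append(
                    IHCObservation(case_id, "Ki67", arm, t, ki, None)
                )
                c_noise = 1.0 if t == 0.0 else float(_lognormal_factor(rng, p.noise_cv))
                casp3 = float(np.clip(casp3_base * c_factor * c_noise, 0.0, 100.0))
                observations.append(
                    IHCObservation(case_id, "CASP3", arm, t, casp3, casp3_intensity)
                )

    return SyntheticCohort(
        cases=cases,
        observations=observations,
        params=p,
        _true_classes=truth,
        _planted_relative=planted,
    )


# ---------------------------------------------------------------------------
# Gene-card Ct tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionParams:
    """Parameters of the gene-card Ct generator.

    ``effect_genes`` maps gene name -> log2 fold-change of the second
    class (NonResponder) over the first; a positive value lowers the
    NonResponder Ct by that many cycles.
    """

    n_targets: int = 92
    reference_genes: tuple[str, ...] = ("ACTB", "TBP", "HMBS")
    base_ct: float = 26.0
    base_ct_spread: float = 3.0  # per-gene offsets drawn U(-spread, +spread)
    ct_sd: float = 0.25
    effect_genes: Mapping[str, float] = field(default_factory=dict)
    duplicate_wells: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ct_sd < 0:
            raise GeneratorError("ct_sd must be >= 0")
        if self.duplicate_wells < 1:
            raise GeneratorError("need at least one well per gene")
        if self.n_targets < 1:
            raise GeneratorError("need at least one target gene")

    def target_names(self) -> list[str]:
        panel = load_panel_fixture()
        targets = panel.loc[panel["role"] == "target", "gene"].tolist()
        if self.n_targets <= len(targets):
            return targets[: self.n_targets]
        extra = [f"SYNGENE{i:03d}" for i in range(1, self.n_targets - len(targets) + 1)]
        return targets + extra


def generate_ct_table(classes: Mapping[str, str], params: ExpressionParams) -> pd.DataFrame:
    """Simulate a duplicate-well Ct table for the given sample -> class map.

    Reference genes are class-independent; each effect gene's class-mean
    Ct differs by minus its log2 fold-change (lower Ct = higher
    expression).  Returns the long-format table used by the expression
    stage (sample_id, class, gene, role, replicate, ct).
    """
    p = params
    targets = p.target_names()
    unknown = set(p.effect_genes) - set(targets)
    if unknown:
        raise GeneratorError(f"effect genes not on the card: {sorted(unknown)}")
    classes = dict(classes)
    rng = _rng(p.seed, "ct-table")
    genes = targets + list(p.reference_genes)
    base = {
        g: p.base_ct + float(rng.uniform(-p.base_ct_spread, p.base_ct_spread)) for g in genes
    }
    rows = []
    for sample_id, cls in classes.items():
        for gene in genes:
            role = "reference" if gene in p.reference_genes else "target"
            mean_ct = base[gene]
            if role == "target" and cls == "NonResponder":
                mean_ct -= float(p.effect_genes.get(gene, 0.0))
            for rep in range(1, p.duplicate_wells + 1):
                ct = mean_ct + float(rng.normal(0.0, p.ct_sd)) if p.ct_sd > 0 else mean_ct
                rows.append(
                    {
                        "sample_id": sample_id,
                        "class": cls,
                        "gene": gene,
                        "role": role,
                        "replicate": rep,
                        "ct": max(ct, 1e-6),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Dose-matrix plates
# ---------------------------------------------------------------------------

def _geomspace7(lo: float, hi: float) -> tuple[float, ...]:
    return tuple(float(x) for x in np.geomspace(lo, hi, 7))


@dataclass(frozen=True)
class PlateParams:
    """Parameters of the two-drug Hill-response plate generator.

    Default dose ranges follow the screening layout: drug A 0.0004-0.1
    umol/L, drug B 0.004-1 umol/L, 7 log-spaced doses each.
    """

    doses_a: tuple[float, ...] = _geomspace7(0.0004, 0.1)
    doses_b: tuple[float, ...] = _geomspace7(0.004, 1.0)
    hill_ec50_a: float = 0.0063
    hill_ec50_b: float = 0.063
    hill_slope_a: float = 1.0
    hill_slope_b: float = 1.0
    interaction: str = "independent"
    interaction_strength: float = 0.0
    f_neg_mean: float = 10000.0
    f_pos_mean: float = 1000.0
    replicate_wells: int = 2
    control_wells: int = 12
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f_neg_mean <= self.f_pos_mean:
            raise GeneratorError("f_neg_mean must exceed f_pos_mean")
        for name, doses in (("doses_a", self.doses_a), ("doses_b", self.doses_b)):
            if len(doses) != 7:
                raise GeneratorError(f"{name} must hold exactly 7 doses")
            if list(doses) != sorted(doses) or len(set(doses)) != 7 or doses[0] <= 0:
                raise GeneratorError(f"{name} must be strictly increasing positives")
        if self.interaction not in ("independent", "synergistic", "antagonistic"):
            raise GeneratorError(f"unknown interaction {self.interaction!r}")
        if self.interaction_strength < 0:
            raise GeneratorError("interaction_strength must be >= 0")
        if min(self.hill_ec50_a, self.hill_ec50_b, self.hill_slope_a, self.hill_slope_b) <= 0:
            raise GeneratorError("Hill parameters must be > 0")


def hill_inhibition(dose, ec50: float, slope: float):
    """Fractional inhibition f(d) = d^h / (d^h + EC50^h)."""
    dose = np.asarray(dose, dtype=float)
    out = dose**slope / (dose**slope + ec50**slope)
    return float(out) if out.ndim == 0 else out


def true_combination_inhibition(a, b, interaction: str, strength: float):
    """Planted combination truth: Bliss E shifted by an interaction term.

    The bump is strength * sqrt(A*B) * (1-E) (synergy) or the mirrored
    strength * sqrt(A*B) * E (antagonism), clipped to [0, 1]: symmetric in
    the two drugs, zero whenever either agent is inert, and at strength 1
    with A = B = 0.5 it gives 0.75 + 0.25*0.5 = 0.875.
    """
    e = a + b - a * b
    if interaction == "independent":
        return e
    coupling = strength * np.sqrt(a * b)
    if interaction == "synergistic":
        return np.clip(e + coupling * (1.0 - e), 0.0, 1.0)
    return np.clip(e - coupling * e, 0.0, 1.0)


def generate_dose_matrix(params: PlateParams) -> DoseMatrixPlate:
    """Simulate a full dose-matrix plate with controls.

    Single-agent wells follow the Hill curves, combination wells follow
    the planted interaction model, and fluorescence maps inhibition f to
    f_neg_mean - f * (f_neg_mean - f_pos_mean) plus Gaussian noise.
    """
    p = params
    rng = _rng(p.seed, "dose-matrix")
    span = p.f_neg_mean - p.f_pos_mean

    def fluor(inhibition: float, n: int) -> list[float]:
        base = p.f_neg_mean - inhibition * span
        noise = rng.normal(0.0, p.noise_sd, size=n) if p.noise_sd > 0 else np.zeros(n)
        return [float(base + x) for x in noise]

    rows = []

    def add_wells(da: float, db: float, inhibition: float) -> None:
        for rep, f in enumerate(fluor(inhibition, p.replicate_wells), start=1):
            rows.append(
                {
                    "drug_a_dose": da,
                    "drug_b_dose": db,
                    "replicate": rep,
                    "fluorescence": f,
                    "well_role": "assay",
                }
            )

    a_fracs = {da: hill_inhibition(da, p.hill_ec50_a, p.hill_slope_a) for da in p.doses_a}
    b_fracs = {db: hill_inhibition(db, p.hill_ec50_b, p.hill_slope_b) for db in p.doses_b}
    for da in p.doses_a:
        add_wells(da, 0.0, a_fracs[da])
    for db in p.doses_b:
        add_wells(0.0, db, b_fracs[db])
    for da in p.doses_a:
        for db in p.doses_b:
            truth = float(
                true_combination_inhibition(
                    a_fracs[da], b_fracs[db], p.interaction, p.interaction_strength
                )
            )
            add_wells(da, db, truth)

    for role, inhibition in (("neg_ctrl", 0.0), ("pos_ctrl", 1.0)):
        for rep, f in enumerate(fluor(inhibition, p.control_wells), start=1):
            rows.append(
                {
                    "drug_a_dose": 0.0,
                    "drug_b_dose": 0.0,
                    "replicate": rep,
                    "fluorescence": f,
                    "well_role": role,
                }
            )

    return DoseMatrixPlate.from_table(pd.DataFrame(rows), drug_a="drug_a", drug_b="drug_b")


def params_to_dict(params) -> dict:
    """Serializable view of any generator parameter block (for manifests)."""
    return dataclasses.asdict(params)
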