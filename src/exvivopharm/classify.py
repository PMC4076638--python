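"""Drug-response classification and group-level association statistics.

Cases are called Responder when the final relative Ki-67 (drug arm versus
vehicle control, both baseline-normalized) drops to 50% of control or
below; Non-Responders retain >50%.  Group comparisons use the classical
unpaired t test for continuous variables and Fisher's exact test (full
hypergeometric enumeration) for 2x2 contingency tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .ihc import MarkerTrajectory, ScoreError

__all__ = [
    "RESPONDER_THRESHOLD",
    "RULE_VERSION",
    "TumorCase",
    "ResponseCall",
    "load_clinical_fixture",
    "parse_clinical_table",
    "relative_ki67",
    "classify_response",
    "unpaired_t_test",
    "fisher_exact_2x2",
    "association_screen",
]

#: Relative Ki-67 (% of control) at or below which a case is a Responder.
RESPONDER_THRESHOLD = 50.0
#: Documented tie rule: exactly 50% of control resolves to Responder.
RULE_VERSION = "relative-ki67-final<=50=responder/v1"

HISTOTYPES = ("IDC", "ILC", "DLC", "PC")
GRADES = ("G1", "G2", "G3")


class ClassificationError(ValueError):
    """Raised on invalid classification inputs."""


@dataclass(frozen=True)
class TumorCase:
    """One clinicopathology record (diagnosis-time characteristics plus
    the ex vivo doxorubicin response class, when known)."""

    case_id: str
    histotype: str
    t_stage: str
    n_stage: str
    grade: str
    er_percent: float | None  # None encodes negative staining
    pr_percent: float | None
    her2: str
    ki67_diagnosis: float
    p53_status: str
    doxo_class: str = "Unknown"

    def __post_init__(self) -> None:
        if self.histotype not in HISTOTYPES:
            raise ClassificationError(f"unknown histotype {self.histotype!r}")
        if self.grade not in GRADES:
            raise ClassificationError(f"unknown grade {self.grade!r}")
        if self.her2 not in ("Pos", "Neg"):
            raise ClassificationError(f"unknown HER2 status {self.her2!r}")
        if not 0 <= self.ki67_diagnosis <= 100:
            raise ClassificationError(f"Ki-67 {self.ki67_diagnosis} outside [0, 100]")
        if self.doxo_class not in ("Responder", "NonResponder", "Unknown"):
            raise ClassificationError(f"unknown response class {self.doxo_class!r}")

    @property
    def p53_mutant(self) -> bool:
        return self.p53_status != "Wt"


@dataclass(frozen=True)
class ResponseCall:
    case_id: str
    relative_ki67_final: float
    call: str
    rule_version: str = RULE_VERSION


def _parse_receptor(value: str) -> float | None:
    value = str(value).strip()
    if value in ("Neg", "neg", ""):
        return None
    return float(value.rstrip("%"))


def parse_clinical_table(frame: pd.DataFrame) -> list[TumorCase]:
    """Build :class:`TumorCase` records from a clinicopathology table."""
    required = {
        "case_id", "histotype", "t_stage", "n_stage", "grade",
        "er", "pr", "her2", "ki67_percent", "p53", "doxo_class",
    }
    missing = required - set(frame.columns)
    if missing:
        raise ClassificationError(f"clinical table missing columns: {sorted(missing)}")
    cases = []
    for row in frame.itertuples(index=False):
        cases.append(
            TumorCase(
                case_id=str(row.case_id),
                histotype=str(row.histotype),
                t_stage=str(row.t_stage),
                n_stage=str(row.n_stage),
                grade=str(row.grade),
                er_percent=_parse_receptor(row.er),
                pr_percent=_parse_receptor(row.pr),
                her2=str(row.her2),
                ki67_diagnosis=float(row.ki67_percent),
                p53_status=str(row.p53),
                doxo_class=str(row.doxo_class).replace("Non Responder", "NonResponder"),
            )
        )
    return cases


def load_clinical_fixture() -> list[TumorCase]:
    """Load the packaged 33-case clinicopathology fixture."""
    with resources.files("exvivopharm.data").joinpath("clinical_cohort.csv").open("r") as fh:
        frame = pd.read_csv(fh)
    return parse_clinical_table(frame)


def relative_ki67(
    doxo: MarkerTrajectory, vehicle: MarkerTrajectory, final_time: float | None = None
) -> float:
    """Final drug-arm Ki-67 as percent of the vehicle arm at the same time.

    Both trajectories must already be T0-normalized.  ``final_time``
    defaults to the latest timepoint shared by the two arms.
    """
    shared = sorted(set(doxo.times_h) & set(vehicle.times_h))
    if not shared:
        raise ScoreError("no shared timepoints between arms")
    if final_time is None:
        final_time = shared[-1]
    return 100.0 * doxo.at(final_time) / vehicle.at(final_time)


def classify_response(rel: float) -> str:
    """Responder iff final relative Ki-67 <= 50% of control."""
    if rel < 0:
        raise ClassificationError(f"relative Ki-67 must be >= 0, got {rel}")
    return "Responder" if rel <= RESPONDER_THRESHOLD else "NonResponder"


def unpaired_t_test(a, b, welch: bool = False) -> tuple[float, float, float]:
    """Two-sided unpaired t test; classical equal-variance by default.

    Returns (t, p, df).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ClassificationError("each sample needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and np.mean(a) == np.mean(b):
        # identical constant samples: no evidence either way
        df = a.size + b.size - 2 if not welch else float("nan")
        return 0.0, 1.0, float(df)
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ClassificationError("degenerate samples: zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue), float(res.df)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table by full enumeration.

    All tables with the observed margins are enumerated; exact rational
    hypergeometric probabilities no larger than the observed one (with a
    1e-7 relative tie tolerance) are summed.
    """
    tab = np.asarray(table)
    if tab.shape != (2, 2):
        raise ClassificationError(f"expected a 2x2 table, got shape {tab.shape}")
    if np.any(tab < 0):
        raise ClassificationError("counts must be nonnegative")
    if not np.all(tab == np.floor(tab)) or not np.issubdtype(tab.dtype, np.number):
        raise ClassificationError("counts must be integers")
    a, b, c, d = (int(x) for x in tab.ravel())
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        raise ClassificationError("empty table")

    def pmf(k: int) -> Fraction:
        return Fraction(
            math.comb(r1, k) * math.comb(r2, c1 - k), math.comb(n, c1)
        )

    k_min = max(0, c1 - r2)
    k_max = min(r1, c1)
    p_obs = pmf(a)
    gate = p_obs + p_obs * Fraction(1, 10**7)
    total = sum(pmf(k) for k in range(k_min, k_max + 1) if pmf(k) <= gate)
    return float(min(total, Fraction(1)))


# ---------------------------------------------------------------------------
# Association screen over clinicopathological features
# ---------------------------------------------------------------------------

def _dichotomies(case: TumorCase) -> dict[str, bool]:
    """Collapse multi-level features to 2-level splits for 2x2 tables."""
    return {
        "histotype_IDC": case.histotype == "IDC",
        "t_stage_pT1": case.t_stage.startswith("pT1"),
        "n_stage_positive": case.n_stage not in ("N0", "Nx", "pNx"),
        "grade_G3": case.grade == "G3",
        "er_positive": case.er_percent is not None,
        "pr_positive": case.pr_percent is not None,
        "her2_positive": case.her2 == "Pos",
        "ki67_gt15": case.ki67_diagnosis > 15.0,
        "p53_mutant": case.p53_mutant,
    }


def association_screen(cases) -> pd.DataFrame:
    """Test each clinicopathological feature against the response class.

    Categorical features (dichotomized) get a Fisher exact p; diagnostic
    Ki-67 additionally gets an unpaired t test on the raw percentages.
    """
    cases = list(cases)
    labels = [c.doxo_class for c in cases]
    n_resp = labels.count("Responder")
    n_nonresp = labels.count("NonResponder")
    if n_resp < 2 or n_nonresp < 2:
        raise ClassificationError(
            f"need >=2 cases per class, got {n_resp} Responder / {n_nonresp} NonResponder"
        )
    rows = []
    for feature in _dichotomies(cases[0]):
        tab = np.zeros((2, 2), dtype=int)
        for case in cases:
            i = 0 if case.doxo_class == "Responder" else 1
            j = 0 if _dichotomies(case)[feature] else 1
            tab[i, j] += 1
        rows.append({"feature": feature, "test": "fisher_exact", "p": fisher_exact_2x2(tab)})

    ki_resp = [c.ki67_diagnosis for c in cases if c.doxo_class == "Responder"]
    ki_non = [c.ki67_diagnosis for c in cases if c.doxo_class == "NonResponder"]
    t, p, _ = unpaired_t_test(ki_resp, ki_non)
    rows.append({"feature": "ki67_diagnosis_mean", "test": "unpaired_t", "p": p})
    report = pd.DataFrame(rows)
    report["mean_responder"] = np.nan
    report["mean_nonresponder"] = np.nan
    report.loc[report["feature"] == "ki67_diagnosis_mean", ["mean_responder", "mean_nonresponder"]] = [
        float(np.mean(ki_resp)),
        float(np.mean(ki_non)),
    ]
    return report
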