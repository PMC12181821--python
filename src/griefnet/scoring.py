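"""ICD-11 diagnostic scoring, reliability, and pooled prevalence.

Implements the probable-diagnosis algorithms for prolonged grief
disorder (PGD), PTSD and complex PTSD (cPTSD) from the instrument item
maps: TGI-SR+ symptoms count as present at ratings >= 4, CAPS/COPISAC
symptoms at ratings >= 2, the loss must lie more than 6 months back, and
cPTSD supersedes PTSD (no double diagnosis). Severity scores are item
sums; McDonald's omega quantifies internal consistency from a one-factor
model; prevalence and comorbidity are pooled over multiply imputed
datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CAPS_ITEMS, COPISAC_ITEMS, TGI_ITEMS, ItemResponseMatrix
from .imputation import ImputationStack

__all__ = [
    "InstrumentSpec",
    "DiagnosisRecord",
    "ReliabilityResult",
    "score_severity",
    "diagnose_pgd",
    "diagnose_ptsd_icd11",
    "diagnose_cptsd",
    "diagnose_all",
    "prevalence_and_comorbidity",
    "mcdonald_omega",
]

# TGI-SR+ item numbers in the ICD-11 PGD algorithm
PGD_B_ITEMS = ("TGI_03", "TGI_01")          # longing; preoccupation
PGD_C_ITEMS = tuple(f"TGI_{i:02d}" for i in (2, 5, 8, 9, 10, 16, 19, 20, 21, 22))
PGD_E_ITEM = "TGI_13"                        # functional impairment

PTSD_SEVERITY_ITEMS = ("CAPS_01", "CAPS_02", "CAPS_06", "CAPS_07", "CAPS_17", "CAPS_18")


@dataclass
class InstrumentSpec:
    """Thresholds and item maps of the three diagnostic algorithms."""

    symptom_threshold_pgd: int = 4
    symptom_threshold_ptsd: int = 2
    pgd_min_months: float = 6.0
    dso_items: tuple[str, ...] = ("COPISAC_CO1", "COPISAC_CO2", "COPISAC_CO3")
    include_caps13_in_dso: bool = False

    @property
    def dso_severity_items(self) -> tuple[str, ...]:
        return self.dso_items + (("CAPS_13",) if self.include_caps13_in_dso else ())


DEFAULT_SPEC = InstrumentSpec()


@dataclass
class DiagnosisRecord:
    pgd: bool
    ptsd_icd11: bool
    cptsd: bool
    severity_pgd: float
    severity_ptsd: float
    severity_dso: float

    @property
    def severity_cptsd(self) -> float:
        return self.severity_ptsd + self.severity_dso


def _require(row: pd.Series | dict, items) -> None:
    for it in items:
        v = row.get(it) if isinstance(row, dict) else (row[it] if it in row else None)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"required item {it!r} is missing")


def score_severity(row: pd.Series | dict, instrument: InstrumentSpec = DEFAULT_SPEC) -> dict:
    """Severity sums: PGD (22 TGI items, 22-110), PTSD (six CAPS items),
    DSO (COPISAC DSO items), cPTSD = PTSD + DSO."""
    _require(row, TGI_ITEMS)
    _require(row, PTSD_SEVERITY_ITEMS)
    _require(row, instrument.dso_severity_items)
    sev_pgd = float(sum(row[c] for c in TGI_ITEMS))
    sev_ptsd = float(sum(row[c] for c in PTSD_SEVERITY_ITEMS))
    sev_dso = float(sum(row[c] for c in instrument.dso_severity_items))
    return {
        "severity_pgd": sev_pgd,
        "severity_ptsd": sev_ptsd,
        "severity_dso": sev_dso,
        "severity_cptsd": sev_ptsd + sev_dso,
    }


def diagnose_pgd(row: pd.Series | dict, months_since_loss: float, bereaved: bool,
                 instrument: InstrumentSpec = DEFAULT_SPEC) -> bool:
    """Probable ICD-11 PGD.

    Requires bereavement, a core symptom (longing, item 3, or
    preoccupation, item 1), at least one accompanying symptom (items 2,
    5, 8, 9, 10, 16, 19, 20, 21, 22), functional impairment (item 13) —
    each rated >= 4 — and a loss more than 6 months ago.
    """
    if months_since_loss is None or (isinstance(months_since_loss, float) and np.isnan(months_since_loss)):
        raise ValueError("months_since_loss is unknown; supply an imputed or floor value")
    _require(row, PGD_B_ITEMS + PGD_C_ITEMS + (PGD_E_ITEM,))
    t = instrument.symptom_threshold_pgd
    return bool(
        bereaved
        and any(row[c] >= t for c in PGD_B_ITEMS)
        and any(row[c] >= t for c in PGD_C_ITEMS)
        and row[PGD_E_ITEM] >= t
        and months_since_loss > instrument.pgd_min_months
    )


def diagnose_ptsd_icd11(row: pd.Series | dict, trauma_flag: bool = True,
                        instrument: InstrumentSpec = DEFAULT_SPEC) -> bool:
    """Probable ICD-11 PTSD from the CAPS item map.

    One symptom per cluster rated >= 2: re-experiencing (CAPS 1 or 2),
    avoidance (CAPS 6 or 7), sense of current threat (CAPS 17 or 18),
    impairment (CAPS 24 or 25); plus Criterion-A trauma and symptom
    duration of more than a couple of weeks (CAPS 22 gate).
    """
    _require(row, ("CAPS_01", "CAPS_02", "CAPS_06", "CAPS_07",
                   "CAPS_17", "CAPS_18", "CAPS_22", "CAPS_24", "CAPS_25"))
    t = instrument.symptom_threshold_ptsd
    duration_ok = bool(row["CAPS_22"] >= 1)
    return bool(
        trauma_flag
        and (row["CAPS_01"] >= t or row["CAPS_02"] >= t)
        and (row["CAPS_06"] >= t or row["CAPS_07"] >= t)
        and (row["CAPS_17"] >= t or row["CAPS_18"] >= t)
        and (row["CAPS_24"] >= t or row["CAPS_25"] >= t)
        and duration_ok
    )


def diagnose_cptsd(row: pd.Series | dict, trauma_flag: bool = True,
                   instrument: InstrumentSpec = DEFAULT_SPEC) -> tuple[bool, bool]:
    """Probable ICD-11 cPTSD; returns (cptsd, ptsd_additional).

    cPTSD requires the PTSD criteria plus, each rated >= 2: affective
    dysregulation (CO1), negative self-concept (CO2), relationship
    disturbance (CO3 or CAPS 13), and impairment (CO4 or CO5). A cPTSD
    case never receives an additional PTSD diagnosis.
    """
    _require(row, COPISAC_ITEMS + ("CAPS_13",))
    ptsd = diagnose_ptsd_icd11(row, trauma_flag, instrument)
    t = instrument.symptom_threshold_ptsd
    cptsd = bool(
        ptsd
        and row["COPISAC_CO1"] >= t
        and row["COPISAC_CO2"] >= t
        and (row["COPISAC_CO3"] >= t or row["CAPS_13"] >= t)
        and (row["COPISAC_CO4"] >= t or row["COPISAC_CO5"] >= t)
    )
    return cptsd, (ptsd and not cptsd)


def diagnose_all(items: pd.DataFrame, metadata: pd.DataFrame,
                 instrument: InstrumentSpec = DEFAULT_SPEC) -> pd.DataFrame:
    """Apply all three algorithms row-wise to a completed dataset."""
    records = []
    for i in range(len(items)):
        row = items.iloc[i]
        meta = metadata.iloc[i]
        sev = score_severity(row, instrument)
        pgd = diagnose_pgd(row, float(meta["MONTHS_SINCE_LOSS"]), bool(meta["BEREAVED"]), instrument)
        cptsd, ptsd_add = diagnose_cptsd(row, bool(meta["TRAUMA_A"]), instrument)
        records.append({"pgd": pgd, "ptsd_icd11": ptsd_add, "cptsd": cptsd, **sev})
    return pd.DataFrame(records, index=items.index)


def prevalence_and_comorbidity(stack: ImputationStack, metadata: pd.DataFrame,
                               instrument: InstrumentSpec = DEFAULT_SPEC) -> dict:
    """Pooled probable prevalence and comorbidity over m imputations.

    Counts are averaged across the completed datasets; proportions are
    relative to N (and, for conditional rates, to the pooled PGD count).
    ``ptsd_icd11`` already excludes cPTSD cases (mutual exclusivity), so
    PGD comorbidity with "PTSD" uses the PTSD-without-cPTSD diagnosis.
    """
    n = stack.datasets[0].n
    keys = ("pgd", "ptsd_icd11", "cptsd", "pgd_and_ptsd", "pgd_and_cptsd")
    counts = {k: [] for k in keys}
    for d in stack.datasets:
        diag = diagnose_all(d.values, metadata, instrument)
        counts["pgd"].append(diag["pgd"].sum())
        counts["ptsd_icd11"].append(diag["ptsd_icd11"].sum())
        counts["cptsd"].append(diag["cptsd"].sum())
        counts["pgd_and_ptsd"].append((diag["pgd"] & diag["ptsd_icd11"]).sum())
        counts["pgd_and_cptsd"].append((diag["pgd"] & diag["cptsd"]).sum())
    pooled = {k: float(np.mean(v)) for k, v in counts.items()}
    out = {
        "n": n,
        "m": stack.m,
        "pooled_counts": pooled,
        # reported n is the pooled count rounded half-up
        "pooled_n": {k: int(np.floor(v + 0.5)) for k, v in pooled.items()},
        "proportions_pct": {k: 100.0 * v / n for k, v in pooled.items()},
    }
    pgd_count = pooled["pgd"]
    out["conditional_on_pgd_pct"] = {
        "ptsd_icd11": 100.0 * pooled["pgd_and_ptsd"] / pgd_count if pgd_count else 0.0,
        "cptsd": 100.0 * pooled["pgd_and_cptsd"] / pgd_count if pgd_count else 0.0,
    }
    return out


@dataclass
class ReliabilityResult:
    omega_total: float
    loadings: np.ndarray = field(default_factory=lambda: np.array([]))
    error_variances: np.ndarray = field(default_factory=lambda: np.array([]))


def mcdonald_omega(items: pd.DataFrame | np.ndarray, max_iter: int = 2000) -> ReliabilityResult:
    """McDonald's omega-total from a one-factor model.

    Items are standardized and a single-factor maximum-likelihood factor
    model is fitted (correlation-matrix metric); omega_total =
    (sum lambda)^2 / ((sum lambda)^2 + sum psi). Negative error
    variances (Heywood cases) are clipped at zero with a warning.
    """
    X = np.asarray(items, dtype=float)
    n, k = X.shape
    if k < 3:
        raise ValueError("McDonald's omega needs at least 3 items (one-factor identification)")
    if n <= k:
        raise ValueError("need more observations than items")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant item; omega undefined")
    Z = (X - X.mean(axis=0)) / sd

    from sklearn.decomposition import FactorAnalysis

    fa = FactorAnalysis(n_components=1, max_iter=max_iter, tol=1e-8, random_state=0)
    fa.fit(Z)
    if fa.n_iter_ >= max_iter:
        raise RuntimeError("one-factor model did not converge")
    lam = fa.components_.ravel()
    if lam.sum() < 0:  # fix the factor's sign
        lam = -lam
    psi = fa.noise_variance_.copy()
    if np.any(psi < 0):
        warnings.warn("Heywood case: negative error variance clipped at 0")
        psi = np.maximum(psi, 0.0)
    s = lam.sum()
    omega = s**2 / (s**2 + psi.sum())
    return ReliabilityResult(float(omega), lam, psi)
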