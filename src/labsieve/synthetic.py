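"""Synthetic lab-cohort generator with known ground truth.

Hospital lab extracts cannot be redistributed, so the pipeline is exercised
on synthetic cohorts that reproduce the statistical structure the analysis
has to cope with:

* a case × analyte matrix with one fully observed dominant diagnostic
  analyte (a troponin analog, on every request of the differential-diagnosis
  cohort by construction);
* heavily right-skewed analyte value distributions, calibrated so each
  analyte's sample median and IQR approach published-style targets;
* a probit-link outcome generated from known standardized coefficients on
  the latent (log-scale for skewed analytes) values, so recovery can be
  scored against ground truth;
* tiered missingness (MCAR, or MAR with hiding probability increasing in
  the latent severity) emulating the 20/40/60/80% sparsity structure of a
  retrospective lab matrix; and
* a derived analyte — the CKD-EPI estimated glomerular filtration rate —
  computed deterministically from creatinine, age and sex.

Correlation between analytes is induced by a single shared latent severity
factor; each analyte's latent value is loading * severity plus independent
noise, the simplest structure that makes imputation non-trivial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, ndtr

from .records import CohortLabels, LabMatrix

#: interquartile width of the standard normal (q75 - q25)
_NORMAL_IQR = 1.3489795003921634
#: micromol/L of creatinine per mg/dL
_CREA_UMOL_PER_MGDL = 88.4

IN_RANGE_CODES = ("I21.0", "I21.4", "I20.0", "I25.1", "I25.9")
OUT_RANGE_CODES = ("E11.9", "J18.9", "K52.9", "Z03.8", "M54.5")


@dataclass
class AnalyteSpec:
    """Target distribution, outcome effect and observability of one analyte."""

    name: str
    family: str  # "lognormal" | "normal" | "binary"
    median: float = 0.0
    iqr: float = 0.0
    unit: str = ""
    true_coefficient: float = 0.0  # standardized probit coefficient
    coverage_target: float = 1.0
    missingness: str = "MCAR"  # or "MAR_on_severity"
    loading: float = 0.3  # on the shared latent severity factor
    derived_from: str | None = None  # e.g. "ckdepi"
    tokens: tuple[str, str] = ("arterial", "venous")

    def __post_init__(self) -> None:
        if self.family == "lognormal" and self.derived_from is None and self.median <= 0:
            raise ValueError(f"{self.name}: lognormal needs a positive median")
        if not 0.0 < self.coverage_target <= 1.0:
            raise ValueError(f"{self.name}: coverage_target must be in (0, 1]")
        if self.missingness not in ("MCAR", "MAR_on_severity"):
            raise ValueError(f"{self.name}: unknown missingness {self.missingness!r}")


@dataclass
class GeneratorConfig:
    seed: int
    n_cases: int = 2000
    prevalence: float = 0.1
    analyte_specs: list[AnalyteSpec] = field(default_factory=lambda: default_panel())

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")


@dataclass
class CohortTruth:
    """Ground truth retained for recovery scoring."""

    coefficients: dict[str, float]
    alpha0: float
    linear_predictor: np.ndarray
    severity: np.ndarray
    latent: pd.DataFrame  # standardized latent values per analyte
    age: np.ndarray
    female: np.ndarray
    diagnoses: dict[str, list[str]]


def default_panel() -> list[AnalyteSpec]:
    """The default ~30-analyte panel.

    Median/IQR targets follow published myocardial-ischemia cohort values
    where available and plausible reference-interval values otherwise; the
    coverage targets recreate the nested 8/16/23/30 tier widths of a
    retrospective matrix.  Four analytes carry nonzero standardized probit
    coefficients, the troponin analog dominant at 2.0.
    """
    A = AnalyteSpec
    return [
        # coverage >= 0.8 (20%-sparsity tier)
        A("troponin_t", "lognormal", 25.0, 78.62, "ng/L", true_coefficient=2.0,
          coverage_target=1.0, loading=0.5),
        A("potassium", "normal", 4.1, 0.5, "mmol/L", true_coefficient=0.7, coverage_target=0.93),
        A("sodium", "normal", 140.0, 6.0, "mmol/L", coverage_target=0.92),
        A("glucose", "lognormal", 6.0, 2.1, "mmol/L", coverage_target=0.90),
        A("creatinine", "lognormal", 80.0, 40.0, "µmol/L", coverage_target=0.90),
        A("creatine_kinase", "lognormal", 103.0, 154.0, "U/L", coverage_target=0.85),
        A("hemoglobin", "normal", 138.0, 25.0, "g/L", coverage_target=0.85),
        A("leukocytes", "lognormal", 8.7, 4.5, "G/L", coverage_target=0.82),
        # coverage >= 0.6 (40%-sparsity tier)
        A("urea", "lognormal", 5.9, 4.4, "mmol/L", true_coefficient=0.5, coverage_target=0.75),
        A("rdw", "normal", 13.5, 1.9, "%", true_coefficient=0.5, coverage_target=0.75),
        A("egfr", "normal", 84.0, 39.0, "mL/min/1.73m2", coverage_target=0.70,
          derived_from="ckdepi"),
        A("inr", "lognormal", 1.01, 0.07, "", coverage_target=0.72),
        A("crp", "lognormal", 5.0, 25.0, "mg/L", coverage_target=0.70),
        A("thrombocytes", "normal", 240.0, 100.0, "G/L", coverage_target=0.68),
        A("aptt", "normal", 29.0, 6.0, "s", coverage_target=0.65),
        A("collection_type", "binary", coverage_target=0.65),
        # coverage >= 0.4 (60%-sparsity tier)
        A("calcium_total", "normal", 2.24, 0.2, "mmol/L", coverage_target=0.55),
        A("chloride", "normal", 107.0, 7.0, "mmol/L", coverage_target=0.55),
        A("bilirubin", "lognormal", 8.0, 10.0, "µmol/L", coverage_target=0.50),
        A("alat", "lognormal", 28.0, 25.0, "U/L", coverage_target=0.50),
        A("asat", "lognormal", 30.0, 22.0, "U/L", coverage_target=0.45),
        A("ggt", "lognormal", 35.0, 45.0, "U/L", coverage_target=0.45),
        A("thrombin_time", "lognormal", 16.1, 2.5, "s", coverage_target=0.42),
        # coverage >= 0.2 (80%-sparsity tier)
        A("ck_mb_mass", "lognormal", 4.6, 11.5, "µg/L", coverage_target=0.38,
          missingness="MAR_on_severity"),
        A("hdl_cholesterol", "normal", 1.23, 0.55, "mmol/L", coverage_target=0.35),
        A("ldl_cholesterol", "normal", 2.25, 1.38, "mmol/L", coverage_target=0.35),
        A("mcv", "normal", 86.0, 7.0, "fl", coverage_target=0.30),
        A("mch", "normal", 30.0, 3.0, "pg", coverage_target=0.30),
        A("mchc", "normal", 343.0, 17.0, "g/L", coverage_target=0.28),
        A("fio2", "lognormal", 32.0, 43.0, "mmHg", coverage_target=0.25,
          missingness="MAR_on_severity"),
    ]


def ckdepi_egfr(
    scr_mg_dl: np.ndarray | float,
    age_years: np.ndarray | float,
    female: np.ndarray | bool,
    black: np.ndarray | bool = False,
) -> np.ndarray | float:
    """CKD-EPI estimated glomerular filtration rate (mL/min/1.73 m²).

    eGFR = 141 * min(Scr/k, 1)^a * max(Scr/k, 1)^(-1.209) * 0.993^Age
           * 1.018 (if female) * 1.159 (if black),

    with Scr serum creatinine in mg/dL, k = 0.7 (female) / 0.9 (male),
    a = -0.329 (female) / -0.411 (male).
    """
    scr = np.asarray(scr_mg_dl, dtype=float)
    if np.any(scr <= 0):
        raise ValueError("serum creatinine must be positive")
    age = np.asarray(age_years, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be non-negative")
    fem = np.asarray(female, dtype=bool)
    blk = np.asarray(black, dtype=bool)
    kappa = np.where(fem, 0.7, 0.9)
    a = np.where(fem, -0.329, -0.411)
    ratio = scr / kappa
    egfr = (
        141.0
        * np.minimum(ratio, 1.0) ** a
        * np.maximum(ratio, 1.0) ** (-1.209)
        * 0.993**age
        * np.where(fem, 1.018, 1.0)
        * np.where(blk, 1.159, 1.0)
    )
    return egfr if egfr.ndim else float(egfr)


def _lognormal_sigma(median: float, iqr: float) -> float:
    # IQR = median * 2 sinh(z75 * sigma) with z75 = 0.6745
    z75 = _NORMAL_IQR / 2.0
    return float(np.arcsinh(iqr / (2.0 * median)) / z75)


def _values_from_latent(spec: AnalyteSpec, z: np.ndarray) -> np.ndarray:
    if spec.family == "lognormal":
        return spec.median * np.exp(_lognormal_sigma(spec.median, spec.iqr) * z)
    if spec.family == "normal":
        return spec.median + (spec.iqr / _NORMAL_IQR) * z
    raise ValueError(f"no value map for family {spec.family!r}")


def generate_cohort(config: GeneratorConfig) -> tuple[LabMatrix, CohortLabels, CohortTruth]:
    """Draw a complete (no missingness) cohort with known ground truth.

    Latent standardized values z_j = loading_j * severity + noise feed both
    the analyte values (through each family's quantile map) and the probit
    outcome: eta = sum_j c_j z_j with the intercept solved numerically so the
    sample mean of Phi(alpha0 + eta) hits the prevalence target.  Derived
    analytes are computed from their parents after the parents are drawn.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    specs = config.analyte_specs
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate analyte names in panel")

    severity = rng.standard_normal(n)
    latent = np.empty((n, len(specs)))
    for j, s in enumerate(specs):
        noise = rng.standard_normal(n)
        latent[:, j] = s.loading * severity + np.sqrt(1.0 - s.loading**2) * noise

    age = np.clip(rng.normal(65.0, 15.0, size=n), 18.0, 100.0)
    female = rng.uniform(size=n) < 0.45

    # outcome from the standardized latents of non-derived continuous analytes
    eta = np.zeros(n)
    coefficients: dict[str, float] = {}
    for j, s in enumerate(specs):
        coefficients[s.name] = s.true_coefficient
        if s.true_coefficient != 0.0:
            if s.family == "binary" or s.derived_from is not None:
                raise ValueError(
                    f"{s.name}: nonzero coefficients are supported for "
                    "continuous non-derived analytes only"
                )
            eta += s.true_coefficient * latent[:, j]

    def excess(a: float) -> float:
        return float(np.mean(ndtr(a + eta))) - config.prevalence

    if excess(-35.0) > 0 or excess(35.0) < 0:
        raise ValueError(f"prevalence target {config.prevalence} unreachable")
    alpha0 = brentq(excess, -35.0, 35.0, xtol=1e-10)
    y = (rng.uniform(size=n) < ndtr(alpha0 + eta)).astype(int)

    values = np.empty((n, len(specs)))
    encoding_map: dict[str, dict[str, int]] = {}
    for j, s in enumerate(specs):
        if s.derived_from == "ckdepi":
            if "creatinine" not in names:
                raise ValueError("ckdepi-derived analyte needs a 'creatinine' parent")
            crea = values[:, names.index("creatinine")]
            values[:, j] = ckdepi_egfr(crea / _CREA_UMOL_PER_MGDL, age, female)
        elif s.family == "binary":
            # two-level token; sorted-first token encodes to 1
            arterial = latent[:, j] > float(np.quantile(latent[:, j], 0.7))
            values[:, j] = arterial.astype(float)
            t0, t1 = sorted(s.tokens)
            encoding_map[s.name] = {t0: 1, t1: 0}
        else:
            values[:, j] = _values_from_latent(s, latent[:, j])

    cases = [f"case{i:06d}" for i in range(n)]
    matrix = LabMatrix(
        values=values,
        observed_mask=np.ones_like(values, dtype=bool),
        cases=cases,
        analytes=names,
        analyte_names={s.name: s.name.replace("_", " ") for s in specs},
        units={s.name: s.unit for s in specs},
        encoding_map=encoding_map,
    )

    diagnoses: dict[str, list[str]] = {}
    for i, c in enumerate(cases):
        codes = [str(rng.choice(OUT_RANGE_CODES))]
        if y[i]:
            codes.append(str(rng.choice(IN_RANGE_CODES)))
        diagnoses[c] = codes
    labels = CohortLabels({c: int(v) for c, v in zip(cases, y)})

    truth = CohortTruth(
        coefficients=coefficients,
        alpha0=float(alpha0),
        linear_predictor=eta,
        severity=severity,
        latent=pd.DataFrame(latent, index=cases, columns=names),
        age=age,
        female=female,
        diagnoses=diagnoses,
    )
    return matrix, labels, truth


def apply_missingness(
    complete: LabMatrix,
    specs: list[AnalyteSpec],
    seed: int,
    severity: np.ndarray | None = None,
) -> LabMatrix:
    """Hide cells per analyte to reach each spec's coverage target.

    MCAR hides cells independently at rate 1 - coverage; MAR_on_severity
    makes the hiding probability logistic in the latent severity (sicker
    patients get the rarer tests ordered, so their values are *observed*
    more often), with the offset solved so the marginal rate still matches
    the target.  Fully covered analytes — the troponin analog — are never
    touched.
    """
    rng = np.random.default_rng(seed)
    by_name = {s.name: s for s in specs}
    mask = complete.observed_mask.copy()
    n = complete.n_cases
    for j, a in enumerate(complete.analytes):
        s = by_name.get(a)
        if s is None or s.coverage_target >= 1.0:
            continue
        rate = 1.0 - s.coverage_target
        if s.missingness == "MCAR":
            hide = rng.uniform(size=n) < rate
        else:
            if severity is None:
                raise ValueError(f"{a}: MAR_on_severity needs the latent severity")
            sev = np.asarray(severity, dtype=float)

            def mean_hide(b: float) -> float:
                return float(np.mean(expit(b - sev))) - rate

            offset = brentq(mean_hide, -40.0, 40.0, xtol=1e-10)
            hide = rng.uniform(size=n) < expit(offset - sev)
        mask[hide, j] = False
    values = complete.values.copy()
    values[~mask] = np.nan
    return LabMatrix(
        values=values,
        observed_mask=mask,
        cases=list(complete.cases),
        analytes=list(complete.analytes),
        analyte_names=dict(complete.analyte_names),
        units=dict(complete.units),
        encoding_map=dict(complete.encoding_map),
    )


def generate_dataset(config: GeneratorConfig) -> tuple[LabMatrix, CohortLabels, CohortTruth]:
    """Complete cohort + missingness in one call (sparse matrix out)."""
    complete, labels, truth = generate_cohort(config)
    sparse = apply_missingness(
        complete, config.analyte_specs, seed=config.seed + 1, severity=truth.linear_predictor
    )
    return sparse, labels, truth


def write_fixture(
    out_dir: str | Path,
    matrix: LabMatrix,
    truth: CohortTruth,
) -> dict[str, Path]:
    """Emit the long-format record/diagnosis/truth files records ingestion reads.

    Only observed cells become record rows; encoded binary analytes are
    written back as their tokens, so a parse → build round trip reproduces
    the matrix.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    decode = {
        a: {code: tok for tok, code in m.items()} for a, m in matrix.encoding_map.items()
    }
    rows = []
    for i, case in enumerate(matrix.cases):
        for j, a in enumerate(matrix.analytes):
            if not matrix.observed_mask[i, j]:
                continue
            v = matrix.values[i, j]
            value = decode[a][int(v)] if a in decode else repr(float(v))
            rows.append(
                (case, a, matrix.analyte_names.get(a, a), value, matrix.units.get(a, ""), j)
            )
    records_path = out_dir / "lab_records.tsv"
    pd.DataFrame(
        rows, columns=["case_id", "analyte_id", "analyte_name", "value", "unit", "timestamp"]
    ).to_csv(records_path, sep="\t", index=False)

    diagnoses_path = out_dir / "diagnoses.tsv"
    pd.DataFrame(
        [(c, ";".join(codes)) for c, codes in truth.diagnoses.items()],
        columns=["case_id", "icd10_codes"],
    ).to_csv(diagnoses_path, sep="\t", index=False)

    truth_path = out_dir / "truth.tsv"
    pd.DataFrame(
        sorted(truth.coefficients.items()), columns=["analyte_id", "true_coefficient"]
    ).to_csv(truth_path, sep="\t", index=False)
    return {"records": records_path, "diagnoses": diagnoses_path, "truth": truth_path}
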