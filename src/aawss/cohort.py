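"""Patient cohort ingestion and summary statistics.

Reads a cohort table (one row per patient: demographics, comorbidity
flags, last-CT aneurysm diameter, the reported range bin of each WSS
index at the rupture site, intraluminal-thrombus group, aneurysm shape
and rupture status) and reproduces the descriptive statistics: comorbidity
prevalences overall and per ILT group, per-parameter bin histograms, the
share of ruptured cases at or under the 5.5 cm surgical threshold, and
mean ages.  Percentages are rounded half-up to one decimal, matching the
conventional reporting style.  No inferential statistics are computed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .datasets import cohort_table_path
from .risk import DEFAULT_BINS, bin_label

COMORBIDITIES = ("htn", "dyslip", "dm", "cad", "vasculitis", "smoking")

VALID_BINS = {par: [bin_label(lo, hi) for lo, hi in bins]
              for par, bins in DEFAULT_BINS.items()}

_REQUIRED = ["patient", "age", "sex", *COMORBIDITIES, "size_cm",
             "tawss_bin", "osi_bin", "ecap_bin", "rrt_bin",
             "ilt_group", "shape", "status"]


@dataclass(frozen=True)
class PatientRecord:
    patient: int
    age: float
    sex: str                 # M | F
    comorbidities: dict      # flag per condition
    size_cm: float           # AAA diameter at last CT
    bins: dict               # parameter -> reported range label
    ilt_group: str           # low | high
    shape: str               # fusiform | saccular
    status: str              # ruptured | impending

    def __post_init__(self):
        if self.age <= 0 or self.size_cm <= 0:
            raise ValueError(
                f"patient {self.patient}: age and size must be positive")
        if self.sex not in ("M", "F"):
            raise ValueError(f"patient {self.patient}: sex must be M or F")
        if self.ilt_group not in ("low", "high"):
            raise ValueError(f"patient {self.patient}: ilt_group invalid")
        if self.shape not in ("fusiform", "saccular"):
            raise ValueError(f"patient {self.patient}: shape invalid")
        if self.status not in ("ruptured", "impending"):
            raise ValueError(f"patient {self.patient}: status invalid")
        for par, label in self.bins.items():
            if label not in VALID_BINS[par]:
                raise ValueError(
                    f"patient {self.patient}: unknown {par} bin {label!r}; "
                    f"expected one of {VALID_BINS[par]}")


def load_cohort(path=None) -> list[PatientRecord]:
    """Parse and validate a cohort CSV; defaults to the packaged table."""
    if path is None:
        path = io.StringIO(cohort_table_path().read_text())
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError("cohort table is empty")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        flags = {c: str(row[c]).strip().lower() in ("yes", "y", "1", "true")
                 for c in COMORBIDITIES}
        records.append(PatientRecord(
            patient=int(row["patient"]), age=float(row["age"]),
            sex=str(row["sex"]).strip(), comorbidities=flags,
            size_cm=float(row["size_cm"]),
            bins={par: str(row[f"{par}_bin"]).strip()
                  for par in ("tawss", "osi", "ecap", "rrt")},
            ilt_group=str(row["ilt_group"]).strip().lower(),
            shape=str(row["shape"]).strip().lower(),
            status=str(row["status"]).strip().lower()))
    return records


def round1(x: float) -> float:
    """Half-up rounding to one decimal (printed-style percentages)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"),
                                           rounding=ROUND_HALF_UP))


def prevalence(records: list[PatientRecord], condition: str,
               ilt_group: str | None = None) -> float:
    """Percent of (optionally ILT-group-filtered) patients with the
    comorbidity, to one decimal."""
    sel = [r for r in records if ilt_group is None or r.ilt_group == ilt_group]
    if not sel:
        raise ValueError("empty selection")
    n_with = sum(r.comorbidities[condition] for r in sel)
    return round1(100.0 * n_with / len(sel))


def bin_histogram(records: list[PatientRecord], parameter: str,
                  ilt_group: str | None = None) -> dict:
    """Counts and percents per reported range of one parameter."""
    sel = [r for r in records if ilt_group is None or r.ilt_group == ilt_group]
    if not sel:
        raise ValueError("empty selection")
    counts = {label: 0 for label in VALID_BINS[parameter]}
    for r in sel:
        counts[r.bins[parameter]] += 1
    n = len(sel)
    return {"n": n, "counts": counts,
            "percents": {k: round1(100.0 * v / n) for k, v in counts.items()}}


def size_rupture_stats(records: list[PatientRecord],
                       threshold_cm: float = 5.5) -> dict:
    """Ruptured cases at/below the diameter threshold, plus mean ages."""
    ruptured = [r for r in records if r.status == "ruptured"]
    small = [r for r in ruptured if r.size_cm <= threshold_cm]
    ages = [r.age for r in records]
    out = {
        "n": len(records),
        "n_ruptured": len(ruptured),
        "n_impending": len(records) - len(ruptured),
        "n_ruptured_small": len(small),
        "pct_ruptured_small": round1(100.0 * len(small) / len(ruptured))
        if ruptured else None,
        "mean_age": round1(sum(ages) / len(ages)),
    }
    for sex in ("M", "F"):
        a = [r.age for r in records if r.sex == sex]
        out[f"mean_age_{sex}"] = round1(sum(a) / len(a)) if a else None
        out[f"n_{sex}"] = len(a)
    return out


def summarize(records: list[PatientRecord]) -> dict:
    """Full cohort summary: prevalences (overall and per ILT group),
    per-parameter histograms, size/rupture and age statistics."""
    summary = {
        "prevalence": {c: prevalence(records, c) for c in COMORBIDITIES},
        "prevalence_by_ilt": {
            g: {c: prevalence(records, c, g) for c in COMORBIDITIES}
            for g in ("low", "high")},
        "histograms": {p: bin_histogram(records, p)
                       for p in ("tawss", "osi", "ecap", "rrt")},
        "size_rupture": size_rupture_stats(records),
    }
    return summary
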