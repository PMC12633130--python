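"""Feature schema and cohort container for the oropharyngeal-cancer twin.

Patients are described by five variable groups that structure the treatment
process: pre-treatment features (PTF), first-cycle interventions (ACTIONS),
post-intervention outcomes (PIO), patient-reported symptom scores (PRS,
MDASI-HN 0-10 scale), and treatment-plan outcomes (TPO, year-3 relapse).

A :class:`Cohort` is a patient-by-feature table with an explicit missingness
mask; missing cells carry no value.  Two kinds of missingness occur: random
(e.g. unlabeled year-3 outcomes) and structural (post-surgical pathology such
as extranodal extension exists only for patients who had definitive surgery).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GROUPS = ("PTF", "ACTIONS", "PIO", "PRS", "TPO")

#: column-name cleanups for the two misspelled registry variables; offered at
#: I/O, never applied silently (the canonical names keep the registry printout
#: traceable).
CLEAN_ALIASES = {
    "status_at_enrollememt": "status_at_enrollment",
    "p16_hpv_postive": "p16_hpv_positive",
}


@dataclass(frozen=True)
class MissingPolicy:
    """How a feature may be missing.

    kind: 'never', 'random', or 'structural'.  Structural features are
    observed only when ``condition_feature`` takes one of
    ``condition_values`` (e.g. ENE requires definitive == 'yes').
    """

    kind: str = "never"
    condition_feature: str | None = None
    condition_values: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in ("never", "random", "structural"):
            raise ValueError(f"unknown missing policy kind: {self.kind!r}")
        if self.kind == "structural" and not self.condition_feature:
            raise ValueError("structural policy requires a condition feature")


NEVER = MissingPolicy("never")
RANDOM = MissingPolicy("random")


def structural(feature: str, *values: str) -> MissingPolicy:
    return MissingPolicy("structural", feature, tuple(values))


@dataclass(frozen=True)
class FeatureSpec:
    """One registry variable: its group, type, and marginal description."""

    name: str
    group: str
    kind: str  # 'categorical' | 'numerical'
    categories: tuple[str, ...] = ()
    mean: float | None = None
    sd: float | None = None
    bounds: tuple[float | None, float | None] | None = None
    integer: bool = False
    missing_policy: MissingPolicy = NEVER

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"{self.name}: unknown group {self.group!r}")
        if self.kind == "categorical":
            if len(self.categories) < 2:
                raise ValueError(f"{self.name}: categorical needs >=2 categories")
            if self.mean is not None or self.sd is not None:
                raise ValueError(f"{self.name}: categorical spec carries moments")
        elif self.kind == "numerical":
            if self.categories:
                raise ValueError(f"{self.name}: numerical spec carries categories")
            if self.mean is None or self.sd is None:
                raise ValueError(f"{self.name}: numerical spec needs mean and sd")
            if self.sd < 0:
                raise ValueError(f"{self.name}: sd must be >= 0")
        else:
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")
        if self.bounds is not None:
            lo, hi = self.bounds
            if lo is not None and hi is not None and not lo < hi:
                raise ValueError(f"{self.name}: bounds need lo < hi")

    @property
    def is_categorical(self) -> bool:
        return self.kind == "categorical"


class FeatureSchema:
    """Ordered registry of :class:`FeatureSpec` with unique names."""

    def __init__(self, features: Iterable[FeatureSpec]):
        self.features: tuple[FeatureSpec, ...] = tuple(features)
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in schema")
        self._by_name = {f.name: f for f in self.features}

    def __iter__(self):
        return iter(self.features)

    def __len__(self):
        return len(self.features)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> FeatureSpec:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def group(self, group: str) -> list[FeatureSpec]:
        return [f for f in self.features if f.group == group]

    def group_names(self, group: str) -> list[str]:
        return [f.name for f in self.features if f.group == group]

    def subset(self, names: Sequence[str]) -> "FeatureSchema":
        return FeatureSchema([self._by_name[n] for n in names])

    # -- JSON round trip ---------------------------------------------------
    def to_json(self) -> str:
        def enc(f: FeatureSpec) -> dict:
            d: dict = {"name": f.name, "group": f.group, "kind": f.kind}
            if f.is_categorical:
                d["categories"] = list(f.categories)
            else:
                d["mean"], d["sd"] = f.mean, f.sd
            if f.bounds is not None:
                d["bounds"] = list(f.bounds)
            if f.integer:
                d["integer"] = True
            mp = f.missing_policy
            if mp.kind != "never":
                d["missing_policy"] = {
                    "kind": mp.kind,
                    "condition_feature": mp.condition_feature,
                    "condition_values": list(mp.condition_values),
                }
            return d

        return json.dumps([enc(f) for f in self.features], indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FeatureSchema":
        specs = []
        for d in json.loads(text):
            mp = d.get("missing_policy")
            policy = NEVER
            if mp is not None:
                policy = MissingPolicy(
                    mp["kind"], mp.get("condition_feature"),
                    tuple(mp.get("condition_values", ())),
                )
            specs.append(
                FeatureSpec(
                    name=d["name"],
                    group=d["group"],
                    kind=d["kind"],
                    categories=tuple(d.get("categories", ())),
                    mean=d.get("mean"),
                    sd=d.get("sd"),
                    bounds=tuple(d["bounds"]) if d.get("bounds") else None,
                    integer=d.get("integer", False),
                    missing_policy=policy,
                )
            )
        return cls(specs)


# ---------------------------------------------------------------------------
# Default schema: the registry variables with their printed marginals.
# Counts/moments are the all-patients (N=676) column of the registry tables;
# swallow/taste score moments are documented package defaults (the registry
# prints only fatigue and drymouth).
# ---------------------------------------------------------------------------

#: categorical marginals as raw counts over N=676 (kept as counts, not
#: probabilities, so the printed table stays recognizable).
CATEGORICAL_COUNTS: dict[str, dict[str, int]] = {
    "gender": {"Male": 616, "Female": 60},
    "ethnicity": {"Not Hispanic or Latino": 612, "Hispanic or Latino": 49, "Unknown": 15},
    "race": {
        "White": 640, "Black or African American": 14, "Other Race": 17,
        "Asian": 4, "American Indian/Alaska Native": 1,
    },
    "smoking_status": {"4": 290, "5": 344, "1": 26, "2": 5, "7": 6, "9": 2, "10": 3},
    "site_of_tumor": {
        "BOT": 337, "NOS": 10, "Tonsil": 312, "Soft Palate": 8,
        "GPS": 6, "Pharyngeal Wall": 3,
    },
    "ajcc_version": {"7th Version": 48, "8th Version": 628},
    "p16_hpv_postive": {"Yes": 596, "No": 56, "Unknown": 24},
    "tumor_laterality": {"Right": 345, "Left": 314, "Bilateral": 17},
    "t_nominal": {"t0": 9, "t1": 223, "t2": 243, "t3": 116, "t4": 82, "tx": 3},
    "n_nominal": {
        "n0": 54, "n1": 446, "n2a": 4, "n2b": 35, "n2": 94,
        "n2c": 23, "n3": 18, "nx": 2,
    },
    "m": {"m0": 661, "mx": 10, "m1": 5},
    "status_at_enrollememt": {"Previously_Untreated": 605, "Previously_Treated": 71},
    "definitive": {"no": 609, "yes": 67},
    "induction": {"no": 600, "yes": 76},
    "radio/chemo": {"no": 29, "yes": 174, "yes-with-concurrent-chemotherapy": 473},
    # PIO pathology conditional on definitive surgery (67 surgical patients;
    # the remaining 'Unknown' mass in the registry is the non-surgical group).
    "ENE": {"Positive": 50, "Negative": 13, "Unknown": 4},
    "Margin": {
        "Negative": 38, "Positive": 14, "<1mm": 3, "<2mm": 1,
        "<1m": 1, "<2m": 1, "1mm": 1,
    },
    "rt_type": {"IMPT": 165, "Vmat": 389, "IMRT": 105, "3d Conformal": 2, "Other": 15},
    "relapse_yr3": {"False": 153, "True": 35},
}

#: numerical marginals (mean, sd) from the registry printout; swallow/taste
#: entries are package defaults chosen to resemble the printed fatigue /
#: drymouth trajectories (spike at end of radiotherapy, partial recovery).
NUMERICAL_MOMENTS: dict[str, tuple[float, float]] = {
    "age": (60.49, 8.92),
    "tobacco_packs_per_day": (0.65, 0.72),
    "tobacco_used_years": (13.49, 15.47),
    "pack_years": (14.99, 22.78),
    "rt_dose": (6823.85, 307.80),
    "rt_fraction": (32.56, 1.27),
    "mdasi_baseline_fatigue": (2.00, 2.36),
    "mdasi_baseline_drymouth": (1.08, 2.02),
    "mdasi_baseline_swallow": (1.00, 1.90),   # package default
    "mdasi_baseline_taste": (0.80, 1.80),     # package default
    "mdasi_endrt_fatigue": (4.67, 2.62),
    "mdasi_endrt_drymouth": (4.97, 2.96),
    "mdasi_endrt_swallow": (4.50, 2.90),      # package default
    "mdasi_endrt_taste": (4.60, 3.00),        # package default
    "mdasi_wk6_fatigue": (3.01, 2.38),
    "mdasi_wk6_drymouth": (4.04, 2.78),
    "mdasi_wk6_swallow": (3.20, 2.60),        # package default
    "mdasi_wk6_taste": (3.50, 2.80),          # package default
    "mdasi_m3_fatigue": (2.05, 2.14),
    "mdasi_m3_drymouth": (4.22, 2.79),
    "mdasi_m3_swallow": (2.40, 2.30),         # package default
    "mdasi_m3_taste": (2.80, 2.60),           # package default
    "mdasi_m12_fatigue": (1.76, 1.99),
    "mdasi_m12_drymouth": (3.35, 2.69),
    "mdasi_m12_swallow": (2.00, 2.20),        # package default
    "mdasi_m12_taste": (2.30, 2.40),          # package default
}

SYMPTOMS = ("fatigue", "drymouth", "swallow", "taste")
TIMEPOINTS = ("endrt", "wk6", "m3", "m12")

_RT_GIVEN = structural("radio/chemo", "yes", "yes-with-concurrent-chemotherapy")
_SURGERY_GIVEN = structural("definitive", "yes")


def default_schema() -> FeatureSchema:
    """The 45-feature registry schema across the five variable groups."""

    def cat(name, group, policy=NEVER):
        return FeatureSpec(
            name=name, group=group, kind="categorical",
            categories=tuple(CATEGORICAL_COUNTS[name]), missing_policy=policy,
        )

    def num(name, group, bounds=None, integer=False, policy=NEVER):
        mean, sd = NUMERICAL_MOMENTS[name]
        return FeatureSpec(
            name=name, group=group, kind="numerical", mean=mean, sd=sd,
            bounds=bounds, integer=integer, missing_policy=policy,
        )

    specs: list[FeatureSpec] = [
        num("age", "PTF"),
        cat("gender", "PTF"),
        cat("ethnicity", "PTF"),
        cat("race", "PTF"),
        cat("smoking_status", "PTF"),
        num("tobacco_packs_per_day", "PTF", bounds=(0.0, None)),
        num("tobacco_used_years", "PTF", bounds=(0.0, None)),
        num("pack_years", "PTF", bounds=(0.0, None)),
        cat("site_of_tumor", "PTF"),
        cat("ajcc_version", "PTF"),
        cat("p16_hpv_postive", "PTF"),
        cat("tumor_laterality", "PTF"),
        cat("t_nominal", "PTF"),
        cat("n_nominal", "PTF"),
        cat("m", "PTF"),
        cat("status_at_enrollememt", "PTF"),
    ]
    for s in SYMPTOMS:
        specs.append(num(f"mdasi_baseline_{s}", "PTF", bounds=(0.0, 10.0), integer=True))
    specs += [
        cat("definitive", "ACTIONS"),
        cat("induction", "ACTIONS"),
        cat("radio/chemo", "ACTIONS"),
        cat("ENE", "PIO", policy=_SURGERY_GIVEN),
        cat("Margin", "PIO", policy=_SURGERY_GIVEN),
        cat("rt_type", "PIO", policy=_RT_GIVEN),
        num("rt_dose", "PIO", bounds=(0.0, None), policy=_RT_GIVEN),
        num("rt_fraction", "PIO", bounds=(0.0, None), integer=True, policy=_RT_GIVEN),
    ]
    for t in TIMEPOINTS:
        for s in SYMPTOMS:
            specs.append(
                num(f"mdasi_{t}_{s}", "PRS", bounds=(0.0, 10.0), integer=True,
                    policy=RANDOM)
            )
    specs.append(cat("relapse_yr3", "TPO", policy=RANDOM))
    return FeatureSchema(specs)


# ---------------------------------------------------------------------------
# Cohort container
# ---------------------------------------------------------------------------

class Cohort:
    """Patient-by-feature table; missing cells are NaN and mirrored in a mask.

    Categorical values are stored as string labels, numerical as floats.
    """

    def __init__(self, values: pd.DataFrame):
        values = values.copy()
        values.index.name = "patient_id"
        self.values = values

    @property
    def patient_ids(self) -> pd.Index:
        return self.values.index

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, col: str) -> pd.Series:
        return self.values[col]

    def observed(self, col: str) -> pd.Series:
        s = self.values[col]
        return s[s.notna()]

    def subset_columns(self, names: Sequence[str]) -> "Cohort":
        return Cohort(self.values[list(names)])

    def subset_rows(self, ids) -> "Cohort":
        return Cohort(self.values.loc[ids])

    def equals(self, other: "Cohort") -> bool:
        a, b = self.values, other.values
        if a.shape != b.shape or list(a.columns) != list(b.columns):
            return False
        if not a.index.equals(b.index):
            return False
        for col in a.columns:
            x, y = a[col], b[col]
            if not x.isna().equals(y.isna()):
                return False
            xo, yo = x.dropna(), y.dropna()
            if x.dtype.kind == "f" or y.dtype.kind == "f":
                if not np.allclose(xo.astype(float), yo.astype(float),
                                   rtol=0, atol=1e-12):
                    return False
            elif not (xo == yo).all():
                return False
        return True


@dataclass
class Violation:
    feature: str
    patient_id: object
    kind: str  # 'category' | 'bounds' | 'structural'
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __len__(self):
        return len(self.violations)

    def summary(self) -> str:
        if self.ok:
            return "cohort valid: no violations"
        lines = [f"{len(self.violations)} violation(s):"]
        lines += [f"  [{v.kind}] {v.feature} @ {v.patient_id}: {v.message}"
                  for v in self.violations]
        return "\n".join(lines)


def validate(cohort: Cohort, schema: FeatureSchema) -> ValidationReport:
    """Check declared categories, bounds, and structural-missingness rules."""
    unknown = [c for c in cohort.columns if c not in schema]
    if unknown:
        raise ValueError(f"unknown column(s) not in schema: {', '.join(unknown)}")

    report = ValidationReport()
    for col in cohort.columns:
        spec = schema[col]
        series = cohort.values[col]
        obs = series[series.notna()]
        if spec.is_categorical:
            bad = obs[~obs.astype(str).isin(spec.categories)]
            for pid, val in bad.items():
                report.violations.append(Violation(
                    col, pid, "category",
                    f"value {val!r} not among declared categories"))
        else:
            vals = pd.to_numeric(obs, errors="coerce")
            for pid, val in obs[vals.isna()].items():
                report.violations.append(Violation(
                    col, pid, "bounds", f"non-numeric value {val!r}"))
            vals = vals.dropna()
            if spec.bounds is not None:
                lo, hi = spec.bounds
                if lo is not None:
                    for pid, val in vals[vals < lo].items():
                        report.violations.append(Violation(
                            col, pid, "bounds", f"{val} < lower bound {lo}"))
                if hi is not None:
                    for pid, val in vals[vals > hi].items():
                        report.violations.append(Violation(
                            col, pid, "bounds", f"{val} > upper bound {hi}"))
        mp = spec.missing_policy
        if (mp.kind == "structural" and mp.condition_feature in cohort.columns):
            cond = cohort.values[mp.condition_feature].astype("object")
            allowed = cond.isin(mp.condition_values)
            offending = series.notna() & ~allowed
            for pid in series.index[offending]:
                report.violations.append(Violation(
                    col, pid, "structural",
                    f"value present although {mp.condition_feature} is "
                    f"{cond.loc[pid]!r}"))
    return report


# ---------------------------------------------------------------------------
# CSV I/O (UTF-8, comma-separated, empty cell = missing, labels not codes)
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, path) -> None:
    df = cohort.values.copy()
    # format floats compactly but losslessly enough for round trips
    df.to_csv(path, index=True, index_label="patient_id", na_rep="")


def read_cohort(path, schema: FeatureSchema, clean_aliases: bool = False) -> Cohort:
    """Read a cohort CSV; empty cells become missing.

    ``clean_aliases`` additionally accepts the cleaned spellings of
    :data:`CLEAN_ALIASES` in the header and maps them back to canonical names.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "patient_id" in df.columns:
        df = df.set_index("patient_id")
    df = df.replace({"": np.nan})
    if clean_aliases:
        reverse = {v: k for k, v in CLEAN_ALIASES.items()}
        df = df.rename(columns=reverse)
    extra = [c for c in df.columns if c not in schema]
    if extra:
        raise ValueError(f"unknown column(s) in file: {', '.join(extra)}")
    out = {}
    for col in df.columns:
        spec = schema[col]
        if spec.is_categorical:
            out[col] = df[col]
        else:
            parsed = pd.to_numeric(df[col], errors="coerce")
            bad = parsed.isna() & df[col].notna()
            if bad.any():
                pid = df.index[bad][0]
                raise ValueError(
                    f"unparseable numeric cell in column {col!r}, row {pid!r}: "
                    f"{df.loc[pid, col]!r}")
            out[col] = parsed.astype(float)
    return Cohort(pd.DataFrame(out, index=df.index))
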